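"""CDR loop extraction, quality filtering, DTW-RMSD clustering and
canonical-form assignment.

Loops are taken from the IMGT definition (CDR1 27-38, CDR2 56-65, CDR3
105-117).  Before clustering, loops are filtered to structures with
resolution at most 2.8 A, no missing residues, and every backbone atom
B-factor strictly below 80 A^2 ("80 or higher" is removed).

Conformations are compared with a length-independent RMSD: after
superposing the flanking framework anchors (three residues on each side),
the CA traces are aligned by dynamic time warping with the standard
symmetric step pattern; the score is sqrt(total squared distance along the
optimal path / path length).  Among equal-total paths the shortest is used,
which makes the score well defined and, for equal-length loops, never
larger than the classical one-to-one RMSD.

The pairwise DTW-RMSD matrix is clustered with DBSCAN (scikit-learn,
precomputed metric); clusters are mapped to named canonical forms via a
user-suppliable table, and new loops inherit the form of the nearest
cluster medoid when within eps.  CDR3 forms are marked provisional.
Antibody-loop matching is stricter: same length, analogous loop type
(α1<->L1, β1<->H1, ...), ordinary backbone RMSD below 1.5 A after anchor
superposition.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .numbering import CDR_RANGES, NumberedChain, _cdr_labels
from .geometry import kabsch

__all__ = [
    "CDRLoop",
    "ClusterAssignment",
    "NOISE",
    "PROVISIONAL_MARK",
    "ANALOGOUS_LOOPS",
    "extract_cdrs",
    "quality_filter",
    "dtw_rmsd",
    "cluster_cdrs",
    "compute_medoids",
    "assign_canonical",
    "predict_canonical",
    "match_antibody_loop",
    "k_distance_profile",
]

NOISE = -1
PROVISIONAL_MARK = "*"  # appended to CDR3 canonical forms

#: TCR loop name -> analogous antibody loop name.
ANALOGOUS_LOOPS = {
    "A1": "L1", "A2": "L2", "A3": "L3",
    "B1": "H1", "B2": "H2", "B3": "H3",
    "G1": "L1", "G2": "L2", "G3": "L3",
    "D1": "H1", "D2": "H2", "D3": "H3",
}

_LOOP_PREFIX = {"TCRA": "A", "TCRB": "B", "TCRG": "G", "TCRD": "D"}
_ANCHOR_OFFSETS = {
    "CDR1": ((24, 25, 26), (39, 40, 41)),
    "CDR2": ((53, 54, 55), (66, 67, 68)),
    "CDR3": ((102, 103, 104), (118, 119, 120)),
}
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclasses.dataclass
class CDRLoop:
    """An extracted CDR loop with its quality metadata.

    ``ca_coords`` is the ordered N->C CA trace; ``backbone_coords`` (when
    available) stacks N/CA/C/O per residue; ``anchor_coords`` holds the six
    flanking framework CA atoms used for pre-superposition.
    """

    loop_id: tuple[str, str, str]  # (entry, chain, loop name e.g. "B3")
    imgt_range: tuple[int, int]
    ca_coords: np.ndarray
    length: int
    resolution: float | None = None
    max_backbone_bfactor: float = 0.0
    missing_residues: bool = False
    anchor_coords: np.ndarray | None = None
    backbone_coords: np.ndarray | None = None
    sequence: str = ""

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, float)
        if self.length < 1 or len(self.ca_coords) != self.length:
            raise ValueError("loop length must be >= 1 and match the CA trace")


@dataclasses.dataclass
class ClusterAssignment:
    loop_id: tuple[str, str, str]
    cluster_label: int  # NOISE (-1) for noise points
    canonical_form: str | None = None
    medoid_distance: float = float("nan")

    def __post_init__(self) -> None:
        if self.cluster_label == NOISE and self.canonical_form is not None:
            raise ValueError("noise loops cannot carry a canonical form")


# ---------------------------------------------------------------------------
# Extraction and filtering
# ---------------------------------------------------------------------------


def extract_cdrs(
    chain: NumberedChain,
    entry_id: str = "",
    resolution: float | None = None,
) -> list[CDRLoop]:
    """Extract the three CDR loops of a numbered TCR chain.

    A loop is emitted when at least one of its residues is resolved.  The
    missing-residue flag is set when the author numbering shows a gap inside
    the loop span, or when the observed IMGT labels differ from the
    convention labels for the observed loop length (both indicate unresolved
    residues inside the loop).
    """
    prefix = _LOOP_PREFIX.get(chain.chain_type, chain.chain_type[:1])
    loops: list[CDRLoop] = []
    for num, (name, (lo, hi)) in enumerate(CDR_RANGES.items(), start=1):
        residues = chain.imgt_residues(lo, hi)
        residues = [r for r in residues if r.atom("CA") is not None]
        if not residues:
            continue
        labels = [chain.imgt_map[r.key] for r in residues]
        if len(residues) <= hi - lo + 1:
            # a fully observed loop of this length occupies exactly the
            # middle-out convention positions; any other pattern means
            # residues are unresolved
            missing = labels != _cdr_labels(lo, hi, len(residues))
        else:
            missing = False  # inserted loops: rely on the author-gap check
        seq_gap = any(
            b.seq_pos - a.seq_pos > 1 and not (a.icode or b.icode)
            for a, b in zip(residues, residues[1:])
        )
        bfactors = [
            atom.b_factor
            for res in residues
            for atom_name in BACKBONE_ATOMS
            if (atom := res.atom(atom_name)) is not None
        ]
        anchors = []
        pre, post = _ANCHOR_OFFSETS[name]
        for pos in pre + post:
            ca = chain.atom_at(pos, "CA")
            anchors.append(ca)
        anchor_arr = np.array(anchors) if all(a is not None for a in anchors) else None
        backbone = []
        full_backbone = True
        for res in residues:
            atoms = [res.atom(a) for a in BACKBONE_ATOMS]
            if any(a is None for a in atoms):
                full_backbone = False
                break
            backbone.append([a.coords for a in atoms])
        loops.append(
            CDRLoop(
                loop_id=(entry_id, chain.chain_id, f"{prefix}{num}"),
                imgt_range=(lo, hi),
                ca_coords=np.array([r.atom("CA").coords for r in residues]),
                length=len(residues),
                resolution=resolution,
                max_backbone_bfactor=max(bfactors) if bfactors else 0.0,
                missing_residues=missing or seq_gap,
                anchor_coords=anchor_arr,
                backbone_coords=np.array(backbone) if full_backbone else None,
            )
        )
    return loops


def quality_filter(
    loops: Sequence[CDRLoop],
    resolution_max: float = 2.8,
    bfactor_max: float = 80.0,
) -> list[CDRLoop]:
    """Retain loops from structures of sufficient quality.

    Retained iff resolution <= ``resolution_max`` (unknown resolution is
    rejected), no missing residues, and every backbone B-factor is strictly
    below ``bfactor_max``.
    """
    return [
        loop
        for loop in loops
        if loop.resolution is not None
        and loop.resolution <= resolution_max
        and not loop.missing_residues
        and loop.max_backbone_bfactor < bfactor_max
    ]


# ---------------------------------------------------------------------------
# DTW-RMSD
# ---------------------------------------------------------------------------


def _superpose_onto(loop_a: CDRLoop, loop_b: CDRLoop) -> np.ndarray:
    """CA trace of ``loop_b`` in the frame of ``loop_a``.

    Uses the framework anchors when both loops carry them; otherwise the
    loops are compared in their stored frames.
    """
    if loop_a.anchor_coords is not None and loop_b.anchor_coords is not None:
        r, t, _ = kabsch(loop_b.anchor_coords, loop_a.anchor_coords)
        return loop_b.ca_coords @ r.T + t
    return loop_b.ca_coords


def dtw_rmsd(loop_a: CDRLoop, loop_b: CDRLoop) -> float:
    """Length-independent RMSD between two CA traces.

    Dynamic time warping with the symmetric step pattern (diagonal,
    horizontal, vertical); each visited cell contributes its squared
    inter-atom distance; the returned score is
    ``sqrt(total / path_length)`` for the minimum-total path (shortest such
    path on ties).  Symmetric in its arguments.
    """
    if loop_a.length == 0 or loop_b.length == 0:
        raise ValueError("cannot compare empty loops")
    a = loop_a.ca_coords
    b = _superpose_onto(loop_a, loop_b)
    n, m = len(a), len(b)
    cost = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)

    inf = float("inf")
    total = np.full((n, m), inf)
    steps = np.zeros((n, m), dtype=int)
    total[0, 0] = cost[0, 0]
    steps[0, 0] = 1
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = (inf, 0)
            for pi, pj in ((i - 1, j - 1), (i - 1, j), (i, j - 1)):
                if pi >= 0 and pj >= 0:
                    cand = (total[pi, pj] + cost[i, j], steps[pi, pj] + 1)
                    if cand < best:
                        best = cand
            total[i, j], steps[i, j] = best
    return float(np.sqrt(total[n - 1, m - 1] / steps[n - 1, m - 1]))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _pairwise_matrix(loops: Sequence[CDRLoop]) -> np.ndarray:
    n = len(loops)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dtw_rmsd(loops[i], loops[j])
    return mat


def cluster_cdrs(
    loops: Sequence[CDRLoop],
    eps: float = 0.8,
    min_pts: int = 3,
) -> list[ClusterAssignment]:
    """DBSCAN on the pairwise DTW-RMSD matrix.

    Loops are sorted by ``loop_id`` before clustering and cluster labels are
    renumbered in order of first appearance, so the labelling is a
    deterministic function of the input set.  Noise is labelled
    :data:`NOISE`.  ``medoid_distance`` is the DTW-RMSD to the loop's
    cluster medoid (NaN for noise).
    """
    loops = sorted(loops, key=lambda l: l.loop_id)
    if not loops:
        return []
    mat = _pairwise_matrix(loops)
    raw = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit_predict(mat)

    relabel: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab == NOISE:
            labels.append(NOISE)
            continue
        if lab not in relabel:
            relabel[lab] = len(relabel)
        labels.append(relabel[lab])

    medoid_idx = _medoid_indices(mat, labels)
    out = []
    for i, loop in enumerate(loops):
        lab = labels[i]
        dist = float("nan") if lab == NOISE else float(mat[i, medoid_idx[lab]])
        out.append(ClusterAssignment(loop_id=loop.loop_id, cluster_label=lab, medoid_distance=dist))
    return out


def _medoid_indices(mat: np.ndarray, labels: Sequence[int]) -> dict[int, int]:
    medoids: dict[int, int] = {}
    for lab in sorted(set(labels) - {NOISE}):
        members = [i for i, l in enumerate(labels) if l == lab]
        sums = [(mat[np.ix_([i], members)].sum(), i) for i in members]
        medoids[lab] = min(sums)[1]
    return medoids


def compute_medoids(
    loops: Sequence[CDRLoop], assignments: Sequence[ClusterAssignment]
) -> dict[int, CDRLoop]:
    """Cluster label -> medoid loop (minimum summed DTW-RMSD to members)."""
    loops = sorted(loops, key=lambda l: l.loop_id)
    labels = [a.cluster_label for a in sorted(assignments, key=lambda a: a.loop_id)]
    mat = _pairwise_matrix(loops)
    return {lab: loops[i] for lab, i in _medoid_indices(mat, labels).items()}


def assign_canonical(
    assignments: Sequence[ClusterAssignment],
    named_forms: Mapping[int, str],
    provisional_prefixes: tuple[str, ...] = ("A3", "B3", "G3", "D3"),
) -> list[ClusterAssignment]:
    """Attach canonical-form labels to clustered loops.

    Cluster members inherit their cluster's named form; CDR3 forms carry a
    provisional marker because those assignments are early-stage.  Noise
    loops keep no form.
    """
    for a in assignments:
        if a.cluster_label == NOISE:
            a.canonical_form = None
            continue
        form = named_forms.get(a.cluster_label)
        if form is not None and a.loop_id[2] in provisional_prefixes:
            form += PROVISIONAL_MARK
        a.canonical_form = form
    return list(assignments)


def predict_canonical(
    loop: CDRLoop,
    medoids: Mapping[int, CDRLoop],
    named_forms: Mapping[int, str],
    eps: float = 0.8,
) -> str | None:
    """Canonical form for a new loop: nearest medoid's form iff within eps."""
    best: tuple[float, int] | None = None
    for lab in sorted(medoids):
        dist = dtw_rmsd(medoids[lab], loop)
        if best is None or dist < best[0]:
            best = (dist, lab)
    if best is None or best[0] > eps:
        return None
    form = named_forms.get(best[1])
    if form is not None and loop.loop_id[2] in ("A3", "B3", "G3", "D3"):
        form += PROVISIONAL_MARK
    return form


# ---------------------------------------------------------------------------
# Antibody loop matching
# ---------------------------------------------------------------------------


def _backbone_or_ca(loop: CDRLoop) -> np.ndarray:
    if loop.backbone_coords is not None:
        return loop.backbone_coords.reshape(-1, 3)
    return loop.ca_coords


def match_antibody_loop(
    tcr_loop: CDRLoop,
    antibody_loops: Sequence[CDRLoop],
    cutoff: float = 1.5,
) -> list[tuple[CDRLoop, float]]:
    """Antibody loops within 1.5 A length-matched backbone RMSD.

    Candidates must have the same length and the analogous loop type
    (α1<->L1, β3<->H3, ...).  RMSD is the ordinary one-to-one backbone RMSD
    after anchor superposition; matches (RMSD strictly below the cutoff) are
    returned sorted by ascending RMSD.
    """
    analog = ANALOGOUS_LOOPS.get(tcr_loop.loop_id[2])
    ref = _backbone_or_ca(tcr_loop)
    matches = []
    for ab in antibody_loops:
        if ab.length != tcr_loop.length or ab.loop_id[2] != analog:
            continue
        coords = _backbone_or_ca(ab)
        if coords.shape != ref.shape:
            continue
        if tcr_loop.anchor_coords is not None and ab.anchor_coords is not None:
            r, t, _ = kabsch(ab.anchor_coords, tcr_loop.anchor_coords)
            coords = coords @ r.T + t
        rmsd = float(np.sqrt(((ref - coords) ** 2).sum() / len(ref)))
        if rmsd < cutoff:
            matches.append((ab, rmsd))
    matches.sort(key=lambda t: (t[1], t[0].loop_id))
    return matches


def k_distance_profile(loops: Sequence[CDRLoop], k: int = 3) -> np.ndarray:
    """Sorted k-th nearest-neighbour DTW-RMSD distances (eps selection aid)."""
    loops = sorted(loops, key=lambda l: l.loop_id)
    if len(loops) <= k:
        return np.array([])
    mat = _pairwise_matrix(loops)
    kth = np.sort(mat, axis=1)[:, k]
    return np.sort(kth)
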