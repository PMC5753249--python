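"""Synthetic ground-truth fixtures for every curation stage.

Generates idealised structures whose chains carry the bundled consensus
sequences (so domain detection and IMGT numbering behave exactly as on the
profiles themselves) and whose landmark atoms are placed to satisfy
requested geometric predicates to within 1e-6 A: the TCR cysteine-104
distance, the four MHC pairing distances, planted CDR3/groove-helix contact
counts (each planted contact contributes exactly one CB-CB pair within the
cutoff), and antigen/hapten placements.  Framework cores of TCR chains are
laid out as rigid copies of the bundled orientation reference core, so
frame registration on fixtures is exact.

Geometry is deliberately non-physical (poly-consensus chains threaded along
construction paths); the fixtures exist to exercise the geometric
predicates, not to look like proteins.  All generators are deterministic
functions of the seed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from .cdr_clustering import CDRLoop
from .geometry import load_reference_core
from .numbering import Profile, load_profiles
from .structure_io import Atom, Chain, Residue, Structure, _format_atom_line

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "GeometryError",
    "make_tcr_mhc_fixture",
    "make_two_complex_entry",
    "make_loop_set",
    "write_fixture_pdb",
    "write_ground_truth_tsv",
]

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

CB_OFFSET = np.array([0.0, 0.0, 1.5])


class GeometryError(ValueError):
    """A requested fixture layout is not geometrically realisable."""


@dataclasses.dataclass
class FixtureSpec:
    """Declarative layout for a synthetic TCR-MHC fixture."""

    seed: int = 0
    entry_id: str = "synt"
    # --- TCR
    tcr_cys_dist: float = 15.0          # target CA104-CA104 distance, A
    beta_type: str = "TCRB"             # TCRB or TCRD
    alpha_type: str = "TCRA"            # TCRA or TCRG
    species: str = "human"
    # --- MHC; constraint targets as fractions of the published maxima, or
    #     explicit distances in A when mhc_distances is set
    mhc_class: str = "MH1"              # MH1 | CD1 | MR1 | MH2 | none
    mhc_fraction: float = 0.5
    mhc_distances: tuple[float, float, float, float] | None = None
    # --- complex
    n_contacts: int = 7                 # planted CDR3/helix CB pairs <= 8 A
    decoy_contacts: int | None = None   # adds a second MHC pair with this count
    contact_dist: float = 5.0           # planted CB-CB distance, A
    # --- antigen
    antigen: str | None = "peptide"     # peptide | protein | hapten | None
    peptide_len: int = 9
    # --- metadata
    resolution: float = 2.0
    b_factor: float = 20.0

    def __post_init__(self) -> None:
        if self.tcr_cys_dist <= 0 or self.contact_dist <= 0:
            raise ValueError("target distances must be positive")


@dataclasses.dataclass
class GroundTruth:
    """The intended annotations planted in a fixture."""

    entry_id: str
    tcr_pairs: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)
    mhc_pairs: list[tuple[str, tuple[str, str]]] = dataclasses.field(default_factory=list)
    complexes: list[tuple[str, str, int]] = dataclasses.field(default_factory=list)
    # (tcr beta chain, antigen id, antigen type)
    antigens: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)
    decoy_counts: dict[str, int] = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# Low-level builders
# ---------------------------------------------------------------------------


def _profile(chain_type: str, species: str) -> Profile:
    for p in load_profiles():
        if p.chain_type == chain_type and p.species == species:
            return p
    raise KeyError(f"no bundled profile for {chain_type}/{species}")


def _residue_atoms(aa: str, ca: np.ndarray, b_factor: float) -> list[Atom]:
    atoms = [
        Atom("N", "N", ca + (-1.2, 0.4, 0.2), 1.0, b_factor),
        Atom("CA", "C", ca.copy(), 1.0, b_factor),
        Atom("C", "C", ca + (1.2, 0.4, 0.2), 1.0, b_factor),
        Atom("O", "O", ca + (1.4, 1.6, 0.2), 1.0, b_factor),
    ]
    if aa != "G":
        atoms.append(Atom("CB", "C", ca + CB_OFFSET, 1.0, b_factor))
    return atoms


def _build_chain(
    chain_id: str,
    sequence: str,
    placed: dict[int, np.ndarray],
    line_origin: np.ndarray,
    line_dir: np.ndarray,
    b_factor: float,
    spacing: float = 3.0,
) -> Chain:
    """A chain whose CA path follows ``line_origin + i*spacing*dir`` except
    at explicitly placed indices."""
    line_dir = np.asarray(line_dir, float)
    line_dir = line_dir / np.linalg.norm(line_dir)
    residues = []
    for i, aa in enumerate(sequence):
        ca = placed.get(i)
        if ca is None:
            ca = np.asarray(line_origin, float) + i * spacing * line_dir
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_pos=i + 1,
                icode="",
                res_name=_AA3.get(aa, "ALA"),
                atoms=_residue_atoms(aa, np.asarray(ca, float), b_factor),
            )
        )
    return Chain(chain_id=chain_id, residues=residues)


def _sphere_intersection(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float, branch: np.ndarray
) -> np.ndarray:
    """A point at distance r1 from c1 and r2 from c2, on the ``branch`` side."""
    d = float(np.linalg.norm(c2 - c1))
    if d > r1 + r2 or d < abs(r1 - r2) or d == 0:
        raise GeometryError(
            f"spheres (r={r1}, r={r2}) at distance {d:.2f} do not intersect"
        )
    u = (c2 - c1) / d
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = math.sqrt(max(r1 * r1 - a * a, 0.0))
    v = np.cross(u, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(v) < 1e-9:
        v = np.cross(u, np.array([0.0, 1.0, 0.0]))
    v /= np.linalg.norm(v)
    if np.dot(v, branch) < 0:
        v = -v
    return c1 + a * u + h * v


def _index_of(profile: Profile, position: int) -> int:
    return profile.positions.index(position)


# ---------------------------------------------------------------------------
# TCR-MHC complex fixture
# ---------------------------------------------------------------------------


def _place_mhc(
    spec: FixtureSpec,
    chain_ids: tuple[str, str],
    offset: np.ndarray,
    b_factor: float,
) -> tuple[list[Chain], dict[str, np.ndarray], np.ndarray]:
    """Build an MHC pair; returns chains, landmark map and helix CB line.

    Groove helix 1 runs along +x with 10 A spacing at ``offset``, so every
    planted CDR3 contact hits exactly one helix CB.
    """
    if spec.mhc_class in ("MH1", "CD1", "MR1"):
        groove = _profile(spec.mhc_class, "human" if spec.mhc_class != "MH1" else spec.species)
        partner = _profile("B2M", spec.species)
        maxima = (32.0, 32.0, 32.0, 37.0)
        cons_pos = ((15, 23), (15, 104), (51, 23), (51, 104))
        helix2_z = 16.0
    elif spec.mhc_class == "MH2":
        groove = _profile("MH2A", spec.species)
        partner = _profile("MH2B", spec.species)
        maxima = (34.0, 22.0, 32.0, 28.0)
        cons_pos = ((29, 64), (29, 39), (37, 64), (37, 39))
        helix2_z = None
    else:
        raise ValueError(f"unsupported mhc_class {spec.mhc_class}")

    targets = spec.mhc_distances or tuple(spec.mhc_fraction * m for m in maxima)

    placed_g: dict[int, np.ndarray] = {}
    helix_line = []
    # groove helix: positions 50.. along +x, 10 A apart
    for pos in range(50, 93):
        if pos in groove.positions:
            pt = offset + np.array([10.0 * (pos - 50), 0.0, 0.0])
            placed_g[_index_of(groove, pos)] = pt
            helix_line.append(pt)
    if helix2_z is not None:  # second groove domain of MH1-like chains
        for pos in range(1050, 1093):
            if pos in groove.positions:
                placed_g[_index_of(groove, pos)] = offset + np.array(
                    [10.0 * (pos - 1050), 0.0, helix2_z]
                )
    # strand floor below the groove
    floor = [p for p in groove.positions if p < 50 or (1000 < p < 1050)]
    for k, pos in enumerate(floor):
        placed_g[_index_of(groove, pos)] = offset + np.array([1.5 * k, -12.0, 6.0])

    g_land = {
        pair[0]: placed_g[_index_of(groove, pair[0])] for pair in cons_pos
    }
    # partner landmarks from the four sphere constraints (branch away from
    # the TCR, which sits at positive y)
    p_first = _sphere_intersection(
        g_land[cons_pos[0][0]], targets[0], g_land[cons_pos[2][0]], targets[2],
        branch=np.array([0.0, -1.0, 0.0]),
    )
    p_second = _sphere_intersection(
        g_land[cons_pos[1][0]], targets[1], g_land[cons_pos[3][0]], targets[3],
        branch=np.array([0.0, -1.0, 0.0]),
    )
    first_pos, second_pos = cons_pos[0][1], cons_pos[1][1]
    i_first = _index_of(partner, first_pos)
    i_second = _index_of(partner, second_pos)
    placed_p: dict[int, np.ndarray] = {i_first: p_first, i_second: p_second}
    lo, hi = sorted((i_first, i_second))
    span = placed_p[hi] - placed_p[lo]
    for i in range(lo + 1, hi):
        placed_p[i] = placed_p[lo] + span * (i - lo) / (hi - lo)

    chains = [
        _build_chain(
            chain_ids[0], groove.sequence, placed_g,
            offset + np.array([0.0, -30.0, 0.0]), np.array([1.0, 0.0, 0.0]), b_factor,
        ),
        _build_chain(
            chain_ids[1], partner.sequence, placed_p,
            placed_p[lo] + np.array([0.0, -15.0, 0.0]), np.array([1.0, 0.0, 0.0]),
            b_factor,
        ),
    ]
    landmarks = {f"{chain_ids[0]}:{p}": g_land[p] for p in g_land}
    landmarks[f"{chain_ids[1]}:{first_pos}"] = p_first
    landmarks[f"{chain_ids[1]}:{second_pos}"] = p_second
    return chains, landmarks, np.array(helix_line)


def _place_tcr(
    spec: FixtureSpec,
    chain_ids: tuple[str, str],
    helix_line: np.ndarray,
    decoy_helix: np.ndarray | None,
    offset: np.ndarray,
    b_factor: float,
) -> tuple[list[Chain], dict[str, int]]:
    """Build the two TCR chains.

    Framework cores are rigid copies of the orientation reference core
    translated above the groove; the cysteine-104 separation equals the
    requested distance exactly.  The beta-like chain's CDR3 CAs are planted
    so that exactly ``n_contacts`` CB pairs fall within the contact cutoff
    (and ``decoy_contacts`` pairs against the decoy helix, when requested).
    """
    core = load_reference_core()
    beta = _profile(spec.beta_type, spec.species)
    alpha = _profile(spec.alpha_type, spec.species)

    base = offset + np.array([0.0, 45.0, 5.0])
    c104 = core[104]
    # oblique inter-domain offset and a fixed alpha-domain rotation keep the
    # two frames in general position (no degenerate orientation torsion)
    direction = np.array([0.55, 0.6, 0.58])
    shift = spec.tcr_cys_dist * direction / np.linalg.norm(direction)
    cz, sz = math.cos(0.7), math.sin(0.7)
    cx, sx = math.cos(0.4), math.sin(0.4)
    rot_a = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]]) @ np.array(
        [[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]]
    )

    placed_b: dict[int, np.ndarray] = {}
    placed_a: dict[int, np.ndarray] = {}
    for pos, pt in core.items():
        if pos in beta.positions:
            placed_b[_index_of(beta, pos)] = base + (pt - c104)
        if pos in alpha.positions:
            placed_a[_index_of(alpha, pos)] = base + shift + rot_a @ (pt - c104)

    cdr3_idx = [i for i, p in enumerate(beta.positions) if 105 <= p <= 117]
    n_main = spec.n_contacts
    n_decoy = spec.decoy_contacts or 0
    if n_main + n_decoy > len(cdr3_idx):
        raise GeometryError(
            f"cannot plant {n_main}+{n_decoy} contacts on a "
            f"{len(cdr3_idx)}-residue CDR3"
        )
    if n_main > len(helix_line) or (decoy_helix is not None and n_decoy > len(decoy_helix)):
        raise GeometryError("more planted contacts than helix positions")
    for j in range(n_main):
        placed_b[cdr3_idx[j]] = helix_line[j] + np.array([0.0, 0.0, spec.contact_dist])
    for j in range(n_decoy):
        placed_b[cdr3_idx[n_main + j]] = decoy_helix[j] + np.array(
            [0.0, 0.0, spec.contact_dist]
        )
    for j in range(n_main + n_decoy, len(cdr3_idx)):
        placed_b[cdr3_idx[j]] = offset + np.array([5.0 * j, 150.0, 0.0])
    # alpha CDR3 far from every helix so only planted contacts count
    for j, idx in enumerate(i for i, p in enumerate(alpha.positions) if 105 <= p <= 117):
        placed_a[idx] = offset + np.array([5.0 * j, 170.0, 0.0])

    chains = [
        _build_chain(chain_ids[0], beta.sequence, placed_b,
                     base + np.array([0.0, 25.0, 0.0]), np.array([1.0, 0.0, 0.0]), b_factor),
        _build_chain(chain_ids[1], alpha.sequence, placed_a,
                     base + shift + np.array([0.0, 25.0, 0.0]), np.array([1.0, 0.0, 0.0]),
                     b_factor),
    ]
    return chains, {"n_main": n_main, "n_decoy": n_decoy}


def _place_peptide(
    chain_id: str, length: int, floor_anchor: np.ndarray, b_factor: float
) -> Chain:
    """A short peptide threaded 4 A below the groove floor (within the 8 A
    complex-contact cutoff of the floor CB atoms)."""
    seq = ("ASGAYKAGL" * 4)[:length]
    placed = {i: floor_anchor + np.array([4.0 * i, -4.0, 0.0]) for i in range(length)}
    return _build_chain(chain_id, seq, placed, floor_anchor, np.array([1, 0, 0]), b_factor)


def _place_hapten(
    chain_id: str, helix_point: np.ndarray, b_factor: float
) -> Residue:
    """A small ligand bridging the groove: 2.5 A below a helix CB (within
    the 3.5 A MHC cutoff) and 7.5 A from the CDR3 CB planted above it."""
    anchor = helix_point + CB_OFFSET + np.array([0.0, 0.0, -2.5])
    atoms = [
        Atom("C1", "C", anchor, 1.0, b_factor),
        Atom("C2", "C", anchor + (1.4, 0.0, 0.0), 1.0, b_factor),
        Atom("O1", "O", anchor + (0.0, 1.3, 0.0), 1.0, b_factor),
        Atom("N1", "N", anchor + (-1.3, 0.5, 0.0), 1.0, b_factor),
    ]
    return Residue(
        chain_id=chain_id, seq_pos=1, icode="", res_name="LIG",
        atoms=atoms, is_polymer=False, is_hapten=True,
    )


def make_tcr_mhc_fixture(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Generate one TCR(-MHC)(-antigen) fixture with its ground truth."""
    b = spec.b_factor
    chains: list[Chain] = []
    truth = GroundTruth(entry_id=spec.entry_id)

    helix_line = np.empty((0, 3))
    decoy_helix = None
    if spec.mhc_class == "none":
        # an unbound TCR has nothing to plant contacts against
        spec = dataclasses.replace(spec, n_contacts=0, decoy_contacts=None)
    if spec.mhc_class != "none":
        mhc_chains, _, helix_line = _place_mhc(spec, ("A", "B"), np.zeros(3), b)
        chains.extend(mhc_chains)
        klass = spec.mhc_class
        truth.mhc_pairs.append((klass, ("A", "B")))
        if spec.decoy_contacts is not None:
            decoy_chains, _, decoy_helix = _place_mhc(
                spec, ("F", "G"), np.array([0.0, 0.0, -60.0]), b
            )
            chains.extend(decoy_chains)
            truth.mhc_pairs.append((klass, ("F", "G")))

    tcr_chains, counts = _place_tcr(
        spec, ("E", "D"), helix_line, decoy_helix, np.zeros(3), b
    )
    chains.extend(tcr_chains)
    if spec.beta_type == "TCRB" and spec.alpha_type == "TCRA":
        tcr_type = "alphabeta"
    elif spec.beta_type == "TCRD" and spec.alpha_type == "TCRG":
        tcr_type = "gammadelta"
    else:
        tcr_type = "other-paired"
    truth.tcr_pairs.append(("E", "D", tcr_type))
    if spec.mhc_class != "none" and counts["n_main"] > 0:
        truth.complexes.append(("E", "A", counts["n_main"]))
        if counts["n_decoy"]:
            truth.decoy_counts["F"] = counts["n_decoy"]

    hapten_residue = None
    if spec.antigen in ("peptide", "protein") and spec.mhc_class != "none":
        length = spec.peptide_len if spec.antigen == "peptide" else 40
        floor_anchor = np.array([0.0, -12.0, 6.0])
        chains.append(_place_peptide("C", length, floor_anchor, b))
        truth.antigens.append(("E", "C", spec.antigen))
    elif spec.antigen == "hapten" and spec.mhc_class != "none":
        hapten_residue = _place_hapten("C", helix_line[0], b)
        chains.append(Chain(chain_id="C", residues=[hapten_residue]))
        truth.antigens.append(("E", "C/LIG1", "hapten"))

    chains.sort(key=lambda c: c.chain_id)
    structure = Structure(
        entry_id=spec.entry_id,
        chains=chains,
        resolution=spec.resolution,
        experiment_method="SYNTHETIC",
    )
    _validate_fixture(structure, spec, truth)
    return structure, truth


def _validate_fixture(structure: Structure, spec: FixtureSpec, truth: GroundTruth) -> None:
    """Construction self-check: landmark predicates hold to 1e-6 A."""
    by_id = {c.chain_id: c for c in structure.chains}
    beta = _profile(spec.beta_type, spec.species)
    alpha = _profile(spec.alpha_type, spec.species)
    ca_b = by_id["E"].residues[_index_of(beta, 104)].atom("CA").coords
    ca_a = by_id["D"].residues[_index_of(alpha, 104)].atom("CA").coords
    if abs(np.linalg.norm(ca_b - ca_a) - spec.tcr_cys_dist) > 1e-6:
        raise GeometryError("cysteine-104 distance not realised")
    if spec.mhc_class != "none":
        if spec.mhc_class == "MH2":
            groove = _profile("MH2A", spec.species)
            partner = _profile("MH2B", spec.species)
            cons_pos = ((29, 64), (29, 39), (37, 64), (37, 39))
            maxima = (34.0, 22.0, 32.0, 28.0)
        else:
            groove = _profile(spec.mhc_class, "human" if spec.mhc_class != "MH1" else spec.species)
            partner = _profile("B2M", spec.species)
            cons_pos = ((15, 23), (15, 104), (51, 23), (51, 104))
            maxima = (32.0, 32.0, 32.0, 37.0)
        targets = spec.mhc_distances or tuple(spec.mhc_fraction * m for m in maxima)
        for (pg, pp), target in zip(cons_pos, targets):
            cg = by_id["A"].residues[_index_of(groove, pg)].atom("CA").coords
            cp = by_id["B"].residues[_index_of(partner, pp)].atom("CA").coords
            if abs(np.linalg.norm(cg - cp) - target) > 1e-6:
                raise GeometryError(f"MHC constraint {pg}-{pp} not realised")


def make_two_complex_entry(seed: int = 0) -> tuple[Structure, GroundTruth]:
    """A synthetic two-TCR entry emulating the chain topology of a PDB
    entry that contains two copies of a TCR-peptide-MH1 complex (such as
    2vlr): TCR E-D binds peptide C presented by MH1 pair A-B, and TCR J-I
    binds peptide H presented by F-G.

    This is a synthetic stand-in constructed by the fixture generator, not
    the experimental structure.
    """
    spec = FixtureSpec(seed=seed, entry_id="2syn")
    first, truth1 = make_tcr_mhc_fixture(spec)
    second, _ = make_tcr_mhc_fixture(spec)
    rename = {"A": "F", "B": "G", "C": "H", "E": "J", "D": "I"}
    shift = np.array([0.0, 400.0, 0.0])
    for chain in second.chains:
        new_id = rename[chain.chain_id]
        chain.chain_id = new_id
        for res in chain.residues:
            res.chain_id = new_id
            for atom in res.atoms:
                atom.coords = atom.coords + shift
    chains = sorted(first.chains + second.chains, key=lambda c: c.chain_id)
    structure = Structure(
        entry_id="2syn", chains=chains, resolution=spec.resolution,
        experiment_method="SYNTHETIC",
    )
    truth = GroundTruth(
        entry_id="2syn",
        tcr_pairs=[("E", "D", "alphabeta"), ("J", "I", "alphabeta")],
        mhc_pairs=[("MH1", ("A", "B")), ("MH1", ("F", "G"))],
        complexes=[("E", "A", spec.n_contacts), ("J", "F", spec.n_contacts)],
        antigens=[("E", "C", "peptide"), ("J", "H", "peptide")],
    )
    return structure, truth


# ---------------------------------------------------------------------------
# Loop sets with planted conformational clusters
# ---------------------------------------------------------------------------


def make_loop_set(
    n_clusters: int = 2,
    loops_per_cluster: int = 10,
    sigma: float = 0.1,
    separation: float = 5.0,
    lengths: tuple[int, ...] | None = None,
    loop_name: str = "B3",
    seed: int = 0,
) -> tuple[list[CDRLoop], list[int]]:
    """Loops drawn from planted conformational clusters.

    Cluster k's template is a smooth planar curve displaced by
    ``k * separation`` along z, so the inter-template DTW-RMSD is at least
    the requested separation (every cross-cluster atom pair is at least that
    far apart); members add isotropic Gaussian noise of scale ``sigma``.
    All loops share identical framework anchors, making the anchor
    superposition the identity.  Returns (loops, true labels).
    """
    if n_clusters < 1 or loops_per_cluster < 1:
        raise ValueError("need at least one cluster and one loop per cluster")
    rng = np.random.default_rng(seed)
    lengths = lengths or tuple(11 + (k % 3) for k in range(n_clusters))
    if len(lengths) != n_clusters:
        raise ValueError("one length per cluster is required")
    anchors = np.array(
        [[-9.0, 0, 0], [-6.0, 0, 0], [-3.0, 0, 0], [33.0, 0, 0], [36.0, 0, 0], [39.0, 0, 0]]
    )
    loops: list[CDRLoop] = []
    labels: list[int] = []
    for k in range(n_clusters):
        length = lengths[k]
        t = np.linspace(0, 1, length)
        template = np.stack(
            [30 * t, 8 * np.sin(np.pi * t) * (1 + 0.3 * k), np.full(length, k * separation)],
            axis=1,
        )
        for m in range(loops_per_cluster):
            coords = template + rng.normal(0.0, sigma, size=template.shape)
            loops.append(
                CDRLoop(
                    loop_id=("loopset", f"{k:02d}{m:02d}", loop_name),
                    imgt_range=(105, 117),
                    ca_coords=coords,
                    length=length,
                    resolution=2.0,
                    max_backbone_bfactor=20.0,
                    anchor_coords=anchors.copy(),
                )
            )
            labels.append(k)
    return loops, labels


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fixture_pdb(structure: Structure, path: str | Path) -> None:
    """Write a fixture as a plain PDB file (with a resolution record)."""
    header = "HEADER    SYNTHETIC FIXTURE"
    lines = [f"{header:<62s}{structure.entry_id.upper()[:4]:<4s}"]
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS."
        )
    serial = 0
    for chain in structure.chains:
        last = None
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(
                    _format_atom_line(
                        serial, atom, res.res_name, chain.chain_id,
                        res.seq_pos, res.icode, hetero=not res.is_polymer,
                    )
                )
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last.res_name:>3s} {chain.chain_id:1s}"
                f"{last.seq_pos:4d}{last.icode or ' ':1s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ground_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    lines = ["record\tfields"]
    for b, a, t in truth.tcr_pairs:
        lines.append(f"tcr_pair\t{b},{a},{t}")
    for klass, ids in truth.mhc_pairs:
        lines.append(f"mhc_pair\t{klass},{ids[0]},{ids[1]}")
    for tcr, mhc, count in truth.complexes:
        lines.append(f"complex\t{tcr},{mhc},{count}")
    for tcr, ag, kind in truth.antigens:
        lines.append(f"antigen\t{tcr},{ag},{kind}")
    Path(path).write_text("\n".join(lines) + "\n")
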