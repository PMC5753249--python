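"""Variable-domain orientation, docking angle and orientation similarity.

The relative pose of the two variable domains of an αβ TCR is summarised by
six parameters in the style of the antibody orientation-angle method: one
torsion (BA), four bend angles (BC1, BC2, AC1, AC2) and the inter-domain
distance dc.  A frame is registered on each domain by least-squares
superposition of its framework-core CA atoms onto a bundled reference core;
the parameters are then pure functions of the two frames, hence invariant
under any common rigid transform.  Absolute values are convention-dependent
(they depend on the bundled core); relative comparisons and invariances are
the contract.

The docking angle describes how the TCR engages the MHC groove: the angle
between the inter-domain cysteine axis (Vβ 104 CA -> Vα 104 CA) and the
first principal axis of the groove-helix CA atoms, both projected into the
groove plane (span of the first two principal axes).  The helix axis is
oriented along the helix chain direction so the angle is a deterministic
value in [0, 180).

Orientation similarity between a TCR and an antibody is the unweighted
Euclidean distance over the six homologous parameters (HL<->BA and so on);
two receptors are similar when the distance is at most 10.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .numbering import NumberedChain

__all__ = [
    "DomainFrame",
    "OrientationParams",
    "DockingGeometry",
    "CoverageError",
    "DegenerateGeometryError",
    "UnsupportedReceptorError",
    "PARAM_NAMES_TCR",
    "PARAM_NAMES_AB",
    "kabsch",
    "load_reference_core",
    "register_frame",
    "compute_trangle",
    "trangle_for_pair",
    "docking_angle_from_points",
    "compute_docking_angle",
    "d_abangle",
    "find_similar_antibody",
    "read_antibody_table",
]

PARAM_NAMES_TCR = ("BA", "BC1", "BC2", "AC1", "AC2", "dc")
PARAM_NAMES_AB = ("HL", "HC1", "HC2", "LC1", "LC2", "dc")


class CoverageError(ValueError):
    """Too few framework-core positions with CA coordinates."""


class DegenerateGeometryError(ValueError):
    """Geometry does not define the requested quantity (e.g. dc = 0)."""


class UnsupportedReceptorError(TypeError):
    """Orientation parameters are only defined for αβ TCRs."""


@dataclasses.dataclass
class DomainFrame:
    """A right-handed orthonormal frame registered on a variable domain."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns are the unit axis vectors
    source_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame is left-handed")


@dataclasses.dataclass
class OrientationParams:
    """Six orientation parameters: five angles (degrees) + dc (Angstrom)."""

    values: tuple[float, float, float, float, float, float]
    names: tuple[str, ...] = PARAM_NAMES_TCR

    def __post_init__(self) -> None:
        if len(self.values) != 6:
            raise ValueError("six parameters are required")
        for angle in self.values[:5]:
            if not -180.0 < angle <= 180.0:
                raise ValueError(f"angle {angle} outside (-180, 180]")
        if self.values[5] <= 0:
            raise ValueError("dc must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[self.names.index(name)]


@dataclasses.dataclass
class DockingGeometry:
    docking_angle: float  # degrees in [0, 180)
    tcr_axis: np.ndarray
    mhc_helix_axis: np.ndarray
    n_helix_atoms: int = 0

    def __post_init__(self) -> None:
        for v in (self.tcr_axis, self.mhc_helix_axis):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
                raise ValueError("axis vectors must be unit-norm")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t, rmsd) with ``R @ mobile_i + t ~= target_i`` and
    ``det(R) = +1``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - r @ mc
    rmsd = float(np.sqrt(((mobile @ r.T + t - target) ** 2).sum() / len(mobile)))
    return r, t, rmsd


_CORE_CACHE: dict[int, np.ndarray] | None = None


def load_reference_core() -> dict[int, np.ndarray]:
    """The bundled reference core: IMGT position -> canonical CA coordinates."""
    global _CORE_CACHE
    if _CORE_CACHE is None:
        text = resources.files("tcrcurate").joinpath("data/reference_core.txt").read_text()
        core = {}
        for line in text.splitlines():
            if line.startswith("#") or not line.strip():
                continue
            pos, x, y, z = line.split()
            core[int(pos)] = np.array([float(x), float(y), float(z)])
        _CORE_CACHE = core
    return _CORE_CACHE


def register_frame(
    domain: NumberedChain | dict[int, np.ndarray],
    core_positions: Sequence[int] | None = None,
) -> DomainFrame:
    """Register the orientation frame on a numbered variable domain.

    ``domain`` may be a numbered chain or a plain {IMGT position -> CA
    coordinate} mapping.  At least 80% of the requested core positions must
    have coordinates.
    """
    core = load_reference_core()
    positions = tuple(core_positions) if core_positions else tuple(sorted(core))
    obs: dict[int, np.ndarray] = {}
    for pos in positions:
        if pos not in core:
            continue
        if isinstance(domain, dict):
            ca = domain.get(pos)
        else:
            ca = domain.atom_at(pos, "CA")
        if ca is not None:
            obs[pos] = np.asarray(ca, float)
    if len(obs) < 0.8 * len(positions):
        missing = sorted(set(positions) - set(obs))
        raise CoverageError(
            f"only {len(obs)}/{len(positions)} core positions present; missing {missing}"
        )
    used = sorted(obs)
    ref = np.array([core[p] for p in used])
    tgt = np.array([obs[p] for p in used])
    r, t, _ = kabsch(ref, tgt)
    return DomainFrame(origin=t, axes=r, source_positions=tuple(used))


# ---------------------------------------------------------------------------
# Orientation parameters
# ---------------------------------------------------------------------------


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return float(np.degrees(np.arccos(c)))


def _torsion_deg(u: np.ndarray, axis: np.ndarray, v: np.ndarray) -> float:
    """Signed dihedral from u to v about axis, in (-180, 180]."""
    axis = axis / np.linalg.norm(axis)
    up = u - np.dot(u, axis) * axis
    vp = v - np.dot(v, axis) * axis
    if np.linalg.norm(up) < 1e-12 or np.linalg.norm(vp) < 1e-12:
        raise DegenerateGeometryError("axis-parallel vector in torsion")
    ang = _angle_deg(up, vp)
    sign = np.sign(np.dot(np.cross(up, vp), axis))
    ang = ang if sign >= 0 else -ang
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def compute_trangle(frame_b: DomainFrame, frame_a: DomainFrame) -> OrientationParams:
    """Six orientation parameters from the beta-like and alpha-like frames.

    BA is the torsion between the two first domain axes about the
    inter-domain vector C; BC1/BC2 (AC1/AC2) are the bend angles of the
    beta (alpha) domain axes against C (-C); dc is |C|.  Coincident origins
    do not define C and raise :class:`DegenerateGeometryError`.
    """
    c = frame_a.origin - frame_b.origin
    dc = float(np.linalg.norm(c))
    if dc < 1e-9:
        raise DegenerateGeometryError("domain origins coincide; dc undefined")
    b1, b2 = frame_b.axes[:, 0], frame_b.axes[:, 1]
    a1, a2 = frame_a.axes[:, 0], frame_a.axes[:, 1]
    ba = _torsion_deg(b1, c, a1)
    return OrientationParams(
        values=(
            ba,
            _angle_deg(b1, c),
            _angle_deg(b2, c),
            _angle_deg(a1, -c),
            _angle_deg(a2, -c),
            dc,
        )
    )


def trangle_for_pair(tcr_pair, chains: Sequence[NumberedChain]) -> OrientationParams:
    """Orientation parameters for a paired αβ TCR.

    γδ and other pairings raise :class:`UnsupportedReceptorError` (the
    method is restricted to αβ TCRs); unpaired chains raise ``ValueError``.
    """
    from .pairing import TCR_AB, TCR_UNPAIRED  # local import avoids a cycle

    if tcr_pair.tcr_type == TCR_UNPAIRED:
        raise ValueError("orientation requires a paired TCR")
    if tcr_pair.tcr_type != TCR_AB:
        raise UnsupportedReceptorError(
            f"orientation parameters are not computed for {tcr_pair.tcr_type} receptors"
        )
    by_id = {c.chain_id: c for c in chains}
    frame_b = register_frame(by_id[tcr_pair.beta_like_chain])
    frame_a = register_frame(by_id[tcr_pair.alpha_like_chain])
    return compute_trangle(frame_b, frame_a)


# ---------------------------------------------------------------------------
# Docking angle
# ---------------------------------------------------------------------------


def docking_angle_from_points(
    cys_beta: np.ndarray,
    cys_alpha: np.ndarray,
    helix_points: np.ndarray,
) -> DockingGeometry:
    """Docking angle from raw coordinates.

    ``helix_points`` are groove-helix CA coordinates in chain order; their
    first principal axis (oriented along the chain direction) is the helix
    axis, and the first two principal axes span the groove plane.
    """
    helix_points = np.asarray(helix_points, float)
    if helix_points.ndim != 2 or len(helix_points) < 8:
        raise CoverageError("at least 8 helix CA atoms are required")
    cys_beta = np.asarray(cys_beta, float)
    cys_alpha = np.asarray(cys_alpha, float)

    centred = helix_points - helix_points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    pc1, pc2 = vt[0], vt[1]
    # orient the helix axis along the chain direction
    if np.dot(pc1, helix_points[-1] - helix_points[0]) < 0:
        pc1 = -pc1

    tcr_vec = cys_alpha - cys_beta
    if np.linalg.norm(tcr_vec) < 1e-9:
        raise DegenerateGeometryError("cysteine CA positions coincide")
    # project into the groove plane
    normal = np.cross(pc1, pc2)
    normal /= np.linalg.norm(normal)
    proj = tcr_vec - np.dot(tcr_vec, normal) * normal
    if np.linalg.norm(proj) < 1e-9:
        raise DegenerateGeometryError("TCR axis perpendicular to the groove plane")
    angle = _angle_deg(proj, pc1)
    if angle >= 180.0:
        angle = 0.0
    return DockingGeometry(
        docking_angle=angle,
        tcr_axis=proj / np.linalg.norm(proj),
        mhc_helix_axis=pc1 / np.linalg.norm(pc1),
        n_helix_atoms=len(helix_points),
    )


def compute_docking_angle(tcr_pair, mhc_pair, chains: Sequence[NumberedChain]) -> DockingGeometry:
    """Docking angle for an assigned TCR-MHC complex."""
    from .config import HELIX_RANGES

    by_id = {c.chain_id: c for c in chains}
    cys = {}
    for role, cid in (("beta", tcr_pair.beta_like_chain), ("alpha", tcr_pair.alpha_like_chain)):
        if cid is None:
            raise CoverageError("docking angle requires a paired TCR")
        ca = by_id[cid].atom_at(104, "CA")
        if ca is None:
            raise CoverageError(f"chain {cid}: no CA at IMGT 104")
        cys[role] = ca
    helix = []
    for cid in mhc_pair.chain_ids:
        chain = by_id[cid]
        for lo, hi in HELIX_RANGES.get(chain.chain_type, ()):
            for res in chain.imgt_residues(lo, hi):
                atom = res.atom("CA")
                if atom is not None:
                    helix.append(atom.coords)
    return docking_angle_from_points(cys["beta"], cys["alpha"], np.array(helix))


# ---------------------------------------------------------------------------
# Orientation similarity
# ---------------------------------------------------------------------------


def d_abangle(a: OrientationParams, t: OrientationParams) -> float:
    """Euclidean distance over the six homologous orientation parameters."""
    va, vt_ = a.as_array(), t.as_array()
    if not (np.all(np.isfinite(va)) and np.all(np.isfinite(vt_))):
        raise ValueError("orientation parameters contain non-finite values")
    return float(np.sqrt(((va - vt_) ** 2).sum()))


def find_similar_antibody(
    tcr_params: OrientationParams,
    antibody_table: Sequence[tuple[str, OrientationParams]],
    cutoff: float = 10.0,
) -> tuple[str, OrientationParams, float] | None:
    """Closest antibody by orientation distance, if within the cutoff.

    Ties on distance resolve to the lexicographically smallest identifier.
    """
    best: tuple[float, str, OrientationParams] | None = None
    for ab_id, params in antibody_table:
        dist = d_abangle(params, tcr_params)
        if best is None or (dist, ab_id) < (best[0], best[1]):
            best = (dist, ab_id, params)
    if best is None or best[0] > cutoff:
        return None
    return best[1], best[2], best[0]


def read_antibody_table(path: str | Path) -> list[tuple[str, OrientationParams]]:
    """Read an antibody orientation table (TSV: id + six parameter columns)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    if header[0].lower() not in ("id", "pdb", "name"):
        raise ValueError(f"{path}: first column must be an identifier")
    names = tuple(header[1:7])
    table = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        values = tuple(float(x) for x in fields[1:7])
        table.append((fields[0], OrientationParams(values=values, names=names)))
    return table
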