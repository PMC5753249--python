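"""Chain pairing, complex assignment, antigen detection and flagging.

The curation rules, applied to IMGT-numbered chains:

* two TCR chains pair when their conserved-cysteine (IMGT 104) CA atoms are
  strictly closer than 22 A; beta-like chains (TCRβ/TCRδ) pair with
  alpha-like chains (TCRα/TCRγ), cross-type pairs (e.g. an engineered δ/α
  receptor) are kept but typed ``other-paired``;
* an MH1-like chain (MH1/CD1/MR1) pairs with beta-2 microglobulin, and an
  MH2α with an MH2β chain, when all four landmark CA-CA distances are within
  their maxima (inclusive);
* a TCR and an MHC pair form a complex when at least one CB atom of the
  TCR's CDR3 loops lies within 8 A of a CB atom in the MHC groove helices;
  among candidates the pair with the highest CB-CB contact count wins;
* peptide/protein antigens are polymer chains with a CB atom within 8 A of
  the complex; haptens (non-polymeric ligands) must lie within 3.5 A of the
  MHC and within 8 A of a CDR3 CB atom.

Glycine has no CB; its CA is used as the CB proxy throughout so that
glycine-rich CDR3 loops are not silently under-counted.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .config import HELIX_RANGES, PairingThresholds
from .numbering import NumberedChain
from .structure_io import Residue

__all__ = [
    "TCRPair",
    "MHCPair",
    "ComplexRecord",
    "TCR_AB",
    "TCR_GD",
    "TCR_OTHER",
    "TCR_UNPAIRED",
    "pair_tcr_chains",
    "pair_mhc_chains",
    "assign_complexes",
    "detect_antigens",
    "flag_unconventional",
    "cdr3_cb_atoms",
    "helix_cb_atoms",
]

TCR_AB = "alphabeta"
TCR_GD = "gammadelta"
TCR_OTHER = "other-paired"
TCR_UNPAIRED = "unpaired"

BETA_LIKE = {"TCRB", "TCRD"}
ALPHA_LIKE = {"TCRA", "TCRG"}


@dataclasses.dataclass
class TCRPair:
    beta_like_chain: str | None
    alpha_like_chain: str | None
    tcr_type: str
    cys104_distance: float | None

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c for c in (self.beta_like_chain, self.alpha_like_chain) if c)


@dataclasses.dataclass
class MHCPair:
    mhc_class: str  # MH1 | MH2 | CD1 | MR1
    chain_ids: tuple[str, str]  # (groove chain, B2M) or (MH2A, MH2B)
    constraint_distances: tuple[float, float, float, float]


@dataclasses.dataclass
class ComplexRecord:
    tcr: TCRPair
    mhc: MHCPair | None = None
    antigens: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    cb_contact_count: int = 0
    unconventional_flag: bool = False
    unconventional_reasons: list[str] = dataclasses.field(default_factory=list)

    def flag(self, reason: str) -> None:
        self.unconventional_flag = True
        if reason not in self.unconventional_reasons:
            self.unconventional_reasons.append(reason)


# ---------------------------------------------------------------------------
# Coordinate collection helpers
# ---------------------------------------------------------------------------


def cdr3_cb_atoms(chain: NumberedChain) -> np.ndarray:
    """CB-proxy coordinates of the chain's CDR3 (IMGT 105-117) residues."""
    coords = []
    for res in chain.imgt_residues(105, 117):
        atom = res.cbeta_proxy()
        if atom is not None:
            coords.append(atom.coords)
    return np.array(coords) if coords else np.empty((0, 3))


def helix_cb_atoms(chain: NumberedChain) -> np.ndarray:
    """CB-proxy coordinates of the groove helix regions of an MHC chain."""
    ranges = HELIX_RANGES.get(chain.chain_type, ())
    coords = []
    for lo, hi in ranges:
        for res in chain.imgt_residues(lo, hi):
            atom = res.cbeta_proxy()
            if atom is not None:
                coords.append(atom.coords)
    return np.array(coords) if coords else np.empty((0, 3))


def _all_cb(chain: NumberedChain) -> np.ndarray:
    coords = [
        res.cbeta_proxy().coords
        for res in chain.chain.polymer_residues()
        if res.cbeta_proxy() is not None
    ]
    return np.array(coords) if coords else np.empty((0, 3))


def _count_within(a: np.ndarray, b: np.ndarray, cutoff: float) -> int:
    if a.size == 0 or b.size == 0:
        return 0
    return int((cdist(a, b) <= cutoff).sum())


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return float("inf")
    return float(cdist(a, b).min())


# ---------------------------------------------------------------------------
# TCR pairing
# ---------------------------------------------------------------------------


def _pair_type(beta_type: str, alpha_type: str) -> str:
    if beta_type == "TCRB" and alpha_type == "TCRA":
        return TCR_AB
    if beta_type == "TCRD" and alpha_type == "TCRG":
        return TCR_GD
    return TCR_OTHER


def pair_tcr_chains(
    chains: Sequence[NumberedChain],
    thresholds: PairingThresholds | None = None,
) -> list[TCRPair]:
    """Pair beta-like with alpha-like TCR chains by the cysteine-104 rule.

    Chains missing the 104 CA, and chains left over after the minimum-total-
    distance greedy matching, are reported as ``unpaired``.
    """
    thresholds = thresholds or PairingThresholds()
    betas = sorted(
        (c for c in chains if c.chain_type in BETA_LIKE), key=lambda c: c.chain_id
    )
    alphas = sorted(
        (c for c in chains if c.chain_type in ALPHA_LIKE), key=lambda c: c.chain_id
    )

    candidates = []
    for b, a in itertools.product(betas, alphas):
        ca_b = b.atom_at(104, "CA")
        ca_a = a.atom_at(104, "CA")
        if ca_b is None or ca_a is None:
            continue
        dist = float(np.linalg.norm(ca_b - ca_a))
        if dist < thresholds.tcr_cys_dist:
            candidates.append((dist, b, a))
    candidates.sort(key=lambda t: (t[0], t[1].chain_id, t[2].chain_id))

    pairs: list[TCRPair] = []
    used: set[str] = set()
    for dist, b, a in candidates:
        if b.chain_id in used or a.chain_id in used:
            continue
        used.update((b.chain_id, a.chain_id))
        pairs.append(
            TCRPair(
                beta_like_chain=b.chain_id,
                alpha_like_chain=a.chain_id,
                tcr_type=_pair_type(b.chain_type, a.chain_type),
                cys104_distance=dist,
            )
        )
    for chain in betas:
        if chain.chain_id not in used:
            pairs.append(TCRPair(chain.chain_id, None, TCR_UNPAIRED, None))
    for chain in alphas:
        if chain.chain_id not in used:
            pairs.append(TCRPair(None, chain.chain_id, TCR_UNPAIRED, None))
    pairs.sort(key=lambda p: p.chain_ids)
    return pairs


# ---------------------------------------------------------------------------
# MHC pairing
# ---------------------------------------------------------------------------


def pair_mhc_chains(
    chains: Sequence[NumberedChain],
    thresholds: PairingThresholds | None = None,
) -> list[MHCPair]:
    """Pair MHC groove chains with their partners by the four-distance rule.

    All four constraint distances must be within their maxima (inclusive)
    for a candidate pair; matching is greedy on minimum total distance.
    """
    thresholds = thresholds or PairingThresholds()
    grooves1 = sorted(
        (c for c in chains if c.chain_type in ("MH1", "CD1", "MR1")),
        key=lambda c: c.chain_id,
    )
    b2ms = sorted((c for c in chains if c.chain_type == "B2M"), key=lambda c: c.chain_id)
    mh2as = sorted((c for c in chains if c.chain_type == "MH2A"), key=lambda c: c.chain_id)
    mh2bs = sorted((c for c in chains if c.chain_type == "MH2B"), key=lambda c: c.chain_id)

    candidates: list[tuple[float, MHCPair]] = []
    for groove, partner, constraints, klass in [
        *[(g, b, thresholds.mh1_constraints, g.chain_type) for g in grooves1 for b in b2ms],
        *[(a, b, thresholds.mh2_constraints, "MH2") for a in mh2as for b in mh2bs],
    ]:
        dists = []
        ok = True
        for pos_g, pos_p, maximum in constraints:
            ca_g = groove.atom_at(pos_g, "CA")
            ca_p = partner.atom_at(pos_p, "CA")
            if ca_g is None or ca_p is None:
                ok = False
                break
            d = float(np.linalg.norm(ca_g - ca_p))
            if d > maximum:
                ok = False
                break
            dists.append(d)
        if ok:
            candidates.append(
                (
                    sum(dists),
                    MHCPair(
                        mhc_class=klass,
                        chain_ids=(groove.chain_id, partner.chain_id),
                        constraint_distances=tuple(dists),
                    ),
                )
            )
    candidates.sort(key=lambda t: (t[0], t[1].chain_ids))

    pairs: list[MHCPair] = []
    used: set[str] = set()
    for _, pair in candidates:
        if used.isdisjoint(pair.chain_ids):
            used.update(pair.chain_ids)
            pairs.append(pair)
    pairs.sort(key=lambda p: p.chain_ids)
    return pairs


# ---------------------------------------------------------------------------
# Complex assignment
# ---------------------------------------------------------------------------


def _tcr_cdr3_cb(tcr: TCRPair, by_id: dict[str, NumberedChain]) -> np.ndarray:
    parts = [cdr3_cb_atoms(by_id[c]) for c in tcr.chain_ids]
    parts = [p for p in parts if p.size]
    return np.vstack(parts) if parts else np.empty((0, 3))


def _mhc_helix_cb(mhc: MHCPair, by_id: dict[str, NumberedChain]) -> np.ndarray:
    parts = [helix_cb_atoms(by_id[c]) for c in mhc.chain_ids]
    parts = [p for p in parts if p.size]
    return np.vstack(parts) if parts else np.empty((0, 3))


def assign_complexes(
    tcr_pairs: Sequence[TCRPair],
    mhc_pairs: Sequence[MHCPair],
    chains: Sequence[NumberedChain],
    thresholds: PairingThresholds | None = None,
) -> list[ComplexRecord]:
    """Match each TCR to the MHC pair with the most CDR3/helix CB contacts.

    Candidates with zero contacts are excluded; each MHC pair serves at most
    one TCR.  A TCR whose best contact count is achieved by two or more
    available MHC pairs is flagged (``ambiguous MHC assignment``) and matched
    to the lexicographically smallest of the tied pairs.
    """
    thresholds = thresholds or PairingThresholds()
    by_id = {c.chain_id: c for c in chains}
    records: list[ComplexRecord] = []
    available = list(mhc_pairs)
    for tcr in sorted(tcr_pairs, key=lambda p: p.chain_ids):
        record = ComplexRecord(tcr=tcr)
        if tcr.tcr_type != TCR_UNPAIRED:
            cdr3 = _tcr_cdr3_cb(tcr, by_id)
            scored = []
            for mhc in available:
                count = _count_within(
                    cdr3, _mhc_helix_cb(mhc, by_id), thresholds.complex_contact_dist
                )
                if count > 0:
                    scored.append((count, mhc))
            if scored:
                scored.sort(key=lambda t: (-t[0], t[1].chain_ids))
                best_count = scored[0][0]
                if len(scored) > 1 and scored[1][0] == best_count:
                    record.flag("ambiguous MHC assignment")
                record.mhc = scored[0][1]
                record.cb_contact_count = best_count
                available.remove(record.mhc)
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Antigen detection
# ---------------------------------------------------------------------------


def _hapten_id(res: Residue) -> str:
    return f"{res.chain_id}/{res.res_name}{res.seq_pos}"


def detect_antigens(
    complexes: Sequence[ComplexRecord],
    chains: Sequence[NumberedChain],
    haptens: Iterable[Residue] = (),
    thresholds: PairingThresholds | None = None,
) -> list[ComplexRecord]:
    """Populate each complex's antigen list.

    Polymer chains outside the complex qualify when any CB proxy lies within
    the contact cutoff of the complex's CB atoms (``peptide`` when at most
    ``peptide_max_len`` residues long, else ``protein``).  Chains carrying a
    TCR or MHC domain are receptor components, never antigen candidates.
    Haptens qualify only when both hapten cutoffs hold (MHC proximity AND
    CDR3 proximity).
    """
    thresholds = thresholds or PairingThresholds()
    by_id = {c.chain_id: c for c in chains}
    receptor_types = BETA_LIKE | ALPHA_LIKE | {"MH1", "CD1", "MR1", "MH2A", "MH2B", "B2M"}
    for record in complexes:
        member_ids = set(record.tcr.chain_ids)
        if record.mhc is not None:
            member_ids.update(record.mhc.chain_ids)
        complex_cb = [_all_cb(by_id[c]) for c in sorted(member_ids) if c in by_id]
        complex_cb = [p for p in complex_cb if p.size]
        if not complex_cb:
            continue
        complex_cb = np.vstack(complex_cb)

        for chain in sorted(chains, key=lambda c: c.chain_id):
            if chain.chain_id in member_ids or chain.chain_type in receptor_types:
                continue
            cb = _all_cb(chain)
            if _min_dist(cb, complex_cb) <= thresholds.complex_contact_dist:
                n_res = len(chain.chain.polymer_residues())
                kind = "peptide" if n_res <= thresholds.peptide_max_len else "protein"
                record.antigens.append((chain.chain_id, kind))

        if record.mhc is not None:
            mhc_atoms = []
            for cid in record.mhc.chain_ids:
                for res in by_id[cid].chain.polymer_residues():
                    mhc_atoms.extend(a.coords for a in res.heavy_atoms())
            mhc_atoms = np.array(mhc_atoms) if mhc_atoms else np.empty((0, 3))
            cdr3 = _tcr_cdr3_cb(record.tcr, by_id)
            for res in haptens:
                atoms = np.array([a.coords for a in res.heavy_atoms()])
                if atoms.size == 0:
                    continue
                near_mhc = _min_dist(atoms, mhc_atoms) <= thresholds.hapten_mhc_dist
                near_cdr3 = _min_dist(atoms, cdr3) <= thresholds.hapten_cdr3_dist
                if near_mhc and near_cdr3:
                    record.antigens.append((_hapten_id(res), "hapten"))
        record.antigens.sort()
    return list(complexes)


# ---------------------------------------------------------------------------
# Unconventional-structure flagging
# ---------------------------------------------------------------------------


def flag_unconventional(
    record: ComplexRecord,
    chains: Sequence[NumberedChain],
    mhc_pairs: Sequence[MHCPair] = (),
    thresholds: PairingThresholds | None = None,
) -> ComplexRecord:
    """Flag structures needing manual inspection.

    Reasons: an ambiguous MHC assignment tie (set during assignment), a
    non-canonical cross-type chain pairing, or an interposed protein antigen
    that bridges the TCR and an MHC with which the TCR makes no direct
    contact.
    """
    thresholds = thresholds or PairingThresholds()
    by_id = {c.chain_id: c for c in chains}
    if record.tcr.tcr_type == TCR_OTHER:
        record.flag("non-canonical chain pairing")
    if record.mhc is None and record.tcr.tcr_type != TCR_UNPAIRED:
        cdr3 = _tcr_cdr3_cb(record.tcr, by_id)
        for antigen_id, kind in record.antigens:
            if kind != "protein" or antigen_id not in by_id:
                continue
            ag_cb = _all_cb(by_id[antigen_id])
            touches_tcr = (
                _min_dist(ag_cb, cdr3) <= thresholds.complex_contact_dist
            )
            touches_mhc = any(
                _min_dist(ag_cb, _mhc_helix_cb(mhc, by_id))
                <= thresholds.complex_contact_dist
                for mhc in mhc_pairs
            )
            if touches_tcr and touches_mhc:
                record.flag("interposed antigen")
                break
    return record
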