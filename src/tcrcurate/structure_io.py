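"""Structure input/output.

Reads macromolecular structures from PDB-format files into a light internal
model (:class:`Structure` / :class:`Chain` / :class:`Residue` / :class:`Atom`)
and writes the two curation artifacts:

* an IMGT-renumbered PDB file whose header carries one ``REMARK 950`` block
  per detected TCR, listing its paired chain, matched MHC chains and class,
  and antigen chain or ligand;
* a tab-separated summary file with one line per TCR.

Reading policy: exactly one model is kept per file (the first, unless another
is requested), alternate locations are collapsed to the highest-occupancy
conformer (ties broken by the lexicographically smallest altloc label),
waters are dropped, and non-polymeric hetero residues are retained and
flagged as haptens.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "SummaryRecord",
    "SUMMARY_COLUMNS",
    "NA",
    "FormatError",
    "EmptyStructureError",
    "NumberingConsistencyError",
    "read_structure",
    "write_renumbered_pdb",
    "write_summary_tsv",
    "read_summary_tsv",
]

#: Sentinel used for missing values in the summary file.
NA = "NA"

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class FormatError(ValueError):
    """Raised when a PDB file cannot be parsed; names the offending line."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no atoms."""


class NumberingConsistencyError(KeyError):
    """Raised when a numbering map refers to a residue the structure lacks."""


@dataclasses.dataclass
class Atom:
    """A single atom; coordinates in Angstrom, B-factor in Angstrom^2."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor {self.b_factor}")


@dataclasses.dataclass
class Residue:
    """A residue (or non-polymeric ligand) with its retained atoms.

    ``seq_pos`` is the author sequence number; ``icode`` the insertion code
    (empty when absent).  ``is_hapten`` marks non-polymeric, non-water
    hetero residues with at least one heavy atom.
    """

    chain_id: str
    seq_pos: int
    icode: str
    res_name: str
    atoms: list[Atom]
    is_polymer: bool = True
    is_hapten: bool = False

    def __post_init__(self) -> None:
        if self.is_hapten and self.is_polymer:
            raise ValueError("a residue cannot be both polymer and hapten")

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_pos, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def cbeta_proxy(self) -> Atom | None:
        """The CB atom, or CA for residues without one (glycine)."""
        return self.atom("CB") or self.atom("CA")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def haptens(self) -> list[Residue]:
        return [r for r in self.residues if r.is_hapten]

    def sequence(self) -> str:
        """One-letter sequence of the polymer residues (X for non-standard)."""
        out = []
        for res in self.polymer_residues():
            info = gemmi.find_tabulated_residue(res.res_name)
            one = info.one_letter_code.upper() if info else "X"
            out.append(one if one.isalpha() else "X")
        return "".join(out)


@dataclasses.dataclass
class Structure:
    entry_id: str
    chains: list[Chain]
    resolution: float | None = None
    experiment_method: str = ""
    model_index_used: int = 1

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain identifiers")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _validate_pdb_text(path: Path) -> None:
    """Cheap per-line validation so parse failures can name the line."""
    with open(path, "r", errors="replace") as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(f"{path}: line {lineno}: truncated coordinate record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: bad coordinate field") from exc


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by label."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in by_name:
            by_name[atom.name] = atom
            order.append(atom.name)
        else:
            best = by_name[atom.name]
            if (atom.occupancy, _neg_label(atom.altloc)) > (
                best.occupancy,
                _neg_label(best.altloc),
            ):
                by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _neg_label(label: str):
    # sort helper: higher occupancy wins; among equals the lexicographically
    # smallest altloc label must win, so invert the label ordering
    return tuple(-ord(c) for c in label)


def read_structure(path: str | Path, model_policy: str | int = "first") -> Structure:
    """Read a PDB-format file.

    Parameters
    ----------
    path:
        PDB-format file.
    model_policy:
        ``"first"`` (default) keeps the first model; an integer selects a
        specific model by its serial number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    if model_policy == "first":
        model = st[0]
    else:
        wanted = int(model_policy)
        model = None
        for m in st:
            if m.num == wanted:
                model = m
                break
        if model is None:
            raise ValueError(f"{path}: no model {wanted}")
    model_index = model.num

    chains: list[Chain] = []
    n_atoms = 0
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in WATER_NAMES or gres.is_water():
                continue
            atoms = []
            for gatom in gres:
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        b_factor=max(gatom.b_iso, 0.0),
                        altloc=gatom.altloc.strip("\x00").strip(),
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            n_atoms += len(atoms)
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = bool(info and info.is_amino_acid())
            is_polymer = is_aa or gres.het_flag == "A"
            heavy = any(a.element.upper() not in ("H", "D") for a in atoms)
            is_hapten = (not is_polymer) and heavy
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_pos=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    res_name=gres.name,
                    atoms=atoms,
                    is_polymer=is_polymer,
                    is_hapten=is_hapten,
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: structure contains no atoms")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    entry_id = ""
    with open(path, "r", errors="replace") as handle:
        first = handle.readline()
        if first.startswith("HEADER") and len(first.rstrip()) >= 66:
            entry_id = first[62:66].strip().lower()
    entry_id = entry_id or (st.name or path.stem)[:4].lower() or path.stem[:4].lower()
    return Structure(
        entry_id=entry_id,
        chains=chains,
        resolution=resolution,
        experiment_method=dict(st.info).get("_exptl.method", ""),
        model_index_used=model_index,
    )


# ---------------------------------------------------------------------------
# Renumbered-PDB writing
# ---------------------------------------------------------------------------


def _format_atom_line(
    serial: int,
    atom: Atom,
    res_name: str,
    chain_id: str,
    seq_pos: int,
    icode: str,
    hetero: bool,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    name = atom.name
    # standard PDB atom-name justification: element starts in column 14
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record}{serial:5d} {name:<4s}{'':1s}{res_name:>3s} {chain_id:1s}"
        f"{seq_pos:4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
        f"{atom.element:>2s}  "
    )


def pairing_remarks(complexes: Sequence) -> list[str]:
    """``REMARK 950`` pairing header: one block per TCR.

    Grammar (one line per TCR, fixed field order)::

        REMARK 950 TCR <beta-like> <alpha-like> | MHC <class> <chains> | AG <ids>

    Missing items are written as ``NONE``.
    """
    lines = ["REMARK 950 TCR PAIRING"]
    for rec in complexes:
        beta = rec.tcr.beta_like_chain or "NONE"
        alpha = rec.tcr.alpha_like_chain or "NONE"
        if rec.mhc is not None:
            mhc = f"{rec.mhc.mhc_class} {' '.join(rec.mhc.chain_ids)}"
        else:
            mhc = "NONE"
        ags = " ".join(a[0] for a in rec.antigens) if rec.antigens else "NONE"
        lines.append(f"REMARK 950 TCR {beta} {alpha} | MHC {mhc} | AG {ags}")
    return lines


def write_renumbered_pdb(
    structure: Structure,
    numbering: Mapping[str, Mapping[tuple[int, str], tuple[int, str]]],
    complexes: Sequence,
    path: str | Path,
) -> None:
    """Write ``structure`` with IMGT numbering applied where available.

    ``numbering`` maps chain id -> {(seq_pos, icode) -> (imgt_pos, icode)}.
    Chains absent from the map keep their original numbering.  The header
    carries one ``REMARK 950`` block per TCR (see :func:`pairing_remarks`).
    """
    for cid, cmap in numbering.items():
        chain = structure.chain(cid)
        keys = {r.key for r in chain.residues}
        for res_key in cmap:
            if res_key not in keys:
                raise NumberingConsistencyError(
                    f"chain {cid}: numbering refers to missing residue {res_key}"
                )

    lines: list[str] = [f"REMARK 950 ENTRY {structure.entry_id}"]
    lines.extend(pairing_remarks(complexes))
    serial = 0
    for chain in structure.chains:
        cmap = numbering.get(chain.chain_id, {})
        last = None
        for res in chain.residues:
            seq_pos, icode = cmap.get(res.key, res.key)
            for atom in res.atoms:
                serial += 1
                lines.append(
                    _format_atom_line(
                        serial,
                        atom,
                        res.res_name,
                        chain.chain_id,
                        seq_pos,
                        icode,
                        hetero=not res.is_polymer,
                    )
                )
            last = (seq_pos, icode, res.res_name)
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last[2]:>3s} {chain.chain_id:1s}"
                f"{last[0]:4d}{last[1] or ' ':1s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Summary file
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "pdb",
    "Bchain",
    "Achain",
    "TCRtype",
    "mhc_type",
    "mhc_chain1",
    "mhc_chain2",
    "antigen_chain",
    "antigen_type",
    "resolution",
    "Bchain_species",
    "Achain_species",
    "BA",
    "BC1",
    "BC2",
    "AC1",
    "AC2",
    "dc",
    "docking_angle",
    "cdr_B1_form",
    "cdr_B2_form",
    "cdr_B3_form",
    "cdr_A1_form",
    "cdr_A2_form",
    "cdr_A3_form",
    "affinity",
]


@dataclasses.dataclass
class SummaryRecord:
    """One summary-file line: one TCR and everything matched to it.

    The beta-like chain (TCRβ or TCRδ) is listed first, mirroring the
    heavy-chain-first convention for antibodies.  Any field may be ``None``
    and serialises as the :data:`NA` sentinel.
    """

    pdb: str
    Bchain: str | None = None
    Achain: str | None = None
    TCRtype: str | None = None
    mhc_type: str | None = None
    mhc_chain1: str | None = None
    mhc_chain2: str | None = None
    antigen_chain: str | None = None
    antigen_type: str | None = None
    resolution: float | None = None
    Bchain_species: str | None = None
    Achain_species: str | None = None
    BA: float | None = None
    BC1: float | None = None
    BC2: float | None = None
    AC1: float | None = None
    AC2: float | None = None
    dc: float | None = None
    docking_angle: float | None = None
    cdr_B1_form: str | None = None
    cdr_B2_form: str | None = None
    cdr_B3_form: str | None = None
    cdr_A1_form: str | None = None
    cdr_A2_form: str | None = None
    cdr_A3_form: str | None = None
    affinity: float | None = None

    def to_fields(self) -> list[str]:
        out = []
        for col in SUMMARY_COLUMNS:
            value = getattr(self, col)
            if value is None:
                out.append(NA)
            elif isinstance(value, float):
                out.append(NA if math.isnan(value) else f"{value:.3f}".rstrip("0").rstrip("."))
            else:
                out.append(str(value).replace("\t", " "))
        return out

    @classmethod
    def from_fields(cls, fields: Sequence[str]) -> "SummaryRecord":
        if len(fields) != len(SUMMARY_COLUMNS):
            raise ValueError("field count does not match summary header")
        kwargs = {}
        float_cols = {
            "resolution", "BA", "BC1", "BC2", "AC1", "AC2", "dc",
            "docking_angle", "affinity",
        }
        for col, raw in zip(SUMMARY_COLUMNS, fields):
            if raw == NA:
                kwargs[col] = None
            elif col in float_cols:
                kwargs[col] = float(raw)
            else:
                kwargs[col] = raw
        return cls(**kwargs)


def write_summary_tsv(records: Iterable[SummaryRecord], path: str | Path) -> None:
    """Write the tab-separated summary: header + one line per record."""
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for rec in records:
        lines.append("\t".join(rec.to_fields()))
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary_tsv(path: str | Path) -> list[SummaryRecord]:
    text = Path(path).read_text().splitlines()
    if not text or text[0].split("\t") != SUMMARY_COLUMNS:
        raise ValueError(f"{path}: not a summary file")
    return [SummaryRecord.from_fields(line.split("\t")) for line in text[1:]]
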