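"""Curation thresholds and run configuration.

All distance cutoffs used by the pairing stage live in
:class:`PairingThresholds`; the defaults are the published curation values:
TCR chains pair when the two conserved-cysteine (IMGT 104) CA atoms are
strictly closer than 22 A; MHC chains pair when all four landmark distances
are within their maxima (inclusive); TCR-MHC complexes and peptide/protein
antigens use an 8 A CB contact cutoff; haptens use 3.5 A to the MHC plus
8 A to the CDR3 CB atoms.

The groove "helix region" position ranges are an interpretation from the
IMGT G-domain topology (the C-terminal half of each groove domain forms the
helix): positions 50-92 of each G domain.  They are configurable here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

__all__ = ["PairingThresholds", "RunConfig", "HELIX_RANGES"]

#: Inclusive IMGT position ranges forming the groove helices, per chain type.
#: MH1-like chains carry two groove domains; the second is offset by +1000.
HELIX_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "MH1": ((50, 92), (1050, 1092)),
    "CD1": ((50, 92), (1050, 1092)),
    "MR1": ((50, 92), (1050, 1092)),
    "MH2A": ((50, 92),),
    "MH2B": ((50, 92),),
}

# (MHC-chain position, partner position, maximum CA-CA distance in A)
_MH1_CONSTRAINTS = ((15, 23, 32.0), (15, 104, 32.0), (51, 23, 32.0), (51, 104, 37.0))
_MH2_CONSTRAINTS = ((29, 64, 34.0), (29, 39, 22.0), (37, 64, 32.0), (37, 39, 28.0))


@dataclasses.dataclass(frozen=True)
class PairingThresholds:
    """Distance cutoffs for chain pairing, complex assignment and antigens."""

    tcr_cys_dist: float = 22.0          # strict upper bound, A
    mh1_constraints: tuple = _MH1_CONSTRAINTS   # inclusive maxima, A
    mh2_constraints: tuple = _MH2_CONSTRAINTS   # inclusive maxima, A
    complex_contact_dist: float = 8.0   # CB-CB, A
    hapten_mhc_dist: float = 3.5        # any heavy atom to MHC, A
    hapten_cdr3_dist: float = 8.0       # any hapten atom to CDR3 CB, A
    peptide_max_len: int = 30           # <= this many residues -> "peptide"

    def __post_init__(self) -> None:
        for value in (
            self.tcr_cys_dist,
            self.complex_contact_dist,
            self.hapten_mhc_dist,
            self.hapten_cdr3_dist,
        ):
            if value <= 0:
                raise ValueError("distance thresholds must be positive")
        for cons in (self.mh1_constraints, self.mh2_constraints):
            if len(cons) != 4 or any(c[2] <= 0 for c in cons):
                raise ValueError("four positive MHC constraints are required")


@dataclasses.dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through a key=value file."""

    thresholds: PairingThresholds = dataclasses.field(default_factory=PairingThresholds)
    eps: float = 0.8                 # DBSCAN radius on DTW-RMSD, A
    min_pts: int = 3                 # DBSCAN core-point neighbour count
    resolution_max: float = 2.8      # loop quality filter, A (inclusive)
    bfactor_max: float = 80.0        # loops with any backbone B >= this removed
    orientation_cutoff: float = 10.0 # d_ABangle similarity threshold
    min_score: float | None = None   # numbering detection threshold override
    profiles_dir: str | None = None
    antibody_table: str | None = None
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def dump(self, path: str | Path) -> None:
        t = self.thresholds
        lines = [
            "# tcrcurate configuration",
            f"tcr_cys_dist = {t.tcr_cys_dist}",
            "mh1_constraints = " + "; ".join(f"{a},{b},{d}" for a, b, d in t.mh1_constraints),
            "mh2_constraints = " + "; ".join(f"{a},{b},{d}" for a, b, d in t.mh2_constraints),
            f"complex_contact_dist = {t.complex_contact_dist}",
            f"hapten_mhc_dist = {t.hapten_mhc_dist}",
            f"hapten_cdr3_dist = {t.hapten_cdr3_dist}",
            f"peptide_max_len = {t.peptide_max_len}",
            f"eps = {self.eps}",
            f"min_pts = {self.min_pts}",
            f"resolution_max = {self.resolution_max}",
            f"bfactor_max = {self.bfactor_max}",
            f"orientation_cutoff = {self.orientation_cutoff}",
            f"min_score = {'' if self.min_score is None else self.min_score}",
            f"profiles_dir = {self.profiles_dir or ''}",
            f"antibody_table = {self.antibody_table or ''}",
            f"output_dir = {self.output_dir}",
            f"seed = {self.seed}",
            f"log_level = {self.log_level}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        fields: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()

        def cons(raw: str) -> tuple:
            out = []
            for part in raw.split(";"):
                a, b, d = part.split(",")
                out.append((int(a), int(b), float(d)))
            return tuple(out)

        defaults = PairingThresholds()
        thresholds = PairingThresholds(
            tcr_cys_dist=float(fields.get("tcr_cys_dist", defaults.tcr_cys_dist)),
            mh1_constraints=cons(fields["mh1_constraints"])
            if "mh1_constraints" in fields
            else defaults.mh1_constraints,
            mh2_constraints=cons(fields["mh2_constraints"])
            if "mh2_constraints" in fields
            else defaults.mh2_constraints,
            complex_contact_dist=float(
                fields.get("complex_contact_dist", defaults.complex_contact_dist)
            ),
            hapten_mhc_dist=float(fields.get("hapten_mhc_dist", defaults.hapten_mhc_dist)),
            hapten_cdr3_dist=float(fields.get("hapten_cdr3_dist", defaults.hapten_cdr3_dist)),
            peptide_max_len=int(fields.get("peptide_max_len", defaults.peptide_max_len)),
        )
        base = cls()
        return cls(
            thresholds=thresholds,
            eps=float(fields.get("eps", base.eps)),
            min_pts=int(fields.get("min_pts", base.min_pts)),
            resolution_max=float(fields.get("resolution_max", base.resolution_max)),
            bfactor_max=float(fields.get("bfactor_max", base.bfactor_max)),
            orientation_cutoff=float(fields.get("orientation_cutoff", base.orientation_cutoff)),
            min_score=float(fields["min_score"]) if fields.get("min_score") else None,
            profiles_dir=fields.get("profiles_dir") or None,
            antibody_table=fields.get("antibody_table") or None,
            output_dir=fields.get("output_dir", "."),
            seed=int(fields.get("seed", 0)),
            log_level=fields.get("log_level", "INFO"),
        )
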