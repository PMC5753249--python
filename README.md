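# tcrcurate

Automated curation of T-cell receptor (TCR) structural data: a Python
re-implementation of the annotation pipeline behind structural TCR
databases, usable as a library or from the command line.

T cells recognise antigen through the TCR, a heterodimer of TCRα/TCRβ
(αβ TCR) or TCRγ/TCRδ (γδ TCR) chains, typically engaging a peptide
presented by a major histocompatibility complex (MHC) molecule.  Structures
of these complexes are deposited in the PDB with arbitrary chain naming and
author numbering; before any comparative analysis one has to decide which
chains form a TCR, which form an MHC, which TCR binds which MHC, what the
antigen is, and how the variable domains and the TCR-MHC interface are
oriented.  `tcrcurate` automates exactly that:

* **Domain detection and IMGT numbering** — chains are scanned against
  bundled per-domain consensus profiles (TCR Vα/Vβ/Vγ/Vδ, MHC groove
  G-domains for MH1/CD1/MR1/MH2, β2 microglobulin; human and mouse) and
  renumbered in the IMGT scheme: conserved cysteines at positions 23 and
  104, CDR1 = 27–38, CDR2 = 56–65, CDR3 = 105–117, CDR3 insertions lettered
  symmetrically around 111/112.  Pre-computed numbering maps can be
  supplied to bypass this stage.
* **Chain pairing** — two TCR chains pair when the Cα–Cα distance between
  their conserved cysteines (IMGT 104) is < 22 Å.  MH1-like chains pair
  with β2m when all four landmark distances α15–β23 ≤ 32, α15–β104 ≤ 32,
  α51–β23 ≤ 32 and α51–β104 ≤ 37 Å hold; MH2α pairs with MH2β under
  α29–β64 ≤ 34, α29–β39 ≤ 22, α37–β64 ≤ 32, α37–β39 ≤ 28 Å.
* **Complex assignment and antigens** — a TCR is matched to the MHC pair
  with the highest number of CDR3-Cβ / groove-helix-Cβ contacts within
  8 Å (glycine contributes its Cα).  Peptide (≤ 30 residues) and protein
  antigens lie within 8 Å of the complex; haptens (small non-polymeric
  ligands) must be within 3.5 Å of the MHC *and* 8 Å of a CDR3 Cβ.
  Unconventional structures (cross-type pairings, interposed antigens,
  ambiguous MHC ties) are flagged for manual inspection.
* **Orientation** — the Vα-Vβ pose is summarised by six parameters
  (BA, BC1, BC2, AC1, AC2 angles and the inter-domain distance dc) from
  frames registered on a bundled reference core, plus the TCR-MHC docking
  angle (cysteine axis vs groove-helix principal axis).  Orientation
  similarity to antibodies uses the unweighted Euclidean distance
  d = sqrt(Σᵢ (θ_{i,a} − θ_{i,t})²) over the six homologous parameters
  (HL↔BA, …), with matches reported at d ≤ 10.
* **CDR canonical forms** — loops from structures at resolution ≤ 2.8 Å
  with no missing residues and all backbone B-factors < 80 are compared by
  a length-independent dynamic-time-warp RMSD and clustered with DBSCAN;
  clusters map to named canonical forms, and individual loops can be
  matched to antibody CDR loops at < 1.5 Å length-matched backbone RMSD.

A first-class synthetic-fixture generator (`tcrcurate.synthetic`) builds
ground-truth-bearing structures and loop sets satisfying any requested
landmark geometry to 1e-6 Å, so the entire pipeline is testable without
downloading anything.

## Worked example

Generate a synthetic αβ-TCR / MH1 / peptide complex and annotate it:

```sh
python -c "
from tcrcurate.synthetic import FixtureSpec, make_tcr_mhc_fixture, write_fixture_pdb
structure, truth = make_tcr_mhc_fixture(FixtureSpec())
write_fixture_pdb(structure, 'synt.pdb')"
tcrcurate annotate synt.pdb --out-dir out
```

`out/summary.tsv` then contains one line per TCR (first columns shown):

```
pdb   Bchain  Achain  TCRtype    mhc_type  mhc_chain1  mhc_chain2  antigen_chain  antigen_type
synt  E       D       alphabeta  MH1       A           B           C              peptide
```

i.e. chains E (TCRβ) and D (TCRα) form an αβ TCR bound to the class-I MHC
pair A/B presenting the peptide on chain C.  The renumbered file
`out/synt_imgt.pdb` carries the pairing header:

```
REMARK 950 TCR E D | MHC MH1 A B | AG C
```

and the orientation report:

```sh
$ tcrcurate orientation synt.pdb
TCR E-D:
    BA =    38.021 deg
   BC1 =    78.840 deg
   BC2 =    56.352 deg
   AC1 =   120.330 deg
   AC2 =   126.213 deg
    dc =    14.682 A
  docking_angle = 46.520 deg
```

The five angles and dc describe the relative pose of the Vβ and Vα frames
(convention-dependent absolute values; invariant under any rigid motion of
the whole structure), and the docking angle is the crossing angle between
the inter-domain cysteine axis and the MHC groove helices.  With
`--antibody-table table.tsv` the closest antibody by orientation distance
is reported when within the cutoff (default 10).

Loop clustering runs over any set of annotated structures:

```sh
tcrcurate cluster *.pdb --eps 0.8 --min-pts 3 --out clusters.tsv
```

## Layout

| Module | Role |
| --- | --- |
| `tcrcurate.structure_io` | PDB reading; renumbered-PDB and summary-TSV writing |
| `tcrcurate.numbering` | domain detection, IMGT numbering, MHC classification |
| `tcrcurate.pairing` | TCR/MHC pairing, complex assignment, antigens, flags |
| `tcrcurate.geometry` | orientation parameters, docking angle, similarity search |
| `tcrcurate.cdr_clustering` | CDR extraction, filters, DTW-RMSD, DBSCAN, canonical forms |
| `tcrcurate.synthetic` | ground-truth synthetic structures and loop sets |
| `tcrcurate.cli` | `annotate` / `cluster` / `orientation` commands |

See `docs/methods.md` for the precise definitions, defaults and known
limitations.
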