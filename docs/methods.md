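# Methods

This note records the precise definitions, defaults and design choices
behind `tcrcurate`, and what the synthetic fixtures do and do not
demonstrate.

## Domain detection and IMGT numbering

Chains are detected by glocal (global-in-profile, free-end-gap) affine-gap
alignment of each bundled consensus profile against the chain sequence
(BLOSUM62, gap open −10, extend −0.5; unknown residues mapped to X).  A
profile is a consensus sequence whose columns carry IMGT position labels.
The bundled set covers TCR Vα/Vβ/Vγ/Vδ and MHC G-domains, β2m, for human
and mouse (36 chain-type/species combinations over 18 files).

The profiles were constructed by the package authors with the IMGT anchors
fixed — first conserved cysteine at 23, tryptophan at 41, second cysteine
at 104, FGXG-like FR4 start at 118 for variable domains; the two β2m
cysteines at the immunoglobulin C-domain positions 23 and 104.  They are a
compact substitute for profile HMMs built from full germline alignments:
alignment scores are internally comparable but are not meant to reproduce
any external numbering tool's scores, and coverage is deliberately limited
to human and mouse.  Users with their own numbering can bypass this stage
entirely by passing pre-computed maps to `number_chain`.

Numbering transfers framework labels through the alignment columns and
re-derives CDR positions from the observed loop length with the IMGT
middle-out convention: a loop shorter than its slot leaves gaps in the
middle of the slot; a longer loop inserts lettered positions symmetrically
around the two central positions (111/112 for CDR3, with the extra residue
on the N-terminal side: …111, 111A, 112A, 112…).

**Detection threshold.** `min_score = 62.5`, the 1 − 10⁻³ quantile of the
empirical null distribution of best-per-profile scores over 2000 random
sequences of length 250 with uniform residue frequencies
(`calibrate_min_score` reproduces the procedure).  Genuine domains score
several hundred, so detection is insensitive to the exact value.

**MHC G-domains.** MH1-like chains (MH1/CD1/MR1) carry two groove domains;
both are numbered 1–92-style, with the second domain offset by +1000 so a
renumbered chain never carries duplicate residue identifiers.  The groove
"helix region" is taken as positions 50–92 of each G domain (the
C-terminal helical half of the IMGT G-domain topology); this range is an
interpretation and is configurable (`config.HELIX_RANGES`).

## Pairing rules and thresholds

| Rule | Default | Strictness |
| --- | --- | --- |
| TCR pairing, Cα104–Cα104 | 22 Å | strict `<` |
| MH1-like–β2m: α15–β23, α15–β104, α51–β23, α51–β104 | 32, 32, 32, 37 Å | inclusive `≤`, all four |
| MH2α–MH2β: α29–β64, α29–β39, α37–β64, α37–β39 | 34, 22, 32, 28 Å | inclusive `≤`, all four |
| complex contact (CDR3 Cβ vs helix Cβ) | 8 Å | inclusive |
| peptide/protein antigen (Cβ vs complex Cβ) | 8 Å | inclusive |
| hapten: heavy atom vs MHC AND atom vs CDR3 Cβ | 3.5 Å and 8 Å | inclusive, conjunction |
| peptide vs protein antigen split | 30 residues | `≤` → peptide |

The TCR cutoff is strict because it is stated as a strict bound; the MHC
constraints are stated as plain maxima and are implemented inclusively so
the printed values remain usable as exact bounds.  Glycine has no Cβ, so
its Cα serves as the Cβ proxy everywhere — CDR3 loops are glycine-rich and
skipping them would silently deflate contact counts.  Hapten distances use
heavy atoms only.

Matchings (both TCR and MHC) are greedy on minimum distance (minimum total
distance for the four-constraint MHC rule), with lexicographic chain-id
order as the deterministic tie-break; each chain joins at most one pair.
Candidate TCR pairs are beta-like × alpha-like ({β,δ} × {α,γ}); the
canonical combinations type as `alphabeta`/`gammadelta`, anything else as
`other-paired` (flagged).

Complex assignment counts Cβ–Cβ pairs within 8 Å between the TCR's CDR3
loops (both chains) and the MHC groove helices; zero-contact candidates
are excluded, the highest count wins, each MHC pair serves one TCR, and an
exact tie flags the record (`ambiguous MHC assignment`) while still
assigning deterministically.  Antigen candidates are polymer chains that
carry no TCR/MHC domain hit — a second MHC pair touching the TCR is a
receptor, not an antigen.  A structure is also flagged when a protein
antigen bridges a TCR and an MHC that share no direct contact
(`interposed antigen`).

## Orientation parameters and docking angle

A frame is registered on each variable domain by least-squares (Kabsch)
superposition of the bundled reference core (32 framework Cα positions,
stored in `data/reference_core.txt` in its canonical frame) onto the
observed Cα atoms; at least 80% of the core positions must be present.
With C the vector from the β-frame origin to the α-frame origin:

* `BA` — signed torsion from the β first axis to the α first axis about C;
* `BC1`, `BC2` — angles of the β first/second axes against C;
* `AC1`, `AC2` — angles of the α first/second axes against −C;
* `dc` — |C| (Å).  Coincident origins are rejected as degenerate.

These are functions of the relative pose only, hence invariant under any
common rigid transform, and swap equivariant (BA preserved, BC↔AC
exchanged).  Because the reference core is this package's own scaffold,
absolute values are convention-dependent; only relative comparisons and
the invariances are contractual.  Orientation is computed for αβ TCRs
only; γδ and cross-type receptors return a typed not-supported result.

The docking angle is the angle between (i) the Vβ104→Vα104 Cα axis and
(ii) the first principal axis of the groove-helix Cα atoms (oriented along
the helix chain direction), both projected into the groove plane (span of
the first two principal axes); reported in [0, 180).  At least 8 helix Cα
atoms are required.

Orientation similarity to antibodies is the unweighted Euclidean distance
over the six homologous parameters (HL↔BA, HC1↔BC1, …, dc↔dc) — the dc
term (Å) enters unscaled alongside the angles (degrees), as the distance
is defined without weights.  The similarity cutoff is 10 (inclusive); only
the closest entry is reported, ties resolving to the smallest identifier.

## CDR loops and clustering

Loops follow the IMGT definition (27–38, 56–65, 105–117).  Quality filter:
resolution ≤ 2.8 Å (unknown resolution is rejected), no missing residues,
and every backbone (N, Cα, C, O) B-factor strictly below 80 Å²
("80 or higher" removed).  Missing residues are detected from author-
numbering gaps inside the loop span, or from an observed label pattern
that differs from the middle-out convention for the observed length.

The loop distance is a DTW-RMSD: after superposing the six flanking
framework Cα anchors (three per side), the Cα traces are aligned by
dynamic time warping with the standard symmetric step pattern (diagonal,
horizontal, vertical; every visited cell contributes its squared
distance).  The score is `sqrt(total / path_length)` for the
minimum-total path, taking the shortest such path on ties — this makes
the score well defined and guarantees, for equal-length loops, that it
never exceeds the classical one-to-one RMSD.  Cα-only traces are used for
clustering; the antibody-loop match uses the full backbone.

Clustering is DBSCAN (scikit-learn, precomputed distance matrix).  `eps =
0.8 Å` and `min_pts = 3` by default: these are corpus-dependent knobs, so
they are exposed in the configuration and a k-distance profile helper
(`k_distance_profile`) supports per-dataset eps selection.  Loops are
sorted by identifier before clustering and labels renumbered by first
appearance, making the output order-independent up to nothing — it is
simply deterministic.  Cluster members inherit their cluster's named
canonical form; new loops take the nearest medoid's form iff within eps;
CDR3 forms carry a `*` marker because third-loop canonical classes are
early-stage.  γ/δ loops are extracted and filtered but not clustered by
default, mirroring the α/β-only scope of current canonical-form sets.

Antibody matching restricts candidates to the analogous loop type
(α1↔L1, α2↔L2, α3↔L3, β1↔H1, β2↔H2, β3↔H3) and identical length, then
applies ordinary backbone RMSD after anchor superposition, with matches
strictly below 1.5 Å.

## Structure I/O

One model per file (the first, unless requested otherwise); altlocs
resolve to the highest-occupancy conformer, ties to the lexicographically
smallest label; waters dropped; non-polymeric, non-water hetero residues
with ≥ 1 heavy atom are haptens.  The renumbered PDB applies IMGT numbers
to TCR variable domains, MHC G-domains and β2m; all other chains keep
author numbering.  The pairing header grammar is fixed as

```
REMARK 950 TCR <beta-like> <alpha-like> | MHC <class> <chains> | AG <ids>
```

one line per TCR (the original service's exact record layout is not
published; the semantics — TCR pair, its MHC, its antigen — are).  The
summary file is one header plus one tab-separated line per TCR with a
fixed, documented column order (`structure_io.SUMMARY_COLUMNS`); missing
values serialise as the literal token `NA`.

## Synthetic fixtures

`make_tcr_mhc_fixture` builds chains whose sequences are the bundled
consensus profiles (so detection and numbering behave exactly as on the
profiles) threaded along construction paths: groove helices run along x
with 10 Å spacing (so each planted CDR3 contact yields exactly one Cβ–Cβ
pair within 8 Å), partner-chain landmarks are solved from the four
pairing constraints by sphere intersection (unrealisable layouts raise a
geometry error), and the TCR framework cores are rigid copies of the
orientation reference core in general position.  Every requested landmark
distance is realised to 1e-6 Å and re-verified at construction time.
`make_loop_set` plants conformational clusters as planar template curves
displaced along z by the requested separation (a lower bound on the
inter-cluster DTW-RMSD) plus isotropic Gaussian noise.  All generators
are deterministic given their seed.

What the fixtures deliberately do **not** emulate: protein-like backbone
geometry, side chains, real sequence diversity (fixture chains *are* the
consensus), crystallographic artefacts (disorder, alternate conformers at
domain interfaces), or numbering edge cases from distant homologs.
Passing tests therefore demonstrate the correctness of the geometric and
combinatorial rules and of the numbering conventions — not detection
performance on divergent real sequences, which depends on profile quality.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic problems sized
for exactness: 50 seeded complexes for ground-truth recovery, 100
randomized instances per brute-force-oracle comparison (DTW path
enumeration at trace lengths ≤ 6, DBSCAN at ≤ 12 loops), 100 random rigid
transforms for invariance at 1e-6 tolerance.  Oracle comparisons are
exact (same floating-point inputs); rigid-transform checks use 1e-6
because rotation of coordinates legitimately perturbs distances at the
1e-12 level.  Frames require orthonormality to 1e-9; degenerate inputs
(coincident frame origins, axis-parallel torsion vectors, in-plane-free
docking axes, empty loops) raise typed errors rather than returning
values.

## Known limitations

* Bundled profiles cover human/mouse TCR V domains, MH1/CD1/MR1/MH2
  G-domains and β2m only; constant domains and other species are not
  numbered (author numbering is retained there).
* Absolute orientation-parameter values depend on the bundled reference
  core and are not numerically comparable to other orientation tools;
  orientation distances computed against external antibody tables are
  meaningful only if those parameters were derived with a compatible
  convention.
* Canonical-form names are user-supplied; the package assigns cluster
  structure, not the published form nomenclature.
* Binding affinities are accepted as an input column and passed through;
  no affinity curation is performed.
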