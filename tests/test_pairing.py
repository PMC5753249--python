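import itertools

import numpy as np
import pytest

from tcrcurate.config import PairingThresholds
from tcrcurate.numbering import number_chain
from tcrcurate.pairing import (
    TCR_AB,
    TCR_GD,
    TCR_OTHER,
    TCR_UNPAIRED,
    assign_complexes,
    cdr3_cb_atoms,
    detect_antigens,
    flag_unconventional,
    helix_cb_atoms,
    pair_mhc_chains,
    pair_tcr_chains,
)
from tcrcurate.synthetic import (
    FixtureSpec,
    GeometryError,
    make_tcr_mhc_fixture,
    _build_chain,
)

from oracles import brute_count_contacts, brute_min_dist


def annotate_chains(structure):
    return [number_chain(c) for c in structure.chains]


def pipeline(spec):
    structure, truth = make_tcr_mhc_fixture(spec)
    chains = annotate_chains(structure)
    thresholds = PairingThresholds()
    tcr = pair_tcr_chains(chains, thresholds)
    mhc = pair_mhc_chains(chains, thresholds)
    complexes = assign_complexes(tcr, mhc, chains, thresholds)
    haptens = [r for c in structure.chains for r in c.haptens()]
    complexes = detect_antigens(complexes, chains, haptens, thresholds)
    for rec in complexes:
        flag_unconventional(rec, chains, mhc, thresholds)
    return structure, truth, chains, tcr, mhc, complexes


class TestTcrPairing:
    @pytest.mark.parametrize("dist,n_pairs", [(21.9, 1), (22.1, 0)])
    def test_cysteine_cutoff_is_strict(self, point_chain_factory, dist, n_pairs):
        beta = point_chain_factory("B", "TCRB", {104: (0, 0, 0)})
        alpha = point_chain_factory("A", "TCRA", {104: (dist, 0, 0)})
        pairs = pair_tcr_chains([beta, alpha])
        paired = [p for p in pairs if p.tcr_type != TCR_UNPAIRED]
        assert len(paired) == n_pairs

    def test_planted_matching_recovered(self, point_chain_factory):
        """3 beta + 3 alpha chains: the generating permutation (15 A apart,
        all cross distances > 22 A) is recovered exactly."""
        spots = [np.array([0, 0, 0]), np.array([100, 0, 0]), np.array([0, 100, 0])]
        betas = [point_chain_factory(f"{i}B", "TCRB", {104: s}) for i, s in enumerate(spots)]
        alphas = [
            point_chain_factory(f"{i}A", "TCRA", {104: s + (0.0, 0.0, 15.0)})
            for i, s in enumerate(spots)
        ]
        pairs = pair_tcr_chains(betas + alphas)
        paired = {(p.beta_like_chain, p.alpha_like_chain)
                  for p in pairs if p.tcr_type != TCR_UNPAIRED}
        assert paired == {("0B", "0A"), ("1B", "1A"), ("2B", "2A")}

    def test_cross_type_pairs_are_other(self, point_chain_factory):
        delta = point_chain_factory("D", "TCRD", {104: (0, 0, 0)})
        alpha = point_chain_factory("A", "TCRA", {104: (10, 0, 0)})
        (pair,) = [p for p in pair_tcr_chains([delta, alpha])]
        assert pair.tcr_type == TCR_OTHER

    def test_gammadelta_type(self, point_chain_factory):
        delta = point_chain_factory("D", "TCRD", {104: (0, 0, 0)})
        gamma = point_chain_factory("G", "TCRG", {104: (10, 0, 0)})
        (pair,) = pair_tcr_chains([delta, gamma])
        assert pair.tcr_type == TCR_GD

    def test_missing_cys104_reported_unpaired(self, point_chain_factory):
        beta = point_chain_factory("B", "TCRB", {50: (0, 0, 0)})  # no 104
        alpha = point_chain_factory("A", "TCRA", {104: (5, 0, 0)})
        pairs = pair_tcr_chains([beta, alpha])
        assert {p.tcr_type for p in pairs} == {TCR_UNPAIRED}

    def test_each_chain_in_at_most_one_pair(self, point_chain_factory):
        chains = [
            point_chain_factory("B", "TCRB", {104: (0, 0, 0)}),
            point_chain_factory("A", "TCRA", {104: (10, 0, 0)}),
            point_chain_factory("C", "TCRA", {104: (12, 0, 0)}),
        ]
        pairs = pair_tcr_chains(chains)
        seen = list(itertools.chain.from_iterable(p.chain_ids for p in pairs))
        assert len(seen) == len(set(seen))


class TestMhcPairing:
    def test_half_maxima_accepted(self):
        structure, truth, chains, _, mhc, _ = pipeline(FixtureSpec(mhc_fraction=0.5))
        assert [(m.mhc_class, m.chain_ids) for m in mhc] == [("MH1", ("A", "B"))]
        maxima = (32.0, 32.0, 32.0, 37.0)
        for d, m in zip(mhc[0].constraint_distances, maxima):
            assert d == pytest.approx(0.5 * m, abs=1e-6)

    def test_one_constraint_over_maximum_rejected(self):
        spec = FixtureSpec(mhc_distances=(32.1, 16.0, 16.0, 18.5))
        structure, _ = make_tcr_mhc_fixture(spec)
        chains = annotate_chains(structure)
        assert pair_mhc_chains(chains) == []

    def test_mh1_exact_maxima_inclusive(self):
        spec = FixtureSpec(mhc_distances=(32.0, 32.0, 32.0, 37.0))
        structure, _ = make_tcr_mhc_fixture(spec)
        chains = annotate_chains(structure)
        (pair,) = pair_mhc_chains(chains)
        assert pair.constraint_distances == pytest.approx((32.0, 32.0, 32.0, 37.0))

    def test_mh2_exact_maxima_inclusive(self):
        spec = FixtureSpec(mhc_class="MH2", mhc_distances=(34.0, 22.0, 32.0, 28.0),
                           n_contacts=5)
        structure, _ = make_tcr_mhc_fixture(spec)
        chains = annotate_chains(structure)
        (pair,) = pair_mhc_chains(chains)
        assert pair.mhc_class == "MH2"

    def test_unrealisable_layout_raises(self):
        with pytest.raises(GeometryError):
            make_tcr_mhc_fixture(FixtureSpec(mhc_distances=(1.0, 1.0, 32.0, 37.0)))


class TestComplexAssignment:
    def test_highest_contact_mhc_wins(self):
        spec = FixtureSpec(n_contacts=7, decoy_contacts=3)
        structure, truth, chains, tcr, mhc, complexes = pipeline(spec)
        (rec,) = complexes
        assert rec.mhc.chain_ids == ("A", "B")
        assert rec.cb_contact_count == 7
        assert not rec.unconventional_flag

    def test_no_contacts_no_complex(self):
        spec = FixtureSpec(n_contacts=0, antigen=None)
        structure, truth, chains, tcr, mhc, complexes = pipeline(spec)
        (rec,) = complexes
        assert rec.mhc is None and rec.cb_contact_count == 0

    def test_exact_tie_flagged_ambiguous(self):
        spec = FixtureSpec(n_contacts=4, decoy_contacts=4, antigen=None)
        structure, truth, chains, tcr, mhc, complexes = pipeline(spec)
        (rec,) = complexes
        assert rec.unconventional_flag
        assert "ambiguous MHC assignment" in rec.unconventional_reasons

    @pytest.mark.parametrize("seed", range(5))
    def test_contact_count_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        spec = FixtureSpec(n_contacts=int(rng.integers(1, 9)))
        structure, truth, chains, tcr, mhc, complexes = pipeline(spec)
        by_id = {c.chain_id: c for c in chains}
        cdr3 = np.vstack([cdr3_cb_atoms(by_id["E"]), cdr3_cb_atoms(by_id["D"])])
        helix = np.vstack([helix_cb_atoms(by_id["A"]), helix_cb_atoms(by_id["B"])]) \
            if helix_cb_atoms(by_id["B"]).size else helix_cb_atoms(by_id["A"])
        expected = brute_count_contacts(cdr3, helix, 8.0)
        assert complexes[0].cb_contact_count == expected == spec.n_contacts


class TestAntigens:
    def test_peptide_detected(self):
        _, truth, chains, _, _, complexes = pipeline(FixtureSpec(antigen="peptide"))
        assert complexes[0].antigens == [("C", "peptide")]

    def test_protein_split_by_length(self):
        _, truth, chains, _, _, complexes = pipeline(FixtureSpec(antigen="protein"))
        assert complexes[0].antigens == [("C", "protein")]

    def test_hapten_requires_both_cutoffs(self):
        structure, truth, chains, tcr, mhc, complexes = pipeline(
            FixtureSpec(antigen="hapten")
        )
        assert complexes[0].antigens == [("C/LIG1", "hapten")]
        # move the hapten away from the CDR3 loops (keep MHC proximity):
        # the conjunction rule must then reject it
        hapten = structure.chain("C").residues[0]
        for atom in hapten.atoms:
            atom.coords = atom.coords + np.array([300.0, 0.0, 0.0])
        helix_end = helix_cb_atoms({c.chain_id: c for c in chains}["A"])[-1]
        shift = helix_end - hapten.atoms[0].coords + np.array([0.0, 0.0, -2.5])
        for atom in hapten.atoms:
            atom.coords = atom.coords + shift
        fresh = assign_complexes(tcr, mhc, chains)
        fresh = detect_antigens(fresh, chains, [hapten])
        by_id = {c.chain_id: c for c in chains}
        cdr3 = cdr3_cb_atoms(by_id["E"])
        assert brute_min_dist([hapten.atoms[0].coords], cdr3) > 8.0
        assert all(kind != "hapten" for _, kind in fresh[0].antigens)

    def test_far_chain_not_antigen(self):
        spec = FixtureSpec(antigen=None)
        structure, truth, chains, tcr, mhc, complexes = pipeline(spec)
        assert complexes[0].antigens == []


class TestUnconventional:
    def test_clean_complex_not_flagged(self):
        _, _, _, _, _, complexes = pipeline(FixtureSpec())
        assert not complexes[0].unconventional_flag

    def test_cross_pair_flagged(self):
        spec = FixtureSpec(beta_type="TCRD", alpha_type="TCRA")
        _, _, _, _, _, complexes = pipeline(spec)
        assert complexes[0].unconventional_flag
        assert "non-canonical chain pairing" in complexes[0].unconventional_reasons

    def test_interposed_protein_flagged(self):
        spec = FixtureSpec(n_contacts=0, antigen=None)
        structure, truth = make_tcr_mhc_fixture(spec)
        chains = annotate_chains(structure)
        by_id = {c.chain_id: c for c in chains}
        cdr3 = cdr3_cb_atoms(by_id["E"])
        helix = helix_cb_atoms(by_id["A"])
        placed = {i: cdr3[i % len(cdr3)] + (0.0, 3.0, 0.0) for i in range(20)}
        placed.update({20 + i: helix[i] + (0.0, 0.0, 4.0) for i in range(20)})
        bridge = _build_chain("X", "A" * 40, placed, np.zeros(3), np.array([1, 0, 0]), 20.0)
        structure.chains.append(bridge)
        chains = annotate_chains(structure)
        thresholds = PairingThresholds()
        tcr = pair_tcr_chains(chains, thresholds)
        mhc = pair_mhc_chains(chains, thresholds)
        complexes = assign_complexes(tcr, mhc, chains, thresholds)
        complexes = detect_antigens(complexes, chains, [], thresholds)
        (rec,) = complexes
        flag_unconventional(rec, chains, mhc, thresholds)
        assert rec.mhc is None
        assert rec.unconventional_flag
        assert "interposed antigen" in rec.unconventional_reasons


class TestInvariances:
    def test_chain_order_permutation(self):
        structure, truth = make_tcr_mhc_fixture(FixtureSpec(decoy_contacts=2))
        chains = annotate_chains(structure)
        base = pair_tcr_chains(chains)
        base_m = pair_mhc_chains(chains)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(chains)
            rng.shuffle(perm)
            assert pair_tcr_chains(perm) == base
            assert pair_mhc_chains(perm) == base_m

    def test_rigid_transform_invariance(self):
        structure, truth = make_tcr_mhc_fixture(FixtureSpec(decoy_contacts=3))
        chains = annotate_chains(structure)
        base_t = pair_tcr_chains(chains)
        base_m = pair_mhc_chains(chains)
        base_c = assign_complexes(base_t, base_m, chains)
        rng = np.random.default_rng(1)
        for _ in range(5):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            shift = rng.uniform(-50, 50, 3)
            for chain in structure.chains:
                for res in chain.residues:
                    for atom in res.atoms:
                        atom.coords = rot @ atom.coords + shift
            tp = pair_tcr_chains(chains)
            mp = pair_mhc_chains(chains)
            cp = assign_complexes(tp, mp, chains)
            assert [(p.chain_ids, p.tcr_type) for p in tp] == [
                (p.chain_ids, p.tcr_type) for p in base_t
            ]
            assert [p.chain_ids for p in mp] == [p.chain_ids for p in base_m]
            assert [(r.mhc.chain_ids if r.mhc else None, r.cb_contact_count)
                    for r in cp] == [
                (r.mhc.chain_ids if r.mhc else None, r.cb_contact_count)
                for r in base_c
            ]

    def test_threshold_monotonicity(self, point_chain_factory):
        """Shrinking the cysteine cutoff never increases accepted pairs."""
        rng = np.random.default_rng(5)
        chains = []
        for i in range(4):
            chains.append(point_chain_factory(f"{i}B", "TCRB", {104: rng.uniform(0, 30, 3)}))
            chains.append(point_chain_factory(f"{i}A", "TCRA", {104: rng.uniform(0, 30, 3)}))
        counts = []
        for cutoff in (30.0, 22.0, 15.0, 8.0, 2.0):
            thresholds = PairingThresholds(tcr_cys_dist=cutoff)
            pairs = pair_tcr_chains(chains, thresholds)
            counts.append(sum(1 for p in pairs if p.tcr_type != TCR_UNPAIRED))
        assert counts == sorted(counts, reverse=True)
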