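import numpy as np
import pytest

from tcrcurate.cdr_clustering import (
    NOISE,
    CDRLoop,
    assign_canonical,
    cluster_cdrs,
    compute_medoids,
    dtw_rmsd,
    extract_cdrs,
    match_antibody_loop,
    predict_canonical,
    quality_filter,
)
from tcrcurate.synthetic import make_loop_set

from oracles import brute_dbscan, brute_dtw, brute_quality_filter, brute_rmsd, same_partition


def make_loop(name="B3", coords=None, length=None, resolution=2.0, bfactor=20.0,
              missing=False, anchors=None, loop_id=None, backbone=None):
    coords = np.asarray(coords if coords is not None else
                        [[i * 1.5, 0.0, 0.0] for i in range(6)], float)
    return CDRLoop(
        loop_id=loop_id or ("test", "X", name),
        imgt_range=(105, 117),
        ca_coords=coords,
        length=length or len(coords),
        resolution=resolution,
        max_backbone_bfactor=bfactor,
        missing_residues=missing,
        anchor_coords=anchors,
        backbone_coords=backbone,
    )


class TestExtractCdrs:
    def test_full_cdr1_coverage_length_twelve(self, point_chain_factory):
        chain = point_chain_factory(
            "X", "TCRB", {p: (p * 2.0, 0, 0) for p in range(24, 42)}
        )
        loops = extract_cdrs(chain, "tst", 2.0)
        cdr1 = next(l for l in loops if l.loop_id[2] == "B1")
        assert cdr1.length == 12
        assert not cdr1.missing_residues

    def test_gap_inside_cdr1_flags_missing(self, point_chain_factory):
        positions = [p for p in range(24, 42) if p not in (30, 31)]
        chain = point_chain_factory("X", "TCRB", {p: (p * 2.0, 0, 0) for p in positions})
        loops = extract_cdrs(chain, "tst", 2.0)
        cdr1 = next(l for l in loops if l.loop_id[2] == "B1")
        assert cdr1.missing_residues

    def test_cdr3_insertions_counted(self, point_chain_factory):
        positions = {p: (p * 2.0, 0, 0) for p in range(102, 121)}
        positions[(111, "A")] = (300.0, 0, 0)
        positions[(111, "B")] = (301.0, 0, 0)
        chain = point_chain_factory("X", "TCRA", positions)
        loops = extract_cdrs(chain, "tst", 2.0)
        cdr3 = next(l for l in loops if l.loop_id[2] == "A3")
        assert cdr3.length == 15
        assert cdr3.anchor_coords is not None and len(cdr3.anchor_coords) == 6


class TestQualityFilter:
    @pytest.mark.parametrize(
        "resolution,bfactor,missing,kept",
        [
            (2.8, 79.9, False, True),   # both boundaries on the kept side
            (2.8, 80.0, False, False),  # "80 or higher" removed
            (2.9, 20.0, False, False),
            (2.0, 20.0, True, False),
            (None, 20.0, False, False),
        ],
    )
    def test_boundary_semantics(self, resolution, bfactor, missing, kept):
        loop = make_loop(resolution=resolution, bfactor=bfactor, missing=missing)
        assert (quality_filter([loop]) == [loop]) is kept

    def test_matches_oracle_on_planted_violations(self):
        rng = np.random.default_rng(21)
        loops = []
        for i in range(100):
            loops.append(
                make_loop(
                    loop_id=("t", f"{i:03d}", "B1"),
                    resolution=float(rng.uniform(1.5, 4.0)),
                    bfactor=float(rng.uniform(40.0, 120.0)),
                    missing=bool(rng.random() < 0.3),
                )
            )
        kept = quality_filter(loops)
        expected = brute_quality_filter(loops, 2.8, 80.0)
        assert [l.loop_id for l in kept] == [l.loop_id for l in expected]


class TestDtwRmsd:
    def test_self_distance_zero(self):
        loop = make_loop()
        assert dtw_rmsd(loop, loop) == 0.0

    def test_identity_warp_equals_classical_rmsd(self):
        """Small perturbations of an equal-length trace keep the identity
        warp optimal, so DTW-RMSD equals the classical CA RMSD."""
        rng = np.random.default_rng(31)
        base = np.array([[i * 3.0, 0.0, 0.0] for i in range(6)])
        for _ in range(20):
            other = base + rng.normal(0, 0.05, base.shape)
            got = dtw_rmsd(make_loop(coords=base), make_loop(coords=other))
            assert got == pytest.approx(brute_rmsd(base, other), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 7), rng.integers(2, 7)
        a = rng.uniform(-5, 5, (na, 3))
        b = rng.uniform(-5, 5, (nb, 3))
        got = dtw_rmsd(make_loop(coords=a), make_loop(coords=b))
        assert got == pytest.approx(brute_dtw(a, b), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(32)
        a = make_loop(coords=rng.uniform(-5, 5, (5, 3)))
        b = make_loop(coords=rng.uniform(-5, 5, (7, 3)))
        assert dtw_rmsd(a, b) == pytest.approx(dtw_rmsd(b, a), abs=1e-12)

    def test_never_exceeds_classical_rmsd_equal_lengths(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            a = rng.uniform(-5, 5, (6, 3))
            b = rng.uniform(-5, 5, (6, 3))
            assert dtw_rmsd(make_loop(coords=a), make_loop(coords=b)) <= (
                brute_rmsd(a, b) + 1e-12
            )

    def test_anchor_superposition_removes_pose(self):
        rng = np.random.default_rng(34)
        coords = rng.uniform(-5, 5, (6, 3))
        anchors = rng.uniform(-8, 8, (6, 3))
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([4.0, -2.0, 9.0])
        a = make_loop(coords=coords, anchors=anchors)
        b = make_loop(coords=coords @ rot.T + shift, anchors=anchors @ rot.T + shift)
        assert dtw_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_empty_loop_rejected(self):
        with pytest.raises(ValueError):
            make_loop(coords=np.empty((0, 3)), length=0)


class TestClustering:
    def test_planted_clusters_recovered(self):
        loops, truth = make_loop_set(n_clusters=2, loops_per_cluster=10,
                                     sigma=0.1, separation=5.0, seed=1)
        assignments = cluster_cdrs(loops, eps=1.0, min_pts=3)
        order = sorted(range(len(loops)), key=lambda i: loops[i].loop_id)
        got = [a.cluster_label for a in assignments]
        assert same_partition([truth[i] for i in order], got)
        assert got.count(NOISE) == 0

    def test_all_far_apart_is_noise(self):
        loops = [
            make_loop(coords=[[i * 100.0 + j, 0, 0] for j in range(5)],
                      loop_id=("t", str(i), "B3"))
            for i in range(6)
        ]
        assignments = cluster_cdrs(loops, eps=0.5, min_pts=3)
        assert all(a.cluster_label == NOISE for a in assignments)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_dbscan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        loops = [
            make_loop(coords=rng.uniform(0, 6, (4, 3)), loop_id=("t", f"{i:02d}", "B3"))
            for i in range(n)
        ]
        eps = float(rng.uniform(1.0, 4.0))
        min_pts = int(rng.integers(2, 4))
        assignments = cluster_cdrs(loops, eps=eps, min_pts=min_pts)
        mat = [[dtw_rmsd(a, b) for b in loops] for a in loops]
        expected = brute_dbscan(mat, eps, min_pts)
        assert same_partition(expected, [a.cluster_label for a in assignments])

    def test_input_order_invariance(self):
        loops, _ = make_loop_set(n_clusters=2, loops_per_cluster=5, seed=2)
        base = cluster_cdrs(loops, eps=1.0, min_pts=3)
        rng = np.random.default_rng(0)
        shuffled = list(loops)
        rng.shuffle(shuffled)
        again = cluster_cdrs(shuffled, eps=1.0, min_pts=3)
        assert [(a.loop_id, a.cluster_label) for a in base] == [
            (a.loop_id, a.cluster_label) for a in again
        ]


class TestCanonicalForms:
    def _clustered(self):
        loops, _ = make_loop_set(n_clusters=2, loops_per_cluster=5, sigma=0.05,
                                 separation=5.0, seed=5)
        assignments = cluster_cdrs(loops, eps=1.0, min_pts=3)
        medoids = compute_medoids(loops, assignments)
        return loops, assignments, medoids

    def test_members_inherit_cluster_form(self):
        loops, assignments, medoids = self._clustered()
        named = {0: "B3-1", 1: "B3-2"}
        assignments = assign_canonical(assignments, named)
        for a in assignments:
            assert a.canonical_form == named[a.cluster_label] + "*"  # CDR3: provisional

    def test_medoid_gets_own_cluster_form(self):
        loops, assignments, medoids = self._clustered()
        named = {0: "form-a", 1: "form-b"}
        assign_canonical(assignments, named)
        by_id = {a.loop_id: a for a in assignments}
        for label, medoid in medoids.items():
            assert by_id[medoid.loop_id].canonical_form.rstrip("*") == named[label]

    def test_new_loop_nearest_medoid_within_eps(self):
        loops, assignments, medoids = self._clustered()
        named = {0: "form-a", 1: "form-b"}
        near = CDRLoop(
            loop_id=("new", "Z", "B3"),
            imgt_range=(105, 117),
            ca_coords=medoids[0].ca_coords + 0.01,
            length=medoids[0].length,
            anchor_coords=medoids[0].anchor_coords,
        )
        assert predict_canonical(near, medoids, named, eps=1.0) == "form-a*"

    def test_new_loop_beyond_eps_unassigned(self):
        loops, assignments, medoids = self._clustered()
        far = CDRLoop(
            loop_id=("new", "Z", "B3"),
            imgt_range=(105, 117),
            ca_coords=medoids[0].ca_coords + np.array([0.0, 0.0, 50.0]),
            length=medoids[0].length,
            anchor_coords=medoids[0].anchor_coords,
        )
        assert predict_canonical(far, medoids, {0: "x", 1: "y"}, eps=1.0) is None

    def test_noise_has_no_form(self):
        loops = [
            make_loop(coords=[[i * 50.0 + j, 0, 0] for j in range(4)],
                      loop_id=("t", str(i), "B1"))
            for i in range(4)
        ]
        assignments = cluster_cdrs(loops, eps=0.5, min_pts=3)
        assign_canonical(assignments, {0: "whatever"})
        assert all(a.canonical_form is None for a in assignments)


class TestAntibodyMatch:
    def _pair(self, rmsd_target, length=8, seed=41):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-5, 5, (length, 3))
        backbone = np.stack([coords + off for off in
                             [(-1.2, 0.4, 0), (0, 0, 0), (1.2, 0.4, 0), (1.4, 1.6, 0)]],
                            axis=1)
        anchors = rng.uniform(-8, 8, (6, 3))
        noise = rng.normal(0, 1.0, backbone.shape)
        flat = noise.reshape(-1, 3)
        scale = rmsd_target / brute_rmsd(np.zeros_like(flat), flat)
        other = backbone + noise * scale
        tcr = make_loop(name="B3", coords=coords, anchors=anchors, backbone=backbone)
        ab = CDRLoop(
            loop_id=("ab", "H", "H3"), imgt_range=(105, 117),
            ca_coords=other[:, 1, :], length=length,
            anchor_coords=anchors.copy(), backbone_coords=other,
        )
        return tcr, ab

    def test_identical_coordinates_match_at_zero(self):
        tcr, ab = self._pair(0.0)
        matches = match_antibody_loop(tcr, [ab])
        assert len(matches) == 1 and matches[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_non_analogous_type_rejected(self):
        tcr, ab = self._pair(0.0)
        ab.loop_id = ("ab", "H", "L3")  # β3 must match H3, not L3
        assert match_antibody_loop(tcr, [ab]) == []

    def test_length_mismatch_rejected(self):
        tcr, ab = self._pair(0.0, length=8)
        _, ab7 = self._pair(0.0, length=7)
        ab7.loop_id = ("ab", "H", "H3")
        assert match_antibody_loop(tcr, [ab7]) == []

    @pytest.mark.parametrize("target,matched", [(1.49, True), (1.51, False)])
    def test_cutoff_boundary(self, target, matched):
        tcr, ab = self._pair(target)
        got = match_antibody_loop(tcr, [ab])
        assert bool(got) is matched
        if matched:
            assert got[0][1] == pytest.approx(target, abs=1e-9)
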