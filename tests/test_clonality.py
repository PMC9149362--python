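"""Distances, MLL delimitation, richness and clone correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radpop.clonality import (
    MLLClusterer,
    calibrate_clone_threshold,
    clone_correct,
    delimit_mlls,
    distance_matrix,
    exact_match_mlg,
    genotypic_richness,
    prevosti_distance,
)
from radpop.core import PopulationMap, SSRMatrix
from radpop.synthetic import SimConfig, simulate_dataset

from conftest import make_gm


class TestPrevostiDistance:
    def test_identical_vectors(self):
        gm = make_gm([[0, 1, 2], [0, 1, 2]])
        assert prevosti_distance(gm, "s1", "s2") == 0.0

    def test_hand_example(self):
        gm = make_gm([[0, 1, 2, 1], [0, 1, 0, 2]])
        assert prevosti_distance(gm, "s1", "s2") == pytest.approx(0.375)

    def test_opposite_homozygotes(self):
        gm = make_gm([[0, 0, 0], [2, 2, 2]])
        assert prevosti_distance(gm, "s1", "s2") == 1.0

    def test_missing_loci_excluded(self):
        gm = make_gm([[0, 2, -1], [0, -1, 2]])
        assert prevosti_distance(gm, "s1", "s2") == 0.0

    def test_no_shared_loci_is_nan(self):
        gm = make_gm([[0, -1], [-1, 2]])
        assert np.isnan(prevosti_distance(gm, "s1", "s2"))


def test_distance_matrix_matches_brute_force():
    """All-pairs grid equals a per-pair double loop on a 6 x 20 matrix."""
    rng = np.random.default_rng(3)
    calls = rng.integers(-1, 3, size=(6, 20)).astype(np.int8)
    gm = make_gm(calls, positions=list(range(1, 21)))
    dm = distance_matrix(gm)
    for i in range(6):
        for j in range(6):
            expected = 0.0 if i == j else prevosti_distance(
                gm, gm.samples[i], gm.samples[j]
            )
            if np.isnan(expected):
                assert np.isnan(dm.values[i, j])
            else:
                assert dm.values[i, j] == pytest.approx(expected)
    assert np.allclose(dm.values, dm.values.T, equal_nan=True)


def test_distance_matrix_ignores_all_missing_locus():
    calls = np.array([[0, 1], [2, 1], [1, 0]], dtype=np.int8)
    gm = make_gm(calls)
    with_extra = make_gm(
        np.hstack([calls, np.full((3, 1), -1, dtype=np.int8)]),
        positions=[1, 38, 75],
    )
    assert np.allclose(
        distance_matrix(gm).values, distance_matrix(with_extra).values
    )


def test_calibrate_threshold_is_replicate_maximum():
    gm = make_gm(
        [
            [0] * 100,
            [0] * 98 + [1, 1],           # d = 0.01 from s1
            [1] * 100,
            [1] * 90 + [0] * 10,         # d = 0.05 from s3
        ],
        samples=["a", "a_rep", "b", "b_rep"],
        positions=list(range(1, 101)),
    )
    pm = PopulationMap(
        assignment={s: "P" for s in gm.samples},
        replicate_pairs=[("a", "a_rep"), ("b", "b_rep")],
    )
    dm = distance_matrix(gm)
    assert calibrate_clone_threshold(dm, pm) == pytest.approx(0.05)
    # threshold >= every replicate distance by construction
    for a, b in pm.replicate_pairs:
        assert dm.get(a, b) <= 0.05 + 1e-12


def test_calibrate_without_replicates_is_error(toy_gm, toy_pm):
    dm = distance_matrix(toy_gm)
    with pytest.raises(ValueError, match="manual threshold"):
        calibrate_clone_threshold(dm, toy_pm)


class TestDelimitation:
    def _chain_dm(self):
        # d(A,B) = d(B,C) = 0.05, d(A,C) = 0.20
        from radpop.clonality import DistanceMatrix

        values = np.array(
            [[0.0, 0.05, 0.20], [0.05, 0.0, 0.05], [0.20, 0.05, 0.0]]
        )
        return DistanceMatrix(
            samples=["A", "B", "C"], values=values,
            shared=np.full((3, 3), 10),
        )

    def test_all_zero_distances_one_mll(self):
        from radpop.clonality import DistanceMatrix

        dm = DistanceMatrix(
            samples=["A", "B", "C"], values=np.zeros((3, 3)),
            shared=np.full((3, 3), 5),
        )
        assert delimit_mlls(dm, 0.073).n_lineages == 1

    def test_farthest_neighbor_splits_chain(self):
        part = delimit_mlls(self._chain_dm(), 0.073, "farthest_neighbor")
        assert sorted(map(sorted, part.clusters)) == [["A", "B"], ["C"]]

    def test_nearest_neighbor_chains_through(self):
        part = delimit_mlls(self._chain_dm(), 0.073, "nearest_neighbor")
        assert part.n_lineages == 1

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValueError, match="linkage"):
            MLLClusterer(threshold=0.1, linkage="ward").fit(np.zeros((2, 2)))

    def test_threshold_zero_equals_exact_matching(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        calls[5] = calls[0]
        calls[7] = calls[2]
        gm = make_gm(calls, positions=list(range(1, 41)))
        part = delimit_mlls(distance_matrix(gm), 0.0)
        labels = part.labels()
        for i in range(12):
            for j in range(i + 1, 12):
                same = labels[gm.samples[i]] == labels[gm.samples[j]]
                assert same == bool((calls[i] == calls[j]).all())

    def test_mll_count_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(10, 60)).astype(np.int8)
        gm = make_gm(calls, positions=list(range(1, 61)))
        dm = distance_matrix(gm)
        counts = [
            delimit_mlls(dm, t).n_lineages for t in np.linspace(0, 1, 11)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRichness:
    @pytest.mark.parametrize(
        "G,N,expected",
        [(4, 14, 0.23), (11, 15, 0.71), (1, 9, 0.0), (11, 12, 0.91)],
    )
    def test_values(self, G, N, expected):
        assert genotypic_richness(G, N).rounded == pytest.approx(expected)

    def test_undefined_below_two_samples(self):
        with pytest.raises(ValueError):
            genotypic_richness(1, 1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 50), st.data())
    def test_bounds_and_relabeling_invariance(self, N, data):
        G = data.draw(st.integers(1, N))
        r = genotypic_richness(G, N)
        assert 0.0 <= r.R <= 1.0


def test_clone_correct_keeps_best_call_rate():
    gm = make_gm(
        [[0, 1, 2, 1], [0, 1, -1, 1], [2, 2, 2, 2]],
        samples=["a1", "a2", "b"],
    )
    part = delimit_mlls(distance_matrix(gm), 0.0)
    out = clone_correct(gm, part)
    assert out.samples == ["a1", "b"]  # a1 has the higher call rate
    assert part.representatives is not None


def test_clone_correct_identity_for_all_unique():
    rng = np.random.default_rng(12)
    gm = make_gm(rng.integers(0, 3, size=(5, 30)).astype(np.int8),
                 positions=list(range(1, 31)))
    part = delimit_mlls(distance_matrix(gm), 0.0)
    assert clone_correct(gm, part).samples == gm.samples


class TestExactMatchMLG:
    def test_identical_profiles_share_mlg(self):
        calls = [[(178, 182), (100, 100)], [(178, 182), (100, 100)]]
        ssr = SSRMatrix(samples=["a", "b"], loci=["L1", "L2"], calls=calls)
        assert exact_match_mlg(ssr).n_lineages == 1

    def test_one_allele_difference_separates(self):
        calls = [[(178, 182)], [(178, 180)]]
        ssr = SSRMatrix(samples=["a", "b"], loci=["L1"], calls=calls)
        assert exact_match_mlg(ssr).n_lineages == 2

    def test_missing_needs_one_shared_locus(self):
        calls = [[(1, 2), None], [None, (3, 4)]]
        ssr = SSRMatrix(samples=["a", "b"], loci=["L1", "L2"], calls=calls)
        assert exact_match_mlg(ssr).n_lineages == 2

    def test_six_mlgs_over_twelve_gives_r_045(self):
        cfg = SimConfig(seed=21, n_pops=1, samples_per_pop=12,
                        genets_per_pop=6, ramet_allocation=((4, 3, 2, 1, 1, 1),),
                        missing_rate=0.05)
        ssr, truth = simulate_ssr_helper(cfg)
        part = exact_match_mlg(ssr)
        assert part.n_lineages == 6
        assert genotypic_richness(6, 12).rounded == pytest.approx(0.45)


def simulate_ssr_helper(cfg):
    from radpop.synthetic import simulate_ssr

    return simulate_ssr(cfg)


def test_replicate_calibrated_threshold_recovers_planted_genets():
    """Single-run version of the recovery property (the 100-run suite lives
    in the acceptance tests)."""
    cfg = SimConfig(seed=77, n_pops=2, samples_per_pop=10, n_loci=400,
                    neutral_f=0.3, outlier_fraction=0.0, genets_per_pop=3,
                    ramet_allocation=((5, 4, 1), (6, 3, 1)),
                    flip_rate=0.05, missing_rate=0.1, replicates_per_pop=10)
    gm, pm, truth = simulate_dataset(cfg)
    dm = distance_matrix(gm)
    t = calibrate_clone_threshold(dm, pm)
    part = delimit_mlls(dm, t, "nearest_neighbor")
    recovered = {frozenset(cl) for cl in part.clusters}
    assert recovered == {frozenset(v) for v in truth.genet_partition().values()}


def test_linkage_newick_parses_and_covers_all_samples():
    from io import StringIO

    import dendropy

    from radpop.clonality import linkage_newick

    rng = np.random.default_rng(14)
    calls = rng.integers(0, 3, size=(7, 50)).astype(np.int8)
    gm = make_gm(calls, positions=list(range(1, 51)))
    model = MLLClusterer(threshold=0.5).fit(distance_matrix(gm).values)
    nwk = linkage_newick(model.linkage_tree_, gm.samples)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == sorted(gm.samples)
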