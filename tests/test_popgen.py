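"""Diversity, Weir-Cockerham FST and the permutation G-test."""

import numpy as np
import pytest

from radpop.core import PopulationMap
from radpop.popgen import (
    allele_frequencies,
    diversity_summary,
    fis,
    g_test_differentiation,
    observed_heterozygosity,
    pca_structure,
    unbiased_gene_diversity,
    wc_fst,
    wc_variance_components,
)
from radpop.synthetic import SimConfig, simulate_dataset

from conftest import make_gm


def wc_theta_oracle(n1, n2, p1, p2, h1, h2):
    """Independent straight-line transcription of the two-population
    Weir & Cockerham variance-component formulas."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestAlleleFrequencies:
    def test_mixed_genotypes(self):
        gm = make_gm([[0], [1], [2]], populations=["P", "P", "P"])
        p, n = allele_frequencies(gm)["P"]
        assert p[0] == pytest.approx(0.5) and n[0] == 3

    def test_all_ref(self):
        gm = make_gm([[0], [0]], populations=["P", "P"])
        assert allele_frequencies(gm)["P"][0][0] == 0.0

    def test_all_missing_is_nan(self):
        gm = make_gm([[-1], [-1]], populations=["P", "P"])
        assert np.isnan(allele_frequencies(gm)["P"][0][0])

    def test_within_binomial_error_of_truth(self):
        cfg = SimConfig(seed=31, n_pops=2, samples_per_pop=200, n_loci=300,
                        outlier_fraction=0.0, flip_rate=0.0, missing_rate=0.0,
                        replicates_per_pop=0)
        gm, pm, truth = simulate_dataset(cfg)
        freqs = allele_frequencies(gm)
        for pop, (p, n) in freqs.items():
            sd = np.sqrt(truth.pop_freqs[pop] * (1 - truth.pop_freqs[pop]) / (2 * n))
            assert (np.abs(p - truth.pop_freqs[pop]) <= 3 * sd + 1e-9).mean() > 0.97


def test_observed_heterozygosity():
    gm = make_gm([[1], [1], [2]], populations=["P"] * 3)
    assert observed_heterozygosity(gm)["P"][0] == pytest.approx(2 / 3)
    gm2 = make_gm([[1], [1]], populations=["P"] * 2)
    assert observed_heterozygosity(gm2)["P"][0] == 1.0


def test_unbiased_gene_diversity_hand_value():
    # p = 0.5, n = 10 -> (20/19) * 0.5 = 0.5263...
    calls = [[1]] * 10
    gm = make_gm(calls, populations=["P"] * 10)
    he = unbiased_gene_diversity(gm)["P"][0]
    assert he == pytest.approx(20 / 19 * 0.5, abs=1e-10)


def test_he_zero_for_monomorphic():
    gm = make_gm([[0]] * 5, populations=["P"] * 5)
    assert unbiased_gene_diversity(gm)["P"][0] == 0.0


class TestFis:
    def test_all_heterozygotes_hand_value(self):
        gm = make_gm([[1]] * 10, populations=["P"] * 10)
        assert fis(gm)["P"] == pytest.approx(1 - 1 / (20 / 19 * 0.5), abs=1e-9)

    def test_fully_inbred_segregating(self):
        gm = make_gm([[0], [0], [2], [2]], populations=["P"] * 4)
        assert fis(gm)["P"] == pytest.approx(1.0)

    def test_hwe_population_near_zero(self):
        cfg = SimConfig(seed=32, n_pops=1, samples_per_pop=150, n_loci=400,
                        outlier_fraction=0.0, flip_rate=0.0, missing_rate=0.0,
                        replicates_per_pop=0)
        gm, _, _ = simulate_dataset(cfg)
        assert abs(fis(gm)["pop1"]) < 0.05

    def test_clonality_drives_fis_negative(self):
        """More clonal populations show more negative multilocus FIS."""
        results = {}
        for genets in (2, 10, 20):
            cfg = SimConfig(seed=33, n_pops=1, samples_per_pop=20, n_loci=500,
                            genets_per_pop=genets, outlier_fraction=0.0,
                            flip_rate=0.0, missing_rate=0.0, replicates_per_pop=0)
            gm, _, _ = simulate_dataset(cfg)
            results[genets] = fis(gm)["pop1"]
        assert results[2] < results[10] < 0.1
        assert results[2] < -0.2


class TestWcFst:
    def test_fixed_difference(self):
        gm = make_gm([[2], [2], [0], [0]], populations=["A", "A", "B", "B"])
        res = wc_fst(gm, None, ("A", "B"))
        assert res.per_locus_theta[0] == pytest.approx(1.0)
        assert res.a[0] > 0 and res.b[0] == pytest.approx(0.0)
        assert res.c[0] == pytest.approx(0.0)

    def test_hand_value(self):
        n = np.array([[10.0], [10.0]])
        p = np.array([[0.5], [0.5]])
        h = np.array([[0.5], [0.5]])
        a, b, c = wc_variance_components(n, p, h)
        assert (a / (a + b + c))[0] == pytest.approx(-0.0556, abs=1e-4)

    def test_matches_independent_transcription(self):
        """Per-locus theta equals the straight-line oracle to 1e-12 on 100
        random loci."""
        rng = np.random.default_rng(41)
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, size=2)
            p1, p2 = rng.uniform(0.05, 0.95, size=2)
            h1, h2 = rng.uniform(0, 1, size=2)
            a, b, c = wc_variance_components(
                np.array([[n1], [n2]], dtype=float),
                np.array([[p1], [p2]]),
                np.array([[h1], [h2]]),
            )
            ao, bo, co = wc_theta_oracle(n1, n2, p1, p2, h1, h2)
            assert a[0] == pytest.approx(ao, abs=1e-12)
            assert b[0] == pytest.approx(bo, abs=1e-12)
            assert c[0] == pytest.approx(co, abs=1e-12)

    def test_monomorphic_loci_excluded(self):
        gm = make_gm(
            [[0, 2], [0, 2], [0, 0], [0, 0]],
            populations=["A", "A", "B", "B"],
        )
        res = wc_fst(gm, None, ("A", "B"))
        assert res.n_loci_used == 1  # the first locus is monomorphic in both


def test_g_test_identical_counts_null():
    gm = make_gm(
        [[0], [1], [2], [0], [1], [2]],
        populations=["A", "A", "A", "B", "B", "B"],
    )
    res = g_test_differentiation(gm, None, ("A", "B"), n_permutations=99, seed=1)
    assert res.per_locus_g[0] == pytest.approx(0.0, abs=1e-10)
    assert res.per_locus_p[0] == 1.0


def test_g_test_fixed_difference_significant():
    calls = [[2]] * 10 + [[0]] * 10
    gm = make_gm(calls, populations=["A"] * 10 + ["B"] * 10)
    res = g_test_differentiation(gm, None, ("A", "B"), n_permutations=999, seed=2)
    assert res.per_locus_p[0] <= 0.01
    assert res.combined_p <= 0.01


def test_g_test_null_rejection_rate_calibrated():
    """Splitting one panmictic population at random gives a ~5% rejection
    rate at alpha = 0.05."""
    rng = np.random.default_rng(55)
    rejections = 0
    n_runs = 120
    for k in range(n_runs):
        cfg = SimConfig(seed=6000 + k, n_pops=1, samples_per_pop=16, n_loci=30,
                        outlier_fraction=0.0, flip_rate=0.0, missing_rate=0.0,
                        replicates_per_pop=0)
        gm, _, _ = simulate_dataset(cfg)
        labels = np.array(["A"] * 8 + ["B"] * 8)
        rng.shuffle(labels)
        gm.populations = labels.tolist()
        res = g_test_differentiation(gm, None, ("A", "B"),
                                     n_permutations=199, seed=k)
        rejections += res.combined_p <= 0.05
    rate = rejections / n_runs
    sd = np.sqrt(0.05 * 0.95 / n_runs)
    assert abs(rate - 0.05) <= 3 * sd


def test_g_test_requires_enough_permutations(toy_gm):
    with pytest.raises(ValueError, match="99"):
        g_test_differentiation(toy_gm, None, ("A", "B"), n_permutations=10, seed=1)


class TestPcaStructure:
    def test_two_clusters_separate_on_pc1(self):
        calls = np.array([[0] * 20] * 5 + [[2] * 20] * 5, dtype=np.int8)
        # add a polymorphic locus inside each cluster to avoid degeneracy
        calls[0, 0] = 1
        calls[5, 1] = 1
        gm = make_gm(calls, positions=list(range(1, 21)))
        scores, pct = pca_structure(gm, n_components=2)
        side = scores[:, 0] > 0
        assert side[:5].all() != side[5:].all()  # PC1 splits the clusters
        assert pct[0] > pct[1] and pct.sum() <= 100.0 + 1e-9

    def test_scores_invariant_to_sample_order_up_to_sign(self):
        rng = np.random.default_rng(60)
        calls = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        gm = make_gm(calls, positions=list(range(1, 41)))
        perm = list(rng.permutation(8))
        s1, _ = pca_structure(gm, 2)
        s2, _ = pca_structure(gm.take_samples(perm), 2)
        for k in range(2):
            col = s1[perm, k]
            assert np.allclose(col, s2[:, k], atol=1e-8) or np.allclose(
                col, -s2[:, k], atol=1e-8
            )
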