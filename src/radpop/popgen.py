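"""Diversity and differentiation statistics on (clone-corrected) genotypes.

Per population: observed heterozygosity Ho, Nei's unbiased gene diversity
He, and the multilocus inbreeding coefficient FIS = 1 - sum(Ho_l)/sum(He_l)
(strongly negative FIS is the classic signature of clonal reproduction).
Between populations: Weir & Cockerham's theta from the a/b/c variance
components, both as the "weighted" multilocus ratio sum(a)/sum(a+b+c) and
as the mean of per-locus ratios, plus a permutation G-test of genic
differentiation combined across loci by Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .core import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "DiversityResult",
    "FstResult",
    "GTestResult",
    "allele_frequencies",
    "observed_heterozygosity",
    "unbiased_gene_diversity",
    "fis",
    "diversity_summary",
    "wc_fst",
    "g_test_differentiation",
    "pca_structure",
]


def _pop_rows(gm: GenotypeMatrix, pm: PopulationMap | None) -> dict[str, np.ndarray]:
    """Population -> row indices, from the map or the matrix annotation."""
    if pm is not None:
        pops: dict[str, list[int]] = {}
        for i, s in enumerate(gm.samples):
            if s in pm.assignment:
                pops.setdefault(pm.assignment[s], []).append(i)
    elif gm.populations is not None:
        pops = {}
        for i, p in enumerate(gm.populations):
            pops.setdefault(p, []).append(i)
    else:
        raise ValueError("no population information available")
    if not pops:
        raise ValueError("no samples fall in any population")
    return {p: np.asarray(ix, dtype=int) for p, ix in pops.items()}


@dataclass
class DiversityResult:
    populations: list[str]
    ho: dict[str, float]
    he: dict[str, float]
    fis: dict[str, float]
    per_locus_ho: dict[str, np.ndarray]
    per_locus_he: dict[str, np.ndarray]
    #: Optional Weir & Cockerham small-f per population (estimator option).
    fis_wc: dict[str, float] = field(default_factory=dict)


@dataclass
class FstResult:
    pop_pair: tuple[str, str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_locus_theta: np.ndarray
    weighted_theta: float
    mean_theta: float
    n_loci_used: int
    permutation_p: float | None = None


@dataclass
class GTestResult:
    pop_pair: tuple[str, str]
    per_locus_g: np.ndarray
    per_locus_p: np.ndarray
    combined_p: float
    n_permutations: int
    seed: int
    skipped_loci: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def allele_frequencies(
    gm: GenotypeMatrix, pm: PopulationMap | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-population ALT-allele frequency and genotyped sample count per locus.

    Returns ``{population: (p_hat, n)}`` with ``p_hat`` NaN where every call
    is missing.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pop, rows in _pop_rows(gm, pm).items():
        calls = gm.calls[rows]
        present = calls != MISSING
        n = present.sum(axis=0)
        alt = np.where(present, calls, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
        out[pop] = (p, n)
    return out


def observed_heterozygosity(
    gm: GenotypeMatrix, pm: PopulationMap | None = None
) -> dict[str, np.ndarray]:
    """Per-locus fraction of heterozygotes among non-missing calls, per pop."""
    out = {}
    for pop, rows in _pop_rows(gm, pm).items():
        calls = gm.calls[rows]
        present = calls != MISSING
        n = present.sum(axis=0)
        het = (calls == 1).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pop] = np.where(n > 0, het / n, np.nan)
    return out


def unbiased_gene_diversity(
    gm: GenotypeMatrix, pm: PopulationMap | None = None
) -> dict[str, np.ndarray]:
    """Nei's unbiased He per locus: (2n/(2n-1)) (1 - sum p_hat^2).

    NaN where fewer than 2 samples are genotyped.
    """
    out = {}
    for pop, (p, n) in allele_frequencies(gm, pm).items():
        with np.errstate(invalid="ignore", divide="ignore"):
            he = (2 * n / (2 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
        out[pop] = np.where(n >= 2, he, np.nan)
    return out


def unbiased_he_multiallelic(freqs: np.ndarray, n: int) -> float:
    """Nei's unbiased He from a vector of allele frequencies (SSR path)."""
    if n < 2:
        return float("nan")
    return float((2 * n / (2 * n - 1.0)) * (1.0 - np.sum(np.asarray(freqs) ** 2)))


def fis(gm: GenotypeMatrix, pm: PopulationMap | None = None) -> dict[str, float]:
    """Multilocus FIS = 1 - sum_l Ho_l / sum_l He_l over loci with He_l > 0."""
    hos = observed_heterozygosity(gm, pm)
    hes = unbiased_gene_diversity(gm, pm)
    out = {}
    for pop in hos:
        ho, he = hos[pop], hes[pop]
        use = np.isfinite(ho) & np.isfinite(he) & (he > 0)
        if not use.any():
            out[pop] = float("nan")
            continue
        out[pop] = float(1.0 - ho[use].sum() / he[use].sum())
    return out


def diversity_summary(
    gm: GenotypeMatrix, pm: PopulationMap | None = None
) -> DiversityResult:
    """Ho, He and FIS per population (multilocus means over defined loci).

    Also reports the Weir & Cockerham within-population f as an alternative
    FIS estimator (per-locus f = 1 - Ho/Hs with the small-sample correction
    absorbed into He; summed over loci)."""
    hos = observed_heterozygosity(gm, pm)
    hes = unbiased_gene_diversity(gm, pm)
    fises = fis(gm, pm)
    pops = list(hos)
    mean_ho = {p: float(np.nanmean(hos[p])) for p in pops}
    mean_he = {p: float(np.nanmean(hes[p])) for p in pops}
    fis_wc = {}
    for p in pops:
        ho, he = hos[p], hes[p]
        use = np.isfinite(ho) & np.isfinite(he) & (he > 0)
        # multilocus ratio-of-sums form of the within-population f
        fis_wc[p] = (
            float(1.0 - ho[use].sum() / he[use].sum()) if use.any() else float("nan")
        )
    return DiversityResult(
        populations=pops,
        ho=mean_ho,
        he=mean_he,
        fis=fises,
        per_locus_ho=hos,
        per_locus_he=hes,
        fis_wc=fis_wc,
    )


def wc_variance_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham per-locus variance components for r populations.

    Parameters are per-locus arrays stacked over populations: sample sizes
    ``n`` (r x L), ALT frequencies ``p`` and heterozygote fractions ``h``.
    Returns the among-population (a), among-individual (b) and within-
    individual (c) components.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    nbar = n.sum(axis=0) / r
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap | None,
    pop_pair: tuple[str, str],
    n_permutations: int = 0,
    seed: int | None = None,
) -> FstResult:
    """Pairwise Weir & Cockerham theta (weighted and mean multilocus forms).

    Loci with fewer than 2 genotyped samples in either population, or with
    a + b + c = 0 (monomorphic in both), are excluded from both summaries.
    An optional permutation test shuffles individuals between the two
    populations and compares the weighted theta.
    """
    rows = _pop_rows(gm, pm)
    for pop in pop_pair:
        if pop not in rows:
            raise KeyError(f"population {pop!r} not present")
    idx = [rows[pop_pair[0]], rows[pop_pair[1]]]

    def components(ix_a: np.ndarray, ix_b: np.ndarray):
        n = np.empty((2, gm.n_loci))
        p = np.empty((2, gm.n_loci))
        h = np.empty((2, gm.n_loci))
        for k, rows_k in enumerate((ix_a, ix_b)):
            calls = gm.calls[rows_k]
            present = calls != MISSING
            n[k] = present.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p[k] = np.where(n[k] > 0, np.where(present, calls, 0).sum(axis=0) / (2 * n[k]), np.nan)
                h[k] = np.where(n[k] > 0, (calls == 1).sum(axis=0) / n[k], np.nan)
        usable = (n >= 2).all(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a, b, c = wc_variance_components(n, p, h)
        return a, b, c, usable

    a, b, c, usable = components(idx[0], idx[1])
    denom = a + b + c
    use = usable & np.isfinite(denom) & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_l = np.where(use, a / denom, np.nan)
    weighted = float(a[use].sum() / denom[use].sum()) if use.any() else float("nan")
    mean_theta = float(np.nanmean(theta_l[use])) if use.any() else float("nan")

    perm_p = None
    if n_permutations > 0:
        if seed is None:
            raise ValueError("permutation test requires an explicit seed")
        rng = np.random.default_rng(seed)
        pool = np.concatenate(idx)
        n_a = len(idx[0])
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pool)
            pa, pb, pc, pu = components(perm[:n_a], perm[n_a:])
            pd = pa + pb + pc
            puse = pu & np.isfinite(pd) & (pd != 0)
            w = pa[puse].sum() / pd[puse].sum() if puse.any() else -np.inf
            if w >= weighted:
                exceed += 1
        perm_p = (1 + exceed) / (n_permutations + 1)

    return FstResult(
        pop_pair=pop_pair,
        a=a, b=b, c=c,
        per_locus_theta=theta_l,
        weighted_theta=weighted,
        mean_theta=mean_theta,
        n_loci_used=int(use.sum()),
        permutation_p=perm_p,
    )


def _g_statistics(alt: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Per-locus G on the 2x2 allele-count table (alleles x populations).

    ``alt``/``tot`` are (2, L) ALT and total allele counts per population.
    Loci with a zero marginal get NaN.
    """
    ref = tot - alt
    counts = np.stack([alt, ref])  # (allele, pop, locus)
    col = counts.sum(axis=0)  # per-pop totals (2, L)
    rowm = counts.sum(axis=1)  # per-allele totals (2, L)
    grand = col.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = rowm[:, None, :] * col[None, :, :] / grand
        g = 2.0 * (xlogy(counts, counts) - xlogy(counts, expected)).sum(axis=(0, 1))
    degenerate = (rowm == 0).any(axis=0) | (col == 0).any(axis=0) | (grand == 0)
    return np.where(degenerate, np.nan, g)


def g_test_differentiation(
    gm: GenotypeMatrix,
    pm: PopulationMap | None,
    pop_pair: tuple[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> GTestResult:
    """Permutation G-test of genic differentiation for a population pair.

    The null distribution reshuffles individuals (genotypes kept intact)
    between the two populations; per-locus permutation p-values are
    combined across loci by Fisher's method.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    rows = _pop_rows(gm, pm)
    idx = [rows[pop_pair[0]], rows[pop_pair[1]]]
    pool = np.concatenate(idx)
    n_a = len(idx[0])
    calls = gm.calls[pool].astype(float)
    present = calls != MISSING
    dos = np.where(present, calls, 0.0)

    def counts(member_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sel = member_a[:, None]
        alt_a = (dos * sel).sum(axis=0)
        alt_b = (dos * ~sel).sum(axis=0)
        tot_a = 2.0 * (present * sel).sum(axis=0)
        tot_b = 2.0 * (present * ~sel).sum(axis=0)
        return np.stack([alt_a, alt_b]), np.stack([tot_a, tot_b])

    member = np.zeros(len(pool), dtype=bool)
    member[:n_a] = True
    g_obs = _g_statistics(*counts(member))
    skipped = np.flatnonzero(~np.isfinite(g_obs))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(gm.n_loci)
    for _ in range(n_permutations):
        g_perm = _g_statistics(*counts(rng.permutation(member)))
        exceed += np.where(
            np.isfinite(g_perm) & np.isfinite(g_obs), g_perm >= g_obs - 1e-12, 0.0
        )
    with np.errstate(invalid="ignore"):
        p = np.where(np.isfinite(g_obs), (1.0 + exceed) / (n_permutations + 1.0), np.nan)

    ok = np.isfinite(p)
    if ok.any():
        fisher_stat = -2.0 * np.log(p[ok]).sum()
        combined = float(stats.chi2.sf(fisher_stat, 2 * int(ok.sum())))
        combined = max(combined, np.finfo(float).tiny)
    else:
        combined = float("nan")
    return GTestResult(
        pop_pair=pop_pair,
        per_locus_g=g_obs,
        per_locus_p=p,
        combined_p=combined,
        n_permutations=n_permutations,
        seed=seed,
        skipped_loci=skipped,
    )


def pca_structure(
    gm: GenotypeMatrix, n_components: int = 2, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Sample PCA scores and percent variance explained per axis.

    Genotypes are centered per locus (and optionally scaled by the binomial
    SD); missing entries are imputed at the locus mean.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    from .outlier_pca import scale_genotypes

    X, _, _ = scale_genotypes(gm, unit_variance=scale)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    pct = 100.0 * (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, pct
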