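"""Post-variant-calling locus/sample filters and per-tag SNP thinning.

RAD loci with excess heterozygosity are likely lumped paralogs, and loci
with poor genotyping rates are enriched for null alleles caused by
restriction-site mutations, so the default filter keeps biallelic loci
genotyped in >=90% of individuals with at most 50% heterozygous calls.
Thinning keeps one SNP per 36-bp RAD tag — the one with the largest minor
allele frequency — so downstream statistics are not driven by within-tag
linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "SampleFilterReport",
    "LocusFilterReport",
    "drop_poor_samples",
    "filter_loci",
    "thin_per_tag_maxaf",
    "minor_allele_frequencies",
]


@dataclass
class FilterConfig:
    """Thresholds for locus/sample filtering.

    All call-rate and heterozygosity boundaries are inclusive.
    """

    min_locus_call_rate: float = 0.90
    max_locus_heterozygosity: float = 0.50
    biallelic_only: bool = True
    min_sample_call_rate: float = 0.50
    thin_per_tag: bool = True
    #: "maf" = keep the SNP with maximal minor-allele frequency (the
    #: informative-SNP convention); "max_alt" keys on the ALT frequency.
    thin_criterion: str = "maf"

    def __post_init__(self) -> None:
        for name in ("min_locus_call_rate", "max_locus_heterozygosity", "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.thin_criterion not in ("maf", "max_alt"):
            raise ValueError(f"unknown thin_criterion {self.thin_criterion!r}")


@dataclass
class SampleFilterReport:
    dropped: list[str]
    call_rates: dict[str, float]


@dataclass
class LocusFilterReport:
    n_input: int
    n_retained: int
    removed_multiallelic: int = 0
    removed_call_rate: int = 0
    removed_heterozygosity: int = 0
    dropped_ids: list[str] = field(default_factory=list)


def drop_poor_samples(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, SampleFilterReport]:
    """Remove samples whose call rate falls below ``min_sample_call_rate``."""
    cfg = cfg or FilterConfig()
    if gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    rates = gm.sample_call_rates()
    keep = [i for i in range(gm.n_samples) if rates[i] >= cfg.min_sample_call_rate]
    if not keep:
        raise ValueError("sample filter would drop every sample")
    dropped = [gm.samples[i] for i in range(gm.n_samples) if i not in set(keep)]
    report = SampleFilterReport(
        dropped=dropped,
        call_rates={s: float(r) for s, r in zip(gm.samples, rates)},
    )
    return gm.take_samples(keep), report


def locus_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of heterozygous calls among non-missing calls."""
    het = (gm.calls == 1).sum(axis=0).astype(float)
    n = (gm.calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het / n, np.nan)


def filter_loci(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Keep biallelic loci with sufficient call rate and bounded heterozygosity.

    Removal counts are attributed to the first failing criterion in the
    order multiallelic -> call rate -> heterozygosity.  Locus order is
    preserved; the filter is idempotent.
    """
    cfg = cfg or FilterConfig()
    rates = gm.locus_call_rates()
    hets = locus_heterozygosity(gm)
    report = LocusFilterReport(n_input=gm.n_loci, n_retained=0)
    keep: list[int] = []
    for j, locus in enumerate(gm.loci):
        if cfg.biallelic_only and locus.n_alt != 1:
            report.removed_multiallelic += 1
            report.dropped_ids.append(locus.locus_id)
        elif rates[j] < cfg.min_locus_call_rate:
            report.removed_call_rate += 1
            report.dropped_ids.append(locus.locus_id)
        elif np.isnan(hets[j]) or hets[j] > cfg.max_locus_heterozygosity:
            report.removed_heterozygosity += 1
            report.dropped_ids.append(locus.locus_id)
        else:
            keep.append(j)
    report.n_retained = len(keep)
    if not keep:
        warnings.warn("locus filter removed every locus")
    return gm.take_loci(keep), report


def alt_allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Pooled ALT-allele frequency per locus over all non-missing calls."""
    present = gm.calls != MISSING
    alt = np.where(present, gm.calls, 0).sum(axis=0).astype(float)
    n = present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / (2 * n), np.nan)


def minor_allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    p = alt_allele_frequencies(gm)
    return np.minimum(p, 1.0 - p)


def thin_per_tag_maxaf(gm: GenotypeMatrix, criterion: str = "maf") -> GenotypeMatrix:
    """Keep one SNP per RAD tag: the one with maximal allele frequency.

    ``criterion="maf"`` (default) maximizes the minor-allele frequency;
    ``"max_alt"`` maximizes the ALT frequency.  Ties break to the smallest
    position, then lexicographically smallest locus id.
    """
    if criterion == "maf":
        score = minor_allele_frequencies(gm)
    elif criterion == "max_alt":
        score = alt_allele_frequencies(gm)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    score = np.where(np.isnan(score), -1.0, score)

    def sort_key(j: int) -> tuple:
        locus = gm.loci[j]
        return (-score[j], locus.position, locus.locus_id)

    best: dict[str, int] = {}
    for j, locus in enumerate(gm.loci):
        cur = best.get(locus.tag_id)
        if cur is None or sort_key(j) < sort_key(cur):
            best[locus.tag_id] = j
    keep = sorted(best.values())
    return gm.take_loci(keep)
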