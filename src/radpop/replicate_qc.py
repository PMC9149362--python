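"""Genotyping reproducibility from technical replicates and the Ti/Tv spectrum.

Technical replicates (independent library preparation and sequencing of the
same DNA) are "confirmed clones": the fraction of identical genotype calls
between the two members of a pair, over loci typed in both, measures the
genotyping error rate and later calibrates the clone-delimitation distance
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "ReplicateQC",
    "SubstitutionSpectrum",
    "replicate_concordance",
    "classify_substitution",
    "titv_summary",
    "drop_replicate_samples",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

#: Canonical order of the six unordered substitution classes.
SUBSTITUTION_CLASSES = ("A<->G", "C<->T", "A<->C", "A<->T", "C<->G", "G<->T")


@dataclass
class ReplicateQC:
    """Per-pair genotype concordance among technical replicates."""

    per_pair_concordance: dict[tuple[str, str], float]
    per_pair_shared: dict[tuple[str, str], int]
    per_pair_distance: dict[tuple[str, str], float]
    mean: float
    sd: float
    #: Pairs with zero mutually typed loci, excluded from the summary.
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SubstitutionSpectrum:
    counts: dict[str, int]
    transitions: int
    transversions: int
    titv_ratio: float | None
    percent_transversions: float


def classify_substitution(ref: str, alt: str) -> str:
    """A<->G and C<->T are transitions; the other four classes transversions."""
    if ref == alt or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not a substitution: {ref!r} -> {alt!r}")
    return "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"


def replicate_concordance(gm: GenotypeMatrix, pm: PopulationMap) -> ReplicateQC:
    """Concordance = identical calls / loci non-missing in both pair members.

    Pairs with zero shared loci are flagged and excluded from the mean/SD.
    """
    if not pm.replicate_pairs:
        raise ValueError("no technical-replicate pairs in the population map")
    from .clonality import prevosti_distance

    conc: dict[tuple[str, str], float] = {}
    shared: dict[tuple[str, str], int] = {}
    dist: dict[tuple[str, str], float] = {}
    undefined: list[tuple[str, str]] = []
    for a, b in pm.replicate_pairs:
        ga = gm.calls[gm.sample_index(a)]
        gb = gm.calls[gm.sample_index(b)]
        both = (ga != MISSING) & (gb != MISSING)
        n = int(both.sum())
        if n == 0:
            undefined.append((a, b))
            continue
        conc[(a, b)] = float((ga[both] == gb[both]).mean())
        shared[(a, b)] = n
        dist[(a, b)] = prevosti_distance(gm, a, b)
    values = np.array(list(conc.values()))
    if values.size == 0:
        raise ValueError("every replicate pair had zero shared loci")
    return ReplicateQC(
        per_pair_concordance=conc,
        per_pair_shared=shared,
        per_pair_distance=dist,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        undefined_pairs=undefined,
    )


def titv_summary(gm: GenotypeMatrix) -> SubstitutionSpectrum:
    """Six-class substitution counts, Ti/Tv ratio and transversion percent."""
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for locus in gm.loci:
        pair = frozenset((locus.ref_allele, locus.alt_allele))
        for cls in SUBSTITUTION_CLASSES:
            if frozenset((cls[0], cls[-1])) == pair:
                counts[cls] += 1
                break
    ti = counts["A<->G"] + counts["C<->T"]
    tv = sum(counts.values()) - ti
    total = ti + tv
    return SubstitutionSpectrum(
        counts=counts,
        transitions=ti,
        transversions=tv,
        titv_ratio=(ti / tv) if tv > 0 else None,
        percent_transversions=(100.0 * tv / total) if total else 0.0,
    )


def drop_replicate_samples(gm: GenotypeMatrix, pm: PopulationMap) -> GenotypeMatrix:
    """Remove the second member of each replicate pair (QC done, keep one)."""
    drop = {b for _, b in pm.replicate_pairs}
    keep = [i for i, s in enumerate(gm.samples) if s not in drop]
    return gm.take_samples(keep)
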