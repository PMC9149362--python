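"""Genotype data model and I/O for the standard formats the pipeline touches.

The central container is :class:`GenotypeMatrix`: a samples x loci grid of
diploid allele-dosage codes (0/1/2 copies of the alternative allele) with a
missing sentinel, plus per-locus metadata (:class:`LocusInfo`) carrying the
contig, 1-based position, RAD-tag assignment and the two alleles.  Sample to
population assignments, technical-replicate pairings and a priori exclusions
travel in :class:`PopulationMap`.  Multiallelic SSR (microsatellite)
genotypes use the separate :class:`SSRMatrix`.

Coordinates are 1-based inclusive at I/O boundaries (VCF convention);
internal window arithmetic is 0-based half-open.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "TAG_LENGTH",
    "LocusInfo",
    "GenotypeMatrix",
    "PopulationMap",
    "SSRMatrix",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_ssr_table",
    "read_population_map",
    "apply_population_map",
]

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

#: Length in bp of a 2b-RAD tag (type IIB restriction fragments are uniform).
TAG_LENGTH: int = 36

_NUCLEOTIDES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one SNP locus.

    ``tag_id`` identifies the 36-bp RAD tag the SNP belongs to; by default it
    is derived from the contig and the 36-bp bin index of the position.
    ``n_alt`` records how many ALT alleles the source record carried so the
    filter stage can drop multiallelic loci.
    """

    locus_id: str
    contig: str
    position: int  # 1-based
    tag_id: str
    ref_allele: str
    alt_allele: str
    n_alt: int = 1

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.locus_id}: ref and alt alleles are equal")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _NUCLEOTIDES:
                raise ValueError(f"{self.locus_id}: allele {allele!r} not in ACGT")


def default_tag_id(contig: str, position: int) -> str:
    """Tag identifier from contig + 36-bp bin of a 1-based position."""
    return f"{contig}:{(position - 1) // TAG_LENGTH}"


@dataclass
class GenotypeMatrix:
    """Samples x loci grid of diploid allele-dosage codes.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers (row order).
    loci : list of LocusInfo
        Per-locus metadata (column order); locus ids unique.
    calls : ndarray of int8, shape (n_samples, n_loci)
        Dosage of the alternative allele, 0/1/2, or :data:`MISSING`.
    populations : list of str, optional
        Per-sample population labels, aligned with ``samples``.
    """

    samples: list[str]
    loci: list[LocusInfo]
    calls: np.ndarray
    populations: list[str] | None = None
    ploidy: int = field(default=2, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers are not unique")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus identifiers are not unique")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid dosage codes present: {bad.tolist()}")
        if self.populations is not None and len(self.populations) != len(self.samples):
            raise ValueError("populations length does not match samples")
        if self.ploidy != 2:
            raise ValueError("only diploid data supported")

    # -- basic queries -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def dosages(self) -> np.ndarray:
        """Calls as float with missing encoded as NaN."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def locus_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    # -- subsetting ----------------------------------------------------

    def take_samples(self, indices: "list[int] | np.ndarray") -> "GenotypeMatrix":
        indices = list(indices)
        return replace(
            self,
            samples=[self.samples[i] for i in indices],
            calls=self.calls[indices, :],
            populations=(
                [self.populations[i] for i in indices] if self.populations else None
            ),
        )

    def take_loci(self, indices: "list[int] | np.ndarray") -> "GenotypeMatrix":
        indices = list(indices)
        return replace(
            self,
            loci=[self.loci[i] for i in indices],
            calls=self.calls[:, indices],
        )

    def pop_of(self, sample_id: str) -> str:
        if self.populations is None:
            raise ValueError("matrix carries no population annotation")
        return self.populations[self.sample_index(sample_id)]


@dataclass
class PopulationMap:
    """Sample-to-population assignment plus technical-replicate pairings."""

    assignment: dict[str, str]
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.replicate_pairs:
            for s in (a, b):
                if s not in self.assignment:
                    raise ValueError(f"replicate-pair member {s!r} has no assignment")
        if not self.assignment:
            raise ValueError("assignment is empty")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == population]


@dataclass
class SSRMatrix:
    """Multiallelic SSR genotypes: per sample/locus an unordered allele pair.

    ``calls[i][j]`` is a sorted ``(allele, allele)`` tuple of integer
    fragment sizes or ``None`` when the whole genotype is missing.
    """

    samples: list[str]
    loci: list[str]
    calls: list[list[tuple[int, int] | None]]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.samples):
            raise ValueError("calls row count does not match samples")
        for row in self.calls:
            if len(row) != len(self.loci):
                raise ValueError("calls column count does not match loci")
        self.calls = [
            [None if g is None else tuple(sorted(g)) for g in row] for row in self.calls
        ]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str, tag_regex: str | None = None) -> GenotypeMatrix:
    """Read a multi-sample diploid VCF into a :class:`GenotypeMatrix`.

    GT fields are encoded as alt-allele dosage (``0/0`` -> 0, ``0/1`` -> 1,
    ``1/1`` -> 2, ``./.`` -> missing); phased separators are accepted and
    phasing discarded.  Multiallelic records are retained with their ALT
    count recorded (downstream filtering drops them); calls involving an
    allele index above 1 are set missing.  ``tag_regex``, if given, must
    contain one capture group extracting the tag identifier from the locus
    id; otherwise tags are contig + 36-bp bin.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    loci: list[LocusInfo] = []
    columns: list[np.ndarray] = []
    pattern = re.compile(tag_regex) if tag_regex else None

    for n, variant in enumerate(vcf, start=1):
        alts = variant.ALT or []
        if not alts:
            continue
        ref, alt = variant.REF, alts[0]
        if len(ref) != 1 or any(len(a) != 1 for a in alts):
            continue  # indels: never produced upstream, skip defensively
        locus_id = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}_{variant.POS}"
        )
        if pattern is not None:
            m = pattern.search(locus_id)
            tag = m.group(1) if m else default_tag_id(variant.CHROM, variant.POS)
        else:
            tag = default_tag_id(variant.CHROM, variant.POS)

        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = [int(a) for a in gt[:-1] if a is not None]
            if len(alleles) != 2:
                if len(alleles) == 0 or all(a == -1 for a in alleles):
                    continue
                raise VcfParseError(
                    f"record {n} ({variant.CHROM}:{variant.POS}): "
                    f"non-diploid genotype for sample {samples[i]}"
                )
            if any(a < 0 for a in alleles) or any(a > 1 for a in alleles):
                continue  # partially missing or involves a 2nd ALT
            col[i] = sum(alleles)
        loci.append(
            LocusInfo(
                locus_id=locus_id,
                contig=variant.CHROM,
                position=variant.POS,
                tag_id=tag,
                ref_allele=ref,
                alt_allele=alt,
                n_alt=len(alts),
            )
        )
        columns.append(col)

    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 (GT-only FORMAT, one record per locus)."""
    contigs: dict[str, int] = {}
    for locus in gm.loci:
        contigs[locus.contig] = max(contigs.get(locus.contig, 0), locus.position)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, max_pos in contigs.items():
            fh.write(f"##contig=<ID={contig},length={max_pos + TAG_LENGTH}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + gm.samples) + "\n")
        for j, locus in enumerate(gm.loci):
            row = [
                locus.contig,
                str(locus.position),
                locus.locus_id,
                locus.ref_allele,
                locus.alt_allele,
                ".",
                "PASS",
                ".",
                "GT",
            ]
            row += [_GT_STRINGS[int(c)] for c in gm.calls[:, j]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# SSR and population tables


def read_ssr_table(path: str) -> SSRMatrix:
    """Read an SSR genotype CSV: sample_id column + two columns per locus.

    Blank cells mark missing alleles; if only one allele of a pair is blank
    the whole genotype is treated as missing (with a warning).  Allele pairs
    are stored sorted.
    """
    df = pd.read_csv(path, dtype=str).rename(columns=lambda c: c.strip())
    if df.shape[1] < 3 or (df.shape[1] - 1) % 2 != 0:
        raise ValueError(
            f"SSR table needs a sample column plus an even number of allele "
            f"columns; got {df.shape[1]} columns"
        )
    samples = df.iloc[:, 0].tolist()
    allele_cols = list(df.columns[1:])
    loci = []
    for k in range(0, len(allele_cols), 2):
        a = allele_cols[k]
        stem = re.sub(r"[._-]?(a1|a2|1|2|a|b)$", "", a, flags=re.IGNORECASE)
        loci.append(stem if stem else a)
    calls: list[list[tuple[int, int] | None]] = []
    for _, row in df.iterrows():
        genos: list[tuple[int, int] | None] = []
        for k in range(0, len(allele_cols), 2):
            v1 = row[allele_cols[k]]
            v2 = row[allele_cols[k + 1]]
            blank1 = pd.isna(v1) or str(v1).strip() == ""
            blank2 = pd.isna(v2) or str(v2).strip() == ""
            if blank1 != blank2:
                warnings.warn(
                    f"sample {row.iloc[0]}, locus {loci[k // 2]}: half-missing "
                    f"genotype treated as missing"
                )
                genos.append(None)
            elif blank1:
                genos.append(None)
            else:
                genos.append((int(float(v1)), int(float(v2))))
        calls.append(genos)
    return SSRMatrix(samples=samples, loci=loci, calls=calls)


def read_population_map(
    pops_path: str,
    replicates_path: str | None = None,
    exclusions: list[str] | None = None,
) -> PopulationMap:
    """Read sample->population CSV (columns sample_id, population) and an
    optional replicate-pair CSV (columns sample_id_a, sample_id_b)."""
    pops = pd.read_csv(pops_path, dtype=str)
    assignment = dict(zip(pops.iloc[:, 0], pops.iloc[:, 1]))
    pairs: list[tuple[str, str]] = []
    if replicates_path is not None:
        reps = pd.read_csv(replicates_path, dtype=str)
        pairs = [tuple(r) for r in reps.iloc[:, :2].itertuples(index=False)]
    return PopulationMap(
        assignment=assignment,
        replicate_pairs=pairs,
        exclusions=list(exclusions or []),
    )


def apply_population_map(gm: GenotypeMatrix, pm: PopulationMap) -> GenotypeMatrix:
    """Drop excluded samples and annotate the rest with population labels."""
    excluded = set(pm.exclusions)
    keep = [i for i, s in enumerate(gm.samples) if s not in excluded]
    unmapped = [gm.samples[i] for i in keep if gm.samples[i] not in pm.assignment]
    if unmapped:
        raise ValueError(f"samples without population assignment: {unmapped}")
    out = gm.take_samples(keep)
    out.populations = [pm.assignment[s] for s in out.samples]
    return out
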