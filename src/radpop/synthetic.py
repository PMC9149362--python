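"""Synthetic genotype datasets with the structure the pipeline assumes.

Population allele frequencies follow the Balding-Nichols island model:
for ancestral frequency p0 and differentiation F, each population draws
p_j ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F), so E[p_j] = p0 and the expected
FST among populations is approximately F.  Clonality is planted by drawing
one diploid HWE genotype per *genet* and copying it to its ramets; a small
fraction of loci can be planted with an elevated F to serve as outlier
ground truth.  Genotyping error is a per-allele flip (so hom <-> het
errors dominate, the dropout-like pattern of RAD data), missingness an
independent mask, and technical replicates are independently re-noised
copies of chosen samples.  All randomness derives from one seed and every
planted quantity is emitted as :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    GenotypeMatrix,
    LocusInfo,
    PopulationMap,
    SSRMatrix,
    default_tag_id,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_ssr",
    "emit_reference_and_transcriptome",
    "write_fasta",
    "example_meadow_config",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator parameters; ``seed`` is mandatory.

    ``samples_per_pop``, ``neutral_f`` and ``genets_per_pop`` accept either
    a scalar (shared by all populations) or a per-population sequence.
    ``genets_per_pop=None`` makes every sample its own genet (no clonality).
    """

    seed: int
    n_pops: int = 3
    samples_per_pop: "int | tuple[int, ...]" = 20
    n_loci: int = 5000
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    neutral_f: "float | tuple[float, ...]" = 0.1
    outlier_fraction: float = 0.01
    outlier_f: float = 0.5
    genets_per_pop: "int | tuple[int, ...] | None" = None
    ramet_allocation: "str | tuple[tuple[int, ...], ...]" = "geometric"
    geometric_ratio: float = 0.5
    flip_rate: float = 0.05
    missing_rate: float = 0.1
    replicates_per_pop: int = 4
    pop_names: tuple[str, ...] | None = None
    multi_snp_tag_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("outlier_fraction", "flip_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for f in np.atleast_1d(np.asarray(self.neutral_f, dtype=float)):
            if not 0.0 <= f < 1.0:
                raise ValueError("neutral F must be in [0, 1); F = 1 rejected")
        if self.outlier_fraction > 0 and self.outlier_f <= np.max(self.neutral_f):
            raise ValueError("outlier F must exceed the neutral F")

    def _per_pop(self, value) -> list:
        if np.isscalar(value) or value is None:
            return [value] * self.n_pops
        value = list(value)
        if len(value) != self.n_pops:
            raise ValueError("per-population sequence length != n_pops")
        return value

    @property
    def pops(self) -> list[str]:
        if self.pop_names is not None:
            return list(self.pop_names)
        return [f"pop{k + 1}" for k in range(self.n_pops)]


@dataclass
class SimTruth:
    """Everything the generator planted, for closed-form downstream checks."""

    pop_freqs: dict[str, np.ndarray]  # per-pop true allele frequency per locus
    genet_of: dict[str, str]  # sample -> genet identifier
    outlier_loci: list[str]
    replicate_pairs: list[tuple[str, str]]
    clean_calls: np.ndarray  # pre-noise dosages, samples x loci
    flip_rate: float
    missing_rate: float
    samples: list[str] = field(default_factory=list)

    def genet_partition(self) -> dict[str, set[str]]:
        part: dict[str, set[str]] = {}
        for s, g in self.genet_of.items():
            part.setdefault(g, set()).add(s)
        return part

    def expected_replicate_concordance(self) -> float:
        """Exact expectation of per-pair genotype concordance under the
        per-allele flip model (missingness is independent of the value, so
        it does not shift the expectation)."""
        e = self.flip_rate
        # P(observed dosage | clean dosage) under two per-allele flips
        hom = np.array([(1 - e) ** 2, 2 * e * (1 - e), e**2])
        het = np.array([e * (1 - e), (1 - e) ** 2 + e**2, e * (1 - e)])
        m_hom = float((hom**2).sum())
        m_het = float((het**2).sum())
        reps = {a for a, _ in self.replicate_pairs}
        rows = [self.samples.index(s) for s in reps]
        clean = self.clean_calls[rows]
        n_het = (clean == 1).sum()
        n_hom = clean.size - n_het
        return (n_hom * m_hom + n_het * m_het) / clean.size


def _noise(rng: np.random.Generator, clean: np.ndarray, eps: float, miss: float):
    """Per-allele flips then a missing mask; returns int8 with sentinel."""
    alt_losses = rng.binomial(clean, eps)
    ref_gains = rng.binomial(2 - clean, eps)
    obs = (clean - alt_losses + ref_gains).astype(np.int8)
    mask = rng.random(obs.shape) < miss
    obs[mask] = MISSING
    return obs


def _allocate_ramets(
    rng: np.random.Generator, n_samples: int, n_genets: int, cfg: SimConfig, k: int
) -> np.ndarray:
    """Genet index per sample; geometric allocation skews ramets toward the
    first genet (one lineage dominating, as clonal meadows show)."""
    if isinstance(cfg.ramet_allocation, str):
        if cfg.ramet_allocation != "geometric":
            raise ValueError(f"unknown ramet allocation {cfg.ramet_allocation!r}")
        sizes = np.ones(n_genets, dtype=int)
        extra = n_samples - n_genets
        if extra > 0:
            w = cfg.geometric_ratio ** np.arange(n_genets)
            sizes += rng.multinomial(extra, w / w.sum())
    else:
        sizes = np.asarray(cfg.ramet_allocation[k], dtype=int)
        if sizes.sum() != n_samples or len(sizes) != n_genets:
            raise ValueError("explicit ramet allocation inconsistent with sizes")
    return np.repeat(np.arange(n_genets), sizes)


def _make_loci(rng: np.random.Generator, cfg: SimConfig) -> list[LocusInfo]:
    loci = []
    tag = 0
    contig_tags = 200  # tags per synthetic chromosome
    prev_same = rng.random(cfg.n_loci) < cfg.multi_snp_tag_fraction
    for j in range(cfg.n_loci):
        if j > 0 and not prev_same[j]:
            tag += 1
        contig = f"chr{tag // contig_tags + 1}"
        tag_start = (tag % contig_tags) * 36
        pos = tag_start + int(rng.integers(0, 36)) + 1
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            LocusInfo(
                locus_id=f"{contig}_{pos}_{j}",
                contig=contig,
                position=pos,
                tag_id=default_tag_id(contig, pos),
                ref_allele=str(_BASES[ref]),
                alt_allele=str(_BASES[alt]),
            )
        )
    return loci


def _balding_nichols(
    rng: np.random.Generator, p0: np.ndarray, f: float
) -> np.ndarray:
    if f == 0.0:
        return p0.copy()
    shape = (1.0 - f) / f
    return rng.beta(p0 * shape, (1.0 - p0) * shape)


def _draw_outlier_freqs(
    rng: np.random.Generator, p0: float, f_out: float, n_pops: int,
    max_tries: int = 500,
) -> np.ndarray:
    """Per-population frequencies for a planted outlier locus.

    Raw Balding-Nichols draws at high F are U-shaped, so a large fraction
    would land every population near the *same* fixation boundary — a
    "planted outlier" with no realized divergence at all.  To make the
    ground-truth label mean what it says, draws are rejection-sampled until
    the realized among-population differentiation, s2 / (pbar (1 - pbar)),
    reaches the nominal outlier F; after ``max_tries`` the most divergent
    draw seen is kept.
    """
    p0v = np.full(n_pops, p0)
    best, best_f = None, -1.0
    for _ in range(max_tries):
        pj = _balding_nichols(rng, p0v, f_out)
        pbar = pj.mean()
        denom = pbar * (1.0 - pbar)
        f_real = pj.var(ddof=1) / denom if denom > 1e-12 else 0.0
        if f_real >= f_out:
            return pj
        if f_real > best_f:
            best, best_f = pj, f_real
    return best


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Generate a genotype matrix, its population map and the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.pops
    sizes = cfg._per_pop(cfg.samples_per_pop)
    fs = cfg._per_pop(cfg.neutral_f)
    genets = cfg._per_pop(cfg.genets_per_pop)

    loci = _make_loci(rng, cfg)
    L = cfg.n_loci
    p0 = rng.uniform(cfg.ancestral_low, cfg.ancestral_high, size=L)
    n_out = int(round(cfg.outlier_fraction * L))
    outlier_idx = (
        rng.choice(L, size=n_out, replace=False) if n_out > 0 else np.empty(0, int)
    )
    is_outlier = np.zeros(L, dtype=bool)
    is_outlier[outlier_idx] = True
    # joint draw across populations so realized divergence can be enforced
    outlier_freqs = np.array(
        [_draw_outlier_freqs(rng, p0[j], cfg.outlier_f, cfg.n_pops)
         for j in outlier_idx]
    ).reshape(n_out, cfg.n_pops)

    samples: list[str] = []
    assignment: dict[str, str] = {}
    genet_of: dict[str, str] = {}
    clean_rows: list[np.ndarray] = []
    obs_rows: list[np.ndarray] = []
    replicate_pairs: list[tuple[str, str]] = []
    pop_freqs: dict[str, np.ndarray] = {}
    rep_jobs: list[tuple[str, np.ndarray]] = []

    for k, pop in enumerate(pops):
        n = int(sizes[k])
        g = n if genets[k] is None else int(genets[k])
        if not 1 <= g <= n:
            raise ValueError(f"{pop}: need 1 <= genets <= samples")
        f_neutral = float(fs[k])
        pj = _balding_nichols(rng, p0, f_neutral)
        if n_out > 0:
            pj[outlier_idx] = outlier_freqs[:, k]
        pop_freqs[pop] = pj
        genotypes = rng.binomial(2, pj, size=(g, L))  # one HWE draw per genet
        alloc = _allocate_ramets(rng, n, g, cfg, k)
        for i in range(n):
            sid = f"{pop}_{i + 1:02d}"
            clean = genotypes[alloc[i]]
            samples.append(sid)
            assignment[sid] = pop
            genet_of[sid] = f"{pop}_g{alloc[i] + 1}"
            clean_rows.append(clean)
            obs_rows.append(_noise(rng, clean, cfg.flip_rate, cfg.missing_rate))
            if i < cfg.replicates_per_pop:
                rep_jobs.append((sid, clean))

    for sid, clean in rep_jobs:
        rid = f"{sid}_rep"
        samples.append(rid)
        assignment[rid] = assignment[sid]
        genet_of[rid] = genet_of[sid]
        clean_rows.append(clean)
        obs_rows.append(_noise(rng, clean, cfg.flip_rate, cfg.missing_rate))
        replicate_pairs.append((sid, rid))

    calls = np.vstack(obs_rows).astype(np.int8)
    gm = GenotypeMatrix(
        samples=samples,
        loci=loci,
        calls=calls,
        populations=[assignment[s] for s in samples],
    )
    pm = PopulationMap(assignment=assignment, replicate_pairs=replicate_pairs)
    truth = SimTruth(
        pop_freqs=pop_freqs,
        genet_of=genet_of,
        outlier_loci=[loci[j].locus_id for j in sorted(outlier_idx)],
        replicate_pairs=replicate_pairs,
        clean_calls=np.vstack(clean_rows),
        flip_rate=cfg.flip_rate,
        missing_rate=cfg.missing_rate,
        samples=list(samples),
    )
    return gm, pm, truth


def simulate_ssr(
    cfg: SimConfig, n_ssr_loci: int = 7, n_alleles: int = 8
) -> tuple[SSRMatrix, SimTruth]:
    """Multiallelic SSR genotypes with the same genet/ramet logic.

    Allele labels are fragment sizes (150 + 2k).  Per population each locus
    gets Dirichlet(1) allele frequencies; genets draw two alleles, ramets
    copy them; whole genotypes go missing at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pops = cfg.pops
    sizes = cfg._per_pop(cfg.samples_per_pop)
    genets = cfg._per_pop(cfg.genets_per_pop)
    labels = 150 + 2 * np.arange(n_alleles)

    samples: list[str] = []
    genet_of: dict[str, str] = {}
    calls: list[list[tuple[int, int] | None]] = []
    for k, pop in enumerate(pops):
        n = int(sizes[k])
        g = n if genets[k] is None else int(genets[k])
        freqs = rng.dirichlet(np.ones(n_alleles), size=n_ssr_loci)
        genet_calls = [
            [
                tuple(sorted(rng.choice(labels, size=2, p=freqs[l])))
                for l in range(n_ssr_loci)
            ]
            for _ in range(g)
        ]
        alloc = _allocate_ramets(rng, n, g, cfg, k)
        for i in range(n):
            sid = f"{pop}_{i + 1:02d}"
            samples.append(sid)
            genet_of[sid] = f"{pop}_g{alloc[i] + 1}"
            row: list[tuple[int, int] | None] = []
            for l in range(n_ssr_loci):
                if rng.random() < cfg.missing_rate:
                    row.append(None)
                else:
                    row.append(genet_calls[alloc[i]][l])
            calls.append(row)
    ssr = SSRMatrix(
        samples=samples,
        loci=[f"SSR{l + 1}" for l in range(n_ssr_loci)],
        calls=calls,
    )
    truth = SimTruth(
        pop_freqs={},
        genet_of=genet_of,
        outlier_loci=[],
        replicate_pairs=[],
        clean_calls=np.empty((0, 0)),
        flip_rate=0.0,
        missing_rate=cfg.missing_rate,
        samples=list(samples),
    )
    return ssr, truth


def write_fasta(path: str, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def emit_reference_and_transcriptome(
    gm: GenotypeMatrix,
    planted_loci: list[str],
    seed: int,
    planted_identity: float = 1.0,
    window: int = 80,
    flank: int = 30,
) -> tuple[dict[str, str], dict[str, str], list[str]]:
    """Reference contigs consistent with the loci, plus a transcriptome in
    which each planted locus has its flanking window embedded (optionally
    mutated down to a target identity).

    Returns ``(contigs, transcripts, expected_positive_locus_ids)``.
    """
    from .consensus import extract_flank_window

    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    for locus in gm.loci:
        lengths[locus.contig] = max(
            lengths.get(locus.contig, 0), locus.position + window
        )
    contigs = {
        c: "".join(rng.choice(_BASES, size=n)) for c, n in lengths.items()
    }
    # place each locus's REF base at its coordinate
    arrays = {c: np.array(list(s)) for c, s in contigs.items()}
    for locus in gm.loci:
        arrays[locus.contig][locus.position - 1] = locus.ref_allele
    contigs = {c: "".join(a) for c, a in arrays.items()}

    by_id = {l.locus_id: l for l in gm.loci}
    transcripts: dict[str, str] = {}
    expected_positive: list[str] = []
    for lid in planted_loci:
        locus = by_id[lid]
        win, offset = extract_flank_window(contigs, locus, width=window)
        seq = np.array(list(win))
        n_mut = int(round((1.0 - planted_identity) * len(seq)))
        if n_mut > 0:
            sites = [i for i in range(len(seq)) if i != offset]
            chosen = rng.choice(sites, size=n_mut, replace=False)
            for i in chosen:
                options = [b for b in "ACGT" if b != seq[i]]
                seq[i] = options[int(rng.integers(0, 3))]
        embedded = (
            "".join(rng.choice(_BASES, size=flank))
            + "".join(seq)
            + "".join(rng.choice(_BASES, size=flank))
        )
        transcripts[f"tx_{lid}"] = embedded
        if planted_identity >= 0.90:
            expected_positive.append(lid)
    return contigs, transcripts, expected_positive


def example_meadow_config(seed: int, n_loci: int = 2000) -> SimConfig:
    """A realistic three-meadow sampling design: 14/20/15 shoots holding
    4/2/11 genets, strong differentiation, 4 technical replicates per
    population, ~10% replicate discordance and ~10% missing calls."""
    return SimConfig(
        seed=seed,
        n_pops=3,
        pop_names=("GC", "FA", "EB"),
        samples_per_pop=(14, 20, 15),
        genets_per_pop=(4, 2, 11),
        n_loci=n_loci,
        neutral_f=0.35,
        outlier_fraction=0.01,
        outlier_f=0.8,
        flip_rate=0.05,
        missing_rate=0.1,
        replicates_per_pop=4,
    )
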