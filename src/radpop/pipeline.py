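"""End-to-end orchestration: filter -> replicate QC -> thinning -> clone
delimitation -> clone correction -> diversity/differentiation -> outlier
scans -> consensus -> annotation, as one configured, logged, reproducible
run.

Stage order is fixed; outlier scans run on both the full and the
clone-corrected matrix.  All stochastic stages take explicit seeds and a
rerun with the same config is byte-identical, so output paths carry no
timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonality, consensus, core, filtering, outlier_bayes, outlier_pca, popgen, replicate_qc

log = logging.getLogger("radpop")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    vcf: str
    pops: str
    replicates: str | None = None
    reference_fasta: str | None = None
    transcriptome_fasta: str | None = None
    out_dir: str = "radpop_run"
    exclusions: list[str] = field(default_factory=list)
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    clone_threshold: float | None = None  # None -> replicate-calibrated
    clone_linkage: str = "farthest_neighbor"
    pca_k: int = 2
    pca_alpha: float = 0.001
    bayes: outlier_bayes.BayesScanConfig = field(
        default_factory=outlier_bayes.BayesScanConfig
    )
    n_permutations: int = 499
    seed: int = 1

    def validate_paths(self) -> None:
        for p in (self.vcf, self.pops, self.replicates,
                  self.reference_fasta, self.transcriptome_fasta):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.seed}
    stage = "load"
    try:
        gm = core.read_vcf(cfg.vcf)
        pm = core.read_population_map(cfg.pops, cfg.replicates, cfg.exclusions)
        gm = core.apply_population_map(gm, pm)
        manifest["stages"].append(
            {"stage": stage, "samples": gm.n_samples, "loci": gm.n_loci}
        )

        stage = "sample_filter"
        gm, sample_report = filtering.drop_poor_samples(gm, cfg.filter)
        manifest["stages"].append(
            {"stage": stage, "samples": gm.n_samples,
             "dropped": sample_report.dropped}
        )

        stage = "locus_filter"
        gm, locus_report = filtering.filter_loci(gm, cfg.filter)
        manifest["stages"].append(
            {"stage": stage, "loci": gm.n_loci,
             "removed_multiallelic": locus_report.removed_multiallelic,
             "removed_call_rate": locus_report.removed_call_rate,
             "removed_heterozygosity": locus_report.removed_heterozygosity}
        )

        stage = "replicate_qc"
        qc = None
        if pm.replicate_pairs:
            qc = replicate_qc.replicate_concordance(gm, pm)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"sample_a": a, "sample_b": b,
                         "concordance": qc.per_pair_concordance[(a, b)],
                         "shared_loci": qc.per_pair_shared[(a, b)],
                         "prevosti_distance": qc.per_pair_distance[(a, b)]}
                        for a, b in qc.per_pair_concordance
                    ]
                ),
                out / "replicate_qc.tsv",
            )
        spectrum = replicate_qc.titv_summary(gm)
        (out / "substitution_spectrum.json").write_text(
            json.dumps(
                {"counts": spectrum.counts, "transitions": spectrum.transitions,
                 "transversions": spectrum.transversions,
                 "titv_ratio": spectrum.titv_ratio,
                 "percent_transversions": spectrum.percent_transversions},
                indent=2,
            )
        )
        manifest["stages"].append(
            {"stage": stage,
             "mean_concordance": qc.mean if qc else None,
             "titv": spectrum.titv_ratio}
        )

        stage = "clone_delimitation"
        dm = clonality.distance_matrix(gm)
        if cfg.clone_threshold is not None:
            threshold = cfg.clone_threshold
        else:
            threshold = clonality.calibrate_clone_threshold(dm, pm)
        partition = clonality.delimit_mlls(dm, threshold, cfg.clone_linkage)
        _write_tsv(
            pd.DataFrame(
                [{"sample": s, "mll": k} for s, k in partition.labels().items()]
            ),
            out / "mll_assignments.tsv",
        )
        manifest["stages"].append(
            {"stage": stage, "threshold": threshold,
             "n_mlls": partition.n_lineages}
        )

        stage = "drop_replicates"
        gm_main = replicate_qc.drop_replicate_samples(gm, pm)
        main_samples = set(gm_main.samples)
        main_partition = clonality.MLLPartition(
            threshold=threshold, linkage=cfg.clone_linkage,
            clusters=[
                [s for s in cl if s in main_samples]
                for cl in partition.clusters
                if any(s in main_samples for s in cl)
            ],
        )

        stage = "thinning"
        if cfg.filter.thin_per_tag:
            gm_main = filtering.thin_per_tag_maxaf(
                gm_main, cfg.filter.thin_criterion
            )
        core.write_vcf(gm_main, str(out / "filtered.vcf"))
        manifest["stages"].append(
            {"stage": stage, "samples": gm_main.n_samples, "loci": gm_main.n_loci}
        )

        stage = "clone_correction"
        gm_cc = clonality.clone_correct(gm_main, main_partition)
        core.write_vcf(gm_cc, str(out / "clone_corrected.vcf"))

        # per-population Table-1 analogue: N, MLLs, R, Ho, FIS
        rows = []
        labels = main_partition.labels()
        div = popgen.diversity_summary(gm_cc)
        for pop in sorted(set(gm_main.populations or [])):
            members = [s for s, p in zip(gm_main.samples, gm_main.populations)
                       if p == pop]
            G = len({labels[s] for s in members})
            N = len(members)
            rich = clonality.genotypic_richness(G, N) if N >= 2 else None
            rows.append(
                {"population": pop, "N": N, "MLLs": G,
                 "R": rich.rounded if rich else float("nan"),
                 "Ho": round(div.ho.get(pop, float("nan")), 4),
                 "FIS": round(div.fis.get(pop, float("nan")), 4)}
            )
        summary = pd.DataFrame(rows)
        _write_tsv(summary, out / "population_summary.tsv")
        manifest["stages"].append(
            {"stage": stage, "samples": gm_cc.n_samples,
             "n_mlls_total": int(summary["MLLs"].sum())}
        )

        stage = "differentiation"
        pair_rows = []
        pops = sorted(set(gm_cc.populations or []))
        for pa, pb in combinations(pops, 2):
            fst = popgen.wc_fst(gm_cc, None, (pa, pb))
            gt = popgen.g_test_differentiation(
                gm_cc, None, (pa, pb),
                n_permutations=cfg.n_permutations, seed=cfg.seed,
            )
            pair_rows.append(
                {"pop_a": pa, "pop_b": pb,
                 "weighted_fst": fst.weighted_theta,
                 "mean_fst": fst.mean_theta,
                 "g_test_p": gt.combined_p}
            )
        _write_tsv(pd.DataFrame(pair_rows), out / "pairwise_fst.tsv")

        stage = "outlier_scans"
        scans = {}
        for label, matrix in (("full", gm_main), ("clone_corrected", gm_cc)):
            pca_res = outlier_pca.pca_scan(matrix, K=cfg.pca_k, alpha=cfg.pca_alpha)
            alt, tot, _ = outlier_bayes.allele_count_table(matrix)
            bcfg = outlier_bayes.BayesScanConfig(
                **{**asdict(cfg.bayes), "seed": cfg.seed}
            )
            bayes_res = outlier_bayes.bayescan_fit(
                alt, tot, bcfg, locus_ids=matrix.locus_ids
            )
            shared = consensus.consensus_outliers(
                {lid: bool(f) for lid, f in zip(matrix.locus_ids, pca_res.outlier_flags)},
                {lid: bool(f) for lid, f in zip(matrix.locus_ids, bayes_res.flags)},
            )
            freqs = popgen.allele_frequencies(matrix)
            report = pd.DataFrame(
                {"locus_id": matrix.locus_ids,
                 "pca_p": pca_res.pvalues,
                 "pca_flag": pca_res.outlier_flags,
                 "bayes_P": bayes_res.P,
                 "bayes_q": bayes_res.q,
                 "bayes_fst": bayes_res.fst,
                 "bayes_flag": bayes_res.flags,
                 "consensus": [lid in shared for lid in matrix.locus_ids]}
            )
            for pop, (p, _) in freqs.items():
                report[f"alt_freq_{pop}"] = p
            _write_tsv(report, out / f"outliers_{label}.tsv")
            scans[label] = {"pca": int(pca_res.outlier_flags.sum()),
                            "bayes": int(bayes_res.flags.sum()),
                            "consensus": len(shared),
                            "gif": pca_res.gif}
        manifest["stages"].append({"stage": stage, **scans})

        stage = "annotation"
        if cfg.reference_fasta and cfg.transcriptome_fasta:
            ref = consensus.read_fasta(cfg.reference_fasta)
            tx = consensus.read_fasta(cfg.transcriptome_fasta)
            by_id = {l.locus_id: l for l in gm_main.loci}
            final = pd.read_csv(out / "outliers_full.tsv", sep="\t")
            shared_ids = final.loc[final["consensus"], "locus_id"].tolist()
            ann_rows = []
            for lid in shared_ids:
                window, offset = consensus.extract_flank_window(ref, by_id[lid])
                hits = consensus.annotate_outlier(window, offset, tx, locus_id=lid)
                if not hits:
                    ann_rows.append({"locus_id": lid, "transcript_id": "",
                                     "identity": float("nan"), "length": 0,
                                     "spans_snp": False, "positive": False})
                for h in hits:
                    ann_rows.append(
                        {"locus_id": lid, "transcript_id": h.transcript_id,
                         "identity": round(h.identity, 4),
                         "length": h.block_length,
                         "spans_snp": h.spans_snp, "positive": h.positive}
                    )
            _write_tsv(pd.DataFrame(ann_rows), out / "annotation.tsv")
            manifest["stages"].append(
                {"stage": stage, "n_annotated": len(shared_ids)}
            )

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    except Exception as exc:  # noqa: BLE001 - abort with the stage name
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
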