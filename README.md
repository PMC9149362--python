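# radpop

Clonality-aware population genomics for RAD-seq SNP data.

In clonal plants and other partially clonal organisms, the sampling unit (a
shoot, a ramet) is not the genetic individual (the genet): a meadow of
hundreds of shoots can be a single clone. Standard diversity and
differentiation statistics are badly biased when ramets of the same genet
are treated as independent individuals. `radpop` implements the full
post-variant-calling workflow for such datasets:

- **Filtering** of a multi-sample SNP genotype matrix (biallelic loci,
  call-rate and heterozygosity bounds, one SNP per 36-bp RAD tag by maximal
  minor-allele frequency);
- **Technical-replicate QC**: per-pair genotype concordance and the
  transition/transversion spectrum;
- **Clone (MLL) delimitation**: agglomerative clustering of samples on the
  Prevosti genetic distance (mean per-locus allele-sharing distance,
  `|g_a − g_b| / 2` over mutually typed loci) with the clustering threshold
  calibrated as the *maximum distance observed between technical
  replicates* — pairs known a priori to be the same genotype, so any
  distance between them is pure genotyping error;
- **Clonal richness** R = (G − 1)/(N − 1), where G is the number of
  distinct multilocus lineages among N samples;
- **Clone-corrected statistics**: observed heterozygosity H_o, Nei's
  unbiased gene diversity, multilocus F_IS = 1 − ΣH_o/ΣH_e, pairwise
  Weir–Cockerham θ (weighted Σa/Σ(a+b+c) and mean-of-ratios forms), and a
  seeded permutation G-test of genic differentiation combined across loci
  by Fisher's method;
- **Two outlier-locus scans**: a Bayesian F_ST scan (beta-binomial
  allele-count likelihood, logit-linear locus/population decomposition of
  F_ST, reversible-jump MCMC over locus-effect inclusion, q-values from
  posterior inclusion probabilities, decision rule q ≤ 0.3 and P > 0.7 at
  prior odds 100) and a PCA scan (per-SNP z-scores from regression on K
  principal components, Mahalanobis D², genomic-inflation rescaling
  λ = median(D²)/median(χ²_K), Bonferroni decisions at α = 0.001);
  loci flagged by both scans are the consensus "best outliers";
- **Annotation** of outlier SNPs: an 80-bp flanking window (two adjacent
  RAD tags) is aligned to a transcriptome with an affine-gap
  Smith–Waterman aligner; a hit is a positive only at ≥90% identity over
  ≥25 aligned columns covering the SNP;
- **A synthetic-data generator** (Balding–Nichols island model with
  planted genets, planted high-F_ST outlier loci, per-allele genotyping
  error, missingness and technical replicates) that emits full ground
  truth, so every stage of the pipeline is testable against known answers.

## Worked example

```python
import radpop

cfg = radpop.SimConfig(
    seed=7, n_pops=3, samples_per_pop=(14, 20, 15),
    genets_per_pop=(4, 2, 11),
    ramet_allocation=((11, 1, 1, 1), (19, 1), (5,) + (1,) * 10),
    n_loci=800, neutral_f=0.35, flip_rate=0.05, missing_rate=0.1,
    replicates_per_pop=4, pop_names=("GC", "FA", "EB"),
)
gm, pm, truth = radpop.simulate_dataset(cfg)
gm = radpop.apply_population_map(gm, pm)
gm, _ = radpop.filter_loci(gm)

qc = radpop.replicate_concordance(gm, pm)
dm = radpop.distance_matrix(gm)
threshold = radpop.calibrate_clone_threshold(dm, pm)
part = radpop.delimit_mlls(dm, threshold, "nearest_neighbor")
labels = part.labels()
print(f"replicate concordance {qc.mean:.2f} +/- {qc.sd:.2f}; "
      f"clone threshold {threshold:.3f}")
for pop in ("GC", "FA", "EB"):
    members = [s for s in gm.samples
               if gm.pop_of(s) == pop and not s.endswith("_rep")]
    G = len({labels[s] for s in members})
    r = radpop.genotypic_richness(G, len(members))
    print(f"{pop}: N={r.N} MLLs={r.G} R={r.rounded:.2f}")
```

prints

```
replicate concordance 0.83 +/- 0.01; clone threshold 0.099
GC: N=14 MLLs=4 R=0.23
FA: N=20 MLLs=2 R=0.05
EB: N=15 MLLs=11 R=0.71
```

i.e. the replicate-calibrated threshold (here 0.099 — all replicate pairs
lie below it by construction) collapses ramets into exactly the planted
genet structure: a near-monoclonal population (R = 0.05, one lineage
dominating), a moderately clonal one (R = 0.23) and a mostly sexual one
(R = 0.71). Genotyping concordance between replicate library preps is
~83% under the generator's 5% per-allele error and ~10% missingness.

The same workflow runs from the shell:

```sh
radpop simulate --seed 7 --out data/
radpop clones --vcf data/genotypes.vcf --pops data/pops.csv --replicates data/reps.csv
radpop run --config run.yaml        # full pipeline into an output directory
```

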