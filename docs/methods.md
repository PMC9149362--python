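# Methods

This note documents the models, estimators and numerical choices behind
`radpop`, and what the synthetic-data tests do and do not establish about
real data.

## Data model

Genotypes are diploid allele-dosage codes (0/1/2 copies of the ALT allele)
with an explicit missing sentinel. Coordinates are 1-based inclusive at
I/O boundaries (the VCF convention); all internal window arithmetic is
0-based half-open and converted at the boundary. RAD tags are 36 bp
(type IIB restriction fragments are uniform); when the VCF does not encode
tag membership, a SNP's tag is its contig plus the 36-bp bin of its
position, overridable by a locus-ID regex.

## Filtering

Defaults: biallelic loci only, locus call rate ≥ 0.90 (inclusive — the
boundary is not specified more precisely by the usual tooling, so the
inclusive reading is used and configurable), per-locus heterozygote
fraction ≤ 0.50 among non-missing calls (inclusive). The heterozygosity
cap removes lumped paralogs, which present as loci where most individuals
appear heterozygous; the call-rate floor removes loci prone to null
alleles from restriction-site mutations. Sample filtering removes
individuals under 50% call rate. Per-criterion removal counts are
attributed to the first failing rule in the order multiallelic → call
rate → heterozygosity.

Thinning keeps one SNP per tag. "Maximal allele frequency" is read as
maximal *minor*-allele frequency — the most informative SNP of the tag —
with max-ALT-frequency available as a config option. MAF is pooled across
populations because thinning precedes any population-level analysis. Ties
break to the smallest position, then the lexicographically smallest locus
id, so the operation is deterministic and idempotent.

## Replicate QC and clone delimitation

Technical replicates are independent library preparations of the same DNA.
Concordance is genotype-level (fraction of identical calls over loci typed
in both members); it is computed after locus filtering by default.

The clone metric is the Prevosti distance: mean over mutually typed loci
of |g_a − g_b|/2, taking values 0, 0.5, 1 per locus. Missing data are
handled by pairwise deletion — equivalent to assuming missing loci match
at the average rate — because the alternative (counting missing as
mismatch) inflates exactly the replicate distances the threshold is
calibrated on. Pairs with no shared loci have undefined distance and are
treated as above any threshold.

The delimitation threshold is the maximum distance among technical
replicate pairs ("confirmed clones"): every distance observed between two
library preps of the same DNA is genotyping noise, so genuine clones are
expected to fall at or below the largest such distance. Pairs at distance
≤ threshold (inclusive: the calibrating pair itself must collapse) share a
multilocus lineage (MLL). Clustering is agglomerative with
farthest-neighbor (complete) linkage by default — the conservative choice,
under which a cluster forms only if every internal pair satisfies the
threshold chain rule — with nearest-neighbor (single) linkage available.

**Linkage and exact recovery.** For *exact* recovery of planted genets
the package's own recovery suite uses nearest-neighbor linkage, many
replicate pairs, and planted genet sizes ≥ 3. The reasoning is
order-statistics, not tuning: replicate-pair distances and within-genet
ramet distances are draws from the same noise distribution, so the
probability that *every* within-genet pair falls below the maximum of m
replicate pairs is roughly m/(m+k) for k within-genet pairs — a coin flip
under complete linkage whenever k > m. Single linkage needs only chain
connectivity (each ramet within threshold of *some* clone-mate), which is
nearly certain when genets have several ramets and between-genet distances
are far above the threshold. Under strong differentiation the two linkages
give identical partitions except in these borderline tail events.

Clonal richness is R = (G − 1)/(N − 1) (0 = monoclonal, 1 = all
distinct). Clone correction keeps one ramet per MLL — the one with the
highest call rate, ties resolved by input order. For SSR data, MLGs are
exact multilocus matches (equal at all mutually typed loci, at least one
locus mutually typed, transitive closure).

## Diversity and differentiation

Per population: per-locus observed heterozygosity H_o; Nei's unbiased gene
diversity H_e = (2n/(2n−1))(1 − Σp̂²); multilocus
F_IS = 1 − Σ_l H_o,l / Σ_l H_e,l over loci with H_e > 0 (a ratio of sums,
which is far more stable than averaging per-locus ratios at small n).
Strongly negative F_IS is the fixed-heterozygosity signature of clonal
reproduction, and on simulated clonal populations F_IS decreases as
clonality increases.

Pairwise F_ST is Weir & Cockerham's θ from the a (among-population),
b (among-individual) and c (within-individual) variance components, with
r = 2 populations. Both multilocus summaries are reported: the weighted
ratio Σa/Σ(a+b+c) (the headline estimator) and the mean of defined
per-locus ratios. Loci monomorphic in both populations (a+b+c = 0), or
with fewer than two genotyped samples in either population, are excluded
from both summaries.

The exact test of genic differentiation is replaced by a permutation
G-test with the same statistic: per locus, G = 2ΣO·ln(O/E) on the 2×2
allele-count table, with the null built by reshuffling individuals
(genotypes intact) between the two populations and a mandatory seed;
per-locus permutation p-values (1+#{G* ≥ G})/(n_perm+1) combine across
loci by Fisher's method. The permutation null is slightly conservative at
small sample sizes because the p-values are discrete with floor
1/(n_perm+1).

## PCA outlier scan

Genotype columns are centered at 2p̂ and scaled by √(2p̂(1−p̂)); missing
entries are imputed at the column mean (0 after centering) — the simplest
defensible choice, recorded in output metadata. Monomorphic columns are
dropped. The top K left-singular vectors give sample scores; regressing
each scaled column on them yields K coefficients standardized by the
residual standard error (dof = n − K) — the per-SNP z-vector. The squared
Mahalanobis distance D² of each z-vector under the sample covariance of
all z-vectors is rescaled by the genomic inflation factor
λ = median(D²)/median(χ²_K) and referred to χ²_K; decisions are
Bonferroni at α = 0.001 (inclusive at the cutoff). K is chosen by the
user from the emitted scree; K = 2 is the natural choice for three
populations.

Numerical notes: loci with zero residual variance (perfectly explained by
the PCs) are flagged and excluded from the covariance and the test; the
covariance is the plain sample covariance by default with a robust
(median/MAD, 50% shrinkage) option — the robust option is a known source
of numeric divergence from tools that use a fully robust estimator. The
χ² reference has slightly heavy tails relative to the exact
Hotelling-type null of t-distributed z-scores: at n = 60, K = 2 the null
rejection rate at the 5% level runs near 5.8% rather than 5.0%. The
calibration tests therefore use the binomial Monte-Carlo band of a single
dataset's rejection fraction, and λ is checked against [0.8, 1.25].

## Bayesian F_ST scan

Allele counts per locus i and population j follow the beta-binomial
marginal of the multinomial-Dirichlet model:
alt_ij ~ Binomial(tot_ij, p̃_ij), p̃_ij ~ Beta(θ_ij p_i, θ_ij(1−p_i)),
θ_ij = 1/F_ij − 1, with logit(F_ij) = α_i δ_i + β_j. Writing
logit(F) = η gives θ = e^{−η}, keeping the sampler unconstrained. Priors:
β_j ~ N(−1, 1.8²), α_i ~ N(0, 1) when included, δ_i ~ Bernoulli(π) with
π = 1/(1+prior_odds), p_i ~ U(0,1). The sampled frequency p̃ is
integrated analytically, so the chain updates only (p_i, α_i, δ_i, β_j).

Updates are Metropolis-within-Gibbs random walks on logit(p), α and β,
plus a reversible-jump flip of δ_i. Proposal step sizes are tuned in
pilot rounds (20 × 500 iterations by default, targeting 25–45%
acceptance). During the pilot phase all loci are forced in, which serves
two purposes: every α_i gets conditional-posterior samples for step
tuning, and the per-locus posterior mean/SD learned there become the RJ
birth proposal (with the exact prior/proposal Hastings correction). A
birth proposal drawn from the prior N(0,1) almost never reaches the large
α a genuinely divergent locus requires, so this adaptation is what makes
trans-dimensional mixing workable at realistic chain lengths. RJ
acceptance rates are naturally low (≈ π at neutral loci) and are not
warned about; sub-5% acceptance in the p/α/β blocks is.

Chain defaults are desk-scale: 5,000 burn-in + 25,000 iterations thinned
by 10 — far shorter than the original genome-scan tools use, adequate for
the few-hundred-locus datasets of the test suite (chains with different
seeds agree on inclusion probabilities to < 0.1 median). Posterior
inclusion probabilities P_i give q-values (running mean of 1 − P down the
P-ranking); the decision rule is q ≤ 0.3 (inclusive) *and* P > 0.7
(strict). These thresholds are permissive; they are exposed as parameters
and applied exactly as stated, with no judgment encoded.

Correctness is anchored two ways: a drift-only single-locus configuration
(locus effects off, tied β) whose posterior mean F_ST matches a dense
3-D grid integration of the same posterior, and null/power suites on
simulated data. With prior odds 100, a locus needs a Bayes factor above
~230 to clear P > 0.7: at 3 populations × 20 diploids even a locus with
sample frequencies (0.12, 0.85, 0.0) only reaches BF ≈ 38, so power
studies use ≥ 50 diploids per population.

## Synthetic data

The generator is a Balding–Nichols island model: ancestral frequencies
p0 ~ U(0.05, 0.95); population frequencies p_j ~ Beta(p0(1−F)/F,
(1−p0)(1−F)/F), so F parameterizes the expected F_ST directly (F = 0
copies p0; F = 1 is rejected). Clonality: G genets per population each
draw one HWE genotype; ramets copy their genet. Ramet allocation is
geometric by default (one lineage dominating, as real clonal meadows
show), or an explicit size vector. Genotyping error is a per-allele flip
at rate ε (hom↔het errors dominate, the allelic-dropout-like pattern of
RAD data); missingness is an independent mask at rate m; technical
replicates are independently re-noised copies of the chosen samples'
clean genotypes. Defaults (ε = 0.05, m = 0.10, 3 populations, 20
samples/population, 4 replicates/population) reproduce the data regime
the pipeline is built for: ~10% per-genotype replicate discordance and
~10% missing calls, with strong differentiation available through F.
The exact expectation of replicate concordance under the flip model is
emitted with the truth, so QC tests are closed-form.

**Planted outliers are conditioned on realized divergence.** A raw
Balding–Nichols draw at F_out = 0.5 lands all populations near the *same*
fixation boundary ~45% of the time — a "planted outlier" with zero
realized divergence that no method could detect. Outlier frequencies are
therefore rejection-sampled until the realized among-population
differentiation s²/(p̄(1−p̄)) reaches the nominal F_out (keeping the most
divergent of 500 draws otherwise), so the ground-truth label "locus with
elevated differentiation" is true of the emitted data. Power estimates
against this truth are per-locus detection rates of *genuinely divergent*
loci; they do not describe the (lower) rate at which raw high-F draws
would be flagged.

What the generator does not emulate: linkage between tags, allele-specific
depth (there are no reads), null alleles, inbreeding within populations,
migration or mutation dynamics. Passing tests therefore establish the
estimators' correctness and calibration under the island model with
independent loci — not robustness to LD, depth artifacts or demographic
history.

## Annotation

Flanking windows are 80 bp centered on the SNP (two adjacent 36-bp tags),
clipped at contig bounds. The local aligner is affine-gap Smith–Waterman
(Gotoh): match +1, mismatch −2, gap open −2, gap extend −1, where a gap of
length k costs open + (k−1)·extend; N is a universal mismatch. Both
orientations are aligned and the better used (transcripts are strandless
here). A hit is an unambiguous positive iff identity ≥ 0.90, aligned
block ≥ 25 columns, and the block contains the SNP column ("around the
SNP position" read as containment; a stricter flank requirement is a
config option). E-values are deliberately not computed: the decision rule
is the identity/length/position criterion, and Karlin–Altschul calibration
would add scope without changing any decision. Scores are verified against
exhaustive enumeration on tiny instances and against an independent local
aligner under the same scoring scheme.

## Pipeline and reproducibility

Stage order is fixed: sample drop → locus filter → replicate QC → clone
delimitation → replicate removal → per-tag thinning → clone correction →
diversity/differentiation → outlier scans (on both the full and the
clone-corrected matrix) → consensus → annotation. Every stochastic stage
takes an explicit seed, and a rerun with the same config is byte-identical
— for that reason output directories are caller-named and no output file
embeds a timestamp. MLL delimitation is global (one clustering across
populations) with richness reported per population; under strong
differentiation this is equivalent to per-population clustering because
between-population distances sit far above any replicate-calibrated
threshold.

Problem sizes in the test and acceptance suites are desk-scale by design:
hundreds to a few thousand loci, tens of samples, short MCMC chains, 100
recovery replicates. They are chosen so each statistical check has real
power at that scale (e.g. ±0.02 on weighted θ at 2,000 loci; ≥95/100
exact clone recoveries; Bayes power runs at 50 diploids/population).

## Known limitations

- The Bayesian scan handles biallelic loci and a shared pairwise model
  only (no dominant-marker mode, no >2 alleles).
- No exact numeric parity is claimed with the original scan tools (robust
  covariance details and MCMC implementations differ), nor with any
  specific F_IS implementation; estimator formulas are documented above
  instead.
- The exact-test replacement (permutation G-test) is conservative at very
  small clone-corrected sample sizes.
- Automatic selection of K, LD clumping, AMOVA, HWE/LD exact tests and
  probabilistic clone assignment (p_sex) are out of scope.
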