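"""Clone (MLL/MLG) delimitation, replicate-calibrated thresholding,
genotypic richness and clone correction.

In clonal plants the sampling unit (ramet) is not the genetic individual
(genet): samples whose pairwise genetic distance falls below a threshold are
grouped into one multilocus lineage (MLL).  The threshold is calibrated as
the maximum distance observed between technical replicates — pairs known to
be the same genotype, so any distance between them is pure genotyping
error.  Genotypic richness is summarized as R = (G-1)/(N-1) where G is the
number of distinct lineages among N samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .core import MISSING, GenotypeMatrix, PopulationMap, SSRMatrix

__all__ = [
    "DistanceMatrix",
    "MLLPartition",
    "RichnessResult",
    "MLLClusterer",
    "prevosti_distance",
    "distance_matrix",
    "calibrate_clone_threshold",
    "delimit_mlls",
    "genotypic_richness",
    "clone_correct",
    "exact_match_mlg",
]

#: Placeholder fed to the clusterer for undefined distances (no shared loci):
#: guaranteed above any threshold since true distances live in [0, 1].
_UNDEFINED_FILL = 2.0

_LINKAGES = {"farthest_neighbor": "complete", "nearest_neighbor": "single"}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genotype distances in [0, 1] with shared-locus counts.

    Pairs with zero mutually typed loci carry NaN and are listed in
    ``undefined_pairs``.
    """

    samples: list[str]
    values: np.ndarray
    shared: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.values.shape != (n, n) or self.shared.shape != (n, n):
            raise ValueError("distance grid shape does not match samples")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance grid is not symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.values[i, j])


@dataclass
class MLLPartition:
    """Partition of samples into multilocus lineages at a distance threshold."""

    threshold: float
    linkage: str
    clusters: list[list[str]]
    representatives: dict[int, str] | None = None

    @property
    def n_lineages(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        return {s: k for k, cl in enumerate(self.clusters) for s in cl}


@dataclass
class RichnessResult:
    G: int
    N: int
    R: float

    @property
    def rounded(self) -> float:
        return round(self.R, 2)


def prevosti_distance(gm: GenotypeMatrix, sample_a: str, sample_b: str) -> float:
    """Mean per-locus allele-sharing distance |d_a - d_b| / 2 over shared loci.

    Per-locus values are 0 (identical genotype), 0.5 (one allele differs)
    or 1 (opposite homozygotes); loci missing in either sample are excluded
    (pairwise deletion).  Returns NaN when no locus is typed in both.
    """
    ga = gm.calls[gm.sample_index(sample_a)]
    gb = gm.calls[gm.sample_index(sample_b)]
    both = (ga != MISSING) & (gb != MISSING)
    if not both.any():
        return float("nan")
    return float(np.abs(ga[both].astype(float) - gb[both]).mean() / 2.0)


def distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs Prevosti distances with pairwise deletion of missing calls."""
    n = gm.n_samples
    present = gm.calls != MISSING
    dos = gm.calls.astype(float)
    dos[~present] = 0.0
    values = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        both = present[i] & present[i + 1 :]
        diff = np.abs(dos[i] - dos[i + 1 :]) * both
        counts = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(counts > 0, diff.sum(axis=1) / (2.0 * counts), np.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        shared[i, i + 1 :] = counts
        shared[i + 1 :, i] = counts
        for off, c in enumerate(counts):
            if c == 0:
                undefined.append((gm.samples[i], gm.samples[i + 1 + off]))
    np.fill_diagonal(shared, present.sum(axis=1))
    return DistanceMatrix(
        samples=list(gm.samples), values=values, shared=shared,
        undefined_pairs=undefined,
    )


def calibrate_clone_threshold(dm: DistanceMatrix, pm: PopulationMap) -> float:
    """Clone threshold = maximum distance between technical replicates."""
    if not pm.replicate_pairs:
        raise ValueError(
            "no technical-replicate pairs available; supply a manual threshold"
        )
    dists = []
    for a, b in pm.replicate_pairs:
        if a in dm.samples and b in dm.samples:
            d = dm.get(a, b)
            if np.isfinite(d):
                dists.append(d)
    if not dists:
        raise ValueError(
            "no replicate pair with a defined distance; supply a manual threshold"
        )
    return float(max(dists))


class MLLClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative clone clustering on a precomputed distance matrix.

    Parameters
    ----------
    threshold : float
        Samples whose cophenetic distance is <= threshold share a lineage
        (the replicate pair sitting exactly at the calibrated maximum must
        collapse, so the boundary is inclusive).
    linkage : {"farthest_neighbor", "nearest_neighbor"}
        Farthest-neighbor (complete) linkage is the conservative default:
        two clusters merge only if *every* inter-pair distance satisfies
        the threshold chain rule.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per sample, 0-based, ordered by first occurrence.
    linkage_tree_ : ndarray
        The scipy condensed linkage matrix of the agglomeration.
    """

    def __init__(self, threshold: float = 0.0, linkage: str = "farthest_neighbor"):
        self.threshold = threshold
        self.linkage = linkage

    def fit(self, X, y=None):
        if self.linkage not in _LINKAGES:
            raise ValueError(
                f"linkage must be one of {sorted(_LINKAGES)}, got {self.linkage!r}"
            )
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("expected a square precomputed distance matrix")
        D = D.copy()
        D[np.isnan(D)] = _UNDEFINED_FILL
        if D.shape[0] == 1:
            self.labels_ = np.zeros(1, dtype=int)
            self.linkage_tree_ = np.empty((0, 4))
            return self
        condensed = squareform(D, checks=False)
        tree = scipy_linkage(condensed, method=_LINKAGES[self.linkage])
        raw = fcluster(tree, t=self.threshold, criterion="distance")
        # relabel by first occurrence for a deterministic, order-stable output
        remap: dict[int, int] = {}
        labels = np.empty_like(raw)
        for i, r in enumerate(raw):
            labels[i] = remap.setdefault(r, len(remap))
        self.labels_ = labels
        self.linkage_tree_ = tree
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def delimit_mlls(
    dm: DistanceMatrix,
    threshold: float,
    linkage: str = "farthest_neighbor",
) -> MLLPartition:
    """Cluster samples into MLLs at the given distance threshold."""
    model = MLLClusterer(threshold=threshold, linkage=linkage).fit(dm.values)
    clusters: list[list[str]] = [[] for _ in range(int(model.labels_.max()) + 1)]
    for s, lab in zip(dm.samples, model.labels_):
        clusters[int(lab)].append(s)
    return MLLPartition(threshold=threshold, linkage=linkage, clusters=clusters)


def linkage_newick(tree: np.ndarray, samples: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths
    (half the merge height on each side, ultrametric)."""
    n = len(samples)

    def node(idx: int, parent_height: float) -> str:
        if idx < n:
            return f"{samples[idx]}:{parent_height / 2:.6g}"
        row = tree[idx - n]
        h = row[2]
        left = node(int(row[0]), h)
        right = node(int(row[1]), h)
        return f"({left},{right}):{(parent_height - h) / 2:.6g}"

    if n == 1:
        return f"{samples[0]};"
    root = tree[-1]
    h = root[2]
    return f"({node(int(root[0]), h)},{node(int(root[1]), h)});"


def genotypic_richness(G: int, N: int) -> RichnessResult:
    """Clonal richness R = (G - 1) / (N - 1)."""
    if N < 2:
        raise ValueError("R is undefined for fewer than 2 samples")
    if not 1 <= G <= N:
        raise ValueError(f"need 1 <= G <= N, got G={G}, N={N}")
    return RichnessResult(G=G, N=N, R=(G - 1) / (N - 1))


def clone_correct(gm: GenotypeMatrix, partition: MLLPartition) -> GenotypeMatrix:
    """Keep one representative ramet per MLL: highest call rate, ties by
    input order."""
    labels = partition.labels()
    missing = [s for s in gm.samples if s not in labels]
    if missing:
        raise ValueError(f"partition does not cover samples: {missing}")
    rates = gm.sample_call_rates()
    best: dict[int, int] = {}
    for i, s in enumerate(gm.samples):
        k = labels[s]
        if k not in best or rates[i] > rates[best[k]]:
            best[k] = i
    partition.representatives = {k: gm.samples[i] for k, i in best.items()}
    keep = sorted(best.values())
    return gm.take_samples(keep)


def exact_match_mlg(ssr: SSRMatrix) -> MLLPartition:
    """Exact multilocus-genotype matching for SSR data.

    Two samples match if they are equal at every mutually typed locus and
    share at least one typed locus; the transitive closure of matches
    defines the MLGs.
    """
    n = ssr.n_samples
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            shared = 0
            equal = True
            for a, b in zip(ssr.calls[i], ssr.calls[j]):
                if a is None or b is None:
                    continue
                shared += 1
                if a != b:
                    equal = False
                    break
            if equal and shared >= 1:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ssr.samples[i])
    clusters = sorted(groups.values(), key=lambda cl: ssr.samples.index(cl[0]))
    return MLLPartition(threshold=0.0, linkage="exact_match", clusters=clusters)
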