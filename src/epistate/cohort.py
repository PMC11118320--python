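"""Cohort-level matrices, clustering with bootstrap stability, and
H3K4me3 breadth/occupancy statistics.

Sample clustering follows the rank-based recipe used throughout tumor
epigenome studies: pairwise distance 1 - Spearman correlation over features,
Ward.D2 agglomeration, and ordinary bootstrap probabilities (BP, percent of
feature-resampled replicates reproducing a cluster) with 70% as the
conventional stability threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .intervals import GeneModel, GenomeLayout
from .states import MarkSet
from .states import _window_arrays

__all__ = [
    "FeatureMatrix",
    "variance_filter",
    "hierarchical_cluster",
    "bootstrap_stability",
    "occupancy_stats",
    "promoter_peak_width",
    "promoter_occupancy_matrix",
]


@dataclass
class FeatureMatrix:
    """Samples x features matrix with a provenance tag (bins | promoters | genes)."""

    values: pd.DataFrame
    provenance: str = "features"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("sample and feature labels must be unique")


def variance_filter(
    matrix: FeatureMatrix,
    mode: str,
    fraction: float | None = None,
    factor: float = 1.25,
    threshold: float = 0.01,
) -> FeatureMatrix:
    """Feature filters used before clustering; composable in sequence.

    ``top_fraction``  keeps the stated fraction of features by variance
                      (stable original order; ties by first occurrence).
    ``std_over_mean`` keeps features whose sample standard deviation exceeds
                      ``factor`` times their mean.
    ``low_signal``    drops features below ``threshold`` in ALL samples.
    """
    df = matrix.values
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError("matrix must be non-empty")
    if mode == "top_fraction":
        if fraction is None or not (0 < fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        n_keep = int(round(fraction * df.shape[1]))
        n_keep = max(n_keep, 1)
        variances = df.var(axis=0, ddof=1).to_numpy()
        order = np.argsort(-variances, kind="mergesort")[:n_keep]
        keep = df.columns[np.sort(order)]
    elif mode == "std_over_mean":
        std = df.std(axis=0, ddof=1)
        mean = df.mean(axis=0)
        keep = df.columns[std > factor * mean]
    elif mode == "low_signal":
        keep = df.columns[(df >= threshold).any(axis=0)]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return FeatureMatrix(values=df[keep], provenance=matrix.provenance)


def _spearman_distance(X: np.ndarray, on_constant: str = "error",
                       sample_names: Sequence[str] | None = None) -> np.ndarray:
    """Pairwise 1 - Spearman rho between sample rows (values in [0, 2])."""
    const = X.std(axis=1) == 0
    if const.any():
        if on_constant == "error":
            names = (
                [sample_names[i] for i in np.flatnonzero(const)]
                if sample_names is not None
                else list(np.flatnonzero(const))
            )
            raise ValueError(f"zero-variance sample profile(s): {names}")
    rho = spearmanr(X, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.where(np.isnan(rho), 0.0, rho)  # constant rows -> rho treated as 0
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ClusterResult:
    """Dendrogram (scipy linkage matrix) with flat two-group labels."""

    linkage: np.ndarray
    samples: list[str]
    labels: pd.Series  # k=2 flat labels (1/2)

    def node_members(self) -> list[frozenset]:
        """Sample membership of every internal dendrogram node."""
        n = len(self.samples)
        clusters: dict[int, frozenset] = {
            i: frozenset([self.samples[i]]) for i in range(n)
        }
        members = []
        for step, (a, b, _h, _c) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + step] = merged
            members.append(merged)
        return members

    def bipartition(self) -> frozenset:
        """The smaller side of the k=2 split, as a frozenset of sample ids."""
        g1 = frozenset(s for s, l in self.labels.items() if l == 1)
        g2 = frozenset(self.samples) - g1
        return min(g1, g2, key=lambda g: (len(g), sorted(g)))

    def to_newick(self) -> str:
        n = len(self.samples)
        names: dict[int, str] = {i: self.samples[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for step, (a, b, h, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            names[n + step] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            heights[n + step] = h
        return names[n + len(self.linkage) - 1] + ";"


def _cluster_from_values(X: np.ndarray, samples: Sequence[str],
                         on_constant: str = "error") -> ClusterResult:
    D = _spearman_distance(X, on_constant=on_constant, sample_names=list(samples))
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    flat = hierarchy.fcluster(Z, 2, criterion="maxclust")
    return ClusterResult(
        linkage=Z,
        samples=list(samples),
        labels=pd.Series(flat, index=list(samples), name="cluster"),
    )


def hierarchical_cluster(matrix: FeatureMatrix) -> ClusterResult:
    """Ward.D2 clustering of samples on 1 - Spearman feature distances.

    Deterministic given input order (scipy's nearest-neighbor chain with
    lowest-index tie resolution).  A sample whose feature profile has zero
    variance makes the rank correlation undefined and raises an error naming
    the sample.
    """
    df = matrix.values
    if df.shape[0] < 3:
        raise ValueError("need >= 3 samples to cluster")
    if df.shape[1] < 2:
        raise ValueError("need >= 2 features")
    return _cluster_from_values(
        df.to_numpy(dtype=float), list(df.index), on_constant="error"
    )


@dataclass
class BootstrapResult:
    """Bootstrap probabilities for the original dendrogram's clusters."""

    node_table: pd.DataFrame  # node, size, members, bp
    top_split_bp: float  # % of replicates reproducing the k=2 bipartition
    n_boot: int


def bootstrap_stability(
    matrix: FeatureMatrix, n_boot: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Feature-resampling bootstrap of the sample dendrogram.

    Features are resampled with replacement ``n_boot`` times and the samples
    reclustered; each original cluster's probability is the percentage of
    replicates whose dendrogram contains the same sample membership, and the
    top-split probability is the percentage reproducing the original two-group
    bipartition.  Fewer than 100 replicates is an error (estimates too noisy
    to report).  In replicates, a resampled profile that happens to be
    constant is treated as rank-uncorrelated (rho 0) instead of erroring.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    base = hierarchical_cluster(matrix)
    base_nodes = base.node_members()
    base_bipart = base.bipartition()
    X = matrix.values.to_numpy(dtype=float)
    samples = list(matrix.values.index)
    node_hits = np.zeros(len(base_nodes), dtype=int)
    bipart_hits = 0
    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_feat, size=n_feat)
        rep = _cluster_from_values(X[:, cols], samples, on_constant="zero")
        rep_nodes = set(rep.node_members())
        for i, node in enumerate(base_nodes):
            if node in rep_nodes:
                node_hits[i] += 1
        if rep.bipartition() == base_bipart:
            bipart_hits += 1
    table = pd.DataFrame(
        {
            "node": np.arange(len(base_nodes)),
            "size": [len(m) for m in base_nodes],
            "members": [",".join(sorted(m)) for m in base_nodes],
            "bp": 100.0 * node_hits / n_boot,
        }
    )
    return BootstrapResult(
        node_table=table,
        top_split_bp=100.0 * bipart_hits / n_boot,
        n_boot=n_boot,
    )


@dataclass
class OccupancyStats:
    """Genome occupancy summary for one mark in one sample."""

    occupancy_fraction: float
    n_peaks: int
    widths: np.ndarray

    @property
    def mean_width(self) -> float:
        return float(self.widths.mean()) if len(self.widths) else float("nan")


def occupancy_stats(sample: MarkSet, mark: str, layout: GenomeLayout) -> OccupancyStats:
    """Genome-wide occupancy fraction, peak count and width distribution.

    Occupancy = mark territory bp / total genome bp; widths are those of the
    normalized (merged) intervals.
    """
    iset = sample.require(mark)
    widths = np.concatenate(
        [iset.array(c)[:, 1] - iset.array(c)[:, 0] for c in iset.chroms]
    ) if iset.chroms else np.empty(0, dtype=np.int64)
    return OccupancyStats(
        occupancy_fraction=iset.total_bp / layout.total_bp,
        n_peaks=len(iset),
        widths=widths,
    )


def promoter_peak_width(
    sample: MarkSet,
    mark: str,
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    upstream: int = 2000,
    downstream: int = 2000,
) -> float:
    """Mean width of the mark's peaks that overlap >= 1 promoter window.

    Each (normalized) peak counts once even when it spans several promoters.
    Returns NaN when no peak touches a promoter.
    """
    iset = sample.require(mark)
    windows = _window_arrays(genes, upstream, downstream, layout)
    from .intervals import IntervalSet

    win_set = IntervalSet(
        (chrom, int(s), int(e))
        for chrom, (_idx, ss, ee) in windows.items()
        for s, e in zip(ss, ee)
    )
    widths = []
    for chrom in iset.chroms:
        arr = iset.array(chrom)
        if not len(arr):
            continue
        hits = win_set.overlaps_any(chrom, arr[:, 0], arr[:, 1])
        widths.extend((arr[hits, 1] - arr[hits, 0]).tolist())
    return float(np.mean(widths)) if widths else float("nan")


def promoter_occupancy_matrix(
    cohort: Iterable[MarkSet],
    mark: str,
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    upstream: int = 2000,
    downstream: int = 300,
) -> FeatureMatrix:
    """Samples x genes matrix of promoter-window coverage by a mark.

    Each entry is the fraction of the promoter window's bp covered by the
    mark's peak territory.  The default window (-2 kb/+300 bp) is the
    convention for sharp H3K4me3 promoter occupancy; pass -2 kb/+2 kb for
    the broader marks.
    """
    windows = _window_arrays(genes, upstream, downstream, layout)
    gene_ids = [g.gene_id for g in genes]
    rows = {}
    for sample in cohort:
        iset = sample.require(mark)
        vals = np.zeros(len(gene_ids))
        for chrom, (idxs, ss, ee) in windows.items():
            frac = iset.overlap_bp(chrom, ss, ee) / (ee - ss)
            vals[np.asarray(idxs)] = frac
        rows[sample.sample_id] = vals
    return FeatureMatrix(
        values=pd.DataFrame(rows, index=gene_ids).T, provenance="promoters"
    )
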