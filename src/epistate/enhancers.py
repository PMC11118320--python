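"""Enhancer-continuum analytics.

Given a samples x regions signal matrix over candidate enhancer regions, the
module normalizes raw counts to an RPKM-like scale, identifies group-specific
regions with a defined two-group test (Welch t on log2 signal, BH-adjusted),
scores each sample on the bivalent-of-two-archetypes continuum
(log10 mean signal in set 1 minus log10 mean signal in set 2), and compares
the TSS-distance distributions of two peak sets with a two-sample KS test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .intervals import GeneModel, GenomicInterval, IntervalSet, closest_tss_distance

__all__ = [
    "SignalMatrix",
    "normalize_signal",
    "differential_regions",
    "continuum_score",
    "quartile_assign",
    "tss_distance_ecdf_compare",
]


@dataclass
class SignalMatrix:
    """Samples x regions matrix of non-negative normalized signal."""

    values: pd.DataFrame
    regions: list[GenomicInterval] | None = None
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signal matrix must be non-negative")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("sample and region labels must be unique")
        if self.regions is not None and len(self.regions) != self.values.shape[1]:
            raise ValueError("regions length must match number of columns")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


def normalize_signal(
    raw_counts: pd.DataFrame, region_widths: Sequence[int]
) -> SignalMatrix:
    """Reads-per-kb-per-million normalization of a raw count matrix.

    entry = raw * 1e9 / (library_size * width_bp), with the library size
    taken as the sample's row sum.  A sample with zero total counts is an
    error (its normalization is undefined).
    """
    widths = np.asarray(region_widths, dtype=float)
    if (widths <= 0).any():
        raise ValueError("region widths must be > 0")
    if widths.size != raw_counts.shape[1]:
        raise ValueError("one width per region required")
    counts = raw_counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("raw counts must be >= 0")
    lib = counts.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"zero library size for sample(s): {list(raw_counts.index[zero])}"
        )
    norm = counts * 1e9 / (lib[:, None] * widths[None, :])
    return SignalMatrix(
        values=pd.DataFrame(norm, index=raw_counts.index, columns=raw_counts.columns),
        library_size=pd.Series(lib, index=raw_counts.index, name="library_size"),
    )


def _welch_arrays(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t over columns of two groups; returns (t, p)."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate columns: zero variance in both groups
    degen = se2 == 0
    equal = degen & (m1 == m2)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    unequal = degen & (m1 != m2)
    t = np.where(unequal, np.where(m1 > m2, np.inf, -np.inf), t)
    p = np.where(unequal, 0.0, p)
    return t, p


def differential_regions(
    signal: SignalMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential signal over regions.

    Per region: log2 fold change of group means (with pseudocount), a Welch
    t test on log2(signal + pseudocount), and Benjamini-Hochberg adjustment
    across regions.  Calls are ``|log2FC| > lfc_min and q < q_max``, labelled
    by the enriched group.
    """
    g1, g2 = list(group1), list(group2)
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")
    x1 = signal.values.loc[g1].to_numpy(dtype=float)
    x2 = signal.values.loc[g2].to_numpy(dtype=float)
    log2fc = np.log2(x1.mean(axis=0) + pseudocount) - np.log2(
        x2.mean(axis=0) + pseudocount
    )
    t, p = _welch_arrays(np.log2(x1 + pseudocount), np.log2(x2 + pseudocount))
    q = stats.false_discovery_control(p, method="bh")
    called = (np.abs(log2fc) > lfc_min) & (q < q_max)
    direction = np.where(log2fc > 0, "group1", np.where(log2fc < 0, "group2", "none"))
    return pd.DataFrame(
        {
            "region": signal.values.columns,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": q,
            "called": called,
            "direction": direction,
        }
    ).set_index("region")


def continuum_score(
    signal: SignalMatrix,
    set1: Sequence,
    set2: Sequence,
    statistic: str = "mean",
) -> pd.Series:
    """Per-sample continuum score between two region sets.

    score = log10(signal intensity over set1) - log10(signal intensity over
    set2), where the intensity is the mean (default) or sum of normalized
    signal over the set.  A sample with zero intensity in either set gets a
    missing score and a warning.  Antisymmetric under swapping the sets.
    """
    if len(set1) == 0 or len(set2) == 0:
        raise ValueError("both region sets must be non-empty")
    agg = {"mean": np.mean, "sum": np.sum}[statistic]
    v1 = signal.values.loc[:, list(set1)].to_numpy(dtype=float)
    v2 = signal.values.loc[:, list(set2)].to_numpy(dtype=float)
    i1, i2 = agg(v1, axis=1), agg(v2, axis=1)
    bad = (i1 <= 0) | (i2 <= 0)
    if bad.any():
        warnings.warn(
            f"zero signal intensity for sample(s) "
            f"{list(signal.values.index[bad])}; scores set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(bad, np.nan, np.log10(i1) - np.log10(i2))
    return pd.Series(score, index=signal.values.index, name="continuum_score")


def quartile_assign(scores: pd.Series) -> pd.Series:
    """Rank-based quartile labels Q1..Q4; Q1 is the top quarter by score.

    Ties are broken by stable sample-id order.  Samples with missing scores
    receive a missing label; >= 4 finite scores are required.
    """
    finite = scores[np.isfinite(scores.to_numpy(dtype=float))]
    if len(finite) < 4:
        raise ValueError("need >= 4 finite scores for quartile assignment")
    order = sorted(finite.index, key=lambda i: (-finite[i], str(i)))
    n = len(order)
    labels = pd.Series(pd.NA, index=scores.index, dtype="object", name="quartile")
    for pos, sample in enumerate(order):
        labels[sample] = f"Q{pos * 4 // n + 1}"
    return labels


def tss_distance_ecdf_compare(
    peaks_a: IntervalSet,
    peaks_b: IntervalSet,
    genes: Sequence[GeneModel],
) -> tuple[ECDF, ECDF, float, float]:
    """Compare the TSS-distance distributions of two peak sets.

    Returns right-continuous ECDFs of the peak-to-closest-TSS distances of
    each set and the two-sample Kolmogorov-Smirnov statistic and p-value.
    """
    if not peaks_a or not peaks_b:
        raise ValueError("both peak sets must be non-empty")
    if not genes:
        raise ValueError("gene list must be non-empty")
    d_a = [d for d in closest_tss_distance(peaks_a, genes) if d is not None]
    d_b = [d for d in closest_tss_distance(peaks_b, genes) if d is not None]
    if not d_a or not d_b:
        raise ValueError("a peak set has no defined TSS distances")
    ks = stats.ks_2samp(d_a, d_b)
    return ECDF(d_a), ECDF(d_b), float(ks.statistic), float(ks.pvalue)
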