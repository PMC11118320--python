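"""Coverage-weighted DNA methylation summaries.

Fractional methylation of a region is the coverage-weighted mean of its CpG
methylation fractions, sum(f_i * c_i) / sum(c_i), restricted to CpGs passing
a minimum-coverage filter (default 3x, applied per CpG; a per-region total
alternative is available).  CpG-island shores are derived by flanking each
island by a fixed width (default 2 kb, the field-standard definition) and
the shore methylation gradient is summarized in distance bins from the
island edge.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    promoter_window,
)

CPG_COLUMNS = ["chrom", "pos", "fraction", "coverage"]


@dataclass(frozen=True)
class CpGCall:
    """A single (strand-collapsed) CpG methylation call."""

    chrom: str
    pos: int
    fraction: float
    coverage: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0,1], got {self.fraction}")
        if self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


def calls_frame(calls) -> pd.DataFrame:
    """Coerce a list of CpGCall or a DataFrame into the canonical frame."""
    if isinstance(calls, pd.DataFrame):
        missing = [c for c in CPG_COLUMNS if c not in calls.columns]
        if missing:
            raise ValueError(f"CpG frame missing columns {missing}")
        return calls[CPG_COLUMNS]
    return pd.DataFrame(
        [(c.chrom, c.pos, c.fraction, c.coverage) for c in calls],
        columns=CPG_COLUMNS,
    )


def read_bismark_coverage(path) -> pd.DataFrame:
    """Read a Bismark-style coverage file.

    Columns: chrom, start (1-based), end, methylation %, count_methylated,
    count_unmethylated.  Positions are converted to 0-based; fraction and
    coverage are derived from the counts (the percent column is ignored,
    avoiding rounding drift).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    cov = df["n_meth"] + df["n_unmeth"]
    with np.errstate(invalid="ignore"):
        frac = np.where(cov > 0, df["n_meth"] / cov.replace(0, np.nan), 0.0)
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64) - 1,
            "fraction": frac,
            "coverage": cov.astype(np.int64),
        }
    )


def write_bismark_coverage(calls: pd.DataFrame, path) -> None:
    """Write calls in Bismark coverage format (1-based positions)."""
    df = calls_frame(calls)
    n_meth = np.rint(df["fraction"] * df["coverage"]).astype(np.int64)
    n_unmeth = df["coverage"].astype(np.int64) - n_meth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(df["coverage"] > 0, 100.0 * n_meth / df["coverage"], 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(np.int64) + 1,
            "end": df["pos"].astype(np.int64) + 1,
            "pct": pct,
            "n_meth": n_meth,
            "n_unmeth": n_unmeth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def region_methylation(
    calls,
    region: GenomicInterval,
    min_cov: int = 3,
    per_region_total: bool = False,
) -> float:
    """Coverage-weighted fractional methylation of one region.

    Returns NaN ("missing") if no CpG qualifies.  With the default per-CpG
    filter, CpGs with coverage < ``min_cov`` are dropped before weighting;
    with ``per_region_total=True`` all region CpGs are pooled and the region
    is missing when their total coverage is below ``min_cov``.
    """
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    df = calls_frame(calls)
    sel = df[
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] < region.end)
    ]
    if not per_region_total:
        sel = sel[sel["coverage"] >= min_cov]
    total = sel["coverage"].sum()
    if len(sel) == 0 or total == 0:
        return float("nan")
    if per_region_total and total < min_cov:
        return float("nan")
    return float((sel["fraction"] * sel["coverage"]).sum() / total)


def _indexed_calls(df: pd.DataFrame, min_cov: int, per_region_total: bool):
    """Per-chrom sorted positions with prefix sums of c and f*c."""
    out = {}
    if not per_region_total:
        df = df[df["coverage"] >= min_cov]
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        c = sub["coverage"].to_numpy(dtype=float)
        fc = (sub["fraction"] * sub["coverage"]).to_numpy(dtype=float)
        out[chrom] = (
            pos,
            np.concatenate([[0.0], np.cumsum(c)]),
            np.concatenate([[0.0], np.cumsum(fc)]),
        )
    return out


def promoter_methylation_table(
    calls_by_sample: Mapping[str, object],
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    upstream: int = 2000,
    downstream: int = 2000,
    min_cov: int = 3,
    per_region_total: bool = False,
) -> pd.DataFrame:
    """Samples x genes matrix of promoter fractional methylation.

    Entries are coverage-weighted means over the strand-aware promoter
    window; missing (NaN) where no qualifying CpG falls in the window.
    """
    windows = [promoter_window(g, upstream, downstream, layout) for g in genes]
    gene_ids = [g.gene_id for g in genes]
    rows = {}
    for sample_id, calls in calls_by_sample.items():
        idx = _indexed_calls(calls_frame(calls), min_cov, per_region_total)
        vals = np.full(len(windows), np.nan)
        for i, w in enumerate(windows):
            if w.chrom not in idx:
                continue
            pos, cum_c, cum_fc = idx[w.chrom]
            lo = np.searchsorted(pos, w.start, side="left")
            hi = np.searchsorted(pos, w.end, side="left")
            c = cum_c[hi] - cum_c[lo]
            if hi == lo or c == 0:
                continue
            if per_region_total and c < min_cov:
                continue
            vals[i] = (cum_fc[hi] - cum_fc[lo]) / c
        rows[sample_id] = vals
    return pd.DataFrame(rows, index=gene_ids).T


@dataclass
class CGIAnnotation:
    """CpG islands with derived flanking shores (disjoint from islands)."""

    islands: IntervalSet
    shores: IntervalSet
    shore_bp: int = 2000


def derive_shores(
    islands: IntervalSet, layout: GenomeLayout, shore_bp: int = 2000
) -> CGIAnnotation:
    """Shores = (islands expanded by shore_bp on both sides) minus islands.

    Shores are clipped to chromosome bounds and merged where the flanks of
    nearby islands overlap; by construction they never intersect island
    territory.
    """
    if shore_bp <= 0:
        raise ValueError("shore_bp must be > 0")
    expanded = islands.expand(shore_bp, layout)
    shores = expanded.subtract(islands)
    return CGIAnnotation(islands=islands, shores=shores, shore_bp=shore_bp)


def shore_gradient(
    calls,
    annotation: CGIAnnotation,
    bin_bp: int = 200,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Weighted mean methylation of shore CpGs binned by island distance.

    Each shore CpG is assigned its distance to the nearest island edge (the
    first bp outside an island has distance 1) and the coverage-weighted
    mean methylation is computed per distance bin [0, bin_bp),
    [bin_bp, 2*bin_bp), ...  Returns an empty frame if no shore CpG passes
    the coverage filter.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    df = calls_frame(calls)
    df = df[df["coverage"] >= min_cov]
    records = []
    for chrom, sub in df.groupby("chrom", sort=False):
        shore_arr = annotation.shores.array(chrom)
        isl = annotation.islands.array(chrom)
        if not len(shore_arr):
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        in_shore = annotation.shores.overlaps_any(chrom, pos, pos + 1)
        if not in_shore.any():
            continue
        pos_s = pos[in_shore]
        frac = sub["fraction"].to_numpy(dtype=float)[in_shore]
        cov = sub["coverage"].to_numpy(dtype=float)[in_shore]
        if len(isl):
            starts, ends = isl[:, 0], isl[:, 1]
            idx = np.searchsorted(starts, pos_s, side="right")
            d_left = np.where(idx > 0, pos_s - ends[np.maximum(idx - 1, 0)] + 1,
                              np.iinfo(np.int64).max)
            d_right = np.where(idx < len(starts),
                               starts[np.minimum(idx, len(starts) - 1)] - pos_s,
                               np.iinfo(np.int64).max)
            dist = np.minimum(d_left, d_right)
        else:
            continue
        records.append(pd.DataFrame(
            {"dist": dist, "fraction": frac, "coverage": cov}
        ))
    if not records:
        return pd.DataFrame(
            columns=["bin_start", "bin_end", "mean_methylation", "n_cpg"]
        )
    allr = pd.concat(records, ignore_index=True)
    allr["bin"] = allr["dist"] // bin_bp
    grouped = allr.groupby("bin")
    out = pd.DataFrame(
        {
            "bin_start": grouped["bin"].first() * bin_bp,
            "bin_end": (grouped["bin"].first() + 1) * bin_bp,
            "mean_methylation": grouped.apply(
                lambda g: (g["fraction"] * g["coverage"]).sum() / g["coverage"].sum(),
                include_groups=False,
            ),
            "n_cpg": grouped.size(),
        }
    ).reset_index(drop=True)
    return out
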