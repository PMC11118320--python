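"""Independent brute-force oracles used across the test suite.

Everything here works on per-base boolean arrays or exhaustive enumeration,
deliberately ignoring the package's interval algebra so it can serve as an
independent check of it.
"""
from __future__ import annotations

import numpy as np

from epistate import IntervalSet


def bool_mask(iset: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Per-base occupancy mask of an IntervalSet on one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for iv in iset.intervals():
        if iv.chrom == chrom:
            mask[iv.start: min(iv.end, length)] = True
    return mask


def random_interval_set(
    rng: np.random.Generator,
    chrom: str = "chrT",
    length: int = 100_000,
    n: int = 40,
    max_len: int = 3000,
) -> IntervalSet:
    starts = rng.integers(0, length - 1, size=n)
    lens = rng.integers(1, max_len, size=n)
    ends = np.minimum(starts + lens, length)
    return IntervalSet(
        (chrom, int(s), int(e)) for s, e in zip(starts, ends) if s < e
    )


def brute_coverage_fraction(a, b, chrom, length) -> float:
    ma, mb = bool_mask(a, chrom, length), bool_mask(b, chrom, length)
    return (ma & mb).sum() / ma.sum()


def brute_bin_fractions(iset, chrom, length, bin_bp) -> np.ndarray:
    mask = bool_mask(iset, chrom, length)
    n_bins = -(-length // bin_bp)
    out = np.empty(n_bins)
    for i in range(n_bins):
        chunk = mask[i * bin_bp: min((i + 1) * bin_bp, length)]
        out[i] = chunk.mean()
    return out


def mask_to_intervals(mask: np.ndarray, chrom: str) -> IntervalSet:
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return IntervalSet((chrom, int(s), int(e)) for s, e in zip(starts, ends))


def brute_closest_tss(peaks, genes) -> list:
    """Exhaustive all-pairs minimum under d = max(0, start-tss, tss-end)."""
    out = []
    for iv in peaks.intervals():
        ds = [
            max(0, iv.start - g.tss, g.tss - iv.end)
            for g in genes
            if g.chrom == iv.chrom
        ]
        out.append(min(ds) if ds else None)
    return out
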