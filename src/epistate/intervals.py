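"""Genomic interval algebra.

All coordinates are 0-based, half-open (BED convention).  The central
container is :class:`IntervalSet`, a per-chromosome collection of sorted,
non-overlapping intervals ("territory").  Every peak-derived statistic in the
package (co-occupancy, bivalency, occupancy fractions, bin proportions) is
territory-based, so overlapping or bookended input intervals are merged on
normalization and per-interval labels are not retained.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "GenomeLayout",
    "promoter_window",
    "coverage_fraction",
    "closest_tss_distance",
    "bin_occupancy",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval ``chrom:[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based start (inclusive) and end (exclusive); ``0 <= start < end``.
    name : str, optional
        Free-text label (e.g. a peak or gene id).
    score : float, optional
        Signal or confidence score.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene annotation reduced to what promoter analytics need.

    The TSS is a single 0-based position; promoter windows are derived from
    it in a strand-aware fashion by :func:`promoter_window`.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


class GenomeLayout:
    """Ordered map of chromosome name to length in bp."""

    def __init__(self, lengths: Mapping[str, int]):
        self._lengths: dict[str, int] = {}
        for name, length in lengths.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._lengths[name] = length

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self):
        return self._lengths.items()

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeLayout({self._lengths!r})"


def _merge_array(arr: np.ndarray) -> np.ndarray:
    """Merge a (n, 2) start/end array into sorted disjoint intervals.

    Bookended intervals ([0,5) + [5,10)) are joined: the resulting territory
    is identical and the canonical form is unique.
    """
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    out = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        s, e = int(s), int(e)
        if s <= cur_e:  # overlap or touch
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


class IntervalSet:
    """Normalized per-chromosome interval territory.

    Invariants (established on construction): within each chromosome the
    intervals are sorted by start, non-overlapping and non-bookended.
    ``total_bp`` is therefore invariant under input record order and under
    re-normalization.
    """

    def __init__(self, intervals: Iterable = ()):  # intervals: GenomicInterval or (chrom, start, end)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv[0], int(iv[1]), int(iv[2])
                if not chrom:
                    raise ValueError("chrom must be non-empty")
                if start < 0 or start >= end:
                    raise ValueError(f"bad interval [{start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._data: dict[str, np.ndarray] = {}
        for chrom in sorted(by_chrom):
            self._data[chrom] = _merge_array(
                np.asarray(by_chrom[chrom], dtype=np.int64)
            )

    @classmethod
    def _from_arrays(cls, data: Mapping[str, np.ndarray]) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._data = {
            chrom: np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            for chrom, arr in sorted(data.items())
            if len(arr)
        }
        return obj

    # -- introspection -----------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def array(self, chrom: str) -> np.ndarray:
        """(n, 2) start/end array for ``chrom`` (empty if absent)."""
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> Iterator[GenomicInterval]:
        """Iterate intervals in canonical order (chrom name, then start)."""
        for chrom, arr in self._data.items():
            for s, e in arr:
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self._data[c], other._data[c]) for c in self._data
        )

    def __repr__(self) -> str:
        return f"IntervalSet(<{len(self)} intervals, {self.total_bp} bp>)"

    @property
    def total_bp(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values())
        )

    # -- set algebra -------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom in sorted(set(self.chroms) | set(other.chroms)):
            merged = np.vstack([self.array(chrom), other.array(chrom)])
            data[chrom] = _merge_array(merged)
        return IntervalSet._from_arrays(data)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom in self.chroms:
            a, b = self.array(chrom), other.array(chrom)
            if not len(a) or not len(b):
                continue
            out = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return IntervalSet._from_arrays(data)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom in self.chroms:
            a, b = self.array(chrom), other.array(chrom)
            if not len(b):
                data[chrom] = a.copy()
                continue
            out = []
            for s, e in a:
                cur = int(s)
                k = int(np.searchsorted(b[:, 1], cur, side="right"))
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        out.append((cur, int(b[k, 0])))
                    cur = max(cur, int(b[k, 1]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out.append((cur, int(e)))
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return IntervalSet._from_arrays(data)

    def expand(self, pad: int, layout: GenomeLayout) -> "IntervalSet":
        """Grow every interval by ``pad`` bp on both sides, clipped to the
        chromosome bounds, re-merging any resulting overlaps."""
        if pad < 0:
            raise ValueError("pad must be >= 0")
        data = {}
        for chrom in self.chroms:
            if chrom not in layout:
                raise KeyError(f"chromosome {chrom!r} not in layout")
            arr = self.array(chrom).copy()
            arr[:, 0] = np.maximum(arr[:, 0] - pad, 0)
            arr[:, 1] = np.minimum(arr[:, 1] + pad, layout[chrom])
            data[chrom] = _merge_array(arr)
        return IntervalSet._from_arrays(data)

    def restrict(self, chroms: Sequence[str]) -> "IntervalSet":
        keep = set(chroms)
        return IntervalSet._from_arrays(
            {c: a for c, a in self._data.items() if c in keep}
        )

    # -- vectorized queries ------------------------------------------------

    def _covered_upto(self, chrom: str, xs: np.ndarray) -> np.ndarray:
        """Territory bp in [0, x) for each x, via prefix sums."""
        arr = self.array(chrom)
        xs = np.asarray(xs, dtype=np.int64)
        if not len(arr):
            return np.zeros(xs.shape, dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
        cum = np.concatenate([[0], np.cumsum(ends - starts)])
        idx = np.searchsorted(starts, xs, side="right")
        full = cum[idx]
        prev = np.maximum(idx - 1, 0)
        overshoot = np.where(idx > 0, np.maximum(ends[prev] - xs, 0), 0)
        return full - overshoot

    def overlap_bp(self, chrom: str, starts, ends) -> np.ndarray:
        """Territory bp overlapping each query interval [start, end)."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        return self._covered_upto(chrom, ends) - self._covered_upto(chrom, starts)

    def overlaps_any(self, chrom: str, starts, ends) -> np.ndarray:
        """Boolean array: does each query overlap >= 1 bp of territory?"""
        return self.overlap_bp(chrom, starts, ends) > 0


def promoter_window(
    gene: GeneModel, upstream: int, downstream: int, layout: GenomeLayout
) -> GenomicInterval:
    """Strand-aware promoter window around a TSS, clipped to the chromosome.

    For a + strand gene the window is ``[tss - upstream, tss + downstream)``;
    for a - strand gene it is mirrored: ``[tss - downstream, tss + upstream)``.

    Raises
    ------
    ValueError
        If the window falls entirely outside the chromosome or has zero
        width after clipping.
    KeyError
        If the gene's chromosome is not in the layout.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if gene.chrom not in layout:
        raise KeyError(f"chromosome {gene.chrom!r} not in layout")
    length = layout[gene.chrom]
    if gene.strand == "+":
        s, e = gene.tss - upstream, gene.tss + downstream
    else:
        s, e = gene.tss - downstream, gene.tss + upstream
    if e <= 0 or s >= length:
        raise ValueError(
            f"promoter window for {gene.gene_id} lies outside {gene.chrom}"
        )
    s, e = max(s, 0), min(e, length)
    if s >= e:
        raise ValueError(
            f"promoter window for {gene.gene_id} has zero width after clipping"
        )
    return GenomicInterval(gene.chrom, s, e, name=gene.gene_id)


def coverage_fraction(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of ``a``'s territory covered by ``b``'s territory.

    This is the quantity behind mark co-occupancy summaries: e.g. the
    fraction of genome-wide H2AK119Ub1 occupancy overlapping another
    histone mark.
    """
    denom = a.total_bp
    if denom == 0:
        raise ValueError("coverage fraction undefined for an empty set")
    return a.intersect(b).total_bp / denom


def closest_tss_distance(
    peaks: IntervalSet, genes: Sequence[GeneModel]
) -> list[int | None]:
    """Distance in bp from each peak to the closest TSS on its chromosome.

    Convention: 0 for any overlap or bookended touch, otherwise the gap in
    bp, i.e. ``d = max(0, start - tss, tss - end)`` minimized over TSSs.
    Peaks on chromosomes without any TSS yield ``None``.  Output order is
    the canonical peak order (chromosome name, then start).
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {
        c: np.asarray(sorted(v), dtype=np.int64) for c, v in tss_by_chrom.items()
    }
    out: list[int | None] = []
    for chrom in peaks.chroms:
        arr = peaks.array(chrom)
        tss = tss_by_chrom.get(chrom)
        if tss is None or not len(tss):
            out.extend([None] * len(arr))
            continue
        for s, e in arr:
            lo = int(np.searchsorted(tss, s))
            hi = int(np.searchsorted(tss, e))
            cand = tss[max(lo - 1, 0): min(hi + 1, len(tss))]
            d = np.maximum(0, np.maximum(s - cand, cand - e)).min()
            out.append(int(d))
    return out


def bin_occupancy(
    peaks: IntervalSet,
    layout: GenomeLayout,
    bin_bp: int,
    chroms: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-bin fraction of each fixed-width genomic bin covered by peaks.

    The genome is tiled by ``bin_bp`` windows per chromosome; the value of a
    bin is the proportion of its bp covered by peak territory.  The last bin
    of a chromosome may be short and is normalized by its actual width.
    ``chroms`` restricts the tiling (e.g. to autosomes); by default every
    chromosome in the layout is binned.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    use = list(chroms) if chroms is not None else layout.chroms
    result: dict[str, np.ndarray] = {}
    for chrom in use:
        length = layout[chrom]
        n_bins = -(-length // bin_bp)  # ceil
        cov = np.zeros(n_bins, dtype=np.float64)
        for s, e in peaks.array(chrom):
            s, e = max(int(s), 0), min(int(e), length)
            if s >= e:
                continue
            first, last = s // bin_bp, (e - 1) // bin_bp
            if first == last:
                cov[first] += e - s
            else:
                cov[first] += (first + 1) * bin_bp - s
                cov[last] += e - last * bin_bp
                cov[first + 1: last] += bin_bp
        widths = np.full(n_bins, bin_bp, dtype=np.float64)
        widths[-1] = length - (n_bins - 1) * bin_bp
        result[chrom] = cov / widths
    return result
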