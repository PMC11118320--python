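"""Promoter chromatin-state calling and histone-mark co-occupancy.

A promoter is classified per sample from the overlap of its window with
H3K4me3 and H3K27me3 peak territory:

* ``bivalent`` -- >= 1 bp overlap with both marks,
* ``active``   -- H3K4me3 only,
* ``repressed`` -- H3K27me3 only,
* ``unmarked`` -- neither.

Where H2AK119Ub1 (PRC1-deposited ubiquitination) was profiled, each promoter
additionally carries a boolean co-marking flag, supporting stratified
summaries of polycomb behaviour at fusion-target versus other promoters.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GeneModel,
    GenomeLayout,
    IntervalSet,
    coverage_fraction,
    promoter_window,
)

MARK_H3K4ME3 = "H3K4me3"
MARK_H3K27ME3 = "H3K27me3"
MARK_UB = "H2AK119Ub1"


class PromoterState(str, enum.Enum):
    ACTIVE = "active"
    BIVALENT = "bivalent"
    REPRESSED = "repressed"
    UNMARKED = "unmarked"


STATE_ORDER = [s.value for s in PromoterState]


@dataclass
class MarkSet:
    """Per-sample compendium of histone-mark peak territories."""

    sample_id: str
    marks: dict[str, IntervalSet] = field(default_factory=dict)

    def require(self, mark: str) -> IntervalSet:
        if mark not in self.marks:
            raise KeyError(
                f"mark {mark!r} not profiled for sample {self.sample_id!r}"
            )
        return self.marks[mark]

    @property
    def mark_names(self) -> list[str]:
        return list(self.marks)


@dataclass
class PromoterStateTable:
    """Samples x genes matrix of promoter chromatin states.

    ``states`` holds the state strings; ``ub`` holds the H2AK119Ub1 co-marking
    flag for the subset of samples where that mark was profiled (rows absent
    for unprofiled samples).  For every sample the four state counts sum to
    the size of the gene universe.
    """

    states: pd.DataFrame
    ub: pd.DataFrame | None = None
    upstream: int = 2000
    downstream: int = 2000

    @property
    def samples(self) -> list[str]:
        return list(self.states.index)

    @property
    def genes(self) -> list[str]:
        return list(self.states.columns)

    def state_counts(self) -> pd.DataFrame:
        """Per-sample counts of each of the four states."""
        counts = pd.DataFrame(
            0, index=self.states.index, columns=STATE_ORDER, dtype=int
        )
        for state in STATE_ORDER:
            counts[state] = (self.states == state).sum(axis=1)
        return counts

    def to_long(self) -> pd.DataFrame:
        long = self.states.stack().rename("state").reset_index()
        long.columns = ["sample", "gene", "state"]
        if self.ub is not None:
            ub_long = self.ub.stack().rename("ub").reset_index()
            ub_long.columns = ["sample", "gene", "ub"]
            long = long.merge(ub_long, on=["sample", "gene"], how="left")
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame, **kwargs) -> "PromoterStateTable":
        states = long.pivot(index="sample", columns="gene", values="state")
        ub = None
        if "ub" in long.columns:
            ub_w = long.pivot(index="sample", columns="gene", values="ub")
            ub_w = ub_w.dropna(how="all")
            if len(ub_w):
                ub = ub_w.astype(bool)
        return cls(states=states, ub=ub, **kwargs)


def call_bivalent_regions(k4: IntervalSet, k27: IntervalSet) -> IntervalSet:
    """Bivalent territory: bp intersection of H3K4me3 and H3K27me3 peaks."""
    return k4.intersect(k27)


def _window_arrays(
    genes: Sequence[GeneModel],
    upstream: int,
    downstream: int,
    layout: GenomeLayout,
) -> dict[str, tuple[list[int], np.ndarray, np.ndarray]]:
    """Group promoter windows by chromosome, keeping gene order indices."""
    per_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
    for i, g in enumerate(genes):
        w = promoter_window(g, upstream, downstream, layout)
        idxs, starts, ends = per_chrom.setdefault(g.chrom, ([], [], []))
        idxs.append(i)
        starts.append(w.start)
        ends.append(w.end)
    return {
        c: (idxs, np.asarray(ss, dtype=np.int64), np.asarray(ee, dtype=np.int64))
        for c, (idxs, ss, ee) in per_chrom.items()
    }


def _windows_overlap(
    iset: IntervalSet,
    windows: Mapping[str, tuple[list[int], np.ndarray, np.ndarray]],
    n_genes: int,
) -> np.ndarray:
    hit = np.zeros(n_genes, dtype=bool)
    for chrom, (idxs, starts, ends) in windows.items():
        hit[np.asarray(idxs)] = iset.overlaps_any(chrom, starts, ends)
    return hit


def classify_promoter_states(
    sample: MarkSet,
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    upstream: int = 2000,
    downstream: int = 2000,
) -> tuple[pd.Series, pd.Series | None]:
    """Classify every promoter of one sample; returns (states, ub or None).

    Overlap means >= 1 bp between the strand-aware promoter window and the
    mark's peak territory (bedtools-intersect default semantics).
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    k4 = sample.require(MARK_H3K4ME3)
    k27 = sample.require(MARK_H3K27ME3)
    windows = _window_arrays(genes, upstream, downstream, layout)
    n = len(genes)
    has_k4 = _windows_overlap(k4, windows, n)
    has_k27 = _windows_overlap(k27, windows, n)
    state = np.select(
        [has_k4 & has_k27, has_k4, has_k27],
        [
            PromoterState.BIVALENT.value,
            PromoterState.ACTIVE.value,
            PromoterState.REPRESSED.value,
        ],
        default=PromoterState.UNMARKED.value,
    )
    gene_ids = [g.gene_id for g in genes]
    states = pd.Series(state, index=gene_ids, name=sample.sample_id)
    ub = None
    if MARK_UB in sample.marks:
        has_ub = _windows_overlap(sample.marks[MARK_UB], windows, n)
        ub = pd.Series(has_ub, index=gene_ids, name=sample.sample_id)
    return states, ub


def build_state_table(
    cohort: Iterable[MarkSet],
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    upstream: int = 2000,
    downstream: int = 2000,
) -> PromoterStateTable:
    """Run :func:`classify_promoter_states` across a cohort of samples."""
    state_rows, ub_rows = {}, {}
    for sample in cohort:
        states, ub = classify_promoter_states(
            sample, genes, layout, upstream=upstream, downstream=downstream
        )
        state_rows[sample.sample_id] = states
        if ub is not None:
            ub_rows[sample.sample_id] = ub
    states_df = pd.DataFrame(state_rows).T
    ub_df = pd.DataFrame(ub_rows).T if ub_rows else None
    return PromoterStateTable(
        states=states_df, ub=ub_df, upstream=upstream, downstream=downstream
    )


def cooccupancy_matrix(
    sample: MarkSet, anchor: str, mode: str = "bp"
) -> dict[str, float]:
    """Fraction of the anchor mark's occupancy overlapped by each other mark.

    ``mode='bp'`` (default) computes fractions over peak territory bp;
    ``mode='count'`` computes the fraction of anchor peaks that touch >= 1
    peak of the other mark.  The anchor-vs-anchor entry is reported as 1.
    """
    if mode not in ("bp", "count"):
        raise ValueError("mode must be 'bp' or 'count'")
    anchor_set = sample.require(anchor)
    if anchor_set.total_bp == 0:
        raise ValueError(
            f"anchor mark {anchor!r} has empty territory in {sample.sample_id!r}"
        )
    out: dict[str, float] = {}
    for mark, iset in sample.marks.items():
        if mark == anchor:
            out[mark] = 1.0
        elif mode == "bp":
            out[mark] = coverage_fraction(anchor_set, iset)
        else:
            hits = 0
            for chrom in anchor_set.chroms:
                arr = anchor_set.array(chrom)
                if len(arr):
                    hits += int(iset.overlaps_any(chrom, arr[:, 0], arr[:, 1]).sum())
            out[mark] = hits / len(anchor_set)
    return out


def ub_stratified_fractions(
    table: PromoterStateTable, sample_id: str, targets: Iterable[str]
) -> dict[str, dict]:
    """Partition promoters into fusion-target vs other, summarizing
    H2AK119Ub1 co-marking and its split across chromatin states.

    For each group the ``states`` sub-fractions (computed over the group's
    promoter count) sum exactly to the group's ``ub_fraction``.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("target gene set must be non-empty")
    if table.ub is None or sample_id not in table.ub.index:
        raise ValueError(f"H2AK119Ub1 flags not defined for sample {sample_id!r}")
    universe = set(table.genes)
    unknown = targets - universe
    if unknown:
        raise ValueError(f"target genes outside the gene universe: {sorted(unknown)[:5]}")
    states = table.states.loc[sample_id]
    ub = table.ub.loc[sample_id].astype(bool)
    result = {}
    for label, members in (
        ("target", [g for g in table.genes if g in targets]),
        ("nontarget", [g for g in table.genes if g not in targets]),
    ):
        n = len(members)
        sub_states = states[members]
        sub_ub = ub[members]
        ub_frac = float(sub_ub.mean()) if n else float("nan")
        shares = {
            state: float((sub_ub & (sub_states == state)).sum()) / n if n else float("nan")
            for state in STATE_ORDER
        }
        result[label] = {"n": n, "ub_fraction": ub_frac, "states": shares}
    return result


def group_mean_contrast(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t test (Welch-Satterthwaite df), two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
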