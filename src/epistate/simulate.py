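"""Synthetic multi-omics cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes, so every stage is testable without any data download:

* per-sample histone-mark peak compendia with planted promoter-state
  mixtures (active / bivalent / repressed / unmarked) and H2AK119Ub1
  co-marking,
* a directional bivalent-to-active continuum: each sample carries a planted
  bivalent-promoter count, and unselected "pool" promoters resolve to the
  active state with probability ``resolution_strength``, inducing the
  negative bivalent/active count coupling observed in tumor cohorts,
* survival times exponentially distributed with the hazard multiplied by
  ``hazard_ratio`` for the planted high-bivalency group, with uniform
  censoring,
* an enhancer signal matrix blending two group archetypes continuously per
  sample,
* CGI/shore-structured methylomes: hypomethylated islands, a linear
  methylation ramp across the shores, high background,
* an expression matrix in which active promoters are more expressed and a
  planted set of "switch" genes is bivalent in bivH samples, active and
  upregulated in bivL samples.

Every draw flows from a single seed through a fixed generator-splitting
scheme (``numpy.random.SeedSequence.spawn``), one child stream per stage, so
stage-level outputs are independently reproducible.

Genome layout convention: the first 80% of every chromosome is the genic
zone holding promoters; the remaining 20% is partitioned into intergenic
regulatory sites (peak co-occupancy structure), CpG islands, and candidate
enhancer regions.  Promoter peaks are clipped so that a peak planted at one
TSS can never reach a neighboring promoter window, which keeps the emitted
peak files exactly consistent with the ground-truth state table.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GeneModel, GenomeLayout, GenomicInterval, IntervalSet
from .io import ensure_dir, write_gene_table, write_genome_layout, write_intervals
from .methylation import write_bismark_coverage
from .prognosis import GROUP_HIGH, GROUP_LOW
from .states import (
    MARK_H3K27ME3,
    MARK_H3K4ME3,
    MARK_UB,
    MarkSet,
    PromoterState,
    PromoterStateTable,
)
from .survival import SurvivalRecord, write_survival_table

ALL_MARKS = [
    "H3K4me3", "H3K27me3", "H2AK119Ub1", "H3K27ac",
    "H3K4me1", "H3K36me3", "H3K36me2", "H3K9me3",
]

_DEFAULT_WIDTH_MEDIANS = {
    "H3K4me3": 700, "H3K27me3": 2500, "H2AK119Ub1": 2500, "H3K27ac": 800,
    "H3K4me1": 900, "H3K36me3": 2000, "H3K36me2": 2500, "H3K9me3": 2500,
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_samples: int = 40
    chrom_lengths: dict = field(
        default_factory=lambda: {f"chr{i}": 5_000_000 for i in range(1, 5)}
    )
    n_genes: int = 2000
    # promoter-state mixture
    p_active: float = 0.60
    p_repressed: float = 0.15
    p_unmarked: float = 0.25
    biv_pool_fraction: float = 0.25
    biv_low_range: tuple = (120, 200)
    biv_high_range: tuple = (380, 460)
    n_switch_genes: int = 50
    resolution_strength: float = 1.0
    # H2AK119Ub1 co-marking
    ub_profiled_fraction: float = 0.75
    p_ub_by_state: dict = field(
        default_factory=lambda: {
            "bivalent": 0.8, "active": 0.45, "repressed": 0.3, "unmarked": 0.05,
        }
    )
    # survival
    hazard_ratio: float = 4.0
    baseline_hazard: float = 0.01  # events per month in the bivL group
    censoring_fraction: float = 0.2
    # enhancer continuum
    n_regions: int = 500
    n_group_specific: int = 50  # per group
    region_width: int = 1000
    log10_separation: float = 2.0
    signal_base_mean: float = 100.0
    # methylome
    n_islands: int = 60
    island_width: int = 1000
    shore_bp: int = 2000
    island_methylation: float = 0.10
    background_methylation: float = 0.80
    methylation_noise_sd: float = 0.05
    cpg_spacing_island: int = 20
    cpg_spacing_shore: int = 150
    n_background_cpgs: int = 2000
    coverage_mean: float = 30.0
    # expression
    expr_base_log2: float = 5.0
    expr_gene_sd: float = 1.0
    active_bonus_log2: float = 1.0
    switch_log2fc: float = 2.0
    expr_noise_sd: float = 0.5
    # peak geometry
    peak_width_medians: dict = field(
        default_factory=lambda: dict(_DEFAULT_WIDTH_MEDIANS)
    )
    peak_width_sigma: float = 0.35
    k4_broad_multiplier: float = 1.0
    promoter_margin: int = 5000
    genic_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if not 0 <= self.resolution_strength <= 1:
            raise ValueError("resolution_strength must be in [0, 1]")
        probs = self.p_active + self.p_repressed + self.p_unmarked
        if abs(probs - 1.0) > 1e-9:
            raise ValueError("base state probabilities must sum to 1")
        pool = self.pool_size
        if self.n_switch_genes > pool:
            raise ValueError(
                "infeasible spec: more planted switch genes than pool genes"
            )
        if self.biv_high_range[0] < self.n_switch_genes:
            raise ValueError(
                "infeasible spec: bivH counts below the planted switch-gene count"
            )
        if self.biv_high_range[1] - self.n_switch_genes > pool - self.n_switch_genes:
            raise ValueError("infeasible spec: bivH counts exceed the bivalent pool")
        if self.biv_low_range[1] > pool - self.n_switch_genes:
            raise ValueError("infeasible spec: bivL counts exceed the bivalent pool")
        if 2 * self.n_group_specific > self.n_regions:
            raise ValueError("infeasible spec: group-specific regions exceed n_regions")

    @property
    def pool_size(self) -> int:
        return int(round(self.biv_pool_fraction * self.n_genes))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("biv_low_range", "biv_high_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["biv_low_range"] = list(self.biv_low_range)
        data["biv_high_range"] = list(self.biv_high_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticCohort:
    """A simulated cohort together with its planted ground truth."""

    spec: CohortSpec
    layout: GenomeLayout
    genes: list[GeneModel]
    samples: list[str]
    groups: pd.Series  # planted bivH/bivL labels
    mark_sets: dict[str, MarkSet]
    truth_states: PromoterStateTable
    survival: list[SurvivalRecord]
    signal_counts: pd.DataFrame  # samples x regions, raw counts
    regions: list[GenomicInterval]
    region_labels: pd.Series  # group1 / group2 / shared per region
    blend: pd.Series  # per-sample archetype blend t in [0, 1]
    methylation: dict[str, pd.DataFrame]
    islands: IntervalSet
    expression: pd.DataFrame  # samples x genes
    switch_genes: list[str]


# ---------------------------------------------------------------------------
# survival component (reused standalone for calibration studies)

def simulate_survival(
    n: int,
    hazard_ratio: float,
    baseline_hazard: float,
    censoring_fraction: float,
    rng: np.random.Generator,
    high: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential survival with a group hazard ratio and uniform censoring.

    Returns (times, events, high) where ``high`` marks the elevated-hazard
    group (assigned to a random half when not supplied).  A censored subject
    is observed at a uniform time before its latent event time, so the
    expected censoring fraction equals ``censoring_fraction`` in both groups.
    """
    if high is None:
        high = np.zeros(n, dtype=bool)
        high[: n // 2] = True
        rng.shuffle(high)
    rate = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < censoring_fraction
    t_obs = np.where(censored, rng.uniform(0, t_event), t_event)
    return t_obs, (~censored).astype(int), high


def simulate_planted_signal(
    seed: int,
    n_regions: int = 2000,
    n_planted: int = 20,
    log2fc: float = 3.0,
    n_per_group: int = 10,
    base_mean: float = 500.0,
    sigma_log2: float = 0.5,
) -> tuple[pd.DataFrame, list[str], list[str], list[int]]:
    """Two-group signal matrix with planted differential regions.

    Signal is log-normally distributed around a per-region base mean; the
    planted regions are shifted by ``log2fc`` in group 1.  Returns the raw
    signal frame, the two sample-id groups, and the planted region indices.
    """
    rng = np.random.default_rng(seed)
    base = base_mean * 2.0 ** rng.normal(0, 1.0, size=n_regions)
    n = 2 * n_per_group
    noise = rng.normal(0, sigma_log2, size=(n, n_regions))
    log2sig = np.log2(base)[None, :] + noise
    planted = list(rng.choice(n_regions, size=n_planted, replace=False))
    log2sig[:n_per_group, planted] += log2fc
    samples = [f"A{i:02d}" for i in range(n_per_group)] + [
        f"B{i:02d}" for i in range(n_per_group)
    ]
    df = pd.DataFrame(
        2.0**log2sig, index=samples, columns=[f"region{j}" for j in range(n_regions)]
    )
    return df, samples[:n_per_group], samples[n_per_group:], sorted(int(i) for i in planted)


# ---------------------------------------------------------------------------
# cohort assembly

def _gene_positions(spec: CohortSpec) -> tuple[list[GeneModel], int]:
    """Evenly spaced TSSs in the genic zone; returns genes and the spacing."""
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(spec.n_genes * lengths / lengths.sum()).astype(int)
    while counts.sum() < spec.n_genes:
        counts[int(np.argmax(lengths / (counts + 1)))] += 1
    genes: list[GeneModel] = []
    min_spacing = np.inf
    idx = 0
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        genic_end = int(spec.genic_fraction * spec.chrom_lengths[chrom])
        span = genic_end - 2 * spec.promoter_margin
        spacing = span / n_c
        if spacing < 2600:
            raise ValueError(
                "infeasible spec: too many genes for the genic zone "
                f"on {chrom} (spacing {spacing:.0f} bp)"
            )
        min_spacing = min(min_spacing, spacing)
        for j in range(n_c):
            tss = spec.promoter_margin + int(round(j * spacing))
            genes.append(
                GeneModel(
                    gene_id=f"G{idx:05d}",
                    chrom=chrom,
                    strand="+" if idx % 2 == 0 else "-",
                    tss=tss,
                )
            )
            idx += 1
    return genes, int(min_spacing)


def _draw_half_widths(
    rng: np.random.Generator, mark: str, n: int, spec: CohortSpec, h_max: int
) -> np.ndarray:
    median = spec.peak_width_medians[mark]
    if mark == MARK_H3K4ME3:
        median = median * spec.k4_broad_multiplier
    widths = median * np.exp(rng.normal(0, spec.peak_width_sigma, size=n))
    return np.clip((widths / 2).astype(np.int64), 50, h_max)


def _intergenic_slices(spec: CohortSpec, chrom: str) -> dict[str, tuple[int, int]]:
    length = spec.chrom_lengths[chrom]
    start = int(spec.genic_fraction * length)
    width = length - start
    a = start + int(0.4 * width)
    b = start + int(0.7 * width)
    return {"sites": (start, a), "islands": (a, b), "regions": (b, length)}


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort under ``spec``; fully seeded."""
    streams = np.random.SeedSequence(spec.seed).spawn(8)
    rng_states, rng_peaks, rng_ub, rng_surv, rng_signal, rng_meth, rng_expr, rng_cov = (
        np.random.default_rng(s) for s in streams
    )

    layout = GenomeLayout(spec.chrom_lengths)
    genes, spacing = _gene_positions(spec)
    h_max = min(4000, spacing - 2001)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(genes)
    pool = spec.pool_size
    n_switch = spec.n_switch_genes

    # planted groups and bivalency counts ---------------------------------
    high = np.zeros(spec.n_samples, dtype=bool)
    high[: spec.n_samples // 2] = True
    rng_states.shuffle(high)
    groups = pd.Series(
        np.where(high, GROUP_HIGH, GROUP_LOW), index=samples, name="group"
    )
    biv_counts = np.where(
        high,
        rng_states.integers(spec.biv_high_range[0], spec.biv_high_range[1] + 1,
                            size=spec.n_samples),
        rng_states.integers(spec.biv_low_range[0], spec.biv_low_range[1] + 1,
                            size=spec.n_samples),
    )

    # per-sample promoter states ------------------------------------------
    # gene indices: [0, n_switch) switch, [n_switch, pool) rest of bivalent
    # pool, [pool, n_genes) base genes with a fixed state mixture
    switch_idx = np.arange(n_switch)
    pool_rest = np.arange(n_switch, pool)
    base_idx = np.arange(pool, n_genes)
    state_codes = np.empty((spec.n_samples, n_genes), dtype="<U9")
    base_probs = [spec.p_active, spec.p_repressed, spec.p_unmarked]
    base_states = np.array(
        [PromoterState.ACTIVE.value, PromoterState.REPRESSED.value,
         PromoterState.UNMARKED.value]
    )
    for i, sample in enumerate(samples):
        state_codes[i, base_idx] = rng_states.choice(
            base_states, size=len(base_idx), p=base_probs
        )
        if high[i]:
            state_codes[i, switch_idx] = PromoterState.BIVALENT.value
            n_pool_biv = biv_counts[i] - n_switch
        else:
            state_codes[i, switch_idx] = PromoterState.ACTIVE.value
            n_pool_biv = biv_counts[i]
        chosen = rng_states.choice(pool_rest, size=n_pool_biv, replace=False)
        state_codes[i, pool_rest] = PromoterState.UNMARKED.value
        resolved = rng_states.random(len(pool_rest)) < spec.resolution_strength
        state_codes[i, pool_rest[resolved]] = PromoterState.ACTIVE.value
        state_codes[i, chosen] = PromoterState.BIVALENT.value
    states_df = pd.DataFrame(state_codes, index=samples, columns=gene_ids)

    # H2AK119Ub1 profiling subset and per-promoter flags -------------------
    n_ub = int(round(spec.ub_profiled_fraction * spec.n_samples))
    ub_samples = sorted(rng_ub.choice(spec.n_samples, size=n_ub, replace=False))
    ub_flags = {}
    for i in ub_samples:
        p = np.vectorize(spec.p_ub_by_state.get)(state_codes[i])
        ub_flags[samples[i]] = rng_ub.random(n_genes) < p.astype(float)
    ub_df = (
        pd.DataFrame(ub_flags, index=gene_ids).T if ub_flags else None
    )

    truth_states = PromoterStateTable(
        states=states_df, ub=ub_df, upstream=2000, downstream=2000
    )

    # peak emission --------------------------------------------------------
    tss = np.array([g.tss for g in genes], dtype=np.int64)
    chrom_of = np.array([g.chrom for g in genes])
    mark_sets: dict[str, MarkSet] = {}
    site_positions = []
    for chrom in layout.chroms:
        lo, hi = _intergenic_slices(spec, chrom)["sites"]
        centers = np.arange(lo + 5000, hi - 5000, 10_000)
        site_positions.extend((chrom, int(c)) for c in centers)
    p_site = {  # site occupancy probabilities (given / not given Ub present)
        "H3K27ac": (0.7, 0.3), "H3K4me1": (0.7, 0.3), "H3K4me3": (0.3, 0.1),
        "H3K27me3": (0.2, 0.2), "H3K36me3": (0.4, 0.4), "H3K36me2": (0.4, 0.4),
        "H3K9me3": (0.3, 0.3),
    }
    for i, sample in enumerate(samples):
        peaks: dict[str, list] = {m: [] for m in ALL_MARKS}
        st = state_codes[i]
        need_k4 = np.isin(st, [PromoterState.ACTIVE.value, PromoterState.BIVALENT.value])
        need_k27 = np.isin(st, [PromoterState.REPRESSED.value, PromoterState.BIVALENT.value])
        for mark, mask in ((MARK_H3K4ME3, need_k4), (MARK_H3K27ME3, need_k27)):
            idxs = np.flatnonzero(mask)
            h = _draw_half_widths(rng_peaks, mark, len(idxs), spec, h_max)
            for j, hw in zip(idxs, h):
                peaks[mark].append((chrom_of[j], tss[j] - hw, tss[j] + hw))
        # promoter-proximal active marks (no bearing on state truth)
        for mark, p_act in (("H3K27ac", 0.8), ("H3K4me1", 0.7)):
            idxs = np.flatnonzero(
                (st == PromoterState.ACTIVE.value)
                & (rng_peaks.random(n_genes) < p_act)
            )
            h = _draw_half_widths(rng_peaks, mark, len(idxs), spec, h_max)
            for j, hw in zip(idxs, h):
                peaks[mark].append((chrom_of[j], tss[j] - hw, tss[j] + hw))
        if sample in (ub_flags or {}):
            idxs = np.flatnonzero(ub_flags[sample])
            h = _draw_half_widths(rng_peaks, MARK_UB, len(idxs), spec, h_max)
            for j, hw in zip(idxs, h):
                peaks[MARK_UB].append((chrom_of[j], tss[j] - hw, tss[j] + hw))
        # intergenic regulatory sites with Ub/active co-occurrence
        for chrom, center in site_positions:
            has_ub = rng_peaks.random() < 0.5
            if has_ub and sample in (ub_flags or {}):
                hw = int(_draw_half_widths(rng_peaks, MARK_UB, 1, spec, 4000)[0])
                peaks[MARK_UB].append((chrom, center - hw, center + hw))
            for mark, (p_if_ub, p_else) in p_site.items():
                if rng_peaks.random() < (p_if_ub if has_ub else p_else):
                    hw = int(_draw_half_widths(rng_peaks, mark, 1, spec, 4000)[0])
                    peaks[mark].append((chrom, center - hw, center + hw))
        marks = {
            m: IntervalSet(ivs) for m, ivs in peaks.items()
            if ivs and (m != MARK_UB or sample in (ub_flags or {}))
        }
        mark_sets[sample] = MarkSet(sample_id=sample, marks=marks)

    # survival --------------------------------------------------------------
    times, events, _ = simulate_survival(
        spec.n_samples,
        spec.hazard_ratio,
        spec.baseline_hazard,
        spec.censoring_fraction,
        rng_surv,
        high=high,
    )
    sexes = rng_surv.choice(["F", "M"], size=spec.n_samples)
    fusions = rng_surv.choice(["SSX1", "SSX2"], size=spec.n_samples)
    locations = rng_surv.choice(
        ["axial", "proximal_extremity", "distal_extremity"], size=spec.n_samples
    )
    survival = [
        SurvivalRecord(
            sample_id=samples[i],
            time=round(float(times[i]), 3),
            event=int(events[i]),
            covariates={
                "sex": sexes[i],
                "fusion_variant": fusions[i],
                "location": locations[i],
                "bivalency_group": groups.iloc[i],
                "bivalency_count": int(biv_counts[i]),
            },
        )
        for i in range(spec.n_samples)
    ]

    # enhancer continuum -----------------------------------------------------
    regions: list[GenomicInterval] = []
    chroms = layout.chroms
    per_chrom = -(-spec.n_regions // len(chroms))
    for chrom in chroms:
        lo, hi = _intergenic_slices(spec, chrom)["regions"]
        step = spec.region_width + 1000
        n_fit = (hi - lo - 1000) // step
        if len(regions) < spec.n_regions and n_fit <= 0:
            raise ValueError("infeasible spec: enhancer zone too small")
        for j in range(min(per_chrom, n_fit)):
            if len(regions) >= spec.n_regions:
                break
            s = lo + 500 + j * step
            regions.append(GenomicInterval(chrom, s, s + spec.region_width,
                                           name=f"E{len(regions):04d}"))
    if len(regions) < spec.n_regions:
        raise ValueError("infeasible spec: enhancer zone too small for n_regions")
    labels = np.array(
        ["group1"] * spec.n_group_specific
        + ["group2"] * spec.n_group_specific
        + ["shared"] * (spec.n_regions - 2 * spec.n_group_specific)
    )
    region_ids = [r.name for r in regions]
    blend = rng_signal.random(spec.n_samples)  # 0 -> archetype 1, 1 -> archetype 2
    base_log10 = np.log10(
        spec.signal_base_mean * 2.0 ** rng_signal.normal(0, 0.5, size=spec.n_regions)
    )
    mean_log10 = np.tile(base_log10, (spec.n_samples, 1))
    mean_log10[:, labels == "group1"] += spec.log10_separation * (1 - blend)[:, None]
    mean_log10[:, labels == "group2"] += spec.log10_separation * blend[:, None]
    counts = rng_signal.poisson(10.0**mean_log10)
    signal_counts = pd.DataFrame(counts, index=samples, columns=region_ids)

    # methylome --------------------------------------------------------------
    island_list = []
    for chrom in chroms:
        lo, hi = _intergenic_slices(spec, chrom)["islands"]
        block = spec.island_width + 2 * spec.shore_bp + 1000
        n_fit = (hi - lo) // block
        for j in range(n_fit):
            s = lo + j * block + spec.shore_bp
            island_list.append((chrom, s, s + spec.island_width))
    if len(island_list) < spec.n_islands:
        raise ValueError("infeasible spec: island zone too small for n_islands")
    island_list = island_list[: spec.n_islands]
    islands = IntervalSet(island_list)
    cpg_chrom, cpg_pos, cpg_base = [], [], []
    delta = spec.background_methylation - spec.island_methylation
    for chrom, s, e in island_list:
        for p in range(s, e, spec.cpg_spacing_island):
            cpg_chrom.append(chrom)
            cpg_pos.append(p)
            cpg_base.append(spec.island_methylation)
        for d in range(spec.cpg_spacing_shore, spec.shore_bp,
                       spec.cpg_spacing_shore):
            level = spec.island_methylation + delta * d / spec.shore_bp
            for p in (s - d, e - 1 + d):
                cpg_chrom.append(chrom)
                cpg_pos.append(p)
                cpg_base.append(level)
    bg_per_chrom = -(-spec.n_background_cpgs // len(chroms))
    n_bg = 0
    for chrom in chroms:
        genic_end = int(spec.genic_fraction * spec.chrom_lengths[chrom])
        step = max(genic_end // (bg_per_chrom + 1), 1)
        for j in range(bg_per_chrom):
            if n_bg >= spec.n_background_cpgs:
                break
            cpg_chrom.append(chrom)
            cpg_pos.append(step // 2 + j * step)
            cpg_base.append(spec.background_methylation)
            n_bg += 1
    cpg_base = np.asarray(cpg_base)
    methylation: dict[str, pd.DataFrame] = {}
    for sample in samples:
        p = np.clip(
            cpg_base + rng_meth.normal(0, spec.methylation_noise_sd, len(cpg_base)),
            0.005, 0.995,
        )
        cov = np.maximum(rng_cov.poisson(spec.coverage_mean, len(cpg_base)), 1)
        n_meth = rng_meth.binomial(cov, p)
        methylation[sample] = pd.DataFrame(
            {
                "chrom": cpg_chrom,
                "pos": np.asarray(cpg_pos, dtype=np.int64),
                "fraction": n_meth / cov,
                "coverage": cov.astype(np.int64),
            }
        )

    # expression -------------------------------------------------------------
    gene_base = spec.expr_base_log2 + rng_expr.normal(0, spec.expr_gene_sd, n_genes)
    log2x = np.tile(gene_base, (spec.n_samples, 1))
    log2x += spec.active_bonus_log2 * (state_codes == PromoterState.ACTIVE.value)
    log2x[:, switch_idx] += spec.switch_log2fc * (~high)[:, None]
    log2x += rng_expr.normal(0, spec.expr_noise_sd, size=log2x.shape)
    expression = pd.DataFrame(2.0**log2x, index=samples, columns=gene_ids)

    return SyntheticCohort(
        spec=spec,
        layout=layout,
        genes=genes,
        samples=samples,
        groups=groups,
        mark_sets=mark_sets,
        truth_states=truth_states,
        survival=survival,
        signal_counts=signal_counts,
        regions=regions,
        region_labels=pd.Series(labels, index=region_ids, name="label"),
        blend=pd.Series(blend, index=samples, name="blend"),
        methylation=methylation,
        islands=islands,
        expression=expression,
        switch_genes=gene_ids[:n_switch],
    )


# ---------------------------------------------------------------------------
# emission

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def emit(cohort: SyntheticCohort, directory) -> Path:
    """Write the cohort as a plain-text file tree with a checksum manifest.

    Layout: ``peaks/<sample>/<mark>.bed``, ``genes.tsv``, ``layout.tsv``,
    ``survival.tsv``, ``signal_counts.tsv`` (regions x samples with BED-style
    coordinate columns), ``expression.tsv``, ``islands.bed``,
    ``methylation/<sample>.cov`` and ground-truth tables under ``truth/``.
    ``manifest.tsv`` lists every emitted file with its sha256.
    """
    root = ensure_dir(directory)
    written: list[Path] = []

    def note(p: Path) -> None:
        written.append(p.relative_to(root))

    write_gene_table(cohort.genes, root / "genes.tsv")
    note(root / "genes.tsv")
    write_genome_layout(cohort.layout, root / "layout.tsv")
    note(root / "layout.tsv")
    write_survival_table(cohort.survival, root / "survival.tsv")
    note(root / "survival.tsv")

    for sample in cohort.samples:
        sdir = ensure_dir(root / "peaks" / sample)
        for mark, iset in cohort.mark_sets[sample].marks.items():
            p = sdir / f"{mark}.bed"
            write_intervals(iset, p)
            note(p)

    sig = pd.DataFrame(
        {
            "chrom": [r.chrom for r in cohort.regions],
            "start": [r.start for r in cohort.regions],
            "end": [r.end for r in cohort.regions],
            "region": [r.name for r in cohort.regions],
        }
    )
    sig = pd.concat(
        [sig, cohort.signal_counts.T.reset_index(drop=True)], axis=1
    )
    sig.to_csv(root / "signal_counts.tsv", sep="\t", index=False)
    note(root / "signal_counts.tsv")

    cohort.expression.to_csv(
        root / "expression.tsv", sep="\t", index_label="sample_id",
        float_format="%.6g",
    )
    note(root / "expression.tsv")

    write_intervals(cohort.islands, root / "islands.bed")
    note(root / "islands.bed")

    mdir = ensure_dir(root / "methylation")
    for sample, calls in cohort.methylation.items():
        p = mdir / f"{sample}.cov"
        write_bismark_coverage(calls, p)
        note(p)

    tdir = ensure_dir(root / "truth")
    cohort.truth_states.to_long().to_csv(
        tdir / "promoter_states.tsv", sep="\t", index=False
    )
    note(tdir / "promoter_states.tsv")
    cohort.groups.to_frame().to_csv(tdir / "groups.tsv", sep="\t",
                                    index_label="sample_id")
    note(tdir / "groups.tsv")
    (tdir / "switch_genes.txt").write_text(
        "\n".join(cohort.switch_genes) + "\n"
    )
    note(tdir / "switch_genes.txt")
    cohort.region_labels.to_frame().to_csv(
        tdir / "region_labels.tsv", sep="\t", index_label="region"
    )
    note(tdir / "region_labels.tsv")
    cohort.blend.to_frame().to_csv(
        tdir / "blend.tsv", sep="\t", index_label="sample_id", float_format="%.6g"
    )
    note(tdir / "blend.tsv")

    with open(root / "manifest.tsv", "w") as fh:
        fh.write("path\tsha256\n")
        for rel in sorted(written, key=lambda p: str(p)):
            fh.write(f"{rel}\t{_sha256(root / rel)}\n")
    return root


def verify_manifest(directory) -> bool:
    """Re-hash every file listed in the manifest; True if all match."""
    root = Path(directory)
    manifest = pd.read_csv(root / "manifest.tsv", sep="\t")
    return all(
        _sha256(root / row["path"]) == row["sha256"]
        for _, row in manifest.iterrows()
    )


def load_mark_sets(directory) -> dict[str, MarkSet]:
    """Read an emitted ``peaks/`` tree back into per-sample MarkSets."""
    from .io import read_intervals

    root = Path(directory) / "peaks"
    out: dict[str, MarkSet] = {}
    for sdir in sorted(root.iterdir()):
        if not sdir.is_dir():
            continue
        marks = {
            bed.stem: read_intervals(bed) for bed in sorted(sdir.glob("*.bed"))
        }
        out[sdir.name] = MarkSet(sample_id=sdir.name, marks=marks)
    return out
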