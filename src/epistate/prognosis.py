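"""Prognostic bivalency analytics.

Tumors are stratified by their count of bivalently marked promoters into
bivalency-high (bivH) and bivalency-low (bivL) groups via a deterministic
variance-minimizing two-class split of the 1-D count distribution.  The
module also quantifies the directionality of bivalency resolution (the
correlation between bivalent and H3K4me3-only promoter counts across the
cohort), selects marker genes that switch from a bivalent to an expressed
active state between the groups, and trains a seeded random-forest proxy
classifier on marker expression so that bivalency group can be predicted
from expression alone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .states import PromoterState, PromoterStateTable, STATE_ORDER

GROUP_HIGH = "bivH"
GROUP_LOW = "bivL"


@dataclass
class BivalencyProfile:
    """Per-sample promoter-state counts with optional bivH/bivL grouping."""

    counts: pd.DataFrame  # columns: bivalent, active, repressed, unmarked
    groups: pd.Series | None = None  # sample -> bivH/bivL

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)


def bivalency_counts(table: PromoterStateTable) -> BivalencyProfile:
    """Tally promoter states per sample (no grouping yet)."""
    counts = table.state_counts()[STATE_ORDER]
    return BivalencyProfile(counts=counts)


def split_biv_groups(
    profile: BivalencyProfile, threshold: float | None = None
) -> BivalencyProfile:
    """Assign bivH/bivL groups from the bivalent-count distribution.

    Default: the two-class 1-D split minimizing total within-group variance
    of the sorted counts (Otsu / exact 2-means); the higher-mean class is
    bivH.  Ties between cut points resolve to the lowest cut; the result is
    deterministic and invariant to sample order.  A fixed ``threshold``
    overrides the data-driven split (count >= threshold -> bivH).
    """
    counts = profile.counts["bivalent"].astype(float)
    if len(counts) < 4 and threshold is None:
        raise ValueError("need >= 4 samples for a data-driven split")
    if threshold is not None:
        groups = pd.Series(
            np.where(counts >= threshold, GROUP_HIGH, GROUP_LOW),
            index=counts.index,
            name="group",
        )
        return BivalencyProfile(counts=profile.counts.copy(), groups=groups)
    if counts.nunique() == 1:
        raise ValueError("all bivalent counts identical; no split exists")
    order = np.argsort(counts.to_numpy(), kind="mergesort")
    x = counts.to_numpy()[order]
    n = len(x)
    best_k, best_ss = None, np.inf
    for k in range(1, n):
        left, right = x[:k], x[k:]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if ss < best_ss - 1e-12:
            best_ss, best_k = ss, k
    cut_value = x[best_k]  # lowest count in the upper class
    groups = pd.Series(
        np.where(counts >= cut_value, GROUP_HIGH, GROUP_LOW),
        index=counts.index,
        name="group",
    )
    return BivalencyProfile(counts=profile.counts.copy(), groups=groups)


def resolution_correlation(profile: BivalencyProfile) -> dict[str, float]:
    """Pearson correlation of bivalent count with H3K4me3-only and with
    H3K27me3-only counts across samples.

    A strongly negative bivalent-vs-active correlation indicates directional
    resolution of bivalency toward the active state.  Zero variance in a
    variable yields NaN.
    """
    if len(profile.counts) < 3:
        raise ValueError("need >= 3 samples")
    biv = profile.counts["bivalent"].to_numpy(dtype=float)
    out = {}
    for key, col in (("bivalent_vs_active", "active"),
                     ("bivalent_vs_repressed", "repressed")):
        other = profile.counts[col].to_numpy(dtype=float)
        if biv.std() == 0 or other.std() == 0:
            out[key] = float("nan")
        else:
            out[key] = float(stats.pearsonr(biv, other).statistic)
    return out


def select_marker_genes(
    table: PromoterStateTable,
    expression: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    k: int = 50,
    majority: float = 0.6,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank genes that switch from bivalent (bivH) to active (bivL).

    Eligibility: bivalent in >= ``majority`` of bivH samples AND active in
    >= ``majority`` of bivL samples.  Eligible genes are tested for
    differential expression between the groups (Welch t on
    log2(expression + pseudocount), BH across eligible genes); genes with
    q < ``q_max`` are ranked by \\|log2FC\\| and the top ``k`` returned.  If
    fewer than ``k`` qualify, all are returned with a warning.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    high = [s for s in table.samples if groups.get(s) == GROUP_HIGH]
    low = [s for s in table.samples if groups.get(s) == GROUP_LOW]
    if not high or not low:
        raise ValueError("both bivH and bivL groups must be non-empty")
    states = table.states
    biv_frac_high = (states.loc[high] == PromoterState.BIVALENT.value).mean(axis=0)
    act_frac_low = (states.loc[low] == PromoterState.ACTIVE.value).mean(axis=0)
    eligible = states.columns[(biv_frac_high >= majority) & (act_frac_low >= majority)]
    eligible = [g for g in eligible if g in expression.columns]
    if not eligible:
        warnings.warn("no eligible switch genes found", stacklevel=2)
        return pd.DataFrame(columns=["log2fc", "p", "q"])
    e_high = np.log2(expression.loc[high, eligible].to_numpy(dtype=float) + pseudocount)
    e_low = np.log2(expression.loc[low, eligible].to_numpy(dtype=float) + pseudocount)
    m_h, m_l = e_high.mean(axis=0), e_low.mean(axis=0)
    v_h, v_l = e_high.var(axis=0, ddof=1), e_low.var(axis=0, ddof=1)
    n_h, n_l = len(high), len(low)
    se2 = v_h / n_h + v_l / n_l
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m_h - m_l) / np.sqrt(se2)
        df = se2**2 / ((v_h / n_h) ** 2 / (n_h - 1) + (v_l / n_l) ** 2 / (n_l - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se2 == 0, np.where(m_h == m_l, 1.0, 0.0), p)
    q = stats.false_discovery_control(p, method="bh")
    log2fc = np.log2(
        expression.loc[high, eligible].mean(axis=0).to_numpy() + pseudocount
    ) - np.log2(expression.loc[low, eligible].mean(axis=0).to_numpy() + pseudocount)
    res = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q}, index=pd.Index(eligible, name="gene")
    )
    res = res[res["q"] < q_max]
    res = res.reindex(res["log2fc"].abs().sort_values(ascending=False, kind="mergesort").index)
    if len(res) < k:
        warnings.warn(
            f"only {len(res)} marker genes qualify (requested {k})", stacklevel=2
        )
        return res
    return res.head(k)


@dataclass
class ProxyClassifierResult:
    """Fitted proxy classifier with its cross-validated training AUC."""

    model: RandomForestClassifier
    cv_auc: float
    predictions: pd.Series
    scores: pd.Series
    positive_label: str


def proxy_classifier(
    train_expression: pd.DataFrame,
    train_labels: Mapping[str, str] | pd.Series,
    test_expression: pd.DataFrame | None = None,
    seed: int = 0,
    n_estimators: int = 200,
    cv: int = 5,
) -> ProxyClassifierResult:
    """Seeded ensemble-of-decision-trees bivalency-group classifier.

    A random forest is trained on marker-gene expression; the reported
    training AUC is cross-validated (stratified K-fold, seeded).  Given the
    same seed and data the predictions are deterministic.  Predictions are
    produced for ``test_expression`` (or the training samples if omitted).
    """
    y = pd.Series(dict(train_labels) if not isinstance(train_labels, pd.Series)
                  else train_labels).loc[train_expression.index]
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"training labels must have exactly 2 classes, got {classes}")
    counts = y.value_counts()
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class in training")
    positive = classes[-1]
    X = train_expression.to_numpy(dtype=float)
    y_bin = (y == positive).astype(int).to_numpy()
    n_splits = min(cv, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    proba = cross_val_predict(model, X, y_bin, cv=skf, method="predict_proba")[:, 1]
    cv_auc = float(roc_auc_score(y_bin, proba))
    model.fit(X, y_bin)
    target = test_expression if test_expression is not None else train_expression
    scores = model.predict_proba(target.to_numpy(dtype=float))[:, 1]
    preds = np.where(scores >= 0.5, positive, classes[0])
    return ProxyClassifierResult(
        model=model,
        cv_auc=cv_auc,
        predictions=pd.Series(preds, index=target.index, name="predicted_group"),
        scores=pd.Series(scores, index=target.index, name="score"),
        positive_label=positive,
    )
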