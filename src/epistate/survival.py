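"""Survival analysis: Kaplan-Meier, log-rank, and Cox proportional hazards.

These estimators are implemented directly because their exact conventions
matter for the prognostic bivalency analysis and are verified against
independent oracles (hand product-limit computation, label-permutation
null, 1-D partial-likelihood grid search) in the test suite:

* Kaplan-Meier product-limit estimator with a risk table,
* two-group log-rank test (hypergeometric observed-vs-expected events),
* Cox partial-likelihood maximization by Newton iteration with Breslow
  tie handling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalRecord:
    """Follow-up time (months), event indicator and covariates for a sample.

    ``event`` is 1 for metastasis or death, 0 for censoring at the recorded
    time.
    """

    sample_id: str
    time: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if int(self.event) not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        self.event = int(self.event)


def read_survival_table(path) -> list[SurvivalRecord]:
    """TSV with columns sample_id, time_months, event (+ covariates)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "time_months", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    extras = [c for c in df.columns if c not in required]
    return [
        SurvivalRecord(
            sample_id=str(row["sample_id"]),
            time=float(row["time_months"]),
            event=int(row["event"]),
            covariates={c: row[c] for c in extras},
        )
        for _, row in df.iterrows()
    ]


def write_survival_table(records: Sequence[SurvivalRecord], path) -> None:
    extras = sorted({k for r in records for k in r.covariates})
    rows = [
        {
            "sample_id": r.sample_id,
            "time_months": r.time,
            "event": r.event,
            **{k: r.covariates.get(k) for k in extras},
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class KaplanMeierCurve:
    """Step-function survival estimate with an at-risk table."""

    table: pd.DataFrame  # columns: time, n_risk, n_event, n_censor, survival

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous, S(t)=1 before the first event."""
        tab = self.table[self.table["n_event"] > 0]
        past = tab[tab["time"] <= t]
        if past.empty:
            return 1.0
        return float(past["survival"].iloc[-1])


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KaplanMeierCurve:
    """Product-limit estimator.

    S(0) = 1; the curve steps only at event times, while censoring reduces
    the risk set without a step.  The table lists every distinct observed
    time with its risk-set size, event and censor counts, and S(t).
    """
    if not records:
        raise ValueError("need >= 1 record")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    uniq = np.unique(times)
    n = len(times)
    rows = []
    surv = 1.0
    for t in uniq:
        at = times == t
        n_event = int(events[at].sum())
        n_censor = int((~events[at].astype(bool)).sum())
        n_risk = int((times >= t).sum())
        if n_event > 0:
            surv *= 1.0 - n_event / n_risk
        rows.append((float(t), n_risk, n_event, n_censor, surv))
    table = pd.DataFrame(
        rows, columns=["time", "n_risk", "n_event", "n_censor", "survival"]
    )
    return KaplanMeierCurve(table=table)


def _logrank_arrays(
    times: np.ndarray, events: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float]:
    """Log-rank chi-square statistic and p for a 0/1 group indicator."""
    event_times = np.unique(times[events == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_group1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_test(
    records: Sequence[SurvivalRecord], groups: Mapping[str, object] | Sequence
) -> tuple[float, float]:
    """Two-group log-rank test.

    ``groups`` is a mapping from sample_id to group label or a sequence of
    labels aligned with ``records``.  Exactly two labels, each non-empty,
    and >= 1 event overall are required.  Returns (chi-square statistic, p)
    with 1 degree of freedom.
    """
    if isinstance(groups, Mapping):
        labels = [groups[r.sample_id] for r in records]
    else:
        labels = list(groups)
        if len(labels) != len(records):
            raise ValueError("group labels must align with records")
    uniq = sorted(set(map(str, labels)))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 groups required, got {uniq}")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    in_g1 = np.asarray([str(l) == uniq[0] for l in labels], dtype=bool)
    if in_g1.all() or not in_g1.any():
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("log-rank test undefined with no events")
    return _logrank_arrays(times, events, in_g1)


def encode_covariates(
    records: Sequence[SurvivalRecord],
    names: Sequence[str],
    reference: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Design matrix: numeric covariates as-is, categoricals one-hot encoded
    against a stated reference level (default: first level in sorted order).
    """
    reference = dict(reference or {})
    raw = pd.DataFrame(
        {name: [r.covariates.get(name) for r in records] for name in names},
        index=[r.sample_id for r in records],
    )
    cols = {}
    for name in names:
        col = raw[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols[name] = col.astype(float)
        else:
            levels = sorted(map(str, col.unique()))
            ref = str(reference.get(name, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for {name!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=raw.index)


class ConvergenceError(RuntimeError):
    pass


def _cox_loglik(beta, times, events, X):
    """Breslow partial log-likelihood, gradient and Hessian."""
    order = np.argsort(-times, kind="mergesort")  # descending time
    t_s, e_s, X_s = times[order], events[order], X[order]
    eta = X_s @ beta
    eta -= eta.max()  # stabilize
    w = np.exp(eta)
    # running sums over the risk set {time >= t}
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * X_s, axis=0)
    S2 = np.cumsum(w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)
    # individuals with equal times must share the full risk set: take the
    # last cumulative index of each tied block
    ll = 0.0
    g = np.zeros(X.shape[1])
    H = np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        ev = np.flatnonzero(e_s[i: j + 1] == 1) + i
        if ev.size:
            s0, s1, s2 = S0[j], S1[j], S2[j]
            mean = s1 / s0
            for k in ev:
                ll += eta[k] - np.log(s0)
                g += X_s[k] - mean
            H -= ev.size * (s2 / s0 - np.outer(mean, mean))
        i = j + 1
    return ll, g, H


def cox_ph(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str],
    reference: Mapping[str, object] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Cox proportional-hazards regression.

    Partial-likelihood maximization with Breslow tie handling and Newton
    iteration to gradient norm < ``tol``.  Returns per-covariate rows with
    coefficient, hazard ratio exp(coef), standard error, Wald z and p.

    Raises :class:`ConvergenceError` on non-convergence within ``max_iter``
    iterations or on apparent complete separation (diverging coefficients).
    """
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    if events.sum() == 0:
        raise ValueError("Cox model requires >= 1 event")
    Xdf = encode_covariates(records, covariates, reference=reference)
    X = Xdf.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError("no covariate columns after encoding")
    variances = X.var(axis=0)
    dead = [c for c, v in zip(Xdf.columns, variances) if v == 0]
    if dead:
        raise ValueError(f"covariates with zero variance: {dead}")
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        ll, g, H = _cox_loglik(beta, times, events, X)
        if np.linalg.norm(g) < tol:
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian: {exc}") from None
        beta = beta + step
        # |beta| > 15 means a hazard ratio beyond e^15: no plausible fit
        # reaches this; it indicates monotone likelihood / separation
        if np.abs(beta).max() > 15:
            raise ConvergenceError(
                "coefficients diverging (possible complete separation); "
                f"beta={beta}"
            )
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
    _, _, H = _cox_loglik(beta, times, events, X)
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": beta,
            "hazard_ratio": np.exp(beta),
            "se": se,
            "z": z,
            "p": p,
        },
        index=Xdf.columns,
    )
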