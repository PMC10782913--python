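"""Survival evaluation suite: Kaplan-Meier, log-rank, time-dependent ROC,
Harrell's C-index and calibration.

Orientation convention throughout: a *higher* risk score predicts *shorter*
survival. The time-dependent ROC uses the cumulative-case / dynamic-control
definition with inverse-probability-of-censoring weights (IPCW) from the
Kaplan-Meier estimate of the censoring distribution; horizons default to
12, 36 and 60 months (1-, 3- and 5-year overall survival).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .expression_io import ClinicalTable, ValidationError
from .pair_encoding import PairIndicatorMatrix
from .signature_fit import PairSignature, RiskScores

DEFAULT_HORIZONS = (12.0, 36.0, 60.0)


class EvaluationError(ValueError):
    pass


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def at(self, t: float) -> float:
        """Right-continuous survival probability at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TimeROC:
    """IPCW cumulative/dynamic ROC at one horizon."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.auc)


@dataclass
class CalibrationTable:
    """Predicted vs KM-observed survival at a horizon, by score bins."""

    horizon: float
    table: pd.DataFrame  # columns: bin, n, predicted, observed

    @property
    def max_abs_gap(self) -> float:
        ok = self.table.dropna(subset=["observed"])
        return float(np.max(np.abs(ok["predicted"] - ok["observed"])))


def km_curve(clinical: ClinicalTable, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier curve of one clinical subset."""
    if len(clinical.data) == 0:
        raise EvaluationError("empty clinical subset")
    kmf = KaplanMeierFitter()
    kmf.fit(clinical.time, clinical.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float)
    # drop the t=0 anchor row lifelines prepends
    if times[0] == 0.0 and (len(clinical.data) == 0 or clinical.time.min() > 0):
        pass  # keep anchor; S(0)=1 by construction
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk, label=label)


def logrank(groups: Sequence[ClinicalTable]) -> tuple[float, float]:
    """Log-rank test across >= 2 groups: (chi-square statistic, p-value)."""
    if len(groups) < 2:
        raise EvaluationError("log-rank needs at least 2 groups")
    if any(len(g.data) == 0 for g in groups):
        raise EvaluationError("log-rank group is empty")
    times = np.concatenate([g.time for g in groups])
    events = np.concatenate([g.event for g in groups])
    labels = np.concatenate([np.full(len(g.data), i) for i, g in enumerate(groups)])
    if events.sum() == 0:
        raise EvaluationError("no events in any group; log-rank undefined")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> SurvivalCurve:
    """KM estimate of the censoring distribution (censorings as 'events')."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    sf = kmf.survival_function_
    return SurvivalCurve(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        at_risk=np.zeros(len(sf)),
        label="censoring",
    )


def _left_limit(curve: SurvivalCurve, t: float) -> float:
    """G(t-): censoring survival just before t."""
    idx = np.searchsorted(curve.times, t, side="left") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def time_dependent_auc(
    scores: RiskScores,
    clinical: ClinicalTable,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> list[TimeROC]:
    """IPCW cumulative/dynamic ROC at each horizon.

    Cases at horizon t: event observed at or before t. Controls: observed
    time beyond t. Cases are weighted 1/G(T-), controls 1/G(t), with G the
    KM censoring-survival estimate. A horizon with no cases or no controls
    is reported with ``auc = nan`` rather than raising.
    """
    clin = clinical.subset(scores.sample_ids)
    time, event = clin.time, clin.event
    s = np.asarray(scores.score, dtype=float)
    G = _censoring_survival(time, event)
    out: list[TimeROC] = []
    for t in horizons:
        case = (time <= t) & (event == 1)
        ctrl = time > t
        if case.sum() == 0 or ctrl.sum() == 0:
            out.append(TimeROC(t, np.array([]), np.array([]), np.array([]), float("nan")))
            continue
        w_case = np.array([1.0 / max(_left_limit(G, ti), 1e-12) for ti in time[case]])
        g_t = max(G.at(t), 1e-12)
        w_ctrl = np.full(ctrl.sum(), 1.0 / g_t)
        sc, st = s[case], s[ctrl]
        # weighted probability that a case outranks a control (ties 0.5)
        diff = sc[:, None] - st[None, :]
        concord = (diff > 0) + 0.5 * (diff == 0)
        wmat = w_case[:, None] * w_ctrl[None, :]
        auc = float((concord * wmat).sum() / wmat.sum())
        thresholds = np.unique(s)
        sens = np.array([(w_case * (sc > c)).sum() / w_case.sum() for c in thresholds])
        spec = np.array([(w_ctrl * (st <= c)).sum() / w_ctrl.sum() for c in thresholds])
        # pad so the ROC runs from (0,0) to (1,1) in (1-spec, sens) space
        sens = np.concatenate(([1.0], sens, [0.0]))
        spec = np.concatenate(([0.0], spec, [1.0]))
        thresholds = np.concatenate(([-np.inf], thresholds, [np.inf]))
        out.append(TimeROC(t, thresholds, sens, spec, auc))
    return out


def concordance_index(scores: RiskScores, clinical: ClinicalTable) -> float:
    """Harrell's C: fraction of usable pairs where the higher score dies sooner.

    Usable pairs are those where the shorter observed time carries an event;
    pairs tied on time are excluded; score ties count 0.5.
    """
    clin = clinical.subset(scores.sample_ids)
    time, event = clin.time, clin.event
    s = np.asarray(scores.score, dtype=float)
    ti = time[:, None]
    tj = time[None, :]
    usable = (ti < tj) & (event[:, None] == 1)  # i dies first, observed
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise EvaluationError("no usable (comparable) pairs for the C-index")
    si = s[:, None]
    sj = s[None, :]
    concordant = (si > sj) & usable
    tied = (si == sj) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


def breslow_baseline_cumhaz(
    linear_predictor: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard.

    Returns (event_times, H0 at those times); H0(t) steps by
    d(t) / sum_{j at risk at t} exp(lp_j) at each distinct event time.
    """
    order = np.argsort(time, kind="stable")
    t_s, e_s, lp_s = time[order], event[order], linear_predictor[order]
    exp_lp = np.exp(lp_s)
    # risk-set denominator at each index: sum over j >= i (times ascending)
    denom_from = np.cumsum(exp_lp[::-1])[::-1]
    uniq, start = np.unique(t_s, return_index=True)
    steps = []
    for u, st in zip(uniq, start):
        mask = t_s == u
        d = int(e_s[mask].sum())
        if d > 0:
            steps.append((u, d / denom_from[st]))
    if not steps:
        return np.array([]), np.array([])
    times = np.array([x[0] for x in steps])
    h0 = np.cumsum([x[1] for x in steps])
    return times, h0


def calibration(
    signature: PairSignature,
    indicators: PairIndicatorMatrix,
    clinical: ClinicalTable,
    horizon: float,
    n_bins: int = 3,
) -> CalibrationTable:
    """Predicted vs observed survival at ``horizon``, by predicted-risk bins.

    Predicted survival uses the signature's linear predictor with a Breslow
    baseline hazard estimated on this cohort: S_i(t) = exp(-H0(t) e^{lp_i}).
    Observed survival is the KM estimate within each bin. A bin whose
    follow-up ends before the horizon is reported with observed = NaN.
    """
    from .signature_fit import risk_score

    rs = risk_score(signature, indicators)
    clin = clinical.subset(rs.sample_ids)
    lp = np.asarray(rs.score, dtype=float)
    bt, bh = breslow_baseline_cumhaz(lp, clin.time, clin.event)
    if len(bt) == 0:
        raise EvaluationError("no events; baseline hazard undefined")
    idx = np.searchsorted(bt, horizon, side="right") - 1
    h0_t = 0.0 if idx < 0 else float(bh[idx])
    pred = np.exp(-h0_t * np.exp(lp))
    ranks = pd.Series(pred).rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(set(ranks))), labels=False, duplicates="drop")
    rows = []
    for b in sorted(pd.unique(bins)):
        mask = (bins == b).to_numpy()
        sub = clin.subset([s for s, m in zip(clin.sample_ids, mask) if m])
        observed: float | None
        if sub.time.max() < horizon:
            observed = float("nan")  # nobody at risk at the horizon
        else:
            observed = km_curve(sub).at(horizon)
        rows.append(
            {"bin": int(b), "n": int(mask.sum()),
             "predicted": float(pred[mask].mean()), "observed": observed}
        )
    table = pd.DataFrame(rows)
    if table["n"].sum() != len(rs.sample_ids):
        raise EvaluationError("calibration bins do not partition the cohort")
    return CalibrationTable(horizon=horizon, table=table)


def evaluate_cohort(
    scores: RiskScores,
    clinical: ClinicalTable,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> dict:
    """Bundle of the standard metrics for one scored cohort."""
    clin = clinical.subset(scores.sample_ids)
    groups = pd.Series(scores.group, index=scores.sample_ids)
    high = clin.subset([s for s in scores.sample_ids if groups[s] == "high"])
    low = clin.subset([s for s in scores.sample_ids if groups[s] == "low"])
    metrics: dict = {}
    if len(high.data) and len(low.data):
        chi2, p = logrank([low, high])
        metrics["logrank_chi2"] = chi2
        metrics["logrank_p"] = p
    rocs = time_dependent_auc(scores, clin, horizons)
    metrics["auc"] = {f"{int(r.horizon)}m": r.auc for r in rocs}
    metrics["c_index"] = concordance_index(scores, clin)
    return metrics
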