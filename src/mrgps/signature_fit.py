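"""Penalized-Cox pair selection, multivariate refit and risk scoring.

The signature is a short list of regulator-target pairs with Cox
coefficients; a sample's risk score is the coefficient-weighted sum of its
+1/-1 pair indicators, and cohorts are stratified at the median score.
Candidate pairs are screened by L1-penalized Cox regression with the penalty
chosen by k-fold cross-validated partial-likelihood deviance, then refit
without penalty to obtain hazard ratios and confidence intervals.

The published five-pair glioma signature (MrGPS) ships as a packaged asset:
    -0.204*(EIF3A-AK2) - 0.266*(EIF3A-EMP3) - 0.439*(YTHDC1-IGFBP2)
    - 0.140*(YTHDC1-TUBA1C) + 0.647*(IGF2BP3-CYP17A1)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .expression_io import ClinicalTable, ExpressionMatrix, ValidationError
from .pair_encoding import PairIndicatorMatrix


class FitError(RuntimeError):
    """Raised on non-convergence, collinearity, or degenerate inputs."""


@dataclass
class PairSignature:
    """Ordered regulator-target pairs with Cox coefficients."""

    entries: list[tuple[tuple[str, str], float]]
    provenance: str = "fitted"
    hazard_ratios: pd.DataFrame | None = None  # index pair label; HR, ci, p
    global_p: float | None = None
    name: str = "signature"

    def __post_init__(self) -> None:
        pairs = [tuple(p) for p, _ in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate pairs in signature")
        if not all(np.isfinite(c) for _, c in self.entries):
            raise ValidationError("signature coefficients must be finite")
        self.entries = [(tuple(p), float(c)) for p, c in self.entries]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [p for p, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.entries])

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for (m, g), _ in self.entries:
            for x in (m, g):
                if x not in out:
                    out.append(x)
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "provenance": self.provenance,
            "pairs": [list(p) for p in self.pairs],
            "coefficients": [c for _, c in self.entries],
        }
        if self.global_p is not None:
            d["global_p"] = self.global_p
        if self.hazard_ratios is not None:
            d["hazard_ratios"] = self.hazard_ratios.reset_index().to_dict("records")
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PairSignature":
        hr = None
        if "hazard_ratios" in d:
            hr = pd.DataFrame(d["hazard_ratios"]).set_index("index")
        return cls(
            entries=list(zip((tuple(p) for p in d["pairs"]), d["coefficients"])),
            provenance=d.get("provenance", "fitted"),
            global_p=d.get("global_p"),
            hazard_ratios=hr,
            name=d.get("name", "signature"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PairSignature":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RiskScores:
    """Per-sample risk scores with median-split high/low groups."""

    sample_ids: list[str]
    score: np.ndarray
    group: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.score, "group": self.group}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def published_mrgps() -> PairSignature:
    """The published five-pair glioma signature with its printed coefficients."""
    ref = resources.files("mrgps.data").joinpath("mrgps_signature.json")
    sig = PairSignature.from_dict(json.loads(ref.read_text()))
    return sig


def _surv_y(clinical: ClinicalTable) -> np.ndarray:
    return Surv.from_arrays(event=clinical.event.astype(bool), time=clinical.time)


def _breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow tie handling."""
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # running logsumexp over the risk set (samples with time >= t)
    shift = lp.max()
    log_risk = shift + np.log(np.cumsum(np.exp(lp - shift)))
    # with ties, every sample tied at t belongs to the risk set of events at t
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        denom = log_risk[j]
        ll += float(np.sum(lp[i:j + 1][event[i:j + 1] == 1]) - denom * event[i:j + 1].sum())
        i = j + 1
    return ll


def _drop_degenerate(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def _cv_lasso_path(
    X: np.ndarray,
    clinical: ClinicalTable,
    folds: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (alphas, mean CV deviance) over a coxnet L1 path."""
    y = _surv_y(clinical)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(alphas)))
    time, event = clinical.time, clinical.event
    for k, (tr, te) in enumerate(kf.split(X)):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        m.fit(X[tr], y[tr])
        for j, al in enumerate(alphas):
            lp = m.predict(X[te], alpha=al)
            dev[k, j] = -2.0 * _breslow_partial_loglik(lp, time[te], event[te])
    return alphas, dev.mean(axis=0)


def lasso_cox_select(
    indicators: PairIndicatorMatrix,
    clinical: ClinicalTable,
    folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    return_coefficients: bool = False,
) -> list[tuple[str, str]] | tuple[list[tuple[str, str]], dict[tuple[str, str], float]]:
    """L1-penalized Cox screen of candidate pairs.

    The penalty is chosen by ``folds``-fold cross-validated partial-likelihood
    deviance (minimum), unless ``alpha`` pins it explicitly. Returns the pairs
    with nonzero coefficients at the chosen penalty; deterministic given seed.
    With ``return_coefficients`` the penalized coefficients come along too.
    """
    clinical = clinical.subset(indicators.sample_ids)
    if clinical.event.sum() == 0:
        raise FitError("no events in clinical table; Cox model undefined")
    X = indicators.values.T.astype(float)
    names = [f"{m}|{g}" for m, g in indicators.pairs]
    X, names = _drop_degenerate(X, names)
    if X.shape[1] == 0:
        return []
    if X.shape[1] < 2 and alpha is None:
        raise FitError("need at least 2 candidate pairs for the penalty path")
    y = _surv_y(clinical)
    if alpha is None:
        alphas, cv_dev = _cv_lasso_path(X, clinical, folds, seed)
        alpha = float(alphas[int(np.argmin(cv_dev))])
    alpha = max(float(alpha), 1e-8)
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha], fit_baseline_model=False)
    model.fit(X, y)
    coefs = model.coef_[:, 0]
    lookup = {f"{m}|{g}": (m, g) for m, g in indicators.pairs}
    selected = [lookup[n] for n, c in zip(names, coefs) if c != 0.0]
    if return_coefficients:
        return selected, {lookup[n]: float(c) for n, c in zip(names, coefs) if c != 0.0}
    return selected


def cox_refit(
    selected: Sequence[tuple[str, str]],
    indicators: PairIndicatorMatrix,
    clinical: ClinicalTable,
) -> PairSignature:
    """Unpenalized multivariate Cox fit of the selected pairs.

    Produces per-pair hazard ratios with 95% Wald intervals and the global
    likelihood-ratio p-value.
    """
    if not selected:
        raise FitError("no pairs selected; nothing to refit")
    sub = indicators.subset_pairs(selected)
    clinical = clinical.subset(sub.sample_ids)
    X = sub.values.T.astype(float)
    names = [f"{m}|{g}" for m, g in sub.pairs]
    _raise_on_collinear(X, names)
    df = pd.DataFrame(X, columns=names)
    df["time"] = clinical.time
    df["event"] = clinical.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise FitError(f"Cox refit failed to converge: {exc}") from exc
    summary = cph.summary
    hr = pd.DataFrame(
        {
            "coef": summary["coef"],
            "se": summary["se(coef)"],
            "HR": summary["exp(coef)"],
            "HR_lower95": summary["exp(coef) lower 95%"],
            "HR_upper95": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    hr.index.name = "index"
    global_p = float(cph.log_likelihood_ratio_test().p_value)
    entries = [(tuple(p), float(summary.loc[n, "coef"])) for p, n in zip(sub.pairs, names)]
    return PairSignature(
        entries=entries, provenance="fitted", hazard_ratios=hr, global_p=global_p
    )


def _raise_on_collinear(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] < 2:
        return
    Xc = X - X.mean(axis=0)
    corr = np.corrcoef(Xc, rowvar=False)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise FitError(f"collinear features: {names[i]} and {names[j]}")


def risk_score(signature: PairSignature, indicators: PairIndicatorMatrix) -> RiskScores:
    """Risk score per sample: sum of coefficient x indicator over signature pairs.

    High/low groups split at the median score; samples exactly at the median
    go to the low-risk group.
    """
    available = {tuple(p) for p in indicators.pairs}
    missing = [p for p in signature.pairs if tuple(p) not in available]
    if missing:
        raise KeyError(
            f"signature pair(s) missing from indicator matrix: {missing}"
        )
    sub = indicators.subset_pairs(signature.pairs)
    scores = signature.coefficients @ sub.values.astype(float)
    med = float(np.median(scores)) if len(scores) else 0.0
    group = ["high" if s > med else "low" for s in scores]
    return RiskScores(list(indicators.sample_ids), scores, group)


@dataclass
class CombinedCoxModel:
    """Cox model over pair indicators plus clinical covariates."""

    model: CoxPHFitter
    features: list[str]
    hazard_ratios: pd.DataFrame
    linear_predictor: pd.Series  # prognostic index, indexed by sample id
    global_p: float


def _encode_covariate(series: pd.Series, name: str) -> np.ndarray:
    if series.dtype == object:
        mapping = {"yes": 1.0, "no": 0.0, "male": 1.0, "female": 0.0}
        vals = series.astype(str).str.lower().map(mapping)
        if vals.isna().any():
            raise ValidationError(f"covariate {name!r} has unmappable values")
        return vals.to_numpy(float)
    return series.to_numpy(float)


def combine_clinical(
    signature: PairSignature,
    indicators: PairIndicatorMatrix,
    clinical: ClinicalTable,
    covariates: Sequence[str] = ("age", "radiotherapy"),
) -> CombinedCoxModel:
    """Refit the signature pairs jointly with clinical covariates.

    Yes/no and male/female covariates are encoded 1/0; the returned linear
    predictor is the combined prognostic index.
    """
    sub = indicators.subset_pairs(signature.pairs)
    clin = clinical.subset(sub.sample_ids)
    cols: dict[str, np.ndarray] = {}
    for (m, g), row in zip(sub.pairs, sub.values):
        cols[f"{m}|{g}"] = row.astype(float)
    for cov in covariates:
        if cov not in clin.data.columns:
            raise ValidationError(f"covariate {cov!r} not in clinical table")
        vals = _encode_covariate(clin.data[cov], cov)
        if np.ptp(vals) == 0:
            raise ValidationError(f"covariate {cov!r} is constant")
        cols[cov] = vals
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    _raise_on_collinear(X, names)
    df = pd.DataFrame(X, columns=names)
    df["time"] = clin.time
    df["event"] = clin.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise FitError(f"combined Cox fit failed: {exc}") from exc
    summary = cph.summary
    hr = pd.DataFrame(
        {
            "coef": summary["coef"],
            "HR": summary["exp(coef)"],
            "HR_lower95": summary["exp(coef) lower 95%"],
            "HR_upper95": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    lp = pd.Series(
        X @ summary["coef"].to_numpy(), index=clin.sample_ids, name="prognostic_index"
    )
    return CombinedCoxModel(
        model=cph,
        features=names,
        hazard_ratios=hr,
        linear_predictor=lp,
        global_p=float(cph.log_likelihood_ratio_test().p_value),
    )


@dataclass
class GeneSignature:
    """Single-gene LASSO Cox baseline for comparison against the pair model."""

    genes: list[str]
    coefficients: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray

    def score(self, expr: ExpressionMatrix) -> RiskScores:
        if not self.genes:
            n = len(expr.sample_ids)
            return RiskScores(list(expr.sample_ids), np.zeros(n), ["low"] * n)
        idx = {g: i for i, g in enumerate(expr.gene_ids)}
        missing = [g for g in self.genes if g not in idx]
        if missing:
            raise KeyError(f"signature gene(s) missing: {missing}")
        vals = expr.values[[idx[g] for g in self.genes]]
        z = (vals - self.gene_means[:, None]) / self.gene_sds[:, None]
        s = self.coefficients @ z
        med = float(np.median(s))
        group = ["high" if v > med else "low" for v in s]
        return RiskScores(list(expr.sample_ids), s, group)


def baseline_gene_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    n_target: int | None = 20,
    folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
) -> tuple[GeneSignature, RiskScores]:
    """Classical LASSO Cox on standardized individual gene expressions.

    With ``n_target`` set, the penalty on the CV path whose selection size is
    closest to ``n_target`` is used (ties go to the sparser model); with
    ``n_target=None`` the CV-deviance minimum decides.
    """
    clin = clinical.subset([s for s in clinical.sample_ids if s in expr.sample_ids])
    sub = expr.subset_samples(clin.sample_ids)
    if clin.event.sum() == 0:
        raise FitError("no events in clinical table")
    means = sub.values.mean(axis=1)
    sds = sub.values.std(axis=1)
    keep = sds > 0
    genes = [g for g, k in zip(sub.gene_ids, keep) if k]
    Z = ((sub.values[keep] - means[keep][:, None]) / sds[keep][:, None]).T
    y = _surv_y(clin)
    if alpha is None:
        alphas, cv_dev = _cv_lasso_path(Z, clin, folds, seed)
        if n_target is None:
            alpha = float(alphas[int(np.argmin(cv_dev))])
        else:
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas),
                                       fit_baseline_model=False).fit(Z, y)
            sizes = (m.coef_ != 0).sum(axis=0)
            gap = np.abs(sizes - n_target)
            # alphas descend; take the largest alpha (sparsest) among the best
            alpha = float(alphas[int(np.argmin(gap))])
    alpha = max(float(alpha), 1e-8)
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha], fit_baseline_model=False)
    model.fit(Z, y)
    coefs = model.coef_[:, 0]
    sel = coefs != 0
    sig = GeneSignature(
        genes=[g for g, s in zip(genes, sel) if s],
        coefficients=coefs[sel],
        gene_means=means[keep][sel],
        gene_sds=sds[keep][sel],
    )
    return sig, sig.score(expr)
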