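"""Survival modeling: LASSO-Cox selection, PRS, KM/log-rank, C-index.

Feature selection follows the glmnet convention: features standardized
on training data, a 100-point log-spaced penalty grid walked downward
from the all-zero solution, and the penalty chosen by cross-validated
partial-likelihood deviance (minimum rule, with a fallback to the
largest penalty selecting at least one feature).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv


@dataclass
class SurvivalData:
    times: np.ndarray
    events: np.ndarray
    X: pd.DataFrame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if np.any(self.times <= 0):
            raise ValueError("all survival times must be positive")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be binary")
        if len(self.X) != len(self.times) or len(self.times) != len(self.events):
            raise ValueError("times, events and X must have equal length")
        if self.X.isna().any().any():
            raise ValueError("X contains missing values")


@dataclass
class PRSModel:
    """LASSO-selected features, standardized Cox coefficients and threshold."""

    selected: tuple[str, ...]
    beta: np.ndarray
    lambda_: float
    threshold: float
    means: np.ndarray
    scales: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if len(self.selected) < 1:
            raise ValueError("PRSModel requires at least one selected feature")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "selected": list(self.selected),
                "beta": self.beta.tolist(),
                "lambda": self.lambda_,
                "threshold": self.threshold,
                "standardization": {"means": self.means.tolist(), "scales": self.scales.tolist()},
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "PRSModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            selected=tuple(d["selected"]),
            beta=np.asarray(d["beta"]),
            lambda_=float(d["lambda"]),
            threshold=float(d["threshold"]),
            means=np.asarray(d["standardization"]["means"]),
            scales=np.asarray(d["standardization"]["scales"]),
        )


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    hr: pd.Series
    ci95: pd.DataFrame  # columns: lower, upper (hazard-ratio scale)
    wald_p: pd.Series
    cindex: float
    linear_predictor: np.ndarray = field(repr=False, default=None)


def breslow_loglik(times: np.ndarray, events: np.ndarray, lp: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood of a linear predictor."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    lp = np.asarray(lp, dtype=float)
    order = np.argsort(-times)  # decreasing: risk sets grow as time drops
    t, e, z = times[order], events[order], lp[order]
    log_cum = np.logaddexp.accumulate(z)
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0:
            ll += z[i:j][e[i:j] == 1].sum() - d * log_cum[j - 1]
        i = j
    return float(ll)


def lasso_cox_select(
    data: SurvivalData,
    n_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
) -> PRSModel:
    """Select features by L1-penalized Cox regression with CV-tuned penalty."""
    if data.events.sum() == 0:
        raise ValueError("no events: cannot fit a Cox model")
    if data.events.sum() < 10:
        warnings.warn("fewer than 10 events; selection will be unstable", stacklevel=2)

    X = data.X.copy()
    stds = X.std(ddof=0)
    constant = stds[stds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s)", stacklevel=2)
        X = X.drop(columns=constant)
    names = list(X.columns)
    means = X.mean().to_numpy()
    scales = X.std(ddof=0).to_numpy()
    Z = (X.to_numpy() - means) / scales

    y = Surv.from_arrays(event=data.events.astype(bool), time=data.times)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio)
    path.fit(Z, y)
    alphas = np.asarray(path.alphas_)

    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    deviance = np.zeros((n_folds, len(alphas)))
    for k, (tr, te) in enumerate(folds.split(Z)):
        if data.events[te].sum() == 0 or data.events[tr].sum() == 0:
            deviance[k] = np.nan
            continue
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        fold_fit.fit(Z[tr], y[tr])
        fold_alphas = list(fold_fit.alphas_)
        for a_idx, alpha in enumerate(alphas):
            if alpha in fold_alphas:
                coef = fold_fit.coef_[:, fold_alphas.index(alpha)]
            else:
                coef = fold_fit.coef_[:, -1]
            lp = Z[te] @ coef
            deviance[k, a_idx] = -2.0 * breslow_loglik(data.times[te], data.events[te], lp)

    mean_dev = np.nanmean(deviance, axis=0)
    best = int(np.nanargmin(mean_dev))
    coefs = path.coef_  # (n_features, n_alphas), alphas decreasing
    chosen = best
    if not np.any(coefs[:, chosen] != 0):
        nonzero_alphas = np.flatnonzero((coefs != 0).any(axis=0))
        if len(nonzero_alphas) == 0:
            raise RuntimeError("LASSO path never selects a feature")
        chosen = int(nonzero_alphas[0])  # largest penalty with >= 1 selected
    beta_full = coefs[:, chosen]
    sel = np.flatnonzero(beta_full != 0)

    selected = tuple(names[i] for i in sel)
    beta = beta_full[sel]
    z_sel = Z[:, sel]
    prs_train = z_sel @ beta
    return PRSModel(
        selected=selected,
        beta=beta,
        lambda_=float(alphas[chosen]),
        threshold=float(prs_train.mean()),
        means=means[sel],
        scales=scales[sel],
    )


def prs_score(model: PRSModel, X_new: pd.DataFrame) -> np.ndarray:
    """PRS = sum of standardized selected features weighted by beta."""
    missing = [c for c in model.selected if c not in X_new.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    Z = (X_new[list(model.selected)].to_numpy() - model.means) / model.scales
    return Z @ model.beta


def dichotomize(prs: np.ndarray, threshold: float) -> np.ndarray:
    """High-risk iff PRS >= threshold (ties go to high-risk)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(prs) >= threshold


def fit_cox(times: np.ndarray, events: np.ndarray, X: pd.DataFrame) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with Wald inference and C-index."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    df = X.reset_index(drop=True).copy()
    df["__T"] = times
    df["__E"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="__T", event_col="__E")
    beta = cph.params_
    se = cph.standard_errors_
    hr = np.exp(beta)
    ci = pd.DataFrame(
        {"lower": np.exp(beta - 1.96 * se), "upper": np.exp(beta + 1.96 * se)}, index=beta.index
    )
    p = cph.summary["p"]
    lp = X.to_numpy() @ beta.to_numpy()
    c = harrell_c(lp, times, events)
    return CoxFit(beta=beta, se=se, hr=hr, ci95=ci, wald_p=p, cindex=c, linear_predictor=lp)


def harrell_c(scores: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's concordance: higher score should mean shorter survival.

    Pairs (i, j) with ``times_i < times_j`` and ``events_i = 1`` are
    comparable; score ties earn half credit.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    greater = scores[:, None] > scores[None, :]
    ties = scores[:, None] == scores[None, :]
    concordant = (comparable & greater).sum()
    tied = (comparable & ties).sum()
    return float((concordant + 0.5 * tied) / n_comp)


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) immediately after each event time

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator (right-continuous steps)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times)
    t_sorted, e_sorted = times[order], events[order]
    distinct = np.unique(t_sorted[e_sorted == 1])
    s = 1.0
    surv = []
    n = len(times)
    for t in distinct:
        at_risk = np.sum(t_sorted >= t)
        d = np.sum((t_sorted == t) & (e_sorted == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KMCurve(times=distinct, survival=np.asarray(surv))


@dataclass
class LogrankResult:
    chi2: float
    p: float
    curves: dict


def km_logrank(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> LogrankResult:
    """Two-sample log-rank test with hypergeometric variance, plus KM curves."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly two nonempty groups required, got {len(labels)}")
    curves = {
        lab: km_curve(times[groups == lab], events[groups == lab]) for lab in labels
    }
    if events.sum() == 0:
        warnings.warn("no events: log-rank p set to 1", stacklevel=2)
        return LogrankResult(chi2=0.0, p=1.0, curves=curves)

    g1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        nj = at_risk.sum()
        n1j = (at_risk & g1).sum()
        dying = (times == t) & (events == 1)
        dj = dying.sum()
        d1j = (dying & g1).sum()
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var <= 0:
        return LogrankResult(chi2=0.0, p=1.0, curves=curves)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(chi2=float(chi2), p=p, curves=curves)
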