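"""Multivariable logistic regression with the study's two-step variable
selection: a univariable screen at p < 0.2 followed by stepwise selection
(entry p = 0.1, removal p = 0.05), reporting adjusted odds ratios with
Wald 95% CIs and AIC/BIC/log-likelihood.

Estimation is ordinary unconditional maximum likelihood (the age matching
is deliberately not modelled, as in the source analysis). Fits are
delegated to statsmodels; complete separation is detected and flagged on
the result rather than raised.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_data import Cohort

__all__ = [
    "FittedLogit",
    "OddsRatioRow",
    "fit_logistic",
    "univariable_screen",
    "stepwise_select",
    "odds_ratios",
    "predict_prob",
    "model_to_json",
]

#: |coefficient| beyond which a binary-predictor fit is treated as separated
#: (odds ratio above ~e^15 ≈ 3e6 carries no finite information here).
_SEPARATION_COEF = 15.0
_GRADIENT_TOL = 1e-6


@dataclass
class FittedLogit:
    """A maximum-likelihood logistic fit.

    ``coefficients`` are on the log-odds scale, ordered as ``names``;
    ``cov`` is the observed-information covariance of
    (intercept, coefficients).
    """

    names: list[str]
    intercept: float
    coefficients: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    bic: float
    n: int
    separation: bool = False
    converged: bool = True
    p_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        """Number of estimated parameters, intercept included."""
        return 1 + len(self.names)

    def se(self) -> np.ndarray:
        """Standard errors of the predictor coefficients."""
        return np.sqrt(np.diag(self.cov)[1:])


def _design(X: pd.DataFrame | np.ndarray, names: list[str] | None):
    X = pd.DataFrame(X)
    if names is not None:
        if set(names) <= set(map(str, X.columns)):
            X = X[list(names)]
        elif len(names) == X.shape[1]:
            X = X.set_axis(list(names), axis=1)
        else:
            raise ValueError("names do not match design matrix columns")
    names = [str(c) for c in X.columns]
    return X.to_numpy(dtype=float), names


def _ridge_irls(design: np.ndarray, y: np.ndarray, alpha: float = 1e-6,
                maxiter: int = 50) -> np.ndarray:
    """Lightly ridge-penalised IRLS, used only as a fallback to obtain
    finite coefficients on separated data (the result is flagged)."""
    beta = np.zeros(design.shape[1])
    for _ in range(maxiter):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = design.T @ (w[:, None] * design) + alpha * np.eye(design.shape[1])
        new = np.linalg.solve(A, design.T @ (w * z))
        if np.abs(new - beta).max() < 1e-8:
            beta = new
            break
        beta = new
    return beta


def fit_logistic(X, y, names: list[str] | None = None) -> FittedLogit:
    """Fit a logistic regression by maximum likelihood.

    ``X`` holds the predictors (no intercept column; one is added), ``y``
    the 0/1 class labels. Complete or quasi-complete separation is
    detected — by a statsmodels separation error, non-convergence, or a
    divergent coefficient — and flagged on the result; coefficients are
    still returned for inspection.
    """
    Xm, names = _design(X, names)
    y = np.asarray(y, dtype=float)
    if Xm.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if Xm.shape[0] <= Xm.shape[1] + 1:
        raise ValueError("need n > number of parameters")
    variances = Xm.var(axis=0)
    if (variances == 0).any():
        bad = [names[i] for i in np.flatnonzero(variances == 0)]
        raise ValueError(f"constant predictor column(s): {bad}")

    design = sm.add_constant(Xm, has_constant="add")
    model = sm.Logit(y, design)
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", maxiter=100)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # separation error or singular Hessian
            res = None
            params = _ridge_irls(design, y)
            separation = True
    if np.abs(params).max() > _SEPARATION_COEF or not converged:
        separation = True
    try:
        cov = np.asarray(res.cov_params(), dtype=float) if res is not None \
            else np.full((len(params), len(params)), np.nan)
    except Exception:
        cov = np.full((len(params), len(params)), np.nan)
    grad = model.score(params) if not separation else None
    if grad is not None and np.abs(grad).max() > _GRADIENT_TOL * max(1.0, len(y)):
        separation = True

    llf = float(model.loglike(params))
    k = len(params)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.diag(cov))
        z = params / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return FittedLogit(
        names=names,
        intercept=float(params[0]),
        coefficients=params[1:].copy(),
        cov=cov,
        loglik=llf,
        aic=2 * k - 2 * llf,
        bic=k * np.log(len(y)) - 2 * llf,
        n=len(y),
        separation=separation,
        converged=converged,
        p_values=np.asarray(pvals[1:]),
    )


def univariable_screen(cohort: Cohort, predictors: list[str] | None = None,
                       alpha: float = 0.2) -> list[str]:
    """First-stage screen: keep predictors whose single-predictor logistic
    Wald p-value is below ``alpha``. Constant or all-missing predictors
    are excluded (a degenerate column cannot enter any model)."""
    predictors = predictors if predictors is not None else cohort.predictors
    y = cohort.data["group"].to_numpy(dtype=float)
    kept = []
    for name in predictors:
        x = cohort.data[name].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.nanvar(x) == 0:
            continue
        fit = fit_logistic(x[ok].reshape(-1, 1), y[ok], names=[name])
        p = fit.p_values[0]
        if fit.separation or (np.isfinite(p) and p < alpha):
            # a separated predictor is maximally associated; it passes the screen
            kept.append(name)
    return kept


def stepwise_select(X: pd.DataFrame, y, p_enter: float = 0.1,
                    p_remove: float = 0.05) -> FittedLogit:
    """Forward selection with backward pruning on Wald p-values.

    Starting from the empty (intercept-only) model, at each cycle the
    candidate with the smallest Wald p enters if p < ``p_enter`` (ties
    broken by lowest p, then lexicographic name); then any in-model
    predictor with p > ``p_remove`` is pruned, worst first. Stops when a
    cycle changes nothing. An empty final model is a valid outcome and is
    returned as an intercept-only fit.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    candidates = sorted(str(c) for c in X.columns)
    selected: list[str] = []

    def wald_p(names: list[str]) -> dict[str, float]:
        fit = fit_logistic(X[names], y, names=names)
        if fit.separation:
            return {}
        return dict(zip(fit.names, fit.p_values))

    seen: set[frozenset] = set()  # cycle guard: enter/remove can oscillate
    changed = True
    while changed:
        state = frozenset(selected)
        if state in seen:
            break
        seen.add(state)
        changed = False
        # forward step
        best: tuple[float, str] | None = None
        for name in candidates:
            if name in selected:
                continue
            trial = selected + [name]
            try:
                ps = wald_p(trial)
            except ValueError:
                continue
            p = ps.get(name, np.inf)
            if p < p_enter and (best is None or (p, name) < best):
                best = (p, name)
        if best is not None:
            selected.append(best[1])
            changed = True
        # backward pruning
        while selected:
            ps = wald_p(selected)
            if not ps:
                break
            worst = max(selected, key=lambda nm: (ps.get(nm, 0.0), nm))
            if ps.get(worst, 0.0) > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break

    if not selected:
        return _intercept_only(y)
    return fit_logistic(X[selected], y, names=selected)


def _intercept_only(y: np.ndarray) -> FittedLogit:
    n = len(y)
    p = y.mean()
    llf = float(n * (p * np.log(p) + (1 - p) * np.log(1 - p))) if 0 < p < 1 else 0.0
    return FittedLogit(names=[], intercept=float(np.log(p / (1 - p))),
                       coefficients=np.array([]),
                       cov=np.array([[1.0 / (n * p * (1 - p))]]),
                       loglik=llf, aic=2 - 2 * llf, bic=np.log(n) - 2 * llf,
                       n=n, p_values=np.array([]))


@dataclass(frozen=True)
class OddsRatioRow:
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def odds_ratios(model: FittedLogit, level: float = 0.95) -> list[OddsRatioRow]:
    """Adjusted odds ratios with Wald confidence intervals:
    exp(beta +/- z * SE)."""
    z = stats.norm.ppf(0.5 + level / 2)
    se = model.se()
    rows = []
    with np.errstate(over="ignore"):  # a separated fit yields an inf CI bound
        for i, name in enumerate(model.names):
            b = model.coefficients[i]
            rows.append(OddsRatioRow(
                predictor=name,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * se[i])),
                ci_high=float(np.exp(b + z * se[i])),
                p=float(model.p_values[i]),
            ))
    return rows


def predict_prob(model: FittedLogit, record) -> float:
    """Probability of the positive class for one patient record
    (mapping or Series of predictor values). Raises naming any model
    predictor the record lacks."""
    missing = [nm for nm in model.names
               if nm not in record or pd.isna(record[nm])]
    if missing:
        raise ValueError(f"record missing model predictor(s): {missing}")
    eta = model.intercept + sum(model.coefficients[i] * float(record[nm])
                                for i, nm in enumerate(model.names))
    return float(1.0 / (1.0 + np.exp(-eta)))


def predict_prob_cohort(model: FittedLogit, cohort: Cohort) -> np.ndarray:
    """Vectorised :func:`predict_prob` over a cohort, order-preserving."""
    X = cohort.data[model.names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("cohort has missing values in model predictors")
    eta = model.intercept + X @ model.coefficients
    return 1.0 / (1.0 + np.exp(-eta))


def model_to_json(model: FittedLogit, path=None) -> dict:
    """Serialize a fit (names, coefficients, covariance, fit statistics)."""
    obj = {
        "names": model.names,
        "intercept": model.intercept,
        "coefficients": model.coefficients.tolist(),
        "cov": model.cov.tolist(),
        "loglik": model.loglik,
        "aic": model.aic,
        "bic": model.bic,
        "n": model.n,
        "separation": model.separation,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
    return obj
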