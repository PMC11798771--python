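"""Cox proportional-hazards diagnostics.

A proportional-hazards check motivates the AFT modelling choice: the
Cox model is fitted by Newton-Raphson on the Breslow partial
likelihood, and the Grambsch-Therneau test regresses scaled Schoenfeld
residuals on a transform of the event times.  Categorical factors are
tested jointly (df = levels - 1) and a global test covers every
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data import SurvivalDataset

__all__ = ["CoxFit", "PHTestResult", "cox_fit", "ph_test", "CoxPH"]


@dataclass
class CoxFit:
    """Breslow partial-likelihood estimates and their covariance."""

    coef: np.ndarray
    cov: np.ndarray                      # inverse observed information
    labels: tuple[str, ...]
    loglik: float
    converged: bool
    n_events: int


def _risk_sums(time, event, X, beta):
    """Breslow risk-set sums S0, S1, S2 evaluated at each event.

    Returns (event_rows, S0_at_events (e,), xbar_at_events (e,p),
    S2-term (e,p,p)); risk sets are 'time >= t' so tied events share a
    denominator.
    """
    order = np.argsort(-time, kind="stable")
    t_s, d_s, X_s = time[order], event[order], X[order]
    w = np.exp(X_s @ beta)
    S0 = np.cumsum(w)
    S1 = np.cumsum(X_s * w[:, None], axis=0)
    S2 = np.cumsum(np.einsum("ij,ik->ijk", X_s, X_s) * w[:, None, None],
                   axis=0)
    # index of the last record sharing each time (descending order):
    # the cumulative sums there cover the whole risk set {time >= t}
    n = len(t_s)
    last = np.arange(n)
    for i in range(n - 2, -1, -1):
        if t_s[i] == t_s[i + 1]:
            last[i] = last[i + 1]
    ev = np.flatnonzero(d_s == 1)
    at = last[ev]
    return order, ev, X_s, S0[at], S1[at] / S0[at, None], S2[at]


def _partial_loglik_parts(time, event, X, beta):
    order, ev, X_s, S0e, xbar, S2e = _risk_sums(time, event, X, beta)
    Xe = X_s[ev]
    ll = float(np.sum(Xe @ beta - np.log(S0e)))
    grad = (Xe - xbar).sum(axis=0)
    V = S2e / S0e[:, None, None] - np.einsum("ij,ik->ijk", xbar, xbar)
    hess = -V.sum(axis=0)
    return ll, grad, hess, Xe - xbar, V


def cox_fit(dataset: SurvivalDataset, max_iter: int = 50,
            tol: float = 1e-12) -> CoxFit:
    """Newton-Raphson maximisation of the Breslow partial likelihood.

    Raises on monotone likelihood (separation, detected as a runaway
    coefficient) naming the covariate, and on non-convergence.
    """
    X, labels = dataset.design_matrix()
    time, event = dataset.times, dataset.events
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    ll, grad, hess, *_ = _partial_loglik_parts(time, event, X, beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            worst = int(np.argmax(np.abs(beta)))
            raise FloatingPointError(
                "singular information matrix (monotone likelihood?); "
                f"largest coefficient is {labels[worst]!r}") from None
        new_beta = beta + step
        new_ll, new_grad, new_hess, *_ = _partial_loglik_parts(
            time, event, X, new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess, *_ = _partial_loglik_parts(
                time, event, X, new_beta)
            halvings += 1
        runaway = np.flatnonzero(np.abs(new_beta) > 50)
        if len(runaway):
            raise FloatingPointError(
                f"monotone likelihood: coefficient for {labels[runaway[0]]!r} "
                "diverges (separation)")
        improved = new_ll - ll
        step_size = float(np.max(np.abs(new_beta - beta)))
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        # converge on the log-likelihood change; the step-size guard
        # keeps a monotone likelihood (whose improvements also vanish
        # while beta marches off to infinity) from passing as converged
        if abs(improved) < tol * (abs(ll) + 1.0) and \
                step_size < 1e-4 * (1.0 + np.max(np.abs(beta))):
            cov = np.linalg.inv(-hess)
            return CoxFit(beta, cov, tuple(labels), ll, True, n_events)
    worst = int(np.argmax(np.abs(beta)))
    if np.abs(beta[worst]) > 10:
        raise FloatingPointError(
            f"monotone likelihood: coefficient for {labels[worst]!r} "
            "diverges (separation)")
    raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")


# ----------------------------------------------------------------------
@dataclass
class PHTestResult:
    """Grambsch-Therneau test table: one row per covariate term plus a
    global row (chi-square, df, p-value)."""

    frame: pd.DataFrame
    transform: str

    def __str__(self) -> str:
        return self.frame.to_string(
            index=False, formatters={"p": "{:.4g}".format,
                                     "chisq": "{:.3f}".format})


def _km_transform(time, event):
    """1 - Kaplan-Meier survival evaluated at each record's time."""
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    uniq, first = np.unique(t_s, return_index=True)
    at_risk = len(t_s) - first
    deaths = np.array([int(event[time == t].sum()) for t in uniq])
    surv = np.cumprod(1.0 - deaths / at_risk)
    lookup = dict(zip(uniq, surv))
    return np.array([1.0 - lookup[t] for t in time])


def ph_test(fit: CoxFit, dataset: SurvivalDataset,
            transform: str = "km") -> PHTestResult:
    """Scaled-Schoenfeld-residual test of proportional hazards.

    Per term (each categorical factor jointly, each metric covariate
    alone) and globally: with Schoenfeld residuals ``r_k`` at the
    events, covariance ``Iinv = fit.cov``, event count ``d`` and
    centred transformed event times ``g_k``,

        q = sum_k g_k r_k Iinv * d,   chi2_J = q_J' [c d Iinv_JJ]^-1 q_J

    where ``c = sum_k g_k^2``.  ``transform`` is ``"km"`` (default;
    1 - Kaplan-Meier at the event time) or ``"identity"``.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    time, event = dataset.times, dataset.events
    d = int(event.sum())
    if d < 2:
        raise ValueError("at least two events are required")
    X, labels = dataset.design_matrix()
    if tuple(labels) != tuple(fit.labels):
        raise ValueError("fit does not match this dataset's design")

    _, ev, X_s, S0e, xbar, _ = _risk_sums(time, event, X, fit.coef)
    resid = X_s[ev] - xbar                     # Schoenfeld residuals (e, p)

    if transform == "km":
        g_all = _km_transform(time, event)
        order = np.argsort(-time, kind="stable")
        g = g_all[order][ev]
    elif transform == "identity":
        order = np.argsort(-time, kind="stable")
        g = time[order][ev]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    c = float(np.sum(gc ** 2))

    Iinv = fit.cov
    q = d * (gc @ resid) @ Iinv                # (p,)

    groups: list[tuple[str, list[int]]] = []
    pos = 0
    for name in dataset.metric:
        groups.append((name, [pos]))
        pos += 1
    for name, levels in dataset.factors.items():
        span = len(levels) - 1
        groups.append((name, list(range(pos, pos + span))))
        pos += span

    rows = []
    for name, idx in groups:
        sub = np.ix_(idx, idx)
        chi2 = float(q[idx] @ np.linalg.solve(c * d * Iinv[sub], q[idx]))
        rows.append({"covariate": name, "chisq": chi2, "df": len(idx),
                     "p": float(stats.chi2.sf(chi2, len(idx)))})
    p_tot = len(fit.coef)
    chi2_g = float(q @ np.linalg.solve(c * d * Iinv, q))
    rows.append({"covariate": "GLOBAL", "chisq": chi2_g, "df": p_tot,
                 "p": float(stats.chi2.sf(chi2_g, p_tot))})
    return PHTestResult(pd.DataFrame(rows), transform)


# ----------------------------------------------------------------------
class CoxPH(BaseEstimator):
    """Cox proportional-hazards model (Breslow ties) with the
    Grambsch-Therneau proportionality check.

    Thin estimator wrapper over :func:`cox_fit` / :func:`ph_test`:
    ``fit`` stores ``coef_``, ``cov_`` and ``labels_``;
    ``check_proportional_hazards`` returns the test table.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-12,
                 transform: str = "km"):
        self.max_iter = max_iter
        self.tol = tol
        self.transform = transform

    def fit(self, dataset: SurvivalDataset) -> "CoxPH":
        result = cox_fit(dataset, max_iter=self.max_iter, tol=self.tol)
        self.result_ = result
        self.coef_ = result.coef
        self.cov_ = result.cov
        self.labels_ = result.labels
        return self

    def check_proportional_hazards(self, dataset: SurvivalDataset
                                   ) -> PHTestResult:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "result_")
        return ph_test(self.result_, dataset, transform=self.transform)

    def predict(self, dataset: SurvivalDataset) -> np.ndarray:
        """Linear risk score x'beta per record."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "result_")
        X, labels = dataset.design_matrix()
        if tuple(labels) != tuple(self.labels_):
            raise ValueError("dataset design does not match the fit")
        return X @ self.coef_
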