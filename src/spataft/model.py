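"""Hierarchical Weibull AFT model with IID and Besag ICAR random effects.

The event time :math:`T_i` follows a Weibull accelerated-failure-time
model: ``T_i ~ Weibull(shape k, scale lambda_i)`` with
``lambda_i = exp(eta_i)`` and the additive linear predictor

    eta_i = intercept + x_i' beta + u_{household(i)} + s_{state(i)}

where ``u`` are IID Gaussian household frailties with precision
``tau_u`` and ``s`` is a Besag intrinsic conditional autoregressive
(ICAR) field on the state adjacency graph with precision ``tau_s``.
Right censoring is administrative at a threshold age: censored records
contribute ``log S(t)``, events ``log f(t)``.

Because the model is AFT, ``exp(beta_j)`` is a *time ratio*: a value
above 1 means the covariate stretches time to the event (a later
debut), below 1 a shorter time (an earlier debut).

The ICAR prior is improper (rank-deficient by one per connected graph
component); it is evaluated as a proper density on the sum-to-zero
subspace, including the generalized log-determinant of the weighted
graph Laplacian so the density is correctly normalized there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .graphs import AdjacencyGraph

__all__ = [
    "WeibullAFTParams", "RandomEffectState", "ModelSpec",
    "MODEL_VARIANTS", "linear_predictor", "weibull_aft_loglik",
    "time_ratio", "icar_logpdf", "iid_logpdf", "joint_log_posterior",
    "center_spatial",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class WeibullAFTParams:
    """Weibull shape plus fixed effects on the log-time scale."""

    shape: float
    intercept: float
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("Weibull shape must be > 0")
        self.coefficients = np.atleast_1d(
            np.asarray(self.coefficients, dtype=float))

    @property
    def sigma(self) -> float:
        """Scale of the extreme-value error on log time (1/shape)."""
        return 1.0 / self.shape


@dataclass
class RandomEffectState:
    """Household frailties, spatial field and their precisions."""

    u: np.ndarray
    tau_u: float
    s: np.ndarray
    tau_s: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.tau_u <= 0 or self.tau_s <= 0:
            raise ValueError("precisions must be > 0")

    @classmethod
    def zeros(cls, n_households: int, n_states: int,
              tau_u: float = 1.0, tau_s: float = 1.0) -> "RandomEffectState":
        return cls(np.zeros(n_households), tau_u, np.zeros(n_states), tau_s)


@dataclass
class ModelSpec:
    """Which random effects are active, plus the prior configuration.

    The four (include_iid, include_icar) combinations are the four
    model variants compared by DIC/WAIC: no clustering, IID household
    clustering only, Besag ICAR spatial clustering only, and both.

    Priors (all overridable): intercept and coefficients are
    Normal(0, prior_beta_sd^2); log shape is Normal(log_shape_prior_mean,
    log_shape_prior_sd^2); the active precisions are
    Gamma(prior_precision_shape, rate=prior_precision_rate).
    """

    include_iid: bool = True
    include_icar: bool = True
    prior_beta_sd: float = 10.0
    prior_precision_shape: float = 1.0
    prior_precision_rate: float = 5e-5
    log_shape_prior_mean: float = 0.0
    log_shape_prior_sd: float = 1.0
    censor_threshold: float = 17.0
    fixed_shape: float | None = None

    def __post_init__(self) -> None:
        for name in ("prior_beta_sd", "prior_precision_shape",
                     "prior_precision_rate", "log_shape_prior_sd",
                     "censor_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fixed_shape is not None and self.fixed_shape <= 0:
            raise ValueError("fixed_shape must be > 0")

    @property
    def label(self) -> str:
        return MODEL_VARIANTS[(self.include_iid, self.include_icar)]

    def variant(self, include_iid: bool, include_icar: bool) -> "ModelSpec":
        return replace(self, include_iid=include_iid, include_icar=include_icar)


#: Labels for the four nested model variants.
MODEL_VARIANTS: dict[tuple[bool, bool], str] = {
    (False, False): "No clustering",
    (True, False): "IID clustering",
    (False, True): "Besag ICAR",
    (True, True): "IID and Besag ICAR",
}


# ----------------------------------------------------------------------
def linear_predictor(dataset: SurvivalDataset, params: WeibullAFTParams,
                     re: RandomEffectState, spec: ModelSpec,
                     graph: AdjacencyGraph | None = None) -> np.ndarray:
    """Per-record eta = intercept + x'beta (+ frailty) (+ spatial effect).

    ``graph`` is required when the ICAR effect is active (it defines the
    state-label -> index mapping).
    """
    X, _ = dataset.design_matrix()
    if X.shape[1] != params.coefficients.size:
        raise ValueError(
            f"design width {X.shape[1]} != coefficient length "
            f"{params.coefficients.size}")
    eta = params.intercept + X @ params.coefficients
    if spec.include_iid:
        if re.u.size != dataset.n_households:
            raise IndexError(
                f"frailty vector length {re.u.size} does not cover the "
                f"{dataset.n_households} household ids")
        eta = eta + re.u[dataset.household_index]
    if spec.include_icar:
        if graph is None:
            raise ValueError("graph required when the ICAR effect is active")
        idx = dataset.state_index(graph)  # raises KeyError naming unknown ids
        if re.s.size != graph.n_nodes:
            raise IndexError(
                f"spatial vector length {re.s.size} != {graph.n_nodes} nodes")
        eta = eta + re.s[idx]
    return eta


def weibull_aft_loglik(dataset: SurvivalDataset, params: WeibullAFTParams,
                       eta: np.ndarray) -> tuple[float, np.ndarray]:
    """Right-censored Weibull AFT log likelihood.

    With ``lambda_i = exp(eta_i)``: events contribute
    ``log f(t) = log k + (k-1) log t - k eta - (t/lambda)^k`` and
    censored records ``log S(t) = -(t/lambda)^k``.

    Returns the total and the per-record vector (the pointwise matrix
    row needed by WAIC).
    """
    t = dataset.times
    d = dataset.events
    k = params.shape
    if np.any(t <= 0):
        raise ValueError("all times must be > 0")
    if k <= 0:
        raise ValueError("shape must be > 0")
    log_t = np.log(t)
    z = np.exp(k * (log_t - eta))  # (t/lambda)^k
    pointwise = d * (math.log(k) + (k - 1.0) * log_t - k * eta) - z
    return float(pointwise.sum()), pointwise


def time_ratio(coefficient: float | np.ndarray) -> float | np.ndarray:
    """AFT time ratio exp(coefficient).

    TR > 1 means the covariate lengthens time to the event (delayed
    debut); TR < 1 shortens it.
    """
    return np.exp(coefficient)


# ----------------------------------------------------------------------
def icar_logpdf(s: np.ndarray, tau_s: float, graph: AdjacencyGraph,
                constraint_tol: float = 1e-6) -> float:
    """Besag ICAR log pseudo-density on the sum-to-zero subspace.

    ``log pi(s | tau) = ((n - c)/2) (log tau - log 2 pi)
    + (1/2) logdet+(L) - (tau/2) sum_{i~j} w_ij (s_i - s_j)^2``

    where ``L`` is the weighted graph Laplacian, ``c`` the number of
    connected components and ``logdet+`` the product of the nonzero
    eigenvalues.  ``s`` must sum to zero within each component (checked
    to ``constraint_tol`` per node).
    """
    s = np.asarray(s, dtype=float)
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if s.shape != (graph.n_nodes,):
        raise ValueError("field length does not match graph")
    for comp in graph.components:
        total = float(s[comp].sum())
        if abs(total) > constraint_tol * max(1, len(comp)):
            raise ValueError(
                f"sum-to-zero constraint violated on component {comp.tolist()}"
                f" (sum = {total:.3g})")
    n_eff = graph.n_nodes - graph.n_components
    quad = graph.quadratic_form(s)
    return (0.5 * n_eff * (math.log(tau_s) - _LOG_2PI)
            + 0.5 * graph.logdet_plus()
            - 0.5 * tau_s * quad)


def iid_logpdf(u: np.ndarray, tau_u: float) -> float:
    """Sum of independent Normal(0, 1/tau_u) log densities."""
    if tau_u <= 0:
        raise ValueError("tau_u must be > 0")
    u = np.asarray(u, dtype=float)
    n = u.size
    return float(0.5 * n * (math.log(tau_u) - _LOG_2PI)
                 - 0.5 * tau_u * np.sum(u * u))


def center_spatial(s: np.ndarray, graph: AdjacencyGraph) -> np.ndarray:
    """Subtract each connected component's mean from the field.

    Idempotent; enforces the ICAR sum-to-zero identifiability
    constraint per component.
    """
    s = np.array(s, dtype=float)
    for comp in graph.components:
        s[comp] -= s[comp].mean()
    return s


# ----------------------------------------------------------------------
def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return float(stats.gamma.logpdf(x, a=shape, scale=1.0 / rate))


def joint_log_posterior(dataset: SurvivalDataset, params: WeibullAFTParams,
                        re: RandomEffectState, spec: ModelSpec,
                        graph: AdjacencyGraph | None = None) -> float:
    """Unnormalized joint log posterior of the hierarchical model.

    Likelihood plus: ICAR density and Gamma prior on ``tau_s`` when the
    spatial effect is active; IID density and Gamma prior on ``tau_u``
    when the frailty is active; Gaussian priors on intercept,
    coefficients and log shape.  Terms for disabled effects contribute
    exactly zero.
    """
    eta = linear_predictor(dataset, params, re, spec, graph)
    total, _ = weibull_aft_loglik(dataset, params, eta)

    sd = spec.prior_beta_sd
    fixed = np.concatenate(([params.intercept], params.coefficients))
    total += float(np.sum(stats.norm.logpdf(fixed, 0.0, sd)))
    total += float(stats.norm.logpdf(math.log(params.shape),
                                     spec.log_shape_prior_mean,
                                     spec.log_shape_prior_sd))
    if spec.include_iid:
        total += iid_logpdf(re.u, re.tau_u)
        total += _gamma_logpdf(re.tau_u, spec.prior_precision_shape,
                               spec.prior_precision_rate)
    if spec.include_icar:
        if graph is None:
            raise ValueError("graph required when the ICAR effect is active")
        total += icar_logpdf(re.s, re.tau_s, graph)
        total += _gamma_logpdf(re.tau_s, spec.prior_precision_shape,
                               spec.prior_precision_rate)
    return total
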