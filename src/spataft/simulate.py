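"""DHS-like multi-level survival data with known ground truth.

The generator emulates the structure of a national household survey:
respondents nested in households, households nested in states, states
joined by a contiguity graph.  Covariates are drawn from configurable
marginal frequency tables whose defaults approximate the source
survey's descriptive margins; event times follow the Weibull AFT model
with household frailties and an ICAR spatial field, and censoring is
administrative at the debut-age threshold (17 years by default).

Default effect sizes are the study's reported posterior means, so a
default simulation is a plausible stand-in for the restricted survey
microdata.  Joint dependence between covariates is *not* emulated —
factors are sampled independently — and the region covariate is derived
from the state allocation (states are partitioned into contiguous
region blocks) rather than sampled, mirroring the real nesting of
states in regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats
import pandas as pd

from .data import SurvivalDataset
from .graphs import AdjacencyGraph, make_lattice_graph

__all__ = ["MetricSpec", "FactorSpec", "SimulationConfig",
           "sample_icar", "simulate_dataset"]


@dataclass(frozen=True)
class MetricSpec:
    """Truncated-normal metric covariate with its true AFT effect."""
    mean: float
    sd: float
    lower: float
    upper: float
    beta: float


@dataclass(frozen=True)
class FactorSpec:
    """Categorical covariate: levels (first = reference), marginal
    frequencies, and true effects for the non-reference levels."""
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probs) != len(self.levels):
            raise ValueError("probs length must match levels")
        if len(self.betas) != len(self.levels) - 1:
            raise ValueError("betas must cover the non-reference levels")
        if any(p < 0 for p in self.probs):
            raise ValueError("negative frequency")
        if abs(sum(self.probs) - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")


def _default_factors() -> dict[str, FactorSpec]:
    # Margins approximate the source survey's descriptive table
    # (combined over event status); betas are the reported posterior
    # means for each non-reference level.
    return {
        "shh": FactorSpec(("female", "male"), (0.875, 0.125), (0.075,)),
        "em": FactorSpec(("not_married", "formerly", "married"),
                         (0.012, 0.983, 0.005), (-0.012, 0.343)),
        "rsa": FactorSpec(("none", "not_postpartum", "postpartum"),
                          (0.723, 0.071, 0.206), (-0.05, -0.158)),
        "education": FactorSpec(("none", "primary", "secondary", "higher"),
                                (0.499, 0.199, 0.241, 0.061),
                                (-0.136, -0.317, -0.843)),
        "internet": FactorSpec(("never", "last_12m", "before_12m"),
                               (0.934, 0.057, 0.009), (-0.154, 0.012)),
        "wealth": FactorSpec(("poorest", "poorer", "middle", "richer", "richest"),
                             (0.244, 0.231, 0.213, 0.182, 0.130),
                             (-0.11, -0.1, -0.352, -0.321)),
        "religion": FactorSpec(
            ("catholic", "other_christian", "islam", "traditionalist", "other"),
            (0.087, 0.308, 0.596, 0.005, 0.004),
            (0.06, 0.268, -0.058, 0.24)),
        "tpr": FactorSpec(("rural", "urban"), (0.346, 0.654), (0.028,)),
    }


def _default_region() -> FactorSpec:
    # probs unused for the region factor (membership follows the state
    # allocation); kept uniform for completeness.
    return FactorSpec(
        ("north_central", "north_east", "north_west",
         "south_east", "south_south", "south_west"),
        (1 / 6,) * 6,
        (0.267, 0.233, -0.71, -0.319, -0.317))


@dataclass
class SimulationConfig:
    """Full description of one synthetic survey draw.

    The seed fully determines the output; independent sub-streams are
    spawned per stage (covariates, frailties, spatial field, times) so
    e.g. enlarging the covariate block does not perturb the event
    times' stream.
    """

    n_subjects: int = 5000
    n_households: int = 500
    graph: AdjacencyGraph = field(default_factory=lambda: make_lattice_graph(6, 6))
    intercept: float = 2.895
    shape: float = 2.0
    tau_u: float = 4.0
    tau_s: float = 2.0
    censor_threshold: float = 17.0
    metric: dict[str, MetricSpec] = field(
        default_factory=lambda: {"ahh": MetricSpec(46.5, 12.6, 14.0, 98.0, -0.003)})
    factors: dict[str, FactorSpec] = field(default_factory=_default_factors)
    region: FactorSpec | None = field(default_factory=_default_region)
    household_allocation: Literal["balanced", "dirichlet"] = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_households < 1:
            raise ValueError("counts must be >= 1")
        if self.shape <= 0 or self.tau_u <= 0 or self.tau_s <= 0:
            raise ValueError("shape and precisions must be > 0")
        if self.censor_threshold <= 0:
            raise ValueError("censor_threshold must be > 0")
        if self.region is not None and len(self.region.levels) > self.graph.n_nodes:
            raise ValueError("more regions than states")


def sample_icar(graph: AdjacencyGraph, tau_s: float,
                seed: int | np.random.Generator) -> np.ndarray:
    """One draw of the ICAR field restricted to the sum-to-zero subspace.

    The weighted Laplacian is eigendecomposed; coordinates along the
    null space (per-component constants) are set to zero and each
    remaining coordinate is Normal(0, 1/(tau_s * eigenvalue)).  Every
    connected component of the result sums to zero; isolated nodes get
    an effect of exactly zero (flagged with a warning).
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    iso = graph.isolated_nodes
    if len(iso):
        warnings.warn(
            f"isolated nodes {[graph.labels[i] for i in iso]} receive a "
            "spatial effect of exactly 0", stacklevel=2)
    vals, vecs = graph.laplacian_eig()
    c = graph.n_components
    nz_vals = vals[c:]
    z = rng.standard_normal(len(nz_vals)) / np.sqrt(tau_s * nz_vals)
    return vecs[:, c:] @ z


def _allocate(n_items: int, n_groups: int, how: str,
              rng: np.random.Generator) -> np.ndarray:
    """Group index per item: balanced round-robin or Dirichlet sizes."""
    if how == "balanced":
        return np.arange(n_items) % n_groups
    if how == "dirichlet":
        p = rng.dirichlet(np.full(n_groups, 5.0))
        out = rng.choice(n_groups, size=n_items, p=p)
        # guarantee every group is non-empty so cluster labels are dense
        for g in range(min(n_groups, n_items)):
            out[g] = g
        return np.sort(out)
    raise ValueError(f"unknown allocation {how!r}")


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None
                     ) -> tuple[SurvivalDataset, dict]:
    """Draw one synthetic survey and return it with its ground truth.

    Event times follow the Weibull AFT inverse-CDF construction
    ``T = exp(eta) * (-log U)^(1/shape)`` with U uniform; records with
    ``T <= censor_threshold`` are events observed at T, the rest are
    censored at the threshold.

    Returns
    -------
    dataset : SurvivalDataset
    truth : dict
        True intercept, shape, coefficient vector (keyed by design
        label), frailties ``u``, spatial field ``s``, precisions, the
        household -> state allocation and the seed used.
    """
    if seed is None:
        seed = config.seed
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(5)]
    rng_alloc, rng_cov, rng_u, rng_s, rng_t = streams

    n, H, G = config.n_subjects, config.n_households, config.graph.n_nodes
    hh_of_subject = _allocate(n, H, config.household_allocation, rng_alloc)
    state_of_hh = _allocate(H, G, "balanced", rng_alloc)
    state_idx = state_of_hh[hh_of_subject]

    # --- covariates -----------------------------------------------------
    columns: dict[str, np.ndarray] = {}
    beta: dict[str, float] = {}
    factor_schema: dict[str, tuple[str, ...]] = {}
    for name, m in config.metric.items():
        a = (m.lower - m.mean) / m.sd
        b = (m.upper - m.mean) / m.sd
        columns[name] = stats.truncnorm.rvs(
            a, b, loc=m.mean, scale=m.sd, size=n, random_state=rng_cov)
        beta[name] = m.beta
    for name, fac in config.factors.items():
        draws = rng_cov.choice(len(fac.levels), size=n, p=np.asarray(fac.probs))
        columns[name] = np.asarray(fac.levels, dtype=object)[draws]
        factor_schema[name] = fac.levels
        for level, b_ in zip(fac.levels[1:], fac.betas):
            beta[f"{name}[{level}]"] = b_

    if config.region is not None:
        n_reg = len(config.region.levels)
        region_of_state = np.arange(G) * n_reg // G
        reg_idx = region_of_state[state_idx]
        columns["region"] = np.asarray(config.region.levels,
                                       dtype=object)[reg_idx]
        factor_schema["region"] = config.region.levels
        for level, b_ in zip(config.region.levels[1:], config.region.betas):
            beta[f"region[{level}]"] = b_
        region_id = reg_idx + 1
    else:
        region_id = np.ones(n, dtype=int)

    # --- random effects -------------------------------------------------
    u = rng_u.standard_normal(H) / np.sqrt(config.tau_u)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated-node flag not useful here
        s = sample_icar(config.graph, config.tau_s, rng_s)

    # --- event times ----------------------------------------------------
    frame = pd.DataFrame(columns)
    frame["household_id"] = hh_of_subject
    frame["state_id"] = np.asarray(config.graph.labels,
                                   dtype=object)[state_idx]
    frame["region_id"] = region_id

    metric_names = tuple(config.metric)
    dataset_proto = SurvivalDataset(
        frame.assign(time=1.0, event=0), metric=metric_names,
        factors=factor_schema)
    X, labels = dataset_proto.design_matrix()
    beta_vec = np.array([beta[lab] for lab in labels])
    eta = config.intercept + X @ beta_vec + u[hh_of_subject] + s[state_idx]

    T = np.exp(eta) * (-np.log(rng_t.uniform(size=n))) ** (1.0 / config.shape)
    event = (T <= config.censor_threshold).astype(int)
    time = np.where(event == 1, T, config.censor_threshold)
    frame["time"] = time
    frame["event"] = event

    dataset = SurvivalDataset(frame, metric=metric_names, factors=factor_schema)
    truth = {
        "intercept": config.intercept,
        "shape": config.shape,
        "coefficients": {lab: beta[lab] for lab in labels},
        "u": u,
        "s": s,
        "tau_u": config.tau_u,
        "tau_s": config.tau_s,
        "state_of_household": state_of_hh,
        "seed": seed,
    }
    return dataset, truth
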