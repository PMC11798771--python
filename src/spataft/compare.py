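"""DIC and WAIC model comparison across the nested model variants.

Both criteria are computed from the per-draw x per-record pointwise
log-likelihood matrix stored with every fit; lower is better.  DIC uses
the classic Spiegelhalter effective-parameter count
``pD = mean deviance - deviance at the posterior mean`` with the
posterior mean taken component-wise on the sampled scale (the shape is
averaged as a log-shape).  WAIC uses the pointwise log predictive
density with the variance-based penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import SurvivalDataset
from .graphs import AdjacencyGraph
from .mcmc import PosteriorSamples
from .model import ModelSpec, linear_predictor, weibull_aft_loglik

__all__ = ["dic", "waic", "compare_models", "ComparisonTable"]


def dic(samples: PosteriorSamples, dataset: SurvivalDataset,
        spec: ModelSpec | None = None,
        graph: AdjacencyGraph | None = None) -> tuple[float, float]:
    """Deviance information criterion and its effective parameter count.

    ``D(theta) = -2 loglik``; ``DIC = mean(D) + pD`` with
    ``pD = mean(D) - D(posterior mean)``.
    """
    if spec is None:
        spec = samples.spec
    total_ll = samples.pointwise_loglik.sum(axis=1)
    d_bar = float(np.mean(-2.0 * total_ll))
    params, re = samples.mean_params()
    eta = linear_predictor(dataset, params, re, spec, graph)
    ll_at_mean, _ = weibull_aft_loglik(dataset, params, eta)
    if not np.isfinite(ll_at_mean):
        raise FloatingPointError("non-finite deviance at the posterior mean")
    p_d = d_bar - (-2.0 * ll_at_mean)
    return d_bar + p_d, p_d


def waic(samples: PosteriorSamples) -> tuple[float, float]:
    """Widely applicable information criterion and its penalty.

    ``lppd = sum_i log mean_d exp(l_di)`` (log-sum-exp stabilised),
    ``p_waic = sum_i var_d(l_di)``, ``WAIC = -2 (lppd - p_waic)``.
    Warns listing record indices whose pointwise variance exceeds 0.4
    (the standard reliability heuristic).
    """
    ll = samples.pointwise_loglik
    n_draws = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    var_i = ll.var(axis=0, ddof=1) if n_draws > 1 else np.zeros(ll.shape[1])
    high = np.flatnonzero(var_i > 0.4)
    if len(high):
        import warnings
        warnings.warn(
            f"p_waic unreliable for {len(high)} records "
            f"(first few: {high[:10].tolist()})", stacklevel=2)
    p_waic = float(var_i.sum())
    lppd = float(lppd_i.sum())
    return -2.0 * (lppd - p_waic), p_waic


@dataclass
class ComparisonTable:
    """Per-model DIC/WAIC with the minima starred."""

    frame: pd.DataFrame

    def __str__(self) -> str:
        show = self.frame.copy()
        for crit in ("dic", "waic"):
            show[crit] = [
                f"{v:.2f}{'*' if star else ''}"
                for v, star in zip(show[crit], show[f"{crit}_best"])]
        return show[["model", "dic", "p_d", "waic", "p_waic"]].to_string(
            index=False)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def best(self, criterion: str = "dic") -> str:
        return self.frame.loc[self.frame[f"{criterion}_best"], "model"].iloc[0]


def compare_models(fits: list[tuple[str, PosteriorSamples]],
                   dataset: SurvivalDataset,
                   graph: AdjacencyGraph | None = None) -> ComparisonTable:
    """Rank >= 2 fits of the same dataset by DIC and WAIC.

    Ties are all starred (with a warning).  Fits whose pointwise
    matrices disagree on the record count are rejected.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    labels = [lab for lab, _ in fits]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate model labels")
    n_records = {s.n_records for _, s in fits}
    if len(n_records) != 1 or n_records.pop() != len(dataset):
        raise ValueError("fits do not share this dataset's record count")

    rows = []
    for label, samples in fits:
        dic_val, p_d = dic(samples, dataset, samples.spec, graph)
        waic_val, p_waic = waic(samples)
        rows.append({"model": label, "dic": dic_val, "p_d": p_d,
                     "waic": waic_val, "p_waic": p_waic})
    frame = pd.DataFrame(rows)
    for crit in ("dic", "waic"):
        best = frame[crit].min()
        frame[f"{crit}_best"] = np.isclose(frame[crit], best) | \
            (frame[crit] == best)
        if frame[f"{crit}_best"].sum() > 1:
            import warnings
            warnings.warn(f"tie on {crit.upper()}", stacklevel=2)
    return ComparisonTable(frame)
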