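"""Respondent-level survival data with household and state clustering.

The data model mirrors a DHS-style design: one row per respondent with a
time-to-event (age at first sexual debut in years, or the censoring age),
an event indicator (debut at or below a threshold age), coded covariates,
and two nested cluster labels — household and state.  States index into a
companion :class:`~spataft.graphs.AdjacencyGraph`.

Covariates come in two kinds: metric columns used as-is and categorical
factors that are dummy-expanded against a declared reference category
(always the first level).  The default schema reproduces the survey
coding used in the source study: age of household head (AHH, metric);
sex of household head (SHH, ref female); ever-married status (ref not
married); recent sexual activity (ref none); education (ref none);
internet use (ref never); wealth index (ref poorest); religion (ref
Catholic); type of residence (ref rural); region (ref North Central).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import AdjacencyGraph

__all__ = ["SurvivalDataset", "DEFAULT_FACTORS", "DEFAULT_METRIC"]

#: Factor levels in coding order; the first level is the reference category.
DEFAULT_FACTORS: dict[str, tuple[str, ...]] = {
    "shh": ("female", "male"),
    "em": ("not_married", "formerly", "married"),
    "rsa": ("none", "not_postpartum", "postpartum"),
    "education": ("none", "primary", "secondary", "higher"),
    "internet": ("never", "last_12m", "before_12m"),
    "wealth": ("poorest", "poorer", "middle", "richer", "richest"),
    "religion": ("catholic", "other_christian", "islam", "traditionalist", "other"),
    "tpr": ("rural", "urban"),
    "region": ("north_central", "north_east", "north_west",
               "south_east", "south_south", "south_west"),
}

DEFAULT_METRIC: tuple[str, ...] = ("ahh",)

_ID_COLS = ("time", "event", "household_id", "state_id", "region_id")


@dataclass
class SurvivalDataset:
    """One row per respondent: event time, status, covariates, clusters.

    Parameters
    ----------
    frame : DataFrame
        Must contain ``time`` (positive years), ``event`` (0/1),
        ``household_id``, ``state_id``, ``region_id`` plus the declared
        covariate columns.  ``state_id`` values are strings matching
        graph node labels.
    metric : tuple of str
        Names of metric covariate columns.
    factors : dict
        Factor name -> ordered levels (first level is the reference).
    """

    frame: pd.DataFrame
    metric: tuple[str, ...] = DEFAULT_METRIC
    factors: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS))

    def __post_init__(self) -> None:
        f = self.frame
        missing_cols = [c for c in (*_ID_COLS, *self.metric, *self.factors)
                        if c not in f.columns]
        if missing_cols:
            raise ValueError(f"missing columns: {missing_cols}")
        used = [*_ID_COLS, *self.metric, *self.factors]
        na_rows = f.index[f[used].isna().any(axis=1)]
        if len(na_rows):
            raise ValueError(
                f"missing values in rows {list(na_rows[:10])}"
                + ("..." if len(na_rows) > 10 else ""))
        t = f["time"].to_numpy(dtype=float)
        if np.any(t <= 0):
            bad = f.index[t <= 0]
            raise ValueError(f"non-positive times in rows {list(bad[:10])}")
        ev = f["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            bad = f.index[~np.isin(ev, (0, 1))]
            raise ValueError(f"event must be 0/1; offending rows {list(bad[:10])}")
        for name, levels in self.factors.items():
            vals = f[name].astype(str)
            unknown = sorted(set(vals) - set(levels))
            if unknown:
                raise ValueError(f"factor {name!r}: unknown levels {unknown}")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def household_labels(self) -> np.ndarray:
        """Sorted unique household ids."""
        return np.unique(self.frame["household_id"].to_numpy())

    @property
    def household_index(self) -> np.ndarray:
        """Per-record 0-based household index (sorted-label order)."""
        labels = self.household_labels
        return np.searchsorted(labels, self.frame["household_id"].to_numpy())

    @property
    def n_households(self) -> int:
        return len(self.household_labels)

    def state_index(self, graph: AdjacencyGraph) -> np.ndarray:
        """Per-record 0-based node index into ``graph``.

        Raises a KeyError naming the first state label absent from the
        graph.
        """
        lookup = {lab: i for i, lab in enumerate(graph.labels)}
        out = np.empty(len(self.frame), dtype=int)
        for r, lab in enumerate(self.frame["state_id"].astype(str)):
            if lab not in lookup:
                raise KeyError(f"state_id {lab!r} not a node of the graph")
            out[r] = lookup[lab]
        return out

    # ------------------------------------------------------------------
    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dummy-expanded design matrix (no intercept column).

        Metric covariates enter as-is; each factor contributes one 0/1
        column per non-reference level, labelled ``"factor[level]"``.
        """
        cols: list[np.ndarray] = []
        labels: list[str] = []
        for name in self.metric:
            cols.append(self.frame[name].to_numpy(dtype=float))
            labels.append(name)
        for name, levels in self.factors.items():
            vals = self.frame[name].astype(str).to_numpy()
            for level in levels[1:]:
                cols.append((vals == level).astype(float))
                labels.append(f"{name}[{level}]")
        X = np.column_stack(cols) if cols else np.empty((len(self.frame), 0))
        return X, labels

    @property
    def n_coefficients(self) -> int:
        return len(self.metric) + sum(len(v) - 1 for v in self.factors.values())

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, *,
                 metric: tuple[str, ...] = DEFAULT_METRIC,
                 factors: dict[str, tuple[str, ...]] | None = None,
                 ) -> "SurvivalDataset":
        frame = pd.read_csv(path, dtype={"state_id": str})
        return cls(frame, metric=metric,
                   factors=dict(DEFAULT_FACTORS) if factors is None else factors)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)
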