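"""Posterior summaries, descriptive cross-tabs, and choropleth export.

Covers the study-style outputs: a fixed-effects table with posterior
means, spreads, 95% credible intervals and Weibull time ratios
(``TR = exp(posterior mean)``, matching the arithmetic of the reported
tables rather than the posterior mean of ``exp(beta)``); descriptive
level x event-status cross-tabs with column percentages; per-state
spatial-effect summaries binned on the time-ratio scale; and a GeoJSON
join + static choropleth rendering.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .graphs import AdjacencyGraph
from .mcmc import PosteriorSamples
from .model import time_ratio

__all__ = [
    "fixed_effects_table", "status_crosstab", "spatial_effect_table",
    "bin_spatial_effects", "export_choropleth",
    "DEFAULT_BREAKS", "DEFAULT_BIN_LABELS", "FIG_PRESET_BREAKS",
]

#: Default symmetric time-ratio breaks (left-closed, right-open bins).
DEFAULT_BREAKS: tuple[float, ...] = (0.80, 0.95, 1.05, 1.25)

DEFAULT_BIN_LABELS: tuple[str, ...] = (
    "strong-deceleration", "mild-deceleration", "near-null",
    "mild-acceleration", "strong-acceleration")

#: Approximate reconstruction of the source study's irregular
#: figure-derived bins; marked approximate because the exact break
#: values are not printed anywhere.
FIG_PRESET_BREAKS: tuple[float, ...] = (0.80, 0.95, 1.06, 1.24)


def fixed_effects_table(samples: PosteriorSamples,
                        labels: tuple[str, ...] | None = None
                        ) -> pd.DataFrame:
    """Posterior mean/sd/95% interval and time ratio per coefficient.

    The first row is the intercept (no time ratio: it is the log-scale
    baseline, not a covariate contrast).
    """
    if labels is None:
        labels = samples.coef_labels
    if len(labels) != samples.beta.shape[1]:
        raise ValueError(
            f"{len(labels)} labels for {samples.beta.shape[1]} coefficients")
    draws = np.column_stack([samples.intercept, samples.beta])
    names = ["(Intercept)", *labels]
    mean = draws.mean(axis=0)
    frame = pd.DataFrame({
        "label": names,
        "mean": mean,
        "sd": draws.std(axis=0, ddof=1) if len(draws) > 1 else 0.0,
        "ci_low": np.quantile(draws, 0.025, axis=0),
        "ci_high": np.quantile(draws, 0.975, axis=0),
        "time_ratio": time_ratio(mean),
    })
    frame.loc[0, "time_ratio"] = np.nan
    return frame


def status_crosstab(dataset: SurvivalDataset, factor: str) -> pd.DataFrame:
    """Counts and column percentages of a factor by event status.

    One row per level; columns ``censored``/``event`` counts and
    ``censored_pct``/``event_pct``, each percentage column summing to
    100 up to rounding of the underlying counts.
    """
    if factor not in dataset.factors:
        raise KeyError(f"unknown factor {factor!r}")
    levels = dataset.factors[factor]
    vals = dataset.frame[factor].astype(str)
    ev = dataset.events
    rows = []
    n_cens = int((ev == 0).sum())
    n_ev = int((ev == 1).sum())
    for level in levels:
        c = int(((vals == level) & (ev == 0)).sum())
        e = int(((vals == level) & (ev == 1)).sum())
        rows.append({
            "level": level, "censored": c, "event": e,
            "censored_pct": 100.0 * c / n_cens if n_cens else np.nan,
            "event_pct": 100.0 * e / n_ev if n_ev else np.nan,
        })
    return pd.DataFrame(rows)


def spatial_effect_table(samples: PosteriorSamples,
                         graph: AdjacencyGraph,
                         labels: tuple[str, ...] | None = None
                         ) -> pd.DataFrame:
    """Per-state posterior summary of the ICAR field with time ratios."""
    if not samples.spec.include_icar:
        raise ValueError(
            "the fitted model has no ICAR effect; a spatial-effect table "
            "would be meaningless")
    if labels is None:
        labels = samples.state_labels
    if len(labels) != samples.s.shape[1]:
        raise ValueError("label count does not match the spatial field")
    if len(labels) != graph.n_nodes:
        raise ValueError("graph does not match the spatial field")
    mean = samples.s.mean(axis=0)
    return pd.DataFrame({
        "state": labels,
        "mean": mean,
        "sd": samples.s.std(axis=0, ddof=1) if samples.n_draws > 1 else 0.0,
        "time_ratio": time_ratio(mean),
    })


def bin_spatial_effects(table: pd.DataFrame,
                        breaks: tuple[float, ...] = DEFAULT_BREAKS,
                        labels: tuple[str, ...] = DEFAULT_BIN_LABELS
                        ) -> pd.DataFrame:
    """Assign each state's time ratio to a left-closed right-open bin.

    A ratio exactly on a break goes to the upper bin.  ``labels`` must
    have ``len(breaks) + 1`` entries.
    """
    breaks = tuple(float(b) for b in breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    if len(labels) != len(breaks) + 1:
        raise ValueError(f"need {len(breaks) + 1} bin labels")
    tr = table["time_ratio"].to_numpy(dtype=float)
    idx = np.searchsorted(breaks, tr, side="right")
    out = table.copy()
    out["bin"] = idx + 1
    out["bin_label"] = np.asarray(labels, dtype=object)[idx]
    return out


# ----------------------------------------------------------------------
def _norm_key(value: str) -> str:
    return " ".join(str(value).strip().lower().split())


def export_choropleth(table: pd.DataFrame, geojson: str | Path | dict,
                      key_field: str, out_geojson: str | Path,
                      out_image: str | Path | None = None) -> dict:
    """Join per-state time ratios onto polygons and render a map.

    Every state in ``table`` must match a feature whose
    ``properties[key_field]`` equals the state label up to case and
    whitespace; unmatched states raise (no silent drops).  The joined
    GeoJSON (with ``time_ratio``, ``mean``, and bin properties added)
    is serialised deterministically; ``out_image`` optionally renders a
    static choropleth coloured by bin.
    """
    if isinstance(geojson, (str, Path)):
        with open(geojson) as fh:
            geo = json.load(fh)
    else:
        geo = json.loads(json.dumps(geojson))  # deep copy
    features = geo.get("features", [])
    lookup: dict[str, dict] = {}
    for feat in features:
        props = feat.get("properties", {})
        if key_field not in props:
            raise KeyError(f"feature without {key_field!r} property")
        lookup[_norm_key(props[key_field])] = feat

    if "bin" not in table.columns:
        table = bin_spatial_effects(table)
    unmatched = [str(s) for s in table["state"]
                 if _norm_key(s) not in lookup]
    if unmatched:
        raise KeyError(f"states without a matching polygon: {unmatched}")

    matched = 0
    for row in table.itertuples(index=False):
        feat = lookup[_norm_key(row.state)]
        feat["properties"].update({
            "time_ratio": float(row.time_ratio),
            "mean": float(row.mean),
            "bin": int(row.bin),
            "bin_label": str(row.bin_label),
        })
        matched += 1
    out_geojson = Path(out_geojson)
    out_geojson.write_text(
        json.dumps(geo, sort_keys=True, separators=(",", ":"),
                   ensure_ascii=True) + "\n")

    if out_image is not None:
        _render_choropleth(geo, table, key_field, Path(out_image))
    return {"matched": matched,
            "unmatched_features": len(features) - matched}


def _render_choropleth(geo: dict, table: pd.DataFrame, key_field: str,
                       path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection
    from shapely.geometry import shape

    wanted = {_norm_key(s) for s in table["state"]}
    n_bins = int(table["bin"].max())
    cmap = plt.get_cmap("RdYlGn_r", max(n_bins, 5))
    verts, colors = [], []
    for feat in geo.get("features", []):
        key = _norm_key(feat["properties"][key_field])
        if key not in wanted:
            continue
        geom = shape(feat["geometry"])
        polys = getattr(geom, "geoms", [geom])
        for poly in polys:
            verts.append(np.asarray(poly.exterior.coords))
            colors.append(cmap(feat["properties"]["bin"] - 1))
    fig, ax = plt.subplots(figsize=(6, 6))
    coll = PolyCollection(verts, facecolors=colors, edgecolors="black",
                          linewidths=0.5)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title("Spatial time ratios")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
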