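"""Variance partitioning and disease-map exports.

The BYM fit decomposes residual area variation into a spatially structured
field ``s`` and unstructured heterogeneity ``u``.  The spatial fraction

    rho = sigma2_s / (sigma2_s + sigma2_u)

is computed from the *marginal* variation of the random effects — the
empirical across-area variance of each field, evaluated per retained draw and
then summarised — rather than from the precision hyper-parameters, because
the ICAR precision tau_s is conditional and not interpretable as a marginal
variance.  Excess prevalence ratios exp(s_j + u_j) map each area's residual
risk multiplier after fixed effects.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .bym import PosteriorDraws


def spatial_fraction(draws: PosteriorDraws, method: str = "per_draw") -> dict:
    """Spatial fraction rho and the component variances.

    ``method='per_draw'`` computes rho for every retained draw and reports
    its posterior median and 95% CrI; ``method='median_ratio'`` instead takes
    the ratio of the posterior medians of the per-draw variances.  Both are
    defensible summaries of the same quantity; per-draw is the default.
    """
    s = draws.pooled("s")
    u = draws.pooled("u")
    if s.shape[1] < 2:
        raise ValueError("need >=2 areas to partition variance")
    var_s = s.var(axis=1)
    var_u = u.var(axis=1)
    med_s, med_u = float(np.median(var_s)), float(np.median(var_u))
    if method == "per_draw":
        with np.errstate(invalid="ignore"):
            rho_draws = var_s / (var_s + var_u)
        rho_draws = np.nan_to_num(rho_draws, nan=0.0)
        med, lo, hi = np.percentile(rho_draws, [50, 2.5, 97.5])
    elif method == "median_ratio":
        med = med_s / (med_s + med_u) if (med_s + med_u) > 0 else 0.0
        lo = hi = np.nan
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"rho": float(med), "rho_low": float(lo), "rho_high": float(hi),
            "sigma2_s": med_s, "sigma2_u": med_u, "method": method}


def excess_pr(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-area posterior median of exp(s_j + u_j) (excess prevalence ratio)."""
    re = draws.pooled("s") + draws.pooled("u")
    med = np.median(np.exp(re), axis=0)
    return pd.DataFrame({"area_id": draws.structure.area_ids,
                         "excess_pr": med})


def variance_reduction(draws_a: PosteriorDraws, draws_b: PosteriorDraws) -> float:
    """Percent reduction in median spatial variance from model a to model b.

    ``100 * (1 - median sigma2_s(b) / median sigma2_s(a))``; undefined (NaN)
    when the baseline variance is zero.  Both fits must cover the same areas.
    """
    if draws_a.structure.area_ids != draws_b.structure.area_ids:
        raise ValueError("fits cover different areas")
    va = float(np.median(draws_a.pooled("s").var(axis=1)))
    vb = float(np.median(draws_b.pooled("s").var(axis=1)))
    if va == 0:
        return float("nan")
    return 100.0 * (1.0 - vb / va)


def export_choropleth(values: pd.DataFrame, lattice, value_col: str,
                      n_classes: int = 5, path=None) -> dict:
    """GeoJSON FeatureCollection with the value and a quantile class per area.

    Class breaks are deterministic empirical quantiles of the values; a
    constant surface collapses to a single class.  Raises if any area with a
    value lacks geometry.
    """
    geo_ids = list(lattice.area_ids)
    missing = [a for a in values["area_id"] if a not in set(geo_ids)]
    if missing:
        raise ValueError(f"missing geometry for areas: {missing}")
    vmap = dict(zip(values["area_id"], values[value_col]))
    vals = np.array([vmap[a] for a in values["area_id"]], float)
    qs = np.quantile(vals, np.linspace(0, 1, n_classes + 1))
    breaks = np.unique(qs)
    features = []
    fc_src = lattice.to_geojson()
    for feat in fc_src["features"]:
        aid = feat["properties"]["area_id"]
        if aid not in vmap:
            continue
        v = float(vmap[aid])
        inner = breaks[1:-1]
        cls = int(np.clip(np.searchsorted(inner, v, side="left"),
                          0, max(len(breaks) - 2, 0)))
        feat = {"type": "Feature", "geometry": feat["geometry"],
                "properties": {"area_id": aid, value_col: v, "class": cls}}
        features.append(feat)
    fc = {"type": "FeatureCollection",
          "properties": {"value": value_col,
                         "class_breaks": [float(b) for b in breaks]},
          "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def plot_choropleth(fc: dict, path, cmap: str = "viridis") -> None:
    """Optional raster rendering of an exported choropleth (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    polys, vals = [], []
    name = fc["properties"]["value"]
    for feat in fc["features"]:
        coords = feat["geometry"]["coordinates"][0]
        polys.append(coords)
        vals.append(feat["properties"][name])
    coll = PolyCollection(polys, array=np.array(vals), cmap=cmap,
                          edgecolor="white", linewidth=0.3)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.colorbar(coll, ax=ax, shrink=0.7, label=name)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
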