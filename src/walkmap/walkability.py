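"""Area-level walkability index.

An abridged three-variable walkability index in the NQLS/PLACE tradition:

* residential dwelling density — dwellings per hectare of residential land;
* intersection density — intersections with three or more road junctures per
  km**2 of total land area;
* land-use mix — normalised Shannon entropy of the land-area shares of five
  land-use classes (residential, commercial, industrial, recreational,
  other), which is unit-free and therefore comparable across areas of
  different size.

Each variable is ranked into deciles scored 1 (lowest) to 10 (highest); the
three decile scores are summed to a total out of 30, and the totals are split
into sample-specific quartiles labelled low, low-medium, medium-high and
high walkability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LAND_USE_CLASSES = ["residential", "commercial", "industrial",
                    "recreational", "other"]

QUARTILE_LABELS = ["low", "low_medium", "medium_high", "high"]

ENV_COLUMNS = ["area_id", "residential_dwellings", "residential_land_ha",
               "intersections_3plus", "land_area_km2"] + [
                   f"class_{c}_km2" for c in LAND_USE_CLASSES]


class WalkabilityError(ValueError):
    pass


def land_use_mix_entropy(class_areas, n_classes: int = 5) -> np.ndarray:
    """Normalised land-use entropy H = -sum(p_i ln p_i) / ln(n_classes).

    ``class_areas`` is an (n_areas, 5) array (or a single 5-vector) of
    nonnegative class land areas.  Shares p_i are taken over the summed class
    area of each row, so any common rescaling of the areas (a change of
    spatial-unit size) leaves the entropy unchanged.  Classes with zero area
    contribute 0 (the 0*ln 0 := 0 convention).  Normalising by ln 5 — the
    number of *defined* classes — keeps H in [0, 1] with 1 only for a
    perfectly even five-way mix; pass ``n_classes=None`` to normalise by the
    number of classes present instead.
    """
    a = np.atleast_2d(np.asarray(class_areas, float))
    if a.shape[1] != len(LAND_USE_CLASSES):
        raise WalkabilityError(
            f"expected {len(LAND_USE_CLASSES)} land-use classes, got {a.shape[1]}"
        )
    if np.any(a < 0):
        raise WalkabilityError("class areas must be nonnegative")
    totals = a.sum(axis=1)
    if np.any(totals <= 0):
        raise WalkabilityError("all land-use class areas are zero for some area")
    p = a / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    if n_classes is None:
        k = (a > 0).sum(axis=1)
        denom = np.where(k > 1, np.log(np.maximum(k, 2)), 1.0)
        h = np.where(k > 1, -plogp.sum(axis=1) / denom, 0.0)
    else:
        h = -plogp.sum(axis=1) / np.log(n_classes)
    h = np.clip(h, 0.0, 1.0)
    return h if np.asarray(class_areas).ndim > 1 else float(h[0])


def densities(profile: pd.DataFrame) -> pd.DataFrame:
    """Residential dwelling density (per ha) and intersection density (per km**2).

    Zero residential land with zero dwellings yields a density of 0 by
    convention; zero residential land with dwellings present is an error.
    """
    dw = np.asarray(profile["residential_dwellings"], float)
    ha = np.asarray(profile["residential_land_ha"], float)
    land = np.asarray(profile["land_area_km2"], float)
    inter = np.asarray(profile["intersections_3plus"], float)
    if np.any(land <= 0):
        raise WalkabilityError("land_area_km2 must be positive")
    bad = (ha <= 0) & (dw > 0)
    if np.any(bad):
        ids = np.asarray(profile["area_id"])[bad]
        raise WalkabilityError(
            f"dwellings present on zero residential land for areas {ids.tolist()}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        res_density = np.where(ha > 0, dw / np.where(ha > 0, ha, 1.0), 0.0)
    int_density = inter / land
    return pd.DataFrame(
        {"area_id": profile["area_id"].to_numpy(),
         "res_density": res_density, "int_density": int_density}
    )


def decile_scores(values, area_ids=None) -> np.ndarray:
    """Rank-based decile scores 1 (lowest) to 10 (highest).

    Areas are sorted by value with ties broken by the stable order of
    ``area_ids`` (input order if omitted), then cut into 10 near-equal groups
    (sizes floor(n/10) or ceil(n/10), larger groups first where n % 10 > 0).
    """
    v = np.asarray(values, float)
    n = v.size
    if n < 10:
        raise WalkabilityError(f"need >=10 areas for deciles, got {n}")
    order = np.argsort(v, kind="stable")  # stable => ties by input order
    base, extra = divmod(n, 10)
    sizes = [base + (1 if d < extra else 0) for d in range(10)]
    scores = np.empty(n, int)
    start = 0
    for d, size in enumerate(sizes, start=1):
        scores[order[start:start + size]] = d
        start += size
    return scores


def classify_quartiles(totals, labels=QUARTILE_LABELS) -> np.ndarray:
    """Sample-specific quartiles of the total walkability score.

    Cut points are the 25/50/75 empirical percentiles of the totals; a total
    exactly on a boundary is assigned to the *lower* quartile.
    """
    t = np.asarray(totals, float)
    if t.size < 4:
        raise WalkabilityError("need >=4 areas for quartiles")
    q1, q2, q3 = np.percentile(t, [25, 50, 75])
    out = np.where(
        t <= q1, labels[0],
        np.where(t <= q2, labels[1], np.where(t <= q3, labels[2], labels[3])),
    )
    return out


def walkability_scores(profile: pd.DataFrame, entropy_classes: int = 5) -> pd.DataFrame:
    """Full index: densities, entropy, decile scores, total and quartile.

    ``profile`` has one row per area with the raw environment columns (see
    ``ENV_COLUMNS``).  Returns one row per area with the three raw measures,
    their decile scores, the total score (3-30 for this abridged
    three-variable index) and the walkability quartile label.
    """
    dens = densities(profile)
    class_cols = [f"class_{c}_km2" for c in LAND_USE_CLASSES]
    lum = land_use_mix_entropy(profile[class_cols].to_numpy(),
                               n_classes=entropy_classes)
    ids = profile["area_id"].to_numpy()
    d_res = decile_scores(dens["res_density"].to_numpy(), ids)
    d_int = decile_scores(dens["int_density"].to_numpy(), ids)
    d_lum = decile_scores(np.asarray(lum), ids)
    total = d_res + d_int + d_lum
    scores = pd.DataFrame(
        {"area_id": ids,
         "res_density": dens["res_density"].to_numpy(),
         "int_density": dens["int_density"].to_numpy(),
         "lum_entropy": np.asarray(lum),
         "decile_res": d_res, "decile_int": d_int, "decile_lum": d_lum,
         "total": total}
    )
    scores["quartile"] = classify_quartiles(total)
    scores["quartile"] = pd.Categorical(
        scores["quartile"], categories=QUARTILE_LABELS, ordered=True
    )
    return scores
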