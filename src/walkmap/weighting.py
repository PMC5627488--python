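"""Post-stratification weighting check.

Survey weights benchmark the cohort to a reference population on cells formed
by area x sex x age band (five-year bands with a pooled terminal >=85 band).
The check compares area prevalence ratios O_j / e_j computed with and without
the weights: near-unit Pearson correlation indicates geographically
structured non-response is not distorting the unweighted spatial analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .individual import expected_counts

logger = logging.getLogger(__name__)

STRATUM_KEYS = ["area_id", "sex", "age_group"]


def compute_weights(sample: pd.DataFrame, benchmark: pd.DataFrame,
                    keys=STRATUM_KEYS) -> pd.DataFrame:
    """Post-stratum weights: benchmark count / sample count per cell.

    ``benchmark`` has one row per stratum with a ``count`` column and must
    cover every sampled stratum.  Benchmark strata that drew no sample are
    flagged (``sample_count`` 0, weight NaN), excluded from weighting, and
    counted in the log.
    """
    samp = (sample.groupby(keys, observed=True).size()
            .rename("sample_count").reset_index())
    for c in keys:
        samp[c] = samp[c].astype(str)
    bench = benchmark.copy()
    for c in keys:
        bench[c] = bench[c].astype(str)
    merged = bench.merge(samp, on=keys, how="outer", indicator=True)
    unmatched = merged["_merge"] == "right_only"
    if unmatched.any():
        cells = merged.loc[unmatched, keys].to_dict("records")
        raise ValueError(f"sampled strata absent from benchmark: {cells[:5]}")
    merged["sample_count"] = merged["sample_count"].fillna(0).astype(int)
    merged = merged.rename(columns={"count": "benchmark_count"})
    merged["weight"] = np.where(merged["sample_count"] > 0,
                                merged["benchmark_count"] / merged["sample_count"],
                                np.nan)
    n_empty = int((merged["sample_count"] == 0).sum())
    if n_empty:
        logger.info("%d benchmark strata drew no sample; excluded", n_empty)
    return merged.drop(columns="_merge")


def attach_weights(sample: pd.DataFrame, weights: pd.DataFrame,
                   keys=STRATUM_KEYS) -> np.ndarray:
    """Per-person weight vector aligned with the sample rows."""
    samp = sample[keys].astype(str)
    merged = samp.merge(weights[keys + ["weight"]].astype({k: str for k in keys}),
                        on=keys, how="left")
    w = merged["weight"].to_numpy()
    if np.any(~np.isfinite(w)):
        raise ValueError("some sampled persons fall in unweighted strata")
    return w


def weighted_area_pr(cohort: pd.DataFrame, y, mode: str = "unadjusted",
                     weights=None, fit=None, X=None) -> pd.DataFrame:
    """Per-area prevalence ratios PR_j = O_j / e_j, optionally weighted.

    Both offset modes are supported: ``unadjusted`` (overall prevalence x
    area size) and ``adjusted`` (stage-1 fitted probabilities).  Weights, when
    given, enter both the observed counts and the expectations.  Areas with
    zero expectation are excluded and logged.
    """
    tbl = expected_counts(cohort, y, mode=mode, fit=fit, X=X, weights=weights)
    zero = tbl["e_j"] <= 0
    if zero.any():
        logger.info("excluding %d areas with zero expectation", int(zero.sum()))
        tbl = tbl[~zero]
    tbl = tbl.copy()
    tbl["pr"] = tbl["observed"] / tbl["e_j"]
    return tbl[["area_id", "observed", "n_j", "e_j", "pr"]]


def compare_pr(unweighted: pd.DataFrame, weighted: pd.DataFrame):
    """Pearson correlation between paired area PRs, plus the scatter table.

    Areas are matched on ``area_id``; returns ``(r, scatter)`` where r is NaN
    if either PR vector has zero variance.
    """
    merged = unweighted.merge(weighted, on="area_id",
                              suffixes=("_unweighted", "_weighted"))
    if len(merged) < 3:
        raise ValueError("need >=3 areas to correlate")
    a = merged["pr_unweighted"].to_numpy()
    b = merged["pr_weighted"].to_numpy()
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return float("nan"), merged
    if np.array_equal(a, b):
        r = 1.0
    else:
        r = float(pearsonr(a, b).statistic)
    scatter = merged[["area_id", "pr_unweighted", "pr_weighted"]]
    return r, scatter


def uniform_benchmark(cohort: pd.DataFrame, rate: float = 0.1,
                      keys=STRATUM_KEYS) -> pd.DataFrame:
    """Synthetic benchmark population: sample cells scaled up by 1/rate.

    Emulates a census benchmark for a cohort sampled uniformly at ``rate``
    from the population, for weighting checks on generated data.
    """
    bench = (cohort.groupby(keys, observed=True).size()
             .rename("count").reset_index())
    bench["count"] = np.maximum((bench["count"] / rate).round(), 1).astype(int)
    return bench
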