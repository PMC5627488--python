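"""Physical-activity outcome derivation from weekly activity items.

The survey instrument records, separately for walking, moderate and vigorous
activity, the number of sessions in the last week and the total minutes spent.
Three guideline-based binary outcomes are derived:

* **sufficient walking** — >=150 weekly minutes of walking over >=5 walking
  sessions (meets the activity guideline from walking alone);
* **sufficient MVPA** — >=150 weekly minutes of moderate-and-vigorous
  physical activity (vigorous minutes double-weighted for intensity) over
  >=5 sessions of any type;
* **high MVPA** — >=300 weekly MVPA minutes over >=5 sessions.

All thresholds are inclusive.  Sufficient walking implies sufficient MVPA
(walking minutes and sessions count toward MVPA) and high MVPA implies
sufficient MVPA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ITEM_COLUMNS = ["walk_times", "mod_times", "vig_times",
                "walk_min", "mod_min", "vig_min"]

OUTCOME_NAMES = ["sufficient_walking", "sufficient_mvpa", "high_mvpa"]


def _validate_items(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing activity items: {missing}")
    vals = df[ITEM_COLUMNS]
    if (vals.to_numpy() < 0).any():
        raise ValueError("activity items must be nonnegative")
    return df


def mvpa_minutes(week) -> np.ndarray:
    """Weekly MVPA minutes: walk_min + mod_min + 2 * vig_min.

    Vigorous minutes are double-weighted to reflect their greater intensity.
    Accepts a DataFrame of activity items or anything coercible to one.
    """
    df = _validate_items(pd.DataFrame(week))
    out = (df["walk_min"] + df["mod_min"] + 2 * df["vig_min"]).to_numpy()
    return out


def classify(week) -> pd.DataFrame:
    """Derive the three outcome flags from weekly activity items.

    Returns a DataFrame with boolean columns ``sufficient_walking``,
    ``sufficient_mvpa`` and ``high_mvpa`` aligned with the input rows.
    """
    df = _validate_items(pd.DataFrame(week))
    total_min = mvpa_minutes(df)
    sessions = (df["walk_times"] + df["mod_times"] + df["vig_times"]).to_numpy()
    flags = pd.DataFrame(index=df.index)
    flags["sufficient_walking"] = (
        (df["walk_min"].to_numpy() >= 150) & (df["walk_times"].to_numpy() >= 5)
    )
    flags["sufficient_mvpa"] = (total_min >= 150) & (sessions >= 5)
    flags["high_mvpa"] = (total_min >= 300) & (sessions >= 5)
    return flags


def cohort_prevalence(flags, strata=None, outcome=None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Stratified outcome prevalence with Wald 95% confidence intervals.

    Parameters
    ----------
    flags
        DataFrame holding boolean outcome columns and (optionally) stratum
        columns.
    strata
        Column name(s) to stratify on; ``None`` pools the whole cohort.
    outcome
        Outcome column(s); defaults to every recognised outcome present.

    Returns one row per stratum x outcome with ``n`` (stratum size),
    ``events``, ``percent`` and the Wald interval bounds (percent scale).
    Empty strata yield missing percents.
    """
    from scipy.stats import norm

    flags = pd.DataFrame(flags)
    if outcome is None:
        outcome = [c for c in OUTCOME_NAMES if c in flags.columns]
    elif isinstance(outcome, str):
        outcome = [outcome]
    if not outcome:
        raise ValueError("no outcome columns found")
    if flags.empty:
        raise ValueError("empty cohort")
    z = norm.ppf(1 - alpha / 2)

    def summarise(group, label):
        rows = []
        n = len(group)
        for oc in outcome:
            events = int(group[oc].sum())
            if n == 0:
                pct = lo = hi = np.nan
            else:
                p = events / n
                se = np.sqrt(p * (1 - p) / n)
                pct, lo, hi = 100 * p, 100 * (p - z * se), 100 * (p + z * se)
            rows.append(
                {"stratum": label, "outcome": oc, "n": n, "events": events,
                 "percent": pct, "ci_low": lo, "ci_high": hi}
            )
        return rows

    records = []
    if strata is None:
        records += summarise(flags, "all")
    else:
        if isinstance(strata, str):
            strata = [strata]
        for key, group in flags.groupby(strata, observed=True, sort=True):
            label = key if len(strata) > 1 else key
            if isinstance(label, tuple) and len(label) == 1:
                label = label[0]
            records += summarise(group, label)
    return pd.DataFrame.from_records(records)


def pooled_prevalence(events, totals) -> float:
    """Percent prevalence pooled over strata: 100 * sum(events) / sum(n)."""
    events = np.asarray(events, float)
    totals = np.asarray(totals, float)
    if totals.sum() <= 0:
        raise ValueError("empty pooled denominator")
    return float(100.0 * events.sum() / totals.sum())
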