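"""Published summary counts from the emulated cohort study.

The synthetic generator emulates a large Sydney cohort study of adults aged
45 and over (95,837 respondents with complete activity data, of 115,153
geocoded to the study region).  The published outcome counts by area-level
walkability quartile, reproduced below, serve as worked-example inputs for
the prevalence machinery and as cross-checks: pooling them recovers the
published cohort prevalences (31.7% sufficient walking, 69.4% sufficient
MVPA, 56.1% high MVPA).
"""

#: respondents and outcome events by walkability quartile of residence
WALKABILITY_STRATA = {
    "low": {
        "n": 26435, "sufficient_walking": 7582,
        "sufficient_mvpa": 18079, "high_mvpa": 14763,
    },
    "low_medium": {
        "n": 32696, "sufficient_walking": 9854,
        "sufficient_mvpa": 22225, "high_mvpa": 17961,
    },
    "medium_high": {
        "n": 20299, "sufficient_walking": 6565,
        "sufficient_mvpa": 14119, "high_mvpa": 11388,
    },
    "high": {
        "n": 16407, "sufficient_walking": 6353,
        "sufficient_mvpa": 12087, "high_mvpa": 9668,
    },
}

#: respondents with complete data / respondents geocoded to the study region
COMPLETE_DATA = (95837, 115153)


def stratum_counts(outcome: str):
    """(events, totals) arrays over walkability strata for one outcome."""
    events = [v[outcome] for v in WALKABILITY_STRATA.values()]
    totals = [v["n"] for v in WALKABILITY_STRATA.values()]
    return events, totals
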