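"""Individual-level covariate catalogue.

Thirteen demographic, socioeconomic and health covariates measured on a large
Sydney cohort of adults aged 45 and over.  The stratum counts below are the
published sample margins of that cohort (n = 95,837 respondents with complete
data); they are the default category frequencies of the synthetic-cohort
generator and define the dummy coding of the stage-1 logistic model.

Reference levels follow the published full-model presentation (male,
youngest age band, English at home, university degree, partnered, full-time
work, private insurance with extras, never smoked, normal weight, zero
chronic conditions, no functional limitation, no emotional problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: stratum counts per covariate level (cohort margins, n = 95,837)
MARGIN_COUNTS = {
    "sex": {"male": 46099, "female": 49738},
    "age_group": {
        "45-49": 13605, "50-54": 16843, "55-59": 17008, "60-64": 14114,
        "65-69": 10703, "70-74": 7387, "75-79": 5519, "80-84": 7464,
        "85+": 3194,
    },
    "language": {"english": 81196, "other": 14641},
    "education": {
        "university": 29484, "trade_certificate_diploma": 30119,
        "secondary": 28177, "less_than_secondary": 8057,
    },
    "relationship": {"partner": 71083, "no_partner": 24754},
    "employment": {
        "full_time": 33116, "part_time": 13509, "other_work": 1417,
        "not_working": 47795,
    },
    "insurance": {
        "private_extras": 55802, "private_no_extras": 13597,
        "health_care_card": 12977, "none": 13461,
    },
    "smoking": {"never": 56362, "past": 32897, "current": 6578},
    "body_mass": {
        "normal": 37712, "underweight": 1360, "overweight": 37271,
        "obese": 19494,
    },
    "dx_conditions": {"0": 32167, "1": 38557, "2": 19082, "3+": 6031},
    "rx_conditions": {"0": 42523, "1": 31399, "2": 15478, "3+": 6437},
    "functional_limitation": {
        "none": 33079, "minor": 25661, "moderate": 21192, "severe": 15905,
    },
    "emotional_problems": {
        "none": 67240, "minor": 13394, "moderate": 7638, "severe": 7565,
    },
}

REFERENCE_LEVELS = {
    "sex": "male",
    "age_group": "45-49",
    "language": "english",
    "education": "university",
    "relationship": "partner",
    "employment": "full_time",
    "insurance": "private_extras",
    "smoking": "never",
    "body_mass": "normal",
    "dx_conditions": "0",
    "rx_conditions": "0",
    "functional_limitation": "none",
    "emotional_problems": "none",
}


def default_margins() -> dict:
    """Covariate -> {level: probability}, normalised from the cohort counts."""
    out = {}
    for cov, counts in MARGIN_COUNTS.items():
        total = sum(counts.values())
        out[cov] = {lvl: c / total for lvl, c in counts.items()}
    return out


@dataclass
class CovariateSpec:
    """Ordered covariates with declared levels and a reference level each.

    The dummy (reference-cell) coding of the stage-1 logistic design is fully
    determined by this spec: one column per non-reference level, covariates
    and levels in declared order.
    """

    levels: dict = field(default_factory=lambda: {
        cov: list(cnt) for cov, cnt in MARGIN_COUNTS.items()
    })
    reference: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    def __post_init__(self):
        for cov, ref in self.reference.items():
            if ref not in self.levels[cov]:
                raise ValueError(f"reference {ref!r} not a level of {cov!r}")

    @property
    def covariates(self) -> list:
        return list(self.levels)

    def column_names(self) -> list:
        """Design column names: intercept then covariate=level dummies."""
        cols = ["intercept"]
        for cov in self.covariates:
            for lvl in self.levels[cov]:
                if lvl != self.reference[cov]:
                    cols.append(f"{cov}={lvl}")
        return cols

    def validate(self, cohort) -> None:
        """Raise if any cohort value falls outside the declared levels."""
        for cov in self.covariates:
            seen = set(cohort[cov].unique())
            extra = seen - set(self.levels[cov])
            if extra:
                raise ValueError(
                    f"unseen categories for {cov!r}: {sorted(extra)}"
                )


def margin_probabilities(margins: dict) -> dict:
    """Validate and return margins as arrays; probabilities must sum to 1."""
    out = {}
    for cov, probs in margins.items():
        lvls = list(probs)
        p = np.array([probs[l] for l in lvls], float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"margins for {cov!r} sum to {p.sum()}, not 1")
        if np.any(p < 0):
            raise ValueError(f"negative margin probability in {cov!r}")
        out[cov] = (lvls, p)
    return out
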