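"""Synthetic study generator.

Emulates the statistical structure of an area-level walkability study on a
large metropolitan cohort: a lattice of ~256 contiguous small areas (queen
contiguity), spatially autocorrelated built-environment fields, a cohort of
middle-aged-and-older respondents allocated unevenly to areas, and binary
activity outcomes driven by known area-level effects — an ICAR-structured
spatial field ``s``, an iid heterogeneity field ``u``, and log-prevalence-
ratio covariate effects — so that every downstream stage (index construction,
stage-1 adjustment, BYM ecological regression, variance partitioning,
weighting) can be tested against ground truth without any external data.

Outcomes are simulated with a log link on probability, so the ground-truth
covariate effects are prevalence ratios, the scale on which the spatial model
reports its estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from . import covariates as cov
from .lattice import AreaLattice, grid_lattice, connected_components
from .outcomes import classify, OUTCOME_NAMES
from .walkability import LAND_USE_CLASSES

logger = logging.getLogger(__name__)

#: target marginal prevalences of the three outcomes (study conditions)
TARGET_PREVALENCE = {
    "sufficient_walking": 0.317,
    "sufficient_mvpa": 0.694,
    "high_mvpa": 0.561,
}

DISADVANTAGE_LABELS = ["q1_most", "q2", "q3_middling", "q4", "q5_least"]


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Simulation ground truth and problem size.

    ``truth_beta`` maps covariate name -> {level: log prevalence ratio};
    covariates may be area-level (e.g. ``walkability``) or individual-level.
    ``spatial_range`` controls the smoothness of the environment fields (0 =
    independent areas).  ``truth_tau_s``/``truth_tau_u`` are the precisions of
    the ICAR and heterogeneity fields.  ``allocation_sigma`` is the log-scale
    spread of area sampling weights (1.0 reproduces a heavily skewed
    respondents-per-area distribution, max/median ~ 13).
    """

    n_areas: int = 256
    grid_side: int = None
    seed: int = 0
    spatial_range: float = 1.5
    truth_beta: dict = field(default_factory=dict)
    truth_tau_s: float = 10.0
    truth_tau_u: float = 10.0
    cohort_size: int = 20000
    covariate_margins: dict = field(default_factory=cov.default_margins)
    baseline_prevalence: float = None  # default: TARGET_PREVALENCE[outcome]
    outcome: str = "sufficient_walking"
    allocation_sigma: float = 1.0
    land_area_median_km2: float = 7.6
    land_area_sigma: float = 0.6

    def __post_init__(self):
        if self.grid_side is not None:
            if self.grid_side < 2:
                raise ConfigError("grid_side must be >= 2")
            self.n_areas = self.grid_side ** 2
        elif self.n_areas < 4:
            raise ConfigError("n_areas must be >= 4")
        if self.truth_tau_s <= 0 or self.truth_tau_u <= 0:
            raise ConfigError("precisions must be positive")
        if self.outcome not in OUTCOME_NAMES:
            raise ConfigError(f"unknown outcome {self.outcome!r}")
        if not self.covariate_margins:
            raise ConfigError("covariate_margins must be nonempty")
        cov.margin_probabilities(self.covariate_margins)  # validates sums

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage substream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


# --------------------------------------------------------------------- lattice
def generate_lattice(config: GeneratorConfig) -> AreaLattice:
    """Square-grid lattice with queen contiguity and lognormal land areas."""
    if config.grid_side is not None:
        sx = sy = config.grid_side
    else:
        sx = int(np.ceil(np.sqrt(config.n_areas)))
        sy = int(np.ceil(config.n_areas / sx))
    rng = config.rng(0)
    n = sx * sy
    land = np.exp(
        np.log(config.land_area_median_km2)
        + config.land_area_sigma * rng.standard_normal(n)
    )
    return grid_lattice(sx, sy, land_area_km2=land)


def gaussian_markov_field(lattice: AreaLattice, rng, spatial_range: float,
                          size: int = 1) -> np.ndarray:
    """Standardised spatially smooth field(s) on the lattice graph.

    White noise is smoothed by solving (I + r*L) z = eps with L the graph
    Laplacian; r = ``spatial_range`` >= 0 controls smoothness (r = 0 gives
    iid fields).  Each field is re-standardised to zero mean, unit variance.
    """
    n = lattice.n
    eps = rng.standard_normal((n, size))
    if spatial_range > 0:
        W = lattice.adjacency_matrix()
        L = sp.diags(np.asarray(lattice.degrees(), float)) - W
        A = (sp.eye(n) + spatial_range * L).tocsc()
        z = spsolve(A, eps)
        z = np.atleast_2d(z.T).T if z.ndim == 1 else z
        z = z.reshape(n, size)
    else:
        z = eps
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    return z[:, 0] if size == 1 else z


def icar_sample(lattice_or_W, tau_s: float, rng) -> np.ndarray:
    """Exact draw from the (centered) intrinsic CAR distribution.

    Uses the eigen-decomposition of the graph Laplacian Q = D - W: the draw
    is built from the eigenvectors with nonzero eigenvalue, scaled by
    1/sqrt(tau_s * lambda), which makes it orthogonal to the constant vector
    on every connected component (per-component sum-to-zero).  Exact on the
    small graphs used here.
    """
    if isinstance(lattice_or_W, AreaLattice):
        W = lattice_or_W.adjacency_matrix().toarray()
    else:
        W = np.asarray(lattice_or_W, float)
    deg = W.sum(axis=1)
    Q = np.diag(deg) - W
    lam, V = np.linalg.eigh(Q)
    keep = lam > 1e-10
    z = rng.standard_normal(keep.sum())
    s = V[:, keep] @ (z / np.sqrt(tau_s * lam[keep]))
    return s


# ----------------------------------------------------------------- environment
def generate_environment(lattice: AreaLattice, config: GeneratorConfig) -> pd.DataFrame:
    """Built-environment table: one row per area.

    Three positive, spatially autocorrelated measures sharing a latent
    "walkability" factor (so decile structure is monotone across quartiles),
    plus a five-class land-use decomposition that sums exactly to the land
    area, and a spatially smooth socioeconomic-disadvantage quintile.
    Magnitudes emulate a metropolitan range: dwelling densities ~0.1-200 per
    ha, intersection densities ~0.1-700 per km**2, land-use entropies mostly
    below 0.2.
    """
    if lattice.n == 0:
        raise ConfigError("empty lattice")
    rng = config.rng(1)
    n = lattice.n
    zw = gaussian_markov_field(lattice, rng, config.spatial_range)  # shared factor
    e1, e2, e3 = rng.standard_normal((3, n))

    res_density = np.exp(np.log(12.0) + 1.15 * zw + 0.45 * e1)
    int_density = np.exp(np.log(45.0) + 1.05 * zw + 0.45 * e2)

    land = lattice.land_area_km2
    # non-residential share drives land-use evenness (hence entropy)
    eps_mix = np.clip(np.exp(np.log(0.03) + 1.2 * zw + 0.5 * e3), 1e-4, 0.8)
    class_res = (1.0 - eps_mix) * land
    split = rng.dirichlet(np.ones(4), size=n)
    class_rest = split * (eps_mix * land)[:, None]

    residential_land_ha = class_res * 100.0  # km**2 -> ha
    dwellings = np.rint(res_density * residential_land_ha).astype(int)
    intersections = np.rint(int_density * land).astype(int)

    zd = gaussian_markov_field(lattice, rng, config.spatial_range)
    quint = pd.qcut(pd.Series(zd).rank(method="first"), 5,
                    labels=DISADVANTAGE_LABELS)

    env = pd.DataFrame({
        "area_id": lattice.area_ids,
        "residential_dwellings": dwellings,
        "residential_land_ha": residential_land_ha,
        "intersections_3plus": intersections,
        "land_area_km2": land,
    })
    env["class_residential_km2"] = class_res
    for i, c in enumerate(LAND_USE_CLASSES[1:]):
        env[f"class_{c}_km2"] = class_rest[:, i]
    env["disadvantage"] = pd.Categorical(quint, categories=DISADVANTAGE_LABELS,
                                         ordered=True)
    return env


# ---------------------------------------------------------------------- cohort
def simulate_cohort(lattice: AreaLattice, config: GeneratorConfig) -> pd.DataFrame:
    """Respondent table: area allocation plus independent covariate draws.

    Areas receive respondents with multinomial probabilities proportional to
    lognormal weights (sigma = ``allocation_sigma``), reproducing a heavily
    skewed respondents-per-area distribution.  Covariates are drawn
    independently from the configured margins.
    """
    if config.cohort_size < lattice.n:
        raise ConfigError("cohort_size must be >= number of areas")
    rng = config.rng(2)
    n = lattice.n
    w = np.exp(config.allocation_sigma * rng.standard_normal(n))
    counts = rng.multinomial(config.cohort_size, w / w.sum())
    area_col = np.repeat(np.asarray(lattice.area_ids), counts)
    m = area_col.size
    cohort = pd.DataFrame({"person_id": np.arange(m), "area_id": area_col})
    for name, (levels, probs) in cov.margin_probabilities(
            config.covariate_margins).items():
        draws = rng.choice(len(levels), size=m, p=probs)
        cohort[name] = pd.Categorical.from_codes(draws, categories=levels)
    return cohort


# -------------------------------------------------------------------- outcomes
def simulate_outcomes(cohort: pd.DataFrame, lattice: AreaLattice,
                      config: GeneratorConfig,
                      area_covariates: pd.DataFrame = None):
    """Draw outcome flags with known area effects; returns (flags, truth).

    The configured outcome is generated from the log-link model
    ``p_i = exp(log p0 + x_i beta_true + s_j(i) + u_j(i))`` clipped to
    (0, 0.99), with ``s`` an exact ICAR draw (per-component sum-to-zero) and
    ``u`` iid normal.  The remaining two outcomes are filled in from fixed
    conditional probabilities chosen to match the target margins while
    preserving the logical implications (sufficient walking => sufficient
    MVPA; high MVPA => sufficient MVPA).

    ``truth`` holds ``s_true``, ``u_true``, ``beta_true``, ``p0`` and the
    per-person linear predictor, for recovery tests.
    """
    rng = config.rng(3)
    n = lattice.n
    s_true = icar_sample(lattice, config.truth_tau_s, rng)
    u_true = rng.normal(0.0, 1.0 / np.sqrt(config.truth_tau_u), n)
    p0 = (config.baseline_prevalence if config.baseline_prevalence is not None
          else TARGET_PREVALENCE[config.outcome])

    merged = cohort
    if area_covariates is not None:
        merged = cohort.merge(area_covariates, on="area_id", how="left",
                              validate="many_to_one")
    xb = np.zeros(len(cohort))
    for name, effects in config.truth_beta.items():
        if name not in merged.columns:
            raise ConfigError(f"truth_beta covariate {name!r} not available")
        col = merged[name].astype(str)
        for level, logpr in effects.items():
            xb += np.where(col == level, logpr, 0.0)

    aidx = np.array([lattice.index_of(a) for a in cohort["area_id"]])
    eta = np.log(p0) + xb + s_true[aidx] + u_true[aidx]
    p_raw = np.exp(eta)
    frac_over = float(np.mean(p_raw > 1.0))
    if frac_over > 0.01:
        warnings.warn(
            f"simulation regime too extreme: {100 * frac_over:.1f}% of "
            "persons had pre-clipping probability > 1", stacklevel=2)
    p = np.clip(p_raw, 1e-12, 0.99)
    y = rng.random(len(cohort)) < p

    flags = pd.DataFrame(index=cohort.index)
    t = TARGET_PREVALENCE
    if config.outcome == "sufficient_walking":
        walk = y
        p_extra = (t["sufficient_mvpa"] - t["sufficient_walking"]) / (
            1 - t["sufficient_walking"])
        mvpa = walk | (rng.random(len(cohort)) < p_extra)
        high = mvpa & (rng.random(len(cohort))
                       < t["high_mvpa"] / t["sufficient_mvpa"])
    elif config.outcome == "sufficient_mvpa":
        mvpa = y
        walk = mvpa & (rng.random(len(cohort))
                       < t["sufficient_walking"] / t["sufficient_mvpa"])
        high = mvpa & (rng.random(len(cohort))
                       < t["high_mvpa"] / t["sufficient_mvpa"])
    else:  # high_mvpa
        high = y
        p_extra = (t["sufficient_mvpa"] - t["high_mvpa"]) / (1 - t["high_mvpa"])
        mvpa = high | (rng.random(len(cohort)) < p_extra)
        walk = mvpa & (rng.random(len(cohort))
                       < t["sufficient_walking"] / t["sufficient_mvpa"])
    flags["sufficient_walking"] = walk
    flags["sufficient_mvpa"] = mvpa
    flags["high_mvpa"] = high

    truth = {"s_true": s_true, "u_true": u_true,
             "beta_true": dict(config.truth_beta), "p0": p0,
             "linear_predictor": eta}
    return flags, truth


# ----------------------------------------------------------------------- items
def synthesize_activity_items(flags: pd.DataFrame, seed_or_rng=0) -> pd.DataFrame:
    """Weekly activity items consistent with given outcome flags.

    Builds sessions/minutes for walking, moderate and vigorous activity such
    that re-deriving the outcomes from the items (``outcomes.classify``)
    reproduces the input flags exactly, while respecting the container
    invariants (minutes are 0 iff the matching sessions are 0).
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    w = flags["sufficient_walking"].to_numpy()
    m = flags["sufficient_mvpa"].to_numpy()
    h = flags["high_mvpa"].to_numpy()
    if np.any(w & ~m) or np.any(h & ~m):
        raise ValueError("flags violate outcome implications")
    n = len(flags)
    wt = np.zeros(n, int); wm = np.zeros(n, int)
    mt = np.zeros(n, int); mm = np.zeros(n, int)
    vt = np.zeros(n, int); vm = np.zeros(n, int)

    # -- sufficient walkers (=> sufficient MVPA)
    c = w & h
    k = int(c.sum())
    if k:
        wt[c] = 5 + rng.poisson(2, k)
        wm[c] = 150 + np.rint(rng.exponential(100, k)).astype(int)
        vt[c] = rng.poisson(1, k)
        vm[c] = 15 * vt[c]
        mt[c] = 1 + rng.poisson(1, k)
        need = np.maximum(300 - wm[c] - 2 * vm[c], 0)
        mm[c] = need + 10 + np.rint(rng.exponential(30, k)).astype(int)
    c = w & ~h
    k = int(c.sum())
    if k:
        wt[c] = 5 + rng.poisson(2, k)
        wm[c] = 150 + rng.integers(0, 100, k)          # <= 249
        mt[c] = rng.poisson(1, k)
        budget = 299 - wm[c]                            # total stays < 300
        mm[c] = np.where(mt[c] > 0,
                         1 + rng.integers(0, np.maximum(budget, 1), k), 0)
        mm[c] = np.minimum(mm[c], budget)

    # -- sufficient MVPA without sufficient walking
    c = ~w & m & h
    k = int(c.sum())
    if k:
        wt[c] = rng.integers(0, 5, k)
        wm[c] = wt[c] * rng.integers(5, 21, k)          # < 150 always
        mt[c] = np.maximum(5 - wt[c], 1) + rng.poisson(1, k)
        vt[c] = rng.poisson(0.7, k)
        vm[c] = 10 * vt[c]
        need = np.maximum(300 - wm[c] - 2 * vm[c], 10)
        mm[c] = need + np.rint(rng.exponential(40, k)).astype(int)
    c = ~w & m & ~h
    k = int(c.sum())
    if k:
        wt[c] = rng.integers(0, 5, k)
        wm[c] = wt[c] * rng.integers(5, 21, k)          # <= 80
        mt[c] = np.maximum(5 - wt[c], 1) + rng.poisson(1, k)
        mm[c] = (150 - wm[c]) + rng.integers(0, 150, k)  # total in [150, 299]
        mm[c] = np.minimum(mm[c], 299 - wm[c])

    # -- insufficient MVPA: too few sessions, or too few minutes
    c = ~m
    k = int(c.sum())
    if k:
        few_sessions = rng.random(k) < 0.6
        wt_c = np.where(few_sessions, rng.integers(0, 3, k), rng.integers(0, 5, k))
        mt_c = np.where(few_sessions, rng.integers(0, 3, k),
                        5 - wt_c + rng.poisson(1, k))
        mt_c = np.where(few_sessions, np.minimum(mt_c, 4 - wt_c), mt_c)
        wm_c = wt_c * rng.integers(5, 16, k)            # <= 60 minutes
        mm_c = np.where(mt_c > 0, 1 + rng.integers(0, 80, k), 0)
        total = wm_c + mm_c
        over = total > 149                              # keep minutes < 150
        mm_c = np.where(over & (mt_c > 0), np.maximum(149 - wm_c, 1), mm_c)
        mm_c = np.where(mt_c > 0, mm_c, 0)
        wt[c], wm[c], mt[c], mm[c] = wt_c, wm_c, mt_c, mm_c

    items = pd.DataFrame(
        {"walk_times": wt, "mod_times": mt, "vig_times": vt,
         "walk_min": wm, "mod_min": mm, "vig_min": vm}, index=flags.index)
    check = classify(items)
    for col in OUTCOME_NAMES:
        if not np.array_equal(check[col].to_numpy(), flags[col].to_numpy()):
            raise AssertionError(f"item synthesis inconsistent for {col}")
    return items


# --------------------------------------------------------------------- bundles
def simulate_study(config: GeneratorConfig) -> dict:
    """Full synthetic study: lattice, environment, walkability, cohort, truth.

    Convenience wrapper running every generator stage with per-stage
    substreams of ``config.seed``.  The returned cohort includes activity
    items consistent with the simulated flags, so the outcome-derivation
    stage can be exercised end-to-end.
    """
    from .walkability import walkability_scores

    lattice = generate_lattice(config)
    env = generate_environment(lattice, config)
    scores = walkability_scores(env)
    area_cov = scores[["area_id", "quartile"]].rename(
        columns={"quartile": "walkability"})
    area_cov = area_cov.merge(env[["area_id", "disadvantage"]], on="area_id")
    cohort = simulate_cohort(lattice, config)
    flags, truth = simulate_outcomes(cohort, lattice, config, area_cov)
    items = synthesize_activity_items(flags, config.rng(4))
    cohort = pd.concat([cohort, items, flags], axis=1)
    return {"lattice": lattice, "environment": env, "scores": scores,
            "area_covariates": area_cov, "cohort": cohort, "truth": truth}
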