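"""Synthetic-data generator: determinism, conservation, ground truth."""

import warnings

import numpy as np
import pandas as pd
import pytest

import walkmap as wm
from walkmap.synthetic import (ConfigError, GeneratorConfig,
                               synthesize_activity_items, TARGET_PREVALENCE)
from walkmap.walkability import LAND_USE_CLASSES


def cfg(**kw):
    kw.setdefault("grid_side", 8)
    kw.setdefault("cohort_size", 2000)
    kw.setdefault("seed", 3)
    return GeneratorConfig(**kw)


class TestConfig:
    def test_margins_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            cfg(covariate_margins={"sex": {"male": 0.6, "female": 0.5}})

    def test_precisions_must_be_positive(self):
        with pytest.raises(ConfigError):
            cfg(truth_tau_s=0.0)

    def test_tiny_lattice_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_areas=2)

    def test_empty_margins_rejected(self):
        with pytest.raises(ConfigError):
            cfg(covariate_margins={})


class TestEnvironment:
    def test_same_seed_identical(self):
        c = cfg()
        lat = wm.generate_lattice(c)
        env1 = wm.generate_environment(lat, c)
        env2 = wm.generate_environment(lat, c)
        pd.testing.assert_frame_equal(env1, env2)

    def test_class_areas_sum_to_land_area(self):
        c = cfg()
        lat = wm.generate_lattice(c)
        env = wm.generate_environment(lat, c)
        total = sum(env[f"class_{u}_km2"] for u in LAND_USE_CLASSES)
        np.testing.assert_allclose(total, env["land_area_km2"], atol=1e-9)

    def test_positive_autocorrelation_of_density(self):
        c = cfg(grid_side=12, spatial_range=1.5)
        lat = wm.generate_lattice(c)
        env = wm.generate_environment(lat, c)
        dens = env["residential_dwellings"] / env["residential_land_ha"]
        assert wm.morans_i(np.log(dens), lat) > 0.2

    def test_fields_positive(self):
        c = cfg()
        lat = wm.generate_lattice(c)
        env = wm.generate_environment(lat, c)
        assert (env["residential_land_ha"] > 0).all()
        assert (env["land_area_km2"] > 0).all()
        assert (env["intersections_3plus"] >= 0).all()


class TestCohort:
    def test_female_share_matches_margin(self):
        c = cfg(grid_side=10, cohort_size=40000)
        lat = wm.generate_lattice(c)
        cohort = wm.simulate_cohort(lat, c)
        share = (cohort["sex"] == "female").mean()
        assert share == pytest.approx(0.519, abs=0.01)

    def test_totals_conserved_and_deterministic(self):
        c = cfg()
        lat = wm.generate_lattice(c)
        c1 = wm.simulate_cohort(lat, c)
        c2 = wm.simulate_cohort(lat, c)
        assert len(c1) == c.cohort_size
        pd.testing.assert_frame_equal(c1, c2)

    def test_cohort_smaller_than_lattice_rejected(self):
        c = cfg()
        lat = wm.generate_lattice(c)
        c.cohort_size = 10
        with pytest.raises(ConfigError):
            wm.simulate_cohort(lat, c)

    def test_allocation_skew(self):
        """Skewed allocation produces a heavy-tailed respondents-per-area
        distribution, qualitatively like the emulated study (max >> median)."""
        c = cfg(grid_side=16, cohort_size=20000, allocation_sigma=1.0)
        lat = wm.generate_lattice(c)
        counts = wm.simulate_cohort(lat, c)["area_id"].value_counts()
        assert counts.max() / counts.median() > 4


class TestOutcomes:
    def test_null_model_prevalence(self):
        """No covariate effects, near-degenerate random effects: prevalence
        equals the baseline."""
        c = cfg(grid_side=10, cohort_size=30000, truth_tau_s=1e6,
                truth_tau_u=1e6, baseline_prevalence=0.30)
        lat = wm.generate_lattice(c)
        cohort = wm.simulate_cohort(lat, c)
        flags, truth = wm.simulate_outcomes(cohort, lat, c)
        assert flags["sufficient_walking"].mean() == pytest.approx(0.30, abs=0.01)

    def test_icar_truth_sums_to_zero(self):
        c = cfg()
        lat = wm.generate_lattice(c)
        cohort = wm.simulate_cohort(lat, c)
        _, truth = wm.simulate_outcomes(cohort, lat, c)
        assert abs(truth["s_true"].sum()) < 1e-9

    def test_fixed_seed_identical_outcomes(self):
        c = cfg()
        lat = wm.generate_lattice(c)
        cohort = wm.simulate_cohort(lat, c)
        f1, t1 = wm.simulate_outcomes(cohort, lat, c)
        f2, t2 = wm.simulate_outcomes(cohort, lat, c)
        pd.testing.assert_frame_equal(f1, f2)
        np.testing.assert_array_equal(t1["s_true"], t2["s_true"])

    def test_crude_prevalence_ratio_recovers_truth(self):
        """High-vs-low quartile crude PR averages ~1.2 over replicates."""
        prs = []
        for seed in range(20):
            c = cfg(grid_side=10, cohort_size=8000, seed=seed,
                    allocation_sigma=0.0, spatial_range=0.3,
                    truth_tau_s=100.0, truth_tau_u=100.0,
                    truth_beta={"walkability": {"high": float(np.log(1.2))}})
            study = wm.simulate_study(c)
            coh = study["cohort"].merge(study["area_covariates"], on="area_id")
            g = coh.groupby("walkability", observed=True)["sufficient_walking"].mean()
            prs.append(g["high"] / g["low"])
        assert np.mean(prs) == pytest.approx(1.2, abs=0.04)

    def test_extreme_regime_warns(self):
        c = cfg(baseline_prevalence=0.9,
                truth_beta={"sex": {"female": 1.0}})
        lat = wm.generate_lattice(c)
        cohort = wm.simulate_cohort(lat, c)
        with pytest.warns(UserWarning, match="too extreme"):
            wm.simulate_outcomes(cohort, lat, c)

    def test_icar_variance_monotone_in_precision(self):
        """Between-area variance of the ICAR draw decreases as tau_s grows."""
        lat = wm.grid_lattice(8)
        taus = [1.0, 10.0, 100.0]
        mean_vars = []
        for tau in taus:
            vs = [wm.icar_sample(lat, tau, np.random.default_rng(r)).var()
                  for r in range(50)]
            mean_vars.append(np.mean(vs))
        assert mean_vars[0] > mean_vars[1] > mean_vars[2]


class TestItemSynthesis:
    def test_items_reproduce_flags(self, small_study):
        flags = small_study["cohort"][
            ["sufficient_walking", "sufficient_mvpa", "high_mvpa"]]
        derived = wm.classify(small_study["cohort"])
        for col in flags:
            np.testing.assert_array_equal(derived[col], flags[col])

    def test_minutes_zero_iff_times_zero(self, small_study):
        c = small_study["cohort"]
        for act in ("walk", "mod", "vig"):
            zero_times = c[f"{act}_times"] == 0
            assert (c.loc[zero_times, f"{act}_min"] == 0).all()

    def test_inconsistent_flags_rejected(self):
        bad = pd.DataFrame({"sufficient_walking": [True],
                            "sufficient_mvpa": [False],
                            "high_mvpa": [False]})
        with pytest.raises(ValueError, match="implications"):
            synthesize_activity_items(bad)

    def test_marginal_prevalences_near_targets(self):
        c = cfg(grid_side=12, cohort_size=30000, truth_tau_s=50.0,
                truth_tau_u=50.0)
        study = wm.simulate_study(c)
        for oc, target in TARGET_PREVALENCE.items():
            assert study["cohort"][oc].mean() == pytest.approx(target, abs=0.03)
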