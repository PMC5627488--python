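"""Generate a synthetic walkability study and inspect its structure.

Builds a 16x16 areal lattice with queen contiguity, spatially autocorrelated
built-environment fields, and a 20,000-person cohort whose sufficient-walking
outcome carries a true high-vs-low walkability prevalence ratio of 1.2 plus
ICAR-structured and iid area effects.
"""

import numpy as np

import walkmap as wm

cfg = wm.GeneratorConfig(
    grid_side=16, cohort_size=20000, seed=7,
    truth_beta={"walkability": {"high": float(np.log(1.2))}})
study = wm.simulate_study(cfg)

lat = study["lattice"]
env = study["environment"]
cohort = study["cohort"]

dens = env["residential_dwellings"] / env["residential_land_ha"]
print(f"areas: {lat.n}, cohort: {len(cohort)}")
print(f"respondents per area: median {cohort['area_id'].value_counts().median():.0f}, "
      f"max {cohort['area_id'].value_counts().max()}")
print(f"Moran's I of log dwelling density: {wm.morans_i(np.log(dens), lat):.2f}")
print("outcome prevalence:",
      {c: round(float(cohort[c].mean()), 3)
       for c in ("sufficient_walking", "sufficient_mvpa", "high_mvpa")})
print(f"true ICAR field sums to {study['truth']['s_true'].sum():.2e} (centred)")

# Positive Moran's I says the environment is spatially clustered, as in real
# cities; the outcome prevalences sit near the cohort rates the generator
# emulates (31.7 / 69.4 / 56.1 percent).
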