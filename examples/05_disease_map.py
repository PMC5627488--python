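"""Export a disease map of excess prevalence ratios.

The excess PR exp(s_j + u_j) is each area's residual risk multiplier after
fixed effects; mapping it locates clusters the covariates do not explain.
Writes GeoJSON (and a PNG if matplotlib rendering is wanted).
"""

import warnings
from pathlib import Path

import numpy as np

import walkmap as wm
from walkmap.variance import export_choropleth, plot_choropleth

warnings.filterwarnings("ignore")

rng = np.random.default_rng(3)
lat = wm.grid_lattice(12)
s_true = wm.icar_sample(lat, 4.0, rng)
e = np.full(lat.n, 40.0)
O = rng.poisson(e * np.exp(s_true))

draws = wm.run_mcmc(wm.BYMModelSpec(O, e),
                    wm.ICARStructure.from_lattice(lat),
                    wm.MCMCConfig(iterations=6000, thin=4, seed=3))
epr = wm.excess_pr(draws)
print(f"excess PR range: {epr['excess_pr'].min():.2f} - "
      f"{epr['excess_pr'].max():.2f}")
print(f"correlation with truth exp(s): "
      f"{np.corrcoef(epr['excess_pr'], np.exp(s_true))[0, 1]:.2f}")

out = Path("scratch")
out.mkdir(exist_ok=True)
fc = export_choropleth(epr, lat, "excess_pr", path=out / "excess_pr.geojson")
plot_choropleth(fc, out / "excess_pr.png")
print(f"wrote {out/'excess_pr.geojson'} and {out/'excess_pr.png'}")
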