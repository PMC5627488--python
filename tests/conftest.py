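import numpy as np
import pytest

import walkmap as wm


@pytest.fixture(scope="session")
def small_study():
    """8x8 lattice, 4,000 persons, known high-walkability effect."""
    cfg = wm.GeneratorConfig(
        grid_side=8, cohort_size=4000, seed=42,
        truth_beta={"walkability": {"high": float(np.log(1.2))}})
    return wm.simulate_study(cfg)


@pytest.fixture(scope="session")
def grid4():
    return wm.grid_lattice(4)


@pytest.fixture(scope="session")
def mcmc_fit():
    """One BYM disease-mapping fit on area-level Poisson data (shared)."""
    rng = np.random.default_rng(7)
    lat = wm.grid_lattice(8)
    s = wm.icar_sample(lat, 5.0, rng)
    u = rng.normal(0, 0.2, lat.n)
    e = np.full(lat.n, 50.0)
    O = rng.poisson(e * np.exp(0.1 + s + u))
    spec = wm.BYMModelSpec(O, e)
    structure = wm.ICARStructure.from_lattice(lat)
    cfg = wm.MCMCConfig(iterations=6000, thin=4, seed=7)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = wm.run_mcmc(spec, structure, cfg)
    return {"draws": draws, "spec": spec, "structure": structure,
            "O": O, "e": e}
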