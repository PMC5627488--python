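"""Stage 2: Besag-York-Mollie (BYM) ecological regression by MCMC.

Area counts are modelled as ``O_j ~ Poisson(e_j * theta_j)`` with

    log(theta_j) = alpha + x_j' beta + s_j + u_j

where ``e_j`` is the expected-count offset from stage 1, ``alpha`` the
overall log relative risk, ``x_j`` optional area-level covariates
(walkability quartiles, disadvantage quintiles), ``s`` an intrinsic
conditional autoregressive (ICAR) spatial field and ``u`` iid normal
heterogeneity.  Precisions tau_s, tau_u carry Gamma(0.5, 0.0005) (shape,
rate) hyper-priors.  The ICAR impropriety is handled WinBUGS-style by
recentring ``s`` to sum zero every sweep, with the subtracted mean absorbed
into ``alpha``.

Sampling: conjugate Gibbs updates for the two precisions; adaptive
random-walk Metropolis for ``alpha``, each ``beta`` coefficient, the ``u``
field (sites conditionally independent, updated as one vector), and the
``s`` field updated in graph-colour blocks (sites within a colour class are
non-adjacent, hence conditionally independent given the rest).  Step sizes
adapt toward 44% acceptance during burn-in and are frozen afterwards to
preserve detailed balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

from .lattice import AreaLattice, connected_components

PRIOR_SHAPE = 0.5
PRIOR_RATE = 0.0005

LADDER_IDS = ["M1", "M2", "M3", "M4", "M5", "M6"]


# ------------------------------------------------------------------ structure
class ICARStructure:
    """Neighbourhood graph of the ICAR prior.

    Holds the symmetric adjacency, neighbour counts ``k_j``, island flags
    (areas with no neighbours contribute nothing to the ICAR kernel and have
    their spatial effect pinned at zero), a graph colouring used for blocked
    Metropolis updates, and the Laplacian rank ``n_active - n_components``
    entering the precision's Gibbs update.
    """

    def __init__(self, area_ids, neighbors: dict):
        self.area_ids = list(area_ids)
        self._index = {a: i for i, a in enumerate(self.area_ids)}
        n = len(self.area_ids)
        for a, nbrs in neighbors.items():
            if a in nbrs:
                raise ValueError(f"self-adjacency for {a}")
            for b in nbrs:
                if a not in neighbors.get(b, set()):
                    raise ValueError(f"asymmetric adjacency {a}~{b}")
        self.neighbors = {a: set(neighbors.get(a, set())) for a in self.area_ids}
        self.k = np.array([len(self.neighbors[a]) for a in self.area_ids])
        self.islands = self.k == 0
        rows, cols = [], []
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                rows.append(self._index[a])
                cols.append(self._index[b])
        self.W = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n))
        comps = [c for c in connected_components(self.neighbors)
                 if len(c) > 1]
        self.components = [np.array([self._index[a] for a in c]) for c in comps]
        self.rank = int((~self.islands).sum() - len(self.components))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(zip(rows, cols))
        colouring = nx.greedy_color(g, strategy="largest_first")
        classes = {}
        for node, col in colouring.items():
            if not self.islands[node]:
                classes.setdefault(col, []).append(node)
        self.colour_blocks = [np.array(sorted(v)) for _, v in sorted(classes.items())]

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @classmethod
    def from_lattice(cls, lattice: AreaLattice) -> "ICARStructure":
        return cls(lattice.area_ids, lattice.neighbors)

    def subset(self, area_ids) -> "ICARStructure":
        """Induced substructure on ``area_ids`` (data-absent areas removed
        from the graph; their former neighbours lose the corresponding
        edges)."""
        keep = set(area_ids)
        nbrs = {a: self.neighbors[a] & keep for a in self.area_ids if a in keep}
        return ICARStructure([a for a in self.area_ids if a in keep], nbrs)


def build_adjacency(src) -> ICARStructure:
    """ICAR structure from polygon geometry (GeoJSON path/dict or lattice).

    Two areas are neighbours iff their boundaries intersect in more than the
    empty set (queen rule: shared edges and shared corner points count).
    """
    if isinstance(src, AreaLattice):
        return ICARStructure.from_lattice(src)
    lattice = AreaLattice.from_geojson(src)
    return ICARStructure.from_lattice(lattice)


def icar_logkernel(s, tau_s: float, structure: ICARStructure) -> float:
    """ICAR log-density up to an additive constant.

    ``-(tau_s/2) * sum over adjacent pairs (i<j) of (s_i - s_j)**2``;
    islands contribute nothing.
    """
    s = np.asarray(s, float)
    if s.size != structure.n:
        raise ValueError(f"s has length {s.size}, expected {structure.n}")
    Ws = structure.W @ s
    quad = float(s @ (structure.k * s) - s @ Ws)  # = sum_{i~j} (s_i-s_j)^2 over ordered pairs
    return -0.5 * tau_s * quad


# ---------------------------------------------------------------------- specs
@dataclass
class BYMModelSpec:
    """Observed counts, offsets and area-level design for one model."""

    observed: np.ndarray
    offsets: np.ndarray
    design: np.ndarray = None          # (n, p) or None for intercept-only
    design_columns: list = field(default_factory=list)
    ladder_id: str = None
    prior_shape: float = PRIOR_SHAPE
    prior_rate: float = PRIOR_RATE
    beta_prior_sd: float = 100.0

    def __post_init__(self):
        self.observed = np.asarray(self.observed, float)
        self.offsets = np.asarray(self.offsets, float)
        if np.any(self.offsets <= 0):
            raise ValueError("offsets e_j must be positive")
        if self.design is not None:
            self.design = np.asarray(self.design, float)
            if self.design.shape[0] != self.observed.size:
                raise ValueError("design/counts length mismatch")
            if np.linalg.matrix_rank(
                    np.column_stack([np.ones(self.design.shape[0]), self.design])
            ) < self.design.shape[1] + 1:
                raise ValueError("design (with intercept) not full rank")

    @property
    def p(self) -> int:
        return 0 if self.design is None else self.design.shape[1]


@dataclass
class MCMCConfig:
    """Sampler schedule.  Retained draws = chains * iters * (1-burn)/thin."""

    n_chains: int = 2
    iterations: int = 40000
    thin: int = 10
    burn_in: float = 0.5
    seed: int = 0
    overdispersion: float = 0.5
    adapt_window: int = 50

    def __post_init__(self):
        if not (0 < self.burn_in < 1):
            raise ValueError("burn_in fraction must be in (0,1)")
        retained = self.n_chains * int(
            self.iterations * (1 - self.burn_in)) // self.thin
        if retained < 500:
            warnings.warn(
                f"only {retained} retained draws; >=500 recommended for inference",
                stacklevel=2)


class PosteriorDraws:
    """Retained MCMC samples, stacked per chain."""

    def __init__(self, alpha, beta, s, u, tau_s, tau_u, spec, structure,
                 accept_rates=None):
        self.alpha = alpha          # (C, T)
        self.beta = beta            # (C, T, p)
        self.s = s                  # (C, T, n)
        self.u = u                  # (C, T, n)
        self.tau_s = tau_s          # (C, T)
        self.tau_u = tau_u          # (C, T)
        self.spec = spec
        self.structure = structure
        self.accept_rates = accept_rates or {}

    @property
    def n_chains(self):
        return self.alpha.shape[0]

    @property
    def n_draws(self):
        return self.alpha.shape[1]

    def pooled(self, name):
        """Draws for one parameter with chains concatenated."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def eta_draws(self) -> np.ndarray:
        """Per-draw log relative risks (without the offset), (C*T, n)."""
        a = self.pooled("alpha")[:, None]
        eta = a + self.pooled("s") + self.pooled("u")
        if self.spec.design is not None:
            eta = eta + self.pooled("beta") @ self.spec.design.T
        return eta


# -------------------------------------------------------------------- sampler
def run_mcmc(spec: BYMModelSpec, structure: ICARStructure,
             config: MCMCConfig, include_spatial: bool = True,
             include_heterogeneity: bool = True) -> PosteriorDraws:
    """Sample the BYM posterior.  Fully deterministic given ``config.seed``.

    ``include_spatial`` / ``include_heterogeneity`` switch the two random
    effects off (useful for reduced oracle models such as the
    single-parameter Poisson fit).
    """
    O, E = spec.observed, spec.offsets
    n = O.size
    if structure.n != n:
        raise ValueError("structure/data size mismatch")
    X = spec.design
    p = spec.p
    binary_cols = []
    if p:
        for r in range(p):
            colvals = X[:, r]
            binary_cols.append(
                np.flatnonzero(colvals == 1.0)
                if set(np.unique(colvals)) <= {0.0, 1.0} else None)
    logE = np.log(E)
    k = structure.k.astype(float)
    W = structure.W
    active = ~structure.islands
    n_active = int(active.sum())
    blocks = structure.colour_blocks
    a_shape, a_rate = spec.prior_shape, spec.prior_rate
    bsd2 = spec.beta_prior_sd ** 2

    # smooth transfer basis: low-frequency eigenvectors of the Laplacian of
    # the active subgraph.  Moves along these fixed directions shuttle the
    # smooth component of the residual field between s and u (likelihood
    # unchanged, unit Jacobian), which is what single-site updates cannot do
    # once the precisions have adapted to the wrong mode.
    eigvecs = eigvals = None
    if include_spatial and include_heterogeneity and (~structure.islands).any():
        act_idx = np.flatnonzero(~structure.islands)
        Wa = structure.W[np.ix_(act_idx, act_idx)].toarray()
        Qa = np.diag(Wa.sum(axis=1)) - Wa
        lam_a, V_a = np.linalg.eigh(Qa)
        keepv = lam_a > 1e-10
        n_dir = min(12, int(keepv.sum()))
        order_v = np.argsort(lam_a[keepv])[:n_dir]
        Vk = V_a[:, keepv][:, order_v]
        eigvals = lam_a[keepv][order_v]
        eigvecs = np.zeros((len(structure.islands), n_dir))
        eigvecs[act_idx] = Vk

    n_keep = int(config.iterations * (1 - config.burn_in)) // config.thin
    burn = config.iterations - n_keep * config.thin
    C = config.n_chains
    out = {nm: np.zeros((C, n_keep)) for nm in ("alpha", "tau_s", "tau_u")}
    out["beta"] = np.zeros((C, n_keep, p))
    out["s"] = np.zeros((C, n_keep, n))
    out["u"] = np.zeros((C, n_keep, n))
    acc_report = {}

    for chain in range(C):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, chain]))
        sign = -1.0 if chain % 2 else 1.0
        alpha = sign * 2 * chain * config.overdispersion
        beta = np.full(p, sign * config.overdispersion * min(chain, 1))
        # seed the spatial field from the observed log-SMR residuals: a
        # zero field would make the first conjugate tau_s draw enormous and
        # freeze s at zero (a well-known BYM funnel).  Chains get different
        # scalings of the residual as over-dispersed starting fields.
        resid = np.log((O + 0.5) / E)
        resid -= resid.mean()
        factor = (0.5, 1.5, 0.25, 2.0)[chain % 4]
        s = np.where(active, factor * resid, 0.0)
        if n_active:
            s[active] -= s[active].mean()
        u = 0.1 * rng.standard_normal(n)
        tau_s = 0.1 if chain % 2 == 0 else 10.0
        tau_u = 10.0 if chain % 2 == 0 else 0.1
        if not include_spatial:
            s = np.zeros(n)
        if not include_heterogeneity:
            u = np.zeros(n)

        step_s = np.full(n, 0.5)
        step_u = np.full(n, 0.5)
        step_a = 0.1
        step_b = np.full(p, 0.2)
        n_dir = eigvecs.shape[1] if eigvecs is not None else 0
        step_t = np.full(n_dir, 0.3)
        acc_t = np.zeros(n_dir)
        acc_s = np.zeros(n)
        acc_u = np.zeros(n)
        acc_a = 0.0
        acc_b = np.zeros(p)
        frozen_rates = {}

        xb = X @ beta if p else 0.0
        lam = E * np.exp(alpha + xb + s + u)

        kept = 0
        for it in range(config.iterations):
            # --- spatial field, by colour blocks
            if include_spatial and n_active:
                for block in blocks:
                    Ws = W @ s
                    z = rng.standard_normal(block.size)
                    prop = s[block] + step_s[block] * z
                    d = prop - s[block]
                    dlik = O[block] * d - lam[block] * np.expm1(d)
                    dpri = -0.5 * tau_s * (
                        k[block] * (prop ** 2 - s[block] ** 2)
                        - 2.0 * Ws[block] * d)
                    acc = np.log(rng.random(block.size)) < dlik + dpri
                    idx = block[acc]
                    s[idx] = prop[acc]
                    lam[idx] *= np.exp(d[acc])
                    acc_s[block] += acc
                # recentre: absorb the mean into alpha (linear predictor kept)
                m = s[active].mean()
                s[active] -= m
                alpha += m

            # --- heterogeneity field (sites independent given the rest);
            # like s, the field is centred each sweep with the mean absorbed
            # into the flat-prior intercept, which keeps alpha identified and
            # makes the mode-swap move below exact
            if include_heterogeneity:
                z = rng.standard_normal(n)
                prop = u + step_u * z
                d = prop - u
                dlik = O * d - lam * np.expm1(d)
                dpri = -0.5 * tau_u * (prop ** 2 - u ** 2)
                acc = np.log(rng.random(n)) < dlik + dpri
                u[acc] = prop[acc]
                lam[acc] *= np.exp(d[acc])
                acc_u += acc
                mu_u = u.mean()
                u -= mu_u
                alpha += mu_u

            # --- reallocation move: shuttle variance between s and u while
            # keeping s_j + u_j (hence the likelihood) fixed; accepted on the
            # prior ratio alone.  Without it the two fields mix between their
            # near-equivalent modes extremely slowly.
            if include_spatial and include_heterogeneity and n_active:
                def prior_logdens(s_f, u_f):
                    quad = float(s_f @ (k * s_f) - s_f @ (W @ s_f))
                    return -0.5 * tau_s * quad - 0.5 * tau_u * float(u_f @ u_f)

                # (a) partial transfer s' = s + g(u-ubar), u' = u - g(u-ubar);
                # the linear map has Jacobian (1-g)^(n_active-1)
                ubar = u[active].mean()
                v = np.where(active, u - ubar, 0.0)
                gam = 0.3 * rng.standard_normal()
                if abs(1.0 - gam) > 1e-8:
                    s_prop = s + gam * v
                    u_prop = u - gam * v
                    logacc = (prior_logdens(s_prop, u_prop)
                              - prior_logdens(s, u)
                              + (n_active - 1) * np.log(abs(1.0 - gam)))
                    if np.log(rng.random()) < logacc:
                        s, u = s_prop, u_prop
                        ubar = u[active].mean()
                # (b) involutive mode swap (unit Jacobian): exchange the two
                # fields AND their precisions, jumping directly between the
                # s-dominant and u-dominant posterior modes.  The precision
                # normalising constants enter with exponents rank/2 (ICAR)
                # and (n-1)/2 (centred heterogeneity field).
                ubar = u[active].mean()
                s_prop = np.where(active, u - ubar, 0.0)
                u_prop = np.where(active, s + ubar, u)
                quad_s = float(s @ (k * s) - s @ (W @ s))
                quad_sp = float(s_prop @ (k * s_prop) - s_prop @ (W @ s_prop))
                logacc = (
                    -0.5 * tau_u * quad_sp - 0.5 * tau_s * float(u_prop @ u_prop)
                    + 0.5 * tau_s * quad_s + 0.5 * tau_u * float(u @ u)
                    + 0.5 * (structure.rank - (n - 1))
                    * (np.log(tau_u) - np.log(tau_s)))
                if np.log(rng.random()) < logacc:
                    s, u = s_prop, u_prop
                    tau_s, tau_u = tau_u, tau_s

                # (c) smooth-direction transfers: for each low-frequency
                # eigenvector phi (Q phi = lambda phi), propose
                # s' = s + g phi, u' = u - g phi; prior-only acceptance with
                # closed-form quadratic increments
                if eigvecs is not None:
                    gs = step_t * rng.standard_normal(eigvecs.shape[1])
                    for m in range(eigvecs.shape[1]):
                        phi = eigvecs[:, m]
                        g = gs[m]
                        sphi = float(s @ phi)
                        uphi = float(u @ phi)
                        dlog = (-0.5 * tau_s * (2 * g * eigvals[m] * sphi
                                                + g * g * eigvals[m])
                                - 0.5 * tau_u * (-2 * g * uphi + g * g))
                        if np.log(rng.random()) < dlog:
                            s = s + g * phi
                            u = u - g * phi
                            acc_t[m] += 1

            # --- intercept (flat prior)
            d = step_a * rng.standard_normal()
            dlik = O.sum() * d - np.expm1(d) * lam.sum()
            if np.log(rng.random()) < dlik:
                alpha += d
                lam *= np.exp(d)
                acc_a += 1

            # --- covariate effects
            for r in range(p):
                d = step_b[r] * rng.standard_normal()
                idx = binary_cols[r]
                if idx is not None:
                    dlik = O[idx].sum() * d - np.expm1(d) * lam[idx].sum()
                else:
                    dd = X[:, r] * d
                    dlik = float(O @ dd - lam @ np.expm1(dd))
                bnew = beta[r] + d
                dpri = -(bnew ** 2 - beta[r] ** 2) / (2 * bsd2)
                if np.log(rng.random()) < dlik + dpri:
                    beta[r] = bnew
                    if idx is not None:
                        lam[idx] *= np.exp(d)
                    else:
                        lam *= np.exp(X[:, r] * d)
                    acc_b[r] += 1

            # --- precisions (conjugate Gibbs)
            if include_spatial:
                quad = float(s @ (k * s) - s @ (W @ s))
                tau_s = rng.gamma(a_shape + 0.5 * structure.rank,
                                  1.0 / (a_rate + 0.5 * quad))
            if include_heterogeneity:
                # centred field: n-1 free dimensions
                tau_u = rng.gamma(a_shape + 0.5 * (n - 1),
                                  1.0 / (a_rate + 0.5 * float(u @ u)))

            # --- adaptation during burn-in only
            if it < burn and (it + 1) % config.adapt_window == 0:
                win = config.adapt_window
                step_s *= np.exp(0.6 * (acc_s / win - 0.44))
                step_u *= np.exp(0.6 * (acc_u / win - 0.44))
                step_a *= np.exp(0.6 * (acc_a / win - 0.44))
                if p:
                    step_b *= np.exp(0.6 * (acc_b / win - 0.44))
                if n_dir:
                    step_t *= np.exp(0.6 * (acc_t / win - 0.44))
                acc_s[:] = 0; acc_u[:] = 0; acc_a = 0.0; acc_t[:] = 0
                if p:
                    acc_b[:] = 0
                if it + config.adapt_window >= burn:
                    acc_s[:] = 0; acc_u[:] = 0; acc_a = 0.0; acc_t[:] = 0
                    if p:
                        acc_b[:] = 0

            if not np.all(np.isfinite(lam)):
                raise RuntimeError(
                    f"non-finite likelihood at iteration {it} (chain {chain})")

            # --- retain
            if it >= burn and (it - burn + 1) % config.thin == 0:
                out["alpha"][chain, kept] = alpha
                out["tau_s"][chain, kept] = tau_s
                out["tau_u"][chain, kept] = tau_u
                if p:
                    out["beta"][chain, kept] = beta
                out["s"][chain, kept] = s
                out["u"][chain, kept] = u
                kept += 1

        post_iters = config.iterations - burn
        rates = {
            "s": float(np.mean(acc_s[active]) / post_iters) if (include_spatial and n_active) else None,
            "u": float(np.mean(acc_u) / post_iters) if include_heterogeneity else None,
            "alpha": acc_a / post_iters,
        }
        if p:
            rates["beta"] = (acc_b / post_iters).tolist()
        acc_report[chain] = rates
        for nm, rate in rates.items():
            vals = rate if isinstance(rate, list) else [rate]
            for v in vals:
                if v is not None and not (0.1 <= v <= 0.6):
                    warnings.warn(
                        f"acceptance rate {v:.2f} for {nm} (chain {chain}) "
                        "outside [0.1, 0.6] after adaptation", stacklevel=2)

    return PosteriorDraws(out["alpha"], out["beta"], out["s"], out["u"],
                          out["tau_s"], out["tau_u"], spec, structure,
                          acc_report)


def prior_predictive_precisions(structure: ICARStructure, n_draws: int,
                                seed: int = 0,
                                shape: float = PRIOR_SHAPE,
                                rate: float = PRIOR_RATE):
    """Gibbs draws of (tau_s, tau_u) with the data term removed.

    Alternates exact field draws given the precisions with the conjugate
    precision updates; the stationary marginals of both precisions are the
    Gamma(shape, rate) hyper-prior, so this exposes the prior the sampler
    actually uses.
    """
    from .synthetic import icar_sample

    rng = np.random.default_rng(seed)
    n = structure.n
    tau_s, tau_u = 1.0, 1.0
    W = structure.W.toarray()
    k = structure.k.astype(float)
    ts = np.zeros(n_draws)
    tu = np.zeros(n_draws)
    for i in range(n_draws):
        s = icar_sample(W, tau_s, rng)
        u = rng.normal(0, 1 / np.sqrt(tau_u), n)
        quad = float(s @ (k * s) - s @ (W @ s))
        tau_s = rng.gamma(shape + 0.5 * structure.rank, 1 / (rate + 0.5 * quad))
        tau_u = rng.gamma(shape + 0.5 * n, 1 / (rate + 0.5 * float(u @ u)))
        ts[i], tu[i] = tau_s, tau_u
    return ts, tu


# ------------------------------------------------------------------------ DIC
def poisson_deviance(O, mu) -> np.ndarray:
    """-2 log Poisson likelihood (constants included), summed over areas."""
    mu = np.atleast_2d(mu)
    ll = O * np.log(mu) - mu - gammaln(O + 1.0)
    return -2.0 * ll.sum(axis=1)


def dic(draws: PosteriorDraws):
    """Deviance information criterion: (Dbar, pD, DIC).

    Dbar is the posterior mean deviance; Dhat the deviance at the posterior
    means of the per-area log rates (plug-in on the log-rate scale, the
    WinBUGS convention); pD = Dbar - Dhat and DIC = Dbar + pD.
    """
    if draws.n_chains * draws.n_draws < 2:
        raise ValueError("need at least 2 retained draws for DIC")
    O, E = draws.spec.observed, draws.spec.offsets
    eta = draws.eta_draws()
    mu = E[None, :] * np.exp(eta)
    dbar = float(poisson_deviance(O, mu).mean())
    eta_hat = eta.mean(axis=0)
    dhat = float(poisson_deviance(O, E * np.exp(eta_hat))[0])
    pd_ = dbar - dhat
    return dbar, pd_, dbar + pd_


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from >=2 equal-length chains.

    ``chains`` is (n_chains, n_draws).  Rhat = sqrt(((T-1)/T * W + B/T) / W)
    with B the between-chain and W the within-chain variance.
    """
    x = np.asarray(chains, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >=2 chains of equal length")
    C, T = x.shape
    means = x.mean(axis=1)
    B = T * np.var(means, ddof=1)
    Wv = np.mean(np.var(x, axis=1, ddof=1))
    if Wv == 0:
        return 1.0
    var_hat = (T - 1) / T * Wv + B / T
    return float(np.sqrt(var_hat / Wv))


# -------------------------------------------------------------------- summary
def summarize(draws: PosteriorDraws, exponentiate: bool = True) -> pd.DataFrame:
    """Posterior medians and 95% credible intervals per scalar parameter.

    ``alpha`` and ``beta`` rows also carry the exponentiated (prevalence
    ratio) scale; precisions are summarised as sampled.  Rhat uses the
    per-chain draws.
    """
    rows = []

    def add(name, per_chain, pr_scale):
        pooled = per_chain.reshape(-1)
        med, lo, hi = np.percentile(pooled, [50, 2.5, 97.5])
        row = {"parameter": name, "median": med, "cri_low": lo, "cri_high": hi,
               "rhat": gelman_rubin(per_chain) if per_chain.shape[0] > 1 else np.nan}
        if pr_scale and exponentiate:
            row.update(pr=np.exp(med), pr_low=np.exp(lo), pr_high=np.exp(hi))
        rows.append(row)

    add("alpha", draws.alpha, True)
    for r, name in enumerate(draws.spec.design_columns):
        add(f"beta[{name}]", draws.beta[:, :, r], True)
    add("tau_s", draws.tau_s, False)
    add("tau_u", draws.tau_u, False)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- ladder
def dummy_design(labels, categories) -> tuple:
    """Reference-coded dummies for an area-level categorical (first level
    is the reference)."""
    lab = pd.Categorical(labels, categories=categories, ordered=True)
    if pd.isna(lab).any():
        raise ValueError("labels outside declared categories")
    cols = []
    names = []
    for lvl in categories[1:]:
        cols.append((lab == lvl).astype(float))
        names.append(lvl)
    return np.column_stack(cols), names


def ladder_design(model: str, walkability=None, disadvantage=None,
                  walk_categories=None, dis_categories=None):
    """Area-level design matrix for one rung of the M1-M6 model ladder."""
    from .synthetic import DISADVANTAGE_LABELS
    from .walkability import QUARTILE_LABELS

    walk_categories = walk_categories or QUARTILE_LABELS
    dis_categories = dis_categories or DISADVANTAGE_LABELS
    if model in ("M1", "M2"):
        return None, []
    parts, names = [], []
    if model in ("M3", "M5", "M6"):
        Xw, nw = dummy_design(walkability, walk_categories)
        parts.append(Xw)
        names += [f"walkability={v}" for v in nw]
    if model in ("M4", "M5", "M6"):
        Xd, nd = dummy_design(disadvantage, dis_categories)
        parts.append(Xd)
        names += [f"disadvantage={v}" for v in nd]
    if model == "M6":
        Xw, nw = dummy_design(walkability, walk_categories)
        Xd, nd = dummy_design(disadvantage, dis_categories)
        inter = np.einsum("ij,ik->ijk", Xw, Xd).reshape(len(Xw), -1)
        parts.append(inter)
        names += [f"walkability={w}:disadvantage={d}" for w in nw for d in nd]
    return np.column_stack(parts), names


def fit_ladder(expected_unadjusted: pd.DataFrame,
               expected_adjusted: pd.DataFrame,
               scores: pd.DataFrame, disadvantage: pd.DataFrame,
               structure: ICARStructure, config: MCMCConfig,
               models=("M1", "M2", "M3", "M4", "M5")) -> dict:
    """Fit a ladder of BYM models and compare them by DIC.

    M1: unadjusted offsets (p*n_j), no covariates.  M2: stage-1-adjusted
    offsets.  M3: M2 + walkability quartiles.  M4: M2 + disadvantage
    quintiles.  M5: M3 + disadvantage.  M6: M5 + walkability x disadvantage
    interaction.  Models within 1-2 DIC of the best deserve consideration,
    3-7 have less support, >7 none.

    Returns {"fits": {model: {draws, summary, dbar, pd, dic}},
    "comparison": DataFrame}.
    """
    with_data = set(expected_adjusted["area_id"]) if expected_adjusted is not None \
        else set(expected_unadjusted["area_id"])
    order = [a for a in structure.area_ids if a in with_data]
    if len(order) < structure.n:
        structure = structure.subset(order)
    walk = scores.set_index("area_id").loc[order, "quartile"].to_numpy()
    dis = disadvantage.set_index("area_id").loc[order, "disadvantage"].to_numpy()

    fits = {}
    for model in models:
        if model not in LADDER_IDS:
            raise ValueError(f"unknown ladder id {model!r}")
        exp_tbl = expected_unadjusted if model == "M1" else expected_adjusted
        if exp_tbl is None:
            raise ValueError(f"missing offset table for {model}")
        tbl = exp_tbl.set_index("area_id").loc[order]
        X, names = ladder_design(model, walkability=walk, disadvantage=dis)
        spec = BYMModelSpec(tbl["observed"].to_numpy(), tbl["e_j"].to_numpy(),
                            design=X, design_columns=names, ladder_id=model)
        draws = run_mcmc(spec, structure, config)
        dbar, pd_, dic_ = dic(draws)
        fits[model] = {"draws": draws, "summary": summarize(draws),
                       "dbar": dbar, "pd": pd_, "dic": dic_}

    best = min(fits, key=lambda mdl: fits[mdl]["dic"])
    rows = []
    for model in models:
        delta = fits[model]["dic"] - fits[best]["dic"]
        support = ("best" if delta == 0 else
                   "consider" if delta <= 2 else
                   "less support" if delta <= 7 else "no support")
        rows.append({"model": model, "pd": fits[model]["pd"],
                     "dic": fits[model]["dic"], "delta_dic": delta,
                     "support": support})
    comparison = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    comparison["rank"] = np.arange(1, len(comparison) + 1)
    return {"fits": fits, "comparison": comparison}
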