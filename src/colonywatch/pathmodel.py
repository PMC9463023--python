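"""Bayesian structural path analysis: five pathways from site quality to
breeding success.

Each pathway is an ordered chain of single-predictor regressions of the
form ``γ_i = α + β_i X_i + ε_site``; a site random intercept accounts for
unmeasured site-specific variation.  Breeding success (the endpoint of
every pathway) is Bernoulli with a logit link; every mediator
(return date, occupancy frequency, lay date) is Gaussian, parameterized by
mean and precision τ.  Continuous variables are standardized
(mean-centered and scaled) before modeling; the binary endpoint is left
0/1, since standardizing a Bernoulli response is not model-coherent.

Priors are minimally informative: Normal(0, precision 0.001) on intercepts
and slopes, Gamma(shape 0.001, rate 0.001) on every precision (residual
and site-effect).

Sampling is adaptive Metropolis-within-Gibbs: Gaussian-linear
coefficients, random effects, and precisions have conjugate Gibbs updates;
the Bernoulli-logit regressions use random-walk Metropolis with proposal
scales tuned during burn-in only (so the post-burn-in chain is a valid
time-homogeneous MCMC).  The canonical schedule is 3 chains × 200,000
iterations, burn-in 15,000, thinning 3; a reduced schedule
(3 × 20,000, burn-in 2,000, thin 3) is provided for quick runs and is
flagged non-canonical.

A pathway coefficient is the product of the standardized edge coefficients
along the chain (the classic path-analysis composition rule); the direct
last-edge coefficient is also emitted for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "EdgeSpec",
    "PathwaySpec",
    "PriorSpec",
    "MCMCConfig",
    "PathwayPosterior",
    "build_pathways",
    "standardize_path_data",
    "mcmc_fit",
    "fit_all_pathways",
    "sample_prior",
    "gelman_rubin",
    "effective_sample_size",
    "pathway_estimate",
    "pathways_table",
    "diagnostics_table",
]


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class EdgeSpec:
    """One regression in a pathway chain: response ~ predictor + (1|site)."""

    response: str
    predictor: str
    family: str  # "gaussian" or "bernoulli"

    def key(self) -> str:
        return f"{self.response}~{self.predictor}"


@dataclass(frozen=True)
class PathwaySpec:
    """An ordered variable chain from site quality to breeding success."""

    name: str
    chain: tuple[str, ...]
    edges: tuple[EdgeSpec, ...]

    def __post_init__(self):
        if self.chain[0] != "quality" or self.chain[-1] != "success":
            raise ConfigurationError(
                "every pathway starts at site quality and ends at breeding "
                f"success; got chain {self.chain}"
            )


@dataclass(frozen=True)
class PriorSpec:
    """Minimally informative priors for every pathway regression."""

    coef_mean: float = 0.0
    coef_precision: float = 0.001
    precision_shape: float = 0.001
    precision_rate: float = 0.001

    def __post_init__(self):
        if self.coef_precision <= 0 or self.precision_shape <= 0 \
                or self.precision_rate <= 0:
            raise ConfigurationError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chains / iterations / thinning / burn-in; the default is canonical."""

    chains: int = 3
    iterations: int = 200_000
    thin: int = 3
    burn_in: int = 15_000
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ConfigurationError("burn_in must be < iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.chains < 1:
            raise ConfigurationError("need at least one chain")

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        """Reduced, non-canonical schedule for quick runs."""
        return cls(chains=3, iterations=20_000, thin=3, burn_in=2_000,
                   seed=seed)

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


def build_pathways() -> list[PathwaySpec]:
    """The five fixed pathways, each decomposed into its chain of edges."""

    def _edges(chain):
        fams = {"success": "bernoulli"}
        return tuple(
            EdgeSpec(resp, pred, fams.get(resp, "gaussian"))
            for pred, resp in zip(chain[:-1], chain[1:])
        )

    chains = [
        ("quality", "success"),
        ("quality", "return_day", "success"),
        ("quality", "lay_date", "success"),
        ("quality", "occ_freq", "lay_date", "success"),
        ("quality", "return_day", "occ_freq", "lay_date", "success"),
    ]
    names = [
        "success ~ quality",
        "success ~ quality + return date",
        "success ~ quality + lay date",
        "success ~ quality + occupancy frequency + lay date",
        "success ~ quality + return date + occupancy frequency + lay date",
    ]
    return [
        PathwaySpec(name, tuple(chain), _edges(chain))
        for name, chain in zip(names, chains)
    ]


_CONTINUOUS = ("quality", "return_day", "occ_freq", "lay_date")


def standardize_path_data(data: pd.DataFrame) -> pd.DataFrame:
    """Center and scale the continuous chain variables; success stays 0/1."""
    need = [c for c in _CONTINUOUS + ("success",) if c in data.columns]
    missing = set(("quality", "success")) - set(need)
    if missing:
        raise DataError(f"path data lacks required columns: {sorted(missing)}")
    out = data.copy()
    if out[need].isna().any().any():
        raise DataError("path data contains missing values in chain columns")
    for c in _CONTINUOUS:
        if c in out.columns:
            v = out[c].astype(float)
            sd = v.std(ddof=1)
            if sd == 0:
                raise DataError(f"column {c!r} has zero variance")
            out[c] = (v - v.mean()) / sd
    out["success"] = out["success"].astype(int)
    if not out["success"].isin((0, 1)).all():
        raise DataError("success must be binary 0/1")
    return out


# ---------------------------------------------------------------------------
# edge samplers (vectorized across chains)


def _logp_bern(y, eta):
    # sum over rows, per chain
    return (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)


class _EdgeSampler:
    """Adaptive Metropolis-within-Gibbs for one edge regression.

    State arrays hold all chains at once; Gaussian edges are fully
    conjugate, Bernoulli edges use random-walk Metropolis for (α, β) and
    the site effects with a Gibbs update for the site-effect precision.
    The proposal scale for the site-effect vector shrinks with the current
    precision (scale depends on τ only, so the walk stays symmetric in u).
    """

    def __init__(self, edge: EdgeSpec, x, y, site_codes, n_sites,
                 priors: PriorSpec, config: MCMCConfig, seed_seq):
        self.edge = edge
        self.x = x
        self.y = y
        self.codes = site_codes
        self.S = n_sites
        self.n = x.size
        self.priors = priors
        self.config = config
        self.rng = np.random.default_rng(seed_seq)
        C = config.chains
        # overdispersed starts
        self.alpha = self.rng.normal(0.0, 1.0, C)
        self.beta = self.rng.normal(0.0, 1.0, C)
        self.u = self.rng.normal(0.0, 0.5, (C, self.S))
        self.tau_u = np.full(C, 1.0)
        self.tau_e = np.full(C, 1.0)
        self.site_n = np.bincount(site_codes, minlength=n_sites).astype(float)
        # one-hot site matrix for fast per-site sums
        self.M = np.zeros((self.n, self.S))
        self.M[np.arange(self.n), site_codes] = 1.0
        # full design [1, x, Z] for the joint Gaussian coefficient draw
        design = np.column_stack([np.ones(self.n), x, self.M])
        self.DtD = design.T @ design
        self.Dty = design.T @ y if self.n else np.zeros(2 + self.S)
        # MH adaptation state (Bernoulli edges)
        self.log_step = np.zeros((C, 3))  # alpha, beta, u
        self.acc = np.zeros((C, 3))
        self.tries = np.zeros((C, 3))

    # -- conjugate Gaussian updates -----------------------------------------

    def _update_gaussian(self):
        pr = self.priors
        x, y, C = self.x, self.y, self.config.chains
        # joint conjugate draw of (alpha, beta, u): updating the intercept
        # and the site effects one block at a time mixes slowly when the
        # site variance dominates the residual, because alpha trades off
        # against mean(u); the joint draw removes that coupling exactly
        k = 2 + self.S
        prior_diag = np.concatenate([
            [pr.coef_precision, pr.coef_precision], np.zeros(self.S)])
        z = self.rng.standard_normal((C, k))
        from scipy.linalg import cho_factor, cho_solve, solve_triangular

        for c in range(C):
            P = self.tau_e[c] * self.DtD + np.diag(
                prior_diag + np.concatenate([[0.0, 0.0],
                                             np.full(self.S,
                                                     self.tau_u[c])]))
            L, low = cho_factor(P, lower=True)
            mean = cho_solve((L, low), self.tau_e[c] * self.Dty)
            draw = mean + solve_triangular(L, z[c], lower=True, trans="T")
            self.alpha[c], self.beta[c] = draw[0], draw[1]
            self.u[c] = draw[2:]
        # residual precision
        resid = (y[None, :] - self.alpha[:, None] - self.beta[:, None] * x
                 - self.u[:, self.codes])
        ssr = (resid ** 2).sum(axis=1)
        self.tau_e = self.rng.gamma(pr.precision_shape + 0.5 * self.n,
                                    1.0 / (pr.precision_rate + 0.5 * ssr))
        # site-effect precision
        ssu = (self.u ** 2).sum(axis=1)
        self.tau_u = self.rng.gamma(pr.precision_shape + 0.5 * self.S,
                                    1.0 / (pr.precision_rate + 0.5 * ssu))

    # -- Metropolis Bernoulli updates ---------------------------------------

    def _eta(self, alpha, beta, u):
        return alpha[:, None] + beta[:, None] * self.x + u[:, self.codes]

    def _update_bernoulli(self, adapt: bool):
        pr = self.priors
        C = self.config.chains
        y = self.y
        for j, name in enumerate(("alpha", "beta")):
            cur = self.alpha if name == "alpha" else self.beta
            step = np.exp(self.log_step[:, j]) * 0.3
            prop = cur + step * self.rng.standard_normal(C)
            eta0 = self._eta(self.alpha, self.beta, self.u)
            if name == "alpha":
                eta1 = self._eta(prop, self.beta, self.u)
            else:
                eta1 = self._eta(self.alpha, prop, self.u)
            d = _logp_bern(y, eta1) - _logp_bern(y, eta0)
            d += -0.5 * pr.coef_precision * (prop ** 2 - cur ** 2)
            ok = np.log(self.rng.random(C)) < d
            cur[ok] = prop[ok]
            if adapt:
                self.acc[:, j] += ok
                self.tries[:, j] += 1
        # site effects and their precision: a few interleaved sweeps per
        # iteration decorrelate the (u, τ) pair, whose coupling is otherwise
        # the slowest-mixing part of the logit edges
        for _ in range(3):
            scale = (np.exp(self.log_step[:, 2])
                     / np.sqrt(self.tau_u + 0.25 * self.site_n.mean())
                     )[:, None]
            prop_u = self.u + scale * self.rng.standard_normal((C, self.S))
            eta0 = self._eta(self.alpha, self.beta, self.u)
            eta1 = self._eta(self.alpha, self.beta, prop_u)
            d_row = (y[None, :] * (eta1 - eta0)
                     - np.logaddexp(0.0, eta1) + np.logaddexp(0.0, eta0))
            d_site = d_row @ self.M
            d_site += -0.5 * self.tau_u[:, None] * (prop_u ** 2 - self.u ** 2)
            ok = np.log(self.rng.random((C, self.S))) < d_site
            self.u = np.where(ok, prop_u, self.u)
            if adapt:
                self.acc[:, 2] += ok.mean(axis=1)
                self.tries[:, 2] += 1
            # site-effect precision (conjugate)
            ssu = (self.u ** 2).sum(axis=1)
            self.tau_u = self.rng.gamma(
                pr.precision_shape + 0.5 * self.S,
                1.0 / (pr.precision_rate + 0.5 * ssu),
            )
        # exact translation move alpha -> alpha + d, u -> u - d: the linear
        # predictor is invariant, so d has a Gaussian full conditional from
        # the priors alone; it decouples alpha from mean(u)
        prec_d = pr.coef_precision + self.S * self.tau_u
        mean_d = (self.tau_u * self.u.sum(axis=1)
                  - pr.coef_precision * self.alpha) / prec_d
        d = mean_d + self.rng.standard_normal(C) / np.sqrt(prec_d)
        self.alpha = self.alpha + d
        self.u = self.u - d[:, None]

    def _adapt_steps(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.tries > 0, self.acc / self.tries, 0.44)
        self.log_step += 0.15 * (rate - 0.44)
        self.log_step = np.clip(self.log_step, -4.0, 4.0)
        self.acc[:] = 0
        self.tries[:] = 0

    # -- main loop -----------------------------------------------------------

    def run(self):
        cfg = self.config
        kept = cfg.kept_per_chain
        C = cfg.chains
        gaussian = self.edge.family == "gaussian"
        out = {
            "alpha": np.empty((C, kept)),
            "beta": np.empty((C, kept)),
            "tau_site": np.empty((C, kept)),
        }
        if gaussian:
            out["tau_resid"] = np.empty((C, kept))
        k = 0
        for it in range(1, cfg.iterations + 1):
            if gaussian:
                self._update_gaussian()
            else:
                adapt = it <= cfg.burn_in
                self._update_bernoulli(adapt)
                if adapt and it % 50 == 0:
                    self._adapt_steps()
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 \
                    and k < kept:
                out["alpha"][:, k] = self.alpha
                out["beta"][:, k] = self.beta
                out["tau_site"][:, k] = self.tau_u
                if gaussian:
                    out["tau_resid"][:, k] = self.tau_e
                k += 1
            if not (np.isfinite(self.alpha).all()
                    and np.isfinite(self.beta).all()):
                raise RuntimeError(
                    f"divergent chain in edge {self.edge.key()} at "
                    f"iteration {it}: state alpha={self.alpha}, "
                    f"beta={self.beta}"
                )
        return out


def _run_edge(edge: EdgeSpec, data: pd.DataFrame, priors: PriorSpec,
              config: MCMCConfig, seed_seq) -> dict[str, np.ndarray]:
    codes, levels = pd.factorize(data["site_id"], sort=True)
    sampler = _EdgeSampler(
        edge,
        data[edge.predictor].to_numpy(float),
        data[edge.response].to_numpy(float),
        codes, len(levels), priors, config, seed_seq,
    )
    return sampler.run()


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from ≥2 equal-length chains.

    ``chains`` is (n_chains, n_draws).  Computed from the classic
    between/within-chain variance decomposition; identical chains give a
    value of (essentially) 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _ess_one(x: np.ndarray) -> float:
    """ESS of one chain via Geyer's initial monotone positive sequence."""
    n = x.size
    x = x - x.mean()
    v = float(x @ x) / n
    if v == 0:
        raise ValueError("constant chain: ESS undefined")
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    # pair sums Γ_k = ρ(2k) + ρ(2k+1): truncate at first negative, enforce
    # monotone non-increasing
    n_pairs = (n - 1) // 2
    gamma = rho[1:2 * n_pairs + 1:2] + rho[2:2 * n_pairs + 1:2]
    tau = 1.0
    prev = np.inf
    for g in gamma:
        if g < 0:
            break
        g = min(g, prev)
        tau += 2.0 * g
        prev = g
    return n / tau


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-time-based ESS, summed over chains."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    return float(sum(_ess_one(c) for c in chains))


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class PathwayPosterior:
    """Post burn-in, thinned draws and summaries for one pathway."""

    pathway: PathwaySpec
    draws: dict[str, np.ndarray]  # name -> (chains, kept)
    config: MCMCConfig
    n_obs: int

    def pathway_draws(self) -> np.ndarray:
        return self.draws["pathway"]

    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            rows.append({
                "variable": name,
                "rhat": gelman_rubin(arr) if arr.shape[0] > 1 else np.nan,
                "ess": effective_sample_size(arr),
            })
        return pd.DataFrame(rows)

    @property
    def converged(self) -> bool:
        d = self.diagnostics()
        return bool((d["rhat"].dropna() <= 1.05).all())

    def summary(self) -> dict:
        out = pathway_estimate(self.pathway_draws())
        out["pathway"] = self.pathway.name
        out["direct"] = float(self.draws["direct"].mean())
        out["n_obs"] = self.n_obs
        out["converged"] = self.converged
        return out


def pathway_estimate(draws: np.ndarray) -> dict:
    """Posterior mean, 95% credible interval, and % same sign as the mean.

    ``draws`` are per-draw pathway coefficients (the product of the
    standardized edge coefficients along the chain).
    """
    flat = np.asarray(draws, dtype=float).ravel()
    est = float(flat.mean())
    lo, hi = np.percentile(flat, [2.5, 97.5])
    same = float(np.mean(np.sign(flat) == np.sign(est)) * 100.0)
    return {
        "estimate": est,
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "pct_same_sign": same,
    }


# ---------------------------------------------------------------------------
# fitting


def _assemble_posterior(pathway: PathwaySpec, edge_draws: dict[str, dict],
                        config: MCMCConfig, n_obs: int) -> PathwayPosterior:
    draws = {}
    prod = None
    for e in pathway.edges:
        for par, arr in edge_draws[e.key()].items():
            draws[f"{e.key()}.{par}"] = arr
        b = edge_draws[e.key()]["beta"]
        prod = b if prod is None else prod * b
    draws["pathway"] = prod
    draws["direct"] = edge_draws[pathway.edges[-1].key()]["beta"]
    return PathwayPosterior(pathway, draws, config, n_obs)


def mcmc_fit(pathway: PathwaySpec, data: pd.DataFrame,
             priors: PriorSpec | None = None,
             config: MCMCConfig | None = None) -> PathwayPosterior:
    """Fit one pathway's chain of regressions by MCMC.

    ``data`` must already be standardized (see
    :func:`standardize_path_data`) and complete for the chain variables.
    Reproducible given ``config.seed``.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    cols = set(pathway.chain) | {"site_id"}
    missing = cols - set(data.columns)
    if missing:
        raise DataError(f"missing columns for pathway: {sorted(missing)}")
    if data[list(cols)].isna().any().any():
        raise DataError("missing values in pathway chain variables")
    edge_draws = {}
    for e in pathway.edges:
        seed_seq = np.random.SeedSequence(
            entropy=config.seed, spawn_key=(_edge_index(e),)
        )
        edge_draws[e.key()] = _run_edge(e, data, priors, config, seed_seq)
    return _assemble_posterior(pathway, edge_draws, config, len(data))


_ALL_EDGE_KEYS = [
    e.key() for p in build_pathways() for e in p.edges
]
_EDGE_ORDER = {k: i for i, k in enumerate(dict.fromkeys(_ALL_EDGE_KEYS))}


def _edge_index(edge: EdgeSpec) -> int:
    return _EDGE_ORDER.get(edge.key(), 97 + hash(edge.key()) % 1000)


def fit_all_pathways(data: pd.DataFrame, priors: PriorSpec | None = None,
                     config: MCMCConfig | None = None
                     ) -> list[PathwayPosterior]:
    """Fit all five pathways, sampling each unique edge regression once.

    The five pathways share edges (eight unique regressions in total) and
    no parameters are shared across edges, so each edge's posterior is
    sampled once and reused — identical results to fitting the pathways
    one at a time with the same seed.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    pathways = build_pathways()
    edge_draws = {}
    for p in pathways:
        for e in p.edges:
            if e.key() not in edge_draws:
                seed_seq = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(_edge_index(e),)
                )
                edge_draws[e.key()] = _run_edge(e, data, priors, config,
                                                seed_seq)
    return [
        _assemble_posterior(p, edge_draws, config, len(data))
        for p in pathways
    ]


def sample_prior(priors: PriorSpec | None = None,
                 config: MCMCConfig | None = None) -> dict[str, np.ndarray]:
    """Prior-only draws (no data) for the Gaussian-edge parameter block.

    With zero observations every conditional collapses to its prior, so the
    sampler draws α, β ~ Normal(0, 1/coef_precision) and the precisions
    from Gamma(shape, rate); used to verify the stated priors' moments.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig.fast()
    edge = EdgeSpec("y", "x", "gaussian")
    sampler = _EdgeSampler(
        edge, np.empty(0), np.empty(0), np.empty(0, dtype=int), 1,
        priors, config, np.random.SeedSequence(config.seed),
    )
    return sampler.run()


def pathways_table(posteriors: list[PathwayPosterior]) -> pd.DataFrame:
    """Pathway summary table: estimate, credible interval, % same sign."""
    rows = []
    for p in posteriors:
        s = p.summary()
        rows.append({
            "pathway": s["pathway"],
            "estimate": s["estimate"],
            "ci_lower": s["ci_lower"],
            "ci_upper": s["ci_upper"],
            "pct_same_sign": s["pct_same_sign"],
            "direct_last_edge": s["direct"],
            "n_obs": s["n_obs"],
            "converged": s["converged"],
        })
    return pd.DataFrame(rows)


def diagnostics_table(posteriors: list[PathwayPosterior]) -> pd.DataFrame:
    """R-hat and ESS per monitored variable across all pathway fits."""
    frames = []
    for p in posteriors:
        d = p.diagnostics()
        d.insert(0, "pathway", p.pathway.name)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)
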