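"""General/generalized linear mixed models with AIC-based selection.

The estimation target is maximum likelihood throughout (not REML), because
fixed-effect AIC comparison is only valid under ML.  Gaussian responses use
the exact profiled ML deviance; binomial and Bernoulli responses use a
first-order Laplace approximation to the marginal likelihood with the fixed
effects profiled out by penalized IRLS — the approach of lme4's default
``glmer``.  Aggregated binomial responses (occupancy frequency, relative
time investment) are modeled as counts with their recorded denominators as
trials.

Random structures supported, per grouping factor: random intercept,
correlated intercept + slope, independent intercept and slope, and slope
only; up to two crossed grouping factors (site, subcolony-year) — the
design this pipeline needs.

Model selection follows a two-step AIC rule: when the gap to the
next-closest candidate exceeds 2, the lowest-AIC model wins; otherwise the
most parsimonious model within 2 AIC units is selected (fewest parameters,
ties broken by lexicographic term order — deterministic).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .errors import ComparabilityError, DegenerateGroupError

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "MixedModelFit",
    "SelectionResult",
    "fit_mixed",
    "confint_fixed",
    "aic_select",
    "candidate_specs",
    "random_structure_select",
    "r_squared_nakagawa",
    "ks_normality",
    "collinearity_screen",
]

_STRUCTURES = ("intercept", "intercept_slope", "intercept_slope_indep",
               "slope")
_LOGIT_RESID_VAR = np.pi ** 2 / 3.0
_BOUNDARY_LOG_SD = -6.0  # log-SD below this is treated as a zero variance


@dataclass(frozen=True)
class RandomTerm:
    """One grouping factor and its random-effect structure."""

    group: str
    structure: str = "intercept"
    slope: str | None = None

    def __post_init__(self):
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown random structure {self.structure!r}")
        if self.structure != "intercept" and self.slope is None:
            raise ValueError(f"structure {self.structure!r} needs a slope "
                             "variable")

    @property
    def n_theta(self) -> int:
        return {"intercept": 1, "slope": 1, "intercept_slope_indep": 2,
                "intercept_slope": 3}[self.structure]

    def label(self) -> str:
        if self.structure == "intercept":
            return f"(1|{self.group})"
        if self.structure == "slope":
            return f"(0+{self.slope}|{self.group})"
        if self.structure == "intercept_slope_indep":
            return f"(1|{self.group})+(0+{self.slope}|{self.group})"
        return f"(1+{self.slope}|{self.group})"


@dataclass(frozen=True)
class ModelSpec:
    """Response, family, fixed terms (with interactions), random terms.

    ``fixed`` is a tuple of terms, each a tuple of covariate names; an
    interaction may only involve covariates whose main effects are present.
    ``trials`` names the denominator column for aggregated binomial
    responses.
    """

    response: str
    family: str  # gaussian | binomial | bernoulli
    fixed: tuple[tuple[str, ...], ...] = ()
    random: tuple[RandomTerm, ...] = ()
    trials: str | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial", "bernoulli"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and self.trials is None:
            raise ValueError("binomial family requires a trials column")
        mains = {t[0] for t in self.fixed if len(t) == 1}
        for t in self.fixed:
            if len(t) > 1 and not set(t) <= mains:
                raise ValueError(
                    f"interaction {t} without all main effects present"
                )

    def variables(self) -> set[str]:
        out = {v for t in self.fixed for v in t}
        out.add(self.response)
        if self.trials:
            out.add(self.trials)
        for r in self.random:
            out.add(r.group)
            if r.slope:
                out.add(r.slope)
        return out

    def term_names(self) -> tuple[str, ...]:
        return tuple(":".join(t) for t in self.fixed)

    def label(self) -> str:
        rhs = " + ".join(self.term_names()) or "1"
        rand = " + ".join(r.label() for r in self.random)
        return f"{self.response} ~ {rhs}" + (f" + {rand}" if rand else "")


# ---------------------------------------------------------------------------
# design construction


def _expand_variable(data: pd.DataFrame, var: str):
    """One variable -> list of (column name, values)."""
    col = data[var]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        levels = (list(col.cat.categories)
                  if isinstance(col.dtype, pd.CategoricalDtype)
                  else sorted(col.dropna().unique()))
        return [
            (f"{var}[{lev}]", (col == lev).to_numpy(float))
            for lev in levels[1:]
        ]
    return [(var, col.to_numpy(float))]


def build_fixed_design(data: pd.DataFrame, fixed):
    """Fixed design matrix with intercept; categoricals expand to dummies."""
    n = len(data)
    cols, names = [np.ones(n)], ["(Intercept)"]
    ordered = sorted(fixed, key=lambda t: (len(t), t))
    for term in ordered:
        parts = [_expand_variable(data, v) for v in term]
        for combo in itertools.product(*parts):
            names.append(":".join(c[0] for c in combo))
            cols.append(np.prod([c[1] for c in combo], axis=0))
    return np.column_stack(cols), names


def _group_codes(data: pd.DataFrame, var: str):
    codes, levels = pd.factorize(data[var], sort=True)
    return codes, list(levels)


class _RandomBlock:
    """Indicator/slope columns for one random term, in spherical-u form."""

    def __init__(self, data: pd.DataFrame, term: RandomTerm):
        self.term = term
        codes, levels = _group_codes(data, term.group)
        self.codes = codes
        self.levels = levels
        n, g = len(data), len(levels)
        self.n_groups = g
        x = (data[term.slope].to_numpy(float)
             if term.slope is not None else None)
        # raw columns per level; scaled by theta in zl()
        self.ind = np.zeros((n, g))
        self.ind[np.arange(n), codes] = 1.0
        self.slope_cols = self.ind * x[:, None] if x is not None else None

    @property
    def n_cols(self) -> int:
        return {"intercept": self.n_groups, "slope": self.n_groups,
                "intercept_slope_indep": 2 * self.n_groups,
                "intercept_slope": 2 * self.n_groups}[self.term.structure]

    def zl(self, theta: np.ndarray) -> np.ndarray:
        """Z·Λ(θ) for this block; u is standard normal."""
        s = self.term.structure
        if s == "intercept":
            return np.exp(theta[0]) * self.ind
        if s == "slope":
            return np.exp(theta[0]) * self.slope_cols
        if s == "intercept_slope_indep":
            return np.hstack([np.exp(theta[0]) * self.ind,
                              np.exp(theta[1]) * self.slope_cols])
        # correlated: per level the pair (1, x) is multiplied by lower
        # Cholesky [[l11, 0], [l21, l22]]
        l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        return np.hstack([l11 * self.ind + l21 * self.slope_cols,
                          l22 * self.slope_cols])

    def covariance(self, theta: np.ndarray) -> dict[str, float]:
        s = self.term.structure
        if s == "intercept":
            return {"intercept_var": np.exp(2 * theta[0])}
        if s == "slope":
            return {"slope_var": np.exp(2 * theta[0])}
        if s == "intercept_slope_indep":
            return {"intercept_var": np.exp(2 * theta[0]),
                    "slope_var": np.exp(2 * theta[1])}
        l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        return {"intercept_var": l11 ** 2,
                "slope_var": l21 ** 2 + l22 ** 2,
                "intercept_slope_cov": l11 * l21}


# ---------------------------------------------------------------------------
# results


@dataclass
class MixedModelFit:
    """Estimates, intervals, information criteria for one fitted model."""

    spec: ModelSpec
    term_names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    n: int
    k_params: int
    variance_components: dict[str, dict[str, float]]
    sigma2: float | None
    converged: bool
    boundary: bool
    theta: np.ndarray
    notes: list[str] = field(default_factory=list)
    ci: pd.DataFrame | None = None
    _problem: object = None

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "term": self.term_names,
            "estimate": self.estimates,
            "se": self.se,
        })
        if self.ci is not None:
            out = out.merge(self.ci[["term", "lower", "upper",
                                     "significant"]], on="term")
        return out


@dataclass
class SelectionResult:
    """AIC table, the chosen model, and which selection rule applied."""

    table: pd.DataFrame
    chosen: MixedModelFit
    rule: str
    fits: dict[str, MixedModelFit]


# ---------------------------------------------------------------------------
# core fitting machinery


class _MixedProblem:
    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        used = sorted(spec.variables())
        data = data.dropna(subset=[v for v in used if v in data.columns])
        missing = [v for v in used if v not in data.columns]
        if missing:
            raise KeyError(f"columns missing from data: {missing}")
        self.data = data.reset_index(drop=True)
        self.n = len(self.data)
        self.row_index = tuple(data.index)
        self.y = self.data[spec.response].to_numpy(float)
        if spec.family == "binomial":
            self.trials = self.data[spec.trials].to_numpy(float)
            if np.any(self.trials <= 0):
                raise ValueError("binomial trials must be positive")
        elif spec.family == "bernoulli":
            self.trials = np.ones(self.n)
        else:
            self.trials = None
        self.X, self.x_names = build_fixed_design(self.data, spec.fixed)
        self.blocks = [_RandomBlock(self.data, r) for r in spec.random]
        self.theta_slices = []
        pos = 0
        for b in self.blocks:
            k = b.term.n_theta
            self.theta_slices.append(slice(pos, pos + k))
            pos += k
        self.n_theta = pos
        if spec.family == "binomial":
            self.ll_const = float(np.sum(
                gammaln(self.trials + 1) - gammaln(self.y + 1)
                - gammaln(self.trials - self.y + 1)
            ))
        else:
            self.ll_const = 0.0

    # -- helpers ------------------------------------------------------------

    def zl(self, theta: np.ndarray) -> np.ndarray | None:
        if not self.blocks:
            return None
        return np.hstack([
            b.zl(theta[s]) for b, s in zip(self.blocks, self.theta_slices)
        ])

    def _binomial_loglik(self, eta: np.ndarray) -> float:
        m = self.trials
        return float(np.sum(self.y * eta - m * np.logaddexp(0.0, eta)))

    # -- gaussian profiled deviance -----------------------------------------

    def _gauss_solve(self, theta, offset, x_cols=None):
        X = self.X if x_cols is None else self.X[:, x_cols]
        y = self.y - offset
        zl = self.zl(theta)
        p = X.shape[1]
        if zl is None:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            r2 = float(resid @ resid)
            return beta, np.zeros(0), r2, 0.0
        q = zl.shape[1]
        A = np.empty((q + p, q + p))
        A[:q, :q] = zl.T @ zl + np.eye(q)
        A[:q, q:] = zl.T @ X
        A[q:, :q] = A[:q, q:].T
        A[q:, q:] = X.T @ X
        rhs = np.concatenate([zl.T @ y, X.T @ y])
        sol = np.linalg.solve(A, rhs)
        u, beta = sol[:q], sol[q:]
        resid = y - X @ beta - zl @ u
        r2 = float(resid @ resid + u @ u)
        sign, logdet = np.linalg.slogdet(zl.T @ zl + np.eye(q))
        return beta, u, r2, logdet

    def gauss_deviance(self, theta, offset=0.0, x_cols=None,
                       reml: bool = False) -> float:
        beta, _, r2, logdet = self._gauss_solve(theta, offset, x_cols)
        n = self.n
        if not reml:
            return n * (1.0 + np.log(2 * np.pi * r2 / n)) + logdet
        # REML: integrate the fixed effects out (scale-free part of
        # log det X'V0^-1 X added; n replaced by n - p)
        X = self.X if x_cols is None else self.X[:, x_cols]
        p = X.shape[1]
        zl = self.zl(theta)
        if zl is None:
            S = X.T @ X
        else:
            q = zl.shape[1]
            inner = np.linalg.inv(zl.T @ zl + np.eye(q))
            S = X.T @ X - X.T @ zl @ inner @ zl.T @ X
        _, logdet_s = np.linalg.slogdet(S)
        np_ = n - p
        return (np_ * (1.0 + np.log(2 * np.pi * r2 / np_))
                + logdet + logdet_s)

    # -- binomial Laplace deviance ------------------------------------------

    def _pirls(self, theta, offset, x_cols=None):
        X = self.X if x_cols is None else self.X[:, x_cols]
        zl = self.zl(theta)
        p = X.shape[1]
        q = 0 if zl is None else zl.shape[1]
        beta = np.zeros(p)
        u = np.zeros(q)
        m = self.trials
        eta = X @ beta + offset
        for _ in range(50):
            if q:
                eta = X @ beta + zl @ u + offset
            else:
                eta = X @ beta + offset
            mu = m * expit(eta)
            w = np.maximum(mu * (1.0 - mu / m), 1e-10)
            g_eta = self.y - mu
            if q:
                A = np.empty((q + p, q + p))
                zlw = zl * w[:, None]
                A[:q, :q] = zl.T @ zlw + np.eye(q)
                A[:q, q:] = zlw.T @ X
                A[q:, :q] = A[:q, q:].T
                A[q:, q:] = X.T @ (X * w[:, None])
                grad = np.concatenate([zl.T @ g_eta - u, X.T @ g_eta])
                try:
                    step = np.linalg.solve(A, grad)
                except np.linalg.LinAlgError:
                    return None
                du, dbeta = step[:q], step[q:]
            else:
                A = X.T @ (X * w[:, None])
                try:
                    dbeta = np.linalg.solve(A, X.T @ g_eta)
                except np.linalg.LinAlgError:
                    return None
                du = np.zeros(0)
            # step-halving on the penalized objective
            pen0 = self._binomial_loglik(eta) - 0.5 * float(u @ u)
            scale = 1.0
            for _ in range(20):
                b_new, u_new = beta + scale * dbeta, u + scale * du
                eta_new = X @ b_new + offset + (zl @ u_new if q else 0.0)
                pen1 = (self._binomial_loglik(eta_new)
                        - 0.5 * float(u_new @ u_new))
                if pen1 >= pen0 - 1e-12:
                    break
                scale *= 0.5
            delta = max(np.max(np.abs(scale * dbeta), initial=0.0),
                        np.max(np.abs(scale * du), initial=0.0))
            beta, u = b_new, u_new
            if delta < 1e-9:
                break
        eta = X @ beta + offset + (zl @ u if q else 0.0)
        return beta, u, zl, eta

    def laplace_deviance(self, theta, offset=0.0, x_cols=None) -> float:
        res = self._pirls(theta, offset, x_cols)
        if res is None:
            return np.inf
        beta, u, zl, eta = res
        ll = self._binomial_loglik(eta) + self.ll_const
        if zl is not None:
            m = self.trials
            mu = m * expit(eta)
            w = np.maximum(mu * (1.0 - mu / m), 1e-10)
            q = zl.shape[1]
            sign, logdet = np.linalg.slogdet(zl.T @ (zl * w[:, None])
                                             + np.eye(q))
            ll += -0.5 * float(u @ u) - 0.5 * logdet
        return -2.0 * ll

    def deviance(self, theta, offset=0.0, x_cols=None,
                 reml: bool = False) -> float:
        if self.spec.family == "gaussian":
            return self.gauss_deviance(theta, offset, x_cols, reml=reml)
        return self.laplace_deviance(theta, offset, x_cols)

    # -- outer optimization ---------------------------------------------------

    def optimize_theta(self, offset=0.0, x_cols=None, reml: bool = False):
        if self.n_theta == 0:
            return (np.zeros(0),
                    self.deviance(np.zeros(0), offset, x_cols, reml), True)
        theta0 = np.full(self.n_theta, np.log(0.5))
        for b, s in zip(self.blocks, self.theta_slices):
            if b.term.structure == "intercept_slope":
                theta0[s] = [np.log(0.5), 0.0, np.log(0.5)]
        res = optimize.minimize(
            lambda th: self.deviance(th, offset, x_cols, reml), theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
        )
        return res.x, float(res.fun), bool(res.success)

    def fixed_cov(self, theta, offset=0.0, reml: bool = False):
        """Fixed-effect covariance from the Schur complement at the optimum."""
        X = self.X
        if self.spec.family == "gaussian":
            beta, u, r2, _ = self._gauss_solve(theta, offset)
            sigma2 = r2 / (self.n - X.shape[1] if reml else self.n)
            zl = self.zl(theta)
            if zl is None:
                cov = sigma2 * np.linalg.inv(X.T @ X)
                return beta, cov, sigma2
            q = zl.shape[1]
            inner = np.linalg.inv(zl.T @ zl + np.eye(q))
            S = X.T @ X - X.T @ zl @ inner @ zl.T @ X
            return beta, sigma2 * np.linalg.inv(S), sigma2
        beta, u, zl, eta = self._pirls(theta, offset)
        m = self.trials
        mu = m * expit(eta)
        w = np.maximum(mu * (1.0 - mu / m), 1e-10)
        if zl is None:
            cov = np.linalg.inv(X.T @ (X * w[:, None]))
            return beta, cov, None
        q = zl.shape[1]
        zlw = zl * w[:, None]
        inner = np.linalg.inv(zl.T @ zlw + np.eye(q))
        S = X.T @ (X * w[:, None]) - X.T @ zlw @ inner @ zlw.T @ X
        return beta, np.linalg.inv(S), None


def fit_mixed(spec: ModelSpec, data: pd.DataFrame,
              reml: bool = False) -> MixedModelFit:
    """Fit one mixed model by (Laplace-approximated) maximum likelihood.

    Deterministic given data and spec.  Non-convergence and boundary
    (zero-variance) solutions are flagged on the returned fit, never
    silently dropped.  ``reml=True`` (Gaussian responses only) switches to
    restricted ML — the conventional choice for *reporting* a chosen
    Gaussian model, since ML variance components are biased low with few
    observations per group; REML fits must never be compared by AIC across
    fixed structures, and the returned fit says so.
    """
    if reml and spec.family != "gaussian":
        raise ValueError("REML is only defined for Gaussian responses")
    prob = _MixedProblem(spec, data)
    theta, dev, ok = prob.optimize_theta(reml=reml)
    beta, vcov, sigma2 = prob.fixed_cov(theta, reml=reml)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    loglik = -0.5 * dev
    p = len(beta)
    k = p + prob.n_theta + (1 if spec.family == "gaussian" else 0)
    boundary = bool(prob.n_theta and np.any(
        np.array([
            theta[s][i]
            for b, s in zip(prob.blocks, prob.theta_slices)
            for i in ([0] if b.term.structure in ("intercept", "slope")
                      else ([0, 1] if b.term.structure
                            == "intercept_slope_indep" else [0, 2]))
        ]) < _BOUNDARY_LOG_SD
    ))
    vc = {}
    for b, s in zip(prob.blocks, prob.theta_slices):
        cov = b.covariance(theta[s])
        if spec.family == "gaussian":
            cov = {k2: v * sigma2 for k2, v in cov.items()}
        vc[b.term.label()] = cov
    fit = MixedModelFit(
        spec=spec, term_names=prob.x_names, estimates=beta, se=se,
        vcov=vcov, loglik=loglik, aic=2 * k - 2 * loglik, n=prob.n,
        k_params=k, variance_components=vc,
        sigma2=sigma2, converged=ok, boundary=boundary, theta=theta,
        _problem=prob,
    )
    if reml:
        fit.notes.append("REML fit: loglik/AIC not comparable across "
                         "fixed-effect structures")
    if not ok:
        fit.notes.append("outer optimizer did not report convergence")
    if boundary:
        fit.notes.append("variance component at boundary (~0)")
    fit.ci = confint_fixed(fit, method="wald")
    return fit


# ---------------------------------------------------------------------------
# confidence intervals


_CHI2_95 = stats.chi2.ppf(0.95, df=1)


def _profile_one(fit: MixedModelFit, j: int):
    prob: _MixedProblem = fit._problem
    x_cols = [i for i in range(len(fit.term_names)) if i != j]
    xj = prob.X[:, j]
    dev_hat = -2.0 * fit.loglik
    target = dev_hat + _CHI2_95

    def dev_at(c):
        _, d, _ = prob.optimize_theta(offset=c * xj, x_cols=x_cols)
        return d

    est, se_j = fit.estimates[j], max(fit.se[j], 1e-8)
    bounds = []
    for sign in (-1.0, 1.0):
        width = 1.96 * se_j
        lo_c, hi_c = est, est + sign * width
        d_hi = dev_at(hi_c)
        n_exp = 0
        while d_hi < target and n_exp < 8:
            lo_c, hi_c = hi_c, hi_c + sign * width
            d_hi = dev_at(hi_c)
            n_exp += 1
        if d_hi < target:
            raise RuntimeError("profile bound not bracketed")
        root = optimize.brentq(
            lambda c: dev_at(c) - target, min(lo_c, hi_c), max(lo_c, hi_c),
            xtol=1e-4 * se_j,
        )
        bounds.append(root)
    return min(bounds), max(bounds)


def confint_fixed(fit: MixedModelFit, method: str = "profile",
                  level: float = 0.95) -> pd.DataFrame:
    """95% intervals per fixed effect, with a significance flag.

    ``profile`` inverts the likelihood-ratio test term by term (falling back
    to Wald, with a recorded note, if a profile fails to bracket); ``wald``
    is estimate ± z·SE.  A term is significant when its interval excludes
    zero.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for j, name in enumerate(fit.term_names):
        lo = fit.estimates[j] - z * fit.se[j]
        hi = fit.estimates[j] + z * fit.se[j]
        used = "wald"
        if method == "profile" and level == 0.95:
            try:
                lo, hi = _profile_one(fit, j)
                used = "profile"
            except Exception as exc:  # noqa: BLE001 - fallback is the contract
                fit.notes.append(f"profile CI failed for {name}: {exc}; "
                                 "Wald used")
        rows.append({
            "term": name, "estimate": fit.estimates[j], "se": fit.se[j],
            "lower": lo, "upper": hi, "method": used,
            "significant": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model selection


def _apply_aic_rule(entries: list[dict]) -> tuple[dict, str]:
    """Two-step AIC rule on a list of {name, aic, k, order} entries."""
    best = min(entries, key=lambda e: e["aic"])
    rest = [e for e in entries if e is not best]
    if not rest or min(e["aic"] for e in rest) - best["aic"] > 2.0:
        return best, "delta_aic>2: lowest AIC"
    within = [e for e in entries if e["aic"] - best["aic"] <= 2.0]
    chosen = min(within, key=lambda e: (e["k"], e["order"]))
    return chosen, "delta_aic<=2: most parsimonious within 2 AIC units"


def candidate_specs(spec: ModelSpec) -> list[ModelSpec]:
    """All sub-models of the fixed structure, closed under marginality."""
    terms = list(spec.fixed)
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            mains = {t[0] for t in combo if len(t) == 1}
            if all(set(t) <= mains for t in combo if len(t) > 1):
                out.append(replace(spec, fixed=tuple(combo)))
    return out


def aic_select(candidates: list[ModelSpec], data: pd.DataFrame
               ) -> SelectionResult:
    """Fit every candidate on identical rows and apply the two-step rule."""
    union_vars = sorted(set().union(*(c.variables() for c in candidates)))
    present = [v for v in union_vars if v in data.columns]
    rows = data.dropna(subset=present)
    fits, entries = {}, []
    reference_rows = None
    for c in candidates:
        fit = fit_mixed(c, rows)
        if reference_rows is None:
            reference_rows = fit._problem.row_index
        elif fit._problem.row_index != reference_rows:
            raise ComparabilityError(
                f"candidate {c.label()!r} fitted on different rows"
            )
        name = c.label()
        fits[name] = fit
        entries.append({"name": name, "aic": fit.aic, "k": fit.k_params,
                        "order": tuple(sorted(c.term_names()))})
    chosen_entry, rule = _apply_aic_rule(entries)
    table = pd.DataFrame(entries).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["chosen"] = table["name"] == chosen_entry["name"]
    return SelectionResult(table=table.drop(columns="order"),
                           chosen=fits[chosen_entry["name"]],
                           rule=rule, fits=fits)


def random_structure_select(spec: ModelSpec, data: pd.DataFrame,
                            group: str, slope: str) -> SelectionResult:
    """Compare the four random structures for one grouping factor by AIC."""
    other = tuple(r for r in spec.random if r.group != group)
    candidates = [
        replace(spec, random=other + (RandomTerm(group, s, None if s ==
                                                 "intercept" else slope),))
        for s in _STRUCTURES
    ]
    fits, entries = {}, []
    for c, s in zip(candidates, _STRUCTURES):
        fit = fit_mixed(c, data)
        name = c.random[-1].label()
        fits[name] = fit
        entries.append({"name": name, "aic": fit.aic, "k": fit.k_params,
                        "order": (s,)})
    chosen_entry, rule = _apply_aic_rule(entries)
    table = pd.DataFrame(entries).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["chosen"] = table["name"] == chosen_entry["name"]
    return SelectionResult(table=table.drop(columns="order"),
                           chosen=fits[chosen_entry["name"]],
                           rule=rule, fits=fits)


# ---------------------------------------------------------------------------
# fit statistics and diagnostics


def r_squared_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional R² for a mixed model.

    Marginal: fixed-effect variance over total (fixed + random + residual);
    conditional adds the random-effect variance to the numerator.  The
    residual variance on the logit scale is π²/3.
    """
    prob: _MixedProblem = fit._problem
    eta_fixed = prob.X @ fit.estimates
    var_f = float(np.var(eta_fixed))
    zl = prob.zl(fit.theta)
    var_r = 0.0
    if zl is not None:
        var_r = float(np.mean(np.sum(zl ** 2, axis=1)))
        if fit.spec.family == "gaussian":
            var_r *= fit.sigma2
    var_e = (fit.sigma2 if fit.spec.family == "gaussian"
             else _LOGIT_RESID_VAR)
    total = var_f + var_r + var_e
    marginal = var_f / total
    conditional = (var_f + var_r) / total
    return float(np.clip(marginal, 0, 1)), float(np.clip(conditional, 0, 1))


def ks_normality(values) -> dict:
    """Two-sided one-sample KS test against a moment-matched normal."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise ValueError("need at least 5 values for the KS check")
    if np.ptp(v) == 0:
        raise DegenerateGroupError("constant input: KS check undefined")
    d, p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return {"D": float(d), "p": float(p), "n": int(v.size)}


def collinearity_screen(data: pd.DataFrame, covariates: list[str],
                        cutoff: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations among covariates, flagged above 0.7."""
    rows = []
    for a, b in itertools.combinations(covariates, 2):
        sub = data[[a, b]].dropna()
        r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        rows.append({"var_a": a, "var_b": b, "pearson_r": r,
                     "flagged": bool(abs(r) > cutoff)})
    return pd.DataFrame(rows)
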