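"""Heteroscedastic replicate mixed model for MBW outcomes.

The model for outcome ``y`` of individual *i*, scenario *s*, replicate *k*:

    y_{isk} = mu + alpha_s + b_i + c_{is} + eps_{isk}

with ``alpha_none = 0``, individual effect ``b_i ~ N(0, omega^2)``,
individual-by-scenario interaction ``c_{is} ~ N(0, tau^2)`` (one SD shared
across scenarios), and scenario-specific residual ``eps ~ N(0, sigma_s^2)``.
Each individual's observations are jointly normal with covariance

    Sigma_i = omega^2 J + tau^2 S + diag(sigma_s^2)

where J is all-ones and S indicates same-scenario pairs. The marginal
likelihood is evaluated per individual block; individuals sharing the same
scenario pattern share a covariance factorisation, so the whole-cohort
likelihood costs one Cholesky per distinct pattern.

Fitting maximises the marginal likelihood. For fixed variance components the
fixed effects have a closed-form GLS solution, so the numeric search runs
over (log omega, log tau, log sigma_s) only, with multi-start quasi-Newton
(L-BFGS-B). Wald confidence intervals come from the finite-difference Hessian
of the full (unprofiled) log-likelihood; variance-component intervals are
formed on the log scale and exponentiated, and residual-SD ratios use the
delta method on the log scale. REML is available behind a flag for
cross-checks. Pre-fit filters (outlier rules, sparse-scenario removal) and
BLUPs of the random effects are also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "ModelParams",
    "FitResult",
    "exclude_outliers",
    "drop_sparse_scenarios",
    "loglik",
    "fit_ml",
    "blups",
    "DEFAULT_OUTLIER_RULES",
]

_LOG2PI = math.log(2.0 * math.pi)
_Z95 = norm.ppf(0.975)

#: Default exclusion rules: a test is dropped when *all* conditions of any
#: one rule hold (column -> strict lower threshold).
DEFAULT_OUTLIER_RULES: tuple[dict, ...] = (
    {"lci": 9.5},
    {"cev_l": 1.4, "lci": 9.0},
)


@dataclass
class ModelParams:
    """Parameters of the replicate model for a single outcome variable.

    ``alpha`` maps scenario to mean shift (``none`` fixed at 0); ``sigma``
    maps scenario to residual SD. ``omega`` and ``tau`` are the SDs of the
    individual effect and the individual-by-scenario interaction.
    """

    mu: float
    alpha: dict[str, float]
    omega: float
    tau: float
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        self.alpha = dict(self.alpha)
        self.sigma = dict(self.sigma)
        self.alpha.setdefault("none", 0.0)
        if self.alpha["none"] != 0.0:
            raise ValueError("alpha['none'] must be 0 (reference scenario)")
        if self.omega < 0 or self.tau < 0:
            raise ValueError("omega and tau must be non-negative")
        if any(v < 0 for v in self.sigma.values()):
            # zero is allowed for simulation of degenerate cases; the
            # likelihood itself rejects singular covariances
            raise ValueError("residual SDs must be non-negative")
        missing = set(self.alpha) - set(self.sigma)
        if missing - {"none"}:
            raise ValueError(f"scenarios with alpha but no sigma: {sorted(missing)}")

    def scenarios(self) -> list[str]:
        """Scenarios with a residual SD, reference (``none``) first."""
        return sorted(self.sigma, key=lambda s: (s != "none", s))

    def sd_ratio(self, scenario: str) -> float:
        """Residual-SD ratio sigma_s / sigma_none."""
        return self.sigma[scenario] / self.sigma["none"]

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "alpha": dict(self.alpha),
            "omega": self.omega,
            "tau": self.tau,
            "sigma": dict(self.sigma),
            "sigma_ratio": {
                s: self.sd_ratio(s) for s in self.scenarios() if s != "none"
            },
        }


@dataclass
class FitResult:
    """Maximum-likelihood fit of the replicate model."""

    params: ModelParams
    loglik: float
    ci: dict[str, tuple[float, float]]
    se: dict[str, float]
    n_used: int
    n_individuals: int
    excluded: list = field(default_factory=list)
    converged: bool = True
    boundary: bool = False
    method: str = "ml"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "se": dict(self.se),
            "n_used": self.n_used,
            "n_individuals": self.n_individuals,
            "excluded": list(self.excluded),
            "converged": self.converged,
            "boundary": self.boundary,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# Pre-fit filtering


def exclude_outliers(
    outcomes: pd.DataFrame,
    rules: Sequence[Mapping[str, float]] = DEFAULT_OUTLIER_RULES,
    id_col: str = "test_id",
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop tests with extreme outcome values.

    Each rule is a mapping column -> threshold; a test is excluded when every
    listed column strictly exceeds its threshold (rules combine by OR). Rules
    referring to columns absent from the table are skipped. Returns the
    filtered table and a log of exclusions with reasons.
    """
    mask = pd.Series(False, index=outcomes.index)
    reasons = pd.Series("", index=outcomes.index)
    for rule in rules:
        if not set(rule) <= set(outcomes.columns):
            continue
        hit = pd.Series(True, index=outcomes.index)
        for col, thr in rule.items():
            hit &= outcomes[col] > thr
        desc = " and ".join(f"{c} > {t}" for c, t in rule.items())
        reasons[hit & ~mask] = desc
        mask |= hit
    log = [
        {"test_id": outcomes.loc[i, id_col] if id_col in outcomes else i,
         "reason": reasons[i]}
        for i in outcomes.index[mask]
    ]
    return outcomes[~mask].copy(), log


def drop_sparse_scenarios(
    outcomes: pd.DataFrame,
    min_n: int = 20,
    scenario_col: str = "scenario",
) -> pd.DataFrame:
    """Remove all tests of scenarios with fewer than ``min_n`` tests."""
    counts = outcomes[scenario_col].value_counts()
    keep = counts[counts >= min_n].index
    return outcomes[outcomes[scenario_col].isin(keep)].copy()


# ---------------------------------------------------------------------------
# Likelihood machinery


class _BlockData:
    """Cohort grouped by scenario pattern for fast block likelihoods.

    Within each individual, tests are sorted by scenario so that individuals
    with the same multiset of scenarios share one covariance matrix.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        outcome_col: str,
        id_col: str = "individual_id",
        scenario_col: str = "scenario",
    ) -> None:
        scenarios = sorted(
            df[scenario_col].unique(), key=lambda s: (s != "none", s)
        )
        self.scenarios: list[str] = list(scenarios)
        smap = {s: i for i, s in enumerate(self.scenarios)}
        self.n_obs = len(df)
        self.n_groups = df[id_col].nunique()

        patterns: dict[tuple, list[np.ndarray]] = {}
        y_all = df[outcome_col].to_numpy(dtype=float)
        sidx_all = df[scenario_col].map(smap).to_numpy()
        codes, _ = pd.factorize(df[id_col], sort=False)
        order = np.argsort(codes, kind="stable")
        bounds = np.flatnonzero(np.diff(codes[order])) + 1
        for rows in np.split(order, bounds):
            s = sidx_all[rows]
            o = np.argsort(s, kind="stable")
            key = tuple(s[o])
            patterns.setdefault(key, []).append(y_all[rows][o])
        self.blocks: list[tuple[np.ndarray, np.ndarray]] = [
            (np.array(key, dtype=int), np.vstack(ys))
            for key, ys in patterns.items()
        ]

    # -- evaluation ---------------------------------------------------------

    def loglik(self, beta: np.ndarray, vparams: np.ndarray) -> float:
        """Marginal log-likelihood at fixed effects ``beta`` (mu then the
        non-reference alphas in scenario order) and variance components
        ``vparams = (omega, tau, sigma_0..sigma_{S-1})``."""
        omega, tau = vparams[0], vparams[1]
        sig2 = vparams[2:] ** 2
        mean_by_scen = self._mean_by_scenario(beta)
        total = 0.0
        for sidx, Y in self.blocks:
            V = self._cov(sidx, omega, tau, sig2)
            L = np.linalg.cholesky(V)
            R = Y - mean_by_scen[sidx]
            z = solve_triangular(L, R.T, lower=True)
            m, k = Y.shape
            total += (
                -0.5 * m * k * _LOG2PI
                - m * float(np.sum(np.log(np.diag(L))))
                - 0.5 * float(np.sum(z * z))
            )
        return total

    def profile_negloglik(
        self, log_vparams: np.ndarray, reml: bool = False
    ) -> tuple[float, np.ndarray]:
        """Negative log-likelihood profiled over the fixed effects.

        Returns the criterion value and the GLS fixed-effect estimates. With
        ``reml=True`` the REML adjustment ``+ 0.5 log|X' V^-1 X|`` is added.
        Points where a block covariance is numerically non-positive-definite
        (extreme variance ratios explored during line search) evaluate to
        ``+inf`` so the optimiser backtracks.
        """
        vparams = np.exp(log_vparams)
        omega, tau = vparams[0], vparams[1]
        sig2 = vparams[2:] ** 2
        p = len(self.scenarios)
        A = np.zeros((p, p))
        rhs = np.zeros(p)
        cache = []
        for sidx, Y in self.blocks:
            V = self._cov(sidx, omega, tau, sig2)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return float("inf"), np.zeros(len(self.scenarios))
            X = self._design(sidx)
            Vinv_X = cho_solve((L, True), X)
            m = Y.shape[0]
            A += m * X.T @ Vinv_X
            rhs += Vinv_X.T @ Y.sum(axis=0)
            cache.append((sidx, Y, L))
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(rhs))):
            return float("inf"), np.zeros(len(self.scenarios))
        beta = np.linalg.solve(A, rhs)
        mean_by_scen = self._mean_by_scenario(beta)
        total = 0.0
        for sidx, Y, L in cache:
            R = Y - mean_by_scen[sidx]
            z = solve_triangular(L, R.T, lower=True)
            m, k = Y.shape
            total += (
                -0.5 * m * k * _LOG2PI
                - m * float(np.sum(np.log(np.diag(L))))
                - 0.5 * float(np.sum(z * z))
            )
        if reml:
            sign, logdet = np.linalg.slogdet(A)
            if sign <= 0:
                raise np.linalg.LinAlgError("X'V^-1X not positive definite")
            total -= 0.5 * logdet
        return -total, beta

    # -- helpers ------------------------------------------------------------

    @property
    def _p(self) -> int:
        return len(self.scenarios)

    def _design(self, sidx: np.ndarray) -> np.ndarray:
        """Fixed-effect design rows for a scenario-index vector."""
        k = sidx.size
        p = len(self.scenarios)
        X = np.zeros((k, p))
        X[:, 0] = 1.0
        for j in range(1, p):
            X[:, j] = sidx == j
        return X

    def _mean_by_scenario(self, beta: np.ndarray) -> np.ndarray:
        mean = np.full(len(self.scenarios), beta[0])
        mean[1:] += beta[1:]
        return mean

    @staticmethod
    def _cov(sidx: np.ndarray, omega: float, tau: float, sig2: np.ndarray):
        S = sidx[:, None] == sidx[None, :]
        V = omega**2 + tau**2 * S + np.diag(sig2[sidx])
        return V

    def params_to_theta(self, params: ModelParams, clamp: bool = False) -> np.ndarray:
        """Pack parameters as (beta, log variance components).

        With ``clamp`` zero components map to a tiny positive value (useful
        for optimiser starting points); otherwise they map to -inf so that a
        degenerate covariance is evaluated as such.
        """
        beta = [params.mu] + [params.alpha.get(s, 0.0) for s in self.scenarios[1:]]
        v = [params.omega, params.tau] + [params.sigma[s] for s in self.scenarios]
        if clamp:
            logs = [math.log(max(x, 1e-6)) for x in v]
        else:
            logs = [math.log(x) if x > 0 else -math.inf for x in v]
        return np.array(beta + logs)

    def theta_to_params(self, theta: np.ndarray) -> ModelParams:
        p = len(self.scenarios)
        beta = theta[:p]
        v = np.exp(theta[p:])
        alpha = {"none": 0.0}
        alpha.update({s: float(b) for s, b in zip(self.scenarios[1:], beta[1:])})
        sigma = {s: float(x) for s, x in zip(self.scenarios, v[2:])}
        return ModelParams(
            mu=float(beta[0]), alpha=alpha, omega=float(v[0]), tau=float(v[1]),
            sigma=sigma,
        )

    def full_loglik_theta(self, theta: np.ndarray) -> float:
        p = len(self.scenarios)
        return self.loglik(theta[:p], np.exp(theta[p:]))


def loglik(
    params: ModelParams,
    outcomes: pd.DataFrame,
    outcome_col: str = "lci",
    id_col: str = "individual_id",
    scenario_col: str = "scenario",
) -> float:
    """Marginal log-likelihood of a cohort table under ``params``.

    Evaluated block-by-block per individual; raises on scenarios missing from
    the parameters or on a singular block covariance.
    """
    data = _BlockData(outcomes, outcome_col, id_col, scenario_col)
    missing = set(data.scenarios) - set(params.sigma)
    if missing:
        raise KeyError(f"scenarios missing from params: {sorted(missing)}")
    theta = data.params_to_theta(params)
    try:
        return data.full_loglik_theta(theta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular block covariance (all variance components ~ 0?)"
        ) from exc


# ---------------------------------------------------------------------------
# Fitting


def _log_scale_ci(est: float, s_log: float) -> tuple[float, float]:
    """95% interval for a positive parameter from its log-scale SE."""
    if not np.isfinite(s_log):
        return (float("nan"), float("nan"))
    spread = min(_Z95 * s_log, 300.0)  # guard exp overflow for wild SEs
    return (est * math.exp(-spread), est * math.exp(spread))


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _moment_init(data: _BlockData) -> np.ndarray:
    """Rough moment-based starting values for the variance components."""
    per_scen_sd = []
    ys = {i: [] for i in range(len(data.scenarios))}
    indiv_means = []
    for sidx, Y in data.blocks:
        for j, s in enumerate(sidx):
            ys[s].extend(Y[:, j].tolist())
        indiv_means.extend(Y.mean(axis=1).tolist())
    for i in range(len(data.scenarios)):
        arr = np.array(ys[i])
        per_scen_sd.append(float(np.std(arr)) if arr.size > 1 else 1.0)
    sd_ref = per_scen_sd[0] if per_scen_sd[0] > 0 else 1.0
    omega0 = max(0.5 * sd_ref, 1e-3)
    tau0 = max(0.25 * sd_ref, 1e-3)
    sigma0 = [max(0.75 * s, 1e-3) for s in per_scen_sd]
    return np.log(np.array([omega0, tau0] + sigma0))


def fit_ml(
    outcomes: pd.DataFrame,
    init: ModelParams | None = None,
    *,
    outcome_col: str = "lci",
    id_col: str = "individual_id",
    scenario_col: str = "scenario",
    n_starts: int = 5,
    seed: int = 0,
    reml: bool = False,
    log_bounds: tuple[float, float] = (-12.0, 6.0),
    gtol: float = 1e-7,
) -> FitResult:
    """Fit the replicate model by maximum likelihood.

    Fixed effects are profiled out by GLS, so the numeric search is over the
    log variance components only; ``n_starts`` L-BFGS-B runs (a moment-based
    start plus seeded random perturbations) guard against local optima. Wald
    95% intervals are derived from the finite-difference Hessian of the full
    log-likelihood; variance components and residual-SD ratios get intervals
    on the log scale. Estimates pinned at the box bounds are flagged
    ``boundary`` (e.g. omega -> 0), not treated as failures.
    """
    data = _BlockData(outcomes, outcome_col, id_col, scenario_col)
    if len(data.blocks) == 0:
        raise ValueError("no data to fit")
    rng = np.random.default_rng(seed)

    x0 = (
        data.params_to_theta(init, clamp=True)[len(data.scenarios):]
        if init is not None
        else _moment_init(data)
    )
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(x0 + rng.normal(0.0, 0.5, size=x0.size))

    lo, hi = log_bounds
    bounds = [(lo, hi)] * x0.size
    best = None
    any_success = False
    # inf objective values at degenerate points trip numpy warnings inside
    # the finite-difference gradient; they are expected and handled
    with np.errstate(invalid="ignore", over="ignore"):
        for s in starts:
            try:
                res = minimize(
                    lambda x: data.profile_negloglik(x, reml=reml)[0],
                    np.clip(s, lo, hi),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
                )
            except np.linalg.LinAlgError:
                continue
            if best is None or res.fun < best.fun:
                best = res
            any_success = any_success or bool(res.success)
    if best is None:
        raise RuntimeError("all optimisation starts failed (singular covariance)")

    neg, beta = data.profile_negloglik(best.x, reml=reml)
    theta = np.concatenate([beta, best.x])
    params = data.theta_to_params(theta)
    ll = data.full_loglik_theta(theta)
    boundary = bool(np.any(best.x <= lo + 0.5) or np.any(best.x >= hi - 0.5))

    # Wald machinery on theta = (beta, log variance components)
    H = _numeric_hessian(lambda th: -data.full_loglik_theta(th), theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan  # non-PD Hessian (boundary fits)

    p = len(data.scenarios)
    names_beta = ["mu"] + [f"alpha:{s}" for s in data.scenarios[1:]]
    names_v = ["omega", "tau"] + [f"sigma:{s}" for s in data.scenarios]
    se: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(names_beta):
        s_ = math.sqrt(var[j]) if np.isfinite(var[j]) else float("nan")
        se[name] = s_
        ci[name] = (theta[j] - _Z95 * s_, theta[j] + _Z95 * s_)
    for j, name in enumerate(names_v):
        k = p + j
        s_log = math.sqrt(var[k]) if np.isfinite(var[k]) else float("nan")
        est = math.exp(theta[k])
        se[name] = est * s_log  # delta method on the natural scale
        ci[name] = _log_scale_ci(est, s_log)
    # residual-SD ratios sigma_s / sigma_none via the delta method (log scale)
    k_none = p + 2
    for j, scen in enumerate(data.scenarios[1:], start=1):
        k_s = p + 2 + j
        log_ratio = theta[k_s] - theta[k_none]
        v = cov[k_s, k_s] + cov[k_none, k_none] - 2 * cov[k_s, k_none]
        s_log = math.sqrt(v) if v > 0 else float("nan")
        est = math.exp(log_ratio)
        name = f"sigma_ratio:{scen}"
        se[name] = est * s_log
        ci[name] = _log_scale_ci(est, s_log)

    return FitResult(
        params=params,
        loglik=float(ll),
        ci=ci,
        se=se,
        n_used=data.n_obs,
        n_individuals=data.n_groups,
        converged=any_success,
        boundary=boundary,
        method="reml" if reml else "ml",
    )


def blups(
    params: ModelParams,
    outcomes: pd.DataFrame,
    outcome_col: str = "lci",
    id_col: str = "individual_id",
    scenario_col: str = "scenario",
) -> pd.DataFrame:
    """Best linear unbiased predictors of the random effects.

    Returns one row per individual effect (``effect == 'individual'``) and per
    individual-by-scenario interaction (``effect == 'interaction'``), via the
    conditional-normal formula ``G Z' V^{-1} (y - X beta)``.
    """
    rows = []
    for indiv, g in outcomes.groupby(id_col, sort=True):
        scen = g[scenario_col].tolist()
        y = g[outcome_col].to_numpy(dtype=float)
        mean = np.array([params.mu + params.alpha.get(s, 0.0) for s in scen])
        uniq = sorted(set(scen))
        k = len(scen)
        Z = np.zeros((k, 1 + len(uniq)))
        Z[:, 0] = 1.0
        for j, s in enumerate(uniq):
            Z[:, 1 + j] = [x == s for x in scen]
        G = np.diag([params.omega**2] + [params.tau**2] * len(uniq))
        sig2 = np.array([params.sigma[s] ** 2 for s in scen])
        V = Z @ G @ Z.T + np.diag(sig2)
        u = G @ Z.T @ np.linalg.solve(V, y - mean)
        rows.append(
            {"individual_id": indiv, "effect": "individual", "scenario": None,
             "blup": float(u[0])}
        )
        for j, s in enumerate(uniq):
            rows.append(
                {"individual_id": indiv, "effect": "interaction", "scenario": s,
                 "blup": float(u[1 + j])}
            )
    return pd.DataFrame(rows)


def standardized_residuals(
    params: ModelParams,
    outcomes: pd.DataFrame,
    outcome_col: str = "lci",
    id_col: str = "individual_id",
    scenario_col: str = "scenario",
) -> pd.DataFrame:
    """Residuals after removing fixed effects and BLUPs, scaled by sigma_s.

    Used to inspect model fit per scenario.
    """
    out = outcomes.copy()
    resid = np.empty(len(out), dtype=float)
    pos = {idx: i for i, idx in enumerate(out.index)}
    for indiv, g in outcomes.groupby(id_col, sort=True):
        scen = g[scenario_col].tolist()
        y = g[outcome_col].to_numpy(dtype=float)
        mean = np.array([params.mu + params.alpha.get(s, 0.0) for s in scen])
        uniq = sorted(set(scen))
        Z = np.zeros((len(scen), 1 + len(uniq)))
        Z[:, 0] = 1.0
        for j, s in enumerate(uniq):
            Z[:, 1 + j] = [x == s for x in scen]
        G = np.diag([params.omega**2] + [params.tau**2] * len(uniq))
        sig = np.array([params.sigma[s] for s in scen])
        V = Z @ G @ Z.T + np.diag(sig**2)
        u = G @ Z.T @ np.linalg.solve(V, y - mean)
        r = (y - mean - Z @ u) / sig
        for idx, val in zip(g.index, r):
            resid[pos[idx]] = val
    out["std_resid"] = resid
    return out
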