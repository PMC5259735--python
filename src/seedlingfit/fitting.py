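"""Generalized non-linear least squares for grouped growth trajectories.

The observation model: plant ``i`` of line ``l`` measured on days
``t_1 < ... < t_m`` yields

    y_ij = f(t_j; theta_{g(l)}) + e_ij,

where ``f`` is one of the registered curve families, ``g`` maps lines to
the parameter levels of a grouping scheme, and the within-plant error
vector is Gaussian with covariance

    Cov(e_ij, e_ij') = sigma^2 * v(t_j) v(t_j') * rho^{|j - j'|}.

``rho`` is a first-order autoregressive (AR1) coefficient applied per
observation-order step (the design is equally spaced); ``v`` is a variance
function of the measurement day — constant, exponential ``exp(delta * t)``,
or one free ratio per harvest day (first day anchored at 1).  Plants are
independent, so the likelihood factorizes over per-plant blocks.

Estimation is full maximum likelihood: the residual scale ``sigma`` is
profiled out analytically and the remaining parameters are optimized by
quasi-Newton iterations on transformed coordinates (log for positive
parameters, atanh for ``rho``), with seeded multi-start as a
non-convergence fallback.  Standard errors for the curve parameters come
from the generalized least-squares information ``J' Sigma^{-1} J`` at the
optimum (variance parameters held at their estimates, as is conventional
for this model class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cholesky as _cholesky, solve_triangular

from . import curves
from .curves import family_info
from .data import Dataset
from .grouping import GroupingScheme

__all__ = [
    "CovarianceSpec",
    "ModelSpec",
    "FitControl",
    "FitResult",
    "build_plant_covariance",
    "negative_log_likelihood",
    "initial_values",
    "fit_gnls",
    "asymptotic_ci",
]

_Z975 = stats.norm.ppf(0.975)
_EXP_CLIP = 350.0


@dataclass(frozen=True)
class CovarianceSpec:
    """Within-plant error structure.

    correlation : "ar1" (estimate rho) or "independent"
    variance    : "constant", "exponential" (sd multiplier exp(delta*day))
                  or "per_stratum" (one sd ratio per harvest day, first
                  day fixed at 1)
    """

    correlation: str = "ar1"
    variance: str = "exponential"

    def __post_init__(self):
        if self.correlation not in ("ar1", "independent"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.variance not in ("constant", "exponential", "per_stratum"):
            raise ValueError(f"unknown variance model {self.variance!r}")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: trait, curve family, grouping and covariance."""

    trait: str
    family: str
    scheme: GroupingScheme
    covariance: CovarianceSpec = field(default_factory=CovarianceSpec)

    def __post_init__(self):
        family_info(self.family)


@dataclass(frozen=True)
class FitControl:
    """Optimizer settings; defaults are conventional and recorded in the
    result."""

    maxiter: int = 500
    tol: float = 1e-8          # relative log-likelihood change
    grad_tol: float = 1e-5
    n_starts: int = 5          # multi-start fallback on non-convergence
    seed: int = 0
    free_decay_rate: bool = False


@dataclass
class FitResult:
    """Maximum-likelihood fit of one grouped trajectory model."""

    spec: ModelSpec
    estimates: dict            # level -> curve parameter dataclass
    sigma: float
    rho: float | None
    delta: float | None
    stratum_ratios: dict | None   # day -> sd ratio (first day 1.0)
    loglik: float
    n_obs: int
    n_params: int
    param_index: tuple         # ((level, param_name), ...) for cov rows
    cov: np.ndarray            # covariance of the curve-parameter estimates
    se: dict                   # (level, param_name) -> float
    ci95: dict                 # (level, param_name) -> (lo, hi)
    converged: bool
    n_iter: int
    grad_norm: float
    message: str

    def estimate_of(self, level: str, name: str) -> float:
        return float(getattr(self.estimates[level], name))

    def estimates_table(self) -> pd.DataFrame:
        """Per-parameter table with columns parameter, level, estimate,
        se, ll95, ul95 (the layout of a published estimates table)."""
        rows = []
        for level, name in self.param_index:
            lo, hi = self.ci95[(level, name)]
            rows.append((name, level, self.estimate_of(level, name),
                         self.se[(level, name)], lo, hi))
        return pd.DataFrame(
            rows, columns=["parameter", "level", "estimate", "se",
                           "ll95", "ul95"])


# ---------------------------------------------------------------------------
# covariance pieces

def _variance_multiplier(covariance: CovarianceSpec, days: np.ndarray,
                         delta: float | None,
                         ratios: Mapping | None) -> np.ndarray:
    if covariance.variance == "constant":
        return np.ones_like(days, dtype=float)
    if covariance.variance == "exponential":
        if delta is None:
            raise ValueError("exponential variance needs a delta coefficient")
        return np.exp(np.clip(float(delta) * days, -_EXP_CLIP, _EXP_CLIP))
    if ratios is None:
        raise ValueError("per_stratum variance needs per-day ratios")
    try:
        return np.array([float(ratios[d]) for d in days])
    except KeyError as err:
        raise ValueError(f"no variance ratio for harvest day {err}") from None


def build_plant_covariance(covariance: CovarianceSpec,
                           days: Sequence[float], *, sigma: float = 1.0,
                           rho: float = 0.0, delta: float | None = None,
                           ratios: Mapping | None = None) -> np.ndarray:
    """Within-plant covariance block sigma^2 v_i v_j rho^|i-j|.

    ``days`` must be sorted; the AR1 exponent is the observation-order lag.
    """
    days = np.asarray(days, dtype=float)
    if days.size < 1 or np.any(np.diff(days) <= 0):
        raise ValueError("days must be sorted strictly increasing, >= 1 entry")
    if abs(rho) >= 1:
        raise ValueError("AR1 coefficient must satisfy |rho| < 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = _variance_multiplier(covariance, days, delta, ratios)
    lag = np.abs(np.subtract.outer(np.arange(days.size),
                                   np.arange(days.size)))
    corr = np.asarray(rho, dtype=float) ** lag
    return sigma ** 2 * np.outer(v, v) * corr


# ---------------------------------------------------------------------------
# problem container

class _Problem:
    """Preprocessed arrays for one trait under one model spec."""

    def __init__(self, spec: ModelSpec, data: Dataset,
                 control: FitControl):
        self.spec = spec
        self.control = control
        sub = data.subset(spec.trait).sort_values(
            ["plant_id", "day"], kind="mergesort").reset_index(drop=True)
        unmapped = sorted(set(sub["line_id"]) - set(spec.scheme.level_of))
        if unmapped:
            raise ValueError(f"lines {unmapped} have no level under scheme "
                             f"{spec.scheme.name}")
        self.t = sub["day"].to_numpy(dtype=float)
        self.y = sub["value"].to_numpy(dtype=float)
        self.n = len(sub)
        self.strata = np.unique(self.t)
        if self.strata.size < 2:
            raise ValueError(
                "need measurements on >= 2 distinct days to fit a curve")
        self.levels = spec.scheme.levels
        level_pos = {lv: i for i, lv in enumerate(self.levels)}
        self.level_idx = np.array(
            [level_pos[spec.scheme.level_of[l]] for l in sub["line_id"]])
        observed = set(self.level_idx)
        missing = [lv for lv, i in level_pos.items() if i not in observed]
        if missing:
            raise ValueError(f"levels {missing} have no observations")

        # group plants by their day pattern so each distinct covariance
        # block is factorized once per likelihood evaluation
        patterns: dict[tuple, list] = {}
        for _, idx in sub.groupby("plant_id", sort=False).indices.items():
            idx = np.asarray(idx)
            patterns.setdefault(tuple(self.t[idx]), []).append(idx)
        self.patterns = [(np.array(key), np.vstack(rows))
                         for key, rows in patterns.items()]
        self.max_block = max(len(key) for key, _ in self.patterns)
        if (spec.covariance.correlation == "ar1" and self.max_block < 2):
            raise ValueError(
                "AR1 correlation is not identifiable: no plant has more "
                "than one observation (destructive sampling) — use "
                "correlation='independent'")

        fam = family_info(spec.family)
        self.family = fam
        self.free_names = list(fam.param_names)
        if spec.family == "decay" and not control.free_decay_rate:
            self.free_names.remove("rate")
        self.p_free = len(self.free_names)
        self.has_rho = spec.covariance.correlation == "ar1"
        self.var_kind = spec.covariance.variance
        self.n_var_free = {"constant": 0, "exponential": 1,
                           "per_stratum": self.strata.size - 1}[self.var_kind]
        self.n_params = (len(self.levels) * self.p_free + 1  # sigma
                         + int(self.has_rho) + self.n_var_free)

    # -- parameter packing --------------------------------------------------

    def _transform_level(self, p) -> np.ndarray:
        a = p.to_array()
        if self.spec.family == "expolinear":
            x = [math.log(a[0]), math.log(a[1]), a[2]]
        elif self.spec.family == "gompertz":
            x = [math.log(a[0]), math.log(a[1]), a[2]]
        else:  # decay: (maximum, minimum, tt[, rate])
            x = [math.log(max(a[0] - a[1], 1e-10)),
                 math.log(max(a[1], 1e-10)), a[2]]
            if "rate" in self.free_names:
                x.append(math.log(a[3]))
        return np.array(x)

    def _untransform_level(self, x: np.ndarray):
        f = self.spec.family
        if f == "expolinear":
            return curves.ExpolinearParams(math.exp(x[0]), math.exp(x[1]),
                                           x[2])
        if f == "gompertz":
            return curves.GompertzParams(math.exp(x[0]), math.exp(x[1]),
                                         x[2])
        minimum = math.exp(x[1])
        maximum = minimum + math.exp(x[0])
        rate = math.exp(x[3]) if "rate" in self.free_names else 1.0
        return curves.DecayParams(maximum, minimum, x[2], rate)

    def pack(self, estimates: Mapping, rho: float | None,
             delta: float | None, ratios: Mapping | None) -> np.ndarray:
        x = [self._transform_level(estimates[lv]) for lv in self.levels]
        x = list(np.concatenate(x))
        if self.has_rho:
            x.append(math.atanh(0.0 if rho is None else rho))
        if self.var_kind == "exponential":
            x.append(0.0 if delta is None else float(delta))
        elif self.var_kind == "per_stratum":
            for d in self.strata[1:]:
                r = 1.0 if ratios is None else float(ratios[d])
                x.append(math.log(r))
        return np.array(x)

    def unpack(self, x: np.ndarray):
        L, p = len(self.levels), self.p_free
        estimates = {lv: self._untransform_level(x[i * p:(i + 1) * p])
                     for i, lv in enumerate(self.levels)}
        pos = L * p
        rho = None
        if self.has_rho:
            rho = math.tanh(x[pos]); pos += 1
        delta = None
        ratios = None
        if self.var_kind == "exponential":
            delta = float(x[pos]); pos += 1
        elif self.var_kind == "per_stratum":
            ratios = {self.strata[0]: 1.0}
            for d, xr in zip(self.strata[1:], x[pos:]):
                ratios[d] = math.exp(min(xr, _EXP_CLIP))
        return estimates, rho, delta, ratios

    # -- likelihood ---------------------------------------------------------

    def mean(self, estimates: Mapping) -> np.ndarray:
        theta = np.array([estimates[lv].to_array() for lv in self.levels])
        cols = [theta[self.level_idx, j] for j in range(theta.shape[1])]
        return self.family.value(self.t, *cols)

    def _quad_logdet(self, resid: np.ndarray, rho: float | None,
                     delta: float | None, ratios: Mapping | None):
        rho = 0.0 if rho is None else rho
        quad = 0.0
        logdet = 0.0
        for days, idx in self.patterns:
            m = days.size
            v = _variance_multiplier(self.spec.covariance, days, delta,
                                     ratios)
            lag = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            V = np.outer(v, v) * rho ** lag
            try:
                L = _cholesky(V, lower=True)
            except np.linalg.LinAlgError as err:
                raise FloatingPointError(
                    f"covariance block for days {days} is not positive "
                    f"definite (rho={rho}, variance={self.var_kind})"
                ) from err
            X = solve_triangular(L, resid[idx].T, lower=True)
            quad += float(np.sum(X * X))
            logdet += 2.0 * idx.shape[0] * float(np.sum(np.log(np.diag(L))))
        return quad, logdet

    def nll_profiled(self, x: np.ndarray) -> float:
        try:
            estimates, rho, delta, ratios = self.unpack(x)
        except (OverflowError, ValueError):
            return 1e12
        resid = self.y - self.mean(estimates)
        try:
            quad, logdet = self._quad_logdet(resid, rho, delta, ratios)
        except FloatingPointError:
            return 1e12
        if quad <= 0:
            quad = 1e-300
        sigma2 = quad / self.n
        return 0.5 * (self.n * (math.log(2 * math.pi) + 1.0
                                + math.log(sigma2)) + logdet)

    def sigma_hat(self, x: np.ndarray) -> float:
        estimates, rho, delta, ratios = self.unpack(x)
        resid = self.y - self.mean(estimates)
        quad, _ = self._quad_logdet(resid, rho, delta, ratios)
        return math.sqrt(quad / self.n)

    # -- asymptotic covariance of the curve parameters ----------------------

    def mean_information(self, estimates: Mapping, sigma: float,
                         rho: float | None, delta: float | None,
                         ratios: Mapping | None) -> np.ndarray:
        fam = self.family
        theta = np.array([estimates[lv].to_array() for lv in self.levels])
        cols = [theta[self.level_idx, j] for j in range(theta.shape[1])]
        grads = fam.grad(self.t, *cols)  # (n, n_declared)
        keep = [fam.param_names.index(nm) for nm in self.free_names]
        grads = grads[:, keep]
        q = self.p_free
        L_levels = len(self.levels)
        J = np.zeros((self.n, L_levels * q))
        for i in range(L_levels):
            rows = self.level_idx == i
            J[rows, i * q:(i + 1) * q] = grads[rows]
        rho = 0.0 if rho is None else rho
        info = np.zeros((J.shape[1], J.shape[1]))
        for days, idx in self.patterns:
            m = days.size
            v = _variance_multiplier(self.spec.covariance, days, delta,
                                     ratios)
            lag = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            V = np.outer(v, v) * rho ** lag
            Lc = _cholesky(V, lower=True)
            Jp = J[idx.reshape(-1)].reshape(idx.shape[0], m, -1)
            B = Jp.transpose(1, 0, 2).reshape(m, -1)
            X = solve_triangular(Lc, B, lower=True)
            X = X.reshape(m, idx.shape[0], -1)
            info += np.einsum("mpq,mpr->qr", X, X)
        return info / sigma ** 2


# ---------------------------------------------------------------------------
# public operations

def negative_log_likelihood(spec: ModelSpec, params: Mapping,
                            data: Dataset) -> float:
    """Exact Gaussian negative log-likelihood of a full parameter set.

    ``params`` maps ``"levels"`` to a level -> curve-parameter mapping and
    supplies the nuisance values ``"sigma"`` plus, as required by the
    covariance spec, ``"rho"``, ``"delta"`` or ``"ratios"``.
    """
    prob = _Problem(spec, data, FitControl())
    levels = params["levels"]
    missing = [lv for lv in prob.levels if lv not in levels]
    if missing:
        raise ValueError(f"missing curve parameters for levels {missing}")
    sigma = float(params["sigma"])
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rho = params.get("rho")
    if prob.has_rho and rho is None:
        raise ValueError("covariance spec requires an AR1 rho")
    delta = params.get("delta")
    ratios = params.get("ratios")
    resid = prob.y - prob.mean(levels)
    quad, logdet = prob._quad_logdet(resid, rho, delta, ratios)
    n = prob.n
    return 0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma ** 2)
                  + logdet + quad / sigma ** 2)


def _day_means(t: np.ndarray, y: np.ndarray):
    days = np.unique(t)
    means = np.array([y[t == d].mean() for d in days])
    return days, means


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    return float(xc @ (y - y.mean()) / denom) if denom > 0 else 0.0


def initial_values(family: str, data_by_level: Mapping) -> dict:
    """Data-driven starting points, one parameter set per level.

    ``data_by_level`` maps each level to a ``(t, y)`` pair of arrays.
    Heuristics: expolinear takes the terminal slope as Cm, the terminal
    line's x-intercept as tb and the early log-linear slope as Rm;
    Gompertz takes 1.05 x the maximum as Wf, the day nearest Wf/e as TT
    and a log-log regression slope as k; decay takes the first/last
    harvest means as Max/Min and the mid-crossing as TT.
    """
    fam = family_info(family)
    out = {}
    for level, (t, y) in data_by_level.items():
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        if t.size < 3:
            raise ValueError(
                f"level {level!r}: need >= 3 observations for starting "
                "values")
        d, m = _day_means(t, y)
        if d.size < 2:
            raise ValueError(f"level {level!r}: need >= 2 distinct days")
        if family == "expolinear":
            cm = (m[-1] - m[-2]) / (d[-1] - d[-2])
            if cm <= 0:
                cm = max(m[-1], 1e-6) / max(d[-1] - d[0], 1.0)
            tb = d[-1] - m[-1] / cm
            early = slice(0, max(2, d.size // 2))
            pos = m[early] > 0
            rm = (_slope(d[early][pos], np.log(m[early][pos]))
                  if pos.sum() >= 2 else 0.5)
            rm = float(np.clip(rm, 0.05, 5.0))
            out[level] = curves.ExpolinearParams(cm, rm, tb)
        elif family == "gompertz":
            wf = 1.05 * max(m.max(), 1e-6)
            tt = float(d[np.argmin(np.abs(m - wf / math.e))])
            frac = np.clip(m / wf, 1e-6, 1 - 1e-6)
            z = -np.log(-np.log(frac))
            k = float(np.clip(_slope(d, z), 0.02, 5.0))
            out[level] = curves.GompertzParams(wf, k, tt)
        else:  # decay
            mn = max(float(m[-1]), 0.0)
            mx = float(m[0])
            if mx <= mn:
                mx = mn + max(abs(mn), 1.0) * 0.1 + 1e-6
            mid = 0.5 * (mx + mn)
            below = np.nonzero(m <= mid)[0]
            if below.size and below[0] > 0:
                i = below[0]
                f = (m[i - 1] - mid) / max(m[i - 1] - m[i], 1e-12)
                tt = float(d[i - 1] + f * (d[i] - d[i - 1]))
            else:
                tt = float(np.median(d))
            out[level] = curves.DecayParams(mx, mn, tt, 1.0)
    return out


def _group_by_level(spec: ModelSpec, data: Dataset) -> dict:
    sub = data.subset(spec.trait)
    grouped = {}
    for level in spec.scheme.levels:
        lines = spec.scheme.lines_in(level)
        rows = sub[sub["line_id"].isin(lines)]
        grouped[level] = (rows["day"].to_numpy(float),
                          rows["value"].to_numpy(float))
    return grouped


def fit_gnls(spec: ModelSpec, data: Dataset, init: Mapping | None = None,
             control: FitControl | None = None) -> FitResult:
    """Fit one grouped curve model by maximum likelihood.

    ``init`` may supply curve parameters per level (e.g. warm starts from
    a coarser grouping); nuisance parameters always start at neutral
    values (rho=0, delta=0, ratios=1).  Returns a :class:`FitResult`
    whose ``converged`` flag reflects the optimizer's own verdict.
    """
    control = control or FitControl()
    prob = _Problem(spec, data, control)
    if init is None:
        init = initial_values(spec.family, _group_by_level(spec, data))
    x0 = prob.pack(init, rho=None, delta=None, ratios=None)

    rng = np.random.default_rng(control.seed)
    opts = {"maxiter": control.maxiter, "ftol": control.tol,
            "gtol": control.grad_tol}
    best = None
    n_tried = 0
    for attempt in range(max(1, control.n_starts)):
        x_start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.3, x0.size)
        res = optimize.minimize(prob.nll_profiled, x_start,
                                method="L-BFGS-B", options=opts)
        n_tried += 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.success:
            break

    estimates, rho, delta, ratios = prob.unpack(best.x)
    sigma = prob.sigma_hat(best.x)
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None \
        else float("nan")

    info = prob.mean_information(estimates, sigma, rho, delta, ratios)
    param_index = tuple((lv, nm) for lv in prob.levels
                        for nm in prob.free_names)
    cov = _invert_information(info, param_index)
    se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    est_vec = np.array([getattr(estimates[lv], nm)
                        for lv, nm in param_index])
    se = {key: float(s) for key, s in zip(param_index, se_vec)}
    ci95 = {key: (float(e - _Z975 * s), float(e + _Z975 * s))
            for key, e, s in zip(param_index, est_vec, se_vec)}

    return FitResult(
        spec=spec, estimates=estimates, sigma=float(sigma), rho=rho,
        delta=delta, stratum_ratios=ratios, loglik=-float(best.fun),
        n_obs=prob.n, n_params=prob.n_params, param_index=param_index,
        cov=cov, se=se, ci95=ci95, converged=bool(best.success),
        n_iter=int(best.nit) * n_tried, grad_norm=grad_norm,
        message=str(best.message))


def _invert_information(info: np.ndarray, param_index: tuple) -> np.ndarray:
    diag = np.diag(info)
    if np.any(diag <= 0) or not np.all(np.isfinite(info)):
        bad = param_index[int(np.argmin(diag))]
        raise np.linalg.LinAlgError(
            f"information matrix singular at parameter {bad[1]!r} "
            f"(level {bad[0]!r})")
    try:
        L = np.linalg.cholesky(info)
    except np.linalg.LinAlgError:
        # name the parameter contributing least information
        scaled = info / np.sqrt(np.outer(diag, diag))
        bad = param_index[int(np.argmin(np.linalg.eigvalsh(scaled)))]
        raise np.linalg.LinAlgError(
            f"information matrix singular at parameter {bad[1]!r} "
            f"(level {bad[0]!r})") from None
    eye = np.eye(info.shape[0])
    Linv = solve_triangular(L, eye, lower=True)
    return Linv.T @ Linv


def asymptotic_ci(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Wald confidence intervals estimate +/- z * SE at any level.

    Requires a converged fit; the covariance comes from the inverse
    generalized least-squares information at the optimum.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for lv, nm in fit.param_index:
        e = fit.estimate_of(lv, nm)
        s = fit.se[(lv, nm)]
        rows.append((nm, lv, e, s, e - z * s, e + z * s))
    return pd.DataFrame(rows, columns=["parameter", "level", "estimate",
                                       "se", "lower", "upper"])
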