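"""Unified structural equation model (uSEM) estimation.

The uSEM expresses each endogenous node at time t as a linear function of
the other nodes at t (contemporaneous paths, matrix A), all nodes at t-1
(lagged paths, matrix Phi, whose diagonal holds the autoregressive paths),
and exogenous task inputs (matrix Lambda):

    x_t = A x_t + Phi x_{t-1} + Lambda u_t + zeta_t,   zeta_t ~ N(0, diag(Psi))

Estimation is maximum likelihood on the lag-embedded observation vector
z_t = [x_{t-1}; u_{t-1}; u_t; x_t], with the predictor block (everything but
x_t) saturated. With the predictor block saturated the ML discrepancy
reduces to the conditional Gaussian likelihood of x_t given the predictors,
which this module optimizes with analytic gradients after profiling out the
residual variances. Modification indices are 1-df score tests computed from
the analytic gradient and Hessian of the discrepancy, so scoring every
candidate path costs one Hessian build rather than one refit each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .timeseries_io import ROITimeSeries

__all__ = [
    "PathSpec",
    "ParamSet",
    "FitResult",
    "NetworkModel",
    "LaggedData",
    "lag_augment",
    "candidate_paths",
    "ar_paths",
    "fit_usem",
    "modification_indices",
    "fit_indices",
    "fit_index_formulas",
    "evaluate_fit",
    "prune",
    "DEFAULT_FIT_THRESHOLDS",
    "EXCELLENT_FIT_THRESHOLDS",
    "MI_CRITICAL_95",
]

#: chi-square(1) critical value at alpha = .05, used for MI significance
MI_CRITICAL_95 = float(stats.chi2.ppf(0.95, 1))

#: adequate-fit thresholds used to evaluate final models
DEFAULT_FIT_THRESHOLDS = {"cfi": 0.90, "nnfi": 0.90, "rmsea": 0.08, "srmr": 0.08}

#: stricter "excellent" thresholds used in the search stopping rule
EXCELLENT_FIT_THRESHOLDS = {"cfi": 0.95, "nnfi": 0.95, "rmsea": 0.05, "srmr": 0.05}


class EstimationError(RuntimeError):
    """Raised when data are unusable for estimation."""


@dataclass(frozen=True)
class PathSpec:
    """A directed path ``from_node -> to_node`` at lag 0 or 1.

    ``level`` records at which aggregation level a path was discovered
    (null_base, group, subgroup, individual, aggregate) and is excluded
    from identity: two PathSpecs are equal iff (from, to, lag) agree.
    """

    from_node: str
    to_node: str
    lag: int = 0
    level: str = field(default="individual", compare=False)

    def __post_init__(self):
        if self.lag not in (0, 1):
            raise ValueError("lag must be 0 or 1")
        if self.lag == 0 and self.from_node == self.to_node:
            raise ValueError("contemporaneous self-loop is not allowed")

    def sort_key(self):
        return (self.lag, self.from_node, self.to_node)

    def relevel(self, level: str) -> "PathSpec":
        return PathSpec(self.from_node, self.to_node, self.lag, level)

    def __repr__(self):
        arrow = "->" if self.lag == 0 else "=>"  # => marks lag-1
        return f"{self.from_node}{arrow}{self.to_node}[{self.level}]"


@dataclass
class ParamSet:
    """Realized coefficient matrices of a fitted (or generating) uSEM."""

    A: np.ndarray        # p x p contemporaneous, zero diagonal
    Phi: np.ndarray      # p x (p + q) lag-1 (endogenous cols first)
    Lambda: np.ndarray   # p x q contemporaneous exogenous
    Psi: np.ndarray      # p residual variances


@dataclass
class FitResult:
    """Likelihood discrepancy and derived fit indices for one model."""

    f_ml: float
    chi2: float
    df: int
    n_effective: int
    cfi: float = np.nan
    nnfi: float = np.nan
    rmsea: float = np.nan
    srmr: float = np.nan
    loglik: float = np.nan
    converged: bool = True


@dataclass
class NetworkModel:
    """A fitted directed network: free paths with estimates, SEs, and fit."""

    node_names: list[str]
    exog_names: list[str]
    free_paths: set[PathSpec]
    estimates: dict[PathSpec, float]
    se: dict[PathSpec, float]
    params: ParamSet
    fit: FitResult
    theta: np.ndarray = None  # packed coefficients, for warm starts

    @property
    def z(self) -> dict[PathSpec, float]:
        return {
            pth: (self.estimates[pth] / s if (s := self.se.get(pth, np.nan)) and s > 0
                  else np.nan)
            for pth in self.estimates
        }

    def pvalues(self) -> dict[PathSpec, float]:
        return {pth: 2 * stats.norm.sf(abs(zv)) if np.isfinite(zv) else 1.0
                for pth, zv in self.z.items()}

    def to_frame(self, scope: str = "") -> pd.DataFrame:
        zs = self.z
        rows = []
        for pth in sorted(self.free_paths, key=PathSpec.sort_key):
            rows.append(dict(scope=scope, from_node=pth.from_node,
                             to_node=pth.to_node, lag=pth.lag, level=pth.level,
                             beta=self.estimates[pth], se=self.se[pth],
                             z=zs[pth]))
        return pd.DataFrame(rows)


class LaggedData:
    """Lag-embedded second moments of one (possibly concatenated) dataset.

    Variable layout of z = [w; x]: the predictor block w holds the lagged
    endogenous nodes, then (optionally) the lagged exogenous inputs, then
    the contemporaneous exogenous inputs; x is the contemporaneous
    endogenous block. Everything downstream needs only the ML covariance
    ``S`` of z and the effective sample size ``n``.
    """

    def __init__(self, S: np.ndarray, n: int, node_names: list[str],
                 exog_names: list[str], lagged_exogenous: bool):
        self.S = S
        self.n = n
        self.node_names = list(node_names)
        self.exog_names = list(exog_names)
        self.lagged_exogenous = lagged_exogenous
        self.p = len(node_names)
        self.q = len(exog_names)
        self.k = self.p + self.q * (2 if lagged_exogenous else 1)
        self.m = self.k + self.p
        self._node_idx = {nm: i for i, nm in enumerate(node_names)}
        self._exog_idx = {nm: i for i, nm in enumerate(exog_names)}
        # constant term ln|S_x|w| of the conditional discrepancy
        sign_full, logdet_full = np.linalg.slogdet(S)
        sign_w, logdet_w = np.linalg.slogdet(S[: self.k, : self.k])
        if sign_full <= 0 or sign_w <= 0:
            raise EstimationError("rank-deficient data: singular covariance")
        self.logdet_cond = logdet_full - logdet_w

    # ---- path <-> parameter coordinates -------------------------------
    def param_coord(self, path: PathSpec) -> tuple[int, int]:
        """Map a path to (equation row i, regressor column a) with a < k
        for predictor-block sources and a >= k for contemporaneous
        endogenous sources."""
        if path.to_node not in self._node_idx:
            raise ValueError(f"path target '{path.to_node}' is not endogenous")
        i = self._node_idx[path.to_node]
        src = path.from_node
        if src in self._node_idx:
            j = self._node_idx[src]
            a = j if path.lag == 1 else self.k + j
        elif src in self._exog_idx:
            j = self._exog_idx[src]
            if path.lag == 1:
                if not self.lagged_exogenous:
                    raise ValueError(
                        f"lagged exogenous path {path!r} requested but lagged "
                        "exogenous block is disabled")
                a = self.p + j
            else:
                a = self.p + (self.q if self.lagged_exogenous else 0) + j
        else:
            raise ValueError(f"unknown source node '{path.from_node}'")
        return i, a

    def free_param_count(self, n_paths: int) -> int:
        # saturated predictor block + structural coefficients + residuals
        return self.k * (self.k + 1) // 2 + n_paths + self.p

    def df_model(self, n_paths: int) -> int:
        return self.m * (self.m + 1) // 2 - self.free_param_count(n_paths)


def lag_augment(series: ROITimeSeries,
                boundaries: list[int] | None = None,
                lagged_exogenous: bool = False) -> LaggedData:
    """Lag-embed a series into paired observations and their moments.

    ``boundaries`` lists segment start offsets (0-based) for concatenated
    data; no (t-1, t) pair spans a segment break, so concatenating subjects
    never creates spurious cross-subject transitions. The effective sample
    size is the total number of valid pairs, sum(len_segment - 1).
    """
    X = series.values
    U = series.exogenous
    T, p = X.shape
    starts = sorted(set(boundaries or [0]) | {0})
    ends = starts[1:] + [T]
    blocks = []
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue  # a length-1 segment contributes no pairs
        w_parts = [X[s:e - 1]]
        if lagged_exogenous:
            w_parts.append(U[s:e - 1])
        w_parts.append(U[s + 1:e])
        blocks.append(np.hstack(w_parts + [X[s + 1:e]]))
    if not blocks:
        raise EstimationError("no usable lagged pairs (all segments too short)")
    Z = np.vstack(blocks)
    n = Z.shape[0]
    Zc = Z - Z.mean(axis=0)
    S = Zc.T @ Zc / n
    return LaggedData(S, n, series.node_names, series.exogenous_names,
                      lagged_exogenous)


def ar_paths(data: LaggedData, level: str = "null_base") -> set[PathSpec]:
    """The autoregressive (lag-1 self) base paths, freed in every null model."""
    return {PathSpec(nm, nm, lag=1, level=level) for nm in data.node_names}


def candidate_paths(data: LaggedData, free: set[PathSpec],
                    exogenous_lag0: bool = True,
                    exogenous_lag1: bool = False) -> list[PathSpec]:
    """All admissible paths not currently free.

    Candidates are contemporaneous endogenous paths (i != j), lag-1
    endogenous paths (including AR), and exogenous effects (contemporaneous
    by default). Paths into exogenous nodes never exist.
    """
    cands: list[PathSpec] = []
    for to in data.node_names:
        for frm in data.node_names:
            if frm != to:
                cands.append(PathSpec(frm, to, 0))
            cands.append(PathSpec(frm, to, 1))
        for ex in data.exog_names:
            if exogenous_lag0:
                cands.append(PathSpec(ex, to, 0))
            if exogenous_lag1 and data.lagged_exogenous:
                cands.append(PathSpec(ex, to, 1))
    return sorted((c for c in cands if c not in free), key=PathSpec.sort_key)


# ---------------------------------------------------------------------------
# ML fitting


def _unpack(data: LaggedData, paths: list[PathSpec]):
    rows = np.empty(len(paths), dtype=int)
    cols = np.empty(len(paths), dtype=int)
    for s, pth in enumerate(paths):
        rows[s], cols[s] = data.param_coord(pth)
    return rows, cols


def _discrepancy_parts(data: LaggedData, Theta: np.ndarray):
    """Residual-vs-variable covariances R, residual variances M, and C^-1."""
    p, k = data.p, data.k
    S = data.S
    C = np.eye(p) - Theta[:, k:]
    R = S[k:, :] - Theta @ S          # Cov(e, z), p x m
    # M_ii = Var(e_i) = Cov(e_i, x_i) - sum_a Theta[i, a] Cov(e_i, z_a)
    M = R[np.arange(p), k + np.arange(p)] - np.einsum("ia,ia->i", R, Theta)
    return C, R, M


def _objective(theta, data: LaggedData, rows, cols):
    p, k = data.p, data.k
    Theta = np.zeros((p, data.m))
    Theta[rows, cols] = theta
    C, R, M = _discrepancy_parts(data, Theta)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0 or np.any(M <= 1e-300):
        return 1e10, np.zeros_like(theta)
    f = float(np.sum(np.log(M)) - 2.0 * logdet - data.logdet_cond)
    Cinv = np.linalg.inv(C)
    G = -2.0 * R / M[:, None]
    G[:, k:] += 2.0 * Cinv.T
    return f, G[rows, cols]


def _ols_init(data: LaggedData, rows, cols) -> np.ndarray:
    """Per-equation least-squares start ignoring simultaneity feedback."""
    theta0 = np.zeros(len(rows))
    S = data.S
    for i in np.unique(rows):
        sel = np.nonzero(rows == i)[0]
        a = cols[sel]
        Sa = S[np.ix_(a, a)]
        sy = S[a, data.k + i]
        try:
            theta0[sel] = np.linalg.solve(
                Sa + 1e-10 * np.eye(len(a)), sy)
        except np.linalg.LinAlgError:
            theta0[sel] = 0.0
    return theta0


def _hessian(data: LaggedData, Theta, psi, rows, cols, expected=True):
    """Analytic Hessian of the (unprofiled) discrepancy F over the listed
    structural parameters followed by the p residual variances.

    With ``expected=True`` the sample moments are replaced by the
    model-implied ones (Fisher information), which is positive
    semidefinite and is what the score tests and standard errors use; the
    observed version keeps the raw sample moments.
    """
    p, k = data.p, data.k
    C, R, M = _discrepancy_parts(data, Theta)
    Cinv = np.linalg.inv(C)
    if expected:
        # model-implied covariance of z (predictor block is saturated)
        B = Theta[:, :k]
        Pi = Cinv @ B
        Om = (Cinv * psi[None, :]) @ Cinv.T
        S = np.empty_like(data.S)
        Sww = data.S[:k, :k]
        S[:k, :k] = Sww
        S[k:, :k] = Pi @ Sww
        S[:k, k:] = S[k:, :k].T
        S[k:, k:] = Pi @ Sww @ Pi.T + Om
        # implied Cov(e_i, z): zero against w, psi_i * Cinv[j, i] against x_j
        Rm = np.zeros_like(R)
        Rm[:, k:] = psi[:, None] * Cinv.T
        Mm = psi.copy()
    else:
        S, Rm, Mm = data.S, R, M
    ns = len(rows)
    H = np.zeros((ns + p, ns + p))
    same = rows[:, None] == rows[None, :]
    block = np.where(same, 2.0 * S[np.ix_(cols, cols)] / psi[rows][:, None], 0.0)
    contemp = cols >= k
    if contemp.any():
        j = np.where(contemp, cols - k, 0)
        ld = 2.0 * Cinv[np.ix_(j, rows)] * Cinv[np.ix_(j, rows)].T
        # ld[s1, s2] = 2 * Cinv[j1, i2] * Cinv[j2, i1]
        mask = contemp[:, None] & contemp[None, :]
        block = block + np.where(mask, ld, 0.0)
    H[:ns, :ns] = block
    # struct x psi
    H[np.arange(ns), ns + rows] = 2.0 * Rm[rows, cols] / psi[rows] ** 2
    H[ns + rows, np.arange(ns)] = H[np.arange(ns), ns + rows]
    # psi x psi
    H[ns + np.arange(p), ns + np.arange(p)] = -1.0 / psi ** 2 + 2.0 * Mm / psi ** 3
    return H, C, R, M, Cinv


def fit_usem(data: LaggedData, free_paths: set[PathSpec],
             options: dict | None = None,
             init: np.ndarray | None = None) -> NetworkModel:
    """Fit the uSEM with the given free path set by maximum likelihood.

    Residual variances are profiled out of the discrepancy, so the search
    space is just the structural coefficients. Standard errors come from
    the inverse observed information over coefficients and residual
    variances jointly.
    """
    opts = {"gtol": 1e-6, "maxiter": 500}
    opts.update(options or {})
    paths = sorted(free_paths, key=PathSpec.sort_key)
    rows, cols = _unpack(data, paths)
    p, k, m = data.p, data.k, data.m

    if len(paths) == 0:
        theta = np.zeros(0)
        converged = True
    else:
        theta0 = init if init is not None and len(init) == len(paths) \
            else _ols_init(data, rows, cols)
        res = optimize.minimize(
            _objective, theta0, args=(data, rows, cols), jac=True,
            method="L-BFGS-B",
            options={"maxiter": opts["maxiter"], "ftol": 1e-14,
                     "gtol": 1e-10, "maxcor": 20})
        theta = res.x
        _, g = _objective(theta, data, rows, cols)
        converged = bool(np.linalg.norm(g, np.inf) < opts["gtol"])
        if not converged:
            # one polishing pass with a fresh memory sometimes finishes the job
            res2 = optimize.minimize(
                _objective, theta, args=(data, rows, cols), jac=True,
                method="L-BFGS-B",
                options={"maxiter": opts["maxiter"], "ftol": 1e-16,
                         "gtol": 1e-12})
            _, g2 = _objective(res2.x, data, rows, cols)
            if np.linalg.norm(g2, np.inf) < np.linalg.norm(g, np.inf):
                theta = res2.x
            converged = bool(
                np.linalg.norm(_objective(theta, data, rows, cols)[1], np.inf)
                < opts["gtol"])

    Theta = np.zeros((p, m))
    Theta[rows, cols] = theta
    C, R, M = _discrepancy_parts(data, Theta)
    psi = M.copy()
    f_val, _ = _objective(theta, data, rows, cols)
    n = data.n
    chi2 = max((n - 1) * f_val, 0.0)
    df = data.df_model(len(paths))

    # standard errors from observed information
    se = {}
    if len(paths):
        H, *_ = _hessian(data, Theta, psi, rows, cols)
        info = 0.5 * (n - 1) * H
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)[: len(paths)]
            se_vec = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            se_vec = np.full(len(paths), np.nan)
        se = {pth: float(se_vec[s]) for s, pth in enumerate(paths)}

    estimates = {pth: float(theta[s]) for s, pth in enumerate(paths)}
    # assemble ParamSet in conventional blocks
    A = Theta[:, k:].copy()
    Phi = np.zeros((p, p + data.q))
    Phi[:, :p] = Theta[:, :p]
    Lam = np.zeros((p, data.q))
    off = p
    if data.lagged_exogenous:
        Phi[:, p:] = Theta[:, p:p + data.q]
        off = p + data.q
    Lam[:, :] = Theta[:, off:k]
    params = ParamSet(A=A, Phi=Phi, Lambda=Lam, Psi=psi)

    # Gaussian log-likelihood of the conditional model (up to the
    # saturated predictor block, which is common to all models)
    loglik = -0.5 * n * (f_val + data.logdet_cond + p * np.log(2 * np.pi) + p)
    fit = FitResult(f_ml=f_val, chi2=chi2, df=df, n_effective=n,
                    loglik=loglik, converged=converged)
    model = NetworkModel(node_names=data.node_names,
                         exog_names=data.exog_names,
                         free_paths=set(paths), estimates=estimates, se=se,
                         params=params, fit=fit, theta=theta)
    try:
        fit_indices(model, data)
    except EstimationError:
        pass  # degenerate case (model df >= baseline df): indices stay NaN
    return model


def _implied_sigma(data: LaggedData, model: NetworkModel) -> np.ndarray:
    p, k = data.p, data.k
    S = data.S
    Theta = np.zeros((p, data.m))
    rows, cols = _unpack(data, sorted(model.free_paths, key=PathSpec.sort_key))
    Theta[rows, cols] = model.theta
    B = Theta[:, :k]
    C = np.eye(p) - Theta[:, k:]
    Cinv = np.linalg.inv(C)
    Pi = Cinv @ B
    Om = Cinv @ np.diag(model.params.Psi) @ Cinv.T
    Sigma = np.empty_like(S)
    Sww = S[:k, :k]
    Sigma[:k, :k] = Sww
    Sigma[k:, :k] = Pi @ Sww
    Sigma[:k, k:] = Sigma[k:, :k].T
    Sigma[k:, k:] = Pi @ Sww @ Pi.T + Om
    return Sigma


def _baseline_chi2(data: LaggedData) -> tuple[float, int]:
    """Independence baseline: all covariances zero, variances free."""
    S = data.S
    f_b = float(np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
    df_b = data.m * (data.m - 1) // 2
    return max((data.n - 1) * f_b, 0.0), df_b


def fit_index_formulas(chi2_m: float, df_m: int, chi2_b: float, df_b: int,
                       n: int) -> tuple[float, float, float]:
    """CFI, NNFI (TLI), and RMSEA from model and baseline chi-squares.

    CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_B - df_B, chi2_M - df_M, 0);
    NNFI = (chi2_B/df_B - chi2_M/df_M) / (chi2_B/df_B - 1);
    RMSEA = sqrt(max(chi2_M - df_M, 0) / (df_M (n-1))), 0 for df_M = 0.
    """
    if df_b <= df_m:
        raise EstimationError("baseline must have more df than the model")
    d_m = max(chi2_m - df_m, 0.0)
    d_b = max(chi2_b - df_b, d_m)
    # both excesses at numerical zero: the model fits as well as anything can
    cfi = 1.0 if d_b <= 1e-10 else 1.0 - d_m / d_b
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df_m == 0:
        nnfi = 1.0
        rmsea = 0.0
    else:
        denom = chi2_b / df_b - 1.0
        nnfi = ((chi2_b / df_b - chi2_m / df_m) / denom
                if denom > 0 else 1.0)
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
    return cfi, float(nnfi), rmsea


def fit_indices(model: NetworkModel, data: LaggedData,
                baseline: NetworkModel | None = None) -> FitResult:
    """Populate CFI, NNFI (TLI), RMSEA, and SRMR on the model's FitResult.

    The baseline is the independence model (all covariances zero) unless an
    explicit baseline model on the same data is supplied.
    """
    chi2_m, df_m, n = model.fit.chi2, model.fit.df, model.fit.n_effective
    if baseline is None:
        chi2_b, df_b = _baseline_chi2(data)
    else:
        chi2_b, df_b = baseline.fit.chi2, baseline.fit.df
    cfi, nnfi, rmsea = fit_index_formulas(chi2_m, df_m, chi2_b, df_b, n)
    Sigma = _implied_sigma(data, model)
    S = data.S
    scale = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    resid = (S - Sigma) / scale
    iu = np.triu_indices(data.m)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    model.fit = replace(model.fit, cfi=cfi, nnfi=float(nnfi), rmsea=rmsea,
                        srmr=srmr)
    return model.fit


def evaluate_fit(fit: FitResult, thresholds: dict | None = None
                 ) -> tuple[int, dict[str, bool]]:
    """Count how many of the four fit criteria a model meets (inclusive)."""
    th = dict(DEFAULT_FIT_THRESHOLDS)
    th.update(thresholds or {})
    flags = {
        "cfi": fit.cfi >= th["cfi"],
        "nnfi": fit.nnfi >= th["nnfi"],
        "rmsea": fit.rmsea <= th["rmsea"],
        "srmr": fit.srmr <= th["srmr"],
    }
    return sum(flags.values()), flags


def excellent_fit(fit: FitResult, min_criteria: int = 2) -> bool:
    """Search stopping rule: at least ``min_criteria`` of the four indices
    meet the stricter excellent thresholds."""
    count, _ = evaluate_fit(fit, EXCELLENT_FIT_THRESHOLDS)
    return count >= min_criteria


def modification_indices(model: NetworkModel, data: LaggedData,
                         candidates: list[PathSpec] | None = None,
                         exogenous_lag0: bool = True,
                         exogenous_lag1: bool = False) -> pd.DataFrame:
    """Score-test modification index and expected parameter change for every
    candidate fixed path.

    Each MI approximates the chi-square drop from freeing that single path;
    the EPC is the first-order Newton estimate of its coefficient. A
    singular information matrix yields NaN for the affected candidates with
    a warning rather than a failure.
    """
    free = sorted(model.free_paths, key=PathSpec.sort_key)
    if candidates is None:
        candidates = candidate_paths(data, model.free_paths,
                                     exogenous_lag0, exogenous_lag1)
    else:
        candidates = [c for c in candidates if c not in model.free_paths]
    if not candidates:
        return pd.DataFrame(columns=["from_node", "to_node", "lag", "mi", "epc"])
    all_params = free + list(candidates)
    rows, cols = _unpack(data, all_params)
    p, k, m = data.p, data.k, data.m
    Theta = np.zeros((p, m))
    nf = len(free)
    Theta[rows[:nf], cols[:nf]] = model.theta
    psi = model.params.Psi
    H, C, R, M, Cinv = _hessian(data, Theta, psi, rows, cols)
    n = data.n

    # gradient of F at the fitted point, for candidate coordinates
    G = -2.0 * R / psi[:, None]
    G[:, k:] += 2.0 * Cinv.T
    g_cand = G[rows[nf:], cols[nf:]]

    # free block: free structural params + residual variances
    ns = len(all_params)
    free_idx = np.r_[np.arange(nf), np.arange(ns, ns + p)]
    cand_idx = np.arange(nf, ns)
    Hff = H[np.ix_(free_idx, free_idx)]
    Hcf = H[np.ix_(cand_idx, free_idx)]
    hcc = H[cand_idx, cand_idx]
    try:
        Hff_inv = np.linalg.inv(Hff)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; using pseudo-inverse "
                      "for modification indices")
        Hff_inv = np.linalg.pinv(Hff)
    schur = hcc - np.einsum("cf,fg,cg->c", Hcf, Hff_inv, Hcf)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = 0.5 * (n - 1) * g_cand ** 2 / schur
        epc = -g_cand / schur
    # candidates with non-positive restricted curvature (typically not
    # identified jointly with the current free set) get NaN
    bad = ~(schur > 0)
    if bad.any():
        mi = np.where(bad, np.nan, mi)
        epc = np.where(bad, np.nan, epc)
    out = pd.DataFrame({
        "from_node": [c.from_node for c in candidates],
        "to_node": [c.to_node for c in candidates],
        "lag": [c.lag for c in candidates],
        "mi": mi,
        "epc": epc,
    })
    return out


def prune(model: NetworkModel, data: LaggedData, alpha: float = 0.05,
          protected: set[PathSpec] | None = None,
          prunable_levels: set[str] | None = None,
          options: dict | None = None) -> NetworkModel:
    """Backward pruning: repeatedly drop the least significant free path
    with p >= alpha, refitting after each removal.

    Autoregressive base paths (level ``null_base``) are never pruned;
    additional paths can be protected explicitly or by restricting
    ``prunable_levels``.
    """
    protected = set(protected or ())
    current = model
    while True:
        pvals = current.pvalues()
        removable = [
            pth for pth in current.free_paths
            if pth.level != "null_base" and pth not in protected
            and (prunable_levels is None or pth.level in prunable_levels)
        ]
        worst = None
        worst_p = alpha
        for pth in removable:
            pv = pvals.get(pth, 1.0)
            if pv >= worst_p:
                worst, worst_p = pth, pv
        if worst is None:
            return current
        new_free = set(current.free_paths) - {worst}
        current = fit_usem(data, new_free, options=options)
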