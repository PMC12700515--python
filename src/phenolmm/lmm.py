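"""Maximum-likelihood linear mixed models for longitudinal symptom data.

Implements, from scratch, the three-model family used throughout the
analysis:

* ``RI`` — random patient intercept, iid residuals;
* ``RI_AR1`` — random intercept plus first-order autoregressive residual
  correlation within patient (corr(e_j, e_k) = rho^|j-k|, constant marginal
  residual variance);
* ``RI_RS`` / ``RI_RS_AR1`` — adds a random slope on the phenotype
  predictor with an unstructured 2x2 random-effect covariance, without or
  with the AR(1) residual correlation.

Estimation is marginal Gaussian maximum likelihood (never REML, so that
-2LL differences are valid for fixed- and random-part comparisons alike).
Fixed effects are profiled out by generalized least squares and the
residual variance is profiled in closed form, leaving a low-dimensional
optimization over variance *ratios* (log scale) and correlations
(Fisher-z scale).  All likelihood evaluation factorizes per patient; a
dense all-observations covariance is never formed.

Inference: Wald t-tests with Satterthwaite-type degrees of freedom
(moment-matching on the estimated variance of the contrast, via the
observed information of the variance parameters), the Nakagawa-style
marginal pseudo-R^2 and Cohen f^2 = Rm/(1-Rm) for random-intercept fits,
and likelihood-ratio tests against either a chi^2_1 null (one extra
correlation parameter) or the equal-weight chi^2_1/chi^2_2 mixture null
(a variance component on the boundary plus its covariance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .exceptions import DataError, NumericError, UnsupportedModelError

RANDOM_STRUCTURES = ("RI", "RI_AR1", "RI_RS", "RI_RS_AR1")

_LG_BOUND = 16.0  # log variance-ratio bounds (gamma in [~1e-7, ~1e7])
_Z_BOUND = 6.0    # Fisher-z bounds (|corr| <= tanh(6) ~ 0.99999)


@dataclass(frozen=True)
class LmmSpec:
    """Declarative description of one mixed model.

    ``fixed_terms`` are column names of the modelling table (numeric;
    categorical covariates must be dummy-encoded upstream).  The random
    slope, when the structure has one, is on ``slope_term`` (defaults to
    the first fixed term — the phenotype predictor).
    """

    outcome: str
    fixed_terms: tuple[str, ...]
    random_structure: str = "RI"
    slope_term: str | None = None
    group_col: str = "patient_id"
    time_col: str | None = "month_index"

    def __post_init__(self):
        if self.random_structure not in RANDOM_STRUCTURES:
            raise DataError(f"unknown random structure {self.random_structure!r}")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        if self.random_structure in ("RI_RS", "RI_RS_AR1"):
            st = self.slope_term or (self.fixed_terms[0] if self.fixed_terms else None)
            if st is None or st not in self.fixed_terms:
                raise DataError(
                    "random-slope structures need the slope predictor among the fixed terms"
                )
            object.__setattr__(self, "slope_term", st)

    @property
    def has_slope(self) -> bool:
        return self.random_structure in ("RI_RS", "RI_RS_AR1")

    @property
    def has_ar1(self) -> bool:
        return self.random_structure in ("RI_AR1", "RI_RS_AR1")

    @property
    def n_theta(self) -> int:
        return 1 + 2 * self.has_slope + self.has_ar1


@dataclass
class LrtResult:
    """A likelihood-ratio comparison of two nested fits."""

    statistic: float
    null_type: str  # "chi2_1" | "mix_half_chi2_1_chi2_2"
    p_value: float


@dataclass
class LmmFit:
    """A fitted mixed model with Wald inference and variance parameters."""

    spec: LmmSpec
    term_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    satterthwaite_df: np.ndarray
    p_values: np.ndarray
    var_params: dict
    minus2_loglik: float
    Rm: float | None
    f2: float | None
    converged: bool
    n_obs: int
    n_groups: int
    # private fitting state, used by satterthwaite_df and warm starts
    _kernel: object = field(default=None, repr=False)
    _theta: np.ndarray = field(default=None, repr=False)
    _eta: np.ndarray = field(default=None, repr=False)
    _M: np.ndarray = field(default=None, repr=False)
    _Hinv: np.ndarray = field(default=None, repr=False)

    def coef(self, term: str) -> dict:
        i = self.term_names.index(term)
        return {
            "estimate": float(self.beta[i]),
            "se": float(self.se[i]),
            "t": float(self.t_values[i]),
            "df": float(self.satterthwaite_df[i]),
            "p": float(self.p_values[i]),
        }

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "fixed_terms": list(self.spec.fixed_terms),
            "random_structure": self.spec.random_structure,
            "term_names": list(self.term_names),
            "beta": [float(v) for v in self.beta],
            "se": [float(v) for v in self.se],
            "t_values": [float(v) for v in self.t_values],
            "satterthwaite_df": [float(v) for v in self.satterthwaite_df],
            "p_values": [float(v) for v in self.p_values],
            "var_params": {k: (None if v is None else float(v)) for k, v in self.var_params.items()},
            "minus2_loglik": float(self.minus2_loglik),
            "Rm": None if self.Rm is None else float(self.Rm),
            "f2": None if self.f2 is None else float(self.f2),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
        }


# ---------------------------------------------------------------------------
# design construction


def _build_design(spec: LmmSpec, data: pd.DataFrame):
    """Sorted per-group design matrices on the raw scale."""
    cols = [spec.group_col, spec.outcome, *spec.fixed_terms]
    if spec.time_col and spec.time_col in data.columns:
        cols.append(spec.time_col)
    missing = [c for c in (spec.group_col, spec.outcome, *spec.fixed_terms) if c not in data.columns]
    if missing:
        raise DataError(f"columns missing from modelling table: {missing}")
    df = data[list(dict.fromkeys(cols))].dropna()
    sort_cols = [spec.group_col] + ([spec.time_col] if spec.time_col and spec.time_col in df.columns else [])
    df = df.sort_values(sort_cols, kind="mergesort")
    y = df[spec.outcome].to_numpy(float)
    X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy(float) for t in spec.fixed_terms])
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise DataError("non-finite values in outcome or predictors")
    codes, _ = pd.factorize(df[spec.group_col], sort=True)
    order = np.argsort(codes, kind="mergesort")
    y, X, codes = y[order], X[order], codes[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(codes) != 0, True])
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    return y, X, slices


def _standardize(y, X, slope_idx):
    """Scale y and center/scale non-intercept columns; return transforms.

    Returns (y_std, X_std, sy, M, slope_m, slope_s) where
    beta_raw = sy * M @ beta_std.
    """
    sy = float(np.std(y))
    sy = sy if sy > 0 else 1.0
    p = X.shape[1]
    m = np.zeros(p)
    s = np.ones(p)
    Xs = X.copy()
    for j in range(1, p):
        m[j] = X[:, j].mean()
        sj = X[:, j].std()
        s[j] = sj if sj > 0 else 1.0
        Xs[:, j] = (X[:, j] - m[j]) / s[j]
    M = np.zeros((p, p))
    M[0, 0] = 1.0
    for j in range(1, p):
        M[j, j] = 1.0 / s[j]
        M[0, j] = -m[j] / s[j]
    sm = m[slope_idx] if slope_idx is not None else 0.0
    ssl = s[slope_idx] if slope_idx is not None else 1.0
    return y / sy, Xs, sy, M, sm, ssl


# ---------------------------------------------------------------------------
# likelihood kernels (standardized scale)


def _unpack_theta(spec: LmmSpec, theta):
    """theta -> (G* entries, rho) on the natural scale (variance ratios)."""
    theta = np.asarray(theta, float)
    g0 = np.exp(theta[0])
    if spec.has_slope:
        g1 = np.exp(theta[1])
        r01 = np.tanh(theta[2])
        rho = np.tanh(theta[3]) if spec.has_ar1 else 0.0
        Gs = np.array([[g0, r01 * np.sqrt(g0 * g1)], [r01 * np.sqrt(g0 * g1), g1]])
    else:
        rho = np.tanh(theta[1]) if spec.has_ar1 else 0.0
        Gs = np.array([[g0]])
    return Gs, rho


class _GenericKernel:
    """Per-group factorized profile likelihood for any supported structure.

    Groups of equal length are batched so every evaluation runs through
    stacked (k, n, n) cholesky factorizations instead of a Python loop —
    the Monte-Carlo suites fit tens of thousands of these models.
    """

    def __init__(self, spec: LmmSpec, y, X, slices, slope_col):
        self.spec = spec
        self.N = len(y)
        self.p = X.shape[1]
        by_size: dict[int, list] = {}
        for s in slices:
            by_size.setdefault(s.stop - s.start, []).append(s)
        self.batches = []
        for n, group in sorted(by_size.items()):
            Y = np.stack([y[s] for s in group])               # (k, n)
            Xb = np.stack([X[s] for s in group])              # (k, n, p)
            if slope_col is not None:
                Zb = np.stack(
                    [np.column_stack([np.ones(n), slope_col[s]]) for s in group]
                )                                             # (k, n, 2)
            else:
                Zb = np.ones((len(group), n, 1))
            self.batches.append((Y, Xb, Zb))

    def _gls(self, theta):
        Gs, rho = _unpack_theta(self.spec, theta)
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        q = 0.0
        logdet = 0.0
        for Y, Xb, Zb in self.batches:
            k, n, p = Xb.shape
            W = Zb @ Gs @ Zb.transpose(0, 2, 1)
            idx = np.arange(n)
            if rho != 0.0:
                W = W + rho ** np.abs(idx[:, None] - idx[None, :])
            else:
                W[:, idx, idx] += 1.0
            try:
                L = np.linalg.cholesky(W)
            except np.linalg.LinAlgError as e:
                raise NumericError(f"non-positive-definite within-group covariance: {e}") from e
            logdet += 2.0 * float(np.sum(np.log(L[:, idx, idx])))
            rhs = np.concatenate([Xb, Y[:, :, None]], axis=2)
            sol = np.linalg.solve(W, rhs)                     # (k, n, p+1)
            A += np.einsum("knp,knq->pq", Xb, sol[:, :, :p])
            b += np.einsum("knp,kn->p", Xb, sol[:, :, p])
            q += float(np.einsum("kn,kn->", Y, sol[:, :, p]))
        beta = np.linalg.solve(A, b)
        rss = q - beta @ b
        return beta, A, max(rss, 0.0), logdet

    def profile_nll(self, theta) -> float:
        try:
            beta, A, rss, logdet = self._gls(theta)
        except (NumericError, np.linalg.LinAlgError):
            return np.inf
        s2 = max(rss / self.N, 1e-300)
        return 0.5 * (self.N * np.log(2 * np.pi * s2) + logdet + self.N)

    def nll_eta(self, eta) -> float:
        s2 = np.exp(eta[0])
        try:
            beta, A, rss, logdet = self._gls(eta[1:])
        except (NumericError, np.linalg.LinAlgError):
            return np.inf
        return 0.5 * (self.N * np.log(2 * np.pi) + self.N * eta[0] + logdet + rss / s2)

    def var_cbeta(self, eta, c) -> float:
        s2 = np.exp(eta[0])
        _, A, _, _ = self._gls(eta[1:])
        return float(s2 * c @ np.linalg.solve(A, c))


class _RIKernel:
    """Sufficient-statistic fast path for the random-intercept model.

    With W_g = I + gamma * 1 1', Woodbury reduces every evaluation to O(G p^2)
    on precomputed cross-products — this is the workhorse behind the
    100-model screening step.
    """

    def __init__(self, spec: LmmSpec, y, X, slices, slope_col=None):
        self.spec = spec
        self.N = len(y)
        self.p = X.shape[1]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Sx = np.stack([X[s].sum(axis=0) for s in slices])
        self.Sy = np.array([y[s].sum() for s in slices])
        self.ng = np.array([s.stop - s.start for s in slices], float)

    def _gls(self, theta):
        gamma = np.exp(float(np.asarray(theta).ravel()[0]))
        c = gamma / (1.0 + self.ng * gamma)
        A = self.XtX - self.Sx.T @ (c[:, None] * self.Sx)
        b = self.Xty - self.Sx.T @ (c * self.Sy)
        q = self.yty - float(c @ (self.Sy * self.Sy))
        beta = np.linalg.solve(A, b)
        rss = q - beta @ b
        logdet = float(np.sum(np.log1p(self.ng * gamma)))
        return beta, A, max(rss, 0.0), logdet

    profile_nll = _GenericKernel.profile_nll
    nll_eta = _GenericKernel.nll_eta
    var_cbeta = _GenericKernel.var_cbeta


def _make_kernel(spec, y, X, slices, slope_col):
    if spec.random_structure == "RI":
        return _RIKernel(spec, y, X, slices)
    return _GenericKernel(spec, y, X, slices, slope_col)


# ---------------------------------------------------------------------------
# public operations


def loglik_lmm(spec: LmmSpec, data: pd.DataFrame, var_params: dict, beta: Sequence[float]) -> float:
    """Marginal Gaussian log-likelihood at explicit raw-scale parameters.

    ``var_params`` carries ``sigma2_resid``, ``sigma2_intercept`` and, per
    structure, ``sigma2_slope``, ``cov_intercept_slope``, ``rho``.  Used as
    the reference evaluation path; the fitter optimizes an equivalent
    profiled form.
    """
    y, X, slices = _build_design(spec, data)
    s2 = float(var_params["sigma2_resid"])
    v0 = float(var_params.get("sigma2_intercept", 0.0))
    rho = float(var_params.get("rho", 0.0) or 0.0)
    if abs(rho) >= 1 or s2 < 0 or v0 < 0:
        raise DataError("invalid variance parameters")
    if spec.has_slope:
        v1 = float(var_params.get("sigma2_slope", 0.0))
        c01 = float(var_params.get("cov_intercept_slope", 0.0))
        G = np.array([[v0, c01], [c01, v1]])
    else:
        G = np.array([[v0]])
    beta = np.asarray(beta, float)
    if beta.shape[0] != X.shape[1]:
        raise DataError(f"beta has {beta.shape[0]} entries, design has {X.shape[1]} columns")
    slope_idx = (1 + spec.fixed_terms.index(spec.slope_term)) if spec.has_slope else None
    ll = 0.0
    for s in slices:
        yg, Xg = y[s], X[s]
        n = len(yg)
        Z = np.column_stack([np.ones(n), Xg[:, slope_idx]]) if spec.has_slope else np.ones((n, 1))
        idx = np.arange(n)
        R = rho ** np.abs(idx[:, None] - idx[None, :]) if rho != 0.0 else np.eye(n)
        V = Z @ G @ Z.T + s2 * R
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as e:
            raise NumericError(f"non-positive-definite V: {e}") from e
        r = yg - Xg @ beta
        quad = r @ cho_solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return float(ll)


def _starts(spec: LmmSpec) -> list[np.ndarray]:
    if spec.random_structure == "RI":
        raw = [[-2.0], [0.0], [2.0]]
    elif spec.random_structure == "RI_AR1":
        raw = [[0.0, 0.0], [-2.0, 1.0], [2.0, -1.0], [0.0, 1.5]]
    elif spec.random_structure == "RI_RS":
        raw = [[0.0, 0.0, 0.0], [-2.0, -2.0, 0.0], [2.0, 0.0, 0.0], [0.0, -4.0, 0.0]]
    else:
        raw = [
            [0.0, 0.0, 0.0, 0.0],
            [-2.0, -2.0, 0.0, 1.0],
            [2.0, 0.0, 0.0, 0.0],
            [0.0, -4.0, 0.0, 1.0],
        ]
    return [np.array(v) for v in raw]


def fit_lmm(
    spec: LmmSpec,
    data: pd.DataFrame,
    extra_starts: Sequence[Sequence[float]] = (),
) -> LmmFit:
    """Fit one mixed model by profiled maximum likelihood.

    Variance ratios are optimized on the log scale and correlations on the
    Fisher-z scale by L-BFGS-B from several dispersed deterministic starts
    (plus any ``extra_starts``, used to warm-start a larger model from a
    nested fit so likelihood-ratio statistics cannot go negative).
    Convergence failure is recorded on the fit, not raised.
    """
    y_raw, X_raw, slices = _build_design(spec, data)
    N, p = X_raw.shape
    if N < p:
        raise DataError(f"{N} observations cannot identify {p} fixed effects")
    if len(slices) < 2:
        raise DataError("at least 2 groups are required")
    slope_idx = (1 + spec.fixed_terms.index(spec.slope_term)) if spec.has_slope else None
    y, X, sy, M, sm, ss = _standardize(y_raw, X_raw, slope_idx)
    slope_col = X[:, slope_idx] if spec.has_slope else None
    kernel = _make_kernel(spec, y, X, slices, slope_col)

    nt = spec.n_theta
    bounds = []
    for i in range(nt):
        if spec.has_slope and i in (0, 1):
            bounds.append((-_LG_BOUND, _LG_BOUND))
        elif not spec.has_slope and i == 0:
            bounds.append((-_LG_BOUND, _LG_BOUND))
        else:
            bounds.append((-_Z_BOUND, _Z_BOUND))

    starts = _starts(spec) + [np.clip(np.asarray(s, float), -_LG_BOUND, _LG_BOUND) for s in extra_starts]
    best = None
    any_success = False
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                kernel.profile_nll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 0.0:
            best = res
    if best is None:
        raise NumericError("all optimizer starts failed")
    theta = best.x
    beta_std, A, rss, logdet = kernel._gls(theta)
    s2_std = max(rss / N, 1e-300)
    nll = kernel.profile_nll(theta)
    minus2ll = 2.0 * nll + 2.0 * N * np.log(sy)
    eta = np.r_[np.log(s2_std), theta]

    # raw-scale fixed effects and covariance
    beta = sy * (M @ beta_std)
    cov_std = s2_std * np.linalg.inv(A)
    cov_raw = sy**2 * (M @ cov_std @ M.T)
    se = np.sqrt(np.maximum(np.diag(cov_raw), 0.0))

    # raw-scale variance parameters
    Gs, rho = _unpack_theta(spec, theta)
    vp: dict = {"sigma2_resid": sy**2 * s2_std}
    if spec.has_slope:
        v0s, v1s, c01s = Gs[0, 0] * s2_std, Gs[1, 1] * s2_std, Gs[0, 1] * s2_std
        k = sm / ss
        vp["sigma2_intercept"] = sy**2 * (v0s - 2 * k * c01s + k * k * v1s)
        vp["sigma2_slope"] = sy**2 * v1s / ss**2
        vp["cov_intercept_slope"] = sy**2 * (c01s - k * v1s) / ss
    else:
        vp["sigma2_intercept"] = sy**2 * Gs[0, 0] * s2_std
    vp["rho"] = rho if spec.has_ar1 else None

    fit = LmmFit(
        spec=spec,
        term_names=("intercept", *spec.fixed_terms),
        beta=beta,
        se=se,
        t_values=np.full(p, np.nan),
        satterthwaite_df=np.full(p, np.nan),
        p_values=np.full(p, np.nan),
        var_params=vp,
        minus2_loglik=float(minus2ll),
        Rm=None,
        f2=None,
        converged=bool(any_success),
        n_obs=N,
        n_groups=len(slices),
        _kernel=kernel,
        _theta=theta,
        _eta=eta,
        _M=M,
    )
    for j in range(p):
        c = np.zeros(p)
        c[j] = 1.0
        df = satterthwaite_df(fit, c)
        t, pv = wald_t_test(beta[j], se[j], df) if se[j] > 0 else (np.nan, np.nan)
        fit.satterthwaite_df[j] = df
        fit.t_values[j] = t
        fit.p_values[j] = pv
    if spec.random_structure == "RI":
        # linear predictor variance on the raw scale (intercept adds none)
        fitted = X_raw @ beta
        var_fix = float(np.var(fitted))
        denom = var_fix + vp["sigma2_intercept"] + vp["sigma2_resid"]
        fit.Rm = var_fix / denom if denom > 0 else 0.0
        fit.f2 = fit.Rm / (1.0 - fit.Rm)
    return fit


def _num_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def satterthwaite_df(fit: LmmFit, contrast: Sequence[float]) -> float:
    """Satterthwaite-type degrees of freedom for a 1-df fixed-effect contrast.

    df = 2 [Var(c'beta)]^2 / Var[Var(c'beta)], with the variance of the
    variance obtained by the delta method over the variance parameters and
    the observed information from a numerical Hessian of the beta-profiled
    negative log-likelihood.  Clamped to [1, n_obs - p]; a singular
    information matrix falls back to the residual df with a warning.
    """
    kernel, eta = fit._kernel, fit._eta
    p = len(fit.beta)
    cap = max(float(fit.n_obs - p), 1.0)
    c_raw = np.asarray(contrast, float)
    c_std = fit._M.T @ c_raw
    try:
        f0 = kernel.var_cbeta(eta, c_std)
        if fit._Hinv is None:
            H = _num_hessian(kernel.nll_eta, eta)
            fit._Hinv = np.linalg.inv(H)
        g = np.zeros(len(eta))
        h = 1e-4
        for i in range(len(eta)):
            e = np.zeros(len(eta)); e[i] = h
            g[i] = (kernel.var_cbeta(eta + e, c_std) - kernel.var_cbeta(eta - e, c_std)) / (2 * h)
        denom = float(g @ fit._Hinv @ g)
        if not np.isfinite(denom) or denom <= 0 or f0 <= 0:
            raise NumericError("non-positive variance-of-variance")
        df = 2.0 * f0 * f0 / denom
    except (NumericError, np.linalg.LinAlgError):
        warnings.warn("singular variance-parameter information; falling back to residual df")
        return cap
    if not np.isfinite(df):
        return cap
    return float(np.clip(df, 1.0, cap))


def wald_t_test(estimate: float, se: float, df: float) -> tuple[float, float]:
    """Two-tailed t-test: t = estimate/se, p = 2 P(T_df > |t|)."""
    if not se > 0:
        raise NumericError(f"standard error must be positive, got {se}")
    if not df > 0:
        raise NumericError(f"degrees of freedom must be positive, got {df}")
    t = estimate / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def marginal_r2_f2(fit: LmmFit) -> tuple[float, float]:
    """Marginal pseudo-R^2 (fixed-effect variance share) and Cohen f^2.

    Defined only for the random-intercept fit, where the residual variance
    is a scalar: Rm = var(X beta) / (var(X beta) + sigma2_intercept +
    sigma2_resid) and f^2 = Rm / (1 - Rm).  With AR(1) or random-slope
    structures the residual (co)variance is no longer a single scalar and
    this proportion is not comparable, so the request is rejected.
    """
    if fit.spec.random_structure != "RI":
        raise UnsupportedModelError(
            "marginal R^2 is defined here only for the random-intercept model; "
            "with AR(1) or random-slope structures the residual variance is a "
            "matrix, not a scalar, and the proportion is not comparable"
        )
    return float(fit.Rm), float(fit.f2)


def lrt(fit_big: LmmFit, fit_small: LmmFit, null_type: str) -> LrtResult:
    """Likelihood-ratio comparison of two nested ML fits.

    ``null_type`` is ``"chi2_1"`` for the AR(1) parameter and
    ``"mix_half_chi2_1_chi2_2"`` (equal-weight chi-bar-square) for adding a
    random slope variance plus its covariance with the intercept.
    """
    if null_type not in ("chi2_1", "mix_half_chi2_1_chi2_2"):
        raise DataError(f"unknown null type {null_type!r}")
    if fit_big.n_obs != fit_small.n_obs:
        raise DataError("LRT requires both fits on the same rows")
    raw = fit_small.minus2_loglik - fit_big.minus2_loglik
    if raw < -1e-6:
        raise NumericError(
            f"larger model fits worse (-2LL difference {raw:.3g}); "
            "re-run the larger fit with more optimizer restarts"
        )
    lam = max(raw, 0.0)
    if null_type == "chi2_1":
        pv = float(stats.chi2.sf(lam, 1))
    else:
        pv = float(0.5 * stats.chi2.sf(lam, 1) + 0.5 * stats.chi2.sf(lam, 2))
    return LrtResult(statistic=lam, null_type=null_type, p_value=pv)


def mixture_p_value(lam: float) -> float:
    """Equal-weight chi^2_1 / chi^2_2 mixture tail probability."""
    return float(0.5 * stats.chi2.sf(lam, 1) + 0.5 * stats.chi2.sf(lam, 2))
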