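"""Semiparametric mixed model: pain score vs. asymmetry with a spline smooth.

The model for one observer x scale combination is

    score_ij = beta0 + f(TAS_ij) + beta1 * 1[before_gait]
               + b_i + eps_ij,
    b_i ~ N(0, sigma2_horse),   corr(eps_ij, eps_ij') = phi^|j - j'|

with ``f`` a penalized cubic B-spline smooth (basis dimension ``k``, default
10, quantile-spaced knots, second-order divided-difference penalty whose null
space is exactly the linear functions) and AR(1) within-horse residual
correlation, rows ordered by proportional time.  Estimation uses the
mixed-model representation of the penalized spline: the smooth's wiggly
component enters as an i.i.d. random coefficient block, and the variance
parameters (smoothing parameter, horse variance, AR(1) phi) are estimated by
numerically maximized restricted (or full) likelihood on the profiled
criterion.  The smooth's effective degrees of freedom (EDF) is the trace of
its block of the influence matrix: EDF ~ 1 means the fitted relation is
linear, larger values mean increasing curvature.

The association test is a likelihood-ratio test of the full model against
the smooth-dropped model with a chi-square reference on EDF degrees of
freedom; the before/after-gait-analysis effect is a Wald test.
``r2_adj = 1 - [RSS/(n - edf_total)] / [TSS/(n - 1)]`` (may be negative).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats

from .exceptions import (ConfigurationError, InsufficientDataError,
                         ModelFitError, ValidationError)

__all__ = [
    "PenalizedBasis",
    "ModelData",
    "SmoothModelFit",
    "build_penalized_basis",
    "fit_association_model",
    "predict_scores",
    "partial_effect_curve",
]

_DEGREE = 3  # cubic B-splines


# -------------------------------------------------------------------- basis

@dataclass
class PenalizedBasis:
    """Cubic B-spline basis with a second-order difference penalty.

    ``knots`` is the full padded knot vector; ``greville`` the coefficient
    abscissae.  The penalty uses divided second differences on the Greville
    points, so coefficient vectors linear in x incur zero penalty and the
    penalty null space is exactly {1, x}.  ``design(x)`` returns the raw
    basis; beyond the training range basis rows are extended linearly.
    """

    knots: np.ndarray
    k: int
    x_min: float
    x_max: float
    x_mean: float
    D: np.ndarray  # (k-2, k) divided-difference penalty root
    Dplus: np.ndarray  # (k, k-2) minimum-norm right inverse of D
    z_center: np.ndarray  # training-sample column means of the wiggle block

    @property
    def penalty(self) -> np.ndarray:
        """Penalty matrix S = D'D (quadratic form on raw coefficients)."""
        return self.D.T @ self.D

    def design(self, x: np.ndarray) -> np.ndarray:
        """Raw (uncentred) basis matrix, linearly extrapolated outside range."""
        x = np.asarray(x, float)
        spl = interpolate.BSpline(self.knots, np.eye(self.k), _DEGREE,
                                  extrapolate=False)
        dspl = spl.derivative()
        B = np.empty((len(x), self.k))
        inside = (x >= self.x_min) & (x <= self.x_max)
        if inside.any():
            B[inside] = spl(x[inside])
        for bound in (self.x_min, self.x_max):
            mask = (x < bound) if bound == self.x_min else (x > bound)
            if mask.any():
                b0 = spl(np.array([bound]))[0]
                db0 = dspl(np.array([bound]))[0]
                B[mask] = b0[None, :] + (x[mask] - bound)[:, None] * db0[None, :]
        return B

    def smooth_columns(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Mixed-form smooth design: (centred linear column, wiggle block Z)."""
        x = np.asarray(x, float)
        x_lin = x - self.x_mean
        Z = self.design(x) @ self.Dplus - self.z_center[None, :]
        return x_lin, Z


def build_penalized_basis(x: Sequence[float], k: int = 10) -> PenalizedBasis:
    """Build the basis on quantile-spaced knots from the training x values."""
    x = np.asarray(x, float)
    uniq = np.unique(x)
    if k < 5:
        raise ConfigurationError("basis dimension k must be >= 5")
    if len(uniq) < k:
        raise ConfigurationError(
            f"basis dimension k={k} exceeds the {len(uniq)} distinct x values"
        )
    n_interior = k - _DEGREE - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(uniq, qs)
    lo, hi = float(uniq.min()), float(uniq.max())
    knots = np.concatenate([[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)])
    greville = np.array([knots[j + 1: j + _DEGREE + 1].mean() for j in range(k)])

    # divided second differences on the Greville abscissae
    D = np.zeros((k - 2, k))
    for j in range(k - 2):
        h1 = greville[j + 1] - greville[j]
        h2 = greville[j + 2] - greville[j + 1]
        D[j, j] = 1.0 / h1
        D[j, j + 1] = -(1.0 / h1 + 1.0 / h2)
        D[j, j + 2] = 1.0 / h2
    # scale-free normalization so gamma_s is comparable across data scalings
    D *= np.mean(np.diff(greville)) ** 1.5
    Dplus = D.T @ np.linalg.inv(D @ D.T)

    basis = PenalizedBasis(knots=knots, k=k, x_min=lo, x_max=hi,
                           x_mean=float(x.mean()), D=D, Dplus=Dplus,
                           z_center=np.zeros(k - 2))
    spl = interpolate.BSpline(knots, np.eye(k), _DEGREE, extrapolate=False)
    basis.z_center = (spl(x) @ Dplus).mean(axis=0)
    return basis


# --------------------------------------------------------------------- data

@dataclass
class ModelData:
    """Rows of one observer x scale: horse, prop_time, TAS, timing, score."""

    horse: np.ndarray
    prop_time: np.ndarray  # percent
    tas: np.ndarray  # mm
    before_gait: np.ndarray  # bool
    score: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModelData":
        req = {"horse", "prop_time_pct", "tas_mm", "timing", "total"}
        if not req <= set(df.columns):
            raise ValidationError(f"model data needs columns {sorted(req)}")
        d = df.sort_values(["horse", "prop_time_pct"], kind="mergesort")
        for col in ("tas_mm", "total"):
            if d[col].isna().any():
                raise ValidationError(f"model data: missing values in {col}")
        return cls(
            horse=d["horse"].to_numpy(),
            prop_time=d["prop_time_pct"].to_numpy(float),
            tas=d["tas_mm"].to_numpy(float),
            before_gait=(d["timing"].astype(str) == "before_gait").to_numpy(),
            score=d["total"].to_numpy(float),
        )


# ---------------------------------------------------------------------- fit

@dataclass
class SmoothModelFit:
    basis: PenalizedBasis
    coef: np.ndarray  # [beta0, beta_timing, beta_lin, a_1..a_{k-2}]
    cov: np.ndarray  # Bayesian covariance of coef
    sigma2: float  # residual variance
    sigma2_horse: float
    phi: float
    lambda_: float  # smoothing parameter (1 / gamma_s)
    edf: float  # smooth term EDF (linear column + wiggle block)
    edf_total: float
    r2_adj: float
    p_association: float
    p_timing: float
    loglik: float  # ML log-likelihood at the reported parameters
    fitted: np.ndarray  # population-level fitted values
    fitted_conditional: np.ndarray  # including horse BLUPs
    horse_levels: np.ndarray
    horse_blups: np.ndarray
    n: int
    mean_before: float = 0.0  # training fraction of before-gait rows
    converged: bool = True

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def timing_coef(self) -> float:
        return float(self.coef[1])


def _ar1_block(m: int, phi: float) -> np.ndarray:
    idx = np.arange(m)
    return phi ** np.abs(idx[:, None] - idx[None, :])


class _Worker:
    """Profiled (restricted) likelihood machinery for one dataset."""

    def __init__(self, y, X, Zs, blocks):
        self.y = y
        self.X = X
        self.Zs = Zs
        self.blocks = blocks  # list of slices, one per horse
        self.n = len(y)
        self.ZZ = Zs @ Zs.T if Zs is not None else None

    def _W(self, gamma_s, gamma_h, phi):
        if self.ZZ is not None and gamma_s > 0:
            W = gamma_s * self.ZZ.copy()
        else:
            W = np.zeros((self.n, self.n))
        for sl in self.blocks:
            m = sl.stop - sl.start
            W[sl, sl] += _ar1_block(m, phi) + gamma_h
        return W

    def profile(self, gamma_s, gamma_h, phi, reml=True):
        """Negative profiled criterion; also returns GLS pieces."""
        W = self._W(gamma_s, gamma_h, phi)
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdetW = 2.0 * np.sum(np.log(np.diag(L)))
        Xw = np.linalg.solve(L, self.X)
        yw = np.linalg.solve(L, self.y)
        XtX = Xw.T @ Xw
        try:
            beta = np.linalg.solve(XtX, Xw.T @ yw)
        except np.linalg.LinAlgError:
            return np.inf, None
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        n, p = self.n, self.X.shape[1]
        if reml:
            sigma2 = rss / (n - p)
            sign, logdetXtX = np.linalg.slogdet(XtX)
            crit = ((n - p) * np.log(sigma2) + logdetW + logdetXtX
                    + (n - p) * (1.0 + np.log(2.0 * np.pi)))
        else:
            sigma2 = rss / n
            crit = n * np.log(sigma2) + logdetW + n * (1.0 + np.log(2.0 * np.pi))
        return 0.5 * crit, (beta, sigma2, W)

    def loglik_ml(self, gamma_s, gamma_h, phi) -> float:
        crit, _ = self.profile(gamma_s, gamma_h, phi, reml=False)
        return -crit


def _optimize(worker: _Worker, free: Dict[str, bool], start: Dict[str, float],
              reml: bool) -> Tuple[Dict[str, float], bool, object]:
    names = [n for n in ("ls", "lh", "psi") if free[n]]

    def unpack(theta):
        vals = dict(start)
        for n, v in zip(names, theta):
            vals[n] = v
        gamma_s = np.exp(vals["ls"]) if vals["ls"] is not None else 0.0
        gamma_h = np.exp(vals["lh"])
        phi = np.tanh(vals["psi"])
        return gamma_s, gamma_h, phi

    if not names:
        return dict(start), True, None

    def fun(theta):
        crit, _ = worker.profile(*unpack(theta), reml=reml)
        return crit if np.isfinite(crit) else 1e12

    x0 = np.array([start[n] for n in names], float)
    bounds = {"ls": (-18.0, 18.0), "lh": (-18.0, 12.0), "psi": (-2.2, 2.2)}
    res = optimize.minimize(fun, x0, method="L-BFGS-B",
                            bounds=[bounds[n] for n in names],
                            options={"maxiter": 200, "ftol": 1e-10})
    if not res.success and "MAXLS" not in str(res.message).upper():
        # L-BFGS-B can stall on flat profiles; polish with Nelder-Mead
        res2 = optimize.minimize(fun, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-5, "fatol": 1e-8,
                                          "maxiter": 400})
        if res2.fun <= res.fun:
            res = res2
    vals = dict(start)
    for n, v in zip(names, res.x):
        vals[n] = float(v)
    return vals, bool(np.isfinite(res.fun)), res


def fit_association_model(
    data: ModelData | pd.DataFrame,
    k: int = 10,
    fix_lambda: Optional[float] = None,
    fix_phi: Optional[float] = None,
    fix_sigma2_horse_ratio: Optional[float] = None,
    reml: bool = True,
    compute_tests: bool = True,
) -> SmoothModelFit:
    """Fit the spline mixed model for one observer x scale dataset.

    ``fix_lambda=numpy.inf`` forces the smooth to its linear limit,
    ``fix_phi`` / ``fix_sigma2_horse_ratio`` pin the AR(1) parameter and the
    horse-to-residual variance ratio (``fix_sigma2_horse_ratio=0`` removes the
    random intercept); free parameters are estimated by REML (default) or ML.
    """
    if isinstance(data, pd.DataFrame):
        data = ModelData.from_frame(data)
    n = len(data.score)
    if n < 20:
        raise InsufficientDataError(f"need >= 20 rows, got {n}")
    horse_levels, horse_codes = np.unique(data.horse, return_inverse=True)
    if len(horse_levels) < 2:
        raise InsufficientDataError("need >= 2 horses")
    # rows arrive sorted by (horse, prop_time); blocks are contiguous
    blocks = []
    start = 0
    for h in range(len(horse_levels)):
        m = int((horse_codes == h).sum())
        blocks.append(slice(start, start + m))
        start += m

    basis = build_penalized_basis(data.tas, k=k)
    x_lin, Zs = basis.smooth_columns(data.tas)
    X = np.column_stack([np.ones(n), data.before_gait.astype(float), x_lin])
    y = data.score.astype(float)

    drop_smooth_ranef = fix_lambda is not None and np.isinf(fix_lambda)
    worker = _Worker(y, X, None if drop_smooth_ranef else Zs, blocks)

    free = {"ls": not drop_smooth_ranef and fix_lambda is None,
            "lh": fix_sigma2_horse_ratio is None,
            "psi": fix_phi is None}
    start_vals = {
        "ls": None if drop_smooth_ranef else (
            0.0 if fix_lambda is None else float(np.log(1.0 / fix_lambda))),
        "lh": np.log(0.1) if fix_sigma2_horse_ratio is None else float(
            np.log(max(fix_sigma2_horse_ratio, 1e-18))),
        "psi": 0.0 if fix_phi is None else float(np.arctanh(np.clip(fix_phi, -0.99, 0.99))),
    }
    vals, ok, res = _optimize(worker, free, start_vals, reml)
    if not ok:
        raise ModelFitError("variance-parameter optimization failed", trace=res)

    gamma_s = 0.0 if vals["ls"] is None else float(np.exp(vals["ls"]))
    if drop_smooth_ranef:
        gamma_s = 0.0
    gamma_h = float(np.exp(vals["lh"]))
    if fix_sigma2_horse_ratio == 0.0:
        gamma_h = 0.0
    phi = float(np.tanh(vals["psi"]))
    if fix_phi is not None:
        phi = float(fix_phi)

    if abs(phi) > 0.97 and free["psi"]:
        warnings.warn(f"AR(1) parameter on boundary (phi={phi:.3f}); "
                      "profile refit at +-0.95")
        return fit_association_model(
            data, k=k, fix_lambda=fix_lambda, fix_phi=float(np.sign(phi) * 0.95),
            fix_sigma2_horse_ratio=fix_sigma2_horse_ratio, reml=reml,
            compute_tests=compute_tests)

    crit, pieces = worker.profile(gamma_s, gamma_h, phi, reml=reml)
    if pieces is None:
        raise ModelFitError("likelihood evaluation failed at the optimum", trace=res)
    _, sigma2, _ = pieces

    # --- penalized-GLS estimates, EDF and covariance -----------------------
    V0 = np.zeros((n, n))
    for sl in blocks:
        m = sl.stop - sl.start
        V0[sl, sl] = _ar1_block(m, phi) + gamma_h
    L0 = np.linalg.cholesky(V0)
    if gamma_s > 0:
        C = np.column_stack([X, Zs])
        P = np.zeros((C.shape[1], C.shape[1]))
        P[3:, 3:] = np.eye(Zs.shape[1]) / gamma_s
    else:
        C = X
        P = np.zeros((3, 3))
    Cw = np.linalg.solve(L0, C)
    yw = np.linalg.solve(L0, y)
    CtC = Cw.T @ Cw
    M = CtC + P
    Minv = np.linalg.inv(M)
    coef = Minv @ (Cw.T @ yw)
    F = Minv @ CtC
    edf_per_col = np.diag(F)
    edf_total = float(np.trace(F))
    edf_smooth = float(edf_per_col[2] + (edf_per_col[3:].sum() if C.shape[1] > 3 else 0.0))
    edf_smooth = float(np.clip(edf_smooth, 1.0, basis.k - 1))
    cov = sigma2 * Minv

    if gamma_s == 0:
        coef_full = np.concatenate([coef, np.zeros(basis.k - 2)])
        cov_full = np.zeros((3 + basis.k - 2, 3 + basis.k - 2))
        cov_full[:3, :3] = cov
    else:
        coef_full, cov_full = coef, cov

    fitted_pop = np.column_stack([X, Zs]) @ coef_full
    # horse BLUPs from the marginal residuals
    resid0 = y - fitted_pop
    blups = np.zeros(len(horse_levels))
    if gamma_h > 0:
        Vinv_r = np.linalg.solve(V0, resid0)
        for h, sl in enumerate(blocks):
            blups[h] = gamma_h * Vinv_r[sl].sum()
    # rows are sorted by horse, so the inverse codes map rows to blups directly
    fitted_cond = fitted_pop + blups[horse_codes]

    rss = float(np.sum((y - fitted_pop) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    denom_df = max(n - edf_total, 1.0)
    r2_adj = 1.0 - (rss / denom_df) / (tss / (n - 1)) if tss > 0 else float("nan")

    se_timing = float(np.sqrt(max(cov_full[1, 1], 0.0)))
    if se_timing > 0:
        z = coef_full[1] / se_timing
        p_timing = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p_timing = float("nan")

    loglik = worker.loglik_ml(gamma_s, gamma_h, phi)

    fit = SmoothModelFit(
        basis=basis, coef=coef_full, cov=cov_full,
        sigma2=float(sigma2), sigma2_horse=float(gamma_h * sigma2), phi=phi,
        lambda_=float(np.inf if gamma_s == 0 else 1.0 / gamma_s),
        edf=edf_smooth, edf_total=edf_total, r2_adj=float(r2_adj),
        p_association=float("nan"), p_timing=p_timing, loglik=float(loglik),
        fitted=fitted_pop, fitted_conditional=fitted_cond,
        horse_levels=horse_levels, horse_blups=blups, n=n,
        mean_before=float(data.before_gait.mean()),
    )

    if compute_tests:
        fit.p_association = _association_pvalue(
            data, worker, basis, X, Zs, blocks, edf_smooth,
            fix_lambda, fix_phi, fix_sigma2_horse_ratio)
    return fit


def _association_pvalue(data, worker_full, basis, X, Zs, blocks, edf_smooth,
                        fix_lambda, fix_phi, fix_ratio) -> float:
    """ML likelihood-ratio test of the smooth term, chi2(edf) reference."""
    free = {"ls": fix_lambda is None and Zs is not None and worker_full.Zs is not None,
            "lh": fix_ratio is None, "psi": fix_phi is None}
    start = {
        "ls": 0.0 if free["ls"] else (
            None if (fix_lambda is not None and np.isinf(fix_lambda))
            else (0.0 if fix_lambda is None else float(np.log(1.0 / fix_lambda)))),
        "lh": np.log(0.1) if free["lh"] else float(np.log(max(fix_ratio, 1e-18))),
        "psi": 0.0 if free["psi"] else float(np.arctanh(np.clip(fix_phi, -0.99, 0.99))),
    }
    vals_f, ok_f, _ = _optimize(worker_full, free, start, reml=False)
    gs = 0.0 if vals_f["ls"] is None else float(np.exp(vals_f["ls"]))
    if worker_full.Zs is None:
        gs = 0.0
    ll_full = worker_full.loglik_ml(gs, np.exp(vals_f["lh"]), np.tanh(vals_f["psi"]))

    worker_null = _Worker(worker_full.y, X[:, :2], None, blocks)
    free_null = {"ls": False, "lh": free["lh"], "psi": free["psi"]}
    start_null = dict(start)
    start_null["ls"] = None
    vals_n, ok_n, _ = _optimize(worker_null, free_null, start_null, reml=False)
    ll_null = worker_null.loglik_ml(0.0, np.exp(vals_n["lh"]), np.tanh(vals_n["psi"]))

    if not (ok_f and ok_n):
        return float("nan")
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    df = max(edf_smooth, 1.0)
    return float(stats.chi2.sf(lrt, df))


# ---------------------------------------------------------------- predict

def predict_scores(fit: SmoothModelFit, newdata: pd.DataFrame,
                   conditional: bool = False) -> np.ndarray:
    """Predicted totals; population-level (random effects at 0) by default.

    With ``conditional=True`` horse BLUPs are added for horses seen in
    training.  TAS outside the training range triggers a warning and linear
    extrapolation of the smooth.
    """
    if "tas_mm" not in newdata.columns:
        raise ValidationError("newdata needs a tas_mm column")
    tas = newdata["tas_mm"].to_numpy(float)
    if np.any((tas < fit.basis.x_min) | (tas > fit.basis.x_max)):
        warnings.warn("TAS outside the training range: smooth extrapolated linearly")
    before = (newdata["timing"].astype(str) == "before_gait").to_numpy() \
        if "timing" in newdata.columns else np.zeros(len(tas), bool)
    x_lin, Z = fit.basis.smooth_columns(tas)
    Cnew = np.column_stack([np.ones(len(tas)), before.astype(float), x_lin, Z])
    pred = Cnew @ fit.coef
    if conditional:
        if "horse" not in newdata.columns:
            raise ValidationError("conditional predictions need a horse column")
        lookup = {h: b for h, b in zip(fit.horse_levels, fit.horse_blups)}
        pred = pred + np.array([lookup.get(h, 0.0) for h in newdata["horse"]])
    return pred


def partial_effect_curve(fit: SmoothModelFit, tas_grid: Sequence[float]
                         ) -> pd.DataFrame:
    """Centred smooth estimate with a pointwise 95% confidence band.

    Returns columns ``tas, estimate, lo, hi``; the estimate is centred to
    mean zero over the training TAS values (the plotting convention for
    partial effects).
    """
    grid = np.asarray(tas_grid, float)
    x_lin, Z = fit.basis.smooth_columns(grid)
    Cs = np.column_stack([x_lin, Z])
    sm_coef = fit.coef[2:]
    est = Cs @ sm_coef

    # centring constant from the training-sample partial effect
    est = est - _training_partial_mean(fit)

    cov_s = fit.cov[2:, 2:]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Cs, cov_s, Cs), 0.0))
    return pd.DataFrame({"tas": grid, "estimate": est,
                         "lo": est - 1.96 * se, "hi": est + 1.96 * se})


def _training_partial_mean(fit: SmoothModelFit) -> float:
    # fitted = X beta + smooth; the smooth's training mean equals the
    # fitted mean minus the fixed-effect mean contribution
    return float(fit.fitted.mean() - fit.coef[0] - fit.coef[1] * fit.mean_before)
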