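"""Penalized-spline additive models with term shrinkage.

The model is Gaussian and additive: ``y = b0 + sum_j f_j(x_j) + e``.  Each
smooth ``f_j`` is a cubic B-spline on quantile-spaced knots with a
second-difference penalty; a sum-to-zero constraint (absorbed by a null
space reparameterization) keeps terms identifiable against the intercept.
With shrinkage on, each term additionally carries a separate penalty on
the null space of its curvature penalty, so driving both of a term's
smoothing parameters to infinity removes it entirely -- straight line
included -- without coupling curvature smoothing to slope shrinkage.

Smoothing parameters are chosen by restricted maximum likelihood (REML):
the Gaussian restricted likelihood, with the error variance profiled out,
is minimized coordinate-wise over a log-spaced grid of 40 values per
penalty (two sweeps), all evaluations per coordinate batched through a
stacked Cholesky factorization.  GCV is available as a cheaper
alternative.  Per-term significance uses a Wald-type F statistic (squared
norm of the fitted term values over its effective degrees of freedom,
scaled by the residual variance), which is monotone-consistent for
ranking terms; an exact reference distribution is not attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

LAMBDA_GRID = np.logspace(-6.0, 10.0, 40)
N_SWEEPS = 2
#: Weak prior on log10(lambda) added to the REML score.  The restricted
#: likelihood is often near-flat in lambda for terms with no signal; this
#: tilt (a fraction of a likelihood unit per decade) resolves such plateaus
#: toward the smoother model and leaves sharp interior optima untouched.
SMOOTHNESS_TILT = 0.02
ALPHA_BACKWARD = 0.05
CURVE_POINTS = 100


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------

def basis_dimension_rule(n_obs: int, n_covariates: int, k_min: int = 3) -> int:
    """Per-term basis dimension: floor(n_obs / n_covariates), floored at k_min."""
    if n_covariates < 1 or n_obs <= n_covariates:
        raise ValueError("need n_obs > n_covariates >= 1")
    return max(k_min, n_obs // n_covariates)


@dataclass
class SplineBasis:
    """A centred penalized B-spline basis for one covariate.

    ``S`` is the curvature (second-difference) penalty in the centred
    coordinates; ``N`` is the projector on its null space (the straight-
    line direction), used as the separate shrinkage penalty so a term can
    be removed entirely without biasing sloped smooths at moderate
    curvature penalties.
    """

    covariate: str
    knots: np.ndarray            # full clamped knot vector
    degree: int
    k: int                       # raw basis dimension
    Q: np.ndarray                # (k, k-1) constraint null-space map
    S: np.ndarray                # (k-1, k-1) second-difference penalty
    N: np.ndarray                # null-space projector (shrinkage penalty)
    rank_S: int
    logpdet_S: float
    null_dim: int
    x_min: float
    x_max: float
    col_means: np.ndarray        # raw-basis column means used for centring

    def raw_matrix(self, x: np.ndarray) -> np.ndarray:
        t, d = self.knots, self.degree
        lo, hi = t[d], t[-d - 1]
        xc = np.clip(np.asarray(x, float), lo, np.nextafter(hi, -np.inf))
        return BSpline.design_matrix(xc, t, d).toarray()

    def design(self, x: np.ndarray) -> np.ndarray:
        """Centred (identifiable) design matrix, (n, k-1)."""
        B = self.raw_matrix(x) - self.col_means
        return B @ self.Q


def build_basis(x, k: int, covariate: str = "x") -> SplineBasis:
    """B-spline basis with second-difference penalty on quantile knots.

    Cubic for k >= 4 (quadratic at the k = 3 floor).  The raw basis rows
    form a partition of unity; the second-difference penalty annihilates
    constant and linear coefficient patterns.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    ux = np.unique(x)
    if ux.size < k:
        raise ValueError(f"need >= {k} distinct values for a k={k} basis "
                         f"({covariate}: {ux.size})")
    degree = 3 if k >= 4 else 2
    n_interior = k - degree - 1
    probs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    interior = np.quantile(ux, probs) if n_interior > 0 else np.array([])
    t = np.concatenate([np.repeat(ux[0], degree + 1), interior,
                        np.repeat(ux[-1], degree + 1)])

    D2 = np.diff(np.eye(k), n=2, axis=0)
    S_raw = D2.T @ D2

    lo, hi = t[degree], t[-degree - 1]
    xc = np.clip(x, lo, np.nextafter(hi, -np.inf))
    B = BSpline.design_matrix(xc, t, degree).toarray()
    col_means = B.mean(axis=0)
    Q = linalg.null_space(col_means[None, :])          # (k, k-1)
    S = Q.T @ S_raw @ Q

    evals, evecs = linalg.eigh(S)
    tol = max(evals.max(), 1.0) * 1e-10
    null = evecs[:, evals < tol]
    N = null @ null.T
    return SplineBasis(covariate=covariate, knots=t, degree=degree, k=k,
                       Q=Q, S=S, N=N,
                       rank_S=int((evals >= tol).sum()),
                       logpdet_S=float(np.sum(np.log(evals[evals >= tol]))),
                       null_dim=int(null.shape[1]),
                       x_min=float(ux[0]), x_max=float(ux[-1]),
                       col_means=col_means)


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class SmoothTermFit:
    covariate: str
    coefficients: np.ndarray
    lam: float
    edf: float
    F: float
    p: float
    dropped: bool = False


@dataclass
class GAMFit:
    response: str
    variant: str
    terms: list[SmoothTermFit]
    intercept: float
    pct_dev: float
    adj_r2: float
    n_obs: int
    resid_var: float
    method: str
    edf_total: float
    bases: dict[str, SplineBasis] = field(repr=False, default_factory=dict)
    coef_cov: np.ndarray | None = field(repr=False, default=None)
    index: dict[str, slice] = field(repr=False, default_factory=dict)
    y: np.ndarray | None = field(repr=False, default=None)
    covariates: pd.DataFrame | None = field(repr=False, default=None)
    shrinkage: bool = True
    removal_history: list[str] = field(default_factory=list)

    @property
    def model_id(self) -> str:
        return f"{self.response}|{self.variant}"

    def term(self, covariate: str) -> SmoothTermFit:
        for t in self.terms:
            if t.covariate == covariate:
                return t
        raise KeyError(covariate)

    @property
    def active_terms(self) -> list[SmoothTermFit]:
        return [t for t in self.terms if not t.dropped]


# ---------------------------------------------------------------------------
# the penalized least-squares / REML machinery
# ---------------------------------------------------------------------------

def _assemble(y: np.ndarray, covariates: pd.DataFrame,
              bases: dict[str, SplineBasis]):
    cols = [np.ones((len(y), 1))]
    index: dict[str, slice] = {}
    pos = 1
    for name in covariates.columns:
        Z = bases[name].design(covariates[name].to_numpy(float))
        index[name] = slice(pos, pos + Z.shape[1])
        pos += Z.shape[1]
        cols.append(Z)
    X = np.hstack(cols)
    return X, index


def _embed(P: np.ndarray, sl: slice, q: int) -> np.ndarray:
    out = np.zeros((q, q))
    out[sl, sl] = P
    return out


def _chol_stack(A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.mean(np.trace(A, axis1=-2, axis2=-1)) / A.shape[-1]
        return np.linalg.cholesky(A + jitter * np.eye(A.shape[-1]))


def _criterion_over_grid(XtX, Xty, yty, n, comps, lam, j, grid, method, M):
    """Vector of REML/GCV scores as penalty component j runs over the grid.

    ``comps`` is a list of (embedded penalty, rank, log pseudo-det); the
    curvature and null-space penalties of one term are separate components
    (the null space lives in a subspace orthogonal to the curvature
    penalty's range, so the total log pseudo-determinant is additive).
    """
    q = XtX.shape[0]
    A_base = XtX + sum(l * P for m, (l, (P, _, _)) in enumerate(zip(lam, comps))
                       if m != j)
    Pj = comps[j][0]
    A = A_base[None, :, :] + grid[:, None, None] * Pj[None, :, :]
    L = _chol_stack(A)
    logdetA = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    beta = np.linalg.solve(A, np.broadcast_to(Xty[:, None], (len(grid), q, 1)).copy())
    beta = beta[..., 0]
    rss = yty - 2.0 * beta @ Xty + np.einsum("gi,ij,gj->g", beta, XtX, beta)
    pen = np.einsum("gi,gij,gj->g", beta, (A - XtX[None, :, :]), beta)
    if method == "REML":
        log_pdet_S = sum(r * np.log(l) + lp
                         for m, (l, (_, r, lp)) in enumerate(zip(lam, comps))
                         if m != j)
        log_pdet_S = log_pdet_S + comps[j][1] * np.log(grid) + comps[j][2]
        score = ((n - M) * np.log(np.maximum(rss + pen, 1e-300))
                 + logdetA - log_pdet_S - SMOOTHNESS_TILT * np.log10(grid))
    else:  # GCV
        AinvXtX = np.linalg.solve(A, np.broadcast_to(XtX, A.shape).copy())
        edf = np.trace(AinvXtX, axis1=-2, axis2=-1)
        score = n * np.maximum(rss, 1e-300) / np.maximum(n - edf, 1e-6) ** 2
    return score


def fit_additive_model(y, covariates: pd.DataFrame, variant: str = "custom",
                       method: str = "REML", shrinkage: bool = True,
                       k: int | None = None, gamma: float = 1.0,
                       response_name: str = "y",
                       lambda_grid: np.ndarray = LAMBDA_GRID,
                       n_sweeps: int = N_SWEEPS,
                       _drop_terms: tuple[str, ...] = ()) -> GAMFit:
    """Fit a penalized-spline additive model with per-term smoothing.

    Rows with any missing value are dropped (complete-case, logged).  The
    per-term basis dimension follows ``basis_dimension_rule`` unless ``k``
    is given, capped at one less than the number of distinct values.
    """
    if method not in ("REML", "GCV"):
        raise ValueError("method must be REML or GCV")
    y = np.asarray(y, dtype=float)
    covariates = covariates.copy()
    active_cols = [c for c in covariates.columns if c not in _drop_terms]
    ok = np.isfinite(y)
    for c in active_cols:
        ok &= np.isfinite(covariates[c].to_numpy(float))
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropping %d incomplete rows", n_dropped)
    y = y[ok]
    cov = covariates.loc[ok, active_cols]
    n, p = len(y), len(active_cols)
    if n < 10 + p:
        raise ValueError(f"too few complete observations (n={n}) for {p} terms")

    k_rule = k if k is not None else basis_dimension_rule(n, p)
    bases: dict[str, SplineBasis] = {}
    for c in active_cols:
        x = cov[c].to_numpy(float)
        k_c = int(min(k_rule, np.unique(x).size - 1))
        k_c = max(k_c, 3)
        bases[c] = build_basis(x, k_c, covariate=c)

    X, index = _assemble(y, cov, bases)
    q = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    # penalty components: curvature per term, plus (with shrinkage) a
    # separate null-space penalty per term so the whole term can vanish
    comps: list[tuple[np.ndarray, int, float]] = []
    comp_term: list[str] = []        # owning covariate per component
    for c in active_cols:
        b = bases[c]
        comps.append((_embed(b.S, index[c], q), b.rank_S, b.logpdet_S))
        comp_term.append(c)
        if shrinkage and b.null_dim > 0:
            comps.append((_embed(b.N, index[c], q), b.null_dim, 0.0))
            comp_term.append(c)
    M = 1 if shrinkage else 1 + sum(bases[c].null_dim for c in active_cols)

    lam = np.ones(len(comps))
    for _ in range(n_sweeps):
        for j in range(len(comps)):
            scores = _criterion_over_grid(XtX, Xty, yty, n, comps, lam, j,
                                          lambda_grid, method, M)
            lam[j] = lambda_grid[int(np.argmin(scores))]

    A = XtX + sum(l * P for l, (P, _, _) in zip(lam, comps))
    try:
        cf = linalg.cho_factor(A)
    except linalg.LinAlgError:
        A = A + 1e-8 * np.mean(np.diag(A)) * np.eye(q)
        cf = linalg.cho_factor(A)
    beta = linalg.cho_solve(cf, Xty)
    Ainv = linalg.cho_solve(cf, np.eye(q))
    H = Ainv @ XtX
    edf_total = float(np.trace(H))

    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    pct_dev = 1.0 - rss / tss if tss > 0 else 0.0
    denom = max(n - edf_total, 1e-6)
    sigma2 = rss / denom
    adj_r2 = 1.0 - sigma2 / (tss / (n - 1)) if n > 1 and tss > 0 else 0.0

    terms: list[SmoothTermFit] = []
    for c in covariates.columns:
        if c in _drop_terms:
            terms.append(SmoothTermFit(covariate=c, coefficients=np.zeros(0),
                                       lam=np.inf, edf=0.0, F=0.0, p=1.0,
                                       dropped=True))
            continue
        sl = index[c]
        cj = beta[sl]
        fj = X[:, sl] @ cj
        edf_j = float(np.trace(H[sl, sl]))
        if edf_j > 1e-8 and sigma2 > 0 and float(fj @ fj) > 0:
            # flooring the numerator df at 1 keeps heavily shrunk terms
            # (edf << 1) from looking spuriously significant under an
            # F reference with fractional df
            df1 = max(edf_j, 1.0)
            F = float(fj @ fj) / df1 / sigma2
            df2 = max(n - edf_total, 1.0)
            pval = float(stats.f.sf(F, df1, df2))
        else:
            F, pval = 0.0, 1.0
        lam_c = float(lam[comp_term.index(c)])     # curvature-penalty lambda
        terms.append(SmoothTermFit(covariate=c, coefficients=cj,
                                   lam=lam_c, edf=edf_j, F=F, p=pval))

    return GAMFit(response=response_name, variant=variant, terms=terms,
                  intercept=float(beta[0]), pct_dev=pct_dev, adj_r2=adj_r2,
                  n_obs=n, resid_var=sigma2, method=method,
                  edf_total=edf_total, bases=bases,
                  coef_cov=sigma2 * Ainv, index=index, y=y,
                  covariates=covariates.loc[ok], shrinkage=shrinkage)


# ---------------------------------------------------------------------------
# significance, selection, curves
# ---------------------------------------------------------------------------

def term_significance(fit: GAMFit) -> pd.DataFrame:
    """Per-term F and p, ranked by descending F (dropped terms last)."""
    rows = [(t.covariate, t.F, t.p, t.edf, t.dropped) for t in fit.terms]
    df = pd.DataFrame(rows, columns=["covariate", "F", "p", "edf", "dropped"])
    df = df.sort_values(["dropped", "F"], ascending=[True, False],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def backward_select(fit: GAMFit, alpha: float = ALPHA_BACKWARD) -> GAMFit:
    """Iteratively refit, removing the least significant term (p >= alpha).

    Removed terms stay in the returned fit flagged ``dropped`` (their
    curves are identically zero).  If every term falls, the intercept-only
    fit is returned (pct_dev = 0).
    """
    dropped: list[str] = [t.covariate for t in fit.terms if t.dropped]
    current = fit
    while True:
        cands = [t for t in current.terms if not t.dropped]
        if not cands:
            break
        worst = max(cands, key=lambda t: t.p)
        if worst.p < alpha:
            break
        dropped.append(worst.covariate)
        if len(dropped) == len(fit.terms):
            current = _intercept_only(fit, dropped)
            break
        current = fit_additive_model(
            fit.y, fit.covariates, variant=fit.variant, method=fit.method,
            shrinkage=fit.shrinkage, response_name=fit.response,
            _drop_terms=tuple(dropped))
    current.removal_history = dropped
    return current


def _intercept_only(fit: GAMFit, dropped: list[str]) -> GAMFit:
    y = fit.y
    n = len(y)
    terms = [SmoothTermFit(covariate=c, coefficients=np.zeros(0), lam=np.inf,
                           edf=0.0, F=0.0, p=1.0, dropped=True)
             for c in dropped]
    rss = float(np.sum((y - y.mean()) ** 2))
    return GAMFit(response=fit.response, variant=fit.variant, terms=terms,
                  intercept=float(y.mean()), pct_dev=0.0,
                  adj_r2=0.0, n_obs=n, resid_var=rss / max(n - 1, 1),
                  method=fit.method, edf_total=1.0, bases=fit.bases,
                  coef_cov=None, index={}, y=y, covariates=fit.covariates,
                  shrinkage=fit.shrinkage)


@dataclass
class SmoothCurveSet:
    """Per-covariate partial-effect curves on a common 1-100 index grid.

    ``data_sd`` records each fitted term's standard deviation over the
    observed covariate values -- its actual contribution to the response
    variation, as opposed to the curve's spread over the uniform grid,
    which over-weights data-sparse extremes of heavy-tailed covariates.
    """

    model_id: str
    pct_dev: float
    curves: dict[str, pd.DataFrame]     # covariate -> (grid_index, x, value, se)
    data_sd: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cov, df in self.curves.items():
            d = df.copy()
            d.insert(0, "covariate", cov)
            d.insert(0, "model_id", self.model_id)
            rows.append(d)
        return pd.concat(rows, ignore_index=True)


def extract_curves(fit: GAMFit, n_points: int = CURVE_POINTS) -> SmoothCurveSet:
    """Centred partial-effect curves on ``n_points`` evenly spaced values
    spanning each covariate's observed range; dropped terms give the zero
    curve."""
    curves: dict[str, pd.DataFrame] = {}
    data_sd: dict[str, float] = {}
    for t in fit.terms:
        basis = fit.bases.get(t.covariate)
        if basis is None:   # dropped before any basis was built
            x_obs = fit.covariates[t.covariate].to_numpy(float)
            x_obs = x_obs[np.isfinite(x_obs)]
            lo, hi = float(np.min(x_obs)), float(np.max(x_obs))
        else:
            lo, hi = basis.x_min, basis.x_max
        grid = np.linspace(lo, hi, n_points)
        if t.dropped or basis is None or t.coefficients.size == 0:
            val = np.zeros(n_points)
            se = np.zeros(n_points)
            data_sd[t.covariate] = 0.0
        else:
            Z = basis.design(grid)
            val = Z @ t.coefficients
            val = val - val.mean()
            sl = fit.index[t.covariate]
            V = fit.coef_cov[sl, sl]
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, V, Z), 0.0))
            x_obs = fit.covariates[t.covariate].to_numpy(float)
            x_obs = x_obs[np.isfinite(x_obs)]
            f_obs = basis.design(x_obs) @ t.coefficients
            data_sd[t.covariate] = float(np.std(f_obs))
        curves[t.covariate] = pd.DataFrame({
            "grid_index": np.arange(1, n_points + 1),
            "x": grid, "value": val, "se": se})
    return SmoothCurveSet(model_id=fit.model_id, pct_dev=fit.pct_dev,
                          curves=curves, data_sd=data_sd)


def predict(fit: GAMFit, newdata: pd.DataFrame,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Model prediction and standard error at new covariate values."""
    n = len(newdata)
    mu = np.full(n, fit.intercept)
    q = 1 + sum(t.coefficients.size for t in fit.terms if not t.dropped)
    Xn = np.zeros((n, q))
    Xn[:, 0] = 1.0
    for t in fit.terms:
        if t.dropped or t.coefficients.size == 0:
            continue
        Z = fit.bases[t.covariate].design(newdata[t.covariate].to_numpy(float))
        mu += Z @ t.coefficients
        Xn[:, fit.index[t.covariate]] = Z
    if fit.coef_cov is not None:
        se = np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", Xn, fit.coef_cov, Xn), 0.0))
    else:
        se = np.zeros(n)
    return mu, se


def fit_latitude_gam(y, latitude, response_name: str = "y",
                     min_stations: int = 30, n_points: int = CURVE_POINTS,
                     ) -> tuple[GAMFit, pd.DataFrame] | None:
    """Single-smooth latitude model with a prediction +- SE curve.

    Returns None (with a logged reason) when fewer than ``min_stations``
    complete observations are available.
    """
    y = np.asarray(y, float)
    lat = np.asarray(latitude, float)
    ok = np.isfinite(y) & np.isfinite(lat)
    if ok.sum() < min_stations:
        log.info("latitude model for %s skipped: n=%d < %d",
                 response_name, int(ok.sum()), min_stations)
        return None
    cov = pd.DataFrame({"latitude": lat[ok]})
    fit = fit_additive_model(y[ok], cov, variant="latitude-only",
                             response_name=response_name)
    grid = pd.DataFrame({"latitude": np.linspace(lat[ok].min(), lat[ok].max(),
                                                 n_points)})
    mu, se = predict(fit, grid)
    curve = pd.DataFrame({"latitude": grid["latitude"], "fit": mu, "se": se})
    return fit, curve
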