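"""Confirmatory factor analysis by robust maximum likelihood.

The measurement model is the LISREL covariance structure

    Sigma(theta) = Lambda Phi Lambda' + Theta

with every item loading on exactly one factor, factor variances fixed to 1
(all loadings free), all factor correlations free, and a diagonal residual
matrix (no correlated errors).  An observed covariate, when present, is
handled as an extra "factor" with a single perfect indicator: its variance
is free, it is orthogonal to the latent factors, and a free path runs from
it to every item.

Estimation minimizes the normal-theory discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with analytic gradients.  Non-normality is handled by the Satorra-Bentler
mean adjustment: T_sb = T_ml / c with the scaling factor c computed from
the distribution-free fourth-moment matrix Gamma, and standard errors use
the corresponding sandwich estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import ModelSpec, count_free_parameters, degrees_of_freedom

_THETA_FLOOR = 1e-6


class ConvergenceError(RuntimeError):
    pass


class HeywoodWarning(UserWarning):
    """A residual variance hit its lower bound during estimation."""


# ---------------------------------------------------------------------------
# Sample moments
# ---------------------------------------------------------------------------

@dataclass
class SampleMoments:
    """Covariance matrix, means and (lazily) the fourth-moment matrix."""

    S: np.ndarray
    means: np.ndarray
    N: int
    variable_names: tuple[str, ...]
    data: np.ndarray | None = None  # raw rows, needed for Gamma
    _gamma: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_data(cls, values, variable_names=None) -> "SampleMoments":
        if isinstance(values, pd.DataFrame):
            variable_names = tuple(values.columns)
            values = values.to_numpy(dtype=float)
        values = np.asarray(values, dtype=float)
        if np.isnan(values).any():
            raise ValueError("complete data required; impute first")
        n = values.shape[0]
        if variable_names is None:
            variable_names = tuple(f"V{i+1}" for i in range(values.shape[1]))
        S = np.cov(values, rowvar=False, ddof=1)
        return cls(S=S, means=values.mean(axis=0), N=n,
                   variable_names=tuple(variable_names), data=values)

    def subset(self, names) -> "SampleMoments":
        idx = [self.variable_names.index(v) for v in names]
        return SampleMoments(
            S=self.S[np.ix_(idx, idx)], means=self.means[idx], N=self.N,
            variable_names=tuple(names),
            data=None if self.data is None else self.data[:, idx])

    def gamma(self) -> np.ndarray:
        """Distribution-free estimate of N * acov(vech(S)).

        Gamma_(ij),(kl) = mean over rows of (z_i z_j - s_ij)(z_k z_l - s_kl)
        with z the centered data.
        """
        if self._gamma is None:
            if self.data is None:
                raise ValueError("raw data required for the robust correction")
            z = self.data - self.data.mean(axis=0)
            p = z.shape[1]
            rows, cols = np.tril_indices(p)
            b = z[:, rows] * z[:, cols]
            b = b - b.mean(axis=0)
            self._gamma = b.T @ b / z.shape[0]
        return self._gamma


def duplication_matrix(p: int) -> np.ndarray:
    """D with vec(A) = D vech(A) for symmetric A (lower-triangle vech)."""
    rows, cols = np.tril_indices(p)
    d = np.zeros((p * p, len(rows)))
    for ell, (i, j) in enumerate(zip(rows, cols)):
        d[j * p + i, ell] = 1.0
        d[i * p + j, ell] = 1.0
    return d


# ---------------------------------------------------------------------------
# Parameters and model structure
# ---------------------------------------------------------------------------

@dataclass
class Parameters:
    """Estimates aligned with a ModelSpec.

    lam[i] is the loading of item i on its assigned factor; phi is the
    factor correlation matrix; theta[i] the residual variance; beta and psi
    are the covariate paths and covariate variance (combined model only).
    """

    lam: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    beta: np.ndarray | None = None
    psi: float | None = None

    def validate(self, spec: ModelSpec) -> None:
        k, m = spec.n_items, spec.n_factors
        if self.lam.shape != (k,) or self.theta.shape != (k,):
            raise ValueError("lam/theta shape mismatch with spec")
        if self.phi.shape != (m, m):
            raise ValueError("phi shape mismatch with spec")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError("phi must be symmetric")
        if not np.allclose(np.diag(self.phi), 1.0):
            raise ValueError("phi must have unit diagonal")
        if (spec.covariate is not None) != (self.beta is not None):
            raise ValueError("beta presence must match spec covariate")


class _Structure:
    """Free-parameter layout for a spec; maps theta-vector <-> matrices.

    Column layout of the extended loading matrix: spec factors first, then
    (for a covariate model) one extra column whose indicator is the
    observed covariate with a fixed unit loading, zero residual and free
    variance, orthogonal to the factors.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        k, m = spec.n_items, spec.n_factors
        self.has_cov = spec.covariate is not None
        self.p = k + (1 if self.has_cov else 0)
        self.M = m + (1 if self.has_cov else 0)
        fidx = {f: a for a, f in enumerate(spec.factors)}
        self.free_load = [(i, fidx[spec.loading[it]])
                          for i, it in enumerate(spec.items)]
        if self.has_cov:
            self.free_load += [(i, m) for i in range(k)]  # covariate paths
        self.theta_idx = list(range(k))  # covariate residual fixed at 0
        self.phi_off = [(a, b) for b in range(m) for a in range(b)]
        self.phi_diag = [m] if self.has_cov else []
        self.n_load = len(self.free_load)
        self.n_theta = len(self.theta_idx)
        self.n_off = len(self.phi_off)
        self.nq = self.n_load + self.n_theta + self.n_off + len(self.phi_diag)
        assert self.nq == count_free_parameters(spec)
        # may be negative for toy specs; fit_ml rejects those
        self.df = self.p * (self.p + 1) // 2 - self.nq

    def unpack(self, t: np.ndarray):
        k = self.spec.n_items
        lam = np.zeros((self.p, self.M))
        pos = 0
        for (i, f) in self.free_load:
            lam[i, f] = t[pos]
            pos += 1
        if self.has_cov:
            lam[k, self.M - 1] = 1.0
        theta = np.zeros(self.p)
        theta[self.theta_idx] = t[pos:pos + self.n_theta]
        pos += self.n_theta
        phi = np.eye(self.M)
        for (a, b) in self.phi_off:
            phi[a, b] = phi[b, a] = t[pos]
            pos += 1
        for a in self.phi_diag:
            phi[a, a] = t[pos]
            pos += 1
        return lam, phi, theta

    def pack(self, params: Parameters) -> np.ndarray:
        t = np.empty(self.nq)
        k, m = self.spec.n_items, self.spec.n_factors
        pos = 0
        for (i, f) in self.free_load:
            t[pos] = params.lam[i] if f < m else params.beta[i]
            pos += 1
        t[pos:pos + self.n_theta] = params.theta
        pos += self.n_theta
        for (a, b) in self.phi_off:
            t[pos] = params.phi[a, b]
            pos += 1
        if self.phi_diag:
            t[pos] = params.psi
        return t

    def to_parameters(self, t: np.ndarray) -> Parameters:
        lam, phi, theta = self.unpack(t)
        k, m = self.spec.n_items, self.spec.n_factors
        lam_item = np.array([lam[i, f] for (i, f) in self.free_load[:k]])
        out = Parameters(lam=lam_item, phi=phi[:m, :m].copy(),
                         theta=theta[:k].copy())
        if self.has_cov:
            out.beta = lam[:k, m].copy()
            out.psi = float(phi[m, m])
        return out

    def sigma(self, t: np.ndarray) -> np.ndarray:
        lam, phi, theta = self.unpack(t)
        return lam @ phi @ lam.T + np.diag(theta)

    def dsigma(self, t: np.ndarray) -> list[np.ndarray]:
        """dSigma/dtheta_j as dense matrices (used once, at the optimum)."""
        lam, phi, _ = self.unpack(t)
        lp = lam @ phi
        out = []
        for (i, f) in self.free_load:
            d = np.zeros((self.p, self.p))
            d[i, :] += lp[:, f]
            d[:, i] += lp[:, f]
            out.append(d)
        for i in self.theta_idx:
            d = np.zeros((self.p, self.p))
            d[i, i] = 1.0
            out.append(d)
        for (a, b) in self.phi_off:
            d = np.outer(lam[:, a], lam[:, b])
            out.append(d + d.T)
        for a in self.phi_diag:
            out.append(np.outer(lam[:, a], lam[:, a]))
        return out

    def start(self, S: np.ndarray) -> np.ndarray:
        """Start values: loadings 0.5, residuals 0.5, correlations 0.3,
        covariate paths 0.2, all on the per-variable SD scale."""
        k = self.spec.n_items
        sd = np.sqrt(np.diag(S))
        t = np.empty(self.nq)
        pos = 0
        for (i, f) in self.free_load:
            if f < self.spec.n_factors:
                t[pos] = 0.5 * sd[i]
            else:
                t[pos] = 0.2 * sd[i] / sd[k]
            pos += 1
        t[pos:pos + self.n_theta] = 0.5 * np.diag(S)[self.theta_idx]
        pos += self.n_theta
        t[pos:pos + self.n_off] = 0.3
        pos += self.n_off
        if self.phi_diag:
            t[pos] = S[k, k]
        return t

    def bounds(self):
        b: list[tuple] = [(None, None)] * self.n_load
        b += [(_THETA_FLOOR, None)] * self.n_theta
        b += [(-0.999, 0.999)] * self.n_off
        b += [(1e-8, None)] * len(self.phi_diag)
        return b


def implied_covariance(params: Parameters, spec: ModelSpec) -> np.ndarray:
    """Model-implied covariance of the observed variables (items first,
    covariate last when present)."""
    params.validate(spec)
    st = _Structure(spec)
    eig = np.linalg.eigvalsh(params.phi)
    if eig.min() <= 0:
        raise ValueError("factor correlation matrix is not positive definite")
    return st.sigma(st.pack(params))


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    spec: ModelSpec
    params: Parameters
    T_ml: float
    df: int
    loglik: float
    N: int
    converged: bool
    n_iter: int
    F_min: float
    c: float | None = None           # Satorra-Bentler scaling factor
    T_sb: float | None = None
    se: Parameters | None = None     # robust (sandwich) standard errors
    std_lam: np.ndarray | None = None
    std_beta: np.ndarray | None = None
    se_std_lam: np.ndarray | None = None
    se_std_beta: np.ndarray | None = None
    cfi: float | None = None
    tli: float | None = None
    rmsea: float | None = None
    rmsea_ci: tuple[float, float] | None = None
    bic: float | None = None
    acov: np.ndarray | None = field(default=None, repr=False)
    _theta_hat: np.ndarray | None = field(default=None, repr=False)

    @property
    def T_robust(self) -> float:
        return self.T_sb if self.T_sb is not None else self.T_ml

    def parameter_table(self) -> pd.DataFrame:
        spec = self.spec
        rows = []
        for i, item in enumerate(spec.items):
            row = {"item": item, "factor": spec.loading[item],
                   "loading": self.params.lam[i],
                   "residual_var": self.params.theta[i]}
            if self.std_lam is not None:
                row["std_loading"] = self.std_lam[i]
            if self.se is not None:
                row["se_loading"] = self.se.lam[i]
            if self.params.beta is not None:
                row["beta"] = self.params.beta[i]
                if self.std_beta is not None:
                    row["std_beta"] = self.std_beta[i]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _fml(S: np.ndarray, sigma: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return logdet + float(np.trace(np.linalg.solve(sigma, S))) \
        - logdet_s - S.shape[0]


def fit_ml(moments: SampleMoments, spec: ModelSpec,
           gtol: float = 1e-8, max_iter: int = 500) -> FitResult:
    """Minimize F_ML for a spec; returns the unadjusted ML solution.

    T_ml = (N - 1) * F_ML at the optimum.  Residual variances are bounded
    below at 1e-6; an active bound (Heywood case) raises a warning.
    """
    names = spec.observed_variables
    if tuple(moments.variable_names) != tuple(names):
        moments = moments.subset(names)
    S = moments.S
    p = S.shape[0]
    if moments.N <= p:
        raise ValueError("need N greater than the number of variables")
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    st = _Structure(spec)
    if st.df < 0:
        degrees_of_freedom(spec)  # raises the descriptive error

    def fungrad(t):
        lam, phi, theta = st.unpack(t)
        sigma = lam @ phi @ lam.T + np.diag(theta)
        try:
            cf = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(t)
        sig_inv = np.linalg.inv(sigma)
        logdet = 2.0 * float(np.log(np.diag(cf)).sum())
        f = logdet + float((sig_inv * S).sum()) - logdet_s - p
        a = sig_inv - sig_inv @ S @ sig_inv
        g_mat = a @ lam           # p x M
        gphi = g_mat @ phi        # p x M
        h = lam.T @ g_mat         # M x M
        grad = np.empty(st.nq)
        pos = 0
        for (i, f_) in st.free_load:
            grad[pos] = 2.0 * gphi[i, f_]
            pos += 1
        grad[pos:pos + st.n_theta] = np.diag(a)[st.theta_idx]
        pos += st.n_theta
        for (a_, b_) in st.phi_off:
            grad[pos] = 2.0 * h[a_, b_]
            pos += 1
        for a_ in st.phi_diag:
            grad[pos] = h[a_, a_]
            pos += 1
        return f, grad

    t0 = st.start(S)
    res = optimize.minimize(
        fungrad, t0, jac=True, method="L-BFGS-B", bounds=st.bounds(),
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12,
                 "maxcor": 30})
    if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-3:
        raise ConvergenceError(
            f"optimizer failed for {spec.name!r}: {res.message}")
    theta_hat = res.x
    _, _, th = st.unpack(theta_hat)
    if np.any(th[st.theta_idx] <= _THETA_FLOOR * 1.01):
        warnings.warn(
            f"Heywood case in {spec.name!r}: residual variance at lower "
            "bound", HeywoodWarning, stacklevel=2)
    f_min = max(float(res.fun), 0.0)
    n = moments.N
    t_ml = (n - 1) * f_min
    s_ml = S * (n - 1) / n
    sigma_hat = st.sigma(theta_hat)
    loglik = -0.5 * n * (p * np.log(2 * np.pi)
                         + np.linalg.slogdet(sigma_hat)[1]
                         + float(np.trace(np.linalg.solve(sigma_hat, s_ml))))
    return FitResult(
        spec=spec, params=st.to_parameters(theta_hat), T_ml=t_ml, df=st.df,
        loglik=float(loglik), N=n, converged=bool(res.success),
        n_iter=int(res.nit), F_min=f_min, _theta_hat=theta_hat)


def _weight_matrix(sigma: np.ndarray) -> np.ndarray:
    p = sigma.shape[0]
    d = duplication_matrix(p)
    sig_inv = np.linalg.inv(sigma)
    return 0.5 * d.T @ np.kron(sig_inv, sig_inv) @ d


def _delta_matrix(st: _Structure, theta_hat: np.ndarray) -> np.ndarray:
    p = st.p
    rows, cols = np.tril_indices(p)
    ds = st.dsigma(theta_hat)
    return np.column_stack([d[rows, cols] for d in ds])


def satorra_bentler(moments: SampleMoments, fit: FitResult) -> FitResult:
    """Attach the mean-adjusted scaling factor c and T_sb = T_ml / c.

    c = tr(U Gamma) / df with U the normal-theory residual weight matrix at
    the optimum and Gamma the distribution-free fourth-moment estimate.
    """
    if fit.df == 0:
        raise ValueError("scaling factor undefined for a saturated model")
    names = fit.spec.observed_variables
    if tuple(moments.variable_names) != tuple(names):
        moments = moments.subset(names)
    st = _Structure(fit.spec)
    sigma_hat = st.sigma(fit._theta_hat)
    v = _weight_matrix(sigma_hat)
    delta = _delta_matrix(st, fit._theta_hat)
    vd = v @ delta
    bread = np.linalg.inv(delta.T @ vd)
    u = v - vd @ bread @ vd.T
    gamma = moments.gamma()
    c = float(np.trace(u @ gamma)) / fit.df
    if c <= 0:
        warnings.warn("nonpositive scaling factor; falling back to c=1",
                      stacklevel=2)
        c = 1.0
    fit.c = c
    fit.T_sb = fit.T_ml / c
    return fit


def robust_se(moments: SampleMoments, fit: FitResult) -> FitResult:
    """Sandwich standard errors and delta-method standardized solution."""
    names = fit.spec.observed_variables
    if tuple(moments.variable_names) != tuple(names):
        moments = moments.subset(names)
    st = _Structure(fit.spec)
    sigma_hat = st.sigma(fit._theta_hat)
    v = _weight_matrix(sigma_hat)
    delta = _delta_matrix(st, fit._theta_hat)
    vd = v @ delta
    bread = np.linalg.inv(delta.T @ vd)
    gamma = moments.gamma()
    acov = bread @ (vd.T @ gamma @ vd) @ bread / moments.N
    fit.acov = acov
    se_vec = np.sqrt(np.maximum(np.diag(acov), 0.0))
    fit.se = st.to_parameters(se_vec)
    # to_parameters copies positions, not a covariance; phi/psi entries of
    # `se` hold the SEs of the corresponding free elements
    fit.se.phi = _se_phi_matrix(st, se_vec)
    if st.phi_diag:
        fit.se.psi = float(se_vec[st.nq - 1])

    # standardized loadings / covariate paths with delta-method SEs
    k = fit.spec.n_items

    def std_map(t):
        lam, phi, _ = st.unpack(t)
        sig = st.sigma(t)
        sd = np.sqrt(np.diag(sig))
        out = [lam[i, f] / sd[i] for (i, f) in st.free_load[:k]]
        if st.has_cov:
            psi = phi[st.M - 1, st.M - 1]
            out += [lam[i, st.M - 1] * np.sqrt(psi) / sd[i]
                    for i in range(k)]
        return np.array(out)

    base = std_map(fit._theta_hat)
    jac = np.empty((base.size, st.nq))
    eps = 1e-6
    for j in range(st.nq):
        tp = fit._theta_hat.copy()
        tp[j] += eps
        jac[:, j] = (std_map(tp) - base) / eps
    cov_std = jac @ acov @ jac.T
    se_std = np.sqrt(np.maximum(np.diag(cov_std), 0.0))
    fit.std_lam = base[:k]
    fit.se_std_lam = se_std[:k]
    if st.has_cov:
        fit.std_beta = base[k:2 * k]
        fit.se_std_beta = se_std[k:2 * k]
    return fit


def _se_phi_matrix(st: _Structure, se_vec: np.ndarray) -> np.ndarray:
    m = st.spec.n_factors
    out = np.zeros((m, m))
    pos = st.n_load + st.n_theta
    for (a, b) in st.phi_off:
        out[a, b] = out[b, a] = se_vec[pos]
        pos += 1
    return out


# ---------------------------------------------------------------------------
# Baseline model and fit indices
# ---------------------------------------------------------------------------

def baseline_statistics(moments: SampleMoments, robust: bool = True):
    """Independence-model chi-square (variances only), df = p(p-1)/2.

    Returns (T_baseline, df_baseline) where T is the Satorra-Bentler
    adjusted statistic when robust raw data are available.
    """
    S = moments.S
    p = S.shape[0]
    n = moments.N
    t_b = (n - 1) * float(np.log(np.diag(S)).sum() - np.linalg.slogdet(S)[1])
    df_b = p * (p - 1) // 2
    if robust and moments.data is not None:
        sigma0 = np.diag(np.diag(S))
        v = _weight_matrix(sigma0)
        rows, cols = np.tril_indices(p)
        delta = np.zeros((len(rows), p))
        for j in range(p):
            d = np.zeros((p, p))
            d[j, j] = 1.0
            delta[:, j] = d[rows, cols]
        vd = v @ delta
        u = v - vd @ np.linalg.inv(delta.T @ vd) @ vd.T
        c_b = float(np.trace(u @ moments.gamma())) / df_b
        if c_b > 0:
            t_b = t_b / c_b
    return t_b, df_b


def rmsea_ci(t: float, df: int, n: int, level: float = 0.90):
    """Noncentral-chi-square confidence interval for RMSEA."""

    def ncp_for(prob):
        # find lambda with ncx2.cdf(t; df, lambda) = prob
        f = lambda lam: stats.ncx2.cdf(t, df, lam) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(t, 1.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e7:
                break
        return optimize.brentq(f, 0.0, hi)

    alpha = (1.0 - level) / 2.0
    lo = ncp_for(1.0 - alpha)
    hi = ncp_for(alpha)
    return (np.sqrt(lo / (df * n)), np.sqrt(hi / (df * n)))


def fit_indices(fit: FitResult, moments: SampleMoments,
                robust: bool = True) -> FitResult:
    """CFI, TLI, RMSEA (with 90% CI) and BIC.

    Indices use the robust statistic for both target and baseline model
    when available; RMSEA uses N in the denominator.  BIC is on the
    standard -2 loglik + q ln N scale.
    """
    names = fit.spec.observed_variables
    if tuple(moments.variable_names) != tuple(names):
        moments = moments.subset(names)
    t = fit.T_robust if robust else fit.T_ml
    df = fit.df
    n = fit.N
    t_b, df_b = baseline_statistics(moments, robust=robust)
    if df_b <= 0:
        raise ValueError("baseline df must be positive")
    num = max(t - df, 0.0)
    den = max(t_b - df_b, t - df, 0.0)
    fit.cfi = 1.0 - (num / den if den > 0 else 0.0)
    rb = t_b / df_b
    fit.tli = ((rb - t / df) / (rb - 1.0)) if df > 0 else np.nan
    fit.rmsea = float(np.sqrt(max(t - df, 0.0) / (df * n))) if df > 0 else 0.0
    fit.rmsea_ci = rmsea_ci(t, df, n) if df > 0 else (0.0, 0.0)
    q = count_free_parameters(fit.spec) + len(names)  # + saturated means
    fit.bic = -2.0 * fit.loglik + q * np.log(n)
    return fit


def fit(moments: SampleMoments, spec: ModelSpec, robust: bool = True,
        se: bool = False, indices: bool = True, **kw) -> FitResult:
    """Fit a spec end to end: ML estimate, S-B adjustment, indices, SEs."""
    result = fit_ml(moments, spec, **kw)
    if robust and moments.data is not None and result.df > 0:
        satorra_bentler(moments, result)
    if indices:
        fit_indices(result, moments, robust=robust)
    if se and moments.data is not None:
        robust_se(moments, result)
    return result


def fit_table(fits) -> pd.DataFrame:
    """Goodness-of-fit summary, one row per fitted model."""
    rows = []
    for f in fits:
        rows.append({
            "model": f.spec.name, "T_sb": f.T_robust, "df": f.df,
            "scaling_c": f.c, "CFI": f.cfi, "TLI": f.tli,
            "RMSEA": f.rmsea,
            "RMSEA_lo": None if f.rmsea_ci is None else f.rmsea_ci[0],
            "RMSEA_hi": None if f.rmsea_ci is None else f.rmsea_ci[1],
            "BIC": f.bic, "converged": f.converged,
        })
    return pd.DataFrame(rows)
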