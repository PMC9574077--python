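"""Fixed-effects spatial Durbin panel model, effects, and test battery.

Model, for n spatial units observed over T periods:

    y_t = rho W y_t + X_t beta + (W X_t) eta + mu + v_t 1 + e_t

with W a row-standardized contiguity matrix, mu unit fixed effects, v_t time
fixed effects, and spherical errors.  Estimation is by maximum likelihood
after the two-way within transformation (demeaning by unit and period): the
spatial autoregressive coefficient rho is concentrated out and found by
derivative-free search over the invertibility interval of (I - rho W), with
the coefficients and error variance profiled out by least squares at each
rho.  The log-determinant term T * log|I - rho W| is evaluated from the
eigenvalues of W, computed once.

Marginal effects: the reduced form y = (I - rho W)^-1 (X beta + WX eta + ...)
makes the impact of covariate r the n x n matrix

    S_r(W) = (I - rho W)^-1 (I beta_r + W eta_r)

whose average diagonal is the direct effect, average overall element the
total effect, and difference the indirect (spillover) effect.  Dispersion of
the effects comes from seeded draws from the asymptotic normal of
(rho, beta, eta).

Also provided: the Lagrange-multiplier battery (LM and robust LM for spatial
lag / spatial error on the non-spatial within residuals), likelihood-ratio
and Wald tests of whether the Durbin terms can be reduced to a pure lag or
pure error model, and the classical panel Hausman test of fixed versus
random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .spatial import SpatialWeights

__all__ = [
    "SpatialDurbinFE",
    "SpatialErrorFE",
    "fit_sdm",
    "effects_decomposition",
    "lm_tests",
    "lr_wald_tests",
    "hausman_test",
    "panel_hausman",
]


# ---------------------------------------------------------------- helpers

def _as_panel(y, X, n: int):
    """Coerce y -> (T, n) and X -> (T, n, k), period-major."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim == 1:
        if y.size % n:
            raise ValueError("length of y is not a multiple of n units")
        y = y.reshape(-1, n)
    T = y.shape[0]
    if X.ndim == 2:
        X = X.reshape(T, n, -1)
    if X.shape[:2] != (T, n):
        raise ValueError(f"X must be (T={T}, n={n}, k); got {X.shape}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("y and X must be finite (log-transform before fit)")
    return y, X, T


def _within_twoway(a: np.ndarray) -> np.ndarray:
    """Two-way demeaning over axes (period, unit); idempotent."""
    return (a - a.mean(axis=0, keepdims=True)
            - a.mean(axis=1, keepdims=True)
            + a.mean(axis=(0, 1), keepdims=True))


def _spatial_lag(a: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Apply W to the unit axis of a (T, n) or (T, n, k) array."""
    if a.ndim == 2:
        return a @ W.T
    return np.einsum("ij,tjk->tik", W, a)


def _real_eigs(W: np.ndarray) -> np.ndarray:
    eigs = np.linalg.eigvals(W)
    if np.max(np.abs(eigs.imag)) > 1e-8:
        # possible for genuinely asymmetric weights; the log-determinant
        # below then uses the complex product's real logarithm
        return eigs
    return eigs.real


def _logdet(rho: float, eigs: np.ndarray) -> float:
    vals = 1.0 - rho * eigs
    if np.iscomplexobj(vals):
        return float(np.log(vals).sum().real)
    if np.any(vals <= 0):
        return -np.inf
    return float(np.log(vals).sum())


# ---------------------------------------------------------------- SDM / SLM

class SpatialDurbinFE:
    """Two-way fixed-effects spatial Durbin (or spatial lag) estimator.

    Parameters
    ----------
    weights : SpatialWeights (row-standardized).
    durbin : include the spatially lagged covariates WX (eta); with
        ``durbin=False`` this is the plain spatial lag (SAR) panel model.
    bias_correction : apply the lost-degrees-of-freedom correction to the
        error variance, sigma2 * nT / ((n-1)(T-1)), after the within
        transformation (Lee-Yu style); recorded in ``meta_``.
    rho_interval : search interval for rho, intersected with the
        invertibility interval implied by the eigenvalues of W.

    Fitted attributes: ``rho_``, ``beta_``, ``eta_`` (None when
    ``durbin=False``), ``sigma2_``, ``loglik_``, ``vcov_`` (over
    (rho, beta[, eta])), ``residuals_``, ``converged_``, ``meta_``.
    """

    def __init__(self, weights: SpatialWeights, durbin: bool = True,
                 bias_correction: bool = True,
                 rho_interval: tuple = (-0.999, 0.999)):
        self.weights = weights
        self.durbin = durbin
        self.bias_correction = bias_correction
        self.rho_interval = rho_interval

    def get_params(self, deep: bool = True) -> dict:
        return {"weights": self.weights, "durbin": self.durbin,
                "bias_correction": self.bias_correction,
                "rho_interval": self.rho_interval}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _interval(self, eigs) -> tuple[float, float]:
        lo, hi = self.rho_interval
        re = eigs.real if np.iscomplexobj(eigs) else eigs
        emin, emax = re.min(), re.max()
        if emin < 0:
            lo = max(lo, 1.0 / emin + 1e-9)
        if emax > 0:
            hi = min(hi, 1.0 / emax - 1e-9)
        return lo, hi

    def fit(self, X, y):
        """Fit by concentrated ML.  X is (T, n, k) or (nT, k) period-major."""
        if not self.weights.standardized:
            raise ValueError("weights must be row-standardized")
        W = self.weights.matrix
        n = self.weights.n
        y, X, T = _as_panel(y, X, n)
        if T < 2 or n < 3:
            raise ValueError("need T >= 2 periods and n >= 3 units")
        k = X.shape[2]

        Xfull = np.concatenate([X, _spatial_lag(X, W)], axis=2) if self.durbin else X
        p = Xfull.shape[2]
        yt = _within_twoway(y)
        Wyt = _within_twoway(_spatial_lag(y, W))
        Xt = _within_twoway(Xfull)

        yv = yt.ravel()
        wyv = Wyt.ravel()
        Xv = Xt.reshape(T * n, p)
        XtX = Xv.T @ Xv
        if np.linalg.cond(XtX) > 1e12:
            raise np.linalg.LinAlgError(
                "singular regressor cross-product: collinear covariates "
                "(after within transformation)"
            )
        XtX_inv = np.linalg.inv(XtX)
        by = XtX_inv @ (Xv.T @ yv)
        bw = XtX_inv @ (Xv.T @ wyv)
        e0 = yv - Xv @ by       # residuals of y on X
        ew = wyv - Xv @ bw      # residuals of Wy on X
        N = n * T
        eigs = self._real_eigs_cache = _real_eigs(W)
        lo, hi = self._interval(eigs)

        def negll(rho: float) -> float:
            e = e0 - rho * ew
            s2 = (e @ e) / N
            return 0.5 * N * np.log(s2) - T * _logdet(rho, eigs)

        opt = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        rho = float(opt.x)
        boundary = min(rho - lo, hi - rho) < 1e-6
        delta = by - rho * bw
        e = (e0 - rho * ew)
        s2_ml = float(e @ e) / N
        df_corr = N / ((n - 1) * (T - 1))
        s2 = s2_ml * df_corr if self.bias_correction else s2_ml
        loglik = (-0.5 * N * (np.log(2 * np.pi * s2_ml) + 1)
                  + T * _logdet(rho, eigs))

        self.rho_ = rho
        self.beta_ = delta[:k]
        self.eta_ = delta[k:] if self.durbin else None
        self.coef_ = delta
        self.sigma2_ = s2
        self.sigma2_ml_ = s2_ml
        self.loglik_ = float(loglik)
        self.residuals_ = e.reshape(T, n)
        self.converged_ = bool(opt.success) and not boundary
        self.rho_at_boundary_ = boundary
        self.n_, self.T_, self.k_ = n, T, k
        self._Xv, self._yv = Xv, yv
        self.vcov_ = self._information_vcov(W, Xv, delta, rho, s2, n, T)
        self.meta_ = {
            "bias_correction": self.bias_correction,
            "durbin": self.durbin,
            "rho_interval_used": (lo, hi),
            "effects_absorbed": {"individual": True, "time": True},
        }
        if boundary:
            self.meta_["warning"] = "rho search hit the interval boundary"
        return self

    def _information_vcov(self, W, Xv, delta, rho, s2, n, T):
        """Analytic information matrix for (rho, coef); inverse returned.

        Parameter order of the returned matrix: (rho, beta[, eta]).
        """
        A = np.eye(n) - rho * W
        G = W @ np.linalg.inv(A)
        p = Xv.shape[1]
        Xb = (Xv @ delta).reshape(T, n)
        GXb = Xb @ G.T
        gxb = GXb.ravel()

        I = np.zeros((p + 2, p + 2))  # order: coef (p), rho, sigma2
        I[:p, :p] = Xv.T @ Xv / s2
        I[:p, p] = Xv.T @ gxb / s2
        I[p, :p] = I[:p, p]
        I[p, p] = T * (np.trace(G @ G) + np.trace(G.T @ G)) + (gxb @ gxb) / s2
        I[p, p + 1] = T * np.trace(G) / s2
        I[p + 1, p] = I[p, p + 1]
        I[p + 1, p + 1] = n * T / (2 * s2 * s2)
        V = np.linalg.inv(I)
        # reorder to (rho, coef), dropping sigma2
        order = [p] + list(range(p))
        V = V[np.ix_(order, order)]
        return 0.5 * (V + V.T)

    @property
    def bse_(self) -> np.ndarray:
        """Standard errors in (rho, beta[, eta]) order."""
        return np.sqrt(np.diag(self.vcov_))

    def summary_frame(self, names=None) -> pd.DataFrame:
        k = self.k_
        labels = list(names) if names is not None else [f"x{i+1}" for i in range(k)]
        rows = [f"rho"] + labels + ([f"W*{c}" for c in labels] if self.durbin else [])
        est = np.concatenate([[self.rho_], self.coef_])
        se = self.bse_
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        ci = stats.norm.ppf(0.975) * se
        return pd.DataFrame({
            "coefficient": est, "std_err": se, "z": z, "p_value": p,
            "ci_low": est - ci, "ci_high": est + ci,
        }, index=rows)


def fit_sdm(X, y, weights: SpatialWeights, durbin: bool = True,
            bias_correction: bool = True) -> SpatialDurbinFE:
    """Convenience wrapper over :class:`SpatialDurbinFE`."""
    return SpatialDurbinFE(weights, durbin=durbin,
                           bias_correction=bias_correction).fit(X, y)


# ---------------------------------------------------------------- SEM

class SpatialErrorFE:
    """Two-way fixed-effects spatial error model (ML), for the LR battery.

    y_t = X_t beta + u_t,  u_t = lambda W u_t + e_t.
    """

    def __init__(self, weights: SpatialWeights,
                 lambda_interval: tuple = (-0.999, 0.999)):
        self.weights = weights
        self.lambda_interval = lambda_interval

    def fit(self, X, y):
        W = self.weights.matrix
        n = self.weights.n
        y, X, T = _as_panel(y, X, n)
        k = X.shape[2]
        yt = _within_twoway(y)
        Xt = _within_twoway(X)
        eigs = _real_eigs(W)
        re = eigs.real if np.iscomplexobj(eigs) else eigs
        lo = max(self.lambda_interval[0],
                 1.0 / re.min() + 1e-9 if re.min() < 0 else self.lambda_interval[0])
        hi = min(self.lambda_interval[1],
                 1.0 / re.max() - 1e-9 if re.max() > 0 else self.lambda_interval[1])
        N = n * T

        def profile(lam: float):
            B = np.eye(n) - lam * W
            ys = yt @ B.T
            Xs = np.einsum("ij,tjk->tik", B, Xt)
            Xv = Xs.reshape(N, k)
            yv = ys.ravel()
            b, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
            e = yv - Xv @ b
            s2 = (e @ e) / N
            return b, e, s2

        def negll(lam: float) -> float:
            _, _, s2 = profile(lam)
            return 0.5 * N * np.log(s2) - T * _logdet(lam, eigs)

        opt = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        lam = float(opt.x)
        b, e, s2 = profile(lam)
        self.lambda_ = lam
        self.beta_ = b
        self.sigma2_ = float(s2)
        self.loglik_ = float(-0.5 * N * (np.log(2 * np.pi * s2) + 1)
                             + T * _logdet(lam, eigs))
        self.converged_ = bool(opt.success)
        self.n_, self.T_, self.k_ = n, T, k
        return self


# ---------------------------------------------------------------- effects

def effects_decomposition(fit: SpatialDurbinFE, n_draws: int = 1000,
                          seed: int | None = None,
                          names=None) -> pd.DataFrame:
    """Direct / indirect / total marginal effects with simulation dispersion.

    Point estimates come from S_r(W) = (I - rho W)^-1 (I beta_r + W eta_r):
    direct = mean diagonal, total = mean element, indirect = total - direct
    (the additivity direct + indirect = total is exact by construction).
    Standard errors and z come from ``n_draws`` seeded draws of
    (rho, beta, eta) from the fit's asymptotic normal.
    """
    if not getattr(fit, "converged_", False):
        raise ValueError("effects require a converged fit")
    W = fit.weights.matrix
    n = fit.n_
    k = fit.k_
    labels = list(names) if names is not None else [f"x{i+1}" for i in range(k)]

    def point(rho, beta, eta):
        Ainv = np.linalg.inv(np.eye(n) - rho * W)
        direct = np.empty(k)
        total = np.empty(k)
        for r in range(k):
            S = Ainv * beta[r] + Ainv @ (W * eta[r])
            direct[r] = np.trace(S) / n
            total[r] = S.sum() / n
        return direct, total - direct, total

    eta = fit.eta_ if fit.eta_ is not None else np.zeros(k)
    d0, i0, t0 = point(fit.rho_, fit.beta_, eta)

    mean = np.concatenate([[fit.rho_], fit.beta_, eta])
    V = fit.vcov_
    if fit.eta_ is None:
        V = np.pad(V, ((0, k), (0, k)))
    # guard against tiny asymmetry / negative eigenvalues in the draw cov
    evals, evecs = np.linalg.eigh(0.5 * (V + V.T))
    L = evecs * np.sqrt(np.clip(evals, 0, None))
    rng = np.random.default_rng(seed)
    draws = mean + rng.standard_normal((n_draws, mean.size)) @ L.T

    sims = np.empty((n_draws, 3, k))
    for b in range(n_draws):
        rho_b = np.clip(draws[b, 0], -0.999, 0.999)
        sims[b] = point(rho_b, draws[b, 1:k + 1], draws[b, k + 1:])
    se = sims.std(axis=0, ddof=1)

    out = pd.DataFrame({
        "direct": d0, "indirect": i0, "total": t0,
        "direct_se": se[0], "indirect_se": se[1], "total_se": se[2],
        "direct_z": d0 / se[0], "indirect_z": i0 / se[1], "total_z": t0 / se[2],
    }, index=labels)
    out.attrs["n_draws"] = n_draws
    out.attrs["seed"] = seed
    return out


# ---------------------------------------------------------------- LM tests

def lm_tests(X, y, weights: SpatialWeights) -> dict:
    """Anselin LM and robust-LM statistics for spatial lag vs spatial error.

    Computed on the residuals of the non-spatial two-way within regression.
    Returns a dict of name -> (statistic, p_value); each statistic is
    chi-square with 1 degree of freedom under its null.
    """
    W = weights.matrix
    n = weights.n
    y, X, T = _as_panel(y, X, n)
    k = X.shape[2]
    yt = _within_twoway(y)
    Xt = _within_twoway(X)
    N = n * T
    Xv = Xt.reshape(N, k)
    yv = yt.ravel()
    b, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
    e = yv - Xv @ b
    # df-corrected variance: the within transformation absorbs n-1 unit and
    # T-1 period means, and the ML-style e'e/N over-rejects in finite panels
    df = N - k - (n - 1) - (T - 1) - 1
    s2 = float(e @ e) / df
    if s2 <= 0 or df <= 0:
        raise ValueError("degenerate residual variance")

    We = (e.reshape(T, n) @ W.T).ravel()
    Wy = (yt @ W.T).ravel()
    d_e = float(e @ We) / s2
    d_y = float(e @ Wy) / s2
    T1 = T * float(np.trace(W.T @ W + W @ W))

    fitted = (Xv @ b).reshape(T, n)
    Wf = (fitted @ W.T).ravel()
    resid_Wf = Wf - Xv @ np.linalg.lstsq(Xv, Wf, rcond=None)[0]
    J = float(resid_Wf @ resid_Wf) / s2 + T1

    lm_lag = d_y ** 2 / J
    lm_err = d_e ** 2 / T1
    r_lag = (d_y - d_e) ** 2 / (J - T1)
    r_err = (d_e - (T1 / J) * d_y) ** 2 / (T1 * (1 - T1 / J))
    chi2 = stats.chi2(df=1)
    return {
        name: (float(val), float(chi2.sf(val)))
        for name, val in [
            ("lm_error", lm_err), ("robust_lm_error", r_err),
            ("lm_lag", lm_lag), ("robust_lm_lag", r_lag),
        ]
    }


# ---------------------------------------------------------------- LR / Wald

def lr_wald_tests(full: SpatialDurbinFE, X, y) -> dict:
    """Can the Durbin model be reduced to a pure lag or pure error model?

    * lag direction: H0 eta = 0 (reduces to the spatial lag model);
    * error direction: H0 eta + rho * beta = 0 (reduces to the error model,
      the common-factor restriction).

    LR statistics refit the restricted models by ML; Wald statistics use the
    delta method on the full fit.  All are chi-square with k degrees of
    freedom.  A restricted likelihood above the full one is flagged instead
    of silently truncated.
    """
    if full.eta_ is None:
        raise ValueError("lr_wald_tests requires a Durbin fit (eta present)")
    k = full.k_
    chi2 = stats.chi2(df=k)

    slm = SpatialDurbinFE(full.weights, durbin=False,
                          bias_correction=full.bias_correction).fit(X, y)
    sem = SpatialErrorFE(full.weights).fit(X, y)
    out: dict = {"df": k}
    for name, restricted_ll in (("lr_lag", slm.loglik_),
                                ("lr_error", sem.loglik_)):
        lr = 2.0 * (full.loglik_ - restricted_ll)
        flag = lr < 0
        out[name] = (float(max(lr, 0.0)), float(chi2.sf(max(lr, 0.0))))
        if flag:
            out[f"{name}_nonconvergence"] = True

    V = full.vcov_  # (rho, beta, eta)
    rho, beta, eta = full.rho_, full.beta_, full.eta_
    # Wald lag: eta = 0
    Veta = V[1 + k:, 1 + k:]
    w_lag = float(eta @ np.linalg.solve(Veta, eta))
    out["wald_lag"] = (w_lag, float(chi2.sf(w_lag)))
    # Wald error: g = eta + rho * beta = 0; grad rows over (rho, beta, eta)
    g = eta + rho * beta
    G = np.hstack([beta[:, None], rho * np.eye(k), np.eye(k)])
    Vg = G @ V @ G.T
    w_err = float(g @ np.linalg.solve(Vg, g))
    out["wald_error"] = (w_err, float(chi2.sf(w_err)))
    return out


# ---------------------------------------------------------------- Hausman

def hausman_test(b_fe, V_fe, b_re, V_re):
    """Classical Hausman statistic H = d'(V_FE - V_RE)^-1 d, df = k.

    Returns ``(statistic, df, p_value, used_pinv)``.  A non-positive-definite
    covariance difference falls back to the Moore-Penrose inverse.
    """
    b_fe, b_re = np.asarray(b_fe, float), np.asarray(b_re, float)
    if b_fe.shape != b_re.shape:
        raise ValueError("estimate vectors have mismatched dimensions")
    d = b_fe - b_re
    dV = np.asarray(V_fe, float) - np.asarray(V_re, float)
    used_pinv = False
    try:
        np.linalg.cholesky(dV)
        stat = float(d @ np.linalg.solve(dV, d))
    except np.linalg.LinAlgError:
        used_pinv = True
        stat = float(d @ np.linalg.pinv(dV) @ d)
    stat = max(stat, 0.0)
    df = d.size
    return stat, df, float(stats.chi2(df=df).sf(stat)), used_pinv


def panel_hausman(X, y, n: int) -> dict:
    """Fixed- vs random-effects Hausman test for a one-way panel.

    Within (unit-demeaned) OLS against Swamy-Arora feasible GLS, comparing
    the common slope vector.  This is the classical (non-spatial) variant;
    the result dict records that explicitly.
    """
    y, X, T = _as_panel(y, X, n)
    k = X.shape[2]
    N = n * T

    # within estimator (unit demeaning)
    yw = (y - y.mean(axis=0, keepdims=True)).ravel()
    Xw = (X - X.mean(axis=0, keepdims=True)).reshape(N, k)
    XwtXw_inv = np.linalg.inv(Xw.T @ Xw)
    b_fe = XwtXw_inv @ (Xw.T @ yw)
    rss_w = float(np.sum((yw - Xw @ b_fe) ** 2))
    s2_e = rss_w / (n * (T - 1) - k)
    V_fe = s2_e * XwtXw_inv

    # between regression on unit means (with intercept)
    yb = y.mean(axis=0)
    Xb = np.column_stack([np.ones(n), X.mean(axis=0)])
    bb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    rss_b = float(np.sum((yb - Xb @ bb) ** 2))
    s2_1 = rss_b / max(n - k - 1, 1)
    s2_u = max(0.0, s2_1 - s2_e / T)

    theta = 1.0 - np.sqrt(s2_e / (s2_e + T * s2_u))
    yq = (y - theta * y.mean(axis=0, keepdims=True)).ravel()
    Xq = np.concatenate(
        [np.full((T, n, 1), 1.0 - theta), X - theta * X.mean(axis=0, keepdims=True)],
        axis=2).reshape(N, k + 1)
    XqtXq_inv = np.linalg.inv(Xq.T @ Xq)
    b_re_full = XqtXq_inv @ (Xq.T @ yq)
    # GLS whitens the composite error to variance sigma_e^2 by construction;
    # using the (alternative-inflated) RE residuals here would break the
    # positive-definiteness of V_FE - V_RE exactly when it matters
    V_re_full = s2_e * XqtXq_inv

    stat, df, p, used_pinv = hausman_test(
        b_fe, V_fe, b_re_full[1:], V_re_full[1:, 1:])
    return {"statistic": stat, "df": df, "p_value": p,
            "variant": "classical", "used_pinv": used_pinv,
            "b_fe": b_fe, "b_re": b_re_full[1:]}
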