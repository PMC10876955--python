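"""Two-sample Mendelian randomisation estimators and instrument diagnostics.

Given per-instrument effects on an exposure (beta_exp, se_exp) and an outcome
(beta_out, se_out), harmonised to a common effect allele, the suite provides
the Wald ratio (single instrument), inverse-variance-weighted estimators with
fixed or multiplicative random effects, MR-Egger regression with an
unconstrained intercept, the weighted-median and weighted-mode estimators,
leave-one-out sensitivity analysis, instrument strength diagnostics (F,
I2_GX) and multivariable MR (IVW / Egger / weighted-median / LASSO with
conditional F-statistics).

Standard-error convention: the multiplicative random-effects (MRE) residual
scale sigma-hat = sqrt(Q/(k-1)) is NOT floored at 1, so MRE standard errors
can be smaller than fixed-effects ones when the instruments are
under-dispersed (sigma-hat < 1).  A ``floor_sigma`` switch restores the
floored variant for comparison.  The same convention applies to the Egger
residual scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import z_to_p

Z95 = stats.norm.ppf(0.975)


@dataclass
class IVSet:
    """Harmonised exposure/outcome effect quadruples for a set of instruments."""

    iv_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray | None = None

    def __post_init__(self):
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.iv_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have length {k}")
        if k == 0:
            raise ValueError("empty IV set")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be > 0")

    @property
    def k(self):
        return len(self.iv_ids)

    def drop(self, i):
        keep = np.arange(self.k) != i
        return IVSet([v for j, v in enumerate(self.iv_ids) if keep[j]],
                     self.beta_exp[keep], self.se_exp[keep],
                     self.beta_out[keep], self.se_out[keep],
                     None if self.eaf is None else self.eaf[keep])

    def oriented(self):
        """Flip instruments so every beta_exp > 0 (Egger convention)."""
        s = np.where(self.beta_exp < 0, -1.0, 1.0)
        return IVSet(self.iv_ids, self.beta_exp * s, self.se_exp,
                     self.beta_out * s, self.se_out, self.eaf)

    def ratios(self):
        """First-order Wald ratios and their variances per instrument."""
        r = self.beta_out / self.beta_exp
        v = self.se_out ** 2 / self.beta_exp ** 2
        return r, v


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    p: float
    n_iv: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
            self.ci_high = self.beta + Z95 * self.se


@dataclass
class SensitivityReport:
    q_stat: float
    p_het: float
    egger_intercept: float
    intercept_p: float
    loo_max_p: float
    mean_f: float
    i2_gx: float


def wald_ratio(ivs: IVSet) -> MrEstimate:
    """Single-instrument causal estimate beta_out/beta_exp (first-order SE)."""
    if ivs.k != 1:
        raise ValueError("wald_ratio takes exactly one instrument")
    bx, by, sy = ivs.beta_exp[0], ivs.beta_out[0], ivs.se_out[0]
    if bx == 0:
        raise ValueError("beta_exp is zero: instrument carries no information")
    beta = by / bx
    se = sy / abs(bx)
    return MrEstimate("wald", float(beta), float(se), z_to_p(beta / se), 1)


def ivw(ivs: IVSet, effects="multiplicative_random", floor_sigma=False) -> MrEstimate:
    """Inverse-variance-weighted estimate: WLS through the origin.

    beta = sum(w bx by) / sum(w bx^2) with w = 1/se_out^2; base variance
    V = 1/sum(w bx^2).  ``fixed``: se = sqrt(V).  ``multiplicative_random``:
    se = sigma_hat * sqrt(V) with sigma_hat^2 = Q/(k-1), not floored at 1
    unless ``floor_sigma``.  A single instrument delegates to the Wald ratio.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects!r}")
    if ivs.k == 1:
        est = wald_ratio(ivs)
        est.method = f"ivw_{'fe' if effects == 'fixed' else 'mre'}"
        return est
    if np.all(ivs.beta_exp == 0):
        raise ValueError("all exposure effects are zero")
    w = ivs.se_out ** -2
    sxx = (w * ivs.beta_exp ** 2).sum()
    beta = (w * ivs.beta_exp * ivs.beta_out).sum() / sxx
    v = 1.0 / sxx
    resid = ivs.beta_out - beta * ivs.beta_exp
    q = float((w * resid ** 2).sum())
    sigma2 = q / (ivs.k - 1)
    if sigma2 <= 1e-12 * (w * ivs.beta_out ** 2).sum() / (ivs.k - 1):
        sigma2 = 0.0  # ratios numerically collinear
    extra = {"q_stat": q, "q_df": ivs.k - 1,
             "p_het": float(stats.chi2.sf(q, ivs.k - 1))}
    if effects == "fixed":
        se = np.sqrt(v)
        method = "ivw_fe"
    else:
        if floor_sigma:
            sigma2 = max(sigma2, 1.0)
        se = np.sqrt(sigma2 * v)
        method = "ivw_mre"
        if sigma2 == 0:
            extra["degenerate"] = True  # perfectly collinear ratios
    p = z_to_p(beta / se) if se > 0 else 0.0
    return MrEstimate(method, float(beta), float(se), float(p), ivs.k, extra=extra)


def egger(ivs: IVSet, floor_sigma=False):
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Instruments are first oriented so beta_exp > 0; the slope estimates the
    causal effect, the intercept the average directional pleiotropy.  SEs use
    the multiplicative residual scale sigma_hat = sqrt(RSS_w/(k-2)), same
    no-floor convention as IVW-MRE.  Returns (MrEstimate, intercept,
    intercept_se, intercept_p).
    """
    if ivs.k < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    o = ivs.oriented()
    w = o.se_out ** -2
    X = np.column_stack([np.ones(o.k), o.beta_exp])
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ o.beta_out)
    resid = o.beta_out - X @ coef
    sigma2 = float((w * resid ** 2).sum() / (o.k - 2))
    if floor_sigma:
        sigma2 = max(sigma2, 1.0)
    cov = sigma2 * np.linalg.inv(xtx)
    icpt, slope = coef
    icpt_se, slope_se = np.sqrt(np.diag(cov))
    est = MrEstimate("egger", float(slope), float(slope_se),
                     z_to_p(slope / slope_se) if slope_se > 0 else 0.0, ivs.k,
                     extra={"intercept": float(icpt),
                            "intercept_se": float(icpt_se)})
    icpt_p = z_to_p(icpt / icpt_se) if icpt_se > 0 else 0.0
    est.extra["intercept_p"] = float(icpt_p)
    return est, float(icpt), float(icpt_se), float(icpt_p)


def _weighted_median(values, weights):
    """Weighted 50th percentile via linear interpolation of cumulative-weight
    midpoints (ties in values broken by position after a stable sort)."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint of each weight block
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def weighted_median(ivs: IVSet, n_boot=1000, seed=None) -> MrEstimate:
    """Weighted-median MR estimate; consistent if >= 50% of weight is valid.

    Per-IV ratios r_i = beta_out_i/beta_exp_i with first-order variances
    v_i = se_out_i^2/beta_exp_i^2; inverse-variance weights.  SE by seeded
    parametric bootstrap (resampling beta_exp and beta_out from their
    sampling distributions).  ``n_boot=0`` skips the bootstrap (se = nan).
    """
    if ivs.k < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    if 0 < n_boot < 100:
        import warnings
        warnings.warn("n_boot < 100 gives unstable bootstrap SEs")
    r, v = ivs.ratios()
    beta = _weighted_median(r, 1.0 / v)
    se = _bootstrap_se(ivs, lambda s: _weighted_median(*_ratio_w(s)),
                       n_boot, seed)
    p = z_to_p(beta / se) if se and se > 0 else np.nan
    return MrEstimate("weighted_median", float(beta), se, p, ivs.k,
                      extra={"n_boot": n_boot})


def _ratio_w(ivs):
    r, v = ivs.ratios()
    return r, 1.0 / v


def _bootstrap_se(ivs, estimator, n_boot, seed):
    if not n_boot:
        return np.nan
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(ivs.beta_exp, ivs.se_exp)
        by = rng.normal(ivs.beta_out, ivs.se_out)
        bx = np.where(bx == 0, 1e-300, bx)
        est[b] = estimator(IVSet(ivs.iv_ids, bx, ivs.se_exp, by, ivs.se_out))
    return float(est.std(ddof=1))


def _mode_of_ratios(r, w, bandwidth_factor=1.0, grid_size=512):
    """Mode of the weighted Gaussian-kernel density of ratio estimates.

    Bandwidth h = factor * 0.9 * min(sd, mad/0.6745) * k^(-1/5) (the
    modified-MAD rule with the conventional phi = 1 multiplier).
    """
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    sd = r.std(ddof=1) if r.size > 1 else 0.0
    mad = np.median(np.abs(r - np.median(r))) / 0.6745
    s = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 1e-8
    h = bandwidth_factor * 0.9 * s * r.size ** (-1 / 5)
    lo, hi = r.min() - 3 * h, r.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(ivs: IVSet, bandwidth_factor=1.0, n_boot=1000, seed=None) -> MrEstimate:
    """Weighted-mode MR estimate (mode-based estimator).

    Consistent when the largest group of instruments sharing a ratio is
    valid, even if they are a minority of the total weight.
    """
    if ivs.k < 3:
        raise ValueError("weighted mode needs >= 3 instruments")
    r, v = ivs.ratios()
    beta = _mode_of_ratios(r, 1.0 / v, bandwidth_factor)
    se = _bootstrap_se(
        ivs, lambda s: _mode_of_ratios(*_ratio_w(s), bandwidth_factor),
        n_boot, seed)
    p = z_to_p(beta / se) if se and se > 0 else np.nan
    return MrEstimate("weighted_mode", float(beta), se, p, ivs.k,
                      extra={"bandwidth_factor": bandwidth_factor,
                             "n_boot": n_boot})


def leave_one_out(ivs: IVSet):
    """IVW-MRE refits omitting each instrument in turn.

    Returns (list of (dropped_id, MrEstimate), loo_max_p).  A large
    loo_max_p flags an estimate whose significance is carried by one IV.
    """
    if ivs.k < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    fits = [(ivs.iv_ids[i], ivw(ivs.drop(i), "multiplicative_random"))
            for i in range(ivs.k)]
    loo_max_p = max(f.p for _, f in fits)
    return fits, float(loo_max_p)


def instrument_diagnostics(ivs: IVSet):
    """Instrument strength: per-IV F, mean F and the I2_GX statistic.

    f_i = (beta_exp_i / se_exp_i)^2.  I2_GX = max(0, (Q_GX - (k-1))/Q_GX)
    where Q_GX is the Cochran Q of |beta_exp| (weights 1/se_exp^2) about
    their weighted mean — the regression-dilution reliability measure used to
    judge suitability for MR-Egger (I2_GX > 0.9 recommended).
    """
    f = (ivs.beta_exp / ivs.se_exp) ** 2
    mean_f = float(f.mean())
    if ivs.k < 2:
        return mean_f, f, np.nan
    x = np.abs(ivs.beta_exp)
    w = ivs.se_exp ** -2
    xbar = (w * x).sum() / w.sum()
    q_gx = float((w * (x - xbar) ** 2).sum())
    i2 = max(0.0, (q_gx - (ivs.k - 1)) / q_gx) if q_gx > 0 else 0.0
    return mean_f, f, float(i2)


def fit_all(ivs: IVSet, n_boot=1000, seed=None):
    """All five estimators plus the sensitivity report, as the screening
    pipeline consumes them.  Returns (dict of MrEstimate, SensitivityReport)."""
    mre = ivw(ivs, "multiplicative_random")
    fe = ivw(ivs, "fixed")
    eg, icpt, icpt_se, icpt_p = egger(ivs)
    wm = weighted_median(ivs, n_boot=n_boot, seed=seed)
    wmo = weighted_mode(ivs, n_boot=n_boot, seed=None if seed is None else seed + 1)
    _, loo_max_p = leave_one_out(ivs)
    mean_f, _, i2 = instrument_diagnostics(ivs)
    sens = SensitivityReport(mre.extra["q_stat"], mre.extra["p_het"],
                             icpt, icpt_p, loo_max_p, mean_f, i2)
    return ({"ivw_mre": mre, "ivw_fe": fe, "egger": eg,
             "weighted_median": wm, "weighted_mode": wmo}, sens)


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------

def _wls(X, y, w):
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ y)
    return coef, xtx


def mvmr_fit(beta_exp, se_exp, beta_out, se_out, method="ivw",
             exposure_names=None, lasso_alpha=0.05):
    """Multivariable MR: joint causal effects of E exposures from k IVs.

    Parameters
    ----------
    beta_exp, se_exp : (k, E) arrays of per-IV exposure effects and SEs.
    beta_out, se_out : (k,) outcome effects and SEs.
    method : 'ivw' (WLS of beta_out on the exposure matrix, weights
        1/se_out^2, no intercept), 'egger' (adds an intercept after orienting
        IVs to the first exposure), 'median' (per-exposure weighted median of
        ratios after partialling out the other exposures), or 'lasso'
        (per-IV L1-penalised intercepts; the penalty is relaxed until the
        retained "valid" instruments fail a chi-square heterogeneity check at
        ``lasso_alpha``, then IVW is refit on the valid set).

    Returns a dict with per-exposure ``beta``, ``se``, ``p`` and
    ``conditional_f`` (Sanderson-style Q statistic; instruments jointly weak
    for an exposure when its conditional F is small).
    """
    X = np.atleast_2d(np.asarray(beta_exp, dtype=float))
    SX = np.atleast_2d(np.asarray(se_exp, dtype=float))
    y = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    k, E = X.shape
    if k <= E:
        raise ValueError("need more instruments than exposures")
    if np.linalg.matrix_rank(X) < E:
        raise ValueError("rank-deficient exposure matrix")
    names = list(exposure_names) if exposure_names else [f"exp{j+1}" for j in range(E)]
    w = sy ** -2

    if method == "ivw":
        coef, xtx = _wls(X, y, w)
        resid = y - X @ coef
        sigma2 = float((w * resid ** 2).sum() / (k - E))
        cov = sigma2 * np.linalg.inv(xtx)
        valid = np.ones(k, bool)
    elif method == "egger":
        s = np.where(X[:, 0] < 0, -1.0, 1.0)
        Xo, yo = X * s[:, None], y * s
        Xi = np.column_stack([np.ones(k), Xo])
        coef_i, xtx = _wls(Xi, yo, w)
        resid = yo - Xi @ coef_i
        sigma2 = float((w * resid ** 2).sum() / (k - E - 1))
        cov_full = sigma2 * np.linalg.inv(xtx)
        coef, cov = coef_i[1:], cov_full[1:, 1:]
        valid = np.ones(k, bool)
        intercept = (float(coef_i[0]), float(np.sqrt(cov_full[0, 0])))
    elif method == "median":
        out = {}
        for j in range(E):
            others = [c for c in range(E) if c != j]
            if others:
                co_y, _ = _wls(X[:, others], y, w)
                co_x, _ = _wls(X[:, others], X[:, j], w)
                ry = y - X[:, others] @ co_y
                rx = X[:, j] - X[:, others] @ co_x
            else:
                ry, rx = y, X[:, j]
            rx = np.where(rx == 0, 1e-300, rx)
            ratios = ry / rx
            wv = rx ** 2 / sy ** 2
            est = _weighted_median(ratios, wv)
            # normal-theory SE from the IVW fit as a pragmatic scale
            coef, xtx = _wls(X, y, w)
            se_j = float(np.sqrt(np.linalg.inv(xtx)[j, j]))
            out[names[j]] = {"beta": float(est), "se": se_j,
                             "p": z_to_p(est / se_j)}
        cf = _conditional_f(X, SX, sy)
        return {"method": "median", "exposures": out,
                "conditional_f": dict(zip(names, cf))}
    elif method == "lasso":
        coef, cov, valid, lam = _mvmr_lasso(X, y, w, E, lasso_alpha)
    else:
        raise ValueError(f"unknown MVMR method {method!r}")

    se = np.sqrt(np.diag(cov))
    res = {"method": method,
           "exposures": {names[j]: {"beta": float(coef[j]), "se": float(se[j]),
                                    "p": z_to_p(coef[j] / se[j])}
                         for j in range(E)},
           "conditional_f": dict(zip(names, _conditional_f(X, SX, sy))),
           "n_valid_iv": int(valid.sum())}
    if method == "egger":
        res["intercept"], res["intercept_se"] = intercept
    if method == "lasso":
        res["lambda"] = lam
        res["selection"] = "heterogeneity stopping rule (valid-set Q vs chi2 0.95)"
    return res


def _mvmr_lasso(X, y, w, E, alpha):
    """Per-IV intercept L1 path; keep the largest valid set passing Cochran Q."""
    k = X.shape[0]
    # lambda large enough that every per-IV intercept starts at zero
    coef0, _ = _wls(X, y, w)
    lam_max = 2.2 * np.max(w * np.abs(y - X @ coef0)) + 1e-12
    lam_grid = np.geomspace(lam_max, lam_max * 1e-6, 60)
    best = None
    for lam in lam_grid:
        a = np.zeros(k)
        coef = np.zeros(E)
        for _ in range(200):
            coef_new, _ = _wls(X, y - a, w)
            r = y - X @ coef_new
            thr = lam / (2 * w)
            a_new = np.sign(r) * np.maximum(np.abs(r) - thr, 0.0)
            if np.allclose(a_new, a, atol=1e-12) and np.allclose(coef_new, coef, atol=1e-12):
                coef, a = coef_new, a_new
                break
            coef, a = coef_new, a_new
        valid = a == 0
        if valid.sum() <= E:
            break
        cf, xtx = _wls(X[valid], y[valid], w[valid])
        q = float((w[valid] * (y[valid] - X[valid] @ cf) ** 2).sum())
        df = int(valid.sum()) - E
        if stats.chi2.sf(q, df) >= alpha:
            best = (cf, xtx, valid, lam)  # largest lambda whose valid set is homogeneous
            break
    if best is None:  # fall back to all-IV IVW
        cf, xtx = _wls(X, y, w)
        valid = np.ones(k, bool)
        lam = float(lam_grid[-1])
        best = (cf, xtx, valid, lam)
    cf, xtx, valid, lam = best
    resid = y[valid] - X[valid] @ cf if valid.any() else y - X @ cf
    df = max(int(valid.sum()) - E, 1)
    sigma2 = float((w[valid] * resid ** 2).sum() / df)
    cov = max(sigma2, 0.0) * np.linalg.inv(xtx)
    return cf, cov, valid, float(lam)


def _conditional_f(X, SX, sy):
    """Sanderson-style conditional F per exposure.

    Q_j = weighted residual sum of squares (weights 1/se_exp_j^2) from
    regressing exposure j's instrument effects on the other exposures';
    conditional F_j = Q_j/(k - E + 1).  Reduces to mean((beta/se)^2) for a
    single exposure.
    """
    k, E = X.shape
    out = []
    for j in range(E):
        others = [c for c in range(E) if c != j]
        wj = SX[:, j] ** -2
        if others:
            co, _ = _wls(X[:, others], X[:, j], wj)
            resid = X[:, j] - X[:, others] @ co
        else:
            resid = X[:, j]
        q = float((wj * resid ** 2).sum())
        out.append(q / (k - E + 1))
    return out
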