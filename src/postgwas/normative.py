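"""Age-conditional normative centile modelling of a biomarker.

The reference distribution of a biomarker at age t is modelled with a
location-scale family whose location and log-scale are first-order
fractional polynomials of age:

    mu(t)        = b0 + b1 * fp(t; p) + batch offsets
    log sigma(t) = c0 + c1 * fp(t; p)

with the fractional-polynomial exponent p searched over the standard set
{-2, -1, -0.5, 0, 0.5, 1, 2, 3} (p = 0 meaning log t).  Two families are
supported: plain Gaussian (``gaussian_ls``) and a Box-Cox location-scale
family (``boxcox_ls``, the Cole-Green form z = ((y/mu)^nu - 1)/(nu*sigma)
~ N(0,1)), which captures skew; family and exponent are chosen by minimum
BIC (AIC reported alongside).  Centile curves are quantile curves of the
fitted conditional distribution and cannot cross at any age because the
conditional quantile map is monotone.

Participants whose measurement lies above the model's 95th centile for
their age are called supra-normal, below the 5th infra-normal (strict
inequalities).  A split-half protocol fits the model on one half and calls
deviations on the other, then swaps, so every participant is called from a
model they did not train.  Deviation status is then related to a
standardised polygenic score by binomial logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def fp_transform(age, power):
    """First-order fractional polynomial basis; power 0 is log(age)."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("ages must be positive")
    return np.log(age) if power == 0 else age ** power


@dataclass
class CentileModel:
    family: str  # gaussian_ls | boxcox_ls
    fp_power: float
    mu_params: np.ndarray = field(repr=False)       # [b0, b1]
    sigma_params: np.ndarray = field(repr=False)    # [c0, c1] on log scale
    nu: float = 1.0                                 # Box-Cox power
    covariate_offsets: dict = field(default_factory=dict)  # batch -> mu shift
    age_range: tuple = (0.0, np.inf)
    aic: float = np.nan
    bic: float = np.nan
    loglik: float = np.nan

    def mu(self, age, batch=None):
        x = fp_transform(age, self.fp_power)
        out = self.mu_params[0] + self.mu_params[1] * x
        if batch is not None:
            off = np.vectorize(lambda b: self.covariate_offsets.get(b, 0.0))(batch)
            out = out + off
        return out

    def sigma(self, age):
        x = fp_transform(age, self.fp_power)
        return np.exp(self.sigma_params[0] + self.sigma_params[1] * x)

    def cdf(self, value, age, batch=None):
        """Model CDF of a measurement at the given age/batch (= its centile)."""
        m, s = self.mu(age, batch), self.sigma(age)
        v = np.asarray(value, dtype=float)
        if self.family == "gaussian_ls":
            return stats.norm.cdf((v - m) / s)
        z = _boxcox_z(v, m, s, self.nu)
        return stats.norm.cdf(z)

    def quantile(self, q, age, batch=None):
        """Inverse CDF; used to draw centile curves."""
        m, s = self.mu(age, batch), self.sigma(age)
        z = stats.norm.ppf(q)
        if self.family == "gaussian_ls":
            return m + z * s
        return m * np.maximum(1.0 + self.nu * s * z, 1e-12) ** (1.0 / self.nu)

    def centile_table(self, age_grid, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95),
                      batch=None):
        tab = {"age": np.asarray(age_grid, dtype=float)}
        for q in quantiles:
            tab[f"c{int(round(q * 100))}"] = self.quantile(q, age_grid, batch)
        return pd.DataFrame(tab)


def _boxcox_z(y, mu, sigma, nu):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox family needs positive values")
    r = y / mu
    if abs(nu) < 1e-8:
        return np.log(r) / sigma
    return (r ** nu - 1.0) / (nu * sigma)


def _neg_loglik(theta, x, y, B, family):
    nb = B.shape[1]
    b0, b1 = theta[0], theta[1]
    c0, c1 = theta[2], theta[3]
    off = B @ theta[4:4 + nb] if nb else 0.0
    nu = theta[4 + nb] if family == "boxcox_ls" else 1.0
    mu = b0 + b1 * x + off
    logs = np.clip(c0 + c1 * x, -20, 20)
    s = np.exp(logs)
    if family == "gaussian_ls":
        z = (y - mu) / s
        return float(0.5 * (z ** 2).sum() + logs.sum())
    if np.any(mu <= 0):
        return 1e12
    z = _boxcox_z(y, mu, s, nu)
    # Jacobian of z wrt y: y^(nu-1) / (mu^nu sigma)
    logjac = (nu - 1.0) * np.log(y) - nu * np.log(mu) - logs
    return float(0.5 * (z ** 2).sum() - logjac.sum())


def fit_centile_model(data: pd.DataFrame, family="gaussian_ls",
                      powers=FP_POWERS) -> CentileModel:
    """Maximum-likelihood fit over the candidate fractional-polynomial powers.

    ``data`` needs columns age, value and optionally batch (categorical,
    entering the location only; the first level is the reference).
    ``family='auto'`` fits both families and keeps the smaller BIC.
    """
    if family == "auto":
        fits = [fit_centile_model(data, fam, powers)
                for fam in ("gaussian_ls", "boxcox_ls")]
        return min(fits, key=lambda m: m.bic)
    if family not in ("gaussian_ls", "boxcox_ls"):
        raise ValueError(f"unknown family {family!r}")
    age = data["age"].to_numpy(dtype=float)
    y = data["value"].to_numpy(dtype=float)
    if family == "boxcox_ls" and np.any(y <= 0):
        raise ValueError("boxcox_ls requires strictly positive values; "
                         "shift the biomarker or use gaussian_ls")
    if len(data) < 100:
        warnings.warn("fewer than 100 rows: centile tails will be unstable")
    if "batch" in data.columns:
        levels = sorted(pd.unique(data["batch"]))
        B = np.column_stack([(data["batch"] == lv).to_numpy(float)
                             for lv in levels[1:]]) if len(levels) > 1 \
            else np.empty((len(data), 0))
    else:
        levels, B = [None], np.empty((len(data), 0))
    nb = B.shape[1]
    best = None
    for p in powers:
        x = fp_transform(age, p)
        # warm start: OLS for mu, log|resid| regression for sigma
        X = np.column_stack([np.ones_like(x), x, B])
        co, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ co
        lr = np.log(np.maximum(np.abs(resid), 1e-8 * max(np.std(y), 1e-8)))
        cs, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), lr,
                                 rcond=None)
        cs[0] += 0.6351  # -E[log|N(0,1)|]: log|resid| underestimates log sigma
        theta0 = np.concatenate([[co[0], co[1]], cs, co[2:]])
        if family == "boxcox_ls":
            mu0 = max(np.mean(y), 1e-6)
            theta0 = np.concatenate([theta0, [1.0]])
            theta0[2] -= np.log(mu0)  # sigma is on the relative scale
        res = optimize.minimize(_neg_loglik, theta0, args=(x, y, B, family),
                                method="Nelder-Mead" if family == "boxcox_ls"
                                else "BFGS",
                                options={"maxiter": 2000})
        nll = res.fun
        npar = theta0.size
        aic = 2 * nll + 2 * npar
        bic = 2 * nll + npar * np.log(len(y))
        if best is None or bic < best[0]:
            best = (bic, aic, p, res.x, -nll)
    bic, aic, p, th, ll = best
    offsets = {lv: float(th[4 + j]) for j, lv in enumerate(levels[1:])} \
        if nb else {}
    model = CentileModel(
        family=family, fp_power=p,
        mu_params=np.array(th[:2]), sigma_params=np.array(th[2:4]),
        nu=float(th[4 + nb]) if family == "boxcox_ls" else 1.0,
        covariate_offsets=offsets,
        age_range=(float(age.min()), float(age.max())),
        aic=float(aic), bic=float(bic), loglik=float(ll))
    # the nll above omits the 0.5*log(2*pi) constant; restore it in the
    # reported loglik (AIC/BIC comparisons between fits are unaffected)
    model.loglik -= 0.5 * len(y) * np.log(2 * np.pi)
    return model


def centile_position(model: CentileModel, age, batch, value):
    """The model CDF of ``value`` at the given age/batch; warns outside the
    fitted age range (+/- 10%)."""
    lo, hi = model.age_range
    span = hi - lo
    a = np.asarray(age, dtype=float)
    if np.any((a < lo - 0.1 * span) | (a > hi + 0.1 * span)):
        warnings.warn("age outside fitted range; centile is an extrapolation")
    return model.cdf(value, age, batch)


def classify_deviation(model: CentileModel, rows: pd.DataFrame,
                       lower=0.05, upper=0.95) -> pd.DataFrame:
    """Supra/infra/normal calls at strict 5%/95% thresholds.

    ``rows`` needs participant, visit, age, value and optionally batch.
    """
    batch = rows["batch"] if "batch" in rows.columns else None
    pos = centile_position(model, rows["age"].to_numpy(), batch,
                           rows["value"].to_numpy())
    call = np.where(pos > upper, "supra", np.where(pos < lower, "infra", "normal"))
    out = rows[[c for c in ("participant", "visit") if c in rows.columns]].copy()
    out["centile_position"] = pos
    out["call"] = call
    return out


def split_half_deviations(rows: pd.DataFrame, family="gaussian_ls",
                          seed=0) -> pd.DataFrame:
    """Fit on one random participant half, call the other, then swap.

    Every participant is called exactly once per visit, always from a model
    fitted without them.
    """
    rng = np.random.default_rng(seed)
    participants = np.array(sorted(rows["participant"].unique()))
    rng.shuffle(participants)
    half = set(participants[: len(participants) // 2])
    in_a = rows["participant"].isin(half)
    calls = []
    for fit_mask, call_mask in ((in_a, ~in_a), (~in_a, in_a)):
        model = fit_centile_model(rows[fit_mask], family=family)
        calls.append(classify_deviation(model, rows[call_mask]))
    return pd.concat(calls, ignore_index=True)


def pgs_deviation_association(calls: pd.DataFrame, pgs: pd.Series,
                              covariates: pd.DataFrame | None = None,
                              classes=("supra", "infra")):
    """Per-SD odds of deviation status for a standardised polygenic score.

    One binomial logistic regression per deviation class (class vs all
    remaining participants), returning the odds ratio per PGS standard
    deviation with a Wald 95% CI.  Classes with fewer than 10 events trigger
    a warning and a small-ridge penalised fit (flagged in the output).
    """
    df = calls.set_index("participant")
    s = pgs.reindex(df.index)
    if s.std(ddof=0) > 0:
        s = (s - s.mean()) / s.std(ddof=0)
    results = {}
    for cls in classes:
        yb = (df["call"] == cls).astype(float).to_numpy()
        X = [np.ones(len(df)), s.to_numpy(dtype=float)]
        if covariates is not None:
            cv = covariates.reindex(df.index)
            X += [cv[c].to_numpy(dtype=float) for c in cv.columns]
        X = np.column_stack(X)
        penalised = yb.sum() < 10
        if penalised:
            warnings.warn(f"fewer than 10 '{cls}' events: penalised fit")
            fit = sm.Logit(yb, X).fit_regularized(alpha=1e-3, L1_wt=0.0,
                                                  disp=0)
            # refit covariance at the penalised solution
            cov = _logit_cov(fit.params, X)
            beta, se = fit.params[1], np.sqrt(cov[1, 1])
        else:
            fit = sm.Logit(yb, X).fit(disp=0)
            beta, se = fit.params[1], fit.bse[1]
        results[cls] = {
            "odds_ratio": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
            "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
            "p": float(2 * stats.norm.sf(abs(beta / se))),
            "n_events": int(yb.sum()),
            "penalised": penalised,
        }
    return results


def _logit_cov(params, X):
    eta = X @ params
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    return np.linalg.inv((X * W[:, None]).T @ X)
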