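"""Empirical-Bayes estimation of the fraction of non-null variant effects.

Observed effect estimates are modelled as beta_hat_i ~ N(b_i, se_i^2) with a
unimodal, symmetric prior on the true effects:

    b ~ pi0 * delta_0 + sum_k pi_k * N(0, sigma_k^2),

a point mass at zero plus a ladder of zero-centred normals (the adaptive-
shrinkage family restricted to normal components, which keeps the EM
closed-form).  The mixture proportions are fitted by EM on the marginal
likelihood — each component's marginal for observation i is
N(0, se_i^2 + sigma_k^2) — and 1 - pi0 estimates the proportion of variants
with non-zero effects.  Stratifying variants into equal-count bins of LD
score and averaging per-bin estimates gives the polygenicity profile as a
function of how much signal a variant tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

log = logging.getLogger(__name__)


@dataclass
class EbFit:
    pi0: float
    grid_sd: np.ndarray = field(repr=False)
    pi_k: np.ndarray = field(repr=False)
    loglik: float = np.nan
    n_iter: int = 0
    loglik_path: np.ndarray = field(default=None, repr=False)

    @property
    def nonnull_fraction(self):
        return 1.0 - self.pi0


def default_grid(betas, ses):
    """Geometric SD ladder from min(se)/10 to 2*max(|beta|), ratio sqrt(2)."""
    lo = np.min(ses) / 10.0
    hi = max(2.0 * np.max(np.abs(betas)), lo * 2)
    n = int(np.ceil(np.log(hi / lo) / np.log(np.sqrt(2.0)))) + 1
    return lo * np.sqrt(2.0) ** np.arange(n)


def fit_eb_mixture(betas, ses, grid=None, tol=1e-8, max_iter=5000,
                   null_penalty=10.0) -> EbFit:
    """EM fit of the point-normal mixture to (beta, se) pairs.

    ``null_penalty`` (lambda >= 1) adds a Dirichlet-style prior count of
    lambda - 1 pseudo-observations on the null component, the standard
    null-biased regularisation of the adaptive-shrinkage family: it resolves
    the near-flat likelihood between the point mass and vanishingly small
    normal components in favour of the null, making 1 - pi0 conservative.
    The penalised marginal log-likelihood is non-decreasing across
    iterations (asserted); convergence when the gain drops below ``tol``.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("empty input")
    if np.any(s <= 0):
        raise ValueError("ses must be > 0")
    grid = default_grid(b, s) if grid is None else np.asarray(grid, dtype=float)
    K = grid.size
    # component 0 is the null point mass; columns 1..K the normal ladder
    var = s[:, None] ** 2 + np.concatenate([[0.0], grid ** 2])[None, :]
    loglik_ik = -0.5 * (np.log(2 * np.pi * var) + b[:, None] ** 2 / var)
    # row-shifted likelihood matrix: EM needs only L @ pi per iteration
    shift = loglik_ik.max(axis=1)
    L = np.exp(loglik_ik - shift[:, None])
    shift_sum = float(shift.sum())
    pi = np.full(K + 1, 1.0 / (K + 1))
    extra0 = max(null_penalty, 1.0) - 1.0
    prev = -np.inf
    path = []
    for it in range(max_iter):
        denom = L @ pi
        ll = float(np.log(denom).sum() + shift_sum
                   + extra0 * np.log(max(pi[0], 1e-300)))
        path.append(ll)
        if ll < prev - 1e-6:
            raise AssertionError("EM log-likelihood decreased")
        if ll - prev < tol:
            break
        prev = ll
        counts = pi * (L.T @ (1.0 / denom))
        counts[0] += extra0
        pi = counts / counts.sum()
    return EbFit(float(pi[0]), grid, pi[1:], ll, it + 1, np.array(path))


def binned_nonnull_fraction(betas, ses, ld_scores, n_bins=1000,
                            min_bin_size=20, grid=None, smooth_frac=0.3):
    """Per-LD-score-bin non-null fractions and their unweighted mean.

    Variants are sorted into ``n_bins`` equal-count quantile bins of
    ascending LD score; the mixture is fitted per bin; bins smaller than
    ``min_bin_size`` are merged with their neighbour.  Returns a dict with
    per-bin fractions, the mean, and a local-regression smoothed trend over
    bin rank (a simple moving local linear fit standing in for an
    additive-model trend line).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ld = np.asarray(ld_scores, dtype=float)
    order = np.argsort(ld, kind="stable")
    edges = np.array_split(order, max(int(n_bins), 1))
    merged, carry = [], np.array([], dtype=int)
    for idx in edges:
        idx = np.concatenate([carry, idx])
        if idx.size < min_bin_size:
            carry = idx
            continue
        merged.append(idx)
        carry = np.array([], dtype=int)
    if carry.size:
        if merged:
            merged[-1] = np.concatenate([merged[-1], carry])
            log.info("merged trailing bin of %d variants with neighbour", carry.size)
        else:
            merged = [carry]
    fracs, mean_ld = [], []
    for idx in merged:
        fit = fit_eb_mixture(b[idx], s[idx], grid=grid)
        fracs.append(fit.nonnull_fraction)
        mean_ld.append(float(ld[idx].mean()))
    fracs = np.array(fracs)
    return {
        "per_bin": fracs,
        "bin_mean_ld_score": np.array(mean_ld),
        "mean_nonnull": float(fracs.mean()),
        "trend": _local_linear_smooth(fracs, frac=smooth_frac),
        "n_bins": len(merged),
    }


def _local_linear_smooth(y, frac=0.3):
    """Moving local linear fit over index rank (tricube weights)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        return y.copy()
    span = max(int(np.ceil(frac * n)), 3)
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - span // 2)
        hi = min(n, lo + span)
        lo = max(0, hi - span)
        xi, yi = x[lo:hi], y[lo:hi]
        d = np.abs(xi - x[i])
        dmax = d.max() if d.max() > 0 else 1.0
        w = (1 - (d / dmax) ** 3) ** 3
        X = np.column_stack([np.ones_like(xi), xi - x[i]])
        coef = np.linalg.lstsq(X * w[:, None], yi * w, rcond=None)[0]
        out[i] = coef[0]
    return out
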