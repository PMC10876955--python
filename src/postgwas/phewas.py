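"""Phenome-wide causal screening and the evidence-tiering algorithm.

The screen estimates the exposure's effect on every outcome with the
IVW-MRE, controls the false discovery rate across outcomes with
Benjamini–Hochberg, and subjects survivors (q below the screen threshold,
default 0.01) to three sensitivity filters:

  i)   no significant heterogeneity between instrument effects
       (Cochran's Q p >= 0.05),
  ii)  a non-significant MR-Egger intercept (p >= 0.05), and
  iii) no single instrument carrying the result (largest leave-one-out
       p < 0.05).

Outcomes passing all three are tiered by how many of the five estimators
(IVW-MRE, IVW-FE, Egger, weighted median, weighted mode) are nominally
significant: 5/5 is tier 1, 4/5 tier 2, 3/5 tier 3; fewer, or any failed
filter, leaves the outcome untier-ed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mr import IVSet, fit_all, ivw

SCREEN_Q = 0.01
NOMINAL_P = 0.05
MIN_IVS_POLYGENIC = 6

FIVE_METHODS = ("ivw_mre", "ivw_fe", "egger", "weighted_median", "weighted_mode")


def bh_fdr(p_values):
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class TierResult:
    outcome_id: str
    q_value: float
    passed_het: bool
    passed_egger_intercept: bool
    passed_loo: bool
    n_sig_methods: int
    tier: str  # tier1 | tier2 | tier3 | none
    direction_concordant_with_single_iv: bool | None = None


def screen_outcomes(outcome_ivs: dict[str, IVSet], q_threshold=SCREEN_Q,
                    min_ivs=MIN_IVS_POLYGENIC):
    """IVW-MRE screen across outcomes with BH-FDR control.

    Outcomes with fewer than ``min_ivs`` instruments available are excluded
    before testing (the polygenic screen requires >= 6 IVs; a single-IV Wald
    screen is a separate pathway).  Returns (survivors ordered by q,
    per-outcome q dict, per-outcome MrEstimate dict).
    """
    eligible = {k: v for k, v in outcome_ivs.items() if v.k >= min_ivs}
    if not eligible:
        return [], {}, {}
    est = {k: ivw(v, "multiplicative_random") for k, v in eligible.items()}
    ids = list(est)
    q = bh_fdr([est[k].p for k in ids])
    qmap = dict(zip(ids, q))
    survivors = sorted([k for k in ids if qmap[k] < q_threshold],
                       key=lambda k: qmap[k])
    return survivors, qmap, est


def assign_tier(estimates, sens, q_value, outcome_id="outcome",
                q_threshold=SCREEN_Q, single_iv_beta=None) -> TierResult:
    """Apply the three sensitivity filters and count significant methods.

    ``estimates`` must contain all five methods.  Any failed filter, or a
    screen q-value at/above the threshold, forces tier 'none' regardless of
    the significance count.
    """
    missing = [m for m in FIVE_METHODS if m not in estimates]
    if missing:
        raise ValueError(f"missing estimator(s): {missing}")
    passed_het = sens.p_het >= NOMINAL_P
    passed_icpt = sens.intercept_p >= NOMINAL_P
    passed_loo = sens.loo_max_p < NOMINAL_P
    n_sig = sum(1 for m in FIVE_METHODS
                if np.isfinite(estimates[m].p) and estimates[m].p < NOMINAL_P)
    tier = "none"
    if passed_het and passed_icpt and passed_loo and q_value < q_threshold:
        tier = {5: "tier1", 4: "tier2", 3: "tier3"}.get(n_sig, "none")
    concord = None
    if single_iv_beta is not None:
        concord = bool(np.sign(estimates["ivw_mre"].beta) == np.sign(single_iv_beta))
    return TierResult(outcome_id, float(q_value), passed_het, passed_icpt,
                      passed_loo, n_sig, tier, concord)


def run_phewas(outcome_ivs: dict[str, IVSet], q_threshold=SCREEN_Q,
               n_boot=200, seed=0, exclusions=()):
    """Screen, then tier the survivors (the full pipeline order).

    ``exclusions`` is a user-supplied list of outcome ids removed after
    tiering (manual-curation stand-in).  Returns list of TierResult for
    survivors, plus the full q map.
    """
    survivors, qmap, _ = screen_outcomes(outcome_ivs, q_threshold)
    results = []
    for i, out in enumerate(survivors):
        if out in exclusions:
            continue
        ests, sens = fit_all(outcome_ivs[out], n_boot=n_boot,
                             seed=None if seed is None else seed + 2 * i)
        results.append(assign_tier(ests, sens, qmap[out], out, q_threshold))
    return results, qmap


def bidirectional_check(forward: IVSet, reverse: IVSet | None,
                        reverse_binary=False, n_boot=200, seed=0):
    """Fit the full estimator suite in both directions.

    ``reverse`` is None when no instruments for the outcome->exposure
    direction were available at either the genome-wide (5e-8) or suggestive
    (1e-5) threshold, in which case the reverse direction is marked
    untestable.  A binary outcome used as a reverse exposure is labelled a
    null-hypothesis test only (its effect scale is not interpretable).
    """
    fwd_est, fwd_sens = fit_all(forward, n_boot=n_boot, seed=seed)
    report = {"forward": {"estimates": fwd_est, "sensitivity": fwd_sens},
              "reverse": None}
    if reverse is None or reverse.k < 3:
        report["reverse_untestable"] = True
        return report
    rev_est, rev_sens = fit_all(reverse, n_boot=n_boot,
                                seed=None if seed is None else seed + 1)
    report["reverse"] = {"estimates": rev_est, "sensitivity": rev_sens,
                         "nominal_signal": rev_est["ivw_mre"].p < NOMINAL_P,
                         "interpretation": ("null-hypothesis test only"
                                            if reverse_binary else "effect estimate")}
    report["reverse_untestable"] = False
    return report
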