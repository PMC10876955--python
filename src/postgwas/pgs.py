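"""Polygenic-score construction and evaluation.

Two weighting schemes: LD clumping + p-value thresholding (C+T), where
retained variants carry their marginal effect sizes, and posterior-weighted
scoring, where each variant's effect is shrunk by its posterior probability
of causality from single-causal finemapping of independent LD blocks
(upweighting signals more likely to be causal and discounting LD
double-counting).  Scores are additive over allele dosages; evaluation is
the incremental variance explained (delta R^2) of a covariate+PGS linear
model over the covariate-only model in a held-out test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, LdMatrix
from .finemap import finemap_region, DEFAULT_PRIOR_VARIANCE

#: p-value thresholds conventionally profiled for C+T scores
CT_THRESHOLDS = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class PgsModel:
    method: str  # ct | abf_weighted
    weights: pd.DataFrame = field(repr=False)  # SNP, EA, weight
    parameters: dict = field(default_factory=dict)
    provenance: str = ""

    def __len__(self):
        return len(self.weights)


def clump(ss: SummaryStats, ld: LdMatrix, r2_max=0.001, window_kb=250.0):
    """Greedy p-ascending LD clumping; returns retained variant ids.

    The most significant remaining variant is kept and every variant within
    ``window_kb`` of it with r^2 > ``r2_max`` is removed; repeat.  Variants
    absent from the LD matrix are treated as unlinked (with a warning).
    """
    df = ss.df.dropna(subset=["P"]).sort_values("P")
    missing = [v for v in df["SNP"] if v not in ld._index]
    if missing:
        warnings.warn(f"{len(missing)} variants not in LD matrix; treated as unlinked")
    retained, removed = [], set()
    pos = df.set_index("SNP")["POS"]
    chrom = df.set_index("SNP")["CHR"]
    for v in df["SNP"]:
        if v in removed:
            continue
        retained.append(v)
        for u in df["SNP"]:
            if u == v or u in removed:
                continue
            if chrom[u] != chrom[v] or abs(pos[u] - pos[v]) > window_kb * 1000.0:
                continue
            if v in ld._index and u in ld._index and ld.r2(v, u) > r2_max:
                removed.add(u)
    return retained


def build_ct_score(ss: SummaryStats, ld: LdMatrix, p_thresholds=CT_THRESHOLDS,
                   r2_max=0.001, window_kb=250.0):
    """One C+T model per threshold: clump once, then filter p < threshold."""
    if any(t <= 0 or t > 1 for t in p_thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    kept = clump(ss, ld, r2_max=r2_max, window_kb=window_kb)
    base = ss.df.set_index("SNP").loc[kept]
    models = {}
    for t in p_thresholds:
        sel = base[base["P"] < t] if t < 1.0 else base
        if sel.empty:
            warnings.warn(f"no variants retained at threshold {t}")
        models[t] = PgsModel(
            "ct",
            sel.reset_index()[["SNP", "EA", "BETA", "EAF"]].rename(
                columns={"BETA": "weight"}),
            parameters={"p_threshold": t, "r2_max": r2_max,
                        "window_kb": window_kb},
            provenance=ss.study_name)
    return models


def build_abf_score(ss: SummaryStats, ld_blocks, prior_variance=DEFAULT_PRIOR_VARIANCE):
    """Posterior-probability-weighted score over independent LD blocks.

    ``ld_blocks`` is a list of variant-id lists partitioning the scored
    variants.  Within each block, single-causal finemapping yields posterior
    inclusion probabilities; weight_i = beta_i * pip_i.  ``prior_variance``
    may be a scalar or a per-variant mapping (data-driven, e.g. derived from
    SNP heritability).
    """
    df = ss.df.set_index("SNP")
    rows = []
    for block in ld_blocks:
        block = [v for v in block if v in df.index]
        if not block:
            continue
        b = df.loc[block]
        if isinstance(prior_variance, dict):
            W = np.array([prior_variance[v] for v in block])
        else:
            W = prior_variance
        fr = finemap_region(block, b["BETA"].to_numpy(), b["SE"].to_numpy(),
                            prior_variance=W, p_values=b["P"].to_numpy())
        for v, pip, beta, ea, eaf in zip(block, fr.pip, b["BETA"], b["EA"], b["EAF"]):
            rows.append((v, ea, beta * pip, eaf))
    return PgsModel("abf_weighted",
                    pd.DataFrame(rows, columns=["SNP", "EA", "weight", "EAF"]),
                    parameters={"prior_variance": (
                        "data_driven" if isinstance(prior_variance, dict)
                        else prior_variance)},
                    provenance=ss.study_name)


def score_individuals(model: PgsModel, dosages: pd.DataFrame):
    """Additive PGS: score = sum over variants of dosage * weight.

    ``dosages`` is individuals x variants (columns named by variant id,
    values in [0, 2] counting model effect alleles).  Missing dosages are
    imputed at 2*EAF when the model carries an EAF, otherwise the variant is
    dropped for that individual.
    """
    common = [v for v in model.weights["SNP"] if v in dosages.columns]
    if not common:
        raise ValueError("no overlap between model variants and dosage columns")
    wmap = model.weights.set_index("SNP")
    D = dosages[common].to_numpy(dtype=float)
    w = wmap.loc[common, "weight"].to_numpy(dtype=float)
    if "EAF" in wmap.columns:
        eaf = wmap.loc[common, "EAF"].to_numpy(dtype=float)
        fill = np.where(np.isfinite(eaf), 2.0 * eaf, 0.0)
    else:
        fill = np.zeros(len(common))
    D = np.where(np.isfinite(D), D, fill[None, :])
    return pd.Series(D @ w, index=dosages.index, name="PGS")


def evaluate_pgs(scores, phenotype, covariates=None, train_fraction=0.7,
                 seed=0):
    """Incremental variance explained by the PGS on a held-out test split.

    Fits covariate-only and covariate+PGS linear models on the test
    partition (the training partition is where threshold tuning would
    happen) and returns test-partition R^2(full) - R^2(null).  Repeated
    visits should be averaged by the caller before evaluation.
    """
    y = np.asarray(phenotype, dtype=float)
    s = np.asarray(scores, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    test = rng.random(n) >= train_fraction
    if test.sum() < 30:
        warnings.warn("test partition has fewer than 30 individuals")
    C = (np.asarray(covariates, dtype=float).reshape(n, -1)
         if covariates is not None else np.empty((n, 0)))

    def r2(Xcols):
        X = np.column_stack([np.ones(test.sum())] + Xcols)
        yv = y[test]
        coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ coef
        tss = ((yv - yv.mean()) ** 2).sum()
        return 1.0 - (resid ** 2).sum() / tss

    null_cols = [C[test, j] for j in range(C.shape[1])]
    return float(r2(null_cols + [s[test]]) - r2(null_cols))
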