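"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure of two-cohort metabolite
GWAS: standardised-trait effect sizes under a point-normal architecture,
block-diagonal LD with geometric within-block decay, instrument sets under
configurable pleiotropy models (none / balanced / directional / correlated,
the last violating the InSIDE assumption), Hardy-Weinberg genotype dosages
with a phenotype of configurable polygenic-score R^2, and age-dependent
biomarker measurements with a known centile structure (three visits spaced
roughly seven years apart, the layout of a longitudinal twin-registry
metabolomics panel).

Every generator is a pure function of its configuration: the master seed is
combined with a stable hash of the operation name so repeated calls are
bit-identical and independent operations never share a stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, LdMatrix
from .mr import IVSet


@dataclass
class SynthConfig:
    seed: int
    n_variants: int = 1000
    n_blocks: int = 50
    block_size: int = 20
    ld_decay: float = 0.8          # within-block correlation of adjacent variants
    pi_nonnull: float = 0.02       # fraction of variants with non-zero effects
    effect_sd: float = 0.05        # SD of non-null effects, trait SD units
    cohort_ns: tuple = (10000, 7000)   # two-cohort metabolite GWAS scale
    maf_range: tuple = (0.05, 0.5)
    pleiotropy: str = "none"       # none | balanced | directional | correlated
    pleiotropy_sd: float = 0.05
    pleiotropy_mean: float = 0.05  # directional only
    true_causal_effect: float = 0.15
    n_iv: int = 30
    exposure_n: int = 20000
    outcome_n: int = 50000
    age_range: tuple = (40.0, 70.0)
    centile_mu: tuple = (2.0, 0.5)     # value ~ mu0 + mu1*log(age)
    centile_sigma: tuple = (0.3, 0.0)  # log sigma = log(s0) + s1*log(age)
    n_batches: int = 2
    batch_sd: float = 0.1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f, v in (("ld_decay", self.ld_decay), ("pi_nonnull", self.pi_nonnull)):
            if not 0 <= v < 1 + 1e-12:
                raise ValueError(f"{f} out of range: {v}")


def _rng(cfg: SynthConfig, op: str):
    """Independent stream per operation, derived from the master seed."""
    return np.random.default_rng([cfg.seed % (2 ** 31), zlib.crc32(op.encode())])


def gen_ld_blocks(cfg: SynthConfig) -> LdMatrix:
    """Block-diagonal LD, r(i,j) = ld_decay^|i-j| within blocks (AR(1) form,
    positive-definite by construction)."""
    n = cfg.n_blocks * cfg.block_size
    ids = [f"rs{i+1}" for i in range(n)]
    r = np.zeros((n, n))
    idx = np.arange(cfg.block_size)
    block = cfg.ld_decay ** np.abs(idx[:, None] - idx[None, :]) \
        if cfg.ld_decay > 0 else np.eye(cfg.block_size)
    for b in range(cfg.n_blocks):
        s = b * cfg.block_size
        r[s:s + cfg.block_size, s:s + cfg.block_size] = block
    return LdMatrix(ids, r)


def _positions(cfg, n):
    """1-based positions, blocks spaced 1 Mb apart, 1 kb between variants."""
    block = np.arange(n) // cfg.block_size
    within = np.arange(n) % cfg.block_size
    return 1 + block * 1_000_000 + within * 1_000


def gen_gwas_pair(cfg: SynthConfig, single_causal_per_block=False):
    """Two cohorts' summary statistics sharing point-normal true effects.

    True per-variant effects b are zero with probability 1 - pi_nonnull and
    N(0, effect_sd^2) otherwise (``single_causal_per_block`` instead plants
    exactly one causal variant per block, for credible-set coverage tests).
    Per cohort, observed effects follow the standard summary-statistic
    model: beta_hat ~ N(R b, R/n) per block (standardised genotypes and
    trait), so SE = 1/sqrt(n); cohorts share the truth and have independent
    noise.  Returns (SummaryStats a, SummaryStats b, truth DataFrame).
    """
    rng = _rng(cfg, "gen_gwas_pair")
    ld = gen_ld_blocks(cfg)
    n = len(ld)
    ids = ld.variant_ids
    if single_causal_per_block:
        b = np.zeros(n)
        for blk in range(cfg.n_blocks):
            j = blk * cfg.block_size + rng.integers(cfg.block_size)
            b[j] = rng.normal(0.0, cfg.effect_sd) or cfg.effect_sd
    else:
        nonnull = rng.random(n) < cfg.pi_nonnull
        b = np.where(nonnull, rng.normal(0.0, cfg.effect_sd, n), 0.0)
    eaf = rng.uniform(*cfg.maf_range, n)
    pos = _positions(cfg, n)
    alleles = rng.choice(["A", "C", "G", "T"], size=(n, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    chol = np.linalg.cholesky(
        cfg.ld_decay ** np.abs(np.subtract.outer(np.arange(cfg.block_size),
                                                 np.arange(cfg.block_size)))
        if cfg.ld_decay > 0 else np.eye(cfg.block_size))
    studies = []
    for ci, n_s in enumerate(cfg.cohort_ns[:2]):
        se = np.full(n, 1.0 / np.sqrt(n_s))
        beta_hat = np.empty(n)
        for blk in range(cfg.n_blocks):
            s = slice(blk * cfg.block_size, (blk + 1) * cfg.block_size)
            Rb = (chol @ (chol.T @ b[s]))
            noise = chol @ rng.standard_normal(cfg.block_size)
            beta_hat[s] = Rb + noise / np.sqrt(n_s)
        z = beta_hat / se
        df = pd.DataFrame({
            "SNP": ids, "CHR": "1", "POS": pos,
            "EA": alleles[:, 0], "NEA": alleles[:, 1], "EAF": eaf,
            "BETA": beta_hat, "SE": se, "Z": z,
            "P": 2 * _norm_sf(np.abs(z)), "N": n_s,
        })
        studies.append(SummaryStats(df, study_name=f"cohort{ci+1}"))
    truth = pd.DataFrame({"SNP": ids, "true_beta": b,
                          "block": np.arange(n) // cfg.block_size,
                          "POS": pos, "EAF": eaf})
    return studies[0], studies[1], truth


def _norm_sf(x):
    from scipy.stats import norm
    return norm.sf(x)


def gen_iv_set(cfg: SynthConfig):
    """An instrument set under the configured pleiotropy model, plus truth.

    Exposure effects |N(0, 2*effect_sd^2)| with SE = 1/sqrt(exposure_n);
    outcome effects true_causal_effect * beta_exp + alpha + noise with
    SE = 1/sqrt(outcome_n), where the direct (pleiotropic) effects alpha are
    zero (none), mean-zero normal (balanced), normal around
    ``pleiotropy_mean`` (directional), or proportional to instrument
    strength plus noise (correlated — violating the InSIDE assumption that
    pleiotropy is independent of instrument strength).
    """
    rng = _rng(cfg, "gen_iv_set")
    k = cfg.n_iv
    beta_exp_true = np.abs(rng.normal(0.0, 2 * cfg.effect_sd, k)) + 0.5 * cfg.effect_sd
    se_exp = np.full(k, 1.0 / np.sqrt(cfg.exposure_n))
    se_out = np.full(k, 1.0 / np.sqrt(cfg.outcome_n))
    if cfg.pleiotropy == "none":
        alpha = np.zeros(k)
    elif cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, k)
    elif cfg.pleiotropy == "directional":
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, k)
    elif cfg.pleiotropy == "correlated":
        alpha = 0.5 * beta_exp_true + rng.normal(0.0, cfg.pleiotropy_sd, k)
    else:
        raise ValueError(f"unknown pleiotropy model {cfg.pleiotropy!r}")
    beta_exp = beta_exp_true + rng.normal(0.0, se_exp)
    beta_out = (cfg.true_causal_effect * beta_exp_true + alpha
                + rng.normal(0.0, se_out))
    ivs = IVSet([f"iv{i+1}" for i in range(k)], beta_exp, se_exp,
                beta_out, se_out)
    truth = {"true_effect": cfg.true_causal_effect, "alpha": alpha,
             "beta_exp_true": beta_exp_true,
             "mean_pleiotropy": float(alpha.mean())}
    return ivs, truth


def gen_cohort_biomarker(cfg: SynthConfig, n_participants=800, n_visits=3):
    """Age-dependent biomarker measurements with known centile positions.

    value ~ family(mu(age) + batch offset, sigma(age)) with
    mu(age) = mu0 + mu1*log(age) and log sigma(age) = log(s0) + s1*log(age).
    Visits shift ages by ~+7 years each.  Returns (rows DataFrame with the
    per-row true centile, batch offsets dict).
    """
    rng = _rng(cfg, "gen_cohort_biomarker")
    age0 = rng.uniform(*cfg.age_range, n_participants)
    batches = rng.integers(cfg.n_batches, size=n_participants)
    offsets = {b: (rng.normal(0.0, cfg.batch_sd) if b > 0 else 0.0)
               for b in range(cfg.n_batches)}
    mu0, mu1 = cfg.centile_mu
    s0, s1 = cfg.centile_sigma
    rows = []
    for visit in range(1, n_visits + 1):
        age = age0 + (visit - 1) * 7.0 + rng.normal(0.0, 0.5, n_participants)
        mu = mu0 + mu1 * np.log(age) + np.vectorize(offsets.get)(batches)
        sigma = s0 * np.exp(s1 * np.log(age))
        z = rng.standard_normal(n_participants)
        value = mu + sigma * z
        true_centile = _norm_cdf(z)
        for i in range(n_participants):
            rows.append((f"p{i+1}", visit, age[i], int(batches[i]),
                         value[i], true_centile[i]))
    df = pd.DataFrame(rows, columns=["participant", "visit", "age", "batch",
                                     "value", "true_centile"])
    return df, offsets


def _norm_cdf(x):
    from scipy.stats import norm
    return norm.cdf(x)


def gen_genotypes(cfg: SynthConfig, n_individuals=1600, n_snps=50,
                  target_r2=0.02):
    """Hardy-Weinberg dosages and a phenotype with a known PGS R^2.

    Dosages ~ Binomial(2, maf); the genetic value g = sum dosage*w (random
    weights) is scaled so its population variance share of the phenotype is
    ``target_r2``; the remainder is Gaussian noise.  Returns (dosage
    DataFrame, phenotype Series, weights Series).
    """
    rng = _rng(cfg, "gen_genotypes")
    maf = rng.uniform(*cfg.maf_range, n_snps)
    D = rng.binomial(2, maf, size=(n_individuals, n_snps)).astype(float)
    w = rng.normal(0.0, 1.0, n_snps)
    g = (D - 2 * maf) @ w
    if target_r2 > 0 and g.std() > 0:
        g = g / g.std() * np.sqrt(target_r2)
        noise_sd = np.sqrt(1.0 - target_r2)
    else:
        g = np.zeros(n_individuals)
        noise_sd = 1.0
    y = g + rng.normal(0.0, noise_sd, n_individuals)
    ids = [f"rs{i+1}" for i in range(n_snps)]
    dosages = pd.DataFrame(D, columns=ids,
                           index=[f"p{i+1}" for i in range(n_individuals)])
    return dosages, pd.Series(y, index=dosages.index, name="phenotype"), \
        pd.Series(w, index=ids, name="weight")
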