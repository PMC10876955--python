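"""Meta-analysis of harmonised GWAS summary statistics.

Two estimators are provided: the sample-size-weighted combination of Z-scores
(Stouffer's method), used when constituent studies report effects in
different units, and the fixed-effects inverse-variance-weighted (IVW)
estimator, which pools effect sizes directly when all studies share a unit
(e.g. trait SD per effect allele).  Between-study heterogeneity is measured
with Cochran's Q.  The module also defines genome-wide significant loci
(greedy LD clumping of significant variants with block merging), the
directional-consistency binomial replication test, and the Cauchy
combination (ACAT) gene-level aggregation of rare-variant p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStats, LdMatrix, z_to_p


def stouffer_meta(studies: list[SummaryStats]) -> pd.DataFrame:
    """Sample-size-weighted Z-score meta-analysis.

    z_meta = sum_i sqrt(n_i) z_i / sqrt(sum_i n_i) over studies carrying the
    variant.  Variants present in fewer than two studies (or with missing n
    or z in any carrying study) are passed through flagged ``single_study``
    rather than meta-analysed.  A per-variant direction string records the
    sign of each study's harmonised z ('+', '-', '?').
    """
    if len(studies) < 2:
        raise ValueError("need >= 2 studies")
    frames = [s.df.set_index("SNP")[["Z", "N"]] for s in studies]
    all_ids = sorted(set().union(*[f.index for f in frames]))
    z = np.full((len(all_ids), len(studies)), np.nan)
    n = np.full_like(z, np.nan)
    for j, f in enumerate(frames):
        common = f.index.intersection(all_ids)
        loc = pd.Index(all_ids).get_indexer(common)
        z[loc, j] = f.loc[common, "Z"].to_numpy(dtype=float)
        n[loc, j] = f.loc[common, "N"].to_numpy(dtype=float)
    have = np.isfinite(z) & np.isfinite(n)
    k = have.sum(axis=1)
    w = np.where(have, np.sqrt(np.where(have, n, 0.0)), 0.0)
    z_meta = (w * np.where(have, z, 0.0)).sum(axis=1) / np.sqrt((w ** 2).sum(axis=1))
    single = k < 2
    # flagged pass-through keeps the single study's own z
    z_meta = np.where(single, np.nansum(np.where(have, z, np.nan), axis=1), z_meta)
    direction = ["".join("?" if not h else ("+" if zz >= 0 else "-")
                         for h, zz in zip(hrow, zrow))
                 for hrow, zrow in zip(have, z)]
    out = pd.DataFrame({
        "SNP": all_ids,
        "Z_META": z_meta,
        "P_META": z_to_p(np.nan_to_num(z_meta)),
        "N_STUDIES": k,
        "DIRECTION": direction,
        "single_study": single,
    })
    out.loc[~np.isfinite(z_meta), "P_META"] = np.nan
    return out


def ivw_meta(studies: list[SummaryStats]) -> pd.DataFrame:
    """Fixed-effects inverse-variance-weighted meta-analysis of effect sizes.

    Weights w_i = 1/se_i^2; beta_meta = sum w_i b_i / sum w_i and
    se_meta = (sum w_i)^(-1/2).  Cochran's Q heterogeneity statistic and its
    chi-square p-value (df = k-1) are reported for variants in >= 2 studies.
    Variants with any non-positive SE are excluded and counted in the
    ``n_excluded`` attribute of the result frame.
    """
    frames = [s.df.set_index("SNP")[["BETA", "SE"]] for s in studies]
    all_ids = sorted(set.intersection(*[set(f.index) for f in frames])) \
        if len(frames) > 1 else sorted(frames[0].index)
    rows, n_excluded = [], 0
    for v in all_ids:
        b = np.array([f.loc[v, "BETA"] for f in frames], dtype=float)
        se = np.array([f.loc[v, "SE"] for f in frames], dtype=float)
        ok = np.isfinite(b) & np.isfinite(se)
        if np.any(se[ok] <= 0) or not ok.any():
            n_excluded += 1
            continue
        b, se = b[ok], se[ok]
        w = se ** -2
        beta = float((w * b).sum() / w.sum())
        se_m = float(w.sum() ** -0.5)
        if len(b) >= 2:
            q, df, p_het = cochran_q(b, se, beta)
        else:
            q, df, p_het = np.nan, 0, np.nan
        z = beta / se_m
        rows.append((v, beta, se_m, z, z_to_p(z), q, df, p_het, int(len(b))))
    out = pd.DataFrame(rows, columns=["SNP", "BETA_META", "SE_META", "Z_META",
                                      "P_META", "Q", "Q_DF", "P_HET", "N_STUDIES"])
    out.attrs["n_excluded"] = n_excluded
    return out


def cochran_q(betas, ses, pooled):
    """Cochran's Q about a pooled estimate; returns (Q, df, p_het)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise ValueError("Cochran's Q needs k >= 2 estimates")
    q = float((((betas - pooled) ** 2) / ses ** 2).sum())
    df = betas.size - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class Locus:
    """A merged LD block of genome-wide significant variants (1-based closed)."""

    chrom: str
    start: int
    end: int
    lead_variant_id: str
    member_ids: list[str] = field(default_factory=list)
    independent_ids: list[str] = field(default_factory=list)
    closest_tss_gene: str | None = None


def define_loci(meta: pd.DataFrame, positions: pd.DataFrame, ld: LdMatrix,
                p_threshold=5e-8, r2_indep=0.6, r2_lead=0.1,
                merge_kb=250.0) -> list[Locus]:
    """Greedy lead-SNP and locus definition from meta-analysis results.

    ``meta`` needs SNP and P_META columns; ``positions`` needs SNP, CHR, POS.
    Independent significant SNPs are selected p-ascending at pairwise
    r^2 <= ``r2_indep`` (default 0.6); lead SNPs among them at r^2 <=
    ``r2_lead`` (default 0.1).  Each independent SNP spans a block over the
    significant variants it clumps (r^2 > r2_indep); blocks on the same
    chromosome whose edges are within ``merge_kb`` are merged into one locus
    whose lead is the smallest-p lead SNP it contains.
    """
    df = meta.merge(positions[["SNP", "CHR", "POS"]], on="SNP")
    sig = df[df["P_META"] < p_threshold].sort_values("P_META")
    if sig.empty:
        return []
    sig = sig.reset_index(drop=True)
    in_ld = {v: i for i, v in enumerate(sig["SNP"]) if v in ld._index}

    def r2(u, v):
        if u in ld._index and v in ld._index:
            return ld.r2(u, v)
        return 0.0

    indep, clumped = [], {}
    for _, row in sig.iterrows():
        v = row["SNP"]
        owner = next((u for u in indep if r2(u, v) > r2_indep), None)
        if owner is None:
            indep.append(v)
            clumped[v] = [v]
        else:
            clumped[owner].append(v)
    leads = []
    for v in indep:  # already p-ascending
        if all(r2(u, v) <= r2_lead for u in leads):
            leads.append(v)

    posmap = df.set_index("SNP")
    blocks = []
    for v in indep:
        members = clumped[v]
        ps = [int(posmap.loc[m, "POS"]) for m in members]
        blocks.append({"chrom": str(posmap.loc[v, "CHR"]), "start": min(ps),
                       "end": max(ps), "indep": [v], "members": list(members)})
    blocks.sort(key=lambda b: (b["chrom"], b["start"]))
    merged = []
    for b in blocks:
        if merged and merged[-1]["chrom"] == b["chrom"] \
                and b["start"] - merged[-1]["end"] <= merge_kb * 1000.0:
            m = merged[-1]
            m["end"] = max(m["end"], b["end"])
            m["indep"] += b["indep"]
            m["members"] += b["members"]
        else:
            merged.append(b)
    loci = []
    for m in merged:
        cand = [v for v in leads if v in m["members"]] or m["indep"]
        lead = min(cand, key=lambda v: posmap.loc[v, "P_META"])
        loci.append(Locus(chrom=m["chrom"], start=m["start"], end=m["end"],
                          lead_variant_id=lead, member_ids=sorted(set(m["members"])),
                          independent_ids=m["indep"]))
    return loci


def sign_replication_test(discovery_signs, replication_z):
    """One-sided binomial test of directional consistency in replication.

    Counts lead variants whose replication mean-Z shares the discovery sign
    and returns P(X >= k) under Binomial(n, 1/2).
    """
    s = np.asarray(discovery_signs, dtype=float)
    z = np.asarray(replication_z, dtype=float)
    if s.size == 0 or s.size != z.size:
        raise ValueError("inputs must be equal-length and non-empty")
    k = int((np.sign(z) == np.sign(s)).sum())
    n = s.size
    return k, n, float(stats.binom.sf(k - 1, n, 0.5))


def cauchy_gene_test(p_values, weights=None):
    """Cauchy combination (ACAT) of p-values, robust to unknown correlation.

    T = sum_j w_j tan((0.5 - p_j) pi) / sum_j w_j; combined
    p = 0.5 - arctan(T)/pi.  p-values of exactly 1 are clipped to 1 - 1e-16.
    The heavy Cauchy tail makes the combined p insensitive to LD between the
    constituent (rare-variant) tests, whose covariance is hard to estimate.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.minimum(p, 1.0 - 1e-16)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    # tan((0.5-p)pi) overflows only for p < ~1e-308; map tiny p via 1/(p*pi)
    small = p < 1e-15
    t = np.empty_like(p)
    t[~small] = np.tan((0.5 - p[~small]) * np.pi)
    t[small] = 1.0 / (p[small] * np.pi)
    T = float((w * t).sum() / w.sum())
    if T > 1e15:  # arctan saturates; use the same tail approximation
        return 1.0 / (T * np.pi)
    return float(0.5 - np.arctan(T) / np.pi)
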