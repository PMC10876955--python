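"""GWAS summary-statistic containers, I/O, harmonisation and imputation.

Per-variant association records (effect allele, frequency, beta, SE, Z, p, N)
are held in a :class:`SummaryStats` object wrapping a pandas DataFrame with
canonical column names ``SNP CHR POS EA NEA EAF BETA SE Z P N``.  Effect sizes
are in trait standard-deviation units per effect-allele copy (or log-odds for
binary traits).  Positions are 1-based; locus intervals downstream are closed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "Z", "P", "N"]
MANDATORY = ["SNP", "CHR", "POS", "EA", "NEA"]

#: palindromic (strand-ambiguous) allele pairs
PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: drop palindromic variants when min(EAF, 1-EAF) exceeds this, or EAF missing
AMBIGUITY_WINDOW = 0.42


class SumstatsFormatError(ValueError):
    """Raised for files missing mandatory columns or containing no rows."""


def z_to_p(z):
    """Two-sided normal-tail p-value, p = 2*Phi(-|z|).

    Computed through the survival function so p-values far below the double
    underflow threshold of a naive ``1 - cdf`` remain distinguishable (scipy's
    ``norm.sf`` is accurate down to ~1e-308; ``log_p_from_z`` covers anything
    smaller).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    p = 2.0 * stats.norm.sf(np.abs(z))
    return p if p.ndim else float(p)


def log_p_from_z(z):
    """Natural log of the two-sided p-value; exact for arbitrarily large |z|."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    lp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    return lp if lp.ndim else float(lp)


def p_to_z(p, sign=1.0):
    """Inverse of :func:`z_to_p`; ``sign`` restores the direction."""
    return sign * -stats.norm.ppf(np.asarray(p, dtype=float) / 2.0)


def format_p(p):
    """Scientific notation with 3 significant figures, mirroring table output."""
    return np.format_float_scientific(float(p), precision=2, exp_digits=1)


@dataclass
class SummaryStats:
    """One study's per-variant association records.

    Attributes
    ----------
    df : pandas.DataFrame
        Canonical columns; one row per variant, unique ``SNP`` keys.
    study_name : str
    trait_units : str
        ``sd`` (trait standard deviations), ``log`` (log-odds) or ``other``.
    genome_build : str
    n_dropped : int
        Rows discarded at read time for violating record invariants.
    """

    df: pd.DataFrame
    study_name: str = "study"
    trait_units: str = "sd"
    genome_build: str = "hg19"
    n_dropped: int = 0

    def __post_init__(self):
        if self.df["SNP"].duplicated().any():
            dup = self.df["SNP"][self.df["SNP"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def variant_ids(self):
        return self.df["SNP"].tolist()


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating record invariants; return (clean, n_dropped)."""
    n0 = len(df)
    ok = pd.Series(True, index=df.index)
    ok &= df["EA"].astype(str) != df["NEA"].astype(str)
    if "SE" in df and df["SE"].notna().any():
        ok &= df["SE"].isna() | (df["SE"] > 0)
    if "EAF" in df:
        ok &= df["EAF"].isna() | ((df["EAF"] >= 0) & (df["EAF"] <= 1))
    if "P" in df:
        ok &= df["P"].isna() | ((df["P"] > 0) & (df["P"] <= 1))
    if "N" in df:
        ok &= df["N"].isna() | (df["N"] > 0)
    # beta/se/z internal consistency: recompute z where possible
    clean = df[ok].copy()
    if "BETA" in clean and "SE" in clean:
        has = clean["BETA"].notna() & clean["SE"].notna()
        z_imp = clean.loc[has, "BETA"] / clean.loc[has, "SE"]
        if "Z" not in clean:
            clean["Z"] = np.nan
        missing_z = has & clean["Z"].isna()
        clean.loc[missing_z, "Z"] = z_imp[missing_z[missing_z].index]
    if "Z" in clean and "P" not in clean.columns:
        clean["P"] = np.nan
    if "Z" in clean:
        fill_p = clean["P"].isna() & clean["Z"].notna()
        clean.loc[fill_p, "P"] = z_to_p(clean.loc[fill_p, "Z"].to_numpy())
    n_dropped = n0 - len(clean)
    if n_dropped:
        log.info("dropped %d rows failing record invariants", n_dropped)
    return clean, n_dropped


def read_sumstats(path, column_map=None, sep="\t", study_name=None,
                  trait_units="sd", genome_build="hg19") -> SummaryStats:
    """Read delimited summary statistics.

    ``column_map`` maps canonical names (SNP, CHR, POS, EA, NEA, EAF, BETA,
    SE, Z, P, N) to the file's header names; identity by default.  Rows
    violating record invariants (SE <= 0, p outside (0,1], EA == NEA, ...)
    are dropped and counted in ``n_dropped``.
    """
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise SumstatsFormatError(f"{path}: no data rows")
    if column_map:
        inv = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inv)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory column(s) {missing}")
    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[CANONICAL_COLUMNS]
    for c in ("SNP", "CHR"):
        df[c] = df[c].astype(str)
    for c in ("EA", "NEA"):
        df[c] = df[c].astype(str).str.upper()
    clean, n_dropped = _validate_rows(df)
    return SummaryStats(clean, study_name=study_name or str(path),
                        trait_units=trait_units, genome_build=genome_build,
                        n_dropped=n_dropped)


def write_sumstats(ss: SummaryStats, path, sep="\t"):
    """Write canonical tab-delimited summary statistics (full float precision)."""
    ss.df.to_csv(path, sep=sep, index=False)


def is_palindromic(ea, nea):
    return (str(ea).upper(), str(nea).upper()) in PALINDROMES


def _ambiguous(eaf):
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        return True
    return min(eaf, 1.0 - eaf) > AMBIGUITY_WINDOW


def harmonise(a: SummaryStats, b: SummaryStats) -> pd.DataFrame:
    """Pair two studies' records on shared variants, aligned to ``a``'s coding.

    For each shared variant, if ``b``'s effect allele equals ``a``'s other
    allele (and vice versa), ``b``'s beta and z change sign and its EAF is
    complemented.  Palindromic (A/T, C/G) variants are dropped when either
    study's EAF is missing or inside the ambiguity window (min(EAF,1-EAF) >
    0.42), since strand cannot be resolved.  Allele-mismatched variants are
    dropped.  Returns a DataFrame with ``_a``/``_b`` suffixed value columns.
    """
    if a.genome_build != b.genome_build:
        raise ValueError("studies are on different genome builds")
    m = a.df.merge(b.df, on="SNP", suffixes=("_a", "_b"))
    if m.empty:
        warnings.warn("no shared variants between studies")
        return m
    same = (m["EA_a"] == m["EA_b"]) & (m["NEA_a"] == m["NEA_b"])
    flipped = (m["EA_a"] == m["NEA_b"]) & (m["NEA_a"] == m["EA_b"])
    keep = same | flipped
    pal = m.apply(lambda r: is_palindromic(r["EA_a"], r["NEA_a"]), axis=1)
    amb = m["EAF_a"].apply(_ambiguous) | m["EAF_b"].apply(_ambiguous)
    keep &= ~(pal & amb)
    m = m[keep].copy()
    fl = flipped[keep]
    for col in ("BETA_b", "Z_b"):
        m.loc[fl, col] = -m.loc[fl, col]
    m.loc[fl, "EAF_b"] = 1.0 - m.loc[fl, "EAF_b"]
    m.loc[fl, ["EA_b", "NEA_b"]] = m.loc[fl, ["NEA_b", "EA_b"]].to_numpy()
    return m.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------

@dataclass
class LdMatrix:
    """A symmetric variant-by-variant correlation matrix with unit diagonal."""

    variant_ids: list[str]
    r: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValueError("r must be square and match variant_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("r must be symmetric within 1e-8")
        self.r = 0.5 * (self.r + self.r.T)
        np.fill_diagonal(self.r, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __len__(self):
        return len(self.variant_ids)

    def index_of(self, ids):
        return np.array([self._index[v] for v in ids], dtype=int)

    def submatrix(self, ids):
        idx = self.index_of(ids)
        return self.r[np.ix_(idx, idx)]

    def r2(self, v1, v2):
        return float(self.r[self._index[v1], self._index[v2]] ** 2)

    @classmethod
    def from_dense(cls, matrix_path, ids_path):
        ids = [ln.strip() for ln in open(ids_path) if ln.strip()]
        r = np.loadtxt(matrix_path)
        return cls(ids, np.atleast_2d(r))

    @classmethod
    def from_triplets(cls, path, sep="\t"):
        """Sparse (id_i, id_j, r) triplet text; unlisted pairs are 0."""
        trip = pd.read_csv(path, sep=sep, header=None, names=["i", "j", "r"])
        ids = sorted(set(trip["i"]) | set(trip["j"]))
        idx = {v: k for k, v in enumerate(ids)}
        r = np.eye(len(ids))
        for _, row in trip.iterrows():
            i, j = idx[row["i"]], idx[row["j"]]
            r[i, j] = r[j, i] = row["r"]
        return cls(ids, r)

    def to_dense(self, matrix_path, ids_path):
        np.savetxt(matrix_path, self.r)
        with open(ids_path, "w") as fh:
            fh.write("\n".join(self.variant_ids) + "\n")


def impute_z(observed: SummaryStats, targets, ld: LdMatrix, ridge=0.1,
             window_kb=250.0, min_r2=0.8) -> pd.DataFrame:
    """Gaussian summary-statistic imputation of Z-scores at unobserved variants.

    Under the standard multivariate-normal model for GWAS Z-scores, the
    conditional expectation of a target variant's Z given observed Z-scores is

        z_t = S_to (S_oo + ridge*I)^-1 z_o

    with imputation quality r2_t = S_to (S_oo + ridge*I)^-1 S_ot, where S is
    the LD correlation matrix.  Observed variants are restricted to a window
    (default 250 kb) around each target.  ``filter_pass`` marks r2 > min_r2
    (default 0.8), the confident-imputation retention rule.

    Raises ``np.linalg.LinAlgError`` with guidance if the observed-observed
    block is singular at ridge 0.
    """
    if not 0 <= ridge < 1:
        raise ValueError("ridge must be in [0, 1)")
    obs_df = observed.df.set_index("SNP")
    obs_ids = [v for v in ld.variant_ids if v in obs_df.index]
    pos = {}
    for v in obs_ids:
        pos[v] = obs_df.loc[v, "POS"]
    rows = []
    for t in targets:
        if t not in ld._index:
            raise KeyError(f"target {t} not in LD matrix")
        t_pos = pos.get(t, None)
        use = obs_ids
        if t_pos is not None and window_kb is not None:
            use = [v for v in obs_ids
                   if abs(pos[v] - t_pos) <= window_kb * 1000.0] or obs_ids
        z_o = obs_df.loc[use, "Z"].to_numpy(dtype=float)
        S_oo = ld.submatrix(use) + ridge * np.eye(len(use))
        s_to = ld.r[ld._index[t], ld.index_of(use)]
        try:
            w = np.linalg.solve(S_oo, np.column_stack([z_o, s_to]))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular LD system for target {t}; increase ridge "
                f"(currently {ridge})") from err
        z_t = float(s_to @ w[:, 0])
        r2_t = float(s_to @ w[:, 1])
        rows.append((t, z_t, r2_t, r2_t > min_r2))
    return pd.DataFrame(rows, columns=["SNP", "Z_IMP", "R2_IMP", "filter_pass"])
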