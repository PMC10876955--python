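import numpy as np
import pandas as pd
import pytest

from postgwas import SummaryStats, LdMatrix, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sumstats(ids, betas, ses, study="s", eaf=None, pos=None, chrom="1",
                  ea="A", nea="G", n=10000):
    k = len(ids)
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    from postgwas.sumstats import z_to_p
    z = betas / ses
    df = pd.DataFrame({
        "SNP": ids,
        "CHR": chrom,
        "POS": pos if pos is not None else np.arange(1, k + 1) * 1000,
        "EA": [ea] * k if isinstance(ea, str) else ea,
        "NEA": [nea] * k if isinstance(nea, str) else nea,
        "EAF": eaf if eaf is not None else 0.3,
        "BETA": betas, "SE": ses, "Z": z, "P": z_to_p(z), "N": n,
    })
    return SummaryStats(df, study_name=study)


@pytest.fixture
def small_cfg():
    return SynthConfig(seed=11, n_blocks=10, block_size=10,
                       cohort_ns=(10000, 8000))


@pytest.fixture
def toy_ld():
    r = np.array([[1.0, 0.5, 0.3],
                  [0.5, 1.0, 0.4],
                  [0.3, 0.4, 1.0]])
    return LdMatrix(["v1", "v2", "v3"], r)
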