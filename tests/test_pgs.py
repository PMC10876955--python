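"""Clumping, C+T and posterior-weighted scores, scoring, evaluation."""

import numpy as np
import pandas as pd
import pytest

import postgwas as pg
from tests.conftest import make_sumstats


def ld_from_r2(ids, pairs):
    """Build an LdMatrix from {(i, j): r2} pairs (r = sqrt(r2))."""
    n = len(ids)
    r = np.eye(n)
    idx = {v: k for k, v in enumerate(ids)}
    for (a, b), r2 in pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = np.sqrt(r2)
    return pg.LdMatrix(ids, r)


class TestClump:
    def test_linked_pair_keeps_smaller_p(self):
        ss = make_sumstats(["a", "b"], [0.08, 0.05], [0.01, 0.01],
                           pos=[1000, 2000])
        ld = ld_from_r2(["a", "b"], {("a", "b"): 0.9})
        assert pg.clump(ss, ld) == ["a"]

    def test_unlinked_all_retained(self):
        ss = make_sumstats(["a", "b", "c"], [0.08, 0.05, 0.03],
                           [0.01, 0.01, 0.01], pos=[1000, 2000, 3000])
        ld = ld_from_r2(["a", "b", "c"], {})
        assert set(pg.clump(ss, ld)) == {"a", "b", "c"}

    def test_five_variant_greedy_trace(self):
        # p ascending: a, b, c, d, e. a removes b (r2 .5); c removes d;
        # e is beyond the window of everything.
        ss = make_sumstats(["a", "b", "c", "d", "e"],
                           [0.10, 0.09, 0.08, 0.07, 0.06],
                           [0.01] * 5,
                           pos=[1_000, 2_000, 50_000, 51_000, 900_000])
        ld = ld_from_r2(list("abcde"),
                        {("a", "b"): 0.5, ("c", "d"): 0.7, ("d", "e"): 0.9})
        assert pg.clump(ss, ld, r2_max=0.1) == ["a", "c", "e"]

    def test_variant_missing_from_ld_warned_unlinked(self):
        ss = make_sumstats(["a", "zzz"], [0.08, 0.05], [0.01, 0.01],
                           pos=[1000, 1500])
        ld = ld_from_r2(["a"], {})
        with pytest.warns(UserWarning, match="unlinked"):
            kept = pg.clump(ss, ld)
        assert set(kept) == {"a", "zzz"}


class TestCtScore:
    def test_threshold_one_no_ld_keeps_all(self):
        ss = make_sumstats(["a", "b", "c"], [0.05, 0.01, 0.002],
                           [0.01, 0.01, 0.01], pos=[1, 1_000_000, 2_000_000])
        models = pg.build_ct_score(ss, ld_from_r2(["a", "b", "c"], {}),
                                   p_thresholds=(1.0,))
        assert len(models[1.0]) == 3

    def test_genome_wide_threshold_subset(self, small_cfg):
        a, _, _ = pg.gen_gwas_pair(small_cfg)
        ld = pg.gen_ld_blocks(small_cfg)
        models = pg.build_ct_score(a, ld, p_thresholds=(5e-8, 1.0))
        gw = models[5e-8].weights
        assert (a.df.set_index("SNP").loc[gw["SNP"], "P"] < 5e-8).all()

    def test_retention_nested_across_thresholds(self, small_cfg):
        a, _, _ = pg.gen_gwas_pair(small_cfg)
        ld = pg.gen_ld_blocks(small_cfg)
        models = pg.build_ct_score(a, ld)
        sets = [set(models[t].weights["SNP"]) for t in pg.CT_THRESHOLDS]
        for s1, s2 in zip(sets, sets[1:]):
            assert s1 <= s2

    def test_invalid_threshold_raises(self, small_cfg):
        a, _, _ = pg.gen_gwas_pair(small_cfg)
        with pytest.raises(ValueError):
            pg.build_ct_score(a, pg.gen_ld_blocks(small_cfg), p_thresholds=(0.0,))


class TestAbfScore:
    def test_single_variant_block_full_weight(self):
        ss = make_sumstats(["a"], [0.08], [0.01])
        model = pg.build_abf_score(ss, [["a"]])
        assert model.weights.loc[0, "weight"] == pytest.approx(0.08)

    def test_identical_evidence_splits_weight(self):
        m = 4
        ss = make_sumstats([f"v{i}" for i in range(m)], [0.08] * m, [0.01] * m)
        model = pg.build_abf_score(ss, [[f"v{i}" for i in range(m)]])
        np.testing.assert_allclose(model.weights["weight"], 0.08 / m)

    def test_two_block_composition_oracle(self):
        ids = ["a", "b", "c", "d", "e"]
        betas = [0.08, 0.02, 0.05, 0.04, 0.01]
        ses = [0.01, 0.01, 0.012, 0.02, 0.01]
        ss = make_sumstats(ids, betas, ses)
        blocks = [["a", "b"], ["c", "d", "e"]]
        model = pg.build_abf_score(ss, blocks)
        w = model.weights.set_index("SNP")["weight"]
        for block in blocks:
            sub = ss.df.set_index("SNP").loc[block]
            fr = pg.finemap_region(block, sub["BETA"].to_numpy(),
                                   sub["SE"].to_numpy())
            for v, pip, beta in zip(block, fr.pip, sub["BETA"]):
                assert w[v] == pytest.approx(beta * pip, rel=1e-12)

    def test_block_weight_mass_bounded(self, small_cfg):
        a, _, _ = pg.gen_gwas_pair(small_cfg)
        blocks = [a.df["SNP"].tolist()[i * 10:(i + 1) * 10] for i in range(10)]
        model = pg.build_abf_score(a, blocks)
        w = model.weights.set_index("SNP")["weight"]
        beta = a.df.set_index("SNP")["BETA"]
        for block in blocks:
            assert np.abs(w[block]).sum() <= np.abs(beta[block]).max() + 1e-12


class TestScoreIndividuals:
    def _model(self, ids, weights, eaf=None):
        df = pd.DataFrame({"SNP": ids, "EA": "A", "weight": weights})
        if eaf is not None:
            df["EAF"] = eaf
        return pg.PgsModel("ct", df)

    def test_zero_weights(self):
        dos = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        scores = pg.score_individuals(self._model(["a", "b"], [0.0, 0.0]), dos)
        np.testing.assert_allclose(scores, 0.0)

    def test_single_variant_dosage_scaling(self):
        dos = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        scores = pg.score_individuals(self._model(["a"], [0.5]), dos)
        np.testing.assert_allclose(scores, [0.0, 0.5, 1.0])

    def test_matches_double_loop_oracle(self, rng):
        n, m = 20, 50
        ids = [f"v{j}" for j in range(m)]
        D = pd.DataFrame(rng.uniform(0, 2, (n, m)), columns=ids)
        w = rng.normal(0, 0.1, m)
        scores = pg.score_individuals(self._model(ids, w), D)
        oracle = np.array([sum(D.iloc[i, j] * w[j] for j in range(m))
                           for i in range(n)])
        np.testing.assert_allclose(scores, oracle, atol=1e-12)

    def test_missing_dosage_mean_imputed(self):
        dos = pd.DataFrame({"a": [np.nan, 2.0]})
        scores = pg.score_individuals(self._model(["a"], [1.0], eaf=[0.3]), dos)
        np.testing.assert_allclose(scores, [0.6, 2.0])

    def test_no_overlap_raises(self):
        dos = pd.DataFrame({"x": [1.0]})
        with pytest.raises(ValueError):
            pg.score_individuals(self._model(["a"], [1.0]), dos)

    def test_linearity_in_dosages(self, rng):
        ids = [f"v{j}" for j in range(10)]
        model = self._model(ids, rng.normal(size=10))
        d1 = pd.DataFrame(rng.uniform(0, 1, (5, 10)), columns=ids)
        d2 = pd.DataFrame(rng.uniform(0, 1, (5, 10)), columns=ids)
        s = pg.score_individuals
        np.testing.assert_allclose(s(model, d1 + d2),
                                   s(model, d1) + s(model, d2), atol=1e-10)


class TestEvaluatePgs:
    def test_independent_pgs_near_zero(self, rng):
        n = 2000
        y = rng.normal(size=n)
        s = rng.normal(size=n)
        assert abs(pg.evaluate_pgs(s, y, seed=3)) < 0.01

    def test_recovers_planted_r2(self):
        deltas = []
        for i in range(200):
            cfg = pg.SynthConfig(seed=6000 + i)
            dos, pheno, w = pg.gen_genotypes(cfg, n_individuals=1600,
                                             n_snps=50, target_r2=0.02)
            model = pg.PgsModel("ct", pd.DataFrame(
                {"SNP": dos.columns, "EA": "A", "weight": w.values}))
            scores = pg.score_individuals(model, dos)
            deltas.append(pg.evaluate_pgs(scores, pheno, seed=i))
        assert abs(np.mean(deltas) - 0.02) < 0.01

    def test_noise_covariate_leaves_delta_unchanged(self, rng):
        diffs = []
        for i in range(50):
            r = np.random.default_rng(i)
            n = 800
            s = r.normal(size=n)
            y = 0.14 * s + r.normal(size=n)
            noise_cov = r.normal(size=(n, 1))
            d0 = pg.evaluate_pgs(s, y, seed=i)
            d1 = pg.evaluate_pgs(s, y, covariates=noise_cov, seed=i)
            diffs.append(d1 - d0)
        assert abs(np.mean(diffs)) < 0.005
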