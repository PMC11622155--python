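"""Outlier scans: oracle equivalence, null calibration, consensus rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import geascan as g
from geascan.scans import ScanResult, outlier_count_grid


def _env_noise(sites, n_vars=1, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(len(sites), n_vars)),
        index=sites,
        columns=[f"v{k}" for k in range(n_vars)],
    )


class TestRda:
    def test_loadings_match_brute_force_oracle(self):
        """Explicit projection + eigendecomposition on a 10 x 20 instance."""
        m, _ = g.gen_admixed_genotypes(5, 2, 20, fst=0.3, seed=31)
        env = _env_noise(sorted(set(m.ind_meta["site"])), n_vars=2, seed=1)
        res = g.rda_scan(m, env, n_permutations=9, seed=2)
        loadings = res.metadata["loadings"]

        # oracle: hat-matrix projection of centred genotypes, then the
        # eigenvectors of the fitted values' cross-product matrix
        Y = m.calls.astype(float)
        Y = Y - Y.mean(axis=0)
        X = env.loc[m.ind_meta["site"]].to_numpy()
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        Yhat = H @ Y
        w, V = np.linalg.eigh(Yhat.T @ Yhat)
        order = np.argsort(w)[::-1][: loadings.shape[1]]
        V = V[:, order]
        for k in range(loadings.shape[1]):
            assert min(
                np.abs(loadings[:, k] - V[:, k]).max(),
                np.abs(loadings[:, k] + V[:, k]).max(),
            ) < 1e-8

    def test_null_outlier_fraction_near_normal_tail(self):
        m, _ = g.gen_admixed_genotypes(10, 20, 4000, fst=0.0, seed=32)
        env = _env_noise(sorted(set(m.ind_meta["site"])), n_vars=1, seed=3)
        res = g.rda_scan(m, env, n_permutations=9, seed=4)
        frac = len(res.outliers) / m.n_loci
        expected = 2 * sps.norm.sf(2.5)  # ~0.0124 per axis, one axis here
        assert frac == pytest.approx(expected, abs=0.006)

    def test_planted_loci_are_outliers_and_model_significant(self, planted_dataset, env_table):
        m, truth = planted_dataset
        res = g.rda_scan(m, env_table[["AvTemp"]], n_permutations=999, seed=5)
        planted = set(m.locus_meta.index[truth.adaptive_loci])
        assert len(planted & res.outliers) / len(planted) >= 0.9
        # permutation floor with 999 permutations
        assert res.metadata["model_p"] <= 0.001

    def test_too_many_predictors_raise(self, small_admixed):
        m, _ = small_admixed
        env = _env_noise(sorted(set(m.ind_meta["site"])), n_vars=5, seed=6)
        with pytest.raises(ValueError):
            g.rda_scan(m, env)


class TestPcadapt:
    def test_null_gif_and_uncorrected_count(self):
        m, _ = g.gen_admixed_genotypes(1, 200, 3000, fst=0.0, seed=33)
        res = g.pcadapt_scan(m, K=1, alpha=0.05, mode="bonferroni")
        assert 0.8 <= res.metadata["gif"] <= 1.2
        # uncorrected outliers at alpha should appear at roughly that rate
        raw = (res.stats["pvalue"] < 0.05).mean()
        assert raw == pytest.approx(0.05, abs=0.02)

    def test_fixed_difference_locus_has_smallest_p(self):
        m, _ = g.gen_admixed_genotypes(2, 30, 500, fst=0.02, seed=34)
        sites = m.ind_meta["site"].to_numpy()
        m.calls[:, 0] = np.where(sites == "deme_01", 0, 2)
        res = g.pcadapt_scan(m, K=1)
        assert res.stats["pvalue"].idxmin() == m.locus_meta.index[0]

    def test_duplicate_locus_columns_identical_statistics(self, small_admixed):
        m, _ = small_admixed
        m = m.copy()
        m.calls[:, 1] = m.calls[:, 0]
        res = g.pcadapt_scan(m, K=2)
        a, b = res.stats.iloc[0], res.stats.iloc[1]
        assert a["statistic"] == pytest.approx(b["statistic"], abs=1e-10)

    def test_mode_validation(self, small_admixed):
        m, _ = small_admixed
        with pytest.raises(ValueError):
            g.pcadapt_scan(m, K=2, mode="banana")


class TestLfmm:
    def test_k0_reduces_to_ols(self, small_admixed):
        m, _ = small_admixed
        env = _env_noise(sorted(set(m.ind_meta["site"])), n_vars=1, seed=7)
        res = g.lfmm_scan(m, env, K=0)
        x = env.loc[m.ind_meta["site"], "v0"].to_numpy()
        x = (x - x.mean()) / x.std()
        xc = x - x.mean()
        slopes = xc @ m.calls.astype(float) / (xc @ xc)
        got = res.stats.set_index("locus")["beta"]
        assert np.abs(got.to_numpy() - slopes).max() < 1e-8

    def test_null_gif_and_fdr(self):
        m, _ = g.gen_admixed_genotypes(13, 23, 4000, fst=0.0, seed=35)
        env = _env_noise(sorted(set(m.ind_meta["site"])), n_vars=1, seed=8)
        res = g.lfmm_scan(m, env, K=2)
        gif = res.metadata["gif"]["v0"]
        assert 0.8 <= gif <= 1.2
        # under the global null every declared outlier is false; the
        # BH + raw-p conjunction should declare (almost) none
        assert len(res.outliers) <= 2

    def test_planted_sensitivity(self, planted_dataset, env_table):
        m, truth = planted_dataset
        res = g.lfmm_scan(m, env_table, K=5)
        planted = set(m.locus_meta.index[truth.adaptive_loci])
        sens = len(planted & res.outliers) / len(planted)
        assert sens >= 0.8
        # the planted variable collects the most outliers
        assert max(res.per_variable, key=res.per_variable.get) == "AvTemp"

    def test_missing_values_raise(self, small_admixed):
        m, _ = small_admixed
        d = g.degrade(m, missing_rate=0.1, seed=36)
        env = _env_noise(sorted(set(m.ind_meta["site"])), seed=9)
        with pytest.raises(ValueError, match="imput"):
            g.lfmm_scan(d, env, K=2)

    def test_pvalues_uniform_under_null(self):
        m, _ = g.gen_admixed_genotypes(5, 40, 3000, fst=0.0, seed=37)
        env = _env_noise(sorted(set(m.ind_meta["site"])), n_vars=1, seed=10)
        res = g.lfmm_scan(m, env, K=2)
        ks = sps.kstest(res.stats["pvalue"], "uniform").statistic
        crit_1pct = 1.63 / np.sqrt(len(res.stats))
        assert ks < crit_1pct


class TestConsensus:
    @staticmethod
    def fake(method, loci):
        return ScanResult(method=method, stats=pd.DataFrame(), outliers=set(loci))

    def test_disjoint_sets_empty_consensus(self):
        res = [self.fake("a", "xy"), self.fake("b", "zw"), self.fake("c", "uv")]
        assert g.consensus(res, min_methods=2).consensus == set()

    def test_enumerated_example(self):
        res = [self.fake("m1", {"a", "b"}), self.fake("m2", {"b", "c"}), self.fake("m3", {"c"})]
        cs = g.consensus(res, min_methods=2)
        assert cs.consensus == {"b", "c"}

    def test_min_methods_one_gives_union(self):
        res = [self.fake("m1", {"a"}), self.fake("m2", {"b"})]
        assert g.consensus(res, min_methods=1).consensus == {"a", "b"}

    def test_monotone_in_min_methods(self):
        res = [
            self.fake("m1", {"a", "b", "c"}),
            self.fake("m2", {"b", "c"}),
            self.fake("m3", {"c", "d"}),
        ]
        sets = [g.consensus(res, min_methods=k).consensus for k in (1, 2, 3)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_requires_two_results(self):
        with pytest.raises(ValueError):
            g.consensus([self.fake("m1", {"a"})])


def test_outlier_count_grid_shape(planted_dataset, env_table):
    m, _ = planted_dataset
    lf = g.lfmm_scan(m, env_table[["AvTemp", "MaxTemp"]], K=3)
    rda = g.rda_scan(m, env_table[["AvTemp", "MaxTemp"]], n_permutations=9, seed=11)
    grid = outlier_count_grid([lf, rda])
    assert set(grid.index) == {"lfmm", "rda"}
    assert set(grid.columns) == {"AvTemp", "MaxTemp"}
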