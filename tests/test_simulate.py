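"""Generator contracts: shapes, determinism, F_ST recovery, degradation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import pearsonr

import geascan as g
from geascan.containers import MISSING


def wc_fst_oracle(calls, deme_labels):
    """Brute-force Weir-Cockerham theta: per-locus variance components
    computed with explicit python loops, independent of the package path."""
    demes = sorted(set(deme_labels))
    r = len(demes)
    num = den = 0.0
    for j in range(calls.shape[1]):
        n_i, p_i, h_i = [], [], []
        for d in demes:
            sub = [c for c, lab in zip(calls[:, j], deme_labels) if lab == d and c != MISSING]
            if not sub:
                break
            n_i.append(len(sub))
            p_i.append(sum(sub) / (2 * len(sub)))
            h_i.append(sum(1 for c in sub if c == 1) / len(sub))
        else:
            n_bar = sum(n_i) / r
            if n_bar <= 1:
                continue
            n_tot = sum(n_i)
            nc = (n_tot - sum(n**2 for n in n_i) / n_tot) / (r - 1)
            p_bar = sum(n * p for n, p in zip(n_i, p_i)) / n_tot
            s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
            h_bar = sum(n * h for n, h in zip(n_i, h_i)) / n_tot
            a = (n_bar / nc) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    return num / den


class TestGenerator:
    def test_shape_contract_and_no_missing(self):
        m, truth = g.gen_admixed_genotypes(13, 26, 3277, fst=0.05, seed=1)
        assert m.calls.shape == (338, 3277)
        assert not m.missing_mask().any()
        assert truth.k_true == 13
        assert m.locus_meta.index.is_unique
        # DArT-style locus ids
        assert m.locus_meta.index.str.match(r"^\d+-\d+-[ACGT]/[ACGT]$").all()

    def test_determinism(self):
        a, _ = g.gen_admixed_genotypes(4, 10, 200, fst=0.1, seed=7)
        b, _ = g.gen_admixed_genotypes(4, 10, 200, fst=0.1, seed=7)
        assert np.array_equal(a.calls, b.calls)
        assert list(a.locus_meta.index) == list(b.locus_meta.index)

    def test_fst_zero_means_no_differentiation(self):
        m, _ = g.gen_admixed_genotypes(5, 30, 5000, fst=0.0, seed=3)
        assert abs(g.weir_cockerham_fst(m)) < 0.01

    def test_fst_recovery_against_oracle(self):
        m, _ = g.gen_admixed_genotypes(5, 30, 5000, fst=0.1, seed=2)
        fst_pkg = g.weir_cockerham_fst(m)
        fst_ora = wc_fst_oracle(m.calls, list(m.ind_meta["site"]))
        assert abs(fst_pkg - 0.1) < 0.02
        assert abs(fst_pkg - fst_ora) < 1e-10

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            g.gen_admixed_genotypes(0, 10, 100, 0.1, seed=1)
        with pytest.raises(ValueError):
            g.gen_admixed_genotypes(2, 10, 100, 1.0, seed=1)


class TestPlantEnvEffects:
    def test_beta_zero_redraw_is_reproducible(self):
        m, truth = g.gen_admixed_genotypes(4, 15, 300, fst=0.1, seed=5)
        truth.adaptive_loci = [0, 5, 10]
        truth.beta = 0.0
        env = np.arange(4.0)
        a = g.plant_env_effects(m, truth, env, seed=9)
        b = g.plant_env_effects(m, truth, env, seed=9)
        assert np.array_equal(a.calls, b.calls)
        untouched = np.setdiff1d(np.arange(300), truth.adaptive_loci)
        assert np.array_equal(a.calls[:, untouched], m.calls[:, untouched])

    def test_two_deme_closed_form_frequencies(self):
        m, truth = g.gen_admixed_genotypes(2, 4000, 3, fst=0.0, seed=6)
        truth.deme_freqs = np.full((2, 3), 0.5)
        truth.adaptive_loci = [0, 1, 2]
        truth.beta = 3.0
        out = g.plant_env_effects(m, truth, np.array([1.0, -1.0]), seed=7)
        sites = out.ind_meta["site"].to_numpy()
        f_a = out.calls[sites == "deme_01"].mean(axis=0) / 2
        f_b = out.calls[sites == "deme_02"].mean(axis=0) / 2
        assert np.allclose(f_a, expit(3.0), atol=0.02)
        assert np.allclose(f_b, expit(-3.0), atol=0.02)

    def test_planted_cline_correlates_with_gradient(self, env_table):
        m, truth = g.gen_admixed_genotypes(
            13, 30, 80, fst=0.02, seed=8, site_names=list(env_table.index)
        )
        truth.adaptive_loci = list(range(40))
        truth.beta = 1.5
        avtemp = env_table["AvTemp"].to_numpy()
        out = g.plant_env_effects(m, truth, avtemp, seed=9)
        sites = out.ind_meta["site"].to_numpy()
        rs = []
        for j in truth.adaptive_loci:
            freqs = [out.calls[sites == s, j].mean() / 2 for s in env_table.index]
            rs.append(pearsonr(freqs, avtemp)[0])
        rs = np.array(rs)
        assert (rs > 0).all()
        assert (np.abs(rs) > 0.5).mean() > 0.5

    def test_env_length_mismatch_raises(self):
        m, truth = g.gen_admixed_genotypes(3, 5, 50, fst=0.1, seed=1)
        truth.adaptive_loci = [0]
        with pytest.raises(ValueError):
            g.plant_env_effects(m, truth, np.zeros(4), seed=1)


class TestDegrade:
    def test_no_missing_gives_unit_call_rates(self, small_admixed):
        m, _ = small_admixed
        d = g.degrade(m, missing_rate=0.0, seed=1)
        assert (d.locus_meta["call_rate"] == 1.0).all()

    def test_zero_replicate_error_gives_zero_distance(self, small_admixed):
        m, _ = small_admixed
        d = g.degrade(m, replicate_pairs=4, replicate_error=0.0, seed=2)
        distances = g.replicate_error_rate(d)["distance"]
        assert (distances == 0.0).all()

    def test_missing_rate_recovered(self):
        m, _ = g.gen_admixed_genotypes(13, 26, 3277, fst=0.05, seed=4)
        d = g.degrade(m, missing_rate=0.2, seed=5)
        assert abs(d.missing_mask().mean() - 0.2) < 0.01
        # metadata call rate equals 1 - per-locus missing fraction
        assert np.allclose(
            d.locus_meta["call_rate"], 1 - d.missing_mask().mean(axis=0)
        )

    def test_replicate_error_rate_recovered(self, small_admixed):
        m, _ = small_admixed
        d = g.degrade(m, replicate_pairs=15, replicate_error=0.05, seed=6)
        distances = g.replicate_error_rate(d, threshold=1.0)["distance"]
        se = np.sqrt(0.05 * 0.95 / m.n_loci)
        assert abs(distances.mean() - 0.05) < 4 * se

    def test_clones_are_exact_copies(self, small_admixed):
        m, _ = small_admixed
        d = g.degrade(m, clone_pairs=3, seed=7)
        clones = d.ind_meta.index[d.ind_meta.index.str.endswith("_clone")]
        for name in clones:
            src = name.removesuffix("_clone")
            i, k = d.ind_meta.index.get_loc(src), d.ind_meta.index.get_loc(name)
            assert np.array_equal(d.calls[i], d.calls[k])


class TestEnvFixture:
    def test_dimensions_and_values(self, env_table):
        assert env_table.shape == (13, 9)
        assert env_table.loc["Wallis Lake", "AvTemp"] == 23.39
        assert env_table.loc["Pambula", "pHRange"] == 0.19
        assert list(env_table.columns) == [
            "AvTemp", "MaxTemp", "TempRange", "pHRange", "MinpH",
            "MaxSal", "AvSal", "TurbRange", "MinTurb",
        ]
        assert not env_table.isna().any().any()

    def test_csv_round_trip(self, env_table, tmp_path):
        from geascan import io

        path = tmp_path / "env.csv"
        io.write_env_csv(env_table, path)
        back = io.read_env_csv(path)
        pd.testing.assert_frame_equal(back, env_table)
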