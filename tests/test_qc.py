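"""Replicate-error estimation, sequential filtering, NN imputation."""

import numpy as np
import pandas as pd
import pytest

import geascan as g
from geascan.containers import GenotypeMatrix, MISSING, bitwise_distance


def toy_matrix(calls, sites=None, **locus_cols):
    calls = np.asarray(calls, dtype=np.int16)
    n, L = calls.shape
    ind_meta = pd.DataFrame(
        {
            "site": sites or ["s1"] * n,
            "replicate_pair": pd.array([pd.NA] * n, dtype="Int64"),
            "clone_id": pd.array([pd.NA] * n, dtype="Int64"),
        },
        index=[f"i{k}" for k in range(n)],
    )
    locus_meta = pd.DataFrame(
        {
            "ref": ["A"] * L,
            "alt": ["C"] * L,
            "call_rate": locus_cols.get("call_rate", np.ones(L)),
            "reproducibility": locus_cols.get("reproducibility", np.ones(L)),
            "mean_depth": locus_cols.get("mean_depth", np.full(L, 10.0)),
        },
        index=[f"L{k}" for k in range(L)],
    )
    return GenotypeMatrix(calls, ind_meta, locus_meta)


class TestReplicateError:
    def test_identical_replicates_zero_distance(self):
        m = toy_matrix([[0, 1, 2], [0, 1, 2]])
        res = g.replicate_error_rate(m, pairs=[("i0", "i1")])
        assert res.loc[0, "distance"] == 0.0
        assert not res.loc[0, "flagged"]

    def test_one_in_hundred_is_flagged(self):
        calls = np.zeros((2, 100), dtype=np.int16)
        calls[1, 0] = 1
        m = toy_matrix(calls)
        res = g.replicate_error_rate(m, pairs=[("i0", "i1")])
        assert res.loc[0, "distance"] == pytest.approx(0.01)
        assert res.loc[0, "flagged"]

    def test_missing_excluded_from_denominator(self):
        # 3 differing calls over 950 jointly callable loci, 50 missing in one
        calls = np.zeros((2, 1000), dtype=np.int16)
        calls[1, :3] = 2
        calls[0, 950:] = MISSING
        m = toy_matrix(calls)
        res = g.replicate_error_rate(m, pairs=[("i0", "i1")])
        assert res.loc[0, "distance"] == pytest.approx(3 / 950)
        assert not res.loc[0, "flagged"]

    def test_no_shared_loci_raises(self):
        calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int16)
        m = toy_matrix(calls)
        with pytest.raises(ValueError):
            g.replicate_error_rate(m, pairs=[("i0", "i1")])

    def test_per_allele_distance_halves_het_differences(self):
        assert bitwise_distance(np.array([0, 2]), np.array([1, 2]), per_allele=True) == 0.25
        assert bitwise_distance(np.array([0, 2]), np.array([1, 2])) == 0.5


class TestFilterPipeline:
    def test_low_callrate_locus_removed_first(self):
        calls = np.zeros((10, 2), dtype=np.int16)
        calls[:4, 0] = MISSING  # locus 0 call rate 0.6 < 0.67
        calls[0, 1] = 1  # keep locus 1 polymorphic
        m = toy_matrix(calls)
        m.refresh_call_rates()
        out, report = g.filter_pipeline(m, maf=0.0)
        assert list(out.locus_meta.index) == ["L1"]
        assert report.to_frame().set_index("step").loc["locus_callrate", "n_loci"] == 1

    def test_monomorphic_locus_removed_by_maf(self):
        calls = np.array([[0, 1], [0, 1], [0, 0], [0, 2]], dtype=np.int16)
        m = toy_matrix(calls)
        out, _ = g.filter_pipeline(m)
        assert list(out.locus_meta.index) == ["L1"]

    def test_depth_window(self):
        calls = np.array([[0, 1, 1], [1, 0, 2], [2, 1, 0], [1, 2, 1]], dtype=np.int16)
        m = toy_matrix(calls, mean_depth=np.array([10.0, 60.0, 1.0]))
        out, report = g.filter_pipeline(m)
        assert list(out.locus_meta.index) == ["L0"]
        steps = report.to_frame().set_index("step")
        assert steps.loc["read_depth", "n_loci"] == 1
        assert steps.loc["reproducibility", "n_loci"] == 3

    def test_individual_callrate_then_locus_rates_recomputed(self):
        calls = np.array(
            [[0, 1, 1, 0], [MISSING, MISSING, MISSING, 0], [2, 1, 0, 1], [1, 0, 2, 1]],
            dtype=np.int16,
        )
        m = toy_matrix(calls)
        m.refresh_call_rates()
        out, _ = g.filter_pipeline(m, ind_callrate=0.5, maf=0.0)
        assert "i1" not in out.ind_meta.index
        assert (out.locus_meta["call_rate"] == 1.0).all()

    def test_idempotence_and_monotonicity(self, small_admixed):
        m, _ = small_admixed
        d = g.degrade(m, missing_rate=0.25, seed=11)
        once, _ = g.filter_pipeline(d)
        twice, _ = g.filter_pipeline(once)
        assert set(once.locus_meta.index) <= set(d.locus_meta.index)
        assert list(twice.locus_meta.index) == list(once.locus_meta.index)
        assert list(twice.ind_meta.index) == list(once.ind_meta.index)

    def test_empty_result_names_the_step(self):
        calls = np.array([[MISSING, MISSING], [MISSING, MISSING]], dtype=np.int16)
        m = toy_matrix(calls)
        m.refresh_call_rates()
        with pytest.raises(ValueError, match="locus_callrate"):
            g.filter_pipeline(m)


class TestImputation:
    def test_no_missing_returned_unchanged(self, small_admixed):
        m, _ = small_admixed
        out = g.impute_nearest_neighbour(m)
        assert np.array_equal(out.calls, m.calls)

    def test_imputes_from_identical_neighbour(self):
        calls = np.array(
            [[0, 1, 2, MISSING], [0, 1, 2, 1], [2, 2, 0, 0]], dtype=np.int16
        )
        out = g.impute_nearest_neighbour(toy_matrix(calls))
        assert out.calls[0, 3] == 1

    def test_falls_through_when_nearest_lacks_a_call(self):
        # i1 is nearest to i0 but missing at the target locus; i2 is next
        calls = np.array(
            [
                [0, 1, 2, 0, MISSING],
                [0, 1, 2, 0, MISSING],
                [0, 1, 2, 1, 2],
            ],
            dtype=np.int16,
        )
        out = g.impute_nearest_neighbour(toy_matrix(calls))
        assert out.calls[0, 4] == 2
        assert out.calls[1, 4] == 2

    def test_never_alters_non_missing(self, small_admixed):
        m, _ = small_admixed
        d = g.degrade(m, missing_rate=0.3, seed=12)
        out = g.impute_nearest_neighbour(d)
        keep = ~d.missing_mask()
        assert np.array_equal(out.calls[keep], d.calls[keep])
        assert not out.missing_mask().any()

    def test_all_missing_locus_raises(self):
        calls = np.array([[0, MISSING], [1, MISSING]], dtype=np.int16)
        with pytest.raises(ValueError):
            g.impute_nearest_neighbour(toy_matrix(calls))


def test_drop_replicates_and_dedup_clones(small_admixed):
    m, _ = small_admixed
    d = g.degrade(m, replicate_pairs=3, clone_pairs=2, seed=13)
    assert d.n_ind == m.n_ind + 5
    assert g.drop_replicates(d).n_ind == m.n_ind + 2
    assert g.dedup_clones(g.drop_replicates(d)).n_ind == m.n_ind
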