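"""Filtering, normalization, dispersion, NB Wald test and BH adjustment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detoxshift.de import (
    adjust_bh,
    call_de,
    estimate_dispersion,
    filter_low_counts,
    nb_wald_test,
    normalize_counts,
    regularized_log,
    size_factors_median_ratio,
)
from detoxshift.types import CountMatrix, SampleDesign, ValidationError

from oracles import bh_stepup


def make_counts(arr, n_species=1, plants=("eggplant",), reps=None):
    arr = np.asarray(arr)
    n_samples = arr.shape[1]
    species = []
    plant_col = []
    rep_col = []
    per_cell = n_samples // (n_species * len(plants))
    i = 0
    for s in range(n_species):
        for p in plants:
            for r in range(per_cell):
                species.append(f"S{s}")
                plant_col.append(p)
                rep_col.append(r + 1)
                i += 1
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(n_samples)],
                "species": species,
                "plant": plant_col,
                "replicate": rep_col,
            }
        )
    )
    values = pd.DataFrame(
        arr,
        index=pd.Index([f"g{k}" for k in range(arr.shape[0])], name="gene_id"),
        columns=design.sample_ids,
    )
    return CountMatrix(values, design)


class TestFilter:
    def test_72_sample_threshold_is_three(self, design6x4):
        n = 72
        base = np.ones((3, n), dtype=int)
        base[0, :3] = 10  # >=10 in exactly 3 samples -> kept
        base[1, :2] = 10  # only 2 samples -> dropped
        base[2, :] = 0  # all zero -> dropped
        values = pd.DataFrame(
            base, index=["keep", "drop", "zero"], columns=design6x4.sample_ids
        )
        counts = CountMatrix(values, design6x4)
        kept = filter_low_counts(counts)
        assert kept.gene_ids == ["keep"]
        assert math.ceil(0.04 * n) == 3

    def test_all_tens_retained(self):
        counts = make_counts(np.full((1, 4), 10), n_species=2)
        assert filter_low_counts(counts).gene_ids == ["g0"]

    def test_empty_result_warns(self):
        counts = make_counts(np.zeros((2, 4), dtype=int), n_species=2)
        with pytest.warns(UserWarning):
            out = filter_low_counts(counts)
        assert out.n_genes == 0


class TestSizeFactors:
    def test_identical_columns_normalize_to_one(self):
        counts = make_counts(np.tile([[10], [20], [40]], (1, 4)), n_species=2)
        np.testing.assert_allclose(size_factors_median_ratio(counts).to_numpy(), 1.0)

    def test_scale_equivariance(self):
        arr = np.array([[10, 20], [30, 60], [7, 14], [100, 200]])
        counts = make_counts(arr, n_species=2, reps=1)
        f = size_factors_median_ratio(counts)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_hand_computed_five_by_four(self):
        arr = np.array(
            [
                [10, 20, 30, 40],
                [5, 5, 5, 5],
                [8, 16, 8, 16],
                [100, 50, 100, 50],
                [12, 24, 36, 48],
            ]
        )
        counts = make_counts(arr, n_species=2)
        # independent spreadsheet-style computation
        logg = np.log(arr).mean(axis=1)
        expected = np.exp(np.median(np.log(arr) - logg[:, None], axis=0))
        np.testing.assert_allclose(
            size_factors_median_ratio(counts).to_numpy(), expected
        )

    def test_no_all_positive_gene_rejected(self):
        arr = np.array([[0, 5, 5, 5], [5, 0, 5, 5]])
        counts = make_counts(arr, n_species=2)
        with pytest.raises(ValidationError, match="pseudocount"):
            size_factors_median_ratio(counts)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(1, 100, size=(20, 4))
        counts = make_counts(arr, n_species=2)
        f = size_factors_median_ratio(counts).to_numpy()
        perm = [2, 0, 3, 1]
        counts_p = make_counts(arr[:, perm], n_species=2)
        f_p = size_factors_median_ratio(counts_p).to_numpy()
        np.testing.assert_allclose(f_p, f[perm])


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        counts = make_counts(np.full((3, 6), 50), n_species=2, reps=3)
        factors = pd.Series(1.0, index=counts.sample_ids)
        disp = estimate_dispersion(counts, factors, counts.design)
        np.testing.assert_allclose(disp.to_numpy(), 1e-8)

    def test_poisson_counts_near_floor(self):
        rng = np.random.default_rng(4)
        arr = rng.poisson(200, size=(2_000, 6))
        counts = make_counts(arr, n_species=2)
        factors = pd.Series(1.0, index=counts.sample_ids)
        disp = estimate_dispersion(counts, factors, counts.design)
        assert np.median(disp) < 0.01

    def test_nb_dispersion_recovered_with_replication(self):
        rng = np.random.default_rng(5)
        alpha, mu, reps = 0.2, 300.0, 12
        lam = rng.gamma(1 / alpha, mu * alpha, size=(2_000, 2 * reps))
        arr = rng.poisson(lam)
        counts = make_counts(arr, n_species=2)
        factors = pd.Series(1.0, index=counts.sample_ids)
        disp = estimate_dispersion(counts, factors, counts.design)
        assert 0.1 <= np.median(disp) <= 0.3

    def test_single_replicate_everywhere_rejected(self):
        counts = make_counts(np.array([[5, 6]]), n_species=2)
        factors = pd.Series(1.0, index=counts.sample_ids)
        with pytest.raises(ValidationError):
            estimate_dispersion(counts, factors, counts.design)


class TestWald:
    def test_identical_groups_null(self):
        arr = np.tile([[40], [80]], (1, 6))
        counts = make_counts(arr, n_species=2)
        factors = pd.Series(1.0, index=counts.sample_ids)
        disp = pd.Series(0.1, index=counts.gene_ids)
        res = nb_wald_test(
            counts, factors, disp, (("S0", "eggplant"), ("S1", "eggplant"))
        )
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_fold_change_recovery(self):
        rng = np.random.default_rng(6)
        alpha, mu = 0.05, 200.0
        n = 2_000
        lam_a = rng.gamma(1 / alpha, mu * alpha, size=(n, 3))
        lam_b = rng.gamma(1 / alpha, 4 * mu * alpha, size=(n, 3))
        arr = np.hstack([rng.poisson(lam_a), rng.poisson(lam_b)])
        counts = make_counts(arr, n_species=2)
        factors = pd.Series(1.0, index=counts.sample_ids)
        disp = pd.Series(alpha, index=counts.gene_ids)
        res = nb_wald_test(
            counts, factors, disp, (("S0", "eggplant"), ("S1", "eggplant"))
        )
        assert abs(np.median(res["log2fc"]) - 2.0) < 0.3

    def test_empty_cell_rejected(self):
        counts = make_counts(np.full((1, 4), 9), n_species=2)
        factors = pd.Series(1.0, index=counts.sample_ids)
        disp = pd.Series(0.1, index=counts.gene_ids)
        with pytest.raises(ValidationError):
            nb_wald_test(counts, factors, disp, (("S0", "eggplant"), ("S9", "kale")))


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.42])), [0.42])

    def test_hand_applied_stepup(self):
        np.testing.assert_allclose(
            adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh(np.ones(5)), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh(np.array([0.1, np.nan]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_textbook_oracle(self, pvals):
        p = np.array(pvals)
        np.testing.assert_allclose(adjust_bh(p), bh_stepup(p), atol=1e-12)


class TestRlogAndCalls:
    def test_rlog_examples(self):
        arr = np.array([[0, 7, 15, 3]])
        counts = make_counts(arr, n_species=2)
        factors = pd.Series(1.0, index=counts.sample_ids)
        expr = regularized_log(counts, factors)
        assert expr.values.iloc[0, 0] == pytest.approx(0.0)
        assert expr.values.iloc[0, 1] == pytest.approx(3.0)  # log2(7 + 1)
        assert expr.values.iloc[0, 2] == pytest.approx(4.0)

    def test_rlog_factor_equivariance(self):
        arr = np.array([[20, 20, 20, 20]])
        counts = make_counts(arr, n_species=2)
        f1 = pd.Series(1.0, index=counts.sample_ids)
        f2 = pd.Series(2.0, index=counts.sample_ids)
        e1 = regularized_log(counts, f1).values.iloc[0, 0]
        e2 = regularized_log(counts, f2).values.iloc[0, 0]
        assert e2 == pytest.approx(math.log2(10 + 1))
        assert e1 > e2

    @pytest.mark.parametrize(
        "lfc,padj,threshold,called",
        [
            (0.9, 0.01, 1.0, False),
            (0.6, 0.04, 0.58, True),
            (-1.2, 0.2, 1.0, False),
            (-1.2, 0.01, 1.0, True),
        ],
    )
    def test_call_thresholds(self, lfc, padj, threshold, called):
        df = pd.DataFrame({"log2fc": [lfc], "padj": [padj]}, index=["g"])
        out = call_de(df, lfc_threshold=threshold)
        assert (len(out) == 1) is called
        if called:
            assert out["direction"].iloc[0] == ("up" if lfc > 0 else "down")
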