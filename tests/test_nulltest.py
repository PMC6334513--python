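"""Profile construction, clustering success criterion and the subset null."""

import numpy as np
import pandas as pd
import pytest

from detoxshift.hierclust import hierarchical_cluster
from detoxshift.nulltest import (
    bipartition_success,
    mean_profiles,
    pca_correlation,
    pearson_dissimilarity,
    profile_dendrogram,
    random_subset_null,
    standardize_per_gene,
    variance_partition,
)
from detoxshift.simulate import default_design
from detoxshift.types import (
    ExpressionMatrix,
    PerformanceGrouping,
    SampleDesign,
    ValidationError,
    cell_label,
)

GROUPING = PerformanceGrouping.study_default()


def expr_from_profiles(profiles: pd.DataFrame, design: SampleDesign, noise=0.0, seed=0):
    """Expand genes x cell profiles into genes x samples with optional noise."""
    rng = np.random.default_rng(seed)
    cols = {}
    for _, row in design.table.iterrows():
        cell = cell_label(row["species"], row["plant"])
        vals = profiles[cell].to_numpy(dtype=float)
        if noise:
            vals = vals + rng.normal(0, noise, len(vals))
        cols[row["sample_id"]] = vals
    return ExpressionMatrix(pd.DataFrame(cols, index=profiles.index))


def group_profiles(design, n_genes=60, group_amp=2.0, species_amp=0.5, seed=1):
    """Profiles with performance-group structure plus species individuality."""
    rng = np.random.default_rng(seed)
    cells = design.cells()
    labels = [cell_label(s, p) for s, p in cells]
    species = design.species
    arr = np.zeros((n_genes, len(cells)))
    for g in range(n_genes):
        a = rng.normal(0, group_amp)
        d = rng.normal(0, species_amp, len(species))
        for c, (sp, pl) in enumerate(cells):
            side = 1.0 if sp in GROUPING.high else -1.0
            arr[g, c] = a * side + d[species.index(sp)]
    return pd.DataFrame(arr, index=[f"g{k}" for k in range(n_genes)], columns=labels)


class TestProfiles:
    def test_identical_replicates_pass_through(self, design6x4):
        profiles = group_profiles(design6x4, n_genes=5)
        expr = expr_from_profiles(profiles, design6x4)
        out = mean_profiles(expr, design6x4)
        pd.testing.assert_frame_equal(out, profiles, check_like=True)

    def test_simple_mean(self):
        design = SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2", "s3"],
                    "species": ["A"] * 3,
                    "plant": ["kale"] * 3,
                    "replicate": [1, 2, 3],
                }
            )
        )
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["g"])
        )
        assert mean_profiles(expr, design).iloc[0, 0] == pytest.approx(2.0)

    def test_matches_groupby_oracle(self, design6x4):
        rng = np.random.default_rng(2)
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(10, 72)),
                index=[f"g{k}" for k in range(10)],
                columns=design6x4.sample_ids,
            )
        )
        out = mean_profiles(expr, design6x4)
        t = design6x4.table
        for sp, pl in design6x4.cells():
            samples = t.loc[
                (t["species"] == sp) & (t["plant"] == pl), "sample_id"
            ].tolist()
            expected = expr.values[samples].mean(axis=1)
            np.testing.assert_allclose(out[cell_label(sp, pl)], expected)


class TestStandardize:
    def test_row_moments(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        z, flat = standardize_per_gene(df)
        assert z.to_numpy().mean() == pytest.approx(0.0, abs=1e-12)
        assert z.to_numpy().std(ddof=1) == pytest.approx(1.0)
        assert len(flat) == 0

    def test_constant_row_flagged_zero(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"])
        z, flat = standardize_per_gene(df)
        np.testing.assert_allclose(z.to_numpy(), 0.0)
        assert list(flat) == ["g"]

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(4, 6)))
        z1, _ = standardize_per_gene(df)
        z2, _ = standardize_per_gene(df * 3.5 - 2.0)
        pd.testing.assert_frame_equal(z1, z2)


class TestPearson:
    def test_identical_columns_zero(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert pearson_dissimilarity(df).loc["a", "b"] == pytest.approx(0.0)

    def test_negated_column_two(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [-1.0, -2, -3]})
        assert pearson_dissimilarity(df).loc["a", "b"] == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        d = pearson_dissimilarity(df)
        for i in "abcde":
            for j in "abcde":
                r = np.corrcoef(df[i], df[j])[0, 1]
                assert d.loc[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(ValidationError, match="a"):
            pearson_dissimilarity(df)


class TestBipartition:
    def test_engineered_group_signal_succeeds(self, design6x4):
        profiles = group_profiles(design6x4, seed=5)
        expr = expr_from_profiles(profiles, design6x4, noise=0.1, seed=5)
        dend = profile_dendrogram(expr, design6x4)
        assert bipartition_success(dend, GROUPING)

    def test_species_split_across_top_cut_fails(self, design6x4):
        profiles = group_profiles(design6x4, seed=6)
        # move one high-group species' cassava profile to the other side
        moved = profiles.copy()
        moved.loc[:, cell_label("MEAM1", "cassava")] = (
            -profiles[cell_label("MEAM1", "cassava")] * 3.0
        )
        expr = expr_from_profiles(moved, design6x4, noise=0.05, seed=6)
        dend = profile_dendrogram(expr, design6x4)
        assert not bipartition_success(dend, GROUPING)

    def test_invalid_grouping_rejected(self):
        with pytest.raises(ValidationError):
            PerformanceGrouping(high=frozenset(), low=frozenset({"NW2"}))

    def test_unknown_species_rejected(self, design6x4):
        profiles = group_profiles(design6x4, seed=7)
        expr = expr_from_profiles(profiles, design6x4, noise=0.05, seed=7)
        dend = profile_dendrogram(expr, design6x4)
        bad = PerformanceGrouping(
            high=frozenset({"MEAM1", "Martian"}), low=frozenset({"NW2"})
        )
        with pytest.raises(ValidationError, match="Martian"):
            bipartition_success(dend, bad)


class TestSubsetNull:
    def test_zero_trials(self, design6x4):
        profiles = group_profiles(design6x4, n_genes=40, seed=8)
        expr = expr_from_profiles(profiles, design6x4, noise=0.1, seed=8)
        res = random_subset_null(expr, design6x4, GROUPING, subset_size=10, n_trials=0)
        assert res.n_success == 0
        assert res.empirical_p == 1.0

    def test_positive_control_all_successes(self, design6x4):
        profiles = group_profiles(design6x4, n_genes=80, group_amp=3.0, seed=9)
        expr = expr_from_profiles(profiles, design6x4, noise=0.1, seed=9)
        res = random_subset_null(
            expr, design6x4, GROUPING, subset_size=30, n_trials=10, seed=1
        )
        assert res.n_success == res.n_trials == 10

    def test_no_signal_pool_success_counts_concentrate_at_zero(self, small_scenario):
        """Background pools give zero successes across resampling seeds."""
        from detoxshift.de import (
            filter_low_counts,
            regularized_log,
            size_factors_median_ratio,
        )

        counts, catalog, truth = small_scenario
        filtered = filter_low_counts(counts)
        factors = size_factors_median_ratio(filtered)
        rld = regularized_log(filtered, factors)
        background = ExpressionMatrix(
            rld.values.loc[~rld.values.index.isin(catalog.entries)]
        )
        zero_runs = sum(
            random_subset_null(
                background,
                counts.design,
                GROUPING,
                subset_size=100,
                n_trials=25,
                seed=seed,
            ).n_success
            == 0
            for seed in range(20)
        )
        assert zero_runs >= 19

    def test_pool_smaller_than_subset_rejected(self, design6x4):
        profiles = group_profiles(design6x4, n_genes=5, seed=10)
        expr = expr_from_profiles(profiles, design6x4, seed=10)
        with pytest.raises(ValidationError):
            random_subset_null(expr, design6x4, GROUPING, subset_size=10, n_trials=1)


class TestPCA:
    def test_fractions_sum_to_one_scores_orthogonal(self, design6x4):
        rng = np.random.default_rng(11)
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(50, 72)),
                index=[f"g{k}" for k in range(50)],
                columns=design6x4.sample_ids,
            )
        )
        scores, fractions = pca_correlation(expr, design6x4)
        assert fractions.sum() == pytest.approx(1.0, abs=1e-10)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_dominant_axis_found(self, design6x4):
        rng = np.random.default_rng(12)
        axis = rng.normal(size=72)
        loadings = rng.normal(size=50)
        data = np.outer(loadings, axis) + rng.normal(0, 0.1, size=(50, 72))
        expr = ExpressionMatrix(
            pd.DataFrame(
                data, index=[f"g{k}" for k in range(50)], columns=design6x4.sample_ids
            )
        )
        _, fractions = pca_correlation(expr, design6x4)
        assert fractions[0] > 0.5


class TestVariancePartition:
    def test_pure_species_gene(self, design6x4):
        t = design6x4.table
        vals = np.array([hash(s) % 7 for s in t["species"]], dtype=float)
        expr = ExpressionMatrix(
            pd.DataFrame([vals], index=["g"], columns=design6x4.sample_ids)
        )
        vp = variance_partition(expr, design6x4)
        assert vp.loc["g", "species"] == pytest.approx(1.0, abs=1e-12)
        assert vp.loc["g", "residual"] == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_sums_to_one(self, design6x4):
        rng = np.random.default_rng(13)
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(20, 72)),
                index=[f"g{k}" for k in range(20)],
                columns=design6x4.sample_ids,
            )
        )
        vp = variance_partition(expr, design6x4)
        np.testing.assert_allclose(vp.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_statsmodels_anova(self, design6x4):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(14)
        y = rng.normal(size=72)
        expr = ExpressionMatrix(
            pd.DataFrame([y], index=["g"], columns=design6x4.sample_ids)
        )
        vp = variance_partition(expr, design6x4)
        df = design6x4.table.assign(y=y)
        model = ols("y ~ C(species) * C(plant)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=1)
        ss_total = tab["sum_sq"].sum()
        assert vp.loc["g", "species"] == pytest.approx(
            tab.loc["C(species)", "sum_sq"] / ss_total
        )
        assert vp.loc["g", "plant"] == pytest.approx(
            tab.loc["C(plant)", "sum_sq"] / ss_total
        )
        assert vp.loc["g", "interaction"] == pytest.approx(
            tab.loc["C(species):C(plant)", "sum_sq"] / ss_total
        )

    def test_unbalanced_rejected(self):
        design = SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2", "s3", "s4", "s5"],
                    "species": ["A", "A", "A", "B", "B"],
                    "plant": ["kale", "kale", "pepper", "kale", "pepper"],
                    "replicate": [1, 2, 1, 1, 1],
                }
            )
        )
        expr = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2, 3, 4, 5]], index=["g"], columns=design.sample_ids
            )
        )
        with pytest.raises(ValidationError):
            variance_partition(expr, design)
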