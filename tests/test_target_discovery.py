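"""Discovery screen: normalization, Welch testing, signature algebra,
ortholog filtering, ranking and PCA, each against an independent route."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from rmskit import synthetic_data as sd
from rmskit import target_discovery as td

from conftest import make_study
from oracles import welch_p_closed_form


class TestQuantileNormalize:
    def test_hand_2x2_example(self, toy_study):
        out = td.quantile_normalize(toy_study)
        expected = pd.DataFrame(
            [[1.5, 3.5], [3.5, 1.5]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        pd.testing.assert_frame_equal(out.values, expected)

    def test_single_gene_forced_to_row_mean(self):
        study = make_study(np.array([[2.0, 6.0]]), ["a", "a"])
        out = td.quantile_normalize(study)
        assert (out.values.to_numpy() == 4.0).all()

    def test_identical_distributions_are_fixed_point(self):
        col = np.array([1.0, 5.0, 2.0, 9.0])
        study = make_study(np.column_stack([col, col[::-1]]), ["a", "a"])
        out = td.quantile_normalize(study)
        np.testing.assert_allclose(out.values.to_numpy(), study.values.to_numpy())

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 12), st.integers(2, 5)),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_idempotent_and_columns_share_sorted_values(self, x):
        # continuous values: ties have measure zero, perturb exact ones away
        x = x + np.arange(x.size).reshape(x.shape) * 1e-7
        study = make_study(x, ["a"] * x.shape[1])
        once = td.quantile_normalize(study)
        arr = once.values.to_numpy()
        ref_sorted = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            np.testing.assert_allclose(np.sort(arr[:, j]), ref_sorted, atol=1e-9)
        twice = td.quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(), arr, atol=1e-9)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            make_study(np.array([[1.0, np.nan], [2.0, 3.0]]), ["a", "a"])


class TestWelch:
    def test_identical_groups(self):
        res = td.welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        res = td.welch_t_test([10, 11, 12], [14, 15, 16])
        assert res.t_stat == pytest.approx(-4.89898, abs=1e-5)
        assert res.welch_df == pytest.approx(4.0)

    def test_antisymmetric_in_group_order(self, rng):
        a = rng.normal(size=5).tolist()
        b = rng.normal(1.0, 2.0, size=7).tolist()
        fwd = td.welch_t_test(a, b)
        rev = td.welch_t_test(b, a)
        assert fwd.t_stat == pytest.approx(-rev.t_stat)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_matches_closed_form_oracle(self, rng):
        """t, df and p match a from-scratch computation (incomplete beta)."""
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 8)).tolist()
            b = rng.normal(0.5, 1.5, size=rng.integers(2, 8)).tolist()
            res = td.welch_t_test(a, b)
            t, df, p = welch_p_closed_form(a, b)
            assert res.t_stat == pytest.approx(t)
            assert res.welch_df == pytest.approx(df)
            assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_zero_variance_degenerate(self):
        res = td.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p_value == 1.0 and res.t_stat == 0.0
        res = td.welch_t_test([3.0, 3.0], [2.0, 2.0])
        assert res.degenerate and res.p_value == 0.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            td.welch_t_test([1.0], [1.0, 2.0])


class TestDifferentialExpression:
    def test_planted_effect_estimated_within_half_log2(self):
        """Estimated log2fc lands in [1.5, 2.5] for >= 95% of seeds."""
        hits = 0
        total = 0
        for seed in range(40):
            study, truth, _ = sd.sim_expression_study(
                n_genes=100, n_shared=0, n_pf_unique=5, n_pax3_unique=0,
                noise_sd=0.25, seed=seed,
            )
            de = td.differential_expression(study, "pax3_foxo1", "gfp")
            planted = truth[truth.klass == "pf_unique_up"].gene_id
            est = de.loc[planted, "log2fc"]
            hits += ((est >= 1.5) & (est <= 2.5)).sum()
            total += len(planted)
        assert hits / total >= 0.95

    def test_null_pvalues_uniform(self):
        from scipy import stats as sps

        study, _, _ = sd.sim_expression_study(
            n_genes=5000, n_shared=0, n_pf_unique=0, n_pax3_unique=0,
            effect_log2fc=0.0, n_reps=10, seed=8,
        )
        de = td.differential_expression(study, "pax3_foxo1", "gfp")
        ks = sps.kstest(de.p_value, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_gene_flagged_degenerate(self):
        x = np.vstack([np.full(6, 5.0), np.arange(6, dtype=float)])
        study = make_study(x, ["gfp", "gfp", "gfp", "pf", "pf", "pf"])
        de = td.differential_expression(study, "pf", "gfp")
        assert bool(de.iloc[0].degenerate) and de.iloc[0].p_value == 1.0
        assert not bool(de.iloc[1].degenerate)

    def test_absent_condition_rejected(self):
        study = make_study(np.ones((2, 4)), ["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            td.differential_expression(study, "c", "a")


class TestCallsAndSets:
    def test_direction_filter_excludes_downregulated(self):
        stats = pd.DataFrame(
            {"log2fc": [-1.0, 1.0], "p_value": [0.04, 0.04]},
            index=["down", "up"],
        )
        assert td.call_upregulated(stats) == {"up"}

    def test_empty_stats(self):
        assert td.call_upregulated(pd.DataFrame(columns=["log2fc", "p_value"])) == set()

    def test_null_call_rate_near_upper_tail_alpha(self):
        study, _, _ = sd.sim_expression_study(
            n_genes=8000, n_shared=0, n_pf_unique=0, n_pax3_unique=0,
            effect_log2fc=0.0, n_reps=10, seed=13,
        )
        de = td.differential_expression(study, "pax3_foxo1", "gfp")
        rate = len(td.call_upregulated(de, alpha=0.05)) / len(de)
        assert rate == pytest.approx(0.025, abs=0.006)

    def test_intersection_algebra(self):
        sig = td.intersect_signatures({"x", "y"}, {"y", "z"})
        assert sig.shared == {"y"}
        assert sig.unique_b == {"z"}
        disjoint = td.intersect_signatures({"x"}, {"y", "z"})
        assert disjoint.shared == set()
        assert disjoint.unique_b == {"y", "z"}


class TestOrthologFilter:
    def test_empty_map_removes_everything(self):
        empty = pd.DataFrame(columns=["organism_gene", "human_gene"])
        assert td.filter_orthologs({"a", "b"}, empty) == {}

    def test_retained_fraction_tracks_bernoulli_rate(self):
        _, truth, ortho = sd.sim_expression_study(
            n_genes=2000, ortholog_fraction=0.5, seed=21
        )
        kept = td.filter_orthologs(set(truth.gene_id), ortho)
        frac = len(kept) / len(truth)
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(2000))

    def test_one_to_many_mapping_rejected(self):
        dup = pd.DataFrame(
            {"organism_gene": ["a", "a"], "human_gene": ["H1", "H2"]}
        )
        with pytest.raises(ValueError):
            td.filter_orthologs({"a"}, dup)


class TestRanking:
    def test_tie_break_by_p_then_id(self):
        stats = pd.DataFrame(
            {"log2fc": [1.0, 1.0, 1.0], "p_value": [0.02, 0.01, 0.02]},
            index=["b", "c", "a"],
        )
        ranked = td.rank_candidates(["a", "b", "c"], stats)
        assert list(ranked.gene_id) == ["c", "a", "b"]

    def test_fold_change_is_linear_scale_and_sorted(self):
        stats = pd.DataFrame(
            {"log2fc": [3.0, 1.0], "p_value": [0.01, 0.01]}, index=["hi", "lo"]
        )
        ranked = td.rank_candidates(["lo", "hi"], stats)
        assert list(ranked.fold_change) == [8.0, 2.0]
        assert list(ranked.gene_id) == ["hi", "lo"]

    def test_missing_stat_rejected(self):
        stats = pd.DataFrame({"log2fc": [1.0], "p_value": [0.5]}, index=["a"])
        with pytest.raises(ValueError):
            td.rank_candidates(["a", "ghost"], stats)

    def test_strong_planted_gene_ranks_first(self):
        """A ~21-fold planted gene tops the ranking in >= 95% of seeds."""
        wins = 0
        for seed in range(40):
            study, truth, ortho = sd.sim_expression_study(
                n_genes=500, n_shared=0, n_pf_unique=10, n_pax3_unique=0,
                effect_log2fc=2.0, ortholog_fraction=1.0, seed=seed,
            )
            star = truth[truth.klass == "pf_unique_up"].gene_id.iloc[0]
            study.values.loc[star, study.condition_columns("pax3_foxo1")] += 2.39
            res = td.discover(study, ortho)
            if len(res.candidates) and res.candidates.iloc[0].gene_id == star:
                wins += 1
        assert wins >= 38  # >= 95% of 40 seeds


class TestPCA:
    def test_rank_one_data_explains_everything(self):
        direction = np.array([1.0, 2.0, 3.0])
        weights = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.outer(weights, direction)  # 4 genes x 3 samples, collinear
        study = make_study(x, ["a", "a", "a"])
        _, var = td.pca_embed(study, n_components=2)
        assert var[0] == pytest.approx(1.0)
        assert var[1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_fractions_non_increasing(self, rng):
        study = make_study(rng.normal(size=(30, 6)), ["a"] * 6)
        _, var = td.pca_embed(study, n_components=5)
        assert all(var[i] >= var[i + 1] - 1e-12 for i in range(len(var) - 1))
        assert var.sum() <= 1.0 + 1e-9

    def test_matches_eigendecomposition_oracle(self, rng):
        """Scores match an independent eigendecomposition of the sample
        covariance (up to component sign)."""
        x = rng.normal(size=(4, 3))
        study = make_study(x, ["a", "a", "a"])
        scores, var = td.pca_embed(study, n_components=2)
        y = x.T - x.T.mean(axis=0)  # samples x genes, gene-centered
        cov = y @ y.T / (y.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        expected = evecs * np.sqrt(np.maximum(evals, 0) * (y.shape[0] - 1))
        for k in range(2):
            got = scores.to_numpy()[:, k]
            assert np.allclose(got, expected[:, k], atol=1e-8) or np.allclose(
                got, -expected[:, k], atol=1e-8
            )
        nonzero = evals[evals > 1e-12]
        np.testing.assert_allclose(var[: len(nonzero)], nonzero / evals.sum(), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        study = make_study(rng.normal(size=(10, 3)), ["a"] * 3)
        with pytest.raises(ValueError):
            td.pca_embed(study, n_components=3)


class TestDiscover:
    def test_top_candidate_is_planted_fusion_unique(self):
        study, truth, ortho = sd.sim_expression_study(seed=7)
        res = td.discover(study, ortho)
        planted = set(truth[truth.klass == "pf_unique_up"].gene_id)
        assert res.candidates.iloc[0].gene_id in planted

    def test_shared_genes_never_in_candidates(self):
        study, truth, ortho = sd.sim_expression_study(seed=7)
        res = td.discover(study, ortho)
        shared = set(truth[truth.klass == "shared_up"].gene_id)
        assert not (set(res.candidates.gene_id) & shared)

    def test_candidates_all_have_orthologs_and_sorted(self):
        study, truth, ortho = sd.sim_expression_study(seed=7)
        res = td.discover(study, ortho)
        assert (res.candidates.human_ortholog != "").all()
        fc = res.candidates.fold_change.to_numpy()
        assert (np.diff(fc) <= 1e-12).all()

    def test_null_study_yields_nearly_empty_list(self):
        study, _, ortho = sd.sim_expression_study(
            n_genes=800, n_shared=0, n_pf_unique=0, n_pax3_unique=0,
            effect_log2fc=0.0, seed=17,
        )
        res = td.discover(study, ortho)
        # false positives only: unique set stays a small fraction of genes
        assert len(res.candidates) < 0.05 * 800


class TestIO:
    def test_matrix_and_sheet_roundtrip(self, tmp_path):
        study, _, _ = sd.sim_expression_study(n_genes=100, seed=1)
        study.values.to_csv(tmp_path / "m.tsv", sep="\t")
        pd.DataFrame(
            {
                "sample_id": study.values.columns,
                "condition": study.sample_conditions.loc[study.values.columns].values,
                "replicate_index": study.replicate_index.loc[study.values.columns].values,
            }
        ).to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        loaded = td.read_expression_study(tmp_path / "m.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(loaded.values, study.values)
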