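"""Label-free statistics: transform, normalize, impute, test, FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import apquant as aq
from apquant.stats import permutation_fdr, two_sample_ttest
from conftest import make_dataset, make_matrix


class TestLog2Transform:
    def test_zero_becomes_missing(self, small_design):
        frame = pd.DataFrame(
            {
                "protein_ids": ["P1"],
                "gene_names": [""],
                "reverse": False,
                "potential_contaminant": False,
                "only_identified_by_site": False,
            },
            index=["P1"],
        )
        values = [4.0, 0.0, 8.0, 1.0, 2.0, 1024.0]
        for s, v in zip(small_design.groups, values):
            frame[f"intensity_{s}"] = v
            frame[f"lfq_intensity_{s}"] = v
        table = aq.ProteinGroupsTable(frame=frame, samples=list(small_design.groups))
        m = aq.log2_transform(table, which="lfq", design=small_design)
        row = m.values.loc["P1"]
        assert row["a1"] == 2.0 and row["a3"] == 3.0 and row["b3"] == 10.0
        assert np.isnan(row["a2"])


class TestMedianNormalize:
    def test_median_zero_and_idempotent(self, small_design):
        m = make_matrix(
            [[1, 5, 1, 0, 2, 3], [2, np.nan, 4, 1, 3, 9], [3, 7, 9, 2, 4, 27]],
            small_design,
        )
        out = aq.median_normalize(m)
        med = out.values.median(axis=0, skipna=True)
        assert np.allclose(med, 0, atol=1e-12)
        # mask preserved
        assert np.isnan(out.values.iloc[1, 1])
        again = aq.median_normalize(out)
        pd.testing.assert_frame_equal(again.values, out.values)

    def test_column_with_missing_values(self, small_design):
        m = make_matrix([[5] * 6, [np.nan] * 6, [7] * 6], small_design)
        out = aq.median_normalize(m)
        assert np.allclose(out.values.iloc[0], -1)
        assert np.allclose(out.values.iloc[2], 1)

    def test_empty_column_rejected(self, small_design):
        m = make_matrix([[np.nan, 1, 1, 1, 1, 1]], small_design)
        with pytest.raises(ValueError, match="no present values"):
            aq.median_normalize(m)


class TestFilterMinValid:
    def test_rule_examples(self, small_design):
        # row 0: 3 valid in a, 0 in b -> kept; row 1: 2 and 2 -> removed
        m = make_matrix(
            [
                [1, 2, 3, np.nan, np.nan, np.nan],
                [1, 2, np.nan, 1, 2, np.nan],
            ],
            small_design,
            index=["keep", "drop"],
        )
        out = aq.filter_min_valid(m, 3)
        assert list(out.values.index) == ["keep"]

    def test_min_valid_one_keeps_any_value(self, small_design):
        m = make_matrix(
            [[np.nan] * 5 + [1.0], [np.nan] * 6], small_design, index=["one", "none"]
        )
        out = aq.filter_min_valid(m, 1)
        assert list(out.values.index) == ["one"]

    def test_min_valid_above_group_size_warns(self, small_design):
        m = make_matrix([[1.0] * 6], small_design)
        with pytest.warns(UserWarning, match="exceeds"):
            aq.filter_min_valid(m, 4)


class TestImputation:
    def test_monte_carlo_matches_stated_law(self, small_design):
        """Imputed cells follow Normal(mu - 1.8 sigma, (0.3 sigma)^2)."""
        rng = np.random.default_rng(0)
        observed = rng.normal(0, 1, 50)
        observed = (observed - observed.mean()) / observed.std(ddof=1) + 20.0
        # sample mean exactly 20, sd exactly 1
        col = np.concatenate([observed, np.full(10000, np.nan)])
        m = make_matrix(np.column_stack([col] * 6), small_design)
        out = aq.impute_gaussian_downshift(m, aq.ImputeParams(seed=3))
        imputed = out.values["a1"].to_numpy()[50:]
        assert imputed.mean() == pytest.approx(18.2, abs=0.05)
        assert imputed.std(ddof=1) == pytest.approx(0.3, abs=0.03)

    def test_no_missing_is_identity(self, small_design):
        m = make_matrix(np.arange(12.0).reshape(2, 6), small_design)
        out = aq.impute_gaussian_downshift(m, aq.ImputeParams(seed=0))
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_same_seed_identical_and_row_permutation_equivariant(self, small_design):
        rng = np.random.default_rng(1)
        base = rng.normal(20, 2, size=(30, 6))
        base[rng.random(base.shape) < 0.3] = np.nan
        idx = [f"p{i}" for i in range(30)]
        m = make_matrix(base, small_design, index=idx)
        out1 = aq.impute_gaussian_downshift(m, aq.ImputeParams(seed=9))
        out2 = aq.impute_gaussian_downshift(m, aq.ImputeParams(seed=9))
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_degenerate_column_rejected(self, small_design):
        m = make_matrix(
            [[1.0] * 6, [1.0] * 6, [np.nan] * 6], small_design
        )
        with pytest.raises(ValueError, match="zero spread"):
            aq.impute_gaussian_downshift(m)


class TestTTest:
    def test_identical_groups_null(self, small_design):
        m = make_matrix([[1, 2, 3, 1, 2, 3]], small_design)
        res = two_sample_ttest(m)
        assert res["difference"].iloc[0] == 0
        # identical values within groups -> zero variance, zero diff
        m2 = make_matrix([[5, 5, 5, 5, 5, 5]], small_design)
        res2 = two_sample_ttest(m2)
        assert res2["t"].iloc[0] == 0 and res2["p"].iloc[0] == 1

    def test_matches_hand_computed_pooled_t(self):
        """{0,1} vs {2,3}: diff -2, pooled sd = sqrt(1/2), t = -2/sqrt(1/2 * 1) = -2.828..."""
        design = aq.SampleDesign(
            groups={"a1": "a", "a2": "a", "b1": "b", "b2": "b"},
            treatment="a",
            control="b",
        )
        m = make_matrix([[0, 1, 2, 3]], design)
        res = two_sample_ttest(m)
        se = math.sqrt(0.5 * (1 / 2 + 1 / 2))
        expected_t = -2.0 / se
        assert res["t"].iloc[0] == pytest.approx(expected_t)
        assert res["difference"].iloc[0] == -2.0
        expected_p = 2 * scipy.stats.t.sf(abs(expected_t), df=2)
        assert res["p"].iloc[0] == pytest.approx(expected_p)

    def test_matches_scipy_on_random_data(self, small_design):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, size=(40, 6))
        m = make_matrix(data, small_design)
        res = two_sample_ttest(m)
        ref = scipy.stats.ttest_ind(data[:, :3], data[:, 3:], axis=1, equal_var=True)
        assert np.allclose(res["t"], ref.statistic)
        assert np.allclose(res["p"], ref.pvalue)

    def test_missing_values_rejected(self, small_design):
        m = make_matrix([[1, np.nan, 3, 4, 5, 6]], small_design)
        with pytest.raises(ValueError, match="impute"):
            two_sample_ttest(m)


def oracle_permutation_fdr(values, n1, s0=0.0):
    """Brute-force reference: enumerate every group-label assignment,
    recompute d = diff/(se+s0), and estimate q as the monotonized ratio of
    mean permuted exceedances to observed exceedances."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]

    def d_stat(idx1):
        idx1 = list(idx1)
        idx2 = [i for i in range(n) if i not in idx1]
        a, b = values[:, idx1], values[:, idx2]
        va = a.var(ddof=1, axis=1)
        vb = b.var(ddof=1, axis=1)
        pooled = ((a.shape[1] - 1) * va + (b.shape[1] - 1) * vb) / (n - 2)
        se = np.sqrt(pooled * (1 / a.shape[1] + 1 / b.shape[1]))
        diff = a.mean(axis=1) - b.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se + s0 > 0, diff / (se + s0),
                            np.where(diff == 0, 0.0, np.sign(diff) * np.inf))

    observed = np.abs(d_stat(range(n1)))
    assignments = list(itertools.combinations(range(n), n1))
    perm_abs = np.array([np.abs(d_stat(a)) for a in assignments])
    qs = np.empty_like(observed)
    fdrs = {}
    for i, t in enumerate(observed):
        obs_count = (observed >= t).sum()
        mean_perm = (perm_abs >= t).sum() / len(assignments)
        fdrs[t] = min(1.0, mean_perm / obs_count)
    for i, t in enumerate(observed):
        qs[i] = min(v for u, v in fdrs.items() if u <= t)
    return qs


class TestPermutationFDR:
    def test_equals_bruteforce_oracle_3v3(self, small_design):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, size=(60, 6))
        data[:5, :3] += 4  # a few real effects
        m = make_matrix(data, small_design)
        res = permutation_fdr(m, params=aq.TestParams())
        assert res.attrs["exhaustive"] and res.attrs["n_permutations_used"] == 20
        expected_q = oracle_permutation_fdr(data, 3)
        assert np.allclose(res["q"], expected_q)

    def test_equals_oracle_on_unbalanced_design(self):
        design = aq.SampleDesign(
            groups={"a1": "a", "a2": "a", "a3": "a", "a4": "a",
                    "b1": "b", "b2": "b", "b3": "b"},
            treatment="a",
            control="b",
        )
        rng = np.random.default_rng(8)
        data = rng.normal(0, 1, size=(40, 7))
        data[:3, :4] -= 3
        m = make_matrix(data, design)
        res = permutation_fdr(m, params=aq.TestParams())
        assert np.allclose(res["q"], oracle_permutation_fdr(data, 4))

    def test_planted_outlier_has_smallest_q(self, small_design):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 1, size=(200, 6))
        data[0, :3] += 50
        m = make_matrix(data, small_design, index=[f"p{i}" for i in range(200)])
        res = permutation_fdr(m, params=aq.TestParams())
        assert res["q"].idxmin() == "p0"
        assert res.loc["p0", "q"] == res["q"].min()

    def test_sampled_mode_excludes_identity_and_is_seeded(self, small_design):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 1, size=(50, 6))
        m = make_matrix(data, small_design)
        params = aq.TestParams(n_permutations=10)
        r1 = permutation_fdr(m, params=params, seed=3)
        r2 = permutation_fdr(m, params=params, seed=3)
        assert not r1.attrs["exhaustive"]
        assert r1.attrs["n_permutations_used"] == 10
        pd.testing.assert_frame_equal(r1, r2)

    def test_too_few_samples_rejected(self):
        design = aq.SampleDesign(groups={"a1": "a", "b1": "b"},
                                 treatment="a", control="b")
        m = make_matrix([[1.0, 2.0]], design)
        with pytest.raises(ValueError):
            permutation_fdr(m, params=aq.TestParams())


class TestEnrichmentModel:
    def test_stage_log_monotone_and_planted_recovery(self):
        # strong-effect regime: every interactor far above the dropout floor
        truth = aq.generate_ground_truth(seed=17, bait_amount=1000.0)
        fasta = aq.generate_sequences(truth, seed=17)
        ds = aq.simulate_pulldown(truth, fasta, aq.SimulationConfig(seed=17))
        res = aq.EnrichmentModel(ds.protein_groups, ds.design).fit(seed=17)
        counts = [n for _, n in res.stage_log]
        assert counts == sorted(counts, reverse=True)
        interactors = set(ds.truth.interactor_ids)
        sig = set(res.significant.index)
        tested = interactors & set(res.table.index)
        assert len(sig & tested) / len(tested) > 0.9

    def test_summary_mentions_stages_and_counts(self):
        ds = make_dataset(seed=17)
        res = aq.EnrichmentModel(ds.protein_groups, ds.design).fit(seed=17)
        text = res.summary()
        assert "filter_min_valid" in text and "significant" in text

    def test_flagged_rows_never_reach_testing(self):
        ds = make_dataset(seed=19)
        frame = ds.protein_groups.frame.copy()
        frame.loc[frame.index[0], "reverse"] = True
        table = aq.ProteinGroupsTable(frame=frame, samples=ds.protein_groups.samples)
        res = aq.EnrichmentModel(table, ds.design).fit(seed=19)
        assert frame.index[0] not in res.table.index

    def test_empty_after_filtering_is_explicit_error(self, small_design):
        frame = pd.DataFrame(
            {
                "protein_ids": ["P1"],
                "gene_names": [""],
                "reverse": True,
                "potential_contaminant": False,
                "only_identified_by_site": False,
            },
            index=["P1"],
        )
        for s in small_design.groups:
            frame[f"intensity_{s}"] = 1.0
            frame[f"lfq_intensity_{s}"] = 1.0
        table = aq.ProteinGroupsTable(frame=frame, samples=list(small_design.groups))
        with pytest.raises(ValueError, match="no rows"):
            aq.EnrichmentModel(table, small_design).fit()


class TestSetOverlap:
    def test_printed_count_arithmetic(self):
        r = aq.set_overlap([f"g{i}" for i in range(1227)],
                           [f"g{i}" for i in range(289, 289 + 3151)])
        assert r.n_intersection == 938
        assert r.pct_a_in_b_rounded == 76

    def test_identical_sets_full_overlap(self):
        r = aq.set_overlap(["a", "b"], ["b", "a"])
        assert r.pct_a_in_b == 100.0 and r.pct_b_in_a == 100.0

    def test_empty_set_flagged_undefined(self):
        r = aq.set_overlap([], ["a"])
        assert r.pct_a_in_b is None and r.pct_b_in_a == 0.0
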