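import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rplsig.containers import ExpressionMatrix, GeneSet, Signature
from rplsig.scoring import (
    _spearman,
    annotate_rp_like_bulk,
    annotate_rp_like_cells,
    anticorrelation_diagnostic,
    cell_rank_score,
    cell_score_table,
    classify_by_median,
    geometric_mean_score,
    rank_auc,
    rpls_raw,
    score_table,
    subset_score,
    zscore,
)


def make_expr(rows: dict, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df.astype(float), "linear")


class TestRawScore:
    def test_pseudocount_arithmetic(self):
        # sum_rp=7, sum_ls=1 -> log2(8) - log2(2) = 2
        expr = make_expr({"R1": [7.0], "L1": [1.0]})
        sig = Signature(["R1"], ["L1"])
        tab = rpls_raw(expr, sig)
        assert tab["raw_score"].iloc[0] == pytest.approx(2.0)

    def test_equal_sums_give_zero(self):
        expr = make_expr({"R1": [5.0], "L1": [5.0]})
        tab = rpls_raw(expr, Signature(["R1"], ["L1"]))
        assert tab["raw_score"].iloc[0] == pytest.approx(0.0)

    def test_scale_invariance_at_large_sums(self):
        # rescaling a sample by c shifts each arm's log2(sum+1) by at most
        # |log2((c*s+1) / (c*(s+1)))|; the raw score moves by their sum
        sig = Signature(["R1"], ["L1"])
        c = 10.0
        for s_rp, s_ls in ((1e4, 1e3), (1e4, 1e4), (1e5, 1e5)):
            r1 = rpls_raw(make_expr({"R1": [s_rp], "L1": [s_ls]}), sig)["raw_score"].iloc[0]
            r10 = rpls_raw(make_expr({"R1": [c * s_rp], "L1": [c * s_ls]}), sig)["raw_score"].iloc[0]
            bound = sum(
                abs(np.log2((c * s + 1) / (c * (s + 1)))) for s in (s_rp, s_ls)
            )
            assert abs(r10 - r1) <= bound + 1e-12
        # with both arm sums >= 1e4 the drift is below 1e-3
        r1 = rpls_raw(make_expr({"R1": [1e4], "L1": [1e4]}), sig)["raw_score"].iloc[0]
        r10 = rpls_raw(make_expr({"R1": [1e5], "L1": [1e5]}), sig)["raw_score"].iloc[0]
        assert abs(r10 - r1) < 1e-3

    def test_log_input_back_transformed(self):
        lin = make_expr({"R1": [7.0], "L1": [1.0]})
        logm = lin.to_log2p1()
        tab = rpls_raw(logm, Signature(["R1"], ["L1"]))
        assert tab["raw_score"].iloc[0] == pytest.approx(2.0)

    def test_missing_arm_errors_naming_it(self):
        expr = make_expr({"R1": [1.0]})
        with pytest.raises(ValueError, match="ls_high"):
            rpls_raw(expr, Signature(["R1"], ["MISSING"]))

    def test_coverage_floor_enforced(self):
        expr = make_expr({"R1": [1.0], "L1": [1.0]})
        sig = Signature(["R1", "R2", "R3"], ["L1"])
        with pytest.raises(ValueError, match="coverage"):
            rpls_raw(expr, sig, min_coverage=0.5)

    def test_gene_and_sample_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.lognormal(2, 1, size=(6, 5)),
            index=["R1", "R2", "L1", "L2", "N1", "N2"],
            columns=[f"s{i}" for i in range(5)],
        )
        sig = Signature(["R1", "R2"], ["L1", "L2"])
        base = rpls_raw(ExpressionMatrix(values, "linear"), sig).set_index("sample_id")
        perm = values.iloc[rng.permutation(6), rng.permutation(5)]
        shuffled = rpls_raw(ExpressionMatrix(perm, "linear"), sig).set_index("sample_id")
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index())


class TestZscore:
    def test_two_point_example(self):
        np.testing.assert_allclose(zscore([2.0, -2.0]), [0.7071067811865475, -0.7071067811865475])

    def test_normalization_identities(self):
        rng = np.random.default_rng(1)
        z = zscore(rng.normal(size=37))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_constant_scores_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z = zscore([3.0, 3.0, 3.0])
        assert (z == 0).all()

    def test_single_sample_directed_to_reference_mode(self):
        with pytest.raises(ValueError, match="reference"):
            zscore([1.0])


class TestMedianSplit:
    def test_even_cohort(self):
        calls = classify_by_median([1, 2, 3, 4])
        assert calls.tolist() == ["low", "low", "high", "high"]

    def test_median_sample_goes_low(self):
        calls = classify_by_median([1, 2, 3])
        assert calls.tolist() == ["low", "low", "high"]

    def test_all_equal_all_low(self):
        with pytest.warns(UserWarning):
            calls = classify_by_median([2, 2, 2, 2])
        assert (calls == "low").all()


class TestSubsetScore:
    def test_all_filter_is_noop(self, toy_expr, toy_signature):
        full = score_table(toy_expr, toy_signature)
        sub = subset_score(toy_expr, toy_signature, "all", pd.DataFrame())
        pd.testing.assert_frame_equal(full, sub)

    def test_single_gene_arms_arithmetic(self):
        expr = make_expr(
            {"R1": [3.0, 9.0], "R2": [50.0, 1.0], "L1": [1.0, 1.0], "L2": [50.0, 2.0]}
        )
        sig = Signature(["R1", "R2"], ["L1", "L2"])
        origins = pd.DataFrame(
            {"gene_id": ["R1", "L1"], "assigned_type": ["myeloid", "myeloid"]}
        )
        tab = subset_score(expr, sig, "myeloid", origins)
        # first sample: log2(3+1) - log2(1+1) = 1
        assert tab["raw_score"].iloc[0] == pytest.approx(1.0)
        assert tab.attrs["arm_sizes"] == {"rp_high": 1, "ls_high": 1}

    def test_emptied_arm_errors_listing_survivors(self, toy_expr, toy_signature):
        origins = pd.DataFrame({"gene_id": ["R1"], "assigned_type": ["myeloid"]})
        with pytest.raises(ValueError, match="R1"):
            subset_score(toy_expr, toy_signature, "myeloid", origins)


class TestCellRankScore:
    def test_extreme_ranks_arithmetic(self):
        # G=10; rp at ranks 9,10; ls at ranks 1,2 -> 0.90 - 0.10 = 0.80
        genes = [f"g{i}" for i in range(10)]
        values = np.arange(1.0, 11.0)
        sig = Signature([genes[8], genes[9]], [genes[0], genes[1]])
        assert cell_rank_score(values, genes, sig) == pytest.approx(0.80)

    def test_symmetric_interleaving_is_zero(self):
        genes = ["a", "b", "c", "d"]
        sig = Signature(["a", "d"], ["b", "c"])
        assert cell_rank_score([1.0, 2.0, 3.0, 4.0], genes, sig) == pytest.approx(0.0)

    def test_constant_cell_is_zero_via_midranks(self):
        genes = ["a", "b", "c", "d"]
        sig = Signature(["a"], ["b"])
        assert cell_rank_score([5.0] * 4, genes, sig) == pytest.approx(0.0)

    def test_absent_arm_flagged_nan(self):
        sig = Signature(["zz"], ["b"])
        assert np.isnan(cell_rank_score([1.0, 2.0], ["a", "b"], sig))

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        values = rng.lognormal(0, 1, size=20)
        sig = Signature(genes[:5], genes[10:15])
        base = cell_rank_score(values, genes, sig)
        for transform in (np.log1p, np.sqrt, lambda v: 3 * v + 7, np.expm1):
            assert cell_rank_score(transform(values), genes, sig) == pytest.approx(base)


class TestAnnotateRpLike:
    def test_reference_mode_sign_rule(self):
        out = annotate_rp_like_bulk([0.5, -0.2], reference_mean=0.0, reference_sd=1.0)
        assert out["call"].tolist() == ["RP-like", "LS-like"]

    def test_missing_reference_stats_error(self):
        with pytest.raises(ValueError, match="reference"):
            annotate_rp_like_bulk([0.5], reference_mean=0.0, reference_sd=None)

    def test_two_patients_disjoint_cell_scores_split(self):
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(8)],
                "patient_id": ["p1"] * 4 + ["p2"] * 4,
                "rank_score": [0.5, 0.6, 0.55, 0.65, -0.5, -0.6, -0.55, -0.65],
            }
        )
        out = annotate_rp_like_cells(cells).set_index("patient_id")
        assert out.loc["p1", "call"] == "RP-like"
        assert out.loc["p2", "call"] == "LS-like"
        assert out["p_vs_rest"].between(0, 1).all()


class TestAnticorrelation:
    def test_perfect_inverse_ranks(self):
        rho, _ = _spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_identical_summaries(self):
        rho, _ = _spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_exact_permutation_p_matches_enumeration(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho, p = _spearman(x, y)
        hits = 0
        for perm in itertools.permutations(y):
            r = stats.spearmanr(x, list(perm)).statistic
            hits += abs(r) >= abs(rho) - 1e-12
        assert p == pytest.approx(hits / 120)

    def test_opposite_single_gene_arms_give_minus_one(self):
        expr = make_expr({"R1": [1, 2, 3, 4], "L1": [4, 3, 2, 1]})
        rho, _ = anticorrelation_diagnostic(expr, Signature(["R1"], ["L1"]))
        assert rho == pytest.approx(-1.0)

    def test_too_few_samples_rejected(self):
        expr = make_expr({"R1": [1, 2, 3], "L1": [3, 2, 1]})
        with pytest.raises(ValueError, match="4 samples"):
            anticorrelation_diagnostic(expr, Signature(["R1"], ["L1"]))


class TestGeometricMean:
    def test_two_gene_example(self):
        # values {1, 7}: geometric mean of 2 and 8 is 4 -> score 3
        expr = make_expr({"a": [1.0], "b": [7.0]})
        s = geometric_mean_score(expr, GeneSet("S", "", ["a", "b"]))
        assert s.iloc[0] == pytest.approx(3.0)

    def test_all_zero_sample(self):
        expr = make_expr({"a": [0.0], "b": [0.0]})
        s = geometric_mean_score(expr, GeneSet("S", "", ["a", "b"]))
        assert s.iloc[0] == pytest.approx(0.0)

    def test_single_gene_identity(self):
        expr = make_expr({"a": [13.5]})
        s = geometric_mean_score(expr, GeneSet("S", "", ["a"]))
        assert s.iloc[0] == pytest.approx(13.5)

    def test_empty_overlap_errors(self, toy_expr):
        with pytest.raises(ValueError, match="no genes"):
            geometric_mean_score(toy_expr, GeneSet("S", "", ["nope"]))


def test_rank_auc_known_values():
    assert rank_auc([1, 2, 3, 4], ["n", "n", "p", "p"], "p") == 1.0
    assert rank_auc([4, 3, 2, 1], ["n", "n", "p", "p"], "p") == 0.0
    assert rank_auc([1, 2, 3, 4], ["n", "p", "n", "p"], "p") == 0.75


def test_cell_score_table_matches_scalar_path():
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(15)]
    counts = pd.DataFrame(
        rng.poisson(5, size=(15, 6)), index=genes, columns=[f"c{i}" for i in range(6)]
    )
    ann = pd.DataFrame(
        {"cell_id": counts.columns, "patient_id": ["p"] * 6, "cell_type": ["t"] * 6}
    )
    sig = Signature(genes[:4], genes[8:12])
    tab = cell_score_table(counts, ann, sig)
    for i, cell in enumerate(counts.columns):
        expected = cell_rank_score(counts[cell].to_numpy(), genes, sig)
        assert tab.loc[i, "rank_score"] == pytest.approx(expected)
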