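import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rplsig.containers import Signature
from rplsig.scoring import score_table
from rplsig.signature import derive_signature
from rplsig.survival import logrank_test
from rplsig.synthio import (
    SyntheticCohortConfig,
    SyntheticSingleCellConfig,
    SyntheticTruth,
    generate_bulk_cohort,
    generate_cell_line_panel,
    generate_single_cell,
    generate_survival,
    generate_two_references,
)


def truth_signature(truth: SyntheticTruth) -> Signature:
    return Signature(truth.arm_genes("rp_high"), truth.arm_genes("ls_high"))


class TestConfigValidation:
    def test_programme_genes_cannot_exceed_total(self):
        with pytest.raises(ValueError, match="exceed"):
            SyntheticCohortConfig(n_genes=100, n_rp_high=60, n_ls_high=60)

    def test_effect_requires_both_groups(self):
        with pytest.raises(ValueError, match="non-empty"):
            SyntheticCohortConfig(n_group_b=0, effect_log2fc=2.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(noise_sd=-0.1)

    def test_sc_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticSingleCellConfig(cell_type_proportions={"myeloid": 0.5, "t": 0.4})


class TestBulkCohort:
    def test_determinism_bit_identical(self):
        cfg = SyntheticCohortConfig(seed=77, n_genes=100, n_rp_high=10, n_ls_high=10)
        e1, a1, t1 = generate_bulk_cohort(cfg)
        e2, a2, t2 = generate_bulk_cohort(cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        pd.testing.assert_frame_equal(a1, a2)
        assert t1.latent_activity == t2.latent_activity

    def test_linear_scale_non_negative_and_counts(self):
        cfg = SyntheticCohortConfig(seed=1)
        expr, ann, truth = generate_bulk_cohort(cfg)
        assert (expr.values.to_numpy() > 0).all()
        memberships = pd.Series(truth.gene_membership)
        assert (memberships == "rp_high").sum() == cfg.n_rp_high
        assert (memberships == "ls_high").sum() == cfg.n_ls_high
        assert ann["group"].value_counts().to_dict() == {"A": 7, "B": 6}

    def test_deterministic_anticorrelated_loadings_in_noise_free_limit(self):
        # coupling 1, noise ~0: within a sample, rp and ls deviations are
        # exactly sign-opposite multiples of the latent activity
        cfg = SyntheticCohortConfig(
            seed=5, n_genes=40, n_rp_high=15, n_ls_high=15, noise_sd=0.0, libsize_cv=0.0,
            program_coupling=1.0,
        )
        expr, _, truth = generate_bulk_cohort(cfg)
        log2 = np.log2(expr.values)
        rp = log2.loc[truth.arm_genes("rp_high")]
        ls = log2.loc[truth.arm_genes("ls_high")]
        rp_dev = rp.sub(rp.mean(axis=1), axis=0).mean(axis=0)
        ls_dev = ls.sub(ls.mean(axis=1), axis=0).mean(axis=0)
        np.testing.assert_allclose(rp_dev, -ls_dev, atol=1e-10)

    def test_null_genes_untouched_by_latent(self):
        cfg = SyntheticCohortConfig(
            seed=9, n_genes=50, n_rp_high=10, n_ls_high=10, noise_sd=0.0, libsize_cv=0.0,
            effect_log2fc=3.0,
        )
        expr, _, truth = generate_bulk_cohort(cfg)
        nulls = expr.values.loc[truth.arm_genes("null")]
        # noise-free null genes are constant across samples
        assert nulls.std(axis=1).max() < 1e-9

    def test_null_calibration_type_one_error(self):
        """Rank-sum size at nominal 0.05 under the no-effect generator,
        measured over 30 independent cohorts (60000 gene-tests)."""
        fracs = []
        for s in range(30):
            cfg = SyntheticCohortConfig(
                n_group_a=15, n_group_b=15, effect_log2fc=0.0, program_coupling=0.0,
                seed=9100 + s,
            )
            expr, ann, _ = generate_bulk_cohort(cfg)
            _, de = derive_signature(expr, ann, group_a="A")
            fracs.append((de["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_planted_effect_monotonicity(self):
        """Mean between-group raw-score difference is non-decreasing in the
        planted effect (3 grid points, 50 replicates each)."""
        means = []
        for eff in (0.0, 1.0, 2.0):
            diffs = []
            for s in range(50):
                cfg = SyntheticCohortConfig(
                    effect_log2fc=eff, seed=7000 + s, n_genes=300,
                    n_rp_high=50, n_ls_high=50,
                )
                expr, ann, truth = generate_bulk_cohort(cfg)
                tab = score_table(expr, truth_signature(truth))
                grp = ann.set_index("sample_id")["group"]
                scores = tab.set_index("sample_id")["raw_score"]
                diffs.append(scores[grp == "A"].mean() - scores[grp == "B"].mean())
            means.append(np.mean(diffs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > 1.0  # the planted effect is actually there


class TestSurvivalGenerator:
    def test_preconditions(self):
        truth = SyntheticTruth({}, {"s1": 0.0, "s2": 1.0}, 0.0, {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError):
            generate_survival(truth, baseline_hazard=0.0, censor_time=10, seed=0)
        with pytest.raises(ValueError):
            generate_survival(truth, baseline_hazard=1.0, censor_time=0, seed=0)

    def test_non_finite_latent_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SyntheticTruth({}, {"s1": np.inf}, 0.0, {"s1": "A"})

    def test_exponential_mean_without_censoring(self):
        # beta=0, censor at infinity: mean event time ~ 1/lambda
        acts = {f"s{i}": 0.0 for i in range(4000)}
        truth = SyntheticTruth({}, acts, 0.0, {k: "A" for k in acts})
        tab = generate_survival(truth, baseline_hazard=0.25, censor_time=np.inf, seed=3)
        assert tab["event"].all()
        assert tab["time"].mean() == pytest.approx(4.0, rel=0.05)

    def test_equal_latents_give_exchangeable_groups(self):
        acts = {f"s{i}": 0.7 for i in range(400)}
        truth = SyntheticTruth({}, acts, 2.0, {k: ("A" if i % 2 else "B") for i, k in enumerate(acts)})
        tab = generate_survival(truth, baseline_hazard=0.1, censor_time=50.0, seed=4)
        tab["group"] = [truth.group_label[s] for s in tab["sample_id"]]
        _, p = logrank_test(tab, "group")
        assert p > 0.01  # identical hazards: no systematic difference

    def test_logrank_p_uniform_under_null(self):
        """K-S uniformity of the log-rank p over 200 null replicates."""
        pvals = []
        for s in range(200):
            cfg = SyntheticCohortConfig(
                n_group_a=25, n_group_b=25, effect_log2fc=0.0, n_genes=20,
                n_rp_high=5, n_ls_high=5, seed=5000 + s,
            )
            _, _, truth = generate_bulk_cohort(cfg)
            tab = generate_survival(truth, 0.05, 36.0, seed=5000 + s, true_beta=0.0)
            tab["group"] = np.where(tab["latent_z"] > np.median(tab["latent_z"]), "hi", "lo")
            pvals.append(logrank_test(tab, "group")[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSingleCell:
    def test_zero_cells_degenerate(self):
        cfg = SyntheticSingleCellConfig(cells_per_patient=0, seed=0)
        sig = Signature(["R1"], ["L1"])
        counts, ann, _ = generate_single_cell(cfg, sig)
        assert counts.shape[1] == 0 and len(ann) == 0

    def test_pure_myeloid_proportions(self):
        cfg = SyntheticSingleCellConfig(
            cell_type_proportions={"myeloid": 1.0}, cells_per_patient=20, seed=0
        )
        sig = Signature(["R1"], ["L1"])
        _, ann, _ = generate_single_cell(cfg, sig)
        assert (ann["cell_type"] == "myeloid").all()

    def test_planted_genes_myeloid_predominant(self):
        """Planted genes have higher mean counts in myeloid cells than in
        every other type in >= 95% of simulations."""
        genes = [f"R{i}" for i in range(10)] + [f"L{i}" for i in range(10)]
        sig = Signature(genes[:10], genes[10:])
        wins = 0
        n_reps = 40
        for s in range(n_reps):
            cfg = SyntheticSingleCellConfig(n_patients=2, cells_per_patient=100, seed=s)
            counts, ann, planted = generate_single_cell(cfg, sig)
            by_type = counts.loc[planted].T.groupby(ann["cell_type"].to_numpy()).mean().T
            myeloid = by_type["myeloid"]
            others = by_type.drop(columns="myeloid")
            wins += (myeloid.to_numpy()[:, None] > others.to_numpy()).all()
        assert wins / n_reps >= 0.95

    def test_determinism(self):
        cfg = SyntheticSingleCellConfig(seed=6, n_patients=1, cells_per_patient=50)
        sig = Signature(["R1", "R2"], ["L1", "L2"])
        c1, a1, _ = generate_single_cell(cfg, sig)
        c2, a2, _ = generate_single_cell(cfg, sig)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(a1, a2)


class TestTwoReferences:
    @pytest.mark.parametrize("fraction,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_planted_concordance_fraction(self, fraction, expected):
        genes = [f"g{i}" for i in range(60)]
        _, _, truth = generate_two_references(genes, concordant_fraction=fraction, seed=21)
        assert truth["concordant"].mean() == pytest.approx(expected, abs=0.02)

    def test_discordant_genes_have_different_tops(self):
        genes = [f"g{i}" for i in range(50)]
        _, _, truth = generate_two_references(genes, concordant_fraction=0.4, seed=22)
        disc = truth[~truth["concordant"]]
        assert (disc["type_ref1"] != disc["type_ref2"]).all()
        conc = truth[truth["concordant"]]
        assert (conc["type_ref1"] == conc["type_ref2"]).all()


class TestCellLinePanel:
    def test_sensitivity_anticorrelates_with_activity(self):
        sig = Signature([f"R{i}" for i in range(20)], [f"L{i}" for i in range(20)])
        expr, panel = generate_cell_line_panel(sig, seed=31)
        r = stats.spearmanr(panel["activity"], panel["drug_sensitivity"]).statistic
        assert r < -0.5
        assert expr.n_samples == 25
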