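"""ΔCt quantification, empirical-Bayes moderation and differential calls."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special

from epimir.io import CtTable, SampleMeta
from epimir.qpcr import (
    ContrastResult, ModerationPrior, call_mature_differential,
    contrast_fold_change, delta_ct, estimate_moderation_prior,
    moderated_t, pri_quantification, relative_quantity, student_t,
)


def make_ct(values, targets, conditions, replicates=2, censored_at=None):
    """Ct table with columns for each (cell, treatment) x replicate."""
    samples = [
        SampleMeta("RNA", cell, trt, r)
        for (cell, trt) in conditions for r in range(1, replicates + 1)
    ]
    ct = pd.DataFrame(values, index=targets,
                      columns=[s.sample_id for s in samples])
    censored = pd.DataFrame(False, index=ct.index, columns=ct.columns)
    if censored_at:
        for pos in censored_at:
            censored.iloc[pos] = True
    return CtTable(ct=ct, censored=censored, samples=samples)


class TestDeltaCt:
    def test_subtracts_reference_per_sample(self):
        table = make_ct(
            [[20.0, 20.0], [25.0, 26.0]], ["REF", "MIRX"],
            [("PrEC", "none")], replicates=2,
        )
        dct, _ = delta_ct(table, "REF")
        assert list(dct.index) == ["MIRX"]
        np.testing.assert_allclose(dct.loc["MIRX"], [5.0, 6.0])

    def test_missing_reference_rejected(self):
        table = make_ct([[25.0, 26.0]], ["MIRX"], [("PrEC", "none")])
        with pytest.raises(ValueError):
            delta_ct(table, "REF")

    def test_censored_reference_rejected(self):
        table = make_ct(
            [[40.0, 20.0], [25.0, 26.0]], ["REF", "MIRX"],
            [("PrEC", "none")], censored_at=[(0, 0)],
        )
        with pytest.raises(ValueError, match="censored"):
            delta_ct(table, "REF")

    def test_censored_target_flag_propagates(self):
        table = make_ct(
            [[20.0, 20.0], [40.0, 26.0]], ["REF", "MIRX"],
            [("PrEC", "none")], censored_at=[(1, 0)],
        )
        dct, censored = delta_ct(table, "REF")
        assert dct.loc["MIRX"].iloc[0] == 20.0  # computed at the censor bound
        assert bool(censored.loc["MIRX"].iloc[0])


class TestRelativeQuantity:
    @pytest.mark.parametrize("dct, expected", [(0.0, 1.0), (5.0, 0.03125), (-1.0, 2.0)])
    def test_two_to_minus_dct(self, dct, expected):
        out = relative_quantity(pd.DataFrame([[dct]]))
        assert out.iloc[0, 0] == pytest.approx(expected)


class TestContrastFoldChange:
    def test_ddct_arithmetic(self):
        dct = pd.DataFrame(
            [[4.0, 4.0, 5.0, 5.0]], index=["MIRX"], columns=list("abcd")
        )
        fc, log2fc = contrast_fold_change(dct, ["a", "b"], ["c", "d"])
        assert fc.loc["MIRX"] == pytest.approx(2.0)
        assert log2fc.loc["MIRX"] == pytest.approx(1.0)

    def test_equal_means_give_unit_fold_change(self):
        dct = pd.DataFrame([[3.0, 3.0]], index=["M"], columns=["a", "b"])
        fc, _ = contrast_fold_change(dct, ["a"], ["b"])
        assert fc.loc["M"] == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        dct = pd.DataFrame(rng.normal(5, 1, size=(10, 4)),
                           columns=list("abcd"))
        fc_ab, _ = contrast_fold_change(dct, ["a", "b"], ["c", "d"])
        fc_ba, _ = contrast_fold_change(dct, ["c", "d"], ["a", "b"])
        np.testing.assert_allclose(fc_ab * fc_ba, 1.0, rtol=1e-12)

    def test_empty_group_rejected(self):
        dct = pd.DataFrame([[3.0]], columns=["a"])
        with pytest.raises(ValueError):
            contrast_fold_change(dct, [], ["a"])


class TestModerationPrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_moderation_prior(np.full(50, 0.3), 4.0)
        assert math.isinf(prior.d0)
        # geometric-mean estimate with log-chi-square bias correction:
        # exp(log 0.3 - digamma(d/2) + log(d/2)) for d = 4
        expected = 0.3 * math.exp(-special.digamma(2.0) + math.log(2.0))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-9)

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValueError):
            estimate_moderation_prior([0.1, 0.2], 4.0)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_moderation_prior(np.zeros(20), 4.0)

    def test_parameter_recovery_from_scaled_inv_chisq(self):
        # true variances from the s0^2 * d0 / chisq_d0 prior, observed as
        # 4-df sample variances; moment estimator recovers both parameters
        rng = np.random.default_rng(42)
        d0, s0_sq, n, d_g = 4.0, 1.0, 5000, 4.0
        sigma2 = s0_sq * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d_g, n) / d_g
        prior = estimate_moderation_prior(s2, d_g)
        assert 3.0 <= prior.d0 <= 5.0
        assert 0.9 <= prior.s0_sq <= 1.1


class TestModeratedT:
    def test_d0_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(3)
        prior = ModerationPrior(d0=0.0, s0_sq=1.0)
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            t_m, df_m, p_m = moderated_t(a, b, prior)
            t_c, df_c, p_c = student_t(a, b)
            assert abs(t_m - t_c) < 1e-10
            assert abs(p_m - p_c) < 1e-10
            assert df_m == df_c

    def test_d0_infinite_uses_prior_variance_exactly(self):
        prior = ModerationPrior(d0=math.inf, s0_sq=0.04)
        t, df, p = moderated_t([1.0, 1.2], [0.0, 0.2], prior)
        assert t == pytest.approx(1.0 / math.sqrt(0.04 * 1.0))
        assert math.isinf(df)

    def test_worked_example(self):
        prior = ModerationPrior(d0=2.0, s0_sq=0.02)
        t, df, p = moderated_t([4.0, 4.2], [5.0, 5.2], prior)
        assert t == pytest.approx(-7.0710678, rel=1e-6)
        assert df == 4.0

    def test_shrinkage_monotone_in_d0(self):
        # small observed variance is pulled up, large pulled down, as d0 grows
        def s_tilde2(s_g2, d0, s0_sq=1.0, d_g=2.0):
            return (d0 * s0_sq + d_g * s_g2) / (d0 + d_g)

        for s_g2, increasing in [(0.1, True), (4.0, False)]:
            vals = [s_tilde2(s_g2, d0) for d0 in (0.0, 1.0, 4.0, 16.0)]
            assert (np.diff(vals) > 0).all() == increasing

    def test_matches_limma_on_small_panel(self, tmp_path):
        # independent oracle: R limma on the same 30-target 2v2 panel
        rng = np.random.default_rng(17)
        n = 30
        a = rng.normal(0, 0.5, size=(n, 2))
        b = rng.normal(0, 0.5, size=(n, 2)) + rng.normal(0, 1, size=(n, 1))
        mat = np.hstack([a, b])
        csv = tmp_path / "panel.csv"
        pd.DataFrame(mat).to_csv(csv, index=False, header=False)
        out = tmp_path / "limma_t.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{csv}", header=FALSE))
            design <- cbind(Intercept=1, Diff=c(0,0,1,1))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(t=fit$t[,"Diff"], d0=fit$df.prior,
                                 s0=fit$s2.prior), "{out}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)

        d_g = 2.0
        s2 = (
            ((mat[:, :2] - mat[:, :2].mean(1, keepdims=True)) ** 2).sum(1)
            + ((mat[:, 2:] - mat[:, 2:].mean(1, keepdims=True)) ** 2).sum(1)
        ) / d_g
        prior = estimate_moderation_prior(s2, d_g)
        assert prior.d0 == pytest.approx(ref["d0"][0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s0"][0], rel=1e-4)
        ours = np.array(
            [moderated_t(mat[i, 2:], mat[i, :2], prior)[0] for i in range(n)]
        )
        np.testing.assert_allclose(ours, ref["t"].to_numpy(), rtol=1e-6)


class TestDifferentialCalls:
    @pytest.mark.parametrize(
        "fc, p, significant",
        [
            (2.235, 0.01, True),     # clear induction, starred
            (1.4, 0.001, False),     # fails the fold cutoff
            (1.505, 0.2, False),     # fold passes, p does not
            (0.637, 0.01, True),     # repression beyond 1/1.5
            (1.5, 0.01, True),       # inclusive boundary
        ],
    )
    def test_p_and_fold_rule(self, fc, p, significant):
        r = ContrastResult(target_id="M", contrast="LvP", fold_change=fc,
                           log2fc=math.log2(fc), p_value=p)
        (out,) = call_mature_differential([r], p_cut=0.05, fc_cut=1.5)
        assert out.significant is significant

    def test_type_i_error_calibrated_on_null_panel(self):
        rng = np.random.default_rng(7)
        n = 5000
        a = rng.normal(0, 0.35, size=(n, 2))
        b = rng.normal(0, 0.35, size=(n, 2))
        s2 = (
            ((a - a.mean(1, keepdims=True)) ** 2).sum(1)
            + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        ) / 2.0
        prior = estimate_moderation_prior(s2, 2.0)
        p = np.array([moderated_t(a[i], b[i], prior)[2] for i in range(n)])
        assert 0.03 <= (p < 0.05).mean() <= 0.07


class TestPriQuantification:
    def _table(self, lncap_shift, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        conditions = [("PrEC", "none"), ("LNCaP", "none")]
        ref = np.full(2 * n, 15.0)
        target = np.concatenate(
            [np.full(n, 24.0), np.full(n, 24.0 - lncap_shift)]
        ) + rng.normal(0, noise, 2 * n)
        return make_ct(
            np.vstack([ref, target]), ["18S", "PRIX"], conditions, replicates=n
        )

    def test_identical_groups_are_not_different(self):
        out = pri_quantification(self._table(0.0), contrasts=("LvP",))
        row = out[(out.target_id == "PRIX") & (out.contrast == "LvP")].iloc[0]
        assert row.p_value == 1.0
        assert not row.significant

    def test_planted_repression_recovers_quarter_ratio(self):
        out = pri_quantification(self._table(-2.0), contrasts=("LvP",))
        row = out[(out.target_id == "PRIX") & (out.contrast == "LvP")].iloc[0]
        assert row.fold_change == pytest.approx(0.25)
        assert row.mean_a / row.mean_b == pytest.approx(0.25)

    def test_single_replicate_rejected(self):
        table = self._table(1.0, n=1)
        with pytest.raises(ValueError):
            pri_quantification(table, contrasts=("LvP",))

    def test_noisy_planted_change_detected(self):
        out = pri_quantification(self._table(-2.0, noise=0.3, seed=5), contrasts=("LvP",))
        row = out[(out.target_id == "PRIX") & (out.contrast == "LvP")].iloc[0]
        assert row.significant
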