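import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from regiospec import ExpressionBundle, diffexpr

from conftest import stepup_bh


def test_hand_solved_two_donor_design(tiny_bundle):
    """donorA other=1/focal=3, donorB other=3/focal=5: beta=2, zero residuals."""
    stats = diffexpr.fit_region_model(tiny_bundle, "focal")
    row = stats.loc["p1"]
    assert row["beta"] == pytest.approx(2.0, abs=1e-10)
    assert row["s2"] == pytest.approx(0.0, abs=1e-18)
    assert row["d"] == 1.0


def test_constant_probe_has_zero_beta_and_variance(tiny_bundle):
    stats = diffexpr.fit_region_model(tiny_bundle, "focal")
    assert stats.loc["p3", "beta"] == pytest.approx(0.0, abs=1e-12)
    assert stats.loc["p3", "s2"] == pytest.approx(0.0, abs=1e-18)


def test_permutation_invariance(tiny_bundle):
    perm = ["s3", "s1", "s4", "s2"]
    shuffled = ExpressionBundle(
        tiny_bundle.matrix[perm],
        tiny_bundle.probe_annot,
        tiny_bundle.sample_annot.loc[perm],
    )
    a = diffexpr.fit_region_model(tiny_bundle, "focal")
    b = diffexpr.fit_region_model(shuffled, "focal")
    pd.testing.assert_frame_equal(a, b)


def test_absent_region_errors_with_name(tiny_bundle):
    with pytest.raises(diffexpr.DesignError, match="elsewhere"):
        diffexpr.fit_region_model(tiny_bundle, "elsewhere")


def test_collinear_design_detected():
    matrix = pd.DataFrame(
        np.arange(8.0).reshape(2, 4), index=["p1", "p2"], columns=list("abcd")
    )
    annot = pd.DataFrame(
        {
            "donor_id": ["d1", "d1", "d2", "d2"],
            "region_name": ["focal", "focal", "other", "other"],
        },
        index=pd.Index(list("abcd"), name="sample_id"),
    )
    bundle = ExpressionBundle(matrix, pd.Series(["G1", "G2"], index=matrix.index), annot)
    with pytest.raises(diffexpr.DesignError, match="rank-deficient"):
        diffexpr.fit_region_model(bundle, "focal")


def test_ols_matches_normal_equations_on_random_designs():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n_donors = rng.integers(2, 4)
        donors = [f"d{i}" for i in range(n_donors)]
        n = int(rng.integers(8, 15))
        annot = pd.DataFrame(
            {
                "donor_id": rng.choice(donors, n),
                "region_name": rng.choice(["focal", "r1", "r2"], n),
            },
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        Y = rng.normal(size=(5, n))
        matrix = pd.DataFrame(Y, index=[f"p{i}" for i in range(5)], columns=annot.index)
        bundle = ExpressionBundle(
            matrix, pd.Series([f"G{i}" for i in range(5)], index=matrix.index), annot
        )
        try:
            stats = diffexpr.fit_region_model(bundle, "focal")
        except diffexpr.DesignError:
            continue
        X = diffexpr.build_design(annot, "focal").to_numpy()
        beta_ref = np.linalg.solve(X.T @ X, X.T @ Y.T)[-1]
        np.testing.assert_allclose(stats["beta"].to_numpy(), beta_ref, atol=1e-10)


class TestVariancePrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = diffexpr.estimate_variance_prior(np.full(500, 2.5), d=6)
        assert math.isinf(prior.d0)
        assert prior.s0sq == pytest.approx(2.5, rel=1e-6)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(42)
        d0_true, s0sq_true, d = 4.0, 1.0, 10
        sigma2 = s0sq_true * d0_true / rng.chisquare(d0_true, size=10_000)
        s2 = sigma2 * rng.chisquare(d, size=10_000) / d
        prior = diffexpr.estimate_variance_prior(s2, d=d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0sq == pytest.approx(s0sq_true, rel=0.15)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        s2 = rng.chisquare(5, size=2000)
        p1 = diffexpr.estimate_variance_prior(s2, d=8)
        p2 = diffexpr.estimate_variance_prior(2 * s2, d=8)
        assert p2.s0sq == pytest.approx(2 * p1.s0sq, rel=1e-9)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-6)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            diffexpr.estimate_variance_prior(np.zeros(100), d=5)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in [0.01, 0.5, 1.0, 7.3, 250.0]:
            y = float(polygamma(1, x))
            assert diffexpr.trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeration:
    def _stats(self, beta, s2, d, v):
        return pd.DataFrame(
            {"beta": [beta], "s2": [s2], "d": [float(d)], "v": [v],
             "stderr_unmoderated": [np.sqrt(s2 * v)],
             "t_ordinary": [beta / np.sqrt(s2 * v) if s2 > 0 else 0.0]},
            index=["p1"],
        )

    def test_worked_value(self):
        mod = diffexpr.moderate(self._stats(2.0, 4.0, 4, 0.5), diffexpr.VariancePrior(4, 1))
        assert mod["s2_tilde"].iloc[0] == pytest.approx(2.5)
        assert mod["t_tilde"].iloc[0] == pytest.approx(2 / math.sqrt(2.5 * 0.5), rel=1e-12)
        assert mod["t_tilde"].iloc[0] == pytest.approx(1.7889, abs=5e-5)
        assert mod["df_total"].iloc[0] == 8.0

    def test_no_shrinkage_limit_matches_ordinary_t(self):
        stats = self._stats(1.3, 2.0, 6, 0.4)
        mod = diffexpr.moderate(stats, diffexpr.VariancePrior(1e-12, 1.0))
        assert mod["t_tilde"].iloc[0] == pytest.approx(stats["t_ordinary"].iloc[0], rel=1e-9)
        assert mod["df_total"].iloc[0] == pytest.approx(6.0, rel=1e-9)

    def test_infinite_shrinkage_limit(self):
        mod = diffexpr.moderate(self._stats(1.3, 2.0, 6, 0.4), diffexpr.VariancePrior(math.inf, 0.9))
        assert mod["s2_tilde"].iloc[0] == 0.9
        assert mod["t_tilde"].iloc[0] == pytest.approx(1.3 / math.sqrt(0.9 * 0.4), rel=1e-12)
        assert math.isinf(mod["df_total"].iloc[0])
        # p comes from the normal in this limit
        assert mod["p"].iloc[0] == pytest.approx(2 * ss.norm.sf(abs(mod["t_tilde"].iloc[0])))

    def test_zero_beta_gives_p_one(self):
        mod = diffexpr.moderate(self._stats(0.0, 2.0, 6, 0.4), diffexpr.VariancePrior(4, 1))
        assert mod["t_tilde"].iloc[0] == 0.0
        assert mod["p"].iloc[0] == 1.0

    def test_zero_variance_probe_is_analyzable(self):
        mod = diffexpr.moderate(self._stats(1.0, 0.0, 4, 0.5), diffexpr.VariancePrior(4, 1))
        assert mod["s2_tilde"].iloc[0] == pytest.approx(4 * 1 / 8)
        assert np.isfinite(mod["t_tilde"].iloc[0])

    def test_sign_of_t_matches_beta_and_q_dominates_p(self, default_atlas):
        cfg, bundle, _, _ = default_atlas
        stats = diffexpr.fit_region_model(bundle, cfg.focal_region)
        prior = diffexpr.estimate_variance_prior(stats["s2"].to_numpy(), stats["d"].iloc[0])
        mod = diffexpr.moderate(stats, prior)
        assert (np.sign(mod["t_tilde"]) == np.sign(mod["beta"])).all()
        assert (mod["q"] >= mod["p"] - 1e-15).all()
        assert mod["q"].between(0, 1).all()


class TestBH:
    def test_worked_example(self):
        q = diffexpr.bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(diffexpr.bh_adjust(np.ones(5)), np.ones(5))
        np.testing.assert_allclose(diffexpr.bh_adjust(np.array([0.2])), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_stepup_definition(self, p_list):
        p = np.array(p_list)
        np.testing.assert_allclose(diffexpr.bh_adjust(p), stepup_bh(p), atol=1e-12)


def test_pvalues_uniform_under_null():
    """KS distance of null moderated p-values from U(0,1) is small."""
    from regiospec import simulate

    cfg = simulate.SyntheticConfig(
        seed=123, n_genes=10_000, probes_per_gene={2: 1.0}, effect_size_delta=0.0
    )
    bundle, _ = simulate.generate_atlas(cfg)
    stats = diffexpr.fit_region_model(bundle, cfg.focal_region)
    prior = diffexpr.estimate_variance_prior(stats["s2"].to_numpy(), stats["d"].iloc[0])
    mod = diffexpr.moderate(stats, prior)
    ks = ss.kstest(mod["p"], "uniform").statistic
    assert ks < 0.02


def test_boundary_and_direction_filters():
    mod = pd.DataFrame(
        {
            "beta": [1.0, -1.0, 1.0],
            "p": [0.001, 0.001, 0.01],
            "q": [0.04, 0.04, 0.05],
        },
        index=["up", "down", "at_alpha"],
    )
    sig = diffexpr.significant_upregulated(mod, alpha=0.05)
    assert list(sig.index) == ["up"]


def test_empirical_fdr_on_mixed_atlas():
    """Observed FDR among up-regulated calls stays near nominal on spiked data."""
    from regiospec import simulate

    total_false = total_called = 0
    for seed in range(10):
        cfg = simulate.SyntheticConfig(seed=seed, spike_fraction=0.10)
        bundle, truth = simulate.generate_atlas(cfg)
        stats = diffexpr.fit_region_model(bundle, cfg.focal_region)
        prior = diffexpr.estimate_variance_prior(stats["s2"].to_numpy(), stats["d"].iloc[0])
        mod = diffexpr.moderate(stats, prior)
        sig = diffexpr.significant_upregulated(mod, alpha=0.05)
        genes = bundle.probe_annot.loc[sig.index]
        spiked = set(truth.spiked_genes)
        total_called += len(sig)
        total_false += int((~genes.isin(spiked)).sum())
    assert total_called > 0
    assert total_false / total_called <= 1.5 * 0.05
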