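"""Monte Carlo study machinery: replicates, aggregation, seeding, quadrature oracle."""

import numpy as np
import pandas as pd
import pytest

import lomaxbayes as lb
from lomaxbayes.study import _cell_rng, _simulate_gamma


SMALL = lb.StudyConfig(n_values=(25,), beta_values=(1.0,), reps=200, seed=42)


class TestRunReplicate:
    def test_deterministic(self):
        r1 = lb.run_replicate(SMALL, 1.0, 25, np.random.default_rng(3))
        r2 = lb.run_replicate(SMALL, 1.0, 25, np.random.default_rng(3))
        assert r1 == r2

    def test_all_columns_present(self):
        r = lb.run_replicate(SMALL, 1.0, 25, np.random.default_rng(3))
        assert len(r) == 1 + 2 * (3 + 3 * len(SMALL.c_values))
        assert {"MLE", "B-SELF", "EB-WCLLF(c=1.5)"} <= set(r)

    def test_bayes_self_passthrough(self):
        # the squared-error Bayes column is (n+z)/(gamma+k) for the replicate's own gamma
        rng = np.random.default_rng(3)
        stats = lb.sample(lb.LomaxParams(1.0, 3.0), 25, np.random.default_rng(3))
        r = lb.run_replicate(SMALL, 1.0, 25, rng)
        assert r["B-SELF"] == pytest.approx((25 + 0.6) / (stats.gamma_stat + 0.5), rel=1e-12)

    def test_weight_decay_shrinks_composite(self):
        # per replicate, the omega=0.5 weighted estimate sits below the unweighted one
        for seed in range(10):
            r = lb.run_replicate(SMALL, 1.0, 25, np.random.default_rng(seed))
            assert r["B-WCLLF(c=0.5)"] < r["B-CLLF(c=0.5)"]
            assert r["EB-WCLLF(c=0.5)"] < r["EB-CLLF(c=0.5)"]


class TestAggregate:
    def test_degenerate(self):
        out = lb.aggregate([{"e": 1.0}, {"e": 1.0}, {"e": 1.0}], 1.0).iloc[0]
        assert out["AE"] == 1.0 and out["MASE"] == 0.0

    def test_arithmetic(self):
        out = lb.aggregate({"e": [0.9, 1.1]}, 1.0).iloc[0]
        assert out["AE"] == pytest.approx(1.0)
        assert out["MASE"] == pytest.approx(0.01)

    def test_bias_variance_identity(self, rng):
        vals = rng.normal(1.2, 0.3, 500)
        out = lb.aggregate({"e": vals}, 1.0).iloc[0]
        decomposed = vals.var() + (out["AE"] - 1.0) ** 2
        assert out["MASE"] == pytest.approx(decomposed, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lb.aggregate([], 1.0)


class TestRunStudy:
    def test_vectorized_path_matches_replicate_loop(self):
        cfg = lb.StudyConfig(n_values=(10,), beta_values=(1.5,), reps=6, seed=9)
        gam = _simulate_gamma(cfg, 1.5, 10, _cell_rng(cfg, 0))
        # consume the same per-cell stream sequentially for all 6 replicates
        rng = _cell_rng(cfg, 0)
        rows = [lb.run_replicate(cfg, 1.5, 10, rng) for _ in range(6)]
        mles = np.array([r["MLE"] for r in rows])
        np.testing.assert_array_equal(mles, 10.0 / gam)

    def test_single_replicate_degenerate(self):
        cfg = lb.StudyConfig(n_values=(25,), beta_values=(1.0,), reps=1, seed=5)
        table = lb.run_study(cfg).long
        rng = _cell_rng(cfg, 0)
        rep = lb.run_replicate(cfg, 1.0, 25, rng)
        for _, row in table.iterrows():
            assert row["AE"] == pytest.approx(rep[row["estimator"]], rel=1e-12)
            assert row["MASE"] == pytest.approx((rep[row["estimator"]] - 1.0) ** 2, rel=1e-12)

    def test_reproducible_and_cell_independent(self):
        cfg = lb.StudyConfig(n_values=(10, 20), beta_values=(1.0,), reps=50, seed=77)
        t1 = lb.run_study(cfg).long
        t2 = lb.run_study(cfg).long
        pd.testing.assert_frame_equal(t1, t2)
        # any cell is reproducible in isolation from the master seed and its index
        gam_joint = _simulate_gamma(cfg, 1.0, 20, _cell_rng(cfg, 1))
        gam_again = _simulate_gamma(cfg, 1.0, 20, _cell_rng(cfg, 1))
        np.testing.assert_array_equal(gam_joint, gam_again)

    def test_doubling_reps_converges(self):
        c1 = lb.StudyConfig(n_values=(25,), beta_values=(1.0,), reps=2000, seed=8)
        c2 = lb.StudyConfig(n_values=(25,), beta_values=(1.0,), reps=4000, seed=8)
        r1 = lb.run_study(c1).long.set_index("estimator")
        r2 = lb.run_study(c2).long.set_index("estimator")
        for lbl in r1.index:
            pooled = np.hypot(r1.loc[lbl, "AE_se"], r2.loc[lbl, "AE_se"])
            assert abs(r1.loc[lbl, "AE"] - r2.loc[lbl, "AE"]) < 3 * pooled

    def test_skip_invalid_counts(self):
        # gamma below c=1.5 trips the E-Bayes composite guard at tiny n
        cfg = lb.StudyConfig(n_values=(1,), beta_values=(1.0,), reps=300, seed=4,
                             c_values=(1.5,), skip_invalid=True)
        table = lb.run_study(cfg)
        assert table.failed_replicates > 0
        cfg_strict = lb.StudyConfig(n_values=(1,), beta_values=(1.0,), reps=300, seed=4,
                                    c_values=(1.5,))
        with pytest.raises(ValueError, match="outside the domain"):
            lb.run_study(cfg_strict)

    def test_wide_layout(self, study_result):
        wide = study_result.wide("MASE", "ebayes")
        assert wide.shape == (12, 9)
        assert all(lbl.startswith("EB-") for lbl in wide.columns)
        assert study_result.failed_replicates == 0

    def test_serialization(self, tmp_path, study_result):
        study_result.to_csv(tmp_path / "t.csv")
        study_result.to_json(tmp_path / "t.json")
        back = pd.read_csv(tmp_path / "t.csv")
        assert len(back) == len(study_result.long)


class TestQuadratureOracle:
    def test_mle_closed_form_moments(self, reference_config):
        # gamma ~ Gamma(n, rate beta): E[n/gamma] = n beta/(n-1),
        # E[(n/gamma - beta)^2] = beta^2 [n^2/((n-1)(n-2)) - 2n/(n-1) + 1]
        ae, mase = lb.expected_performance_quadrature(reference_config, 1.0, 25, "MLE")
        assert ae == pytest.approx(25.0 / 24.0, rel=1e-9)
        assert mase == pytest.approx(625.0 / 552.0 - 50.0 / 24.0 + 1.0, rel=1e-8)

    def test_scales_with_beta(self, reference_config):
        ae, mase = lb.expected_performance_quadrature(reference_config, 2.0, 25, "MLE")
        assert ae == pytest.approx(2.0 * 25.0 / 24.0, rel=1e-9)
        assert mase == pytest.approx(4.0 * (625.0 / 552.0 - 50.0 / 24.0 + 1.0), rel=1e-8)

    @pytest.mark.parametrize("label", ["B-SELF", "B-WCLLF(c=1.5)", "EB-SELF", "EB-WCLLF(c=1.5)"])
    def test_monte_carlo_agrees_with_quadrature(self, label, reference_config, study_result):
        long = study_result.long
        row = long[(long.beta == 1.0) & (long.n == 25) & (long.estimator == label)].iloc[0]
        ae_q, mase_q = lb.expected_performance_quadrature(reference_config, 1.0, 25, label)
        assert abs(row["AE"] - ae_q) < 4 * row["AE_se"]
        assert abs(row["MASE"] - mase_q) < 4 * row["MASE_se"]

    def test_undefined_region_refused(self, reference_config):
        # at n=2, beta=1 the event gamma <= c = 1.5 has visible mass
        with pytest.raises(ValueError, match="probability"):
            lb.expected_performance_quadrature(reference_config, 1.0, 2, "EB-CLLF(c=1.5)")

    def test_unknown_label(self, reference_config):
        with pytest.raises(KeyError):
            lb.expected_performance_quadrature(reference_config, 1.0, 25, "nope")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_values=()), dict(beta_values=(-1.0,)), dict(sigma=0.0),
         dict(c_values=(0.0,)), dict(omega=-0.1), dict(reps=0)],
    )
    def test_rejects_bad_fields(self, kwargs):
        with pytest.raises(ValueError):
            lb.StudyConfig(**kwargs)
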