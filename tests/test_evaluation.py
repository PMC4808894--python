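"""Replication harness: metrics, Bonferroni CIs, exclusion rule, bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from usualintake import (
    EstimatorConfig,
    ReplicateOutcome,
    ScenarioSpec,
    TrueDistribution,
    UsualIntakeEstimate,
    VarianceComponents,
    bonferroni_ci,
    compute_metrics,
    get_scenario,
    run_replicate,
    run_study,
)

FAST = EstimatorConfig(nci_pseudo_persons=1000)

_COMPS = VarianceComponents(7.5, 0.25, 1.0, truncated=False)


def _fake_outcome(idx, values_by_method, degenerate=False):
    """Outcome where every statistic of a method equals one number."""
    estimates = {
        m: UsualIntakeEstimate(
            method=m,
            mean=v,
            percentiles={p: v for p in (0.1, 0.5, 0.9)},
            lam_hat=0.2,
            components=_COMPS,
            degenerate=degenerate,
        )
        for m, v in values_by_method.items()
    }
    return ReplicateOutcome(idx, estimates, excluded=degenerate)


_TRUTH = TrueDistribution(mean=2.0, percentiles={0.1: 2.0, 0.5: 2.0, 0.9: 2.0})


class TestComputeMetrics:
    def test_symmetric_errors_cancel(self):
        outcomes = [
            _fake_outcome(i, {"spade": v, "nci": v, "msm": v})
            for i, v in enumerate([1.0, 2.0, 3.0])
        ]
        table = compute_metrics(outcomes, _TRUTH)
        assert (table["bias"] == 0).all()
        assert (table["rel_bias_pct"] == 0).all()
        assert table["mse"].unique() == pytest.approx([2 / 3])

    def test_direct_substitution(self):
        # constant estimate 3 against truth 2: B=1, RB=50%, MSE=1
        outcomes = [
            _fake_outcome(i, {"spade": 3.0, "nci": 3.0, "msm": 3.0}) for i in range(2)
        ]
        table = compute_metrics(outcomes, _TRUTH)
        assert (table["bias"] == 1.0).all()
        assert (table["rel_bias_pct"] == 50.0).all()
        assert (table["mse"] == 1.0).all()

    def test_mse_dominates_squared_bias(self):
        rng = np.random.default_rng(1)
        outcomes = [
            _fake_outcome(i, {"spade": v, "nci": v, "msm": v})
            for i, v in enumerate(rng.normal(2.5, 1.0, size=50))
        ]
        table = compute_metrics(outcomes, _TRUTH)
        assert (table["mse"] >= table["bias"] ** 2).all()
        assert (table["mse"] >= 0).all()

    def test_exclusion_removes_replicate_for_all_methods(self):
        good = [
            _fake_outcome(i, {"spade": 2.0, "nci": 2.0, "msm": 2.0}) for i in range(5)
        ]
        # degenerate in one method only -> whole replicate excluded everywhere
        bad = _fake_outcome(5, {"spade": 9.0, "nci": 2.0, "msm": 2.0})
        bad = ReplicateOutcome(
            5,
            {
                **bad.estimates,
                "spade": replace(bad.estimates["spade"], degenerate=True),
            },
            excluded=True,
        )
        table = compute_metrics(good + [bad], _TRUTH)
        assert (table["N"] == 5).all()
        assert (table["bias"] == 0).all()
        # without the rule the ruined replicate leaks in
        table_all = compute_metrics(good + [bad], _TRUTH, apply_exclusion=False)
        assert (table_all["N"] == 6).all()
        assert table_all.query("method == 'spade'")["bias"].iloc[0] > 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        outcomes = [
            _fake_outcome(i, {"spade": v, "nci": v + 0.1, "msm": v - 0.1})
            for i, v in enumerate(rng.normal(2.0, 0.5, size=30))
        ]
        a = compute_metrics(outcomes, _TRUTH)
        b = compute_metrics(outcomes[::-1], _TRUTH)
        a = a.sort_values(["method", "statistic"]).reset_index(drop=True)
        b = b.sort_values(["method", "statistic"]).reset_index(drop=True)
        num = a.select_dtypes("number")
        np.testing.assert_allclose(num.to_numpy(), b[num.columns].to_numpy(), rtol=1e-12)

    def test_all_excluded_raises(self):
        outcomes = [
            _fake_outcome(i, {"spade": 2.0, "nci": 2.0, "msm": 2.0}, degenerate=True)
            for i in range(3)
        ]
        with pytest.raises(ValueError):
            compute_metrics(outcomes, _TRUTH)


class TestBonferroniCi:
    def test_constant_values_give_point_interval(self):
        lo, hi = bonferroni_ci([1.5] * 10, n_methods=3)
        assert lo == pytest.approx(1.5)
        assert hi == pytest.approx(1.5)

    def test_single_method_is_plain_t_interval(self, rng):
        x = rng.normal(0, 1, size=40)
        lo, hi = bonferroni_ci(x, n_methods=1, level=0.95)
        ref = stats.t.interval(0.95, len(x) - 1, loc=x.mean(), scale=stats.sem(x))
        assert (lo, hi) == pytest.approx(ref)

    def test_correction_widens_interval(self, rng):
        x = rng.normal(0, 1, size=40)
        plain = bonferroni_ci(x, n_methods=1)
        corr = bonferroni_ci(x, n_methods=4)
        assert corr[0] < plain[0] < plain[1] < corr[1]

    def test_coverage_with_correction(self, rng):
        # per-interval nominal level is 1 - 0.05/4 = 98.75%
        covered = 0
        for _ in range(300):
            lo, hi = bonferroni_ci(rng.normal(0, 1, size=50), n_methods=4)
            covered += lo <= 0 <= hi
        assert covered / 300 > 0.95

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bonferroni_ci([1.0], n_methods=3)
        with pytest.raises(ValueError):
            bonferroni_ci([1.0, 2.0], n_methods=0)


class TestRunReplicate:
    def test_determinism(self):
        spec = get_scenario("I")
        a = run_replicate(spec, 3, 11, FAST)
        b = run_replicate(spec, 3, 11, FAST)
        assert a.excluded == b.excluded
        for m in a.estimates:
            assert a.estimates[m].mean == b.estimates[m].mean
            assert a.estimates[m].percentiles == b.estimates[m].percentiles

    def test_nearly_zero_between_variance_is_excluded(self):
        spec = ScenarioSpec("degen", n=50, sigma_eps_sq=1.0, sigma_u_sq=1e-12)
        out = run_replicate(spec, 0, 5, FAST)
        assert out.excluded

    def test_healthy_large_sample_rarely_excluded(self):
        spec = get_scenario("V")
        outs = [run_replicate(spec, r, 13, FAST) for r in range(5)]
        assert sum(o.excluded for o in outs) == 0


class TestRunStudy:
    def test_bookkeeping_and_determinism(self):
        specs = [replace(get_scenario("I"), n=40), replace(get_scenario("VII"), n=40)]
        a = run_study(specs, replicates=5, seed=3, config=FAST)
        b = run_study(specs, replicates=5, seed=3, config=FAST)
        assert a.metrics.equals(b.metrics)

        # 2 scenarios x 5 replicates x 3 methods x (mean + 7 percentiles)
        assert len(a.replicates) == 2 * 5 * 3 * 8
        assert set(a.exclusions["scenario"]) == {"I", "VII"}
        assert (a.exclusions["replicates"] == 5).all()
        assert set(a.metrics["method"]) == {"spade", "nci", "msm"}
        # the no-exclusion table never has fewer usable replicates
        assert (a.metrics_all["N"] >= a.metrics["N"].min()).all()

    def test_study_writer(self, tmp_path):
        from usualintake.evaluation import write_study

        spec = replace(get_scenario("I"), n=40)
        result = run_study([spec], replicates=3, seed=1, config=FAST)
        write_study(result, tmp_path, manifest={"seed": 1})
        for name in ("summary.csv", "summary_all.csv", "replicates.csv",
                     "exclusions.csv", "manifest.json"):
            assert (tmp_path / name).exists()
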