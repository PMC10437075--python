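import numpy as np
import pytest

from structlearn.agents import AgentConfig
from structlearn.protocol import build_group_config, run_experiment
from structlearn.stats_report import (
    agent_summary,
    cognitive_scores,
    correlation,
    group_design,
    incremental_r2,
    post_normalized_pi,
    recovery_experiment,
    training_block_tables,
)


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.arange(5.0)
        assert correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_from_definition_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r = correlation(x, y).r
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_ci_brackets_r_and_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        small = correlation(x[:20], y[:20])
        large = correlation(x, y)
        for res in (small, large):
            assert res.ci[0] < res.r < res.ci[1]
        assert (large.ci[1] - large.ci[0]) < (small.ci[1] - small.ci[0])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlation([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


class TestIncrementalR2:
    def test_adding_the_response_explains_the_remainder(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        base = group_design([1] * 20 + [2] * 20)
        full_gain = incremental_r2(y, base, y)
        beta, *_ = np.linalg.lstsq(base, y, rcond=None)
        resid = y - base @ beta
        base_r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert full_gain == pytest.approx(1.0 - base_r2, abs=1e-10)

    def test_collinear_addition_gains_nothing(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        base = group_design([1] * 10 + [2] * 10 + [3] * 10)
        dup = base[:, 1] * 2.0  # linear in an existing column
        assert incremental_r2(y, base, dup) == pytest.approx(0.0, abs=1e-10)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(3)
        n = 60
        base = np.column_stack([np.ones(n), rng.normal(size=n)])
        added = rng.normal(size=n)
        y = rng.normal(size=n)

        def r2(design):
            proj = design @ np.linalg.pinv(design)
            fit = proj @ y
            return 1 - np.sum((y - fit) ** 2) / np.sum((y - y.mean()) ** 2)

        oracle = r2(np.column_stack([base, added])) - r2(base)
        assert incremental_r2(y, base, added) == pytest.approx(oracle, abs=1e-10)

    def test_rank_deficient_base_rejected(self):
        y = np.arange(10.0)
        base = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            incremental_r2(y, base, y)

    def test_group_design_shape(self):
        d = group_design([1, 1, 2, 3, 3])
        assert d.shape == (5, 3)
        np.testing.assert_array_equal(d[:, 0], 1.0)
        np.testing.assert_array_equal(d[:, 1], [0, 0, 1, 0, 0])


@pytest.fixture(scope="module")
def small():
    cfg = build_group_config(1, n_training_blocks=4, seed=17)
    log = run_experiment(cfg, AgentConfig(policy="matching", p_null=0.009))
    return cfg, log


@pytest.fixture(scope="module")
def short_config():
    return build_group_config(1, n_training_blocks=6, seed=0)


class TestAgentSummary:
    def test_block_tables_in_order(self, small):
        cfg, log = small
        tables = training_block_tables(log)
        assert len(tables) == cfg.n_training_blocks
        for t in tables:
            assert t.support_counts.sum() == cfg.trials_per_training_block

    def test_summary_fields_consistent(self, small):
        cfg, log = small
        s = agent_summary(log, cfg)
        assert set(s) == {
            "strategy_index",
            "pre_normalized_pi",
            "post_normalized_pi",
            "improvement",
        }
        assert s["improvement"] == pytest.approx(
            s["post_normalized_pi"] - s["pre_normalized_pi"]
        )
        assert s["post_normalized_pi"] == pytest.approx(post_normalized_pi(log, cfg))

    def test_matching_agent_post_pi_near_ceiling(self, small):
        cfg, log = small
        # an exact-matching responder's normalized PI sits near 1 - 0.45
        assert post_normalized_pi(log, cfg) > 0.40

    def test_empty_training_log_rejected(self, small):
        _, log = small
        with pytest.raises(ValueError, match="training"):
            training_block_tables(log[log["session"] != "training"])


class TestCognitiveScores:
    def test_fields_and_ranges(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            s = cognitive_scores(rng)
            assert s["wm_score"] >= 2.0
            assert 16.7 <= s["attention_score"] <= 500.0

    def test_reproducible(self):
        a = cognitive_scores(np.random.default_rng(8))
        b = cognitive_scores(np.random.default_rng(8))
        assert a == b


class TestRecovery:
    def test_pure_grid_index_monotone_and_correlation_negative(self, short_config):
        cohort, summary = recovery_experiment(
            n_agents=4, lambda_grid=(0.0, 0.5, 1.0), config=short_config, seed=10
        )
        assert len(cohort) == 12
        assert summary["index_monotone_in_lambda"]
        # with agents applying their policy to the true table, PI decreases
        # in lambda, so the cohort correlation must come out negative
        assert summary["correlation"].r < 0

    def test_quality_linked_correlation_positive(self, short_config):
        cohort, summary = recovery_experiment(
            n_agents=6,
            lambda_grid=(0.0, 0.5, 1.0),
            config=short_config,
            seed=10,
            quality_linked=True,
        )
        assert summary["index_monotone_in_lambda"]
        assert summary["correlation"].r > 0

    def test_covariates_attached_when_requested(self, short_config):
        cohort, _ = recovery_experiment(
            n_agents=1, lambda_grid=(0.0, 1.0), config=short_config, seed=3,
            with_covariates=True,
        )
        assert {"wm_score", "attention_score"} <= set(cohort.columns)

    def test_degenerate_cohort_surfaces_correlation_error(self, short_config):
        _, summary = recovery_experiment(
            n_agents=1, lambda_grid=(0.5,), config=short_config, seed=1
        )
        assert summary["correlation"] is None
        assert "correlation_error" in summary
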