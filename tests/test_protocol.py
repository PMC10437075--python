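import numpy as np
import pytest

from structlearn.agents import AgentConfig, ResponseRecord
from structlearn.markov_design import SYMBOLS, generate_trial
from structlearn.protocol import (
    GROUP_PRESETS,
    build_group_config,
    emit_feedback,
    model_for_config,
    run_experiment,
)


class TestGroupConfigs:
    def test_presets_cover_the_six_designs(self):
        assert set(GROUP_PRESETS) == set(range(1, 7))
        assert GROUP_PRESETS[2]["p_high"] == 0.6
        assert GROUP_PRESETS[3]["isi_mode"] == "jitter"
        assert GROUP_PRESETS[4]["feedback_mode"] == "trial"
        assert GROUP_PRESETS[5]["feedback_mode"] == "none"
        assert GROUP_PRESETS[6]["feedback_mode"] == "uncorrelated"
        for g in range(1, 7):
            if g != 2:
                assert GROUP_PRESETS[g]["p_high"] == 0.8

    def test_overrides_and_validation(self):
        cfg = build_group_config(1, n_training_blocks=2, seed=9)
        assert cfg.n_training_blocks == 2 and cfg.seed == 9
        with pytest.raises(ValueError):
            build_group_config(7)
        with pytest.raises(ValueError):
            build_group_config(1, feedback_mode="banana")
        with pytest.raises(ValueError):
            build_group_config(1, p_high=0.4)


class TestEmitFeedback:
    def _rec(self, chosen):
        v = np.zeros(4)
        if chosen is not None:
            v[SYMBOLS.index(chosen)] = 1.0
        else:
            v[:] = 0.25
        return ResponseRecord(0, 0, "A", v, chosen)

    def test_trial_mode_scores_against_hidden_target(self, model08, rng):
        tr = generate_trial(model08, rng=rng)
        assert emit_feedback(self._rec(tr.hidden_target), tr, "trial", rng) == "correct"
        wrong = next(s for s in SYMBOLS if s != tr.hidden_target)
        assert emit_feedback(self._rec(wrong), tr, "trial", rng) == "incorrect"
        assert emit_feedback(self._rec(None), tr, "trial", rng) == "incorrect"

    def test_trial_mode_maximizer_rate(self, model08, rng):
        # the hidden target follows the contingency, so a maximizer is
        # correct at the p_high rate
        ag = AgentConfig(policy="maximizing")
        from structlearn.agents import respond

        hits = 0
        n = 10_000
        for _ in range(n):
            tr = generate_trial(model08, rng=rng)
            rec = respond(ag, tr, model08, rng)
            hits += emit_feedback(rec, tr, "trial", rng) == "correct"
        assert hits / n == pytest.approx(0.8, abs=0.012)

    def test_uncorrelated_mode_is_independent_of_response(self, model08, rng):
        tr = generate_trial(model08, rng=rng)
        outcomes = {True: [0, 0], False: [0, 0]}
        for _ in range(4000):
            chosen = tr.hidden_target if rng.random() < 0.5 else next(
                s for s in SYMBOLS if s != tr.hidden_target
            )
            fb = emit_feedback(self._rec(chosen), tr, "uncorrelated", rng)
            outcomes[chosen == tr.hidden_target][fb == "correct"] += 1
        for was_hit in (True, False):
            total = sum(outcomes[was_hit])
            assert outcomes[was_hit][1] / total == pytest.approx(0.5, abs=0.03)

    def test_block_and_none_give_no_signal(self, model08, rng):
        tr = generate_trial(model08, rng=rng)
        assert emit_feedback(self._rec("A"), tr, "block", rng) == "none"
        assert emit_feedback(self._rec("A"), tr, "none", rng) == "none"


@pytest.fixture(scope="module")
def small_log():
    cfg = build_group_config(1, n_training_blocks=3, seed=5)
    return cfg, run_experiment(cfg, AgentConfig(policy="matching", p_null=0.009))


class TestRunExperiment:
    def test_row_counts(self, small_log):
        cfg, log = small_log
        assert len(log) == 2 * 3 * 40 + 3 * 60
        full = build_group_config(1, seed=5)
        assert full.n_training_blocks * full.trials_per_training_block == 1380
        assert 2 * len(full.test_block_plan) * full.trials_per_test_block == 240

    def test_session_structure(self, small_log):
        _, log = small_log
        assert set(log["session"]) == {"pre", "training", "post"}
        for sess in ("pre", "post"):
            plan = log[log["session"] == sess].groupby("block_id")["block_kind"].first()
            assert list(plan) == ["structured", "random", "structured"]
        assert set(log.loc[log["session"] == "training", "block_kind"]) == {"structured"}

    def test_test_sessions_carry_no_feedback(self, small_log):
        _, log = small_log
        tests = log[log["session"] != "training"]
        assert set(tests["feedback"]) == {"none"}

    def test_random_blocks_have_uniform_hidden_targets(self):
        cfg = build_group_config(1, n_training_blocks=1, trials_per_test_block=400, seed=2)
        log = run_experiment(cfg, AgentConfig(policy="matching"))
        rand = log[log["block_kind"] == "random"]
        freqs = rand["hidden_target"].value_counts(normalize=True)
        assert np.allclose(freqs.reindex(list(SYMBOLS)).to_numpy(), 0.25, atol=0.05)

    def test_same_config_and_seed_reproduces_log(self):
        cfg = build_group_config(4, n_training_blocks=1, seed=11)
        ag = AgentConfig(policy="interpolated", lambda_mix=0.5, p_null=0.009)
        a = run_experiment(cfg, ag)
        b = run_experiment(cfg, ag)
        assert a.equals(b)

    def test_retest_session_appended(self):
        cfg = build_group_config(1, n_training_blocks=1, retest=True, seed=3)
        log = run_experiment(cfg, AgentConfig(policy="matching"))
        assert set(log["session"]) == {"pre", "training", "post", "retest"}
        assert (log["session"] == "retest").sum() == 120

    def test_learning_agent_improves_over_training(self, model08):
        # block-level PI trend: the learning agent's late-block PI exceeds its
        # early-block PI in the large majority of seeds
        from structlearn.metrics import (
            performance_index,
            renormalized_weights,
        )
        from structlearn.markov_design import stationary_distribution
        from structlearn.stats_report import training_block_tables

        w_full = stationary_distribution(model08)
        wins = 0
        for seed in range(10):
            cfg = build_group_config(1, n_training_blocks=8, seed=seed)
            ag = AgentConfig(policy="learning", learn_rate=1.0)
            log = run_experiment(cfg, ag)
            tables = training_block_tables(log)

            def block_pi(cond):
                w = renormalized_weights(w_full, cond.supported)
                return performance_index(cond, model08, w).overall

            early = np.mean([block_pi(t) for t in tables[:2]])
            late = np.mean([block_pi(t) for t in tables[-2:]])
            wins += late > early
        assert wins >= 8

    def test_weaker_contingency_yields_lower_post_pi(self):
        # paired seeds: learning agents trained on 0.6 structure end with a
        # smaller normalized PI than those trained on 0.8 structure
        from structlearn.stats_report import post_normalized_pi

        wins = 0
        for seed in range(6):
            scores = {}
            for group in (1, 2):
                cfg = build_group_config(group, n_training_blocks=6, seed=seed)
                ag = AgentConfig(policy="learning", learn_rate=1.0)
                log = run_experiment(cfg, ag)
                scores[group] = post_normalized_pi(log, cfg)
            wins += scores[1] > scores[2]
        assert wins >= 5
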