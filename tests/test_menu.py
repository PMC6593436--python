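"""Menu-search simulator: generation, mechanics, Q-learning, summaries."""

import math
import random

import numpy as np
import pytest

from lfikit.menu import (
    Menu,
    MenuConfig,
    MenuParams,
    MenuSimulator,
    MenuSummary,
    TrainConfig,
    discrepancy_lnE,
    generate_menu,
    initial_state,
    simulate_sessions,
    state_key,
    step,
    summarize,
    train_policy,
)

PARAMS = MenuParams(280.0, 290.0, 0.69)


class TestGeneration:
    def test_target_present_fraction_and_size(self):
        cfg = MenuConfig()
        rng = random.Random(0)
        menus = [generate_menu(cfg, rng) for _ in range(10000)]
        n_present = sum(m.target_present for m in menus)
        assert abs(n_present - 9000) <= 3 * math.sqrt(10000 * 0.9 * 0.1)
        assert all(m.n_items == 8 for m in menus)
        # at most one target, carrying the highest relevance
        for m in menus[:200]:
            if m.target_present:
                assert m.relevances[m.target_index] == cfg.target_relevance
                assert sum(r >= cfg.target_relevance for r in m.relevances) == 1

    def test_same_seed_same_menu(self):
        cfg = MenuConfig()
        assert generate_menu(cfg, 42) == generate_menu(cfg, 42)

    def test_recall_probability_controls_initial_observation(self):
        cfg = MenuConfig()
        menu = generate_menu(cfg, 1)
        full = initial_state(menu, MenuParams(280, 290, 1.0), 5, cfg)
        none = initial_state(menu, MenuParams(280, 290, 0.0), 5, cfg)
        assert all(r is not None for r in full.obs_relevance)
        assert all(r is None for r in none.obs_relevance)
        rng = random.Random(9)
        recalled = sum(
            initial_state(menu, PARAMS, rng, cfg).obs_relevance[0] is not None
            for _ in range(10000)
        )
        se = math.sqrt(10000 * 0.69 * 0.31)
        assert abs(recalled - 6900) <= 3 * se


class TestStepMechanics:
    def _blank_state(self, menu, cfg):
        return initial_state(menu, MenuParams(280.0, 290.0, 0.0), 0, cfg)

    def test_target_fixation_time_composition(self):
        cfg = MenuConfig()
        menu = Menu(tuple(0.3 if i != 1 else 1.0 for i in range(8)), (0,) * 8, 1)
        state = self._blank_state(menu, cfg)  # position starts at item 0
        _, reward, done, elapsed = step(state, 1, menu, PARAMS, 0, cfg)
        expected = cfg.saccade_ms(0, 1) + PARAMS.f_dur + PARAMS.d_sel
        assert done
        assert elapsed == pytest.approx(expected)
        assert reward == pytest.approx(cfg.reward_big - expected)

    def test_quit_rewards_depend_on_target_presence(self):
        cfg = MenuConfig()
        absent = Menu((0.3,) * 8, (0,) * 8, None)
        present = Menu(tuple(0.3 if i != 2 else 1.0 for i in range(8)), (0,) * 8, 2)
        s = self._blank_state(absent, cfg)
        _, r, done, _ = step(s, cfg.quit_action, absent, PARAMS, 0, cfg)
        assert done and r == cfg.reward_big
        s = self._blank_state(present, cfg)
        _, r, done, _ = step(s, cfg.quit_action, present, PARAMS, 0, cfg)
        assert done and r == -cfg.reward_big

    def test_neighbor_reveal_frequency_matches_peripheral_probability(self):
        cfg = MenuConfig()
        menu = Menu((0.3,) * 8, (0,) * 8, None)
        rng = random.Random(4)
        reveals = 0
        n = 10000
        for _ in range(n):
            s = self._blank_state(menu, cfg)
            s2, _, _, _ = step(s, 4, menu, PARAMS, rng, cfg)  # interior item
            if s2.obs_relevance[3] is not None and s2.obs_relevance[5] is not None:
                reveals += 1
        se = math.sqrt(n * 0.93 * 0.07)
        assert abs(reveals - 0.93 * n) <= 3 * se

    def test_acting_on_finished_episode_rejected(self):
        cfg = MenuConfig()
        menu = Menu((0.3,) * 8, (0,) * 8, None)
        s = self._blank_state(menu, cfg)
        s2, _, _, _ = step(s, cfg.quit_action, menu, PARAMS, 0, cfg)
        with pytest.raises(RuntimeError):
            step(s2, 0, menu, PARAMS, 0, cfg)

    def test_observations_never_unlearned(self):
        cfg = MenuConfig()
        menu = generate_menu(cfg, 3)
        rng = random.Random(1)
        s = self._blank_state(menu, cfg)
        observed = set()
        for a in (0, 3, 6):
            if menu.target_index == a:
                continue
            s, _, done, _ = step(s, a, menu, PARAMS, rng, cfg)
            if done:
                break
            now = {i for i, r in enumerate(s.obs_relevance) if r is not None}
            assert observed <= now
            observed = now


# ---------------------------------------------------------------------------
# Q-learning vs an exact enumeration oracle on a degenerate 2-item MDP
# ---------------------------------------------------------------------------

TINY = MenuConfig(n_items=2, p_present=1.0, relevance_levels=(0.0, 0.6),
                  n_length_classes=1, max_actions=4)
FULL_RECALL = MenuParams(280.0, 290.0, 1.0)


def oracle_value(state_tuple, position, n_actions, menu, cfg, params):
    """Exact optimal value by exhaustive recursion (deterministic MDP under
    full recall: every item observed, no peripheral randomness left)."""
    if n_actions >= cfg.max_actions:
        return 0.0
    best = -math.inf
    for a in list(range(cfg.n_items)) + [cfg.quit_action]:
        if n_actions == cfg.max_actions - 1 and a != cfg.quit_action:
            continue
        if a == cfg.quit_action:
            q = cfg.reward_big if menu.target_index is None else -cfg.reward_big
        else:
            elapsed = cfg.saccade_ms(position, a) + params.f_dur
            if a == menu.target_index:
                q = cfg.reward_big - (elapsed + params.d_sel)
            else:
                q = -elapsed + oracle_value(state_tuple, a, n_actions + 1, menu, cfg, params)
        best = max(best, q)
    return best


def oracle_action(menu, cfg, params, position=0):
    """Greedy action of the exact oracle from the initial (fully recalled) state."""
    best_a, best_q = None, -math.inf
    for a in list(range(cfg.n_items)) + [cfg.quit_action]:
        if a == cfg.quit_action:
            q = cfg.reward_big if menu.target_index is None else -cfg.reward_big
        else:
            elapsed = cfg.saccade_ms(position, a) + params.f_dur
            if a == menu.target_index:
                q = cfg.reward_big - (elapsed + params.d_sel)
            else:
                q = -elapsed + oracle_value(None, a, 1, menu, cfg, params)
        if q > best_q:
            best_a, best_q = a, q
    return best_a, best_q


class TestQLearningOptimality:
    def _tiny_menus(self):
        menus = []
        for tgt in (0, 1):
            for other_rel in TINY.relevance_levels:
                rel = [other_rel, other_rel]
                rel[tgt] = TINY.target_relevance
                menus.append(Menu(tuple(rel), (0, 0), tgt))
        return menus

    def test_greedy_policy_matches_enumeration_oracle(self):
        policy = train_policy(FULL_RECALL, TrainConfig(n_episodes=4000), seed=0,
                              menu_config=TINY)
        assert not policy.aggregated  # tiny state space uses the full key
        for menu in self._tiny_menus():
            state = initial_state(menu, FULL_RECALL, 0, TINY)
            a_policy = policy.action(state)
            a_oracle, _ = oracle_action(menu, TINY, FULL_RECALL)
            assert a_policy == a_oracle == menu.target_index

    def test_more_training_does_not_increase_reward_deficit(self):
        def mean_deficit(policy):
            deficit = 0.0
            menus = self._tiny_menus()
            for menu in menus:
                ep_rewards = 0.0
                state = initial_state(menu, FULL_RECALL, 0, TINY)
                rng = random.Random(0)
                while not state.done:
                    a = policy.action(state)
                    state, r, _, _ = step(state, a, menu, FULL_RECALL, rng, TINY)
                    ep_rewards += r
                _, optimal = oracle_action(menu, TINY, FULL_RECALL)
                deficit += optimal - ep_rewards
            return deficit / len(menus)

        small = train_policy(FULL_RECALL, TrainConfig(n_episodes=1000), seed=1,
                             menu_config=TINY)
        big = train_policy(FULL_RECALL, TrainConfig(n_episodes=10000), seed=1,
                           menu_config=TINY)
        assert mean_deficit(big) <= mean_deficit(small) + 1e-9

    def test_full_recall_present_episodes_take_one_fixation(self):
        policy = train_policy(FULL_RECALL, TrainConfig(n_episodes=4000), seed=0,
                              menu_config=TINY)
        episodes = simulate_sessions(policy, FULL_RECALL, 200, seed=2, config=TINY)
        for e in episodes:
            assert e.outcome == "found"
            assert len(e.actions) == 1
            # time = saccade + f_dur + d_sel for the single target fixation
            assert e.total_time_ms <= TINY.saccade_ms(0, 1) + 280.0 + 290.0 + 1e-9


class TestSessionsAndSummaries:
    def test_episodes_terminate_and_are_reproducible(self):
        policy = train_policy(PARAMS, TrainConfig(n_episodes=1500), seed=0)
        eps1 = simulate_sessions(policy, PARAMS, 300, seed=5)
        eps2 = simulate_sessions(policy, PARAMS, 300, seed=5)
        assert eps1 == eps2
        cfg = policy.menu_config
        for e in eps1:
            assert len(e.actions) <= cfg.max_actions
            if len(e.actions) >= 1 and e.actions[0] != cfg.quit_action:
                assert e.total_time_ms > 0

    def test_condition_split_converges_to_nine_to_one(self):
        policy = train_policy(PARAMS, TrainConfig(n_episodes=1500), seed=0)
        eps = simulate_sessions(policy, PARAMS, 5000, seed=8)
        n_present = sum(e.condition == "present" for e in eps)
        assert abs(n_present / 5000 - 0.9) <= 3 * math.sqrt(0.9 * 0.1 / 5000)

    def test_summary_arithmetic_and_order_invariance(self):
        eps = [
            type("E", (), {"total_time_ms": 100.0, "condition": "present"})(),
            type("E", (), {"total_time_ms": 300.0, "condition": "present"})(),
            type("E", (), {"total_time_ms": 50.0, "condition": "absent"})(),
        ]
        s = summarize(eps)
        assert s.mu_pre == 200.0 and s.sigma_pre == 100.0
        assert s.mu_abs == 50.0 and s.sigma_abs == 0.0
        assert summarize(eps[::-1]) == s

    def test_missing_condition_error_names_it(self):
        eps = [type("E", (), {"total_time_ms": 100.0, "condition": "present"})()]
        with pytest.raises(ValueError, match="absent"):
            summarize(eps)

    def test_mu_pre_strictly_increases_with_f_dur_under_fixed_policy(self):
        policy = train_policy(PARAMS, TrainConfig(n_episodes=1500), seed=0)
        lo = summarize(simulate_sessions(policy, MenuParams(200, 290, 0.69), 500, seed=3))
        hi = summarize(simulate_sessions(policy, MenuParams(350, 290, 0.69), 500, seed=3))
        assert hi.mu_pre > lo.mu_pre


class TestDiscrepancy:
    def test_known_arithmetic_value(self):
        a = MenuSummary(1000.0, 400.0, 2000.0, 500.0)
        b = MenuSummary(900.0, 380.0, 1950.0, 490.0)
        # E = 100 + 20 + 50 + 10 = 180
        assert discrepancy_lnE(a, b) == pytest.approx(math.log(180.0), abs=1e-10)
        assert discrepancy_lnE(a, b) == pytest.approx(5.1930, abs=1e-4)

    def test_identical_summaries_hit_the_floor(self):
        a = MenuSummary(1000.0, 400.0, 2000.0, 500.0)
        assert discrepancy_lnE(a, a) == pytest.approx(math.log(1e-6))

    def test_symmetry(self):
        a = MenuSummary(1000.0, 400.0, 2000.0, 500.0)
        b = MenuSummary(800.0, 300.0, 1500.0, 700.0)
        assert discrepancy_lnE(a, b) == discrepancy_lnE(b, a)


class TestSimulatorContract:
    def test_same_theta_same_seed_identical_summaries(self):
        sim = MenuSimulator(train_config=TrainConfig(n_episodes=800), n_eval_episodes=200)
        a = sim.run([280.0, 290.0, 0.69], seed=77)
        b = sim.run([280.0, 290.0, 0.69], seed=77)
        assert a == b

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            MenuParams(600.0, 290.0, 0.69)
        with pytest.raises(ValueError):
            MenuParams(280.0, 290.0, 1.2)
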