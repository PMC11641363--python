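import numpy as np
import pytest

from enhancerrl.ppo import (PPOAgent, PpoHyperparams, Transition,
                            clipped_objective, compute_reward, gae_advantages)


class TestReward:
    def test_examples(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 64)
        probs = np.where(labels == 1, 0.9, 0.1).astype(float)
        wrong = rng.choice(64, 16, replace=False)
        probs[wrong] = 1.0 - probs[wrong]
        assert compute_reward(probs, labels) == pytest.approx(48 / 64)
        assert compute_reward(np.where(labels == 1, 0.9, 0.1), labels) == 1.0
        assert compute_reward([0.9, 0.2, 0.6], [1, 1, 0]) == pytest.approx(1 / 3)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            compute_reward([], [])

    def test_reward_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(1, 50)
            r = compute_reward(rng.random(n), rng.integers(0, 2, n))
            assert 0.0 <= r <= 1.0


class TestClippedObjective:
    def test_examples(self):
        assert clipped_objective(1.3, 1.0, 0.2) == pytest.approx(1.2)
        assert clipped_objective(0.5, -1.0, 0.2) == pytest.approx(-0.8)
        for adv in (-2.0, 0.0, 3.7):
            assert clipped_objective(1.0, adv, 0.15) == pytest.approx(adv)

    def test_matches_brute_force_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            r = rng.uniform(0.01, 3.0)
            a = rng.normal(scale=2.0)
            eps = rng.uniform(0.05, 0.4)
            brute = min(r * a, min(max(r, 1 - eps), 1 + eps) * a)
            assert abs(clipped_objective(r, a, eps) - brute) < 1e-12

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            clipped_objective(-0.1, 1.0, 0.2)


class TestGae:
    def test_single_terminal_step_is_delta(self):
        adv, ret = gae_advantages(np.array([1.0]), np.array([0.3]),
                                  np.array([True]), 0.99, 0.95)
        assert adv[0] == pytest.approx(1.0 - 0.3)
        assert ret[0] == pytest.approx(1.0)

    def test_matches_hand_unrolled_recursion(self):
        rewards = np.array([1.0, 0.5, 0.25])
        values = np.array([0.2, 0.1, 0.4])
        dones = np.array([False, False, True])
        gamma, lam = 0.9, 0.8
        d2 = rewards[2] - values[2]
        d1 = rewards[1] + gamma * values[2] - values[1]
        d0 = rewards[0] + gamma * values[1] - values[0]
        a2 = d2
        a1 = d1 + gamma * lam * a2
        a0 = d0 + gamma * lam * a1
        adv, _ = gae_advantages(rewards, values, dones, gamma, lam)
        assert np.allclose(adv, [a0, a1, a2])


class TestAgent:
    def make_agent(self, dim=6, **hp):
        return PPOAgent(dim, PpoHyperparams(**hp), hidden=16, rng=0)

    def force_probs(self, agent, logit):
        """Pin the actor output to a constant logit on every dimension."""
        last = agent.actor.layers[-1]
        last.weight.data[:] = 0.0
        last.bias.data[:] = logit
        for layer in agent.actor.layers[:-1]:
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0

    def test_forced_certain_policy_gives_ones_and_zero_logprob(self):
        agent = self.make_agent()
        self.force_probs(agent, 50.0)     # keep-probability ~ 1
        bits, logp, _ = agent.act(np.zeros(6), np.random.default_rng(0))
        assert np.array_equal(bits, np.ones(6))
        assert logp == pytest.approx(0.0, abs=1e-4)

    def test_uniform_policy_logprob_closed_form(self):
        agent = self.make_agent()
        self.force_probs(agent, 0.0)      # keep-probability 1/2 everywhere
        for seed in range(3):
            bits, logp, _ = agent.act(np.zeros(6),
                                      np.random.default_rng(seed))
            assert logp == pytest.approx(6 * np.log(0.5))

    def test_greedy_mode_deterministic(self):
        agent = self.make_agent()
        state = np.random.default_rng(1).normal(size=6)
        a1, lp1, v1 = agent.act(state, greedy=True)
        a2, lp2, v2 = agent.act(state, greedy=True)
        assert np.array_equal(a1, a2) and lp1 == lp2 and v1 == v2

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            self.make_agent().act(np.array([1.0, np.nan] + [0.0] * 4))

    def test_update_epochs_zero_is_noop(self):
        agent = self.make_agent(update_epochs=0)
        before = agent.state_hash()
        t = Transition(np.zeros(6), np.ones(6, dtype=int), 0.5, True,
                       -0.1, 0.0)
        diag = agent.update([t])
        assert agent.state_hash() == before
        assert diag["updates"] == 0

    def test_update_changes_params_keeps_shapes(self):
        agent = self.make_agent()
        shapes = [p.data.shape for p in agent.parameters()]
        rng = np.random.default_rng(2)
        transitions = []
        for i in range(8):
            s = rng.normal(size=6)
            bits, lp, v = agent.act(s, rng)
            transitions.append(Transition(s, bits, rng.random(), i == 7,
                                          lp, v))
        agent.update(transitions)
        assert [p.data.shape for p in agent.parameters()] == shapes

    def test_empty_buffer_rejected(self):
        with pytest.raises(ValueError):
            self.make_agent().update([])


def bandit_converges(seed, n_updates=200, batch=16):
    """Reward = fraction of mask bits matching a fixed target; the unique
    optimum is the target mask itself."""
    rng = np.random.default_rng(seed)
    target = np.array([1, 0, 1, 0])
    state = np.full(4, 0.5)
    agent = PPOAgent(4, PpoHyperparams(lr=3e-3), hidden=32, rng=seed)
    for _ in range(n_updates):
        transitions = []
        for _ in range(batch):
            bits, lp, v = agent.act(state, rng)
            reward = float((bits == target).mean())
            transitions.append(Transition(state, bits, reward, True, lp, v))
        agent.update(transitions)
        greedy, _, _ = agent.act(state, greedy=True)
        if np.array_equal(greedy, target):
            return True
    return False


def test_bandit_mask_recovery_single_seed():
    assert bandit_converges(0)
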