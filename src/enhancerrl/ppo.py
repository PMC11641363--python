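"""Proximal policy optimisation for feature masking.

The environment is the classifier itself: the state is the
batch-averaged fused feature vector, the action a binary keep/discard
mask over its dimensions, and the reward the fraction of the batch the
classifier got right under that mask.  The policy factorises over
dimensions as independent Bernoulli variables; updates maximise the
clipped surrogate objective with GAE advantages, plus an entropy bonus
and a value-function loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

_EPS = 1e-6


@dataclass
class PpoHyperparams:
    clip_eps: float = 0.2
    gamma: float = 0.99
    gae_lambda: float = 0.95
    update_epochs: int = 4
    entropy_coef: float = 0.01
    value_coef: float = 0.5
    lr: float = 3e-4

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.clip_eps <= 0.0:
            raise ValueError(f"clip_eps must be positive, got {self.clip_eps}")


@dataclass
class Transition:
    state: np.ndarray
    action: np.ndarray
    reward: float
    done: bool
    log_prob_old: float
    value_est: float


def compute_reward(predictions: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.5) -> float:
    """Fraction of the batch predicted correctly at ``threshold``."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("empty batch has no reward")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    correct = (predictions >= threshold).astype(int) == labels.astype(int)
    return float(correct.mean())


def clipped_objective(ratio, advantage, clip_eps: float):
    """min(r * A, clip(r, 1-eps, 1+eps) * A), elementwise."""
    ratio = np.asarray(ratio, dtype=float)
    advantage = np.asarray(advantage, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("probability ratio must be positive")
    clipped = np.clip(ratio, 1.0 - clip_eps, 1.0 + clip_eps)
    value = np.minimum(ratio * advantage, clipped * advantage)
    return float(value) if value.ndim == 0 else value


def gae_advantages(rewards: np.ndarray, values: np.ndarray,
                   dones: np.ndarray, gamma: float,
                   lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Generalised advantage estimates and value targets for one buffer.

    The value after a terminal step (and after the final stored step) is
    taken as zero.
    """
    T = len(rewards)
    adv = np.zeros(T)
    last = 0.0
    for t in reversed(range(T)):
        nonterminal = 0.0 if dones[t] else 1.0
        next_value = values[t + 1] if t + 1 < T else 0.0
        delta = rewards[t] + gamma * next_value * nonterminal - values[t]
        last = delta + gamma * lam * nonterminal * last
        adv[t] = last
    return adv, adv + values


def _tmin(a: Tensor, b: Tensor) -> Tensor:
    pick_a = Tensor((a.data < b.data).astype(float))
    return a * pick_a + b * (1.0 - pick_a)


class PPOAgent(nn.Module):
    """Actor-critic over the fused-feature state.

    Actor: MLP emitting one keep-probability per feature dimension.
    Critic: MLP emitting a scalar state value.
    """

    def __init__(self, state_dim: int, hp: PpoHyperparams | None = None,
                 hidden: int = 256, rng: np.random.Generator | int = 0,
                 init_keep_bias: float = 1.0):
        super().__init__()
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.state_dim = state_dim
        self.hp = hp or PpoHyperparams()
        self.actor = nn.MLP([state_dim, hidden, hidden, state_dim], rng)
        # Start near the all-ones mask (the phase-1 operating point) so the
        # agent prunes features selectively instead of disrupting half of
        # them from the first rollout.
        self.actor.layers[-1].bias.data += init_keep_bias
        self.critic = nn.MLP([state_dim, hidden, hidden, 1], rng)
        self.optimizer = nn.Adam(self.actor.parameters()
                                 + self.critic.parameters(), lr=self.hp.lr)

    # -- acting ---------------------------------------------------------------
    def keep_probabilities(self, states: np.ndarray) -> Tensor:
        states = np.atleast_2d(states)
        return self.actor(Tensor(states)).sigmoid().clip(_EPS, 1.0 - _EPS)

    def act(self, state: np.ndarray, rng: np.random.Generator | None = None,
            greedy: bool = False) -> tuple[np.ndarray, float, float]:
        """Sample (or take greedily) a mask; return (bits, log_prob, value)."""
        state = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(state)):
            raise ValueError("non-finite state")
        with nn.no_grad():
            probs = self.keep_probabilities(state).data[0]
            value = float(self.critic(Tensor(state[None, :])).data[0, 0])
        if greedy:
            bits = (probs >= 0.5).astype(np.int64)
        else:
            if rng is None:
                rng = np.random.default_rng()
            bits = (rng.random(self.state_dim) < probs).astype(np.int64)
        log_prob = float(np.sum(bits * np.log(probs)
                                + (1 - bits) * np.log(1.0 - probs)))
        return bits, log_prob, value

    # -- learning -------------------------------------------------------------
    def _log_prob_tensor(self, probs: Tensor, actions: np.ndarray) -> Tensor:
        a = Tensor(actions.astype(float))
        return (a * probs.log()
                + (1.0 - a) * (1.0 - probs).log()).sum(axis=1)

    def update(self, transitions: list[Transition],
               hp: PpoHyperparams | None = None) -> dict[str, float]:
        """Run PPO passes over one collected buffer; return diagnostics."""
        if not transitions:
            raise ValueError("empty transition buffer")
        hp = hp or self.hp
        states = np.stack([t.state for t in transitions])
        actions = np.stack([t.action for t in transitions])
        rewards = np.array([t.reward for t in transitions])
        dones = np.array([t.done for t in transitions])
        logp_old = np.array([t.log_prob_old for t in transitions])
        values = np.array([t.value_est for t in transitions])

        adv, returns = gae_advantages(rewards, values, dones,
                                      hp.gamma, hp.gae_lambda)
        if len(adv) > 1 and adv.std() > 0:
            adv = (adv - adv.mean()) / (adv.std() + 1e-8)

        diag = {"policy_loss": 0.0, "value_loss": 0.0, "entropy": 0.0,
                "mean_reward": float(rewards.mean()), "updates": 0}
        for _ in range(hp.update_epochs):
            probs = self.keep_probabilities(states)
            logp = self._log_prob_tensor(probs, actions)
            ratio = (logp - Tensor(logp_old)).exp()
            adv_t = Tensor(adv)
            surrogate = _tmin(ratio * adv_t,
                              ratio.clip(1.0 - hp.clip_eps,
                                         1.0 + hp.clip_eps) * adv_t)
            entropy = -(probs * probs.log()
                        + (1.0 - probs) * (1.0 - probs).log()).sum(axis=1)
            value_pred = self.critic(Tensor(states)).reshape(-1)
            value_loss = ((value_pred - Tensor(returns)) ** 2).mean()
            loss = (-surrogate.mean() + hp.value_coef * value_loss
                    - hp.entropy_coef * entropy.mean())
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            diag["policy_loss"] = float(-surrogate.mean().item())
            diag["value_loss"] = float(value_loss.item())
            diag["entropy"] = float(entropy.mean().item())
            diag["updates"] += 1
        return diag
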