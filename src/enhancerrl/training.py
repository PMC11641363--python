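"""Three-phase training: supervised pretraining of the extractor and
classifier under an all-ones mask, PPO pretraining against the frozen
network, then joint training with one PPO update per epoch.

The best network/agent pair seen on validation accuracy (greedy mask)
is checkpointed and restored at the end of a fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluation import MetricReport, evaluate
from .kmer import build_vocabulary, default_l_max, encode_batch
from .network import EnhancerNetwork, NetworkConfig
from .nn import Tensor
from .ppo import PPOAgent, PpoHyperparams, Transition, compute_reward
from .sequence_io import LabeledSequence

logger = logging.getLogger(__name__)

BCE_EPS = 1e-7


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs_phase1: int = 20
    epochs_phase2: int = 10
    epochs_phase3: int = 30
    lr_main: float = 1e-3
    phase3_lr_factor: float = 0.5   # staged decay for the joint phase
    weight_decay: float = 0.0
    seed: int = 42
    k: int = 4
    l_max: int | None = None
    threshold: float = 0.5
    drop_resnet: bool = False
    drop_transformer: bool = False
    drop_ppo: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.drop_resnet and self.drop_transformer:
            raise ValueError("cannot drop both feature branches")


def bce_loss(probabilities, labels):
    """Mean binary cross-entropy; accepts Tensors (for training) or arrays.

    Probabilities are clamped to (BCE_EPS, 1-BCE_EPS) to avoid log(0).
    """
    if isinstance(probabilities, Tensor):
        y = Tensor(np.asarray(labels, dtype=float))
        if probabilities.data.size == 0:
            raise ValueError("empty batch")
        p = probabilities.clip(BCE_EPS, 1.0 - BCE_EPS)
        return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()
    probs = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.size == 0:
        raise ValueError("empty batch")
    p = np.clip(probs, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(labels * np.log(p)
                          + (1.0 - labels) * np.log(1.0 - p)))


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Fan one global seed out to named, order-stable substreams."""
    root = np.random.SeedSequence(seed)
    names = ("init", "data", "ppo", "synth")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


class Trainer:
    """Owns the network, the agent and the three-phase schedule."""

    def __init__(self, train_records: list[LabeledSequence],
                 val_records: list[LabeledSequence],
                 net_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None,
                 ppo_hparams: PpoHyperparams | None = None):
        if not train_records:
            raise ValueError("empty training set")
        self.cfg = train_config or TrainConfig()
        self.hp = ppo_hparams or PpoHyperparams()
        self.streams = seed_streams(self.cfg.seed)

        self.vocab = build_vocabulary(train_records, self.cfg.k)
        self.l_max = (self.cfg.l_max if self.cfg.l_max is not None
                      else default_l_max(train_records, self.cfg.k))

        net_config = net_config or NetworkConfig()
        net_config.vocab_size = len(self.vocab)
        net_config.use_resnet = (net_config.use_resnet
                                 and not self.cfg.drop_resnet)
        net_config.use_transformer = (net_config.use_transformer
                                      and not self.cfg.drop_transformer)
        self.net_config = net_config

        self.network = EnhancerNetwork(net_config, self.l_max,
                                       rng=self.streams["init"])
        self.agent = PPOAgent(net_config.fused_dim, self.hp,
                              rng=self.streams["init"])
        self.optimizer = nn.Adam(self.network.parameters(),
                                 lr=self.cfg.lr_main,
                                 weight_decay=self.cfg.weight_decay)

        self.train_data = encode_batch(train_records, self.vocab, self.l_max)
        self.val_data = (encode_batch(val_records, self.vocab, self.l_max)
                         if val_records else None)
        self.history: list[dict] = []
        self.best_val_acc = -1.0
        self.best_state: dict | None = None
        self._phase_done = 0
        self._last_mean_state: np.ndarray | None = None

    # -- plumbing -------------------------------------------------------------
    def _batches(self, data, shuffle: bool = True):
        ids, lengths, labels = data
        n = len(labels)
        order = (self.streams["data"].permutation(n) if shuffle
                 else np.arange(n))
        for start in range(0, n, self.cfg.batch_size):
            sel = order[start:start + self.cfg.batch_size]
            yield ids[sel], lengths[sel], labels[sel]

    def greedy_mask(self) -> np.ndarray:
        """The deterministic evaluation mask (all ones when PPO is off)."""
        if self.cfg.drop_ppo or self._phase_done < 2:
            return np.ones(self.net_config.fused_dim)
        if self._last_mean_state is not None:
            state = self._last_mean_state
        else:
            ids, lengths, _ = self.train_data
            sel = slice(0, min(len(lengths), 4 * self.cfg.batch_size))
            state = self._mean_state(ids[sel], lengths[sel])
        bits, _, _ = self.agent.act(state, greedy=True)
        return bits.astype(float)

    def _mean_state(self, ids, lengths) -> np.ndarray:
        self.network.eval()
        with nn.no_grad():
            fused = self.network.extract(ids, lengths)
        return fused.data.mean(axis=0)

    def _val_accuracy(self, mask: np.ndarray | None) -> float:
        if self.val_data is None:
            return float("nan")
        ids, lengths, labels = self.val_data
        probs = self.network.predict_proba(ids, lengths, mask)
        pred = (probs >= self.cfg.threshold).astype(int)
        return float((pred == labels.astype(int)).mean())

    def _checkpoint(self, phase: int, epoch: int, val_acc: float,
                    mask: np.ndarray) -> None:
        """Keep the best (network, agent, mask) triple seen on validation.

        The mask the checkpoint was validated under is stored with it, so
        later evaluation reproduces the selected operating point exactly.
        """
        if np.isnan(val_acc) or val_acc >= self.best_val_acc:
            self.best_val_acc = max(self.best_val_acc,
                                    0.0 if np.isnan(val_acc) else val_acc)
            self.best_state = {
                "network": self.network.state_dict(),
                "agent": self.agent.state_dict(),
                "phase": phase,
                "epoch": epoch,
                "mask": mask.copy(),
                "mean_state": (None if self._last_mean_state is None
                               else self._last_mean_state.copy()),
            }

    # -- phases ---------------------------------------------------------------
    def phase1_pretrain_extractor(self) -> list[dict]:
        """Supervised pretraining under the all-ones mask (PPO disabled)."""
        ones = np.ones(self.net_config.fused_dim)
        entries = []
        for epoch in range(self.cfg.epochs_phase1):
            self.network.train()
            losses = []
            for ids, lengths, labels in self._batches(self.train_data):
                probs = self.network(ids, lengths, ones)
                loss = bce_loss(probs, labels)
                self.optimizer.zero_grad()
                loss.backward()
                self.optimizer.step()
                losses.append(loss.item())
            val_acc = self._val_accuracy(ones)
            entry = {"phase": 1, "epoch": epoch,
                     "train_loss": float(np.mean(losses)),
                     "val_acc": val_acc}
            entries.append(entry)
            self.history.append(entry)
            self._checkpoint(1, epoch, val_acc, ones)
            logger.info("phase1 epoch %d loss %.4f val_acc %.4f",
                        epoch, entry["train_loss"], val_acc)
        self._phase_done = max(self._phase_done, 1)
        return entries

    def phase2_pretrain_ppo(self) -> list[dict]:
        """Train the agent against the frozen network on batch rewards."""
        if self._phase_done < 1:
            raise RuntimeError("phase 1 must run before phase 2")
        self.network.eval()           # frozen: no grads, no BN-stat updates
        entries = []
        for epoch in range(self.cfg.epochs_phase2):
            transitions, batches = [], list(self._batches(self.train_data))
            for i, (ids, lengths, labels) in enumerate(batches):
                with nn.no_grad():
                    fused = self.network.extract(ids, lengths)
                state = fused.data.mean(axis=0)
                bits, logp, value = self.agent.act(state,
                                                   rng=self.streams["ppo"])
                with nn.no_grad():
                    probs = self.network.classify(fused, bits.astype(float))
                reward = compute_reward(probs.data, labels,
                                        self.cfg.threshold)
                transitions.append(Transition(state, bits, reward,
                                              i == len(batches) - 1,
                                              logp, value))
            self._last_mean_state = np.mean(
                [t.state for t in transitions], axis=0)
            diag = self.agent.update(transitions, self.hp)
            entry = {"phase": 2, "epoch": epoch,
                     "mean_reward": diag["mean_reward"],
                     "entropy": diag["entropy"]}
            entries.append(entry)
            self.history.append(entry)
            logger.info("phase2 epoch %d reward %.4f", epoch,
                        diag["mean_reward"])
        self._phase_done = max(self._phase_done, 2)
        return entries

    def phase3_joint_train(self) -> list[dict]:
        """Joint loop: supervised steps per batch, one PPO update per epoch."""
        if not self.cfg.drop_ppo and self._phase_done < 2:
            raise RuntimeError("phases 1-2 must run before phase 3")
        self.optimizer.lr = self.cfg.lr_main * self.cfg.phase3_lr_factor
        ones = np.ones(self.net_config.fused_dim)
        entries = []
        for epoch in range(self.cfg.epochs_phase3):
            transitions, losses = [], []
            batches = list(self._batches(self.train_data))
            for i, (ids, lengths, labels) in enumerate(batches):
                self.network.train()
                fused = self.network.extract(ids, lengths)
                if self.cfg.drop_ppo:
                    bits = ones.astype(np.int64)
                else:
                    state = fused.data.mean(axis=0)
                    bits, logp, value = self.agent.act(
                        state, rng=self.streams["ppo"])
                probs = self.network.classify(fused, bits.astype(float))
                loss = bce_loss(probs, labels)
                self.optimizer.zero_grad()
                loss.backward()
                self.optimizer.step()
                losses.append(loss.item())
                if not self.cfg.drop_ppo:
                    reward = compute_reward(probs.data, labels,
                                            self.cfg.threshold)
                    transitions.append(Transition(state, bits, reward,
                                                  i == len(batches) - 1,
                                                  logp, value))
            ppo_updates = 0
            if not self.cfg.drop_ppo:
                self._last_mean_state = np.mean(
                    [t.state for t in transitions], axis=0)
                diag = self.agent.update(transitions, self.hp)
                ppo_updates = 1
                self._phase_done = max(self._phase_done, 2)
            eval_mask = self.greedy_mask()
            val_acc = self._val_accuracy(eval_mask)
            entry = {"phase": 3, "epoch": epoch,
                     "train_loss": float(np.mean(losses)),
                     "val_acc": val_acc, "ppo_updates_this_epoch": ppo_updates}
            entries.append(entry)
            self.history.append(entry)
            self._checkpoint(3, epoch, val_acc, eval_mask)
            logger.info("phase3 epoch %d loss %.4f val_acc %.4f",
                        epoch, entry["train_loss"], val_acc)
        self._phase_done = 3
        return entries

    # -- public API -----------------------------------------------------------
    def fit(self) -> "Trainer":
        self.phase1_pretrain_extractor()
        if not self.cfg.drop_ppo:
            self.phase2_pretrain_ppo()
        self.phase3_joint_train()
        if self.best_state is not None:
            self.network.load_state_dict(self.best_state["network"])
            self.agent.load_state_dict(self.best_state["agent"])
            if self.best_state["mean_state"] is not None:
                self._last_mean_state = self.best_state["mean_state"].copy()
        return self

    def predict_proba(self, records: list[LabeledSequence],
                      mask: np.ndarray | None = None) -> np.ndarray:
        ids, lengths, _ = encode_batch(records, self.vocab, self.l_max)
        if mask is None:
            if (self._phase_done >= 3 and self.best_state is not None
                    and "mask" in self.best_state):
                mask = self.best_state["mask"]
            else:
                mask = self.greedy_mask()
        return self.network.predict_proba(ids, lengths, mask)

    def evaluate(self, records: list[LabeledSequence]) -> MetricReport:
        labels = np.array([r.label for r in records])
        return evaluate(self.predict_proba(records), labels,
                        self.cfg.threshold)


def save_checkpoint(trainer: Trainer, path) -> None:
    """Serialise network+agent state, vocabulary and config to one .npz."""
    import dataclasses
    import json

    state = {f"network.{k}": v for k, v in
             trainer.network.state_dict().items()}
    state.update({f"agent.{k}": v for k, v in
                  trainer.agent.state_dict().items()})
    meta = {
        "net_config": dataclasses.asdict(trainer.net_config),
        "train_config": dataclasses.asdict(trainer.cfg),
        "ppo_hparams": dataclasses.asdict(trainer.hp),
        "l_max": trainer.l_max,
        "k": trainer.vocab.k,
        "best_val_acc": trainer.best_val_acc,
    }
    vocab_items = sorted(trainer.vocab.token_to_id.items(),
                         key=lambda kv: kv[1])
    np.savez(path,
             __meta__=np.frombuffer(json.dumps(meta).encode(),
                                    dtype=np.uint8),
             __vocab__=np.array([t for t, _ in vocab_items]),
             __mean_state__=(trainer._last_mean_state
                             if trainer._last_mean_state is not None
                             else np.zeros(0)),
             **state)


class LoadedModel:
    """Inference-only view of a saved checkpoint."""

    def __init__(self, path):
        import json

        from .kmer import KmerVocabulary
        from .network import EnhancerNetwork, NetworkConfig

        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["__meta__"]).decode())
        tokens = [str(t) for t in data["__vocab__"]]
        self.vocab = KmerVocabulary(
            k=meta["k"], token_to_id={t: i + 2 for i, t in enumerate(tokens)})
        self.l_max = meta["l_max"]
        self.cfg = TrainConfig(**meta["train_config"])
        self.net_config = NetworkConfig(**meta["net_config"])
        self.best_val_acc = meta["best_val_acc"]
        self.network = EnhancerNetwork(self.net_config, self.l_max)
        self.network.load_state_dict(
            {k[len("network."):]: data[k] for k in data.files
             if k.startswith("network.")})
        self.agent = PPOAgent(self.net_config.fused_dim,
                              PpoHyperparams(**meta["ppo_hparams"]))
        self.agent.load_state_dict(
            {k[len("agent."):]: data[k] for k in data.files
             if k.startswith("agent.")})
        mean_state = data["__mean_state__"]
        self._mean_state = mean_state if mean_state.size else None

    def greedy_mask(self) -> np.ndarray:
        if self.cfg.drop_ppo or self._mean_state is None:
            return np.ones(self.net_config.fused_dim)
        bits, _, _ = self.agent.act(self._mean_state, greedy=True)
        return bits.astype(float)

    def predict_proba(self, records: list[LabeledSequence]) -> np.ndarray:
        ids, lengths, _ = encode_batch(records, self.vocab, self.l_max)
        return self.network.predict_proba(ids, lengths, self.greedy_mask())

    def evaluate(self, records: list[LabeledSequence]) -> MetricReport:
        labels = np.array([r.label for r in records])
        return evaluate(self.predict_proba(records), labels,
                        self.cfg.threshold)


def ablate(train_records: list[LabeledSequence],
           val_records: list[LabeledSequence],
           test_records: list[LabeledSequence],
           net_config: NetworkConfig,
           train_config: TrainConfig,
           ppo_hparams: PpoHyperparams | None = None,
           **drop_flags: bool) -> MetricReport:
    """Train with one module removed and report test metrics."""
    import dataclasses
    cfg = dataclasses.replace(train_config, **drop_flags)
    net = dataclasses.replace(net_config)
    trainer = Trainer(train_records, val_records, net, cfg, ppo_hparams)
    trainer.fit()
    return trainer.evaluate(test_records)
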