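"""Model/Results facade over the training machinery.

``EnhancerClassifier`` is constructed from data (records, a DataFrame,
or FASTA paths), ``fit()`` runs the three-phase schedule and returns a
``FitResults`` object carrying the trained network and agent, the
per-epoch history, evaluation helpers and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import MetricReport
from .interpretability import (MaskHeatmap, branch_importance, collect_masks,
                               correlation_analysis, reference_matrix)
from .network import NetworkConfig
from .ppo import PpoHyperparams
from .sequence_io import LabeledSequence, read_dataset, split_dataset
from .training import TrainConfig, Trainer


class EnhancerClassifier:
    """Binary enhancer classifier with PPO-masked fused features."""

    def __init__(self, train_records: list[LabeledSequence],
                 val_records: list[LabeledSequence] | None = None,
                 split_fraction: float = 0.1, split_seed: int = 75,
                 net_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None,
                 ppo_hparams: PpoHyperparams | None = None):
        if val_records is None:
            split = split_dataset(train_records, split_fraction, split_seed)
            train_records, val_records = split.train, split.validation
        self.train_records = train_records
        self.val_records = val_records
        self.trainer = Trainer(train_records, val_records, net_config,
                               train_config, ppo_hparams)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, seq_col: str = "seq",
                       label_col: str = "label", **kwargs
                       ) -> "EnhancerClassifier":
        records = [LabeledSequence(str(row.Index), getattr(row, seq_col),
                                   int(getattr(row, label_col)))
                   for row in frame.itertuples()]
        return cls(records, **kwargs)

    @classmethod
    def from_fasta(cls, fasta_path, labels_path=None, **kwargs
                   ) -> "EnhancerClassifier":
        return cls(read_dataset(fasta_path, labels_path), **kwargs)

    def fit(self) -> "FitResults":
        self.trainer.fit()
        return FitResults(self)


class FitResults:
    """Estimates, history and diagnostics of a fitted classifier."""

    def __init__(self, model: EnhancerClassifier):
        self.model = model
        self.trainer = model.trainer
        self.history = pd.DataFrame(self.trainer.history)
        self.best_val_accuracy = self.trainer.best_val_acc

    @property
    def network(self):
        return self.trainer.network

    @property
    def agent(self):
        return self.trainer.agent

    @property
    def mask(self) -> np.ndarray:
        """The greedy evaluation mask."""
        return self.trainer.greedy_mask()

    def predict_proba(self, records) -> np.ndarray:
        return self.trainer.predict_proba(records)

    def predict(self, records, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(records) >= threshold).astype(int)

    def evaluate(self, records) -> MetricReport:
        return self.trainer.evaluate(records)

    # -- interpretability -----------------------------------------------------
    def mask_heatmap(self, records) -> MaskHeatmap:
        return collect_masks(self.trainer, records)

    def branch_keep_rates(self, records) -> tuple[float, float]:
        heatmap = self.mask_heatmap(records)
        return branch_importance(heatmap,
                                 self.trainer.net_config.resnet_out_dim)

    def reference_correlations(self, records):
        """(pre-mask, post-mask) per-sample correlation series."""
        from . import nn
        from .kmer import encode_batch

        ids, lengths, _ = encode_batch(records, self.trainer.vocab,
                                       self.trainer.l_max)
        self.network.eval()
        with nn.no_grad():
            fused = self.network.extract(ids, lengths).data
        post = fused * self.mask[None, :]
        refs = reference_matrix(records)
        return correlation_analysis(fused, post, refs)

    def summary(self) -> str:
        cfg = self.trainer.cfg
        net = self.trainer.net_config
        lines = [
            "Enhancer classifier fit",
            "=" * 47,
            f"training records        {len(self.model.train_records)}",
            f"validation records      {len(self.model.val_records)}",
            f"k-mer length            {cfg.k}",
            f"vocabulary size         {len(self.trainer.vocab)}",
            f"token length (L_max)    {self.trainer.l_max}",
            f"embedding dim           {net.embed_dim}",
            f"fused feature dim       {net.fused_dim}",
            f"  ResNet slice          [0, {net.resnet_out_dim})"
            if net.use_resnet else "  ResNet branch         dropped",
            f"  Transformer slice     [{net.resnet_out_dim if net.use_resnet else 0}, {net.fused_dim})"
            if net.use_transformer else "  Transformer branch    dropped",
            f"phase epochs            {cfg.epochs_phase1}/"
            f"{cfg.epochs_phase2}/{cfg.epochs_phase3}",
            f"best validation acc     {self.best_val_accuracy:.4f}",
            f"mask keep fraction      {self.mask.mean():.4f}"
            if not cfg.drop_ppo else "mask                    all-ones (PPO dropped)",
            "=" * 47,
        ]
        return "\n".join(lines)
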