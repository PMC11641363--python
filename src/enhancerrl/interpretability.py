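"""Interpretability analyses for the trained classifier.

Three views of what the PPO mask has learned:

* mask heatmaps — the greedy keep/discard mask per evaluation batch,
  one row per batch over the fused-feature dimensions;
* branch importance — mean keep-rate over the ResNet slice versus the
  Transformer slice of the fused vector;
* reference-feature correlation — per-sample Pearson correlation of the
  PCA-reduced (6-dim) pre- and post-mask fused features with six
  sequence statistics known to track enhancer activity: GC content,
  CpG-dinucleotide count and the four nucleotide fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

#: Fixed order of the six reference dimensions.
REFERENCE_ORDER = ("gc_content", "cpg_count", "frac_a", "frac_c",
                   "frac_g", "frac_t")


@dataclass(frozen=True)
class ReferenceFeatures:
    gc_content: float
    cpg_count: int
    frac_a: float
    frac_c: float
    frac_g: float
    frac_t: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.gc_content, self.cpg_count, self.frac_a,
                         self.frac_c, self.frac_g, self.frac_t])


def reference_features(seq: str) -> ReferenceFeatures:
    """Six-dimensional sequence statistics in REFERENCE_ORDER."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    counts = {b: seq.count(b) for b in "ACGT"}
    cpg = sum(1 for i in range(n - 1) if seq[i:i + 2] == "CG")
    return ReferenceFeatures(
        gc_content=(counts["G"] + counts["C"]) / n,
        cpg_count=cpg,
        frac_a=counts["A"] / n,
        frac_c=counts["C"] / n,
        frac_g=counts["G"] / n,
        frac_t=counts["T"] / n,
    )


@dataclass(frozen=True)
class MaskHeatmap:
    """Rows = evaluation batches, columns = fused-feature dimensions."""

    matrix: np.ndarray

    @property
    def n_batches(self) -> int:
        return self.matrix.shape[0]

    @property
    def fused_dim(self) -> int:
        return self.matrix.shape[1]

    def keep_frequencies(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def save_tsv(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.3f", delimiter="\t")


def collect_masks(trainer, records, batch_size: int | None = None
                  ) -> MaskHeatmap:
    """Greedy mask per evaluation batch of ``records``.

    The state of each batch is its own batch-averaged fused feature, so
    rows may differ across batches.
    """
    from . import nn
    from .kmer import encode_batch

    batch_size = batch_size or trainer.cfg.batch_size
    ids, lengths, _ = encode_batch(records, trainer.vocab, trainer.l_max)
    rows = []
    trainer.network.eval()
    for start in range(0, len(lengths), batch_size):
        sel = slice(start, start + batch_size)
        with nn.no_grad():
            fused = trainer.network.extract(ids[sel], lengths[sel])
        state = fused.data.mean(axis=0)
        bits, _, _ = trainer.agent.act(state, greedy=True)
        rows.append(bits.astype(float))
    return MaskHeatmap(np.stack(rows))


def branch_importance(heatmap: MaskHeatmap,
                      resnet_dim: int) -> tuple[float, float]:
    """Mean keep-rate of the ResNet slice vs the Transformer slice."""
    if not 0 < resnet_dim < heatmap.fused_dim:
        raise ValueError(f"resnet_dim {resnet_dim} out of range for "
                         f"fused_dim {heatmap.fused_dim}")
    freq = heatmap.keep_frequencies()
    return float(freq[:resnet_dim].mean()), float(freq[resnet_dim:].mean())


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def paired_correlations(vectors: np.ndarray,
                        refs: np.ndarray) -> np.ndarray:
    """Pearson correlation between each row pair of two aligned matrices.

    Rows with zero variance yield NaN.
    """
    vectors = np.asarray(vectors, dtype=float)
    refs = np.asarray(refs, dtype=float)
    out = np.full(len(refs), np.nan)
    for i in range(len(refs)):
        if vectors[i].std() == 0 or refs[i].std() == 0:
            continue
        out[i] = pearsonr(vectors[i], refs[i]).statistic
    return out


def correlation_analysis(pre_mask: np.ndarray, post_mask: np.ndarray,
                         refs: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Pearson correlation of projected features vs references.

    Fits a separate 6-component PCA on the pre- and post-mask feature
    matrices, standardises each projected dimension and each reference
    dimension, then correlates the two 6-vectors per sample in the fixed
    REFERENCE_ORDER pairing.  Samples whose vectors have zero variance
    get NaN.

    Principal-component signs follow the fitted PCA's deterministic
    convention, which is arbitrary with respect to the class axis; the
    sign of any class-wise difference in these correlations is therefore
    a property of the particular fit, and only its magnitude should be
    read as evidence of class structure.
    """
    pre_mask = np.asarray(pre_mask, dtype=float)
    post_mask = np.asarray(post_mask, dtype=float)
    refs = np.asarray(refs, dtype=float)
    n = len(refs)
    if not (len(pre_mask) == len(post_mask) == n):
        raise ValueError("sample sets must align")
    if n < 7:
        raise ValueError("need at least 7 samples for a 6-component PCA")
    refs_z = _standardize(refs)

    def series(features: np.ndarray) -> np.ndarray:
        proj = PCA(n_components=6).fit_transform(features)
        return paired_correlations(_standardize(proj), refs_z)

    return series(pre_mask), series(post_mask)


def reference_matrix(records) -> np.ndarray:
    """Stack reference features for a record list (samples x 6)."""
    return np.stack([reference_features(r.seq).as_vector() for r in records])
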