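"""Feature-extraction and classification graph.

Embedded k-mer tokens flow through two parallel branches: a 1-D residual
CNN capturing local/hierarchical motifs, and a Transformer encoder with
sinusoidal positional encoding capturing long-range context.  The two
branch vectors are concatenated — ResNet entries first — into the fused
feature vector (192-dim under the default 64+128 widths), which a PPO
agent may mask elementwise before the sigmoid classifier head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class NetworkConfig:
    vocab_size: int = 258                 # 4^4 k-mers + <unk> + <pad>
    embed_dim: int = 128
    resnet_out_dim: int = 64
    transformer_out_dim: int | None = None  # defaults to embed_dim
    n_heads: int = 4
    n_encoder_blocks: int = 2
    dropout: float = 0.0
    resnet_width_factor: float = 0.25
    kernel: int = 3
    ffn_mult: int = 4
    head_hidden: int = 64
    branch_dropout: float = 0.0
    use_resnet: bool = True
    use_transformer: bool = True

    def __post_init__(self):
        if self.transformer_out_dim is None:
            self.transformer_out_dim = self.embed_dim
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(f"embed_dim {self.embed_dim} not divisible by "
                             f"n_heads {self.n_heads}")
        if not (self.use_resnet or self.use_transformer):
            raise ValueError("at least one feature branch must be enabled")

    @property
    def fused_dim(self) -> int:
        dim = 0
        if self.use_resnet:
            dim += self.resnet_out_dim
        if self.use_transformer:
            dim += self.transformer_out_dim
        return dim

    @property
    def resnet_channels(self) -> list[int]:
        return [max(4, int(w * self.resnet_width_factor))
                for w in (64, 128, 256, 512)]


def positional_encoding(l_max: int, dim: int, base: float = 1e4) -> np.ndarray:
    """Sinusoidal position table: sin on even slots, cos on odd slots."""
    pos = np.arange(l_max)[:, None]
    i = np.arange(0, dim, 2)[None, :]
    angles = pos / base ** (i / dim)
    table = np.zeros((l_max, dim))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles[:, : table[:, 1::2].shape[1]])
    return table


def fuse(resnet_vec: Tensor, transformer_vec: Tensor) -> Tensor:
    """Concatenate branch outputs: ResNet entries first, then Transformer."""
    if resnet_vec.shape[0] != transformer_vec.shape[0]:
        raise ValueError(f"batch mismatch: {resnet_vec.shape[0]} vs "
                         f"{transformer_vec.shape[0]}")
    return nn.concat([resnet_vec, transformer_vec], axis=1)


class ResidualBlock(nn.Module):
    """conv-bn-relu-conv-bn with identity or strided 1x1-projection skip."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        pad = kernel // 2
        self.conv1 = nn.Conv1d(in_ch, out_ch, kernel, rng, stride, pad)
        self.bn1 = nn.BatchNorm1d(out_ch)
        self.conv2 = nn.Conv1d(out_ch, out_ch, kernel, rng, 1, pad)
        self.bn2 = nn.BatchNorm1d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv1d(in_ch, out_ch, 1, rng, stride, 0)
            self.bn_proj = nn.BatchNorm1d(out_ch)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = x if self.proj is None else self.bn_proj(self.proj(x))
        return (out + skip).relu()


class ResNetBranch(nn.Module):
    """Simplified ResNet18-style 1-D CNN: 4 stages of 2 residual blocks,
    global average pooling over positions, linear projection to the
    branch width."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        widths = cfg.resnet_channels
        self.stem = nn.Conv1d(cfg.embed_dim, widths[0], cfg.kernel, rng,
                              1, cfg.kernel // 2)
        self.stem_bn = nn.BatchNorm1d(widths[0])
        blocks = []
        in_ch = widths[0]
        for stage, width in enumerate(widths):
            for b in range(2):
                stride = 2 if (stage > 0 and b == 0) else 1
                blocks.append(ResidualBlock(in_ch, width, cfg.kernel,
                                            stride, rng))
                in_ch = width
        self.blocks = blocks
        self.proj = nn.Linear(in_ch, cfg.resnet_out_dim, rng)

    def __call__(self, embedded: Tensor) -> Tensor:
        x = embedded.transpose(0, 2, 1)        # (B, D, L)
        x = self.stem_bn(self.stem(x)).relu()
        for block in self.blocks:
            x = block(x)
        pooled = x.mean(axis=2)                # global average over positions
        return self.proj(pooled)


class EncoderBlock(nn.Module):
    """Post-norm Transformer encoder block with pad-masked attention."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.embed_dim
        self.n_heads = cfg.n_heads
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self.ln1 = nn.LayerNorm(d)
        self.ln2 = nn.LayerNorm(d)
        self.ffn1 = nn.Linear(d, cfg.ffn_mult * d, rng)
        self.ffn2 = nn.Linear(cfg.ffn_mult * d, d, rng)
        self.drop = nn.Dropout(cfg.dropout)

    def attention(self, x: Tensor, key_bias: np.ndarray) -> Tensor:
        B, L, D = x.shape
        h, dh = self.n_heads, D // self.n_heads

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q = heads(self.wq(x)) * (1.0 / np.sqrt(dh))   # scale before matmul
        k, v = heads(self.wk(x)), heads(self.wv(x))
        scores = q @ k.transpose(0, 1, 3, 2)
        attn = nn.softmax(scores, axis=-1, bias=key_bias)  # -1e9 at pad keys
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)

    def __call__(self, x: Tensor, key_bias: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop(self.attention(x, key_bias)))
        x = self.ln2(x + self.drop(self.ffn2(self.ffn1(x).relu())))
        return x


class TransformerBranch(nn.Module):
    """Positional encoding + encoder stack + masked mean pooling."""

    def __init__(self, cfg: NetworkConfig, l_max: int,
                 rng: np.random.Generator, use_positional: bool = True):
        super().__init__()
        self.pe = positional_encoding(l_max, cfg.embed_dim) if use_positional \
            else np.zeros((l_max, cfg.embed_dim))
        self.encoders = [EncoderBlock(cfg, rng)
                         for _ in range(cfg.n_encoder_blocks)]
        self.proj = nn.Linear(cfg.embed_dim, cfg.transformer_out_dim, rng)

    def __call__(self, embedded: Tensor, lengths: np.ndarray) -> Tensor:
        B, L, _ = embedded.shape
        pad = np.arange(L)[None, :] >= lengths[:, None]    # (B, L)
        key_bias = np.where(pad, -1e9, 0.0)[:, None, None, :]
        x = embedded + Tensor(self.pe[:L])
        for enc in self.encoders:
            x = enc(x, key_bias)
        weights = (~pad).astype(float) / lengths[:, None]  # mean over non-pad
        pooled = (x * Tensor(weights[:, :, None])).sum(axis=1)
        return self.proj(pooled)


class ClassifierHead(nn.Module):
    """Two-layer sigmoid head with two mask-shaped regularisers.

    Elementwise dropout on the fused vector exposes the head to zeroed
    feature dimensions — the operation the PPO mask applies at
    inference.  Branch dropout goes further: with probability
    ``branch_dropout`` per sample it zeroes one entire branch slice
    (uncompensated, like a real mask), so each branch must stay
    independently predictive and the fused model cannot collapse onto a
    shortcut carried by a single branch.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.rng = np.random.default_rng(rng.integers(2 ** 31))
        self.drop = nn.Dropout(cfg.dropout,
                               np.random.default_rng(rng.integers(2 ** 31)))
        self.fc1 = nn.Linear(cfg.fused_dim, cfg.head_hidden, rng)
        self.fc2 = nn.Linear(cfg.head_hidden, 1, rng)

    def _branch_dropout(self, fused: Tensor) -> Tensor:
        cfg = self.cfg
        if (not self.training or cfg.branch_dropout <= 0.0
                or not (cfg.use_resnet and cfg.use_transformer)):
            return fused
        n = fused.shape[0]
        hit = self.rng.random(n) < cfg.branch_dropout
        which = self.rng.random(n) < 0.5       # True: drop ResNet slice
        keep = np.ones((n, cfg.fused_dim))
        keep[hit & which, :cfg.resnet_out_dim] = 0.0
        keep[hit & ~which, cfg.resnet_out_dim:] = 0.0
        return fused * Tensor(keep)

    def __call__(self, fused: Tensor) -> Tensor:
        fused = self.drop(self._branch_dropout(fused))
        return self.fc2(self.fc1(fused).relu()).reshape(-1).sigmoid()


class EnhancerNetwork(nn.Module):
    """Full graph: embedding -> branches -> fusion -> maskable head."""

    def __init__(self, cfg: NetworkConfig, l_max: int,
                 rng: np.random.Generator | int = 0,
                 use_positional: bool = True):
        super().__init__()
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.l_max = l_max
        self.embedding = nn.Embedding(cfg.vocab_size, cfg.embed_dim, rng)
        self.resnet = ResNetBranch(cfg, rng) if cfg.use_resnet else None
        self.transformer = (TransformerBranch(cfg, l_max, rng, use_positional)
                            if cfg.use_transformer else None)
        self.head = ClassifierHead(cfg, rng)

    @property
    def fused_dim(self) -> int:
        return self.cfg.fused_dim

    def embed(self, ids: np.ndarray) -> Tensor:
        if ids.max() >= self.cfg.vocab_size:
            raise IndexError(f"token id {ids.max()} out of range for "
                             f"vocab size {self.cfg.vocab_size}")
        return self.embedding(ids)

    def extract(self, ids: np.ndarray, lengths: np.ndarray) -> Tensor:
        """Fused feature batch (B, fused_dim)."""
        embedded = self.embed(ids)
        branches = []
        if self.resnet is not None:
            branches.append(self.resnet(embedded))
        if self.transformer is not None:
            branches.append(self.transformer(embedded, lengths))
        return branches[0] if len(branches) == 1 else fuse(*branches)

    def classify(self, fused: Tensor, mask: np.ndarray | None = None
                 ) -> Tensor:
        """P(label=1) per sample after elementwise feature masking.

        ``mask=None`` and the all-ones mask are the same forward pass.
        """
        if mask is not None:
            mask = np.asarray(mask, dtype=float)
            if mask.shape != (self.fused_dim,):
                raise ValueError(f"mask shape {mask.shape} != "
                                 f"({self.fused_dim},)")
            fused = fused * Tensor(mask[None, :])
        return self.head(fused)

    def __call__(self, ids: np.ndarray, lengths: np.ndarray,
                 mask: np.ndarray | None = None) -> Tensor:
        return self.classify(self.extract(ids, lengths), mask)

    def predict_proba(self, ids: np.ndarray, lengths: np.ndarray,
                      mask: np.ndarray | None = None) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                return self(ids, lengths, mask).data
        finally:
            self.train(was_training)
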