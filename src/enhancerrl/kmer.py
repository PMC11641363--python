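"""Overlapping k-mer tokenisation and the frequency-ranked vocabulary.

A DNA sequence of length N yields N-k+1 overlapping k-mers (step 1).
The vocabulary maps k-mer strings to integer ids: id 0 is the unknown
token, id 1 the padding token, and real k-mers receive ids from 2
upward in order of decreasing training-corpus frequency (ties broken
lexicographically so vocabularies are stable across runs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import LabeledSequence

UNK_ID = 0
PAD_ID = 1


def split_kmers(seq: str, k: int) -> list[str]:
    """All overlapping k-mers of ``seq`` with step 1, left to right."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than "
                         f"k={k}")
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


@dataclass(frozen=True)
class KmerVocabulary:
    k: int
    token_to_id: dict[str, int]
    unk_id: int = UNK_ID
    pad_id: int = PAD_ID

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    def save(self, path: str | Path) -> None:
        lines = ["<unk>\t0", "<pad>\t1"]
        lines += [f"{tok}\t{idx}" for tok, idx in
                  sorted(self.token_to_id.items(), key=lambda kv: kv[1])]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerVocabulary":
        token_to_id: dict[str, int] = {}
        k = None
        for line in Path(path).read_text().splitlines():
            tok, idx = line.split("\t")
            if tok in ("<unk>", "<pad>"):
                continue
            token_to_id[tok] = int(idx)
            k = len(tok)
        if k is None:
            raise ValueError(f"{path}: vocabulary has no k-mer entries")
        return cls(k=k, token_to_id=token_to_id)


def build_vocabulary(corpus: list[LabeledSequence],
                     k: int) -> KmerVocabulary:
    """Rank k-mers of the training corpus by descending frequency.

    Must be built from training records only so the unknown token is
    meaningful on held-out data.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for rec in corpus:
        counts.update(split_kmers(rec.seq, k))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    token_to_id = {tok: i + 2 for i, (tok, _) in enumerate(ranked)}
    return KmerVocabulary(k=k, token_to_id=token_to_id)


@dataclass(frozen=True)
class EncodedSequence:
    ids: np.ndarray = field(repr=False)
    true_length: int


def encode(seq: str, vocab: KmerVocabulary, l_max: int) -> EncodedSequence:
    """Integer-encode ``seq``: unknown k-mers -> 0, pad/truncate to l_max."""
    tokens = split_kmers(seq, vocab.k)
    ids = [vocab.id_of(t) for t in tokens[:l_max]]
    true_length = len(ids)
    ids.extend([vocab.pad_id] * (l_max - true_length))
    return EncodedSequence(np.asarray(ids, dtype=np.int64), true_length)


def decode(encoded: EncodedSequence, vocab: KmerVocabulary) -> list[str]:
    """Token strings of the non-pad positions (unknown -> '<unk>')."""
    inverse = vocab.id_to_token
    inverse[vocab.unk_id] = "<unk>"
    return [inverse[int(i)] for i in encoded.ids[:encoded.true_length]]


def encode_batch(records: list[LabeledSequence], vocab: KmerVocabulary,
                 l_max: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a record list to (ids, lengths, labels) arrays."""
    encoded = [encode(r.seq, vocab, l_max) for r in records]
    ids = np.stack([e.ids for e in encoded])
    lengths = np.asarray([e.true_length for e in encoded], dtype=np.int64)
    labels = np.asarray([r.label for r in records], dtype=np.float64)
    return ids, lengths, labels


def default_l_max(records: list[LabeledSequence], k: int) -> int:
    """Median token count of the corpus (N-k+1 for fixed-length data)."""
    counts = [len(r.seq) - k + 1 for r in records]
    return int(np.median(counts))
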