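"""Reading, writing, validating and splitting labeled DNA sequence sets.

Datasets are FASTA files accompanied by a two-column TSV label table
(``id<TAB>label``).  As a convenience the label may instead be carried in
the FASTA header itself as ``>id|label``; both dialects are accepted by
:func:`read_dataset`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class LabeledSequence:
    """One DNA string with a binary label (1 = enhancer / strong)."""

    id: str
    seq: str
    label: int

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, "
                             f"got {self.label!r}")


@dataclass(frozen=True)
class DatasetSplit:
    train: list[LabeledSequence]
    validation: list[LabeledSequence]
    split_fraction: float
    split_seed: int


def _normalize(rec_id: str, seq: str, label: int) -> LabeledSequence | None:
    """Uppercase and validate; non-ACGT records are dropped with a warning."""
    seq = seq.upper()
    if not seq:
        raise ValueError(f"record {rec_id!r}: empty sequence")
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        logger.warning("record %r rejected: non-ACGT characters %s",
                       rec_id, bad)
        return None
    return LabeledSequence(rec_id, seq, int(label))


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a TSV label table (id, label) into a dict."""
    labels: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rec_id, value = line.split("\t")
        labels[rec_id] = int(value)
    return labels


def read_fasta(path: str | Path,
               labels: dict[str, int]) -> list[LabeledSequence]:
    """Read FASTA records, attaching labels from an id->{0,1} mapping.

    Record order is preserved; sequences are uppercased; records containing
    characters outside A/C/G/T are rejected with a logged warning.
    """
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise ValueError(f"{path}: no FASTA records found")
    records = []
    for rec in raw:
        if rec.id not in labels:
            raise KeyError(f"{path}: record {rec.id!r} missing from the "
                           "label table")
        parsed = _normalize(rec.id, str(rec.seq), labels[rec.id])
        if parsed is not None:
            records.append(parsed)
    return records


def read_dataset(fasta_path: str | Path,
                 labels_path: str | Path | None = None
                 ) -> list[LabeledSequence]:
    """Read FASTA + TSV labels, or header-encoded ``>id|label`` FASTA."""
    if labels_path is not None:
        return read_fasta(fasta_path, read_labels(labels_path))
    raw = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not raw:
        raise ValueError(f"{fasta_path}: no FASTA records found")
    records = []
    for rec in raw:
        if "|" not in rec.id:
            raise KeyError(f"{fasta_path}: record {rec.id!r} has no "
                           "'|label' suffix and no label table was given")
        rec_id, label = rec.id.rsplit("|", 1)
        parsed = _normalize(rec_id, str(rec.seq), int(label))
        if parsed is not None:
            records.append(parsed)
    return records


def write_dataset(records: list[LabeledSequence], fasta_path: str | Path,
                  labels_path: str | Path | None = None) -> None:
    """Write FASTA (+ optional TSV label table, else ``id|label`` headers)."""
    seq_records = []
    for rec in records:
        header = rec.id if labels_path is not None else f"{rec.id}|{rec.label}"
        seq_records.append(SeqRecord(Seq(rec.seq), id=header, description=""))
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    if labels_path is not None:
        lines = [f"{rec.id}\t{rec.label}" for rec in records]
        Path(labels_path).write_text("\n".join(lines) + "\n")


def split_dataset(records: list[LabeledSequence], split_fraction: float,
                  split_seed: int) -> DatasetSplit:
    """Random train/validation split, reproducible from ``split_seed``.

    Validation size is round-half-up of ``split_fraction * len(records)``.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError(f"split_fraction must be in (0, 1), "
                         f"got {split_fraction}")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    n_val = int(math.floor(split_fraction * len(records) + 0.5))
    n_val = max(1, min(n_val, len(records) - 1))
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(records))
    val_idx = set(order[:n_val].tolist())
    train = [r for i, r in enumerate(records) if i not in val_idx]
    validation = [r for i, r in enumerate(records) if i in val_idx]
    return DatasetSplit(train, validation, split_fraction, split_seed)
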