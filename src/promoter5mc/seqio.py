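"""Reading, writing and splitting labelled promoter windows.

The unit of input is a fixed-length DNA window (41 bp by default) centred on
a candidate cytosine, with a binary label: 1 for a genuine 5mC site, 0 for a
spurious one. Labels travel either in the FASTA header as a ``|label=0/1``
suffix or in a separate two-column TSV (id <tab> label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "DnaSequence", "LabeledDataset", "DatasetSummary",
    "read_fasta", "write_fasta", "read_labels_tsv", "write_labels_tsv",
    "stratified_split", "summarize",
    "FastaParseError", "SequenceValidationError", "LabelingError", "SplitError",
    "BENCHMARK_COMPOSITION", "WINDOW_LENGTH",
]

WINDOW_LENGTH = 41

ALPHABET = frozenset("ACGT")
ALPHABET_WITH_N = frozenset("ACGTN")

#: Per-cancer-type (n_positive, n_negative) window counts of the CCLE-derived
#: promoter-5mC benchmark this package targets.  Used for dataset arithmetic
#: and as the reference imbalance (~1:7.6); the full data itself is external.
BENCHMARK_COMPOSITION: dict[str, tuple[int, int]] = {
    "human small cell lung cancer": (69_750, 823_576),
    "human non-small cell lung cancer": (170_484, 1_164_674),
    "human hepatocellular carcinoma": (146_539, 935_624),
}


class FastaParseError(ValueError):
    """Malformed FASTA input; ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class SequenceValidationError(ValueError):
    """A record violates the alphabet or window-length contract."""


class LabelingError(ValueError):
    """A record could not be resolved to a binary label."""


class SplitError(ValueError):
    """A class is too small to populate both partitions."""


@dataclass(frozen=True)
class DnaSequence:
    """An identified DNA window with an optional binary label."""

    id: str
    bases: str
    label: int | None = None

    def validate(self, allow_n: bool = False, window_length: int | None = None) -> "DnaSequence":
        allowed = ALPHABET_WITH_N if allow_n else ALPHABET
        bad = set(self.bases) - allowed
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)}; "
                f"allowed alphabet is {''.join(sorted(allowed))}")
        if window_length is not None and len(self.bases) != window_length:
            raise SequenceValidationError(
                f"record {self.id!r}: length {len(self.bases)} != window length {window_length}")
        return self

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class LabeledDataset:
    """An ordered collection of labelled windows."""

    sequences: list[DnaSequence] = field(default_factory=list)

    def __post_init__(self):
        for s in self.sequences:
            if s.label not in (0, 1):
                raise LabelingError(f"record {s.id!r} has no binary label")

    @property
    def n_pos(self) -> int:
        return sum(1 for s in self.sequences if s.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for s in self.sequences if s.label == 0)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sequences], dtype=int)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.sequences[i] for i in indices])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[DnaSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> DnaSequence:
        return self.sequences[i]


@dataclass(frozen=True)
class DatasetSummary:
    n_pos: int
    n_neg: int
    ratio: float  # n_neg / n_pos

    def __str__(self) -> str:
        return (f"{self.n_pos + self.n_neg} windows: {self.n_pos} positive, "
                f"{self.n_neg} negative (1:{self.ratio:.1f})")


def _check_fasta_shape(path: Path) -> None:
    # Biopython is permissive; enforce "first non-blank line is a header"
    # so malformed input fails with a line number instead of silently
    # yielding zero records.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError("expected FASTA header '>'", line=lineno)
            return
    raise FastaParseError("empty FASTA file", line=1)


def _label_from_header(record_id: str, description: str) -> tuple[str, int]:
    for token in description.replace("|", " ").split():
        if token.startswith("label="):
            value = token[len("label="):]
            if value not in ("0", "1"):
                raise LabelingError(f"record {record_id!r}: label must be 0 or 1, got {value!r}")
            return record_id.split("|")[0], int(value)
    raise LabelingError(f"record {record_id!r}: no '|label=' tag in header")


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise LabelingError(f"labels file line {lineno}: expected 'id<TAB>0/1'")
            labels[parts[0]] = int(parts[1])
    return labels


def write_labels_tsv(data: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in data:
            fh.write(f"{s.id}\t{s.label}\n")


def read_fasta(path: str | Path,
               labels: str | Path | Mapping[str, int] | None = None,
               allow_n: bool = False,
               window_length: int | None = None) -> LabeledDataset:
    """Read a labelled FASTA file.

    Parameters
    ----------
    path:
        Multi-record FASTA. Every record must resolve to a binary label.
    labels:
        ``None`` — labels are taken from a ``|label=0/1`` header suffix;
        a path — a two-column TSV of ``id<TAB>label``; a mapping — used
        directly.
    allow_n:
        Accept ``N`` bases (encoders emit an all-zero column for them).
    window_length:
        If given, every record must have exactly this length.
    """
    path = Path(path)
    _check_fasta_shape(path)
    label_map: Mapping[str, int] | None
    if labels is None:
        label_map = None
    elif isinstance(labels, (str, Path)):
        label_map = read_labels_tsv(labels)
    else:
        label_map = labels

    sequences: list[DnaSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        if label_map is None:
            rec_id, label = _label_from_header(record.id, record.description)
        else:
            rec_id = record.id
            if rec_id not in label_map:
                raise LabelingError(f"record {rec_id!r}: no label in labels file")
            label = label_map[rec_id]
        seq = DnaSequence(rec_id, str(record.seq).upper(), label)
        seq.validate(allow_n=allow_n, window_length=window_length)
        sequences.append(seq)
    return LabeledDataset(sequences)


def write_fasta(data: LabeledDataset, path: str | Path,
                label_in_header: bool = True) -> None:
    with open(path, "w") as fh:
        for s in data:
            header = f">{s.id}|label={s.label}" if label_in_header else f">{s.id}"
            fh.write(f"{header}\n{s.bases}\n")


def stratified_split(data: LabeledDataset, test_fraction: float,
                     seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class random partition into train and test sets.

    Per class, ``round(test_fraction * class_count)`` sequences (round half
    up) go to the test partition; the remainder stays in train. The split is
    a deterministic function of ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise SplitError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    labels = data.labels()
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size == 0:
            raise SplitError(f"class {cls} is empty")
        n_test = int(np.floor(test_fraction * members.size + 0.5))
        if n_test == 0 or n_test == members.size:
            raise SplitError(
                f"class {cls} with {members.size} members cannot populate both partitions "
                f"at test_fraction {test_fraction}")
        perm = rng.permutation(members)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return data.subset(sorted(train_idx)), data.subset(sorted(test_idx))


def summarize(data: LabeledDataset) -> DatasetSummary:
    if len(data) == 0:
        raise ValueError("cannot summarize an empty dataset")
    n_pos, n_neg = data.n_pos, data.n_neg
    if n_pos == 0:
        raise ZeroDivisionError("imbalance ratio undefined: no positive samples")
    return DatasetSummary(n_pos, n_neg, n_neg / n_pos)
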