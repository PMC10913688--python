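"""Sequence encoders: one-hot (4 x L), nucleotide chemical property (3 x L),
and their row-stacked merged form (7 x L).

One-hot follows the alphabet order A, C, G, T. The NCP code maps each base
to a 3-bit vector built from ring structure, functional group and
hydrogen-bonding chemistry: A -> (1,1,1), C -> (0,1,0), G -> (1,0,0),
T -> (0,0,1). With ``allow_n``, an ``N`` becomes an all-zero column in
every scheme.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .seqio import DnaSequence, SequenceValidationError

__all__ = [
    "one_hot_encode", "ncp_encode", "merge_encodings", "encode_sequences",
    "decode_one_hot", "DnaEncoder", "ONE_HOT_ROWS", "NCP_ROWS", "MERGED_ROWS",
]

ONE_HOT_ROWS = 4
NCP_ROWS = 3
MERGED_ROWS = ONE_HOT_ROWS + NCP_ROWS

_BASES = "ACGT"

_ONE_HOT = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "T": (0, 0, 0, 1),
    "N": (0, 0, 0, 0),
}

_NCP = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "T": (0, 0, 1),
    "N": (0, 0, 0),
}


def _bases_of(seq) -> str:
    return seq.bases if isinstance(seq, DnaSequence) else str(seq)


def _columns(bases: str, table: dict, allow_n: bool) -> np.ndarray:
    allowed = set("ACGTN") if allow_n else set("ACGT")
    bad = set(bases) - allowed
    if bad:
        raise SequenceValidationError(
            f"cannot encode sequence containing {sorted(bad)}")
    return np.array([table[b] for b in bases], dtype=float).T


def one_hot_encode(seq, allow_n: bool = False) -> np.ndarray:
    """Encode a sequence as a 4 x L binary matrix, row order A, C, G, T."""
    return _columns(_bases_of(seq), _ONE_HOT, allow_n)


def ncp_encode(seq, allow_n: bool = False) -> np.ndarray:
    """Encode a sequence as a 3 x L chemical-property matrix."""
    return _columns(_bases_of(seq), _NCP, allow_n)


def merge_encodings(onehot: np.ndarray, ncp: np.ndarray) -> np.ndarray:
    """Row-stack a 4 x L one-hot and a 3 x L NCP matrix into 7 x L."""
    if onehot.shape[0] != ONE_HOT_ROWS:
        raise ValueError(f"expected a {ONE_HOT_ROWS}-row one-hot matrix, got {onehot.shape}")
    if ncp.shape[0] != NCP_ROWS:
        raise ValueError(f"expected a {NCP_ROWS}-row NCP matrix, got {ncp.shape}")
    if onehot.shape[1] != ncp.shape[1]:
        raise ValueError(
            f"length mismatch: one-hot has {onehot.shape[1]} columns, NCP {ncp.shape[1]}")
    return np.vstack([onehot, ncp])


def merged_encode(seq, allow_n: bool = False) -> np.ndarray:
    return merge_encodings(one_hot_encode(seq, allow_n), ncp_encode(seq, allow_n))


def decode_one_hot(matrix: np.ndarray) -> str:
    """Recover the base string from the 4 one-hot rows (of a 4- or 7-row matrix)."""
    return "".join(_BASES[i] for i in np.argmax(matrix[:ONE_HOT_ROWS], axis=0))


def encode_sequences(seqs: Iterable, scheme: str = "merged",
                     allow_n: bool = False) -> np.ndarray:
    """Encode sequences into an (n, rows, L) array.

    ``seqs`` may be a :class:`LabeledDataset`, DnaSequence objects or plain
    strings; all must share one length.
    """
    encoders = {"onehot": one_hot_encode, "ncp": ncp_encode, "merged": merged_encode}
    if scheme not in encoders:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(encoders)}")
    fn = encoders[scheme]
    mats = [fn(s, allow_n=allow_n) for s in seqs]
    if not mats:
        raise ValueError("no sequences to encode")
    lengths = {m.shape[1] for m in mats}
    if len(lengths) > 1:
        raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")
    return np.stack(mats)


class DnaEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer from sequences to feature matrices.

    Parameters
    ----------
    scheme : {"merged", "onehot", "ncp"}
        Which feature matrix to produce per sequence.
    allow_n : bool
        Encode ``N`` as an all-zero column instead of rejecting it.

    ``transform`` returns an array of shape (n_sequences, rows, length) with
    rows 7, 4 or 3 according to the scheme.
    """

    def __init__(self, scheme: str = "merged", allow_n: bool = False):
        self.scheme = scheme
        self.allow_n = allow_n

    def fit(self, X, y=None):
        encode_sequences(X[:1] if len(X) else X, self.scheme, self.allow_n)
        self.n_rows_ = {"onehot": ONE_HOT_ROWS, "ncp": NCP_ROWS, "merged": MERGED_ROWS}[self.scheme]
        return self

    def transform(self, X) -> np.ndarray:
        return encode_sequences(X, self.scheme, self.allow_n)
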