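"""Synthetic labelled 41-bp window generator.

Emulates the statistical structure the classifier assumes: fixed-length
windows centred on a candidate cytosine (centre base forced to C in *both*
classes, so the centre base itself carries no class signal), a planted
degenerate motif (position weight matrix) that distinguishes positives from
negatives, i.i.d. background elsewhere, and a configurable negative:positive
imbalance defaulting to 7.6 — the imbalance of the CCLE-derived promoter-5mC
benchmark this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import DnaSequence, LabeledDataset, WINDOW_LENGTH

__all__ = [
    "SyntheticSpec", "generate", "default_benchmark_spec", "consensus_pwm",
    "pwm_scores", "DEFAULT_IMBALANCE",
]

_BASES = "ACGT"

#: Negative:positive ratio of the reference benchmark composition.
DEFAULT_IMBALANCE = 7.6


def consensus_pwm(consensus: str, consensus_weight: float = 0.85) -> np.ndarray:
    """A 4 x w PWM putting ``consensus_weight`` on the consensus base per
    column and the remainder uniformly on the other three bases."""
    if not 0.0 < consensus_weight <= 1.0:
        raise ValueError("consensus_weight must be in (0, 1]")
    off = (1.0 - consensus_weight) / 3.0
    pwm = np.full((4, len(consensus)), off)
    for j, base in enumerate(consensus):
        pwm[_BASES.index(base), j] = consensus_weight
    return pwm


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; fully determines a dataset together with seed."""

    n_pos: int
    n_neg: int
    window_length: int = WINDOW_LENGTH
    motif: np.ndarray = field(default_factory=lambda: consensus_pwm("ACGTAC"))
    motif_offset: int = 10
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        motif = np.asarray(self.motif, dtype=float)
        if motif.ndim != 2 or motif.shape[0] != 4:
            raise ValueError("motif must be a 4 x w matrix over A,C,G,T")
        if not np.allclose(motif.sum(axis=0), 1.0):
            raise ValueError("PWM columns must sum to 1")
        if np.any(motif < 0):
            raise ValueError("PWM entries must be non-negative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or np.any(bg < 0):
            raise ValueError("background must be a length-4 distribution")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.motif_offset < 0 or self.motif_offset + motif.shape[1] > self.window_length:
            raise ValueError("motif does not fit inside the window")

    @property
    def centre(self) -> int:
        return self.window_length // 2

    @property
    def ratio(self) -> float:
        return self.n_neg / self.n_pos if self.n_pos else float("inf")

    def replace(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


def default_benchmark_spec(seed: int = 1) -> SyntheticSpec:
    """The canonical test fixture: 800 positives, 6080 negatives (1:7.6),
    a width-6 PWM with 0.85 consensus weight per column at offset 10,
    uniform background, no label noise."""
    return SyntheticSpec(n_pos=800, n_neg=6080, motif=consensus_pwm("ACGTAC", 0.85),
                         motif_offset=10, label_noise=0.0, seed=seed)


def _sample(rng: np.random.Generator, probs: np.ndarray, n: int, length: int) -> np.ndarray:
    """(n, length) array of base indices drawn i.i.d. from ``probs`` columns.

    ``probs`` is (4,) for background or (4, length) per-position."""
    if probs.ndim == 1:
        probs = np.repeat(probs[:, None], length, axis=1)
    u = rng.random((n, length))
    cum = np.cumsum(probs, axis=0)
    return (u[:, None, :] > cum[None, :, :]).sum(axis=1)


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labelled dataset from the spec, reproducibly from its seed."""
    rng = np.random.default_rng(spec.seed)
    w = spec.motif.shape[1]
    records: list[DnaSequence] = []

    def build(n: int, with_motif: bool, prefix: str, label: int) -> None:
        if n == 0:
            return
        idx = _sample(rng, spec.background, n, spec.window_length)
        if with_motif:
            motif_idx = np.stack(
                [rng.choice(4, size=n, p=spec.motif[:, j]) for j in range(w)], axis=1)
            idx[:, spec.motif_offset:spec.motif_offset + w] = motif_idx
        idx[:, spec.centre] = 1  # centre base C in both classes
        for i in range(n):
            bases = "".join(_BASES[b] for b in idx[i])
            records.append(DnaSequence(f"{prefix}{i:06d}", bases, label))

    build(spec.n_pos, True, "pos", 1)
    build(spec.n_neg, False, "neg", 0)

    if spec.label_noise > 0:
        flip = rng.random(len(records)) < spec.label_noise
        records = [DnaSequence(s.id, s.bases, 1 - s.label) if f else s
                   for s, f in zip(records, flip)]
    return LabeledDataset(records)


def pwm_scores(sequences, pwm: np.ndarray, offset: int,
               background: np.ndarray | None = None) -> np.ndarray:
    """Log-likelihood-ratio motif scores at a fixed offset.

    A deliberately simple reference classifier: with the true PWM and offset
    it upper-bounds what any learned model can extract from the planted
    signal, so it serves as a sanity yardstick in tests.
    """
    pwm = np.asarray(pwm, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    w = pwm.shape[1]
    log_ratio = np.log(np.maximum(pwm, 1e-12)) - np.log(np.maximum(bg, 1e-12))[:, None]
    scores = []
    for s in sequences:
        bases = s.bases if hasattr(s, "bases") else str(s)
        window = bases[offset:offset + w]
        scores.append(sum(log_ratio[_BASES.index(b), j] for j, b in enumerate(window)))
    return np.asarray(scores)
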