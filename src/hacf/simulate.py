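"""Synthetic labeled datasets and toy expression matrices.

The generator emulates the study design end to end without external data:

* negatives are Markov-model background sequences (default order 0 with a
  human-like ~41% GC composition), standing in for non-enhancer intergenic
  regions;
* positives are background sequences seeded with dinucleotide repeat
  motifs (DRMs such as GCGCGC and GAGAGA, the repeat class reported to be
  required for active enhancers), inserted at Poisson-distributed counts —
  the insertion rate is the controlled effect size, and rate 0 degenerates
  exactly to background (the null case);
* the class ratio defaults to 1 positive : 10 negatives, matching the
  genomic prior used for training design;
* a log-normal "TPM" expression matrix with independent dropout supports
  the dataset-filtering stage: an element is kept when its minimal nonzero
  expression across conditions is at least alpha (default 0.08); all-zero
  rows are dropped as inactive.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, DNASequence

#: dinucleotide repeat motifs reported as required for active enhancers
DEFAULT_MOTIFS = ("GCGCGC", "GAGAGA")

#: order-0 background with human-like base composition (~41% GC)
HUMAN_LIKE_COMPOSITION = (0.295, 0.205, 0.205, 0.295)  # A, C, G, T

MIN_SEQ_LEN = 100  # shorter elements are never emitted (failed-featurization floor)


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the synthetic dataset generator.

    ``insertion_rate`` is the expected number of motif insertions per
    positive sequence (Poisson); it is the effect-size dial.  The default
    of 8 gives a clearly learnable but imperfect class signal at 1 kb.
    """

    seed: int = 0
    n_pos: int = 50
    n_neg: Optional[int] = None  # default: neg_pos_ratio * n_pos
    seq_len: int = 1000
    background_order: int = 0
    background_params: Optional[np.ndarray] = None  # (4,) or (4**order, 4)
    motif_set: tuple[str, ...] = DEFAULT_MOTIFS
    insertion_rate: float = 8.0
    neg_pos_ratio: int = 10

    def __post_init__(self) -> None:
        if self.seq_len < MIN_SEQ_LEN:
            raise ConfigError(f"seq_len must be >= {MIN_SEQ_LEN}, got {self.seq_len}")
        if self.insertion_rate < 0:
            raise ConfigError("insertion_rate must be >= 0")
        if self.background_order < 0:
            raise ConfigError("background_order must be >= 0")
        if self.neg_pos_ratio < 1:
            raise ConfigError("neg_pos_ratio must be >= 1")
        for m in self.motif_set:
            if set(m) - set(ALPHABET):
                raise ConfigError(f"motif {m!r} is not over ACGT")
            if len(m) > self.seq_len:
                raise ConfigError(f"motif {m!r} longer than seq_len {self.seq_len}")
        probs = self._probs()
        if probs.shape != (4 ** self.background_order, 4):
            raise ConfigError(
                f"background_params shape {probs.shape} != "
                f"({4 ** self.background_order}, 4) for order {self.background_order}"
            )
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("background probabilities must be >= 0 and rows sum to 1")

    def _probs(self) -> np.ndarray:
        if self.background_params is None:
            base = np.asarray(HUMAN_LIKE_COMPOSITION, dtype=float)
            return np.tile(base, (4 ** self.background_order, 1))
        p = np.asarray(self.background_params, dtype=float)
        if p.ndim == 1:
            p = p.reshape(1, -1)
        return p

    @property
    def effective_n_neg(self) -> int:
        return self.n_neg if self.n_neg is not None else self.neg_pos_ratio * self.n_pos


def _sample_background(
    rng: np.random.Generator, n_seqs: int, seq_len: int, order: int, probs: np.ndarray
) -> list[str]:
    letters = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    out = []
    if order == 0:
        p = probs[0]
        draws = rng.choice(4, size=(n_seqs, seq_len), p=p)
        for row in draws:
            out.append(letters[row].tobytes().decode())
    else:
        cum = np.cumsum(probs, axis=1)
        for _ in range(n_seqs):
            seq = list(rng.choice(4, size=order, p=probs.mean(axis=0) / probs.mean(axis=0).sum()))
            state = 0
            for s in seq:
                state = state * 4 + int(s)
            u = rng.random(seq_len - order)
            for t in range(seq_len - order):
                nxt = int(np.searchsorted(cum[state], u[t], side="right"))
                nxt = min(nxt, 3)
                seq.append(nxt)
                state = (state * 4 + nxt) % (4 ** order)
            out.append(letters[np.array(seq)].tobytes().decode())
    return out


def generate_background(config: GeneratorConfig, n: Optional[int] = None,
                        id_prefix: str = "neg") -> list[DNASequence]:
    """Markov-background sequences (the negative/null class)."""
    n = config.effective_n_neg if n is None else n
    rng = np.random.default_rng(config.seed)
    words = _sample_background(
        rng, n, config.seq_len, config.background_order, config._probs()
    )
    return [DNASequence(id=f"{id_prefix}_{i + 1}", bases=w) for i, w in enumerate(words)]


def generate_enhancer_like(config: GeneratorConfig, n: Optional[int] = None,
                           id_prefix: str = "pos") -> list[DNASequence]:
    """Background sequences with Poisson(insertion_rate) DRM insertions.

    Each insertion overwrites background bases with a motif drawn uniformly
    from the motif set at a uniform admissible position.  At insertion
    rate 0 the output is distributionally identical to background.
    """
    n = config.n_pos if n is None else n
    # offset the stream so positives never replay the negatives' randomness
    rng = np.random.default_rng((config.seed, 1))
    words = _sample_background(
        rng, n, config.seq_len, config.background_order, config._probs()
    )
    out = []
    for i, w in enumerate(words):
        chars = list(w)
        k = rng.poisson(config.insertion_rate)
        for _ in range(k):
            motif = config.motif_set[rng.integers(len(config.motif_set))]
            pos = int(rng.integers(0, config.seq_len - len(motif) + 1))
            chars[pos : pos + len(motif)] = motif
        out.append(DNASequence(id=f"{id_prefix}_{i + 1}", bases="".join(chars)))
    return out


def build_labeled_dataset(config: GeneratorConfig) -> tuple[list[DNASequence], np.ndarray]:
    """Positives + ratio-matched negatives, shuffled deterministically.

    Returns ``(sequences, labels)`` with labels in {0, 1}; all sequences
    have length ``config.seq_len``.
    """
    pos = generate_enhancer_like(config)
    neg = generate_background(config)
    seqs = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=int)
    rng = np.random.default_rng((config.seed, 2))
    order = rng.permutation(len(seqs))
    return [seqs[i] for i in order], labels[order]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A toy TPM-style matrix: rows = elements, columns = conditions."""

    element_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        if self.tpm.shape != (len(self.element_ids), len(self.condition_ids)):
            raise ValueError("tpm shape inconsistent with ids")
        if not np.all(np.isfinite(self.tpm)) or np.any(self.tpm < 0):
            raise ValueError("tpm values must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.tpm, index=list(self.element_ids), columns=list(self.condition_ids)
        )


def generate_tpm_matrix(
    n_elements: int, n_conditions: int, sparsity: float, seed: int = 0
) -> ExpressionMatrix:
    """Log-normal positive entries with independent zero-dropout."""
    if n_elements < 1 or n_conditions < 1:
        raise ConfigError("dimensions must be >= 1")
    if not 0.0 <= sparsity <= 1.0:
        raise ConfigError(f"sparsity must be in [0, 1], got {sparsity}")
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=-1.0, sigma=1.2, size=(n_elements, n_conditions))
    vals[rng.random(size=vals.shape) < sparsity] = 0.0
    return ExpressionMatrix(
        element_ids=tuple(f"elem_{i + 1}" for i in range(n_elements)),
        condition_ids=tuple(f"cond_{j + 1}" for j in range(n_conditions)),
        tpm=vals,
    )


def filter_by_tpm(matrix: ExpressionMatrix, alpha: float = 0.08) -> list[str]:
    """Elements whose minimal nonzero TPM across conditions is >= alpha.

    All-zero rows have no nonzero minimum and are dropped as inactive.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    kept = []
    for i, eid in enumerate(matrix.element_ids):
        row = matrix.tpm[i]
        nz = row[row > 0]
        if nz.size and nz.min() >= alpha:
            kept.append(eid)
    return kept
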