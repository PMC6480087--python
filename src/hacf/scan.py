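"""Sliding-window genome scanning and candidate-enhancer calling.

A trained model is slid across a long sequence (default 1 kb window, 10 bp
step), producing one probability-like score per full window.  Windows with
score strictly greater than 0.5 become candidate intervals; overlapping or
near-adjacent candidates are merged into predicted enhancers.  Candidates
can also be exported as a scored BED file for external peak calling
(e.g. MACS2, which is not re-implemented here — :func:`merge_candidates`
is a simple documented substitute).

Only full windows are scored: the number of windows over a length-L
sequence is floor((L - window_len)/step) + 1.  Windows containing an 'N'
are skipped and counted, since the complexity features are undefined off
the 4-letter alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureRecipe
from .model import SCORE_THRESHOLD, TrainedModel
from .sequence_io import DNASequence, GenomicInterval, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Window scores over one sequence/contig."""

    chrom: str
    window_starts: np.ndarray  # ascending 0-based starts of scored windows
    scores: np.ndarray  # aligned, each in [0, 1]
    window_len: int
    step: int
    n_skipped: int = 0  # windows dropped for containing N

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.window_starts) != len(self.scores):
            raise ValueError("starts and scores must align")
        if len(self.window_starts) > 1 and not np.all(np.diff(self.window_starts) > 0):
            raise ValueError("window starts must be strictly increasing")


@dataclass(frozen=True)
class PredictedEnhancer:
    """A merged run of above-threshold windows."""

    interval: GenomicInterval
    peak_score: float
    n_supporting_windows: int


def scan_sequence(
    seq: DNASequence,
    model: TrainedModel,
    window_len: int = 1000,
    step: int = 10,
    batch_size: int = 128,
    symmetrize: bool = False,
) -> ScanResult:
    """Score every full window of ``seq`` with ``model``.

    Evaluation is streamed in batches of ``batch_size`` windows so memory
    stays bounded in the sequence length.  With ``symmetrize`` the score is
    the mean of the window and its reverse complement (the ACF block is
    reverse-complement invariant already; TNF is not).
    """
    L = len(seq)
    if L < window_len:
        raise ValueError(f"sequence length {L} < window length {window_len}")
    if model.recipe.seq_len != window_len and model.recipe.kind != "tnf":
        raise ValueError(
            f"model analysis length {model.recipe.seq_len} != window {window_len}"
        )
    chrom = seq.source_interval[0] if seq.source_interval else seq.id
    offset = seq.source_interval[1] if seq.source_interval else 0
    all_starts = range(0, L - window_len + 1, step)
    starts_out: list[int] = []
    scores_out: list[np.ndarray] = []
    n_skipped = 0
    batch: list[DNASequence] = []
    batch_starts: list[int] = []

    def flush() -> None:
        if not batch:
            return
        X = _featurize_windows(batch, model.recipe)
        s = model.score(X)
        if symmetrize:
            rc = [
                DNASequence(id=w.id + "_rc", bases=reverse_complement(w.bases))
                for w in batch
            ]
            s = (s + model.score(_featurize_windows(rc, model.recipe))) / 2.0
        scores_out.append(s)
        starts_out.extend(batch_starts)
        batch.clear()
        batch_starts.clear()

    for start in all_starts:
        bases = seq.bases[start : start + window_len]
        if "N" in bases:
            n_skipped += 1
            continue
        batch.append(DNASequence(id=f"{chrom}:{start}", bases=bases))
        batch_starts.append(start)
        if len(batch) >= batch_size:
            flush()
    flush()
    if n_skipped:
        logger.info("%s: skipped %d window(s) containing N", chrom, n_skipped)
    scores = np.concatenate(scores_out) if scores_out else np.empty(0)
    return ScanResult(
        chrom=chrom,
        window_starts=np.asarray(starts_out, dtype=np.int64) + offset,
        scores=scores,
        window_len=window_len,
        step=step,
        n_skipped=n_skipped,
    )


def _featurize_windows(windows: Sequence[DNASequence], recipe: FeatureRecipe) -> pd.DataFrame:
    rows = [recipe.featurize(w).values for w in windows]
    return pd.DataFrame(
        np.asarray(rows), index=[w.id for w in windows], columns=recipe.feature_names()
    )


def call_candidates(
    result: ScanResult, threshold: float = SCORE_THRESHOLD
) -> list[tuple[GenomicInterval, float]]:
    """Windows with score strictly greater than ``threshold`` (0.5 default)."""
    out = []
    for start, score in zip(result.window_starts, result.scores):
        if score > threshold:
            out.append(
                (
                    GenomicInterval(
                        result.chrom, int(start), int(start) + result.window_len,
                        score=float(score),
                    ),
                    float(score),
                )
            )
    return out


def merge_candidates(
    candidates: Sequence[tuple[GenomicInterval, float]],
    max_gap: int = 0,
) -> list[PredictedEnhancer]:
    """Merge overlapping (or gap <= max_gap) candidate windows.

    Each merged run becomes one predicted enhancer whose peak score is the
    maximum member score.  Input must be sorted by start position.
    """
    if not candidates:
        return []
    starts = [iv.start for iv, _ in candidates]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("candidates must be sorted by start")
    merged: list[PredictedEnhancer] = []
    cur_chrom = candidates[0][0].chrom
    cur_start, cur_end = candidates[0][0].start, candidates[0][0].end
    cur_peak, cur_n = candidates[0][1], 1
    for iv, score in candidates[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end + max_gap:
            cur_end = max(cur_end, iv.end)
            cur_peak = max(cur_peak, score)
            cur_n += 1
        else:
            merged.append(
                PredictedEnhancer(
                    GenomicInterval(cur_chrom, cur_start, cur_end, score=cur_peak),
                    cur_peak, cur_n,
                )
            )
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_peak, cur_n = score, 1
    merged.append(
        PredictedEnhancer(
            GenomicInterval(cur_chrom, cur_start, cur_end, score=cur_peak),
            cur_peak, cur_n,
        )
    )
    return merged


def export_for_macs2(result: ScanResult, path: str | Path,
                     threshold: float = SCORE_THRESHOLD) -> int:
    """Write candidate windows as scored BED suitable as peak-caller input.

    Returns the number of lines written; byte output is deterministic for
    a fixed input.
    """
    candidates = call_candidates(result, threshold)
    with open(path, "w") as fh:
        for k, (iv, score) in enumerate(candidates):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcand_{k + 1}\t{round(score, 6):g}\n"
            )
    return len(candidates)


def write_scores_bedgraph(result: ScanResult, path: str | Path) -> None:
    """Per-window scores as bedGraph lines (one per scored window)."""
    with open(path, "w") as fh:
        for start, score in zip(result.window_starts, result.scores):
            fh.write(
                f"{result.chrom}\t{int(start)}\t{int(start) + result.window_len}\t"
                f"{round(float(score), 6):g}\n"
            )


def overlap_fraction(
    predicted: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
) -> float:
    """Fraction of reference intervals overlapping >= 1 predicted interval by >= 1 bp."""
    if not reference:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in predicted:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
    hit = 0
    for ref in reference:
        spans = by_chrom.get(ref.chrom, [])
        # linear scan is fine at the scales handled here
        if any(s < ref.end and ref.start < e for s, e in spans):
            hit += 1
    return hit / len(reference)
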