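"""Sequence and interval I/O.

Reads FASTA into validated :class:`DNASequence` records, standardizes
sequences to a fixed analysis length, and writes genomic intervals as BED
or bedGraph.  Coordinates are 0-based half-open everywhere internally and
on output; FASTA headers of the UCSC form ``chrom:start-end`` (1-based,
inclusive) are converted on parse.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the four-letter DNA alphabet all complexity functions are defined over
ALPHABET = "ACGT"

_VALID_PARSE = set("ACGTNacgtn")
_UCSC_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Sequence contains characters outside the accepted alphabet."""


class UnsupportedExpansionError(ValueError):
    """Expansion to a longer length requested without a reference source."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally scored."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class DNASequence:
    """A validated word over {A,C,G,T} (N tolerated at parse time).

    ``source_interval`` when present is ``(chrom, start, end)`` in 0-based
    half-open convention with ``end - start == len(bases)``.
    """

    id: str
    bases: str
    source_interval: Optional[tuple[str, int, int]] = field(default=None)

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.source_interval is not None:
            chrom, start, end = self.source_interval
            if start < 0 or end <= start:
                raise ValueError(
                    f"record {self.id!r}: bad interval {chrom}:{start}-{end}"
                )
            if end - start != len(self.bases):
                raise ValueError(
                    f"record {self.id!r}: interval span {end - start} != "
                    f"sequence length {len(self.bases)}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def has_ambiguous(self) -> bool:
        """True when the sequence contains one or more 'N' bases."""
        return "N" in self.bases


def _interval_from_header(header: str) -> Optional[tuple[str, int, int]]:
    m = _UCSC_RE.match(header)
    if m is None:
        return None
    # UCSC 1-based inclusive -> 0-based half-open
    start = int(m.group("start")) - 1
    end = int(m.group("end"))
    if start < 0 or end <= start:
        return None
    return (m.group("chrom"), start, end)


def read_fasta(path: str | Path) -> list[DNASequence]:
    """Read a FASTA file into a list of :class:`DNASequence`.

    Record ids are the header up to the first whitespace; bases are
    uppercased.  Characters outside ``{A,C,G,T,N}`` (either case) raise
    :class:`SequenceValidationError` naming the record; a non-header first
    line raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line.strip()[:30]!r}"
                )
            break
    out: list[DNASequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        bad = set(raw) - _VALID_PARSE
        if bad:
            raise SequenceValidationError(
                f"record {rec.id!r}: invalid characters {sorted(bad)}"
            )
        bases = raw.upper()
        interval = _interval_from_header(rec.id)
        if interval is not None and interval[2] - interval[1] != len(bases):
            interval = None  # header coordinates disagree with the sequence
        out.append(DNASequence(id=rec.id, bases=bases, source_interval=interval))
    return out


def write_fasta(seqs: Iterable[DNASequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA (fixed line width, deterministic bytes)."""
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(str(rec.seq[i : i + width]) + "\n")


# A reference accessor maps (chrom, start, end) -> bases; pyfaidx.Fasta can be
# adapted with `lambda c, s, e: str(genome[c][s:e])`.
ReferenceAccessor = Callable[[str, int, int], str]


def standardize_length(
    seq: DNASequence,
    target_len: int,
    reference: Optional[ReferenceAccessor] = None,
) -> DNASequence:
    """Truncate or expand a sequence to ``target_len``, centered on its midpoint.

    Truncation removes an equal number of bases from each end; when the
    amount is odd the extra base comes off the 3' end.  Expansion requires
    both genomic coordinates on the sequence and a ``reference`` accessor
    for the flanking bases; otherwise :class:`UnsupportedExpansionError`.
    """
    if target_len < 1:
        raise ValueError(f"target_len must be >= 1, got {target_len}")
    n = len(seq)
    if n == target_len:
        return seq
    if n > target_len:
        trim = n - target_len
        left = trim // 2  # odd remainder comes off the 3' end
        start = left
        bases = seq.bases[start : start + target_len]
        interval = None
        if seq.source_interval is not None:
            chrom, s0, _ = seq.source_interval
            interval = (chrom, s0 + start, s0 + start + target_len)
        return DNASequence(id=seq.id, bases=bases, source_interval=interval)
    # expansion
    if reference is None or seq.source_interval is None:
        raise UnsupportedExpansionError(
            f"record {seq.id!r}: expansion from {n} to {target_len} bp needs "
            "genomic coordinates and a reference accessor"
        )
    grow = target_len - n
    left = grow // 2
    right = grow - left
    chrom, s0, e0 = seq.source_interval
    if s0 - left < 0:
        # clamp at the chromosome start, take the deficit from the right
        right += left - s0
        left = s0
    flank5 = reference(chrom, s0 - left, s0).upper()
    flank3 = reference(chrom, e0, e0 + right).upper()
    bases = flank5 + seq.bases + flank3
    if len(bases) != target_len:
        raise UnsupportedExpansionError(
            f"record {seq.id!r}: reference returned {len(bases)} bp, "
            f"expected {target_len} (near a contig end?)"
        )
    return DNASequence(
        id=seq.id,
        bases=bases,
        source_interval=(chrom, s0 - left, e0 + right),
    )


def write_intervals(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    format: str = "BED",
) -> None:
    """Write intervals as BED (chrom/start/end[/name/score]) or bedGraph.

    Input is sorted by (chrom, start); bedGraph requires a score on every
    interval.  Coordinates are written as exact integers.
    """
    fmt = format.lower()
    if fmt not in ("bed", "bedgraph"):
        raise ValueError(f"unknown interval format {format!r}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for k, iv in enumerate(ivs):
            if fmt == "bedgraph":
                if iv.score is None:
                    raise ValueError(
                        f"bedGraph requires a score on every interval "
                        f"({iv.chrom}:{iv.start}-{iv.end} has none)"
                    )
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt_score(iv.score)}\n")
            else:
                if iv.score is None:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                else:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                        f"region_{k + 1}\t{_fmt_score(iv.score)}\n"
                    )


def _fmt_score(x: float) -> str:
    return repr(round(float(x), 6))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(bases: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return bases.translate(_COMPLEMENT)[::-1]


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of ``id<TAB>label`` with labels in {0,1}."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>0|1'")
            labels[parts[0]] = int(parts[1])
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{int(lab)}\n")
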