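"""Circular reference genome, named regions, and circular-coordinate arithmetic.

All coordinates are 1-based inclusive, following mitochondrial community
numbering (human rCRS, L = 16 569 bp).  An interval with ``start > end`` is an
origin-spanning arc (e.g. the D-loop, 16030-570) and is kept as a single
record; it is never split.  File formats that use 0-based half-open
coordinates (BED) are converted at the I/O boundary, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

HUMAN_MTDNA_LENGTH = 16569
_ALPHABET = frozenset("ACGTN")


class CoordinateError(ValueError):
    """A position or interval lies outside the bound circular genome."""


def check_position(p: int, length: int) -> int:
    if not 1 <= int(p) <= length:
        raise CoordinateError(f"position {p} outside circular genome of length {length}")
    return int(p)


def circ_distance(a: int, b: int, length: int) -> int:
    """Minimal arc distance between two positions on the circle.

    Symmetric, at most ``length // 2``.
    """
    check_position(a, length)
    check_position(b, length)
    forward = (b - a) % length
    return min(forward, length - forward)


def rotate_coordinates(p: int, shift: int, length: int) -> int:
    """Rotate position ``p`` clockwise by ``shift`` bases (bijective for fixed shift)."""
    check_position(p, length)
    return (p - 1 + shift) % length + 1


def arc_length(start: int, end: int, length: int) -> int:
    """Number of positions on the clockwise arc start..end, both inclusive."""
    check_position(start, length)
    check_position(end, length)
    return (end - start) % length + 1


def interval_contains(start: int, end: int, p: int, length: int) -> bool:
    """True iff ``p`` lies on the clockwise arc start..end (inclusive).

    Origin-spanning arcs (start > end) contain p iff p >= start or p <= end.
    """
    check_position(p, length)
    check_position(start, length)
    check_position(end, length)
    if start <= end:
        return start <= p <= end
    return p >= start or p <= end


def arcs_overlap(a_start: int, a_end: int, b_start: int, b_end: int, length: int) -> bool:
    """True iff the two clockwise arcs share at least one position."""
    return interval_contains(a_start, a_end, b_start, length) or interval_contains(
        b_start, b_end, a_start, length
    )


def arc_gap(a_start: int, a_end: int, b_start: int, b_end: int, length: int) -> int:
    """Minimal circular gap between two arcs: the positional distance between
    their nearest members (adjacent arcs have gap 1); 0 when they overlap."""
    if arcs_overlap(a_start, a_end, b_start, b_end, length):
        return 0
    return min((b_start - a_end) % length, (a_start - b_end) % length)


@dataclass(frozen=True)
class CircularInterval:
    """1-based inclusive arc on the circle; start > end spans the origin."""

    start: int
    end: int
    label: str = ""

    def validate(self, length: int) -> "CircularInterval":
        check_position(self.start, length)
        check_position(self.end, length)
        return self

    def contains(self, p: int, length: int) -> bool:
        return interval_contains(self.start, self.end, p, length)

    def length(self, genome_length: int) -> int:
        return arc_length(self.start, self.end, genome_length)

    def spans_origin(self) -> bool:
        return self.start > self.end

    def rotated(self, shift: int, length: int) -> "CircularInterval":
        return replace(
            self,
            start=rotate_coordinates(self.start, shift, length),
            end=rotate_coordinates(self.end, shift, length),
        )


@dataclass
class CircularGenome:
    """A circular nucleotide genome; the sequence is optional.

    End profiling needs only the length; motif scanning and fragment-sequence
    export need the sequence.
    """

    name: str = "mtDNA"
    length: int = HUMAN_MTDNA_LENGTH
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"length {self.length} != |sequence| = {len(self.sequence)}"
                )
            bad = set(self.sequence) - _ALPHABET
            if bad:
                raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        if self.length <= 0:
            raise ValueError("genome length must be positive")

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "CircularGenome":
        record = next(SeqIO.parse(str(path), "fasta"))
        seq = str(record.seq).upper()
        return cls(name=name or record.id, length=len(seq), sequence=seq)

    def base(self, p: int) -> str:
        if self.sequence is None:
            raise ValueError("genome carries no sequence")
        return self.sequence[check_position(p, self.length) - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Clockwise arc sequence start..end inclusive, wrapping the origin if needed."""
        if self.sequence is None:
            raise ValueError("genome carries no sequence")
        check_position(start, self.length)
        check_position(end, self.length)
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass
class RegionSet:
    """Named circular intervals bound to one genome length; labels unique."""

    genome_length: int
    intervals: list[CircularInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [iv.label for iv in self.intervals]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")
        for iv in self.intervals:
            iv.validate(self.genome_length)

    def __iter__(self) -> Iterator[CircularInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, label: str) -> CircularInterval:
        for iv in self.intervals:
            if iv.label == label:
                return iv
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    def subset(self, labels: Iterable[str]) -> "RegionSet":
        wanted = set(labels)
        return RegionSet(
            self.genome_length, [iv for iv in self.intervals if iv.label in wanted]
        )

    def overlapping(self, start: int, end: int) -> list[str]:
        """Labels of regions whose arc overlaps the query arc."""
        return [
            iv.label
            for iv in self.intervals
            if arcs_overlap(iv.start, iv.end, start, end, self.genome_length)
        ]

    def rotated(self, shift: int) -> "RegionSet":
        return RegionSet(
            self.genome_length,
            [iv.rotated(shift, self.genome_length) for iv in self.intervals],
        )

    @classmethod
    def from_tsv(cls, path: str | Path, genome_length: int) -> "RegionSet":
        """Read a region table: columns label, start, end (1-based inclusive).

        Lines starting with '#' are comments; a header line naming the three
        columns is expected.
        """
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"label", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"region table must have columns {sorted(required)}")
        ivs = [
            CircularInterval(int(r.start), int(r.end), str(r.label))
            for r in df.itertuples()
        ]
        return cls(genome_length, ivs)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "label": [iv.label for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def human_mtdna_regions(length: int = HUMAN_MTDNA_LENGTH) -> RegionSet:
    """Canonical human mtDNA annotation used throughout the analysis.

    D-loop spans the origin (16030-570); oriL 5770-5820; the EagI exclusion
    window 2550-2585 flanks the single-cutter site used for linearization.
    oriH and TAS use standard rCRS coordinates.
    """
    return RegionSet(
        length,
        [
            CircularInterval(16030, 570, "D-loop"),
            CircularInterval(110, 441, "oriH"),
            CircularInterval(5770, 5820, "oriL"),
            CircularInterval(16157, 16172, "TAS"),
            CircularInterval(2550, 2585, "EagI_exclusion"),
        ],
    )
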