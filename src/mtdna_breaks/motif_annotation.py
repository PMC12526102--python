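"""Sequence context of called hotspots: GC stretches and G-quadruplex motifs.

SSB clusters in the data sit on long GC stretches with G-quadruplex-forming
potential, so every call is annotated with the circular distance to the
nearest GC run and G4 motif on either strand.  The G4 rule is the standard
four-tract pattern G{3,}(N1-7 G{3,}){3} (Quadparser-style); alternative rules
can be passed as a compiled regex.  Circular wrap is handled by scanning the
doubled sequence and deduplicating.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import CircularGenome, arc_gap, rotate_coordinates
from .break_calling import HotspotCall

G4_PATTERN = re.compile(r"G{3,}(?:[ACGTN]{1,7}?G{3,}){3}")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GCStretch:
    """Maximal circular run of G/C bases, 1-based inclusive coordinates."""

    start: int
    end: int
    length: int
    sequence: str


@dataclass(frozen=True)
class G4Motif:
    """G-quadruplex motif in heavy-strand coordinates; strand records which
    strand carries the G-tracts."""

    start: int
    end: int
    strand: str  # "heavy" or "light"
    pattern: str


def find_gc_stretches(genome: CircularGenome, min_run: int = 6) -> list[GCStretch]:
    """Maximal runs of {G, C} of length >= min_run, including origin-spanning
    runs; maximality makes the output non-overlapping."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    L = genome.length
    mask = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    is_gc = (mask == ord("G")) | (mask == ord("C"))
    if is_gc.all():
        if L >= min_run:
            return [GCStretch(1, L, L, genome.sequence)]
        return []
    doubled = np.concatenate([is_gc, is_gc])
    stretches: list[GCStretch] = []
    i = 0
    while i < 2 * L:
        if not doubled[i]:
            i += 1
            continue
        j = i
        while j < 2 * L and doubled[j]:
            j += 1
        run = j - i
        # keep runs starting in the first copy; a run starting at 0 is the
        # circular continuation of a wrapping run iff the last base is GC
        if i < L and run >= min_run and not (i == 0 and is_gc[L - 1]):
            start = i + 1
            end = (i + run - 1) % L + 1
            stretches.append(GCStretch(start, end, run, genome.subsequence(start, end)))
        i = j
    return stretches


def _dedupe(motifs: list[G4Motif]) -> list[G4Motif]:
    seen: set[tuple[int, int, str]] = set()
    out = []
    for m in sorted(motifs, key=lambda m: (m.start, m.end, m.strand)):
        key = (m.start, m.end, m.strand)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def find_g4_motifs(
    genome: CircularGenome, pattern: re.Pattern[str] = G4_PATTERN
) -> list[G4Motif]:
    """Four-tract G4 motifs on both strands, reported in heavy-strand 1-based
    coordinates.  Origin-spanning matches are found on the doubled sequence;
    non-overlapping matches per strand (left-to-right scan)."""
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    L = genome.length
    motifs: list[G4Motif] = []

    doubled = genome.sequence + genome.sequence
    for m in pattern.finditer(doubled):
        if m.start() >= L or (m.end() - m.start()) > L:
            continue
        start = m.start() + 1
        end = (m.end() - 1) % L + 1
        motifs.append(G4Motif(start, end, "heavy", m.group()))

    rc = reverse_complement(genome.sequence)
    for m in pattern.finditer(rc + rc):
        if m.start() >= L or (m.end() - m.start()) > L:
            continue
        # rc index j (0-based, mod L) maps to heavy-strand index L-1-j
        start = (L - 1 - (m.end() - 1) % L) % L + 1
        end = (L - 1 - m.start() % L) % L + 1
        motifs.append(G4Motif(start, end, "light", m.group()))
    return _dedupe(motifs)


def _near(
    call: HotspotCall, start: int, end: int, flank: int, length: int
) -> bool:
    return arc_gap(call.bin_start, call.bin_end, start, end, length) <= flank


def annotate_hotspots(
    calls: Sequence[HotspotCall],
    stretches: Sequence[GCStretch],
    motifs: Sequence[G4Motif],
    genome_length: int,
    flank: int = 100,
) -> list[HotspotCall]:
    """Set gc_within_flank / g4_within_flank per call using circular distance
    from the bin interval to the nearest feature.  Idempotent."""
    for c in calls:
        c.gc_within_flank = any(
            _near(c, s.start, s.end, flank, genome_length) for s in stretches
        )
        c.g4_within_flank = any(
            _near(c, m.start, m.end, flank, genome_length) for m in motifs
        )
    return list(calls)


def rotate_motifs(
    motifs: Sequence[G4Motif], shift: int, length: int
) -> list[G4Motif]:
    return [
        replace(
            m,
            start=rotate_coordinates(m.start, shift, length),
            end=rotate_coordinates(m.end, shift, length),
        )
        for m in motifs
    ]


@dataclass
class AssociationResult:
    observed: int
    null_mean: float
    p_value: float
    n_rotations: int


def rotation_association_test(
    calls: Sequence[HotspotCall],
    features: Sequence[GCStretch] | Sequence[G4Motif],
    genome_length: int,
    flank: int = 100,
    n_rotations: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Permutation test of call/motif co-localization under circular rotation.

    The null preserves the feature set's internal clustering by rotating all
    features by one uniform offset per permutation.  The add-one estimator
    p = (1 + #{null >= observed}) / (1 + n) is never zero.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    if not calls or not features:
        raise ValueError("need at least one call and one feature")
    arcs = [(f.start, f.end) for f in features]

    def overlap_count(offset: int) -> int:
        return sum(
            1
            for c in calls
            if any(
                _near(
                    c,
                    rotate_coordinates(s, offset, genome_length),
                    rotate_coordinates(e, offset, genome_length),
                    flank,
                    genome_length,
                )
                for s, e in arcs
            )
        )

    observed = overlap_count(0)
    rng = np.random.default_rng(seed)
    null = np.array(
        [overlap_count(int(r)) for r in rng.integers(1, genome_length, n_rotations)]
    )
    p = (1 + int((null >= observed).sum())) / (1 + n_rotations)
    return AssociationResult(
        observed=observed,
        null_mean=float(null.mean()),
        p_value=p,
        n_rotations=n_rotations,
    )


def stretches_to_frame(stretches: Sequence[GCStretch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [s.start for s in stretches],
            "end": [s.end for s in stretches],
            "length": [s.length for s in stretches],
            "sequence": [s.sequence for s in stretches],
        }
    )


def motifs_to_frame(motifs: Sequence[G4Motif]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [m.start for m in motifs],
            "end": [m.end for m in motifs],
            "strand": [m.strand for m in motifs],
            "pattern": [m.pattern for m in motifs],
        }
    )
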