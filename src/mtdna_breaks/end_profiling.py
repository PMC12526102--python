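"""Binned, depth-normalized fragment-end profiles on the circular genome.

Fragment upstream/downstream ends are tallied into fixed-width bins (40 nt by
default), after excluding ends inside the linearization-artifact window
around the single-cutter site.  Bins are anchored at position 1; bin k
(1-based) covers positions (k-1)*w+1 .. k*w, and the final bin may be short
(9 nt for L = 16 569, w = 40) — it is kept, never merged.  Profiles are
normalized to mean sequencing depth = (sum of fragment lengths) / L, computed
from retained (post-size-selection) mitochondrial fragments.

Nuclear background fragments never contribute ends; they exist for the
length-bias normalization, which reweights libraries to the nuclear fragment
size distribution of the reference library (the one with the highest
proportion of large fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import CircularInterval, CoordinateError, check_position
from .synthetic_data import FragmentRecord


class NormalizationError(ValueError):
    pass


@dataclass
class EndTable:
    """Per-library mitochondrial fragment-end positions, with exclusion counts."""

    genome_length: int
    upstream: list[int] = field(default_factory=list)
    downstream: list[int] = field(default_factory=list)
    excluded_upstream: int = 0
    excluded_downstream: int = 0
    label: str = ""
    s1_treated: bool = False

    @property
    def excluded(self) -> int:
        return self.excluded_upstream + self.excluded_downstream


@dataclass
class BinnedEndProfile:
    """Per-bin upstream/downstream end values for one library."""

    genome_length: int
    bin_width: int
    upstream: np.ndarray
    downstream: np.ndarray
    normalized: str = "raw_counts"  # or "per_depth"
    label: str = ""

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.genome_length / self.bin_width))

    def bin_of(self, p: int) -> int:
        """0-based bin index containing 1-based position p."""
        check_position(p, self.genome_length)
        return (p - 1) // self.bin_width

    def bin_bounds(self, k: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of 0-based bin k; last bin clipped at L."""
        if not 0 <= k < self.n_bins:
            raise IndexError(f"bin {k} outside 0..{self.n_bins - 1}")
        start = k * self.bin_width + 1
        end = min((k + 1) * self.bin_width, self.genome_length)
        return start, end

    def values(self, end_class: str) -> np.ndarray:
        if end_class == "upstream":
            return self.upstream
        if end_class == "downstream":
            return self.downstream
        raise ValueError(f"unknown end class {end_class!r}")


def extract_ends(
    frags: Sequence[FragmentRecord],
    genome_length: int,
    exclusion: CircularInterval | None = None,
    label: str = "",
    s1_treated: bool = False,
) -> EndTable:
    """Collect mito fragment ends, dropping (and counting) ends inside the
    artifact exclusion window.  Nuclear records are ignored."""
    table = EndTable(genome_length=genome_length, label=label, s1_treated=s1_treated)
    for f in frags:
        if f.compartment != "mito":
            continue
        up = check_position(f.upstream_end, genome_length)
        down = check_position(f.downstream_end, genome_length)
        if exclusion is not None and exclusion.contains(up, genome_length):
            table.excluded_upstream += 1
        else:
            table.upstream.append(up)
        if exclusion is not None and exclusion.contains(down, genome_length):
            table.excluded_downstream += 1
        else:
            table.downstream.append(down)
    return table


def bin_ends(table: EndTable, bin_width: int = 40) -> BinnedEndProfile:
    """Tally end positions into fixed-width bins; each end lands in exactly one
    bin, so the per-class bin sums equal the retained end counts."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    L = table.genome_length
    n_bins = int(np.ceil(L / bin_width))

    def tally(positions: list[int]) -> np.ndarray:
        arr = np.asarray(positions, dtype=np.int64)
        if arr.size and (arr.min() < 1 or arr.max() > L):
            raise CoordinateError("end position outside genome")
        idx = (arr - 1) // bin_width
        return np.bincount(idx, minlength=n_bins).astype(float)

    return BinnedEndProfile(
        genome_length=L,
        bin_width=bin_width,
        upstream=tally(table.upstream),
        downstream=tally(table.downstream),
        normalized="raw_counts",
        label=table.label,
    )


def mean_depth(frags: Sequence[FragmentRecord], genome_length: int) -> float:
    """Average sequencing depth from retained mito fragments: sum(lengths)/L."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return sum(f.length for f in frags if f.compartment == "mito") / genome_length


def normalize_to_depth(profile: BinnedEndProfile, depth: float) -> BinnedEndProfile:
    """End frequencies normalized to average sequencing depth."""
    if depth <= 0:
        raise NormalizationError(f"depth must be positive, got {depth}")
    if profile.normalized != "raw_counts":
        raise NormalizationError("profile is already normalized")
    return replace(
        profile,
        upstream=profile.upstream / depth,
        downstream=profile.downstream / depth,
        normalized="per_depth",
    )


# ---------------------------------------------------------------------------
# Fragment size distributions and length-bias normalization


def default_size_edges(max_bp: int = 20000, step: int = 500) -> np.ndarray:
    """Left edges of the size classes: [0, step, ..., max_bp]; the last class
    is the overflow >= max_bp."""
    return np.arange(0, max_bp + step, step, dtype=np.int64)


@dataclass
class SizeDistribution:
    """Fragment-length class proportions; class i spans [edges[i], edges[i+1]),
    the final class is open-ended."""

    edges: np.ndarray
    proportions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.edges.size != self.proportions.size:
            raise ValueError("one proportion per class (edges are left edges)")
        if self.proportions.size and abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    @classmethod
    def from_lengths(
        cls,
        lengths: Sequence[int],
        edges: np.ndarray | None = None,
        label: str = "",
    ) -> "SizeDistribution":
        edges = default_size_edges() if edges is None else np.asarray(edges, dtype=np.int64)
        arr = np.asarray(lengths, dtype=np.int64)
        if arr.size == 0:
            raise ValueError("cannot build a size distribution from zero fragments")
        idx = np.clip(np.searchsorted(edges, arr, side="right") - 1, 0, edges.size - 1)
        counts = np.bincount(idx, minlength=edges.size).astype(float)
        return cls(edges=edges, proportions=counts / counts.sum(), label=label)

    @classmethod
    def from_fragments(
        cls,
        frags: Sequence[FragmentRecord],
        compartment: str = "nuclear",
        edges: np.ndarray | None = None,
        label: str = "",
    ) -> "SizeDistribution":
        return cls.from_lengths(
            [f.length for f in frags if f.compartment == compartment], edges, label
        )

    def class_of(self, length_bp: int) -> int:
        return int(np.clip(np.searchsorted(self.edges, length_bp, side="right") - 1, 0, self.edges.size - 1))


def _check_edges(a: SizeDistribution, b: SizeDistribution) -> None:
    if a.edges.size != b.edges.size or not np.array_equal(a.edges, b.edges):
        raise ValueError("size-class edges do not match")


def length_bias_weights(
    sample: SizeDistribution, reference: SizeDistribution
) -> tuple[np.ndarray, list[int]]:
    """Per-class weights mapping the sample's nuclear size distribution onto
    the reference's: weight = reference proportion / sample proportion.

    Classes with zero sample mass get weight 0 and are reported (second
    return value) so the caller can log the degenerate classes.
    """
    _check_edges(sample, reference)
    weights = np.zeros_like(sample.proportions)
    degenerate: list[int] = []
    nonzero = sample.proportions > 0
    weights[nonzero] = reference.proportions[nonzero] / sample.proportions[nonzero]
    for i in np.nonzero(~nonzero)[0]:
        if reference.proportions[i] > 0:
            degenerate.append(int(i))
    return weights, degenerate


def select_reference_library(
    libraries: Sequence[SizeDistribution], large_threshold: int = 10000
) -> int:
    """Index of the library with the highest proportion of large fragments
    (classes whose lower edge >= threshold); ties broken by lowest index."""
    if not libraries:
        raise ValueError("no libraries supplied")
    best_idx, best_mass = 0, -1.0
    for i, lib in enumerate(libraries):
        mass = float(lib.proportions[lib.edges >= large_threshold].sum())
        if mass > best_mass + 1e-12:
            best_idx, best_mass = i, mass
    return best_idx


@dataclass
class DivergenceSummary:
    per_class_difference: np.ndarray  # a - b
    total_variation: float
    full_length_difference: float
    full_length_class: int


def compare_size_distributions(
    a: SizeDistribution, b: SizeDistribution, full_length_bp: int = 16569
) -> DivergenceSummary:
    """Per-class proportion differences (a - b), the difference in the class
    holding full-length molecules, and total variation distance 0.5*sum|d|."""
    _check_edges(a, b)
    diff = a.proportions - b.proportions
    k = a.class_of(full_length_bp)
    return DivergenceSummary(
        per_class_difference=diff,
        total_variation=0.5 * float(np.abs(diff).sum()),
        full_length_difference=float(diff[k]),
        full_length_class=k,
    )


# ---------------------------------------------------------------------------
# I/O


def read_fragments_bed(path: str | Path, genome_length: int) -> list[FragmentRecord]:
    """Read fragments from BED (0-based half-open chromStart/chromEnd).

    Columns: chrom, chromStart, chromEnd, then optionally compartment and an
    origin-spanning flag (0/1).  Conversion: upstream_end = chromStart + 1,
    downstream_end = chromEnd; flagged rows may have chromStart + 1 >
    chromEnd, denoting a fragment wrapping the origin, with length
    L - chromStart + chromEnd.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValueError("BED input needs at least 3 columns")
    frags: list[FragmentRecord] = []
    for r in df.itertuples(index=False):
        row = tuple(r)
        compartment = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else "mito"
        spanning = bool(int(row[4])) if len(row) > 4 and not pd.isna(row[4]) else False
        start0, end = int(row[1]), int(row[2])
        if compartment == "nuclear":
            frags.append(FragmentRecord(None, None, end - start0, "nuclear"))
            continue
        up = start0 + 1
        down = end
        check_position(up, genome_length)
        check_position(down, genome_length)
        if not spanning and up > down:
            raise ValueError(f"BED record {row[:3]} inverted without origin-spanning flag")
        length = (down - up) % genome_length + 1
        frags.append(FragmentRecord(up, down, length, "mito", up > down))
    return frags


def profile_to_frame(profile: BinnedEndProfile) -> pd.DataFrame:
    bounds = [profile.bin_bounds(k) for k in range(profile.n_bins)]
    return pd.DataFrame(
        {
            "bin": np.arange(1, profile.n_bins + 1),
            "bin_start": [b[0] for b in bounds],
            "bin_end": [b[1] for b in bounds],
            "upstream": profile.upstream,
            "downstream": profile.downstream,
        }
    )


def write_profile_tsv(
    profile: BinnedEndProfile, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        profile_to_frame(profile).to_csv(fh, sep="\t", index=False)


def read_profile_tsv(
    path: str | Path, genome_length: int, normalized: str = "per_depth"
) -> BinnedEndProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    width = int(df.bin_end.iloc[0] - df.bin_start.iloc[0] + 1)
    return BinnedEndProfile(
        genome_length=genome_length,
        bin_width=width,
        upstream=df.upstream.to_numpy(dtype=float),
        downstream=df.downstream.to_numpy(dtype=float),
        normalized=normalized,
    )
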