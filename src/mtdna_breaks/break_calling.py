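"""Differential SSB/DSB inference and background-subtracted hotspot ranking.

Native libraries expose only double-strand breaks; S1-treated libraries
expose the sum of SSBs and DSBs (S1 converts nicks and gaps into DSBs).  The
per-bin SSB frequency is therefore the clamped difference S1 - native.
Hotspots are ranked by residuals against a circular running-median
background; ranking (not profile computation) excludes bins overlapping
configured regions (D-loop 16030-570, oriL 5770-5820 by default, mirroring
how replication intermediates are set aside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .end_profiling import BinnedEndProfile, EndTable
from .genome_model import RegionSet, check_position

#: Degradation stalling sites queried by default (position, end class).
DEFAULT_STALLING_SITES: tuple[tuple[int, str], ...] = (
    (3210, "upstream"),
    (5736, "upstream"),
    (5969, "upstream"),
    (9921, "downstream"),
    (14249, "downstream"),
)


@dataclass
class SSBProfile:
    """Per-bin SSB frequency = max(0, S1 - native), with clamp diagnostics."""

    genome_length: int
    bin_width: int
    upstream: np.ndarray
    downstream: np.ndarray
    clamped_upstream_bins: int = 0
    clamped_downstream_bins: int = 0
    clamped_mass: float = 0.0

    def values(self, end_class: str) -> np.ndarray:
        return {"upstream": self.upstream, "downstream": self.downstream}[end_class]


@dataclass
class ResidualProfile:
    """Profile minus circular running-median background, per end class."""

    genome_length: int
    bin_width: int
    upstream: np.ndarray
    downstream: np.ndarray
    window_halfwidth: int = 25

    @property
    def n_bins(self) -> int:
        return self.upstream.size

    def values(self, end_class: str) -> np.ndarray:
        return {"upstream": self.upstream, "downstream": self.downstream}[end_class]


@dataclass
class HotspotCall:
    bin_index: int  # 0-based
    bin_start: int  # 1-based inclusive
    bin_end: int
    end_class: str
    residual: float
    rank: int
    break_class: str | None = None  # SSB / DSB / mixed
    region_labels: list[str] = field(default_factory=list)
    gc_within_flank: bool | None = None
    g4_within_flank: bool | None = None


def _require_per_depth(profile: BinnedEndProfile) -> None:
    if profile.normalized != "per_depth":
        raise ValueError("profile must be depth-normalized first")


def ssb_differential(s1: BinnedEndProfile, native: BinnedEndProfile) -> SSBProfile:
    """Clamped per-bin difference of depth-normalized S1 and native profiles.

    Negative raw differences (sampling noise: S1 ends are a superset of
    native ends in expectation) are clamped to zero and counted.
    """
    _require_per_depth(s1)
    _require_per_depth(native)
    if s1.bin_width != native.bin_width or s1.genome_length != native.genome_length:
        raise ValueError("S1 and native profiles use different binning")
    diff_up = s1.upstream - native.upstream
    diff_down = s1.downstream - native.downstream
    return SSBProfile(
        genome_length=s1.genome_length,
        bin_width=s1.bin_width,
        upstream=np.maximum(diff_up, 0.0),
        downstream=np.maximum(diff_down, 0.0),
        clamped_upstream_bins=int((diff_up < 0).sum()),
        clamped_downstream_bins=int((diff_down < 0).sum()),
        clamped_mass=float(-diff_up[diff_up < 0].sum() - diff_down[diff_down < 0].sum()),
    )


def circular_running_median(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Median over the wrapped window [k-w, k+w] for every bin k."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if not 1 <= halfwidth <= n // 2:
        raise ValueError(f"window halfwidth {halfwidth} outside 1..{n // 2}")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    return np.median(values[idx], axis=1)


def background_subtract(
    profile: BinnedEndProfile | SSBProfile, window_halfwidth: int = 25
) -> ResidualProfile:
    """Residuals against a circular running-median local background.

    The median window wraps around the origin; adding a constant to the
    profile leaves the residuals unchanged (location invariance).
    """
    return ResidualProfile(
        genome_length=profile.genome_length,
        bin_width=profile.bin_width,
        upstream=np.asarray(profile.upstream, float)
        - circular_running_median(profile.upstream, window_halfwidth),
        downstream=np.asarray(profile.downstream, float)
        - circular_running_median(profile.downstream, window_halfwidth),
        window_halfwidth=window_halfwidth,
    )


def _bin_bounds(k: int, bin_width: int, length: int) -> tuple[int, int]:
    return k * bin_width + 1, min((k + 1) * bin_width, length)


def rank_top_bins(
    res: ResidualProfile,
    end_class: str,
    exclude: RegionSet | None = None,
    n_top: int = 15,
) -> list[HotspotCall]:
    """Top-n bins by residual, after removing bins overlapping excluded regions.

    Sorted by residual descending; ties broken by lower bin index, so output
    is deterministic and invariant under positive rescaling of the residuals.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    values = res.values(end_class)
    L = res.genome_length
    calls: list[HotspotCall] = []
    eligible: list[tuple[float, int]] = []
    for k in range(values.size):
        start, end = _bin_bounds(k, res.bin_width, L)
        if exclude is not None and exclude.overlapping(start, end):
            continue
        eligible.append((-float(values[k]), k))
    eligible.sort()
    for rank, (neg, k) in enumerate(eligible[:n_top], start=1):
        start, end = _bin_bounds(k, res.bin_width, L)
        calls.append(
            HotspotCall(
                bin_index=k,
                bin_start=start,
                bin_end=end,
                end_class=end_class,
                residual=-neg,
                rank=rank,
            )
        )
    return calls


def classify_calls(
    calls: Sequence[HotspotCall],
    ssb: SSBProfile | None,
    native_residual: ResidualProfile | None,
    noise_floor: float = 0.0,
) -> list[HotspotCall]:
    """Assign SSB / DSB / mixed classes from the differential and native signals.

    A call is SSB-supported when the clamped S1-native difference at its bin
    exceeds the noise floor, DSB-supported when the native residual does; both
    -> 'mixed', neither -> left None.
    """
    out = []
    for c in calls:
        s = float(ssb.values(c.end_class)[c.bin_index]) if ssb is not None else 0.0
        d = (
            float(native_residual.values(c.end_class)[c.bin_index])
            if native_residual is not None
            else 0.0
        )
        is_ssb = s > noise_floor
        is_dsb = d > noise_floor
        c.break_class = "mixed" if (is_ssb and is_dsb) else "SSB" if is_ssb else "DSB" if is_dsb else None
        out.append(c)
    return out


def annotate_regions(calls: Sequence[HotspotCall], regions: RegionSet) -> list[HotspotCall]:
    for c in calls:
        c.region_labels = regions.overlapping(c.bin_start, c.bin_end)
    return list(calls)


def stalling_site_query(
    sites: Sequence[tuple[int, str]] = DEFAULT_STALLING_SITES,
    *,
    end_table: EndTable | None = None,
    profile: BinnedEndProfile | None = None,
    depth: float | None = None,
) -> pd.DataFrame:
    """Depth-normalized end frequency at specific positions.

    Per-position mode (``end_table`` + ``depth``): exact-position counts
    divided by depth.  Binned mode (``profile``): the containing bin's value.
    The mode used is recorded per row.
    """
    rows = []
    for position, end_class in sites:
        if end_class not in ("upstream", "downstream"):
            raise ValueError(f"unknown end class {end_class!r}")
        if end_table is not None:
            if depth is None or depth <= 0:
                raise ValueError("per-position mode needs a positive depth")
            check_position(position, end_table.genome_length)
            ends = end_table.upstream if end_class == "upstream" else end_table.downstream
            freq = sum(1 for p in ends if p == position) / depth
            mode = "per_position"
        elif profile is not None:
            _require_per_depth(profile)
            freq = float(profile.values(end_class)[profile.bin_of(position)])
            mode = "binned"
        else:
            raise ValueError("supply an end_table or a profile")
        rows.append({"position": position, "end_class": end_class, "frequency": freq, "mode": mode})
    return pd.DataFrame(rows)


@dataclass
class PairedCallResult:
    """All intermediates of the native/S1 differential pipeline."""

    native_profile: BinnedEndProfile
    s1_profile: BinnedEndProfile
    native_table: EndTable
    s1_table: EndTable
    native_depth: float
    s1_depth: float
    ssb: SSBProfile
    native_residual: ResidualProfile
    ssb_residual: ResidualProfile
    s1_residual: ResidualProfile
    calls: list[HotspotCall]


def call_pipeline(
    native_frags,
    s1_frags,
    genome_length: int,
    exclusion=None,
    ranking_exclude: RegionSet | None = None,
    bin_width: int = 40,
    window_halfwidth: int = 25,
    n_top: int = 15,
    end_class: str = "upstream",
) -> PairedCallResult:
    """extract -> bin -> normalize -> differential -> residual -> rank,
    for one native/S1 library pair.  Ranking is on the S1 residual profile."""
    from .end_profiling import bin_ends, extract_ends, mean_depth, normalize_to_depth

    native_table = extract_ends(native_frags, genome_length, exclusion, label="native")
    s1_table = extract_ends(s1_frags, genome_length, exclusion, label="s1", s1_treated=True)
    native_depth = mean_depth(native_frags, genome_length)
    s1_depth = mean_depth(s1_frags, genome_length)
    native_profile = normalize_to_depth(bin_ends(native_table, bin_width), native_depth)
    s1_profile = normalize_to_depth(bin_ends(s1_table, bin_width), s1_depth)
    ssb = ssb_differential(s1_profile, native_profile)
    native_residual = background_subtract(native_profile, window_halfwidth)
    s1_residual = background_subtract(s1_profile, window_halfwidth)
    ssb_residual = background_subtract(ssb, window_halfwidth)
    calls = rank_top_bins(s1_residual, end_class, ranking_exclude, n_top)
    calls = classify_calls(calls, ssb, native_residual)
    return PairedCallResult(
        native_profile=native_profile,
        s1_profile=s1_profile,
        native_table=native_table,
        s1_table=s1_table,
        native_depth=native_depth,
        s1_depth=s1_depth,
        ssb=ssb,
        native_residual=native_residual,
        ssb_residual=ssb_residual,
        s1_residual=s1_residual,
        calls=calls,
    )


def calls_to_frame(calls: Sequence[HotspotCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [c.rank for c in calls],
            "bin": [c.bin_index + 1 for c in calls],
            "bin_start": [c.bin_start for c in calls],
            "bin_end": [c.bin_end for c in calls],
            "end_class": [c.end_class for c in calls],
            "residual": [c.residual for c in calls],
            "break_class": [c.break_class or "NA" for c in calls],
            "regions": [",".join(c.region_labels) or "." for c in calls],
            "gc_within_flank": [
                "." if c.gc_within_flank is None else int(c.gc_within_flank) for c in calls
            ],
            "g4_within_flank": [
                "." if c.g4_within_flank is None else int(c.g4_within_flank) for c in calls
            ],
        }
    )
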