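"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: stepwise walks, explicit enumeration, hand-rolled run and
tract parsers.  They share no code with the package paths they check.
"""

from __future__ import annotations

import statistics


def walk_distance(a: int, b: int, length: int) -> int:
    """Minimal arc distance by stepping one base at a time in both directions."""
    forward = 0
    p = a
    while p != b:
        p = p % length + 1
        forward += 1
    backward = 0
    p = a
    while p != b:
        p = (p - 2) % length + 1
        backward += 1
    return min(forward, backward)


def arc_members(start: int, end: int, length: int) -> set[int]:
    """All positions on the clockwise arc start..end inclusive, by walking."""
    members = {start}
    p = start
    while p != end:
        p = p % length + 1
        members.add(p)
    return members


def brute_bin_counts(positions: list[int], bin_width: int, length: int) -> list[int]:
    """Per-bin tallies via an explicit per-position, per-bin membership scan."""
    n_bins = (length + bin_width - 1) // bin_width
    counts = [0] * n_bins
    for k in range(n_bins):
        lo = k * bin_width + 1
        hi = min((k + 1) * bin_width, length)
        for p in positions:
            if lo <= p <= hi:
                counts[k] += 1
    return counts


def brute_circular_median(values: list[float], halfwidth: int) -> list[float]:
    n = len(values)
    out = []
    for k in range(n):
        window = [values[(k + o) % n] for o in range(-halfwidth, halfwidth + 1)]
        out.append(statistics.median(window))
    return out


def brute_gc_stretches(seq: str, min_run: int) -> list[tuple[int, int, int]]:
    """Maximal circular G/C runs as (start, end, length), 1-based inclusive.

    Rotates the sequence so it ends on a non-GC base, then scans linearly.
    """
    L = len(seq)
    gc = [ch in "GC" for ch in seq]
    if all(gc):
        return [(1, L, L)] if L >= min_run else []
    pivot = gc.index(False)  # 0-based index of a non-GC base
    order = [(pivot + 1 + j) % L for j in range(L)]  # rotated ends at pivot
    runs: list[tuple[int, int, int]] = []
    run_start = None
    for j, idx in enumerate(order + [None]):
        if idx is not None and gc[idx]:
            if run_start is None:
                run_start = j
        else:
            if run_start is not None:
                run_len = j - run_start
                if run_len >= min_run:
                    start = order[run_start] + 1
                    end = order[j - 1] + 1
                    runs.append((start, end, run_len))
                run_start = None
    return sorted(runs)


def parse_g4_tracts(
    seq: str, tracts: int = 4, min_g: int = 3, loop: tuple[int, int] = (1, 7)
) -> bool:
    """Backtracking matcher for the four-tract G-quadruplex grammar:
    G-run(>=3) + 3 * (loop of 1-7 bases + G-run(>=3)), consuming the whole
    string.  Independent of the regex engine."""
    n = len(seq)

    def match(i: int, t: int) -> bool:
        g = 0
        while i + g < n and seq[i + g] == "G":
            g += 1
        if g < min_g:
            return False
        for use in range(min_g, g + 1):
            j = i + use
            if t == 1:
                if j == n:
                    return True
                continue
            for lp in range(loop[0], loop[1] + 1):
                if j + lp < n and match(j + lp, t - 1):
                    return True
        return False

    return match(0, tracts)


def has_g4(seq_linear: str) -> bool:
    """Whether any window of the (linear) sequence is a four-tract G4 motif."""
    n = len(seq_linear)
    for i in range(n):
        if seq_linear[i] != "G":
            continue
        for j in range(i + 15, min(i + 60, n) + 1):  # minimal motif is 15 nt
            if parse_g4_tracts(seq_linear[i:j]):
                return True
    return False
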