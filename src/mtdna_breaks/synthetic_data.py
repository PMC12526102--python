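"""Generative model for linearized mtDNA fragment libraries.

Each simulated molecule is a circular genome carrying strand-specific nicks
(single-strand breaks on the heavy or light strand) and double-strand breaks,
deposited by planted hotspots plus a uniform Poisson background.  Opposing
nicks closer than a conversion distance collapse into a DSB.  Library
preparation is modelled as: optional S1 nuclease treatment (every remaining
nick becomes a DSB), single-cutter linearization (EagI) with configurable
efficiency, partition of the circle into fragments at the DSB/cut positions,
bead size selection removing short fragments, and admixture of nuclear
background fragments with a log-normal length law.

Conventions
-----------
A DSB at position p separates p from p+1: the fragment ending there has
``downstream_end = p`` and the adjacent fragment has ``upstream_end = p + 1``
(mod L).  A molecule with a single cut yields one full-length linear
fragment; an uncut circle yields no fragment (circles are not sequenced).

Randomness: a single integer seed drives one ``numpy`` Generator.  Draw
order within :func:`simulate_molecules` is: hotspot firing matrix, per-strand
background counts, then per-molecule background positions (heavy before
light).  :func:`simulate_paired_libraries` continues the same stream with the
native library's EagI draws, then the S1 library's, then nuclear lengths
(native before S1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome_model import CircularGenome, check_position, rotate_coordinates

BreakKind = Literal["nick_heavy", "nick_light", "dsb"]
_KINDS = ("nick_heavy", "nick_light", "dsb")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class BreakSpec:
    """A planted break hotspot: fires independently per molecule at ``rate``."""

    position: int
    kind: BreakKind
    rate: float

    def validate(self, length: int) -> "BreakSpec":
        check_position(self.position, length)
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown break kind {self.kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigError(f"rate {self.rate} outside [0, 1]")
        return self


@dataclass(frozen=True)
class NuclearLengthLaw:
    """Length distribution for nuclear background fragments.

    Log-normal parameterized by its median (bp) and the standard deviation of
    the log; sampling truncates below the size-selection threshold by
    rejection.
    """

    name: str = "lognormal"
    median: float = 8000.0
    sigma_log: float = 0.5

    def sample(self, rng: np.random.Generator, n: int, size_min: int) -> np.ndarray:
        if self.name != "lognormal":
            raise ConfigError(f"unknown nuclear length law {self.name!r}")
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.lognormal(math.log(self.median), self.sigma_log, size=n - filled)
            keep = draw[draw >= max(size_min, 1)]
            out[filled : filled + keep.size] = np.asarray(keep, dtype=np.int64)
            filled += keep.size
        return out


@dataclass
class SimulationConfig:
    genome: CircularGenome = field(default_factory=CircularGenome)
    hotspots: list[BreakSpec] = field(default_factory=list)
    background_nick_rate: float = 1e-5  # per base per strand
    nick_to_dsb_distance: int = 10  # opposing nicks within d bp collapse to a DSB
    eagI_position: int = 2567  # inside the excluded window 2550-2585
    eagI_efficiency: float = 0.9
    s1_treated: bool = False
    n_molecules: int = 5000
    size_min: int = 3000
    nuclear_fraction: float = 0.0
    nuclear_length_law: NuclearLengthLaw = field(default_factory=NuclearLengthLaw)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        L = self.genome.length
        for h in self.hotspots:
            h.validate(L)
        if not 0.0 <= self.background_nick_rate <= 1.0:
            raise ConfigError("background_nick_rate outside [0, 1]")
        if not 0.0 <= self.eagI_efficiency <= 1.0:
            raise ConfigError("eagI_efficiency outside [0, 1]")
        if not 0.0 <= self.nuclear_fraction < 1.0:
            raise ConfigError("nuclear_fraction must lie in [0, 1)")
        check_position(self.eagI_position, L)
        if self.n_molecules <= 0:
            raise ConfigError("n_molecules must be positive")
        if self.size_min < 0:
            raise ConfigError("size_min must be non-negative")
        if self.nick_to_dsb_distance < 0:
            raise ConfigError("nick_to_dsb_distance must be non-negative")
        return self


@dataclass
class MoleculeState:
    """Break content of one circular molecule (positions sorted, duplicate-free)."""

    nicks_heavy: list[int] = field(default_factory=list)
    nicks_light: list[int] = field(default_factory=list)
    dsbs: list[int] = field(default_factory=list)
    linearized: bool = False


@dataclass(frozen=True)
class FragmentRecord:
    """A linear fragment as a directed clockwise arc on the circle.

    Nuclear background records carry only a length (ends are None).
    """

    upstream_end: int | None
    downstream_end: int | None
    length: int
    compartment: Literal["mito", "nuclear"] = "mito"
    origin_spanning: bool = False


def _convert_opposing_nicks(
    heavy: list[int], light: list[int], d: int, length: int
) -> tuple[list[int], list[int], list[int]]:
    """Pair heavy/light nicks within circular distance d; each pair becomes one
    DSB at the heavy-strand nick position.  Greedy nearest-neighbour pairing in
    heavy-position order; each light nick is consumed at most once."""
    new_dsbs: list[int] = []
    remaining_light = list(light)
    remaining_heavy: list[int] = []
    for h in heavy:
        best = None
        best_dist = d + 1
        for lt in remaining_light:
            dist = min((lt - h) % length, (h - lt) % length)
            if dist < best_dist or (dist == best_dist and (best is None or lt < best)):
                best, best_dist = lt, dist
        if best is not None and best_dist <= d:
            remaining_light.remove(best)
            new_dsbs.append(h)
        else:
            remaining_heavy.append(h)
    return remaining_heavy, remaining_light, new_dsbs


def simulate_molecules(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[MoleculeState]:
    """Draw the break content of ``n_molecules`` circular genomes."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome.length
    n = config.n_molecules
    lam = L * config.background_nick_rate

    fires = (
        rng.random((n, len(config.hotspots))) < [h.rate for h in config.hotspots]
        if config.hotspots
        else np.zeros((n, 0), dtype=bool)
    )
    bg_counts = rng.poisson(lam, size=(n, 2)) if lam > 0 else np.zeros((n, 2), dtype=int)

    molecules: list[MoleculeState] = []
    for i in range(n):
        heavy: set[int] = set()
        light: set[int] = set()
        dsbs: set[int] = set()
        for j, spec in enumerate(config.hotspots):
            if fires[i, j]:
                {"nick_heavy": heavy, "nick_light": light, "dsb": dsbs}[spec.kind].add(
                    spec.position
                )
        if bg_counts[i, 0]:
            heavy.update(int(p) for p in rng.integers(1, L + 1, bg_counts[i, 0]))
        if bg_counts[i, 1]:
            light.update(int(p) for p in rng.integers(1, L + 1, bg_counts[i, 1]))
        h_left, l_left, converted = _convert_opposing_nicks(
            sorted(heavy), sorted(light), config.nick_to_dsb_distance, L
        )
        dsbs.update(converted)
        molecules.append(
            MoleculeState(
                nicks_heavy=sorted(h_left),
                nicks_light=sorted(l_left),
                dsbs=sorted(dsbs),
            )
        )
    return molecules


def s1_treat(molecule: MoleculeState) -> MoleculeState:
    """S1 nuclease model: every nick (either strand) becomes a DSB; idempotent."""
    dsbs = sorted(set(molecule.dsbs) | set(molecule.nicks_heavy) | set(molecule.nicks_light))
    return MoleculeState(nicks_heavy=[], nicks_light=[], dsbs=dsbs, linearized=molecule.linearized)


def linearize_and_fragment(
    molecule: MoleculeState,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[FragmentRecord]:
    """Cut at the EagI site (with probability ``eagI_efficiency``) and at every
    DSB; each arc between consecutive cuts becomes one fragment.

    Zero cuts -> no fragment (circles do not enter the library); one cut -> a
    single full-length linear fragment.  One rng draw is consumed per call.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome.length
    cuts = set(molecule.dsbs)
    if rng.random() < config.eagI_efficiency:
        cuts.add(config.eagI_position)
    if not cuts:
        return []
    ordered = sorted(cuts)
    frags: list[FragmentRecord] = []
    for i, down in enumerate(ordered):
        up = ordered[i - 1] % L + 1  # previous cut + 1, wrapping
        length = (down - up) % L + 1
        frags.append(
            FragmentRecord(
                upstream_end=up,
                downstream_end=down,
                length=length,
                compartment="mito",
                origin_spanning=up > down,
            )
        )
    return frags


def size_select(frags: Sequence[FragmentRecord], size_min: int) -> list[FragmentRecord]:
    """Bead size selection: keep fragments with length >= size_min (stable order).

    'Remove fragments <3 kb' is read literally: a 3000-bp fragment is kept.
    """
    return [f for f in frags if f.length >= size_min]


def _nuclear_records(
    n_mito: int, config: SimulationConfig, rng: np.random.Generator
) -> list[FragmentRecord]:
    f = config.nuclear_fraction
    if f <= 0 or n_mito == 0:
        return []
    n_nuc = int(round(n_mito * f / (1.0 - f)))
    lengths = config.nuclear_length_law.sample(rng, n_nuc, config.size_min)
    return [
        FragmentRecord(None, None, int(ln), compartment="nuclear") for ln in lengths
    ]


def sample_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[FragmentRecord]:
    """Full generative chain: simulate -> (S1 if configured) -> linearize ->
    size-select -> append nuclear background.  Deterministic under the seed."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(config, rng)
    frags: list[FragmentRecord] = []
    for m in molecules:
        if config.s1_treated:
            m = s1_treat(m)
        frags.extend(linearize_and_fragment(m, config, rng))
    frags = size_select(frags, config.size_min)
    frags.extend(_nuclear_records(len(frags), config, rng))
    return frags


def simulate_paired_libraries(
    config: SimulationConfig,
) -> tuple[list[FragmentRecord], list[FragmentRecord]]:
    """Native and S1-treated libraries drawn from ONE molecule population,
    modelling a split DNA preparation (S1 applied to a copy of each molecule)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(config, rng)
    native: list[FragmentRecord] = []
    for m in molecules:
        native.extend(linearize_and_fragment(m, config, rng))
    treated: list[FragmentRecord] = []
    for m in molecules:
        treated.extend(linearize_and_fragment(s1_treat(m), config, rng))
    native = size_select(native, config.size_min)
    treated = size_select(treated, config.size_min)
    native.extend(_nuclear_records(len(native), config, rng))
    treated.extend(_nuclear_records(len(treated), config, rng))
    return native, treated


def rotate_fragment(frag: FragmentRecord, shift: int, length: int) -> FragmentRecord:
    """Rotate a mito fragment's end coordinates; nuclear records are unchanged."""
    if frag.compartment != "mito":
        return frag
    up = rotate_coordinates(frag.upstream_end, shift, length)
    down = rotate_coordinates(frag.downstream_end, shift, length)
    return replace(frag, upstream_end=up, downstream_end=down, origin_spanning=up > down)


def rotate_fragments(
    frags: Iterable[FragmentRecord], shift: int, length: int
) -> list[FragmentRecord]:
    return [rotate_fragment(f, shift, length) for f in frags]


# ---------------------------------------------------------------------------
# Fragment-table and truth-table I/O

FRAGMENT_COLUMNS = ["compartment", "upstream_end", "downstream_end", "length", "origin_spanning"]


def fragments_to_frame(frags: Sequence[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compartment": [f.compartment for f in frags],
            "upstream_end": [f.upstream_end if f.upstream_end is not None else -1 for f in frags],
            "downstream_end": [
                f.downstream_end if f.downstream_end is not None else -1 for f in frags
            ],
            "length": [f.length for f in frags],
            "origin_spanning": [int(f.origin_spanning) for f in frags],
        }
    )


def frame_to_fragments(df: pd.DataFrame) -> list[FragmentRecord]:
    out = []
    for r in df.itertuples():
        nuclear = r.compartment == "nuclear"
        out.append(
            FragmentRecord(
                upstream_end=None if nuclear else int(r.upstream_end),
                downstream_end=None if nuclear else int(r.downstream_end),
                length=int(r.length),
                compartment=str(r.compartment),
                origin_spanning=bool(int(r.origin_spanning)),
            )
        )
    return out


def write_fragments_tsv(
    frags: Sequence[FragmentRecord], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fragments_to_frame(frags).to_csv(fh, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> list[FragmentRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fragment table missing columns {sorted(missing)}")
    return frame_to_fragments(df)


def hotspot_truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Planted-break truth table written next to simulated libraries."""
    return pd.DataFrame(
        {
            "position": [h.position for h in config.hotspots],
            "kind": [h.kind for h in config.hotspots],
            "rate": [h.rate for h in config.hotspots],
        }
    )


def write_fragment_fasta(
    frags: Sequence[FragmentRecord], genome: CircularGenome, path: str | Path
) -> int:
    """Write mito fragment sequences (requires a genome sequence); returns count."""
    n = 0
    with open(path, "w") as fh:
        for i, f in enumerate(frags):
            if f.compartment != "mito":
                continue
            seq = genome.subsequence(f.upstream_end, f.downstream_end)
            fh.write(f">frag{i}|{f.upstream_end}-{f.downstream_end}\n{seq}\n")
            n += 1
    return n


def synthetic_genome(
    length: int = 16569,
    seed: int = 0,
    gc_islands: Sequence[tuple[int, int]] = (),
    g4_sites: Sequence[int] = (),
    gc_content: float = 0.44,
) -> CircularGenome:
    """Random circular genome with optional planted GC islands and G4 motifs.

    ``gc_islands`` are (start, run_length) pairs planted as pure G/C runs;
    ``g4_sites`` receive a canonical four-tract G-quadruplex motif
    (GGGTTAGGGTTAGGGTTAGGG) on the heavy strand starting at the site.
    """
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    seq = bases.tolist()
    for start, run in gc_islands:
        check_position(start, length)
        island = rng.choice(list("GC"), size=run)
        for k in range(run):
            seq[(start - 1 + k) % length] = island[k]
    motif = "GGGTTAGGGTTAGGGTTAGGG"
    for site in g4_sites:
        check_position(site, length)
        for k, ch in enumerate(motif):
            seq[(site - 1 + k) % length] = ch
    return CircularGenome(name=f"synthetic_L{length}", length=length, sequence="".join(seq))
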