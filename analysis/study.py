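"""Shared study design for the analysis drivers.

One synthetic circular genome (human-mtDNA-sized, 16 569 bp) with GC islands
and G-quadruplex motifs planted at the nick hotspot positions, emulating the
observation that SSB clusters sit in GC-rich, G4-capable sequence.  Two
library pairs are simulated from it:

* ``repair_proficient`` — low nick rates at the hotspot sites, modelling a
  cell line with intact single-strand break repair;
* ``repair_deficient`` — five-fold elevated nick rates at the same sites,
  modelling loss of the mitochondrial DNA ligase.

Both carry the same double-strand-break hotspot (a degradation-prone site)
and uniform background nicks.
"""

from __future__ import annotations

from pathlib import Path

from mtdna_breaks.genome_model import CircularGenome
from mtdna_breaks.synthetic_data import BreakSpec, SimulationConfig, synthetic_genome

L = 16569
GENOME_SEED = 12345
STUDY_SEED = 20260921
N_MOLECULES = 5000
NICK_SITES = (6000, 9500, 13000)  # outside D-loop/oriL, > 3 kb from the cutter
DSB_SITE = 14500
BACKGROUND_NICK_RATE = 1e-5

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

CONDITIONS = {"repair_proficient": 0.01, "repair_deficient": 0.05}
DSB_RATE = 0.03


def study_genome() -> CircularGenome:
    return synthetic_genome(
        L,
        seed=GENOME_SEED,
        gc_islands=[(p - 4, 12) for p in NICK_SITES],
        g4_sites=[p + 12 for p in NICK_SITES],
    )


def condition_config(condition: str, seed_offset: int = 0) -> SimulationConfig:
    nick_rate = CONDITIONS[condition]
    return SimulationConfig(
        genome=study_genome(),
        hotspots=[
            BreakSpec(NICK_SITES[0], "nick_heavy", nick_rate),
            BreakSpec(NICK_SITES[1], "nick_light", nick_rate),
            BreakSpec(NICK_SITES[2], "nick_heavy", nick_rate),
            BreakSpec(DSB_SITE, "dsb", DSB_RATE),
        ],
        background_nick_rate=BACKGROUND_NICK_RATE,
        n_molecules=N_MOLECULES,
        nuclear_fraction=0.05,
        seed=STUDY_SEED + seed_offset,
    )


def library_path(condition: str, treatment: str) -> Path:
    return SCRATCH / f"{condition}_{treatment}_fragments.tsv"
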