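from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from mtdna_breaks import CircularGenome, human_mtdna_regions
from mtdna_breaks.break_calling import call_pipeline
from mtdna_breaks.synthetic_data import BreakSpec, SimulationConfig, simulate_paired_libraries

#: Planted hotspots for the recovery study: three nick-only sites and one DSB
#: site, all outside the D-loop / oriL ranking exclusions and > 3 kb from the
#: EagI site so size selection does not shadow them.
RECOVERY_NICKS = (6000, 9500, 13000)
RECOVERY_DSB = 14500
RECOVERY_RATE = 0.05
RECOVERY_BACKGROUND = 1e-5
RECOVERY_N_MOLECULES = 5000
RECOVERY_SEED = 20260921


def recovery_config(seed: int = RECOVERY_SEED, n_molecules: int = RECOVERY_N_MOLECULES) -> SimulationConfig:
    return SimulationConfig(
        genome=CircularGenome(length=16569),
        hotspots=[
            BreakSpec(RECOVERY_NICKS[0], "nick_heavy", RECOVERY_RATE),
            BreakSpec(RECOVERY_NICKS[1], "nick_light", RECOVERY_RATE),
            BreakSpec(RECOVERY_NICKS[2], "nick_heavy", RECOVERY_RATE),
            BreakSpec(RECOVERY_DSB, "dsb", RECOVERY_RATE),
        ],
        background_nick_rate=RECOVERY_BACKGROUND,
        n_molecules=n_molecules,
        seed=seed,
    )


def run_recovery_pipeline(seed: int = RECOVERY_SEED):
    """Simulate the paired recovery libraries and run the full calling chain."""
    config = recovery_config(seed)
    native, treated = simulate_paired_libraries(config)
    regions = human_mtdna_regions()
    result = call_pipeline(
        native,
        treated,
        genome_length=config.genome.length,
        exclusion=regions["EagI_exclusion"],
        ranking_exclude=regions.subset(["D-loop", "oriL"]),
    )
    return config, native, treated, result


@pytest.fixture(scope="session")
def recovery_run():
    """Session-wide seeded simulation + calling run (the expensive fixture)."""
    return run_recovery_pipeline()


@pytest.fixture(scope="session")
def regions():
    return human_mtdna_regions()
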