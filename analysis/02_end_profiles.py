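#!/usr/bin/env python
"""Binned, depth-normalized end profiles and fragment size distributions.

Reads the simulated libraries (run 01 first), excludes ends in the
linearization-artifact window (2550-2585), bins ends at 40 nt, normalizes to
mean sequencing depth, and writes per-library profile tables plus nuclear
size distributions and the reference-library choice used for length-bias
normalization.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import study

from mtdna_breaks.end_profiling import (
    SizeDistribution,
    bin_ends,
    extract_ends,
    mean_depth,
    normalize_to_depth,
    select_reference_library,
    write_profile_tsv,
)
from mtdna_breaks.genome_model import human_mtdna_regions
from mtdna_breaks.synthetic_data import read_fragments_tsv


def main() -> None:
    exclusion = human_mtdna_regions()["EagI_exclusion"]
    study.RESULTS.mkdir(parents=True, exist_ok=True)
    nuclear_dists, labels = [], []
    for condition in study.CONDITIONS:
        for treatment in ("native", "s1"):
            path = study.library_path(condition, treatment)
            if not path.exists():
                sys.exit(f"missing {path}; run analysis/01_simulate_libraries.py first")
            frags = read_fragments_tsv(path)
            table = extract_ends(frags, study.L, exclusion, label=f"{condition}_{treatment}")
            depth = mean_depth(frags, study.L)
            profile = normalize_to_depth(bin_ends(table, 40), depth)
            out = study.RESULTS / f"profile_{condition}_{treatment}.tsv"
            write_profile_tsv(
                profile, out,
                [f"library: {condition}_{treatment}", f"depth: {depth:.4f}",
                 f"excluded_ends: {table.excluded}"],
            )
            print(f"{condition}/{treatment}: depth {depth:.1f}, "
                  f"{len(table.upstream)} upstream + {len(table.downstream)} downstream ends, "
                  f"{table.excluded} excluded near the cutter site")
            if any(f.compartment == "nuclear" for f in frags):
                nuclear_dists.append(SizeDistribution.from_fragments(frags, "nuclear"))
                labels.append(f"{condition}_{treatment}")
    if nuclear_dists:
        ref = select_reference_library(nuclear_dists)
        print(f"\nreference library for length-bias normalization: {labels[ref]} "
              f"(highest proportion of large nuclear fragments)")
        frame = pd.DataFrame(
            {"left_edge_bp": nuclear_dists[0].edges}
            | {lab: d.proportions for lab, d in zip(labels, nuclear_dists)}
        )
        frame.to_csv(study.RESULTS / "nuclear_size_distributions.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
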