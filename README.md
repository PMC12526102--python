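# mtdna-breaks

Strand-break end profiling and turnover kinetics for circular mitochondrial
genomes.

Mammalian mtDNA is a multicopy circular genome (human reference length
16 569 bp) whose damaged copies are preferentially degraded rather than
repaired. Long-read sequencing of restriction-linearized mtDNA turns every
double-strand break (DSB) into a pair of fragment ends, and pre-treating the
DNA with S1 nuclease — which converts single-strand breaks (SSBs: nicks and
gaps) into DSBs — makes SSBs visible too: ends in an S1-treated library
represent the sum of SSBs and DSBs, so the difference against the untreated
(native) library estimates the SSB landscape. This package implements that
analysis end to end for anyone mapping mtDNA strand breaks from fragment-end
tables, plus the kinetic fits used to quantify mtDNA turnover.

## What it computes

Fragment ends are tallied on the circle in 40-nt bins (bin *k* covers
positions *(k−1)·40+1 … k·40*), after excluding ends inside the
linearization-artifact window around the single-cutter site (positions
2550–2585 for EagI on human mtDNA). Binned counts are normalized to mean
sequencing depth, `depth = Σ fragment lengths / L`. Per-bin SSB frequency is
the clamped differential

```
SSB(k) = max(0, S1(k) − native(k))
```

and hotspots are ranked by the residual against a circular running-median
background (half-width 25 bins ≈ 1 kb), excluding the D-loop (16030–570) and
oriL (5770–5820) where replication intermediates dominate. Called bins are
annotated with nearby GC stretches and G-quadruplex motifs
(`G{3,}(N{1,7}G{3,}){3}` on either strand), with a circular-rotation
permutation test for co-localization.

The kinetics module fits label-chase decay `S(t) = N0·e^(−kt)` (half-life
`ln 2 / k`), decomposes the apparent rate into degradation plus dilution by
cell division (`k_deg = k_app − ln 2 / T_doubling`), fits qPCR amplification
with the four-parameter Chapman sigmoid `y = y0 + a(1 − e^(−bx))^c` whose
inflection `Ct = ln(c)/b` defines the quantification cycle, and converts
ΔCt against a diploid single-copy nuclear locus into mtDNA copies per cell
(`2 · E^ΔCt`).

A seeded generative model (`synthetic_data`) produces fragment libraries
with the full experimental structure — planted nick/DSB hotspots, Poisson
background nicks, opposing-nick collapse, S1 conversion, single-cutter
linearization, <3 kb size selection, nuclear background fragments — so every
stage is testable without sequencing data.

## Worked example

```python
from mtdna_breaks import CircularGenome, human_mtdna_regions
from mtdna_breaks.synthetic_data import BreakSpec, SimulationConfig, simulate_paired_libraries
from mtdna_breaks.break_calling import call_pipeline

config = SimulationConfig(
    genome=CircularGenome(length=16569),
    hotspots=[BreakSpec(6000, "nick_heavy", 0.05),   # SSB hotspot
              BreakSpec(14500, "dsb", 0.05)],        # DSB hotspot
    background_nick_rate=1e-5,
    n_molecules=5000,
    seed=1,
)
native, s1 = simulate_paired_libraries(config)
regions = human_mtdna_regions()
result = call_pipeline(
    native, s1, 16569,
    exclusion=regions["EagI_exclusion"],
    ranking_exclude=regions.subset(["D-loop", "oriL"]),
)
for c in result.calls[:3]:
    print(f"rank {c.rank}: bin {c.bin_start}-{c.bin_end}  "
          f"residual {c.residual:.5f}  class {c.break_class}")
```

prints

```
rank 1: bin 14481-14520  residual 0.05665  class DSB
rank 2: bin 6001-6040  residual 0.04794  class SSB
rank 3: bin 5721-5760  residual 0.00153  class SSB
```

Both planted hotspots surface in the top ranks of the S1 residual profile:
the DSB at 14500 (its upstream ends fall at 14501, in bin 14481–14520,
present in the native library too, hence class DSB) and the nick at 6000
(ends at 6001, absent natively, hence class SSB). Residuals are per-depth
end frequencies: ≈0.05 matches the planted per-molecule hotspot rate. The
kinetics side in two lines:

```python
from mtdna_breaks.kinetics import DecaySeries, fit_exponential, decompose_dilution
fit = fit_exponential(DecaySeries([0.0, 24.0], [1.0, 0.25]))
deco = decompose_dilution(fit, doubling_time=30.0)
print(f"apparent half-life {fit.half_life:.0f} h, "
      f"degradation half-life {deco.degradation_half_life:.0f} h")
# apparent half-life 12 h, degradation half-life 20 h
```

A label signal falling to 0.25 of baseline in 24 h is two halvings — a 12-h
apparent half-life; removing dilution by division at a 30-h doubling time
leaves a 20-h degradation half-life.

## Analysis scripts and CLI

The `analysis/` directory holds numbered drivers that run the whole study on
simulated libraries (two conditions: repair-proficient vs repair-deficient,
with GC/G4 context planted at the nick hotspot sites) and write their tables
under `results/`:

```sh
python analysis/01_simulate_libraries.py   # paired native/S1 libraries
python analysis/02_end_profiles.py         # binned depth-normalized profiles
python analysis/03_call_hotspots.py        # SSB differential + hotspot ranking
python analysis/04_annotate_motifs.py      # GC/G4 scan + rotation null
python analysis/05_kinetics.py             # decay, depletion, qPCR fits
```

The same stages are available from a shell via the `mtdna-breaks` console
command (`simulate`, `profile`, `call`, `motifs`, `kinetics`, `all`); see
`mtdna-breaks --help`.

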