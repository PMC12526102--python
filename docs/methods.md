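# Methods

This note documents the models, conventions and numerical choices behind
`mtdna-breaks`, and what the simulation-based tests do and do not establish
about real sequencing data.

## Coordinate model

All genome coordinates are 1-based inclusive, following mitochondrial
community numbering; the circle is handled natively, never linearized
internally. An interval with `start > end` is a single origin-spanning arc
(the D-loop, 16030–570, is the canonical case). BED input (0-based
half-open) is converted at the I/O boundary: `upstream_end = chromStart + 1`,
`downstream_end = chromEnd`; rows flagged origin-spanning may have
`upstream_end > downstream_end` and get length `L − chromStart + chromEnd`.
The minimal arc distance `min((a−b) mod L, (b−a) mod L)` is a metric on the
circle and drives all proximity queries (motif flanks, arc gaps).

## Generative model of a fragment library

Each simulated molecule is a circular genome carrying three kinds of breaks:

* **hotspot breaks** — each planted `BreakSpec(position, kind, rate)` fires
  independently per molecule with probability `rate`; kinds are
  `nick_heavy`, `nick_light` (strand-specific SSBs) and `dsb`;
* **background nicks** — per strand, a Poisson number with mean
  `L × background_nick_rate` (default 1e-5 per base per strand, giving
  ≈0.17 nicks per strand on a 16 569-nt genome) at uniform positions;
* **opposing-nick collapse** — a heavy- and a light-strand nick within
  `d = 10` bp (circular distance) merge into one DSB at the heavy-strand
  position, modelling spontaneous DSB formation from clustered SSBs while
  keeping the truth table simple. Pairing is greedy nearest-neighbour in
  heavy-position order; each light nick is consumed once.

Library preparation is then: optional S1 nuclease treatment (every remaining
nick becomes a DSB — idempotent by construction), a single-cutter cut at
`eagI_position = 2567` with probability `eagI_efficiency = 0.9` (the enzyme's
true efficiency is not a measured quantity; 0.9 models a near-complete
digest and is configurable), partition of the circle into fragments at the
cut positions, and size selection keeping fragments of length ≥ 3000 bp
("remove fragments <3 kb" read as a strict inequality, so exactly 3000 is
kept). A molecule with no cut never enters the library (circles are not
sequenced); one cut yields one full-length linear fragment.

**End convention.** A DSB at position *p* separates *p* from *p+1*: the
fragment ending there has `downstream_end = p`, the adjacent fragment starts
at `upstream_end = p + 1`. This fixes a one-off ambiguity that the data
formats leave open and is used consistently by the profiler, so simulator
truth is exactly recoverable from fragment ends before size selection.

Nuclear background fragments (default 5 % of the library in the analysis
drivers, 0 by default in the API) carry only a length, drawn from a
log-normal law (median 8 kb, σ_log 0.5) truncated at the size-selection
threshold. They model the trace nuclear DNA used for length-bias
normalization and never contribute ends.

One integer seed drives a single `numpy` generator; draw order is fixed and
documented in `synthetic_data`, so identical configurations yield
byte-identical fragment tables.

### What the generator does not emulate

No base-level sequencing error, chimeras, adapters or quality scores; no
instrument length bias (so length-bias reweighting defaults to off for
simulated input); no replication intermediates (the real oriH/TAS/oriL peaks
arise from asynchronous strand-displacement replication, not from breaks —
the simulator can only mimic them as planted hotspots). Passing tests
therefore establish the correctness of the computation given the generative
assumptions, not the biological fidelity of any particular real library.

## End profiling

Bins are anchored at position 1 with width 40 nt; the final bin is short
(9 nt for L = 16 569) and is kept rather than merged — the simplest
reproducible convention. Ends inside the cutter-artifact window (2550–2585)
are dropped and counted before binning. Depth is computed from retained
(post-size-selection) mitochondrial fragments, matching what a sequencer
observes, and uses mitochondrial fragments only (switchable). Size
distributions use 500-bp classes from 0 to 20 kb plus an overflow class;
"large fragments" means a class lower edge ≥ 10 kb. The reference library
for length-bias weights is the one with the highest large-fragment
proportion of its nuclear size distribution (ties: lowest index), and
`weight(class) = reference proportion / sample proportion`, with zero-mass
sample classes reported and weighted 0.

## Hotspot calling

The background estimator is a circular running median with half-width 25
bins (≈1 kb): robust to sparse peaks, location-invariant, and the
least-assumption choice for an undefined "local background". Residual
ranking sorts descending with ties broken by lower bin index — deterministic
regardless of input order and invariant under positive rescaling. Ranking
(not profile computation) excludes bins overlapping the D-loop and oriL.
Ranking operates on the S1 residual profile by default (the S1 library sees
SSBs + DSBs); the native residual profile is available for DSB-focused
ranking. The SSB differential clamps negative bins at zero — S1 ends are a
superset of native ends in expectation, so negative differences are sampling
noise — and reports clamp counts as diagnostics. Break classes compare the
differential and the native residual at the called bin: SSB-only, DSB-only
or mixed.

The stalling-site query reports per-depth end frequencies either at exact
positions or at the containing bin, for a default panel of five degradation
stalling sites (3210, 5736, 5969 upstream; 9921, 14249 downstream). Note
the end-convention offset: a DSB planted at *p* produces upstream ends at
*p + 1*.

## Motif annotation

GC stretches are maximal circular runs of {G, C} with a configurable minimum
length (default 6 nt — "long GC stretch" has no canonical definition, so the
threshold is reported in output). The G-quadruplex rule is the standard
four-tract Quadparser-style pattern `G{3,}(N{1,7}G{3,}){3}`, scanned
non-overlapping on the doubled sequence of each strand and deduplicated, so
origin-spanning motifs are found; light-strand matches are reported in
heavy-strand coordinates. The co-localization null rotates the whole motif
set by a uniform random offset per permutation — this preserves motif
clustering and is therefore conservative — with the add-one estimator
`p = (1 + #{null ≥ obs}) / (1 + n)`, which is never zero.

## Kinetics

Exponential decay is fitted log-linearly (exact on noiseless data; requires
positive signals — a direct nonlinear fit handles series with zeros). The
reader normalizes each series to its first timepoint, so amplitudes are
dimensionless with `S(0) = 1`. Dilution decomposition subtracts
`ln 2 / T_doubling` (default 30 h, an average HEK 293 doubling time) from the
apparent rate; a non-positive remainder is flagged dilution-dominated rather
than reported as a negative rate.

The Chapman qPCR fit `y = y0 + a(1 − e^(−bx))^c` uses multi-start
Levenberg–Marquardt from `y0 = min(y)`, `a = range(y)` over a coarse grid of
b ∈ {0.05…1.0} and c ∈ {1.5…80}, keeping the lowest-RSS solution; the
inflection `Ct = ln(c)/b` exists only for `c > 1`, and fits with `c ≤ 1.001`
are flagged as boundary cases with an undefined Ct. Amplification efficiency
defaults to 2.0 (100 % per cycle) in the copy-number conversion
`copies = 2 · E^(Ct_nuclear − Ct_mito)`; the factor 2 is the diploid
single-copy nuclear reference. Depletion/repopulation series fit decay on
points strictly before the drug-removal time; recovery is the first sampled
time at/after removal reaching 90 % of baseline (configurable), so an
instant-plateau series reports recovery time 0.

## Problem sizes and numerical checks

The test suite and the acceptance script run entirely on simulated data:
hotspot-recovery studies use 5 000 molecules per condition (hotspot rates
0.05, background 1e-5), conservation checks 100 independent 20-molecule
simulations, decay-recovery 500 noisy replicates of 6 timepoints (σ_log
0.2), and oracle-equivalence checks 100 randomized instances per primitive
against brute-force implementations (stepwise walks, per-position tallies,
explicit circular medians, run/tract parsers). Bin-level rotation
equivariance is exercised on a 16 000-nt circle, where the 40-nt bin lattice
tiles the genome exactly; with L = 16 569 the short final bin breaks exact
bin-level equivariance near the origin (position-level rotation is tested at
the native length). The Chapman inflection closed form is cross-checked
against the numeric root of a symbolically differentiated curve.

## Known limitations

* The SSB differential assumes equal underlying break populations in the
  paired libraries; it is unbiased only because the simulator splits one
  molecule population. Real paired libraries add biological and technical
  variance that the clamp diagnostics only partially expose.
* Hotspots are ranked, not tested: there is no FDR control across bins.
* Size selection shadows ends within ~3 kb of the cutter site; hotspots in
  that region are systematically under-called, as in the real protocol.
* The greedy opposing-nick pairing is order-dependent in contrived dense
  configurations; at realistic nick densities pairs are unambiguous.
* Copy-number estimates inherit any error in the assumed amplification
  efficiency; no standard-curve calibration is implemented.
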