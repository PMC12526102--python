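"""mtDNA turnover kinetics.

Three fitted quantities:

* exponential decay of label (BrdU chase) signal, S(t) = N0 * exp(-k t),
  fitted log-linearly; half-life t_1/2 = ln 2 / k.  The apparent decay rate
  mixes true degradation with dilution by cell division; for doubling time
  T_d the dilution rate is ln 2 / T_d and k_deg = k_apparent - ln 2 / T_d.
* qPCR amplification curves fitted with the four-parameter Chapman sigmoid
  y = y0 + a * (1 - exp(-b x))^c; the quantification cycle Ct is defined at
  the inflection point, Ct = ln(c) / b (requires c > 1).
* mtDNA copy number per cell from the Ct difference against a diploid
  single-copy nuclear locus: copies = 2 * E^(Ct_nuclear - Ct_mito), with
  amplification efficiency E per cycle (2 = 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

LN2 = math.log(2.0)
_ZERO_RATE_TOL = 1e-12


class FitError(RuntimeError):
    pass


@dataclass
class DecaySeries:
    """Time course of a normalized signal (1.0 at t = 0 by convention)."""

    timepoints: np.ndarray  # hours
    signals: np.ndarray  # dimensionless intensity
    label: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.timepoints.size != self.signals.size:
            raise ValueError("timepoints and signals differ in length")
        if self.timepoints.size < 2:
            raise ValueError("need at least two timepoints")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class DecayFit:
    rate: float  # per hour
    amplitude: float  # N0
    half_life: float  # hours; inf when rate == 0
    rss: float  # residual sum of squares in log space (or linear for NLS)
    method: str = "log_linear"

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * np.asarray(t, float))


def fit_exponential(series: DecaySeries) -> DecayFit:
    """Log-linear least squares: exact on noiseless exponential data.

    Requires strictly positive signals; series containing zeros should use
    :func:`fit_exponential_nls`.
    """
    if np.any(series.signals <= 0):
        raise ValueError(
            "non-positive signal: log-linear fit undefined; use fit_exponential_nls"
        )
    slope, intercept = np.polyfit(series.timepoints, np.log(series.signals), 1)
    k = -float(slope)
    if abs(k) < _ZERO_RATE_TOL:
        k = 0.0
    resid = np.log(series.signals) - (slope * series.timepoints + intercept)
    return DecayFit(
        rate=k,
        amplitude=float(np.exp(intercept)),
        half_life=math.inf if k <= 0 else LN2 / k,
        rss=float(resid @ resid),
    )


def fit_exponential_nls(series: DecaySeries) -> DecayFit:
    """Direct nonlinear least squares, usable when some signals are zero."""
    t, y = series.timepoints, series.signals
    k0 = 0.01 if y[0] <= 0 or y[-1] <= 0 or y[-1] >= y[0] else math.log(y[0] / y[-1]) / (t[-1] - t[0])
    popt, _ = curve_fit(
        lambda t, n0, k: n0 * np.exp(-k * t), t, y, p0=[max(y.max(), 1e-6), max(k0, 1e-6)],
        maxfev=10000,
    )
    n0, k = float(popt[0]), float(popt[1])
    if abs(k) < _ZERO_RATE_TOL:
        k = 0.0
    resid = y - n0 * np.exp(-k * t)
    return DecayFit(
        rate=k,
        amplitude=n0,
        half_life=math.inf if k <= 0 else LN2 / k,
        rss=float(resid @ resid),
        method="nonlinear",
    )


@dataclass
class DilutionDecomposition:
    degradation_rate: float  # per hour
    degradation_half_life: float  # hours; inf when dilution-dominated
    dilution_dominated: bool


def decompose_dilution(fit: DecayFit, doubling_time: float) -> DilutionDecomposition:
    """Remove the dilution component (rate ln2 / doubling_time) from an
    apparent decay rate.  ``doubling_time = inf`` is the no-division limit and
    returns the apparent half-life unchanged."""
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    k_div = 0.0 if math.isinf(doubling_time) else LN2 / doubling_time
    k_deg = fit.rate - k_div
    if k_deg <= _ZERO_RATE_TOL:
        return DilutionDecomposition(0.0, math.inf, True)
    return DilutionDecomposition(k_deg, LN2 / k_deg, False)


# ---------------------------------------------------------------------------
# qPCR: Chapman sigmoid and copy numbers


def chapman(x: np.ndarray, y0: float, a: float, b: float, c: float) -> np.ndarray:
    return y0 + a * np.power(1.0 - np.exp(-b * np.asarray(x, float)), c)


@dataclass
class ChapmanFit:
    y0: float
    a: float
    b: float  # per cycle, > 0
    c: float  # shape; inflection interior only for c > 1
    ct: float  # ln(c)/b, nan when c <= 1
    rss: float
    c_at_boundary: bool = False  # c ~ 1: saturating exponential, no inflection


def chapman_fit(
    cycles: Sequence[float],
    fluorescence: Sequence[float],
    b_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0),
    c_grid: Sequence[float] = (1.5, 5.0, 20.0, 80.0),
) -> ChapmanFit:
    """Four-parameter Chapman fit with multi-start nonlinear least squares.

    Starts combine y0 = min(y), a = range(y) with a coarse (b, c) grid; the
    start with the lowest residual sum of squares wins.  Raises
    :class:`FitError` if no start converges.
    """
    x = np.asarray(cycles, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points for a four-parameter fit")
    if not np.all(np.diff(x) > 0):
        raise ValueError("cycles must be strictly increasing")
    y0_0 = float(y.min())
    a_0 = max(float(y.max() - y.min()), 1e-9)
    best: tuple[float, np.ndarray] | None = None
    failures = 0
    for b0 in b_grid:
        for c0 in c_grid:
            try:
                popt, _ = curve_fit(
                    chapman,
                    x,
                    y,
                    p0=[y0_0, a_0, b0, c0],
                    bounds=([-np.inf, 1e-12, 1e-6, 1e-6], [np.inf, np.inf, 10.0, 1e6]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                failures += 1
                continue
            resid = y - chapman(x, *popt)
            rss = float(resid @ resid)
            if best is None or rss < best[0]:
                best = (rss, popt)
    if best is None:
        raise FitError(
            f"Chapman fit failed to converge from {failures} starts "
            f"(n={x.size}, y range {y.min():.3g}..{y.max():.3g})"
        )
    rss, (y0, a, b, c) = best
    boundary = c <= 1.0 + 1e-3
    return ChapmanFit(
        y0=float(y0),
        a=float(a),
        b=float(b),
        c=float(c),
        ct=math.nan if boundary else math.log(c) / b,
        rss=rss,
        c_at_boundary=bool(boundary),
    )


@dataclass
class CopyNumberResult:
    delta_ct: float  # Ct_nuclear - Ct_mito, cycles
    copies_per_cell: float
    efficiency: float


def copy_number(
    ct_mito: float, ct_nuclear: float, efficiency: float = 2.0
) -> CopyNumberResult:
    """mtDNA copies per cell against a diploid single-copy nuclear locus:
    2 * efficiency^(Ct_nuclear - Ct_mito)."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    dct = ct_nuclear - ct_mito
    return CopyNumberResult(dct, 2.0 * efficiency**dct, efficiency)


# ---------------------------------------------------------------------------
# Depletion / repopulation (replication-arrest) time courses


@dataclass
class DepletionRepopulationFit:
    decay: DecayFit
    switch_time: float
    recovery_time: float | None  # time after switch to reach the threshold
    recovery_threshold: float
    recovered: bool


def fit_depletion_repopulation(
    series: DecaySeries,
    switch_time: float,
    recovery_fraction: float = 0.9,
    baseline: float | None = None,
) -> DepletionRepopulationFit:
    """Two-phase summary of a depletion (drug on) / repopulation (drug off)
    time course.

    Decay is fitted to points strictly before ``switch_time``; recovery is the
    first sampled time at/after the switch whose signal reaches
    ``recovery_fraction * baseline`` (baseline defaults to the first
    pre-switch signal), reported relative to the switch.  No post-switch
    points -> recovery not observed.
    """
    pre = series.timepoints < switch_time
    if pre.sum() < 2:
        raise ValueError("need at least two points before the switch")
    decay = fit_exponential(
        DecaySeries(series.timepoints[pre], series.signals[pre], series.label)
    )
    base = float(series.signals[pre][0]) if baseline is None else baseline
    threshold = recovery_fraction * base
    post_t = series.timepoints[~pre]
    post_y = series.signals[~pre]
    recovery_time: float | None = None
    for t, y in zip(post_t, post_y):
        if y >= threshold:
            recovery_time = float(t - switch_time)
            break
    return DepletionRepopulationFit(
        decay=decay,
        switch_time=switch_time,
        recovery_time=recovery_time,
        recovery_threshold=threshold,
        recovered=recovery_time is not None,
    )


# ---------------------------------------------------------------------------
# I/O


def read_decay_series(path: str | Path, normalize: bool = True) -> list[DecaySeries]:
    """Read time-series TSV (time_h, signal, label); one series per label.

    When ``normalize`` is set (the default), each series is divided by its
    first-timepoint signal so curves start at 1.0.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"time_h", "signal"}
    if not required.issubset(df.columns):
        raise ValueError("time-series table needs columns time_h, signal")
    if "label" not in df.columns:
        df = df.assign(label="series")
    out = []
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("time_h")
        signals = grp.signal.to_numpy(dtype=float)
        if normalize:
            if signals[0] == 0:
                raise ValueError(f"series {label!r}: zero signal at first timepoint")
            signals = signals / signals[0]
        out.append(DecaySeries(grp.time_h.to_numpy(dtype=float), signals, str(label)))
    return out


def read_qpcr_table(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read qPCR TSV (cycle, fluorescence, well, target) -> per-well curves."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"cycle", "fluorescence", "well"}
    if not required.issubset(df.columns):
        raise ValueError("qPCR table needs columns cycle, fluorescence, well")
    curves = {}
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("cycle")
        curves[str(well)] = (
            grp.cycle.to_numpy(dtype=float),
            grp.fluorescence.to_numpy(dtype=float),
        )
    return curves
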