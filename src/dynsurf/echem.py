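"""Cyclic-voltammetry quantification and immobilization kinetics.

Surface coverage of an electroactive monolayer follows from the faradaic
charge of one voltammetric wave: Gamma = Q / (n F A), with Q the
baseline-subtracted integral of the wave divided by the scan rate,
n the electrons transferred per molecule, F = 96485 C/mol, and A the
electrode area.  Ligand immobilization is quantified as a conversion
fraction over time and fitted to pseudo-first-order kinetics
f(t) = 1 - exp(-k t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .config import FARADAY

__all__ = [
    "Voltammogram",
    "Segment",
    "Peak",
    "CoverageEstimate",
    "KineticsSeries",
    "KineticsFit",
    "FitError",
    "detect_peaks",
    "integrate_wave",
    "coverage_from_charge",
    "estimate_coverage",
    "fit_pseudo_first_order",
]


class FitError(RuntimeError):
    """Raised when a kinetics fit has no usable signal."""


@dataclass
class Segment:
    """One sweep direction of a cyclic voltammogram."""

    potential_mV: np.ndarray
    current_uA: np.ndarray
    direction: str  # "oxidation" (anodic) or "reduction" (cathodic)

    def __post_init__(self) -> None:
        self.potential_mV = np.asarray(self.potential_mV, dtype=float)
        self.current_uA = np.asarray(self.current_uA, dtype=float)
        if self.direction not in ("oxidation", "reduction"):
            raise ValueError("direction must be 'oxidation' or 'reduction'")
        d = np.diff(self.potential_mV)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("potential must be monotone within a segment")


@dataclass
class Voltammogram:
    segments: list[Segment]
    scan_rate: float  # mV/s
    electrode_area: float  # cm^2
    reference_electrode: str = "Ag/AgCl"

    def __post_init__(self) -> None:
        if self.scan_rate <= 0 or self.electrode_area <= 0:
            raise ValueError("scan_rate and electrode_area must be > 0")

    def segment(self, direction: str) -> Segment:
        for seg in self.segments:
            if seg.direction == direction:
                return seg
        raise ValueError(f"no {direction!r} segment in voltammogram")


@dataclass(frozen=True)
class Peak:
    potential_mV: float
    direction: str
    prominence_uA: float


@dataclass(frozen=True)
class CoverageEstimate:
    peak_potential_mV: float
    charge_C: float
    n_electrons: int
    coverage_mol_cm2: float


@dataclass
class KineticsSeries:
    """Conversion-fraction time course (fraction of monolayer converted)."""

    t_min: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any(self.t_min < 0):
            raise ValueError("timepoints must be non-negative")
        if len(self.t_min) != len(self.fraction):
            raise ValueError("t_min and fraction must have equal length")


@dataclass(frozen=True)
class KineticsFit:
    k: float  # min^-1
    stderr: float
    residual_norm: float


def _flank_baseline(seg: Segment, flank: float) -> np.ndarray:
    """Linear baseline fitted to the first and last ``flank`` fraction of points."""
    n = len(seg.potential_mV)
    k = max(int(round(flank * n)), 2)
    idx = np.concatenate([np.arange(k), np.arange(n - k, n)])
    coef = np.polyfit(seg.potential_mV[idx], seg.current_uA[idx], 1)
    return np.polyval(coef, seg.potential_mV)


def detect_peaks(
    vgram: Voltammogram, prominence_floor: float = 0.5, flank: float = 0.1
) -> list[Peak]:
    """Locate faradaic peaks per sweep direction, ranked by prominence.

    Each segment is baseline-corrected with a linear fit over its flanking
    windows; local extrema of the corrected current (maxima on the anodic
    sweep, minima on the cathodic) above ``prominence_floor`` (uA) are
    reported.  Peak positions are refined by a 3-point parabolic fit, so
    accuracy is limited by noise rather than the potential grid.  An empty
    list (not an error) means no peak cleared the floor.
    """
    peaks: list[Peak] = []
    for seg in vgram.segments:
        if len(seg.potential_mV) < 20:
            raise ValueError("need >= 20 points per segment for peak detection")
        resid = seg.current_uA - _flank_baseline(seg, flank)
        oriented = resid if seg.direction == "oxidation" else -resid
        idx, props = signal.find_peaks(oriented, prominence=prominence_floor)
        for i, prom in zip(idx, props["prominences"]):
            e = seg.potential_mV
            if 0 < i < len(e) - 1:
                y0, y1, y2 = oriented[i - 1], oriented[i], oriented[i + 1]
                denom = y0 - 2 * y1 + y2
                shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
                pot = e[i] + shift * (e[min(i + 1, len(e) - 1)] - e[i - 1]) / 2.0
            else:
                pot = e[i]
            peaks.append(Peak(float(pot), seg.direction, float(prom)))
    peaks.sort(key=lambda p: -p.prominence_uA)
    return peaks


def integrate_wave(
    vgram: Voltammogram, window: tuple[float, float], direction: str
) -> float:
    """Faradaic charge (C) of one wave: Q = (1/v) * int |i - baseline| dE.

    The baseline is the chord between the window endpoints; integration is
    trapezoidal over the window, and the scan rate converts the swept
    potential into time.  Currents in uA and potentials in mV give charge
    in coulombs.
    """
    lo, hi = sorted(window)
    seg = vgram.segment(direction)
    e, i = seg.potential_mV, seg.current_uA
    if lo < e.min() - 1e-9 or hi > e.max() + 1e-9:
        raise ValueError(f"window ({lo}, {hi}) mV outside sweep range ({e.min()}, {e.max()})")
    order = np.argsort(e)
    e, i = e[order], i[order]
    mask = (e >= lo) & (e <= hi)
    ew, iw = e[mask], i[mask]
    if len(ew) < 2:
        raise ValueError("window contains fewer than 2 samples")
    chord = iw[0] + (iw[-1] - iw[0]) * (ew - ew[0]) / (ew[-1] - ew[0])
    area = np.trapezoid(np.abs(iw - chord), ew)  # uA * mV
    return float(area * 1e-6 / vgram.scan_rate)  # C


def coverage_from_charge(charge: float, n_electrons: int, area: float) -> float:
    """Surface coverage Gamma = Q / (n F A), mol/cm^2."""
    if n_electrons not in (1, 2):
        raise ValueError("n_electrons must be 1 or 2")
    if charge < 0 or area <= 0:
        raise ValueError("charge must be >= 0 and area > 0")
    return charge / (n_electrons * FARADAY * area)


def estimate_coverage(
    vgram: Voltammogram,
    window: tuple[float, float],
    direction: str = "reduction",
    n_electrons: int = 2,
) -> CoverageEstimate:
    """Integrate one wave and convert its charge to surface coverage."""
    q = integrate_wave(vgram, window, direction)
    in_window = [
        p
        for p in detect_peaks(vgram)
        if p.direction == direction and window[0] <= p.potential_mV <= window[1]
    ]
    peak_pot = in_window[0].potential_mV if in_window else float(np.mean(window))
    return CoverageEstimate(
        peak_potential_mV=peak_pot,
        charge_C=q,
        n_electrons=n_electrons,
        coverage_mol_cm2=coverage_from_charge(q, n_electrons, vgram.electrode_area),
    )


def fit_pseudo_first_order(series: KineticsSeries) -> KineticsFit:
    """Fit f(t) = 1 - exp(-k t) by nonlinear least squares.

    The starting value comes from the linearized through-origin regression
    of -ln(1 - f) on t, excluding near-saturated points (f >= 0.99).
    Raises :class:`FitError` when the series carries no decay signal
    (all zero, or non-increasing overall).
    """
    t, f = series.t_min, series.fraction
    if len(t) < 4:
        raise FitError("need >= 4 timepoints")
    if np.any((f < 0) | (f > 1)):
        raise FitError("fractions must lie in [0, 1]")
    if np.max(f) <= 0:
        raise FitError("all-zero series: no conversion signal")
    # overall increase check (robust to noise): late mean must exceed early mean
    half = len(f) // 2
    if np.mean(f[half:]) <= np.mean(f[:half]) + 1e-9:
        raise FitError("series is not increasing overall: no decay signal")
    mask = (f < 0.99) & (t > 0)
    if mask.sum() >= 2:
        y = -np.log1p(-f[mask])
        k0 = float(np.sum(t[mask] * y) / np.sum(t[mask] ** 2))
    else:
        k0 = np.log(2.0) / max(np.median(t[t > 0]), 1e-9)
    k0 = max(k0, 1e-9)

    def model(tt, k):
        return 1.0 - np.exp(-k * tt)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(model, t, f, p0=[k0], maxfev=10000)
    k = float(popt[0])
    if k <= 0:
        raise FitError(f"fit converged to non-positive rate constant k={k}")
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    resid = f - model(t, k)
    return KineticsFit(k=k, stderr=se, residual_norm=float(np.linalg.norm(resid)))
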