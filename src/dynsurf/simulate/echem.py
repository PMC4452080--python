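"""Synthetic cyclic voltammograms and immobilization time courses.

Voltammograms are built as Gaussian faradaic peaks on a linear capacitive
baseline, one peak per sweep direction.  Peak amplitudes are scaled so the
integrated faradaic charge of each wave equals n F A Gamma for the
configured surface coverage, which makes the downstream integration /
coverage pipeline exactly invertible up to numerical error.  Conversion
kinetics follow f(t) = 1 - exp(-k t) with multiplicative noise.
"""

from __future__ import annotations

import numpy as np

from ..config import FARADAY, ConfigError, SimulationConfig
from ..echem import KineticsSeries, Segment, Voltammogram

__all__ = ["gen_voltammogram", "gen_kinetics_series"]


def gen_voltammogram(config: SimulationConfig, couple: str = "hydroquinone_quinone") -> Voltammogram:
    """Generate a two-segment cyclic voltammogram for one redox couple.

    ``couple`` must be configured in ``config.cv_peaks`` with a peak for
    both sweep directions.  The anodic (oxidation) segment sweeps from low
    to high potential with positive current; the cathodic segment sweeps
    back with negative current.
    """
    if couple not in config.cv_peaks:
        known = ", ".join(sorted(config.cv_peaks))
        raise ConfigError(f"unknown couple {couple!r}; configured: {known}")
    peaks = config.cv_peaks[couple]
    for direction in ("oxidation", "reduction"):
        if direction not in peaks:
            raise ConfigError(f"couple {couple!r} missing a {direction} peak definition")
    e_lo, e_hi = config.potential_range
    n = config.points_per_segment
    # target faradaic charge per wave: Q = n F A Gamma  (C)
    q = config.n_electrons * FARADAY * config.electrode_area * config.coverage
    rng = config.rng("voltammogram", couple)
    segments = []
    for direction, sign in (("oxidation", +1.0), ("reduction", -1.0)):
        e = np.linspace(e_lo, e_hi, n) if sign > 0 else np.linspace(e_hi, e_lo, n)
        pk = peaks[direction]
        sigma = pk.sigma_mV
        # int i dE = Ip * sigma * sqrt(2 pi)  must equal  q * scan_rate * 1e6 (uA*mV)
        ip = q * config.scan_rate * 1e6 / (sigma * np.sqrt(2.0 * np.pi))
        faradaic = ip * np.exp(-((e - pk.center_mV) ** 2) / (2.0 * sigma**2))
        e_mid = 0.5 * (e_lo + e_hi)
        baseline = config.capacitive_current + config.capacitive_slope * (e - e_mid)
        current = sign * (faradaic + baseline)
        if config.cv_noise > 0:
            scale = max(ip, config.capacitive_current)
            current = current + rng.normal(0.0, config.cv_noise * scale, size=n)
        segments.append(Segment(potential_mV=e, current_uA=current, direction=direction))
    return Voltammogram(
        segments=segments, scan_rate=config.scan_rate, electrode_area=config.electrode_area
    )


def gen_kinetics_series(
    config: SimulationConfig,
    timepoints=None,
    noise: float | None = None,
) -> KineticsSeries:
    """Simulate a pseudo-first-order conversion fraction time course.

    ``f(t) = 1 - exp(-k t)`` with ``k = config.k_immob`` (min^-1), each
    point multiplied by ``1 + eps`` with ``eps ~ N(0, noise)`` and clipped
    to [0, 1].  Default grid: every 10 min over 120 min.
    """
    if timepoints is None:
        timepoints = np.arange(0.0, 121.0, 10.0)
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ConfigError("timepoints must be non-negative")
    sigma = config.kinetics_noise if noise is None else float(noise)
    f = 1.0 - np.exp(-config.k_immob * t)
    if sigma > 0:
        rng = config.rng("kinetics")
        f = f * (1.0 + rng.normal(0.0, sigma, size=len(t)))
    return KineticsSeries(t_min=t, fraction=np.clip(f, 0.0, 1.0))
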