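"""Oscillation frequency, phase lag and wave-propagation speed.

The islet-average time course sets the peak frequency (periodogram
argmax, DC excluded).  Each block whose correlation with the islet
average exceeds 0.7 receives a phase: the argument of its discrete
Fourier component at the peak-frequency bin, taken relative to the
islet average so that a common delay of all traces cancels.

The phase difference between the maximum- and minimum-phase blocks is
converted to a time lag in two modes:

* ``as_printed`` — ``dt = (1/f) * arctan(phi1 - phi2)`` with ``f`` the
  *sampling* frequency.  This literal form is dimensionally unusual
  (arctan applied to a phase difference, normalised by the sampling
  rate) but is retained verbatim for fidelity to the published
  procedure.
* ``standard`` — ``dt = (phi1 - phi2) / (2 * pi * f_peak)``, the usual
  phase-to-time conversion at the oscillation frequency; this is the
  mode that recovers generator ground truth.

Wave speed divides the centroid distance between the extreme-phase
blocks by the time lag.  Speed is only reported for eligible islets:
largest coordinated fraction strictly above 0.80 and a clear phase
transition, operationalised as R^2 >= 0.5 of a planar fit of phase
against block position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .coordination import BlockTraceSet, CoordinationMap
from .errors import InputError, UndefinedResultError

INCLUSION_R = 0.7
COORDINATION_GATE = 0.80
PHASE_FIT_R2_MIN = 0.5

ELIGIBLE = "eligible"
LOW_COORDINATION = "low_coordination"
NO_PHASE_TRANSITION = "no_phase_transition"


@dataclass
class PhaseMap:
    """Per-block phase at the islet's peak frequency, plus wave summary."""

    f_peak_hz: float
    phi: np.ndarray  # (n_blocks,) radians in (-pi, pi]; NaN if excluded
    included: np.ndarray  # (n_blocks,) bool
    dt_as_printed_s: Optional[float]
    dt_standard_s: Optional[float]
    dt_max_s: Optional[float]  # |dt| in the primary mode
    speed_um_s: Optional[float]
    speed_as_printed_um_s: Optional[float]
    eligibility: str
    phase_fit_r2: float
    mode: str = "as_printed"


def power_spectrum_peak(trace: np.ndarray, fs: float) -> float:
    """Peak frequency of the periodogram over (0, fs/2], DC excluded."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] < 32:
        raise InputError("need at least 32 samples for a spectral peak")
    if np.ptp(trace) == 0:
        raise UndefinedResultError("constant trace has no spectral peak")
    freqs, power = signal.periodogram(trace, fs=fs, detrend=False)
    power[0] = 0.0  # exclude DC
    return float(freqs[int(np.argmax(power))])


def phase_at_peak(trace: np.ndarray, f_peak: float, fs: float) -> float:
    """Argument of the DFT component at the bin nearest ``f_peak``."""
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    spectrum = np.fft.rfft(trace - trace.mean())
    k = int(round(f_peak * n / fs))
    k = min(max(k, 1), len(spectrum) - 1)
    return float(np.angle(spectrum[k]))


def wrap_phase(phi):
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


def time_lag(phi1: float, phi2: float, f: float, mode: str = "as_printed") -> float:
    """Convert a phase difference to a time lag (seconds).

    ``phi1`` is the maximum-phase region, ``phi2`` the minimum-phase
    region.  See the module docstring for the two modes.
    """
    if f <= 0:
        raise InputError("frequency must be > 0")
    d = phi1 - phi2
    if mode == "as_printed":
        return float(np.arctan(d) / f)
    if mode == "standard":
        return float(d / (2.0 * np.pi * f))
    raise InputError(f"unknown mode {mode!r}")


def phase_gradient_fit(
    phi: np.ndarray, centroids_px: np.ndarray, included: np.ndarray
) -> float:
    """R^2 of a planar fit of phase against (y, x) block position.

    A clear phase transition across the islet means phase varies
    linearly along some axis; the planar fit's R^2 measures exactly
    that, with the fitted gradient defining the axis.
    """
    sel = included & np.isfinite(phi)
    if sel.sum() < 3:
        return 0.0
    y = phi[sel]
    design = np.column_stack(
        [centroids_px[sel, 0], centroids_px[sel, 1], np.ones(sel.sum())]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / sst)


def analyze_wave(
    blocks: BlockTraceSet,
    cmap: CoordinationMap,
    frame_interval_s: float,
    pixel_size_um: float,
    z_spacing_um: float = 8.0,
    mode: str = "as_printed",
    coordination_gate: float = COORDINATION_GATE,
    phase_fit_r2_min: float = PHASE_FIT_R2_MIN,
) -> PhaseMap:
    """Full phase/wave analysis of a segmented movie.

    The islet average is the pixel-weighted mean of active block traces;
    only blocks correlating > 0.7 with it receive phases.  Phases are
    relative to the islet average (common delays cancel).
    """
    fs = 1.0 / frame_interval_s
    active = cmap.active_blocks
    if active.sum() < 2:
        raise UndefinedResultError("need at least 2 active blocks for wave analysis")
    weights = blocks.n_pixels[active].astype(float)
    islet_avg = weights @ blocks.traces[active] / weights.sum()

    f_peak = power_spectrum_peak(islet_avg, fs)
    n = blocks.traces.shape[1]
    k = min(max(int(round(f_peak * n * frame_interval_s)), 1), n // 2)
    ref_component = np.fft.rfft(islet_avg - islet_avg.mean())[k]

    phi = np.full(blocks.n_blocks, np.nan)
    included = np.zeros(blocks.n_blocks, dtype=bool)
    for i in np.nonzero(active)[0]:
        trace = blocks.traces[i]
        r = np.corrcoef(trace, islet_avg)[0, 1]
        if not np.isfinite(r) or r <= INCLUSION_R:
            continue
        comp = np.fft.rfft(trace - trace.mean())[k]
        phi[i] = float(np.angle(comp * np.conj(ref_component)))
        included[i] = True

    from .coordination import largest_coordinated_fraction  # cycle-free local import

    fraction = largest_coordinated_fraction(cmap)
    r2 = phase_gradient_fit(phi, blocks.centroids_px, included)

    dt_printed = dt_standard = dt_max = speed = speed_printed = None
    if fraction <= coordination_gate:
        eligibility = LOW_COORDINATION
    elif r2 < phase_fit_r2_min:
        eligibility = NO_PHASE_TRANSITION
    else:
        eligibility = ELIGIBLE
        idx = np.nonzero(included)[0]
        i_max = idx[np.nanargmax(phi[idx])]
        i_min = idx[np.nanargmin(phi[idx])]
        phi1, phi2 = float(phi[i_max]), float(phi[i_min])
        dt_printed = time_lag(phi1, phi2, fs, mode="as_printed")
        dt_standard = time_lag(phi1, phi2, f_peak, mode="standard")
        dt_primary = dt_printed if mode == "as_printed" else dt_standard
        dt_max = abs(dt_primary)
        dyx = (blocks.centroids_px[i_max] - blocks.centroids_px[i_min]) * pixel_size_um
        dz = (blocks.z[i_max] - blocks.z[i_min]) * z_spacing_um
        dist = float(np.sqrt((dyx**2).sum() + dz**2))
        speed = wave_speed_from(dist, dt_standard)
        speed_printed = wave_speed_from(dist, dt_printed)

    return PhaseMap(
        f_peak_hz=f_peak,
        phi=phi,
        included=included,
        dt_as_printed_s=dt_printed,
        dt_standard_s=dt_standard,
        dt_max_s=dt_max,
        speed_um_s=speed,
        speed_as_printed_um_s=speed_printed,
        eligibility=eligibility,
        phase_fit_r2=r2,
        mode=mode,
    )


def wave_speed_from(distance_um: float, dt_s: Optional[float]) -> Optional[float]:
    """Distance between extreme-phase regions divided by the time lag.

    Returns None (infinite-speed flag) when the lag is zero.
    """
    if dt_s is None or dt_s == 0:
        return None
    return float(distance_um / abs(dt_s))
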