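"""Per-element phase aberration correction delays.

Three routes of increasing fidelity:

* ``geometric_focus_phases`` — closed-form water-path focusing (oracle),
* ``ray_trace_phases``       — straight-ray time-of-flight through the
                               heterogeneous speed map (geometric baseline;
                               refraction deliberately ignored),
* ``time_reversal_phases``   — full-wave: a test burst is emitted from the
                               target, per-element arrival delays are
                               estimated from the recorded traces, and the
                               conjugated delays are returned (the element
                               that hears the pulse last fires first).

All routes return a :class:`PhaseVector` whose delays are non-negative with
min 0; wrapped phases at the drive frequency are available alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .acoustics import (AcousticMedium, ArraySpec, ElementTraces, SimConfig,
                        record_at_elements, tone_burst)
from .phantoms import element_positions

__all__ = [
    "PhaseVector",
    "geometric_focus_phases",
    "ray_trace_phases",
    "time_reversal_phases",
    "estimate_arrival_delays",
    "wrap_phase",
    "delay_from_phase",
]

logger = logging.getLogger(__name__)


@dataclass
class PhaseVector:
    """Per-element emission delays with an explicit unit/wrapping convention.

    ``delays_s`` are relative delays in seconds, normalized so min = 0.
    ``phases_rad`` is the equivalent wrapped phase 2 pi f0 tau mod 2 pi.
    ``fractions`` are delays as fractions of a period in [0, 1) — the bounded
    representation used as surrogate-network targets.
    """

    delays_s: np.ndarray
    f0_hz: float

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        d = np.asarray(self.delays_s, dtype=np.float64)
        self.delays_s = d - d.min()

    @property
    def n_elements(self) -> int:
        return len(self.delays_s)

    @property
    def phases_rad(self) -> np.ndarray:
        ph = np.mod(2 * np.pi * self.f0_hz * self.delays_s, 2 * np.pi)
        # an exact multiple of one period is phase 0, not 2*pi - epsilon
        return np.where(np.isclose(ph, 2 * np.pi, atol=1e-9), 0.0, ph)

    @property
    def fractions(self) -> np.ndarray:
        return np.mod(self.delays_s * self.f0_hz, 1.0)


def wrap_phase(v: PhaseVector) -> PhaseVector:
    """Fold delays into one period (phase information only)."""
    period = 1.0 / v.f0_hz
    return PhaseVector(delays_s=np.mod(v.delays_s, period), f0_hz=v.f0_hz)


def delay_from_phase(phases_rad: np.ndarray, f0_hz: float) -> PhaseVector:
    """Delays (one period at most) realizing the given wrapped phases."""
    if f0_hz <= 0:
        raise ValueError("f0_hz must be positive")
    ph = np.mod(np.asarray(phases_rad, dtype=np.float64), 2 * np.pi)
    return PhaseVector(delays_s=ph / (2 * np.pi * f0_hz), f0_hz=f0_hz)


# ---------------------------------------------------------------------------


def _element_xy_mm(shape, pixel_spacing_mm, array: ArraySpec) -> np.ndarray:
    rcs = element_positions(shape, pixel_spacing_mm, array.n_elements,
                            array.pitch_mm, array.standoff_mm)
    return np.array(rcs, dtype=np.float64) * pixel_spacing_mm  # (n, 2) in mm


def geometric_focus_phases(
    c0: float,
    array: ArraySpec,
    target_rc: tuple[int, int],
    pixel_spacing_mm: float,
    shape: tuple[int, int] | None = None,
) -> PhaseVector:
    """Analytic water-path focusing delays: t_k = |x_k - x_t| / c0,
    emission delay = max(t) - t_k."""
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    n = shape or (512, 512)
    el_mm = _element_xy_mm(n, pixel_spacing_mm, array)
    tgt_mm = np.array(target_rc, dtype=np.float64) * pixel_spacing_mm
    t = np.hypot(*(el_mm - tgt_mm).T) * 1e-3 / c0
    return PhaseVector(delays_s=t.max() - t, f0_hz=array.f0_hz)


def ray_trace_phases(
    medium: AcousticMedium,
    array: ArraySpec,
    target_rc: tuple[int, int],
    step_fraction: float = 0.25,
) -> PhaseVector:
    """Straight-ray travel times through the heterogeneous speed map.

    Each element-to-target segment is sampled every ``step_fraction`` pixels
    with bilinear speed interpolation; t_k = integral ds / c(x). Refraction
    is ignored by construction (this is the geometric baseline the full-wave
    correction is compared against).
    """
    rcs = np.array(element_positions(medium.shape, medium.pixel_spacing_mm,
                                     array.n_elements, array.pitch_mm,
                                     array.standoff_mm), dtype=np.float64)
    tgt = np.array(target_rc, dtype=np.float64)
    dx_m = medium.pixel_spacing_mm * 1e-3
    times = np.empty(array.n_elements)
    for k, rc in enumerate(rcs):
        seg = tgt - rc
        length_px = np.hypot(*seg)
        n_samp = max(2, int(np.ceil(length_px / step_fraction)) + 1)
        s = np.linspace(0.0, 1.0, n_samp)
        pts = rc[:, np.newaxis] + seg[:, np.newaxis] * s[np.newaxis, :]
        c = ndimage.map_coordinates(medium.speed, pts, order=1, mode="nearest")
        ds = length_px * dx_m / (n_samp - 1)
        # trapezoidal integral of slowness
        times[k] = np.trapezoid(1.0 / c, dx=ds)
    return PhaseVector(delays_s=times.max() - times, f0_hz=array.f0_hz)


# ---------------------------------------------------------------------------


def estimate_arrival_delays(
    traces: ElementTraces,
    f0_hz: float,
    n_cycles: int = 5,
    method: str = "fourier",
    min_amplitude_ratio: float = 0.05,
) -> np.ndarray:
    """Per-element arrival times from recorded traces.

    ``fourier`` (default): per element, a coarse arrival from the envelope
    peak of the matched-filter (cross-correlation with the emitted burst),
    refined by the phase of the Fourier component at f0 computed over a
    window around that arrival. Windowing keeps late skull reverberations
    out of the phase estimate, and the coarse arrival resolves the
    one-period phase ambiguity per element, so no cross-element unwrapping
    chain is needed. ``xcorr``: the coarse envelope-peak arrival alone.
    Elements whose trace amplitude falls below ``min_amplitude_ratio`` x
    median are flagged and their delay linearly interpolated from
    neighbours.
    """
    tr = traces.traces
    dt = traces.dt_s
    n_el, n_t = tr.shape
    amp = np.abs(tr).max(axis=1)
    ok = amp >= min_amplitude_ratio * np.median(amp)
    if method not in ("fourier", "xcorr"):
        raise ValueError(f"unknown estimator {method!r}")

    period = 1.0 / f0_hz
    burst_len = int(round(n_cycles / f0_hz / dt)) + 1
    ref = tone_burst(np.arange(burst_len) * dt, f0_hz, n_cycles)
    tau = np.empty(n_el)
    for k in range(n_el):
        xc = signal.correlate(tr[k], ref, mode="full")
        env = np.abs(signal.hilbert(xc))
        coarse = (np.argmax(env) - (len(ref) - 1)) * dt
        if method == "xcorr":
            tau[k] = coarse
            continue
        lo = max(0, int(round((coarse - period) / dt)))
        hi = min(n_t, int(round(coarse / dt)) + burst_len + int(round(period / dt)))
        t_win = np.arange(lo, hi) * dt
        spectral = tr[k, lo:hi] @ np.exp(-2j * np.pi * f0_hz * t_win)
        fine = -np.angle(spectral) / (2 * np.pi * f0_hz)
        delta = np.mod(fine - coarse, period)
        if delta > period / 2:
            delta -= period
        tau[k] = coarse + delta
    tau -= tau.min()

    if not ok.all():
        bad = np.where(~ok)[0]
        logger.warning("interpolating %d low-amplitude element delays: %s",
                       len(bad), bad.tolist())
        idx = np.arange(n_el)
        tau[~ok] = np.interp(idx[~ok], idx[ok], tau[ok])
    return tau


def time_reversal_phases(
    medium: AcousticMedium,
    array: ArraySpec,
    target_rc: tuple[int, int],
    config: SimConfig,
    method: str = "fourier",
) -> PhaseVector:
    """Full-wave time-reversal correction delays.

    Runs the receive leg (point burst at the target, traces at the array),
    estimates per-element arrival times tau_k, and returns conjugated
    emission delays max(tau) - tau_k. Invariant to source amplitude because
    both estimators are amplitude-normalized.
    """
    traces = record_at_elements(medium, target_rc, array, config)
    tau = estimate_arrival_delays(traces, array.f0_hz, array.n_cycles, method=method)
    return PhaseVector(delays_s=tau.max() - tau, f0_hz=array.f0_hz)
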