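"""2D linear heterogeneous acoustic propagation for a flat phased array.

Maps Hounsfield units to acoustic material properties (density, sound speed,
absorption) and integrates the first-order linear acoustic equations

    dv/dt = -(1/rho) grad p,      dp/dt = -rho c^2 div v + source

on a staggered grid with Fourier (k-space) spatial derivatives, a split-field
perfectly matched layer, and a frequency-independent absorption factor
evaluated at the drive frequency. The solver records the per-pixel running
maximum |p| (the max-amplitude projection used as the steady-state field
surrogate) and, optionally, pressure time traces at the element positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phantoms import SkullSlice, element_positions

__all__ = [
    "AcousticMedium",
    "ArraySpec",
    "SimConfig",
    "PressureField",
    "ElementTraces",
    "HuDensityCalibration",
    "map_hu_to_medium",
    "tone_burst",
    "simulate_forward",
    "record_at_elements",
]

WATER_DENSITY = 997.0  # kg/m^3, lower clip
SPEED_SLOPE = 1.33  # c = 1.33 rho + 166.67  (m/s per kg/m^3)
SPEED_OFFSET = 166.67
SKULL_ATTENUATION_DB_MHZ_CM = 13.3
NEPER_PER_DB = 1.0 / 8.685889638065035  # ln(10)/20


@dataclass
class HuDensityCalibration:
    """Piecewise-linear CT number -> mass density calibration.

    Standard two-segment soft-tissue/bone curve: air (-1000 HU -> 1.293),
    water (0 HU -> 997) and a linear bone segment reaching ~2000 kg/m^3 near
    1600 HU, extrapolated with the bone slope above. Densities are clipped
    below at 997 so everything outside bone behaves as water.
    """

    hu_knots: tuple[float, ...] = (-1000.0, 0.0, 1600.0)
    density_knots: tuple[float, ...] = (1.293, 997.0, 2000.0)
    clip_min: float = WATER_DENSITY

    def density(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=np.float64)
        slope_hi = ((self.density_knots[-1] - self.density_knots[-2])
                    / (self.hu_knots[-1] - self.hu_knots[-2]))
        rho = np.interp(hu, self.hu_knots, self.density_knots)
        above = hu > self.hu_knots[-1]
        rho = np.where(above, self.density_knots[-1] + slope_hi * (hu - self.hu_knots[-1]), rho)
        return np.clip(rho, self.clip_min, None)


@dataclass
class AcousticMedium:
    """Co-registered material property grids derived from a skull slice."""

    density: np.ndarray  # kg/m^3
    speed: np.ndarray  # m/s
    attenuation_coeff: np.ndarray  # dB/(MHz cm)
    pixel_spacing_mm: float
    skull_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape  # type: ignore[return-value]

    def mirrored_lr(self) -> "AcousticMedium":
        return AcousticMedium(
            density=self.density[:, ::-1].copy(),
            speed=self.speed[:, ::-1].copy(),
            attenuation_coeff=self.attenuation_coeff[:, ::-1].copy(),
            pixel_spacing_mm=self.pixel_spacing_mm,
            skull_mask=self.skull_mask[:, ::-1].copy(),
        )


@dataclass
class ArraySpec:
    """Flat phased-array transducer along the top of the window.

    Full-scale defaults: 80 elements at 0.7 mm pitch (5.53 cm aperture),
    3 mm standoff from the top row, 500 kHz, 5-cycle burst, 1 MPa drive.
    """

    n_elements: int = 80
    pitch_mm: float = 0.7
    standoff_mm: float = 3.0
    f0_hz: float = 500e3
    n_cycles: int = 5
    element_pressure_pa: float = 1e6
    element_width_mm: float = 0.35

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")

    @property
    def aperture_mm(self) -> float:
        return (self.n_elements - 1) * self.pitch_mm

    @classmethod
    def reduced(cls, n_elements: int = 40, pitch_mm: float = 1.4,
                f0_hz: float = 250e3) -> "ArraySpec":
        """Desk-scale array preserving the ~5.5 cm aperture with fewer,
        coarser elements and a lower drive frequency."""
        return cls(n_elements=n_elements, pitch_mm=pitch_mm, f0_hz=f0_hz)


@dataclass
class SimConfig:
    """Simulation window / discretization / recording options.

    Full-scale default: 6 cm x 6 cm window on a 512 x 512 grid
    (0.117 mm spacing). ``total_time_s=None`` integrates for the burst
    duration plus a diagonal transit at the minimum sound speed plus a
    20% margin.
    """

    window_mm: float = 60.0
    grid_n: int = 512
    cfl: float = 0.3
    pml_px: int = 20
    pml_alpha: float = 2.0  # peak absorption in nepers per time step at the edge
    total_time_s: float | None = None
    record_mode: str = "max_amplitude"  # or "traces", "both"
    seed: int = 0

    @property
    def dx_m(self) -> float:
        return self.window_mm * 1e-3 / self.grid_n

    @property
    def pixel_spacing_mm(self) -> float:
        return self.window_mm / self.grid_n


@dataclass
class PressureField:
    """Per-pixel maximum |pressure| over a simulation, plus peak info."""

    field: np.ndarray  # Pa
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)

    @property
    def peak_pa(self) -> float:
        return float(self.field.max())

    @property
    def peak_rc(self) -> tuple[int, int]:
        # ties broken by first occurrence in row-major order
        idx = int(np.argmax(self.field))
        return np.unravel_index(idx, self.field.shape)  # type: ignore[return-value]

    @property
    def normalized(self) -> np.ndarray:
        peak = self.peak_pa
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero field")
        return self.field / peak


@dataclass
class ElementTraces:
    """Pressure time series recorded at each element position."""

    traces: np.ndarray  # (n_elements, n_t), Pa
    dt_s: float
    t0_s: float = 0.0

    @property
    def n_elements(self) -> int:
        return self.traces.shape[0]


# ---------------------------------------------------------------------------
# material mapping


def map_hu_to_medium(sl: SkullSlice, calibration: HuDensityCalibration | None = None) -> AcousticMedium:
    """Hounsfield units -> density, sound speed, and absorption grids.

    Density from the piecewise-linear CT calibration clipped at 997 kg/m^3
    (water); speed c = 1.33 rho + 166.67; absorption 13.3 dB/(MHz cm) on the
    skull mask and zero elsewhere.
    """
    if not np.all(np.isfinite(sl.hu_grid)):
        raise ValueError("non-finite HU values")
    calibration = calibration or HuDensityCalibration()
    rho = calibration.density(sl.hu_grid)
    speed = SPEED_SLOPE * rho + SPEED_OFFSET
    att = np.where(sl.skull_mask, SKULL_ATTENUATION_DB_MHZ_CM, 0.0)
    return AcousticMedium(
        density=rho,
        speed=speed,
        attenuation_coeff=att,
        pixel_spacing_mm=sl.pixel_spacing_mm,
        skull_mask=sl.skull_mask.copy(),
    )


def water_medium(grid_n: int, pixel_spacing_mm: float, c0: float = 1500.0,
                 rho0: float = WATER_DENSITY) -> AcousticMedium:
    """Homogeneous water medium, for oracles and calibration runs."""
    shape = (grid_n, grid_n)
    return AcousticMedium(
        density=np.full(shape, rho0),
        speed=np.full(shape, c0),
        attenuation_coeff=np.zeros(shape),
        pixel_spacing_mm=pixel_spacing_mm,
        skull_mask=np.zeros(shape, dtype=bool),
    )


# ---------------------------------------------------------------------------
# solver


def tone_burst(t: np.ndarray, f0_hz: float, n_cycles: int, delay_s: float = 0.0) -> np.ndarray:
    """Hann-windowed sine burst of ``n_cycles`` cycles starting at ``delay_s``."""
    tt = np.asarray(t, dtype=np.float64) - delay_s
    dur = n_cycles / f0_hz
    env = np.where((tt >= 0) & (tt <= dur), 0.5 * (1 - np.cos(2 * np.pi * tt / dur)), 0.0)
    return env * np.sin(2 * np.pi * f0_hz * tt)


def _choose_dt(config: SimConfig, c_max: float, f0_hz: float) -> float:
    """CFL-limited step, rounded down so a drive period is an integer number
    of samples (keeps the burst spectrally clean)."""
    dt0 = config.cfl * config.dx_m / c_max
    n_per_cycle = int(math.ceil(1.0 / (f0_hz * dt0)))
    return 1.0 / (f0_hz * n_per_cycle)


def _auto_time(config: SimConfig, c_min: float, burst_s: float) -> float:
    transit = math.sqrt(2.0) * config.window_mm * 1e-3 / c_min
    return 1.2 * (burst_s + transit)


def _pml_profiles(n: int, pml_px: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """exp(-sigma dt / 2) attenuation factors along one axis (edges only)."""
    sigma = np.zeros(n)
    if pml_px > 0:
        ramp = (np.arange(pml_px, 0, -1) / pml_px) ** 4 * alpha
        sigma[:pml_px] = ramp
        sigma[-pml_px:] = ramp[::-1]
    return np.exp(-sigma / 2.0), sigma


class _Solver:
    """Split-field pseudospectral solver state, reused across time steps.

    The perfectly matched layer lives *outside* the stated window: the
    material grids are edge-padded by ``pml_px`` on every side, so sources
    and targets anywhere in the window stay in the interior. Returned
    fields are cropped back to the window.
    """

    def __init__(self, medium: AcousticMedium, config: SimConfig, f0_hz: float):
        if medium.shape != (config.grid_n, config.grid_n):
            raise ValueError("medium grid does not match config.grid_n")
        pad = config.pml_px
        self.pad = pad
        n = config.grid_n + 2 * pad
        dx = config.dx_m
        self.n = n
        self.rho = np.pad(medium.density, pad, mode="edge")
        self.c = np.pad(medium.speed, pad, mode="edge")
        self.kappa = self.rho * self.c ** 2
        self.dt = _choose_dt(config, float(self.c.max()), f0_hz)

        k = 2 * np.pi * np.fft.fftfreq(n, d=dx)
        if n % 2 == 0:
            # zero the Nyquist bin: an odd-order spectral derivative of a
            # real field has no consistent sign there
            k[n // 2] = 0.0
        # centered spectral derivative operators. A centered (non-staggered)
        # scheme anticommutes exactly with grid reflection, so the solver is
        # mirror-equivariant to rounding error; the usual half-pixel
        # staggering would break that at material interfaces and in the PML.
        self.ddx_pos = (1j * k)[np.newaxis, :]
        self.ddx_neg = (1j * k)[np.newaxis, :]
        self.ddy_pos = (1j * k)[:, np.newaxis]
        self.ddy_neg = (1j * k)[:, np.newaxis]

        px_fac, _ = _pml_profiles(n, config.pml_px, config.pml_alpha)
        self.pml_x = px_fac[np.newaxis, :]
        self.pml_y = px_fac[:, np.newaxis]

        # absorption: dp/dt += -alpha_np c p  ->  spatial decay rate alpha_np
        alpha_np_per_m = np.pad(medium.attenuation_coeff, pad, mode="edge") \
            * (f0_hz / 1e6) * 100.0 * NEPER_PER_DB
        self.abs_fac = np.exp(-alpha_np_per_m * self.c * self.dt)
        self.has_absorption = bool(np.any(alpha_np_per_m > 0))

        self.px = np.zeros((n, n))
        self.py = np.zeros((n, n))
        self.vx = np.zeros((n, n))
        self.vy = np.zeros((n, n))

    def shift_idx(self, idx):
        """Window-frame (rows, cols) index -> padded-frame index."""
        return (idx[0] + self.pad, idx[1] + self.pad)

    def crop(self, arr: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return arr
        return arr[self.pad:-self.pad, self.pad:-self.pad]

    def step(self, source_values: np.ndarray | None, source_idx) -> np.ndarray:
        """Advance one time step; returns the current total pressure field."""
        p = self.px + self.py
        dpdx = np.real(np.fft.ifft(self.ddx_pos * np.fft.fft(p, axis=1), axis=1))
        dpdy = np.real(np.fft.ifft(self.ddy_pos * np.fft.fft(p, axis=0), axis=0))
        self.vx = self.pml_x * (self.pml_x * self.vx - self.dt / self.rho * dpdx)
        self.vy = self.pml_y * (self.pml_y * self.vy - self.dt / self.rho * dpdy)
        dvxdx = np.real(np.fft.ifft(self.ddx_neg * np.fft.fft(self.vx, axis=1), axis=1))
        dvydy = np.real(np.fft.ifft(self.ddy_neg * np.fft.fft(self.vy, axis=0), axis=0))
        self.px = self.pml_x * (self.pml_x * self.px - self.dt * self.kappa * dvxdx)
        self.py = self.pml_y * (self.pml_y * self.py - self.dt * self.kappa * dvydy)
        if source_values is not None:
            self.px[source_idx] += 0.5 * source_values
            self.py[source_idx] += 0.5 * source_values
        if self.has_absorption:
            self.px *= self.abs_fac
            self.py *= self.abs_fac
        return self.px + self.py


def _element_pixel_groups(medium: AcousticMedium, array: ArraySpec) -> list[list[tuple[int, int]]]:
    """Pixels driven by each element: the element center widened to
    ``element_width_mm`` along the array row."""
    centers = element_positions(medium.shape, medium.pixel_spacing_mm,
                                array.n_elements, array.pitch_mm, array.standoff_mm)
    half_w = max(0, int(round(array.element_width_mm / medium.pixel_spacing_mm / 2)))
    groups = []
    for r, c in centers:
        cols = range(max(0, c - half_w), min(medium.shape[1], c + half_w + 1))
        groups.append([(r, cc) for cc in cols])
    return groups


def simulate_forward(
    medium: AcousticMedium,
    array: ArraySpec,
    delays_s: Sequence[float] | np.ndarray,
    config: SimConfig,
    record_rcs: Sequence[tuple[int, int]] | None = None,
) -> PressureField | tuple[PressureField, ElementTraces]:
    """Transmit a delayed 5-cycle burst from every element and record the
    max-amplitude projection.

    ``delays_s`` holds one emission delay per element (seconds). The source
    injects an additive pressure term scaled by c dt / dx per pixel, so the
    drive amplitude tracks ``array.element_pressure_pa`` up to a constant
    calibration factor; all downstream metrics are relative, or compare
    fields produced by this same solver.
    """
    delays = np.asarray(delays_s, dtype=np.float64)
    if delays.shape != (array.n_elements,):
        raise ValueError("delays length must equal n_elements")

    solver = _Solver(medium, config, array.f0_hz)
    dt = solver.dt
    burst_s = array.n_cycles / array.f0_hz
    t_end = config.total_time_s or _auto_time(config, float(medium.speed.min()), burst_s + delays.max())
    n_steps = int(round(t_end / dt))

    groups = _element_pixel_groups(medium, array)
    src_rows = np.array([rc[0] for g in groups for rc in g])
    src_cols = np.array([rc[1] for g in groups for rc in g])
    src_elem = np.array([k for k, g in enumerate(groups) for _ in g])
    src_idx = solver.shift_idx((src_rows, src_cols))
    scale = (medium.speed[src_rows, src_cols] * dt / config.dx_m) * array.element_pressure_pa

    max_p = np.zeros(solver.rho.shape)
    want_traces = record_rcs is not None
    if want_traces:
        rec_idx = solver.shift_idx((np.array([r for r, _ in record_rcs]),
                                    np.array([c for _, c in record_rcs])))
        traces = np.zeros((len(record_rcs), n_steps))

    t_src_end = delays.max() + burst_s + dt
    for i in range(n_steps):
        t = i * dt
        if t <= t_src_end:
            sig = tone_burst(np.full(src_elem.shape, t), array.f0_hz, array.n_cycles,
                             delays[src_elem])
            vals = scale * sig
        else:
            vals = None
        p = solver.step(vals, src_idx)
        np.maximum(max_p, np.abs(p), out=max_p)
        if not np.isfinite(p[0, 0]):
            raise FloatingPointError("solver blew up: unstable configuration")
        if want_traces:
            traces[:, i] = p[rec_idx]

    pf = PressureField(field=solver.crop(max_p), pixel_spacing_mm=medium.pixel_spacing_mm)
    if want_traces:
        return pf, ElementTraces(traces=traces, dt_s=dt)
    return pf


def record_at_elements(
    medium: AcousticMedium,
    source_rc: tuple[int, int],
    array: ArraySpec,
    config: SimConfig,
    amplitude_pa: float = 1.0,
) -> ElementTraces:
    """Emit a test burst from a point source at ``source_rc`` and record the
    pressure arriving at each element (the receive leg of time reversal).

    Each element trace is the pressure averaged over the same pixel group
    that the element drives on transmit, so the receive and transmit legs
    see one another reciprocally even for finite-width elements."""
    r, c = source_rc
    if not (0 <= r < medium.shape[0] and 0 <= c < medium.shape[1]):
        raise ValueError("source outside grid")

    solver = _Solver(medium, config, array.f0_hz)
    dt = solver.dt
    burst_s = array.n_cycles / array.f0_hz
    t_end = config.total_time_s or _auto_time(config, float(medium.speed.min()), burst_s)
    n_steps = int(round(t_end / dt))

    groups = _element_pixel_groups(medium, array)
    rec_rows = np.array([rc[0] for g in groups for rc in g])
    rec_cols = np.array([rc[1] for g in groups for rc in g])
    rec_elem = np.array([k for k, g in enumerate(groups) for _ in g])
    rec_idx = solver.shift_idx((rec_rows, rec_cols))
    counts = np.bincount(rec_elem, minlength=array.n_elements).astype(float)
    src_idx = solver.shift_idx((np.array([r]), np.array([c])))
    scale = float(medium.speed[r, c]) * dt / config.dx_m * amplitude_pa

    traces = np.zeros((array.n_elements, n_steps))
    for i in range(n_steps):
        t = i * dt
        if t <= burst_s + dt:
            vals = np.array([scale * tone_burst(np.array([t]), array.f0_hz, array.n_cycles)[0]])
        else:
            vals = None
        p = solver.step(vals, src_idx)
        traces[:, i] = np.bincount(rec_elem, weights=p[rec_idx],
                                   minlength=array.n_elements) / counts
    return ElementTraces(traces=traces, dt_s=dt)
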