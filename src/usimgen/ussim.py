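"""Pulse-echo simulation and image formation for a convex array.

The chain mirrors a conventional research beamforming pipeline:

1. ``simulate_rf`` — linear pulse-echo model. A single diverging
   transmit wave (virtual source at the array's center of curvature)
   insonifies the medium; each element receives the sum over scatterers
   of a Gaussian-windowed sinusoidal pulse delayed by the two-way travel
   time, weighted by the reflection coefficient, element directivity and
   geometric spreading.
2. ``demodulate_iq`` — mix to complex baseband and low-pass filter.
3. ``das_beamform`` — delay-and-sum with linear delay interpolation and
   baseband phase rotation, on a sector (polar) or Cartesian grid.
4. ``bmode`` — envelope, log compression to a dynamic range in dB,
   affine mapping to [0, 255].
5. ``scan_convert`` — bilinear resampling of the sector image onto a
   Cartesian display grid.

With the virtual source at the center of curvature, the transmit delay
for a point at range r straight ahead of the center element is exactly
r/c, so the round-trip time there is 2r/c.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, signal

from .errors import GeometryError, RangeError, SamplingError
from .scatterers import SOUND_SPEED_M_S, ScattererMap

__all__ = [
    "ProbeSpec",
    "RFFrame",
    "IQFrame",
    "BModeImage",
    "SectorGrid",
    "CartesianGrid",
    "simulate_rf",
    "demodulate_iq",
    "das_beamform",
    "bmode",
    "scan_convert",
]


@dataclass(frozen=True)
class ProbeSpec:
    """Convex-array probe parameters.

    Defaults model a C3-class abdominal probe: 192 elements, 73° field
    of view, 2–6 MHz band (design center frequency 4 MHz), 0.46 mm
    pitch. The curvature radius is chosen so the full aperture arc
    subtends the field of view (≈ 69 mm). ``max_depth`` is the deepest
    range the simulator accepts, not a claim about penetration.
    """

    n_elements: int = 192
    center_freq: float = 4e6
    bandwidth_frac: float = 0.6
    fov: float = 73.0
    max_depth: float = 0.4
    element_pitch: float = 0.46e-3
    curvature_radius: float | None = None
    sampling_freq: float | None = None
    sound_speed: float = SOUND_SPEED_M_S

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if not (0 < self.fov < 180):
            raise ValueError("fov must be in (0, 180) degrees")
        if self.curvature_radius is None:
            arc = self.n_elements * self.element_pitch
            object.__setattr__(
                self, "curvature_radius", float(arc / np.radians(self.fov))
            )
        if self.sampling_freq is None:
            object.__setattr__(
                self,
                "sampling_freq",
                4.0 * self.center_freq * (1.0 + self.bandwidth_frac),
            )
        if self.sampling_freq <= 2 * self.center_freq * (1 + self.bandwidth_frac):
            raise SamplingError(
                "sampling_freq must exceed twice the upper band edge"
            )

    @property
    def wavelength(self) -> float:
        return self.sound_speed / self.center_freq

    def element_positions(self) -> np.ndarray:
        """(n, 2) element centers; the central element touches (0, 0).

        The array lies on a circle of curvature radius R centered at
        (0, -R); elements bulge toward positive z (into the tissue).
        """
        R = self.curvature_radius
        dtheta = self.element_pitch / R
        theta = (np.arange(self.n_elements) - (self.n_elements - 1) / 2) * dtheta
        return np.column_stack([R * np.sin(theta), R * np.cos(theta) - R])

    def element_normals(self) -> np.ndarray:
        R = self.curvature_radius
        dtheta = self.element_pitch / R
        theta = (np.arange(self.n_elements) - (self.n_elements - 1) / 2) * dtheta
        return np.column_stack([np.sin(theta), np.cos(theta)])

    @property
    def virtual_source(self) -> np.ndarray:
        """Transmit virtual source: the center of curvature (0, -R)."""
        return np.array([0.0, -self.curvature_radius])

    @classmethod
    def fast_profile(cls, **overrides) -> "ProbeSpec":
        """Reduced configuration for quick runs and the test suite."""
        defaults = dict(n_elements=32, max_depth=0.08, element_pitch=0.46e-3)
        defaults.update(overrides)
        return cls(**defaults)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({k: float(v) if isinstance(v, (int, float)) and k != "n_elements" else v for k, v in self.__dict__.items()})
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProbeSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RFFrame:
    """Per-element radio-frequency traces for one transmit event."""

    samples: np.ndarray  # (n_elements, n_samples), real
    t0: float
    sampling_freq: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) / self.sampling_freq

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.attrs["t0"] = self.t0
            f.attrs["sampling_freq"] = self.sampling_freq


@dataclass
class IQFrame:
    """Complex baseband traces per element."""

    samples: np.ndarray  # (n_elements, n_samples), complex
    t0: float
    sampling_freq: float
    demod_freq: float


@dataclass
class SectorGrid:
    """Polar beamforming grid tied to a convex probe.

    Rows index range (depth along each scan line, from the probe
    surface), columns index steering angle across the field of view.
    """

    probe: ProbeSpec
    depth: float
    n_range: int = 96
    n_angle: int = 96

    def angles(self) -> np.ndarray:
        half = np.radians(self.probe.fov) / 2.0
        return np.linspace(-half, half, self.n_angle)

    def ranges(self) -> np.ndarray:
        return np.linspace(0.0, self.depth, self.n_range)

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, z) coordinates of every grid node, each (n_range, n_angle)."""
        R = self.probe.curvature_radius
        phi = self.angles()[None, :]
        rr = self.ranges()[:, None] + R
        return rr * np.sin(phi), rr * np.cos(phi) - R

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_range, self.n_angle)


@dataclass
class CartesianGrid:
    """Regular display grid: pixel (row, col) -> physical (x, z) meters."""

    origin: tuple[float, float]  # physical (x, z) of pixel (0, 0)
    spacing: tuple[float, float]  # (dx, dz) meters per pixel
    shape: tuple[int, int]  # (rows, cols)

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        x = self.origin[0] + cols * self.spacing[0]
        z = self.origin[1] + rows * self.spacing[1]
        return x, z

    def physical_to_pixel(self, x, z) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, z) m -> fractional (col, row)."""
        col = (np.asarray(x, float) - self.origin[0]) / self.spacing[0]
        row = (np.asarray(z, float) - self.origin[1]) / self.spacing[1]
        return col, row

    @property
    def spacing_mm(self) -> tuple[float, float]:
        return (self.spacing[0] * 1e3, self.spacing[1] * 1e3)


@dataclass
class BModeImage:
    """Log-compressed display image with its pixel-to-physical mapping."""

    pixels: np.ndarray  # values in [0, 255]
    dynamic_range: float  # dB
    grid: SectorGrid | CartesianGrid | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 255 + 1e-9:
            raise ValueError("pixels must lie in [0, 255]")

    def to_png(self, path: str | Path) -> Path:
        from PIL import Image

        Image.fromarray(np.round(self.pixels).astype(np.uint8)).save(path)
        return Path(path)


def _pulse_sigma(probe: ProbeSpec) -> float:
    """Std of the Gaussian pulse envelope (s) for the -6 dB bandwidth."""
    bandwidth = probe.bandwidth_frac * probe.center_freq
    return np.sqrt(2.0 * np.log(2.0)) / (np.pi * bandwidth)


def pulse_waveform(t: np.ndarray, probe: ProbeSpec) -> np.ndarray:
    """Gaussian-windowed sinusoid at the probe center frequency."""
    sigma = _pulse_sigma(probe)
    return np.exp(-(t**2) / (2 * sigma**2)) * np.sin(2 * np.pi * probe.center_freq * t)


def pulse_halfwidth(probe: ProbeSpec) -> float:
    """Half the effective pulse duration (s); ±4σ support is used."""
    return 4.0 * _pulse_sigma(probe)


def transmit_delays(probe: ProbeSpec, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """One-way transmit time for the diverging wave, zero at the surface."""
    vs = probe.virtual_source
    return (np.hypot(x - vs[0], z - vs[1]) - probe.curvature_radius) / probe.sound_speed


def simulate_rf(
    scat: ScattererMap,
    probe: ProbeSpec,
    tx: str = "diverging",
    attenuation_db_cm_mhz: float = 0.0,
) -> RFFrame:
    """Simulate the received RF traces for one transmit event.

    Linear in the reflection coefficients by construction. Amplitude
    terms: far-field hard-baffle directivity (sinc in the element width),
    1/r spreading on both legs, optional frequency-independent
    attenuation in dB/cm/MHz evaluated at the center frequency.
    """
    if tx != "diverging":
        raise ValueError(f"unsupported transmit scheme {tx!r}")
    fs = probe.sampling_freq
    elems = probe.element_positions()
    normals = probe.element_normals()

    if len(scat):
        depth = (
            np.hypot(*(scat.positions - probe.virtual_source).T)
            - probe.curvature_radius
        )
        if np.any(depth > probe.max_depth + 1e-12):
            raise RangeError(
                f"scatterer at {depth.max() * 1e3:.1f} mm beyond max depth "
                f"{probe.max_depth * 1e3:.1f} mm"
            )

    t_end = 2.0 * probe.max_depth / probe.sound_speed + 2 * pulse_halfwidth(probe)
    n_samples = int(np.ceil(t_end * fs)) + 1
    traces = np.zeros((probe.n_elements, n_samples))
    if not len(scat):
        return RFFrame(traces, 0.0, fs)

    x, z = scat.positions[:, 0], scat.positions[:, 1]
    tau_tx = transmit_delays(probe, x, z)
    r_tx = np.maximum(tau_tx * probe.sound_speed, 1e-3)
    sigma = _pulse_sigma(probe)
    n_tap = int(np.ceil(4 * sigma * fs))
    k = np.arange(-n_tap, n_tap + 1)
    elem_width = 0.9 * probe.element_pitch

    att = 1.0
    if attenuation_db_cm_mhz > 0:
        db = attenuation_db_cm_mhz * (probe.center_freq / 1e6) * (2 * r_tx * 100)
        att = 10 ** (-db / 20.0)

    for e in range(probe.n_elements):
        dvec = scat.positions - elems[e]
        r_rx = np.maximum(np.hypot(dvec[:, 0], dvec[:, 1]), 1e-3)
        tau = tau_tx + r_rx / probe.sound_speed
        # angle of arrival relative to the element normal
        sin_phi = np.clip(
            (dvec[:, 0] * normals[e, 1] - dvec[:, 1] * normals[e, 0]) / r_rx,
            -1.0,
            1.0,
        )
        directivity = np.sinc(elem_width / probe.wavelength * sin_phi)
        amp = scat.coeffs * directivity * att / (r_tx * r_rx)
        base = np.round(tau * fs).astype(int)
        idx = base[:, None] + k[None, :]
        tt = idx / fs - tau[:, None]
        w = amp[:, None] * pulse_waveform(tt, probe)
        idx_flat = idx.ravel()
        valid = (idx_flat >= 0) & (idx_flat < n_samples)
        traces[e] = np.bincount(
            idx_flat[valid], weights=w.ravel()[valid], minlength=n_samples
        )
    return RFFrame(traces, 0.0, fs)


def demodulate_iq(rf: RFFrame, demod_freq: float | None = None) -> IQFrame:
    """Mix RF to complex baseband and low-pass filter.

    ``demod_freq`` defaults to the dominant band center implied by the
    sampling setup (fs / (4 (1 + bw)) is not recoverable from the frame
    alone, so pass the probe center frequency explicitly in pipelines).
    """
    if demod_freq is None:
        raise ValueError("demod_freq is required")
    if demod_freq <= 0:
        raise ValueError("demod_freq must be positive")
    if demod_freq >= rf.sampling_freq / 2:
        raise ValueError("demod_freq must be below Nyquist")
    t = rf.times[None, :]
    mixed = rf.samples * np.exp(-2j * np.pi * demod_freq * t)
    cutoff = 0.8 * demod_freq / (rf.sampling_freq / 2)
    b, a = signal.butter(5, cutoff)
    iq = 2.0 * signal.filtfilt(b, a, mixed, axis=1)
    return IQFrame(iq, rf.t0, rf.sampling_freq, demod_freq)


def das_beamform(
    iq: IQFrame,
    probe: ProbeSpec,
    grid: SectorGrid | CartesianGrid,
) -> np.ndarray:
    """Delay-and-sum the baseband data onto an image grid.

    For every pixel, the IQ trace of each element is linearly
    interpolated at the two-way travel time (diverging-wave transmit leg
    plus receive leg), phase-rotated back to RF by the demodulation
    frequency, and summed across the aperture. Returns a complex image
    with the grid's shape.
    """
    x, z = grid.points()
    vs = probe.virtual_source
    rng_from_surface = np.hypot(x - vs[0], z - vs[1]) - probe.curvature_radius
    if np.any(rng_from_surface < -1e-9) or np.any(
        rng_from_surface > probe.max_depth + 1e-9
    ):
        raise GeometryError("grid extends outside the probe's depth range")
    ang = np.degrees(np.arctan2(x - vs[0], z - vs[1]))
    if np.any(np.abs(ang) > probe.fov / 2.0 + 1e-6):
        raise GeometryError("grid extends outside the probe's sector")

    tau_tx = rng_from_surface / probe.sound_speed
    elems = probe.element_positions()
    sample_t = iq.t0 + np.arange(iq.samples.shape[1]) / iq.sampling_freq
    flat_x, flat_z, flat_tx = x.ravel(), z.ravel(), tau_tx.ravel()
    acc = np.zeros(flat_x.shape, dtype=complex)
    for e in range(probe.n_elements):
        tau = flat_tx + np.hypot(flat_x - elems[e, 0], flat_z - elems[e, 1]) / probe.sound_speed
        re = np.interp(tau, sample_t, iq.samples[e].real, left=0.0, right=0.0)
        im = np.interp(tau, sample_t, iq.samples[e].imag, left=0.0, right=0.0)
        acc += (re + 1j * im) * np.exp(2j * np.pi * iq.demod_freq * tau)
    return acc.reshape(x.shape)


def bmode(
    beamformed: np.ndarray,
    dynamic_range: float = 30.0,
    grid: SectorGrid | CartesianGrid | None = None,
) -> BModeImage:
    """Envelope-detect, log-compress and map to 8-bit display values.

    dB = 20 log10(env / max(env)), clipped to [-DR, 0] and mapped
    affinely onto [0, 255]; the maximum-envelope pixel maps to 255 and
    anything at or below -DR dB maps to 0. An all-zero input yields an
    all-black image.
    """
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    env = np.abs(np.asarray(beamformed))
    peak = env.max()
    if peak == 0.0:
        return BModeImage(np.zeros(env.shape), dynamic_range, grid)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    db = np.clip(db, -dynamic_range, 0.0)
    return BModeImage((db / dynamic_range + 1.0) * 255.0, dynamic_range, grid)


def scan_convert(
    image: BModeImage,
    probe: ProbeSpec,
    out_shape: tuple[int, int],
) -> BModeImage:
    """Resample a sector-grid image onto a Cartesian display grid.

    Bilinear interpolation; pixels outside the sector are set to 0. If
    the image already sits on a Cartesian grid of the requested shape it
    is returned unchanged (copy).
    """
    if out_shape[0] < 2 or out_shape[1] < 2:
        raise ValueError("out_shape must be at least 2x2")
    if isinstance(image.grid, CartesianGrid):
        if tuple(image.pixels.shape) != tuple(out_shape):
            raise ValueError("Cartesian input must already match out_shape")
        return BModeImage(image.pixels.copy(), image.dynamic_range, image.grid)
    if not isinstance(image.grid, SectorGrid):
        raise ValueError("scan_convert needs an image with a SectorGrid")

    sector: SectorGrid = image.grid
    half = np.radians(probe.fov) / 2.0
    R = probe.curvature_radius
    depth = sector.depth
    x_max = (R + depth) * np.sin(half)
    z_min = R * np.cos(half) - R  # edge elements sit above z=0
    z_max = depth
    rows, cols = out_shape
    dx = 2 * x_max / (cols - 1)
    dz = (z_max - z_min) / (rows - 1)
    cart = CartesianGrid(origin=(-x_max, z_min), spacing=(dx, dz), shape=out_shape)

    x, z = cart.points()
    vs = probe.virtual_source
    rr = np.hypot(x - vs[0], z - vs[1]) - R
    phi = np.arctan2(x - vs[0], z - vs[1])
    r_idx = rr / depth * (sector.n_range - 1)
    a_idx = (phi + half) / (2 * half) * (sector.n_angle - 1)
    out = ndimage.map_coordinates(
        image.pixels, [r_idx, a_idx], order=1, mode="constant", cval=0.0
    )
    inside = (rr >= 0) & (rr <= depth) & (np.abs(phi) <= half)
    out = np.where(inside, out, 0.0)
    return BModeImage(out, image.dynamic_range, cart)
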