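"""Point-scatterer maps: tissue background and needle.

The background map is drawn from a template image — random pixels become
point scatterers whose reflection coefficient is the (normalized) pixel
intensity, so bright template structures are echogenic. The needle is a
thin rectangle of denser, stronger scatterers along a straight in-plane
insertion trajectory. Coordinates are (lateral x, axial z) in meters
with z >= 0 pointing away from the probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .errors import GeometryError, OversamplingError
from .preprocess import TemplateImage

__all__ = [
    "ScattererMap",
    "NeedleSpec",
    "wavelength_m",
    "sample_background",
    "make_needle_scatterers",
    "needle_trajectory",
    "merge",
]

SOUND_SPEED_M_S = 1540.0


def wavelength_m(center_freq_hz: float, sound_speed: float = SOUND_SPEED_M_S) -> float:
    """Acoustic wavelength for a design center frequency."""
    return sound_speed / center_freq_hz


@dataclass
class ScattererMap:
    """Point scatterers with reflection coefficients.

    ``positions`` is (n, 2) — lateral x and axial z in meters; ``coeffs``
    is (n,) dimensionless and non-negative.
    """

    positions: np.ndarray
    coeffs: np.ndarray
    part_tag: str = "background"  # background | needle | merged

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(-1)
        if len(self.positions) != len(self.coeffs):
            raise ValueError("positions and coeffs must have equal length")
        if np.any(self.coeffs < 0):
            raise ValueError("reflection coefficients must be >= 0")
        if len(self.positions) and np.any(self.positions[:, 1] < 0):
            raise ValueError("axial positions must be >= 0")

    def __len__(self) -> int:
        return len(self.coeffs)

    @classmethod
    def empty(cls, part_tag: str = "background") -> "ScattererMap":
        return cls(np.empty((0, 2)), np.empty(0), part_tag)

    def to_hdf5(self, path: str | Path, **metadata) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("coeffs", data=self.coeffs)
            f.attrs["part_tag"] = self.part_tag
            for k, v in metadata.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ScattererMap":
        with h5py.File(path, "r") as f:
            return cls(
                f["positions"][()], f["coeffs"][()], str(f.attrs["part_tag"])
            )


@dataclass
class NeedleSpec:
    """Geometry of a rigid biopsy needle inserted in the imaging plane.

    ``insertion_angle`` is measured in degrees from the lateral (x) axis,
    positive downward (into the tissue); the trajectory direction is
    ``(cos θ, sin θ)`` in the (x, z) plane.
    """

    length_mm: float = 200.0
    diameter_mm: float = 1.52
    entry_point_m: tuple[float, float] = (0.0, 0.0)
    insertion_angle_deg: float = 45.0
    insertion_depth_mm: float = 60.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("needle length and diameter must be positive")
        if not (0 < self.insertion_angle_deg < 90):
            raise ValueError("insertion angle must be in (0, 90) degrees")
        if self.insertion_depth_mm > self.length_mm:
            raise ValueError("insertion depth cannot exceed needle length")

    @property
    def direction(self) -> np.ndarray:
        a = np.radians(self.insertion_angle_deg)
        return np.array([np.cos(a), np.sin(a)])


def sample_background(
    template: TemplateImage,
    density: float = 6.0,
    wavelength: float = wavelength_m(4e6),
    seed: int | np.random.SeedSequence | None = None,
) -> ScattererMap:
    """Draw background scatterers from a template image.

    The number of scatterers is Poisson with mean
    ``density * area / wavelength**2`` where the area is that of the
    template's valid field of view (the whole pixel grid when no FOV mask
    is set). Source pixels are drawn without replacement, each scatterer
    gets a uniform sub-pixel jitter, and its reflection coefficient is
    the pixel intensity.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    rng = np.random.default_rng(seed)
    if template.fov_mask is not None:
        candidates = np.argwhere(template.fov_mask)
    else:
        h, w = template.shape
        candidates = np.argwhere(np.ones((h, w), dtype=bool))
    pixel_area_m2 = (template.spacing[0] * 1e-3) * (template.spacing[1] * 1e-3)
    area_m2 = len(candidates) * pixel_area_m2
    mean = density * area_m2 / wavelength**2
    if mean == 0:
        return ScattererMap.empty("background")
    if mean > len(candidates):
        raise OversamplingError(
            f"expected count {mean:.0f} exceeds {len(candidates)} source pixels"
        )
    n = min(int(rng.poisson(mean)), len(candidates))
    take = rng.choice(len(candidates), size=n, replace=False)
    rows = candidates[take, 0].astype(float)
    cols = candidates[take, 1].astype(float)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    x, z = template.pixel_to_physical(cols + jitter[:, 0], rows + jitter[:, 1])
    coeffs = template.pixels[candidates[take, 0], candidates[take, 1]]
    return ScattererMap(
        np.column_stack([x, np.clip(z, 0.0, None)]), coeffs, "background"
    )


def make_needle_scatterers(
    needle: NeedleSpec,
    tip_m: tuple[float, float],
    density: float = 10.0,
    wavelength: float = wavelength_m(4e6),
    cb_max: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> ScattererMap:
    """Scatterers filling the inserted part of the needle.

    The inserted part is the rectangle from the entry point to ``tip_m``
    (width = needle diameter). Coefficients are drawn uniformly in
    ``[cb_max / 4, cb_max]`` — strong relative to the background maximum
    ``cb_max``, which is what renders the shaft bright.
    """
    if cb_max <= 0:
        raise ValueError("cb_max must be positive")
    rng = np.random.default_rng(seed)
    entry = np.asarray(needle.entry_point_m, dtype=float)
    tip = np.asarray(tip_m, dtype=float)
    delta = tip - entry
    length_m = float(np.linalg.norm(delta))
    if length_m == 0.0:
        return ScattererMap.empty("needle")
    direction = delta / length_m
    if float(direction @ needle.direction) < 1.0 - 1e-6:
        raise GeometryError("tip must lie on the insertion trajectory, past entry")
    width_m = needle.diameter_mm * 1e-3
    mean = density * length_m * width_m / wavelength**2
    n = int(rng.poisson(mean))
    if n == 0:
        return ScattererMap.empty("needle")
    u = rng.uniform(0.0, length_m, size=n)
    v = rng.uniform(-width_m / 2.0, width_m / 2.0, size=n)
    perp = np.array([-direction[1], direction[0]])
    pos = entry[None, :] + u[:, None] * direction[None, :] + v[:, None] * perp[None, :]
    pos[:, 1] = np.clip(pos[:, 1], 0.0, None)
    coeffs = rng.uniform(cb_max / 4.0, cb_max, size=n)
    return ScattererMap(pos, coeffs, "needle")


def needle_trajectory(needle: NeedleSpec, n_steps: int = 48) -> np.ndarray:
    """Equally spaced tip positions along the straight insertion line.

    Returns an (n_steps, 2) array in meters; the first tip is the entry
    point and the last is at the full insertion depth.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    entry = np.asarray(needle.entry_point_m, dtype=float)
    end = entry + needle.insertion_depth_mm * 1e-3 * needle.direction
    frac = np.linspace(0.0, 1.0, n_steps)[:, None]
    return entry[None, :] * (1 - frac) + end[None, :] * frac


def merge(background: ScattererMap, needle: ScattererMap) -> ScattererMap:
    """Concatenate the background and needle maps (same coordinate frame)."""
    return ScattererMap(
        np.vstack([background.positions, needle.positions]),
        np.concatenate([background.coeffs, needle.coeffs]),
        "merged",
    )
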