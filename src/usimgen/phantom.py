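"""Synthetic 3D phantoms emulating preoperative clinical recordings.

Downstream stages only consume voxel intensities as echogenicity, so the
generators aim for the *statistical* features that matter to ultrasound
simulation — texture, contrast, target morphology — not anatomical
realism. Three phantoms are provided:

* a liver-like volume with embedded high-contrast quasi-spherical
  lesions (CT-phantom-like), with masks for a subset of them;
* a heart-like volume with a single low-contrast target whose
  cross-section changes shape from slice to slice (MRI-like);
* a fiducial layout of spherical targets in a box, used by the
  calibration / aiming experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionError, PlacementError

__all__ = [
    "Volume3D",
    "FiducialLayout",
    "make_lesion_volume",
    "make_heart_like_volume",
    "make_fiducial_layout",
    "save_volume",
    "load_volume",
]


@dataclass
class Volume3D:
    """A voxel volume with physical spacing and named binary label masks.

    Parameters
    ----------
    voxels : ndarray, shape (n0, n1, n2)
        Scalar intensities in arbitrary units.
    spacing : tuple of float
        Voxel size (d0, d1, d2) in mm along each array axis.
    labels : dict of str -> ndarray of bool
        Binary masks, each with the same shape as ``voxels``.
    modality_tag : str
        Free-text provenance tag (e.g. ``"synthetic-ct-like"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    modality_tag: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise DimensionError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        for name, mask in self.labels.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.voxels.shape:
                raise ValueError(
                    f"label {name!r} shape {mask.shape} != voxel shape "
                    f"{self.voxels.shape}"
                )
            self.labels[name] = mask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class FiducialLayout:
    """Spherical fiducial targets inside a rectangular extent (all mm)."""

    centers: np.ndarray  # (n, 3) mm
    diameters: np.ndarray  # (n,) mm
    extent: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")
        ext = np.asarray(self.extent, dtype=float)
        if np.any(self.centers < 0) or np.any(self.centers > ext):
            raise ValueError("all centers must lie inside the extent")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "units": "mm",
            "centers": self.centers.tolist(),
            "diameters": self.diameters.tolist(),
            "extent": list(self.extent),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FiducialLayout":
        payload = json.loads(Path(path).read_text())
        return cls(
            centers=np.asarray(payload["centers"], dtype=float),
            diameters=np.asarray(payload["diameters"], dtype=float),
            extent=tuple(payload["extent"]),
        )


def _band_limited_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sigma_vox: float,
    mean: float,
    std: float,
) -> np.ndarray:
    """Smoothed white noise: the generic soft-tissue echogenicity texture."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma_vox)
    smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    return np.clip(mean + std * smooth, 0.0, None)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    q = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm)
    )
    return q <= 1.0


def make_lesion_volume(
    n_lesions: int = 6,
    n_labeled: int = 2,
    shape: tuple[int, int, int] = (48, 96, 96),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    contrast: float = 2.5,
    seed: int | np.random.SeedSequence | None = 0,
    diameter_range_mm: tuple[float, float] = (8.0, 14.0),
    max_retries: int = 500,
) -> Volume3D:
    """Liver-like textured volume with quasi-spherical inclusions.

    The background is band-limited noise; each lesion is an ellipsoid with
    volume-preserving axis jitter (axis ratios within 20% of a sphere)
    whose mean intensity is ``contrast`` times the background mean.
    Masks are emitted for the first ``n_labeled`` lesions, mirroring
    source datasets in which only a subset of the lesions is annotated.

    Raises
    ------
    PlacementError
        If a lesion cannot be placed without overlap after bounded retries.
    """
    if n_labeled > n_lesions:
        raise ValueError("n_labeled must not exceed n_lesions")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    rng = np.random.default_rng(seed)

    bg_mean, bg_std = 0.35, 0.08
    voxels = _band_limited_noise(rng, shape, sigma_vox=1.5, mean=bg_mean, std=bg_std)
    extent_mm = np.array([n * s for n, s in zip(shape, spacing)])

    placed: list[tuple[np.ndarray, float]] = []  # (center_mm, radius_mm)
    labels: dict[str, np.ndarray] = {}
    for i in range(n_lesions):
        diameter = rng.uniform(*diameter_range_mm)
        radius = diameter / 2.0
        # volume-preserving jitter: a1*a2*a3 == r^3 keeps the analytic
        # sphere volume exact so mask voxel counts track (4/3)*pi*r^3
        j1, j2 = rng.uniform(0.9, 1.1, size=2)
        semi_axes = radius * np.array([j1, j2, 1.0 / (j1 * j2)])
        for attempt in range(max_retries):
            margin = semi_axes.max() + 1.0
            if np.any(extent_mm <= 2 * margin):
                raise PlacementError(
                    f"volume extent too small to place lesion {i}"
                )
            center = rng.uniform(margin, extent_mm - margin)
            if all(
                np.linalg.norm(center - c) > radius + r + 2.0
                for c, r in placed
            ):
                break
        else:
            raise PlacementError(
                f"could not place lesion {i} after {max_retries} retries"
            )
        placed.append((center, radius))
        mask = _ellipsoid_mask(shape, spacing, center, semi_axes)
        texture = _band_limited_noise(
            rng, shape, sigma_vox=1.5, mean=bg_mean * contrast, std=bg_std
        )
        voxels[mask] = texture[mask]
        if i < n_labeled:
            labels[f"lesion_{i}"] = mask

    return Volume3D(voxels, tuple(spacing), labels, modality_tag="synthetic-ct-like")


def make_heart_like_volume(
    shape: tuple[int, int, int] = (32, 96, 96),
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0),
    seed: int | np.random.SeedSequence | None = 0,
    contrast_bound: float = 1.3,
    target_label: str = "target",
    n_target_slices: int = 16,
) -> Volume3D:
    """Low-contrast volume with a heterogeneous, slice-varying target.

    Emulates a cardiac-chamber-like structure: across consecutive slices
    along axis 0 the target cross-section drifts, dilates and changes
    outline (low-order angular harmonics with slowly varying
    coefficients). Target intensity stays below ``contrast_bound`` times
    the background mean, so the target is a low-contrast detection
    benchmark rather than a bright inclusion.
    """
    if shape[0] < 8:
        raise DimensionError("need at least 8 slices along the slicing axis")
    n_target_slices = min(n_target_slices, shape[0])
    if n_target_slices < 8:
        raise DimensionError("target must span at least 8 slices")
    rng = np.random.default_rng(seed)

    bg_mean, bg_std = 0.35, 0.08
    voxels = _band_limited_noise(rng, shape, sigma_vox=1.5, mean=bg_mean, std=bg_std)

    start = (shape[0] - n_target_slices) // 2
    rows, cols = np.mgrid[0 : shape[1], 0 : shape[2]]
    base_center = np.array([shape[1] * 0.45, shape[2] * 0.5])
    base_radius_mm = 0.18 * min(shape[1] * spacing[1], shape[2] * spacing[2])

    # slowly varying harmonic coefficients -> outlines differ per slice
    n_harm = 3
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    amp_walk = rng.normal(0.0, 0.05, size=(n_target_slices, n_harm)).cumsum(axis=0)
    amps = np.clip(0.15 + amp_walk, 0.05, 0.35)
    drift = rng.normal(0.0, 1.2, size=(n_target_slices, 2)).cumsum(axis=0)
    breathe = 1.0 + 0.25 * np.sin(
        np.linspace(0, 2.2 * np.pi, n_target_slices) + rng.uniform(0, np.pi)
    )

    mask = np.zeros(shape, dtype=bool)
    for k in range(n_target_slices):
        c = base_center + drift[k]
        dy = (rows - c[0]) * spacing[1]
        dx = (cols - c[1]) * spacing[2]
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        boundary = base_radius_mm * breathe[k]
        for h in range(n_harm):
            boundary = boundary * (
                1.0 + amps[k, h] * 0.3 * np.cos((h + 2) * theta + phases[h])
            )
        sl = r <= boundary
        # keep the largest connected blob only
        lab, n = ndimage.label(sl)
        if n > 1:
            sizes = ndimage.sum(sl, lab, index=range(1, n + 1))
            sl = lab == (1 + int(np.argmax(sizes)))
        mask[start + k] = sl

    target_mean = bg_mean * min(contrast_bound, 1.25)
    texture = _band_limited_noise(rng, shape, sigma_vox=1.5, mean=target_mean, std=bg_std)
    voxels[mask] = texture[mask]
    return Volume3D(
        voxels,
        tuple(spacing),
        {target_label: mask},
        modality_tag="synthetic-mri-like",
    )


def make_fiducial_layout(
    n_targets: int = 9,
    mean_diameter_mm: float = 8.1,
    extent_mm: tuple[float, float, float] = (130.0, 80.0, 90.0),
    seed: int | np.random.SeedSequence | None = 0,
    diameter_sd_mm: float = 0.3,
    max_retries: int = 2000,
) -> FiducialLayout:
    """Random non-overlapping spherical fiducials inside a box.

    A single fiducial is placed at the box center; multiple fiducials are
    drawn uniformly with non-overlap rejection. Sampled diameters are
    normal around ``mean_diameter_mm`` with a small spread, so the sample
    mean stays within a few percent of the nominal value.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    ext = np.asarray(extent_mm, dtype=float)
    diameters = np.clip(
        rng.normal(mean_diameter_mm, diameter_sd_mm, size=n_targets),
        0.5 * mean_diameter_mm,
        1.5 * mean_diameter_mm,
    )
    if np.any(ext <= diameters.max()):
        raise PlacementError("extent too small for the fiducial diameters")

    if n_targets == 1:
        centers = np.array([ext / 2.0])
        return FiducialLayout(centers, diameters, tuple(extent_mm))

    centers: list[np.ndarray] = []
    for i, d in enumerate(diameters):
        r = d / 2.0
        for _ in range(max_retries):
            c = rng.uniform(r, ext - r)
            if all(
                np.linalg.norm(c - cj) > r + diameters[j] / 2.0
                for j, cj in enumerate(centers)
            ):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place fiducial {i} after {max_retries} retries"
            )
    return FiducialLayout(np.array(centers), diameters, tuple(extent_mm))


def save_volume(volume: Volume3D, path: str | Path) -> list[Path]:
    """Write a volume as NIfTI plus one NIfTI mask file per label.

    ``path`` is the main image file (``.nii`` or ``.nii.gz``); each label
    goes to ``<stem>_label_<name>`` next to it. Returns written paths.
    """
    path = Path(path)
    affine = np.diag([*volume.spacing, 1.0])
    written = [path]
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))
    suffix = "".join(path.suffixes)
    stem = path.name[: -len(suffix)] if suffix else path.name
    for name, mask in volume.labels.items():
        p = path.with_name(f"{stem}_label_{name}{suffix}")
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(p))
        written.append(p)
    return written


def load_volume(path: str | Path, modality_tag: str = "") -> Volume3D:
    """Read a NIfTI volume and any ``<stem>_label_*`` masks next to it."""
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    suffix = "".join(path.suffixes)
    stem = path.name[: -len(suffix)] if suffix else path.name
    labels = {}
    for p in sorted(path.parent.glob(f"{stem}_label_*{suffix}")):
        name = p.name[len(stem) + len("_label_") : -len(suffix)]
        labels[name] = np.asanyarray(nib.load(str(p)).dataobj).astype(bool)
    return Volume3D(
        np.asanyarray(img.dataobj).astype(float), spacing, labels, modality_tag
    )
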