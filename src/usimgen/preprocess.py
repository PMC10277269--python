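"""Slice selection and field-of-view cropping for speckle templates.

Converts an annotated 3D volume into the 2D gray-scale template images
whose intensities drive the background scatterer reflection
coefficients. Pixel conventions used throughout the package: 0-based,
origin top-left, x lateral (columns), y axial/depth (rows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import EmptyTargetError, GeometryError, UnknownLabelError
from .phantom import Volume3D

__all__ = [
    "TemplateImage",
    "extract_salient_slices",
    "select_visible_slices",
    "resample_template",
    "crop_to_fov",
    "save_template",
    "load_template",
]


@dataclass
class TemplateImage:
    """A pre-processed 2D gray-scale slice used as echogenicity template.

    Attributes
    ----------
    pixels : ndarray (rows, cols)
        Intensities normalized to [0, 1].
    spacing : (lateral, axial) mm per pixel.
    target_masks : dict label -> binary mask, same shape as ``pixels``.
    source_index : slice index in the source volume.
    apex_px : (col, row) position of the ultrasound sector apex; the
        physical origin for scatterer coordinates. Defaults to top-center.
    fov_mask : optional binary mask of the valid field of view; ``None``
        means the whole image is valid.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    target_masks: dict[str, np.ndarray] = field(default_factory=dict)
    source_index: int = 0
    apex_px: tuple[float, float] | None = None
    fov_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixels must be normalized to [0, 1]")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name, m in self.target_masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.pixels.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            self.target_masks[name] = m
        if self.apex_px is None:
            self.apex_px = ((self.pixels.shape[1] - 1) / 2.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def physical_extent_mm(self) -> tuple[float, float]:
        """(width, height) of the pixel grid in mm."""
        return (
            self.pixels.shape[1] * self.spacing[0],
            self.pixels.shape[0] * self.spacing[1],
        )

    def pixel_to_physical(self, cols: np.ndarray, rows: np.ndarray):
        """Pixel indices -> (x, z) meters relative to the apex."""
        ax, ay = self.apex_px
        x = (np.asarray(cols, float) - ax) * self.spacing[0] * 1e-3
        z = (np.asarray(rows, float) - ay) * self.spacing[1] * 1e-3
        return x, z


def _window_slices(volume: Volume3D, axis: int, index: int) -> np.ndarray:
    return np.take(volume.voxels, index, axis=axis)


def extract_salient_slices(
    volume: Volume3D,
    target_label: str,
    n_slices: int = 8,
    axis: int = 0,
) -> list[TemplateImage]:
    """Pick the contiguous window of slices where the target is most visible.

    Saliency of a window is the total target-mask area it contains; the
    returned window maximizes it over all contiguous candidates.
    Intensities are min-max normalized jointly over the window so
    echogenicity is comparable across the dynamic sequence.
    """
    if target_label not in volume.labels:
        raise UnknownLabelError(
            f"label {target_label!r} not in volume (has {sorted(volume.labels)})"
        )
    mask3d = volume.labels[target_label]
    if not mask3d.any():
        raise EmptyTargetError(f"label {target_label!r} is empty everywhere")
    n_total = volume.shape[axis]
    if n_total < n_slices:
        raise ValueError(f"volume has {n_total} slices < n_slices={n_slices}")

    other_axes = tuple(a for a in range(3) if a != axis)
    areas = mask3d.sum(axis=other_axes)
    window_sums = np.convolve(areas, np.ones(n_slices, dtype=int), mode="valid")
    start = int(np.argmax(window_sums))

    window = np.stack(
        [_window_slices(volume, axis, i) for i in range(start, start + n_slices)]
    )
    lo, hi = window.min(), window.max()
    scale = hi - lo if hi > lo else 1.0
    lateral_axis, axial_axis = other_axes[1], other_axes[0]
    spacing = (volume.spacing[lateral_axis], volume.spacing[axial_axis])

    out = []
    for k, i in enumerate(range(start, start + n_slices)):
        masks = {
            name: np.take(m, i, axis=axis)
            for name, m in volume.labels.items()
            if np.take(m, i, axis=axis).any()
        }
        out.append(
            TemplateImage(
                pixels=(window[k] - lo) / scale,
                spacing=spacing,
                target_masks=masks,
                source_index=i,
            )
        )
    return out


def select_visible_slices(
    volume: Volume3D,
    n_slices: int,
    axis: int = 0,
    labels: list[str] | None = None,
) -> list[TemplateImage]:
    """Pick the ``n_slices`` (not necessarily contiguous) slices where the
    union of the given labels is most visible — one template per slice,
    each normalized independently. Used when every intervention runs on a
    single static background slice.
    """
    names = labels if labels is not None else sorted(volume.labels)
    for n in names:
        if n not in volume.labels:
            raise UnknownLabelError(f"label {n!r} not in volume")
    union = np.zeros(volume.shape, dtype=bool)
    for n in names:
        union |= volume.labels[n]
    if not union.any():
        raise EmptyTargetError("no labeled voxels in the volume")
    other_axes = tuple(a for a in range(3) if a != axis)
    areas = union.sum(axis=other_axes)
    order = np.argsort(areas)[::-1][:n_slices]
    if len(order) < n_slices or areas[order[-1]] == 0:
        raise ValueError(f"only {int((areas > 0).sum())} slices show a label")
    lateral_axis, axial_axis = other_axes[1], other_axes[0]
    spacing = (volume.spacing[lateral_axis], volume.spacing[axial_axis])
    out = []
    for i in sorted(int(i) for i in order):
        sl = _window_slices(volume, axis, i)
        lo, hi = sl.min(), sl.max()
        scale = hi - lo if hi > lo else 1.0
        masks = {
            name: np.take(m, i, axis=axis)
            for name, m in volume.labels.items()
            if np.take(m, i, axis=axis).any()
        }
        out.append(
            TemplateImage((sl - lo) / scale, spacing, masks, source_index=i)
        )
    return out


def resample_template(template: TemplateImage, factor: int) -> TemplateImage:
    """Upsample a template to a finer pixel pitch (bilinear; masks nearest).

    Scatterer sampling draws source *pixels*, so the pixel grid must be
    finer than the requested scatterer spacing; coarse voxel grids
    (~1 mm) are upsampled before sampling at several scatterers per
    squared wavelength.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return template
    pixels = ndimage.zoom(template.pixels, factor, order=1)
    pixels = np.clip(pixels, 0.0, 1.0)
    masks = {
        name: ndimage.zoom(m.astype(np.uint8), factor, order=0).astype(bool)
        for name, m in template.target_masks.items()
    }
    fov = None
    if template.fov_mask is not None:
        fov = ndimage.zoom(
            template.fov_mask.astype(np.uint8), factor, order=0
        ).astype(bool)
    ax, ay = template.apex_px
    return TemplateImage(
        pixels=pixels,
        spacing=(template.spacing[0] / factor, template.spacing[1] / factor),
        target_masks=masks,
        source_index=template.source_index,
        apex_px=(ax * factor, ay * factor),
        fov_mask=fov,
    )


def crop_to_fov(
    template: TemplateImage,
    fov_deg: float = 73.0,
    depth_mm: float = 45.0,
    apex_px: tuple[float, float] | None = None,
) -> TemplateImage:
    """Zero everything outside a circular sector (the ultrasound FOV).

    The sector opens downward from ``apex_px`` with half-angle
    ``fov_deg / 2`` and radius ``depth_mm``. Masks are cropped
    identically; spacing is preserved. Idempotent.
    """
    if not (0 < fov_deg < 180):
        raise ValueError("fov_deg must be in (0, 180)")
    if depth_mm <= 0:
        raise ValueError("depth_mm must be positive")
    h, w = template.shape
    ax, ay = apex_px if apex_px is not None else ((w - 1) / 2.0, 0.0)
    if not (0 <= ax <= w - 1 and 0 <= ay <= h - 1):
        raise GeometryError(f"apex {(ax, ay)} outside image {w}x{h}")

    rows, cols = np.mgrid[0:h, 0:w]
    dx = (cols - ax) * template.spacing[0]
    dy = (rows - ay) * template.spacing[1]
    r = np.hypot(dx, dy)
    # angle from the downward (axial) direction
    ang = np.degrees(np.abs(np.arctan2(dx, dy)))
    sector = (dy >= 0) & (r <= depth_mm) & (ang <= fov_deg / 2.0)

    return TemplateImage(
        pixels=np.where(sector, template.pixels, 0.0),
        spacing=template.spacing,
        target_masks={
            name: m & sector for name, m in template.target_masks.items()
        },
        source_index=template.source_index,
        apex_px=(ax, ay),
        fov_mask=sector,
    )


def save_template(template: TemplateImage, png_path: str | Path) -> Path:
    """Write the template as 16-bit PNG with a JSON sidecar of metadata."""
    png_path = Path(png_path)
    arr = np.round(template.pixels * 65535).astype(np.uint16)
    Image.fromarray(arr).save(png_path)
    sidecar = {
        "spacing_mm_per_px": list(template.spacing),
        "apex_px": list(template.apex_px),
        "source_index": template.source_index,
        "masks": {
            name: np.argwhere(m).tolist()
            for name, m in template.target_masks.items()
        },
        "has_fov_mask": template.fov_mask is not None,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar))
    return png_path


def load_template(png_path: str | Path) -> TemplateImage:
    png_path = Path(png_path)
    arr = np.asarray(Image.open(png_path), dtype=float) / 65535.0
    meta = json.loads(png_path.with_suffix(".json").read_text())
    masks = {}
    for name, idx in meta["masks"].items():
        m = np.zeros(arr.shape, dtype=bool)
        if idx:
            ij = np.asarray(idx)
            m[ij[:, 0], ij[:, 1]] = True
        masks[name] = m
    return TemplateImage(
        pixels=arr,
        spacing=tuple(meta["spacing_mm_per_px"]),
        target_masks=masks,
        source_index=meta["source_index"],
        apex_px=tuple(meta["apex_px"]),
    )
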