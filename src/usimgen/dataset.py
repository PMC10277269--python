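"""Dynamic intervention sequences, annotations, and dataset export.

An *intervention* is one simulated needle insertion: a short template
sequence supplies the (possibly moving) background, the needle tip
advances along its straight trajectory frame by frame, and every frame
is rendered once per requested dynamic range. Annotations follow the
convention used to train small-object detectors on these images: the
needle tip sits exactly at the *left-bottom corner* of its bounding box
(display coordinates, y down — corner = (min-x, max-y)), and the box
side is between 20 and 30 pixels; target boxes are the tight axis-
aligned boxes of the transformed masks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import scatterers as sc
from . import ussim
from .errors import BorderError, EmptyDatasetError
from .preprocess import TemplateImage

__all__ = [
    "Annotation",
    "FrameRecord",
    "DatasetManifest",
    "annotate_needle",
    "annotate_target",
    "build_intervention",
    "export_coco",
    "read_coco",
    "split",
]

log = logging.getLogger(__name__)

NEEDLE_BOX_MIN = 20
NEEDLE_BOX_MAX = 30


@dataclass
class Annotation:
    """One object annotation in pixel coordinates.

    ``bbox`` = (x, y, w, h) with (x, y) the top-left corner (columns,
    rows). For needles the tip is the box's left-bottom corner, i.e.
    ``tip_px == (x, y + h)``.
    """

    class_name: str  # "needle" | "target"
    bbox: tuple[float, float, float, float]
    frame_id: int | None = None

    def __post_init__(self) -> None:
        if self.class_name not in ("needle", "target"):
            raise ValueError(f"unknown class {self.class_name!r}")
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError("bbox width/height must be positive")
        if self.class_name == "needle" and not (
            NEEDLE_BOX_MIN <= w <= NEEDLE_BOX_MAX
            and NEEDLE_BOX_MIN <= h <= NEEDLE_BOX_MAX
        ):
            raise ValueError(
                f"needle box must be within [{NEEDLE_BOX_MIN}, {NEEDLE_BOX_MAX}] px"
            )

    @property
    def tip_px(self) -> tuple[float, float] | None:
        if self.class_name != "needle":
            return None
        x, y, w, h = self.bbox
        return (x, y + h)


@dataclass
class FrameRecord:
    """One rendered (or planned) image with its annotations."""

    scenario: str
    intervention_id: int
    frame_index: int
    dynamic_range: float
    image_path: str | None
    annotations: list[Annotation] = field(default_factory=list)
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class DatasetManifest:
    records: list[FrameRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_scenario(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.scenario] = out.get(r.scenario, 0) + 1
        return out

    def validate(self) -> None:
        keys = {
            (r.intervention_id, r.frame_index, r.dynamic_range)
            for r in self.records
        }
        if len(keys) != len(self.records):
            raise ValueError("duplicate (intervention, frame, DR) keys")
        for r in self.records:
            if not r.annotations and not r.flagged:
                raise ValueError(
                    f"unflagged record without annotations: "
                    f"{(r.intervention_id, r.frame_index, r.dynamic_range)}"
                )

    def extend(self, records: list[FrameRecord]) -> None:
        self.records.extend(records)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "scenario": r.scenario,
                "intervention_id": r.intervention_id,
                "frame_index": r.frame_index,
                "dynamic_range": r.dynamic_range,
                "image_path": r.image_path,
                "n_annotations": len(r.annotations),
                "flagged": r.flagged,
                "flag_reason": r.flag_reason,
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def annotate_needle(
    tip_px: tuple[float, float],
    box_size: int = 24,
    image_shape: tuple[int, int] | None = None,
    frame_id: int | None = None,
) -> Annotation:
    """Place a square needle box so its left-bottom corner is the tip.

    With y pointing down, the left-bottom corner is (min-x, max-y):
    the box occupies ``[tip_x, tip_x + s] × [tip_y - s, tip_y]``. A box
    that would be clipped by the image border is rejected (BorderError),
    never shrunk.
    """
    if not (NEEDLE_BOX_MIN <= box_size <= NEEDLE_BOX_MAX):
        raise ValueError(
            f"box_size must be within [{NEEDLE_BOX_MIN}, {NEEDLE_BOX_MAX}]"
        )
    tx, ty = tip_px
    x, y = tx, ty - box_size
    if image_shape is not None:
        h, w = image_shape
        if not (0 <= tx <= w - 1 and 0 <= ty <= h - 1):
            raise BorderError(f"tip {tip_px} outside image {w}x{h}")
        if x < 0 or y < 0 or x + box_size > w - 1 or ty > h - 1:
            raise BorderError(
                f"needle box at tip {tip_px} (size {box_size}) would be clipped"
            )
    return Annotation("needle", (x, y, box_size, box_size), frame_id)


def annotate_target(
    mask: np.ndarray, frame_id: int | None = None
) -> Annotation | None:
    """Tight axis-aligned bounding box of a binary mask.

    Returns None (and logs) for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        log.info("empty target mask for frame %s; no annotation emitted", frame_id)
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    return Annotation(
        "target", (float(c0), float(r0), float(c1 - c0 + 1), float(r1 - r0 + 1)), frame_id
    )


def _resample_mask_to_grid(
    mask: np.ndarray, template: TemplateImage, grid: ussim.CartesianGrid
) -> np.ndarray:
    """Nearest-neighbour transfer of a template-pixel mask onto the
    Cartesian display grid, through physical coordinates."""
    x, z = grid.points()
    ax, ay = template.apex_px
    col = x / (template.spacing[0] * 1e-3) + ax
    row = z / (template.spacing[1] * 1e-3) + ay
    return (
        ndimage.map_coordinates(
            mask.astype(float), [row, col], order=0, mode="constant", cval=0.0
        )
        > 0.5
    )


def display_grid(
    probe: ussim.ProbeSpec, depth: float, out_shape: tuple[int, int]
) -> ussim.CartesianGrid:
    """The Cartesian grid that scan conversion of this sector produces."""
    half = np.radians(probe.fov) / 2.0
    R = probe.curvature_radius
    x_max = (R + depth) * np.sin(half)
    z_min = R * np.cos(half) - R
    rows, cols = out_shape
    return ussim.CartesianGrid(
        origin=(-x_max, z_min),
        spacing=(2 * x_max / (cols - 1), (depth - z_min) / (rows - 1)),
        shape=out_shape,
    )


def build_intervention(
    templates: list[TemplateImage],
    needle: sc.NeedleSpec,
    probe: ussim.ProbeSpec,
    n_frames: int = 48,
    dr_list: tuple[float, ...] = (25.0, 30.0, 35.0),
    seed: int | np.random.SeedSequence | None = None,
    scenario: str = "scenario1",
    intervention_id: int = 0,
    out_dir: str | Path | None = None,
    render: bool = True,
    box_size: int = 24,
    background_density: float = 6.0,
    needle_density: float = 10.0,
    out_shape: tuple[int, int] = (192, 192),
    grid_shape: tuple[int, int] = (96, 96),
    depth: float | None = None,
    cycle_mode: str = "cycle",
) -> list[FrameRecord]:
    """Simulate one needle insertion and return its annotated frames.

    Frame ``k`` uses template ``k mod len(templates)`` (or a ping-pong
    pattern) as background, with the needle tip at trajectory step
    ``k``; the background scatterers are re-drawn every frame, which is
    what makes frames differ even on a static template. The scatterer
    realization is shared across the dynamic ranges of a frame: dynamic
    range is a display-stage choice applied after beamforming.

    With ``render=False`` (dry run) no acoustic simulation happens; the
    frames and annotations are still computed on the display geometry.
    """
    if not templates:
        raise ValueError("templates must be nonempty")
    if n_frames < 1 or not dr_list:
        raise ValueError("need n_frames >= 1 and a nonempty dr_list")
    if cycle_mode not in ("cycle", "pingpong"):
        raise ValueError("cycle_mode must be 'cycle' or 'pingpong'")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    frame_seeds = ss.spawn(n_frames)
    if depth is None:
        w_mm, h_mm = templates[0].physical_extent_mm()
        depth = h_mm * 1e-3
    grid = display_grid(probe, depth, out_shape)
    traj = sc.needle_trajectory(needle, n_frames) if n_frames >= 2 else np.array(
        [needle.entry_point_m]
    )
    wavelength = probe.wavelength
    n_t = len(templates)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    records: list[FrameRecord] = []
    for k in range(n_frames):
        if cycle_mode == "cycle" or n_t == 1:
            template = templates[k % n_t]
        else:
            period = 2 * n_t - 2
            j = k % period
            template = templates[j if j < n_t else period - j]
        tip = traj[k]

        flagged, reason = False, ""
        annotations: list[Annotation] = []
        tip_col, tip_row = grid.physical_to_pixel(tip[0], tip[1])
        try:
            needle_ann = annotate_needle(
                (float(tip_col), float(tip_row)), box_size, out_shape, k
            )
            annotations.append(needle_ann)
        except BorderError as exc:
            flagged, reason = True, str(exc)
            log.warning("intervention %d frame %d: %s", intervention_id, k, exc)
        for name, mask in template.target_masks.items():
            t_ann = annotate_target(
                _resample_mask_to_grid(mask, template, grid), k
            )
            if t_ann is not None:
                annotations.append(t_ann)
        if not annotations and not flagged:
            flagged, reason = True, "no annotations in frame"

        envelope = None
        if render:
            f_seed, n_seed = frame_seeds[k].spawn(2)
            background = sc.sample_background(
                template, background_density, wavelength, f_seed
            )
            cb_max = float(background.coeffs.max()) if len(background) else 1.0
            needle_map = sc.make_needle_scatterers(
                needle, tip, needle_density, wavelength, cb_max, n_seed
            )
            merged = sc.merge(background, needle_map)
            rf = ussim.simulate_rf(merged, probe)
            iq = ussim.demodulate_iq(rf, probe.center_freq)
            sector = ussim.SectorGrid(probe, depth, *grid_shape)
            envelope = ussim.das_beamform(iq, probe, sector)

        for dr in dr_list:
            path = None
            if render:
                bm = ussim.bmode(envelope, dr, ussim.SectorGrid(probe, depth, *grid_shape))
                cart = ussim.scan_convert(bm, probe, out_shape)
                if out_dir is not None:
                    path = str(
                        out_dir
                        / f"{scenario}_i{intervention_id:03d}_f{k:03d}_dr{int(dr)}.png"
                    )
                    cart.to_png(path)
            records.append(
                FrameRecord(
                    scenario,
                    intervention_id,
                    k,
                    dr,
                    path,
                    list(annotations),
                    flagged,
                    reason,
                )
            )
    return records


_CATEGORY_IDS = {"needle": 1, "target": 2}


def export_coco(manifest: DatasetManifest, path: str | Path) -> Path:
    """Write the manifest as a COCO-style detection JSON.

    Internal boxes already use the COCO xywh top-left convention (the
    tip-corner rule only fixes where the tip sits inside the box), so no
    coordinate change is needed.
    """
    path = Path(path)
    if path.exists():
        raise FileExistsError(f"refusing to overwrite {path}")
    manifest.validate()
    images, annotations = [], []
    ann_id = 1
    for img_id, r in enumerate(manifest.records, start=1):
        images.append(
            {
                "id": img_id,
                "file_name": r.image_path or "",
                "scenario": r.scenario,
                "intervention_id": r.intervention_id,
                "frame_index": r.frame_index,
                "dynamic_range": r.dynamic_range,
            }
        )
        for a in r.annotations:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": _CATEGORY_IDS[a.class_name],
                    "bbox": [float(v) for v in a.bbox],
                    "area": float(a.bbox[2] * a.bbox[3]),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i, "name": n} for n, i in _CATEGORY_IDS.items()
        ],
    }
    path.write_text(json.dumps(payload))
    return path


def read_coco(path: str | Path) -> dict[int, list[Annotation]]:
    """Read a COCO JSON back into per-image annotation lists."""
    payload = json.loads(Path(path).read_text())
    id_to_name = {c["id"]: c["name"] for c in payload["categories"]}
    out: dict[int, list[Annotation]] = {img["id"]: [] for img in payload["images"]}
    for a in payload["annotations"]:
        out[a["image_id"]].append(
            Annotation(id_to_name[a["category_id"]], tuple(a["bbox"]), a["image_id"])
        )
    return out


def split(
    manifest: DatasetManifest,
    train_frac: float = 0.8,
    seed: int | None = 0,
    by_intervention: bool = False,
) -> tuple[DatasetManifest, DatasetManifest]:
    """Random train/test split of the manifest.

    ``train size = round(train_frac * N)``; disjoint and exhaustive.
    ``by_intervention=True`` groups all frames of an intervention on the
    same side, avoiding frame-level leakage between splits.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    n = len(manifest)
    if n == 0:
        raise EmptyDatasetError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    if by_intervention:
        groups = sorted({r.intervention_id for r in manifest.records})
        order = rng.permutation(len(groups))
        n_train_groups = round(train_frac * len(groups))
        train_ids = {groups[i] for i in order[:n_train_groups]}
        train = [r for r in manifest.records if r.intervention_id in train_ids]
        test = [r for r in manifest.records if r.intervention_id not in train_ids]
    else:
        order = rng.permutation(n)
        n_train = round(train_frac * n)
        train_idx = set(order[:n_train].tolist())
        train = [r for i, r in enumerate(manifest.records) if i in train_idx]
        test = [r for i, r in enumerate(manifest.records) if i not in train_idx]
    return DatasetManifest(train), DatasetManifest(test)
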