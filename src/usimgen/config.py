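"""Scenario configuration and end-to-end orchestration.

Two presets mirror the two simulated study conditions:

* **scenario1** — heart-like: 20 interventions, each on the 8 most
  salient consecutive slices of a fresh low-contrast volume, cycled
  under a 48-step needle insertion, rendered at 3 dynamic ranges
  (20 × 48 × 3 = 2,880 images).
* **scenario2** — lesion-like: a single high-contrast lesion volume,
  14 static background slices → 14 interventions × 48 frames × 3
  dynamic ranges = 2,016 images; frames differ through the per-frame
  re-draw of the background scatterers.

A single config seed fans out to per-intervention and per-frame
sub-seeds through ``numpy.random.SeedSequence`` spawning, so runs are
bit-reproducible while every frame still gets an independent stream.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import phantom, preprocess
from .dataset import DatasetManifest, build_intervention, export_coco
from .scatterers import NeedleSpec
from .ussim import ProbeSpec

__all__ = ["ScenarioConfig", "scenario1_preset", "scenario2_preset", "run_scenario"]

log = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    scenario: str = "scenario1"
    n_interventions: int = 20
    n_slices_per_intervention: int = 8
    n_frames: int = 48
    dynamic_ranges: tuple[float, ...] = (25.0, 30.0, 35.0)
    angle_range_deg: tuple[float, float] = (40.0, 60.0)
    fov_deg: float = 73.0
    crop_depth_mm: float = 45.0
    probe_profile: str = "fast"  # "fast" | "full"
    background_density: float = 0.2  # scatterers per squared wavelength
    needle_density: float = 2.0
    box_size: int = 24
    out_shape: tuple[int, int] = (192, 192)
    grid_shape: tuple[int, int] = (96, 96)
    needle_length_mm: float = 200.0
    needle_diameter_mm: float = 1.52
    template_upsample: int = 4  # fine pixel pitch for scatterer sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("scenario1", "scenario2"):
            raise ValueError("scenario must be 'scenario1' or 'scenario2'")
        for name in ("n_interventions", "n_slices_per_intervention", "n_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.dynamic_ranges or any(d <= 0 for d in self.dynamic_ranges):
            raise ValueError("dynamic ranges must be positive and nonempty")
        lo, hi = self.angle_range_deg
        if not (0 < lo <= hi < 90):
            raise ValueError("angle range must lie within (0, 90) degrees")
        if self.probe_profile not in ("fast", "full"):
            raise ValueError("probe_profile must be 'fast' or 'full'")

    def probe(self) -> ProbeSpec:
        if self.probe_profile == "full":
            return ProbeSpec()
        return ProbeSpec.fast_profile(
            max_depth=max(0.08, self.crop_depth_mm * 1.2e-3)
        )

    def expected_records(self) -> int:
        return self.n_interventions * self.n_frames * len(self.dynamic_ranges)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in (
            "dynamic_ranges",
            "angle_range_deg",
            "out_shape",
            "grid_shape",
        ):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def scenario1_preset(fast: bool = True, seed: int = 0) -> ScenarioConfig:
    """Heart-like dynamic-background preset (2,880 images)."""
    return ScenarioConfig(
        scenario="scenario1",
        n_interventions=20,
        n_slices_per_intervention=8,
        probe_profile="fast" if fast else "full",
        background_density=0.2 if fast else 6.0,
        needle_density=2.0 if fast else 10.0,
        template_upsample=4 if fast else 8,
        seed=seed,
    )


def scenario2_preset(fast: bool = True, seed: int = 0) -> ScenarioConfig:
    """Lesion-like static-background preset (2,016 images)."""
    return ScenarioConfig(
        scenario="scenario2",
        n_interventions=14,
        n_slices_per_intervention=1,
        probe_profile="fast" if fast else "full",
        background_density=0.2 if fast else 6.0,
        needle_density=2.0 if fast else 10.0,
        template_upsample=4 if fast else 8,
        seed=seed,
    )


def _default_needle(cfg: ScenarioConfig, angle_deg: float) -> NeedleSpec:
    depth_m = cfg.crop_depth_mm * 1e-3
    return NeedleSpec(
        length_mm=cfg.needle_length_mm,
        diameter_mm=cfg.needle_diameter_mm,
        entry_point_m=(-0.35 * depth_m, 0.15 * depth_m),
        insertion_angle_deg=angle_deg,
        insertion_depth_mm=min(0.6 * cfg.crop_depth_mm, cfg.needle_length_mm),
    )


def _scenario1_templates(cfg: ScenarioConfig, rng_seed) -> list:
    vol = phantom.make_heart_like_volume(seed=rng_seed)
    slices = preprocess.extract_salient_slices(
        vol, "target", cfg.n_slices_per_intervention
    )
    return [
        preprocess.crop_to_fov(
            preprocess.resample_template(s, cfg.template_upsample),
            cfg.fov_deg,
            cfg.crop_depth_mm,
        )
        for s in slices
    ]


def _scenario2_templates(cfg: ScenarioConfig, rng_seed) -> list:
    """One template per intervention, all from a single lesion volume."""
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    last_err: Exception | None = None
    for attempt_seed in ss.spawn(20):
        # shallow volume: lesion depths stay within the cropped sector
        vol = phantom.make_lesion_volume(
            shape=(48, 48, 96),
            seed=attempt_seed,
            diameter_range_mm=(10.0, 14.0),
        )
        try:
            slices = preprocess.select_visible_slices(vol, cfg.n_interventions)
        except ValueError as exc:  # too few slices show a lesion; retry
            last_err = exc
            continue
        out = []
        for s in slices:
            fine = preprocess.resample_template(s, cfg.template_upsample)
            # aim the sector at the labeled lesions, like an operator would
            union = np.zeros(fine.shape, dtype=bool)
            for m in fine.target_masks.values():
                union |= m
            apex_col = (
                float(np.argwhere(union)[:, 1].mean())
                if union.any()
                else (fine.shape[1] - 1) / 2.0
            )
            out.append(
                preprocess.crop_to_fov(
                    fine,
                    cfg.fov_deg,
                    cfg.crop_depth_mm,
                    apex_px=(apex_col, 0.0),
                )
            )
        return out
    raise RuntimeError(f"could not generate scenario2 templates: {last_err}")


def run_scenario(
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    dry_run: bool = False,
) -> DatasetManifest:
    """Run phantom → preprocess → scatterers → simulation → dataset.

    ``dry_run`` skips all acoustic rendering but still produces the full
    manifest with geometry-derived annotations. When ``out_dir`` is
    given, writes PNG frames (unless dry run), the COCO JSON, a manifest
    CSV and a config snapshot YAML.
    """
    t_start = time.time()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config_snapshot.yaml")

    root = np.random.SeedSequence(config.seed)
    intervention_seeds = root.spawn(config.n_interventions + 1)
    probe = config.probe()
    manifest = DatasetManifest()

    shared_templates = None
    if config.scenario == "scenario2":
        shared_templates = _scenario2_templates(config, intervention_seeds[-1])

    for i in range(config.n_interventions):
        s_vol, s_angle, s_frames = intervention_seeds[i].spawn(3)
        if config.scenario == "scenario1":
            templates = _scenario1_templates(config, s_vol)
        else:
            templates = [shared_templates[i]]
        angle = float(
            np.random.default_rng(s_angle).uniform(*config.angle_range_deg)
        )
        needle = _default_needle(config, angle)
        records = build_intervention(
            templates,
            needle,
            probe,
            n_frames=config.n_frames,
            dr_list=config.dynamic_ranges,
            seed=s_frames,
            scenario=config.scenario,
            intervention_id=i,
            out_dir=out_dir,
            render=not dry_run,
            box_size=config.box_size,
            background_density=config.background_density,
            needle_density=config.needle_density,
            out_shape=config.out_shape,
            grid_shape=config.grid_shape,
            depth=config.crop_depth_mm * 1e-3,
        )
        manifest.extend(records)
        log.info(
            "%s intervention %d/%d done (angle %.1f deg, %d records)",
            config.scenario,
            i + 1,
            config.n_interventions,
            angle,
            len(records),
        )

    if len(manifest) != config.expected_records():
        raise RuntimeError(
            f"manifest has {len(manifest)} records, expected "
            f"{config.expected_records()}"
        )
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv")
        coco = out_dir / "annotations_coco.json"
        if coco.exists():
            coco.unlink()
        export_coco(manifest, coco)
    log.info(
        "%s finished: %d records in %.1f s",
        config.scenario,
        len(manifest),
        time.time() - t_start,
    )
    return manifest
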