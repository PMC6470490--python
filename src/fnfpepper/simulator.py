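"""Synthetic flash/no-flash greenhouse-scene generator with ground truth.

The simulator emulates the acquisition physics the FNF method relies on,
so the compositor, detector and evaluation protocol can be exercised end
to end without a field database:

* every surface has an illumination-independent *reflectance* color;
* the no-flash frame is reflectance times a variable ambient illuminant
  (global intensity, per-channel color tint, and a directional gradient
  standing in for low sun / shadows);
* the flash frame adds an artificial-light term that falls off with the
  inverse square of object depth, so near-range fruit is brightly lit
  while the background and distant fruit stay dark;
* both frames are quantized to 8 bits and clipped to [0, 255], which
  produces genuine sensor-saturated pixels under strong light;
* additive Gaussian sensor noise, seeded and reproducible.

Scenes are built from elliptical sweet peppers of three maturity classes
(mature ~35 deg hue, immature ~105 deg, partially mature a spatial hue
ramp between the two) plus green elliptical leaves — near occluders and a
mid-depth foliage canopy — over a deep dark background.  Peppers beyond a
configurable depth cutoff are labeled *distant* (out of working range).  Generated datasets
mirror the reference on-disk layout: one directory per scene with
``flash.png``, ``noflash.png``, ``labels.png`` and ``truth.json``, plus a
dataset-level manifest and class map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import color as _skcolor

from .evaluation import GroundTruthObject, MaturityClass
from .imaging import RGBImage

__all__ = [
    "PepperSpec",
    "OccluderSpec",
    "BackgroundSpec",
    "SceneSpec",
    "SceneTruth",
    "Scene",
    "GeneratorConfig",
    "CLASS_CODES",
    "CLASS_NAMES",
    "render_scene",
    "random_scene_spec",
    "simulate_scenes",
    "generate_dataset",
    "mask_to_rle",
    "rle_to_mask",
]

# Label raster codes (labels.png), declared in classmap.json at dataset root.
CLASS_CODES: dict[str, int] = {
    "background": 0,
    "mature": 1,
    "partially_mature": 2,
    "immature": 3,
    "distant": 4,
}
CLASS_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

_MATURITY_CODE = {
    MaturityClass.MATURE: 1,
    MaturityClass.PARTIALLY_MATURE: 2,
    MaturityClass.IMMATURE: 3,
    MaturityClass.DISTANT: 4,
}


# ---------------------------------------------------------------------------
# Scene description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PepperSpec:
    """One elliptical fruit.

    ``depth`` is meters from the camera and controls the flash falloff.
    ``maturity_level`` only matters for partially mature fruit: it is the
    fraction of the fruit surface (along the major axis) carrying the
    mature hue, the rest ramping to ``green_hue``.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    depth: float
    maturity: MaturityClass
    base_hue: float
    base_sat: float = 205.0
    base_val: float = 160.0
    maturity_level: float = 1.0
    green_hue: float = 105.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) < 3:
            raise ValueError("pepper semi-axes must be >= 3 px")
        if self.depth <= 0:
            raise ValueError("pepper depth must be > 0")


@dataclass(frozen=True)
class OccluderSpec:
    """A leaf-shaped elliptical occluder in front of the fruit."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    depth: float
    hue: float = 115.0
    sat: float = 150.0
    val: float = 130.0


@dataclass(frozen=True)
class BackgroundSpec:
    """The deep background behind the crop row (constant reflectance).

    At its default depth the flash contribution is negligible, so the
    background is dark in the composite regardless of ambient light.
    """

    hue: float = 100.0
    sat: float = 180.0
    val: float = 60.0
    depth: float = 2.5


@dataclass(frozen=True)
class SceneSpec:
    """Generative description of one synthetic greenhouse scene.

    ``ambient_base`` is the illuminant intensity (in 8-bit units) reaching
    a perfect reflector at ``ambient_intensity = 1`` before tinting; the
    flash term for a surface at depth ``d`` is
    ``255 * flash_intensity / d**2`` times its reflectance, i.e. exactly
    inverse-square in depth.
    """

    width: int = 320
    height: int = 240
    peppers: tuple[PepperSpec, ...] = ()
    occluders: tuple[OccluderSpec, ...] = ()
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    ambient_intensity: float = 1.0
    ambient_tint: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ambient_tint2: Optional[tuple[float, float, float]] = None
    gradient_angle_deg: float = 0.0
    gradient_strength: float = 0.0
    dapple_strength: float = 0.0
    ambient_base: float = 100.0
    flash_intensity: float = 0.023
    noise_sigma: float = 2.0
    distant_cutoff: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene dimensions must be positive")
        if self.ambient_intensity < 0:
            raise ValueError("ambient_intensity must be >= 0")
        if self.flash_intensity < 0:
            raise ValueError("flash_intensity must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.gradient_strength <= 1:
            raise ValueError("gradient_strength must lie in [0, 1]")
        if not 0 <= self.dapple_strength <= 1:
            raise ValueError("dapple_strength must lie in [0, 1]")


@dataclass
class SceneTruth:
    """Per-pixel class raster plus per-object ground truth for one scene."""

    label_mask: np.ndarray
    objects: list[GroundTruthObject]
    spec: Optional[SceneSpec] = None


@dataclass
class Scene:
    """An image pair with optional composite and ground truth."""

    scene_id: str
    flash: RGBImage
    noflash: RGBImage
    truth: Optional[SceneTruth] = None
    composite: Optional[RGBImage] = None


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _ellipse_coords(
    spec_center: tuple[float, float],
    semi_axes: tuple[float, float],
    rotation: float,
    xx: np.ndarray,
    yy: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (inside mask, normalized major-axis coord in [0,1], radius^2)."""
    cx, cy = spec_center
    a, b = semi_axes
    theta = np.deg2rad(rotation)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    r2 = (u / a) ** 2 + (v / b) ** 2
    return r2 <= 1.0, (u / a + 1.0) / 2.0, r2


def _hsv_to_reflectance(h_deg: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized HSV (deg, 0-255, 0-255) -> linear RGB reflectance in [0,1]."""
    stacked = np.stack(
        [np.mod(h_deg, 360.0) / 360.0, np.asarray(s) / 255.0, np.asarray(v) / 255.0],
        axis=-1,
    )
    return _skcolor.hsv2rgb(stacked.reshape(-1, 1, 3)).reshape(stacked.shape)


def _pepper_hue_field(p: PepperSpec, t: np.ndarray) -> np.ndarray:
    """Hue across the fruit surface; partial maturity is a sigmoidal ramp."""
    if p.maturity is not MaturityClass.PARTIALLY_MATURE:
        return np.full_like(t, p.base_hue)
    ramp = 1.0 / (1.0 + np.exp(-(t - p.maturity_level) / 0.06))
    return p.base_hue + (p.green_hue - p.base_hue) * ramp


def render_scene(spec: SceneSpec) -> tuple[RGBImage, RGBImage, SceneTruth]:
    """Render the flash frame, the no-flash frame and the ground truth.

    Per pixel the topmost (smallest-depth) surface wins.  With the scene's
    RNG seed fixed the output is fully deterministic.
    """
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # Painter's pass: reflectance, depth and owning pepper per pixel.
    reflectance = np.empty((h, w, 3), dtype=np.float64)
    reflectance[:] = _hsv_to_reflectance(
        np.array(spec.background.hue),
        np.array(spec.background.sat),
        np.array(spec.background.val),
    )
    depth = np.full((h, w), spec.background.depth, dtype=np.float64)
    owner = np.full((h, w), -1, dtype=np.int32)  # pepper index, -1 bg, -2 leaf

    for idx, p in enumerate(spec.peppers):
        inside, t, r2 = _ellipse_coords(p.center, p.semi_axes, p.rotation, xx, yy)
        visible = inside & (p.depth < depth)
        if not visible.any():
            continue
        shade = 1.0 - 0.25 * r2[visible]  # gentle radial shading, hue-preserving
        hue = _pepper_hue_field(p, t[visible])
        reflectance[visible] = _hsv_to_reflectance(
            hue, np.full_like(hue, p.base_sat), (p.base_val * shade)
        )
        depth[visible] = p.depth
        owner[visible] = idx

    for leaf in spec.occluders:
        inside, _, r2 = _ellipse_coords(leaf.center, leaf.semi_axes, leaf.rotation, xx, yy)
        visible = inside & (leaf.depth < depth)
        if not visible.any():
            continue
        shade = 1.0 - 0.25 * r2[visible]
        reflectance[visible] = _hsv_to_reflectance(
            np.full(visible.sum(), leaf.hue),
            np.full(visible.sum(), leaf.sat),
            leaf.val * shade,
        )
        depth[visible] = leaf.depth
        owner[visible] = -2

    # Illumination.  The ambient term is the product of a directional
    # intensity gradient (low sun across the frame) and a smooth random
    # "dapple" field standing in for foliage-cast patchy hard light: sunlit
    # patches are brighter and carry the first illuminant tint, shaded
    # patches are dimmer and carry the second (skylight) tint, so ambient
    # chromaticity varies within a scene as well as across scenes.  The
    # flash term is unshadowed and exactly inverse-square in depth, so the
    # FNF composite cancels all of the ambient structure.
    theta = np.deg2rad(spec.gradient_angle_deg)
    proj = xx * np.cos(theta) + yy * np.sin(theta)
    span = proj.max() - proj.min()
    frac = (proj - proj.min()) / span if span > 0 else np.zeros_like(proj)
    gradient = 1.0 + spec.gradient_strength * (2.0 * frac - 1.0)
    rng = np.random.default_rng(spec.rng_seed)
    if spec.dapple_strength > 0:
        coarse = rng.uniform(0.0, 1.0, size=(6, 8))
        field = ndi.zoom(coarse, (h / 6.0, w / 8.0), order=3, grid_mode=True, mode="nearest")
        sun_frac = np.clip(field, 0.0, 1.0)
    else:
        sun_frac = np.full((h, w), 0.5)
    dapple = 1.0 + spec.dapple_strength * (2.0 * sun_frac - 1.0)
    tint_a = np.asarray(spec.ambient_tint, dtype=np.float64)
    tint_b = np.asarray(
        spec.ambient_tint if spec.ambient_tint2 is None else spec.ambient_tint2,
        dtype=np.float64,
    )
    if spec.ambient_tint2 is None:
        tint_field = np.broadcast_to(tint_a, (h, w, 3))
    else:
        tint_field = sun_frac[..., None] * tint_a + (1.0 - sun_frac[..., None]) * tint_b
    ambient = (
        spec.ambient_base
        * spec.ambient_intensity
        * gradient[..., None]
        * dapple[..., None]
        * tint_field
    )
    noflash_signal = reflectance * ambient
    flash_signal = noflash_signal + reflectance * (
        255.0 * spec.flash_intensity / depth[..., None] ** 2
    )

    if spec.noise_sigma > 0:
        noise_nf = rng.normal(0.0, spec.noise_sigma, noflash_signal.shape)
        noise_f = rng.normal(0.0, spec.noise_sigma, flash_signal.shape)
    else:
        noise_nf = noise_f = 0.0
    noflash = RGBImage(
        np.clip(np.rint(noflash_signal + noise_nf), 0, 255).astype(np.uint8)
    )
    flash = RGBImage(np.clip(np.rint(flash_signal + noise_f), 0, 255).astype(np.uint8))

    # Ground truth from the painter's ownership map.
    label_mask = np.zeros((h, w), dtype=np.uint8)
    objects: list[GroundTruthObject] = []
    for idx, p in enumerate(spec.peppers):
        visible = owner == idx
        if not visible.any():
            continue  # fully occluded fruit cannot be labeled or scored
        maturity = (
            MaturityClass.DISTANT if p.depth > spec.distant_cutoff else p.maturity
        )
        label_mask[visible] = _MATURITY_CODE[maturity]
        rows = np.flatnonzero(visible.any(axis=1))
        cols = np.flatnonzero(visible.any(axis=0))
        bbox = (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)
        objects.append(GroundTruthObject(mask=visible, bbox=bbox, maturity=maturity))

    return flash, noflash, SceneTruth(label_mask=label_mask, objects=objects, spec=spec)


# ---------------------------------------------------------------------------
# Random scene generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Distributions from which random scenes are drawn.

    Defaults describe a close-range greenhouse viewpoint: one to three
    target peppers at 0.16-0.22 m working distance, occasional clusters and
    distant background fruit, zero to two occluding leaves, and ambient
    illumination varying across scenes in overall intensity (0.2-2.0),
    color tint (per-channel 0.55-1.45) and direction.
    """

    width: int = 320
    height: int = 240
    n_peppers_range: tuple[int, int] = (1, 3)
    cluster_probability: float = 0.35
    distant_probability: float = 0.4
    n_leaves_range: tuple[int, int] = (0, 2)
    p_mature: float = 0.6
    p_partial: float = 0.25
    p_immature: float = 0.15
    maturity_level_range: tuple[float, float] = (0.55, 0.95)
    pepper_axis_range: tuple[float, float] = (16.0, 26.0)
    axis_ratio_range: tuple[float, float] = (0.7, 0.95)
    distant_axis_range: tuple[float, float] = (8.0, 14.0)
    target_depth_range: tuple[float, float] = (0.16, 0.22)
    distant_depth_range: tuple[float, float] = (0.8, 1.6)
    leaf_depth_range: tuple[float, float] = (0.12, 0.16)
    n_foliage_range: tuple[int, int] = (22, 30)
    foliage_depth_range: tuple[float, float] = (0.23, 0.33)
    background_depth_range: tuple[float, float] = (2.0, 3.0)
    mature_hue: tuple[float, float] = (35.0, 2.5)  # mean, sd (deg)
    immature_hue: tuple[float, float] = (105.0, 8.0)
    base_sat: tuple[float, float] = (205.0, 6.0)
    base_val: tuple[float, float] = (160.0, 8.0)
    ambient_base: float = 100.0
    ambient_intensity_range: tuple[float, float] = (0.2, 2.0)
    tint_range: tuple[float, float] = (0.3, 1.7)
    gradient_strength_range: tuple[float, float] = (0.0, 0.5)
    dapple_strength_range: tuple[float, float] = (0.2, 0.5)
    flash_intensity: float = 0.023
    noise_sigma: float = 2.0
    distant_cutoff: float = 0.6


def _draw_maturity(rng: np.random.Generator, cfg: GeneratorConfig) -> MaturityClass:
    classes = [MaturityClass.MATURE, MaturityClass.PARTIALLY_MATURE, MaturityClass.IMMATURE]
    p = np.array([cfg.p_mature, cfg.p_partial, cfg.p_immature], dtype=float)
    return classes[int(rng.choice(3, p=p / p.sum()))]


def _draw_pepper(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    center: tuple[float, float],
    depth: float,
    maturity: MaturityClass,
    axis_range: tuple[float, float],
) -> PepperSpec:
    a = rng.uniform(*axis_range)
    b = a * rng.uniform(*cfg.axis_ratio_range)
    if maturity is MaturityClass.IMMATURE:
        hue = float(np.clip(rng.normal(*cfg.immature_hue), 85.0, 130.0))
    else:
        hue = float(np.clip(rng.normal(*cfg.mature_hue), 26.0, 44.0))
    return PepperSpec(
        center=center,
        semi_axes=(float(a), float(b)),
        rotation=float(rng.uniform(0.0, 180.0)),
        depth=float(depth),
        maturity=maturity,
        base_hue=hue,
        base_sat=float(np.clip(rng.normal(*cfg.base_sat), 160.0, 250.0)),
        base_val=float(np.clip(rng.normal(*cfg.base_val), 160.0, 250.0)),
        maturity_level=float(rng.uniform(*cfg.maturity_level_range)),
        green_hue=float(np.clip(rng.normal(*cfg.immature_hue), 85.0, 130.0)),
    )


def random_scene_spec(config: GeneratorConfig, seed: int) -> SceneSpec:
    """Draw one scene description from the configured distributions."""
    rng = np.random.default_rng(seed)
    cfg = config
    margin_x, margin_y = 45.0, 40.0
    peppers: list[PepperSpec] = []

    n_targets = int(rng.integers(cfg.n_peppers_range[0], cfg.n_peppers_range[1] + 1))
    for _ in range(n_targets):
        center = (
            float(rng.uniform(margin_x, cfg.width - margin_x)),
            float(rng.uniform(margin_y, cfg.height - margin_y)),
        )
        peppers.append(
            _draw_pepper(
                rng,
                cfg,
                center,
                rng.uniform(*cfg.target_depth_range),
                _draw_maturity(rng, cfg),
                cfg.pepper_axis_range,
            )
        )
        # Clustered partner: an adjacent, overlapping fruit at the same depth.
        if rng.uniform() < cfg.cluster_probability:
            base = peppers[-1]
            ang = rng.uniform(0.0, 2 * np.pi)
            dist = (base.semi_axes[0] + base.semi_axes[0]) * rng.uniform(0.75, 0.95)
            partner_center = (
                float(np.clip(base.center[0] + dist * np.cos(ang), 10, cfg.width - 10)),
                float(np.clip(base.center[1] + dist * np.sin(ang), 10, cfg.height - 10)),
            )
            peppers.append(
                _draw_pepper(
                    rng,
                    cfg,
                    partner_center,
                    base.depth + float(rng.uniform(0.0, 0.01)),
                    _draw_maturity(rng, cfg),
                    cfg.pepper_axis_range,
                )
            )

    if rng.uniform() < cfg.distant_probability:
        for _ in range(int(rng.integers(1, 3))):
            center = (
                float(rng.uniform(15.0, cfg.width - 15.0)),
                float(rng.uniform(15.0, cfg.height - 15.0)),
            )
            peppers.append(
                _draw_pepper(
                    rng,
                    cfg,
                    center,
                    rng.uniform(*cfg.distant_depth_range),
                    MaturityClass.MATURE,
                    cfg.distant_axis_range,
                )
            )

    occluders: list[OccluderSpec] = []
    # Mid-depth foliage layer: the target plant's leaf canopy behind the
    # fruit, filling most of the frame within flash range.  Distant fruit
    # and the deep background show through the gaps.
    n_foliage = int(rng.integers(cfg.n_foliage_range[0], cfg.n_foliage_range[1] + 1))
    for _ in range(n_foliage):
        a = rng.uniform(30.0, 55.0)
        occluders.append(
            OccluderSpec(
                center=(
                    float(rng.uniform(-10.0, cfg.width + 10.0)),
                    float(rng.uniform(-10.0, cfg.height + 10.0)),
                ),
                semi_axes=(float(a), float(a * rng.uniform(0.5, 0.8))),
                rotation=float(rng.uniform(0.0, 180.0)),
                depth=float(rng.uniform(*cfg.foliage_depth_range)),
                hue=float(np.clip(rng.normal(110.0, 10.0), 85.0, 140.0)),
                sat=float(rng.uniform(140.0, 200.0)),
                val=float(rng.uniform(100.0, 150.0)),
            )
        )
    n_leaves = int(rng.integers(cfg.n_leaves_range[0], cfg.n_leaves_range[1] + 1))
    for _ in range(n_leaves):
        anchor = peppers[int(rng.integers(0, len(peppers)))]
        center = (
            float(anchor.center[0] + rng.uniform(-25.0, 25.0)),
            float(anchor.center[1] + rng.uniform(-25.0, 25.0)),
        )
        a = rng.uniform(8.0, 14.0)
        occluders.append(
            OccluderSpec(
                center=center,
                semi_axes=(float(a), float(a * rng.uniform(0.5, 0.8))),
                rotation=float(rng.uniform(0.0, 180.0)),
                depth=float(rng.uniform(*cfg.leaf_depth_range)),
                hue=float(np.clip(rng.normal(115.0, 10.0), 90.0, 140.0)),
                sat=float(rng.uniform(130.0, 180.0)),
                val=float(rng.uniform(100.0, 150.0)),
            )
        )

    tint = tuple(float(rng.uniform(*cfg.tint_range)) for _ in range(3))
    tint2 = tuple(float(rng.uniform(*cfg.tint_range)) for _ in range(3))
    return SceneSpec(
        width=cfg.width,
        height=cfg.height,
        peppers=tuple(peppers),
        occluders=tuple(occluders),
        background=BackgroundSpec(
            hue=float(np.clip(rng.normal(100.0, 8.0), 80.0, 125.0)),
            sat=float(rng.uniform(160.0, 200.0)),
            val=float(rng.uniform(40.0, 70.0)),
            depth=float(rng.uniform(*cfg.background_depth_range)),
        ),
        ambient_intensity=float(rng.uniform(*cfg.ambient_intensity_range)),
        ambient_tint=tint,  # type: ignore[arg-type]
        ambient_tint2=tint2,  # type: ignore[arg-type]
        gradient_angle_deg=float(rng.uniform(0.0, 360.0)),
        gradient_strength=float(rng.uniform(*cfg.gradient_strength_range)),
        dapple_strength=float(rng.uniform(*cfg.dapple_strength_range)),
        ambient_base=cfg.ambient_base,
        flash_intensity=cfg.flash_intensity,
        noise_sigma=cfg.noise_sigma,
        distant_cutoff=cfg.distant_cutoff,
        rng_seed=int(seed),
    )


def _scene_seeds(master_seed: int, n_scenes: int) -> np.ndarray:
    """Deterministic per-scene seeds derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n_scenes)


def simulate_scenes(
    config: GeneratorConfig, n_scenes: int, master_seed: int
) -> list[Scene]:
    """Render ``n_scenes`` random scenes in memory (no disk I/O)."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    scenes = []
    for i, seed in enumerate(_scene_seeds(master_seed, n_scenes)):
        spec = random_scene_spec(config, int(seed))
        flash, noflash, truth = render_scene(spec)
        scenes.append(Scene(f"scene_{i:04d}", flash, noflash, truth))
    return scenes


# ---------------------------------------------------------------------------
# On-disk datasets
# ---------------------------------------------------------------------------

def mask_to_rle(mask: np.ndarray) -> list[list[int]]:
    """Row-major run-length encoding of a boolean raster: [[start, length], ...]."""
    flat = np.asarray(mask, dtype=bool).ravel()
    padded = np.concatenate(([False], flat, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[0::2], changes[1::2]
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def rle_to_mask(runs: Sequence[Sequence[int]], height: int, width: int) -> np.ndarray:
    flat = np.zeros(height * width, dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(height, width)


def _truth_to_json(scene: Scene) -> dict:
    truth = scene.truth
    assert truth is not None
    h, w = truth.label_mask.shape
    return {
        "scene_id": scene.scene_id,
        "width": w,
        "height": h,
        "objects": [
            {
                "maturity": obj.maturity.value,
                "bbox": list(obj.bbox),
                "rle": mask_to_rle(obj.mask),
            }
            for obj in truth.objects
        ],
    }


def generate_dataset(
    config: GeneratorConfig,
    n_scenes: int,
    master_seed: int,
    out_dir: str | Path,
) -> Path:
    """Write a synthetic dataset to disk in the reference layout.

    ``out_dir/scene_%04d/{flash.png, noflash.png, labels.png, truth.json}``
    plus ``classmap.json`` and ``manifest.json`` at the root.  Scene
    parameters are drawn from per-scene seeds derived deterministically from
    ``master_seed``: repeated runs produce byte-identical output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _scene_seeds(master_seed, n_scenes)
    manifest_scenes = []
    for i, seed in enumerate(seeds):
        spec = random_scene_spec(config, int(seed))
        flash, noflash, truth = render_scene(spec)
        scene = Scene(f"scene_{i:04d}", flash, noflash, truth)
        sdir = out / scene.scene_id
        sdir.mkdir(exist_ok=True)
        iio.imwrite(sdir / "flash.png", flash.pixels)
        iio.imwrite(sdir / "noflash.png", noflash.pixels)
        iio.imwrite(sdir / "labels.png", truth.label_mask)
        (sdir / "truth.json").write_text(json.dumps(_truth_to_json(scene), indent=1))
        manifest_scenes.append(
            {
                "scene_id": scene.scene_id,
                "seed": int(seed),
                "n_objects": len(truth.objects),
            }
        )
    (out / "classmap.json").write_text(
        json.dumps({str(v): k for k, v in CLASS_CODES.items()}, indent=1)
    )
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "n_scenes": n_scenes,
                "master_seed": int(master_seed),
                "config": dataclasses.asdict(config),
                "scenes": manifest_scenes,
            },
            indent=1,
        )
    )
    return out
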