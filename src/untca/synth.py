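"""Seeded generator of corneal-stromal-cell-like images with ground truth.

Confocal frames of the corneal stroma show sparse, elongated, bright
keratocyte bodies on a dark, unevenly illuminated background. The generator
emulates the three acquisition conditions found in clinical material:

* ``clear``    - well-lit frames with crisp cell boundaries;
* ``occluded`` - dark vessel-like curvilinear streaks traversing the field
                 and covering parts of the cells (image only - the mask keeps
                 the true cell extent);
* ``blurred``  - defocused low-contrast frames with soft cell edges.

Cells are rotated ellipses with an intensity falloff toward their edge; the
mask is the union of the analytic ellipse extents computed before any
corruption, so mask and image stay registered by construction. Every scene
is a pure function of its configuration (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

__all__ = [
    "SceneConfig",
    "SegmentationSample",
    "generate_scene",
    "generate_dataset",
    "load_dataset",
    "DEFAULT_REGIME_MIX",
]

REGIMES = ("clear", "occluded", "blurred")

# Test-split condition mix of the clinical material the generator emulates:
# 24 clear, 10 vessel-occluded, 6 blurred fields out of 40.
DEFAULT_REGIME_MIX = (24, 10, 6)


@dataclass(frozen=True)
class SceneConfig:
    """Everything that determines one synthetic scene."""

    image_size: int = 384
    n_cells: int = 30
    axis_range: tuple = (7.0, 16.0)       # semi-major axis, px
    elongation_range: tuple = (0.35, 0.7)  # semi-minor / semi-major
    cell_intensity: tuple = (0.55, 0.9)
    background_intensity: tuple = (0.08, 0.18)
    regime: str = "clear"
    n_vessels: int = 4
    vessel_width: int = 5
    blur_sigma: float = 2.5
    contrast_factor: float = 0.5           # blurred-regime contrast squeeze
    illumination_amplitude: float = 0.12
    noise_std: float = 0.02
    allow_overlap: bool = False
    max_retries: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.axis_range[1] >= self.image_size / 2:
            raise ValueError("cells must fit inside the canvas")


@dataclass
class SegmentationSample:
    """Image in [0, 1], binary mask (1 = cell), and the condition tag."""

    image: np.ndarray
    mask: np.ndarray
    tag: str
    name: str = ""


def _ellipse_region(size: int, cy: float, cx: float, a: float, b: float,
                    theta: float, margin: float = 0.0) -> np.ndarray:
    """Boolean map of the analytic (optionally inflated) ellipse extent."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / (a + margin)) ** 2 + (v / (b + margin)) ** 2 <= 1.0


def _r2_inside(size, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2


def generate_scene(cfg: SceneConfig) -> SegmentationSample:
    """Render one scene; raises if non-overlapping placement is infeasible."""
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size

    lo, hi = cfg.background_intensity
    direction = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    plane = np.cos(direction) * xx + np.sin(direction) * yy
    span = plane.max() - plane.min()
    if span > 0:
        plane = (plane - plane.min()) / span
    image = rng.uniform(lo, hi) + cfg.illumination_amplitude * (plane - 0.5)

    mask = np.zeros((size, size), dtype=bool)
    for _ in range(cfg.n_cells):
        placed = False
        for _ in range(cfg.max_retries):
            a = rng.uniform(*cfg.axis_range)
            b = a * rng.uniform(*cfg.elongation_range)
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(a + 1, size - a - 1)
            cx = rng.uniform(a + 1, size - a - 1)
            region = _ellipse_region(size, cy, cx, a, b, theta)
            if not cfg.allow_overlap:
                inflated = _ellipse_region(size, cy, cx, a, b, theta, margin=2.0)
                if np.logical_and(inflated, mask).any():
                    continue
            r2 = _r2_inside(size, cy, cx, a, b, theta)
            peak = rng.uniform(*cfg.cell_intensity)
            body = np.where(region, peak * (1.0 - 0.45 * np.clip(r2, 0, 1)), 0.0)
            image = np.maximum(image, body)
            mask |= region
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"infeasible cell placement after {cfg.max_retries} retries "
                f"(n_cells={cfg.n_cells}, axis_range={cfg.axis_range})")

    if cfg.regime == "occluded":
        vessel = np.zeros((size, size), dtype=bool)
        for _ in range(cfg.n_vessels):
            edge = rng.integers(4)
            pos = np.array([0.0 if edge == 0 else size - 1.0 if edge == 1
                            else rng.uniform(0, size - 1),
                            rng.uniform(0, size - 1) if edge < 2
                            else (0.0 if edge == 2 else size - 1.0)])
            centre = np.array([size / 2.0, size / 2.0])
            heading = float(np.arctan2(*(centre - pos))) + rng.normal(0, 0.3)
            for _ in range(3 * size):
                heading += rng.normal(0, 0.25)
                step = np.array([np.cos(heading), np.sin(heading)])
                nxt = pos + step
                iy, ix = int(round(nxt[0])), int(round(nxt[1]))
                if not (0 <= iy < size and 0 <= ix < size):
                    break
                vessel[iy, ix] = True
                pos = nxt
        if cfg.vessel_width > 1:
            iters = max(cfg.vessel_width // 2, 1)
            vessel = binary_dilation(vessel, iterations=iters)
        image = np.where(vessel, rng.uniform(0.02, 0.06), image)
    elif cfg.regime == "blurred":
        image = gaussian_filter(image, cfg.blur_sigma)
        image = cfg.contrast_factor * (image - image.mean()) + image.mean()

    image = image + rng.normal(0, cfg.noise_std, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SegmentationSample(image=image.astype(np.float64),
                              mask=mask.astype(np.uint8), tag=cfg.regime)


def generate_dataset(n_images: int, regime_mix=None, size: int = 384,
                     seed: int = 0, out_dir=None,
                     base_config: SceneConfig | None = None):
    """Generate a tagged dataset; optionally write PNGs plus a CSV manifest.

    ``regime_mix`` is ``(clear, occluded, blurred)`` counts and must sum to
    ``n_images`` (default: the 24:10:6 test-split proportions scaled is NOT
    applied - pass counts explicitly or use ``DEFAULT_REGIME_MIX`` with
    ``n_images=40``). Returns ``(samples, manifest)``.
    """
    if regime_mix is None:
        if n_images != sum(DEFAULT_REGIME_MIX):
            raise ValueError(
                f"no regime_mix given and n_images={n_images} does not match "
                f"the default mix {DEFAULT_REGIME_MIX}")
        regime_mix = DEFAULT_REGIME_MIX
    regime_mix = tuple(int(c) for c in regime_mix)
    if len(regime_mix) != 3 or any(c < 0 for c in regime_mix):
        raise ValueError(f"regime_mix must be 3 non-negative counts, got {regime_mix}")
    if sum(regime_mix) != n_images:
        raise ValueError(
            f"regime_mix {regime_mix} sums to {sum(regime_mix)}, expected {n_images}")
    base = base_config if base_config is not None else SceneConfig(image_size=size)
    if base.image_size != size:
        base = replace(base, image_size=size)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2 ** 31)
    regimes = [r for r, c in zip(REGIMES, regime_mix) for _ in range(c)]
    samples, rows = [], []
    for i, regime in enumerate(regimes):
        cfg = replace(base, regime=regime, seed=int(child_seeds[i]))
        sample = generate_scene(cfg)
        sample.name = f"img{i:04d}"
        samples.append(sample)
        rows.append({"name": sample.name, "regime": regime,
                     "seed": int(child_seeds[i]),
                     "image": f"images/{sample.name}.png",
                     "mask": f"masks/{sample.name}.png"})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for s, row in zip(samples, rows):
            iio.imwrite(out / row["image"],
                        np.round(s.image * 255).astype(np.uint8))
            iio.imwrite(out / row["mask"], (s.mask * 255).astype(np.uint8))
        manifest.to_csv(out / "manifest.csv", index=False)
    return samples, manifest


def load_dataset(manifest_path) -> list[SegmentationSample]:
    """Reload a written dataset from its manifest, byte-for-byte."""
    root = Path(manifest_path).parent
    manifest = pd.read_csv(manifest_path)
    samples = []
    for _, row in manifest.iterrows():
        image = iio.imread(root / row["image"]).astype(np.float64) / 255.0
        mask = (iio.imread(root / row["mask"]) > 127).astype(np.uint8)
        samples.append(SegmentationSample(image=image, mask=mask,
                                          tag=row["regime"], name=row["name"]))
    return samples
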