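"""Image/mask I/O, schema-validated run configuration, heatmaps, logging.

Conventions: 0-based pixel indexing, (row, col) order, origin at top-left;
masks are 255 = foreground on disk and 1 = foreground in memory; images are
scaled to [0, 1] on read (8-bit by 255, 16-bit by 65535). Heatmaps colour
probability maps with a cold-to-warm map (blue = background, red = cell).
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from matplotlib import colormaps
from pydantic import BaseModel, ConfigDict

from .backbone import BackboneConfig
from .training import AugmentToggles, TrainConfig

__all__ = [
    "logger",
    "read_image",
    "read_mask",
    "write_mask",
    "export_heatmap",
    "RunConfig",
    "ModelSection",
    "TrainSection",
    "DataSection",
]

logger = logging.getLogger("untca")


# ---------------------------------------------------------------------------
# Image and mask I/O
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF into a float array in [0, 1].

    Multi-channel input is converted to luminance with a logged warning.
    """
    arr = iio.imread(path)
    src_dtype = arr.dtype
    if arr.ndim == 3:
        logger.warning("multi-channel image %s converted to luminance", path)
        arr = arr[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
    else:
        arr = arr.astype(np.float64)
    if src_dtype == np.uint8:
        arr = arr / 255.0
    elif src_dtype == np.uint16:
        arr = arr / 65535.0
    return np.clip(arr, 0.0, 1.0)


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG (255 = foreground) as a 0/1 array."""
    return (iio.imread(path) > 127).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a 0/1 (or boolean) mask as a 0/255 8-bit PNG."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1, 255)).all():
        raise ValueError("mask must be binary")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, ((mask > 0) * 255).astype(np.uint8))


def export_heatmap(prob_map: np.ndarray, path) -> None:
    """Colour-map a probability map (cold -> warm with rising probability)."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        logger.warning("probability map clipped to [0, 1] for heatmap export")
        prob_map = np.clip(prob_map, 0.0, 1.0)
    rgba = colormaps["jet"](prob_map)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (rgba[..., :3] * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Section):
    depth: int = 5
    in_channels: int = 1
    input_size: int = 384
    num_classes: int = 2
    width_schedule: tuple | None = None
    token_widths: tuple | None = None
    encoding_strategy: str = "concatenation"
    use_gnconv: bool = True
    use_transformer: bool = True
    gn_order: int = 3
    pad_policy: str = "pad"
    ffn_hidden: int = 2048
    dropout: float = 0.1
    alpha: float = 0.3
    heads: int = 1
    norm: bool = True
    max_token_grid: int | None = None

    def to_backbone_config(self) -> BackboneConfig:
        return BackboneConfig(**self.model_dump())


class AugmentSection(_Section):
    rotate: bool = True
    contrast: bool = True
    noise: bool = True
    translate: bool = True
    flip: bool = True


class TrainSection(_Section):
    steps: int = 1000
    batch_size: int = 2
    learning_rate: float = 0.01
    momentum: float = 0.99
    nesterov: bool = True
    poly_power: float = 0.9
    seed: int = 0
    folds: int = 5
    val_fraction: float = 0.2
    eval_every: int = 50
    noise_std: float = 0.02
    max_translate_frac: float = 0.1
    augment: AugmentSection = AugmentSection()

    def to_train_config(self) -> TrainConfig:
        d = self.model_dump()
        aug = d.pop("augment")
        return TrainConfig(augment=AugmentToggles(**aug), **d)


class DataSection(_Section):
    n_images: int = 40
    size: int = 384
    mix: tuple = (24, 10, 6)
    n_cells: int = 30
    axis_min: float = 7.0
    axis_max: float = 16.0


class RunConfig(_Section):
    """Merged model + training + data configuration.

    Unknown keys are rejected; every field has a default; the resolved
    configuration round-trips through YAML unchanged and is serialised next
    to every output so a run can be reproduced from its log.
    """

    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    data: DataSection = DataSection()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                             sort_keys=False))

    def write_run_log(self, out_dir, seed: int) -> None:
        """Record the resolved configuration and seed alongside outputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        resolved = self.model_copy(deep=True)
        resolved.train.seed = seed
        resolved.to_yaml(out / "run_config.yaml")
        logger.info("run configuration written to %s (seed=%d)",
                    out / "run_config.yaml", seed)
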