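"""End-to-end orchestration: saliency -> segmentation -> strategy -> LRG.

:func:`run_pipeline` runs the whole chain on one image and dumps every stage
artifact (saliency map, binary mask, strategy output, one percept per
configured resolution) plus a JSON manifest with parameters and SHA-256
checksums, so any run is reproducible and auditable from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from prosthvis import phosphenes, strategies
from prosthvis.errors import InvalidInputError, ProsthvisError
from prosthvis.saliency import SaliencyConfig, detect_salient_object
from prosthvis.segmentation import SegmentationConfig, segment_saliency
from prosthvis.strategies import EdgeConfig

logger = logging.getLogger("prosthvis")

STRATEGIES = ("febr", "fze", "none")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the full pipeline; YAML round-trippable."""

    strategy: str = "febr"
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    edge: EdgeConfig = field(default_factory=EdgeConfig)
    resolutions: tuple[int, ...] = phosphenes.DEFAULT_RESOLUTIONS
    sigma_ratio: float = phosphenes.DEFAULT_SIGMA_RATIO
    normalization: str = "peak"
    pad_frac: float = 0.05
    seed: int = 0
    quiet: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise InvalidInputError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["edge"]["kernel_sizes"] = list(self.edge.kernel_sizes)
        d["resolutions"] = list(self.resolutions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sal = d.pop("saliency", {})
        seg = d.pop("segmentation", {})
        edge = dict(d.pop("edge", {}))
        if "kernel_sizes" in edge:
            edge["kernel_sizes"] = tuple(edge["kernel_sizes"])
        if "resolutions" in d:
            d["resolutions"] = tuple(d["resolutions"])
        return cls(
            saliency=SaliencyConfig(**sal),
            segmentation=SegmentationConfig(**seg),
            edge=EdgeConfig(**edge),
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec.601 luma conversion to 8-bit grayscale; pass-through for 2-D input."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.uint8)
    if img.ndim == 3 and img.shape[2] >= 3:
        luma = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        return np.clip(np.round(luma), 0, 255).astype(np.uint8)
    raise InvalidInputError(f"cannot convert image of shape {img.shape} to grayscale")


def load_image(path: str | Path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise ProsthvisError(f"cannot read image {path}: {exc}") from exc
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]  # drop alpha
    return img


def save_gray_png(path: str | Path, raster01: np.ndarray) -> None:
    """Write a [0, 1] raster as 8-bit PNG (score*255, rounded)."""
    iio.imwrite(path, np.clip(np.round(np.asarray(raster01) * 255.0), 0, 255).astype(np.uint8))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    image: str | Path | np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path = "prosthvis_out",
) -> dict:
    """Run the full chain on one image and write all stage artifacts.

    Saliency runs on the color input when available; the strategy and LRG
    stages run on the Rec.601 grayscale conversion.  Returns the manifest,
    which is also written to ``out_dir/manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(image, (str, Path)):
        input_name = str(image)
        image = load_image(image)
    else:
        input_name = "<array>"
        image = np.asarray(image)

    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 4)
            if not config.quiet:
                logger.info("stage %-12s %.3fs", name, timings[name])

        return done

    done = _stage("saliency")
    final, stage1, sp_ = detect_salient_object(image, config.saliency)
    done()
    artifacts["saliency_stage1"] = out_dir / "saliency_stage1.png"
    artifacts["saliency"] = out_dir / "saliency.png"
    save_gray_png(artifacts["saliency_stage1"], stage1.pixel_map)
    save_gray_png(artifacts["saliency"], final.pixel_map)

    done = _stage("segmentation")
    mask, thresholds = segment_saliency(final.pixel_map, config.segmentation)
    done()
    artifacts["mask"] = out_dir / "mask.png"
    iio.imwrite(artifacts["mask"], mask.astype(np.uint8) * 255)

    gray = to_grayscale(image)
    done = _stage("strategy")
    if config.strategy == "febr":
        processed = strategies.febr(gray, mask, config.edge)
    elif config.strategy == "fze":
        processed = strategies.fze(gray, mask, edge_cfg=config.edge, pad_frac=config.pad_frac)
    else:
        processed = gray
    done()
    artifacts["strategy"] = out_dir / f"strategy_{config.strategy}.png"
    iio.imwrite(artifacts["strategy"], processed)

    done = _stage("lrg")
    percepts = phosphenes.lrg_batch(
        processed, config.resolutions, config.sigma_ratio, config.normalization
    )
    done()
    for n, percept in percepts.items():
        key = f"percept_{n:02d}"
        artifacts[key] = out_dir / f"percept_{n:02d}.png"
        iio.imwrite(artifacts[key], np.clip(np.round(percept.raster), 0, 255).astype(np.uint8))

    manifest = {
        "input": input_name,
        "config": config.to_dict(),
        "parameters": {"t_low": thresholds.t_low, "t_high": thresholds.t_high, "n_superpixels": sp_.n},
        "timings_s": timings,
        "artifacts": {
            name: {"path": str(path), "sha256": _sha256(path)} for name, path in artifacts.items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
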