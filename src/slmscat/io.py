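"""File formats and run configuration.

Frame stacks travel as multi-page 16-bit unsigned TIFF with a JSON sidecar
(`<name>.json`) holding the grid and per-frame metadata; SLM patterns export
as device-ready 8-bit grayscale bitmaps plus JSON parameter records; run
configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .imaging import CameraModel, FrameStack
from .optics import GridSpec
from .patterns import SLMPattern

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "export_pattern",
    "write_run_log",
]


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    pixels = np.round(stack.pixels)
    if pixels.min() < 0 or pixels.max() > 65535:
        raise ValueError("pixel counts outside the 16-bit range")
    tifffile.imwrite(path, pixels.astype(np.uint16))
    sidecar = {
        "grid": dataclasses.asdict(stack.grid),
        "frames": stack.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    A missing sidecar is tolerated (grid reconstructed with default optics
    and 0.1 μm pixels, metadata empty); non-square frames are rejected.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.shape[1] != pixels.shape[2]:
        raise ValueError(f"non-square frames {pixels.shape[1:]}; stacks must be square")
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        grid = GridSpec(**sidecar["grid"])
        metadata = sidecar.get("frames", [])
    else:
        warnings.warn(f"no sidecar {sidecar_path.name}; using default grid metadata")
        grid = GridSpec(n=pixels.shape[1], pixel_size=0.1)
        metadata = [{} for _ in range(pixels.shape[0])]
    return FrameStack(pixels.astype(float), grid, metadata)


def export_pattern(pattern: SLMPattern, path: str | Path) -> None:
    """Export a pattern as a device-ready 8-bit grayscale bitmap (PNG/TIFF)
    with a JSON parameter record alongside."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pattern.levels)
    else:
        iio.imwrite(path, pattern.levels)
    record = {
        "kind": pattern.kind,
        "mode": pattern.mode.value,
        "params": pattern.params,
        "grid": dataclasses.asdict(pattern.grid),
    }
    path.with_suffix(".json").write_text(json.dumps(record, indent=2, default=str))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration of one simulation/analysis run."""

    # optics
    n: int = 512
    pixel_size: float = 0.1
    wavelength: float = 0.640
    na: float = 1.40
    effective_na: float | None = None  # None -> calibrated default
    # camera
    full_well: float = 10000.0
    read_noise: float = 5.0
    exposure_target_fraction: float = 0.875
    bit_depth: int = 16
    # scene
    preset: str = "aunp40"
    n_particles: int = 12
    # acquisition
    n_frames: int = 16
    lateral_step: float = 2.0
    noise: bool = False
    # filter / sweep
    filter: dict[str, Any] = field(default_factory=dict)
    sweep: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def grid(self) -> GridSpec:
        from .optics import CALIBRATED_EFFECTIVE_NA

        eff = self.effective_na if self.effective_na is not None else CALIBRATED_EFFECTIVE_NA
        return GridSpec(
            n=self.n,
            pixel_size=self.pixel_size,
            wavelength=self.wavelength,
            na=self.na,
            effective_na=eff,
        )

    def camera(self) -> CameraModel:
        return CameraModel(
            full_well=self.full_well,
            read_noise=self.read_noise,
            exposure_target_fraction=self.exposure_target_fraction,
            bit_depth=self.bit_depth,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


def write_run_log(config: RunConfig, out_dir: str | Path, extra: dict | None = None) -> Path:
    """Record the fully resolved config (and anything extra) next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_config.yaml"
    log_path.write_text(config.to_yaml())
    if extra:
        (out_dir / "run_log.json").write_text(json.dumps(extra, indent=2, default=str))
    return log_path
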