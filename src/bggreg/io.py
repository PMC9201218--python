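"""Image and metadata I/O plus run manifests."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .motion import RigidTransform2D

__all__ = [
    "ImageFormatError",
    "read_image",
    "write_image",
    "read_transform",
    "write_transform",
    "RunManifest",
    "write_result",
]

# Rec. 709 luminance coefficients for RGB -> gray conversion.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


class ImageFormatError(RuntimeError):
    pass


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF as a 2-D float image on the [0, 255] scale.

    RGB(A) inputs are converted by luminance; 16-bit inputs are linearly
    rescaled from [0, 65535] to [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:
        raise ImageFormatError(f"unreadable image file: {path}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[-1] >= 3:
            arr = arr[..., :3].astype(float) @ _LUMA
        else:
            arr = arr[..., 0].astype(float)
    elif arr.ndim != 2:
        raise ImageFormatError(f"unsupported image dimensionality in {path}")
    arr = arr.astype(float)
    if raw.dtype == np.uint16:
        arr = arr * (255.0 / 65535.0)
    return np.clip(arr, 0.0, 255.0)


def write_image(path, image) -> None:
    """Write a [0, 255] image as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255)
    iio.imwrite(Path(path), np.round(arr).astype(np.uint8))


def write_transform(transform: RigidTransform2D, path) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=2)


def read_transform(path) -> RigidTransform2D:
    with open(path) as fh:
        return RigidTransform2D.from_dict(json.load(fh))


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI result."""

    command: str
    seed: int
    config: dict
    version: str = "0.1.0"
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "version": self.version,
            "timings": self.timings,
            "outputs": self.outputs,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_result(result, path, manifest: RunManifest | None = None, warped=None, warped_path=None) -> None:
    """Write a registration result: transform JSON (+ manifest, + warped PNG)."""
    path = Path(path)
    payload = {
        "transform": result.transform.to_dict(),
        "converged": bool(result.converged),
        "iterations_used": list(result.iterations_used),
        "level_transforms": [t.to_dict() for t in result.level_transforms],
        "final_log_likelihood": (
            result.likelihood_trace[-1][-1] if result.likelihood_trace and result.likelihood_trace[-1] else None
        ),
    }
    if result.pad is not None:
        payload["pad"] = result.pad
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if manifest is not None:
        manifest.outputs.append(str(path))
        manifest.write(path.with_suffix(".manifest.json"))
    if warped is not None and warped_path is not None:
        write_image(warped_path, warped)
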