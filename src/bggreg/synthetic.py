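"""Synthetic phantoms, perturbation protocols, and the PAD error metric."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .motion import ImagePair, RigidTransform2D, warp_image
from .pipeline import RegistrationConfig, register

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "NoiseSpec",
    "generate_phantom",
    "random_transform",
    "add_noise",
    "transformed_pair",
    "pad",
    "sweep",
]

TRANSLATION_RANGE = (-20.0, 20.0)
ROTATION_RANGE = (-10.0, 10.0)
NOISE_VARIANCE_MAX = 0.04


@dataclass(frozen=True)
class GroundTruth:
    """The known rigid transform used to displace a synthetic floating image."""

    true_transform: RigidTransform2D


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian noise on the unit intensity scale."""

    variance: float
    seed: int = 0
    mean: float = 0.0

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")


def generate_phantom(size: int = 128, seed: int = 0, modality: str = "monomodal") -> ImagePair:
    """Seeded smooth phantom pair spanning [0, 255].

    The reference composes smooth blobs, a filled ellipse and a soft bar on
    a gentle gradient.  The monomodal floating image is a copy; the
    multimodal floating applies a monotone sigmoid remap plus a
    contrast-inverted mid-intensity band (emulating T1/T2-style inversion),
    so the joint scatter is multi-cluster rather than a single diagonal.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if modality not in ("monomodal", "multimodal"):
        raise ValueError("modality must be 'monomodal' or 'multimodal'")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)

    img = 0.10 + 0.15 * (0.6 * xx + 0.4 * yy)
    for _ in range(7):
        cx, cy = rng.uniform(0.15, 0.85, 2)
        sx, sy = rng.uniform(0.05, 0.18, 2)
        amp = rng.uniform(-0.4, 0.9)
        img += amp * np.exp(-(((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2))
    # filled ellipse, off-center and tilted so rotation is observable
    ecx, ecy = rng.uniform(0.3, 0.7, 2)
    era, erb = rng.uniform(0.12, 0.25), rng.uniform(0.05, 0.12)
    theta = rng.uniform(0, np.pi)
    xr = (xx - ecx) * np.cos(theta) + (yy - ecy) * np.sin(theta)
    yr = -(xx - ecx) * np.sin(theta) + (yy - ecy) * np.cos(theta)
    img += 0.45 * ((xr / era) ** 2 + (yr / erb) ** 2 < 1.0)
    # soft-edged bar
    bx = rng.uniform(0.2, 0.8)
    img += 0.3 * (np.abs(xx - bx) < 0.04) * (yy > 0.3)
    img = gaussian_filter(img, sigma=1.5)

    img -= img.min()
    img /= img.max()
    reference = 5.0 + 245.0 * img

    if modality == "monomodal":
        floating = reference.copy()
    else:
        v = (reference - 5.0) / 245.0
        remap = 1.0 / (1.0 + np.exp(-8.0 * (v - 0.45)))
        band = (v >= 0.4) & (v < 0.7)
        remap = np.where(band, 1.0 - remap, remap)
        floating = 5.0 + 245.0 * remap
    return ImagePair(reference, floating)


def random_transform(seed: int) -> RigidTransform2D:
    """Uniform rigid transform on the protocol ranges: +/-20 px, +/-10 deg."""
    rng = np.random.default_rng(seed)
    tx, ty = rng.uniform(*TRANSLATION_RANGE, 2)
    angle = rng.uniform(*ROTATION_RANGE)
    return RigidTransform2D(float(tx), float(ty), float(angle))


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Additive zero-mean Gaussian noise with the given variance on [0, 1].

    The image is scaled to [0, 1], perturbed, clipped, and rescaled to
    [0, 255]; variance 0 returns the image unchanged.
    """
    img = np.asarray(image, dtype=float)
    if spec.variance == 0:
        return img.copy()
    rng = np.random.default_rng(spec.seed)
    unit = img / 255.0
    noisy = unit + rng.normal(spec.mean, np.sqrt(spec.variance), img.shape)
    return np.clip(noisy, 0.0, 1.0) * 255.0


def transformed_pair(base: ImagePair, truth: RigidTransform2D, noise: NoiseSpec | None = None) -> ImagePair:
    """Displace the floating image by the inverse of ``truth`` so that
    registering the pair should recover ``truth`` (optionally adding noise)."""
    moved, mask = warp_image(base.floating, truth.inverse())
    moved = np.where(mask, moved, 0.0)
    if noise is not None:
        moved = add_noise(moved, noise)
    return ImagePair(base.reference, moved)


def pad(estimated: RigidTransform2D, truth: RigidTransform2D, shape) -> float:
    """Average pixel displacement between two transforms on a pixel grid.

    Mean over all grid points of the Euclidean distance between the two
    mappings; zero iff the transforms agree on every grid point.
    """
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    d = estimated.apply_points(pts, shape) - truth.apply_points(pts, shape)
    return float(np.linalg.norm(d, axis=1).mean())


def sweep(
    base: ImagePair,
    protocol: str,
    levels,
    seeds,
    config: RegistrationConfig,
) -> pd.DataFrame:
    """Perturb-register-measure sweep over noise variances or displacements.

    ``noise``: for each seed a random protocol transform displaces the
    floating image and noise of the given variance is added to it.
    ``displacement``: the floating image is moved by (t, t) pixels.
    Returns a tidy table (level, seed, pad, converged, runtime); failed
    runs are recorded with a NaN pad rather than raised.
    """
    if protocol not in ("noise", "displacement"):
        raise ValueError("protocol must be 'noise' or 'displacement'")
    rows = []
    for level in levels:
        if protocol == "noise" and not (0 <= level <= NOISE_VARIANCE_MAX):
            raise ValueError(f"noise variance {level} outside [0, {NOISE_VARIANCE_MAX}]")
        if protocol == "displacement" and not (0 <= level <= 30):
            raise ValueError(f"displacement {level} outside [0, 30]")
        for seed in seeds:
            if protocol == "noise":
                truth = random_transform(seed)
                noisy = NoiseSpec(variance=float(level), seed=seed) if level > 0 else None
                pair = transformed_pair(base, truth, noisy)
            else:
                truth = RigidTransform2D(float(level), float(level), 0.0)
                pair = transformed_pair(base, truth)
            start = time.perf_counter()
            try:
                result = register(pair, config)
                err = pad(result.transform, truth, base.shape)
                converged = result.converged
            except Exception as exc:  # individual failures are data, not fatal
                logger.warning("sweep run failed (level=%s seed=%s): %s", level, seed, exc)
                err, converged = np.nan, False
            rows.append(
                {
                    "level": level,
                    "seed": seed,
                    "pad": err,
                    "converged": converged,
                    "runtime": time.perf_counter() - start,
                }
            )
    return pd.DataFrame(rows)
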