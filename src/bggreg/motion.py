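"""Rigid 2-D transforms, backward warping, joint fields, motion increments.

Conventions: pixel centers at integer coordinates, origin top-left,
points are (x, y) = (column, row), rotation in degrees about the image
center (positive = counter-clockwise in the (x, y) right-handed frame).
A transform maps output-pixel coordinates to floating-image sampling
coordinates: warped(x) = floating(R(angle) @ (x - c) + c + t), i.e.
backward warping with bilinear interpolation and out-of-bounds masking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from .model import shape_constants

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform2D",
    "MotionIncrement",
    "ImagePair",
    "JointIntensityField",
    "NoOverlapError",
    "warp_image",
    "build_joint_field",
    "intensity_jacobian",
    "solve_increment",
    "apply_increment",
]


class NoOverlapError(RuntimeError):
    """The warped floating image shares no valid pixels with the reference."""


def _center(shape) -> np.ndarray:
    h, w = shape
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


@dataclass(frozen=True)
class RigidTransform2D:
    """Translation (pixels) plus rotation (degrees) about the image center."""

    tx: float = 0.0
    ty: float = 0.0
    angle: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        a = math.radians(self.angle)
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s], [s, c]])

    def apply_points(self, points, shape) -> np.ndarray:
        """Map (N, 2) points (x, y) through the transform for an image shape."""
        pts = np.asarray(points, dtype=float)
        c = _center(shape)
        t = np.array([self.tx, self.ty])
        return (pts - c) @ self.rotation_matrix().T + c + t

    def inverse(self) -> "RigidTransform2D":
        r_inv = RigidTransform2D(0.0, 0.0, -self.angle).rotation_matrix()
        t = -r_inv @ np.array([self.tx, self.ty])
        return RigidTransform2D(float(t[0]), float(t[1]), -self.angle)

    def compose(self, inner: "RigidTransform2D") -> "RigidTransform2D":
        """Transform mapping x -> self(inner(x)) (about a shared center)."""
        t = self.rotation_matrix() @ np.array([inner.tx, inner.ty]) + np.array([self.tx, self.ty])
        return RigidTransform2D(float(t[0]), float(t[1]), self.angle + inner.angle)

    def to_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "angle_deg": self.angle}

    @classmethod
    def from_dict(cls, payload: dict) -> "RigidTransform2D":
        return cls(float(payload["tx"]), float(payload["ty"]), float(payload["angle_deg"]))


@dataclass(frozen=True)
class MotionIncrement:
    """Small additive change to the rigid parameters."""

    dtx: float = 0.0
    dty: float = 0.0
    dangle: float = 0.0

    def __post_init__(self):
        if not np.isfinite([self.dtx, self.dty, self.dangle]).all():
            raise ValueError("motion increment must be finite")

    def norm(self) -> float:
        """Max of pixel and degree magnitudes (mixed-unit convergence norm)."""
        return max(abs(self.dtx), abs(self.dty), abs(self.dangle))

    def scaled(self, factor: float) -> "MotionIncrement":
        return MotionIncrement(self.dtx * factor, self.dty * factor, self.dangle * factor)


@dataclass(frozen=True)
class ImagePair:
    """Reference and floating single-channel images on the [0, 255] scale."""

    reference: np.ndarray
    floating: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        flt = np.asarray(self.floating, dtype=float)
        if ref.ndim != 2 or flt.ndim != 2:
            raise ValueError("images must be 2-D single-channel arrays")
        if ref.shape != flt.shape:
            raise ValueError("reference and floating must share a shape (resample first)")
        for name, img in (("reference", ref), ("floating", flt)):
            if img.min() < -1e-6 or img.max() > 255 + 1e-6:
                raise ValueError(f"{name} intensities must lie in [0, 255]")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "floating", flt)

    @property
    def shape(self):
        return self.reference.shape


@dataclass(frozen=True)
class JointIntensityField:
    """Per-pixel joint intensity vectors [A_x; B_x^theta] over the overlap.

    ``vectors`` holds one row per valid pixel; ``mask`` marks validity on
    the full grid; ``count`` is the number of valid pixels.
    """

    vectors: np.ndarray
    mask: np.ndarray
    count: int

    def __post_init__(self):
        if self.vectors.shape != (int(self.mask.sum()), 2):
            raise ValueError("vectors must hold one 2-vector per valid pixel")


def _sample_coords(image_shape, transform: RigidTransform2D):
    h, w = image_shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    mapped = transform.apply_points(pts, image_shape)
    sx = mapped[:, 0].reshape(h, w)
    sy = mapped[:, 1].reshape(h, w)
    return sx, sy


def warp_image(image, transform: RigidTransform2D):
    """Backward-warp ``image`` by ``transform`` with bilinear interpolation.

    Returns (warped, mask); pixels sampling outside the image are masked
    invalid and set to 0 in the warped array.  The identity transform
    returns the input bit-exactly with a full mask.
    """
    img = np.asarray(image, dtype=float)
    sx, sy = _sample_coords(img.shape, transform)
    h, w = img.shape
    mask = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
    warped = map_coordinates(img, [sy, sx], order=1, mode="constant", cval=0.0)
    warped[~mask] = 0.0
    return warped, mask


def build_joint_field(pair: ImagePair, transform: RigidTransform2D) -> JointIntensityField:
    """Stack reference and warped floating intensities over the overlap."""
    warped, mask = warp_image(pair.floating, transform)
    if not mask.any():
        raise NoOverlapError("transform leaves no overlap with the floating image")
    vectors = np.column_stack([pair.reference[mask], warped[mask]])
    return JointIntensityField(vectors=vectors, mask=mask, count=int(mask.sum()))


def _fill_invalid(image, mask):
    if mask.all():
        return image
    idx = distance_transform_edt(~mask, return_distances=False, return_indices=True)
    return image[tuple(idx)]


def intensity_jacobian(pair: ImagePair, transform: RigidTransform2D) -> np.ndarray:
    """Per-valid-pixel 2x3 derivative of the joint vector w.r.t. (tx, ty, angle).

    The reference channel row is identically zero.  The floating row uses
    central differences of the warped floating image (invalid pixels filled
    with their nearest valid neighbour before differencing) combined with
    the transform's coordinate Jacobian; the angle column is per degree.
    """
    warped, mask = warp_image(pair.floating, transform)
    if not mask.any():
        raise NoOverlapError("transform leaves no overlap with the floating image")
    filled = _fill_invalid(warped, mask)
    gy, gx = np.gradient(filled)
    h, w = warped.shape
    cx, cy = _center((h, w))
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - cx
    dy = ys - cy
    per_deg = math.pi / 180.0
    dang = (gx * (-dy) + gy * dx) * per_deg
    jac = np.zeros((int(mask.sum()), 2, 3))
    jac[:, 1, 0] = gx[mask]
    jac[:, 1, 1] = gy[mask]
    jac[:, 1, 2] = dang[mask]
    return jac


def solve_increment(
    field: JointIntensityField,
    jacobian: np.ndarray,
    responsibilities,
    mixture,
    weight_mode: str = "derived",
    epsilon: float = 1e-6,
) -> MotionIncrement:
    """Assemble and solve the 3x3 linearized system for the motion increment.

    Channel weights: ``derived`` uses scale**(-shape) * |I-u|**(shape-2)
    (consistent with the likelihood derivative); ``as_printed`` uses
    1/scale.  A singular system yields a zero increment.
    """
    if weight_mode not in ("derived", "as_printed"):
        raise ValueError("weight_mode must be 'derived' or 'as_printed'")
    eta = getattr(responsibilities, "values", responsibilities)
    eta = np.asarray(eta, dtype=float)
    vectors = field.vectors
    a_mat = np.zeros((3, 3))
    b_vec = np.zeros(3)
    for m, comp in enumerate(mixture.components):
        lam = comp.shape
        _, beta = shape_constants(lam, comp.scale)
        for c in range(2):
            jc = jacobian[:, c, :]
            if not jc.any():
                continue
            resid = vectors[:, c] - comp.mean[c]
            if weight_mode == "derived":
                w = comp.scale[c] ** (-lam[c]) * np.maximum(np.abs(resid), epsilon) ** (lam[c] - 2.0)
            else:
                w = np.full(resid.shape, 1.0 / comp.scale[c])
            coef = eta[:, m] * lam[c] * beta[c] * w
            a_mat += jc.T @ (coef[:, None] * jc)
            b_vec += -(jc.T @ (coef * resid))
    if not (np.isfinite(a_mat).all() and np.isfinite(b_vec).all()):
        raise ValueError("non-finite entries in the motion normal equations")
    try:
        sol = np.linalg.solve(a_mat, b_vec)
    except np.linalg.LinAlgError:
        logger.warning("singular motion system; returning zero increment")
        return MotionIncrement(0.0, 0.0, 0.0)
    if not np.isfinite(sol).all():
        logger.warning("non-finite motion solution; returning zero increment")
        return MotionIncrement(0.0, 0.0, 0.0)
    return MotionIncrement(float(sol[0]), float(sol[1]), float(sol[2]))


def apply_increment(transform: RigidTransform2D, increment: MotionIncrement) -> RigidTransform2D:
    """Componentwise addition of the increment to the transform parameters."""
    return RigidTransform2D(
        transform.tx + increment.dtx,
        transform.ty + increment.dty,
        transform.angle + increment.dangle,
    )
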