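"""Planar homogeneous transforms and image/mask resampling.

Four model classes are supported, ordered by degrees of freedom:

* ``translation`` — :math:`T(x) = x + t`
* ``rigid``       — :math:`T(x) = R(x - c) + t + c`, :math:`R` proper orthonormal
* ``affine``      — :math:`T(x) = A(x - c) + t + c`, :math:`A` unrestricted
* ``homography``  — full projective map, 8 free parameters

All transforms are stored as 3x3 homogeneous matrices acting on 0-based,
pixel-centre coordinates (x rightward along columns, y downward along rows),
expressed in the absolute pixel frame: the rotation centre ``c`` is recorded
for provenance but already folded into the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "MODEL_ORDER",
    "Transform2D",
    "CameraModel",
    "identity",
    "translation",
    "rigid",
    "affine",
    "homography",
    "scaling",
    "compose",
    "invert",
    "apply_to_points",
    "warp_mask",
    "warp_image",
    "angular_scale",
    "crop_to",
]

#: model classes from most to least restrictive
MODEL_ORDER = ("translation", "rigid", "affine", "homography")

_EPS_W = 1e-12  # homogeneous coordinate considered at infinity below this


@dataclass(frozen=True)
class Transform2D:
    """A 3x3 homogeneous planar transform tagged with its model class."""

    matrix: np.ndarray
    model: str = "affine"
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"transform matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix contains non-finite entries")
        if self.model not in MODEL_ORDER:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_ORDER}")
        if self.model == "homography":
            if abs(m[2, 2]) < _EPS_W:
                raise ValueError("homography matrix has m33 ~ 0; cannot normalize")
            m = m / m[2, 2]
        else:
            if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=1e-9):
                raise ValueError(
                    f"bottom row must be [0,0,1] for model {self.model!r}, got {m[2]}"
                )
            m[2] = (0.0, 0.0, 1.0)
        if self.model == "rigid":
            rr = m[:2, :2]
            if not (np.allclose(rr @ rr.T, np.eye(2), atol=1e-8) and np.linalg.det(rr) > 0):
                raise ValueError("rigid transform requires a proper orthonormal 2x2 block")
        if abs(np.linalg.det(m)) < _EPS_W:
            raise ValueError("transform matrix is singular")
        object.__setattr__(self, "matrix", m)

    # -- convenience -------------------------------------------------------

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=1e-12))

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return apply_to_points(self, pts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "matrix": self.matrix.tolist(),
                "center": list(self.center),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Transform2D":
        d = json.loads(text)
        return cls(np.array(d["matrix"], float), d["model"], tuple(d["center"]))


# -- constructors ----------------------------------------------------------


def identity() -> Transform2D:
    return Transform2D(np.eye(3), "translation")


def translation(tx: float, ty: float) -> Transform2D:
    m = np.eye(3)
    m[0, 2], m[1, 2] = tx, ty
    return Transform2D(m, "translation")


def _centered(block: np.ndarray, t: np.ndarray, center) -> np.ndarray:
    """Absolute-frame matrix for x -> block @ (x - c) + t + c."""
    c = np.asarray(center, float)
    m = np.eye(3)
    m[:2, :2] = block
    m[:2, 2] = t + c - block @ c
    return m


def rigid(theta_rad: float, t=(0.0, 0.0), center=(0.0, 0.0)) -> Transform2D:
    """Rotation by ``theta_rad`` about ``center`` followed by translation ``t``."""
    ct, st = np.cos(theta_rad), np.sin(theta_rad)
    r = np.array([[ct, -st], [st, ct]])
    return Transform2D(_centered(r, np.asarray(t, float), center), "rigid", tuple(center))


def affine(a: np.ndarray, t=(0.0, 0.0), center=(0.0, 0.0)) -> Transform2D:
    return Transform2D(
        _centered(np.asarray(a, float), np.asarray(t, float), center), "affine", tuple(center)
    )


def homography(m: np.ndarray) -> Transform2D:
    return Transform2D(np.asarray(m, float), "homography")


def scaling(sx: float, sy: float | None = None, center=(0.0, 0.0)) -> Transform2D:
    sy = sx if sy is None else sy
    return affine(np.diag([sx, sy]), (0.0, 0.0), center)


# -- algebra ---------------------------------------------------------------


def _least_restrictive(a: str, b: str) -> str:
    return max(a, b, key=MODEL_ORDER.index)


def compose(a: Transform2D, b: Transform2D) -> Transform2D:
    """Transform applying ``b`` first, then ``a`` (matrix product a @ b)."""
    return Transform2D(a.matrix @ b.matrix, _least_restrictive(a.model, b.model), a.center)


def invert(t: Transform2D) -> Transform2D:
    try:
        m = np.linalg.inv(t.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in ctor
        raise ValueError("transform is singular and cannot be inverted") from exc
    return Transform2D(m, t.model, t.center)


# -- application -----------------------------------------------------------


def apply_to_points(t: Transform2D, pts: np.ndarray) -> np.ndarray:
    """Map an (N, 2) array of (x, y) points through ``t``.

    Homogeneous multiply followed by perspective divide; for non-homography
    models the divisor is identically 1.
    """
    p = np.atleast_2d(np.asarray(pts, float))
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"expected (N, 2) points, got shape {np.shape(pts)}")
    if not np.all(np.isfinite(p)):
        raise ValueError("points contain non-finite coordinates")
    h = np.column_stack([p, np.ones(len(p))]) @ t.matrix.T
    w = h[:, 2]
    bad = np.abs(w) < _EPS_W
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"point {tuple(p[i])} maps to infinity (homogeneous w = {w[i]:.3g})"
        )
    out = h[:, :2] / w[:, None]
    return out if np.asarray(pts).ndim == 2 else out[0]


def _inverse_sample_coords(t: Transform2D, out_shape: tuple[int, int]) -> np.ndarray:
    """(2, H, W) array of source (row, col) sample positions for an inverse warp."""
    h, w = out_shape
    inv = invert(t).matrix
    yy, xx = np.mgrid[0:h, 0:w]
    denom = inv[2, 0] * xx + inv[2, 1] * yy + inv[2, 2]
    sx = (inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]) / denom
    sy = (inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]) / denom
    return np.stack([sy, sx])


def warp_mask(t: Transform2D, src: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resample a {0,1} mask into ``out_shape`` under ``t`` (inverse mapping).

    Nearest-neighbour interpolation so the output stays strictly binary;
    out-of-bounds samples are 0.
    """
    src = np.asarray(src)
    coords = _inverse_sample_coords(t, tuple(out_shape))
    out = ndimage.map_coordinates(
        src.astype(np.uint8), coords, order=0, mode="constant", cval=0
    )
    return out.astype(np.uint8)


def warp_image(t: Transform2D, src: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear inverse-mapping warp for intensity images."""
    coords = _inverse_sample_coords(t, tuple(out_shape))
    return ndimage.map_coordinates(
        np.asarray(src, float), coords, order=1, mode="constant", cval=0.0
    )


# -- camera geometry -------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Pinhole-style camera on a rigid two-sensor rig.

    ``baseline_mm`` is the lateral offset of the optical axis from the rig
    origin; ``axial_offset_mm`` a small depth offset of the sensor behind
    the rig's reference plane (sensors on a shared mount are rarely
    perfectly coplanar). ``focal_plane_mm`` is the rig's nominal working
    distance at which calibration is performed.
    """

    width_px: int
    height_px: int
    hfov_deg: float
    vfov_deg: float
    baseline_mm: float = 0.0
    focal_plane_mm: float = 800.0
    axial_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("camera resolution must be positive")
        if not (0 < self.hfov_deg < 180 and 0 < self.vfov_deg < 180):
            raise ValueError("fields of view must lie in (0, 180) degrees")

    @property
    def angres_x(self) -> float:
        """Horizontal angular resolution, degrees per pixel."""
        return self.hfov_deg / self.width_px

    @property
    def angres_y(self) -> float:
        return self.vfov_deg / self.height_px

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def px_per_mm(self, distance_mm: float) -> tuple[float, float]:
        """Small-angle plate scale at a fronto-parallel plane ``distance_mm`` away."""
        d = distance_mm + self.axial_offset_mm
        k = np.degrees(1.0) / d
        return k / self.angres_x, k / self.angres_y


def angular_scale(cam_src: CameraModel, cam_dst: CameraModel) -> Transform2D:
    """Axis-wise scaling that equalizes degrees-per-pixel between two cameras.

    ``sx = (hfov_src/width_src) / (hfov_dst/width_dst)`` and analogously for
    ``sy``: a source pixel is stretched so it subtends the same angle as a
    destination pixel.
    """
    return scaling(cam_src.angres_x / cam_dst.angres_x, cam_src.angres_y / cam_dst.angres_y)


def crop_to(t_in: Transform2D, offset=(0.0, 0.0)) -> Transform2D:
    """Re-express ``t_in`` in an output window whose origin is at ``offset``.

    Pure bookkeeping on the homogeneous matrix: composes a translation by
    ``(-dx, -dy)`` so the window corner becomes (0, 0) of the output frame.
    """
    dx, dy = offset
    if dx == 0.0 and dy == 0.0:
        return t_in
    return compose(translation(-dx, -dy), t_in)
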