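"""Synthetic two-camera rig: scenes, checkerboards, raters, frame streams.

The real acquisition the package targets — a visible RGB camera (1280x720)
and a thermal microbolometer (384x288) on a rigid mount imaging the soles of
a subject's feet at working distances around a fixed 800 mm focal plane —
is emulated by a fronto-parallel small-angle pinhole model.  A scene is a
binary "feet" silhouette on a world plane (1 grid cell = 1 mm); each camera
projects it with a similarity transform whose plate scale falls off as
``focal_plane / distance`` and whose lateral shift is the baseline disparity
``baseline * px_per_mm(distance)``.  The composed visible→thermal map at
each distance is the exact ground-truth registration transform.

Every generator is a pure function of its arguments and an explicit seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .transforms import (
    CameraModel,
    Transform2D,
    compose,
    invert,
    translation,
    warp_image,
    warp_mask,
)

__all__ = [
    "RigConfig",
    "SceneBundle",
    "CheckerboardScene",
    "FrameStream",
    "Projection",
    "DEFAULT_RIG",
    "make_foot_mask",
    "project_scene",
    "make_scene_bundle",
    "make_checkerboard_scene",
    "make_rater_stack",
    "make_frame_streams",
    "write_bundles",
]

_MIN_DIM = 32
_DIST_RANGE = (500.0, 1500.0)


@dataclass(frozen=True)
class RigConfig:
    """The two-camera rig plus generator noise settings."""

    visible: CameraModel
    thermal: CameraModel
    image_noise_sigma: float = 0.02  # fraction of dynamic range
    world_width_mm: int = 480
    world_height_mm: int = 360

    @property
    def focal_plane_mm(self) -> float:
        return self.visible.focal_plane_mm


#: Default rig: resolutions of the emulated sensors; FOVs, baseline and the
#: small axial offset are plausible for a compact dual-camera mount and are
#: not a claim about any physical device.
DEFAULT_RIG = RigConfig(
    visible=CameraModel(1280, 720, hfov_deg=65.0, vfov_deg=40.0, baseline_mm=0.0,
                        focal_plane_mm=800.0),
    thermal=CameraModel(384, 288, hfov_deg=50.0, vfov_deg=37.5, baseline_mm=30.0,
                        focal_plane_mm=800.0, axial_offset_mm=4.0),
)


@dataclass(frozen=True)
class Projection:
    """World-plane → pixel similarity used by one camera for one scene."""

    transform: Transform2D
    scale_rel: float  # magnification relative to the focal plane (= f/d)
    px_per_mm: tuple[float, float]
    disparity_px: float  # lateral pixel shift induced by the camera baseline


@dataclass(frozen=True)
class SceneBundle:
    visible_image: np.ndarray
    thermal_image: np.ndarray
    visible_mask: np.ndarray
    thermal_mask: np.ndarray
    distance_mm: float
    gt_transform: Transform2D  # exact visible→thermal pixel map at this distance
    rng_seed: int


@dataclass(frozen=True)
class CheckerboardScene:
    visible_image: np.ndarray
    thermal_image: np.ndarray
    true_keypoints_visible: np.ndarray  # (N, 2) x, y
    true_keypoints_thermal: np.ndarray
    grid_rows: int
    grid_cols: int


@dataclass(frozen=True)
class FrameStream:
    """Timestamped frames captured into a fixed-length software buffer."""

    frames: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.frames]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be non-decreasing")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames])


# -- feet silhouette -------------------------------------------------------


def _ellipse(yy, xx, cx, cy, rx, ry, theta=0.0):
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _one_foot(yy, xx, cx, cy, length, width, theta, rng):
    """Sole silhouette: elongated sole + heel bulge + five toe pads."""
    sole = _ellipse(yy, xx, cx, cy, width * 0.52, length * 0.42, theta)
    heel = _ellipse(yy, xx, cx - length * 0.38 * np.sin(theta),
                    cy + length * 0.36 * np.cos(theta),
                    width * 0.42, length * 0.18, theta)
    out = sole | heel
    # toes along the front edge
    for k in range(5):
        frac = (k - 2) / 2.6
        tx = cx + frac * width * 0.42 * np.cos(theta) - length * 0.47 * np.sin(theta)
        ty = cy + frac * width * 0.42 * np.sin(theta) - length * 0.47 * np.cos(theta)
        r = width * (0.10 - 0.012 * abs(k - 2)) * (1 + 0.1 * rng.standard_normal())
        out |= _ellipse(yy, xx, tx, ty, r, r * 1.2)
    return out


def make_foot_mask(width: int, height: int, seed: int) -> np.ndarray:
    """Deterministic binary silhouette of a pair of feet.

    Two mirrored sole-shaped blobs with mild seed-driven variation in size,
    stance and rotation, smoothed at pixel scale, covering 10–40% of the
    grid.
    """
    if width < _MIN_DIM or height < _MIN_DIM:
        raise ValueError(
            f"mask dimensions must be at least {_MIN_DIM}x{_MIN_DIM}, "
            f"got {width}x{height}"
        )
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    length = height * (0.62 + 0.06 * rng.uniform(-1, 1))
    width_f = width * (0.17 + 0.02 * rng.uniform(-1, 1))
    gap = width * (0.16 + 0.03 * rng.uniform(-1, 1))
    cy = height * (0.48 + 0.03 * rng.uniform(-1, 1))
    mask = np.zeros((height, width), bool)
    for side in (-1.0, 1.0):
        cx = width / 2 + side * gap
        theta = side * (0.06 + 0.04 * rng.uniform(-1, 1))
        mask |= _one_foot(yy, xx, cx, cy, length, width_f, theta, rng)
    # smooth the boundary at pixel scale without breaking connectivity
    sm = ndimage.gaussian_filter(mask.astype(float), sigma=1.5)
    return (sm > 0.5).astype(np.uint8)


# -- projection ------------------------------------------------------------


def project_scene(
    camera: CameraModel,
    world_mask: np.ndarray,
    distance_mm: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, Projection]:
    """Render one camera's view of a fronto-parallel world-plane mask.

    The world grid is metric (1 cell = 1 mm) and centred on the rig origin.
    The camera sees it through a similarity transform with plate scale
    ``px_per_mm(distance)`` (∝ focal_plane/distance) and a lateral disparity
    shift ``baseline * px_per_mm``.  Returns the intensity image (bilinear
    resampling of the mask, plus optional additive Gaussian noise), the
    nearest-neighbour-resampled binary mask, and the exact world→pixel
    transform used.
    """
    lo, hi = _DIST_RANGE
    if not (lo <= distance_mm <= hi):
        raise ValueError(
            f"distance_mm={distance_mm} outside the supported range [{lo}, {hi}]"
        )
    world_mask = np.asarray(world_mask)
    gh, gw = world_mask.shape
    kx, ky = camera.px_per_mm(distance_mm)
    disparity = camera.baseline_mm * kx
    m = np.array(
        [
            [kx, 0.0, camera.width_px / 2 - kx * (gw / 2 + camera.baseline_mm)],
            [0.0, ky, camera.height_px / 2 - ky * gh / 2],
            [0.0, 0.0, 1.0],
        ]
    )
    t = Transform2D(m, "affine")
    mask = warp_mask(t, world_mask, camera.shape)
    image = warp_image(t, world_mask.astype(float), camera.shape)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    proj = Projection(
        transform=t,
        scale_rel=camera.focal_plane_mm / distance_mm,
        px_per_mm=(kx, ky),
        disparity_px=disparity,
    )
    return image, mask, proj


def make_scene_bundle(cfg: RigConfig, distance_mm: float, seed: int) -> SceneBundle:
    """Paired visible/thermal views of one feet scene with its exact
    visible→thermal ground-truth transform."""
    world = make_foot_mask(cfg.world_width_mm, cfg.world_height_mm, seed)
    vis_img, vis_mask, proj_v = project_scene(
        cfg.visible, world, distance_mm, cfg.image_noise_sigma, seed=seed * 2 + 1
    )
    ir_img, ir_mask, proj_t = project_scene(
        cfg.thermal, world, distance_mm, cfg.image_noise_sigma, seed=seed * 2 + 2
    )
    gt = compose(proj_t.transform, invert(proj_v.transform))
    return SceneBundle(
        visible_image=vis_img,
        thermal_image=ir_img,
        visible_mask=vis_mask,
        thermal_mask=ir_mask,
        distance_mm=float(distance_mm),
        gt_transform=gt,
        rng_seed=seed,
    )


# -- calibration checkerboard ---------------------------------------------


def _render_blobs(shape, centers, radius, polarity, background):
    """Anti-aliased discs via analytic pixel coverage (windowed per blob)."""
    h, w = shape
    img = np.full((h, w), background, float)
    sign = 1.0 if polarity == "bright" else -1.0
    r_out = int(np.ceil(radius)) + 2
    for cx, cy in centers:
        x0, x1 = max(int(cx) - r_out, 0), min(int(cx) + r_out + 1, w)
        y0, y1 = max(int(cy) - r_out, 0), min(int(cy) + r_out + 1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        d = np.hypot(xx - cx, yy - cy)
        cover = np.clip(radius + 0.5 - d, 0.0, 1.0)
        img[y0:y1, x0:x1] += sign * cover * 0.8
    return np.clip(img, 0.0, 1.0)


def make_checkerboard_scene(
    cfg: RigConfig,
    jitter_px: float = 0.0,
    n_outliers: int = 0,
    seed: int = 0,
    grid_rows: int = 5,
    grid_cols: int = 7,
    pitch_mm: float = 55.0,
) -> CheckerboardScene:
    """Dual-spectrum calibration target at the rig's focal plane.

    A ``grid_rows x grid_cols`` lattice of circular keypoints (pitch in mm)
    rendered as bright blobs in the visible view and cold (dark) blobs in
    the thermal view.  Thermal keypoints get i.i.d. Gaussian position jitter
    of ``jitter_px`` emulating detection noise on the low-resolution sensor;
    ``n_outliers`` spurious blobs are injected per image away from the
    lattice.
    """
    if grid_rows < 4 or grid_cols < 4:
        raise ValueError("checkerboard grid must be at least 4x4")
    rng = np.random.default_rng(seed)
    d = cfg.focal_plane_mm
    # lattice in world mm, centred
    gx = (np.arange(grid_cols) - (grid_cols - 1) / 2) * pitch_mm
    gy = (np.arange(grid_rows) - (grid_rows - 1) / 2) * pitch_mm
    world_pts = np.array([(x, y) for y in gy for x in gx])
    world_grid = np.zeros((cfg.world_height_mm, cfg.world_width_mm), np.uint8)

    def to_pixels(cam: CameraModel):
        _, _, proj = project_scene(cam, world_grid, d)
        shifted = world_pts + [cfg.world_width_mm / 2, cfg.world_height_mm / 2]
        return proj.transform(shifted)

    kp_vis = to_pixels(cfg.visible)
    kp_ir = to_pixels(cfg.thermal)
    if jitter_px > 0:
        kp_ir = kp_ir + rng.normal(0.0, jitter_px, size=kp_ir.shape)

    def outlier_points(cam: CameraModel, lattice: np.ndarray) -> np.ndarray:
        pts, margin = [], 16.0
        pitch_px = pitch_mm * cam.px_per_mm(d)[0]
        while len(pts) < n_outliers:
            p = rng.uniform(
                [margin, margin], [cam.width_px - margin, cam.height_px - margin]
            )
            if np.min(np.hypot(*(lattice - p).T)) > 1.8 * pitch_px:
                pts.append(p)
        return np.array(pts).reshape(-1, 2)

    out_vis = outlier_points(cfg.visible, kp_vis)
    out_ir = outlier_points(cfg.thermal, kp_ir)
    r_vis = 0.22 * pitch_mm * cfg.visible.px_per_mm(d)[0]
    r_ir = 0.22 * pitch_mm * cfg.thermal.px_per_mm(d)[0]
    vis_img = _render_blobs(
        cfg.visible.shape, np.vstack([kp_vis, out_vis]), r_vis, "bright", 0.08
    )
    ir_img = _render_blobs(
        cfg.thermal.shape, np.vstack([kp_ir, out_ir]), r_ir, "dark", 0.92
    )
    if cfg.image_noise_sigma > 0:
        vis_img = np.clip(
            vis_img + rng.normal(0, cfg.image_noise_sigma, vis_img.shape), 0, 1
        )
        ir_img = np.clip(
            ir_img + rng.normal(0, cfg.image_noise_sigma, ir_img.shape), 0, 1
        )
    return CheckerboardScene(
        visible_image=vis_img,
        thermal_image=ir_img,
        true_keypoints_visible=kp_vis,
        true_keypoints_thermal=kp_ir,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
    )


# -- imperfect raters ------------------------------------------------------


def make_rater_stack(
    truth: np.ndarray, sens: list[float], spec: list[float], seed: int
) -> list[np.ndarray]:
    """Bernoulli raters: rater ``j`` marks a true-foreground pixel with
    probability ``sens[j]`` and a true-background pixel with probability
    ``1 - spec[j]``, independently per pixel."""
    if len(sens) != len(spec):
        raise ValueError("sens and spec must have the same length")
    for name, vals in (("sensitivity", sens), ("specificity", spec)):
        for v in vals:
            if not (0.5 < v <= 1.0):
                raise ValueError(
                    f"{name} {v} outside (0.5, 1.0]; rater performance below "
                    "chance is not identifiable"
                )
    truth = np.asarray(truth).astype(bool)
    rng = np.random.default_rng(seed)
    masks = []
    for s, q in zip(sens, spec):
        u = rng.random(truth.shape)
        m = np.where(truth, u < s, u < (1.0 - q))
        masks.append(m.astype(np.uint8))
    return masks


# -- frame timing ----------------------------------------------------------


def make_frame_streams(
    rate_a_fps: float,
    rate_b_fps: float,
    window_s: float = 2.0,
    seed: int = 0,
    jitter_frac: float = 0.0,
) -> tuple[FrameStream, FrameStream]:
    """Two timestamped capture buffers at different frame rates.

    Emulates software-timestamped reception into a fixed window: frames at
    the nominal period plus optional Gaussian reception jitter
    (``jitter_frac`` of the period), clipped to the window.
    """
    if rate_a_fps <= 0 or rate_b_fps <= 0:
        raise ValueError("frame rates must be positive")
    rng = np.random.default_rng(seed)

    def one(rate: float) -> FrameStream:
        n = int(np.floor(rate * window_s)) + 1
        t = np.arange(n) / rate
        if jitter_frac > 0:
            t = t + rng.normal(0.0, jitter_frac / rate, size=n)
        t = np.clip(np.sort(t), 0.0, window_s)
        t = t[t <= window_s]
        return FrameStream(tuple((float(ti), i) for i, ti in enumerate(t)))

    return one(rate_a_fps), one(rate_b_fps)


# -- disk output -----------------------------------------------------------


def write_bundles(bundles: list[SceneBundle], out_dir: str | Path) -> Path:
    """Write scenes as 8-bit PNGs, masks as {0,255} PNGs, ground-truth
    transforms as JSON sidecars, and a manifest CSV."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bundles:
        stem = f"d{int(b.distance_mm):04d}_s{b.rng_seed}"
        paths = {}
        for name, arr, is_mask in (
            ("visible", b.visible_image, False),
            ("thermal", b.thermal_image, False),
            ("visible_mask", b.visible_mask, True),
            ("thermal_mask", b.thermal_mask, True),
        ):
            p = out_dir / f"{stem}_{name}.png"
            if is_mask:
                Image.fromarray((np.asarray(arr) * 255).astype(np.uint8)).save(p)
            else:
                u8 = np.clip(np.asarray(arr), 0, 1) * 255
                Image.fromarray(u8.astype(np.uint8)).save(p)
            paths[name] = p.name
        tj = out_dir / f"{stem}_gt_transform.json"
        tj.write_text(b.gt_transform.to_json())
        rows.append(
            {
                "distance_mm": b.distance_mm,
                "seed": b.rng_seed,
                **paths,
                "gt_transform": tj.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
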