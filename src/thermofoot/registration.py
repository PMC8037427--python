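"""The four visible→thermal registration estimators.

* **GOT** (geometric optical translation): fixed angular-resolution scaling
  between the sensors plus a robust (median) translation from checkerboard
  correspondences, then a crop to the thermal frame.
* **Homography**: 8-parameter projective fit by normalized DLT inside a
  RANSAC consensus loop over checkerboard correspondences.
* **ICP**: rigid (rotation + translation) alignment of contour keypoints
  extracted from the two segmentation masks; scale differences are handled
  by the fixed angular-resolution pre-scaling.
* **Affine-ASGD**: 6-parameter affine fit minimizing the mean squared
  difference of Gaussian-smoothed masks with an adaptive stochastic
  gradient descent optimizer (self-tuning step-size schedule).

All estimators return the transform mapping visible pixel coordinates into
the thermal frame.  Stochastic components (RANSAC sampling, ASGD sampling)
take explicit seeds; GOT, DLT and ICP are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .calibration import Correspondences, KeypointSet
from .transforms import (
    CameraModel,
    Transform2D,
    affine,
    angular_scale,
    apply_to_points,
    compose,
    crop_to,
    homography,
    invert,
    translation,
    warp_image,
)

__all__ = [
    "RansacConfig",
    "IcpConfig",
    "IcpResult",
    "AsgdConfig",
    "estimate_got",
    "estimate_homography_dlt",
    "estimate_homography_ransac",
    "extract_contour_keypoints",
    "estimate_icp",
    "estimate_affine_asgd",
    "fit_rigid_lsq",
    "fit_affine_lsq",
]


# -- configs ---------------------------------------------------------------


@dataclass(frozen=True)
class RansacConfig:
    n_iters: int = 2000
    inlier_thresh_px: float = 2.0
    min_inliers: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.inlier_thresh_px <= 0:
            raise ValueError("inlier_thresh_px must be positive")


@dataclass(frozen=True)
class IcpConfig:
    n_keypoints: int = 200
    max_iters: int = 100
    rmse_tol: float = 1e-6
    #: mask denoising before edge detection, in target-frame pixels
    #: (rater noise leaves jagged contours that bias the rigid fit)
    smooth_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_keypoints < 3:
            raise ValueError("n_keypoints must be >= 3")
        if self.rmse_tol <= 0:
            raise ValueError("rmse_tol must be positive")


@dataclass(frozen=True)
class AsgdConfig:
    max_iters: int = 1500  # per pyramid level
    samples_per_iter: int = 2048
    a: float = 0.0  # 0 -> automatic gain from the initial gradient
    A: float = 20.0
    alpha: float = 0.602
    pyramid_levels: int = 2
    smooth_sigma_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.samples_per_iter < 16:
            raise ValueError("samples_per_iter must be >= 16")
        if not (0.5 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0.5, 1]")


# -- closed-form point-set fits --------------------------------------------


def fit_rigid_lsq(src: np.ndarray, dst: np.ndarray, center=(0.0, 0.0)) -> Transform2D:
    """Least-squares rigid fit (rotation + translation) of paired points.

    Cross-covariance SVD with determinant correction so the rotation stays
    proper; expressed about the given rotation centre.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    sm, dm = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sm).T @ (dst - dm)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    c = np.asarray(center, float)
    t = dm - c - r @ (sm - c)
    theta = np.arctan2(r[1, 0], r[0, 0])
    from .transforms import rigid as make_rigid

    return make_rigid(theta, t, center=tuple(c))


def fit_affine_lsq(src: np.ndarray, dst: np.ndarray) -> Transform2D:
    """Least-squares 6-parameter affine fit of paired points."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    ones = np.ones((len(src), 1))
    x = np.hstack([src, ones])
    sol, *_ = np.linalg.lstsq(x, dst, rcond=None)
    a = sol[:2].T
    t = sol[2]
    return affine(a, t)


# -- GOT -------------------------------------------------------------------


def estimate_got(
    corr: Correspondences,
    cam_vis: CameraModel,
    cam_ir: CameraModel,
    crop_offset=(0.0, 0.0),
) -> Transform2D:
    """Geometric optical translation: fixed scaling + median translation.

    The scaling equalizes the two sensors' angular resolutions; the
    translation is the component-wise median of the residual offsets of the
    checkerboard correspondences (median rather than mean for robustness to
    the odd bad keypoint); the crop re-expresses the result in the thermal
    output window.
    """
    if len(corr) < 1:
        raise ValueError("GOT needs at least one correspondence")
    scale = angular_scale(cam_vis, cam_ir)
    scaled = apply_to_points(scale, corr.src_points)
    t = np.median(corr.dst_points - scaled, axis=0)
    return crop_to(compose(translation(*t), scale), crop_offset)


# -- homography ------------------------------------------------------------


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity sending the centroid to the origin at mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
    return np.array(
        [[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1]]
    )


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    ts, td = _hartley_normalization(src), _hartley_normalization(dst)
    sh = np.column_stack([src, np.ones(len(src))]) @ ts.T
    dh = np.column_stack([dst, np.ones(len(dst))]) @ td.T
    rows = []
    for (x, y, _), (u, v, _) in zip(sh, dh):
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
        rows.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
    a = np.asarray(rows)
    _, s, vt = np.linalg.svd(a)
    # rank deficiency beyond the expected null vector => degenerate points
    if s[-2] < 1e-9 * s[0]:
        raise ValueError(
            "degenerate correspondence configuration (collinear points); "
            "homography is not unique"
        )
    h = vt[-1].reshape(3, 3)
    return np.linalg.inv(td) @ h @ ts


def estimate_homography_dlt(corr: Correspondences) -> Transform2D:
    """Normalized direct linear transform on >= 4 correspondences.

    Hartley point normalization, SVD null vector, matrix scaled so h33 = 1.
    """
    if len(corr) < 4:
        raise ValueError(f"homography needs >= 4 correspondences, got {len(corr)}")
    return homography(_dlt(corr.src_points, corr.dst_points))


def _symmetric_transfer_error(h: np.ndarray, src: np.ndarray, dst: np.ndarray):
    """Per-pair max of forward and backward reprojection distances (px)."""
    t = homography(h)
    fwd = np.linalg.norm(apply_to_points(t, src) - dst, axis=1)
    bwd = np.linalg.norm(apply_to_points(invert(t), dst) - src, axis=1)
    return np.maximum(fwd, bwd)


def estimate_homography_ransac(
    corr: Correspondences, cfg: RansacConfig = RansacConfig()
) -> tuple[Transform2D, np.ndarray]:
    """RANSAC consensus homography with a final all-inlier DLT refit.

    Repeatedly fits minimal 4-pair samples, scores the symmetric transfer
    error, keeps the largest consensus set, and refits on it.  Deterministic
    for a fixed config seed.
    """
    if len(corr) < 4:
        raise ValueError(f"RANSAC homography needs >= 4 pairs, got {len(corr)}")
    src, dst = corr.src_points, corr.dst_points
    rng = np.random.default_rng(cfg.seed)
    best_inliers = np.zeros(len(corr), bool)
    best_err = np.inf
    for _ in range(cfg.n_iters):
        sample = rng.choice(len(corr), size=4, replace=False)
        try:
            h = _dlt(src[sample], dst[sample])
            err = _symmetric_transfer_error(h, src, dst)
        except ValueError:  # degenerate sample or near-singular hypothesis
            continue
        inl = err < cfg.inlier_thresh_px
        n, e = int(inl.sum()), float(err[inl].sum())
        if n > best_inliers.sum() or (n == best_inliers.sum() and e < best_err):
            best_inliers, best_err = inl, e
    n_best = int(best_inliers.sum())
    if n_best < max(4, cfg.min_inliers):
        raise ValueError(
            f"no model supported: best consensus has {n_best} inliers "
            f"(min_inliers={cfg.min_inliers})"
        )
    idx = np.flatnonzero(best_inliers)
    refit = homography(_dlt(src[idx], dst[idx]))
    return refit, idx


# -- ICP -------------------------------------------------------------------


def _trace_contour(pixels: np.ndarray) -> np.ndarray:
    """Order boundary pixels of one connected contour by a nearest-neighbour
    walk starting from the top-left pixel."""
    pts = pixels[np.lexsort((pixels[:, 0], pixels[:, 1]))]  # by y then x
    remaining = list(range(len(pts)))
    path = [remaining.pop(0)]
    while remaining:
        cur = pts[path[-1]]
        d = np.linalg.norm(pts[remaining] - cur, axis=1)
        j = int(np.argmin(d))
        path.append(remaining.pop(j))
    return pts[path]


def extract_contour_keypoints(mask: np.ndarray, n: int) -> np.ndarray:
    """Equal-arc-length keypoints along the boundary of a binary mask.

    The boundary is the morphological gradient (mask minus its erosion);
    its pixels are ordered per closed contour and ``n`` points are sampled
    at equal arc-length steps, allocated to contours in proportion to their
    length.  If ``n`` meets or exceeds the number of boundary pixels, every
    boundary pixel is returned once.  Deterministic.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot extract contour keypoints from an empty mask")
    if n < 3:
        raise ValueError("need n >= 3 contour keypoints")
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    labels, n_lab = ndimage.label(boundary, structure=np.ones((3, 3)))
    contours = []
    for lab in range(1, n_lab + 1):
        ys, xs = np.nonzero(labels == lab)
        contours.append(_trace_contour(np.column_stack([xs, ys]).astype(float)))
    total_px = sum(len(c) for c in contours)
    if n >= total_px:
        return np.vstack(contours)
    # proportional allocation, largest-remainder rounding
    lengths = np.array([len(c) for c in contours], float)
    quota = n * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    for i in np.argsort(quota - counts)[::-1][:rem]:
        counts[i] += 1
    out = []
    for c, k in zip(contours, counts):
        if k <= 0:
            continue
        steps = np.concatenate([[0.0], np.linalg.norm(np.diff(c, axis=0), axis=1)])
        arc = np.cumsum(steps)
        targets = np.arange(k) * arc[-1] / k
        idx = np.searchsorted(arc, targets, side="left")
        out.append(c[np.clip(idx, 0, len(c) - 1)])
    return np.vstack(out)


@dataclass(frozen=True)
class IcpResult:
    transform: Transform2D  # full visible->thermal map (rigid o pre_scale)
    rmse: float
    n_iters: int
    converged: bool
    rmse_history: tuple[float, ...] = ()


def estimate_icp(
    vis_mask: np.ndarray,
    ir_mask: np.ndarray,
    pre_scale: Transform2D,
    cfg: IcpConfig = IcpConfig(),
) -> IcpResult:
    """Rigid ICP between mask contours after fixed angular pre-scaling.

    Contour keypoints are extracted from both masks; the visible set is
    pre-scaled into the thermal plate scale and centroid-aligned (the
    inter-camera baseline leaves a large constant offset that a
    nearest-neighbour loop cannot bridge; centroid alignment needs no
    calibration target and is folded into the returned transform).  Then the
    classic alternation: exact nearest-neighbour correspondences against the
    thermal keypoints, closed-form rigid fit about the thermal image centre,
    until the RMSE change falls below tolerance.  Deterministic.
    """
    ir_mask = np.asarray(ir_mask)
    vis_mask = np.asarray(vis_mask)
    if cfg.smooth_sigma_px > 0:
        # denoise at matched physical scale in each frame before the edge
        # filter: sigma is given in target pixels, the moving mask is
        # smoothed by sigma / pre-scale factor
        s = float(np.sqrt(abs(np.linalg.det(pre_scale.matrix[:2, :2]))))
        ir_mask = (
            ndimage.gaussian_filter(ir_mask.astype(float), cfg.smooth_sigma_px) > 0.5
        )
        vis_mask = (
            ndimage.gaussian_filter(
                vis_mask.astype(float), cfg.smooth_sigma_px / max(s, 1e-9)
            )
            > 0.5
        )
    moving0 = extract_contour_keypoints(vis_mask, cfg.n_keypoints)
    target = extract_contour_keypoints(ir_mask, cfg.n_keypoints)
    center = ((ir_mask.shape[1] - 1) / 2.0, (ir_mask.shape[0] - 1) / 2.0)
    scaled = apply_to_points(pre_scale, moving0)
    shift = target.mean(axis=0) - scaled.mean(axis=0)
    init = compose(translation(*shift), pre_scale)
    moving = scaled + shift

    tree = cKDTree(target)
    rigid_total = Transform2D(np.eye(3), "rigid", center)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iters + 1):
        d, j = tree.query(moving, k=1)
        rmse = float(np.sqrt(np.mean(d**2)))
        step = fit_rigid_lsq(moving, target[j], center=center)
        moving = apply_to_points(step, moving)
        rigid_total = compose(step, rigid_total)
        history.append(rmse)
        if len(history) > 1 and abs(history[-2] - history[-1]) < cfg.rmse_tol:
            converged = True
            break
    d, _ = tree.query(moving, k=1)
    final_rmse = float(np.sqrt(np.mean(d**2)))
    history.append(final_rmse)
    return IcpResult(
        transform=compose(rigid_total, init),
        rmse=final_rmse,
        n_iters=it,
        converged=converged,
        rmse_history=tuple(history),
    )


# -- affine ASGD -----------------------------------------------------------


def _smooth(mask: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(np.asarray(mask, float), sigma)


def _sigmoid_gain(x: float, f_min: float = -0.8, f_max: float = 1.0, omega: float = 0.25):
    """Self-tuning time update of the adaptive gain schedule: positive when
    consecutive gradients agree (accelerate), negative when they oppose
    (decelerate)."""
    return f_min + (f_max - f_min) / (1.0 - (f_max / f_min) * np.exp(-x / omega))


def _asgd_level(
    fixed_s: np.ndarray,
    moving_s: np.ndarray,
    p0: np.ndarray,
    center: np.ndarray,
    scale_len: float,
    cfg: AsgdConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One pyramid level of adaptive stochastic gradient descent.

    Parameters p = (a11, a12, a21, a22, tx, ty) of T(x) = A(x-c) + t + c.
    Internally the matrix entries are scaled by the characteristic length so
    all six parameters have comparable gradient magnitudes.
    """
    h, w = fixed_s.shape
    gy = ndimage.gaussian_filter(moving_s, 1.0, order=(1, 0))
    gx = ndimage.gaussian_filter(moving_s, 1.0, order=(0, 1))
    # sample inside the informative region around the fixed foreground
    ys, xs = np.nonzero(fixed_s > 0.01)
    pad = 0.1 * max(h, w)
    x_lo, x_hi = max(xs.min() - pad, 0), min(xs.max() + pad, w - 1)
    y_lo, y_hi = max(ys.min() - pad, 0), min(ys.max() + pad, h - 1)

    def bilinear(img, x, y):
        return ndimage.map_coordinates(img, [y, x], order=1, mode="constant", cval=0.0)

    # preconditioning: a unit step in q-space displaces points by ~1 px
    # whichever parameter it touches (matrix entries act through |x - c|,
    # which is of order the characteristic length)
    d = np.array([1.0 / scale_len] * 4 + [1.0, 1.0])
    q = p0 / d
    t_k = 0.0
    g_prev = None
    gamma0 = None
    trail: list[np.ndarray] = []
    for _ in range(cfg.max_iters):
        x = rng.uniform(x_lo, x_hi, cfg.samples_per_iter)
        y = rng.uniform(y_lo, y_hi, cfg.samples_per_iter)
        p = q * d
        a = p[:4].reshape(2, 2)
        t = p[4:]
        xc, yc = x - center[0], y - center[1]
        tx = a[0, 0] * xc + a[0, 1] * yc + t[0] + center[0]
        ty = a[1, 0] * xc + a[1, 1] * yc + t[1] + center[1]
        r = bilinear(moving_s, tx, ty) - bilinear(fixed_s, x, y)
        mgx = bilinear(gx, tx, ty)
        mgy = bilinear(gy, tx, ty)
        grad_p = (
            2.0
            / cfg.samples_per_iter
            * np.array(
                [
                    np.sum(r * mgx * xc),
                    np.sum(r * mgx * yc),
                    np.sum(r * mgy * xc),
                    np.sum(r * mgy * yc),
                    np.sum(r * mgx),
                    np.sum(r * mgy),
                ]
            )
        )
        g = grad_p * d  # chain rule into q-space
        gn = np.linalg.norm(g)
        if gamma0 is None:
            if cfg.a > 0:
                gamma0 = cfg.a
            elif gn > 1e-8:
                # automatic gain: first step moves ~0.5 px-equivalent units
                gamma0 = 0.5 * (cfg.A + 1) ** cfg.alpha / gn
            else:
                continue  # flat start (already aligned); wait for signal
        if g_prev is not None and gn > 0 and np.linalg.norm(g_prev) > 0:
            agree = -np.dot(g, g_prev) / (gn * np.linalg.norm(g_prev))
            t_k = max(0.0, t_k + _sigmoid_gain(agree))
        gamma = gamma0 / (t_k + cfg.A) ** cfg.alpha
        step = gamma * g
        sn = np.linalg.norm(step)
        if sn > 1.0:  # trust region: never move more than ~1 px per iteration
            step = step / sn
        q = q - step
        g_prev = g
        trail.append(q.copy())
    if not trail:
        return p0
    # Polyak-Ruppert tail averaging damps the stochastic wander of the
    # final iterates without touching the adaptive schedule
    tail = max(1, len(trail) // 4)
    return np.mean(trail[-tail:], axis=0) * d


def estimate_affine_asgd(
    moving: np.ndarray,
    fixed: np.ndarray,
    cfg: AsgdConfig = AsgdConfig(),
    init: Transform2D | None = None,
) -> Transform2D:
    """Affine registration by adaptive stochastic gradient descent.

    Minimizes the mean squared difference between the Gaussian-smoothed
    fixed mask and the warped, smoothed moving mask, coarse-to-fine over an
    image pyramid.  The step size follows gamma_k = a / (t_k + A)^alpha with
    the adaptive time t_k advanced by a sigmoid of the (negated) inner
    product of consecutive stochastic gradients.  Stochastic but fully
    reproducible for a fixed seed.  ``init`` pre-aligns the moving mask
    (e.g. the angular scaling plus a centroid shift when the two sensors'
    frames differ); the returned transform includes it.
    """
    moving = np.asarray(moving)
    fixed = np.asarray(fixed)
    if not moving.any() or not fixed.any():
        raise ValueError("both masks must be nonempty")
    if init is None:
        init = Transform2D(np.eye(3), "affine")
    moving_in_fixed = warp_image(init, np.asarray(moving, float), fixed.shape)
    fixed_s = _smooth(fixed, cfg.smooth_sigma_px)
    moving_s = _smooth(moving_in_fixed, cfg.smooth_sigma_px)
    if float(np.sum(fixed_s * moving_s)) <= 0.0:
        raise ValueError(
            "initial masks do not overlap; pre-align first (e.g. with the "
            "GOT transform or an angular-scale + centroid initialization)"
        )
    h, w = fixed.shape
    center_full = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    rng = np.random.default_rng(cfg.seed)
    p = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        f = 2**level
        if f > 1:
            fs = ndimage.zoom(fixed_s, 1 / f, order=1)
            ms = ndimage.zoom(moving_s, 1 / f, order=1)
        else:
            fs, ms = fixed_s, moving_s
        center = (center_full + 0.5) / f - 0.5
        scale_len = 0.5 * np.hypot(*fs.shape)
        p_level = p.copy()
        p_level[4:] = p[4:] / f
        p_level = _asgd_level(fs, ms, p_level, center, scale_len, cfg, rng)
        p = p_level.copy()
        p[4:] = p_level[4:] * f
    a = p[:4].reshape(2, 2)
    # the optimized map pulls fixed-frame samples back into the moving
    # frame; the registration transform is its inverse
    refine = invert(affine(a, p[4:], center=tuple(center_full)))
    return compose(refine, init)
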