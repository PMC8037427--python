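"""Checkerboard keypoint detection and cross-spectrum pairing.

The rig is calibrated with a dual-spectrum target: circular features that
appear bright in the visible image and cold (dark) in the thermal image.
Detection is a deterministic pipeline — global Otsu threshold, connected
components of the requested polarity, area filter, intensity-weighted
sub-pixel centroid.  Pairing exploits the known ``rows x cols`` lattice:
each detection set is snapped onto the lattice independently (spurious
detections far from the lattice are left unpaired) and same-cell keypoints
are matched across the two spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import filters, measure

__all__ = ["KeypointSet", "Correspondences", "detect_blobs", "pair_grid_keypoints"]


@dataclass(frozen=True)
class KeypointSet:
    """Sub-pixel 2D keypoints (x, y) detected in one image."""

    points: np.ndarray  # (N, 2) float
    source_image_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float).reshape(-1, 2)
        h, w = self.source_image_shape
        if len(pts) and (
            pts[:, 0].min() < -0.5
            or pts[:, 1].min() < -0.5
            or pts[:, 0].max() > w - 0.5
            or pts[:, 1].max() > h - 0.5
        ):
            raise ValueError("keypoints must lie inside the image bounds")
        if len(pts) > 1:
            d, _ = cKDTree(pts).query(pts, k=2)
            if d[:, 1].min() < 1.0:
                raise ValueError("duplicate keypoints closer than 1 px")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Correspondences:
    """Injective pairing between two keypoint sets."""

    src: KeypointSet
    dst: KeypointSet
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        si = [i for i, _ in self.pairs]
        di = [j for _, j in self.pairs]
        if si and (max(si) >= len(self.src) or max(di) >= len(self.dst)):
            raise ValueError("correspondence index out of range")
        if len(set(si)) != len(si) or len(set(di)) != len(di):
            raise ValueError("pairing must be injective in both directions")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def src_points(self) -> np.ndarray:
        return self.src.points[[i for i, _ in self.pairs]]

    @property
    def dst_points(self) -> np.ndarray:
        return self.dst.points[[j for _, j in self.pairs]]

    def subset(self, indices) -> "Correspondences":
        return Correspondences(
            self.src, self.dst, tuple(self.pairs[i] for i in indices)
        )


def from_point_arrays(src_pts, dst_pts, src_shape, dst_shape) -> Correspondences:
    """Build one-to-one correspondences from two equal-length point arrays."""
    src_pts = np.asarray(src_pts, float)
    dst_pts = np.asarray(dst_pts, float)
    if len(src_pts) != len(dst_pts):
        raise ValueError("point arrays must have equal length")
    return Correspondences(
        KeypointSet(src_pts, src_shape),
        KeypointSet(dst_pts, dst_shape),
        tuple((i, i) for i in range(len(src_pts))),
    )


def detect_blobs(
    img: np.ndarray,
    min_area_px: int = 8,
    max_area_px: int = 20000,
    polarity: str = "bright",
) -> KeypointSet:
    """Detect circular calibration features as connected components.

    Otsu threshold on the (polarity-corrected) image, connected-component
    labelling, area filtering, and an intensity-weighted centroid per
    surviving component.  An image with no detectable blobs yields an empty
    set rather than an error.
    """
    if not (0 < min_area_px < max_area_px):
        raise ValueError("need 0 < min_area_px < max_area_px")
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    work = np.asarray(img, float)
    if polarity == "dark":
        work = -work
    work = work - work.min()
    if work.max() <= 0:  # constant image
        return KeypointSet(np.empty((0, 2)), np.asarray(img).shape)
    try:
        thr = filters.threshold_otsu(work)
    except ValueError:
        return KeypointSet(np.empty((0, 2)), np.asarray(img).shape)
    labels = measure.label(work > thr, connectivity=2)
    pts = []
    for region in measure.regionprops(labels, intensity_image=work):
        if min_area_px <= region.area <= max_area_px:
            cy, cx = region.centroid_weighted
            pts.append((cx, cy))
    pts = np.array(sorted(pts), float).reshape(-1, 2)  # canonical order
    return KeypointSet(pts, np.asarray(img).shape)


# -- lattice pairing -------------------------------------------------------

_MAX_BOARD_TILT_DEG = 5.0


def _snap_to_lattice(kp: KeypointSet, rows: int, cols: int, label: str) -> np.ndarray:
    """Indices of ``kp`` arranged row-major on the rows x cols lattice.

    Lattice membership: a point is a lattice candidate if it has at least
    two neighbours at roughly the grid pitch (robust to spurious detections
    far from the board).  The candidate set is then rotated by its principal
    axis (boards are mounted nearly level; beyond ~5 deg tilt is refused)
    and cut into rows by gaps in y.
    """
    pts = kp.points
    n_need = rows * cols
    if len(pts) < n_need:
        raise ValueError(
            f"{label}: found {len(pts)} keypoints, need at least {n_need}"
        )
    tree = cKDTree(pts)
    k = min(len(pts), 5)
    dists, _ = tree.query(pts, k=k)
    pitch = float(np.median(dists[:, 1]))
    # lattice membership: largest connected component of the graph linking
    # points at roughly the grid pitch (including diagonals); spurious
    # detections away from the board form small components
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    pairs = np.array(
        [
            (i, j)
            for i, j in tree.query_pairs(1.45 * pitch)
            if np.linalg.norm(pts[i] - pts[j]) > 0.6 * pitch
        ]
    ).reshape(-1, 2)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(pts),) * 2
    )
    n_comp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp)
    on_grid = comp == np.argmax(sizes)
    cand = pts[on_grid]
    if len(cand) < n_need:
        raise ValueError(
            f"{label}: only {len(cand)} lattice-consistent keypoints of the "
            f"{n_need} required"
        )
    # principal-axis tilt of the board, folded onto the lattice axes
    centred = cand - cand.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    angle = np.degrees(np.arctan2(axis[1], axis[0]))
    angle = (angle + 45) % 90 - 45  # fold to [-45, 45): nearest lattice axis
    if abs(angle) > _MAX_BOARD_TILT_DEG:
        raise ValueError(
            f"{label}: board tilt {angle:.1f} deg exceeds the "
            f"{_MAX_BOARD_TILT_DEG} deg tolerance of the fixed rig"
        )
    th = np.radians(-angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rotated = cand @ rot.T
    order = np.argsort(rotated[:, 1], kind="stable")
    ys = rotated[order, 1]
    gaps = np.diff(ys)
    # the rows-1 largest gaps separate the rows
    cut_idx = np.sort(np.argsort(gaps)[::-1][: rows - 1])
    groups = np.split(order, cut_idx + 1)
    bad = [f"row {r}: {len(g)} points" for r, g in enumerate(groups) if len(g) != cols]
    if bad:
        raise ValueError(
            f"{label}: cannot form a complete {rows}x{cols} lattice "
            f"({'; '.join(bad)})"
        )
    cand_idx = np.flatnonzero(on_grid)
    lattice = []
    for g in groups:
        row_sorted = g[np.argsort(rotated[g, 0], kind="stable")]
        lattice.extend(cand_idx[row_sorted])
    return np.array(lattice, int)


def pair_grid_keypoints(
    a: KeypointSet, b: KeypointSet, rows: int, cols: int
) -> Correspondences:
    """Pair same-lattice-cell keypoints of two views of the checkerboard.

    Each set is independently snapped onto the known ``rows x cols`` grid;
    extra detections far from the lattice stay unpaired.  The result is
    invariant to the ordering of the input point lists.
    """
    ia = _snap_to_lattice(a, rows, cols, "first set")
    ib = _snap_to_lattice(b, rows, cols, "second set")
    return Correspondences(a, b, tuple(zip(ia.tolist(), ib.tolist())))
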