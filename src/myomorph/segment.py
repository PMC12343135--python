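"""Myofibril detection and centerline extraction.

The automatic analysis mode expects images of isolated myofibrils on a
dark background: after a light median filter the phalloidin channel is
thresholded (Otsu by default), connected components are filtered by
length, and each surviving component receives quality-control flags.
Components whose (pruned) skeleton branches, or that run within two
pixels of a neighbour, are kept in the output but flagged so that the
downstream pipeline can skip them.

A centerline is a smoothing spline through the ordered skeleton pixels,
re-sampled at uniform arclength so that intensity profiles can be read
off along or across the fibril axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.filters import median as median_filter
from skimage.filters import threshold_li, threshold_otsu, threshold_yen
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, skeletonize

from .errors import BranchedSkeleton, EmptyStack, NothingSegmented, TooShort

#: Uniform arclength re-sampling step for centerlines, um.
CENTERLINE_STEP = 0.05

_THRESHOLDS = {"otsu": threshold_otsu, "li": threshold_li, "yen": threshold_yen}


@dataclass
class ImageStack:
    """Two-channel image (2D) or z-stack (3D, z first)."""

    phalloidin_channel: np.ndarray
    zdisc_channel: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.phalloidin_channel.shape != self.zdisc_channel.shape:
            raise ValueError("channels must share shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class MyofibrilMask:
    """One segmented connected component with QC flags."""

    mask: np.ndarray  # full-frame boolean
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    major_axis_length_um: float
    qc_flags: dict = field(default_factory=dict)
    label: int = 0

    @property
    def flagged(self) -> bool:
        return any(self.qc_flags.values())


@dataclass
class Centerline:
    """Arclength-parameterised myofibril axis.

    ``points`` are (x, y) in um; ``arclength`` is strictly increasing and
    starts at 0; ``tangents`` and ``normals`` are unit vectors per sample
    (the normal is the tangent rotated +90 degrees).
    """

    points: np.ndarray       # (N, 2)
    arclength: np.ndarray    # (N,)
    tangents: np.ndarray     # (N, 2)
    normals: np.ndarray      # (N, 2)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s):
        s = np.asarray(s, dtype=float)
        x = np.interp(s, self.arclength, self.points[:, 0])
        y = np.interp(s, self.arclength, self.points[:, 1])
        return np.stack([x, y], axis=-1)

    def normal_at(self, s):
        s = np.asarray(s, dtype=float)
        nx = np.interp(s, self.arclength, self.normals[:, 0])
        ny = np.interp(s, self.arclength, self.normals[:, 1])
        n = np.stack([nx, ny], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    @classmethod
    def from_points(
        cls,
        xy: np.ndarray,
        smoothing: float = 0.0,
        step: float = CENTERLINE_STEP,
    ) -> "Centerline":
        """Fit a smoothing spline through ordered (x, y) points (um) and
        re-sample at uniform arclength ``step``."""
        xy = np.asarray(xy, dtype=float)
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))]
        )
        k = min(3, len(xy) - 1)
        tck, _ = splprep([xy[:, 0], xy[:, 1]], u=chord, s=smoothing, k=k)
        # dense evaluation to build the arclength map, then invert it
        u_fine = np.linspace(0.0, chord[-1], max(10 * len(xy), 100))
        fx, fy = splev(u_fine, tck)
        seg = np.hypot(np.diff(fx), np.diff(fy))
        s_fine = np.concatenate([[0.0], np.cumsum(seg)])
        total = s_fine[-1]
        s_out = np.arange(0.0, total + step / 2, step)
        s_out = s_out[s_out <= total]
        u_out = np.interp(s_out, s_fine, u_fine)
        px_, py_ = splev(u_out, tck)
        dx, dy = splev(u_out, tck, der=1)
        t = np.stack([dx, dy], axis=1)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        n = np.stack([-t[:, 1], t[:, 0]], axis=1)
        return cls(np.stack([px_, py_], axis=1), s_out, t, n)


# ---------------------------------------------------------------------
# projection and segmentation
# ---------------------------------------------------------------------

def project_stack(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection over z; 2D input is returned as-is."""
    ph, zd = stack.phalloidin_channel, stack.zdisc_channel
    if ph.ndim == 2:
        return stack
    if ph.ndim != 3 or ph.shape[0] < 1:
        raise EmptyStack("stack must have at least one z-plane")
    return ImageStack(ph.max(axis=0), zd.max(axis=0), stack.pixel_size)


def _neighbour_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _endpoints(skel: np.ndarray) -> np.ndarray:
    return skel & (_neighbour_count(skel) == 1)


def _pruned_skeleton(mask: np.ndarray, n_prune: int) -> np.ndarray:
    """Skeletonize and iteratively strip endpoints to remove short spurs.

    ``n_prune`` iterations remove spurs up to that many pixels long;
    the two genuine ends of a line erode by the same amount, which is
    harmless because centerline ends are trimmed anyway.
    """
    skel = skeletonize(mask)
    for _ in range(n_prune):
        ep = _endpoints(skel)
        if not ep.any():
            break
        skel = skel & ~ep
    return skel


def _has_significant_branch(mask: np.ndarray, width_px: int) -> bool:
    """True if the mask skeleton carries a side branch longer than one
    fibril width once the main (longest geodesic) path is removed.

    Boundary-noise spurs and staircase corners leave only small residues;
    a crossing or forking fibril leaves whole arms behind.
    """
    filled = ndimage.binary_fill_holes(mask)
    skel = skeletonize(filled)
    if not skel.any():
        return False
    path = _ordered_skeleton_path(skel)
    path_mask = np.zeros_like(skel)
    path_mask[path[:, 0], path[:, 1]] = True
    residue = skel & ~dilation(path_mask, disk(2))
    if not residue.any():
        return False
    sizes = np.bincount(cc_label(residue, connectivity=2).ravel())[1:]
    return bool(sizes.max() > width_px)


def segment_myofibrils(
    image: np.ndarray,
    pixel_size: float,
    min_length_um: float = 4.0,
    threshold_method: str | float = "otsu",
) -> list[MyofibrilMask]:
    """Threshold the phalloidin channel and return per-fibril masks.

    Components shorter than ``min_length_um`` along their major axis are
    dropped; the rest are returned with QC flags ``touches_border``,
    ``branched_skeleton`` and ``overlaps_neighbour``.  Flagged masks are
    meant to be excluded from automatic downstream analysis but are
    still reported.
    """
    if np.min(image) < 0:
        raise ValueError("image must be nonnegative")
    smoothed = median_filter(image, footprint=np.ones((3, 3)))
    if isinstance(threshold_method, str):
        try:
            thr = _THRESHOLDS[threshold_method](smoothed)
        except KeyError:
            raise ValueError(f"unknown threshold method {threshold_method!r}")
    else:
        thr = float(threshold_method)
    binary = smoothed > thr
    labels = cc_label(binary, connectivity=2)
    out: list[MyofibrilMask] = []
    props = regionprops(labels)
    for p in props:
        length_um = p.axis_major_length * pixel_size
        if length_um < min_length_um:
            continue
        mask = labels == p.label
        minr, minc, maxr, maxc = p.bbox
        touches = (minr == 0 or minc == 0
                   or maxr == image.shape[0] or maxc == image.shape[1])
        width_px = max(int(round(p.axis_minor_length)), 3)
        branched = _has_significant_branch(mask, width_px)
        dilated = dilation(mask, disk(2))
        overlaps = bool((dilated & binary & ~mask).any())
        out.append(
            MyofibrilMask(
                mask=mask,
                area=int(p.area),
                bbox=p.bbox,
                major_axis_length_um=float(length_um),
                qc_flags={
                    "touches_border": bool(touches),
                    "branched_skeleton": bool(branched),
                    "overlaps_neighbour": overlaps,
                },
                label=int(p.label),
            )
        )
    if not out:
        raise NothingSegmented(
            f"no component of length >= {min_length_um} um found"
        )
    return out


# ---------------------------------------------------------------------
# centerline fitting
# ---------------------------------------------------------------------

def _ordered_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through the skeleton; (row, col) array.

    Skeletons of thresholded noisy masks carry short spurs and 1-2 px
    loops; the longest shortest-path between any two skeleton pixels is
    the fibril axis and traverses those defects gracefully.  Found with
    the standard double-sweep: farthest node from an arbitrary start,
    then farthest node from there.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    pts = np.argwhere(skel)
    index = -np.ones(skel.shape, dtype=int)
    index[pts[:, 0], pts[:, 1]] = np.arange(len(pts))
    rows, cols, wts = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        src = pts + (dr, dc)
        ok = ((src[:, 0] >= 0) & (src[:, 0] < skel.shape[0])
              & (src[:, 1] >= 0) & (src[:, 1] < skel.shape[1]))
        j = np.where(ok, index[src[:, 0] % skel.shape[0],
                               src[:, 1] % skel.shape[1]], -1)
        keep = ok & (j >= 0)
        rows.extend(np.flatnonzero(keep))
        cols.extend(j[keep])
        wts.extend([float(np.hypot(dr, dc))] * int(keep.sum()))
    g = coo_matrix((wts, (rows, cols)), shape=(len(pts), len(pts)))
    d0 = dijkstra(g, directed=False, indices=0)
    d0[np.isinf(d0)] = -1
    a = int(np.argmax(d0))
    d1, pred = dijkstra(g, directed=False, indices=a,
                        return_predecessors=True)
    d1[np.isinf(d1)] = -1
    b = int(np.argmax(d1))
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    return pts[path]


def _refine_by_centroid(
    cl: Centerline,
    image: np.ndarray,
    pixel_size: float,
    half_width_um: float,
) -> np.ndarray:
    """Shift every centerline sample to the intensity centroid along its
    normal; returns refined (x, y) points.

    The skeleton is quantised to the pixel grid and biased by threshold
    noise; the transverse intensity centroid of the (symmetric) fibril
    profile locates the true axis to a small fraction of a pixel.
    """
    from scipy.ndimage import map_coordinates

    offs = np.arange(-half_width_um, half_width_um + 1e-9, pixel_size / 2)
    pts, nrm = cl.points, cl.normals
    xs = pts[:, 0][:, None] + offs[None, :] * nrm[:, 0][:, None]
    ys = pts[:, 1][:, None] + offs[None, :] * nrm[:, 1][:, None]
    vals = map_coordinates(image, [ys / pixel_size, xs / pixel_size],
                           order=1, mode="nearest")
    w = np.clip(vals - vals.min(axis=1, keepdims=True), 0.0, None)
    tot = w.sum(axis=1)
    ok = tot > 0
    delta = np.zeros(len(pts))
    delta[ok] = (w[ok] * offs[None, :]).sum(axis=1) / tot[ok]
    delta = np.clip(delta, -3 * pixel_size, 3 * pixel_size)
    return pts + delta[:, None] * nrm


def _cap_distance(
    mask: np.ndarray, point: np.ndarray, direction: np.ndarray,
    pixel_size: float, max_um: float,
) -> float:
    """Distance (um) from ``point`` along ``direction`` to the mask edge."""
    steps = np.arange(0.0, max_um, pixel_size / 2)
    px = point[0] + steps * direction[0]
    py = point[1] + steps * direction[1]
    rows = np.clip(np.round(py / pixel_size).astype(int), 0,
                   mask.shape[0] - 1)
    cols = np.clip(np.round(px / pixel_size).astype(int), 0,
                   mask.shape[1] - 1)
    inside = mask[rows, cols]
    if inside.all():
        return float(steps[-1])
    return float(steps[np.argmin(inside)])


def fit_centerline(
    mask: MyofibrilMask,
    pixel_size: float,
    smoothing: float | None = None,
    min_length_um: float = 4.0,
    trim_um: float | None = None,
    image: np.ndarray | None = None,
    allow_branched: bool = False,
) -> Centerline:
    """Extract an arclength-parameterised spline axis from a mask.

    The skeleton's longest geodesic path seeds a smoothing spline, which
    is then refined by shifting each sample to the transverse intensity
    centroid (of ``image`` if given, else of the mask itself).  Both
    ends are trimmed by one fibril diameter, measured from the mask cap
    positions, to avoid the rounded-cap artefact.  Masks flagged as
    branched are refused unless ``allow_branched`` (the axis is then the
    longest geodesic through the skeleton).
    """
    if mask.qc_flags.get("branched_skeleton") and not allow_branched:
        raise BranchedSkeleton(
            "mask flagged branched_skeleton; pass allow_branched=True "
            "to take the longest path anyway"
        )
    m = ndimage.binary_fill_holes(mask.mask)
    edt = ndimage.distance_transform_edt(m)
    skel = _pruned_skeleton(m, max(int(round(edt.max())) + 3, 3))
    if not skel.any():
        raise TooShort("mask too small to skeletonize")
    path = _ordered_skeleton_path(skel)
    if len(path) < 4:
        raise TooShort("skeleton path shorter than 4 pixels")
    xy = path[:, ::-1].astype(float) * pixel_size  # (col, row) -> (x, y)
    if smoothing is None:
        smoothing = len(path) * pixel_size ** 2  # residual RMS ~1 px
    rough = Centerline.from_points(xy, smoothing=smoothing)
    radius_um = float(edt[skel].mean()) * pixel_size
    diameter_um = 2.0 * radius_um
    target = image if image is not None else m.astype(float)
    refined_pts = _refine_by_centroid(rough, target, pixel_size,
                                      radius_um + 4 * pixel_size)
    n = len(refined_pts)
    cl = Centerline.from_points(refined_pts,
                                smoothing=n * (0.5 * pixel_size) ** 2)
    if trim_um is None:
        trim_um = diameter_um
    # trim one diameter measured from the mask caps, which are stable
    # under image isometries (the skeleton ends are not); if the skeleton
    # stopped short of that mark, extend the axis linearly first
    e0 = _cap_distance(m, cl.points[0], -cl.tangents[0], pixel_size,
                       2 * diameter_um)
    e1 = _cap_distance(m, cl.points[-1], cl.tangents[-1], pixel_size,
                       2 * diameter_um)
    back = max(e0 - trim_um, 0.0)
    fwd = max(e1 - trim_um, 0.0)
    if back > CENTERLINE_STEP or fwd > CENTERLINE_STEP:
        pre = np.empty((0, 2))
        post = np.empty((0, 2))
        if back > CENTERLINE_STEP:
            db = np.arange(CENTERLINE_STEP, back + 1e-9, CENTERLINE_STEP)[::-1]
            pre = cl.points[0][None, :] - np.outer(db, cl.tangents[0])
        if fwd > CENTERLINE_STEP:
            df = np.arange(CENTERLINE_STEP, fwd + 1e-9, CENTERLINE_STEP)
            post = cl.points[-1][None, :] + np.outer(df, cl.tangents[-1])
        ext = np.vstack([pre, cl.points, post])
        cl = Centerline.from_points(ext,
                                    smoothing=len(ext) * (0.5 * pixel_size) ** 2)
        e0 = _cap_distance(m, cl.points[0], -cl.tangents[0], pixel_size,
                           2 * diameter_um)
        e1 = _cap_distance(m, cl.points[-1], cl.tangents[-1], pixel_size,
                           2 * diameter_um)
    lo = max(trim_um - e0, 0.0)
    hi = cl.length - max(trim_um - e1, 0.0)
    keep = (cl.arclength >= lo) & (cl.arclength <= hi)
    if keep.sum() < 4 or hi - lo < min_length_um:
        raise TooShort(
            f"centerline {cl.length:.2f} um too short after trimming "
            f"{trim_um:.2f} um per end"
        )
    pts = cl.points[keep]
    s = cl.arclength[keep] - cl.arclength[keep][0]
    return Centerline(pts, s, cl.tangents[keep], cl.normals[keep])
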