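"""Intensity profiles along and across a myofibril centerline.

A longitudinal profile averages the image over a short normal segment at
every arclength sample (the rectangular ROI running along the fibril); a
transverse profile samples along the local normal at one arclength.
Both use bilinear interpolation and physical (um) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import OutOfBounds
from .segment import Centerline

#: Default half-width of the longitudinal averaging ROI, um.
LONGITUDINAL_HALF_WIDTH = 0.3
#: Default half-length of the transverse profile, um (fibril radius plus
#: PSF tails with margin).
TRANSVERSE_HALF_LENGTH = 2.5


@dataclass
class IntensityProfile:
    """1D sampled intensity versus physical position.

    ``positions`` are uniformly spaced and strictly increasing (um);
    for transverse profiles they are signed distances from the
    centerline.  ``axis_tag`` is ``"longitudinal"`` or ``"transverse"``.
    """

    positions: np.ndarray
    values: np.ndarray
    axis_tag: str
    channel: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values) or len(self.positions) < 8:
            raise ValueError("profile needs >= 8 (position, value) pairs")
        steps = np.diff(self.positions)
        if steps.min() <= 0 or np.ptp(steps) > 1e-9:
            raise ValueError("positions must be uniform and strictly increasing")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.positions, self.values]),
                   delimiter=",", header="position_um,intensity", comments="")


def _sample_bilinear(image: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                     pixel_size: float) -> np.ndarray:
    rows = ys / pixel_size
    cols = xs / pixel_size
    eps = 1e-9
    if (rows.min() < -eps or cols.min() < -eps
            or rows.max() > image.shape[0] - 1 + eps
            or cols.max() > image.shape[1] - 1 + eps):
        raise OutOfBounds("profile ROI leaves the image")
    return map_coordinates(image, [rows, cols], order=1, mode="nearest")


def longitudinal_profile(
    image: np.ndarray,
    pixel_size: float,
    cl: Centerline,
    half_width: float = LONGITUDINAL_HALF_WIDTH,
    step: float | None = None,
    channel: str = "",
) -> IntensityProfile:
    """Mean intensity over the normal segment [-half_width, +half_width]
    at each arclength sample; positions are arclength along the axis."""
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    if step is None:
        step = pixel_size / 2
    if step <= 0:
        raise ValueError("step must be > 0")
    s = np.arange(0.0, cl.length + step / 2, step)
    s = s[s <= cl.length]
    pts = cl.point_at(s)           # (N, 2)
    nrm = cl.normal_at(s)          # (N, 2)
    n_off = max(int(np.ceil(2 * half_width / (pixel_size / 2))) + 1, 3)
    offs = np.linspace(-half_width, half_width, n_off)
    xs = pts[:, 0][:, None] + offs[None, :] * nrm[:, 0][:, None]
    ys = pts[:, 1][:, None] + offs[None, :] * nrm[:, 1][:, None]
    vals = _sample_bilinear(image, xs, ys, pixel_size).mean(axis=1)
    return IntensityProfile(s, vals, "longitudinal", channel)


def transverse_profile(
    image: np.ndarray,
    pixel_size: float,
    cl: Centerline,
    at_arclength: float,
    half_length: float = TRANSVERSE_HALF_LENGTH,
    step: float | None = None,
    channel: str = "",
) -> IntensityProfile:
    """Intensity along the local normal at one arclength; positions are
    signed distance from the centerline."""
    if not (0.0 <= at_arclength <= cl.length):
        raise ValueError("at_arclength outside the centerline span")
    if step is None:
        step = pixel_size / 2
    offs = np.arange(-half_length, half_length + step / 2, step)
    offs = offs[np.abs(offs) <= half_length + 1e-12]
    p = cl.point_at(at_arclength)
    n = cl.normal_at(at_arclength)
    xs = p[0] + offs * n[0]
    ys = p[1] + offs * n[1]
    vals = _sample_bilinear(image, xs, ys, pixel_size)
    return IntensityProfile(offs, vals, "transverse", channel)
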