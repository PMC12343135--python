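"""Synthetic two-channel myofibril micrographs with known ground truth.

Indirect-flight-muscle myofibrils are nearly uniform cylinders whose
F-actin (phalloidin) signal carries the sarcomeric banding: thin-filament
regions are singly labelled, the Z-disc overlap (where thin filaments of
adjacent sarcomeres interdigitate) is doubly labelled, and the central
H-zone carries no thin filaments at all.  A second channel images a
Z-disc marker (alpha-actinin-like), i.e. the same cylinder restricted to
narrow bands around each Z-line.

Image formation is simulated in three steps, in this order:

1. analytic ground-truth rendering (chord-weighted 2D projection of a
   uniformly labelled cylinder, normalised to peak 100 grey levels);
2. uneven labelling as zero-mean Gaussian noise (clipped at zero),
   followed by diffraction blur with an Airy-disc kernel;
3. shot noise as a per-pixel Poisson draw after scaling to photons.

All geometry is in micrometres; images use the convention that the
physical position of pixel ``i`` is ``i * pixel_size`` at the pixel
centre.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import j1

from .errors import InvalidSpec, SpecOutOfCanvas

#: Linear supersampling factor for ground-truth rendering.  At the
#: typical 50 nm pixel / 1.5 um diameter scale, 4x subpixel evaluation
#: of the analytic chord removes aliasing on the cylinder boundary.
SUPERSAMPLE = 4

#: Peak grey level of the normalised ground-truth image.  The labelling
#: noise sigma is expressed on this scale.
GROUND_TRUTH_PEAK = 100.0


@dataclass(frozen=True)
class MyofibrilSpec:
    """Geometry of one simulated myofibril.

    Parameters
    ----------
    n_sarcomeres : int
        Number of serially connected sarcomeres (Z-line to Z-line units).
        The fibril carries ``n_sarcomeres + 1`` Z-lines.
    sarcomere_length : float
        Z-line to Z-line distance, um.
    diameter : float
        Cylinder diameter, um.
    zdisc_width : float
        Width of the thin-filament overlap band centred on each Z-line, um.
    hzone_width : float
        Width of the actin-free gap centred on each M-line, um.
    orientation : float
        In-plane angle of the fibril axis, degrees counter-clockwise from
        the +x (column) axis.
    curvature : float
        Signed curvature of the axis, 1/um; 0 renders a straight fibril,
        otherwise a circular arc.
    origin : tuple of float
        (x, y) position of the first Z-line in the image frame, um.
    """

    n_sarcomeres: int
    sarcomere_length: float
    diameter: float
    zdisc_width: float = 0.12
    hzone_width: float = 0.12
    orientation: float = 0.0
    curvature: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_sarcomeres < 0:
            raise InvalidSpec("n_sarcomeres must be >= 0")
        if self.diameter <= 0:
            raise InvalidSpec("diameter must be > 0")
        if not (0 <= self.zdisc_width < self.sarcomere_length):
            raise InvalidSpec("need 0 <= zdisc_width < sarcomere_length")
        if not (0 <= self.hzone_width < self.sarcomere_length):
            raise InvalidSpec("need 0 <= hzone_width < sarcomere_length")
        if self.zdisc_width + self.hzone_width >= self.sarcomere_length:
            raise InvalidSpec("zdisc_width + hzone_width must be < sarcomere_length")

    @property
    def length(self) -> float:
        """Total axial length (first to last Z-line), um."""
        return self.n_sarcomeres * self.sarcomere_length

    def axis_point(self, s: np.ndarray | float):
        """Axis position(s) at arclength ``s`` (um) as (x, y) arrays."""
        s = np.asarray(s, dtype=float)
        theta = np.deg2rad(self.orientation)
        x0, y0 = self.origin
        if self.curvature == 0.0:
            return x0 + s * np.cos(theta), y0 + s * np.sin(theta)
        r = 1.0 / self.curvature
        # centre of the arc sits at distance r along the left normal
        cx = x0 - r * np.sin(theta)
        cy = y0 + r * np.cos(theta)
        phi = theta - np.pi / 2 * np.sign(r) + s / r
        return cx + abs(r) * np.cos(phi), cy + abs(r) * np.sin(phi)


@dataclass(frozen=True)
class ImagingSpec:
    """Optics and noise model for image formation.

    ``label_noise_sigma`` is in grey levels of the ground truth
    normalised to peak :data:`GROUND_TRUTH_PEAK`; ``photon_scale`` is
    the expected photon count per grey level.
    """

    pixel_size: float = 0.05  # um/px
    numerical_aperture: float = 1.4
    emission_wavelength: float = 525.0  # nm
    label_noise_sigma: float = 2.0
    photon_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidSpec("pixel_size must be > 0")
        if not (0 < self.numerical_aperture <= 1.7):
            raise InvalidSpec("numerical_aperture must be in (0, 1.7]")
        if self.emission_wavelength <= 0:
            raise InvalidSpec("emission_wavelength must be > 0")
        if self.label_noise_sigma < 0:
            raise InvalidSpec("label_noise_sigma must be >= 0")
        if self.photon_scale <= 0:
            raise InvalidSpec("photon_scale must be > 0")


@dataclass
class SyntheticImage:
    """Two-channel synthetic micrograph plus its generating ground truth."""

    phalloidin_channel: np.ndarray
    zdisc_channel: np.ndarray
    pixel_size: float
    ground_truth: list[MyofibrilSpec] = field(default_factory=list)
    imaging: ImagingSpec | None = None

    def to_manifest(self) -> str:
        """Serialise the generating specs to a JSON manifest string."""
        payload = {
            "pixel_size": self.pixel_size,
            "specs": [asdict(s) for s in self.ground_truth],
            "imaging": asdict(self.imaging) if self.imaging else None,
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def manifest_specs(manifest: str) -> tuple[list[MyofibrilSpec], ImagingSpec | None]:
        """Recover specs (and imaging, if present) from a manifest string."""
        payload = json.loads(manifest)
        specs = []
        for d in payload["specs"]:
            d = dict(d)
            d["origin"] = tuple(d["origin"])
            specs.append(MyofibrilSpec(**d))
        imaging = ImagingSpec(**payload["imaging"]) if payload.get("imaging") else None
        return specs, imaging


# ---------------------------------------------------------------------
# ground-truth rendering
# ---------------------------------------------------------------------

def _axial_coordinates(spec: MyofibrilSpec, xs: np.ndarray, ys: np.ndarray):
    """Map image points to fibril coordinates (arclength s, signed offset t)."""
    theta = np.deg2rad(spec.orientation)
    x0, y0 = spec.origin
    if spec.curvature == 0.0:
        dx = xs - x0
        dy = ys - y0
        s = dx * np.cos(theta) + dy * np.sin(theta)
        t = -dx * np.sin(theta) + dy * np.cos(theta)
        return s, t
    r = 1.0 / spec.curvature
    cx = x0 - r * np.sin(theta)
    cy = y0 + r * np.cos(theta)
    vx = xs - cx
    vy = ys - cy
    dist = np.hypot(vx, vy)
    phi0 = np.arctan2(y0 - cy, x0 - cx)
    dphi = np.arctan2(vy, vx) - phi0
    dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
    s = r * dphi  # positive along travel direction for either sign of r
    t = np.sign(r) * (abs(r) - dist)
    return s, t


def _axial_factor(spec: MyofibrilSpec, s: np.ndarray) -> np.ndarray:
    """Phalloidin axial intensity: 2 in Z-disc bands, 0 in H-zones, else 1."""
    L = spec.sarcomere_length
    u = np.mod(s, L)
    near_z = np.minimum(u, L - u) <= spec.zdisc_width / 2
    near_h = np.abs(u - L / 2) <= spec.hzone_width / 2
    out = np.ones_like(s)
    out[near_h] = 0.0
    out[near_z] = 2.0
    return out


def _zdisc_factor(spec: MyofibrilSpec, s: np.ndarray) -> np.ndarray:
    L = spec.sarcomere_length
    u = np.mod(s, L)
    return (np.minimum(u, L - u) <= spec.zdisc_width / 2).astype(float)


def _check_in_canvas(spec: MyofibrilSpec, pixel_size: float, canvas: tuple[int, int]):
    """Raise SpecOutOfCanvas unless the whole fibril envelope fits."""
    rows, cols = canvas
    cap = spec.zdisc_width / 2
    n = max(int(np.ceil((spec.length + 2 * cap) / (pixel_size / 2))), 2)
    s = np.linspace(-cap, spec.length + cap, n)
    ax, ay = spec.axis_point(s)
    # tangent direction via finite differences; offset by the radius both ways
    tx = np.gradient(ax)
    ty = np.gradient(ay)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm
    R = spec.diameter / 2
    edge_x = np.concatenate([ax + R * nx, ax - R * nx])
    edge_y = np.concatenate([ay + R * ny, ay - R * ny])
    xmax = (cols - 1) * pixel_size
    ymax = (rows - 1) * pixel_size
    if (edge_x.min() < 0 or edge_x.max() > xmax
            or edge_y.min() < 0 or edge_y.max() > ymax):
        raise SpecOutOfCanvas(
            f"fibril envelope [{edge_x.min():.2f},{edge_x.max():.2f}] x "
            f"[{edge_y.min():.2f},{edge_y.max():.2f}] um exceeds canvas "
            f"{xmax:.2f} x {ymax:.2f} um"
        )


def render_ground_truth(
    specs: list[MyofibrilSpec],
    imaging: ImagingSpec,
    canvas: tuple[int, int],
) -> SyntheticImage:
    """Render noiseless, unblurred two-channel ground truth.

    The phalloidin channel is the chord-weighted projection of a uniform
    cylinder with axial factor 1 in thin-filament regions, 2 in the
    Z-disc overlap and 0 in the H-zone; the Z-disc channel is the same
    transverse profile restricted to the ``n_sarcomeres + 1`` Z-disc
    bands.  Each channel is normalised to peak :data:`GROUND_TRUTH_PEAK`.
    """
    rows, cols = canvas
    px = imaging.pixel_size
    f = SUPERSAMPLE
    phall = np.zeros((rows * f, cols * f))
    zdisc = np.zeros((rows * f, cols * f))
    if specs:
        row_pos = (np.arange(rows * f) + 0.5) / f - 0.5
        col_pos = (np.arange(cols * f) + 0.5) / f - 0.5
        ys = row_pos[:, None] * px
        xs = col_pos[None, :] * px
        xs, ys = np.broadcast_arrays(xs, ys)
        for spec in specs:
            if spec.n_sarcomeres == 0:
                continue
            _check_in_canvas(spec, px, canvas)
            s, t = _axial_coordinates(spec, xs, ys)
            R = spec.diameter / 2
            # the terminal Z-discs are complete: the fibril extends half a
            # band past the first and last Z-line
            cap = spec.zdisc_width / 2
            inside = (np.abs(t) <= R) & (s >= -cap) & (s <= spec.length + cap)
            if not inside.any():
                continue
            chord = np.sqrt(np.clip(1.0 - (t[inside] / R) ** 2, 0.0, None))
            phall[inside] += chord * _axial_factor(spec, s[inside])
            zdisc[inside] += chord * _zdisc_factor(spec, s[inside])
    # bin the supersampled buffers back to the pixel grid
    phall = phall.reshape(rows, f, cols, f).mean(axis=(1, 3))
    zdisc = zdisc.reshape(rows, f, cols, f).mean(axis=(1, 3))
    for ch in (phall, zdisc):
        m = ch.max()
        if m > 0:
            ch *= GROUND_TRUTH_PEAK / m
    return SyntheticImage(phall, zdisc, px, list(specs), imaging)


# ---------------------------------------------------------------------
# point spread function
# ---------------------------------------------------------------------

def airy_psf(imaging: ImagingSpec, kernel_radius: int = 15) -> np.ndarray:
    """Airy-disc PSF kernel sampled on the pixel grid.

    ``kernel(r) ~ (2 J1(v) / v)**2`` with ``v = 2 pi NA r / lambda``;
    the returned ``(2k+1, 2k+1)`` array is rotationally symmetric and
    sums to one.  The first dark ring sits at
    ``r = 3.8317 lambda / (2 pi NA)``.
    """
    if kernel_radius < 3:
        raise ValueError("kernel_radius must be >= 3 px")
    k = int(kernel_radius)
    px_nm = imaging.pixel_size * 1000.0
    offs = np.arange(-k, k + 1, dtype=float)
    r = np.hypot(offs[:, None], offs[None, :]) * px_nm
    v = 2 * np.pi * imaging.numerical_aperture * r / imaging.emission_wavelength
    out = np.ones_like(v)
    nz = v > 0
    out[nz] = (2 * j1(v[nz]) / v[nz]) ** 2
    return out / out.sum()


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    k = kernel.shape[0] // 2
    padded = np.pad(image, k, mode="reflect")
    return fftconvolve(padded, kernel, mode="valid")


# ---------------------------------------------------------------------
# full image formation
# ---------------------------------------------------------------------

def simulate_image(
    specs: list[MyofibrilSpec],
    imaging: ImagingSpec,
    canvas: tuple[int, int],
    kernel_radius: int = 15,
    no_noise: bool = False,
) -> SyntheticImage:
    """Simulate the full image-formation pipeline.

    Order: render ground truth -> add zero-mean Gaussian labelling noise
    (clipped at 0) -> convolve with the Airy PSF (reflect padding) ->
    scale by ``photon_scale`` and draw Poisson counts.  With
    ``no_noise=True`` both noise steps are skipped and the output is the
    blurred ground truth (still scaled by ``photon_scale``), i.e. the
    expected image.  The same ``imaging.rng_seed`` reproduces the image
    bit-for-bit.
    """
    gt = render_ground_truth(specs, imaging, canvas)
    kernel = airy_psf(imaging, kernel_radius)
    rng = np.random.default_rng(imaging.rng_seed)
    channels = []
    for raw in (gt.phalloidin_channel, gt.zdisc_channel):
        img = raw
        if not no_noise and imaging.label_noise_sigma > 0:
            img = np.clip(
                img + rng.normal(0.0, imaging.label_noise_sigma, img.shape), 0.0, None
            )
        img = _convolve_reflect(img, kernel) * imaging.photon_scale
        if not no_noise:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        channels.append(img)
    return SyntheticImage(channels[0], channels[1], imaging.pixel_size,
                          list(specs), imaging)
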