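"""File I/O, analysis configuration and the end-to-end pipeline.

OME-TIFF is the interchange image format: two channels (phalloidin
first, Z-disc marker second) with the physical pixel size carried in
the OME metadata.  ``analyze`` runs the whole measurement chain —
project, segment, centerline, profiles, model fits, superplot summary —
and logs one line per fibril per stage, including a reason code for
every quality-control rejection.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fitmodels, profile as profiling, segment
from .errors import ChannelCountError, MissingPixelSize, MyomorphError
from .morphometrics import MeasurementTable, summarize
from .segment import Centerline, ImageStack
from .simgen import SyntheticImage

log = logging.getLogger("myomorph")


# ---------------------------------------------------------------------
# OME-TIFF
# ---------------------------------------------------------------------

def write_ome_tiff(img: SyntheticImage, path, manifest: bool = True) -> None:
    """Write a two-channel OME-TIFF (axes CYX, PhysicalSizeX/Y in um)
    and, for synthetic images, a JSON ground-truth manifest alongside."""
    path = Path(path)
    data = np.stack([img.phalloidin_channel, img.zdisc_channel]).astype(
        np.float32
    )
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": img.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": img.pixel_size,
            "PhysicalSizeYUnit": "µm",
        },
    )
    if manifest and img.ground_truth:
        path.with_suffix(".manifest.json").write_text(img.to_manifest())


def _pixel_size_from_ome(tif: tifffile.TiffFile) -> float | None:
    if not tif.ome_metadata:
        return None
    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
            return float(el.attrib["PhysicalSizeX"])
    return None


def load_stack(
    path,
    pixel_size_override: float | None = None,
    channel_order: tuple[int, int] = (0, 1),
) -> ImageStack:
    """Read a two-channel TIFF/OME-TIFF into an :class:`ImageStack`.

    Channels are mapped by ``channel_order`` (default: channel 0 is
    phalloidin, channel 1 the Z-disc marker).  The pixel size comes from
    OME metadata unless overridden.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        px = _pixel_size_from_ome(tif)
    if pixel_size_override is not None:
        px = pixel_size_override
    if px is None:
        raise MissingPixelSize(
            f"{path}: no PhysicalSizeX metadata; pass pixel_size_override"
        )
    if "C" in axes:
        data = np.moveaxis(data, axes.index("C"), 0)
    elif data.ndim >= 3:
        pass  # assume channels first
    else:
        raise ChannelCountError(f"{path}: single-channel image")
    if data.shape[0] < 2:
        raise ChannelCountError(
            f"{path}: need >= 2 channels, found {data.shape[0]}"
        )
    ph = data[channel_order[0]].astype(float)
    zd = data[channel_order[1]].astype(float)
    return ImageStack(ph, zd, float(px))


def write_label_image(masks: list[segment.MyofibrilMask], path) -> None:
    """Write segmentation masks as a label-image TIFF."""
    if not masks:
        return
    lbl = np.zeros(masks[0].mask.shape, dtype=np.uint16)
    for i, m in enumerate(masks, start=1):
        lbl[m.mask] = i
    tifffile.imwrite(str(path), lbl)


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All pipeline defaults in one serialisable object."""

    mode: str = "auto"                      # "auto" | "manual"
    threshold_method: str = "otsu"
    min_length_um: float = 4.0
    longitudinal_half_width_um: float = 0.3
    transverse_half_length_um: float = 2.5
    profile_step_um: float | None = None    # default: pixel_size / 2
    min_prominence_frac: float = 0.2
    psf_sigma_init_um: float = fitmodels.PSF_SIGMA_INIT
    exclude_terminal: bool = True
    n_transverse: int = 10
    centerline_smoothing: float | None = None
    pixel_size_override: float | None = None
    channel_order: tuple[int, int] = (0, 1)
    polyline_sidecar: str | None = None     # manual mode: JSON polylines

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.mode not in ("auto", "manual"):
            raise ValueError(f"mode must be auto|manual, got {cfg.mode!r}")
        cfg.channel_order = tuple(cfg.channel_order)
        return cfg

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        d = asdict(self)
        d["channel_order"] = list(self.channel_order)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_polylines(path) -> dict[str, np.ndarray]:
    """Manual-mode sidecar: JSON list of {"id": ..., "points_um": [[x,y],...]}."""
    payload = json.loads(Path(path).read_text())
    return {str(e["id"]): np.asarray(e["points_um"], dtype=float)
            for e in payload}


# ---------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------

@dataclass
class FibrilResult:
    """Measurements and diagnostics for one analysed myofibril."""

    fibril_id: str
    sarcomere_lengths_um: np.ndarray
    diameter_um: float
    n_peaks: int
    length_residual_rms: float
    diameter_fits: list = field(default_factory=list)


def _centerlines_auto(stack: ImageStack, cfg: AnalysisConfig):
    masks = segment.segment_myofibrils(
        stack.phalloidin_channel, stack.pixel_size,
        min_length_um=cfg.min_length_um,
        threshold_method=cfg.threshold_method,
    )
    out = []
    for m in masks:
        fid = f"fibril{m.label:03d}"
        if m.flagged:
            reasons = [k for k, v in m.qc_flags.items() if v]
            log.info("qc_reject id=%s reasons=%s", fid, ",".join(reasons))
            continue
        try:
            cl = segment.fit_centerline(
                m, stack.pixel_size,
                smoothing=cfg.centerline_smoothing,
                min_length_um=cfg.min_length_um,
                image=stack.phalloidin_channel,
            )
        except MyomorphError as exc:
            log.info("qc_reject id=%s reasons=%s", fid,
                     type(exc).__name__)
            continue
        log.info("centerline id=%s length_um=%.3f", fid, cl.length)
        out.append((fid, cl))
    return out


def _centerlines_manual(cfg: AnalysisConfig):
    if not cfg.polyline_sidecar:
        raise ValueError("manual mode needs a polyline_sidecar path")
    out = []
    for fid, pts in load_polylines(cfg.polyline_sidecar).items():
        cl = Centerline.from_points(pts, smoothing=0.0)
        log.info("manual_centerline id=%s length_um=%.3f", fid, cl.length)
        out.append((fid, cl))
    return out


def analyze_stack(
    stack: ImageStack, cfg: AnalysisConfig | None = None,
    experiment: str = "exp1",
) -> tuple[MeasurementTable, pd.DataFrame]:
    """Run the full measurement pipeline on one loaded stack.

    Returns the superplot summary plus a per-fit diagnostics table
    (one row per fibril: peak count, residual RMS, disc-fit stats).
    """
    cfg = cfg or AnalysisConfig()
    flat = segment.project_stack(stack)
    if cfg.mode == "manual":
        centerlines = _centerlines_manual(cfg)
    else:
        centerlines = _centerlines_auto(flat, cfg)
    results: list[FibrilResult] = []
    for fid, cl in centerlines:
        try:
            prof = profiling.longitudinal_profile(
                flat.zdisc_channel, flat.pixel_size, cl,
                half_width=cfg.longitudinal_half_width_um,
                step=cfg.profile_step_um, channel="zdisc",
            )
            peaks = fitmodels.fit_gaussian_peaks(
                prof, min_prominence_frac=cfg.min_prominence_frac
            )
            sl = fitmodels.sarcomere_lengths(
                peaks, exclude_terminal=cfg.exclude_terminal
            )
            dm = fitmodels.measure_diameter(
                flat.phalloidin_channel, flat.pixel_size, cl,
                n_positions=cfg.n_transverse,
                half_length=cfg.transverse_half_length_um,
                psf_sigma_init=cfg.psf_sigma_init_um,
            )
        except MyomorphError as exc:
            log.info("fit_reject id=%s reasons=%s", fid, type(exc).__name__)
            continue
        log.info("measured id=%s n_sarcomeres=%d sl_mean=%.4f diam=%.4f",
                 fid, len(sl.distances), sl.mean, dm.diameter)
        results.append(FibrilResult(fid, sl.distances, dm.diameter,
                                    peaks.n_peaks, peaks.residual_rms,
                                    dm.fits))
    if not results:
        raise MyomorphError("no analysable myofibril in this stack")
    rows = []
    for r in results:
        for s in r.sarcomere_lengths_um:
            rows.append({"experiment": experiment, "myofibril": r.fibril_id,
                         "sarcomere_length_um": s,
                         "diameter_um": r.diameter_um})
    table = summarize(pd.DataFrame(rows))
    diag = pd.DataFrame([
        {
            "fibril": r.fibril_id,
            "n_peaks": r.n_peaks,
            "gauss_residual_rms": r.length_residual_rms,
            "sl_mean_um": float(np.mean(r.sarcomere_lengths_um)),
            "diameter_um": r.diameter_um,
            "n_disc_converged": sum(1 for f in r.diameter_fits
                                    if f is not None and f.converged),
        }
        for r in results
    ])
    return table, diag


def analyze(
    paths, cfg: AnalysisConfig | None = None,
) -> tuple[MeasurementTable, pd.DataFrame]:
    """Analyse one file or a list of files (each file = one experiment)."""
    cfg = cfg or AnalysisConfig()
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_rows = []
    diags = []
    for i, p in enumerate(paths, start=1):
        stack = load_stack(p, cfg.pixel_size_override, cfg.channel_order)
        table, diag = analyze_stack(stack, cfg, experiment=f"exp{i}")
        all_rows.append(table.measurements)
        diag.insert(0, "experiment", f"exp{i}")
        diags.append(diag)
    return (summarize(pd.concat(all_rows, ignore_index=True)),
            pd.concat(diags, ignore_index=True))
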