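"""Filament lengths from band widths, stage tables and superplot summaries.

In a fibrillar sarcomere the filament lengths follow directly from the
band widths measurable in (super-resolution) micrographs:

* thick filaments span the A-band, so
  ``L_thick = L_sarcomere - W_I_band``
  (one I-band half-width on each side of the A-band);
* thin filaments run from their barbed-end overlap inside the Z-disc to
  their pointed ends at the H-zone border, so
  ``L_thin = (L_sarcomere - W_H_zone + W_Z_disc) / 2``.

The summary follows the superplot convention used for hierarchical
imaging data: individual measurements pool into per-myofibril means,
myofibril means into per-experiment means, and the grand mean is the
mean of experiment means (never the pooled mean, so one over-sampled
experiment cannot dominate).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import EmptyInput, NegativeLength

STAGE_CSV_COLUMNS = [
    "stage", "L_sarcomere_um", "W_I_band_um", "W_H_zone_um",
    "W_Z_disc_um", "n_thick", "spacing_nm",
]


def thick_length(L_sarcomere: float, W_I_band: float) -> float:
    """Thick-filament length, um: ``L_sarcomere - 2 * (W_I_band / 2)``."""
    if not 0 <= W_I_band < L_sarcomere:
        raise NegativeLength(
            f"W_I_band={W_I_band} not in [0, L_sarcomere={L_sarcomere})"
        )
    return L_sarcomere - W_I_band


def thin_length(L_sarcomere: float, W_H_zone: float, W_Z_disc: float) -> float:
    """Thin-filament length, um:
    ``L_sarcomere/2 - W_H_zone/2 + W_Z_disc/2``."""
    if W_H_zone < 0 or W_Z_disc < 0:
        raise NegativeLength("band widths must be >= 0")
    out = (L_sarcomere - W_H_zone + W_Z_disc) / 2.0
    if W_H_zone >= L_sarcomere or out <= 0:
        raise NegativeLength(
            f"widths (W_H={W_H_zone}, W_Z={W_Z_disc}) inconsistent with "
            f"L_sarcomere={L_sarcomere}"
        )
    return out


@dataclass(frozen=True)
class StageMorphometrics:
    """Average sarcomere geometry at one developmental stage.

    Lengths in um, spacing in nm.  ``L_thick`` and ``L_thin`` are derived
    from the band widths so the length identities hold exactly.
    """

    stage: str
    L_sarcomere: float
    W_I_band: float
    W_H_zone: float
    W_Z_disc: float
    n_thick: int
    spacing_nm: float

    def __post_init__(self) -> None:
        for name in ("W_I_band", "W_H_zone", "W_Z_disc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.W_I_band >= self.L_sarcomere:
            raise ValueError("W_I_band must be < L_sarcomere")
        if self.W_H_zone >= self.L_sarcomere:
            raise ValueError("W_H_zone must be < L_sarcomere")
        if self.n_thick < 0:
            raise ValueError("n_thick must be >= 0")
        if self.spacing_nm <= 0:
            raise ValueError("spacing_nm must be > 0")

    @property
    def L_thick(self) -> float:
        return thick_length(self.L_sarcomere, self.W_I_band)

    @property
    def L_thin(self) -> float:
        return thin_length(self.L_sarcomere, self.W_H_zone, self.W_Z_disc)


def load_stage_table() -> pd.DataFrame:
    """Packaged per-stage morphometric defaults (indexed by stage label)."""
    with resources.files("myomorph").joinpath("data/stages.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("stage", drop=False)


def stage_morphometrics(stage: str) -> StageMorphometrics:
    """Look one stage up in the packaged table."""
    df = load_stage_table()
    if stage not in df.index:
        raise KeyError(
            f"unknown stage {stage!r}; available: {list(df.index)}"
        )
    r = df.loc[stage]
    return StageMorphometrics(
        stage=str(r["stage"]),
        L_sarcomere=float(r["L_sarcomere_um"]),
        W_I_band=float(r["W_I_band_um"]),
        W_H_zone=float(r["W_H_zone_um"]),
        W_Z_disc=float(r["W_Z_disc_um"]),
        n_thick=int(r["n_thick"]),
        spacing_nm=float(r["spacing_nm"]),
    )


# ---------------------------------------------------------------------
# superplot-style hierarchical summary
# ---------------------------------------------------------------------

@dataclass
class MeasurementTable:
    """Hierarchical summary of per-sarcomere measurements.

    ``grand`` holds the mean of per-experiment means and the s.d. across
    experiments for each measured column; ``n_label`` reports sample
    size as "experiments/individual measurements".
    """

    measurements: pd.DataFrame
    per_myofibril: pd.DataFrame
    per_experiment: pd.DataFrame
    grand: pd.DataFrame
    n_experiments: int
    n_measurements: int
    single_experiment: bool

    @property
    def n_label(self) -> str:
        return f"{self.n_experiments}/{self.n_measurements}"


def summarize(rows: pd.DataFrame) -> MeasurementTable:
    """Superplot aggregation of a per-sarcomere measurement table.

    ``rows`` needs columns ``experiment`` and ``myofibril`` plus one or
    more numeric value columns (e.g. ``sarcomere_length_um``,
    ``diameter_um``).  NaNs are ignored per column.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    if len(rows) == 0:
        raise EmptyInput("no measurements")
    for col in ("experiment", "myofibril"):
        if col not in rows.columns:
            raise ValueError(f"missing required column {col!r}")
    value_cols = [c for c in rows.columns
                  if c not in ("experiment", "myofibril")
                  and np.issubdtype(rows[c].dtype, np.number)]
    if not value_cols:
        raise ValueError("no numeric value columns to summarise")
    per_myo = rows.groupby(["experiment", "myofibril"])[value_cols].mean()
    per_exp = per_myo.groupby("experiment").mean()
    grand = pd.DataFrame({
        "mean": per_exp.mean(),
        "sd": per_exp.std(ddof=1) if len(per_exp) > 1
              else pd.Series(0.0, index=value_cols),
    })
    return MeasurementTable(
        measurements=rows.reset_index(drop=True),
        per_myofibril=per_myo,
        per_experiment=per_exp,
        grand=grand,
        n_experiments=len(per_exp),
        n_measurements=int(rows[value_cols].notna().any(axis=1).sum()),
        single_experiment=len(per_exp) == 1,
    )
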