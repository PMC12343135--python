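"""Hexagonal myofilament lattice and scaled 3D sarcomere models.

Thick (myosin) filaments of fibrillar flight muscle pack on a triangular
(hexagonal) lattice with centre-to-centre spacing ``d``; thin (actin)
filaments sit in the MyAc layer at the midpoint of every nearest-
neighbour thick-filament pair.  Each interior thick filament therefore
touches 6 thin sites, each shared between 2 thick filaments, giving the
characteristic 3 thin filaments per thick filament in the bulk.

Lattices are built in concentric hexagonal rings from a central site;
a partial outer ring is filled in angular order (counter-clockwise from
angle 0).  The 3D model extrudes the cross-section: thick filaments are
centred on the M-line, and every thin lattice site carries two thin
filaments, one anchored at each Z-line and reaching toward the M-line,
mirror-symmetric about it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    GeometryError,
    InvalidCount,
    NoInteriorSites,
    NonPositiveGrowth,
    NotInterior,
)
from .morphometrics import StageMorphometrics

_NEIGHBOUR_TOL = 1e-6  # relative tolerance on the nearest-neighbour distance


@dataclass
class LatticeModel:
    """2D cross-sectional filament positions (nm)."""

    thick: np.ndarray          # (n_thick, 2) nm
    thin: np.ndarray           # (n_thin, 2) nm
    spacing: float             # d, nm
    interior: np.ndarray       # bool per thick site (6 thick neighbours)

    @property
    def n_thick(self) -> int:
        return len(self.thick)

    @property
    def n_thin(self) -> int:
        return len(self.thin)


@dataclass
class Sarcomere3DModel:
    """Filament spans of one average sarcomere.

    Each row of ``filaments`` is (type, x_nm, y_nm, z_start_um, z_end_um)
    with z=0 and z=L_sarcomere at the Z-lines and the M-line at
    z = L_sarcomere / 2.
    """

    filaments: list[tuple[str, float, float, float, float]]
    L_sarcomere: float
    stage: StageMorphometrics
    lattice: LatticeModel

    @property
    def m_line(self) -> float:
        return self.L_sarcomere / 2.0

    def spans(self, kind: str) -> np.ndarray:
        return np.array([[f[3], f[4]] for f in self.filaments if f[0] == kind])

    # --- re-measurement of band widths from the filament geometry ----
    def measured_W_I_band(self) -> float:
        """Twice the thick-filament end distance to the nearer Z-line."""
        th = self.spans("thick")
        return 2.0 * float(np.min([th[:, 0].min(),
                                   self.L_sarcomere - th[:, 1].max()]))

    def measured_W_H_zone(self) -> float:
        """Twice the minimum thin pointed-end distance to the M-line."""
        tn = self.spans("thin")
        ends = np.where(tn.mean(axis=1) < self.m_line, tn[:, 1], tn[:, 0])
        return 2.0 * float(np.min(np.abs(self.m_line - ends)))

    def measured_W_Z_disc(self) -> float:
        """Twice the maximum thin-filament overhang past its Z-line."""
        tn = self.spans("thin")
        over = np.where(tn.mean(axis=1) < self.m_line,
                        -tn[:, 0], tn[:, 1] - self.L_sarcomere)
        return 2.0 * float(np.max(over))

    def export_obj(self, path, thick_radius_nm: float = 8.0,
                   thin_radius_nm: float = 4.0, sections: int = 12) -> None:
        """Write the filaments as display-only cylinders in Wavefront OBJ
        (x, y in nm; z scaled from um to nm)."""
        import trimesh

        meshes = []
        for kind, x, y, z0, z1 in self.filaments:
            r = thick_radius_nm if kind == "thick" else thin_radius_nm
            h = (z1 - z0) * 1000.0
            cyl = trimesh.creation.cylinder(radius=r, height=h,
                                            sections=sections)
            cyl.apply_translation([x, y, z0 * 1000.0 + h / 2.0])
            meshes.append(cyl)
        trimesh.util.concatenate(meshes).export(path, file_type="obj")

    def export_csv(self, path) -> None:
        """Exact filament spans as CSV."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["type", "x_nm", "y_nm", "z_start_um", "z_end_um"])
            w.writerows(self.filaments)


# ---------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------

def _ring_sites(k: int) -> np.ndarray:
    """Axial coordinates of hexagonal ring k (6k sites), unit spacing."""
    if k == 0:
        return np.zeros((1, 2))
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, np.sqrt(3) / 2.0])
    corners = [k * a1, k * a2, k * (a2 - a1), -k * a1, -k * a2, k * (a1 - a2)]
    sites = []
    for i in range(6):
        c0, c1 = corners[i], corners[(i + 1) % 6]
        for j in range(k):
            sites.append(c0 + (c1 - c0) * (j / k))
    return np.array(sites)


def build_hex_lattice(n_thick: int, d: float) -> LatticeModel:
    """Triangular lattice of ``n_thick`` thick filaments with spacing
    ``d`` (nm), thin sites at all nearest-neighbour bond midpoints.

    Rings are filled concentrically; a partial outer ring is filled in
    angular order counter-clockwise from angle 0 (ties toward 0).
    """
    if n_thick < 1:
        raise InvalidCount("n_thick must be >= 1")
    if d <= 0:
        raise InvalidCount("spacing d must be > 0")
    sites = []
    placed = 0
    k = 0
    while placed < n_thick:
        ring = _ring_sites(k)
        remaining = n_thick - placed
        if len(ring) > remaining:
            ang = np.mod(np.arctan2(ring[:, 1], ring[:, 0]), 2 * np.pi)
            ring = ring[np.argsort(ang, kind="stable")][:remaining]
        sites.append(ring)
        placed += len(ring)
        k += 1
    thick = np.vstack(sites) * d
    tree = cKDTree(thick)
    pairs = tree.query_pairs(d * (1 + _NEIGHBOUR_TOL), output_type="ndarray")
    if len(pairs):
        thin = (thick[pairs[:, 0]] + thick[pairs[:, 1]]) / 2.0
    else:
        thin = np.zeros((0, 2))
    counts = np.zeros(len(thick), dtype=int)
    for i, j in pairs:
        counts[i] += 1
        counts[j] += 1
    return LatticeModel(thick, thin, float(d), counts == 6)


def thin_neighbours(lat: LatticeModel, site: int) -> int:
    """Number of thin sites at distance d/2 from an interior thick site
    (6 by construction)."""
    if not lat.interior[site]:
        raise NotInterior(f"site {site} is on the lattice boundary")
    dist = np.linalg.norm(lat.thin - lat.thick[site], axis=1)
    return int(np.sum(np.abs(dist - lat.spacing / 2)
                      <= lat.spacing * _NEIGHBOUR_TOL))


def interior_thin_per_thick(lat: LatticeModel) -> float:
    """Mean thin filaments per interior thick filament, each adjacent
    thin site weighted 1/2 (it is shared by two thick filaments)."""
    if not lat.interior.any():
        raise NoInteriorSites("no thick site with 6 thick neighbours")
    ratios = [thin_neighbours(lat, i) * 0.5
              for i in np.flatnonzero(lat.interior)]
    return float(np.mean(ratios))


def equivalent_diameter(n_thick: int, d: float) -> float:
    """Area-equivalent circular diameter (um) of ``n_thick`` filaments
    hexagonally packed at spacing ``d`` nm: each filament occupies a
    unit cell of area ``(sqrt(3)/2) d^2``."""
    if n_thick < 0:
        raise InvalidCount("n_thick must be >= 0")
    if d <= 0:
        raise InvalidCount("spacing d must be > 0")
    area_nm2 = n_thick * (np.sqrt(3) / 2.0) * d * d
    return 2.0 * np.sqrt(area_nm2 / np.pi) / 1000.0


def incorporation_time(n1: int, n2: int, delta_t_hours: float) -> float:
    """Minutes per incorporated thick filament (equivalently per six thin
    filaments) over a developmental interval: ``60 * dt / (n2 - n1)``."""
    if n2 <= n1:
        raise NonPositiveGrowth(f"count did not grow: {n1} -> {n2}")
    if delta_t_hours <= 0:
        raise NonPositiveGrowth("delta_t must be > 0")
    return 60.0 * delta_t_hours / (n2 - n1)


# ---------------------------------------------------------------------
# 3D sarcomere model
# ---------------------------------------------------------------------

def build_3d_sarcomere(stage: StageMorphometrics,
                       d: float | None = None) -> Sarcomere3DModel:
    """Scaled 3D model of the average sarcomere at one stage.

    Thick filaments are centred on the M-line with length ``L_thick``;
    every thin lattice site carries two thin filaments, one per Z-line,
    spanning ``[-W_Z_disc/2, L_thin - W_Z_disc/2]`` and its mirror image
    about the M-line.  Consequently the pointed-end distance to the
    M-line is ``W_H_zone/2`` and the thick-end distance to the Z-line is
    ``W_I_band/2`` — exact identities under the band-width equations.
    """
    if d is None:
        d = stage.spacing_nm
    Ls = stage.L_sarcomere
    Lt, Ln = stage.L_thick, stage.L_thin
    Wz = stage.W_Z_disc
    if Ln > Ls / 2 + Wz / 2 + 1e-12:
        raise GeometryError("thin filaments would cross the M-line")
    lat = build_hex_lattice(stage.n_thick, d)
    filaments: list[tuple[str, float, float, float, float]] = []
    z0t, z1t = Ls / 2 - Lt / 2, Ls / 2 + Lt / 2
    if z0t >= z1t:
        raise GeometryError("inverted thick-filament span")
    for x, y in lat.thick:
        filaments.append(("thick", float(x), float(y), z0t, z1t))
    za0, za1 = -Wz / 2, Ln - Wz / 2          # anchored at Z-line z=0
    zb0, zb1 = Ls - Ln + Wz / 2, Ls + Wz / 2  # mirror, anchored at z=Ls
    if za0 >= za1:
        raise GeometryError("inverted thin-filament span")
    for x, y in lat.thin:
        filaments.append(("thin", float(x), float(y), za0, za1))
        filaments.append(("thin", float(x), float(y), zb0, zb1))
    return Sarcomere3DModel(filaments, Ls, stage, lat)
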