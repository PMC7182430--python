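"""Membrane-geometry calculations: nanodisc capacity and leaflet footprints.

Two estimates connect the lipidomics to membrane structure.  First, the
carrying capacity of a SMALP nanodisc: the polymer belt bounds a disc of
~9 nm; subtracting the belt rim and a typical membrane-protein cross-section
leaves an annulus whose two leaflets hold the periprotein lipids.  Second,
the cross-sectional footprint of a membrane-positioned protein at each
leaflet plane, computed by polar wedge integration: a fan of n wedges is
drawn from the protein center, the most distant atom within each wedge sets
the wedge radius r_i, and the footprint area is Σ r_i²·tan(θ/2) with
θ = 2π/n.  Comparing the footprints of two conformations of a transporter
gives the number of lipids each leaflet must gain or lose during the
conformational cycle.

Structures must already be membrane-positioned (OPM convention: the membrane
normal along z, leaflet planes marked by DUM pseudo-atoms), or the planes
supplied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "GeometryParams",
    "MembraneStructure",
    "WedgeFan",
    "LeafletFootprint",
    "read_membrane_pdb",
    "leaflet_cross_section",
    "leaflet_footprint",
    "lipid_count_in_circle",
    "conformational_lipid_delta",
    "smalp_lipid_capacity",
]


@dataclass(frozen=True)
class GeometryParams:
    """Geometric constants of the analysis.

    ``area_per_lipid`` (47.1 Ų = 0.471 nm²) is the average in-plane area of
    one plasma-membrane lipid; ``circle_radius`` (35 Å) bounds the 1–2 lipid
    shells around the protein whose occupancy is counted.  The SMALP disc
    diameter (9 ± 1 nm) minus the 1 nm SMA polymer rim bounds the lipid-
    accessible area of a nanodisc; ``protein_area`` (20 nm²) is a typical
    membrane-protein cross-section.
    """

    area_per_lipid: float = 47.1  # Å^2
    circle_radius: float = 35.0  # Å
    slab_half_width: float = 2.0  # Å
    n_wedges: int = 80
    smalp_diameter_nm: float = 9.0
    sma_rim_nm: float = 1.0
    protein_area_nm2: float = 20.0

    def __post_init__(self) -> None:
        if self.n_wedges < 8:
            raise ValueError("need at least 8 wedges")
        for name in ("area_per_lipid", "circle_radius", "slab_half_width",
                     "smalp_diameter_nm", "sma_rim_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MembraneStructure:
    """Heavy-atom coordinates with leaflet planes (Å, membrane normal = z)."""

    elements: np.ndarray  # (N,) str
    coords: np.ndarray  # (N, 3) float
    z_outer: float
    z_inner: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.z_outer <= self.z_inner:
            raise ValueError("z_outer must exceed z_inner")
        between = (self.coords[:, 2] >= self.z_inner) & (
            self.coords[:, 2] <= self.z_outer
        )
        if not between.any():
            raise ValueError("no atoms between the leaflet planes")

    def plane(self, leaflet: str) -> float:
        if leaflet == "outer":
            return self.z_outer
        if leaflet == "inner":
            return self.z_inner
        raise ValueError(f"unknown leaflet {leaflet!r}")


@dataclass
class WedgeFan:
    """Per-wedge maximum radii of a polar fan around the protein center."""

    n_wedges: int
    radii: np.ndarray  # (n,) Å, 0 for empty wedges
    center: tuple[float, float]

    @property
    def theta(self) -> float:
        return 2.0 * math.pi / self.n_wedges

    @property
    def area(self) -> float:
        """Σ r_i²·tan(θ/2): each wedge as two right triangles of half-angle θ/2."""
        return float(np.sum(self.radii**2) * math.tan(self.theta / 2.0))


@dataclass
class LeafletFootprint:
    """Protein footprint and lipid occupancy at one leaflet plane."""

    leaflet: str
    area: float  # Å^2
    lipid_count: int
    circle_radius: float
    params: GeometryParams


def read_membrane_pdb(
    path: str | Path,
    planes: tuple[float, float] | None = None,
    label: str = "",
) -> MembraneStructure:
    """Read a membrane-positioned PDB file.

    Leaflet planes come from OPM DUM pseudo-atoms (two z-levels of dummy
    atoms marking the hydrophobic boundaries) unless ``planes``
    (z_outer, z_inner) is given, which takes precedence.  Hydrogens, waters,
    and the DUM markers themselves are excluded from the atom set.
    """
    structure = gemmi.read_pdb(str(path))
    elements, coords, dum_z = [], [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.name == "DUM":
                    dum_z.extend(atom.pos.z for atom in residue)
                    continue
                if residue.name == "HOH":
                    continue
                for atom in residue:
                    if atom.element.name == "H":
                        continue
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if planes is not None:
        z_outer, z_inner = planes
    elif dum_z:
        dum_z = np.asarray(dum_z)
        mid = dum_z.mean()
        z_outer = float(dum_z[dum_z >= mid].mean())
        z_inner = float(dum_z[dum_z < mid].mean())
    else:
        raise ValueError(
            f"{path}: no DUM leaflet markers found and no explicit planes given"
        )
    if not coords:
        raise ValueError(f"{path}: no heavy atoms parsed")
    return MembraneStructure(
        elements=np.asarray(elements),
        coords=np.asarray(coords, dtype=float),
        z_outer=float(z_outer),
        z_inner=float(z_inner),
        label=label or Path(path).stem,
    )


def leaflet_cross_section(
    structure: MembraneStructure,
    leaflet: str,
    params: GeometryParams | None = None,
) -> tuple[WedgeFan, float]:
    """Wedge-integrated protein cross-section at one leaflet plane.

    Atoms within ``slab_half_width`` of the plane define the slab; the fan
    center is their x/y centroid; each wedge's radius is the largest in-plane
    distance of a slab atom falling in that wedge (0 if empty).  Returns the
    fan and its area Σ r_i²·tan(θ/2) in Ų.
    """
    params = params or GeometryParams()
    plane = structure.plane(leaflet)
    z = structure.coords[:, 2]
    slab = structure.coords[np.abs(z - plane) <= params.slab_half_width]
    if slab.size == 0:
        raise ValueError(f"no atoms within the {leaflet}-leaflet slab")
    cx, cy = slab[:, 0].mean(), slab[:, 1].mean()
    dx = slab[:, 0] - cx
    dy = slab[:, 1] - cy
    r = np.hypot(dx, dy)
    angle = np.mod(np.arctan2(dy, dx), 2.0 * math.pi)
    n = params.n_wedges
    idx = np.minimum((angle / (2.0 * math.pi) * n).astype(int), n - 1)
    radii = np.zeros(n)
    np.maximum.at(radii, idx, r)
    fan = WedgeFan(n_wedges=n, radii=radii, center=(float(cx), float(cy)))
    return fan, fan.area


def lipid_count_in_circle(
    protein_area: float, params: GeometryParams | None = None
) -> int:
    """Lipids fitting between the protein footprint and a bounding circle.

    round((π·radius² − protein_area) / area_per_lipid), floored at 0.
    """
    params = params or GeometryParams()
    if protein_area < 0:
        raise ValueError("protein area must be non-negative")
    free = math.pi * params.circle_radius**2 - protein_area
    return max(0, int(round(free / params.area_per_lipid)))


def leaflet_footprint(
    structure: MembraneStructure,
    leaflet: str,
    params: GeometryParams | None = None,
) -> LeafletFootprint:
    """Cross-section area and in-circle lipid count for one leaflet."""
    params = params or GeometryParams()
    _, area = leaflet_cross_section(structure, leaflet, params)
    return LeafletFootprint(
        leaflet=leaflet,
        area=area,
        lipid_count=lipid_count_in_circle(area, params),
        circle_radius=params.circle_radius,
        params=params,
    )


def conformational_lipid_delta(
    inward: tuple[LeafletFootprint, LeafletFootprint],
    outward: tuple[LeafletFootprint, LeafletFootprint],
) -> dict[str, int]:
    """Per-leaflet lipid gain/loss for the inward → outward transition.

    Both conformations must have been analyzed with identical parameters.
    Returns {"outer": Δ, "inner": Δ} with Δ = count(outward) − count(inward).
    """
    by_leaflet = {}
    for fp_in in inward:
        fp_out = next((f for f in outward if f.leaflet == fp_in.leaflet), None)
        if fp_out is None:
            raise ValueError(f"outward conformation missing {fp_in.leaflet} leaflet")
        if fp_in.params != fp_out.params:
            raise ValueError("footprints computed with mismatched parameters")
        by_leaflet[fp_in.leaflet] = fp_out.lipid_count - fp_in.lipid_count
    return by_leaflet


def smalp_lipid_capacity(params: GeometryParams | None = None) -> int:
    """Lipids (both leaflets) in a SMALP around one protein.

    The polymer rim reduces the disc radius; the remaining bilayer area minus
    the protein cross-section, doubled for the two leaflets, divided by the
    area per lipid.  Zero if the protein fills the disc.
    """
    params = params or GeometryParams()
    radius_nm = params.smalp_diameter_nm / 2.0 - params.sma_rim_nm
    if radius_nm <= 0:
        raise ValueError("SMA rim is at least as large as the disc radius")
    free_nm2 = math.pi * radius_nm**2 - params.protein_area_nm2
    if free_nm2 <= 0:
        return 0
    apl_nm2 = params.area_per_lipid / 100.0
    return int(round(free_nm2 * 2.0 / apl_nm2))


def with_circle_radius(params: GeometryParams, radius: float) -> GeometryParams:
    """Convenience: copy of params with a different counting circle."""
    return replace(params, circle_radius=radius)
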