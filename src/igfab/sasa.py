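"""Solvent-accessible surface area by the Shrake-Rupley point-sampling method.

Each atom's van der Waals sphere is expanded by the probe radius and covered
with quasi-uniform surface points (a Fibonacci/golden-section lattice); the
accessible area is the fraction of points not inside any neighbouring expanded
sphere. Totals are partitioned into polar (N, O and attached polar hydrogens)
and non-polar contributions, and interface burial on dimerisation is obtained
by subtracting the complex total from the sum of the subunit totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from ._pdb import residues_of

#: Van der Waals radii by element (Angstrom); a standard protein set.
DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
POLAR_ELEMENTS = frozenset({"N", "O"})

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and total accessible areas with the parameters used."""

    atom_areas: np.ndarray  # Angstrom^2, one per atom
    total: float
    polar: float
    nonpolar: float
    probe: float
    n_points: int
    radii_label: str = "default"

    def __post_init__(self) -> None:
        if self.atom_areas.size and self.atom_areas.min() < 0:
            raise ValueError("negative per-atom area")
        if abs(self.polar + self.nonpolar - self.total) > 1e-6:
            raise ValueError("polar + nonpolar != total")


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _element_of(atom) -> str:
    el = (getattr(atom, "element", "") or "").strip().upper()
    if not el:
        el = atom.get_name().strip()[:1].upper()
    return el


def structure_atoms(structure):
    """Atoms of a structure with coordinates, elements and polarity flags."""
    atoms = [a for r in residues_of(structure) for a in r]
    coords = np.array([a.coord for a in atoms], dtype=float)
    elements = [_element_of(a) for a in atoms]
    return atoms, coords, elements


def sasa_spheres(coords: np.ndarray, radii: np.ndarray,
                 probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Shrake-Rupley per-sphere accessible areas for arbitrary spheres."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    unit = sphere_points(n_points)
    expanded = radii + probe
    areas = np.empty(n_atoms)
    tree = cKDTree(coords)
    max_r = expanded.max() if n_atoms else 0.0
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i],
                                                       expanded[i] + max_r)
                      if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * exposed.mean()
    return areas


def atom_sasa(structure, probe: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS,
              radii: Mapping[str, float] = DEFAULT_RADII,
              polar_elements=POLAR_ELEMENTS) -> SasaResult:
    """Solvent-accessible surface area of a structure, with polar partition."""
    if probe <= 0:
        raise ValueError("probe radius must be > 0")
    atoms, coords, elements = structure_atoms(structure)
    if not atoms:
        raise ValueError("empty structure: no atoms")
    try:
        r = np.array([radii[e] for e in elements])
    except KeyError as err:
        raise KeyError(f"no radius for element {err.args[0]!r}") from None
    areas = sasa_spheres(coords, r, probe, n_points)
    polar_mask = np.array([e in polar_elements for e in elements])
    polar = float(areas[polar_mask].sum())
    total = float(areas.sum())
    return SasaResult(areas, total, polar, total - polar, probe, n_points)


def buried_surface(A, B, AB, probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_N_POINTS, **kwargs) -> float:
    """Interface burial: SASA(A) + SASA(B) - SASA(AB), Angstrom^2.

    Non-negative up to point-sampling noise; zero for non-interacting
    subunits.
    """
    from ._pdb import atom_count
    if atom_count(AB) != atom_count(A) + atom_count(B):
        raise ValueError("dimer atom count does not match the sum of subunits")
    sa = atom_sasa(A, probe, n_points, **kwargs).total
    sb = atom_sasa(B, probe, n_points, **kwargs).total
    sab = atom_sasa(AB, probe, n_points, **kwargs).total
    return sa + sb - sab


def isolated_sphere_area(radius: float, probe: float = DEFAULT_PROBE) -> float:
    """Closed form 4 pi (r + probe)^2 for an isolated atom."""
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_areas(r1: float, r2: float, d: float,
                     probe: float = DEFAULT_PROBE) -> tuple[float, float]:
    """Analytic accessible areas of two overlapping expanded spheres.

    The area of each expanded sphere lost to the other is a spherical cap;
    used as the independent closed-form check on the point-sampled estimate.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * R1 ** 2, 4 * math.pi * R2 ** 2
    if d <= abs(R1 - R2):
        # one sphere inside the other
        big = 4 * math.pi * max(R1, R2) ** 2
        return (big, 0.0) if R1 >= R2 else (0.0, big)
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return (4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * h1,
            4 * math.pi * R2 ** 2 - 2 * math.pi * R2 * h2)
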