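"""Promolecule Hirshfeld surfaces, (d_i, d_e) fingerprint plots, and
close-contact percentage breakdowns.

The Hirshfeld surface of a molecule in a crystal is the isosurface
where the weight function

    w(r) = rho_molecule(r) / (rho_molecule(r) + rho_environment(r))

equals 0.5, with both densities built from spherically averaged
free-atom (promolecule) densities.  Every surface point carries d_i
(distance to the nearest atom of the molecule inside) and d_e (nearest
atom outside); the area-weighted 2D histogram of (d_i, d_e) is the
fingerprint plot, and grouping area by the (inside element, outside
element) pair gives the contact percentages.

Atomic densities are single-zeta Slater shells with Slater-rule
exponents — a deliberately simple promolecule model; only density
*ratios* enter w, so the absolute normalization is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import marching_cubes

from .crystal_core import CrystalStructure, ExpandedCrystal

__all__ = [
    "HirshfeldSurface", "Fingerprint", "promolecule_weight",
    "atomic_density", "hirshfeld_surface", "contact_percentages",
    "fingerprint", "UndefinedRegionError",
]

BOHR_PER_ANGSTROM = 1.8897259886

# Slater shells per element: (principal n, occupancy, zeta in bohr^-1)
_SLATER_SHELLS = {
    "H": [(1, 1.0, 1.00)],
    "C": [(1, 2.0, 5.70), (2, 4.0, 1.625)],
    "N": [(1, 2.0, 6.70), (2, 5.0, 1.95)],
    "O": [(1, 2.0, 7.70), (2, 6.0, 2.275)],
    "F": [(1, 2.0, 8.70), (2, 7.0, 2.60)],
    "S": [(1, 2.0, 15.70), (2, 8.0, 5.3125), (3, 6.0, 1.8167)],
    "Cl": [(1, 2.0, 16.70), (2, 8.0, 5.6625), (3, 7.0, 2.0333)],
}


class UndefinedRegionError(ValueError):
    """Point too far from every atom: promolecule weight undefined."""


def atomic_density(element: str, r_angstrom) -> np.ndarray:
    """Spherically averaged free-atom density (electrons / bohr^3) at
    distance r (angstrom) from the nucleus."""
    shells = _SLATER_SHELLS[element]
    r = np.asarray(r_angstrom, dtype=float) * BOHR_PER_ANGSTROM
    rho = np.zeros_like(r)
    for n, occ, zeta in shells:
        norm2 = (2 * zeta) ** (2 * n + 1) / math.factorial(2 * n)
        rr = np.maximum(r, 1e-12)
        radial2 = norm2 * rr ** (2 * n - 2) * np.exp(-2 * zeta * rr)
        rho += occ * radial2 / (4 * math.pi)
    return rho


def _density_sum(points, atoms):
    """Summed promolecule density at points; atoms = (elements, coords)."""
    elements, coords = atoms
    points = np.asarray(points, dtype=float)
    rho = np.zeros(len(points))
    el_arr = np.asarray(elements)
    chunk = max(1, int(5e6 // max(len(coords), 1)))
    for e in np.unique(el_arr):
        sub = coords[el_arr == e]
        for s0 in range(0, len(points), chunk):
            p = points[s0:s0 + chunk]
            d = np.linalg.norm(p[:, None, :] - sub[None, :, :], axis=2)
            rho[s0:s0 + chunk] += atomic_density(e, d).sum(axis=1)
    return rho


def promolecule_weight(point, inside_atoms, outside_atoms,
                       threshold: float = 1e-12) -> float:
    """Hirshfeld weight w = rho_in / (rho_in + rho_out) at one point.

    ``inside_atoms`` / ``outside_atoms`` are ``(elements, coords)``
    pairs.  Raises :class:`UndefinedRegionError` when the total density
    is below ``threshold`` (point too far from all atoms).
    """
    p = np.asarray(point, dtype=float).reshape(1, 3)
    rin = float(_density_sum(p, inside_atoms)[0])
    rout = float(_density_sum(p, outside_atoms)[0])
    total = rin + rout
    if total < threshold:
        raise UndefinedRegionError(
            f"total promolecule density {total:.2e} below threshold")
    return rin / total


@dataclass
class HirshfeldSurface:
    """Triangulated w = 0.5 isosurface around one molecule."""

    points: np.ndarray       # (T, 3) triangle centroids, A
    areas: np.ndarray        # (T,) triangle areas, A^2
    d_i: np.ndarray          # distance to nearest inside atom
    d_e: np.ndarray          # distance to nearest outside atom
    inside_element: np.ndarray
    outside_element: np.ndarray

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def _environment(ex: ExpandedCrystal, mol_index: int, radius: float):
    """All molecule copies (periodic images included) with an atom
    within ``radius`` of the central molecule's bounding box."""
    central = ex.mol_coords[mol_index]
    lo = central.min(axis=0) - radius
    hi = central.max(axis=0) + radius
    A = ex.cell.matrix
    widths = 1.0 / np.linalg.norm(np.linalg.inv(A), axis=1)
    span = float(np.linalg.norm(ex.molecule.centered_coords(),
                                axis=1).max())
    nmax = np.ceil((radius + 2 * span + np.linalg.norm(hi - lo) / 2)
                   / widths).astype(int)
    out = []
    for i in range(-nmax[0], nmax[0] + 1):
        for j in range(-nmax[1], nmax[1] + 1):
            for k in range(-nmax[2], nmax[2] + 1):
                shift = A @ np.array([i, j, k], dtype=float)
                for m, block in enumerate(ex.mol_coords):
                    if (i, j, k) == (0, 0, 0) and m == mol_index:
                        continue
                    b = block + shift
                    if np.all(b.max(axis=0) >= lo) and \
                            np.all(b.min(axis=0) <= hi):
                        out.append(b)
    return out


def hirshfeld_surface(structure, molecule_index: int = 0,
                      grid_spacing: float = 0.3,
                      environment_radius: float = 8.0,
                      margin: float = 3.0) -> HirshfeldSurface:
    """Hirshfeld surface of one molecule by marching cubes on the
    promolecule weight function.

    ``environment_radius`` truncates the outside promolecule beyond the
    molecule's bounding box; 8 A keeps every atom with a non-negligible
    density contribution.
    """
    ex = structure.expand(check_overlap=False) \
        if isinstance(structure, CrystalStructure) else structure
    if not 0 <= molecule_index < ex.n_molecules:
        raise IndexError(f"molecule index {molecule_index} out of range")
    central = ex.mol_coords[molecule_index]
    elements = list(ex.molecule.elements)
    env_blocks = _environment(ex, molecule_index, environment_radius)
    if not env_blocks:
        raise ValueError("no environment molecules within radius")
    env_coords = np.concatenate(env_blocks, axis=0)
    env_elements = np.array(elements * len(env_blocks))

    lo = central.min(axis=0) - margin
    hi = central.max(axis=0) + margin
    h = grid_spacing
    axes = [np.arange(lo[d], hi[d] + h, h) for d in range(3)]
    shape = tuple(len(ax) for ax in axes)
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    rho_in = _density_sum(G, (elements, central))
    rho_out = _density_sum(G, (env_elements, env_coords))
    w = (rho_in / np.maximum(rho_in + rho_out, 1e-300)).reshape(shape)

    verts, faces, _, _ = marching_cubes(w, level=0.5,
                                        spacing=(h, h, h))
    verts = verts + lo
    tri = verts[faces]
    cents = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    keep = areas > 0
    cents, areas = cents[keep], areas[keep]

    din = np.linalg.norm(cents[:, None, :] - central[None, :, :], axis=2)
    i_in = np.argmin(din, axis=1)
    d_i = din[np.arange(len(cents)), i_in]
    dout = np.linalg.norm(cents[:, None, :] - env_coords[None, :, :],
                          axis=2)
    i_out = np.argmin(dout, axis=1)
    d_e = dout[np.arange(len(cents)), i_out]
    el_in = np.array(elements)[i_in]
    el_out = env_elements[i_out]
    return HirshfeldSurface(points=cents, areas=areas, d_i=d_i, d_e=d_e,
                            inside_element=el_in, outside_element=el_out)


def contact_percentages(surface: HirshfeldSurface) -> dict:
    """Percentage of surface area per symmetrized element pair
    (C...H and H...C pooled); percentages sum to 100."""
    if len(surface.areas) == 0:
        raise ValueError("empty surface")
    total = surface.total_area
    out: dict = {}
    for ei, eo, a in zip(surface.inside_element, surface.outside_element,
                         surface.areas):
        key = "...".join(sorted((ei, eo)))
        out[key] = out.get(key, 0.0) + a
    return {k: 100.0 * v / total for k, v in
            sorted(out.items(), key=lambda kv: -kv[1])}


@dataclass
class Fingerprint:
    """Area-weighted 2D histogram over (d_i, d_e)."""

    d_grid: np.ndarray       # bin edges, A
    hist: np.ndarray         # (n, n) area per bin, A^2

    @property
    def total_area(self) -> float:
        return float(self.hist.sum())


def fingerprint(surface: HirshfeldSurface, bin_width: float = 0.01,
                d_max: float = 3.0) -> Fingerprint:
    """Fingerprint plot histogram: bin 0.01 A, area-weighted."""
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    hist, _, _ = np.histogram2d(
        np.clip(surface.d_i, 0, d_max - 1e-9),
        np.clip(surface.d_e, 0, d_max - 1e-9),
        bins=(edges, edges), weights=surface.areas)
    return Fingerprint(d_grid=edges, hist=hist)


def render_fingerprint(fp: Fingerprint, path, title: str = "") -> None:
    """Save a fingerprint plot image (standard log-like color scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    masked = np.ma.masked_where(fp.hist.T == 0, fp.hist.T)
    ax.pcolormesh(fp.d_grid, fp.d_grid, masked, cmap="jet",
                  shading="auto")
    ax.set_xlabel(r"$d_i$ ($\AA$)")
    ax.set_ylabel(r"$d_e$ ($\AA$)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
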