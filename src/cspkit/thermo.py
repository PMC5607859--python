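"""Polymorph stability thermodynamics.

Three layers:

* :func:`melting_point_dG` — the melting-point depression estimate of a
  metastable form's free-energy penalty,
  ``dG = (Tm(ref) - Tm) * dH_fus / Tm(ref)`` with temperatures in kelvin.
* :func:`hessian` / :func:`mode_frequencies` — rigid-body (librational +
  translational) harmonic modes of a supercell from central finite
  differences of the analytic force-field gradient, mass/inertia
  weighted.  The force field is intermolecular-only, so intramolecular
  modes are undefined by construction and the rigid-body treatment is
  the consistent harmonic model.
* :func:`harmonic_free_energy` / :func:`rank_polymorphs` — vibrational
  free energies (quantum or classical oscillators) on a temperature
  grid, G(T) = E_lattice + F_vib(T), with pairwise stability crossover
  detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .crystal_core import CrystalStructure, ExpandedCrystal, UnitCell
from .energy import ForceField, cell_energy_and_atom_gradient, lattice_energy

__all__ = [
    "KELVIN_OFFSET", "MeltingData", "FreeEnergyCurve", "NotAtMinimumError",
    "melting_point_dG", "hessian", "mode_frequencies",
    "harmonic_free_energy", "free_energy_curve", "rank_polymorphs",
    "PolymorphEntry",
]

KELVIN_OFFSET = 273.15
K_B = 0.008314462618  # kJ/(mol K)
H_PLANCK_KJMOL_THZ = 0.399031002270895  # h * 1 THz * N_A in kJ/mol


class NotAtMinimumError(RuntimeError):
    """Hessian requested away from a force-field minimum."""


class ImaginaryModeError(ValueError):
    """Negative eigenvalues beyond the acoustic modes."""


# --------------------------------------------------------------------------
# melting-point relation

@dataclass(frozen=True)
class MeltingData:
    """Melting points (deg C) of the polymorph family, the reference
    (most stable) form's melting point, and its heat of fusion."""

    t_m: dict              # polymorph label -> Tm in deg C (None = n/d)
    t_m_ref: float         # Tm of the reference form, deg C
    dh_fus: float          # kJ/mol

    def __post_init__(self):
        if self.dh_fus <= 0:
            raise ValueError("heat of fusion must be positive")
        if self.t_m_ref + KELVIN_OFFSET <= 0:
            raise ValueError("reference melting point below 0 K")


def melting_point_dG(data: MeltingData, warn=None) -> dict:
    """Free-energy penalty of each form relative to the reference at the
    reference melting point:

        dG = (Tm(ref) - Tm) * dH / Tm(ref),   temperatures in kelvin.

    Forms without a measured melting point are skipped (with a warning
    callback if given); a form melting above the reference triggers the
    warning too but is still computed (dG < 0).
    """
    t_ref = data.t_m_ref + KELVIN_OFFSET
    out = {}
    for label, tm in data.t_m.items():
        if tm is None:
            if warn:
                warn(f"{label}: no melting point; skipped")
            continue
        t = tm + KELVIN_OFFSET
        if t > t_ref and warn:
            warn(f"{label}: melts above the reference form")
        out[label] = (t_ref - t) * data.dh_fus / t_ref
    return out


# --------------------------------------------------------------------------
# rigid-body Hessian

def _supercell_blocks(ex: ExpandedCrystal, min_length: float):
    """Replicate the expanded cell so every perpendicular width is at
    least ``min_length`` angstrom; returns (supercell, blocks)."""
    A = ex.cell.matrix
    widths = 1.0 / np.linalg.norm(np.linalg.inv(A), axis=1)
    reps = np.maximum(np.ceil(min_length / widths).astype(int), 1)
    sc = UnitCell(ex.cell.a * reps[0], ex.cell.b * reps[1],
                  ex.cell.c * reps[2], ex.cell.alpha, ex.cell.beta,
                  ex.cell.gamma)
    blocks = []
    for i in range(reps[0]):
        for j in range(reps[1]):
            for k in range(reps[2]):
                shift = A @ np.array([i, j, k], dtype=float)
                for c in ex.mol_coords:
                    blocks.append(c + shift)
    return sc, blocks


def _dof_basis(block, masses):
    """Rotational principal axes with non-negligible inertia for one
    rigid molecule; returns (centroid, offsets, axes (3, k), moments)."""
    centroid = block.mean(axis=0)
    v = block - centroid
    inertia = np.zeros((3, 3))
    for m, vi in zip(masses, v):
        inertia += m * (np.dot(vi, vi) * np.eye(3) - np.outer(vi, vi))
    moments, axes = np.linalg.eigh(inertia)
    keep = moments > 1e-8 * max(moments.max(), 1.0)
    return centroid, v, axes[:, keep], moments[keep]


def _dof_gradient(atom_grad, blocks, dofs, n_at):
    """Project per-atom gradients onto the rigid-body DOFs."""
    out = []
    for m, (centroid, v, axes, moments) in enumerate(dofs):
        g = atom_grad[m * n_at:(m + 1) * n_at]
        gt = g.sum(axis=0)
        torque = np.cross(v, g).sum(axis=0)
        out.append(np.concatenate([gt, axes.T @ torque]))
    return np.concatenate(out)


def _rotate_about(block, centroid, axis, angle):
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K
    return centroid + (R @ (block - centroid).T).T


def hessian(structure, ff: ForceField, displacement: float = 1e-3,
            min_supercell: float = 10.0, force_tol: float = 5e-3):
    """Symmetrized rigid-body Hessian of a supercell at the Gamma point.

    Central finite differences of the analytic gradient over each
    molecule's translational and (non-degenerate) rotational DOFs;
    ``displacement`` is used in angstrom for translations and radians
    for rotations.  Returns ``(H, M, meta)`` where M is the diagonal
    mass/inertia matrix (amu, amu A^2) matching H's DOF ordering.
    Raises :class:`NotAtMinimumError` unless the residual DOF gradient
    is below ``force_tol`` (kJ/mol per A or rad).
    """
    ex = structure.expand(check_overlap=False) \
        if isinstance(structure, CrystalStructure) else structure
    sc, blocks = _supercell_blocks(ex, min_supercell)
    mol = ex.molecule
    masses = mol.masses
    n_at = mol.n_atoms
    dofs = [_dof_basis(b, masses) for b in blocks]
    sizes = [3 + d[2].shape[1] for d in dofs]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_dof = offsets[-1]

    def grad_of(blks):
        _, g = cell_energy_and_atom_gradient(sc, blks, mol, ff)
        return _dof_gradient(g, blks, dofs, n_at)

    g0 = grad_of(blocks)
    if np.abs(g0).max() > force_tol:
        raise NotAtMinimumError(
            f"max residual generalized force {np.abs(g0).max():.3e} "
            f"kJ/mol exceeds {force_tol}; optimize the structure first")

    H = np.zeros((n_dof, n_dof))
    for m, (centroid, v, axes, moments) in enumerate(dofs):
        base = offsets[m]
        for k in range(sizes[m]):
            plus = [b.copy() for b in blocks]
            minus = [b.copy() for b in blocks]
            if k < 3:
                e = np.zeros(3)
                e[k] = displacement
                plus[m] = blocks[m] + e
                minus[m] = blocks[m] - e
            else:
                axis = axes[:, k - 3]
                plus[m] = _rotate_about(blocks[m], centroid, axis,
                                        displacement)
                minus[m] = _rotate_about(blocks[m], centroid, axis,
                                         -displacement)
            H[base + k] = (grad_of(plus) - grad_of(minus)) \
                / (2 * displacement)
    H = 0.5 * (H + H.T)
    Mdiag = np.concatenate([
        np.concatenate([np.full(3, masses.sum()), moments])
        for (_, _, axes, moments) in dofs])
    meta = {"n_molecules": len(blocks), "supercell": sc,
            "dof_sizes": sizes}
    return H, np.diag(Mdiag), meta


#: sqrt(1 kJ/mol / (amu A^2)) expressed in THz (nu = omega / 2 pi)
_FREQ_THZ = 1e13 / (2 * math.pi) / 1e12


def mode_frequencies(structure, ff: ForceField, min_supercell: float = 10.0,
                     displacement: float = 1e-3, force_tol: float = 5e-3,
                     zero_tol_thz: float = 0.05):
    """Harmonic mode frequencies (THz) of the supercell Gamma point.

    The three acoustic translations are identified as the smallest-
    magnitude eigenvalues and removed.  Returns ``(freqs_thz,
    n_imaginary, meta)`` where ``n_imaginary`` counts negative
    eigenvalues beyond the acoustic set.
    """
    H, M, meta = hessian(structure, ff, displacement=displacement,
                         min_supercell=min_supercell, force_tol=force_tol)
    evals = scipy.linalg.eigh(H, M, eigvals_only=True)
    order = np.argsort(np.abs(evals))
    evals = np.delete(evals, order[:3])  # acoustic Gamma modes
    nu = np.sign(evals) * np.sqrt(np.abs(evals)) * _FREQ_THZ
    n_imag = int(np.sum(nu < -zero_tol_thz))
    freqs = nu[nu > zero_tol_thz]
    meta = dict(meta)
    meta["all_modes_thz"] = nu
    return np.sort(freqs), n_imag, meta


# --------------------------------------------------------------------------
# harmonic free energies

def harmonic_free_energy(frequencies_thz, temperature: float,
                         kind: str = "quantum",
                         n_molecules: int = 1) -> float:
    """Vibrational free energy (kJ/mol per molecule) of independent
    harmonic oscillators.

    quantum:   F = sum_i [ h nu/2 + kB T ln(1 - exp(-h nu / kB T)) ]
    classical: F = sum_i kB T ln(h nu / kB T)
    """
    nu = np.asarray(frequencies_thz, dtype=float)
    if np.any(nu < 0):
        bad = nu[nu < 0]
        raise ImaginaryModeError(
            f"negative frequencies present: {bad.tolist()}")
    nu = nu[nu > 0]
    hnu = H_PLANCK_KJMOL_THZ * nu
    if kind == "quantum":
        f = float(np.sum(hnu / 2))
        if temperature > 0:
            kt = K_B * temperature
            f += float(kt * np.sum(np.log1p(-np.exp(-hnu / kt))))
    elif kind == "classical":
        if temperature <= 0:
            raise ValueError("classical free energy undefined at T <= 0")
        kt = K_B * temperature
        f = float(kt * np.sum(np.log(hnu / kt)))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return f / n_molecules


@dataclass
class FreeEnergyCurve:
    """Per-structure vibrational thermodynamics on a temperature grid."""

    label: str
    e_lattice: float          # kJ/mol per molecule
    frequencies_thz: np.ndarray
    temperatures: np.ndarray
    f_vib: np.ndarray         # kJ/mol per molecule

    @property
    def zero_point_energy(self) -> float:
        return harmonic_free_energy(self.frequencies_thz, 0.0,
                                    kind="quantum")

    def g(self) -> np.ndarray:
        return self.e_lattice + self.f_vib


@dataclass(frozen=True)
class PolymorphEntry:
    """Input to :func:`rank_polymorphs` when modes are precomputed."""

    label: str
    e_lattice: float
    frequencies_thz: np.ndarray
    n_molecules: int = 1


def free_energy_curve(structure: CrystalStructure, ff: ForceField,
                      temperatures, label: str = "",
                      kind: str = "quantum",
                      min_supercell: float = 10.0) -> FreeEnergyCurve:
    """Compute E_lattice and F_vib(T) for one optimized structure."""
    freqs, n_imag, meta = mode_frequencies(structure, ff,
                                           min_supercell=min_supercell)
    if n_imag:
        raise ImaginaryModeError(
            f"{label or 'structure'} has {n_imag} imaginary modes")
    n_mol = meta["n_molecules"]
    temps = np.asarray(temperatures, dtype=float)
    f = np.array([harmonic_free_energy(freqs, t, kind=kind,
                                       n_molecules=n_mol) for t in temps])
    e = lattice_energy(structure, ff).e_total
    return FreeEnergyCurve(label=label, e_lattice=e,
                           frequencies_thz=freqs, temperatures=temps,
                           f_vib=f)


def rank_polymorphs(entries, temperatures, ff: ForceField = None,
                    kind: str = "quantum"):
    """Temperature-dependent stability ranking G(T) = E_latt + F_vib(T).

    ``entries`` are :class:`PolymorphEntry` (precomputed modes) or
    ``(label, CrystalStructure)`` pairs (modes computed with ``ff``).
    Structures with imaginary modes are excluded with a flag.

    Returns a dict with per-T orderings, the G curves, pairwise
    crossover temperatures (linear interpolation between grid points),
    and the excluded labels.
    """
    temps = np.asarray(temperatures, dtype=float)
    curves = []
    excluded = []
    for entry in entries:
        if isinstance(entry, PolymorphEntry):
            try:
                f = np.array([harmonic_free_energy(
                    entry.frequencies_thz, t, kind=kind,
                    n_molecules=entry.n_molecules) for t in temps])
            except ImaginaryModeError:
                excluded.append(entry.label)
                continue
            curves.append(FreeEnergyCurve(
                label=entry.label, e_lattice=entry.e_lattice,
                frequencies_thz=np.asarray(entry.frequencies_thz),
                temperatures=temps, f_vib=f))
        else:
            label, structure = entry
            try:
                curves.append(free_energy_curve(structure, ff, temps,
                                                label=label, kind=kind))
            except ImaginaryModeError:
                excluded.append(label)
    G = np.array([c.g() for c in curves])
    order = [tuple(np.array([c.label for c in curves])[np.argsort(G[:, i])])
             for i in range(len(temps))]
    crossovers = {}
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            diff = G[i] - G[j]
            for k in range(len(temps) - 1):
                if diff[k] == 0:
                    continue
                if diff[k] * diff[k + 1] < 0:
                    t = temps[k] + (temps[k + 1] - temps[k]) \
                        * abs(diff[k]) / (abs(diff[k]) + abs(diff[k + 1]))
                    crossovers.setdefault(
                        (curves[i].label, curves[j].label), []).append(t)
    return {"curves": curves, "temperatures": temps, "ordering": order,
            "crossovers": crossovers, "excluded": excluded}
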