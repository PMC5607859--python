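"""Classical intermolecular lattice energy and rigid-body optimization.

The model is a 12-6 Lennard-Jones potential plus point-charge Coulomb
electrostatics evaluated by Ewald summation.  Only intermolecular pairs
contribute: the molecules are rigid, so all intramolecular terms are
constants and are excluded from the sums (the Ewald reciprocal part is
corrected accordingly).

Units: angstrom, kJ/mol, electron charges.  The Coulomb prefactor
e^2/(4 pi eps0) is 1389.35457644382 kJ A / (mol e^2).

Gradients with respect to the rigid-body degrees of freedom (fractional
centroid + orientation) are analytic, assembled from per-atom Cartesian
gradients through the Cartesian images of the space-group operations.
Cell-parameter gradients use central finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import erfc

from .crystal_core import (
    CrystalStructure, ExpandedCrystal, UnitCell, Placement,
    quat_canonical, quat_multiply, quat_to_matrix, rotvec_to_quat,
)

__all__ = [
    "COULOMB_KJ", "ForceField", "EnergyBreakdown", "MissingParameterError",
    "NonNeutralCellError", "ewald_coulomb", "lj_energy", "lattice_energy",
    "optimize", "OptimizationResult", "cell_free_parameters",
    "placement_gradient",
]

COULOMB_KJ = 1389.35457644382  # kJ A mol^-1 e^-2


class MissingParameterError(KeyError):
    """A vdW class has no force-field parameters."""


class NonNeutralCellError(ValueError):
    """Ewald summation requires a charge-neutral cell."""


@dataclass(frozen=True)
class ForceField:
    """Lennard-Jones + point-charge force field.

    Parameters
    ----------
    classes : dict
        ``{vdw_class: (epsilon kJ/mol, sigma A)}``.  Combining rule is the
        geometric mean for both epsilon and sigma (OPLS convention).
    cutoff : float
        Real-space cutoff in angstrom for both LJ and the Ewald
        real-space sum (default 12 A).
    alpha : float
        Ewald damping parameter in A^-1 (default 0.3 A^-1 = 3 nm^-1).
    recip_cutoff : float or None
        Reciprocal-space cutoff in A^-1.  ``None`` auto-tunes it from
        ``accuracy`` (recommended); a literal value (e.g. 0.2 A^-1) is
        honoured if given.
    accuracy : float
        Target truncation error of the reciprocal sum, kJ/mol per cell.
    tail_correction : bool
        Add the analytic isotropic LJ tail beyond the cutoff.
    """

    classes: dict
    cutoff: float = 12.0
    alpha: float = 0.3
    recip_cutoff: float | None = None
    accuracy: float = 1e-5
    tail_correction: bool = False

    def __post_init__(self):
        for cls, (eps, sig) in self.classes.items():
            if eps < 0 or sig <= 0:
                raise ValueError(f"bad LJ parameters for class {cls!r}")

    def lookup(self, vdw_classes):
        eps, sig = [], []
        for c in vdw_classes:
            if c not in self.classes:
                raise MissingParameterError(
                    f"no LJ parameters for vdW class {c!r}")
            e, s = self.classes[c]
            eps.append(e)
            sig.append(s)
        return np.array(eps), np.array(sig)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Lattice-energy components in kJ/mol per molecule."""

    e_lj: float
    e_coul_real: float
    e_coul_recip: float
    e_coul_self: float
    e_total: float

    @classmethod
    def per_molecule(cls, lj, real, recip, self_corr, n_mol):
        return cls(lj / n_mol, real / n_mol, recip / n_mol,
                   self_corr / n_mol,
                   (lj + real + recip + self_corr) / n_mol)


# --------------------------------------------------------------------------
# internal flat system representation

class _System:
    """Flat per-atom arrays for one unit cell plus the lattice geometry."""

    def __init__(self, cell: UnitCell, coords, q, eps, sig, mol_id,
                 span: float):
        self.cell = cell
        self.A = cell.matrix
        self.volume = float(abs(np.linalg.det(self.A)))
        self.coords = np.asarray(coords, dtype=float)
        self.q = np.asarray(q, dtype=float)
        self.eps = np.asarray(eps, dtype=float)
        self.sig = np.asarray(sig, dtype=float)
        self.mol_id = np.asarray(mol_id)
        self.span = span  # max atom-centroid distance, for image margin
        self.n_mol = int(self.mol_id.max()) + 1 if len(self.mol_id) else 0

    @classmethod
    def from_expanded(cls, ex: ExpandedCrystal, ff: ForceField):
        eps, sig = ff.lookup(ex.molecule.vdw_classes)
        local = ex.molecule.centered_coords()
        span = float(np.linalg.norm(local, axis=1).max()) if len(local) else 0.0
        k = len(ex.mol_coords)
        n = ex.molecule.n_atoms
        return cls(ex.cell, np.concatenate(ex.mol_coords, axis=0),
                   np.tile(ex.molecule.charges, k), np.tile(eps, k),
                   np.tile(sig, k), np.repeat(np.arange(k), n), span)

    def shifts(self, cutoff: float) -> np.ndarray:
        """Integer lattice shift vectors (half-space, excluding 0) whose
        images can host pairs within the cutoff."""
        margin = cutoff + 2 * self.span + 1e-9
        Ainv = np.linalg.inv(self.A)
        widths = 1.0 / np.linalg.norm(Ainv, axis=1)  # perpendicular widths
        nmax = np.ceil(margin / widths).astype(int)
        grids = np.meshgrid(*(np.arange(-n, n + 1) for n in nmax),
                            indexing="ij")
        n = np.stack([g.ravel() for g in grids], axis=1)
        # lexicographic half-space, excluding the zero shift
        keep = ((n[:, 0] > 0)
                | ((n[:, 0] == 0) & (n[:, 1] > 0))
                | ((n[:, 0] == 0) & (n[:, 1] == 0) & (n[:, 2] > 0)))
        return n[keep].astype(float) @ self.A.T


def _expand(structure) -> ExpandedCrystal:
    if isinstance(structure, CrystalStructure):
        return structure.expand(check_overlap=False)
    if isinstance(structure, ExpandedCrystal):
        return structure
    raise TypeError("expected CrystalStructure or ExpandedCrystal")


# --------------------------------------------------------------------------
# pairwise real-space sums (LJ + screened Coulomb), with gradients

def _real_space(sys: _System, ff: ForceField, do_coulomb: bool,
                do_lj: bool, want_grad: bool):
    """Real-space lattice sums within the cutoff.

    Returns (e_lj, e_coul_real, grad (M,3) or None).  Intramolecular
    pairs (same molecule copy, zero shift) are excluded.
    """
    X = sys.coords
    M = len(X)
    rc = ff.cutoff
    a = ff.alpha
    e_lj = 0.0
    e_cr = 0.0
    grad = np.zeros((M, 3)) if want_grad else None

    eps_ij_cache = {}

    def pair_terms(d, idx_i, idx_j):
        """d: (P,3) displacement x_i - x_j; returns energies and adds
        gradient contributions."""
        nonlocal e_lj, e_cr
        r2 = np.einsum("ij,ij->i", d, d)
        mask = r2 < rc * rc
        if not mask.any():
            return
        d = d[mask]
        r2 = r2[mask]
        i = idx_i[mask]
        j = idx_j[mask]
        r = np.sqrt(r2)
        coef = np.zeros_like(r)  # (1/r) dE/dr
        if do_lj:
            eps = np.sqrt(sys.eps[i] * sys.eps[j])
            sig = np.sqrt(sys.sig[i] * sys.sig[j])
            s6 = (sig * sig / r2) ** 3
            s12 = s6 * s6
            # energy-shifted truncation: the pair energy vanishes at the
            # cutoff, keeping the lattice energy continuous as pairs
            # cross it (essential for line searches)
            s6c = (sig * sig / (rc * rc)) ** 3
            shift = 4 * eps * (s6c * s6c - s6c)
            e_lj += float(np.sum(4 * eps * (s12 - s6) - shift))
            if want_grad:
                coef += 4 * eps * (-12 * s12 + 6 * s6) / r2
        if do_coulomb:
            qq = COULOMB_KJ * sys.q[i] * sys.q[j]
            er = erfc(a * r)
            shift_c = erfc(a * rc) / rc
            e_cr += float(np.sum(qq * (er / r - shift_c)))
            if want_grad:
                coef += qq * (-er / r - 2 * a / math.sqrt(math.pi)
                              * np.exp(-a * a * r2)) / r2
        if want_grad:
            g = coef[:, None] * d
            np.add.at(grad, i, g)
            np.add.at(grad, j, -g)

    # zero-shift: unordered in-cell pairs, skip intramolecular
    iu, ju = np.triu_indices(M, k=1)
    keep = sys.mol_id[iu] != sys.mol_id[ju]
    pair_terms(X[iu[keep]] - X[ju[keep]], iu[keep], ju[keep])

    # nonzero shifts (half-space): every ordered (i, j) pair counted once;
    # chunked over shifts to bound memory
    shifts = sys.shifts(rc)
    ii, jj = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    base = X[ii] - X[jj]  # (M*M, 3)
    chunk = max(1, int(4e6 // max(len(base), 1)))
    for s0 in range(0, len(shifts), chunk):
        sblk = shifts[s0:s0 + chunk]
        d = (base[None, :, :] - sblk[:, None, :]).reshape(-1, 3)
        k = len(sblk)
        pair_terms(d, np.tile(ii, k), np.tile(jj, k))
    return e_lj, e_cr, grad


def _recip_space(sys: _System, ff: ForceField, want_grad: bool):
    """Ewald reciprocal-space sum and the self + intramolecular
    corrections.  Returns (e_recip, e_self_plus_intra, grad or None)."""
    a = ff.alpha
    V = sys.volume
    q = sys.q
    X = sys.coords
    if ff.recip_cutoff is not None:
        kcut = ff.recip_cutoff
    else:
        # continuum estimate of the neglected tail:
        #   err ~ KE sum(q^2) alpha/sqrt(pi) * erfc(kcut / 2 alpha)
        # (V-independent); choose kcut for err < accuracy
        qsum2 = float(np.sum(q * q))
        scale = max(COULOMB_KJ * qsum2 * a / math.sqrt(math.pi), 1e-12)
        arg = max(scale / ff.accuracy, math.e)
        kcut = 2 * a * math.sqrt(math.log(arg))
    # integer ranges: |m_i| <= kcut * |a_i| / (2 pi)
    lengths = np.linalg.norm(sys.A, axis=0)
    mmax = np.ceil(kcut * lengths / (2 * math.pi)).astype(int)
    Binv = 2 * math.pi * np.linalg.inv(sys.A).T  # reciprocal basis columns
    grids = np.meshgrid(*(np.arange(-n, n + 1) for n in mmax),
                        indexing="ij")
    mvec = np.stack([g.ravel() for g in grids], axis=1)
    half = ((mvec[:, 0] > 0)
            | ((mvec[:, 0] == 0) & (mvec[:, 1] > 0))
            | ((mvec[:, 0] == 0) & (mvec[:, 1] == 0) & (mvec[:, 2] > 0)))
    ms = mvec[half]
    e_recip = 0.0
    grad = np.zeros_like(X) if want_grad else None
    if len(ms):
        K = ms.astype(float) @ Binv.T  # (Nk, 3)
        k2 = np.einsum("ij,ij->i", K, K)
        sel = k2 <= kcut * kcut
        K = K[sel]
        k2 = k2[sel]
        if len(K):
            pref = np.exp(-k2 / (4 * a * a)) / k2
            phase = X @ K.T  # (M, Nk)
            ei = np.exp(1j * phase)
            S = q @ ei  # (Nk,)
            # factor 2: half-space enumeration (k and -k)
            e_recip = float((2 * math.pi * COULOMB_KJ / V)
                            * 2 * np.sum(pref * np.abs(S) ** 2))
            if want_grad:
                # dE/dx_j = -(2 pi KE / V) * 2 * sum_k pref * 2 q_j
                #           Im(conj(S) e^{ik x_j}) k
                im = np.imag(np.conj(S)[None, :] * ei)  # (M, Nk)
                coef = (2 * math.pi * COULOMB_KJ / V) * 2 * 2
                grad += -coef * (q[:, None] * im * pref[None, :]) @ K
    # self term
    e_self = -COULOMB_KJ * a / math.sqrt(math.pi) * float(np.sum(q * q))
    # intramolecular correction: remove the erf-screened interaction of
    # excluded (rigid intramolecular) pairs.  Constant for rigid bodies.
    e_intra = 0.0
    from scipy.special import erf
    for m in range(sys.n_mol):
        idx = np.where(sys.mol_id == m)[0]
        if len(idx) < 2:
            continue
        xi = X[idx]
        iu, ju = np.triu_indices(len(idx), k=1)
        d = xi[iu] - xi[ju]
        r = np.linalg.norm(d, axis=1)
        qq = COULOMB_KJ * q[idx][iu] * q[idx][ju]
        e_intra += float(np.sum(-qq * erf(a * r) / r))
    return e_recip, e_self + e_intra, grad


def _check_neutral(sys: _System):
    total = float(np.sum(sys.q))
    if abs(total) > 1e-6:
        raise NonNeutralCellError(
            f"cell carries net charge {total:.2e} e; Ewald summation "
            "requires neutrality")


def ewald_point_charges(cell: UnitCell, positions, charges,
                        cutoff: float = 12.0, alpha: float = 0.3,
                        accuracy: float = 1e-6):
    """Ewald Coulomb energy (kJ/mol per cell) of bare point charges with
    no exclusions (every charge its own body).  For ionic reference
    lattices and cross-checks."""
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    ff = ForceField(classes={}, cutoff=cutoff, alpha=alpha,
                    accuracy=accuracy)
    m = len(positions)
    sys = _System(cell, positions, charges, np.zeros(m), np.ones(m),
                  np.arange(m), span=0.0)
    _check_neutral(sys)
    _, e_real, _ = _real_space(sys, ff, do_coulomb=True, do_lj=False,
                               want_grad=False)
    e_recip, e_selfcorr, _ = _recip_space(sys, ff, want_grad=False)
    return e_real + e_recip + e_selfcorr


def ewald_coulomb(structure, ff: ForceField):
    """Total Coulomb energy of one unit cell in kJ/mol by Ewald
    summation.  Returns ``(e_total, components)`` with components
    ``{'real', 'recip', 'self'}`` (self includes the rigid-intramolecular
    correction).  Independent of the damping alpha at converged cutoffs."""
    sys = _System.from_expanded(_expand(structure), ff)
    _check_neutral(sys)
    if not np.any(sys.q):
        return 0.0, {"real": 0.0, "recip": 0.0, "self": 0.0}
    _, e_real, _ = _real_space(sys, ff, do_coulomb=True, do_lj=False,
                               want_grad=False)
    e_recip, e_selfcorr, _ = _recip_space(sys, ff, want_grad=False)
    total = e_real + e_recip + e_selfcorr
    return total, {"real": e_real, "recip": e_recip, "self": e_selfcorr}


def lj_energy(structure, ff: ForceField) -> float:
    """Lennard-Jones energy of one unit cell in kJ/mol (intermolecular
    pairs within the cutoff, minimum-image lattice sum)."""
    sys = _System.from_expanded(_expand(structure), ff)
    e_lj, _, _ = _real_space(sys, ff, do_coulomb=False, do_lj=True,
                             want_grad=False)
    if ff.tail_correction:
        e_lj += _lj_tail(sys, ff)
    return e_lj


def _lj_tail(sys: _System, ff: ForceField) -> float:
    rc = ff.cutoff
    eps = np.sqrt(np.outer(sys.eps, sys.eps))
    sig = np.sqrt(np.outer(sys.sig, sys.sig))
    s3 = (sig / rc) ** 3
    s9 = s3 ** 3
    per_pair = (8 * math.pi / (3 * sys.volume)) * eps * sig ** 3 \
        * (s9 / 3 - s3)
    return float(per_pair.sum() / 2)


def lattice_energy(structure, ff: ForceField) -> EnergyBreakdown:
    """Lattice energy per molecule (kJ/mol), broken into components."""
    ex = _expand(structure)
    sys = _System.from_expanded(ex, ff)
    _check_neutral(sys)
    e_lj, e_real, _ = _real_space(sys, ff, do_coulomb=bool(np.any(sys.q)),
                                  do_lj=True, want_grad=False)
    if ff.tail_correction:
        e_lj += _lj_tail(sys, ff)
    if np.any(sys.q):
        e_recip, e_selfcorr, _ = _recip_space(sys, ff, want_grad=False)
    else:
        e_recip = e_selfcorr = 0.0
    return EnergyBreakdown.per_molecule(e_lj, e_real, e_recip, e_selfcorr,
                                        sys.n_mol)


def cell_energy_and_atom_gradient(cell: UnitCell, mol_coords, molecule,
                                  ff: ForceField):
    """Energy (kJ/mol per cell) and per-atom Cartesian gradient for an
    explicit list of rigid-molecule coordinate blocks."""
    ex = ExpandedCrystal(cell=cell, molecule=molecule,
                         mol_coords=list(mol_coords))
    sys = _System.from_expanded(ex, ff)
    do_coul = bool(np.any(sys.q))
    if do_coul:
        _check_neutral(sys)
    e_lj, e_real, grad = _real_space(sys, ff, do_coulomb=do_coul,
                                     do_lj=True, want_grad=True)
    e = e_lj + e_real
    if ff.tail_correction:
        e += _lj_tail(sys, ff)
    if do_coul:
        e_recip, e_selfcorr, g2 = _recip_space(sys, ff, want_grad=True)
        e += e_recip + e_selfcorr
        grad = grad + g2
    return e, grad


# --------------------------------------------------------------------------
# rigid-body + cell optimization

_CELL_FREE = {
    "triclinic": (0, 1, 2, 3, 4, 5),
    "monoclinic": (0, 1, 2, 4),
    "orthorhombic": (0, 1, 2),
    "tetragonal": (0, 2),
    "trigonal": (0, 2),
    "hexagonal": (0, 2),
    "cubic": (0,),
}


def cell_free_parameters(group) -> tuple:
    """Indices into (a, b, c, alpha, beta, gamma) that the space group's
    crystal system leaves free."""
    return _CELL_FREE[group.crystal_system]


def _cell_with(cell: UnitCell, free_idx, values) -> UnitCell:
    params = list(cell.parameters)
    for idx, v in zip(free_idx, values):
        params[idx] = v
    # propagate constrained equalities
    if free_idx == (0, 2):   # tetragonal/trigonal/hexagonal: b = a
        params[1] = params[0]
    if free_idx == (0,):     # cubic
        params[1] = params[2] = params[0]
    return UnitCell(*params)


@dataclass
class OptimizationResult:
    structure: CrystalStructure
    breakdown: EnergyBreakdown
    converged: bool
    grad_norm: float
    n_iter: int


def _so3_left_jacobian(w: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3): maps rotation-vector parameter velocities
    to world-frame angular velocities, d exp([w]x) = [(J w_dot)]x exp."""
    theta = np.linalg.norm(w)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    if theta < 1e-8:
        return np.eye(3) + 0.5 * K + K @ K / 6.0
    return (np.eye(3) + (1 - math.cos(theta)) / theta ** 2 * K
            + (theta - math.sin(theta)) / theta ** 3 * K @ K)


def _structure_energy_grad(structure: CrystalStructure, ff: ForceField,
                           fix_cell: bool, cell0: UnitCell, free_idx,
                           params: np.ndarray, h_cell: float = 1e-4):
    """Energy and gradient in the optimizer's parameter space.

    Layout of ``params``: [cell free values (if not fix_cell)] followed by
    Z' blocks of [frac position (3), rotation vector (3)].
    """
    nc = 0 if fix_cell else len(free_idx)
    cell = cell0 if fix_cell else _cell_with(cell0, free_idx, params[:nc])
    zp = structure.z_prime
    placements = []
    for p in range(zp):
        off = nc + 6 * p
        t = params[off:off + 3]
        w = params[off + 3:off + 6]
        q = quat_canonical(quat_multiply(rotvec_to_quat(w),
                                         structure.placements[p].orientation))
        placements.append(Placement(position=t, orientation=q))
    trial = CrystalStructure(cell=cell, group=structure.group,
                             molecule=structure.molecule,
                             placements=tuple(placements))

    def energy_of(c: UnitCell):
        ex = expand_nowrap(trial.with_cell(c))
        e, _ = cell_energy_and_atom_gradient(c, ex, trial.molecule, ff)
        return e

    ex_blocks = expand_nowrap(trial)
    e, atom_grad = cell_energy_and_atom_gradient(cell, ex_blocks,
                                                 trial.molecule, ff)
    grad = np.zeros_like(params)
    # chain atomic gradients to placement DOFs
    A = cell.matrix
    Ainv = np.linalg.inv(A)
    n_at = trial.molecule.n_atoms
    n_ops = trial.group.multiplicity
    local = trial.molecule.centered_coords()
    for p in range(zp):
        off = nc + 6 * p
        R = quat_to_matrix(placements[p].orientation)
        v = (R @ local.T).T  # current rotated offsets
        gt = np.zeros(3)
        gw = np.zeros(3)
        for g, (W, w_tr) in enumerate(trial.group.operations):
            blk = (p * n_ops + g) * n_at
            Fg = atom_grad[blk:blk + n_at]  # (n_at, 3) dE/dx
            Mg = A @ W @ Ainv
            gt += (A @ W).T @ Fg.sum(axis=0)
            gw += np.cross(v, Fg @ Mg).sum(axis=0)
        grad[off:off + 3] = gt
        grad[off + 3:off + 6] = _so3_left_jacobian(
            params[off + 3:off + 6]).T @ gw
    if not fix_cell:
        for i in range(nc):
            dp = np.array(params[:nc])
            dp[i] += h_cell
            ep = energy_of(_cell_with(cell0, free_idx, dp))
            dp[i] -= 2 * h_cell
            em = energy_of(_cell_with(cell0, free_idx, dp))
            grad[i] = (ep - em) / (2 * h_cell)
    return e, grad, trial


def expand_nowrap(structure: CrystalStructure):
    """Expanded molecule blocks with centroids wrapped (same convention
    as expand_to_cell, without the special-position check)."""
    return structure.expand(check_overlap=False).mol_coords


def placement_gradient(structure: CrystalStructure, ff: ForceField):
    """Analytic gradient of the cell energy with respect to the Z' x 6
    placement DOFs (fractional position, rotation vector), for gradient
    verification and the optimizer."""
    free_idx = cell_free_parameters(structure.group)
    zp = structure.z_prime
    params = np.zeros(6 * zp)
    for p in range(zp):
        params[6 * p:6 * p + 3] = structure.placements[p].position
    _, grad, _ = _structure_energy_grad(structure, ff, True,
                                        structure.cell, free_idx, params)
    return grad


def optimize(structure: CrystalStructure, ff: ForceField,
             fix_cell: bool = False, max_iter: int = 500,
             gtol: float = 1e-4, restarts: int = 2) -> OptimizationResult:
    """Local minimization of the lattice energy over the asymmetric-unit
    rigid-body DOFs (Z' x 6) and, unless ``fix_cell``, the free cell
    parameters of the crystal system.

    Quasi-Newton (L-BFGS-B); orientations are updated multiplicatively on
    quaternions (rotation-vector increments, re-centered between
    restarts).  Non-convergence is flagged, not raised.
    """
    free_idx = cell_free_parameters(structure.group)
    current = structure
    nit_total = 0
    result = None
    for _ in range(max(1, restarts)):
        nc = 0 if fix_cell else len(free_idx)
        zp = current.z_prime
        x0 = np.zeros(nc + 6 * zp)
        cell0 = current.cell
        if not fix_cell:
            x0[:nc] = [cell0.parameters[i] for i in free_idx]
        for p in range(zp):
            x0[nc + 6 * p:nc + 6 * p + 3] = current.placements[p].position
        bounds = []
        for i in range(nc):
            if free_idx[i] < 3:
                bounds.append((2.0, 100.0))
            else:
                bounds.append((50.0, 130.0))
        bounds += [(None, None)] * (6 * zp)
        state = {}

        def fun(x, _cur=current, _c0=cell0):
            try:
                e, g, trial = _structure_energy_grad(
                    _cur, ff, fix_cell, _c0, free_idx, x)
            except Exception:
                return 1e8, np.zeros_like(x)
            state["trial"] = trial
            state["grad"] = g
            return e, g

        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": max_iter, "ftol": 1e-12,
                                "gtol": gtol / 10})
        nit_total += res.nit
        e, g, trial = _structure_energy_grad(current, ff, fix_cell,
                                             cell0, free_idx, res.x)
        current = trial
        gnorm = float(np.abs(g).max()) if len(g) else 0.0
        result = (e, gnorm)
        if gnorm < gtol:
            break
    breakdown = lattice_energy(current, ff)
    if fix_cell:
        current = current.with_cell(structure.cell)  # bit-identical cell
    return OptimizationResult(structure=current, breakdown=breakdown,
                              converged=result[1] < gtol,
                              grad_norm=result[1], n_iter=nit_total)
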