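"""Powder X-ray diffraction: pattern simulation, quantitative pattern
matching, lattice refinement from peak positions, and simplified
rigid-body whole-profile refinement.

Kinematic diffraction with IT92 atomic form factors, isotropic
displacement, Lorentz-polarization correction
``LP = (1 + cos^2 2theta) / (sin^2 theta cos theta)``, pseudo-Voigt peak
shapes with a Caglioti FWHM law, and a Chebyshev background.  Pattern
similarity is a de Gelder-style weighted cross-correlation with a
triangular 2theta window, invariant to overall intensity scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import gemmi
import numpy as np
from numpy.polynomial import chebyshev
from scipy.optimize import least_squares

from .crystal_core import (
    CrystalStructure, ExpandedCrystal, Placement, SpaceGroupSetting,
    UnitCell, quat_canonical, quat_multiply, rotvec_to_quat,
)
from .energy import cell_free_parameters, _cell_with

__all__ = [
    "PowderPattern", "ReflectionList", "AgreementFactors", "PeakProfile",
    "reflection_list", "structure_factors", "simulate_pattern",
    "pattern_similarity", "refine_lattice", "rigid_body_refine",
    "match_candidates", "read_pattern", "write_pattern",
    "IndexingError", "MatchResult", "RefinedLattice",
]


class IndexingError(ValueError):
    """Peak indexing failed (no or ambiguous hkl assignment)."""


@dataclass
class PowderPattern:
    """1D powder pattern: wavelength (A), uniform 2theta grid (degrees),
    intensities (counts), optional statistical weights."""

    wavelength: float
    two_theta: np.ndarray
    intensities: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        tt = np.asarray(self.two_theta, dtype=float)
        ii = np.asarray(self.intensities, dtype=float)
        if tt.ndim != 1 or len(tt) < 2:
            raise ValueError("2theta grid needs at least two points")
        steps = np.diff(tt)
        if steps.min() <= 0 or (steps.max() - steps.min()) > 1e-9:
            raise ValueError("2theta grid must be strictly increasing "
                             "and uniform")
        if not np.isfinite(ii).all() or ii.shape != tt.shape:
            raise ValueError("intensities must be finite, one per grid "
                             "point")
        self.two_theta = tt
        self.intensities = ii
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def step(self) -> float:
        return float(self.two_theta[1] - self.two_theta[0])


@dataclass
class ReflectionList:
    """Symmetry-unique allowed reflections with Bragg geometry."""

    hkl: np.ndarray          # (N, 3) int
    d: np.ndarray            # A
    two_theta: np.ndarray    # degrees
    multiplicity: np.ndarray
    f2: np.ndarray | None = None  # |F|^2, arbitrary units

    def __len__(self):
        return len(self.hkl)


@dataclass(frozen=True)
class PeakProfile:
    """Pseudo-Voigt profile with Caglioti width law
    FWHM^2 = U tan^2(theta) + V tan(theta) + W (degrees^2) and mixing
    eta = eta0 + eta1 * 2theta."""

    u: float = 0.004
    v: float = 0.0
    w: float = 0.004
    eta0: float = 0.3
    eta1: float = 0.0

    def fwhm(self, two_theta_deg):
        t = np.tan(np.radians(np.asarray(two_theta_deg) / 2))
        f2 = self.u * t * t + self.v * t + self.w
        if np.any(f2 <= 0):
            raise ValueError("profile FWHM^2 must be positive over the "
                             "pattern range")
        return np.sqrt(f2)

    def eta(self, two_theta_deg):
        return np.clip(self.eta0 + self.eta1 * np.asarray(two_theta_deg),
                       0.0, 1.0)


@dataclass(frozen=True)
class AgreementFactors:
    """Rietveld agreement statistics (percent) and chi^2 =
    (R_wp/R_exp)^2."""

    r_p: float
    r_wp: float
    r_exp: float
    chi2: float
    n_reflections: int

    @classmethod
    def compute(cls, obs, calc, weights, n_params, n_reflections=0):
        obs = np.asarray(obs, dtype=float)
        calc = np.asarray(calc, dtype=float)
        w = np.asarray(weights, dtype=float)
        denom = np.abs(obs).sum()
        r_p = 100.0 * np.abs(obs - calc).sum() / max(denom, 1e-300)
        swo = float(np.sum(w * obs * obs))
        r_wp = 100.0 * math.sqrt(
            float(np.sum(w * (obs - calc) ** 2)) / max(swo, 1e-300))
        ndof = max(len(obs) - n_params, 1)
        r_exp = 100.0 * math.sqrt(ndof / max(swo, 1e-300))
        chi2 = (r_wp / r_exp) ** 2 if r_exp > 0 else float("inf")
        return cls(r_p=float(r_p), r_wp=float(r_wp), r_exp=float(r_exp),
                   chi2=float(chi2), n_reflections=int(n_reflections))


# --------------------------------------------------------------------------
# reflections and structure factors

def _cell_group_of(structure):
    if isinstance(structure, CrystalStructure):
        return structure.cell, structure.group
    if isinstance(structure, ExpandedCrystal):
        return structure.cell, SpaceGroupSetting.from_symbol("P1")
    if isinstance(structure, tuple):
        return structure
    raise TypeError("expected structure or (cell, group) tuple")


def reflection_list(structure, wavelength: float,
                    two_theta_max: float = 30.0) -> ReflectionList:
    """Symmetry-unique reflections with 2theta <= two_theta_max.

    Bragg's law ``2 d sin(theta) = lambda``; systematic absences removed
    via the group's operations; multiplicity counts the full orbit under
    the Laue class (Friedel pairs included).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    cell, group = _cell_group_of(structure)
    d_min = wavelength / (2 * math.sin(math.radians(two_theta_max / 2)))
    gstar = np.linalg.inv(cell.metric)
    hmax = [int(math.ceil(l / d_min)) + 1
            for l in (cell.a, cell.b, cell.c)]
    hs = np.stack([g.ravel() for g in np.meshgrid(
        *(np.arange(-m, m + 1) for m in hmax), indexing="ij")], axis=1)
    hs = hs[np.any(hs != 0, axis=1)]
    inv_d2 = np.einsum("ij,jk,ik->i", hs, gstar, hs)
    sel = inv_d2 <= 1.0 / (d_min * d_min) + 1e-12
    hs = hs[sel]
    inv_d2 = inv_d2[sel]

    rots = [np.rint(np.array(W)).astype(int)
            for W, _ in group.operations]
    gops = group.hall_ops

    seen: dict = {}
    for h, q2 in zip(hs, inv_d2):
        orbit = set()
        for W in rots:
            hh = tuple(int(x) for x in (h @ W))
            orbit.add(hh)
            orbit.add(tuple(-x for x in hh))
        canon = max(orbit)
        if canon in seen:
            continue
        if gops.is_systematically_absent([int(h[0]), int(h[1]), int(h[2])]):
            seen[canon] = None
            continue
        seen[canon] = (canon, q2, len(orbit))
    rows = [v for v in seen.values() if v is not None]
    rows.sort(key=lambda r: r[1])
    if not rows:
        return ReflectionList(hkl=np.zeros((0, 3), dtype=int),
                              d=np.zeros(0), two_theta=np.zeros(0),
                              multiplicity=np.zeros(0, dtype=int))
    hkl = np.array([r[0] for r in rows], dtype=int)
    d = 1.0 / np.sqrt(np.array([r[1] for r in rows]))
    arg = wavelength / (2 * d)
    ok = arg <= 1.0
    hkl, d, arg = hkl[ok], d[ok], arg[ok]
    mult = np.array([r[2] for r in rows], dtype=int)[ok]
    tt = 2 * np.degrees(np.arcsin(arg))
    keep = tt <= two_theta_max + 1e-9
    return ReflectionList(hkl=hkl[keep], d=d[keep], two_theta=tt[keep],
                          multiplicity=mult[keep])


#: default isotropic displacement parameter, Ang^2 (room-T organic)
DEFAULT_B_ISO = 3.0


def structure_factors(structure, reflections: ReflectionList,
                      b_iso: float = DEFAULT_B_ISO) -> np.ndarray:
    """|F|^2 per reflection from IT92 form factors and isotropic
    displacement: F(h) = sum_j f_j(s) exp(-B s^2) exp(2 pi i h.x_j)."""
    ex = structure.expand(check_overlap=False) \
        if isinstance(structure, CrystalStructure) else structure
    Ainv = np.linalg.inv(ex.cell.matrix)
    cart = np.concatenate(ex.mol_coords, axis=0)
    frac = (Ainv @ cart.T).T
    elements = list(ex.molecule.elements) * ex.n_molecules
    uniq = sorted(set(elements))
    it92 = {e: gemmi.Element(e).it92 for e in uniq}
    if len(reflections) == 0:
        return np.zeros(0)
    stol2 = 1.0 / (4.0 * reflections.d ** 2)  # (sin th / lambda)^2
    f_el = {e: np.array([it92[e].calculate_sf(s) for s in stol2])
            for e in uniq}
    debye = np.exp(-b_iso * stol2)
    phase = 2j * math.pi * (frac @ reflections.hkl.T)  # (M, N)
    ph = np.exp(phase)
    F = np.zeros(len(reflections), dtype=complex)
    el_arr = np.array(elements)
    for e in uniq:
        idx = el_arr == e
        F += f_el[e] * ph[idx].sum(axis=0)
    F *= debye
    return np.abs(F) ** 2


def lorentz_polarization(two_theta_deg):
    th = np.radians(np.asarray(two_theta_deg) / 2)
    return (1 + np.cos(2 * th) ** 2) / (np.sin(th) ** 2 * np.cos(th))


def _pseudo_voigt(x, fwhm, eta):
    """Unit-area pseudo-Voigt on the 2theta axis (degrees)."""
    g = (2.0 / fwhm) * math.sqrt(math.log(2) / math.pi) \
        * np.exp(-4 * math.log(2) * (x / fwhm) ** 2)
    l = (2.0 / (math.pi * fwhm)) / (1 + 4 * (x / fwhm) ** 2)
    return eta * l + (1 - eta) * g


def simulate_pattern(structure, wavelength: float, grid,
                     profile: PeakProfile = PeakProfile(),
                     background=None, scale: float = 1.0,
                     zero_shift: float = 0.0, b_iso: float = DEFAULT_B_ISO,
                     reflections: ReflectionList | None = None,
                     f2: np.ndarray | None = None) -> PowderPattern:
    """Simulated powder pattern on a uniform 2theta grid.

    I(2th) = scale * sum_refl m |F|^2 LP(th) pV(2th - 2th_refl - zero)
             + background(2th); every intensity is nonnegative.
    """
    grid = np.asarray(grid, dtype=float)
    if reflections is None:
        reflections = reflection_list(structure, wavelength,
                                      two_theta_max=float(grid[-1]) + 2.0)
    if f2 is None:
        f2 = structure_factors(structure, reflections, b_iso=b_iso)
    intens = np.zeros_like(grid)
    if len(reflections):
        amp = reflections.multiplicity * f2 \
            * lorentz_polarization(reflections.two_theta)
        fwhm = profile.fwhm(reflections.two_theta)
        eta = profile.eta(reflections.two_theta)
        x = grid[None, :] - (reflections.two_theta
                             + zero_shift)[:, None]
        prof = _pseudo_voigt(x, fwhm[:, None], eta[:, None])
        intens = amp @ prof
    intens = scale * intens
    if background is not None:
        bg = background(grid) if callable(background) \
            else np.asarray(background, dtype=float)
        intens = intens + bg
    return PowderPattern(wavelength=wavelength, two_theta=grid,
                         intensities=np.maximum(intens, 0.0))


# --------------------------------------------------------------------------
# similarity

def pattern_similarity(obs: PowderPattern, calc: PowderPattern,
                       window: float = 0.5) -> float:
    """Weighted cross-correlation similarity in [0, 1] (de Gelder style).

    Triangular lag window of half-width ``window`` degrees; 1 for
    patterns of identical shape; invariant to overall intensity scale.
    """
    if abs(obs.wavelength - calc.wavelength) > 1e-6:
        raise ValueError("patterns must share a wavelength")
    lo = max(obs.two_theta[0], calc.two_theta[0])
    hi = min(obs.two_theta[-1], calc.two_theta[-1])
    if hi <= lo:
        raise ValueError("patterns have disjoint 2theta ranges")
    step = min(obs.step, calc.step)
    grid = np.arange(lo, hi + step / 2, step)
    f = np.interp(grid, obs.two_theta, obs.intensities)
    g = np.interp(grid, calc.two_theta, calc.intensities)
    # mean-centering removes constant background so that featureless
    # signals score ~0 rather than correlating through their offset
    f = f - f.mean()
    g = g - g.mean()
    lmax = int(round(window / step))

    def wcc(u, v):
        total = 0.0
        for l in range(-lmax, lmax + 1):
            wl = 1.0 - abs(l) * step / window
            if wl <= 0:
                continue
            if l >= 0:
                c = float(np.dot(u[: len(u) - l], v[l:]))
            else:
                c = float(np.dot(u[-l:], v[: len(v) + l]))
            total += wl * c
        return total

    cfg = wcc(f, g)
    cff = wcc(f, f)
    cgg = wcc(g, g)
    if cff <= 0 or cgg <= 0:
        return 0.0
    return float(np.clip(cfg / math.sqrt(cff * cgg), 0.0, 1.0))


def estimate_background(pattern: PowderPattern, order: int = 6,
                        iterations: int = 10) -> np.ndarray:
    """Smooth background estimate by iterative Chebyshev fitting with
    peak clipping: points above the current fit are pulled down to it,
    so Bragg peaks are progressively excluded while the broad amorphous
    halo is kept."""
    y = pattern.intensities.astype(float).copy()
    x = pattern.two_theta
    for _ in range(iterations):
        coef = chebyshev.chebfit(x, y, order)
        fit = chebyshev.chebval(x, coef)
        y = np.minimum(y, fit)
    return np.maximum(chebyshev.chebval(
        x, chebyshev.chebfit(x, y, order)), 0.0)


# --------------------------------------------------------------------------
# lattice refinement from peak positions

@dataclass
class RefinedLattice:
    cell: UnitCell
    std_errors: dict          # parameter name -> estimated sigma
    residual: float           # rms 2theta residual, degrees
    assignments: list         # (obs 2theta, hkl)


_PARAM_NAMES = ("a", "b", "c", "alpha", "beta", "gamma")


def refine_lattice(peak_positions, cell0: UnitCell,
                   group: SpaceGroupSetting, wavelength: float,
                   window: float = 0.3,
                   prescale: bool = True) -> RefinedLattice:
    """Nonlinear least squares of observed vs calculated Bragg angles.

    With ``prescale`` (default) an overall isotropic scale of the
    starting cell is fitted first by a coarse scan, so a starting cell
    that is a few percent off still indexes; afterwards each observed
    position must match exactly one symmetry-unique reflection within
    ``window`` degrees, otherwise an :class:`IndexingError` lists the
    colliding hkl.
    """
    peaks = np.sort(np.asarray(peak_positions, dtype=float))
    free_idx = cell_free_parameters(group)
    if len(peaks) < len(free_idx):
        raise IndexingError(
            f"need at least {len(free_idx)} peaks to refine "
            f"{len(free_idx)} cell parameters")
    if prescale:
        best = None
        for s in np.linspace(0.92, 1.08, 81):
            cs = UnitCell(cell0.a * s, cell0.b * s, cell0.c * s,
                          cell0.alpha, cell0.beta, cell0.gamma)
            rs = reflection_list((cs, group), wavelength,
                                 two_theta_max=float(peaks[-1]) + 3.0)
            if len(rs) == 0:
                continue
            cost = float(np.sum(np.min(np.abs(
                rs.two_theta[None, :] - peaks[:, None]), axis=1) ** 2))
            if best is None or cost < best[0]:
                best = (cost, cs)
        if best is not None:
            cell0 = best[1]
    refl = reflection_list((cell0, group), wavelength,
                           two_theta_max=float(peaks[-1]) + 2 * window)
    assignments = []
    for p in peaks:
        close = np.where(np.abs(refl.two_theta - p) < window)[0]
        if len(close) == 0:
            raise IndexingError(f"peak at {p:.3f} deg matches no "
                                "reflection of the starting cell")
        if len(close) > 1:
            hkls = [tuple(refl.hkl[i]) for i in close]
            raise IndexingError(
                f"peak at {p:.3f} deg is ambiguous: candidates {hkls}")
        assignments.append((p, tuple(int(x) for x in refl.hkl[close[0]])))

    hkl = np.array([h for _, h in assignments], dtype=float)
    obs = np.array([p for p, _ in assignments])

    def calc_tt(params):
        cell = _cell_with(cell0, free_idx, params)
        gstar = np.linalg.inv(cell.metric)
        inv_d2 = np.einsum("ij,jk,ik->i", hkl, gstar, hkl)
        arg = wavelength * np.sqrt(inv_d2) / 2
        arg = np.clip(arg, 0, 1)
        return 2 * np.degrees(np.arcsin(arg))

    x0 = np.array([cell0.parameters[i] for i in free_idx])
    res = least_squares(lambda p: calc_tt(p) - obs, x0, method="lm")
    cell = _cell_with(cell0, free_idx, res.x)
    dof = max(len(obs) - len(free_idx), 1)
    s2 = 2 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        sig = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        sig = np.full(len(free_idx), np.nan)
    errors = {_PARAM_NAMES[i]: float(s)
              for i, s in zip(free_idx, sig)}
    rms = math.sqrt(2 * res.cost / len(obs))
    return RefinedLattice(cell=cell, std_errors=errors, residual=rms,
                          assignments=assignments)


# --------------------------------------------------------------------------
# rigid-body profile refinement

def _cheb_basis(grid, order):
    x = 2 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1
    return chebyshev.chebvander(x, order)


def rigid_body_refine(structure: CrystalStructure, obs: PowderPattern,
                      vary=("placements",), profile: PeakProfile = None,
                      background_order: int = 6,
                      b_iso: float = DEFAULT_B_ISO,
                      max_nfev: int = 60):
    """Least-squares fit of a calculated profile to an observed pattern
    with molecules moving only as rigid bodies.

    ``vary`` may contain "placements", "cell", "profile", "background";
    an overall scale and a 2theta zero shift are always refined.  The
    statistical weights are ``1/max(I_obs, 1)`` (Poisson counting).
    Returns ``(refined structure, AgreementFactors, details)``; on
    divergence the best-so-far parameters are returned with a flag in
    ``details``.
    """
    if profile is None:
        profile = PeakProfile()
    vary = set(vary)
    grid = obs.two_theta
    w = obs.weights if obs.weights is not None \
        else 1.0 / np.maximum(obs.intensities, 1.0)
    free_idx = cell_free_parameters(structure.group)
    zp = structure.z_prime

    # parameter layout
    names = ["scale", "zero"]
    if "placements" in vary:
        names += [f"pl{p}_{k}" for p in range(zp) for k in range(6)]
    if "cell" in vary:
        names += [f"cell{i}" for i in range(len(free_idx))]
    if "profile" in vary:
        names += ["u", "w_prof", "eta0"]
    nbg = background_order + 1 if "background" in vary else 0
    B = _cheb_basis(grid, background_order) if nbg else None

    def build(x):
        i = 2
        st = structure
        if "placements" in vary:
            placements = []
            for p in range(zp):
                t = x[i:i + 3]
                rv = x[i + 3:i + 6]
                q = quat_canonical(quat_multiply(
                    rotvec_to_quat(rv), structure.placements[p].orientation))
                placements.append(Placement(position=t, orientation=q))
                i += 6
            st = replace(st, placements=tuple(placements))
        if "cell" in vary:
            vals = x[i:i + len(free_idx)]
            st = st.with_cell(_cell_with(structure.cell, free_idx, vals))
            i += len(free_idx)
        prof = profile
        if "profile" in vary:
            prof = PeakProfile(u=abs(x[i]), v=profile.v, w=abs(x[i + 1]),
                               eta0=float(np.clip(x[i + 2], 0, 1)),
                               eta1=profile.eta1)
            i += 3
        return st, prof, i

    def model(x):
        st, prof, i = build(x)
        sim = simulate_pattern(st, obs.wavelength, grid, profile=prof,
                               zero_shift=x[1], b_iso=b_iso)
        calc = x[0] * sim.intensities
        if nbg:
            calc = calc + B @ x[i:i + nbg]
        return calc

    # initial values
    x0 = [1.0, 0.0]
    if "placements" in vary:
        for p in range(zp):
            x0 += list(structure.placements[p].position) + [0.0] * 3
    if "cell" in vary:
        x0 += [structure.cell.parameters[i] for i in free_idx]
    if "profile" in vary:
        x0 += [profile.u, profile.w, profile.eta0]
    x0 = np.array(x0 + [0.0] * nbg)
    raw = model(x0)
    denom = float(np.dot(raw, raw))
    if denom > 0:
        x0[0] = max(float(np.dot(obs.intensities, raw)) / denom, 1e-12)

    sw = np.sqrt(w)

    def residuals(x):
        try:
            return sw * (model(x) - obs.intensities)
        except Exception:
            return np.full(len(grid), 1e6)

    res = least_squares(residuals, x0, method="trf", max_nfev=max_nfev,
                        x_scale="jac")
    st, prof, _ = build(res.x)
    calc = model(res.x)
    n_params = len(res.x)
    refl = reflection_list(st, obs.wavelength,
                           two_theta_max=float(grid[-1]) + 2.0)
    factors = AgreementFactors.compute(obs.intensities, calc, w,
                                       n_params, n_reflections=len(refl))
    details = {"success": bool(res.success), "nfev": int(res.nfev),
               "params": dict(zip(names + [f"bg{i}" for i in range(nbg)],
                                  res.x)),
               "calc": calc}
    return st, factors, details


# --------------------------------------------------------------------------
# candidate matching

@dataclass
class MatchResult:
    index: int
    similarity: float
    r_wp: float | None = None


def match_candidates(candidates, obs: PowderPattern,
                     profile: PeakProfile = None,
                     solved_threshold: float = 0.8,
                     refine_top: int = 0,
                     subtract_background: bool = True):
    """Rank candidate structures against an observed pattern.

    The observed pattern is background-subtracted first (amorphous halo
    and constant base removed with :func:`estimate_background`), then
    each candidate is simulated on the observed grid and scored with
    :func:`pattern_similarity`; optionally the ``refine_top`` best are
    profile-refined and re-ranked by R_wp.  Returns ``(matches, solved)``
    where matches are sorted best first and ``solved`` says whether the
    top similarity clears the threshold.
    """
    structures = [c.structure if hasattr(c, "structure") else c
                  for c in candidates]
    if not structures:
        raise ValueError("empty candidate set")
    if profile is None:
        profile = PeakProfile()
    if subtract_background:
        bg = estimate_background(obs)
        obs = PowderPattern(wavelength=obs.wavelength,
                            two_theta=obs.two_theta,
                            intensities=np.maximum(
                                obs.intensities - bg, 0.0),
                            weights=obs.weights)
    results = []
    for i, st in enumerate(structures):
        sim = simulate_pattern(st, obs.wavelength, obs.two_theta,
                               profile=profile)
        score = pattern_similarity(obs, sim)
        results.append(MatchResult(index=i, similarity=score))
    results.sort(key=lambda m: -m.similarity)
    for m in results[:refine_top]:
        try:
            _, factors, _ = rigid_body_refine(
                structures[m.index], obs, vary=("placements",),
                profile=profile, max_nfev=20)
            m.r_wp = factors.r_wp
        except Exception:
            m.r_wp = None
    if refine_top:
        top = results[:refine_top]
        top.sort(key=lambda m: (m.r_wp if m.r_wp is not None else 1e9))
        results = top + results[refine_top:]
    solved = results[0].similarity >= solved_threshold
    return results, solved


# --------------------------------------------------------------------------
# pattern I/O (two-column xy / three-column xye text)

def write_pattern(pattern: PowderPattern, path) -> None:
    header = f"# wavelength {pattern.wavelength:.6f}\n"
    cols = [pattern.two_theta, pattern.intensities]
    if pattern.weights is not None:
        cols.append(1.0 / np.sqrt(np.maximum(pattern.weights, 1e-300)))
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.6f")


def read_pattern(path, wavelength: float | None = None) -> PowderPattern:
    wl = wavelength
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "wavelength" in line and wl is None:
                    wl = float(line.split()[-1])
                continue
            rows.append([float(x) for x in line.split()])
    if wl is None:
        raise ValueError("wavelength not given and not found in header")
    data = np.array(rows)
    weights = None
    if data.shape[1] >= 3:
        weights = 1.0 / np.maximum(data[:, 2], 1e-300) ** 2
    return PowderPattern(wavelength=wl, two_theta=data[:, 0],
                         intensities=data[:, 1], weights=weights)
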