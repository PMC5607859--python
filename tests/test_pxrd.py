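"""Powder diffraction: geometry, intensities, matching, refinement."""

import numpy as np
import pytest

from cspkit.crystal_core import (
    CrystalStructure, ExpandedCrystal, Placement, RigidMolecule,
    SpaceGroupSetting, UnitCell,
)
from cspkit.pxrd import (
    AgreementFactors, IndexingError, PeakProfile, PowderPattern,
    estimate_background, lorentz_polarization, pattern_similarity,
    read_pattern, reflection_list, refine_lattice, rigid_body_refine,
    simulate_pattern, structure_factors, write_pattern,
)

CU_KA = 1.5406


def _point_atom(cell, fracs, element="C"):
    mol = RigidMolecule(elements=(element,), coords=np.zeros((1, 3)),
                        charges=np.zeros(1), vdw_classes=(element,))
    return ExpandedCrystal(
        cell=cell, molecule=mol,
        mol_coords=[(cell.matrix @ np.asarray(f)).reshape(1, 3)
                    for f in fracs])


def test_bragg_position_cubic():
    """Bragg's law: cubic a=4 A, Cu K-alpha, (100) at 22.21 degrees."""
    rl = reflection_list((UnitCell(4, 4, 4),
                          SpaceGroupSetting.from_symbol("P1")),
                         CU_KA, 30.0)
    i = next(k for k, h in enumerate(rl.hkl)
             if sorted(np.abs(h)) == [0, 0, 1])
    assert rl.two_theta[i] == pytest.approx(22.21, abs=0.01)
    assert rl.d[i] == pytest.approx(4.0, abs=1e-9)


def test_systematic_absences():
    """2(1) screw axes kill odd h00; C-centering kills h+k odd; the
    c-glide of Pc kills h0l with l odd."""
    rl = reflection_list((UnitCell(6, 7, 8),
                          SpaceGroupSetting.from_symbol("P212121")),
                         CU_KA, 40.0)
    h00 = [tuple(h) for h in rl.hkl if h[1] == 0 and h[2] == 0]
    assert h00 and all(h[0] % 2 == 0 for h in h00)

    rl = reflection_list((UnitCell(8, 9, 7, 90, 100, 90),
                          SpaceGroupSetting.from_symbol("C2")),
                         CU_KA, 35.0)
    assert all((h[0] + h[1]) % 2 == 0 for h in rl.hkl)

    rl = reflection_list((UnitCell(8, 9, 7, 90, 100, 90),
                          SpaceGroupSetting.from_symbol("Pc")),
                         CU_KA, 35.0)
    h0l = [tuple(h) for h in rl.hkl if h[1] == 0]
    assert h0l and all(h[2] % 2 == 0 for h in h0l)


def test_multiplicity_cubic_laue():
    rl = reflection_list((UnitCell(4, 4, 4),
                          SpaceGroupSetting.from_symbol("P23")),
                         CU_KA, 30.0)
    i = next(k for k, h in enumerate(rl.hkl)
             if sorted(np.abs(h)) == [0, 0, 1])
    assert rl.multiplicity[i] == 6


def test_structure_factor_limits():
    # single atom at origin, B=0: |F|^2 = f(s)^2 > 0 and smooth
    cell = UnitCell(8, 8, 8)
    ex = _point_atom(cell, [[0, 0, 0]])
    rl = reflection_list((cell, SpaceGroupSetting.from_symbol("P1")),
                         CU_KA, 40.0)
    f2 = structure_factors(ex, rl, b_iso=0.0)
    assert np.all(f2 > 0)

    # two identical atoms at 0 and 1/2 along c: (00l) odd vanish
    ex2 = _point_atom(UnitCell(8, 8, 4), [[0, 0, 0], [0, 0, 0.5]])
    rl2 = reflection_list((ex2.cell,
                           SpaceGroupSetting.from_symbol("P1")),
                          CU_KA, 50.0)
    f22 = structure_factors(ex2, rl2, b_iso=0.0)
    odd = [f for h, f in zip(rl2.hkl, f22)
           if h[0] == 0 and h[1] == 0 and h[2] % 2 == 1]
    even = [f for h, f in zip(rl2.hkl, f22)
            if h[0] == 0 and h[1] == 0 and h[2] % 2 == 0]
    assert max(odd) < 1e-20 * max(even)

    # centrosymmetric arrangement: F is real (Im F = 0)
    cellc = UnitCell(9, 9, 9)
    ex3 = _point_atom(cellc, [[0.2, 0.3, 0.4], [-0.2, -0.3, -0.4]])
    rl3 = reflection_list((cellc, SpaceGroupSetting.from_symbol("P1")),
                          CU_KA, 30.0)
    # oracle: direct complex sum
    frac = np.array([[0.2, 0.3, 0.4], [0.8, 0.7, 0.6]])
    for h in rl3.hkl[:40]:
        F = np.exp(2j * np.pi * frac @ h).sum()
        assert abs(F.imag) < 1e-10


def test_peak_integral_and_gaussian_limit():
    """One isolated reflection integrates to m |F|^2 LP; eta=0 is a
    pure Gaussian."""
    cell = UnitCell(10, 10, 10)
    ex = _point_atom(cell, [[0, 0, 0]])
    full = reflection_list((cell, SpaceGroupSetting.from_symbol("P1")),
                           CU_KA, 10.2)
    keep = [i for i, h in enumerate(full.hkl) if tuple(h) == (1, 0, 0)]
    from cspkit.pxrd import ReflectionList
    rl = ReflectionList(hkl=full.hkl[keep], d=full.d[keep],
                        two_theta=full.two_theta[keep],
                        multiplicity=full.multiplicity[keep])
    f2 = structure_factors(ex, rl, b_iso=0.0)
    assert len(rl) == 1
    prof = PeakProfile(u=0.0, v=0.0, w=0.01, eta0=0.3)
    grid = np.arange(4.0, 14.0, 0.005)
    pat = simulate_pattern(ex, CU_KA, grid, profile=prof,
                           reflections=rl, f2=f2)
    integral = np.trapezoid(pat.intensities, grid)
    expected = float(rl.multiplicity[0] * f2[0]
                     * lorentz_polarization(rl.two_theta[0]))
    assert integral == pytest.approx(expected, rel=2e-3)

    g0 = simulate_pattern(ex, CU_KA, grid,
                          profile=PeakProfile(u=0, v=0, w=0.01, eta0=0.0),
                          reflections=rl, f2=f2)
    x = grid - rl.two_theta[0]
    fwhm = 0.1
    gauss = (2 / fwhm) * np.sqrt(np.log(2) / np.pi) \
        * np.exp(-4 * np.log(2) * (x / fwhm) ** 2) * expected
    assert np.allclose(g0.intensities, gauss, rtol=1e-6, atol=1e-6)


def test_simulated_peaks_sit_on_bragg_positions(p21_toy):
    """Internal consistency: local maxima of the simulated pattern
    coincide with reflection-list positions."""
    rl = reflection_list(p21_toy, CU_KA, 35.0)
    grid = np.arange(5.0, 35.0, 0.01)
    pat = simulate_pattern(p21_toy, CU_KA, grid)
    strong = np.argsort(-(rl.multiplicity
                          * structure_factors(p21_toy, rl)))[:5]
    for i in strong:
        tt = rl.two_theta[i]
        if not grid[2] < tt < grid[-3]:
            continue
        k = np.argmin(np.abs(grid - tt))
        window = pat.intensities[max(k - 25, 0):k + 25]
        assert pat.intensities[k] > 0.5 * window.max()


def test_pattern_similarity_contract(p21_toy):
    grid = np.arange(5, 40, 0.02)
    pat = simulate_pattern(p21_toy, CU_KA, grid)
    scaled = PowderPattern(CU_KA, grid, 3.7 * pat.intensities)
    assert pattern_similarity(pat, scaled) == pytest.approx(1.0,
                                                            abs=1e-9)
    flat = PowderPattern(CU_KA, grid, np.full_like(grid, 7.0))
    assert pattern_similarity(pat, flat) < 0.05
    with pytest.raises(ValueError):
        pattern_similarity(pat, PowderPattern(CU_KA,
                                              np.arange(50, 60, 0.02),
                                              np.ones(500)))


def test_similarity_separates_polymorph_cells(coumarin):
    """Patterns simulated in the form I vs form II cells are far less
    similar than a pattern and its noisy self."""
    rng = np.random.default_rng(0)
    from cspkit.synthetic_data import FORM_CELLS
    structures = {}
    for form in ("I", "II"):
        sym, cell, _ = FORM_CELLS[form]
        structures[form] = CrystalStructure(
            cell=cell, group=SpaceGroupSetting.from_symbol(sym),
            molecule=coumarin,
            placements=(Placement(
                position=np.array([0.13, 0.22, 0.31]),
                orientation=np.array([1.0, 0, 0, 0])),))
    grid = np.arange(1.0, 14.0, 0.005)
    lam = 0.41064
    p1 = simulate_pattern(structures["I"], lam, grid)
    p2 = simulate_pattern(structures["II"], lam, grid)
    s12 = pattern_similarity(p1, p2)
    noisy = PowderPattern(lam, grid, rng.poisson(
        1e4 * p1.intensities / p1.intensities.max() + 10).astype(float))
    s_self = pattern_similarity(p1, noisy)
    assert s12 < 0.9
    assert s12 < s_self


def _isolated_peaks(rl, min_sep):
    tt = rl.two_theta
    keep = []
    for i in range(len(tt)):
        if np.min(np.abs(np.delete(tt, i) - tt[i])) > min_sep:
            keep.append(i)
    return np.array(keep, dtype=int)


def test_refine_lattice_fixed_point_and_noise():
    truth = UnitCell(6.1, 7.3, 8.9)
    grp = SpaceGroupSetting.from_symbol("P212121")
    rl = reflection_list((truth, grp), CU_KA, 30.0)
    iso = _isolated_peaks(rl, 0.7)[:12]
    peaks = rl.two_theta[iso]
    start = UnitCell(6.15, 7.26, 8.95)
    ref = refine_lattice(peaks, start, grp, CU_KA)
    assert np.allclose(ref.cell.parameters[:3], (6.1, 7.3, 8.9),
                       atol=1e-5)
    assert ref.residual < 1e-10

    # noisy positions: refined cell within 3 estimated sigma of truth
    rng = np.random.default_rng(4)
    hits = 0
    n_rep = 30
    for _ in range(n_rep):
        noisy = peaks + rng.normal(0, 0.005, len(peaks))
        r = refine_lattice(noisy, start, grp, CU_KA)
        ok = all(abs(r.cell.parameters[i] - truth.parameters[i])
                 < 3 * max(r.std_errors[k], 1e-6)
                 for i, k in ((0, "a"), (1, "b"), (2, "c")))
        hits += ok
    assert hits >= int(0.9 * n_rep)

    # 5% off starting cell still converges: the isotropic scale prefit
    # re-anchors indexing before the strict single-candidate window
    far = UnitCell(6.1 * 1.05, 7.3 * 1.05, 8.9 * 1.05)
    r2 = refine_lattice(peaks, far, grp, CU_KA, window=0.3)
    assert np.allclose(r2.cell.parameters[:3], (6.1, 7.3, 8.9),
                       atol=1e-4)


def test_refine_lattice_ambiguity_raises():
    truth = UnitCell(6.1, 7.3, 8.9)
    grp = SpaceGroupSetting.from_symbol("P212121")
    rl = reflection_list((truth, grp), CU_KA, 30.0)
    # find two colliding reflections and aim a peak between them
    tt = np.sort(rl.two_theta)
    gaps = np.diff(tt)
    i = int(np.argmin(gaps))
    mid = 0.5 * (tt[i] + tt[i + 1])
    with pytest.raises(IndexingError, match="ambiguous"):
        refine_lattice(np.concatenate([[mid], tt[_isolated_peaks(
            rl, 0.7)[:6]]]), truth, grp, CU_KA, window=0.3)


def test_rigid_body_refine_exact_data_and_chi2_identity(p21_toy):
    grid = np.arange(5.0, 35.0, 0.02)
    obs = simulate_pattern(p21_toy, CU_KA, grid)
    obs = PowderPattern(CU_KA, grid, obs.intensities)
    st, fac, det = rigid_body_refine(p21_toy, obs, vary=(), max_nfev=5)
    assert fac.r_p < 1e-6 and fac.r_wp < 1e-6
    assert fac.chi2 == pytest.approx((fac.r_wp / fac.r_exp) ** 2,
                                     rel=1e-9)


def test_agreement_factor_identity_random():
    rng = np.random.default_rng(2)
    obs = rng.uniform(10, 1000, 400)
    calc = obs + rng.normal(0, 5, 400)
    w = 1 / obs
    fac = AgreementFactors.compute(obs, calc, w, n_params=7)
    assert fac.chi2 == pytest.approx((fac.r_wp / fac.r_exp) ** 2,
                                     rel=1e-12)
    assert fac.r_p >= 0 and fac.r_wp >= 0 and fac.r_exp >= 0


def test_background_estimate_recovers_halo(p21_toy):
    grid = np.arange(5.0, 35.0, 0.02)
    pat = simulate_pattern(p21_toy, CU_KA, grid)
    halo = 500 * np.exp(-0.5 * ((grid - 15) / 4) ** 2) + 50
    with_bg = PowderPattern(
        CU_KA, grid, 2e3 * pat.intensities / pat.intensities.max()
        + halo)
    est = estimate_background(with_bg)
    assert np.mean(np.abs(est - halo)) < 0.15 * halo.max()


def test_pattern_io_round_trip(tmp_path, p21_toy):
    grid = np.arange(5.0, 20.0, 0.05)
    pat = simulate_pattern(p21_toy, CU_KA, grid)
    path = tmp_path / "p.xy"
    write_pattern(pat, path)
    back = read_pattern(path)
    assert back.wavelength == pytest.approx(CU_KA, abs=1e-6)
    assert np.allclose(back.two_theta, pat.two_theta, atol=1e-6)
    assert np.allclose(back.intensities, pat.intensities, atol=1e-4)


def test_pattern_grid_validation():
    with pytest.raises(ValueError):
        PowderPattern(CU_KA, np.array([1.0, 2.0, 2.5]),
                      np.zeros(3))  # non-uniform
    with pytest.raises(ValueError):
        PowderPattern(CU_KA, np.array([2.0, 1.0]), np.zeros(2))
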