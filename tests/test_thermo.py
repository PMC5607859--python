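"""Thermodynamics: melting-point dG, rigid-body phonons, free energies."""

import math

import numpy as np
import pytest

from cspkit.crystal_core import ExpandedCrystal, RigidMolecule, UnitCell
from cspkit.energy import ForceField
from cspkit.thermo import (
    _FREQ_THZ, FreeEnergyCurve, H_PLANCK_KJMOL_THZ, K_B, MeltingData,
    NotAtMinimumError, PolymorphEntry, harmonic_free_energy, hessian,
    melting_point_dG, mode_frequencies, rank_polymorphs,
)
from cspkit.thermo import ImaginaryModeError

COUMARIN_MELTING = MeltingData(
    t_m={"II": 66.2, "III": 66.0, "IV": 64.9, "V": 54.0},
    t_m_ref=69.7, dh_fus=18.4)


def test_melting_point_dG_reproduces_polymorph_penalties():
    """The melting-point depression relation gives 0.19 / 0.20 / 0.26 /
    0.84 kJ/mol for the four metastable forms and the stability order
    II < III < IV < V (reference form most stable)."""
    dg = melting_point_dG(COUMARIN_MELTING)
    assert round(dg["II"], 2) == 0.19
    assert round(dg["III"], 2) == 0.20
    assert round(dg["IV"], 2) == 0.26
    assert round(dg["V"], 2) == 0.84
    assert dg["II"] < dg["III"] < dg["IV"] < dg["V"]


def test_melting_point_dG_edge_cases():
    data = MeltingData(t_m={"X": 69.7, "Y": None}, t_m_ref=69.7,
                       dh_fus=18.4)
    warnings = []
    dg = melting_point_dG(data, warn=warnings.append)
    assert dg["X"] == 0.0
    assert "Y" not in dg and len(warnings) == 1
    with pytest.raises(ValueError):
        MeltingData(t_m={}, t_m_ref=60.0, dh_fus=-1.0)


def _chain(a0, transverse=25.0):
    mol = RigidMolecule(elements=("Ar",), coords=np.zeros((1, 3)),
                        charges=np.zeros(1), vdw_classes=("AR",))
    cell = UnitCell(a0, transverse, transverse)
    return ExpandedCrystal(cell=cell, molecule=mol,
                           mol_coords=[np.zeros((1, 3))])


CHAIN_FF = ForceField(classes={"AR": (1.0, 1.0)}, cutoff=6.0)


def test_chain_phonons_match_analytic_dispersion():
    """Gamma-point modes of an N-cell supercell of a 1D LJ chain equal
    the analytic dispersion at commensurate wavevectors within 0.5%."""
    import gemmi
    a0 = 1.16  # slightly stretched: all branches real
    N = 8
    ex = _chain(a0)
    freqs, n_imag, meta = mode_frequencies(
        ex, CHAIN_FF, min_supercell=N * a0 - 1e-6, force_tol=1e-2)
    assert n_imag == 0
    got = np.sort(meta["all_modes_thz"])

    eps = sig = 1.0
    m = gemmi.Element("Ar").weight

    def phi1(r):
        return 4 * eps * (-12 * sig ** 12 / r ** 13
                          + 6 * sig ** 6 / r ** 7)

    def phi2(r):
        return 4 * eps * (156 * sig ** 12 / r ** 14
                          - 42 * sig ** 6 / r ** 8)

    nmax = int(CHAIN_FF.cutoff / a0)
    modes = []
    for j in range(N):
        k = 2 * math.pi * j / (N * a0)
        sL = sum(2 * phi2(n * a0) * (1 - math.cos(n * k * a0))
                 for n in range(1, nmax + 1))
        sT = sum(2 * (phi1(n * a0) / (n * a0))
                 * (1 - math.cos(n * k * a0))
                 for n in range(1, nmax + 1))
        modes += [sL / m, sT / m, sT / m]
    analytic = np.sort(np.sign(modes) * np.sqrt(np.abs(modes))
                       * _FREQ_THZ)
    # drop the 3 acoustic zeros from the analytic set and compare
    analytic_nz = analytic[np.abs(analytic) > 1e-6]
    got_nz = got[np.abs(got) > 1e-6]
    assert len(got_nz) == len(analytic_nz)
    assert np.allclose(got_nz, analytic_nz, rtol=5e-3)


def test_free_rigid_body_has_no_modes():
    """A single molecule in a huge cell: every vibration is (numerically)
    zero — there is nothing to vibrate against."""
    mol = RigidMolecule(elements=("C", "O"),
                        coords=np.array([[0, 0, 0], [1.2, 0, 0.0]]),
                        charges=np.zeros(2), vdw_classes=("CT", "OT"))
    ex = ExpandedCrystal(cell=UnitCell(40, 41, 42), molecule=mol,
                         mol_coords=[np.array([[20., 20, 20],
                                               [21.2, 20, 20]])])
    ff = ForceField(classes={"CT": (0.4, 3.4), "OT": (0.6, 3.0)},
                    cutoff=8.0)
    freqs, n_imag, meta = mode_frequencies(ex, ff, min_supercell=1.0,
                                           force_tol=1e-2)
    assert len(freqs) == 0
    assert np.abs(meta["all_modes_thz"]).max() < 0.05


def test_hessian_symmetry_and_minimum_guard():
    ex = _chain(1.16)
    H, M, meta = hessian(ex, CHAIN_FF, min_supercell=4 * 1.16 - 1e-6,
                         force_tol=1e-2)
    assert np.abs(H - H.T).max() < 1e-6
    assert np.all(np.diag(M) > 0)
    # non-uniform spacing: forces no longer vanish
    mol = RigidMolecule(elements=("Ar",), coords=np.zeros((1, 3)),
                        charges=np.zeros(1), vdw_classes=("AR",))
    bad = ExpandedCrystal(
        cell=UnitCell(2 * 1.16, 25, 25), molecule=mol,
        mol_coords=[np.zeros((1, 3)),
                    np.array([[1.16 + 0.15, 0.0, 0.0]])])
    with pytest.raises(NotAtMinimumError):
        hessian(bad, CHAIN_FF, min_supercell=4 * 1.16 - 1e-6,
                force_tol=1e-6)


def test_harmonic_free_energy_limits():
    nu = np.array([1.0, 2.5])  # THz
    # T = 0 quantum: pure zero-point energy sum(h nu / 2)
    zpe = harmonic_free_energy(nu, 0.0, kind="quantum")
    assert zpe == pytest.approx(H_PLANCK_KJMOL_THZ * nu.sum() / 2,
                                rel=1e-12)
    # doubling frequencies doubles the ZPE
    assert harmonic_free_energy(2 * nu, 0.0) == pytest.approx(2 * zpe)
    # classical limit: quantum - classical -> 0 for kT >> h nu
    nu1 = np.array([0.01])
    t = H_PLANCK_KJMOL_THZ * nu1[0] / (0.01 * K_B)  # h nu / kT = 0.01
    dq = harmonic_free_energy(nu1, t, kind="quantum") \
        - harmonic_free_energy(nu1, t, kind="classical")
    assert abs(dq) < 1e-4
    with pytest.raises(ImaginaryModeError):
        harmonic_free_energy(np.array([-1.0, 2.0]), 300.0)
    with pytest.raises(ValueError):
        harmonic_free_energy(nu, 0.0, kind="classical")


def test_entropy_positive_and_f_concave():
    nu = np.array([0.5, 1.0, 3.0])
    ts = np.linspace(10, 400, 80)
    f = np.array([harmonic_free_energy(nu, t) for t in ts])
    s = -np.gradient(f, ts)
    assert np.all(s > 0)            # entropy positive
    assert np.all(np.diff(s) >= -1e-9)  # F concave in T


def test_rank_polymorphs_planted_crossover():
    """Two-oscillator construction with an analytically planted
    stability crossover at T* = 250 K is detected within one grid
    step."""
    nu_hard, nu_soft = 2.0, 1.0
    t_star = 250.0
    # classical dG(T) = dE - kB T ln(nu_hard/nu_soft) = 0 at T*
    de = K_B * t_star * math.log(nu_hard / nu_soft)
    grid = np.arange(50.0, 451.0, 10.0)
    out = rank_polymorphs(
        [PolymorphEntry("hard", 0.0, np.array([nu_hard])),
         PolymorphEntry("soft", de, np.array([nu_soft]))],
        grid, kind="classical")
    key = ("hard", "soft")
    assert key in out["crossovers"]
    assert abs(out["crossovers"][key][0] - t_star) <= 10.0
    # below T* the low-energy structure wins; above, the soft one
    assert out["ordering"][0][0] == "hard"
    assert out["ordering"][-1][0] == "soft"


def test_rank_polymorphs_entropy_monotonicity_and_exclusion():
    nus = np.array([1.0, 1.5, 2.0])
    grid = np.linspace(50, 400, 36)
    out = rank_polymorphs(
        [PolymorphEntry("stiff", 0.0, nus),
         PolymorphEntry("soft", 0.0, 0.7 * nus)],
        grid, kind="classical")
    ga, gb = out["curves"][0].g(), out["curves"][1].g()
    assert np.all(gb < ga)  # softer spectrum lower G at all T > 0
    assert out["crossovers"] == {}

    out2 = rank_polymorphs(
        [PolymorphEntry("ok", 0.0, nus),
         PolymorphEntry("unstable", 0.0, np.array([-0.5, 1.0]))],
        grid, kind="classical")
    assert out2["excluded"] == ["unstable"]

    same = rank_polymorphs(
        [PolymorphEntry("a", 1.0, nus), PolymorphEntry("b", 1.0, nus)],
        grid, kind="classical")
    assert same["crossovers"] == {}
    assert np.allclose(same["curves"][0].g(), same["curves"][1].g())


def test_free_energy_curve_dataclass():
    nu = np.array([1.0, 2.0])
    temps = np.array([0.0, 100.0, 300.0])
    f = np.array([harmonic_free_energy(nu, t) for t in temps])
    c = FreeEnergyCurve(label="x", e_lattice=-20.0, frequencies_thz=nu,
                        temperatures=temps, f_vib=f)
    assert c.zero_point_energy == pytest.approx(f[0])
    assert np.allclose(c.g(), -20.0 + f)
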