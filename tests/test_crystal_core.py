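"""Crystallographic core: cells, symmetry, expansion, density, CIF."""

import numpy as np
import pytest

from cspkit.crystal_core import (
    SPACE_GROUPS_IN_SCOPE, CifParseError, CrystalStructure,
    InvalidCellError, Placement, RigidMolecule, SpaceGroupSetting,
    SpecialPositionError, UnitCell, cart_to_frac, cell_volume, density,
    expand_to_cell, frac_to_cart, niggli_reduce, quat_canonical,
    read_cif, read_molecule_file, write_cif, write_molecule_file,
)


@pytest.mark.parametrize("cell,expected,decimals", [
    # room-temperature lattice constants of the polymorph family
    (UnitCell(15.5023, 5.6630, 7.9102), 694.4, 1),
    (UnitCell(3.980, 15.291, 5.858, 90, 85.76, 90), 355.5, 1),
    (UnitCell(17.066, 6.038, 13.888), 1431.0, 1),
    (UnitCell(24.722, 5.994, 14.310), 2120.5, 1),
    (UnitCell(1, 1, 1), 1.0, 6),
])
def test_cell_volume(cell, expected, decimals):
    assert cell_volume(cell) == pytest.approx(
        expected, abs=1.0 * 10 ** -decimals)


def test_degenerate_cell_rejected():
    with pytest.raises(InvalidCellError):
        UnitCell(5, 5, 5, 10, 10, 170)  # metric not positive definite
    with pytest.raises(InvalidCellError):
        UnitCell(-1, 5, 5)


def test_frac_cart_round_trip_and_metric_oracle():
    cell = UnitCell(3.980, 15.291, 5.858, 90, 85.76, 90)
    rng = np.random.default_rng(0)
    f = rng.random((100, 3))
    assert np.allclose(cart_to_frac(cell, frac_to_cart(cell, f)), f,
                       atol=1e-10)
    # distances from the Cartesianization must match the metric tensor
    g = cell.metric
    f2 = rng.random((100, 3))
    d_cart = np.linalg.norm(frac_to_cart(cell, f) - frac_to_cart(cell, f2),
                            axis=1)
    diff = f - f2
    d_metric = np.sqrt(np.einsum("ij,jk,ik->i", diff, g, diff))
    assert np.allclose(d_cart, d_metric, atol=1e-9)
    # trivial orthorhombic check
    assert np.allclose(frac_to_cart(UnitCell(2, 3, 4), [0.5, 0.5, 0.5]),
                       [1.0, 1.5, 2.0])


def test_volume_equals_det_of_basis():
    for cell in (UnitCell(4, 5, 6), UnitCell(3.1, 7.2, 5.5, 80, 95, 103)):
        assert cell_volume(cell) == pytest.approx(
            abs(np.linalg.det(cell.matrix)), rel=1e-9)


@pytest.mark.parametrize("symbol", SPACE_GROUPS_IN_SCOPE)
def test_group_closure_identity_multiplicity(symbol):
    """Operations form a group: identity present, closed under
    composition modulo lattice translations."""
    g = SpaceGroupSetting.from_symbol(symbol)
    ops = g.operations
    assert any(np.allclose(W, np.eye(3)) and np.allclose(w % 1, 0)
               for W, w in ops)
    assert g.multiplicity == len(ops)
    for W1, w1 in ops:
        for W2, w2 in ops:
            W = W1 @ W2
            w = (W1 @ w2 + w1) % 1.0
            assert any(np.allclose(W, Wk) and
                       np.allclose(w, wk % 1.0, atol=1e-9)
                       for Wk, wk in ops), f"not closed: {symbol}"


def _place(molecule, group, cell, positions, seed=0):
    rng = np.random.default_rng(seed)
    placements = tuple(
        Placement(position=np.asarray(p),
                  orientation=quat_canonical(rng.normal(size=4)))
        for p in positions)
    return CrystalStructure(cell=cell, group=group, molecule=molecule,
                            placements=placements)


def test_expand_counts_and_rigidity(diatomic):
    p212121 = SpaceGroupSetting.from_symbol("P212121")
    s = _place(diatomic, p212121, UnitCell(8, 9, 10),
               [[0.1, 0.2, 0.3], [0.4, 0.8, 0.6], [0.7, 0.15, 0.9]])
    ex = s.expand()
    assert s.z_prime == 3 and s.z == 12 and ex.n_molecules == 12
    # rigid-body contract: intramolecular distances preserved exactly
    d0 = np.linalg.norm(diatomic.coords[0] - diatomic.coords[1])
    for block in ex.mol_coords:
        assert np.linalg.norm(block[0] - block[1]) == pytest.approx(
            d0, abs=1e-8)

    p1 = SpaceGroupSetting.from_symbol("P1")
    assert _place(diatomic, p1, UnitCell(6, 6, 6),
                  [[0.5, 0.5, 0.5]]).expand().n_molecules == 1


def test_expand_screw_image_matches_operation(diatomic):
    """P2(1): the second copy equals the screw operation applied
    directly to the first."""
    g = SpaceGroupSetting.from_symbol("P21")
    s = _place(diatomic, g, UnitCell(6, 7, 8), [[0.1, 0.2, 0.3]])
    ex = s.expand()
    assert ex.n_molecules == 2
    A = s.cell.matrix
    Ainv = np.linalg.inv(A)
    W, w = s.group.operations[1]
    frac0 = (Ainv @ ex.mol_coords[0].T).T
    imaged = (A @ ((W @ frac0.T).T + w).T).T
    shift = ex.mol_coords[1][0] - imaged[0]  # lattice wrap offset
    frac_shift = Ainv @ shift
    assert np.allclose(frac_shift, np.round(frac_shift), atol=1e-8)
    assert np.allclose(imaged + shift, ex.mol_coords[1], atol=1e-8)


def test_special_position_detected(diatomic):
    g = SpaceGroupSetting.from_symbol("P-1")
    s = _place(diatomic, g, UnitCell(7, 7, 7), [[0.0, 0.0, 0.0]])
    with pytest.raises(SpecialPositionError):
        s.expand()


def test_density_form_I_and_scaling(coumarin):
    g = SpaceGroupSetting.from_symbol("Pca21")
    s = _place(coumarin, g, UnitCell(15.5023, 5.6630, 7.9102),
               [[0.13, 0.2, 0.3]])
    # rho = Z M / (N_A V) with Z=4, M=146.14, V=694.4
    assert density(s) == pytest.approx(1.398, abs=2e-3)
    s8 = s.with_cell(UnitCell(2 * 15.5023, 2 * 5.6630, 2 * 7.9102))
    assert density(s8) == pytest.approx(density(s) / 8, rel=1e-12)


def test_niggli_reduction_properties():
    rng = np.random.default_rng(1)
    for _ in range(50):
        cell = UnitCell(*rng.uniform(3, 12, 3), *rng.uniform(70, 110, 3))
        red, P = niggli_reduce(cell)
        assert cell_volume(red) == pytest.approx(cell_volume(cell),
                                                 abs=1e-8)
        red2, _ = niggli_reduce(red)  # idempotent
        assert np.allclose(red2.parameters, red.parameters, atol=1e-6)
    # a' = a + b basis change describes the same lattice
    base = UnitCell(4, 5, 6)
    A = base.matrix
    sheared = A @ np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1]]).T
    g = sheared.T @ sheared
    abc = np.sqrt(np.diag(g))
    ang = [np.degrees(np.arccos(g[i, j] / (abc[i] * abc[j])))
           for i, j in ((1, 2), (0, 2), (0, 1))]
    red_a, _ = niggli_reduce(UnitCell(*abc, *ang))
    red_b, _ = niggli_reduce(base)
    assert np.allclose(sorted(red_a.parameters[:3]),
                       sorted(red_b.parameters[:3]), atol=1e-6)


def test_cif_round_trip(tmp_path, diatomic):
    g = SpaceGroupSetting.from_symbol("P21")
    s = _place(diatomic, g, UnitCell(6.1, 7.2, 8.3, 90, 97.5, 90),
               [[0.15, 0.25, 0.35], [0.6, 0.1, 0.8]])
    path = tmp_path / "s.cif"
    write_cif(s, path)
    ex = read_cif(path)
    assert np.allclose(ex.cell.parameters, s.cell.parameters, atol=1e-4)
    ref = s.expand(check_overlap=False)
    got = np.sort(np.concatenate(ex.mol_coords), axis=0)
    want = np.sort(np.concatenate(ref.mol_coords), axis=0)
    Ainv = np.linalg.inv(s.cell.matrix)
    assert np.allclose((Ainv @ got.T).T, (Ainv @ want.T).T, atol=1e-4)


def test_cif_missing_cell_length_errors(tmp_path):
    path = tmp_path / "bad.cif"
    path.write_text("data_x\n_cell_length_b 5.0\n_cell_length_c 6.0\n")
    with pytest.raises(CifParseError, match="_cell_length_a"):
        read_cif(path)


def test_molecule_file_round_trip(tmp_path, coumarin):
    path = tmp_path / "mol.txt"
    write_molecule_file(coumarin, path)
    back = read_molecule_file(path)
    assert back.elements == coumarin.elements
    assert np.allclose(back.coords, coumarin.coords, atol=1e-6)
    assert np.allclose(back.charges, coumarin.charges, atol=1e-6)
    assert back.vdw_classes == coumarin.vdw_classes


def test_molecule_invariants():
    with pytest.raises(ValueError, match="charge"):
        RigidMolecule(elements=("C",), coords=np.zeros((1, 3)),
                      charges=np.array([0.5]), vdw_classes=("C",))
    m = RigidMolecule(elements=("C", "O"),
                      coords=np.array([[0, 0, 0], [1.2, 0, 0.0]]),
                      charges=np.array([0.3, -0.3]),
                      vdw_classes=("C", "O"))
    assert m.molar_mass == pytest.approx(12.011 + 15.999, abs=0.01)


def test_quaternion_double_cover_canonicalized():
    q = np.array([-0.5, 0.5, 0.5, 0.5])
    p = Placement(position=np.zeros(3), orientation=q)
    assert p.orientation[0] >= 0
    assert np.allclose(np.abs(p.orientation), np.abs(q))
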