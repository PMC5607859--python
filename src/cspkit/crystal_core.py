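"""Crystallographic data model: rigid molecules, unit cells, space-group
symmetry, coordinate transforms, density, and CIF I/O.

Conventions
-----------
* Cartesianization: lattice vector **a** lies along x, **b** in the x-y
  plane (standard crystallographic setting).  The cell matrix ``A`` holds
  the lattice vectors as *columns*, so ``cart = A @ frac`` for column
  vectors; all (N, 3) coordinate arrays are row-stacked and transformed as
  ``(A @ X.T).T``.
* Fractional coordinates are wrapped to the half-open interval [0, 1).
  Molecules are assigned to cells by centroid and are never split across
  periodic images.
* Orientations are unit quaternions ``(w, x, y, z)``; the double cover is
  canonicalized by forcing a nonnegative scalar part.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "SPACE_GROUPS_IN_SCOPE",
    "RigidMolecule",
    "UnitCell",
    "SpaceGroupSetting",
    "Placement",
    "CrystalStructure",
    "ExpandedCrystal",
    "InvalidCellError",
    "SpecialPositionError",
    "CifParseError",
    "cell_volume",
    "frac_to_cart",
    "cart_to_frac",
    "expand_to_cell",
    "density",
    "niggli_reduce",
    "read_cif",
    "write_cif",
    "read_molecule_file",
    "write_molecule_file",
    "quat_to_matrix",
    "quat_multiply",
    "quat_canonical",
    "rotvec_to_quat",
]

#: Avogadro constant in mol^-1 (2019 SI).
N_AVOGADRO = 6.02214076e23

#: The space groups the packing search supports: the 13 most common groups
#: for organic molecules plus P2(1)2(1)2 (used in fixed-cell searches).
SPACE_GROUPS_IN_SCOPE = (
    "P21/c", "P-1", "P212121", "P21", "Pbca", "C2/c", "Pna21",
    "Cc", "Pca21", "C2", "P1", "Pbcn", "Pc", "P21212",
)


class InvalidCellError(ValueError):
    """Raised for degenerate (non-positive-definite) unit cells."""


class SpecialPositionError(ValueError):
    """Raised when symmetry copies of a molecule overlap a parent copy."""


class CifParseError(ValueError):
    """Raised when a CIF file lacks a mandatory item."""


# --------------------------------------------------------------------------
# quaternion helpers (scalar-first convention)

def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Normalize and force a nonnegative scalar part (q and -q are the
    same rotation)."""
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix (acts on column vectors) of a unit quaternion."""
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_multiply(q1, q2) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def rotvec_to_quat(v) -> np.ndarray:
    """Rotation-vector (axis * angle, radians) to unit quaternion."""
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-300:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / theta
    return np.concatenate([[np.cos(theta / 2)], np.sin(theta / 2) * axis])


# --------------------------------------------------------------------------
# molecules

@dataclass(frozen=True)
class RigidMolecule:
    """A rigid molecule: the only structural input to a packing search.

    Parameters
    ----------
    elements : tuple of str
        Element symbols per atom.
    coords : (N, 3) ndarray
        Cartesian coordinates in angstrom (arbitrary frame; the packing
        machinery re-centers on the centroid).
    charges : (N,) ndarray
        Point charges in units of e.  Must sum to an integer (0 for a
        neutral molecule) within 1e-6.
    vdw_classes : tuple of str
        Force-field class label per atom.
    """

    elements: tuple
    coords: np.ndarray
    charges: np.ndarray
    vdw_classes: tuple
    name: str = "molecule"

    def __post_init__(self):
        coords = np.ascontiguousarray(np.asarray(self.coords, dtype=float))
        charges = np.ascontiguousarray(np.asarray(self.charges, dtype=float))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "vdw_classes", tuple(self.vdw_classes))
        n = len(self.elements)
        if n < 1:
            raise ValueError("molecule needs at least one atom")
        if coords.shape != (n, 3) or not np.isfinite(coords).all():
            raise ValueError("coords must be a finite (N, 3) array")
        if charges.shape != (n,):
            raise ValueError("one charge per atom required")
        total = charges.sum()
        if abs(total - round(total)) > 1e-6:
            raise ValueError(
                f"net charge {total:.8f} e is not integral within 1e-6")
        if len(self.vdw_classes) != n:
            raise ValueError("one vdW class per atom required")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([gemmi.Element(e).weight for e in self.elements])

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol (sum of tabulated atomic masses)."""
        return float(self.masses.sum())

    def centered_coords(self) -> np.ndarray:
        """Coordinates relative to the (unweighted) centroid."""
        return self.coords - self.coords.mean(axis=0)


# --------------------------------------------------------------------------
# cells

@dataclass(frozen=True)
class UnitCell:
    """Unit cell: lengths in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise InvalidCellError(f"cell angle {name} outside (0, 180)")
        # positive-definite metric check
        ca, cb, cg = (np.cos(np.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        v2 = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if v2 <= 1e-12:
            raise InvalidCellError("degenerate cell: metric tensor not "
                                   "positive definite")

    @property
    def parameters(self) -> tuple:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def matrix(self) -> np.ndarray:
        """Cell matrix with lattice vectors as columns (a along x, b in
        the x-y plane)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        return np.array([
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ])

    @property
    def inv_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def metric(self) -> np.ndarray:
        A = self.matrix
        return A.T @ A


def cell_volume(cell: UnitCell) -> float:
    """Cell volume in cubic angstrom, sqrt(det(metric tensor))."""
    return float(np.sqrt(np.linalg.det(cell.metric)))


def frac_to_cart(cell: UnitCell, frac) -> np.ndarray:
    """Fractional -> Cartesian (angstrom).  Accepts (3,) or (N, 3)."""
    frac = np.asarray(frac, dtype=float)
    return (cell.matrix @ frac.T).T


def cart_to_frac(cell: UnitCell, cart) -> np.ndarray:
    """Cartesian (angstrom) -> fractional."""
    cart = np.asarray(cart, dtype=float)
    return (cell.inv_matrix @ cart.T).T


def niggli_reduce(cell: UnitCell):
    """Niggli-reduced cell of the same lattice.

    Returns
    -------
    (UnitCell, ndarray)
        The reduced cell and the 3x3 integer change-of-basis matrix P
        (fractional columns transform as ``frac_new = P @ frac_old`` up
        to lattice translations).
    """
    g = gemmi.UnitCell(*cell.parameters)
    gv = gemmi.GruberVector(g, None, track_change_of_basis=True)
    gv.niggli_reduce()
    p = gv.change_of_basis
    reduced = UnitCell(*gv.get_cell().parameters)
    rot = np.array(p.rot, dtype=float) / 24.0
    return reduced, rot


# --------------------------------------------------------------------------
# space groups

@dataclass(frozen=True)
class SpaceGroupSetting:
    """Space-group symmetry in its standard setting.

    ``operations`` is a tuple of ``(W, w)`` pairs acting on fractional
    column vectors: ``x' = W @ x + w``.
    """

    symbol: str
    operations: tuple

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupSetting":
        sg = gemmi.SpaceGroup(symbol)
        ops = []
        for op in sg.operations():
            W = np.array(op.rot, dtype=float) / 24.0
            w = np.array(op.tran, dtype=float) / 24.0
            ops.append((W, w))
        return cls(symbol=symbol, operations=tuple(ops))

    @property
    def multiplicity(self) -> int:
        return len(self.operations)

    @property
    def hall_ops(self):
        return gemmi.SpaceGroup(self.symbol).operations()

    def triplets(self) -> list:
        return [op.triplet() for op in self.hall_ops]

    @property
    def crystal_system(self) -> str:
        return gemmi.SpaceGroup(self.symbol).crystal_system_str()

    def is_sohncke(self) -> bool:
        """True if all operations are proper rotations (chirality
        preserving)."""
        return all(np.linalg.det(W) > 0 for W, _ in self.operations)


# --------------------------------------------------------------------------
# crystal structures

@dataclass(frozen=True)
class Placement:
    """One symmetry-independent rigid-body placement: fractional centroid
    plus orientation quaternion."""

    position: np.ndarray  # (3,) fractional centroid
    orientation: np.ndarray  # (4,) unit quaternion, scalar first

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        q = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must be unit norm")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", quat_canonical(q))


@dataclass(frozen=True)
class CrystalStructure:
    """Unit cell + space group + Z' rigid-body placements of one molecule."""

    cell: UnitCell
    group: SpaceGroupSetting
    molecule: RigidMolecule
    placements: tuple

    def __post_init__(self):
        object.__setattr__(self, "placements", tuple(self.placements))
        if len(self.placements) < 1:
            raise ValueError("at least one placement (Z' >= 1) required")

    @property
    def z_prime(self) -> int:
        return len(self.placements)

    @property
    def z(self) -> int:
        return self.z_prime * self.group.multiplicity

    def with_cell(self, cell: UnitCell) -> "CrystalStructure":
        return replace(self, cell=cell)

    def expand(self, check_overlap: bool = True) -> "ExpandedCrystal":
        return expand_to_cell(self, check_overlap=check_overlap)


@dataclass
class ExpandedCrystal:
    """All Z molecule copies of a structure, Cartesian, centroids wrapped
    into the cell.  ``mol_coords[i]`` is the (N, 3) coordinate block of
    copy i; copies keep the parent molecule's atom ordering."""

    cell: UnitCell
    molecule: RigidMolecule
    mol_coords: list
    group_symbol: str = "P1"

    @property
    def n_molecules(self) -> int:
        return len(self.mol_coords)

    def all_coords(self) -> np.ndarray:
        return np.concatenate(self.mol_coords, axis=0)

    def mol_ids(self) -> np.ndarray:
        n = self.molecule.n_atoms
        return np.repeat(np.arange(self.n_molecules), n)

    def centroids(self) -> np.ndarray:
        return np.array([c.mean(axis=0) for c in self.mol_coords])


def expand_to_cell(structure: CrystalStructure,
                   check_overlap: bool = True) -> ExpandedCrystal:
    """Apply all space-group operations to the Z' placements, producing
    the Z molecule copies of one unit cell.

    Rigid geometry is preserved exactly: each copy is the parent's atom
    block transformed by the (orthogonal up to cell metric) Cartesian
    image of a fractional symmetry operation.  Centroids are wrapped to
    [0, 1); atoms follow their centroid so molecules stay whole.
    """
    cell = structure.cell
    A = cell.matrix
    Ainv = np.linalg.inv(A)
    local = structure.molecule.centered_coords()
    copies = []
    for placement in structure.placements:
        R = quat_to_matrix(placement.orientation)
        offsets = (R @ local.T).T  # (N, 3) cart offsets from centroid
        t_frac = placement.position
        for W, w in structure.group.operations:
            M = A @ W @ Ainv  # Cartesian image of the fractional op
            cf = W @ t_frac + w
            cf -= np.floor(cf)  # wrap centroid, not atoms
            centroid_cart = A @ cf
            copies.append(centroid_cart + (M @ offsets.T).T)
    if check_overlap and len(copies) > 1:
        cents = np.array([c.mean(axis=0) for c in copies])
        fr = (Ainv @ cents.T).T
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                d = fr[i] - fr[j]
                d -= np.round(d)
                if np.linalg.norm(A @ d) < 0.5:
                    raise SpecialPositionError(
                        f"symmetry copies {i} and {j} overlap; molecule "
                        "appears to sit on a special position")
    return ExpandedCrystal(cell=cell, molecule=structure.molecule,
                           mol_coords=copies,
                           group_symbol=structure.group.symbol)


def density(structure: CrystalStructure) -> float:
    """Crystal density rho = Z M / (N_A V) in g/cm^3."""
    v = cell_volume(structure.cell)
    m = structure.molecule.molar_mass
    if m <= 0:
        raise ValueError("molar mass must be positive")
    # V in A^3 -> cm^3 carries 1e-24
    return structure.z * m / (N_AVOGADRO * v * 1e-24)


# --------------------------------------------------------------------------
# CIF I/O

def write_cif(structure, path) -> None:
    """Write a structure as CIF (cell, symmetry xyz strings, fractional
    atom sites of the asymmetric unit, formula weight).

    Accepts a :class:`CrystalStructure` (asymmetric unit written, symmetry
    retained) or an :class:`ExpandedCrystal` (written in P1).
    """
    doc = gemmi.cif.Document()
    block = doc.add_new_block("cspkit")
    if isinstance(structure, CrystalStructure):
        cell = structure.cell
        symbol = structure.group.symbol
        triplets = structure.group.triplets()
        mol = structure.molecule
        A = cell.matrix
        Ainv = np.linalg.inv(A)
        local = mol.centered_coords()
        blocks = []
        for placement in structure.placements:
            R = quat_to_matrix(placement.orientation)
            cart = (A @ placement.position) + (R @ local.T).T
            blocks.append((Ainv @ cart.T).T)
    elif isinstance(structure, ExpandedCrystal):
        cell = structure.cell
        symbol = "P1"
        triplets = ["x,y,z"]
        mol = structure.molecule
        Ainv = np.linalg.inv(cell.matrix)
        blocks = [(Ainv @ c.T).T for c in structure.mol_coords]
    else:
        raise TypeError("expected CrystalStructure or ExpandedCrystal")

    block.set_pair("_chemical_formula_weight", f"{mol.molar_mass:.4f}")
    for tag, val in zip(
            ("_cell_length_a", "_cell_length_b", "_cell_length_c",
             "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"),
            cell.parameters):
        block.set_pair(tag, f"{val:.6f}")
    block.set_pair("_space_group_name_H-M_alt", gemmi.cif.quote(symbol))
    loop = block.init_loop("_space_group_symop_", ["operation_xyz"])
    for t in triplets:
        loop.add_row([gemmi.cif.quote(t)])
    loop = block.init_loop("_atom_site_", [
        "label", "type_symbol", "fract_x", "fract_y", "fract_z"])
    for m, fr in enumerate(blocks):
        for k, el in enumerate(mol.elements):
            loop.add_row([f"M{m}_{el}{k}", el,
                          f"{fr[k, 0]:.6f}", f"{fr[k, 1]:.6f}",
                          f"{fr[k, 2]:.6f}"])
    doc.write_file(str(path))


def read_cif(path) -> ExpandedCrystal:
    """Read a CIF written by :func:`write_cif` (or any small-molecule CIF
    with cell, symmetry xyz strings, and fractional sites) and return the
    symmetry-expanded crystal.

    Atom sites labelled ``M<i>_...`` are grouped into molecules by the
    ``M<i>`` prefix; otherwise all sites form one molecule.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def need(tag):
        val = block.find_value(tag)
        if val is None:
            raise CifParseError(f"CIF missing mandatory item {tag}")
        return val

    params = [float(gemmi.cif.as_number(need(t))) for t in (
        "_cell_length_a", "_cell_length_b", "_cell_length_c",
        "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma")]
    cell = UnitCell(*params)
    symbol = block.find_value("_space_group_name_H-M_alt")
    if symbol is None:
        symbol = block.find_value("_symmetry_space_group_name_H-M")
    symbol = gemmi.cif.as_string(symbol) if symbol is not None else "P1"

    ops = []
    for tag in ("_space_group_symop_operation_xyz",
                "_symmetry_equiv_pos_as_xyz"):
        col = block.find_loop(tag)
        if len(col) > 0:
            for trip in col:
                op = gemmi.Op(gemmi.cif.as_string(trip))
                ops.append((np.array(op.rot, dtype=float) / 24.0,
                            np.array(op.tran, dtype=float) / 24.0))
            break
    if not ops:
        ops = [(np.eye(3), np.zeros(3))]

    table = block.find("_atom_site_", ["label", "type_symbol",
                                       "fract_x", "fract_y", "fract_z"])
    if len(table) == 0:
        raise CifParseError("CIF missing mandatory item _atom_site_ loop")
    groups: dict = {}
    for row in table:
        label = row[0]
        key = label.split("_")[0] if label.startswith("M") else "M0"
        groups.setdefault(key, []).append(
            (row[1], [gemmi.cif.as_number(row[i]) for i in (2, 3, 4)]))

    A = cell.matrix
    Ainv = np.linalg.inv(A)
    mol_coords = []
    molecule = None
    for key in sorted(groups, key=lambda k: int(k[1:]) if k[1:].isdigit() else 0):
        elements = tuple(e for e, _ in groups[key])
        frac = np.array([f for _, f in groups[key]])
        if molecule is None:
            cart = (A @ frac.T).T
            molecule = RigidMolecule(
                elements=elements, coords=cart,
                charges=np.zeros(len(elements)),
                vdw_classes=elements, name="cif")
        for W, w in ops:
            fr = (W @ frac.T).T + w
            cart = (A @ fr.T).T
            centroid = cart.mean(axis=0)
            cf = Ainv @ centroid
            shift = A @ (cf - np.floor(cf)) - centroid
            mol_coords.append(cart + shift)
    return ExpandedCrystal(cell=cell, molecule=molecule,
                           mol_coords=mol_coords, group_symbol=symbol)


# --------------------------------------------------------------------------
# molecule file I/O (XYZ-extended: element x y z charge vdw_class)

def write_molecule_file(mol: RigidMolecule, path) -> None:
    lines = [str(mol.n_atoms),
             f"molar_mass={mol.molar_mass:.4f} name={mol.name}"]
    for el, xyz, q, cls in zip(mol.elements, mol.coords, mol.charges,
                               mol.vdw_classes):
        lines.append(f"{el:2s} {xyz[0]:14.8f} {xyz[1]:14.8f} "
                     f"{xyz[2]:14.8f} {q:10.6f} {cls}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_molecule_file(path) -> RigidMolecule:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    name = "molecule"
    for token in lines[1].split():
        if token.startswith("name="):
            name = token[5:]
    elements, coords, charges, classes = [], [], [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
        charges.append(float(parts[4]))
        classes.append(parts[5])
    return RigidMolecule(elements=tuple(elements), coords=np.array(coords),
                         charges=np.array(charges),
                         vdw_classes=tuple(classes), name=name)
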