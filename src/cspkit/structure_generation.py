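"""Candidate packing generation: seeded random search over cell and
placement degrees of freedom, and a small evolutionary search with
heredity / mutation / fresh-random operators.

Sampling strategy: centroids are drawn uniformly in the full fractional
cube (duplicates arising from not constructing exact asymmetric units
are removed downstream by the RDF/cluster deduplication), orientations
uniformly on SO(3) (Shoemake), and free cells by drawing a target
density inside the density window, a log-normal shape, and the angles
the crystal system leaves free.  Raw candidates must pass a
minimum-contact filter (no intermolecular atom pair closer than
``contact_factor`` times the sum of vdW radii) before they are locally
optimized under the force field.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .crystal_core import (
    CrystalStructure, Placement, RigidMolecule, SpaceGroupSetting,
    UnitCell, cell_volume, density, frac_to_cart, quat_canonical,
    write_cif, N_AVOGADRO,
)
from .dedup_compare import deduplicate
from .energy import ForceField, optimize

__all__ = [
    "SearchConfig", "Candidate", "CandidateSet", "GenerationFailure",
    "random_candidate", "run_random_search", "run_fixed_cell_search",
    "evolve", "run_evolutionary_search", "check_contacts",
    "random_quaternion",
]


class GenerationFailure(RuntimeError):
    """The contact filter could not be satisfied within the attempt
    budget."""


@dataclass(frozen=True)
class SearchConfig:
    """Settings of one packing search.

    ``cell_mode`` is "free" or a fixed :class:`UnitCell`;
    ``density_window`` (g/cm^3) bounds sampled free cells;
    ``contact_factor`` scales the sum of vdW radii in the feasibility
    filter.
    """

    space_groups: tuple = ("P21",)
    z_prime: int = 1
    cell_mode: object = "free"          # "free" | UnitCell
    density_window: tuple = (0.8, 1.6)
    n_samples: int = 100
    generations: int = 0
    population: int = 20
    seed: int = 0
    contact_factor: float = 0.65
    max_attempts: int = 300
    opt_max_iter: int = 150
    # evolutionary operator fractions (heredity, mutation, random)
    operator_mix: tuple = (0.5, 0.3, 0.2)

    def __post_init__(self):
        lo, hi = self.density_window
        if not (0 < lo < hi):
            raise ValueError("density window must be positive and ordered")
        if self.z_prime not in (1, 2, 3):
            raise ValueError("z_prime must be 1, 2, or 3")


@dataclass
class Candidate:
    structure: CrystalStructure
    energy: float | None = None        # kJ/mol per molecule
    provenance: dict = field(default_factory=dict)
    converged: bool = True


@dataclass
class CandidateSet:
    candidates: list
    config: SearchConfig

    def __len__(self):
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]

    def sorted_by_energy(self) -> "CandidateSet":
        cands = sorted(self.candidates,
                       key=lambda c: (c.energy is None,
                                      c.energy if c.energy is not None
                                      else 0.0))
        return CandidateSet(candidates=cands, config=self.config)

    def best(self) -> Candidate | None:
        s = self.sorted_by_energy()
        return s.candidates[0] if s.candidates else None

    def save(self, directory) -> None:
        """Serialize as a directory of CIFs plus a CSV manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, c in enumerate(self.candidates):
            name = f"candidate_{i:04d}.cif"
            write_cif(c.structure, directory / name)
            rows.append({
                "id": i, "file": name,
                "group": c.structure.group.symbol,
                "z_prime": c.structure.z_prime,
                "energy_kj_per_mol": c.energy,
                "density_g_cm3": density(c.structure),
                "seed": c.provenance.get("seed"),
                "index": c.provenance.get("index"),
                "generation": c.provenance.get("generation"),
                "parents": ";".join(map(str,
                                        c.provenance.get("parents", []))),
            })
        with open(directory / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows
                                    else ["id"])
            writer.writeheader()
            writer.writerows(rows)


# --------------------------------------------------------------------------
# sampling primitives

def random_quaternion(rng) -> np.ndarray:
    """Uniform random rotation (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    q = np.array([
        math.sqrt(1 - u1) * math.sin(2 * math.pi * u2),
        math.sqrt(1 - u1) * math.cos(2 * math.pi * u2),
        math.sqrt(u1) * math.sin(2 * math.pi * u3),
        math.sqrt(u1) * math.cos(2 * math.pi * u3),
    ])
    return quat_canonical(q)


def _sample_cell(group: SpaceGroupSetting, molecule: RigidMolecule,
                 z: int, window, rng) -> UnitCell:
    rho = rng.uniform(*window)
    target_v = z * molecule.molar_mass / (N_AVOGADRO * rho * 1e-24)
    system = group.crystal_system
    alpha = beta = gamma = 90.0
    if system == "monoclinic":
        beta = rng.uniform(75.0, 115.0)
    elif system == "triclinic":
        alpha, beta, gamma = rng.uniform(75.0, 115.0, size=3)
    ratios = np.exp(rng.normal(0.0, 0.35, size=3))
    ratios /= ratios.prod() ** (1 / 3)
    probe = UnitCell(ratios[0], ratios[1], ratios[2], alpha, beta, gamma)
    scale = (target_v / cell_volume(probe)) ** (1 / 3)
    return UnitCell(ratios[0] * scale, ratios[1] * scale,
                    ratios[2] * scale, alpha, beta, gamma)


_VDW_CACHE: dict = {}


def _vdw_radii(molecule: RigidMolecule) -> np.ndarray:
    key = molecule.elements
    if key not in _VDW_CACHE:
        _VDW_CACHE[key] = np.array(
            [gemmi.Element(e).vdw_r for e in molecule.elements])
    return _VDW_CACHE[key]


def check_contacts(structure: CrystalStructure,
                   factor: float = 0.65) -> bool:
    """True when no intermolecular atom pair (images included) is closer
    than factor * (sum of vdW radii)."""
    try:
        ex = structure.expand(check_overlap=False)
    except Exception:
        return False
    radii = np.tile(_vdw_radii(structure.molecule), ex.n_molecules)
    X = np.concatenate(ex.mol_coords, axis=0)
    n_at = structure.molecule.n_atoms
    mol_id = np.repeat(np.arange(ex.n_molecules), n_at)
    A = ex.cell.matrix
    rmax = factor * 2 * radii.max()
    span = float(np.linalg.norm(
        structure.molecule.centered_coords(), axis=1).max())
    widths = 1.0 / np.linalg.norm(np.linalg.inv(A), axis=1)
    nmax = np.ceil((rmax + 2 * span) / widths).astype(int)
    grids = np.meshgrid(*(np.arange(-n, n + 1) for n in nmax),
                        indexing="ij")
    shifts = (np.stack([g.ravel() for g in grids], axis=1).astype(float)
              @ A.T)
    zero = np.all(np.abs(shifts) < 1e-12, axis=1)
    M = len(X)
    ii, jj = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    base = X[ii] - X[jj]
    limit = factor * (radii[ii] + radii[jj])
    intra = mol_id[ii] == mol_id[jj]
    for s, z0 in zip(shifts, zero):
        d2 = np.einsum("ij,ij->i", base - s, base - s)
        viol = d2 < limit * limit
        if z0:
            viol &= ~intra
        if viol.any():
            return False
    return True


def random_candidate(config: SearchConfig, molecule: RigidMolecule,
                     rng, index: int = 0) -> Candidate:
    """One contact-feasible random candidate, deterministic given the
    rng state.  Raises :class:`GenerationFailure` after
    ``max_attempts`` rejections."""
    groups = [SpaceGroupSetting.from_symbol(s)
              for s in config.space_groups]
    for attempt in range(config.max_attempts):
        group = groups[rng.integers(len(groups))] if len(groups) > 1 \
            else groups[0]
        z = config.z_prime * group.multiplicity
        if isinstance(config.cell_mode, UnitCell):
            cell = config.cell_mode
        else:
            cell = _sample_cell(group, molecule, z,
                                config.density_window, rng)
        placements = tuple(
            Placement(position=rng.random(3),
                      orientation=random_quaternion(rng))
            for _ in range(config.z_prime))
        structure = CrystalStructure(cell=cell, group=group,
                                     molecule=molecule,
                                     placements=placements)
        if check_contacts(structure, config.contact_factor):
            return Candidate(structure=structure,
                             provenance={"seed": config.seed,
                                         "index": index,
                                         "attempt": attempt,
                                         "group": group.symbol})
    raise GenerationFailure(
        f"no contact-feasible candidate in {config.max_attempts} "
        f"attempts (groups {config.space_groups}, Z'={config.z_prime}, "
        f"window {config.density_window} g/cm3)")


# --------------------------------------------------------------------------
# searches

def _optimize_candidate(cand: Candidate, ff: ForceField,
                        config: SearchConfig,
                        fix_cell: bool) -> Candidate:
    try:
        res = optimize(cand.structure, ff, fix_cell=fix_cell,
                       max_iter=config.opt_max_iter, restarts=1)
    except Exception as exc:  # propagate per candidate, not the search
        cand.energy = None
        cand.provenance["error"] = repr(exc)
        cand.converged = False
        return cand
    cand.structure = res.structure
    cand.energy = res.breakdown.e_total
    cand.converged = res.converged
    return cand


def _dedup_candidates(cands, config):
    ok = [c for c in cands if c.energy is not None
          and np.isfinite(c.energy)]
    ok_ids = {id(c) for c in ok}
    failed = [c for c in cands if id(c) not in ok_ids]
    if len(ok) > 1:
        reps, labels = deduplicate([c.structure for c in ok])
        by_label: dict = {}
        for c, lbl in zip(ok, labels):
            if lbl not in by_label or c.energy < by_label[lbl].energy:
                by_label[lbl] = c
        ok = list(by_label.values())
    ok.sort(key=lambda c: c.energy)
    return CandidateSet(candidates=ok, config=config), failed


def run_random_search(config: SearchConfig, molecule: RigidMolecule,
                      ff: ForceField, deduplicate_results: bool = True):
    """Random packing search: sample, optimize, deduplicate, rank.

    Returns a :class:`CandidateSet` sorted by energy.  Candidate
    failures (generation or energy) are recorded, not raised.
    """
    rng = np.random.default_rng(config.seed)
    fix_cell = isinstance(config.cell_mode, UnitCell)
    raw = []
    for i in range(config.n_samples):
        try:
            cand = random_candidate(config, molecule, rng, index=i)
        except GenerationFailure:
            continue
        raw.append(_optimize_candidate(cand, ff, config, fix_cell))
    if not deduplicate_results:
        ok = [c for c in raw if c.energy is not None]
        ok.sort(key=lambda c: c.energy)
        return CandidateSet(candidates=ok, config=config)
    cset, _ = _dedup_candidates(raw, config)
    return cset


def run_fixed_cell_search(config: SearchConfig, molecule: RigidMolecule,
                          ff: ForceField, **kw):
    """Random search with the experimental cell held fixed (only the
    placements vary)."""
    if not isinstance(config.cell_mode, UnitCell):
        raise ValueError("fixed-cell search needs cell_mode=UnitCell")
    return run_random_search(config, molecule, ff, **kw)


# --------------------------------------------------------------------------
# evolutionary search

def _mutate(structure: CrystalStructure, rng, sigma_frac=0.05,
            sigma_rot=0.15, sigma_strain=0.04,
            mutate_cell=True) -> CrystalStructure:
    from .crystal_core import quat_multiply, rotvec_to_quat
    placements = []
    for p in structure.placements:
        t = p.position + rng.normal(0, sigma_frac, 3)
        q = quat_canonical(quat_multiply(
            rotvec_to_quat(rng.normal(0, sigma_rot, 3)), p.orientation))
        placements.append(Placement(position=t - np.floor(t),
                                    orientation=q))
    cell = structure.cell
    if mutate_cell and sigma_strain > 0:
        pars = list(cell.parameters)
        for i in range(3):
            pars[i] *= 1.0 + rng.normal(0, sigma_strain)
        free = {"monoclinic": [4], "triclinic": [3, 4, 5]}.get(
            structure.group.crystal_system, [])
        for i in free:
            pars[i] += rng.normal(0, 2.0)
        cell = UnitCell(*pars)
    return CrystalStructure(cell=cell, group=structure.group,
                            molecule=structure.molecule,
                            placements=tuple(placements))


def evolve(population: CandidateSet, config: SearchConfig,
           molecule: RigidMolecule, ff: ForceField, rng,
           generation: int = 1) -> CandidateSet:
    """One generation: elitism (best kept), heredity (cell of one parent
    with placements of another), placement/lattice mutation, and fresh
    random candidates."""
    parents = population.sorted_by_energy().candidates
    if not parents:
        raise ValueError("empty population")
    n = config.population
    f_her, f_mut, f_rand = config.operator_mix
    n_her = int(round(f_her * (n - 1)))
    n_mut = int(round(f_mut * (n - 1)))
    n_rand = max(n - 1 - n_her - n_mut, 0)
    fix_cell = isinstance(config.cell_mode, UnitCell)
    children = [replace(parents[0])]  # elite
    children[0].provenance = dict(parents[0].provenance,
                                  generation=generation, operator="elite")

    def pick():
        # rank-weighted parent choice
        w = 1.0 / (1 + np.arange(len(parents)))
        w /= w.sum()
        return parents[rng.choice(len(parents), p=w)]

    attempts = 0
    made_her = made_mut = 0
    while made_her < n_her and attempts < 20 * n_her + 10:
        attempts += 1
        pa, pb = pick(), pick()
        try:
            child = CrystalStructure(
                cell=pa.structure.cell, group=pb.structure.group,
                molecule=molecule, placements=pb.structure.placements)
        except Exception:
            continue
        if pa.structure.group.symbol != pb.structure.group.symbol:
            continue
        if not check_contacts(child, config.contact_factor * 0.9):
            continue
        cand = Candidate(structure=child, provenance={
            "seed": config.seed, "generation": generation,
            "operator": "heredity",
            "parents": [pa.provenance.get("index"),
                        pb.provenance.get("index")]})
        children.append(_optimize_candidate(cand, ff, config, fix_cell))
        made_her += 1
    attempts = 0
    while made_mut < n_mut and attempts < 20 * n_mut + 10:
        attempts += 1
        pa = pick()
        try:
            child = _mutate(pa.structure, rng, mutate_cell=not fix_cell)
        except Exception:
            continue
        if not check_contacts(child, config.contact_factor * 0.9):
            continue
        cand = Candidate(structure=child, provenance={
            "seed": config.seed, "generation": generation,
            "operator": "mutation",
            "parents": [pa.provenance.get("index")]})
        children.append(_optimize_candidate(cand, ff, config, fix_cell))
        made_mut += 1
    for i in range(n_rand + (n_her - made_her) + (n_mut - made_mut)):
        try:
            cand = random_candidate(config, molecule, rng,
                                    index=1000 * generation + i)
        except GenerationFailure:
            continue
        cand.provenance["generation"] = generation
        cand.provenance["operator"] = "random"
        children.append(_optimize_candidate(cand, ff, config, fix_cell))
    ok = [c for c in children if c.energy is not None]
    ok.sort(key=lambda c: c.energy)
    return CandidateSet(candidates=ok, config=config)


def run_evolutionary_search(config: SearchConfig,
                            molecule: RigidMolecule, ff: ForceField):
    """Evolutionary search: random initial population then
    ``config.generations`` rounds of :func:`evolve`."""
    rng = np.random.default_rng(config.seed + 1)
    init = replace(config, n_samples=config.population)
    population = run_random_search(init, molecule, ff,
                                   deduplicate_results=False)
    history = [population.best().energy if population.best() else None]
    for gen in range(1, config.generations + 1):
        population = evolve(population, config, molecule, ff, rng,
                            generation=gen)
        history.append(population.best().energy
                       if population.best() else None)
    cset, _ = _dedup_candidates(list(population), config)
    return cset, history
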