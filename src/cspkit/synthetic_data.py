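"""Synthetic inputs for the whole pipeline: toy rigid molecules, a
coumarin model, ground-truth packings, and noisy powder patterns that
emulate a synchrotron capillary measurement of a melt-crystallized
polycrystalline sample (sharp Bragg peaks, Poisson counting noise, and
a broad amorphous halo from the resin matrix the samples are embedded
in).

Everything is generated from code and fully deterministic given
(spec, seed); nothing is downloaded.

The bundled coumarin point charges are a synthetic stand-in set (simple
chemically motivated values summing to zero), NOT fitted to any
electronic-structure calculation; quantitative force-field energies of
the coumarin model are therefore illustrative only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .crystal_core import (
    CrystalStructure, Placement, RigidMolecule, SpaceGroupSetting,
    UnitCell, write_cif, write_molecule_file,
)
from .energy import ForceField, optimize
from .pxrd import PeakProfile, PowderPattern, simulate_pattern
from .structure_generation import (
    SearchConfig, run_fixed_cell_search, run_random_search,
)

__all__ = [
    "diatomic_model", "planar_ring_model", "coumarin_model",
    "toy_forcefield", "coumarin_forcefield", "PatternRecipe",
    "synthetic_pattern", "ground_truth_structure", "form_analogue_recipe",
    "ScenarioSpec", "end_to_end_scenario", "solve_scenario",
    "save_bundle", "FORM_CELLS", "EASY", "FIXED_CELL",
]


# --------------------------------------------------------------------------
# molecules

def diatomic_model() -> RigidMolecule:
    """Polar CO-like rigid diatomic: the cheapest packing test body."""
    return RigidMolecule(
        elements=("C", "O"),
        coords=np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0]]),
        charges=np.array([0.35, -0.35]),
        vdw_classes=("CT", "OT"), name="diatomic")


def planar_ring_model() -> RigidMolecule:
    """Benzene-like planar hexagonal ring (6 C + 6 H)."""
    coords, elements, charges, classes = [], [], [], []
    for k in range(6):
        th = math.pi / 3 * k
        c = np.array([1.40 * math.cos(th), 1.40 * math.sin(th), 0.0])
        coords.append(c)
        elements.append("C")
        charges.append(-0.115)
        classes.append("CA")
        coords.append(c * (1 + 1.08 / 1.40))
        elements.append("H")
        charges.append(0.115)
        classes.append("HA")
    return RigidMolecule(elements=tuple(elements),
                         coords=np.array(coords),
                         charges=np.array(charges),
                         vdw_classes=tuple(classes), name="ring")


def coumarin_model() -> RigidMolecule:
    """Planar bicyclic C9H6O2 model (2H-chromen-2-one) built from two
    fused regular hexagons with standard bond lengths (ring C-C/C-O
    1.40 A, C=O 1.22 A, C-H 1.08 A); molar mass 146.14 g/mol.

    Charges are the bundled synthetic stand-in set (sum = 0)."""
    s = 1.40                       # ring bond length
    cL = np.array([-s * math.sqrt(3) / 2, 0.0])   # benzo ring center
    cR = np.array([s * math.sqrt(3) / 2, 0.0])    # pyranone ring center

    def hexv(center, theta_deg):
        th = math.radians(theta_deg)
        return np.array([center[0] + s * math.cos(th),
                         center[1] + s * math.sin(th), 0.0])

    atoms = {}
    atoms["C8a"] = hexv(cR, 150)   # (0, +0.7)
    atoms["C4a"] = hexv(cR, 210)   # (0, -0.7)
    atoms["O1"] = hexv(cR, 90)
    atoms["C2"] = hexv(cR, 30)
    atoms["C3"] = hexv(cR, -30)
    atoms["C4"] = hexv(cR, -90)
    atoms["C5"] = hexv(cL, -90)
    atoms["C6"] = hexv(cL, -150)
    atoms["C7"] = hexv(cL, 150)
    atoms["C8"] = hexv(cL, 90)
    # carbonyl O outward from the pyranone center through C2
    u = (atoms["C2"][:2] - cR)
    u = u / np.linalg.norm(u)
    atoms["O2"] = np.array([*(atoms["C2"][:2] + 1.22 * u), 0.0])

    order = ["O1", "C2", "O2", "C3", "C4", "C4a", "C5", "C6", "C7",
             "C8", "C8a"]
    elements = ["O", "C", "O", "C", "C", "C", "C", "C", "C", "C", "C"]
    # electronegativity-equalization (Gasteiger PEOE) stand-in charges
    charges = [-0.4227, 0.3357, -0.2465, 0.0244, -0.0440, 0.0176,
               -0.0512, -0.0614, -0.0585, -0.0185, 0.1379]
    classes = ["OS", "C", "O", "CA", "CA", "CA", "CA", "CA", "CA", "CA",
               "CA"]
    coords = [atoms[k] for k in order]
    # ring H on C3, C4 (pyranone) and C5-C8 (benzo)
    h_charges = {"C3": 0.0700, "C4": 0.0633, "C5": 0.0630,
                 "C6": 0.0623, "C7": 0.0624, "C8": 0.0662}
    for name, center in (("C3", cR), ("C4", cR), ("C5", cL), ("C6", cL),
                         ("C7", cL), ("C8", cL)):
        u = atoms[name][:2] - center
        u = u / np.linalg.norm(u)
        coords.append(np.array([*(atoms[name][:2] + 1.08 * u), 0.0]))
        elements.append("H")
        charges.append(h_charges[name])
        classes.append("HA")
    charges = np.array(charges)
    charges -= charges.sum() / len(charges)  # enforce exact neutrality
    return RigidMolecule(elements=tuple(elements),
                         coords=np.array(coords),
                         charges=np.array(charges),
                         vdw_classes=tuple(classes), name="coumarin")


def toy_forcefield() -> ForceField:
    """Force field for the toy bodies (8 A cutoff keeps small-cell
    searches fast)."""
    return ForceField(classes={"CT": (0.4, 3.4), "OT": (0.6, 3.0),
                               "CA": (0.29288, 3.55),
                               "HA": (0.12552, 2.42)},
                      cutoff=8.0, alpha=0.35, accuracy=1e-6)


def coumarin_forcefield() -> ForceField:
    """OPLS-style parameters for the coumarin model atom classes
    (aromatic C/H, carbonyl C/O, ester O); 12 A cutoff, Ewald damping
    0.3 A^-1."""
    return ForceField(classes={
        "CA": (0.29288, 3.55), "HA": (0.12552, 2.42),
        "C": (0.43932, 3.75), "O": (0.87864, 2.96),
        "OS": (0.58576, 2.90)},
        cutoff=12.0, alpha=0.3, accuracy=1e-5)


# --------------------------------------------------------------------------
# ground-truth packings

#: Room-temperature cells and symmetry of the five coumarin forms used
#: as packing recipes for analogue structures.
FORM_CELLS = {
    "I": ("Pca21", UnitCell(15.5023, 5.6630, 7.9102), 1),
    "II": ("P21", UnitCell(3.980, 15.291, 5.858, 90, 85.76, 90), 1),
    "III": ("P212121", UnitCell(17.066, 6.038, 13.888), 2),
    "IV": ("P212121", UnitCell(24.722, 5.994, 14.310), 3),
    "V": ("P212121", UnitCell(4.868, 6.882, 20.851), 1),
}


def form_analogue_recipe(form: str) -> dict:
    """Packing recipe (group, cell, Z') of a coumarin polymorph
    analogue."""
    group, cell, zp = FORM_CELLS[form]
    return {"group": group, "cell": cell, "z_prime": zp,
            "molecule": "coumarin"}


def ground_truth_structure(recipe: dict, seed: int = 11,
                           n_samples: int = 12,
                           ff: ForceField | None = None,
                           molecule: RigidMolecule | None = None,
                           contact_factor: float = 0.6):
    """Deterministic, contact-feasible, locally optimized packing in the
    requested group / cell / Z'.

    The best of ``n_samples`` seeded fixed-cell random candidates is
    returned; raises :class:`RuntimeError` when the recipe is infeasible
    (no candidate survives the contact filter).
    """
    if molecule is None:
        molecule = coumarin_model() if recipe.get("molecule") == \
            "coumarin" else diatomic_model()
    if ff is None:
        ff = coumarin_forcefield() if molecule.name == "coumarin" \
            else toy_forcefield()
    cfg = SearchConfig(space_groups=(recipe["group"],),
                       z_prime=recipe["z_prime"],
                       cell_mode=recipe["cell"],
                       n_samples=n_samples, seed=seed,
                       contact_factor=contact_factor,
                       density_window=(0.5, 3.0))
    result = run_fixed_cell_search(cfg, molecule, ff,
                                   deduplicate_results=False)
    best = result.best()
    if best is None:
        raise RuntimeError(f"infeasible recipe: {recipe}")
    return best.structure


# --------------------------------------------------------------------------
# synthetic powder patterns

@dataclass(frozen=True)
class PatternRecipe:
    """Measurement emulation: synchrotron-like wavelength and step, a
    counts scale, a broad amorphous background, and Poisson noise."""

    wavelength: float = 0.41064
    two_theta_min: float = 1.0
    two_theta_max: float = 16.0
    step: float = 0.005
    counts_scale: float = 5e4      # peak counts order of magnitude
    background_frac: float = 0.2   # halo amplitude vs strongest peak
    halo_center_d: float = 4.0     # A, near the main packing d-spacing
    halo_width: float = 2.5        # degrees 2theta
    poisson_noise: bool = True
    profile: PeakProfile = field(
        default_factory=lambda: PeakProfile(u=0.002, v=0.0, w=0.0015,
                                            eta0=0.3))


def synthetic_pattern(structure, recipe: PatternRecipe, rng=None):
    """Noisy synthetic pattern plus the noiseless truth.

    Returns ``(pattern, truth_pattern)``; the Poisson noise (variance =
    intensity, counting statistics) and amorphous Gaussian halo follow
    the recipe.  Deterministic given the rng state.
    """
    grid = np.arange(recipe.two_theta_min, recipe.two_theta_max,
                     recipe.step)
    clean = simulate_pattern(structure, recipe.wavelength, grid,
                             profile=recipe.profile)
    peak_max = clean.intensities.max()
    scale = recipe.counts_scale / max(peak_max, 1e-300)
    signal = clean.intensities * scale
    if recipe.background_frac > 0:
        tt0 = 2 * math.degrees(math.asin(
            recipe.wavelength / (2 * recipe.halo_center_d)))
        halo = recipe.background_frac * recipe.counts_scale * np.exp(
            -0.5 * ((grid - tt0) / recipe.halo_width) ** 2)
        signal = signal + halo
    signal = signal + 0.01 * recipe.counts_scale  # constant base count
    truth = PowderPattern(wavelength=recipe.wavelength, two_theta=grid,
                          intensities=signal)
    if recipe.poisson_noise:
        if rng is None:
            rng = np.random.default_rng(0)
        noisy = rng.poisson(signal).astype(float)
    else:
        noisy = signal.copy()
    pattern = PowderPattern(wavelength=recipe.wavelength, two_theta=grid,
                            intensities=noisy,
                            weights=1.0 / np.maximum(noisy, 1.0))
    return pattern, truth


# --------------------------------------------------------------------------
# scenarios

@dataclass(frozen=True)
class ScenarioSpec:
    """A complete, regenerable pipeline exercise.

    ``difficulty`` tiers: "easy" (diatomic, Z'=1, free cell),
    "fixed-cell" (diatomic, Z'=2, true cell supplied), "coumarin"
    (coumarin model in a polymorph cell).
    """

    name: str = "easy"
    molecule: str = "diatomic"     # diatomic | ring | coumarin
    group: str = "P21"
    z_prime: int = 1
    supply_cell: bool = False
    truth_seed: int = 101
    truth_samples: int = 30
    solve_seed: int = 202
    solve_samples: int = 40
    pattern: PatternRecipe = field(default_factory=PatternRecipe)
    density_window: tuple = (1.0, 2.2)


EASY = ScenarioSpec(name="easy")
# Z' = 2 doubles the placement DOFs, so the solve stage gets a deeper
# sampling budget (the fixed cell makes each candidate much cheaper).
# The planar ring is used rather than the polar diatomic: a polar
# diatomic crystal has a nearly homometric "all dipoles reversed" twin
# whose powder pattern is almost indistinguishable, which makes a
# ground-truth identity test ill-posed; a molecule with in-plane
# two-fold symmetry has no such twin.
FIXED_CELL = ScenarioSpec(name="fixed-cell", molecule="ring",
                          z_prime=2, supply_cell=True, truth_seed=303,
                          truth_samples=12, solve_seed=404,
                          solve_samples=60,
                          density_window=(0.8, 1.4))


def _molecule_of(spec: ScenarioSpec):
    return {"diatomic": diatomic_model, "ring": planar_ring_model,
            "coumarin": coumarin_model}[spec.molecule]()


def _ff_of(spec: ScenarioSpec):
    return coumarin_forcefield() if spec.molecule == "coumarin" \
        else toy_forcefield()


def end_to_end_scenario(spec: ScenarioSpec, seed: int = 0) -> dict:
    """Build a scenario bundle: molecule, force field, observed noisy
    pattern, optional approximate cell, and the withheld ground truth.

    The truth packing is the best structure of an independent seeded
    free-cell search (so it is a realistic force-field minimum, not a
    hand-placed configuration); the observed pattern is simulated from
    it with noise.  ``seed`` offsets all internal seeds.
    """
    molecule = _molecule_of(spec)
    ff = _ff_of(spec)
    truth_cfg = SearchConfig(space_groups=(spec.group,),
                             z_prime=spec.z_prime,
                             n_samples=spec.truth_samples,
                             seed=(spec.truth_seed + 7919 * seed)
                             % (2 ** 31),
                             density_window=spec.density_window)
    truth = run_random_search(truth_cfg, molecule, ff).best()
    if truth is None:
        return {"molecule": molecule, "ff": ff, "truth": None,
                "pattern": None, "spec": spec}
    rng = np.random.default_rng((spec.truth_seed + 104729 * (seed + 1))
                                % (2 ** 31))
    pattern, clean = synthetic_pattern(truth.structure, spec.pattern,
                                       rng)
    bundle = {"molecule": molecule, "ff": ff, "spec": spec,
              "pattern": pattern, "clean_pattern": clean,
              "truth": truth.structure, "truth_energy": truth.energy,
              "cell": truth.structure.cell if spec.supply_cell else None,
              "seed": seed}
    return bundle


def solve_scenario(bundle: dict) -> dict:
    """Run the solution pipeline on a bundle: generate candidates
    (never looking at the truth), match against the observed pattern,
    and report the top match.  Validation against the withheld truth is
    the caller's job (see dedup_compare.cluster_rmsd)."""
    from .pxrd import match_candidates
    spec: ScenarioSpec = bundle["spec"]
    cell_mode = bundle["cell"] if bundle["cell"] is not None else "free"
    cfg = SearchConfig(space_groups=(spec.group,), z_prime=spec.z_prime,
                       cell_mode=cell_mode,
                       n_samples=spec.solve_samples,
                       seed=(spec.solve_seed + 7919 * bundle.get(
                           "seed", 0)) % (2 ** 31),
                       density_window=spec.density_window)
    cands = run_random_search(cfg, bundle["molecule"], bundle["ff"])
    if len(cands) == 0:
        return {"solved": False, "candidates": cands, "matches": [],
                "best_structure": None}
    matches, solved = match_candidates(list(cands), bundle["pattern"],
                                       profile=spec.pattern.profile)
    best = cands[matches[0].index].structure
    return {"solved": solved, "candidates": cands, "matches": matches,
            "best_structure": best,
            "best_similarity": matches[0].similarity}


def save_bundle(bundle: dict, directory) -> None:
    """Serialize a scenario bundle (molecule file, pattern xy, truth
    CIF, manifest) for offline inspection."""
    import json
    from pathlib import Path
    from .pxrd import write_pattern
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_molecule_file(bundle["molecule"], d / "molecule.txt")
    write_pattern(bundle["pattern"], d / "observed.xy")
    if bundle["truth"] is not None:
        write_cif(bundle["truth"], d / "ground_truth.cif")
    spec = bundle["spec"]
    manifest = {"name": spec.name, "molecule": spec.molecule,
                "group": spec.group, "z_prime": spec.z_prime,
                "supply_cell": spec.supply_cell,
                "wavelength": spec.pattern.wavelength,
                "truth_energy": bundle.get("truth_energy")}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
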