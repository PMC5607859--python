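"""Duplicate detection and structure identity checks.

Two complementary tools:

* :func:`rdf_fingerprint` — cheap radial-distribution-function
  fingerprints (per element pair, Gaussian-smeared, cell-normalized) used
  to cluster search output and discard duplicates.
* :func:`cluster_rmsd` — a COMPACK-style identity test: build an
  N-molecule cluster around a central molecule in each structure, find a
  molecular correspondence, and superimpose the matched heavy atoms
  (quaternion-free Kabsch).  Two packings are "the same structure" when
  the cluster RMSD is below 0.3 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal_core import CrystalStructure, ExpandedCrystal, UnitCell

__all__ = [
    "RdfFingerprint", "ClusterMatch", "rdf_fingerprint",
    "fingerprint_distance", "is_duplicate", "cluster_rmsd", "deduplicate",
    "kabsch_rmsd",
]

RMSD_DUPLICATE = 0.3   # A, the validation bar for identity
FP_THRESHOLD = 0.05    # L2 distance on unit-normalized fingerprints


def _expand(structure) -> ExpandedCrystal:
    if isinstance(structure, CrystalStructure):
        return structure.expand(check_overlap=False)
    return structure


@dataclass(frozen=True)
class RdfFingerprint:
    """Smeared interatomic-distance histograms per element pair."""

    pairs: tuple            # sorted element-pair labels, e.g. ("C|O", ...)
    grid: np.ndarray        # distance grid, A
    values: np.ndarray      # (n_pairs, n_grid), per-molecule normalized

    def vector(self) -> np.ndarray:
        v = self.values.ravel()
        n = np.linalg.norm(v)
        return v / n if n > 0 else v


def rdf_fingerprint(structure, cutoff: float = 7.0,
                    tolerance: float = 0.25) -> RdfFingerprint:
    """Intermolecular radial distribution fingerprint.

    Distances up to ``cutoff`` between atoms of distinct molecules
    (periodic images included) are accumulated per unordered element
    pair and smeared with a Gaussian of width ``tolerance``; the result
    is normalized per molecule, which makes it invariant under supercell
    expansion.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ex = _expand(structure)
    X = np.concatenate(ex.mol_coords, axis=0)
    n_at = ex.molecule.n_atoms
    n_mol = ex.n_molecules
    mol_id = np.repeat(np.arange(n_mol), n_at)
    elements = np.array(list(ex.molecule.elements) * n_mol)
    A = ex.cell.matrix
    # all shifts whose image sphere can reach the cutoff
    span = float(np.linalg.norm(
        ex.molecule.centered_coords(), axis=1).max())
    Ainv = np.linalg.inv(A)
    widths = 1.0 / np.linalg.norm(Ainv, axis=1)
    nmax = np.ceil((cutoff + 2 * span) / widths).astype(int)
    grids = np.meshgrid(*(np.arange(-n, n + 1) for n in nmax),
                        indexing="ij")
    shifts = (np.stack([g.ravel() for g in grids], axis=1).astype(float)
              @ A.T)

    uniq = sorted(set(ex.molecule.elements))
    pair_labels = []
    for i, e1 in enumerate(uniq):
        for e2 in uniq[i:]:
            pair_labels.append(f"{e1}|{e2}")
    pair_index = {lbl: i for i, lbl in enumerate(pair_labels)}

    step = tolerance / 5.0
    grid = np.arange(0.0, cutoff + step, step)
    values = np.zeros((len(pair_labels), len(grid)))

    M = len(X)
    ii, jj = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    base = X[ii] - X[jj]
    chunk = max(1, int(4e6 // max(len(base), 1)))
    dists_by_pair = [[] for _ in pair_labels]
    zero = np.all(np.abs(shifts) < 1e-12, axis=1)
    for s0 in range(0, len(shifts), chunk):
        sblk = shifts[s0:s0 + chunk]
        zblk = zero[s0:s0 + chunk]
        d = base[None, :, :] - sblk[:, None, :]
        r2 = np.einsum("kij,kij->ki", d, d)
        intra = (mol_id[ii] == mol_id[jj])[None, :] & zblk[:, None]
        ok = (r2 < cutoff * cutoff) & (r2 > 1e-12) & ~intra
        if not ok.any():
            continue
        kidx, pidx = np.nonzero(ok)
        r = np.sqrt(r2[kidx, pidx])
        e1 = elements[ii[pidx]]
        e2 = elements[jj[pidx]]
        swap = e1 > e2
        lo = np.where(swap, e2, e1)
        hi = np.where(swap, e1, e2)
        for lbl in pair_labels:
            a, b = lbl.split("|")
            sel = (lo == a) & (hi == b)
            if sel.any():
                dists_by_pair[pair_index[lbl]].append(r[sel])
    sigma = tolerance
    for k, chunks in enumerate(dists_by_pair):
        if not chunks:
            continue
        r = np.concatenate(chunks)
        # each ordered pair counted once per direction; normalize per mol
        g = np.exp(-0.5 * ((grid[None, :] - r[:, None]) / sigma) ** 2)
        values[k] = g.sum(axis=0) / (n_mol * sigma * np.sqrt(2 * np.pi))
    return RdfFingerprint(pairs=tuple(pair_labels), grid=grid,
                          values=values)


def fingerprint_distance(a: RdfFingerprint, b: RdfFingerprint) -> float:
    """L2 distance between unit-normalized fingerprints (0 = identical
    shape; at most sqrt(2) for nonnegative histograms)."""
    return float(np.linalg.norm(a.vector() - b.vector()))


# --------------------------------------------------------------------------
# cluster RMSD

@dataclass(frozen=True)
class ClusterMatch:
    rmsd: float
    n_matched: int
    correspondence: tuple  # pairs (index in cluster a, index in cluster b)


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray, allow_inversion=False):
    """Optimal-superposition RMSD of two centered point sets; returns
    (rmsd, rotation) with rotation applied to P."""
    best = None
    for flip in ([1.0, -1.0] if allow_inversion else [1.0]):
        Pf = P * flip
        H = Pf.T @ Q
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
        diff = (R @ Pf.T).T - Q
        rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
        if best is None or rmsd < best[0]:
            best = (rmsd, R, flip)
    return best


def _build_cluster(ex: ExpandedCrystal, n: int, center_index: int,
                   margin: float = 0.0):
    """Cluster of the n molecules nearest (by centroid) to the chosen
    central molecule, built from a replicated supercell; with a
    positive ``margin`` every molecule within (n-th radius + margin) is
    included, so radius ties at the cluster boundary cannot exclude a
    correspondence partner.  Coordinates are relative to the central
    centroid."""
    z = ex.n_molecules
    rep = 1
    while (2 * rep + 1) ** 3 * z < 3 * n:
        rep += 1
    A = ex.cell.matrix
    blocks = []
    cents = []
    for i in range(-rep, rep + 1):
        for j in range(-rep, rep + 1):
            for k in range(-rep, rep + 1):
                shift = A @ np.array([i, j, k], dtype=float)
                for m, c in enumerate(ex.mol_coords):
                    blocks.append(c + shift)
                    cents.append(c.mean(axis=0) + shift)
                    if (i, j, k) == (0, 0, 0) and m == center_index:
                        center = len(blocks) - 1
    cents = np.array(cents)
    d = np.linalg.norm(cents - cents[center], axis=1)
    order = np.argsort(d, kind="stable")
    if len(order) < n:
        raise ValueError(f"fewer than {n} molecules reachable")
    r_n = d[order[n - 1]]
    keep = order[d[order] <= r_n + margin] if margin > 0 else order[:n]
    origin = cents[center]
    return [blocks[i] - origin for i in keep], cents[keep] - origin


def cluster_rmsd(a, b, n: int = 20, allow_inversion: bool = True,
                 max_rmsd: float = 1.5):
    """COMPACK-style comparison: minimal RMSD of optimally superimposed
    n-molecule clusters over choices of central molecule.

    Returns a :class:`ClusterMatch`, or ``None`` if no molecular
    correspondence within tolerance exists (the structures are then
    definitely different packings at the ``max_rmsd`` level).
    Hydrogens are excluded from the superposition.
    """
    ea, eb = _expand(a), _expand(b)
    if ea.molecule.n_atoms != eb.molecule.n_atoms:
        raise ValueError("structures must contain the same molecule")
    heavy = np.array([el != "H" for el in ea.molecule.elements])
    if not heavy.any():
        heavy = np.ones(ea.molecule.n_atoms, dtype=bool)
    best = None
    for ca in range(min(ea.n_molecules, 4)):
        blocks_a, cents_a = _build_cluster(ea, n, ca)
        for cb in range(min(eb.n_molecules, 4)):
            blocks_b, cents_b = _build_cluster(eb, n, cb, margin=0.5)
            m = _match_clusters(blocks_a, cents_a, blocks_b, cents_b,
                                heavy, allow_inversion,
                                elements=ea.molecule.elements)
            if m is not None and (best is None or m.rmsd < best.rmsd):
                best = m
    if best is not None and best.rmsd > max_rmsd:
        return None
    return best


def _frame(d1, v2):
    """Right-handed orthonormal frame with e1 along d1 and e2 toward
    v2's component orthogonal to d1; None if degenerate."""
    n1 = np.linalg.norm(d1)
    if n1 < 1e-9:
        return None
    e1 = d1 / n1
    w = v2 - np.dot(v2, e1) * e1
    n2 = np.linalg.norm(w)
    if n2 < 1e-6:
        return None
    e2 = w / n2
    return np.column_stack([e1, e2, np.cross(e1, e2)])


def _initial_rotations(pa, pb, cents_a, cents_b, allow_inversion):
    """Candidate (rotation, flip) pairs aligning cluster a onto cluster
    b: the Kabsch superposition of the central molecules, plus frame
    candidates built from a chemically defined molecular axis (offset of
    the farthest-from-centroid atom) and nearby molecule centroids —
    the latter resolve the rotation left free by (near-)linear or
    symmetric central molecules."""
    cands = []
    flips = [1.0, -1.0] if allow_inversion else [1.0]
    ia = int(np.argmax(np.linalg.norm(pa - pa.mean(axis=0), axis=1)))
    axis_a = pa[ia] - pa.mean(axis=0)
    axis_b = pb[ia] - pb.mean(axis=0)
    order_a = np.argsort(np.linalg.norm(cents_a, axis=1), kind="stable")
    order_b = np.argsort(np.linalg.norm(cents_b, axis=1), kind="stable")
    nbr_a = [cents_a[i] for i in order_a
             if np.linalg.norm(cents_a[i]) > 1e-6][:2]
    nbr_b = [cents_b[i] for i in order_b
             if np.linalg.norm(cents_b[i]) > 1e-6][:5]
    for flip in flips:
        P = pa * flip
        H = P.T @ pb
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        cands.append((R, flip))
        for va in nbr_a:
            Fa = _frame(axis_a * flip, va * flip)
            if Fa is None:
                continue
            for vb in nbr_b:
                Fb = _frame(axis_b, vb)
                if Fb is None:
                    continue
                cands.append((Fb @ Fa.T, flip))
    return cands


def _atom_correspondence(P, Q, elements):
    """Element-restricted optimal atom assignment between two aligned
    molecule blocks (handles molecular-symmetry index permutations).
    Returns the index array ``perm`` with Q[perm] matched to P."""
    from scipy.optimize import linear_sum_assignment
    perm = np.arange(len(P))
    els = np.asarray(elements)
    for e in np.unique(els):
        idx = np.where(els == e)[0]
        if len(idx) == 1:
            continue
        cost = np.linalg.norm(P[idx][:, None, :] - Q[idx][None, :, :],
                              axis=2)
        r, c = linear_sum_assignment(cost)
        perm[idx[r]] = idx[c]
    return perm


def _match_clusters(blocks_a, cents_a, blocks_b, cents_b, heavy,
                    allow_inversion, elements=None):
    n = len(blocks_a)
    pa = blocks_a[0][heavy] if heavy.sum() >= 2 else blocks_a[0]
    pb = blocks_b[0][heavy] if heavy.sum() >= 2 else blocks_b[0]
    heavy_el = None if elements is None else \
        np.asarray(elements)[heavy if heavy.sum() >= 2
                             else slice(None)]
    best = None
    for R0, flip in _initial_rotations(pa, pb, cents_a, cents_b,
                                       allow_inversion):
        R = R0
        match = None
        for _ in range(3):  # assignment / superposition refinement
            ca = (R @ (cents_a * flip).T).T
            used = np.zeros(len(cents_b), dtype=bool)
            pairs = []
            ok = True
            order = np.argsort(np.linalg.norm(cents_a, axis=1),
                               kind="stable")
            for ia in order:
                d = np.linalg.norm(cents_b - ca[ia], axis=1)
                d[used] = np.inf
                ib = int(np.argmin(d))
                tol = max(0.25 * np.linalg.norm(cents_a[ia]), 1.0)
                if d[ib] > tol:
                    ok = False
                    break
                used[ib] = True
                pairs.append((int(ia), ib))
            if not ok:
                match = None
                break
            P = np.concatenate([blocks_a[ia][heavy] * flip
                                for ia, _ in pairs])
            Qb = []
            for ia, ib in pairs:
                qa = (R @ (blocks_a[ia][heavy] * flip).T).T
                qb = blocks_b[ib][heavy]
                if heavy_el is not None and len(qb) > 1:
                    perm = _atom_correspondence(qa, qb, heavy_el)
                    qb = qb[perm]
                Qb.append(qb)
            Q = np.concatenate(Qb)
            rmsd, R, _ = kabsch_rmsd(P, Q, allow_inversion=False)
            match = ClusterMatch(rmsd=rmsd, n_matched=n,
                                 correspondence=tuple(pairs))
        if match is not None and (best is None or match.rmsd < best.rmsd):
            best = match
    return best


def is_duplicate(a, b, fp_threshold: float = FP_THRESHOLD,
                 rmsd_threshold: float = RMSD_DUPLICATE,
                 n_cluster: int = 12, cutoff: float = 7.0,
                 tolerance: float = 0.25) -> bool:
    """Two-stage duplicate test: RDF fingerprint distance below the
    threshold, confirmed by cluster RMSD below 0.3 A.  Symmetric and
    reflexive."""
    fa = rdf_fingerprint(a, cutoff=cutoff, tolerance=tolerance)
    fb = rdf_fingerprint(b, cutoff=cutoff, tolerance=tolerance)
    if fingerprint_distance(fa, fb) > fp_threshold:
        return False
    m = cluster_rmsd(a, b, n=n_cluster)
    return m is not None and m.rmsd < rmsd_threshold


def deduplicate(structures, n_cluster: int = 12,
                fp_threshold: float = FP_THRESHOLD,
                rmsd_threshold: float = RMSD_DUPLICATE):
    """Union-find clustering of a structure list under
    :func:`is_duplicate`; returns (representative indices, cluster label
    per structure).  Fingerprints are computed once per structure."""
    m = len(structures)
    fps = [rdf_fingerprint(s) for s in structures]
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            if find(i) == find(j):
                continue
            if fingerprint_distance(fps[i], fps[j]) > fp_threshold:
                continue
            match = cluster_rmsd(structures[i], structures[j], n=n_cluster)
            if match is not None and match.rmsd < rmsd_threshold:
                parent[find(j)] = find(i)
    labels = [find(i) for i in range(m)]
    reps = sorted(set(labels))
    return reps, labels
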