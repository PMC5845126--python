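"""Conformer generation, preserved-space alignment, receptor scoring, and
group efficiency.

The scorer is a deliberately simple, deterministic stand-in for external
docking energies:

    E = w_hb * sum g(d)  +  w_ph * sum h(d)  +  w_cl * sum clash(d)

over ligand-receptor atom pairs, where ``g`` is a piecewise-linear
hydrogen-bond well (-1 on d in [2.6, 3.2] A, rising to 0 at 2.2 and 4.0 A)
between donor/acceptor pairs, ``h`` is a hydrophobic well for carbon-carbon
pairs (-1 up to 4.5 A, 0 beyond 5.5 A, linear in between; short range is
handled by the clash term), and clash adds +5 per heavy-atom pair closer
than 0.8x the summed van der Waals radii.  More negative is better.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .chem_core import RxngrowError, vdw_radius
from .block_library import PreservedFragment


class ConformerError(RxngrowError):
    """3D embedding failed for a molecule."""


class ScoringError(RxngrowError):
    """A pose is missing coordinates."""


class DegenerateGrowthError(RxngrowError):
    """Group efficiency is undefined when no heavy atoms were added."""


DEFAULT_CONFORMER_SEED = 2024
DEFAULT_N_CONFORMERS = 30


@dataclass(frozen=True)
class ScoreWeights:
    hbond: float = 1.0
    hydrophobic: float = 0.2
    clash: float = 1.0


@dataclass
class Receptor:
    """Receptor atoms plus typed interaction sites (atom index lists)."""

    elements: list[str]
    coords: np.ndarray
    donors: tuple[int, ...] = ()
    acceptors: tuple[int, ...] = ()
    hydrophobic: tuple[int, ...] = ()
    residues: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("receptor coordinates must be finite")
        n = len(self.elements)
        for idxs in (self.donors, self.acceptors, self.hydrophobic):
            if any(i < 0 or i >= n for i in idxs):
                raise ValueError("typed site references a missing atom")

    def to_json(self) -> str:
        return json.dumps(
            {
                "elements": list(self.elements),
                "coords": self.coords.tolist(),
                "donors": list(self.donors),
                "acceptors": list(self.acceptors),
                "hydrophobic": list(self.hydrophobic),
                "residues": list(self.residues),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Receptor":
        d = json.loads(text)
        return cls(
            elements=d["elements"],
            coords=np.array(d["coords"], dtype=float),
            donors=tuple(d.get("donors", ())),
            acceptors=tuple(d.get("acceptors", ())),
            hydrophobic=tuple(d.get("hydrophobic", ())),
            residues=d.get("residues", []),
        )

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Receptor":
        """Read ATOM records; type sites by element (N -> donor, O -> acceptor,
        C -> hydrophobic) -- a deliberately coarse convention."""
        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("receptor", str(path))
        elements, coords, residues = [], [], []
        for atom in structure.get_atoms():
            el = (atom.element or atom.get_name()[0]).strip().capitalize()
            if el == "H":
                continue
            elements.append(el)
            coords.append(atom.get_coord())
            parent = atom.get_parent()
            residues.append(f"{parent.get_resname()}{parent.get_id()[1]}")
        donors = tuple(i for i, e in enumerate(elements) if e == "N")
        acceptors = tuple(i for i, e in enumerate(elements) if e == "O")
        hydrophobic = tuple(i for i, e in enumerate(elements) if e == "C")
        return cls(
            elements=elements,
            coords=np.array(coords, dtype=float),
            donors=donors,
            acceptors=acceptors,
            hydrophobic=hydrophobic,
            residues=residues,
        )


@dataclass(frozen=True)
class InteractionTarget:
    """A receptor site the grown ligand must reach; ``kind`` names the ligand
    atom class expected near the anchor."""

    id: str
    anchor: np.ndarray
    kind: str  # hbond-donor | hbond-acceptor | hydrophobic | aromatic
    satisfied_radius: float

    def __post_init__(self):
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        if self.satisfied_radius <= 0:
            raise ValueError("satisfied_radius must be positive")


@dataclass
class ScoredPose:
    coords: np.ndarray
    alignment_overlap: float
    energy: float
    new_moiety_atoms: frozenset[int]
    group_efficiency: float | None = None


# ---------------------------------------------------------------------------
# ligand atom typing (shared by scorer and direction check)


def ligand_donors(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs() >= 1
    ]


def ligand_acceptors(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)]


def ligand_carbons(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]


def atom_compatible(mol: Chem.Mol, idx: int, kind: str) -> bool:
    atom = mol.GetAtomWithIdx(idx)
    if kind == "hbond-donor":
        return atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() >= 1
    if kind == "hbond-acceptor":
        return atom.GetAtomicNum() in (7, 8)
    if kind == "hydrophobic":
        return atom.GetAtomicNum() == 6
    if kind == "aromatic":
        return atom.GetIsAromatic()
    raise ValueError(f"unknown target kind {kind!r}")


# ---------------------------------------------------------------------------
# conformers


def generate_conformers(
    mol: Chem.Mol,
    k: int = DEFAULT_N_CONFORMERS,
    seed: int = DEFAULT_CONFORMER_SEED,
    inherited_coords: dict[int, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Up to ``k`` ETKDG conformers (heavy-atom coordinates), deterministic
    under ``seed``.  When >= 3 inherited coordinates are available each
    conformer is rigidly moved to start near the inherited pose."""
    if k < 1:
        raise ValueError("k must be >= 1")
    molh = Chem.AddHs(Chem.Mol(mol))
    conf_ids = []
    if inherited_coords and len(inherited_coords) >= 3:
        # soft positional restraints bias the ensemble toward the posed part
        from rdkit.Geometry import Point3D

        cmap = {
            i: Point3D(float(x), float(y), float(z))
            for i, (x, y, z) in sorted(inherited_coords.items())
        }
        conf_ids = AllChem.EmbedMultipleConfs(
            molh, numConfs=int(k), randomSeed=int(seed), coordMap=cmap
        )
    if len(conf_ids) == 0:
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(k), params=params)
    if len(conf_ids) == 0:
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(k), params=params)
    if len(conf_ids) == 0:
        raise ConformerError(f"embedding failed for {Chem.MolToSmiles(mol)}")

    n_heavy = mol.GetNumAtoms()
    out = []
    for cid in conf_ids:
        coords = np.array(molh.GetConformer(cid).GetPositions(), dtype=float)[:n_heavy]
        if inherited_coords and len(inherited_coords) >= 3:
            idxs = sorted(inherited_coords)
            ref = np.array([inherited_coords[i] for i in idxs])
            rot, trans = kabsch(coords[idxs], ref)
            coords = coords @ rot.T + trans
        out.append(coords)
    return out


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R P + t - Q|| (no reflection)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


# ---------------------------------------------------------------------------
# Gaussian volume overlap

_GAUSS_P = 2.7
_KAPPA = np.pi * (3.0 * _GAUSS_P / (4.0 * np.pi)) ** (2.0 / 3.0)


def _alphas(elements: list[str]) -> np.ndarray:
    pt = Chem.GetPeriodicTable()
    radii = np.array([pt.GetRvdw(pt.GetAtomicNumber(e)) for e in elements])
    return _KAPPA / radii**2


def gaussian_cross_volume(
    a_coords: np.ndarray, a_alpha: np.ndarray, b_coords: np.ndarray, b_alpha: np.ndarray
) -> float:
    """First-order Gaussian-sphere shared volume between two atom sets."""
    d2 = cdist(a_coords, b_coords) ** 2
    asum = a_alpha[:, None] + b_alpha[None, :]
    prod = a_alpha[:, None] * b_alpha[None, :]
    terms = _GAUSS_P**2 * (np.pi / asum) ** 1.5 * np.exp(-prod / asum * d2)
    return float(terms.sum())


def align_to_preserved(
    mol: Chem.Mol,
    coords: np.ndarray,
    frag: PreservedFragment,
) -> tuple[np.ndarray, float]:
    """Rigid-body transform of the conformer maximizing Gaussian-volume
    overlap between its preserved-fragment atoms and the reference pose.

    Returns (aligned coordinates, shared volume / fragment volume).  Internal
    geometry is untouched.  Raises :class:`RxngrowError` if the fragment is
    not contained in the molecule.
    """
    embeddings = frag.embeddings(mol)
    if not embeddings:
        raise RxngrowError("preserved fragment not found in molecule")

    frag_elements = [a.GetSymbol() for a in frag.pattern.GetAtoms()]
    frag_alpha = _alphas(frag_elements)
    ref = np.asarray(frag.reference_coords, dtype=float)
    v_ref = gaussian_cross_volume(ref, frag_alpha, ref, frag_alpha)

    best: tuple[float, np.ndarray] | None = None
    for emb in embeddings:
        pat_idx = sorted(emb)
        mol_idx = [emb[p] for p in pat_idx]
        sub_alpha = np.array([frag_alpha[p] for p in pat_idx])
        rot, trans = kabsch(coords[mol_idx], ref[pat_idx])
        moved = coords @ rot.T + trans

        # local refinement of the 6-parameter rigid transform
        center = moved[mol_idx].mean(axis=0)

        def neg_overlap(x, moved=moved, mol_idx=mol_idx, sub_alpha=sub_alpha,
                        pat_idx=pat_idx, center=center):
            r = Rotation.from_rotvec(x[:3]).as_matrix()
            pts = (moved[mol_idx] - center) @ r.T + center + x[3:]
            return -gaussian_cross_volume(pts, sub_alpha, ref[pat_idx], frag_alpha[pat_idx])

        res = minimize(neg_overlap, np.zeros(6), method="Powell",
                       options={"maxiter": 200, "xtol": 1e-4, "ftol": 1e-8})
        r = Rotation.from_rotvec(res.x[:3]).as_matrix()
        aligned = (moved - center) @ r.T + center + res.x[3:]
        v_cross = -float(res.fun)
        overlap = min(1.0, max(0.0, v_cross / v_ref))
        if best is None or overlap > best[0]:
            best = (overlap, aligned)

    return best[1], best[0]


# ---------------------------------------------------------------------------
# scoring


def _hbond_well(d: np.ndarray) -> np.ndarray:
    """Piecewise-linear well: 0 below 2.2, -1 on [2.6, 3.2], 0 above 4.0."""
    out = np.zeros_like(d)
    rise = (d >= 2.2) & (d < 2.6)
    out[rise] = -(d[rise] - 2.2) / 0.4
    out[(d >= 2.6) & (d <= 3.2)] = -1.0
    fall = (d > 3.2) & (d < 4.0)
    out[fall] = -(4.0 - d[fall]) / 0.8
    return out


def _hydrophobic_well(d: np.ndarray) -> np.ndarray:
    """-1 up to 4.5 A, 0 beyond 5.5 A, linear in between."""
    out = np.zeros_like(d)
    out[d <= 4.5] = -1.0
    mid = (d > 4.5) & (d < 5.5)
    out[mid] = -(5.5 - d[mid])
    return out


def score_pose(
    mol: Chem.Mol,
    coords: np.ndarray,
    receptor: Receptor,
    weights: ScoreWeights = ScoreWeights(),
) -> float:
    """Deterministic interaction energy of a ligand pose (more negative is
    better); see the module docstring for the functional form."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3) or not np.all(np.isfinite(coords)):
        raise ScoringError("pose is missing coordinates")

    energy = 0.0
    don = ligand_donors(mol)
    acc = ligand_acceptors(mol)
    carb = ligand_carbons(mol)

    for lig_idx, rec_idx in ((don, receptor.acceptors), (acc, receptor.donors)):
        if lig_idx and rec_idx:
            d = cdist(coords[lig_idx], receptor.coords[list(rec_idx)])
            energy += weights.hbond * _hbond_well(d).sum()

    if carb and receptor.hydrophobic:
        d = cdist(coords[carb], receptor.coords[list(receptor.hydrophobic)])
        energy += weights.hydrophobic * _hydrophobic_well(d).sum()

    lig_r = np.array([vdw_radius(a.GetAtomicNum()) for a in mol.GetAtoms()])
    pt = Chem.GetPeriodicTable()
    rec_r = np.array([pt.GetRvdw(pt.GetAtomicNumber(e)) for e in receptor.elements])
    d = cdist(coords, receptor.coords)
    clash = d < 0.8 * (lig_r[:, None] + rec_r[None, :])
    energy += weights.clash * 5.0 * int(clash.sum())

    return float(energy)


def check_direction(
    mol: Chem.Mol,
    coords: np.ndarray,
    new_atoms: frozenset[int] | set[int],
    target: InteractionTarget,
    previous_best_distance: float,
) -> bool:
    """True iff the new moiety moved strictly toward the target anchor and
    its nearest new atom is type-compatible with the target."""
    if not new_atoms:
        raise ValueError("new_atoms must be nonempty")
    idxs = sorted(new_atoms)
    dists = np.linalg.norm(coords[idxs] - target.anchor, axis=1)
    nearest = idxs[int(np.argmin(dists))]
    if float(dists.min()) >= previous_best_distance:
        return False
    return atom_compatible(mol, nearest, target.kind)


def group_efficiency(
    e_new: float, e_prev: float, n_new: int, n_prev: int
) -> float:
    """Incremental binding energy per added heavy atom."""
    if n_new <= n_prev:
        raise DegenerateGrowthError(
            f"no heavy atoms added (n {n_prev} -> {n_new})"
        )
    return (e_new - e_prev) / (n_new - n_prev)


# ---------------------------------------------------------------------------
# local pose refinement (used by candidate ranking)


def _rotatable_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() > 1 and b.GetDegree() > 1:
            out.append((a.GetIdx(), b.GetIdx()))
    return out


def _side_atoms(mol: Chem.Mol, a: int, b: int) -> list[int]:
    """Atoms on the b side of bond a-b (excluding a's component)."""
    seen = {a, b}
    stack = [b]
    while stack:
        cur = stack.pop()
        for nbr in mol.GetAtomWithIdx(cur).GetNeighbors():
            i = nbr.GetIdx()
            if i not in seen:
                seen.add(i)
                stack.append(i)
    seen.discard(a)
    return sorted(seen)


def refine_pose(
    mol: Chem.Mol,
    coords: np.ndarray,
    receptor: Receptor,
    weights: ScoreWeights = ScoreWeights(),
    n_sweeps: int = 8,
    use_rigid: bool = True,
    frozen: frozenset[int] | set[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Greedy rigid-body + torsion coordinate descent on the scorer.

    Deterministic; only improving moves are accepted, so the returned energy
    never exceeds the input energy.  With ``use_rigid=False`` only torsions
    are explored, and torsion moves that would displace an atom in ``frozen``
    are skipped (used during growth to keep the preserved fragment on the
    reference pose).
    """
    coords = np.array(coords, dtype=float)
    energy = score_pose(mol, coords, receptor, weights)
    frozen = frozenset(frozen or ())
    torsions = _rotatable_bonds(mol)
    moves: list[tuple[int, int, tuple[int, ...]]] = []
    for (a, b) in torsions:
        for pivot, other in ((a, b), (b, a)):
            side = tuple(_side_atoms(mol, pivot, other))
            if side and not frozen.intersection(side):
                moves.append((pivot, other, side))

    trans_step, rot_step, tors_step = 0.25, np.deg2rad(5.0), np.deg2rad(10.0)
    for _ in range(n_sweeps):
        improved = False
        if use_rigid:
            for axis in range(3):
                for sign in (1.0, -1.0):
                    cand = coords.copy()
                    cand[:, axis] += sign * trans_step
                    e = score_pose(mol, cand, receptor, weights)
                    if e < energy - 1e-12:
                        coords, energy, improved = cand, e, True
            centroid = coords.mean(axis=0)
            for axis in range(3):
                for sign in (1.0, -1.0):
                    vec = np.zeros(3)
                    vec[axis] = sign * rot_step
                    r = Rotation.from_rotvec(vec).as_matrix()
                    cand = (coords - centroid) @ r.T + centroid
                    e = score_pose(mol, cand, receptor, weights)
                    if e < energy - 1e-12:
                        coords, energy, improved = cand, e, True
        for (pivot, other, moving) in moves:
            axis_vec = coords[other] - coords[pivot]
            norm = np.linalg.norm(axis_vec)
            if norm < 1e-9:
                continue
            axis_vec = axis_vec / norm
            for sign in (1.0, -1.0):
                r = Rotation.from_rotvec(sign * tors_step * axis_vec).as_matrix()
                cand = coords.copy()
                midx = list(moving)
                cand[midx] = (cand[midx] - coords[pivot]) @ r.T + coords[pivot]
                e = score_pose(mol, cand, receptor, weights)
                if e < energy - 1e-12:
                    coords, energy, improved = cand, e, True
        if not improved:
            trans_step *= 0.5
            rot_step *= 0.5
            tors_step *= 0.5
            if tors_step < np.deg2rad(1.0):
                break
    return coords, energy
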