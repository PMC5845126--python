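"""Molecular-graph data model, descriptors, and standard-format I/O.

Molecules are RDKit ``Mol`` objects throughout the package; this module pins
the conventions every other stage relies on:

- implicit hydrogens are the default representation;
- aromaticity is perceived at parse time with RDKit's default model, and
  patterns are matched under that same model;
- stereochemistry is parsed but ignored by matching and assembly;
- cLogP is the Crippen atom-contribution method shipped with RDKit (the
  parameter table is pinned by the rdkit version in ``pyproject.toml``).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors as _rd_descriptors

RDLogger.DisableLog("rdApp.*")


class RxngrowError(Exception):
    """Base class for package errors."""


class FormatError(RxngrowError):
    """Input text could not be parsed in the declared format."""


class ChemistryError(RxngrowError):
    """A molecule violates valence or sanitization rules."""


@dataclass(frozen=True)
class MolDescriptors:
    molecular_weight: float
    heavy_atom_count: int
    clogp: float


def parse_molecule(text: str, fmt: str = "smiles") -> Chem.Mol:
    """Parse SMILES or an MDL MOL block into a sanitized molecule.

    Atom-map numbers are preserved.  Raises :class:`FormatError` on syntax
    problems and :class:`ChemistryError` on valence violations.
    """
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text, sanitize=False)
        if mol is None:
            raise FormatError(f"unparseable SMILES: {text!r}")
    elif fmt == "mol":
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if mol is None:
            raise FormatError("unparseable MOL block")
        mol = Chem.RemoveHs(mol, sanitize=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return sanitize(mol)


def sanitize(mol: Chem.Mol) -> Chem.Mol:
    """Run RDKit sanitization, translating failures to :class:`ChemistryError`."""
    try:
        Chem.SanitizeMol(mol)
    except (Chem.AtomValenceException, Chem.KekulizeException) as exc:
        raise ChemistryError(str(exc)) from exc
    except Exception as exc:  # other sanitization failures
        raise ChemistryError(str(exc)) from exc
    return mol


def strip_maps(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def canonical_key(mol: Chem.Mol) -> str:
    """Canonical identity key: equal iff the molecular graphs are isomorphic.

    Atom maps and stereochemistry are ignored.
    """
    out = strip_maps(mol)
    Chem.RemoveStereochemistry(out)
    return Chem.MolToSmiles(out, canonical=True)


def compute_descriptors(mol: Chem.Mol) -> MolDescriptors:
    """Molecular weight (incl. implicit H), heavy-atom count, Crippen cLogP."""
    return MolDescriptors(
        molecular_weight=_rd_descriptors.MolWt(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        clogp=Crippen.MolLogP(mol),
    )


def is_sp3_carbon(atom: Chem.Atom) -> bool:
    """Carbon, not aromatic, no multiple bonds -- the moiety stop criterion."""
    if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
        return False
    return all(b.GetBondType() == Chem.BondType.SINGLE for b in atom.GetBonds())


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def bond_order(bond: Chem.Bond) -> float:
    """Numeric bond order; aromatic bonds are their own class (1.5)."""
    try:
        return _BOND_ORDER[bond.GetBondType()]
    except KeyError as exc:
        raise ChemistryError(f"unsupported bond type {bond.GetBondType()}") from exc


def mol_to_nx(mol: Chem.Mol) -> nx.Graph:
    """Undirected attribute graph used by the substructure matcher.

    Node attributes: element, charge, aromatic, n_h (total hydrogens),
    degree (heavy neighbors), sp3c.  Edge attribute: order.
    """
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetAtomicNum(),
            charge=atom.GetFormalCharge(),
            aromatic=atom.GetIsAromatic(),
            n_h=atom.GetTotalNumHs(),
            degree=atom.GetDegree(),
            sp3c=is_sp3_carbon(atom),
        )
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=bond_order(bond))
    return g


def map_numbers(mol: Chem.Mol) -> dict[int, int]:
    """atom index -> atom-map number, for mapped atoms only."""
    return {
        a.GetIdx(): a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0
    }


def get_coords(mol: Chem.Mol, conf_id: int = -1) -> np.ndarray:
    conf = mol.GetConformer(conf_id)
    return np.array(conf.GetPositions(), dtype=float)


def set_coords(mol: Chem.Mol, coords: np.ndarray, conf_id: int = -1) -> None:
    conf = mol.GetConformer(conf_id)
    for i, xyz in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, [float(xyz[0]), float(xyz[1]), float(xyz[2])])


def mol_to_molblock(mol: Chem.Mol, coords: np.ndarray | None = None) -> str:
    """V2000 MOL block; attaches ``coords`` as the (single) conformer if given."""
    out = Chem.Mol(mol)
    if coords is not None:
        out.RemoveAllConformers()
        conf = Chem.Conformer(out.GetNumAtoms())
        for i, xyz in enumerate(np.asarray(coords, dtype=float)):
            conf.SetAtomPosition(i, [float(xyz[0]), float(xyz[1]), float(xyz[2])])
        out.AddConformer(conf, assignId=True)
    return Chem.MolToMolBlock(out, kekulize=True)


# van der Waals radii (A) for the clash term; RDKit's periodic table values.
_PT = Chem.GetPeriodicTable()


def vdw_radius(atomic_num: int) -> float:
    return _PT.GetRvdw(atomic_num)
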