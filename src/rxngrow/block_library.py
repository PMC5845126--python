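"""Building-block storage plus seed / participant lookup.

Seed identification is 2D: a block is a seed candidate when it contains the
preserved fragment's graph as a substructure (3D compliance is enforced later
by alignment onto the fragment's reference pose).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_core import RxngrowError, mol_to_nx, parse_molecule
from .rule_extraction import ReactionRule, RuleDB, match_graphs


class IndexError_(RxngrowError):
    """The rule database has no block index for the requested rule."""


@dataclass(frozen=True)
class BuildingBlock:
    id: str
    mol: Chem.Mol
    provenance: str = ""


@dataclass(frozen=True)
class PreservedFragment:
    """User-designated substructure of the query ligand plus its 3D pose.

    ``pattern`` is matched permissively (element / charge / aromaticity on
    atoms, order on bonds; substitution allowed everywhere), so the fragment
    stays contained as the molecule grows.
    """

    pattern: Chem.Mol
    reference_coords: np.ndarray

    def __post_init__(self):
        if self.pattern.GetNumAtoms() != len(self.reference_coords):
            raise ValueError("reference_coords length must equal pattern atom count")

    def embeddings(self, mol: Chem.Mol) -> list[dict[int, int]]:
        """Containment matches on element / charge / aromaticity and bond
        order only; substitution (and hybridization change) allowed at every
        atom so the fragment stays found as the molecule grows."""
        pat_g = mol_to_nx(self.pattern)
        for n in pat_g.nodes:
            pat_g.nodes[n]["relaxed"] = True
            pat_g.nodes[n]["enforce_sp3"] = False
        return match_graphs(pat_g, mol_to_nx(mol))


def load_library(path: str | Path) -> list[BuildingBlock]:
    """Read blocks from a SMILES file (``smiles<TAB>id`` per line) or SDF."""
    path = Path(path)
    blocks: list[BuildingBlock] = []
    if path.suffix.lower() == ".sdf":
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                continue
            bid = mol.GetProp("_Name") or f"block-{i}"
            blocks.append(BuildingBlock(id=bid, mol=mol, provenance=str(path)))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            bid = parts[1] if len(parts) > 1 else f"block-{i}"
            blocks.append(
                BuildingBlock(id=bid, mol=parse_molecule(smiles), provenance=str(path))
            )
    _check_unique_ids(blocks)
    return blocks


def write_library(blocks: list[BuildingBlock], path: str | Path) -> None:
    lines = [f"{Chem.MolToSmiles(b.mol)}\t{b.id}" for b in blocks]
    Path(path).write_text("\n".join(lines) + "\n")


def _check_unique_ids(blocks: list[BuildingBlock]) -> None:
    seen = set()
    for b in blocks:
        if b.id in seen:
            raise RxngrowError(f"duplicate building-block id {b.id!r}")
        seen.add(b.id)


def find_seed_blocks(
    frag: PreservedFragment, library: list[BuildingBlock]
) -> list[BuildingBlock]:
    """Blocks containing the preserved fragment, smallest first."""
    hits = [b for b in library if frag.embeddings(b.mol)]
    return sorted(hits, key=lambda b: (b.mol.GetNumHeavyAtoms(), b.id))


def participants_for_slot(
    rule: ReactionRule, rule_id: int, slot: int, db: RuleDB, library: list[BuildingBlock]
) -> list[BuildingBlock]:
    """Indexed building blocks matching the given reactant-moiety slot."""
    if (rule_id, slot) not in db.block_index:
        raise IndexError_(f"no block index for rule {rule_id} slot {slot}")
    by_id = {b.id: b for b in library}
    return [by_id[i] for i in db.block_index[(rule_id, slot)] if i in by_id]
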