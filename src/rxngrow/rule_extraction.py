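"""Turn atom-mapped reactions into reusable reaction rules.

A rule is extracted in two stages: (1) the *reaction core* -- atoms whose
tracked attributes (element, charge, aromaticity, heavy-neighbor count, or
the multiset of bonds to mapped partners) change between the two sides of a
mapped reaction; (2) *moiety extension* -- the core is grown outward
breadth-first until each growth direction hits an sp3 carbon (included, and
eligible for substitution when the rule is later matched) or enters an
aromatic ring (the whole aromatic system is included).  The reactant
moieties, the principal-product moiety and their map-number correspondence
form the :class:`ReactionRule` applied by virtual synthesis.
"""

from __future__ import annotations

import json
from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem

from .chem_core import (
    ChemistryError,
    RxngrowError,
    bond_order,
    is_sp3_carbon,
    map_numbers,
    mol_to_nx,
    parse_molecule,
)


class MappingError(RxngrowError):
    """Atom maps are inconsistent (duplicates within a side, or product maps
    absent from the reactant side)."""


class EmptyRuleError(RxngrowError):
    """The reaction has no core (identity reaction); no rule can be built."""


@dataclass(frozen=True)
class MappedReaction:
    """An atom-mapped multi-reactant -> multi-product transformation."""

    reactants: tuple[Chem.Mol, ...]
    products: tuple[Chem.Mol, ...]
    name: str = ""

    @classmethod
    def from_smiles(cls, rxn_smiles: str, name: str = "") -> "MappedReaction":
        try:
            lhs, rhs = rxn_smiles.split(">>")
        except ValueError as exc:
            raise MappingError(f"not a reaction SMILES: {rxn_smiles!r}") from exc
        reactants = tuple(parse_molecule(s) for s in lhs.split(".") if s)
        products = tuple(parse_molecule(s) for s in rhs.split(".") if s)
        rxn = cls(reactants=reactants, products=products, name=name)
        rxn.validate()
        return rxn

    def to_smiles(self) -> str:
        lhs = ".".join(Chem.MolToSmiles(m, canonical=False) for m in self.reactants)
        rhs = ".".join(Chem.MolToSmiles(m, canonical=False) for m in self.products)
        return f"{lhs}>>{rhs}"

    def validate(self) -> None:
        r_maps = _side_maps(self.reactants, "reactant")
        p_maps = _side_maps(self.products, "product")
        missing = set(p_maps) - set(r_maps)
        if missing:
            raise MappingError(
                f"{self.name or 'reaction'}: product maps {sorted(missing)} "
                "have no reactant partner"
            )


def _side_maps(
    mols: tuple[Chem.Mol, ...], side: str
) -> dict[int, tuple[int, int]]:
    """map number -> (molecule position, atom index); raises on duplicates."""
    out: dict[int, tuple[int, int]] = {}
    for mi, mol in enumerate(mols):
        for idx, mp in map_numbers(mol).items():
            if mp in out:
                raise MappingError(f"map {mp} appears twice on the {side} side")
            out[mp] = (mi, idx)
    return out


@dataclass(frozen=True)
class ReactionCore:
    """Per-molecule core atom sets, keyed by (side, molecule position)."""

    atoms: dict[tuple[str, int], frozenset[int]]

    def for_mol(self, side: str, pos: int) -> frozenset[int]:
        return self.atoms.get((side, pos), frozenset())


def _atom_signature(mol: Chem.Mol, idx: int) -> tuple:
    """Tracked attributes compared between mapped partners."""
    atom = mol.GetAtomWithIdx(idx)
    bonds = Counter()
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetAtomMapNum() > 0:
            bonds[(bond_order(bond), other.GetAtomMapNum())] += 1
    return (
        atom.GetAtomicNum(),
        atom.GetFormalCharge(),
        atom.GetIsAromatic(),
        atom.GetDegree(),
        frozenset(bonds.items()),
    )


def identify_reaction_core(rxn: MappedReaction) -> ReactionCore:
    """Atoms that are unmapped, lose their partner, or change a tracked
    attribute relative to their mapped partner on the other side."""
    r_maps = _side_maps(rxn.reactants, "reactant")
    p_maps = _side_maps(rxn.products, "product")

    core: dict[tuple[str, int], set[int]] = {}

    def _mark(side: str, pos: int, idx: int) -> None:
        core.setdefault((side, pos), set()).add(idx)

    for side, mols, own, other in (
        ("reactant", rxn.reactants, r_maps, p_maps),
        ("product", rxn.products, p_maps, r_maps),
    ):
        for pos, mol in enumerate(mols):
            for atom in mol.GetAtoms():
                mp = atom.GetAtomMapNum()
                if mp == 0 or mp not in other:
                    _mark(side, pos, atom.GetIdx())
                    continue
                o_pos, o_idx = other[mp]
                o_mol = rxn.products[o_pos] if side == "reactant" else rxn.reactants[o_pos]
                if _atom_signature(mol, atom.GetIdx()) != _atom_signature(o_mol, o_idx):
                    _mark(side, pos, atom.GetIdx())

    return ReactionCore(atoms={k: frozenset(v) for k, v in core.items()})


@dataclass(frozen=True)
class Moiety:
    """A connected(-per-core-component) subgraph of a source molecule.

    ``boundary`` atoms are where extension stopped (sp3 carbons or atoms of a
    fully-included aromatic system); substitution is permitted there when the
    moiety is matched as a pattern.  ``attachment_atoms`` are the boundary
    atoms that actually carry bonds out of the pattern in the source.
    """

    source: Chem.Mol
    atoms: frozenset[int]
    boundary: frozenset[int]

    @property
    def attachment_atoms(self) -> frozenset[int]:
        ext = set()
        for idx in self.atoms:
            atom = self.source.GetAtomWithIdx(idx)
            for nbr in atom.GetNeighbors():
                if nbr.GetIdx() not in self.atoms:
                    ext.add(idx)
        return frozenset(ext)

    @property
    def map_to_idx(self) -> dict[int, int]:
        return {
            self.source.GetAtomWithIdx(i).GetAtomMapNum(): i
            for i in self.atoms
            if self.source.GetAtomWithIdx(i).GetAtomMapNum() > 0
        }

    def pattern_graph(self) -> nx.Graph:
        g = mol_to_nx(self.source).subgraph(self.atoms).copy()
        for n in g.nodes:
            g.nodes[n]["relaxed"] = n in self.boundary
        return g

    def smiles(self) -> str:
        return Chem.MolFragmentToSmiles(
            self.source, atomsToUse=sorted(self.atoms), canonical=False
        )


def _aromatic_component(mol: Chem.Mol, start: int) -> set[int]:
    """Atoms reachable from ``start`` through aromatic bonds (the fused
    aromatic system)."""
    seen = {start}
    queue = deque([start])
    while queue:
        idx = queue.popleft()
        atom = mol.GetAtomWithIdx(idx)
        for bond in atom.GetBonds():
            if bond.GetBondType() == Chem.BondType.AROMATIC:
                o = bond.GetOtherAtomIdx(idx)
                if o not in seen:
                    seen.add(o)
                    queue.append(o)
    return seen


def extend_moiety(mol: Chem.Mol, core_atoms: frozenset[int]) -> Moiety:
    """Grow the core outward; stop at (and include) sp3 carbons, complete any
    aromatic ring system that is entered.  Core atoms always expand."""
    atoms: set[int] = set(core_atoms)
    boundary: set[int] = set()
    queue: deque[int] = deque()

    for idx in core_atoms:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetIsAromatic():
            ring = _aromatic_component(mol, idx)
            atoms |= ring
            boundary |= ring
        queue.append(idx)

    while queue:
        idx = queue.popleft()
        for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
            nidx = nbr.GetIdx()
            if nidx in atoms:
                continue
            if nbr.GetIsAromatic():
                ring = _aromatic_component(mol, nidx)
                atoms |= ring
                boundary |= ring
                continue
            atoms.add(nidx)
            if is_sp3_carbon(nbr):
                boundary.add(nidx)
            else:
                queue.append(nidx)

    return Moiety(source=mol, atoms=frozenset(atoms), boundary=frozenset(boundary))


def extend_to_moieties(rxn: MappedReaction, core: ReactionCore) -> dict[tuple[str, int], Moiety]:
    """One moiety per molecule with a nonempty core (both sides)."""
    out = {}
    for (side, pos), atoms in core.atoms.items():
        mol = rxn.reactants[pos] if side == "reactant" else rxn.products[pos]
        out[(side, pos)] = extend_moiety(mol, atoms)
    return out


@dataclass(frozen=True)
class ReactionRule:
    """Reactant moieties + principal-product moiety + map correspondence."""

    name: str
    reactant_moieties: tuple[Moiety, ...]
    product_moiety: Moiety

    @property
    def n_slots(self) -> int:
        return len(self.reactant_moieties)

    @property
    def product_maps(self) -> frozenset[int]:
        return frozenset(self.product_moiety.map_to_idx)

    def leaving_maps(self, slot: int) -> frozenset[int]:
        """Maps of slot-moiety atoms that do not survive into the product."""
        return frozenset(self.reactant_moieties[slot].map_to_idx) - self.product_maps


def _principal_product(rxn: MappedReaction, core: ReactionCore) -> int:
    """The product sharing the most mapped atoms with the largest reactant."""
    largest = max(
        range(len(rxn.reactants)), key=lambda i: rxn.reactants[i].GetNumHeavyAtoms()
    )
    r_maps = set(map_numbers(rxn.reactants[largest]).values())

    def _shared(pi: int) -> tuple[int, int]:
        p_maps = set(map_numbers(rxn.products[pi]).values())
        return (len(p_maps & r_maps), len(p_maps))

    return max(range(len(rxn.products)), key=_shared)


def build_rule(rxn: MappedReaction) -> ReactionRule:
    """Extract the reaction rule; raises :class:`EmptyRuleError` for
    identity reactions and :class:`MappingError` on inconsistent maps."""
    rxn.validate()
    core = identify_reaction_core(rxn)
    if not any(core.atoms.values()):
        raise EmptyRuleError(f"{rxn.name or 'reaction'}: empty reaction core")

    moieties = extend_to_moieties(rxn, core)
    reactant_moieties = tuple(
        moieties[("reactant", pos)]
        for pos in range(len(rxn.reactants))
        if ("reactant", pos) in moieties
    )
    if not reactant_moieties:
        raise EmptyRuleError(f"{rxn.name or 'reaction'}: no reactant-side core")
    if len(reactant_moieties) > 2:
        raise ChemistryError(
            f"{rxn.name or 'reaction'}: more than two participating reactants"
        )

    ppos = _principal_product(rxn, core)
    if ("product", ppos) not in moieties:
        raise EmptyRuleError(
            f"{rxn.name or 'reaction'}: principal product has no core atoms"
        )
    return ReactionRule(
        name=rxn.name,
        reactant_moieties=reactant_moieties,
        product_moiety=moieties[("product", ppos)],
    )


# ---------------------------------------------------------------------------
# substructure matching


def _node_match(host: dict, pat: dict) -> bool:
    if (
        host["element"] != pat["element"]
        or host["charge"] != pat["charge"]
        or host["aromatic"] != pat["aromatic"]
    ):
        return False
    if pat.get("relaxed", False):
        # substitution allowed; sp3 boundary carbons must stay sp3 unless the
        # pattern explicitly waives it (preserved-fragment containment)
        if pat.get("enforce_sp3", True) and pat["sp3c"] and not host["sp3c"]:
            return False
        return True
    return host["n_h"] == pat["n_h"] and host["degree"] == pat["degree"]


def _edge_match(host: dict, pat: dict) -> bool:
    return host["order"] == pat["order"]


def find_embeddings(moiety: Moiety, host: Chem.Mol) -> list[dict[int, int]]:
    """All embeddings of the moiety pattern in ``host`` (pattern atom index ->
    host atom index), collapsed over automorphisms of the matched atom set."""
    return match_graphs(moiety.pattern_graph(), mol_to_nx(host))


def match_graphs(pat_g: nx.Graph, host_g: nx.Graph) -> list[dict[int, int]]:
    gm = isomorphism.GraphMatcher(
        host_g, pat_g, node_match=_node_match, edge_match=_edge_match
    )
    seen: set[frozenset[int]] = set()
    out: list[dict[int, int]] = []
    for mapping in gm.subgraph_monomorphisms_iter():
        inv = {p: h for h, p in mapping.items()}
        key = frozenset(inv.values())
        if key not in seen:
            seen.add(key)
            out.append(inv)
    return out


@dataclass(frozen=True)
class RuleMatch:
    rule_id: int
    slot: int
    mapping: dict[int, int]  # moiety pattern atom index -> host atom index


@dataclass
class RuleDB:
    """Extracted rules plus the per-(rule, slot) building-block index."""

    rules: list[ReactionRule]
    block_index: dict[tuple[int, int], list[str]] = field(default_factory=dict)

    def match_rules(self, mol: Chem.Mol) -> list[RuleMatch]:
        out = []
        for rid, rule in enumerate(self.rules):
            for slot, moiety in enumerate(rule.reactant_moieties):
                for emb in find_embeddings(moiety, mol):
                    out.append(RuleMatch(rule_id=rid, slot=slot, mapping=emb))
        return out

    def build_block_index(self, library) -> None:
        """Index every building block against every (rule, slot) moiety."""
        self.block_index = {}
        for rid, rule in enumerate(self.rules):
            for slot, moiety in enumerate(rule.reactant_moieties):
                ids = [
                    block.id
                    for block in library
                    if find_embeddings(moiety, block.mol)
                ]
                self.block_index[(rid, slot)] = ids

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "rules": [_rule_to_dict(rule) for rule in self.rules],
            "block_index": [
                {"rule": rid, "slot": slot, "blocks": ids}
                for (rid, slot), ids in sorted(self.block_index.items())
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RuleDB":
        payload = json.loads(text)
        rules = [_rule_from_dict(d) for d in payload["rules"]]
        index = {
            (e["rule"], e["slot"]): list(e["blocks"])
            for e in payload.get("block_index", [])
        }
        return cls(rules=rules, block_index=index)


def _moiety_to_dict(moiety: Moiety) -> dict:
    maps = map_numbers(moiety.source)
    for idx in moiety.atoms:
        if moiety.source.GetAtomWithIdx(idx).GetAtomMapNum() == 0:
            raise MappingError("serialization requires fully mapped moiety atoms")
    idx_to_map = {i: m for i, m in maps.items()}
    return {
        "source": Chem.MolToSmiles(moiety.source, canonical=False),
        "atoms": sorted(idx_to_map[i] for i in moiety.atoms),
        "boundary": sorted(idx_to_map[i] for i in moiety.boundary),
    }


def _moiety_from_dict(d: dict) -> Moiety:
    source = parse_molecule(d["source"])
    map_to_idx = {m: i for i, m in map_numbers(source).items()}
    return Moiety(
        source=source,
        atoms=frozenset(map_to_idx[m] for m in d["atoms"]),
        boundary=frozenset(map_to_idx[m] for m in d["boundary"]),
    )


def _rule_to_dict(rule: ReactionRule) -> dict:
    return {
        "name": rule.name,
        "reactant_moieties": [_moiety_to_dict(m) for m in rule.reactant_moieties],
        "product_moiety": _moiety_to_dict(rule.product_moiety),
    }


def _rule_from_dict(d: dict) -> ReactionRule:
    return ReactionRule(
        name=d["name"],
        reactant_moieties=tuple(_moiety_from_dict(m) for m in d["reactant_moieties"]),
        product_moiety=_moiety_from_dict(d["product_moiety"]),
    )


def build_rule_db(reactions: list[MappedReaction]) -> RuleDB:
    return RuleDB(rules=[build_rule(rxn) for rxn in reactions])
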