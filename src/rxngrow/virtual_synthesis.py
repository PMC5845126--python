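"""Apply a reaction rule to a posed reactant (plus a participant block) to
generate valence-correct products.

A matched molecule is split into the moiety-matched atoms and the
*clipped* remainder; the product is the product moiety with each remainder
re-attached through the rule's map-number correspondence.  Atoms inherited
from the posed reactant keep their 3D coordinates so conformer generation can
start from the existing pose.  Leaving groups (moiety atoms absent from the
product moiety) are dropped; by-product molecules are not emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_core import ChemistryError, RxngrowError, canonical_key, sanitize
from .rule_extraction import Moiety, ReactionRule, RuleDB, RuleMatch


class MatchError(RxngrowError):
    """The supplied mapping is not a genuine embedding of the moiety."""


class AssemblyError(RxngrowError):
    """Attachment bookkeeping failed (e.g. a substituent hangs off a
    leaving atom, or slot arity does not fit the rule)."""


@dataclass(frozen=True)
class ClippedFragment:
    """A molecule minus its matched moiety atoms, with attachment records."""

    host: Chem.Mol
    moiety: Moiety
    mapping: dict[int, int]  # moiety pattern atom index -> host atom index
    remainder_atoms: tuple[int, ...]  # host indices outside the match
    # (pattern atom index, host remainder atom index, bond type)
    attachments: tuple[tuple[int, int, Chem.BondType], ...]


def clip(host: Chem.Mol, moiety: Moiety, mapping: dict[int, int]) -> ClippedFragment:
    """Split ``host`` into matched moiety atoms and the remainder."""
    _verify_embedding(host, moiety, mapping)
    image = set(mapping.values())
    inv = {h: p for p, h in mapping.items()}
    remainder = tuple(
        a.GetIdx() for a in host.GetAtoms() if a.GetIdx() not in image
    )
    attachments = []
    for bond in host.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in image and j not in image:
            attachments.append((inv[i], j, bond.GetBondType()))
        elif j in image and i not in image:
            attachments.append((inv[j], i, bond.GetBondType()))
    return ClippedFragment(
        host=host,
        moiety=moiety,
        mapping=dict(mapping),
        remainder_atoms=remainder,
        attachments=tuple(attachments),
    )


def _verify_embedding(host: Chem.Mol, moiety: Moiety, mapping: dict[int, int]) -> None:
    if set(mapping) != set(moiety.atoms):
        raise MatchError("mapping does not cover the moiety atom set")
    src = moiety.source
    for p, h in mapping.items():
        if src.GetAtomWithIdx(p).GetAtomicNum() != host.GetAtomWithIdx(h).GetAtomicNum():
            raise MatchError(f"element mismatch at pattern atom {p}")
    for p1 in moiety.atoms:
        for bond in src.GetAtomWithIdx(p1).GetBonds():
            p2 = bond.GetOtherAtomIdx(p1)
            if p2 in moiety.atoms and p2 > p1:
                hb = host.GetBondBetweenAtoms(mapping[p1], mapping[p2])
                if hb is None or hb.GetBondType() != bond.GetBondType():
                    raise MatchError(f"bond mismatch between pattern atoms {p1},{p2}")


@dataclass
class ProductRecord:
    product: Chem.Mol
    rule_id: int
    rule_name: str
    reactant_key: str
    participant_id: str | None
    # product atom index -> xyz (A) for atoms inherited from the posed reactant
    inherited_coords: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return canonical_key(self.product)


def _copy_atom(atom: Chem.Atom) -> Chem.Atom:
    """Heavy-atom copy under the implicit-hydrogen model; sanitization
    recomputes hydrogen counts after assembly."""
    out = Chem.Atom(atom.GetAtomicNum())
    out.SetFormalCharge(atom.GetFormalCharge())
    out.SetIsAromatic(atom.GetIsAromatic())
    out.SetNoImplicit(False)
    return out


def assemble_product(
    rule: ReactionRule,
    rule_id: int,
    reactant_clip: ClippedFragment,
    participant_clip: ClippedFragment | None = None,
    reactant_coords: np.ndarray | None = None,
    participant_id: str | None = None,
) -> ProductRecord:
    """Join the clipped remainders onto the product moiety.

    Raises :class:`AssemblyError` when the clip arity does not match the rule
    or a substituent is attached to a leaving atom; :class:`ChemistryError`
    when the joined graph fails valence/kekulization checks.
    """
    clips = [reactant_clip] + ([participant_clip] if participant_clip else [])
    if len(clips) != rule.n_slots:
        raise AssemblyError(
            f"rule {rule.name!r} expects {rule.n_slots} reactants, got {len(clips)}"
        )

    pm = rule.product_moiety
    rw = Chem.RWMol()
    new_idx_of_pm: dict[int, int] = {}
    for src_idx in sorted(pm.atoms):
        new_idx_of_pm[src_idx] = rw.AddAtom(_copy_atom(pm.source.GetAtomWithIdx(src_idx)))
    for bond in pm.source.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in pm.atoms and j in pm.atoms:
            rw.AddBond(new_idx_of_pm[i], new_idx_of_pm[j], bond.GetBondType())

    pm_map_to_new = {
        pm.source.GetAtomWithIdx(src).GetAtomMapNum(): new
        for src, new in new_idx_of_pm.items()
        if pm.source.GetAtomWithIdx(src).GetAtomMapNum() > 0
    }

    inherited: dict[int, np.ndarray] = {}
    for slot, cl in enumerate(clips):
        is_posed = slot == 0 and reactant_coords is not None
        new_idx_of_rem: dict[int, int] = {}
        for h_idx in cl.remainder_atoms:
            new_idx_of_rem[h_idx] = rw.AddAtom(_copy_atom(cl.host.GetAtomWithIdx(h_idx)))
            if is_posed:
                inherited[new_idx_of_rem[h_idx]] = np.array(reactant_coords[h_idx])
        for bond in cl.host.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in new_idx_of_rem and j in new_idx_of_rem:
                rw.AddBond(new_idx_of_rem[i], new_idx_of_rem[j], bond.GetBondType())
        slot_moiety = rule.reactant_moieties[slot]
        for p_idx, h_rem, btype in cl.attachments:
            mp = slot_moiety.source.GetAtomWithIdx(p_idx).GetAtomMapNum()
            if mp not in pm_map_to_new:
                raise AssemblyError(
                    f"substituent attached to leaving atom (map {mp}) of rule "
                    f"{rule.name!r}"
                )
            rw.AddBond(pm_map_to_new[mp], new_idx_of_rem[h_rem], btype)
        if is_posed:
            # product-moiety atoms whose map survives from the posed reactant
            for mp, p_idx in slot_moiety.map_to_idx.items():
                if mp in pm_map_to_new:
                    h_idx = cl.mapping[p_idx]
                    inherited[pm_map_to_new[mp]] = np.array(reactant_coords[h_idx])

    product = rw.GetMol()
    sanitize(product)
    Chem.Kekulize(Chem.Mol(product), clearAromaticFlags=False)
    return ProductRecord(
        product=product,
        rule_id=rule_id,
        rule_name=rule.name,
        reactant_key=canonical_key(reactant_clip.host),
        participant_id=participant_id,
        inherited_coords=inherited,
    )


def identity_clip(moiety: Moiety) -> ClippedFragment:
    """Clip of the moiety's own source molecule at the identity embedding."""
    return clip(moiety.source, moiety, {i: i for i in moiety.atoms})


def apply_rule_to_source(rule: ReactionRule, rule_id: int = -1) -> ProductRecord:
    """Round-trip check helper: apply the rule to its own source reactants."""
    clips = [identity_clip(m) for m in rule.reactant_moieties]
    return assemble_product(
        rule,
        rule_id,
        clips[0],
        clips[1] if len(clips) > 1 else None,
    )


def enumerate_products(
    reactant: Chem.Mol,
    db: RuleDB,
    library,
    reactant_coords: np.ndarray | None = None,
) -> list[ProductRecord]:
    """Cartesian expansion over (matched rule, matched slot, participant for
    the complementary slot), deduplicated by canonical key and returned in a
    deterministic order (rule id, participant id, product key)."""
    by_id = {b.id: b for b in library}
    records: list[ProductRecord] = []
    for match in db.match_rules(reactant):
        rule = db.rules[match.rule_id]
        try:
            r_clip = clip(reactant, rule.reactant_moieties[match.slot], match.mapping)
        except MatchError:
            continue
        if rule.n_slots == 1:
            _try_assemble(records, rule, match, r_clip, None, None, reactant_coords)
            continue
        other = 1 - match.slot
        if match.slot != 0:
            # the posed reactant must occupy slot 0 of the assembly call;
            # rebuild the rule view with slots swapped
            rule = ReactionRule(
                name=rule.name,
                reactant_moieties=(
                    rule.reactant_moieties[match.slot],
                    rule.reactant_moieties[other],
                ),
                product_moiety=rule.product_moiety,
            )
            other_moiety = rule.reactant_moieties[1]
        else:
            other_moiety = rule.reactant_moieties[1]
        for block_id in db.block_index.get((match.rule_id, other), []):
            block = by_id.get(block_id)
            if block is None:
                continue
            from .rule_extraction import find_embeddings

            for emb in find_embeddings(other_moiety, block.mol):
                try:
                    p_clip = clip(block.mol, other_moiety, emb)
                except MatchError:
                    continue
                _try_assemble(
                    records, rule, match, r_clip, p_clip, block.id, reactant_coords
                )

    seen: set[str] = set()
    out: list[ProductRecord] = []
    for rec in sorted(records, key=lambda r: (r.rule_id, r.participant_id or "", r.key)):
        if rec.key not in seen:
            seen.add(rec.key)
            out.append(rec)
    return out


def _try_assemble(records, rule, match: RuleMatch, r_clip, p_clip, block_id, coords):
    try:
        records.append(
            assemble_product(
                rule,
                match.rule_id,
                r_clip,
                p_clip,
                reactant_coords=coords,
                participant_id=block_id,
            )
        )
    except (AssemblyError, ChemistryError):
        pass
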