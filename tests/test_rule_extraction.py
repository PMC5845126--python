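import pytest

from rxngrow.chem_core import canonical_key, is_sp3_carbon, parse_molecule
from rxngrow.rule_extraction import (
    EmptyRuleError,
    MappedReaction,
    MappingError,
    RuleDB,
    build_rule,
    build_rule_db,
    extend_moiety,
    find_embeddings,
    identify_reaction_core,
)
from rxngrow.virtual_synthesis import apply_rule_to_source

from .oracles import brute_embeddings

AMIDE = (
    "[CH3:1][C:2](=[O:3])[OH:4].[NH2:5][CH3:6]"
    ">>[CH3:1][C:2](=[O:3])[NH:5][CH3:6].[OH2:4]"
)
WILLIAMSON = (
    "[CH3:1][OH:2].[Br:3][CH2:4][CH3:5]"
    ">>[CH3:1][O:2][CH2:4][CH3:5].[BrH:3]"
)
ARYL_AMIDE = (
    "[OH:1][C:2](=[O:3])[c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1.[NH2:10][CH3:11]"
    ">>[CH3:11][NH:10][C:2](=[O:3])[c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1.[OH2:1]"
)


def _core_maps(rxn, core, side, pos):
    mol = rxn.reactants[pos] if side == "reactant" else rxn.products[pos]
    return {
        mol.GetAtomWithIdx(i).GetAtomMapNum() for i in core.for_mol(side, pos)
    }


class TestReactionCore:
    def test_amide_coupling_core(self):
        rxn = MappedReaction.from_smiles(AMIDE, "amide")
        core = identify_reaction_core(rxn)
        assert _core_maps(rxn, core, "reactant", 0) == {2, 4}
        assert _core_maps(rxn, core, "reactant", 1) == {5}

    def test_identity_reaction_empty_core(self):
        rxn = MappedReaction.from_smiles("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        core = identify_reaction_core(rxn)
        assert not any(core.atoms.values())

    def test_williamson_core(self):
        rxn = MappedReaction.from_smiles(WILLIAMSON, "williamson")
        core = identify_reaction_core(rxn)
        reactant_maps = _core_maps(rxn, core, "reactant", 0) | _core_maps(
            rxn, core, "reactant", 1
        )
        assert reactant_maps == {2, 3, 4}

    def test_duplicate_map_rejected(self):
        with pytest.raises(MappingError):
            MappedReaction.from_smiles("[CH3:1][OH:1]>>[CH3:1][OH:2]")

    def test_product_map_without_reactant_partner_rejected(self):
        with pytest.raises(MappingError):
            MappedReaction.from_smiles("[CH3:1][OH:2]>>[CH3:1][O:2][CH3:9]")


class TestMoietyExtension:
    def test_acetic_acid_moiety_is_whole_acid(self):
        rxn = MappedReaction.from_smiles(AMIDE, "amide")
        rule = build_rule(rxn)
        acid = rule.reactant_moieties[0]
        assert acid.atoms == frozenset(range(4))  # the whole acid

    def test_aromatic_ring_fully_included(self):
        rxn = MappedReaction.from_smiles(ARYL_AMIDE, "aryl-amide")
        rule = build_rule(rxn)
        acid = rule.reactant_moieties[0]
        # O, C(=O), O plus the six ring atoms
        assert len(acid.atoms) == 9

    def test_core_with_no_outside_neighbors(self):
        mol = parse_molecule("O")
        moiety = extend_moiety(mol, frozenset({0}))
        assert moiety.atoms == frozenset({0})

    def test_boundary_atoms_are_sp3_or_aromatic(self, reaction_set):
        for rxn in reaction_set:
            rule = build_rule(rxn)
            for moiety in list(rule.reactant_moieties) + [rule.product_moiety]:
                for idx in moiety.attachment_atoms:
                    atom = moiety.source.GetAtomWithIdx(idx)
                    assert is_sp3_carbon(atom) or (
                        atom.GetIsAromatic()
                        and _ring_inside(moiety, idx)
                    ), f"{rxn.name}: bad attachment atom {idx}"

    def test_core_subset_of_moiety(self, reaction_set):
        for rxn in reaction_set:
            core = identify_reaction_core(rxn)
            rule = build_rule(rxn)
            for slot, pos in enumerate(_participating(rxn, core)):
                assert core.for_mol("reactant", pos) <= rule.reactant_moieties[slot].atoms


def _ring_inside(moiety, idx):
    ri = moiety.source.GetRingInfo()
    return any(
        idx in ring and set(ring) <= moiety.atoms
        for ring in ri.AtomRings()
        if all(moiety.source.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )


def _participating(rxn, core):
    return [
        pos for pos in range(len(rxn.reactants)) if core.for_mol("reactant", pos)
    ]


class TestBuildRule:
    def test_amide_rule_shape(self):
        rule = build_rule(MappedReaction.from_smiles(AMIDE, "amide"))
        assert rule.n_slots == 2
        assert rule.leaving_maps(0) == {4}  # the acid OH leaves
        assert rule.leaving_maps(1) == frozenset()

    def test_identity_reaction_raises(self):
        with pytest.raises(EmptyRuleError):
            build_rule(MappedReaction.from_smiles("[CH3:1][OH:2]>>[CH3:1][OH:2]"))

    def test_unimolecular_rule(self):
        # intramolecular etherification: one reactant, one moiety
        rxn = MappedReaction.from_smiles(
            "[OH:1][CH2:2][CH2:3][CH2:4][CH2:5][Br:6]"
            ">>[O:1]1[CH2:2][CH2:3][CH2:4][CH2:5]1.[BrH:6]",
            "cyclization",
        )
        rule = build_rule(rxn)
        assert rule.n_slots == 1
        rec = apply_rule_to_source(rule)
        assert rec.key == canonical_key(rxn.products[0])

    def test_all_fixture_rules_round_trip(self, reaction_set):
        for rxn in reaction_set:
            rule = build_rule(rxn)
            rec = apply_rule_to_source(rule)
            core = identify_reaction_core(rxn)
            from rxngrow.rule_extraction import _principal_product

            principal = rxn.products[_principal_product(rxn, core)]
            assert rec.key == canonical_key(principal), rxn.name


@pytest.fixture(scope="module")
def amide_db():
    return build_rule_db([MappedReaction.from_smiles(AMIDE, "amide")])


class TestMatching:
    def test_benzamide_matches_nothing(self, amide_db):
        assert amide_db.match_rules(parse_molecule("NC(=O)c1ccccc1")) == []

    def test_acetic_acid_matches_acid_slot(self, amide_db):
        matches = amide_db.match_rules(parse_molecule("CC(=O)O"))
        assert len(matches) == 1 and matches[0].slot == 0

    def test_succinic_acid_two_matches(self, amide_db):
        matches = amide_db.match_rules(parse_molecule("OC(=O)CCC(=O)O"))
        assert len(matches) == 2
        assert {frozenset(m.mapping.values()) for m in matches} == {
            frozenset({0, 1, 2, 3}),
            frozenset({4, 5, 6, 7}),
        } or len({frozenset(m.mapping.values()) for m in matches}) == 2

    def test_agrees_with_brute_force(self, rule_db, library):
        small = [b for b in library if b.mol.GetNumHeavyAtoms() <= 12][:20]
        for rule in rule_db.rules[:5]:
            for moiety in rule.reactant_moieties:
                pat_g = moiety.pattern_graph()
                for block in small:
                    from rxngrow.chem_core import mol_to_nx

                    fast = find_embeddings(moiety, block.mol)
                    slow = brute_embeddings(pat_g, mol_to_nx(block.mol))
                    fast_sets = {frozenset(m.values()) for m in fast}
                    slow_sets = {frozenset(m.values()) for m in slow}
                    assert fast_sets == slow_sets, (rule.name, block.id)


class TestSerialization:
    def test_json_round_trip(self, rule_db, library):
        text = rule_db.to_json()
        back = RuleDB.from_json(text)
        assert len(back.rules) == len(rule_db.rules)
        assert back.block_index == rule_db.block_index
        # reloaded rules behave identically
        for rule in back.rules:
            rec = apply_rule_to_source(rule)
            assert rec.product.GetNumAtoms() > 0
        mol = parse_molecule("CC(=O)O")
        assert {(m.rule_id, m.slot) for m in back.match_rules(mol)} == {
            (m.rule_id, m.slot) for m in rule_db.match_rules(mol)
        }

    def test_index_spot_check(self, rule_db, library):
        by_id = {b.id: b for b in library}
        for (rid, slot), ids in rule_db.block_index.items():
            moiety = rule_db.rules[rid].reactant_moieties[slot]
            for bid in ids[:2]:
                assert find_embeddings(moiety, by_id[bid].mol)
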