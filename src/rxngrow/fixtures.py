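"""Deterministic toy data standing in for the external reaction database,
building-block catalog, and receptor systems.

The reaction set and block library are fixed text (seed-independent); the
pocket is constructed around a *planted* 3-step growth chain: receptor sites
are placed at ideal interaction distances from a reference pose of the
planted product, so that the planted chain dominates group efficiency at
every step.  ``make_pocket`` verifies by exhaustive enumeration that the
planted product is the unique refined-energy optimum among all molecules
reachable in <= 3 accepted steps, and fails loudly otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .block_library import BuildingBlock, PreservedFragment
from .chem_core import RxngrowError, canonical_key, parse_molecule
from .growth_engine import GrowthConfig, GrowthState
from .pose_eval import (
    InteractionTarget,
    Receptor,
    generate_conformers,
    refine_pose,
)
from .rule_extraction import MappedReaction, RuleDB, build_rule_db
from .virtual_synthesis import enumerate_products


class FixtureGenerationError(RxngrowError):
    """The planted product failed the generation-time uniqueness check."""


# ---------------------------------------------------------------------------
# reactions (fixed text, fully atom-mapped on heavy atoms)

_REACTIONS: list[tuple[str, str]] = [
    (
        "amide-aliphatic",
        "[CH3:1][C:2](=[O:3])[OH:4].[NH2:5][CH2:6][CH3:7]"
        ">>[CH3:1][C:2](=[O:3])[NH:5][CH2:6][CH3:7].[OH2:4]",
    ),
    (
        "amide-aromatic",
        "[CH3:1][C:2](=[O:3])[OH:4].[NH2:5][c:6]1[cH:7][cH:8][cH:9][cH:10][cH:11]1"
        ">>[CH3:1][C:2](=[O:3])[NH:5][c:6]1[cH:7][cH:8][cH:9][cH:10][cH:11]1.[OH2:4]",
    ),
    (
        "ester-formation",
        "[CH3:1][C:2](=[O:3])[OH:4].[OH:5][CH2:6][CH3:7]"
        ">>[CH3:1][C:2](=[O:3])[O:5][CH2:6][CH3:7].[OH2:4]",
    ),
    (
        "ether-aromatic",
        "[OH:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1.[Br:8][CH2:9][CH3:10]"
        ">>[CH3:10][CH2:9][O:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1.[BrH:8]",
    ),
    (
        "sulfonamide",
        "[CH3:1][S:2](=[O:3])(=[O:4])[Cl:5].[NH2:6][c:7]1[cH:8][cH:9][cH:10][cH:11][cH:12]1"
        ">>[CH3:1][S:2](=[O:3])(=[O:4])[NH:6][c:7]1[cH:8][cH:9][cH:10][cH:11][cH:12]1.[ClH:5]",
    ),
    (
        "reductive-amination",
        "[CH3:1][C:2](=[O:3])[CH3:4].[NH2:5][CH2:6][CH3:7]"
        ">>[CH3:1][CH:2]([CH3:4])[NH:5][CH2:6][CH3:7].[OH2:3]",
    ),
    (
        "biaryl-coupling",
        "[Br:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1."
        "[OH:8][B:9]([OH:10])[c:11]1[cH:12][cH:13][cH:14][cH:15][cH:16]1"
        ">>[cH:3]1[cH:4][cH:5][cH:6][cH:7][c:2]1-[c:11]1[cH:12][cH:13][cH:14][cH:15][cH:16]1."
        "[Br:1][B:9]([OH:8])[OH:10]",
    ),
    (
        "urea-formation",
        "[CH3:1][N:2]=[C:3]=[O:4].[NH2:5][CH2:6][CH3:7]"
        ">>[CH3:1][NH:2][C:3](=[O:4])[NH:5][CH2:6][CH3:7]",
    ),
    (
        "snar-amination",
        "[F:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1.[NH2:8][CH2:9][CH3:10]"
        ">>[CH2:9]([CH3:10])[NH:8][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1.[FH:1]",
    ),
    (
        "ether-aliphatic",
        "[OH:1][CH2:2][CH3:3].[Br:4][CH2:5][CH3:6]"
        ">>[CH3:3][CH2:2][O:1][CH2:5][CH3:6].[BrH:4]",
    ),
]


def make_reaction_set(seed: int = 0) -> list[MappedReaction]:
    """The fixed toy reaction set (seed-independent)."""
    return [MappedReaction.from_smiles(smi, name) for name, smi in _REACTIONS]


# ---------------------------------------------------------------------------
# building blocks (fixed text)

_BLOCKS: list[tuple[str, str]] = [
    # seed for the planted pocket: phenol + aryl bromide + aromatic amine;
    # the meta O/N arrangement makes the preserved-fragment embedding unique
    ("BB-SEED", "Oc1cccc(N)c1Br"),
    # carboxylic acids
    ("BB-ACID-ACET", "CC(=O)O"),
    ("BB-ACID-PROP", "CCC(=O)O"),
    ("BB-ACID-BUT", "CCCC(=O)O"),
    ("BB-ACID-ISOBUT", "CC(C)C(=O)O"),
    ("BB-ACID-PHACET", "O=C(O)Cc1ccccc1"),
    # aromatic primary amines
    ("BB-ANILINE", "Nc1ccccc1"),
    ("BB-TOLUIDINE", "Nc1ccc(C)cc1"),
    ("BB-FLUOROANILINE", "Nc1ccc(F)cc1"),
    ("BB-ANISIDINE", "Nc1ccc(OC)cc1"),
    # aliphatic primary amines
    ("BB-ETHYLAMINE", "CCN"),
    ("BB-PROPYLAMINE", "CCCN"),
    ("BB-ISOBUTYLAMINE", "CC(C)CN"),
    ("BB-METHOXYETHYLAMINE", "COCCN"),
    # alcohols
    ("BB-ETHANOL", "CCO"),
    ("BB-PROPANOL", "CCCO"),
    ("BB-ISOPROPANOL", "CC(C)O"),
    ("BB-BUTANOL", "CCCCO"),
    # alkyl bromides
    ("BB-BRET", "CCBr"),
    ("BB-BRPROP", "CCCBr"),
    ("BB-BRBUT", "CCCCBr"),
    ("BB-BRPHENETHYL", "BrCCc1ccccc1"),
    # phenols
    ("BB-PHENOL", "Oc1ccccc1"),
    ("BB-CRESOL", "Cc1ccc(O)cc1"),
    ("BB-FLUOROPHENOL", "Oc1ccc(F)cc1"),
    # sulfonyl chlorides
    ("BB-MSCL", "CS(=O)(=O)Cl"),
    ("BB-ESCL", "CCS(=O)(=O)Cl"),
    ("BB-PSCL", "CCCS(=O)(=O)Cl"),
    # ketones
    ("BB-ACETONE", "CC(C)=O"),
    ("BB-BUTANONE", "CCC(C)=O"),
    ("BB-CYCLOHEXANONE", "O=C1CCCCC1"),
    # arylboronic acids
    ("BB-BORO-PH", "OB(O)c1ccccc1"),
    ("BB-BORO-TOL", "Cc1ccc(cc1)B(O)O"),
    ("BB-BORO-FLUORO", "OB(O)c1ccc(F)cc1"),
    ("BB-BORO-ANIS", "COc1ccc(cc1)B(O)O"),
    # aryl bromides
    ("BB-BRBENZENE", "Brc1ccccc1"),
    ("BB-BRTOLUENE", "Cc1ccc(Br)cc1"),
    ("BB-BRANISOLE", "COc1ccc(Br)cc1"),
    # isocyanates
    ("BB-MIC", "CN=C=O"),
    ("BB-EIC", "CCN=C=O"),
    ("BB-PIC", "CCCN=C=O"),
    # aryl fluorides
    ("BB-FBENZENE", "Fc1ccccc1"),
    ("BB-FTOLUENE", "Cc1ccc(F)cc1"),
    ("BB-FANISOLE", "COc1ccc(F)cc1"),
    # assorted decoys / inert blocks
    ("BB-CYCLOHEXANE", "C1CCCCC1"),
    ("BB-TOLUENE", "Cc1ccccc1"),
    ("BB-PYRIDINE", "c1ccncc1"),
    ("BB-THF", "C1CCOC1"),
    ("BB-DMA", "CN(C)C"),
    ("BB-BENZONITRILE", "N#Cc1ccccc1"),
]


def make_block_library(seed: int = 0) -> list[BuildingBlock]:
    """The fixed toy building-block library (seed-independent)."""
    return [
        BuildingBlock(id=bid, mol=parse_molecule(smi), provenance="fixture")
        for bid, smi in _BLOCKS
    ]


# blocks available inside the planted pocket scenario (keeps the reachable
# space small enough for exhaustive verification)
POCKET_LIBRARY_IDS = [
    "BB-SEED",
    "BB-ACID-ACET",
    "BB-ACID-PROP",
    "BB-MSCL",
    "BB-BORO-PH",
    "BB-BRET",
    "BB-ETHYLAMINE",
]

PLANTED_ROUTE = [
    ("amide-aromatic", "BB-ACID-PROP"),
    ("biaryl-coupling", "BB-BORO-PH"),
    ("ether-aromatic", "BB-BRET"),
]

_SEED_ID = "BB-SEED"
_FRAGMENT_SMILES = "Oc1cccc(N)c1"


@dataclass
class ToyPocket:
    """A synthetic cleft with typed sites and a planted optimal chain."""

    receptor: Receptor
    targets: list[InteractionTarget]
    fragment: PreservedFragment
    seed_id: str
    library_ids: list[str]
    planted_route: list[tuple[str, str]]
    planted_key: str
    query_mol: Chem.Mol
    query_coords: np.ndarray
    config: GrowthConfig = field(default_factory=GrowthConfig)


def _planted_product_chain(db: RuleDB, library: list[BuildingBlock]):
    """Apply the planted route step by step; returns the molecule chain."""
    by_id = {b.id: b for b in library}
    name_to_id = {r.name: i for i, r in enumerate(db.rules)}
    mol = by_id[_SEED_ID].mol
    chain = [mol]
    for rule_name, participant in PLANTED_ROUTE:
        rid = name_to_id[rule_name]
        recs = [
            r
            for r in enumerate_products(mol, db, library)
            if r.rule_id == rid and r.participant_id == participant
        ]
        if len(recs) != 1:
            raise FixtureGenerationError(
                f"planted step {rule_name}+{participant} yielded {len(recs)} products"
            )
        mol = recs[0].product
        chain.append(mol)
    return chain


def _outward(p: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    v = p - centroid
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def make_pocket(seed: int = 0, verify: bool = True) -> ToyPocket:
    """Build the planted pocket; different seeds rigidly reorient the whole
    system (pose, sites, anchors), which leaves all energies invariant."""
    db = build_rule_db(make_reaction_set())
    library = make_block_library()
    db.build_block_index(library)
    pocket_library = [b for b in library if b.id in POCKET_LIBRARY_IDS]
    db.build_block_index(pocket_library)

    chain = _planted_product_chain(db, pocket_library)
    planted = chain[-1]

    # reference pose of the planted product
    coords = generate_conformers(planted, k=1, seed=7)[0]
    centroid = coords.mean(axis=0)

    frag_pattern = parse_molecule(_FRAGMENT_SMILES)
    tmp_frag = PreservedFragment(
        pattern=frag_pattern,
        reference_coords=np.zeros((frag_pattern.GetNumAtoms(), 3)),
    )
    emb = tmp_frag.embeddings(planted)
    if not emb:
        raise FixtureGenerationError("preserved fragment missing from planted product")
    frag_idx = [emb[0][p] for p in sorted(emb[0])]
    frag_ref = coords[frag_idx]

    # locate the planted additions in the final pose
    amide_match = _match_one(planted, "[OX1]=[CX3][NX3]")
    amide_o, amide_c = amide_match[0], amide_match[1]
    acyl = _match_one(planted, "[CH3][CH2][CX3](=O)N")
    acyl_carbons = [acyl[0], acyl[1]]
    ethyl = _match_one(planted, "[CH3][CH2][OX2]c")
    ethyl_carbons = [ethyl[0], ethyl[1]]
    pendant_ring = _pendant_ring(planted)

    rec_elements: list[str] = []
    rec_coords: list[np.ndarray] = []

    def _add(element: str, pos: np.ndarray) -> int:
        rec_elements.append(element)
        rec_coords.append(pos)
        return len(rec_elements) - 1

    def _pair(i: int, dist: float = 4.0) -> None:
        """Two hydrophobic receptor atoms straddling ligand atom ``i``."""
        u = _outward(coords[i], centroid)
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        for s in (0.45, -0.45):
            v = u + s * perp
            v /= np.linalg.norm(v)
            _add("C", coords[i] + dist * v)

    # hinge-like donor rewarding the amide carbonyl oxygen, placed along the
    # C=O bond direction (ideal hydrogen-bond geometry)
    co_dir = coords[amide_o] - coords[amide_c]
    co_dir /= np.linalg.norm(co_dir)
    donor_idx = _add("N", coords[amide_o] + 2.9 * co_dir)
    # hydrophobic atoms rewarding the acyl ethyl
    for i in acyl_carbons:
        _pair(i)
    # hydrophobic shell around the pendant aryl ring
    ring_pos = coords[pendant_ring]
    ring_centroid = ring_pos.mean(axis=0)
    for i in pendant_ring[::2]:
        _add("C", coords[i] + 3.9 * _outward(coords[i], centroid))
    # hydrophobic atoms rewarding the O-ethyl
    for i in ethyl_carbons:
        _pair(i)

    receptor = Receptor(
        elements=rec_elements,
        coords=np.array(rec_coords),
        donors=(donor_idx,),
        acceptors=(),
        hydrophobic=tuple(i for i in range(len(rec_elements)) if rec_elements[i] == "C"),
    )

    targets = [
        InteractionTarget(
            id="hinge-hbond",
            anchor=receptor.coords[donor_idx],
            kind="hbond-acceptor",
            satisfied_radius=4.0,
        ),
        InteractionTarget(
            id="aryl-pocket",
            anchor=ring_centroid + 3.9 * _outward(ring_centroid, centroid),
            kind="aromatic",
            satisfied_radius=5.5,
        ),
        InteractionTarget(
            id="alkyl-pocket",
            anchor=coords[ethyl_carbons].mean(axis=0)
            + 4.0 * _outward(coords[ethyl_carbons].mean(axis=0), centroid),
            kind="hydrophobic",
            satisfied_radius=5.5,
        ),
    ]

    # seed-dependent rigid reorientation of the whole system
    rng = np.random.default_rng(seed)
    rot = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3)).as_matrix()
    shift = rng.uniform(-5.0, 5.0, 3)

    def _move(x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ rot.T + shift

    receptor = Receptor(
        elements=receptor.elements,
        coords=_move(receptor.coords),
        donors=receptor.donors,
        acceptors=receptor.acceptors,
        hydrophobic=receptor.hydrophobic,
    )
    targets = [replace(t, anchor=_move(t.anchor)) for t in targets]
    frag_ref = _move(frag_ref)
    coords = _move(coords)

    pocket = ToyPocket(
        receptor=receptor,
        targets=targets,
        fragment=PreservedFragment(pattern=frag_pattern, reference_coords=frag_ref),
        seed_id=_SEED_ID,
        library_ids=list(POCKET_LIBRARY_IDS),
        planted_route=list(PLANTED_ROUTE),
        planted_key=canonical_key(planted),
        query_mol=planted,
        query_coords=coords,
        config=GrowthConfig(n_conformers=8, steps_per_target=2, beam=3),
    )

    if verify:
        verify_pocket(pocket, db, pocket_library)
    return pocket


def _match_one(mol: Chem.Mol, smarts: str) -> tuple[int, ...]:
    patt = Chem.MolFromSmarts(smarts)
    matches = mol.GetSubstructMatches(patt)
    if len(matches) != 1:
        raise FixtureGenerationError(f"expected one match for {smarts}, got {len(matches)}")
    return matches[0]


def _pendant_ring(mol: Chem.Mol) -> list[int]:
    """The aromatic ring carrying no N/O substituents (the coupled aryl)."""
    for ring in mol.GetRingInfo().AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() for a in atoms):
            continue
        has_het_sub = any(
            nbr.GetAtomicNum() in (7, 8)
            for a in atoms
            for nbr in a.GetNeighbors()
            if nbr.GetIdx() not in ring
        )
        if not has_het_sub:
            return list(ring)
    raise FixtureGenerationError("no pendant aromatic ring found")


# ---------------------------------------------------------------------------
# exhaustive enumeration (generation-time verifier; also the independent
# search oracle used by the test suite against the beam engine)


def exhaustive_states(
    pocket: ToyPocket, db: RuleDB, library: list[BuildingBlock]
) -> list[GrowthState]:
    """Every growth state reachable through accepted steps (depth-first, no
    beam truncation), including all intermediates and the bare seed."""
    from .growth_engine import _evaluate_product, _initial_state

    by_id = {b.id: b for b in library}
    seed_block = by_id[pocket.seed_id]
    cfg = pocket.config
    state0 = _initial_state(seed_block, pocket.fragment, pocket.receptor, cfg)
    if state0 is None:
        raise FixtureGenerationError("seed could not be posed")

    all_states: list[GrowthState] = []

    def _expand(state: GrowthState, target_pos: int, steps_on_target: int) -> None:
        all_states.append(state)
        if target_pos >= len(pocket.targets):
            return
        target = pocket.targets[target_pos]
        if target.id in state.satisfied or steps_on_target >= cfg.steps_per_target:
            _expand_next(state, target_pos)
            return
        any_step = False
        for rec in enumerate_products(state.mol, db, library, reactant_coords=state.coords):
            new_state = _evaluate_product(
                rec, state, target, pocket.fragment, pocket.receptor, cfg
            )
            if new_state is not None:
                any_step = True
                if target.id in new_state.satisfied:
                    _expand_next(new_state, target_pos)
                else:
                    _expand(new_state, target_pos, steps_on_target + 1)
        if not any_step:
            _expand_next(state, target_pos)

    def _expand_next(state: GrowthState, target_pos: int) -> None:
        if target_pos + 1 < len(pocket.targets):
            _expand(state, target_pos + 1, 0)
        else:
            all_states.append(state)

    _expand(state0, 0, 0)

    # deduplicate by molecule, keeping the best-energy pose
    best: dict[str, GrowthState] = {}
    for s in all_states:
        k = s.key
        if k not in best or s.energy < best[k].energy:
            best[k] = s
    return sorted(best.values(), key=lambda s: (s.energy, s.key))


def verify_pocket(
    pocket: ToyPocket, db: RuleDB, library: list[BuildingBlock]
) -> None:
    """Check the planted product is the unique refined-energy optimum among
    all reachable molecules; raise :class:`FixtureGenerationError` if not."""
    states = exhaustive_states(pocket, db, library)
    refined: list[tuple[float, str]] = []
    for s in states:
        _, e = refine_pose(s.mol, s.coords, pocket.receptor, pocket.config.weights)
        refined.append((e, s.key))
    refined.sort()
    if not refined or refined[0][1] != pocket.planted_key:
        raise FixtureGenerationError(
            f"planted product is not the optimum (best = {refined[0] if refined else None})"
        )
    if len(refined) > 1 and refined[1][0] <= refined[0][0]:
        raise FixtureGenerationError("planted optimum is not unique")


# ---------------------------------------------------------------------------
# persistence for the CLI


def write_fixture_files(outdir, seed: int = 0, verify: bool = True) -> None:
    from pathlib import Path

    from .block_library import write_library
    from .chem_core import mol_to_molblock

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reactions = make_reaction_set(seed)
    lines = [f"{r.to_smiles()}\t{r.name}" for r in reactions]
    (outdir / "reactions.smi").write_text("\n".join(lines) + "\n")

    library = make_block_library(seed)
    write_library(library, outdir / "blocks.smi")

    pocket = make_pocket(seed, verify=verify)
    (outdir / "pocket.json").write_text(pocket_to_json(pocket))

    sdf = mol_to_molblock(pocket.query_mol, coords=pocket.query_coords)
    (outdir / "query.sdf").write_text(sdf + "$$$$\n")


def pocket_from_json(text: str) -> dict:
    """Load the receptor / targets / fragment triple from pocket JSON.

    Returns a dict with keys ``receptor``, ``targets``, ``fragment``,
    ``seed_id``, ``library_ids`` (the query pose is not round-tripped)."""
    d = json.loads(text)
    return {
        "receptor": Receptor.from_json(json.dumps(d["receptor"])),
        "targets": [
            InteractionTarget(
                id=t["id"],
                anchor=np.array(t["anchor"], dtype=float),
                kind=t["kind"],
                satisfied_radius=t["satisfied_radius"],
            )
            for t in d["targets"]
        ],
        "fragment": PreservedFragment(
            pattern=parse_molecule(d["fragment"]["smiles"]),
            reference_coords=np.array(d["fragment"]["reference_coords"], dtype=float),
        ),
        "seed_id": d.get("seed_id"),
        "library_ids": d.get("library_ids"),
        "planted_route": [tuple(s) for s in d.get("planted_route", [])],
        "planted_key": d.get("planted_key"),
    }


def pocket_to_json(pocket: ToyPocket) -> str:
    return json.dumps(
        {
            "receptor": json.loads(pocket.receptor.to_json()),
            "targets": [
                {
                    "id": t.id,
                    "anchor": t.anchor.tolist(),
                    "kind": t.kind,
                    "satisfied_radius": t.satisfied_radius,
                }
                for t in pocket.targets
            ],
            "fragment": {
                # non-canonical output keeps atom order in sync with coords
                "smiles": Chem.MolToSmiles(pocket.fragment.pattern, canonical=False),
                "reference_coords": pocket.fragment.reference_coords.tolist(),
            },
            "seed_id": pocket.seed_id,
            "library_ids": pocket.library_ids,
            "planted_route": [list(s) for s in pocket.planted_route],
            "planted_key": pocket.planted_key,
        },
        indent=1,
    )
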