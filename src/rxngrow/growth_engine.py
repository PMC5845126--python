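"""The recursive optimization loop: seed -> rule-based products -> pose
evaluation -> best-group-efficiency conformer becomes the next reactant, per
interaction target, followed by property filtering, energy ranking, and
synthetic-route export.

Beam width 1 reproduces pure greedy growth; the default keeps the top 3
growth states per step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .block_library import BuildingBlock, PreservedFragment
from .chem_core import MolDescriptors, RxngrowError, canonical_key, compute_descriptors
from .pose_eval import (
    InteractionTarget,
    Receptor,
    ScoreWeights,
    align_to_preserved,
    atom_compatible,
    check_direction,
    generate_conformers,
    group_efficiency,
    refine_pose,
    score_pose,
)
from .rule_extraction import RuleDB
from .virtual_synthesis import ProductRecord, enumerate_products

log = logging.getLogger("rxngrow")


def accepts_step(
    e_prev: float, e_new: float, n_prev: int, n_new: int, config: "GrowthConfig"
) -> bool:
    """The engine's growth-step acceptance rule: incremental group efficiency
    strictly below the configured threshold."""
    ge = group_efficiency(e_new, e_prev, n_new, n_prev)
    return ge < config.ge_threshold


class RouteReplayError(RxngrowError):
    """An exported route failed to regenerate its candidate (must never fire)."""


@dataclass(frozen=True)
class GrowthConfig:
    n_conformers: int = 30
    ge_threshold: float = -0.1
    mw_max: float = 600.0
    clogp_max: float = 5.0
    beam: int = 3
    seed: int = 2024
    steps_per_target: int = 2
    min_overlap: float = 0.0
    weights: ScoreWeights = field(default_factory=ScoreWeights)


@dataclass(frozen=True)
class RouteStep:
    rule_id: int
    rule_name: str
    reactant_key: str
    participant_id: str | None
    product_key: str


@dataclass
class GrowthState:
    mol: Chem.Mol
    coords: np.ndarray
    energy: float
    route: tuple[RouteStep, ...]
    seed_id: str
    satisfied: frozenset[str] = frozenset()

    @property
    def key(self) -> str:
        return canonical_key(self.mol)

    def best_distance(self, target: InteractionTarget) -> float:
        return float(np.linalg.norm(self.coords - target.anchor, axis=1).min())


@dataclass
class CandidateCompound:
    state: GrowthState
    descriptors: MolDescriptors
    refined_energy: float | None = None
    rank: int | None = None


def _fragment_atoms(mol: Chem.Mol, frag: PreservedFragment) -> frozenset[int]:
    embs = frag.embeddings(mol)
    return frozenset(embs[0].values()) if embs else frozenset()


def _initial_state(
    block: BuildingBlock,
    frag: PreservedFragment,
    receptor: Receptor,
    config: GrowthConfig,
) -> GrowthState | None:
    """Pose the seed block on the preserved-fragment reference and keep its
    best-energy conformer."""
    try:
        confs = generate_conformers(block.mol, k=config.n_conformers, seed=config.seed)
    except RxngrowError as exc:
        log.warning("seed %s: %s", block.id, exc)
        return None
    frag_atoms = _fragment_atoms(block.mol, frag)
    best: GrowthState | None = None
    for coords in confs:
        aligned, overlap = align_to_preserved(block.mol, coords, frag)
        if overlap < config.min_overlap:
            continue
        aligned, e = refine_pose(
            block.mol, aligned, receptor, config.weights,
            n_sweeps=4, use_rigid=False, frozen=frag_atoms,
        )
        if best is None or e < best.energy:
            best = GrowthState(
                mol=block.mol, coords=aligned, energy=e, route=(), seed_id=block.id
            )
    return best


def _evaluate_product(
    rec: ProductRecord,
    state: GrowthState,
    target: InteractionTarget,
    frag: PreservedFragment,
    receptor: Receptor,
    config: GrowthConfig,
) -> GrowthState | None:
    """Best-GE conformer of one product that passes the direction check;
    None when no conformer qualifies or GE fails the threshold."""
    n_prev = state.mol.GetNumHeavyAtoms()
    n_new = rec.product.GetNumHeavyAtoms()
    if n_new <= n_prev:
        return None
    new_atoms = frozenset(
        range(rec.product.GetNumAtoms())
    ) - frozenset(rec.inherited_coords)
    if not new_atoms:
        return None
    prev_best = state.best_distance(target)

    try:
        confs = generate_conformers(
            rec.product,
            k=config.n_conformers,
            seed=config.seed,
            inherited_coords=rec.inherited_coords,
        )
    except RxngrowError:
        return None

    frag_atoms = _fragment_atoms(rec.product, frag)
    best_ge, best_coords, best_e = None, None, None
    for coords in confs:
        try:
            aligned, overlap = align_to_preserved(rec.product, coords, frag)
        except RxngrowError:
            return None
        if overlap < config.min_overlap:
            continue
        aligned, e = refine_pose(
            rec.product, aligned, receptor, config.weights,
            n_sweeps=4, use_rigid=False, frozen=frag_atoms,
        )
        if not check_direction(rec.product, aligned, new_atoms, target, prev_best):
            continue
        ge = group_efficiency(e, state.energy, n_new, n_prev)
        if best_ge is None or ge < best_ge:
            best_ge, best_coords, best_e = ge, aligned, e
    if best_ge is None or not accepts_step(state.energy, best_e, n_prev, n_new, config):
        return None

    step = RouteStep(
        rule_id=rec.rule_id,
        rule_name=rec.rule_name,
        reactant_key=state.key,
        participant_id=rec.participant_id,
        product_key=rec.key,
    )
    satisfied = state.satisfied
    dists = np.linalg.norm(best_coords[sorted(new_atoms)] - target.anchor, axis=1)
    for idx, d in zip(sorted(new_atoms), dists):
        if d <= target.satisfied_radius and atom_compatible(
            rec.product, idx, target.kind
        ):
            satisfied = satisfied | {target.id}
            break
    return GrowthState(
        mol=rec.product,
        coords=best_coords,
        energy=best_e,
        route=state.route + (step,),
        seed_id=state.seed_id,
        satisfied=satisfied,
    )


def _beam_select(states: list[GrowthState], beam: int) -> list[GrowthState]:
    uniq: dict[str, GrowthState] = {}
    for s in states:
        k = s.key
        if k not in uniq or s.energy < uniq[k].energy:
            uniq[k] = s
    ordered = sorted(
        uniq.values(),
        key=lambda s: (s.energy, s.mol.GetNumHeavyAtoms(), _route_id(s.route)),
    )
    return ordered[:beam]


def _route_id(route: tuple[RouteStep, ...]) -> str:
    return "|".join(
        f"{s.rule_id}:{s.participant_id or ''}:{s.product_key}" for s in route
    )


def grow(
    seeds: list[BuildingBlock],
    targets: list[InteractionTarget],
    db: RuleDB,
    library: list[BuildingBlock],
    receptor: Receptor,
    frag: PreservedFragment,
    config: GrowthConfig = GrowthConfig(),
) -> list[CandidateCompound]:
    """Grow every seed toward the ordered interaction targets.

    Returns unfiltered, unranked candidates (every surviving beam state with
    its route); apply :func:`filter_candidates` and :func:`rank_candidates`
    downstream.
    """
    if not seeds:
        raise ValueError("no seeds supplied")
    candidates: list[CandidateCompound] = []
    matched_any = False

    for seed in seeds:
        state0 = _initial_state(seed, frag, receptor, config)
        if state0 is None:
            continue
        states = [state0]
        if targets and db.match_rules(seed.mol):
            matched_any = True

        for target in targets:
            for _ in range(config.steps_per_target):
                next_states: list[GrowthState] = list(states)
                stepped = False
                for state in states:
                    if target.id in state.satisfied:
                        continue
                    for rec in enumerate_products(
                        state.mol, db, library, reactant_coords=state.coords
                    ):
                        new_state = _evaluate_product(
                            rec, state, target, frag, receptor, config
                        )
                        if new_state is not None:
                            next_states.append(new_state)
                            stepped = True
                states = _beam_select(next_states, config.beam)
                if not stepped or all(target.id in s.satisfied for s in states):
                    break

        for s in states:
            candidates.append(
                CandidateCompound(state=s, descriptors=compute_descriptors(s.mol))
            )

    if targets and not matched_any:
        log.warning("no seed matched any reaction rule; returning seeds unchanged")

    # deduplicate across seeds, best energy wins
    by_key: dict[str, CandidateCompound] = {}
    for c in candidates:
        k = c.state.key
        if k not in by_key or c.state.energy < by_key[k].state.energy:
            by_key[k] = c
    return sorted(
        by_key.values(),
        key=lambda c: (c.state.energy, c.descriptors.heavy_atom_count, c.state.key),
    )


def filter_candidates(
    cands: list[CandidateCompound], config: GrowthConfig = GrowthConfig()
) -> list[CandidateCompound]:
    """Keep candidates with MW strictly below ``mw_max`` and cLogP strictly
    below ``clogp_max``."""
    return [
        c
        for c in cands
        if c.descriptors.molecular_weight < config.mw_max
        and c.descriptors.clogp < config.clogp_max
    ]


def rank_candidates(
    cands: list[CandidateCompound],
    receptor: Receptor,
    config: GrowthConfig = GrowthConfig(),
) -> list[CandidateCompound]:
    """Locally refine each pose on the scorer, then sort by ascending refined
    energy (ties: fewer heavy atoms, then canonical key)."""
    out = []
    for c in cands:
        coords, energy = refine_pose(
            c.state.mol, c.state.coords, receptor, config.weights
        )
        state = replace(c.state, coords=coords, energy=energy)
        out.append(
            CandidateCompound(
                state=state, descriptors=c.descriptors, refined_energy=energy
            )
        )
    out.sort(
        key=lambda c: (
            c.refined_energy,
            c.descriptors.heavy_atom_count,
            c.state.key,
        )
    )
    for i, c in enumerate(out):
        c.rank = i + 1
    return out


# ---------------------------------------------------------------------------
# route export / replay


def export_route(cand: CandidateCompound) -> dict:
    """Machine-readable synthetic route for one candidate."""
    return {
        "seed": cand.state.seed_id,
        "final_key": cand.state.key,
        "rank": cand.rank,
        "energy": None if cand.refined_energy is None else round(cand.refined_energy, 6),
        "molecular_weight": round(cand.descriptors.molecular_weight, 3),
        "clogp": round(cand.descriptors.clogp, 4),
        "steps": [
            {
                "rule_id": s.rule_id,
                "rule_name": s.rule_name,
                "reactant_key": s.reactant_key,
                "participant_id": s.participant_id,
                "product_key": s.product_key,
            }
            for s in cand.state.route
        ],
    }


def route_to_text(doc: dict) -> str:
    lines = [f"candidate {doc['final_key']} (seed {doc['seed']})"]
    if not doc["steps"]:
        lines.append("  no reaction steps (seed emitted unchanged)")
    for i, s in enumerate(doc["steps"], 1):
        part = f" + {s['participant_id']}" if s["participant_id"] else ""
        lines.append(
            f"  step {i}: [{s['rule_name']}] {s['reactant_key']}{part}"
            f" -> {s['product_key']}"
        )
    return "\n".join(lines)


def replay_route(
    doc: dict,
    seed_mol: Chem.Mol,
    db: RuleDB,
    library: list[BuildingBlock],
) -> Chem.Mol:
    """Re-execute an exported route through virtual synthesis; raises
    :class:`RouteReplayError` on any mismatch."""
    mol = seed_mol
    if canonical_key(mol) != (
        doc["steps"][0]["reactant_key"] if doc["steps"] else doc["final_key"]
    ):
        raise RouteReplayError("seed molecule does not match the route's start")
    for i, step in enumerate(doc["steps"]):
        recs = [
            r
            for r in enumerate_products(mol, db, library)
            if r.rule_id == step["rule_id"]
            and r.participant_id == step["participant_id"]
            and r.key == step["product_key"]
        ]
        if not recs:
            raise RouteReplayError(
                f"step {i + 1} of route to {doc['final_key']} is not reproducible"
            )
        mol = recs[0].product
    if canonical_key(mol) != doc["final_key"]:
        raise RouteReplayError(f"route replay ended at {canonical_key(mol)}")
    return mol


def routes_json(cands: list[CandidateCompound]) -> str:
    return json.dumps([export_route(c) for c in cands], indent=1, sort_keys=True)
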