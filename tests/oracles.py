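"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit Python loops, exhaustive
enumeration) and shares no code path with the routines it checks.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

# standard atomic weights for the molecules used in the fixtures
ATOMIC_WEIGHT = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
}


def brute_molecular_weight(mol: Chem.Mol) -> float:
    total = 0.0
    for atom in mol.GetAtoms():
        total += ATOMIC_WEIGHT[atom.GetSymbol()]
        total += ATOMIC_WEIGHT["H"] * atom.GetTotalNumHs()
    return total


def brute_heavy_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def brute_embeddings(pat_g, host_g) -> list[dict]:
    """Exhaustive subgraph-monomorphism enumeration by backtracking over all
    candidate assignments (only viable for small graphs)."""
    pat_nodes = list(pat_g.nodes)
    host_nodes = list(host_g.nodes)
    out: list[dict] = []

    def node_ok(p, h):
        hp, pp = host_g.nodes[h], pat_g.nodes[p]
        if (
            hp["element"] != pp["element"]
            or hp["charge"] != pp["charge"]
            or hp["aromatic"] != pp["aromatic"]
        ):
            return False
        if pp.get("relaxed", False):
            if pp["sp3c"] and not hp["sp3c"]:
                return False
            return True
        return hp["n_h"] == pp["n_h"] and hp["degree"] == pp["degree"]

    def extend(assign: dict):
        if len(assign) == len(pat_nodes):
            out.append(dict(assign))
            return
        p = pat_nodes[len(assign)]
        for h in host_nodes:
            if h in assign.values() or not node_ok(p, h):
                continue
            ok = True
            for q, hq in assign.items():
                pe = pat_g.get_edge_data(p, q)
                he = host_g.get_edge_data(h, hq)
                if pe is not None and (he is None or he["order"] != pe["order"]):
                    ok = False
                    break
                # monomorphism: host may have extra edges
            if ok:
                assign[p] = h
                extend(assign)
                del assign[p]

    extend({})
    return out


def brute_score(mol: Chem.Mol, coords: np.ndarray, receptor, weights) -> float:
    """O(n*m) pairwise re-implementation of the pose scorer."""

    def hbond(d):
        if d < 2.2 or d >= 4.0:
            return 0.0
        if d < 2.6:
            return -(d - 2.2) / 0.4
        if d <= 3.2:
            return -1.0
        return -(4.0 - d) / 0.8

    def phobic(d):
        if d <= 4.5:
            return -1.0
        if d >= 5.5:
            return 0.0
        return -(5.5 - d)

    pt = Chem.GetPeriodicTable()
    lig_don = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs() >= 1
    ]
    lig_acc = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)]
    lig_c = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]

    e = 0.0
    for i in lig_don:
        for j in receptor.acceptors:
            e += weights.hbond * hbond(
                float(np.linalg.norm(coords[i] - receptor.coords[j]))
            )
    for i in lig_acc:
        for j in receptor.donors:
            e += weights.hbond * hbond(
                float(np.linalg.norm(coords[i] - receptor.coords[j]))
            )
    for i in lig_c:
        for j in receptor.hydrophobic:
            e += weights.hydrophobic * phobic(
                float(np.linalg.norm(coords[i] - receptor.coords[j]))
            )
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        ri = pt.GetRvdw(atom.GetAtomicNum())
        for j, el in enumerate(receptor.elements):
            rj = pt.GetRvdw(pt.GetAtomicNumber(el))
            d = float(np.linalg.norm(coords[i] - receptor.coords[j]))
            if d < 0.8 * (ri + rj):
                e += weights.clash * 5.0
    return e
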