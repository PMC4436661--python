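"""Steric clash detection and the clashes-per-1000-atoms score.

A clash is a non-bonded atom pair whose van der Waals spheres interpenetrate
by at least ``threshold`` (0.4 A by default): overlap = r_a + r_b - d.
Excluded from consideration are pairs connected by up to three covalent
bonds (within a residue, or across the O3'(i)-P(i+1) backbone linkage) and
nitrogen/oxygen pairs at hydrogen-bonding distance (>= 2.6 A), which are
treated as hydrogen bonds rather than collisions.

The score is 1000 x clashes / atoms over all retained atoms.  Full clash
analysers place hydrogens and score probe dots; this implementation scores
the atoms actually present, so values on hydrogen-free coordinates are an
approximation to such tools and the hydrogen status is carried in reports.

Neighbour search uses a KD-tree; a brute-force all-pairs route is kept as
an exact cross-check (``brute_force=True``) and the two must agree on every
input by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, StructureModel

__all__ = ["VDW_RADII", "ClashRecord", "find_clashes", "clash_score"]

#: van der Waals radii, A.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "H": 1.20}
_DEFAULT_RADIUS = 1.70

#: Covalent bonds of the sugar-phosphate moiety (every nucleotide).
_BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
    ("C4'", "C3'"), ("C4'", "O4'"), ("C3'", "O3'"), ("C3'", "C2'"),
    ("C2'", "C1'"), ("C2'", "O2'"), ("C1'", "O4'"),
]

_BASE_BONDS = {
    "A": [("C1'", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"),
          ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "N9"),
          ("C4", "C5"), ("C6", "N6")],
    "G": [("C1'", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"),
          ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "N9"),
          ("C4", "C5"), ("C6", "O6"), ("C2", "N2")],
    "C": [("C1'", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
          ("C5", "C6"), ("C6", "N1"), ("C2", "O2"), ("C4", "N4")],
    "U": [("C1'", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
          ("C5", "C6"), ("C6", "N1"), ("C2", "O2"), ("C4", "O4")],
}


@dataclass(frozen=True)
class ClashRecord:
    """One overlapping non-bonded atom pair."""

    atom_a: tuple   # (residue key, atom name)
    atom_b: tuple
    distance: float
    overlap: float


def _bond_graph(model: StructureModel):
    """Adjacency over (residue_key, atom_name) nodes: residue-internal bonds,
    the inter-residue O3'-P linkage, and hydrogens bonded to their nearest
    heavy atom."""
    adj: dict[tuple, set] = {}

    def add(u, v):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    for _, residues in model.chains:
        for idx, res in enumerate(residues):
            names = {a.name for a in res.atoms}
            bonds = _BACKBONE_BONDS + _BASE_BONDS.get(res.base_type or "", [])
            for u, v in bonds:
                if u in names and v in names:
                    add((res.key, u), (res.key, v))
            heavies = [a for a in res.atoms if a.element != "H"]
            for a in res.atoms:
                if a.element == "H" and heavies:
                    nearest = min(heavies, key=lambda h: np.linalg.norm(h.position - a.position))
                    add((res.key, a.name), (res.key, nearest.name))
            if idx + 1 < len(residues):
                nxt = residues[idx + 1]
                if res.atom("O3'") is not None and nxt.atom("P") is not None:
                    add((res.key, "O3'"), (nxt.key, "P"))
    return adj


def _within_k_bonds(adj, start, k=3) -> set:
    seen = {start}
    frontier = {start}
    for _ in range(k):
        nxt = set()
        for node in frontier:
            nxt |= adj.get(node, set())
        nxt -= seen
        seen |= nxt
        frontier = nxt
    return seen


def find_clashes(
    model: StructureModel,
    threshold: float = 0.4,
    hbond_exemption: bool = True,
    brute_force: bool = False,
) -> list[ClashRecord]:
    """All non-excluded atom pairs with vdW overlap >= ``threshold``."""
    atoms = []
    for res in model.residues:
        for a in res.atoms:
            atoms.append((res.key, a))
    if not atoms:
        return []
    coords = np.array([a.position for _, a in atoms])
    radii = np.array([VDW_RADII.get(a.element, _DEFAULT_RADIUS) for _, a in atoms])
    adj = _bond_graph(model)
    near = {node: _within_k_bonds(adj, node) for node in adj}

    max_reach = 2 * radii.max() - threshold
    if brute_force:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        ii, jj = np.nonzero(np.triu(d <= max_reach, k=1))
        candidates = zip(ii.tolist(), jj.tolist())
    else:
        tree = cKDTree(coords)
        candidates = sorted(tree.query_pairs(max_reach))

    out = []
    for i, j in candidates:
        key_i, ai = atoms[i]
        key_j, aj = atoms[j]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        overlap = float(radii[i] + radii[j] - d)
        if overlap < threshold - 1e-9:  # tolerance keeps exact-boundary overlaps in
            continue
        node_i, node_j = (key_i, ai.name), (key_j, aj.name)
        if node_j in near.get(node_i, ()):  # covalently 1-2/1-3/1-4 related
            continue
        if (
            hbond_exemption
            and ai.element in ("N", "O")
            and aj.element in ("N", "O")
            and d >= 2.6
        ):
            continue
        out.append(ClashRecord(atom_a=node_i, atom_b=node_j, distance=d, overlap=overlap))
    return out


def clash_score(model: StructureModel, threshold: float = 0.4, **kwargs) -> float:
    """Clashes per 1000 retained atoms."""
    if model.atom_count == 0:
        raise ValueError("empty model")
    clashes = find_clashes(model, threshold=threshold, **kwargs)
    return 1000.0 * len(clashes) / model.atom_count


def clashes_to_csv(records: list[ClashRecord]) -> str:
    lines = ["residue_a,atom_a,residue_b,atom_b,distance,overlap"]
    for r in records:
        (ka, na), (kb, nb) = r.atom_a, r.atom_b
        lines.append(
            f"{ka[0]}:{ka[1]}{ka[2]},{na},{kb[0]}:{kb[1]}{kb[2]},{nb},"
            f"{r.distance:.4f},{r.overlap:.4f}"
        )
    return "\n".join(lines) + "\n"


# referenced from __all__ consumers
__all__.append("clashes_to_csv")
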