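"""Optimal rigid-body superposition and RMSD.

RMSD is the primary ranking statistic for predicted models: the root mean
square distance between paired atoms after the least-squares rigid motion
(Kabsch, via SVD with the reflection branch excluded) has been applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspondence import ResidueCorrespondence
from .structure_io import StructureModel

__all__ = [
    "Superposition",
    "ATOM_SELECTIONS",
    "paired_atoms",
    "kabsch_superpose",
    "rmsd_between",
]

#: Named atom subsets for superposition.  ``None`` means every heavy atom.
ATOM_SELECTIONS: dict[str, frozenset | None] = {
    "all-heavy": None,
    "backbone": frozenset({"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"}),
    "c1-prime": frozenset({"C1'"}),
    "phosphate": frozenset({"P"}),
}


@dataclass
class Superposition:
    """Least-squares rigid motion mapping one point set onto another."""

    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # 3-vector, A
    rmsd: float               # A
    atom_pairs_used: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply ``x -> R x + t`` to an (n, 3) array."""
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def paired_atoms(
    reference: StructureModel,
    model: StructureModel,
    correspondence: ResidueCorrespondence,
    selection: str = "all-heavy",
):
    """Coordinate lists for atoms shared by each paired residue.

    For every residue pair, atoms present in both residues under the
    selection are collected in deterministic order (residue order, then
    atom name).  Returns ``(ref_coords, model_coords, names)`` where names
    are ``(residue_key, atom_name)`` tuples on the reference side.
    """
    if selection not in ATOM_SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}; one of {sorted(ATOM_SELECTIONS)}")
    wanted = ATOM_SELECTIONS[selection]
    ref_pts, mod_pts, names = [], [], []
    for ref_key, mod_key in correspondence.pairs:
        r_ref = reference.residue(ref_key)
        r_mod = model.residue(mod_key)
        common = sorted(
            {a.name for a in r_ref.atoms if a.element != "H"}
            & {a.name for a in r_mod.atoms if a.element != "H"}
        )
        for name in common:
            if wanted is not None and name not in wanted:
                continue
            ref_pts.append(r_ref.atom(name).position)
            mod_pts.append(r_mod.atom(name).position)
            names.append((ref_key, name))
    if not ref_pts:
        raise ValueError("zero common atoms under the requested selection")
    return np.array(ref_pts), np.array(mod_pts), names


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares rigid motion mapping point set ``Q`` onto ``P``.

    Reflections are excluded: the rotation determinant is forced to +1 by
    flipping the smallest singular direction when necessary.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise ValueError("need two equal (n>=3, 3) coordinate arrays")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate sets leave the in-plane rotation under-determined
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, atom_pairs_used=len(P))


def rmsd_between(
    reference: StructureModel,
    model: StructureModel,
    correspondence: ResidueCorrespondence,
    selection: str = "all-heavy",
) -> Superposition:
    """RMSD of ``model`` against ``reference`` over the paired atoms."""
    P, Q, _ = paired_atoms(reference, model, correspondence, selection)
    return kabsch_superpose(P, Q)
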