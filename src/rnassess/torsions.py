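"""Torsion-space comparison: backbone/glycosidic dihedrals, sugar
pseudorotation, and the Mean of Circular Quantities (MCQ).

A nucleotide contributes eight angular slots: the six backbone torsions
alpha..zeta, the glycosidic torsion chi, and the sugar pseudorotation phase
P computed from the five endocyclic torsions nu0..nu4.  MCQ-global is the
circular mean of the per-slot differences between two structures and lives
in [0, 180] degrees; MCQ-local keeps the raw per-slot differences.  Because
torsions are internal coordinates, MCQ needs no superposition and is
insensitive to rigid motion — a single local distortion moves only the
affected slots, unlike RMSD which it may dominate.

Interpretation bands carried into reports: a global MCQ below 15 degrees
indicates high similarity between large structures; above 45 degrees, an
overall dissimilarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .correspondence import ResidueCorrespondence
from .structure_io import Residue, StructureModel

__all__ = [
    "ANGLE_NAMES",
    "MCQ_SIMILAR_BELOW",
    "MCQ_DISSIMILAR_ABOVE",
    "TorsionTable",
    "McqResult",
    "dihedral",
    "compute_torsions",
    "circular_diff",
    "mcq_global",
    "mcq_local",
]

ANGLE_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi", "P")

#: Reported interpretation thresholds for global MCQ on large RNAs (degrees).
MCQ_SIMILAR_BELOW = 15.0
MCQ_DISSIMILAR_ABOVE = 45.0

# endocyclic sugar torsions nu0..nu4, all intra-residue
_NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


@dataclass
class TorsionTable:
    """Per-residue torsions in degrees; ``None`` marks an undefined slot."""

    residue_keys: list[tuple]
    angles: dict[tuple, dict[str, float | None]] = field(default_factory=dict)

    def value(self, key, name) -> float | None:
        return self.angles.get(key, {}).get(name)

    def defined_count(self) -> int:
        return sum(
            1 for key in self.residue_keys for n in ANGLE_NAMES if self.value(key, n) is not None
        )

    def to_rows(self):
        """Flat ``(residue, angle, value, defined)`` rows for CSV export."""
        rows = []
        for key in self.residue_keys:
            for name in ANGLE_NAMES:
                v = self.value(key, name)
                rows.append((f"{key[0]}:{key[1]}{key[2]}", name, v, v is not None))
        return rows


@dataclass
class McqResult:
    """Outcome of an MCQ-global comparison."""

    global_value: float          # degrees, [0, 180]
    per_residue: list            # (residue_key, angle, delta_degrees)
    angles_compared: int
    angles_skipped: int          # defined on one side only


def dihedral(p1, p2, p3, p4) -> float | None:
    """Signed torsion p1-p2-p3-p4 in degrees, (-180, 180]; atan2 form.

    Returns ``None`` for degenerate geometry (coincident points or a
    collinear triple), mirroring the undefined-slot convention.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def _pos(res: Residue | None, name: str):
    if res is None:
        return None
    a = res.atom(name)
    return None if a is None else a.position


def _torsion(atoms) -> float | None:
    if any(a is None for a in atoms):
        return None
    return dihedral(*atoms)


def _pseudorotation(res: Residue) -> float | None:
    """Pseudorotation phase P in [0, 360) from nu0..nu4.

    ``tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72))`` with
    the quadrant fixed by the sign of nu2 (the atan2 denominator carries it).
    """
    nus = []
    for quad in _NU_ATOMS:
        v = _torsion([_pos(res, n) for n in quad])
        if v is None:
            return None
        nus.append(v)
    nu0, nu1, nu2, nu3, nu4 = nus
    num = (nu4 + nu1) - (nu3 + nu0)
    den = 2.0 * nu2 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    if abs(num) < 1e-12 and abs(den) < 1e-12:
        return None
    p = math.degrees(math.atan2(num, den))
    return p + 360.0 if p < 0 else p


def compute_torsions(model: StructureModel) -> TorsionTable:
    """All eight angular slots per residue, with defined/undefined flags.

    Chain-terminal slots that span a missing neighbour (alpha and beta at
    the 5' end, epsilon and zeta at the 3' end) come out undefined, as do
    slots whose constituent atoms are absent.
    """
    table = TorsionTable(residue_keys=[])
    for _, residues in model.chains:
        for i, res in enumerate(residues):
            prev = residues[i - 1] if i > 0 else None
            nxt = residues[i + 1] if i + 1 < len(residues) else None
            n_gly = res.glycosidic_nitrogen
            chi_tail = ("C4",) if res.is_purine else ("C2",)
            angles = {
                "alpha": _torsion(
                    [_pos(prev, "O3'"), _pos(res, "P"), _pos(res, "O5'"), _pos(res, "C5'")]
                ),
                "beta": _torsion(
                    [_pos(res, "P"), _pos(res, "O5'"), _pos(res, "C5'"), _pos(res, "C4'")]
                ),
                "gamma": _torsion(
                    [_pos(res, "O5'"), _pos(res, "C5'"), _pos(res, "C4'"), _pos(res, "C3'")]
                ),
                "delta": _torsion(
                    [_pos(res, "C5'"), _pos(res, "C4'"), _pos(res, "C3'"), _pos(res, "O3'")]
                ),
                "epsilon": _torsion(
                    [_pos(res, "C4'"), _pos(res, "C3'"), _pos(res, "O3'"), _pos(nxt, "P")]
                ),
                "zeta": _torsion(
                    [_pos(res, "C3'"), _pos(res, "O3'"), _pos(nxt, "P"), _pos(nxt, "O5'")]
                ),
                "chi": _torsion(
                    [_pos(res, "O4'"), _pos(res, "C1'"), _pos(res, n_gly), _pos(res, chi_tail[0])]
                ),
                "P": _pseudorotation(res),
            }
            table.residue_keys.append(res.key)
            table.angles[res.key] = angles
    return table


def circular_diff(t1: float, t2: float) -> float:
    """Absolute angular difference in degrees, [0, 180]."""
    d = abs(t1 - t2) % 360.0
    return 360.0 - d if d > 180.0 else d


def _comparable_slots(reference: TorsionTable, model: TorsionTable, correspondence=None):
    """Yield ``(ref_key, angle, ref_value, model_value)`` for slots defined on
    both sides; count slots defined on one side only."""
    if correspondence is None:
        mapping = [(k, k) for k in reference.residue_keys]
    else:
        mapping = correspondence.pairs
    deltas, skipped = [], 0
    for rk, mk in mapping:
        for name in ANGLE_NAMES:
            a = reference.value(rk, name)
            b = model.value(mk, name)
            if a is None and b is None:
                continue
            if a is None or b is None:
                skipped += 1
                continue
            deltas.append((rk, name, a, b))
    return deltas, skipped


def mcq_global(
    reference: TorsionTable,
    model: TorsionTable,
    correspondence: ResidueCorrespondence | None = None,
    aggregation: str = "circular",
) -> McqResult:
    """MCQ-global: mean dissimilarity of the two torsion tables, [0, 180] deg.

    The default aggregation is the circular mean of the per-slot differences
    (atan2 of averaged sines and cosines); ``aggregation="arithmetic"`` takes
    the plain arithmetic mean instead.  Slots defined on only one side are
    excluded from the mean and reported in ``angles_skipped``.
    """
    slots, skipped = _comparable_slots(reference, model, correspondence)
    if not slots:
        raise ValueError("zero comparable torsion slots")
    deltas = [(rk, name, circular_diff(a, b)) for rk, name, a, b in slots]
    vals = np.radians([d for _, _, d in deltas])
    if aggregation == "circular":
        value = math.degrees(math.atan2(float(np.mean(np.sin(vals))), float(np.mean(np.cos(vals)))))
        value = abs(value)  # deltas lie in [0, 180] so the mean does too
    elif aggregation == "arithmetic":
        value = float(np.degrees(np.mean(vals)))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return McqResult(
        global_value=value,
        per_residue=deltas,
        angles_compared=len(deltas),
        angles_skipped=skipped,
    )


def mcq_local(
    reference: TorsionTable,
    model: TorsionTable,
    correspondence: ResidueCorrespondence | None = None,
):
    """Raw per-slot circular differences (MCQ-local); no averaging.

    Returns ``(rows, skipped)`` where rows are ``(ref_key, angle, delta)``
    and ``skipped`` counts slots defined on one side only.
    """
    slots, skipped = _comparable_slots(reference, model, correspondence)
    return [(rk, name, circular_diff(a, b)) for rk, name, a, b in slots], skipped
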