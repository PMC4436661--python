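"""Geometric annotation of base pairs and stacking contacts.

Base pairs are classified in the Leontis-Westhof scheme: each base engages
one of three edges (Watson-Crick, Hoogsteen, or Sugar) and the glycosidic
bonds are in cis or trans orientation.  A pair is *canonical* when both
edges are Watson-Crick, the orientation is cis, and the base combination is
AU, GC, or GU (the wobble pair is counted on the Watson-Crick side by
default, with a switch for the stricter convention).

Detection is purely geometric, driven by one block of thresholds
(:class:`AnnotationConfig`) so the detector can be calibrated against a
reference annotator: hydrogen-bond-range donor/acceptor contacts between
edge atoms, near-coplanarity of the base planes, a bounded vertical offset,
and a bounded separation of base centroids.  Stacking asks the converse:
parallel planes at ring-contact distance with the centroid-centroid vector
near a plane normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Residue, StructureModel

__all__ = [
    "AnnotationConfig",
    "BaseFrame",
    "BasePair",
    "StackingContact",
    "InteractionSet",
    "base_frame",
    "detect_base_pairs",
    "detect_stacking",
    "interactions_of",
]

#: Base ring atoms used for the plane fit and centroid.
RING_ATOMS = {
    "purine": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "pyrimidine": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Edge atoms per base (heavy donors/acceptors facing each edge).
EDGE_ATOMS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"W": ("N1", "N6"), "H": ("N7", "N6"), "S": ("N3", "C2")},
    "G": {"W": ("N1", "N2", "O6"), "H": ("N7", "O6"), "S": ("N3", "N2")},
    "C": {"W": ("N3", "O2", "N4"), "H": ("N4", "C5"), "S": ("O2",)},
    "U": {"W": ("N3", "O2", "O4"), "H": ("O4", "C5"), "S": ("O2",)},
}

_CANONICAL_COMBOS = {frozenset(("A", "U")), frozenset(("G", "C"))}
_WOBBLE = frozenset(("G", "U"))


@dataclass
class AnnotationConfig:
    """Geometric thresholds; one block so calibration happens in one place."""

    contact_cutoff: float = 3.5      # A, donor-acceptor contact
    tight_contact_cutoff: float = 3.2  # A, sufficient as a single contact
    min_contacts: int = 2            # contacts needed at the loose cutoff
    plane_angle_max: float = 65.0    # deg between base planes
    vertical_offset_max: float = 2.5  # A, origin out of partner plane
    origin_distance_max: float = 12.0  # A between base centroids
    stack_distance_max: float = 5.5  # A between centroids
    stack_plane_angle_max: float = 30.0  # deg between normals
    stack_rise_angle_max: float = 40.0   # deg, centroid vector vs normal
    wobble_is_canonical: bool = True


@dataclass
class BaseFrame:
    """Orthonormal reference frame of one base."""

    origin: np.ndarray   # ring-atom centroid
    x_axis: np.ndarray   # toward the glycosidic nitrogen, in-plane
    y_axis: np.ndarray
    z_axis: np.ndarray   # best-fit plane normal, ring-traversal handedness
    plane_rms: float     # A, residual of the plane fit


@dataclass(frozen=True)
class BasePair:
    residue_i: tuple
    residue_j: tuple
    edge_i: str          # W | H | S
    edge_j: str
    orientation: str     # cis | trans
    canonical_wc: bool


@dataclass(frozen=True)
class StackingContact:
    residue_i: tuple
    residue_j: tuple


@dataclass
class InteractionSet:
    """Annotated pairs and stacks of one structure."""

    pairs: list[BasePair] = field(default_factory=list)
    stacks: list[StackingContact] = field(default_factory=list)
    source_label: str = ""
    unannotatable: list[tuple] = field(default_factory=list)

    def pair_keys(self) -> set[frozenset]:
        return {frozenset((p.residue_i, p.residue_j)) for p in self.pairs}

    def stack_keys(self) -> set[frozenset]:
        return {frozenset((s.residue_i, s.residue_j)) for s in self.stacks}

    def to_csv(self) -> str:
        lines = ["residue_i,residue_j,type,edge_i,edge_j,orientation"]
        for p in self.pairs:
            kind = "wc" if p.canonical_wc else "nwc"
            lines.append(
                f"{_fmt(p.residue_i)},{_fmt(p.residue_j)},{kind},"
                f"{p.edge_i},{p.edge_j},{p.orientation}"
            )
        for s in self.stacks:
            lines.append(f"{_fmt(s.residue_i)},{_fmt(s.residue_j)},stack,,,")
        return "\n".join(lines) + "\n"


def _fmt(key) -> str:
    return f"{key[0]}:{key[1]}{key[2]}"


def base_frame(res: Residue) -> BaseFrame | None:
    """Centroid + orthonormal axes of the base ring; ``None`` when ring
    atoms are missing (the residue is then unannotatable)."""
    ring = RING_ATOMS["purine" if res.is_purine else "pyrimidine"]
    coords = []
    for name in ring:
        a = res.atom(name)
        if a is None:
            return None
        coords.append(a.position)
    coords = np.array(coords)
    origin = coords.mean(axis=0)
    centred = coords - origin
    # plane normal by SVD; handedness fixed by the ring traversal so the
    # frame co-rotates with the structure
    _, svals, Vt = np.linalg.svd(centred)
    normal = Vt[2]
    winding = np.zeros(3)
    for k in range(len(centred)):
        winding += np.cross(centred[k], centred[(k + 1) % len(centred)])
    if np.dot(winding, normal) < 0:
        normal = -normal
    plane_rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    n_gly = res.atom(res.glycosidic_nitrogen)
    if n_gly is None:
        return None
    x = n_gly.position - origin
    x = x - np.dot(x, normal) * normal
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        return None
    x /= nx
    y = np.cross(normal, x)
    return BaseFrame(origin=origin, x_axis=x, y_axis=y, z_axis=normal, plane_rms=plane_rms)


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return math.degrees(math.acos(c))


def _edge_contacts(ri: Residue, rj: Residue, cfg: AnnotationConfig):
    """Donor/acceptor contacts between edge atoms of the two bases.

    Returns ``(contacts, per_edge_i, per_edge_j)`` where ``contacts`` is the
    list of (distance, edge_i, edge_j) under the loose cutoff and the
    per-edge dicts count contributions for edge assignment.
    """
    contacts = []
    counts_i = {"W": 0, "H": 0, "S": 0}
    counts_j = {"W": 0, "H": 0, "S": 0}
    for ei, names_i in EDGE_ATOMS[ri.base_type].items():
        for ni in names_i:
            ai = ri.atom(ni)
            if ai is None or ai.element not in ("N", "O"):
                continue
            for ej, names_j in EDGE_ATOMS[rj.base_type].items():
                for nj in names_j:
                    aj = rj.atom(nj)
                    if aj is None or aj.element not in ("N", "O"):
                        continue
                    d = float(np.linalg.norm(ai.position - aj.position))
                    if d <= cfg.contact_cutoff:
                        contacts.append((d, ei, ej))
                        counts_i[ei] += 1
                        counts_j[ej] += 1
    return contacts, counts_i, counts_j


def _best_edge(counts: dict) -> str:
    # max contacts; ties broken by fixed priority W > H > S
    return max(("W", "H", "S"), key=lambda e: (counts[e], -("WHS".index(e))))


def detect_base_pairs(model: StructureModel, config: AnnotationConfig | None = None):
    """Emit one :class:`BasePair` per interacting residue pair.

    Criteria (all must hold): hydrogen-bond-range donor/acceptor contacts
    between edge atoms (two at the loose cutoff or one at the tight one),
    base planes within ``plane_angle_max``, each centroid within
    ``vertical_offset_max`` of the partner plane, centroids within
    ``origin_distance_max``.  Sequence neighbours (i, i+1) in one chain are
    never base pairs.  Unannotatable residues are skipped and recorded.
    """
    cfg = config or AnnotationConfig()
    frames: dict[tuple, BaseFrame] = {}
    unannotatable: list[tuple] = []
    residues = model.residues
    for r in residues:
        f = base_frame(r)
        if f is None:
            unannotatable.append(r.key)
        else:
            frames[r.key] = f

    pairs: list[BasePair] = []
    order = {r.key: i for i, r in enumerate(residues)}
    for i in range(len(residues)):
        ri = residues[i]
        if ri.key not in frames:
            continue
        fi = frames[ri.key]
        for j in range(i + 1, len(residues)):
            rj = residues[j]
            if rj.key not in frames:
                continue
            if ri.chain_id == rj.chain_id and abs(order[rj.key] - order[ri.key]) == 1:
                continue  # covalent neighbours stack, never pair
            fj = frames[rj.key]
            sep = fj.origin - fi.origin
            if np.linalg.norm(sep) > cfg.origin_distance_max:
                continue
            if _plane_angle(fi.z_axis, fj.z_axis) > cfg.plane_angle_max:
                continue
            if abs(float(np.dot(sep, fi.z_axis))) > cfg.vertical_offset_max:
                continue
            if abs(float(np.dot(sep, fj.z_axis))) > cfg.vertical_offset_max:
                continue
            contacts, counts_i, counts_j = _edge_contacts(ri, rj, cfg)
            if not contacts:
                continue
            strong = min(d for d, _, _ in contacts) <= cfg.tight_contact_cutoff
            if len(contacts) < cfg.min_contacts and not strong:
                continue
            edge_i = _best_edge(counts_i)
            edge_j = _best_edge(counts_j)
            tor = _glycosidic_pseudo_dihedral(ri, rj)
            orientation = "cis" if tor is not None and abs(tor) <= 90.0 else "trans"
            combo = frozenset((ri.base_type, rj.base_type))
            canonical = (
                orientation == "cis"
                and edge_i == "W"
                and edge_j == "W"
                and (
                    combo in _CANONICAL_COMBOS
                    or (cfg.wobble_is_canonical and combo == _WOBBLE)
                )
            )
            pairs.append(
                BasePair(
                    residue_i=ri.key,
                    residue_j=rj.key,
                    edge_i=edge_i,
                    edge_j=edge_j,
                    orientation=orientation,
                    canonical_wc=canonical,
                )
            )
    return pairs, unannotatable


def _glycosidic_pseudo_dihedral(ri: Residue, rj: Residue) -> float | None:
    from .torsions import dihedral  # local import; torsions has no annotation dep

    c1i = ri.atom("C1'")
    c1j = rj.atom("C1'")
    ngi = ri.atom(ri.glycosidic_nitrogen)
    ngj = rj.atom(rj.glycosidic_nitrogen)
    if None in (c1i, c1j, ngi, ngj):
        return None
    return dihedral(c1i.position, ngi.position, ngj.position, c1j.position)


def detect_stacking(
    model: StructureModel,
    config: AnnotationConfig | None = None,
    exclude: set[frozenset] | None = None,
):
    """Stacking contacts: near-parallel base planes at ring-contact distance.

    ``exclude`` removes residue pairs already emitted as base pairs.
    """
    cfg = config or AnnotationConfig()
    exclude = exclude or set()
    residues = [r for r in model.residues]
    frames = {}
    for r in residues:
        f = base_frame(r)
        if f is not None:
            frames[r.key] = f
    stacks = []
    keys = [r.key for r in residues if r.key in frames]
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ki, kj = keys[a], keys[b]
            if frozenset((ki, kj)) in exclude:
                continue
            fi, fj = frames[ki], frames[kj]
            sep = fj.origin - fi.origin
            d = float(np.linalg.norm(sep))
            if d > cfg.stack_distance_max or d < 1e-6:
                continue
            if _plane_angle(fi.z_axis, fj.z_axis) > cfg.stack_plane_angle_max:
                continue
            u = sep / d
            rise_i = _plane_angle(u, fi.z_axis)
            rise_j = _plane_angle(u, fj.z_axis)
            if min(rise_i, rise_j) > cfg.stack_rise_angle_max:
                continue
            stacks.append(StackingContact(residue_i=ki, residue_j=kj))
    return stacks


def interactions_of(model: StructureModel, config: AnnotationConfig | None = None) -> InteractionSet:
    """Aggregate base-pair and stacking detection, deterministic order."""
    cfg = config or AnnotationConfig()
    pairs, unannotatable = detect_base_pairs(model, cfg)
    stacks = detect_stacking(model, cfg, exclude={frozenset((p.residue_i, p.residue_j)) for p in pairs})
    return InteractionSet(
        pairs=pairs, stacks=stacks, source_label=model.label, unannotatable=unannotatable
    )
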