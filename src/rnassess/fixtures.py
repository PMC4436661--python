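"""Synthetic reference/decoy structures with known ground truth.

Every metric in this package is testable without downloading coordinates:
:func:`build_helix` constructs an ideal A-form duplex (or single strand)
from a template ribonucleotide propagated by helical symmetry (twist 32.7
degrees, rise 2.81 A per step — standard A-form fibre values), and
:func:`perturb` degrades a structure in three ways with exactly predictable
consequences:

* ``noise`` — i.i.d. Gaussian displacement of every coordinate; the
  expected all-atom RMSD against the parent is sigma * sqrt(3);
* ``rigid-domain`` — a rigid rotation/translation of a residue range,
  leaving internal coordinates (and hence torsions) of both bodies intact;
* ``bond-rotation`` — rotation of everything distal to one covalent bond,
  changing exactly the torsion centred on that bond.

The template nucleotide is generated in code, deterministically: base atoms
in their standard planar reference frames, a C3'-endo ribose ring closed
numerically, and the phosphate placed by closing the backbone across the
helical step (so O3'(i)-P(i+1) is a bond-length contact on both strands of
the duplex by symmetry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .structure_io import Atom, Residue, StructureModel

__all__ = [
    "PerturbationSpec",
    "build_helix",
    "build_trace",
    "perturb",
    "decoy_suite",
    "LARIAT_CAPPING_RIBOZYME_SEQ",
    "ADOCBL_RIBOSWITCH_SEQ",
    "TBOX_SEQ",
    "TRNA_SEQ",
]

# ---------------------------------------------------------------------------
# example sequences (targets of the blind-prediction round this tool serves)

#: Lariat-capping ribozyme, 188 nt.
LARIAT_CAPPING_RIBOZYME_SEQ = (
    "GGUUGGGUUGGGAAGUAUCAUGGCUAAUCACCAUGAUGCAAUCGGGUUGAACACUUAAUUGGGUUAAAACGG"
    "UGGGGGACGAUCCCGUAACAUCCGUCCUAACGGCGACAGACUGCACGGCCCUGCCUCUUAGGUGUGUUCAAU"
    "GAACAGUCGUUCCGAAAGGAAGCAUCCGGUAUCCCAAGACAAUC"
)

#: Adenosylcobalamin riboswitch, 168 nt.
ADOCBL_RIBOSWITCH_SEQ = (
    "CGGCAGGUGCUCCCGACCCUGCGGUCGGGAGUUAAAAGGGAAGCCGGUGCAAGUCCGGCACGGUCCCGCCAC"
    "UGUGACGGGGAGUCGCCCCUCGGGAUGUGCCACUGGCCCGAAGGCCGGGAAGGCGGAGGGGCGGCGAGGAUC"
    "CGGAGUCAGGAAACCUGCCUGCCG"
)

#: T-box riboswitch fragment, 96 nt.
TBOX_SEQ = (
    "UGCGAUGAGAAGAAGAGUAUUAAGGAUUUACUAUGAUUAGCGACUCUAGGAUAGUGAAAGCUAGAGGAUAGU"
    "AACCUUAAGAAGGCACUUCGAGCA"
)

#: tRNA (glycine acceptor), 75 nt.
TRNA_SEQ = (
    "GCGGAAGUAGUUCAGUGGUAGAACACCACCUUGCCAAGGUGGGGGUCGCGGGUUCGAAUCCCGUCUUCCGCUCCA"
)

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# ---------------------------------------------------------------------------
# geometry constants

#: A-form helical symmetry: twist per step (deg) and rise per step (A).
TWIST_DEG = 32.7
RISE = 2.81

#: Displacement of the base-pair frame from the helix axis along the pair
#: x-axis (A) and base-pair inclination about that axis (deg).  Calibrated
#: once so the generated duplex is clash-free and annotates cleanly.
PAIR_X_DISPLACEMENT = -5.0
PAIR_INCLINATION_DEG = 24.0

#: Glycosidic torsion chi of the template nucleotide (deg, anti).
CHI_TEMPLATE = -160.0

#: Sugar ring: circumradius (A), pucker amplitude (A), and ring phase (deg)
#: of the out-of-plane wave (sets the C3'-endo pucker).
RING_RADIUS = 1.24
PUCKER_AMPLITUDE = 0.38
RING_PHASE_DEG = 250.0

# exocyclic bond lengths (A)
BOND_C1N = 1.48
BOND_C2O2 = 1.42
BOND_C3O3 = 1.42
BOND_C4C5 = 1.51
BOND_O3P = 1.59
BOND_C5O5 = 1.42
BOND_POP = 1.48

#: Internal coordinates of O5': C4'-C5'-O5' angle and the gamma torsion
#: O5'-C5'-C4'-C3' (deg, A-form gauche+).
ANGLE_C4C5O5 = 110.0
GAMMA_TEMPLATE = 65.0

#: Which of the two free tetrahedral slots each exocyclic atom takes
#: (sugar-face choices; +1/-1 select opposite faces of the ring).
SLOT_SIGNS = {"N": -1, "O2'": -1, "O3'": -1, "C5'": +1}

#: Standard planar reference-frame coordinates of the base heavy atoms (A).
#: The Watson-Crick partner of a base is obtained by the 180-degree
#: rotation about the frame x-axis, (x, y, z) -> (x, -y, -z).
BASE_FRAMES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.0),
        "N9": (-1.291, 4.498, 0.0),
        "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0),
        "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0),
        "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0),
        "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0),
        "C4": (-1.267, 3.124, 0.0),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.0),
        "N9": (-1.289, 4.551, 0.0),
        "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0),
        "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0),
        "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0),
        "C2": (-1.999, 1.087, 0.0),
        "N2": (-2.949, 0.139, 0.0),
        "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.0),
        "N1": (-1.285, 4.542, 0.0),
        "C2": (-1.472, 3.158, 0.0),
        "O2": (-2.628, 2.709, 0.0),
        "N3": (-0.391, 2.344, 0.0),
        "C4": (0.837, 2.868, 0.0),
        "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0),
        "C6": (-0.023, 5.068, 0.0),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.0),
        "N1": (-1.284, 4.500, 0.0),
        "C2": (-1.462, 3.131, 0.0),
        "O2": (-2.563, 2.608, 0.0),
        "N3": (-0.302, 2.397, 0.0),
        "C4": (0.989, 2.884, 0.0),
        "O4": (1.935, 2.094, 0.0),
        "C5": (1.089, 4.311, 0.0),
        "C6": (-0.024, 5.053, 0.0),
    },
}

_ATOM_ORDER = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"]


def _unit(v):
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _rot_axis(axis, deg):
    """Rotation matrix about ``axis`` by ``deg`` degrees (Rodrigues)."""
    a = _unit(axis)
    t = math.radians(deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def _tetra_slots(center, n1, n2):
    """The two remaining tetrahedral bond directions at ``center`` whose
    known neighbours are ``n1`` and ``n2``."""
    u1 = _unit(n1 - center)
    u2 = _unit(n2 - center)
    c = float(np.dot(u1, u2))
    b = -_unit(u1 + u2)
    p = _unit(np.cross(u1, u2))
    cos_g = min(1.0, 1.0 / (3.0 * math.sqrt((1.0 + c) / 2.0)))
    g = math.acos(cos_g)
    return (math.cos(g) * b + math.sin(g) * p, math.cos(g) * b - math.sin(g) * p)


def _ribose_ring():
    """C3'-endo ribose ring atoms in a local frame: a regular pentagon of
    circumradius ``RING_RADIUS`` with a sinusoidal out-of-plane pucker."""
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    phase = math.radians(RING_PHASE_DEG)
    zamp = PUCKER_AMPLITUDE * math.sqrt(2.0 / 5.0)
    ring = {}
    for k, name in enumerate(names):
        a = 2.0 * math.pi * k / 5.0
        ring[name] = np.array(
            [RING_RADIUS * math.cos(a), RING_RADIUS * math.sin(a),
             zamp * math.cos(2.0 * a + phase)]
        )
    return ring


def _dihedral_deg(p1, p2, p3, p4):
    from .torsions import dihedral

    return dihedral(p1, p2, p3, p4)


def _build_nucleoside(base: str) -> dict[str, np.ndarray]:
    """Base (standard frame) + ribose with O2'/O3'/C5', chi set to
    ``CHI_TEMPLATE``.  Returns atom name -> coordinate in the pair frame."""
    atoms = {k: np.array(v) for k, v in BASE_FRAMES[base].items()}
    n_gly = "N9" if base in ("A", "G") else "N1"
    chi_tail = "C4" if base in ("A", "G") else "C2"
    ring = _ribose_ring()

    # glycosidic slot on C1'
    slots = _tetra_slots(ring["C1'"], ring["C2'"], ring["O4'"])
    d_n = slots[0] if SLOT_SIGNS["N"] > 0 else slots[1]

    # rigid placement: sugar C1' onto template C1', N-slot onto C1'->N axis
    c1_t = atoms["C1'"]
    d_t = _unit(atoms[n_gly] - c1_t)
    axis = np.cross(d_n, d_t)
    if np.linalg.norm(axis) < 1e-9:
        R1 = np.eye(3) if np.dot(d_n, d_t) > 0 else _rot_axis([1.0, 0.0, 0.0], 180.0)
    else:
        ang = math.degrees(math.acos(float(np.clip(np.dot(d_n, d_t), -1, 1))))
        R1 = _rot_axis(axis, ang)
    sugar = {k: R1 @ (v - ring["C1'"]) + c1_t for k, v in ring.items()}

    # spin about the glycosidic axis to reach the target chi
    def chi_of(s):
        return _dihedral_deg(s["O4'"], s["C1'"], atoms[n_gly], atoms[chi_tail])

    def spun(s, deg):
        R = _rot_axis(d_t, deg)
        return {k: R @ (v - c1_t) + c1_t for k, v in s.items()}

    cur = chi_of(sugar)
    for delta in (CHI_TEMPLATE - cur, cur - CHI_TEMPLATE):
        trial = spun(sugar, delta)
        if abs(_circ(chi_of(trial) - CHI_TEMPLATE)) < 1e-6:
            sugar = trial
            break

    # exocyclic substituents
    def place(center, nb1, nb2, sign, length):
        s = _tetra_slots(sugar[center], sugar[nb1], sugar[nb2])
        d = s[0] if sign > 0 else s[1]
        return sugar[center] + length * d

    out = dict(atoms)
    out.update({k: v for k, v in sugar.items() if k != "C1'"})
    out["C1'"] = sugar["C1'"]
    out["O2'"] = place("C2'", "C1'", "C3'", SLOT_SIGNS["O2'"], BOND_C2O2)
    out["O3'"] = place("C3'", "C2'", "C4'", SLOT_SIGNS["O3'"], BOND_C3O3)
    out["C5'"] = place("C4'", "C3'", "O4'", SLOT_SIGNS["C5'"], BOND_C4C5)
    return out


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _circ(d):
    d = (d + 180.0) % 360.0 - 180.0
    return d


def _helix_op(i: int):
    """Rotation/translation of helical step ``i``."""
    R = _rot_axis([0.0, 0.0, 1.0], TWIST_DEG * i)
    t = np.array([0.0, 0.0, RISE * i])
    return R, t


@lru_cache(maxsize=None)
def _strand_template(base: str) -> tuple:
    """Complete template nucleotide (strand 1) in helix coordinates,
    including the phosphate group closed across the helical step."""
    nuc = _build_nucleoside(base)
    W = _rot_axis([1.0, 0.0, 0.0], PAIR_INCLINATION_DEG)
    off = np.array([PAIR_X_DISPLACEMENT, 0.0, 0.0])
    t = {k: W @ v + off for k, v in nuc.items()}

    # The phosphate bridges the previous residue's O3' (one helical step
    # down, by symmetry the image of this template's own O3') and this
    # residue's O5'.  Both bridging bonds are made exact by placing P on
    # the intersection circle of the two bond spheres, taking the point
    # directed away from the sugar; if the spheres do not intersect the
    # C3'-O3' bond extension is used instead.
    Rh, th = _helix_op(1)
    t["O5'"] = _nerf(t["C3'"], t["C4'"], t["C5'"], BOND_C5O5, ANGLE_C4C5O5, GAMMA_TEMPLATE)
    prev_o3 = Rh.T @ (t["O3'"] - th)  # the O3' bonded to this P
    t["P"] = _bridge_point(prev_o3, BOND_O3P, t["O5'"], 1.60, away_from=t["C4'"])
    if t["P"] is None:
        ext = t["O3'"] + BOND_O3P * _unit(t["O3'"] - t["C3'"])
        t["P"] = Rh.T @ (ext - th)
    s1, s2 = _tetra_slots(t["P"], prev_o3, t["O5'"])
    t["OP1"] = t["P"] + BOND_POP * s1
    t["OP2"] = t["P"] + BOND_POP * s2
    return tuple((k, tuple(v)) for k, v in t.items())


def _bridge_point(a, ra_, b, rb, away_from):
    """Deterministic point at distance ``ra_`` from ``a`` and ``rb`` from
    ``b``, on the side facing away from ``away_from``; ``None`` when the
    spheres do not intersect."""
    u = b - a
    d = float(np.linalg.norm(u))
    if d < 1e-9 or d > ra_ + rb or d < abs(ra_ - rb):
        return None
    u /= d
    x = (ra_ ** 2 - rb ** 2 + d ** 2) / (2.0 * d)
    h2 = ra_ ** 2 - x ** 2
    if h2 < 0:
        return None
    centre = a + x * u
    w = centre - np.asarray(away_from, float)
    w = w - np.dot(w, u) * u
    n = np.linalg.norm(w)
    if n < 1e-9:
        w = np.cross(u, [0.0, 0.0, 1.0])
        n = np.linalg.norm(w)
    return centre + math.sqrt(h2) * (w / n)


def _template(base: str, flipped: bool) -> dict[str, np.ndarray]:
    t = {k: np.array(v) for k, v in _strand_template(base)}
    if flipped:
        F = np.diag([1.0, -1.0, -1.0])
        t = {k: F @ v for k, v in t.items()}
    return t


def _make_residue(chain_id: str, number: int, base: str, atoms: dict) -> Residue:
    alist = []
    order = _ATOM_ORDER + [n for n in atoms if n not in _ATOM_ORDER]
    for name in order:
        if name in atoms:
            alist.append(Atom(name=name, element=name[0], position=np.round(atoms[name], 6)))
    return Residue(chain_id=chain_id, number=number, base_type=base, res_name=base, atoms=alist)


def build_helix(sequence: str, duplex: bool = True, label: str = "helix") -> StructureModel:
    """Ideal A-form helix for ``sequence`` (chain A); with ``duplex`` the
    reverse complement is added as an antiparallel chain B so that every
    position forms one canonical Watson-Crick pair."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    bad = set(sequence) - set("ACGU")
    if bad:
        raise ValueError(f"sequence may contain only A/C/G/U, got {sorted(bad)}")
    n = len(sequence)
    chains = []
    res_a = []
    for i, letter in enumerate(sequence):
        R, t = _helix_op(i)
        atoms = {k: R @ v + t for k, v in _template(letter, flipped=False).items()}
        res_a.append(_make_residue("A", i + 1, letter, atoms))
    chains.append(("A", res_a))
    if duplex:
        res_b = []
        for k in range(n):
            i = n - 1 - k
            letter = COMPLEMENT[sequence[i]]
            R, t = _helix_op(i)
            atoms = {kk: R @ v + t for kk, v in _template(letter, flipped=True).items()}
            res_b.append(_make_residue("B", k + 1, letter, atoms))
        chains.append(("B", res_b))
    return StructureModel(label=label, chains=chains)


def build_trace(sequence: str, label: str = "trace") -> StructureModel:
    """Single-strand C1'-only trace of ``sequence`` — a minimal coordinate
    carrier for sequence-level operations."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    bad = set(sequence) - set("ACGU")
    if bad:
        raise ValueError(f"sequence may contain only A/C/G/U, got {sorted(bad)}")
    residues = []
    for i, letter in enumerate(sequence):
        R, t = _helix_op(i)
        c1 = R @ np.array(dict(_strand_template(letter))["C1'"]) + t
        residues.append(_make_residue("A", i + 1, letter, {"C1'": c1}))
    return StructureModel(label=label, chains=[("A", residues)])


# ---------------------------------------------------------------------------
# perturbations


@dataclass
class PerturbationSpec:
    """One deterministic structural perturbation.

    ``kind`` selects the mechanism; the relevant parameter block depends on
    it (sigma for ``noise``; residue range + rotation for ``rigid-domain``;
    bond + delta for ``bond-rotation``).  A fixed seed makes the output
    bit-stable.
    """

    kind: str                     # noise | rigid-domain | bond-rotation
    seed: int = 0
    sigma: float = 0.0            # A, per coordinate (noise)
    chain: str | None = None      # rigid-domain residue range
    start: int | None = None
    end: int | None = None
    axis_point: tuple = (0.0, 0.0, 0.0)
    axis_direction: tuple = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    translation: tuple = (0.0, 0.0, 0.0)
    bond: tuple | None = None     # (residue_key, atom_from, atom_to)
    delta_deg: float = 0.0

    def __post_init__(self):
        if self.kind not in ("noise", "rigid-domain", "bond-rotation"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


def perturb(model: StructureModel, spec: PerturbationSpec) -> StructureModel:
    """Apply ``spec`` to a copy of ``model`` (the input is not modified)."""
    import copy

    out = copy.deepcopy(model)
    if spec.kind == "noise":
        rng = np.random.default_rng(spec.seed)
        for res in out.residues:
            for a in res.atoms:
                a.position = a.position + rng.normal(0.0, spec.sigma, size=3)
    elif spec.kind == "rigid-domain":
        R = _rot_axis(spec.axis_direction, spec.angle_deg)
        p0 = np.asarray(spec.axis_point, float)
        tr = np.asarray(spec.translation, float)
        for res in out.residues:
            if spec.chain is not None and res.chain_id != spec.chain:
                continue
            if spec.start is not None and not (spec.start <= res.number <= (spec.end or spec.start)):
                continue
            for a in res.atoms:
                a.position = R @ (a.position - p0) + p0 + tr
    else:  # bond-rotation
        _rotate_about_bond(out, spec.bond, spec.delta_deg)
    return out


def _rotate_about_bond(model: StructureModel, bond, delta_deg: float) -> None:
    from .clash import _bond_graph

    res_key, name_from, name_to = bond
    adj = _bond_graph(model)
    u = (res_key, name_from)
    v = (res_key, name_to)
    if v not in adj.get(u, ()):  # not a covalent bond we know
        raise ValueError(f"no covalent bond {name_from}-{name_to} in residue {res_key}")
    # atoms distal to the bond: the component of v once the edge is cut;
    # reaching u again through another path means the bond closes a ring
    seen = {v}
    frontier = [v]
    distal = set()
    while frontier:
        node = frontier.pop()
        for nb in adj.get(node, ()):
            if nb == u and node == v:
                continue
            if nb == u:
                raise ValueError(f"bond {name_from}-{name_to} in {res_key} is inside a ring")
            if nb not in seen:
                seen.add(nb)
                distal.add(nb)
                frontier.append(nb)
    res = model.residue(res_key)
    p_from = res.atom(name_from).position
    p_to = res.atom(name_to).position
    R = _rot_axis(p_to - p_from, delta_deg)
    index = {r.key: r for r in model.residues}
    for key, aname in distal:
        a = index[key].atom(aname)
        a.position = R @ (a.position - p_from) + p_from


def decoy_suite(
    sequence: str,
    sigmas=(0.1, 0.5, 1.0),
    seeds=(0,),
    label: str = "decoy",
):
    """Graded noise decoys of the duplex for ``sequence``.

    Returns ``(reference, decoys)`` where each decoy is a dict holding the
    perturbed model and its analytic expectations (``expected_rmsd`` is
    sigma * sqrt(3) in the large-atom-count limit).
    """
    reference = build_helix(sequence, label=f"{label}-reference")
    decoys = []
    for sigma in sigmas:
        for seed in seeds:
            spec = PerturbationSpec(kind="noise", sigma=sigma, seed=seed)
            m = perturb(reference, spec)
            m.label = f"{label}-s{sigma}-r{seed}"
            decoys.append(
                {
                    "model": m,
                    "spec": spec,
                    "expected_rmsd": sigma * math.sqrt(3.0),
                    "sigma": sigma,
                    "seed": seed,
                }
            )
    return reference, decoys
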