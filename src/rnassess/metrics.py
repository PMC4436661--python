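"""Interaction Network Fidelity, Deformation Index, and Deformation Profile.

INF is the geometric mean of precision (PPV) and sensitivity (STY) of the
model's annotated interactions against the reference annotation,

    INF = sqrt( TP/(TP+FP) * TP/(TP+FN) ),

computed per category (canonical Watson-Crick pairs, non-WC pairs, stacking)
and pooled.  An empty reference category leaves that INF undefined (NA) —
"nothing to predict" is never conflated with "all wrong".

DI = RMSD / INF couples global geometric deviation with interaction
recovery; a model with perfect interactions keeps DI = RMSD, while poor
interaction recovery inflates it.

The Deformation Profile is an N x N matrix over paired nucleotides: row i
holds, under the superposition anchored on residue i alone, the mean atomic
distance of every other residue j.  Rows anchored inside a well-predicted
domain stay flat within it and jump at mispredicted regions, exposing
quality at multiple scales; named domains are summarised as min/mean/max
over their blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import InteractionSet
from .correspondence import ResidueCorrespondence
from .structure_io import StructureModel
from .superposition import kabsch_superpose

__all__ = [
    "CategoryCounts",
    "InfBreakdown",
    "Domain",
    "DeformationProfile",
    "match_interactions",
    "inf_score",
    "deformation_index",
    "deformation_profile",
]


@dataclass
class CategoryCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class InfBreakdown:
    """Per-category TP/FP/FN counts and INF values (``None`` = undefined)."""

    counts: dict[str, CategoryCounts]
    inf_all: float | None
    inf_wc: float | None
    inf_nwc: float | None
    inf_stack: float | None

    def inf(self, category: str) -> float | None:
        return {"all": self.inf_all, "wc": self.inf_wc, "nwc": self.inf_nwc,
                "stack": self.inf_stack}[category]


def inf_score(tp: int, fp: int, fn: int) -> float | None:
    """sqrt(PPV x STY); 0 when nothing was recovered; ``None`` (undefined)
    when the reference category is empty (tp + fn == 0)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0:
        return None
    if tp == 0:
        return 0.0
    ppv = tp / (tp + fp)
    sty = tp / (tp + fn)
    return math.sqrt(ppv * sty)


def match_interactions(
    reference_set: InteractionSet,
    model_set: InteractionSet,
    correspondence: ResidueCorrespondence,
    strict: bool = False,
) -> InfBreakdown:
    """Per-category TP/FP/FN between two interaction sets.

    Interactions are mapped through the correspondence onto reference keys.
    A base pair matches when its residue pair agrees; the category of a
    matched pair (canonical-WC vs non-WC) is taken from the *reference*
    annotation, and unmatched model pairs fall into the model's own
    category.  With ``strict=True`` a base-pair match additionally requires
    identical edges and orientation.  Interactions involving residues
    outside the correspondence count as FN (reference side) or FP (model
    side).  Stacking contacts match on the residue pair alone.
    """
    m2r = correspondence.model_to_ref
    ref_keys = set(correspondence.ref_to_model)

    def map_pair(p):
        ki, kj = m2r.get(p.residue_i), m2r.get(p.residue_j)
        if ki is None or kj is None:
            return None
        return frozenset((ki, kj))

    # reference pairs by residue-pair key
    ref_pairs = {}
    for p in reference_set.pairs:
        if p.residue_i in ref_keys and p.residue_j in ref_keys:
            ref_pairs[frozenset((p.residue_i, p.residue_j))] = p
    ref_out = [p for p in reference_set.pairs
               if p.residue_i not in ref_keys or p.residue_j not in ref_keys]

    model_pairs = {}
    model_out = []
    for p in model_set.pairs:
        k = map_pair(p)
        if k is None:
            model_out.append(p)
        else:
            model_pairs[k] = p

    counts = {c: CategoryCounts() for c in ("wc", "nwc", "stack")}

    def agrees(rp, mp) -> bool:
        if not strict:
            return True
        edges_r = (rp.edge_i, rp.edge_j)
        edges_m = (mp.edge_i, mp.edge_j)
        return rp.orientation == mp.orientation and (
            edges_r == edges_m or edges_r == edges_m[::-1]
        )

    matched_model = set()
    for k, rp in ref_pairs.items():
        cat = "wc" if rp.canonical_wc else "nwc"
        mp = model_pairs.get(k)
        if mp is not None and agrees(rp, mp):
            counts[cat].tp += 1
            matched_model.add(k)
        else:
            counts[cat].fn += 1
    for k, mp in model_pairs.items():
        if k in matched_model:
            continue
        cat = "wc" if mp.canonical_wc else "nwc"
        counts[cat].fp += 1
    for rp in ref_out:
        counts["wc" if rp.canonical_wc else "nwc"].fn += 1
    for mp in model_out:
        counts["wc" if mp.canonical_wc else "nwc"].fp += 1

    # stacking: residue-pair set comparison
    ref_stacks = set()
    fn_stack = 0
    for s in reference_set.stacks:
        if s.residue_i in ref_keys and s.residue_j in ref_keys:
            ref_stacks.add(frozenset((s.residue_i, s.residue_j)))
        else:
            fn_stack += 1
    model_stacks = set()
    fp_stack = 0
    for s in model_set.stacks:
        ki, kj = m2r.get(s.residue_i), m2r.get(s.residue_j)
        if ki is None or kj is None:
            fp_stack += 1
        else:
            model_stacks.add(frozenset((ki, kj)))
    counts["stack"].tp = len(ref_stacks & model_stacks)
    counts["stack"].fn = len(ref_stacks - model_stacks) + fn_stack
    counts["stack"].fp = len(model_stacks - ref_stacks) + fp_stack

    def pooled(attr):
        return sum(getattr(counts[c], attr) for c in counts)

    return InfBreakdown(
        counts=counts,
        inf_all=inf_score(pooled("tp"), pooled("fp"), pooled("fn")),
        inf_wc=inf_score(counts["wc"].tp, counts["wc"].fp, counts["wc"].fn),
        inf_nwc=inf_score(counts["nwc"].tp, counts["nwc"].fp, counts["nwc"].fn),
        inf_stack=inf_score(counts["stack"].tp, counts["stack"].fp, counts["stack"].fn),
    )


def deformation_index(rmsd: float, inf_value: float | None) -> float | None:
    """DI = RMSD / INF; undefined when INF is 0 or undefined."""
    if rmsd < 0:
        raise ValueError("rmsd must be nonnegative")
    if inf_value is None or inf_value == 0:
        return None
    return rmsd / inf_value


@dataclass(frozen=True)
class Domain:
    """Named residue range (1-based inclusive PDB numbering)."""

    name: str
    chain: str
    start: int
    end: int

    def contains(self, key) -> bool:
        return key[0] == self.chain and self.start <= key[1] <= self.end


@dataclass
class DeformationProfile:
    """Per-anchor mean residue distances; NaN rows mark unusable anchors."""

    residue_keys: list[tuple]
    values: np.ndarray                     # N x N, A
    domain_summaries: dict[str, dict] = field(default_factory=dict)

    def to_csv(self) -> str:
        labels = [f"{k[0]}:{k[1]}{k[2]}" for k in self.residue_keys]
        lines = ["anchor," + ",".join(labels)]
        for lab, row in zip(labels, self.values):
            cells = ["" if not np.isfinite(v) else f"{v:.4f}" for v in row]
            lines.append(lab + "," + ",".join(cells))
        return "\n".join(lines) + "\n"

    def summaries_to_csv(self) -> str:
        lines = ["domain,min,mean,max"]
        for name, s in self.domain_summaries.items():
            lines.append(f"{name},{s['min']:.4f},{s['mean']:.4f},{s['max']:.4f}")
        return "\n".join(lines) + "\n"


def deformation_profile(
    reference: StructureModel,
    model: StructureModel,
    correspondence: ResidueCorrespondence,
    anchor_selection: list[str] | None = None,
    domains: list[Domain] | None = None,
    window: int = 0,
) -> DeformationProfile:
    """The DP matrix: entry (i, j) is the mean distance over residue j's
    paired atoms after superposing the model on residue i's paired atoms.

    ``anchor_selection`` restricts which atom names anchor the per-residue
    fits (default: every heavy atom of the residue).  ``window`` widens the
    anchor to +-window sequence neighbours.  Anchors with fewer than three
    usable atoms give NaN rows and columns.
    """
    pairs = correspondence.pairs
    n = len(pairs)
    ref_coords: list[np.ndarray] = []
    mod_coords: list[np.ndarray] = []
    for rk, mk in pairs:
        r_ref = reference.residue(rk)
        r_mod = model.residue(mk)
        common = sorted(
            {a.name for a in r_ref.atoms if a.element != "H"}
            & {a.name for a in r_mod.atoms if a.element != "H"}
        )
        if anchor_selection is not None:
            anchor_names = [c for c in common if c in anchor_selection]
        else:
            anchor_names = common
        ref_coords.append((r_ref.coords(common), r_ref.coords(anchor_names)))
        mod_coords.append((r_mod.coords(common), r_mod.coords(anchor_names)))

    sizes = [len(rc[0]) for rc in ref_coords]
    all_ref = np.vstack([rc[0] for rc in ref_coords])
    all_mod = np.vstack([mc[0] for mc in mod_coords])
    bounds = np.cumsum([0] + sizes)

    values = np.full((n, n), np.nan)
    usable = []
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        P = np.vstack([ref_coords[k][1] for k in range(lo, hi)])
        Q = np.vstack([mod_coords[k][1] for k in range(lo, hi)])
        if len(P) < 3:
            continue
        try:
            sup = kabsch_superpose(P, Q)
        except ValueError:
            continue
        usable.append(i)
        moved = sup.transform(all_mod)
        dists = np.linalg.norm(moved - all_ref, axis=1)
        for j in range(n):
            seg = dists[bounds[j] : bounds[j + 1]]
            if len(seg):
                values[i, j] = float(seg.mean())
    # anchors that failed also blank out their measured column
    bad = [i for i in range(n) if i not in usable]
    for i in bad:
        values[:, i] = np.nan

    dp = DeformationProfile(residue_keys=[rk for rk, _ in pairs], values=values)
    for dom in domains or []:
        idx = [k for k, (rk, _) in enumerate(pairs) if dom.contains(rk)]
        block = values[np.ix_(idx, idx)]
        block = block[np.isfinite(block)]
        if block.size:
            dp.domain_summaries[dom.name] = {
                "min": float(block.min()),
                "mean": float(block.mean()),
                "max": float(block.max()),
            }
    return dp
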