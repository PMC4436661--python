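"""Full assessment pipeline: one scorecard per model, ranked.

:func:`assess_models` runs correspondence building, superposition,
annotation, INF/DI, MCQ, and Clash Score for each candidate model against
the reference and returns ranked :class:`MetricReport` rows, mirroring the
summary tables used to compare blind predictions: RMSD as the primary
ranking key (ascending), ties broken by DI and then by label.

Undefined quantities (an empty reference interaction category, a model
that failed to parse) are reported as NA, never as 0: "nothing to predict"
and "all wrong" are different outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import annotation, clash, metrics, torsions
from .correspondence import build_correspondence
from .structure_io import StructureModel, read_pdb
from .superposition import rmsd_between

__all__ = ["AssessmentConfig", "MetricReport", "assess_models", "assess_paths", "reports_to_csv", "reports_to_json"]

_NUM_FMT = "{:.4f}"  # documented output precision


@dataclass
class AssessmentConfig:
    """Pipeline switches: correspondence mode, atom selection, thresholds."""

    mode: str = "by-alignment"
    selection: str = "all-heavy"
    annotation_config: annotation.AnnotationConfig = field(default_factory=annotation.AnnotationConfig)
    clash_threshold: float = 0.4
    strict_interactions: bool = False
    rank_key: str = "rmsd"


@dataclass
class MetricReport:
    """One model's full scorecard (NA encoded as ``None``)."""

    label: str
    ok: bool = True
    error: str | None = None
    rmsd: float | None = None
    atom_pairs_used: int | None = None
    inf_all: float | None = None
    inf_wc: float | None = None
    inf_nwc: float | None = None
    inf_stack: float | None = None
    di_all: float | None = None
    di_wc: float | None = None
    di_nwc: float | None = None
    di_stack: float | None = None
    clash_score: float | None = None
    has_hydrogens: bool | None = None
    mcq_global: float | None = None
    mcq_angles_compared: int | None = None
    mcq_angles_skipped: int | None = None
    unmatched_reference: int | None = None
    unmatched_model: int | None = None
    rank: int | None = None

    FIELDS = (
        "label", "rank", "rmsd", "di_all", "inf_all", "inf_wc", "inf_nwc",
        "inf_stack", "di_wc", "di_nwc", "di_stack", "mcq_global", "clash_score",
        "atom_pairs_used", "mcq_angles_compared", "mcq_angles_skipped",
        "unmatched_reference", "unmatched_model", "has_hydrogens", "ok", "error",
    )


def assess_one(
    reference: StructureModel,
    model: StructureModel,
    config: AssessmentConfig | None = None,
    reference_interactions: annotation.InteractionSet | None = None,
    reference_torsions: torsions.TorsionTable | None = None,
) -> MetricReport:
    """Scorecard of a single model against the reference."""
    cfg = config or AssessmentConfig()
    report = MetricReport(label=model.label)
    corr = build_correspondence(reference, model, mode=cfg.mode)
    report.unmatched_reference = len(corr.unmatched_reference)
    report.unmatched_model = len(corr.unmatched_model)

    sup = rmsd_between(reference, model, corr, cfg.selection)
    report.rmsd = sup.rmsd
    report.atom_pairs_used = sup.atom_pairs_used

    ref_ia = reference_interactions or annotation.interactions_of(reference, cfg.annotation_config)
    mod_ia = annotation.interactions_of(model, cfg.annotation_config)
    inf = metrics.match_interactions(ref_ia, mod_ia, corr, strict=cfg.strict_interactions)
    report.inf_all, report.inf_wc = inf.inf_all, inf.inf_wc
    report.inf_nwc, report.inf_stack = inf.inf_nwc, inf.inf_stack
    report.di_all = metrics.deformation_index(sup.rmsd, inf.inf_all)
    report.di_wc = metrics.deformation_index(sup.rmsd, inf.inf_wc)
    report.di_nwc = metrics.deformation_index(sup.rmsd, inf.inf_nwc)
    report.di_stack = metrics.deformation_index(sup.rmsd, inf.inf_stack)

    ref_tt = reference_torsions or torsions.compute_torsions(reference)
    mod_tt = torsions.compute_torsions(model)
    mcq = torsions.mcq_global(ref_tt, mod_tt, corr)
    report.mcq_global = mcq.global_value
    report.mcq_angles_compared = mcq.angles_compared
    report.mcq_angles_skipped = mcq.angles_skipped

    report.clash_score = clash.clash_score(model, threshold=cfg.clash_threshold)
    report.has_hydrogens = model.has_hydrogens
    return report


def assess_models(
    reference: StructureModel,
    models: list[StructureModel],
    config: AssessmentConfig | None = None,
) -> list[MetricReport]:
    """Assess every model, rank the successful ones, and return all rows.

    A model that raises during assessment yields a failed row (``ok=False``)
    and the run continues.
    """
    cfg = config or AssessmentConfig()
    ref_ia = annotation.interactions_of(reference, cfg.annotation_config)
    ref_tt = torsions.compute_torsions(reference)
    reports = []
    for model in models:
        try:
            reports.append(assess_one(reference, model, cfg, ref_ia, ref_tt))
        except Exception as exc:  # failed row, run continues
            reports.append(MetricReport(label=model.label, ok=False, error=str(exc)))
    _rank(reports, cfg.rank_key)
    return reports


def assess_paths(
    reference_path,
    model_paths,
    config: AssessmentConfig | None = None,
) -> list[MetricReport]:
    """File-path front end of :func:`assess_models`; unreadable or
    unparseable models become failed rows."""
    import os

    reference = read_pdb(reference_path, label=os.path.basename(str(reference_path)))
    models, failed = [], []
    for p in model_paths:
        label = os.path.basename(str(p))
        try:
            models.append(read_pdb(p, label=label))
        except Exception as exc:
            failed.append(MetricReport(label=label, ok=False, error=str(exc)))
    reports = assess_models(reference, models, config)
    return reports + failed


def _rank(reports: list[MetricReport], key: str) -> None:
    scored = [r for r in reports if r.ok and getattr(r, key) is not None]
    inf_big = float("inf")

    def sort_key(r):
        primary = getattr(r, key)
        di = r.di_all if r.di_all is not None else inf_big
        return (primary, di, r.label)

    for i, r in enumerate(sorted(scored, key=sort_key), start=1):
        r.rank = i


def _cell(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return _NUM_FMT.format(v)
    return str(v)


def reports_to_csv(reports: list[MetricReport]) -> str:
    lines = [",".join(MetricReport.FIELDS)]
    ordered = sorted(reports, key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0, r.label))
    for r in ordered:
        lines.append(",".join(_cell(getattr(r, f)) for f in MetricReport.FIELDS))
    return "\n".join(lines) + "\n"


def reports_to_json(reports: list[MetricReport]) -> str:
    rows = []
    ordered = sorted(reports, key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0, r.label))
    for r in ordered:
        row = {}
        for f in MetricReport.FIELDS:
            v = getattr(r, f)
            row[f] = round(v, 4) if isinstance(v, float) else v
        rows.append(row)
    return json.dumps(rows, indent=2, sort_keys=False) + "\n"
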