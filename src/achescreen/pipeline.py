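"""Sequential virtual-screening cascade.

A screening library passes through, in order: a molecular-weight cap,
per-family machine-learning classifiers (predicted actives combined with
duplicate removal), a ligand-based pharmacophore filter (at least one
hypothesis match in an externally produced match table), the
pharmacophore-model-ensemble stage scored by YN2, and finally a top-N
truncation of the YN2 ranking per family.  Each molecule is screened by
the ensemble of every family whose ML model accepted it (multi-acceptance
fans out).  Counts are logged per stage and rendered as JSON/Markdown.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chemclust import MoleculeRecord
from .mlscreen import DescriptorTable, TrainedModel
from .pharmensemble import PhaseScoreMatrix, screen_ensemble
from .scoring import YN2Params, YN2Record

logger = logging.getLogger("achescreen.pipeline")


@dataclass
class ScreeningCascadeConfig:
    """Cascade configuration.

    ``mw_cap`` defaults to 500 Da (drug-like screening libraries);
    ``top_n`` defaults to 500 molecules per family.  ``stage_toggles``
    lets any stage be disabled, which makes it the identity filter.
    """

    families: list[str]
    mw_cap: float = 500.0
    top_n: int = 500
    ml_threshold: float = 0.5
    stage_toggles: dict[str, bool] = field(
        default_factory=lambda: {"mw": True, "ml": True, "ligand_pharm": True, "ensemble": True}
    )
    seed: int = 0


@dataclass
class StageLog:
    stage: str
    family: str | None
    n_in: int
    n_out: int

    @property
    def retention_pct(self) -> float:
        return self.n_out / self.n_in * 100.0 if self.n_in else 0.0


@dataclass
class CascadeReport:
    stages: list[StageLog] = field(default_factory=list)
    final_ranked: dict[str, list[YN2Record]] = field(default_factory=dict)

    def log(self, stage: str, family: str | None, n_in: int, n_out: int) -> None:
        entry = StageLog(stage, family, n_in, n_out)
        self.stages.append(entry)
        logger.info(
            "stage=%s family=%s in=%d out=%d retention=%.1f%%",
            stage, family or "-", n_in, n_out, entry.retention_pct,
        )
        if n_out == 0:
            logger.warning("stage %s (family %s) retained zero molecules", stage, family)


def run_cascade(
    library: Sequence[MoleculeRecord],
    config: ScreeningCascadeConfig,
    descriptor_table: DescriptorTable | None = None,
    models: Mapping[str, TrainedModel] | None = None,
    ligand_pharm_matches: Mapping[str, Mapping[str, int]] | None = None,
    ensemble_matrices: Mapping[str, PhaseScoreMatrix] | None = None,
    ensemble_params: Mapping[str, YN2Params] | None = None,
) -> CascadeReport:
    """Run the staged screening cascade over a molecule library.

    ``ligand_pharm_matches`` maps family → (mol_id → number of
    ligand-based hypotheses matched); the stage retains molecules with at
    least one match.  ``ensemble_matrices``/``ensemble_params`` supply the
    per-family phase-score matrices and fitted YN2 parameters.  Disabled
    or un-supplied stages act as identity filters.
    """
    toggles = config.stage_toggles
    report = CascadeReport()
    current = list(library)

    if toggles.get("mw", True):
        n_in = len(current)
        current = [m for m in current if m.mw is not None and m.mw <= config.mw_cap]
        report.log("mw_filter", None, n_in, len(current))

    # per-family ML predictions; union with duplicate removal
    per_family: dict[str, list[MoleculeRecord]]
    if toggles.get("ml", True) and models:
        if descriptor_table is None:
            raise ValueError("ML stage requires a descriptor table")
        row_of = {m: i for i, m in enumerate(descriptor_table.mol_ids)}
        per_family = {}
        union_ids: dict[str, MoleculeRecord] = {}
        for fam in config.families:
            model = models.get(fam)
            if model is None:
                raise ValueError(f"missing model artifact for family {fam}")
            members = [m for m in current if m.mol_id in row_of]
            sub = DescriptorTable(
                mol_ids=[m.mol_id for m in members],
                descriptor_names=list(descriptor_table.descriptor_names),
                values=descriptor_table.values[[row_of[m.mol_id] for m in members], :],
            )
            scores = model.predict_scores(sub) if members else []
            accepted = [
                m for m, s in zip(members, scores) if s >= config.ml_threshold
            ]
            per_family[fam] = accepted
            for m in accepted:
                union_ids.setdefault(m.mol_id, m)
            report.log("ml_predict", fam, len(members), len(accepted))
        n_in = len(current)
        current = list(union_ids.values())
        report.log("ml_union_dedup", None, n_in, len(current))
    else:
        per_family = {fam: list(current) for fam in config.families}

    if toggles.get("ligand_pharm", True) and ligand_pharm_matches is not None:
        for fam in config.families:
            matches = ligand_pharm_matches.get(fam, {})
            n_in = len(per_family[fam])
            kept_ids = {m.mol_id for m in current}
            per_family[fam] = [
                m for m in per_family[fam]
                if m.mol_id in kept_ids and matches.get(m.mol_id, 0) >= 1
            ]
            report.log("ligand_pharm", fam, n_in, len(per_family[fam]))
    else:
        kept_ids = {m.mol_id for m in current}
        per_family = {
            fam: [m for m in mols if m.mol_id in kept_ids]
            for fam, mols in per_family.items()
        }

    if toggles.get("ensemble", True) and ensemble_matrices is not None:
        if ensemble_params is None:
            raise ValueError("ensemble stage requires fitted YN2 parameters")
        for fam in config.families:
            members = per_family[fam]
            n_in = len(members)
            if n_in == 0:
                logger.warning("family %s empty before ensemble stage; skipped", fam)
                report.final_ranked[fam] = []
                report.log("ensemble_yn2", fam, 0, 0)
                continue
            matrix = ensemble_matrices[fam]
            ids = [m.mol_id for m in members if m.mol_id in matrix.scores.index]
            sub = PhaseScoreMatrix(
                scores=matrix.scores.loc[ids], origins=dict(matrix.origins)
            )
            ranked = screen_ensemble(sub, ensemble_params[fam], top_n=config.top_n)
            report.final_ranked[fam] = ranked
            report.log("ensemble_yn2", fam, n_in, len(ranked))
    else:
        for fam in config.families:
            report.final_ranked[fam] = []

    return report


def render_report(report: CascadeReport) -> tuple[dict, str]:
    """JSON- and Markdown-ready renderings carrying identical numbers."""
    doc = {
        "stages": [
            {
                "stage": s.stage,
                "family": s.family,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "retention_pct": round(s.retention_pct, 2),
                "warning": s.n_out == 0,
            }
            for s in report.stages
        ],
        "final_counts": {fam: len(recs) for fam, recs in report.final_ranked.items()},
    }
    lines = [
        "| stage | family | in | out | retention % |",
        "|---|---|---|---|---|",
    ]
    for s in doc["stages"]:
        warn = " ⚠" if s["warning"] else ""
        lines.append(
            f"| {s['stage']} | {s['family'] or '-'} | {s['n_in']} | "
            f"{s['n_out']} | {s['retention_pct']}{warn} |"
        )
    return doc, "\n".join(lines)


def write_report(report: CascadeReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc, md = render_report(report)
    (out / "cascade_report.json").write_text(json.dumps(doc, indent=2))
    (out / "cascade_report.md").write_text(md + "\n")
    for fam, recs in report.final_ranked.items():
        pd.DataFrame(
            [
                {"mol_id": r.mol_id, "yn2": r.yn2, "ph_score": r.ph_score,
                 "c_stable": r.c_stable, "c_unstable": r.c_unstable}
                for r in recs
            ]
        ).to_csv(out / f"ranked_{fam}.csv", index=False)
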