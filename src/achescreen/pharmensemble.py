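"""Ensembles of complex-based pharmacophore models.

A pharmacophore-model ensemble couples hypotheses built from stable and
unstable active-site conformations.  Screening a molecule against every
model of the ensemble yields a row of phase scores (no-match cells empty);
the models are OR-combined — one match suffices for activity — and the
per-origin match counts together with the ensemble phase score feed the
YN2 metric.  This module owns the bookkeeping, validation (plain phase
score or YN2 mode with threshold fitting) and YN2-ranked screening; the
metric arithmetic lives in :mod:`achescreen.scoring`.

Hypothesis generation and 3D pharmacophore matching happen upstream of
this module; the score matrix is the interchange contract, and the
synthetic-data module fabricates it for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    MetricReport,
    YN2Params,
    YN2Record,
    classification_metrics,
    optimize_yn2_threshold,
    yn2,
)


@dataclass(frozen=True)
class PharmacophoreModelRef:
    """One hypothesis: id, origin (stable/unstable conformation), optional
    source time window and feature summary (annotation only — feature types
    A/D/R/H/P/N with residue notes never affect computation)."""

    model_id: str
    origin: str  # "stable" | "unstable"
    source_zone: tuple[float, float] | None = None
    feature_summary: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.origin not in ("stable", "unstable"):
            raise ValueError("origin must be 'stable' or 'unstable'")


@dataclass
class PhaseScoreMatrix:
    """Molecules × pharmacophore-models phase scores; NaN marks no-match."""

    scores: pd.DataFrame          # index mol_id, columns model_id, NaN = no match
    origins: dict[str, str]       # model_id -> "stable" | "unstable"

    def __post_init__(self) -> None:
        if set(self.scores.columns) != set(self.origins):
            raise ValueError("origin labels must cover exactly the matrix columns")
        bad = [m for m, o in self.origins.items() if o not in ("stable", "unstable")]
        if bad:
            raise ValueError(f"invalid origins for models: {bad}")

    @property
    def stable_models(self) -> list[str]:
        return [m for m in self.scores.columns if self.origins[m] == "stable"]

    @property
    def unstable_models(self) -> list[str]:
        return [m for m in self.scores.columns if self.origins[m] == "unstable"]


@dataclass
class EnsembleDefinition:
    models: list[PharmacophoreModelRef]
    yn2_params: YN2Params
    provenance: str = ""

    def __post_init__(self) -> None:
        n_stable = sum(m.origin == "stable" for m in self.models)
        n_unstable = len(self.models) - n_stable
        if (
            n_stable != self.yn2_params.n_stable_total
            or n_unstable != self.yn2_params.n_unstable_total
        ):
            raise ValueError("yn2_params totals inconsistent with model list")


def match_counts(matrix: PhaseScoreMatrix) -> pd.DataFrame:
    """Per-molecule stable/unstable match counts and ensemble phase score."""
    stable = matrix.scores[matrix.stable_models]
    unstable = matrix.scores[matrix.unstable_models]
    out = pd.DataFrame(index=matrix.scores.index)
    out["c_stable"] = stable.notna().sum(axis=1).astype(int)
    out["c_unstable"] = unstable.notna().sum(axis=1).astype(int)
    out["ph_score"] = matrix.scores.max(axis=1, skipna=True).fillna(0.0)
    return out


def is_active_or(row: Mapping[str, float] | pd.Series) -> bool:
    """OR combination: active iff at least one model matched."""
    if isinstance(row, pd.Series):
        return bool(row.notna().any())
    return len(row) > 0


def yn2_records(
    matrix: PhaseScoreMatrix, params: YN2Params
) -> list[YN2Record]:
    counts = match_counts(matrix)
    return [
        yn2(str(mol), row.ph_score, int(row.c_stable), int(row.c_unstable), params)
        for mol, row in counts.iterrows()
    ]


def validate_ensemble(
    matrix: PhaseScoreMatrix,
    labels: Mapping[str, bool],
    mode: str = "yn2",
) -> tuple[MetricReport, YN2Params | None]:
    """Validate an ensemble against labelled actives and decoys.

    ``plain`` mode scores molecules by ensemble phase score and reports
    metrics at the OR-combination operating point (active iff ≥ 1 match).
    ``yn2`` mode fits ph_min/ph_max from the actives' ensemble phase
    scores, computes YN2 for every molecule, optimizes the threshold by
    recall + specificity, and reports metrics at that threshold, returning
    the fitted parameters.
    """
    lab = np.array([bool(labels[m]) for m in matrix.scores.index])
    if lab.all() or (~lab).all():
        raise ValueError("both classes must be present")
    counts = match_counts(matrix)
    if mode == "plain":
        # OR operating point: any match => active; rank by phase score,
        # unmatched molecules below every matched one.
        matched = (counts[["c_stable", "c_unstable"]].sum(axis=1) > 0).to_numpy()
        ph = counts["ph_score"].to_numpy()
        floor = (ph[matched].min() - 1.0) if matched.any() else 0.0
        scores = np.where(matched, ph, floor)
        thr = float(ph[matched].min()) if matched.any() else np.inf
        return classification_metrics(scores, lab, threshold=thr), None
    if mode != "yn2":
        raise ValueError("mode must be 'plain' or 'yn2'")
    active_ph = counts.loc[lab, "ph_score"]
    params = YN2Params(
        ph_min=float(active_ph.min()),
        ph_max=float(active_ph.max()),
        n_stable_total=len(matrix.stable_models),
        n_unstable_total=len(matrix.unstable_models),
    )
    recs = yn2_records(matrix, params)
    values = np.array([r.yn2 for r in recs])
    theta, _ = optimize_yn2_threshold(values, lab)
    fitted = YN2Params(
        ph_min=params.ph_min,
        ph_max=params.ph_max,
        n_stable_total=params.n_stable_total,
        n_unstable_total=params.n_unstable_total,
        threshold=theta,
    )
    report = classification_metrics(values, lab, threshold=theta)
    return report, fitted


def screen_ensemble(
    matrix: PhaseScoreMatrix, params: YN2Params, top_n: int = 500
) -> list[YN2Record]:
    """YN2-ranked screening: actives (YN2 ≥ threshold) sorted descending,
    ties ascending by mol_id, truncated to ``top_n``."""
    recs = yn2_records(matrix, params)
    actives = [r for r in recs if r.yn2 >= params.threshold and r.yn2 > 0]
    actives.sort(key=lambda r: (-r.yn2, r.mol_id))
    return actives[:top_n]


# ---------------------------------------------------------------------------
# I/O: TSV matrix with a two-row header (model ids, origins); JSON ensemble
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path) -> PhaseScoreMatrix:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    origin_row = lines[1].split("\t")
    model_ids = header[1:]
    origins = dict(zip(model_ids, origin_row[1:]))
    rows, index = [], []
    for line in lines[2:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        index.append(cells[0])
        rows.append([float(c) if c.strip() != "" else np.nan for c in cells[1:]])
    df = pd.DataFrame(rows, index=index, columns=model_ids)
    return PhaseScoreMatrix(scores=df, origins=origins)


def write_matrix_tsv(matrix: PhaseScoreMatrix, path: str | Path) -> None:
    cols = list(matrix.scores.columns)
    out = ["\t".join(["mol_id"] + cols)]
    out.append("\t".join(["origin"] + [matrix.origins[c] for c in cols]))
    for mol, row in matrix.scores.iterrows():
        cells = ["" if pd.isna(v) else repr(float(v)) for v in row]
        out.append("\t".join([str(mol)] + cells))
    Path(path).write_text("\n".join(out) + "\n")


def write_ensemble_json(ensemble: EnsembleDefinition, path: str | Path) -> None:
    doc = {
        "models": [
            {
                "model_id": m.model_id,
                "origin": m.origin,
                "source_zone": list(m.source_zone) if m.source_zone else None,
                "feature_summary": [list(f) for f in m.feature_summary],
            }
            for m in ensemble.models
        ],
        "yn2_params": {
            "ph_min": ensemble.yn2_params.ph_min,
            "ph_max": ensemble.yn2_params.ph_max,
            "n_stable_total": ensemble.yn2_params.n_stable_total,
            "n_unstable_total": ensemble.yn2_params.n_unstable_total,
            "threshold": ensemble.yn2_params.threshold,
        },
        "provenance": ensemble.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_ensemble_json(path: str | Path) -> EnsembleDefinition:
    doc = json.loads(Path(path).read_text())
    models = [
        PharmacophoreModelRef(
            model_id=m["model_id"],
            origin=m["origin"],
            source_zone=tuple(m["source_zone"]) if m.get("source_zone") else None,
            feature_summary=tuple(tuple(f) for f in m.get("feature_summary", [])),
        )
        for m in doc["models"]
    ]
    p = doc["yn2_params"]
    return EnsembleDefinition(
        models=models,
        yn2_params=YN2Params(
            ph_min=p["ph_min"], ph_max=p["ph_max"],
            n_stable_total=p["n_stable_total"],
            n_unstable_total=p["n_unstable_total"],
            threshold=p.get("threshold", 0.0),
        ),
        provenance=doc.get("provenance", ""),
    )
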