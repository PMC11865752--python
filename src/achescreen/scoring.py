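"""Affinity and screening metrics.

Two bespoke scores rank candidate inhibitors:

* **YN1** combines ensemble-docking scores with experimental potency:
  the within-cluster min–max-normalized ligand efficiency (LE = −score/MW)
  plus the inverted normalized log10 IC50, so YN1 ∈ [0, 2] and nears 2 for
  molecules strong both computationally and experimentally.

* **YN2** summarizes screening against an ensemble of pharmacophore
  models: the mean of the fraction of stable models matched, the fraction
  of unstable models matched, and the normalized ensemble phase score,
  with a hard zero for molecules whose ensemble phase score falls below
  the minimum observed among known actives.  YN2 ∈ [0, 1].

Also provided: best-pose aggregation of ensemble-docking output,
recall+specificity threshold optimization for YN2, and the
confusion/enrichment metric suite (recall, specificity, ACC, BACC,
ROC-AUC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class DockingRecord:
    mol_id: str
    conformation_id: str
    xp_gscore: float  # kcal/mol; more negative = better

    def __post_init__(self) -> None:
        if not math.isfinite(self.xp_gscore):
            raise ValueError("xp_gscore must be finite")


@dataclass(frozen=True)
class YN1Record:
    mol_id: str
    xp_gscore_best: float
    mw: float
    ic50_nM: float
    le: float
    le_norm: float
    ic50_term: float
    yn1: float
    degenerate_flag: bool = False


@dataclass(frozen=True)
class YN2Params:
    """Fitted ensemble-screening parameters.

    ``ph_min``/``ph_max`` are the extreme ensemble phase scores observed
    among known actives during validation; the stable/unstable totals are
    the ensemble composition; ``threshold`` is the optimized activity
    cutoff on YN2.
    """

    ph_min: float
    ph_max: float
    n_stable_total: int
    n_unstable_total: int
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.ph_max < self.ph_min:
            raise ValueError("ph_max must be >= ph_min")
        if self.n_stable_total < 1 or self.n_unstable_total < 1:
            raise ValueError("model totals must be >= 1")


@dataclass(frozen=True)
class YN2Record:
    mol_id: str
    ph_score: float
    c_stable: int
    c_unstable: int
    yn2: float
    clamped_flag: bool = False


@dataclass(frozen=True)
class MetricReport:
    tp: int
    tn: int
    fp: int
    fn: int
    recall: float
    specificity: float
    accuracy: float
    bacc: float
    roc_auc: float | None


def best_pose_score(records: Sequence[DockingRecord]) -> float | None:
    """Most negative docking score across receptor conformations.

    ``None`` when the molecule has no scored pose — it was not recovered by
    ensemble docking and is excluded from YN1 ranking downstream.
    """
    if not records:
        return None
    return min(r.xp_gscore for r in records)


def ligand_efficiency(xp_gscore: float, mw: float) -> float:
    """LE = −score / MW (kcal·mol⁻¹·(g/mol)⁻¹); mw must be positive."""
    if mw <= 0:
        raise ValueError("mw must be positive")
    return -xp_gscore / mw


def yn1(
    cluster: Sequence[tuple[str, float, float, float]],
) -> list[YN1Record]:
    """YN1 affinity score for every molecule of one cluster.

    ``cluster`` rows are (mol_id, best XP GScore, MW, IC50 in nM).  The
    normalization min/max are computed within exactly this set (i.e. the
    molecules recovered by ensemble docking for the cluster).  Degenerate
    all-equal LE or IC50 makes the corresponding term 0 and sets a flag.
    """
    if not cluster:
        return []
    le = np.array([ligand_efficiency(s, mw) for _, s, mw, _ in cluster])
    log_ic50 = np.log10([ic for *_, ic in cluster])
    le_rng = le.max() - le.min()
    ic_rng = log_ic50.max() - log_ic50.min()
    degenerate = le_rng == 0 or ic_rng == 0
    out = []
    for i, (mol_id, score, mw, ic50) in enumerate(cluster):
        le_norm = (le[i] - le.min()) / le_rng if le_rng > 0 else 0.0
        ic_term = 1.0 - (log_ic50[i] - log_ic50.min()) / ic_rng if ic_rng > 0 else 0.0
        out.append(
            YN1Record(
                mol_id=mol_id,
                xp_gscore_best=score,
                mw=mw,
                ic50_nM=ic50,
                le=float(le[i]),
                le_norm=float(le_norm),
                ic50_term=float(ic_term),
                yn1=float(le_norm + ic_term),
                degenerate_flag=degenerate,
            )
        )
    return out


def ensemble_phase_score(row: Mapping[str, float]) -> float:
    """Highest phase score across matched models; 0 when nothing matched."""
    return max(row.values()) if row else 0.0


def yn2(
    mol_id: str,
    ph_score: float,
    c_stable: int,
    c_unstable: int,
    params: YN2Params,
) -> YN2Record:
    """YN2 ensemble-screening score for one molecule.

    Below ``ph_min`` the score is exactly 0 regardless of match counts.
    Otherwise YN2 is the mean of the stable-match fraction, the
    unstable-match fraction, and the normalized phase score; a phase score
    above ``ph_max`` (possible on novel screening libraries) is clamped to
    a normalized value of 1 and flagged.
    """
    if not 0 <= c_stable <= params.n_stable_total:
        raise ValueError("c_stable out of range")
    if not 0 <= c_unstable <= params.n_unstable_total:
        raise ValueError("c_unstable out of range")
    if ph_score < params.ph_min:
        return YN2Record(mol_id, ph_score, c_stable, c_unstable, 0.0)
    clamped = False
    if params.ph_max == params.ph_min:
        ph_norm = 1.0  # degenerate active range
        clamped = True
    else:
        ph_norm = (ph_score - params.ph_min) / (params.ph_max - params.ph_min)
        if ph_norm > 1.0:
            ph_norm = 1.0
            clamped = True
    val = (
        c_stable / params.n_stable_total
        + c_unstable / params.n_unstable_total
        + ph_norm
    ) / 3.0
    return YN2Record(mol_id, ph_score, c_stable, c_unstable, float(val), clamped)


def optimize_yn2_threshold(
    yn2_values: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float]:
    """Threshold on YN2 maximizing recall + specificity.

    Candidates are the observed YN2 values (the objective is piecewise
    constant between them, so this enumeration is exact); a molecule is
    called active when its score is ≥ the threshold.  Ties resolve to the
    smallest threshold.  Returns (threshold, objective value).
    """
    y = np.asarray(yn2_values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if lab.all() or (~lab).all():
        raise ValueError("both classes must be present")
    best_theta, best_obj = None, -np.inf
    for theta in sorted(np.unique(y)):
        pred = y >= theta
        recall = (pred & lab).sum() / lab.sum()
        spec = (~pred & ~lab).sum() / (~lab).sum()
        obj = recall + spec
        if obj > best_obj:
            best_theta, best_obj = theta, obj
    return float(best_theta), float(best_obj)


def classification_metrics(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> MetricReport:
    """Confusion counts at ``threshold`` (active iff score ≥ threshold) plus
    recall, specificity, accuracy, BACC and rank-based ROC-AUC."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if len(s) != len(lab):
        raise ValueError("scores and labels must align")
    pred = s >= threshold
    tp = int((pred & lab).sum())
    fn = int((~pred & lab).sum())
    tn = int((~pred & ~lab).sum())
    fp = int((pred & ~lab).sum())
    recall = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(s)
    auc = None
    if lab.any() and (~lab).any():
        auc = float(roc_auc_score(lab, s))
    return MetricReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        recall=recall, specificity=spec, accuracy=acc,
        bacc=(recall + spec) / 2.0, roc_auc=auc,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_docking_csv(path) -> list[DockingRecord]:
    """Read docking scores from CSV ``mol_id,conformation_id,xp_gscore``."""
    df = pd.read_csv(path)
    recs = [
        DockingRecord(str(r.mol_id), str(r.conformation_id), float(r.xp_gscore))
        for r in df.itertuples(index=False)
    ]
    if len({(r.mol_id, r.conformation_id) for r in recs}) != len(recs):
        raise ValueError("(mol_id, conformation_id) pairs must be unique")
    return recs


def write_yn1_csv(records: Sequence[YN1Record], path) -> None:
    pd.DataFrame(
        [
            {
                "mol_id": r.mol_id, "xp_gscore_best": r.xp_gscore_best,
                "mw": r.mw, "ic50_nM": r.ic50_nM, "le": r.le,
                "le_norm": r.le_norm, "ic50_term": r.ic50_term,
                "yn1": r.yn1, "degenerate_flag": r.degenerate_flag,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_yn2_csv(records: Sequence[YN2Record], path) -> None:
    pd.DataFrame(
        [
            {
                "mol_id": r.mol_id, "ph_score": r.ph_score,
                "c_stable": r.c_stable, "c_unstable": r.c_unstable,
                "yn2": r.yn2, "clamped_flag": r.clamped_flag,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
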