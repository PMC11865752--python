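"""Seeded generators for every input the screening pipeline consumes.

The pipeline's upstream producers — inhibitor bioactivity databases,
commercial docking engines, MD simulations, and pharmacophore-matching
software — are emulated here by seeded generators that also return the
ground truth needed to score recovery tests:

* family-structured inhibitor libraries (scaffold + enumerated
  decorations, log-normal within-family IC50s);
* RMSD traces with planted change points separating stationary segments;
* per-conformation docking score tables in which actives' best scores
  stochastically dominate decoys';
* molecule × pharmacophore-model phase-score matrices with origin- and
  label-dependent match probabilities;
* Ellman-type kinetic plates with known initial velocities and a known
  true IC50.

Every generator is a pure function of its config (seed included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemclust import MoleculeRecord
from .pharmensemble import PhaseScoreMatrix
from .scoring import DockingRecord
from .trajzones import RMSDTrace
from .assay import KineticTrace

# Scaffold templates: one core per family, decorated with enumerated
# substituents so within-family Tanimoto similarity exceeds between-family.
FAMILY_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc2c(c1)cccn2",          # quinoline
    "c1ccc2c(c1)[nH]c3ccccc23",  # carbazole
    "c1ccc(cc1)C(=O)N",          # benzamide
    "c1ccc2c(c1)oc3ccccc23",     # dibenzofuran
    "c1ccc(cc1)S(=O)(=O)N",      # benzenesulfonamide
    "c1ccc2c(c1)ncc3ccccc23",    # acridine-like aza core
    "c1ccc(cc1)c2ccccn2",        # phenylpyridine
    "c1ccc2c(c1)cc[nH]2",        # indole
    "c1ccc(cc1)C(=O)Oc2ccccc2",  # phenyl benzoate
)

# decoration fragments prepended to a scaffold; each ends in a carbon so the
# attachment bond is always valid
_DECORATIONS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "OCC", "NCC", "NCCC", "COCC",
    "CC(C)C", "OCCC", "ClCC", "FCC", "CC(C)CC", "CNCC", "COCCC", "NCCCC",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic stand-ins.

    Defaults emulate a desk-scale slice of the real screening campaign:
    a few structural families of a few dozen inhibitors each with
    log-normal IC50s around a family-specific geometric mean, a −2
    kcal/mol mean docking-score advantage for actives, 5,000-frame RMSD
    traces (EMA period 500, keeping the 1:10 frames-to-period ratio), and
    2% multiplicative assay noise.
    """

    seed: int = 0
    n_families: int = 3
    family_size: tuple[int, int] = (20, 30)
    ic50_gm_nM: tuple[float, ...] = (200.0, 2_000.0, 20_000.0)
    ic50_gsd: float = 3.0
    score_gap_kcal: float = -2.0
    score_sd_kcal: float = 1.0
    drop_fraction: float = 0.1
    trace_len: int = 5_000
    trace_span_ns: float = 500.0
    segment_noise_A: float = 0.15
    ramp_frames: int = 50
    match_p_active: tuple[float, float] = (0.8, 0.7)   # (stable, unstable)
    match_p_decoy: tuple[float, float] = (0.15, 0.1)
    phase_mu_active: float = 1.6
    phase_mu_decoy: float = 0.8
    phase_sd: float = 0.25
    assay_noise: float = 0.02


@dataclass
class GroundTruth:
    family_of: dict[str, str] = field(default_factory=dict)
    change_points_ns: list[float] = field(default_factory=list)
    active_labels: dict[str, bool] = field(default_factory=dict)
    true_ic50: dict[str, float] = field(default_factory=dict)
    planted_exemplars: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "family_of": self.family_of,
                    "change_points_ns": self.change_points_ns,
                    "active_labels": self.active_labels,
                    "true_ic50": self.true_ic50,
                    "planted_exemplars": self.planted_exemplars,
                },
                indent=2,
            )
        )


def gen_library(config: GeneratorConfig) -> tuple[list[MoleculeRecord], GroundTruth]:
    """Family-structured inhibitor library with log-normal within-family IC50s."""
    rng = np.random.default_rng(config.seed)
    if config.n_families > len(FAMILY_SCAFFOLDS):
        raise ValueError(f"at most {len(FAMILY_SCAFFOLDS)} families supported")
    truth = GroundTruth()
    library: list[MoleculeRecord] = []
    for f in range(config.n_families):
        scaffold = FAMILY_SCAFFOLDS[f]
        if Chem.MolFromSmiles(scaffold) is None:
            raise ValueError(f"invalid scaffold template: {scaffold}")
        size = int(rng.integers(config.family_size[0], config.family_size[1] + 1))
        gm = config.ic50_gm_nM[f % len(config.ic50_gm_nM)]
        decor_idx = rng.permutation(len(_DECORATIONS))
        for m in range(size):
            deco = _DECORATIONS[decor_idx[m % len(_DECORATIONS)]]
            extra = "C" * (m // len(_DECORATIONS))  # extend chain when decorations recycle
            smiles = f"{deco}{extra}{scaffold}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ValueError(f"decoration produced invalid SMILES: {smiles}")
            ic50 = float(np.exp(rng.normal(np.log(gm), np.log(config.ic50_gsd))))
            mol_id = f"F{f + 1}M{m + 1:03d}"
            library.append(
                MoleculeRecord(
                    mol_id=mol_id,
                    structure=Chem.MolToSmiles(mol),
                    ic50_nM=ic50,
                    mw=float(Descriptors.MolWt(mol)),
                    source_tag=f"family{f + 1}",
                )
            )
            truth.family_of[mol_id] = f"family{f + 1}"
    return library, truth


def gen_trace(
    config: GeneratorConfig,
    change_points_ns: Sequence[float] = (),
    levels_A: Sequence[float] | None = None,
) -> tuple[RMSDTrace, GroundTruth]:
    """Piecewise-stationary Gaussian RMSD trace with linear transition ramps.

    ``change_points_ns`` plant the transitions; segment levels default to
    an alternating low/high pattern 1.5 Å apart.  Overlapping ramps are
    rejected.
    """
    rng = np.random.default_rng(config.seed)
    n = config.trace_len
    span = config.trace_span_ns
    times = np.linspace(0.0, span, n)
    cps = sorted(float(c) for c in change_points_ns)
    if any(c <= 0 or c >= span for c in cps):
        raise ValueError("change points must lie strictly inside the span")
    cp_frames = [int(round(c / span * (n - 1))) for c in cps]
    half = config.ramp_frames // 2
    for a, b in zip(cp_frames, cp_frames[1:]):
        if b - a <= 2 * half:
            raise ValueError("change points overlap (ramps collide)")
    n_seg = len(cps) + 1
    if levels_A is None:
        levels_A = [2.0 + 1.5 * (i % 2) for i in range(n_seg)]
    if len(levels_A) != n_seg:
        raise ValueError("need one level per segment")

    base = np.empty(n)
    bounds = [0] + cp_frames + [n - 1]
    for i in range(n_seg):
        base[bounds[i]: bounds[i + 1] + 1] = levels_A[i]
    for i, cf in enumerate(cp_frames):  # linear ramp across each change point
        lo, hi = max(0, cf - half), min(n - 1, cf + half)
        base[lo: hi + 1] = np.linspace(levels_A[i], levels_A[i + 1], hi - lo + 1)
    values = np.clip(base + rng.normal(0.0, config.segment_noise_A, n), 0.0, None)
    trace = RMSDTrace(frames=np.arange(n), times=times, values=values)
    return trace, GroundTruth(change_points_ns=list(cps))


def gen_docking_scores(
    library: Sequence[MoleculeRecord],
    active_ids: set[str],
    n_conformations: int,
    config: GeneratorConfig,
) -> list[DockingRecord]:
    """Ensemble-docking score table; actives shifted by the configured gap.

    A ``drop_fraction`` of molecules is emitted with no poses at all,
    mirroring molecules not recovered by docking.
    """
    if n_conformations < 1:
        raise ValueError("need at least one receptor conformation")
    rng = np.random.default_rng(config.seed)
    records = []
    for rec in library:
        if rng.random() < config.drop_fraction:
            continue  # not recovered: no scored pose
        mu = -7.0 + (config.score_gap_kcal if rec.mol_id in active_ids else 0.0)
        for c in range(n_conformations):
            records.append(
                DockingRecord(
                    mol_id=rec.mol_id,
                    conformation_id=f"conf{c + 1}",
                    xp_gscore=float(rng.normal(mu, config.score_sd_kcal)),
                )
            )
    return records


def gen_phase_matrix(
    mol_ids: Sequence[str],
    active_ids: set[str],
    n_stable: int,
    n_unstable: int,
    config: GeneratorConfig,
) -> tuple[PhaseScoreMatrix, GroundTruth]:
    """Molecule × model phase-score matrix with planted label separation.

    Per molecule and model, a Bernoulli match with origin- and
    label-dependent probability; matched cells draw a phase score from a
    label-dependent normal.
    """
    if n_stable < 1 or n_unstable < 1:
        raise ValueError("need at least one model per origin")
    rng = np.random.default_rng(config.seed)
    models = [f"S{i + 1}" for i in range(n_stable)] + [f"U{i + 1}" for i in range(n_unstable)]
    origins = {m: ("stable" if m.startswith("S") else "unstable") for m in models}
    rows = []
    truth = GroundTruth()
    for mol in mol_ids:
        active = mol in active_ids
        truth.active_labels[mol] = active
        p_s, p_u = config.match_p_active if active else config.match_p_decoy
        mu = config.phase_mu_active if active else config.phase_mu_decoy
        row = []
        for m in models:
            p = p_s if origins[m] == "stable" else p_u
            if rng.random() < p:
                row.append(max(0.05, float(rng.normal(mu, config.phase_sd))))
            else:
                row.append(np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, index=list(mol_ids), columns=models)
    return PhaseScoreMatrix(scores=df, origins=origins), truth


def gen_descriptor_blobs(
    n_per_blob: int,
    n_blobs: int,
    n_features: int,
    config: GeneratorConfig,
    blob_sd: float = 0.05,
) -> tuple["np.ndarray", list[str], list[int], list[str]]:
    """Gaussian descriptor blobs with a known per-blob exemplar.

    Returns (matrix, mol_ids, blob labels, exemplar ids).  The ground-truth
    exemplar of a blob is its member nearest the blob's sample mean — the
    point a correct per-cluster centroid-nearest extraction must return
    once the blobs are recovered as clusters.
    """
    rng = np.random.default_rng(config.seed)
    centers = rng.uniform(0.0, 1.0, size=(n_blobs, n_features)) * 10.0
    xs, ids, labels = [], [], []
    for b in range(n_blobs):
        pts = centers[b] + rng.normal(0.0, blob_sd, (n_per_blob, n_features))
        xs.append(pts)
        ids.extend(f"D{b + 1:02d}_{i + 1:03d}" for i in range(n_per_blob))
        labels.extend([b] * n_per_blob)
    x = np.vstack(xs)
    # exemplars in the min-max-scaled space the extractor operates in
    rng_cols = x.max(axis=0) - x.min(axis=0)
    rng_cols[rng_cols == 0] = 1.0
    scaled = (x - x.min(axis=0)) / rng_cols
    exemplars = []
    for b in range(n_blobs):
        idx = [i for i, lab in enumerate(labels) if lab == b]
        pts = scaled[idx]
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        best = min(zip(d, (ids[i] for i in idx)), key=lambda t: (t[0], t[1]))[1]
        exemplars.append(best)
    return x, ids, labels, exemplars


def gen_assay_plate(
    true_ic50: float,
    config: GeneratorConfig,
    top_conc: float = 450.0,
    n_dilutions: int = 10,
    n_replicates: int = 3,
    v0_control: float = 1e-3,
    hill: float = 1.0,
) -> tuple[list[KineticTrace], KineticTrace, GroundTruth]:
    """Ellman-type kinetic plate with a known true IC50.

    A 1:1 dilution series from ``top_conc`` down (the standard plate
    design), absorbance sampled every 45 s over 15 min; velocities follow
    a logistic inhibition curve around ``true_ic50`` with multiplicative
    noise.  Returns (sample traces, control trace, truth).
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, 15 * 60 + 1, 45.0)
    concs = top_conc / (2.0 ** np.arange(n_dilutions))

    def trace_for(v0: float, well: str, comp: str, conc: float | None) -> KineticTrace:
        absorbance = 0.05 + v0 * times + rng.normal(0.0, 1e-4, len(times))
        return KineticTrace(
            times=times,
            absorbance=absorbance,
            well_id=well,
            compound_id=comp,
            concentration=conc,
            conc_unit="ug/mL",
        )

    control = trace_for(v0_control, "CTRL", "control", None)
    traces = []
    for r in range(n_replicates):
        for i, c in enumerate(concs):
            frac = 1.0 / (1.0 + (true_ic50 / c) ** hill)  # fractional inhibition
            v0 = v0_control * (1.0 - frac) * float(np.exp(rng.normal(0.0, config.assay_noise)))
            traces.append(trace_for(v0, f"R{r + 1}C{i + 1}", "test", float(c)))
    truth = GroundTruth(true_ic50={"test": true_ic50})
    return traces, control, truth
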