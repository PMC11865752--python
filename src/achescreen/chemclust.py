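"""Structure-based family clustering of enzyme inhibitors.

Libraries of known inhibitors are grouped into structural families by
circular-fingerprint Tanimoto similarity and average-linkage hierarchical
clustering.  The number of families is chosen with the Kelley–Gardner–
Sutcliffe penalty, per-family IC50 statistics are computed, families are
retained by a four-criteria activity filter, and one representative
(centroid) molecule is extracted per family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, SMILES, optional IC50 (nM), MW (g/mol)."""

    mol_id: str
    structure: str
    ic50_nM: float | None = None
    mw: float | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.ic50_nM is not None and not self.ic50_nM > 0:
            raise ValueError(f"{self.mol_id}: ic50_nM must be positive")
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"{self.mol_id}: mw must be positive")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Tanimoto similarity matrix over an ordered id list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if (v < -1e-9).any() or (v > 1 + 1e-9).any():
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")

    def distance(self) -> np.ndarray:
        return 1.0 - self.values


@dataclass(frozen=True)
class ClusterStats:
    cluster_id: str
    mean_ic50: float
    sd_ic50: float
    cv_ic50: float
    size: int
    singleton_flag: bool = False


@dataclass(frozen=True)
class ClusterFilterCriteria:
    """Activity filter: strict thresholds on family IC50 statistics.

    A family is retained when it satisfies at least ``min_criteria_met`` of:
    mean IC50 below ``max_mean_ic50``, IC50 standard deviation under
    ``max_sd_ic50``, population exceeding ``min_size``, and coefficient of
    variation less than ``max_cv``.  All four inequalities are strict.
    """

    max_mean_ic50: float = 10_000.0
    max_sd_ic50: float = 14_900.0
    min_size: int = 58
    max_cv: float = 1.7
    min_criteria_met: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.min_criteria_met <= 4):
            raise ValueError("min_criteria_met must be in 1..4")
        if min(self.max_mean_ic50, self.max_sd_ic50, self.min_size, self.max_cv) <= 0:
            raise ValueError("all thresholds must be positive")


class StructureParseError(ValueError):
    """Raised when one or more SMILES cannot be parsed; carries mol_ids."""

    def __init__(self, bad_ids: Sequence[str]):
        self.bad_ids = list(bad_ids)
        super().__init__(f"unparseable structures: {', '.join(self.bad_ids)}")


def _morgan_bitsets(
    library: Sequence[MoleculeRecord], radius: int, n_bits: int
) -> list[frozenset[int]]:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bad, out = [], []
    for rec in library:
        mol = Chem.MolFromSmiles(rec.structure)
        if mol is None:
            bad.append(rec.mol_id)
            continue
        fp = gen.GetFingerprint(mol)
        out.append(frozenset(fp.GetOnBits()))
    if bad:
        raise StructureParseError(bad)
    return out


def tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
    """Tanimoto = |A∩B| / |A∪B|; both-empty pair defined as 1, one-empty as 0."""
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union


def fingerprint_similarity(
    library: Sequence[MoleculeRecord], radius: int = 2, n_bits: int = 2048
) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity over circular (Morgan) fingerprints.

    Radius-2/2048-bit circular fingerprints are the open equivalent of the
    radial fingerprints used by commercial clustering suites.
    """
    ids = [rec.mol_id for rec in library]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mol_id in library")
    sets = _morgan_bitsets(library, radius, n_bits)
    n = len(sets)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(sets[i], sets[j])
    return SimilarityMatrix(ids=tuple(ids), values=sim)


def average_linkage_tree(sim: SimilarityMatrix) -> np.ndarray:
    """Average-linkage merge tree (scipy linkage matrix) on distance = 1 − sim."""
    dist = sim.distance().copy()
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method="average")

def average_linkage_cluster(
    sim: SimilarityMatrix, k: int, tree: np.ndarray | None = None
) -> dict[str, str]:
    """Cut the average-linkage dendrogram at ``k`` clusters.

    Returns mol_id → cluster_id; cluster ids are "C1".."Ck", numbered by
    first appearance in input order so the labelling is deterministic.
    """
    n = len(sim.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if tree is None:
        tree = average_linkage_tree(sim)
    raw = fcluster(tree, t=k, criterion="maxclust")
    relabel: dict[int, str] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = f"C{len(relabel) + 1}"
    return {mol: relabel[lab] for mol, lab in zip(sim.ids, raw)}


def kelley_penalty(
    tree: np.ndarray,
    dist: np.ndarray,
    k_range: tuple[int, int] | None = None,
) -> tuple[pd.Series, int]:
    """Kelley–Gardner–Sutcliffe penalty profile over cluster counts.

    Per level k the average spread is the mean, over clusters with more than
    one member, of the mean within-cluster pairwise distance.  Spreads are
    linearly rescaled across levels onto [1, n−1] and penalty(k) = rescaled
    spread + k.  Returns the profile (indexed by k, NaN where every cluster
    is a singleton) and the minimizing k (smallest on ties).
    """
    n = dist.shape[0]
    lo, hi = k_range if k_range is not None else (2, n - 1)
    if lo < 2 or hi > n - 1 or lo > hi:
        raise ValueError(f"k_range ({lo}, {hi}) outside [2, {n - 1}]")
    spreads: dict[int, float] = {}
    for k in range(lo, hi + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        per_cluster = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if len(idx) < 2:
                continue
            sub = dist[np.ix_(idx, idx)]
            per_cluster.append(sub[np.triu_indices(len(idx), k=1)].mean())
        if per_cluster:
            spreads[k] = float(np.mean(per_cluster))
    if not spreads:
        raise ValueError("every level is all-singleton; spread undefined")
    vals = np.array(list(spreads.values()))
    smin, smax = vals.min(), vals.max()
    if smax > smin:
        rescaled = (vals - smin) / (smax - smin) * (n - 2) + 1.0
    else:
        rescaled = np.ones_like(vals)
    profile = pd.Series(np.nan, index=pd.RangeIndex(lo, hi + 1, name="k"), name="kelley_penalty")
    for (k, _), r in zip(spreads.items(), rescaled):
        profile.loc[k] = r + k
    argmin_k = int(profile.idxmin())  # idxmin returns first (smallest k) on ties
    return profile, argmin_k


def cluster_stats(
    assignment: Mapping[str, str], library: Sequence[MoleculeRecord]
) -> list[ClusterStats]:
    """Per-cluster IC50 mean, sample SD (n−1), CV = sd/mean, and size."""
    by_id = {rec.mol_id: rec for rec in library}
    missing = [m for m in assignment if by_id[m].ic50_nM is None]
    if missing:
        raise ValueError(f"molecules without ic50_nM: {', '.join(missing)}")
    groups: dict[str, list[float]] = {}
    for mol, cid in assignment.items():
        groups.setdefault(cid, []).append(by_id[mol].ic50_nM)
    out = []
    for cid in sorted(groups):
        vals = np.asarray(groups[cid], dtype=float)
        mean = float(vals.mean())
        singleton = len(vals) == 1
        sd = 0.0 if singleton else float(vals.std(ddof=1))
        cv = sd / mean if mean > 0 else 0.0
        out.append(ClusterStats(cid, mean, sd, cv, len(vals), singleton_flag=singleton))
    return out


@dataclass(frozen=True)
class FilterResult:
    cluster_id: str
    criteria_met: int
    passed: tuple[bool, bool, bool, bool]
    all_four: bool
    retained: bool


def filter_clusters(
    stats: Sequence[ClusterStats],
    criteria: ClusterFilterCriteria = ClusterFilterCriteria(),
) -> list[FilterResult]:
    """Evaluate the four strict activity criteria per cluster.

    Retained iff at least ``criteria.min_criteria_met`` of (i) mean IC50 <
    max_mean_ic50, (ii) SD < max_sd_ic50, (iii) size > min_size, (iv) CV <
    max_cv hold.
    """
    if not stats:
        raise ValueError("stats must be non-empty")
    out = []
    for s in stats:
        passed = (
            s.mean_ic50 < criteria.max_mean_ic50,
            s.sd_ic50 < criteria.max_sd_ic50,
            s.size > criteria.min_size,
            s.cv_ic50 < criteria.max_cv,
        )
        met = sum(passed)
        out.append(
            FilterResult(
                cluster_id=s.cluster_id,
                criteria_met=met,
                passed=passed,
                all_four=met == 4,
                retained=met >= criteria.min_criteria_met,
            )
        )
    return out


def cluster_centroid(
    assignment: Mapping[str, str], sim: SimilarityMatrix
) -> dict[str, str]:
    """Representative molecule per cluster: minimal mean distance to the rest.

    Ties break to the lexicographically smallest mol_id.
    """
    pos = {mol: i for i, mol in enumerate(sim.ids)}
    dist = sim.distance()
    clusters: dict[str, list[str]] = {}
    for mol, cid in assignment.items():
        clusters.setdefault(cid, []).append(mol)
    reps: dict[str, str] = {}
    for cid, members in clusters.items():
        if not members:
            raise ValueError(f"cluster {cid} is empty")
        if len(members) == 1:
            reps[cid] = members[0]
            continue
        idx = [pos[m] for m in members]
        sub = dist[np.ix_(idx, idx)]
        mean_d = sub.sum(axis=1) / (len(idx) - 1)
        best = min(zip(mean_d, members), key=lambda t: (t[0], t[1]))
        reps[cid] = best[1]
    return reps


# ---------------------------------------------------------------------------
# I/O: molecule library readers/writers
# ---------------------------------------------------------------------------

def read_library_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read a library CSV with header ``mol_id,smiles,ic50_nM,mw``."""
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        ic50 = getattr(row, "ic50_nM", None)
        mw = getattr(row, "mw", None)
        recs.append(
            MoleculeRecord(
                mol_id=str(row.mol_id),
                structure=str(row.smiles),
                ic50_nM=None if ic50 is None or pd.isna(ic50) else float(ic50),
                mw=None if mw is None or pd.isna(mw) else float(mw),
            )
        )
    return recs


def write_library_csv(library: Iterable[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"mol_id": r.mol_id, "smiles": r.structure, "ic50_nM": r.ic50_nM, "mw": r.mw}
            for r in library
        ]
    ).to_csv(path, index=False)


def read_library_smiles(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES file: ``smiles<TAB>mol_id`` per line."""
    recs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        smiles, mol_id = line.split("\t")[:2]
        recs.append(MoleculeRecord(mol_id=mol_id.strip(), structure=smiles.strip()))
    return recs


def read_library_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read an SDF; ic50_nM and mw taken from molecule properties when present."""
    recs = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        recs.append(
            MoleculeRecord(
                mol_id=str(props.get("mol_id", mol.GetProp("_Name"))),
                structure=Chem.MolToSmiles(mol),
                ic50_nM=float(props["ic50_nM"]) if "ic50_nM" in props else None,
                mw=float(props["mw"]) if "mw" in props else None,
            )
        )
    return recs


def write_assignment_csv(assignment: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["mol_id", "cluster_id"]
    ).to_csv(path, index=False)


def write_stats_csv(
    stats: Sequence[ClusterStats], results: Sequence[FilterResult], path: str | Path
) -> None:
    by_id = {r.cluster_id: r for r in results}
    pd.DataFrame(
        [
            {
                "cluster_id": s.cluster_id,
                "mean_ic50": s.mean_ic50,
                "sd_ic50": s.sd_ic50,
                "cv_ic50": s.cv_ic50,
                "size": s.size,
                "criteria_met": by_id[s.cluster_id].criteria_met,
                "all_four": by_id[s.cluster_id].all_four,
            }
            for s in stats
        ]
    ).to_csv(path, index=False)
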