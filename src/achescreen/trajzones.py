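"""Trajectory-derived conformational sampling.

Operations on per-frame RMSD/RMSF series from molecular-dynamics
trajectories of protein–ligand complexes:

* the seven-point statistical frame extractor (mean, mean ± 2·sd, two
  lowest, two highest RMSD frames);
* paired RMSD between coordinate sets (optionally after Kabsch
  superposition) and greedy-maximin diversity selection;
* per-residue RMSF ranking;
* EMA smoothing, min–max normalization, absolute forward difference, and
  dual-threshold segmentation of a trajectory into stable and unstable
  time zones;
* simplified extraction of representative frames from stable zones
  (k-means medoids) and atypical frames from unstable zones (z-score
  outliers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class RMSDTrace:
    """Per-frame deviation time series from one trajectory."""

    frames: np.ndarray  # integer frame indices from 0
    times: np.ndarray   # ns, strictly increasing
    values: np.ndarray  # Å, >= 0

    def __post_init__(self) -> None:
        f, t, v = map(np.asarray, (self.frames, self.times, self.values))
        if not (len(f) == len(t) == len(v)):
            raise ValueError("frames, times, values must have equal length")
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (v < 0).any():
            raise ValueError("RMSD values must be non-negative")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_values(cls, values: Sequence[float], dt_ns: float = 0.01) -> "RMSDTrace":
        values = np.asarray(values, dtype=float)
        n = len(values)
        return cls(frames=np.arange(n), times=np.arange(n) * dt_ns, values=values)


@dataclass(frozen=True)
class ZoneSegmentation:
    """Stable/unstable time intervals (ns) partitioning a trace span."""

    stable: tuple[tuple[float, float], ...]
    unstable: tuple[tuple[float, float], ...]

    def span(self) -> tuple[float, float]:
        all_iv = list(self.stable) + list(self.unstable)
        return min(a for a, _ in all_iv), max(b for _, b in all_iv)


@dataclass(frozen=True)
class SmoothingParams:
    """Segmentation parameters.

    ``ema_period`` defaults to 5,000 frames, one tenth of a 50,000-frame
    production trajectory (a 1:10 frames-to-period ratio).  ``threshold``
    applies to the min–max-normalized derivative of the normalized moving
    average; ``gap_merge_fraction`` merges flagged runs closer than that
    fraction of the trace length into one unstable interval.
    """

    ema_period: int = 5_000
    threshold: float = 0.6
    gap_merge_fraction: float = 0.01
    min_duration_fraction: float = 0.01
    normalize_derivative: bool = True

    def __post_init__(self) -> None:
        if self.ema_period < 1:
            raise ValueError("ema_period must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class CoordinateSet:
    labels: tuple[str, ...]
    coords: np.ndarray  # n x 3, Å

    def __post_init__(self) -> None:
        c = np.asarray(self.coords)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] != len(self.labels):
            raise ValueError("coords must be n×3 matching labels")
        if not np.isfinite(c).all():
            raise ValueError("coordinates must be finite")


def extract_statistical_frames(trace: RMSDTrace) -> list[int]:
    """Seven statistically chosen frames from one RMSD series.

    Selectors are applied in fixed order: nearest to the mean, nearest to
    mean − 2·sd, nearest to mean + 2·sd, lowest, second-lowest, highest,
    second-highest (sample sd, n−1).  Each selector takes its best-matching
    frame among those not yet taken, ties resolved to the earliest frame,
    so the result is always 7 distinct frames.
    """
    v = np.asarray(trace.values, dtype=float)
    n = len(v)
    if n < 7:
        raise ValueError(f"trace has {n} frames; need at least 7")
    mean = v.mean()
    sd = v.std(ddof=1)
    # key(v_i) per selector; min over unused frames with (key, frame) ordering
    selectors = [
        lambda x: abs(x - mean),
        lambda x: abs(x - (mean - 2 * sd)),
        lambda x: abs(x - (mean + 2 * sd)),
        lambda x: x,          # lowest
        lambda x: x,          # second-lowest: next smallest unused
        lambda x: -x,         # highest
        lambda x: -x,         # second-highest: next largest unused
    ]
    taken: list[int] = []
    for key in selectors:
        best = min(
            (i for i in range(n) if i not in taken),
            key=lambda i: (key(v[i]), i),
        )
        taken.append(best)
    return taken


def pairwise_rmsd(a: CoordinateSet, b: CoordinateSet, superpose: bool = False) -> float:
    """RMSD between two conformations sharing atom labels and order.

    With ``superpose`` the optimal rigid-body (Kabsch) superposition of b
    onto a is applied first.
    """
    if a.labels != b.labels:
        raise ValueError("atom labels/order must match")
    pa = np.asarray(a.coords, dtype=float)
    pb = np.asarray(b.coords, dtype=float)
    if superpose:
        ca, cb = pa - pa.mean(axis=0), pb - pb.mean(axis=0)
        h = cb.T @ ca
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        pb = cb @ rot.T
        pa = ca
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))


def diversity_select(rmsd_matrix: np.ndarray, n_keep: int) -> list[int]:
    """Greedy maximin subset of conformations by pairwise RMSD.

    Seeds with the globally most distant pair, then repeatedly adds the
    item maximizing its minimum distance to the chosen set.  Ties break to
    the smallest index.
    """
    d = np.asarray(rmsd_matrix, dtype=float)
    m = d.shape[0]
    if n_keep > m:
        raise ValueError(f"n_keep={n_keep} exceeds {m} items")
    if n_keep <= 0:
        return []
    if n_keep == 1:
        return [0]
    iu = np.triu_indices(m, k=1)
    best_flat = np.argmax(d[iu])
    i, j = iu[0][best_flat], iu[1][best_flat]
    chosen = [min(i, j), max(i, j)]
    while len(chosen) < n_keep:
        rest = [i for i in range(m) if i not in chosen]
        mind = [d[i, chosen].min() for i in rest]
        nxt = min(zip(mind, rest), key=lambda t: (-t[0], t[1]))[1]
        chosen.append(nxt)
    return chosen


def rank_rmsf(rmsf_per_residue: Mapping[int, float], n_top: int = 6) -> list[int]:
    """Residues ranked by descending RMSF; ties ascend by residue number."""
    if not rmsf_per_residue:
        raise ValueError("empty RMSF map")
    if n_top > len(rmsf_per_residue):
        raise ValueError("n_top exceeds number of residues")
    ranked = sorted(rmsf_per_residue.items(), key=lambda kv: (-kv[1], kv[0]))
    return [res for res, _ in ranked[:n_top]]


def ema(values: Sequence[float], period: int) -> np.ndarray:
    """Recursive exponential moving average, α = 2/(period+1), seeded at x₀."""
    if period < 1:
        raise ValueError("period must be >= 1")
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty series")
    alpha = 2.0 / (period + 1.0)
    out = np.empty_like(v)
    out[0] = v[0]
    for i in range(1, len(v)):
        out[i] = alpha * v[i] + (1.0 - alpha) * out[i - 1]
    return out


def minmax_normalize(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """(x − min) / range onto [0, 1]; zero-range series maps to zeros.

    Returns (normalized, degenerate_flag); the flag marks a zero-range
    input, for which the all-zero output is a defined degenerate value
    rather than an error.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty series")
    rng = v.max() - v.min()
    if rng == 0:
        return np.zeros_like(v), True
    return (v - v.min()) / rng, False


def abs_forward_difference(values: Sequence[float], spacing: float = 1.0) -> np.ndarray:
    """|x_{i+1} − x_i| / spacing; the last point copies its predecessor."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("series must have length >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    d = np.abs(np.diff(v)) / spacing
    return np.concatenate([d, d[-1:]])


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive frame indices."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def segment_zones(
    traces: RMSDTrace | Sequence[RMSDTrace],
    params: SmoothingParams = SmoothingParams(),
) -> ZoneSegmentation:
    """Partition a trajectory span into stable and unstable time zones.

    Per trace: EMA smoothing, min–max normalization, absolute forward
    difference of the normalized moving average, then (by default) min–max
    normalization of that derivative.  Frames where the normalized
    derivative exceeds the threshold are flagged unstable — a large
    derivative of the moving average marks a transition between stationary
    RMSD levels.  Flags are OR-combined across the trace bundle, nearby
    flagged runs are merged across gaps shorter than the gap-merge window,
    and the complement of the unstable intervals is stable.
    """
    bundle = [traces] if isinstance(traces, RMSDTrace) else list(traces)
    t0 = np.asarray(bundle[0].times, dtype=float)
    for tr in bundle[1:]:
        if len(tr) != len(bundle[0]) or not np.allclose(tr.times, t0):
            raise ValueError("traces must share the time grid")
    n = len(t0)
    flagged = np.zeros(n, dtype=bool)
    for tr in bundle:
        ma, _ = minmax_normalize(ema(tr.values, params.ema_period))
        deriv = abs_forward_difference(ma)
        if params.normalize_derivative:
            deriv, degenerate = minmax_normalize(deriv)
            if degenerate:
                continue  # constant derivative: no transition anywhere
        flagged |= deriv > params.threshold

    gap = max(1, int(round(params.gap_merge_fraction * n)))
    runs = _runs_from_mask(flagged)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # isolated flagged blips shorter than the window are noise, not
    # transitions: real unstable zones are contiguous multi-frame intervals
    min_len = max(2, int(round(params.min_duration_fraction * n)))
    merged = [r for r in merged if r[1] - r[0] + 1 >= min_len]

    unstable = [(float(t0[s]), float(t0[e])) for s, e in merged]
    stable: list[tuple[float, float]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            stable.append((float(t0[cursor]), float(t0[s])))
        cursor = e
    if cursor < n - 1:
        stable.append((float(t0[cursor]), float(t0[n - 1])))
    if not merged:
        stable = [(float(t0[0]), float(t0[-1]))]
    return ZoneSegmentation(stable=tuple(stable), unstable=tuple(unstable))


def sample_zone_frames(
    trace: RMSDTrace,
    zones: ZoneSegmentation,
    descriptors: np.ndarray | None = None,
    k_stable: int = 3,
    z_cut: float = 2.0,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Representative frames per stable zone and atypical frames per unstable zone.

    Stable zones are summarized by k-means (k = ``k_stable``) on per-frame
    feature vectors — the RMSD value itself, or the supplied descriptor
    rows — returning the medoid frame of each cluster.  Unstable zones
    yield the frames whose descriptor z-score magnitude exceeds ``z_cut``.
    This is a deliberately simplified conformation extractor standing in
    for pocket-descriptor tooling.
    """
    times = np.asarray(trace.times, dtype=float)
    feats = (
        np.asarray(trace.values, dtype=float).reshape(-1, 1)
        if descriptors is None
        else np.asarray(descriptors, dtype=float)
    )
    if feats.ndim == 1:
        feats = feats.reshape(-1, 1)

    stable_frames: list[int] = []
    for a, b in zones.stable:
        idx = np.flatnonzero((times >= a) & (times <= b))
        if len(idx) == 0:
            warnings.warn(f"empty stable zone [{a}, {b}]; skipped")
            continue
        x = feats[idx]
        k = min(k_stable, len(np.unique(x, axis=0)))
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        for c in range(k):
            members = np.flatnonzero(km.labels_ == c)
            dist = np.linalg.norm(x[members] - km.cluster_centers_[c], axis=1)
            best = members[np.lexsort((members, dist))[0]]
            stable_frames.append(int(trace.frames[idx[best]]))

    unstable_frames: list[int] = []
    for a, b in zones.unstable:
        idx = np.flatnonzero((times >= a) & (times <= b))
        if len(idx) == 0:
            warnings.warn(f"empty unstable zone [{a}, {b}]; skipped")
            continue
        x = feats[idx]
        mu, sigma = x.mean(axis=0), x.std(axis=0)
        sigma[sigma == 0] = 1.0
        z = np.abs((x - mu) / sigma).max(axis=1)
        for i in idx[z > z_cut]:
            unstable_frames.append(int(trace.frames[i]))
    return sorted(set(stable_frames)), sorted(set(unstable_frames))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace_csv(path: str | Path) -> RMSDTrace:
    """Read a trace CSV with columns ``frame,time_ns,value``."""
    df = pd.read_csv(path)
    return RMSDTrace(
        frames=df["frame"].to_numpy(),
        times=df["time_ns"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
    )


def write_trace_csv(trace: RMSDTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"frame": trace.frames, "time_ns": trace.times, "value": trace.values}
    ).to_csv(path, index=False)


def write_zones_csv(
    zones: ZoneSegmentation,
    path: str | Path,
    counts: Mapping[tuple[float, float], int] | None = None,
) -> None:
    rows = []
    for a, b in zones.stable:
        rows.append(("stable", a, b, (counts or {}).get((a, b), "")))
    for a, b in zones.unstable:
        rows.append(("unstable", a, b, (counts or {}).get((a, b), "")))
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(
        rows, columns=["zone_type", "t_start_ns", "t_end_ns", "n_frames_extracted"]
    ).to_csv(path, index=False)


def read_coordinates_csv(path: str | Path) -> CoordinateSet:
    """Read coordinates from CSV ``label,x,y,z``."""
    df = pd.read_csv(path)
    return CoordinateSet(
        labels=tuple(df["label"].astype(str)),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )
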