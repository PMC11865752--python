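"""Ellman-type enzyme-inhibition assay analysis.

Kinetic absorbance reads (407 nm, every 45 s over 15 min in the standard
plate design) are reduced to initial velocities; percent inhibition is
computed against an uninhibited control; IC50 is determined either by
log-linear interpolation of the dose–response around 50% inhibition or by
a four-parameter logistic fit; and mass concentrations are converted to
molar units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class KineticTrace:
    """One well's kinetic read: absorbance (AU) vs. time (s)."""

    times: np.ndarray
    absorbance: np.ndarray
    well_id: str = ""
    compound_id: str = ""
    concentration: float | None = None
    conc_unit: str = "nM"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if len(t) != len(a) or len(t) < 3:
            raise ValueError("need >= 3 aligned (time, absorbance) points")
        if not np.isfinite(a).all() or not np.isfinite(t).all():
            raise ValueError("non-finite values in trace")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class DoseResponse:
    """Inhibition (%) vs. concentration (one consistent unit), with
    optional replicate ids; concentrations sorted ascending."""

    concentrations: np.ndarray
    inhibition_pct: np.ndarray
    replicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")


def initial_velocity(trace: KineticTrace, max_window_s: float = 300.0) -> float:
    """Least-squares slope (AU/s) of the early linear portion of the read.

    Window rule: among all prefixes of at least 3 points ending within the
    first ``max_window_s`` seconds, take the longest one maximizing R²;
    for a degenerate (constant-absorbance) prefix R² is treated as 1 with
    slope 0.
    """
    t = np.asarray(trace.times, dtype=float)
    a = np.asarray(trace.absorbance, dtype=float)
    in_window = np.flatnonzero(t - t[0] <= max_window_s)
    last = max(in_window[-1] + 1, 3)
    best_slope, best_r2, best_len = 0.0, -np.inf, 0
    for end in range(3, min(last, len(t)) + 1):
        res = stats.linregress(t[:end], a[:end])
        r2 = res.rvalue**2 if not np.isnan(res.rvalue) else 1.0
        if r2 > best_r2 + 1e-12 or (abs(r2 - best_r2) <= 1e-12 and end > best_len):
            best_slope, best_r2, best_len = res.slope, r2, end
    return float(best_slope)


def percent_inhibition(v0_sample: float, v0_control: float, factor: float = 100.0) -> float:
    """(1 − V0_sample / V0_control) × 100.

    ``factor`` is configurable for audit but the percent scale (×100) is
    the default.
    """
    if v0_control <= 0:
        raise ValueError("v0_control must be positive")
    return (1.0 - v0_sample / v0_control) * factor


def _four_param_logistic(c, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)


def ic50(
    dr: DoseResponse, method: str = "interpolation"
) -> tuple[float, dict]:
    """IC50 from a dose–response curve.

    ``interpolation`` (default): log-linear interpolation between the pair
    of measured concentrations bracketing 50% inhibition — the
    concentration at which 50% inhibition is observed.  ``four_param``: a
    least-squares four-parameter logistic fit returning its midpoint, with
    fallback to interpolation (flagged) if the fit fails.  Returns
    (ic50, info); ``info`` carries the method actually used, and when
    replicates exist, a standard deviation over per-replicate estimates.
    """
    if method not in ("interpolation", "four_param"):
        raise ValueError("method must be 'interpolation' or 'four_param'")
    conc = np.asarray(dr.concentrations, dtype=float)
    inh = np.asarray(dr.inhibition_pct, dtype=float)

    reps = dr.replicate_ids or tuple([""] * len(conc))
    per_rep = []
    for rep in sorted(set(reps)):
        mask = np.array([r == rep for r in reps])
        est = _ic50_single(conc[mask], inh[mask], method)
        if est is not None:
            per_rep.append(est)
    order = np.argsort(conc)
    # pool replicates by mean inhibition per concentration for the headline value
    pooled = pd.DataFrame({"c": conc[order], "i": inh[order]}).groupby("c").mean()
    est = _ic50_single(pooled.index.to_numpy(), pooled["i"].to_numpy(), method)
    if est is None:
        raise ValueError("inhibition does not bracket 50% and fit failed")
    value, used = est
    info = {"method": used, "n_replicates": len(set(reps))}
    if len(per_rep) > 1:
        info["sd"] = float(np.std([v for v, _ in per_rep], ddof=1))
    return float(value), info


def _ic50_single(conc, inh, method) -> tuple[float, str] | None:
    order = np.argsort(conc)
    conc, inh = conc[order], inh[order]
    if method == "four_param":
        if len(conc) >= 4:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(
                        _four_param_logistic,
                        conc,
                        inh,
                        p0=[0.0, 100.0, float(np.median(conc)), 1.0],
                        bounds=([-50, 50, conc.min() / 100, 0.1], [50, 150, conc.max() * 100, 10]),
                        maxfev=20000,
                    )
                return float(popt[2]), "four_param"
            except Exception:
                warnings.warn("4PL fit failed; falling back to interpolation")
        res = _interpolate_ic50(conc, inh)
        return (res, "interpolation_fallback") if res is not None else None
    res = _interpolate_ic50(conc, inh)
    return (res, "interpolation") if res is not None else None


def _interpolate_ic50(conc, inh) -> float | None:
    exact = np.flatnonzero(inh == 50.0)
    if len(exact):
        return float(conc[exact[0]])
    for i in range(len(conc) - 1):
        lo, hi = inh[i], inh[i + 1]
        if (lo - 50.0) * (hi - 50.0) < 0:
            # log-linear between the bracketing pair
            f = (50.0 - lo) / (hi - lo)
            return float(10 ** (np.log10(conc[i]) + f * (np.log10(conc[i + 1]) - np.log10(conc[i]))))
    return None


def ug_per_ml_to_nM(conc_ug_ml: float, mw: float, round_nearest_100: bool = False) -> float:
    """Convert µg/mL to nM: conc / MW × 10⁶; optional nearest-100 rounding."""
    if conc_ug_ml <= 0 or mw <= 0:
        raise ValueError("concentration and mw must be positive")
    nm = conc_ug_ml / mw * 1e6
    if round_nearest_100:
        nm = round(nm / 100.0) * 100.0
    return nm


# ---------------------------------------------------------------------------
# I/O: long-format plate reads
# ---------------------------------------------------------------------------

def read_plate_csv(path: str | Path) -> list[KineticTrace]:
    """Read plate reads from long CSV
    ``well_id,compound_id,concentration,conc_unit,time_s,absorbance``."""
    df = pd.read_csv(path)
    traces = []
    for (well, comp, conc, unit), grp in df.groupby(
        ["well_id", "compound_id", "concentration", "conc_unit"], sort=False
    ):
        grp = grp.sort_values("time_s")
        traces.append(
            KineticTrace(
                times=grp["time_s"].to_numpy(dtype=float),
                absorbance=grp["absorbance"].to_numpy(dtype=float),
                well_id=str(well),
                compound_id=str(comp),
                concentration=float(conc),
                conc_unit=str(unit),
            )
        )
    return traces


def write_results_csv(rows: Sequence[dict], path: str | Path) -> None:
    """Write IC50 results: ``compound_id,ic50,ic50_unit,method,n_replicates,sd``."""
    pd.DataFrame(
        rows, columns=["compound_id", "ic50", "ic50_unit", "method", "n_replicates", "sd"]
    ).to_csv(path, index=False)
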