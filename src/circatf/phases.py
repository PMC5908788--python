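"""Time-phase machinery: TP assignment, TP-specific feature selection,
peak times, and the day/night fold-change screen.

The 24-h day is split into four 6-h time phases anchored at ZT0
(TP1 = [0,6), TP2 = [6,12), TP3 = [12,18), TP4 = [18,24)); daytime is
ZT0-12 (lights on).  Two-cycle designs are reduced mod 24 so that both
cycles contribute to every phase.  Fold-based rules operate on the FOT
(or FPKM) scale, never on zero-centred z-scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import OmicsMatrix

logger = logging.getLogger("circatf")

TPS = ("TP1", "TP2", "TP3", "TP4")


def assign_time_phases(timepoints) -> dict[float, str]:
    """Map each ZT hour (reduced mod 24) to its 6-h time phase."""
    out = {}
    for t in np.asarray(timepoints, dtype=float):
        out[float(t)] = TPS[int((t % 24) // 6)]
    return out


def _tp_column_groups(timepoints) -> dict[str, np.ndarray]:
    tp_of = assign_time_phases(timepoints)
    tps = np.asarray(timepoints, dtype=float)
    return {
        tp: np.flatnonzero([tp_of[float(t)] == tp for t in tps]) for tp in TPS
    }


def tp_specific_features(
    m: OmicsMatrix, fold: float = 2.0, pooled_rest: bool = False
) -> dict[str, list[str]]:
    """Features whose mean abundance in one TP exceeds ``fold`` times the
    mean in every other TP (strict; both cycles pooled per TP).

    With ``pooled_rest=True`` the comparison is against the single mean of
    all non-peak timepoints instead of each other TP separately.  Features
    lacking data in some TP are skipped (logged).  A feature can be
    specific to at most one TP.
    """
    if fold < 0:
        raise ValueError(f"fold must be nonnegative, got {fold}")
    groups = {tp: g for tp, g in _tp_column_groups(m.timepoints).items() if g.size}
    vals = m.data.to_numpy(dtype=float)
    out: dict[str, list[str]] = {tp: [] for tp in groups}
    n_skipped = 0
    for fi, fid in enumerate(m.data.index):
        means = {}
        ok = True
        for tp, g in groups.items():
            block = vals[fi, g]
            if np.all(np.isnan(block)):
                ok = False
                break
            means[tp] = np.nanmean(block)
        if not ok:
            n_skipped += 1
            continue
        for tp in groups:
            others = [means[o] for o in groups if o != tp]
            if not others:
                continue
            if pooled_rest:
                rest_cols = np.concatenate([groups[o] for o in groups if o != tp])
                rest = np.nanmean(vals[fi, rest_cols])
                if means[tp] > fold * rest:
                    out[tp].append(fid)
                    break
            elif all(means[tp] > fold * o for o in others):
                out[tp].append(fid)
                break  # uniqueness guaranteed by the per-TP rule anyway
    if n_skipped:
        logger.info("tp_specific_features: skipped %d feature(s) with an empty TP", n_skipped)
    return out


def cycle_averaged_profile(m: OmicsMatrix) -> pd.DataFrame:
    """Average the two cycles: columns are distinct ZT mod 24 hours."""
    tps = m.timepoints
    hours = sorted({float(t % 24) for t in tps})
    cols = {h: np.flatnonzero((tps % 24) == h) for h in hours}
    vals = m.data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        data = {h: np.nanmean(vals[:, g], axis=1) for h, g in cols.items()}
    return pd.DataFrame(data, index=m.data.index)


def peak_time(m: OmicsMatrix, rt: pd.DataFrame) -> pd.DataFrame:
    """Per-feature peak ZT (in [0, 24)), time phase, and day/night flag.

    Rhythmic features take their best template lag; non-rhythmic features
    take the argmax of the cycle-averaged profile (mod-24 averaging merges
    cross-cycle ties to the earlier hour).  Daytime is ZT0-12.
    """
    prof = cycle_averaged_profile(m)
    hours = np.asarray(prof.columns, dtype=float)
    rt_idx = rt.set_index("feature_id")
    rows = []
    for fid in m.data.index:
        peak = np.nan
        if fid in rt_idx.index and bool(rt_idx.loc[fid, "rhythmic"]):
            peak = float(rt_idx.loc[fid, "best_lag_h"]) % 24.0
        else:
            row = prof.loc[fid].to_numpy(dtype=float)
            if not np.all(np.isnan(row)):
                peak = float(hours[np.nanargmax(row)]) % 24.0
        tp = TPS[int(peak // 6)] if not np.isnan(peak) else None
        day = bool(0 <= peak < 12) if not np.isnan(peak) else None
        rows.append((fid, peak, tp, day))
    return pd.DataFrame(rows, columns=["feature_id", "peak_zt_h", "tp", "day_peak"])


def day_night_fold_change(m: OmicsMatrix, threshold: float = 5.0) -> pd.DataFrame:
    """Screen for strong day/night switchers: FC = max/min of the day
    (ZT mod 24 in [0,12)) and night mean abundances, selected iff
    FC > threshold (strict).  A zero minimum gives infinite FC, selected
    and flagged."""
    tps = m.timepoints
    day_cols = np.flatnonzero((tps % 24) < 12)
    night_cols = np.flatnonzero((tps % 24) >= 12)
    if day_cols.size == 0 or night_cols.size == 0:
        raise ValueError("both day and night timepoints are required")
    vals = m.data.to_numpy(dtype=float)
    rows = []
    with np.errstate(invalid="ignore"):
        mean_day = np.nanmean(vals[:, day_cols], axis=1)
        mean_night = np.nanmean(vals[:, night_cols], axis=1)
    for fid, d, n in zip(m.data.index, mean_day, mean_night):
        hi, lo = max(d, n), min(d, n)
        flagged = False
        if np.isnan(d) or np.isnan(n):
            fc, selected, flagged = np.nan, False, True
        elif lo == 0:
            if hi == 0:
                fc, selected, flagged = np.nan, False, True
            else:
                fc, selected, flagged = np.inf, True, True
        else:
            fc = hi / lo
            selected = fc > threshold
        rows.append((fid, d, n, fc, selected, flagged))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "mean_day", "mean_night", "fold_change", "selected", "flagged"],
    )
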