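"""Label-free quantification transforms: iBAQ -> FOT and per-cycle z-scores.

FOT ("fraction of total") divides every column by its column total over
non-missing entries, making runs compositionally comparable.  The z-score
transform standardises each feature within each circadian cycle,
z = (x - mu) / sigma, with mu and sigma the per-cycle mean and sample
standard deviation of that feature.  Constant (sigma = 0) cycles carry no
rhythm information and are set to missing rather than zero, so that the
downstream rank test never sees fabricated ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import OmicsMatrix

logger = logging.getLogger("circatf")

DEFAULT_CYCLES = ((0.0, 24.0), (24.0, 48.0))


@dataclass
class CycleSpec:
    """Half-open ``[start, end)`` hour intervals partitioning the timepoints."""

    cycle_boundaries: tuple[tuple[float, float], ...] = DEFAULT_CYCLES

    def __post_init__(self) -> None:
        iv = sorted(self.cycle_boundaries)
        for (a, b) in iv:
            if b <= a:
                raise ValueError(f"empty cycle interval ({a}, {b})")
        for (_, b1), (a2, _) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValueError("cycle intervals must be disjoint")
        self.cycle_boundaries = tuple(tuple(c) for c in iv)

    @classmethod
    def for_timepoints(cls, timepoints) -> "CycleSpec":
        """Default two-cycle layout restricted to intervals actually sampled."""
        tps = np.asarray(timepoints, dtype=float)
        kept = tuple(
            (a, b) for a, b in DEFAULT_CYCLES if np.any((tps >= a) & (tps < b))
        )
        if not kept:
            raise ValueError("no default cycle interval covers the timepoints")
        return cls(kept)

    def assign(self, timepoints) -> list[np.ndarray]:
        """Column-index arrays per cycle; every timepoint must be covered."""
        tps = np.asarray(timepoints, dtype=float)
        covered = np.zeros(len(tps), dtype=bool)
        groups = []
        for a, b in self.cycle_boundaries:
            sel = (tps >= a) & (tps < b)
            covered |= sel
            groups.append(np.flatnonzero(sel))
        if not covered.all():
            missing = tps[~covered]
            raise ValueError(f"timepoints {missing.tolist()} not covered by cycles")
        return [g for g in groups if g.size]


def ibaq_to_fot(m: OmicsMatrix) -> OmicsMatrix:
    """Divide each column by its sum over non-missing entries.

    Requires a raw matrix; every column must have at least one positive
    value (an all-zero column is a degenerate run and raises, naming the
    ZT column).  Scale-invariant per column by construction.
    """
    if m.norm_state != "raw":
        raise ValueError(f"ibaq_to_fot expects raw values, got {m.norm_state!r}")
    vals = m.data.to_numpy(dtype=float)
    totals = np.nansum(vals, axis=0)
    for j, tot in enumerate(totals):
        if not tot > 0:
            raise ValueError(f"column ZT{int(m.data.columns[j])} has no positive value")
    return m.with_values(vals / totals, "fot")


def zscore_per_cycle(
    m: OmicsMatrix, cycles: CycleSpec | None = None, joint: bool = False
) -> OmicsMatrix:
    """Standardise each feature within each cycle to mean 0, sample sd 1.

    Cycles with fewer than two non-missing values, or zero variance, have
    their entries set to missing and the feature is logged as degenerate
    for that cycle.  With ``joint=True`` the cycles are standardised
    together (single mu/sigma over all timepoints).
    """
    if m.norm_state not in ("fot", "fpkm", "raw"):
        raise ValueError(f"cannot z-score a matrix in state {m.norm_state!r}")
    if cycles is None:
        cycles = CycleSpec.for_timepoints(m.timepoints)
    groups = (
        [np.arange(m.data.shape[1])] if joint else cycles.assign(m.timepoints)
    )
    vals = m.data.to_numpy(dtype=float).copy()
    n_degen = 0
    for g in groups:
        block = vals[:, g]
        n_ok = np.sum(~np.isnan(block), axis=1)
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(block, axis=1, keepdims=True)
            sd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        bad = (n_ok < 2) | (sd[:, 0] == 0) | np.isnan(sd[:, 0])
        with np.errstate(invalid="ignore", divide="ignore"):
            block = (block - mu) / sd
        block[bad, :] = np.nan
        n_degen += int(bad.sum())
        vals[:, g] = block
    if n_degen:
        logger.info("zscore_per_cycle: %d degenerate feature-cycle(s) set missing", n_degen)
    out_state = "fpkm_zscored" if m.norm_state == "fpkm" else "zscored"
    return m.with_values(vals, out_state)
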