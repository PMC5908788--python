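"""Nonparametric rhythmicity detection in the JTK_CYCLE family.

Each feature's time series is compared against cosine reference templates
over a period x phase-lag grid by Kendall-tau concordance.  The
concordance statistic S (#concordant - #discordant pairs over pairs
untied in the reference) has an exact null distribution under uniformly
random data orderings given the reference's tie pattern: the number of
concordant pairs is distributed as the inversion count of a random
multiset permutation, whose generating function is the Gaussian
(q-)multinomial coefficient.  We compute it by dynamic-programming
convolution of q-binomial coefficient arrays — the same null as the
Jonckheere-Terpstra statistic for the reference's tie groups.

The minimum p over the template grid is Bonferroni-adjusted by the
(deduplicated) template count, paying for the free amplitude/phase
search, and features are classified rhythmic at a per-layer alpha.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import OmicsMatrix, RunConfig

# fraction of data-tied pairs above which the exact reference-tie null is
# abandoned for a seeded permutation estimate
TIE_FALLBACK_FRACTION = 0.25
N_PERMUTATIONS = 10_000
MAX_EXACT_N = 50


@dataclass(frozen=True)
class ReferenceTemplate:
    """Cosine reference ordering for one (period, lag) grid point."""

    period_h: float
    lag_h: float
    ranks: tuple[float, ...]  # average ranks of cos(2pi (t - lag)/period)
    tie_pattern: tuple[int, ...]  # sorted multiset of tie-group sizes

    @property
    def n(self) -> int:
        return len(self.ranks)


def admissible_periods(period_range_h, sampling_interval_h) -> list[float]:
    """Periods in the search window that are integer multiples of the
    sampling interval (reference ranks must align to sampled phases)."""
    lo, hi = period_range_h
    dt = float(sampling_interval_h)
    k_lo = max(int(np.ceil(lo / dt - 1e-9)), 1)
    k_hi = int(np.floor(hi / dt + 1e-9))
    return [k * dt for k in range(k_lo, k_hi + 1)]


def _cosine_ranks(timepoints, period: float, lag: float) -> np.ndarray:
    ref = np.cos(2 * np.pi * (np.asarray(timepoints, dtype=float) - lag) / period)
    return rankdata(np.round(ref, 9), method="average")


def _tie_pattern(ranks: np.ndarray) -> tuple[int, ...]:
    _, counts = np.unique(ranks, return_counts=True)
    return tuple(sorted(int(c) for c in counts))


def build_reference_grid(timepoints, config: RunConfig) -> list[ReferenceTemplate]:
    """Enumerate templates over the period x lag grid, deduplicated by rank
    vector.  Lags step by the sampling interval within [0, period)."""
    periods = admissible_periods(config.period_range_h, config.sampling_interval_h)
    if not periods:
        raise ValueError(
            f"no admissible period in {config.period_range_h} at "
            f"{config.sampling_interval_h} h sampling"
        )
    dt = config.sampling_interval_h
    seen: set[tuple[float, ...]] = set()
    out: list[ReferenceTemplate] = []
    for period in periods:
        for lag in np.arange(0.0, period - 1e-9, dt):
            ranks = _cosine_ranks(timepoints, period, float(lag))
            key = tuple(ranks)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ReferenceTemplate(
                    period_h=float(period),
                    lag_h=float(lag),
                    ranks=key,
                    tie_pattern=_tie_pattern(ranks),
                )
            )
    return out


# ---------------------------------------------------------------------------
# exact null distribution of S


def _gaussian_binomial(m: int, t: int) -> np.ndarray:
    """Coefficient array of the q-binomial [m+t choose t]_q.

    Entry k counts the interleavings of a t-element block into m earlier
    elements that produce exactly k crossing pairs.  Recurrence
    f(i, j) = f(i-1, j) + q^i f(i, j-1).
    """
    if m == 0 or t == 0:
        return np.ones(1)
    f = [np.ones(1)] + [None] * t  # f[j] holds f(i, j) as i advances
    for j in range(1, t + 1):
        f[j] = np.ones(1)  # f(0, j) = 1
    for i in range(1, m + 1):
        for j in range(1, t + 1):
            a = f[j]  # f(i-1, j)
            b = f[j - 1]  # f(i, j-1), already updated this i
            size = max(len(a), len(b) + i)
            new = np.zeros(size)
            new[: len(a)] += a
            new[i : i + len(b)] += b
            f[j] = new
    return f[t]


@functools.lru_cache(maxsize=4096)
def _concordance_null(tie_pattern: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """(probability array over K = #concordant pairs, M = #untied pairs)."""
    poly = np.ones(1)
    placed = 0
    for t in tie_pattern:
        poly = np.convolve(poly, _gaussian_binomial(placed, t))
        placed += t
    n = placed
    m_pairs = n * (n - 1) // 2 - sum(t * (t - 1) // 2 for t in tie_pattern)
    assert len(poly) == m_pairs + 1
    return poly / poly.sum(), m_pairs


@functools.lru_cache(maxsize=4096)
def _abs_s_tail(tie_pattern: tuple[int, ...]) -> np.ndarray:
    """Array p[a] = P(|S| >= a) for a = 0..M, under the exact null."""
    probs, m_pairs = _concordance_null(tie_pattern)
    s_vals = 2 * np.arange(m_pairs + 1) - m_pairs
    tail = np.zeros(m_pairs + 1)
    for a in range(m_pairs + 1):
        tail[a] = probs[np.abs(s_vals) >= a].sum()
    tail[0] = 1.0  # P(|S| >= 0) exactly
    return np.minimum(tail, 1.0)


def exact_null_pvalue(
    s: int,
    n: int,
    tie_pattern,
    rng: np.random.Generator | None = None,
    n_perm: int = N_PERMUTATIONS,
) -> float:
    """Two-sided P(|S_null| >= |s|) for untied data against a reference with
    the given tie pattern.

    Exact by DP convolution for n <= 50; beyond that a seeded permutation
    approximation with ``n_perm`` draws is used (``rng`` required).
    """
    pattern = tuple(sorted(int(t) for t in tie_pattern))
    if sum(pattern) != n:
        raise ValueError(f"tie pattern {pattern} does not sum to n={n}")
    if n <= MAX_EXACT_N:
        tail = _abs_s_tail(pattern)
        a = min(abs(int(s)), len(tail) - 1)
        return float(max(tail[a], np.finfo(float).tiny))
    if rng is None:
        raise ValueError("n > 50 requires a seeded rng for the permutation null")
    ranks = np.repeat(np.arange(len(pattern)), pattern).astype(float)
    count = 0
    for _ in range(n_perm):
        x = rng.permutation(n).astype(float)
        sp, _, _ = kendall_s(x, ranks)
        if abs(sp) >= abs(s):
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# concordance statistic


def kendall_s(x, ref_ranks) -> tuple[int, float, int]:
    """Concordance of data ``x`` with a reference ranking.

    Returns ``(S, tau, n_used)`` where S = #concordant - #discordant over
    pairs untied in the reference (data-tied pairs contribute zero), tau
    divides S by the number of pairs untied in both reference and data,
    and ``n_used`` is the number of non-missing points.  Missing entries
    are excluded pairwise.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(ref_ranks, dtype=float)
    ok = ~np.isnan(x)
    x, r = x[ok], r[ok]
    n = len(x)
    if n < 2:
        return 0, 0.0, n
    i, j = np.triu_indices(n, k=1)
    ref_diff = np.sign(r[j] - r[i])
    dat_diff = np.sign(x[j] - x[i])
    untied_ref = ref_diff != 0
    s = int(np.sum(ref_diff[untied_ref] * dat_diff[untied_ref]))
    denom = int(np.sum(untied_ref & (dat_diff != 0)))
    tau = s / denom if denom else 0.0
    return s, tau, n


def _data_tie_fraction(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        return 0.0
    _, counts = np.unique(x, return_counts=True)
    tied = sum(c * (c - 1) // 2 for c in counts)
    return tied / (n * (n - 1) // 2)


def _permutation_pvalue(
    x: np.ndarray, ranks: np.ndarray, s_obs: int, rng: np.random.Generator
) -> float:
    """Seeded permutation p for data whose own ties exceed the fallback
    threshold (the reference-tie exact null would be anti-conservative)."""
    count = 0
    for _ in range(N_PERMUTATIONS):
        sp, _, _ = kendall_s(rng.permutation(x), ranks)
        if abs(sp) >= abs(s_obs):
            count += 1
    return (1 + count) / (N_PERMUTATIONS + 1)


# ---------------------------------------------------------------------------
# per-matrix test

RHYTHM_COLUMNS = [
    "feature_id",
    "best_period_h",
    "best_lag_h",
    "tau",
    "S",
    "amplitude_est",
    "p_raw",
    "p_adj",
    "rhythmic",
]


def _amplitude_estimate(x: np.ndarray, ranks: np.ndarray) -> float:
    """Half the contrast between means at the template's top- and
    bottom-quartile reference ranks (non-canonical estimator)."""
    ok = ~np.isnan(x)
    x, r = x[ok], np.asarray(ranks)[ok]
    n = len(x)
    if n < 4:
        return float("nan")
    k = max(1, n // 4)
    order = np.argsort(r, kind="stable")
    bot = x[order[:k]]
    top = x[order[-k:]]
    return float((top.mean() - bot.mean()) / 2)


def _peak_lag(tmpl: ReferenceTemplate, tau: float) -> float:
    """Estimated peak clock time (ZT, in [0, 24)) for the winning template.

    The two-sided test cannot distinguish a template from its antiphase,
    and for off-24 periods the antiphase lag is not on the lag grid, so a
    discordant fit (tau < 0) marks a peak half a period away.  Off-24
    periods drift across the two sampled cycles; the two in-window peaks
    (lag and lag + period, mod 24) are averaged, which reduces to the lag
    itself for a 24-h template.
    """
    lag = tmpl.lag_h
    if tau < 0:
        lag += tmpl.period_h / 2.0
    return (lag + (tmpl.period_h - 24.0) / 2.0) % 24.0


def jtk_cycle(
    m: OmicsMatrix,
    config: RunConfig,
    alpha: float | None = None,
    grid: list[ReferenceTemplate] | None = None,
) -> pd.DataFrame:
    """Run the rhythm test on every feature of a (normalized) matrix.

    Per feature: the minimum two-sided p over the template grid, the
    winning period and estimated peak ZT (see :func:`_peak_lag`; ties in
    p broken by larger \\|tau\\|, then larger signed tau, then smaller
    period, then smaller lag), a Bonferroni adjustment by the template
    count, and a quartile-contrast amplitude estimate.  Degenerate
    features (all-tied or < 4 usable points) are carried through with
    p = 1.
    """
    if alpha is None:
        alpha = config.alpha_for_layer(m.layer)
    tps = m.timepoints
    if grid is None:
        grid = build_reference_grid(tps, config)
    n_templates = len(grid)
    values = m.data.to_numpy(dtype=float)
    n_feat, n_tp = values.shape

    rank_mat = np.array([t.ranks for t in grid])  # T x n
    i_idx, j_idx = np.triu_indices(n_tp, k=1)

    # per-template pair machinery
    ref_sign = np.sign(rank_mat[:, j_idx] - rank_mat[:, i_idx])  # T x P
    tails = [_abs_s_tail(t.tie_pattern) for t in grid]

    tie_frac = np.apply_along_axis(_data_tie_fraction, 1, values)
    has_nan = np.isnan(values).any(axis=1)
    n_ok = (~np.isnan(values)).sum(axis=1)
    fast = ~has_nan & (tie_frac <= TIE_FALLBACK_FRACTION)

    # statistic arrays: p, tau, S per feature x template
    p_all = np.ones((n_feat, n_templates))
    tau_all = np.zeros((n_feat, n_templates))
    s_all = np.zeros((n_feat, n_templates), dtype=int)
    degenerate = np.zeros(n_feat, dtype=bool)

    if fast.any():
        xv = values[fast]
        dat_sign = np.sign(xv[:, j_idx] - xv[:, i_idx])  # F x P
        all_tied = (dat_sign == 0).all(axis=1)
        for ti in range(n_templates):
            rs = ref_sign[ti]
            untied = rs != 0
            s = (dat_sign[:, untied] * rs[untied]).sum(axis=1).astype(int)
            denom = np.maximum((dat_sign[:, untied] != 0).sum(axis=1), 1)
            tail = tails[ti]
            p = tail[np.minimum(np.abs(s), len(tail) - 1)]
            rows = np.flatnonzero(fast)
            p_all[rows, ti] = np.where(all_tied, 1.0, p)
            tau_all[rows, ti] = np.where(all_tied, 0.0, s / denom)
            s_all[rows, ti] = s
        degenerate[np.flatnonzero(fast)[all_tied]] = True

    slow_rows = np.flatnonzero(~fast)
    for row in slow_rows:
        x = values[row]
        if n_ok[row] < 4:
            degenerate[row] = True
            continue
        heavy_ties = tie_frac[row] > TIE_FALLBACK_FRACTION
        rng = (
            np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), int(row)]))
            if heavy_ties
            else None
        )
        all_tied = len(np.unique(x[~np.isnan(x)])) < 2
        if all_tied:
            degenerate[row] = True
            continue
        ok = ~np.isnan(x)
        for ti, tmpl in enumerate(grid):
            sub_ranks = rankdata(np.asarray(tmpl.ranks)[ok], method="average")
            s, tau, n_used = kendall_s(x[ok], sub_ranks)
            if heavy_ties:
                p = _permutation_pvalue(x[ok], sub_ranks, s, rng)
            else:
                p = exact_null_pvalue(s, n_used, _tie_pattern(sub_ranks))
            p_all[row, ti] = p
            tau_all[row, ti] = tau
            s_all[row, ti] = s

    # best template per feature: min p, tie-break |tau| desc, then signed tau
    # desc (the antiphase template shares p and |tau|; the concordant one
    # carries the phase), then smaller period, smaller lag
    periods = np.array([t.period_h for t in grid])
    lags = np.array([t.lag_h for t in grid])
    order_key = np.lexsort(
        (lags[None, :] * np.ones((n_feat, 1)),
         periods[None, :] * np.ones((n_feat, 1)),
         -tau_all,
         -np.abs(tau_all),
         p_all),
        axis=1,
    )
    best = order_key[:, 0]

    rows_out = []
    for fi, fid in enumerate(m.data.index):
        if degenerate[fi]:
            rows_out.append((fid, np.nan, np.nan, 0.0, 0, np.nan, 1.0, 1.0, False))
            continue
        ti = best[fi]
        p_raw = float(p_all[fi, ti])
        p_adj = min(1.0, p_raw * n_templates)
        amp = _amplitude_estimate(values[fi], np.asarray(grid[ti].ranks))
        rows_out.append(
            (
                fid,
                grid[ti].period_h,
                _peak_lag(grid[ti], float(tau_all[fi, ti])),
                float(tau_all[fi, ti]),
                int(s_all[fi, ti]),
                amp,
                p_raw,
                p_adj,
                bool(p_adj < alpha),
            )
        )
    return pd.DataFrame(rows_out, columns=RHYTHM_COLUMNS)


def classify_rhythmic(rt: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Re-flag a rhythm table at a (strict) adjusted-p threshold."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    out = rt.copy()
    out["rhythmic"] = out["p_adj"] < alpha
    return out
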