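"""Dominant-rhythmic-TF (DR-TF) nomination and ubiquitylation coupling.

A DR-TF must (a) show rhythmic DNA-binding activity, (b) have at least
``min_tg`` target genes measured in the transcriptome, and (c) have
targets enriched for rhythmicity against the transcriptome background
(one-sided hypergeometric test).  TF->target edges are additionally
labelled activator (Pearson r > 0.5 between TF DBA and target transcript)
or repressor (r < -0.5), both strict.

Ubiquitylation analyses cross-tabulate ubiquitylated fractions among
rhythmic vs non-rhythmic TFs and their target-gene unions, and compare
the observed ubiquitylated-target count of the rhythmic TFs against
same-size random TF sets (add-one permutation p, never zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("circatf")


def targets_of(net: nx.DiGraph, tf: str) -> list[str]:
    return sorted(net.successors(tf)) if tf in net else []


def _pairwise_complete_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, n
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan, n
    return float(np.corrcoef(xs, ys)[0, 1]), n


def classify_regulator_sign(
    tf_profile,
    tg_profiles: pd.DataFrame,
    r_act: float = 0.5,
    r_rep: float = -0.5,
) -> pd.DataFrame:
    """Label each TF->target edge by the sign of the TF-DBA / target
    correlation: activator iff r > r_act, repressor iff r < r_rep, else
    unclassified.  Pairwise-complete over the timepoints; fewer than
    three shared points or a zero-variance profile leaves the edge
    unclassified and flagged."""
    x = np.asarray(tf_profile, dtype=float)
    rows = []
    for tg in tg_profiles.index:
        r, n = _pairwise_complete_r(x, tg_profiles.loc[tg].to_numpy(dtype=float))
        if np.isnan(r):
            label, flagged = "unclassified", True
        elif r > r_act:
            label, flagged = "activator", False
        elif r < r_rep:
            label, flagged = "repressor", False
        else:
            label, flagged = "unclassified", False
        rows.append((tg, r, n, label, flagged))
    return pd.DataFrame(rows, columns=["target", "r", "n_points", "label", "flagged"])


DRTF_COLUMNS = [
    "tf_id",
    "rhythmic_dba",
    "n_targets",
    "n_rhythmic_targets",
    "target_rhythm_p",
    "is_dr_tf",
    "insufficient_targets",
    "n_activated",
    "n_repressed",
    "n_unclassified",
]


def nominate_dr_tfs(
    tf_rhythms: pd.DataFrame,
    tg_rhythms: pd.DataFrame,
    net: nx.DiGraph,
    min_tg: int = 3,
    enrich_alpha: float = 0.05,
    tf_matrix=None,
    tg_matrix=None,
    r_act: float = 0.5,
    r_rep: float = -0.5,
) -> pd.DataFrame:
    """Nominate DR-TFs and (optionally) count activated/repressed targets.

    ``tf_rhythms`` / ``tg_rhythms`` are rhythm tables for the TF-DBA and
    transcriptome layers; the background for the hypergeometric enrichment
    is every gene in ``tg_rhythms``.  If z-scored ``tf_matrix`` and
    ``tg_matrix`` (:class:`~circatf.io.OmicsMatrix`) are given, per-edge
    activator/repressor counts are filled in.
    """
    if net.number_of_edges() == 0:
        raise ValueError("empty TF->TG network")
    tf_flag = tf_rhythms.set_index("feature_id")["rhythmic"]
    tg_flag = tg_rhythms.set_index("feature_id")["rhythmic"]
    n_bg = len(tg_flag)
    n_bg_rhythmic = int(tg_flag.sum())
    rows = []
    for tf in sorted(n for n in net.nodes if net.out_degree(n) > 0):
        if tf not in tf_flag.index:
            continue
        tgs = [t for t in targets_of(net, tf) if t in tg_flag.index]
        n_t = len(tgs)
        n_r = int(tg_flag.loc[tgs].sum()) if n_t else 0
        rhythmic = bool(tf_flag.loc[tf])
        insufficient = n_t < min_tg
        if n_t:
            p = float(stats.hypergeom.sf(n_r - 1, n_bg, n_bg_rhythmic, n_t))
        else:
            p = 1.0
        is_dr = rhythmic and not insufficient and p < enrich_alpha
        n_act = n_rep = n_unc = 0
        if tf_matrix is not None and tg_matrix is not None and n_t:
            present = [t for t in tgs if t in tg_matrix.data.index]
            if tf in tf_matrix.data.index and present:
                signs = classify_regulator_sign(
                    tf_matrix.data.loc[tf].to_numpy(dtype=float),
                    tg_matrix.data.loc[present],
                    r_act,
                    r_rep,
                )
                n_act = int((signs["label"] == "activator").sum())
                n_rep = int((signs["label"] == "repressor").sum())
            n_unc = n_t - n_act - n_rep
        rows.append(
            (tf, rhythmic, n_t, n_r, p, is_dr, insufficient, n_act, n_rep, n_unc)
        )
    return pd.DataFrame(rows, columns=DRTF_COLUMNS)


@dataclass
class UbiCrosstab:
    """Ubiquitylated percentages (0-100, ``None`` for empty denominators)."""

    pct_rhythmic_tfs: float | None
    pct_nonrhythmic_tfs: float | None
    pct_tgs_of_rhythmic: float | None
    pct_tgs_of_nonrhythmic: float | None
    counts: dict

    def to_dict(self) -> dict:
        return {
            "pct_rhythmic_tfs": self.pct_rhythmic_tfs,
            "pct_nonrhythmic_tfs": self.pct_nonrhythmic_tfs,
            "pct_tgs_of_rhythmic": self.pct_tgs_of_rhythmic,
            "pct_tgs_of_nonrhythmic": self.pct_tgs_of_nonrhythmic,
            "counts": self.counts,
        }


def _pct(k: int, n: int) -> float | None:
    return 100.0 * k / n if n else None


def ubiquitylation_crosstab(
    tf_rhythms: pd.DataFrame, net: nx.DiGraph, ubi_set
) -> UbiCrosstab:
    """Ubiquitylated fractions among rhythmic / non-rhythmic TFs and among
    the unions of their target genes (a shared target counts once)."""
    ubi = set(ubi_set)
    flags = tf_rhythms.set_index("feature_id")["rhythmic"]
    tfs_in_net = [t for t in flags.index if t in net and net.out_degree(t) > 0]
    r_tfs = [t for t in tfs_in_net if flags.loc[t]]
    nr_tfs = [t for t in tfs_in_net if not flags.loc[t]]
    r_tgs = set().union(*(targets_of(net, t) for t in r_tfs)) if r_tfs else set()
    nr_tgs = set().union(*(targets_of(net, t) for t in nr_tfs)) if nr_tfs else set()
    counts = {
        "n_rhythmic_tfs": len(r_tfs),
        "n_nonrhythmic_tfs": len(nr_tfs),
        "n_ubi_rhythmic_tfs": len(ubi & set(r_tfs)),
        "n_ubi_nonrhythmic_tfs": len(ubi & set(nr_tfs)),
        "n_tgs_of_rhythmic": len(r_tgs),
        "n_tgs_of_nonrhythmic": len(nr_tgs),
        "n_ubi_tgs_of_rhythmic": len(ubi & r_tgs),
        "n_ubi_tgs_of_nonrhythmic": len(ubi & nr_tgs),
    }
    return UbiCrosstab(
        pct_rhythmic_tfs=_pct(counts["n_ubi_rhythmic_tfs"], counts["n_rhythmic_tfs"]),
        pct_nonrhythmic_tfs=_pct(
            counts["n_ubi_nonrhythmic_tfs"], counts["n_nonrhythmic_tfs"]
        ),
        pct_tgs_of_rhythmic=_pct(
            counts["n_ubi_tgs_of_rhythmic"], counts["n_tgs_of_rhythmic"]
        ),
        pct_tgs_of_nonrhythmic=_pct(
            counts["n_ubi_tgs_of_nonrhythmic"], counts["n_tgs_of_nonrhythmic"]
        ),
        counts=counts,
    )


def random_tf_resample_test(
    net: nx.DiGraph,
    ubi_set,
    rhythmic_tfs,
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict:
    """Empirical enrichment of ubiquitylated targets of the rhythmic TFs.

    The statistic is the number of ubiquitylated genes in the union of the
    rhythmic TFs' target sets; the null redraws same-size TF sets
    uniformly without replacement ``n_iter`` times.  Returns the observed
    statistic, the null mean, and the add-one empirical p
    (1 + #{null >= obs}) / (n_iter + 1).
    """
    if n_iter < 100:
        raise ValueError(f"n_iter must be >= 100, got {n_iter}")
    all_tfs = sorted(n for n in net.nodes if net.out_degree(n) > 0)
    rhythmic = sorted(set(rhythmic_tfs) & set(all_tfs))
    k = len(rhythmic)
    if k > len(all_tfs):
        raise ValueError("more rhythmic TFs than TFs in the network")
    genes = sorted(set().union(*(targets_of(net, t) for t in all_tfs)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    a = np.zeros((len(all_tfs), len(genes)), dtype=np.float32)
    for ti, tf in enumerate(all_tfs):
        for g in targets_of(net, tf):
            a[ti, gene_idx[g]] = 1.0
    ubi_vec = np.array([g in set(ubi_set) for g in genes])

    rset = [all_tfs.index(t) for t in rhythmic]
    observed = int(((a[rset].sum(axis=0) > 0) & ubi_vec).sum()) if rset else 0

    rng = np.random.default_rng(seed)
    if k == 0 or k == len(all_tfs):
        null_stats = np.full(n_iter, observed)
    else:
        # sample without replacement per draw via random-key argpartition
        keys = rng.random((n_iter, len(all_tfs)))
        sel = np.argpartition(keys, k, axis=1)[:, :k]
        null_stats = np.empty(n_iter)
        chunk = 256
        for start in range(0, n_iter, chunk):
            idx = sel[start : start + chunk]
            pick = np.zeros((len(idx), len(all_tfs)), dtype=np.float32)
            np.put_along_axis(pick, idx, 1.0, axis=1)
            union = (pick @ a) > 0
            null_stats[start : start + len(idx)] = (union & ubi_vec).sum(axis=1)
    p = (1 + int((null_stats >= observed).sum())) / (n_iter + 1)
    return {
        "observed": observed,
        "null_mean": float(null_stats.mean()),
        "p": float(p),
        "n_iter": n_iter,
        "n_tfs": len(all_tfs),
        "n_rhythmic_tfs": k,
    }
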