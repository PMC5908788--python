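"""Graph and correlation analyses around the regulatory core.

Covers unweighted shortest paths from phosphorylated substrates to TFs on
a PPI graph, paired comparison of mean path lengths, linking TFs to their
top-k correlated Mediator subunits, paired comparison of correlation
sets, bipartite edge counts between Kupffer-cell and whole-liver protein
sets, and a generic hypergeometric (Fisher-style) set enrichment with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("circatf")


@dataclass
class TestResult:
    statistic: float
    df: int
    p_two_sided: float


def pearson_r(x, y) -> float:
    """Product-moment correlation on pairwise-complete entries.

    Requires at least three complete pairs and nonzero variance in both
    vectors (raises otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("pearson_r needs >= 3 pairwise-complete pairs")
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("pearson_r undefined for a zero-variance vector")
    return float(np.corrcoef(xs, ys)[0, 1])


def shortest_path_lengths(g: nx.Graph, sources, targets) -> pd.DataFrame:
    """Unweighted (BFS) shortest-path length for every (source, target)
    pair; unreachable pairs carry NaN.  Nodes absent from the graph are
    logged and skipped."""
    sources = sorted(set(sources))
    targets = sorted(set(targets))
    if not sources or not targets:
        raise ValueError("sources and targets must be non-empty")
    src_in = [s for s in sources if s in g]
    tgt_in = [t for t in targets if t in g]
    n_absent = (len(sources) - len(src_in)) + (len(targets) - len(tgt_in))
    if n_absent:
        logger.info("shortest_path_lengths: skipped %d node(s) absent from graph", n_absent)
    if not src_in or not tgt_in:
        raise ValueError("no source/target nodes present in the graph")
    rows = []
    for s in src_in:
        dist = nx.single_source_shortest_path_length(g, s)
        for t in tgt_in:
            rows.append((s, t, float(dist[t]) if t in dist else np.nan))
    return pd.DataFrame(rows, columns=["source", "target", "length"])


def substrate_path_summary(
    g: nx.Graph, substrates, pathway_tfs, all_tfs
) -> pd.DataFrame:
    """Per-substrate mean shortest-path length to the pathway-specific TFs
    and to all detected TFs (means over reachable targets only)."""
    lp = shortest_path_lengths(g, substrates, set(pathway_tfs) | set(all_tfs))
    pathway = set(pathway_tfs)
    allset = set(all_tfs)
    rows = []
    for s, sub in lp.groupby("source"):
        pw = sub[sub["target"].isin(pathway)]["length"].dropna()
        al = sub[sub["target"].isin(allset)]["length"].dropna()
        rows.append(
            (
                s,
                pw.mean() if len(pw) else np.nan,
                al.mean() if len(al) else np.nan,
                len(pw),
                len(al),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "substrate_id",
            "mean_path_to_pathway_tfs",
            "mean_path_to_all_tfs",
            "n_reachable_pathway",
            "n_reachable_all",
        ],
    )


def paired_t(diffs: np.ndarray) -> TestResult:
    """Two-sided paired Student's t on per-entity differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    n = len(d)
    if n < 3:
        raise ValueError("paired t-test needs >= 3 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate paired t-test: all differences equal")
    t = d.mean() * np.sqrt(n) / sd
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(statistic=float(t), df=n - 1, p_two_sided=float(p))


def compare_path_lengths(ps: pd.DataFrame) -> TestResult:
    """Paired t-test of per-substrate mean path length to pathway TFs vs to
    all TFs."""
    sub = ps.dropna(subset=["mean_path_to_pathway_tfs", "mean_path_to_all_tfs"])
    if len(sub) < 3:
        raise ValueError("need >= 3 substrates with both means defined")
    return paired_t(
        sub["mean_path_to_pathway_tfs"].to_numpy()
        - sub["mean_path_to_all_tfs"].to_numpy()
    )


def top_k_correlated_mediators(
    tf_profiles: pd.DataFrame, mediator_profiles: pd.DataFrame, k: int = 3
) -> pd.DataFrame:
    """Link each TF to its k highest-Pearson-correlated Mediator subunits
    (pairwise-complete); ties on r break lexicographically by mediator id,
    and TFs with fewer than k mediators link to all of them, flagged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for tf in tf_profiles.index:
        x = tf_profiles.loc[tf].to_numpy(dtype=float)
        rs = []
        for med in mediator_profiles.index:
            y = mediator_profiles.loc[med].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            rs.append((med, float(np.corrcoef(x[ok], y[ok])[0, 1])))
        rs.sort(key=lambda mr: (-mr[1], mr[0]))
        short = len(rs) < k
        for rank, (med, r) in enumerate(rs[:k], start=1):
            rows.append((tf, med, r, rank, short))
    return pd.DataFrame(rows, columns=["tf_id", "mediator_id", "r", "rank", "fewer_than_k"])


def compare_correlation_sets(
    r_pathway: pd.DataFrame, r_all: pd.DataFrame
) -> dict:
    """Compare TF-Mediator correlations of pathway-specific TFs against all
    TFs.  Inputs are long tables with columns (tf_id, mediator_id, r).
    Reports both set means and a two-sided paired t-test on per-mediator
    average correlations (pairing unit: the Mediator subunit)."""
    if len(r_pathway) < 3 or len(r_all) < 3:
        raise ValueError("both correlation sets need >= 3 entries")
    mean_pw = float(r_pathway["r"].mean())
    mean_all = float(r_all["r"].mean())
    by_med_pw = r_pathway.groupby("mediator_id")["r"].mean()
    by_med_all = r_all.groupby("mediator_id")["r"].mean()
    common = sorted(set(by_med_pw.index) & set(by_med_all.index))
    if len(common) < 3:
        raise ValueError("need >= 3 mediators present in both sets")
    diffs = by_med_pw.loc[common].to_numpy() - by_med_all.loc[common].to_numpy()
    if np.all(diffs == 0):
        # identical correlation sets: no evidence either way
        res = TestResult(statistic=0.0, df=len(common) - 1, p_two_sided=1.0)
    else:
        res = paired_t(diffs)
    return {
        "mean_r_pathway": mean_pw,
        "mean_r_all": mean_all,
        "t": res.statistic,
        "df": res.df,
        "p_two_sided": res.p_two_sided,
        "n_mediators": len(common),
    }


def bipartite_edge_count(set_a, set_b, g: nx.Graph) -> int:
    """Number of graph edges with one endpoint in ``set_a`` and the other
    in ``set_b`` (each qualifying edge counted once; edges inside one set
    only do not count)."""
    sa, sb = set(set_a), set(set_b)
    return sum(
        1
        for u, v in g.edges()
        if (u in sa and v in sb) or (u in sb and v in sa)
    )


def fisher_enrichment(
    fg, bg, sets: dict, bh: bool = True
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``fg`` within each
    annotation set, against background ``bg``.

    Foreground and annotation ids outside the background are logged and
    clipped.  Returns per-set counts, p, and (optionally) BH q-values.
    """
    bg = set(bg)
    fg = set(fg)
    if not fg:
        raise ValueError("empty foreground set")
    clipped = len(fg - bg)
    fg = fg & bg
    if clipped:
        logger.info("fisher_enrichment: clipped %d foreground id(s) outside background", clipped)
    if not fg:
        raise ValueError("foreground has no overlap with background")
    n_bg, n_fg = len(bg), len(fg)
    rows = []
    for name in sorted(sets):
        members = set(sets[name])
        out = len(members - bg)
        if out:
            logger.info(
                "fisher_enrichment: set %s: clipped %d id(s) outside background", name, out
            )
        members &= bg
        k = len(fg & members)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n_fg))
        rows.append((name, len(members), k, p))
    df = pd.DataFrame(rows, columns=["set", "n_set", "n_overlap", "p"])
    if bh and len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
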