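"""Synthetic multi-layer circadian study generator with known ground truth.

The planted model per feature is a cosine with Gaussian noise,

    x(t) = baseline + amplitude * cos(2*pi*(t - acrophase)/period) + N(0, noise_sd),

truncated at zero for raw abundance layers.  The generator emulates the
study design: 16 timepoints (ZT0..ZT45, 3-h sampling over two cycles) for
the main layers, a single cycle for the ubiquitylome and four timepoints
(ZT0/6/12/18) for the Kupffer-cell proteome.  Rhythmic TFs receive
acrophases at the four time-phase midpoints (ZT1.5/7.5/13.5/19.5) with a
large relative amplitude, an on/off DNA-binding pattern that makes them
TP-specific by construction; target genes of "dominant" rhythmic TFs are
sign-coupled to their TF (activators share the acrophase, repressors are
shifted 12 h) with independent noise.  ``noise_sd`` is the reference
amplitude divided by ``snr`` for every feature, so ``snr=inf`` is the
noiseless limit.

Every planted parameter is recorded in a :class:`SyntheticTruth` so each
downstream stage has a recovery-testable input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import OmicsMatrix, write_edge_list, write_omics_table

TWO_CYCLE_TPS = tuple(range(0, 48, 3))  # 16 points
ONE_CYCLE_TPS = tuple(range(0, 24, 3))  # 8 points
KC_TPS = (0, 6, 12, 18)
TP_MIDPOINTS = (1.5, 7.5, 13.5, 19.5)

ALL_LAYERS = (
    "tf_dba",
    "transcriptome",
    "whole_proteome",
    "nuclear",
    "phospho",
    "ubiquitylome",
    "kc_proteome",
)


@dataclass
class RhythmParams:
    """Planted oscillation parameters for one feature."""

    baseline: float
    amplitude: float
    period_h: float = 24.0
    acrophase_h: float = 0.0
    noise_sd: float = 0.0
    is_rhythmic: bool = False

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.is_rhythmic and self.amplitude == 0:
            raise ValueError("rhythmic feature needs amplitude > 0")
        if not self.is_rhythmic and self.amplitude != 0:
            raise ValueError("non-rhythmic feature must have amplitude 0")
        self.acrophase_h = float(self.acrophase_h) % 24.0


def simulate_profile(
    params: RhythmParams,
    timepoints,
    rng: np.random.Generator,
    nonneg_clip: bool = False,
) -> np.ndarray:
    """Evaluate the planted cosine-plus-noise model at the timepoints.

    With ``noise_sd=0`` the result is the exact cosine evaluation.  When
    ``nonneg_clip`` is requested the conservative positivity condition
    baseline > 3*(amplitude + 3*noise_sd) must hold, which guarantees the
    clip is (almost surely) inactive.
    """
    t = np.asarray(timepoints, dtype=float)
    if nonneg_clip and not params.baseline > 3 * (params.amplitude + 3 * params.noise_sd):
        raise ValueError(
            "nonneg_clip requires baseline > 3*(amplitude + 3*noise_sd)"
        )
    x = params.baseline + params.amplitude * np.cos(
        2 * np.pi * (t - params.acrophase_h) / params.period_h
    )
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=len(t))
    if nonneg_clip:
        x = np.maximum(x, 0.0)
    return x


@dataclass
class StudyConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_tfs: int = 40
    n_tgs_per_tf: int = 8
    frac_rhythmic: float = 0.5
    dr_frac: float = 1.0  # fraction of rhythmic TFs with rhythm-coupled targets
    repressor_frac: float = 0.3
    snr: float = 4.0
    tf_rel_amplitude: float = 5.0  # on/off DBA: amplitude >> baseline
    tg_rel_amplitude: float = 0.5
    mediator_rel_amplitude: float = 1.0
    kc_rel_amplitude: float = 4.0
    n_background: int = 0
    n_mediators: int = 8
    n_substrates: int = 20
    n_kc_proteins: int = 30
    ubi_rate: float = 0.08
    ubi_rhythmic_tg_boost: float = 1.0  # 1.0 = no coupling (null)
    missing_rate: float = 0.0
    layers: tuple = ALL_LAYERS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_rhythmic", "dr_frac", "repressor_frac", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_tfs < 1:
            raise ValueError("n_tfs must be >= 1")
        if not 0 <= self.ubi_rate <= 1:
            raise ValueError("ubi_rate must be in [0, 1]")
        if (
            self.n_tgs_per_tf == 0
            and self.frac_rhythmic > 0
            and self.dr_frac > 0
        ):
            raise ValueError("cannot plant DR-TFs with n_tgs_per_tf = 0")
        unknown = set(self.layers) - set(ALL_LAYERS)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Planted per-feature parameters and network ground truth."""

    features: pd.DataFrame  # feature, layer, role, params, tp_label, flags
    tf_ids: list[str]
    rhythmic_tf_ids: list[str]
    dr_tf_ids: list[str]
    tg_map: dict[str, list[tuple[str, int]]]
    mediator_ids: list[str]
    ubi_set: set[str]
    annotations: dict[str, set[str]]

    def __post_init__(self) -> None:
        rset = set(self.rhythmic_tf_ids)
        for tf in self.dr_tf_ids:
            if tf not in rset:
                raise ValueError(f"planted DR-TF {tf} is not rhythmic")
            if not self.tg_map.get(tf):
                raise ValueError(f"planted DR-TF {tf} has no targets")
        feats = set(self.features["feature"])
        for name, members in self.annotations.items():
            if not set(members) <= feats:
                raise ValueError(f"annotation set {name} references unknown features")

    def tf_tg_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf, tgs in self.tg_map.items():
            for tg, sign in tgs:
                g.add_edge(tf, tg, sign=sign)
        return g

    def tp_of(self, acrophase_h: float) -> str:
        return f"TP{int((acrophase_h % 24) // 6) + 1}"


@dataclass
class StudyBundle:
    matrices: dict[str, OmicsMatrix]
    truth: SyntheticTruth
    tf_tg: nx.DiGraph


def _noise_sd(ref_amplitude: float, snr: float) -> float:
    return 0.0 if np.isinf(snr) else ref_amplitude / snr


def _matrix(layer, rows, ids, tps, missing_rate, rng) -> OmicsMatrix:
    vals = np.vstack(rows) if rows else np.empty((0, len(tps)))
    if missing_rate > 0 and vals.size:
        mask = rng.random(vals.shape) < missing_rate
        vals = np.where(mask, np.nan, vals)
    df = pd.DataFrame(vals, index=pd.Index(ids, name="feature"), columns=list(tps))
    return OmicsMatrix(layer=layer, data=df, norm_state="raw" if layer != "transcriptome" else "fpkm")


def simulate_study(cfg: StudyConfig) -> StudyBundle:
    """Generate the per-layer matrices, the TF->TG network and the truth.

    See the module docstring for the planted model.  All randomness flows
    from ``cfg.seed``; identical configs reproduce identical bundles.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    feat_rows: list[dict] = []

    def record(feature, layer, role, p: RhythmParams, **extra):
        feat_rows.append(
            dict(
                feature=feature,
                layer=layer,
                role=role,
                baseline=p.baseline,
                amplitude=p.amplitude,
                period_h=p.period_h,
                acrophase_h=p.acrophase_h,
                noise_sd=p.noise_sd,
                is_rhythmic=p.is_rhythmic,
                **extra,
            )
        )

    def draw(p: RhythmParams, tps) -> np.ndarray:
        return np.maximum(simulate_profile(p, tps, rng), 0.0)

    # ---- TFs ------------------------------------------------------------
    tf_ids = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    n_rhythmic = int(round(cfg.frac_rhythmic * cfg.n_tfs))
    rhythmic_idx = sorted(rng.choice(cfg.n_tfs, size=n_rhythmic, replace=False))
    rhythmic_tfs = [tf_ids[i] for i in rhythmic_idx]
    n_dr = int(round(cfg.dr_frac * n_rhythmic))
    dr_tfs = rhythmic_tfs[:n_dr]  # interleaved TP assignment keeps TPs balanced

    tf_params: dict[str, RhythmParams] = {}
    dba_rows, dba_ids = [], []
    r_counter = 0
    for tf in tf_ids:
        b = float(rng.lognormal(0.0, 0.3))
        rhythmic = tf in set(rhythmic_tfs)
        amp_ref = cfg.tf_rel_amplitude * b
        if rhythmic:
            acro = TP_MIDPOINTS[r_counter % 4]
            r_counter += 1
            p = RhythmParams(
                baseline=b,
                amplitude=amp_ref,
                acrophase_h=acro,
                noise_sd=_noise_sd(amp_ref, cfg.snr),
                is_rhythmic=True,
            )
        else:
            p = RhythmParams(
                baseline=b,
                amplitude=0.0,
                noise_sd=_noise_sd(amp_ref, cfg.snr),
                is_rhythmic=False,
            )
        tf_params[tf] = p
        dba_ids.append(tf)
        dba_rows.append(draw(p, TWO_CYCLE_TPS))
        record(
            tf,
            "tf_dba",
            "tf",
            p,
            tp_label=f"TP{int(p.acrophase_h // 6) + 1}" if p.is_rhythmic else None,
            is_tp_specific=p.is_rhythmic,
            is_dr_tf=tf in set(dr_tfs),
        )

    # ---- Mediators (co-regulators observed in the DBA layer) ------------
    mediator_ids = [f"MED{i:02d}" for i in range(cfg.n_mediators)]
    for i, med in enumerate(mediator_ids):
        b = float(rng.lognormal(0.0, 0.3))
        amp_ref = cfg.mediator_rel_amplitude * b
        if rng.random() < cfg.frac_rhythmic:
            p = RhythmParams(
                baseline=b,
                amplitude=amp_ref,
                acrophase_h=TP_MIDPOINTS[i % 4],
                noise_sd=_noise_sd(amp_ref, cfg.snr),
                is_rhythmic=True,
            )
        else:
            p = RhythmParams(baseline=b, amplitude=0.0,
                             noise_sd=_noise_sd(amp_ref, cfg.snr),
                             is_rhythmic=False)
        dba_ids.append(med)
        dba_rows.append(draw(p, TWO_CYCLE_TPS))
        record(med, "tf_dba", "mediator", p,
               tp_label=f"TP{i % 4 + 1}" if p.is_rhythmic else None,
               is_tp_specific=False, is_dr_tf=False)

    # ---- Target genes ----------------------------------------------------
    tg_map: dict[str, list[tuple[str, int]]] = {}
    tg_params: dict[str, RhythmParams] = {}
    tx_rows, tx_ids = [], []
    for ti, tf in enumerate(tf_ids):
        tgs = []
        coupled = tf in set(dr_tfs)
        for j in range(cfg.n_tgs_per_tf):
            tg = f"TG{ti:03d}_{j:02d}"
            sign = -1 if rng.random() < cfg.repressor_frac else 1
            b = float(rng.lognormal(0.0, 0.3))
            amp_ref = cfg.tg_rel_amplitude * b
            if coupled:
                acro = tf_params[tf].acrophase_h + (12.0 if sign < 0 else 0.0)
                p = RhythmParams(
                    baseline=b,
                    amplitude=amp_ref,
                    acrophase_h=acro,
                    noise_sd=_noise_sd(amp_ref, cfg.snr),
                    is_rhythmic=True,
                )
            else:
                p = RhythmParams(
                    baseline=b,
                    amplitude=0.0,
                    noise_sd=_noise_sd(amp_ref, cfg.snr),
                    is_rhythmic=False,
                )
            tgs.append((tg, sign))
            tg_params[tg] = p
            tx_ids.append(tg)
            tx_rows.append(draw(p, TWO_CYCLE_TPS))
            record(tg, "transcriptome", "tg", p,
                   tp_label=None, is_tp_specific=False, is_dr_tf=False,
                   parent_tf=tf, sign=sign)
        tg_map[tf] = tgs

    for i in range(cfg.n_background):
        bgid = f"BG{i:03d}"
        b = float(rng.lognormal(0.0, 0.3))
        amp_ref = cfg.tg_rel_amplitude * b
        if rng.random() < cfg.frac_rhythmic:
            p = RhythmParams(
                baseline=b, amplitude=amp_ref,
                acrophase_h=float(rng.uniform(0, 24)),
                noise_sd=_noise_sd(amp_ref, cfg.snr), is_rhythmic=True,
            )
        else:
            p = RhythmParams(
                baseline=b, amplitude=0.0,
                noise_sd=_noise_sd(amp_ref, cfg.snr), is_rhythmic=False,
            )
        tx_ids.append(bgid)
        tx_rows.append(draw(p, TWO_CYCLE_TPS))
        record(bgid, "transcriptome", "background", p,
               tp_label=None, is_tp_specific=False, is_dr_tf=False)

    # ---- ubiquitylation assignment --------------------------------------
    coupled_tgs = {tg for tf in dr_tfs for tg, _ in tg_map[tf]}
    ubi_set: set[str] = set()
    for fid in tf_ids + tx_ids:
        rate = cfg.ubi_rate
        if fid in coupled_tgs:
            rate = min(1.0, rate * cfg.ubi_rhythmic_tg_boost)
        if rng.random() < rate:
            ubi_set.add(fid)

    matrices: dict[str, OmicsMatrix] = {}
    if "tf_dba" in cfg.layers:
        matrices["tf_dba"] = _matrix("tf_dba", dba_rows, dba_ids, TWO_CYCLE_TPS,
                                     cfg.missing_rate, rng)
    if "transcriptome" in cfg.layers:
        matrices["transcriptome"] = _matrix("transcriptome", tx_rows, tx_ids,
                                            TWO_CYCLE_TPS, cfg.missing_rate, rng)

    # ---- whole proteome: protein counterparts of the transcripts ---------
    if "whole_proteome" in cfg.layers:
        rows = [draw(tg_params[tg], TWO_CYCLE_TPS) for tg in tx_ids if tg in tg_params]
        ids = [tg for tg in tx_ids if tg in tg_params]
        for tg in ids:
            record(tg, "whole_proteome", "protein", tg_params[tg],
                   tp_label=None, is_tp_specific=False, is_dr_tf=False)
        matrices["whole_proteome"] = _matrix("whole_proteome", rows, ids,
                                             TWO_CYCLE_TPS, cfg.missing_rate, rng)

    # ---- nuclear proteome: TF protein abundance, flat (the study's point)
    if "nuclear" in cfg.layers:
        rows, ids = [], []
        for tf in tf_ids:
            b = tf_params[tf].baseline
            p = RhythmParams(baseline=b, amplitude=0.0,
                             noise_sd=0.15 * b if not np.isinf(cfg.snr) else 0.0,
                             is_rhythmic=False)
            ids.append(tf)
            rows.append(draw(p, TWO_CYCLE_TPS))
            record(tf, "nuclear", "tf_protein", p,
                   tp_label=None, is_tp_specific=False, is_dr_tf=False)
        matrices["nuclear"] = _matrix("nuclear", rows, ids, TWO_CYCLE_TPS,
                                      cfg.missing_rate, rng)

    # ---- phosphoproteome: substrates, day/night acrophases ----------------
    substrate_ids = [f"SUB{i:03d}" for i in range(cfg.n_substrates)]
    if "phospho" in cfg.layers:
        rows, ids = [], []
        for i, sid in enumerate(substrate_ids):
            b = float(rng.lognormal(0.0, 0.3))
            amp_ref = cfg.tg_rel_amplitude * b
            if rng.random() < cfg.frac_rhythmic:
                p = RhythmParams(
                    baseline=b, amplitude=amp_ref,
                    acrophase_h=6.0 if i % 2 == 0 else 18.0,
                    noise_sd=_noise_sd(amp_ref, cfg.snr), is_rhythmic=True,
                )
            else:
                p = RhythmParams(baseline=b, amplitude=0.0,
                                 noise_sd=_noise_sd(amp_ref, cfg.snr),
                                 is_rhythmic=False)
            ids.append(sid)
            rows.append(draw(p, TWO_CYCLE_TPS))
            record(sid, "phospho", "substrate", p,
                   tp_label=None, is_tp_specific=False, is_dr_tf=False)
        matrices["phospho"] = _matrix("phospho", rows, ids, TWO_CYCLE_TPS,
                                      cfg.missing_rate, rng)

    # ---- ubiquitylome: single cycle over the ubiquitylated features -------
    if "ubiquitylome" in cfg.layers:
        rows, ids = [], []
        for fid in sorted(ubi_set):
            p = tf_params.get(fid) or tg_params.get(fid)
            if p is None:
                continue
            ids.append(fid)
            rows.append(draw(p, ONE_CYCLE_TPS))
            record(fid, "ubiquitylome", "ubiquitylated", p,
                   tp_label=None, is_tp_specific=False, is_dr_tf=False)
        matrices["ubiquitylome"] = _matrix("ubiquitylome", rows, ids,
                                           ONE_CYCLE_TPS, cfg.missing_rate, rng)

    # ---- Kupffer-cell proteome: 4 points, strong day/night switchers ------
    if "kc_proteome" in cfg.layers:
        rows, ids, switcher = [], [], {}
        for i in range(cfg.n_kc_proteins):
            kid = f"KC{i:03d}"
            b = float(rng.lognormal(0.0, 0.3))
            rhythmic = rng.random() < cfg.frac_rhythmic
            strong = rhythmic and i % 2 == 0
            rel = cfg.kc_rel_amplitude if strong else 0.3
            amp_ref = rel * b
            if rhythmic:
                # peak centred on the sampled day (ZT0/6) or night (ZT12/18)
                # bin so a strong switcher's planted fold change clears the
                # screen decisively
                p = RhythmParams(
                    baseline=b, amplitude=amp_ref,
                    acrophase_h=3.0 if i % 4 < 2 else 15.0,
                    noise_sd=_noise_sd(amp_ref, max(cfg.snr, 8.0) if strong else cfg.snr),
                    is_rhythmic=True,
                )
            else:
                p = RhythmParams(baseline=b, amplitude=0.0,
                                 noise_sd=_noise_sd(amp_ref, cfg.snr),
                                 is_rhythmic=False)
            ids.append(kid)
            rows.append(draw(p, KC_TPS))
            switcher[kid] = strong
            record(kid, "kc_proteome", "kc_protein", p,
                   tp_label=None, is_tp_specific=False, is_dr_tf=False,
                   is_day_switcher=strong)
        matrices["kc_proteome"] = _matrix("kc_proteome", rows, ids, KC_TPS,
                                          cfg.missing_rate, rng)

    # ---- annotations ------------------------------------------------------
    feats_df = pd.DataFrame(feat_rows)
    annotations: dict[str, set[str]] = {}
    for tp_i, tp in enumerate(("TP1", "TP2", "TP3", "TP4")):
        members = {
            tf for tf in rhythmic_tfs
            if tf_params[tf].is_rhythmic
            and int(tf_params[tf].acrophase_h // 6) == tp_i
        }
        for tf in list(members):
            if tf in set(dr_tfs):
                members |= {tg for tg, _ in tg_map[tf]}
        if members:
            annotations[f"pathway_{tp}"] = members
    all_feats = sorted(set(feats_df["feature"]))
    n_rand = max(3, len(all_feats) // 10)
    annotations["random_set"] = set(
        rng.choice(all_feats, size=min(n_rand, len(all_feats)), replace=False)
    )

    truth = SyntheticTruth(
        features=feats_df,
        tf_ids=tf_ids,
        rhythmic_tf_ids=rhythmic_tfs,
        dr_tf_ids=dr_tfs,
        tg_map=tg_map,
        mediator_ids=mediator_ids,
        ubi_set=ubi_set,
        annotations=annotations,
    )
    return StudyBundle(matrices=matrices, truth=truth, tf_tg=truth.tf_tg_graph())


# ---------------------------------------------------------------------------
# networks


def simulate_networks(
    n_nodes: int,
    edge_prob: float | None = None,
    degree_seq=None,
    n_kinases: int = 0,
    seed: int = 0,
    nodes=None,
    substrates=None,
    n_substrates_per_kinase: int = 5,
) -> tuple[nx.Graph, nx.DiGraph]:
    """Erdos-Renyi PPI graph plus a kinase->substrate map.

    ``nodes`` optionally names the PPI nodes (defaults to ``N000``...);
    kinase edges are drawn only to ``substrates`` (defaults to the PPI
    node set).  ``n_kinases=0`` yields an empty kinase map.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    if nodes is None:
        nodes = [f"N{i:03d}" for i in range(n_nodes)]
    if len(nodes) != n_nodes:
        raise ValueError("len(nodes) must equal n_nodes")
    if degree_seq is not None:
        g0 = nx.configuration_model(degree_seq, seed=int(rng.integers(2**31)))
        g0 = nx.Graph(g0)
        g0.remove_edges_from(nx.selfloop_edges(g0))
    else:
        if edge_prob is None or not 0 < edge_prob <= 1:
            raise ValueError("edge_prob must be in (0, 1]")
        g0 = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(2**31)))
    ppi = nx.relabel_nodes(g0, dict(enumerate(nodes)))
    ppi.add_nodes_from(nodes)

    kin = nx.DiGraph()
    if n_kinases > 0:
        pool = sorted(substrates) if substrates is not None else list(nodes)
        if not pool:
            raise ValueError("no substrates available for kinase edges")
        for i in range(n_kinases):
            kid = f"KIN{i:02d}"
            size = min(n_substrates_per_kinase, len(pool))
            for s in rng.choice(pool, size=size, replace=False):
                kin.add_edge(kid, str(s))
    return ppi, kin


def simulate_pathway_ppi(
    substrates,
    pathway_tfs,
    other_tfs,
    seed: int = 0,
    attach_prob: float = 0.6,
) -> nx.Graph:
    """PPI with a planted hub topology: pathway-specific TFs sit adjacent
    to the substrates while all other TFs hang off a two-hop bridge, so
    substrate->pathway-TF paths are shorter than substrate->any-TF paths."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    g = nx.Graph()
    hub, bridge = "PPI_HUB", "PPI_BRIDGE"
    g.add_edge(hub, bridge)
    for s in substrates:
        g.add_edge(hub, s)
    for tf in other_tfs:
        g.add_edge(bridge, tf)
    subs = list(substrates)
    for tf in pathway_tfs:
        attached = [s for s in subs if rng.random() < attach_prob]
        if not attached:
            attached = [subs[int(rng.integers(len(subs)))]]
        for s in attached:
            g.add_edge(tf, s)
    return g


# ---------------------------------------------------------------------------
# bundle serialization (CLI "simulate" output)


def write_bundle(bundle: StudyBundle, out_dir, ppi: nx.Graph | None = None,
                 kinase: nx.DiGraph | None = None) -> dict:
    """Write matrices, edge lists, annotation sets and the truth record;
    returns the map of written paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for layer, m in bundle.matrices.items():
        p = os.path.join(out_dir, f"{layer}.tsv")
        write_omics_table(m, p)
        paths[layer] = p
    p = os.path.join(out_dir, "tf_tg.tsv")
    write_edge_list(bundle.tf_tg, p)
    paths["tf_tg"] = p
    if ppi is not None:
        p = os.path.join(out_dir, "ppi.tsv")
        write_edge_list(ppi, p)
        paths["ppi"] = p
    if kinase is not None:
        p = os.path.join(out_dir, "kinase.tsv")
        write_edge_list(kinase, p)
        paths["kinase"] = p
    p = os.path.join(out_dir, "annotations.json")
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(
            {k: sorted(v) for k, v in bundle.truth.annotations.items()},
            fh, indent=1, sort_keys=True,
        )
    paths["annotations"] = p
    p = os.path.join(out_dir, "truth.json")
    t = bundle.truth
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "tf_ids": t.tf_ids,
                "rhythmic_tf_ids": t.rhythmic_tf_ids,
                "dr_tf_ids": t.dr_tf_ids,
                "mediator_ids": t.mediator_ids,
                "ubi_set": sorted(t.ubi_set),
                "tg_map": {k: [[tg, s] for tg, s in v] for k, v in t.tg_map.items()},
                "features": t.features.to_dict(orient="records"),
            },
            fh, indent=1, sort_keys=True, default=str,
        )
    paths["truth"] = p
    return paths
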