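"""End-to-end pipeline: normalize -> rhythm -> phases -> DR-TFs -> networks.

Outputs are a pure function of (inputs, config, seed): every table is
written with deterministic ordering and float formatting, and the run
manifest records the config, the seed and SHA-256 hashes of all inputs
and outputs, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os

import networkx as nx
import numpy as np
import pandas as pd

from . import networks as net_ops
from . import phases as phase_ops
from . import regulation as reg_ops
from .io import (
    ConfigError,
    OmicsMatrix,
    RunConfig,
    file_sha256,
    read_edge_list,
    read_omics_table,
    write_omics_table,
)
from .normalize import CycleSpec, ibaq_to_fot, zscore_per_cycle
from .rhythm import classify_rhythmic, jtk_cycle
from .synth import StudyBundle

logger = logging.getLogger("circatf")

MANDATORY_LAYERS = ("tf_dba", "transcriptome")


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


def normalize_layer(m: OmicsMatrix, joint_cycles: bool = False) -> tuple[OmicsMatrix, OmicsMatrix]:
    """(abundance-scale matrix, z-scored matrix) for one layer.

    Proteome-style layers go iBAQ -> FOT -> per-cycle z-score; the
    transcriptome (already FPKM) is z-scored directly.
    """
    cycles = CycleSpec.for_timepoints(m.timepoints)
    if m.norm_state == "raw":
        fot = ibaq_to_fot(m)
        return fot, zscore_per_cycle(fot, cycles, joint=joint_cycles)
    if m.norm_state == "fpkm":
        return m, zscore_per_cycle(m, cycles, joint=joint_cycles)
    raise ValueError(f"layer {m.layer} already normalized ({m.norm_state})")


def run_pipeline(
    config: RunConfig,
    layers: dict[str, "OmicsMatrix | str"],
    out_dir: str,
    tf_tg: "nx.DiGraph | str | None" = None,
    ppi: "nx.Graph | str | None" = None,
    kinase: "nx.DiGraph | str | None" = None,
    mediator_ids=None,
    annotations: "dict | str | None" = None,
    pathway_tfs=None,
) -> dict:
    """Run every applicable stage and write the report bundle.

    ``layers`` maps layer names to :class:`OmicsMatrix` objects or TSV
    paths; the TF-DBA and transcriptome layers are mandatory (checked
    before any computation).  Optional inputs enable the corresponding
    stages; absent ones are skipped with a warning.  Returns a summary
    dict (also serialized as ``manifest.json``).
    """
    missing = [l for l in MANDATORY_LAYERS if l not in layers]
    if missing:
        raise ConfigError(f"mandatory layer(s) missing: {missing}")
    os.makedirs(out_dir, exist_ok=True)

    input_hashes = {}
    mats: dict[str, OmicsMatrix] = {}
    for layer in sorted(layers):
        src = layers[layer]
        if isinstance(src, (str, os.PathLike)):
            input_hashes[f"layer:{layer}"] = file_sha256(src)
            mats[layer] = read_omics_table(src, layer)
        else:
            mats[layer] = src

    def _load_graph(obj, directed, name):
        if obj is None:
            return None
        if isinstance(obj, (str, os.PathLike)):
            input_hashes[name] = file_sha256(obj)
            return read_edge_list(obj, directed=directed)
        return obj

    tf_tg = _load_graph(tf_tg, True, "tf_tg")
    ppi = _load_graph(ppi, False, "ppi")
    kinase = _load_graph(kinase, True, "kinase")
    if isinstance(annotations, (str, os.PathLike)):
        input_hashes["annotations"] = file_sha256(annotations)
        with open(annotations, "r", encoding="utf-8") as fh:
            annotations = {k: set(v) for k, v in json.load(fh).items()}

    outputs: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(out_dir, name)
        _write_tsv(df, path)
        outputs.append(name)

    # ---- normalization and rhythm detection ------------------------------
    abundance: dict[str, OmicsMatrix] = {}
    zscored: dict[str, OmicsMatrix] = {}
    rhythms: dict[str, pd.DataFrame] = {}
    for layer in sorted(mats):
        ab, z = normalize_layer(mats[layer])
        abundance[layer], zscored[layer] = ab, z
        path = os.path.join(out_dir, f"normalized_{layer}.tsv")
        write_omics_table(z, path)
        outputs.append(f"normalized_{layer}.tsv")
        rt = jtk_cycle(z, config)
        rt = classify_rhythmic(rt, config.alpha_for_layer(layer))
        rhythms[layer] = rt
        emit(rt, f"rhythm_{layer}.tsv")

    summary: dict = {
        "n_features": {l: len(m.data) for l, m in sorted(mats.items())},
        "n_rhythmic": {l: int(rt["rhythmic"].sum()) for l, rt in sorted(rhythms.items())},
    }

    # ---- phase analysis ---------------------------------------------------
    tp_sets = phase_ops.tp_specific_features(abundance["tf_dba"], fold=config.tp_fold)
    tp_df = pd.DataFrame(
        [(tp, f) for tp in sorted(tp_sets) for f in sorted(tp_sets[tp])],
        columns=["tp", "feature_id"],
    )
    emit(tp_df, "tp_specific_tfs.tsv")
    summary["n_tp_specific"] = {tp: len(v) for tp, v in sorted(tp_sets.items())}

    peaks = phase_ops.peak_time(abundance["tf_dba"], rhythms["tf_dba"])
    emit(peaks, "peak_times_tf_dba.tsv")

    fc_layer = "kc_proteome" if "kc_proteome" in abundance else "whole_proteome"
    if fc_layer in abundance:
        fc = phase_ops.day_night_fold_change(abundance[fc_layer], config.day_night_fc)
        emit(fc, f"day_night_fc_{fc_layer}.tsv")
        summary["n_day_night_switchers"] = int(fc["selected"].sum())
        summary["day_night_layer"] = fc_layer

    # ---- DR-TF nomination and ubiquitylation ------------------------------
    if tf_tg is not None and tf_tg.number_of_edges() > 0:
        drtf = reg_ops.nominate_dr_tfs(
            rhythms["tf_dba"],
            rhythms["transcriptome"],
            tf_tg,
            min_tg=config.min_tg,
            enrich_alpha=config.enrich_alpha,
            tf_matrix=zscored["tf_dba"],
            tg_matrix=zscored["transcriptome"],
            r_act=config.activator_r,
            r_rep=config.repressor_r,
        )
        emit(drtf, "dr_tfs.tsv")
        summary["n_dr_tfs"] = int(drtf["is_dr_tf"].sum())
        summary["n_rhythmic_tfs_in_net"] = int(drtf["rhythmic_dba"].sum())

        if "ubiquitylome" in mats:
            ubi_set = set(mats["ubiquitylome"].feature_ids)
            ct = reg_ops.ubiquitylation_crosstab(rhythms["tf_dba"], tf_tg, ubi_set)
            rhythmic_tfs = [
                t for t in drtf[drtf["rhythmic_dba"]]["tf_id"] if t in tf_tg
            ]
            rs = reg_ops.random_tf_resample_test(
                tf_tg, ubi_set, rhythmic_tfs, seed=config.seed
            )
            ubi_report = {"crosstab": ct.to_dict(), "resampling": rs}
            with open(os.path.join(out_dir, "ubiquitylation.json"), "w") as fh:
                json.dump(ubi_report, fh, indent=1, sort_keys=True)
            outputs.append("ubiquitylation.json")
            summary["ubiquitylation"] = ubi_report
    else:
        logger.warning("no TF->TG network given; skipping DR-TF stage")

    # ---- network analyses -------------------------------------------------
    if ppi is not None and kinase is not None and kinase.number_of_edges() > 0 \
            and "phospho" in mats:
        substrates = sorted(
            set().union(*(set(kinase.successors(k)) for k in kinase
                          if kinase.out_degree(k) > 0))
        )
        all_tfs = [t for t in mats["tf_dba"].feature_ids if t in ppi]
        pw_tfs = [t for t in (pathway_tfs or all_tfs) if t in ppi]
        if substrates and all_tfs and pw_tfs:
            ps = net_ops.substrate_path_summary(ppi, substrates, pw_tfs, all_tfs)
            emit(ps, "path_summary.tsv")
            try:
                res = net_ops.compare_path_lengths(ps)
                summary["path_comparison"] = {
                    "t": res.statistic, "df": res.df, "p": res.p_two_sided,
                }
            except ValueError as exc:
                logger.warning("path comparison degenerate: %s", exc)
    elif kinase is not None and kinase.number_of_edges() == 0:
        logger.warning("empty kinase map; skipping path stage")

    if mediator_ids:
        dba = zscored["tf_dba"]
        meds = [m_ for m_ in mediator_ids if m_ in dba.data.index]
        tfs = [t for t in dba.data.index if t not in set(mediator_ids)]
        if meds and tfs:
            links = net_ops.top_k_correlated_mediators(
                dba.data.loc[tfs], dba.data.loc[meds], k=config.mediator_k
            )
            emit(links, "mediator_links.tsv")

    if annotations:
        rhythmic_dba = sorted(
            rhythms["tf_dba"][rhythms["tf_dba"]["rhythmic"]]["feature_id"]
        )
        if rhythmic_dba:
            enr = net_ops.fisher_enrichment(
                rhythmic_dba, mats["tf_dba"].feature_ids, annotations
            )
            emit(enr, "enrichment_rhythmic_tf_dba.tsv")

    if ppi is not None and "kc_proteome" in mats and "whole_proteome" in mats:
        n_cross = net_ops.bipartite_edge_count(
            mats["kc_proteome"].feature_ids,
            mats["whole_proteome"].feature_ids,
            ppi,
        )
        summary["kc_whole_liver_edges"] = n_cross

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "input_hashes": dict(sorted(input_hashes.items())),
        "outputs": sorted(outputs),
        "summary": summary,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["output_hashes"] = {
        name: file_sha256(os.path.join(out_dir, name)) for name in sorted(outputs)
    }
    return manifest


def run_on_bundle(bundle: StudyBundle, config: RunConfig, out_dir: str,
                  ppi=None, kinase=None) -> dict:
    """Convenience wrapper: run the pipeline on a synthetic bundle."""
    return run_pipeline(
        config,
        layers=dict(bundle.matrices),
        out_dir=out_dir,
        tf_tg=bundle.tf_tg,
        ppi=ppi,
        kinase=kinase,
        mediator_ids=bundle.truth.mediator_ids,
        annotations=bundle.truth.annotations,
    )
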