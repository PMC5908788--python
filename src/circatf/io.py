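"""Data model and TSV readers/writers for omics matrices and edge lists.

The on-disk dialect is tab-separated UTF-8 with a mandatory header row,
"." decimal point and the empty string for missing values.  Matrices are
feature-by-timepoint tables whose header cells are Zeitgeber-time labels
("ZT0" .. "ZT45"); edge lists are two- or three-column tables
(source, target[, sign]).  Feature identity is the case-sensitive gene
symbol; cross-layer joins are exact symbol matches.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields, replace

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("circatf")

LAYERS = (
    "tf_dba",
    "nuclear",
    "whole_proteome",
    "phospho",
    "ubiquitylome",
    "transcriptome",
    "kc_proteome",
)

NORM_STATES = ("raw", "fot", "zscored", "fpkm", "fpkm_zscored")


class ParseError(ValueError):
    """Malformed input file (bad header, non-numeric cell, duplicate id)."""


class ConfigError(ValueError):
    """Invalid run configuration or missing mandatory input."""


@dataclass
class OmicsMatrix:
    """Feature x timepoint abundance table for one omics layer.

    Parameters
    ----------
    layer : str
        One of :data:`LAYERS`.
    data : pandas.DataFrame
        Rows indexed by gene symbol, columns are integer ZT hours
        (strictly increasing).  NaN marks missing values.
    norm_state : str
        One of :data:`NORM_STATES`.
    """

    layer: str
    data: pd.DataFrame
    norm_state: str = "raw"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.norm_state not in NORM_STATES:
            raise ValueError(f"unknown norm_state {self.norm_state!r}")
        tps = list(self.data.columns)
        if any(int(t) != t for t in tps):
            raise ValueError("timepoints must be integer ZT hours")
        if not all(b > a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.norm_state in ("raw", "fpkm"):
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"{self.norm_state} values must be nonnegative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def degenerate_features(self) -> list[str]:
        """Features with fewer than two non-missing values."""
        ok = self.data.notna().sum(axis=1) >= 2
        return list(self.data.index[~ok])

    def with_values(self, values: np.ndarray, norm_state: str) -> "OmicsMatrix":
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return OmicsMatrix(layer=self.layer, data=df, norm_state=norm_state)


@dataclass
class RunConfig:
    """Analysis-wide thresholds and the random seed.

    Defaults follow the study's stated settings: a 20-28 h period search
    window on 3-h sampling, per-layer rhythmicity cut-offs p<0.1 (proteome
    layers) and p<0.05 (transcripts), a twofold rule for time-phase-specific
    TFs, activator/repressor correlation cut-offs +-0.5, three Mediators per
    TF, and a >5 day/night fold-change screen.
    """

    period_range_h: tuple[float, float] = (20.0, 28.0)
    sampling_interval_h: float = 3.0
    alpha_proteome: float = 0.1
    alpha_transcript: float = 0.05
    tp_fold: float = 2.0
    activator_r: float = 0.5
    repressor_r: float = -0.5
    mediator_k: int = 3
    day_night_fc: float = 5.0
    min_tg: int = 3
    enrich_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_proteome", "alpha_transcript", "enrich_alpha"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {a}")
        lo, hi = self.period_range_h
        if hi < lo:
            raise ConfigError("period_range_h must be (min, max) with min <= max")
        dt = self.sampling_interval_h
        if dt <= 0:
            raise ConfigError("sampling_interval_h must be positive")
        k_lo = int(np.ceil(lo / dt - 1e-9))
        k_hi = int(np.floor(hi / dt + 1e-9))
        if k_hi < max(k_lo, 1):
            raise ConfigError(
                f"no admissible period (multiple of {dt} h) in {self.period_range_h}"
            )
        if self.tp_fold <= 1:
            raise ConfigError(f"tp_fold must be > 1, got {self.tp_fold}")
        if self.mediator_k < 1:
            raise ConfigError("mediator_k must be >= 1")
        if self.min_tg < 1:
            raise ConfigError("min_tg must be >= 1")
        self.seed = int(self.seed)

    def alpha_for_layer(self, layer: str) -> float:
        return self.alpha_transcript if layer == "transcriptome" else self.alpha_proteome

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["period_range_h"] = list(self.period_range_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "period_range_h" in d:
            d["period_range_h"] = tuple(d["period_range_h"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# matrix I/O


def _parse_zt_label(label: str, col_index: int) -> int:
    label = label.strip()
    if not label.startswith("ZT"):
        raise ParseError(f"column {col_index}: header {label!r} is not a ZT label")
    try:
        return int(label[2:])
    except ValueError:
        raise ParseError(
            f"column {col_index}: cannot parse hours from header {label!r}"
        ) from None


def read_omics_table(path, layer: str) -> OmicsMatrix:
    """Read a feature x ZT TSV into an :class:`OmicsMatrix`.

    The first column holds the feature id, remaining headers are
    ``ZT<hours>`` labels.  Empty cells become missing values.  Duplicate
    feature ids, malformed headers and non-numeric cells raise
    :class:`ParseError` naming the offending row/column.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: header must contain at least one ZT column")
    tps = [_parse_zt_label(h, i + 1) for i, h in enumerate(header[1:])]
    ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path} line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        fid = cells[0]
        if fid in seen:
            raise ParseError(f"{path} line {lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        ids.append(fid)
        row: list[float] = []
        for j, cell in enumerate(cells[1:]):
            if cell == "":
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path} line {lineno} (feature {fid!r}), column "
                    f"{header[j + 1]!r}: non-numeric cell {cell!r}"
                ) from None
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="feature"), columns=tps)
    norm_state = "fpkm" if layer == "transcriptome" else "raw"
    return OmicsMatrix(layer=layer, data=df, norm_state=norm_state)


def _fmt(v: float) -> str:
    if isinstance(v, float) and np.isnan(v):
        return ""
    return repr(float(v))


def write_omics_table(m: OmicsMatrix, path) -> None:
    """Write a matrix in the TSV dialect (round-trips bit-exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\t" + "\t".join(f"ZT{int(t)}" for t in m.data.columns) + "\n")
        arr = m.data.to_numpy(dtype=float)
        for fid, row in zip(m.data.index, arr):
            fh.write(str(fid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# edge-list I/O

_SIGNS = {"+1": 1, "1": 1, "-1": -1, "−1": -1}


def read_edge_list(path, directed: bool) -> nx.Graph:
    """Read a (source, target[, sign]) TSV into a networkx graph.

    Duplicate edges are collapsed, self-loops dropped with a logged count,
    and an optional third column must hold +1 / -1 (stored as edge
    attribute ``sign``).
    """
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    n_self = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            cells = ln.split("\t")
            if lineno == 1 and cells[0].lower() in ("source", "from", "tf"):
                continue
            if len(cells) not in (2, 3):
                raise ParseError(
                    f"{path} line {lineno}: expected 2 or 3 columns, got {len(cells)}"
                )
            u, v = cells[0], cells[1]
            if u == v:
                n_self += 1
                continue
            attrs = {}
            if len(cells) == 3:
                if cells[2] not in _SIGNS:
                    raise ParseError(
                        f"{path} line {lineno}: sign must be +1 or -1, got {cells[2]!r}"
                    )
                attrs["sign"] = _SIGNS[cells[2]]
            g.add_edge(u, v, **attrs)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    signed = any("sign" in d for _, _, d in g.edges(data=True))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsign\n" if signed else "source\ttarget\n")
        for u, v, d in sorted(g.edges(data=True)):
            if signed:
                fh.write(f"{u}\t{v}\t{d.get('sign', 1):+d}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
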