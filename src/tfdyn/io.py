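"""Readers and writers for the on-disk formats.

All tabular inputs and outputs are tab-separated values with a header row;
networks travel as edge lists (source, target, sign, score); structured
results (fitted models, importance reports) are JSON and round-trip
losslessly. Gene/TF identifiers are opaque case-sensitive strings.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import (
    ACTIVATING,
    DifferentialExpression,
    Edge,
    ExpressionSeries,
    InfluenceRanking,
    OmicsSnapshot,
    ScoredNetwork,
    SignedNetwork,
    ValidationError,
)

logger = logging.getLogger("tfdyn")
if not logger.handlers:  # one structured stderr line per pipeline stage
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("tfdyn %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def log_stage(stage: str, **fields: Any) -> None:
    """Emit one structured log line for a pipeline stage."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", stage, payload)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"malformed table {path}: {exc}") from exc


def _two_column_map(path: str | Path, value_name: str) -> dict[str, float]:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected id + {value_name} columns")
    ids = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        bad = ids[vals.isna()].tolist()
        raise ValidationError(f"{path}: non-numeric {value_name} for {bad}")
    if ids.duplicated().any():
        raise ValidationError(f"{path}: duplicate identifiers")
    return dict(zip(ids, vals.astype(float)))


def read_snapshot(
    expression_path: str | Path,
    activity_path: str | Path,
    binding_path: str | Path,
    time_label: float,
) -> OmicsSnapshot:
    """Assemble one time point's snapshot from three delimited tables.

    The binding table is either long form (source, target, value columns) or
    a dense matrix whose first column holds source TFs and whose header holds
    target genes. Pairs absent from the table are treated as B_ij = 0;
    duplicate (source, target) rows are an error.
    """
    expression = _two_column_map(expression_path, "expression")
    activity = _two_column_map(activity_path, "activity")

    df = _read_tsv(binding_path)
    binding: dict[tuple[str, str], float] = {}
    first_data_col = pd.to_numeric(df.iloc[:, 1], errors="coerce") if df.shape[1] > 1 else None
    long_form = df.shape[1] == 3 and first_data_col is not None and first_data_col.isna().all()
    if long_form:
        for _, (src, tgt, val) in df.iterrows():
            key = (str(src), str(tgt))
            if key in binding:
                raise ValidationError(f"{binding_path}: duplicate binding row {key}")
            binding[key] = float(val)
    else:
        sources = df.iloc[:, 0].astype(str)
        if sources.duplicated().any():
            raise ValidationError(f"{binding_path}: duplicate source rows")
        for col in df.columns[1:]:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"{binding_path}: non-numeric binding value")
            for src, val in zip(sources, vals):
                binding[(src, str(col))] = float(val)
    return OmicsSnapshot(float(time_label), expression, activity, binding)


def read_expression_series(path: str | Path) -> ExpressionSeries:
    """Genes x time points table; header row = time labels, increasing."""
    df = _read_tsv(path)
    try:
        times = np.asarray([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric time header") from exc
    genes = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(values).any():
        raise ValidationError(f"{path}: non-numeric expression cell")
    return ExpressionSeries(times, genes, values)


def write_expression_series(series: ExpressionSeries, path: str | Path) -> None:
    df = pd.DataFrame(series.values, index=series.genes,
                      columns=[_fmt_time(t) for t in series.times])
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_differential_expression(
    path: str | Path, comparison: tuple[float, float]
) -> DifferentialExpression:
    """Three-column table: gene, log2fc, padj."""
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected gene, log2fc, padj columns")
    genes = df.iloc[:, 0].astype(str)
    lfc = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    padj = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    if lfc.isna().any() or padj.isna().any():
        raise ValidationError(f"{path}: non-numeric log2fc/padj value")
    return DifferentialExpression(
        comparison, dict(zip(genes, lfc.astype(float))), dict(zip(genes, padj.astype(float)))
    )


def write_differential_expression(de: DifferentialExpression, path: str | Path) -> None:
    rows = [(g, de.log2fc[g], de.padj.get(g, 1.0)) for g in sorted(de.log2fc)]
    pd.DataFrame(rows, columns=["gene", "log2fc", "padj"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_scored_network(net: ScoredNetwork, path: str | Path) -> None:
    df = pd.DataFrame(net.scores, index=net.nodes, columns=net.nodes)
    df.index.name = "source"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_scored_network(path: str | Path, time_label: float,
                        mode: str = ACTIVATING) -> ScoredNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoredNetwork(float(time_label), [str(c) for c in df.columns],
                         df.to_numpy(dtype=float), mode)


def write_network(net: SignedNetwork, path: str | Path) -> None:
    """Edge-list TSV: source, target, sign, score; marker nodes flagged."""
    rows = [(e.source, e.target, e.sign, e.score) for e in net.sorted_edges()]
    df = pd.DataFrame(rows, columns=["source", "target", "sign", "score"])
    with open(path, "w") as fh:
        fh.write("# nodes: " + ",".join(sorted(net.nodes)) + "\n")
        fh.write("# markers: " + ",".join(sorted(net.marker_nodes)) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_network(path: str | Path) -> SignedNetwork:
    with open(path) as fh:
        node_line = fh.readline()
        marker_line = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    if not node_line.startswith("# nodes:") or not marker_line.startswith("# markers:"):
        raise ValidationError(f"{path}: missing node/marker header lines")
    nodes = [n for n in node_line.split(":", 1)[1].strip().split(",") if n]
    markers = {n for n in marker_line.split(":", 1)[1].strip().split(",") if n}
    edges = [Edge(str(r.source), str(r.target), str(r.sign), float(r.score))
             for r in df.itertuples()]
    return SignedNetwork(nodes, edges, markers)


def write_influence_ranking(ranking: InfluenceRanking, path: str | Path) -> None:
    ranked = sorted(ranking.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    pd.DataFrame(ranked, columns=["tf", "influence"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_trajectory(times: np.ndarray, nodes: list[str], states: np.ndarray,
                     path: str | Path) -> None:
    """Trajectory TSV: one row per time point, one column per TF."""
    df = pd.DataFrame(states.T, columns=nodes)
    df.insert(0, "time", times)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _fmt_time(t: float) -> str:
    return f"{t:g}"


def _canonical_json(obj: Any) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n"


def write_results(result: Any, path: str | Path) -> None:
    """Serialize a result object (anything with ``to_dict``) as canonical JSON.

    The representation is deterministic, so write -> read -> write is
    byte-identical.
    """
    payload = result.to_dict() if hasattr(result, "to_dict") else result
    Path(path).write_text(_canonical_json(payload))


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
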