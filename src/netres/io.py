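"""Plain-text readers and writers.

Formats: nodes x time TSV with a header row of node ids; dense matrix TSV;
Matrix Market (.mtx) via scipy; edge-list TSV (node_a, node_b[, weight])
with ``#``-prefixed header comments recording construction parameters;
two-column score TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import scipy.io
import scipy.sparse

from netres.networks import (
    BinaryNetwork,
    CorrelationMatrix,
    SignedWeightedNetwork,
    TimeSeriesMatrix,
)


def write_timeseries_tsv(ts: TimeSeriesMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ts.values.T, columns=[str(n) for n in ts.node_ids])
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path: str | Path) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(df.to_numpy().T, list(df.columns))


def write_matrix_tsv(mat: CorrelationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mat.values, columns=[str(n) for n in mat.node_ids])
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t")
    return CorrelationMatrix(df.to_numpy(), list(df.columns))


def write_matrix_mtx(mat: CorrelationMatrix, path: str | Path) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat.values))


def read_labels_tsv(path: str | Path) -> Mapping[str, str]:
    """Two-column node -> ROI label file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "roi"], dtype=str)
    return dict(zip(df["node"], df["roi"]))


def _meta_header(meta: Mapping) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in sorted(meta.items(), key=lambda kv: str(kv[0])))


def write_edgelist_tsv(net: BinaryNetwork | SignedWeightedNetwork, path: str | Path) -> None:
    weighted = isinstance(net, SignedWeightedNetwork)
    with open(path, "w") as fh:
        fh.write(_meta_header(net.meta))
        fh.write("# nodes = " + ",".join(str(n) for n in net.node_ids) + "\n")
        fh.write("node_a\tnode_b\tweight\n" if weighted else "node_a\tnode_b\n")
        if weighted:
            for u, v, w in net.graph.edges(data="weight"):
                fh.write(f"{u}\t{v}\t{w:.10g}\n")
        else:
            for u, v in net.graph.edges():
                fh.write(f"{u}\t{v}\n")


def read_edgelist_tsv(path: str | Path) -> BinaryNetwork | SignedWeightedNetwork:
    meta: dict = {}
    nodes: list[str] | None = None
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("nodes ="):
                    nodes = [s for s in body.split("=", 1)[1].strip().split(",") if s]
                elif "=" in body:
                    k, v = (s.strip() for s in body.split("=", 1))
                    meta[k] = v
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    weighted = header is not None and "weight" in header
    if nodes is None:
        nodes = sorted({r[0] for r in rows} | {r[1] for r in rows})
    if weighted:
        return SignedWeightedNetwork.from_weighted_edges(
            nodes, [(r[0], r[1], float(r[2])) for r in rows], meta
        )
    return BinaryNetwork.from_edges(nodes, [(r[0], r[1]) for r in rows], meta)


def write_scores_tsv(scores, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# metric = {scores.metric}\n# variant = {scores.variant}\n")
        fh.write("node_id\tscore\n")
        for n, v in scores.scores.items():
            fh.write(f"{n}\t{v:.10g}\n")


def write_table_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(_meta_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
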