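"""Tabular and graph exports for interaction matrices and reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Mapping

import networkx as nx
import pandas as pd

from .core import CoefficientMatrix

FLOAT_FORMAT = "%.12g"

EDGE_COLUMNS = ("source", "target", "weight", "sign", "context")


def matrix_to_edgelist(cmat: CoefficientMatrix) -> pd.DataFrame:
    """Edge list of one matrix: source = influencer, target = affected."""
    rows = [
        (j, i, v, "positive" if v > 0 else ("negative" if v < 0 else "neutral"),
         cmat.context)
        for (i, j), v in sorted(cmat.entries.items())
    ]
    return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))


def matrices_to_edgelist(matrices: Iterable[CoefficientMatrix]) -> pd.DataFrame:
    frames = [matrix_to_edgelist(m) for m in matrices]
    if not frames:
        return pd.DataFrame(columns=list(EDGE_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def write_edgelist_tsv(matrices: Iterable[CoefficientMatrix], path) -> None:
    matrices_to_edgelist(matrices).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def matrix_to_graph(cmat: CoefficientMatrix) -> nx.DiGraph:
    """Directed signed interaction graph of one community context."""
    graph = nx.DiGraph(context=cmat.context, form=cmat.form)
    graph.add_nodes_from(cmat.members)
    for (i, j), v in sorted(cmat.entries.items()):
        graph.add_edge(
            j,
            i,
            weight=float(v),
            sign="positive" if v > 0 else ("negative" if v < 0 else "neutral"),
            context=cmat.context,
        )
    return graph


def write_graphml(cmat: CoefficientMatrix, path) -> None:
    nx.write_graphml(matrix_to_graph(cmat), path)


def write_json(payload: Mapping, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_frame(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
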