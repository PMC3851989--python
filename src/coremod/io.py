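"""Readers and writers for the TSV dialects used by the pipeline.

All matrices are tab-separated with the first row holding gene labels and
the first column holding sample labels.  Binary matrices are validated to
contain only 0/1.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .matrices import AlterationCalls, DataError, ExpressionMatrix, MutationMatrix

__all__ = [
    "read_alteration_calls",
    "read_expression_matrix",
    "write_alteration_calls",
    "write_expression_matrix",
    "write_mutation_matrix",
    "write_metagene_map",
    "write_network_tables",
    "write_graphml",
    "write_truth",
]


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"{path}: empty matrix")
    return df


def read_alteration_calls(path) -> AlterationCalls:
    return AlterationCalls(indicator=_read_matrix(path))


def read_expression_matrix(path) -> ExpressionMatrix:
    return ExpressionMatrix(values=_read_matrix(path))


def write_alteration_calls(calls: AlterationCalls, path) -> None:
    calls.indicator.to_csv(path, sep="\t")


def write_expression_matrix(b: ExpressionMatrix, path) -> None:
    b.values.to_csv(path, sep="\t", float_format="%.6g")


def write_mutation_matrix(a: MutationMatrix, path) -> None:
    a.indicator.to_csv(path, sep="\t")


def write_metagene_map(a: MutationMatrix, path) -> None:
    """Two-column TSV: unit_id, member_gene (one row per member)."""
    rows = [(unit, gene) for unit in a.unit_ids for gene in a.metagene_map[unit]]
    pd.DataFrame(rows, columns=["unit_id", "member_gene"]).to_csv(
        path, sep="\t", index=False
    )


def write_network_tables(net, prefix) -> None:
    """Weighted edge-list and vertex-weight TSVs for any of the networks."""
    prefix = Path(prefix)
    units = list(net.units)
    net.vertex_weight.rename_axis("unit_id").to_frame("weight").to_csv(
        f"{prefix}.vertices.tsv", sep="\t", float_format="%.6g"
    )
    rows = []
    for i, ui in enumerate(units):
        for uj in units[i + 1:]:
            rows.append((ui, uj, float(net.edge_weight.loc[ui, uj])))
    pd.DataFrame(rows, columns=["unit_i", "unit_j", "weight"]).to_csv(
        f"{prefix}.edges.tsv", sep="\t", index=False, float_format="%.6g"
    )


def write_graphml(integrative, path, en=None, mn=None) -> None:
    """GraphML export of the integrative network, optionally annotated with
    the expression and mutation weights."""
    import networkx as nx

    g = nx.Graph()
    for u in integrative.units:
        attrs = {"c": float(integrative.vertex_weight[u])}
        if en is not None:
            attrs["f"] = float(en.vertex_weight[u])
        if mn is not None:
            attrs["h"] = float(mn.vertex_weight[u])
        g.add_node(u, **attrs)
    units = list(integrative.units)
    for i, ui in enumerate(units):
        for uj in units[i + 1:]:
            attrs = {"w": float(integrative.edge_weight.loc[ui, uj])}
            if en is not None:
                attrs["u"] = float(en.edge_weight.loc[ui, uj])
            if mn is not None:
                attrs["v"] = float(mn.edge_weight.loc[ui, uj])
            g.add_edge(ui, uj, **attrs)
    nx.write_graphml(g, path)


def write_truth(truth, path) -> None:
    payload = {
        "modules": [list(m) for m in truth.modules],
        "influenced": {g: list(t) for g, t in truth.influenced.items()},
        "realized_coverage": truth.realized_coverage,
        "per_gene_counts": truth.per_gene_counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
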