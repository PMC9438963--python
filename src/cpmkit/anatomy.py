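"""Consensus-edge extraction and anatomical labelling.

Per-fold selection masks differ because each LOOCV training set differs; the
edges worth reporting are the *consensus* edges selected in every fold.
These are mapped through the canonical edge ordering to node pairs and
labelled with the packaged AAL-116 atlas table (90 cerebral regions followed
by 26 cerebellar/vermis regions, standard ordering; a user-supplied table
with the same columns substitutes any other parcellation).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .connectome import edge_index_pairs, n_edges
from .cpm import SelectionMasks

__all__ = [
    "load_node_table",
    "generic_node_table",
    "consensus_edges",
    "label_edges",
    "consensus_report",
    "render_edge_table",
]

_LABEL_COLUMNS = [
    "node1_index",
    "node2_index",
    "node1_name",
    "node2_name",
    "node1_abbrev",
    "node2_abbrev",
]


def load_node_table(path=None) -> pd.DataFrame:
    """Node label table (columns: node_index, aal_name, abbreviation, hemisphere).

    With no path, the packaged AAL-116 table is returned.
    """
    if path is None:
        with resources.files("cpmkit").joinpath("data/aal116.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    idx = table["node_index"].to_numpy()
    if len(np.unique(idx)) != len(idx) or not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError("node_index must be unique and contiguous from 0")
    return table


def generic_node_table(n_nodes: int) -> pd.DataFrame:
    """Placeholder labels for parcellations without a packaged atlas table."""
    idx = np.arange(n_nodes)
    return pd.DataFrame(
        {
            "node_index": idx,
            "aal_name": [f"Node_{i}" for i in idx],
            "abbreviation": [f"N{i}" for i in idx],
            "hemisphere": ["L"] * n_nodes,
        }
    )


def consensus_edges(
    fold_masks: list[SelectionMasks],
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise AND of the per-fold masks: (positive, negative) consensus."""
    if not fold_masks:
        raise ValueError("need at least one fold")
    sizes = {m.n_edges for m in fold_masks}
    if len(sizes) != 1:
        raise ValueError(f"inconsistent edge counts across folds: {sorted(sizes)}")
    pos = np.logical_and.reduce([m.positive_mask for m in fold_masks])
    neg = np.logical_and.reduce([m.negative_mask for m in fold_masks])
    return pos, neg


def label_edges(
    mask, nodes: pd.DataFrame, mean_selection_rho=None
) -> pd.DataFrame:
    """Convert a boolean edge mask into a labelled node-pair table.

    Rows follow canonical edge order; node1_index < node2_index always.
    ``mean_selection_rho`` (length-E) adds a convenience column with the mean
    over folds of each edge's selection correlation.
    """
    mask = np.asarray(mask, dtype=bool)
    n_nodes = len(nodes)
    if mask.size != n_edges(n_nodes):
        raise ValueError(
            f"mask length {mask.size} does not match {n_nodes} nodes "
            f"({n_edges(n_nodes)} edges)"
        )
    pairs = edge_index_pairs(n_nodes)[mask]
    name = nodes["aal_name"].to_numpy()
    abbrev = nodes["abbreviation"].to_numpy()
    out = pd.DataFrame(
        {
            "node1_index": pairs[:, 0],
            "node2_index": pairs[:, 1],
            "node1_name": name[pairs[:, 0]],
            "node2_name": name[pairs[:, 1]],
            "node1_abbrev": abbrev[pairs[:, 0]],
            "node2_abbrev": abbrev[pairs[:, 1]],
        },
        columns=_LABEL_COLUMNS,
    )
    if mean_selection_rho is not None:
        rho = np.asarray(mean_selection_rho, dtype=float)
        if rho.size != mask.size:
            raise ValueError("mean_selection_rho length disagrees with mask")
        out["mean_selection_rho"] = rho[mask]
    return out


def reindex_edges(labelled: pd.DataFrame, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`label_edges`: labelled pairs back to a boolean mask."""
    mask = np.zeros(n_edges(n_nodes), dtype=bool)
    pairs = edge_index_pairs(n_nodes)
    lookup = {(int(i), int(j)): k for k, (i, j) in enumerate(pairs)}
    for i, j in zip(labelled["node1_index"], labelled["node2_index"]):
        mask[lookup[(int(i), int(j))]] = True
    return mask


def consensus_report(prediction, nodes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Labelled consensus-edge tables for both networks of a LOOCV fit.

    ``prediction`` is a :class:`cpmkit.cpm.LoocvPrediction` produced with
    fold detail (as :func:`cpmkit.cpm.loocv_predict` returns).
    """
    if not prediction.fold_masks:
        raise ValueError("prediction carries no fold masks; run loocv_predict")
    pos, neg = consensus_edges(prediction.fold_masks)
    mean_rho = (
        prediction.fold_rhos.mean(axis=0) if prediction.fold_rhos is not None else None
    )
    return {
        "positive": label_edges(pos, nodes, mean_selection_rho=mean_rho),
        "negative": label_edges(neg, nodes, mean_selection_rho=mean_rho),
    }


def render_edge_table(labelled: pd.DataFrame) -> str:
    """Plain-text rendering; an empty network renders as an em-dash row."""
    if labelled.empty:
        return "—\t—\t—\t—"
    lines = [
        f"{r.node1_name}\t{r.node2_name}\t{r.node1_abbrev}\t{r.node2_abbrev}"
        for r in labelled.itertuples()
    ]
    return "\n".join(lines)
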