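"""Tabular and network artifact I/O, run configuration, logging.

Data enter as CSV/TSV with a header row: one participant per row, one node
per column, plus a node-metadata table (``name``, ``description``,
``var_type``, ``community``).  Ingestion is complete-case: rows with
missing entries are a hard error by default, or dropped and counted with
``drop_missing=True`` (mirroring a design that excludes participants with
incomplete questionnaires).  Estimated networks serialize to a TSV edge
list plus a JSON document carrying the full weight matrix, thresholds and
settings; GraphML export is available for external viewers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .data import ItemMatrix, meta_from_frame, meta_to_frame
from .network import EstimatedNetwork

__all__ = ["read_item_matrix", "write_item_matrix", "write_network",
           "read_network", "load_config", "setup_logging"]

logger = logging.getLogger("symnet")


def setup_logging(level=logging.INFO) -> None:
    """Configure the package logger with stage-stamped lines."""
    h = logging.StreamHandler()
    h.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [h]
    logger.setLevel(level)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_item_matrix(path, meta_path, drop_missing: bool = False,
                     id_column: str | None = None) -> ItemMatrix:
    """Read and validate a participant-by-node table with its metadata.

    Parameters
    ----------
    path, meta_path : str or Path
        CSV/TSV files (separator inferred from the extension).
    drop_missing : bool
        Drop rows containing missing values (count logged) instead of
        raising.
    id_column : str, optional
        Column to treat as a participant identifier and exclude from the
        analysis; a column literally named ``id`` is always excluded.

    Raises
    ------
    ValueError
        Empty file, data column without a metadata row, or a non-{0,1}
        value in a binary column (the error names the column and row).
    """
    path, meta_path = Path(path), Path(meta_path)
    values = pd.read_csv(path, sep=_sep_for(path))
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError(f"empty data file: {path}")
    drop_cols = [c for c in values.columns
                 if c == "id" or (id_column and c == id_column)]
    values = values.drop(columns=drop_cols)

    meta_frame = pd.read_csv(meta_path, sep=_sep_for(meta_path))
    if meta_frame.shape[0] == 0:
        raise ValueError(f"empty metadata file: {meta_path}")
    meta = meta_from_frame(meta_frame)
    known = {m.name for m in meta}
    orphan = [c for c in values.columns if c not in known]
    if orphan:
        raise ValueError(f"data column(s) without a metadata row: {orphan}")

    n_in = len(values)
    if values.isna().any().any():
        if not drop_missing:
            bad = values.columns[values.isna().any()].tolist()
            raise ValueError(
                f"missing values in column(s) {bad}; pass drop_missing=True "
                "for complete-case ingestion"
            )
        values = values.dropna().reset_index(drop=True)
    n_dropped = n_in - len(values)
    if n_dropped:
        logger.info("ingestion: dropped %d/%d incomplete rows", n_dropped, n_in)
    if len(values) == 0:
        raise ValueError("no complete rows after dropping missing data")
    im = ItemMatrix(values, [m for m in meta if m.name in values.columns])
    im.n_dropped = n_dropped
    logger.info("ingestion: n=%d participants, p=%d nodes", im.n, im.p)
    return im


def write_item_matrix(items: ItemMatrix, path, meta_path=None) -> None:
    """Write an ItemMatrix (and optionally its metadata) to CSV/TSV."""
    path = Path(path)
    items.values.to_csv(path, sep=_sep_for(path), index=False)
    if meta_path is not None:
        meta_path = Path(meta_path)
        meta_to_frame(items.meta).to_csv(meta_path, sep=_sep_for(meta_path),
                                         index=False)


def write_network(net: EstimatedNetwork, prefix, graphml: bool = False,
                  ) -> list[Path]:
    """Write a network as ``<prefix>.edges.tsv`` + ``<prefix>.json``.

    The edge list holds nonzero edges only; the JSON retains the full
    weight matrix, thresholds and settings and round-trips exactly through
    :func:`read_network`.  With ``graphml=True`` a ``<prefix>.graphml`` is
    also written.
    """
    W = np.asarray(net.weights)
    if not np.allclose(W, W.T):
        raise ValueError("network weights must be symmetric")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    edges = net.edge_list()
    edge_path = prefix.with_suffix(prefix.suffix + ".edges.tsv")
    edges.to_csv(edge_path, sep="\t", index=False)
    written.append(edge_path)

    json_path = prefix.with_suffix(prefix.suffix + ".json")
    net.to_json(json_path)
    written.append(json_path)

    if graphml:
        G = nx.Graph()
        for i, name in enumerate(net.node_names):
            G.add_node(name, threshold=float(net.thresholds[i]))
        for row in edges.itertuples(index=False):
            G.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        gpath = prefix.with_suffix(prefix.suffix + ".graphml")
        nx.write_graphml(G, gpath)
        written.append(gpath)
    return written


def read_network(path) -> EstimatedNetwork:
    """Read a network JSON written by :func:`write_network`."""
    return EstimatedNetwork.from_json(path)


def load_config(path) -> dict:
    """Load a YAML or JSON run-configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
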