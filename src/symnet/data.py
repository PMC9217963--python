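"""Core data containers: participant-by-node item matrices and node metadata.

An :class:`ItemMatrix` holds a participants x nodes table in which every
column is either a binary item (lifetime presence/absence of a symptom,
or a dichotomized risk factor) or a continuous risk-factor measure.  Node
metadata assigns each column a variable type and a community (predefined
symptom/risk-factor grouping used for bridge centrality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_VAR_TYPES = ("binary", "continuous")
VALID_COMMUNITIES = ("depression", "psychosis", "polygenic", "environmental")

META_COLUMNS = ("name", "description", "var_type", "community")


@dataclass(frozen=True)
class NodeMeta:
    """Metadata for one network node (one column of an :class:`ItemMatrix`).

    Parameters
    ----------
    name : str
        Short node label (e.g. ``Sad``, ``Con``, ``Trau``, ``PRd``).
    description : str
        Human-readable item description.
    var_type : {"binary", "continuous"}
        Measurement scale of the column.
    community : str
        Predefined node grouping; the analysis uses four communities
        (``depression``, ``psychosis``, ``polygenic``, ``environmental``).
    """

    name: str
    description: str = ""
    var_type: str = "binary"
    community: str = "depression"

    def __post_init__(self):
        if self.var_type not in VALID_VAR_TYPES:
            raise ValueError(
                f"node {self.name!r}: var_type must be one of {VALID_VAR_TYPES}, "
                f"got {self.var_type!r}"
            )


def meta_to_frame(meta: list[NodeMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.name, m.description, m.var_type, m.community) for m in meta],
        columns=list(META_COLUMNS),
    )


def meta_from_frame(frame: pd.DataFrame) -> list[NodeMeta]:
    missing = {"name", "var_type"} - set(frame.columns)
    if missing:
        raise ValueError(f"metadata table lacks required columns: {sorted(missing)}")
    def _str(value, default=""):
        return default if value is None or pd.isna(value) else str(value)

    out = []
    for _, row in frame.iterrows():
        out.append(
            NodeMeta(
                name=str(row["name"]),
                description=_str(row.get("description")),
                var_type=str(row["var_type"]),
                community=_str(row.get("community"), "depression"),
            )
        )
    return out


class ItemMatrix:
    """Validated participants x nodes data table with node metadata.

    Invariants enforced at construction:

    * no missing values,
    * binary columns contain only 0/1,
    * column names are unique and each has exactly one metadata row.

    Parameters
    ----------
    values : pandas.DataFrame
        Participants in rows, nodes in columns.
    meta : list of NodeMeta, optional
        One entry per column.  If omitted, every column is assumed binary
        and assigned to the ``depression`` community (convenient for toy
        data; real analyses should always pass metadata).
    """

    def __init__(self, values: pd.DataFrame, meta: list[NodeMeta] | None = None):
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        if values.shape[1] == 0:
            raise ValueError("ItemMatrix requires at least one column")
        names = [str(c) for c in values.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in item matrix")
        values = values.copy()
        values.columns = names

        if meta is None:
            meta = [NodeMeta(name=c) for c in names]
        by_name = {m.name: m for m in meta}
        if len(by_name) != len(meta):
            raise ValueError("duplicate node names in metadata")
        missing = [c for c in names if c not in by_name]
        if missing:
            raise ValueError(f"no metadata row for column(s): {missing}")
        # order metadata to match columns; extra metadata rows are ignored
        meta = [by_name[c] for c in names]

        if values.isna().any().any():
            bad = values.columns[values.isna().any()].tolist()
            raise ValueError(f"missing values in column(s) {bad}; ingest with "
                             "drop_missing=True or supply complete cases")
        for m in meta:
            col = values[m.name]
            if m.var_type == "binary":
                arr = col.to_numpy()
                ok = np.isin(arr, (0, 1))
                if not ok.all():
                    row = int(np.nonzero(~ok)[0][0])
                    raise ValueError(
                        f"binary column {m.name!r} contains non-{{0,1}} value "
                        f"{arr[row]!r} at row {row}"
                    )
                values[m.name] = col.astype(np.int8)
            else:
                values[m.name] = col.astype(float)

        self.values = values
        self.meta = meta

    # -- basic introspection -------------------------------------------------

    @property
    def n(self) -> int:
        """Participant count."""
        return int(self.values.shape[0])

    @property
    def p(self) -> int:
        """Node count."""
        return int(self.values.shape[1])

    @property
    def node_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def var_types(self) -> dict[str, str]:
        return {m.name: m.var_type for m in self.meta}

    @property
    def communities(self) -> dict[str, str]:
        return {m.name: m.community for m in self.meta}

    def binary_nodes(self) -> list[str]:
        return [m.name for m in self.meta if m.var_type == "binary"]

    def continuous_nodes(self) -> list[str]:
        return [m.name for m in self.meta if m.var_type == "continuous"]

    # -- manipulation --------------------------------------------------------

    def subset(self, nodes: list[str]) -> "ItemMatrix":
        """Column subset preserving metadata (order follows ``nodes``)."""
        unknown = [c for c in nodes if c not in self.values.columns]
        if unknown:
            raise KeyError(f"unknown node(s): {unknown}")
        by_name = {m.name: m for m in self.meta}
        return ItemMatrix(self.values[nodes], [by_name[c] for c in nodes])

    def take_rows(self, idx) -> "ItemMatrix":
        """Row subset (bootstrap resamples, case-dropping subsamples)."""
        return ItemMatrix(self.values.iloc[idx].reset_index(drop=True), self.meta)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def __repr__(self):  # pragma: no cover
        k = len(self.binary_nodes())
        return (f"ItemMatrix(n={self.n}, p={self.p}, "
                f"binary={k}, continuous={self.p - k})")
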