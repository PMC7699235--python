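"""Core data containers and TSV/GraphML readers and writers.

The pipeline starts from finished feature tables: 16S OTU abundances and
GC-MS / NMR metabolite concentrations, rows = features, columns = samples,
plus a per-sample trait table (case/control condition, responder status).
The canonical on-disk format is UTF-8 TSV with a "." decimal; networks are
exported as GraphML or a plain whitespace edge list.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

OTU = "OTU"
METABOLITE = "metabolite"
VALID_KINDS = frozenset({OTU, METABOLITE})

__all__ = [
    "OTU",
    "METABOLITE",
    "FeatureTable",
    "TraitTable",
    "MergedDataset",
    "Network",
    "read_feature_table",
    "read_trait_table",
    "merge_tables",
    "concatenate_groups",
    "write_network",
    "read_network",
]


@dataclasses.dataclass
class FeatureTable:
    """Features x samples abundance matrix with per-feature metadata.

    Parameters
    ----------
    data:
        Dense numeric matrix, index = feature ids, columns = sample ids.
        All values must be finite and non-negative (counts, relative
        abundances, ppm or µmol/g concentrations -- per-feature z-scoring
        downstream makes the scale irrelevant).
    kind:
        Per-feature label, ``"OTU"`` or ``"metabolite"``.
    units:
        Optional per-feature unit string (e.g. ``"counts"``, ``"ppm"``).
    """

    data: pd.DataFrame
    kind: pd.Series
    units: pd.Series | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        self.kind = pd.Series(self.kind, copy=True)
        if not self.kind.index.equals(self.data.index):
            self.kind = self.kind.reindex(self.data.index)
        if self.kind.isna().any() or not set(self.kind).issubset(VALID_KINDS):
            raise ValueError(f"feature kinds must be in {sorted(VALID_KINDS)}")
        if self.units is None:
            self.units = pd.Series("", index=self.data.index)
        else:
            self.units = pd.Series(self.units).reindex(self.data.index).fillna("")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.kind.copy(), self.units.copy())


@dataclasses.dataclass
class TraitTable:
    """Per-sample binary traits.

    ``condition``: 0 = control (CTRL), 1 = case (NSCLC).
    ``treatment``: 0 = non-responder, 1 = responder; missing (NaN) exactly
    for control samples, which were never treated.
    """

    condition: pd.Series
    treatment: pd.Series | None = None

    def __post_init__(self) -> None:
        self.condition = pd.Series(self.condition, copy=True).astype(int)
        if self.condition.index.has_duplicates:
            raise ValueError("duplicate sample ids in trait table")
        if not set(self.condition).issubset({0, 1}):
            raise ValueError("condition codes must be 0 (CTRL) or 1 (case)")
        if self.treatment is None:
            self.treatment = pd.Series(np.nan, index=self.condition.index)
        self.treatment = pd.Series(self.treatment, copy=True).astype(float)
        if not self.treatment.index.equals(self.condition.index):
            self.treatment = self.treatment.reindex(self.condition.index)
        ctrl = self.condition == 0
        if self.treatment[ctrl].notna().any():
            raise ValueError("treatment must be missing for control samples")
        bad = self.treatment[~ctrl].dropna()
        if not set(bad).issubset({0.0, 1.0}):
            raise ValueError("treatment codes must be 0 (NR) or 1 (R)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.condition.index)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": self.condition, "treatment": self.treatment}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.frame().to_csv(path, sep="\t", index_label="sample_id")


@dataclasses.dataclass
class MergedDataset:
    """A feature table (OTUs + metabolites stacked) with aligned traits.

    Samples are ordered patients-first, i.e. ``[P_1..P_n, C_1..C_m]``.
    """

    features: FeatureTable
    traits: TraitTable

    def __post_init__(self) -> None:
        if self.features.sample_ids != self.traits.sample_ids:
            raise ValueError("feature table and trait table sample ids differ")
        cond = self.traits.condition.to_numpy()
        # patients (1) must precede controls (0)
        if cond.size and np.any(np.diff(cond) > 0):
            raise ValueError("samples must be ordered patients before controls")

    @property
    def n_samples(self) -> int:
        return self.features.n_samples

    @property
    def n_patients(self) -> int:
        return int((self.traits.condition == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.traits.condition == 0).sum())


def read_feature_table(
    path: str | Path, kind: str, units: str = ""
) -> FeatureTable:
    """Read a TSV feature table (header = sample ids, first column = feature ids).

    All rows are tagged with ``kind`` (``"OTU"`` or ``"metabolite"``).
    Non-numeric or negative cells and duplicate ids raise ``ValueError``.
    """
    if kind not in VALID_KINDS:
        raise ValueError(f"kind must be one of {sorted(VALID_KINDS)}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    try:
        data = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric value at feature {row!r}, sample {col!r}"
                ) from None
        raise
    kinds = pd.Series(kind, index=data.index)
    unit_col = pd.Series(units, index=data.index)
    return FeatureTable(data, kinds, unit_col)


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    treatment = df["treatment"] if "treatment" in df else None
    return TraitTable(df["condition"], treatment)


def merge_tables(otus: FeatureTable, metabolites: FeatureTable) -> FeatureTable:
    """Row-stack OTU and metabolite tables over the same sample set.

    Metabolite columns are re-ordered to the OTU sample order; sample sets
    that differ raise with the asymmetric ids named.
    """
    s_otu, s_met = set(otus.sample_ids), set(metabolites.sample_ids)
    if s_otu != s_met:
        only_otu = sorted(s_otu - s_met)
        only_met = sorted(s_met - s_otu)
        raise ValueError(
            f"sample sets differ: only in OTU table {only_otu}, "
            f"only in metabolite table {only_met}"
        )
    met = metabolites.data[otus.sample_ids]
    overlap = set(otus.feature_ids) & set(metabolites.feature_ids)
    if overlap:
        raise ValueError(f"feature ids present in both tables: {sorted(overlap)}")
    data = pd.concat([otus.data, met])
    kind = pd.concat([otus.kind, metabolites.kind])
    units = pd.concat([otus.units, metabolites.units])
    return FeatureTable(data, kind, units)


def concatenate_groups(
    patients: FeatureTable,
    controls: FeatureTable,
    treatment: Sequence[float] | None = None,
) -> MergedDataset:
    """Concatenate patient and control tables sample-wise, patients first.

    Both tables must carry the identical feature list. The condition trait
    is set to 1 for patient samples and 0 for controls; ``treatment``
    optionally gives responder codes for the patient samples. Sample-id
    collisions between the two groups are disambiguated with a ``_ctrl``
    suffix on the control side.
    """
    if patients.feature_ids != controls.feature_ids:
        if set(patients.feature_ids) != set(controls.feature_ids):
            miss = sorted(
                set(patients.feature_ids) ^ set(controls.feature_ids)
            )
            raise ValueError(f"feature lists differ: {miss}")
        controls = FeatureTable(
            controls.data.loc[patients.feature_ids],
            controls.kind,
            controls.units,
        )
    ctrl_data = controls.data.copy()
    collisions = set(patients.sample_ids) & set(ctrl_data.columns)
    if collisions:
        ctrl_data.columns = [
            f"{c}_ctrl" if c in collisions else c for c in ctrl_data.columns
        ]
    data = pd.concat([patients.data, ctrl_data], axis=1)
    table = FeatureTable(data, patients.kind, patients.units)
    cond = pd.Series(
        [1] * patients.n_samples + [0] * controls.n_samples, index=data.columns
    )
    treat = pd.Series(np.nan, index=data.columns)
    if treatment is not None:
        if len(treatment) != patients.n_samples:
            raise ValueError("treatment codes must match patient sample count")
        treat.iloc[: patients.n_samples] = list(treatment)
    return MergedDataset(table, TraitTable(cond, treat))


@dataclasses.dataclass
class Network:
    """A binarized feature-association network.

    Wraps an undirected ``networkx.Graph`` whose nodes are feature ids with
    attributes ``kind`` and ``label`` (1-based numeric id in insertion
    order of the retained features) and whose edges carry the sign and
    value of the underlying correlation where known.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for node, deg in self.graph.degree():
            if deg == 0 and self.graph.number_of_nodes() > 1:
                raise ValueError(f"isolated node {node!r} in network")

    @classmethod
    def from_graph(
        cls, graph: nx.Graph, kinds: pd.Series | dict | None = None
    ) -> "Network":
        g = nx.Graph()
        for i, node in enumerate(graph.nodes, start=1):
            attrs = dict(graph.nodes[node])
            attrs.setdefault("label", i)
            if kinds is not None:
                attrs["kind"] = kinds[node]
            attrs.setdefault("kind", METABOLITE)
            g.add_node(node, **attrs)
        g.add_edges_from(graph.edges(data=True))
        return cls(g)

    @property
    def node_ids(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> tuple[list, np.ndarray]:
        """Binarized adjacency matrix (zero diagonal) and its node order."""
        nodes = self.node_ids
        a = nx.to_numpy_array(self.graph, nodelist=nodes, weight=None)
        np.fill_diagonal(a, 0.0)
        return nodes, a

    def kinds(self) -> pd.Series:
        return pd.Series(
            {n: self.graph.nodes[n].get("kind", METABOLITE) for n in self.node_ids}
        )


def write_network(net: Network, path: str | Path, format: str = "graphml") -> None:
    """Write a network as GraphML (with node attributes) or whitespace edge list."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            for u, v in net.graph.edges:
                fh.write(f"{u} {v}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> Network:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return Network(nx.Graph(g))
    if format == "edgelist":
        g = nx.read_edgelist(path)
        return Network(g)
    raise ValueError(f"unknown network format {format!r}")
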