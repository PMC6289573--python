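"""Readers and writers for the flat-file exports the package consumes.

Formats: SWC skeletons (coordinates scaled into nm on read), connector and
annotation CSVs (comma-separated, UTF-8, header required, one connector row
per postsynaptic site), similarity-matrix and adjacency CSVs, Newick
dendrograms, and GraphML path graphs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path as _Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .errors import ParseError, SezconnError
from .model import Connector, ConnectomeGraph, Neuron, SkeletonNode

CONNECTOR_COLUMNS = ["connector_id", "pre_neuron", "post_neuron", "x", "y", "z"]
PRE_POS_COLUMNS = ["pre_x", "pre_y", "pre_z"]
ANNOTATION_COLUMNS = ["neuron_id", "name", "class", "nerve", "bundle", "origin", "side"]


@dataclass
class DatasetBundle:
    """A loaded dataset: neurons, connectors, annotations, and provenance."""

    neurons: dict = field(default_factory=dict)  # id -> Neuron
    connectors: list = field(default_factory=list)
    annotations: pd.DataFrame = None
    provenance: dict = field(default_factory=dict)

    def unresolved_connector_neurons(self) -> set:
        """Connector neuron ids that do not resolve to a loaded neuron."""
        known = set(self.neurons)
        missing = set()
        for c in self.connectors:
            if c.pre[0] not in known:
                missing.add(c.pre[0])
            for nid, _ in c.posts:
                if nid not in known:
                    missing.add(nid)
        return missing


# ---------------------------------------------------------------------------
# SWC


def read_swc(path, unit_scale: float = 1.0) -> list:
    """Parse an SWC file into SkeletonNodes; coordinates multiplied into nm.

    Node ids are arbitrary positive integers (CATMAID exports are sparse);
    parent -1 marks the root. Duplicate ids, bad column counts and dangling
    parent references raise ParseError with the offending line number.
    """
    nodes = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ParseError(
                    f"expected 7 whitespace-separated columns, got {len(fields)}",
                    path=path, line=lineno,
                )
            try:
                nid = int(fields[0])
                struct = int(fields[1])
                x, y, z, radius = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"malformed value: {exc}", path=path, line=lineno)
            if nid in seen:
                raise ParseError(f"duplicate node id {nid}", path=path, line=lineno)
            seen.add(nid)
            nodes.append(
                SkeletonNode(
                    node_id=nid,
                    parent_id=None if parent == -1 else parent,
                    position=np.array([x, y, z]) * unit_scale,
                    radius=radius * unit_scale,
                    structure=struct,
                )
            )
    ids = {n.node_id for n in nodes}
    for n in nodes:
        if n.parent_id is not None and n.parent_id not in ids:
            raise ParseError(
                f"node {n.node_id} references missing parent {n.parent_id}",
                path=path,
            )
    return nodes


def write_swc(path, nodes, unit_scale: float = 1.0) -> None:
    """Write SkeletonNodes as SWC; coordinates divided by unit_scale."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in nodes:
            p = n.position / unit_scale
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(
                f"{n.node_id} {n.structure} {p[0]:.17g} {p[1]:.17g} "
                f"{p[2]:.17g} {n.radius / unit_scale:.17g} {parent}\n"
            )


def read_neuron_swc(path, neuron_id=None, unit_scale: float = 1.0) -> Neuron:
    """Load one SWC file as a Neuron (id defaults to the file stem)."""
    p = _Path(path)
    return Neuron(
        neuron_id=neuron_id if neuron_id is not None else p.stem,
        name=p.stem,
        skeleton=read_swc(path, unit_scale=unit_scale),
    )


# ---------------------------------------------------------------------------
# CSV tables


def _read_csv_strict(path, required_columns):
    """csv-module reader that rejects ragged rows with the offending line."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", path=path, line=1)
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise ParseError(f"missing required column(s) {missing}", path=path, line=1)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, got {len(row)}",
                    path=path, line=lineno,
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=header)


def read_connectors_csv(path) -> list:
    """Load a polyadic connector table (one row per postsynaptic site).

    The connector's presynaptic position comes from pre_x/pre_y/pre_z when
    present, otherwise the centroid of its postsynaptic sites is used.
    """
    df = _read_csv_strict(path, CONNECTOR_COLUMNS)
    for c in ["x", "y", "z"] + [c for c in PRE_POS_COLUMNS if c in df.columns]:
        df[c] = df[c].astype(float)
    has_pre_pos = all(c in df.columns for c in PRE_POS_COLUMNS)
    connectors = []
    for cid, group in df.groupby("connector_id", sort=True):
        pres = group["pre_neuron"].unique()
        if len(pres) != 1:
            raise ParseError(
                f"connector {cid!r} lists multiple presynaptic neurons {list(pres)}",
                path=path,
            )
        posts = tuple(
            (row.post_neuron, np.array([row.x, row.y, row.z]))
            for row in group.itertuples()
        )
        if has_pre_pos:
            pre_pos = group[PRE_POS_COLUMNS].iloc[0].to_numpy(dtype=float)
        else:
            pre_pos = np.mean([p for _, p in posts], axis=0)
        connectors.append(Connector(cid, (pres[0], pre_pos), posts))
    return connectors


def write_connectors_csv(path, connectors) -> None:
    """Write connectors as one row per postsynaptic site, with pre positions."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONNECTOR_COLUMNS + PRE_POS_COLUMNS)
        for c in connectors:
            pre_id, pre_pos = c.pre
            for post_id, pos in c.posts:
                writer.writerow(
                    [c.connector_id, pre_id, post_id]
                    + [f"{v:.17g}" for v in pos]
                    + [f"{v:.17g}" for v in pre_pos]
                )


def read_annotations_csv(path) -> pd.DataFrame:
    """Load the neuron annotation table, indexed by neuron_id."""
    df = _read_csv_strict(path, ["neuron_id", "class"])
    return df.set_index("neuron_id")


def write_annotations_csv(path, annotations: pd.DataFrame) -> None:
    annotations.to_csv(path, index_label="neuron_id")


def read_graph_csv(path) -> ConnectomeGraph:
    """Load a directed adjacency list CSV with columns src,dst,weight."""
    df = _read_csv_strict(path, ["src", "dst", "weight"])
    g = ConnectomeGraph()
    for row in df.itertuples():
        g.add_edge(row.src, row.dst, int(row.weight))
    return g


def write_graph_csv(path, graph: ConnectomeGraph) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["src", "dst", "weight"])
        for src, dst, w in sorted(graph.edges(), key=lambda e: (str(e[0]), str(e[1]))):
            writer.writerow([src, dst, w])


def read_matrix_csv(path):
    """Load a labelled square similarity matrix CSV."""
    from .clustering import SimilarityMatrix

    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ParseError("matrix row and column labels differ", path=path)
    return SimilarityMatrix.from_frame(df)


def write_matrix_csv(path, matrix) -> None:
    matrix.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Newick / GraphML


def write_dendrogram_newick(dendrogram) -> str:
    """Serialize a dendrogram as Newick text.

    Leaf names are the neuron ids; branch lengths are merge-height
    differences, so leaves sit at depth equal to their first merge height.
    """
    labels = [str(l) for l in dendrogram.labels]
    if len(labels) == 1:
        return f"{labels[0]};"
    root = to_tree(dendrogram.linkage)

    def fmt(x: float) -> str:
        return f"{x:.12g}"

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        parts = []
        for child in (node.left, node.right):
            parts.append(f"{rec(child)}:{fmt(node.dist - child.dist)}")
        return "(" + ",".join(parts) + ")"

    return rec(root) + ";"


def write_paths_graphml(pathset, path, annotations=None, layers=None) -> None:
    """Write the union graph of a PathSet as GraphML.

    Nodes carry 'class' and 'layer' attributes, edges their synapse weights.
    An empty pathset produces a document with zero nodes.
    """
    import networkx as nx

    from .model import class_map

    cmap = class_map(annotations) if annotations is not None else {}
    layer_map = layers.mapping if hasattr(layers, "mapping") else dict(layers or {})
    g = nx.DiGraph()
    for p in pathset.paths:
        for node in p.nodes:
            if node not in g:
                g.add_node(
                    str(node),
                    **{
                        "class": str(cmap.get(node, "")),
                        "layer": str(layer_map.get(node, "")),
                    },
                )
        for (a, b), w in zip(zip(p.nodes, p.nodes[1:]), p.weights):
            g.add_edge(str(a), str(b), weight=int(w))
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# bundle-level helpers


def load_bundle(connectors_path, annotations_path, swc_dir=None,
                unit_scale: float = 1.0) -> DatasetBundle:
    """Load connectors + annotations (+ optional SWC directory) as one bundle."""
    connectors = read_connectors_csv(connectors_path)
    annotations = read_annotations_csv(annotations_path)
    neurons = {}
    if swc_dir is not None:
        for swc in sorted(_Path(swc_dir).glob("*.swc")):
            neuron = read_neuron_swc(swc, unit_scale=unit_scale)
            neurons[neuron.neuron_id] = neuron
    return DatasetBundle(
        neurons=neurons,
        connectors=connectors,
        annotations=annotations,
        provenance={
            "connectors": str(connectors_path),
            "annotations": str(annotations_path),
            "swc_dir": str(swc_dir) if swc_dir else None,
            "unit_scale_to_nm": unit_scale,
        },
    )


def write_bundle(bundle: DatasetBundle, outdir) -> dict:
    """Write a bundle's tables (and skeletons) under a directory; returns paths."""
    out = _Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "connectors": out / "connectors.csv",
        "annotations": out / "annotations.csv",
    }
    write_connectors_csv(paths["connectors"], bundle.connectors)
    write_annotations_csv(paths["annotations"], bundle.annotations)
    if bundle.neurons:
        swc_dir = out / "skeletons"
        swc_dir.mkdir(exist_ok=True)
        for nid, neuron in sorted(bundle.neurons.items(), key=lambda kv: str(kv[0])):
            if neuron.skeleton:
                write_swc(swc_dir / f"{nid}.swc", neuron.skeleton)
        paths["skeletons"] = swc_dir
    return {k: str(v) for k, v in paths.items()}
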