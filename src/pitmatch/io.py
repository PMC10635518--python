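"""On-disk formats: GraphML graphs, JSON manifests, Matrix Market bulks.

A population lives in a directory:

- ``graph_XXXX.graphml``: one file per graph, node attributes ``x, y, z,
  is_dummy`` (plus any extra scalar attributes), edge attribute ``length``;
- ``manifest.json``: ordered list of graph files (the order defines block
  positions in bulk matrices) and the simulation/config echo;
- ``ground_truth.json``: per graph, the list of reference identities
  (-1 = outlier), present only for simulated data.

Bulk assignment matrices are sparse and stored in Matrix Market coordinate
format; labelings as JSON lists with -1 for unlabeled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.io
import scipy.sparse

from .core import BulkAssignment, GraphPopulation, SulcalGraph


class SchemaError(ValueError):
    """Raised when a file lacks a required attribute or dimension."""


_RESERVED = {"x", "y", "z", "is_dummy"}


def write_graphml(g: SulcalGraph, path: str | Path) -> None:
    G = nx.Graph()
    for v in range(g.n_nodes):
        attrs = {
            "x": float(g.coords[v, 0]),
            "y": float(g.coords[v, 1]),
            "z": float(g.coords[v, 2]),
            "is_dummy": bool(g.dummy[v]),
        }
        for name, arr in g.node_attrs.items():
            attrs[name] = float(arr[v])
        G.add_node(v, **attrs)
    for (i, j) in g.edges:
        G.add_edge(i, j, length=float(g.edge_lengths[(i, j)]))
    nx.write_graphml(G, str(path))


def read_graphml(path: str | Path) -> SulcalGraph:
    G = nx.read_graphml(str(path))
    nodes = sorted(G.nodes, key=int)
    n = len(nodes)
    coords = np.zeros((n, 3))
    dummy = np.zeros(n, dtype=bool)
    extra_names = set()
    for v in nodes:
        extra_names |= set(G.nodes[v]) - _RESERVED
    node_attrs = {name: np.full(n, np.nan) for name in sorted(extra_names)}
    for v in nodes:
        data = G.nodes[v]
        k = int(v)
        for c, axis in enumerate("xyz"):
            if axis not in data:
                raise SchemaError(f"node {v} in {path} is missing attribute '{axis}'")
            coords[k, c] = float(data[axis])
        dummy[k] = bool(data.get("is_dummy", False))
        for name in extra_names:
            if name in data:
                node_attrs[name][k] = float(data[name])
    edges = []
    lengths = {}
    for (a, b, data) in G.edges(data=True):
        if "length" not in data:
            raise SchemaError(f"edge ({a},{b}) in {path} is missing attribute 'length'")
        e = tuple(sorted((int(a), int(b))))
        edges.append(e)
        lengths[e] = float(data["length"])
    return SulcalGraph(coords, sorted(edges), lengths, dummy, node_attrs)


def _jsonable(obj):
    if is_dataclass(obj):
        return asdict(obj)
    return obj


def write_population(
    pop: GraphPopulation,
    out_dir: str | Path,
    ground_truth: list[np.ndarray] | None = None,
    config=None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for q, g in enumerate(pop):
        name = f"graph_{q:04d}.graphml"
        write_graphml(g, out / name)
        files.append(name)
    manifest = {"graphs": files, "n_max": pop.n_max}
    if config is not None:
        manifest["config"] = _jsonable(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if ground_truth is not None:
        gt = {str(q): np.asarray(ids).astype(int).tolist() for q, ids in enumerate(ground_truth)}
        (out / "ground_truth.json").write_text(json.dumps(gt))


def read_population(
    pop_dir: str | Path,
) -> tuple[GraphPopulation, list[np.ndarray] | None]:
    d = Path(pop_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.json in {d}")
    manifest = json.loads(manifest_path.read_text())
    graphs = [read_graphml(d / name) for name in manifest["graphs"]]
    pop = GraphPopulation(graphs)
    gt_path = d / "ground_truth.json"
    gt = None
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        gt = [np.array(raw[str(q)], dtype=int) for q in range(len(graphs))]
    return pop, gt


def write_bulk(bulk: BulkAssignment, path: str | Path) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(bulk.matrix))


def read_bulk(path: str | Path, n_max: int, binary: bool = False) -> BulkAssignment:
    M = scipy.io.mmread(str(path))
    M = np.asarray(M.todense() if scipy.sparse.issparse(M) else M, dtype=float)
    if M.shape[0] != M.shape[1] or M.shape[0] % n_max:
        raise SchemaError(
            f"bulk of shape {M.shape} incompatible with n_max = {n_max}"
        )
    if binary and not np.isin(M, (0.0, 1.0)).all():
        raise SchemaError("binarized bulk contains values outside {0, 1}")
    return BulkAssignment(M, n_max)


def write_labeling(labeling: list[np.ndarray], path: str | Path) -> None:
    data = {str(q): np.asarray(lab).astype(int).tolist() for q, lab in enumerate(labeling)}
    Path(path).write_text(json.dumps(data))


def read_labeling(path: str | Path) -> list[np.ndarray]:
    raw = json.loads(Path(path).read_text())
    return [np.array(raw[str(q)], dtype=int) for q in range(len(raw))]
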