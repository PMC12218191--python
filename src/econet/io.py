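"""Readers, writers and real-network adapters.

Formats: comma-separated edge lists (``source, target, weight``) plus node
coordinate tables (``id, x, y[, z ...]``), or GraphML with ``x``/``y``/``z``
node attributes.  Directed duplicates are symmetrised by summing (A + A'),
isolated nodes are dropped with a log message, and inconsistent inputs are
rejected rather than repaired.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .graph import SpatialGraph

__all__ = [
    "read_graph",
    "read_graphml",
    "write_graph",
    "celegans_backbone",
    "write_provenance",
]

logger = logging.getLogger("econet")

#: connection-type labels treated as neuromuscular (excluded from backbones)
NEUROMUSCULAR_LABELS = frozenset({"nmj", "neuromuscular"})


def _load_coords(coord_path) -> pd.DataFrame:
    coords = (
        coord_path.copy()
        if isinstance(coord_path, pd.DataFrame)
        else pd.read_csv(coord_path, float_precision="round_trip")
    )
    if "id" not in coords.columns:
        raise ValueError("coordinate table must have an 'id' column")
    axes = [c for c in coords.columns if c != "id"]
    if not axes:
        raise ValueError("coordinate table has no coordinate columns")
    if coords["id"].astype(str).duplicated().any():
        raise ValueError("duplicate node ids in coordinate table")
    if not np.all(np.isfinite(coords[axes].to_numpy(dtype=float))):
        raise ValueError("non-finite coordinates")
    return coords.assign(id=coords["id"].astype(str))


def read_graph(edge_path, coord_path, metric: str = "euclidean") -> SpatialGraph:
    """Read an edge-list CSV plus a coordinate CSV into a :class:`SpatialGraph`.

    Reciprocated (i, j)/(j, i) rows are merged by summing weights; nodes in
    the coordinate table without any edge are dropped (logged); edges that
    reference nodes missing from the coordinate table are a hard error.
    """
    edges = pd.read_csv(edge_path, float_precision="round_trip")
    required = {"source", "target"}
    if not required <= set(edges.columns):
        raise ValueError("edge list must have 'source' and 'target' columns")
    if "weight" not in edges.columns:
        edges = edges.assign(weight=1.0)
    weights = pd.to_numeric(edges["weight"], errors="raise")
    if (weights <= 0).any() or not np.all(np.isfinite(weights)):
        raise ValueError("edge weights must be strictly positive and finite")
    coords = _load_coords(coord_path)
    axes = [c for c in coords.columns if c != "id"]
    known = set(coords["id"])
    refs = set(edges["source"].astype(str)) | set(edges["target"].astype(str))
    missing = sorted(refs - known)
    if missing:
        raise ValueError(f"edges reference nodes with no coordinates: {missing}")
    connected = refs
    dropped = known - connected
    if dropped:
        logger.info("dropping %d isolated node(s)", len(dropped))
    coords = coords[coords["id"].isin(connected)]
    mapping = {
        row.id: np.asarray([getattr(row, a) for a in axes], dtype=float)
        for row in coords.itertuples()
    }
    triples = zip(
        edges["source"].astype(str), edges["target"].astype(str), weights
    )
    return SpatialGraph.from_edges(mapping, triples, metric=metric)


def read_graphml(path, metric: str = "euclidean") -> SpatialGraph:
    """Read a GraphML file whose nodes carry ``x``/``y``(/``z``) attributes."""
    g = nx.read_graphml(path)
    axes = ["x", "y", "z"]
    coords = {}
    for node, data in g.nodes(data=True):
        vec = [float(data[a]) for a in axes if a in data]
        if not vec:
            raise ValueError(f"node {node!r} has no coordinate attributes")
        coords[str(node)] = vec
    dims = {len(v) for v in coords.values()}
    if len(dims) > 1:
        raise ValueError("inconsistent coordinate dimensions across nodes")
    edges = [
        (str(u), str(v), float(d.get("weight", 1.0))) for u, v, d in g.edges(data=True)
    ]
    connected = {u for u, v, _ in edges} | {v for u, v, _ in edges}
    dropped = set(coords) - connected
    if dropped:
        logger.info("dropping %d isolated node(s)", len(dropped))
        coords = {k: v for k, v in coords.items() if k in connected}
    return SpatialGraph.from_edges(coords, edges, metric=metric)


def write_graph(graph: SpatialGraph, edge_path, coord_path) -> None:
    """Write the CSV pair read back by :func:`read_graph` (lossless round trip)."""
    pairs = graph.edge_pairs()
    pd.DataFrame(
        {
            "source": [u for u, _ in pairs],
            "target": [v for _, v in pairs],
            "weight": graph.weights,
        }
    ).to_csv(edge_path, index=False)
    axes = ["x", "y", "z"][: graph.s] if graph.s <= 3 else [
        f"x{k}" for k in range(graph.s)
    ]
    coord_df = pd.DataFrame(graph.coords, columns=axes)
    coord_df.insert(0, "id", list(graph.node_ids))
    coord_df.to_csv(coord_path, index=False)


def celegans_backbone(
    synapses: pd.DataFrame,
    positions: pd.DataFrame,
    on_unknown_type: str = "error",
) -> SpatialGraph:
    """Backbone graph of a connectome synapse table.

    All chemical synapses and gap junctions between a neuron pair collapse
    into a single unweighted undirected edge; neuromuscular rows are dropped.
    ``synapses`` needs columns ``pre, post, type`` (``count`` optional);
    ``positions`` is a coordinate table (``id, x[, y, z]``).
    ``on_unknown_type``: ``"error"`` or ``"skip"`` (with a warning).
    """
    required = {"pre", "post", "type"}
    if not required <= set(synapses.columns):
        raise ValueError("synapse table must have columns pre, post, type")
    kinds = synapses["type"].astype(str).str.lower()
    known = kinds.isin({"chemical", "synapse", "electrical", "gap", "gap_junction"})
    neuromuscular = kinds.isin(NEUROMUSCULAR_LABELS)
    unknown = ~(known | neuromuscular)
    if unknown.any():
        if on_unknown_type == "skip":
            logger.warning("skipping %d rows of unknown type", int(unknown.sum()))
        else:
            raise ValueError(
                f"unknown connection types: {sorted(synapses.loc[unknown, 'type'].unique())}"
            )
    keep = synapses.loc[known]
    pairs = {
        frozenset((str(r.pre), str(r.post)))
        for r in keep.itertuples()
        if str(r.pre) != str(r.post)
    }
    coords = _load_coords(positions)
    axes = [c for c in coords.columns if c != "id"]
    nodes = {u for p in pairs for u in p}
    missing = sorted(nodes - set(coords["id"]))
    if missing:
        raise ValueError(f"neurons with no position: {missing}")
    coords = coords[coords["id"].isin(nodes)]
    mapping = {
        row.id: np.asarray([getattr(row, a) for a in axes], dtype=float)
        for row in coords.itertuples()
    }
    edges = [tuple(sorted(p)) + (1.0,) for p in pairs]
    return SpatialGraph.from_edges(mapping, sorted(edges))


def write_provenance(path, command: str, params: dict, seed=None,
                     inputs: Iterable[str] = (), outputs: Iterable[str] = ()) -> None:
    """JSON run record: command, parameters, seed, inputs/outputs, versions."""
    from . import __version__

    record = {
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "seed": seed,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "versions": {
            "econet": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, Path):
        return str(v)
    return v
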