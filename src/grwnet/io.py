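"""Readers and writers for networks, coordinate tables and layer stacks.

All on-disk formats are plain text: TSV edge lists (``i  j  w``), TSV
coordinate tables (``id  theta  kappa  sigma  x  y  z  hemisphere``), and a
layer-stack directory of per-layer files plus a JSON manifest carrying the
node→supernode maps.  Round trips are lossless at 15 significant digits.

Also houses the fiber-density weight of tractography-derived connectomes:
for ROIs of surface areas A_i, A_j connected by the fiber set F_e,

    w_ij = 2 / (A_i + A_j) · Σ_{f ∈ F_e} 1 / l(f),

i.e. streamlines per unit surface, each normalized by its length in mm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import LayerStack, NetworkError, NodeTable, WeightedNetwork

__all__ = [
    "FiberRecord",
    "fiber_density_weight",
    "read_network",
    "write_network",
    "read_coordinates",
    "write_coordinates",
    "read_layer_stack",
    "write_layer_stack",
]

logger = logging.getLogger("grwnet")

_FMT = "%.15g"


@dataclass(frozen=True)
class FiberRecord:
    """Surface areas (mm²) of two ROIs and the lengths (mm) of connecting fibers."""

    area_i: float
    area_j: float
    fiber_lengths: Sequence[float]

    def __post_init__(self) -> None:
        if self.area_i <= 0 or self.area_j <= 0:
            raise ValueError("ROI areas must be positive")
        if any(l <= 0 for l in self.fiber_lengths):
            raise ValueError("fiber lengths must be positive")


def fiber_density_weight(record: FiberRecord) -> float:
    """Fiber-density connection weight: 2/(A_i + A_j) Σ_f 1/l(f)."""
    if len(record.fiber_lengths) == 0:
        raise ValueError("no fibers: the connection does not exist")
    return 2.0 / (record.area_i + record.area_j) * sum(1.0 / l for l in record.fiber_lengths)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_network(network: WeightedNetwork, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# i\tj\tweight\n")
        for (i, j), w in zip(network.edges, network.weights):
            fh.write(f"{network.node_ids[i]}\t{network.node_ids[j]}\t{w:.15g}\n")


def read_network(path: str | Path, node_ids: Sequence[str] | None = None) -> WeightedNetwork:
    """Read a TSV edge list.  Node ids are opaque strings; the node set is the
    union of endpoint ids (pass ``node_ids`` to pin the full set, including
    isolated nodes, and the index order)."""
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                w = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: weight {parts[2]!r} is not a number")
            if not w > 0:
                raise ParseError(f"{path}:{lineno}: weight must be strictly positive")
            if parts[0] == parts[1]:
                raise ParseError(f"{path}:{lineno}: self-loop on node {parts[0]!r}")
            rows.append((parts[0], parts[1], w))
    if node_ids is None:
        seen: dict[str, int] = {}
        for a, b, _ in rows:
            for x in (a, b):
                if x not in seen:
                    seen[x] = len(seen)
        node_ids = list(seen)
    index = {nid: k for k, nid in enumerate(node_ids)}
    try:
        edges = np.array([[index[a], index[b]] for a, b, _ in rows], dtype=np.int64)
    except KeyError as exc:
        raise ParseError(f"{path}: edge references unknown node id {exc}")
    edges = edges.reshape(-1, 2)
    weights = np.array([w for _, _, w in rows])
    try:
        return WeightedNetwork(len(node_ids), edges, weights, list(node_ids))
    except NetworkError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_coordinates(nodes: NodeTable, path: str | Path,
                      node_ids: Sequence[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = len(nodes)
    ids = list(node_ids) if node_ids is not None else [str(i) for i in range(n)]
    df = pd.DataFrame({
        "id": ids,
        "theta": nodes.theta,
        "kappa": nodes.kappa,
        "sigma": nodes.sigma,
    })
    if nodes.xyz is not None:
        df["x"], df["y"], df["z"] = nodes.xyz.T
    if nodes.hemisphere is not None:
        df["hemisphere"] = nodes.hemisphere
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_coordinates(
    path: str | Path, required_ids: Sequence[str] | None = None
) -> tuple[NodeTable, list[str]]:
    """Read a coordinate table; θ is normalized to [0, 2π).  If
    ``required_ids`` is given (e.g. the node set of a network), every id must
    be present and rows are returned in that order."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ("id", "theta", "kappa", "sigma"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["theta"].isna().any():
        bad = df.index[df["theta"].isna()][0]
        raise ParseError(f"{path}: node {df['id'][bad]!r} has no theta")
    if required_ids is not None:
        missing = set(required_ids) - set(df["id"])
        if missing:
            raise ParseError(f"{path}: coordinates missing for nodes {sorted(missing)[:10]}")
        df = df.set_index("id").loc[list(required_ids)].reset_index()
    xyz = df[["x", "y", "z"]].to_numpy() if {"x", "y", "z"} <= set(df.columns) else None
    hemi = df["hemisphere"].to_numpy() if "hemisphere" in df.columns else None
    nodes = NodeTable(
        theta=df["theta"].to_numpy(),
        kappa=df["kappa"].to_numpy(),
        sigma=df["sigma"].to_numpy(),
        xyz=xyz,
        hemisphere=hemi,
    )
    return nodes, df["id"].tolist()


def write_layer_stack(stack: LayerStack, directory: str | Path) -> None:
    """Per-layer edge lists + coordinate tables and a JSON manifest of the
    node→supernode maps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_layers": stack.n_layers,
        "layer_files": [],
        "maps": [m.tolist() for m in stack.maps],
    }
    for l, net in enumerate(stack.layers):
        fname = f"layer{l}.tsv"
        write_network(net, directory / fname)
        entry = {"edges": fname, "n_nodes": net.n_nodes}
        if stack.node_tables is not None:
            cname = f"layer{l}_coords.tsv"
            write_coordinates(stack.node_tables[l], directory / cname, net.node_ids)
            entry["coords"] = cname
        manifest["layer_files"].append(entry)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_layer_stack(directory: str | Path) -> LayerStack:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    layers, tables = [], []
    have_coords = all("coords" in e for e in manifest["layer_files"])
    for entry in manifest["layer_files"]:
        # pin the id order so indices line up with the stored supernode maps
        ids = [str(i) for i in range(entry["n_nodes"])]
        layers.append(read_network(directory / entry["edges"], node_ids=ids))
        if have_coords:
            nodes, _ = read_coordinates(directory / entry["coords"])
            tables.append(nodes)
    maps = [np.asarray(m, dtype=np.int64) for m in manifest["maps"]]
    return LayerStack(layers=layers, maps=maps, node_tables=tables if have_coords else None)
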