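"""Persistence for model artifacts.

CSV dialect: comma-separated, header row, UTF-8, '.' decimal.  Reals are
written with ``repr``-level precision so write/read round-trips are exact
for integers and within 1e-15 relative for floats.  Graphs go to
edge-list CSV and GraphML (via networkx); configs to YAML; manifests to
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .blocks import BlockPartition, ConstraintSet, MixingDensityMatrix

__all__ = [
    "write_partition_csv", "read_partition_csv",
    "write_matrix_csv", "read_matrix_csv",
    "write_vector_csv", "read_vector_csv",
    "write_edgelist_csv", "read_edgelist_csv",
    "write_graphml", "read_graphml",
    "write_yaml", "read_yaml",
    "write_manifest", "read_manifest",
]

_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Malformed persisted artifact."""


def write_partition_csv(path, part: BlockPartition) -> None:
    pd.DataFrame(
        {"vertex_id": np.arange(part.N), "block_id": part.assignment}
    ).to_csv(path, index=False)


def read_partition_csv(path) -> BlockPartition:
    df = _read_csv(path, {"vertex_id", "block_id"})
    df = df.sort_values("vertex_id")
    if not (df["vertex_id"].to_numpy() == np.arange(len(df))).all():
        raise FormatError(f"{path}: vertex_id must be 0..N-1 without gaps")
    return BlockPartition(assignment=df["block_id"].to_numpy())


def write_matrix_csv(path, m: np.ndarray) -> None:
    np.savetxt(path, np.asarray(m, dtype=float), delimiter=",", fmt=_FLOAT_FMT,
               header=",".join(str(i) for i in range(np.asarray(m).shape[1])),
               comments="")


def read_matrix_csv(path) -> np.ndarray:
    try:
        m = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    return m


def write_vector_csv(path, v: np.ndarray, name: str = "value") -> None:
    pd.DataFrame({"vertex_id": np.arange(len(v)), name: v}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_vector_csv(path, name: str = "value") -> np.ndarray:
    df = _read_csv(path, {"vertex_id", name})
    return df.sort_values("vertex_id")[name].to_numpy()


def write_edgelist_csv(path, g: nx.Graph) -> None:
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    df = pd.DataFrame(edges, columns=["u", "v"]) if edges else pd.DataFrame(
        columns=["u", "v"]
    )
    # vertices are 0..N-1 throughout the package
    n = 1 + max(g.nodes) if g.number_of_nodes() else 0
    header = f"# N={n}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_edgelist_csv(path) -> nx.Graph:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# N="):
            raise FormatError(f"{path}: line 1: missing '# N=' header")
        try:
            n = int(first.strip().split("=", 1)[1])
        except ValueError as e:
            raise FormatError(f"{path}: line 1: bad vertex count") from e
        df = pd.read_csv(fh)
    if set(df.columns) != {"u", "v"}:
        raise FormatError(f"{path}: expected columns u,v")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(df.itertuples(index=False, name=None))
    return g


def write_graphml(path, g: nx.Graph) -> None:
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path, node_type=int)
    return g


def write_yaml(path, obj: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        try:
            obj = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise FormatError(f"{path}: {e}") from e
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    return obj


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: {e}") from e


def write_constraints(outdir: Path, c: ConstraintSet) -> None:
    outdir = Path(outdir)
    write_matrix_csv(outdir / "K.csv", c.K)
    write_vector_csv(outdir / "k.csv", c.k, name="expected_degree")
    write_partition_csv(outdir / "partition.csv", c.part)


def write_delta(path, delta: MixingDensityMatrix) -> None:
    write_matrix_csv(path, delta.delta)


def read_delta(path) -> MixingDensityMatrix:
    return MixingDensityMatrix(delta=read_matrix_csv(path))


def _read_csv(path, required: set) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"{path}: {e}") from e
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
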