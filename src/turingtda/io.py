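"""CSV/HDF5/JSON serialisation of fields, diagrams, distance matrices and
cluster labels."""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .persistence import PersistenceDiagram
from .simulate import Field, build_grid

__all__ = [
    "write_fields_csv",
    "read_fields_csv",
    "write_fields_h5",
    "read_fields_h5",
    "diagrams_to_frame",
    "write_diagrams_csv",
    "read_diagrams_csv",
    "write_distance_csv",
    "read_distance_csv",
    "write_labels_csv",
]


def write_fields_csv(path, u: Field, v: Field) -> None:
    x, y = u.grid.coords()
    pd.DataFrame({"x": x, "y": y, "u": u.values, "v": v.values}).to_csv(
        path, index=False
    )


def read_fields_csv(path) -> tuple[Field, Field]:
    df = pd.read_csv(path)
    xs = np.unique(df["x"])
    ys = np.unique(df["y"])
    step = float(xs[1] - xs[0])
    grid = build_grid(float(xs[-1]), float(ys[-1]), step)
    df = df.sort_values(["y", "x"])
    return (
        Field(grid, df["u"].to_numpy(), "u"),
        Field(grid, df["v"].to_numpy(), "v"),
    )


def write_fields_h5(path, u: Field, v: Field, attrs: Mapping | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=u.as_grid())
        f.create_dataset("v", data=v.as_grid())
        g = u.grid
        f.attrs["Lx"], f.attrs["Ly"], f.attrs["stepsize"] = g.Lx, g.Ly, g.stepsize
        for k, val in (attrs or {}).items():
            f.attrs[k] = val


def read_fields_h5(path) -> tuple[Field, Field, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        grid = build_grid(
            float(f.attrs["Lx"]), float(f.attrs["Ly"]), float(f.attrs["stepsize"])
        )
        u = Field(grid, f["u"][()].ravel(), "u")
        v = Field(grid, f["v"][()].ravel(), "v")
        attrs = {k: f.attrs[k] for k in f.attrs}
    return u, v, attrs


def diagrams_to_frame(
    rows: Iterable[tuple[int, str, str, PersistenceDiagram]]
) -> pd.DataFrame:
    """Rows of (node_id, species, direction, diagram) to a long table;
    death is the string "inf" for essential bars."""
    records = []
    for node_id, species, direction, diag in rows:
        for b, d in diag.pairs:
            records.append(
                {
                    "node_id": node_id,
                    "species": species,
                    "direction": direction,
                    "degree": diag.degree,
                    "birth_level": b,
                    "death_level": "inf" if math.isinf(d) else d,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "node_id",
            "species",
            "direction",
            "degree",
            "birth_level",
            "death_level",
        ],
    )


def write_diagrams_csv(path, rows) -> None:
    diagrams_to_frame(rows).to_csv(path, index=False)


def read_diagrams_csv(path) -> dict[tuple[int, str, int], PersistenceDiagram]:
    """Inverse of write_diagrams_csv, keyed by (node_id, species, degree)."""
    df = pd.read_csv(path)
    out: dict[tuple[int, str, int], list] = {}
    for _, r in df.iterrows():
        d = math.inf if str(r["death_level"]) == "inf" else float(r["death_level"])
        out.setdefault(
            (int(r["node_id"]), str(r["species"]), int(r["degree"])), []
        ).append((float(r["birth_level"]), d))
    return {
        k: PersistenceDiagram(degree=k[2], pairs=tuple(v)) for k, v in out.items()
    }


def write_distance_csv(path, matrix: np.ndarray, node_ids=None) -> None:
    n = matrix.shape[0]
    ids = list(node_ids) if node_ids is not None else list(range(n))
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path)


def read_distance_csv(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy()


def write_labels_csv(path, node_ids, labels, params=None) -> None:
    data = {"node_id": list(node_ids), "cluster": list(labels)}
    if params is not None:
        for key in ("alpha", "beta", "sigma", "delta"):
            data[key] = [getattr(p, key) for p in params]
    pd.DataFrame(data).to_csv(path, index=False)
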