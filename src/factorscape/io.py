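"""Delimited-text readers and writers shared across the pipeline.

Everything on disk is plain TSV with a header row, plus small JSON sidecars
describing provenance (matrix kind, estimator, seeds).  Floats are written
with a fixed ``%.12g`` format so that reruns with identical seeds produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import SimilarityMatrix
from .mind import VertexFeatureTable
from .synthetic import ReceptorAtlas, SpherePoints

FLOAT_FMT = "%.12g"


def write_matrix(sm: SimilarityMatrix, path, sidecar: dict | None = None) -> None:
    """Write an R x R matrix as TSV (header = region labels) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(sm.values, columns=sm.labels)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {"kind": sm.kind, "n_regions": sm.n_regions}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def read_matrix(path, kind: str | None = None) -> SimilarityMatrix:
    """Read a matrix written by :func:`write_matrix` (kind from sidecar if present)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    if kind is None:
        if sidecar.exists():
            kind = json.loads(sidecar.read_text())["kind"]
        else:
            kind = "signed"
    return SimilarityMatrix(df.to_numpy(dtype=float), kind, list(df.columns))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vertex_features(table: VertexFeatureTable, path) -> None:
    """Long-format features: columns region, vertex_id, then one per feature."""
    rows = []
    for region in table.regions:
        arr = table.data[region]
        frame = pd.DataFrame(arr, columns=table.features)
        frame.insert(0, "vertex_id", np.arange(arr.shape[0]))
        frame.insert(0, "region", region)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_vertex_features(path) -> VertexFeatureTable:
    df = pd.read_csv(path, sep="\t")
    features = [c for c in df.columns if c not in ("region", "vertex_id")]
    regions = list(dict.fromkeys(df["region"]))  # preserve file order
    data = {
        r: df.loc[df["region"] == r, features].to_numpy(dtype=float) for r in regions
    }
    return VertexFeatureTable(regions=regions, features=features, data=data)


def write_timeseries(ts: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(ts, columns=labels).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_sphere(sphere: SpherePoints, path, labels: list[str] | None = None) -> None:
    write_table(sphere.to_frame(labels), path)


def read_sphere(path) -> SpherePoints:
    df = read_table(path)
    return SpherePoints(
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=df["hemisphere"].to_numpy(),
    )


def write_receptor_atlas(atlas: ReceptorAtlas, densities_path, sphere_path) -> None:
    df = pd.DataFrame(atlas.densities, columns=atlas.names)
    df.insert(0, "region", [f"region_{i:03d}" for i in range(atlas.n_regions)])
    write_table(df, densities_path)
    write_sphere(atlas.sphere, sphere_path)


def read_receptor_atlas(densities_path, sphere_path) -> ReceptorAtlas:
    df = read_table(densities_path)
    names = [c for c in df.columns if c != "region"]
    return ReceptorAtlas(
        densities=df[names].to_numpy(dtype=float),
        names=names,
        sphere=read_sphere(sphere_path),
    )


def write_loadings(loadings: np.ndarray, path, subject_ids: list[str] | None = None) -> None:
    n, k = loadings.shape
    df = pd.DataFrame(loadings, columns=[f"factor_{i + 1}" for i in range(k)])
    df.insert(0, "subject", subject_ids or [f"sub_{i:04d}" for i in range(n)])
    write_table(df, path)


def read_loadings(path) -> tuple[np.ndarray, list[str]]:
    df = read_table(path)
    cols = [c for c in df.columns if c != "subject"]
    return df[cols].to_numpy(dtype=float), list(df["subject"])
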