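"""File formats: rasters as sparse columnar text, networks as GraphML/edge
lists, traces and movies as HDF5/TIFF."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "save_raster_txt",
    "load_raster_txt",
    "save_network",
    "save_traces_h5",
    "load_traces_h5",
    "save_movie_tiff",
    "load_movie_tiff",
]


def save_raster_txt(path, raster: np.ndarray, frame_rate: float = 20.0) -> None:
    """Sparse (neuron_id, frame) text export with a shape header."""
    raster = np.atleast_2d(raster).astype(bool)
    n, T = raster.shape
    rows, cols = np.nonzero(raster)
    with open(path, "w") as fh:
        fh.write(f"# neurons={n} frames={T} frame_rate={frame_rate}\n")
        fh.write("neuron_id\tframe\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\n")


def load_raster_txt(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline()
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    n, T = int(meta["neurons"]), int(meta["frames"])
    fr = float(meta.get("frame_rate", 20.0))
    data = np.loadtxt(path, skiprows=2, dtype=np.int64, ndmin=2)
    raster = np.zeros((n, T), dtype=bool)
    if data.size:
        raster[data[:, 0], data[:, 1]] = True
    return raster, fr


def save_network(path_prefix, adjacency: np.ndarray, scores=None, status=None) -> None:
    """Adjacency as GraphML + edge-list text, with a JSON status sidecar."""
    import networkx as nx

    prefix = Path(path_prefix)
    G = nx.from_numpy_array(np.atleast_2d(adjacency).astype(int),
                            create_using=nx.DiGraph)
    nx.write_graphml(G, prefix.with_suffix(".graphml"))
    with open(prefix.with_suffix(".edges.txt"), "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in G.edges():
            fh.write(f"{u}\t{v}\n")
    if status is not None:
        with open(prefix.with_suffix(".status.json"), "w") as fh:
            json.dump(status, fh, indent=1)
    if scores is not None:
        import h5py

        with h5py.File(prefix.with_suffix(".scores.h5"), "w") as fh:
            fh.create_dataset("gte_scores", data=np.asarray(scores))


def save_traces_h5(path, traces: np.ndarray, frame_rate: float, name="traces") -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(name, data=np.asarray(traces))
        ds.attrs["frame_rate"] = frame_rate


def load_traces_h5(path, name="traces") -> tuple[np.ndarray, float]:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh[name]
        return ds[...], float(ds.attrs.get("frame_rate", 20.0))


def save_movie_tiff(path, movie: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(movie))


def load_movie_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
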