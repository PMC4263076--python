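"""Readers and writers for the package's on-disk formats.

Matrices travel as delimited text (CSV/TSV chosen by extension) or as HDF5
containers; trajectories and pattern ensembles are HDF5 (int8 state
matrices) with their run metadata stored as a JSON string attribute, so a
file is self-describing without a sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import TimeCourses
from .repertoire import ClusterResult, PatternEnsemble
from .spinglass import SimulationConfig, Trajectory

__all__ = [
    "load_matrix", "save_matrix",
    "load_timecourses", "save_timecourses",
    "load_trajectory", "save_trajectory",
    "load_patterns", "save_patterns",
    "save_cluster_report",
]

_TEXT_SUFFIXES = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _sep_for(path: Path) -> str | None:
    return _TEXT_SUFFIXES.get(path.suffix.lower())


def save_matrix(M: np.ndarray, path: str | Path, dataset: str = "matrix") -> None:
    path = Path(path)
    sep = _sep_for(path)
    if sep is not None:
        pd.DataFrame(np.asarray(M)).to_csv(path, sep=sep, index=False, header=False)
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=np.asarray(M))


def load_matrix(path: str | Path, dataset: str = "matrix") -> np.ndarray:
    path = Path(path)
    sep = _sep_for(path)
    if sep is not None:
        return pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
    with h5py.File(path, "r") as f:
        return f[dataset][()]


def save_timecourses(tc: TimeCourses, path: str | Path) -> None:
    """HDF5 container with datasets data/site_ids/coordinates, or delimited
    text with site ids as the first column (sites x timepoints)."""
    path = Path(path)
    sep = _sep_for(path)
    if sep is not None:
        df = pd.DataFrame(tc.data, index=tc.site_ids)
        df.to_csv(path, sep=sep, index_label="site_id")
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=tc.data)
            f.create_dataset("site_ids", data=np.array(tc.site_ids, dtype="S"))
            if tc.coordinates is not None:
                f.create_dataset("coordinates", data=tc.coordinates)


def load_timecourses(path: str | Path) -> TimeCourses:
    path = Path(path)
    sep = _sep_for(path)
    if sep is not None:
        df = pd.read_csv(path, sep=sep, index_col=0)
        return TimeCourses(data=df.to_numpy(dtype=float), site_ids=df.index.astype(str))
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        site_ids = [s.decode() for s in f["site_ids"][()]] if "site_ids" in f else None
        coords = f["coordinates"][()] if "coordinates" in f else None
    return TimeCourses(data=data, site_ids=site_ids, coordinates=coords)


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("states", data=traj.states, compression="gzip")
        f.create_dataset("sweep_index", data=traj.sweep_index)
        if traj.flips_per_sweep is not None:
            f.create_dataset("flips_per_sweep", data=traj.flips_per_sweep)
        f.attrs["config"] = json.dumps(asdict(traj.config))
        f.attrs["graph_hash"] = traj.graph_hash


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        cfg = SimulationConfig(**json.loads(f.attrs["config"]))
        flips = f["flips_per_sweep"][()] if "flips_per_sweep" in f else None
        return Trajectory(
            states=f["states"][()],
            sweep_index=f["sweep_index"][()],
            config=cfg,
            graph_hash=str(f.attrs.get("graph_hash", "")),
            flips_per_sweep=flips,
        )


def save_patterns(ensemble: PatternEnsemble, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("patterns", data=ensemble.patterns, compression="gzip")
        f.create_dataset("converged", data=ensemble.converged)
        if ensemble.seeds is not None:
            f.create_dataset("seeds", data=np.asarray(ensemble.seeds))


def load_patterns(path: str | Path) -> PatternEnsemble:
    with h5py.File(path, "r") as f:
        return PatternEnsemble(
            patterns=f["patterns"][()],
            converged=f["converged"][()] if "converged" in f else None,
            seeds=f["seeds"][()] if "seeds" in f else None,
        )


def save_cluster_report(result: ClusterResult, prefix: str | Path) -> None:
    """TSV table (cluster id, size, frequency) plus the centroid matrix."""
    prefix = Path(prefix)
    m = result.labels.size
    sizes = np.round(result.frequencies * m).astype(int)
    pd.DataFrame({
        "cluster": np.arange(result.n_clusters),
        "size": sizes,
        "frequency": result.frequencies,
    }).to_csv(prefix.with_suffix(".clusters.tsv"), sep="\t", index=False)
    save_matrix(result.centroids, prefix.with_suffix(".centroids.csv"))
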