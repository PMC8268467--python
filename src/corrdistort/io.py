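"""Reading and writing OTU tables (TSV/CSV/BIOM) and run configuration.

TSV/CSV tables are sample-major: header row of feature ids, first column of
sample ids.  BIOM tables (both the JSON dialect and the HDF5 2.x layout) are
observation-major on disk and are transposed to sample-major on read; the
HDF5 layout is read directly through h5py (CSR over observations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pretreat import CountTable

__all__ = ["RunConfig", "read_otu_table", "write_otu_table", "resolve_config"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved run-time settings for the whole pipeline."""

    alpha: float = 0.05
    delta_n: int = 1
    n_max: int | str = "auto"
    epsilon: float = 1e-12
    closure_k: float = 100.0
    compositional: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not isinstance(self.delta_n, int) or self.delta_n < 1:
            raise ValueError("delta_n must be a positive integer")
        if self.n_max != "auto" and (not isinstance(self.n_max, int) or self.n_max < 2):
            raise ValueError("n_max must be 'auto' or an integer >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.closure_k <= 0:
            raise ValueError("closure_k must be positive")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError("log_level must be DEBUG/INFO/WARNING/ERROR")


def resolve_config(config_file: str | Path | None = None, **overrides) -> RunConfig:
    """Merge defaults, an optional YAML file, and keyword overrides (flags win)."""
    values: dict = {}
    if config_file is not None:
        with open(config_file, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def _table_from_frame(frame: pd.DataFrame, group_label: str, source: str) -> CountTable:
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in {source}: {dupes}")
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids in {source}: {dupes}")
    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count in {source} at sample {frame.index[i]!r}, feature {frame.columns[j]!r}"
        )
    return CountTable(
        values,
        sample_ids=[str(s) for s in frame.index],
        feature_ids=[str(f) for f in frame.columns],
        group_label=group_label,
    )


def _read_biom_json(path: Path, group_label: str) -> CountTable:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    obs_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    shape = tuple(doc["shape"])  # (observations, samples)
    dense = np.zeros(shape)
    if doc.get("matrix_type") == "dense":
        dense = np.asarray(doc["data"], dtype=float)
    else:
        for r, c, v in doc["data"]:
            dense[int(r), int(c)] = v
    return CountTable(dense.T, sample_ids=sample_ids, feature_ids=obs_ids, group_label=group_label)


def _read_biom_hdf5(path: Path, group_label: str) -> CountTable:
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as fh:
        obs_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["observation/ids"][:]]
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    return CountTable(
        mat.toarray().T, sample_ids=sample_ids, feature_ids=obs_ids, group_label=group_label
    )


def read_otu_table(path: str | Path, fmt: str | None = None, group_label: str = "unlabeled") -> CountTable:
    """Read an OTU count table from TSV, CSV or BIOM into sample-major form.

    ``fmt`` is inferred from the suffix when omitted.  BIOM files may be the
    JSON dialect or the HDF5 layout; both are detected automatically.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".biom": "biom"}.get(
            path.suffix.lower(), "tsv"
        )
    if fmt in ("tsv", "csv"):
        frame = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        return _table_from_frame(frame, group_label, str(path))
    if fmt == "biom":
        with open(path, "rb") as fh:
            magic = fh.read(8)
        if magic.startswith(b"\x89HDF"):
            return _read_biom_hdf5(path, group_label)
        return _read_biom_json(path, group_label)
    raise ValueError(f"unknown table format: {fmt!r}")


def write_otu_table(table: CountTable, path: str | Path, fmt: str = "tsv") -> None:
    """Write a table (or any labeled matrix) as sample-major TSV/CSV."""
    frame = pd.DataFrame(table.values, index=table.sample_ids, columns=table.feature_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t" if fmt == "tsv" else ",")


def write_matrix_tsv(values: np.ndarray, sample_ids, feature_ids, path: str | Path) -> None:
    frame = pd.DataFrame(np.asarray(values), index=list(sample_ids), columns=list(feature_ids))
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")
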