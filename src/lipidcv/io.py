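"""CSV/TSV input-output with validation and provenance headers.

The on-disk schema is three CSVs: the lipid matrix (rows = samples,
first column ``sample_id``, one column per species), the species-to-class
map (``species_id,class_name``) and the sample metadata (snake_case
clinical variable names). Output files start with ``#`` comment lines
recording tool version, config hash and seed, and are read back with
those lines skipped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GROUPS, BINARY_COVARIATES, LipidMatrix, validate_sample_table

__all__ = [
    "config_hash",
    "provenance_header",
    "read_lipid_matrix",
    "write_lipid_matrix",
    "read_metadata",
    "write_metadata",
    "write_table",
    "check_alignment",
]


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a JSON-serialisable config mapping."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None = None, cfg_hash: str = "") -> str:
    parts = [f"lipidcv v{__version__}"]
    if cfg_hash:
        parts.append(f"config_hash={cfg_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def _write_frame(frame: pd.DataFrame, path: Path, sep: str, header: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, sep=sep, lineterminator="\n")


def write_lipid_matrix(
    matrix: LipidMatrix,
    matrix_csv: str | Path,
    classmap_csv: str | Path,
    seed: int | None = None,
    cfg_hash: str = "",
) -> None:
    header = provenance_header(seed, cfg_hash) + f" scale={matrix.scale}"
    _write_frame(matrix.data, Path(matrix_csv), ",", header)
    cmap = pd.DataFrame(
        {"class_name": [matrix.class_map[s] for s in matrix.species_ids]},
        index=pd.Index(matrix.species_ids, name="species_id"),
    )
    _write_frame(cmap, Path(classmap_csv), ",", header)


def read_lipid_matrix(
    matrix_csv: str | Path, classmap_csv: str | Path, scale: str | None = None
) -> LipidMatrix:
    """Read and validate a lipid matrix plus its species-to-class map.

    ``scale`` overrides the scale recorded in the matrix header comment
    (``raw`` assumed when neither is available).
    """
    if scale is None:
        scale = "raw"
        with open(matrix_csv) as fh:
            first = fh.readline()
        if first.startswith("#") and "scale=" in first:
            scale = first.rsplit("scale=", 1)[1].strip()
    data = pd.read_csv(matrix_csv, comment="#", index_col=0)
    data.index = data.index.astype(str)
    if data.index.has_duplicates:
        dupes = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id in {matrix_csv}: {dupes}")
    cmap_frame = pd.read_csv(classmap_csv, comment="#")
    if not {"species_id", "class_name"} <= set(cmap_frame.columns):
        raise ValueError(f"{classmap_csv} must have columns species_id,class_name")
    class_map = dict(zip(cmap_frame["species_id"].astype(str), cmap_frame["class_name"].astype(str)))
    missing = [s for s in data.columns if s not in class_map]
    if missing:
        raise ValueError(f"species lacking a class in {classmap_csv}: {missing}")
    values = data.to_numpy(dtype=float)
    bad = ~np.isfinite(values) if scale == "log10" else (~np.isfinite(values) | (values < 0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid value {values[i, j]!r} at sample {data.index[i]!r}, "
            f"species {data.columns[j]!r} in {matrix_csv}"
        )
    return LipidMatrix(data, class_map, scale=scale)


def write_metadata(
    samples: pd.DataFrame, metadata_csv: str | Path, seed: int | None = None, cfg_hash: str = ""
) -> None:
    _write_frame(samples, Path(metadata_csv), ",", provenance_header(seed, cfg_hash))


def read_metadata(metadata_csv: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata table."""
    samples = pd.read_csv(metadata_csv, comment="#", index_col=0)
    samples.index = samples.index.astype(str)
    if samples.index.has_duplicates:
        dupes = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id in {metadata_csv}: {dupes}")
    if "group" not in samples.columns:
        raise ValueError(f"{metadata_csv} must have a 'group' column")
    bad_groups = sorted(set(samples["group"]) - set(GROUPS))
    if bad_groups:
        raise ValueError(f"unknown group labels in {metadata_csv}: {bad_groups}")
    for col in BINARY_COVARIATES:
        if col in samples.columns:
            bad = ~samples[col].isin([0, 1])
            if bad.any():
                pos = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"binary column {col!r} has value {samples[col].iloc[pos]!r} "
                    f"at row {pos + 1} ({samples.index[pos]!r}) in {metadata_csv}"
                )
    return validate_sample_table(samples)


def check_alignment(matrix: LipidMatrix, samples: pd.DataFrame) -> None:
    """Require a 1:1 sample correspondence between matrix and metadata."""
    m = set(matrix.sample_ids)
    s = set(samples.index)
    only_m = sorted(m - s)
    only_s = sorted(s - m)
    if only_m or only_s:
        raise ValueError(
            "matrix/metadata sample mismatch; "
            f"matrix-only ids: {only_m}; metadata-only ids: {only_s}"
        )


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str = "",
    index: bool = False,
) -> None:
    """Write a result table as TSV with a provenance header comment."""
    with open(path, "w", newline="") as fh:
        fh.write(provenance_header(seed, cfg_hash) + "\n")
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")
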