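"""Readers, writers and model serialization.

Matrices are plain TSV/CSV: first column feature names, header row sample
ids, numeric body.  Metadata is a TSV/CSV with required columns
``sample_id``, ``individual_id``, ``time`` (extra columns are preserved but
ignored).  Gene sets use standard GMT.  Models are versioned JSON — not a
pickle — so archives stay portable across languages and library versions.

All tables are written with 17 significant digits so that write -> read
round-trips are exact for float64.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .align import ConsensusTrajectory, TrajectoryModel
from .core import LongitudinalDataset, SampleRecord, StandardizationParams
from .seed import SeedSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "dataset_from_files",
    "read_gmt",
    "save_model",
    "load_model",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = "1.0"
FLOAT_FORMAT = "%.17g"
REQUIRED_META_COLUMNS = ("sample_id", "individual_id", "time")


def _sep_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(
    path: str | Path, delimiter: str | None = None
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a feature x sample table -> (feature_names, sample_ids, values).

    Dialect follows the extension (.csv -> comma, else tab) unless
    ``delimiter`` overrides it.  Ragged rows, non-numeric cells and
    duplicate labels are errors naming the offender.
    """
    sep = _sep_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature names in {path}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().to_numpy().any() and not df[col].isna().to_numpy().any():
                row = df.index[bad.isna() & ~df[col].isna()][0]
                raise ValueError(
                    f"non-numeric cell in {path} at feature {row!r}, sample {col!r}"
                ) from exc
        raise ValueError(f"non-numeric data in {path}: {exc}") from exc
    return df.index.astype(str).tolist(), df.columns.astype(str).tolist(), values


def write_matrix(
    path: str | Path,
    feature_names: list[str],
    sample_ids: list[str],
    values: np.ndarray,
    delimiter: str | None = None,
) -> None:
    sep = _sep_for(path, delimiter)
    df = pd.DataFrame(values, index=feature_names, columns=sample_ids)
    df.index.name = "feature"
    df.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path, delimiter: str | None = None) -> list[SampleRecord]:
    """Read sample metadata (sample_id, individual_id, time)."""
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"metadata {path} contains no samples")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                individual_id=str(row["individual_id"]),
                time=float(row["time"]),
            )
        )
    return records


def dataset_from_files(
    matrix_path: str | Path,
    metadata_path: str | Path,
    delimiter: str | None = None,
) -> LongitudinalDataset:
    """Assemble a dataset, aligning metadata rows to matrix columns.

    Samples present in only one of the two files are an error, reported as
    an explicit diff.
    """
    feature_names, sample_ids, values = read_matrix(matrix_path, delimiter)
    records = read_metadata(metadata_path, delimiter)
    by_id = {r.sample_id: r for r in records}
    if len(by_id) != len(records):
        seen: set[str] = set()
        dupes = [r.sample_id for r in records if r.sample_id in seen or seen.add(r.sample_id)]
        raise ValueError(f"duplicate sample_id in metadata: {sorted(set(dupes))}")
    only_matrix = [s for s in sample_ids if s not in by_id]
    only_meta = [s for s in by_id if s not in set(sample_ids)]
    if only_matrix or only_meta:
        raise ValueError(
            "matrix/metadata sample mismatch: "
            f"only in matrix {only_matrix}; only in metadata {only_meta}"
        )
    return LongitudinalDataset(
        feature_names=feature_names,
        samples=[by_id[s] for s in sample_ids],
        values=values,
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members; tab-separated).

    Duplicate set names are an error; duplicate members within a set are
    deduplicated (order kept) with a warning.
    """
    import warnings

    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} deduplicated",
                    stacklevel=2,
                )
            sets[name] = deduped
    return sets


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------


def save_model(model: TrajectoryModel, path: str | Path) -> None:
    """Serialize a fitted model to versioned JSON."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "seed": {
            "feature_names": model.seed.feature_names,
            "conservation_scores": _tolist(model.seed.conservation_scores),
            "trend_signs": model.seed.trend_signs.tolist(),
            "provenance": model.seed.provenance,
        },
        "standardization": {
            "feature_names": model.standardization.feature_names,
            "center": model.standardization.center.tolist(),
            "scale": model.standardization.scale.tolist(),
        },
        "ensemble": [
            {"points": c.points.tolist(), "weights": c.weights.tolist()}
            for c in model.ensemble
        ],
        "hyperparams": model.hyperparams,
        "rng_seed": model.rng_seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _tolist(arr: np.ndarray) -> list:
    # JSON has no NaN literal; store as None and restore on load
    return [None if (isinstance(x, float) and math.isnan(x)) else x
            for x in arr.tolist()]


def load_model(path: str | Path) -> TrajectoryModel:
    """Load a model archive; round-trips reproduce predictions bit-for-bit."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted model archive {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r} in {path} "
            f"(this build reads {MODEL_SCHEMA_VERSION})"
        )
    try:
        seed = SeedSet(
            feature_names=payload["seed"]["feature_names"],
            conservation_scores=np.array(
                [np.nan if x is None else x
                 for x in payload["seed"]["conservation_scores"]],
                dtype=float,
            ),
            trend_signs=np.array(payload["seed"]["trend_signs"], dtype=int),
            provenance=payload["seed"]["provenance"],
        )
        std = StandardizationParams(
            feature_names=payload["standardization"]["feature_names"],
            center=np.array(payload["standardization"]["center"], dtype=float),
            scale=np.array(payload["standardization"]["scale"], dtype=float),
        )
        ensemble = [
            ConsensusTrajectory(
                points=np.array(c["points"], dtype=float),
                weights=np.array(c["weights"], dtype=float),
            )
            for c in payload["ensemble"]
        ]
        return TrajectoryModel(
            seed=seed,
            standardization=std,
            ensemble=ensemble,
            hyperparams=payload["hyperparams"],
            rng_seed=payload["rng_seed"],
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"corrupted model archive {path}: {exc}") from exc
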