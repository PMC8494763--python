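"""Reading and writing the package's tidy CSV dialects.

Three file kinds are used throughout:

* stream CSV — one file per consultation, header ``frame_idx,aoi_hit,valid``
  with 0-based consecutive frame indices, binary AOI hits, and an optional
  validity column (default 1).  Filename convention ``<consultation_id>.csv``.
* cohort CSV — header ``consultation_id,physician_id,satisfaction``; one row
  per consultation, satisfaction on a 0–100 visual-analogue scale (may be
  empty).
* measures CSV — tidy one-row-per-consultation result tables, written by
  :func:`write_measures_table` and round-trippable through
  :func:`read_measures_table`.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import StreamParseError, StreamValidationError
from .stream import DEFAULT_FRAME_INTERVAL_S, GazeStream

__all__ = [
    "read_stream",
    "write_stream",
    "read_stream_dir",
    "read_cohort",
    "write_cohort",
    "write_measures_table",
    "read_measures_table",
]

STREAM_COLUMNS = ("frame_idx", "aoi_hit", "valid")
COHORT_COLUMNS = ("consultation_id", "physician_id", "satisfaction")


def _consultation_id_from_path(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]


def read_stream(
    path: str,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    consultation_id: str | None = None,
    physician_id: str = "",
) -> GazeStream:
    """Read one consultation's frame-coded gaze stream.

    The ``valid`` column is optional; missing means every frame is analysed.
    Raises :class:`StreamParseError` with a 1-based line number for malformed
    rows and :class:`StreamValidationError` for out-of-range values or an
    empty file.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise StreamValidationError(f"{path}: empty stream file") from None
    except pd.errors.ParserError as exc:
        raise StreamParseError(f"{path}: {exc}") from exc

    missing = [c for c in ("frame_idx", "aoi_hit") if c not in df.columns]
    if missing:
        raise StreamParseError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise StreamValidationError(f"{path}: stream file has no data rows")

    def _to_int(col: str, allowed: tuple[int, ...] | None) -> np.ndarray:
        raw = df[col].str.strip()
        ok = raw.str.fullmatch(r"-?\d+")
        if not ok.all():
            line = int(np.flatnonzero(~ok.to_numpy())[0]) + 2  # header is line 1
            raise StreamParseError(
                f"{path}: non-integer value {raw.iloc[line - 2]!r} in column "
                f"{col!r}", line=line
            )
        vals = raw.astype(np.int64).to_numpy()
        if allowed is not None and not np.isin(vals, allowed).all():
            bad = int(np.flatnonzero(~np.isin(vals, allowed))[0])
            raise StreamValidationError(
                f"{path}: value {vals[bad]} outside {set(allowed)} in column "
                f"{col!r} (line {bad + 2})"
            )
        return vals

    frame_idx = _to_int("frame_idx", None)
    expected = np.arange(len(df))
    if not np.array_equal(frame_idx, expected):
        bad = int(np.flatnonzero(frame_idx != expected)[0])
        raise StreamValidationError(
            f"{path}: frame_idx must be 0-based consecutive integers; "
            f"found {frame_idx[bad]} at line {bad + 2} (expected {bad})"
        )
    hits = _to_int("aoi_hit", (0, 1)).astype(bool)
    if "valid" in df.columns:
        valid = _to_int("valid", (0, 1)).astype(bool)
    else:
        valid = np.ones(len(df), dtype=bool)

    return GazeStream(
        consultation_id=consultation_id or _consultation_id_from_path(path),
        physician_id=physician_id,
        hits=hits,
        valid=valid,
        frame_interval_s=frame_interval_s,
    )


def write_stream(stream: GazeStream, path: str) -> None:
    """Write a stream in the ``frame_idx,aoi_hit,valid`` dialect."""
    df = pd.DataFrame(
        {
            "frame_idx": np.arange(stream.n_frames),
            "aoi_hit": stream.hits.astype(np.int8),
            "valid": stream.valid.astype(np.int8),
        }
    )
    df.to_csv(path, index=False)


def read_stream_dir(
    directory: str,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    cohort: pd.DataFrame | None = None,
) -> list[GazeStream]:
    """Read every ``*.csv`` stream in a directory (skipping ``cohort.csv``).

    When a cohort table is given, each stream's physician id is filled in
    from it and unknown consultation ids raise a validation error.
    """
    phys = {}
    if cohort is not None:
        phys = dict(zip(cohort["consultation_id"], cohort["physician_id"]))
    streams = []
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".csv") or name == "cohort.csv":
            continue
        cid = os.path.splitext(name)[0]
        if cohort is not None and cid not in phys:
            raise StreamValidationError(
                f"stream {cid!r} has no row in the cohort table"
            )
        streams.append(
            read_stream(
                os.path.join(directory, name),
                frame_interval_s=frame_interval_s,
                consultation_id=cid,
                physician_id=phys.get(cid, ""),
            )
        )
    return streams


def read_cohort(path: str) -> pd.DataFrame:
    """Read the cohort metadata table.

    Satisfaction values must lie in [0, 100] or be missing; consultation ids
    must be unique.
    """
    df = pd.read_csv(path, dtype={"consultation_id": str, "physician_id": str})
    missing = [c for c in ("consultation_id", "physician_id") if c not in df.columns]
    if missing:
        raise StreamParseError(f"{path}: missing cohort column(s) {missing}")
    if df["consultation_id"].duplicated().any():
        dup = df.loc[df["consultation_id"].duplicated(), "consultation_id"].iloc[0]
        raise StreamValidationError(f"{path}: duplicate consultation_id {dup!r}")
    if "satisfaction" in df.columns:
        sat = pd.to_numeric(df["satisfaction"], errors="coerce")
        given = df["satisfaction"].notna() & (df["satisfaction"].astype(str) != "")
        bad = given & (sat.isna() | (sat < 0) | (sat > 100))
        if bad.any():
            raise StreamValidationError(
                f"{path}: satisfaction outside [0, 100] at line "
                f"{int(np.flatnonzero(bad.to_numpy())[0]) + 2}"
            )
        df["satisfaction"] = sat
    else:
        df["satisfaction"] = np.nan
    return df


def write_cohort(cohort: pd.DataFrame, path: str) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    extra = [c for c in cohort.columns if c not in cols]
    cohort[cols + extra].to_csv(path, index=False)


def write_measures_table(
    records: Iterable[Mapping[str, object]] | pd.DataFrame, path: str
) -> None:
    """Write per-consultation results as a tidy CSV.

    All records must share one field set; an empty collection yields a
    header-only file when fields can be inferred, otherwise an empty file.
    """
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False)
        return
    records = list(records)
    if not records:
        # no schema to infer; write the canonical minimal header
        with open(path, "w") as fh:
            fh.write("consultation_id\n")
        return
    fields: Sequence[str] = list(records[0].keys())
    for i, rec in enumerate(records):
        if list(rec.keys()) != list(fields):
            raise StreamValidationError(
                f"record {i} fields {list(rec.keys())} differ from first "
                f"record's {list(fields)}"
            )
    pd.DataFrame.from_records(records, columns=fields).to_csv(path, index=False)


def read_measures_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "consultation_id" in df.columns:
        df["consultation_id"] = df["consultation_id"].astype(str)
    if "physician_id" in df.columns:
        df["physician_id"] = df["physician_id"].astype(str)
    return df
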