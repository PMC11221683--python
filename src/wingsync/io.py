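"""CSV input/output for recordings, phenotype-count tables and intensity tables.

Recordings travel as two-column CSV (left, right), one row per sample,
matching the rig's native export; the sampling rate is never inferred from
the data — it is supplied by the caller or read from a small YAML sidecar
written next to the CSV.  Count and intensity tables are tidy CSV with one
row per record; their invariants (class counts not exceeding the total,
finite intensities) are validated on load and the offending record named.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import IntensitySample, PhenotypeCount, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_counts",
    "read_intensities",
    "write_table",
    "sidecar_path",
]

_COUNT_FIELDS = ["image_id", "n_ruptured", "n_frayed", "n_enlarged", "n_total"]
_INTENSITY_FIELDS = ["disc_id", "disc_class", "genotype", "mean_gray"]


def sidecar_path(path: str | Path) -> Path:
    """Path of the YAML metadata sidecar for a recording CSV."""
    path = Path(path)
    return path.with_name(path.name + ".meta.yaml")


def write_recording(recording: Recording, path: str | Path,
                    write_sidecar: bool = True) -> Path:
    """Write a recording as two-column CSV with a ``left,right`` header.

    The sampling rate and any scalar metadata go to a YAML sidecar
    (``<name>.meta.yaml``) unless ``write_sidecar`` is false.
    """
    path = Path(path)
    df = pd.DataFrame({"left": recording.left, "right": recording.right})
    df.to_csv(path, index=False)
    if write_sidecar:
        meta = {k: v for k, v in recording.meta.items()
                if isinstance(v, (str, int, float, bool))}
        payload = {"fs_hz": float(recording.fs_hz), "meta": meta}
        sidecar_path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_recording(path: str | Path, fs_hz: float | None = None) -> Recording:
    """Read a two-column recording CSV.

    Parameters
    ----------
    path
        CSV with exactly two value columns (left, right), one row per
        sample.  A single header line is auto-detected: if the first row
        is non-numeric it is treated as the header.
    fs_hz
        Sampling rate in Hz.  If omitted, the YAML sidecar written by
        :func:`write_recording` must exist.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        Empty file, wrong column count (the count is named), non-numeric
        data rows (the first bad row index is named), or no sampling rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True,
                      comment="#")
    if raw.empty:
        raise ValueError(f"{path}: empty recording file")
    if raw.shape[1] != 2:
        raise ValueError(
            f"{path}: expected exactly 2 columns (left, right), found {raw.shape[1]}"
        )
    first_numeric = raw.iloc[0].map(_is_number).all()
    body = raw if first_numeric else raw.iloc[1:]
    if body.empty:
        raise ValueError(f"{path}: no data rows")
    values = body.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        # report the 1-based file row, accounting for a skipped header
        row = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: non-numeric value in row {row}")

    if fs_hz is None:
        sidecar = sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"{path}: sampling rate not given and sidecar {sidecar.name} not found"
            )
        payload = yaml.safe_load(sidecar.read_text())
        fs_hz = float(payload["fs_hz"])
        meta = dict(payload.get("meta", {}))
    else:
        meta = {}
    meta.setdefault("source", str(path))
    left = values.iloc[:, 0].to_numpy()
    right = values.iloc[:, 1].to_numpy()
    if np.allclose(left, np.round(left)) and np.allclose(right, np.round(right)):
        left = left.astype(np.int64)
        right = right.astype(np.int64)
    return Recording(fs_hz=float(fs_hz), left=left, right=right, meta=meta)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def write_table(records: Sequence, path: str | Path) -> Path:
    """Write phenotype counts or intensity samples as tidy CSV."""
    path = Path(path)
    rows = [dataclasses.asdict(r) for r in records]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=_COUNT_FIELDS)
    df.to_csv(path, index=False)
    return path


def read_counts(path: str | Path) -> list[PhenotypeCount]:
    """Read a phenotype-count table, validating each record.

    A class count exceeding its image total raises ``ValueError`` naming
    the image.  An empty table yields an empty list.
    """
    df = _read_table(path, _COUNT_FIELDS)
    records = []
    for row in df.itertuples(index=False):
        records.append(PhenotypeCount(
            image_id=str(row.image_id),
            n_ruptured=int(row.n_ruptured),
            n_frayed=int(row.n_frayed),
            n_enlarged=int(row.n_enlarged),
            n_total=int(row.n_total),
        ))
    return records


def read_intensities(path: str | Path) -> list[IntensitySample]:
    """Read an intensity table, validating each record."""
    df = _read_table(path, _INTENSITY_FIELDS)
    return [
        IntensitySample(
            disc_id=str(row.disc_id),
            disc_class=str(row.disc_class),
            genotype=str(row.genotype),
            mean_gray=float(row.mean_gray),
        )
        for row in df.itertuples(index=False)
    ]


def _read_table(path: str | Path, fields: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(fields) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[fields]
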