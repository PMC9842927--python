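"""Readers and writers for the TSV artifact formats.

Matrices and timeseries are labeled TSV; a ``<file>.json`` sidecar
carries metadata that the TSV body cannot (kind, lag, sampling interval,
provenance).  All numeric output uses ``repr``-precision floats and a
locale-independent decimal point.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BoldTimeseries, ConnectivityMatrix, Parcellation
from .errors import MatrixFormatError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_parcellation",
    "write_parcellation",
]

_FMT = "%.17g"


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_matrix(m: ConnectivityMatrix, path) -> None:
    """Write a labeled square TSV plus a JSON sidecar (kind, tau)."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join([""] + m.region_ids) + "\n")
        for label, row in zip(m.region_ids, m.values):
            fh.write(label + "\t" + "\t".join(_FMT % v for v in row) + "\n")
    _sidecar(path).write_text(json.dumps({"kind": m.kind, "tau": m.tau}, indent=1))


def _parse_labeled_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_labels = header[1:]
    width = len(header)
    row_labels, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != width:
            raise MatrixFormatError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {width}"
            )
        row_labels.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    return col_labels, row_labels, np.asarray(rows, dtype=float)


def read_matrix(
    path,
    kind: str | None = None,
    tau: float | None = None,
    regions: list[str] | None = None,
) -> ConnectivityMatrix:
    """Read a labeled square TSV matrix.

    ``kind``/``tau`` override the sidecar when given.  ``regions``
    requests a consistent row/column permutation on read.
    """
    col_labels, row_labels, values = _parse_labeled_tsv(path)
    if col_labels != row_labels:
        raise MatrixFormatError(f"{path}: header labels do not match row labels")
    if values.shape[0] != values.shape[1]:
        raise MatrixFormatError(f"{path}: matrix body is not square")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    kind = kind or meta.get("kind", "FC")
    tau = tau if tau is not None else float(meta.get("tau", 0.0))
    if kind == "EC":
        np.fill_diagonal(values, 0.0)  # self-coupling is dropped at load time
    m = ConnectivityMatrix(values, kind=kind, region_ids=row_labels, tau=tau)
    if regions is not None:
        m = m.reorder(regions)
    return m


def write_timeseries(ts: BoldTimeseries, path, extra_meta: dict | None = None) -> None:
    """Write a region-by-time TSV plus a sidecar with tr and provenance."""
    path = Path(path)
    n_t = ts.n_timepoints
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(["region"] + [f"t{k}" for k in range(n_t)]) + "\n")
        for label, row in zip(ts.region_ids, ts.data):
            fh.write(label + "\t" + "\t".join(_FMT % v for v in row) + "\n")
    meta = {"tr": ts.tr, "subject_id": ts.subject_id, "session_id": ts.session_id}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_timeseries(path, expected_regions: list[str] | None = None) -> BoldTimeseries:
    """Read a region-by-time TSV; the sidecar must provide ``tr``."""
    side = _sidecar(path)
    if not side.exists():
        raise MatrixFormatError(f"{path}: missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    if "tr" not in meta or meta["tr"] is None:
        raise MatrixFormatError(f"{side}: metadata is missing 'tr'")
    _, row_labels, values = _parse_labeled_tsv(path)
    if expected_regions is not None and row_labels != list(expected_regions):
        raise MatrixFormatError(
            f"{path}: region labels do not match the expected parcellation "
            f"({len(row_labels)} vs {len(expected_regions)} regions)"
        )
    return BoldTimeseries(
        data=values,
        tr=float(meta["tr"]),
        region_ids=row_labels,
        subject_id=meta.get("subject_id"),
        session_id=meta.get("session_id"),
    )


def write_parcellation(parc: Parcellation, path) -> None:
    pd.DataFrame(
        {
            "region_id": parc.region_ids,
            "name": parc.names,
            "hemisphere": parc.hemisphere,
            "group": parc.group,
        }
    ).to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region_id", "name", "hemisphere", "group"}
    if not required.issubset(df.columns):
        raise MatrixFormatError(f"{path}: parcellation needs columns {sorted(required)}")
    return Parcellation(
        region_ids=df["region_id"].tolist(),
        names=df["name"].tolist(),
        hemisphere=df["hemisphere"].tolist(),
        group=df["group"].tolist(),
    )
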