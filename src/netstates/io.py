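"""Plain-text matrix container with a JSON sidecar header.

A matrix lives in a tab-delimited ``.tsv`` file (one row per line, ``%.17g``
so values round-trip bitwise through text) next to a ``.json`` sidecar of the
same stem carrying at least the sampling rate ``fs`` and the channel count.
No binary formats are used anywhere in the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_matrix", "read_matrix"]

_REQUIRED_HEADER = ("fs", "n_channels")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    fs: float,
    channel_names: list[str] | None = None,
    **extra,
) -> Path:
    """Write a 2-D matrix as TSV plus a JSON header.

    ``extra`` keys (group label, seed, axis convention, ...) are stored
    verbatim in the sidecar.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    header = {
        "fs": float(fs),
        "n_channels": int(values.shape[1]),
        "n_rows": int(values.shape[0]),
    }
    if channel_names is not None:
        if len(channel_names) != values.shape[1]:
            raise ValueError("channel_names length does not match column count")
        header["channel_names"] = list(channel_names)
    header.update(extra)
    np.savetxt(path, values, fmt="%.17g", delimiter="\t")
    _sidecar(path).write_text(json.dumps(header, indent=1, sort_keys=True))
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a matrix written by :func:`write_matrix`.

    Returns ``(values, header)``.  Raises ``ValueError`` on a missing or
    incomplete header, or on ragged rows (with the offending line number).
    """
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(f"missing sidecar header {side}")
    header = json.loads(side.read_text())
    for key in _REQUIRED_HEADER:
        if key not in header:
            raise ValueError(f"header {side} lacks required key {key!r}")
    ncol = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if ncol is None:
                ncol = len(fields)
            elif len(fields) != ncol:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {ncol})"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as err:
                raise ValueError(f"{path}: parse error at line {lineno}: {err}") from None
    values = np.asarray(rows, dtype=float)
    if values.size and values.shape[1] != header["n_channels"]:
        raise ValueError(
            f"{path}: {values.shape[1]} columns but header declares "
            f"{header['n_channels']} channels"
        )
    return values, header
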