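"""Sample/report file I/O.

Samples are one observation per line (CSV, optional single header line);
values must lie strictly inside (0, 1).  Decimal parsing is
locale-independent (dot separator).  Reports round-trip through JSON or
CSV and always record the seed and library version for provenance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .censoring import CensoringScheme, PCS2Sample, read_scheme

__all__ = ["read_sample", "write_report"]


def read_sample(path, scheme_path=None):
    """Read observations from a one-column CSV; optionally bind a scheme.

    Without a scheme: returns the values in file order as an array.  With
    one: validates length against the scheme and returns a sorted
    :class:`PCS2Sample`.  Errors name the offending line.
    """
    path = Path(path)
    values = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip().rstrip(",")
            if not text:
                continue
            try:
                value = float(text)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(f"{path}:{lineno}: not a number: {text!r}")
            if not (0.0 < value < 1.0):
                raise ValueError(
                    f"{path}:{lineno}: value {value} outside the open interval (0, 1)"
                )
            values.append(value)
    if not values:
        raise ValueError(f"{path}: no observations found")
    data = np.asarray(values)
    if scheme_path is None:
        return data
    scheme = (
        scheme_path
        if isinstance(scheme_path, CensoringScheme)
        else read_scheme(scheme_path)
    )
    if len(data) != scheme.m:
        raise ValueError(
            f"{path}: {len(data)} observations but scheme expects m={scheme.m}"
        )
    return PCS2Sample(np.sort(data), scheme)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(results, path, format: str = "json", seed=None) -> None:
    """Write a results mapping (or dataclass) to JSON or CSV.

    JSON output carries ``seed`` and the library version; CSV expects a
    list of flat row dicts (or a DataFrame-like with ``to_csv``).
    """
    from . import __version__

    path = Path(path)
    if format == "json":
        payload = _jsonable(results)
        if isinstance(payload, dict):
            payload.setdefault("provenance", {"seed": seed, "version": __version__})
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        if hasattr(results, "to_csv"):
            results.to_csv(path, index=False)
            return
        rows = [_jsonable(r) for r in results]
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown format {format!r} (use 'json' or 'csv')")
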