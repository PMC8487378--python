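"""Reading and writing lifetime samples.

Two interchangeable on-disk forms, both plain text:

* ``txt`` — one value per line;
* ``csv`` — a single ``value`` column with a header row.

Lines starting with ``#`` carry provenance (generator seed, parameters,
source) and are preserved on write, ignored on read.  Values round-trip
at full double precision via ``repr``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import SampleSet

__all__ = ["read_sample", "write_sample"]


def read_sample(path: str | Path, format: str | None = None) -> SampleSet:
    """Read a sample of positive lifetimes from ``path``.

    ``format`` may be ``"txt"``, ``"csv"`` or ``None`` to infer from the
    suffix (a ``value`` header row is tolerated either way).  Raises on
    non-numeric or non-positive entries, naming the offending line.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "txt"
    if format not in ("txt", "csv"):
        raise ValueError(f"unknown sample format {format!r}; use 'txt' or 'csv'")
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            if text.lower() in ("value", "values"):  # header row
                continue
            try:
                v = float(text.rstrip(","))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {text!r} as a lifetime"
                ) from None
            if v <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive lifetime {v}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no sample values found")
    return SampleSet(values=np.asarray(values), provenance={"source": str(path)})


def write_sample(sample: SampleSet, path: str | Path, format: str = "txt") -> None:
    """Write ``sample`` to ``path`` with provenance comment lines."""
    if format not in ("txt", "csv"):
        raise ValueError(f"unknown sample format {format!r}; use 'txt' or 'csv'")
    path = Path(path)
    with open(path, "w") as fh:
        if sample.provenance:
            fh.write(f"# provenance: {json.dumps(sample.provenance, default=str)}\n")
        if format == "csv":
            fh.write("value\n")
        for v in sample.values:
            fh.write(f"{float(v)!r}\n")
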