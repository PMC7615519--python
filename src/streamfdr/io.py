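"""Readers, writers and packaged fixtures.

Streams and decision logs are plain CSV.  Floats are written with
``repr`` so that ``read(write(x))`` round-trips bit-exactly; run metadata
(config, seed, package version) is carried in ``#``-prefixed header
comments that readers skip.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .core import DecisionLog, DecisionRecord

__all__ = [
    "PValueStream",
    "read_stream",
    "stampede_fixture",
    "write_log",
    "read_log",
    "write_results",
    "FIXTURES",
]

FIXTURES = ("stampede",)


@dataclass(frozen=True)
class PValueStream:
    """An ordered stream of (id, p-value, optional batch label) rows."""

    ids: tuple
    pvals: tuple
    batches: tuple | None = None

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("stream ids must be unique")
        if self.batches is not None and len(self.batches) != len(self.ids):
            raise ValueError("batch column length mismatch")

    def __len__(self) -> int:
        return len(self.ids)


def _parse_stream(lines, source: str) -> PValueStream:
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError(f"{source}: empty file, expected a header row") from None
    header = [h.strip().lower() for h in header]
    if header[:2] != ["id", "pval"]:
        raise ValueError(f"{source}: header must start with 'id,pval', got {header}")
    has_batch = len(header) > 2 and header[2] == "batch"
    ids, pvals, batches = [], [], []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise ValueError(f"{source}: malformed row at line {lineno}: {row}")
        try:
            p = float(row[1])
        except ValueError:
            raise ValueError(f"{source}: unparseable p-value at line {lineno}: {row[1]!r}") from None
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{source}: p-value out of [0, 1] at line {lineno}: {p}")
        ids.append(row[0])
        pvals.append(p)
        batches.append(row[2] if has_batch and len(row) > 2 else "")
    return PValueStream(
        ids=tuple(ids),
        pvals=tuple(pvals),
        batches=tuple(batches) if has_batch else None,
    )


def read_stream(path) -> PValueStream:
    """Read an ordered p-value stream CSV (columns ``id,pval[,batch]``)."""
    path = Path(path)
    with path.open(newline="") as fh:
        return _parse_stream(fh, str(path))


def stampede_fixture() -> PValueStream:
    """The packaged 7-hypothesis platform-trial stream (order B,C,E,D,F,G,H)."""
    text = resources.files("streamfdr.data").joinpath("stampede.csv").read_text()
    return _parse_stream(_io.StringIO(text), "stampede fixture")


def _format(x: float) -> str:
    return repr(float(x))


def write_log(path, log: DecisionLog) -> None:
    """Write a decision log as CSV with a metadata header and a summary
    footer comment holding the next-hypothesis level (full precision and
    rounded half-even to 4 decimals)."""
    from . import __version__

    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# streamfdr {__version__}\n")
        fh.write(f"# config: {json.dumps(log.config)}\n")
        writer = csv.writer(fh)
        cols = ["index", "id", "pval", "alpha", "reject", "wealth"]
        if log.batches is not None:
            cols.append("batch")
        writer.writerow(cols)
        for i, rec in enumerate(log.records):
            row = [rec.index, rec.id, _format(rec.pval), _format(rec.alpha),
                   rec.reject, _format(rec.wealth)]
            if log.batches is not None:
                row.append(log.batches[i])
            writer.writerow(row)
        fh.write(f"# next_level: {_format(log.next_level)}\n")
        fh.write(f"# next_level_rounded: {round(log.next_level, 4)}\n")


def read_log(path) -> DecisionLog:
    """Read back a decision log written by :func:`write_log` (bit-exact)."""
    path = Path(path)
    records, batches = [], []
    next_level = float("nan")
    algorithm, config = "", {}
    header = None
    with path.open(newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("next_level:"):
                    next_level = float(body.split(":", 1)[1])
                elif body.startswith("config:"):
                    config = json.loads(body.split(":", 1)[1])
                    algorithm = config.get("algorithm", "")
                continue
            row = next(csv.reader([line]))
            if header is None:
                header = row
                continue
            records.append(
                DecisionRecord(int(row[0]), row[1], float(row[2]), float(row[3]),
                               int(row[4]), float(row[5]))
            )
            if header and len(header) > 6:
                batches.append(row[6])
    return DecisionLog(
        records,
        next_level=next_level,
        algorithm=algorithm,
        config=config,
        batches=batches if batches else None,
    )


def write_results(path, table) -> None:
    """Write an experiment results table (pandas DataFrame) as CSV."""
    table.to_csv(path, index=False)
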