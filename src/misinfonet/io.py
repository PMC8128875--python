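"""Stream serialization (JSON-Lines) and validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import StreamFormatError
from .synthetic_stream import MisinfoRecord, Stream

__all__ = ["write_stream_jsonl", "read_stream_jsonl", "validate_stream", "ValidationReport"]

NORM_TOL = 1e-6


def write_stream_jsonl(stream: Stream, path: str | Path) -> None:
    """Write a stream: a header line (metadata) then one record per line."""
    path = Path(path)
    header = {"kind": "misinfonet-stream", "version": 1}
    if stream.config is not None:
        header["n_days"] = stream.config.n_days
        header["embedding_dim"] = stream.config.embedding_dim
        header["seed"] = stream.config.seed
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for r in stream.records:
            row = {
                "id": r.id,
                "day": r.day,
                "embedding": [float(x) for x in r.embedding],
            }
            if r.tokens is not None:
                row["tokens"] = r.tokens
            if r.popularity is not None:
                row["popularity"] = r.popularity
            if r.category is not None:
                row["category"] = r.category
            if r.true_topic is not None:
                row["true_topic"] = r.true_topic
            fh.write(json.dumps(row) + "\n")


def read_stream_jsonl(path: str | Path) -> Stream:
    path = Path(path)
    records: list[MisinfoRecord] = []
    with path.open() as fh:
        first = fh.readline()
        try:
            header = json.loads(first)
        except json.JSONDecodeError as exc:
            raise StreamFormatError(f"{path}:1: malformed header: {exc}") from exc
        if header.get("kind") != "misinfonet-stream":
            raise StreamFormatError(f"{path}: not a stream file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(f"{path}:{lineno}: malformed record: {exc}") from exc
            records.append(
                MisinfoRecord(
                    id=row["id"],
                    day=int(row["day"]),
                    embedding=np.asarray(row["embedding"], dtype=float),
                    tokens=row.get("tokens"),
                    popularity=row.get("popularity"),
                    category=row.get("category"),
                    true_topic=row.get("true_topic"),
                )
            )
    return Stream(records=records, config=None)


@dataclass
class ValidationReport:
    n_records: int
    n_days: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_stream(path: str | Path) -> ValidationReport:
    """Schema / norm / ordering checks on a stream file, with line numbers."""
    path = Path(path)
    violations: list[str] = []
    n = 0
    prev_key: Optional[tuple[int, str]] = None
    dims: set[int] = set()
    max_day = -1
    with path.open() as fh:
        first = fh.readline()
        try:
            header = json.loads(first)
            if header.get("kind") != "misinfonet-stream":
                violations.append("line 1: missing stream header")
        except json.JSONDecodeError:
            violations.append("line 1: malformed header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError:
                violations.append(f"line {lineno}: malformed JSON")
                continue
            n += 1
            missing = [k for k in ("id", "day", "embedding") if k not in row]
            if missing:
                violations.append(f"line {lineno}: missing fields {missing}")
                continue
            emb = np.asarray(row["embedding"], dtype=float)
            dims.add(emb.size)
            norm = float(np.linalg.norm(emb))
            if abs(norm - 1.0) > NORM_TOL:
                violations.append(f"line {lineno}: embedding norm {norm:.6f} != 1")
            day = int(row["day"])
            if day < 0:
                violations.append(f"line {lineno}: negative day")
            key = (day, str(row["id"]))
            if prev_key is not None and key < prev_key:
                violations.append(f"line {lineno}: records out of (day, id) order")
            prev_key = key
            max_day = max(max_day, day)
    if len(dims) > 1:
        violations.append(f"inconsistent embedding dimensions: {sorted(dims)}")
    return ValidationReport(n_records=n, n_days=max_day + 1, violations=violations)
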