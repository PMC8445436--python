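"""Session protocol logs: crash-tolerant JSON-lines persistence.

A log file is append-only JSON lines: a ``header`` record first, one
``checkpoint`` record per logging period, and a ``final`` record at normal
termination.  A file truncated after checkpoint *k* reads back with *k*
checkpoints and ``terminated_normally=False``, so a crashed session retains
its last saved progress.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import LogParseError

__all__ = ["SessionLog", "write_log", "read_log"]

Snapshot = dict[str, tuple[float, float]]


@dataclass
class SessionLog:
    """Protocol record of one training session."""

    session_id: str
    started_at: str  # ISO 8601, UTC
    runtime_s: float
    click_count: int
    checkpoints: list[tuple[float, Snapshot]] = field(default_factory=list)
    final_coordinates: Snapshot = field(default_factory=dict)
    seed: int = 0
    config_digest: str = ""
    terminated_normally: bool = True


def _snap_to_json(snap: Snapshot) -> dict:
    return {k: [v[0], v[1]] for k, v in snap.items()}


def _snap_from_json(obj: dict) -> Snapshot:
    return {k: (float(v[0]), float(v[1])) for k, v in obj.items()}


def write_log(log: SessionLog, path: str | Path) -> None:
    """Write a complete session log (header, checkpoints, final record)."""
    with open(path, "w") as fh:
        fh.write(
            json.dumps(
                {
                    "type": "header",
                    "session_id": log.session_id,
                    "started_at": log.started_at,
                    "seed": log.seed,
                    "config_digest": log.config_digest,
                }
            )
            + "\n"
        )
        for elapsed, snap in log.checkpoints:
            fh.write(
                json.dumps(
                    {"type": "checkpoint", "elapsed_s": elapsed, "coords": _snap_to_json(snap)}
                )
                + "\n"
            )
        if log.terminated_normally:
            fh.write(
                json.dumps(
                    {
                        "type": "final",
                        "runtime_s": log.runtime_s,
                        "click_count": log.click_count,
                        "final_coordinates": _snap_to_json(log.final_coordinates),
                    }
                )
                + "\n"
            )


def _require(record: dict, key: str, lineno: int):
    if key not in record:
        raise LogParseError(f"line {lineno}: missing field {key!r}")
    return record[key]


def read_log(path: str | Path) -> SessionLog:
    """Read a session log, tolerating truncation after any complete line.

    A missing or torn ``final`` record (crash) yields
    ``terminated_normally=False`` with the last checkpoint as the final
    coordinate snapshot.  Structural errors raise :class:`LogParseError`
    naming the offending field.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise LogParseError("line 1: missing field 'type' (empty file)")
    records = []
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            records.append((i, json.loads(line)))
        except json.JSONDecodeError:
            if i == len(lines):
                break  # torn final line from a crash mid-write
            raise LogParseError(f"line {i}: malformed JSON record") from None
    if not records:
        raise LogParseError("line 1: missing field 'type' (no complete records)")
    lineno, header = records[0]
    if _require(header, "type", lineno) != "header":
        raise LogParseError(f"line {lineno}: first record must have type 'header'")
    log = SessionLog(
        session_id=_require(header, "session_id", lineno),
        started_at=_require(header, "started_at", lineno),
        runtime_s=0.0,
        click_count=0,
        seed=int(_require(header, "seed", lineno)),
        config_digest=_require(header, "config_digest", lineno),
        terminated_normally=False,
    )
    for lineno, rec in records[1:]:
        kind = _require(rec, "type", lineno)
        if kind == "checkpoint":
            log.checkpoints.append(
                (
                    float(_require(rec, "elapsed_s", lineno)),
                    _snap_from_json(_require(rec, "coords", lineno)),
                )
            )
        elif kind == "final":
            log.runtime_s = float(_require(rec, "runtime_s", lineno))
            log.click_count = int(_require(rec, "click_count", lineno))
            log.final_coordinates = _snap_from_json(
                _require(rec, "final_coordinates", lineno)
            )
            log.terminated_normally = True
        else:
            raise LogParseError(f"line {lineno}: unknown record type {kind!r}")
    if not log.terminated_normally and log.checkpoints:
        log.final_coordinates = dict(log.checkpoints[-1][1])
        log.runtime_s = log.checkpoints[-1][0]
    return log
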