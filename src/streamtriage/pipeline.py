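"""Stream orchestration: watch a directory, queue objects, triage, report.

Each incoming data object is driven through feature extraction -> the
interestingness function -> the policy -> tier placement, and a triage
record (features, score, tier, final location) is persisted to an embedded
append-only metadata store.  The queue is an in-process closable FIFO
behind a minimal interface, so an external broker adapter could be
substituted without touching the triage logic.
"""

from __future__ import annotations

import fnmatch
import json
import logging
import math
import queue as _queue
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .features import FeatureVector, extract_features, load_grayscale
from .policy import PlacementError, Policy, Tier, assign_tier, place_in_tier

__all__ = [
    "DataObject",
    "TriageRecord",
    "MetadataStore",
    "DuplicateObjectError",
    "ObjectQueue",
    "QueueClosed",
    "DirectoryWatcher",
    "PipelineConfig",
    "QUARANTINE_TIER_ID",
    "triage_object",
    "worker_loop",
    "export_report",
]

log = logging.getLogger(__name__)

#: Pseudo-tier recorded for objects that could not be scored (corrupt or
#: degenerate payloads); never a valid policy target.
QUARANTINE_TIER_ID = "__quarantine__"

#: Stable column order for exported reports.
REPORT_COLUMNS = [
    "object_id",
    "plls",
    "mean_intensity",
    "std_intensity",
    "interestingness",
    "tier_id",
    "final_location",
]


@dataclass(frozen=True)
class DataObject:
    """One element of a stream: a payload file plus its stream coordinates."""

    object_id: str
    stream_id: str
    payload_path: Path
    arrival_index: int
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.arrival_index < 0:
            raise ValueError("arrival_index must be non-negative")
        object.__setattr__(self, "payload_path", Path(self.payload_path))


@dataclass(frozen=True)
class TriageRecord:
    """Persisted outcome of triaging one object."""

    object_id: str
    features: FeatureVector
    interestingness: float
    tier_id: str
    final_location: str  # path, or "trash:<path>" / "quarantine:<path>"
    wall_time: float = 0.0

    def to_row(self) -> dict:
        row = {"object_id": self.object_id}
        row.update(self.features.as_dict())
        row["interestingness"] = self.interestingness
        row["tier_id"] = self.tier_id
        row["final_location"] = self.final_location
        return row


class DuplicateObjectError(ValueError):
    """An object_id was submitted twice; the store is left unchanged."""


class MetadataStore:
    """Embedded append-only store of triage records, indexed by object_id.

    Optionally backed by a JSON-lines file so a run can be inspected or the
    report regenerated after the process exits.  Re-insertion of an
    existing object_id is rejected.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._records: dict[str, TriageRecord] = {}
        if self.path is not None and self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    rec = _record_from_json(json.loads(line))
                    self._records[rec.object_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, object_id: str) -> bool:
        return object_id in self._records

    def get(self, object_id: str) -> TriageRecord:
        return self._records[object_id]

    def records(self) -> list[TriageRecord]:
        return list(self._records.values())

    def insert(self, record: TriageRecord) -> None:
        if record.object_id in self._records:
            raise DuplicateObjectError(f"object {record.object_id!r} already triaged")
        self._records[record.object_id] = record
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(json.dumps(_record_to_json(record), sort_keys=True) + "\n")


def _record_to_json(rec: TriageRecord) -> dict:
    d = rec.to_row()
    d["plls_ok"] = rec.features.plls_ok
    d["wall_time"] = rec.wall_time
    # NaN is not valid JSON; encode as None.
    if isinstance(d["plls"], float) and math.isnan(d["plls"]):
        d["plls"] = None
    return d


def _record_from_json(d: dict) -> TriageRecord:
    plls = d["plls"] if d["plls"] is not None else float("nan")
    fv = FeatureVector(
        plls=plls,
        mean_intensity=d["mean_intensity"],
        std_intensity=d["std_intensity"],
        plls_ok=bool(d.get("plls_ok", True)),
    )
    return TriageRecord(
        object_id=d["object_id"],
        features=fv,
        interestingness=d["interestingness"],
        tier_id=d["tier_id"],
        final_location=d["final_location"],
        wall_time=d.get("wall_time", 0.0),
    )


class QueueClosed(Exception):
    """Raised by :meth:`ObjectQueue.get` once the queue is closed and drained."""


class ObjectQueue:
    """Bounded in-process FIFO of data objects with close semantics.

    Stands in for an external message broker; the interface (put / get /
    close) is all the worker loop depends on.
    """

    _SENTINEL = object()

    def __init__(self, maxsize: int = 0):
        self._q: _queue.Queue = _queue.Queue(maxsize=maxsize)
        self._closed = False

    def put(self, obj: DataObject) -> None:
        if self._closed:
            raise QueueClosed("queue is closed")
        self._q.put(obj)

    def close(self) -> None:
        if not self._closed:
            self._closed = True
            self._q.put(self._SENTINEL)

    def get(self, timeout: float | None = None) -> DataObject:
        item = self._q.get(timeout=timeout)
        if item is self._SENTINEL:
            self._q.put(self._SENTINEL)  # let other consumers observe closure
            raise QueueClosed("queue closed and drained")
        return item


class DirectoryWatcher:
    """Polls a source directory and enqueues each new matching file exactly once.

    Files are discovered in sorted-name order within a scan, so arrival
    indices are deterministic for a pre-populated directory.  A file that
    vanishes between discovery and read is skipped with a log message at
    triage time; duplicate discovery of the same name never re-enqueues.
    """

    def __init__(
        self,
        source_dir: str | Path,
        queue: ObjectQueue,
        pattern: str = "*.png",
        stream_id: str | None = None,
    ):
        self.source_dir = Path(source_dir)
        if not self.source_dir.is_dir():
            raise FileNotFoundError(f"source directory {self.source_dir} does not exist")
        self.queue = queue
        self.patterns = [p.strip() for p in pattern.split("|") if p.strip()]
        self.stream_id = stream_id or f"{self.source_dir.name}-{int(time.time())}"
        self._seen: set[str] = set()
        self._next_index = 0
        self._t0 = time.monotonic()

    def _matches(self, name: str) -> bool:
        return any(fnmatch.fnmatch(name, p) for p in self.patterns)

    def scan_once(self) -> int:
        """Enqueue all not-yet-seen matching files; returns how many."""
        n = 0
        for path in sorted(self.source_dir.iterdir()):
            if not path.is_file() or path.name in self._seen or not self._matches(path.name):
                continue
            self._seen.add(path.name)
            obj = DataObject(
                object_id=path.name,
                stream_id=self.stream_id,
                payload_path=path,
                arrival_index=self._next_index,
                timestamp=time.monotonic() - self._t0,
            )
            self._next_index += 1
            self.queue.put(obj)
            n += 1
        return n

    def watch(self, poll_interval: float = 0.5, idle_timeout: float | None = None) -> int:
        """Poll until ``idle_timeout`` seconds pass with no new files (or forever)."""
        total = 0
        idle_since = time.monotonic()
        while True:
            n = self.scan_once()
            total += n
            now = time.monotonic()
            if n:
                idle_since = now
            elif idle_timeout is not None and now - idle_since >= idle_timeout:
                return total
            time.sleep(poll_interval)


@dataclass
class PipelineConfig:
    """Everything the worker needs: extractor, IF, policy, tiers, locations."""

    if_fn: Callable[[FeatureVector], float]
    policy: Policy
    tiers: Mapping[str, Tier]
    extractor: Callable[[Path], FeatureVector] = field(
        default=lambda path: extract_features(load_grayscale(path))
    )
    trash_dir: Path = Path("trash")
    quarantine_dir: Path = Path("quarantine")
    copy: bool = False  # copy payloads instead of moving them


def _quarantine(
    obj: DataObject,
    features: FeatureVector,
    config: PipelineConfig,
    store: MetadataStore,
    reason: str,
    t0: float,
) -> TriageRecord:
    config.quarantine_dir.mkdir(parents=True, exist_ok=True)
    location = f"quarantine:{config.quarantine_dir}"
    if obj.payload_path.exists():
        tier = Tier(QUARANTINE_TIER_ID, kind="directory", path=config.quarantine_dir)
        try:
            final = place_in_tier(obj.payload_path, tier, copy=config.copy)
            location = f"quarantine:{final}"
        except PlacementError:  # pragma: no cover - unwritable quarantine
            location = f"quarantine-failed:{obj.payload_path}"
    log.warning("quarantined %s: %s", obj.object_id, reason)
    record = TriageRecord(
        object_id=obj.object_id,
        features=features,
        interestingness=float("nan"),
        tier_id=QUARANTINE_TIER_ID,
        final_location=location,
        wall_time=time.monotonic() - t0,
    )
    store.insert(record)
    return record


def triage_object(
    obj: DataObject,
    config: PipelineConfig,
    store: MetadataStore,
) -> TriageRecord:
    """Run one object through extraction -> IF -> policy -> placement.

    The returned record echoes the persisted one.  An unreadable or
    degenerate payload is moved to quarantine and recorded as such rather
    than dropped; a duplicate object_id raises before any file is touched.
    """
    if obj.object_id in store:
        raise DuplicateObjectError(f"object {obj.object_id!r} already triaged")
    t0 = time.monotonic()
    empty = FeatureVector(float("nan"), float("nan"), float("nan"), plls_ok=False)
    try:
        features = config.extractor(obj.payload_path)
    except FileNotFoundError:
        log.warning("payload vanished before read: %s", obj.payload_path)
        return _quarantine(obj, empty, config, store, "payload vanished", t0)
    except Exception as exc:  # corrupt/undecodable payload
        return _quarantine(obj, empty, config, store, f"unreadable payload: {exc}", t0)

    if not features.plls_ok:
        return _quarantine(obj, features, config, store, "degenerate focus spectrum", t0)

    score = config.if_fn(features)
    tier_id = assign_tier(score, config.policy)
    tier = config.tiers[tier_id]
    try:
        final = place_in_tier(
            obj.payload_path, tier, trash_dir=config.trash_dir, copy=config.copy
        )
    except PlacementError as exc:
        return _quarantine(obj, features, config, store, f"placement failed: {exc}", t0)
    location = f"trash:{final}" if tier.kind == "trash" else str(final)
    record = TriageRecord(
        object_id=obj.object_id,
        features=features,
        interestingness=score,
        tier_id=tier_id,
        final_location=location,
        wall_time=time.monotonic() - t0,
    )
    store.insert(record)
    return record


def worker_loop(
    queue: ObjectQueue,
    config: PipelineConfig,
    store: MetadataStore,
    timeout: float | None = None,
) -> int:
    """Drain the queue, triaging every object; returns the processed count.

    Per-object failures are isolated (quarantined and logged); the loop
    only stops when the queue is closed and fully drained.
    """
    processed = 0
    while True:
        try:
            obj = queue.get(timeout=timeout)
        except QueueClosed:
            return processed
        except _queue.Empty:
            return processed
        try:
            triage_object(obj, config, store)
        except DuplicateObjectError:
            log.warning("duplicate object %s skipped", obj.object_id)
        processed += 1


def export_report(
    store: MetadataStore,
    predicate: Callable[[TriageRecord], bool] | None = None,
) -> pd.DataFrame:
    """Tabulate triage records (one row per object, sorted by object_id).

    Column order is stable so repeated exports of the same store are
    byte-identical when written to CSV.
    """
    rows = [r.to_row() for r in store.records() if predicate is None or predicate(r)]
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return frame.sort_values("object_id", kind="mergesort").reset_index(drop=True)
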