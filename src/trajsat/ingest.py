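"""Reading interview paradata, exclusion filtering, and response-speed computation.

A participant-visit record carries the survey start/end timestamps logged by the
interview software and the total word count of the variables the participant
responded to.  Response speed for a visit is the word count divided by the
elapsed survey time in seconds (words per second).  Records with a missing
start time, a missing end time, or illogical timestamps (end at or before
start, or an implausibly long duration) are excluded before any speed is
computed; the three filters are mutually exclusive and applied in that order,
so the exclusion report partitions the input exactly.

Visit indices are mapped onto a coded time axis: the first visit of the study
window is coded t=0, the next t=1, and so on.  This is the single time
convention used throughout the package.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

#: First visit of the observation window; visit ``VISIT_BASE + t`` has coded time t.
VISIT_BASE = 50

#: Durations longer than this are treated as illogical (multi-day artefacts).
MAX_DURATION = timedelta(hours=24)


class DataError(ValueError):
    """Malformed input data (duplicate keys, unparseable fields)."""


@dataclass(frozen=True)
class VisitRecord:
    """One participant-visit of interview paradata.

    ``start_time`` / ``end_time`` may be ``None`` when the interview software
    failed to log them; such records are removed by :func:`clean_visits`.
    ``word_count`` is the total number of words across all responded variables.
    ``sexual_activity`` and ``drug_use`` are visit-level behavioural covariates
    with levels ``none`` / ``one`` / ``multiple``.
    """

    participant_id: str
    visit: int
    start_time: datetime | None
    end_time: datetime | None
    word_count: int
    sexual_activity: str = "none"
    drug_use: str = "none"

    @property
    def coded_time(self) -> int:
        return self.visit - VISIT_BASE

    @property
    def duration_seconds(self) -> float | None:
        if self.start_time is None or self.end_time is None:
            return None
        return (self.end_time - self.start_time).total_seconds()


@dataclass(frozen=True)
class CleanReport:
    """Partition of the input records by exclusion category."""

    n_input: int
    n_missing_start: int
    n_missing_end: int
    n_illogical: int
    n_kept: int

    def __post_init__(self) -> None:
        total = self.n_missing_start + self.n_missing_end + self.n_illogical + self.n_kept
        if total != self.n_input:
            raise ValueError(
                f"clean report does not partition input: {total} != {self.n_input}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_missing_start": self.n_missing_start,
            "n_missing_end": self.n_missing_end,
            "n_illogical": self.n_illogical,
            "n_kept": self.n_kept,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class SpeedObservation:
    """Response speed at one cleaned participant-visit."""

    participant_id: str
    coded_time: int
    duration: float  # seconds, > 0
    speed: float  # words per second

    def __post_init__(self) -> None:
        if not np.isfinite(self.speed) or self.duration <= 0:
            raise ValueError("speed observation requires positive finite duration")


@dataclass(frozen=True)
class SpeedSeries:
    """One participant's response-speed observations, ordered by coded time."""

    participant_id: str
    observations: tuple[SpeedObservation, ...]

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise ValueError("speed series must contain at least one observation")
        times = [o.coded_time for o in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("coded times must be strictly increasing within a series")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.coded_time for o in self.observations], dtype=float)

    @property
    def speeds(self) -> np.ndarray:
        return np.array([o.speed for o in self.observations], dtype=float)


def clean_visits(
    records: list[VisitRecord],
    *,
    max_duration: timedelta = MAX_DURATION,
) -> tuple[list[VisitRecord], CleanReport]:
    """Apply the exclusion filters and report the resulting partition.

    Filters are mutually exclusive and applied in order: missing start time,
    then missing end time, then illogical times (end at or before start, or a
    duration above ``max_duration``).  Kept records therefore all have a
    strictly positive duration within the cap.

    Raises
    ------
    DataError
        If any (participant, visit) pair occurs more than once.
    """
    keys = Counter((r.participant_id, r.visit) for r in records)
    dupes = sorted(k for k, c in keys.items() if c > 1)
    if dupes:
        raise DataError(f"duplicate (participant, visit) pairs: {dupes[:10]}")

    kept: list[VisitRecord] = []
    n_ms = n_me = n_il = 0
    for r in records:
        if r.start_time is None:
            n_ms += 1
        elif r.end_time is None:
            n_me += 1
        elif r.end_time <= r.start_time or (r.end_time - r.start_time) > max_duration:
            n_il += 1
        else:
            kept.append(r)
    report = CleanReport(
        n_input=len(records),
        n_missing_start=n_ms,
        n_missing_end=n_me,
        n_illogical=n_il,
        n_kept=len(kept),
    )
    return kept, report


def compute_speed(record: VisitRecord, *, visit_base: int = VISIT_BASE) -> SpeedObservation:
    """Response speed = word count / elapsed seconds for one cleaned record."""
    duration = record.duration_seconds
    if duration is None or duration <= 0:
        raise ValueError(
            f"record {record.participant_id}/visit {record.visit} has non-positive "
            "duration; run clean_visits first"
        )
    return SpeedObservation(
        participant_id=record.participant_id,
        coded_time=record.visit - visit_base,
        duration=duration,
        speed=record.word_count / duration,
    )


def build_series(
    kept: list[VisitRecord], *, visit_base: int = VISIT_BASE
) -> list[SpeedSeries]:
    """Group cleaned records into one per-participant speed series.

    Participants are retained no matter how few visits they contributed
    (unbalanced panels are expected downstream).  Output order is sorted by
    participant id, and observations within a series by coded time, so the
    result is invariant to the input row order.
    """
    by_pid: dict[str, list[SpeedObservation]] = {}
    for r in kept:
        by_pid.setdefault(r.participant_id, []).append(
            compute_speed(r, visit_base=visit_base)
        )
    series = []
    for pid in sorted(by_pid):
        obs = sorted(by_pid[pid], key=lambda o: o.coded_time)
        series.append(SpeedSeries(participant_id=pid, observations=tuple(obs)))
    return series


# ---------------------------------------------------------------------------
# Delimited-text I/O (the dialect written by trajsat.synth, also accepted from
# real exports with the same header).

VISIT_COLUMNS = [
    "participant_id",
    "visit",
    "start_time",
    "end_time",
    "word_count",
    "sexual_activity",
    "drug_use",
]


def _parse_ts(text: str) -> datetime | None:
    text = text.strip()
    if not text:
        return None
    try:
        return datetime.fromisoformat(text)
    except ValueError as exc:
        raise DataError(f"unparseable timestamp {text!r}") from exc


def read_visits_csv(path: str | Path) -> list[VisitRecord]:
    """Read participant-visit records from a CSV file (empty timestamp = missing)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(VISIT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"visit CSV missing columns: {sorted(missing)}")
        for row in reader:
            records.append(
                VisitRecord(
                    participant_id=row["participant_id"],
                    visit=int(row["visit"]),
                    start_time=_parse_ts(row["start_time"]),
                    end_time=_parse_ts(row["end_time"]),
                    word_count=int(row["word_count"]),
                    sexual_activity=row["sexual_activity"],
                    drug_use=row["drug_use"],
                )
            )
    return records


def write_visits_csv(records: list[VisitRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(VISIT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.visit,
                    r.start_time.isoformat() if r.start_time else "",
                    r.end_time.isoformat() if r.end_time else "",
                    r.word_count,
                    r.sexual_activity,
                    r.drug_use,
                ]
            )


def write_speed_csv(series: list[SpeedSeries], path: str | Path) -> None:
    """Write speed series as tidy CSV: participant_id, t, speed."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "t", "speed"])
        for s in series:
            for o in s.observations:
                writer.writerow([s.participant_id, o.coded_time, repr(o.speed)])
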