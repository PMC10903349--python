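"""Capture-event ingestion and encounter-history construction.

A mark-release-recapture (MRR) survey produces one row per handling event:
an individual's unique mark, the calendar day, sex, GPS position, behaviour
at capture, an ordinal wing-wear score (1 fresh .. 4 heavily worn) and,
when the animal was nectaring, the plant genus. This module validates such
tables and reshapes them into the binary encounter histories that
open-population abundance models consume.

Occasions are calendar days on which fieldwork happened; days without any
event are absent from the occasion list rather than zero-filled. Multiple
same-day handlings of one individual collapse to a single detection,
keeping the first record's attributes.
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaptureEvent",
    "EncounterHistorySet",
    "EffortSchedule",
    "SchemaError",
    "ValidationError",
    "DEFAULT_SCHEMA",
    "read_events",
    "write_events",
    "events_to_frame",
    "frame_to_events",
    "build_encounter_histories",
    "recapture_summary",
    "write_inp",
    "read_inp",
]

SEXES = ("male", "female")

#: canonical field -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "individual_id": "individual_id",
    "date": "date",
    "sex": "sex",
    "lat": "lat",
    "lon": "lon",
    "behaviour": "behaviour",
    "wing_score": "wing_score",
    "nectar_genus": "nectar_genus",
    "generation": "generation",
}

REQUIRED_FIELDS = ("individual_id", "date", "sex")


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is invalid."""


class ValidationError(ValueError):
    """A row violates a field invariant; the message names the row."""


@dataclass(frozen=True)
class CaptureEvent:
    """One capture or recapture record."""

    individual_id: str
    date: dt.date
    sex: str
    lat: float = float("nan")
    lon: float = float("nan")
    behaviour: str | None = None
    wing_score: int | None = None
    nectar_genus: str | None = None
    generation: int = 1

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"sex must be one of {SEXES}, got {self.sex!r} for {self.individual_id!r}"
            )
        if self.wing_score is not None and self.wing_score not in (1, 2, 3, 4):
            raise ValidationError(
                f"wing_score must be in 1..4, got {self.wing_score!r} "
                f"for {self.individual_id!r} on {self.date}"
            )
        if self.nectar_genus and self.behaviour != "nectaring":
            raise ValidationError(
                f"nectar_genus set but behaviour is {self.behaviour!r} "
                f"for {self.individual_id!r} on {self.date}"
            )


@dataclass
class EffortSchedule:
    """Per-occasion sampling effort.

    Effort on a day is (sum of person factors) x hours of sampling, with
    factor 1.0 for a skilled collector, 0.5 for an unskilled one and 1.0
    per team.
    """

    occasions: list[dt.date]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.occasions) != self.values.size:
            raise ValueError("occasions and values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("effort must be non-negative")

    @classmethod
    def from_counts(
        cls,
        occasions: Sequence[dt.date],
        skilled: Sequence[int],
        hours: Sequence[float],
        unskilled: Sequence[int] | None = None,
        teams: Sequence[int] | None = None,
    ) -> "EffortSchedule":
        n = len(occasions)
        unskilled = unskilled if unskilled is not None else [0] * n
        teams = teams if teams is not None else [0] * n
        vals = [
            (s + 0.5 * u + 1.0 * t) * h
            for s, u, t, h in zip(skilled, unskilled, teams, hours, strict=True)
        ]
        return cls(list(occasions), np.asarray(vals))

    def subset(self, occasions: Sequence[dt.date]) -> "EffortSchedule":
        idx = {d: i for i, d in enumerate(self.occasions)}
        missing = [d for d in occasions if d not in idx]
        if missing:
            raise ValueError(f"effort undefined for occasions {missing}")
        return EffortSchedule(list(occasions), self.values[[idx[d] for d in occasions]])


@dataclass
class EncounterHistorySet:
    """Binary detection matrix (individuals x occasions) with sex groups."""

    occasions: list[dt.date]
    histories: np.ndarray  # (n_ind, K) of 0/1
    individual_ids: list[str]
    groups: np.ndarray  # sex label per individual
    masked_occasions: list[dt.date] = field(default_factory=list)
    n_dropped: int = 0  # individuals seen only on masked occasions

    def __post_init__(self) -> None:
        self.histories = np.asarray(self.histories, dtype=np.int8)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.histories.ndim != 2:
            raise ValueError("histories must be 2-D")
        if self.histories.shape != (len(self.individual_ids), len(self.occasions)):
            raise ValueError("histories shape does not match ids/occasions")
        if self.histories.size and not np.all(self.histories.sum(axis=1) >= 1):
            raise ValueError("every encounter history must contain a detection")
        if any(b <= a for a, b in zip(self.occasions, self.occasions[1:])):
            raise ValueError("occasions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.histories.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.histories.shape[1]

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def subset_group(self, group: str) -> "EncounterHistorySet":
        sel = self.groups == group
        return EncounterHistorySet(
            self.occasions,
            self.histories[sel],
            [i for i, keep in zip(self.individual_ids, sel) if keep],
            self.groups[sel],
            self.masked_occasions,
        )


def _canonical_row(raw: Mapping[str, str], schema: Mapping[str, str], line: int) -> CaptureEvent:
    def get(fieldname: str) -> str | None:
        col = schema.get(fieldname, DEFAULT_SCHEMA[fieldname])
        v = raw.get(col)
        if v is None:
            return None
        v = v.strip()
        return v or None

    try:
        date = dt.date.fromisoformat(get("date"))  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"line {line}: unparseable date: {exc}") from None
    ws_raw = get("wing_score")
    try:
        ws = int(ws_raw) if ws_raw is not None else None
    except ValueError:
        raise ValidationError(f"line {line}: wing_score {ws_raw!r} is not an integer") from None
    gen_raw = get("generation")
    try:
        return CaptureEvent(
            individual_id=get("individual_id") or "",
            date=date,
            sex=(get("sex") or "").lower(),
            lat=float(get("lat") or "nan"),
            lon=float(get("lon") or "nan"),
            behaviour=get("behaviour"),
            wing_score=ws,
            nectar_genus=get("nectar_genus"),
            generation=int(gen_raw) if gen_raw is not None else 1,
        )
    except ValidationError as exc:
        raise ValidationError(f"line {line}: {exc}") from None


def read_events(path, schema: Mapping[str, str] | None = None) -> list[CaptureEvent]:
    """Read and validate a capture-event CSV.

    ``schema`` maps canonical field names to the file's column names; fields
    absent from the mapping use the defaults in :data:`DEFAULT_SCHEMA`.
    Events are returned sorted by (individual_id, date). Duplicate
    (individual, day) pairs raise :class:`ValidationError`.
    """
    schema = dict(schema or {})
    unknown = set(schema) - set(DEFAULT_SCHEMA)
    if unknown:
        raise SchemaError(f"unknown canonical fields in schema: {sorted(unknown)}")
    events: list[CaptureEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for fieldname in REQUIRED_FIELDS:
            col = schema.get(fieldname, DEFAULT_SCHEMA[fieldname])
            if col not in header:
                raise SchemaError(f"required column {col!r} (field {fieldname}) missing")
        for line, raw in enumerate(reader, start=2):
            events.append(_canonical_row(raw, schema, line))
    seen: set[tuple[str, dt.date]] = set()
    for ev in events:
        key = (ev.individual_id, ev.date)
        if key in seen:
            raise ValidationError(f"duplicate capture of {ev.individual_id!r} on {ev.date}")
        seen.add(key)
    events.sort(key=lambda e: (e.individual_id, e.date))
    return events


def write_events(events: Iterable[CaptureEvent], path) -> None:
    """Write events as CSV using the canonical column names."""
    cols = list(DEFAULT_SCHEMA)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for ev in sorted(events, key=lambda e: (e.individual_id, e.date)):
            w.writerow(
                [
                    ev.individual_id,
                    ev.date.isoformat(),
                    ev.sex,
                    "" if np.isnan(ev.lat) else repr(ev.lat),
                    "" if np.isnan(ev.lon) else repr(ev.lon),
                    ev.behaviour or "",
                    "" if ev.wing_score is None else ev.wing_score,
                    ev.nectar_genus or "",
                    ev.generation,
                ]
            )


def events_to_frame(events: Iterable[CaptureEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


def frame_to_events(df: pd.DataFrame) -> list[CaptureEvent]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if isinstance(d["date"], str):
            d["date"] = dt.date.fromisoformat(d["date"])
        out.append(CaptureEvent(**d))
    return out


def dedupe_same_day(events: Sequence[CaptureEvent]) -> list[CaptureEvent]:
    """Collapse same-day recaptures of one individual to the first record."""
    seen: dict[tuple[str, dt.date], CaptureEvent] = {}
    for ev in sorted(events, key=lambda e: (e.individual_id, e.date)):
        seen.setdefault((ev.individual_id, ev.date), ev)
    return list(seen.values())


def build_encounter_histories(
    events: Sequence[CaptureEvent],
    generation: int | None = None,
    mask_occasions: Sequence[dt.date] = (),
) -> EncounterHistorySet:
    """Build the 0/1 individuals-by-occasions detection matrix.

    Occasions are the distinct event dates of the requested generation,
    minus ``mask_occasions`` (days judged unusable for modelling, e.g.
    near-empty start-up days). Individuals detected only on masked days
    are dropped; the count is recorded on the result and warned about.
    """
    if generation is not None:
        events = [e for e in events if e.generation == generation]
    events = dedupe_same_day(events)
    if not events:
        raise ValueError("no events for requested generation")
    mask = set(mask_occasions)
    occasions = sorted({e.date for e in events} - mask)
    if len(occasions) < 2:
        raise ValueError("need at least 2 unmasked occasions")
    col = {d: k for k, d in enumerate(occasions)}
    by_id: dict[str, list[CaptureEvent]] = {}
    for e in events:
        by_id.setdefault(e.individual_id, []).append(e)
    ids, rows, groups = [], [], []
    n_dropped = 0
    for iid, evs in sorted(by_id.items()):
        row = np.zeros(len(occasions), dtype=np.int8)
        hit = False
        for e in evs:
            if e.date in col:
                row[col[e.date]] = 1
                hit = True
        if not hit:
            n_dropped += 1
            continue
        ids.append(iid)
        rows.append(row)
        groups.append(evs[0].sex)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} individual(s) seen only on masked occasions were dropped",
            stacklevel=2,
        )
    return EncounterHistorySet(
        occasions,
        np.asarray(rows),
        ids,
        np.asarray(groups, dtype=object),
        sorted(mask),
        n_dropped,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def recapture_summary(histories: EncounterHistorySet) -> pd.DataFrame:
    """Marked / recaptured counts and recapture percentage per sex.

    ``percent_recaptured`` is rounded half-up to the nearest integer for
    reporting; ``ratio_recaptured`` keeps the raw fraction.
    """
    rows = []
    caps = histories.histories.sum(axis=1)
    for g in histories.group_names:
        sel = histories.groups == g
        marked = int(sel.sum())
        recap = int((caps[sel] >= 2).sum())
        ratio = recap / marked if marked else float("nan")
        rows.append(
            {
                "group": g,
                "marked": marked,
                "recaptured": recap,
                "max_captures": int(caps[sel].max()) if marked else 0,
                "ratio_recaptured": ratio,
                "percent_recaptured": _round_half_up(100 * ratio) if marked else None,
            }
        )
        if not marked:
            warnings.warn(f"group {g!r} is empty; percent undefined", stacklevel=2)
    return pd.DataFrame(rows)


def write_inp(histories: EncounterHistorySet, path) -> None:
    """Write MARK-style ``.inp`` capture histories with group frequency columns."""
    names = histories.group_names
    uniq: dict[tuple, np.ndarray] = {}
    for row, g in zip(histories.histories, histories.groups):
        key = tuple(int(v) for v in row)
        freq = uniq.setdefault(key, np.zeros(len(names), dtype=int))
        freq[names.index(g)] += 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"/* groups: {' '.join(names)} */\n")
        for key in sorted(uniq, reverse=True):
            freq = " ".join(str(v) for v in uniq[key])
            fh.write(f"{''.join(map(str, key))} {freq};\n")


def read_inp(path, occasions: Sequence[dt.date] | None = None) -> EncounterHistorySet:
    """Read a MARK-style ``.inp`` file (one or more group frequency columns)."""
    rows, groups = [], []
    names: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("/*"):
                if "groups:" in line:
                    names = line.split("groups:")[1].split("*/")[0].split()
                continue
            if not line:
                continue
            body = line.rstrip(";").split()
            hist = np.array([int(c) for c in body[0]], dtype=np.int8)
            freqs = [int(v) for v in body[1:]]
            if names is None:
                names = [f"group{i + 1}" for i in range(len(freqs))]
            for gname, f in zip(names, freqs):
                for _ in range(f):
                    rows.append(hist)
                    groups.append(gname)
    if not rows:
        raise ValueError("empty .inp file")
    K = len(rows[0])
    occ = list(occasions) if occasions else [dt.date(2000, 1, 1) + dt.timedelta(days=k) for k in range(K)]
    ids = [f"h{i:05d}" for i in range(len(rows))]
    return EncounterHistorySet(occ, np.asarray(rows), ids, np.asarray(groups, dtype=object))
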