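"""Canonical in-memory patient record and I/O for CGM event streams.

A patient record is a set of event streams (CGM glucose, fingerstick
self-monitoring readings, bolus insulin doses, meal carbohydrate estimates,
5-minute step aggregates, plus auxiliary band channels) aligned to a uniform
5-minute grid.  Two on-disk dialects are supported: an OhioT1DM-style XML
layout and a flat CSV with one row per grid slot.

Missing CGM slots are represented as NaN and are never imputed here; gap
handling is the Kalman smoother's job.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GRID_MINUTES = 5
SLOTS_PER_DAY = 24 * 60 // GRID_MINUTES  # 288

#: event kinds stored on the dense grid (one value per slot, last one wins)
DENSE_KINDS = ("cgm", "steps", "basal", "heart_rate", "gsr", "skin_temp", "air_temp")
#: event kinds kept as sparse (index, value) lists
SPARSE_KINDS = ("fingerstick", "bolus", "meal")
EVENT_KINDS = DENSE_KINDS + SPARSE_KINDS

AUX_KINDS = ("basal", "heart_rate", "gsr", "skin_temp", "air_temp")

#: XML element name per event kind (OhioT1DM layout)
XML_ELEMENTS = {
    "cgm": "glucose_level",
    "fingerstick": "finger_stick",
    "bolus": "bolus",
    "meal": "meal",
    "basal": "basal",
    "steps": "basis_steps",
    "heart_rate": "basis_heart_rate",
    "gsr": "basis_gsr",
    "skin_temp": "basis_skin_temperature",
    "air_temp": "basis_air_temperature",
}

#: default attribute holding the numeric value, per kind; overridable via
#: the ``attr_map`` argument of :func:`read_ohio_xml` for schema variants
DEFAULT_VALUE_ATTR = {
    "bolus": "dose",
    "meal": "carbs",
}

XML_TS_FORMAT = "%d-%m-%Y %H:%M:%S"

CSV_COLUMNS = ["timestamp", "cgm", "fingerstick", "bolus", "meal_carbs", "steps", "truth_bg"]


class DataFormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


@dataclass(frozen=True)
class EventRecord:
    """A single timestamped measurement or care event."""

    timestamp: datetime
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise DataFormatError(f"unknown event kind {self.kind!r}")
        if not math.isfinite(self.value):
            raise DataFormatError(f"non-finite value for {self.kind} at {self.timestamp}")
        if self.value < 0:
            raise DataFormatError(f"negative value {self.value} for {self.kind} at {self.timestamp}")


@dataclass
class PatientSeries:
    """Multichannel patient record on a uniform 5-minute grid.

    Grid index ``i`` corresponds to wall-clock time ``grid_start + 5*i``
    minutes.  Dense channels (``cgm``, auxiliary band channels, ``truth_bg``)
    hold one float per slot with NaN for missing; ``steps`` is dense with 0
    for missing.  Sparse channels hold ``(index, value)`` pairs.
    ``truth_bg`` is populated only by the simulator and never by file readers
    of real data.
    """

    patient_id: str
    grid_start: datetime
    n_index: int
    cgm: np.ndarray
    gender: str = "unknown"
    fingerstick: list[tuple[int, float]] = field(default_factory=list)
    bolus_events: list[tuple[int, float]] = field(default_factory=list)
    meal_events: list[tuple[int, float]] = field(default_factory=list)
    steps: np.ndarray = None  # type: ignore[assignment]
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    truth_bg: np.ndarray | None = None
    fault_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.steps is None:
            self.steps = np.zeros(self.n_index)
        self.cgm = np.asarray(self.cgm, dtype=float)
        self.steps = np.asarray(self.steps, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_index < 0:
            raise DataFormatError("n_index must be non-negative")
        for name, arr in [("cgm", self.cgm), ("steps", self.steps)] + list(self.aux.items()):
            if len(arr) != self.n_index:
                raise DataFormatError(f"channel {name!r} has length {len(arr)}, expected {self.n_index}")
        if self.truth_bg is not None and len(self.truth_bg) != self.n_index:
            raise DataFormatError("truth_bg length mismatch")
        with np.errstate(invalid="ignore"):
            if np.any(self.cgm[np.isfinite(self.cgm)] <= 0):
                raise DataFormatError("cgm values must be positive where present")
        for name, events in [
            ("fingerstick", self.fingerstick),
            ("bolus_events", self.bolus_events),
            ("meal_events", self.meal_events),
        ]:
            for idx, val in events:
                if not 0 <= idx < self.n_index:
                    raise DataFormatError(f"{name} index {idx} outside grid [0, {self.n_index})")
                if not math.isfinite(val) or val < 0:
                    raise DataFormatError(f"{name} value {val} invalid at index {idx}")

    def index_time(self, i: int) -> datetime:
        """Wall-clock time of grid slot ``i``."""
        return self.grid_start + timedelta(minutes=GRID_MINUTES * i)

    def copy(self) -> "PatientSeries":
        return PatientSeries(
            patient_id=self.patient_id,
            gender=self.gender,
            grid_start=self.grid_start,
            n_index=self.n_index,
            cgm=self.cgm.copy(),
            fingerstick=list(self.fingerstick),
            bolus_events=list(self.bolus_events),
            meal_events=list(self.meal_events),
            steps=self.steps.copy(),
            aux={k: v.copy() for k, v in self.aux.items()},
            truth_bg=None if self.truth_bg is None else self.truth_bg.copy(),
            fault_log=[dict(e) for e in self.fault_log],
        )

    def fingerprint(self) -> tuple:
        """Identity used for train/test leakage checks."""
        return (self.patient_id, self.grid_start.isoformat(), self.n_index)


def _floor_to_grid(t: datetime) -> datetime:
    return t.replace(second=0, microsecond=0) - timedelta(minutes=t.minute % GRID_MINUTES)


def align_to_grid(
    events: Sequence[EventRecord], grid_start: datetime, n_index: int
) -> tuple[dict[str, np.ndarray], dict[str, list[tuple[int, float]]]]:
    """Place time-sorted events onto the 5-minute grid.

    Each event maps to index ``floor((t - grid_start) / 5 min)`` (half-open
    bins).  For dense kinds a later event in the same slot replaces the
    earlier one with a warning; sparse kinds keep every event.  Events
    outside ``[grid_start, grid end)`` are an error.
    """
    dense = {k: np.full(n_index, np.nan) for k in DENSE_KINDS}
    sparse: dict[str, list[tuple[int, float]]] = {k: [] for k in SPARSE_KINDS}
    for ev in events:
        offset = (ev.timestamp - grid_start).total_seconds() / 60.0
        idx = math.floor(offset / GRID_MINUTES)
        if offset < 0 or idx >= n_index:
            raise DataFormatError(
                f"{ev.kind} event at {ev.timestamp} falls outside grid "
                f"[{grid_start}, +{n_index * GRID_MINUTES} min)"
            )
        if ev.kind in DENSE_KINDS:
            if np.isfinite(dense[ev.kind][idx]):
                warnings.warn(
                    f"two {ev.kind} events in slot {idx}; keeping the later value",
                    stacklevel=2,
                )
            dense[ev.kind][idx] = ev.value
        else:
            sparse[ev.kind].append((idx, ev.value))
    return dense, sparse


def _series_from_events(
    patient_id: str, gender: str, events: list[EventRecord], truth: list[EventRecord] | None = None
) -> PatientSeries:
    if not events:
        return PatientSeries(
            patient_id=patient_id,
            gender=gender,
            grid_start=datetime(2000, 1, 1),
            n_index=0,
            cgm=np.empty(0),
        )
    for kind in EVENT_KINDS:
        stream = [e.timestamp for e in events if e.kind == kind]
        if any(b <= a for a, b in zip(stream, stream[1:])):
            raise DataFormatError(f"timestamps in {kind} stream are not strictly increasing")
    t_min = min(e.timestamp for e in events)
    t_max = max(e.timestamp for e in events)
    grid_start = _floor_to_grid(t_min)
    n_index = math.floor((t_max - grid_start).total_seconds() / 60.0 / GRID_MINUTES) + 1
    dense, sparse = align_to_grid(events, grid_start, n_index)
    steps = dense["steps"]
    steps = np.where(np.isfinite(steps), steps, 0.0)
    truth_bg = None
    if truth:
        truth_bg = np.full(n_index, np.nan)
        for ev in truth:
            idx = math.floor((ev.timestamp - grid_start).total_seconds() / 60.0 / GRID_MINUTES)
            if 0 <= idx < n_index:
                truth_bg[idx] = ev.value
    return PatientSeries(
        patient_id=patient_id,
        gender=gender,
        grid_start=grid_start,
        n_index=n_index,
        cgm=dense["cgm"],
        fingerstick=sparse["fingerstick"],
        bolus_events=sparse["bolus"],
        meal_events=sparse["meal"],
        steps=steps,
        aux={k: dense[k] for k in AUX_KINDS},
        truth_bg=truth_bg,
    )


def read_ohio_xml(path, attr_map: dict[str, str] | None = None) -> PatientSeries:
    """Read an OhioT1DM-style XML patient file.

    The expected layout is a ``<patient>`` root with one child element per
    event kind (``<glucose_level>``, ``<finger_stick>``, ...), each a list of
    ``<event ts="DD-MM-YYYY HH:MM:SS" .../>`` records.  ``attr_map`` maps an
    event kind to the attribute carrying its numeric value, for tolerance to
    schema variants (default: ``value``, except ``dose`` for bolus and
    ``carbs`` for meal).
    """
    value_attr = dict(DEFAULT_VALUE_ATTR)
    if attr_map:
        value_attr.update(attr_map)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise DataFormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "patient":
        raise DataFormatError(f"expected <patient> root element, got <{root.tag}>")
    element_to_kind = {v: k for k, v in XML_ELEMENTS.items()}
    events: list[EventRecord] = []
    for child in root:
        kind = element_to_kind.get(child.tag)
        if kind is None:
            warnings.warn(f"unknown event kind element <{child.tag}> skipped", stacklevel=2)
            continue
        attr = value_attr.get(kind, "value")
        for ev in child.iter("event"):
            ts_text = ev.get("ts")
            val_text = ev.get(attr, ev.get("value"))
            if ts_text is None or val_text is None:
                raise DataFormatError(f"<event> under <{child.tag}> missing ts/{attr} attribute")
            events.append(
                EventRecord(datetime.strptime(ts_text, XML_TS_FORMAT), kind, float(val_text))
            )
    return _series_from_events(root.get("id", "unknown"), root.get("gender", "unknown"), events)


def write_ohio_xml(series: PatientSeries, path) -> None:
    """Serialize a PatientSeries to the XML layout read by :func:`read_ohio_xml`."""
    root = ET.Element("patient", id=series.patient_id, gender=series.gender)

    def add(kind: str, pairs: Iterable[tuple[int, float]]) -> None:
        parent = ET.SubElement(root, XML_ELEMENTS[kind])
        attr = DEFAULT_VALUE_ATTR.get(kind, "value")
        for idx, val in pairs:
            ET.SubElement(
                parent,
                "event",
                ts=series.index_time(idx).strftime(XML_TS_FORMAT),
                **{attr: repr(float(val))},
            )

    add("cgm", ((i, v) for i, v in enumerate(series.cgm) if np.isfinite(v)))
    add("fingerstick", series.fingerstick)
    add("bolus", series.bolus_events)
    add("meal", series.meal_events)
    add("steps", ((i, v) for i, v in enumerate(series.steps) if v != 0))
    for kind in AUX_KINDS:
        arr = series.aux.get(kind)
        if arr is not None:
            add(kind, ((i, v) for i, v in enumerate(arr) if np.isfinite(v)))
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_csv(path) -> PatientSeries:
    """Read the flat CSV dialect (one row per 5-minute slot).

    Header: ``timestamp,cgm,fingerstick,bolus,meal_carbs,steps,truth_bg``;
    ISO-8601 timestamps; empty cell means missing.
    """
    df = pd.read_csv(path, dtype={"timestamp": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"CSV {path} missing mandatory columns: {missing}")
    if len(df) == 0:
        return PatientSeries(
            patient_id="unknown", grid_start=datetime(2000, 1, 1), n_index=0, cgm=np.empty(0)
        )
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise DataFormatError(f"duplicate timestamp rows in {path} (first: {dup})")
    deltas = ts.diff().dropna()
    if not (deltas == pd.Timedelta(minutes=GRID_MINUTES)).all():
        raise DataFormatError(f"CSV rows in {path} are not on a strict 5-minute grid")
    n = len(df)

    def sparse(col: str) -> list[tuple[int, float]]:
        vals = pd.to_numeric(df[col], errors="raise")
        return [(int(i), float(v)) for i, v in enumerate(vals) if np.isfinite(v)]

    steps = pd.to_numeric(df["steps"], errors="raise").to_numpy(dtype=float)
    steps = np.where(np.isfinite(steps), steps, 0.0)
    truth = pd.to_numeric(df["truth_bg"], errors="raise").to_numpy(dtype=float)
    return PatientSeries(
        patient_id="unknown",
        grid_start=ts.iloc[0].to_pydatetime(),
        n_index=n,
        cgm=pd.to_numeric(df["cgm"], errors="raise").to_numpy(dtype=float),
        fingerstick=sparse("fingerstick"),
        bolus_events=sparse("bolus"),
        meal_events=sparse("meal_carbs"),
        steps=steps,
        truth_bg=None if np.all(np.isnan(truth)) else truth,
    )


def write_csv(series: PatientSeries, path) -> None:
    """Write the CSV dialect; floats at full (repr) precision for exact round trips."""
    n = series.n_index
    cols: dict[str, list[str]] = {c: [""] * n for c in CSV_COLUMNS}
    cols["timestamp"] = [series.index_time(i).isoformat() for i in range(n)]

    def fmt(v: float) -> str:
        return repr(float(v))

    for i, v in enumerate(series.cgm):
        if np.isfinite(v):
            cols["cgm"][i] = fmt(v)
    for idx, v in series.fingerstick:
        cols["fingerstick"][idx] = fmt(v)
    for idx, v in series.bolus_events:
        cols["bolus"][idx] = fmt(v)
    for idx, v in series.meal_events:
        cols["meal_carbs"][idx] = fmt(v)
    cols["steps"] = [fmt(v) for v in series.steps]
    if series.truth_bg is not None:
        for i, v in enumerate(series.truth_bg):
            if np.isfinite(v):
                cols["truth_bg"][i] = fmt(v)
    pd.DataFrame(cols, columns=CSV_COLUMNS).to_csv(path, index=False)
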