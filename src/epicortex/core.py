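"""Domain types and text-format I/O shared by every analysis stage.

The recording model: sorted single units (spike times in seconds, a mean
waveform in microvolts sampled at a known rate, a laminar channel 1-23),
spontaneous-population-activity (SPA) events whose LFPg peak defines time
zero, and non-overlapping pharmacological epochs (control / APV /
NBQX+APV / washout) of up to 300 s each.

Files are plain delimited text so fixtures stay inspectable and diff-able:
``spikes.tsv`` with columns (unit_id, time_s, channel), a waveform sidecar
with one row per sample, and SPA events as (event_time_s, location).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("epicortex")

EPOCH_LABELS = ("control", "APV", "NBQX+APV", "washout")
LAYER_LABELS = ("supragranular", "granular", "infragranular")

#: Target epoch duration per pharmacological condition, seconds.
EPOCH_TARGET_S = 300.0

#: Default guard trimmed from both ends of each annotated block, seconds.
#: Transitions between bathing solutions are not instantaneous; the
#: guarded margin removes intervals considered transitionary.
DEFAULT_GUARD_S = 30.0


class FormatError(ValueError):
    """Raised when an input file violates the declared contract."""


@dataclass
class Unit:
    """One sorted single unit."""

    unit_id: str
    spike_times: np.ndarray  # seconds, strictly increasing
    channel: int  # laminar contact, 1..23
    mean_waveform: np.ndarray | None = None  # microvolts
    waveform_fs: float | None = None  # Hz

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise FormatError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )
        if not (1 <= int(self.channel) <= 23):
            raise FormatError(f"unit {self.unit_id}: channel {self.channel} outside 1-23")
        if self.mean_waveform is not None:
            self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)
            if self.mean_waveform.size < 32:
                raise FormatError(
                    f"unit {self.unit_id}: waveform needs >= 32 samples, "
                    f"got {self.mean_waveform.size}"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class UnitSet:
    """A collection of simultaneously recorded units."""

    units: list[Unit]
    recording_duration: float  # seconds
    sampling_rate_waveform: float | None = None  # Hz

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise FormatError("unit ids must be unique")
        for u in self.units:
            if u.spike_times.size and (
                u.spike_times[0] < 0 or u.spike_times[-1] > self.recording_duration + 1e-9
            ):
                raise FormatError(
                    f"unit {u.unit_id}: spike times outside [0, recording_duration]"
                )

    def __len__(self) -> int:
        return len(self.units)

    def __getitem__(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]


@dataclass
class LayerMap:
    """Laminar channel -> cortical layer assignment.

    Defaults follow the usual laminar probe geometry (contacts 1-8
    supragranular, 9-13 granular, 14-23 infragranular); a per-recording
    override table wins where the cortical thickness required correction.
    """

    supragranular: tuple[int, int] = (1, 8)
    granular: tuple[int, int] = (9, 13)
    infragranular: tuple[int, int] = (14, 23)
    overrides: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, lab in self.overrides.items():
            if lab not in LAYER_LABELS:
                raise FormatError(f"override for channel {ch}: unknown layer {lab!r}")


def layer_of(channel: int, layer_map: LayerMap | None = None) -> str:
    """Map a laminar channel (1-23) to its cortical layer label."""
    layer_map = layer_map or LayerMap()
    channel = int(channel)
    if not (1 <= channel <= 23):
        raise FormatError(f"channel {channel} outside 1-23")
    if channel in layer_map.overrides:
        return layer_map.overrides[channel]
    for label in LAYER_LABELS:
        lo, hi = getattr(layer_map, label)
        if lo <= channel <= hi:
            return label
    raise FormatError(f"channel {channel} not covered by layer map")


@dataclass
class Epoch:
    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Half-open membership [start, end)."""
        t = np.asarray(t)
        return (t >= self.start) & (t < self.end)


@dataclass
class EpochSet:
    epochs: list[Epoch]
    transition_gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.epochs:
            if e.label not in EPOCH_LABELS:
                raise FormatError(f"unknown epoch label {e.label!r}")
            if e.duration > EPOCH_TARGET_S + 1e-9:
                raise FormatError(f"epoch {e.label}: duration {e.duration:.1f}s > 300s")
        starts = sorted((e.start, e.end) for e in self.epochs)
        for (s0, e0), (s1, _) in zip(starts, starts[1:]):
            if s1 < e0 - 1e-9:
                raise FormatError("epochs overlap")

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def by_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]


def segment_epochs(
    annotations: list[tuple[str, float, float]],
    guard_s: float = DEFAULT_GUARD_S,
    target_s: float = EPOCH_TARGET_S,
) -> EpochSet:
    """Cut guarded, <=300-s analysis epochs out of condition annotations.

    Each annotated block is trimmed by ``guard_s`` at both ends (rejecting
    intervals considered transitionary between two bathing solutions) and
    capped at ``target_s`` measured from the trimmed start.  Time not
    covered by an emitted epoch is recorded as a transition gap.
    """
    anns = sorted(annotations, key=lambda a: a[1])
    for (l0, s0, e0), (l1, s1, e1) in zip(anns, anns[1:]):
        if s1 < e0 - 1e-9:
            raise FormatError(f"annotations {l0!r} and {l1!r} overlap")
    epochs: list[Epoch] = []
    gaps: list[tuple[float, float]] = []
    for label, start, end in anns:
        if label not in EPOCH_LABELS:
            raise FormatError(f"unknown condition label {label!r}")
        if end <= start:
            raise FormatError(f"annotation {label!r}: end <= start")
        lo = start + guard_s
        hi = min(end - guard_s, lo + target_s)
        if hi <= lo:
            log.warning("annotation %s [%g, %g]: shorter than twice the guard, dropped",
                        label, start, end)
            gaps.append((start, end))
            continue
        if hi - lo < target_s:
            log.info("epoch %s: only %.1f s available (< %.0f s target)",
                     label, hi - lo, target_s)
        epochs.append(Epoch(label, lo, hi))
        if lo > start:
            gaps.append((start, lo))
        if hi < end:
            gaps.append((hi, end))
    return EpochSet(epochs, gaps)


@dataclass
class SPAEventSet:
    """Recurring population-burst events of one SPA.

    ``event_times`` are the LFPg peak times (time zero of every
    event-related analysis).  Optional per-event traces share a common
    millisecond time base ``trace_time_ms``.
    """

    event_times: np.ndarray  # seconds, ascending
    location_label: str = "supragranular"
    lfpg_traces: np.ndarray | None = None  # (n_events, n_samples), microvolts
    mua_traces: np.ndarray | None = None
    trace_time_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.size and np.any(np.diff(self.event_times) <= 0):
            raise FormatError("SPA event times must be strictly increasing")
        if self.location_label not in LAYER_LABELS + ("mixed",):
            raise FormatError(f"unknown SPA location {self.location_label!r}")
        for tr in (self.lfpg_traces, self.mua_traces):
            if tr is not None:
                tr = np.asarray(tr)
                if self.trace_time_ms is None:
                    raise FormatError("traces present but no common time base")
                if tr.shape != (self.event_times.size, self.trace_time_ms.size):
                    raise FormatError("trace array shape does not match events/time base")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


# ---------------------------------------------------------------------------
# readers / writers

_TIME_FMT = "%.6f"


def write_units(unitset: UnitSet, spikes_path: str | Path,
                waveforms_path: str | Path | None = None) -> None:
    """Write spikes (and optionally waveforms) as delimited text."""
    spikes_path = Path(spikes_path)
    rows = []
    for u in unitset.units:
        for t in u.spike_times:
            rows.append((u.unit_id, t, u.channel))
    df = pd.DataFrame(rows, columns=["unit_id", "time_s", "channel"])
    with open(spikes_path, "w") as fh:
        fh.write(f"# recording_duration_s={unitset.recording_duration:.6f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_TIME_FMT)
    if waveforms_path is not None:
        wrows = []
        for u in unitset.units:
            if u.mean_waveform is None:
                continue
            for i, v in enumerate(u.mean_waveform):
                wrows.append((u.unit_id, i, v))
        wdf = pd.DataFrame(wrows, columns=["unit_id", "sample_index", "voltage_uv"])
        with open(waveforms_path, "w") as fh:
            fs = unitset.sampling_rate_waveform or 0.0
            fh.write(f"# sampling_rate_hz={fs:.6f}\n")
            wdf.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def _read_header_value(path: Path, key: str) -> float | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and key in first:
        return float(first.split("=", 1)[1])
    return None


def load_units(spikes_path: str | Path,
               waveforms_path: str | Path | None = None) -> UnitSet:
    """Load a spike-event table (and optional waveform sidecar).

    Rejects duplicate timestamps within a unit and channels outside 1-23.
    Recording duration is taken from the ``# recording_duration_s`` header
    when present, otherwise from the last spike.
    """
    spikes_path = Path(spikes_path)
    duration = _read_header_value(spikes_path, "recording_duration_s")
    df = pd.read_csv(spikes_path, sep="\t", comment="#")
    for col in ("unit_id", "time_s", "channel"):
        if col not in df.columns:
            raise FormatError(f"{spikes_path}: missing column {col!r}")

    waveforms: dict[str, np.ndarray] = {}
    fs = None
    if waveforms_path is not None:
        waveforms_path = Path(waveforms_path)
        fs = _read_header_value(waveforms_path, "sampling_rate_hz")
        wdf = pd.read_csv(waveforms_path, sep="\t", comment="#")
        for uid, g in wdf.groupby("unit_id", sort=False):
            waveforms[str(uid)] = (
                g.sort_values("sample_index")["voltage_uv"].to_numpy(dtype=float)
            )

    units = []
    for uid, g in df.groupby("unit_id", sort=False):
        uid = str(uid)
        times = np.sort(g["time_s"].to_numpy(dtype=float))
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise FormatError(f"unit {uid}: duplicate spike timestamps")
        channels = g["channel"].unique()
        if len(channels) != 1:
            raise FormatError(f"unit {uid}: inconsistent channel assignment")
        units.append(Unit(uid, times, int(channels[0]),
                          mean_waveform=waveforms.get(uid), waveform_fs=fs))
    if duration is None:
        duration = max((u.spike_times[-1] for u in units if u.n_spikes), default=0.0)
    return UnitSet(units, recording_duration=float(duration),
                   sampling_rate_waveform=fs)


def write_spa_events(events: SPAEventSet, path: str | Path) -> None:
    df = pd.DataFrame({"event_time_s": events.event_times})
    df["location"] = events.location_label
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format=_TIME_FMT)


def load_spa_events(path: str | Path) -> SPAEventSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    loc = str(df["location"].iloc[0]) if len(df) else "supragranular"
    return SPAEventSet(df["event_time_s"].to_numpy(dtype=float), loc)


def load_epoch_annotations(path: str | Path) -> list[tuple[str, float, float]]:
    """Read condition annotations from a YAML list of {label, start_s, end_s}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [(str(d["label"]), float(d["start_s"]), float(d["end_s"])) for d in raw]


def write_epoch_annotations(annotations: list[tuple[str, float, float]],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [{"label": l, "start_s": float(s), "end_s": float(e)}
             for l, s, e in annotations], fh)
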