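"""Sunrise-anchored scheduling: solar computation, sampling grids, scenario
enumeration, record subsetting, and sample-accurate WAV cutting.

Sunrise is defined as the moment the top edge of the solar disc reaches the
horizon, i.e. solar zenith 90.833 deg (16' semi-diameter + 34' standard
refraction), computed with the NOAA solar-position equations. A
user-supplied sunrise table always overrides computation.
"""

from __future__ import annotations

import math
import wave
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, time, timedelta, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import NoSunriseError, SchedulingWindowError, SunriseLookupError
from .model import (
    BASE_STEP_MIN,
    DAY_PHASES,
    DetectionRecord,
    Phase,
    Scenario,
    phase_offsets,
)

#: Recorders run continuously across this local clock window each day.
RECORDING_WINDOW = (time(4, 30), time(11, 0))

_SUNRISE_ZENITH_DEG = 90.833


# ---------------------------------------------------------------------------
# Solar computation (NOAA solar-position equations)

def _noaa_sun_events_minutes(latitude: float, longitude: float, d: Date, utc_offset: float) -> tuple[float, float, float]:
    """(sunrise, solar noon, sunset) in minutes after local midnight.

    Implements the NOAA general solar-position calculation evaluated at
    local noon of the given civil date; accuracy is about one minute at
    non-polar latitudes, well inside the +/-2 min contract.
    """
    # Julian day for local noon
    days = (d - Date(2000, 1, 1)).days + 2451544.5
    jd = days + 0.5 - utc_offset / 24.0
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eccent = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    decl = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))

    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    i = math.radians(geom_mean_long)
    eot = 4.0 * math.degrees(
        var_y * math.sin(2 * i)
        - 2.0 * eccent * math.sin(m)
        + 4.0 * eccent * var_y * math.sin(m) * math.cos(2 * i)
        - 0.5 * var_y * var_y * math.sin(4 * i)
        - 1.25 * eccent * eccent * math.sin(2 * m)
    )

    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(_SUNRISE_ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if cos_ha > 1.0 or cos_ha < -1.0:
        raise NoSunriseError(
            f"sun does not cross the horizon at latitude {latitude} on {d.isoformat()} (polar day/night)"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    solar_noon = 720.0 - 4.0 * longitude - eot + utc_offset * 60.0
    return solar_noon - 4.0 * ha_deg, solar_noon, solar_noon + 4.0 * ha_deg


def compute_sunrise(latitude: float, longitude: float, d: Date, utc_offset: float) -> datetime:
    """Local-clock sunrise (top edge of the sun on the horizon).

    Returns a timezone-aware datetime, rounded to the nearest second so
    downstream audio cuts have a defined sample boundary.

    Raises
    ------
    NoSunriseError
        On polar day/night (no horizon crossing).
    """
    if not (-90.0 <= latitude <= 90.0):
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    if not (-180.0 <= longitude <= 180.0):
        raise ValueError(f"longitude {longitude} outside [-180, 180]")
    sunrise_min, _, _ = _noaa_sun_events_minutes(latitude, longitude, d, utc_offset)
    tz = timezone(timedelta(hours=utc_offset))
    midnight = datetime.combine(d, time(0, 0), tzinfo=tz)
    seconds = round(sunrise_min * 60.0)
    return midnight + timedelta(seconds=seconds)


def compute_solar_noon(latitude: float, longitude: float, d: Date, utc_offset: float) -> datetime:
    """Local-clock solar noon (transit), rounded to the nearest second."""
    _, noon_min, _ = _noaa_sun_events_minutes(latitude, longitude, d, utc_offset)
    tz = timezone(timedelta(hours=utc_offset))
    return datetime.combine(d, time(0, 0), tzinfo=tz) + timedelta(seconds=round(noon_min * 60.0))


def compute_sunset(latitude: float, longitude: float, d: Date, utc_offset: float) -> datetime:
    """Local-clock sunset (top edge leaves the horizon), nearest second."""
    _, _, sunset_min = _noaa_sun_events_minutes(latitude, longitude, d, utc_offset)
    tz = timezone(timedelta(hours=utc_offset))
    return datetime.combine(d, time(0, 0), tzinfo=tz) + timedelta(seconds=round(sunset_min * 60.0))


@dataclass(frozen=True, slots=True)
class SolarContext:
    """Coordinates + date + UTC offset with the derived sunrise time."""

    latitude: float
    longitude: float
    date: Date
    utc_offset: float

    @property
    def sunrise(self) -> datetime:
        return compute_sunrise(self.latitude, self.longitude, self.date, self.utc_offset)


# ---------------------------------------------------------------------------
# Sampling grid and scenarios

def build_sampling_grid(phases: Iterable[str | Phase], base_step_min: int = BASE_STEP_MIN) -> list[int]:
    """Window-start offsets (minutes from sunrise) for the given phases,
    sorted ascending. ``{dawn}`` yields 20 offsets starting at -60."""
    phase_set = {Phase(p) for p in phases}
    if not phase_set:
        raise ValueError("at least one phase required")
    offsets: list[int] = []
    for phase in sorted(phase_set, key=lambda p: p.start):
        offsets.extend(phase_offsets(phase, base_step_min))
    return offsets


def enumerate_scenarios(
    intensities: Sequence[int] = (3, 6, 15, 30, 60),
    phases: Sequence[str] = DAY_PHASES,
    durations: Sequence[int] = (1, 2, 3, 4),
) -> list[Scenario]:
    """Full factorial of the three gradients, ordered (intensity, phase,
    duration) — the default design grid gives 60 scenarios spanning 1-160
    annotation minutes."""
    scenarios = [
        Scenario(i, p, d)
        for i in sorted(set(intensities))
        for p in [p for p in DAY_PHASES if p in set(phases)]
        for d in sorted(set(durations))
    ]
    if not scenarios:
        raise ValueError("empty scenario grid")
    return scenarios


def subset_records(records: Iterable[DetectionRecord], scenario: Scenario) -> list[DetectionRecord]:
    """Pure filter selecting the records a scenario would have annotated.

    Keeps records with ``day_index <= duration_days`` (first-d-days rule),
    phase among the scenario's phases, and offset on the intensity grid
    anchored at the phase start. Because every intensity grid anchored at
    the phase start is a subset of each finer grid that divides it, outputs
    nest along intensity chains and along durations.
    """
    phases = set(scenario.phases)
    k = scenario.intensity_min
    return [
        r
        for r in records
        if r.day_index <= scenario.duration_days
        and r.phase in phases
        and (r.offset_min - r.phase.start) % k == 0
    ]


# ---------------------------------------------------------------------------
# Cut schedules and WAV cutting

@dataclass(frozen=True, slots=True)
class CutEntry:
    plot_id: str
    day_index: int
    offset_min: int
    clock_start: datetime
    duration_s: int = 60

    @property
    def name(self) -> str:
        """Deterministic segment name: plot_day_offset."""
        return f"{self.plot_id}_d{self.day_index}_m{self.offset_min:+04d}"


@dataclass(frozen=True)
class CutSchedule:
    """Ordered 1-min cut entries, unique on (plot, day, offset)."""

    entries: tuple[CutEntry, ...]
    recording_window: tuple[time, time] = RECORDING_WINDOW

    def __post_init__(self) -> None:
        keys = [(e.plot_id, e.day_index, e.offset_min) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (plot, day, offset) entries in cut schedule")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot": [e.plot_id for e in self.entries],
                "day": [e.day_index for e in self.entries],
                "offset_min": [e.offset_min for e in self.entries],
                "clock_start": [e.clock_start.isoformat() for e in self.entries],
                "duration_s": [e.duration_s for e in self.entries],
            }
        )


def build_cut_schedule(
    sunrise_map: Mapping[tuple[str, Date], datetime],
    scenario: Scenario,
    *,
    recording_window: tuple[time, time] = RECORDING_WINDOW,
) -> CutSchedule:
    """One cut entry per (plot, day, retained offset) of a scenario.

    Days per plot are the sorted dates present in ``sunrise_map``; the
    scenario's duration selects the first d of them (day_index 1..d).
    ``clock_start = sunrise + offset``, rounded to the nearest second.
    Entries outside the recording window abort with all offenders listed.
    """
    per_plot: dict[str, list[Date]] = {}
    for plot, d in sorted(sunrise_map):
        per_plot.setdefault(plot, []).append(d)
    offsets = [
        o
        for o in build_sampling_grid([p.value for p in scenario.phases])
        if (o - (Phase.DAWN.start if o < 0 else Phase.MORNING.start)) % scenario.intensity_min == 0
    ]
    entries: list[CutEntry] = []
    violations: list[str] = []
    for plot, dates in per_plot.items():
        if len(dates) < scenario.duration_days:
            raise SunriseLookupError(
                f"plot {plot}: {len(dates)} sunrise dates available, scenario needs {scenario.duration_days}"
            )
        for day_index, d in enumerate(dates[: scenario.duration_days], start=1):
            sunrise = sunrise_map[(plot, d)]
            for o in offsets:
                start = sunrise + timedelta(minutes=o)
                if start.microsecond:  # round to nearest second for a defined sample boundary
                    start = (start + timedelta(microseconds=500_000)).replace(microsecond=0)
                t = start.timetz().replace(tzinfo=None)
                if not (recording_window[0] <= t and _end_time(start) <= recording_window[1]):
                    violations.append(f"{plot} {d.isoformat()} offset {o} -> {start.isoformat()}")
                entries.append(CutEntry(plot, day_index, o, start))
    if violations:
        raise SchedulingWindowError(
            "scheduled cuts outside recording window "
            f"[{recording_window[0]}, {recording_window[1]}]: " + "; ".join(violations)
        )
    return CutSchedule(tuple(entries), recording_window)


def _end_time(start: datetime) -> time:
    return (start + timedelta(seconds=60)).timetz().replace(tzinfo=None)


def cut_wav_segments(
    wav_path: str | Path,
    entries: Sequence[CutEntry],
    out_dir: str | Path,
    *,
    file_start: datetime,
) -> dict[str, str]:
    """Cut sample-accurate 60-s segments out of a long PCM WAV recording.

    ``file_start`` is the clock time of the recording's first sample; each
    entry's position in the file is ``clock_start - file_start``. Segments
    are exactly ``60 * sample_rate`` frames, with sample rate, bit depth
    and channel count preserved. A segment outside the file span raises
    (no partial or zero-padded output is ever written).

    Returns a {segment name: output path} manifest.
    """
    wav_path, out_dir = Path(wav_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    with wave.open(str(wav_path), "rb") as src:
        if src.getcomptype() != "NONE":
            raise ValueError(f"{wav_path}: only uncompressed PCM WAV is supported (got {src.getcomptype()})")
        rate = src.getframerate()
        n_frames = src.getnframes()
        seg_frames = 60 * rate
        for entry in entries:
            delta = (entry.clock_start - file_start).total_seconds()
            start_frame = round(delta * rate)
            if start_frame < 0 or start_frame + seg_frames > n_frames:
                raise ValueError(
                    f"segment {entry.name} spans frames [{start_frame}, {start_frame + seg_frames}) "
                    f"outside file span [0, {n_frames})"
                )
            src.setpos(start_frame)
            data = src.readframes(seg_frames)
            out_path = out_dir / f"{entry.name}.wav"
            with wave.open(str(out_path), "wb") as dst:
                dst.setnchannels(src.getnchannels())
                dst.setsampwidth(src.getsampwidth())
                dst.setframerate(rate)
                dst.writeframes(data)
            manifest[entry.name] = str(out_path)
    return manifest
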