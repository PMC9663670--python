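"""From plot coordinates to sample-accurate 1-min audio cuts.

Computes sunrise for a Black Forest plot, builds the cut schedule for a
scenario, and cuts the 1-min segments out of a (synthetic) continuous
recording, preserving sample rate and bit depth exactly.
"""

import tempfile
import wave
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path

import numpy as np

from chorus_effort import Scenario, build_cut_schedule, compute_sunrise, cut_wav_segments

lat, lon, tz_hours = 48.0, 8.2, 2.0
days = [date(2021, 5, 10) + timedelta(days=i) for i in range(2)]
sunrise_map = {("P01", d): compute_sunrise(lat, lon, d, tz_hours) for d in days}
for (plot, d), t in sunrise_map.items():
    print(f"sunrise {plot} {d}: {t.time()}")

scenario = Scenario(30, "dawn", 2)
schedule = build_cut_schedule(sunrise_map, scenario)
print(f"\nscenario {scenario}: {len(schedule.entries)} one-minute cuts")
for e in schedule.entries:
    print(f"  day {e.day_index}  offset {e.offset_min:+d} min  starts {e.clock_start.timetz()}")

# synthesize a continuous recording covering day 1 (10 min around dawn)
with tempfile.TemporaryDirectory() as tmp:
    rate = 22050
    file_start = schedule.entries[0].clock_start - timedelta(minutes=2)
    n = rate * 60 * 40
    samples = (3000 * np.sin(2 * np.pi * 600 * np.arange(n) / rate)).astype("<i2")
    wav = Path(tmp) / "continuous.wav"
    with wave.open(str(wav), "wb") as fh:
        fh.setnchannels(1); fh.setsampwidth(2); fh.setframerate(rate)
        fh.writeframes(samples.tobytes())

    day1 = [e for e in schedule.entries if e.day_index == 1]
    manifest = cut_wav_segments(wav, day1, Path(tmp) / "cuts", file_start=file_start)
    print(f"\ncut {len(manifest)} segments; each exactly {60 * rate} frames:")
    for name, path in manifest.items():
        with wave.open(path, "rb") as fh:
            print(f"  {name}.wav  {fh.getnframes()} frames @ {fh.getframerate()} Hz")
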