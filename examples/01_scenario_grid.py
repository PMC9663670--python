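"""Enumerate the effort-allocation design grid.

Builds the full factorial of intensity (1-min windows every 3/6/15/30/60
min) x day phase (dawn, morning, both) x duration (1-4 days) and prints
how much manual annotation each scenario costs.
"""

from chorus_effort import Scenario, build_sampling_grid, enumerate_scenarios

scenarios = enumerate_scenarios()
print(f"{len(scenarios)} scenarios in the full factorial")
print(f"dawn base grid: {len(build_sampling_grid(['dawn']))} one-minute windows per hour")
print(f"annotation minutes span {min(s.n_minutes for s in scenarios)}"
      f"-{max(s.n_minutes for s in scenarios)} per plot")

cheap = [s for s in scenarios if s.n_minutes <= 20]
print(f"\n{len(cheap)} scenarios cost no more than a 20-min point count:")
for s in sorted(cheap, key=lambda s: s.n_minutes):
    print(f"  every {s.intensity_min:>2} min | {s.day_phase:<7} | {s.duration_days} day(s) "
          f"-> {s.n_minutes:>2} min of audio")

# The maximal scenario defines the files to cut from continuous audio:
maximal = Scenario(3, "both", 4)
print(f"\nmaximal scenario needs {maximal.n_minutes} files per plot "
      f"({maximal.n_minutes * 17} for a 17-plot campaign)")
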