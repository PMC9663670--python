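"""Synthetic dawn-chorus detection data with known ground truth.

Emulates the statistical structure the analysis assumes: a community of
species with unimodal, species-specific vocal-activity envelopes over
time-of-day, per-plot occupancy, and independent per-window detection.
Four archetypes span the phenology the design probes:

* ``early_caller``     — dawn specialists peaking well before sunrise
                         (robin/thrush-like), high occupancy;
* ``persistent``       — generalists with wide envelopes spanning both
                         phases (chaffinch/tit-like);
* ``morning_biased``   — species mostly active in the post-dawn morning
                         hour (late-calling, low-density forest species);
* ``crepuscular_rare`` — rare owl/woodcock-like species: narrow pre-dawn
                         activity, low occupancy and detectability.

Detection probability of species s in a 1-min window starting at offset
t (minutes from sunrise) is a Gaussian envelope

    p_s(t) = p_max * exp(-(t - mu)^2 / (2 sigma^2)),

occupancy is Bernoulli(psi) per plot (fixed across the recording days),
and detections are independent Bernoulli(p_s(t)) per occupied plot, day
and base-grid window. The archetype parameter values are illustrative
defaults for a temperate-forest breeding community, not estimates fitted
to any particular dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import DetectionRecord, Phase, phase_offsets

ARCHETYPES = ("early_caller", "persistent", "morning_biased", "crepuscular_rare")

#: Default archetype mix (fractions of the community).
DEFAULT_MIX: dict[str, float] = {
    "early_caller": 0.20,
    "persistent": 0.40,
    "morning_biased": 0.30,
    "crepuscular_rare": 0.10,
}

# (mu center, mu jitter, sigma center, sigma jitter, psi range, p_max range)
_ARCHETYPE_PARAMS: dict[str, tuple[float, float, float, float, tuple[float, float], tuple[float, float]]] = {
    "early_caller": (-40.0, 10.0, 20.0, 5.0, (0.60, 0.90), (0.10, 0.30)),
    "persistent": (60.0, 30.0, 110.0, 20.0, (0.45, 0.80), (0.08, 0.25)),
    "morning_biased": (200.0, 15.0, 25.0, 8.0, (0.35, 0.70), (0.08, 0.30)),
    "crepuscular_rare": (-55.0, 4.0, 12.0, 4.0, (0.08, 0.20), (0.02, 0.08)),
}

_ARCHETYPE_PREFIX = {
    "early_caller": "EAR",
    "persistent": "PER",
    "morning_biased": "MOR",
    "crepuscular_rare": "CRE",
}


@dataclass(frozen=True, slots=True)
class SpeciesProfile:
    """Occupancy and time-of-day activity of one simulated species."""

    species_code: str
    archetype: str
    psi: float  # probability a plot is occupied
    mu: float  # activity peak, minutes relative to sunrise
    sigma: float  # activity envelope width, minutes
    p_max: float  # per-window detection probability at the peak

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"psi={self.psi} outside [0, 1]")
        if not (0.0 <= self.p_max <= 1.0):
            raise ValueError(f"p_max={self.p_max} outside [0, 1]")
        if self.sigma <= 0:
            raise ValueError(f"sigma={self.sigma} must be > 0")

    def detection_prob(self, offset_min: float) -> float:
        """p_s(t): Gaussian activity envelope evaluated at a window start."""
        z = (offset_min - self.mu) / self.sigma
        return self.p_max * math.exp(-0.5 * z * z)


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Study-design parameters of a simulated campaign.

    Defaults reproduce the field design: 17 plots recorded over 4
    good-weather days, both one-hour phases sampled on the 3-min grid.
    """

    n_plots: int = 17
    n_days: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.n_days < 1:
            raise ValueError("n_plots and n_days must be positive")

    @property
    def plot_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i:02d}" for i in range(1, self.n_plots + 1))


def _allocate_counts(n_species: int, mix: Mapping[str, float]) -> dict[str, int]:
    """At least one species per archetype, remainder by largest-remainder
    apportionment of the mix fractions."""
    total = sum(mix.values())
    rest = n_species - len(ARCHETYPES)
    quotas = {a: rest * mix[a] / total for a in ARCHETYPES}
    counts = {a: 1 + int(math.floor(quotas[a])) for a in ARCHETYPES}
    leftover = n_species - sum(counts.values())
    by_remainder = sorted(ARCHETYPES, key=lambda a: quotas[a] - math.floor(quotas[a]), reverse=True)
    for a in by_remainder[:leftover]:
        counts[a] += 1
    return counts


def default_community(
    n_species: int = 50,
    seed: int = 0,
    *,
    mix: Mapping[str, float] | None = None,
) -> list[SpeciesProfile]:
    """A seeded community of species profiles mixing the four archetypes.

    Per-species parameters are drawn around the archetype centres so no
    two species are identical; deterministic for a given seed.
    """
    if n_species < len(ARCHETYPES):
        raise ValueError(f"need at least {len(ARCHETYPES)} species (one per archetype)")
    mix = dict(mix or DEFAULT_MIX)
    if set(mix) != set(ARCHETYPES) or any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
        raise ValueError(f"mix must assign non-negative weight to each of {ARCHETYPES}")
    counts = _allocate_counts(n_species, mix)
    rng = np.random.default_rng(seed)
    profiles: list[SpeciesProfile] = []
    for archetype in ARCHETYPES:
        mu0, mu_j, sg0, sg_j, psi_rng, pmax_rng = _ARCHETYPE_PARAMS[archetype]
        for i in range(1, counts[archetype] + 1):
            profiles.append(
                SpeciesProfile(
                    species_code=f"{_ARCHETYPE_PREFIX[archetype]}{i:02d}",
                    archetype=archetype,
                    psi=float(rng.uniform(*psi_rng)),
                    mu=float(rng.uniform(mu0 - mu_j, mu0 + mu_j)),
                    sigma=float(max(rng.uniform(sg0 - sg_j, sg0 + sg_j), 1.0)),
                    p_max=float(rng.uniform(*pmax_rng)),
                )
            )
    return profiles


def simulate_detections(
    profiles: Sequence[SpeciesProfile],
    config: SimulationConfig,
) -> tuple[list[DetectionRecord], dict[str, frozenset[str]]]:
    """Simulate the full base-grid annotation table plus the true occupancy.

    Per plot and species, occupancy ~ Bernoulli(psi), constant across
    days; per occupied plot, day, and base-grid offset an independent
    Bernoulli(p_s(t)) detection. Returns records in deterministic
    (plot, day, offset, species) order and the species -> occupied-plots
    truth map. Byte-identical output for identical seed and config.
    """
    offsets = phase_offsets(Phase.DAWN) + phase_offsets(Phase.MORNING)
    rng = np.random.default_rng(config.seed)
    plots = config.plot_ids
    S = len(profiles)

    occ = rng.random((config.n_plots, S)) < np.array([p.psi for p in profiles])
    p_t = np.array([[p.detection_prob(o) for o in offsets] for p in profiles])  # (S, O)
    draws = rng.random((config.n_plots, config.n_days, len(offsets), S))
    detected = draws < p_t.T[None, None, :, :]  # broadcast (O, S)
    detected &= occ[:, None, None, :]

    records: list[DetectionRecord] = []
    for pi, plot in enumerate(plots):
        for day in range(1, config.n_days + 1):
            for oi, offset in enumerate(offsets):
                for si in np.nonzero(detected[pi, day - 1, oi])[0]:
                    records.append(DetectionRecord(plot, day, offset, profiles[si].species_code))
    truth = {
        p.species_code: frozenset(plots[j] for j in np.nonzero(occ[:, si])[0])
        for si, p in enumerate(profiles)
    }
    return records, truth
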