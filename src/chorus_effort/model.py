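"""Core domain types for annotation-effort allocation analyses.

The sampling design is anchored to local sunrise: every 1-min annotation
window is identified by the signed minute offset of its start relative to
sunrise. Two one-hour day phases are sampled on a 3-min base grid:

* ``dawn``    — the hour before sunrise, window starts in [-60, 0);
* ``morning`` — the hour beginning 3 h after sunrise, starts in [180, 240).

Windows are half-open and labelled by their start minute, so each phase
contains exactly 20 base-grid slots (60 / 3).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASE_STEP_MIN = 3
DAWN_START = -60
DAWN_END = 0
MORNING_START = 180
MORNING_END = 240

#: The intensity gradient: one 1-min window every ``k`` minutes.
INTENSITIES = (3, 6, 15, 30, 60)
#: The duration gradient: number of recording days in the subset.
DURATIONS = (1, 2, 3, 4)
#: Day-phase gradient values accepted by :class:`Scenario`.
DAY_PHASES = ("dawn", "morning", "both")


class Phase(str, enum.Enum):
    """One of the two one-hour day phases."""

    DAWN = "dawn"
    MORNING = "morning"

    @property
    def start(self) -> int:
        return DAWN_START if self is Phase.DAWN else MORNING_START

    @property
    def end(self) -> int:
        return DAWN_END if self is Phase.DAWN else MORNING_END


PHASE_START = {Phase.DAWN: DAWN_START, Phase.MORNING: MORNING_START}


def phase_offsets(phase: Phase, base_step_min: int = BASE_STEP_MIN) -> list[int]:
    """Base-grid window-start offsets (minutes from sunrise) for one phase."""
    return list(range(phase.start, phase.end, base_step_min))


def phase_of_offset(offset_min: int) -> Phase:
    """Map a base-grid offset to its phase.

    Raises
    ------
    ValueError
        If the offset does not lie on the 3-min base grid of either phase.
    """
    if DAWN_START <= offset_min < DAWN_END:
        phase = Phase.DAWN
    elif MORNING_START <= offset_min < MORNING_END:
        phase = Phase.MORNING
    else:
        raise ValueError(f"offset {offset_min} outside dawn [-60,0) and morning [180,240) windows")
    if (offset_min - phase.start) % BASE_STEP_MIN != 0:
        raise ValueError(f"offset {offset_min} not on the {BASE_STEP_MIN}-min base grid")
    return phase


@dataclass(frozen=True, slots=True)
class DetectionRecord:
    """One species detection in one 1-min window of one plot-day.

    ``offset_min`` is the window start in minutes relative to sunrise and
    must lie on the base grid; ``day_index`` is 1-based within the selected
    good-weather recording days, in chronological order.
    """

    plot_id: str
    day_index: int
    offset_min: int
    species_code: str
    genus_only: bool = False

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")
        phase_of_offset(self.offset_min)  # raises if off-grid

    @property
    def phase(self) -> Phase:
        return phase_of_offset(self.offset_min)


@dataclass(frozen=True, slots=True)
class Scenario:
    """An (intensity, day-phase, duration) annotation-effort choice.

    ``intensity_min`` is the spacing between selected 1-min windows; it
    must divide 60 and be a multiple of the 3-min base step so selections
    stay on the base grid and nest across intensities.
    """

    intensity_min: int
    day_phase: str
    duration_days: int

    def __post_init__(self) -> None:
        if self.intensity_min <= 0 or 60 % self.intensity_min != 0 or self.intensity_min % BASE_STEP_MIN != 0:
            raise ValueError(
                f"intensity_min must divide 60 and be a multiple of {BASE_STEP_MIN}, got {self.intensity_min}"
            )
        if self.day_phase not in DAY_PHASES:
            raise ValueError(f"day_phase must be one of {DAY_PHASES}, got {self.day_phase!r}")
        if self.duration_days < 1:
            raise ValueError(f"duration_days must be >= 1, got {self.duration_days}")

    @property
    def phases(self) -> tuple[Phase, ...]:
        if self.day_phase == "both":
            return (Phase.DAWN, Phase.MORNING)
        return (Phase(self.day_phase),)

    @property
    def n_minutes(self) -> int:
        """Total 1-min files to annotate: (60/intensity) x phases x days."""
        return (60 // self.intensity_min) * len(self.phases) * self.duration_days

    @property
    def label(self) -> str:
        return f"i{self.intensity_min:02d}_{self.day_phase}_d{self.duration_days}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class IncidenceMatrix:
    """Plots x species presence/absence with incidence-frequency summaries.

    Attributes
    ----------
    unit_ids : list of str
        Ordered sampling units (plots). Rows.
    species_ids : list of str
        Ordered species codes. Columns.
    cells : ndarray of bool, shape (T, S)
    """

    def __init__(self, unit_ids: Sequence[str], species_ids: Sequence[str], cells: np.ndarray):
        cells = np.asarray(cells, dtype=bool)
        if cells.shape != (len(unit_ids), len(species_ids)):
            raise ValueError(f"cells shape {cells.shape} does not match {len(unit_ids)} units x {len(species_ids)} species")
        if len(set(unit_ids)) != len(unit_ids):
            raise ValueError("duplicate unit ids")
        if len(set(species_ids)) != len(species_ids):
            raise ValueError("duplicate species ids")
        self.unit_ids = list(unit_ids)
        self.species_ids = list(species_ids)
        self.cells = cells

    # -- derived quantities -------------------------------------------------
    @property
    def T(self) -> int:
        """Number of sampling units."""
        return len(self.unit_ids)

    @property
    def incidence_frequencies(self) -> np.ndarray:
        """Y_s: number of units in which species s is present."""
        return self.cells.sum(axis=0).astype(int)

    @property
    def S_obs(self) -> int:
        """Observed species richness (species with Y_s >= 1)."""
        return int((self.incidence_frequencies >= 1).sum())

    @property
    def Q1(self) -> int:
        """Uniques: species present in exactly one unit."""
        return int((self.incidence_frequencies == 1).sum())

    @property
    def Q2(self) -> int:
        """Duplicates: species present in exactly two units."""
        return int((self.incidence_frequencies == 2).sum())

    @property
    def row_richness(self) -> np.ndarray:
        """Species count per sampling unit."""
        return self.cells.sum(axis=1).astype(int)

    @property
    def species_set(self) -> frozenset[str]:
        """Pooled species set (species present in >= 1 unit)."""
        present = self.incidence_frequencies >= 1
        return frozenset(s for s, p in zip(self.species_ids, present) if p)

    # -- construction / conversion -----------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], unit_ids: Sequence[str] | None = None) -> "IncidenceMatrix":
        """Build from (unit, species) detection pairs.

        ``unit_ids`` fixes the row order and may include all-zero units;
        when omitted, units appear in first-seen order.
        """
        pairs = list(pairs)
        if unit_ids is None:
            seen: dict[str, None] = {}
            for u, _ in pairs:
                seen.setdefault(u, None)
            unit_ids = list(seen)
        species = sorted({s for _, s in pairs})
        u_index = {u: i for i, u in enumerate(unit_ids)}
        s_index = {s: j for j, s in enumerate(species)}
        cells = np.zeros((len(unit_ids), len(species)), dtype=bool)
        for u, s in pairs:
            if u not in u_index:
                raise KeyError(f"unit {u!r} not in declared unit_ids")
            cells[u_index[u], s_index[s]] = True
        return cls(list(unit_ids), species, cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells.astype(int), index=self.unit_ids, columns=self.species_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IncidenceMatrix(T={self.T}, S_obs={self.S_obs}, Q1={self.Q1}, Q2={self.Q2})"


@dataclass(frozen=True, slots=True)
class BetaPartition:
    """Pairwise Sorensen dissimilarity partitioned into turnover + nestedness.

    ``a`` species shared; ``b``/``c`` unique to either assemblage;
    beta_sim = min(b,c)/(a+min(b,c)) (Simpson turnover),
    beta_sor = (b+c)/(2a+b+c) (total Sorensen),
    beta_sne = beta_sor - beta_sim (nestedness-resultant fraction).
    """

    a: int
    b: int
    c: int
    beta_sim: float
    beta_sne: float
    beta_sor: float

    def __post_init__(self) -> None:
        for name in ("beta_sim", "beta_sne", "beta_sor"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not math.isclose(self.beta_sim + self.beta_sne, self.beta_sor, abs_tol=1e-12):
            raise ValueError("partition identity beta_sim + beta_sne = beta_sor violated")


@dataclass(frozen=True, slots=True)
class CurvePoint:
    """One point of a rarefaction/extrapolation curve."""

    t: int
    estimate: float
    kind: str  # interpolated | observed | extrapolated
    ci_lower: float = math.nan
    ci_upper: float = math.nan


@dataclass(frozen=True, slots=True)
class RarefactionCurve:
    """Expected richness over numbers of sampling units, with optional CI."""

    points: tuple[CurvePoint, ...]
    reference_t: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": [p.t for p in self.points],
                "estimate": [p.estimate for p in self.points],
                "kind": [p.kind for p in self.points],
                "ci_lower": [p.ci_lower for p in self.points],
                "ci_upper": [p.ci_upper for p in self.points],
            }
        )

    def estimate_at(self, t: int) -> float:
        for p in self.points:
            if p.t == t:
                return p.estimate
        raise KeyError(f"no point at t={t}")


@dataclass(frozen=True, slots=True)
class SummaryRow:
    """One row of the scenario summary table (two spatial scales).

    ``local_mean``/``local_sd`` summarise per-plot richness; ``pooled_richness``
    is the unique species count across all plots. Rank 1 = highest richness.
    """

    scenario: Scenario | None  # None for the point-count reference row
    n_minutes: int
    local_mean: float
    local_sd: float
    pooled_richness: int
    rank_local: int
    rank_pooled: int
    exceeds_reference_local: bool | None = None
    exceeds_reference_pooled: bool | None = None
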