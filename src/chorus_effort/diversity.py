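"""Incidence-based diversity statistics for effort-allocation scenarios.

Covers per-scenario community matrices, local (alpha) richness summaries,
sample-size-based rarefaction/extrapolation of species richness (Hill
number of order q = 0) from incidence frequencies, bootstrap confidence
bands, the pairwise Sorensen dissimilarity partition into turnover and
nestedness, gradient-wise two-sample t-tests, the occurrence-by-time
matrix, and the two-scale scenario summary table.

Rarefaction/extrapolation follows the standard incidence-frequency
formulation: with T sampling units and incidence frequencies Y_s,

    E[S(t)] = S_obs - sum_s C(T - Y_s, t) / C(T, t)          (t <= T)

and beyond the reference sample, with Q1 uniques, Q2 duplicates, and the
Chao2-type estimate of undetected richness

    Q0 = ((T-1)/T) * Q1^2 / (2 Q2)        (Q2 > 0)
    Q0 = ((T-1)/T) * Q1 (Q1 - 1) / 2      (Q2 = 0)

    S(T + m) = S_obs + Q0 * [1 - (1 - Q1 / (Q1 + T Q0))^m].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    BetaPartition,
    CurvePoint,
    DetectionRecord,
    IncidenceMatrix,
    RarefactionCurve,
    Scenario,
    SummaryRow,
    phase_offsets,
    Phase,
)


# ---------------------------------------------------------------------------
# Community matrices and alpha summaries

def community_matrix(records: Iterable[DetectionRecord], plots: Sequence[str]) -> IncidenceMatrix:
    """Plots x species presence/absence matrix from detection records.

    ``plots`` fixes the row order; plots without detections appear as
    all-zero rows. Records must already be genus-filtered (ingest does
    this) — a genus-flagged record here is a programming error.
    """
    if not plots:
        raise ValueError("plots must be non-empty")
    recs = list(records)
    if any(r.genus_only for r in recs):
        raise ValueError("genus-only records must be excluded before building matrices")
    return IncidenceMatrix.from_pairs(((r.plot_id, r.species_code) for r in recs), unit_ids=plots)


@dataclass(frozen=True, slots=True)
class AlphaSummary:
    """Per-plot richness with its mean and sample SD (NaN when T = 1)."""

    richness: tuple[int, ...]
    mean: float
    sd: float


def alpha_summary(matrix: IncidenceMatrix) -> AlphaSummary:
    """Local-scale richness summary: row sums, mean, sample SD (ddof=1)."""
    if matrix.T < 1:
        raise ValueError("need at least one sampling unit")
    rich = matrix.row_richness
    sd = float(np.std(rich, ddof=1)) if matrix.T >= 2 else math.nan
    return AlphaSummary(tuple(int(r) for r in rich), float(np.mean(rich)), sd)


# ---------------------------------------------------------------------------
# Rarefaction / extrapolation (incidence frequencies, Hill q = 0)

def _interpolated_richness(Y: Sequence[int], T: int, t: int) -> float:
    """Exact E[S(t)] via binomial coefficients (C(n,k) = 0 when n < k)."""
    denom = comb(T, t)
    present = [y for y in Y if y >= 1]
    missing = sum(comb(T - y, t) for y in present) / denom
    return len(present) - missing


def _chao2_undetected(T: int, Q1: int, Q2: int) -> float:
    if T <= 1:
        return 0.0
    if Q2 > 0:
        return (T - 1) / T * Q1 * Q1 / (2.0 * Q2)
    return (T - 1) / T * Q1 * (Q1 - 1) / 2.0


def _extrapolated_richness(S_obs: int, T: int, Q1: int, Q2: int, m: int) -> float:
    if m == 0 or Q1 == 0:
        return float(S_obs)
    Q0 = _chao2_undetected(T, Q1, Q2)
    if Q0 <= 0.0:
        return float(S_obs)
    return S_obs + Q0 * (1.0 - (1.0 - Q1 / (Q1 + T * Q0)) ** m)


def rarefy_extrapolate(
    matrix: IncidenceMatrix,
    t_values: Sequence[int] | None = None,
    *,
    endpoint: int | None = None,
) -> RarefactionCurve:
    """Expected species richness at t sampling units (no CI).

    Interpolates for t <= T and extrapolates to the endpoint (default 2T)
    with the Chao2-type estimator of undetected species. The curve is
    non-decreasing and passes exactly through S_obs at t = T.
    """
    T = matrix.T
    if T < 1:
        raise ValueError("matrix must have at least one sampling unit")
    if t_values is None:
        t_values = list(range(1, (endpoint if endpoint is not None else 2 * T) + 1))
    t_values = [int(t) for t in t_values]
    if any(t <= 0 for t in t_values):
        raise ValueError(f"t values must be positive, got {t_values}")
    Y = matrix.incidence_frequencies
    S_obs, Q1, Q2 = matrix.S_obs, matrix.Q1, matrix.Q2
    points = []
    for t in t_values:
        if t < T:
            points.append(CurvePoint(t, _interpolated_richness(Y, T, t), "interpolated"))
        elif t == T:
            points.append(CurvePoint(t, float(S_obs), "observed"))
        else:
            points.append(CurvePoint(t, _extrapolated_richness(S_obs, T, Q1, Q2, t - T), "extrapolated"))
    return RarefactionCurve(tuple(points), reference_t=T)


def _curves_from_incidence(Yb: np.ndarray, T: int, t_values: Sequence[int]) -> np.ndarray:
    """Vectorised curves for a batch of incidence-frequency vectors.

    ``Yb`` has shape (B, S); returns estimates of shape (B, len(t_values)).
    Interpolation uses the exact product recurrence
    C(T-Y, t)/C(T, t) = prod_{i=0..t-1} (T-Y-i)/(T-i).
    """
    Yb = np.asarray(Yb, dtype=np.int64)
    B, S = Yb.shape
    present = Yb >= 1
    S_obs = present.sum(axis=1).astype(float)
    Q1 = (Yb == 1).sum(axis=1)
    Q2 = (Yb == 2).sum(axis=1)
    t_values = [int(t) for t in t_values]
    tmax_interp = min(max(t_values), T)

    # ratio[b, s] = C(T - Y, t) / C(T, t), built up over t
    ratio = np.ones((B, S))
    interp: dict[int, np.ndarray] = {}
    for t in range(1, tmax_interp + 1):
        numer = np.maximum(T - Yb - (t - 1), 0)
        ratio = ratio * numer / (T - t + 1)
        if t in t_values or t == T:
            interp[t] = S_obs - np.where(present, ratio, 0.0).sum(axis=1)

    # extrapolation pieces (vectorised over replicates)
    Q0 = np.where(
        Q2 > 0,
        (T - 1) / T * Q1 * Q1 / np.maximum(2.0 * Q2, 1),
        (T - 1) / T * Q1 * np.maximum(Q1 - 1, 0) / 2.0,
    )
    if T <= 1:
        Q0 = np.zeros(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(Q1 + T * Q0 > 0, 1.0 - Q1 / (Q1 + T * Q0), 1.0)

    out = np.empty((B, len(t_values)))
    for j, t in enumerate(t_values):
        if t <= T:
            out[:, j] = interp[t] if t < T else S_obs
        else:
            m = t - T
            ext = S_obs + Q0 * (1.0 - base**m)
            out[:, j] = np.where((Q1 == 0) | (Q0 <= 0), S_obs, ext)
    return out


def bootstrap_ci(
    matrix: IncidenceMatrix,
    t_values: Sequence[int] | None = None,
    *,
    B: int = 200,
    seed: int = 0,
    endpoint: int | None = None,
) -> RarefactionCurve:
    """Rarefaction/extrapolation curve with percentile 95% bootstrap CI.

    Sampling units (rows) are resampled with replacement B times and the
    whole curve recomputed per replicate; bounds are the 2.5/97.5
    percentiles, widened if necessary so the point estimate always lies
    inside or on them. Fully deterministic for a given seed.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    base = rarefy_extrapolate(matrix, t_values, endpoint=endpoint)
    ts = [p.t for p in base.points]
    T = matrix.T
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, T, size=(B, T))
    Yb = matrix.cells[idx].sum(axis=1)  # (B, S)
    est = _curves_from_incidence(Yb, T, ts)
    lo = np.percentile(est, 2.5, axis=0)
    hi = np.percentile(est, 97.5, axis=0)
    points = []
    for j, p in enumerate(base.points):
        lower = min(float(lo[j]), p.estimate)
        upper = max(float(hi[j]), p.estimate)
        points.append(CurvePoint(p.t, p.estimate, p.kind, lower, upper))
    return RarefactionCurve(tuple(points), reference_t=T)


# ---------------------------------------------------------------------------
# Beta diversity: Sorensen partition into turnover + nestedness

def beta_pair(assemblage_x: Iterable[str], assemblage_y: Iterable[str]) -> BetaPartition:
    """Pairwise Sorensen dissimilarity partitioned into Simpson turnover
    and its nestedness-resultant complement.

    Conventions for degenerate inputs: two empty assemblages are
    identical (all zero); exactly one empty assemblage is maximally,
    purely nestedness-driven dissimilar (sor = sne = 1, sim = 0).
    """
    x, y = set(assemblage_x), set(assemblage_y)
    a = len(x & y)
    b = len(x - y)
    c = len(y - x)
    if not x and not y:
        return BetaPartition(0, 0, 0, 0.0, 0.0, 0.0)
    if not x or not y:
        return BetaPartition(a, b, c, 0.0, 1.0, 1.0)
    mn = min(b, c)
    beta_sim = mn / (a + mn) if (a + mn) > 0 else 0.0
    beta_sor = (b + c) / (2 * a + b + c)
    return BetaPartition(a, b, c, beta_sim, beta_sor - beta_sim, beta_sor)


def pairwise_beta_table(
    scenario_assemblages: Mapping[Hashable, Iterable[str]],
    comparisons: Sequence[tuple[Hashable, Hashable]] | None = None,
    *,
    family: str | None = None,
) -> pd.DataFrame:
    """Long table of beta partitions for the requested scenario pairs.

    Assemblages are the pooled (all plots merged) species sets per
    scenario. Each row carries both pooled richness values alongside the
    partition, mirroring figure annotations that print the richness at
    the intersection of each pair.
    """
    pools = {k: frozenset(v) for k, v in scenario_assemblages.items()}
    if comparisons is None:
        comparisons = list(combinations(pools.keys(), 2))
    rows = []
    for left, right in comparisons:
        for key in (left, right):
            if key not in pools:
                raise KeyError(f"unknown scenario {key!r} in comparison list")
        part = beta_pair(pools[left], pools[right])
        rows.append(
            {
                "family": family,
                "left": str(left),
                "right": str(right),
                "richness_left": len(pools[left]),
                "richness_right": len(pools[right]),
                "a": part.a,
                "b": part.b,
                "c": part.c,
                "beta_sim": part.beta_sim,
                "beta_sne": part.beta_sne,
                "beta_sor": part.beta_sor,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["family", "left", "right", "richness_left", "richness_right", "a", "b", "c", "beta_sim", "beta_sne", "beta_sor"],
    )
    if family is None:
        df = df.drop(columns=["family"])
    return df


# ---------------------------------------------------------------------------
# Gradient t-tests

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Star coding: * <.05, ** <.01, *** <.001, **** <.0001, else 'ns'."""
    for threshold, stars in _STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def gradient_ttest(
    groups: Mapping[Hashable, Sequence[float]],
    level_pairs: Sequence[tuple[Hashable, Hashable]] | None = None,
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests of scenario richness between gradient levels.

    Classical Student t (pooled variance, df = n1 + n2 - 2) by default,
    Welch's unequal-variance test behind ``welch=True``. Two-sided p with
    star coding; no multiple-testing correction is applied.
    """
    for level, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"level {level!r} has {len(vals)} values; need >= 2")
    if level_pairs is None:
        level_pairs = list(combinations(groups.keys(), 2))
    rows = []
    for left, right in level_pairs:
        x = np.asarray(groups[left], dtype=float)
        y = np.asarray(groups[right], dtype=float)
        res = stats.ttest_ind(x, y, equal_var=not welch)
        p = float(res.pvalue)
        rows.append(
            {
                "left": str(left),
                "right": str(right),
                "n_left": len(x),
                "n_right": len(y),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows, columns=["left", "right", "n_left", "n_right", "t", "df", "p", "stars"])


# ---------------------------------------------------------------------------
# Occurrence-by-time matrix

def occurrence_by_time(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    """Species x offset matrix of distinct-plot counts.

    Cell (s, o) counts the plots with at least one detection of species s
    at window offset o on any day (a plot detected on several days counts
    once). Columns are the full 40-slot base grid; rows are ordered by
    earliest occupied offset, then by total plot-windows (descending),
    then species code.
    """
    offsets = phase_offsets(Phase.DAWN) + phase_offsets(Phase.MORNING)
    plots_at: dict[str, dict[int, set[str]]] = {}
    for r in records:
        if r.genus_only:
            raise ValueError("genus-only records must be excluded before this analysis")
        plots_at.setdefault(r.species_code, {}).setdefault(r.offset_min, set()).add(r.plot_id)
    rows = {}
    order = []
    for sp, by_offset in plots_at.items():
        counts = [len(by_offset.get(o, ())) for o in offsets]
        rows[sp] = counts
        first = min(o for o in offsets if by_offset.get(o))
        order.append((first, -sum(counts), sp))
    ordered = [sp for _, _, sp in sorted(order)]
    return pd.DataFrame([rows[sp] for sp in ordered], index=ordered, columns=offsets)


# ---------------------------------------------------------------------------
# Two-scale scenario summary table

def build_summary_table(
    matrices: Mapping[Scenario, IncidenceMatrix],
    reference: IncidenceMatrix | None = None,
    *,
    reference_minutes: int = 20,
) -> list[SummaryRow]:
    """Scenario summary at both scales, ranked, with reference flags.

    Rank 1 = highest richness; ties are broken by fewer annotation
    minutes, then by scenario order as given. When a reference
    (point-count) matrix is supplied it participates in the ranking and
    is appended as a final row; 'exceeds' flags are strictly-greater
    comparisons against the reference.
    """
    if not matrices:
        raise ValueError("no scenario matrices given")
    plot_sets = {tuple(m.unit_ids) for m in matrices.values()}
    if len(plot_sets) != 1:
        raise ValueError("scenario matrices must share an identical plot set")

    entries = []  # (sort keys and payload)
    for order, (scen, mat) in enumerate(matrices.items()):
        a = alpha_summary(mat)
        entries.append(
            {
                "scenario": scen,
                "n_minutes": scen.n_minutes,
                "local_mean": a.mean,
                "local_sd": a.sd,
                "pooled": mat.S_obs,
                "order": order,
            }
        )
    if reference is not None:
        a = alpha_summary(reference)
        entries.append(
            {
                "scenario": None,
                "n_minutes": reference_minutes,
                "local_mean": a.mean,
                "local_sd": a.sd,
                "pooled": reference.S_obs,
                "order": len(entries),
            }
        )

    def ranks(key: str) -> dict[int, int]:
        idx = sorted(range(len(entries)), key=lambda i: (-entries[i][key], entries[i]["n_minutes"], entries[i]["order"]))
        return {i: rank for rank, i in enumerate(idx, start=1)}

    rank_local = ranks("local_mean")
    rank_pooled = ranks("pooled")
    ref_mean = entries[-1]["local_mean"] if reference is not None else None
    ref_pooled = entries[-1]["pooled"] if reference is not None else None

    rows = []
    for i, e in enumerate(entries):
        rows.append(
            SummaryRow(
                scenario=e["scenario"],
                n_minutes=e["n_minutes"],
                local_mean=e["local_mean"],
                local_sd=e["local_sd"],
                pooled_richness=e["pooled"],
                rank_local=rank_local[i],
                rank_pooled=rank_pooled[i],
                exceeds_reference_local=(e["local_mean"] > ref_mean) if reference is not None and e["scenario"] is not None else None,
                exceeds_reference_pooled=(e["pooled"] > ref_pooled) if reference is not None and e["scenario"] is not None else None,
            )
        )
    return rows


def summary_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Flatten SummaryRows into the writable summary table."""
    return pd.DataFrame(
        {
            "scenario": [r.scenario.label if r.scenario else "point_count" for r in rows],
            "intensity_min": [r.scenario.intensity_min if r.scenario else "" for r in rows],
            "day_phase": [r.scenario.day_phase if r.scenario else "" for r in rows],
            "duration_days": [r.scenario.duration_days if r.scenario else "" for r in rows],
            "n_minutes": [r.n_minutes for r in rows],
            "local_mean": [r.local_mean for r in rows],
            "local_sd": [r.local_sd for r in rows],
            "rank_local": [r.rank_local for r in rows],
            "pooled_richness": [r.pooled_richness for r in rows],
            "rank_pooled": [r.rank_pooled for r in rows],
            "exceeds_reference_local": ["" if r.exceeds_reference_local is None else r.exceeds_reference_local for r in rows],
            "exceeds_reference_pooled": ["" if r.exceeds_reference_pooled is None else r.exceeds_reference_pooled for r in rows],
        }
    )
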