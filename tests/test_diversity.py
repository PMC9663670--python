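import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chorus_effort import (
    DetectionRecord,
    IncidenceMatrix,
    Scenario,
    alpha_summary,
    beta_pair,
    bootstrap_ci,
    build_summary_table,
    community_matrix,
    gradient_ttest,
    occurrence_by_time,
    pairwise_beta_table,
    rarefy_extrapolate,
    significance_stars,
    subset_records,
)
from chorus_effort.diversity import _chao2_undetected, _curves_from_incidence


def brute_force_expected_richness(cells: np.ndarray, t: int) -> float:
    """Mean richness over all C(T, t) equally likely unit subsets."""
    T = cells.shape[0]
    vals = [
        int(cells[list(subset)].any(axis=0).sum())
        for subset in combinations(range(T), t)
    ]
    return float(np.mean(vals))


def random_matrix(rng, T, S):
    cells = rng.random((T, S)) < rng.uniform(0.1, 0.9)
    units = [f"u{i}" for i in range(T)]
    species = [f"s{j}" for j in range(S)]
    return IncidenceMatrix(units, species, cells)


class TestCommunityMatrix:
    def test_empty_records_give_empty_matrix(self):
        m = community_matrix([], ["p1", "p2", "p3"])
        assert m.T == 3 and m.S_obs == 0 and m.cells.shape == (3, 0)

    def test_incidence_counts(self):
        recs = [
            DetectionRecord("p1", 1, -60, "A"),
            DetectionRecord("p2", 1, -60, "A"),
            DetectionRecord("p1", 2, 180, "B"),
        ]
        m = community_matrix(recs, ["p1", "p2"])
        assert dict(zip(m.species_ids, m.incidence_frequencies)) == {"A": 2, "B": 1}
        assert (m.Q1, m.Q2) == (1, 1)

    def test_genus_only_records_rejected(self):
        with pytest.raises(ValueError):
            community_matrix([DetectionRecord("p1", 1, -60, "Certhia sp.", genus_only=True)], ["p1"])


class TestAlphaSummary:
    def test_constant_rows(self):
        m = IncidenceMatrix(["a", "b", "c"], ["x", "y", "z"], np.ones((3, 3), bool))
        a = alpha_summary(m)
        assert a.mean == 3.0 and a.sd == 0.0

    def test_two_rows_closed_form(self):
        cells = np.array([[1, 1, 0, 0], [1, 1, 1, 1]], bool)
        a = alpha_summary(IncidenceMatrix(["a", "b"], list("wxyz"), cells))
        assert a.mean == 3.0
        assert a.sd == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_single_unit_sd_missing(self):
        a = alpha_summary(IncidenceMatrix(["a"], ["x"], np.ones((1, 1), bool)))
        assert math.isnan(a.sd)


class TestRarefaction:
    def test_saturated_matrix_flat(self):
        m = IncidenceMatrix(["a", "b", "c"], list("xyz"), np.ones((3, 3), bool))
        curve = rarefy_extrapolate(m, endpoint=6)
        assert all(p.estimate == 3.0 for p in curve.points)

    def test_two_unit_interpolation(self):
        # Y = {2, 1}: one-unit subsets see 2 or 1 species -> mean 1.5
        cells = np.array([[1, 1], [1, 0]], bool)
        curve = rarefy_extrapolate(IncidenceMatrix(["a", "b"], ["x", "y"], cells))
        assert curve.estimate_at(1) == pytest.approx(1.5, abs=1e-12)

    def test_chao2_asymptote(self):
        # T=4, Q1=2, Q2=1 -> undetected estimate (3/4) * 4 / 2 = 1.5
        assert _chao2_undetected(4, 2, 1) == pytest.approx(1.5)
        # extrapolation approaches S_obs + 1.5
        cells = np.zeros((4, 10), bool)
        cells[:, :7] = True  # 7 widespread species
        cells[0, 7] = True  # unique
        cells[1, 8] = True  # unique
        cells[[0, 1], 9] = True  # duplicate
        m = IncidenceMatrix([f"u{i}" for i in range(4)], [f"s{j}" for j in range(10)], cells)
        assert (m.S_obs, m.Q1, m.Q2) == (10, 2, 1)
        far = rarefy_extrapolate(m, t_values=[4000]).estimate_at(4000)
        assert far == pytest.approx(11.5, abs=1e-9)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(12):
            T = int(rng.integers(2, 9))
            S = int(rng.integers(1, 12))
            m = random_matrix(rng, T, S)
            curve = rarefy_extrapolate(m, t_values=list(range(1, T + 1)))
            for t in range(1, T + 1):
                expected = brute_force_expected_richness(m.cells, t)
                assert curve.estimate_at(t) == pytest.approx(expected, abs=1e-10)

    def test_endpoints_and_monotonicity(self, rng):
        m = random_matrix(rng, 6, 15)
        curve = rarefy_extrapolate(m, endpoint=12)
        assert curve.estimate_at(6) == m.S_obs
        estimates = [p.estimate for p in curve.points]
        assert all(b >= a - 1e-12 for a, b in zip(estimates, estimates[1:]))

    def test_no_uniques_flat_extrapolation(self):
        cells = np.array([[1, 1], [1, 1], [0, 1]], bool)
        m = IncidenceMatrix(["a", "b", "c"], ["x", "y"], cells)
        assert m.Q1 == 0
        curve = rarefy_extrapolate(m, t_values=[3, 4, 10])
        assert all(p.estimate == m.S_obs for p in curve.points)

    def test_invalid_t_rejected(self, rng):
        with pytest.raises(ValueError):
            rarefy_extrapolate(random_matrix(rng, 3, 3), t_values=[0])

    def test_vectorised_batch_matches_scalar(self, rng):
        m = random_matrix(rng, 7, 20)
        ts = list(range(1, 15))
        batch = _curves_from_incidence(m.incidence_frequencies[None, :], 7, ts)[0]
        scalar = [rarefy_extrapolate(m, t_values=[t]).estimate_at(t) for t in ts]
        np.testing.assert_allclose(batch, scalar, atol=1e-10)


class TestBootstrapCI:
    def test_identical_rows_zero_width(self):
        m = IncidenceMatrix(["a", "b", "c"], list("xyz"), np.ones((3, 3), bool))
        curve = bootstrap_ci(m, B=50, seed=1)
        assert all(p.ci_lower == p.ci_upper == p.estimate for p in curve.points)

    def test_deterministic_under_seed(self, rng):
        m = random_matrix(rng, 8, 20)
        c1 = bootstrap_ci(m, B=100, seed=42)
        c2 = bootstrap_ci(m, B=100, seed=42)
        assert c1 == c2

    def test_point_estimate_inside_bounds(self, rng):
        m = random_matrix(rng, 10, 30)
        curve = bootstrap_ci(m, B=100, seed=3)
        assert all(p.ci_lower <= p.estimate <= p.ci_upper for p in curve.points)

    def test_matches_exhaustive_resampling(self, rng):
        # T = 4: all 4^4 = 256 equally likely resamples enumerable exactly
        m = random_matrix(rng, 4, 8)
        ts = [1, 2, 3, 4, 6, 8]
        idx = np.array(np.meshgrid(*[range(4)] * 4, indexing="ij")).reshape(4, -1).T
        Yb = m.cells[idx].sum(axis=1)
        exact = _curves_from_incidence(Yb, 4, ts)
        lo_exact = np.percentile(exact, 2.5, axis=0)
        hi_exact = np.percentile(exact, 97.5, axis=0)
        curve = bootstrap_ci(m, t_values=ts, B=4000, seed=9)
        lo = np.array([p.ci_lower for p in curve.points])
        hi = np.array([p.ci_upper for p in curve.points])
        # Monte-Carlo error on a 256-atom distribution: within one atom gap
        assert np.all(np.abs(lo - np.minimum(lo_exact, [p.estimate for p in curve.points])) < 0.75)
        assert np.all(np.abs(hi - np.maximum(hi_exact, [p.estimate for p in curve.points])) < 0.75)


species_sets = st.sets(st.sampled_from([f"sp{i}" for i in range(30)]), max_size=25)


class TestBetaPartition:
    def test_identical_assemblages(self):
        part = beta_pair({"A", "B"}, {"A", "B"})
        assert (part.beta_sim, part.beta_sne, part.beta_sor) == (0.0, 0.0, 0.0)

    def test_nested_pair_pure_nestedness(self):
        x = {f"s{i}" for i in range(15)}
        y = {f"s{i}" for i in range(10)}  # y subset of x: a=10, b=5, c=0
        part = beta_pair(x, y)
        assert part.beta_sim == 0.0
        assert part.beta_sor == pytest.approx(0.2)
        assert part.beta_sne == pytest.approx(0.2)

    def test_mixed_pair_closed_form(self):
        x = {"a1", "a2", "b1", "b2", "b3"}
        y = {"a1", "a2", "c1"}  # a=2, b=3, c=1
        part = beta_pair(x, y)
        assert part.beta_sim == pytest.approx(1 / 3)
        assert part.beta_sor == pytest.approx(0.5)
        assert part.beta_sne == pytest.approx(1 / 6)

    def test_empty_conventions(self):
        assert beta_pair(set(), set()).beta_sor == 0.0
        one_empty = beta_pair({"A"}, set())
        assert (one_empty.beta_sim, one_empty.beta_sne, one_empty.beta_sor) == (0.0, 1.0, 1.0)

    @given(species_sets, species_sets)
    def test_partition_identity_and_ranges(self, x, y):
        part = beta_pair(x, y)
        # recompute from set operations (independent route)
        assert part.a == len(x & y) and part.b == len(x - y) and part.c == len(y - x)
        assert abs(part.beta_sim + part.beta_sne - part.beta_sor) < 1e-12
        for v in (part.beta_sim, part.beta_sne, part.beta_sor):
            assert -1e-12 <= v <= 1 + 1e-12
        if x and y and (x <= y or y <= x):
            assert part.beta_sim == 0.0

    @given(species_sets, species_sets)
    def test_symmetry(self, x, y):
        p1, p2 = beta_pair(x, y), beta_pair(y, x)
        assert p1.beta_sim == p2.beta_sim and p1.beta_sor == p2.beta_sor


class TestPairwiseBetaTable:
    def test_identical_scenario_pair_zero(self):
        table = pairwise_beta_table({"s1": {"A", "B"}, "s2": {"A", "B"}}, [("s1", "s2")])
        row = table.iloc[0]
        assert row.beta_sim == 0.0 and row.beta_sor == 0.0
        assert row.richness_left == 2 and row.richness_right == 2

    def test_unknown_scenario_raises(self):
        with pytest.raises(KeyError):
            pairwise_beta_table({"s1": {"A"}}, [("s1", "s9")])

    def test_nested_scenarios_zero_turnover(self, sim_dataset):
        records, _, config = sim_dataset
        plots = list(config.plot_ids)
        pools = {}
        for d in (1, 2):
            sub = subset_records(records, Scenario(6, "both", d))
            pools[f"d{d}"] = community_matrix(sub, plots).species_set
        table = pairwise_beta_table(pools, [("d1", "d2")])
        assert table.iloc[0].beta_sim == 0.0


class TestGradientTTest:
    def test_identical_groups(self):
        out = gradient_ttest({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        row = out.iloc[0]
        assert row.t == 0.0 and row.p == 1.0 and row.stars == "ns"

    def test_closed_form_pooled_variance(self):
        out = gradient_ttest({"x": [1.0, 2.0, 3.0], "y": [2.0, 3.0, 4.0]})
        row = out.iloc[0]
        assert row.t == pytest.approx(-1.224745, abs=1e-5)
        assert row.df == 4
        assert row.p == pytest.approx(0.287900, abs=1e-4)

    def test_swap_negates_t_keeps_p(self):
        a = gradient_ttest({"x": [1.0, 5.0, 2.0], "y": [4.0, 4.0, 9.0]}, [("x", "y")]).iloc[0]
        b = gradient_ttest({"x": [1.0, 5.0, 2.0], "y": [4.0, 4.0, 9.0]}, [("y", "x")]).iloc[0]
        assert a.t == pytest.approx(-b.t) and a.p == pytest.approx(b.p)

    def test_shift_invariance(self):
        base = gradient_ttest({"x": [1.0, 5.0, 2.0], "y": [4.0, 4.0, 9.0]}).iloc[0]
        shifted = gradient_ttest({"x": [11.0, 15.0, 12.0], "y": [14.0, 14.0, 19.0]}).iloc[0]
        assert base.t == pytest.approx(shifted.t)

    def test_small_level_rejected(self):
        with pytest.raises(ValueError):
            gradient_ttest({"a": [1.0], "b": [1.0, 2.0]})

    def test_star_mapping(self):
        assert [significance_stars(p) for p in (0.2, 0.04, 0.009, 0.0009, 0.00009)] == [
            "ns", "*", "**", "***", "****",
        ]


class TestOccurrenceByTime:
    def test_repeat_days_count_once(self):
        recs = [DetectionRecord("p1", d, -60, "A") for d in (1, 2, 3)]
        m = occurrence_by_time(recs)
        assert m.loc["A", -60] == 1

    def test_distinct_plots_counted(self):
        recs = [DetectionRecord("p1", 1, -60, "A"), DetectionRecord("p2", 3, -60, "A")]
        assert occurrence_by_time(recs).loc["A", -60] == 2

    def test_cells_bounded_by_plot_count(self, sim_dataset):
        records, _, config = sim_dataset
        m = occurrence_by_time(records)
        assert m.to_numpy().max() <= config.n_plots

    def test_rows_ordered_by_first_occupied_offset(self):
        recs = [
            DetectionRecord("p1", 1, 180, "LATE"),
            DetectionRecord("p1", 1, -60, "EARLY"),
        ]
        assert list(occurrence_by_time(recs).index) == ["EARLY", "LATE"]


def _matrix_from_richness(plot_species):
    pairs = [(p, s) for p, specs in plot_species.items() for s in specs]
    return IncidenceMatrix.from_pairs(pairs, unit_ids=list(plot_species))


class TestSummaryTable:
    def test_single_scenario_rank_one(self):
        m = _matrix_from_richness({"p1": {"A"}, "p2": {"A", "B"}})
        rows = build_summary_table({Scenario(3, "dawn", 1): m})
        assert rows[0].rank_local == 1 and rows[0].rank_pooled == 1
        assert rows[0].local_mean <= rows[0].pooled_richness

    def test_ranks_follow_richness(self):
        m_rich = _matrix_from_richness({"p1": set("ABCDE"), "p2": set("ABCD")})
        m_poor = _matrix_from_richness({"p1": set("AB"), "p2": set("AB")})
        rows = build_summary_table({Scenario(3, "dawn", 1): m_rich, Scenario(60, "dawn", 1): m_poor})
        assert rows[0].rank_pooled == 1 and rows[1].rank_pooled == 2

    def test_tie_broken_by_fewer_minutes(self):
        m = _matrix_from_richness({"p1": set("AB"), "p2": set("AB")})
        rows = build_summary_table({Scenario(3, "dawn", 1): m, Scenario(6, "dawn", 1): m})
        by_scenario = {r.scenario.intensity_min: r for r in rows}
        assert by_scenario[6].rank_pooled == 1  # 10 min < 20 min
        assert by_scenario[3].rank_pooled == 2

    def test_reference_row_and_flags(self):
        scen = _matrix_from_richness({"p1": set("ABC"), "p2": set("ABC")})
        ref = _matrix_from_richness({"p1": set("AB"), "p2": set("AB")})
        rows = build_summary_table({Scenario(3, "dawn", 1): scen}, reference=ref)
        assert rows[-1].scenario is None and rows[-1].n_minutes == 20
        assert rows[0].exceeds_reference_local is True
        assert rows[0].exceeds_reference_pooled is True
        ranks = sorted(r.rank_pooled for r in rows)
        assert ranks == [1, 2]  # permutation incl. reference

    def test_inconsistent_plot_sets_rejected(self):
        m1 = _matrix_from_richness({"p1": {"A"}})
        m2 = _matrix_from_richness({"p2": {"A"}})
        with pytest.raises(ValueError):
            build_summary_table({Scenario(3, "dawn", 1): m1, Scenario(6, "dawn", 1): m2})
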