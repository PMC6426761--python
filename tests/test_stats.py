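import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytonx import (
    ModelConfig,
    Population,
    cumulative_share_curve,
    division_death_times_by_generation,
    division_events,
    expression_distributions,
    family_sizes,
    marker_summary_by_family,
    population_from_table,
    proliferation_rates,
    read_cells,
    simulate,
    spearman_with_ci,
    subset_counts_by_day,
    write_cells,
)

from conftest import zero_noise_config


def brute_force_spearman(x, y):
    """Independent oracle: average ranks by hand, then Pearson."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            r[order[i:j]] = (i + j + 1) / 2  # average rank, 1-based
            i = j
        return r

    rx, ry = ranks(x), ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestFamilySizes:
    def test_every_family_starts_with_one_cell(self):
        pop = simulate(ModelConfig(seed=0, n_naive=25, horizon=60.0))
        assert (family_sizes(pop, 0.0) == 1).all()

    def test_zero_noise_powers_of_two(self):
        pop = simulate(zero_noise_config(n_naive=1))
        # at t=150 h the deterministic tree has completed 10 divisions
        assert family_sizes(pop, 150.0).iloc[0] == 2**10

    def test_out_of_range_rejected(self):
        pop = simulate(ModelConfig(seed=0, n_naive=5, horizon=60.0))
        with pytest.raises(ValueError):
            family_sizes(pop, 61.0)
        with pytest.raises(ValueError):
            family_sizes(pop, -1.0)


class TestCumulativeShare:
    def test_hand_computed_example(self):
        curve, frac = cumulative_share_curve(np.array([50, 30, 10, 5, 5]))
        assert frac == 20.0  # the largest family alone reaches 50/100
        assert list(curve["cumulative_cells"]) == [50, 80, 90, 95, 100]

    def test_equal_sizes_need_half_the_families(self):
        _, frac = cumulative_share_curve(np.full(10, 7))
        assert frac == 50.0

    def test_zero_families_enter_denominator_only(self):
        sizes = np.array([50, 30, 10, 5, 5])
        _, frac = cumulative_share_curve(sizes)
        _, frac_padded = cumulative_share_curve(np.concatenate([sizes, np.zeros(5)]))
        assert frac_padded == frac * 5 / 10  # same k, doubled denominator

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cumulative_share_curve(np.zeros(3))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 10**6), min_size=1).filter(lambda s: sum(s) > 0))
    def test_fraction_for_half_is_minimal(self, sizes):
        curve, frac = cumulative_share_curve(np.array(sizes))
        k = round(frac / 100 * len(sizes))
        assert 1 <= k <= len(sizes)
        assert curve["cumulative_share"].iloc[k - 1] >= 0.5
        if k > 1:
            assert curve["cumulative_share"].iloc[k - 2] < 0.5


class TestSpearman:
    def test_hand_computed_rho(self):
        r = spearman_with_ci([1, 2, 3, 4, 5], [5, 6, 4, 8, 7])
        assert r.rho == pytest.approx(0.6)
        assert r.n == 5

    def test_perfect_monotone(self):
        x = np.arange(10.0)
        r = spearman_with_ci(x, np.exp(x))
        assert r.rho == pytest.approx(1.0, abs=1e-12)
        assert r.p_value < 1e-9

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(4, 30)
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if len(set(x)) < 2:
                continue
            assert spearman_with_ci(x, y).rho == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12
            )

    def test_ci_brackets_rho_and_p_positive(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r = spearman_with_ci(x, y)
        assert r.ci_low <= r.rho <= r.ci_high
        assert 0 < r.p_value <= 1

    def test_bootstrap_ci_option(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        r = spearman_with_ci(x, y, ci_method="bootstrap", n_boot=200, rng=rng)
        assert r.ci_low <= r.rho <= r.ci_high

    def test_nan_pairs_dropped(self):
        r = spearman_with_ci([1, 2, 3, 4, np.nan], [2, 3, 4, 5, 1])
        assert r.n == 4 and r.rho == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_ci([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_with_ci([1, 2], [1, 2])


def toy_population() -> Population:
    """Hand-written 7-cell table: one family over three generations."""
    cells = pd.DataFrame(
        {
            "cell_id": [0, 1, 2, 3, 4, 5, 6],
            "family_id": [0] * 7,
            "parent_id": [-1, 0, 0, 1, 1, 2, 2],
            "generation": [0, 1, 1, 2, 2, 2, 2],
            "birth_time": [0.0, 10.0, 10.0, 30.0, 30.0, 40.0, 40.0],
            "t_p": [10.0, 20.0, 30.0, 50.0, 60.0, 70.0, 80.0],
            "t_d": [50.0, 40.0, 35.0, 20.0, 90.0, 95.0, 99.0],
            "fate": ["divided", "divided", "divided", "died",
                     "alive_at_horizon", "alive_at_horizon", "alive_at_horizon"],
            "end_time": [10.0, 30.0, 40.0, 50.0, 60.0, 60.0, 60.0],
            "cd62l": [100.0, 95.0, 98.0, 90.0, 99.0, 50.0, 98.0],
            "cd27": [100.0, 100.0, 100.0, 100.0, 89.0, 95.0, 20.0],
            "klrg1": [10.0, 12.0, 14.0, 80.0, 85.0, 20.0, 10.0],
        }
    )
    cells["fate"] = pd.Categorical(
        cells["fate"], categories=["divided", "died", "alive_at_horizon", "quiescent"]
    )
    return Population(config=ModelConfig(n_naive=1, horizon=60.0), cells=cells)


class TestMarkerSummary:
    def test_toy_table_by_hand(self):
        pop = toy_population()
        fam = marker_summary_by_family(pop, 60.0)
        # alive at the 60 h horizon: cells 4, 5, 6
        assert fam.loc[0, "size"] == 3
        assert fam.loc[0, "frac_cd62l_pos"] == pytest.approx(2 / 3)  # 99, 98 >= 97
        assert fam.loc[0, "frac_cd27_pos"] == pytest.approx(1 / 3)  # only 95
        assert fam.loc[0, "frac_klrg1_pos"] == pytest.approx(1 / 3)  # only 85
        assert fam.loc[0, "n_cd62l_pos"] == 2

    def test_naive_snapshot_all_positive_fractions(self):
        pop = simulate(ModelConfig(seed=0, n_naive=40, horizon=60.0))
        fam = marker_summary_by_family(pop, 0.0)
        assert (fam["frac_cd62l_pos"] == 1.0).all()
        assert (fam["frac_klrg1_pos"] == 0.0).all()

    def test_zero_size_families_have_nan_fractions(self):
        pop = simulate(ModelConfig(seed=11, n_naive=200, horizon=192.0,
                                   variant="heterogeneous_activation"))
        fam = marker_summary_by_family(pop, 192.0)
        empty = fam[fam["size"] == 0]
        assert len(empty) > 0
        assert empty["frac_cd62l_pos"].isna().all()
        assert empty["n_cd62l_pos"].eq(0).all()


class TestDistributionsAndSubsets:
    def test_day1_relative_expression(self, basic_run):
        table = expression_distributions(basic_run, by="day")
        day1 = table[(table["day"] == 1) & (table["stat"] == "mean")]
        means = dict(zip(day1["marker"], day1["value"]))
        assert means["cd62l"] == pytest.approx(100 / 97, rel=1e-3)
        assert means["klrg1"] == pytest.approx(10 / 80, rel=1e-3)

    def test_generation_medians_zero_marker_noise(self):
        markers = zero_noise_config().markers
        pop = simulate(ModelConfig(seed=3, n_naive=30, horizon=120.0, markers=markers))
        table = expression_distributions(pop, by="generation")
        med = table[(table["marker"] == "cd62l") & (table["stat"] == "q50")]
        for g, value in zip(med["generation"], med["value"]):
            assert value == pytest.approx(100 * 0.95**g / 97, rel=1e-9)

    def test_day1_all_central_memory(self, basic_run):
        counts = subset_counts_by_day(basic_run)
        day1 = counts[counts["day"] == 1].set_index("subset")["count"]
        assert day1["Tcm"] == basic_run.config.n_naive
        assert day1[["Tem", "Teff", "other"]].sum() == 0

    def test_subset_counts_partition_alive_cells(self, basic_run):
        counts = subset_counts_by_day(basic_run)
        for day, grp in counts.groupby("day"):
            t = 24.0 * (day - 1)
            assert grp["count"].sum() == basic_run.n_alive(t)


class TestRates:
    def test_zero_noise_rates_closed_form(self):
        pop = simulate(zero_noise_config(n_naive=1))
        rates = proliferation_rates(pop, by="generation")
        means = rates[rates["stat"] == "mean"]
        for g, value in zip(means["generation"], means["value"]):
            assert value == pytest.approx(1.0 / (4.5 * 1.25**g), rel=1e-9)

    def test_division_day_binning(self):
        pop = toy_population()
        ev = division_events(pop)
        assert list(ev["day"]) == [1, 2, 2]  # events at 10, 30, 40 h
        assert np.allclose(ev["rate"], 1.0 / ev["t_p"])

    def test_dividers_only(self, basic_run):
        ev = division_events(basic_run)
        assert len(ev) == int((basic_run.cells["fate"] == "divided").sum())

    def test_times_by_generation_zero_noise(self):
        pop = simulate(zero_noise_config(n_naive=1))
        table = division_death_times_by_generation(pop)
        div = table[(table["variable"] == "division_time") & (table["stat"] == "mean")]
        observed = {g: v for g, v in zip(div["generation"], div["value"]) if not np.isnan(v)}
        for g, value in observed.items():
            assert value == pytest.approx(4.5 * 1.25**g, rel=1e-9)


class TestRecomputableFromTable:
    def test_round_trip_preserves_statistics(self, tmp_path):
        cfg = ModelConfig(seed=6, n_naive=40, horizon=120.0)
        pop = simulate(cfg)
        path = tmp_path / "cells.csv"
        write_cells(pop, path)
        rebuilt = population_from_table(read_cells(path), cfg)
        pd.testing.assert_series_equal(family_sizes(pop, 120.0), family_sizes(rebuilt, 120.0))
        pd.testing.assert_frame_equal(
            subset_counts_by_day(pop), subset_counts_by_day(rebuilt)
        )
        a = marker_summary_by_family(pop, 120.0)
        b = marker_summary_by_family(rebuilt, 120.0)
        pd.testing.assert_frame_equal(a, b)
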