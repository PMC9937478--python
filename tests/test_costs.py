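import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from saltcost.costs import (AttributableCost, CurrencyRate, aggregate,
                            attributable_cost, convert, integer_shares,
                            render_thousands, round_half_away_from_zero)


class TestAttributableCost:
    @pytest.mark.parametrize("par,total,expected", [
        (0.0, 1000.0, 0.0),
        (10.0, 1000.0, 100.0),
        (100.0, 1000.0, 1000.0),
    ])
    def test_fraction_of_total(self, par, total, expected):
        assert attributable_cost(par, total) == expected

    @given(par=st.floats(0.0, 100.0), total=st.floats(0.0, 1e10))
    def test_never_exceeds_total_for_par_within_bounds(self, par, total):
        assert attributable_cost(par, total) <= total + 1e-6

    def test_interval_must_bracket_point(self):
        with pytest.raises(ValueError):
            AttributableCost("CHD", "hospitalization", "male",
                             point=5.0, ui_low=6.0, ui_high=7.0)


class TestConvert:
    def test_published_exchange_rate_anchor(self):
        assert convert(600.0, CurrencyRate(600.0)) == 1.0

    def test_zero_and_division_oracle(self):
        assert convert(0.0) == 0.0
        assert convert(9_073_200_000.0, CurrencyRate(600.0)) == pytest.approx(
            15_122_000.0)

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            CurrencyRate(0.0)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (14.5, 15), (14.49, 14), (-14.5, -15), (0.5, 1), (52.5, 53)])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away_from_zero(x) == expected


def _cells_from_grid(grid):
    """grid: dict (disease, service, sex) -> value."""
    return [AttributableCost(d, s, x, v) for (d, s, x), v in grid.items()]


def _table2_service_cells():
    # published service components (thousand USD), split evenly across a
    # disease/sex grid — only the service totals matter to the aggregation
    components = {"hospitalization": 8_019_000.0, "consultation": 4_905_000.0,
                  "medication": 2_198_000.0}
    grid = {}
    for service, total in components.items():
        for sex in ("male", "female"):
            grid[("CHD", service, sex)] = total / 2.0
    return _cells_from_grid(grid)


class TestAggregate:
    def test_published_service_components_reproduce_total_and_shares(self):
        report = aggregate(_table2_service_cells())
        assert report.grand_total == pytest.approx(15_122_000.0)
        shares = report.service_shares
        assert shares["hospitalization"] == 53
        assert shares["consultation"] == 32
        assert shares["medication"] == 15

    def test_single_cell_total_and_share(self):
        report = aggregate([AttributableCost("CHD", "hospitalization", "male", 42.0)])
        assert report.grand_total == 42.0
        assert report.service_shares["hospitalization"] == 100

    def test_published_sex_components_round_to_women_52(self):
        cells = [AttributableCost("CHD", "hospitalization", "male", 3_867_000.0),
                 AttributableCost("CHD", "hospitalization", "female", 4_153_000.0)]
        report = aggregate(cells)
        assert report.sex_shares["hospitalization"]["female"] == 52
        assert report.sex_shares["hospitalization"]["male"] == 48

    def test_duplicate_cell_raises(self):
        cells = [AttributableCost("CHD", "hospitalization", "male", 1.0),
                 AttributableCost("CHD", "hospitalization", "male", 2.0)]
        with pytest.raises(ValueError):
            aggregate(cells)

    def test_permutation_invariance(self):
        cells = _table2_service_cells()
        shuffled = cells.copy()
        random.Random(7).shuffle(shuffled)
        a, b = aggregate(cells), aggregate(shuffled)
        assert a.grand_total == b.grand_total
        assert a.disease_by_service.sort_index().equals(
            b.disease_by_service.sort_index())

    def test_sex_stratified_sums_conserve_total_at_full_precision(self):
        rng = np.random.default_rng(3)
        cells = []
        for d in ("CHD", "stroke"):
            for s in ("hospitalization", "consultation"):
                for x in ("male", "female"):
                    cells.append(AttributableCost(d, s, x, float(rng.uniform(0, 1e6))))
        report = aggregate(cells)
        by_sex = sum(v.loc["Total", "Total"] for v in report.sex_tables.values())
        assert by_sex == pytest.approx(report.grand_total, rel=1e-14)

    def test_unavailable_cells_are_excluded_not_zero_filled(self):
        cells = [
            AttributableCost("CHD", "medication", "male", 100.0),
            AttributableCost("hypertensive", "medication", "male", 900.0),
            AttributableCost("CHD", "hospitalization", "male", 500.0),
            AttributableCost("hypertensive", "hospitalization", "male", 500.0),
        ]
        report = aggregate(cells)
        assert ("stroke", "medication") not in {
            (d, s) for d, s in zip(report.cells["disease"], report.cells["service"])}
        # medication total counts only the two present diseases
        assert report.disease_by_service.loc["Total", "medication"] == 1000.0


class TestRendering:
    def test_thousands_rounding_half_away(self):
        report = aggregate([AttributableCost("CHD", "hospitalization", "male",
                                             1_499.99),
                            AttributableCost("CHD", "consultation", "male",
                                             2_500.0)])
        rendered = render_thousands(report.disease_by_service)
        assert rendered.loc["CHD", "hospitalization"] == 1
        assert rendered.loc["CHD", "consultation"] == 3

    def test_integer_shares_of_zero_total(self):
        import pandas as pd
        s = integer_shares(pd.Series({"a": 0.0, "b": 0.0}))
        assert (s == 0).all()
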