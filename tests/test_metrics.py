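"""Response curves, dynamic range, energy measures, and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendroprune import (
    DynamicsParams,
    classify,
    dynamic_range,
    energy,
    isolated_rate_oracle,
    make_chain,
    response_curve,
    simulate,
)
from dendroprune.metrics import (
    DynamicRangeOutOfGrid,
    ResponseCurve,
    UndefinedDynamicRange,
    cell_seed,
    mean_over_cells,
    parameter_space_mean,
)


def curve(h, F, P=0.9):
    return ResponseCurve(h_grid=np.asarray(h, float), F=np.asarray(F, float),
                         target=1, P=P, n_steps=0, seed=0)


class TestDynamicRange:
    def test_exact_crossings_give_delta_20(self):
        # F10 = 10, F90 = 90 hit exactly at h = 1 and h = 100
        c = curve([0.1, 1.0, 10.0, 100.0, 1000.0],
                  [0.0, 10.0, 50.0, 90.0, 100.0])
        dr = dynamic_range(c)
        assert dr.h10 == pytest.approx(1.0)
        assert dr.h90 == pytest.approx(100.0)
        assert dr.delta == pytest.approx(20.0)

    def test_step_confined_to_one_decade(self):
        # the whole rise happens inside one decade segment: both crossings
        # interpolate into it, so delta = 10 * (0.9 - 0.1) * 1 decade = 8
        c = curve([0.1, 1.0, 10.0], [0.0, 100.0, 100.0])
        dr = dynamic_range(c)
        assert dr.h10 == pytest.approx(10 ** -0.9)
        assert dr.h90 == pytest.approx(10 ** -0.1)
        assert dr.delta == pytest.approx(8.0)

    def test_crossing_exactly_at_grid_points(self):
        c = curve([0.1, 1.0, 10.0, 100.0], [0.0, 10.0, 90.0, 100.0])
        dr = dynamic_range(c)
        assert dr.h10 == pytest.approx(1.0)
        assert dr.h90 == pytest.approx(10.0)
        assert dr.delta == pytest.approx(10.0)

    def test_hand_interpolated_piecewise_linear_curve(self):
        # F = 0,30,60,90,120,125 Hz on the decade grid 1e-1..1e4:
        # F_max=125, F10=12.5 crosses between the first two points at
        # log10 h = -1 + 12.5/30; F90=112.5 between 90 and 120 at 2.75;
        # delta = 10*(2.75 + 0.5833...) = 33.3333...
        c = curve(np.logspace(-1, 4, 6), [0, 30, 60, 90, 120, 125])
        dr = dynamic_range(c)
        assert dr.F_max == 125.0
        assert dr.h10 == pytest.approx(10 ** (-1 + 12.5 / 30))
        assert dr.h90 == pytest.approx(10 ** 2.75)
        assert dr.delta == pytest.approx(33.33333333333333)

    def test_all_zero_curve_is_undefined(self):
        with pytest.raises(UndefinedDynamicRange):
            dynamic_range(curve([1.0, 10.0], [0.0, 0.0]))

    def test_unbracketed_low_bound_reported(self):
        with pytest.raises(DynamicRangeOutOfGrid) as exc:
            dynamic_range(curve([1.0, 10.0, 100.0], [50.0, 80.0, 100.0]))
        assert exc.value.bound == "h10"

    def test_invariant_to_grid_density_on_smooth_curve(self):
        # sampling the exact isolated-compartment response at 5 vs 10
        # points per decade moves delta by < 0.2
        deltas = []
        for ppd in (5, 10):
            h = np.logspace(-2, 5, 7 * ppd + 1)
            F = np.array([isolated_rate_oracle(v) for v in h])
            deltas.append(dynamic_range(curve(h, F)).delta)
        assert abs(deltas[0] - deltas[1]) < 0.2


class TestEnergy:
    @staticmethod
    def counts_from(values):
        from dendroprune.dynamics import SpikeCounts

        return SpikeCounts(
            ids=tuple(range(len(values))),
            counts=np.asarray(values, dtype=np.int64),
            n_counted_steps=1000, dt=0.001,
        )

    def test_stated_arithmetic(self):
        e = energy(self.counts_from([10, 5, 15]))
        assert e.E == pytest.approx(2.0)
        assert e.E_rel == pytest.approx(1.0)
        assert e.defined

    def test_silent_dendrites(self):
        e = energy(self.counts_from([10, 0, 0, 0]))
        assert e.E == 0.0 and e.E_rel == 0.0

    def test_efficiency_boundary(self):
        # every compartment fires as often as the soma: E = N, E_rel = 1
        e = energy(self.counts_from([7, 7, 7, 7]))
        assert e.E == pytest.approx(3.0)
        assert e.E_rel == pytest.approx(1.0)

    def test_silent_soma_flagged_not_infinite(self):
        e = energy(self.counts_from([0, 5, 5]))
        assert not e.defined
        assert math.isnan(e.E) and math.isnan(e.E_rel)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=2, max_size=30),
           st.integers(1, 500))
    def test_E_equals_N_times_Erel(self, dend, soma):
        e = energy(self.counts_from([soma] + dend))
        assert e.E == pytest.approx(e.E_rel * e.N)


class TestResponseCurve:
    def test_grid_of_only_zero_rate(self):
        m = make_chain(1)
        c = response_curve(m, 0.5, [0.0], n_steps=500, seed=1)
        assert c.F.tolist() == [0.0]

    def test_empty_or_unsorted_grid_rejected(self):
        m = make_chain(1)
        with pytest.raises(ValueError):
            response_curve(m, 0.5, [], n_steps=100, seed=0)
        with pytest.raises(ValueError):
            response_curve(m, 0.5, [1.0, 1.0], n_steps=100, seed=0)

    def test_soma_only_curve_matches_closed_form(self):
        m = make_chain(0)
        h = np.logspace(0, 4, 5)
        c = response_curve(m, 0.5, h, n_steps=40_000, seed=7)
        for hv, F in zip(h, c.F):
            expected = isolated_rate_oracle(hv)
            # generous Monte-Carlo band: 3 * sqrt(rate/(T)) in Hz terms
            se = math.sqrt(max(expected, 1.0) / (40_000 * 0.001))
            assert abs(F - expected) < 3 * se


class TestParameterSpaceMean:
    def test_mean_over_cells_arithmetic(self):
        rows = [{"E": v, "defined": True} for v in (1.0, 2.0, 3.0, 4.0)]
        mean, excl = mean_over_cells(rows, "E")
        assert mean == pytest.approx(2.5) and excl == 0

    def test_undefined_cells_excluded_and_counted(self):
        rows = [
            {"E": 2.0, "defined": True},
            {"E": float("nan"), "defined": False},
        ]
        mean, excl = mean_over_cells(rows, "E")
        assert mean == pytest.approx(2.0) and excl == 1

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            mean_over_cells([{"E": float("nan"), "defined": False}], "E")

    def test_runs_on_morphology_with_explicit_grid(self):
        m = make_chain(2)
        mean, excl = parameter_space_mean(
            m, "E_rel", p_grid=[0.6, 0.9], h_grid=[1.0, 100.0],
            n_steps=2000, seed=3,
        )
        assert mean >= 0.0 and 0 <= excl <= 4

    def test_quantity_validated(self):
        with pytest.raises(ValueError):
            parameter_space_mean(make_chain(1), "F", n_steps=10, seed=0)


class TestClassify:
    @pytest.mark.parametrize(
        "stems,centrality,expected",
        [
            (1, 0.9, "Type 2"),
            (1, 0.1, "Type 2"),
            (2, 0.5, "Type T"),
            (8, 0.9, "Type 1"),
            (8, 0.1, "Type 3"),
            (3, 0.3, "Type 1"),  # boundary is inclusive upward
        ],
    )
    def test_rules(self, stems, centrality, expected):
        assert classify(stems, centrality) == expected

    def test_threshold_configurable(self):
        assert classify(5, 0.4, centrality_threshold=0.5) == "Type 3"


class TestCellSeed:
    def test_stable_and_distinct(self):
        a = cell_seed(42, 0, 1, 2)
        assert a == cell_seed(42, 0, 1, 2)
        assert a != cell_seed(42, 0, 1, 3)
        assert 0 <= a < 2**31
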