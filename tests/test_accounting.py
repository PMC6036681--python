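"""Unit tests for the headspace mole-balance module."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cowgas.accounting import (
    GAS_CONSTANT_ML_BAR,
    SPECIES,
    BalanceResult,
    BottleSpec,
    GasComposition,
    MeasurementSeries,
    SamplePoint,
    cumulative_balance,
    detect_h2_onset,
    growth_summary,
    headspace_amounts,
    headspace_volume_at,
    normalize_composition,
    o2_depletion_time,
    withdrawal_amounts,
    yield_h2_per_co,
)

from _oracles import ledger_balance

R = GAS_CONSTANT_ML_BAR
T_INC = 333.15


def _balance_with(times, q_h2=None, n_o2=None):
    """Minimal BalanceResult carrying only the columns a summary op reads."""
    n = len(times)
    cumulative = np.zeros((n, len(SPECIES)))
    headspace = np.zeros((n, len(SPECIES)))
    if q_h2 is not None:
        cumulative[:, SPECIES.index("h2")] = q_h2
    if n_o2 is not None:
        headspace[:, SPECIES.index("o2")] = n_o2
    return BalanceResult(
        times=np.asarray(times, dtype=float),
        headspace_volumes=np.full(n, 200.0),
        headspace=headspace,
        removed=np.zeros((n, len(SPECIES))),
        cumulative=cumulative,
        summary=None,
    )


class TestNormalizeComposition:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (dict(co=0.5, o2=0.105, n2=0.395), dict(co=0.5, o2=0.105, n2=0.395)),
            (dict(co=1.0), dict(co=1.0)),
            (dict(co=0.4, o2=0.1, n2=0.3), dict(co=0.5, o2=0.125, n2=0.375)),
        ],
    )
    def test_examples(self, raw, expected):
        out = normalize_composition(GasComposition(**raw))
        for sp in SPECIES:
            assert out[sp] == pytest.approx(expected.get(sp, 0.0), abs=1e-12)
        assert out.total() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError, match="empty GC"):
            normalize_composition(GasComposition())

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=5, max_size=5).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    def test_proportionality(self, fracs):
        raw = GasComposition.from_array(fracs)
        out = normalize_composition(raw)
        assert out.total() == pytest.approx(1.0, abs=1e-9)
        total = raw.total()
        for sp in SPECIES:
            assert out[sp] == pytest.approx(raw[sp] / total, rel=1e-9)


class TestHeadspaceAmounts:
    def test_closed_form_co(self):
        comp = GasComposition(co=0.5, o2=0.105, n2=0.395)
        n = headspace_amounts(comp, 1.0, 200.0, 298.15)
        assert n.co == pytest.approx(0.5 * 1.0 * 200.0 / (R * 298.15), rel=1e-12)
        assert n.co == pytest.approx(4.034, abs=5e-4)
        assert n.total() == pytest.approx(1.0 * 200.0 / (R * 298.15), rel=1e-12)

    def test_initial_o2_of_half_air_fill(self):
        # 50% air at 1 bar, 298.15 K in a 200 ml headspace holds 0.85 mmol O2
        comp = GasComposition(co=0.5, o2=0.105, n2=0.395)
        n = headspace_amounts(comp, 1.0, 200.0, 298.15)
        assert round(n.o2, 2) == 0.85

    def test_absent_species_is_zero(self):
        n = headspace_amounts(GasComposition(co=1.0), 1.0, 200.0, 298.15)
        assert n.h2 == 0.0 and n.co2 == 0.0

    @pytest.mark.parametrize("bad", [dict(pressure=0.0), dict(headspace_volume=-1.0), dict(temperature=0.0)])
    def test_nonpositive_inputs_error(self, bad):
        kwargs = dict(pressure=1.0, headspace_volume=200.0, temperature=298.15)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            headspace_amounts(GasComposition(co=1.0), **kwargs)


class TestWithdrawalAmounts:
    def test_no_pressure_drop_removes_nothing(self):
        out = withdrawal_amounts(GasComposition(co=1.0), 1.0, 1.0, 200.0, T_INC)
        assert out.total() == 0.0

    def test_co_share_of_a_3ml_draw(self):
        comp = GasComposition(co=0.5, n2=0.5)
        out = withdrawal_amounts(comp, 1.0, 1.0 - 0.015, 200.0, T_INC)
        assert out.co == pytest.approx(0.5 * 0.015 * 200.0 / (R * T_INC), rel=1e-12)
        assert out.co == pytest.approx(0.0542, abs=5e-5)
        assert out.co == pytest.approx(0.5 * out.total(), rel=1e-12)

    def test_total_matches_explicit_mole_ledger(self):
        # 3 ml drawn at bottle pressure from 200 ml: the syringe holds
        # n_tot*(3/200) moles, i.e. the full pressure-drop equivalent.
        n_tot = 1.0 * 200.0 / (R * T_INC)
        expected_total = n_tot * 3.0 / 200.0
        delta_p = 1.0 * 3.0 / 200.0
        out = withdrawal_amounts(
            GasComposition(co=0.5, n2=0.5), 1.0, 1.0 - delta_p, 200.0, T_INC
        )
        assert out.total() == pytest.approx(expected_total, rel=1e-12)
        assert out.total() == pytest.approx(0.1083, abs=5e-5)

    def test_inverted_pressures_error(self):
        with pytest.raises(ValueError, match="manometer"):
            withdrawal_amounts(GasComposition(co=1.0), 1.0, 1.01, 200.0, T_INC)


def _point(time, p_before, p_after, comp, od=None, v_gas=3.0, v_liq=1.0):
    return SamplePoint(
        time=time,
        pressure_before=p_before,
        pressure_after=p_after,
        composition=comp,
        od600=od,
        gas_sample_volume=v_gas,
        liquid_sample_volume=v_liq,
    )


class TestHeadspaceVolume:
    def test_initial_volume(self):
        series = MeasurementSeries(
            BottleSpec(),
            [
                _point(float(t), 1.0, 0.99, GasComposition(n2=1.0))
                for t in range(6)
            ],
        )
        assert headspace_volume_at(series.bottle, series, 0) == 200.0
        assert headspace_volume_at(series.bottle, series, 5) == 205.0

    def test_no_liquid_draws_constant_volume(self):
        series = MeasurementSeries(
            BottleSpec(),
            [
                _point(float(t), 1.0, 0.99, GasComposition(n2=1.0), v_liq=0.0)
                for t in range(4)
            ],
        )
        assert all(
            headspace_volume_at(series.bottle, series, i) == 200.0 for i in range(4)
        )

    def test_out_of_range(self):
        series = MeasurementSeries(
            BottleSpec(),
            [_point(0.0, 1.0, 0.99, GasComposition(n2=1.0)),
             _point(1.0, 1.0, 0.99, GasComposition(n2=1.0))],
        )
        with pytest.raises(IndexError):
            headspace_volume_at(series.bottle, series, 2)


class TestCumulativeBalance:
    def test_two_identical_points_conserve_everything(self):
        comp = GasComposition(co=0.4, o2=0.1, n2=0.5)
        points = [
            _point(0.0, 1.0, None, comp, v_gas=0.0, v_liq=0.0),
            _point(4.0, 1.0, None, comp, v_gas=0.0, v_liq=0.0),
        ]
        balance = cumulative_balance(MeasurementSeries(BottleSpec(), points))
        assert np.abs(balance.cumulative).max() < 1e-12

    def test_toy_mole_ledger(self):
        # n_CO(0)=2.0 mmol in 200 ml; the sampling removes 0.1 mmol CO (and
        # 0.1 mmol N2); n_CO(1)=1.5 mmol -> Q_CO(1) = 1.5 - 2.0 + 0.1 = -0.4.
        v0 = 200.0
        comp0 = GasComposition(co=0.5, n2=0.5)
        p0 = 4.0 * R * T_INC / v0  # n_tot(0) = 4.0 mmol
        p0_after = p0 - 0.2 * R * T_INC / v0  # 0.2 mmol removed in total
        v1 = 201.0
        n_co1, n_n21 = 1.5, 1.9
        p1 = (n_co1 + n_n21) * R * T_INC / v1
        comp1 = GasComposition(co=n_co1 / (n_co1 + n_n21), n2=n_n21 / (n_co1 + n_n21))
        series = MeasurementSeries(
            BottleSpec(),
            [_point(0.0, p0, p0_after, comp0), _point(10.0, p1, p1, comp1, v_gas=0.0)],
        )
        balance = cumulative_balance(series)
        assert balance.cumulative_for("co")[0] == pytest.approx(0.0, abs=1e-12)
        assert balance.cumulative_for("co")[-1] == pytest.approx(-0.4, abs=1e-9)
        assert balance.cumulative_for("n2")[-1] == pytest.approx(0.0, abs=1e-9)

    def test_removed_total_matches_pressure_drop(self, dsm2542_run):
        _, series, balance = dsm2542_run
        for i, point in enumerate(series.points):
            expected = (
                (point.pressure_before - point.pressure_after)
                * balance.headspace_volumes[i]
                / (R * T_INC)
            )
            assert balance.removed[i].sum() == pytest.approx(expected, abs=1e-9)

    def test_needs_two_points(self):
        series = MeasurementSeries(
            BottleSpec(), [_point(0.0, 1.0, 0.99, GasComposition(n2=1.0))]
        )
        with pytest.raises(ValueError, match="at least 2"):
            cumulative_balance(series)

    @given(
        st.integers(min_value=2, max_value=5),
        st.randoms(use_true_random=False),
    )
    def test_matches_brute_force_ledger(self, n_points, rnd):
        """Array pipeline equals an explicit scalar ledger on short series."""
        points = []
        t = 0.0
        for _ in range(n_points):
            t += rnd.uniform(0.5, 8.0)
            fracs = [rnd.uniform(0.05, 1.0) for _ in SPECIES]
            total = sum(fracs)
            comp = GasComposition.from_array([f / total for f in fracs])
            p_before = rnd.uniform(0.8, 1.2)
            p_after = p_before - rnd.uniform(0.0, 0.03)
            points.append(
                _point(t, p_before, p_after, comp, v_liq=rnd.choice([0.0, 1.0, 2.0]))
            )
        series = MeasurementSeries(BottleSpec(), points)
        balance = cumulative_balance(series)
        expected = ledger_balance(series)
        for i in range(n_points):
            for j, sp in enumerate(SPECIES):
                assert balance.cumulative[i, j] == pytest.approx(
                    expected[i][sp], abs=1e-10
                )

    def test_missing_pressure_after_uses_nominal_draw(self, caplog):
        comp = GasComposition(co=0.4, o2=0.1, n2=0.5)
        points = [
            _point(0.0, 1.0, None, comp, v_gas=3.0, v_liq=0.0),
            _point(4.0, 1.0, None, comp, v_gas=3.0, v_liq=0.0),
        ]
        with caplog.at_level("WARNING", logger="cowgas.accounting"):
            balance = cumulative_balance(MeasurementSeries(BottleSpec(), points))
        assert "missing pressure_after" in caplog.text
        expected = 1.0 * (3.0 / 200.0) * 200.0 / (R * T_INC)
        assert balance.removed[0].sum() == pytest.approx(expected, rel=1e-9)


class TestSummaries:
    def test_yield_printed_amounts(self):
        bal = _balance_with([0.0, 84.0], q_h2=[0.0, 2.47])
        bal.cumulative[:, SPECIES.index("co")] = [0.0, -2.28]
        assert round(yield_h2_per_co(bal), 2) == 1.08

    def test_yield_equimolar_and_zero(self):
        bal = _balance_with([0.0, 10.0], q_h2=[0.0, 1.0])
        bal.cumulative[:, SPECIES.index("co")] = [0.0, -1.0]
        assert yield_h2_per_co(bal) == pytest.approx(1.0)
        bal = _balance_with([0.0, 10.0], q_h2=[0.0, 0.0])
        bal.cumulative[:, SPECIES.index("co")] = [0.0, -0.37]
        assert yield_h2_per_co(bal) == 0.0

    def test_yield_undefined_without_co_consumption(self):
        bal = _balance_with([0.0, 10.0], q_h2=[0.0, 1.0])
        with pytest.raises(ValueError, match="undefined"):
            yield_h2_per_co(bal)

    def test_onset_detection(self):
        bal = _balance_with([0.0, 32.0, 35.89, 40.0], q_h2=[0.0, 0.005, 0.046, 0.4])
        assert detect_h2_onset(bal) == pytest.approx(35.89)
        assert detect_h2_onset(bal, threshold=1.0) is None
        assert detect_h2_onset(_balance_with([0.0, 84.0], q_h2=[0.0, 0.0])) is None
        with pytest.raises(ValueError):
            detect_h2_onset(bal, threshold=0.0)

    def test_o2_depletion(self):
        bal = _balance_with([0.0, 10.0, 22.0, 30.0], n_o2=[0.85, 0.3, 0.03, 0.01])
        assert o2_depletion_time(bal) == pytest.approx(22.0)
        assert o2_depletion_time(bal, threshold=0.005) is None
        # strict inequality: a zero threshold can never trigger
        assert o2_depletion_time(bal, threshold=0.0) is None

    def test_growth_summary(self):
        comp = GasComposition(n2=1.0)
        series = MeasurementSeries(
            BottleSpec(),
            [
                _point(0.0, 1.0, 0.99, comp, od=0.1),
                _point(6.01, 1.0, 0.99, comp, od=0.82),
                _point(84.0, 1.0, 0.99, comp, od=0.71),
            ],
        )
        gs = growth_summary(series)
        assert gs == (0.82, 6.01, 0.71)

    def test_growth_tie_prefers_earliest(self):
        comp = GasComposition(n2=1.0)
        series = MeasurementSeries(
            BottleSpec(),
            [_point(1.0, 1.0, 0.99, comp, od=0.5), _point(2.0, 1.0, 0.99, comp, od=0.5)],
        )
        gs = growth_summary(series)
        assert gs.max_od_time == 1.0 and gs.final_od == 0.5

    def test_growth_skips_missing_od(self):
        comp = GasComposition(n2=1.0)
        series = MeasurementSeries(
            BottleSpec(),
            [
                _point(0.0, 1.0, 0.99, comp, od=None),
                _point(5.0, 1.0, 0.99, comp, od=0.6),
            ],
        )
        assert growth_summary(series).max_od == 0.6

    def test_growth_requires_some_od(self):
        comp = GasComposition(n2=1.0)
        series = MeasurementSeries(
            BottleSpec(),
            [_point(0.0, 1.0, 0.99, comp), _point(5.0, 1.0, 0.99, comp)],
        )
        with pytest.raises(ValueError, match="OD600"):
            growth_summary(series)


class TestValidation:
    def test_nonmonotone_times_rejected(self):
        comp = GasComposition(n2=1.0)
        with pytest.raises(ValueError, match="strictly increasing"):
            MeasurementSeries(
                BottleSpec(),
                [_point(4.0, 1.0, 0.99, comp), _point(2.0, 1.0, 0.99, comp)],
            )

    def test_pressure_after_cannot_exceed_before(self):
        with pytest.raises(ValueError, match="pressure_after"):
            _point(0.0, 1.0, 1.1, GasComposition(n2=1.0))

    def test_bottle_invariants(self):
        with pytest.raises(ValueError):
            BottleSpec(total_volume=50.0, initial_liquid_volume=60.0)
        with pytest.raises(ValueError):
            BottleSpec(fill_pressure=0.0)
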