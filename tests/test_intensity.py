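"""Interval/category/transition intensities against hand arithmetic and a
brute-force oracle, plus the framework's weighted-mean identities."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lcintensity import (
    MatrixSeries,
    TransitionMatrix,
    category_intensities,
    interval_intensity,
    simple_scheme,
    stationarity_table,
    transition_profile,
    uniform_intensity,
)
from tests._oracle import oracle_gain_loss, oracle_interval, oracle_transition, oracle_uniform
from tests.conftest import random_matrix


class TestIntervalLevel:
    def test_worked_fixture(self, m_star):
        rec = interval_intensity(m_star)
        assert rec.gross_change_km2 == 35
        assert rec.gross_change_pct == pytest.approx(35 / 300 * 100)
        assert rec.annual_intensity == pytest.approx(35 / 5 / 300 * 100)  # 2.3333 %/yr

    def test_diagonal_matrix_no_change(self):
        rec = interval_intensity(TransitionMatrix(np.eye(3) * 50, ["A", "B", "C"], 2000, 2005))
        assert rec.gross_change_km2 == 0
        assert rec.annual_intensity == 0

    def test_scale_invariance(self, m_star):
        doubled = TransitionMatrix(2 * m_star.values, m_star.labels, 1985, 1990)
        a, b = interval_intensity(m_star), interval_intensity(doubled)
        assert a.gross_change_pct == pytest.approx(b.gross_change_pct)
        assert a.annual_intensity == pytest.approx(b.annual_intensity)

    def test_zero_total_area_rejected(self):
        with pytest.raises(ValueError, match="zero total area"):
            interval_intensity(TransitionMatrix(np.zeros((2, 2)), ["A", "B"], 2000, 2005))


class TestUniformIntensity:
    def test_worked_two_interval_series(self, series_two):
        u, recs = uniform_intensity(series_two)
        assert u == pytest.approx(53 / 2100 * 100)  # 2.5238 %/yr
        assert recs[0].tempo == "slow"  # 2.3333 < U
        assert recs[1].tempo == "fast"  # 3.0 > U
        assert recs[1].annual_intensity == pytest.approx(3.0)

    def test_single_interval_u_equals_s_and_flag_equal(self, scheme_abc, m_star):
        series = MatrixSeries.from_matrices(scheme_abc, [m_star])
        u, recs = uniform_intensity(series)
        assert u == pytest.approx(recs[0].annual_intensity)
        assert recs[0].tempo == "equal"

    def test_identical_intervals_all_equal(self, scheme_abc, m_star):
        mats = [
            TransitionMatrix(m_star.values, m_star.labels, y, y + 5)
            for y in (1985, 1990, 1995)
        ]
        series = MatrixSeries.from_matrices(scheme_abc, mats)
        _, recs = uniform_intensity(series)
        assert all(r.tempo == "equal" for r in recs)


class TestCategoryLevel:
    def test_worked_fixture_intensities_and_statuses(self, m_star):
        recs = {r.category: r for r in category_intensities(m_star)}
        assert recs["A"].loss_intensity == pytest.approx(5.0)
        assert recs["A"].loss_status == "active"
        assert recs["A"].gain_intensity == pytest.approx(1.25)
        assert recs["A"].gain_status == "dormant"
        assert recs["B"].gain_intensity == pytest.approx(15 / 5 / 105 * 100)  # 2.857
        assert recs["B"].gain_status == "active"
        assert recs["B"].loss_intensity == pytest.approx(2.0)
        assert recs["B"].loss_status == "dormant"
        assert recs["C"].gain_intensity == pytest.approx(15 / 5 / 115 * 100)  # 2.609
        assert recs["C"].gain_status == "active"
        assert recs["C"].loss_intensity == 0
        assert recs["C"].loss_status == "dormant"

    def test_absent_category_undefined_both_sides(self):
        vals = [[50, 0, 0], [0, 50, 0], [0, 0, 0]]
        recs = {r.category: r for r in category_intensities(
            TransitionMatrix(vals, ["A", "B", "C"], 2000, 2005))}
        assert recs["C"].gain_status == "undefined"
        assert recs["C"].loss_status == "undefined"
        assert math.isnan(recs["C"].gain_intensity)

    def test_diagonal_matrix_dormant_or_equal(self):
        m = TransitionMatrix(np.eye(3) * 40, ["A", "B", "C"], 2000, 2005)
        for r in category_intensities(m, annual_intensity=1.0):
            assert r.gain_status == "dormant" and r.loss_status == "dormant"
        for r in category_intensities(m, annual_intensity=0.0):
            assert r.gain_status == "equal" and r.loss_status == "equal"


class TestTransitionLevel:
    def test_worked_fixture_gaining_b(self, m_star):
        prof = transition_profile(m_star, "B")
        assert prof.donors["A"]["intensity"] == pytest.approx(3.0)
        assert prof.donors["A"]["status"] == "targeted"
        assert prof.donors["C"]["intensity"] == 0
        assert prof.donors["C"]["status"] == "avoided"
        assert prof.uniform_transition_intensity == pytest.approx(1.5)

    def test_weighted_mean_identity_on_fixture(self, m_star):
        prof = transition_profile(m_star, "B")
        num = sum(
            d["intensity"] * d["start_size_km2"]
            for d in prof.donors.values()
            if not math.isnan(d["intensity"])
        )
        den = sum(
            d["start_size_km2"] for d in prof.donors.values() if not math.isnan(d["intensity"])
        )
        assert num / den == pytest.approx(prof.uniform_transition_intensity)

    def test_zero_gains_all_equal(self):
        vals = [[50, 0, 0], [0, 50, 0], [0, 10, 40]]
        prof = transition_profile(TransitionMatrix(vals, ["A", "B", "C"], 2000, 2005), "A")
        assert prof.uniform_transition_intensity == 0
        assert all(d["status"] == "equal" for d in prof.donors.values())

    def test_no_available_donor_area_undefined(self):
        vals = [[0, 0], [0, 100]]
        prof = transition_profile(TransitionMatrix(vals, ["A", "B"], 2000, 2005), "B")
        assert math.isnan(prof.uniform_transition_intensity)
        assert prof.donors["A"]["status"] == "undefined"

    def test_targeted_and_avoided_both_present_when_gaining(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            m = random_matrix(rng, 5)
            for n in m.labels:
                prof = transition_profile(m, n)
                statuses = [d["status"] for d in prof.donors.values()]
                gains = sum(d["area_km2"] for d in prof.donors.values())
                if gains > 0:  # W is a weighted mean of the defined R's
                    assert any(s in ("targeted", "equal") for s in statuses)
                    assert any(s in ("avoided", "equal") for s in statuses)


class TestOracleEquivalence:
    """Vectorized statistics vs explicit-loop reimplementation."""

    def test_hundred_random_matrices(self):
        rng = np.random.default_rng(42)
        for k in range(100):
            m = random_matrix(rng, n_cat=int(rng.integers(2, 7)), duration=int(rng.integers(1, 9)),
                              sparsity=0.3 if k % 3 == 0 else 0.0)
            c = m.values.tolist()
            gross, pct, s = oracle_interval(c, m.duration)
            rec = interval_intensity(m)
            assert rec.gross_change_km2 == pytest.approx(gross, rel=1e-12)
            assert rec.annual_intensity == pytest.approx(s, rel=1e-12)
            for idx, r in enumerate(category_intensities(m)):
                g_o, l_o = oracle_gain_loss(c, m.duration, idx)
                assert r.gain_intensity == pytest.approx(g_o, rel=1e-12, nan_ok=True)
                assert r.loss_intensity == pytest.approx(l_o, rel=1e-12, nan_ok=True)
            for n_idx, n in enumerate(m.labels):
                rs, w = oracle_transition(c, m.duration, n_idx)
                prof = transition_profile(m, n)
                assert prof.uniform_transition_intensity == pytest.approx(w, rel=1e-12, nan_ok=True)
                for m_idx, r_val in rs.items():
                    assert prof.donors[m.labels[m_idx]]["intensity"] == pytest.approx(
                        r_val, rel=1e-12, nan_ok=True
                    )

    def test_uniform_intensity_oracle(self, scheme_abc):
        rng = np.random.default_rng(9)
        year = 1985
        mats = []
        for dur in (5, 5, 2, 7):
            mats.append(random_matrix(rng, 3, from_year=year, duration=dur, labels=["A", "B", "C"]))
            year += dur
        series = MatrixSeries.from_matrices(scheme_abc, mats)
        u, _ = uniform_intensity(series)
        assert u == pytest.approx(
            oracle_uniform([(m.values.tolist(), m.duration) for m in mats]), rel=1e-12
        )


@st.composite
def area_matrices(draw):
    n = draw(st.integers(2, 6))
    vals = draw(
        arrays(
            float,
            (n, n),
            elements=st.floats(0, 1e4, allow_nan=False, allow_infinity=False),
        )
    )
    vals = vals + np.diag(np.full(n, 1.0))  # keep total area positive
    dur = draw(st.integers(1, 10))
    labels = [chr(ord("A") + k) for k in range(n)]
    return TransitionMatrix(vals, labels, 2000, 2000 + dur)


class TestWeightedMeanIdentities:
    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(area_matrices())
    def test_s_is_weighted_mean_of_losses_and_gains(self, m):
        s = interval_intensity(m).annual_intensity
        recs = category_intensities(m, annual_intensity=s)
        start_num = sum(r.loss_intensity * r.start_size_km2 for r in recs if not math.isnan(r.loss_intensity))
        start_den = sum(r.start_size_km2 for r in recs if not math.isnan(r.loss_intensity))
        end_num = sum(r.gain_intensity * r.end_size_km2 for r in recs if not math.isnan(r.gain_intensity))
        end_den = sum(r.end_size_km2 for r in recs if not math.isnan(r.gain_intensity))
        assert start_num / start_den == pytest.approx(s, rel=1e-10, abs=1e-12)
        assert end_num / end_den == pytest.approx(s, rel=1e-10, abs=1e-12)

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(area_matrices())
    def test_w_is_availability_weighted_mean_of_r(self, m):
        for n in m.labels:
            prof = transition_profile(m, n)
            defined = [d for d in prof.donors.values() if not math.isnan(d["intensity"])]
            den = sum(d["start_size_km2"] for d in defined)
            if den == 0:
                assert math.isnan(prof.uniform_transition_intensity)
                continue
            num = sum(d["intensity"] * d["start_size_km2"] for d in defined)
            assert num / den == pytest.approx(
                prof.uniform_transition_intensity, rel=1e-10, abs=1e-12
            )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(area_matrices(), st.floats(0.1, 100.0, allow_nan=False))
    def test_scale_invariance_of_statuses(self, m, c):
        scaled = TransitionMatrix(c * m.values, m.labels, m.from_year, m.to_year)
        for a, b in zip(category_intensities(m), category_intensities(scaled)):
            assert a.gain_status == b.gain_status
            assert a.loss_status == b.loss_status
        for n in m.labels:
            pa, pb = transition_profile(m, n), transition_profile(scaled, n)
            for key in pa.donors:
                assert pa.donors[key]["status"] == pb.donors[key]["status"]

    def test_u_is_duration_weighted_mean_of_s_when_totals_equal(self, scheme_abc):
        rng = np.random.default_rng(31)
        year, mats = 1985, []
        for dur in (5, 5, 2):
            v = rng.gamma(2.0, 5.0, (3, 3)) + np.diag([50, 50, 50.0])
            v *= 300.0 / v.sum()  # constant total area
            mats.append(TransitionMatrix(v, ["A", "B", "C"], year, year + dur))
            year += dur
        series = MatrixSeries.from_matrices(scheme_abc, mats)
        u, recs = uniform_intensity(series)
        num = sum(m.duration * r.annual_intensity for m, r in zip(mats, recs))
        den = sum(m.duration for m in mats)
        assert u == pytest.approx(num / den, rel=1e-10)


class TestStationarity:
    def test_identical_matrices_constant_status(self, scheme_abc, m_star):
        mats = [
            TransitionMatrix(m_star.values, m_star.labels, y, y + 5)
            for y in (1985, 1990, 1995)
        ]
        series = MatrixSeries.from_matrices(scheme_abc, mats)
        stat = stationarity_table(series)
        for statuses in stat.statuses.values():
            assert len(set(statuses)) == 1
        assert stat.count("A", "B") == 3  # targeted in every interval

    def test_constructed_intermittent_pattern(self, scheme_abc):
        # A->B targeted in intervals 1 and 3 only
        hot = [[80, 18, 2], [5, 90, 5], [10, 2, 88]]
        cold = [[96, 1, 3], [5, 90, 5], [2, 8, 90]]
        mats = [
            TransitionMatrix(v, ["A", "B", "C"], y, y + 5)
            for v, y in zip([hot, cold, hot], (1985, 1990, 1995))
        ]
        series = MatrixSeries.from_matrices(scheme_abc, mats)
        stat = stationarity_table(series)
        assert stat.statuses[("A", "B")] == ["targeted", "avoided", "targeted"]
        assert stat.count("A", "B") == 2
        assert stat.n_intervals == 3

    def test_no_change_series_all_counts_zero(self, scheme_abc):
        mats = [
            TransitionMatrix(np.eye(3) * 100, ["A", "B", "C"], y, y + 5)
            for y in (1985, 1990)
        ]
        series = MatrixSeries.from_matrices(scheme_abc, mats)
        stat = stationarity_table(series)
        assert all(stat.count(m, n) == 0 for (m, n) in stat.statuses)
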