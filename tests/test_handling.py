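"""Unit and property tests for the trip-duration and handling-time engines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bombusim.handling import (
    UNBOUNDED,
    ForagerTraits,
    HandlingConfig,
    access_time,
    fixed_handling_time,
    harder_handling_time,
    ingestion_time,
    n_flowers_per_load,
    trip_duration,
)

TRAITS = ForagerTraits(glossa_mm=11.1, weight_g=0.195)


def harder_ti_oracle(V, W, G, C):
    """Independent re-implementation of the ingestion-time regression."""
    arg = 0.3 * W ** (1 / 3) * G ** 1.41 * (1 - C / G) ** 0.4
    return math.log10(V + 1) / math.log10(arg) - 0.3 * (0.3 + 0.04 * C) + 1


class TestAccessTime:
    @pytest.mark.parametrize(
        "corolla, expected",
        [(0.0, 0.3), (10.0, 0.7), (19.0, 1.06)],
    )
    def test_linear_in_corolla_depth(self, corolla, expected):
        assert access_time(corolla) == pytest.approx(expected)

    def test_rejects_negative_corolla(self):
        with pytest.raises(ValueError):
            access_time(-1.0)


class TestIngestionTime:
    def test_matches_independent_oracle_at_zero_corolla(self):
        # frozen from the oracle: V=0.5 µl, W=0.195 g, G=11.1 mm, C=0
        ti = ingestion_time(0.5, TRAITS, 0.0, access_time(0.0))
        assert ti == pytest.approx(1.1564981495319915, rel=1e-12)
        assert ti == pytest.approx(harder_ti_oracle(0.5, 0.195, 11.1, 0.0))

    @pytest.mark.parametrize("corolla", [1.0, 3.0, 5.0, 8.0, 10.0])
    def test_matches_oracle_across_corolla_range(self, corolla):
        ti = ingestion_time(0.5, TRAITS, corolla, access_time(corolla))
        assert ti == pytest.approx(harder_ti_oracle(0.5, 0.195, 11.1, corolla))

    def test_unbounded_growth_towards_pole(self):
        # the regression has a pole just below the glossa length; approaching
        # it from shallower corollas the ingestion time grows without bound
        depths = [10.0, 10.5, 10.8, 10.9, 10.91]
        times = [ingestion_time(0.5, TRAITS, c, access_time(c)) for c in depths]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
        assert times[-1] > 10 * times[0]

    def test_corolla_at_or_past_glossa_is_unreachable(self):
        assert ingestion_time(0.5, TRAITS, 11.1, 0.3) == UNBOUNDED
        assert ingestion_time(0.5, TRAITS, 15.0, 0.3) == UNBOUNDED

    def test_past_pole_is_unbounded_sentinel(self):
        # between the pole (~10.92 mm for G=11.1) and G the denominator is <= 0
        assert ingestion_time(0.5, TRAITS, 11.0, access_time(11.0)) == UNBOUNDED

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ingestion_time(float("nan"), TRAITS, 0.0, 0.3)


class TestNFlowersPerLoad:
    @pytest.mark.parametrize(
        "crop, volume, expected",
        [(120, 0.5, 240), (120, 7, 18), (120, 240, 1)],
    )
    def test_ceiling_with_minimum_one(self, crop, volume, expected):
        assert n_flowers_per_load(crop, volume) == expected

    def test_rejects_zero_volume(self):
        with pytest.raises(ValueError):
            n_flowers_per_load(120, 0.0)


class TestHarderHandlingTime:
    def test_full_patch_example(self):
        r = harder_handling_time(1.0, 0.5, 1.5, 1.0, 100, 3600.0)
        assert r.total_handling_s == pytest.approx(300.0)
        assert not r.capped

    def test_depletion_scales_access_and_travel(self):
        r = harder_handling_time(1.0, 0.5, 1.5, 0.5, 100, 3600.0)
        assert r.total_handling_s == pytest.approx(450.0)

    def test_cap_engages_on_nearly_empty_patch(self):
        r = harder_handling_time(1.0, 0.5, 1.5, 0.02, 100, 3600.0)
        assert r.total_handling_s == 3600.0
        assert r.capped

    def test_zero_gamma_and_sentinel_ti_yield_cap(self):
        assert harder_handling_time(1.0, 0.5, 1.5, 0.0, 100).total_handling_s == 3600.0
        assert harder_handling_time(1.0, 0.5, UNBOUNDED, 1.0, 100).capped

    def test_monotone_in_corolla_depth_up_to_pole(self):
        # per-flower handling (access + travel + ingestion) must not decrease
        # with corolla depth; past the pole the cap takes over
        th = []
        for c in np.linspace(0.0, 10.9, 40):
            ta = access_time(c)
            ti = ingestion_time(1.5, TRAITS, c, ta)
            th.append(harder_handling_time(1.2, ta, ti, 1.0, 80).total_handling_s)
        assert all(b >= a - 1e-9 for a, b in zip(th, th[1:]))

    @given(
        tt=st.floats(0, 10),
        ta=st.floats(0.3, 1.06),
        ti=st.floats(0.1, 50),
        gamma=st.floats(0.001, 1.0),
        n=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_cap_invariant_and_monotone_in_gamma(self, tt, ta, ti, gamma, n):
        r = harder_handling_time(tt, ta, ti, gamma, n, 3600.0)
        assert r.total_handling_s <= 3600.0
        assert r.capped == (((tt + ta) / gamma + ti) * n >= 3600.0)
        # strictly decreasing in gamma below the cap
        r2 = harder_handling_time(tt, ta, ti, min(1.0, gamma * 1.5), n, 3600.0)
        if not r.capped and gamma < 1.0:
            assert r2.total_handling_s < r.total_handling_s


class TestFixedHandlingTime:
    @pytest.mark.parametrize(
        "fixed, gamma, expected, capped",
        [
            (900.0, 1.0, 900.0, False),
            (900.0, 0.5, 1800.0, False),
            (3600.0, 0.25, 3600.0, True),
            (3600.0, 1.0, 3600.0, True),  # at the cap depletion has no effect
        ],
    )
    def test_depletion_scaling_and_cap(self, fixed, gamma, expected, capped):
        r = fixed_handling_time(fixed, gamma, 3600.0)
        assert r.total_handling_s == pytest.approx(expected)
        assert r.capped == capped

    def test_zero_gamma_returns_cap(self):
        assert fixed_handling_time(900.0, 0.0).total_handling_s == 3600.0

    @given(
        fixed=st.floats(1.0, 3600.0),
        gamma=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_linear_in_fixed_below_cap(self, fixed, gamma):
        r1 = fixed_handling_time(fixed, gamma, 3600.0)
        r2 = fixed_handling_time(2 * fixed, gamma, 3600.0)
        assert r1.total_handling_s <= 3600.0
        if not r1.capped and not r2.capped:
            assert r2.total_handling_s == pytest.approx(2 * r1.total_handling_s)


class TestTripDuration:
    @pytest.mark.parametrize(
        "dist, v, th, expected",
        [(500, 5, 900, 1100), (0, 3, 900, 900)],
    )
    def test_round_trip_plus_handling(self, dist, v, th, expected):
        assert trip_duration(dist, v, th) == pytest.approx(expected)

    def test_rejects_zero_speed(self):
        with pytest.raises(ValueError):
            trip_duration(100, 0, 100)

    @given(
        dist=st.floats(0, 10000),
        v=st.floats(0.1, 20),
        th=st.floats(0, 3600),
    )
    @settings(max_examples=200, deadline=None)
    def test_additivity_against_oracle(self, dist, v, th):
        f = trip_duration(dist, v, th)
        assert f == pytest.approx(2 * dist / v + th)
        assert f - 2 * dist / v == pytest.approx(th, abs=1e-6)


def test_handling_config_validation():
    with pytest.raises(ValueError):
        HandlingConfig(t_max_s=0)
    with pytest.raises(ValueError):
        ForagerTraits(glossa_mm=-1)
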