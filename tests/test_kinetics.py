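"""Rate-law unit tests and algebraic-identity properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavekit import (
    ApparentRate,
    KineticParameters,
    ReactionState,
    fraction_cleaved,
    kapp_from_params,
    rate_equal_affinity,
    rate_full,
)
from cleavekit.errors import DomainError

conc = st.floats(0.01, 1000.0)
pos_conc = st.floats(0.01, 1000.0)


class TestRateFull:
    @pytest.mark.parametrize(
        "S,P,kcat,E0,K_M,K_P,expected",
        [
            # half-saturation, no product: plain Michaelis-Menten v = kcat*E0/2
            (10.0, 0.0, 1.0, 1.0, 10.0, 3.0, 0.5),
            # competitive product inhibition: 10/(10*(1 + 5/5 + 10/10)) = 1/3
            (10.0, 5.0, 1.0, 1.0, 10.0, 5.0, 10.0 / 30.0),
            (0.0, 50.0, 1.0, 1.0, 10.0, 5.0, 0.0),  # no substrate left
            (10.0, 0.0, 1.0, 0.0, 10.0, 5.0, 0.0),  # no enzyme
        ],
    )
    def test_values(self, S, P, kcat, E0, K_M, K_P, expected):
        params = KineticParameters(kcat=kcat, K_M=K_M, K_P=K_P, E0=E0, S0=S + P)
        assert rate_full(ReactionState(S=S, P=P), params) == pytest.approx(expected)

    @given(S=conc, P=st.floats(0, 1000), kcat=st.floats(0.001, 100),
           E0=conc, K_M=pos_conc)
    @settings(max_examples=200, derandomize=True)
    def test_reduces_to_michaelis_menten_without_product(self, S, P, kcat, E0, K_M):
        params = KineticParameters(kcat=kcat, K_M=K_M, K_P=K_M, E0=E0, S0=S + P)
        v = rate_full(ReactionState(S=S, P=0.0), params)
        assert v == pytest.approx(kcat * E0 * S / (K_M + S), rel=1e-12)

    def test_rejects_nonfinite_inputs(self):
        params = KineticParameters(kcat=1, K_M=10, K_P=10, E0=1, S0=10)
        with pytest.raises(DomainError, match="S"):
            rate_full(ReactionState(S=float("nan"), P=0.0), params)
        with pytest.raises(DomainError, match="P"):
            rate_full(ReactionState(S=1.0, P=-2.0), params)
        with pytest.raises(DomainError, match="K_M"):
            KineticParameters(kcat=1, K_M=0.0, K_P=10, E0=1, S0=10)


class TestEqualAffinity:
    def test_direct_value(self):
        params = KineticParameters(kcat=1, K_M=10, K_P=99, E0=1, S0=15)
        v = rate_equal_affinity(ReactionState(S=10, P=5), params)
        assert v == pytest.approx(0.4)

    @given(S=conc, P=st.floats(0, 1000), kcat=st.floats(0.001, 100),
           E0=conc, K_M=pos_conc)
    @settings(max_examples=200, derandomize=True)
    def test_identical_to_full_law_when_kp_equals_km(self, S, P, kcat, E0, K_M):
        params = KineticParameters(kcat=kcat, K_M=K_M, K_P=K_M, E0=E0, S0=S + P)
        state = ReactionState(S=S, P=P)
        assert rate_equal_affinity(state, params) == pytest.approx(
            rate_full(state, params), rel=1e-12
        )

    def test_initial_rate_limit(self):
        # at t=0 (P=0, S=S0) the velocity is kcat*E0*S0/(K_M+S0)
        params = KineticParameters(kcat=2.0, K_M=10, K_P=10, E0=1, S0=40)
        v = rate_equal_affinity(ReactionState(S=40, P=0), params)
        assert v == pytest.approx(2.0 * 1.0 * 40 / 50)

    @given(S=st.floats(0.01, 100), kcat=st.floats(0.01, 10), E0=conc,
           K_M=pos_conc, S0_extra=st.floats(0, 100))
    @settings(max_examples=200, derandomize=True)
    def test_reduces_to_first_order_under_mass_conservation(
        self, S, kcat, E0, K_M, S0_extra
    ):
        # with P = S0 - S the equal-affinity law collapses to v = k_app * S
        S0 = S + S0_extra
        params = KineticParameters(kcat=kcat, K_M=K_M, K_P=K_M, E0=E0, S0=S0)
        v = rate_equal_affinity(ReactionState(S=S, P=S0 - S), params)
        k_app = kapp_from_params(params).k_app
        assert v == pytest.approx(k_app * S, rel=1e-12)


class TestApparentRate:
    def test_worked_example(self):
        params = KineticParameters(kcat=1.0, K_M=10.0, K_P=10.0, E0=1.0, S0=90.0)
        rate = kapp_from_params(params)
        assert rate.k_app == pytest.approx(0.01)
        assert rate.provenance == "from-parameters"

    def test_no_substrate_limit(self):
        params = KineticParameters(kcat=2.0, K_M=5.0, K_P=5.0, E0=1.0, S0=0.0)
        assert kapp_from_params(params).k_app == pytest.approx(2.0 / 5.0)

    def test_linearity_in_enzyme_and_monotonicity_in_substrate(self):
        base = KineticParameters(kcat=1.0, K_M=10.0, K_P=10.0, E0=1.0, S0=50.0)
        assert kapp_from_params(base.with_(E0=2.0)).k_app == pytest.approx(
            2 * kapp_from_params(base).k_app
        )
        ks = [kapp_from_params(base.with_(S0=s)).k_app for s in (10, 50, 100, 500)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            ApparentRate(k_app=-0.1, provenance="fitted")


class TestFractionCleaved:
    def test_zero_time(self):
        assert fraction_cleaved(ApparentRate(5.0, "single-point"), 0.0) == 0.0

    def test_half_life_doubling(self):
        # 50% at one half-life, 75% at two: the on-column signature pair
        k = ApparentRate(math.log(2) / 15.0, "single-point")
        assert fraction_cleaved(k, 15.0) == pytest.approx(0.50)
        assert fraction_cleaved(k, 30.0) == pytest.approx(0.75)

    def test_completion_limit(self):
        assert fraction_cleaved(ApparentRate(1e6, "fitted"), 1.0) == pytest.approx(1.0)

    @given(k=st.floats(1e-4, 10), t1=st.floats(0, 100), dt=st.floats(0.01, 100))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_strictly_increasing(self, k, t1, dt):
        rate = ApparentRate(k, "single-point")
        f1 = fraction_cleaved(rate, t1)
        f2 = fraction_cleaved(rate, t1 + dt)
        assert 0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0
        assert f2 >= f1
        if f1 < 1.0 - 1e-12:
            assert f2 > f1

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            fraction_cleaved(ApparentRate(0.1, "fitted"), -1.0)

    def test_vectorized_over_times(self):
        out = fraction_cleaved(ApparentRate(0.1, "fitted"), np.array([0.0, 10.0]))
        assert out.shape == (2,) and out[0] == 0.0
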