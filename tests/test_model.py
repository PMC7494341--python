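"""Hill functions, weighted links and the vector field."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glitimer import (
    HillThresholds,
    KineticRates,
    ModelConfig,
    NetworkWeights,
    NoiseSettings,
    SystemState,
    hill_neg,
    hill_pos,
    rhs,
    rhs_arrays,
    weighted_hill_neg,
    weighted_hill_pos,
)
from glitimer.scenarios import make_preset


@pytest.mark.parametrize(
    "x, h, expected",
    [(0.0, 0.3, 0.0), (0.3, 0.3, 0.5), (0.6, 0.3, 0.8)],
)
def test_hill_pos_values(x, h, expected):
    assert hill_pos(x, h) == pytest.approx(expected, abs=1e-12)
    assert hill_neg(x, h) == pytest.approx(1.0 - expected, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(
    x=st.floats(min_value=0.0, max_value=100.0),
    h=st.floats(min_value=1e-3, max_value=10.0),
)
def test_hill_complement_and_bounds(x, h):
    p, n = hill_pos(x, h), hill_neg(x, h)
    assert p + n == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= p <= 1.0 and 0.0 <= n <= 1.0


def test_hill_monotone_limits():
    x = np.linspace(0, 50, 1000)
    p = hill_pos(x, 0.3)
    assert np.all(np.diff(p) > 0)
    assert hill_pos(1e9, 0.3) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("bad", [(-0.1, 0.3), (np.nan, 0.3), (0.5, 0.0), (0.5, -1.0)])
def test_hill_invalid_arguments(bad):
    with pytest.raises(ValueError):
        hill_pos(*bad)
    with pytest.raises(ValueError):
        hill_neg(*bad)


def test_weighted_hill_absent_link_is_identity():
    # weight 0 removes the link: factor 1 for any x, threshold never read
    for x in (0.0, 0.3, 1e6):
        assert weighted_hill_pos(x, None, 0.0) == 1.0
        assert weighted_hill_neg(x, None, 0.0) == 1.0


def test_weighted_hill_values():
    assert weighted_hill_neg(0.2, 0.2, 1.0) == pytest.approx(0.5)
    assert weighted_hill_pos(0.3, 0.3, 0.4) == pytest.approx(0.6 + 0.4 * 0.5)
    with pytest.raises(ValueError):
        weighted_hill_pos(0.3, 0.3, 1.5)


def test_weights_must_lie_in_unit_interval():
    with pytest.raises(ValueError):
        NetworkWeights(omega_TP=1.5)
    with pytest.raises(ValueError):
        NetworkWeights(omega_AT=-0.2)


def test_rates_validation_allows_clamped_gli():
    KineticRates(lambda_A=0.0)  # Gli1-ON clamp: constant GliA
    with pytest.raises(ValueError):
        KineticRates(v_T=0.0)
    with pytest.raises(ValueError):
        KineticRates(lambda_R=-0.1)


def test_active_link_requires_threshold():
    with pytest.raises(ValueError):
        ModelConfig(weights=NetworkWeights(omega_AP=1.0), thresholds=HillThresholds())


def test_rhs_no_links_relaxation_to_unit_production():
    cfg = ModelConfig()  # all weights 0
    d = rhs(SystemState(A=1, R=1, T=1.0, P=1.0), cfg)
    assert d[2] == pytest.approx(0.0, abs=1e-12)  # v_T(1 - T) at T = 1
    d0 = rhs(SystemState(A=1, R=1, T=0.0, P=1.0), cfg)
    assert d0[2] == pytest.approx(cfg.rates.v_T)


def test_rhs_full_network_initial_phox2b_drive():
    cfg = make_preset("WT")
    d = rhs(SystemState(A=1.0, R=1.0, T=0.0, P=0.0), cfg)
    # independent scalar evaluation of v_P * H+(1, 0.08) * H-(0, 0.3)
    expected = 90.0 * (1.0 / (0.08**2 + 1.0)) * 1.0
    assert d[3] == pytest.approx(expected, rel=1e-12)
    assert d[0] == pytest.approx(-0.86)
    assert d[1] == pytest.approx(-0.86)


def test_rhs_full_config_reduces_to_relay_row():
    # zeroing the WT-only weights must reproduce the relay-row field
    relay = make_preset("relay")
    wt = make_preset("WT")
    reduced = ModelConfig(
        weights=NetworkWeights(omega_RT=1.0, omega_TP=1.0),
        thresholds=HillThresholds(h_AT=wt.thresholds.h_AT, h_RT=0.15,
                                  h_TT=wt.thresholds.h_TT, h_AP=wt.thresholds.h_AP,
                                  h_TP=0.3),
        rates=wt.rates, noise=wt.noise, initial_state=wt.initial_state,
    )
    rng = np.random.default_rng(0)
    for _ in range(20):
        s = SystemState(*rng.uniform(0.01, 1.0, size=4))
        assert np.allclose(rhs(s, reduced), rhs(s, relay))


def test_rhs_rejects_nonfinite_state():
    cfg = make_preset("relay")
    state = SystemState(A=1, R=1, T=0, P=1)
    object.__setattr__(state, "T", np.nan)
    with pytest.raises(ValueError):
        rhs(state, cfg)


@settings(derandomize=True, max_examples=100)
@given(
    wTT=st.floats(min_value=0.0, max_value=1.0),
    wRT=st.floats(min_value=0.0, max_value=1.0),
    wTP=st.floats(min_value=0.0, max_value=1.0),
    A=st.floats(min_value=0.0, max_value=2.0),
    R=st.floats(min_value=0.0, max_value=2.0),
)
def test_unit_interval_is_invariant_for_T_and_P(wTT, wRT, wTP, A, R):
    """Noise-free flow cannot leave [0,1]: inflow at 0, outflow at 1."""
    cfg = ModelConfig(
        weights=NetworkWeights(omega_RT=wRT, omega_TT=wTT, omega_TP=wTP),
        thresholds=HillThresholds(h_RT=0.15, h_TT=0.3, h_TP=0.3),
    )
    _, _, dT0, dP0 = rhs_arrays(A, R, 0.0, 0.0, cfg)
    _, _, dT1, dP1 = rhs_arrays(A, R, 1.0, 1.0, cfg)
    assert dT0 >= -1e-12 and dP0 >= -1e-12
    assert dT1 <= 1e-12 and dP1 <= 1e-12
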