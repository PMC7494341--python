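"""Tgfβ steady states, stability and hysteresis folds.

The independent oracle throughout is a dense brute-force sign-change scan
of g(T) on 2·10^5 grid points, evaluated directly from the Hill formulas
(no shared code path with the bisection-based implementation).
"""

import numpy as np
import pytest

from glitimer import sweep_R, t_steady_states
from glitimer.scenarios import make_preset


def _oracle_roots(R, config, n=200_001, A=1.0):
    """Brute-force root scan written directly from the model definition."""
    w, h = config.weights, config.thresholds
    T = np.linspace(0.0, 1.0, n)

    def Hp(x, hh):
        return x**2 / (hh**2 + x**2)

    def Hw(x, hh, omega, sign):
        if omega == 0:
            return 1.0
        H = Hp(x, hh) if sign > 0 else hh**2 / (hh**2 + x**2)
        return (1 - omega) + omega * H

    prod = (1 - w.omega_TT) * Hw(A, h.h_AT, w.omega_AT, +1) * Hw(R, h.h_RT, w.omega_RT, -1)
    if w.omega_TT > 0:
        prod = prod + w.omega_TT * Hp(T, h.h_TT)
    g = prod - T
    idx = np.where(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
    return 0.5 * (T[idx] + T[idx + 1])


def test_without_self_activation_single_linear_root():
    cfg = make_preset("relay")  # omega_TT = 0: g is linear in T
    for R in (0.0, 0.1, 0.5, 1.0, 5.0):
        roots = t_steady_states(1.0, R, cfg)
        assert len(roots) == 1
        T_star, stable = roots[0]
        expected = 0.15**2 / (0.15**2 + R**2)  # H-(R, h_RT)
        assert T_star == pytest.approx(expected, abs=1e-9)
        assert stable


def test_strong_repression_drives_T_to_zero():
    cfg = make_preset("relay")
    (T_star, _), = t_steady_states(1.0, 100.0, cfg)
    assert T_star < 1e-3


def test_hysteretic_row_bistable_window_matches_oracle():
    cfg = make_preset("hysteresis")
    for R in (0.1, 0.3, 0.5, 1.0):
        found = sorted(T for T, _ in t_steady_states(1.0, R, cfg))
        oracle = sorted(_oracle_roots(R, cfg))
        assert len(found) == len(oracle)
        assert np.allclose(found, oracle, atol=1e-4)
    assert len(t_steady_states(1.0, 0.1, cfg)) == 1  # below the fold: high only
    assert len(t_steady_states(1.0, 0.5, cfg)) == 3  # bistable window


def test_stability_labels_verified_by_forward_integration():
    """Independent check: Euler-integrate dT/dt at frozen (A, R) from small
    perturbations; stable roots attract, unstable roots repel."""
    cfg = make_preset("hysteresis")
    roots = t_steady_states(1.0, 0.5, cfg)
    assert [s for _, s in roots] == [True, False, True]

    w, h = cfg.weights, cfg.thresholds

    def g(T):
        prod = (1 - w.omega_TT) * (h.h_RT**2 / (h.h_RT**2 + 0.25)) \
            + w.omega_TT * T**2 / (h.h_TT**2 + T**2)
        return prod - T

    for T_star, stable in roots:
        for sign in (-1, 1):
            T = np.clip(T_star + sign * 0.01, 0, 1)
            for _ in range(20000):
                T += 1e-3 * g(T)
            if stable:
                assert abs(T - T_star) < 1e-3
            else:
                assert abs(T - T_star) > 0.005


def test_fold_structure_of_canonical_rows():
    # weak self-activation: monotone diagram, no folds
    d_weak = sweep_R(make_preset("self_activation"))
    assert d_weak.fold_points == []
    assert (d_weak.points.groupby("R").size() == 1).all()

    # hysteretic row: an up-fold where the low branch disappears; the high
    # branch is self-sustaining for all R, so the switch is one-way
    d_hyst = sweep_R(make_preset("hysteresis"))
    ups = [f for f in d_hyst.fold_points if f.kind == "up"]
    assert len(ups) == 1
    assert d_hyst.r_up == pytest.approx(0.2399, abs=2e-3)
    # below the fold only the high branch remains; above it the diagram is bistable
    low_side = d_hyst.points[d_hyst.points["R"] < d_hyst.r_up - 0.01]
    assert (low_side.groupby("R").size() == 1).all()
    assert low_side["T_star"].min() > 0.5
    high_side = d_hyst.points[d_hyst.points["R"] > d_hyst.r_up + 0.01]
    assert (high_side.groupby("R").size() == 3).all()


def test_fold_location_against_dense_oracle_bisection():
    cfg = make_preset("hysteresis")
    lo, hi = 0.1, 0.5
    while hi - lo > 1e-5:
        mid = 0.5 * (lo + hi)
        if len(_oracle_roots(mid, cfg)) == 3:
            hi = mid
        else:
            lo = mid
    oracle_fold = 0.5 * (lo + hi)
    d = sweep_R(cfg)
    assert d.r_up == pytest.approx(oracle_fold, abs=1e-3)


def test_diagram_invariant_under_grid_refinement():
    cfg = make_preset("hysteresis")
    coarse = sweep_R(cfg, np.linspace(0, 1, 101), n_grid=5_000)
    fine = sweep_R(cfg, np.linspace(0, 1, 101), n_grid=20_000)
    assert len(coarse.fold_points) == len(fine.fold_points)
    assert abs(coarse.r_up - fine.r_up) < 1e-4


def test_quasi_static_decay_jumps_at_the_fold():
    """Dynamic confirmation of hysteresis: with slowly decaying R the full
    time-dependent system leaves the low branch at the up-fold."""
    from dataclasses import replace

    from glitimer import integrate_ode

    cfg = make_preset("hysteresis")
    slow = replace(cfg, rates=replace(cfg.rates, lambda_A=0.1, lambda_R=0.1),
                   t_end=20.0)
    traj = integrate_ode(slow, record_every=10)
    jump = np.argmax(traj.T > 0.5)
    R_at_jump = traj.R[jump]
    d = sweep_R(cfg)
    assert R_at_jump == pytest.approx(d.r_up, abs=0.02)
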