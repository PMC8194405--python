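"""Core dynamics: stimulus/Hill algebra, the ODE right-hand side, and the
integrator, each checked against independent oracles."""

import numpy as np
import pytest

from gutmuscle.model import (
    SPECIES,
    ModelError,
    SolverError,
    Trajectory,
    degradation_multiplier,
    derivatives,
    find_steady_state,
    hill_factor,
    integrate,
    stimulus_activation,
)
from gutmuscle.params import ParameterSet

from .conftest import (
    STABLE_VALUES,
    jittered_params,
    linear_closed_form,
    make_linear_params,
    rk4_integrate,
)

# ---------------------------------------------------------------- algebra


def test_stimulus_activation_analytic_values():
    assert stimulus_activation(0.0, 2.0, 1.0) == 0.0
    assert stimulus_activation(1.0, 2.0, 1.0) == pytest.approx(1.0)  # c1/2 at s=K
    assert stimulus_activation(1e6, 2.0, 1.0) == pytest.approx(2.0, abs=1e-5 * 2.0)


def test_stimulus_activation_monotone_and_bounded():
    s = np.linspace(0, 50, 200)
    vals = np.array([stimulus_activation(x, 3.0, 2.0) for x in s])
    assert np.all(np.diff(vals) > 0)
    assert vals[0] == 0.0 and np.all(vals < 3.0)


@pytest.mark.parametrize(
    "args", [(-1.0, 2.0, 1.0), (1.0, 0.0, 1.0), (1.0, 2.0, -3.0)])
def test_stimulus_activation_rejects_bad_arguments(args):
    with pytest.raises(ValueError):
        stimulus_activation(*args)


def test_degradation_multiplier_analytic_values():
    assert degradation_multiplier(0.0, 5.0) == 1.0
    assert degradation_multiplier(2.0, 2.0) == 2.0
    assert degradation_multiplier(8.0, 2.0) == 5.0
    with pytest.raises(ValueError):
        degradation_multiplier(1.0, 0.0)
    with pytest.raises(ValueError):
        degradation_multiplier(-1.0, 1.0)


def test_hill_factor_analytic_values_and_monotonicity():
    assert hill_factor(0.0, 2.0) == 1.0
    assert hill_factor(2.0, 2.0) == 0.5
    assert hill_factor(99.0, 1.0) == pytest.approx(0.01)
    u = np.linspace(0, 10, 100)
    vals = hill_factor(u, 1.5)
    assert np.all(np.diff(vals) < 0)
    assert np.all((vals > 0) & (vals <= 1))
    with pytest.raises(ValueError):
        hill_factor(-0.1, 1.0)
    with pytest.raises(ValueError):
        hill_factor(1.0, 0.0)


# ------------------------------------------------------- right-hand side


def _ledger_derivatives(state, p, s):
    """Second, independent transcription of the equation system, built as an
    explicit ledger of (equation, term) entries rather than inline algebra."""
    S, A, T, G, Mu, F, N, Y = state

    def hill(u, K):
        return K / (u + K)

    stim = p.c1 * s / (s + p.K) if s > 0 else 0.0
    ledger = {
        0: [p.a1, stim, -p.c2 * S * A, -p.l3 * hill(S, p.K3) * N,
            -p.l5 * hill(S, p.K5) * Y, -p.d1 * S],
        1: [p.a2, p.c2 * S * A, -p.c3 * A * T, -p.l2 * hill(A, p.K2) * F,
            p.l4 * hill(N, p.K4) * A, p.l6 * hill(Y, p.K6) * A,
            -p.d2 * (1.0 + s / p.M) * A],
        2: [p.a3, p.c3 * A, -p.c4 * A * Mu, -p.d3 * T],
        3: [p.a4, p.c5 * F * G, p.c6 * N * G,
            -p.l1 * hill(G, p.K1) * Mu, -p.d4 * G],
        4: [p.a5, p.c4 * A * Mu, -p.l1 * hill(G, p.K1) * Mu, -p.d5 * Mu],
        5: [p.a6, p.l2 * hill(A, p.K2) * F, p.c7 * Y * F,
            -p.c5 * G * F, -p.d6 * F],
        6: [p.a7, p.l3 * hill(S, p.K3) * N, -p.l4 * hill(N, p.K4) * A,
            -p.c6 * N * G, -p.d7 * N],
        7: [p.a8, p.l5 * hill(S, p.K5) * Y, -p.l6 * hill(Y, p.K6) * A,
            -p.c7 * Y * F, -p.d8 * Y],
    }
    return np.array([np.sum(ledger[i]) for i in range(8)])


def test_derivatives_at_origin_reduce_to_basal_rates(stable_params):
    p = stable_params
    basal = np.array([p.a1, p.a2, p.a3, p.a4, p.a5, p.a6, p.a7, p.a8])
    np.testing.assert_allclose(
        derivatives(np.zeros(8), p, 0.0), basal, rtol=1e-14)
    with_stim = basal.copy()
    with_stim[0] += stimulus_activation(2.0, p.c1, p.K)
    np.testing.assert_allclose(
        derivatives(np.zeros(8), p, 2.0), with_stim, rtol=1e-14)


def test_derivatives_match_independent_term_ledger(stable_params):
    rng = np.random.default_rng(42)
    for _ in range(25):
        state = rng.uniform(0.05, 3.0, size=8)
        s = float(rng.uniform(0, 4))
        np.testing.assert_allclose(
            derivatives(state, stable_params, s),
            _ledger_derivatives(state, stable_params, s),
            rtol=1e-12,
        )


def test_derivatives_rejects_invalid_state(stable_params):
    with pytest.raises(ModelError):
        derivatives([np.nan] + [0.0] * 7, stable_params, 0.0)
    with pytest.raises(ValueError):
        derivatives(np.zeros(7), stable_params, 0.0)
    with pytest.raises(ValueError):
        derivatives(np.zeros(8), stable_params, -1.0)


#: coefficient -> indices of the two species whose summed derivative is
#: invariant to it (the paired flux cancels)
_CANCELLING_PAIRS = {
    "c2": (0, 1), "c4": (2, 4), "c5": (3, 5), "c6": (3, 6), "c7": (5, 7),
    "l2": (1, 5), "l3": (0, 6), "l4": (1, 6), "l5": (0, 7), "l6": (1, 7),
}


def test_paired_interaction_terms_cancel_at_random_states(stable_params):
    """Every exchanged flux appears with opposite signs in its two species,
    so the pairwise-summed derivative is independent of the coefficient —
    except the two documented asymmetries (c3 and l1)."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        state = rng.uniform(0.01, 5.0, size=8)
        s = float(rng.uniform(0, 4))
        d_base = derivatives(state, stable_params, s)
        for coef, (i, j) in _CANCELLING_PAIRS.items():
            bumped = stable_params.replace(
                **{coef: 2.0 * getattr(stable_params, coef)})
            d_bump = derivatives(state, bumped, s)
            assert d_bump[i] + d_bump[j] == pytest.approx(
                d_base[i] + d_base[j], rel=1e-10, abs=1e-12), coef


def test_documented_asymmetries_c3_and_l1(stable_params):
    """c3 removes A*T from AKT but injects only A into mTOR; l1 drains both
    atrogins and muscle.  The summed derivatives therefore shift by exactly
    A(1-T) per unit c3 and -2*H1(G)*Mu per unit l1."""
    rng = np.random.default_rng(11)
    p = stable_params
    for _ in range(20):
        state = rng.uniform(0.05, 3.0, size=8)
        S, A, T, G, Mu, F, N, Y = state
        d_base = derivatives(state, p, 1.0)
        dc = 0.25
        d_c3 = derivatives(state, p.replace(c3=p.c3 + dc), 1.0)
        assert (d_c3[1] + d_c3[2]) - (d_base[1] + d_base[2]) == pytest.approx(
            dc * A * (1.0 - T), rel=1e-9, abs=1e-12)
        d_l1 = derivatives(state, p.replace(l1=p.l1 + dc), 1.0)
        h1 = p.K1 / (G + p.K1)
        assert (d_l1[3] + d_l1[4]) - (d_base[3] + d_base[4]) == pytest.approx(
            -2.0 * dc * h1 * Mu, rel=1e-9, abs=1e-12)


# ------------------------------------------------------------ integrator


def test_integrate_matches_linear_closed_form(linear_params):
    # tolerances tightened beyond the defaults so the discretization error
    # sits well below the closed form's 1e-6 comparison threshold
    traj = integrate(linear_params, 0.0, horizon=24.0, rtol=1e-9, atol=1e-12)
    exact = linear_closed_form(linear_params, traj.times)
    assert np.max(np.abs(traj.states - exact)) < 1e-6


def test_integrate_agrees_with_fixed_step_rk4_oracle():
    rng = np.random.default_rng(3)
    checked = 0
    while checked < 2:
        p = jittered_params(rng)
        s = float(rng.uniform(0.3, 1.2))
        try:
            traj = integrate(p, s, horizon=24.0, dense=False)
        except SolverError:
            continue  # inadmissible draw (runaway dynamics); try another
        oracle = rk4_integrate(p, s, 24.0, h=1e-3)
        rel = np.abs(traj.states[-1] - oracle) / (np.abs(oracle) + 1e-9)
        assert np.max(rel) < 1e-4
        checked += 1


def test_integrate_is_deterministic(stable_params):
    t1 = integrate(stable_params, 1.5, horizon=6.0)
    t2 = integrate(stable_params, 1.5, horizon=6.0)
    assert np.array_equal(t1.times, t2.times)
    assert np.array_equal(t1.states, t2.states)


def test_trajectory_contract(stable_params):
    traj = integrate(stable_params, 1.0, horizon=2.0, grid_step=0.01)
    assert traj.times[0] == 0.0
    np.testing.assert_array_equal(traj.states[0], np.zeros(8))
    assert np.all(np.diff(traj.times) > 0)
    assert traj.times[-1] == pytest.approx(2.0)
    assert len(traj.times) == 201
    assert np.all(np.isfinite(traj.states))


def test_integrate_signals_inadmissible_dynamics():
    """A configuration whose muscle compartment runs away (and drags mTOR
    into the Hill poles) must fail loudly, carrying the failure time."""
    vals = dict(STABLE_VALUES)
    vals.update(a2=0.15, c4=0.225, d3=1.5, a5=0.35, d5=0.35)
    p = ParameterSet.from_dict(vals)
    with pytest.raises(SolverError) as exc:
        integrate(p, 1.5, horizon=24.0)
    assert exc.value.time is not None
    assert 0 < exc.value.time <= 24.0


def test_integrate_validates_arguments(stable_params):
    with pytest.raises(ValueError):
        integrate(stable_params, 0.0, horizon=-1.0)
    with pytest.raises(ValueError):
        integrate(stable_params, 0.0, rtol=-1e-6)


# ---------------------------------------------------------- steady state


def test_steady_state_of_decoupled_system_is_a_over_d(linear_params):
    ss = find_steady_state(linear_params, 0.0, tol=1e-8)
    a = np.array([getattr(linear_params, f"a{i+1}") for i in range(8)])
    d = np.array([getattr(linear_params, f"d{i+1}") for i in range(8)])
    np.testing.assert_allclose(ss, a / d, atol=1e-6)


def test_steady_state_residual_contract(stable_params):
    tol = 1e-8
    ss = find_steady_state(stable_params, 0.0, tol=tol)
    resid = np.max(np.abs(derivatives(ss, stable_params, 0.0)))
    assert resid < tol


def test_steady_state_insensitive_to_horizon_cap(stable_params):
    tol = 1e-8
    ss1 = find_steady_state(stable_params, 0.0, tol=tol, horizon_cap=5000.0)
    ss2 = find_steady_state(stable_params, 0.0, tol=tol, horizon_cap=10000.0)
    assert np.max(np.abs(ss1 - ss2)) < 10 * tol
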