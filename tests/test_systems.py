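import numpy as np
import pytest

from ncie import (LVParams, boolean_truth_table, ideal_posterior_z_table,
                  simulate_boolean, simulate_case, simulate_lv,
                  xor_z_truth_table)
from ncie.systems import lv_derivatives


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table_fn", [boolean_truth_table, xor_z_truth_table,
                                      ideal_posterior_z_table])
def test_truth_tables_are_normalized_distributions(table_fn):
    table = table_fn()
    assert (table.probs >= 0).all()
    assert abs(table.probs.sum() - 1.0) < 1e-12
    assert len(np.unique(table.support, axis=0)) == len(table.support)


def test_and_truth_table_rows():
    table = boolean_truth_table()
    rows = {tuple(r): p for r, p in zip(table.support, table.probs)}
    assert rows[(0, 0, 0)] == 0.25
    assert (1, 1, 0) not in rows  # AND cannot produce y=0 from x=w=1
    assert rows[(1, 1, 1)] == 0.25


def test_xor_table_equals_pushforward_of_and_table():
    """Marginalization oracle: push the AND joint through Z = X XOR Y."""
    base = boolean_truth_table()
    z_col = base.support[:, 0] ^ base.support[:, 2]
    pushed = {}
    for (x, _, y), z, p in zip(base.support, z_col, base.probs):
        pushed[(x, y, z)] = pushed.get((x, y, z), 0.0) + p
    table = xor_z_truth_table()
    got = {tuple(r): p for r, p in zip(table.support, table.probs)}
    assert got == pushed
    assert got[(0, 0, 0)] == 0.5
    assert got[(1, 1, 0)] == 0.25


def test_ideal_posterior_z_matches_w_posterior():
    table = ideal_posterior_z_table()
    rows = {tuple(r): p for r, p in zip(table.support, table.probs)}
    assert rows[(0, 0, 1)] == 0.25
    # deterministic branches: z copies the hidden cause exactly when x = 1
    p_x1y1 = sum(p for (x, y, _), p in rows.items() if x == 1 and y == 1)
    p_x1y1z1 = rows.get((1, 1, 1), 0.0)
    assert p_x1y1z1 / p_x1y1 == 1.0
    assert (1, 0, 1) not in rows


# ---------------------------------------------------------------------------
# Boolean sampler
# ---------------------------------------------------------------------------

def test_boolean_sampler_shape_and_lag():
    panel = simulate_boolean(4, seed=0)
    assert panel.n_rows == 4
    assert panel.columns == ["X", "W", "Y"]


def test_boolean_sampler_rejects_nonpositive_n():
    with pytest.raises(ValueError):
        simulate_boolean(0)


def test_boolean_empirical_joint_converges_to_truth_table():
    panel = simulate_boolean(100_000, seed=3)
    x, w, y = panel.column("X"), panel.column("W"), panel.column("Y")
    # lagged triples (X_{t-1}, W_{t-1}, Y_t)
    triples = np.column_stack([x[:-1], w[:-1], y[1:]]).astype(int)
    np.testing.assert_array_equal(y[1:].astype(int),
                                  x[:-1].astype(int) & w[:-1].astype(int))
    uniq, counts = np.unique(triples, axis=0, return_counts=True)
    emp = {tuple(r): c / counts.sum() for r, c in zip(uniq, counts)}
    truth = {tuple(r): p for r, p in
             zip(boolean_truth_table().support, boolean_truth_table().probs)}
    tv = 0.5 * sum(abs(emp.get(k, 0.0) - truth.get(k, 0.0))
                   for k in set(emp) | set(truth))
    assert tv < 0.02
    assert abs(emp[(0, 0, 0)] - 0.25) < 0.01
    assert abs(np.mean(y) - 0.25) < 0.01


# ---------------------------------------------------------------------------
# driver cases
# ---------------------------------------------------------------------------

def test_case1_values_at_origin():
    panel = simulate_case(1, t_start=0.0, t_end=1.0, n=10)
    assert panel.column("X")[0] == 0.0
    assert panel.column("W")[0] == 0.0
    assert panel.column("Y")[0] == 0.0


@pytest.mark.parametrize("case_id", [1, 2, 3])
def test_case_residual_identities(case_id):
    panel = simulate_case(case_id)
    y, x, w = (panel.column(c) for c in ("Y", "X", "W"))
    if case_id == 1:
        residual = y - x - w
    elif case_id == 2:
        residual = y - x - w * (0.2 + x)
    else:
        residual = y - x - 0.2 * w * (0.2 + x)
    assert np.abs(residual).max() <= 1e-12 * max(1.0, np.abs(y).max())
    assert panel.observed == ("X", "Y")
    assert panel.hidden == ("W",)


def test_case_invalid_arguments():
    with pytest.raises(ValueError, match="case_id"):
        simulate_case(4)
    with pytest.raises(ValueError):
        simulate_case(1, t_start=1.0, t_end=0.0, n=10)
    with pytest.raises(ValueError):
        simulate_case(1, t_start=0.0, t_end=1.0, n=1)


# ---------------------------------------------------------------------------
# Lotka-Volterra ecosystem
# ---------------------------------------------------------------------------

def test_lv_floor_holds_everywhere():
    panel = simulate_lv(LVParams(n_steps=5000))
    assert panel.values().min() >= 1.0
    assert panel.observed == ("W", "G")
    assert panel.hidden == ("S", "R")


def test_lv_zero_rates_keeps_populations_constant():
    params = LVParams(a0=0, a1=0, a2=0, b0=0, b1=0, b2=0, c0=0, c1=0, c2=0,
                      d0=0, d1=0, d2=0, n_steps=50)
    panel = simulate_lv(params)
    for name, init in zip("WSRG", (10.0, 20.0, 20.0, 40.0)):
        np.testing.assert_allclose(panel.column(name), init)


def test_lv_pure_decay_matches_euler_closed_form():
    """With no prey interaction the wolves follow W_{k+1} = W_k (1 - a0 dt)."""
    params = LVParams(a0=0.5, a1=0, a2=0, b0=0, b1=0, b2=0, c0=0, c1=0,
                      c2=0, d0=0, d1=0, d2=0, dt=0.01, n_steps=200,
                      floor=None)
    panel = simulate_lv(params)
    k = np.arange(201)
    expected = 10.0 * (1 - 0.5 * 0.01) ** k
    np.testing.assert_allclose(panel.column("W"), expected, rtol=1e-12)


def test_lv_sign_structure_without_floor():
    """dW/dt < 0 exactly when prey support a1 S + a2 R falls below a0."""
    params = LVParams(floor=None, n_steps=2000, dt=0.005)
    panel = simulate_lv(params)
    w, s, r, g = (panel.column(c) for c in "WSRG")
    dw = np.array([lv_derivatives(params, *state)[0]
                   for state in zip(w, s, r, g)])
    support = params.a1 * s + params.a2 * r
    assert np.all((dw < 0) == (support < params.a0))


def test_lv_divergence_reports_step_index():
    params = LVParams(d0=50.0, dt=10.0, n_steps=500, floor=None,
                      init_w=1.0, init_s=1.0, init_r=1.0, init_g=100.0)
    with pytest.raises(FloatingPointError, match="step"):
        simulate_lv(params)


def test_lv_parameter_validation():
    with pytest.raises(ValueError):
        LVParams(dt=0.0)
    with pytest.raises(ValueError):
        LVParams(a0=-1.0)
    with pytest.raises(ValueError):
        LVParams(init_w=0.5)  # below the floor
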