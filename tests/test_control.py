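"""Control stack: torque models, activation, valves, plants, closed loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from errp_exo import control as C
from errp_exo.protocol import ExperimentEvent


# --------------------------------------------------------------------------
# gravity compensation (required torque)
# --------------------------------------------------------------------------

def test_gravity_torque_values_and_linearity():
    arm = C.ArmParams(m=2.0, l_c=0.2)
    assert C.gravity_required_torque(arm, C.ArmState(theta_e=math.pi)) == pytest.approx(0.0)
    assert C.gravity_required_torque(arm, C.ArmState(theta_e=math.pi / 2)) \
        == pytest.approx(3.924)
    heavy = C.ArmParams(m=4.0, l_c=0.2)
    st_ = C.ArmState(theta_e=1.1)
    assert C.gravity_required_torque(heavy, st_) \
        == pytest.approx(2 * C.gravity_required_torque(arm, st_))


def test_gravity_torque_ignores_shoulder_angle():
    arm = C.ArmParams()
    a = C.ArmState(theta_e=1.0, theta_s=0.0)
    b = C.ArmState(theta_e=1.0, theta_s=0.7)
    assert C.gravity_required_torque(arm, a) == C.gravity_required_torque(arm, b)


# --------------------------------------------------------------------------
# actuator pressure-torque model
# --------------------------------------------------------------------------

def test_effective_radius_limit_and_zero():
    # theta -> 2*pi: a -> w/2 (series limit of the geometry formula)
    g = C.ActuatorGeometry(r=0.01, w=0.005, n=4, theta_act=2 * math.pi - 1e-9)
    assert C.actuator_effective_radius(g) == pytest.approx(0.005 / 2, rel=1e-5)
    g0 = C.ActuatorGeometry(r=0.01, w=0.005, n=1, theta_act=0.0)
    # n=1, theta=0: (r + w/(2 pi)) * sin(pi) = 0
    assert C.actuator_effective_radius(g0) == pytest.approx(0.0, abs=1e-15)
    with pytest.raises(ValueError):
        C.ActuatorGeometry(theta_act=2 * math.pi)


def test_exosuit_torque_zero_pressure_and_linearity():
    g = C.ActuatorGeometry()
    assert C.exosuit_torque(g, C.PneumaticState(P=0.0)) == 0.0
    grid = np.linspace(1e3, 3e5, 37)
    tau = np.array([C.exosuit_torque(g, C.PneumaticState(P=p)) for p in grid])
    slope = tau / grid
    assert np.max(np.abs(slope - slope[0])) / abs(slope[0]) < 1e-12


def test_exosuit_torque_symbolic_oracle():
    """Independent symbolic evaluation of the pressure-torque relationship."""
    import sympy as sp

    l, P, r, n, w, th = sp.symbols("l P r n w theta", positive=True)
    a = (r + n * w / (2 * sp.pi - th)) * sp.sin((2 * sp.pi - th) / (2 * n))
    tau = sp.pi * l * P / 2 * (r**2 - a**2)
    subs = {l: 0.30, P: 1e5, r: 0.01, n: 10, w: 0.01, th: 0.5}
    expected = float(tau.subs(subs).evalf())
    geom = C.ActuatorGeometry(l=0.30, r=0.01, n=10, w=0.01, theta_act=0.5)
    got = C.exosuit_torque(geom, C.PneumaticState(P=1e5))
    assert got == pytest.approx(expected, rel=1e-12)


def test_interaction_torque_antisymmetry():
    assert C.interaction_torque(3.0, 1.0) == 2.0
    assert C.interaction_torque(2.0, 2.0) == 0.0
    assert C.interaction_torque(1.0, 3.0) == -C.interaction_torque(3.0, 1.0)


# --------------------------------------------------------------------------
# myoprocessor chain
# --------------------------------------------------------------------------

def test_muscle_activation_endpoints_and_known_value():
    assert C.muscle_activation(0.0, A=-1) == pytest.approx(0.0)
    assert C.muscle_activation(1.0, A=-1) == pytest.approx(1.0)
    assert C.muscle_activation(0.5, A=-1) == pytest.approx(0.6225, abs=5e-5)
    with pytest.raises(ValueError):
        C.muscle_activation(0.5, A=0.0)


def test_muscle_activation_linear_limit():
    u = np.linspace(0, 1, 11)
    a = C.muscle_activation(u, A=1e-8)
    assert np.allclose(a, u, atol=1e-6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(A=st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
       u=st.floats(0, 1))
def test_muscle_activation_bijection(A, u):
    """Monotone [0,1]->[0,1] map for every nonzero shape factor."""
    a = C.muscle_activation(u, A=A)
    assert -1e-12 <= a <= 1 + 1e-12
    a2 = C.muscle_activation(min(u + 1e-3, 1.0), A=A)
    assert a2 >= a - 1e-12


def test_muscle_force_contract():
    p = C.MuscleModelParams()
    assert C.muscle_force(0.0, p) == 0.0
    assert C.muscle_force(1.0, p) == pytest.approx(p.gain * p.F_max)
    grid = np.linspace(0, 1, 21)
    forces = [C.muscle_force(a, p) for a in grid]
    assert all(b >= a for a, b in zip(forces, forces[1:]))
    p3 = C.MuscleModelParams(mode="three-element")
    assert C.muscle_force(0.0, p3) == 0.0
    assert C.muscle_force(0.5, p3, stretch=0.1) > C.muscle_force(0.5, p3)


def test_moment_arm_table_values():
    assert C.moment_arm("MEF", 0.0) == pytest.approx(-0.014)
    assert C.moment_arm("MEE", 0.0) == pytest.approx(0.025)
    assert C.moment_arm("MEF", 1.0) == pytest.approx(-0.02192)
    with pytest.raises(ValueError):
        C.moment_arm("soleus", 0.0)


def test_myoprocessor_torque_composition():
    """Matches the explicit composition activation -> force -> arm."""
    p = C.MuscleModelParams()
    assert C.myoprocessor_required_torque(0.0, 0.0, 1.0, p) == pytest.approx(0.0)
    u_bi, u_tri, th = 0.4, 0.25, 1.2
    expected = (C.moment_arm("MEF", th) * C.muscle_force(C.muscle_activation(u_bi, p.A), p)
                + C.moment_arm("MEE", th) * C.muscle_force(C.muscle_activation(u_tri, p.A), p))
    assert C.myoprocessor_required_torque(u_bi, u_tri, th, p) == pytest.approx(expected)
    # u_tri = 0 reduces to the flexor term alone
    flexor_only = C.moment_arm("MEF", th) * C.muscle_force(C.muscle_activation(u_bi, p.A), p)
    assert C.myoprocessor_required_torque(u_bi, 0.0, th, p) == pytest.approx(flexor_only)


# --------------------------------------------------------------------------
# low-level control
# --------------------------------------------------------------------------

def test_opening_percentage_affine():
    assert C.opening_percentage(90, 0, 90) == 0.0
    assert C.opening_percentage(0, 0, 90) == 100.0
    assert C.opening_percentage(45, 0, 90) == 50.0
    with pytest.raises(ValueError):
        C.opening_percentage(91, 0, 90)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(tau_i=st.floats(-5, 5, allow_nan=False))
def test_valve_controller_case_partition(tau_i):
    """The command regions partition the interaction-torque axis exactly."""
    cfg = C.ControllerConfig()
    cmd = C.valve_controller(tau_i, cfg, C.ValvePidState())
    if abs(tau_i) >= cfg.tau_state:
        assert (cmd.phi_in, cmd.phi_out) == ((100.0, 0.0) if tau_i > 0 else (0.0, 100.0))
    elif tau_i > cfg.tau_c:
        assert 50.0 <= cmd.phi_in <= 80.0 and cmd.phi_out == 0.0
    elif tau_i < -cfg.tau_c:
        assert cmd.phi_in == 0.0 and 60.0 <= cmd.phi_out <= 90.0
    else:
        assert (cmd.phi_in, cmd.phi_out) == (0.0, 0.0)


def test_valve_controller_pid_outlet_clamped():
    cfg = C.ControllerConfig()
    cmd = C.valve_controller(-(cfg.tau_c + 1e-4), cfg, C.ValvePidState())
    assert cmd.phi_in == 0.0 and 60.0 <= cmd.phi_out <= 90.0


# --------------------------------------------------------------------------
# plants
# --------------------------------------------------------------------------

def test_pneumatic_step_dynamics():
    pn = C.PneumaticState(P=1e5)
    assert C.pneumatic_step(pn, C.ValveCommand(0, 0), 0.01).P == 1e5
    # fill at full inlet follows the exact first-order solution
    k = 8.0
    P, dt = 0.0, 0.01
    pn = C.PneumaticState(P=P)
    for i in range(1, 101):
        pn = C.pneumatic_step(pn, C.ValveCommand(100, 0), dt, k_in=k)
        expected = pn.supply_P * (1 - math.exp(-k * i * dt))
        assert pn.P == pytest.approx(expected, rel=1e-9)
    # vent to zero
    for _ in range(2000):
        pn = C.pneumatic_step(pn, C.ValveCommand(0, 100), dt, k_out=k)
    assert pn.P < 1.0


def test_arm_step_equilibrium_and_clamp():
    arm = C.ArmParams()
    st_ = C.ArmState(theta_e=1.0, omega=0.0)
    tau_g = C.gravity_required_torque(arm, st_)
    nxt = C.arm_step(arm, st_, tau_exo=tau_g, tau_human=0.0, dt=0.01)
    assert nxt.omega == pytest.approx(0.0, abs=1e-12)
    # large torque drives to full extension, where motion stops
    s = C.ArmState(theta_e=3.0, omega=0.0)
    for _ in range(500):
        s = C.arm_step(arm, s, tau_exo=20.0, tau_human=0.0, dt=0.01)
    assert s.theta_e == math.pi and s.omega == 0.0


def test_arm_step_energy_bounded_without_damping():
    """Undamped oscillation about an interior equilibrium conserves energy.

    A constant applied torque biases the swing away from the joint limits
    (which are inelastic stops); total energy including the work of the
    constant torque must stay bounded under the symplectic update.
    """
    arm = C.ArmParams(damping=0.0)
    theta_eq = 0.8
    tau0 = arm.m * arm.g * arm.l_c * math.sin(theta_eq)
    s = C.ArmState(theta_e=0.7, omega=0.0)

    def energy(state):
        return (0.5 * arm.inertia * state.omega**2
                - arm.m * arm.g * arm.l_c * math.cos(state.theta_e)
                - tau0 * state.theta_e)

    e0 = energy(s)
    thetas = []
    for _ in range(5000):
        s = C.arm_step(arm, s, 0.0, tau0, dt=0.001)
        thetas.append(s.theta_e)
    assert 0.0 < min(thetas) and max(thetas) < math.pi  # never hit the stops
    scale = arm.m * arm.g * arm.l_c
    assert abs(energy(s) - e0) < 0.02 * scale


# --------------------------------------------------------------------------
# closed loop
# --------------------------------------------------------------------------

def test_closed_loop_settles_within_half_second():
    """Step in required torque: |tau_i| drops below tau_c within 0.5 s."""
    tr = C.simulate_closed_loop(None, "gravity", theta_start=math.pi / 3,
                                theta_end=math.pi / 3)
    cfg = C.ControllerConfig()
    idx = np.nonzero(np.abs(tr.tau_i) < cfg.tau_c)[0]
    assert len(idx) and tr.time[idx[0]] < 0.5
    # ... and stays inside the state threshold after the initial transient
    after = tr.time > 0.5
    assert np.all(np.abs(tr.tau_i[after]) <= cfg.tau_state)


def test_closed_loop_bounds_and_steady_state():
    cfg = C.SimulationConfig()
    tr = C.simulate_closed_loop(None, "gravity", cfg, duration=2.0,
                                theta_start=1.1, theta_end=1.1)
    assert np.all((tr.pressure >= 0) & (tr.pressure <= cfg.supply_pressure))
    assert np.all((tr.theta_e >= 0) & (tr.theta_e <= math.pi))
    # static hold: steady-state assistance matches gravity within tau_c
    grav = cfg.arm.m * cfg.arm.g * cfg.arm.l_c * np.sin(math.pi - tr.theta_e[-1])
    assert abs(tr.tau_exo[-1] - grav) <= cfg.controller.tau_c + 0.05


def test_closed_loop_release_error_velocity_transient():
    ev = ExperimentEvent(5, 0, 0, 0.0, "gravity", True, "release", False)
    err = C.simulate_closed_loop(ev, "gravity", initial_pressure=1.6e5,
                                 theta_start=math.pi / 3, theta_end=math.pi / 3)
    ok = C.simulate_closed_loop(None, "gravity", initial_pressure=1.6e5,
                                theta_start=math.pi / 3, theta_end=math.pi / 3)
    assert np.max(np.abs(err.omega)) > 3 * np.max(np.abs(ok.omega)) + 0.05


def test_closed_loop_rejects_unknown_scheme():
    with pytest.raises(ValueError):
        C.simulate_closed_loop(None, "unassisted")


def test_myoprocessor_closed_loop_runs_and_assists():
    tr = C.simulate_closed_loop(None, "myoprocessor", duration=2.0,
                                theta_start=1.0, theta_end=1.0)
    assert tr.pressure[-1] > 0  # assistance built up from EMG-decoded effort
    assert np.all(np.isfinite(tr.as_array()))
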