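"""Exosuit control stack: intention decoders, valve control, and plant models.

High-level control decodes a required elbow torque tau_r either from arm
kinematics (gravity compensation, a single-joint m*g*l_c*sin(pi - theta_e)
profile) or from EMG activation through a myoprocessor (activation
nonlinearity -> muscle force -> angle-dependent moment arms -> joint
torque).  The exosuit supplies an assistance torque tau_exo that is linear
in actuator tube pressure; the low-level controller minimises the
interaction torque tau_i = tau_r - tau_exo by modulating inlet/outlet valve
opening percentages with a dual-PID controller inside a state-machine
envelope.  Simple first-order pneumatic and single-joint rigid-body plant
models close the loop at 100 Hz for desk-scale simulation.

Units are SI throughout (rad, N*m, Pa); configs accept bar via BAR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from errp_exo.protocol import ExperimentEvent

BAR = 1e5  # Pa per bar

#: safety relief valve operating band (bar): the regulator limits system
#: pressure to this range; the supply is set to the upper bound
RELIEF_RANGE_BAR: tuple[float, float] = (1.5, 3.0)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmParams:
    """Single-joint forearm model (forearm + hand + distal exosuit mass)."""

    m: float = 2.0            # kg
    l_c: float = 0.15         # m, elbow to combined centre of mass
    g: float = 9.81           # m/s^2
    inertia: float = 0.06     # kg*m^2 about the elbow
    damping: float = 0.8      # N*m*s/rad, lumped joint/tissue damping

    def __post_init__(self) -> None:
        if min(self.m, self.l_c, self.g, self.inertia) <= 0 or self.damping < 0:
            raise ValueError("invalid arm parameters")


@dataclass
class ArmState:
    theta_e: float = math.pi / 2  # elbow angle, rad; pi = fully extended
    omega: float = 0.0            # rad/s
    theta_s: float = 0.0          # shoulder angle, fixed 0 in all control math

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_e <= math.pi:
            raise ValueError("theta_e must lie in [0, pi]")


@dataclass(frozen=True)
class ActuatorGeometry:
    """Segmented snaking-tube actuator geometry."""

    l: float = 0.30        # m, actuator segment length
    r: float = 0.01        # m, tube radius
    n: int = 10            # number of segments
    w: float = 0.01        # m, distance between successive housing chambers
    theta_act: float = 0.0 # rad, actuator angle

    def __post_init__(self) -> None:
        if min(self.l, self.r, self.w) <= 0 or self.n < 1:
            raise ValueError("invalid actuator geometry")
        if not 0.0 <= self.theta_act < 2 * math.pi:
            raise ValueError("theta_act must lie in [0, 2*pi)")


@dataclass
class PneumaticState:
    P: float = 0.0                 # Pa, gauge pressure
    supply_P: float = 3.0 * BAR    # Pa; relief valve limits operation to 1.5-3 bar

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= self.supply_P:
            raise ValueError("pressure must lie in [0, supply_P]")


#: angle-dependent moment-arm polynomial coefficients (a1e, a2e) in metres,
#: monoarticular elbow flexor (MEF) and extensor (MEE)
MOMENT_ARM_COEFFS: dict[str, tuple[float, float]] = {
    "MEF": (-0.014, -3.96e-3),
    "MEE": (0.025, -2.16e-3),
}


@dataclass(frozen=True)
class MuscleModelParams:
    A: float = -1.0          # activation shape factor (non-linear for A != 0)
    gain: float = 0.8        # user-preference scale on the force prediction
    F_max: float = 500.0     # N, maximal isometric force
    moment_arm_coeffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(MOMENT_ARM_COEFFS)
    )
    mode: str = "quasistatic"   # or "three-element"
    k_pe: float = 200.0         # N per unit squared stretch (parallel elastic)
    k_v: float = 0.25           # force-velocity slope, per (lengths/s)

    def __post_init__(self) -> None:
        if self.A == 0:
            raise ValueError("A must be nonzero; use the explicit linear limit instead")
        if self.gain <= 0 or self.F_max <= 0:
            raise ValueError("gain and F_max must be positive")
        if self.mode not in ("quasistatic", "three-element"):
            raise ValueError(f"unknown muscle model mode {self.mode!r}")


@dataclass(frozen=True)
class ControllerConfig:
    tau_c: float = 0.1        # N*m, PID deadband threshold
    tau_state: float = 1.0    # N*m, state-machine threshold
    pid_gains_in: tuple[float, float, float] = (100.0, 60.0, 0.0)
    pid_gains_out: tuple[float, float, float] = (100.0, 60.0, 0.0)
    phi_in_range: tuple[float, float] = (50.0, 80.0)
    phi_out_range: tuple[float, float] = (60.0, 90.0)
    dt: float = 0.01          # s, control period (100 Hz loop)

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_c < self.tau_state:
            raise ValueError("require 0 < tau_c < tau_state")
        for lo, hi in (self.phi_in_range, self.phi_out_range):
            if not (0.0 <= lo < hi <= 100.0):
                raise ValueError("valve ranges must lie within [0, 100]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class ValveCommand:
    phi_in: float
    phi_out: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_in <= 100.0 and 0.0 <= self.phi_out <= 100.0):
            raise ValueError("opening percentages must lie in [0, 100]")


@dataclass
class ValvePidState:
    """Integral/derivative memory for the two valve PIDs."""

    integral_in: float = 0.0
    prev_in: float | None = None
    integral_out: float = 0.0
    prev_out: float | None = None


# --------------------------------------------------------------------------
# high-level decoders
# --------------------------------------------------------------------------

def gravity_required_torque(arm: ArmParams, state: ArmState) -> float:
    """Gravitational position-dependent required torque, m*g*l_c*sin(pi - theta_e).

    Independent of the shoulder angle: flexion assistance can only be given
    at the elbow, so the scheme assumes theta_s = 0.
    """
    return arm.m * arm.g * arm.l_c * math.sin(math.pi - state.theta_e)


def actuator_effective_radius(geom: ActuatorGeometry) -> float:
    """Effective bending radius a = (r + n*w/(2*pi - theta)) * sin((2*pi - theta)/(2n))."""
    gap = 2 * math.pi - geom.theta_act
    if gap <= 0:
        raise ZeroDivisionError("theta_act = 2*pi makes the effective radius singular")
    return (geom.r + geom.n * geom.w / gap) * math.sin(gap / (2 * geom.n))


def exosuit_torque(geom: ActuatorGeometry, pneu: PneumaticState) -> float:
    """Assistance torque tau_exo = (pi*l*P/2) * (r^2 - a^2), linear in pressure."""
    a = actuator_effective_radius(geom)
    return 0.5 * math.pi * geom.l * pneu.P * (geom.r**2 - a**2)


def interaction_torque(tau_r: float, tau_exo: float) -> float:
    """tau_i = tau_r - tau_exo; the low-level control error signal."""
    return tau_r - tau_exo


def muscle_activation(u: float | np.ndarray, A: float = -1.0):
    """Nonlinear EMG-to-activation map a = (exp(A*u) - 1) / (exp(A) - 1).

    ``u`` is the normalised RMS envelope in [0, 1].  A -> 0 recovers the
    linear map pointwise; A = 0 itself is rejected.
    """
    if A == 0:
        raise ValueError("A must be nonzero; the A->0 limit is the identity map")
    u = np.asarray(u, dtype=float) if not np.isscalar(u) else u
    if np.any(np.asarray(u) < 0) or np.any(np.asarray(u) > 1):
        raise ValueError("u must be a normalised envelope in [0, 1]")
    out = (np.expm1(A * np.asarray(u))) / np.expm1(A)
    return float(out) if np.isscalar(u) else out


def muscle_force(
    a: float,
    params: MuscleModelParams,
    stretch: float = 0.0,
    velocity: float = 0.0,
) -> float:
    """Muscle force from activation.

    Default quasi-static reduction F = gain * F_max * a of a three-element
    Hill arrangement (contractile + serial and parallel elastic); only the
    activation pathway drives the controller, so the reduction preserves the
    monotone activation->torque mapping.  ``mode='three-element'`` adds a
    linearised force-velocity factor on the contractile element and a
    quadratic parallel-elastic term driven by ``stretch`` (normalised muscle
    lengthening); both vanish at the quasi-static operating point.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    if params.mode == "quasistatic":
        return params.gain * params.F_max * a
    fv = max(0.0, 1.0 - params.k_v * velocity)
    f_pe = params.k_pe * max(stretch, 0.0) ** 2
    return params.gain * (params.F_max * a * fv + f_pe)


def moment_arm(muscle: str, theta_e: float, params: MuscleModelParams | None = None) -> float:
    """Angle-dependent moment arm, arm_e(theta_e) = a1e + 2*a2e*theta_e (metres)."""
    coeffs = (params.moment_arm_coeffs if params is not None else MOMENT_ARM_COEFFS)
    if muscle not in coeffs:
        raise ValueError(f"unknown muscle {muscle!r}; expected one of {sorted(coeffs)}")
    a1e, a2e = coeffs[muscle]
    return a1e + 2.0 * a2e * theta_e


def myoprocessor_required_torque(
    u_bi: float,
    u_tri: float,
    theta_e: float,
    params: MuscleModelParams | None = None,
) -> float:
    """Myoprocessor torque tau_r = l_bi(theta_e)*F(a_bi) + l_tri(theta_e)*F(a_tri).

    l_bi uses the MEF coefficients, l_tri the MEE coefficients.  Note the
    cadaveric coefficient sign convention: the flexor arm is negative over
    [0, pi], so this literal composition is extension-positive; closed-loop
    control flips the sign to the flexion-positive convention of the gravity
    scheme (see ``SimulationConfig.flexion_sign``).
    """
    params = params or MuscleModelParams()
    tau = 0.0
    for muscle, u in (("MEF", u_bi), ("MEE", u_tri)):
        a = muscle_activation(u, params.A)
        tau += moment_arm(muscle, theta_e, params) * muscle_force(a, params)
    return tau


# --------------------------------------------------------------------------
# low-level control
# --------------------------------------------------------------------------

def opening_percentage(servo_angle: float, servo_min: float, servo_max: float) -> float:
    """Servo angle -> valve opening percentage, ((max - angle)/(max - min)) * 100."""
    if servo_min >= servo_max:
        raise ValueError("servo_min must be below servo_max")
    if not servo_min <= servo_angle <= servo_max:
        raise ValueError("servo angle outside its calibrated range")
    return (servo_max - servo_angle) / (servo_max - servo_min) * 100.0


def _pid_step(
    err: float,
    gains: tuple[float, float, float],
    integral: float,
    prev: float | None,
    out_range: tuple[float, float],
    dt: float,
) -> tuple[float, float]:
    """One clamped PID update with integral freeze on saturation (anti-windup)."""
    kp, ki, kd = gains
    deriv = 0.0 if prev is None else (err - prev) / dt
    tentative = integral + err * dt
    u = kp * err + ki * tentative + kd * deriv
    lo, hi = out_range
    if lo <= u <= hi:
        return u, tentative
    return min(max(u, lo), hi), integral


def valve_controller(
    tau_i: float,
    config: ControllerConfig,
    pid_state: ValvePidState,
) -> ValveCommand:
    """Dual-PID valve controller inside a state-machine envelope.

    Case partition over the interaction torque:
      |tau_i| <= tau_c                     -> both valves closed (deadband)
      tau_c < tau_i < tau_state            -> inlet PID, clamped to phi_in_range
      -tau_state < tau_i < -tau_c         -> outlet PID, clamped to phi_out_range
      |tau_i| >= tau_state                 -> state machine: fully open inlet
                                              (tau_i > 0, under-assistance) or
                                              outlet (tau_i < 0, over-assistance)
    """
    c = config
    if abs(tau_i) >= c.tau_state:
        return ValveCommand(100.0, 0.0) if tau_i > 0 else ValveCommand(0.0, 100.0)
    if tau_i > c.tau_c:
        phi, pid_state.integral_in = _pid_step(
            tau_i, c.pid_gains_in, pid_state.integral_in, pid_state.prev_in,
            c.phi_in_range, c.dt,
        )
        pid_state.prev_in = tau_i
        return ValveCommand(phi, 0.0)
    if tau_i < -c.tau_c:
        phi, pid_state.integral_out = _pid_step(
            -tau_i, c.pid_gains_out, pid_state.integral_out, pid_state.prev_out,
            c.phi_out_range, c.dt,
        )
        pid_state.prev_out = -tau_i
        return ValveCommand(0.0, phi)
    return ValveCommand(0.0, 0.0)


# --------------------------------------------------------------------------
# plant models
# --------------------------------------------------------------------------

def pneumatic_step(
    pneu: PneumaticState,
    cmd: ValveCommand,
    dt: float,
    k_in: float = 8.0,
    k_out: float = 8.0,
) -> PneumaticState:
    """First-order fill/vent dynamics.

    dP/dt = k_in*(phi_in/100)*(supply_P - P) - k_out*(phi_out/100)*P,
    integrated exactly over one tick (the rate is affine in P for fixed valve
    commands) and clamped to [0, supply_P].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = k_in * cmd.phi_in / 100.0
    b = k_out * cmd.phi_out / 100.0
    lam = a + b
    if lam == 0:
        return PneumaticState(P=pneu.P, supply_P=pneu.supply_P)
    p_inf = a * pneu.supply_P / lam
    P = p_inf + (pneu.P - p_inf) * math.exp(-lam * dt)
    return PneumaticState(P=min(max(P, 0.0), pneu.supply_P), supply_P=pneu.supply_P)


def arm_step(
    arm: ArmParams,
    state: ArmState,
    tau_exo: float,
    tau_human: float,
    dt: float,
) -> ArmState:
    """Semi-implicit Euler update of the single-joint rigid-body model.

    inertia * domega/dt = tau_human + tau_exo - m*g*l_c*sin(pi - theta_e)
                          - damping * omega,
    with theta_e clamped to [0, pi] and omega zeroed at the limits.  The
    symplectic update keeps the undamped oscillation energy bounded.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau_grav = arm.m * arm.g * arm.l_c * math.sin(math.pi - state.theta_e)
    alpha = (tau_human + tau_exo - tau_grav - arm.damping * state.omega) / arm.inertia
    omega = state.omega + dt * alpha
    theta = state.theta_e + dt * omega
    if theta <= 0.0:
        theta, omega = 0.0, 0.0
    elif theta >= math.pi:
        theta, omega = math.pi, 0.0
    return ArmState(theta_e=theta, omega=omega, theta_s=state.theta_s)


# --------------------------------------------------------------------------
# closed-loop simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    arm: ArmParams = field(default_factory=ArmParams)
    geom: ActuatorGeometry = field(default_factory=ActuatorGeometry)
    muscle: MuscleModelParams = field(default_factory=MuscleModelParams)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    supply_pressure: float = 3.0 * BAR
    k_in: float = 8.0                  # 1/s, fill rate at fully open inlet
    k_out: float = 8.0                 # 1/s, vent rate at fully open outlet
    error_override_duration: float = 0.4   # s, forced valve override per error
    human_kp: float = 25.0             # N*m/rad, voluntary tracking stiffness
    human_kd: float = 2.5              # N*m*s/rad
    flexion_sign: float = -1.0         # maps Eq.-7 torque to flexion-positive
    emg_effort_gain: float = 0.2       # envelope units per N*m of human effort
    emg_baseline: float = 0.05         # resting normalised envelope


@dataclass
class SimTrace:
    """Per-tick closed-loop record (100 Hz)."""

    time: np.ndarray
    theta_e: np.ndarray
    omega: np.ndarray
    pressure: np.ndarray
    tau_r: np.ndarray
    tau_exo: np.ndarray
    tau_i: np.ndarray
    phi_in: np.ndarray
    phi_out: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.column_stack([
            self.time, self.theta_e, self.omega, self.pressure,
            self.tau_r, self.tau_exo, self.tau_i, self.phi_in, self.phi_out,
        ])

    COLUMNS = ("time", "theta_e", "omega", "pressure",
               "tau_r", "tau_exo", "tau_i", "phi_in", "phi_out")


def _minimum_jerk(t: float, t0: float, t1: float, x0: float, x1: float) -> tuple[float, float]:
    """Minimum-jerk position/velocity between (t0, x0) and (t1, x1)."""
    if t <= t0:
        return x0, 0.0
    if t >= t1:
        return x1, 0.0
    s = (t - t0) / (t1 - t0)
    pos = x0 + (x1 - x0) * (10 * s**3 - 15 * s**4 + 6 * s**5)
    vel = (x1 - x0) * (30 * s**2 - 60 * s**3 + 30 * s**4) / (t1 - t0)
    return pos, vel


def simulate_closed_loop(
    event: ExperimentEvent | None,
    scheme: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    duration: float = 1.5,
    theta_start: float = math.pi / 3,
    theta_end: float | None = None,
    move_window: tuple[float, float] = (0.4, 1.0),
    initial_pressure: float | None = None,
) -> SimTrace:
    """Run one movement event through the full control loop at 100 Hz.

    Per tick: high-level decoder -> tau_i -> valve controller ->
    pneumatic_step -> arm_step.  The simulated wearer tracks a minimum-jerk
    elbow reference from ``theta_start`` to ``theta_end`` (default: a small
    random flexion/extension step) with a PD effort torque.  On an injected
    error event the valve command is overridden for
    ``config.error_override_duration`` seconds from event onset — inlet
    forced open for 'inflate', outlet forced open for 'release' — which
    reproduces the error-locked elbow velocity transient; the pneumatic time
    constant gives the device its characteristic movement lag.
    """
    if scheme not in ("gravity", "myoprocessor"):
        raise ValueError(f"unknown scheme {scheme!r}; closed loop needs an assisted scheme")
    cfg = config or SimulationConfig()
    rng = rng or np.random.default_rng(0)
    dt = cfg.controller.dt
    n = int(round(duration / dt))
    if theta_end is None:
        theta_end = float(np.clip(theta_start + rng.choice([-1, 1]) * rng.uniform(0.15, 0.30),
                                  0.05, math.pi - 0.05))

    state = ArmState(theta_e=theta_start, omega=0.0)
    pneu = PneumaticState(P=0.0 if initial_pressure is None else initial_pressure,
                          supply_P=cfg.supply_pressure)
    pid = ValvePidState()
    cols = {k: np.empty(n) for k in SimTrace.COLUMNS}

    is_error = event is not None and event.is_error
    error_type = event.error_type if event is not None else "none"

    for i in range(n):
        t = i * dt
        theta_ref, omega_ref = _minimum_jerk(t, *move_window, theta_start, theta_end)
        tau_grav = gravity_required_torque(cfg.arm, state)
        tau_human = (cfg.human_kp * (theta_ref - state.theta_e)
                     + cfg.human_kd * (omega_ref - state.omega))

        if scheme == "gravity":
            tau_r = tau_grav
        else:
            # wearer effort maps to EMG envelopes; the myoprocessor decodes
            # flexion-positive torque from them
            effort = tau_human + tau_grav
            u_bi = float(np.clip(cfg.emg_baseline + cfg.emg_effort_gain * max(effort, 0.0), 0, 1))
            u_tri = float(np.clip(cfg.emg_baseline + cfg.emg_effort_gain * max(-effort, 0.0), 0, 1))
            tau_r = cfg.flexion_sign * myoprocessor_required_torque(
                u_bi, u_tri, state.theta_e, cfg.muscle)

        tau_exo = exosuit_torque(cfg.geom, pneu)
        tau_i = interaction_torque(tau_r, tau_exo)
        cmd = valve_controller(tau_i, cfg.controller, pid)
        if is_error and t < cfg.error_override_duration:
            cmd = ValveCommand(100.0, 0.0) if error_type == "inflate" else ValveCommand(0.0, 100.0)

        for k, v in (("time", t), ("theta_e", state.theta_e), ("omega", state.omega),
                     ("pressure", pneu.P), ("tau_r", tau_r), ("tau_exo", tau_exo),
                     ("tau_i", tau_i), ("phi_in", cmd.phi_in), ("phi_out", cmd.phi_out)):
            cols[k][i] = v

        pneu = pneumatic_step(pneu, cmd, dt, cfg.k_in, cfg.k_out)
        state = arm_step(cfg.arm, state, exosuit_torque(cfg.geom, pneu), tau_human, dt)

    return SimTrace(**cols)
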