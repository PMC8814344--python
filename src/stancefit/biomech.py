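"""Single-link inverted pendulum (SIP) mechanics on a translating support base.

The whole body is treated as a rigid rod hinged at the ankle, with the mass
``m`` lumped at the centre of mass a distance ``l`` above the joint; the feet
are inertia-less and fixed to the platform.  Sign conventions: forward lean
``theta > 0``, plantarflexor (toe-down) ankle torque positive, backward
platform displacement ``d > 0``.

The angular-momentum balance about the ankle reads

    M_a = m l^2 th'' - m g l sin(th) + d' m l sin(th) th' - d'' m l cos(th)

where ``M_a`` is the net ankle torque transmitted through the ground reaction
(measured on a force plate as the moment of the reaction force about the
joint).  Collecting the gravitational, Coriolis and base-inertia terms into a
disturbance torque

    tau_d = -m g l sin(th) + d' m l sin(th) th' - d'' m l cos(th)

defines the internal neuromuscular control torque as the remainder,

    tau_c = M_a - tau_d  (= m l^2 th'' identically).

Forward simulation (:func:`simulate_sip`) integrates the balance with a
delayed feedback law producing ``M_a``; :func:`inverse_dynamics` recovers
``tau_c`` from plate and kinematic recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "PendulumParams",
    "MotionSeries",
    "GroundReaction",
    "TorqueSeries",
    "FallError",
    "StateHistory",
    "ankle_torque",
    "disturbance_torque",
    "control_torque",
    "simulate_sip",
    "inverse_dynamics",
    "central_difference",
]

#: relative tolerance on time-grid uniformity
_GRID_RTOL = 1e-9


class FallError(RuntimeError):
    """Raised when |theta| exceeds pi/2 during integration (model invalid)."""


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"expected 1-D array, got shape {a.shape}")
    return a


def _check_uniform(time: np.ndarray) -> float:
    if time.size < 2:
        raise ValueError("time grid needs at least two samples")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=_GRID_RTOL, atol=_GRID_RTOL * max(abs(dt[0]), 1.0)):
        raise ValueError("time grid is not uniform")
    return float(dt[0])


@dataclass(frozen=True)
class PendulumParams:
    """Anthropometric parameters of the lumped pendulum.

    mass : point mass at the COM [kg]; length : ankle-to-COM distance [m];
    gravity : gravitational acceleration [m/s^2].
    """

    mass: float = 70.0
    length: float = 0.9
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.length <= 0 or self.gravity <= 0:
            raise ValueError("mass, length and gravity must all be positive")

    @property
    def inertia(self) -> float:
        """Moment of inertia about the ankle, m*l^2 [kg m^2]."""
        return self.mass * self.length**2


@dataclass
class MotionSeries:
    """Pendulum + platform kinematics on a uniform time grid.

    ``theta`` is the sway angle from vertical (rad, forward positive);
    ``d`` the horizontal platform displacement (m, backward positive).
    Derivative channels may be ``None`` until populated.
    """

    time: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray | None = None
    theta_ddot: np.ndarray | None = None
    d: np.ndarray | None = None
    d_dot: np.ndarray | None = None
    d_ddot: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time)
        self.theta = _as_1d(self.theta)
        n = self.time.size
        for name in ("theta", "theta_dot", "theta_ddot", "d", "d_dot", "d_ddot"):
            v = getattr(self, name)
            if v is not None:
                v = _as_1d(v)
                setattr(self, name, v)
                if v.size != n:
                    raise ValueError(f"channel {name!r} length {v.size} != time length {n}")
        _check_uniform(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class GroundReaction:
    """Sagittal-plane force-plate record: CoP (re ankle projection) and reaction force."""

    time: np.ndarray
    cop_x: np.ndarray
    force_x: np.ndarray
    force_z: np.ndarray

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time)
        self.cop_x = _as_1d(self.cop_x)
        self.force_x = _as_1d(self.force_x)
        self.force_z = _as_1d(self.force_z)
        n = self.time.size
        if n == 0:
            raise ValueError("empty ground-reaction record")
        for name in ("cop_x", "force_x", "force_z"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} misaligned with time grid")
        if np.any(self.force_z < 0):
            raise ValueError("force_z < 0: foot unloaded, record invalid")


@dataclass
class TorqueSeries:
    """Ankle-torque decomposition: total M_a, disturbance tau_d, control tau_c = M_a - tau_d."""

    time: np.ndarray
    m_a: np.ndarray
    tau_d: np.ndarray
    tau_c: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time)
        self.m_a = _as_1d(self.m_a)
        self.tau_d = _as_1d(self.tau_d)
        if self.m_a.size != self.time.size or self.tau_d.size != self.time.size:
            raise ValueError("torque channels misaligned with time grid")
        if self.tau_c is None:
            self.tau_c = self.m_a - self.tau_d
        else:
            self.tau_c = _as_1d(self.tau_c)
            if not np.array_equal(self.tau_c, self.m_a - self.tau_d):
                raise ValueError("tau_c must equal m_a - tau_d elementwise")


# ---------------------------------------------------------------------------
# torque decomposition
# ---------------------------------------------------------------------------

def ankle_torque(grf: GroundReaction, h_ankle: float = 0.0) -> np.ndarray:
    """Net ankle torque from the plate: planar moment of R about the joint.

    M_a = cop_x * force_z - h_ankle * force_x, with ``h_ankle`` the joint
    height above the plate surface (default 0: CoP and ankle coplanar).
    Positive M_a is plantarflexor.
    """
    return grf.cop_x * grf.force_z - h_ankle * grf.force_x


def disturbance_torque(motion: MotionSeries, params: PendulumParams) -> np.ndarray:
    """Gravity + Coriolis + base-inertia torque tau_d at the ankle [N m]."""
    if motion.theta_dot is None or motion.d_dot is None or motion.d_ddot is None:
        raise ValueError("disturbance_torque needs theta_dot, d_dot and d_ddot channels")
    m, l, g = params.mass, params.length, params.gravity
    s, c = np.sin(motion.theta), np.cos(motion.theta)
    return (
        -m * g * l * s
        + motion.d_dot * m * l * s * motion.theta_dot
        - motion.d_ddot * m * l * c
    )


def control_torque(time, m_a, tau_d) -> TorqueSeries:
    """Pack the decomposition tau_c = M_a - tau_d into a :class:`TorqueSeries`."""
    time, m_a, tau_d = _as_1d(time), _as_1d(m_a), _as_1d(tau_d)
    if m_a.size != time.size or tau_d.size != time.size:
        raise ValueError("m_a / tau_d length mismatch with time")
    return TorqueSeries(time=time, m_a=m_a, tau_d=tau_d)


# ---------------------------------------------------------------------------
# numerical differentiation
# ---------------------------------------------------------------------------

def central_difference(x: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """Central differences on a uniform grid, one-sided at the ends.

    order=1 uses np.gradient; order=2 the standard three-point second
    difference with one-sided copies at the boundary samples.
    """
    x = _as_1d(x)
    if order == 1:
        return np.gradient(x, dt)
    if order == 2:
        if x.size < 3:
            raise ValueError("need >= 3 samples for a second difference")
        dd = np.empty_like(x)
        dd[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
        dd[0] = dd[1]
        dd[-1] = dd[-2]
        return dd
    raise ValueError("order must be 1 or 2")


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

class StateHistory:
    """Integrated state history exposed to delayed feedback laws.

    :func:`simulate_sip` appends each accepted (t, theta, theta_dot) sample;
    ``interpolate(t)`` returns the state at any past instant by linear
    interpolation, clamping to the initial state for t <= 0 and to the most
    recent sample beyond the current front (the latter only matters for
    delays shorter than one step).
    """

    def __init__(self, n: int, theta0: float, theta_dot0: float) -> None:
        self._t = np.empty(n)
        self._theta = np.empty(n)
        self._theta_dot = np.empty(n)
        self._len = 0
        self.append(0.0, theta0, theta_dot0)

    def append(self, t: float, theta: float, theta_dot: float) -> None:
        self._t[self._len] = t
        self._theta[self._len] = theta
        self._theta_dot[self._len] = theta_dot
        self._len += 1

    def interpolate(self, t: float) -> tuple[float, float]:
        k = self._len
        if t <= self._t[0]:
            return float(self._theta[0]), float(self._theta_dot[0])
        if t >= self._t[k - 1]:
            return float(self._theta[k - 1]), float(self._theta_dot[k - 1])
        th = np.interp(t, self._t[:k], self._theta[:k])
        thd = np.interp(t, self._t[:k], self._theta_dot[:k])
        return float(th), float(thd)


def simulate_sip(
    params: PendulumParams,
    ankle_torque_fn: Callable[[float, float, float], float],
    platform: MotionSeries,
    theta0: float = 0.0,
    theta_dot0: float = 0.0,
    dt: float = 1e-3,
    duration: float | None = None,
) -> MotionSeries:
    """Integrate the perturbed pendulum under a muscular ankle-torque law.

    ``ankle_torque_fn(t, theta, theta_dot)`` returns the net muscular ankle
    torque M_a [N m] (a delayed feedback law may close the loop by reading
    its own stored history; it is called once per RK4 stage).  The equation
    integrated is the angular-momentum balance rearranged for th'':

        th'' = [M_a + m g l sin(th) - d' m l sin(th) th' + d'' m l cos(th)] / (m l^2)

    Platform channels are interpolated from ``platform`` (which must supply
    d, d_dot, d_ddot over [0, duration]).  Fixed-step RK4; deterministic.

    Raises :class:`FallError` if |theta| exceeds pi/2.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if platform.d is None or platform.d_dot is None or platform.d_ddot is None:
        raise ValueError("platform must provide d, d_dot and d_ddot channels")
    if duration is None:
        duration = float(platform.time[-1])
    if duration < dt:
        raise ValueError("duration must be at least one step")

    n = int(round(duration / dt)) + 1
    time = np.arange(n) * dt
    if time[-1] > platform.time[-1] + 1e-12:
        raise ValueError("platform channels do not cover [0, duration]")

    d = np.interp(time, platform.time, platform.d)
    d_dot = np.interp(time, platform.time, platform.d_dot)
    d_ddot = np.interp(time, platform.time, platform.d_ddot)
    # mid-step platform samples for the RK4 stages
    d_dot_h = np.interp(time + dt / 2, platform.time, platform.d_dot)
    d_ddot_h = np.interp(time + dt / 2, platform.time, platform.d_ddot)

    m, l, g = params.mass, params.length, params.gravity
    inertia = params.inertia

    history = StateHistory(n, theta0, theta_dot0)
    bind = getattr(ankle_torque_fn, "bind_history", None)
    if callable(bind):
        bind(history)

    def accel(t, th, thd, dd, ddd):
        ma = ankle_torque_fn(t, th, thd)
        return (ma + m * g * l * np.sin(th) - dd * m * l * np.sin(th) * thd
                + ddd * m * l * np.cos(th)) / inertia

    theta = np.empty(n)
    theta_dot = np.empty(n)
    theta_ddot = np.empty(n)
    theta[0], theta_dot[0] = theta0, theta_dot0

    for k in range(n - 1):
        t, th, thd = time[k], theta[k], theta_dot[k]
        a1 = accel(t, th, thd, d_dot[k], d_ddot[k])
        a2 = accel(t + dt / 2, th + dt / 2 * thd, thd + dt / 2 * a1, d_dot_h[k], d_ddot_h[k])
        a3 = accel(t + dt / 2, th + dt / 2 * thd + dt**2 / 4 * a1, thd + dt / 2 * a2,
                   d_dot_h[k], d_ddot_h[k])
        a4 = accel(t + dt, th + dt * thd + dt**2 / 2 * a2, thd + dt * a3,
                   d_dot[k + 1], d_ddot[k + 1])
        theta[k + 1] = th + dt * thd + dt**2 / 6 * (a1 + a2 + a3)
        theta_dot[k + 1] = thd + dt / 6 * (a1 + 2 * a2 + 2 * a3 + a4)
        if abs(theta[k + 1]) > np.pi / 2:
            raise FallError(f"pendulum fell at t = {time[k + 1]:.3f} s")
        history.append(time[k + 1], theta[k + 1], theta_dot[k + 1])
        theta_ddot[k] = a1
    theta_ddot[-1] = accel(time[-1], theta[-1], theta_dot[-1], d_dot[-1], d_ddot[-1])

    return MotionSeries(
        time=time, theta=theta, theta_dot=theta_dot, theta_ddot=theta_ddot,
        d=d, d_dot=d_dot, d_ddot=d_ddot,
    )


# ---------------------------------------------------------------------------
# inverse dynamics
# ---------------------------------------------------------------------------

def inverse_dynamics(
    motion: MotionSeries,
    grf: GroundReaction,
    params: PendulumParams,
    h_ankle: float = 0.0,
) -> TorqueSeries:
    """Recover the control torque from synchronized kinematics and plate data.

    ``motion`` needs theta and d on the same uniform grid as ``grf``;
    missing derivative channels are filled by central differences.  Returns
    the full decomposition (M_a, tau_d, tau_c = M_a - tau_d).
    """
    if motion.time.size == 0 or grf.time.size == 0:
        raise ValueError("empty input series")
    if motion.time.size != grf.time.size or not np.allclose(
        motion.time, grf.time, rtol=0, atol=1e-9 * max(motion.dt, 1e-12)
    ):
        raise ValueError("motion and ground-reaction grids are not aligned")
    dt = motion.dt

    theta_dot = motion.theta_dot if motion.theta_dot is not None else central_difference(motion.theta, dt)
    if motion.d is None:
        raise ValueError("motion must carry the platform displacement channel d")
    d_dot = motion.d_dot if motion.d_dot is not None else central_difference(motion.d, dt)
    d_ddot = motion.d_ddot if motion.d_ddot is not None else central_difference(motion.d, dt, order=2)

    filled = MotionSeries(
        time=motion.time, theta=motion.theta, theta_dot=theta_dot,
        d=motion.d, d_dot=d_dot, d_ddot=d_ddot,
    )
    m_a = ankle_torque(grf, h_ankle=h_ankle)
    tau_d = disturbance_torque(filled, params)
    return control_torque(motion.time, m_a, tau_d)
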