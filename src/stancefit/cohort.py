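"""Synthetic perturbed-stance cohort generator.

Emulates a platform-translation posturography session: subjects standing on
a servo-controlled base that translates 5 cm backward in 0.3 s, balancing
via a delayed two-mode PD ankle-torque controller, recorded with optical
kinematics (100 Hz), a force plate and two sEMG channels (1,000 Hz).  Every
trial carries its ground truth (commanded control torque, mode sequence,
switch time) so downstream identification can be validated against a known
hybrid controller.

Also provides a direct PWARX data generator (:func:`generate_pwarx_data`)
for estimator recovery experiments with known coefficients and boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .biomech import (
    FallError,
    MotionSeries,
    PendulumParams,
    StateHistory,
    disturbance_torque,
    simulate_sip,
)
from .regressors import LagCoordinate, RegressionDataset

__all__ = [
    "PlatformProfile",
    "HybridControllerSpec",
    "DelayedTwoModeController",
    "EMGModelSpec",
    "SensorNoiseSpec",
    "CohortSpec",
    "TrialTruth",
    "TrialRecord",
    "TruePWARX",
    "platform_displacement",
    "platform_motion",
    "simulate_trial",
    "generate_cohort",
    "generate_pwarx_data",
    "default_true_pwarx",
]

CONDITIONS = ("EO", "EC", "DT")


# ---------------------------------------------------------------------------
# platform profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlatformProfile:
    """Backward base translation: minimum-jerk ramp of ``amplitude`` in ``duration``."""

    amplitude: float = 0.05  # m
    duration: float = 0.3    # s
    onset: float = 0.5       # s
    shape: str = "minimum_jerk"

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.duration <= 0:
            raise ValueError("amplitude and duration must be positive")
        if self.shape != "minimum_jerk":
            raise ValueError(f"unknown profile shape {self.shape!r}")


def platform_displacement(
    profile: PlatformProfile, time_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic minimum-jerk displacement and derivatives on a uniform grid.

    d(s) = A (10 s^3 - 15 s^4 + 6 s^5) with s = (t - onset)/T clipped to
    [0, 1]; velocity and acceleration vanish at both ends.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size >= 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid is not uniform")
    A, T = profile.amplitude, profile.duration
    s = np.clip((t - profile.onset) / T, 0.0, 1.0)
    d = A * (10 * s**3 - 15 * s**4 + 6 * s**5)
    d_dot = A / T * (30 * s**2 - 60 * s**3 + 30 * s**4)
    d_ddot = A / T**2 * (60 * s - 180 * s**2 + 120 * s**3)
    # outside the support the clipped s makes the derivative factors 0 at s=0,1
    return d, d_dot, d_ddot


def platform_motion(profile: PlatformProfile, time_grid: np.ndarray) -> MotionSeries:
    """Platform channels packed into a MotionSeries (theta channels zeroed)."""
    d, d_dot, d_ddot = platform_displacement(profile, time_grid)
    z = np.zeros_like(d)
    return MotionSeries(time=time_grid, theta=z, theta_dot=z, theta_ddot=z,
                        d=d, d_dot=d_dot, d_ddot=d_ddot)


# ---------------------------------------------------------------------------
# controller
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HybridControllerSpec:
    """Two-mode delayed PD ankle controller.

    Gains are (Kp [N m/rad], Kd [N m s/rad]) around upright.  Mode 1 acts
    until the switch; mode 2 afterwards.  ``switch_rule`` is ``"time"``
    (switch at onset + ``switch_delay``) or ``"accel"`` (switch when the base
    acceleration magnitude first falls back below ``accel_threshold`` after
    onset).  ``feedback_delay`` is the sensorimotor loop delay.
    """

    mode1_gains: tuple[float, float] = (2040.0, 510.0)
    mode2_gains: tuple[float, float] = (1130.0, 340.0)
    feedback_delay: float = 0.15       # s
    switch_rule: str = "time"
    switch_delay: float = 0.25         # s after onset
    accel_threshold: float = 0.5       # m/s^2, for the "accel" rule
    torque_noise_sd: float = 1.0       # N m

    def __post_init__(self) -> None:
        if min(*self.mode1_gains, *self.mode2_gains) < 0:
            raise ValueError("gains must be non-negative")
        if self.feedback_delay < 0:
            raise ValueError("feedback delay must be non-negative")
        if self.switch_rule not in ("time", "accel"):
            raise ValueError(f"unknown switch rule {self.switch_rule!r}")

    def for_condition(self, condition: str) -> "HybridControllerSpec":
        """Condition-specific controller variant.

        EO is the baseline; EC raises both modes' gains by 30% (stiffening
        under visual deprivation); DT shortens the effective loop delay to
        120 ms (more reflex-driven control under cognitive load).  These are
        generator design choices so that identified models differ across
        conditions, not physiological claims.
        """
        if condition == "EO":
            return self
        if condition == "EC":
            scale = 1.3
            return replace(
                self,
                mode1_gains=(self.mode1_gains[0] * scale, self.mode1_gains[1] * scale),
                mode2_gains=(self.mode2_gains[0] * scale, self.mode2_gains[1] * scale),
            )
        if condition == "DT":
            return replace(self, feedback_delay=0.12)
        raise ValueError(f"unknown condition {condition!r}")


class DelayedTwoModeController:
    """Callable ankle-torque law M_a(t) = -Kp th(t-D) - Kd th'(t-D), mode-switched.

    Reads its delayed state from the :class:`~stancefit.biomech.StateHistory`
    bound by the integrator.  ``torque_noise`` is a pre-drawn series on a
    uniform grid, linearly interpolated (band-limited motor noise).
    """

    def __init__(
        self,
        spec: HybridControllerSpec,
        onset: float,
        torque_noise_t: np.ndarray | None = None,
        torque_noise: np.ndarray | None = None,
    ) -> None:
        self.spec = spec
        self.onset = onset
        self._noise_t = torque_noise_t
        self._noise = torque_noise
        self._history: StateHistory | None = None
        if spec.switch_rule == "time":
            self.switch_time = onset + spec.switch_delay
        else:
            self.switch_time = None  # resolved lazily against the platform profile

    def bind_history(self, history: StateHistory) -> None:
        self._history = history

    def resolve_accel_switch(self, profile: PlatformProfile) -> None:
        """Fix the switch instant for the acceleration rule (deterministic)."""
        t = np.arange(0.0, profile.onset + profile.duration + 0.05, 1e-4)
        _, _, ddd = platform_displacement(profile, t)
        above = np.abs(ddd) > self.spec.accel_threshold
        idx = np.nonzero(above)[0]
        if idx.size == 0:
            self.switch_time = profile.onset + profile.duration
        else:
            self.switch_time = float(t[idx[-1]])

    def mode(self, t: float) -> int:
        if self.switch_time is None:
            raise RuntimeError("accel switch rule not resolved; call resolve_accel_switch")
        return 1 if t < self.switch_time else 2

    def __call__(self, t: float, theta: float, theta_dot: float) -> float:
        if self._history is not None:
            theta, theta_dot = self._history.interpolate(t - self.spec.feedback_delay)
        kp, kd = self.spec.mode1_gains if self.mode(t) == 1 else self.spec.mode2_gains
        u = -kp * theta - kd * theta_dot
        if self._noise is not None:
            u += float(np.interp(t, self._noise_t, self._noise))
        return u


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EMGModelSpec:
    """sEMG surrogate: band-limited carrier amplitude-modulated by torque demand.

    The gastrocnemius envelope follows the delayed rectified plantarflexion
    demand max(tau_c, 0), the tibialis anterior max(-tau_c, 0); only the RMS
    envelope is consumed downstream, so carrier realism is secondary.
    Units are arbitrary envelope units (a.u., mV-like).
    """

    electromech_delay: float = 0.04    # s
    gain_ga: float = 2e-3              # a.u. per N m
    gain_ta: float = 2e-3
    baseline: float = 0.02             # a.u.
    noise_sd: float = 5e-3             # a.u., additive measurement noise
    carrier_band: tuple[float, float] = (30.0, 450.0)

    def __post_init__(self) -> None:
        if self.electromech_delay < 0 or self.noise_sd < 0:
            raise ValueError("delays and noise_sd must be non-negative")


@dataclass(frozen=True)
class SensorNoiseSpec:
    """Additive measurement-noise levels at instrument-typical magnitudes."""

    theta_sd: float = 2e-4     # rad, optical motion capture
    d_sd: float = 1e-4         # m, platform marker
    cop_sd: float = 5e-4       # m, force-plate CoP
    force_sd: float = 0.5      # N

    @classmethod
    def noiseless(cls) -> "SensorNoiseSpec":
        return cls(theta_sd=0.0, d_sd=0.0, cop_sd=0.0, force_sd=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 10
    conditions: tuple[str, ...] = CONDITIONS
    mass_mean: float = 70.0
    mass_sd: float = 10.0
    length_mean: float = 0.9
    length_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")


# ---------------------------------------------------------------------------
# trial record
# ---------------------------------------------------------------------------

@dataclass
class TrialTruth:
    """Generator-side ground truth attached to a synthetic trial (100 Hz grid)."""

    tau_c: np.ndarray          # commanded control torque M_a - tau_d  [N m]
    m_a: np.ndarray            # net muscular ankle torque  [N m]
    mode: np.ndarray           # active controller mode per sample, values {1, 2}
    switch_time: float         # s, absolute time of the mode transition

    @property
    def n_switches(self) -> int:
        return int(np.count_nonzero(np.diff(self.mode) != 0))


@dataclass
class TrialRecord:
    """One subject x condition recording with sampling metadata.

    Kinematics (theta, d) at ``fs_kin``; plate and EMG channels at
    ``fs_plate``.  ``truth`` is generator metadata, absent for real data.
    """

    subject: int
    condition: str
    params: PendulumParams
    onset: float
    fs_kin: float
    fs_plate: float
    kin_time: np.ndarray
    theta: np.ndarray
    d: np.ndarray
    plate_time: np.ndarray
    cop_x: np.ndarray
    force_x: np.ndarray
    force_z: np.ndarray
    emg_ga: np.ndarray
    emg_ta: np.ndarray
    h_ankle: float = 0.0
    truth: TrialTruth | None = None


def _bandlimited_carrier(n: int, fs: float, band: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the sEMG carrier band."""
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_trial(
    subject: int,
    condition: str,
    params: PendulumParams,
    controller: HybridControllerSpec,
    emg: EMGModelSpec,
    profile: PlatformProfile,
    seed,
    *,
    sensor_noise: SensorNoiseSpec = SensorNoiseSpec(),
    duration: float = 2.0,
    fs_kin: float = 100.0,
    fs_plate: float = 1000.0,
    h_ankle: float = 0.0,
    theta0: float = 0.0,
    theta_dot0: float = 0.0,
) -> TrialRecord:
    """Closed-loop synthetic trial with model-consistent plate and EMG channels.

    The plate channels are synthesized from the simulated states so that the
    inverse-dynamics decomposition applied to a noiseless trial recovers the
    commanded control torque exactly (up to differencing error):
    force_z = m g, force_x = m * (horizontal COM acceleration), and cop_x is
    solved from M_a = cop_x force_z - h_ankle force_x.

    Raises :class:`~stancefit.biomech.FallError` if the controller
    destabilizes the pendulum (trial to be rejected by the caller).
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_plate
    n_sim = int(round(duration * fs_plate)) + 1
    t_sim = np.arange(n_sim) * dt

    cond_spec = controller.for_condition(condition)
    # band-limited motor noise, drawn on a 100 Hz grid and interpolated
    noise_t = np.arange(0.0, duration + 0.02, 0.01)
    torque_noise = cond_spec.torque_noise_sd * rng.standard_normal(noise_t.size)
    law = DelayedTwoModeController(cond_spec, profile.onset, noise_t, torque_noise)
    if cond_spec.switch_rule == "accel":
        law.resolve_accel_switch(profile)

    platform = platform_motion(profile, t_sim)
    motion = simulate_sip(params, law, platform, theta0=theta0,
                          theta_dot0=theta_dot0, dt=dt, duration=duration)

    m, l, g = params.mass, params.length, params.gravity
    tau_d = disturbance_torque(motion, params)
    tau_c = params.inertia * motion.theta_ddot          # identity M_a - tau_d
    m_a = tau_c + tau_d

    # plate channels, consistent with the rigid-body model
    com_acc = (-motion.d_ddot
               + l * (motion.theta_ddot * np.cos(motion.theta)
                      - motion.theta_dot**2 * np.sin(motion.theta)))
    force_z = np.full(n_sim, m * g)
    force_x = m * com_acc
    cop_x = (m_a + h_ankle * force_x) / force_z

    cop_x = cop_x + sensor_noise.cop_sd * rng.standard_normal(n_sim)
    force_x = force_x + sensor_noise.force_sd * rng.standard_normal(n_sim)
    force_z = force_z + sensor_noise.force_sd * rng.standard_normal(n_sim)

    # sEMG: carriers modulated by the delayed rectified torque demand
    delay_n = int(round(emg.electromech_delay * fs_plate))
    demand = np.concatenate([np.full(delay_n, tau_c[0]), tau_c])[:n_sim]
    env_ga = emg.baseline + emg.gain_ga * np.maximum(demand, 0.0)
    env_ta = emg.baseline + emg.gain_ta * np.maximum(-demand, 0.0)
    emg_ga = env_ga * _bandlimited_carrier(n_sim, fs_plate, emg.carrier_band, rng)
    emg_ta = env_ta * _bandlimited_carrier(n_sim, fs_plate, emg.carrier_band, rng)
    emg_ga = emg_ga + emg.noise_sd * rng.standard_normal(n_sim)
    emg_ta = emg_ta + emg.noise_sd * rng.standard_normal(n_sim)

    # kinematics: every 10th simulation sample (fs_plate must be a multiple)
    step = int(round(fs_plate / fs_kin))
    kin_time = t_sim[::step]
    theta_kin = motion.theta[::step] + sensor_noise.theta_sd * rng.standard_normal(kin_time.size)
    d_kin = motion.d[::step] + sensor_noise.d_sd * rng.standard_normal(kin_time.size)

    mode = np.where(kin_time < law.switch_time, 1, 2).astype(int)
    truth = TrialTruth(tau_c=tau_c[::step], m_a=m_a[::step], mode=mode,
                       switch_time=float(law.switch_time))

    return TrialRecord(
        subject=subject, condition=condition, params=params, onset=profile.onset,
        fs_kin=fs_kin, fs_plate=fs_plate,
        kin_time=kin_time, theta=theta_kin, d=d_kin,
        plate_time=t_sim, cop_x=cop_x, force_x=force_x, force_z=force_z,
        emg_ga=emg_ga, emg_ta=emg_ta, h_ankle=h_ankle, truth=truth,
    )


def generate_cohort(
    spec: CohortSpec,
    controller: HybridControllerSpec = HybridControllerSpec(),
    emg: EMGModelSpec = EMGModelSpec(),
    profile: PlatformProfile = PlatformProfile(),
    *,
    sensor_noise: SensorNoiseSpec = SensorNoiseSpec(),
    duration: float = 2.0,
) -> list[TrialRecord]:
    """All subject x condition trials; fully determined by ``spec.seed``.

    Subject anthropometrics are drawn once per subject; each trial gets an
    independent child seed.  Destabilized trials raise FallError (none occur
    at the default gains; callers emulating trial rejection may catch it).
    """
    ss = np.random.SeedSequence(spec.seed)
    anthro_rng = np.random.default_rng(ss.spawn(1)[0])
    masses = np.clip(anthro_rng.normal(spec.mass_mean, spec.mass_sd, spec.n_subjects), 45.0, 110.0)
    lengths = np.clip(anthro_rng.normal(spec.length_mean, spec.length_sd, spec.n_subjects), 0.7, 1.1)
    trial_seeds = ss.spawn(spec.n_subjects * len(spec.conditions) + 1)[1:]

    trials: list[TrialRecord] = []
    i = 0
    for subj in range(1, spec.n_subjects + 1):
        params = PendulumParams(mass=float(masses[subj - 1]), length=float(lengths[subj - 1]))
        for cond in spec.conditions:
            trials.append(
                simulate_trial(subj, cond, params, controller, emg, profile,
                               trial_seeds[i], sensor_noise=sensor_noise,
                               duration=duration)
            )
            i += 1
    return trials


# ---------------------------------------------------------------------------
# direct PWARX data generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruePWARX:
    """Ground-truth two-region piecewise-affine ARX system.

    ``coeffs`` has shape (s, n_d + 1) with the affine offset last; the
    regression vector is [y_{k-1..k-n_ar}, u_{k-1..k-n_ex}].  ``hyperplane``
    (length n_d + 1) defines region 1 by h.[x; 1] <= 0; ignored when s = 1.
    """

    coeffs: np.ndarray
    hyperplane: np.ndarray | None
    n_ar: int
    n_ex: int
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        object.__setattr__(self, "coeffs", c)
        if self.hyperplane is not None:
            object.__setattr__(self, "hyperplane", np.asarray(self.hyperplane, dtype=float))
        if self.n_ar + self.n_ex != c.shape[1] - 1:
            raise ValueError("n_ar + n_ex must equal n_d = coeffs width - 1")
        if c.shape[0] > 1 and self.hyperplane is None:
            raise ValueError("multi-region truth requires a hyperplane")

    @property
    def s(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_d(self) -> int:
        return self.coeffs.shape[1] - 1

    def region(self, x: np.ndarray) -> int:
        if self.s == 1:
            return 0
        h = self.hyperplane
        return 0 if h[:-1] @ x + h[-1] <= 0 else 1


def default_true_pwarx(noise_sd: float = 0.0) -> TruePWARX:
    """Benchmark two-mode system with well-separated regions.

    Five exogenous regressors, region keyed to the sign of the first one,
    and affine offsets +6 / -6 so the two (x, y) clouds are clearly
    separated.  Intended for ``generate_pwarx_data(..,
    input_process="margin")``, whose two-lobe first input leaves an empty
    corridor around the true boundary x1 = 0: region membership is then
    unambiguous and the boundary is recoverable to high accuracy.
    """
    coeffs = np.array([
        [0.6, 0.3, -0.2, 0.4, 0.15, 6.0],
        [-0.35, 0.5, 0.3, -0.15, -0.4, -6.0],
    ])
    h = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    return TruePWARX(coeffs=coeffs, hyperplane=h, n_ar=0, n_ex=5, noise_sd=noise_sd)


def generate_pwarx_data(
    truth: TruePWARX,
    n: int,
    seed,
    *,
    input_sd: float = 1.0,
    input_process: str = "gaussian",
    boundary_margin: float = 0.5,
    snr_db: float | None = None,
    burn_in: int = 50,
) -> tuple[RegressionDataset, np.ndarray]:
    """Iterate the PWARX recursion; returns the dataset and true region labels.

    Exogenous inputs are iid N(0, input_sd^2) (``input_process="gaussian"``)
    or, with ``input_process="margin"``, the first exogenous input is drawn
    as sign * (boundary_margin + |N(0, input_sd^2)|): a symmetric two-lobe
    distribution leaving an empty corridor around zero, which realizes
    well-separated regions when the boundary is keyed to that input.  Noise
    is iid N(0, noise_sd^2); if ``snr_db`` is given the noise scale is set
    from the noiseless output standard deviation so that var(y)/var(e)
    matches the requested SNR.  Raises if the output diverges (unstable
    truth).
    """
    if n <= truth.n_d + 1:
        raise ValueError("need more than n_d + 1 samples")
    if input_process not in ("gaussian", "margin"):
        raise ValueError(f"unknown input process {input_process!r}")

    def _run(noise_sd: float, rng: np.random.Generator):
        total = n + burn_in
        u = input_sd * rng.standard_normal(total + truth.n_ex)
        if input_process == "margin":
            u = np.sign(u) * (boundary_margin + np.abs(u))
        e = noise_sd * rng.standard_normal(total) if noise_sd > 0 else np.zeros(total)
        y = np.zeros(total + truth.n_ar)
        labels = np.zeros(total, dtype=int)
        X = np.empty((total, truth.n_d))
        for k in range(total):
            # lagged outputs y_{k-1}..y_{k-n_ar} and inputs u_{k-1}..u_{k-n_ex}
            ar = np.array([y[k + truth.n_ar - i] for i in range(1, truth.n_ar + 1)])
            ex = np.array([u[k + truth.n_ex - i] for i in range(1, truth.n_ex + 1)])
            x = np.concatenate([ar, ex])
            j = truth.region(x)
            yk = truth.coeffs[j, :-1] @ x + truth.coeffs[j, -1] + e[k]
            if not np.isfinite(yk) or abs(yk) > 1e8:
                raise ValueError("true PWARX model is unstable: output diverged")
            y[k + truth.n_ar] = yk
            labels[k] = j
            X[k] = x
        return X[burn_in:], y[truth.n_ar + burn_in:], labels[burn_in:]

    ss = np.random.SeedSequence(seed)
    if snr_db is not None:
        X0, y0, _ = _run(0.0, np.random.default_rng(ss.spawn(2)[0]))
        noise_sd = float(np.std(y0) / 10 ** (snr_db / 20))
    else:
        noise_sd = truth.noise_sd
    X, y, labels = _run(noise_sd, np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1]))

    columns = (
        [LagCoordinate("tau_c", i) for i in range(1, truth.n_ar + 1)]
        + [LagCoordinate("theta", i) for i in range(1, truth.n_ex + 1)]
    )
    ds = RegressionDataset(
        X=X, y=y, columns=columns,
        groups=np.zeros(n, dtype=int), condition=None,
    )
    return ds, labels
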