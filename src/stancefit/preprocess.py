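"""Data-cleaning chain for perturbed-stance trials.

Kinematics: second-order zero-phase low-pass Butterworth at 10 Hz.  Kinetic
(plate) channels: same filter at 15 Hz, linear detrend, down-sample to
100 Hz.  sEMG: zero-phase band-pass 30-450 Hz, moving-window RMS envelope,
down-sample to 100 Hz.  The cleaned trial is cropped to a 1 s epoch (100
samples) starting at perturbation onset, yielding the four modelling series:
control torque tau_c, sway angle theta, and the GA / TA RMS envelopes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .biomech import GroundReaction, MotionSeries, TorqueSeries, inverse_dynamics
from .cohort import TrialRecord

__all__ = [
    "CleanEpoch",
    "butterworth_zero_phase",
    "clean_kinematics",
    "clean_kinetics",
    "emg_envelope",
    "extract_epoch",
    "auc_ratio",
]

log = logging.getLogger(__name__)

EPOCH_SAMPLES = 100
EPOCH_FS = 100.0


@dataclass
class CleanEpoch:
    """The four 100-sample modelling series on a common 100 Hz grid from onset."""

    tau_c: np.ndarray
    theta: np.ndarray
    ga_rms: np.ndarray
    ta_rms: np.ndarray
    onset_time: float
    fs: float = EPOCH_FS
    subject: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        for name in ("tau_c", "theta", "ga_rms", "ta_rms"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (EPOCH_SAMPLES,):
                raise ValueError(f"epoch channel {name!r} must have exactly "
                                 f"{EPOCH_SAMPLES} samples, got {v.shape}")

    @property
    def time(self) -> np.ndarray:
        return self.onset_time + np.arange(EPOCH_SAMPLES) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return {"tau_c": self.tau_c, "theta": self.theta,
                "ga": self.ga_rms, "ta": self.ta_rms}[name]


def butterworth_zero_phase(x, order: int, fc, fs: float, btype: str = "lowpass") -> np.ndarray:
    """Forward-backward Butterworth filter (zero net phase shift).

    Odd-reflection padding of 3 * (order + 1) samples at each end keeps end
    transients small on short epochs.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    if np.any(np.asarray(fc, dtype=float) >= nyq):
        raise ValueError(f"cutoff {fc} must lie below the Nyquist frequency {nyq}")
    padlen = 3 * (order + 1)
    if x.size <= padlen:
        raise ValueError(f"series too short ({x.size} samples) for padded zero-phase "
                         f"filtering (need > {padlen})")
    sos = sps.butter(order, fc, btype=btype, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def clean_kinematics(theta_raw, fs: float = 100.0) -> np.ndarray:
    """Kinematic cleaning: order-2 zero-phase low-pass at 10 Hz."""
    return butterworth_zero_phase(theta_raw, order=2, fc=10.0, fs=fs)


def clean_kinetics(plate_raw, fs: float = 1000.0, fs_out: float = 100.0) -> np.ndarray:
    """Kinetic cleaning: order-2 zero-phase low-pass 15 Hz, linear detrend, decimate.

    Decimation keeps every ``fs/fs_out``-th sample after filtering (the 15 Hz
    low-pass already prevents aliasing at 100 Hz).  Lengths not a multiple of
    the factor are truncated (logged at debug level).
    """
    x = np.asarray(plate_raw, dtype=float)
    factor = int(round(fs / fs_out))
    y = butterworth_zero_phase(x, order=2, fc=15.0, fs=fs)
    y = sps.detrend(y, type="linear")
    if y.size % factor:
        log.debug("kinetic series length %d not a multiple of %d; truncating",
                    y.size, factor)
        y = y[: y.size - (y.size % factor)]
    return y[::factor]


def emg_envelope(emg_raw, fs: float = 1000.0, window: float = 0.05,
                 fs_out: float = 100.0) -> np.ndarray:
    """sEMG RMS envelope: zero-phase 30-450 Hz band-pass, centred moving RMS, decimate."""
    x = np.asarray(emg_raw, dtype=float)
    if not 0 < window <= 0.2:
        raise ValueError("RMS window must be in (0, 0.2] s")
    wlen = int(round(window * fs))
    if wlen < 2:
        raise ValueError("RMS window shorter than 2 samples")
    hi = min(450.0, 0.499 * fs)
    y = butterworth_zero_phase(x, order=2, fc=(30.0, hi), fs=fs, btype="bandpass")
    kernel = np.ones(wlen) / wlen
    ms = np.convolve(y**2, kernel, mode="same")
    rms = np.sqrt(np.maximum(ms, 0.0))
    factor = int(round(fs / fs_out))
    return rms[::factor]


def extract_epoch(trial: TrialRecord, onset: float | None = None, *,
                  rms_window: float = 0.05) -> CleanEpoch:
    """Full cleaning chain, cropped to the 1 s / 100-sample epoch from onset.

    theta is filtered at 10 Hz; tau_c comes from inverse dynamics on the
    cleaned plate channels and filtered kinematics; GA/TA are RMS envelopes.
    """
    if onset is None:
        onset = trial.onset
    fs_kin, fs_plate = trial.fs_kin, trial.fs_plate
    need = onset + EPOCH_SAMPLES / EPOCH_FS
    if trial.kin_time[-1] + 1e-9 < need - 1.0 / EPOCH_FS or onset < trial.kin_time[0]:
        raise ValueError(f"trial does not cover the epoch [{onset}, {need}] s")

    theta_f = clean_kinematics(trial.theta, fs=fs_kin)
    d_f = clean_kinematics(trial.d, fs=fs_kin)

    cop = clean_kinetics(trial.cop_x, fs=fs_plate, fs_out=EPOCH_FS)
    fx = clean_kinetics(trial.force_x, fs=fs_plate, fs_out=EPOCH_FS)
    # vertical force: filter + decimate but keep the static (body-weight) level,
    # which linear detrending would remove and the torque arm needs
    fz = butterworth_zero_phase(trial.force_z, order=2, fc=15.0, fs=fs_plate)
    fz = fz[:: int(round(fs_plate / EPOCH_FS))]

    n = min(theta_f.size, cop.size, fx.size, fz.size)
    t = trial.kin_time[:n]
    motion = MotionSeries(time=t, theta=theta_f[:n], d=d_f[:n])
    grf = GroundReaction(time=t, cop_x=cop[:n], force_x=fx[:n],
                         force_z=np.maximum(fz[:n], 0.0))
    torques: TorqueSeries = inverse_dynamics(motion, grf, trial.params,
                                             h_ankle=trial.h_ankle)

    ga = emg_envelope(trial.emg_ga, fs=fs_plate, window=rms_window, fs_out=EPOCH_FS)
    ta = emg_envelope(trial.emg_ta, fs=fs_plate, window=rms_window, fs_out=EPOCH_FS)

    i0 = int(round((onset - t[0]) * EPOCH_FS))
    i1 = i0 + EPOCH_SAMPLES
    if i0 < 0 or i1 > n or i1 > ga.size:
        raise ValueError("insufficient post-onset data for a full 100-sample epoch")

    return CleanEpoch(
        tau_c=torques.tau_c[i0:i1], theta=theta_f[i0:i1],
        ga_rms=ga[i0:i1], ta_rms=ta[i0:i1],
        onset_time=onset, subject=trial.subject, condition=trial.condition,
    )


def auc_ratio(ga_rms, ta_rms, dt: float = 1.0 / EPOCH_FS) -> float:
    """Ratio of GA to TA envelope area under the curve (trapezoidal)."""
    ga = np.asarray(ga_rms, dtype=float)
    ta = np.asarray(ta_rms, dtype=float)
    if ga.size != ta.size:
        raise ValueError("envelope length mismatch")
    denom = np.trapezoid(ta, dx=dt)
    if denom == 0:
        raise ValueError("TA area under the curve is zero; ratio undefined")
    return float(np.trapezoid(ga, dx=dt) / denom)
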