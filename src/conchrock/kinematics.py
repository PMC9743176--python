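"""Rocking kinematics from two-point 3D tracking.

A model released under water rocks about its center of buoyancy.  Two tracked
markers placed on the vertical body axis give, per video frame, an upper and a
lower 3D point; the signed angle of the body axis from vertical is recovered
even when the rocking plane precesses (yaw) because the correction

    theta = arccot( dz / sqrt(dx^2 + dy^2) ) * sign(dx)

uses the full horizontal offset, not just its in-camera-plane component.
Positive angles mean the aperture is tilted up from its equilibrium
orientation.  The angle trace is then fit with an underdamped harmonic
oscillation

    theta_d(t) = theta_0 * exp(-gamma t) * cos(omega t)

whose damping coefficient ``gamma`` (1/s) and angular frequency ``omega``
(rad/s) summarise hydrodynamic restoration.  Angles are carried in degrees
throughout; ``omega`` is in rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TrackedTrajectory",
    "AngleSeries",
    "OscillationFit",
    "InsufficientDataError",
    "DegenerateFitError",
    "FitConvergenceError",
    "corrected_angle",
    "angle_series",
    "fit_oscillation",
    "fit_oscillation_pooled",
    "angular_velocity",
    "time_below_threshold",
    "read_trajectory",
    "write_trajectory",
]


class InsufficientDataError(ValueError):
    """Too few valid frames to proceed."""


class DegenerateFitError(ValueError):
    """The series carries no oscillation signal to fit."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class TrackedTrajectory:
    """Time-stamped upper/lower marker positions (cm) from calibrated tracking.

    Frames with a missing marker are kept (as NaN) and flagged, never
    silently dropped.  If ``times`` is None it is derived from the frame
    index and ``frame_rate``.
    """

    times: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    frame_rate: float | None = None
    point_distance: float | None = None
    release_direction: str | None = None  # "aperture_forward" | "aperture_backward"

    def __post_init__(self):
        u = np.asarray(self.upper, dtype=float).reshape(-1, 3)
        low = np.asarray(self.lower, dtype=float).reshape(-1, 3)
        if self.times is None:
            if not self.frame_rate:
                raise ValueError("need explicit times or a frame_rate")
            t = np.arange(len(u), dtype=float) / self.frame_rate
        else:
            t = np.asarray(self.times, dtype=float)
        if not (len(t) == len(u) == len(low)):
            raise ValueError("times, upper and lower must have equal length")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "upper", u)
        object.__setattr__(self, "lower", low)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.upper).all(axis=1) & np.isfinite(self.lower).all(axis=1)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class AngleSeries:
    """Signed angle from equilibrium (degrees) per frame, with quality flags."""

    times: np.ndarray
    angle: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "angle", np.asarray(self.angle, dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))

    def valid_samples(self) -> tuple[np.ndarray, np.ndarray]:
        return self.times[self.valid], self.angle[self.valid]


@dataclass(frozen=True)
class OscillationFit:
    """Underdamped-oscillation parameters with asymptotic 95% intervals.

    ``theta0`` is in degrees, ``damping`` (gamma) in 1/s, and
    ``angular_frequency`` (omega) in rad/s; ``ci95`` maps each parameter name
    to its (low, high) bounds.  ``natural_frequency`` is the undamped
    sqrt(omega^2 + gamma^2), relevant when comparing fitted frequencies with
    drag-free pendulum periods.
    """

    theta0: float
    damping: float
    angular_frequency: float
    ci95: dict = field(default_factory=dict)
    residual_rms: float = float("nan")
    n_samples: int = 0
    phase: float = 0.0

    @property
    def natural_frequency(self) -> float:
        return math.hypot(self.angular_frequency, self.damping)

    @property
    def damped_period(self) -> float:
        return 2.0 * math.pi / self.angular_frequency if self.angular_frequency > 0 else math.inf

    @property
    def natural_period(self) -> float:
        w0 = self.natural_frequency
        return 2.0 * math.pi / w0 if w0 > 0 else math.inf

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.theta0 * np.exp(-self.damping * t) * np.cos(self.angular_frequency * t + self.phase)


def corrected_angle(upper, lower) -> float:
    """Signed angle (degrees) of the marker axis from vertical.

    The magnitude is ``arccot(dz / hypot(dx, dy))``; the sign follows the sign
    of ``dx`` (the aperture-facing horizontal direction), so positive angles
    are apertures tilted up.  When ``dx == 0`` exactly the sign factor is
    undefined; this scalar form returns the non-negative magnitude (0 for a
    vertical axis) — :func:`angle_series` resolves the sign by continuity.
    """
    du = np.asarray(upper, dtype=float) - np.asarray(lower, dtype=float)
    dx, dy, dz = du
    rho = math.hypot(dx, dy)
    if rho == 0.0 and dz == 0.0:
        raise ValueError("coincident tracking points: angle undefined")
    magnitude = math.degrees(math.atan2(rho, dz))  # arccot(dz/rho) in [0, 180]
    if dx > 0:
        return magnitude
    if dx < 0:
        return -magnitude
    return magnitude  # dx == 0: vertical (0 deg) or sign left to context


def angle_series(trajectory: TrackedTrajectory, min_valid: int = 4) -> AngleSeries:
    """Per-frame corrected angles for a trajectory.

    Frames with a missing marker are propagated as NaN gaps.  A frame with
    exactly zero ``dx`` takes its sign from the previous valid frame
    (continuity of the rocking trace); a perfectly vertical axis is 0.
    """
    valid = trajectory.valid_mask
    if valid.sum() < min_valid:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid frames; need at least {min_valid}"
        )
    n = len(trajectory)
    angles = np.full(n, np.nan)
    prev_sign = 1.0
    for i in range(n):
        if not valid[i]:
            continue
        du = trajectory.upper[i] - trajectory.lower[i]
        dx, dy, dz = du
        rho = math.hypot(dx, dy)
        if rho == 0.0 and dz == 0.0:
            valid = valid.copy()
            valid[i] = False
            continue
        magnitude = math.degrees(math.atan2(rho, dz))
        if dx > 0:
            sign = 1.0
        elif dx < 0:
            sign = -1.0
        elif rho == 0.0:
            sign, magnitude = 1.0, 0.0
        else:
            sign = prev_sign
        prev_sign = sign
        angles[i] = sign * magnitude
    return AngleSeries(times=trajectory.times, angle=angles, valid=valid)


def _model(t, theta0, gamma, omega, phase=0.0):
    return theta0 * np.exp(-gamma * t) * np.cos(omega * t + phase)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting point: first-sample amplitude, spectral omega,
    log-envelope gamma."""
    theta0 = float(y[0]) if y[0] != 0 else float(np.max(np.abs(y)))
    # near-uniform resampling for the spectrum (gaps filled only for the guess)
    dt = float(np.median(np.diff(t)))
    tu = np.arange(t[0], t[-1] + 0.5 * dt, dt)
    yu = np.interp(tu, t, y)
    yu = yu - yu.mean()
    spec = np.abs(np.fft.rfft(yu))
    freqs = np.fft.rfftfreq(len(yu), d=dt)
    k = int(np.argmax(spec[1:]) + 1) if len(spec) > 1 else 0
    omega = 2.0 * math.pi * float(freqs[k]) if k else 1.0
    # envelope decay from |local maxima| of the absolute trace
    mags = np.abs(yu)
    peaks = [i for i in range(1, len(mags) - 1) if mags[i] >= mags[i - 1] and mags[i] >= mags[i + 1] and mags[i] > 0]
    if len(peaks) >= 2:
        slope = np.polyfit(tu[peaks], np.log(mags[peaks]), 1)[0]
        gamma = max(-float(slope), 0.0)
    else:
        gamma = 0.0
    return theta0, gamma, max(omega, 1e-6)


def fit_oscillation(series: AngleSeries, initial_guess=None, fit_phase: bool = False,
                    confidence: float = 0.95) -> OscillationFit:
    """Nonlinear least-squares fit of the underdamped oscillation model.

    Deterministic given the data and starting point: the default guess takes
    ``theta0`` from the first sample, ``omega`` from the dominant nonzero
    spectral peak, and ``gamma`` from a log-linear fit to the peak envelope.
    A phase term is available (``fit_phase=True``) but off by default, since
    the printed model releases at ``t = 0`` with zero angular velocity.

    Confidence intervals are asymptotic (t-based, from the Jacobian at the
    optimum).
    """
    t, y = series.valid_samples()
    if len(t) < 10:
        raise InsufficientDataError(f"need >= 10 valid samples, got {len(t)}")
    if np.max(np.abs(y)) < 1e-9:
        raise DegenerateFitError("series is identically zero; gamma and omega unidentifiable")
    t = t - t[0]  # model clock starts at the first valid sample
    if initial_guess is None:
        initial_guess = _initial_guess(t, y)
    theta0_0, gamma_0, omega_0 = initial_guess
    if (t[-1] - t[0]) * omega_0 < 2.0 * math.pi:
        # spectral guess may still be usable; require at least one period of data
        raise InsufficientDataError("series spans less than one oscillation period")

    names = ["theta0", "damping", "angular_frequency"]
    x0 = [theta0_0, max(gamma_0, 0.0), max(omega_0, 1e-6)]
    lo, hi = [-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]
    if fit_phase:
        names.append("phase")
        x0.append(0.0)
        lo.append(-math.pi)
        hi.append(math.pi)

    def residuals(p):
        return _model(t, *p) - y

    res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise FitConvergenceError(f"fit did not converge: {res.message}", best_params=res.x)

    n, p = len(t), len(res.x)
    dof = max(n - p, 1)
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    s2 = float(res.fun @ res.fun) / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    ci = {name: (float(v - tcrit * e), float(v + tcrit * e))
          for name, v, e in zip(names, res.x, se)}
    return OscillationFit(
        theta0=float(res.x[0]),
        damping=float(res.x[1]),
        angular_frequency=float(res.x[2]),
        phase=float(res.x[3]) if fit_phase else 0.0,
        ci95=ci,
        residual_rms=rms,
        n_samples=n,
    )


def fit_oscillation_pooled(series_list, confidence: float = 0.95) -> OscillationFit:
    """Joint fit across trials with shared (gamma, omega) and per-trial theta0.

    Pools repeated releases of the same model so damping and frequency are
    estimated from all trials at once; the reported ``theta0`` is the mean of
    the per-trial release amplitudes (magnitudes).
    """
    data = []
    for s in series_list:
        t, y = s.valid_samples()
        if len(t) < 10:
            raise InsufficientDataError("each pooled series needs >= 10 valid samples")
        data.append((t - t[0], y))
    if not data:
        raise InsufficientDataError("no series to pool")
    k = len(data)
    guesses = [_initial_guess(t, y) for t, y in data]
    x0 = [g[0] for g in guesses] + [float(np.mean([g[1] for g in guesses])),
                                    float(np.mean([g[2] for g in guesses]))]
    lo = [-np.inf] * k + [0.0, 1e-9]
    hi = [np.inf] * (k + 2)

    def residuals(p):
        gamma, omega = p[k], p[k + 1]
        return np.concatenate([_model(t, p[i], gamma, omega) - y
                               for i, (t, y) in enumerate(data)])

    res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise FitConvergenceError(f"pooled fit did not converge: {res.message}", best_params=res.x)
    n = sum(len(t) for t, _ in data)
    dof = max(n - len(res.x), 1)
    s2 = float(res.fun @ res.fun) / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(res.x), np.nan)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    gamma, omega = float(res.x[k]), float(res.x[k + 1])
    ci = {
        "damping": (gamma - tcrit * se[k], gamma + tcrit * se[k]),
        "angular_frequency": (omega - tcrit * se[k + 1], omega + tcrit * se[k + 1]),
    }
    return OscillationFit(
        theta0=float(np.mean(np.abs(res.x[:k]))),
        damping=gamma,
        angular_frequency=omega,
        ci95=ci,
        residual_rms=float(np.sqrt(np.mean(res.fun ** 2))),
        n_samples=n,
    )


def angular_velocity(fit: OscillationFit, times) -> np.ndarray:
    """Closed-form time derivative of the fitted oscillation, deg/s."""
    t = np.asarray(times, dtype=float)
    g, w, ph = fit.damping, fit.angular_frequency, fit.phase
    return fit.theta0 * np.exp(-g * t) * (-g * np.cos(w * t + ph) - w * np.sin(w * t + ph))


def time_below_threshold(fit: OscillationFit, threshold: float) -> float:
    """Time (s) for the decay envelope |theta0| exp(-gamma t) to reach ``threshold`` degrees.

    Returns 0 when the threshold is at or above the release amplitude and
    +inf for an undamped fit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    amp = abs(fit.theta0)
    if threshold >= amp:
        return 0.0
    if fit.damping == 0:
        return math.inf
    return math.log(amp / threshold) / fit.damping


# ---------------------------------------------------------------------------
# File interface

_TRAJ_COLUMNS = ["xu", "yu", "zu", "xl", "yl", "zl"]


def read_trajectory(path, fps: float | None = None, point_distance: float | None = None,
                    release_direction: str | None = None) -> TrackedTrajectory:
    """Read a trajectory CSV: ``frame,t_s,xu,yu,zu,xl,yl,zl``.

    ``t_s`` may be omitted if ``fps`` is given; missing markers are empty
    fields (become NaN-flagged frames).
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")
    if "t_s" in df.columns:
        times = df["t_s"].to_numpy(float)
    elif fps:
        frame = df["frame"].to_numpy(float) if "frame" in df.columns else np.arange(len(df), dtype=float)
        times = frame / fps
    else:
        raise ValueError("trajectory has no t_s column and no fps was given")
    return TrackedTrajectory(
        times=times,
        upper=df[["xu", "yu", "zu"]].to_numpy(float),
        lower=df[["xl", "yl", "zl"]].to_numpy(float),
        frame_rate=fps,
        point_distance=point_distance,
        release_direction=release_direction,
    )


def write_trajectory(trajectory: TrackedTrajectory, path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(trajectory)),
        "t_s": trajectory.times,
        "xu": trajectory.upper[:, 0], "yu": trajectory.upper[:, 1], "zu": trajectory.upper[:, 2],
        "xl": trajectory.lower[:, 0], "yl": trajectory.lower[:, 1], "zl": trajectory.lower[:, 2],
    })
    df.to_csv(path, index=False)
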