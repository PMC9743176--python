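"""Forward simulator of buoyancy-restored rocking.

A neutrally buoyant model tilted by ``theta_0`` and released behaves as a
physical pendulum pivoting about its center of buoyancy: the buoyancy-weight
couple across the center separation ``S_t * V_wd^(1/3)`` supplies the
restoring moment, and viscous rotational drag removes energy,

    I * theta'' = -m_wd * g * S_t * V_wd^(1/3) * sin(theta) - c * theta'

Linearised about vertical this is the underdamped oscillator with
``gamma = c / (2 I)`` and ``omega = sqrt(omega_0^2 - gamma^2)`` where
``omega_0^2 = m_wd g S_t V_wd^(1/3) / I`` — exactly the model the kinematics
fit estimates.  The observation model emulates calibrated two-camera
tracking: two markers on the body axis sampled at the camera frame rate, with
slow out-of-plane yaw precession, lateral current drift, vertical buoyancy
drift, and Gaussian coordinate noise.  The disturbances are kinematic
overlays (not dynamically coupled); they exist to stress the angle
correction, mirroring the chaotic pool conditions of real releases.

All quantities are cgs (g, cm, s); angles in the public interface are
degrees.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, asdict, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .kinematics import TrackedTrajectory, write_trajectory

__all__ = [
    "SimConfig",
    "MORPHOTYPE_PROFILES",
    "default_inertia",
    "vacuum_period",
    "simulate_rocking",
    "simulate_profile_trials",
    "make_fixture_suite",
    "mechanical_energy",
]

GRAVITY_CGS = 980.665  # standard gravity, cm/s^2
DEFAULT_FRAME_RATE = 23.975  # GoPro "24 fps" actual rate, Hz


def default_inertia(displaced_mass: float, displaced_volume: float) -> float:
    """Reference moment of inertia: thin spherical shell of the displaced volume.

    A conch concentrates mass toward its external envelope, so (2/3) m r^2
    with r the volume-equivalent sphere radius is a physically reasonable
    scale; morphotype profiles multiply it by a shape factor (compressed
    shapes put mass farther from the pitch axis).
    """
    r = (3.0 * displaced_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return (2.0 / 3.0) * displaced_mass * r * r


@dataclass(frozen=True)
class SimConfig:
    """Physical and observational parameters of one simulated release.

    Defaults describe the experimental setting the package targets: a ~985
    cm^3 neutrally buoyant model released at 55 degrees and filmed at 23.975
    frames/s, with millimetre-scale tracking noise (a few pixels of a 4k
    reconstruction) and slow drift/precession disturbances.
    """

    displaced_mass: float = 985.0  # g
    displaced_volume: float = 985.0  # cm^3
    stability_index: float = 0.015
    inertia: float | None = None  # g cm^2 about the pitch axis through the pivot
    rotational_drag: float | None = None  # g cm^2 / s; default gives gamma = 0.2 1/s
    release_angle: float = 55.0  # degrees
    gravity: float = GRAVITY_CGS
    frame_rate: float = DEFAULT_FRAME_RATE
    duration: float = 12.0  # s
    noise_sd: float = 0.15  # cm per marker coordinate
    precession_rate: float = 2.0  # deg/s yaw of the rocking plane
    current_drift: float = 0.5  # cm/s lateral translation
    buoyancy_drift: float = 0.1  # cm/s vertical translation
    marker_distance: float = 12.0  # cm between tracking points
    seed: int = 0

    def __post_init__(self):
        if self.displaced_mass <= 0 or self.displaced_volume <= 0:
            raise ValueError("displaced mass and volume must be > 0")
        if not (0.0 < abs(self.release_angle) < 90.0):
            raise ValueError("release_angle must be in (0, 90) degrees in magnitude")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.inertia is None:
            object.__setattr__(self, "inertia", default_inertia(self.displaced_mass, self.displaced_volume))
        if self.inertia <= 0:
            raise ValueError("inertia must be > 0")
        if self.rotational_drag is None:
            object.__setattr__(self, "rotational_drag", 0.4 * self.inertia)  # gamma = 0.2 1/s
        if self.rotational_drag < 0:
            raise ValueError("rotational_drag must be >= 0")

    # -- linearised ground truth -------------------------------------------
    @property
    def restoring_coefficient(self) -> float:
        """m_wd * g * S_t * V_wd^(1/3): restoring torque per sin(theta), g cm^2/s^2."""
        return (self.displaced_mass * self.gravity * self.stability_index
                * self.displaced_volume ** (1.0 / 3.0))

    @property
    def gamma_linear(self) -> float:
        return self.rotational_drag / (2.0 * self.inertia)

    @property
    def omega_natural(self) -> float:
        return math.sqrt(self.restoring_coefficient / self.inertia)

    @property
    def omega_linear(self) -> float:
        w0, g = self.omega_natural, self.gamma_linear
        if g >= w0:
            return 0.0  # overdamped: no oscillation
        return math.sqrt(w0 * w0 - g * g)

    def truth(self) -> dict:
        return {
            "gamma": self.gamma_linear,
            "omega": self.omega_linear,
            "omega_natural": self.omega_natural,
            "vacuum_period": vacuum_period(self.inertia, self.displaced_mass,
                                           self.stability_index, self.displaced_volume,
                                           self.gravity),
            "release_angle": self.release_angle,
        }


def vacuum_period(inertia: float, displaced_mass: float, stability_index: float,
                  displaced_volume: float, gravity: float = GRAVITY_CGS) -> float:
    """Small-angle physical-pendulum period with hydrodynamic drag ignored.

    ``T = 2 pi sqrt( I / (m_wd g S_t V_wd^(1/3)) )``; the restoring moment is
    the buoyancy-weight couple across the center separation.  Zero stability
    gives an infinite period (no preferred orientation).
    """
    if inertia <= 0 or displaced_mass <= 0 or displaced_volume <= 0 or gravity <= 0:
        raise ValueError("inertia, mass, volume and gravity must be > 0")
    if stability_index < 0:
        raise ValueError("stability_index must be >= 0")
    if stability_index == 0:
        return math.inf
    restoring = displaced_mass * gravity * stability_index * displaced_volume ** (1.0 / 3.0)
    return 2.0 * math.pi * math.sqrt(inertia / restoring)


def _integrate_pendulum(config: SimConfig, times: np.ndarray) -> np.ndarray:
    """Pendulum angle (rad) at the requested sample times via dense output."""
    k = config.restoring_coefficient
    c = config.rotational_drag
    inertia = config.inertia

    def rhs(_t, y):
        theta, omega = y
        return (omega, (-k * math.sin(theta) - c * omega) / inertia)

    theta0 = math.radians(config.release_angle)
    sol = solve_ivp(rhs, (0.0, float(times[-1]) + 1e-12), [theta0, 0.0],
                    method="DOP853", dense_output=True, rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"pendulum integration failed: {sol.message}")
    return sol.sol(times)[0]


def simulate_rocking(config: SimConfig, rng: np.random.Generator | None = None
                     ) -> tuple[TrackedTrajectory, dict]:
    """Simulate one release and observe it through the camera model.

    Returns the tracked trajectory and a ground-truth record holding the
    linearised (gamma, omega), the natural frequency, the drag-free period,
    and the noiseless pitch series.  Deterministic given ``config.seed`` (or
    an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_frames = int(math.floor(config.duration * config.frame_rate)) + 1
    times = np.arange(n_frames) / config.frame_rate
    theta = _integrate_pendulum(config, times)

    psi = np.radians(config.precession_rate) * times  # yaw of the rocking plane
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    axis = np.column_stack([sin_t * np.cos(psi), sin_t * np.sin(psi), cos_t])
    drift = np.column_stack([config.current_drift * times,
                             np.zeros_like(times),
                             config.buoyancy_drift * times])
    half = 0.5 * config.marker_distance
    upper = drift + half * axis
    lower = drift - half * axis
    if config.noise_sd > 0:
        upper = upper + rng.normal(0.0, config.noise_sd, upper.shape)
        lower = lower + rng.normal(0.0, config.noise_sd, lower.shape)

    traj = TrackedTrajectory(
        times=times, upper=upper, lower=lower,
        frame_rate=config.frame_rate,
        point_distance=config.marker_distance,
        release_direction="aperture_forward" if config.release_angle >= 0 else "aperture_backward",
    )
    truth = config.truth()
    truth["theta_deg"] = np.degrees(theta)
    return traj, truth


def mechanical_energy(config: SimConfig, theta_rad, omega_rad_s) -> np.ndarray:
    """Kinetic plus potential energy of the pendulum state, erg."""
    theta = np.asarray(theta_rad, float)
    om = np.asarray(omega_rad_s, float)
    return 0.5 * config.inertia * om ** 2 + config.restoring_coefficient * (1.0 - np.cos(theta))


# ---------------------------------------------------------------------------
# Morphotype fixture suite

#: (stability index, inertia shape factor, rotational drag as a multiple of I).
#: Stability indices are the four examined morphotypes'; inertia factors put
#: more mass far from the pitch axis for compressed shapes; drag factors give
#: stronger effective damping for the stable, faster-oscillating pair, the
#: linear-drag equivalent of velocity-dependent hydrodynamic losses.
MORPHOTYPE_PROFILES: dict[str, tuple[float, float, float]] = {
    "nautilus": (0.043, 1.00, 0.80),
    "oxycone": (0.068, 1.25, 0.70),
    "serpenticone": (0.015, 1.10, 0.36),
    "sphaerocone": (0.006, 0.90, 0.40),
}


def profile_config(label: str, stability_index: float, inertia_factor: float,
                   drag_factor: float, **overrides) -> SimConfig:
    """SimConfig for one morphotype profile at the shared model volume."""
    base_mass = overrides.pop("displaced_mass", 985.0)
    base_vol = overrides.pop("displaced_volume", 985.0)
    inertia = inertia_factor * default_inertia(base_mass, base_vol)
    return SimConfig(
        displaced_mass=base_mass,
        displaced_volume=base_vol,
        stability_index=stability_index,
        inertia=inertia,
        rotational_drag=drag_factor * inertia,
        **overrides,
    )


def simulate_profile_trials(config: SimConfig, trials: int = 15, seed: int = 0,
                            alternate_release: bool = True):
    """Simulate repeated releases with per-trial deterministic substreams.

    Release direction alternates between trials (sign of the release angle)
    as in the experiments; returns ``[(TrackedTrajectory, truth), ...]``.
    """
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(trials)):
        angle = config.release_angle
        if alternate_release and i % 2 == 1:
            angle = -angle
        cfg = replace(config, release_angle=angle)
        out.append(simulate_rocking(cfg, rng=np.random.default_rng(child)))
    return out


def make_fixture_suite(out_dir, profiles=None, trials: int = 15, seed: int = 0,
                       **config_overrides) -> dict:
    """Write trajectory CSV fixtures plus a ground-truth JSON for each profile.

    ``profiles`` maps label -> (stability_index, inertia_factor, drag_factor);
    defaults to the four examined morphotypes at the shared ~985 cm^3 volume.
    Returns the truth record (also written to ``truth.json``).
    """
    if profiles is None:
        profiles = MORPHOTYPE_PROFILES
    labels = list(profiles)
    if len(set(labels)) != len(labels):
        raise ValueError("profile labels must be unique")
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_all: dict = {}
    for p_idx, (label, (st, inertia_f, drag_f)) in enumerate(profiles.items()):
        cfg = profile_config(label, st, inertia_f, drag_f, **config_overrides)
        trials_out = simulate_profile_trials(cfg, trials=trials, seed=seed + 7919 * p_idx)
        records = []
        for i, (traj, truth) in enumerate(trials_out):
            fname = f"{label}_trial{i:02d}.csv"
            write_trajectory(traj, out_dir / fname)
            records.append({
                "file": fname,
                "release_direction": traj.release_direction,
                "gamma": truth["gamma"],
                "omega": truth["omega"],
                "release_angle": truth["release_angle"],
            })
        truth_all[label] = {
            "stability_index": st,
            "inertia": cfg.inertia,
            "rotational_drag": cfg.rotational_drag,
            "gamma": cfg.gamma_linear,
            "omega": cfg.omega_linear,
            "vacuum_period": vacuum_period(cfg.inertia, cfg.displaced_mass, st, cfg.displaced_volume),
            "trials": records,
        }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_all, fh, indent=2)
    return truth_all


def read_sim_config(path) -> SimConfig:
    """Read a SimConfig from YAML (keys mirror the dataclass fields)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(cfg) - valid
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**cfg)


def sim_config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
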