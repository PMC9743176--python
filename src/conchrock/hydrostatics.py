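"""Hydrostatic design calculations for neutrally buoyant counterweighted models.

A physical replica of a shelled cephalopod is assembled from components of
distinct materials (thermoplastic body, brass and gallium counterweights,
screw, bearing, rubber valve, chamber liquid).  Neutral buoyancy requires the
total mass to equal the mass of displaced water; the hydrostatic stability
index

    S_t = |B - M| / V_wd^(1/3)

measures the separation between the center of buoyancy ``B`` (centroid of the
displaced volume) and the total center of mass ``M``, normalised by the cube
root of the displaced volume ``V_wd``.  A threaded counterweight of mass
``m_bc`` translated along the vertical axis shifts ``M`` by a magnified lever
ratio ``m_wd / m_bc``, which lets sub-millimetre center separations be imparted
mechanically.

All quantities are cgs internally (grams, centimetres, seconds); screw thread
pitch is accepted in mm per revolution and converted.  The coordinate frame is
right-handed with ``z`` up and, by convention, its origin at the center of
buoyancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ComponentSpec",
    "HydrostaticModel",
    "StabilityResult",
    "CounterweightPlan",
    "InfeasibleDesignError",
    "combined_center_of_mass",
    "stability_index",
    "center_separation",
    "neutral_petg_mass",
    "target_petg_center",
    "counterweight_travel",
    "screw_turns",
    "design_counterweight",
    "read_components",
    "read_model_config",
]

MM_PER_CM = 10.0


class InfeasibleDesignError(ValueError):
    """Raised when a requested design cannot be physically realised."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ComponentSpec:
    """One material body of the physical model.

    Parameters
    ----------
    name : str
        Component label (e.g. ``"brass_counterweight"``).
    mass : float
        Mass in grams; must be positive.
    center : array-like of 3 floats
        Local center of mass in cm, model frame.
    volume : float, optional
        Component volume in cm^3.
    density : float, optional
        Material density in g/cm^3.  If both volume and density are given
        they must be consistent with the mass.
    """

    name: str
    mass: float
    center: tuple[float, float, float]
    volume: float | None = None
    density: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.mass) or self.mass <= 0:
            raise ValueError(f"component {self.name!r}: mass must be > 0, got {self.mass}")
        object.__setattr__(self, "center", tuple(_as_point(self.center)))
        if self.volume is not None and self.density is not None:
            if abs(self.mass - self.volume * self.density) / self.mass >= 1e-6:
                raise ValueError(
                    f"component {self.name!r}: mass {self.mass} g inconsistent with "
                    f"volume*density = {self.volume * self.density} g"
                )

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class HydrostaticModel:
    """A component assembly plus the external envelope it displaces."""

    components: tuple[ComponentSpec, ...]
    displaced_volume: float
    buoyancy_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    water_density: float = 1.000

    def __post_init__(self):
        if len(self.components) == 0:
            raise ValueError("model needs at least one component")
        if self.displaced_volume <= 0:
            raise ValueError("displaced_volume must be > 0")
        if self.water_density <= 0:
            raise ValueError("water_density must be > 0")
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "buoyancy_center", tuple(_as_point(self.buoyancy_center)))

    @property
    def displaced_mass(self) -> float:
        """Mass of water displaced by the envelope, in grams."""
        return self.water_density * self.displaced_volume

    def stability(self) -> "StabilityResult":
        center, total = combined_center_of_mass(list(self.components))
        return stability_index(self.buoyancy_center, center, self.displaced_volume, total_mass=total)


@dataclass(frozen=True)
class StabilityResult:
    """Hydrostatic centers, their separation, and the stability index."""

    mass_center: tuple[float, float, float]
    buoyancy_center: tuple[float, float, float]
    separation: float
    stability_index: float
    displaced_volume: float
    total_mass: float


@dataclass(frozen=True)
class CounterweightPlan:
    """Design outputs for the adjustable-counterweight mechanism."""

    counterweight_mass: float
    thread_pitch: float  # mm / revolution
    travel: float  # cm
    revolutions: float
    petg_mass: float | None = None
    petg_center: tuple[float, float, float] | None = None
    stability_index: float | None = None
    feasible: bool = True
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = {
            "counterweight_mass_g": self.counterweight_mass,
            "thread_pitch_mm_per_rev": self.thread_pitch,
            "travel_cm": self.travel,
            "revolutions": self.revolutions,
            "stability_index": self.stability_index,
            "feasible": self.feasible,
        }
        if self.petg_mass is not None:
            d["petg_mass_g"] = self.petg_mass
        if self.petg_center is not None:
            d["petg_center_cm"] = list(self.petg_center)
        if self.notes:
            d["notes"] = list(self.notes)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def combined_center_of_mass(components) -> tuple[np.ndarray, float]:
    """Mass-weighted mean of component centers.

    Applied independently in x, y and z.  Returns ``(center, total_mass)``.
    """
    comps = list(components)
    if not comps:
        raise ValueError("need at least one component")
    masses = np.array([c.mass for c in comps], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("all component masses must be > 0")
    centers = np.array([c.center_array for c in comps], dtype=float)
    total = float(masses.sum())
    return (masses[:, None] * centers).sum(axis=0) / total, total


def stability_index(buoyancy_center, mass_center, displaced_volume: float,
                    total_mass: float = float("nan")) -> StabilityResult:
    """Stability index S_t = |B - M| / V_wd^(1/3).

    The numerator is the 3D Euclidean distance between the center of buoyancy
    ``B`` and the center of mass ``M``; the cube root of the displaced volume
    makes the index dimensionless and size-independent.
    """
    if displaced_volume <= 0:
        raise ValueError("displaced_volume must be > 0")
    b = _as_point(buoyancy_center)
    m = _as_point(mass_center)
    sep = float(np.linalg.norm(b - m))
    return StabilityResult(
        mass_center=tuple(m),
        buoyancy_center=tuple(b),
        separation=sep,
        stability_index=sep / displaced_volume ** (1.0 / 3.0),
        displaced_volume=float(displaced_volume),
        total_mass=float(total_mass),
    )


def center_separation(stability_idx: float, displaced_volume: float) -> float:
    """Distance |B - M| in cm implied by a stability index and volume.

    Inverse of :func:`stability_index` on the separation axis:
    ``S_t * V_wd^(1/3)``.
    """
    if stability_idx < 0:
        raise ValueError("stability index must be >= 0")
    if displaced_volume <= 0:
        raise ValueError("displaced_volume must be > 0")
    return stability_idx * displaced_volume ** (1.0 / 3.0)


def neutral_petg_mass(displaced_mass: float, components) -> float:
    """Thermoplastic mass required for neutral buoyancy.

    Subtracts the masses of all other components (counterweights, screw,
    bearing, valve, chamber liquid) from the displaced-water mass so that the
    assembled model weighs exactly what it displaces.
    """
    others = float(sum(c.mass for c in components))
    petg = displaced_mass - others
    if petg < 0:
        raise InfeasibleDesignError(
            f"other components ({others} g) already exceed displaced mass "
            f"({displaced_mass} g); model cannot be neutrally buoyant"
        )
    return petg


def target_petg_center(target_total_center, components, petg_mass: float) -> np.ndarray:
    """Where the printed body's center of mass must sit.

    Moment balance per principal direction: with the non-printed components
    fixed, the printed body of mass ``m_PETG`` must carry the residual moment
    so the assembly's center of mass lands on ``target_total_center``:

        D_PETG = (M * sum(m_i) - sum(D_i * m_i)) / m_PETG

    where the sums run over all components of the assembly (printed body
    included).  Placing the printed body at the returned point and recomputing
    :func:`combined_center_of_mass` recovers the target exactly.
    """
    if petg_mass <= 0:
        raise ValueError("petg_mass must be > 0")
    target = _as_point(target_total_center)
    comps = list(components)
    masses = np.array([c.mass for c in comps], dtype=float) if comps else np.zeros(0)
    centers = (np.array([c.center_array for c in comps], dtype=float)
               if comps else np.zeros((0, 3)))
    total = masses.sum() + petg_mass
    moment_others = (masses[:, None] * centers).sum(axis=0)
    return (target * total - moment_others) / petg_mass


def counterweight_travel(displaced_mass: float, counterweight_mass: float,
                         stability_idx: float, displaced_volume: float) -> float:
    """Counterweight travel D (cm) from the zero-stability configuration.

    ``D = (m_wd / m_bc) * S_t * V_wd^(1/3)``.  The mass ratio magnifies the
    counterweight's range of motion relative to the resulting center-of-mass
    shift, so very small center separations can be imparted reliably.
    """
    if counterweight_mass <= 0:
        raise ValueError("counterweight_mass must be > 0")
    if stability_idx < 0:
        raise ValueError("stability index must be >= 0")
    return (displaced_mass / counterweight_mass) * center_separation(stability_idx, displaced_volume)


def screw_turns(displaced_mass: float, counterweight_mass: float, stability_idx: float,
                displaced_volume: float, thread_pitch: float) -> float:
    """Screw revolutions R to impart a stability index.

    ``R = D / P_t`` with the travel ``D`` converted to mm and the thread pitch
    ``P_t`` in mm per revolution.  Fractional revolutions are meaningful.
    """
    if thread_pitch <= 0:
        raise ValueError("thread_pitch must be > 0")
    d_cm = counterweight_travel(displaced_mass, counterweight_mass, stability_idx, displaced_volume)
    return d_cm * MM_PER_CM / thread_pitch


def turns_to_center_shift(revolutions: float, thread_pitch: float,
                          counterweight_mass: float, displaced_mass: float) -> float:
    """Center-of-mass displacement (cm) produced by turning the screw.

    Inverse of :func:`screw_turns`: a calibration uncertainty of ``r``
    revolutions corresponds to a center-of-mass placement uncertainty of
    ``r * P_t * m_bc / m_wd`` (in mm before conversion).
    """
    if thread_pitch <= 0:
        raise ValueError("thread_pitch must be > 0")
    if counterweight_mass <= 0 or displaced_mass <= 0:
        raise ValueError("masses must be > 0")
    travel_cm = revolutions * thread_pitch / MM_PER_CM
    return travel_cm * counterweight_mass / displaced_mass


def design_counterweight(model: HydrostaticModel, target_st: float,
                         counterweight: str | ComponentSpec = "brass_counterweight",
                         thread_pitch: float = 0.5,
                         chamber_range: float | None = None) -> CounterweightPlan:
    """Full design pass: travel, screw turns and feasibility for a target S_t.

    ``counterweight`` may be a component name present in the model or an
    explicit :class:`ComponentSpec`.  If ``chamber_range`` (cm) is given and
    the travel exceeds it, the plan is flagged infeasible (reported, never
    clamped).
    """
    if isinstance(counterweight, ComponentSpec):
        bc = counterweight
    else:
        matches = [c for c in model.components if c.name == counterweight]
        if not matches:
            raise ValueError(f"no component named {counterweight!r} in model")
        bc = matches[0]
    travel = counterweight_travel(model.displaced_mass, bc.mass, target_st, model.displaced_volume)
    revs = travel * MM_PER_CM / thread_pitch
    notes = []
    feasible = True
    if chamber_range is not None and travel > chamber_range:
        feasible = False
        notes.append(
            f"required travel {travel:.4g} cm exceeds chamber range {chamber_range:.4g} cm"
        )
    return CounterweightPlan(
        counterweight_mass=bc.mass,
        thread_pitch=thread_pitch,
        travel=travel,
        revolutions=revs,
        stability_index=target_st,
        feasible=feasible,
        notes=tuple(notes),
    )


def apply_counterweight_travel(components, counterweight_name: str, travel: float):
    """Return a new component list with the named counterweight lowered by ``travel`` cm (-z)."""
    out = []
    found = False
    for c in components:
        if c.name == counterweight_name:
            found = True
            cx, cy, cz = c.center
            c = ComponentSpec(c.name, c.mass, (cx, cy, cz - travel), c.volume, c.density)
        out.append(c)
    if not found:
        raise ValueError(f"no component named {counterweight_name!r}")
    return out


# ---------------------------------------------------------------------------
# File interfaces

_COMPONENT_COLUMNS = ["name", "mass_g", "x_cm", "y_cm", "z_cm"]


def read_components(path) -> list[ComponentSpec]:
    """Read a component table CSV.

    Expected header: ``name,mass_g,x_cm,y_cm,z_cm[,volume_cm3,density_g_cm3]``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COMPONENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"component table missing columns: {missing}")
    comps = []
    for row in df.itertuples(index=False):
        vol = getattr(row, "volume_cm3", None)
        dens = getattr(row, "density_g_cm3", None)
        comps.append(ComponentSpec(
            name=str(row.name),
            mass=float(row.mass_g),
            center=(float(row.x_cm), float(row.y_cm), float(row.z_cm)),
            volume=None if vol is None or pd.isna(vol) else float(vol),
            density=None if dens is None or pd.isna(dens) else float(dens),
        ))
    return comps


def write_components(components, path) -> None:
    rows = []
    for c in components:
        rows.append({
            "name": c.name, "mass_g": c.mass,
            "x_cm": c.center[0], "y_cm": c.center[1], "z_cm": c.center[2],
            "volume_cm3": c.volume, "density_g_cm3": c.density,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_model_config(path) -> dict:
    """Read model-level fields from YAML.

    Recognised keys: ``displaced_volume``, ``buoyancy_center``,
    ``water_density``, ``thread_pitch``, ``counterweight``, ``chamber_range``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "displaced_volume" not in cfg:
        raise ValueError("model config must define displaced_volume (cm^3)")
    cfg.setdefault("buoyancy_center", [0.0, 0.0, 0.0])
    cfg.setdefault("water_density", 1.000)
    cfg.setdefault("thread_pitch", 0.5)
    return cfg


def model_from_files(components_path, config_path) -> tuple[HydrostaticModel, dict]:
    comps = read_components(components_path)
    cfg = read_model_config(config_path)
    model = HydrostaticModel(
        components=tuple(comps),
        displaced_volume=float(cfg["displaced_volume"]),
        buoyancy_center=tuple(cfg["buoyancy_center"]),
        water_density=float(cfg["water_density"]),
    )
    return model, cfg
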