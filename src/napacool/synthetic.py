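"""Synthetic study data: morphology tables, sealed-chamber CO2 traces,
cooling experiments and storage-environment logs.

Every generator is a pure function of its parameters and a seed, and each
emulates the statistical structure of the corresponding measurement:
per-class truncated-Gaussian morphology, linear CO2 accumulation from the
respiration heat law plus sensor noise, forward-model cooling curves plus
thermocouple noise, and stationary Gaussian environment traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import heat_solver
from .calibration import CoolingExperiment
from .respiration import (
    GAS_CONSTANT,
    STANDARD_PRESSURE,
    RespirationParams,
    SealedChamberTrace,
    rate_from_heat,
    respiration_heat,
)
from .thermophysics import ThermalProperties

#: Storage basket: 52 cm x 30 cm x 30 cm.
BASKET_VOLUME = 0.52 * 0.30 * 0.30  # m^3
CABBAGES_PER_BASKET = 3

TRAIT_COLUMNS = ["length_circumference_cm", "width_circumference_cm", "weight_g"]


@dataclass(frozen=True)
class ClassSpec:
    """Per-class morphology distribution: mean, sd and hard range for the
    length circumference (cm), width circumference (cm) and weight (g)."""

    class_id: int
    length_mean: float
    length_sd: float
    length_min: float
    length_max: float
    width_mean: float
    width_sd: float
    width_min: float
    width_max: float
    weight_mean: float
    weight_sd: float
    weight_min: float
    weight_max: float

    def __post_init__(self) -> None:
        for trait in ("length", "width", "weight"):
            lo = getattr(self, f"{trait}_min")
            mu = getattr(self, f"{trait}_mean")
            hi = getattr(self, f"{trait}_max")
            sd = getattr(self, f"{trait}_sd")
            if not lo <= mu <= hi:
                raise ValueError(f"{trait}: need min <= mean <= max")
            if sd <= 0:
                raise ValueError(f"{trait}: sd must be positive")


#: Measured per-class morphology summaries (three size classes of heads).
CLASS_SPECS = {
    1: ClassSpec(1, 73.32, 3.34, 68.0, 79.0, 46.73, 2.24, 44.0, 48.0, 1503.20, 118.39, 1306.39, 1783.26),
    2: ClassSpec(2, 82.67, 1.17, 80.0, 84.0, 51.89, 2.37, 49.0, 54.0, 2132.48, 127.16, 1795.23, 2483.57),
    3: ClassSpec(3, 89.17, 2.45, 85.0, 93.0, 58.67, 2.77, 55.0, 61.0, 2826.37, 121.25, 2484.77, 3112.85),
}


@dataclass(frozen=True)
class EnvSpec:
    """Cold-room environment summary: mid-height CO2 (ppm), RH range (%)
    and per-height air velocity mean/sd pairs (m/s)."""

    co2_mid_mean: float = 921.0
    co2_mid_sd: float = 8.0
    rh_range: tuple = (59.0, 68.0)
    velocity_low: tuple = (0.45, 0.19)
    velocity_mid: tuple = (0.23, 0.11)
    velocity_high: tuple = (0.53, 0.18)

    def __post_init__(self) -> None:
        vals = [self.co2_mid_mean, self.co2_mid_sd, *self.rh_range]
        vals += [v for pair in (self.velocity_low, self.velocity_mid, self.velocity_high) for v in pair]
        if any(v < 0 for v in vals):
            raise ValueError("environment parameters must be nonnegative")


def _truncated_normal(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_morphology(
    n_per_class: int,
    specs=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw ``n_per_class`` heads per size class from truncated Gaussians.

    Returns an unlabelled record table (id + the three traits, shuffled so
    class order carries no information) and the ground-truth class labels
    aligned with it.  Traits are drawn independently within a class; the
    hard min/max bounds truncate each Gaussian.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 records per class")
    specs = list((specs or CLASS_SPECS).values()) if isinstance(specs or CLASS_SPECS, dict) else list(specs)
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for spec in specs:
        frames.append(
            pd.DataFrame(
                {
                    "length_circumference_cm": _truncated_normal(
                        spec.length_mean, spec.length_sd, spec.length_min, spec.length_max, n_per_class, rng
                    ),
                    "width_circumference_cm": _truncated_normal(
                        spec.width_mean, spec.width_sd, spec.width_min, spec.width_max, n_per_class, rng
                    ),
                    "weight_g": _truncated_normal(
                        spec.weight_mean, spec.weight_sd, spec.weight_min, spec.weight_max, n_per_class, rng
                    ),
                }
            )
        )
        labels.append(np.full(n_per_class, spec.class_id))
    df = pd.concat(frames, ignore_index=True)
    truth = np.concatenate(labels)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    truth = truth[order]
    df.insert(0, "id", [f"cc{i:04d}" for i in range(len(df))])
    return df, truth


def gen_sealed_trace(
    class_id: int,
    duration: float = 12.0,
    dt: float = 0.5,
    T_chamber: float = 5.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    baseline_ppm: float = 500.0,
    params: RespirationParams | None = None,
) -> SealedChamberTrace:
    """Sealed-basket CO2 accumulation trace for three heads of one class.

    The CO2 mole fraction rises linearly at the rate implied by inverting
    the ideal-gas relation for the respiration-heat law evaluated at the
    (constant) chamber temperature; i.i.d. Gaussian sensor noise is added
    in ppm.  Chamber volume is the standard basket; loaded mass is three
    class-mean heads.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    spec = CLASS_SPECS[class_id]
    mass = CABBAGES_PER_BASKET * spec.weight_mean / 1000.0  # kg
    q = respiration_heat(T_chamber, params)
    rate = rate_from_heat(q)  # mol CO2 / kg h
    t_kelvin = T_chamber + 273.15
    slope_ppm = rate * mass * GAS_CONSTANT * t_kelvin / (STANDARD_PRESSURE * BASKET_VOLUME) * 1e6

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    co2 = baseline_ppm + slope_ppm * times
    if noise_sd > 0:
        co2 = co2 + rng.normal(0.0, noise_sd, size=times.shape)
    return SealedChamberTrace(
        times=times,
        co2=np.clip(co2, 0.0, None),
        temperature=np.full_like(times, float(T_chamber)),
        chamber_volume=BASKET_VOLUME,
        loaded_mass=mass,
    )


def gen_cooling_experiment(
    h_true: float,
    T0: float = 20.0,
    T_inf: float = 4.1,
    positions=("top", "middle", "bottom"),
    noise_sd: float = 0.2,
    duration: float = 20.0,
    seed: int = 0,
    class_id: int = 2,
    sample_every_min: float = 10.0,
    respiration: bool = True,
    dt: float = 30.0,
    n_nodes: int = 60,
) -> CoolingExperiment:
    """Forward-model cooling curves with thermocouple noise.

    Runs the radial porous-sphere solver (respiration source on by default)
    for a head of the given class, samples the volume-average temperature
    every ``sample_every_min`` minutes at each named position, and adds
    independent Gaussian noise per position.
    """
    if h_true <= 0 or duration <= 0:
        raise ValueError("h_true and duration must be positive")
    props = ThermalProperties(class_id=class_id)
    geom = heat_solver.SphereGeometry.for_class(class_id)
    bc = heat_solver.BoundaryConditions(h=h_true, T_inf=T_inf, T0=T0)
    source = heat_solver.respiration_source(props) if respiration else None
    sample_s = sample_every_min * 60.0
    field = heat_solver.solve_transient(
        geom, props, bc, source=source, t_end=duration * 3600.0, dt=dt, n_nodes=n_nodes,
        output_every=sample_s,
    )
    sample_times = np.arange(sample_s, duration * 3600.0 + sample_s / 2, sample_s)
    base = np.interp(sample_times, field.times, field.volume_average)

    rng = np.random.default_rng(seed)
    series = {}
    for pos in positions:
        obs = base.copy()
        if noise_sd > 0:
            obs = obs + rng.normal(0.0, noise_sd, size=obs.shape)
        series[pos] = (sample_times / 3600.0, obs)
    return CoolingExperiment(positions=series, class_id=class_id, T0=T0, T_inf=T_inf)


def gen_environment_log(
    spec: EnvSpec | None = None,
    duration: float = 72.0,
    dt: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Stationary Gaussian environment traces (mid-height CO2, RH, air
    velocity at three heights) for a cold room over ``duration`` hours."""
    spec = spec or EnvSpec()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    n = len(times)
    rh_mid = 0.5 * (spec.rh_range[0] + spec.rh_range[1])
    rh_sd = (spec.rh_range[1] - spec.rh_range[0]) / 4.0  # range ~ +/- 2 sd
    return pd.DataFrame(
        {
            "time_h": times,
            "co2_mid_ppm": rng.normal(spec.co2_mid_mean, spec.co2_mid_sd, n),
            "rh_pct": np.clip(rng.normal(rh_mid, rh_sd, n), 0.0, 100.0),
            "velocity_low_ms": np.clip(rng.normal(*spec.velocity_low, n), 0.0, None),
            "velocity_mid_ms": np.clip(rng.normal(*spec.velocity_mid, n), 0.0, None),
            "velocity_high_ms": np.clip(rng.normal(*spec.velocity_high, n), 0.0, None),
        }
    )


def write_morphology_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_trace_csv(trace: SealedChamberTrace, path) -> None:
    pd.DataFrame(
        {
            "time_h": trace.times,
            "co2_ppm": trace.co2,
            "temp_C": trace.temperature,
            "rh_pct": trace.rh if trace.rh is not None else np.full_like(trace.times, np.nan),
        }
    ).to_csv(path, index=False)
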