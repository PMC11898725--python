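"""Respiration rate and respiration heat of fresh produce.

The molar respiration rate is recovered from the CO2 build-up in a sealed
basket via the ideal gas law, and the metabolic heat release is modelled by
the ASHRAE empirical power law in temperature.  The two are linked by the
glucose-oxidation stoichiometry (10.7 kJ of heat per gram of CO2 evolved),
so a heat model can be inverted into an expected CO2 accumulation rate and
vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAS_CONSTANT = 8.314  # J/(mol K)
STANDARD_PRESSURE = 101_325.0  # Pa
#: Heat released per mole of CO2 for aerobic respiration of glucose:
#: 10.7 kJ/g CO2 x 44.01 g/mol.
CO2_HEAT_OF_RESPIRATION = 10.7e3 * 44.01  # J/mol CO2


@dataclass(frozen=True)
class RespirationParams:
    """Coefficients of the empirical respiration-heat law for Chinese cabbage.

    ``Q(T) = 10.7 f / 3600 * (9 T / 5 + 32)^g`` with ``T`` in degC and ``Q``
    in W/kg.  ``literal_9t`` replaces the Fahrenheit conversion ``9T/5 + 32``
    by a literal ``9T + 32``.
    """

    f: float = 6.0803e-4
    g: float = 2.6183
    gas_constant: float = GAS_CONSTANT
    literal_9t: bool = False

    def __post_init__(self) -> None:
        if self.f <= 0 or self.g <= 0:
            raise ValueError("respiration coefficients f and g must be positive")


@dataclass
class SealedChamberTrace:
    """CO2 / temperature time series recorded inside a sealed basket.

    Attributes
    ----------
    times : array, h
    co2 : array, ppm (mole fraction x 1e6)
    temperature : array, degC
    chamber_volume : float, m^3 — free gas volume of the sealed basket
    loaded_mass : float, kg — produce mass inside
    pressure : float, Pa
    """

    times: np.ndarray
    co2: np.ndarray
    temperature: np.ndarray
    chamber_volume: float
    loaded_mass: float
    pressure: float = STANDARD_PRESSURE
    rh: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.co2):
            raise ValueError("times and co2 must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.co2 < 0):
            raise ValueError("co2 concentrations must be nonnegative")
        if self.chamber_volume <= 0 or self.loaded_mass <= 0:
            raise ValueError("chamber volume and loaded mass must be positive")


def estimate_respiration_rate(trace: SealedChamberTrace) -> float:
    """Molar respiration rate (mol CO2 / kg h) from a sealed-chamber trace.

    The CO2 slope (ppm/h) is taken from an ordinary least-squares fit of
    concentration against time — robust to sensor noise — and converted to a
    molar production rate with the ideal gas law at the trace-mean absolute
    temperature: ``R = P V dx/dt / (M R_gas T)`` with ``dx`` the mole-fraction
    change (ppm x 1e-6).
    """
    if len(trace.times) < 2:
        raise ValueError("need at least 2 samples to estimate a rate")
    slope_ppm_per_h = np.polyfit(trace.times, trace.co2, 1)[0]
    t_mean_k = float(np.mean(trace.temperature)) + 273.15
    dx_per_h = slope_ppm_per_h * 1e-6
    return (
        trace.pressure
        * trace.chamber_volume
        * dx_per_h
        / (trace.loaded_mass * GAS_CONSTANT * t_mean_k)
    )


def respiration_heat(T: float | np.ndarray, params: RespirationParams | None = None):
    """Respiration heat release Q(T) in W per kg of produce.

    Strictly increasing in temperature on its domain (the Fahrenheit
    equivalent of ``T`` must be positive).
    """
    params = params or RespirationParams()
    T = np.asarray(T, dtype=float)
    fahrenheit = 9.0 * T + 32.0 if params.literal_9t else 9.0 * T / 5.0 + 32.0
    if np.any(fahrenheit <= 0):
        raise ValueError("temperature outside the domain of the respiration law")
    out = 10.7 * params.f / 3600.0 * fahrenheit**params.g
    return float(out) if out.ndim == 0 else out


def rate_from_heat(Q: float) -> float:
    """Molar CO2 production rate (mol/kg h) implied by a heat release Q (W/kg)."""
    return Q * 3600.0 / CO2_HEAT_OF_RESPIRATION


def heat_from_rate(r_co2: float) -> float:
    """Heat release (W/kg) implied by a molar CO2 production rate (mol/kg h)."""
    return r_co2 * CO2_HEAT_OF_RESPIRATION / 3600.0


def volumetric_source(Q: float, mass_in_basket: float, basket_volume: float) -> float:
    """Volumetric heat source q_dot (W/m^3) for a loaded basket.

    ``q_dot = Q * m / V`` — equivalently the per-mass heat times the bulk
    density of the packed produce.
    """
    if mass_in_basket <= 0 or basket_volume <= 0:
        raise ValueError("mass and basket volume must be positive")
    return Q * mass_in_basket / basket_volume
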