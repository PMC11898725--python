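"""Thermal and porous-medium properties of Chinese cabbage.

Class-indexed temperature polynomials for conductivity and specific heat,
the measured per-class densities, porosity from vacuum-impregnation weight
gain, effective-medium mixing for the porous head, and the Darcy-Forchheimer
pressure-gradient law for vapour flow through the leaf matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Linear conductivity polynomials k(T) = c1*T + c0 (W/m K), per size class.
CONDUCTIVITY_COEFFS = {
    1: (8.1e-5, 2.2e-2),
    2: (8.3e-5, 2.27e-2),
    3: (8.5e-5, 2.3e-2),
}

#: Quadratic specific-heat polynomials Cp(T) = c2*T^2 + c1*T + c0 (J/kg K).
SPECIFIC_HEAT_COEFFS = {
    1: (-0.0048, 1.76, 1770.0),
    2: (-0.00475, 1.765, 1775.0),
    3: (-0.0047, 1.78, 1780.0),
}

#: Whole-head densities (kg/m^3) by size class (mean of the measured values).
DENSITY = {1: 601.64, 2: 675.70, 3: 754.34}

DEFAULT_POROSITY = 0.31


@dataclass(frozen=True)
class FluidProperties:
    """Pore-fluid (water vapour) properties at storage temperature (~4 degC).

    Standard-table values for saturated water vapour; the vapour density is
    so small that the fluid contributes almost nothing to the effective heat
    capacity, but it sets the Forchheimer inertial term.
    """

    density: float = 0.0068  # kg/m^3, saturated vapour at 4 degC
    viscosity: float = 9.2e-6  # Pa s
    specific_heat: float = 1884.0  # J/kg K
    conductivity: float = 0.0184  # W/m K


@dataclass(frozen=True)
class PorousFlowParams:
    """Darcy-Forchheimer closure: permeability K (m^2) and Forchheimer C_F.

    Defaults are order-of-magnitude placeholders for a leafy matrix (the
    measured values for cabbage are not available), clearly not measured
    quantities; override from config for any quantitative flow work.
    """

    permeability: float = 1e-7
    forchheimer: float = 0.55

    def __post_init__(self) -> None:
        if self.permeability <= 0:
            raise ValueError("permeability must be positive")
        if self.forchheimer < 0:
            raise ValueError("Forchheimer coefficient must be nonnegative")


def conductivity(T: float | np.ndarray, class_id: int):
    """Solid (head) thermal conductivity k(T) in W/m K for a size class."""
    try:
        c1, c0 = CONDUCTIVITY_COEFFS[class_id]
    except KeyError:
        raise ValueError(f"unknown size class {class_id!r}") from None
    return c1 * np.asarray(T, dtype=float) + c0


def specific_heat(T: float | np.ndarray, class_id: int):
    """Solid specific heat Cp(T) in J/kg K for a size class."""
    try:
        c2, c1, c0 = SPECIFIC_HEAT_COEFFS[class_id]
    except KeyError:
        raise ValueError(f"unknown size class {class_id!r}") from None
    T = np.asarray(T, dtype=float)
    return c2 * T**2 + c1 * T + c0


def porosity(w_saturated: float, w_initial: float, rho_water: float, v_initial: float) -> float:
    """Porosity from vacuum-impregnation weight gain.

    The pore volume is the impregnated water volume ``(W_sat - W_i)/rho_w``
    and the porosity is its ratio to the initial head volume.  Values above
    0.6 are physically implausible for a cabbage head and raise a warning.
    """
    if v_initial <= 0:
        raise ValueError("initial volume must be positive")
    if w_saturated < w_initial:
        raise ValueError("saturated weight below initial weight (negative uptake)")
    phi = (w_saturated - w_initial) / (rho_water * v_initial)
    if phi > 0.6:
        warnings.warn(
            f"porosity {phi:.3f} exceeds 0.6 — implausible for produce", stacklevel=2
        )
    return phi


def effective_conductivity(phi: float, k_solid: float, k_fluid: float, rule: str = "arithmetic") -> float:
    """Effective conductivity of the saturated porous head.

    Volume-weighted mixing of the solid and pore-fluid conductivities;
    ``rule`` selects arithmetic (parallel), harmonic (series) or geometric
    weighting.  All three are bounded by min/max of the inputs.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("porosity must lie in [0, 1]")
    if rule == "arithmetic":
        return (1.0 - phi) * k_solid + phi * k_fluid
    if rule == "harmonic":
        return 1.0 / ((1.0 - phi) / k_solid + phi / k_fluid)
    if rule == "geometric":
        return k_solid ** (1.0 - phi) * k_fluid**phi
    raise ValueError(f"unknown mixing rule {rule!r}")


def darcy_forchheimer_gradient(
    u: float,
    flow: PorousFlowParams,
    mu: float,
    rho_fluid: float,
) -> float:
    """Pressure-gradient magnitude (Pa/m) for seepage velocity ``u`` (m/s).

    ``|grad P| = mu/K u + rho C_F/sqrt(K) u^2`` — a viscous Darcy term plus
    the Forchheimer inertial correction.
    """
    if u < 0:
        raise ValueError("velocity magnitude must be nonnegative")
    K = flow.permeability
    return mu / K * u + rho_fluid * flow.forchheimer / np.sqrt(K) * u * u


@dataclass
class ThermalProperties:
    """Bundle of class-indexed properties used by the thermal solvers.

    ``k(T)`` and ``cp(T)`` evaluate the solid polynomials; ``rho_cp_eff(T)``
    is the local-thermal-equilibrium volumetric heat capacity
    ``(1-phi) rho_s Cp_s(T) + phi rho_f Cp_f`` and ``k_eff(T)`` the mixed
    effective conductivity.
    """

    class_id: int = 2
    porosity: float = DEFAULT_POROSITY
    fluid: FluidProperties = field(default_factory=FluidProperties)
    mixing_rule: str = "arithmetic"
    density: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.class_id not in DENSITY:
            raise ValueError(f"unknown size class {self.class_id!r}")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")
        if not self.density:
            self.density = DENSITY[self.class_id]

    def k(self, T):
        return conductivity(T, self.class_id)

    def cp(self, T):
        return specific_heat(T, self.class_id)

    def k_eff(self, T):
        ks = conductivity(T, self.class_id)
        return (
            effective_conductivity(self.porosity, ks, self.fluid.conductivity, self.mixing_rule)
            if np.ndim(ks) == 0
            else np.array(
                [
                    effective_conductivity(self.porosity, k, self.fluid.conductivity, self.mixing_rule)
                    for k in np.atleast_1d(ks)
                ]
            )
        )

    def rho_cp_eff(self, T):
        solid = (1.0 - self.porosity) * self.density * specific_heat(T, self.class_id)
        fluid = self.porosity * self.fluid.density * self.fluid.specific_heat
        return solid + fluid


@dataclass
class ConstantProperties:
    """Constant-coefficient stand-in with the same interface as
    :class:`ThermalProperties`; used by verification oracles and tests."""

    k_const: float
    rho_cp_const: float

    def k(self, T):
        return np.full_like(np.asarray(T, dtype=float), self.k_const) if np.ndim(T) else self.k_const

    cp = None

    def k_eff(self, T):
        return self.k(T)

    def rho_cp_eff(self, T):
        return (
            np.full_like(np.asarray(T, dtype=float), self.rho_cp_const)
            if np.ndim(T)
            else self.rho_cp_const
        )
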