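"""Transient radial conduction in a porous cabbage head with metabolic heat.

The head is modelled as an equivalent sphere of porous material in local
thermal equilibrium: a single temperature field with combined volumetric
heat capacity ``(1-phi) rho_s Cp_s + phi rho_f Cp_f`` and effective
conductivity, a respiration heat source, zero-gradient symmetry at the
centre and a Robin (convective) condition at the surface.

The solver is a flux-conservative finite-volume scheme on a uniform radial
grid, marched with backward Euler; temperature-dependent properties and the
source are lagged one step, so each step is a single tridiagonal solve.
Closed-form oracles (the textbook convective-sphere series and the
steady-generation profile) are provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .respiration import RespirationParams, respiration_heat
from .thermophysics import ThermalProperties


@dataclass(frozen=True)
class SphereGeometry:
    """Equivalent sphere for a cabbage head.

    The head is a prolate spheroid with semi-axes taken from the measured
    circumferences (``a = length_circumference / 2 pi``, ``b`` likewise from
    the width); the equivalent radius preserves the spheroid volume:
    ``R = (a b^2)^(1/3)``.
    """

    radius: float  # m
    class_id: int = 2

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @classmethod
    def from_circumferences(cls, length_cm: float, width_cm: float, class_id: int = 2) -> "SphereGeometry":
        a = length_cm / 100.0 / (2.0 * np.pi)
        b = width_cm / 100.0 / (2.0 * np.pi)
        if a < b:
            raise ValueError("length circumference must be >= width circumference")
        return cls(radius=float((a * b * b) ** (1.0 / 3.0)), class_id=class_id)

    @classmethod
    def for_class(cls, class_id: int) -> "SphereGeometry":
        """Equivalent sphere from the class-mean circumferences."""
        from .synthetic import CLASS_SPECS

        spec = CLASS_SPECS[class_id]
        return cls.from_circumferences(spec.length_mean, spec.width_mean, class_id)


@dataclass(frozen=True)
class BoundaryConditions:
    """Convective boundary and initial state: h (W/m^2 K), ambient and
    initial temperatures (degC)."""

    h: float
    T_inf: float
    T0: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("heat transfer coefficient must be positive")


@dataclass
class TemperatureField:
    """Radial grid x time temperature solution.

    ``temperatures[i, j]`` is the cell-centre temperature at radius
    ``node_radii[i]`` and time ``times[j]`` (seconds); ``volume_average``,
    ``surface`` and ``center`` are per-time scalars.
    """

    node_radii: np.ndarray
    times: np.ndarray
    temperatures: np.ndarray
    volume_average: np.ndarray
    surface: np.ndarray
    center: np.ndarray


def respiration_source(props: ThermalProperties, params: RespirationParams | None = None) -> Callable:
    """Volumetric respiration source q(T) = Q(T) * (1-phi) * rho_s (W/m^3).

    The per-mass heat law is scaled by the solid-fraction mass per unit
    volume, consistent with the porous energy balance.
    """
    params = params or RespirationParams()
    scale = (1.0 - props.porosity) * props.density

    def q_dot(T):
        return respiration_heat(T, params) * scale

    return q_dot


def _as_source(source) -> Callable:
    if source is None:
        return lambda T: np.zeros_like(np.asarray(T, dtype=float))
    if np.isscalar(source):
        val = float(source)
        return lambda T: np.full_like(np.asarray(T, dtype=float), val)
    return source


def solve_transient(
    geom: SphereGeometry,
    props,
    bc: BoundaryConditions,
    source=None,
    t_end: float = 72_000.0,
    dt: float = 5.0,
    n_nodes: int = 100,
    output_every: float = 60.0,
) -> TemperatureField:
    """March the radial finite-volume model to ``t_end`` seconds.

    ``source`` may be ``None``, a constant q (W/m^3) or a callable ``q(T)``;
    it is evaluated, like the properties, at the previous-step temperatures.
    Output is recorded every ``output_every`` seconds plus the final time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_nodes < 10:
        raise ValueError("need at least 10 radial cells")
    q_of_T = _as_source(source)

    R = geom.radius
    dr = R / n_nodes
    faces = np.linspace(0.0, R, n_nodes + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    volumes = 4.0 * np.pi / 3.0 * (faces[1:] ** 3 - faces[:-1] ** 3)
    face_areas = 4.0 * np.pi * faces**2  # interior faces 1..n-1 and outer face n

    n_steps = int(round(t_end / dt))
    record_stride = max(1, int(round(output_every / dt)))

    T = np.full(n_nodes, float(bc.T0))
    times = [0.0]
    snaps = [T.copy()]

    ab = np.zeros((3, n_nodes))  # banded matrix for solve_banded
    rhs = np.empty(n_nodes)

    for step in range(1, n_steps + 1):
        k = np.asarray(props.k_eff(T), dtype=float)
        if k.ndim == 0:
            k = np.full(n_nodes, float(k))
        rho_cp = np.asarray(props.rho_cp_eff(T), dtype=float)
        if rho_cp.ndim == 0:
            rho_cp = np.full(n_nodes, float(rho_cp))
        q = np.asarray(q_of_T(T), dtype=float)
        if q.ndim == 0:
            q = np.full(n_nodes, float(q))

        cap = rho_cp * volumes / dt
        k_face = 0.5 * (k[:-1] + k[1:])
        g_int = face_areas[1:-1] * k_face / dr  # conductance across interior faces
        # Robin surface: half-cell conduction in series with convection.
        g_out = face_areas[-1] / (dr / (2.0 * k[-1]) + 1.0 / bc.h)

        lower = -g_int  # coupling to cell i-1
        upper = -g_int  # coupling to cell i+1
        diag = cap.copy()
        diag[:-1] += g_int
        diag[1:] += g_int
        diag[-1] += g_out

        rhs[:] = cap * T + q * volumes
        rhs[-1] += g_out * bc.T_inf

        ab[0, 1:] = upper
        ab[1, :] = diag
        ab[2, :-1] = lower
        T = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(T)):
            raise FloatingPointError(f"solver diverged at step {step} (t={step * dt:.1f} s)")

        if step % record_stride == 0 or step == n_steps:
            times.append(step * dt)
            snaps.append(T.copy())

    temps = np.array(snaps).T  # node x time
    total_v = volumes.sum()
    vol_avg = (volumes[:, None] * temps).sum(axis=0) / total_v
    # Surface temperature from the half-cell flux balance with the last k, h.
    k_last = np.asarray(props.k_eff(temps[-1, :]), dtype=float)
    a = 2.0 * k_last / dr
    surface = (a * temps[-1, :] + bc.h * bc.T_inf) / (a + bc.h)
    return TemperatureField(
        node_radii=centers,
        times=np.array(times),
        temperatures=temps,
        volume_average=vol_avg,
        surface=surface,
        center=temps[0, :],
    )


def _sphere_eigenvalues(bi: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` roots of ``1 - lambda cot(lambda) = Bi``."""
    if bi <= 0:
        raise ValueError("Biot number must be positive")

    def f(lam):
        return 1.0 - lam / np.tan(lam) - bi

    roots = []
    eps = 1e-9
    for n in range(n_terms):
        lo = n * np.pi + eps
        hi = (n + 1) * np.pi - eps
        roots.append(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))
    return np.array(roots)


def analytic_sphere_cooling(
    R: float,
    k: float,
    rho_cp: float,
    h: float,
    T0: float,
    T_inf: float,
    r,
    t,
    n_terms: int = 50,
) -> np.ndarray | float:
    """Series solution for convective cooling of a constant-property sphere.

    ``theta/theta0 = sum C_n sin(lam_n r/R)/(lam_n r/R) exp(-lam_n^2 Fo)``
    with ``C_n = 4 (sin lam - lam cos lam)/(2 lam - sin 2 lam)`` and the
    eigenvalues the roots of ``1 - lam cot lam = Bi``; no heat generation.
    """
    bi = h * R / k
    lam = _sphere_eigenvalues(bi, n_terms)
    C = 4.0 * (np.sin(lam) - lam * np.cos(lam)) / (2.0 * lam - np.sin(2.0 * lam))
    fo = k / rho_cp * np.asarray(t, dtype=float) / R**2
    x = np.asarray(r, dtype=float) / R

    xs = np.atleast_1d(x)[:, None]  # r points x terms
    arg = lam[None, :] * xs
    radial = np.where(np.abs(arg) < 1e-12, 1.0, np.sin(arg) / np.where(arg == 0, 1.0, arg))
    decay = np.exp(-np.outer(np.atleast_1d(fo), lam**2))  # times x terms
    theta = np.einsum("rn,tn->rt", C[None, :] * radial, decay)
    out = T_inf + (T0 - T_inf) * theta
    if np.ndim(r) == 0 and np.ndim(t) == 0:
        return float(out[0, 0])
    if np.ndim(r) == 0:
        return out[0, :]
    if np.ndim(t) == 0:
        return out[:, 0]
    return out


def analytic_sphere_volume_average(
    R: float, k: float, rho_cp: float, h: float, T0: float, T_inf: float, t, n_terms: int = 50
) -> np.ndarray | float:
    """Volume-averaged form of :func:`analytic_sphere_cooling`."""
    bi = h * R / k
    lam = _sphere_eigenvalues(bi, n_terms)
    C = 4.0 * (np.sin(lam) - lam * np.cos(lam)) / (2.0 * lam - np.sin(2.0 * lam))
    B = 3.0 * (np.sin(lam) - lam * np.cos(lam)) / lam**3
    fo = k / rho_cp * np.asarray(t, dtype=float) / R**2
    decay = np.exp(-np.outer(np.atleast_1d(fo), lam**2))
    theta = decay @ (C * B)
    out = T_inf + (T0 - T_inf) * theta
    return float(out[0]) if np.ndim(t) == 0 else out


def steady_state_generation(R: float, k_eff: float, h: float, T_inf: float, q_dot: float, r=None):
    """Steady radial profile with uniform generation ``q_dot`` (W/m^3).

    ``T(r) = T_inf + q R/(3h) + q (R^2 - r^2)/(6 k_eff)`` — the surface
    excess balances the convective flux, the parabolic part the conduction.
    """
    if h <= 0:
        raise ValueError("heat transfer coefficient must be positive")
    rr = np.linspace(0.0, R, 101) if r is None else np.asarray(r, dtype=float)
    out = T_inf + q_dot * R / (3.0 * h) + q_dot * (R**2 - rr**2) / (6.0 * k_eff)
    return float(out) if np.ndim(out) == 0 else out


def time_to_threshold(field: TemperatureField, T_target: float) -> float:
    """First time (s) the volume-average temperature reaches ``T_target``,
    by linear interpolation between the bracketing output times."""
    v = field.volume_average
    t = field.times
    if v[0] <= T_target:
        return 0.0
    below = np.nonzero(v <= T_target)[0]
    if len(below) == 0:
        raise ValueError(f"volume-average never reaches {T_target} degC within t_end")
    j = below[0]
    frac = (v[j - 1] - T_target) / (v[j - 1] - v[j])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))
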