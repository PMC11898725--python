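"""Heat-transfer-coefficient calibration against cooling curves.

The surface coefficient h is the one free boundary parameter of the radial
head-cooling model.  It is estimated the way the original experiment did:
simulate the cooling curve over a grid of candidate h values, score each
against the observed curves by RMSE (averaged over measurement positions),
and take the grid argmin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import heat_solver

DEFAULT_H_GRID = np.arange(150.0, 400.0 + 1e-9, 10.0)


@dataclass
class CoolingExperiment:
    """Observed cooling curves at named basket positions.

    ``positions`` maps a label (top/middle/bottom) to a ``(times_h, temps_C)``
    pair; metadata records the head class and the thermal boundary state.
    """

    positions: dict
    class_id: int = 2
    T0: float = 20.0
    T_inf: float = 4.1

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("need at least one measurement position")
        for label, (t, y) in self.positions.items():
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if len(t) != len(y) or len(t) == 0:
                raise ValueError(f"position {label!r}: times and temps must align")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"position {label!r}: times must be increasing")
            self.positions[label] = (t, y)

    @property
    def t_end_h(self) -> float:
        return max(t[-1] for t, _ in self.positions.values())


def rmse(simulated, observed, sim_times=None, obs_times=None) -> float:
    """Root-mean-square error between a simulated and an observed series.

    With ``sim_times``/``obs_times`` given, the simulated series is aligned
    to the observation times by linear interpolation first; otherwise the
    series must already have equal length.
    """
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(observed) == 0 or len(simulated) == 0:
        raise ValueError("cannot compute RMSE of empty series")
    if sim_times is not None and obs_times is not None:
        sim_times = np.asarray(sim_times, dtype=float)
        obs_times = np.asarray(obs_times, dtype=float)
        if obs_times[0] > sim_times[-1] or obs_times[-1] < sim_times[0]:
            raise ValueError("simulated and observed time ranges do not overlap")
        simulated = np.interp(obs_times, sim_times, simulated)
    if len(simulated) != len(observed):
        raise ValueError("series lengths differ and no time axes were given")
    return float(np.sqrt(np.mean((simulated - observed) ** 2)))


def fit_h(
    experiment: CoolingExperiment,
    geom: heat_solver.SphereGeometry | None = None,
    props=None,
    source="respiration",
    h_grid=None,
    dt: float = 30.0,
    n_nodes: int = 60,
) -> tuple[float, pd.DataFrame]:
    """Grid-scan estimate of the surface heat-transfer coefficient.

    For each candidate h the transient model is solved, its volume-average
    temperature interpolated onto each position's observation times, and
    the position-mean RMSE recorded.  Returns the argmin (ties broken
    toward smaller h by the scan order) and the full RMSE curve.
    """
    from .thermophysics import ThermalProperties

    h_grid = DEFAULT_H_GRID if h_grid is None else np.asarray(h_grid, dtype=float)
    if np.any(h_grid <= 0) or np.any(np.diff(h_grid) <= 0):
        raise ValueError("h grid must be positive and increasing")
    props = props or ThermalProperties(class_id=experiment.class_id)
    geom = geom or heat_solver.SphereGeometry.for_class(experiment.class_id)
    if source == "respiration":
        source = heat_solver.respiration_source(props)
    bc_t_end = experiment.t_end_h * 3600.0

    scores = np.empty(len(h_grid))
    for i, h in enumerate(h_grid):
        bc = heat_solver.BoundaryConditions(h=float(h), T_inf=experiment.T_inf, T0=experiment.T0)
        fld = heat_solver.solve_transient(
            geom, props, bc, source=source, t_end=bc_t_end, dt=dt, n_nodes=n_nodes,
            output_every=max(dt, 300.0),
        )
        per_position = [
            rmse(fld.volume_average, obs, sim_times=fld.times / 3600.0, obs_times=t)
            for t, obs in experiment.positions.values()
        ]
        scores[i] = np.mean(per_position)
    curve = pd.DataFrame({"h": h_grid, "rmse": scores})
    return float(h_grid[int(np.argmin(scores))]), curve


@dataclass
class CalibrationResults:
    """Fitted surface coefficient with its RMSE scan curve."""

    h_opt: float
    rmse_curve: pd.DataFrame
    experiment: CoolingExperiment = field(repr=False)

    @property
    def rmse_at_opt(self) -> float:
        return float(self.rmse_curve["rmse"].min())

    def summary(self) -> str:
        grid = self.rmse_curve["h"].to_numpy()
        lines = [
            "Heat-transfer coefficient calibration",
            "-------------------------------------",
            f"positions:        {', '.join(self.experiment.positions)}",
            f"h grid:           {grid[0]:.0f}..{grid[-1]:.0f} W/m2K "
            f"(step {grid[1] - grid[0]:.0f})",
            f"optimal h:        {self.h_opt:.0f} W/m2K",
            f"RMSE at optimum:  {self.rmse_at_opt:.4f} degC",
        ]
        return "\n".join(lines)


class HeatTransferCalibration:
    """Model object binding a cooling experiment to the radial head model.

    ``fit`` runs the RMSE grid scan and returns :class:`CalibrationResults`.
    """

    def __init__(self, experiment: CoolingExperiment, geom=None, props=None,
                 source="respiration", dt: float = 30.0, n_nodes: int = 60):
        self.experiment = experiment
        self.geom = geom
        self.props = props
        self.source = source
        self.dt = dt
        self.n_nodes = n_nodes

    def fit(self, h_grid=None) -> CalibrationResults:
        h_opt, curve = fit_h(
            self.experiment, geom=self.geom, props=self.props, source=self.source,
            h_grid=h_grid, dt=self.dt, n_nodes=self.n_nodes,
        )
        return CalibrationResults(h_opt=h_opt, rmse_curve=curve, experiment=self.experiment)
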