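"""Macroscopic type-II photochemistry kinetics (the SOED forward model).

State per depth: ground-state photosensitizer [S0] (uM), ground-state oxygen
[3O2] (uM), and the cumulative reacted singlet oxygen [1O2]rx (uM).  The
quasi-steady-state elimination of the triplet and singlet intermediates makes
the system valid on time scales of seconds to hours, so no sub-microsecond
stepping is needed.

In-solution (phantom) model, with x = sigma*([S0]+delta) and f = [3O2]/([3O2]+beta):

    d[S0]/dt   = -xi f phi [S0] * x/(x+1)
    d[3O2]/dt  = -xi f phi [S0] * (x + k7 [A] tau_Delta)/(x+1)
    d[rx]/dt   =  xi f phi [S0] / (x+1)
    [1O2]      =  tau_Delta * d[rx]/dt        (instantaneous concentration)

In-tissue model (assumes x << 1, adds an oxygen perfusion/supply term g):

    d[S0]/dt   = -xi f phi [S0] * x
    d[3O2]/dt  = -xi phi [S0] f + g (1 - [3O2]/[3O2](t=0))
    d[rx]/dt   =  xi f phi [S0]

Depth-resolved runs integrate an independent copy of the system at each depth
with its local phi(d) (no lateral oxygen diffusion).  Oxygen cannot go
negative: [3O2] = 0 is an attracting equilibrium of both systems, and the
right-hand side additionally floors it at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .fluence import FluenceProfile
from .photophysics import PhotophysicalParams

__all__ = [
    "KineticsState",
    "KineticsTimeSeries",
    "instantaneous_singlet_oxygen",
    "simulate_invitro",
    "simulate_invivo",
    "volume_averaged_rx",
    "volume_average",
]

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass
class KineticsState:
    """Concentrations at one instant (all uM)."""

    S0: float
    O2: float
    rx: float = 0.0

    def __post_init__(self) -> None:
        if self.S0 < 0 or self.O2 < 0 or self.rx < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class KineticsTimeSeries:
    """Joint trajectory on a (time, depth) grid.

    Arrays have shape (n_times, n_depths); surface-only runs have a single
    depth at 0 cm.  ``singlet`` is the instantaneous [1O2] (uM) from the
    quasi-steady-state expression; ``phi`` is the fluence rate (mW/cm^2) at
    each depth (constant in time for CW illumination).
    """

    times: np.ndarray
    depths: np.ndarray
    S0: np.ndarray
    O2: np.ndarray
    rx: np.ndarray
    singlet: np.ndarray
    phi: np.ndarray
    params: Optional[PhotophysicalParams] = None
    mode: str = ""

    @property
    def surface(self) -> dict:
        """1-D views of the shallowest depth."""
        return {
            "times": self.times,
            "S0": self.S0[:, 0],
            "O2": self.O2[:, 0],
            "rx": self.rx[:, 0],
            "singlet": self.singlet[:, 0],
            "phi": float(self.phi[0]),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_s, depth_cm, ...)."""
        nt, nd = self.S0.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, nd),
                "depth_cm": np.tile(self.depths, nt),
                "S0_uM": self.S0.ravel(),
                "O2_uM": self.O2.ravel(),
                "rx_uM": self.rx.ravel(),
                "singlet_uM": self.singlet.ravel(),
                "phi_mW_cm2": np.tile(self.phi, nt),
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def instantaneous_singlet_oxygen(
    state: KineticsState,
    params: PhotophysicalParams,
    phi: float,
    full_denominator: bool = True,
) -> float:
    """Quasi-steady-state [1O2] (uM) for one state and fluence rate.

    ``full_denominator=False`` applies the small-bleaching approximation
    (denominator 1) used by the in-tissue model.
    """
    if phi < 0:
        raise ValueError("phi must be non-negative")
    params.require("xi", "tau_Delta", "beta", "sigma", "delta")
    f = state.O2 / (state.O2 + params.beta) if state.O2 > 0 else 0.0
    denom = 1.0 + (params.sigma * (state.S0 + params.delta) if full_denominator else 0.0)
    return params.xi * params.tau_Delta * f * phi * state.S0 / denom


def _resolve_fluence(
    fluence: Union[float, FluenceProfile],
    depths,
    phi0: Optional[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Return (depth grid, phi per depth in mW/cm^2)."""
    if isinstance(fluence, FluenceProfile):
        if phi0 is None:
            raise ValueError("phi0 (incident fluence rate, mW/cm^2) is required "
                             "when fluence is a FluenceProfile")
        d = np.asarray(depths, dtype=float) if depths is not None else fluence.depths
        return d, phi0 * fluence.at(d)
    phi_scalar = float(fluence)
    if phi_scalar < 0:
        raise ValueError("fluence rate must be non-negative")
    d = np.asarray(depths, dtype=float) if depths is not None else np.array([0.0])
    return d, np.full(d.shape, phi_scalar)


def _integrate(params, phi_d, initial, t_grid, mode, o2_baseline=None):
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing with at least two points")
    if initial.S0 <= 0 or initial.O2 <= 0:
        raise ValueError("initial S0 and O2 must be positive")
    params.require("xi", "beta", "sigma", "delta")
    nd = phi_d.size
    xi, beta, sigma, delta = params.xi, params.beta, params.sigma, params.delta
    A = params.quencher_concentration
    if mode == "invitro":
        quench = 0.0
        if A > 0:
            params.require("k7", "tau_Delta")
            quench = params.k7 * A * params.tau_Delta
    else:
        g = params.supply_rate
        O2_baseline = initial.O2 if o2_baseline is None else float(o2_baseline)
        if O2_baseline <= 0:
            raise ValueError("oxygen baseline must be positive")

    def rhs(t_, y):
        S0 = np.maximum(y[:nd], 0.0)
        O2 = np.maximum(y[nd:2 * nd], 0.0)
        f = O2 / (O2 + beta)
        common = xi * f * phi_d * S0
        x = sigma * (S0 + delta)
        if mode == "invitro":
            dS0 = -common * x / (x + 1.0)
            dO2 = -common * (x + quench) / (x + 1.0)
            drx = common / (x + 1.0)
        else:
            dS0 = -common * x
            dO2 = -common + g * (1.0 - O2 / O2_baseline)
            drx = common
        return np.concatenate([dS0, dO2, drx])

    y0 = np.concatenate([
        np.full(nd, initial.S0),
        np.full(nd, initial.O2),
        np.full(nd, initial.rx),
    ])
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, method="LSODA", t_eval=t,
                    rtol=_RTOL, atol=_ATOL)
    if not sol.success:
        raise RuntimeError(
            f"kinetics integration failed: {sol.message}; "
            f"last good time t={sol.t[-1] if sol.t.size else t[0]:.3f} s"
        )
    S0 = np.maximum(sol.y[:nd].T, 0.0)          # (nt, nd)
    O2 = np.maximum(sol.y[nd:2 * nd].T, 0.0)
    rx = np.maximum(sol.y[2 * nd:].T, 0.0)
    return t, S0, O2, rx


def _series(params, depths, phi_d, t, S0, O2, rx, mode) -> KineticsTimeSeries:
    params.require("tau_Delta")
    f = O2 / (O2 + params.beta)
    denom = 1.0 + params.sigma * (S0 + params.delta) if mode == "invitro" else 1.0
    singlet = params.xi * params.tau_Delta * f * phi_d[None, :] * S0 / denom
    return KineticsTimeSeries(
        times=t, depths=np.asarray(depths, dtype=float),
        S0=S0, O2=O2, rx=rx, singlet=singlet, phi=phi_d,
        params=params, mode=mode,
    )


def simulate_invitro(
    params: PhotophysicalParams,
    fluence: Union[float, FluenceProfile],
    initial: KineticsState,
    t_grid,
    depths=None,
    phi0: Optional[float] = None,
) -> KineticsTimeSeries:
    """Integrate the in-solution system with the full photobleaching denominator.

    ``fluence`` is either a scalar fluence rate (mW/cm^2, uniform over the
    depth grid) or a :class:`FluenceProfile` combined with the incident rate
    ``phi0``.
    """
    d, phi_d = _resolve_fluence(fluence, depths, phi0)
    t, S0, O2, rx = _integrate(params, phi_d, initial, t_grid, "invitro")
    return _series(params, d, phi_d, t, S0, O2, rx, "invitro")


def simulate_invivo(
    params: PhotophysicalParams,
    fluence: Union[float, FluenceProfile],
    initial: KineticsState,
    t_grid,
    depths=None,
    phi0: Optional[float] = None,
    o2_baseline: Optional[float] = None,
) -> KineticsTimeSeries:
    """Integrate the in-tissue system (small-bleaching limit, oxygen supply g).

    ``o2_baseline`` is the resting oxygen level the perfusion term restores
    toward; it defaults to the initial oxygen concentration.
    """
    d, phi_d = _resolve_fluence(fluence, depths, phi0)
    t, S0, O2, rx = _integrate(params, phi_d, initial, t_grid, "invivo",
                               o2_baseline=o2_baseline)
    return _series(params, d, phi_d, t, S0, O2, rx, "invivo")


def volume_average(depths: np.ndarray, values: np.ndarray, depth_limit: float) -> np.ndarray:
    """Uniform-weight trapezoidal average of a (time, depth) field over depth.

    Averages over [0, depth_limit]; the endpoint is interpolated if it falls
    between grid points.
    """
    d = np.asarray(depths, dtype=float)
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if depth_limit <= 0:
        raise ValueError("depth_limit must be positive")
    if d[0] > 1e-12 or d[-1] < depth_limit - 1e-12:
        raise ValueError(
            f"depth grid [{d[0]}, {d[-1]}] does not cover [0, {depth_limit}]"
        )
    inside = d <= depth_limit + 1e-12
    d_in = d[inside]
    v_in = v[:, inside]
    if d_in[-1] < depth_limit - 1e-12:
        v_end = np.array([np.interp(depth_limit, d, row) for row in v])
        d_in = np.append(d_in, depth_limit)
        v_in = np.column_stack([v_in, v_end])
    return np.trapezoid(v_in, d_in, axis=1) / depth_limit


def volume_averaged_rx(series: KineticsTimeSeries, depth_limit: float) -> np.ndarray:
    """Volume-averaged cumulative reacted singlet oxygen (uM) at each time."""
    return volume_average(series.depths, series.rx, depth_limit)
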