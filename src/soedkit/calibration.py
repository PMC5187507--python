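"""Parameter extraction and conversion fits.

Four calibrations, all ordinary least squares with covariance-based error
propagation (no robust variants):

* bleaching line: the photobleaching rate per dose,
  (-d[S0]/dt) / (phi [S0] [3O2]/([3O2]+beta)) = xi sigma ([S0] + delta),
  regressed on [S0]; delta = intercept/slope, sigma = slope/xi.
* quencher line: 1/tau_Delta = k6 + k7 [A] from an azide titration.
* luminescence-vs-model line: SOLD counts against SOED values, with and
  without intercept.
* cross-wavelength study: depth-resolved in-tissue simulations at 523 and
  630 nm over a spread of patient optical properties, giving the affine
  conversion rx(630) = a(c) rx(523) + b(c, total fluence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fluence import OpticalProperties, tissue_fluence_profile
from .kinetics import (
    KineticsState,
    KineticsTimeSeries,
    simulate_invivo,
    volume_average,
)
from .photophysics import PhotophysicalParams

__all__ = [
    "BleachingCalibration",
    "QuencherCalibration",
    "LinearFit",
    "WavelengthConversionFit",
    "PhantomRun",
    "photobleaching_rate",
    "fit_delta_sigma",
    "fit_quencher_rates",
    "fit_sold_soed_line",
    "wavelength_conversion_study",
    "convert_523_to_630",
]


def _ols(x: np.ndarray, y: np.ndarray, intercept: bool = True):
    """OLS slope/intercept with standard errors and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate x-range for regression")
    if intercept:
        X = np.column_stack([x, np.ones(n)])
    else:
        X = x[:, None]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    se = np.sqrt(np.diag(cov))
    if intercept:
        return coef[0], coef[1], se[0], se[1], r2, cov
    return coef[0], 0.0, se[0], 0.0, r2, cov


@dataclass
class BleachingCalibration:
    """Result of the bleaching-line regression (all in uM / s / cm / mW units)."""

    slope: float                 # xi*sigma, cm^2 mW^-1 s^-1 uM^-1
    intercept: float             # xi*sigma*delta, cm^2 mW^-1 s^-1
    delta: float                 # uM
    sigma: float                 # uM^-1
    slope_stderr: Optional[float] = None
    intercept_stderr: Optional[float] = None
    delta_stderr: Optional[float] = None
    sigma_stderr: Optional[float] = None
    r_squared: Optional[float] = None
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("bleaching-line slope must be positive (model violated)")
        if not math.isclose(self.delta, self.intercept / self.slope, rel_tol=1e-9):
            raise ValueError("delta must equal intercept/slope")

    @classmethod
    def from_line(cls, slope: float, intercept: float, xi: float,
                  slope_stderr: float = None, intercept_stderr: float = None,
                  cov_si: float = 0.0, r_squared: float = None,
                  n_points: int = 0) -> "BleachingCalibration":
        """Build the calibration from a fitted line and the known xi.

        delta = intercept/slope and sigma = slope/xi, with first-order error
        propagation through the (slope, intercept) covariance.
        """
        if slope <= 0:
            raise ValueError("bleaching-line slope must be positive (model violated)")
        delta = intercept / slope
        sigma = slope / xi
        delta_err = sigma_err = None
        if slope_stderr is not None and intercept_stderr is not None:
            delta_err = abs(delta) * math.sqrt(
                max(
                    (intercept_stderr / intercept) ** 2 if intercept else 0.0,
                    0.0,
                )
                + (slope_stderr / slope) ** 2
                - 2.0 * cov_si / (intercept * slope if intercept else math.inf)
            )
            sigma_err = abs(sigma) * slope_stderr / slope
        return cls(slope, intercept, delta, sigma, slope_stderr, intercept_stderr,
                   delta_err, sigma_err, r_squared, n_points)


@dataclass
class QuencherCalibration:
    """k6 (intercept, s^-1) and k7 (slope, uM^-1 s^-1) from 1/tau_Delta vs [A]."""

    k6: float
    k7: float
    k6_stderr: Optional[float] = None
    k7_stderr: Optional[float] = None
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k6 <= 0 or self.k7 <= 0:
            raise ValueError("k6 and k7 must both be positive")


@dataclass
class LinearFit:
    """A fitted line y = factor*x + offset, plus its no-intercept variant."""

    factor: float
    offset: float
    r_squared: float
    factor_stderr: Optional[float] = None
    offset_stderr: Optional[float] = None
    factor_no_intercept: Optional[float] = None
    r_squared_no_intercept: Optional[float] = None
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


# ---------------------------------------------------------------------------
# bleaching line


@dataclass
class PhantomRun:
    """One phantom illumination: sampled [S0](t) and [3O2](t) plus phi0.

    ``s0_table`` and ``o2_table`` are DataFrames with columns
    (time_s, S0_uM) and (time_s, O2_uM); the grids may differ (oxygen is
    typically sampled at 5–30 s, the sensitizer every 10 s).
    """

    s0_table: pd.DataFrame
    o2_table: pd.DataFrame
    phi0: float

    def __post_init__(self) -> None:
        if self.phi0 <= 0:
            raise ValueError("phi0 must be positive")
        for df, col in [(self.s0_table, "S0_uM"), (self.o2_table, "O2_uM")]:
            if "time_s" not in df or col not in df:
                raise ValueError(f"table must have columns time_s, {col}")


def _local_linear(t, y, window):
    """Sliding-window linear fits: (-slope, fitted value, window-centred?)."""
    n = t.size
    half = window // 2
    rate = np.empty(n)
    smooth = np.empty(n)
    centred = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        b, a = np.polyfit(t[lo:hi], y[lo:hi], 1)
        rate[i] = -b
        smooth[i] = b * t[i] + a
        centred[i] = (lo <= i - half) and (hi > i + half)
    return rate, smooth, centred


def photobleaching_rate(times, S0, window: int = 5) -> np.ndarray:
    """-d[S0]/dt (uM/s) by sliding-window local linear regression.

    A centred window of ``window`` points is used; endpoints fall back to
    one-sided windows of the same length.  Raw finite differences would
    amplify sampling noise, hence the local fits.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(S0, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    if window < 2:
        raise ValueError("window must be >= 2")
    return _local_linear(t, y, window)[0]


def fit_delta_sigma(
    runs: Union[PhantomRun, KineticsTimeSeries, Sequence],
    params: PhotophysicalParams,
    phi: Optional[float] = None,
    window: int = 5,
    o2_floor: float = 3.0,
) -> BleachingCalibration:
    """Fit the bleaching line pooled over one or more runs.

    Accepts :class:`PhantomRun` measured tables (oxygen interpolated onto the
    sensitizer time grid), or a simulated :class:`KineticsTimeSeries` (surface
    values; ``phi`` defaults to its surface fluence rate).  Returns the line
    plus delta = intercept/slope and sigma = slope/xi.

    Only points whose derivative window is fully centred enter the
    regression: one-sided endpoint windows carry an O(h) derivative bias on a
    curved decay, which systematically inflates the intercept.  The sensitizer
    concentration entering the dose denominator and the regressor is the
    window-smoothed value (dividing by the raw noisy readout correlates the
    errors of both axes).  Points with oxygen at or below ``o2_floor`` (uM,
    about the readout noise) are excluded — the triplet-quenching fraction is
    unmeasurable there.
    """
    params.require("xi", "beta")
    if isinstance(runs, (PhantomRun, KineticsTimeSeries)):
        runs = [runs]
    xs, ys = [], []
    for run in runs:
        if isinstance(run, KineticsTimeSeries):
            surf = run.surface
            t, s0, o2 = surf["times"], surf["S0"], surf["O2"]
            phi_run = phi if phi is not None else surf["phi"]
        else:
            t = run.s0_table["time_s"].values.astype(float)
            s0 = run.s0_table["S0_uM"].values.astype(float)
            o2 = np.interp(t, run.o2_table["time_s"].values.astype(float),
                           run.o2_table["O2_uM"].values.astype(float))
            phi_run = run.phi0
        if t.size < 5:
            raise ValueError("need at least 5 time points")
        rate, s0_smooth, centred = _local_linear(t, s0, window)
        f = o2 / (o2 + params.beta)
        valid = centred & (s0_smooth > 0) & (o2 > o2_floor)
        ys.append(rate[valid] / (phi_run * s0_smooth[valid] * f[valid]))
        xs.append(s0_smooth[valid])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    slope, intercept, se_s, se_i, r2, cov = _ols(x, y, intercept=True)
    return BleachingCalibration.from_line(
        slope, intercept, params.xi, se_s, se_i, cov[0, 1], r2, n_points=x.size
    )


# ---------------------------------------------------------------------------
# quencher titration


def fit_quencher_rates(lifetimes: Sequence[tuple]) -> QuencherCalibration:
    """OLS of 1/tau_Delta on quencher concentration [A].

    ``lifetimes`` is a sequence of (A in uM, tau_Delta in s) pairs with at
    least three distinct concentrations.
    """
    A = np.array([p[0] for p in lifetimes], dtype=float)
    tau = np.array([p[1] for p in lifetimes], dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    if np.unique(A).size < 3:
        raise ValueError("need at least 3 distinct quencher concentrations")
    slope, intercept, se_s, se_i, r2, _ = _ols(A, 1.0 / tau, intercept=True)
    return QuencherCalibration(k6=intercept, k7=slope,
                               k6_stderr=se_i, k7_stderr=se_s, r_squared=r2)


# ---------------------------------------------------------------------------
# luminescence vs model


def fit_sold_soed_line(pairs: Sequence[tuple]) -> LinearFit:
    """Least-squares line through (SOLD counts, SOED value) pairs.

    Fits both the intercept-bearing and the through-origin line and reports
    both coefficients of determination.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    slope, intercept, se_s, se_i, r2, _ = _ols(x, y, intercept=True)
    slope0, _, _, _, r2_0, _ = _ols(x, y, intercept=False)
    return LinearFit(slope, intercept, r2, se_s, se_i, slope0, max(r2_0, 0.0), x.size)


# ---------------------------------------------------------------------------
# cross-wavelength conversion


@dataclass
class WavelengthConversionFit:
    """Affine 523→630 nm conversion: rx630 = a(c) rx523 + b(c, fluence).

    a(c) = a_slope*c + a_intercept (c in uM);
    b(c, F) = (b_c_coeff*c + b_const) * F (F = total fluence, J/cm^2; b in mM).
    ``table`` holds the per-(c, fluence) regressions behind the surface fit.
    """

    a_slope: float
    a_intercept: float
    b_c_coeff: float
    b_const: float
    c_range: tuple
    fluence_range: tuple
    table: Optional[pd.DataFrame] = None

    def a(self, c: float) -> float:
        return self.a_slope * c + self.a_intercept

    def b(self, c: float, total_fluence: float) -> float:
        return (self.b_c_coeff * c + self.b_const) * total_fluence

    def covers(self, c: float, total_fluence: float) -> bool:
        return (self.c_range[0] <= c <= self.c_range[1]
                and self.fluence_range[0] <= total_fluence <= self.fluence_range[1])


def wavelength_conversion_study(
    optics_table: pd.DataFrame,
    c_values: Sequence[float],
    fluence_rates: Sequence[float],
    total_fluences: Sequence[float],
    params_523: PhotophysicalParams,
    params_630: PhotophysicalParams,
    depth_limit: float = 1.0,
    dz: float = 0.02,
    O2_initial: float = 40.0,
    fluence_model: Union[str, float, None] = "mc",
    mc_photons: int = 100_000,
    mc_seed: int = 12345,
) -> WavelengthConversionFit:
    """Simulate rx at both wavelengths over an optics spread and fit the conversion.

    ``optics_table`` needs columns (site, mu_a_523, mu_s_prime_523, mu_a_630,
    mu_s_prime_630).  For every (site, c, fluence rate) the in-tissue system
    is integrated once to the longest treatment time and the volume-averaged
    rx read off at each requested total fluence; per (c, total fluence) the
    630 nm values are regressed on the 523 nm values, then a(c) is fitted
    linearly in c and b(c, F) bilinearly as (p*c + q)*F.  rx is in mM in the
    fitted relations.  Initial [3O2] defaults to the 40 uM tissue level.
    """
    required = {"mu_a_523", "mu_s_prime_523", "mu_a_630", "mu_s_prime_630"}
    if not required <= set(optics_table.columns):
        raise ValueError(f"optics_table must have columns {sorted(required)}")
    c_values = np.asarray(c_values, dtype=float)
    fluence_rates = np.asarray(fluence_rates, dtype=float)
    total_fluences = np.asarray(total_fluences, dtype=float)
    if len(optics_table) < 2 or c_values.size < 2 or total_fluences.size < 1:
        raise ValueError("insufficient grid coverage for the conversion study")
    depths = np.arange(0.0, depth_limit + 0.5 * dz, dz)
    caches = {"523": {}, "630": {}}
    records = []
    for c in c_values:
        for rate in fluence_rates:
            # one simulation per (site, wavelength) evaluated at all fluences
            times = np.sort(total_fluences * 1000.0 / rate)  # J/cm2 / (mW/cm2) -> s
            t_grid = np.unique(np.concatenate([[0.0], times]))
            for _, row in optics_table.iterrows():
                rx = {}
                for wl, p in [("523", params_523), ("630", params_630)]:
                    optics = OpticalProperties(row[f"mu_a_{wl}"],
                                               row[f"mu_s_prime_{wl}"],
                                               float(wl))
                    cache = caches[wl]
                    key = (optics.mu_a, optics.mu_s_prime)
                    profile = cache.get(key)
                    if profile is None:
                        profile = tissue_fluence_profile(
                            optics, depths, buildup=fluence_model,
                            mc_photons=mc_photons, mc_seed=mc_seed)
                        cache[key] = profile
                    series = simulate_invivo(
                        p, profile, KineticsState(S0=c, O2=O2_initial),
                        t_grid, depths=depths, phi0=rate)
                    rx_avg = volume_average(series.depths, series.rx, depth_limit)
                    rx[wl] = np.interp(times, t_grid, rx_avg) / 1000.0  # uM -> mM
                for F, r523, r630 in zip(np.sort(total_fluences), rx["523"], rx["630"]):
                    records.append({
                        "site": row.get("site", ""), "c_uM": c,
                        "fluence_rate_mW_cm2": rate, "total_fluence_J_cm2": F,
                        "rx523_mM": r523, "rx630_mM": r630,
                    })
    df = pd.DataFrame(records)
    lines = []
    for (c, F), grp in df.groupby(["c_uM", "total_fluence_J_cm2"]):
        if grp["rx523_mM"].nunique() < 2:
            continue
        slope, intercept, se_s, se_i, r2, _ = _ols(
            grp["rx523_mM"].values, grp["rx630_mM"].values)
        lines.append({"c_uM": c, "total_fluence_J_cm2": F,
                      "a": slope, "b_mM": intercept, "r_squared": r2,
                      "n_points": len(grp)})
    table = pd.DataFrame(lines)
    if table.empty:
        raise ValueError("insufficient grid coverage for the conversion study")
    # a(c): average a over fluences at each c, then linear in c
    a_by_c = table.groupby("c_uM")["a"].mean()
    a_slope, a_intercept, *_ = _ols(a_by_c.index.values, a_by_c.values)
    # b(c, F) = (p*c + q)*F by least squares on b/F vs c
    bF = table["b_mM"].values / table["total_fluence_J_cm2"].values
    b_c_coeff, b_const, *_ = _ols(table["c_uM"].values, bF)
    return WavelengthConversionFit(
        a_slope=a_slope, a_intercept=a_intercept,
        b_c_coeff=b_c_coeff, b_const=b_const,
        c_range=(float(c_values.min()), float(c_values.max())),
        fluence_range=(float(total_fluences.min()), float(total_fluences.max())),
        table=table,
    )


@dataclass
class ConvertedRx:
    """rx at 630 nm converted from a 523 nm value, with extrapolation flag."""

    rx630: float    # mM
    extrapolated: bool


def convert_523_to_630(
    rx523: float,
    c: float,
    total_fluence: float,
    fit: WavelengthConversionFit,
) -> ConvertedRx:
    """Apply the affine conversion rx630 = a(c)*rx523 + b(c, F) (mM in, mM out)."""
    value = fit.a(c) * rx523 + fit.b(c, total_fluence)
    return ConvertedRx(rx630=value, extrapolated=not fit.covers(c, total_fluence))
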