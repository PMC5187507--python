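"""Seeded generators for every input the pipeline consumes.

Each generator returns a ``(data, truth)`` pair: the measured-style tables a
real experiment would produce, plus the hidden ground truth used only in
recovery assertions.  All randomness flows through ``numpy.random.default_rng``
with an explicit integer seed, so outputs are bit-reproducible across
platforms.

What is emulated: phantom oxygen/sensitizer time series with their different
sampling cadences and readout noise; Poisson-noise gated luminescence
histograms at the signal (1270 nm) and background (1210 nm) filters; and
patient optical-property spreads at the two treatment wavelengths.  Raw
spectrometer spectra, detector afterpulsing and instrument response are not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fluence import FluenceProfile
from .kinetics import KineticsState, KineticsTimeSeries, simulate_invitro
from .calibration import PhantomRun
from .photophysics import PhotophysicalParams
from .sold import SoldHistogram, pulse_response

__all__ = [
    "PhantomScenario",
    "OpticsScenario",
    "generate_phantom_timeseries",
    "generate_sold_histograms",
    "expected_total_signal_counts",
    "generate_optics_table",
    "MPM_OPTICS_RANGES",
    "MPM_MEAN_OPTICS",
]


@dataclass
class PhantomScenario:
    """One phantom illumination plus its measurement schedule and noise.

    Noise defaults: additive Gaussian sd 3 uM on the oxygen readout and
    multiplicative Gaussian sd 3% on the sensitizer readout — stand-ins of a
    plausible magnitude, configurable.
    """

    S0_initial: float = 50.0          # uM
    O2_initial: float = 160.4         # uM
    phi0: float = 38.0                # mW/cm^2
    duration: float = 900.0           # s
    o2_interval: float = 15.0         # s (5–30 s in practice)
    s0_interval: float = 10.0         # s
    o2_noise_sd: float = 3.0          # uM, additive
    s0_noise_rel_sd: float = 0.03     # relative, multiplicative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.o2_interval <= 0 or self.s0_interval <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.o2_noise_sd < 0 or self.s0_noise_rel_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.S0_initial <= 0 or self.O2_initial <= 0 or self.phi0 < 0:
            raise ValueError("initial concentrations must be positive")


def generate_phantom_timeseries(
    scenario: PhantomScenario,
    params: PhotophysicalParams,
    fluence: Optional[FluenceProfile] = None,
) -> tuple[PhantomRun, KineticsTimeSeries]:
    """Simulate a phantom run and sample it like the instruments would.

    Ground truth comes from the in-solution kinetics at the surface (or with
    the supplied fluence profile); the returned :class:`PhantomRun` holds the
    noisy sampled tables.
    """
    rng = np.random.default_rng(scenario.seed)
    t_end = scenario.duration
    t_o2 = np.arange(0.0, t_end + 1e-9, scenario.o2_interval)
    t_s0 = np.arange(0.0, t_end + 1e-9, scenario.s0_interval)
    t_grid = np.unique(np.concatenate([t_o2, t_s0, [0.0, t_end]]))
    initial = KineticsState(S0=scenario.S0_initial, O2=scenario.O2_initial)
    if fluence is None:
        truth = simulate_invitro(params, scenario.phi0, initial, t_grid)
    else:
        truth = simulate_invitro(params, fluence, initial, t_grid,
                                 phi0=scenario.phi0)
    surf = truth.surface
    o2_clean = np.interp(t_o2, surf["times"], surf["O2"])
    s0_clean = np.interp(t_s0, surf["times"], surf["S0"])
    o2_meas = np.clip(o2_clean + rng.normal(0.0, scenario.o2_noise_sd, t_o2.size), 0.0, None)
    s0_meas = np.clip(s0_clean * (1.0 + rng.normal(0.0, scenario.s0_noise_rel_sd, t_s0.size)),
                      0.0, None)
    run = PhantomRun(
        s0_table=pd.DataFrame({"time_s": t_s0, "S0_uM": s0_meas}),
        o2_table=pd.DataFrame({"time_s": t_o2, "O2_uM": o2_meas}),
        phi0=scenario.phi0,
    )
    return run, truth


def expected_total_signal_counts(params: PhotophysicalParams, S0: float,
                                 N: float, n_pulses: int) -> float:
    """Expected background-free total counts for a histogram acquisition."""
    params.require("Phi_Delta", "tau_Delta", "tau_R")
    return (n_pulses * N * params.sigma_A() * S0 * params.Phi_Delta
            * params.tau_Delta / params.tau_R)


def generate_sold_histograms(
    params: PhotophysicalParams,
    S0: float,
    N: float,
    n_pulses: int,
    background_rate: float,
    seed: int,
    bin_width: float = 32e-9,
    t_max: float = 60e-6,
    gate_mask: Optional[np.ndarray] = None,
) -> tuple[SoldHistogram, SoldHistogram]:
    """Poisson-sampled (1270 nm, 1210 nm) histogram pair for one acquisition.

    The expected 1270 nm signal per bin is the pulse response integrated over
    the bin, divided by tau_R (phosphorescence emission) and multiplied by the
    pulse count; both filters share a flat background of ``background_rate``
    counts/s (per pulse) within the gate.
    """
    if S0 <= 0 or N <= 0 or n_pulses <= 0 or background_rate < 0:
        raise ValueError("S0, N, n_pulses must be positive; background_rate >= 0")
    params.require("Phi_Delta", "tau_Delta", "tau_t", "tau_R")
    rng = np.random.default_rng(seed)
    edges = np.arange(0.0, t_max + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    signal = (pulse_response(centers, N, params.sigma_A(), S0, params.Phi_Delta,
                             params.tau_Delta, params.tau_t)
              / params.tau_R * bin_width * n_pulses)
    background = background_rate * bin_width * n_pulses
    if gate_mask is None:
        gate_mask = np.ones(centers.shape, dtype=bool)
    else:
        gate_mask = np.asarray(gate_mask, dtype=bool)
    lam_1270 = np.where(gate_mask, signal + background, 0.0)
    lam_1210 = np.where(gate_mask, background, 0.0)
    common = dict(n_pulses=n_pulses, photons_per_pulse=N,
                  accumulation_s=0.0)
    h1270 = SoldHistogram(edges, rng.poisson(lam_1270), "1270", gate_mask.copy(), **common)
    h1210 = SoldHistogram(edges, rng.poisson(lam_1210), "1210", gate_mask.copy(), **common)
    return h1270, h1210


# Patient optical-property spreads at the two wavelengths (cm^-1): uniform
# ranges spanning the measured in-patient values, plus the cohort means.
MPM_OPTICS_RANGES = {
    "523": {"mu_a": (0.66, 23.1), "mu_s_prime": (2.80, 73.7)},
    "630": {"mu_a": (0.17, 1.35), "mu_s_prime": (2.55, 30.5)},
}
MPM_MEAN_OPTICS = {
    "523": {"mu_a": 5.52, "mu_s_prime": 17.61},
    "630": {"mu_a": 0.58, "mu_s_prime": 15.61},
}


@dataclass
class OpticsScenario:
    """Uniform, independent per-wavelength draws of (mu_a, mu_s')."""

    n_sites: int = 8
    ranges: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                  MPM_OPTICS_RANGES.items()})
    include_means: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")
        for wl, r in self.ranges.items():
            for name in ("mu_a", "mu_s_prime"):
                lo, hi = r[name]
                if not (0 < lo < hi):
                    raise ValueError(f"invalid {name} range at {wl} nm: {(lo, hi)}")


def generate_optics_table(scenario: OpticsScenario) -> pd.DataFrame:
    """Per-site paired optical properties at 523 and 630 nm.

    Draws are uniform and independent between mu_a and mu_s' (no measured
    covariance structure is emulated).  When ``include_means`` is set, the
    cohort mean optical properties are appended as a fixed row.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for i in range(scenario.n_sites):
        row = {"site": f"site_{i:02d}"}
        # paired across wavelengths: one quantile per site for absorption and
        # one for scattering, applied to both wavelength ranges (the same
        # chromophore and scatterer content drives both; only mu_a vs mu_s'
        # are independent)
        u_a, u_s = rng.random(), rng.random()
        for wl in ("523", "630"):
            r = scenario.ranges[wl]
            lo, hi = r["mu_a"]
            row[f"mu_a_{wl}"] = lo + u_a * (hi - lo)
            lo, hi = r["mu_s_prime"]
            row[f"mu_s_prime_{wl}"] = lo + u_s * (hi - lo)
        rows.append(row)
    if scenario.include_means:
        row = {"site": "cohort_mean"}
        for wl in ("523", "630"):
            row[f"mu_a_{wl}"] = MPM_MEAN_OPTICS[wl]["mu_a"]
            row[f"mu_s_prime_{wl}"] = MPM_MEAN_OPTICS[wl]["mu_s_prime"]
        rows.append(row)
    return pd.DataFrame(rows)
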