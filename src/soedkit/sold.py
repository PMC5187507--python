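"""Singlet-oxygen luminescence: pulse response, gated histograms, lifetime fits.

After a short excitation pulse the singlet-oxygen concentration follows the
two-exponential rise-and-decay

    [1O2](t) = N sigma_A [S0] Phi_Delta * tau_Delta/(tau_t - tau_Delta)
               * (exp(-t/tau_t) - exp(-t/tau_Delta)),

and the cumulative phosphorescence count over one pulse is its integral
divided by the radiative lifetime tau_R = 1/k6:

    counts = N sigma_A [S0] Phi_Delta tau_Delta / tau_R.

The curve shape is unchanged when the two time constants are swapped and the
amplitude rescaled by their ratio, so a fit alone cannot tell which constant
is which; fitted results follow the labelling convention tau_Delta > tau_t
(which matches the in-solution values 9.4 us vs 0.43 us).

Histograms are time-correlated single-photon-counting records: uniform time
bins, integer counts, a per-bin detector gate mask, and a filter label
(1270 nm carries signal + background, 1210 nm background only; their
difference is the real-valued "net" histogram).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lmfit import Model, Parameters

__all__ = [
    "SoldHistogram",
    "SoldFitResult",
    "SoldCumulative",
    "SoldFitError",
    "pulse_response",
    "pulse_response_peak_time",
    "cumulative_counts",
    "subtract_background",
    "fit_pulse_response",
]

_FILTERS = {"1270", "1210", "net"}


class SoldFitError(RuntimeError):
    """Raised when a lifetime fit is degenerate or of unacceptable quality."""


def pulse_response(t, N, sigma_A, S0, Phi_Delta, tau_Delta, tau_t):
    """[1O2] signal versus time after a short pulse (uM-scale, arbitrary units).

    Vectorized over ``t`` (s).  Raises for tau_Delta == tau_t; the degenerate
    t*exp(-t/tau) limit is not modelled.
    """
    if tau_Delta <= 0 or tau_t <= 0:
        raise ValueError("lifetimes must be positive")
    if tau_Delta == tau_t:
        raise ValueError("degenerate model: tau_Delta == tau_t")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    amp = N * sigma_A * S0 * Phi_Delta
    return amp * tau_Delta / (tau_t - tau_Delta) * (
        np.exp(-t / tau_t) - np.exp(-t / tau_Delta)
    )


def pulse_response_peak_time(tau_Delta: float, tau_t: float) -> float:
    """Location of the pulse-response maximum."""
    if tau_Delta == tau_t:
        raise ValueError("degenerate model: tau_Delta == tau_t")
    return tau_Delta * tau_t / (tau_Delta - tau_t) * math.log(tau_Delta / tau_t)


def cumulative_counts(N, sigma_A, S0, Phi_Delta, tau_Delta, tau_R):
    """Integrated luminescence counts per pulse: N sigma_A S0 Phi_Delta tau_Delta/tau_R."""
    for name, v in [("N", N), ("sigma_A", sigma_A), ("S0", S0),
                    ("Phi_Delta", Phi_Delta), ("tau_Delta", tau_Delta), ("tau_R", tau_R)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return N * sigma_A * S0 * Phi_Delta * tau_Delta / tau_R


@dataclass
class SoldHistogram:
    """Gated photon-count histogram from the TCSPC module."""

    bin_edges: np.ndarray            # s, uniform
    counts: np.ndarray               # per bin; integers for raw filters
    filter_label: str                # "1270", "1210" or "net"
    gate_mask: np.ndarray = None     # True where the detector was on
    n_pulses: int = 1
    photons_per_pulse: float = 1.0   # N
    accumulation_s: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.filter_label not in _FILTERS:
            raise ValueError(f"filter_label must be one of {sorted(_FILTERS)}")
        widths = np.diff(self.bin_edges)
        if widths.size == 0 or np.any(widths <= 0):
            raise ValueError("bin_edges must be increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bins must be uniform")
        if self.counts.shape != (self.bin_edges.size - 1,):
            raise ValueError("counts length must match bins")
        if self.filter_label != "net" and np.any(self.counts < 0):
            raise ValueError("raw filter counts must be non-negative")
        if self.gate_mask is None:
            self.gate_mask = np.ones(self.counts.shape, dtype=bool)
        else:
            self.gate_mask = np.asarray(self.gate_mask, dtype=bool)
            if self.gate_mask.shape != self.counts.shape:
                raise ValueError("gate_mask length must match counts")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"bin_start_s": self.bin_edges[:-1], "counts": self.counts,
             "gate": self.gate_mask.astype(int)}
        ).to_csv(path, index=False)
        sidecar = {
            "filter": self.filter_label, "n_pulses": self.n_pulses,
            "photons_per_pulse": self.photons_per_pulse,
            "accumulation_s": self.accumulation_s, "bin_width_s": self.bin_width,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str) -> "SoldHistogram":
        df = pd.read_csv(path)
        meta = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"filter": "net", "bin_width_s": None}
        starts = df["bin_start_s"].values
        width = meta.get("bin_width_s") or (starts[1] - starts[0])
        edges = np.append(starts, starts[-1] + width)
        return cls(
            edges, df["counts"].values, meta.get("filter", "net"),
            df["gate"].values.astype(bool) if "gate" in df else None,
            n_pulses=meta.get("n_pulses", 1),
            photons_per_pulse=meta.get("photons_per_pulse", 1.0),
            accumulation_s=meta.get("accumulation_s", 0.0),
        )


@dataclass
class SoldFitResult:
    """Fitted pulse-response parameters (labelling convention tau_Delta > tau_t)."""

    amplitude: float                 # counts-scale factor for N sigma_A S0 Phi_Delta
    tau_Delta: float                 # s
    tau_t: float                     # s
    offset: float                    # counts
    amplitude_stderr: Optional[float] = None
    tau_Delta_stderr: Optional[float] = None
    tau_t_stderr: Optional[float] = None
    offset_stderr: Optional[float] = None
    redchi: Optional[float] = None
    n_bins: int = 0

    def __post_init__(self) -> None:
        if not (self.tau_Delta > self.tau_t > 0):
            raise ValueError("labelling convention requires tau_Delta > tau_t > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def curve(self, t) -> np.ndarray:
        """Fitted model evaluated at ``t`` (offset included)."""
        return self.offset + pulse_response(
            t, 1.0, 1.0, 1.0, self.amplitude, self.tau_Delta, self.tau_t
        )


@dataclass
class SoldCumulative:
    """Counts per accumulation window and their running total."""

    counts_per_accumulation: np.ndarray   # counts/s in each window
    cumulative_counts: np.ndarray
    treatment_time: float                 # s

    def __post_init__(self) -> None:
        self.counts_per_accumulation = np.asarray(self.counts_per_accumulation, dtype=float)
        self.cumulative_counts = np.asarray(self.cumulative_counts, dtype=float)
        if np.any(self.cumulative_counts < 0):
            raise ValueError("cumulative counts must be non-negative")
        if np.any(np.diff(self.cumulative_counts) < 0):
            raise ValueError("cumulative counts must be non-decreasing")


def subtract_background(h1270: SoldHistogram, h1210: SoldHistogram) -> SoldHistogram:
    """Per-bin difference of the signal (1270 nm) and background (1210 nm) filters."""
    if h1270.filter_label != "1270" or h1210.filter_label != "1210":
        raise ValueError("expected a (1270, 1210) filter pair")
    if not np.allclose(h1270.bin_edges, h1210.bin_edges, rtol=1e-12, atol=0.0):
        raise ValueError("histograms have mismatched binning")
    if not np.array_equal(h1270.gate_mask, h1210.gate_mask):
        raise ValueError("histograms have mismatched gate masks")
    return SoldHistogram(
        h1270.bin_edges,
        h1270.counts - h1210.counts,
        "net",
        h1270.gate_mask.copy(),
        n_pulses=h1270.n_pulses,
        photons_per_pulse=h1270.photons_per_pulse,
        accumulation_s=h1270.accumulation_s,
    )


def _initial_guesses(t, y, dt):
    """Deterministic starting values: tail log-slope for the slow lifetime,
    peak-position inversion for the fast one."""
    offset0 = float(np.median(y[-max(3, y.size // 10):]))
    y_net = y - offset0
    i_peak = int(np.argmax(y_net))
    peak = y_net[i_peak]
    # slow lifetime from the log-linear tail (counts above 5% of peak)
    tail = np.where(y_net[i_peak:] > 0.05 * peak)[0]
    i_hi = i_peak + (tail[-1] if tail.size else 0)
    if i_hi - i_peak >= 4:
        tt, yy = t[i_peak:i_hi], y_net[i_peak:i_hi]
        good = yy > 0
        slope = np.polyfit(tt[good], np.log(yy[good]), 1)[0]
        tau_slow = -1.0 / slope if slope < 0 else 4.0 * (t[i_peak] + dt)
    else:
        tau_slow = 4.0 * (t[i_peak] + dt)
    tau_slow = max(tau_slow, 3.0 * dt)
    # fast lifetime from the peak location t* = tD tt/(tD-tt) ln(tD/tt)
    t_peak = max(t[i_peak], dt)
    lo, hi = dt * 1e-3, 0.99 * tau_slow
    tau_fast = max(min(t_peak / 3.0, hi), lo)
    for _ in range(60):  # bisection on the monotone peak-time relation
        mid = 0.5 * (lo + hi)
        if pulse_response_peak_time(tau_slow, mid) < t_peak:
            lo = mid
        else:
            hi = mid
        tau_fast = 0.5 * (lo + hi)
    amp0 = max(float(np.sum(y_net) * dt / tau_slow), peak * 1e-3)
    return amp0, tau_slow, tau_fast, offset0


def fit_pulse_response(
    net: SoldHistogram,
    initial_guess: Optional[dict] = None,
    variance: Optional[np.ndarray] = None,
) -> SoldFitResult:
    """Levenberg–Marquardt fit of the pulse response plus a constant offset.

    Only gated bins enter the fit.  Weights follow the propagated Poisson
    variance of the background subtraction — pass ``variance`` as
    counts(1270) + counts(1210) per bin when available; otherwise
    ``|net| + 1`` is used — with a floor of one count.  The two fitted time
    constants are ordered so the larger is reported as tau_Delta.
    """
    mask = net.gate_mask
    t = net.bin_centers[mask]
    y = net.counts[mask]
    if t.size < 50:
        raise ValueError("need at least 50 valid (gated) bins")
    dt = net.bin_width
    if variance is None:
        var = np.abs(y) + 1.0
    else:
        var = np.asarray(variance, dtype=float)[mask]
    var = np.maximum(var, 1.0)

    # refuse fits with no discernible signal above the background level
    baseline = np.median(y)
    noise = math.sqrt(float(np.median(var)))
    if float(np.max(y) - baseline) < 5.0 * noise:
        raise SoldFitError("no significant signal above background; refusing to fit")

    amp0, tau_slow0, tau_fast0, offset0 = _initial_guesses(t, y, dt)
    if initial_guess:
        amp0 = initial_guess.get("amplitude", amp0)
        tau_slow0 = initial_guess.get("tau_Delta", tau_slow0)
        tau_fast0 = initial_guess.get("tau_t", tau_fast0)
        offset0 = initial_guess.get("offset", offset0)

    def model(t, amplitude, tau_slow, tau_fast, offset):
        if tau_slow == tau_fast:
            tau_fast = tau_fast * (1 - 1e-12)
        return offset + amplitude * tau_slow / (tau_fast - tau_slow) * (
            np.exp(-t / tau_fast) - np.exp(-t / tau_slow)
        )

    lm = Model(model)
    p = Parameters()
    p.add("amplitude", value=amp0, min=0.0)
    p.add("tau_slow", value=tau_slow0, min=dt * 1e-2, max=100 * t[-1])
    p.add("tau_fast", value=tau_fast0, min=dt * 1e-4, max=100 * t[-1])
    p.add("offset", value=offset0)
    result = lm.fit(y, p, t=t, weights=1.0 / np.sqrt(var), method="leastsq")
    if not result.success:
        raise SoldFitError(f"fit did not converge: {result.message}")

    vals = result.params
    taus = sorted([vals["tau_slow"].value, vals["tau_fast"].value])
    errs = dict(zip(
        [vals["tau_slow"].value, vals["tau_fast"].value],
        [vals["tau_slow"].stderr, vals["tau_fast"].stderr],
    ))
    tau_fast, tau_slow = taus
    for name in ("amplitude", "tau_slow", "tau_fast"):
        par = vals[name]
        span = (par.max - par.min) if np.isfinite(par.max) else par.value
        if par.value <= par.min + 1e-12 * abs(span) and name != "amplitude":
            raise SoldFitError(f"parameter {name} stuck at its bound")
    if tau_fast <= 0 or tau_slow / tau_fast < 1.0 + 1e-9:
        raise SoldFitError("fitted lifetimes are degenerate")
    amp_err = vals["amplitude"].stderr
    if amp_err is not None and amp_err > 0 and vals["amplitude"].value / amp_err < 5.0:
        raise SoldFitError("fitted amplitude is not significant (no usable signal)")
    slow_err = errs.get(tau_slow)
    if slow_err is not None and slow_err > 0.5 * tau_slow:
        raise SoldFitError("slow lifetime is unconstrained by the data")
    return SoldFitResult(
        amplitude=vals["amplitude"].value,
        tau_Delta=tau_slow,
        tau_t=tau_fast,
        offset=vals["offset"].value,
        amplitude_stderr=vals["amplitude"].stderr,
        tau_Delta_stderr=errs.get(tau_slow),
        tau_t_stderr=errs.get(tau_fast),
        offset_stderr=vals["offset"].stderr,
        redchi=result.redchi,
        n_bins=int(t.size),
    )
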