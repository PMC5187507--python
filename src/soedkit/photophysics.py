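"""Photophysical constants and closed-form parameter derivations for type-II PDT.

Canonical units throughout the package: concentrations in uM, time in s,
lengths in cm (wavelengths in nm), fluence rate in mW/cm^2, total fluence in
J/cm^2.  Unit conversions happen only at I/O boundaries.

The derivations implemented here are the standard macroscopic-model
relations: the specific oxygen consumption rate ``xi = Phi_Delta * sigma_A /
h_nu``, the singlet-oxygen lifetime ``1/tau_Delta = k6 + k7 [A]``, the
triplet lifetime ``1/tau_t = k2 (beta + [3O2])`` and its inverse, the
photosensitizer contribution to absorption ``mu_a = epsilon * c``, and the
partial-pressure conversion ``[3O2] (uM) = alpha * pO2 (mmHg)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "PhotophysicalParams",
    "compute_photon_energy",
    "absorption_cross_section",
    "compute_xi",
    "tau_delta_from_rates",
    "min_acceptor_concentration",
    "triplet_lifetime",
    "k2_from_triplet_lifetime",
    "mu_a_from_concentration",
    "pO2_to_concentration",
    "concentration_to_pO2",
    "photofrin_params",
    "load_params",
    "bundled_parameter_sets",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants in the package's unit system."""

    N_A: float = 6.022e23          # Avogadro's constant, mol^-1
    h: float = 6.62607015e-34      # Planck constant, J s
    c: float = 2.99792458e8        # speed of light, m/s
    alpha_O2: float = 1.3          # mmHg -> uM conversion for dissolved oxygen


CONSTANTS = PhysicalConstants()


def compute_photon_energy(wavelength: float) -> float:
    """Photon energy h*c/lambda expressed in mW·s (= 1e3 J).

    Parameters
    ----------
    wavelength : float
        Wavelength in nm, > 0.
    """
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    joules = CONSTANTS.h * CONSTANTS.c / (wavelength * 1e-9)
    return joules * 1e3  # J -> mW·s


def absorption_cross_section(epsilon: float) -> float:
    """Per-molecule absorption cross-section sigma_A = epsilon * 1e9 / N_A (cm^2).

    ``epsilon`` is the decadic extinction coefficient expressed in
    cm^-1 uM^-1; the 1e9 factor converts uM^-1 to the per-molecule scale.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    return epsilon * 1e9 / CONSTANTS.N_A


def compute_xi(Phi_Delta: float, epsilon: float, wavelength: float) -> float:
    """Specific oxygen consumption rate xi (cm^2 mW^-1 s^-1).

    xi = Phi_Delta * sigma_A / h_nu, i.e. singlet-oxygen quantum yield times
    the photon absorption rate per molecule per unit fluence rate.  This is
    the per-molecule form of the shorthand xi = Phi_Delta * (epsilon/h_nu).
    """
    if Phi_Delta < 0:
        raise ValueError(f"Phi_Delta must be non-negative, got {Phi_Delta}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    return Phi_Delta * absorption_cross_section(epsilon) / compute_photon_energy(wavelength)


def tau_delta_from_rates(k6: float, k7: float, A: float) -> float:
    """Singlet-oxygen lifetime 1/(k6 + k7*[A]) in s.

    k6 is the phosphorescence decay rate (s^-1), k7 the bimolecular quenching
    rate (uM^-1 s^-1) and A the quencher/acceptor concentration (uM).
    """
    if k6 < 0 or k7 < 0 or A < 0:
        raise ValueError("k6, k7, A must be non-negative")
    denom = k6 + k7 * A
    if denom <= 0:
        raise ValueError("k6 + k7*A must be positive")
    return 1.0 / denom


def min_acceptor_concentration(inv_tau_Delta_vivo: float, k7: float) -> float:
    """Lower bound on the in-vivo acceptor concentration (uM).

    Assuming the biological substrate quenches no faster than azide,
    [A] >= (1/tau_Delta_vivo) / k7.
    """
    if inv_tau_Delta_vivo <= 0:
        raise ValueError("inverse lifetime must be positive")
    if k7 <= 0:
        raise ValueError("k7 must be positive")
    return inv_tau_Delta_vivo / k7


def triplet_lifetime(k2: float, beta: float, O2: float) -> float:
    """Triplet-state lifetime 1/(k2*(beta + [3O2])) in s."""
    if k2 <= 0 or beta <= 0 or O2 < 0:
        raise ValueError("k2, beta must be positive and O2 non-negative")
    return 1.0 / (k2 * (beta + O2))


def k2_from_triplet_lifetime(tau_t: float, beta: float, O2: float) -> float:
    """Triplet oxygen-quenching rate k2 (uM^-1 s^-1) from a measured lifetime.

    Exact algebraic inverse of :func:`triplet_lifetime`.
    """
    if tau_t <= 0 or beta <= 0 or O2 < 0:
        raise ValueError("tau_t, beta must be positive and O2 non-negative")
    return 1.0 / (tau_t * (beta + O2))


def mu_a_from_concentration(epsilon: float, concentration: float) -> float:
    """Absorption coefficient (cm^-1) due to the photosensitizer alone."""
    if epsilon < 0 or concentration < 0:
        raise ValueError("epsilon and concentration must be non-negative")
    return epsilon * concentration


def pO2_to_concentration(pO2: float) -> float:
    """Convert oxygen partial pressure (mmHg) to concentration (uM)."""
    if pO2 < 0:
        raise ValueError(f"pO2 must be non-negative, got {pO2}")
    return CONSTANTS.alpha_O2 * pO2


def concentration_to_pO2(O2: float) -> float:
    """Inverse of :func:`pO2_to_concentration`."""
    if O2 < 0:
        raise ValueError(f"O2 must be non-negative, got {O2}")
    return O2 / CONSTANTS.alpha_O2


_POSITIVE_FIELDS = (
    "epsilon", "wavelength", "Phi_Delta", "beta", "delta", "sigma", "xi",
    "tau_Delta", "tau_t", "tau_R", "k1", "k2", "k4", "k6", "k7",
)


@dataclass
class PhotophysicalParams:
    """Rate constants and derived photophysics for one sensitizer/medium/wavelength.

    Any field may be absent (``None``); operations that need a missing field
    raise.  ``A`` (acceptor concentration, uM) and ``g`` (macroscopic oxygen
    supply rate, uM/s) may be zero; everything else must be positive when
    present.  Internal consistency is enforced where the defining relations
    close on themselves: tau_Delta vs (k6, k7, A), and beta vs (k2, k4).
    """

    epsilon: Optional[float] = None       # cm^-1 uM^-1
    wavelength: Optional[float] = None    # nm
    Phi_Delta: Optional[float] = None     # dimensionless
    beta: Optional[float] = None          # uM
    delta: Optional[float] = None         # uM
    sigma: Optional[float] = None         # uM^-1
    xi: Optional[float] = None            # cm^2 mW^-1 s^-1
    tau_Delta: Optional[float] = None     # s
    tau_t: Optional[float] = None         # s
    tau_R: Optional[float] = None         # s, 1/k6
    k1: Optional[float] = None            # s^-1
    k2: Optional[float] = None            # uM^-1 s^-1
    k4: Optional[float] = None            # s^-1
    k6: Optional[float] = None            # s^-1
    k7: Optional[float] = None            # uM^-1 s^-1
    A: Optional[float] = None             # uM, >= 0
    g: Optional[float] = None             # uM/s, >= 0 (in vivo only)
    label: str = ""

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("A", "g"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.k6 is not None and self.k7 is not None and self.A is not None:
            expected = tau_delta_from_rates(self.k6, self.k7, self.A)
            if self.tau_Delta is not None:
                rel = abs(self.tau_Delta - expected) / self.tau_Delta
                if rel >= 1e-9:
                    raise ValueError(
                        f"tau_Delta={self.tau_Delta} inconsistent with "
                        f"1/(k6+k7*A)={expected} (rel. {rel:.2e})"
                    )
        if self.k2 is not None and self.k4 is not None and self.beta is not None:
            rel = abs(self.beta - self.k4 / self.k2) / self.beta
            if rel >= 1e-9:
                raise ValueError(
                    f"beta={self.beta} inconsistent with k4/k2={self.k4 / self.k2}"
                )

    # -- convenience -------------------------------------------------------

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"parameter set {self.label!r} is missing {', '.join(missing)}"
            )

    @property
    def quencher_concentration(self) -> float:
        """[A] treated as 0 when unset (no quencher term)."""
        return 0.0 if self.A is None else self.A

    @property
    def supply_rate(self) -> float:
        """g treated as 0 when unset (no perfusion)."""
        return 0.0 if self.g is None else self.g

    def sigma_A(self) -> float:
        self.require("epsilon")
        return absorption_cross_section(self.epsilon)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None and v != ""}

    @classmethod
    def from_dict(cls, d: dict, label: str = "") -> "PhotophysicalParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known - {"units", "notes"}
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        kw = {}
        for k, v in d.items():
            if k not in known:
                continue
            if k != "label" and isinstance(v, str):
                # YAML 1.1 parses floats like "1.3e4" (unsigned exponent) as strings
                v = float(v)
            kw[k] = v
        kw.setdefault("label", label)
        return cls(**kw)


def _bundled_yaml() -> dict:
    with resources.files("soedkit.data").joinpath("photofrin.yaml").open() as fh:
        return yaml.safe_load(fh)


def bundled_parameter_sets() -> dict:
    """Raw bundled YAML (Photofrin parameter sets plus titration record)."""
    return _bundled_yaml()


def photofrin_params(key: str) -> PhotophysicalParams:
    """Load a bundled Photofrin parameter set.

    Keys: ``in_vitro_632`` (water/Intralipid phantom, 632 nm CW),
    ``in_vitro_523_meoh`` (MeOH solution, 523 nm pulsed),
    ``in_vivo_632`` and ``in_vivo_523`` (tissue).
    """
    data = _bundled_yaml()["parameter_sets"]
    if key not in data:
        raise KeyError(f"no bundled parameter set {key!r}; have {sorted(data)}")
    return PhotophysicalParams.from_dict(data[key], label=key)


def load_params(path: str) -> PhotophysicalParams:
    """Load a parameter set from a user YAML/JSON file (single mapping)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PhotophysicalParams.from_dict(d, label=str(path))
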