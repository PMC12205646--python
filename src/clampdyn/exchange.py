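"""Two-state fast-exchange relaxation model.

In the fast-exchange limit of two-site conformational exchange (k_ex >> Δω),
a single population-weighted resonance is observed and the effective
transverse relaxation rate measured in a CPMG experiment disperses with the
pulsing rate ν_CPMG as

    R₂(ν) = R₂,₀ + (R_ex / k_ex) · [1 − (4ν / k_ex) · tanh(k_ex / 4ν)]

(the Luz–Meiboom form), where R₂,₀ is the population-weighted intrinsic rate,
k_ex = k_AB + k_BA is the exchange rate constant, and the exchange amplitude

    R_ex = p_A · p_B · Δω²         [rad²·s⁻²]

collects the state populations p_A, p_B and the chemical-shift difference Δω
between the exchanging states.  R_ex / k_ex (in s⁻¹) is the exchange
contribution to R₂ in the slow-pulsing limit ν → 0; fast pulsing refocuses
the exchange broadening and R₂(ν → ∞) → R₂,₀.

This module is the pure model layer: closed-form evaluation, the
population/shift relations, and unit conversions.  Fitting lives in
:mod:`clampdyn.cpmg`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FastExchangeParams",
    "TwoStatePopulations",
    "CPMGGrid",
    "DEFAULT_F19_FIELD_MHZ",
    "r2_fast_exchange",
    "rex_from_populations",
    "population_from_shift",
    "ppm_to_rad_per_s",
    "rad_per_s_to_ppm",
    "rex_amplitude_to_plateau",
    "rex_plateau_to_amplitude",
]

#: Default ¹⁹F Larmor frequency (MHz) used for ppm ↔ rad·s⁻¹ conversion.
#: Corresponds to a 16.4 T spectrometer; override per-dataset when known.
DEFAULT_F19_FIELD_MHZ = 657.0

# Below this value of x = k_ex/(4ν) the dispersion factor 1 - tanh(x)/x is
# evaluated by series to avoid catastrophic cancellation (relative error of
# the truncated series < 1e-17 for x < 1e-4).
_SERIES_THRESHOLD = 1e-4


@dataclass(frozen=True)
class FastExchangeParams:
    """Parameters of the two-state fast-exchange dispersion model.

    Attributes
    ----------
    r2_0 : float
        Intrinsic transverse relaxation rate, s⁻¹ (population-weighted
        average over the two states). Must be >= 0.
    rex : float
        Exchange amplitude p_A·p_B·Δω², rad²·s⁻². Must be >= 0.
    kex : float
        Exchange rate constant k_AB + k_BA, s⁻¹. Must be > 0.
    """

    r2_0: float
    rex: float
    kex: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.r2_0) or self.r2_0 < 0:
            raise ValueError(f"r2_0 must be finite and >= 0, got {self.r2_0}")
        if not np.isfinite(self.rex) or self.rex < 0:
            raise ValueError(f"rex must be finite and >= 0, got {self.rex}")
        if not np.isfinite(self.kex) or self.kex <= 0:
            raise ValueError(f"kex must be finite and > 0, got {self.kex}")

    @property
    def rex_plateau(self) -> float:
        """Exchange contribution R_ex/k_ex to R₂ at ν → 0, in s⁻¹."""
        return self.rex / self.kex


@dataclass(frozen=True)
class TwoStatePopulations:
    """Steady-state populations and shift difference of two exchanging states.

    ``delta_omega`` is the chemical-shift difference between the states in
    rad·s⁻¹ (use :func:`ppm_to_rad_per_s` for ppm input).
    """

    p_a: float
    p_b: float
    delta_omega: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_a <= 1.0 and 0.0 <= self.p_b <= 1.0):
            raise ValueError(
                f"populations must lie in [0, 1], got p_a={self.p_a}, p_b={self.p_b}"
            )
        if abs(self.p_a + self.p_b - 1.0) > 1e-9:
            raise ValueError(
                f"populations must sum to 1, got {self.p_a + self.p_b}"
            )
        if not np.isfinite(self.delta_omega):
            raise ValueError("delta_omega must be finite")


@dataclass(frozen=True)
class CPMGGrid:
    """Grid of CPMG field strengths ν_CPMG = 1/(4·τ_CPMG).

    ``nu_cpmg`` must be strictly positive and strictly increasing.  When the
    inter-pulse delays ``tau_cpmg`` are given they must satisfy
    ν·4τ = 1 to within ``_TAU_RTOL`` relative tolerance.
    """

    nu_cpmg: np.ndarray
    tau_cpmg: np.ndarray | None = field(default=None)

    _TAU_RTOL = 1e-6

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_cpmg, dtype=float)
        object.__setattr__(self, "nu_cpmg", nu)
        if nu.ndim != 1 or nu.size == 0:
            raise ValueError("nu_cpmg must be a non-empty 1-D array")
        if np.any(nu <= 0):
            raise ValueError("all nu_cpmg must be > 0")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("nu_cpmg must be strictly increasing")
        if self.tau_cpmg is not None:
            tau = np.asarray(self.tau_cpmg, dtype=float)
            object.__setattr__(self, "tau_cpmg", tau)
            if tau.shape != nu.shape:
                raise ValueError("tau_cpmg must match nu_cpmg in length")
            if not np.allclose(nu * 4.0 * tau, 1.0, rtol=self._TAU_RTOL):
                raise ValueError("nu_cpmg and tau_cpmg violate nu = 1/(4 tau)")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return int(self.nu_cpmg.size)


def _dispersion_factor(x: np.ndarray) -> np.ndarray:
    """Evaluate g(x) = 1 - tanh(x)/x stably, with x = k_ex/(4ν) > 0.

    g is monotonically increasing from 0 (x → 0, fast pulsing) to 1
    (x → ∞, slow pulsing).  For small x the direct expression loses all
    significant digits, so the Taylor series g = x²/3 − 2x⁴/15 + O(x⁶)
    is used below ``_SERIES_THRESHOLD``.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < _SERIES_THRESHOLD
    xs = x[small]
    out[small] = xs * xs / 3.0 - 2.0 * xs**4 / 15.0
    xl = x[~small]
    out[~small] = 1.0 - np.tanh(xl) / xl
    return out


def r2_fast_exchange(
    params: FastExchangeParams, nu: float | np.ndarray
) -> float | np.ndarray:
    """Effective R₂ at CPMG field strength(s) ``nu`` (Hz), in s⁻¹.

    Implements R₂(ν) = R₂,₀ + (R_ex/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/(4ν))].
    Monotonically non-increasing in ν; R₂(ν→0) = R₂,₀ + R_ex/k_ex and
    R₂(ν→∞) = R₂,₀.

    Parameters
    ----------
    params : FastExchangeParams
    nu : float or array
        CPMG field strength(s) in Hz, all > 0.

    Returns
    -------
    float or ndarray matching the shape of ``nu``.
    """
    nu_arr = np.asarray(nu, dtype=float)
    if np.any(~np.isfinite(nu_arr)) or np.any(nu_arr <= 0):
        raise ValueError("nu must be finite and > 0")
    x = params.kex / (4.0 * nu_arr)
    r2 = params.r2_0 + (params.rex / params.kex) * _dispersion_factor(x)
    if np.isscalar(nu) or np.ndim(nu) == 0:
        return float(r2)
    return r2


def rex_from_populations(pop: TwoStatePopulations) -> float:
    """Exchange amplitude R_ex = p_A·p_B·Δω², rad²·s⁻².

    Symmetric under swapping the state labels; maximal at p_A = p_B = 1/2
    for fixed Δω.
    """
    return pop.p_a * pop.p_b * pop.delta_omega**2


def population_from_shift(
    delta_obs: float, delta_a: float, delta_b: float
) -> float:
    """Excited-state population from an exchange-averaged chemical shift.

    Inverts the fast-exchange weighted average
    δ_obs = p_A·δ_A + p_B·δ_B, returning p_B = (δ_obs − δ_A)/(δ_B − δ_A).
    All shifts in the same units (ppm).

    A result outside [0, 1] indicates the observed shift lies outside the
    two reference shifts (model inconsistency); a warning is emitted and the
    value is returned unchanged.

    Raises
    ------
    ValueError
        If ``delta_a == delta_b`` (degenerate reference shifts).
    """
    if delta_a == delta_b:
        raise ValueError("degenerate reference shifts: delta_a == delta_b")
    p_b = (delta_obs - delta_a) / (delta_b - delta_a)
    if not 0.0 <= p_b <= 1.0:
        warnings.warn(
            f"population {p_b:.4g} outside [0, 1]: observed shift is not "
            "bracketed by the reference shifts",
            stacklevel=2,
        )
    return p_b


def ppm_to_rad_per_s(
    shift_ppm: float, field_mhz: float = DEFAULT_F19_FIELD_MHZ
) -> float:
    """Convert a shift difference in ppm to rad·s⁻¹ at the given Larmor MHz."""
    if field_mhz <= 0:
        raise ValueError("field_mhz must be > 0")
    return 2.0 * np.pi * shift_ppm * field_mhz


def rad_per_s_to_ppm(
    delta_omega: float, field_mhz: float = DEFAULT_F19_FIELD_MHZ
) -> float:
    """Convert a shift difference in rad·s⁻¹ to ppm at the given Larmor MHz."""
    if field_mhz <= 0:
        raise ValueError("field_mhz must be > 0")
    return delta_omega / (2.0 * np.pi * field_mhz)


def rex_amplitude_to_plateau(rex: float, kex: float) -> float:
    """Convert the amplitude convention (R_ex in rad²·s⁻²) to the plateau
    convention: the ν→0 exchange contribution R_ex/k_ex in s⁻¹."""
    if kex <= 0:
        raise ValueError("kex must be > 0")
    return rex / kex


def rex_plateau_to_amplitude(plateau: float, kex: float) -> float:
    """Inverse of :func:`rex_amplitude_to_plateau`."""
    if kex <= 0:
        raise ValueError("kex must be > 0")
    return plateau * kex
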