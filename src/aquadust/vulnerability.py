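"""Hydraulic vulnerability curves: resistance as a function of water potential.

A vulnerability curve gives a tissue's flow resistance R(ψ) (m²·s·MPa·kg⁻¹,
leaf-area-normalized) as water potential drops.  It is parameterized by the
well-watered resistance R(ψ=0) = ``r_sat`` and ψ50, the potential at 50% loss
of conductance — equivalently a doubling of resistance.

Two sigmoid shapes are supported:

``log_logistic`` (default)
    R(ψ) = r_sat · (1 + (ψ/ψ50)^a), the resistance form of the standard
    conductance sigmoid K = Kmax / (1 + (ψ/ψ50)^a).  Resistance doubles at
    ψ50 exactly for any exponent ``a``; growth is polynomial, so series
    networks driven at fixed flux retain steady states deep into stress.

``exponential``
    R(ψ) = r_sat · (1 + exp(s·(ψ50 − ψ))) / (1 + exp(s·ψ50)), normalized so
    R(0) = r_sat exactly; resistance at ψ50 approaches 2·r_sat only in the
    sharp-slope limit, and the exponential growth caps the stress a
    fixed-flux network can sustain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError

#: default log-logistic exponent (dimensionless)
DEFAULT_EXPONENT = 1.2
#: default exponential rate, expressed as a multiple of 1/|psi50| (MPa^-1)
DEFAULT_RATE_FACTOR = 8.0


@dataclass(frozen=True)
class VulnerabilityCurve:
    """ψ-dependent hydraulic resistance with R(0) = r_sat exactly.

    Parameters
    ----------
    r_sat : float
        Resistance at ψ = 0, m²·s·MPa·kg⁻¹ (> 0).
    psi50 : float
        Potential at 50% loss of conductance (doubling of resistance), MPa (< 0).
    steepness : float, optional
        Shape steepness: the exponent ``a`` for ``log_logistic`` shape, or the
        rate ``s`` (MPa⁻¹) for ``exponential``.  Defaults: a = 1.2,
        s = 8/|psi50|.
    shape : str
        "log_logistic" (default) or "exponential".
    """

    r_sat: float
    psi50: float
    steepness: float | None = None
    shape: str = "log_logistic"

    def __post_init__(self):
        if not self.r_sat > 0:
            raise DomainError(f"r_sat must be > 0, got {self.r_sat}")
        if not self.psi50 < 0:
            raise DomainError(f"psi50 must be < 0 MPa, got {self.psi50}")
        if self.shape not in ("log_logistic", "exponential"):
            raise DomainError(f"unknown vulnerability shape {self.shape!r}")
        if self.steepness is not None and not self.steepness > 0:
            raise DomainError(f"steepness must be > 0, got {self.steepness}")

    @property
    def effective_steepness(self) -> float:
        if self.steepness is not None:
            return self.steepness
        if self.shape == "log_logistic":
            return DEFAULT_EXPONENT
        return DEFAULT_RATE_FACTOR / abs(self.psi50)

    def resistance(self, psi: float) -> float:
        """Resistance at water potential ``psi`` (MPa, ≤ 0).

        Potentials above saturation (ψ > 0, reachable only as nuisance
        boundary values during fitting) are clamped to the saturated
        resistance r_sat.
        """
        if not math.isfinite(psi):
            raise DomainError(f"psi must be finite, got {psi!r}")
        if psi >= 0.0:
            return self.r_sat
        k = self.effective_steepness
        if self.shape == "log_logistic":
            return self.r_sat * (1.0 + (psi / self.psi50) ** k)
        num = 1.0 + math.exp(min(k * (self.psi50 - psi), 700.0))
        den = 1.0 + math.exp(k * self.psi50)
        return self.r_sat * num / den

    def resistance_array(self, psi: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`resistance`."""
        psi = np.asarray(psi, dtype=float)
        out = np.empty_like(psi)
        for i, p in np.ndenumerate(psi):
            out[i] = self.resistance(p)
        return out

    def scaled(self, factor: float) -> "VulnerabilityCurve":
        """Curve with r_sat multiplied by ``factor`` (for prediction banding)."""
        if factor <= 0:
            raise DomainError(f"scale factor must be > 0, got {factor}")
        return replace(self, r_sat=self.r_sat * factor)

    def with_params(self, r_sat: float, psi50: float) -> "VulnerabilityCurve":
        """Copy with new (r_sat, psi50), keeping shape and steepness policy."""
        return replace(self, r_sat=r_sat, psi50=psi50)


#: literature maize leaf xylem vulnerability: R_xyl(0) = 3.47e3 m²·s·MPa·kg⁻¹,
#: ψ50 = −1.58 MPa
def literature_xylem_curve(shape: str = "log_logistic",
                           steepness: float | None = None) -> VulnerabilityCurve:
    return VulnerabilityCurve(r_sat=3.47e3, psi50=-1.58, shape=shape, steepness=steepness)
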