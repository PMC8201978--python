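"""Physics of the hydrogel FRET reporter.

A cross-linked polyacrylamide nanogel swells or collapses with the water
potential ψ of its local environment.  Flory–Rehner theory links the polymer
volume fraction φ at swelling equilibrium to ψ; isotropic swelling moves the
conjugated donor/acceptor dyes apart, and a distance-power energy-transfer law
turns the interdye separation into a relative FRET efficiency ζ.  Composing
the two gives the forward calibration curve ζ_th(ψ); the only free parameter
is the effective interdye separation in the fully swollen state, fixed by a
single in-situ calibration point near saturation.

Sign convention: ψ is in MPa and ≤ 0 for physiological states (0 at pure-water
saturation, negative under tension).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

from .errors import (
    CalibrationError,
    ConvergenceError,
    DomainError,
    OutOfRangeError,
    UncalibratedModelError,
)

GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1

#: tolerance (MPa) above 0 before a water potential is rejected as unphysical
PSI_TOL = 1e-9


def check_psi(psi: float, name: str = "psi") -> float:
    """Validate a water potential value (MPa, ≤ 0, finite)."""
    psi = float(psi)
    if not math.isfinite(psi):
        raise DomainError(f"{name} must be finite, got {psi!r}")
    if psi > PSI_TOL:
        raise DomainError(f"{name} must be <= 0 MPa for physiological states, got {psi}")
    return min(psi, 0.0)


@dataclass(frozen=True)
class GelComposition:
    """Composition of the polyacrylamide network at formation.

    Parameters
    ----------
    chi : float
        Flory–Huggins polymer–water interaction parameter (dimensionless).
    phi0 : float
        Polymer volume fraction at network formation (0 < phi0 < 1).
    n_chain : float
        Effective number of monomer units between cross-links (> 1).
    molar_volume_water : float
        Molar volume of water, m^3 mol^-1.
    temperature : float
        Absolute temperature, K.
    elastic_model : str
        "affine" (default) or "phantom" network elasticity.

    Notes
    -----
    The defaults place the swelling transition inside the physiological window
    0 > ψ > −3 MPa for this reporter design; they are a representative neutral
    polyacrylamide recipe, not a measured composition.
    """

    chi: float = 0.48
    phi0: float = 0.05
    n_chain: float = 100.0
    molar_volume_water: float = 1.805e-5
    temperature: float = 298.15
    elastic_model: str = "affine"

    def __post_init__(self):
        if not 0.0 < self.phi0 < 1.0:
            raise DomainError(f"phi0 must be in (0, 1), got {self.phi0}")
        if not 0.0 < self.chi < 1.0:
            raise DomainError(f"chi must be in (0, 1), got {self.chi}")
        if not self.n_chain > 1.0:
            raise DomainError(f"n_chain must be > 1, got {self.n_chain}")
        if not self.temperature > 0.0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if self.molar_volume_water <= 0.0:
            raise DomainError("molar_volume_water must be positive")
        if self.elastic_model not in ("affine", "phantom"):
            raise DomainError(f"elastic_model must be 'affine' or 'phantom', got {self.elastic_model!r}")

    @property
    def rt_over_vw_mpa(self) -> float:
        """RT / V̄w in MPa."""
        return GAS_CONSTANT * self.temperature / self.molar_volume_water / 1e6


@dataclass(frozen=True)
class FretGeometry:
    """Geometry of the donor–acceptor energy-transfer interaction.

    ``forster_radius`` (R0, nm) sets the 50%-transfer separation;
    ``plane_exponent`` is the distance power of the transfer law (4 for a
    dipole interacting with a plane of acceptors, 6 for point dipoles);
    ``sep_saturation`` (c, nm) is the effective interdye separation in the
    fully swollen gel — the single calibrated parameter, absent until
    calibration.
    """

    forster_radius: float = 5.4
    plane_exponent: int = 4
    sep_saturation: float | None = None

    def __post_init__(self):
        if self.forster_radius <= 0:
            raise DomainError(f"forster_radius must be > 0, got {self.forster_radius}")
        if self.plane_exponent < 2:
            raise DomainError(f"plane_exponent must be >= 2, got {self.plane_exponent}")
        if self.sep_saturation is not None and self.sep_saturation <= 0:
            raise DomainError(f"sep_saturation must be > 0 when set, got {self.sep_saturation}")


def gel_water_potential(phi: float, comp: GelComposition) -> float:
    """Water potential (MPa) of the gel at polymer volume fraction ``phi``.

    Flory–Rehner swelling equilibrium: the mixing contribution
    ln(1−φ) + φ + χφ² plus a network-elastic contribution, scaled by RT/V̄w.
    The affine elastic term is (φ0/n)·[(φ/φ0)^{1/3} − φ/(2φ0)]; the phantom
    variant drops the volume term and halves the stretch term (tetrafunctional
    junctions).
    """
    if not 0.0 < phi < 1.0:
        raise DomainError(f"phi must be in (0, 1), got {phi}")
    mixing = math.log1p(-phi) + phi + comp.chi * phi * phi
    stretch = (phi / comp.phi0) ** (1.0 / 3.0)
    if comp.elastic_model == "affine":
        elastic = (comp.phi0 / comp.n_chain) * (stretch - phi / (2.0 * comp.phi0))
    else:  # phantom
        elastic = (comp.phi0 / comp.n_chain) * 0.5 * stretch
    return comp.rt_over_vw_mpa * (mixing + elastic)


def saturation_phi(comp: GelComposition) -> float:
    """Polymer volume fraction at swelling equilibrium with pure water (ψ = 0)."""
    lo, hi = 1e-8, 1.0 - 1e-12
    f_lo = gel_water_potential(lo, comp)
    f_hi = gel_water_potential(hi, comp)
    if not (f_lo > 0.0 > f_hi):
        raise ConvergenceError(
            f"no saturation root in ({lo}, {hi}): psi({lo})={f_lo:.3e}, psi({hi})={f_hi:.3e}"
        )
    return brentq(lambda p: gel_water_potential(p, comp), lo, hi, xtol=1e-15, rtol=1e-15)


def equilibrium_phi(psi: float, comp: GelComposition, phi_sat: float | None = None) -> float:
    """Invert the swelling equilibrium: φ such that gel_water_potential(φ) = ψ.

    ``psi`` must be ≤ 0.  On the physical (collapsed) branch ψ is strictly
    decreasing in φ, so the root in [φ_sat, 1) is unique.
    """
    psi = check_psi(psi)
    if phi_sat is None:
        phi_sat = saturation_phi(comp)
    if psi == 0.0:
        return phi_sat
    hi = 1.0 - 1e-12
    f = lambda p: gel_water_potential(p, comp) - psi
    if f(hi) > 0.0:
        raise ConvergenceError(
            f"no root for psi={psi} MPa in bracket ({phi_sat}, {hi}); gel cannot collapse that far"
        )
    return brentq(f, phi_sat, hi, xtol=1e-15, rtol=1e-15)


def fret_efficiency_from_separation(r: float, geom: FretGeometry) -> float:
    """Relative FRET efficiency ζ = 1 / (1 + (r/R0)^m) for separation ``r`` (nm)."""
    if r <= 0:
        raise DomainError(f"separation r must be > 0 nm, got {r}")
    return 1.0 / (1.0 + (r / geom.forster_radius) ** geom.plane_exponent)


@dataclass(frozen=True)
class GelFretModel:
    """Composed swelling + energy-transfer model owning the calibration curve ζ_th(ψ).

    Immutable; :meth:`calibrate_single_point` returns a calibrated copy.
    """

    composition: GelComposition = field(default_factory=GelComposition)
    geometry: FretGeometry = field(default_factory=FretGeometry)

    @property
    def phi_saturation(self) -> float:
        """Equilibrium polymer fraction at ψ = 0 (cached per composition)."""
        return _phi_sat_cached(self.composition)

    @property
    def is_calibrated(self) -> bool:
        return self.geometry.sep_saturation is not None

    def _require_calibrated(self) -> float:
        c = self.geometry.sep_saturation
        if c is None:
            raise UncalibratedModelError(
                "sep_saturation is unset: calibrate the model (calibrate_single_point) first"
            )
        return c

    # -- forward pieces ----------------------------------------------------

    def interdye_separation(self, phi: float) -> float:
        """Interdye separation r(φ) = c · (φ_sat/φ)^{1/3} (nm): isotropic swelling."""
        c = self._require_calibrated()
        if phi <= 0:
            raise DomainError(f"phi must be > 0, got {phi}")
        return c * (self.phi_saturation / phi) ** (1.0 / 3.0)

    def zeta_theory(self, psi: float) -> float:
        """Theoretical relative FRET efficiency at water potential ``psi`` (MPa)."""
        psi = check_psi(psi)
        phi = equilibrium_phi(psi, self.composition, self.phi_saturation)
        r = self.interdye_separation(phi)
        return fret_efficiency_from_separation(r, self.geometry)

    # -- calibration and inversion ----------------------------------------

    def calibrate_single_point(self, zeta_obs: float, psi_cal: float = -0.08) -> "GelFretModel":
        """Fix the swollen-state interdye separation from one measurement.

        Solves ζ_th(psi_cal) = zeta_obs for c analytically and returns a new
        model; only ``sep_saturation`` changes.  ``psi_cal`` defaults to the
        near-saturation anchor −0.08 MPa.
        """
        psi_cal = check_psi(psi_cal, "psi_cal")
        if not 0.0 < zeta_obs < 1.0:
            raise CalibrationError(
                f"zeta_obs must lie strictly in (0, 1) to be reachable, got {zeta_obs}"
            )
        phi_cal = equilibrium_phi(psi_cal, self.composition, self.phi_saturation)
        geom = self.geometry
        # zeta = 1/(1+(r/R0)^m)  =>  r = R0 * (1/zeta - 1)^(1/m)
        r_cal = geom.forster_radius * (1.0 / zeta_obs - 1.0) ** (1.0 / geom.plane_exponent)
        c = r_cal * (phi_cal / self.phi_saturation) ** (1.0 / 3.0)
        return replace(self, geometry=replace(geom, sep_saturation=c))

    def invert_zeta(self, zeta: float, search_floor: float = -10.0) -> float:
        """Water potential (MPa) whose theoretical efficiency equals ``zeta``.

        Monotone inversion of ζ_th on [search_floor, 0] by bracketing root
        search; raises :class:`OutOfRangeError` with a direction-specific
        message when ``zeta`` is unattainable.
        """
        self._require_calibrated()
        search_floor = check_psi(search_floor, "search_floor")
        z0 = self.zeta_theory(0.0)
        zf = self.zeta_theory(search_floor)
        tol = 1e-12
        if zeta < z0 - tol:
            raise OutOfRangeError(
                f"zeta={zeta:.6g} below zeta_theory(0)={z0:.6g}: reading is wetter than saturation",
                kind="wetter_than_saturation",
                zeta=zeta,
            )
        if zeta > zf + tol:
            raise OutOfRangeError(
                f"zeta={zeta:.6g} above zeta_theory({search_floor})={zf:.6g}: "
                "reading is drier than the search floor",
                kind="drier_than_floor",
                zeta=zeta,
            )
        zeta = min(max(zeta, z0), zf)
        if zeta == z0:
            return 0.0
        if zeta == zf:
            return search_floor
        return brentq(lambda p: self.zeta_theory(p) - zeta, search_floor, 0.0,
                      xtol=1e-9, rtol=8.9e-16)

    # -- convenience -------------------------------------------------------

    @classmethod
    def reference(cls, zeta_cal: float = 0.25, psi_cal: float = -0.08,
                  composition: GelComposition | None = None,
                  geometry: FretGeometry | None = None) -> "GelFretModel":
        """A calibrated reporter model with default composition and geometry.

        The default anchor efficiency 0.25 sits in the near-saturation band of
        the reporter response; used as the generating truth in synthetic
        studies.
        """
        model = cls(composition=composition or GelComposition(),
                    geometry=geometry or FretGeometry())
        return model.calibrate_single_point(zeta_cal, psi_cal)


# cache of saturation fractions keyed by composition (frozen dataclass => hashable)
_PHI_SAT_CACHE: dict[GelComposition, float] = {}


def _phi_sat_cached(comp: GelComposition) -> float:
    try:
        return _PHI_SAT_CACHE[comp]
    except KeyError:
        _PHI_SAT_CACHE[comp] = saturation_phi(comp)
        return _PHI_SAT_CACHE[comp]
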