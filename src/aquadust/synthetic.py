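"""Synthetic inputs with the statistical structure of the field study.

Every pipeline stage can be exercised without downloads: Gaussian-band
emission spectra whose extracted relative FRET efficiency matches the
calibration curve at a prescribed ψ, gradient measurement tables with the
3 plants × 3 measurements replicate design and 0.067 MPa Gaussian scatter,
and hourly half-sinusoid transpiration traces peaking at the measured midday
rate.

What the generator emulates — and what it does not — is laid out in the
package methods note; peak widths are plausible fluorophore/chlorophyll
values chosen for band separability, not measured ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .gel import GelFretModel
from .hydraulics import (
    MEAN_TRANSPIRATION,
    LeafSegmentation,
    predict_sites,
    solve_steady_state,
)
from .spectra import EmissionSpectrum, SpectralBands
from .vulnerability import VulnerabilityCurve, literature_xylem_curve

#: replicate noise of the reporter against the pressure chamber, MPa
MEASUREMENT_NOISE_SD = 0.067


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumRecipe:
    """Gaussian-band recipe for a leaf emission spectrum.

    ``signal_to_background`` is the ratio of the donor-peak intensity to the
    chlorophyll autofluorescence peak (the study's infiltration concentration
    was chosen for a 10:1 ratio).
    """

    donor_center: float = 520.0
    donor_width: float = 15.0
    acceptor_center: float = 580.0
    acceptor_width: float = 18.0
    chlorophyll_center: float = 680.0
    chlorophyll_width: float = 25.0
    signal_to_background: float = 10.0
    total_amplitude: float = 1000.0
    noise_sd: float = 0.0
    grid_start: float = 500.0
    grid_stop: float = 800.0
    grid_step: float = 1.0

    def __post_init__(self):
        if self.signal_to_background <= 0:
            raise DomainError("signal_to_background must be > 0")
        if self.total_amplitude <= 0:
            raise DomainError("total_amplitude must be > 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + 0.5 * self.grid_step,
                         self.grid_step)


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _band_mean(grid: np.ndarray, profile: np.ndarray, center: float, hw: float) -> float:
    mask = (grid >= center - hw) & (grid <= center + hw)
    return float(profile[mask].mean())


def make_autofluorescence(recipe: SpectrumRecipe | None = None,
                          amplitude: float = 1.0) -> EmissionSpectrum:
    """Pure chlorophyll autofluorescence reference spectrum (no reporter)."""
    recipe = recipe or SpectrumRecipe()
    grid = recipe.grid
    return EmissionSpectrum(
        grid, amplitude * _gauss(grid, recipe.chlorophyll_center, recipe.chlorophyll_width),
        meta={"kind": "autofluorescence_reference"},
    )


def make_spectrum(
    psi: float,
    model: GelFretModel,
    recipe: SpectrumRecipe | None = None,
    bands: SpectralBands | None = None,
    rng: np.random.Generator | int | None = None,
    include_background: bool = True,
) -> EmissionSpectrum:
    """Synthetic leaf emission spectrum whose extracted ζ equals ζ_th(psi).

    Donor and acceptor amplitudes are solved from the band-mean response of
    the two Gaussians (including their cross-talk into each other's window)
    so that, after exact background subtraction, the band-ratio estimator
    recovers the calibration-curve efficiency.  The chlorophyll band is added
    at the recipe's signal-to-background ratio; i.i.d. Gaussian intensity
    noise with SD ``recipe.noise_sd`` is applied last.
    """
    recipe = recipe or SpectrumRecipe()
    bands = bands or SpectralBands()
    zeta = model.zeta_theory(psi)
    grid = recipe.grid
    donor = _gauss(grid, recipe.donor_center, recipe.donor_width)
    acceptor = _gauss(grid, recipe.acceptor_center, recipe.acceptor_width)
    hw = bands.half_window
    g_dd = _band_mean(grid, donor, bands.donor_center, hw)
    g_da = _band_mean(grid, donor, bands.acceptor_center, hw)
    g_ad = _band_mean(grid, acceptor, bands.donor_center, hw)
    g_aa = _band_mean(grid, acceptor, bands.acceptor_center, hw)
    # choose amplitudes (A_D, A_A) so that I_A / (I_A + I_D) = zeta, where
    # I_D = A_D g_dd + A_A g_ad and I_A = A_D g_da + A_A g_aa
    w_d = zeta * g_dd - (1.0 - zeta) * g_da
    w_a = (1.0 - zeta) * g_aa - zeta * g_ad
    if w_d <= 0 or w_a <= 0:
        raise DomainError(
            f"zeta={zeta:.4f} unreachable with this band geometry (cross-talk too strong)"
        )
    a_d, a_a = w_a, w_d
    scale = recipe.total_amplitude / (a_d + a_a)
    a_d, a_a = a_d * scale, a_a * scale
    signal = a_d * donor + a_a * acceptor
    intensity = signal.copy()
    if include_background:
        donor_peak = float(signal[np.argmin(np.abs(grid - recipe.donor_center))])
        a_chl = donor_peak / recipe.signal_to_background
        intensity = intensity + a_chl * _gauss(grid, recipe.chlorophyll_center,
                                               recipe.chlorophyll_width)
    if recipe.noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        intensity = intensity + rng.normal(0.0, recipe.noise_sd, size=grid.size)
    with warnings.catch_warnings():
        # detector-style clipping of noise in signal-free regions is intended
        warnings.simplefilter("ignore", UserWarning)
        return EmissionSpectrum(
            grid, intensity,
            meta={"psi_true_mpa": float(psi), "zeta_true": zeta,
                  "include_background": include_background},
        )


def intensity_noise_for_psi_sd(
    psi: float,
    model: GelFretModel,
    recipe: SpectrumRecipe | None = None,
    bands: SpectralBands | None = None,
    target_psi_sd: float = MEASUREMENT_NOISE_SD,
) -> float:
    """Per-point intensity noise SD that propagates to a given ψ-scale SD.

    First-order (delta-method) propagation: band means average ``n`` grid
    points, ζ = I_A/(I_A+I_D) carries the band noise, and the calibration
    curve slope dζ/dψ converts ζ scatter to ψ scatter.  Used to emulate
    replicate scatter of a stated magnitude (0.067 MPa by default).
    """
    recipe = recipe or SpectrumRecipe()
    bands = bands or SpectralBands()
    spec = make_spectrum(psi, model, recipe, bands=bands, include_background=False)
    from .spectra import band_intensity

    i_d = band_intensity(spec, bands.donor_center, bands.half_window)
    i_a = band_intensity(spec, bands.acceptor_center, bands.half_window)
    grid = recipe.grid
    n_pts = int(((grid >= bands.donor_center - bands.half_window)
                 & (grid <= bands.donor_center + bands.half_window)).sum())
    s = i_a + i_d
    # zeta SD per unit intensity SD (independent band means of n points each)
    zeta_per_intensity = np.sqrt(i_d**2 + i_a**2) / (s**2 * np.sqrt(n_pts))
    h = 1e-4
    dzeta_dpsi = (model.zeta_theory(psi + h) - model.zeta_theory(psi - h)) / (2 * h)
    target_zeta_sd = target_psi_sd * abs(dzeta_dpsi)
    return float(target_zeta_sd / zeta_per_intensity)


# ---------------------------------------------------------------------------
# gradient datasets
# ---------------------------------------------------------------------------

def _default_psi_base() -> dict:
    # WW at saturation; WL days of deepening soil-moisture stress (synthetic
    # stand-ins producing WL-like gradients, not measured boundary values)
    return {("WW", 1): 0.0, ("WL", 1): -0.2, ("WL", 2): -0.5, ("WL", 3): -0.9}


@dataclass(frozen=True)
class ScenarioTruth:
    """Generating truth for a gradient-study scenario.

    Defaults reproduce the study conditions: the fitted outside-xylem curve
    (R(0) = 3.7e3 m²·s·MPa/kg, ψ50 = −0.45 MPa), the literature xylem curve,
    mean steady transpiration 4.2e-5 kg·m⁻²·s⁻¹, replicate scatter SD
    0.067 MPa, and a 3 plants × 3 measurements design per site.
    """

    v_xyl: VulnerabilityCurve = field(default_factory=literature_xylem_curve)
    v_ox: VulnerabilityCurve = field(
        default_factory=lambda: VulnerabilityCurve(r_sat=3.7e3, psi50=-0.45)
    )
    psi_base: dict = field(default_factory=_default_psi_base)
    e_rate: float = MEAN_TRANSPIRATION
    noise_sd: float = MEASUREMENT_NOISE_SD
    n_plants: int = 3
    n_measurements: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.e_rate < 0 or self.noise_sd < 0:
            raise DomainError("e_rate and noise_sd must be >= 0")
        if self.n_plants < 1 or self.n_measurements < 1:
            raise DomainError("replicate design must have >= 1 plant and measurement")
        for key, pb in self.psi_base.items():
            if pb > 1e-9:
                raise DomainError(f"psi_base for {key} must be <= 0 MPa, got {pb}")


def make_gradient_dataset(
    truth: ScenarioTruth | None = None,
    seg: LeafSegmentation | None = None,
) -> pd.DataFrame:
    """Replicate gradient measurements from the forward model plus Gaussian noise.

    One row per (plant, measurement) per site per condition-day; ψ values are
    the solved per-segment outside-xylem potentials plus N(0, noise_sd),
    clipped at 0 MPa.  Deterministic given ``truth.seed``.
    """
    truth = truth or ScenarioTruth()
    seg = seg or LeafSegmentation()
    rng = np.random.default_rng(truth.seed)
    rows = []
    for (cond, day), pb in sorted(truth.psi_base.items(), key=lambda kv: str(kv[0])):
        state = solve_steady_state(truth.e_rate, pb, seg, truth.v_xyl, truth.v_ox)
        sites = predict_sites(state, seg)
        for si, name in enumerate(seg.site_names):
            for plant in range(truth.n_plants):
                for _ in range(truth.n_measurements):
                    noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "plant_id": f"P{plant + 1}",
                            "condition": cond,
                            "day": day,
                            "position": name,
                            "psi_mpa": min(sites[si] + noise, 0.0),
                            "seed": truth.seed,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diurnal transpiration traces
# ---------------------------------------------------------------------------

def make_diurnal_trace(
    e_peak: float = MEAN_TRANSPIRATION,
    sunrise: float = 6.0,
    sunset: float = 18.0,
    date: str = "2019-07-15",
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hourly transpiration trace: zero at night, half-sinusoid in daylight.

    Returns a table with ``time_iso`` and ``e_kg_m2_s`` columns.  Optional
    multiplicative Gaussian jitter (SD ``jitter_sd``, relative) emulates
    eddy-covariance scatter; values are floored at zero.
    """
    if not sunrise < sunset:
        raise DomainError("sunrise must precede sunset")
    hours = np.arange(24)
    e = np.zeros(24)
    day = (hours > sunrise) & (hours < sunset)
    e[day] = e_peak * np.sin(np.pi * (hours[day] - sunrise) / (sunset - sunrise))
    # include endpoints exactly at zero if sunrise/sunset fall on the grid
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        e = np.maximum(e * (1.0 + rng.normal(0.0, jitter_sd, size=e.size)), 0.0)
    times = pd.date_range(start=f"{date} 00:00", periods=24, freq="h")
    return pd.DataFrame({"time_iso": times.strftime("%Y-%m-%dT%H:%M:%S"),
                         "e_kg_m2_s": e})
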