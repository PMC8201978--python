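"""Quasi-steady soil–plant–atmosphere simulation of diurnal leaf water status.

Leaves re-equilibrate with their environment in ~15 minutes, far faster than
the hourly variation of canopy transpiration, so each time step of an hourly
transpiration trace is solved as an independent steady state of the segmented
leaf model.  Soil is taken as saturated (ψ_soil = 0) and root/stem resistance
negligible under well-watered field conditions, both overridable; the leaf
boundary potential at each step is ψ_soil − E·R_upstream.  A prediction band
is produced by re-solving with the low and high outside-xylem resistance
curves rather than by scaling outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DomainError, EmptyComparisonError
from .gel import check_psi
from .hydraulics import LeafSegmentation, predict_sites, solve_steady_state
from .vulnerability import VulnerabilityCurve, literature_xylem_curve


@dataclass(frozen=True)
class TranspirationTrace:
    """Ordered transpiration time series (kg·m⁻²·s⁻¹ per step)."""

    time: pd.DatetimeIndex
    e_rate: np.ndarray

    def __post_init__(self):
        time = pd.DatetimeIndex(self.time)
        e = np.asarray(self.e_rate, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "e_rate", e)
        if len(time) != len(e):
            raise DomainError("time and e_rate must have equal length")
        if len(time) == 0:
            raise DomainError("trace is empty")
        if not time.is_monotonic_increasing or time.has_duplicates:
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(e)) or np.any(e < 0):
            raise DomainError("e_rate values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TranspirationTrace":
        return cls(pd.to_datetime(df["time_iso"]), df["e_kg_m2_s"].to_numpy(float))

    @classmethod
    def from_csv(cls, path) -> "TranspirationTrace":
        return cls.from_frame(pd.read_csv(path))

    def fill_gaps(self, max_gap_hours: float = 2.0, freq: str = "h") -> "TranspirationTrace":
        """Regularize to ``freq`` steps, linearly interpolating gaps ≤ ``max_gap_hours``."""
        s = pd.Series(self.e_rate, index=self.time)
        gaps = s.index.to_series().diff().dt.total_seconds() / 3600.0
        if (gaps > max_gap_hours).any():
            worst = gaps.max()
            raise DomainError(
                f"trace has a {worst:.1f} h gap, larger than the {max_gap_hours} h "
                "interpolation limit"
            )
        s = s.resample(freq).mean().interpolate("time")
        return TranspirationTrace(s.index, s.to_numpy())


@dataclass(frozen=True)
class SpacConfig:
    """Configuration of the soil–plant–atmosphere chain above the leaf model."""

    v_ox: VulnerabilityCurve
    v_xyl: VulnerabilityCurve = field(default_factory=literature_xylem_curve)
    segmentation: LeafSegmentation = field(default_factory=LeafSegmentation)
    psi_soil: float = 0.0
    upstream_resistance: float = 0.0  # root + stem, m2 s MPa / kg
    rox_range: tuple[VulnerabilityCurve, VulnerabilityCurve] | None = None
    site: str = "tip"
    xylem_basis: str = "whole_leaf"

    def __post_init__(self):
        check_psi(self.psi_soil, "psi_soil")
        if self.upstream_resistance < 0:
            raise DomainError("upstream_resistance must be >= 0")
        if self.site not in self.segmentation.site_names:
            raise DomainError(
                f"site {self.site!r} not among {self.segmentation.site_names}"
            )

    @property
    def site_index(self) -> int:
        return self.segmentation.site_names.index(self.site)


@dataclass(frozen=True)
class DiurnalPrediction:
    """Per-step predicted potentials at the reported site, with optional band."""

    time: pd.DatetimeIndex
    psi_ox: np.ndarray
    psi_xyl: np.ndarray
    band_lo: np.ndarray | None
    band_hi: np.ndarray | None
    converged: np.ndarray
    site: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_iso": self.time.strftime("%Y-%m-%dT%H:%M:%S"),
                f"psi_ox_{self.site}_mpa": self.psi_ox,
                f"psi_xyl_{self.site}_mpa": self.psi_xyl,
                "converged": self.converged,
            }
        )
        if self.band_lo is not None:
            df["band_lo_mpa"] = self.band_lo
            df["band_hi_mpa"] = self.band_hi
        return df

    def plot(self, ax=None, obs: pd.DataFrame | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.band_lo is not None:
            ax.fill_between(self.time, self.band_lo, self.band_hi, alpha=0.3,
                            label="resistance-range band")
        ax.plot(self.time, self.psi_ox, "-", label=rf"$\psi_{{ox}}$ ({self.site})")
        if obs is not None:
            ax.plot(pd.to_datetime(obs["time_iso"]), obs["psi_mpa"], "ko", ms=4,
                    label="observed")
        ax.set_ylabel(r"$\psi$ (MPa)")
        ax.legend(fontsize=8)
        return ax


def _solve_step(e: float, cfg: SpacConfig, v_ox: VulnerabilityCurve):
    psi_base = cfg.psi_soil - e * cfg.upstream_resistance
    state = solve_steady_state(
        e, psi_base, cfg.segmentation, cfg.v_xyl, v_ox,
        xylem_basis=cfg.xylem_basis, validate=False,
    )
    i = cfg.site_index
    return predict_sites(state, cfg.segmentation)[i], state.psi_xyl[i]


def simulate_diurnal(trace: TranspirationTrace, cfg: SpacConfig) -> DiurnalPrediction:
    """Quasi-steady simulation: each step solved independently, no carried state.

    Steps whose steady state diverges (runaway vulnerability at that flux) are
    flagged non-converged and reported as NaN; the simulation continues.
    """
    n = len(trace)
    psi_ox = np.full(n, np.nan)
    psi_xyl = np.full(n, np.nan)
    converged = np.zeros(n, dtype=bool)
    lo = np.full(n, np.nan) if cfg.rox_range else None
    hi = np.full(n, np.nan) if cfg.rox_range else None
    for k, e in enumerate(trace.e_rate):
        try:
            psi_ox[k], psi_xyl[k] = _solve_step(e, cfg, cfg.v_ox)
            converged[k] = True
        except ConvergenceError:
            continue
        if cfg.rox_range is not None:
            vals = []
            for v in cfg.rox_range:
                try:
                    vals.append(_solve_step(e, cfg, v)[0])
                except ConvergenceError:
                    vals.append(np.nan)
            vals.append(psi_ox[k])
            lo[k] = np.nanmin(vals)
            hi[k] = np.nanmax(vals)
    return DiurnalPrediction(
        time=trace.time, psi_ox=psi_ox, psi_xyl=psi_xyl,
        band_lo=lo, band_hi=hi, converged=converged, site=cfg.site,
    )


def compare_trace(
    pred: DiurnalPrediction,
    obs: pd.DataFrame,
    window_minutes: float = 30.0,
) -> dict:
    """RMSE and band coverage of observations against a diurnal prediction.

    Observations (columns ``time_iso, psi_mpa``) are matched to the nearest
    prediction step within ``window_minutes``; unmatched observations are
    dropped.  Returns ``rmse`` (MPa), ``fraction_in_band`` (NaN when the
    prediction has no band) and ``n_matched``.
    """
    if "time_iso" not in obs.columns or "psi_mpa" not in obs.columns:
        raise DomainError("observations need columns time_iso, psi_mpa")
    t_obs = pd.to_datetime(obs["time_iso"])
    errors = []
    in_band = []
    for t, psi in zip(t_obs, obs["psi_mpa"].to_numpy(float)):
        dt = np.abs((pred.time - t).total_seconds())
        k = int(np.argmin(dt))
        if dt[k] > window_minutes * 60.0 or not pred.converged[k]:
            continue
        errors.append(psi - pred.psi_ox[k])
        if pred.band_lo is not None:
            in_band.append(pred.band_lo[k] - 1e-12 <= psi <= pred.band_hi[k] + 1e-12)
    if not errors:
        raise EmptyComparisonError(
            f"no observation within {window_minutes} min of a converged prediction step"
        )
    return {
        "rmse": float(np.sqrt(np.mean(np.square(errors)))),
        "fraction_in_band": float(np.mean(in_band)) if in_band else float("nan"),
        "n_matched": len(errors),
    }
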