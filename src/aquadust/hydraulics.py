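"""Segmented leaf hydraulic network: steady states and resistance-partition fitting.

The leaf blade is divided into ``n`` segments in series (node → mid → tip by
default).  Water enters the blade at potential ``psi_base``, flows axially
through ψ-dependent xylem resistances, and leaves each segment laterally
through a ψ-dependent outside-xylem (mesophyll) resistance driven by a uniform
transpiration flux density E.  Nanoreporter measurements correspond to the
outside-xylem potential ψ_ox of each segment, which lets the model separate
xylem from outside-xylem resistance when fitted to node/mid/tip water-potential
measurements across well-watered and water-limited conditions.

The statistical surface follows the Model/Results idiom:
:class:`LeafGradientModel` holds the data and fixed structure;
:meth:`LeafGradientModel.fit` returns a :class:`GradientFitResult` with the
fitted vulnerability parameters, anchored boundary potentials, residual
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConvergenceError, DomainError, IdentifiabilityError
from .gel import check_psi
from .vulnerability import VulnerabilityCurve, literature_xylem_curve

MEAN_TRANSPIRATION = 4.2e-5  # kg m^-2 s^-1, mean measured steady-state E
TRANSPIRATION_RANGE = 0.85e-5  # half-range around the mean

SITE_NAMES_3 = ("node", "mid", "tip")


# ---------------------------------------------------------------------------
# segmentation and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafSegmentation:
    """Division of the blade into series segments with measurement sites.

    ``site_positions`` are fractional positions along the blade used only for
    converting potential differences into MPa/m; site ``i`` reports segment
    ``i``'s outside-xylem potential.  ``leaf_length`` is in metres (default a
    1 m mature maize blade — an assumption flagged in gradient outputs).
    """

    n_segments: int = 3
    area_fractions: tuple[float, ...] | None = None
    site_positions: tuple[float, ...] | None = None
    leaf_length: float | None = 1.0

    def __post_init__(self):
        if self.n_segments < 1:
            raise DomainError(f"n_segments must be >= 1, got {self.n_segments}")
        af = self.area_fractions
        if af is None:
            af = tuple(1.0 / self.n_segments for _ in range(self.n_segments))
            object.__setattr__(self, "area_fractions", af)
        if len(af) != self.n_segments:
            raise DomainError("area_fractions length must equal n_segments")
        if any(a <= 0 for a in af):
            raise DomainError("area_fractions must be positive")
        if abs(sum(af) - 1.0) > 1e-12:
            raise DomainError(f"area_fractions must sum to 1, got {sum(af)}")
        sp = self.site_positions
        if sp is None:
            # segment midpoints: 1/6, 1/2, 5/6 for three equal segments
            edges = np.concatenate([[0.0], np.cumsum(af)])
            sp = tuple((edges[i] + edges[i + 1]) / 2.0 for i in range(self.n_segments))
            object.__setattr__(self, "site_positions", sp)
        if len(sp) != self.n_segments:
            raise DomainError("site_positions length must equal n_segments")
        if any(not 0.0 < p < 1.0 for p in sp) or any(
            sp[i] >= sp[i + 1] for i in range(len(sp) - 1)
        ):
            raise DomainError("site_positions must be strictly increasing in (0, 1)")
        if self.leaf_length is not None and self.leaf_length <= 0:
            raise DomainError("leaf_length must be positive when set")

    @property
    def site_names(self) -> tuple[str, ...]:
        if self.n_segments == 3:
            return SITE_NAMES_3
        return tuple(f"s{i}" for i in range(self.n_segments))

    @property
    def downstream_fractions(self) -> tuple[float, ...]:
        """Downstream-inclusive area fraction feeding each segment's axial resistor."""
        return tuple(float(x) for x in np.cumsum(self.area_fractions[::-1])[::-1])


@dataclass(frozen=True)
class LeafHydraulicState:
    """Solved steady state of the segmented leaf under transpiration ``e_rate``."""

    psi_base: float
    psi_xyl: np.ndarray  # MPa per segment (downstream node of each axial resistor)
    psi_ox: np.ndarray  # MPa per segment
    j_axial: np.ndarray  # kg m^-2 s^-1, leaf-area-normalized axial flux entering each segment
    lateral_flux: np.ndarray  # kg m^-2 s^-1 per segment (area-fraction weighted)
    e_rate: float

    def __post_init__(self):
        for name in ("psi_xyl", "psi_ox", "j_axial", "lateral_flux"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


# ---------------------------------------------------------------------------
# steady-state solver
# ---------------------------------------------------------------------------

_FP_TOL = 1e-10  # MPa
_FP_MAXITER = 20000


def _solve_downstream(psi_up: float, flux: float, res_fn: Callable[[float], float],
                      label: str) -> float:
    """Solve ψ + flux·R(ψ) = psi_up for the downstream potential ψ.

    Fixed-point iteration ψ ← psi_up − flux·R(ψ) starting at ψ = psi_up.
    Because R is non-increasing in ψ, the iterates decrease monotonically to
    the physical (upper-branch) root when one exists and run away otherwise;
    divergence means the vulnerability curve cannot sustain ``flux``.
    """
    if flux == 0.0:
        return psi_up
    floor = psi_up - 500.0
    x = psi_up
    for _ in range(_FP_MAXITER):
        x_new = psi_up - flux * res_fn(x)
        if x_new < floor:
            raise ConvergenceError(
                f"no steady state for {label}: runaway vulnerability at flux "
                f"{flux:.3e} kg/m2/s below psi_up={psi_up:.4g} MPa (last iterate {x:.4g})"
            )
        if abs(x_new - x) < _FP_TOL:
            return x_new
        x = x_new
    raise ConvergenceError(
        f"{label} potential did not converge within {_FP_MAXITER} iterations "
        f"(last iterate {x:.6g} MPa)"
    )


def solve_steady_state(
    e_rate: float,
    psi_base: float,
    seg: LeafSegmentation,
    v_xyl: VulnerabilityCurve,
    v_ox: VulnerabilityCurve | None,
    xylem_basis: str = "whole_leaf",
    validate: bool = True,
) -> LeafHydraulicState:
    """Steady state of the segmented leaf circuit under uniform transpiration.

    Axial drop over segment ``i`` uses the flux J_i = E·(downstream-inclusive
    area fraction) and the xylem resistance evaluated at the segment's solved
    ψ_xyl (downstream-node convention).  The lateral drop of segment ``i`` is
    E·R_ox(ψ_ox,i).  With ``xylem_basis="whole_leaf"`` (default) the printed
    whole-leaf R_xyl is divided equally among segments; ``"per_segment"``
    applies the full value to each segment.

    Passing ``v_ox=None`` disables the outside-xylem resistor (ψ_ox = ψ_xyl),
    the xylem-limited alternative model.
    """
    if e_rate < 0:
        raise DomainError(f"e_rate must be >= 0, got {e_rate}")
    if validate:
        psi_base = check_psi(psi_base, "psi_base")
    if xylem_basis not in ("whole_leaf", "per_segment"):
        raise DomainError(f"xylem_basis must be 'whole_leaf' or 'per_segment', got {xylem_basis!r}")
    n = seg.n_segments
    axial_div = float(n) if xylem_basis == "whole_leaf" else 1.0
    fracs = seg.downstream_fractions
    psi_xyl = np.empty(n)
    psi_ox = np.empty(n)
    prev = float(psi_base)
    for i in range(n):
        j_i = e_rate * fracs[i]
        psi_xyl[i] = _solve_downstream(
            prev, j_i, lambda p: v_xyl.resistance(p) / axial_div, f"xylem segment {i}"
        )
        if v_ox is None:
            psi_ox[i] = psi_xyl[i]
        else:
            psi_ox[i] = _solve_downstream(
                psi_xyl[i], e_rate, v_ox.resistance, f"outside-xylem segment {i}"
            )
        prev = psi_xyl[i]
    return LeafHydraulicState(
        psi_base=float(psi_base),
        psi_xyl=psi_xyl,
        psi_ox=psi_ox,
        j_axial=e_rate * np.asarray(fracs),
        lateral_flux=e_rate * np.asarray(seg.area_fractions),
        e_rate=float(e_rate),
    )


def predict_sites(state: LeafHydraulicState, seg: LeafSegmentation) -> np.ndarray:
    """Per-site outside-xylem potential: site ``i`` reports segment ``i``'s ψ_ox."""
    if len(state.psi_ox) != seg.n_segments:
        raise DomainError("state and segmentation disagree on segment count")
    return state.psi_ox.copy()


def gradient_mpa_per_m(site_psis: Sequence[float], seg: LeafSegmentation) -> float:
    """Node-to-tip potential gradient in MPa per metre of blade.

    (ψ_first − ψ_last) / (L·(pos_last − pos_first)); positive when the tip is
    drier than the node.
    """
    site_psis = np.asarray(site_psis, dtype=float)
    if site_psis.size < 2:
        raise DomainError("need at least two site values for a gradient")
    if seg.leaf_length is None:
        raise DomainError("leaf_length is not set on the segmentation; cannot convert to MPa/m")
    pos = seg.site_positions
    dz = seg.leaf_length * (pos[-1] - pos[0])
    return float((site_psis[0] - site_psis[-1]) / dz)


# ---------------------------------------------------------------------------
# gradient datasets
# ---------------------------------------------------------------------------

GRADIENT_COLUMNS = ("plant_id", "condition", "day", "position", "psi_mpa")


def validate_gradient_data(data: pd.DataFrame, seg: LeafSegmentation | None = None) -> pd.DataFrame:
    """Validate a gradient measurement table (one row per replicate measurement).

    Requires columns ``plant_id, condition, day, position, psi_mpa``; ψ ≤ 0;
    positions drawn from the segmentation's site names; and at least one node
    (first-site) record per condition-day, needed for boundary anchoring.
    """
    seg = seg or LeafSegmentation()
    missing = [c for c in GRADIENT_COLUMNS if c not in data.columns]
    if missing:
        raise DomainError(f"gradient data missing columns {missing}")
    names = set(seg.site_names)
    bad = set(data["position"]) - names
    if bad:
        raise DomainError(f"unknown positions {sorted(bad)}; expected {sorted(names)}")
    if (data["psi_mpa"] > 1e-9).any():
        raise DomainError("psi_mpa must be <= 0 MPa for all records")
    first = seg.site_names[0]
    for (cond, day), grp in data.groupby(["condition", "day"]):
        if not (grp["position"] == first).any():
            raise DomainError(
                f"condition-day ({cond}, {day}) has no {first!r} record for boundary anchoring"
            )
    return data


def read_gradient_csv(path) -> pd.DataFrame:
    return validate_gradient_data(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

DEFAULT_ROX_BOUNDS = ((1e2, 1e5), (-3.0, -0.05))  # (r_sat bounds, psi50 bounds)

#: the boundary potential is a nuisance parameter but stays physical: the
#: leaf-insertion xylem cannot be wetter than a saturated soil (ψ = 0), so
#: anchored values are capped at 0 and the chain re-solved forward when the
#: node mean is wetter than the curve allows at saturation
_PSI_BASE_CAP = 0.0


class LeafGradientModel:
    """Three-segment leaf hydraulic model fitted to node/mid/tip ψ measurements.

    Parameters
    ----------
    data : pandas.DataFrame
        Replicate measurements with columns
        ``plant_id, condition, day, position, psi_mpa``.
    e_rate : float
        Uniform steady transpiration flux density, kg·m⁻²·s⁻¹.
    segmentation : LeafSegmentation
    xylem : VulnerabilityCurve
        Fixed xylem vulnerability (literature values by default).
    xylem_only : bool
        If True, drop the outside-xylem resistor and fit the xylem curve
        instead (the xylem-limited alternative hypothesis).
    shape, steepness :
        Vulnerability shape used for the fitted curve.
    xylem_basis : str
        "whole_leaf" (default) or "per_segment" axial resistance basis.
    anchoring : str
        "ww_saturated" (default): well-watered condition-days use a saturated
        boundary (psi_base = 0, the assumption the diurnal field model makes
        for WW conditions), which makes the absolute well-watered drop
        observable and identifies the resistance scale; water-limited
        condition-days are anchored so the predicted node-site value matches
        that group's mean node measurement (no soil potential required).
        "node": node-mean anchoring for every condition-day.
        "free": boundary potentials enter the least squares as free nuisance
        parameters.
    """

    WW_LABEL = "WW"

    def __init__(
        self,
        data: pd.DataFrame,
        e_rate: float = MEAN_TRANSPIRATION,
        segmentation: LeafSegmentation | None = None,
        xylem: VulnerabilityCurve | None = None,
        xylem_only: bool = False,
        shape: str = "log_logistic",
        steepness: float | None = None,
        xylem_basis: str = "whole_leaf",
        anchoring: str = "ww_saturated",
    ):
        self.segmentation = segmentation or LeafSegmentation()
        self.data = validate_gradient_data(data.reset_index(drop=True), self.segmentation)
        self.e_rate = float(e_rate)
        self.xylem = xylem or literature_xylem_curve(shape=shape, steepness=steepness)
        self.xylem_only = bool(xylem_only)
        self.shape = shape
        self.steepness = steepness
        self.xylem_basis = xylem_basis
        if anchoring not in ("ww_saturated", "node", "free"):
            raise DomainError(
                f"anchoring must be 'ww_saturated', 'node' or 'free', got {anchoring!r}"
            )
        self.anchoring = anchoring
        # group bookkeeping
        self._groups = []
        for (cond, day), grp in self.data.groupby(["condition", "day"], sort=True):
            node_name = self.segmentation.site_names[0]
            node_mean = grp.loc[grp["position"] == node_name, "psi_mpa"].mean()
            site_idx = np.array(
                [self.segmentation.site_names.index(p) for p in grp["position"]]
            )
            self._groups.append(
                {
                    "key": (cond, day),
                    "node_mean": float(node_mean),
                    "site_idx": site_idx,
                    "psi": grp["psi_mpa"].to_numpy(float),
                    "rows": grp.index.to_numpy(),
                }
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "LeafGradientModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LeafGradientModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- forward machinery --------------------------------------------------

    def _curves(self, r_sat: float, psi50: float):
        """(v_xyl, v_ox) pair for candidate parameters."""
        fitted = VulnerabilityCurve(r_sat=r_sat, psi50=psi50, shape=self.shape,
                                    steepness=self.steepness)
        if self.xylem_only:
            return fitted, None
        return self.xylem, fitted

    def _solve(self, psi_base: float, v_xyl, v_ox) -> LeafHydraulicState:
        return solve_steady_state(
            self.e_rate, psi_base, self.segmentation, v_xyl, v_ox,
            xylem_basis=self.xylem_basis, validate=False,
        )

    def _anchored_group(self, node_mean: float, v_xyl, v_ox):
        """Site predictions and boundary potential anchored at the node mean.

        The chain is inverted upstream in closed form: the node segment's
        outside-xylem potential is set to the node mean, ψ_xyl,1 follows by
        adding the lateral drop, and psi_base by adding the first axial drop
        (resistances evaluated at their downstream nodes, matching the forward
        solver).  Segments 2..n are then solved downstream as usual.

        The boundary stays physical: when matching the node mean would require
        psi_base > 0 (wetter than saturated soil), the boundary is pinned at 0
        and the whole chain solved forward instead, leaving a node residual.
        """
        seg = self.segmentation
        axial_div = float(seg.n_segments) if self.xylem_basis == "whole_leaf" else 1.0
        fracs = seg.downstream_fractions
        e = self.e_rate
        n = seg.n_segments
        psi_ox = np.empty(n)
        psi_xyl = np.empty(n)
        if v_ox is None:
            psi_ox[0] = psi_xyl[0] = node_mean
        else:
            psi_ox[0] = node_mean
            psi_xyl[0] = node_mean + e * v_ox.resistance(node_mean)
        pb = psi_xyl[0] + e * fracs[0] * v_xyl.resistance(psi_xyl[0]) / axial_div
        if pb > _PSI_BASE_CAP:
            state = self._solve(_PSI_BASE_CAP, v_xyl, v_ox)
            return predict_sites(state, seg), _PSI_BASE_CAP
        for i in range(1, n):
            psi_xyl[i] = _solve_downstream(
                psi_xyl[i - 1], e * fracs[i],
                lambda p: v_xyl.resistance(p) / axial_div, f"xylem segment {i}"
            )
            if v_ox is None:
                psi_ox[i] = psi_xyl[i]
            else:
                psi_ox[i] = _solve_downstream(
                    psi_xyl[i], e, v_ox.resistance, f"outside-xylem segment {i}"
                )
        return psi_ox, pb

    def _predictions(self, r_sat: float, psi50: float,
                     psi_bases: dict | None = None):
        """Site predictions per condition-day group; returns (preds, bases)."""
        v_xyl, v_ox = self._curves(r_sat, psi50)
        preds, bases = {}, {}
        for grp in self._groups:
            key = grp["key"]
            if psi_bases is not None:
                pb = min(psi_bases[key], _PSI_BASE_CAP)
                state = self._solve(pb, v_xyl, v_ox)
                preds[key] = predict_sites(state, self.segmentation)
            elif self.anchoring == "ww_saturated" and key[0] == self.WW_LABEL:
                pb = 0.0
                state = self._solve(pb, v_xyl, v_ox)
                preds[key] = predict_sites(state, self.segmentation)
            else:
                preds[key], pb = self._anchored_group(grp["node_mean"], v_xyl, v_ox)
            bases[key] = pb
        return preds, bases

    def _objective(self, r_sat: float, psi50: float,
                   psi_bases: dict | None = None) -> tuple[float, dict]:
        try:
            preds, bases = self._predictions(r_sat, psi50, psi_bases)
        except ConvergenceError:
            return math.inf, {}
        sse = 0.0
        for grp in self._groups:
            resid = preds[grp["key"]][grp["site_idx"]] - grp["psi"]
            sse += float(resid @ resid)
        return sse, bases

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_ROX_BOUNDS,
        n_grid: int = 21,
        refine: bool = True,
        seed: int | None = None,
    ) -> "GradientFitResult":
        """Least-squares fit of (r_sat, psi50) by coarse grid then local refinement.

        The grid is log-spaced in r_sat and linear in psi50; refinement is
        derivative-free (Nelder–Mead in (log10 r_sat, psi50)).  Deterministic;
        ``seed`` is recorded for provenance of synthetic-data pipelines only.
        """
        (r_lo, r_hi), (p_lo, p_hi) = bounds
        n_params = 2 + (len(self._groups) if self.anchoring == "free" else 0)
        if len(self.data) < n_params:
            raise IdentifiabilityError(
                f"{len(self.data)} observations cannot identify {n_params} parameters"
            )
        trace: list[tuple[float, float, float]] = []

        def objective_anchored(r_sat, psi50):
            sse, _ = self._objective(r_sat, psi50)
            trace.append((r_sat, psi50, sse))
            return sse

        r_grid = np.geomspace(r_lo, r_hi, n_grid)
        p_grid = np.linspace(p_lo, p_hi, n_grid)
        cands = []
        for r in r_grid:
            for p in p_grid:
                cands.append((objective_anchored(r, p), r, p))
        cands.sort(key=lambda t: t[0])
        sse0, r0, p0 = cands[0]

        if self.anchoring == "free":
            result = self._fit_free(r0, p0, bounds, trace, refine)
        else:
            result = (r0, p0)
            if refine:
                def nm_obj(x):
                    r, p = 10.0 ** x[0], x[1]
                    if not (r_lo <= r <= r_hi and p_lo <= p <= p_hi):
                        return 1e30
                    return objective_anchored(r, p)

                # multi-start from the best grid points: the anchored objective
                # can carry a shallow ridge trading r_sat against psi50
                best_val = sse0
                for _, rs, ps in cands[:4]:
                    opt = minimize(nm_obj, x0=[math.log10(rs), ps], method="Nelder-Mead",
                                   options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 600})
                    if opt.fun < best_val:
                        best_val = float(opt.fun)
                        result = (10.0 ** opt.x[0], float(opt.x[1]))
        r_fit, p_fit = result
        sse, bases = self._objective(r_fit, p_fit)
        preds, _ = self._predictions(r_fit, p_fit, psi_bases=bases)

        resid_rows = []
        for grp in self._groups:
            pr = preds[grp["key"]][grp["site_idx"]]
            for row, p_hat, p_meas in zip(grp["rows"], pr, grp["psi"]):
                resid_rows.append((row, p_hat, p_meas - p_hat))
        resid_rows.sort()
        fitted_vals = np.array([r[1] for r in resid_rows])
        resids = np.array([r[2] for r in resid_rows])
        n_obs = len(resids)
        rmse = float(np.sqrt(np.mean(resids**2)))

        tol_r = 0.01 * (math.log10(r_hi) - math.log10(r_lo))
        at_bound = (
            math.log10(r_fit) - math.log10(r_lo) < tol_r
            or math.log10(r_hi) - math.log10(r_fit) < tol_r
            or p_fit - p_lo < 0.01 * (p_hi - p_lo)
            or p_hi - p_fit < 0.01 * (p_hi - p_lo)
        )
        curve = VulnerabilityCurve(r_sat=r_fit, psi50=p_fit, shape=self.shape,
                                   steepness=self.steepness)
        return GradientFitResult(
            model=self,
            curve=curve,
            psi_base=dict(bases),
            rmse=rmse,
            n_obs=n_obs,
            sse=float(sse),
            fittedvalues=fitted_vals,
            resid=resids,
            objective_trace=trace,
            bounds=bounds,
            boundary_warning=bool(at_bound),
            seed=seed,
        )

    def _fit_free(self, r0, p0, bounds, trace, refine):
        """Free-psi_base variant: boundary values join the simplex search."""
        (r_lo, r_hi), (p_lo, p_hi) = bounds
        keys = [g["key"] for g in self._groups]
        _, bases0 = self._objective(r0, p0)
        x0 = [math.log10(r0), p0] + [bases0.get(k, -0.1) for k in keys]

        def nm_obj(x):
            r, p = 10.0 ** x[0], x[1]
            if not (r_lo <= r <= r_hi and p_lo <= p <= p_hi):
                return 1e30
            pb = {k: min(v, _PSI_BASE_CAP) for k, v in zip(keys, x[2:])}
            sse, _ = self._objective(r, p, psi_bases=pb)
            trace.append((r, p, sse))
            return sse

        opt = minimize(nm_obj, x0=x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 2000})
        return 10.0 ** opt.x[0], float(opt.x[1])


@dataclass
class GradientFitResult:
    """Fitted resistance-partition parameters with diagnostics.

    ``curve`` is the fitted vulnerability curve (outside-xylem in the full
    model, xylem in the xylem-only alternative); ``psi_base`` maps each
    (condition, day) to its anchored boundary potential.
    """

    model: LeafGradientModel
    curve: VulnerabilityCurve
    psi_base: dict
    rmse: float
    n_obs: int
    sse: float
    fittedvalues: np.ndarray
    resid: np.ndarray
    objective_trace: list
    bounds: tuple
    boundary_warning: bool
    seed: int | None = None
    _bse: tuple[float, float] | None = field(default=None, repr=False)

    # spec-facing aliases -------------------------------------------------
    @property
    def r_sat(self) -> float:
        return self.curve.r_sat

    @property
    def psi50(self) -> float:
        return self.curve.psi50

    @property
    def rox_sat(self) -> float:
        if self.model.xylem_only:
            raise AttributeError("xylem-only fit has no outside-xylem resistance")
        return self.curve.r_sat

    @property
    def psi50_ox(self) -> float:
        if self.model.xylem_only:
            raise AttributeError("xylem-only fit has no outside-xylem psi50")
        return self.curve.psi50

    @property
    def rxyl_sat(self) -> float:
        if not self.model.xylem_only:
            raise AttributeError("full-model fit holds the xylem curve fixed")
        return self.curve.r_sat

    @property
    def psi50_xyl(self) -> float:
        if not self.model.xylem_only:
            raise AttributeError("full-model fit holds the xylem curve fixed")
        return self.curve.psi50

    # diagnostics ----------------------------------------------------------

    def bse(self) -> tuple[float, float]:
        """Approximate standard errors of (r_sat, psi50) from a finite-difference
        Gauss–Newton covariance; NaN when the Jacobian is degenerate."""
        if self._bse is not None:
            return self._bse
        m = self.model

        def pred_vector(r_sat, psi50):
            preds, _ = m._predictions(r_sat, psi50)
            return np.concatenate([preds[g["key"]][g["site_idx"]] for g in m._groups])

        theta = np.array([self.curve.r_sat, self.curve.psi50])
        steps = np.array([max(1e-4 * theta[0], 1.0), 1e-4])
        try:
            base = pred_vector(*theta)
            cols = [
                (pred_vector(*(theta + np.eye(2)[j] * steps[j])) - base) / steps[j]
                for j in range(2)
            ]
            J = np.column_stack(cols)
            dof = max(self.n_obs - 2, 1)
            sigma2 = self.sse / dof
            cov = sigma2 * np.linalg.inv(J.T @ J)
            self._bse = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
        except Exception:
            self._bse = (float("nan"), float("nan"))
        return self._bse

    def predict(self, condition: str, day) -> pd.DataFrame:
        """Predicted per-site ψ_ox for one fitted condition-day."""
        key = (condition, day)
        if key not in self.psi_base:
            raise DomainError(f"no fitted boundary potential for group {key}")
        v_xyl, v_ox = self.model._curves(self.curve.r_sat, self.curve.psi50)
        state = self.model._solve(self.psi_base[key], v_xyl, v_ox)
        seg = self.model.segmentation
        return pd.DataFrame(
            {
                "position": seg.site_names,
                "z_fraction": seg.site_positions,
                "psi_ox_mpa": predict_sites(state, seg),
                "psi_xyl_mpa": state.psi_xyl,
            }
        )

    def ww_gradient(self, e_rate: float | None = None, psi_base: float = 0.0) -> float:
        """Node-to-tip gradient (MPa/m) predicted under a saturated boundary."""
        m = self.model
        v_xyl, v_ox = m._curves(self.curve.r_sat, self.curve.psi50)
        state = solve_steady_state(
            e_rate if e_rate is not None else m.e_rate,
            psi_base, m.segmentation, v_xyl, v_ox, xylem_basis=m.xylem_basis,
        )
        return gradient_mpa_per_m(predict_sites(state, m.segmentation), m.segmentation)

    def rox_range_from_transpiration(
        self, e_half_range: float = TRANSPIRATION_RANGE
    ) -> tuple[VulnerabilityCurve, VulnerabilityCurve]:
        """Low/high outside-xylem curves implied by the transpiration range.

        The inferred resistance scales inversely with the assumed flux (the
        fitted drops E·R are pinned by the data), so the E range maps to a
        resistance range r_sat·E/(E ± ΔE).
        """
        if self.model.xylem_only:
            raise AttributeError("xylem-only fit has no outside-xylem curve to band")
        e = self.model.e_rate
        return (self.curve.scaled(e / (e + e_half_range)),
                self.curve.scaled(e / (e - e_half_range)))

    def simulate_diurnal(self, trace, psi_soil: float = 0.0,
                         upstream_resistance: float = 0.0,
                         with_band: bool = True, site: str = "tip"):
        """Quasi-steady diurnal prediction driven by a transpiration trace.

        ``trace`` is a :class:`~aquadust.diurnal.TranspirationTrace` (or a
        frame with ``time_iso, e_kg_m2_s``); the band, when requested, comes
        from :meth:`rox_range_from_transpiration`.
        """
        from .diurnal import SpacConfig, TranspirationTrace, simulate_diurnal

        if not isinstance(trace, TranspirationTrace):
            trace = TranspirationTrace.from_frame(trace)
        cfg = SpacConfig(
            v_ox=self.curve, v_xyl=self.model.xylem,
            segmentation=self.model.segmentation,
            psi_soil=psi_soil, upstream_resistance=upstream_resistance,
            rox_range=self.rox_range_from_transpiration() if with_band else None,
            site=site, xylem_basis=self.model.xylem_basis,
        )
        return simulate_diurnal(trace, cfg)

    def summary(self) -> str:
        role = "xylem (xylem-only model)" if self.model.xylem_only else "outside-xylem"
        se_r, se_p = self.bse()
        lines = [
            "Leaf hydraulic gradient fit",
            "=" * 60,
            f"fitted resistance:        {role}",
            f"vulnerability shape:      {self.curve.shape} (steepness {self.curve.effective_steepness:.4g})",
            f"R(psi=0)  [m2 s MPa/kg]:  {self.curve.r_sat:.4g}  (se {se_r:.3g})",
            f"psi50     [MPa]:          {self.curve.psi50:.4g}  (se {se_p:.3g})",
            f"n_obs:                    {self.n_obs}",
            f"rmse      [MPa]:          {self.rmse:.4g}",
            f"transpiration E:          {self.model.e_rate:.3g} kg/m2/s",
            f"boundary warning:         {self.boundary_warning}",
            "anchored boundary potentials (MPa):",
        ]
        for (cond, day), pb in sorted(self.psi_base.items(), key=lambda kv: str(kv[0])):
            lines.append(f"  {cond} day {day}: {pb:+.4f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "fitted_role": "xylem_only" if self.model.xylem_only else "outside_xylem",
            "r_sat": self.curve.r_sat,
            "psi50": self.curve.psi50,
            "shape": self.curve.shape,
            "steepness": self.curve.effective_steepness,
            "rmse": self.rmse,
            "n_obs": self.n_obs,
            "bounds": self.bounds,
            "boundary_warning": self.boundary_warning,
            "psi_base": {f"{c}|{d}": v for (c, d), v in self.psi_base.items()},
            "e_rate": self.model.e_rate,
            "xylem_basis": self.model.xylem_basis,
            "xylem_fixed": None if self.model.xylem_only else {
                "r_sat": self.model.xylem.r_sat, "psi50": self.model.xylem.psi50,
            },
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot(self, ax=None):
        """Measured vs predicted site potentials per condition-day."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        seg = self.model.segmentation
        for (cond, day), _ in sorted(self.psi_base.items(), key=lambda kv: str(kv[0])):
            pred = self.predict(cond, day)
            ax.plot(pred["z_fraction"], pred["psi_ox_mpa"], "--",
                    label=f"{cond} d{day} predicted")
            grp = self.model.data.query("condition == @cond and day == @day")
            pos = [seg.site_positions[seg.site_names.index(p)] for p in grp["position"]]
            ax.plot(pos, grp["psi_mpa"], "o", ms=4)
        ax.set_xlabel("fractional position along blade")
        ax.set_ylabel(r"$\psi_{ox}$ (MPa)")
        ax.legend(fontsize=7)
        return ax


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------

def fit_outside_xylem(
    data: pd.DataFrame,
    v_xyl: VulnerabilityCurve | None = None,
    e_rate: float = MEAN_TRANSPIRATION,
    seg: LeafSegmentation | None = None,
    bounds=DEFAULT_ROX_BOUNDS,
    seed: int | None = None,
    **model_kwargs,
) -> GradientFitResult:
    """Fit the outside-xylem vulnerability with the xylem curve held fixed."""
    model = LeafGradientModel(data, e_rate=e_rate, segmentation=seg,
                              xylem=v_xyl, xylem_only=False, **model_kwargs)
    return model.fit(bounds=bounds, seed=seed)


def xylem_only_fit(
    data: pd.DataFrame,
    e_rate: float = MEAN_TRANSPIRATION,
    seg: LeafSegmentation | None = None,
    bounds=DEFAULT_ROX_BOUNDS,
    seed: int | None = None,
    **model_kwargs,
) -> GradientFitResult:
    """Alternative hypothesis: no outside-xylem resistor, xylem curve free."""
    model = LeafGradientModel(data, e_rate=e_rate, segmentation=seg,
                              xylem_only=True, **model_kwargs)
    return model.fit(bounds=bounds, seed=seed)
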