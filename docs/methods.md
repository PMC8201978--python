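# Methods

This note documents the models implemented in `aquadust`, the defaults and
why they were chosen, the numerics, and what the synthetic-data pipeline does
and does not establish.

## Reporter physics

### Swelling equilibrium

The nanoreporter is a neutral polyacrylamide gel. Its equilibrium polymer
volume fraction φ at water potential ψ follows Flory–Rehner theory: the
osmotic balance of a mixing term and a network-elastic term,

ψ(φ) = (RT/V̄w)·[ln(1−φ) + φ + χφ²]
     + (RT/V̄w)·(φ₀/n)·[(φ/φ₀)^{1/3} − φ/(2φ₀)],

converted to MPa. `elastic_model="affine"` (default) includes the φ/(2φ₀)
volume term; `"phantom"` drops it and halves the stretch term
(tetrafunctional junctions). The canonical affine form is standard for
polyacrylamide; the package treats the variant as configurable because the
detailed free-energy bookkeeping differs between texts.

Default composition: χ = 0.48, φ₀ = 0.05, n = 100 monomers between
cross-links, T = 298.15 K, V̄w = 1.805×10⁻⁵ m³/mol. These are a
representative neutral-gel recipe, not measured values; they place the
swelling transition across the physiological window (φ goes from ≈0.069 at
saturation to ≈0.35 at −3 MPa), which is the design requirement for a
reporter that must resolve 0 > ψ > −3 MPa. Temperature and pH dependence are
deliberately not modelled (χ constant): the gel chemistry is chosen for
insensitivity to both, and the package treats that as a model invariance.

ψ(φ) is strictly decreasing on the physical branch φ ≥ φ_sat, so both
`saturation_phi` (root of ψ = 0) and `equilibrium_phi` (root of ψ = target)
are bracketed Brent solves at machine precision; the forward/inverse residual
is < 10⁻⁹ MPa.

### Energy transfer and calibration

Swelling is isotropic, so the effective donor–acceptor separation scales as
r(φ) = c·(φ_sat/φ)^{1/3} with c the separation in the fully swollen state.
Transfer efficiency uses a distance-power law ζ = 1/(1 + (r/R₀)^m) with
m = 4 by default — the distance exponent for a dipole interacting with a
plane of acceptors, appropriate when acceptors decorate the gel mesh around
a donor; m = 6 (point dipole) is available for sensitivity analysis.
R₀ = 5.4 nm is a typical Förster radius for a green/yellow dye pair. Only
the ratio r/R₀ enters, so rescaling R₀ and c together leaves the calibration
curve unchanged (tested property).

The single-point calibration solves ζ_th(ψ_cal) = ζ_obs for c in closed form
(default anchor ψ_cal = −0.08 MPa, the wettest practical pressure-chamber
point). `invert_zeta` inverts the strictly monotone ζ_th by Brent's method on
[search_floor, 0] (floor −10 MPa), with out-of-range readings classified as
"wetter than saturation" or "drier than floor".

`GelFretModel.reference()` (anchor efficiency 0.25 at −0.08 MPa) is the
calibrated truth model used by the synthetic pipeline; with the default
composition it spans ζ ≈ 0.22 at saturation to ≈ 0.71 at −3 MPa, comfortably
above the 0.2 sensitivity-window floor asserted in the tests.

## Spectrum processing

Band intensities are means over ±5 nm windows at 520 nm (donor) and 580 nm
(acceptor) — robust to 1-nm grid jitter, unlike a single-point maximum.
ζ_exp = I_A/(I_A + I_D): bounded, monotone in the acceptor/donor ratio. This
is one member of the family of ratiometric definitions; the single-point
calibration absorbs its scale (but not shape — a caveat documented here
rather than hidden). Chlorophyll autofluorescence is removed by subtracting a
reference autofluorescence spectrum scaled to match the sample over
700–750 nm, where reporter emission is negligible. Negative intensities after
subtraction are clipped to zero and counted; a warning fires above 5% of
points (float-epsilon undershoot is ignored).

Uncertainty: `estimate_potential` perturbs the raw spectrum with additive
i.i.d. Gaussian intensity noise, re-extracts and re-inverts ζ over `n_draws`
(default 1000, minimum 200) replicates, and reports the 2.5/97.5 percentile
interval. With intensity noise tuned (first-order propagation, implemented in
`intensity_noise_for_psi_sd`) so the ψ-scale scatter is 0.067 MPa — the
replicate scatter of the reporter against the pressure chamber — the interval
half-width is ≈1.96·0.067 ≈ 0.13 MPa, consistent with the ±0.14 MPa
uncertainty quoted for the measurement; the tests check this as a consistency
band, not an equality.

## Leaf hydraulic network

### Vulnerability curves

Resistance rises as the tissue dries. Both tissues use the log-logistic
form — the resistance version of the standard conductance sigmoid
K = K_max/(1 + (ψ/ψ₅₀)^a):

R(ψ) = R(0) · (1 + (ψ/ψ₅₀)^a),

which satisfies R(0) exactly and doubles exactly at ψ₅₀ for any exponent.
The exponent defaults to a = 1.2. That choice is structural, made once
against three observed behaviors the model must reproduce simultaneously:
(i) with the fitted outside-xylem values (R(0) = 3.7×10³ m²·s·MPa/kg,
ψ₅₀ = −0.45 MPa) the network must possess steady states at mean
transpiration deep into water-limited conditions — polynomially growing
resistance allows this, whereas an exponentially growing (sharp-logistic)
curve loses all steady states below ψ_base ≈ −0.2 MPa because the lateral
equation ψ_ox + E·R_ox(ψ_ox) = ψ_xyl folds; (ii) the predicted well-watered
node-to-tip gradient must land in the measured 0.11–0.22 MPa/m range (it is
≈0.124 MPa/m at a = 1.2); (iii) water-limited drops must amplify several-fold
over well-watered ones. The exponential-logistic shape (normalized so
R(0) = r_sat, rate 8/|ψ₅₀| by default) remains available via
`shape="exponential"`; its slope→0 limit is a constant resistance, which the
solver tests use to disable vulnerability.

The xylem curve is fixed at literature maize values:
R_xyl(0) = 3.47×10³ m²·s·MPa/kg, ψ₅₀ = −1.58 MPa.

### Steady state

The blade is n = 3 equal-area segments in series (node, mid, tip), sites at
fractions 1/6, 1/2, 5/6 of a 1 m blade (the length matters only for the
MPa/m conversion and is flagged as an assumption). The axial flux entering
segment i is J_i = E·(downstream-inclusive area fraction); the whole-leaf
R_xyl is divided equally among segments (`xylem_basis="whole_leaf"`;
`"per_segment"` applies the full value per segment). Resistances are
evaluated at their downstream node. Each segment equation
ψ + flux·R(ψ) = ψ_upstream is solved by damped-free fixed-point iteration
ψ ← ψ_up − flux·R(ψ): because R is non-increasing in ψ the iterates decrease
monotonically to the physical upper-branch root when one exists and run away
otherwise, which the solver reports as a runaway-vulnerability divergence
with the last iterate (tolerance 10⁻¹⁰ MPa). The chain is feed-forward, so
the full network needs no global iteration. Mass balance (Σ lateral fluxes
= E) holds to 10⁻¹² relative by construction and is asserted.

A known regime boundary: at the top of the measured transpiration range
(5.05×10⁻⁵ kg·m⁻²·s⁻¹) the deepest water-limited scenario has no steady
state — a physical consequence of fixing the flux while the mesophyll
resistance runs away, reported as a divergence (and as per-step flags in the
diurnal simulator), not hidden.

### Fitting the resistance partition

`LeafGradientModel.fit()` minimizes the sum of squared differences between
per-site predictions and every replicate measurement over
(R_ox(0), ψ₅₀ox), xylem curve fixed. Boundary potentials per condition-day
are nuisance values. Three anchoring policies are implemented:

- `"ww_saturated"` (default): well-watered groups use ψ_base = 0 — the
  saturated-soil, negligible-upstream-resistance assumption the diurnal SPAC
  model itself makes for well-watered field conditions; water-limited groups
  are anchored so the predicted node-site value equals the group's mean node
  measurement (no soil-potential knowledge required).
- `"node"`: node-mean anchoring for all groups.
- `"free"`: boundary values join the least squares as free parameters.

The default exists because pure node anchoring leaves the problem
structurally under-identified: a uniform lateral drop shifts all sites of a
group equally and is absorbed by that group's boundary value, so the two
curve parameters degenerate along r/|ψ₅₀|^a ≈ const and the estimator
becomes bimodal under replicate noise. Pinning the well-watered boundary at
saturation makes the absolute well-watered drop observable and restores
identifiability; with it, 20-replicate median recovery is stable (ψ₅₀ within
a few hundredths of a MPa, R(0) within a few percent). In all policies the
anchored boundary is capped at 0 MPa — the leaf base cannot be wetter than
saturated soil — and when the cap binds the chain is solved forward from 0,
leaving an informative node residual. Node anchoring is computed in closed
form by inverting the chain upstream from the node mean.

The optimizer is deterministic: a 21×21 grid (log-spaced R(0) over
[10², 10⁵], linear ψ₅₀ over [−3, −0.05]) followed by Nelder–Mead refinement
in (log₁₀R, ψ₅₀) from the four best grid points (the objective can carry a
shallow ridge; multi-start costs little). Fits at the search bounds set a
boundary warning. Standard errors come from a finite-difference Gauss–Newton
covariance and should be read as local curvature only — the profile between
the parameters is genuinely shallow, which is the package's honest answer to
how well two vulnerability parameters can be pinned by one campaign; the
`"node"` policy exposes the un-repaired problem for methodological study.

The xylem-only alternative (`xylem_only=True`) removes the outside-xylem
resistor, reports ψ_xyl at the sites, and frees the xylem parameters. On
data carrying the outside-xylem signature its residual error exceeds the
full model's — the model-comparison property mirroring the rejection of the
xylem-limited hypothesis.

## Diurnal quasi-steady SPAC

Leaves equilibrate in ~15 min, much faster than hourly forcing, so each step
of an hourly transpiration trace is solved as an independent steady state
with ψ_base = ψ_soil − E·R_upstream (defaults: ψ_soil = 0, R_upstream = 0 for
well-watered field conditions). No state carries between steps; halving the
step of a piecewise-constant trace changes nothing (tested). The prediction
band re-solves with low/high outside-xylem curves rather than scaling
outputs; the default band maps the measured transpiration half-range
±0.85×10⁻⁵ onto resistance factors E/(E±ΔE), since the inferred resistance
scales inversely with the assumed flux. Observations are matched to the
nearest step within 30 min; traces with gaps ≤ 2 h may be linearly
interpolated, larger gaps are an error.

## Synthetic data: what it emulates, what it does not

Spectra are sums of Gaussian bands (donor 520/15 nm, acceptor 580/18 nm,
chlorophyll 680/25 nm — plausible widths chosen for band separability, not
measurements), with donor/acceptor amplitudes solved from the band-response
matrix so the extracted ζ equals ζ_th(ψ) exactly after background
subtraction; the chlorophyll amplitude sets a 10:1 signal-to-background peak
ratio and per-point Gaussian intensity noise is added last. Gradient
campaigns apply N(0, 0.067 MPa) scatter to forward-model site values over a
3 plants × 3 measurements design for one well-watered day and three
water-limited days (boundary potentials 0, −0.2, −0.5, −0.9 MPa — the
water-limited values are stand-ins producing realistic stress progressions,
not measured boundaries). Transpiration traces are half-sinusoids peaking at
4.2×10⁻⁵ kg·m⁻²·s⁻¹ at noon.

Passing tests on these data demonstrate internal consistency — estimator,
solver and fit recover what the generators encode under the stated noise —
not field validity: real spectra have non-Gaussian lineshapes, bleaching and
cross-excitation; real replicate scatter is not exactly Gaussian or
homoscedastic; real leaves violate uniform-E and uniform-vulnerability
assumptions; and the well-watered boundary is only approximately saturated.

## Problem sizes

The default test suite uses 50 refit replicates for the recovery property,
200 spectra × 300 draws for CI coverage, and 20 seeded campaigns in the
acceptance experiment — sizes chosen to keep the full suite in single-digit
minutes on one CPU while leaving the stochastic assertions' sampling error
well inside their tolerance bands.

## Known limitations

- The exact spectral ζ definition and the detailed swelling free energy are
  dialect choices; both are configurable and documented rather than asserted.
- (R_ox(0), ψ₅₀ox) are jointly weakly identified by a single campaign; the
  package's default anchoring repairs this with a physically motivated
  constraint, and medians over seeded replicates are the recommended
  estimator for simulation studies.
- The circuit treats vulnerability as uniform along the blade and E as
  spatially uniform and constant within a step.
- No capacitance: sub-step transients and hysteresis are out of scope.
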