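# Methods

## Model

A cell of the riparian corridor is described by its dimensionless
elevation η (stages and elevations are scaled as h = (h* − h̄*)/h̄* with
h̄* the mean water stage in metres) and carries a dimensionless biomass
ν ∈ [0, β].  Time is rescaled by the vegetation growth rate, t = ω t*
(ω in day⁻¹), so that the biomass obeys the two-phase dynamics

    dν/dt = ν^m (β − ν)^p      when h < η   (exposure; default m = p = 1)
    dν/dt = −α ν^n             when h ≥ η   (inundation; default n = 1)

Assumptions inherited from the minimalist modelling tradition: a single
biomass variable (no interspecies interaction), a fixed river morphology,
and no lag between river stage and the adjacent water table.  Phase
durations are idealized as independent exponentials with means τ_E and
τ_I; the integral scale of the alternation is their harmonic combination,
1/τ = 1/τ_E + 1/τ_I, and the fraction of time inundated is
P_I = τ_I/(τ_E + τ_I).  Equivalently τ_E = τ/P_I and τ_I = τ/(1 − P_I).
The empirical run-length distributions of a real (or autocorrelated
synthetic) stage series are *not* exponential; only their means enter the
model.  This idealization is what makes a closed-form stationary law
possible, and its adequacy is checked empirically (see Validation).

### Stationary law

For the default exponents the stationary density follows from the
zero-flux solution of the two-state master equation.  Writing the two
phase velocities f_E = ν(β−ν), f_I = −αν and switching rates 1/τ_E, 1/τ_I,
the flux-free stationary density is

    p(ν) ∝ (1/f_E − 1/f_I) · exp[ −∫ ( 1/(τ_E f_E) + 1/(τ_I f_I) ) dν ]

which evaluates to

    p(ν) = N ν^a (β − ν)^b (α + β − ν),   0 < ν < β
    a = [β(1 − ατ) − (α + β) P_I] / (αβτ),
    b = P_I/(βτ) − 1.

The density is integrable at ν = 0 exactly when a > −1, which reduces to
the viability condition P_I < β/(α + β): when it fails, biomass has a
negative log-growth rate at the origin and the stationary state is a
Dirac atom at ν = 0.  The factor identity α + β − ν = α + (β − ν) shows
p(ν) is a *two-component Beta mixture*:

    p(ν) ∝ α·ν^a(β−ν)^b + ν^a(β−ν)^{b+1}

with component weights computed in log space via `betaln`.  The package
uses this representation throughout: the normalization constant, CDF
(regularized incomplete Beta), raw moments (products of Beta-moment
ratios) and exact samples (mixture of scaled Beta draws) are all
closed-form and stable for the extreme exponents that arise when ατ or
βτ is small.  Numerical quadrature is retained in the test suite as an
independent cross-check of normalization, moments and CDF.

Degenerate limits: P_I = 0 or α = 0 give a noise-free vegetated state,
represented as an atom at ν = β (the analogue of the atom at 0 on the
bare side); P_I = 1 with α > 0 always violates viability.

### Decay rate

The decay rate is tied to the hydrology by
α(k) = (k/P_I) ∫_η^∞ (h − η) p(h) dh — the decay coefficient k times the
mean submergence depth *conditional on being inundated*.  The prefactor
convention is ambiguous in parts of the literature; the alternative
reading α = k·P_I·∫ is available via `prefactor="times_pi"` in
`decay_rate` and the calibration entry points.  Calibration absorbs the
convention into k, so fitted decay *rates* α̂ are convention-independent
while fitted k values are not.

## Hydrological statistics

* Rating curves are piecewise-linear in (Q, h); a discharge below the
  first knot marks the cell dry (sentinel −∞: the water surface is below
  the cell bed, which always counts as exposure), and discharges above
  the last knot extrapolate the final segment with a warning.
* The stage density p(h) is a histogram.  By default 100 equal-width bins
  span the cell's own wet range and the nearest interior edge is snapped
  onto η, making the binned P_I equal to the empirical wet-day fraction
  exactly; when a shared site-wide edge set is supplied (so class-level
  densities can be averaged bin-wise) the straddling bin is split by its
  linear fraction above η.  Dry days are bookkept as a separate
  `dry_mass` so that masses + dry_mass = 1.
* P_I and the submergence integral are computed from the same binned
  density (straddling bins split linearly in both), which keeps
  α(k) and P_I mutually consistent to rounding.
* Mean durations count maximal runs of consecutive wet/dry days,
  including the runs truncated at the series boundaries (at multi-decade
  daily length the truncation bias is negligible).  A state that never
  occurs has infinite mean duration and drops out of the harmonic
  combination.
* Durations are stored in days and rescaled by ω on demand (τ = ω·τ_days).

## Climate transform

The altered-regime discharge series is built by parametric quantile
mapping: a lognormal is moment-matched to the positive daily discharges
(μ = ln(m/√(1+c²)), σ² = ln(1+c²)), a target lognormal is built with
m' = mean_factor·m and c' = cv_factor·c, and each value is mapped through
ln q' = μ' + (σ'/σ)(ln q − μ).  The map is monotone, so the rank order —
and with it the run structure that τ depends on — is preserved; the
identity scenario is the identity map regardless of fit quality.
Nonpositive discharges are excluded from the fit and left unchanged, with
a warning.  An explicit seed parameter is accepted for interface
uniformity although the default transform is deterministic.

## Biomass from canopy heights

DBH is predicted from height by the power law D = aH^b, fitted by
ordinary least squares in log-log space (the standard estimator under
multiplicative error; R² is reported for the log-log fit and differs from
a nonlinear-least-squares R²).  Areal biomass density follows Da Vinci's
rule V = λρH·πD²/4 (Mg m⁻²) with stem density λ (default 0.2 m⁻²) and
fresh wood density ρ; reference site-regressed models for poplars
(a = 0.005680, b = 1.7337, ρ = 0.950), willows (0.003345, 1.6807, 0.500)
and a mixed population (0.004312, 1.7784, 0.725) ship with the package.
Plants below the 1.4-m DBH height are excluded (closed threshold: exactly
1.4 m is kept, since DBH is defined there).  An optional per-cell canopy
cover fraction multiplies λ.  The dimensionless biomass is ν = V/V_scale
clipped to [0, 1]; V_scale defaults to the observed site maximum
("auto") and is recorded in the output, because the absolute meaning of
a calibrated β is defined *relative to this scale* — comparisons across
sites must use a common V_scale.

## Sediment and roughness

Number counts per size class are converted to weight fractions by
s_i = S_i⟨d_i⟩^0.8 / Σ_j S_j⟨d_j⟩^0.8.  Percentiles are read from the
percent-finer curve anchored at class *upper* bounds (the sieve
convention; bounds are geometric midpoints between the mean class
diameters, geometrically mirrored at the ends) with log-linear
interpolation in diameter, clamped to the observed class range.  The six
classical Manning formulas (FHWA 0.0482·d50^{1/6}; Julien 0.062·d50^{1/6}
and 0.038·d90^{1/6}; Strickler d50^{1/6}/21.1 and 0.036·d90^{1/6};
Meyer-Peter–Müller d90^{1/6}/26) take the diameter in metres — the
convention verified by reproducing a published worked table to four
decimals — and are averaged at full precision before rounding.  Total
bed roughness is the sum of the bare-soil and vegetation-induced terms;
the vegetation term is an input here.

## Calibration

* Classification: half-open elevation bins [e_i, e_{i+1}) (default 10
  equal-width bins over the observed range) or inundation-probability
  bins of width ΔP_I = 0.1, the last bin closed at 1.  Every cell belongs
  to exactly one class per scheme.
* Class aggregates are area-weighted means over members: P_I and the
  submergence integral are averaged with the same weights (so the class
  decay rate is k·⟨∫⟩/⟨P_I⟩), durations are averaged over the members
  where the state occurs, and class τ is the harmonic combination of the
  averaged τ_E, τ_I.
* The empirical biomass density of a class is a histogram on [0, 1]
  (default 40 bins); classes with fewer than 30 members are flagged
  unfit and skipped.
* The fit is an exhaustive grid search, k ∈ {0.1, …, 10} step 0.1 and
  β ∈ {0.05, …, 1} step 0.05.  Candidate pairs violating viability are
  infeasible and skipped; a class with no feasible pair is reported as
  such, never silently dropped (classes with P_I near 1 are the typical
  case, since the viability bound on α collapses there).  The objective
  sums squared differences between empirical and theoretical *binned*
  densities (theoretical bin masses from CDF differences, so endpoint
  singularities integrate exactly); a CDF-L2 objective is available
  behind `objective="cdf_l2"`.  Ties break toward smaller k, then
  smaller β (parsimony).
* Grid resolution bounds recovery accuracy: with the truth on the grid,
  recovery is exact at a few hundred cells per class; with β exactly
  midway between grid points the support-endpoint error couples into k
  and the argmin can sit two k-steps away.
* The map disagreement metric PAD is the biomass-weighted L1 relative
  difference, 100·Σ|μ₁_model − μ₁_real|/Σμ₁_real; the mean of per-cell
  percent errors is available behind `method="mean_cell_pct"`.
* Scenario projection keeps the calibrated k and β.  By default
  parameters follow the *place* (each cell keeps its baseline class's
  parameters while α, τ, P_I and viability are recomputed from the new
  hydrology); alternatively (`keying="pi"`) they follow the hydrological
  *state*, i.e. β is looked up by the cell's new P_I bin with
  nearest-bin fallback.  The choice is consequential: under spatial
  keying a flow reduction mostly relieves flooding stress and biomass
  rises, whereas under P_I keying cells inherit the (lower) carrying
  capacities of drier classes and biomass falls — the behaviour expected
  where the water table, not flooding, limits growth.  A scenario
  `beta_factor` (e.g. 1.25, 1.50) models plant adaptation; rescaled β is
  clipped at the dimensionless ceiling of 1.

## Synthetic site

The generator emulates every input the calibration consumes, with known
ground truth, under a single master seed (per-generator sub-seeds are
split with `SeedSequence`, so regenerating one stream does not perturb
the others; outputs are bitwise reproducible).

* Discharge: exponential of a stationary AR(1) Gaussian process —
  lognormal marginal with mean 71 m³ s⁻¹ and CV 0.8, persistence
  φ = 0.97, 30 years daily.  The mean and CV are those of a mid-size
  regulated gravel-bed river; φ = 0.97 gives multi-day flood pulses and
  realistic wet/dry run lengths (a few days to weeks).
* Rating curves: per-cell power laws h = cQ^e (c₀ = 0.3, e₀ = 0.25, wet
  stages of order 1–3 m) with smooth spatial gradients (±20% in c, ±15%
  in e) and 5% lognormal per-cell heterogeneity, tabulated at the 19
  discharge quantiles i/20 plus guard knots outside the observed range.
  The heterogeneity is what scatters the η–P_I relation, so the
  elevation and P_I classifications genuinely differ.
* Topography: cells are laid on a margin-to-crest transect; target
  inundation probabilities are stratified so each P_I class receives an
  equal share, spanning 0.03–0.95, and each cell's bed elevation is
  placed at its own curve's stage quantile at 1 − P_I (plus small
  correlated noise, 0.02 m), which makes the realized P_I track the
  design while keeping the elevation map smooth.
* Vegetation: per P_I class, ground truth k*(P_I) = 2.5·e^{−3P_I} and
  β*(P_I) = 0.2 + 0.7·(P³(1−P)/0.1055) — a decreasing-exponential decay
  coefficient and a right-skewed carrying capacity peaking in the
  P_I = 0.7–0.8 bin — both snapped to the calibration grids so recovery
  is well-posed.  Members draw ν i.i.d. from the class-level stationary
  law (an infeasible class yields bare cells), and heights follow by
  inverting the biomass formula with V_scale = 0.43 Mg m⁻² and censoring
  below 1.4 m.
* The growth rate defaults to ω = 0.05 day⁻¹ (a growth span T_g ≈ 120
  days — fast pioneer vegetation of active bars, reeds and willow
  recruits).  This choice matters: ω sets the rescaled integral scale
  τ = ω·τ_days ≈ 0.2–0.4 for the synthetic hydrology, the regime in
  which the stationary densities are broad and (k, β) are jointly
  identifiable.  For slow woody species (ω ~ 10⁻⁴ day⁻¹, the package
  default in `VegetationParams`) the noise is fast relative to growth,
  densities collapse toward their mode, and k becomes weakly
  identifiable at low P_I — a genuine property of the model, not of the
  implementation.
* Grain counts: 520 lognormal sizes binned half-phi; the log-mean is
  shifted by −0.8σ² so the *weight*-distribution median equals the
  configured d50 (111 mm) after the count-to-weight conversion.

What the generator does not emulate: measurement error in heights and
elevations, species zonation (biomass is drawn from the fitted family
itself), morphological change, seasonality in the discharge, and spatial
autocorrelation of biomass within a class.  Passing the recovery and
map-agreement tests therefore demonstrates the *inference machinery* is
correct and well-conditioned under the stated conditions; it does not
certify performance on field data, where the generating law is unknown.

## Numerical choices

* All Beta-function work in log space (`betaln`, `logaddexp`); densities
  evaluated as exp(a·ln ν + b·ln(β−ν) − ln N)·(α+β−ν).
* Simulator: exact logistic/exponential phase solutions for the default
  exponents (tolerance guard 10⁻⁸ on leaving [0, β]); classical RK4 with
  sub-steps for general exponents (guard 10⁻⁴; with n < 1 the decay can
  reach zero in finite time and the output is clamped at 0).  Sampling
  on a regular grid of step dt, required to be at most half the shorter
  mean phase duration; the stationary start phase is drawn with
  probability P_I.
* Histogram comparisons use masses from CDF differences, never pointwise
  density evaluation, so integrable endpoint singularities are handled
  exactly.
* Quantiles use the linear plotting position i/(n+1) on the sorted
  sample (configurable n, default 19).
* Moment quadrature tolerance in the cross-checking tests: 10⁻⁶–10⁻⁸.

## Known limitations

* The closed-form stationary law requires m = n = p = 1; other exponents
  are supported only through the simulator.
* The exponential phase-duration idealization ignores the heavy-tailed
  run-length distributions of persistent hydrographs; τ is the only
  bridge between the real series and the model.
* Calibrated k values depend on the α(k) prefactor convention, the
  chosen ω, and the biomass normalization V_scale; only α̂ and fitted
  densities are convention-free.
* Classes at P_I ≳ 0.95 are usually infeasible by the viability bound;
  they are reported but carry no parameter estimates.
* The PAD definition weights errors by biomass, so bare-cell mismatches
  are invisible to it; use the per-cell variant when bare/vegetated
  boundaries matter.
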