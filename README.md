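# ripacal

Calibration and projection of a stochastic model for riparian vegetation
biomass driven by river-stage fluctuations.

## The problem

Vegetation on river bars and banks lives under a random alternation of
*exposure* (growth) and *inundation* (flood-induced decay).  A minimal but
powerful description treats the dimensionless above-ground biomass
ν ∈ [0, β] of a location as a two-phase (dichotomous-noise) process: in
growth-rescaled time t = ω t*,

    dν/dt =  ν (β − ν)        while the stage h < η   (exposure)
    dν/dt = −α ν              while the stage h ≥ η   (inundation)

where η is the location's dimensionless elevation, β its local carrying
capacity, ω the vegetation growth rate, and α the flood-induced decay
rate.  The hydrology enters through the stage density p(h): the
inundation probability P_I = ∫_η^∞ p(h) dh, the integral scale τ of the
wet/dry alternation (1/τ = 1/τ_E + 1/τ_I from the mean exposure and
inundation durations), and the decay rate

    α(k) = (k / P_I) ∫_η^∞ (h − η) p(h) dh,

i.e. a vegetation-specific decay coefficient k times the mean submergence
depth while flooded.  The stationary law of ν is, in closed form,

    p(ν) = N ν^a (β − ν)^b (α + β − ν),   0 < ν < β,
    a = [β (1 − ατ) − (α + β) P_I] / (α β τ),
    b = P_I / (β τ) − 1,

valid under the viability condition P_I < β / (α + β); otherwise the
stationary state is bare (a Dirac atom at ν = 0).

The two biological parameters that cannot be measured directly — k and β —
are **calibrated**: the site is partitioned into classes of cells with
similar forcing (by elevation or, better, by inundation probability in
steps of 0.1), each class gets an empirical histogram of observed biomass,
and a grid search over (k, β) minimizes the squared difference between the
empirical and theoretical densities.  The calibrated model then projects
biomass under altered discharge regimes (e.g. mean flow −40%, CV +15%).

Around this core the package implements the supporting field pipeline:
rating-curve stage statistics from a daily discharge record, tree
allometry (D = a H^b) and Da Vinci's rule V = λρH·πD²/4 to turn canopy
heights into biomass, pebble-count → weight-fraction conversion
(s_i ∝ S_i⟨d_i⟩^0.8) with the classical Manning-roughness battery, and a
fully seeded synthetic-site generator with known ground truth.

## Worked example

```
$ python examples/calibrate_synthetic_site.py
       class    P_I    k*    k^  beta*  beta^
   pi[0,0.1)  0.056   2.2   2.2   0.20   0.20
 pi[0.1,0.2)  0.137   1.6   1.7   0.20   0.20
 pi[0.2,0.3)  0.256   1.2   1.2   0.30   0.30
 ...
   pi[0.9,1)  0.918   0.1   0.1   0.50   0.50

mean-biomass map disagreement (PAD): 0.32% — the calibrated model
reconstructs the site's biogeography
```

A 4000-cell synthetic bar is generated from the model's own stationary
law with a decreasing decay-coefficient profile k*(P_I) and a right-skewed
carrying-capacity profile β*(P_I); grid-search calibration (k step 0.1,
β step 0.05) recovers the generating parameters of every class — one
class off by a single grid step in k — and the reconstructed mean-biomass
map differs from the generated one by 0.32% overall.

Other examples, one per capability: `steady_biomass_law_vs_simulation.py`
(closed form vs Monte-Carlo), `climate_scenario_projection.py` (drier
regime, with and without β adaptation), `allometric_biomass.py` (heights →
biomass → ν) and `roughness_from_pebble_counts.py` (counts → d50/d90 →
Manning n).

The same pipeline is scriptable from a shell via the `ripacal` command
(`synth`, `hydro`, `calibrate`, `impact`, `roughness`, `biomass`,
`simulate`); run `ripacal --help`.

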