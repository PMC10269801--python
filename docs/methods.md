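# Methods

## Model

The cell is a well-mixed carbon pool at steady state. Photosynthesis
supplies carbon at per-cell rate F_Pho; growth at rate μ drains it
through sinks proportional to the biosynthetic flux μ·Q_C: biomass
itself (factor 1), growth respiration (E_μ), silica deposition (E_Si)
and, optionally, excretion (E_ex). Setting dQ_C/dt = 0,

    μ = F_Pho / [Q_C · (1 + E_μ + E_Si + E_ex)].

Assumptions worth stating plainly: growth is nutrient-replete (no N,
P, Si or Fe limitation terms), temperature is not modelled, the
budget is strictly steady-state (no transient integration), and all
carbon costs scale linearly with the biosynthetic flux. The silica
share of the total cost, E_Si/(1+E_μ+E_Si+E_ex), is therefore pure
parameter arithmetic — independent of volume, light and growth rate.

The counterfactual taxon class `diatom_no_si` keeps the diatom quota,
Si:C ratio and light field but charges frustule production at the
biomass rate, E_Si = (1+E_μ)·Si:C. Because only the denominator
changes, its growth curve is the diatom curve times the constant
(1+E_μ+0.167·Si:C)/(1+E_μ+(1+E_μ)·Si:C) = 1.718221/1.966633 ≈ 0.8737.

## Parameters

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| A_C, B_C (diatom) | quota allometry Q_C = A_C·V^B_C | pg C, – | 10^−0.933, 0.881 | standard protist carbon–volume compilation; diatoms follow a distinctly lower curve |
| A_C, B_C (other) | quota allometry | pg C, – | 10^−0.665, 0.939 | same compilation, non-diatom protists |
| E_μ | growth respiration | mol C/mol C | 0.691 | 1+E_μ = 1.691 mol C per mol biomass C |
| C cost per Si | direct silica deposition cost | mol C/mol Si | 0.167 | literature estimate of the low frustule cost |
| Si:C | cellular silica content | mol Si/mol C | 0.163 | high end of the observed range (conservative for the cheap-silica claim) |
| E_ex | excreted fraction | mol C/mol C | 0 | sensitivity term only |
| I_0 | incident irradiance | μmol photons m⁻² s⁻¹ | 200 | well-lit surface water, fixed a priori |
| I_sat | saturation irradiance | μmol photons m⁻² s⁻¹ | 100 | moderate light adaptation, fixed a priori |
| k_att | intracellular attenuation | μm⁻¹ | 0.314440 | calibrated (below) |
| p_max_v | max volumetric fixation | mol C μm⁻³ d⁻¹ | 3.02694e-14 | calibrated (below) |

Quota prefactors are supplied in pg C (the unit quota compilations
report) and converted with 12.011 g mol⁻¹. k_att is taken constant
across taxa and sizes — the same photosynthesis physiology for
diatoms and non-diatoms — so group differences are carbon economics
only; size-dependent pigment packing would be a next-order refinement.

**Calibration.** With quota constants and cost factors fixed, the two
free optics parameters are identified by two conditions on the diatom
growth–volume curve: a peak located at V = 100 μm³ (k_att, via
root-finding on the centred log-log slope) and a peak height of
2 d⁻¹ (p_max_v, a linear rescaling). `experiments.calibrate_light`
reproduces the frozen defaults; the `calibrate` CLI subcommand writes
a fitted config. The calibration targets describe where
nutrient-replete growth maxima sit in compilations of lab-measured
rates; they are conditions of the study design, not tuned quantities.

## Optics

Cells are spheres of equivalent volume under a collimated beam;
attenuation follows Beer's law along straight chords with no
scattering or internal reflection, and local fixation follows the
exponential saturation form p_max·(1−e^(−I/I_sat)) (the hyperbolic
alternative would not change the qualitative size trend). The
per-cell rate is

    F_Pho = 2π ∫₀^r ρ ∫₀^{L(ρ)} p(I₀e^(−k·s)) ds dρ,  L(ρ) = 2√(r²−ρ²),

evaluated with fixed-order Gauss–Legendre panels, 128 nodes per
dimension, after substituting ρ = r·sinθ; the substitution removes
the square-root limb behaviour, so the quadrature converges
spectrally (halving the resolution changes F_Pho by < 1e-12
relative; the shipped tests require < 1e-6). Two limits are exact and
short-circuited: k_att = 0 gives F_Pho = V·p(I₀), and I₀ = 0 gives 0.

Two independent cross-checks guard the geometry. The absorbed
fraction of the beam within the sphere has the closed form
1 + 2e^(−x)/x + 2(e^(−x)−1)/x² with x = 2·k_att·r, which the chord
quadrature matches to 1e-8 and a million-point brute-force chord sum
confirms; note the limit toward full absorption is algebraic
(1 − 2/x², from grazing chords), not exponential. In the
linear-response regime (I₀ ≪ I_sat) energy conservation ties the two
integrals together: F_Pho = (p_max/I_sat)·I₀·(πr²/k_att)·absorbed
fraction, which the implementation satisfies to better than 1e-3.
The brute-force midpoint oracle for F_Pho discretises the beam
offset in equal-angle cells; a uniform-offset midpoint grid has an
O(h^{3/2}) limb error that stalls near 1e-5 at 2000² and would test
the oracle, not the integral.

## Experiments

The default sweep covers 60 log-spaced volumes on [10⁰, 10⁸] μm³ —
the span of growth-rate compilations — for the three taxon classes,
with F_Pho computed once per volume and shared. Observation scoring
interpolates the model linearly in (log10 V, log10 μ) and reports the
mean (bias) and RMSE of log10 residuals per group, appropriate for
power-law-dominated curves. The synthetic observation generator
scatters rates lognormally (σ = 0.2 in log10 units, n = 100 per
group) around the model curve at log-uniform volumes: it emulates the
order-of-magnitude spread of literature compilations but none of
their real structure (taxon-specific biases, measurement error
correlated with method, uneven volume coverage), so recovering
RMSE ≈ 0.2 validates the scoring machinery, not the model's fit to
real data.

## Transcript budget

Counts are long-format (sample, size fraction, taxon, function,
reads); normalisation divides each count by the (sample, taxon)
total, so shares sum to one within a taxon and sample and re-multiplying
by totals recovers counts exactly. Pairs with zero total reads are
dropped with a logged warning. The paired comparison keys strictly on
sample id (no pooling across size fractions; pooling is left to the
caller) and reports n, the fraction of samples above the 1:1 line
(ties tallied separately), and the median log2 ratio, excluding and
counting zero-containing pairs rather than adding pseudocounts —
avoiding an arbitrary constant at the cost of a separate tally. These
summary statistics are conventions of this package; the underlying
comparison is usually read off a scatterplot.

The generator draws, per sample and taxon, a lognormal sequencing
depth (median 2×10⁵ reads, log-sd 0.5) and a multinomial split over
four functions. Baseline shares (ribosomal proteins 6%, actin 1.2%,
tubulin 1.2%, remainder 91.6%) are plausible poly(A)+ transcriptome
fractions; diatoms get a ×1.5 ribosomal uplift and ×0.5 cytoskeleton
reduction, the unresolved remainder absorbing the difference. What it
does not emulate: taxon co-occurrence structure, compositional
coupling between the focal functions, overdispersion beyond
multinomial, station covariates. Sign-recovery results on this
generator therefore demonstrate pipeline correctness and statistical
power at survey-like n, not an empirical claim about oceans. The
analytic check interval for the recovered median log2 ratio uses the
delta method at the generator's depth distribution (variance inflated
by e^(σ²/2) for the lognormal reciprocal depth) and the 1.2533·σ/√n
sampling sd of a median.

## Numerical choices and degenerate inputs

Non-positive volumes and radii, negative irradiances, path lengths,
photosynthesis rates and growth rates raise `ValueError`s rather than
propagate NaNs. `expm1` is used wherever 1−e^(−x) is small. Config
validation is strict: unknown keys are rejected by name, and the
`other` group cannot carry a nonzero Si:C. Every output table begins
with comment lines (package version, SHA-256 config hash, seed) that
suffice to regenerate it bit for bit; stochastic modules draw from
per-module sub-streams of the run seed so adding one consumer never
shifts another's draws.

## Known limitations

No nutrient or temperature dependence; spherical geometry only (real
frustule shapes alter both surface:volume and the light path); no
spectral light resolution, chlorophyll acclimation, or frustule
light-harvesting effects; a single growth-respiration factor with no
separate maintenance term; quota allometries enter as point
regressions although real Q_C varies widely at fixed volume, which
alone would spread growth rates at a given size.
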