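# Methods

## Scope

`sonokit` models one specific therapeutic-ultrasound scenario: a
lipid-shelled, perfluorobutane-core microbubble of 1.5 µm resting diameter
driven at 250 kHz — roughly an order of magnitude below its linear
resonance — at peak negative pressures (PNP) of 0–800 kPa, together with
the downstream quantification of the sonoporation experiments such
insonation enables (fluorescent-fraction, fold-uptake and viability
metrics, ANOVA/Tukey statistics, and image-based cell counting). The
wet-lab measurements themselves are not reproducible computationally;
everything around them — the physics, the arithmetic, the statistics and
the image quantification — is, and that is what this package implements
and tests.

## Coated-bubble radial dynamics

The governing equation is a modified Rayleigh–Plesset model for a coated
bubble of the Marmottant family:

    ρ (R R̈ + 3/2 Ṙ²) = P_g0 (R0/R)^{3κ} (1 − 3κ Ṙ/c) + P_v − P_0 − P_ac(t)
                        − 2 σ(R)/R − 4 µ Ṙ/R − 4 κ_s Ṙ/R²

with a polytropic gas core (κ = 1.07, quasi-adiabatic perfluorobutane;
full thermal modelling is omitted as second-order for the
maximum-expansion statistic), first-order acoustic radiation damping
(the `1 − 3κṘ/c` factor), liquid viscosity µ, a dilatational
shell-viscosity term `4 κ_s Ṙ/R²`, and the piecewise shell surface
tension

    σ(R) = 0                        R ≤ R_buck      (buckled monolayer)
         = χ (R²/R_buck² − 1)       R_buck < R < R_rup
         = σ_water                  R ≥ R_rup       (ruptured shell)

The buckling radius is derived from the resting state, `R_buck =
R0 / √(1 + σ(R0)/χ)`, so the configured resting tension is exactly the
elastic-branch value at R0; the rupture radius is where the elastic branch
reaches the clean-interface tension σ_water. The equilibrium gas pressure
`P_g0 = P_0 + 2σ(R0)/R0 − P_v` makes rest an exact fixed point of the
ODE, which the tests verify directly.

The drive is a rarefaction-first sinusoid, `P_ac(t) = −PNP·sin(2πft)`,
over a rectangular 50-cycle window (200 µs at 250 kHz). The experiments
being modelled insonate for tens of seconds; the maximum-expansion ratio
converges within tens of cycles, so the window length is a documented
configuration knob, not a physical claim. An optional two-cycle linear
ramp envelope is provided.

### Numerics

- Adaptive stiff-capable integration (LSODA), rtol 1e-8, absolute
  tolerance 1e-12·R0 on radius; max step of 1/50 drive period so the
  forcing is never skipped. These values are pinned by tests against an
  independent fixed-step classical RK4 oracle at dt = T/10⁴ (agreement
  better than 1e-4 relative on R(t) in the non-collapsing regime).
- Inertial collapse makes the ODE progressively stiffer; an integration
  event truncates the trace when R < 0.05·R0 and flags it. The expansion
  ratio ER = max R/R0 uses the pre-collapse maximum, which for this
  bubble occurs during the first giant expansion, well before the event.
- Regime classification: ER < 1.1 negligible, 1.1–3.5 stable cavitation,
  > 3.5 inertial. Regime boundaries on a PNP sweep are located by linear
  interpolation at the first upward crossing of each threshold (first
  crossing wins); a threshold never reached yields an explicit
  "not reached" (None), not an exception. The default sweep step is
  5 kPa.

### Parameters and shell calibration

Medium defaults are a water-like buffer at ambient conditions
(ρ = 1000 kg/m³, µ = 0.001 Pa·s, c = 1500 m/s, P0 = 101.325 kPa,
σ_water = 0.073 N/m). The shell parameters (χ, κ_s, initial tension σ0)
of the default configuration are *effective fitted values*, not measured
material constants: `calibrate_shell` fits one parameter set jointly to
five anchors of the modelled scenario — expansion ratios 15, 33 and 50 at
300, 500 and 800 kPa, and regime-boundary crossings at 85 and 205 kPa —
by Nelder–Mead in log-parameter space. The objective is the mean squared
tolerance-scaled relative error: each anchor's relative residual is
divided by its acceptable mismatch (±20 % for ER anchors, whose exact
values depend on unpublished shell details; ±15 kPa for the boundaries)
so the tight boundary anchors pull as hard as the loose ER anchors.
Boundary predictions inside the optimizer are located by Brent root
finding on the ER–PNP curve. The fitted set is frozen in
`sonokit/data/default_bubble.yaml`; every simulation logs a hash of its
parameter set. Calibration is validated by parameter recovery: anchors
synthesized from a known shell inside the search box are reproduced to
within 1 %.

The classical quasi-static Blake threshold (isothermal gas, constant
tension) is provided as a closed-form diagnostic only:
`P_B = P0 + (4σ/3)·√(2σ/(3 P_g0 R0³))`. It is deliberately not used for
regime classification, which relies on the simulated sweep.

## Ligand budgets

The targeted-microbubble arithmetic is deterministic: lipid count =
π d²/a with the π d² shell-area convention and a = 0.6 nm² per DSPC
headgroup; 5 % biotinylated lipids; one streptavidin per biotin-lipid;
two antibodies per streptavidin. Counts are floats (order-of-magnitude
estimates). An explicit one-significant-figure mode reproduces the
conventional chained rounding (1e7 → 5e5 → 5e5 → 10e5); exact arithmetic
is the default. The effective binding rate is 100·bound/offered, e.g.
19.4 bound of 50 offered per cell → 38.8 %.

## Uptake statistics

Percentages are stored on the [0, 100] scale throughout. Fold uptake
versus sham has two modes because the two conventions genuinely differ
under replicate variation: `mean-ratio` (default) divides group mean by
sham mean; `replicate` pairs replicates by index and averages the
per-replicate ratios. One-way ANOVA is computed from the definitional
sums of squares (and cross-checked against `scipy.stats.f_oneway`);
all-constant input raises a degenerate-input error rather than returning
0/0. Tukey's multiple-comparison test uses the studentized-range
distribution with the Tukey–Kramer standard error for unequal group sizes
via `scipy.stats.tukey_hsd`, cross-checked against statsmodels; the
two-group case collapses to the pooled-variance t-test (q = √2·|t|), and
a property test verifies the adjustment is never anti-conservative.
No normality pre-tests are applied. The dose–response optimum is the
insonated group with the largest mean, ties broken toward the lower
pressure. Significance stars follow the *, **, ***, **** convention at
0.05, 0.01, 0.001, 0.0001.

The type-I error of the ANOVA and the family-wise error rate of Tukey's
procedure are verified by simulation (10⁴ null datasets of 5 groups × 3
replicates; rejection rates must land in [0.04, 0.06] at α = 0.05).

## Image quantification

The two-channel counter replaces a manual threshold-and-count workflow:
Otsu thresholding (fixed-value override available), removal of connected
components below 20 px, 8-connectivity labelling (both configurable), and
a per-component staining rule — a nucleus counts as reporter-positive
when its mean reporter-channel intensity exceeds the reporter threshold.
A unimodality guard makes Otsu fail gracefully: when the two Otsu classes
are separated by less than three within-class standard deviations (a
constant or pure-noise channel), the threshold is declared degenerate and
the mask is empty, so a fraction-zero frame quantifies as 0 % instead of
thresholding noise. Frames with no detected cells report an undefined
(missing) fraction, not 0. Batches are split into equal consecutive
replicate blocks (e.g. 21 frames → 3 × 7) and averaged per replicate.

Deliberately excluded: watershed splitting of touching nuclei (synthetic
fixtures are generated non-overlapping; heavily confluent real frames
would need a segmentation stage this module does not provide),
illumination correction, and any emulation of proprietary
confluence-estimation software.

## Synthetic data

The generator produces the two input kinds the pipeline needs. Replicate
tables: groups of n = 3 replicates drawn from a normal distribution at
each group's published mean ± SD, truncated to [0, 100] % (truncation is
the natural bound for percentages; the published summaries say nothing
about the true replicate distribution, so truncated-normal independence
is a modelling choice, not a claim about the data). A `zero_sd` switch
collapses the draws onto the means for deterministic downstream
arithmetic. The registry of published group summaries ships as a
read-only YAML data file. Synthetic frames: non-overlapping disks placed
by rejection sampling (bounded retries, then an explicit placement
error), an exact rounded count of stained disks, additive Gaussian noise,
16-bit clipping. Everything is deterministic under a fixed seed;
per-group seeds are spawned from the table seed.

What passing tests on these fixtures do **not** show: real nuclei are not
uniform disks, real noise is not purely additive Gaussian, real staining
is not binary, and real replicates may be correlated. The fixtures
validate the *pipeline*, not the biology.

## Problem sizes

Default problem sizes used by the test suite and the acceptance script:
50-cycle simulations; 0–800 kPa sweeps at 5 kPa (161 simulations, about
a minute) and 0–250 kPa at 5 kPa for boundary location; 10⁴-replicate
null simulations for the statistical calibration checks; 360×360 px
frames with ~100 cells for image-recovery checks; the RK4 oracle runs
8–10 cycles at 10⁴ steps per cycle. These sizes were chosen so every
quantity of interest is converged at comfortably interactive runtimes.

## Known limitations

- Single bubble, unbounded liquid: no bubble–bubble or bubble–wall
  coupling, no transducer field geometry, no tissue attenuation.
- The polytropic exponent is fixed; thermal damping is not modelled.
- Shell parameters are effective values fitted to the modelled scenario;
  they should not be quoted as material properties of any particular
  lipid formulation.
- The expansion-ratio statistic is insensitive to the post-collapse
  rebound physics by construction (trace truncation).
- Fold-uptake conventions differ between modes by design; published fold
  values computed from replicate-wise ratios can differ slightly from
  mean-ratio values computed from the same summary means.
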