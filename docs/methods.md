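# Methods

## Curve families

**Nonasymptotic (Ye) family.** All four light responses — net photosynthesis
A_n–I and the electron-flow curves J–I, J_C–I, J_O–I — share the rational
form `y(I) = α(1 − βI)I/(1 + γI) − R_d`, with the offset R_d present only for
A_n (the electron-flow forms pass through the origin, so their fits pin
R_d = 0). Parameters and units:

| parameter | meaning | units | typical range |
|---|---|---|---|
| α | initial (quantum-limited) slope | μmol μmol⁻¹ photons | 0.05–0.3 |
| β | photoinhibition coefficient | m² s μmol⁻¹ | 10⁻⁴–10⁻³ |
| γ | light-saturation coefficient | m² s μmol⁻¹ | −4×10⁻⁴–2×10⁻³ |
| R_d | dark respiration | μmol m⁻² s⁻¹ | 0–8 |

γ may legitimately be negative (field fits of soybean electron transport
produce γ < 0); every closed form here remains valid provided β + γ > 0
(finite interior maximum) and the denominator 1 + γI stays positive over the
light range. Prediction raises a domain error beyond the validity window
I < −1/γ rather than silently evaluating a pole.

Closed forms: I_sat = (√((β+γ)/β) − 1)/γ and
y_max = α((√(β+γ) − √β)/γ)² − R_d. Both are continuous in γ at 0; below
|γ| = 10⁻¹⁰ the analytic parabola limits I_sat = 1/(2β), y_max = α/(4β) − R_d
are substituted to avoid catastrophic cancellation (relative switch error
~γ/(2β), i.e. ≲10⁻⁶ at the threshold). β = 0 degenerates to a monotone
saturating curve: the maximum is reported as the asymptote α/γ − R_d and
flagged `asymptotic`, with no I_sat.

The light compensation point solves αI(1 − βI)/(1 + γI) = R_d, i.e. the
quadratic αβI² − (α − R_dγ)I + R_d = 0. The smaller positive root is taken —
the physiological crossing below saturation — computed in the product form
2R_d/(lin + √disc) to avoid cancellation; β = 0 reduces to R_d/(α − R_dγ).

**Non-rectangular hyperbola (NH).** The gross response is the lower root of
θy² − (αI + y_max)y + αI·y_max = 0; the net curve subtracts R_d, so the
estimated `y_max` is a gross asymptote and the reported maximum is
y_max − R_d. The lower root is evaluated in the product form
2αIy_max/(b + √(b² − 4αθy_max I)), which is stable for all θ: θ = 1 is
special-cased to the exact Blackman form min(αI, y_max), and θ < 10⁻¹⁰ to the
rectangular hyperbola αIy_max/(αI + y_max). No saturation irradiance is
reported for this family — the asymptote is never attained, which is exactly
the mechanism by which it overestimates attainable maxima on photoinhibited
data (`nh_asymptote_gap` measures the shortfall at the top measured
irradiance). Its compensation point has the closed form
I_c = R_d(y_max − θR_d)/(α(y_max − R_d)), derived by substituting y = R_d
into the defining quadratic; it requires y_max > R_d.

## Electron-flow partitioning

J = Φ_PSII · I · f_PSII · a with defaults f_PSII = 0.5 and leaf absorptance
a = 0.84; both are exposed because they are species- and leaf-dependent in
general use. The split J_C = (J + 8(A_n + R_day))/3,
J_O = 2(J − 4(A_n + R_day))/3 assumes electron sinks other than RuBP
carboxylation and oxygenation are negligible or constant; J_C + J_O = J is an
algebraic identity and is asserted to 10⁻⁹ in the tests. Negative J_O
(J < 4(A_n + R_day)) is returned unmodified but warned about: it diagnoses a
violated assumption, and clipping it would hide exactly the signal a user
needs. R_day defaults to 0.5·R_d — a convention, not a law — and can be
overridden.

## Fitting

Ordinary (unweighted) least squares per replicate, bounded trust-region
(`scipy.optimize.least_squares`, tolerances 10⁻¹⁰, ≤10⁴ evaluations per
start). Both families have shallow, curved cost valleys, so each fit runs a
small deterministic multi-start grid: γ₀ ∈ {−10⁻⁴, 10⁻⁵, 5×10⁻⁴, 2×10⁻³}
with β₀ = 10⁻⁴ for the nonasymptotic family; θ₀ ∈ {0.5, 0.9} with
y_max₀ = 1.05 × max(y) for the hyperbola; α₀ is the slope of the two
lowest-irradiance points in both. Bounds keep the closed forms defined over
the data: notably γ ≥ −1/(1.05·I_max) (denominator positivity) and
θ ∈ (10⁻⁶, 1]. On noiseless curves this setup recovers generating parameters
to machine precision; the test suite requires 10⁻⁴ relative over 100 random
truths per family.

R_d on A_n curves is free by default; `fit(fix_rd=...)` pins it (e.g. to the
measured exchange at I = 0) — both conventions are in use in the literature
and the choice is left explicit. Asymptotic standard errors come from the
Gauss–Newton covariance (JᵀJ)⁻¹·SSE/(n−p); they are omitted when the
information matrix is singular. Goodness of fit is R² = 1 − SSE/SST, which
errors on zero-variance observations rather than returning NaN.

## Observation-model comparison

Per quantity (maximum, saturation irradiance, compensation point,
respiration, residual SS) the per-replicate fitted values of each model and
the measured values form groups compared by one-way fixed-effects ANOVA
(explicit sums of squares) with pairwise Tukey HSD at α = 0.05 supplying
compact-letter homogeneous subsets (maximal cliques of the
not-significantly-different graph, lettered in descending mean order).
Observed conventions: the observed maximum is the largest measured step and
its irradiance is the observed saturation irradiance (matching how such
tables report values near the top applied step); the observed I_c is the
linear interpolation of the lowest zero crossing; the observed R_d is the
negated exchange at I = 0. NH saturation-irradiance cells are deliberately
empty.

## Synthetic data generator

Emulates the field design the package targets: descending steps
2000, 1800, …, 50, 0 μmol m⁻² s⁻¹ (soybean design; wheat design caps at
1800), n = 3 leaf replicates, additive Gaussian noise with σ = 2% of the
noiseless curve maximum by default, and optional multiplicative lognormal
jitter of the truth parameters across replicates (default 0; jittered draws
violating parameter invariants are redrawn, at most 100 times). Fluorescence
is generated by inverting the J definition: Φ_PSII = J/(0.42·I) for I > 0,
with the dark step assigned the smallest-positive-step yield, clipped to
[0, 1] (a clipping rate above 10% warns loudly — truth and design are then
inconsistent).

A carboxylation-consistent mode (`response_kind="j_c"`) instead derives
J = 3·J_C_truth − 8(A_n + R_day) so that partitioning the generated data
returns the J_C truth exactly at every positive irradiance; this closes the
simulate → partition → fit loop for validation. Exact closure cannot include
the dark step: J(0) = 0 forces the partitioned value there to −4R_d/3, a
respiration bookkeeping term no origin-passing curve matches, and at the
lowest irradiances the inversion can imply Φ_PSII > 1 (clipped, warned). The
closure test therefore fits the unclipped, positive-irradiance steps.

What the generator does *not* emulate: heteroscedastic or autocorrelated
instrument noise, drift across the descending sequence, stomatal
ratcheting/hysteresis, or any temperature/CO₂ covariation. Passing recovery
and coverage tests on these synthetic curves shows the estimation machinery
is correct and unbiased under the stated error model, not that field data
meet that model.

The fixture catalog pins ground-truth parameter sets per species and
response family from published replicate-mean fits. The wheat J–I entry is
excluded: its published β_e (2.42×10⁻³) implies a maximum (~30 μmol m⁻² s⁻¹)
an order of magnitude below the published J_max (257), and makes 1 − β_e·I
negative above ~413 μmol m⁻² s⁻¹ — almost certainly a misprinted exponent —
so it cannot serve as a self-consistent truth.

## Simulation scales and statistical checks

The overestimation experiment uses 200 simulated three-replicate soybean
experiments at 2% noise: the hyperbola's fitted maximum must exceed the true
attainable maximum in ≥95% of experiments, and the nonasymptotic per-
experiment mean maxima must lie within 2 SE of the truth in ≥95%, where SE
is the empirical standard deviation of the per-experiment means. With n = 3
replicates a per-experiment (t-based) SE cannot give 95% coverage at 2 SE,
so the across-experiment spread is the meaningful yardstick; it is also
robust to the mild right skew of the fitted-maximum distribution (a few
fits place I_sat beyond the measured range and extrapolate upward, the
median bias being ≈0.04 μmol m⁻² s⁻¹). Grid-oracle sweeps use a 0.1 μmol
step over 1.5×I_sat (1000 parameter draws); recovery sweeps use 100 truths
per family. These sizes keep the full suite under half a minute on one core
while leaving the statistical checks comfortably powered.

## Known limitations

- No mesophyll conductance, temperature or CO₂ response surfaces, FvCB
  A–Ci coupling, or alternative electron sinks beyond
  carboxylation/oxygenation.
- No bootstrap or Bayesian uncertainty; SEs are asymptotic, and
  across-replicate SEs (the tabulated convention) are what `compare_models`
  reports.
- Instrument-native file dialects are not parsed; the input contract is a
  plain CSV/TSV with recognised (or mapped) headers, μmol-based units
  assumed throughout.
- Day respiration estimation (Laisk/Kok) is out of scope; R_day = 0.5·R_d is
  a configurable convention.
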