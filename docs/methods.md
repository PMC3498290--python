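# Methods

This note documents the models, the default parameter values and where they
come from, the synthetic-data generators, the numerical choices, and the known
limitations of `pherokin`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Batch kinetics

The acetyl transferase acting on the pheromone precursor alcohol is modeled by
single-substrate Michaelis–Menten kinetics, v = Vmax·S/(Km+S). The acetyl-CoA
co-substrate is treated as saturating and does not appear in the rate law.
The reference estimator for (Km, Vmax) is the Hanes–Woolf linearization —
ordinary least squares of y = S/v on x = S, Vmax = 1/slope, Km =
intercept/slope — because that is the estimator the source study used; a
direct nonlinear fit (`fit_michaelis_menten_nls`) exists as a cross-check
only. The reported r² is that of the transformed regression. Points with
v ≤ 0 are excluded with a warning rather than failing the fit; a non-positive
slope or intercept yields an *invalid-fit flag with diagnostics*, not an
exception.

**A documented weakness, on purpose.** Under the assay's own design — ten
log-spaced substrate levels on 1.25–1300 µM, i.e. almost all points far above
Km = 1.63 µM — the unweighted OLS on the transform is dominated by the
high-S points (where S/v ≈ (S+Km)/Vmax is large), so with ~10 % multiplicative
velocity noise the intercept, and hence Km, is unstable: in a 500-replicate
brute-force run the median recovered Km is severalfold above the generating
value and a large minority of replicates are flagged invalid. Vmax, carried
by the slope, is recovered with negligible median bias. The test suite
asserts exactly this: per-replicate agreement with an independent
least-squares oracle, unbiased Vmax, and *exact* recovery of both constants
on noise-free data. A green suite therefore establishes the estimator is
implemented correctly — not that Hanes–Woolf is a good Km estimator at this
design, which it is not.

**Units.** The internal canonical velocity unit is µM·s⁻¹. Batch activities
in pKat (pmol·s⁻¹) are accepted at the boundary and convert through a
*mandatory* reference volume (pmol·s⁻¹/µL = µM·s⁻¹): the source material
mixes pKat and µM without stating the conversion volume, so the volume is an
explicit parameter rather than a guess.

## Plug-flow microreactor model

Under plug flow, a fluid slice crossing the packed channel experiences batch
kinetics for the residence time τ = V/F (V from the rectangular channel
geometry, 9.8 mm × 250 µm × 50 µm → 0.1225 µL for the narrow variant; the
packed-bead void fraction is exposed as a parameter and defaults to 1, so the
geometric V is an upper bound). The state is (S, ES, P) in µM:

    dS/dτ  = −k_f·E_free·S + k_b·ES
    dES/dτ =  k_f·E_free·S − (k_b + k_r)·ES
    dP/dτ  = (1 − F_AD)·k_r·ES

This is the canonical mass-action reconstruction of the declared
Michaelis–Menten scheme (it satisfies d[ES]/dτ = 0 at steady state with
Km = (k_b+k_r)/k_f and Vmax = k_r·E_total, which the quasi-steady-state test
verifies against the closed form to <1 % for 20 random parameter draws).

Modeling conventions:

- **Adsorption.** F_AD partitions the product flux at formation time; the
  adsorbed pool is not a tracked state and there is no desorption term. The
  linear invariant S + ES + P/(1−F_AD) = S0 then holds exactly and is used as
  the conservation check (RK4 preserves linear invariants to round-off).
  Whether adsorption should also deplete free substrate is ambiguous in the
  source; the product-only form is implemented and no claim is made that it
  is the original intent.
- **Deactivation.** E_active = E0·exp(−K_D·t_age) with K_D in h⁻¹ acts on the
  hours timescale and is held constant within a single residence-time
  integration (seconds): τ ≪ 1/K_D. A test verifies that aging the enzyme is
  *exactly* equivalent to rescaling E0.
- **Enzyme units.** The immobilized amount (µg) maps to concentration through
  a lumped constant absorbed into k_f and k_r (no molecular weight or liquid
  volume is available for a physical conversion); since (k_f, k_b, k_r) are
  free parameters the lumping is harmless, and only the compounds
  Vmax = k_r·E_active and Km = (k_b+k_r)/k_f are interpreted.
- **k_f units.** The second-order formation constant is µM⁻¹·s⁻¹ (the printed
  "µM sec⁻¹" cannot be right for a bimolecular constant).
- Axial dispersion, bead-scale diffusion limitation, temperature dependence
  and co-substrate depletion are out of scope.

**Integrator.** Classical RK4 (k1..k4 weighted 1/6, 2/6, 2/6, 1/6),
implemented explicitly so the step is a reproducible config value; default
dτ = τ_max/2000, overridable. Concentrations in [−10⁻⁹, 0) are clamped to 0;
anything below −10⁻⁹ or non-finite aborts with the offending step. Empirical
convergence order is verified to be 4 ± 0.3 on an exponential-decay benchmark.
The fitting loop uses a numba-compiled specialization of the same scheme with
a stability-limited step h ≤ 0.5/λ, λ = k_f(E_active+S0)+k_b+k_r, and a step
budget so that extreme rate constants fail fast; a test pins the fast path to
the public integrator at 10⁻¹⁰ relative tolerance.

## Constant estimation

- **K_D**: OLS of log(mean activity ratio) vs time, K_D = −slope; duplicates
  averaged within time point before the log; exact on noise-free exponential
  input; a negative estimate is returned flagged, not raised.
- **F_AD** = 1 − S_recovered/S_initial from the enzyme-free bead control,
  clipped to [0, 1); zero recovery is capped just below 1 with a warning.
- **Free constants**: sum of squared residuals of (S_model − S_obs) and
  (P_model − P_obs), equally weighted in µM (substrate-only and product-only
  weighting available), minimized by Nelder–Mead in log10 space within
  [10⁻⁶, 10⁶], started from a seeded 8-point Latin hypercube over
  [10⁻³, 10³] (the extreme corners of the full box are numerically infeasible
  and would waste starts) plus a polish from the incumbent. Derivative-free
  search was chosen because RK4-in-the-loop objectives have noisy numerical
  gradients. The returned objective is never worse than any start (tested).
  Identifiability is claimed — and tested — only for Vmax and Km; k_f and k_b
  individually lie along sloppy directions.

## Synthetic data: the stated world

All generators are pure functions of a `SyntheticConfig`; substreams derive
from the master seed via `SeedSequence(entropy=seed, spawn_key=(stream_id,))`
with fixed per-generator ids, so adding a generator never perturbs existing
streams. Defaults are the study's stated conditions:

| quantity | default | origin |
|---|---|---|
| batch Km, Vmax | 1.63 µM, 5.5 pKat | printed batch constants |
| substrate levels | 10 log-spaced on 1.25–1300 µM | stated assay design |
| deactivation | K_D = 1.4 h⁻¹ at t = 0, 19, 32 h, duplicate | stated assay |
| adsorption | F_AD = 0.34, S0 = 119 µM, P0 = 0 | printed table |
| reactor Vmax | 19.4 pKat through V = 0.1225 µL | printed value + geometry |
| generating split | k_f = 2, k_b = 0.76, k_r = 2.5 (µM⁻¹s⁻¹, s⁻¹, s⁻¹) | chosen once, see below |
| calibration | y = 1.0658x + 3.3392, flows 0.01–2 µL·min⁻¹, 10 ng·µL⁻¹ | printed line |
| wind tunnel | N = 20; evaporator (0.97, 0.90, 0.73, 0), females (1, 0.85, 0.85, 0.70), blank (0.20, 0, 0, 0) | printed percentages |
| EAG | 10 antennae × 4 replicates; pheromone 40 ± 5 %, blank 5 ± 2 % | stated design / reported ~40 % |

Free choices, made once: the rate-constant split fixes Km at the batch value
(no separate reactor Km is printed) in a non-stiff regime; E0 follows from
Vmax = k_r·E0 = 19.4 pKat/0.1225 µL = 158.4 µM·s⁻¹. With these stated values
conversion saturates on the seconds scale, so the default residence-time grid
is 8 points geomspaced on 0.05–1.5 s, spanning partial to near-complete
conversion. Reactor scatter defaults to 10 % multiplicative Gaussian noise —
a labeled stand-in, since the source reports "large scatter" without a
variance; multiplicative noise is the default everywhere (GC-MS quantification
errors scale with signal) with an additive option for EAG responses. The
females' source-contact probability (0.70) is a stand-in; it is not printed.
Behavioral counts are generated as a Markov chain of conditional continuation
probabilities, so the nesting invariant (a responder at step k responded at
all earlier steps) holds by construction.

What a green test does **not** establish: that real microreactor scatter is
10 % multiplicative, that the two physical reactor geometries behave
identically (the generator reuses one model for both blocks), or that the
seconds-scale τ grid matches the minutes-scale flows of the physical device —
the pKat↔µM lumping absorbs that scale freely.

## Calibration conventions

Inverse prediction uses *mass-flux equivalence*: the antenna is assumed to
respond to concentration × flow, so a corrected response mapping to
calibration flow x_eq, delivered at `source_flow`, implies concentration =
reference × x_eq/source_flow. This is the package's explicit convention — it
is dimensionally consistent and halves the apparent concentration at double
the flow — not a reconstruction of how the original back-estimate was made.
Responses at or below the intercept return a below-detection result;
equivalent flows outside the calibrated range refuse to extrapolate by
default (the dose–response saturates), overridable per call.

## Statistics conventions

- Clopper–Pearson intervals use the exact beta quantiles in the interior and
  the one-sided bound at the boundaries (upper = 1 − α^(1/N) at x = 0, the
  rule-of-three-type form); interior values match `statsmodels`' beta method.
- Pairwise χ² tests are reported without multiple-testing correction,
  matching the source procedure; Holm adjustment is available behind a flag.
  Yates continuity correction is off by default, toggleable. Cells with
  expected counts < 5 trigger a warning. Tables where every treatment sits at
  the same extreme (a zero margin) are trivially homogeneous (χ² = 0, p = 1)
  rather than an error.
- The compact letter display assigns one letter per maximal clique of the
  non-significance graph, so sharing a letter is exactly pairwise
  non-significance; identical rows always share a letter.
- The antenna is the statistical unit for EAG: replicates are averaged within
  antenna before the unpaired two-sided t test. ANOVA + post-hoc machinery is
  deliberately not implemented; the integrated-system comparison is the
  t test.

## Known limitations

- Fig-3-style experimental scatter is not numerically published, so the free
  constants are validated by synthetic-data recovery, never by refitting the
  original points.
- The bead-packed void volume is unknown; geometry-based V (and hence τ and
  the pKat↔µM bridge) is an upper bound.
- Km from Hanes–Woolf under realistic noise is unstable at this assay design
  (see above); use the nonlinear cross-check fit when Km matters.
- The behavioral percentages 97/90/73 % are not consistent with integer
  counts out of N = 20, so bar-level values are treated as generator
  probabilities, not as recoverable targets.
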