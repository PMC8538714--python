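# Methods

## Structural model

Voriconazole disposition is a two-compartment model with linear
elimination, intravenous input, and an extracorporeal removal route that
is split into a constant diffusive clearance into the effluent,
`CL_dial = (1 − F_ADS)·CL_RRT`, and an adsorptive clearance onto the
hemofilter membrane, `CL_ads(t) = F_ADS·CL_RRT·max(0, 1 − A_ads/ADS_MAX)`.
Adsorption is irreversible and capacity-limited: the only two adsorption
parameters the population analysis reports are a fraction (F_ADS) and a
capacity (ADS_MAX), and this is the minimal structure those two
parameters determine.  A reversible variant with a first-order
desorption rate `k_off` exists solely as a candidate in the AIC model
comparison and is off (k_off = 0) everywhere else.

The simulator carries five mass ledgers per subject (central,
peripheral, adsorbed, cumulative effluent, cumulative metabolized) plus
the running integral of the central concentration, so mass conservation
and AUC are available without post-hoc quadrature.  On hemofilter
exchange the adsorbed amount moves to a "discarded" ledger and the
membrane capacity is fresh; central/peripheral amounts are continuous
across the event.

Nonlinear (Michaelis–Menten) body clearance, oral absorption and
protein-binding submodels are out of scope by design.

## Observation model

Three streams are predicted from the state: pre-filter plasma
concentration (C_pre = C₁), effluent concentration
(C_effl = CL_dial·C₁/Q_effl), and measured post-filter concentration
(C_post,meas = C₁·(1 − (CL_dial + CL_ads)/Q_blood,adj)·Q_blood,adj/(Q_blood,adj − Q_FRR)),
the last combining extraction by both removal routes with
hemoconcentration from net fluid removal.  These are exact inverses of
the bedside clearance estimators in `voridial.rrt`; the round trip
(predict streams → estimate clearances) recovers CL_dial from the
effluent route and CL_dial + CL_ads from the pre/post route identically,
which is the model's defining consistency and a standing test.

Residual error is proportional per stream (29.3 / 35.9 / 42.9 %CV for
pre / post / effluent); no additive component, since none is reported.

## Numerics

Between events the linear two-compartment core has an exact solution.
The integrator advances each substep with the closed-form spectral
decomposition of the 2×2 system (eigenvalues are always real and
distinct when Q > 0), treating the infusion rate and the slowly varying
adsorption clearance as constant over the substep, with one midpoint
corrector pass for `CL_ads`.  The step integral of A₁ is computed from
the same closed form, so every ledger is updated consistently and total
mass is conserved to machine precision by construction; the scheme is
unconditionally stable and exact (not merely accurate) whenever
adsorption is absent.  Default substep: 0.1 h for cohort simulation,
0.5 h inside likelihood evaluations (predictions at the two step sizes
agree to <1e-5 relative).  A `numba` JIT kernel executes the loop when
available; a vectorized numpy executor with identical semantics is the
reference and fallback, and equality of the two is tested.

`simulate_individual` additionally provides a stiff-safe adaptive LSODA
integration of the explicit right-hand side (rtol 1e-8, atol 1e-10 mg)
as an independent numerical route; the two integrators agree to ~1e-7
relative on typical trajectories and the exact propagator is checked
against the analytic biexponential bolus solution at rtol 1e-6.

Degenerate inputs: zero pre-filter concentration makes a clearance
estimate undefined and is an error (records are dropped with a logged
warning at table level, never silently zeroed); fluid removal at or
above blood flow, negative flows and hematocrit outside [0, 0.7] are
domain errors; a post-filter concentration above pre-filter is flagged
as implausible data but kept.

## Virtual population

The generator emulates the source study design: 6 + 9 subjects in two
groups (ACLF / no liver failure), 6 mg/kg q12h ×2 loading then 4 mg/kg
q12h as 30-min infusions, three-stream sampling at
0, 1, 2, 4, 6, 8, 12, 24, 25, 48, 49 h.  Random effects: log-normal IIV
on all six structural parameters (ω² = ln(1 + (CV/100)²)), log-normal
IOV on CL_body with one occasion per 12-h dosing interval (a switch
allows 24 h), stream-specific proportional residual error.  Adsorption
fractions drawn above 1 are rejected and resampled.  Body weights are
log-normal with median 80 kg and 20% CV truncated to [40, 150] kg — the
study reports only group medians of 73 and 85 kg, so this distribution
is an invented, documented sensitivity knob for the weight-based dosing
results.  Groups are exchangeable by construction; an optional
multiplicative group effect on CL_body exists to probe the power of the
group comparison.

Default RRT settings (configurable, not asserted as the study's):
CVVHD, blood flow 6 L/h, dialysate flow 2.4 L/h (30 mL/kg/h at 80 kg),
no pre-filter replacement fluid, fluid removal 0.1 L/h, hematocrit 0.30.
Note an unresolved tension in the source analysis: typical
CL_RRT = 1.46 L/h with these flows implies S_eff ≈ 0.45, while the
reported per-group S_eff medians are 0.2–0.25; per-patient flows are not
public, so the defaults are a consistent choice, not a reconstruction.
What passing tests show is internal consistency of generator and
estimators under these settings — not fidelity to any real circuit.

## Estimation

Full nonlinear mixed-effects estimation (FOCE/SAEM) is deliberately not
reimplemented: the package's questions — which adsorption structure the
data support, whether two groups differ, and the Monte-Carlo dosing
study — do not require it.  Instead:

* **Pooled maximum likelihood** on IIV-free datasets estimates the six
  typical structural parameters under the proportional-error Gaussian
  likelihood, on log scale (logit for F_ADS), from ≥5 log-spaced starts
  with a fresh-simplex restart and a quasi-Newton polish.  Practical
  identifiability is probed via the finite-difference Hessian at the
  optimum: an eigendirection along which a 20%-sized move raises −2LL by
  less than 3.84 (the 95% χ² bound) is flagged flat — with pre-filter
  data alone, F_ADS is flagged, as it should be.
* **MAP (empirical Bayes) estimates** per subject minimize the subject's
  −2LL plus the log-normal prior penalty Ση²/ω².  With no observations
  the estimate shrinks to the typical values; with ω → 0 it ignores the
  data.  Note an intrinsic property of proportional-error likelihoods:
  because the error SD scales with the prediction, large nominal CVs
  bias MLE/MAP predictions downward (~CV²); recovery checks therefore
  use small nominal CVs, where the effect is negligible.  The adsorption
  fraction remains the least identified direction at the single-subject
  level and is recovered more loosely than the disposition parameters.
* **AIC comparison** of the adsorption structures (none / irreversible
  capacity-limited / reversible) fits candidates simplest-first with
  warm starts, then refits every candidate from the incumbent best's
  shared parameters.  Without that protocol, AIC differences reflect
  optimizer noise rather than model structure (a richer model must never
  lose badly to its own restriction).
* **Group comparison**: per parameter, a Shapiro–Wilk test (α = 0.05) on
  pooled within-group residuals selects the two-sample t-test (normal)
  or the Wilcoxon rank-sum test; two-sided p-values; summaries are
  mean [sd] when normal, median [min, max] otherwise.  The normality
  gate is a declared convention — the source analysis does not state its
  decision rule.

Experiment scales (chosen once as the package's own designs): parameter
recovery uses 48 IIV-free subjects with hourly three-stream sampling
over 0–49 h at 5% residual CV, 20 seeds, asserting median absolute
relative error ≤ 5% per parameter — at the minimal 6-subject study
design the maximum-likelihood estimates themselves spread 8–14% for
V1/Q, so tighter claims are not statistically attainable there.  Model
selection uses 20 replicate 6-subject study-design datasets per truth
condition at 5% residual CV.  The null-finding emulation runs 500
replicate 6-vs-9 studies and compares the generator's realized
individual parameters (the comparison machinery and the generator null
are what is under test); the type-I error of the CL_body comparison must
lie in 3–8% at α = 0.05.

## Monte-Carlo dosing study

Nine scenarios: three q12h dose levels (6/4, 9/6, 3/2 mg/kg
loading/maintenance, loading on day 1 only) × three RRT modalities
(continuous; continuous with filter change every 72 h, the nominal
lifetime of the circuit used; none).  PTA doses are true boluses;
the synthetic study generator uses 30-min infusions — each section of
the design is followed where it applies.  Six days of dosing; day 6 is
steady state (terminal half-life ≈ 21 h at typical values).  Metrics
per subject: troughs and AUC₂₄ₕ on day 1 and day 6, on true
(noise-free) concentrations; IIV and IOV are included and residual
error excluded by default, all toggleable.

Day-level trough bands pool the two q12h troughs of the day (12 h and
24 h for day 1; 132 h and 144 h for day 6): with q12h dosing a "day 1
trough" is not a single timepoint, and the pooled distribution — not
either single reading — reproduces the reported band tables.  Bands:
< 0.5 (efficacy floor), [0.5, 3] closed (target), > 3 (hepatotoxicity),
> 4 mg/L (neurotoxicity).  AUC attainment is strict: AUC₂₄ₕ/MIC > 32 on
the two-fold grid 0.125–32 mg/L.  Default n = 5000 subjects per
scenario; the acceptance script averages three seeds derived from its
`--seed`.  Every report records n and seed; machine output keeps raw
fractions, rendered tables round to whole percent.

## Known limitations

* The clinical concentration data behind the population estimates are
  not public; all datasets here are synthetic, and agreement of the
  simulation study with the reported attainment tables is evidence about
  the model implementation, not about patients.
* MAP estimation ignores IOV (occasion effects are simulated but not
  estimated), so individual estimates on IOV-bearing data absorb
  occasion-to-occasion clearance variation into other parameters.
* The estimation layer is pooled/MAP, not NLME: variability components
  are inputs, never estimates.
* No LOQ/BLQ handling, no covariate search, no parameter-uncertainty
  (confidence-interval) machinery, no intermittent hemodialysis or ECMO.
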