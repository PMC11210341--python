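# Methods

This note documents the models, estimators and numerical choices behind
`forcekinetics`, and what the synthetic-data tests do and do not establish
about real measurements.

## Single-barrier dissociation (Bell–Evans)

A bond pulled at constant loading rate r crosses a single sharp energy
barrier at a force-dependent rate k(F) = k_off·e^{F x_β/k_BT}, where k_off is
the zero-force off-rate and x_β the width of the force-driven dissociation
path. The rupture-force density is

p(F|r) = (k_off/r)·e^{βF}·exp[a(1 − e^{βF})], β = x_β/k_BT, a = k_off k_BT/(r x_β),

with survival S(F) = exp[a(1 − e^{βF})] and mode
F\*(r) = (k_BT/x_β)·ln(r x_β/(k_off k_BT)) (clipped at zero in the
thermal regime). k_BT is fixed at 4.114 pN·nm (298 K) and configurable.
Sampling is by exact inversion, F = (1/β)·ln(1 + E/a) with E ~ Exp(1).

### Maximum-likelihood estimation

`fit_bell_ml` maximises Σ log p(F_i|r_i) over (ln k_off, ln x_β)
(Nelder–Mead; moment-based start from the F-vs-ln r slope). Standard errors
are on log₁₀ of each parameter, from the inverse observed information
(central-difference Hessian) — the table convention of normal errors on
log k, not on k. Three likelihood refinements, each optional:

* **Left truncation** (on by default when events carry a detection floor):
  each event's density is divided by S(floor|r), conditioning on the rupture
  being large enough for the detector to report. Without it, the missing
  sub-noise ruptures bias the fit; with a floor but almost no censored mass
  the correction is negligible, so it is safe to apply always.
* **Measurement-error convolution** (off by default): the density is
  convolved with each event's Gaussian error by 21-node Gauss–Hermite
  quadrature. Whether the original analysis convolved errors is not
  determinable from its description, so both modes exist and are tested.
* **Robust background** (`outlier_fraction`, default 0.01): the density is
  mixed with a uniform background over 1.5× the maximum observed force.
  p(F|r) decays doubly exponentially above its mode, so a single stray
  multi-bond rupture that survives gating can otherwise contribute thousands
  of nats and dominate the objective. One percent background leaves clean
  data essentially untouched (the recovery and coverage tests pass
  unchanged) while bounding any event's influence; `outlier_fraction=0`
  restores the pure likelihood.

## Multivalent dissociation

A two-Fab attachment is an uncorrelated two-state Markov chain: state 2→1 at
2k_off·e^{sβF} and 1→0 at k_off·e^{βF}, with no mechanical coupling between
the bonds. The load-sharing exponent s is ½ when the applied force is shared
equally ("shared", the default) and 1 when each bond bears the full load
("full"); the original description does not disambiguate the two, so both
are implemented and neither is asserted as its intent.

* **Zero force**: lifetimes are 1/(2k_off) + 1/k_off = 1.5/k_off, hence the
  whole-molecule reduction k_off,2bonds = k_off/1.5 and the two-bond
  lifetime 1.5/k_off. `two_bond_off_rate` is this closed form.
* **Under a ramp**: `sample_double_bond_forces` draws final-rupture forces
  exactly (the integrated hazard of an exponentially growing rate is closed
  form, so each Gillespie step is an inversion with no time-discretisation
  error). `predict_double_bond` solves the master equation in force space
  (P₂ analytic; dP₁/dF integrated with LSODA at rtol 1e-10, atol 1e-18 on an
  8000-point grid reaching ~3 modes above the single-bond mode; the
  computed mass must land within 1% of unity or the routine raises). The
  two routes are independent implementations of the same model and agree to
  KS distance < 0.01 at n = 10⁴ — this dual-route check is a test, never a
  substitute for either implementation.

## Association kinetics

Binding probability versus dwell time follows pseudo-first-order kinetics,
P(t) = A·(1 − e^{−(t−t₀)/τ}) for t > t₀ (else 0), fitted by least squares
with inverse-binomial-variance weights (unweighted optional; t₀ ≥ 0, held at
0 by default). The least-squares surface has a degenerate valley at τ→0
(model ≡ A), so the fit is restarted from three characteristic times and the
best kept. The tethered antibody explores a hemisphere of radius
r_eff = linker (6 nm) + half antibody (4 nm), giving
C_eff = 1/(N_A·(2/3)π r_eff³) ≈ 7.9×10⁻⁴ M, and k_on = 1/(τ·C_eff). This
inversion is adopted as the unique dimensionally consistent closure of the
pseudo-first-order model with the hemisphere C_eff; it reproduces the
expected 10⁴–10⁵ M⁻¹s⁻¹ magnitudes with millisecond-scale τ. The
second-bond formation rate is intramolecular and reported directly as
k_on,2bonds = 1/τ₂ (s⁻¹) from the same functional form fitted to the
double-bond fraction.

K_D defaults to k_off/k_on: the published per-condition equilibrium values
equal that ratio arithmetically, although the accompanying text names the
two-bond rate; (k_off/1.5)/k_on is always reported alongside as
`kd_two_bond`.

## Event detection

Candidates are local maxima of the step statistic
d[i] = mean(F[i−19..i]) − mean(F[i+3..i+14]); an event requires
d ≥ SNR·σ (default SNR 2) with σ the MAD-based noise of the first
differences (robust to sparse jumps). Averaging ~20/12 samples on either
side puts the noise-only sd of d near 0.37σ, which is what makes the
false-positive rate at SNR 2 effectively zero while a 4 pN step at σ = 3 pN
stays below threshold. The peak is snapped to the last sample that still
carries sustained load; a second pass searches a short window upstream of
each confirmed rupture for a step onto a still-loaded intermediate plateau,
resolving sequential double ruptures only a few samples apart (safe on
single-bond curves, where the pre-rupture ramp makes that statistic
negative). Rupture forces are read from the unsmoothed trace as the endpoint
of a short line fit through the last loaded samples, relative to the
end-of-trace baseline; per-event noise is the MAD-based sd of that baseline.
Window parameters are in samples and assume an acquisition pitch of
roughly 1.5–3.5 nm per sample (2000 samples over ~3000 nm); curve sets at a
different pitch should scale `samples_per_curve`/`z_range` accordingly.
Curves with more than two events are classified from the last two (logged);
two events within 5 nm (configurable) count as simultaneous.

Single-bond gating follows the ±2σ rule on the first component of a
two-Gaussian mixture fitted per retraction velocity (pooling velocities
would smear the modes together). A mixture whose components fail Ashman's
D ≥ 2 or whose minor weight is < 2% is degenerate; the pipeline then falls
back to a robust unimodal gate, median ± 2×(1.4826·MAD). The pipeline
excludes morphologically classified multi-bond curves from the Bell pool up
front — their final rupture starts from a pre-loaded surviving bond and does
not follow fresh single-bond statistics.

## Elasticity and loading rates

The pre-rupture stretch is fitted with the interpolated worm-like-chain law
F(x) = (k_BT/L_p)[1/(4(1−x/L_c)²) − ¼ + x/L_c] on the deflection-corrected
extension x = z − F/K_c; K_L is the analytic derivative at the rupture
force, lumping linker and membrane compliance into a single effective
molecular spring. Because the WLC extrapolation diverges when the fitted
contour length lands near the rupture extension, K_L is cross-checked
against the local linear slope of the final 20 stretch samples and replaced
by it when they disagree by more than a factor 2 (flagged
`linear_fallback`). K_eff = (1/K_c + 1/K_L)⁻¹ is the series-compliance
combination — the physically correct model for a cantilever pulling through
a linker (the printed compliance sum without the outer inverse is read as
shorthand for it) — and r = v·K_eff.

## The synthetic-data generator

`simulate_force_curve` emulates the measurement the analysis assumes: 2000
samples per curve over a 3000 nm z-range, cantilever 0.007–0.012 N/m
(default 0.01), approach ramp to a 30–100 pN force limit (default 60),
thermal force noise of a few pN (default 3), retraction velocities spanning
loading rates of ~50–5000 pN/s. The tether is a WLC (contour 6 nm,
persistence 0.38 nm — typical PEG values, overridable)
in series with a linear membrane spring (default 0.35 pN/nm, chosen so the
effective stiffness ≈ 0.33 pN/nm gives r ≈ 1000 pN/s at 3000 nm/s and
reproduces the hundreds-of-nm membrane stretch of bound curves). Rupture
times are drawn by inverting the cumulative Bell hazard integrated along the
actual force trajectory, so sampled forces are exactly consistent with the
Bell density at the local loading rate v·dF/dz. Double bonds are rendered as
two parallel tethers sharing extension: the first rupture drops the trace to
the single-tether tension (a visible step of roughly half the force) and
loading continues until the second rupture. The escape kinetics use the
same two-state rates as the branch model; note the branch model
(`sample_double_bond_forces`/`predict_double_bond`) idealises the force as
an uninterrupted ramp, so its final-force distribution describes bonds
loaded through one shared tether, while the renderer's doubles re-load after
a drop — both pictures occur in real data and the package keeps them
distinct. Bond formation is Bernoulli per curve with P(t) from the dwell
law and double fraction A·f₂·(1 − e^{−k_on,2bonds·t}) (f₂ default 0.5, the
saturated double-bond share consistent with roughly half of bound events
being bivalent). The tip–cell contact extent is dwell·v/2 per segment
(capped at a quarter of the z-range, remainder as an explicit constant-
height dwell segment), so the analyst-side dwell computation — contact
travel divided by velocity, contact point extrapolated from a line fit of
the compressive ramp — recovers the nominal dwell without bias.

Ground truth (class, rupture forces/positions, instantaneous loading rates)
lives only in a `truth` sidecar written to a separate JSON file; analysis
code cannot accidentally consume it. Default kinetic truths and the three
condition presets carry the reference values of the three benchmark conditions
(k_off 0.23/0.77/0.31 s⁻¹; x_β 12.3/11.05/14.01 Å; k_on
4.79/3.60/5.96×10⁴ M⁻¹s⁻¹ via τ = 1/(k_on·C_eff); k_on,2bonds
17.8/16.7/22.2 s⁻¹).

What the generator does **not** emulate: instrument drift, hydrodynamic
drag, cantilever ringing, surface adhesion unrelated to the specific bond,
receptor clustering/diffusion, or velocity-dependent membrane rheology.
Passing recovery tests therefore show the estimators are correct for the
assumed data-generating model at realistic noise and sample sizes — not that
real curves satisfy those assumptions.

## Problem sizes and tolerances in the test suite

Recovery tests run at a realistic per-condition scale where cheap (1000
curves per dwell point for association; 2000 gated events across four
loading rates, 50 replicates, for off-rate coverage) and at a few hundred
curves per cell for the full end-to-end campaign, which keeps the whole
suite within a few minutes. End-to-end estimates carry small systematic
components beyond counting error (detection censoring, force-readout and
stiffness-assignment scatter, residual multi-bond contamination), so the
flagship recovery test allows 3.5 propagated standard errors where
stage-isolated tests use 2–3. Closed-form identities (k_off/1.5, 1/k_off,
k_off/k_on, the 10% binding-probability example) are asserted exactly at
printed precision.
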