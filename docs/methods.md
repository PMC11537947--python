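# Methods

## The model

`sacfield` simulates saccade initiation in the gap task with a
one-dimensional dynamic neural field standing in for the motor map of the
intermediate superior colliculus (SC). The field has N = 100 nodes over
−5…+5 mm of collicular surface on a torus (node spacing Δx = 0.1 mm,
wrap-around distances everywhere, so there are no boundary artifacts).
Each node carries an internal state `u` (arbitrary membrane-potential-like
units) mapped to an output activity `a ∈ (0, 1)` by a sigmoid with
steepness β = 0.09. The field evolves in 1-ms steps as a leaky integrator
with time constant τ = 4 ms:

    u(t+Δt) = (1 − Δt/τ) u(t) + (Δt/τ) (c_ext(t) + W a(t))

`W` is a lateral-interaction matrix built from a Gaussian of width
σ = 0.85 mm and peak sf = 74.7, shifted down by m = 0.8·max(G) and scaled
by Δx: nearby nodes excite each other (W on the diagonal is 1.494), and
every distant pair inhibits (−5.976 per entry beyond ~2 mm; the sign
change sits at 0.568 mm). Because the shift term sums over all 100 nodes,
the field operates in a strongly globally-inhibited regime: total
activity Σa feeds back as −m·Δx·Σa ≈ −60·mean(a)·10 on every node, and
this collective term — not any single input — is the largest force in the
model. At every trial start `u` is reset to −30 at all nodes, so trials
are independent.

A saccade is initiated at the first millisecond at which any node outside
the central fixation zone (|x| > 1 mm, configurable) reaches an output
activity of 0.7; the SRT is that time minus target onset. Ties across
nodes are broken by largest activity, then smallest node index. A trial
with no crossing within 500 ms of target onset is recorded as containing
no saccade. The dynamics are noise-free: all trial-to-trial variability
comes from the parameter draw, so a given assignment reproduces bitwise
the same trial.

## Trial timeline and the eight inputs

A trial is 200 ms of fixation, a 200 ms gap, then target onset at ±2 mm
(the 6° eccentricity mapped to collicular surface; side drawn 50/50 and
dynamically irrelevant by mirror symmetry). The external drive `c_ext`
is the signed sum of eight component inputs, each a spatial profile times
a piecewise-linear temporal envelope. Spatially localized inputs use a
toroidal Gaussian kernel with γ = 0.6 mm and amplitude 1.05. Envelopes
rise by RoR percent of the input's maximum strength (MaxVal) per
millisecond; a 10% RoR therefore reaches its cap in 10 ms.

1. **Visual transient** — excitatory burst at the target, onset 20 ms
   after target onset for marmosets and 50 ms for humans; rises to cap
   and immediately decays at the same rate (a triangle ~10–20 ms wide).
2. **Automated motor** — excitatory ramp-and-hold at the target,
   onset 30–90 ms after the target.
3. **Automated fixation** — excitatory ramp at the center from fixation
   onset; ramps back to zero from gap onset (the foveal stimulus is
   gone).
4. **Voluntary motor** — excitatory, uncapped ramp at the target from
   the internal onset; it rises until a saccade is made. Because it has
   no cap, its RoR is read as an absolute rise of RoR/100 drive units
   per ms (reference strength 1.0, configurable). This scale was chosen
   once so that the slowest build-up level (1%) is genuinely sluggish —
   producing delayed saccades beyond 250 ms in the slow corner of the
   final marmoset grid — while 10–20% crosses within a few tens of ms of
   the internal onset; with a much larger scale the remaining drives
   cross threshold on their own and slow build-up would never matter.
5. **Voluntary fixation** — excitatory at the center from fixation
   onset, ramped back to zero from the internal onset (voluntary
   disengagement precedes the saccade).
6. **Voluntary preparation** — excitatory at both candidate target
   locations (±2 mm) from the internal onset; its rate is tied to its
   MaxVal so the cap is reached in a fixed 100 ms.
7. **Inhibitory gate** — inhibitory over the entire motor map (every
   non-central node) from trial start; from the internal onset it is
   released under a Gaussian window centered on the target.
8. **Peripheral inhibition** — inhibitory over the motor map from trial
   start, released uniformly from the internal onset.

Inputs 4–8 share one jointly drawn onset delay relative to target onset,
the *internal onset* — the model's express/regular watershed.

Two conventions here deserve their rationale.

**Proportional release.** The two inhibitory inputs release by losing
RoR percent of their *current* value per millisecond (geometric decay),
not a fixed amount per millisecond. A linear release would clear any
barrier in exactly 100/RoR ms regardless of its depth, making gate depth
irrelevant a few milliseconds after the internal onset; proportional
release makes a deeper barrier leave a proportionally larger residual at
every time, so deeper inhibition always delays (never accelerates) the
saccade, and a 1% release rate acts as a ~100 ms disinhibition time
constant — the mechanism behind the heavy right tail of the final
marmoset configuration.

**The gate spares the fixation zone.** The inhibitory gate suppresses
motor commands, so it spans the motor map but not the central fixation
zone. This is not cosmetic: in this field's globally-inhibited regime,
central fixation activity (driven by inputs 3 and 5) contributes a large
share of Σa. A gate that also suppressed the fixation zone would lower
Σa, weaken the collective inhibition everywhere, and thereby *speed up*
saccades as it deepens — inverting the gate's function on every
assignment we simulated. Confined to the motor map, a deeper gate
strictly delays initiation, matching its physiological role.

## Controlled variability

Each input attribute (onset delay, RoR, MaxVal) takes one of a small set
of levels, drawn independently and uniformly per trial; the internal
onset is drawn once and mirrored to inputs 4–8. The marmoset grids come
in three cumulative modification steps and the human grids in two:

- **Step 1** shortens the internal onset (75/100/125 ms marmoset,
  100/115/130 ms human).
- **Step 2** (marmoset) accelerates the visual pathway: visual-transient
  onset 20 ms, RoR up to 20%; automated-motor onset 30–60 ms, RoR
  6–10%; and adds a weak level (MaxVal 2) to the voluntary-fixation,
  inhibitory-gate and peripheral-inhibition sets — occasional weak
  fixation and weak inhibition. The human step 2 mirrors only the
  input-1/2 adjustments.
- **Step 3** (marmoset) adds slow levels: 1% RoR for the voluntary
  motor, inhibitory gate and peripheral inhibition, with fixation-input
  rates pinned at 8%.

The final marmoset grid has ten 3-level and three 4-level attributes
(3^10 × 4^3 = 3,779,136 combinations); the final human grid has thirteen
3-level attributes (3^13 = 1,594,323). All level sets live in an
editable YAML file shipped with the package; the hidden print cells of
the source settings table are reconstructions constrained by those
counts and are flagged as such there.

At batch scale (2,000 trials, matched seeds) the steps behave as
intended: the marmoset step-2 median is below step 1, step 3 produces a
>250 ms tail (~1–1.5% of trials) absent in step 2, the marmoset step-3
median sits ~7–10 ms below the human step-2 median (rank-sum p ≪ 0.05),
and no built-in grid cell fails to saccade within the 500 ms window.

## Synthetic behavioural data

No behavioural recordings ship with the package; the generator emulates
their statistical structure so every analysis stage is testable offline.
Marmoset latencies are a mixture of a truncated normal express component
(68 ± 6 ms, weight 0.25) and a shifted log-normal regular component
(75 + LogNormal(4.2085, 0.8323) ms), hard-truncated below 61 ms and
calibrated so the composite median is ≈122 ms and ≈9.4% of saccades
exceed 250 ms. Human latencies are a single shifted log-normal
(100 + LogNormal(3.8501, 0.4378) ms, truncated below 108 ms; median
≈147 ms, ≈0.4% beyond 250 ms). Latencies are rounded to whole
milliseconds (the model's resolution). The landing-point generator adds
an anticipatory fraction (12% by default) at latencies uniformly below a
60 ms boundary with errant-biased direction (60% errant), while visually
driven saccades land near the target with 2% errant contamination —
enough structure for the boundary estimator to recover the boundary
within one 6-ms bin at n = 5,000.

What passing these tests shows is that the pipeline recovers the
summary statistics it was calibrated to; it does not certify
distributional fidelity to real recordings beyond those statistics
(shape details of real marmoset express modes, per-subject
heterogeneity, and sequential effects are all absent).

## Analysis conventions

- Saccade classes: anticipatory < 50 ms (including pre-target
  latencies), express 50–75 ms (marmoset) or 50–100 ms (human), regular
  above. The human express ceiling is a convention; humans in this
  paradigm show almost no express saccades.
- The anticipatory boundary is the left edge of the first 6-ms bin in
  which correct saccades outnumber errant ones for three consecutive
  bins (run length configurable); samples without errant saccades are
  flagged and fall back to the minimum-latency bin edge.
- R² and MSE are computed on 6-ms-binned proportion vectors over a
  common range (so MSE magnitudes are on the proportion scale);
  R² = 1 − SS_res/SS_tot about the observed mean.
- The Wasserstein distance is the first-order 1-D distance in
  milliseconds (the integral of |ΔCDF|); no additional normalization is
  applied, and model variants are compared by their ratio, which is
  scale-free.
- Quantiles use linear interpolation between order statistics (type 7).
  The rank-sum test uses exact enumeration for tie-free samples of ≤10
  per group and the tie-corrected normal approximation otherwise.

## Numerical choices and problem sizes

Batches are simulated in vectorized chunks (128 trials in lockstep);
this is arithmetically the same update as the single-trial path and the
test suite asserts SRT-level agreement between the two. The default
problem sizes — 2,000 trials per model batch and 10,000 synthetic
behavioural trials — were chosen as the package's standard desk-scale
configuration; they put ~1-ms standard errors on batch medians and
resolve tail fractions of a few tenths of a percent. Envelope
turnover for the transient burst happens at the first whole millisecond
at or above the cap, so the incremental (per-ms) and closed-form input
updates agree exactly. The exponent of the proportional release is
clipped so a release window amplitude above 1 can never drive an input
negative.

## Known limitations

- One spatial dimension: only horizontal saccades, no oblique geometry,
  no amplitude/velocity kinematics (the model stops at initiation).
- The express mode of real marmoset data (50–75 ms) is below the
  simulated minimum (~internal onset + a few ms ≈ 85 ms); as in the
  source modelling tradition, the simulated distribution covers the
  visually-and-internally-driven regime, not anticipatory behaviour.
- The globally-inhibited regime implied by the printed field constants
  makes collective background activity the dominant force; conclusions
  about single-input manipulations outside the tested grids should be
  checked against the monotonicity suite before being trusted.
- Parameter grids are sampled, never fitted: the package deliberately
  contains no optimizer.
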