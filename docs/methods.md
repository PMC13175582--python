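# Methods

`sepcue` implements a nearest-neighbor decision-support engine for sepsis
treatment: ICU patient states are embedded with a denoising trajectory
autoencoder, the 100 nearest cohort states of a query state are retrieved
exactly, and a set of reasoning cues (R1–R8) is computed over those
neighbors and assembled into seven interface payloads.  Everything is
testable end-to-end on a bundled synthetic EHR generator with closed-form
ground truth.

## The synthetic cohort generator

Real critical-care EHR data is access-restricted, so the package ships a
generator whose structure matches the assumptions the cue engine relies
on, with every generating quantity available in closed form.

**Latent severity.** Each patient carries a scalar severity process
`s_t` on 4-hour steps: a bounded AR(1),
`s_{t+1} = ρ s_t + δ + ε`, `ε ~ N(0, σ²)`, clipped to [−3, 3], with
`ρ = 0.9`, drift `δ = 0` and innovation SD `σ = 0.35` by default.  This is
the simplest process that makes outcome risk a smooth function of the
patient state — the property that nearest-neighbor risk estimation
assumes.

**Emissions.** The state vector has 16 vital/lab features plus 4 constant
demographics.  Vitals and labs are linear-Gaussian emissions of severity
(`value = μ_f + λ_f s_t + noise`), with clinically signed loadings
(tachycardia, hypotension, rising lactate with severity).  Vitals are
observed about once per bin (per-bin missingness 0.15 by default); labs
are ~3× sparser.  Demographics do not load on severity.

**Clinician policy.** At each bin the simulated clinician samples a volume
action (fluids / nothing / diuretics) and a vasopressor action
(increase–start / maintain / decrease–stop) from a softmax over utilities
that penalize the squared mismatch between an action's intensity (+1/0/−1)
and `tanh(severity)`.  `policy_temperature` scales the softmax:
small values give strong severity-tracking consensus, large values give a
near-uniform (ignorable) policy.  `action_persistence` (default 0.75) is
the per-bin probability of repeating the previous plan, producing
realistic treatment runs.  Vasopressor administration is a device state:
"increase-or-start" turns it on, "decrease-or-stop" turns it off,
"maintain" leaves it unchanged — so an *observed* increase/decrease
requires an actual toggle, and a fully persistent policy produces only
"maintain" observations.

**Outcomes.** Each patient has a decision state (bin 2, i.e. 8–12 h after
admission, or the last bin for shorter stays).  In-admission mortality is
drawn once per patient from
`P(death) = sigmoid(β₀ + β₁ s_d + effect(plan_d))`, where `plan_d` is the
treatment plan realized over the 12-hour window after the decision bin —
discretized by exactly the same rule the cue engine uses — and
`action_effects` maps every cell of the 3×3 plan grid to an additive
log-odds shift (all zero by default).  Defaults `β₀ = −1.2`, `β₁ = 1.8`
give ≈30% cohort mortality.  The vasopressor-at-+12 h label is mechanical
(pressor activity 3 bins ahead) and needs no outcome model.  Comfort
measures only (CMO) orders fire with a small per-bin hazard; suspicion
events (antibiotic + culture within a few hours) are generated for 95% of
patients.

**What the generator does not emulate.** Multivariate physiology beyond a
single severity factor, informative measurement timing, treatment effects
on the severity *trajectory* (effects act directly on the outcome draw),
multiple ICU stays, and ventilation/renal support.  Passing tests
therefore demonstrate that the statistical machinery is correct under the
stated model, not that the cues are clinically valid on real data.

## Cohort construction

Filters and constants follow the suspected-sepsis cohort definition:
antibiotic and culture within 24 h of each other (inclusive window,
earliest qualifying pair), at least 12 h in the ICU (inclusive, measured
from admission), truncation of all data beyond the cohort-level 95th
percentile of stay length (linear-interpolation percentile over eligible
patients, computed before the train/eval split), and removal of timesteps
at or after a CMO order.  Bins are half-open `[4i, 4i+4)` hours from
admission; an event exactly on a boundary belongs to the later bin.
Vitals are averaged within a bin; labs take the most recent observation
and carry forward with an imputed flag; before the first observation a
feature carries the cohort median (imputed flag set).  Fluids are summed
per bin; vasopressor/diuretic flags are any-administration-in-bin.

Labels: `died_in_admission` is the admission's death flag regardless of
horizon.  `on_vasopressor_at_plus_12h` for bin *i* is the vasopressor flag
of bin *i+3*; it is undefined whenever that bin is absent from the
truncated trajectory — for any reason (live discharge, death, CMO or
percentile truncation).  One uniform censoring rule avoids treating an
absent future bin differently depending on why it is absent; undefined
labels are excluded from all risk denominators.

Patients are split half/half at the patient level (seeded permutation,
`|train| = floor(n/2)`).  The encoder, the z-scoring statistics and the
neighbor pool come from the training half; queries come from the
evaluation half.

## Embedding

The denoising autoencoder is a causal (left-to-right) multi-head
self-attention encoder implemented directly in numpy with hand-derived
gradients (verified against finite differences in the test suite) and
Adam.  Defaults: model width 32, 2 blocks, 4 heads, feed-forward factor 4,
sinusoidal positions, post-layer-norm residual blocks.  Inputs are
z-scored features (train-split statistics; zero-SD features contribute 0)
plus three binary action flags; training corrupts the features — masking
each entry to the missing-value sentinel with probability 0.3 by default
(Gaussian jitter and shuffle-mix corruption are available) — and
reconstructs the clean sequence at every timestep with MSE on continuous
channels and cross-entropy on the flags.  The embedding of a state is the
final hidden vector at its timestep; causal masking guarantees it uses
only the patient's past, so cues are honest at decision time (verified by
a truncation-invariance test).

A model-free baseline embedding (the z-scored raw feature vector) obeys
the same contract and is used wherever a deterministic oracle is
preferable to a trained model; every downstream operation accepts either.

## Retrieval

Exact brute-force k-NN (default k = 100, Euclidean; cosine switchable)
with deterministic tie-breaking by (distance, patient_id, bin_index).  The
query's own state is always excluded; by default all states of the query's
patient are excluded so a patient's past cannot dominate their own cue
statistics.  Approximate indexes are deliberately unsupported: cue
statistics over only 100 neighbors are sensitive to retrieval noise, and
the cohort sizes involved make exact search cheap.

## Reasoning cues

* **R1/R2 (consistent/unusual features).** For each non-imputed feature,
  the discrepancy `d_f = |z(query) − mean z(neighbors)|` and the neighbor
  dispersion `s_f = SD of neighbor z`.  R2 shows the `max_features = 3`
  largest `d_f`.  R1 ("consistent") requires both agreement and tightness:
  candidates are restricted to features with `s_f` at or below the median
  dispersion, then the smallest `d_f` win.  Ties break by feature name.
* **R3 (risk score).** Outcome frequency among neighbors with a defined
  label, banded low/moderate/high at 1/3 and 2/3 — three levels to match
  low / "as likely as not" / high phrasing.
* **R4 (plan-conditional risk difference).** Neighbors are partitioned
  into takers of the queried plan vs the rest (each-plan-vs-rest);
  "statistically significant" is a two-sided Fisher exact test on the 2×2
  outcome table at α = 0.05 — exact at the small counts a 100-neighbor
  pool produces.  With fewer than `min_support = 10` takers the
  conditional risk and p-value are reported undefined and the flag is
  false.
* **R5/R6 (peer actions).** Per-category action counts over neighbors'
  observed plans; consensus requires a unique modal action strictly above
  60%.  A tied mode is no consensus.
* **Observed plans.** A neighbor's plan at bin *i* is read from the next
  three bins (the 12-hour decision window, matching the vasopressor
  label horizon): any fluid → give_fluids (fluids win over a simultaneous
  diuretic, logged), else any diuretic → give_diuretics, else none; the
  vasopressor action compares activity at the window end against bin *i*.
  Windows cut short by the end of a trajectory are computed on the
  available bins and flagged partial.
* **R8 (recommendation).** By peer actions: the modal action of each
  category.  By risk: the sufficiently-supported plan with a significant
  and lower conditional risk, lowest risk first, canonical plan order
  breaking ties; absent when no plan qualifies.

## Interfaces

Seven payloads with fixed cue composition (case features {R1,R2}; two risk
interfaces {R3}; two interactive variants {R7,R3,R4,R5,+R8 when the
selected plan is significantly better}; prior clinician actions
{R7,R5,R6} with an implicit modal plan flagged `implicit: true` and no
outcome-derived numbers anywhere in the payload; treatment recommendation
{R7,R8}).  Interactive payloads require a selected plan and set a
no-recommendation flag when its support is below 10/100.  Payloads are
versioned JSON validated by an in-package schema validator
(`payload_schema.json` is the shipped source of truth).

## Calibration experiments

`sepcue.calibration` characterizes the R4 flag under known generating
conditions.  Two design points matter and were chosen for statistical
validity:

* **Independence of replicates.** A patient's mortality label is shared by
  all their states, and plan windows overlap across adjacent bins, so
  neighbor pools containing several states per patient violate the Fisher
  test's independence assumptions (measured null flag rates 0.07–0.13).
  Likewise, many queries into one cohort share any chance cohort-level
  plan–outcome association, making a single-cohort flag rate heavily
  overdispersed.  The type-I experiment therefore draws 50 independent
  ~2,000-state cohorts with 10 queries each and uses one state per patient
  (the decision state) as the pool.  Under this design the flag rate is
  0.02–0.04 across seeds.  Note the exact unconditional size of a
  two-sided Fisher test at these margins (~33 takers of 100, outcome rate
  ~0.3) is 0.031–0.040 — below nominal α by discreteness; this is a
  property of the exact test, not an implementation artifact.
* **Common random numbers for the consistency curve.** The MAE of the
  100-neighbor risk against the closed-form per-patient probability is
  compared across pool sizes 500/2,000/8,000 using nested pools from one
  generated cohort and one fixed query set (500 evaluation decision
  states), isolating the pool-size effect from between-cohort noise.

The calibration cohorts use a uniform (`policy_temperature = 50`) fully
persistent policy: uniformity makes plan assignment ignorable, so the
zero-effect null actually holds; persistence makes the observed plan equal
the sampled plan and concentrates support near one third of the pool,
where the 2×2 tables are least discrete.  Power is evaluated on neighbor
sets of 35 takers + 65 others sampled from a generator that shifts the
target plan's risk from 0.5 to 0.2.

## Numerical and degenerate-input choices

Percentiles use linear interpolation.  Zero-SD features are excluded from
z-scores and feature cues (logged).  Empty partitions give undefined
p-values, never exceptions.  An empty feature-cue (no eligible feature) is
a valid result.  All randomness flows from explicit integer seeds;
training, simulation and retrieval are bit-reproducible given the same
seed and thread configuration (everything is float64 numpy).

## Problem sizes used in the shipped experiments

Experiments run on cohorts of a few hundred to a few thousand patients
with ~16–120 h mean stays (hundreds to ~9,000 states), 100-neighbor pools,
500 replicates for rate estimates, and 200-trajectory autoencoder training
runs with 6 epochs — sizes at which every documented property is already
measurable with comfortable margins on a single CPU.

## Known limitations

Plan-conditional risks are observational contrasts among similar patients,
not causal estimates; the same caveat applies to the synthetic
cohorts too whenever the policy temperature is low (severity-confounded
treatment).  The Fisher flag is anticonservative when the neighbor pool
contains multiple correlated states per patient — a real concern for
deployments that index every timestep; the calibration section quantifies
this.  The generator's single-factor severity makes neighborhoods easier
to find than in real EHR data; embedding quality claims do not transfer.
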