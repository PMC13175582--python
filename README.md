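# sepcue

Nearest-neighbor reasoning cues for sepsis treatment decisions.

Sepsis management hinges on three treatments — IV fluids, vasopressors and
diuretics — whose best use for an individual ICU patient is often
genuinely uncertain.  `sepcue` implements a decision-support engine that,
instead of issuing a single opaque prediction, surfaces discrete
*reasoning cues* derived from the 100 most similar patient states in a
cohort:

| cue | meaning |
|-----|---------|
| R1 / R2 | features of the case most consistent with / most unusual against its neighbors |
| R3 | outcome risk among neighbors (vasopressor need at +12 h, or in-admission mortality), banded low / moderate / high |
| R4 | whether neighbors who took a given treatment plan had a significantly different risk (two-sided Fisher exact test, α = 0.05) |
| R5 | how frequently each action was taken among neighbors |
| R6 | whether a single action reaches strict >60% consensus |
| R7 | a treatment-plan mention |
| R8 | a recommended plan, by peer actions or by risk scores |

A *plan* is a cell of the 3×3 grid (give fluids / nothing / give
diuretics) × (increase-or-start / maintain / decrease-or-stop
vasopressors).  Conditional risks and recommendations are gated on a plan
being taken by at least 10 of the 100 neighbors.  Cues are assembled into
seven JSON interface payloads (case features, two risk displays, two
interactive plan-conditional displays, prior clinician actions, and a
direct recommendation).

The pipeline: relational EHR event tables (a documented MIMIC-like CSV
schema) → suspected-sepsis cohort filters (antibiotics + culture within
24 h, ≥12 h ICU stay, truncation at the 95th-percentile stay length,
censoring after comfort-measures-only orders) → 4-hour patient-state
trajectories → a denoising trajectory autoencoder (causal self-attention,
implemented in numpy with hand-derived gradients) → exact k-NN retrieval →
cues → payloads.  Because real critical-care EHR data is
access-restricted, the package includes a synthetic cohort generator with
a latent-severity process, a configurable clinician policy, and
closed-form plan-conditional outcome probabilities, so every stage is
testable against known ground truth.  `docs/methods.md` describes the
models and the design decisions in detail.

Audience: researchers studying AI-assisted clinical decision making who
need a reproducible, inspectable cue engine, and methods developers who
want a harness in which retrieval, risk estimation and significance
flagging can be validated against a generator with known truth.

## Worked example

```bash
sepcue simulate   --n 200 --seed 7 --out cohort/
sepcue preprocess --cohort cohort/ --out prep/
sepcue train      --prep prep/ --out model/
sepcue embed      --model model/ --prep prep/ --out embeddings.parquet
sepcue interface  --name interactive_mortality_risk --prep prep/ \
                  --embeddings embeddings.parquet \
                  --patient P00003 --bin 2 --plan "give_fluids|maintain"
```

The first four commands print progress
(`wrote 200 patients to cohort`, `183 eligible patients (91 train / 92
eval) -> prep`, `trained 6 epochs; final loss 1.19186 -> model`,
`wrote 4689 embeddings to embeddings.parquet`: 17 of 200 simulated
patients fail the suspicion or 12-hour filters).  The last prints the
interactive mortality payload for patient P00003 at bin 2 (8–12 h after
admission), conditional on the selected plan "give fluids, maintain
vasopressors":

```json
{
  "cues": [
    {"cue_code": "R7", "plan": "give_fluids|maintain", "partial_window": false},
    {"cue_code": "R3-M", "probability": 0.4545, "n_defined": 33, "level": "moderate",
     "conditional_on_plan": "give_fluids|maintain"},
    {"cue_code": "R4-N", "n_plan": 33, "n_rest": 67, "p_value": 1.0,
     "risk_plan": 0.4545, "risk_rest": 0.4776, "significant": false},
    {"cue_code": "R5-Y", "plan": "give_fluids|maintain", "count": 33, "frequency": 0.33}
  ],
  "no_recommendation": false, "...": "..."
}
```

Reading it: 33 of the patient's 100 nearest neighbors received this plan
(`R5-Y`: enough support to show outcome data); among them 45.5% died in
the admission (`R3-M`, moderate), statistically indistinguishable from the
47.8% among the other 67 neighbors (`R4-N`, p = 1.0) — an equipoise
signal, so no R8 recommendation is inferred.  Values are abbreviated here;
the command prints full precision.

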