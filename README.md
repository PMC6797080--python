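# juncture

Multilevel decision-juncture models for implementation science: structural
causal DAGs with identification queries, a hierarchical decision-based
simulator, and Monte Carlo studies showing that implementation and
intervention effects are recovered consistently with minimal covariate sets.

## The problem

Evaluations of evidence-based practices in healthcare systems usually treat
*implementation* outcomes (was the program adopted? did practitioners find it
feasible?) and *intervention* effectiveness (did patients improve?) as
separate questions. This package models both as one system: a chain of
stakeholder decisions — an organization decides to implement (D1), chooses a
basic or enhanced implementation strategy (D2), practitioners form
perceptions of feasibility (X4) and appropriateness (X5) and decide patient
by patient whether to assign the treatment (T1), and assignment moves the
follow-up outcome (Y2). Each decision is a latent-utility threshold

    d = 1[ β₀ + β'·(observed causes) + ε > 0 ],   ε ~ N(0, 1)

so that probit regression is the correctly specified estimator, and each
continuous variable is linear in its structural parents with normal errors.
The causal structure is a DAG with bidirected edges for unobserved
correlated errors (here: management style Z2 ↔ perceived leadership X2).

The built-in canonical system is a hypothetical regional scale-up of
cognitive behavioral therapy (CBT) for youth anxiety: 40 organizations × 5
practitioners × 30 patients = 6 000 patients. Organizations that do not
implement (D1 = 0) contribute no strategy choice, perceptions, assignments
or follow-up scores — downstream variables are missing by selection, and
every identification query conditions on D1.

The package answers three questions about such a system:

1. **Identification** — which covariate sets satisfy the back-door
   criterion for each effect (d-separation, validity checks, enumeration of
   all inclusion-minimal adjustment sets)?
2. **Simulation** — what does a hierarchical draw from the system look
   like, and what are the *true* average effects in that particular sample
   (computed by replaying the structural equations under interventions with
   all error draws held fixed)?
3. **Estimation** — do OLS (continuous outcomes) and probit average
   marginal effects (binary decisions), under a back-door-minimal "short"
   specification or an all-parents "full" specification, recover those
   truths across repeated samples?

## Worked example

```python
import juncture as j

model = j.canonical_cbt_model()

report = j.validate_claims(model)       # certify the encoded DAG
assert report.all_passed

data = j.draw_population(model, j.PopulationConfig.from_model(model, seed=1))
truths = j.true_sample_effects(model, data)
print("implementing organizations:", int(data.organizations["D1"].sum()), "of 40")

for treatment, outcome in [("D2", "X4"), ("X4", "T1"), ("T1", "Y2")]:
    spec = j.build_specification(model, treatment, outcome, "short")
    est = j.fit(model, data, spec)
    print(f"{spec.estimand_id} short, adjust {{{', '.join(spec.covariates)}}}: "
          f"estimate {est.estimate:.3f} (SE {est.se:.3f}), "
          f"sample truth {truths[spec.estimand_id]:.3f}")
```

prints

```
implementing organizations: 21 of 40
D2->X4 short, adjust {X2, Z1}: estimate 0.620 (SE 0.153), sample truth 0.500
X4->T1 short, adjust {X2, X5, Z1}: estimate 0.095 (SE 0.014), sample truth 0.115
T1->Y2 short, adjust {V1, V2, Y1}: estimate 0.928 (SE 0.039), sample truth 1.000
```

Reading the output: the strategy effect on perceived feasibility (D2→X4) is
estimated from only ~21 implementing organizations, so a single sample is
noisy (0.62 against a truth of 0.50, SE 0.15 clustered at the organization
level); the feasibility effect on assignment probability (X4→T1) is a
probit average marginal effect — one unit of perceived feasibility raises
the assignment probability by about 11 percentage points in truth; the
treatment effect on the follow-up score (T1→Y2) is estimated on ~3 000
patients and lands close to its true value of 1. Averaged over many
repetitions these estimators are unbiased — that is the Monte Carlo study:

```bash
juncture mc --reps 1000 --seed 0 --out results/mc
```

writes per-repetition records, a bias summary table, and a
point-with-interval figure of mean relative bias per (estimand,
specification). `juncture identify --claims` prints the identification
report, `juncture simulate` writes one draw as a CSV bundle, and
`juncture report` re-summarizes stored repetitions.

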