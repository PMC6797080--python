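nodes:
- id: B1
  level: organization
  kind: continuous
  label: perceived strength of evidence
- id: D1
  level: organization
  kind: binary-decision
  label: implement CBT at all
- id: D2
  level: organization
  kind: binary-decision
  label: enhanced vs. basic strategy
- id: T1
  level: patient
  kind: binary-decision
  label: practitioner assigns CBT
- id: V1
  level: patient
  kind: continuous
  label: patient age
- id: V2
  level: patient
  kind: binary-decision
  label: patient gender
- id: V3
  level: patient
  kind: continuous
  label: socio-economic status
- id: W
  level: organization
  kind: deterministic-aggregate
  label: aggregate cost
- id: W1
  level: organization
  kind: continuous
  label: anticipated cost, basic strategy
- id: W2
  level: organization
  kind: continuous
  label: anticipated cost, enhanced strategy
- id: X1
  level: practitioner
  kind: continuous
  label: practitioner age
- id: X2
  level: practitioner
  kind: continuous
  label: perceived leadership
- id: X3
  level: practitioner
  kind: continuous
  label: tenure in current job
- id: X4
  level: practitioner
  kind: continuous
  label: perceived feasibility
- id: X5
  level: practitioner
  kind: continuous
  label: perceived appropriateness
- id: Y1
  level: patient
  kind: continuous
  label: baseline symptom score
- id: Y2
  level: patient
  kind: continuous
  label: follow-up symptom score
- id: Z1
  level: organization
  kind: continuous
  label: intra-organizational networks
- id: Z2
  level: organization
  kind: continuous
  label: management style
- id: Z3
  level: organization
  kind: continuous
  label: organizational structure
edges:
- - B1
  - D1
- - B1
  - D2
- - D2
  - X4
- - D2
  - X5
- - T1
  - Y2
- - V1
  - T1
- - V1
  - Y2
- - V2
  - T1
- - V2
  - Y2
- - V3
  - Y1
- - V3
  - Y2
- - W
  - D1
- - W1
  - D2
- - W1
  - W
- - W2
  - D2
- - W2
  - W
- - X1
  - X4
- - X1
  - X5
- - X2
  - T1
- - X2
  - X4
- - X2
  - X5
- - X3
  - T1
- - X4
  - T1
- - X5
  - T1
- - Y1
  - T1
- - Y1
  - Y2
- - Z1
  - D1
- - Z1
  - D2
- - Z1
  - T1
- - Z1
  - X4
- - Z1
  - X5
- - Z2
  - D1
- - Z2
  - D2
- - Z3
  - D1
bidirected:
- pair:
  - X2
  - Z2
  correlation: 0.5
equations:
- child: B1
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: D1
  parents:
  - Z1
  - Z2
  - Z3
  - B1
  - W
  intercept: 0.0
  coefficients:
  - 0.3
  - 0.3
  - 0.3
  - 0.4
  - -0.3
  link: latent-utility-threshold
  error_sd: 1.0
- child: D2
  parents:
  - Z1
  - Z2
  - B1
  - W1
  - W2
  intercept: 0.0
  coefficients:
  - 0.3
  - 0.3
  - 0.4
  - 0.3
  - -0.3
  link: latent-utility-threshold
  error_sd: 1.0
- child: T1
  parents:
  - Z1
  - X2
  - X3
  - X4
  - X5
  - V1
  - V2
  - Y1
  intercept: 0.0
  coefficients:
  - 0.3
  - 0.3
  - 0.3
  - 0.4
  - 0.3
  - 0.3
  - 0.3
  - 0.3
  link: latent-utility-threshold
  error_sd: 1.0
- child: V1
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: V2
  parents: []
  intercept: 0.0
  coefficients: []
  link: latent-utility-threshold
  error_sd: 1.0
- child: V3
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: W
  parents:
  - W1
  - W2
  intercept: 0.0
  coefficients:
  - 1.0
  - 1.0
  link: deterministic-sum
  error_sd: 0.0
- child: W1
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: W2
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: X1
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: X2
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: X3
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: X4
  parents:
  - D2
  - Z1
  - X1
  - X2
  intercept: 0.0
  coefficients:
  - 0.5
  - 0.3
  - 0.3
  - 0.3
  link: linear
  error_sd: 0.5
- child: X5
  parents:
  - D2
  - Z1
  - X1
  - X2
  intercept: 0.0
  coefficients:
  - 0.5
  - 0.3
  - 0.3
  - 0.3
  link: linear
  error_sd: 0.5
- child: Y1
  parents:
  - V3
  intercept: 0.0
  coefficients:
  - 0.3
  link: linear
  error_sd: 1.0
- child: Y2
  parents:
  - T1
  - V1
  - V2
  - V3
  - Y1
  intercept: 0.0
  coefficients:
  - 1.0
  - 0.3
  - 0.3
  - 0.3
  - 0.5
  link: linear
  error_sd: 1.0
- child: Z1
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: Z2
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
- child: Z3
  parents: []
  intercept: 0.0
  coefficients: []
  link: linear
  error_sd: 1.0
hierarchy:
  organizations: 40
  practitioners_per_organization: 5
  patients_per_practitioner: 30
selection_node: D1
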