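# rertkit

A feasibility and decision-support engine for **reirradiation (reRT)
treatment planning**. When a patient needs a further course of radiotherapy
in or near a previously irradiated region, the planning team must answer
three questions: *how much dose have the organs at risk (OARs) already
received*, *how much more can they safely take*, and *what target coverage
can be achieved within that budget*. `rertkit` implements this workflow as a
reusable library plus a small CLI:

- **EQD2 dose accumulation** — every prior course is converted voxel-wise to
  the equieffective dose in 2 Gy fractions under the linear-quadratic model,

  `EQD2 = D · (d + α/β) / (2 + α/β)`, `d = D/n`,

  with α/β = 2 Gy for central nervous system tissue and 3 Gy for other
  normal tissue, then rigidly mapped onto the current planning grid and
  summed. No normal-tissue recovery is assumed except an optional,
  configurable spinal-cord recovery model.
- **Cumulative OAR tolerance evaluation** — a bundled departmental tolerance
  table (organised by anatomical region, with *Objective* and *Variation*
  EQD2 limits per structure/metric, open-ended and no-constraint rows, and
  `+ 1 mm` planning-risk-volume expansion) is evaluated with standard DVH
  metrics: Dmean, D*x*cc (minimum dose to the hottest *x* cc), D*x*%, V*x*.
- **Registration trust routing** — where the rigid registration is recorded
  as untrustworthy for an OAR, 3D mapping is replaced by a conservative
  per-course summation of near-maximum metric values (worst-case assumption
  that hot spots coincide), and the provenance is recorded.
- **Hierarchical decision cascade** — standard constraints at full coverage
  (Level 1, only when a de novo table is supplied) → reRT *Objective* →
  *Variation* limits at full coverage → Variation limits with a permitted
  coverage compromise (V95% > 80 % of GTV/CTV/ITV for conventional EBRT,
  V100% > 80 % of the GTV for SBRT/SRS) → prescription change (Level 3).
- **Retreatment classification** — type 1 (geometric overlap of a prior
  high-dose region with the new target), type 2 (no overlap, but toxicity
  concern), or repeat irradiation.

Everything runs on plain NumPy arrays; DICOM RT Dose / RT Structure Set
import-export and a self-contained JSON+raw fixture format are provided, and
a synthetic phantom generator makes every test and demo run without clinical
data.

## Worked example

```python
import numpy as np
from rertkit import *

grid = Grid3D(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(30, 30, 30))

# new SBRT plan: 35 Gy / 5 fx to a GTV, esophagus nearby
new_spec = PhantomSpec(grid, target_centre_mm=(30, 30, 30), target_radius_mm=8,
                       prescription_gy=35, falloff_sigma_mm=6, n_fractions=5,
                       modality="SBRT_SRS",
                       oars=(OARSpec("Esophagus", "sphere", (44, 30, 30), (5,)),))
new_plan, masks = generate_phantom(new_spec)

# prior course: 60 Gy / 30 fx, slightly displaced
prior_dose, _ = generate_phantom(PhantomSpec(grid, (26, 30, 30), 8, 60, 6, 30))
prior = [PriorCourse(prior_dose,
                     RigidTransform.identity({"Esophagus": "TRUSTED"}))]

print(classify_rert_type(prior, masks["GTV"]).value)

policy = DecisionPolicy(rert_table=default_table())
outcome = evaluate_case(new_plan, [masks["GTV"]], [masks["Esophagus"]],
                        prior, policy, prescription=35, region="THORAX")
print(outcome.level.name, round(outcome.coverage_achieved, 1))
for m in outcome.per_metric:
    print(f"  {m.structure} {m.metric.label()}: {m.cumulative_value:.1f} Gy "
          f"(obj {m.limit_objective}, var {m.limit_variation}) -> {m.status.value}")
```

prints

```
TYPE_1
L2_OBJECTIVE 100.0
  Esophagus D0.03cc [Gy]: 92.2 Gy (obj 100.0, var 120.0) -> PASS_OBJECTIVE
  Esophagus D0.1cc [Gy]: 65.0 Gy (obj 90.0, var 110.0) -> PASS_OBJECTIVE
  Esophagus D1cc [Gy]: 9.9 Gy (obj 80.0, var 90.0) -> PASS_OBJECTIVE
  Esophagus D5cc [Gy]: 9.9 Gy (obj 70.0, var 90.0) -> PASS_OBJECTIVE
```

meaning: the prior high-dose region overlaps the new target (type 1 reRT),
and the cumulative esophagus EQD2 metrics all stay below the stricter
*Objective* limits at 100 % GTV coverage — the plan is acceptable without
any compromise (Level 2, Objective branch).

The same pipeline is scriptable from a shell:

```bash
rert phantom --spec case.yaml --out case/
rert classify --case case/
rert evaluate --case case/ --report report.json   # exit code 0 / 2 / 3
```

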