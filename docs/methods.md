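# Methods

This note documents the models, conventions and design choices behind
`rertkit`, and what the synthetic phantoms do and do not establish about
clinical data.

## Dose accumulation model

Each prior course contributes its voxel dose `D` delivered in `n` fractions,
converted to the equieffective dose in 2 Gy fractions under the
linear-quadratic model:

```
EQD2 = D · (d + α/β) / (2 + α/β),   d = D / n
```

The conversion is applied per course, voxel-wise, with that course's nominal
fraction count (no per-voxel fractionation — the conversion mirrors how
plans are prescribed and recorded). Two consequences worth naming:

- `EQD2 = D` exactly at 2 Gy per fraction, `EQD2 > D` for hypofractionated
  courses, `EQD2 < D` for hyperfractionated ones.
- EQD2 is treated as additive across courses. No elapsed-time factor is
  applied to any OAR except the spinal cord (below). This is deliberately
  conservative for normal tissue.

α/β defaults are 2 Gy for central-nervous-system structures (including the
spinal cord) and 3 Gy for all other normal tissues; per-structure overrides
are configuration. When a tolerance-table row is evaluated, that row's own
printed α/β takes precedence.

### Spinal-cord recovery

The cord is the one OAR whose cumulative tolerance depends on elapsed time.
The engine exposes a piecewise-constant recovery model: a map from elapsed
months to the fraction of the prior cord EQD2 considered recovered, required
to be non-decreasing and 0 at 0 months. The allowed *new* cord dose is

```
allowed = max(0, base_tolerance − prior_EQD2 · (1 − recovery_fraction(Δt)))
```

The published recovery formula this parameterises is intentionally not
hard-coded: its constants are configuration values, with a free-text
provenance field carried into reports, so a clinic can encode the model it
actually uses. With the model disabled the allowance is plain subtraction.

## Grid geometry and resampling

- Coordinates are millimetres in the patient LPS frame, voxel-centre
  convention, index axis order `(i, j, k) → (x, y, z)`, 0-based.
- Transforms are proper rigid (orthonormal rotation, det +1, checked to
  1e-9) and follow the resampling convention: they map *target-grid* points
  into *source* space. Registration itself is an input — a human performs
  and reviews it; the engine only consumes the resulting transform and its
  per-OAR trust flags.
- Dose is resampled trilinearly, masks nearest-neighbour (preserves dose
  smoothness and mask crispness). Mapped points outside the source extent
  receive 0 Gy and are *counted* in an out-of-extent tally carried on the
  resampled grid — conservative for coverage, never silent. Continuous
  indices within 1e-9 of an integer are snapped so that identity and
  whole-voxel-shift resampling reproduce source values bit-identically.
- PRV expansion is a Euclidean dilation on voxel centres honouring
  anisotropic spacing (`distance_transform_edt` with the grid spacing as
  sampling), thresholded at `margin + 1e-9`.

## DVH metric conventions

- `DxCC` is the minimum dose to the hottest `x` cc: voxel doses are sorted
  descending, the cumulative-volume curve is interpolated linearly between
  bracketing voxels, and volumes at or beyond the structure volume return
  the in-mask minimum. No partial-voxel geometry is modelled.
- `Dx%` is `DxCC` at `x`% of the structure volume.
- `V` metrics use a closed threshold (`≥`), conservative for coverage.
- Target coverage (V95 % / V100 % of prescription) is evaluated on the new
  course's *physical* dose — it is a prescription-relative plan-quality
  criterion — while all OAR tolerances are cumulative EQD2.

All four metric families are verified against an independent brute-force
sort-and-count oracle on randomised grids.

## Tolerance table

The bundled table is a CSV (comma-separated, UTF-8, dot decimals) with one
row per structure/metric, guarded by a SHA-256 checksum. Conventions:

- `(region, structure, metric)` is the unique key: the same organ can carry
  different limits in different anatomical blocks (e.g. brainstem in the
  brain block vs the head-and-neck block).
- `open` marks an open-ended limit and `none` an organ without defined
  constraints; both are reported and flagged for case-by-case discussion,
  never silently passed or failed.
- A blank variation cell with a numeric objective means
  `variation = objective` (conservative; used by the lung V20 row).
- A row with a metric but no limits (the thoracic spinal canal) defers its
  limits to the dynamic cord model.
- A structure name ending in `+ 1 mm` triggers automatic PRV expansion by
  that margin before evaluation.
- Two printed heart rows (`D15cc ≤ 60/80`, `D0.1cc ≤ 85/130`) are kept in
  their printed order and both evaluated; no reconciliation is attempted.

The table ships as *reirradiation* limits only. De novo (first-course)
constraint sets are accepted in the same CSV format but none are invented
or bundled.

## Feasibility and trust routing

A retreatment is classified **type 1** when any prior course's isodose
volume — voxels at or above a configurable fraction (default 0.5) of that
course's maximum dose, mapped onto the current grid — intersects the new
target; **type 2** when there is no such overlap but toxicity is a concern;
otherwise **repeat irradiation**. The isodose fraction is configurable and
reported because the precise clinical overlap definition is a consensus
matter, not a computable constant.

Prior-dose metrics are routed by recorded registration trust:

- **Trusted** → the metric is evaluated on the voxel-wise accumulated EQD2
  grid (provenance `MAPPED_3D`), and cumulative checks use
  `accumulated + new plan` EQD2 on the shared grid.
- **Untrusted** → conservative per-course summation (provenance
  `CONSERVATIVE_SUM`): each course's own near-maximum EQD2 metric value is
  computed on its native grid and summed, assuming worst-case spatial
  coincidence of hot spots. A missing trust flag is an error by design —
  trust must be recorded, not guessed.

Two refinements keep the conservative estimate genuinely one-sided under
discretisation. When a course lacks its own contour, the current structure
is mapped back through the inverse transform and expanded by one voxel
diagonal (absorbing the sub-voxel rounding of nearest-neighbour mask
mapping), and relative-volume metrics are pinned to the *current*
structure's absolute volume so a mask approximation cannot deepen the
evaluated hot volume.

The conservativity guarantee is a property of *maximum and near-maximum*
metrics (D0.03cc, D0.1cc, small D%), which is exactly the scope of the
manual clinical estimate it models. It provably does not extend to
deep-volume metrics: with disjoint per-course hot spots, minimum-dose-type
metrics are superadditive (two courses `[20, 0]` and `[0, 20]` give a
two-voxel cumulative minimum of 20 Gy against per-course values of 0). The
mean is exactly additive, so under aligned anatomy the conservative sum
coincides with the mapped value. Volume-percentage metrics cannot be
conservatively summed at all and raise instead; cumulative V-type rows are
evaluated on the mapped grid with a discussion flag when registration is
untrusted.

Residual allowances are `max(0, limit − prior)` per tolerance level, with
open-ended limits yielding unbounded residuals flagged for discussion.

## Decision cascade

The evaluation is a deterministic cascade; all per-metric statuses are
reported regardless of the level reached:

1. **L1** — only when a de novo standard table is supplied: cumulative
   metrics pass it at full coverage.
2. **L2 Objective** → **L2 Variation** at full coverage → **L2 Compromise**:
   Variation limits met by a coverage-compromised plan whose minimum target
   coverage still reaches the floor (80 %). The coverage metric is selected
   by modality: V95 % of prescription over GTV/CTV/ITV for conventional
   EBRT, V100 % over the GTV for SBRT/SRS.
3. **L3** — the prescription itself must change.

Open choices resolved here, as configuration with defaults:

- "Full coverage without compromise" is operationalised as coverage ≥ 95 %
  (configurable), distinct from the 80 % compromise floor, because the
  workflow states the principle but no number.
- The cascade starts at L2 when no standard table is supplied — the bundled
  limits are reirradiation-specific and inventing de novo limits would be a
  clinical statement this package refuses to make.
- The engine evaluates candidate plans; it never optimises them. The
  compromise branch examines a caller-supplied compromised plan (or the
  original plan at the relaxed floor). Inverse planning is out of scope.
- Limit comparisons use `value ≤ limit + 1e-9`.
- Across multiple prior courses an OAR counts as trusted only if trusted in
  every course's registration.

Cohort summaries print percentages the way registries do:
round-half-away-from-zero, integer precision for course kinds, one decimal
for site distributions.

## Synthetic phantoms — what they show and what they don't

The phantom generator produces a spherical target at the prescription with
an isotropic Gaussian falloff beyond the target surface
(`Rx · exp(−r²/2σ²)`, default σ chosen per case; 5–6 mm in the bundled
examples, a realistic penumbra scale for the 2 mm grids used), plus
analytic sphere/cylinder/slab OARs. Generation is deterministic for a fixed
spec; optional seeded Gaussian dose jitter is off by default.

Phantoms exercise the full numerical pipeline — resampling, EQD2
accumulation, DVH metrics, trust routing, the cascade — under known ground
truth. They do **not** emulate tissue heterogeneity, realistic beam
arrangements, anatomical change between courses, or deformable anatomy, so
passing tests validate the *engine's arithmetic and logic*, not the
clinical appropriateness of any individual plan. Test problem sizes
(grids of ≤ 3 × 10⁴ voxels, 50–100 randomised cases per property) were
chosen as the smallest at which every geometric effect the properties probe
(sub-voxel shifts, steep gradients, small hot volumes) is present.

## Degenerate inputs and tie-breaks

- Empty masks, empty cohorts, non-positive prescriptions, missing trust
  flags and malformed table rows raise descriptive errors rather than
  returning sentinel values.
- An accumulation over zero courses is a zero grid; a zero-dose course is
  the identity.
- Equal doses at a DVH volume boundary resolve by the linear interpolation
  of the cumulative curve (ties introduce no ambiguity because the curve is
  evaluated, not searched).
- DICOM import is restricted to axial, axis-aligned grids with uniform
  frame spacing, absolute dose in Gy, and plan-level summation; everything
  else fails loudly with the reason.

## Known limitations

- Rigid registration only, by design; transforms and their trust are inputs.
- No BED reporting, tumour-control modelling, or α/β uncertainty
  propagation.
- Mask-based (voxel) volumes throughout; no contour-interpolated sub-voxel
  DVH.
- The bundled tolerance values are a departmental consensus under
  prospective evaluation, not population-validated safety limits; the
  engine evaluates them, it does not endorse them.
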