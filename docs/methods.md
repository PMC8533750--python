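# Methods

## The measures

A whole-body PET study is represented as a 3D grid `C(i,j,k)` of quantized
tracer concentrations, `0 ≤ C ≤ 255`, with the axial (slice-stacking) axis
last.  A threshold `w` separates meaningful signal from noise; the default
`w = 1` keeps every nonzero quantized voxel, so even the faintest recorded
uptake — possibly a millimetric metastasis — contributes.  Brain uptake is
constitutively high and uninformative, so it is removed by an explicit
axial crop before analysis (`crop_axial`); no automatic anatomy detection
is attempted.  Box counting operates in index space, treating voxels as
unit cubes; the physical voxel spacing (typically 2 × 2 × 4 mm) is carried
as metadata only.

**Fractal dimension.**  For a schedule of box edges `s`, the grid is
partitioned into origin-anchored `s × s × s` boxes and `N(s)` counts the
boxes whose maximum value reaches `w`.  Ordinary least squares of
`log N(s)` on `log s` gives `Df = −slope`, with `r²` and the slope's
standard error reported.  Grid extents not divisible by `s` are
conceptually zero-padded: border boxes are partial but count in the total
`N`; padding never creates occupancy.  A single origin-anchored grid is
used (no offset averaging).  The default schedule is powers of 2 from 1 up
to half the largest extent; triadic phantoms use powers of 3; any explicit
list can be supplied.  For tracer filling the body uniformly `Df → 3`;
concentration of uptake onto a subspace (lesions seeded through the
vasculature, whose tree has dimension ≈ 2.7) lowers it.

**Generalized dimensions.**  At each scale the thresholded field is
reduced to normalized box masses `p_i` (box mass over total thresholded
mass, occupied boxes only, `Σ p_i = 1`).  The moment of integer order `q`
is

    D_q = slope of [ln Z(q,s) / (q − 1)] vs ln s,   Z(q,s) = Σ_i p_i^q,

with the entropy (L'Hôpital) branch at `q = 1`:
`D_1 = slope of [Σ_i p_i ln p_i] vs ln s`.  Restricting the sum to
occupied boxes keeps negative orders finite; partition sums are evaluated
in log space (`logsumexp`) so deep cascades and `q = −10` do not overflow.
All orders share one scale schedule, and `D_0` is by construction
bit-identical to the box-counting `Df` on the same schedule (both are the
same regression).  The normalization `p_i = mass_i / total` is the
standard measure-theoretic choice; variants exist in the literature
(e.g. normalizing by box volume), so this canonical definition is an
explicit, documented assumption of the implementation.

**Longitudinal summaries.**  `⟨MFS⟩_j` is the arithmetic mean of `D_q`
over the 21 integer orders `q = −10..10` at stage `j` (1 = baseline,
2 = interim, 3 = final).  The cumulative measure
`ΔD(j) = Σ_{q=−10..10} [D_q(j) − D_q(1)] / 21` equals
`⟨MFS⟩_j − ⟨MFS⟩_1` by linearity and is identically 0 at baseline; the
implementation exploits the identity and tests enforce it to 1e−12.

## Trend classification and concordance

A change `δ` of a measure relative to baseline is classified with a
stability band `τ`: `|δ| < τ` is *stable*, otherwise the sign decides
(*improved* for increases, *deteriorated* for decreases).  The nominal
band on unrounded measures is `τ = 0.02` (`TAU_TREND`).

Concordance with the PERCIMT reading maps response categories (PMR, CMR)
to any increase, progression (PMD) to any decrease, and stable disease
(SMD) to the stability band.  The packaged cohort tables print measures
rounded to 3 decimals, and two studies are annotated as matching although
their rounded changes sit just outside the nominal band; the defaults
`TAU_FD = 0.025` and `TAU_MFS = 0.13` are the smallest convenient bands
that reproduce every printed matching annotation on the rounded values
and are exposed as configuration.

**Colitis.**  Immune-related colitis floods the colon with tracer,
mimicking diffuse (healthy-looking) spread and inflating both measures.
Two rules are deliberately distinct: the *census* counts any study whose
irAE annotation mentions colitis in any wording (8 studies in the
packaged cohort); the *exclusion* used for the concordance statistics
drops only studies where colitis is listed as an immune-related finding
in its own right (7 follow-up studies) — an incidental "signs of colitis
in descending colon" is a non-specific finding and is retained.  This is
the only reading under which the published percentages over 31 studies
are arithmetically consistent.

**A documented inconsistency.**  The published all-studies MFS matching
figure (76.32%, i.e. 29/38) cannot be reconciled with the published
per-study matching annotations, which contain 28 "YES" over 38 follow-up
studies (73.68%).  The package reports the table-derived 73.68% and does
not force-fit the prose figure; the colitis-excluded figures (77.42% FD,
80.65% MFS) and the all-studies FD figure (71.05%) are all reproduced
exactly.

Percentages are rounded half-up to 2 decimals.

## The phantom generator

Patient volumes are not redistributable, so validation rests on synthetic
volumes whose scaling is known exactly:

* **uniform / point** — the two degenerate anchors, `D_q ≡ 3` and
  `D_q ≡ 0`.
* **menger / cantor_product** — deterministic fractal supports with
  analytic occupied-voxel counts per level (`20^L`; `(k^L)^3`), giving
  exact dimension targets such as `log 20 / log 3 ≈ 2.7268`.
* **cascade** — the dyadic multiplicative cascade: mass fractions `w_i`
  over the 8 octants applied recursively.  Its spectrum is closed-form
  (`closed_form_dq`): `D_q = log2(Σ w_i^q)/(1 − q)` for `q ≠ 1`, entropy
  form at `q = 1`.  Cascade voxel values are kept as unrounded float64
  (scaled so the maximum is 255) because 255-level quantization destroys
  the measure's deep tail; rounding is opt-in.  Since the smallest values
  then fall below 1, cascades are analyzed with a tiny positive threshold
  (`w = 1e−9`) rather than the clinical `w = 1`.
* **body** — a body-like study on a 64³ grid: an ellipsoidal torso with
  diffuse background uptake (rate 1), three fixed "organ" blobs
  (rate 12), and `k` spherical lesions of radius 3 voxels (rate 40,
  within the tumor-to-background ratios seen in FDG imaging) placed along
  a seeded branching random walk, emulating contiguous vessel-borne
  spread rather than uniform scatter.  A fixed budget of tracer quanta
  (1.1 per unit of the lesion-free rate field, independent of `k`) is
  distributed multinomially over the rate field and clipped at 255.
  Because the budget is fixed, lesions capture quanta at the expense of
  the diffuse background, thinning its occupancy — the mechanism by which
  metastatic progression lowers `Df` and `⟨MFS⟩` in patients.  With the
  defaults, `Df ≈ 2.52` with no lesions, falling to ≈ 2.43 at 30 lesions,
  inside the range observed clinically.

What the body phantom does *not* emulate: reconstruction point-spread and
correlated noise, attenuation artifacts, organ physiology (bladder
filling, myocardial variability), or realistic anatomy.  Passing tests
therefore demonstrate that the estimators respond correctly to controlled
concentration of tracer mass, not that the pipeline is validated on real
patients.

## Numerical choices and validity limits

* **Fit degeneracies.**  A constant log-count curve is a perfect fit to a
  horizontal line (`Df = 0`, `r² = 1`, stderr 0).  Fits require ≥ 3
  scales with `N(s) ≥ 1`; a zero count inside the fit range raises an
  error naming the scale.
* **Undersampling at negative q.**  For sampled (shot-noise) volumes such
  as the body phantom, boxes holding O(1) tracer quanta make `Z(q,s)`
  reflect sampling granularity rather than the underlying measure, biasing
  the fitted negative-order dimensions upward and breaking the theoretical
  monotonicity of `D_q` in `q` at the finest scales.  Such volumes should
  be fitted over their well-sampled window — on the 64³ body phantom,
  `s = 4..32`, where a typical occupied box holds ≳ 70 quanta — and the
  tests do so.  Exact-measure phantoms (uniform, cascade, Menger) are
  unaffected and use the full schedule, as do occupancy (`Df`) fits,
  which only need one occupied voxel per box.
* **Bounds on `D_q`.**  `0 ≤ D_q ≤ 3` holds for `q ≥ 0` (monotonicity
  plus `D_0 ≤ 3`).  For `q < 0` the generalized dimensions of a cascade
  approach `−log2(min w_i)` and legitimately exceed 3 whenever
  `min w_i < 1/8`; the implementation does not clamp.
* **Intensity rescaling.**  How raw activity maps to 0–255 is a free
  choice; the default rescales each study linearly (min → 0, max → 255,
  integer rounding), with a `"none"` policy for phantoms and round-trip
  tests.  A constant positive study maps to full scale.
* **Determinism.**  Phantoms are reproducible from `(spec, seed)`;
  identical CLI configurations produce byte-identical CSV/JSON outputs.

## Problem sizes

Tests and the acceptance script use 32³ uniform/point grids, the 81³
level-4 Menger sponge, 128³ level-7 cascades, 64³ body phantoms and 100
random 16³ volumes for the fast-vs-brute-force box-counting
cross-check — sizes at which the deterministic targets are exact and the
whole validation runs in seconds on one CPU.
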