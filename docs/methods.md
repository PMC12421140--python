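# Methods

This note records the models implemented in `rtplaneval`, the conventions
chosen where the underlying definitions are ambiguous, and what the
synthetic cohort does and does not emulate.

## Coordinate frame and metric conventions

All volumes live on a regular, possibly anisotropic voxel grid (axis order
left–right, anterior–posterior, superior–inferior; spacing in mm; the
origin is the centre of voxel (0,0,0)). All distances are Euclidean in
physical millimetres, never voxel index units.

**Overlap metrics.** DSC and JI are computed on full voxel sets. They are
algebraically linked, `JI = DSC / (2 − DSC)`, which the test suite asserts
to 1e−9 on every random mask pair; empty∩empty is treated as undefined
(an error), not 0/0 = 0.

**Surface distances.** A boundary voxel is a foreground voxel with at
least one face-adjacent (6-connectivity) background neighbour; the grid
border counts as background. HD is the exact symmetric Hausdorff distance
between the two boundary point sets (100th percentile, not HD95). "Mean
deviation" needs a notion of corresponding points, which is not well
defined for arbitrary surfaces; MDA is implemented as the **average
symmetric surface distance**: nearest-neighbour distances pooled over both
surfaces. This is the standard reading of a mean contour deviation and
guarantees MDA ≤ HD. Contour-polygon (sub-voxel) surfaces are out of
scope; on desk-scale grids the voxel-centre surface is oracle-checkable
exactly, which the suite exploits (brute-force all-pairs comparison on
random masks).

**DVH quantiles.** Dx is the minimum dose of the hottest x% of a
structure, computed from the exact sorted voxel doses with linear
interpolation at rank 1 + (n−1)p. No histogram binning: bin width would
be a hidden parameter, and exact sorting lets an independent oracle match
to machine precision. Dmax/Dmin are raw voxel extrema (no 0.03-cc
smoothing), matching the bare constraint limits checked. Voxels are
weighted equally; partial-volume effects are ignored.

**Conformity index.** CI = Vri/Vptv with Vri the volume *of the whole
grid* reaching the prescription dose — the "absolute volume" reading of
the definition. A PTV-restricted variant (coverage ratio, bounded by 1)
is available via `vri_within_ptv=True` but is not the default. With the
default noisy dose model roughly half the PTV voxels sit just under the
prescription threshold, so typical CI values are ~0.5–0.8; CI is used
here for its *paired difference*, which is threshold-crossing driven and
responds strongly to contour edits.

**Constraints.** Per-schedule limits (50 Gy/25 F: PTV Dmax < 52.5 Gy,
bladder Dmean < 40 Gy, femoral heads Dmean < 18 Gy; 25 Gy/5 F: 26.5 /
12 / 9 Gy; small bowel report-only) are compared with strict `<`, and
margins (limit − value) are reported. Unknown schedules yield an empty,
flagged report rather than an error.

## Statistical stage

Spearman correlation (average ranks for ties, two-sided p from the
t-approximation with n−2 df), two-tailed paired t-tests with
Shapiro–Wilk p on the differences reported as an advisory gate (the test
is computed regardless — the gate informs interpretation, it does not
switch methods), and Tukey fences at k = 1.5 on the
prescription-normalised deltas ΔDmax/Rx and ΔD95/Rx. These delegate to
`scipy.stats` / `numpy.quantile`; hand-written rank/t/quantile oracles in
the tests provide the independent cross-checks.

Conventions that matter and their defaults:

- **Quartiles**: linear interpolation between order statistics (rank
  1 + (n−1)p). Flags near a fence can depend on the convention, so it is
  a config option.
- **Flag combination**: a plan is unacceptable when flagged on *either*
  normalised delta (union) — the conservative reading; intersection is an
  option.
- **Pooling**: normalised deltas from all prescription groups are pooled
  before fence computation (normalisation puts them on one scale);
  per-group fencing is an option.
- **Sign convention**: deltas are automated − manual throughout.
- **Multiple testing**: none (α = 0.05 per test), recorded in the report
  metadata.
- Outliers are *flagged*, never removed from the summary statistics.

The acceptability rate is 100·(n − |flag union|)/n, reported to one
decimal.

## Delta evaluation convention

Dose grids in this package are deterministic functions of the case's
random substream and the targeted geometry, and the random fields (noise,
hot-spot placement) are shared between the automated and manual plan of a
case. A consequence: if each plan were scored only on its own PTV, the
paired differences would be nearly independent of the contour edit (each
plan is self-consistent by construction). The cohort table therefore
evaluates the PTV dose metrics of *both* plans on one common reference
PTV — the automated one by default (`ptv_reference="auto"`, configurable)
— so that ΔD95, ΔDmax, ΔCI etc. measure what the contour edit does to the
delivered dose on a fixed region. OAR metrics always use the plan's own
structure set (OARs are shared between sets by default anyway).

## Synthetic cohort generator

The generator stands in for a clinical cohort of 117 pelvic cases with
composition 77 × 25 Gy/5 F, 36 × 50 Gy/25 F and 4 other (assigned
deterministically and interleaved, so the composition is exact at any
seed; other cohort sizes scale the composition by largest remainder).
Everything is a pure function of the `CohortConfig`, including its master
seed; per-case substreams are derived as (seed, case index, stage), so
cohorts are bit-reproducible and stable under `n_cases` truncation.

**Anatomy** (per case, jittered in size and placement): the PTV is an
SI-elongated superellipsoid (near-cylindrical, semi-axes ≈ 37×34×62 mm,
volumes ≈ 320–550 cm³ on the default 64×64×96 grid at 2.5 mm isotropic);
the rectum is an SI cylinder embedded in the posterior PTV (nonzero
PTV∩rectum by construction); bladder anterior–superior sphere; femoral
heads lateral spheres kept disjoint from the PTV; small bowel a superior
tube. The default grid is desk-scale yet deep enough (96 slices) for the
truncation scenario.

**Contour edits.** The manual PTV is the sub-level set `sdf < f` of the
automated mask's half-voxel-corrected signed distance, where f is a
Gaussian random field with correlation length 10 mm, standard deviation
1.5 mm (`amplitude_mm`) and mean −0.5 mm (`bias_mm`; negative = net
contraction, encoding that clinicians contract far more often than they
expand), plus an extra contraction of up to 1 mm decaying away from the
rectum (clinicians trim hardest at the PTV–rectum interface). Zero
amplitudes reproduce the input bit-exactly. Scenarios: `typical` (80%),
`si_truncated` (12%; whole axial slices removed from one SI end, extent
log-normal with median 6 mm and log-sd 0.7 — heavy-tailed, because large
truncations are the rare, consequential edits), `asymmetric` (8%;
one-sided lateral contraction ramping to 4 mm). The 20% scenario fraction
approximates the flagged fraction reported for clinical cohorts of this
kind; it is a tunable, not a claim.

These defaults were calibrated once, against the generator's own
contracts — cohort mean PTV DSC > 0.9 and mean JI > 0.8 (they come out
≈ 0.96 / 0.93), DSC monotonically decreasing in amplitude, and forced
truncation lowering the acceptability rate — and are not adjusted per
analysis.

**Dose model.** Prescription dose inside the planned PTV, exponential
falloff `exp(−d/8 mm)` outside, a seeded Gaussian hot spot of +2% placed
at an offset from the PTV centroid, smooth Gaussian noise (sd 0.2 Gy,
5 mm correlation), clipped to 1.10×Rx (in practice Dmax stays below the
1.05×Rx constraint). Within the planned PTV ≥ 95% of voxels receive
≥ 95% of prescription. Because the hot-spot position and falloff depend
on the targeted PTV, truncating or contracting the contour moves dose off
the reference region — the mechanism by which geometric discrepancy
becomes dosimetric discrepancy, and, through the Tukey fences, a lower
acceptability rate when truncation is forced on every case.

**What the generator does not emulate** — hence what passing tests do and
do not show about real data: real pelvic anatomy (parametric shapes
only), CT appearance, optimizer behaviour (doses are geometry-driven
idealisations; in particular, real automated planners can spare OARs
*better* than manual plans for planner-behaviour reasons this geometric
model cannot produce — with a contraction-biased manual target, the
synthetic automated plan irradiates OARs slightly *more*), inter-observer
variability beyond one edit model, and any correlation between anatomy
and prescription. Quantities that depend on a real cohort (reported
correlation coefficients, OAR dose means, the exact acceptability
percentage) are deliberately not asserted anywhere; the suite checks
calibration bounds, identities, oracle equalities and qualitative
directions instead.

## Numerical choices and degenerate inputs

- Metrics error on empty masks (undefined) rather than return sentinels;
  the pipeline surfaces such cases with the case id and ROI.
- The perturbation guards against degenerate over-contraction (an edit
  that would empty the PTV keeps the original mask; slice truncation
  never removes the last occupied slice).
- CSV output uses 6 significant digits; determinism tests compare bytes,
  numeric tests use stated tolerances.
- Cohort sizes in the test suite: the full n = 117 default cohort is
  generated once per session for the calibration and invariant checks;
  the 20-seed calibration robustness check runs n = 12 per seed; pipeline
  round-trip tests use 4–6 cases. These sizes are the package's choice of
  desk-scale problem sizes; all contracts they check are size-free.

## Known limitations

- Voxel-centre surfaces bias HD/MDA by up to about half a voxel relative
  to polygon contours; at 2.5 mm spacing this is visible in the MDA of
  near-identical masks.
- The Tukey-fence acceptability rate is a *relative* criterion: it flags
  plans unusual within their cohort, not plans violating absolute limits
  (absolute limits are reported separately via the constraint checks).
- `run_study` requires at least 4 cases (fences) and non-constant columns
  for correlations; degenerate columns are reported as null entries
  rather than failing the whole report.
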