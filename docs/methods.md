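# Methods

`synmorph` analyzes annotation files from flash-and-freeze serial-section
electron microscopy of *C. elegans* neuromuscular junctions: worms
expressing channelrhodopsin receive a single light stimulus and are
high-pressure-frozen at a defined interval, and each 33-nm section through
a synaptic varicosity is annotated with the plasma-membrane trace, the
dense-projection outline, adherens-junction marks, and every vesicle and
membrane pit.  The package classifies those structures, computes the
morphometry, balances the membrane budget, and fits the recycling
kinetics.  Because no public archive of such annotations exists, a
first-class synthetic generator reproduces the statistical structure of
the experiment so that every analysis is testable end to end.

## Data model and units

Lengths are nm, areas nm², times ms, everywhere; records carry no unit
fields.  Coordinates are 2-D within a section; the out-of-plane coordinate
is implicit as `section_index × section_thickness` (33 nm default, stored
per reconstruction and never re-derived).  A "synapse" is the contiguous
run of sections sharing one dense projection, typically 4–6 profiles; it
is the counting unit for endocytic structures, while docked/tethered
vesicle statistics are per profile.  Canonical storage is JSON (one
condition dataset per file); a flat CSV dialect (one row per
profile/vesicle/pit, metadata repeated) supports spreadsheets.  Points
claimed to lie on the membrane (adherens-junction marks, pit mouths) must
fall within a placement tolerance of 5 nm, absorbing annotation jitter.

### CSV dialect, column by column

One row per record; `record_type` ∈ {`profile`, `vesicle`, `pit`}
(`dataset` for an empty dataset's metadata row) selects which columns are
meaningful.  Dataset metadata (`condition_label`, `stimulated`,
`interval_to_freeze_ms`) repeats on every row.

| column | rows | meaning |
| --- | --- | --- |
| `record_type` | all | record kind |
| `condition_label`, `stimulated`, `interval_to_freeze_ms` | all | dataset metadata |
| `synapse_id`, `section_index` | all | reconstruction / section key |
| `section_thickness_nm` | profile | out-of-plane section spacing |
| `profile_area_nm2` | profile | annotated varicosity cross-section |
| `membrane`, `dense_projection`, `adherens_junctions` | profile | point lists, `"x y;x y;…"` (nm) |
| `id` | vesicle, pit | structure label |
| `x_nm`, `y_nm`, `diameter_nm`, `core`, `tether_observed` | vesicle | center, size, appearance, tether call |
| `apex_x_nm`, `apex_y_nm` | pit | deepest point |
| `mouth_left_*`, `mouth_right_*` | pit | where the mouth meets the membrane |
| `width_nm`, `depth_nm` | pit | mouth span and invagination depth |

Floats are written in shortest-round-trip form and read back exactly, so
CSV and JSON forms of a dataset compare equal after parsing.

## Classification rules

* **Kind** — dense-core by appearance; clear-core vesicles strictly larger
  than 35 nm are *large vesicles* (the endocytic product tracked over
  time); the rest are synaptic vesicles.  The 35.0 nm tie goes to
  synaptic vesicle.
* **Pool** — docked when the vesicle's outer edge is within 2 nm of the
  membrane trace (contact with tolerance for annotation jitter, rather
  than exact touching); tethered when within 30 nm with the annotator's
  tether flag; "30-nm pool" when within 30 nm without it; cytoplasmic
  beyond.  The tether is a visual feature of the micrograph, so it is
  taken from the annotation, never inferred from geometry.
* **Zone** — the active zone runs along the membrane from the dense
  projection to the flanking adherens junctions; a vesicle's zone is
  decided by its membrane foot-point's arc position, boundaries assigned
  inward.  If a side has no junction mark the membrane end bounds the
  zone and the label is flagged.
* **Site** — endocytic structures within 100 nm (3-D) of the nearest
  dense-projection edge belong to the dense projection; otherwise within
  50 nm of an adherens-junction mark, to that junction; otherwise
  interior.  A structure inside both radii is counted once, at the dense
  projection (the primary site), and flagged for audit.
* **Pits** — a pit with a synaptic-vesicle-sized mouth (≤ 35 nm) away from
  adherens junctions is a collapsing fusion intermediate (exocytic);
  other pits are endocytic, shallow below the hemisphere point
  (`depth < width/2`) and deep from it on.  The shallow/deep cut is a
  package choice; the hemisphere is the natural geometric boundary.

## Morphometry

Distances to the dense projection follow the Pythagorean construction:
the in-plane distance from the structure to the nearest edge of the
nearest dense-projection-bearing section's outline (projected into the
structure's plane; zero inside the outline), combined with
`sections × 33 nm` out of plane.  Distance histograms use 33-nm bins with
a reserved bin 0 for structures in contact with the dense projection;
other bins are half-open, lower-inclusive.

Counts are normalized to reference geometry so varicosity size does not
masquerade as a pool change: active-zone counts scale by
`670 nm / observed active-zone length` (arc length from the
dense-projection edge to the flanking junction, summed over both sides),
whole-profile counts by `60,700 nm² / observed profile area`.  Summary
statistics are mean ± SEM, per profile for docked/tethered/total pools
and per synapse for endocytic structures; the SEM of a single observation
is reported as 0.

Group comparisons use the two-sided Mann-Whitney U test (counts are small
and skewed): exact when both samples have ≤ 8 observations (full
permutation null when ties are present), otherwise the normal
approximation with tie and continuity correction.  Multiple comparisons
use a Bonferroni-adjusted threshold (0.05/7 ≈ 0.007 for the seven
stimulation timepoints).

## Membrane budget

At 300 ms and 1 s — the timepoints where both endocytic sites can be
quantified — the budget compares membrane added by fusion against
membrane recovered:

* exocytosis: `synapses × released per synapse × 2700 nm²` (the 29.3 nm
  vesicle's surface area), reported as a low–high range with the mean
  taken at the integer midpoint of the vesicle range;
* dense-projection recovery: observed large vesicles are corrected for
  the fraction that already drifted away
  (`total = round(observed / (1 − departure))`; 47% at 300 ms, 50% at
  1 s), then split 70% (truncated) at 37 nm / 4300 nm² and the rest at
  46 nm / 6600 nm²;
* adherens-junction recovery: each pit or large vesicle resolves into a
  43.2 nm vesicle, at the rounded 6000 nm² per structure or by exact
  4πr² (5863 nm²) with two-significant-figure rounding — both paths are
  provided because the printed constants mix the two conventions;
* the total, expressed in synaptic-vesicle equivalents by truncation
  (304,200 / 2700 → 112).

Defaults use the rounded per-structure constants so the worked numbers
reproduce digit for digit.  Note the stated 6000 nm² is not 4π(43.2/2)²
(= 5863 nm²); and the 1 s junction area only reproduces 140,000 nm² via
the exact-formula path (24 × 5863 ≈ 140,700 → 140,000), not via
24 × 6000 = 144,000.  Both are kept, selectable per call.

## Kinetics

Three model classes, all least squares (weighted 1/SEM² when SEMs are
given), initialized from a log-linear regression on endpoint-normalized
data:

* docked-pool refill: `y(t) = y∞ − (y∞ − y₀)·exp(−t/τ)` (τ ≈ 2.4 s);
* pit resolution: exponential decay with the peak time fixed at the first
  sample (τ ≈ 1.4 s);
* paired-pulse recovery: `1 − A_f·e^(−t/τ_f) − A_s·e^(−t/τ_s)` with
  non-negative amplitudes, five seeded multi-starts, components ordered
  fast < slow (τ ≈ 0.1 s and 2.2 s).

The functional forms are the conventional saturating/bi-exponential
recovery models; only the time constants are anchored to the study.
Degenerate inputs (constant series, rising "decays") come back as flagged
results rather than exceptions.  Bootstrap confidence intervals resample
residuals inflated by √(n/(n−p)) — with as few as seven timepoints the
raw fitted residuals understate the noise and uncorrected intervals
undercover.

## Diameter mixtures

Large-vesicle diameters near the dense projection are binned at 2 nm and
fitted with sums of 1–3 Gaussians by least squares on the counts (the
histogram route is what makes an R² on counts meaningful).  Each fit
reports R², RSS, and `AIC = n·ln(RSS/n) + 2·3k` over the n bins.  Model
ranking, however, defaults to the small-sample-corrected AICc: with only
~10–15 bins the uncorrected AIC essentially always selects the
nine-parameter trimodal fit because interpolating bin noise is cheaper
than the 2Δp penalty.  The reference comparison of unimodal/bimodal/
trimodal fits (352.6 / 346.4 / 353.9) itself cannot arise from the
uncorrected formula — the trimodal value exceeds the bimodal by more
than 2Δp = 6, impossible for nested optimal fits — which is why the
corrected criterion is the default.  Ties favor the smaller k.

A caveat the tests make explicit: at the generator's component width
(sd 3 nm) the 8 nm separation between the 38 and 46 nm peaks is marginal
bimodality (Ashman D ≈ 1.9).  With 200 diameters no selector — including
maximum-likelihood AIC on the raw values — identifies two components in
more than ~90% of samples; detection becomes reliable as the sample
grows (tested at n = 600).  The peak separation corresponds to a surface
area step of 2111 nm², about 0.78 of one synaptic vesicle's 2697 nm² —
close to, though not exactly, "one vesicle of membrane".

## Synthetic generator

The generator's defaults are the study's conditions, not tuning knobs:

* docked vesicles per profile follow
  `2.5 − (2.5 − 0.9)·exp(−t / 2.4 s)`; tethered run 3.1 → 2.6 on the
  same time scale; counts are Poisson.  The 30-nm pool (1.5), perisynaptic
  docked vesicles (0.5), cytoplasmic vesicles (20) and dense-core
  vesicles (0.5 per profile) have no printed anchors and are fixed at
  values typical of the micrographs.
* endocytic-structure means per synapse are piecewise-linear in time,
  anchored to the printed counts: dense-projection large vesicles peak at
  50 ms and pass through 14/22 at 300 ms and 25/23 at 1 s; junction
  shallow pits rise to 29/22 at 300 ms and decay with τ = 1.4 s toward a
  0.05 baseline; junction large vesicles peak at 3 s.  These curves are
  approximations — the underlying per-timepoint source data are not
  printed.
* geometry: a gently waving membrane polyline (amplitude 4 nm), an
  80 × 40 nm dense projection at the origin, adherens junctions at
  250–350 nm on the near side and, with probability 0.4, 350–1000 nm on
  the far side — a mix chosen so the expected active-zone length is
  exactly the 670 nm reference.  Zone-count intensities scale with each
  profile's actual active-zone length (area counts with its area), so
  raw *and* normalized per-profile means equal the configured values in
  expectation.
* placements are classifier-consistent by construction (docked edges
  ≤ 2 nm, tethered/30-nm ≤ 30 nm, site structures inside their radii),
  and each structure's id records its generating label, so label-recovery
  is testable exactly.
* diameters: synaptic vesicles 29.3 ± 2 nm (floor 15 nm); large vesicles
  a 38/46 nm mixture (sd 3, weights 0.7/0.3) truncated above 35 nm.
* paired-pulse ratios: `1 − 0.3·e^(−t/0.1 s) − 0.5·e^(−t/2.2 s)` plus
  Gaussian noise (σ = 0.05); the amplitude split is not printed and the
  chosen values leave the observed ~0.3 ratio at 50 ms.
* freeze timing: the freezer's start signal leads freezing by
  `170 + 8 ms`, so a commanded interval t means triggering at `t − 178`
  relative to the light (822 ms after it for 1 s; 78 ms *before* it for
  100 ms); the actual delay is uniform in 170 ± 20 ms and the realized
  interval is reconstructed post hoc, flagged when negative.

What the generator does not emulate: realistic axon cross-section shapes,
spatial clustering of vesicles, annotation errors other than placement
jitter, per-animal nesting, or correlations between neighboring sections
beyond the shared synapse geometry.  Passing tests therefore demonstrate
that the analysis recovers known truth under the study's sampling and
noise model — not that it is robust to every property of real
micrographs.

## Problem sizes and reproducibility

The replicated experiments use the study's sample sizes: per-timepoint
profile counts 50–121 (docked recovery), per-timepoint synapse counts
19–26 (pit resolution), paired-pulse intervals from 50 ms to 15 s.
Reported time constants are medians over 200 seeded replicates.  All
randomness flows through explicit seeds (`numpy.random.default_rng`);
identical seeds reproduce byte-identical datasets, series, and reports.

## Known limitations

* The pit-resolution fit uses four timepoints (300 ms–10 s) for three
  parameters; individual replicate fits are noisy and the median τ runs
  ~10% low at study-scale counts.
* Mixture-component recovery from 200-diameter histograms carries ~1 nm
  uncertainty in the peak positions.
* The Mann-Whitney exact path is limited to ≤ 8 + 8 observations;
  beyond that the corrected normal approximation is used.
* The CSV dialect stores geometry as coordinate strings; it is meant for
  spreadsheet inspection, not as an interchange schema.
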