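# Methods

This note records the models and procedures `supraconnect` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
reproducing results.

## Coordinate and counting conventions

Points live in atlas space, in micrometres, with the origin at the corner
of the annotation array. A coordinate `c` on an axis with voxel size `s`
belongs to voxel `floor(c / s)`; voxel ownership is half-open, so a point
exactly on a voxel boundary belongs to the higher-indexed voxel. Label 0
is reserved for outside-brain tissue: points landing there are flagged
unassigned, and points outside the array are flagged out of bounds —
neither is dropped, and both are reported alongside region counts so that
`sum(region counts) + flagged == points seen` for every animal and
channel. Hemispheres split at a declared midline voxel plane; a point
exactly on the midline is assigned to the left hemisphere (an arbitrary
but fixed tie-break, chosen so the rule is testable).

Counts collapse through two explicit maps: leaf region → reporting region
→ summary category. Collapse is configuration, not code: the maps are
derivable from a toy hierarchy automatically, while for a real Allen-style
structure graph the grouping is curated (an editable template with the
groupings that have published precedent, such as merging the spinal,
medial, and lateral vestibular nuclei into one vestibular category, ships
in `src/supraconnect/data/allen_summary_template.json`). The loader
asserts totality of the collapse — every leaf that can carry counts must
reach a summary category — rather than any fixed region count, because
structure-graph revisions differ in how many leaves they contain.
Collapsing is a homomorphism on counts (collapse-then-sum equals
sum-then-collapse); the test suite verifies this against brute-force
recounts.

A region exclusion list is supported throughout the injury analyses and
defaults to empty; populations with unreliable detection (in practice the
deep cerebellar nuclei, which image poorly from a ventral camera) are the
intended use.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the statistical
structure the estimators are validated against.

* **Counts.** Per-region nucleus counts per animal are negative binomial
  with mean `m_r` and a shared size (overdispersion) parameter `k`
  (default 8); `k = inf` recovers Poisson. Published data report only
  means, SEMs, and ranges; a negative binomial was chosen because
  brain-wide totals in real cohorts span roughly two-fold ranges
  (e.g. ~20,000–40,000 around a mean of ~31,000), far wider than Poisson
  at those counts. With `k = 8` a region with mean 300 has an
  inter-animal CV of ~0.37, reproducing that spread.
* **Placement.** Nuclei are placed uniformly within their region's
  voxels (pick a voxel uniformly, then uniform inside it). No
  within-region density structure is modeled.
* **Dual projection.** Each lumbar-labeled nucleus is independently
  dual-projecting with a region-specific probability; dual nuclei appear
  in both channels at the same location up to isotropic Gaussian jitter
  (sd 0.5 µm, far below the 4 µm match distance, so matching is testable
  with and without the noise).
* **Intensities.** Lognormal per channel (default location 6, scale 0.5
  on the log scale). In dual nuclei the two channels' log-intensities are
  drawn jointly with correlation ρ (default 0.6, the positive coupling
  expected when two co-delivered vectors express in one cell), and the
  cervical intensity is multiplied by a dimming factor in (0, 1]
  (default 0.5): dual cells carry dimmer cervical label, the feature that
  makes detection-threshold dropout informative. Dimming acts on the
  cervical channel only.
* **Injury.** Each severity arm thins every region's counts binomially by
  a per-region sparing fraction. The demo design's arms average roughly
  57% (mild), 24% (moderate), and ~0% (severe) sparing brain-wide, with
  a corticospinal-like region hit hardest — the severity ordering and
  spread typical of graded crush injuries.
* **Behavior.** The locomotor score is `9 × (weighted realized sparing of
  the linked regions) + N(0, sd)`, clipped to the 0–9 BMS range, with
  optional quantization to the scale's 0.5 steps (off by default; the
  continuous score keeps rank statistics well-defined at small n).

The generator does **not** emulate: optical-clearing artifacts,
registration error fields, autofluorescence, detector nonlinearity,
classifier false positives/negatives, within-region spatial structure, or
longitudinal behavior trajectories (only final scores). Tests passing on
synthetic cohorts therefore validate the estimators' correctness under
the stated statistical model, not robustness to registration or detection
failure modes in real data.

Determinism: a design carries its seed, and an identical design yields a
byte-identical serialized cohort.

## Spot detection and matching

The spot detector is a classical stand-in for commercial spot functions
(whose algorithms are unpublished): difference-of-Gaussian band-pass with
inner sigma = diameter/4 per axis (4 µm XY, 8 µm Z defaults) and outer
sigma 1.6× inner, local maxima with a one-diameter ellipsoidal minimum
separation, and a threshold on the filtered response at the peak.
Reported coordinates are voxel centers; reported intensity is the raw
image at the peak voxel. It is documented as not byte-equivalent to any
commercial implementation.

Dual-label matching is greedy one-to-one: all candidate pairs within the
match distance (default 4 µm) are sorted by distance (ties broken by
lowest index pair) and accepted in order, each nucleus used at most once.
The greedy rule is deterministic and, at realistic nuclear densities,
agrees with the optimal (Hungarian) matching — the test suite checks
exact agreement of pair counts against a maximum-bipartite-matching
oracle on random instances, and the oracle is kept in tests only. Plain
Euclidean distance is the default (matching the published 4 µm rule,
whose Z handling is unstated); an anisotropic option divides z
separations by the axial/lateral diameter ratio (default 2) before
thresholding.

The dropout analysis ranks cervical nuclei by intensity (ties by index),
keeps the brightest `floor(q·n)`, and recomputes the match. Relative
change is reported in percent against q = 1.

Intensity contrasts use Welch t-tests on log intensities (the intensity
distribution is unstated in published work; lognormal-like positive data
make the log scale the natural choice, and Welch avoids assuming equal
variances between dual and single cells).

## Indices

Both headline indices are computed per animal first and then averaged
across animals with SEM — matching how cohort results are conventionally
reported (mean ± SEM over N animals). Pooled alternatives are available
where noted.

* Lumbar-projection index: `lumbar / (lumbar + cervical)` per animal and
  region; animal-region cells with zero total are undefined and excluded
  from the region average. The brain-wide index defaults to per-animal
  brain-wide totals (`brainwide_mode="totals"`); averaging each animal's
  defined region indices is available as `"region_mean"`. Totals mode is
  the default because a brain-wide figure should weight regions by their
  cell numbers rather than giving a 50-cell region the weight of a
  5,000-cell one.
* Sparing index: `100 × count / mean uninjured count` per region, and
  `100 × total / mean uninjured total` brain-wide. The reference cohort
  must have ≥ 2 animals; regions with zero reference mean are excluded
  with a flag (a ratio to zero is undefined, and such regions carry no
  information about sparing).
* Brain-wide summary: per-animal totals with mean/SEM/range, and the
  number of detected regions — by default a region counts as detected
  with ≥ 1 nucleus in ≥ 1 animal (both thresholds configurable).

## GFAP bridge fraction

Lesion sections are binarized at a configurable threshold. Within the
lesion band, 8-connected components of GFAP-positive pixels that touch
both the first and last band rows count as astrocytic bridges; the
fraction is bridge-covered cord columns over total cord columns × 100.
Cord columns are those with positive signal outside the band (the intact
cord). The column-path connectivity rule is this package's
operationalization — published work states only that bridge width was
measured — and is exact to ±1 column on synthetic sections. The result
is invariant to intensity rescaling on either side of the threshold.

## Group statistics

* **BMS split:** high performers at score ≥ 5 (consistent plantar
  stepping), impaired at ≤ 3.5 (no or infrequent stepping); scores in the
  open gap are excluded. Thresholds are configurable.
* **Region screen:** per-region Welch two-sample t-tests on spared
  counts. Welch is used even where a paired test might be quoted, because
  impaired/high groups are generally unequal in size and carry no pairing
  structure. Bonferroni control is applied as a threshold adjustment
  (significant ⇔ p < α/m) rather than p-value inflation, with m counting
  only regions actually tested (≥ 2 animals per group and not excluded).
  The gap statistic min(high) − max(impaired) is reported per region:
  positive gaps are the non-overlap signature of a recovery-relevant
  region. Under a simulated global null the family-wise error is at the
  nominal α within Monte-Carlo error (Bonferroni is slightly
  conservative).
  A power caveat: at n = 6 vs 6 and m = 26, a 3-sd group effect yields
  per-region Welch power of only ~0.73 at the adjusted threshold (exact
  noncentral-t computation; ~0.80 for a pooled t) — screens of this size
  reliably detect only effects approaching 3.5–4 sd, which is worth
  remembering when interpreting non-significant regions.
* **ANOVA:** one-way by direct sums of squares; two-way
  (region × condition with interaction) through an OLS fit. Pairwise
  post-hoc comparisons use the pooled residual mean square with Šidák
  adjustment `p_adj = 1 − (1 − p)^k`; in the two-group one-way case the
  ANOVA F equals the squared pairwise t exactly. Zero residual variance
  flags the result degenerate instead of failing.
* **Sparing–behavior association:** per-region Spearman rank correlation
  against final scores (rank-based because BMS is ordinal and nonlinear),
  with constant vectors flagged undefined and scatter data exported for
  plotting.

## Problem sizes and determinism

All simulations in the tests and the acceptance script are sized for a
single CPU: toy atlases of 4–8 regions at 25 µm voxels, cohorts of 3–30
animals per arm with per-region means of 40–300 nuclei, 50 random
200+200-point matching instances, 200 power replicates and 400–1,000
null replicates for screening calibration. These sizes keep every
Monte-Carlo check's sampling error well inside its assertion band while
completing in seconds. Every source of randomness flows from an explicit
seed; the acceptance script derives all of its sub-seeds from `--seed`.

## Known limitations

* The pipeline consumes registered point clouds; image-to-atlas
  registration is out of scope, and registration error directly becomes
  assignment error near region boundaries.
* Volumetric change after injury is not modeled; counts, not region
  sizes, are the measurand.
* The spot detector is a classical stand-in and will not reproduce
  commercial detectors spot-for-spot.
* The greedy matcher can in principle differ from the optimal matching at
  extreme densities (mean spacing approaching the match distance); the
  Hungarian oracle in the tests bounds this in practice.
* Synthetic validation covers the statistical model only (see the
  generator section) — conclusions about real-data robustness require
  real data.
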