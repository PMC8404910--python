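# Methods

This note documents the models, conventions, parameter choices and known
limitations of `tminav`, in the order the data flows through the package.

## Pose geometry and conventions

Quaternions are `(w, x, y, z)` and encode the world-from-tool rotation,
`v_world = R v_tool + p`; translations are millimetres, timestamps seconds,
and every public interface reports angles in degrees. These conventions are
fixed once here because tracked-tool ecosystems disagree on all three and
silent mismatches are the classic failure mode of navigation code.

The polar decomposition of a tool axis about a planned direction `d` needs a
zero azimuth. The display is mounted on the tool and rotates with it, and
there is no single canonical way to relate screen "up" to the world; we make
the mapping deterministic instead of physical. By default φ is measured from
the projection of a configurable world reference direction (world +x) onto
the plane ⊥ `d`, counter-clockwise when viewed against `d`; passing a tool
frame vector as the reference yields a tool-roll-compensated azimuth. Both
modes are exact and testable; neither is claimed to be what any particular
physical mounting shows. θ = 0 fixes φ = 0 so the decomposition is total.
θ is computed with the `atan2(|u×v|, u·v)` form, which is stable near 0°
and 180° where a clipped arccos loses precision.

The display projection is equidistant azimuthal — radius proportional to θ,
clamped at `theta_max` (default 45°, configurable). Of the candidate
hemisphere-to-disc projections this is the one with constant angular
sensitivity everywhere on the face, which is the property a guidance display
needs. An optional exponent `sensitivity_gamma < 1` (used by the updated
Circle preset) magnifies motion near the centre, reflecting user feedback
that asked for higher sensitivity close to the target.

## Displays

All display states are pure functions of `(offset or depth, config)`.
Defaults: tolerance 1.0° (the "perfectly aligned" threshold is not
quantified anywhere authoritative; 1° is at the precision limit a surgeon
can hold freehand and is configurable everywhere, shared between displays
and the success detector), 12 sectors, 4 rings, in-target test inclusive
(θ ≤ tol). The grid flags the patch *containing* the current offset — the
single-moving-object reading — rather than the patch in the direction of
required motion; the alternative is a one-line change at the call site
(negate the offset) but is not a supported mode. Ring bins are equal-width
in θ between tolerance and `theta_max`, with everything beyond `theta_max`
clamped into the outermost ring, so the partition is total.

The depth view lights `floor(n_rings · depth/target)` of 4 rings (ring count
not specified by the design; 4 matches the angular display's ring count and
is configurable) and declares the target reached within `depth_tol` =
0.5 mm, roughly the tracking system's precision. The overshoot warning —
suggested by study participants — exists but is off by default.

The emulated external view resamples a voxel volume with trilinear
interpolation (`scipy.ndimage.map_coordinates`) on three planes through the
tooltip. Both plane families are provided — anatomical (axial / coronal /
sagittal) and tool-axis-normal — because descriptions of conventional
navigation views differ on this point; the default is anatomical.

## Trial engine

The success detector holds state machine semantics: a hold starts at the
first in-tolerance sample, any out-of-tolerance sample before the hold
duration elapses resets it, and success fires at the first *timestamp*
`t ≥ hold_start + 2 s` — timestamps, not sample counts, so dropped frames
cannot shorten the hold. The strict interpretation (no sub-frame dropout
forgiveness) is implemented. Task time runs from the first stream sample
(when the visualization appears) to the success event and therefore includes
the 2-s hold; subtract `hold_duration` for the exclusive reading.

The Euclidean path accumulates over the tracked tool origin (the handle) by
default. During angle alignment the tip is pinned at the entry point, so the
handle is the point whose travel actually discriminates direct from indirect
steering; the tip is selectable for the insertion phase.

Protocols use block randomization: each participant receives an independent
seeded permutation of the condition set. For the spine experiment each
condition block draws two random trajectories per side of the spine and
splits its (even) repetition count over them — 8 trials per condition by
default, i.e. four alignments per side; for the single-entry experiment,
trajectories are drawn with replacement, 5 repetitions per condition.

## Metrics and statistics

Outlier exclusion is a single pass per (group × metric): values outside the
closed interval mean ± 2·std are dropped, with the sample std (n−1). The
filter is deliberately not iterated — re-filtering after exclusion would
remove further points and the procedure being reproduced is single-pass.
Sample std is used everywhere.

ANOVA, Kruskal–Wallis and D'Agostino's K² delegate to `scipy.stats`; the
contracts are the textbook formulas and the tests verify them against
independent oracles (the F = t² identity for two groups, a by-hand rank
computation, and null-calibration simulations) rather than against a second
call of the same routine. Degenerate inputs are made total: identical group
means report F = 0, p = 1; an all-constant pooled sample reports H = 0,
p = 1. The K² screen requires n ≥ 20, below which its chi-square
approximation is unreliable. Pairwise condition comparisons are reported
uncorrected, matching the original analysis style; Holm adjustment is
available behind a flag. The chi-square distribution-shape observation the
original analysis reports for ordinal questionnaire data is not a named
goodness-of-fit procedure we could reconstruct; it gates nothing here and is
not reproduced.

SUS uses the standard scoring (odd items value−1, even items 5−value, ×2.5).
TLX is the *raw* variant — unweighted mean of the six subscales — which is
the single biggest scoring assumption in the package; the pairwise-weighted
original is not implemented. A converter from the 21-tick 0–20 sheet is
provided.

## Synthetic operator and study generator

The operator model is exponential decay plus optional jitter:
θ(t) = θ₀·exp(−g·(t − latency)) with a φ random walk, tip pinned at the
entry. It is the simplest model with a closed-form success time
(`latency + ln(θ₀/tol)/g + hold`), which makes the trial engine verifiable
to one sample period; it does not model human motor control (no Fitts-type
speed–accuracy tradeoff, no corrective submovements). Defaults: gain
0.6 s⁻¹ (chosen so a typical 15° initial offset yields a ~6.8 s trial, the
scale of observed task times), latency 0.3 s (a human reaction time),
jitter 0 (the ideal-operator closed form; nonzero jitter is supported),
sample rate 50 Hz (the tracking workstation's frame rate; the 40 Hz
tool-display rate is only a rendering constant and does not affect timing).

Study datasets are drawn at the level the study reports: per-trial task
times and path distances from zero-truncated normal distributions with the
per-condition mean/std (a lognormal option with matched moments is provided
for the right-skewed distances), questionnaire responses constructed so the
scored means match their targets in expectation (SUS item vectors realizing
the drawn target score; TLX subscales with the mental-demand moment explicit
and the remaining five solving for the overall-load target; Likert values
from a discretized clipped normal). The truncated normals are
moment-matched: the underlying loc/scale are solved numerically so the
*truncated* distribution has the configured mean and std — naive use of the
printed values as loc/scale would inflate the widest condition's mean by
about 9%. Experience levels for simulated surgeons are sampled with weights
0.45/0.2/0.2/0.15 over the four usage-count categories, a skew toward
juniors similar to the study population.

What passing tests on these data do and do not show: they validate the
pipeline's arithmetic, determinism and statistical calibration, and that the
generator reproduces the configured moments; they say nothing about human
performance, and the between-condition differences in generated data are
significant *by construction* of the moments, not as an empirical finding.

The spine fixture (Th11–L5, 14 trajectories) uses plausible fixed geometry —
30 mm level spacing, entries ±15 mm lateral, 15° medial and 5° caudal tilt,
depths 40–50 mm — not a patient CT; the synthetic volume places bright boxes
at the entries so the slice views have content. Neither models anatomy, nor
(like the rigid phantom it stands in for) spine mobility.

## Randomness and reproducibility

All randomness flows from one run seed through named substreams
(`protocol`, `operator`, `dataset`, …) via `SeedSequence`, so modules can be
re-seeded independently and identical configurations reproduce outputs byte
for byte. CLI runs write a `manifest.json` with the effective configuration
and seed.

## Problem sizes

The test suite verifies the heavy invariants at these sizes: 10⁵ random
offsets for the grid-binning oracle, 1 000 random streams for the detector
oracle, 200 poses for pivot calibration, 10 000 null replicates for the
type-I-error calibration of both tests, and 20 seeded replicates × 144
trials/condition for the headline task-time comparison. The acceptance
script uses the same sizes.

## Known limitations

- No hardware drivers, no transport to a physical display, no real CT/DICOM
  ingestion, and no registration of physical phantoms.
- The operator model is a convergence law, not a motor-control model; path
  distances from the pose-level engine reflect its random walk, not human
  steering (study-level datasets use the reported distance moments instead).
- Raw TLX only; SUS item-level correlation structure is not modelled (items
  are constructed to hit the target score, not to mimic response styles).
- The azimuth convention is a package decision; absolute φ values are only
  comparable across systems that share the reference-direction choice.
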