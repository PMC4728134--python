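# Methods

## Tracks, sessions and units

The unit of analysis is one filopodium track: an ordered series of 3D
filament lengths (μm) at a fixed frame interval (minutes), plus the
orientation angle (degrees, reduced to [0, 360)) the filopodium had at its
first appearance. Tracks are grouped into an imaging session — one growth
cone observed over a window `(t_start, t_end)` — with fast sessions at
1-min intervals over 1 hr and slow sessions at 30-min intervals. Times are
minutes from the session start (first frame = 0). Lengths are taken as
exported by the filament tracker; no geometry is recomputed.

The on-disk formats (a long table and a column-per-filopodium wide table)
are reconstructions of typical spreadsheet exports; real tracker exports
(e.g. Imaris "length over time" sheets) may need a one-off conversion to
one of them. The long dialect is canonical because it is unambiguous under
censoring; the session window is not representable in either dialect, so
readers accept it explicitly and otherwise infer `(0, max observed time)`,
which makes censoring flags conservative.

## Step partition and per-filopodium metrics

For consecutive samples the signed change Δℓ is classified against the
static threshold θ (default 0.3 μm): static iff |Δℓ| < θ, extension iff
Δℓ ≥ +θ, retraction iff Δℓ ≤ −θ. The threshold reflects the precision of
manual filament segmentation: smaller changes cannot be distinguished from
tracing noise. A change of exactly θ counts as movement — "static" is
defined strictly below the threshold, which makes the three kinds an
exhaustive partition (per track, static + moving intervals = frames − 1).

From the steps:

- **events** — maximal same-kind runs of moving steps (static steps end a
  run). Runs are the minimal event definition consistent with reading a
  kymograph; no sub-interval interpolation is attempted.
- **mean speed** — mean |Δℓ|/Δt over moving steps only, extension and
  retraction pooled into a single average. Undefined (reported `NA`) when
  no step moves; when defined it is necessarily ≥ θ/Δt. Speeds from 30-min
  sessions are computed by the same formula but should not be pooled with
  1-min sessions.
- **inactivity** — static steps / all steps. The denominator is the
  interval count (frames − 1), not the frame count; undefined for
  single-frame tracks. `inactivity = 1` exactly when mean speed is
  undefined.
- **lifetime** — last minus first sample time; a single-frame track has
  lifetime 0.

Undefined values propagate as `None` in memory and the literal token `NA`
in outputs; they are excluded (with logged counts) from group statistics.
Zero is never used as a stand-in: a zero inactivity is a real measurement.

## Censoring and classification

A track whose first (last) sample coincides with the window start (end) is
flagged left- (right-) censored: its true lifetime is at least the observed
one. Classification uses this lower-bound logic:

- **stable**: lifetime ≥ 60 min (censoring can only lengthen it);
- **transient**: lifetime < 8 min and uncensored;
- **indeterminate**: censored with lifetime < 60 min;
- **intermediate**: uncensored, 8 min ≤ lifetime < 60 min.

This keeps transient and stable counts conservative: a short censored
track is never called transient. Classification is monotone in lifetime
(growing older never demotes a track). Lifetimes are additionally binned
into [0,2), [2,4), [4,8), [8,16), [16,32), [32,60), [60,∞) minutes,
labelled `<1`, `2-3`, `4-7`, `8-15`, `16-31`, `32-59`, `>=60 min` — edges
on whole observed minutes, with the 60-min edge shared with the stable
cutoff.

## Cohort statistics

Two-group comparisons use the unpaired two-sided Student t-test with
pooled variance (`df = n_a + n_b − 2`), the conventional default of the
interactive statistics packages this workflow originated in; Welch's
unequal-variance variant is available behind a flag. Two groups with zero
variance and equal means give t = 0, p = 1; with unequal means the
comparison is degenerate and raises. Raw p-values are reported; no
multiple-testing correction is applied (comparisons are few and reported
individually).

Group inactivity means optionally exclude zero-inactivity filopodia:
short-lived filopodia have zero inactivity almost by construction (one or
two intervals, all moving), which deflates naive transient-group means;
after exclusion transient and early-stage stable filopodia are comparable.

Filopodia-number time courses across developmental stages (x = stage in %
of pupal development) are normalised to a baseline stage (value 100%) and
summarised by OLS quadratics y = c0 + c1·x + c2·x². Both reference
relative-count curves evaluate to ≈100 at the 28% baseline, which fixes
the percent scale and the stage-% x variable used here.

## Heat maps

`build_heatmap` lays a session out as a time × filopodium matrix over the
full window grid: one column per track, sorted ascending by initial
orientation angle, ties broken by first-appearance time then track id (a
deterministic order; the display encodes angle rank, not angle value).
Cells hold lengths where the filopodium exists and NaN elsewhere, so the
map is a bijection from samples to non-missing cells and each column's
non-missing run is one contiguous vertical stroke spanning the lifetime.
The text export serialises floats at full precision, so export → import is
the identity; rendering puts time on the y-axis with length-mapped colour
on a dark background.

## Synthetic growth cones

The simulator generates sessions with exactly the statistical structure
the metrics assume — it is test scaffolding and a parameter-recovery
harness, not a biological model. Per filopodium, independently:

- birth frame uniform over the window; angle uniform on [0, 360);
- class: transient with probability `transient_fraction`, else stable;
- nominal lifetime in frames: geometric (memoryless) with the class mean,
  truncated to ≥ 1 interval and, for stable, ≥ 60 min — the simplest
  discrete-time lifetime law consistent with the heavily short-lived
  observed lifetime histograms;
- per interval: static with probability `p_static`, else a signed step
  whose magnitude is normal(`step_mean_um`, `step_sd_um`) truncated below
  at θ — so every generated moving step is detected as moving and the
  generative and analytic definitions coincide — and whose sign is an
  extension with probability `p_extend_given_moving`;
- a retraction crossing zero is recorded as a final sample at length 0 and
  ends the track (full retraction out of existence; this also produces
  realistic extra short lifetimes). Recording that clamped final step keeps
  the generator's interval count aligned with the analysis, at the price
  of a small downward bias in measured speed (the clamped retraction is
  slower than its drawn magnitude) and a slight upward bias in inactivity
  (a clamp from below θ is recorded static);
- the track is truncated at the window end, so right-censoring arises
  naturally.

A single seed expands into per-track substreams by counter
(`SeedSequence(seed, spawn_key=(session, track))`), so identical seeds
reproduce sessions bit-for-bit and increasing `n_filopodia` extends a
session without reshuffling existing tracks.

Defaults are fixed once to emulate a wild-type growth cone during early
layer formation: `interval_min = 1`, `window_min = 60`, `θ = 0.3 μm`,
`transient_fraction = 0.9` (>90% of filopodia are transient at that
stage), `lifetime_mean_transient_min = 3` (most transients live a few
minutes), `lifetime_mean_stable_min = 90`, `step_mean_um = 1.3` (the
wild-type transient mean speed), `step_sd_um = 0.3`, `p_static = 0.3`
(early-stage inactivity ≈ 0.30), `p_extend_given_moving = 0.5` (extension
and retraction speeds and counts are indistinguishable), and
`init_length_um = 1.5` (the transient mean length, taken as the typical
length at first detection).

What the generator does **not** emulate: spatial/3D geometry, interaction
or competition between filopodia, stage-dependent parameter schedules,
autocorrelated step noise, or segmentation error on lengths. Passing
parameter-recovery tests therefore shows the analysis is faithful to its
own definitions on data satisfying its assumptions — not that real imaging
data satisfy them.

## Validation strategy and problem sizes

The test suite checks every operation against an independent route:
hand-computed worked trajectories; a naive-loop brute-force recomputation
of all per-filopodium metrics on 1,000 random short tracks (agreement to
1e-12); closed-form pooled-t and normal-equations oracles for the
statistics; and Monte-Carlo recovery of `p_static`, the truncation-
corrected step mean and the transient fraction from a 500-filopodium
simulated session. Because window censoring sends most long-lived
filopodia to the indeterminate class, the recovered "transient share" is
measured as the transient + indeterminate share, which is the quantity
with the simple binomial sampling law. Type-I error of the two-arm
comparison is calibrated on 1,000 equal-parameter replicates of
50-filopodium arms — sizes chosen to keep the full suite under a minute of
simulation while leaving the binomial bands narrow enough to detect
miscalibration.

## Known limitations

- The event definition (runs of moving steps) and the 0.3 μm threshold
  are conventions; metrics are threshold-dependent and the threshold is
  exposed everywhere.
- Filopodia are pooled across growth cones in comparisons; no
  mixed-effects nesting or survival analysis of lifetimes is provided.
- The wide-dialect reader requires each filopodium's existence to be one
  contiguous run; trackers that re-use ids after a gap must be converted.
- Angle conventions (origin, direction) are not standardised across
  trackers; only the ordering of angles matters to the heat map.
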