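# Methods

`limblineage` quantifies cell-lineage behavior in a developing arthropod
limb from tracked nuclei.  This note documents the models and procedures
the package implements, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## The lineage model

A tracking session yields a forest of point detections linked over time.
Links may span more than one frame (manual tracking typically annotates a
nucleus every few time-points, with extra annotations around mitosis), so
time is carried in hours derived from the frame index and the frame
interval (default 7.5 min, the acquisition cadence of the light-sheet
recordings the package targets).  Positions are physical micrometres; no
positions are interpolated for skipped frames.

On top of the raw graph the package derives *cells* (branches between
divisions), *division events* (out-degree-2 detections), *cell-cycle
lengths* (CCL; the branch length in hours between a cell's birth at its
parent's division and its own division), *clones* (all descendants of an
ancestor detection up to a time horizon), relative founder birth times on
a 0–100 % scale, and cell-number growth curves anchored at a reference
division.  Division time is the time of the branching detection (the
parent's last annotation), not the daughters' first frame — this matches
how lineaging tools mark the split at the parent node.  Cells whose birth
(roots) or end (terminal or lost tracks) was not observed are flagged
*not applicable* for CCL rather than silently dropped.

## Lineage-tree distance

Each founder's tree is reduced to the multiset **L** of division times in
its subtree, expressed relative to a global temporal anchor (the forest's
first tracked division), optionally multiplied by a linear registration
factor, and truncated at a cut time `t_cut`.  Two trees are compared by:

- **δn = |Card(Lx) − Card(Ly)|**, the difference in division counts;
- **δt**, the mean absolute difference of division times under the
  one-to-one pairing **P\*** that minimizes it.  The pairing covers the
  smaller set (smaller pairings would trivially minimize the mean and an
  empty pairing leaves the mean undefined); it is found exactly by a
  rectangular linear-assignment solve on the |Lx|×|Ly| cost matrix of
  absolute time differences — minimizing the mean over fixed-size
  matchings equals minimizing the sum.  When either set is empty, δt is
  defined as 0 and the disparity is carried entirely by δn.

Within a batch of pairwise comparisons both components are divided by the
batch maxima `nt` and `nn` (a zero maximum forces its component to 0,
avoiding 0/0) and combined into the dimensionless distance Δ.  Two
combinations are provided — the printed definitions of this distance in
the literature are typographically ambiguous about it — with the
Euclidean norm as the default: `Δ = sqrt((δt/nt)² + (δn/nn)²)` and
the arithmetic mean `(δt/nt + δn/nn)/2`.  By construction Δ(L,L)=0, Δ is
symmetric and non-negative, and δt is invariant under a common time shift
of both sets; the triangle inequality is *not* claimed.  Because the
normalization constants are batch-relative, Δ values from different
batches are not directly comparable.

The *union-average tree* of one founder observed in two registered limbs
is the multiset union of the two time collections; duplicates are kept so
that cardinality still counts observed divisions.

Truncation conventions: within-limb clustering uses the full tracked span
(complete trees); cross-limb comparisons use a 35 h cut, the horizon up
to which the more coarsely tracked replicate is faithful.

## Founder clustering and cross-limb statistics

Founder cells are clustered from the Δ matrix with Ward's
minimum-variance method, applying the Lance–Williams recurrence directly
to the given dissimilarities.  *Caveat:* Ward formally presumes squared
Euclidean distances; applying it to Δ follows the analysis convention this
package implements and in practice yields monotone merge heights
(Ward linkage is reducible), but the variance interpretation of merge
heights is approximate.  Flat classes come from cutting the merge
sequence at *k* clusters; dendrograms export as Newick with half-height
branch lengths.

Across two replicate limbs, founders are matched by identity labels
(parasegment + row + column, e.g. `E4c5`) — never by position.  The
homologous (diagonal) and non-homologous (off-diagonal) Δ values of the
cross-limb matrix are compared with a two-sided asymptotic two-sample
Kolmogorov–Smirnov test, and medians are additionally reported as
percentages of the batch-maximum Δ, since raw Δ is batch-relative.

## Growth-curve temporal registration

Replicate limbs imaged at different temperatures develop at different
tempos; their cell-count growth curves superimpose after multiplying one
curve's time axis by a single factor.  Counts are piecewise-constant, so
curves are resampled by previous-value (step) interpolation; counts are
never rescaled (the correction is tempo, not size).  The factor is found
by scanning scales 0.5–3.0 in steps of 0.01 and minimizing the squared
count difference on a uniform 0.5 h grid, followed by a bounded local
refinement kept only when it strictly improves the objective.  By
default the evaluation span adapts to each candidate scale (from the
anchoring division to the latest time inside both curves at that scale)
and the objective is the *mean* square so spans of different lengths are
comparable; a short fixed span leaves the scale poorly identified because
late, information-rich parts of the curves are discarded.  Exact ties —
inevitable with step curves — break toward unit scale.

## Division orientation

Orientation is measured as the angle between the daughter–daughter
separation vector (at the first frame where both daughters are
annotated, the earliest available proxy for the spindle axis) and a
reference axis: the straight anterior–posterior compartment boundary,
which during limb outgrowth is parallel to the proximal–distal axis.
The axis may be supplied directly or fitted to boundary-cell positions
as a total-least-squares line (principal axis of the centred points).
Angles are computed fully in 3D — whether the original measurements were
projected is unstated, so no projection plane is assumed — and folded to
[0°, 90°] because division axes are undirected.  Rose-diagram summaries
use six 15° bins, half-open except the last (90° belongs to bin six), per
developmental-stage windows.

## The synthetic limb generator

Machine-readable lineage annotations for real limb primordia of this
kind are rarely available, so the package ships a generative model of the grid-organized limb
primordium as the test substrate for every other module.  What it
emulates:

- **Founder grid.** Rows b–d of one parasegment plus rows a–b of the
  next, columns 3–9.  The full grid enumerates 35 positions while the
  observed primordium counts 34 founders without naming the excluded
  position; the default drops the lateral-most ventral cell (E4b9) and
  the count is configurable.
- **Three proliferation classes** assigned spatially: fast *central*
  cells (c/d rows of the anterior parasegment, columns ≤ 7), slow
  *peripheral* cells (the ventral b rows), and *mixed* cells (posterior
  a row and lateral c/d columns).  Cell-cycle lengths are truncated
  normal (floor 0.5 h) with class defaults 7.8 ± 0.5 h (central),
  14.0 ± 0.8 h (peripheral) and 10.5 ± 0.6 h (mixed) — means inside the
  reported fast (7.1–8.5 h) and slow (8.5–16.4 h) ranges, standard
  deviations consistent with those narrow ranges.  Each founder lineage
  executes at most `n_generations = 5` division rounds, matching the
  five differential divisions of the fastest observed cells; the classes
  therefore complete their programs inside the 50 h window and differ by
  near-deterministic division counts (31 / 15 / 7), which is what makes
  them recoverable by the distance-clustering pipeline, as the cleanly
  separated founder classes observed in real limbs imply.
- **Founder birth wave.** Births stagger by 0.2 h per row and column
  step plus 0.15 h Gaussian jitter, anterior/medial first.  The steps
  are deliberately small: under the global temporal anchor, birth
  stagger is pure within-class noise for the distance metric, and the
  division waves of the real tissue are developmentally synchronized
  rather than timed from each cell's individual birth.
- **Orientation program.** Division directions follow a folded von Mises
  law (concentration κ = 8) about 90° to the AP boundary before the
  switch time (16 h ≈ two early longitudinal rounds) and 0° after it
  (PD-biased outgrowth).  Daughters are offset ±3 µm along the drawn
  direction; κ = ∞ yields exactly the programmed mean.
- **Tracking emulation.** Detections are emitted on the 7.5-min frame
  grid every 5 frames plus the division-adjacent frames, mirroring
  manual tracking practice.  Division times snap to the frame grid (at
  most half a frame interval of error).
- **Replicate limbs.** A replicate replays the same programmed schedule
  with all times divided by a linear scale factor (default 1.6, a realistic
  temperature-induced tempo difference between replicate limbs)
  plus independent Gaussian jitter per birth/division (implied cycles
  floored at 0.25 h).  Homologous founders share identity labels.

Everything is deterministic given the seed, and every division is logged
in a ground-truth table (programmed continuous time, snapped time,
programmed angle, class) so estimators can be validated against the
program that produced the data.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: tissue mechanics and cell movement (positions
are static apart from daughter offsets), cell-cycle lengthening over
developmental time (real slow cells divided as little as once in 50 h,
which stationary cycle draws within the reported ranges cannot
reproduce; the generator's slow cells divide about three times and its
~600 final cells overshoot the observed 361), track losses and
annotation errors, compartment-boundary geometry, and any coupling
between division orientation and local tissue shape.  Class recovery
results in particular hold under the generator's stereotyped,
well-separated division programs; noisier real lineages may cluster less
cleanly.

## Problem sizes and tolerances

Validation batteries use the study-condition defaults: 34 founders,
50 h, with 10 independent limbs for clustering recovery (adjusted Rand
≥ 0.8 expected in ≥ 8/10 seeds), 20 replicate pairs for scale recovery
(±0.1 of 1.6 in ≥ 18/20) and homolog separation (median ordering and
KS p ≤ 0.01 in ≥ 18/20), 200 random instances for pairing exactness
(equality to brute force within 1e-9), and 2-SEM bands for per-class CCL
recovery.  Angle binning is checked against numerical integration of the
folded von Mises density within three binomial standard errors at
n = 200, and rotation invariance to 1e-9 degrees.  Observed CCLs at the
50 h horizon are slightly right-censored (divisions falling beyond the
recording are unobserved), biasing class sample means low by roughly
0.1–0.2 h; the long-horizon generator test removes the censoring to
check the estimator itself.
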