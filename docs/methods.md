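# Methods

## Problem and model

The package labels a segmented coronary artery tree with the 16 standard
right-dominant segment names. Its core is a distance-transformation rule for
the left circumflex artery (LCx): anatomically the LCx courses through the
left atrioventricular groove between the left atrium (LA) and left
ventricle (LV), so its centerline points are consistently closer to the LA
than those of the left anterior descending artery (LAD), which runs on the
anterior interventricular surface. Given LA and LV surface point clouds
(sets A and B) and a candidate centerline point (x, y, z), the rule uses the
minimum Euclidean distances

    DminLA = min_{(xi,yi,zi) in A} sqrt((x-xi)^2 + (y-yi)^2 + (z-zi)^2)
    DminLV = min_{(xj,yj,zj) in B} sqrt((x-xj)^2 + (y-yj)^2 + (z-zj)^2)

Every root path leaving the LM endpoint is a candidate; each is scored by
the count of its points with DminLA strictly below 25 mm plus the count with
DminLV strictly below 30 mm. The candidate with the highest combined count
is the circumflex; ties are broken by centerline length, residual ties by
lexicographic endpoint coordinates so results are reproducible. Distances
are always evaluated in world millimetres (the thresholds are metric), and
candidate points are the raw centerline points — point density affects the
counts, so resampling is available (`resample_spacing_mm`, 0.5 mm when
enabled) but strictly opt-in.

All geometry lives in a fixed frame: x increases toward the patient's left,
y toward the anterior, z toward the inferior ("LAI"; recorded in every file
the package writes). Readers must convert into this frame; silent
conversion is never attempted.

### Direction pre-filter

Before scoring, candidates are filtered by their net displacement. The
circumflex course in this frame is posterior (and typically leftward); the
default `"anatomical"` filter keeps a path iff its net Δy < 0. This
matters: the LAD hugs the LV over its entire (long) course, so its
DminLV-count alone can rival the circumflex's combined score — the
direction step is what removes anterior-trending paths (LAD, diagonals,
ramus) from the candidate list, leaving the LA-proximity count to
discriminate among the posterior/lateral routes. A `"literal"` mode
implements the alternative stated convention (exclude paths with net
Δy ≤ 0 and net Δx ≥ 0 simultaneously, i.e. require an anterior or rightward
trend); under the declared axis orientations that convention rejects every
anatomically correct circumflex, so it exists behind the config switch for
sensitivity analysis rather than as the default. `"off"` disables
filtering. The x-term is omitted from the anatomical test because the
proximal circumflex's net lateral travel is small and jitter-sensitive,
while the posterior trend is robust.

### Remaining labels

* **LM** — the edge chain from the left ostium to the first node of degree
  ≥ 3. If no bifurcation exists, the tree is labeled LM (first
  `lm_fallback_mm` = 10 mm) then pLAD/mLAD/dLAD, with a warning.
* **LAD** — among root paths from the LM endpoint whose first edge differs
  from the selected LCx's, the one with the greatest anterior–inferior
  extent (net Δy + Δz, ties by arc length).
* **p/m/d subdivision** — equal arc-length thirds for RCA and LAD
  (config-overridable fractions). The circumflex splits into pCx, ending at
  the OM1 origin when OM1 exists and at the first third otherwise, with the
  remainder labeled LCx — the two-label circumflex scheme of the standard
  presence table.
* **RI** — a branch arising within `ri_tol_mm` of the LM endpoint that is
  neither the selected LAD nor LCx (longest such path).
* **D1/D2, OM1/OM2** — side branches off the LAD / circumflex path, ordered
  by origin arc length, minimum length 5 mm (`min_side_branch_mm`) to be
  eligible; branches beyond the second are flagged unlabeled, never given
  out-of-vocabulary names.
* **Right tree** — the longest root path's trunk up to its last bifurcation
  (the crux) is the RCA main vessel (thirds: pRCA/mRCA/dRCA); of the distal
  branches originating within `crux_tol_mm` of the crux, the one with the
  greatest posterior-apical travel (net Δy + Δz) is R-PDA, the other major
  branch R-PLB. Left-dominant labels (L-PDA/L-PLB) are out of scope.
* Missing structures are reported absent, never force-assigned; the
  evaluation module scores absence explicitly.

## Skeletonization

Thinning uses border-point deletion with simple-point tests under the
standard 26/6 foreground/background connectivity pairing, applied on the
voxel lattice (CCTA masks here are 0.625 mm isotropic); metric correctness
enters when voxel indices map to world mm through spacing and origin
(voxel-centre convention). Guarantees verified by tests: the skeleton is a
subset of the input foreground, the 26-connected component count is
preserved, and the operation is idempotent. One repair is applied on top of
the library thinning routine: border-point deletion can erase a small
isolated component entirely, so any input component with no surviving
skeleton voxel gets its innermost voxel (distance-transform argmax)
restored.

The skeleton-to-graph conversion makes voxels with ≠ 2 skeleton neighbours
nodes (26-connectivity), merges 26-adjacent node voxels into one node at
their world centroid, and turns maximal 2-neighbour chains into polyline
edges; every skeleton voxel is assigned exactly once. Pure cycles are
anchored at a deterministic voxel and flagged. Terminal edges shorter than
`spur_min_mm` (default 3 mm) whose far end is a junction are pruned, and
pass-through degree-2 nodes are spliced afterwards.

### Junction fusion tolerances

Thinning a union of finite-radius tubes does not reproduce ideal branch
points: where three tubes meet, the fused region thins into two or three
junction nodes spread over several lumen radii, occasionally with a small
cycle, and tube tips retract by roughly a radius (several mm for a short
stem merging into a thick junction). Three tolerances absorb this —
`ostium_tol_mm` (8) when matching ostium seeds to root nodes, `ri_tol_mm`
(8) when deciding whether a branch arises "at" the LM bifurcation, and
`crux_tol_mm` (8) when collecting distal RCA branches "at" the crux. The
values are a few lumen diameters: large enough to cover observed junction
smear at 1.25 mm tube radius, far below the ≥ 15 mm origin distances of
genuine first side branches. On idealized polyline input (no
rasterization), 1–2 mm would suffice; the defaults favour mask input.

## Phantom generator

Each seeded case contains: LA and LV chamber surfaces as jittered ellipsoid
point samples (LA posterior–superior: centre (44, 16, 32) mm, semi-axes
(20, 14, 16); LV anterior–inferior–left: centre (48, 42, 72), semi-axes
(30, 27, 40)); a coronary tree of cubic-spline centerlines sampled at 1 mm
through anatomically placed control points — LM from the left ostium to the
bifurcation, LAD along the anterior interventricular course to the apex,
LCx through the AV groove gap, RCA around the right AV groove to the crux,
plus optional D1/D2, OM1/OM2, RI, R-PDA/R-PLB; and on demand a binary
volume of 1.25 mm-radius tubes on a 0.625 mm isotropic grid (a voxel is
foreground iff its centre lies within the radius of a densely resampled
centerline, which caps tube ends hemispherically and keeps thinning free of
end-face artifacts).

Variation: a global translation (±3 mm), Gaussian control-point jitter
(σ = 1.5 mm, attachment points pinned to the jittered parent), chamber
point jitter (σ = 0.8 mm), and branch presence sampled with prevalences a
cardiac reader would call typical (two diagonals in 70% of cases, one in
25%; two marginals in 65%, one in 30%; ramus in 35%; both distal RCA
branches in 90%, jointly — a lone distal branch would be indistinguishable
from trunk continuation). Only right-dominant anatomy is generated. Every
case re-verifies the groove premise (mean DminLA of the LCx < mean DminLA
of the LAD) from raw distances; generation is deterministic in (seed,
params) with a fixed draw order.

Ground truth uses the same subdivision conventions as the labeler (thirds,
pCx-at-OM1), built directly from the generating branch geometry — it never
touches the skeleton or the selection rules. Perturbations (`perturb`) drop
branches, truncate them to a fraction, or jitter points, with ground truth
updated consistently; these emulate the incomplete-extraction failure modes
that dominate labeling errors in practice.

What the phantom does **not** emulate: real lumen-segmentation noise
(surface roughness, gaps, stenoses), image intensities, myocardium
segmentation error in the LA/LV clouds, population anatomy statistics,
left-dominant or codominant circulation, and inter-patient scale variation
beyond jitter. Passing the phantom suite therefore demonstrates the
pipeline's rules behave as specified on clean, premise-satisfying anatomy —
not clinical-grade performance.

## Evaluation conventions

Presence is a per-segment binary detection task across cases (TP both, FN
reference-only, FP prediction-only, TN neither) with precision = TP/(TP+FP),
recall = TP/(TP+FN), accuracy = (TP+TN)/n, F1 the harmonic mean. Percentages
keep full precision internally and round half-up to one decimal for
display; zero-denominator metrics are undefined (NaN), never 0 or 100;
totals pool counts rather than averaging percentages. The metric formulas
reproduce every row of the published 157-patient presence table from its
own TP/TN/FP/FN counts at one-decimal rounding, with one caveat: the D1
row's printed F1 is inconsistent with its own printed counts
(2·152/(2·152+0+2) = 99.3%, not 99.4%); the tests assert the
counts-consistent value. The published abstract also quotes an overall
presence accuracy of 96.2% where the table's pooled counts give 95.7%; the
package reproduces the table arithmetic and leaves the discrepancy to the
source.

"Overlap" has no standard closed form; here it is point-wise recall per
segment — the percentage of reference points of a segment whose nearest
predicted point (within a tolerance, default 1 mm; 2 mm when comparing
against skeleton-derived predictions, i.e. about one voxel diagonal)
carries the same label — with a symmetric Dice-style mode for sensitivity
analysis. Comparisons error out when more than 5% of reference points have
no correspondence, unless non-strict matching is requested for scoring
predictions that may legitimately omit branches. The confusion matrix is
row-normalized over reference labels with an extra "unlabeled" column; a
ground-truth segment counts as *recovered* when its label is present and
its overlap is at least 50%.

Two-rater agreement is the percentage of cases with the same presence call
per segment; disagreements take the adjudicator's call when one is given,
otherwise they are flagged unresolved.

## Numerical choices and degenerate inputs

Minimum distances go through a k-d tree and are tested to agree with
exhaustive search to 1e-9 mm. Threshold comparisons are strict (a distance
of exactly 25 mm does not count). All tie-breaks (candidate selection,
path enumeration order, cycle anchoring) are deterministic. Empty clouds,
empty volumes, sub-2-point centerlines, out-of-range arc positions,
out-of-vocabulary labels and mismatched case lists raise errors rather
than guessing. Fragments partition path points half-open so each centerline
point carries exactly one label; junction points claimed by two fragments
are kept by the earlier (more proximal) one.

## Problem sizes

The default verification suite runs 50 phantom seeds end-to-end
(mask → thinning → graph → labels, ~150×130×190 voxel grids), 200
randomized selection-rule trials and 100 random distance-oracle instances;
the full test suite and the acceptance script each complete in well under a
minute on one CPU.

## Known limitations

* The LCx score rewards path length whenever all candidates hug the LV (the
  LV proximity count then equals the point count); on phantoms whose second
  marginal is longer than the remaining groove vessel, the marginal route
  can outscore the true circumflex by a few points, swapping LCx and OM2 —
  the same confusion pattern the method shows on clinical data. Roughly
  2–3% of suite segments are lost to this mode.
* p/m/d boundaries are a convention (thirds); real readers place them at
  anatomical landmarks, so boundary-sensitive overlap against human
  references would be lower than against the phantom's matching convention.
* Junction smear tolerances are tuned to the default tube radius and voxel
  pitch; gross changes to either should be accompanied by revisiting
  `ri_tol_mm`/`crux_tol_mm`/`ostium_tol_mm`.
* Skeleton tips retract by about a lumen radius, so distal segment ends are
  systematically a little short of the true vessel ends.
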