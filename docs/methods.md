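# Methods

## Problem

A tooth detector on a dental panoramic radiograph emits, for each of the 32
permanent-tooth positions (Universal Tooth Numbering: 1–16 upper right→left,
17–32 lower left→right), zero or more candidate bounding boxes with
confidence scores.  Typical failure modes are double detections of one
tooth, spurious boxes, and boxes carrying a neighbor's label.  `dentopt`
refines such output by choosing, per position, one candidate *or* the
explicit "missing tooth" option, maximizing a combined objective; it then
scores the result with standard IOU-based detection metrics.

## Objective and search

A complete assignment **P** = (p₁, …, p₃₂) is scored

    f(P) = (1/32) Σₓ [ ω_c μ_c(pₓ) + ω_p μ_p(pₓ) ]

where μ_c is the detector confidence of the chosen candidate and μ_p is the
mean of a trapezoidal membership function δ over the chosen candidates at
the neighboring positions Ω = {x−2, x−1, x+1, x+2} ∩ [1, 32].  δ depends
only on the absolute horizontal distance between box centers:

* 0 below `a`; linear ramp k→1 on [a, b]; 1 on [b, c]; ramp 1→k on [c, d];
  0 above `d`; and the constant `k` whenever either side is missing.
* Defaults: (a,b,c,d) = (30, 47, 114, 130) px for adjacent neighbors,
  (80, 97, 164, 180) px for next-nearest neighbors, k = 0.35.  These are
  pixel distances calibrated for source images roughly 1400–3100 px wide;
  a `scale` parameter rescales all thresholds for resized inputs.

The search initializes every position with its highest-confidence candidate
(missing where none exists) and then performs coordinate ascent: sweeping
positions 1→32, substituting every alternative candidate, and accepting
strictly improving substitutions until a full sweep changes nothing.  Strict
improvement guarantees termination and determinism.  An exhaustive
enumerator over the ∏ₓ(N(x)+1) product space (capped, default 10⁶
combinations) provides the global optimum and serves as the test oracle; on
200 random 6-tooth instances the greedy search finds that optimum on ≈98%
and never exceeds it.

### Decisions taken where the design was open

* **Boundary points of δ.**  The strict inequalities in the piecewise
  definition leave |Δx| ∈ {a, b, c, d} unassigned; we close each
  ramp/plateau at its ends (a→k, b→1, c→1, d→k), maximizing continuity.
  Measure-zero effect on any non-degenerate input.
* **μ_c of the missing candidate.**  Unspecified by the formulation; we use
  `missing_conf = k = 0.35`, consistent with δ's missing-case value, and
  expose it as a parameter.  Raising it biases the optimizer toward
  declaring teeth missing.
* **Neighborhood across the jaw boundary.**  The index rule 1 ≤ x±i ≤ 32 is
  applied literally, so position 16's neighborhood includes 17 and 18.
  Anatomically those are in the other jaw; `restrict_omega_to_jaw=True`
  truncates Ω at the 16|17 boundary instead.  The literal rule is the
  default because it is what the printed index arithmetic says.
* **Sweep semantics.**  The step description is ambiguous between
  immediate acceptance and applying only the best substitution per sweep;
  `sweep_mode="immediate"` (standard coordinate ascent) is the default,
  `"batch"` is available, and both are tested against the exhaustive
  oracle.
* **Ties.**  Confidence ties within a position keep input order (stable
  sort); exact score ties in the exhaustive search resolve to the
  lexicographically smallest rank vector.  Both choices exist purely for
  determinism.

## Evaluation

A detection is a true positive when it matches a same-class ground-truth
box with IOU ≥ 0.5 (threshold configurable); each ground-truth box absorbs
at most one detection, taken in descending confidence order, so duplicates
count as false positives — precisely the error mode the optimizer removes,
hence it must be penalized.  0/0 precision or recall is reported as 0 with
a warning.  Dataset precision/recall/F1 pool TP/FP/FN over images and
classes (micro-averaging); AP is computed per tooth class from the pooled
confidence ranking — all-point interpolation by default, 11-point
selectable — and macro-averaged into mAP, excluding (with a warning)
classes without ground truth.  A K-fold helper evaluates disjoint image
folds and tabulates per-fold and mean/min/max metrics.

## Synthetic detector simulator

`simulate` emulates the detector so the whole method is testable without
radiographs.  Per image (default 2000 × 1000 px):

* **Arch**: two straight horizontal rows, positions 1–16 left→right and
  17–32 right→left beneath them (so 17 sits under 16, as the numbering
  wraps around the mouth).  Adjacent centers are spaced
  Normal(80, 8) px clipped to (47, 114) — the near-trapezoid plateau — so a
  fully present ground truth scores μ_p = 1 between row-internal
  neighbors; this inverts the relationship by which the thresholds were
  calibrated to real arches.  Teeth are anatomically absent independently
  with p_missing = 0.08 (≈29.5 teeth per mouth, matching typical adult
  panoramic counts).
* **Noise**: each present tooth yields a correct candidate (box jittered
  ≤10% of its size, which keeps IOU ≥ 0.5 with the ground truth;
  confidence ~ U(0.7, 1.0)) unless missed (p = 0.02); a displaced double
  detection (shift 0.5–1.0 box widths, pushing IOU below 0.5;
  confidence ~ U(0.3, 0.8)) with p = 0.15; an extra copy of the true box
  carrying an adjacent position's label with p = 0.05 (an additional box
  rather than a relabeling, because a selector that cannot relabel could
  never recover the recall a relabeling would destroy); and
  Poisson(1) spurious boxes uniform over the image.  The confidence bands
  overlap deliberately so confidence alone cannot separate true from false
  candidates and the positional term matters.
* **Determinism**: image i uses seed `base_seed + i`; a manifest records
  the config and per-image seeds, from which the dataset regenerates
  bit-identically.

What the simulator does *not* model: arch curvature (δ only reads
x-coordinates, so straight rows lose nothing), vertical displacement noise
beyond small jitter, implants, residual roots, severely broken teeth, and
any appearance information.  Passing tests therefore demonstrate the
selection logic under the positional prior the method assumes, not
performance on real radiographs.

## Problem sizes and tolerances

Closed-form checks (δ values, F1 worked examples, IOU geometry) assert to
1e−12 or the printed rounding.  The greedy/exhaustive comparison uses 200
seeded instances of 6 positions with ≤3 candidates each, keeping the oracle
space ≤ 4⁶.  The end-to-end direction check (mean post-optimization
precision above pre-optimization, F1 not lower) uses 20 seeds × 100 images
with all noise processes on.  `scripts/acceptance.py` recomputes the same
quantities from scratch at those sizes for both weight sets
(ω_c, ω_p) = (0.8, 0.2) and (0.5, 0.5).

## Known limitations

* The greedy search is a local optimizer; the chain structure of Ω would
  admit exact dynamic programming, which is deliberately out of scope.
* δ ignores vertical distance and box size, and imposes no left/right
  ordering between neighbors — a mirror-swapped pair at the right spacing
  scores as well as the correct one.
* Metrics follow the VOC-style single-threshold convention (IOU 0.5), not
  COCO mAP@[.5:.95].
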