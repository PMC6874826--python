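# Methods

## Problem

Stand count — the number of germinated plants per plot — is a core early-season
phenotype in row crops such as cotton. A camera carried along a crop row at the
cotyledon stage yields a video in which every plant is detected in dozens of
consecutive frames, so summing per-frame detections overcounts massively. The
package solves the *de-duplication* problem: link detections of the same plant
across frames (tracking-by-detection) so each plant contributes exactly one
track, then count tracks that live long enough to be real plants.

The detector itself is out of scope: the pipeline consumes per-frame bounding
boxes with class labels and confidences (MOT-style CSV or COCO result JSON),
produced by any detector.

## Tracker model

Each tracked plant carries the 7-vector state

    t = [u, v, s, r, u̇, v̇, ṡ]ᵀ

with box center (u, v) in px, area s in px², width/height aspect ratio r, and
per-frame rates (u̇, v̇, ṡ). Time is measured in frames (dt = 1). The motion
model is constant velocity in center and area, with aspect ratio constant:

    prediction   x′ = F x,  P′ = F P Fᵀ + Q
    update       S = H P′ Hᵀ + R,  K = P′ Hᵀ S⁻¹
                 P⁺ = (I − KH) P′ (I − KH)ᵀ + K R Kᵀ      (Joseph form)
                 y = z − H x′,  x⁺ = x′ + K y

where F is the identity plus unit couplings (u,u̇), (v,v̇), (s,ṡ);
Q = diag(1, 1, 1, 1, 10⁻², 10⁻², 10⁻⁴); H selects (u, v, s, r);
R = diag(1, 1, 10, 10). These constants are reproduced verbatim — including
the unit process-noise variance on r, which F never moves — rather than
"simplified". The Joseph-form covariance update is algebraically equivalent to
the short form but keeps P symmetric positive semidefinite under roundoff; the
test suite checks symmetry and the minimum eigenvalue across 1000 random
steps.

**Initial covariance P0.** No published value exists. The package uses
diag(10, 10, 10, 10, 10⁴, 10⁴, 10⁴): moderate uncertainty on the four observed
components and large uncertainty on the three rates, about which a single
detection carries no information. It is a `FilterParams` field and fully
configurable.

**Measurement parameterization.** s = w·h and r = w/h (width over height).
The orientation of r is a convention — the factorization makes box ↔ state a
bijection (w = √(s·r), h = √(s/r)) and is fixed and documented here.

**Degenerate predictions.** A strongly negative ṡ (a box shrinking at the
frame border) can extrapolate to a predicted area ≤ 0. The state arithmetic is
untouched; only the *association anchor box* floors (s, r) at 10⁻⁶, making
such a tracker an effective point that cannot out-compete genuine overlaps.

## Association

Detections are assigned to predicted tracker boxes by maximizing total IOU
subject to (a) one-to-one assignment and (b) every matched pair having
IOU strictly greater than `min_iou` = 0.1. The constraint is folded into the
objective before the Hungarian solve: pairs at or below the floor get zero
gain, `scipy.optimize.linear_sum_assignment` maximizes the total on the
rectangular matrix, and assigned zero-gain pairs are discarded. Because an
inadmissible pair contributes nothing, the optimum of this relaxation equals
the optimum of the constrained problem — unlike the common
solve-then-threshold shortcut, which is suboptimal on instances where the
unconstrained optimum routes through a sub-threshold pair (e.g. the 2×2 IOU
matrix [[0.6, 0.32], [0.32, 0.09]]: demotion leaves total 0.6 where the
feasible optimum is 0.64). The test suite verifies cost equality against
exhaustive enumeration on hundreds of random instances up to 6×6.

## Lifecycle and counting

Per frame: predict all active trackers → associate → Kalman-update matched
trackers (lifetime += 1) → start a new tracker from each unmatched detection
(rates zero, lifetime 1) → terminate every unmatched tracker immediately.
There is no grace period and no re-identification; a single missed detection
ends a track. Lifetime counts every frame in which the tracker existed,
including its creation frame.

The seedling count is the number of trackers (terminated plus still active)
whose lifetime **strictly exceeds** a threshold of ⌊fps/4⌋ frames — 7 at
30 FPS, 15 at 60 FPS. The floor reproduces both published threshold values;
"longer than" is read as strict. Only detections of the target class
(default `seedling`) at or above a confidence floor (default 0.5, no
published value) enter the tracker.

**Known limitation — fragmentation under misses.** Because termination is
immediate, uncorrelated per-frame detection misses fragment tracks, and every
fragment longer than the threshold is counted: with i.i.d. miss probability
q = 0.1 on plants visible ~65 frames, runs between misses are geometric with
mean 10 frames, a track yields ≈ 7.5 runs of which ≈ 0.9⁷ ≈ 48% clear the
7-frame threshold — roughly a 3.5× overcount. The acceptance suite measures
exactly this (mean relative count error ≈ 190% at q = 0.1) and the
corresponding robustness test documents the failure rather than hiding it.
The method's accuracy on real video rests on detector misses being rare and
frame-correlated, not i.i.d.; extended-lifetime termination rules or
appearance-based re-identification would relax this and are deliberately out
of scope here.

## Preprocessing

CLAHE is applied to the value channel of the HSV representation only, so hue
and saturation — the cues separating green seedlings from soil — pass through
(up to 8-bit re-quantization; at pixels crushed to near-black, hue/saturation
are mathematically undefined). Implementation:
`skimage.exposure.equalize_adapthist` with an 8×8 tile grid and a normalized
clip limit of 0.02 (scikit-image's parameterization; both configurable, no
published values exist). Frame extraction samples uniformly at a requested
rate (training sets are typically built at 6 FPS; counting uses the native
rate) and refuses to upsample.

## Detection metrics

COCO-protocol metrics, implemented in-package: greedy confidence-ordered
matching (each ground truth consumed once), 101-point interpolated average
precision, average recall capped at the 100 highest-confidence detections per
image, at IOU 0.5 and averaged over IOU 0.5:0.05:0.95. F1 = 2PR/(P+R) is
computed with P = (m)AP and R = (m)AR100 of the matching regime. AR100 is
threshold-matched to the reporting regime (a single threshold when reported
"at IOU 0.5"). Categories without ground truth are excluded from means. Tests
compare against an independent re-implementation of the protocol (per-image
loops, precision-envelope AP) to 1e-4.

## Counting metrics

Predicted counts are regressed on observed field counts with ordinary least
squares, with or without an intercept (both fits are exposed; published
reports mix the two and state no selection rule). Adjusted R² is the standard
centered statistic with an intercept and the uncentered statsmodels
convention through the origin. RMSE is the root mean square of fit residuals;
MAE = mean |p − o|; MRE = 100 · mean(|p − o| / o). Tests pin all of these to
explicit normal-equation solutions.

## Synthetic scenes

The generator emulates a row-scan acquisition in box space (the tracker
consumes boxes, so no pixels are needed): plants occupy fixed intervals along
a 1-D row, and the camera field of view — a window of the frame width —
slides along it at constant speed. A plant emits a ground-truth box, clipped
to the frame, in every frame its box intersects the window, reproducing the
entry/exit slivers real detectors see at image borders.

Defaults correspond to a handheld scan at ~0.6 m/s, 30 FPS, 1920×1080, camera
~0.5 m above the row (≈1900 px per meter of ground): 150 px mean seed spacing
(≈0.08 m/seed), 90 ± 15 px plant width, 80 ± 12 px height, 30 px camera
travel per frame — each plant stays in view ≈65 frames. Two validity
constraints are enforced as part of the emulated acquisition design:

- *Sliver floor*: boxes thinner than max(2, speed/4) px at the frame edge are
  not emitted (they are below any detector's floor, and the floor guarantees
  an entering box overlaps its successor with IOU ≥ 0.2).
- *Width floor*: the width distribution is truncated at max(20, 1.5·speed) px.
  IOU association is physically impossible for an object narrower than the
  per-frame camera travel (consecutive boxes of the same plant barely
  overlap); the field protocol being emulated keeps camera speed well below
  plant size (~0.02 m/frame vs 0.05–0.1 m plants).

The corruption stage models detector imperfection: i.i.d. per-box misses
(default 0.1), Gaussian center and size jitter (default 2 px), a clipped
Gaussian confidence model (0.9 ± 0.05), and Poisson false positives (default
0.1/frame at lower confidence 0.6 ± 0.1). An optional raster renderer draws
disc-pair "cotyledon" sprites on soil texture so the preprocessing stage can
be exercised; rendering fidelity is not a goal.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: perspective and parallax, occlusion between plants,
frame-correlated detector failures (illumination bursts, motion blur), weeds
with plant-like appearance, and camera speed variation. In particular the
i.i.d. miss model is *harsher* on this tracker than real correlated misses of
equal rate (see the fragmentation limitation above).

## Problem sizes in the shipped checks

The test and acceptance runs use scenes of 5–40 plants over ~100–300 frames,
50 clean scenes and 20 noisy replicates, 500 random association instances
(≤6×6, against exhaustive enumeration), 1000 random filter steps, and
5-image detection fixtures — sizes at which every oracle (enumeration,
rational arithmetic, independent protocol implementation) is exact and fast.
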