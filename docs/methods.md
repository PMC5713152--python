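# Methods

This note documents the models, parameter choices and numerical
decisions behind `litchivision`, and what the synthetic benchmark does
and does not demonstrate.

## Camera model and stereo geometry

Each camera is a zero-skew pinhole: a world point `p` (mm) maps to the
camera frame by `p_c = R·p + T` and to pixels by
`μ = a_x·x_c/z_c + μ₀`, `γ = a_y·y_c/z_c + γ₀` (0-based pixels, x =
column rightward, y = row downward). The relative transform of the rig
is the composition `R_rel = R_r R_lᵀ`, `T_rel = T_r − R_rel T_l`,
validated by the point-transport contract
`right(p) = R_rel·left(p) + T_rel` rather than by any printed formula
(the sign of `T_rel` is purely a convention of the pose
parameterization). Matching assumes a rectified rig (identity
`R_rel`, baseline along x, default 200 mm); an explicit rectifying
rotation is out of scope.

Calibration is solved from given 3-D/2-D correspondences, not from
checkerboard images. Two standard solvers are provided: a normalized
DLT of the 3×4 projection matrix followed by RQ decomposition (≥ 6
non-coplanar points; coplanar input raises a rank-deficiency error) and
a planar multi-pose homography method for a flat board seen in ≥ 3
poses (the 11×8-corner board layout is kept as the test fixture).
Neither applies nonlinear refinement; on noiseless data both recover
the generating parameters to ~1e-9 relative, and at 0.1 px pixel noise
the planar solver's reprojection RMS stays below twice the noise level.
Lens distortion is not modelled.

Triangulation is the rectified closed form `z_c = a_x·b/d` with `x_c`,
`y_c` from inverting the projection; `d ≤ 0` is an error.

## Feature vector

A window is described by 10 numbers: four *effective colour
components* — `R−B` (raw channel difference), `I = (R+G+B)/3` (HSI
intensity), `Cb` per BT.601 full range with +128 offset (achromatic →
128), and `b*` of CIE L\*a\*b\* under sRGB/D65 (via
`skimage.color.rgb2lab`) — averaged over the window, plus the six
Tamura texture statistics of the window's BT.601 luminance:

* **coarseness** — mean over pixels of the best dyadic window size
  `2^k` (k ≤ 5), where best maximizes the difference of displaced
  `2^k × 2^k` means; scales whose displaced supports fall outside the
  patch are excluded from the argmax, since padded borders would bias
  the scale choice toward large k on fine textures.
* **contrast** — `σ / kurtosis^{1/4}`; zero for flat patches (variance
  below 1e-10 is treated as round-off).
* **directionality** — 16-bin orientation histogram over [0, π) from
  3×3 Prewitt gradients (votes require gradient magnitude ≥ 12); the
  statistic is one minus the histogram's normalized second moment about
  its peak with wrap-around distance, so a single dominant orientation
  scores near 1.
* **line-likeness** — mean cosine of the orientation-bin difference
  between each voting pixel and the pixel displaced 4 px along its
  edge direction.
* **regularity** — `1 − 0.25·Σ cv`, where `cv` is the coefficient of
  variation of the four statistics above across the 2×2 sub-window
  partition; sub-window statistics are sliced from the full-patch
  fields so they share its gradient context.
* **roughness** — coarseness + contrast.

Windows must be at least 8×8; the canonical analysis window is the
40×40 training-patch size. Per-pixel features (used by the BP network)
average colour over the 3×3 neighbourhood (reflected at borders) and
take texture from the enclosing 40×40 context window, keeping the
vector 10-dimensional even though a 3×3 neighbourhood cannot support
texture statistics. Whether colour enters per-pixel or window-averaged
is not dictated by the protocol; window-averaging is used throughout.
Features are not globally standardized — each classifier applies its
own scaling.

## Classifiers

All four train on labelled 40×40 patches (default 150 per class) and
emit one binary mask each.

* **Naive Bayes**: per-feature Gaussian class-conditionals with
  frequency priors; "statistics of the training sample" is read as the
  canonical Gaussian-independence model. Zero variances are floored at
  1e-9 rather than rejected.
* **KNN**: cosine similarity, k = 5 (odd, avoids most ties;
  configurable), ties broken toward non-fruit.
* **BP network**: 9 input neurons (the 3×3 neighbourhood intensities,
  scaled to [0, 1]), one sigmoid output thresholded at 0.5, hidden
  width `J = round(√(m+n)) + a` — the rule that reproduces both the
  documented working value J = 7 (a = 4) and the stated admissible
  range, where the literal printed formula does not. Training is
  full-batch gradient descent on MSE (learning rate 2.0), so the loss
  history is monotone for a stable rate and seeds make runs exactly
  reproducible (default seed 1234). An `R−B` colour gate (midpoint of
  the class means) selects candidate pixels; the network refines them.
  The alternative reading — feeding the full 10-feature vector of each
  neighbour — conflicts with the stated 9 input neurons and was not
  adopted.
* **Linear SVM**: soft margin, C = 10, features z-scored internally;
  solved by `sklearn.svm.SVC(kernel="linear")` with `w*`, `b*`
  extracted so stored models predict with one dot product.

Window classifiers vote: a pixel is foreground iff at least half of the
stride-8 windows covering it classified fruit. All models serialize to
JSON and reload with bit-identical predictions.

## Detection, categorization

Masks are dilated by a radius-10 disk, hole-filled, and components
below π·15² px removed. Circle detection runs a Hough transform over
integer radii 30–50 on the mask's Canny edges. The named *sensitivity*
parameter (0.97) maps to a normalized accumulator support floor of
`(1 − sensitivity)^0.46 ≈ 0.2`; the exponent was calibrated on
synthetic disks so that ideal disks (support ≈ 0.9) and the partial
arcs of clustered or occluded fruits (≈ 0.25–0.5) pass while the
phantom peaks that straight mask edges cast into the accumulator
(≤ 0.15) fail — a plain `1 − sensitivity` floor of 0.03 admits
phantoms everywhere and cannot produce one circle per ideal disk.
Near-duplicate circles (< 15 px apart, strict) merge by single-linkage
into their support-weighted mean. OR fusion is dedup-of-union, so one
classifier suffices to keep a fruit.

Categories use single-linkage components of the strict < 40 px
centre-distance graph (pairwise rules are the special cases of the
chain rule); exactly 40 px does **not** cluster. Merged labels span the
member labels' extreme coordinates; the cluster centre is the box
midpoint, which equals the diagonal intersection.

## Matching

The NCC of a template and a right-image window shifted by `d` is the
zero-mean cross-correlation normalized by both root sums of squares —
exactly +1 for any positive linear gray transform of the template.
Search is integer `d ∈ [0, 200]` on the same row; windows crossing the
right border are skipped, not zero-padded (padding would bias the
normalization). Acceptance threshold 0.6. The epipolar check allows
±1 row (configurable to strict). The ordering constraint binds only
matches whose labels overlap vertically — objects in disjoint rows may
legitimately swap horizontal order with depth — and is enforced
greedily by descending score, so the lower-scoring member of a crossing
pair is dropped. Sub-pixel disparity is deliberately not estimated.

## Synthetic scenes

The generator renders what the classifiers and matcher need to be
exercised on, not photorealism: red speckle-textured shaded disks
(radius 30–50 px) in planned clusters (intra-cluster spacing 26–36 px,
below the 40 px threshold; different clusters kept ≥ 120 px apart so
detection-stage mask merging cannot bridge them), a green/brown canopy
with sky gradient, three illumination modes (front-lit with specular
spots, back-lit with darkened fruit, low-contrast cloudy — fruit
luminance ordering front > cloudy > back is asserted in tests), and
consistent stereo: every object is shifted left in the right view by
its own pinhole disparity (fruit depths 900–1800 mm, background at
2500 mm, occluders 3 px nearer than their fruit; a_x = 600 px,
baseline 200 mm). Occlusion draws a leaf over a calibrated fraction of
each occluded fruit's area (equal-circle lens equation solved for the
offset) in both views. All randomness flows from one seed;
re-generation is byte-identical.

Training patches crop generated fruits (positives) and background
(negatives) across the three illumination modes. A third of the
negatives are "sliver" crops taken just outside a fruit's rim —
fruit-free at the centre but with up to a quarter fruit in one corner —
mirroring how manually cropped background samples around a canopy look.
Without such boundary negatives the window classifiers never see mixed
windows and over-segment fruits by 15–20 px, pushing the dilated blobs
of the largest fruits far beyond the 50 px Hough cap.

What passing on these scenes does **not** show: robustness to real
litchi rind texture, to continuous depth within a cluster, to
radiometric differences between physical cameras, or to the full
variety of orchard clutter; the generator's geometry (exact integer
disparities, planar clusters) is kinder than the field.

## Benchmark and problem sizes

The end-to-end suite trains on 60 patches per class and evaluates 20
seeded scenes at 640×480 (mixed A/B/C plans, the three illumination
modes cycled, occlusion fraction 0.3); the acceptance script uses the
same conditions over 12 scenes with all randomness derived from its
`--seed`. Scored quantities: per-cluster recognition recall under the
25 % coverage missed-rules, the fraction of non-occluded clusters
matched at the true disparity ±1 px (a detected cluster is credited to
the truth cluster within 50 px of its centre; clusters are placed
≥ 120 px apart, so this is unambiguous), and — for the occlusion
comparison — the cluster matcher's success rate against a
nearest-disparity single-circle baseline (radius ±5 px, row ±2 px)
credited at correspondence level (paired with the right-image circle of
the same fruit).

## Known limitations

* The four classifiers are only as good as the synthetic patch
  distribution; no illumination normalization is applied.
* Dilation by 10 px pushes large fruits past the 50 px Hough cap, so
  their fitted circles sit a few px off-centre (harmless under the
  25 % coverage rule, visible in centre-error assertions).
* The greedy ordering-constraint resolution is maximal but not
  guaranteed score-optimal for adversarial crossing patterns.
* Integer-disparity matching quantizes depth; at 1.5 m and d ≈ 80 px a
  1 px error is ~19 mm of depth.
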