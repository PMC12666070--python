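# Methods

This note documents the models, parameters and design choices behind
`c2pbench`: what the synthetic generator emulates (and does not), how each
registration baseline is formulated, the numerical choices that matter, and
the known limitations.

## Problem setting

A complete organ surface cloud `X` (M points, from a preoperative model) must
be rigidly aligned to a partial cloud `Y` (N points, N ≪ M, emulating an
intraoperative stereo reconstruction).  `Y` corresponds — up to non-rigid
deformation, a rigid perturbation and noise — to a visible subset
`X_visible ⊂ X`.  The registration unknown is `T = (R, t)` with `R ∈ SO(3)`.
Because every implemented solver is rigid while the simulated anatomy
deforms, a residual error floor exists by construction; the evaluation
exposes it explicitly through the ground-truth row.

## Synthetic pair generator

Each pair is produced by a fixed pipeline, every stage driven by substreams
of a single pair seed (so records regenerate bit-identically):

1. **Source sampling.** 3,500 points are drawn area-weighted from the rest
   mesh, with face indices and barycentric coordinates retained.  3,500
   points at ~200 mm organ width gives a mean point spacing of ≈4 mm, which
   matters below.
2. **Lobe deformation (ARAP).** One of the two lobes is chosen at random
   (split plane through the centroid along the widest axis; handle/anchor
   margin 0.3 of the half-extent).  The handle vertices are displaced by
   independent uniform draws in [−25, +25] mm along x and z (y = 0), and the
   mesh is deformed by 10 local–global ARAP iterations.  Because the
   deformed mesh keeps its connectivity, re-evaluating the stored barycentric
   coordinates yields index-exact source↔deformed correspondences.
3. **Visibility crop.** A virtual endoscope is placed in spherical
   coordinates about the deformed organ (polar 15–75°, azimuth 0–360°,
   radius 2.5 × bounding-sphere radius; ranges are configurable — plausible
   values, since intraoperative ranges are situational).  Candidate points
   are those whose outward normal (k = 16 PCA normals, oriented away from
   the centroid) makes an angle < 80° with the direction to the camera.
   Exactly `round(crop_ratio × 3500)` points are retained as a **contiguous
   patch** grown by Euclidean nearest-neighbour accretion from the candidate
   nearest the camera.  A random thinning of the whole camera-facing
   hemisphere would be unrealistically dispersed for a single endoscopic
   view; the accretion patch mimics one exposure window.  If too few
   candidates exist the camera is resampled (up to 10 attempts).
4. **Landmarks.** 20 landmark pairs (source position, same-index deformed
   position) are chosen by farthest point sampling over the cropped-out
   region, guaranteeing they are never part of the registration input.  TRE
   evaluated at the ground-truth transform therefore equals the mean
   ARAP-induced landmark displacement — the residual non-rigid component —
   and is provably independent of the rigid perturbation.
5. **Normalization.** Source and deformed clouds are normalized by the
   *source* cloud's isotropic map: centered on its bounding-box center and
   divided by half the largest extent, so all coordinates lie in [−1, 1] and
   the widest axis spans exactly [−1, 1].  A single isotropic scale (not
   per-axis min-max) is used because an anisotropic scaling would destroy
   the rigidity of the ground-truth transform.  The map converts mm-specified
   magnitudes into normalized units and back for reporting.
6. **Rigid perturbation.** Rotation: axis uniform on the sphere, angle
   uniform on [0, 45°], applied about the target centroid so the translation
   bound stays meaningful; translation: components uniform in [−50, 50] mm
   (converted through the normalization map).  The stored ground-truth
   transform is the composed normalized-frame motion.
7. **Noise.** Zero-mean Gaussian noise with σ = 0.01 normalized units is
   added to every target coordinate.  Noise is applied last, in normalized
   units, matching the scale at which reconstruction error enters a
   registration network's input.

The pipeline ordering (deform → crop → normalize → perturb → noise) keeps
every mm-specified magnitude in mm and the noise magnitude in normalized
units.  Per-pair seeds are stable 63-bit BLAKE2 hashes of (master seed,
source id, target index), so a split manifest is enumerable without
generating any geometry and a dataset regenerates byte-identically.

**The phantom.**  Clinical liver meshes cannot be redistributed, so sources
are procedural: the smooth (log-sum-exp) implicit union of two overlapping
ellipsoids — a larger right and smaller left lobe — plus seeded
low-frequency sinusoidal surface bumps, extracted by marching cubes at 64³
resolution (~3–5k vertices), rescaled to a 200 mm widest extent (an adult
liver is roughly 20 cm wide).  The phantom is watertight and genus 0.  What
it does *not* reproduce: sharp ridges (falciform notch), vessels/tumour
substructure, per-patient anatomical statistics, and the self-similarity of
a real liver's detailed surface texture.  Consequences: descriptor matching
is, if anything, *harder* on the phantom (smoother → more descriptor
collisions), while ICP basin geometry is comparable; passing tests show the
machinery is correct under the stated conditions, not that clinical accuracy
numbers transfer.

## Registration baselines

All solvers operate in the normalized frame; metrics convert to mm through
the stored map.

**ICP.** Point-to-point, identity initialization, at most 30 iterations,
stopping when the paired-point RMS residual improves by less than 0.001
(read as residual *change*; the alternative reading — absolute residual —
would never trigger on noisy data).  Pairing direction is target → source:
each point of the sparse partial cloud claims its nearest point of the dense
transformed source, avoiding the many-to-one collapse that the opposite
direction produces in the complete-to-partial setting.  Pose updates are
closed-form (Kabsch), so the residual sequence is non-increasing.

**Rigid CPD.** The moving source points are centroids of an isotropic GMM
fitted to the target by EM with a uniform outlier component (weight 0.1 —
the outlier fraction is a modelling choice; 0.1 is a common default and is
configurable), scale fixed at 1, at most 50 iterations, stop threshold 0.001
on the negative log-likelihood change.  **Variance initialization** is the
mean squared nearest-neighbour distance rather than the classic all-pairs
mean squared distance: with a whole-organ source and a small visible patch,
an organ-scale initial variance makes every centroid responsible for every
point and the first M-steps mean-shift the organ onto the patch, destroying
any reasonable initialization.  A locality-scale start keeps EM in the
basin of the initialization (measured: 8/20 → 20/20 recovery on clean
pairs).  A variance collapse below 1e-12 (perfect overlay of exact
subsets) terminates with a flag.

**GMM-L2.** Both clouds are equal-weight isotropic Gaussian mixtures (one
component per point, shared bandwidth; the source is reduced to the target's
size by farthest point sampling, so components = target size).  The
closed-form L2 distance between mixtures reduces, over rigid motions, to the
negative cross-correlation `−2⟨f_T, g⟩`, with Gaussian correlation integrals
`⟨N(μ_i, h²I), N(ν_j, h²I)⟩ = N(μ_i − ν_j; 0, 2h²I)`.  It is minimized over
(rotation vector, translation) by L-BFGS with an analytic point-gradient
(the 3×3 rotation Jacobian uses cheap central differences that never touch
the O(MN) kernel).  **Bandwidth schedule**: two stages at 0.02 and 0.01 of
the target bounding-box diagonal.  Coarse schedules (0.5/0.1 of the
diagonal) were measured to be actively harmful here: at organ-scale
bandwidth the correlation is maximized by translating the whole source
mixture's bulk onto the patch, so the coarse stage ruins a good
initialization instead of refining it.  Starting near the point-spacing
scale keeps the exact-coincidence optimum dominant.

**FPFH + RANSAC.** A non-learned stand-in for learned feature extractors so
the correspondence → robust-pose route is exercisable end to end: fast
point-feature histograms (three 11-bin Darboux-angle histograms; SPFH plus
inverse-distance-weighted neighbour SPFHs; radius 0.08 normalized units by
default), mutual-nearest-neighbour matching in descriptor space, then
RANSAC over 3-point Kabsch hypotheses (default 10⁴ seeded iterations,
inlier threshold `max_correspondence_distance = 0.05`), consensus refit and
ICP polish.  One numerical subtlety: the Darboux-frame source-point choice
compares the two endpoint normals' angles to the connecting line, a
comparison that ties *exactly* on locally spherical geometry; it is
quantized at 1e-9 so floating-point jitter cannot flip the frame under
rotation (this is what makes the descriptor rotation-invariant to 1e-6 in
practice).  On the smooth phantom, exact-index match correctness is
structurally capped (≈30–65% across patch shapes): neighbourhoods within
2× radius of the patch boundary are truncated relative to the complete
cloud, and smooth self-similar regions produce descriptor collisions.
Matches are bimodal — exact or far — which is precisely what RANSAC
tolerates: pose recovery from these matches is exact at the full 45°/50 mm
perturbation on clean pairs.

**Weighted Kabsch–Umeyama.** Closed-form minimizer of
`Σ w_i ‖R s_i + t − y_i‖²`: weighted centroids, SVD of the weighted
cross-covariance, determinant-sign correction enforcing `det(R) = +1`, no
scale.  Degenerate (collinear) support raises rather than returning an
arbitrary rotation.  This is the pose solver used by the overlap-score
route: predicted correspondences weighted by overlap confidence.

**Overlap head and losses.** In complete-to-partial registration the partial
cloud is contained in the complete one by definition, so its overlap scores
are fixed at exactly 1 — predicting them could only inject estimator error —
and only the complete cloud's keypoints are scored, with a single linear
layer + sigmoid over conditioned features.  The three losses are pure
functions: (i) overlap-confidence-weighted mean absolute keypoint position
error; (ii) a contrastive feature loss (true-match feature distances pulled
below 0.1, non-matches pushed beyond 1.0 — the margins are conventional
contrastive-loss values, configurable); (iii) binary cross-entropy of
overlap scores against labels.  The KPConv/transformer feature extractor
that would produce the conditioned features is intentionally out of scope
(GPU-scale training); the head and losses accept any feature matrix, and the
external-adapter interface lets trained models join the benchmark.

## Evaluation

* **MAE(R)**: mean over the three z-y-x Euler angles of the absolute
  difference (wrapped to ±180°) between predicted and ground-truth rotation.
  The Euler-anglewise convention follows the partial-to-partial registration
  literature; since it degenerates near gimbal lock, the geodesic angle is
  emitted as a secondary column.
* **MAE(t)**: mean absolute difference of the three translation components,
  converted to mm via the stored normalization map (the mm scale is the
  source organ's half-width; ~100 mm per normalized unit for a 200 mm
  liver).
* **TRE**: mean Euclidean landmark-pair distance in mm after applying the
  predicted transform.
* **Precision / recall**: a predicted correspondence is correct iff its
  source index equals the ground-truth map of its target index; precision =
  correct/predicted (0 with an empty prediction set), recall = correct/total
  ground-truth pairs.
* **Aggregation**: mean and sample (n−1) standard deviation per method ×
  crop ratio; single-record cells report std 0.  The ground-truth transform
  is always evaluated as an additional "gt" row.

## Reproducibility and sizes

The benchmark runner is deterministic given the master seed (phantom seeds,
pair seeds and RANSAC seeds all derive from it), caches pair archives and
per-method results, and resumes an interrupted run to the identical table.
The test suite exercises parameter recovery on 20 clean pairs at 15%
partiality with an in-basin perturbation of 2° / 2 mm: on a 3,500-point
sampling the mean point spacing is ≈4 mm, and a displacement beyond half a
spacing (≈2° of rotation at a 100 mm half-width) moves local solvers out of
the nearest-neighbour lock-in basin — the full 45°/50 mm condition is
exactly the regime where those baselines fail, which the benchmark reports
rather than hides.  The trend suite and the acceptance script use 10–20
pairs per condition and 10⁴/10⁶ draws for the stochastic bounds; these sizes
give stable statistics while keeping a full run in minutes on one CPU.

## Known limitations

* The phantom's smoothness understates real livers' surface detail;
  descriptor-based matching numbers are pessimistic relative to meshes with
  sharper features.
* ARAP with clamped-at-zero cotangent weights (needed so both local and
  global steps are true minimizations and the energy is provably
  non-increasing) slightly stiffens meshes with many obtuse triangles.
* Only rigid ground truth is recovered; the deformation field itself is not
  an output of any implemented method (the TRE floor of the gt row measures
  what such a method could still gain).
* The evaluation's mm scale depends on the source normalization convention;
  externally produced pairs should be normalized with
  `normalize_with_reference` (complete-cloud min/max) for comparability.
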