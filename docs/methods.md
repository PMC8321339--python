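# Methods

## Model

The package detects *frozen frames* — intervals of (near-)absent facial
motion that flank concealed micro-expressions — with a simplified
motion-energy model. A grayscale clip `f(x, y, t)` (luminance, Rec.601
weighting for color input) is filtered with a separable spatio-temporal
pair: an isotropic spatial Gaussian `ρ` and a temporal kernel, either the
low-pass `ϕ` (the LL pair `l = ρ·ϕ`) or its discrete derivative
`ψ = dϕ/dt` (the LH pair `h = ρ·ψ`). The energy of either channel is the
per-frame *population* spatial standard deviation σ_U(t) over the analysis
region; pixels outside the ROI never enter the statistic.

Because convolution commutes with the time-difference operator, the LH
response is exactly the temporal derivative of the LL response. A frozen
interval therefore forces σ_G = 0 and a critical point of σ_F. Which
critical points are *minima* depends on image content: temporal averaging
of a moving pattern can only lower spatial variance, so pure geometric
motion would make frozen intervals maxima of σ_F. In face video the
dominant effect runs the other way — a deliberately concealed pose is the
relaxed, low-contrast state, while expressions add local contrast — and
frozen poses appear as minima of σ_F. The synthetic generator encodes
exactly this mechanism (see below), and the package's duality checks use
clips where the relationship is exact.

### Duality test family

The σ_F-minima / σ_G-zeros correspondence is verified numerically on
single-mode clips `f = B(x,y) + A(t)·P(x,y)` with smooth random `B`, `P`
and a smooth positive envelope `A`. For these, σ_F² is a quadratic in the
ϕ-filtered envelope and σ_G = |dĀ/dt|·σ_P, so every strict local minimum
of σ_F sits on a zero of σ_G. The envelope's band limit is kept far below
the frame rate (a handful of extrema over 200 frames) so that the sampled
σ_G at the crossing is genuinely near zero; the test asserts each σ_F
minimum has, within ±1 frame, a σ_G value below the clip's 10th
percentile. The check uses the Gaussian ϕ/ψ pair (smooth derivative);
production runs default to the box ϕ.

## Pipeline and parameters

1. **Scene partition** — a cut is declared between consecutive frames whose
   mean absolute luminance difference exceeds `cut_threshold` (default 0.1,
   normalized by the 255 range); an explicit cut list overrides the
   detector. The target footage is single-scene, so the detector only
   needs to be safe.
2. **ROI** — user-supplied rectangle or the full frame; no face detector is
   bundled.
3. **Filtering** — `rho_std` defaults to 9 px (about one degree of visual
   angle on full-resolution face video), truncated at 3 standard
   deviations (<0.3% mass loss) and renormalized. The temporal length
   follows the frame rate: `max(2, round(fps/25))` frames — 2 at 25 Hz, 8
   at 200 Hz — reflecting the ~13 images/s throughput of preattentive
   vision; default kind is the box (moving average). Boundary handling is
   reflect padding on all axes: the clip ends otherwise produce spurious
   σ extrema that would pollute the minima list.
4. **Minima** — interior local minima of σ_F; a run of exactly equal
   values bounded by strictly larger neighbors counts once, at its first
   frame, so an exactly frozen plateau yields one representative. A
   constant trace has no interior minima at all.
5. **Instability removal** — maximal chains of *consecutive* minima, each
   within `d` frames and `τ·(max σ_F − min σ_F)` of its predecessor, are
   replaced by their rounded midpoint (σ taken from the trace there).
   Defaults: `τ = 0.1`, `d = round(N/4)`. Merging is iterated to a fixed
   point, making it idempotent and leaving no consecutive survivor pair
   that still satisfies both conditions.
6. **Selection** — the `K` merged minima of smallest σ_F (ties to the
   earlier frame); `K = 3` for 25 Hz workflows, 5 for 200 Hz.
7. **GOF windows** — `[t − h_b, t + h_a − 1]` per selected minimum, with
   `h_b = h_a = 5` at standard rates and 16 at high-speed rates. Two
   bookkeeping conventions coexist deliberately: *extraction* windows are
   clipped and may overlap, while the *retained-frame percentage* counts
   `(h_b + h_a)` frames per minimum without clipping or union — the
   convention under which the published per-clip percentages were
   computed. Published minima are sometimes numbered in the source video
   rather than the cut, so out-of-clip minima still count for bookkeeping
   and their extraction windows collapse to the clip edge. Percentages are
   rounded half-up; the published rows mix truncation and rounding, so
   exact-match tests use only rows where both conventions agree.

### Evaluation

`N = round(0.32·fps)` is the maximal expected ME length (64 at 200 Hz, 8 at
25 Hz). A detection is *correct* when strictly within `N/2` frames of the
annotated onset or offset. The K-sweep reports the percentage of sequences
(two decimals) with a correct detection among the K smallest-σ minima. The
frame-level ROC grows K from 0, predicting the union of size-N windows
centered on the K best minima (`[t − ⌊N/2⌋, t + ⌊N/2⌋ − 1]` for even N,
clipped and unioned so frames are never double-counted), pools TP/FP/TN/FN
over sequences, anchors the curve at (0,0) and (1,1), and integrates by
trapezoid. Against *annotated event intervals* the positive class is the
closed [onset, offset] span; clips with several planted events may supply
explicit interval lists.

## Synthetic data

`generate_sequence` renders a static background with a mild luminance
gradient plus a face-surrogate blob (radius ~18 px, contrast ~70) carrying
a fixed smooth interior texture. Three ingredients emulate concealment
phenomenology:

* **Plateaus** (frozen poses): the pose is held bit-identically before
  noise, and the blob's overall contrast relaxes by 8%, ramping over 3
  frames just *outside* the plateau so plateau frames stay identical. The
  relaxation encodes the low-contrast concealed pose that makes frozen
  frames σ_F minima in real footage.
* **Bursts** (ME surrogates): a smoothly windowed episode of sub-pixel
  translation (bilinear resampling, 0.5–1 px) plus a localized
  contrast-raising deformation patch (a crease/dimple surrogate,
  amplitude 15–25 luminance units).
* **Nuisances**: per-frame Gaussian noise (redrawn inside plateaus in the
  default realistic mode; suppressed there in `exact_freeze` mode, which
  makes plateau frames bit-identical) and a spatially constant luminance
  drift, which the spatial-std statistic provably ignores. Frames stay
  floating-point; clamping to [0, 255] happens only when writing images.

`make_benchmark` draws 25-fps clips of 100–150 frames with one annotated
burst (30% of clips carry a second, recorded in the ground truth), each
flanked by a frozen plateau before (p=0.2), after (p=0.3) or on both sides
(p=0.5) — concealment most often brackets or follows the event. Plateaus
sit directly against the burst boundary and last 3–4 frames so every
frozen frame lies within the N/2 correctness radius; bursts last 3–5
frames. At 200 fps all temporal scales grow proportionally. The benchmark
pipeline uses `rho_std = 3` — the spatial scale is proportional to the
64×64 synthetic face, whereas the production default of 9 presumes
full-resolution face crops.

**Benchmark scoring.** Recovery is the fraction of clips with a selected
minimum strictly within N/2 of a planted burst boundary. The frame-level
AUC is computed against the generator's per-frame *stillness* flag — the
natural ground truth for a frozen-frame detector. (Scored instead against
the annotated burst intervals the AUC is geometrically capped near 0.75:
windows centered on frozen poses cannot reach the interior of a burst
flanked on one side only; the package reports both numbers.)

**What the generator does not emulate:** photorealistic faces, FACS action
units, head rotation or camera motion, compression artifacts, interlacing,
illumination flicker. Passing the benchmark shows the energy statistic,
minima analysis and selection logic behave as designed under controlled
contrast/motion/noise conditions; it does not certify performance on real
footage, where concealment is approximate and registration errors add
energy.

## Numerical choices

* ψ is the central difference of the zero-extended ϕ
  (`ψ_i = (ϕ_{i+1} − ϕ_{i−1})/2`); for symmetric kernels (box, Gaussian)
  the taps telescope and ψ sums to zero exactly, and for a well-truncated
  Gaussian ϕ it samples `−t/s²·g(t)` to second order. For asymmetric ϕ
  the residual DC gain is `(ϕ_last − ϕ_first)/2`.
* The classic biphasic temporal kernel uses the exponential form
  `(kt)^n e^{−kt} [1/n! − (kt)²/(n+2)!]` with defaults `n = 3`, `k = 1`
  (the fast channel of the original model), sampled at integer lags and
  mean-subtracted; its raw response changes sign once, at
  `kt = sqrt((n+2)!/n!)`.
* Even-length temporal kernels carry an unavoidable half-frame phase; all
  correctness radii are ≥ 2 frames, so this never flips a decision.
* Percentage and midpoint rounding is half-up throughout.
* All generator entry points are seeded; identical configuration and input
  give byte-identical reports.

## Known limitations

* Step counts assume single-face, single-scene footage; the scene-cut
  detector is deliberately conservative.
* The method cannot tell whether a frozen pose precedes or follows the
  expression, hence symmetric GOF windows.
* Reproducing the published dataset-level results requires the CASME II
  and MEVIEW videos; the repository ships the evaluation protocol and the
  published per-clip reference detections, and its CI-scale evidence comes
  from the property suite and the synthetic benchmark.
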