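# Methods

This note documents the measurement models implemented in `scolioscreen`,
the conventions and numerical choices behind them, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Conventions

All images are 8-bit grayscale in the raster frame: origin top-left, x
rightward, y downward, 0-based pixels.  "Higher on the back" means smaller
y.  Angles are reported in degrees.  The seven landmarks of a standing
photo are five spine points ordered cranio-caudally (`spine0` topmost …
`spine4` bottommost) and the two scapular prominences; keypoint detection
itself is out of scope — any detector emitting the documented JSON/CSV
schema can feed the pipeline.

## Spine curve and curvature type

The five spine points are fitted with a degree-4 polynomial by least
squares.  Because photographed spines are near-vertical, the fit treats the
cranio-caudal coordinate t (the pixel y) as the independent variable and
lateral position d (the pixel x) as the dependent one; the landmarks'
strict vertical ordering then guarantees distinct abscissae, and with
exactly five points the least-squares solution interpolates.  Numerically
the system is solved on the normalised coordinate u = (t − t_min)/L ∈
[0, 1] (`numpy.linalg.lstsq` on the 5×5 Vandermonde matrix); at pixel
scales a raw-t Vandermonde would be catastrophically ill-conditioned.
Derivatives are evaluated analytically from the fitted coefficients with
the 1/L chain-rule factor per order.

Apexes ("tangent points") are detected on a dense grid of `n_samples`
(default 200) evaluation points.  A window of `round(n_samples/10)` samples
slides in steps of 2; inside each window a sample where the analytic slope
changes sign is flagged.  Slopes with |d'| ≤ 1e-8 are treated as zero so a
numerically straight spine produces no candidates.  A flagged sample is
retained only when its curvature |d''|/(1+d'²)^{3/2} exceeds the median
curvature of the non-flagged samples, and retained flags closer than one
window width merge into the highest-curvature one (lowest t on ties).  Two
geometric-consistency rules follow:

* a sign change at the very first or last grid sample is discarded — its
  extremum lies at or beyond the spine end and cannot anchor a curve
  segment;
* two consecutive retained apexes with the *same* change direction are
  impossible for real adjacent apexes (a minimum must separate two
  maxima), so only the higher-curvature one is kept.

The apex count maps to the curvature type: 1 = C, 2 = S, >2 = multi.  A
curve with no apex (straight spine) has no class of its own in the
clinical taxonomy; it is labeled C with a `degenerate` flag, and grading
treats the whole domain as one segment, which yields 0° on an exactly
straight spine.  Ties between equal-curvature flags resolve to the lowest
t; this is a convention, not a claim about the data.

Apex detection is invariant to uniform rescaling of both axes (slopes are
dimensionless and the curvature comparison is homogeneous) and equivariant
under lateral mirroring (locations fixed, directions swapped).

## Photographic Cobb angle

For a C curve the domain splits at the apex; in each part the grid point
of maximum |d'| plays the role of the most-tilted vertebral endplate, and
the angle is |atan m_upper − atan m_lower|.  The difference-of-inclinations
form is used deliberately instead of the acute-angle formula with
1 + m₁m₂ in the denominator: it has no undefined case at m₁m₂ = −1 and
matches the clinical convention of summing endplate inclinations.  S- and
multi-curves are first split at their inflection points — zero crossings
of the analytic d'' on the dense grid, refined by bisection to 10⁻³ of the
domain — and each convex/concave part is measured by the C rule (split at
the apex it contains, or its midpoint if it has none) and summed.  Segment
sub-intervals are re-sampled with their endpoints included exactly, so the
maximum-|slope| search does not lose the domain ends to grid resolution.

The angle is invariant to rigid translation, uniform scaling and lateral
mirroring of the keypoints, and on the synthetic C family it increases
strictly with deviation amplitude.

## Scapular-spine triangle and severity grading

The triangle has vertices at the two scapular landmarks and at `spine4`,
the lowest spine landmark; its two *base angles* (interior angles at the
scapular vertices, law of cosines) differ by an amount that grows with
coronal trunk asymmetry, and |left − right| is the index.  Collinear
vertices are rejected.

Both indices map onto the four severity classes through half-open
intervals: [0,10), [10,20), [20,45), [45,∞) degrees for the Cobb angle —
covering every real angle while keeping "<10" and "≥45" exact — and three
ascending thresholds for the triangle index.  No canonical
triangle-to-class thresholds exist, so they are explicit configuration
with defaults (2°, 5°, 10°).

The fusion rule routes by type: C-type (including degenerate) backs are
graded by the triangle index, which discriminates single lateral shifts
well; S and multi backs by the accumulated Cobb angle, since their
near-symmetric scapular geometry makes the triangle index insensitive.

## Contour extraction

The sagittal pipeline accepts a binary silhouette mask from any segmenter;
Otsu thresholding (optionally preceded by 3×3 median denoising and CLAHE)
is a fallback for high-contrast studio photos only.  Edge operators:

* Roberts — kernels [[1,0],[0,−1]] and [[0,1],[−1,0]], implemented by
  direct array slicing (the 2×2 support is anchored at the output pixel,
  avoiding even-kernel centre ambiguity);
* Prewitt — the standard 3×3 ±1 row/column kernel pair via
  `scipy.ndimage.correlate`;
* LOG — Gaussian smoothing (σ default 1.4, configurable), the 4-neighbour
  Laplacian, and a binary map of zero crossings against the right/lower
  neighbour.

All operators use replicate-edge padding so the edge map retains the input
dimensions and stays column-aligned with the profile.  Magnitudes are
S = √(dx² + dy²).

The 1-D *contour profile* assigns each column the height (pixels above the
image bottom) of its topmost foreground pixel — for edge maps, the topmost
pixel with at least half the maximum strength — so the scapular bulges
become local maxima of a uniformly sampled signal.  Columns without
foreground are invalid: marginal ones are trimmed, interior ones linearly
interpolated before peak detection.

## AMPD and the ATR angle

For a detrended signal x of length N, the local maxima scalogram has
L = ⌈N/2⌉ − 1 rows with window lengths w_k = 2k.  Entry m[k, i] is 0 when
x[i] > x[i−k] and x[i] ≥ x[i+k], and r + α otherwise with r ~ U[0,1) drawn
fresh per entry and α = 1; columns within k of either border are filled
with r + α.  Two deliberate refinements:

* **Leftward tie-break.**  With strict comparisons on both sides an exact
  plateau — impossible on continuous signals, routine on integer-rasterised
  profiles and on perfectly symmetric masks — has *no* local maximum at
  small scales and the peak vanishes.  The weak right-hand comparison keeps
  exactly the leftmost plateau sample.
* **Deterministic operating scale.**  γ_k row sums identify the scale with
  the most surviving maxima, but summing the random entries lets argmin γ
  flip between near-tied scales from one seed to the next, which would make
  the peak set seed-dependent.  λ is therefore chosen as the argmin of the
  per-row count of surviving entries — the deterministic quantity γ_k
  estimates, since E[γ_k] = (α + ½)·count — with the first index winning
  ties.  γ itself is still computed and exposed.

Peaks are the columns of the λ-row truncated scalogram whose sample
standard deviation is ≤ 10⁻¹² (an exact-zero test would be brittle under
floating-point summation); since the random entries are almost surely
distinct, a zero-variance column is an all-zero column, which is why the
result cannot depend on the seed.  With λ = 1 the sample standard
deviation is undefined and the all-zero-column criterion is applied
directly.  Structural properties worth knowing: maxima closer than λ
samples to a border sit under boundary-filled rows and cannot be detected,
and for quasi-periodic signals the method assumes the highest peak
frequency stays below four times the lowest.

`measure_atr` composes the full pipeline: mask → edge map → profile → gap
filling → Gaussian smoothing of the profile (σ = 2 columns, configurable)
→ linear detrend → AMPD → bimodal filter → angle.  The profile smoothing
exists to break the flat plateaus integer rasterisation leaves at bump
tops.  Because a back contour is an aperiodic two-bump signal, the
scalogram scale is capped at N/4 here: scales beyond the prominence
separation only compare the two scapular bumps against each other, and the
minimising scale can land there and suppress the lower bump (scale-limited
scalograms are standard practice when applying this detector to
non-periodic signals).  `ampd_peaks` and `compute_lms` keep the full
uncapped construction by default.

When more than two peaks survive, each is scored by prominence
(`scipy.signal.peak_prominences`) divided by local flatness — the standard
deviation of the heights in a ±N/20 window — and the two highest-scoring
peaks at least N/10 columns apart are retained; both window fractions are
configuration.  Fewer than two admissible peaks raise a bimodal-failure
error: the photo cannot be measured and should be retaken.  The ATR is
atan(|Δheight|/|Δcolumn|) between the retained prominences, with heights
read from the unsmoothed profile; it is invariant to uniform scaling of
both profile axes and to left-right mirroring.

## Evaluation metrics

Accuracy, per-class precision/recall/F1 via one-vs-rest reduction of the
binary TP/FP/FN/TN counts, and Cohen's κ = (p_o − p_e)/(1 − p_e) with
p_e = Σ row·col/total².  A class absent from both rows and columns has
undefined precision/recall; it is flagged and excluded from macro averages
rather than silently zeroed, which would distort them.  The OKS similarity
is the visibility-weighted mean of exp(−d_n²/(2 s² k_n²)); no canonical
scale s or weights k_n exist for back landmarks, so s defaults to the
bounding-box diagonal of the reference points and k_n to 1, both
configurable.  Angle agreement uses the mean relative error
(1/N) Σ |measured − reference|/reference × 100 %.

## Synthetic study conditions

The generators provide the ground truth the private clinical photo sets
cannot:

* **Coronal cases.**  Lateral deviation d(t) = A·L·sin(mπt/L) with m = 1,
  2, 3 interior extrema for C/S/multi and m = 0 for straight; the
  extremum count maps one-to-one onto the clinical taxonomy.  Landmarks at
  t = {0, ¼, ½, ¾, 1}·L on a spine of L = 800 px, amplitudes A on the
  grid 1–15 % of spine length (cohorts default to
  `linspace(0.01, 0.15, n_per_class)`, 100 per class), optional Gaussian
  positional jitter on every coordinate (the noisy study condition is
  sd = 1 % of spine length = 8 px).  The reference Cobb angle applies the
  same segment rule as the measurement path but in closed form on the
  degree-4 interpolant of the noiseless landmarks — exact polynomial roots
  (with negligible leading coefficients trimmed first; a leftover 1e-13
  quartic term otherwise derails the companion-matrix root finder) and
  exact slope maximisation over interval endpoints and critical points —
  so the two routes share no grid, window or detection code.  Note the
  reference is defined on the quartic *interpolant*, not the generating
  sine: a quartic through five S-archetype samples has endpoint slopes
  ~70 % steeper than the sine it interpolates, so a sine-slope reference
  would disagree with any polynomial-based measurement by several degrees
  by construction.
* **Sagittal cases.**  Profile = baseline (140 px) + two Gaussian bumps
  (σ = 45 px) centred 200 px apart around the midline of a 640×400 image;
  apex heights are raised/lowered symmetrically about 90 px so they differ
  by exactly separation·tan(ATR) — the physical picture of trunk rotation
  lifting one scapula and lowering the other.  Bump centres sit ≥ 220 px
  from the image borders, outside the scalogram's border blind zone.  The
  mask fills the area below the profile; noise is Gaussian jitter of each
  column height before rasterisation (the noisy study condition is
  sd = 2 px over true ATR 4–16°, 50 cases).

What the generators deliberately do not emulate: photographic texture,
clothing, hair and lighting; detector-specific landmark error structure
(noise is isotropic Gaussian); asymmetric or multi-lobed scapular
prominences; non-polynomial spine shapes.  Passing tests therefore
establish the geometry and signal-processing layers, not end-to-end
performance on real photographs.

Problem sizes used by the test suite and `scripts/acceptance.py` (1000
random fits, 300-case cohorts, 100 noisy AMPD replicates, 50-case ATR
cohorts) keep the full run in the low minutes on one core.  The AMPD
noise experiment uses 10 periods of 50 samples: at 5 % noise the apex
argmax wanders by roughly 0.06·T samples, so a fixed ±3-sample agreement
tolerance is only commensurate with sampling for short periods; across all
periods the detector's peak set equals the regional-argmax oracle exactly,
which is the sharper statement of its noise behaviour.

## Known limitations

* **Noisy curve-type classification at low amplitude.**  With landmark
  jitter at 1 % of spine length, archetypes below ~3 % amplitude have
  signal-to-noise near 1 and the quartic interpolant genuinely gains or
  loses interior extrema; cohort accuracy lands around 0.86–0.91 depending
  on the seed.  This is close to an information-theoretic ceiling: a
  maximum-likelihood classifier that knows the three generating archetypes
  reaches only 0.96–0.98 on the same cohorts, and raising the
  curvature-retention quantile above the median trades away S/multi recall
  faster than it suppresses false apexes.  A model-free apex count cannot
  close that gap; real deployments should treat low-amplitude calls as
  uncertain.
* **AMPD border blind zone.**  Peaks within λ samples of the signal edge
  are undetectable by construction; profiles should frame the back with
  margins, and the sagittal generator does.
* **Grading thresholds.**  The triangle-index thresholds are screening
  configuration, not clinically validated cut-offs.
* **Five landmarks.**  More than five spine points are accepted by the
  least-squares fit but untested; spline or higher-order models are out of
  scope.
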