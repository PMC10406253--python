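# Methods

## Pipeline model and assumptions

`sozloc` assumes a MELODIC-style ICA decomposition: a 4D NIfTI of
unthresholded spatial z-score maps (one volume per IC) and a
whitespace-delimited T×N mixing matrix of BOLD time courses, index-aligned.
Maps are used as-is; nothing is re-standardized on load.  All spatial
analysis is two-dimensional and slice-wise — clusters, contours, and
overlap statistics are computed per axial slice, matching how clinicians
review IC panels — with voxel-unit distances and 0-based `(x, y, slice)`
indexing.

The classification is a waterfall: an IC exits at the first stage that
claims it.  Noise rules run first; a white-matter-noise IC can be rescued
into the SOZ pool by the temporal-sparsity override; everything surviving
the noise stage is split into RSN vs SOZ.

## Density-based cluster scan

A voxel is a core voxel when strictly more than `v_min` *other* active
voxels lie within Euclidean distance `eps`.  Core voxels within `eps` of
each other share a cluster; a non-core voxel within `eps` of a core voxel
joins the cluster of its nearest core voxel.  Defaults `eps = 1.5`
(8-connectivity) and `v_min = 4` make a 3×3 active block the smallest
structure with a core voxel; both are exposed in `PipelineConfig` since no
canonical values exist for this stage.  Ties (a border voxel equidistant
from cores of different clusters) go to the core voxel with the smallest
`(x, y)` coordinate: the partition is deterministic, and the core set — but
deliberately not the tie-broken border assignment — is invariant under grid
symmetries.

## Contour extraction

The anatomy is read from a cluster-free reference image per slice: the
voxel-wise median across all ICs of the subject (activation clusters are
sparse and component-specific, so the median suppresses them), with any
residual supra-threshold voxels in-painted from a surrounding annulus.
Edges come from 3×3 Sobel kernels combined as the Euclidean norm.  The
edge set is thresholded with Otsu's method by default — a fixed gradient
quantile is available via `grad_quantile`, but a quantile marks a fixed
fraction of pixels as edges regardless of content, which is unstable when
most of the image is weak background gradient — then morphologically
closed (disk radius 2) and each closed structure traced to a polygon.

Whether a closed edge band is a solid region or a true annulus cannot be
decided from geometry alone (a solid bright blob also produces a ring of
edges), so the call is intensity-based: the structure is annular when its
enclosed interior resembles the surrounding background more than the band
itself.  A one-pixel erosion strips the gradient halo the Sobel operator
adds on either side of a step.  The periphery is the region whose filled
interior contains all others; the remaining enclosed regions are binned by
mean reference intensity into three quantile classes — the top class is
white matter, the bottom class holds vessel/CSF candidates.  Dark regions
enclosed by a *solid* white-matter region are discarded as CSF; dark
regions merely encircled by an annular white-matter band sit in deep
tissue and remain vessel candidates, which must additionally lie in the
basal central box (the central third of the periphery bounding box).

## Noise rules

Per slice, overlap percentages are normalized by the largest cluster's
size (not the mask's): `|cluster ∩ mask| / |cluster| × 100`.  The boundary
band is the 2-voxel rim inside the periphery; the crescent score is the
fraction of largest-cluster voxels inside that band.  Rules fire in a
fixed order — outside-brain fraction > 0.5, white-matter overlap > 50 %,
vessel overlap > 50 %, crescent score > 0.5, and (> 20 clusters with the
largest < 10 voxels) — and the subtype records the first firing rule.  The
rule structure is fixed by the clinical noise markers; the numeric
thresholds have no published values and are all configurable.  An IC is
noise when a strict majority of its `top_k = 10` largest-cluster slices
(fewer when the IC has fewer informative slices; slices without clusters
never vote) are noise slices; the IC subtype is the modal slice subtype
with ties resolved in rule order.  Two markers are approximations: sudden
BOLD oscillation changes are not scored by default, and "area of signal
loss" is subsumed by the outside-brain test.

## Temporal sparsity features

Time courses are cut into non-overlapping 256-sample windows (a short
signal is zero-padded into one window; a trailing remainder is dropped).
Each window gets two sparsity scores, aggregated across windows by the
maximum — a single seizure-bearing window should dominate; `mean` is
available via `window_agg`:

* **Wavelet sparsity** — a 4-level undecimated (à-trous) stationary
  wavelet transform.  True activelets are exponential-spline wavelets
  tuned to the hemodynamic response; here the basis is a configurable
  spline-family wavelet (`sym4` by default), and the contracted behavior
  — linearity, perfect reconstruction (relative L2 ≤ 1e-6), sparsity on
  burst-like signals — is what the tests pin down, not a specific filter
  bank.  The Gini index is computed on the concatenated detail bands; the
  approximation band carries baseline, not transients.
* **Sine-dictionary matching pursuit** — unit-norm sine and cosine atoms
  on the window's frequency grid (spacing `1/(window_len · TR)`)
  restricted to 0.01–0.1 Hz; greedy pursuit stops at 10 atoms or when the
  residual falls below 1 % of the initial energy; residual energy is
  asserted non-increasing at every iteration.  The Gini index is taken
  over the full coefficient vector, zeros included.

The Gini index uses ascending sorted magnitudes `c(1)..c(N)` with L1 norm
S: `G = 1 − 2·Σ (c(k)/S)·((N−k+0.5)/N)`; it is scale-invariant, 0 for
constant magnitudes, `(N−1)/N` for a one-hot vector, and defined as 0 for
an all-zero input.  The white-matter-noise override reclassifies an IC as
SOZ when the activelet Gini exceeds 0.75.  The sine-pursuit override
threshold defaults to 1.72 as printed in the clinical criteria even
though the Gini index cannot exceed 1 — the value is likely a typo for
0.72, but it is not silently corrected; set
`gini_sine_threshold: 0.72` to activate that reading.

The dominant frequency is the periodogram argmax of the mean-removed full
signal at or above the band's low edge; a signal with no in-band power
reports the low edge itself.

## RSN vs SOZ stage

Six markers per surviving IC: bullseye score (fraction of the largest
high-threshold cluster, at `2·z_threshold`, enclosed by the largest
low-threshold cluster on that slice, halved when the centroids are more
than 3 voxels apart), gray-matter fraction (periphery minus white matter
minus vessels serves as the gray-matter surrogate; no tissue segmentation
input exists), best Dice overlap with the RSN templates, dominant
frequency, and the two Gini indices.

The likelihood model is this package's concretization — the clinical
criteria fix the markers but not the classifier.  Features are
standardized within subject and fit with a two-component
diagonal-covariance Gaussian mixture (EM, k-means++ initialization, 50
restarts, tolerance 1e-6, seeded); the component whose mean is higher on
the majority of (dominant frequency, activelet Gini, bullseye score) is
SOZ, and ICs are assigned by maximum posterior.  Clustering is
per-subject: the method is meant to run without any training cohort.
Degenerate inputs fall back deterministically: a single IC is scored by
the explicit rule (SOZ iff dominant frequency > 0.073 Hz, template
overlap < 0.3, and bullseye ≥ 0.5 or activelet Gini > 0.75); identical
feature vectors conservatively all map to RSN; an EM failure falls back
to the rule with a warning.  `classifier: rule` in the configuration
replaces the mixture with the rule everywhere.

The shipped RSN templates are schematic mirrored bilateral masks for
eight canonical networks (sensorimotor, language, parietal, frontal,
temporal, visual, default-mode, deep gray) placed on the target grid; no
specific atlas is assumed, and real atlas masks on the same grid can be
supplied per run.

## Synthetic phantom

The generator emulates the acquisition geometry the pipeline targets: an
80×80×46 grid (3 mm in-plane, TR = 2 s) and 595 usable volumes, ~50 ICs
per subject with a 60/30/10 noise/RSN/SOZ mix mirroring the strong
clinical imbalance (noise subtypes uniform).  Anatomy is an elliptical
brain with a smooth slice-radius profile, two bright bilateral
white-matter lobes, and two dark basal vessel spots; structures are drawn
only on slices with a large enough brain radius for them to remain
separated (20 of 46 slices at defaults).  Each IC map is anatomy +
class-specific activation + Gaussian noise with σ = 1/snr (snr = 5 by
default, i.e. noise at 20 % of the tissue contrast).

Class signatures: boundary noise is a half-ring crescent in the outer 6 %
of the brain radius; white-matter/vessel noise are Gaussian blobs on
those structures; small-cluster noise scatters ≥ 26 separated 3×3
speckles per slice in gray matter.  RSN ICs are mirrored bilateral
Gaussian blobs at one of the eight template sites with a smooth
0.015–0.04 Hz time course; SOZ ICs are single concentric Gaussian blobs
at off-template gray-matter sites with time courses of 2–4 sparse bursts
(Gaussian envelope, σ = 6 s) on a 0.085–0.098 Hz carrier, placed inside
the analyzed windows.  Burst noise is kept low (σ = 0.008) so the
activelet Gini of every generated SOZ course clears the 0.75 sparsity
marker — the generator's self-consistency contract, verified in the test
suite across seeds.

What the phantom does **not** emulate: hemodynamic forward physics,
spatial autocorrelation of scanner noise, head motion, partial-volume
effects, overlapping or ambiguous components, and inter-subject
anatomical variability.  Recovery rates on the phantom therefore
demonstrate that each rule detects the marker it encodes under clean
conditions — near-ceiling performance here does not predict clinical
accuracy on real decompositions, where markers are weaker and mixed.

## Evaluation

Objective 1 (noise removal) counts RSN-or-SOZ as positive; objective 2
(SOZ identification) counts SOZ as positive, and a true positive requires
both rater and pipeline to say SOZ — the definition consistent with the
false-negative cell (an alternative literal reading that counts agreement
on SOZ-or-RSN as positive is available behind `literal_tp`).  Zero
denominators yield explicit undefined markers, never NaN.  Per-subject
metric sets aggregate as unweighted means with sample standard
deviations, excluding (and counting) undefined entries.

## Problem sizes and numerics

The acceptance script and end-to-end tests use 10 subjects × 50 ICs
(500 ICs, ~3 s per subject on one core), 20 structured slices for contour
recovery, 500 random masks against the brute-force clustering oracle, and
100 seeds for the mixture-model simulation.  Reconstruction tolerance for
the wavelet transform is 1e-6 relative L2; EM tolerance 1e-6; Gini values
are clamped against ±1e-16 rounding.  Uncompressed NIfTI output keeps
same-seed runs byte-identical.

## Known limitations

* Contour extraction presumes the IC background carries visible anatomy;
  on aggressively masked or variance-normalized maps the reference image
  may be featureless, leaving only the outside-brain and small-cluster
  noise rules effective.
* The noise thresholds (50 % overlaps, crescent 0.5, 20/10 small-cluster
  rule) are defaults, not fitted values; real data may need tuning.
* The two-component mixture assumes at least one SOZ-like and one
  RSN-like group among the survivors; a subject with no SOZ ICs relies on
  the component-labeling vote degrading gracefully (the "SOZ" component
  then captures the more SOZ-like RSNs) — the rule classifier is the
  safer choice when SOZ prevalence may be zero.
* Slice-wise 2D clustering ignores through-plane contiguity.
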