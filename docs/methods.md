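# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `azpunct`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Image and scene model

Scenes live on a regular pixel grid (default 20 nm pixels, the STED
acquisition setting this pipeline targets; tests use 256×256 px fields,
~5.1×5.1 µm, rather than the instrument's full 19.4×19.4 µm field, purely
as a desk-scale choice — all geometry is expressed in nm and none of the
algorithms depend on field size). Coordinates are continuous, origin at
the top-left corner, with the center of pixel (row r, col c) at
((c+0.5)·px, (r+0.5)·px).

Each punctum is an isotropic 2D Gaussian of peak amplitude A and width
FWHM = 2√(2 ln 2)·σ, evaluated at pixel centers over a uniform
background. The Gaussian is the conventional approximation of an
effective STED point-spread function; the rendered FWHM is the *observed*
punctum width (true structure ⊗ PSF), not a deconvolved object size.
Per-protein width distributions default to the measured adult-NMJ values
(mean ± SD, nm): VGCC 103.4 ± 8.5, Bassoon 126.4 ± 11.8, Piccolo
107.6 ± 9.7, truncated at ±3 SD (and ≥ 40 nm).

Motifs place puncta in the arrangements seen at active zones:

- **sandwich** — two flank puncta (Piccolo channel) separated by 100 nm
  (default) with one center punctum (Bassoon channel) at their midpoint;
- **tandem_sandwich** — three flanks at 100 nm spacing with two centers
  interleaved (P-B-P-B-P);
- **coloc_pair** — one punctum per channel at the same position (the
  Bassoon/VGCC arrangement);
- **solitary** — a single punctum in one channel.

Every coordinate receives Gaussian jitter (default SD 5 nm). Motif
centers are drawn uniformly from the mask interior (at least
edge-margin + motif reach from the mask boundary, so ground truth never
straddles the analysis region) with a minimum inter-motif spacing
(default 400 nm) enforced by rejection sampling; an infeasible request
raises a placement error naming the constraint. Amplitudes are drawn
per *motif* (default uniform 120–250 counts) with 10% per-punctum
scatter: puncta of one active zone share similar protein content, and a
flank pair with wildly different brightness is not a realistic motif.
Pipeline-generated studies draw the motif count of each synapse from a
Poisson distribution around the configured mean, since real synapses
vary in content; `count_distribution="fixed"` disables this.

Noise follows the photon-counting model: pixel ~ Poisson(clean) +
N(0, σ_read), clipped at zero, with σ_read = 1 count and background
5 counts by default. The default amplitude range then gives peak SNR
A/√(A+bg+σ²) ≈ 10–15. No SNR was reported for the original acquisitions;
these values are chosen once as a realistic photon-limited regime and are
configuration fields, not constants.

## Thresholding

`auto_threshold_light` implements the classic bright-object histogram
rule. The masked pixel histogram uses 256 equal-width bins over
[min, max] (per-gray-level bins for integer images whose range fits).
The histogram is smoothed with a 3-bin moving average before peak
finding: without it, a single-bin sampling fluctuation on the flank of
the background peak can masquerade as the object peak and collapse the
threshold into the background. The pure trough search
(`trough_threshold`) then takes:

- background peak = modal bin (ties → dimmest);
- object peak = highest-count strict local maximum brighter than the
  background peak (plateaus count once, at their dimmest bin; the first
  and last bin see a virtual zero-count neighbour; ties → dimmest);
- trough = minimum-count bin strictly between the peaks (ties →
  dimmest); when the peaks are adjacent the trough degenerates to the
  object-peak bin;
- threshold = the trough bin's upper gray edge (lower edge in the
  degenerate case). Pixels strictly above it are objects.

A constant masked image, or one with no maximum brighter than the
background, raises `NoObjectPeakError`. The pipeline additionally guards
the degenerate *empty-channel* case (e.g. an aged synapse that has lost
all Bassoon): when the chosen threshold would mark more than 25% of the
masked pixels as objects the histogram was noise-only, and the channel
is scored as zero puncta rather than as thousands of noise fragments.

## Segmentation

Objects are 8-connected components of above-threshold pixels (diagonal
contact at punctum scale should not split a blob), kept when their
intensity-weighted centroid lies in the mask and their area is at least
`min_size_px = 4` (0.0016 µm² at 20 nm pixels — rejects single-pixel
noise). Components touching the image border are flagged and excluded
from FWHM and per-punctum intensity statistics but retained in counts
and density, which are area-normalized.

A global threshold cannot separate two puncta whose connecting ridge
stays above it — and a 100 nm flank pair of ~110 nm-wide puncta has
essentially *no* intensity dip at all. The pipeline therefore segments
on deconvolved images (below) with `split_touching` enabled: intensity
local maxima at least 2 px apart that reach ≥ 25% of their component's
maximum become markers for a watershed that divides the component
between peaks. The 25% floor keeps noise spikes and dim shoulders from
oversplitting (after deconvolution, restored peak heights of equal-flux
puncta differ by the square of their width ratio, so a dim wide flank
next to a narrow bright one can legitimately sit near 30% of the
component maximum).

## Deconvolution

Richardson–Lucy with an isotropic Gaussian PSF (default FWHM 100 nm),
implemented as multiplicative EM updates using exact Gaussian
convolutions with reflective boundaries — hence nonnegative output and
total flux conserved (verified to within 1%). This stands in for the
commercial CMLE deconvolution used on the original images, whose
parameters are out of scope; what is retained is the *property* that
quantification from raw and deconvolved images agrees (rank correlation
≥ 0.9 in the validation protocol). The pipeline default of 80 iterations
was set by the flank-splitting requirement: around 15 iterations the
100 nm pair develops a usable dip, and by 80 iterations splitting plus
detection recovers ≳ 95% of sandwiches with no false discoveries in the
seeded validation scenes; beyond ~100 iterations nothing further is
gained and noise spikes grow. Iterations = 0 returns the input.

## Per-punctum metrics

**FWHM.** A line through the punctum's brightest pixel, oriented along
its intensity-weighted principal axis (the original measurements drew
this line by hand; the principal axis is a reproducible convention that
reduces to an arbitrary axis for isotropic puncta), sampled by bilinear
interpolation at half-pixel steps over 3× the punctum extent (minimum
600 nm) so both ends reach background. Background = mean of the outer
20% of samples at each end. Half height = background + (peak −
background)/2; each crossing is linearly interpolated between the
bracketing samples nearest the peak; the FWHM is the distance between
the two crossings. A profile that never falls to half height on one side
(truncated punctum) raises `NoCrossing` and the punctum is skipped.

On shot-noise-limited images the raw profile maximum rides on upward
noise excursions, which biases the half height up and the measured FWHM
down by ~7% at peak SNR 10. `measure_puncta_fwhm` therefore smooths the
sampled profile with a 3-sample (one-pixel) boxcar by default; this
restores the noisy-mean bias to < 1% at the cost of ~1% broadening for a
100 nm punctum, and should be disabled (`smooth_window=1`) for
noise-free data, as the validation protocols do for the noiseless bias
measurement. In full-pipeline runs the FWHM is measured on the *raw*
image using the deconvolved-image labels, so reported sizes are optical
widths rather than deconvolution residuals.

**Intensities and density.** Intensity per area = Σ intensity over
thresholded punctum pixels inside the mask / mask area (µm²); whether
the original quantification summed only thresholded pixels or the whole
mask is not documented, so `over="mask"` is available and
`over="puncta"` is the default, consistent with object-based
quantification. Intensity per punctum = mean over the punctum's labeled
pixels. Density = punctum count / mask area. Mask area = true-pixel
count × (px/1000)².

**Hierarchical sampling.** Seeded uniform sampling without replacement
of 10 eligible (non-border, FWHM-measurable) puncta per synapse mirrors
the 10 × 5 × 5 = 250-puncta design; synapses with fewer eligible puncta
contribute all of them with a warning.

## Colocalization

Association across channels is automated as: edge iff centroid distance
≤ radius (default 150 nm ≈ punctum FWHM plus localization slack) **or**
≥ 1 px overlap of the labeled regions. The manual scoring being
reproduced counted side-by-side, non-overlapping partners ~100 nm apart,
so a pure overlap criterion would miss exactly the arrangement of
interest; the radius is a stated convention and a configurable
parameter. Pixel-intensity correlation coefficients are deliberately not
implemented — categorical, object-based scoring is the method.

Bassoon–VGCC scheme: each Bassoon punctum is scored by its VGCC degree
(1, 2, ≥3, or 0 → B only); VGCC puncta of degree 0 add V only. The
Bassoon-side categories therefore sum to the Bassoon count.

Piccolo–Bassoon scheme: a Piccolo punctum associated with exactly two
Bassoon puncta scores one `1P:2B` (a flank shared between adjacent
sandwiches, as in tandem motifs) and is removed from those Bassoon
puncta's degrees before they are binned (1, 2, ≥3, 0 Piccolo per
Bassoon); unpaired Piccolo are P only. The precedence rule is one
consistent reading of an exhaustive six-category scheme and prevents
double counting; it is a design decision, not a documented fact about
the original manual scoring.

Sandwich detection: for each Bassoon with ≥ 2 associated Piccolo, all
Piccolo pairs with flank separation in [60, 200] nm (bracketing the
~100 nm motif with room for jitter) and flanking angle ≥ 120° are
candidates; candidates are accepted greedily by descending angle with
each Bassoon and each Piccolo used at most once, so the most collinear
motifs win shared flanks deterministically.

## Statistics

Group summaries use the sample SD (n−1) and SEM = SD/√n; FWHM is
conventionally reported as mean ± SD, other measures as mean ± SEM.
Group comparisons use Student's pooled-variance two-tailed unpaired
t-test (df = n₁+n₂−2), the default of the statistics package used for
the original analysis; Welch's correction is available as a flag. The
unit of analysis mirrors the original design — per-synapse values for
density and intensity-per-area, pooled per-punctum values for intensity
and FWHM — without hierarchical correction; that is a fidelity choice,
not a statistical endorsement.

The type-I-error protocol simulates the pipeline's unit of analysis
directly: per-synapse density = Poisson(30) count over a
normally-varying synapse area (6 ± 1.5 µm², floored at 1), both groups
from the same distribution, 25 synapses per group, 1000 replicates. The
imaging stages cannot change the null calibration of a t-test applied to
exchangeable per-synapse values, so this image-free surrogate is what
the full 1000-fold image simulation would measure, at a feasible cost.

## Validation protocols and problem sizes

`azpunct.benchmarks` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs, per seed: 100 randomized bimodal
histograms against an independent exhaustive trough scan; FWHM bias at
widths {60, 80, 100, 120, 160, 240} nm (12 noiseless subpixel placements
each) plus 250 noisy puncta at peak SNR ≈ 10; 50 counting scenes of 12
isolated puncta (≥ 350 nm spacing); 50 mixed-motif scenes (5 sandwiches,
3 colocalized pairs, 3 + 3 solitary each) for category fidelity and
sandwich recall/FDR; the textbook pooled-t example and 1000 null group
comparisons; 30 scene pairs quantified raw versus 10-iteration
deconvolved (scene brightness log-uniform over ~6×, as staining
intensity varies between synapses — a rank correlation over
near-identical brightnesses would measure nothing); two repeated
pipeline runs for byte-identical outputs; and a 5-animal × 5-synapse
adult-versus-aged study in which the aged group has ~⅓ fewer
Bassoon-containing motifs at matched Piccolo content.

## What passing these protocols does and does not show

The simulator produces the geometry the analysis is designed for —
Gaussian puncta at known positions, widths and motif memberships, with
stationary background and uncorrelated photon noise. It does not emulate
antibody-size displacement, labeling stochasticity, depth-dependent
aberrations, sample drift between channels, structured background
(out-of-focus nerve terminal), or non-Gaussian STED side lobes.
Agreement with ground truth here therefore validates the *algorithms*
(thresholding, splitting, measurement, categorization, statistics), not
the biological accuracy of any particular acquisition. Absolute
densities in the demonstration study are lower than at a real NMJ
because scene content is desk-scale; all comparisons are internal.

## Known limitations

- Flank pairs closer than ~70 nm or with strongly mismatched widths can
  survive deconvolution unsplit; sandwich recall is ~97%, not 100%.
- FWHM of a flank punctum measured on the raw image includes its
  partner's tail; isolated-punctum FWHM is unbiased (< 1%), flank FWHM
  is systematically high. Sampling is random, not "representative" in
  the manual sense.
- The trough threshold on deconvolved histograms is noisier than on raw
  ones; absolute deconvolved intensities are comparable only within a
  batch processed identically (the rank-correlation protocol makes this
  precise).
- The 1P:2B precedence rule and the 150 nm association radius are
  conventions; both are parameters.
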