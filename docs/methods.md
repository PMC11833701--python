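# Methods

This note documents the statistical models, numerical choices and defaults
behind `meioquant`, and what the synthetic-data validation does and does
not demonstrate.

## Interference: the gamma shape factor

Consecutive inter-focus (cytological, µm) or inter-CO (genomic, bp)
distances are normalized by their chromosome's physical length and pooled
across chromosomes and nuclei of a genotype.  A two-parameter gamma
distribution is fitted by maximum likelihood.  The scale is profiled out
analytically (θ̂ = x̄/k), leaving a strictly concave one-dimensional
profile log-likelihood in the shape k whose score,

    n · [ mean(log x) − log x̄ + log k − ψ(k) ],

is monotone decreasing; the MLE is found by bracketed root finding
(`brentq`, xtol 1e-12) on (1e-8, `shape_cap`].  The standard error of the
shape is (−ℓ″)^(−1/2) with ℓ″ = n(1/k − ψ′(k)) — the observed profile
information, which equals the shape entry of the inverse observed Fisher
information of the joint fit.  If the score is still positive at
`shape_cap` (default 1000, far above any biologically reported value), the
fit is flagged `capped` with no standard error; this includes the
zero-variance limit, where the gamma MLE diverges.

Interpretation: shape 1 is the memoryless (exponential-gap) case, i.e. no
interference; larger shapes mean more regular spacing.  Normalization is
per chromosome by default for both cytological and genomic data; the
pooled fit treats all gaps as exchangeable (no per-nucleus weighting).

## Crossover mapping in backcross F2 embryos

* **Gliding ratio.** r = Σbristol / (Σbristol + Σhawaiian) over a centered
  window of 100 five-kb windows, truncated (not padded) at chromosome
  ends; a span with zero informative reads is uninformative.  The
  ratio-of-sums form is robust to empty windows.
* **Genotype.** r > 0.9 homozygous Bristol, r < 0.25 homozygous Hawaiian,
  in between (boundaries included) heterozygous.
* **Crossover calls.** Genotype classes are run-length encoded.  Short
  (< 15 kb) uninformative runs are absorbed into a same-class flank,
  bridged as the transition gap when the flanks differ, and treated as
  barriers when ≥ 15 kb.  A boundary between runs of different class is
  retained iff both runs span ≥ 15 kb and the informative reads summed
  over the two runs exceed 1500 (strict).  The read support is accounted
  over the full flanking runs — the most conservative reading of a
  transition-level support threshold.  The reported interval is
  [end of last left-run window, start of first right-run window]; its
  midpoint is the point estimate.  Smoothing displaces a true breakpoint
  by at most half the span (250 kb at the defaults), which sets the
  localization tolerance used in validation.
* **Ploidy.** Copy number per 50-kb window is 2·depth/baseline, where the
  baseline is the median window depth over autosomes (robust to one
  aneuploid chromosome) or supplied explicitly.  The chromosome mean is
  classified haploid (< 1.45), diploid (1.45–2.5, closed) or triploid
  (> 2.5).  Only diploid chromosomes enter CO calling; others are listed
  as skipped.

Coordinates are 0-based half-open throughout.

## Image quantification

* **Background** is the mean intensity of voxels whose in-plane (per
  z-slice, 2D) distance to the nearest labelled voxel lies in (10, 50]
  pixels.  In-plane distance is the appropriate metric for strongly
  z-anisotropic stacks; slices without objects contribute nothing.
* **Axis mask**: nucleus voxels whose axis-channel intensity strictly
  exceeds the mean within that nucleus (mean threshold); a constant
  nucleus yields an empty mask.
* **Totals** are background-corrected by per-voxel subtraction before
  summing, floored at zero; the axis/nucleus ratio divides the two totals
  of the designated ratio channel.  The "intensity ratio" used by the
  nucleus filter is this axis/nucleus ratio.
* **Morphology**: volume = voxel count × voxel volume; sphericity =
  π^(1/3)(6V)^(2/3)/A with A the marching-cubes mesh surface area (the
  mask is padded by one voxel so the mesh closes).  Filters: 10 < V < 60
  µm³, sphericity > 0.4, 0.3 ≤ ratio ≤ 0.8; each decision is a pure
  function of the record.
* **Germline straightening**: nuclei are ordered along the first principal
  component of their centroids; each coordinate is smoothed against that
  parameter by locally weighted quadratic regression (tricube weights,
  span 0.5 — implemented directly because the available lowess routines
  are degree-1 only); arc length along the smoothed curve is accumulated
  on a 2000-point grid.  The annotated start and end nuclei map to 0 and
  1; positions outside [0, 1] are returned as-is for the caller to flag
  (excluded by default downstream).  Profiles are means ± standard error
  in 11 equal-width bins.
* **Per-slide normalization** divides each nucleus's axis total by the
  mean axis total of same-slide wild-type nuclei; a slide without a
  wild-type reference is an error naming the slide.
* **Focus detection**: per nucleus, a histogram threshold (Otsu for
  CO-marker foci, Yen for recombinase foci; 256 bins) is computed inside
  the mask on a 1-voxel Gaussian-smoothed copy of the channel; connected
  components (≥ 4 voxels) become candidates; each candidate's observed
  peak must exceed 5 robust (MAD-based) standard deviations of the
  in-nucleus signal — histogram thresholds always split something, even a
  spot-free nucleus.  Pre-smoothing stabilizes Otsu, which otherwise
  collapses into the background mode when spots occupy ~1% of the nucleus
  volume; the 3D Gaussian fit (amplitude, centroid, per-axis σ, offset;
  bounded least squares) always runs on the raw data.  A failed fit keeps
  the candidate at its intensity-weighted centroid, flagged unfitted.
  Integrated intensity is amp·(2π)^{3/2}σzσyσx.  For recombinase-focus
  counting only nuclei with an equivalent-sphere diameter of 1–6 µm are
  scored.
* **Focus-intensity CV** is the sample standard deviation (ddof = 1) over
  the mean of the integrated intensities of one nucleus; undefined below
  two foci.
* **Treatment contrast**: per-nucleus axis/nucleus ratios are compared
  between genotypes with a linear mixed model (genotype fixed, gonad
  random intercept; statsmodels MixedLM, REML), which accounts for the
  non-independence of nuclei within a gonad.  At least two gonads per
  genotype are required for the random effect to be identifiable.

## Chromosome tracing

Control points are deduplicated and interpolated by a natural cubic spline
over the chord-length parameter (quadratic/linear fallback at 3/2 points).
Arc length is accumulated on a dense grid and inverted; samples are spaced
exactly total/round(total/step) apart (as close as possible to the
requested step, 0.05 µm by default — well below the ~0.1 µm
synaptonemal-complex width) so spacing is uniform and endpoints are
preserved.  The inter-channel offset is the translation minimizing the sum
of squared distances from corrected focus centroids to their nearest trace
samples (Powell coordinate descent from zero; optional 10% trimmed
refinement), returned as the displacement of the focus channel.  Each
corrected centroid maps to the globally nearest sampled point among the
traces of its own nucleus (never across nuclei); exact ties go to the
lowest trace id, then the smallest arc position.  Per-trace focus counts
and length-normalized consecutive gaps feed the interference fit.

## Synthetic data: what it emulates, and what it does not

* **Focus placement**: obligate-single (one uniform focus per chromosome),
  homogeneous Poisson (no interference), and a stationary gamma-renewal
  process (gaps gamma with chosen shape; stationarity approximated by a
  30-gap burn-in before the observation window).  Intensities are
  lognormal with chosen mean and CV.
* **Backcross embryos**: one maternal Bristol/Hawaiian mosaic chromatid
  (breakpoints from any placement model; leftmost haplotype fair-coin) plus
  one paternal Hawaiian copy; the X is maternally guaranteed while sperm
  contribute an X or no X with probability ½ (males are X0), so ~half the
  embryos have a haploid X.  Optional nondisjunction gains/loses a paternal
  copy.  Per 5-kb window, total reads are Poisson at
  coverage·window/read-length·(copies/2) (read length 150 bp); an
  `informative_fraction` (default 0.3 — strain-diagnostic SNV density is a
  free knob, not a published value) splits binomially into Bristol and
  Hawaiian by the local Bristol copy fraction.  Depth windows (50 kb) are
  independent Poisson draws at the same per-copy rate, which is
  distributionally equivalent to aggregating reads for the purpose of
  copy-number estimation.
* **Germline stacks**: spherical nuclei (default radius 2.2 µm) along a
  gently curved tube at (0.2, 0.1, 0.1) µm voxels; three random spline
  filaments per nucleus, dilated to ~2–3 voxels wide, carry the planted
  fraction `axis_ratio` of the SC-channel total, the rest being uniform
  nucleoplasm; Gaussian spots with planted centres and lognormal
  amplitudes.  All channels get a constant background (20 counts) and
  Poisson shot noise.  Read noise is per-channel: the axis and SC channels
  get a camera-like fixed σ (3 counts), while the focus channel's σ is set
  so the spot peak sits `snr` background-noise standard deviations above
  background.  A single amplitude-tied read noise on every channel would
  make mean-threshold axis segmentation fail at any SNR — the threshold
  sits only marginally above background when the filament occupies a few
  percent of the nucleus, so background false positives would swamp the
  mask; tying SNR to the detection channel keeps both halves of the
  pipeline testable under one knob.  Spot centres keep a pairwise
  Mahalanobis separation of 6.5 effective σ so planted spots are
  individually resolvable in the anisotropic stack.

The generators reproduce the *structure* of the real data, not its optics
or genomics: no PSF, no deconvolution artefacts, no mappability or
amplification bias, no chromatin texture, and filaments are random curves
rather than paired homolog axes.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated models, not
robustness to every real-world artefact.

## Validation scales and calibration conditions

* No-interference calibration: Poisson placement at 8 events per unit
  chromosome, ~2000 pooled gaps.  The density matters: at sparse placement
  (≈2 per chromosome) conditioning consecutive gaps on both endpoints
  falling inside the chromosome truncates long gaps and biases the fitted
  shape up to ~1.1–1.25.  At ≥8 events per chromosome the bias is
  negligible and the fitted shape is 1.00 ± a few percent.  Sparse-regime
  edge bias is a known limitation of windowed renewal statistics, shared
  with the real analysis wherever chromosomes carry few COs.
* Shape recovery: true shapes {1, 2.7, 10, 40}, n = 500 gaps, 20
  replicates; median within 15% of truth; the MLE agrees with an
  independent 2-D grid-search maximizer to 1e-3 relative.
* CO calling: 25 embryos × 4 autosomes (100 planted single COs) at 3×
  coverage, ≥95% recovered within 250 kb; 50 CO-free embryos yield zero
  calls.
* Image round-trip: 50-nucleus stacks at SNR 10; planted axis ratios
  {0.5, 0.7, 0.9} recovered within ±0.05 (±0.01 noise-free), planted
  6-focus nuclei counted at 6.0 ± 0.1.
* Ploidy: 400 embryos at 2× coverage give ≈50% haploid-X calls.

These problem sizes keep the full suite and the acceptance script to a few
minutes on one CPU while leaving the statistical tolerances comfortably
resolvable.

## Known limitations

* The gamma fit assumes independent gaps; on chromosomes with many COs the
  gaps are weakly negatively correlated through the shared length
  normalization.
* The CO-caller's interval degenerates to a point when the flanking runs
  are adjacent; the genuine uncertainty (half the smoothing span) is not
  encoded in the interval width.
* The copy-number baseline assumes most autosomes are diploid; a majority-
  aneuploid embryo would shift the baseline.
* Straightening assumes the germline is single-valued along its principal
  axis; strongly U-shaped gonads need prior splitting.
* Offset estimation assumes a single global translation per image;
  field-dependent chromatic aberration is not modelled, so individual foci
  near trace crossings can still be mis-mapped.
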