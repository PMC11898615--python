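# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `septrack`.

## Synthetic data model

The generator (`septrack.simulate`) emulates live-cell SPT of septal
proteins in rod-shaped bacteria, providing ground truth for every pipeline
stage.

**Cell geometry.**  Cells are spherocylinders: a rectangle of length
L − w capped by two half-circles of diameter w (default w = 1 µm), lengths
Normal(2.5, 0.4) µm truncated below at w — typical exponential-phase rod
dimensions.  A Bernoulli septum flag places the septum plane at midcell.
By default cells are laid out in a non-overlapping column in the first
image quadrant (so rendering and track-to-cell assignment are well
defined); `layout="origin"` keeps each cell centred at the origin.  The
polygon is a 33-point-per-cap discretization of the exact spherocylinder;
simulated motion is confined to the exact shape, so containment checks
against the polygon need a tolerance of the cap-chord sagitta (~6 × 10⁻⁴ µm).

**Motion.**  Each molecule belongs to one of k ≤ 3 diffusive populations
with fractions f.  True positions take per-axis Gaussian steps of variance
2DᵢΔt and are specularly reflected at the cell wall (reflection across the
flat wall, or radial reflection off the cap circle; at most 10 reflections,
then clamping).  Specular reflection preserves the uniform stationary
distribution of free diffusion.  Defaults follow the fitted constants of
septal DNA-translocase data: D = (0.017, 0.0509, 0.394) µm²/s for the
confined / slow / fast populations at Δt = 13 ms (10 ms exposure plus
transfer time).  The confined population diffuses at D_static rather than
being strictly immobile, matching the fitted-D representation of such data.
With probability `septal_bias`, a confined molecule starts at the septum
plane of a septum-bearing cell (or at a pole cap otherwise); all other
molecules start uniformly in the cell.

**Photophysics and observation.**  Track length is 1 + Geometric(1 −
p_survive) frames (memoryless bleaching; always ≥ 2 frames).  Observed
positions add per-axis Gaussian localization error (default SD 0.02 µm, a
conventional value — instrument precision is not part of the emulated
data).  Image stacks render each localization as an integrated 2D Gaussian
PSF (σ = 0.13 µm) on a 0.0968 µm pixel grid with Poisson noise on signal
plus background; `peak_photons` is the expected count in the brightest
pixel of a centred emitter, so peak SNR ≈ peak_photons/√background.

**Profiles.**  Three-channel line profiles at 0.0645 µm pitch (a 5-pixel /
322.5 nm line): membrane = Gaussian pole peaks (σ = 0.08 µm, amplitude 100
au) at ±L/2 plus one equal-amplitude interior peak per septum (evenly
spaced); DNA = one Gaussian blob (σ = 0.10 µm, amplitude 80 au) per
nucleoid, distributed round-robin over inter-septal compartments; phase = a
smooth plateau.  Additive Gaussian noise on all channels; peak SNR =
100/noise_sd.  Geometry is validated so planted structures are *optically
resolvable*: septa need ≥ 6σ spacing and nucleoid centres ≥ 5σ — a 4σ
spacing would place the trough between two blobs right at the 50% merge
criterion of the counter, making "two nucleoids" ill-defined at any SNR.

**What the generator does not emulate** (hence what passing tests do not
show about real data): 3D diffusion and defocus, fluorophore blinking,
anisotropic PSFs, curved cells and curved medial axes, membrane-curvature-
dependent motion, chromosome polymer structure, cell growth during
acquisition, and uneven illumination.

## Detection and linking

Spots are detected per frame with a negative Laplacian-of-Gaussian filter,
σ = diameter/(2√2) converted to pixels (default diameter 0.5 µm), local
maxima above a robust response threshold (median + 3 × 1.4826·MAD of the
response), 3×3 quadratic sub-pixel refinement, and a raw-image SNR filter
SNR = (peak − local median)/(1.4826·MAD) ≥ 5.  The LoG σ convention and
the SNR estimator are package choices (configurable); the diameter and
threshold defaults are the standard SPT settings for this kind of data.

Linking is frame-pair optimal assignment (no gap closing, matching the
no-frame-gaps acquisition convention): squared-distance costs, links beyond
0.3 µm forbidden, each unlinked spot paying max_link² in an augmented
square LAP.  Since every feasible link costs less than two unlinked
endpoints, the assignment maximizes links and minimizes total squared
distance among maximal matchings.  Spots within a frame are processed in
(x, y) order, making the result independent of input order; ties beyond
that are resolved by the LAP solver deterministically.  Tracks shorter than
5 frames are discarded.  A track is assigned to a cell only if *every*
localization lies inside (or on the boundary of) that cell's polygon;
straddling tracks are dropped — conservative for per-cell statistics.

## SQD mixture fitting

The empirical CDF of pooled squared displacements (plotting positions
(i − ½)/n) is fitted with F(x) = 1 − Σ fᵢ exp(−x/(4DᵢΔt)) by
Levenberg–Marquardt least squares (lmfit).  The simplex constraint is
implemented with positive weights pᵢ (p₁ ≡ 1 fixed for identifiability),
fᵢ = pᵢ/Σp; fraction standard errors come from the delta method on the
weight covariance.  Ten multi-starts spread the initial D values over
jittered quantiles of the single-jump estimates r²/(4Δt) with a fixed seed,
so fits are bit-reproducible.  Components are reported sorted by D.

By default the model reports *apparent* D (no localization-error term), the
convention of the analysis lineage this package follows; an optional
`loc_error` fits x/(4DΔt + 4σ²) instead.  Note the practical consequence:
with σ = 0.02 µm and Δt = 13 ms, σ²/Δt ≈ 0.031 µm²/s of apparent
diffusivity is added to every component — larger than D_static itself — so
clean-recovery benchmarks run with σ = 0 and real-data confined
coefficients should be read as apparent values.

**Model order** is chosen as the smallest k that is adequate: either the
fit RMSE has reached the ECDF sampling-noise floor √(mean(F(1−F))/n) —
beyond which additional components only chase empirical-CDF noise (a plain
relative-RSS rule misfires here: on pure one-population data a second
component "improves" a noise-floor RSS by 8–55%) — or an extra component
improves the RSS by ≤ 5%.

**Comparing conditions.**  With free D, the confined and slow components
trade off strongly (D ratio ≈ 3), and at a few thousand jumps the fraction
estimates carry SDs of ~0.1.  For two-condition comparisons the package
therefore supports fixing shared D values (fitted once on pooled jumps) and
re-fitting only the fractions per condition (`fix_D=`); the end-to-end
benchmark uses this route.

## MSD and dwell times

The MSD is time-and-ensemble averaged per lag; a straight line
MSD = 4Dτ + b over lags 1–4 gives D, with the intercept absorbing
localization error.  Dwell events are maximal runs of consecutive frames
within r_dwell = 0.1 µm of the run's *first* position, ≥ 2 frames, duration
(n − 1)Δt; radius, anchoring and minimum length are package choices (the
emulated analysis suite leaves them implicit, so printed dwell constants
from real data are not reproducible bit-for-bit — only the machinery is
validated, by recovery on simulated durations).  Dwell distributions are
fitted by maximum likelihood as left-truncated exponentials: order 1 has
the closed form τ̂ = mean(d) − t_min; order 2 runs EM on the shifted
durations (multi-start from quantile splits, seeded; degenerate data fall
back to order 1 with a warning).  EM was cross-checked against direct
likelihood optimization.  At the benchmark scale (τ = 0.14/0.33 s, 50/50,
n = 5000) the MLE of the mixing fraction has a sampling SD of ~8 points —
an identifiability property of exponential mixtures at this τ ratio, not an
optimizer artefact.

## Standardized cell and spatial statistics

The medial axis is the straight pole-to-pole segment (rods are treated as
straight; curved centerlines are out of scope).  The along-axis coordinate
is rescaled so poles map to u = ±1.5 µm; the across-axis offset is divided
by the local half-width (sampled at 101 stations by polygon chord
intersection, linearly interpolated) and scaled to v = ±0.5.  Orientation
is fixed per cell so the pole with fewer localizations sits at negative u;
this convention is applied before any pole-resolved statistic.  Heatmaps
are 30 × 10 proportion grids (0.1 µm pixels, sum = 1); demographs bin each
cell's axial positions at 0.1 µm over its own length, row-normalized to
max 1 and sorted by length.  The midcell region is the central 20% of the
cell length, each polar region the terminal 20% (boundaries inclusive);
the polar ratio is lesser/greater pole count (0 if only one pole is
occupied, NaN if neither).  The most-populated axial bin breaks ties toward
midcell.  Localizations are the counting unit (a per-track option exists
upstream by thinning tracks before projection).

LOESS is local linear regression with tricube weights over the `span`
fraction of nearest neighbours (default 0.75), evaluated on a grid;
pointwise standard errors use the linear-smoother form se(x₀) = σ̂·‖l(x₀)‖
with a global residual variance estimate (dof n − 2).  Local linear fits
reproduce constants and straight lines exactly.

## Profile analysis

Channels are smoothed with a 1-px Gaussian before peak calling.  Peaks must
have prominence ≥ max(20% of the smoothed dynamic range, 5 post-smoothing
noise SDs); the noise SD is estimated robustly from raw first differences
(1.4826·MAD/√2) and propagated through the filter's variance reduction
1/√(2σ√π).  Without the noise floor, SNR-10 profiles yield several percent
spurious peak calls.  Cell length uses quadratic sub-pixel refinement of
the two outermost membrane peaks (exact for symmetrically sampled peaks).
Septa are interior membrane peaks outside a 15%-of-length pole-exclusion
margin.  Nucleoids are DNA peaks, merged when the trough between neighbours
stays above 50% of the lower peak (heights above baseline).  The time-lapse
septal-localization fraction counts frames ≥ threshold within a half-open
cycle range; the 1,800 au default threshold is instrument-specific, not a
transferable constant.

## Statistics

Dunn's test uses pooled mid-ranks with the tie correction Σ(t³−t)/(12(N−1))
and two-sided normal p-values; multiplicity adjustment is Holm by default
(none/Bonferroni/BH available).  The Kruskal–Wallis effect size is
ε² = (H − k + 1)/(N − k), clipped below at 0 (the raw expression is
negative whenever H < k − 1); η²-style alternatives differ only in the
normalizing constant.  The rank-sum test uses exact enumeration for
n_x·n_y ≤ 400 without ties, otherwise the normal approximation with tie and
continuity corrections.  Shapiro–Wilk delegates to scipy's Royston
implementation.  Vargha–Delaney's A is computed from mid-ranks
(equivalent to pairwise counting; A(x,y) + A(y,x) = 1 without ties).

## Benchmark problem sizes

The validation experiments (`septrack.experiments`) use: 3,000 tracks
(~24,000 jumps) for three-component recovery; ~10,000 jumps for the
closed-form single-population checks; 120 frames × 8 emitters at peak
SNR 10 for detection; 5,000 durations for dwell recovery; 10,000 points for
the uniform spatial check; 20 seeds × 150 cells for the LOESS enrichment
sign; 500 profiles at SNR 10 for morphometrics; 2,000 replicates for null
calibration; and 20 seeds × 2 conditions × (40 cells, 1,000 tracks, 350
frames) for the end-to-end experiment.  These sizes put each estimate's
sampling error comfortably inside the property being checked while keeping
the whole suite at minutes on one CPU.

## Known limitations

- 2D only; the imaging it emulates keeps one focal plane near midcell.
- No gap closing, track splitting/merging, or drift correction.
- Apparent-D reporting by default; the confined coefficient absorbs
  localization error unless `loc_error` is set.
- Dwell-event extraction is a package definition; published dwell constants
  obtained with other (unspecified) extraction rules are not directly
  comparable.
- The straight-axis standardized cell mildly distorts strongly bent cells.
- Exponential-mixture fraction estimates are inherently wide when component
  scales are within a factor of ~2.5; compare conditions with shared D.
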