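# Methods

## Noise model and reconstruction

The simulator works on reconstructed HU images because raw projection data
from clinical archives are normally unavailable. HU is mapped to linear
attenuation by `mu = mu_water (1 + HU/1000)` with `mu_water = 0.019 mm^-1`
(roughly the 70 keV effective energy of a 120 kVp spectrum), clamped at
zero so air projects to exactly nothing; the mapping is configurable and is
a bijection on `HU >= -1000`. Parallel-beam line integrals are taken with
the Radon transform over `[0, 180)` degrees at a configurable sampling
interval (angle count = `ceil(180/interval)`); detector bins share the image
pixel spacing and cover the image diagonal.

Noise insertion follows the photon-counting model: per detector bin,
`N ~ Poisson(I0 exp(-p))` with `p` the attenuation path integral, counts
floored at one photon to keep the log defined under photon starvation, and
the bin replaced by `ln(I0/N)`. `I0` is the unattenuated photon count per
bin and is linear in dose, so relative dose `d` is simulated by `I0 -> d I0`.
The `I0` scale is internal to this noise model; values are not comparable
across packages with different detector models.

FBP uses the standard frequency-domain pipeline: the ramp is built from its
real-space kernel (avoiding the DC bias of sampling `|f|` directly),
multiplied by one of five apodization windows expressed in frequency `nu` as
a fraction of Nyquist with cutoff `c` — Ram-Lak `1`, Shepp-Logan
`sinc(nu/2c)`, Cosine `cos(pi nu/2c)`, Hamming `0.54 + 0.46 cos(pi nu/c)`,
Hann `(1 + cos(pi nu/c))/2` — all identically zero above `c`. These
conventions are stated explicitly because cutoff semantics differ between
toolkits. Backprojection uses linear interpolation onto the source grid;
a different output matrix is produced by area-weighted (local-mean)
resampling that preserves the field of view. At cutoff 1.0 the five filters
agree with the scikit-image reference reconstructions to ~1e-14 on a disc
phantom; a noise-free round trip of the chest phantom at 0.5 degree
sampling has a mean absolute error below 30 HU inside the body.

## Synthetic phantom

The phantom is deliberately piecewise-constant: a soft-tissue body ellipse
(300 x 200 mm), two lung ellipses, a spine disc at bone attenuation, and a
left ventricle modelled as a blood-pool ellipsoid (end-diastolic semi-axes
32 x 26 x 42 mm, 450 HU) inside a fixed myocardial shell (14 mm, 100 HU)
with two papillary-muscle ellipsoids (9 x 9 x 17 mm each, myocardial HU,
together ~8% of the cavity) strictly inside the cavity at every phase. The
450/100 HU assignment places LV contrast inside the range observed
clinically (roughly 380-520 HU) and well above the 250 HU floor below which
threshold segmentation is unreliable. Cardiac motion scales only the cavity
semi-axes with a raised cosine over the cycle, so phase 0 is end-diastole
and every phase has an exact analytic volume; ground-truth EDV/ESV/LVEF use
the blood-volume convention (cavity minus papillary inserts) and the
end-systolic scale is solved so the truth LVEF equals the requested target
exactly. The mitral plane caps the LV search region above the cavity apex
so analytic volumes need no truncation terms.

What the phantom does not emulate: anatomical texture, contrast-bolus
dynamics, cardiac/respiratory motion artifacts, other cardiac chambers, and
beam-hardening or scatter physics. Tests passing on this phantom therefore
demonstrate the correctness of the simulation and measurement machinery and
the direction of noise-driven effects, not clinical accuracy on real
anatomy.

## Parameter optimization and flux calibration

The grid search scores every combination of initial flux, angular sampling
interval, filter and cutoff against a 13-level reference dose ladder
(default relative doses from a 10-300 mAs tube-current ladder; the 13
individual default values are this package's choice). Per combination it
simulates all 13 levels from the full-dose input, regresses simulated on
real CNR (ordinary least squares), integrates masked SSIM over the dose
axis, min-max normalizes |slope|, R^2 and AUC across the grid, and ranks by
the deviation norm. A degenerate metric (no spread across the grid)
normalizes to one so it cannot dominate. Ties break toward fewer projection
angles, then filter order. The loop is exhaustive, deterministic given the
master seed (per-level sub-seeds are derived by hashing), restartable from
a partial CSV, and caches forward projections per sampling interval and
noisy sinograms per (interval, flux, level).

The literal deviation norm rewards the largest |slope| in the grid rather
than the slope closest to one; as a consequence a smoother-than-generating
filter always outscores the generating one on the slope component, and the
generating combination is generally not the literal minimizer. The
`slope_mode="distance_to_ideal"` option normalizes `1 - |slope - 1|`
instead; under it, a reference ladder generated by the simulator itself
through the same seed pathway (see `simulate_reference_series`) makes the
generating combination an exact zero of the deviation and recovery is
guaranteed up to ties. The literal form remains the default.

Flux calibration sweeps `n_candidates` log-spaced fluxes (default 200 over
1e3..1e7). For each candidate the input is simulated once at relative dose
1 and the no-insertion round trip is subtracted in the image domain,
leaving a pure inserted-noise sample whose ROI SD forms the objective
curve. The target — the intrinsic stochastic noise of the input — is
estimated by high-pass filtering (input minus an 8 mm Gaussian low-pass),
corrected for the fraction of spatially correlated noise the high-pass
removes; that fraction is measured on the inserted-noise samples
themselves, which share the pipeline's noise statistics. The per-ROI
objective `|SD_ins(f) - SD_intrinsic|` is smoothed with a Gaussian kernel
of fixed 0.1-decade width in log-flux (independent of candidate count,
preventing over-smoothing of coarse sweeps) and minimized with quadratic
sub-grid refinement; the calibrated flux is the mean over the LV and
myocardium ROIs. A noise-free input yields a monotone objective, the
largest candidate, and a boundary flag. Calibration ROIs should sit in
uniform regions: on coarse matrices the phantom's edge ringing contaminates
SD-based estimates, so self-calibration checks run on a uniform disc.

## LVEF measurement

Both segmentation modes threshold the HU volume inside an LV search region
(the end-diastolic cavity grown by a 6 mm margin, capped at the mitral
plane) and keep the largest 3-D connected component, which rejects contrast
reaching the region from elsewhere. BV counts the thresholded voxels
directly, excluding the sub-threshold papillary muscles; ST closes each
axial slice with a 10 mm disk so papillary inclusions are absorbed,
emulating contour-based delineation — closing is extensive, so the BV mask
is always a subset of the ST mask and `LVEF_ST < LVEF_BV` structurally.

Automated contour software smooths before edge detection, and rising noise
widens edges and shrinks small convex structures — most strongly the
end-systolic cavity. Raw thresholding behaves oppositely: spatially
correlated reconstruction-noise blobs accrete onto the cavity boundary
inside the search region and inflate volumes at moderate noise, then
fragment the component at extreme noise. The pipeline therefore emulates
the software behavior explicitly: each reduced-dose level is pre-smoothed
in-plane with a Gaussian whose width is proportional to its inserted-noise
SD (8 mm per 100 HU, capped at 9 mm), measured as the ROI SD of the
difference against the simulated 100% images of the same study — the
reference level itself gets no smoothing, so all noise-driven effects are
expressed relative to it. The segmentation threshold is the midpoint of LV
blood and myocardium ROI means, measured once per study on the simulated
100% end-diastolic mid-ventricular slice (the commercial threshold is
unpublished; the midpoint is an assumption), then shifted per level by the
measured mean HU shift of the blood pool, which tracks the upward HU bias
that photon starvation introduces at very low dose. With this mechanism the
synthetic cohorts reproduce the clinical phenomenology: positive,
monotonically growing standard-mode bias from 25% to 2% dose, widening
blood-volume limits of agreement, and declining mean end-systolic volume.

Output resampling follows the sliding-average convention: each output slice
is the mean of input slices whose centers fall in a 1.0 mm window stepped
by 0.8 mm, with in-plane local-mean resampling to a 256 x 256 matrix. The
synthetic pipeline renders phantoms directly at the measurement resolution
and skips the z-resampling step, which exists for fine-sliced clinical
input.

## Statistics

Bland-Altman agreement per (mode, reduced dose level) against the simulated
100% level: bias = mean difference, limits of agreement = bias +- 1.96 SD
(the conventional normal quantile, not a t quantile), bias CI from t(n-1)
with SE = SD/sqrt(n), each LoA CI from the Bland-Altman approximation
SE = SD sqrt(3/n), and a two-sided paired t-test for nonzero bias at the 5%
level with no multiplicity correction across dose levels. Degenerate
all-zero differences return exact zeros with p = 1. Effective dose is DLP
times the chest conversion factor 0.026 mSv/mGycm and is linear in relative
dose.

## Determinism and problem sizes

All randomness flows from one master seed; every stage (study, dose level,
phase, slice, candidate) derives a 31-bit sub-seed by hashing the master
seed with its context keys, so pipelines are bit-reproducible and stages
are independent. The default full-dose flux for synthetic studies is
2e4 photons/bin, which spans nearly noise-free full-dose images to heavily
streaky photon starvation at 2% dose.

The shipped tests and the acceptance script use deliberately compact
problem sizes chosen to exercise every regime: a 128-256 matrix, 12-21
slices per phantom, 2-6 cardiac phases, cohorts of 20 phantoms at a 1
degree sampling interval, and reduced (40-combination) search grids. These
sizes preserve the qualitative physics (noise scaling, starvation bias,
segmentation trends) at coarser resolution than clinical data; absolute
bias magnitudes at 2% dose are correspondingly larger than on fine-pixel
clinical images, while directions and orderings are stable across seeds.

## Known limitations

* Parallel-beam geometry only; no helical/cone-beam effects, scatter, beam
  hardening, tube-current modulation or iterative reconstruction.
* The absolute photon-flux scale is model-internal.
* The literal deviation norm does not identify generating parameters (see
  above); it is kept as default for fidelity, with the slope-to-one variant
  for recovery work.
* Threshold segmentation on a piecewise-constant phantom is easier than on
  real anatomy; trabeculation, the LV outflow tract and neighboring
  chambers are not modelled.
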