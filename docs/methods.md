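# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations. Units are micrometres and seconds
throughout; pixel-space parameters are flagged explicitly.

## The synthetic forward model

`synmesh.synthdata` renders the imaging experiment the analysis stages
assume: a cytotoxic-lymphocyte synapse imaged *en face* as a
single-plane, multi-channel time-lapse.

**Scene.** A circular cell footprint grows linearly from
`initial_area_um2` to `plateau_area_um2` at `spread_rate_um2_per_s`
(defaults 5 → 64 µm² at 0.5 µm²/s, a NK-like cell reaching its plateau in
~2 min). Inside it, the mature cortical mesh is rendered as a bright
homogeneous carpet (`mesh_floor = 1.0`) carrying ±12 % fiber texture:
randomly oriented 1–4 µm segments of ~2 px thickness, with Gaussian node
blobs at fiber crossings and saturated stacking. This deliberately
low-contrast rendering reflects the "visually homogeneous and dense"
appearance of the mature central mesh — it is the regime in which a
global threshold can meaningfully separate clearances (truly
actin-depleted, intensity ~0) from mesh. The generator does **not** model
polymer physics, filament turnover, or a resolvable fiber/gap dichotomy;
consequently, passing recovery tests demonstrate correctness of the
measurement chain on planted geometry, not performance on arbitrary real
meshes whose gap structure is itself the signal.

**Clearances.** Planted as circles with sub-pixel occupancy computed on a
4× supersampled grid. The recorded ground-truth area is the occupancy sum
(accurate to well under one pixel); the rendered carve removes the top-k
pixels by occupancy with k = ⌈occupancy sum⌉. Ceiling rather than
rounding guarantees a hole planted exactly at a decision boundary (e.g.
0.05 µm²) renders at or above its nominal area, so boundary
classifications are well defined at 40 nm pixels. Holes may open and
close at specified frames. Overlapping or out-of-field holes are
rejected. The default area distribution for randomly placed holes is
log-normal (median 0.15 µm², σ_log = 0.8, clipped to the requested
range): a broad right-skewed distribution consistent with clearances
spanning ~0.01–3 µm²; nothing downstream depends on this choice. Randomly
placed holes keep ≥ 0.3 µm edge-to-edge spacing so they are resolvable at
the emulated ~130 nm resolution.

**Foci.** Bright Gaussian punctae (amplitude 1.8, σ 0.08 µm) with
exponential lifetimes (default mean 42 s). A fixed fraction (default
3.06 %) is long-lived and spans the whole acquisition, creating the
right-censored tail; uncensored lifetimes are redrawn in the negligible
tail that cannot fit strictly inside the movie. Temporally overlapping
foci keep ≥ 0.4 µm spacing so greedy linking is unambiguous; this
overstates the regularity of real foci placement.

**Granules, reporter, bursts.** Diffraction-limited Gaussian spots
present over specified frame intervals; the exocytosis-reporter channel
carries a dim baseline per granule plus step-like bursts
(`amplitude_fold` × baseline) decaying with a 10 s time constant — a
pHluorin-like flash. `render_trace_set` produces the same trace model as
pure tables for classifier tests.

**Optics and noise.** Gaussian PSF of `psf_fwhm_um` (default 130 nm, the
TIRF-SIM regime at 40 nm pixels) is applied to the clean scene; Poisson
noise (optional) and Gaussian read noise follow; finally a Gaussian of
`recon_sigma_um` (default 80 nm) emulates the band-limiting of the
super-resolution reconstruction chain, which is part of the imaging
systems this pipeline targets. **SNR convention:** quoted signal-to-noise
ratios are acquisition-referred — planted mesh–hole contrast divided by
the read-noise SD *before* the reconstruction filter. This matters: the
per-pixel threshold pipeline is only well posed on band-limited imagery,
and white per-pixel noise at low SNR (contrast/SD = 5) provably defeats
any global two-class threshold (~20 % of mesh pixels fall below every
candidate). `movie_snr` measures the post-reconstruction ratio on a
rendered movie for the monotonicity property.

Identical `SimulationConfig` (including `rng_seed`) ⇒ bit-identical
movies and ground truth; all randomness flows through one
`numpy.random.default_rng`.

## Preprocessing

*Rolling-ball subtraction* is implemented as grayscale opening with a
flat square window of half-width `radius_px` (default 50 px). The flat
window is the zero-curvature limit of the classic rolling ball; at these
radii the ball's intensity curvature is negligible, and flat opening is
exactly idempotent and anti-extensive — repeating the subtraction is a
no-op for structures smaller than the window, and the output mean never
exceeds the input mean. A curved kernel would shave a finite amount
(~w²/8r) from narrow structures on every pass.

*Squared twice* maps x → x⁴ and rescales to the input maximum. The
transform is rank-preserving, so it moves the threshold, not the contour
geometry. Whether the original analysis rescaled after squaring is
unknowable from the description; rescaling prevents underflow and leaves
thresholding scale-free, and on well-separated two-class images the
resulting mask is identical either way (tested).

*Automatic threshold* is the iterative-intermeans (IsoData-variant)
"default" method on a 256-bin histogram. The split index scans upward
from the lowest occupied bin and stops at the **first** (lowest)
fixed point of T = (mean below + mean above)/2. This choice is
load-bearing: on clearance imagery the dark phase is a minority class,
and the generic midpoint iteration converges to an upper fixed point
that splits the bright phase instead. For bright-foreground polarity the
inverted histogram is scanned, making the two polarities exact mirrors
(inverting an image and flipping the polarity yields the identical mask).

*Bandpass* is a difference of Gaussians with σ = size/2.355 (FWHM
convention) for the 10–30 px range, mean-removed. A DoG necessarily
responds at the edges of oversized structures; an in-band disc dominates
an oversized one by ~2.3× in peak amplitude at these scales.

## Clearance measurement

The per-frame chain is: rolling-window subtraction (whole frame) →
squared twice → intermeans threshold computed from the ROI pixels → dark
8-connected components inside the ROI (border-touching components
retained by default, switchable). The ROI is a user polygon or an
auto-centred 64 µm² square. Components smaller than 0.01 µm² (the lower
end of the observed clearance range) are discarded as specks. Each
clearance carries permissivity flags for granule diameters 150–800 nm
under A_min(d) = 0.05 µm² · (d/150 nm)²; the quadratic scaling of the
single calibrated point is a geometric (uniform-circularity) choice, and
the calibration constant is exposed — set
`calibration_area_um2 = π·0.075²` for the pure cross-section alternative.
Mean hole area is computed over permissive clearances by default
(`mean_over_permissive=False` for all).

**Resolution-induced area bias and the half-depth option.** The global
threshold after x⁴ lands at ≈ 84 % of the mesh level, i.e. ~1 σ_blur
*outside* the true clearance edge on blurred imagery — inflating blurred
hole areas 1.5–2× at 130 nm FWHM / 40 nm pixels (measured on planted
truth). This bias is inherent to the protocol and cancels in
condition-vs-condition comparisons, but not against ground truth.
`detect_clearances(refine_areas=True)` therefore offers a second pass
that re-measures each component at its local half-depth contour (midway
between the component minimum and the surrounding mesh median on the
background-subtracted image) — the half-depth contour coincides with the
true boundary for a diffraction-blurred step, needs no calibration
constant, discards dips shallower than 40 % of the mesh level (noise
dips are not actin-depleted clearances), and coalesces fragments of one
physical clearance. The default is **off**: the plain thresholded pixel
count is the protocol-faithful measurement. Truth-recovery validation
uses the refined measurement; with it, 20 random meshes at acquisition
SNR 5 give complete planted-hole recovery with zero false positives and
a pooled mean-area error of ~−8 %.

## Foci

Detection: white top-hat (disk, 0.3 µm) removes mesh and fiber plateaus;
the residue is smoothed at the focus scale (σ 0.1 µm); punctae are
components above max(4 × the 75th percentile of the in-cell residue,
10 % of the residue peak). The 75th percentile sits in ordinary fiber
texture (foci occupy a few percent of the synapse), so the factor means
"4× brighter than fiber texture"; the peak floor handles texture-free
fields. Components holding several local maxima are split by
nearest-peak assignment, so resolved neighbors are not merged. The
segmentation threshold and minimum size are exposed configuration — the
source protocol does not state them.

Linking: greedy nearest-neighbor under 0.3 µm/frame (foci have limited
mobility) with 1-frame gap closing, mirroring the vesicle-tracking
default; merges and splits are recorded when tracks contend for one
detection or a detection appears beside a continued track. Lifetime of a
track seen in k consecutive frames is k·Δt (a single-frame focus counts
one interval), so the estimator carries a small positive quantization
bias (~Δt/2–Δt, i.e. +6–12 % at Δt = 5 s on a 42 s mean); censoring =
touching the first or last frame. With 200 planted exponential foci
(mean 42 s) per movie the tracked mean lands within 15 % of truth and
the censored fraction within its binomial confidence interval.

## Optical flow and kymographs

The Farneback estimator is implemented natively: per-frame quadratic
polynomial expansion with Gaussian applicability (neighborhood 5,
σ = 1.25), iterative displacement estimation with Gaussian-weighted
normal equations (filter size 15, σ = 3.75), in a 3-level pyramid of
scale 0.5 with 3 iterations per level — the published parameterization.
Frames are linearly rescaled to 8-bit per movie before estimation. Two
numerical safeguards: the per-iteration solve is for the *residual*
relative to the prior displacement with Tikhonov damping at 0.2× the
median normal-matrix trace (structureless input yields ~zero flow while
coherent texture converges unbiased — planted integer translations of
1–3 px/frame are recovered to three decimals), and per-level updates are
clamped to the filter span. Sign convention: positive dx is motion
toward increasing x between t and t+1.

Kymographs sample a polyline at 1 px spacing with bilinear
interpolation, averaging across `width_px` parallel offsets. The
decomposition partitions the 2-D DFT plane exactly: static = bins with
|f_t| ≤ 1 bin plus the purely temporal f_x = 0 column; the remainder
splits by the sign of f_x·f_t (negative product = motion toward
increasing position, since a ridge x = vt has support on f_t = −v·f_x).
The partition is symmetric under frequency negation, so components are
real and sum to the total at machine precision; the band half-width is
configuration. Low-spatial-frequency motion whose |f_t| falls inside the
static band is attributed to the static component — patterns probing
directionality should carry spatial frequencies above (band
width)·(positions/frames). The rim kymograph erodes each footprint mask
by the rim width (default 2 µm), bins rim pixels into 360 polar-angle
bins about the footprint centroid, and averages per bin per frame; this
replaces boundary-node parameterizations while preserving the
angle × time readout.

## Degranulation

Spot detection is a scale-normalized Laplacian of Gaussian at
σ = d/(2√2) for the 0.5 µm spot size after local background subtraction
(uniform filter at 4× the spot scale), with one quality threshold per
movie (10 % of the movie-wide peak response) so empty frames yield no
rescaled noise peaks; linking allows a 1-frame gap. The reporter trace
per track is the mean intensity in a spot-sized disk; its SD over the
track lifetime is compared against σ_ref with the strict rule
SD > 2·σ_ref — a track at exactly twice the reference is *not* called.
σ_ref defaults to the population median per-track SD (robust while fewer
than half the tracks burst); designated control tracks are the
alternative, and both are reported because the source protocol does not
say which object served as reference. An all-zero-variability population
gives σ_ref = 0 and no calls. Manual confirmation is replaced by an
exported review table (track id, SD ratio, coordinates); nothing is
auto-confirmed. The population metric thresholds the reporter channel
uniformly, keeps connected events ≥ 0.05 µm², and is invariant to joint
rescaling of image and threshold and to cell ordering.

## Morphometrics

Footprint: per-frame bright-polarity threshold, largest 8-connected
component. Plateau = first frame of the earliest run of 5 frames all at
≥ 95 % of the maximum area (both parameters exposed; the source states
only "reaches a plateau"). Spreading speed = least-squares slope of area
vs time from first detection to the plateau frame; normalization maps
the smallest footprint to 0 % and the largest to 100 %. Planted linear
growth of 0.2–2 µm²/s is recovered within 5 %.

Viability gate: 10–30 px bandpass → bright threshold → components gated
by area (25–400 µm², inclusive) and circularity (0.6–1.0). Circularity
is 4πA/P² with the Crofton perimeter estimator, clamped at 1 — a naive
pixel-edge perimeter biases circularity low and would wrongly reject
round cells at the 0.6 bound, while Crofton slightly overshoots 1 for
small rasterized discs. Note the bandpass imposes a minimum apparent
blob size (≈ 39 µm² at 0.568 µm pixels), so the lower area bound is only
observable at finer pixel scales; components below 1 µm² are dropped as
speckle before gating.

## Validation scales

The test suite and acceptance script use desk-scale problem sizes chosen
to exercise every code path with comfortable statistics: 320² px fields
(12.8 µm at 40 nm pixels) with ~35 planted clearances, 20 random meshes
for recovery, 200 foci per movie (pooled ×3 in the acceptance script),
60–300 frame movies, and 10-seed noise ensembles for the flow
properties.

## Known limitations

- The mesh generator's homogeneous-carpet rendering does not reproduce
  real SIM imagery in which inter-fiber gaps of all sizes *are* the
  clearance population; on such data the pipeline measures the full gap
  catalogue, and planted-truth validation does not speak to gap-scale
  segmentation fidelity.
- The protocol-faithful clearance area carries the resolution-dependent
  threshold ring described above; compare conditions, or enable
  `refine_areas`, when absolute areas matter.
- The greedy linker has no motion model; it is adequate for
  limited-mobility foci and sparse granules but will switch identities
  in dense, fast scenes.
- Kymograph directionality is only meaningful for patterns whose
  temporal frequency clears the static band.
- Degranulation calling assumes the reporter trace is stationary apart
  from bursts; slow photobleaching is not detrended (the source protocol
  states none).
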