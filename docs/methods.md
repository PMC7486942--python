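# Methods

This note documents the models and procedures implemented in `locreset`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The package analyses multi-channel time-lapse stacks (T × Z × Y × X) of an
epithelial monolayer expressing a tagged transcription factor: a nuclear
stain channel drives segmentation, a reporter channel carries the factor's
localization signal, and an optional spot channel carries MS2/MCP
nascent-transcription foci. Coordinates are pixel-centred, 0-based, in
(z, y, x) order; public tables also carry micrometres via the pixel size
(default 0.276 µm/px, a typical 63× confocal sampling). The one exception
is the transport-rate fit window, which is quoted 1-based ("frames 1–4")
to match the convention in which such measurements are reported.

## Segmentation and tracking

**Enhancement.** Perona–Malik anisotropic diffusion (10 iterations,
explicit step γ = 0.15, conduction scale κ defaulting to 10% of the image
dynamic range) smooths interior texture while preserving nuclear
boundaries; the L1 sum of absolute spatial derivatives of the smoothed
image is then added, sharpening the boundary response. A constant image is
a fixed point. The parameters are config defaults tuned on the synthetic
fixtures; nothing downstream is sensitive to them at the tested SNRs.

**2D segmentation.** Foreground is a global threshold on the enhanced
image — Otsu by default, with a fixed-value override. Touching nuclei are
split by a watershed on the negated Euclidean distance transform, seeded
at h-maxima of the (Gaussian-smoothed, σ = 1 px) distance map
(h = `seed_h`, default 2 px). Regions below `min_area` (default 50 px) are
discarded. Re-running segmentation on an already-separated mask is a
no-op (idempotence is tested).

**3D local-threshold segmentation.** For variable-brightness nuclei
(e.g. variable MCP expression), a lower-bound threshold first collects
candidate regions containing at least one local intensity maximum. Each
region is then re-thresholded at the peak of the derivative of its own
intensity-percentile curve: I(P) is evaluated on a 0.5-percentile grid,
dI/dP is smoothed with a 5-point moving average, and a peak is significant
when its prominence exceeds 5× the curve's median derivative (peaks above
the 95th percentile are ignored as interior structure). The percentile
curve is computed on the *raw* stack so enhancement halos do not inflate
volumes. Because percentiles are rank-based, the chosen threshold
percentile is invariant under affine intensity rescaling of a region.
Regions smaller than 400 px are kept unsplit and flagged. A final seeded
watershed separates touching nuclei.

**Linking.** Consecutive frames are linked by minimum-total-displacement
bipartite assignment (Hungarian algorithm) with a hard displacement gate;
unmatched labels terminate or start tracks. A greedy nearest-first
fallback is provided. The gate (default 20 px) and minimum nucleus size
are declared defaults: appropriate values depend on magnification and
frame interval, and should be set per dataset. Linking does not handle
division natively; divisions enter through annotation tables, mirroring
manual annotation practice.

## Compartment quantification

The N/C ratio is the ratio of mean background-subtracted fluorescence in
nuclear and cytoplasmic compartments:

* the nuclear volume is the segmented label restricted to the plane of
  maximal stain signal ± 1 plane (2D inputs degrade to a single plane);
* nucleolar pixels — the strictly lowest 35% of reporter intensities
  inside the nuclear mask — are excluded (the factor is physically
  excluded from nucleoli). Ties at the cut are kept, which makes the rule
  deterministic: with n distinct values exactly ⌊0.35 n⌋ pixels are
  removed;
* the cytoplasmic compartment is a ring extending 0.5 µm outward from the
  nucleus boundary, realized by Euclidean-distance thresholding (isotropic
  at small radii) with the radius rounded to the nearest whole pixel
  (minimum 1 px; 2 px at 0.276 µm/px), excluding all nuclear labels. An
  empty ring (fully crowded border cell) yields a missing value, as does a
  non-positive denominator after background subtraction.

Background defaults to the histogram mode of the image outside all
dilated nuclei (the camera offset plus diffuse background); integer
images use an exact per-value mode, float images a 256-bin histogram.
Local density is the count of cell centroids within a 250 px search
radius *including the cell itself* — the self-count makes the constant
offset of 1 explicit; an isolated cell scores 1. The GcAMP-style ring
intensity shares the ring geometry. Pretreatment normalization divides a
per-cell trace by its mean over a stated window. qPCR fold changes are
2^ΔCt with ΔCt = Ct(baseline) − Ct(condition), replicates averaged first,
normalized to a reference housekeeping gene (HPRT1 in the motivating
assays).

## Fluctuation detection

A localization fluctuation is a continuously increasing or decreasing
stretch of the N/C trace with net amplitude ≥ 0.12 (N/C units).
Continuity is broken wherever the trace changes by less than 0.005 over a
sliding 3-frame window (stride 1; window change = |last − first|). Within
each monotone stretch the detector emits every maximal sub-run free of
stagnant windows; runs meeting the amplitude threshold become events with
their direction. Amplitude is the *net* change over the run (not
peak-to-trough). Design choices where the rule is underdetermined:

* zero steps (exact ties) continue the current direction — real traces
  are tie-free, and the brute-force equivalence test is run on tie-free
  traces;
* missing frames split the trace into independently scanned segments;
* comparisons against the two printed thresholds carry a 1e-12 absolute
  guard so that a trace constructed exactly at a boundary (e.g. a ramp of
  net amplitude 0.12 built on a float grid) is classified by the intended
  real-arithmetic rule rather than by the platform's rounding direction.

Cohort statistics: fraction of tracks with ≥ 1 event, per-cell event
frequency (events per observed duration), amplitude distribution.

## Nascent transcription

Candidates are gated per nucleus at the 99.97th percentile of that
nucleus's raw intensities (rank-based, hence invariant to affine
rescaling; in a 10,000-pixel nucleus of distinct values exactly the top 3
pixels qualify), and localized at local maxima of the negated
Laplacian-of-Gaussian response (σ = 1.5 px, matching a diffraction-limited
spot at the reference magnification). The percentile gate applies to raw
intensities; the LoG is used only for localization. Each candidate is
scored by integrated intensity: the sum over the inner disk (pixels at
distance < 3.5 px from the centroid; 37 pixels on the integer grid) minus
37× the mean of the background shell (3.5 ≤ r < 4.5 px; 32 pixels). Disk
and shell counts are locked to brute-force enumeration in the tests. The
shell subtraction also removes the PSF tail sampled in the shell
(≈ 8% of the photon count for σ = 1.5 px), an accepted property of
shell-background photometry. Spots whose disk or shell is clipped by the
image border are excluded.

The integrated-intensity threshold is not a universal constant: the
default is 5× the standard deviation of background-corrected integrated
intensities sampled at random intranuclear positions of spot-free nuclei
(a calibration pass). Sampling includes near-boundary positions, which
inflates the standard deviation enough to reject the disk-inside/
shell-outside edge artifact in flat nuclei.

Consecutive per-cell detections merge into pulses with a gap tolerance of
1 frame (a single missed detection does not split a pulse). Two
simultaneous spots in one nucleus are kept distinct (two alleles).
Transcription activity is the per-frame fraction of tracked cells with a
passing spot, optionally normalized to a pretreatment window. Mitosis
alignment recentres time on cytokinesis, scores post-division activity as
the OR over the two daughters (each daughter inherits one of the two gene
cassettes, so OR keeps the monitored cassette count constant across
division), normalizes pre-division activity to 1, and concatenates the
parent N/C trace with the daughters' per-frame mean.

## FRAP and transport

**Forward models.** Recovery carpets are radial: normalized fluorescence
over (distance from bleach centre) × (time). Pure diffusion evolves the
initial postbleach profile under the radially symmetric 2D diffusion
equation. The reaction–diffusion model couples a diffusing free pool to
an immobile bound pool through pseudo-first-order binding (k*_on is the
association rate times the free binding-site concentration, absorbed into
one effective constant): ∂f/∂t = D_f ∇²f − k*_on f + k_off c,
∂c/∂t = k*_on f − k_off c, with prebleach equilibrium f/c = k_off/k*_on
and observed signal f + c. Keq = k*_on/k_off; bound fraction
Keq/(1 + Keq) (0 at Keq = 0, 1/2 at Keq = 1, monotone). With k*_on = 0
the reaction–diffusion surface reproduces pure diffusion to numerical
precision (nesting is tested).

**Numerics.** Conservative finite-volume discretization on cell-centred
radii with zero-flux faces at r = 0 and the outer boundary; implicit
Crank–Nicolson stepping with sub-steps chosen to resolve both the
diffusive (D dt/dr²) and reaction (k dt) scales; sparse LU factorizations
cached per step size. This preserves the discrete total signal exactly
(tested to 1e-6 over 1000 steps) and matches the closed-form spreading
Gaussian to 1e-4 on a refined grid. The domain extends 1.5× beyond the
outermost measured position by default so the reflecting boundary does not
distort the fitted window. The initial condition is an inverted Gaussian
fitted to the first postbleach profile, with both pools bleached
proportionally (an equilibrium-preserving bleach); the effective
postbleach profile is treated as measured rather than derived from the
bleaching optics.

**Preprocessing.** Raw line scans are normalized per position by the
prescan mean; acquisition bleaching is corrected by a monoexponential fit
to the far field (outer 20% of positions on each side), with a separately
acquired background series supported as an alternative normalizer; the two
rows of the 2-px line are averaged; the bleach centre is located by
inverted-Gaussian fitting of the first postbleach profile (recovered to
< 0.2 px on synthetic scans); profiles are folded about the centre and
averaged.

**Fitting and selection.** Nonlinear least squares over the carpet in
log-parameter space (positivity by construction); deterministic given the
initial guess; SSD = sum of squared residuals. Bootstrap uncertainty
resamples experiments with replacement (default 30 bootstraps of 5),
averages carpets, refits, and reports per-parameter mean ± sd; failed
fits are excluded and counted. Model selection accepts
reaction–diffusion only if its SSD improves on pure diffusion by more
than a 10% relative margin *and* its fitted D_f lies within plausibility
bounds (default 1–30 µm²/s, bracketing the ~21 µm²/s expected for a
~100 kDa protein); otherwise pure diffusion is kept, and the decision
trace is attached to the result. The margin is a configurable stand-in
for a selection that is qualitative in practice.

**Transport rates.** The two-pool exchange dN/dt = k_imp C − k_exp N is
linear, so the compartment-bleach simulator uses the exact closed-form
solution (relaxation rate λ = k_imp + k_exp). The specific rate estimator
takes the nuclear signal change from the first postbleach frame, divides
by the postbleach intensity of the source compartment (cytoplasm for
import, nucleus for export — division first, per the measurement
convention), and fits an OLS line over postbleach frames 1–4 (30 s at
10-s framing). The slope underestimates each rate by a factor that
depends only on λ (≈ 13% at λ·30 s = 0.3, vanishing as the frame interval
shrinks — both properties tested), but because both bleach directions
share λ, the bias cancels exactly in the import/export ratio, which is
the quantity interpreted biologically.

## Synthetic scenes: what they emulate, and what they do not

Nuclei are in-plane-jittered ellipses/ellipsoids on a reflected Gaussian
random walk with overlap rejection; nucleoli are dimmed interior blobs of
a configured fractional size; the reporter renders
nucleus = background + gain·(N/C)(t)·c and cytoplasm = background +
gain·c, with an optional conservation mode that adjusts per-cell
cytoplasm concentrations so a localization-reset redistributes rather
than creates signal. Cytoplasm extends a configurable halo (default
18 px) beyond the nucleus, leaving visible cell-free background for the
background estimator; `None` renders a confluent field. Noise is Poisson
shot noise plus Gaussian read noise plus a constant camera offset. Spots
are Gaussian foci driven by a stationary two-state (telegraph) chain, one
locus per cell at a fixed intranuclear offset. Divisions split one label
into two adjacent half-area labels at an annotated frame.

Deliberately absent: photobleaching of the reporter during time-lapse,
blinking, 3D PSF and optical aberrations, cell–cell mechanics, chromatin
condensation imagery, and realistic intranuclear texture beyond a smooth
random field. Acquisition noise levels of the reference instruments are
unknown, so SNR is a free configuration axis and tests pin specific
SNR values rather than claiming realism. Passing tests therefore
demonstrate correctness of the measurement operators and detectors under
controlled conditions — not performance on any particular instrument's
data.

## Problem sizes and determinism

Default test and example scenes are 128–256 px frames with 2–12 cells and
6–40 frames; FRAP fits use 40–60 radial positions × 15–30 time samples
with interior grids of 80–1200 cells — sizes chosen so the full suite and
the acceptance script run comfortably on a single CPU while leaving the
statistical checks well-powered. Every stochastic component takes an
explicit seed (scene configs, bootstrap, calibration sampling); a fixed
seed yields byte-identical movies and pipeline CSV outputs, which the
tests assert.

## Known limitations

* The fluctuation detector's tie-handling (zero steps continue the
  current run) is one of several defensible readings of "continuously
  increasing"; alternatives differ only on measure-zero inputs.
* The 2D watershed split of heavily overlapping nuclei approximates the
  geometric chord only to ~1 px; heavily confluent fields need the 3D
  local-threshold mode with well-chosen seeds.
* The FRAP model assumes radial symmetry about the bleach centre and a
  single immobile binding mode; anisotropic recoveries or multiple
  binding classes are out of scope.
* Individual transport rates (not their ratio) carry the documented
  finite-window bias; reports should either use the ratio or shrink the
  frame interval.
* Mitosis alignment consumes manual division annotations; no automatic
  division detection is attempted.
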