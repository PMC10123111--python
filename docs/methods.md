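# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical choices that affect results.

## Coordinate and time conventions

Pixels are 0-based; physical position (µm) = origin + pixel · pixel_size.
Frame 0 begins at t = 0; time = frame · line_time, where line_time is the
wall time per scanned line including any inter-line pause. All intervals are
half-open [start, end). A track's duration includes the final frame's
exposure (last time − first time + one line_time), so a single-frame event
has duration one line_time — the minimum detectable dwell.

## Simulator

Binding events arrive at each damage site as a Poisson process with the
configured per-site rate. A site hosts one molecule at a time: the next
arrival is drawn after the current occupant dissociates. At low occupancy
the total event rate approaches (rate × number of sites); the occupancy
correction is the reason simulated event rates fall slightly below that
product.

Dwell times are exponential mixtures, positions follow 1D Brownian motion
(independent Gaussian increments of variance 2DΔt; for α ≠ 1 an
increment-scaling approximation matches the marginal 2Dt^α law — adequate
for sanity checks, not a faithful fractional process, which is why α is
treated as a fit output rather than a simulated input). Each fluorophore
carries a single-exponential photobleaching clock that advances only during
exposure, so a pulsed excitation scheme with duty cycle d stretches the
wall-clock bleach lifetime by 1/d. Blinking is a per-exposed-frame Bernoulli
switch into a dark state with exponential off time truncated at a
configurable maximum (default 2 s, the longest off period the downstream
curation rule must repair).

Rendering is discrete: time is continuous internally, and a molecule
contributes to a frame iff its emitting interval covers at least 50 % of
that frame (symmetric censoring, at most half a frame of bias at each
streak end). Emission adds a Gaussian point-spread profile (default
σ = 1.5 px) at the molecule's position; counts are Poisson draws of signal
plus uniform background. The PSF width and emission rates are free
parameters of the simulator, not claims about any instrument.

Default geometry: a 48,502 bp molecule mapped uniformly onto the tether
span (contour length at 0.34 nm/bp ⇒ ~16.5 µm, 165 pixels of 100 nm), line
time 0.033 s (~30 lines/s). What the simulator does **not** emulate: bead
images at the tether ends, tether fluctuations and drift, non-Poisson
camera noise, spectral crosstalk between channels (except the explicit FRET
donor bleed-through), and protein-protein interactions beyond the scripted
two-color pair events. Passing recovery tests therefore demonstrates
correctness of the analysis under the stated statistical model, not
robustness to every instrumental artifact.

## Detection, linking, curation

Candidate line centers are local maxima within a ±4 px window whose count
exceeds the background by a threshold; each candidate is refined by an
unweighted Gaussian least-squares fit (amplitude, center, σ, offset) on the
same window, giving subpixel centers (~0.02 px at high SNR). The default
threshold is the larger of 4 background standard deviations and the exact
Poisson upper quantile that bounds the per-pixel false-positive probability
at 1e-7 — the two agree at high background, but the quantile is what keeps
megapixel kymographs clean in the skewed low-count regime. Fits that
diverge or return implausible widths (σ outside [0.2, 8] px) drop the
candidate silently.

Linking is greedy nearest-neighbour between consecutive frames with a
maximum step (default 0.5 µm/frame); each detection joins at most one
track. Greedy linking is adequate at the event densities this pipeline
targets (well-separated streaks); it is not a global assignment and will
mis-link crossing trajectories — a documented limitation.

Curation repairs blinking: any two tracks whose temporal gap is < 2 s and
whose junction positions (mean of the ≤5 detections flanking the gap on
each side) differ by < 100 nm are merged, transitively via union-find; the
operation is idempotent. The junction estimator is a choice — "same
position" admits several readings — made for robustness to localization
noise on short fragments. The bead region is excluded by an explicit pixel
ROI supplied in configuration; automatic bead-edge detection is
instrument-specific and deliberately out of scope.

## Dwell-time kinetics

The CRTD counts events with dwell ≥ t at every distinct observed dwell. The
survival model N·Σ fᵢ·e^(−t/τᵢ) is fitted by unweighted nonlinear least
squares on the counts (log-parameterized amplitudes and lifetimes,
Levenberg–Marquardt, three starting lifetime spreads, best residual kept).
Least squares on the CRTD is the default for fidelity to common practice in
this field; a maximum-likelihood EM fit of the raw dwells
(`fit_dwells_mle`) is available as an alternative. Standard errors come
from the Gauss–Newton covariance via the delta method; they ignore the
correlation between cumulative counts and are therefore optimistic —
compare models, don't trust absolute errors.

Model order (1–3 components) is chosen by BIC with two guards: a richer
model needs ΔBIC > 10 (cumulative counts are serially correlated, so the
nominal BIC overstates evidence), and is rejected as redundant when any
fraction falls below 10 % or adjacent lifetimes are within a factor of 3.
Each component additionally requires 5 distinct thresholds. Censored dwells
(touching either end of the recording) are excluded from the CRTD by
default, with an inclusion flag for sensitivity analysis.

Photobleaching: counts from a field of immobilized fluorophores are summed
per line, binned into 1 s intervals, and fitted to A·e^(−t/τ_b) + C with
A, τ_b, C ≥ 0 — the offset is physical background and constraining it to be
non-negative removes a degeneracy that otherwise inflates τ_b. A fit whose
amplitude is within 3 shot-noise standard deviations of zero, or whose τ_b
exceeds a configurable cap, raises a fit-failure (no detectable decay).
Observed lifetimes are corrected per component by rate subtraction,
1/τ_c = 1/τ_obs − 1/τ_b, then averaged with the fitted fractions; the
correction requires τ_b > τ_obs and refuses bleaching-dominated data. This
form reproduces published corrected/uncorrected component pairs to printing
precision.

Reported lifetimes round to one decimal; fractions to whole percent. The
equilibrium constant is K_d = k_off/k_on with k_on supplied by the user —
concentration calibration is out of scope.

## Diffusion

MSD uses overlapping displacements exactly as defined (verified against a
brute-force double loop). The anomalous model 2D(nΔt)^α + y is fitted over
an initial lag window; the window end is scanned over a geometric grid of
up to 24 candidates covering ≥ 10 % of the curve, and the best-R² window
wins (longest on near-ties) — a deterministic automation of "fit the linear
portion". Fits with R² < 0.8 or < 10 % of the curve are rejected; tracks
shorter than 1 s fix α = 1. Motility: a track is motile iff its fit was
accepted and D exceeds a noise floor (default 0.005 µm²/s) calibrated from
immobile simulations at matched signal-to-noise, since localization jitter
masquerades as diffusion; rejected fits are nonmotile by definition.

## Colocalization

Point pairs colocalize when |Δposition| < 200 nm and |Δtime| < 400 ms
(strict), so events that diffuse into proximity are matched from the
approach onward. The taxonomy has 11 classes: A-only (1), B-only (2), and
the 3×3 grid of arrival × departure order, numbered row-major with order
(A first, together, B first) on both axes, i.e. class 7 =
arrive-and-depart-together and class 9 = B binds first / A leaves first.
"Together" reuses the 400 ms window; no separate threshold. When one track
has several colocalized partners it is paired once, with its
longest-overlap partner; remaining tracks become single-color events, so
every track is counted exactly once. Channel swap maps each class to its
mirror (3↔11, 4↔10, 5↔9, 6↔8, 7 fixed). Three-color data are analyzed as
channel pairs.

## smFRET

Per frame, donor and acceptor line intensities integrate a ±2 px window on
the tracked center; background is the mean of the flanking bands 6–9 px on
each side (following the track), scaled to the integration width, falling
back to a one-sided flank with a warning near edges. Donor bleed-through is
removed as I_A − bg_A − ratio·(I_D − bg_D) with the calibrated ratio
(default 0.090). Corrections are applied per frame, then traces are
downsampled (non-overlapping sums of 10 frames, trailing partial bin
dropped) — corrections-then-downsample is a choice; the alternative order
differs only through the nonlinearity of E at low counts. Efficiency is the
proximity ratio E = I_A/(I_A + I_D) with detection factor γ = 1, so
distances r = R₀·(1/E − 1)^(1/6) are apparent distances on the instrument's
detection scale; R₀ is a required configuration parameter with no baked-in
default. Bins with E outside (0, 1) are flagged invalid rather than
converted.

## Binding sites

Physical positions interpolate linearly between the tether anchors to
genomic coordinates (0-based half-open; 1-based only in human-readable
report output). Events cluster by single linkage with default radius
450 bp — three times a typical ~150 bp localization precision. Observed
sites match expected ones by greedy one-to-one nearest assignment within a
tolerance; because tether orientation is ambiguous on the instrument, the
mirrored orientation (L − position) is also scored and the better one kept.

The nickase scan finds a recognition sequence on both strands and reports
the nick one nucleotide 3′ of the recognition heptamer (top-strand
coordinate i+8 for a match at i; j−1 for a bottom-strand match whose
reverse complement starts at j). Counting both strands is what reproduces
the canonical 10-site total for Nt.BspQI on a lambda-length substrate.

The bundled reference (`sites.synthetic_nicked_reference`) is **synthetic**:
a deterministic 48,502 bp random sequence carrying GCTCTTC exactly 10 times
across both strands, at fixed coordinates that echo the real substrate's
layout (minimum pairwise nick distance 436 bp; one site near an end). It
exercises the scanning and matching machinery offline; analyses of real
data should supply the genuine reference FASTA.

## Validation workflows and problem sizes

`kymotrace.validation` runs each recovery end to end at these sizes, chosen
so Monte-Carlo error sits well inside the assertion tolerances: dwell
mixture (1 s 70 % / 20 s 30 %) at n = 1000; photobleach correction on a
simulated 2400 s campaign of ~850 events (true τ = 5 s, τ_b = 20 s;
uncorrected fits recover the analytic 4 s bias, corrected fits recover
5 s); diffusion at 100 tracks of 10 s / 30 fps each for D = 0.05 µm²/s plus
100 immobile tracks with 50 nm jitter; the classifier round-trips
11 classes × 100 seeds; FRET recovers a 51 Å truth over 50 events with 9 %
bleed-through and Poisson noise; curation equates the curated track count
with the *recoverable* ground-truth count on a sparse blinking simulation —
events with at least one emitting frame, coalescing same-site events whose
dark gap is below the merge threshold, since those are indistinguishable
from a single blinked event by construction. All randomness descends from
one seed; identical seeds give bit-identical outputs.

## Known limitations

* Greedy linking and greedy colocalization pairing are not globally optimal.
* CRTD least-squares standard errors are optimistic (correlated counts).
* α ≠ 1 simulation is an approximation; no fractional Brownian generator.
* No drift correction, no 2D area-scan tracking, no ALEX-style FRET
  stoichiometry, no force modeling.
* The motile/nonmotile call depends on the configured noise floor; report
  it alongside results.
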