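# Methods

This note documents the models implemented in `streamtriage`, the
parameters that matter, the synthetic data the test suite runs on, and the
numerical choices made where the design was genuinely open.

## Pipeline model

Every stream object passes through four stages: feature extraction →
interestingness function (IF) → policy → placement. The IF is always
scalar-valued, so policies compose with any IF; all domain knowledge lives
in the IF, all resource decisions in the policy. Two realizations are
provided: interval binning into storage tiers (static hierarchy) and a
priority queue for edge pre-processing/upload (dynamic hierarchy).

## PLLS focus metric

The periodogram is `|FFT2(x − mean(x))|² / N` of the *untapered*,
mean-subtracted image — the simplest reproducible definition; the DC
component is excluded by construction. Power is averaged in `n_bins = 64`
log-spaced radial bins over (0, 0.5] cycles/pixel, with frequencies
normalized per axis so non-square crops are handled symmetrically; empty
bins are dropped, and bin centers are the geometric mean of the bin edges.
PLLS is the unweighted OLS slope of log₁₀(mean power) on log₁₀(frequency)
over the bins inside `fit_range`, requiring ≥ 3 usable bins and strictly
positive power (a constant image raises a degenerate-spectrum error;
`extract_features` converts that into a flagged, NaN-valued feature so the
pipeline can quarantine instead of abort).

**Default fit range (0.02, 0.12) of the sampling frequency.** The lower
edge keeps DC leakage out of the coarsest bins. The upper edge was chosen
after measuring the metric on quantized 16-bit synthetic images: under
strong defocus (σ ≈ 8 px) the signal spectrum falls below the
quantization/read-noise floor above roughly 0.08–0.1 cycles/pixel, and a
fit that spans that floor mixes a steep segment with a flat one — making
the fitted slope *non-monotone* in blur (σ = 4 can fit steeper than
σ = 8). Restricting the fit to the signal-dominated band restores strict
monotonicity of mean PLLS over σ ∈ {0, 1, 2, 4, 8} (Spearman ≈ −0.97).
The cost is higher single-image variance on broadband spectra (≈ 0.13 slope
units for white noise), so property tests of flat/power-law slope recovery
pass a wider range (0.02, 0.45) explicitly — the slope definition is
range-parametric and both are first-class configurations.

PLLS is translation-invariant (periodogram magnitude), verified to 1e−9,
and matches an independent naive implementation (explicit periodogram,
explicit binning, normal-equations OLS) to 1e−9.

## Interestingness functions

**Logistic.** `f(x) = 1/(1+e^{−k(x−x₀)})`, computed via `scipy.special.expit`
and nudged one ULP inside (0, 1) at saturation so the open-interval
contract holds for arbitrarily extreme inputs. Preset (k = 4.5,
x₀ = −1.4) ships as the high-content-screening default. Because PLLS
values shift with magnification, staining and exposure, `calibrate_logistic`
sets (k, x₀) from the mean PLLS of a clearly-sharp and a clearly-blurred
calibration sample, placing them at expit(±spread) (0.95/0.05 by default).

**Linear spline over sweep index.** Knots are (index, observed ρ) pairs
with ρ = bytes saved / CPU-second ≥ 0. Estimates interpolate linearly
between bracketing knots and **clamp to the nearest knot outside the knot
range** — linear extension would extrapolate negative or explosive
reductions from two nearby noisy samples. A repeated index **replaces**
the old knot rather than averaging: the newest measurement reflects the
operator's current behaviour. Models are immutable; updates return a new
model, which keeps the simulator's decision log trivially reproducible.

## Policy and tiers

Score bins must contiguously partition [0, 1] onto declared tiers;
validation emits distinct diagnostics for reversed intervals, overlaps,
gaps, incomplete coverage and unknown tiers. Interval membership is
lower-inclusive, upper-exclusive, with the top bin closed — open intervals
cannot partition the domain, and every score must map somewhere. Trash is
a retained directory (recoverable if the policy was mis-tuned), not
deletion; placement is move-by-default with an optional copy flag, and
name collisions get a numeric suffix so nothing is ever overwritten.
Objects whose payload is unreadable or whose spectrum is degenerate are
moved to a quarantine directory and recorded as such — never silently
dropped — so for any batch, tier counts + trashed + quarantined equals the
batch size.

## Edge agent

One non-preemptive processor and one non-preemptive upload channel (a lab
PC feeding a single uplink). The discrete-event simulator applies
simultaneous events in the order arrival < process-complete <
upload-complete, then by image index, and takes dispatch decisions only
after all events at an instant are applied — upload channel first, so the
uploader never idles while any queued or processed image exists.

**Pre-processing operator.** Pixels below the block threshold θ (default
50 of 255) are set to exactly 0; pixels ≥ θ are untouched, so retained
content is bit-identical and a second pass is a no-op. Sizes are measured
with pinned PNG encoder settings (compress level 6, no optimizer) and
treated as opaque integers by the scheduler. In live mode the CPU cost is
the measured operator wall time; a constant cost can be supplied for
reproducible runs, and the simulator takes costs from the scenario.

**Scheduling heuristic.** Pre-process the queued image with the largest
estimated ρ, gated by `rho_min` (default 0: anything with positive
estimated benefit qualifies). Exploration: over the index span of the
currently queued images, if the largest gap between adjacent spline knots
(span boundaries included) exceeds `G` (default span/8), sample the queued
image nearest that gap's midpoint instead. This deterministic
largest-gap rule is this package's concrete choice for the
explore/exploit trade-off; upload priority is processed-first (earliest
finished), then smallest estimated ρ; all ties break to the lowest index.

**Brute-force oracle.** Exact minimum makespan for ≤ 7 images by
enumerating every pre-process subset and every processing order, with
processing started as early as possible. The upload order is *not*
enumerated: for fixed per-image ready times, earliest-ready-first is
exactly optimal for single-channel makespan (adjacent-exchange argument),
so it is applied directly. A test cross-checks this collapse against a
literal enumeration of all upload orders on 3-image instances. The
heuristic's realized schedule is always in the enumerated family, so
heuristic makespan ≥ oracle holds structurally as well as empirically.

## Synthetic data

Generators are pure functions of (parameters, seed) — byte-identical
reruns — and their manifests carry the full ground truth.

**Fluorescence (HCS) images**: 256×256, 16-bit TIFF; 20–40 Gaussian cell
spots (σ 1.2 px, amplitude 0.4–1.0) on a 0.05 background, plus fine
pre-blur sample texture (sd 0.02 of full scale), defocused by a Gaussian
kernel of the recorded σ, then ~half-LSB read noise and quantization.
Texture before the blur means the blurred spectrum is exactly the sharp
spectrum times the kernel's transfer function, which is what makes PLLS
provably monotone in σ here. These images emulate only the spectral
behaviour relevant to focus scoring — not cell morphology, stains,
channels or optics PSFs — so passing tests demonstrate the ranking
machinery, not biological realism.

**TEM sweep**: 256×256 8-bit PNG frames; a bright textured sample (all
pixels ≥ θ + 10) occluded by a honeycomb mask filled with high-variance
near-black noise. The mask is the top g(t)-fraction of a
distance-to-hexagonal-lattice field (exact pixel count, so the measured
dark fraction matches g(t) to one pixel), with the lattice offset
advancing each frame to emulate holder movement. The occluded fraction
follows g(t) = clip(a₀ + a₁ sin(2πt/P + φ) + drift·t, 0, 1), defaults
a₀ = 0.3, a₁ = 0.2, P = 32 — chosen to reproduce the qualitative
oscillating-with-drift shape of a real sweep, whose irregularity
magnitudes are not otherwise constrained.

**Edge scenarios**: named families — `random` (sizes 2–12 MB, reductions
0–80%, CPU 0.5–3 s, staggered arrivals), `favorable` (half the images
with large cheap reductions, half with none), `all-zero-reduction`,
`process-all-pathology` (2% reductions at twice the upload time in CPU,
where processing everything strictly lengthens the run), and `sweep`
(reductions following g(t)).

## Problem sizes and tolerances

The test suite and acceptance script use 300 images (100 per σ ∈ {0, 2, 8})
for the end-to-end tiering run, 30 per level for the PLLS monotonicity
check, 200 random ≤ 6-image scenarios against the oracle, and 10⁵ scores
for the partition property — sizes at which every check completes in
seconds while leaving no statistical ambiguity at the asserted thresholds.
Exact algebraic identities (logistic closed form, spline knot exactness)
are asserted at 1e−12; cross-implementation agreement at 1e−9; stochastic
spectral estimates at the tolerances their measured variance supports
(±0.1 flat-spectrum slope at the wide fit range, ±0.3 power-law exponent
recovery, Spearman thresholds ±0.9/0.8).

## Known limitations

* PLLS numeric equality with other implementations is not claimed — fit
  range and binning conventions differ across tools; only rank/monotonicity
  behaviour is asserted.
* The exploration rule is a documented deterministic stand-in for online
  sampling strategies; no optimality claim is made for it.
* The watcher polls the filesystem (no inotify); discovery order within a
  scan is sorted-name order, so sub-poll-interval arrival order is not
  preserved.
* Single processor, single uplink, non-preemptive; multi-core pools and
  preemption are out of scope.
* Uploads are simulated (or loopback); there is no real network transfer,
  authentication, or cloud tier driver.
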