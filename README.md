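# streamtriage

Interestingness-driven triage of scientific image streams.

Modern microscopes produce image streams faster than they can be stored,
inspected or uploaded. `streamtriage` implements a small, composable
pipeline model for deciding — online, from image content rather than
metadata — what each incoming image is worth: cheap per-object **features**
feed an **interestingness function** (IF) whose scalar score a **policy**
turns into a placement decision. The induced "data hierarchy" is realized
two ways:

* **Static storage tiers** — high-content-screening images are scored by
  focus quality and binned into tier directories (best images on fast
  storage, hopeless ones to trash), with every decision persisted to an
  embedded metadata store and exportable as a CSV report.
* **A dynamic edge upload queue** — images from a transmission electron
  microscope (TEM) wait at a lab PC for a slow uplink. A pre-processing
  operator flattens the noisy, grid-blocked dark regions so lossless PNG
  compression shrinks the file, but costs CPU time. A scheduler decides,
  concurrently with arrivals and uploads, which image to pre-process and
  which to upload next so the *makespan* (time to the last upload) is
  minimized.

It is aimed at imaging-facility engineers and computational biologists who
want content-aware prioritization bolted onto an existing acquisition
pipeline, and at anyone studying the scheduling problem itself (a
discrete-event simulator and an exact brute-force oracle are included).

## The models

**Focus feature (PLLS).** The Power Log-Log Slope of an image is the OLS
slope of log₁₀(radially averaged periodogram power) on log₁₀(radial
frequency). Defocus suppresses high spatial frequencies, so more blur ⇒ a
more negative slope; the slope is a reference-free focus score.

**Static IF.** A logistic squash of the PLLS value *x*,

    f(x) = 1 / (1 + exp(−k (x − x₀))),  f(x) ∈ (0, 1)

with the shipped preset (k = 4.5, x₀ = −1.4); `calibrate_logistic` fits
(k, x₀) to a sample of pre-images from a new modality. A policy of
contiguous score intervals, e.g. `[0.75, 1.00] → tierA` … `[0, 0.25) →
tierD` (or trash), maps scores to tiers.

**Dynamic IF.** For the edge agent, the quantity of interest is the
normalized reduction ρ = (bytes saved by pre-processing) / (CPU seconds),
modelled as a linear spline over sweep index and refined online from each
observed (index, ρ) sample. The scheduling policy: CPU goes to the queued
image with the largest estimated ρ (with an exploration rule that samples
poorly covered stretches of the sweep); the uplink goes to processed
images first, then to the queued image with the *smallest* estimated ρ.

## Worked example

`python examples/edge_scheduling.py` prints:

```
worked 2-image instance:
  heuristic makespan         12.0 s
  fifo (no preprocessing)    20.0 s
  exhaustive optimum         12.0 s
  decisions: upload img1 (least-reduction), preprocess img0 (exploit), upload img0 (processed-first)
```

Two 10 MB images on a 1 MB/s uplink: uploading both as-is takes 20 s. The
heuristic ships the incompressible image first while the other is
pre-processed (1 s of CPU, 10 MB → 2 MB), then uploads the shrunken file —
12 s in total, matching the exhaustive optimum. On random 6-image
scenarios the same run reports the heuristic within ~8% of the optimum on
average and ~30% faster than uploading everything unprocessed.

`python examples/triage_stream.py` triages 30 synthetic fluorescence
images (defocus σ ∈ {0, 2, 8} px) and prints the tier allocation:

```
images per (defocus sigma, tier):
blur_sigma  tier_id
0.0         tierA      10
2.0         tierB       8
            tierC       2
8.0         tierD      10
```

i.e. sharp images land on the top tier, moderately defocused ones in the
middle, badly defocused ones at the bottom. The other examples show the
PLLS/blur relationship (`focus_metric.py`) and the online spline
(`online_spline.py`).

## Command line

A thin CLI wraps the library: `streamtriage run` (watch a directory and
triage), `streamtriage report` (export the metadata store as CSV),
`streamtriage simulate-edge` (run a scenario under a policy; writes
`timeline.csv` + `summary.json`), and `streamtriage generate hcs|tem|scenario`
(synthetic datasets). See `streamtriage --help`.

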