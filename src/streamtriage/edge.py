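"""Edge agent: prioritized pre-processing and upload of a TEM image sweep.

Images from a transmission electron microscope arrive faster than the
uplink can carry them.  A pre-processing operator zeroes the noisy pixels
inside the dark grid-blocked regions, which makes lossless PNG compression
far more effective — but the operator costs CPU time, and for weakly
occluded images the saving does not pay for the delay.  The agent therefore
runs three concurrent activities — arrival, pre-processing, upload — and
prioritizes:

* the single processor on the queued image with the greatest *estimated*
  normalized reduction rho = bytes saved / CPU-second (with an exploration
  rule that samples poorly covered stretches of the sweep), and
* the single upload channel on (i) already-processed images, earliest
  finished first, then (ii) the queued image whose estimated reduction is
  least (processing it would help least, so ship it as-is).

The rho estimate is the online linear-spline model from
:mod:`streamtriage.interest`, refined with each observed (index, rho)
sample at process-completion.  A discrete-event simulator executes the
policy deterministically, and a brute-force oracle provides the exact
optimal makespan on small instances.
"""

from __future__ import annotations

import io
import itertools
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interest import SplineModel, spline_update

__all__ = [
    "EdgeImage",
    "SimScenario",
    "SimResult",
    "SchedulerState",
    "OperatorError",
    "ScenarioError",
    "encode_png",
    "preprocess_image",
    "preprocess_file",
    "choose_next_preprocess",
    "choose_next_upload",
    "run_simulation",
    "brute_force_schedule",
    "perfect_model",
    "scenario_from_directory",
]

#: Fixed PNG encoder settings: sizes must be deterministic for a given build,
#: since the scheduler treats them as opaque ground truth.
_PNG_COMPRESS_LEVEL = 6

POLICIES = ("heuristic", "fifo_no_preprocess", "preprocess_all")


class OperatorError(ValueError):
    """The pre-processing operator could not decode or encode an image."""


class ScenarioError(ValueError):
    """Invalid simulation scenario."""


# ---------------------------------------------------------------------------
# Pre-processing operator
# ---------------------------------------------------------------------------

def encode_png(image: np.ndarray) -> bytes:
    """Encode a grayscale uint8/uint16 array as PNG with pinned settings."""
    from PIL import Image

    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        im = Image.fromarray(arr, mode="L")
    elif arr.dtype == np.uint16:
        im = Image.fromarray(arr, mode="I;16")
    else:
        raise OperatorError(f"expected uint8 or uint16 image, got dtype {arr.dtype}")
    buf = io.BytesIO()
    im.save(buf, format="PNG", compress_level=_PNG_COMPRESS_LEVEL, optimize=False)
    return buf.getvalue()


def preprocess_image(
    image: np.ndarray, block_threshold: int = 50
) -> tuple[np.ndarray, int, float]:
    """Flatten grid-blocked pixels and measure the compressed-size saving.

    Pixels with intensity strictly below ``block_threshold`` are set to
    exactly 0 (the blocked regions are nearly black but noisy, and the
    noise compresses poorly); all pixels at or above the threshold are left
    bit-identical, so retained content is lossless.  Returns the processed
    array, the reduction in encoded PNG size in bytes (before minus after;
    can be negative in pathological cases and is reported as-is), and the
    CPU wall time of the operator in seconds.
    """
    t0 = time.perf_counter()
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise OperatorError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    before = encode_png(arr)
    out = arr.copy()
    out[arr < block_threshold] = 0
    after = encode_png(out)
    return out, len(before) - len(after), time.perf_counter() - t0


def preprocess_file(path: str | Path, block_threshold: int = 50) -> tuple[np.ndarray, int, float]:
    """Decode an image file and apply :func:`preprocess_image`."""
    from PIL import Image

    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:
        raise OperatorError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]  # grayscale PNGs saved as RGB: channels identical
    return preprocess_image(arr, block_threshold=block_threshold)


# ---------------------------------------------------------------------------
# Scenario containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeImage:
    """One sweep image as the scheduler sees it, plus hidden ground truth."""

    index: int
    size_bytes: int
    cpu_cost: float
    arrival: float = 0.0
    true_reduction_bytes: int = 0

    def __post_init__(self) -> None:
        if self.size_bytes <= 0:
            raise ScenarioError("size_bytes must be positive")
        if self.cpu_cost <= 0:
            raise ScenarioError("cpu_cost must be positive")
        if self.true_reduction_bytes > self.size_bytes:
            raise ScenarioError("reduction cannot exceed the image size")

    @property
    def true_rho(self) -> float:
        """Ground-truth normalized reduction (bytes saved per CPU-second)."""
        return self.true_reduction_bytes / self.cpu_cost

    @property
    def processed_size(self) -> int:
        return self.size_bytes - self.true_reduction_bytes


@dataclass(frozen=True)
class SimScenario:
    """Inputs to the edge simulation.

    ``rho_min`` gates processing: only images whose estimated rho exceeds it
    are worth the CPU.  ``exploration_gap`` G is the knot-gap (in index
    units) beyond which the scheduler samples rather than exploits; None
    means span/8 of the currently queued index range.
    """

    images: tuple[EdgeImage, ...]
    bandwidth: float  # bytes/second
    rho_min: float = 0.0
    exploration_gap: float | None = None
    seed: int = 0

    def __init__(self, images, bandwidth, rho_min=0.0, exploration_gap=None, seed=0):
        imgs = tuple(images)
        if bandwidth <= 0:
            raise ScenarioError("bandwidth must be positive")
        if any(b.arrival < a.arrival for a, b in zip(imgs, imgs[1:])):
            raise ScenarioError("arrival times must be non-decreasing in index order")
        if len({im.index for im in imgs}) != len(imgs):
            raise ScenarioError("image indices must be unique")
        object.__setattr__(self, "images", imgs)
        object.__setattr__(self, "bandwidth", float(bandwidth))
        object.__setattr__(self, "rho_min", float(rho_min))
        object.__setattr__(self, "exploration_gap", exploration_gap)
        object.__setattr__(self, "seed", int(seed))


@dataclass
class SimResult:
    """Outcome of one simulated run."""

    makespan: float
    timeline: pd.DataFrame  # one row per image
    decisions: list[tuple[float, str, int, str]]  # (time, action, index, reason)
    total_uploaded_bytes: int

    def decision_sequence(self) -> list[tuple[str, int, str]]:
        """Decision order without timestamps (for cross-mode comparison)."""
        return [(a, i, r) for _, a, i, r in self.decisions]


# ---------------------------------------------------------------------------
# Scheduling choices
# ---------------------------------------------------------------------------

@dataclass
class SchedulerState:
    """What the two choosers see: queued indices and processed-but-not-uploaded
    indices in order of processing completion."""

    queued: set[int] = field(default_factory=set)
    processed: list[int] = field(default_factory=list)


def _estimate(model: SplineModel, index: float) -> float:
    """Spline estimate, with 0 when the model has no knots yet."""
    return model.estimate(index) if model.n_knots else 0.0


def choose_next_preprocess(
    state: SchedulerState,
    model: SplineModel,
    rho_min: float = 0.0,
    exploration_gap: float | None = None,
) -> tuple[int | None, str]:
    """Pick the next queued image to pre-process, or None.

    Explore/exploit rule: over the index span of the currently queued
    images, find the largest gap between adjacent spline knots (the span
    boundaries count as gap edges).  If that gap exceeds G, sample the
    queued image nearest the gap midpoint ("explore"); otherwise take the
    queued image with the highest estimated rho, provided it beats
    ``rho_min`` ("exploit").  Ties break toward the lowest index.
    """
    if not state.queued:
        return None, "idle"
    queued = sorted(state.queued)
    lo, hi = queued[0], queued[-1]
    gap_limit = exploration_gap if exploration_gap is not None else (hi - lo) / 8.0
    anchors = sorted({float(lo), float(hi), *(k for k in model.indices if lo <= k <= hi)})
    if len(anchors) >= 2:
        gaps = [(b - a, a, b) for a, b in zip(anchors, anchors[1:])]
        width, a, b = max(gaps, key=lambda g: (g[0], -g[1]))
        if width > gap_limit:
            mid = (a + b) / 2.0
            pick = min(queued, key=lambda i: (abs(i - mid), i))
            return pick, "explore"
    best = max(queued, key=lambda i: (_estimate(model, i), -i))
    if _estimate(model, best) > rho_min:
        return best, "exploit"
    return None, "idle"


def choose_next_upload(
    state: SchedulerState, model: SplineModel
) -> tuple[int | None, str]:
    """Pick the next image to upload, or None if nothing is available.

    Processed images go first (earliest finished), because their saving is
    already banked; otherwise ship the queued image whose estimated
    reduction is least — processing it would have helped least.  Images
    currently being processed are unavailable.  Ties break toward the
    lowest index.
    """
    if state.processed:
        return state.processed[0], "processed-first"
    if state.queued:
        pick = min(sorted(state.queued), key=lambda i: (_estimate(model, i), i))
        return pick, "least-reduction"
    return None, "idle"


# ---------------------------------------------------------------------------
# Discrete-event simulator
# ---------------------------------------------------------------------------

# Simultaneous events are applied in this order, then by image index.
_EV_ARRIVAL, _EV_PROC_DONE, _EV_UP_DONE = 0, 1, 2


def perfect_model(scenario: SimScenario) -> SplineModel:
    """Spline model holding every image's true rho (perfect-knowledge runs)."""
    model = SplineModel()
    for im in scenario.images:
        model = spline_update(model, im.index, im.true_rho)
    return model


def run_simulation(
    scenario: SimScenario,
    policy: str = "heuristic",
    initial_model: SplineModel | None = None,
) -> SimResult:
    """Deterministic discrete-event execution of an upload policy.

    One non-preemptive processor and one non-preemptive upload channel.
    Events (arrival, process-complete, upload-complete) at the same instant
    are applied in that order, by index; dispatch decisions are taken after
    all events at an instant have been applied, upload channel first, so
    the uploader never idles while any queued or processed image exists.
    Under the heuristic policy each observed rho updates the spline model
    at process-completion.
    """
    if policy not in POLICIES:
        raise ScenarioError(f"unknown policy {policy!r}; known: {POLICIES}")
    images = {im.index: im for im in scenario.images}
    if not images:
        raise ScenarioError("scenario has no images")
    model = initial_model if initial_model is not None else SplineModel()
    state = SchedulerState()
    uploading: int | None = None
    processing: int | None = None
    decisions: list[tuple[float, str, int, str]] = []
    rows = {
        i: {
            "index": i,
            "arrival_s": images[i].arrival,
            "size_bytes": images[i].size_bytes,
            "proc_start_s": math.nan,
            "proc_end_s": math.nan,
            "upload_start_s": math.nan,
            "upload_end_s": math.nan,
            "uploaded_bytes": images[i].size_bytes,
        }
        for i in images
    }

    import heapq

    events: list[tuple[float, int, int]] = []
    for im in scenario.images:
        heapq.heappush(events, (im.arrival, _EV_ARRIVAL, im.index))

    def pick_upload(t: float) -> None:
        nonlocal uploading
        if policy == "fifo_no_preprocess":
            idx, reason = (min(state.queued), "fifo") if state.queued else (None, "idle")
        elif policy == "preprocess_all":
            # every image must be processed before upload; the uploader waits
            idx, reason = (
                (state.processed[0], "processed-first") if state.processed else (None, "idle")
            )
        else:
            idx, reason = choose_next_upload(state, model)
        if idx is None:
            return
        im = images[idx]
        size = im.processed_size if idx in state.processed else im.size_bytes
        if idx in state.processed:
            state.processed.remove(idx)
        else:
            state.queued.discard(idx)
        uploading = idx
        rows[idx]["upload_start_s"] = t
        rows[idx]["uploaded_bytes"] = size
        decisions.append((t, "upload", idx, reason))
        heapq.heappush(events, (t + size / scenario.bandwidth, _EV_UP_DONE, idx))

    def pick_preprocess(t: float) -> None:
        nonlocal processing
        if policy == "fifo_no_preprocess":
            return
        if policy == "preprocess_all":
            idx, reason = (min(state.queued), "fifo") if state.queued else (None, "idle")
        else:
            idx, reason = choose_next_preprocess(
                state, model, rho_min=scenario.rho_min,
                exploration_gap=scenario.exploration_gap,
            )
        if idx is None:
            return
        state.queued.discard(idx)
        processing = idx
        rows[idx]["proc_start_s"] = t
        decisions.append((t, "preprocess", idx, reason))
        heapq.heappush(events, (t + images[idx].cpu_cost, _EV_PROC_DONE, idx))

    t = 0.0
    while events:
        t = events[0][0]
        # apply every event at this instant, in (kind, index) order
        while events and events[0][0] == t:
            _, kind, idx = heapq.heappop(events)
            if kind == _EV_ARRIVAL:
                state.queued.add(idx)
            elif kind == _EV_PROC_DONE:
                processing = None
                state.processed.append(idx)
                rows[idx]["proc_end_s"] = t
                if policy == "heuristic":
                    model = spline_update(model, idx, images[idx].true_rho)
            else:
                uploading = None
                rows[idx]["upload_end_s"] = t
        if uploading is None:
            pick_upload(t)
        if processing is None:
            pick_preprocess(t)

    timeline = pd.DataFrame(
        [rows[i] for i in sorted(rows)],
        columns=[
            "index", "arrival_s", "size_bytes", "proc_start_s", "proc_end_s",
            "upload_start_s", "upload_end_s", "uploaded_bytes",
        ],
    )
    makespan = float(timeline["upload_end_s"].max())
    return SimResult(
        makespan=makespan,
        timeline=timeline,
        decisions=decisions,
        total_uploaded_bytes=int(timeline["uploaded_bytes"].sum()),
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _upload_makespan_erd(ready: dict[int, float], sizes: dict[int, int], bandwidth: float) -> float:
    """Optimal single-channel upload makespan given per-image ready times.

    Earliest-ready-first is exactly optimal for minimizing makespan on one
    non-preemptive channel with release dates (adjacent-exchange argument),
    so enumerating upload orders is unnecessary.
    """
    t = 0.0
    for i in sorted(ready, key=lambda i: (ready[i], i)):
        t = max(t, ready[i]) + sizes[i] / bandwidth
    return t


def brute_force_schedule(scenario: SimScenario, max_images: int = 7) -> float:
    """Exact minimum makespan by exhaustive enumeration (small instances only).

    Enumerates every subset of images to pre-process and every processing
    order of that subset; processing starts as early as possible and a
    processed image only becomes ready for upload at process completion.
    For each candidate the optimal upload order is earliest-ready-first.
    """
    n = len(scenario.images)
    if n > max_images:
        raise ScenarioError(f"brute force limited to {max_images} images, got {n}")
    arrival = {im.index: im.arrival for im in scenario.images}
    cpu = {im.index: im.cpu_cost for im in scenario.images}
    size = {im.index: im.size_bytes for im in scenario.images}
    red = {im.index: im.true_reduction_bytes for im in scenario.images}
    all_idx = sorted(arrival)

    best = math.inf
    for k in range(n + 1):
        for subset in itertools.combinations(all_idx, k):
            for order in itertools.permutations(subset):
                ready = {i: arrival[i] for i in all_idx if i not in subset}
                sizes = {i: size[i] for i in all_idx if i not in subset}
                t = 0.0
                for i in order:
                    t = max(t, arrival[i]) + cpu[i]
                    ready[i] = t
                    sizes[i] = size[i] - red[i]
                best = min(best, _upload_makespan_erd(ready, sizes, scenario.bandwidth))
    return best


# ---------------------------------------------------------------------------
# Live mode
# ---------------------------------------------------------------------------

def scenario_from_directory(
    source_dir: str | Path,
    bandwidth: float,
    block_threshold: int = 50,
    cpu_cost: float | None = None,
    rho_min: float = 0.0,
    exploration_gap: float | None = None,
) -> SimScenario:
    """Build a scenario by measuring the operator on real PNG files.

    Files are taken in sorted-name order as sweep indices 0..n-1.  For each
    image the encoded size and the operator's actual reduction are measured;
    the CPU cost is the measured operator wall time unless a constant
    ``cpu_cost`` is given (constant costs make the scenario reproducible).
    Negative measured reductions are clamped to 0 (processing such an image
    can never help).
    """
    files = sorted(p for p in Path(source_dir).iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise ScenarioError(f"no PNG files in {source_dir}")
    images = []
    for i, path in enumerate(files):
        t0 = time.perf_counter()
        arr_size = len(path.read_bytes())
        _, reduction, op_cpu = preprocess_file(path, block_threshold=block_threshold)
        cost = cpu_cost if cpu_cost is not None else max(time.perf_counter() - t0, 1e-6)
        images.append(
            EdgeImage(
                index=i,
                size_bytes=arr_size,
                cpu_cost=cost,
                arrival=0.0,
                true_reduction_bytes=max(reduction, 0),
            )
        )
    return SimScenario(
        images=images,
        bandwidth=bandwidth,
        rho_min=rho_min,
        exploration_gap=exploration_gap,
    )
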