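"""Interestingness functions (IFs).

An IF maps cheap extracted features to a single finite scalar used to
prioritize an object for storage, compute or upload.  Two families are
provided:

* a static logistic squash of the PLLS focus feature,
  ``f(x) = 1 / (1 + exp(-k (x - x0)))``, output in (0, 1), used with an
  interval policy to bin an image stream into storage tiers; and
* a dynamic linear-spline model of the per-image normalized size reduction
  achieved by an edge pre-processing operator, refined online from observed
  (image index, reduction / CPU-seconds) samples and used to rank a live
  upload queue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "LogisticParams",
    "SplineModel",
    "EmptySplineError",
    "logistic_if",
    "calibrate_logistic",
    "spline_estimate",
    "spline_update",
    "IF_REGISTRY",
    "make_if",
]

# Open-interval guard: expit saturates to exactly 0.0/1.0 in float64 for
# |k (x - x0)| beyond ~±745; nudge back inside (0, 1).
_ONE_MINUS = float(np.nextafter(1.0, 0.0))
_TINY = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class LogisticParams:
    """Steepness ``k`` (per PLLS unit) and midpoint ``x0`` (PLLS units).

    The shipped defaults are the high-content-screening preset: a PLLS of
    -1.4 maps to score 0.5, with the transition essentially complete within
    about +-1 PLLS unit of the midpoint.  In practice ``k`` and ``x0`` are
    calibrated per modality from a sample of pre-images.
    """

    k: float = 4.5
    x0: float = -1.4

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and math.isfinite(self.x0)):
            raise ValueError("logistic parameters must be finite")


def logistic_if(x: float, params: LogisticParams = LogisticParams()) -> float:
    """Logistic interestingness score of a scalar feature value.

    Strictly increasing in ``x`` for ``k > 0``; output lies in the open
    interval (0, 1).
    """
    if not math.isfinite(x):
        raise ValueError(f"feature value must be finite, got {x!r}")
    score = float(expit(params.k * (x - params.x0)))
    return min(max(score, _TINY), _ONE_MINUS)


def calibrate_logistic(
    plls_low_quality, plls_high_quality, spread: float = 3.0
) -> LogisticParams:
    """Fit logistic parameters to a calibration sample of pre-images.

    PLLS values depend on modality (magnification, staining, exposure), so
    the midpoint and steepness are set from reference images: ``x0`` is the
    midpoint between the mean PLLS of a clearly low-quality (out-of-focus)
    sample and a clearly high-quality (in-focus) one, and ``k`` is chosen
    so each reference mean maps to ``expit(+-spread)`` (0.95 / 0.05 at the
    default spread of 3).
    """
    lo = float(np.mean(plls_low_quality))
    hi = float(np.mean(plls_high_quality))
    if not (math.isfinite(lo) and math.isfinite(hi)) or hi <= lo:
        raise ValueError(
            f"calibration requires mean high-quality PLLS > mean low-quality PLLS, got {hi} <= {lo}"
        )
    x0 = 0.5 * (lo + hi)
    k = spread / (hi - x0)
    return LogisticParams(k=k, x0=x0)


class EmptySplineError(ValueError):
    """Estimate requested from a spline model with no knots."""


@dataclass(frozen=True)
class SplineModel:
    """Piecewise-linear interpolant over (index, rho) knots.

    ``rho`` is the normalized size reduction (bytes saved per CPU-second)
    observed when pre-processing the image at a given stream index.  The
    model is immutable: updates return a new model.  Outside the knot range
    the estimate clamps to the nearest knot's value, which avoids negative
    or explosive linear extrapolation.
    """

    indices: tuple[float, ...] = field(default=())
    rhos: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.rhos):
            raise ValueError("indices and rhos must have equal length")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("knot indices must be strictly increasing")
        if any(r < 0 for r in self.rhos):
            raise ValueError("rho values must be non-negative")

    @property
    def n_knots(self) -> int:
        return len(self.indices)

    def estimate(self, index: float) -> float:
        return spline_estimate(self, index)

    def with_knot(self, index: float, rho: float) -> "SplineModel":
        return spline_update(self, index, rho)


def spline_estimate(model: SplineModel, index: float) -> float:
    """Linear interpolation between bracketing knots; clamped outside the range."""
    if model.n_knots == 0:
        raise EmptySplineError("spline model has no knots")
    # np.interp clamps to the end values outside [indices[0], indices[-1]].
    return float(np.interp(index, model.indices, model.rhos))


def spline_update(model: SplineModel, index: float, observed_rho: float) -> SplineModel:
    """Insert a knot (replacing any existing knot at the same index).

    Replacement rather than averaging: the latest measurement reflects the
    current cost/reduction of the operator on that part of the sweep.
    """
    if not math.isfinite(index):
        raise ValueError("knot index must be finite")
    if not math.isfinite(observed_rho) or observed_rho < 0:
        raise ValueError(f"observed rho must be finite and >= 0, got {observed_rho!r}")
    pairs = dict(zip(model.indices, model.rhos))
    pairs[float(index)] = float(observed_rho)
    items = sorted(pairs.items())
    return SplineModel(
        indices=tuple(i for i, _ in items),
        rhos=tuple(r for _, r in items),
    )


def _make_logistic(params: dict) -> "callable":
    p = LogisticParams(**params) if params else LogisticParams()

    def _if(features) -> float:
        return logistic_if(features.plls, p)

    return _if


def _make_spline(params: dict) -> "callable":
    model = SplineModel(
        indices=tuple(params.get("indices", ())),
        rhos=tuple(params.get("rhos", ())),
    )

    def _if(index: float) -> float:
        return spline_estimate(model, index)

    return _if


#: Registry for config-driven binding: name -> factory(params dict) -> callable.
IF_REGISTRY = {
    "logistic": _make_logistic,
    "spline": _make_spline,
}


def make_if(name: str, params: dict | None = None):
    """Instantiate a registered interestingness function by name."""
    try:
        factory = IF_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown interestingness function {name!r}; known: {sorted(IF_REGISTRY)}"
        ) from None
    return factory(params or {})
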