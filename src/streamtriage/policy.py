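"""Policies that turn an interestingness score into a storage-tier placement.

A policy is an ordered list of contiguous score intervals over [0, 1], each
mapped to a named tier.  Tiers are filesystem directories (plus a special
trash kind); placing an object in a tier relocates its payload file.

Boundary convention: bins are lower-inclusive and upper-exclusive, except
the top bin which is closed above, so every score in [0, 1] maps to exactly
one tier.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Policy",
    "Tier",
    "PolicyValidationError",
    "PlacementError",
    "DEFAULT_QUARTER_POLICY",
    "validate_policy",
    "assign_tier",
    "place_in_tier",
]

_EPS = 1e-12


class PolicyValidationError(ValueError):
    """Invalid policy; ``reason`` is one of 'reversed', 'overlap', 'gap',
    'coverage', 'unknown_tier', 'empty'."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


class PlacementError(OSError):
    """Payload could not be placed in the target tier; object left in place."""


@dataclass(frozen=True)
class Policy:
    """Ordered (lower, upper, tier_id) bins partitioning the score domain [0, 1]."""

    bins: tuple[tuple[float, float, str], ...]

    def __init__(self, bins: Iterable[tuple[float, float, str]]):
        object.__setattr__(
            self, "bins", tuple((float(lo), float(hi), str(t)) for lo, hi, t in bins)
        )

    @property
    def tier_ids(self) -> tuple[str, ...]:
        return tuple(t for _, _, t in self.bins)


#: The quarter-interval preset used with the logistic focus IF: the most
#: in-focus images (score >= 0.75) land in tierA, the worst in tierD.
DEFAULT_QUARTER_POLICY = Policy(
    [
        (0.00, 0.25, "tierD"),
        (0.25, 0.50, "tierC"),
        (0.50, 0.75, "tierB"),
        (0.75, 1.00, "tierA"),
    ]
)


@dataclass(frozen=True)
class Tier:
    """One level of the storage hierarchy: a directory, or the trash destination."""

    tier_id: str
    kind: str = "directory"  # "directory" | "trash"
    path: Path | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("directory", "trash"):
            raise ValueError(f"tier kind must be 'directory' or 'trash', got {self.kind!r}")
        if self.path is not None:
            object.__setattr__(self, "path", Path(self.path))


def validate_policy(policy: Policy, tiers: Mapping[str, Tier] | Iterable[str]) -> Policy:
    """Check that the bins contiguously partition [0, 1] onto known tiers.

    Returns the policy unchanged if valid; otherwise raises
    :class:`PolicyValidationError` with a distinct ``reason`` diagnostic for
    reversed intervals, overlaps, gaps, incomplete coverage of [0, 1], and
    undeclared tier ids.
    """
    known = set(tiers.keys() if isinstance(tiers, Mapping) else tiers)
    if not policy.bins:
        raise PolicyValidationError("empty", "policy has no bins")
    for lo, hi, tier_id in policy.bins:
        if hi <= lo:
            raise PolicyValidationError(
                "reversed", f"reversed or empty interval [{lo}, {hi}) -> {tier_id}"
            )
        if tier_id not in known:
            raise PolicyValidationError(
                "unknown_tier", f"bin [{lo}, {hi}) maps to undeclared tier {tier_id!r}"
            )
    if abs(policy.bins[0][0]) > _EPS or abs(policy.bins[-1][1] - 1.0) > _EPS:
        raise PolicyValidationError(
            "coverage",
            f"bins must span [0, 1]; got [{policy.bins[0][0]}, {policy.bins[-1][1]}]",
        )
    for (_, hi, ta), (lo, _, tb) in zip(policy.bins, policy.bins[1:]):
        if lo < hi - _EPS:
            raise PolicyValidationError(
                "overlap", f"bins for {ta!r} and {tb!r} overlap at {lo} < {hi}"
            )
        if lo > hi + _EPS:
            raise PolicyValidationError(
                "gap", f"gap between {ta!r} (up to {hi}) and {tb!r} (from {lo})"
            )
    return policy


def assign_tier(score: float, policy: Policy) -> str:
    """Map a score in [0, 1] to the unique tier whose bin contains it.

    Bins are [lower, upper) except the last, which is [lower, 1].
    """
    if not math.isfinite(score) or score < 0.0 or score > 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score!r}")
    for i, (lo, hi, tier_id) in enumerate(policy.bins):
        last = i == len(policy.bins) - 1
        if (lo <= score < hi) or (last and lo <= score <= hi):
            return tier_id
    raise ValueError(f"score {score} not covered by policy (was it validated?)")


def _disambiguate(target: Path) -> Path:
    """Append -1, -2, ... before the suffix until the name is free."""
    if not target.exists():
        return target
    stem, suffix = target.stem, target.suffix
    n = 1
    while True:
        candidate = target.with_name(f"{stem}-{n}{suffix}")
        if not candidate.exists():
            return candidate
        n += 1


def place_in_tier(
    payload_path: str | Path,
    tier: Tier,
    *,
    trash_dir: str | Path | None = None,
    copy: bool = False,
) -> Path:
    """Relocate (or copy) a payload file into its assigned tier.

    Directory tiers preserve the filename; a name collision is resolved with
    a numeric suffix so no object is ever overwritten.  Trash placement
    moves the file into ``trash_dir`` (it is retained, not deleted, so a
    mis-tuned policy is recoverable).  Returns the final path.
    """
    src = Path(payload_path)
    if not src.exists():
        raise PlacementError(f"payload {src} does not exist")
    if tier.kind == "trash":
        dest_dir = Path(trash_dir) if trash_dir is not None else (tier.path or Path("trash"))
    else:
        if tier.path is None:
            raise PlacementError(f"directory tier {tier.tier_id!r} has no path")
        dest_dir = tier.path
    try:
        dest_dir.mkdir(parents=True, exist_ok=True)
        target = _disambiguate(dest_dir / src.name)
        if copy:
            shutil.copy2(src, target)
        else:
            shutil.move(str(src), str(target))
    except OSError as exc:
        raise PlacementError(
            f"cannot place {src.name} in tier {tier.tier_id!r}: {exc}"
        ) from exc
    return target
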