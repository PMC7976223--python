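"""Structured configuration for the triage pipeline and edge scenarios.

The pipeline config (YAML or JSON) declares the tiers, the interestingness
function and its parameters, the policy intervals, and the image filename
pattern, e.g.::

    stream_id: plate-42
    pattern: "*.tiff"
    copy: false
    interestingness:
      name: logistic
      params: {k: 4.5, x0: -1.4}
    tiers:
      tierA: tiers/A
      tierB: tiers/B
      tierC: tiers/C
      tierD: tiers/D
    policy:
      - [0.00, 0.25, tierD]
      - [0.25, 0.50, tierC]
      - [0.50, 0.75, tierB]
      - [0.75, 1.00, tierA]
    trash_dir: trash
    quarantine_dir: quarantine

A tier whose value is the string ``trash`` becomes the trash destination.
Edge scenarios use a flat schema of per-image rows plus channel parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .edge import EdgeImage, SimScenario
from .interest import make_if
from .pipeline import PipelineConfig
from .policy import Policy, Tier, validate_policy

__all__ = ["load_pipeline_config", "load_scenario", "save_scenario"]


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_pipeline_config(path: str | Path, base_dir: str | Path | None = None) -> tuple[PipelineConfig, str]:
    """Build a validated :class:`PipelineConfig` from a YAML/JSON file.

    Relative tier/trash/quarantine paths are resolved against ``base_dir``
    (default: the config file's directory).  Returns the config and the
    declared stream id (empty string if none).
    """
    raw = _load_structured(path)
    base = Path(base_dir) if base_dir is not None else Path(path).parent

    tiers: dict[str, Tier] = {}
    for tier_id, value in raw["tiers"].items():
        if value == "trash":
            tiers[tier_id] = Tier(tier_id, kind="trash", path=base / raw.get("trash_dir", "trash"))
        else:
            tiers[tier_id] = Tier(tier_id, kind="directory", path=base / value)
    policy = validate_policy(Policy(raw["policy"]), tiers)

    if_cfg = raw.get("interestingness", {"name": "logistic"})
    if_fn = make_if(if_cfg["name"], if_cfg.get("params"))

    config = PipelineConfig(
        if_fn=if_fn,
        policy=policy,
        tiers=tiers,
        trash_dir=base / raw.get("trash_dir", "trash"),
        quarantine_dir=base / raw.get("quarantine_dir", "quarantine"),
        copy=bool(raw.get("copy", False)),
    )
    # Tier directories auto-created so a fresh config is runnable as-is.
    for tier in tiers.values():
        if tier.path is not None:
            tier.path.mkdir(parents=True, exist_ok=True)
    return config, str(raw.get("stream_id", ""))


def load_scenario(path: str | Path) -> SimScenario:
    """Read an edge scenario from a YAML/JSON file."""
    raw = _load_structured(path)
    images = [
        EdgeImage(
            index=int(row["index"]),
            size_bytes=int(row["size_bytes"]),
            cpu_cost=float(row["cpu_cost_s"]),
            arrival=float(row.get("arrival_s", 0.0)),
            true_reduction_bytes=int(row.get("true_reduction_bytes", 0)),
        )
        for row in raw["images"]
    ]
    return SimScenario(
        images=images,
        bandwidth=float(raw["bandwidth_Bps"]),
        rho_min=float(raw.get("rho_min", 0.0)),
        exploration_gap=raw.get("exploration_gap"),
        seed=int(raw.get("seed", 0)),
    )


def save_scenario(scenario: SimScenario, path: str | Path) -> None:
    """Write a scenario in the same structured schema ``load_scenario`` reads."""
    raw = {
        "bandwidth_Bps": scenario.bandwidth,
        "rho_min": scenario.rho_min,
        "exploration_gap": scenario.exploration_gap,
        "seed": scenario.seed,
        "images": [
            {
                "index": im.index,
                "size_bytes": im.size_bytes,
                "true_reduction_bytes": im.true_reduction_bytes,
                "cpu_cost_s": im.cpu_cost,
                "arrival_s": im.arrival,
            }
            for im in scenario.images
        ],
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
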