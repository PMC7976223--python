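"""Deterministic synthetic data: defocused fluorescence images, occluded TEM
sweeps, and edge-upload scenarios.

Every generator is a pure function of its parameters and seed: re-running
with the same arguments yields byte-identical images and manifests.  The
manifests record the full ground truth (blur sigma, occlusion fraction,
...), so tests never need to re-derive it from pixels.

The fluorescence generator emulates a high-content-screening stream: bright
cell-like blobs and fine sample texture on a dark background, defocused by
a Gaussian blur of known sigma, then read out with faint sensor noise and
16-bit quantization.  Texture and noise are applied *before* the defocus
kernel, so the power spectrum of a blurred image is exactly the sharp
spectrum times the kernel's transfer function — which makes the PLLS focus
score provably monotone in sigma.  The TEM generator emulates a sweep over
a honeycomb support grid: a dark, noisy occlusion mask whose area fraction
oscillates smoothly with image index, over a bright textured sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .edge import EdgeImage, SimScenario

__all__ = [
    "HcsGroundTruth",
    "TemGroundTruth",
    "generate_hcs_images",
    "generate_tem_sweep",
    "generate_edge_scenario",
    "tem_occlusion_profile",
    "SCENARIO_FAMILIES",
]


@dataclass(frozen=True)
class HcsGroundTruth:
    """Ground truth for one synthetic fluorescence image."""

    image_id: str
    blur_sigma: float
    n_cells: int
    seed: int


@dataclass(frozen=True)
class TemGroundTruth:
    """Ground truth for one synthetic TEM sweep image."""

    index: int
    occlusion_fraction: float
    period: float
    phase: float
    seed: int


# ---------------------------------------------------------------------------
# High-content-screening images with controlled defocus
# ---------------------------------------------------------------------------

def _hcs_image(
    rng: np.random.Generator,
    sigma: float,
    image_size: tuple[int, int],
    spot_sigma: float,
    n_cells_range: tuple[int, int],
    texture_sd: float,
    background: float,
    read_noise_sd: float,
) -> tuple[np.ndarray, int]:
    h, w = image_size
    n_cells = int(rng.integers(n_cells_range[0], n_cells_range[1] + 1))
    impulses = np.zeros((h, w))
    ys = rng.integers(0, h, n_cells)
    xs = rng.integers(0, w, n_cells)
    amps = rng.uniform(0.4, 1.0, n_cells)
    np.add.at(impulses, (ys, xs), amps)
    # Gaussian spots with unit peak amplitude per impulse.
    cells = gaussian_filter(impulses, spot_sigma) * (2.0 * math.pi * spot_sigma**2)
    texture = rng.normal(0.0, texture_sd, (h, w))
    sharp = background + cells + texture
    blurred = gaussian_filter(sharp, sigma) if sigma > 0 else sharp
    noisy = blurred + rng.normal(0.0, read_noise_sd, (h, w))
    img = np.clip(noisy, 0.0, 1.0)
    return np.round(img * 65535.0).astype(np.uint16), n_cells


def generate_hcs_images(
    n_per_level: int,
    sigmas: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0),
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    out_dir: str | Path | None = None,
    *,
    spot_sigma: float = 1.2,
    n_cells_range: tuple[int, int] = (20, 40),
    texture_sd: float = 0.02,
    background: float = 0.05,
    read_noise_sd: float = 0.5 / 65535.0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate ``n_per_level`` 16-bit fluorescence images per blur level.

    Defaults: 256x256 frames, 20-40 Gaussian cell spots of sigma 1.2 px,
    fine sample texture (sd 0.02 of full scale) that gives the sharp images
    a shallow spectral fall-off, and sensor read noise of about half a
    16-bit count.  Returns the images plus a manifest with one row per
    image; when ``out_dir`` is given, also writes ``<image_id>.tiff`` files
    and ``manifest.csv``.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    if any(s < 0 for s in sigmas):
        raise ValueError("blur sigmas must be >= 0")
    if image_size[0] < 16 or image_size[1] < 16:
        raise ValueError("image_size must be at least 16x16")

    images: list[np.ndarray] = []
    rows: list[dict] = []
    for level, sigma in enumerate(sigmas):
        for i in range(n_per_level):
            rng = np.random.default_rng([seed, level, i])
            img, n_cells = _hcs_image(
                rng, float(sigma), image_size, spot_sigma, n_cells_range,
                texture_sd, background, read_noise_sd,
            )
            image_id = f"hcs_s{level}_{i:04d}"
            images.append(img)
            rows.append(
                {
                    "image_id": image_id,
                    "filename": f"{image_id}.tiff",
                    "blur_sigma": float(sigma),
                    "n_cells": n_cells,
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, rows):
            tifffile.imwrite(out / row["filename"], img)
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest


# ---------------------------------------------------------------------------
# TEM sweep with honeycomb occlusion
# ---------------------------------------------------------------------------

def tem_occlusion_profile(
    t: np.ndarray | float,
    a0: float = 0.3,
    a1: float = 0.2,
    period: float = 32.0,
    drift: float = 0.0,
    phase: float = 0.0,
) -> np.ndarray | float:
    """Occluded area fraction g(t) = clip(a0 + a1 sin(2 pi t / period + phase)
    + drift * t, 0, 1): a smooth oscillation (grid movement) with slow drift."""
    g = a0 + a1 * np.sin(2.0 * math.pi * np.asarray(t, dtype=float) / period + phase) + drift * np.asarray(t, dtype=float)
    return np.clip(g, 0.0, 1.0)


def _hex_distance_field(
    image_size: tuple[int, int], pitch: float, offset: tuple[float, float]
) -> np.ndarray:
    """Distance from each pixel to the nearest hexagonal-lattice center.

    Thresholding this field at a high quantile selects the pixels farthest
    from any lattice center — the web of walls between hexagonal cells,
    i.e. a honeycomb mask.
    """
    from scipy.spatial import cKDTree

    h, w = image_size
    dy = pitch * math.sqrt(3.0) / 2.0
    centers = []
    row = 0
    y = -pitch + offset[0] % (2 * dy)
    while y < h + pitch:
        shift = (pitch / 2.0) if row % 2 else 0.0
        x = -pitch + (offset[1] + shift) % pitch
        while x < w + pitch:
            centers.append((y, x))
            x += pitch
        y += dy
        row += 1
    tree = cKDTree(np.asarray(centers))
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    dist, _ = tree.query(pts)
    return dist.reshape(h, w)


def generate_tem_sweep(
    n_images: int,
    a0: float = 0.3,
    a1: float = 0.2,
    period: float = 32.0,
    drift: float = 0.0,
    phase: float = 0.0,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    out_dir: str | Path | None = None,
    *,
    pitch: float = 56.0,
    grid_speed: tuple[float, float] = (2.3, 4.1),
    blocked_noise_max: int = 45,
    block_threshold: int = 50,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate an 8-bit PNG-style TEM sweep of ``n_images`` frames.

    Frame ``t`` shows a bright textured sample (all pixels at or above
    ``block_threshold``) occluded by a honeycomb mask covering exactly the
    fraction ``g(t)`` of the frame (to one pixel), filled with high-variance
    near-black noise in ``[0, blocked_noise_max)``.  The noise makes
    blocked regions compress poorly, so flattening them to 0 shrinks the
    encoded size roughly in proportion to the occluded area.  The lattice
    offset advances by ``grid_speed`` pixels per frame, emulating the
    sample holder moving over the grid.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not (0 < blocked_noise_max < block_threshold):
        raise ValueError("blocked_noise_max must lie in (0, block_threshold)")
    h, w = image_size
    images: list[np.ndarray] = []
    rows: list[dict] = []
    for t in range(n_images):
        g = float(tem_occlusion_profile(t, a0, a1, period, drift, phase))
        rng = np.random.default_rng([seed, 7, t])
        # smooth bright sample texture, floored safely above the block threshold
        texture = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 4.0) * 200.0
        bg = np.clip(140.0 + texture, float(block_threshold + 10), 255.0).astype(np.uint8)
        offset = (grid_speed[0] * t, grid_speed[1] * t)
        dist = _hex_distance_field(image_size, pitch, offset)
        n_blocked = int(round(g * h * w))
        mask = np.zeros(h * w, dtype=bool)
        if n_blocked > 0:
            order = np.argsort(dist.ravel(), kind="stable")
            mask[order[-n_blocked:]] = True
        mask = mask.reshape(h, w)
        noise = rng.integers(0, blocked_noise_max, (h, w)).astype(np.uint8)
        img = np.where(mask, noise, bg)
        measured = float(np.mean(img < block_threshold))
        image_id = f"tem_{t:04d}"
        images.append(img)
        rows.append(
            {
                "index": t,
                "filename": f"{image_id}.png",
                "occlusion_fraction": g,
                "measured_dark_fraction": measured,
                "a0": a0,
                "a1": a1,
                "period": period,
                "drift": drift,
                "phase": phase,
                "seed": seed,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, rows):
            Image.fromarray(img, mode="L").save(
                out / row["filename"], format="PNG", compress_level=6, optimize=False
            )
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest


# ---------------------------------------------------------------------------
# Edge-upload scenarios
# ---------------------------------------------------------------------------

SCENARIO_FAMILIES = (
    "random",
    "favorable",
    "all-zero-reduction",
    "process-all-pathology",
    "sweep",
)


def generate_edge_scenario(
    n: int,
    family: str = "random",
    seed: int = 0,
    bandwidth: float = 1e6,
    rho_min: float = 0.0,
    exploration_gap: float | None = None,
) -> SimScenario:
    """Reproducible edge-upload scenario from a named instance family.

    * ``random`` — sizes 2-12 MB, reductions 0-80% of size, CPU costs
      0.5-3 s, staggered arrivals; general-purpose stress instances.
    * ``favorable`` — half the images have large (80%) cheap (0.1-0.2 s)
      reductions, half none; all arrive at t=0.  Processing should always
      pay off here.
    * ``all-zero-reduction`` — processing can never help.
    * ``process-all-pathology`` — tiny reductions (2% of size) at a CPU
      cost exceeding the per-image upload time, so processing everything
      serializes on the CPU and inflates the makespan.
    * ``sweep`` — reductions follow the oscillating TEM occlusion profile
      g(t), emulating the sweep the spline model is designed for.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if family not in SCENARIO_FAMILIES:
        raise ValueError(f"unknown family {family!r}; known: {SCENARIO_FAMILIES}")
    rng = np.random.default_rng([seed, 11])
    images: list[EdgeImage] = []
    if family == "random":
        sizes = rng.integers(2_000_000, 12_000_000, n)
        fracs = rng.uniform(0.0, 0.8, n)
        cpus = rng.uniform(0.5, 3.0, n)
        arrivals = np.sort(rng.uniform(0.0, 1.5 * n, n))
        for i in range(n):
            images.append(
                EdgeImage(
                    index=i,
                    size_bytes=int(sizes[i]),
                    cpu_cost=float(cpus[i]),
                    arrival=float(arrivals[i]),
                    true_reduction_bytes=int(sizes[i] * fracs[i]),
                )
            )
    elif family == "favorable":
        sizes = rng.integers(4_000_000, 8_000_000, n)
        cpus = rng.uniform(0.05, 0.2, n)
        for i in range(n):
            big = i % 2 == 0
            images.append(
                EdgeImage(
                    index=i,
                    size_bytes=int(sizes[i]),
                    cpu_cost=float(cpus[i]),
                    arrival=0.0,
                    true_reduction_bytes=int(0.8 * sizes[i]) if big else 0,
                )
            )
    elif family == "all-zero-reduction":
        sizes = rng.integers(2_000_000, 12_000_000, n)
        cpus = rng.uniform(0.5, 3.0, n)
        for i in range(n):
            images.append(
                EdgeImage(
                    index=i,
                    size_bytes=int(sizes[i]),
                    cpu_cost=float(cpus[i]),
                    arrival=0.0,
                    true_reduction_bytes=0,
                )
            )
    elif family == "process-all-pathology":
        sizes = rng.integers(4_000_000, 6_000_000, n)
        for i in range(n):
            upload_time = sizes[i] / bandwidth
            images.append(
                EdgeImage(
                    index=i,
                    size_bytes=int(sizes[i]),
                    cpu_cost=float(2.0 * upload_time),
                    arrival=0.0,
                    true_reduction_bytes=int(0.02 * sizes[i]),
                )
            )
    else:  # sweep
        sizes = rng.integers(4_000_000, 8_000_000, n)
        cpus = rng.uniform(0.5, 1.5, n)
        g = np.asarray(tem_occlusion_profile(np.arange(n)))
        arrivals = 0.5 * np.arange(n)
        for i in range(n):
            images.append(
                EdgeImage(
                    index=i,
                    size_bytes=int(sizes[i]),
                    cpu_cost=float(cpus[i]),
                    arrival=float(arrivals[i]),
                    true_reduction_bytes=int(0.85 * g[i] * sizes[i]),
                )
            )
    return SimScenario(
        images=images,
        bandwidth=bandwidth,
        rho_min=rho_min,
        exploration_gap=exploration_gap,
        seed=seed,
    )
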