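"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the
naive PLLS oracle builds the full periodogram, bins it with explicit
masking, and fits the line with an explicit normal-equations solve, so
agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


def naive_plls(image: np.ndarray, fit_range=(0.02, 0.12), n_bins: int = 64):
    """Brute-force PLLS: explicit periodogram, binning, and least squares."""
    arr = np.asarray(image, dtype=float)
    ny, nx = arr.shape
    x = arr - arr.mean()
    F = np.fft.fft2(x)
    P = (F * np.conj(F)).real / (ny * nx)

    freqs = []
    powers = []
    for iy in range(ny):
        fy = iy / ny if iy <= ny // 2 else iy / ny - 1.0
        for ix in range(nx):
            fx = ix / nx if ix <= nx // 2 else ix / nx - 1.0
            r = math.hypot(fy, fx)
            if 0.0 < r <= 0.5:
                freqs.append(r)
                powers.append(P[iy, ix])
    freqs = np.asarray(freqs)
    powers = np.asarray(powers)

    f_min = min(1.0 / ny, 1.0 / nx)
    edges = np.geomspace(f_min * (1.0 - 1e-9), 0.5, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mean_f = []
    mean_p = []
    for b in range(n_bins):
        if b < n_bins - 1:
            in_bin = (freqs >= edges[b]) & (freqs < edges[b + 1])
        else:
            in_bin = (freqs >= edges[b]) & (freqs <= edges[b + 1])
        if np.any(in_bin):
            mean_f.append(centers[b])
            mean_p.append(powers[in_bin].mean())
    mean_f = np.asarray(mean_f)
    mean_p = np.asarray(mean_p)

    sel = (mean_f >= fit_range[0]) & (mean_f <= fit_range[1]) & (mean_p > 0)
    lx = np.log10(mean_f[sel])
    ly = np.log10(mean_p[sel])
    # explicit normal equations for the OLS slope
    mx, my = lx.mean(), ly.mean()
    return float(((lx - mx) * (ly - my)).sum() / ((lx - mx) ** 2).sum())


def powerlaw_field(beta: float, n: int = 256, seed: int = 0) -> np.ndarray:
    """Random-phase field with isotropic power spectrum proportional to f^-beta."""
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.hypot(fy, fx)
    r[0, 0] = 1.0
    amp = r ** (-beta / 2.0)
    amp[0, 0] = 0.0
    phases = rng.uniform(0.0, 2.0 * math.pi, (n, n))
    return np.real(np.fft.ifft2(amp * np.exp(1j * phases)))


@pytest.fixture()
def tier_layout(tmp_path):
    """Four directory tiers + trash + quarantine under a tmp root."""
    from streamtriage import DEFAULT_QUARTER_POLICY, PipelineConfig, Tier
    from streamtriage.interest import LogisticParams, logistic_if

    tiers = {
        t: Tier(t, kind="directory", path=tmp_path / "tiers" / t[-1])
        for t in ("tierA", "tierB", "tierC", "tierD")
    }
    for tier in tiers.values():
        tier.path.mkdir(parents=True)
    config = PipelineConfig(
        if_fn=lambda fv: logistic_if(fv.plls, LogisticParams()),
        policy=DEFAULT_QUARTER_POLICY,
        tiers=tiers,
        trash_dir=tmp_path / "trash",
        quarantine_dir=tmp_path / "quarantine",
    )
    return tmp_path, config
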