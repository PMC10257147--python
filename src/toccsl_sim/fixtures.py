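"""Synthetic input generators.

The bleach-curve generator emulates a stroboscopic photobleaching
measurement (a sequence of short illumination pulses, brightness integrated
per frame and normalized): it evaluates the biexponential decay on the
cumulative illumination-time axis and adds Gaussian measurement noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_bleach_curve_fixture"]


def generate_bleach_curve_fixture(
    alpha: float = 235.0,
    beta: float = 30.0,
    A: float = 0.782,
    B: float = 0.218,
    n_frames: int = 200,
    frame_illumination_ms: float = 1.0,
    noise_sd: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Synthetic normalized bleach curve on a cumulative illumination axis.

    Returns a two-column frame ``(time_s, normalized_brightness)`` with
    ``time_s[k] = (k + 1) * frame_illumination_ms / 1000`` and brightness
    ``A exp(-alpha t) + B exp(-beta t)`` (equal to 1 at zero illumination
    for normalized weights) plus optional i.i.d. Gaussian noise.
    """
    if min(alpha, beta, A, B, n_frames, frame_illumination_ms) <= 0:
        raise ValueError("all curve parameters must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = (np.arange(1, n_frames + 1) * frame_illumination_ms) / 1000.0
    b = A * np.exp(-alpha * t) + B * np.exp(-beta * t)
    if noise_sd > 0:
        b = b + np.random.default_rng(seed).normal(0.0, noise_sd, size=b.shape)
    return pd.DataFrame({"time_s": t, "normalized_brightness": b})
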