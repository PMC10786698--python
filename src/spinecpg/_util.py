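"""Small shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_sigfigs(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def format_percent(x: float, sig: int = 3) -> str:
    """Format a percentage at ``sig`` significant figures, e.g. ``'11.9%'``."""
    return f"{round_sigfigs(x, sig):g}%"


def mad_sigma(x: np.ndarray) -> float:
    """Robust noise SD: 1.4826 x median absolute deviation from the median."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def diff_mad_sigma(x: np.ndarray) -> float:
    """Robust noise SD from first differences: MAD-scaled and divided by
    sqrt(2), insensitive to slow transients riding on the noise."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of an empty signal is undefined")
    return float(np.sqrt(np.mean(x**2)))


def cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2D vectors (broadcasting)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
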