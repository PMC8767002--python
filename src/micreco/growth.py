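"""Growth indices for per-fish records.

Fulton's condition factor ``K = 1000 * BW / BL^3`` (BW in grams, BL in cm)
and the daily growth coefficient
``DGC = 100 * (BW_f^(1/3) - BW_i^(1/3)) / t`` (% per day).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["fulton_k", "dgc", "growth_summary"]


def fulton_k(bw, bl):
    """Fulton's body condition factor, 10^3-scaled. Inputs must be positive."""
    bw = np.asarray(bw, dtype=float)
    bl = np.asarray(bl, dtype=float)
    if np.any(bw <= 0) or np.any(bl <= 0):
        raise ValueError("body weight and body length must be positive")
    out = 1000.0 * bw / bl**3
    return float(out) if out.ndim == 0 else out


def dgc(bw_f, bw_i, t):
    """Daily growth coefficient (% per day) from initial/final weight over t days.

    A final weight below the initial weight returns a negative DGC with a
    warning rather than an error (fish can lose condition).
    """
    bw_f = np.asarray(bw_f, dtype=float)
    bw_i = np.asarray(bw_i, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("elapsed days must be positive")
    if np.any(bw_i <= 0):
        raise ValueError("initial weight must be positive")
    if np.any(bw_f < bw_i):
        warnings.warn("final weight below initial weight: negative DGC", stacklevel=2)
    out = (bw_f ** (1.0 / 3.0) - bw_i ** (1.0 / 3.0)) / t * 100.0
    return float(out) if out.ndim == 0 else out


def growth_summary(records: pd.DataFrame, by: str = "sex") -> pd.DataFrame:
    """Per-group mean +/- SE of DGC and Fulton's K from tidy per-fish records.

    Expects columns ``body_weight_g``, ``body_length_cm``, ``initial_weight_g``
    and ``elapsed_days``.
    """
    df = records.copy()
    df["dgc"] = dgc(df["body_weight_g"], df["initial_weight_g"], df["elapsed_days"])
    df["fulton_k"] = fulton_k(df["body_weight_g"], df["body_length_cm"])
    grouped = df.groupby(by)[["dgc", "fulton_k"]]
    mean = grouped.mean()
    se = grouped.sem()
    out = mean.join(se, lsuffix="_mean", rsuffix="_se")
    out["n"] = grouped.size()
    return out
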