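"""Three-ROI FRAP normalization and mono-exponential recovery fitting.

A FRAP experiment records three regions of interest over time: the bleached
spot I(t), a background region outside the cell I_b(t), and a whole-cell
reference I_sb(t) that tracks acquisition photobleaching.  The bleached
trace is normalized as

    In(t) = [I(t) - I_b(t)] / [I_sb(t) - I_b(t)]

(by default the background is also subtracted from the reference — without
it the recovery plateau is biased low by the camera offset; the literal
``[I - I_b]/I_sb`` form is available via ``subtract_background_from_reference
=False``), then rescaled so the pre-bleach mean equals 1 so that fit
parameters read as fractions of the pre-bleach signal.

The post-bleach recovery is fitted with ``A - B*exp(-k*t)`` (t = 0 at the
first post-bleach frame).  Derived quantities: half-time tau_1/2 = ln(2)/k,
mobile fraction = B and immobile fraction = 1 - A (as conventionally
reported with these symbols; note they need not sum to 1), plus the
alternative normalization B/(1 - (A - B)) reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "FrapTrace",
    "FrapFit",
    "normalize_trace",
    "fit_recovery",
    "detect_bleach_index",
    "read_frap_csv",
]

LN2 = math.log(2.0)


@dataclass
class FrapTrace:
    """Raw three-ROI FRAP time series.

    ``bleach_index`` is the index of the first post-bleach frame.
    """

    time_s: np.ndarray
    i_bleach: np.ndarray
    i_background: np.ndarray
    i_cell: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.i_bleach = np.asarray(self.i_bleach, dtype=float)
        self.i_background = np.asarray(self.i_background, dtype=float)
        self.i_cell = np.asarray(self.i_cell, dtype=float)
        n = self.time_s.size
        if not (self.i_bleach.size == self.i_background.size == self.i_cell.size == n):
            raise ValueError("all series must have equal length")
        if n >= 2 and not (np.diff(self.time_s) > 0).all():
            raise ValueError("time_s must be strictly increasing")
        if not 1 <= self.bleach_index < n:
            raise ValueError("bleach_index must be in [1, n_frames)")


def detect_bleach_index(i_bleach) -> int:
    """First post-bleach frame, detected as the largest single-frame drop."""
    i_bleach = np.asarray(i_bleach, dtype=float)
    drops = np.diff(i_bleach)
    return int(np.argmin(drops)) + 1


def normalize_trace(
    trace: FrapTrace, subtract_background_from_reference: bool = True
) -> np.ndarray:
    """Normalize the bleached-ROI trace against background and sample bleach.

    Raises if the (background-corrected) reference is <= 0 at any frame,
    naming the first offending frame.
    """
    ref = trace.i_cell - (trace.i_background if subtract_background_from_reference else 0.0)
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        raise ValueError(
            f"whole-cell reference is <= 0 at frame {int(bad[0])}; "
            "cannot normalize"
        )
    norm = (trace.i_bleach - trace.i_background) / ref
    pre = norm[: trace.bleach_index]
    pre_mean = pre.mean()
    if pre_mean <= 0:
        raise ValueError("pre-bleach mean is <= 0; cannot rescale")
    return norm / pre_mean


@dataclass
class FrapFit:
    """Fitted mono-exponential recovery A - B*exp(-k*t)."""

    A: float
    B: float
    k: float
    tau_half_s: float
    mobile_fraction: float
    immobile_fraction: float
    mobile_fraction_normalized: float
    rss: float
    converged: bool
    n_postbleach: int

    def model(self, t_post: np.ndarray) -> np.ndarray:
        return self.A - self.B * np.exp(-self.k * np.asarray(t_post, dtype=float))


def _recovery(t, A, B, k):
    return A - B * np.exp(-k * t)


def fit_recovery(
    time_s,
    normalized,
    bleach_index: int,
    max_restarts: int = 3,
    seed: int = 0,
) -> FrapFit:
    """Nonlinear least-squares fit of the post-bleach recovery.

    Time is re-zeroed at the first post-bleach frame.  Initialization:
    A0 = mean of the last 5 frames, B0 = A0 - first post-bleach value,
    k0 = 1/(0.3 x post-bleach span); bounds keep B >= 0 and k > 0.  On
    failure the starting point is jittered up to ``max_restarts`` times
    (seeded); if all attempts fail a non-converged fit built from the
    starting values is returned.
    """
    time_s = np.asarray(time_s, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    if time_s.size != normalized.size:
        raise ValueError("time_s and normalized must have equal length")
    n_post = time_s.size - bleach_index
    if n_post < 10:
        raise ValueError("need at least 10 post-bleach frames")
    t = time_s[bleach_index:] - time_s[bleach_index]
    y = normalized[bleach_index:]

    span = t[-1] - t[0]
    A0 = float(y[-5:].mean())
    B0 = float(max(A0 - y[0], 1e-6))
    k0 = 1.0 / (0.3 * span)
    bounds = ([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf])
    rng = np.random.default_rng(seed)

    p0 = np.array([A0, B0, k0])
    params = None
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(_recovery, t, y, p0=p0, bounds=bounds, maxfev=10000)
            params = popt
            break
        except (RuntimeError, ValueError):
            jitter = 1.0 + 0.5 * rng.standard_normal(3)
            p0 = np.array([A0, B0, k0]) * np.abs(jitter)
            p0[2] = max(p0[2], 1e-6)
            logger.warning("fit_recovery: restart %d with jittered p0", attempt + 1)
    converged = params is not None
    if not converged:
        params = np.array([A0, B0, k0])
        logger.error("fit_recovery: did not converge after %d restarts", max_restarts)
    A, B, k = (float(v) for v in params)
    resid = y - _recovery(t, A, B, k)
    return FrapFit(
        A=A,
        B=B,
        k=k,
        tau_half_s=LN2 / k,
        mobile_fraction=B,
        immobile_fraction=1.0 - A,
        mobile_fraction_normalized=B / (1.0 - (A - B)) if (1.0 - (A - B)) != 0 else float("nan"),
        rss=float((resid**2).sum()),
        converged=converged,
        n_postbleach=int(n_post),
    )


def read_frap_csv(path: str | Path, bleach_index: int | None = None) -> FrapTrace:
    """Read a trace CSV with columns time_s, I_bleach, I_background, I_cell.

    If ``bleach_index`` is not given it is detected as the largest
    single-frame drop of the bleached-ROI trace.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = ["time_s", "I_bleach", "I_background", "I_cell"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"FRAP CSV {path} missing columns: {missing}")
    if bleach_index is None:
        bleach_index = detect_bleach_index(df["I_bleach"].to_numpy())
    return FrapTrace(
        time_s=df["time_s"].to_numpy(),
        i_bleach=df["I_bleach"].to_numpy(),
        i_background=df["I_background"].to_numpy(),
        i_cell=df["I_cell"].to_numpy(),
        bleach_index=bleach_index,
    )
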