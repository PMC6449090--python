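"""FRAP normalization and recovery half-life estimation.

The recovery curve is the bleached-region mean intensity divided by the
unbleached-region mean, normalized so the pre-bleach ratio averages 1 —
dividing by the unbleached region cancels global acquisition photobleaching.
Post-bleach recovery is fit with a single exponential with an immobile
fraction,

    R(t) = (1 - d) + d * m * (1 - exp(-t ln2 / t_half)),

where d is the bleach depth, m the mobile fraction, and t_half the recovery
half-life in seconds.  Time zero is the bleach event; frames are stamped at
their midpoints, so the first post-bleach sample sits at half a frame
interval after the bleach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["FRAPCurve", "FRAPFit", "normalize_frap", "fit_frap"]

_LN2 = np.log(2.0)


@dataclass
class FRAPCurve:
    """Raw FRAP series; ``postbleach`` marks frames after the bleach event."""

    times: np.ndarray
    bleached: np.ndarray
    unbleached: np.ndarray
    postbleach: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.unbleached = np.asarray(self.unbleached, dtype=float)
        self.postbleach = np.asarray(self.postbleach, dtype=bool)
        n = self.times.size
        if not (self.bleached.size == self.unbleached.size
                == self.postbleach.size == n):
            raise ValueError("curve arrays must share one length")
        if np.sum(~self.postbleach) < 2:
            raise ValueError("need at least two pre-bleach frames")
        if np.any(self.bleached < 0) or np.any(self.unbleached < 0):
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FRAPCurve":
        required = {"time_s", "bleached_mean", "unbleached_mean", "postbleach"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing FRAP columns: {sorted(missing)}")
        return cls(
            times=df["time_s"].to_numpy(),
            bleached=df["bleached_mean"].to_numpy(),
            unbleached=df["unbleached_mean"].to_numpy(),
            postbleach=df["postbleach"].to_numpy().astype(bool),
        )


@dataclass
class FRAPFit:
    t_half: float
    t_half_se: float
    tau: float
    depth: float
    mobile: float
    plateau: float
    flags: list = field(default_factory=list)


def normalize_frap(curve: FRAPCurve) -> FRAPCurve:
    """Ratio series bleached/unbleached, scaled so pre-bleach averages 1."""
    if np.any(curve.unbleached == 0):
        raise ValueError("zero unbleached intensity")
    ratio = curve.bleached / curve.unbleached
    pre = ratio[~curve.postbleach]
    norm = ratio / pre.mean()
    return FRAPCurve(
        times=curve.times, bleached=curve.bleached,
        unbleached=curve.unbleached, postbleach=curve.postbleach,
        normalized=norm,
    )


def _recovery(t, t_half, depth, mobile):
    return (1.0 - depth) + depth * mobile * (1.0 - np.exp(-t * _LN2 / t_half))


def fit_frap(curve: FRAPCurve) -> FRAPFit:
    """Least-squares recovery fit on the normalized post-bleach ratio.

    Flags ``no_recovery_within_window`` when the fitted half-life exceeds
    three times the post-bleach span or the recovered amplitude is
    negligible (the stably-incorporated-protein case).
    """
    if curve.normalized is None:
        curve = normalize_frap(curve)
    t = curve.times[curve.postbleach]
    r = curve.normalized[curve.postbleach]
    if t.size < 8:
        raise ValueError("need at least 8 post-bleach frames")
    span = float(t.max() - t.min())

    # model-free recovery check: a flat post-bleach series fits the model
    # degenerately (instant tiny recovery), so compare early vs late quarters
    # against the frame-to-frame noise before trusting fitted parameters
    q = max(t.size // 4, 3)
    rise = float(r[-q:].mean() - r[:q].mean())
    noise_sd = float(np.std(np.diff(r)) / np.sqrt(2.0))
    rise_se = noise_sd * np.sqrt(2.0 / q)
    flat_data = rise < max(3.0 * rise_se, 1e-9)

    depth0 = float(np.clip(1.0 - r.min(), 1e-3, 1.0))
    plateau0 = float(np.mean(r[-max(3, t.size // 10):]))
    mobile0 = float(np.clip((plateau0 - (1.0 - depth0)) / depth0, 1e-3, 1.05))
    # first crossing of half the apparent recoverable amplitude
    half_level = (1.0 - depth0) + 0.5 * depth0 * mobile0
    above = np.flatnonzero(r >= half_level)
    t_half0 = float(t[above[0]]) if above.size else span

    flags: list[str] = []
    try:
        popt, pcov = curve_fit(
            _recovery, t, r,
            p0=[max(t_half0, 1e-3), depth0, mobile0],
            bounds=([1e-6, 1e-6, 0.0], [np.inf, 1.0, 1.05]),
            maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        flags.append("non_convergence")
        popt = [np.nan, depth0, mobile0]
        perr = [np.nan, np.nan, np.nan]
    t_half, depth, mobile = (float(v) for v in popt)
    if flat_data or (
        np.isfinite(t_half) and (t_half > 3.0 * span or depth * mobile < 0.02)
    ):
        flags.append("no_recovery_within_window")
    return FRAPFit(
        t_half=t_half,
        t_half_se=float(perr[0]),
        tau=t_half / _LN2 if np.isfinite(t_half) else np.nan,
        depth=depth,
        mobile=mobile,
        plateau=(1.0 - depth) + depth * mobile,
        flags=flags,
    )
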