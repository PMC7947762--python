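"""Melting temperatures from nanoDSF-style thermal unfolding traces.

The instrument reports intrinsic tryptophan fluorescence at 350 and 330 nm
during a linear thermal ramp; the unfolding transition midpoint T_M is the
temperature of the maximum of the first derivative of the F350/F330 ratio.

The estimator smooths the ratio with a local quadratic (Savitzky-Golay)
filter, takes the analytic first derivative of the same filter, and refines
the grid argmax by fitting a parabola to the derivative in a neighbourhood
of the peak.  A trace whose derivative shows no peak standing clear of the
noise floor raises :class:`~lporlab.errors.NoTransitionError` rather than
reporting a meaningless midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import NoTransitionError, ValidationError
from .spectra import Spectrum

__all__ = ["DsfTrace", "TmResult", "melting_temperature", "read_dsf_csv"]


@dataclass
class DsfTrace:
    """Two-channel unfolding trace; ``ratio`` is derived as F350/F330."""

    temps: np.ndarray
    f350: np.ndarray
    f330: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        n = self.temps.size
        if self.f350.size != n or self.f330.size != n:
            raise ValidationError("channel lengths must match the ramp")
        if not np.all(np.diff(self.temps) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        if np.any(self.f330 <= 0):
            raise ValidationError("F330 must be positive everywhere")

    @property
    def ratio(self) -> np.ndarray:
        return self.f350 / self.f330

    @classmethod
    def from_ratio(cls, temps, ratio) -> "DsfTrace":
        ratio = np.asarray(ratio, dtype=float)
        return cls(temps, ratio, np.ones_like(ratio))

    @classmethod
    def from_spectrum(cls, spec: Spectrum) -> "DsfTrace":
        """Interpret a fluorescence-ratio Spectrum (x axis = °C)."""
        return cls.from_ratio(spec.wavelengths, spec.values)


@dataclass
class TmResult:
    tm: float
    peak_height: float          # d(ratio)/dT at the refined peak
    window: int                 # smoothing window used (points)


def melting_temperature(trace: DsfTrace, window: int = 9,
                        snr_threshold: float = 5.0) -> TmResult:
    """T_M as the refined maximum of the first derivative of F350/F330.

    ``window`` is the Savitzky-Golay window in points (degree 2); the peak
    position is refined by a parabolic fit over +-``window`` points around
    the grid maximum.  The peak must stand ``snr_threshold`` robust standard
    deviations above the median derivative, otherwise the trace is declared
    transition-free.
    """
    temps = trace.temps
    ratio = trace.ratio
    if window < 3:
        raise ValidationError("window must be >= 3 points")
    if window % 2 == 0:
        window += 1
    if temps.size < 2 * window:
        raise ValidationError("trace too short for the smoothing window")
    step = float(np.median(np.diff(temps)))
    deriv = savgol_filter(ratio, window_length=window, polyorder=2,
                          deriv=1, delta=step)
    med = float(np.median(deriv))
    mad = float(np.median(np.abs(deriv - med)))
    robust_sd = 1.4826 * mad
    i = int(np.argmax(deriv))
    height = float(deriv[i])
    if height - med <= snr_threshold * robust_sd or height - med <= 1e-12:
        raise NoTransitionError(
            "derivative maximum does not stand above the noise floor")

    # refine over the peak's upper half (at least +-window points): a wider
    # parabola window averages point noise that a 3-point vertex cannot
    half = med + 0.5 * (height - med)
    lo = i
    while lo > 0 and deriv[lo - 1] >= half:
        lo -= 1
    hi = i
    while hi < temps.size - 1 and deriv[hi + 1] >= half:
        hi += 1
    lo = min(lo, max(0, i - window))
    hi = max(hi + 1, min(temps.size, i + window + 1))
    t_loc, d_loc = temps[lo:hi], deriv[lo:hi]
    a, b, c = np.polyfit(t_loc - temps[i], d_loc, 2)
    if a < 0:
        dt = -b / (2.0 * a)
        dt = float(np.clip(dt, t_loc[0] - temps[i], t_loc[-1] - temps[i]))
        tm = temps[i] + dt
        height = float(a * dt * dt + b * dt + c)
    else:  # derivative locally flat/convex; keep the grid maximum
        tm = float(temps[i])
    if not (temps[0] <= tm <= temps[-1]):
        tm = float(temps[i])
    return TmResult(tm=float(tm), peak_height=height, window=window)


def read_dsf_csv(path) -> DsfTrace:
    """Read a (temp_C, f330, f350) CSV into a trace."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        return DsfTrace(df[cols["temp_c"]].to_numpy(),
                        df[cols["f350"]].to_numpy(),
                        df[cols["f330"]].to_numpy())
    except KeyError as exc:
        raise ValidationError(
            f"{path}: expected columns temp_C, f330, f350") from exc
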