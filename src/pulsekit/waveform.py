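"""Parametric model of one radial-artery pulse cycle.

A pulse cycle is modelled as the superposition of three component waves:

* the **main wave** — the large systolic upstroke/downstroke, a cubic
  smoothstep rise to the peak ``Ym`` at ``ts`` followed by a smoothstep
  decay to zero at the cycle end ``T``, modulated by a piecewise
  "curvature" envelope ``k1`` that drops from 1 to the constant ``c``
  between the peak and the main-wave valley time ``b`` and then decays
  as ``c * exp(-((t-b)/(T-b))**3)``;
* the **tidal wave** — a smooth bump of height ``Ym1`` supported on
  ``[b, T1)`` peaking at ``ts1``;
* the **dicrotic wave** — a smooth bump of height ``Ym2`` supported on
  ``[T1, T)`` peaking at ``ts2``.  ``Ym2 = 0`` encodes the *slippery*
  pulse class, whose defining trait is the absent dicrotic wave.

Every ascending/descending segment uses the same canonical cubic with
zero slope at both ends, so the synthesized cycle is continuous and
starts/ends at zero amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PulseParams",
    "SignalTrace",
    "main_wave",
    "tidal_wave",
    "dicrotic_wave",
    "synthesize_cycle",
]

#: units a SignalTrace may carry; "mmHg" is used by cuff-pressure traces.
ALLOWED_UNITS = ("volts", "adc_counts", "normalized", "mmHg")


@dataclass(frozen=True)
class PulseParams:
    """Parameter set defining one pulse cycle.

    Attributes
    ----------
    Ym, Ym1, Ym2 : float
        Peak amplitudes of main, tidal and dicrotic waves (signal
        units). ``Ym > 0``; ``Ym1, Ym2 >= 0``; ``Ym2 == 0`` encodes the
        slippery class.
    T : float
        Cycle period in seconds.
    ts : float
        Ascending-branch duration (main-peak time), seconds.
    b : float
        Main-wave valley time, seconds.
    ts1, T1 : float
        Tidal-wave peak and valley times, seconds.
    ts2 : float
        Dicrotic-wave peak time, seconds (placeholder when ``Ym2 == 0``).
    c : float
        Curvature constant of the main-wave envelope, ``0 < c <= 1``.
    """

    Ym: float
    Ym1: float
    Ym2: float
    T: float
    ts: float
    b: float
    ts1: float
    T1: float
    ts2: float
    c: float = 0.35

    def __post_init__(self) -> None:
        for name in ("Ym", "Ym1", "Ym2", "T", "ts", "b", "ts1", "T1", "ts2", "c"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.Ym <= 0:
            raise ValueError(f"Ym must be > 0, got {self.Ym}")
        if self.Ym1 < 0 or self.Ym2 < 0:
            raise ValueError("Ym1 and Ym2 must be >= 0")
        if not (0 < self.c <= 1):
            raise ValueError(f"c must be in (0, 1], got {self.c}")
        if not (0 < self.ts < self.b < self.ts1 < self.T1):
            raise ValueError(
                "timing must satisfy 0 < ts < b < ts1 < T1 "
                f"(got ts={self.ts}, b={self.b}, ts1={self.ts1}, T1={self.T1})"
            )
        if self.Ym2 > 0:
            if not (self.T1 < self.ts2 < self.T):
                raise ValueError(
                    "with a dicrotic wave, T1 < ts2 < T must hold "
                    f"(got T1={self.T1}, ts2={self.ts2}, T={self.T})"
                )
        else:
            if not (self.T1 <= self.T):
                raise ValueError(f"T1 must be <= T (got T1={self.T1}, T={self.T})")

    @property
    def slippery(self) -> bool:
        """True when the cycle has no dicrotic wave."""
        return self.Ym2 == 0

    def with_(self, **kwargs) -> "PulseParams":
        """Return a copy with some fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass
class SignalTrace:
    """A uniformly sampled amplitude series.

    Parameters
    ----------
    samples : ndarray
        1-D amplitude array.
    fs : float
        Sampling rate in Hz (default 125, the system's acquisition rate).
    unit : str
        One of ``volts``, ``adc_counts``, ``normalized``, ``mmHg``.
    """

    samples: np.ndarray
    fs: float = 125.0
    unit: str = "adc_counts"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.unit not in ALLOWED_UNITS:
            raise ValueError(f"unit must be one of {ALLOWED_UNITS}, got {self.unit!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def _rise(t, t0, tp, Yp):
    """Canonical ascending cubic: 0 at t0, Yp at tp, zero slope at both."""
    u = (t - t0) / (tp - t0)
    return Yp * (3.0 * u**2 - 2.0 * u**3)


def _fall(t, tp, tz, Yp):
    """Canonical descending cubic: Yp at tp, 0 at tz, zero slope at both."""
    u = (tz - t) / (tz - tp)
    return Yp * (3.0 * u**2 - 2.0 * u**3)


def _check_domain(t: np.ndarray, T: float) -> None:
    if np.any(t < 0) or np.any(t >= T):
        raise ValueError(f"t must lie in [0, T={T}), got values outside")


def main_wave(params: PulseParams, t):
    """Main-wave amplitude ``y1(t) = k1(t) * f1(t)``.

    ``f1`` is the cubic smoothstep rising to ``Ym`` at ``ts`` and falling
    to zero at ``T``; ``k1`` is the three-piece curvature envelope (1 on
    the ascending branch, linear from 1 to ``c`` on ``[ts, b)``, then
    ``c * exp(-((t-b)/(T-b))**3)``).
    """
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(t, params.T)
    Ym, T, ts, b, c = params.Ym, params.T, params.ts, params.b, params.c

    f1 = np.where(t < ts, _rise(t, 0.0, ts, Ym), _fall(t, ts, T, Ym))
    k1 = np.ones_like(t)
    mid = (t >= ts) & (t < b)
    k1[mid] = (1.0 - c) * (b - t[mid]) / (b - ts) + c
    late = t >= b
    k1[late] = c * np.exp(-(((t[late] - b) / (T - b)) ** 3))
    y = k1 * f1
    return float(y[0]) if scalar else y


def tidal_wave(params: PulseParams, t):
    """Tidal-wave amplitude: supported on ``[b, T1)``, peak ``Ym1`` at ``ts1``."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(t, params.T)
    b, ts1, T1, Ym1 = params.b, params.ts1, params.T1, params.Ym1

    y = np.zeros_like(t)
    up = (t >= b) & (t < ts1)
    y[up] = _rise(t[up], b, ts1, Ym1)
    down = (t >= ts1) & (t < T1)
    y[down] = _fall(t[down], ts1, T1, Ym1)
    return float(y[0]) if scalar else y


def dicrotic_wave(params: PulseParams, t):
    """Dicrotic-wave amplitude: supported on ``[T1, T)``, peak ``Ym2`` at ``ts2``.

    Identically zero for slippery cycles (``Ym2 == 0``).
    """
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(t, params.T)
    y = np.zeros_like(t)
    if params.Ym2 > 0:
        T1, ts2, T, Ym2 = params.T1, params.ts2, params.T, params.Ym2
        up = (t >= T1) & (t < ts2)
        y[up] = _rise(t[up], T1, ts2, Ym2)
        down = (t >= ts2) & (t < T)
        y[down] = _fall(t[down], ts2, T, Ym2)
    return float(y[0]) if scalar else y


def synthesize_cycle(params: PulseParams, fs: float = 125.0) -> SignalTrace:
    """Sample one full cycle: superposition of the three component waves.

    Returns ``round(T * fs)`` samples at ``t = k / fs``; the first sample
    is 0 and the value at ``t = ts`` equals ``Ym`` (tidal and dicrotic
    waves are zero there).
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    n = int(round(params.T * fs))
    if n < 8:
        raise ValueError(f"cycle unresolvable: T*fs = {params.T * fs:.2f} < 8 samples")
    t = np.arange(n) / fs
    y = main_wave(params, t) + tidal_wave(params, t) + dicrotic_wave(params, t)
    return SignalTrace(y, fs=fs)
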