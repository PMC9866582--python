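"""Feature extraction for pulse-class recognition.

Two feature families per record:

* spatio-temporal features Ft — the ascending/descending duration ratio
  ts/tf, the per-wave occupied-duration ratios t1:t2:t3 (main, tidal,
  dicrotic) and peak-height ratios h1:h2:h3, stored normalized to the
  main wave (t2/t1, t3/t1, h2/h1, h3/h1) so the vector is fixed-length;
* modal-energy features Fy — Euclidean-norm ratios y_i = ||Y_i|| / ||Y||
  of the six wavelet components (detail bands Y1..Y5 and scaling band
  Y6), reported for the components (Y6, Y5, Y4) that pass the component
  correlation filter r > 0.2.

Note the feature-namespace t1:t2:t3 / h1:h2:h3 are per-wave durations
and peak heights, distinct from the landmark times/heights t1..t6 /
h1..h6 of :mod:`pulsekit.reconstruct`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .denoise import CycleSegmentation, segment_periods
from .reconstruct import CycleLandmarks, extract_landmarks
from .waveform import SignalTrace

__all__ = [
    "FeatureVector",
    "FT_NAMES",
    "FY_NAMES",
    "spatial_temporal_features",
    "wavelet_components",
    "component_correlation",
    "modal_energy",
    "modal_energy_features",
    "featurize_record",
]

FT_NAMES = ("ts_tf", "t2_t1", "t3_t1", "h2_h1", "h3_h1")
FY_NAMES = ("y6", "y5", "y4")


@dataclass
class FeatureVector:
    """The 8 numeric features of one record, plus label and QC flags."""

    ts_tf: float
    t2_t1: float
    t3_t1: float
    h2_h1: float
    h3_h1: float
    y6: float
    y5: float
    y4: float
    label: str = "unknown"
    #: modal-energy components that failed the r > 0.2 filter
    low_correlation: tuple = ()

    def __post_init__(self):
        if self.ts_tf <= 0:
            raise ValueError("ts_tf must be > 0")
        for name in ("t2_t1", "t3_t1", "h2_h1", "h3_h1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in FY_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def values(self, feature_set: str = "F") -> np.ndarray:
        names = FT_NAMES if feature_set == "Ft" else FT_NAMES + FY_NAMES
        return np.array([getattr(self, n) for n in names], dtype=float)


def spatial_temporal_features(landmarks: CycleLandmarks, T: float) -> dict:
    """Per-cycle spatio-temporal features from landmarks.

    ts is the main-peak time and tf = T - ts.  Wave durations partition
    the cycle valley-to-valley: main = main-valley time, tidal =
    tidal-valley - main-valley, dicrotic = T - tidal-valley (zero when
    the dicrotic wave is absent, since the tidal wave then runs to the
    cycle end).  Heights are the three wave peaks.  Ratios are
    normalized to the main wave.
    """
    lm = landmarks
    ts = lm.t1
    tf = T - ts
    if tf <= 0:
        raise ValueError("main peak at or beyond cycle end")
    dur_main = lm.t2
    dur_tidal = lm.t4 - lm.t2
    dur_dicro = max(0.0, T - lm.t4) if lm.present_dicrotic else 0.0
    h_dicro = lm.h5 if lm.present_dicrotic else 0.0
    return {
        "ts_tf": ts / tf,
        "t2_t1": dur_tidal / dur_main,
        "t3_t1": dur_dicro / dur_main,
        "h2_h1": lm.h3 / lm.h1,
        "h3_h1": h_dicro / lm.h1,
    }


def wavelet_components(trace: SignalTrace, wavelet: str = "db4",
                       mode: str = "periodization") -> list:
    """Single-band reconstructions Y1..Y6 of a trace.

    Y_i (i = 1..5) keeps only detail band CD_i; Y6 keeps only the
    scaling band CA5.  By linearity the six components sum to the input.
    """
    x = trace.samples
    if x.size < 2**5:
        raise ValueError("trace too short for a 5-level decomposition")
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=5)
    comps = []
    for i in range(1, 6):  # Y1..Y5 from CD1..CD5
        keep = [np.zeros_like(c) for c in coeffs]
        keep[6 - i] = coeffs[6 - i]
        comps.append(pywt.waverec(keep, wavelet, mode=mode)[:x.size])
    keep = [np.zeros_like(c) for c in coeffs]
    keep[0] = coeffs[0]
    comps.append(pywt.waverec(keep, wavelet, mode=mode)[:x.size])  # Y6
    return comps


def component_correlation(Y: np.ndarray, Yi: np.ndarray) -> float:
    """Pearson correlation r = cov(Y, Yi) / (sigma sigma_i)."""
    Y = np.asarray(Y, dtype=float)
    Yi = np.asarray(Yi, dtype=float)
    if Y.shape != Yi.shape:
        raise ValueError("components must have equal length")
    sy, si = Y.std(), Yi.std()
    if sy == 0 or si == 0:
        warnings.warn("zero-variance component; r defined as 0", stacklevel=2)
        return 0.0
    return float(np.cov(Y, Yi, bias=True)[0, 1] / (sy * si))


def modal_energy(Y: np.ndarray, Yi: np.ndarray) -> float:
    """Euclidean-norm ratio ||Yi|| / ||Y||."""
    denom = float(np.linalg.norm(Y))
    if denom == 0:
        raise ValueError("zero-energy signal")
    return float(np.linalg.norm(Yi)) / denom


def modal_energy_features(trace: SignalTrace, wavelet: str = "db4") -> dict:
    """Record-level modal energies (y6, y5, y4) with the r > 0.2 filter.

    The feature layout is fixed; a nominally retained component that
    fails the correlation filter on a given record is still reported,
    flagged under ``low_correlation``.
    """
    comps = wavelet_components(trace, wavelet=wavelet)
    Y = trace.samples
    r = [component_correlation(Y, c) for c in comps]
    energies = [modal_energy(Y, c) for c in comps]
    flagged = tuple(f"y{i}" for i in (6, 5, 4) if r[i - 1] <= 0.2)
    return {
        "y6": energies[5], "y5": energies[4], "y4": energies[3],
        "r": tuple(r), "energies": tuple(energies),
        "low_correlation": flagged,
    }


def featurize_record(trace: SignalTrace,
                     segmentation: CycleSegmentation | None = None,
                     label: str = "unknown",
                     wavelet: str = "db4") -> FeatureVector:
    """Record-level feature vector: per-cycle Ft medians + record Fy.

    Expects a denoised record (see :func:`pulsekit.denoise.denoise_pipeline`).
    Cycles whose landmarks cannot be extracted are skipped for Ft.
    """
    if segmentation is None:
        segmentation = segment_periods(trace)
    rows = []
    for i in range(segmentation.n_cycles):
        cyc = segmentation.cycle(trace.samples, i)
        try:
            lm = extract_landmarks(cyc, trace.fs)
        except ValueError:
            continue
        rows.append(spatial_temporal_features(lm, T=cyc.size / trace.fs))
    if not rows:
        raise ValueError("no cycle yielded landmarks")
    ft = {k: float(np.median([row[k] for row in rows])) for k in FT_NAMES}
    fy = modal_energy_features(trace, wavelet=wavelet)
    return FeatureVector(**ft, y6=fy["y6"], y5=fy["y5"], y4=fy["y4"],
                         label=label, low_correlation=fy["low_correlation"])
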