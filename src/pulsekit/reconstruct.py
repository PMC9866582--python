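"""Predict-and-replace reconstruction of anomalous pulse cycles.

Each processed cycle is summarized by six landmarks — the heights
h1..h6 and times t1..t6 of the main peak, main valley, tidal peak, tidal
valley, dicrotic peak and end trough.  The landmarks of the last valid
cycle are mapped back to waveform parameters (re-anchoring every time by
subtracting t6 - T, taking Ym = h1 and the secondary amplitudes as the
landmark heights minus the already-determined main wave), optionally
refined by bounded least squares on (b, ts, c), and the forward model
predicts a replacement for each flagged cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import signal as sps

from .denoise import CycleSegmentation
from .waveform import PulseParams, SignalTrace, main_wave, synthesize_cycle

__all__ = [
    "CycleLandmarks",
    "extract_landmarks",
    "params_from_landmarks",
    "detect_anomalous_cycles",
    "predict_cycle",
    "refine_params",
    "reconstruct_record",
]


@dataclass
class CycleLandmarks:
    """Per-cycle landmark heights and times.

    h1..h6 / t1..t6: main peak, main valley, tidal peak, tidal valley,
    dicrotic peak, end trough.  Times are seconds from the cycle start
    (plus any offset the caller anchored them with).  When no dicrotic
    wave is present, h5 = h6 = the end value and t5 bisects [t4, t6];
    when no tidal valley exists either (slippery cycles decay
    monotonically after the tidal peak), t4 is the cycle end.
    """

    h1: float; h2: float; h3: float; h4: float; h5: float; h6: float
    t1: float; t2: float; t3: float; t4: float; t5: float; t6: float
    present_dicrotic: bool = True

    def __post_init__(self):
        if not (self.t1 < self.t2 < self.t3 < self.t4):
            raise ValueError("landmark times must satisfy t1 < t2 < t3 < t4")
        if self.present_dicrotic and not (self.t4 < self.t5 < self.t6):
            raise ValueError("with a dicrotic wave, t4 < t5 < t6 must hold")
        if not (self.h1 >= self.h3 >= 0 and self.h1 >= self.h5 >= 0):
            raise ValueError("main peak must dominate: h1 >= h3, h5 >= 0")


def extract_landmarks(cycle: np.ndarray, fs: float, t0: float = 0.0,
                      prominence_frac: float = 0.01) -> CycleLandmarks:
    """Locate the alternating peak/trough landmarks of one clean cycle.

    Expects a detrended, baselined cycle (min 0, matched endpoints).
    Local extrema are found with a prominence floor of
    ``prominence_frac * max(cycle)`` to ignore residual ripple.
    """
    x = np.asarray(cycle, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("cycle too short")
    im = int(np.argmax(x))
    if im == 0 or im == n - 1:
        raise ValueError("no main peak found (monotone segment)")
    h1 = float(x[im])
    prom = prominence_frac * h1

    maxima, _ = sps.find_peaks(x, prominence=prom)
    minima, _ = sps.find_peaks(-x, prominence=prom)
    if im not in maxima:  # flat-topped global max can be missed; add it
        maxima = np.sort(np.append(maxima, im))

    after = minima[minima > im]
    if after.size == 0:
        raise ValueError("no main valley found after the main peak")
    i2 = int(after[0])

    tidal = maxima[maxima > i2]
    if tidal.size == 0:
        raise ValueError("no tidal peak found")
    i3 = int(tidal[0])

    valleys = minima[minima > i3]
    i4 = int(valleys[0]) if valleys.size else n  # slippery: decay to cycle end
    dicrotic = maxima[maxima > i4]
    t6 = n / fs
    h6 = float(x[-1])
    if dicrotic.size:
        i5 = int(dicrotic[0])
        return CycleLandmarks(
            h1=h1, h2=float(x[i2]), h3=float(x[i3]), h4=float(x[i4]),
            h5=float(x[i5]), h6=h6,
            t1=t0 + im / fs, t2=t0 + i2 / fs, t3=t0 + i3 / fs,
            t4=t0 + i4 / fs, t5=t0 + i5 / fs, t6=t0 + t6,
            present_dicrotic=True)
    h4 = float(x[i4]) if i4 < n else h6
    t4 = t0 + (i4 / fs if i4 < n else t6)
    return CycleLandmarks(
        h1=h1, h2=float(x[i2]), h3=float(x[i3]), h4=h4, h5=h6, h6=h6,
        t1=t0 + im / fs, t2=t0 + i2 / fs, t3=t0 + i3 / fs, t4=t4,
        t5=t4 + (t0 + t6 - t4) / 2, t6=t0 + t6,
        present_dicrotic=False)


def params_from_landmarks(prev: CycleLandmarks, T: float,
                          c: float | None = None) -> PulseParams:
    """Map the previous cycle's landmarks to waveform parameters.

    Times are re-anchored by subtracting (t6 - T); Ym = h1; then, with
    the main wave determined, Ym1 = h3 - y1(ts1) and Ym2 = h5 - y1(ts2)
    (order matters).  When ``c`` is not given it is estimated from the
    main-valley height (h2 ~ c * f1(b)), since the landmark mapping
    itself does not determine the curvature constant.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    d = prev.t6 - T
    ts, b, ts1, T1, ts2 = (prev.t1 - d, prev.t2 - d, prev.t3 - d,
                           prev.t4 - d, prev.t5 - d)
    for name, left, right in (("ts < b", ts, b), ("b < ts1", b, ts1),
                              ("ts1 < T1", ts1, T1)):
        if not left < right:
            raise ValueError(f"re-anchored times violate {name}")
    if not 0 < ts:
        raise ValueError("re-anchored times violate 0 < ts")
    if T1 > T:
        if T1 - T < 2e-2 * T:  # end-anchored tidal valley; snap to T
            T1 = T
        else:
            raise ValueError("re-anchored times violate T1 <= T")
    Ym = prev.h1

    def f1_at(t):
        u = (T - t) / (T - ts)
        return Ym * (3 * u**2 - 2 * u**3)

    if c is None:
        c = float(np.clip(prev.h2 / f1_at(b), 0.05, 1.0))

    probe = PulseParams(Ym=Ym, Ym1=0.0, Ym2=0.0, T=T, ts=ts, b=b, ts1=ts1,
                        T1=min(T1, T), ts2=0.5 * (min(T1, T) + T), c=c)
    Ym1 = max(0.0, prev.h3 - float(main_wave(probe, min(ts1, T * (1 - 1e-9)))))
    if prev.present_dicrotic and T1 < ts2 < T:
        Ym2 = max(0.0, prev.h5 - float(main_wave(probe, ts2)))
    else:
        Ym2 = 0.0
        ts2 = 0.5 * (min(T1, T) + T)
    return PulseParams(Ym=Ym, Ym1=Ym1, Ym2=Ym2, T=T, ts=ts, b=b, ts1=ts1,
                       T1=min(T1, T), ts2=ts2, c=c)


def detect_anomalous_cycles(segmentation: CycleSegmentation, landmarks_list,
                            amp_tol: float = 0.3,
                            period_tol: float = 0.25) -> np.ndarray:
    """Flag cycles whose amplitude or period jumps from the last valid cycle.

    A cycle is anomalous when |h1 - h1_ref| / h1_ref > ``amp_tol`` or
    |T - T_ref| / T_ref > ``period_tol`` relative to the most recent
    unflagged cycle, or when its landmarks could not be extracted
    (``None`` entries).  The initial reference is the first cycle whose
    amplitude and period sit within tolerance of the record medians, so
    a corrupted opening cycle cannot poison the comparison chain.
    """
    n = segmentation.n_cycles
    if len(landmarks_list) != n:
        raise ValueError("landmarks_list length must match cycle count")
    flags = np.zeros(n, dtype=bool)
    ok = [lm is not None for lm in landmarks_list]
    if not any(ok):
        return np.ones(n, dtype=bool)
    med_h1 = float(np.median([lm.h1 for lm in landmarks_list if lm is not None]))
    med_T = float(np.median(segmentation.period[np.asarray(ok)]))

    ref_h1 = ref_T = None
    for i in range(n):
        lm = landmarks_list[i]
        T_i = segmentation.period[i]
        if lm is None:
            flags[i] = True
            continue
        if ref_h1 is None:
            if (abs(lm.h1 - med_h1) / med_h1 <= amp_tol
                    and abs(T_i - med_T) / med_T <= period_tol):
                ref_h1, ref_T = lm.h1, T_i
            else:
                flags[i] = True
            continue
        if (abs(lm.h1 - ref_h1) / ref_h1 > amp_tol
                or abs(T_i - ref_T) / ref_T > period_tol):
            flags[i] = True
        else:
            ref_h1, ref_T = lm.h1, T_i
    return flags


def predict_cycle(params: PulseParams, fs: float) -> np.ndarray:
    """Forward-model prediction of one cycle (shared with the simulator)."""
    return synthesize_cycle(params, fs).samples


def refine_params(params: PulseParams, reference_cycle: np.ndarray,
                  fs: float = 125.0) -> PulseParams:
    """Adjust (b, ts, c) by bounded least squares against a reference cycle.

    b and ts move within +/-20% (keeping the timing ordering valid) and
    c within (0, 1] to minimize the squared error between the predicted
    cycle and the reference; the objective never increases.
    """
    ref = np.asarray(reference_cycle, dtype=float)
    if np.ptp(ref) <= 1e-12:
        raise ValueError("degenerate flat reference cycle")
    n = min(ref.size, int(round(params.T * fs)))
    t = np.arange(n) / fs

    def build(b, ts, c):
        return params.with_(b=b, ts=ts, c=c)

    def objective(v):
        b, ts, c = v
        if not (0 < ts < b < params.ts1 and 0 < c <= 1):
            return 1e18
        try:
            p = build(b, ts, c)
        except ValueError:
            return 1e18
        y = (main_wave(p, t)
             + _tidal_dicrotic(p, t))
        return float(np.mean((y - ref[:n]) ** 2))

    x0 = np.array([params.b, params.ts, params.c])
    f0 = objective(x0)
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400})
    if res.fun <= f0 and np.isfinite(res.fun) and res.fun < 1e17:
        b, ts, c = res.x
        # stay within the +/-20% adjustment budget
        b = float(np.clip(b, 0.8 * params.b, 1.2 * params.b))
        ts = float(np.clip(ts, 0.8 * params.ts, 1.2 * params.ts))
        c = float(np.clip(c, 1e-6, 1.0))
        if objective([b, ts, c]) <= f0:
            return build(b, ts, c)
    return params


def _tidal_dicrotic(p: PulseParams, t: np.ndarray) -> np.ndarray:
    from .waveform import dicrotic_wave, tidal_wave

    return tidal_wave(p, t) + dicrotic_wave(p, t)


def reconstruct_record(trace: SignalTrace, segmentation: CycleSegmentation,
                       flags: np.ndarray, refine: bool = True) -> SignalTrace:
    """Replace flagged cycles by model predictions from the last valid cycle.

    Unflagged samples are passed through bit-identical.  A flagged first
    cycle with no prior valid cycle (or a record with every cycle
    flagged) is left unmodified with a warning.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != segmentation.n_cycles:
        raise ValueError("flags length must match cycle count")
    out = trace.samples.copy()
    if flags.all():
        warnings.warn("all cycles flagged; record left unmodified", stacklevel=2)
        return SignalTrace(out, fs=trace.fs, unit=trace.unit)

    last_valid = None  # (landmarks, cycle samples)
    for i in range(segmentation.n_cycles):
        s, e = segmentation.boundaries[i], segmentation.boundaries[i + 1]
        cyc = trace.samples[s:e]
        if not flags[i]:
            try:
                lm = extract_landmarks(cyc, trace.fs)
            except ValueError:
                lm = None
            if lm is not None:
                last_valid = (lm, cyc)
            continue
        if last_valid is None:
            warnings.warn("first cycle flagged with no prior valid cycle; "
                          "left unmodified", stacklevel=2)
            continue
        lm, ref = last_valid
        T_new = (e - s) / trace.fs
        scale = T_new / lm.t6
        lm_scaled = CycleLandmarks(
            h1=lm.h1, h2=lm.h2, h3=lm.h3, h4=lm.h4, h5=lm.h5, h6=lm.h6,
            t1=lm.t1 * scale, t2=lm.t2 * scale, t3=lm.t3 * scale,
            t4=lm.t4 * scale, t5=lm.t5 * scale, t6=lm.t6 * scale,
            present_dicrotic=lm.present_dicrotic)
        params = params_from_landmarks(lm_scaled, T=T_new)
        if refine:
            params = refine_params(params, ref, fs=trace.fs)
        pred = predict_cycle(params, trace.fs)
        m = min(pred.size, e - s)
        out[s:s + m] = pred[:m]
        if m < e - s:  # rounding left a sample or two; hold the end value
            out[s + m:e] = pred[-1]
    return SignalTrace(out, fs=trace.fs, unit=trace.unit)
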