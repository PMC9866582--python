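"""Forward model of the measurement chain.

Everything between the artery and a CSV file: the piezoelectric sensor's
pressure-to-voltage calibration, the 12-bit ADC mapping, the sensor's
0.5-100 Hz band limit, class-conditional pulse-record synthesis with a
configurable noise/artifact model, and the scan-grid and cuff-pressure
sweep fixtures used by the localization stage.  This module is the
package's only data source for tests and benchmarks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .waveform import PulseParams, SignalTrace, synthesize_cycle

__all__ = [
    "SensorModel",
    "NoiseSpec",
    "RecordTruth",
    "sensor_voltage",
    "adc_code",
    "surface_pressure",
    "sensitivity_mV_per_Pa",
    "band_limit",
    "draw_params",
    "synthesize_record",
    "scan_grid_fixture",
    "pressure_sweep_fixture",
    "SCAN_COORDS",
]

#: The 5x5 wrist scan coordinates (cm); x toward the palm edge, y along
#: the arm, origin at the radial styloid protrusion.
SCAN_COORDS = np.array(
    [
        (x, y)
        for y in (-3.0, -1.5, 0.0, 1.5, 3.0)
        for x in (0.25, 0.5, 1.0, 1.5, 1.75)
    ]
)


@dataclass(frozen=True)
class SensorModel:
    """Static model of the piezoelectric sensor and acquisition chain."""

    #: cubic calibration polynomial (highest degree first) mapping
    #: applied mass in grams to output volts
    calib_coeffs: tuple = (2.333, -0.689, 0.171, 0.068)
    full_scale_volts: float = 3.3
    adc_levels: int = 4096
    #: sensor contact area in m^2
    contact_area: float = 0.3025e-4 * math.pi
    #: calibrated mass range in grams
    mass_range: tuple = (0.0, 2.0)
    #: sensor passband in Hz
    band: tuple = (0.5, 100.0)

    def __post_init__(self):
        if self.adc_levels <= 0 or self.full_scale_volts <= 0:
            raise ValueError("adc_levels and full_scale_volts must be positive")


_DEFAULT_SENSOR = SensorModel()


def sensor_voltage(mass_g, sensor: SensorModel = _DEFAULT_SENSOR):
    """Sensor output voltage for an applied mass (grams).

    Evaluates the cubic calibration polynomial; monotone non-decreasing
    over the calibrated 0-2 g range.  Note the polynomial is a formal
    calibration curve: at the top of the mass range it exceeds the 3.3 V
    electrical full scale.
    """
    m = np.asarray(mass_g, dtype=float)
    if np.any(m < 0):
        raise ValueError("mass must be >= 0")
    if np.any(m > sensor.mass_range[1]):
        warnings.warn("mass above calibrated range; extrapolating", stacklevel=2)
    u = np.polyval(sensor.calib_coeffs, m)
    return float(u) if np.isscalar(mass_g) else u


def adc_code(u_volts, sensor: SensorModel = _DEFAULT_SENSOR, quantize: bool = False):
    """Map a voltage to the ADC amplitude scale ``y = u * 4096 / 3.3``.

    Real-valued by default (the amplitude is used as a continuous
    quantity downstream); pass ``quantize=True`` for integer codes.
    Out-of-range voltages are clipped with a warning.
    """
    u = np.asarray(u_volts, dtype=float)
    if np.any(u < 0) or np.any(u > sensor.full_scale_volts):
        warnings.warn("voltage outside [0, full scale]; clipping", stacklevel=2)
        u = np.clip(u, 0.0, sensor.full_scale_volts)
    y = u * sensor.adc_levels / sensor.full_scale_volts
    if quantize:
        y = np.floor(y).astype(int)
        y = np.minimum(y, sensor.adc_levels - 1)
    return float(y) if np.isscalar(u_volts) else y


def surface_pressure(mass_g, sensor: SensorModel = _DEFAULT_SENSOR):
    """Contact pressure in kPa for an applied mass in grams: P = m g / S."""
    m = np.asarray(mass_g, dtype=float)
    if np.any(m < 0):
        raise ValueError("mass must be >= 0")
    p_kpa = (m * 1e-3) * 9.8 / sensor.contact_area / 1000.0
    return float(p_kpa) if np.isscalar(mass_g) else p_kpa


def sensitivity_mV_per_Pa(sensor: SensorModel = _DEFAULT_SENSOR) -> float:
    """Full-scale sensitivity: full-scale millivolts over full-scale pascals.

    The full-scale pressure is rounded to the reported 3-decimal kPa
    figure before dividing, matching how the headline figure is quoted.
    """
    p_pa = round(surface_pressure(sensor.mass_range[1], sensor), 3) * 1000.0
    return sensor.full_scale_volts * 1000.0 / p_pa


def band_limit(trace: SignalTrace, sensor: SensorModel = _DEFAULT_SENSOR) -> SignalTrace:
    """Emulate the sensor's stated passband on a trace.

    A 4th-order zero-phase Butterworth high-pass at the low band edge;
    when the sampling rate can represent the upper edge, a band-pass is
    used instead.  Removes DC; passband gain flat within 1 dB above 1 Hz.
    """
    lo, hi = sensor.band
    if trace.fs > 2 * hi:
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    else:
        sos = sps.butter(4, lo, btype="highpass", fs=trace.fs, output="sos")
    y = sps.sosfiltfilt(sos, trace.samples)
    return SignalTrace(y, fs=trace.fs, unit=trace.unit)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise / artifact model for synthetic records.

    All amplitudes are in the record's signal units (ADC counts by
    default, where main-wave peaks sit near 100).
    """

    baseline_amp: float = 3.0        #: amplitude of sinusoidal drift
    baseline_freq: float = 0.2       #: drift frequency, Hz (< 0.5 Hz)
    white_sd: float = 0.5            #: additive white-noise std
    powerline_amp: float = 0.0       #: 50 Hz interference amplitude
    phase_slope: float = 0.0         #: per-cycle linear trend (units/sample)
    corrupt_prob: float = 0.0        #: probability a cycle is mutated
    corrupt_kind: str = "amplitude"  #: "amplitude" or "period"
    seed: int | None = None

    def __post_init__(self):
        for name in ("baseline_amp", "white_sd", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.corrupt_prob <= 1.0):
            raise ValueError("corrupt_prob must be in [0, 1]")
        if self.corrupt_kind not in ("amplitude", "period"):
            raise ValueError("corrupt_kind must be 'amplitude' or 'period'")


ZERO_NOISE = NoiseSpec(baseline_amp=0.0, white_sd=0.0)

# Class-conditional parameter ranges.  ts/tf ranges follow the two pulse
# classes' reference ranges (normal 0.17-0.20, slippery 0.24-0.29); the
# remaining timing fractions are physiological choices placing the main
# valley, tidal and dicrotic landmarks on the descending branch.
_CLASS_RANGES = {
    "normal": dict(
        ts_tf=(0.17, 0.20), Ym=(80.0, 120.0), Ym1_frac=(0.07, 0.12),
        Ym2_frac=(0.07, 0.12), c=(0.28, 0.42),
    ),
    "slippery": dict(
        ts_tf=(0.24, 0.29), Ym=(80.0, 120.0), Ym1_frac=(0.07, 0.12),
        Ym2_frac=(0.0, 0.0), c=(0.28, 0.42),
    ),
}
_TIMING_FRACS = dict(b=(0.11, 0.14), ts1=(0.09, 0.12), T1=(0.11, 0.14),
                     ts2=(0.09, 0.12))


def draw_params(class_label: str, rng: np.random.Generator,
                T_range=(0.85, 1.1)) -> PulseParams:
    """Draw one cycle's parameters from a class-conditional distribution.

    Uniform over the class ranges: assumption-minimal given only the
    printed feature ranges of each class.
    """
    if class_label not in _CLASS_RANGES:
        raise ValueError(f"unknown class label {class_label!r}")
    r = _CLASS_RANGES[class_label]
    T = rng.uniform(*T_range)
    ratio = rng.uniform(*r["ts_tf"])
    ts = T * ratio / (1.0 + ratio)
    b = ts + rng.uniform(*_TIMING_FRACS["b"]) * T
    ts1 = b + rng.uniform(*_TIMING_FRACS["ts1"]) * T
    T1 = ts1 + rng.uniform(*_TIMING_FRACS["T1"]) * T
    Ym = rng.uniform(*r["Ym"])
    Ym1 = Ym * rng.uniform(*r["Ym1_frac"])
    c = rng.uniform(*r["c"])
    if class_label == "slippery":
        Ym2 = 0.0
        ts2 = 0.5 * (T1 + T)  # placeholder; dicrotic wave is absent
    else:
        Ym2 = Ym * rng.uniform(*r["Ym2_frac"])
        ts2 = T1 + rng.uniform(*_TIMING_FRACS["ts2"]) * T
    return PulseParams(Ym=Ym, Ym1=Ym1, Ym2=Ym2, T=T, ts=ts, b=b,
                       ts1=ts1, T1=T1, ts2=ts2, c=c)


def _jitter(params: PulseParams, rng: np.random.Generator) -> PulseParams:
    """Small beat-to-beat variability around a record's base parameters."""
    sT = rng.uniform(0.97, 1.03)
    sY = rng.uniform(0.96, 1.04)
    return PulseParams(
        Ym=params.Ym * sY, Ym1=params.Ym1 * sY, Ym2=params.Ym2 * sY,
        T=params.T * sT, ts=params.ts * sT, b=params.b * sT,
        ts1=params.ts1 * sT, T1=params.T1 * sT, ts2=params.ts2 * sT,
        c=params.c,
    )


@dataclass
class RecordTruth:
    """Ground truth accompanying a synthetic record."""

    label: str
    params: list               #: per-cycle PulseParams (as synthesized)
    corrupted: np.ndarray      #: per-cycle corruption flags
    boundaries: np.ndarray     #: cycle-start fenceposts (n_cycles + 1)
    clean: SignalTrace         #: record without corruption or noise
    seed: int | None = None


def synthesize_record(class_label: str, n_cycles: int,
                      noise: NoiseSpec = ZERO_NOISE, fs: float = 125.0,
                      seed: int | None = None, corrupt_cycles=None):
    """Generate a multi-cycle pulse record with ground truth.

    Cycles share record-level base parameters drawn from the class
    distribution, with small beat-to-beat jitter.  Corrupted cycles (per
    ``noise.corrupt_prob``) get an amplitude (or period) mutation; the
    returned :class:`RecordTruth` carries the uncorrupted clean trace,
    per-cycle parameters and corruption flags.  ``corrupt_cycles`` may
    list explicit cycle indices to corrupt (overriding the random draw).

    Returns
    -------
    (SignalTrace, RecordTruth)
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(seed)
    base = draw_params(class_label, rng)

    forced = set() if corrupt_cycles is None else set(int(i) for i in corrupt_cycles)
    cycles, clean_cycles, params_list, flags = [], [], [], []
    for k in range(n_cycles):
        p = _jitter(base, rng)
        corrupted = (k in forced) if corrupt_cycles is not None \
            else rng.random() < noise.corrupt_prob
        if corrupted:
            if noise.corrupt_kind == "amplitude":
                s = rng.uniform(1.6, 2.2) if rng.random() < 0.5 else rng.uniform(0.35, 0.6)
                pc = p.with_(Ym=p.Ym * s, Ym1=p.Ym1 * s, Ym2=p.Ym2 * s)
            else:
                s = rng.uniform(1.4, 1.6)
                pc = PulseParams(Ym=p.Ym, Ym1=p.Ym1, Ym2=p.Ym2, T=p.T * s,
                                 ts=p.ts * s, b=p.b * s, ts1=p.ts1 * s,
                                 T1=p.T1 * s, ts2=p.ts2 * s, c=p.c)
        else:
            pc = p
        cycles.append(synthesize_cycle(pc, fs).samples)
        clean_cycles.append(synthesize_cycle(p, fs).samples)
        params_list.append(pc)
        flags.append(corrupted)

    lengths = np.array([len(cyc) for cyc in cycles])
    boundaries = np.concatenate([[0], np.cumsum(lengths)])
    x = np.concatenate(cycles)
    clean = np.concatenate(clean_cycles) if noise.corrupt_kind == "amplitude" \
        else np.concatenate(cycles)  # period mutations change the length

    n = x.size
    t = np.arange(n) / fs
    y = x.copy()
    if noise.baseline_amp > 0:
        y += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.powerline_amp > 0:
        y += noise.powerline_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if noise.phase_slope != 0.0:
        for i in range(n_cycles):
            s, e = boundaries[i], boundaries[i + 1]
            y[s:e] += noise.phase_slope * np.arange(e - s)
    if noise.white_sd > 0:
        y += rng.normal(0.0, noise.white_sd, size=n)

    truth = RecordTruth(label=class_label, params=params_list,
                        corrupted=np.array(flags), boundaries=boundaries,
                        clean=SignalTrace(clean, fs=fs), seed=seed)
    return SignalTrace(y, fs=fs), truth


def scan_grid_fixture(true_surface_coeffs, noise_sd: float = 0.0,
                      seed: int | None = None):
    """Amplitudes on the standard 5x5 wrist scan layout.

    ``z = a0 x^2 + a1 x y + a2 y^2 + a3 x + a4 y + a5`` plus Gaussian
    noise at each of the 25 standard coordinates.  Returns a
    :class:`pulsekit.pulse_finding.ScanGrid`.
    """
    from .pulse_finding import ScanGrid  # local import to avoid a cycle

    a = np.asarray(true_surface_coeffs, dtype=float)
    if a.shape != (6,):
        raise ValueError("expected 6 surface coefficients")
    rng = np.random.default_rng(seed)
    x, y = SCAN_COORDS[:, 0], SCAN_COORDS[:, 1]
    z = a[0] * x**2 + a[1] * x * y + a[2] * y**2 + a[3] * x + a[4] * y + a[5]
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.size)
    return ScanGrid(np.column_stack([x, y, np.maximum(z, 0.0)]))


def pressure_sweep_fixture(optimum_mmHg: float, seed: int | None = None,
                           fs: float = 125.0):
    """Cuff-pressure sweep with a known oscillometric optimum.

    The cuff deflates 160 -> 60 mmHg at 4 mmHg/s (25 s).  Per-cycle pulse
    amplitude follows a unimodal Gaussian envelope in cuff pressure
    peaking at ``optimum_mmHg`` (sigma 18 mmHg), plus small noise.

    Returns
    -------
    (SignalTrace, pandas.Series)
        The cuff-pressure trace (mmHg) and per-cycle amplitudes indexed
        by cycle time in seconds.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    duration = (160.0 - 60.0) / 4.0
    t = np.arange(int(round(duration * fs))) / fs
    pressure = 160.0 - 4.0 * t
    cycle_T = 0.9
    cycle_times = np.arange(0.0, duration - cycle_T, cycle_T)
    p_at_cycle = 160.0 - 4.0 * cycle_times
    amp = 30.0 + 90.0 * np.exp(-((p_at_cycle - optimum_mmHg) ** 2) / (2 * 18.0**2))
    amp = amp + rng.normal(0.0, 0.5, size=amp.size)
    series = pd.Series(amp, index=cycle_times, name="amplitude")
    series.index.name = "time_s"
    return SignalTrace(pressure, fs=fs, unit="mmHg"), series
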