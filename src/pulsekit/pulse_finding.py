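"""Adaptive localization of the radial-artery key points (Cun, Guan, Chi).

A wrist scan gives pulse amplitudes z at known (x, y) positions (cm,
origin at the radial styloid protrusion, x toward the palm edge, y along
the arm).  A full quadratic surface

    z = a0 x^2 + a1 x y + a2 y^2 + a3 x + a4 y + a5

is least-squares fitted to the scan, then the three sensor positions --
collinear, equally spaced 1.5 cm apart, mirroring the three-finger
palpation layout -- are placed to maximize the mean fitted amplitude
subject to a minimum per-point amplitude (60 ADC counts).  The array's
angle to the arm axis is theta = arctan((x2-x1)/(y2-y1)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .waveform import SignalTrace

__all__ = [
    "ScanGrid",
    "SurfaceFit",
    "KeyPoints",
    "NoPulseFoundError",
    "fit_surface",
    "locate_key_points",
    "array_angle",
    "optimal_cuff_pressure",
]


class NoPulseFoundError(ValueError):
    """Raised when no feasible sensor placement reaches the amplitude floor."""


@dataclass
class ScanGrid:
    """Wrist-scan observations: rows of (x_cm, y_cm, amplitude)."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (x, y, z)")
        if self.points.shape[0] < 6:
            raise ValueError("need at least 6 scan points for a 6-parameter surface")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("scan points must be finite")
        if np.any(self.points[:, 2] < 0):
            raise ValueError("amplitudes must be >= 0")

    @property
    def x(self):
        return self.points[:, 0]

    @property
    def y(self):
        return self.points[:, 1]

    @property
    def z(self):
        return self.points[:, 2]

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        cols = ["x_cm", "y_cm", "amplitude"]
        if not all(c in df.columns for c in cols):
            raise ValueError(f"scan CSV must have columns {cols}")
        return cls(df[cols].to_numpy())


@dataclass
class SurfaceFit:
    """Fitted quadratic amplitude surface."""

    a: np.ndarray                  #: coefficients (a0..a5)
    rss: float                     #: residual sum of squares
    x_range: tuple = (0.25, 1.75)  #: scanned x extent (cm)
    y_range: tuple = (-3.0, 3.0)   #: scanned y extent (cm)

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (6,):
            raise ValueError("expected 6 coefficients")
        if not np.all(np.isfinite(self.a)) or self.rss < 0:
            raise ValueError("invalid surface fit")

    def __call__(self, x, y):
        a = self.a
        return a[0] * x**2 + a[1] * x * y + a[2] * y**2 + a[3] * x + a[4] * y + a[5]


@dataclass
class KeyPoints:
    """Located Chi, Guan, Cun positions (ordered by increasing y)."""

    p0: tuple   #: Chi (proximal, smallest y)
    p1: tuple   #: Guan (center)
    p2: tuple   #: Cun (distal, largest y)
    theta: float
    mean_amp: float
    z: tuple    #: fitted amplitudes at the three points
    spacing_cm: float = 1.5

    def __post_init__(self):
        d2 = self.spacing_cm**2
        for a, b in ((self.p0, self.p1), (self.p1, self.p2)):
            s = (b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2
            if abs(s - d2) > 1e-6:
                raise ValueError(f"adjacent squared spacing {s} != {d2}")
        mid = ((self.p0[0] + self.p2[0]) / 2, (self.p0[1] + self.p2[1]) / 2)
        if abs(mid[0] - self.p1[0]) > 1e-6 or abs(mid[1] - self.p1[1]) > 1e-6:
            raise ValueError("points must be collinear and equally spaced")
        if not (self.p0[1] < self.p1[1] < self.p2[1]):
            raise ValueError("points must be ordered y0 < y1 < y2")

    def to_dict(self):
        return {
            "chi": list(self.p0), "guan": list(self.p1), "cun": list(self.p2),
            "theta_rad": self.theta, "mean_amp": self.mean_amp,
            "amplitudes": list(self.z), "spacing_cm": self.spacing_cm,
        }


def fit_surface(grid: ScanGrid) -> SurfaceFit:
    """Least-squares fit of the 6-parameter quadratic surface to a scan."""
    x, y, z = grid.x, grid.y, grid.z
    A = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
    rank = np.linalg.matrix_rank(A)
    if rank < 6:
        raise ValueError(
            f"rank-deficient scan design (rank {rank} < 6): points do not "
            "span a quadratic surface (e.g. collinear or duplicated positions)"
        )
    a, _, _, _ = np.linalg.lstsq(A, z, rcond=None)
    rss = float(np.sum((A @ a - z) ** 2))
    return SurfaceFit(a=a, rss=rss,
                      x_range=(float(x.min()), float(x.max())),
                      y_range=(float(y.min()), float(y.max())))


def _triple(x1, y1, theta, spacing):
    """The three collinear points for center (x1, y1) and array angle theta."""
    dx, dy = spacing * np.sin(theta), spacing * np.cos(theta)
    return (x1 - dx, y1 - dy), (x1, y1), (x1 + dx, y1 + dy)


def _mean_amp(surface, x1, y1, theta, spacing):
    dx, dy = spacing * np.sin(theta), spacing * np.cos(theta)
    z0 = surface(x1 - dx, y1 - dy)
    z1 = surface(x1, y1)
    z2 = surface(x1 + dx, y1 + dy)
    return (z0 + z1 + z2) / 3.0, z0, z1, z2


def locate_key_points(surface: SurfaceFit, spacing_cm: float = 1.5,
                      min_amp: float = 60.0, coarse_xy: float = 0.05,
                      coarse_theta: float = 0.02) -> KeyPoints:
    """Place the three-sensor array to maximize mean fitted amplitude.

    Searches centers (x1, y1) over the scanned rectangle expanded by one
    spacing and angles theta in (-pi/2, pi/2), coarse grid first
    (0.05 cm / 0.02 rad) then local refinement, subject to all three
    fitted amplitudes >= ``min_amp``.  Ties break toward smallest
    |theta|, then smallest y1.
    """
    margin = spacing_cm
    xs = np.arange(surface.x_range[0] - margin, surface.x_range[1] + margin + 1e-9,
                   coarse_xy)
    ys = np.arange(surface.y_range[0] - margin, surface.y_range[1] + margin + 1e-9,
                   coarse_xy)
    thetas = np.arange(-np.pi / 2 + coarse_theta, np.pi / 2, coarse_theta)
    X1, Y1 = np.meshgrid(xs, ys, indexing="ij")

    best = None  # (mean, |theta|, y1, x1, theta)
    for theta in thetas:
        mean, z0, z1, z2 = _mean_amp(surface, X1, Y1, theta, spacing_cm)
        feas = (z0 >= min_amp) & (z1 >= min_amp) & (z2 >= min_amp)
        if not np.any(feas):
            continue
        m = np.where(feas, mean, -np.inf)
        idx = np.unravel_index(np.argmax(m), m.shape)
        cand = (float(m[idx]), abs(theta), float(Y1[idx]), float(X1[idx]), float(theta))
        if best is None or (cand[0] - best[0] > 1e-12) or (
            abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    if best is None:
        raise NoPulseFoundError(
            f"no pulse found: no feasible sensor placement with all three "
            f"amplitudes >= {min_amp}"
        )

    _, _, y1_0, x1_0, th_0 = best
    lo = (surface.x_range[0] - margin, surface.y_range[0] - margin)
    hi = (surface.x_range[1] + margin, surface.y_range[1] + margin)

    def neg(v):
        x1, y1, th = v
        if not (lo[0] <= x1 <= hi[0] and lo[1] <= y1 <= hi[1]
                and -np.pi / 2 < th < np.pi / 2):
            return 1e12
        mean, z0, z1, z2 = _mean_amp(surface, x1, y1, th, spacing_cm)
        if min(z0, z1, z2) < min_amp:
            return 1e12
        return -mean

    res = optimize.minimize(neg, x0=[x1_0, y1_0, th_0], method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    if res.fun < -best[0]:
        x1, y1, theta = map(float, res.x)
    else:
        x1, y1, theta = x1_0, y1_0, th_0

    mean, z0, z1, z2 = _mean_amp(surface, x1, y1, theta, spacing_cm)
    p0, p1, p2 = _triple(x1, y1, theta, spacing_cm)
    return KeyPoints(p0=p0, p1=p1, p2=p2, theta=theta, mean_amp=float(mean),
                     z=(float(z0), float(z1), float(z2)), spacing_cm=spacing_cm)


def array_angle(keypoints: KeyPoints) -> float:
    """Angle between the sensor array and the arm (y) axis.

    theta = arctan((x2 - x1) / (y2 - y1)); undefined when the array is
    perpendicular to the arm axis (y2 == y1).
    """
    (x1, y1), (x2, y2) = keypoints.p1, keypoints.p2
    if y2 == y1:
        raise ValueError("array angle undefined: y2 == y1")
    return math.atan((x2 - x1) / (y2 - y1))


def optimal_cuff_pressure(pressure: SignalTrace, amplitude_per_cycle):
    """Cuff pressure at which the per-cycle pulse amplitude peaks.

    Parameters
    ----------
    pressure : SignalTrace
        Cuff pressure in mmHg, sampled at the acquisition rate.
    amplitude_per_cycle : pandas.Series
        Per-cycle pulse amplitude (ADC counts) indexed by cycle time in
        seconds, aligned with the pressure trace.

    Returns
    -------
    (float, float)
        Optimal pressure (mmHg) and the amplitude there.  Ties break to
        the higher cuff pressure; a monotone envelope returns the
        boundary pressure with a warning.
    """
    amp = np.asarray(amplitude_per_cycle, dtype=float)
    if amp.size == 0 or len(pressure.samples) == 0:
        raise ValueError("empty input")
    if amp.size < 3:
        raise ValueError("need at least 3 cycles")
    times = np.asarray(amplitude_per_cycle.index, dtype=float)
    idx = np.clip(np.round(times * pressure.fs).astype(int), 0,
                  len(pressure.samples) - 1)
    p_cycle = pressure.samples[idx]

    best_amp = amp.max()
    at_best = np.flatnonzero(amp == best_amp)
    k = at_best[np.argmax(p_cycle[at_best])]  # tie-break: higher pressure
    if k == 0 or k == amp.size - 1:
        warnings.warn("amplitude envelope peaks at sweep boundary; optimum "
                      "may lie outside the swept range", stacklevel=2)
    return float(p_cycle[k]), float(amp[k])
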