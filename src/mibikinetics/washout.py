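"""Diagnostic statistics computed from time-activity curves.

The central quantity is the washout rate coefficient

    K_WOR = 1 - (A2 - F2) / (A1 - F1)

where (A1, F1) are the tumor and normal-tissue concentrations at an early
time point and (A2, F2) the same at a late time point (conventionally
60-240 min post injection).  K_WOR measures the fractional loss of
tumor-over-background uptake between the two scans and serves as a proxy for
P-glycoprotein (PGP) mediated tracer efflux: a coefficient below 0.45
indicates low PGP expression, at or above 0.45 high expression.

The module also provides clearance (injected activity over area under the
curve), the classical three-phase segmentation of a time-activity curve
(vascular rise / secretory plateau / excretory decline) and tissue-background
subtraction.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError
from .model import Trajectory

__all__ = [
    "PGP_THRESHOLD",
    "PgpExpression",
    "WashoutResult",
    "CurveSegments",
    "k_wor",
    "classify_pgp",
    "k_wor_from_trajectory",
    "clearance",
    "segment_curve",
    "background_subtract",
]

#: Clinical decision threshold on K_WOR separating low from high PGP expression.
PGP_THRESHOLD = 0.45


class PgpExpression(str, enum.Enum):
    """PGP-expression call derived from the washout coefficient."""

    LOW = "low_pgp"
    HIGH = "high_pgp"


def k_wor(a1: float, f1: float, a2: float, f2: float) -> float:
    """Washout rate coefficient 1 - (a2 - f2)/(a1 - f1).

    ``a1``/``a2`` are tumor concentrations and ``f1``/``f2`` normal-tissue
    (background) concentrations at the early and late time points.  The
    coefficient is invariant under a common rescaling of all four inputs.

    Raises
    ------
    DegenerateDataError
        If the early contrast ``a1 - f1`` is not positive (no tumor uptake
        above background, so washout is undefined).
    """
    early = a1 - f1
    if not early > 0:
        raise DegenerateDataError(
            f"early tumor-over-background contrast must be positive, got a1-f1={early!r}"
        )
    return 1.0 - (a2 - f2) / early


def classify_pgp(k: float, threshold: float = PGP_THRESHOLD) -> PgpExpression:
    """Classify PGP expression from K_WOR.

    Values below the threshold → low expression; values at or above it →
    high expression (the boundary is resolved upward so the high-risk call
    is the conservative one).
    """
    return PgpExpression.HIGH if k >= threshold else PgpExpression.LOW


@dataclass(frozen=True)
class WashoutResult:
    """K_WOR with the time points, concentrations and classification used."""

    k_wor: float
    t1: float
    t2: float
    a1: float
    f1: float
    a2: float
    f2: float
    classification: PgpExpression
    threshold: float = PGP_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "k_wor": self.k_wor,
            "t1_h": self.t1,
            "t2_h": self.t2,
            "a1": self.a1,
            "f1": self.f1,
            "a2": self.a2,
            "f2": self.f2,
            "classification": self.classification.value,
            "threshold": self.threshold,
        }


def k_wor_from_trajectory(
    traj: Trajectory,
    t2: float = 4.0,
    t1_rule: str = "peak_contrast",
    t1: float | None = None,
    threshold: float = PGP_THRESHOLD,
) -> WashoutResult:
    """Evaluate K_WOR on a simulated or measured trajectory.

    The tumor series plays A and the normal series plays F.  The late time
    ``t2`` (default 4 h, the upper end of the conventional 60-240 min window)
    is snapped to the nearest grid point.  The early time is either the grid
    argmax of the tumor-minus-normal contrast before ``t2``
    (``t1_rule="peak_contrast"``, the reproducible analogue of "maximum
    accumulation") or a user-supplied ``t1`` (``t1_rule="fixed"``).
    """
    i2 = traj.index_at(t2)
    if i2 == 0:
        raise ValueError(f"late time t2={t2} h must lie strictly after the grid start")
    if t1_rule == "peak_contrast":
        i1 = int(np.argmax(traj.contrast[:i2]))
    elif t1_rule == "fixed":
        if t1 is None:
            raise ValueError("t1_rule='fixed' requires an explicit t1")
        i1 = traj.index_at(t1)
        if i1 >= i2:
            raise ValueError(f"t1={t1} h must precede t2={t2} h on the grid")
    else:
        raise ValueError(f"unknown t1_rule {t1_rule!r}; expected 'peak_contrast' or 'fixed'")
    a1, f1 = float(traj.x[i1]), float(traj.y[i1])
    a2, f2 = float(traj.x[i2]), float(traj.y[i2])
    k = k_wor(a1, f1, a2, f2)
    return WashoutResult(
        k_wor=k,
        t1=float(traj.times[i1]),
        t2=float(traj.times[i2]),
        a1=a1,
        f1=f1,
        a2=a2,
        f2=f2,
        classification=classify_pgp(k, threshold),
        threshold=threshold,
    )


def clearance(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    series: str = "blood",
    extrapolate: bool = False,
    n0: float | None = None,
) -> float:
    """Clearance: injected activity divided by the area under the curve.

    The AUC is computed by the trapezoid rule on the grid over ``window``
    (default: the full trajectory span), with the window endpoints obtained
    by linear interpolation when they fall between grid points.  With
    ``extrapolate=True`` the analytic tail beyond the window is added using
    the terminal log-slope of the curve (the mono-exponential tail integral
    ``C_end / k_term``), giving the infinite-window clearance.
    """
    if n0 is None:
        if traj.params is None:
            raise ValueError("trajectory has no parameters; pass n0 explicitly")
        n0 = traj.params.n0
    values = traj.series(series)
    t_lo, t_hi = window if window is not None else (traj.times[0], traj.times[-1])
    if not (traj.times[0] <= t_lo < t_hi <= traj.times[-1]):
        raise ValueError(
            f"window [{t_lo}, {t_hi}] h must lie within the trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}] h"
        )
    inside = (traj.times > t_lo) & (traj.times < t_hi)
    t_grid = np.concatenate(([t_lo], traj.times[inside], [t_hi]))
    v_grid = np.concatenate(
        ([np.interp(t_lo, traj.times, values)], values[inside], [np.interp(t_hi, traj.times, values)])
    )
    auc = float(np.trapezoid(v_grid, t_grid))
    if extrapolate:
        auc += _tail_area(t_grid, v_grid)
    if not auc > 0:
        raise DegenerateDataError(f"area under the {series} curve is not positive ({auc!r})")
    return n0 / auc


def _tail_area(t: np.ndarray, v: np.ndarray) -> float:
    """Mono-exponential tail integral from the last two points of a curve."""
    if len(t) < 2 or v[-1] <= 0 or v[-2] <= 0:
        raise DegenerateDataError("tail extrapolation needs two positive terminal values")
    k_term = np.log(v[-2] / v[-1]) / (t[-1] - t[-2])
    if not k_term > 0:
        raise DegenerateDataError(
            f"terminal slope must be negative for tail extrapolation (k_term={k_term:.4g})"
        )
    return float(v[-1] / k_term)


@dataclass(frozen=True)
class CurveSegments:
    """Three-phase partition of a time-activity curve.

    Each segment is a half-open index range ``(start, stop)`` into the grid;
    an empty segment has ``start == stop``.  The three ranges are contiguous
    and jointly cover the whole grid.
    """

    times: np.ndarray
    vascular: tuple[int, int]
    secretory: tuple[int, int]
    excretory: tuple[int, int]

    def interval(self, name: str) -> tuple[float, float] | None:
        """Time interval of a segment, or None when the segment is empty."""
        start, stop = getattr(self, name)
        if start == stop:
            return None
        return (float(self.times[start]), float(self.times[stop - 1]))


def segment_curve(
    times: np.ndarray, values: np.ndarray, rise_frac: float = 0.05
) -> CurveSegments:
    """Partition a time-activity curve into vascular / secretory / excretory
    phases by thresholding the finite-difference slope.

    The vascular (rapid-growth) phase runs from the start until the slope
    first drops below ``rise_frac`` times the peak positive slope; the
    excretory (decline) phase is the terminal run where the slope stays below
    minus that threshold; the secretory plateau is everything in between.
    A curve with no significant rise anywhere is a single secretory plateau.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if times.size < 3:
        raise ValueError(f"need at least 3 points to segment a curve, got {times.size}")
    if not np.all(np.diff(times) > 0):
        raise ValueError("time grid must be strictly increasing")

    slope = np.gradient(values, times)
    peak_slope = float(slope.max())
    scale = np.max(np.abs(values))
    n = times.size
    if peak_slope <= 1e-12 * max(scale, 1.0):
        # no rise anywhere: a flat or declining curve is all plateau unless it
        # declines significantly, in which case the decline is excretory
        threshold = rise_frac * float(np.abs(slope).max())
        i_exc = _terminal_decline_start(slope, threshold, start=0)
        return CurveSegments(times, (0, 0), (0, i_exc), (i_exc, n))

    threshold = rise_frac * peak_slope
    below = np.nonzero(slope < threshold)[0]
    i_vasc = int(below[0]) if below.size else n
    i_exc = _terminal_decline_start(slope, threshold, start=i_vasc)
    return CurveSegments(times, (0, i_vasc), (i_vasc, i_exc), (i_exc, n))


def _terminal_decline_start(slope: np.ndarray, threshold: float, start: int) -> int:
    """First index of the terminal run with slope < -threshold (or n if none)."""
    n = slope.size
    if threshold <= 0:
        return n
    i = n
    while i > start and slope[i - 1] < -threshold:
        i -= 1
    return i


def background_subtract(
    region_curve: np.ndarray, background_curve: np.ndarray
) -> np.ndarray:
    """Subtract the tissue-background curve from a lesion curve, floored at 0.

    Points where the background exceeds the lesion signal are reported as
    zero (counts cannot be negative); a warning carries the number of floored
    points.
    """
    region = np.asarray(region_curve, dtype=float)
    background = np.asarray(background_curve, dtype=float)
    if region.shape != background.shape:
        raise ValueError(
            f"curves must share a grid: {region.shape} vs {background.shape}"
        )
    net = region - background
    n_clipped = int(np.sum(net < 0))
    if n_clipped:
        warnings.warn(
            f"background exceeded the region curve at {n_clipped} point(s); floored at 0",
            stacklevel=2,
        )
    return np.maximum(net, 0.0)
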