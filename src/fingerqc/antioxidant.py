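"""Radical-scavenging antioxidant metrics.

Off-line: percent inhibition from paired control/sample absorbances and
IC50 (concentration scavenging 50% of radicals) by linear regression of
inhibition on concentration over the tested range.

On-line: post-column reaction traces show antioxidant components as
*negative* peaks; this module detects sub-baseline excursions in the
reaction-channel trace and associates them with parent peaks of the
separation channel after the reaction-coil transit delay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, DegenerateInputError, ValidationError

# Reaction coil geometry defaults: 5000 mm of 0.18 mm i.d. tubing,
# 0.8 mL/min column flow + 0.3 mL/min reagent flow.
COIL_LENGTH_MM = 5000.0
COIL_ID_MM = 0.18
COMBINED_FLOW_ML_MIN = 1.1


@dataclass(frozen=True)
class DPPHResult:
    batch_id: str
    concentrations: np.ndarray  # mg/mL
    inhibitions: np.ndarray  # percent
    ic50: float  # mg/mL
    fit: tuple[float, float]  # (slope, intercept) of inhibition vs concentration
    extrapolated: bool


@dataclass(frozen=True)
class ActivityPeak:
    apex_time: float  # minutes
    depth: float  # magnitude of the negative excursion


@dataclass
class ActivityFingerprint:
    batch_id: str
    activity_peaks: list[ActivityPeak]
    associations: dict[str, int | None]  # parent peak id -> activity peak index
    delay: float  # minutes


def inhibition(a_control: float, a_sample: float) -> float:
    """Percent inhibition from control and sample absorbances.

    Negative values (sample absorbs more than control) are returned as-is
    with a warning rather than clamped.
    """
    if a_control <= 0:
        raise ValidationError(f"control absorbance must be positive, got {a_control}")
    value = (a_control - a_sample) / a_control * 100.0
    if value < 0:
        warnings.warn(f"negative inhibition {value:.2f}%", stacklevel=2)
    return value


def estimate_ic50(concentrations, inhibitions, batch_id: str = "") -> DPPHResult:
    """IC50 from the least-squares line of %inhibition on concentration.

    The 50% crossing is read off the fitted line; the ``extrapolated`` flag
    is set when 50% lies outside the observed inhibition range.
    """
    c = np.asarray(concentrations, dtype=float)
    inh = np.asarray(inhibitions, dtype=float)
    if c.shape != inh.shape:
        raise ValidationError("concentration and inhibition lists differ in length")
    if np.unique(c).size < 3:
        raise ValidationError("need at least 3 distinct concentration levels")
    res = stats.linregress(c, inh)
    if res.slope <= 0:
        raise ComputationError(f"no dose response (slope {res.slope:.4g} <= 0)")
    ic50 = (50.0 - res.intercept) / res.slope
    extrapolated = not (inh.min() <= 50.0 <= inh.max())
    return DPPHResult(batch_id=batch_id, concentrations=c, inhibitions=inh,
                      ic50=float(ic50), fit=(float(res.slope), float(res.intercept)),
                      extrapolated=bool(extrapolated))


def coil_delay(length_mm: float = COIL_LENGTH_MM, id_mm: float = COIL_ID_MM,
               flow_ml_min: float = COMBINED_FLOW_ML_MIN) -> float:
    """Transit delay (minutes) of the reaction coil: volume / combined flow."""
    if min(length_mm, id_mm, flow_ml_min) <= 0:
        raise ValidationError("coil dimensions and flow must be positive")
    radius_cm = id_mm / 2.0 / 10.0
    volume_ml = math.pi * radius_cm**2 * (length_mm / 10.0)
    return volume_ml / flow_ml_min


def detect_activity_peaks(time, intensity, baseline_window: float = 2.0,
                          min_depth: float = 3.0) -> list[ActivityPeak]:
    """Find negative peaks in a reaction-channel trace.

    The baseline is a centered rolling median over ``baseline_window``
    minutes; contiguous runs below baseline whose maximum depth reaches
    ``min_depth`` are reported with the apex at the deepest sample.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.shape != y.shape or t.size < 3:
        raise ValidationError("time and intensity must be equal-length series (>=3)")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time axis must be strictly increasing")
    if min_depth <= 0:
        raise ValidationError("min_depth must be positive")
    dt = float(np.median(np.diff(t)))
    win = max(3, int(round(baseline_window / dt)) | 1)  # odd window
    baseline = pd.Series(y).rolling(win, center=True, min_periods=1).median().to_numpy()
    depth = baseline - y
    below = depth > 0
    peaks: list[ActivityPeak] = []
    i = 0
    n = t.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        seg = slice(i, j)
        apex = i + int(np.argmax(depth[seg]))
        if depth[apex] >= min_depth:
            peaks.append(ActivityPeak(apex_time=float(t[apex]), depth=float(depth[apex])))
        i = j
    return peaks


def associate_activity(parent_rts, activity_peaks, delay: float | None = None,
                       tolerance: float = 0.05, parent_ids=None,
                       batch_id: str = "") -> ActivityFingerprint:
    """Greedily match parent peaks (shifted by ``delay``) to activity peaks.

    Parents are processed in elution order and matched to the nearest
    unclaimed activity apex within ``tolerance``; parents with no match map
    to ``None`` (components without radical-scavenging activity).
    """
    if delay is None:
        delay = coil_delay()
    if delay < 0:
        raise ValidationError("delay must be non-negative")
    rts = np.asarray(parent_rts, dtype=float)
    ids = list(parent_ids) if parent_ids is not None else [f"P{i+1:02d}" for i in range(rts.size)]
    if len(ids) != rts.size:
        raise ValidationError("parent_ids length must match parent_rts")
    apexes = np.array([p.apex_time for p in activity_peaks], dtype=float)
    taken: set[int] = set()
    associations: dict[str, int | None] = {}
    for pid, rt in sorted(zip(ids, rts), key=lambda x: x[1]):
        expected = rt + delay
        best, best_dist = None, tolerance
        for k, apex in enumerate(apexes):
            if k in taken:
                continue
            d = abs(apex - expected)
            if d <= best_dist:
                best, best_dist = k, d
        associations[pid] = best
        if best is not None:
            taken.add(best)
    return ActivityFingerprint(batch_id=batch_id, activity_peaks=list(activity_peaks),
                               associations=associations, delay=float(delay))
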