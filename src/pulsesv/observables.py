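"""Extraction of the matched observables from a simulated field.

The inverse estimator matches three numbers per subject: brachial systolic and
diastolic pressure, and the model carotid-femoral pulse wave velocity.  Model
cfPWV mirrors the clinical measurement convention: wave feet are located by
the intersecting-tangent method and the travel distance is the subtracted
path length (root->femoral minus root->carotid), as in sequential
carotid/femoral tonometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ValidationError
from .solver import PressureFlowField
from .tree import ArterialTree

__all__ = ["HemodynamicTriplet", "brachial_pressures", "foot_time", "model_cfpwv"]

#: low-pass cutoff (Hz) for the upstroke-derivative smoothing
FOOT_LP_HZ = 25.0
#: the tangent is fitted where the slope exceeds this fraction of its peak
FOOT_SLOPE_FRACTION = 0.8


@dataclass(frozen=True)
class HemodynamicTriplet:
    """(brachial SBP, brachial DBP, carotid-femoral PWV)."""

    brsbp_mmhg: float
    brdbp_mmhg: float
    cfpwv_mps: float

    def __post_init__(self):
        if not (self.brsbp_mmhg > self.brdbp_mmhg):
            raise ValidationError("SBP must exceed DBP")
        if self.cfpwv_mps <= 0:
            raise ValidationError("cfPWV must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.brsbp_mmhg, self.brdbp_mmhg, self.cfpwv_mps])


def brachial_pressures(field: PressureFlowField) -> tuple[float, float]:
    """(SBP, DBP) = (max, min) of the final-beat brachial-site pressure."""
    if "brachial" not in field.pressures:
        raise ValidationError("field does not contain the brachial site")
    p = field.pressures["brachial"]
    return float(np.max(p)), float(np.min(p))


def _smooth_periodic(p: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase low-pass of one periodic beat (filter on three tiled periods)."""
    if cutoff >= 0.45 * fs:
        return p.copy()
    b, a = signal.butter(4, cutoff / (0.5 * fs))
    tiled = np.concatenate([p, p, p])
    sm = signal.filtfilt(b, a, tiled)
    n = len(p)
    return sm[n:2 * n]


def foot_time(t: np.ndarray, p: np.ndarray) -> float:
    """Wave-foot time by the intersecting-tangent construction.

    The foot is the intersection of the horizontal line through the diastolic
    minimum with the maximum-upstroke tangent.  The slope is taken on a 25 Hz
    low-passed copy (central differences) and the tangent is fitted over the
    region of near-maximal slope; the diastolic minimum is the beat minimum of
    the raw wave.  The construction is invariant to adding a constant and to
    uniform amplitude scaling.
    """
    n = len(p)
    if n < 8:
        raise ValidationError("beat too short for foot detection")
    if np.ptp(p) <= 1e-9 * max(1.0, float(np.max(np.abs(p)))):
        raise ValidationError("no rising edge found (flat wave)")
    fs = 1.0 / (t[1] - t[0])
    sm = _smooth_periodic(p, fs, FOOT_LP_HZ)
    dp = np.gradient(sm, t)
    dp_max = float(np.max(dp))
    if dp_max <= 0:
        raise ValidationError("no rising edge found")
    # The tangent is fitted by weighted least squares over the region of
    # maximal upstroke slope (weights ramp up above FOOT_SLOPE_FRACTION of the
    # peak derivative).  A point tangent at the single argmax sample is
    # ill-defined when the upstroke is quasi-linear (flat derivative
    # plateau); the fitted tangent varies smoothly with the waveform and is
    # affine-invariant like the point construction.
    wgt = np.clip(dp - FOOT_SLOPE_FRACTION * dp_max, 0.0, None)
    wsum = float(np.sum(wgt))
    t_bar = float(np.sum(wgt * t)) / wsum
    p_bar = float(np.sum(wgt * sm)) / wsum
    slope = float(np.sum(wgt * (t - t_bar) * (sm - p_bar))
                  / np.sum(wgt * (t - t_bar) ** 2))
    if slope <= 0:
        raise ValidationError("no rising edge found")
    pmin = float(np.min(p))  # diastolic minimum of the beat
    return float(t_bar - (p_bar - pmin) / slope)


def model_cfpwv(field: PressureFlowField, tree: ArterialTree) -> float:
    """Simulated carotid-femoral PWV (m/s) by foot-to-foot transit.

    Transit time is the difference of the intersecting-tangent feet of the
    femoral- and carotid-site pressure waves; the distance is the difference
    of the root->site path lengths along the tree.
    """
    for site in ("carotid", "femoral"):
        if site not in field.pressures:
            raise ValidationError(f"field does not contain the {site} site")
    t_c = foot_time(field.t, field.pressures["carotid"])
    t_f = foot_time(field.t, field.pressures["femoral"])
    transit = t_f - t_c
    if transit <= 0:
        raise ValidationError(
            f"non-positive carotid-femoral transit time ({transit * 1e3:.2f} ms): "
            "degenerate wave or site mixup")
    dist = field.site_positions_m["femoral"] - field.site_positions_m["carotid"]
    return dist / transit


def extract_triplet(field: PressureFlowField, tree: ArterialTree) -> HemodynamicTriplet:
    """The three observables exactly as the optimizer consumes them."""
    sbp, dbp = brachial_pressures(field)
    return HemodynamicTriplet(sbp, dbp, model_cfpwv(field, tree))
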