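"""Accelerometer preprocessing for trunk-mounted running recordings.

Implements the preparation chain applied to each subject's tri-axial
lower-back acceleration record before feature extraction:

1. whole-series tilt correction (arcsine-of-mean angle estimate, sequential
   plane rotations, static-gravity removal),
2. running-stage localization from vertical-acceleration peaks,
3. cropping of the unsteady start/end of every stage,
4. re-correction of the cropped raw signal in non-overlapping two-minute
   windows, which limits the damage done by the constant-tilt assumption
   when the runner's lean drifts with fatigue.

Also hosts the cohort record type and the study-style exclusion filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "AccelTrace",
    "RunningStage",
    "TiltAngles",
    "CohortRecord",
    "CorrectedWindow",
    "ExclusionReport",
    "StageDetectionParams",
    "TiltEstimationError",
    "estimate_tilt",
    "tilt_correct",
    "detect_running_stages",
    "crop_stage",
    "windowed_correction",
    "apply_exclusions",
    "flag_leading_quiet_segment",
]

GENDERS = ("male", "female")
STATUSES = ("LLOI", "non-LLOI", "none", "unknown")


class TiltEstimationError(ValueError):
    """Mean horizontal acceleration >= 1 g: sensor mis-scaled or not static-dominated."""


@dataclass
class AccelTrace:
    """One subject's tri-axial acceleration record, in units of g.

    Axes follow the lower-back sensor convention: ``vt`` vertical,
    ``ml`` medial-lateral, ``ap`` anterior-posterior.
    """

    subject_id: str
    fs: float
    vt: np.ndarray
    ml: np.ndarray
    ap: np.ndarray

    def __post_init__(self) -> None:
        self.vt = np.asarray(self.vt, dtype=np.float64)
        self.ml = np.asarray(self.ml, dtype=np.float64)
        self.ap = np.asarray(self.ap, dtype=np.float64)
        if not (len(self.vt) == len(self.ml) == len(self.ap)):
            raise ValueError("axis arrays must have equal length")
        if len(self.vt) < 1:
            raise ValueError("trace must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in ("vt", "ml", "ap"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in axis {name!r}")

    def __len__(self) -> int:
        return len(self.vt)

    @property
    def duration_s(self) -> float:
        return len(self.vt) / self.fs


@dataclass(frozen=True, order=True)
class RunningStage:
    """Half-open sample interval [start, end) of steady running."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid stage [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TiltAngles:
    """Sensor tilt in the anterior-posterior and medial-lateral planes, radians."""

    theta_ap: float
    theta_ml: float

    def __post_init__(self) -> None:
        for name in ("theta_ap", "theta_ml"):
            v = getattr(self, name)
            if not -math.pi / 2 < v < math.pi / 2:
                raise ValueError(f"{name} out of (-pi/2, pi/2): {v}")


@dataclass
class CohortRecord:
    """Questionnaire, Cooper-test distance and injury label for one subject.

    ``status`` is one of ``LLOI`` (lower-limb overuse injury during follow-up),
    ``non-LLOI`` (some other diagnosed injury), ``none`` (no injury) or
    ``unknown`` (lost to follow-up). Numeric fields may be NaN/None to mark a
    missing questionnaire answer. ``injury_detail`` optionally refines a
    non-LLOI status (e.g. ``traumatic``).
    """

    subject_id: str
    gender: str
    mass_kg: Optional[float] = None
    height_cm: Optional[float] = None
    prev_injury: Optional[bool] = None
    insoles: Optional[bool] = None
    distance_m: Optional[float] = None
    status: str = "none"
    running_time_s: Optional[float] = None
    injury_detail: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}, expected one of {STATUSES}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}, expected one of {GENDERS}")

    def has_missing(self) -> bool:
        """True if any questionnaire/distance field is absent."""
        def _miss(v) -> bool:
            if v is None:
                return True
            if isinstance(v, float) and math.isnan(v):
                return True
            return False

        return any(
            _miss(v)
            for v in (self.mass_kg, self.height_cm, self.prev_injury, self.insoles, self.distance_m)
        )


@dataclass
class CorrectedWindow:
    """A tilt- and gravity-corrected window of one running stage.

    ``start``/``end`` locate the window in the source trace; ``tilt`` is the
    per-window angle estimate taken on the *uncorrected* signal, which doubles
    as the trunk-lean reading used by the lean-angle features.
    """

    subject_id: str
    start: int
    end: int
    fs: float
    vt: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    tilt: TiltAngles

    @property
    def resultant(self) -> np.ndarray:
        return np.sqrt(self.vt**2 + self.ml**2 + self.ap**2)


@dataclass(frozen=True)
class StageDetectionParams:
    """Thresholds separating running from walking/disturbance blocks.

    Running produces high-impact vertical peaks (typically > 2 g above the
    local baseline) at 2.6-3.2 steps/s; walking gives low peaks at
    1.5-2 steps/s. Defaults separate the two regimes with a wide margin and
    are configurable because no canonical values exist.
    """

    block_s: float = 5.0
    tau_peak_g: float = 1.4      # required peak height above block median
    min_peak_dist_s: float = 0.25
    c_min_hz: float = 2.2        # minimum instantaneous cadence for "running"


def estimate_tilt(trace: AccelTrace, stage: RunningStage) -> TiltAngles:
    """Estimate sensor tilt over ``stage`` from mean horizontal accelerations.

    With a quasi-static 1 g gravity field, the mean AP and ML accelerations
    (in g) are the sines of the respective tilt angles, so
    ``theta = arcsin(mean)`` per axis.
    """
    if not (0 <= stage.start < stage.end <= len(trace)):
        raise ValueError(f"stage {stage} outside trace of length {len(trace)}")
    mean_ap = float(np.mean(trace.ap[stage.start : stage.end]))
    mean_ml = float(np.mean(trace.ml[stage.start : stage.end]))
    for name, v in (("AP", mean_ap), ("ML", mean_ml)):
        if abs(v) >= 1.0:
            raise TiltEstimationError(
                f"mean {name} acceleration {v:.3f} g >= 1 g; cannot be a gravity projection"
            )
    return TiltAngles(theta_ap=math.asin(mean_ap), theta_ml=math.asin(mean_ml))


def _rotate(vt, ml, ap, theta_ap, theta_ml):
    """Sequential plane rotations: AP-VT plane by theta_ap, then ML-VT by theta_ml.

    ``theta_*`` may be scalars or per-sample arrays (time-varying tilt).
    """
    ca, sa = np.cos(theta_ap), np.sin(theta_ap)
    ap1 = ap * ca - vt * sa
    vt1 = ap * sa + vt * ca
    cm, sm = np.cos(theta_ml), np.sin(theta_ml)
    ml2 = ml * cm - vt1 * sm
    vt2 = ml * sm + vt1 * cm
    return vt2, ml2, ap1


def _rotate_inverse(vt, ml, ap, theta_ap, theta_ml):
    """Exact inverse of :func:`_rotate` (world frame -> tilted sensor frame)."""
    cm, sm = np.cos(theta_ml), np.sin(theta_ml)
    ml1 = ml * cm + vt * sm
    vt1 = -ml * sm + vt * cm
    ca, sa = np.cos(theta_ap), np.sin(theta_ap)
    ap2 = ap * ca + vt1 * sa
    vt2 = -ap * sa + vt1 * ca
    return vt2, ml1, ap2


def tilt_correct(
    trace: AccelTrace, stage: RunningStage, angles: TiltAngles
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate the segment to the horizontal-vertical frame and remove gravity.

    Returns the corrected ``(vt, ml, ap)`` arrays for ``trace[stage]``. The
    rotation is applied first in the AP-VT plane, then the ML-VT plane; 1 g is
    subtracted from the rotated vertical axis.
    """
    s = slice(stage.start, stage.end)
    vt, ml, ap = _rotate(trace.vt[s], trace.ml[s], trace.ap[s], angles.theta_ap, angles.theta_ml)
    return vt - 1.0, ml, ap


def detect_running_stages(
    trace: AccelTrace, params: StageDetectionParams | None = None
) -> list[RunningStage]:
    """Locate running stages from vertical-acceleration peaks.

    The (already tilt-corrected) vertical signal is scanned in non-overlapping
    blocks; a block counts as running when enough sufficiently tall peaks occur
    to imply a running cadence. Maximal runs of running blocks are merged.
    """
    p = params or StageDetectionParams()
    fs = trace.fs
    block = int(round(p.block_s * fs))
    n = len(trace)
    if n < block:
        return []
    dist = max(1, int(round(p.min_peak_dist_s * fs)))
    min_count = p.c_min_hz * p.block_s
    running = []
    for b in range(n // block):
        x = trace.vt[b * block : (b + 1) * block]
        xr = x - np.median(x)
        peaks, props = find_peaks(xr, distance=dist, prominence=0.5 * p.tau_peak_g)
        heights = xr[peaks]
        tall = heights >= p.tau_peak_g
        ok = tall.sum() >= min_count and len(heights) > 0 and np.median(heights) >= p.tau_peak_g
        running.append(bool(ok))
    stages: list[RunningStage] = []
    start = None
    for i, r in enumerate(running):
        if r and start is None:
            start = i
        elif not r and start is not None:
            stages.append(RunningStage(start * block, i * block))
            start = None
    if start is not None:
        stages.append(RunningStage(start * block, len(running) * block))
    return stages


def crop_stage(stage: RunningStage, fs: float, *, head_s: float = 60.0, tail_s: float = 10.0) -> Optional[RunningStage]:
    """Drop the unsteady first ``head_s`` and last ``tail_s`` of a stage.

    Returns ``None`` when nothing remains (stage shorter than head+tail).
    """
    start = stage.start + int(round(head_s * fs))
    end = stage.end - int(round(tail_s * fs))
    if end - start <= 0:
        return None
    return RunningStage(start, end)


def windowed_correction(
    trace: AccelTrace, stages: Sequence[RunningStage], *, window_s: float = 120.0
) -> list[CorrectedWindow]:
    """Tilt-correct each cropped stage in consecutive non-overlapping windows.

    Windows shorter than ``window_s`` at the tail of a stage are discarded.
    The tilt estimate is taken per window on the raw signal, so each window's
    correction reflects the trunk lean at that point of the run.
    """
    wlen = int(round(window_s * trace.fs))
    out: list[CorrectedWindow] = []
    for stage in stages:
        n_windows = len(stage) // wlen
        for w in range(n_windows):
            sub = RunningStage(stage.start + w * wlen, stage.start + (w + 1) * wlen)
            tilt = estimate_tilt(trace, sub)
            vt, ml, ap = tilt_correct(trace, sub, tilt)
            out.append(
                CorrectedWindow(
                    subject_id=trace.subject_id,
                    start=sub.start,
                    end=sub.end,
                    fs=trace.fs,
                    vt=vt,
                    ml=ml,
                    ap=ap,
                    tilt=tilt,
                )
            )
    return out


def flag_leading_quiet_segment(trace: AccelTrace, *, min_s: float = 5.0, sd_threshold_g: float = 0.1) -> int:
    """Length (samples) of a leading low-variance segment, or 0 if none.

    The study recordings begin with the runner standing still; this helper
    flags such a quiet lead-in for manual trimming rather than trimming
    automatically.
    """
    block = max(1, int(round(min_s * trace.fs)))
    n = 0
    while n + block <= len(trace):
        if np.std(trace.vt[n : n + block]) < sd_threshold_g:
            n += block
        else:
            break
    return n


EXCLUSION_CRITERIA = ("non-LLOI", "unknown", "missing", "short-run")


@dataclass
class ExclusionReport:
    """Per-criterion exclusion counts (first-matching criterion wins)."""

    counts: dict = field(default_factory=dict)

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())


def apply_exclusions(
    records: Sequence[CohortRecord],
    *,
    min_running_s: float = 600.0,
    feature_missing: Optional[set] = None,
) -> tuple[list[CohortRecord], ExclusionReport]:
    """Apply the study's four exclusion criteria, in order.

    A subject is excluded when (1) a non-LLOI injury was diagnosed, (2) the
    injury status is unknown, (3) any questionnaire/feature value is missing,
    or (4) less than ``min_running_s`` of running was detected in the test.
    Each excluded subject is counted once, under the first matching criterion.
    ``feature_missing`` optionally names subjects whose extracted signal
    features are missing (criterion 3 alongside questionnaire gaps).
    """
    feature_missing = feature_missing or set()
    counts = {c: 0 for c in EXCLUSION_CRITERIA}
    included: list[CohortRecord] = []
    for rec in records:
        if rec.status == "non-LLOI":
            counts["non-LLOI"] += 1
        elif rec.status == "unknown":
            counts["unknown"] += 1
        elif rec.has_missing() or rec.subject_id in feature_missing:
            counts["missing"] += 1
        elif rec.running_time_s is None or rec.running_time_s < min_running_s:
            counts["short-run"] += 1
        else:
            included.append(rec)
    return included, ExclusionReport(counts=counts)
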