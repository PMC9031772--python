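"""Per-window gait and statistical features, normalization and aggregation.

Features are computed on 10-second subwindows of the two-minute corrected
windows produced by :mod:`trunkrun.preprocessing`, then min-max normalized
per subject against the first six subwindows (so later windows express change
relative to the fresh start of the run) and aggregated to one row per
subject. Trunk-lean angle changes use the full two-minute windows and are
centered rather than normalized; step time is computed from the pooled step
events and passes through unchanged.

Two feature families are produced:

* sports-specific: RMS ratio, step/stride regularity (autocorrelation at the
  step and stride lag), sample entropy (+SD), impact (+SD), step time and
  first-vs-last-window lean-angle change;
* statistical: a fixed generic bank (moments, ranges, change statistics,
  spectral summaries) per axis and for the resultant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import find_peaks, resample_poly
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import (
    AccelTrace,
    CohortRecord,
    CorrectedWindow,
    RunningStage,
    StageDetectionParams,
    crop_stage,
    detect_running_stages,
    estimate_tilt,
    tilt_correct,
    windowed_correction,
)

__all__ = [
    "FeatureDef",
    "FeatureTable",
    "GaitFeatureExtractor",
    "detect_steps",
    "step_time",
    "rms_ratio",
    "regularity",
    "sample_entropy",
    "impact",
    "lean_angle_change",
    "statistical_bank",
    "subject_minmax_normalize",
    "aggregate_to_subject",
    "remove_constant_features",
    "attach_questionnaire",
]

DIRECTIONS = ("VT", "ML", "AP", "Res")
FTYPES = ("sport", "stat", "quest")


@dataclass(frozen=True)
class FeatureDef:
    """A feature's name plus its direction and type category tags."""

    name: str
    direction: str  # 'ML', 'AP', 'VT', 'Res' or 'ND'
    ftype: str      # 'sport', 'stat' or 'quest'

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS + ("ND",):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.ftype not in FTYPES:
            raise ValueError(f"unknown ftype {self.ftype!r}")


@dataclass
class FeatureTable:
    """Subjects x features matrix plus the category tags of each column."""

    values: pd.DataFrame
    defs: dict[str, FeatureDef]
    normalized: bool = True

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.defs)
        if missing:
            raise ValueError(f"columns without a FeatureDef: {sorted(missing)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, which: str) -> "FeatureTable":
        """Feature subset: 'All', 'Sport' or 'Stat' (questionnaire always kept)."""
        if which == "All":
            cols = list(self.values.columns)
        elif which in ("Sport", "Stat"):
            keep = {"Sport": ("sport", "quest"), "Stat": ("stat", "quest")}[which]
            cols = [c for c in self.values.columns if self.defs[c].ftype in keep]
        else:
            raise ValueError(f"unknown feature subset {which!r}")
        return FeatureTable(
            values=self.values[cols].copy(),
            defs={c: self.defs[c] for c in cols},
            normalized=self.normalized,
        )


# --------------------------------------------------------------------------
# step detection and step-based features


def detect_steps(
    vt: np.ndarray, fs: float, *, min_dist_s: float = 0.25, prominence_g: float = 1.0
) -> np.ndarray:
    """Foot-contact events as prominent vertical-acceleration maxima.

    Returns ascending sample indices. Fewer than 4 events marks the window
    unusable for step-based features (the caller decides what to do).
    """
    dist = max(1, int(round(min_dist_s * fs)))
    peaks, _ = find_peaks(np.asarray(vt, float), distance=dist, prominence=prominence_g)
    return peaks


def step_time(events: np.ndarray, fs: float) -> float:
    """Mean time between successive foot contacts, seconds."""
    events = np.asarray(events)
    if len(events) < 2:
        return math.nan
    return float(np.mean(np.diff(events)) / fs)


def rms_ratio(axis_signal: np.ndarray, resultant: np.ndarray) -> float:
    """RMS of one axis relative to the RMS of the resultant signal."""
    denom = float(np.sqrt(np.mean(np.square(resultant))))
    if denom == 0:
        return math.nan
    return float(np.sqrt(np.mean(np.square(axis_signal))) / denom)


def _autocorr_unbiased(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized unbiased autocorrelation for lags 0..max_lag."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    denom = float(np.dot(x, x)) / n
    if denom == 0:
        return np.full(max_lag + 1, np.nan)
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    counts = n - np.arange(max_lag + 1)
    return (full / counts) / denom


def regularity(
    signal: np.ndarray,
    fs: float,
    *,
    min_lag_s: float = 0.2,
    max_lag_s: float = 1.2,
) -> tuple[float, float]:
    """Step and stride regularity from the signal's autocorrelation.

    The dominant step period is the first autocorrelation peak beyond
    ``min_lag_s``; step regularity is the (unbiased, normalized)
    autocorrelation at that lag and stride regularity at twice that lag.
    Both are clipped to [-1, 1].
    """
    x = np.asarray(signal, float)
    max_lag = min(len(x) - 1, int(round(2 * max_lag_s * fs)))
    ac = _autocorr_unbiased(x, max_lag)
    if np.any(~np.isfinite(ac)):
        return math.nan, math.nan
    lo = int(round(min_lag_s * fs))
    peaks, _ = find_peaks(ac[lo:])
    if len(peaks) == 0:
        return math.nan, math.nan
    lag = lo + peaks[0]
    step_reg = float(np.clip(ac[lag], -1.0, 1.0))
    stride_reg = float(np.clip(ac[2 * lag], -1.0, 1.0)) if 2 * lag <= max_lag else math.nan
    return step_reg, stride_reg


# --------------------------------------------------------------------------
# sample entropy

try:  # numba kernel, with a pure-numpy fallback
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _sampen_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
        n = x.shape[0]
        b = 0
        a = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                d = 0.0
                for k in range(m):
                    dk = abs(x[i + k] - x[j + k])
                    if dk > d:
                        d = dk
                if d <= r:
                    b += 1
                    dm = abs(x[i + m] - x[j + m])
                    if dm <= r:
                        a += 1
        return a, b

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = len(x)
    nt = n - m  # templates of length m that can be extended to m+1
    d = np.abs(x[:, None] - x[None, :])
    dm = d[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(dm, d[k : k + nt, k : k + nt], out=dm)
    bm = dm <= r
    dm1 = np.maximum(dm, d[m : m + nt, m : m + nt])
    am = dm1 <= r
    iu = np.triu_indices(nt, k=1)
    return int(am[iu].sum()), int(bm[iu].sum())


def sample_entropy(
    signal: np.ndarray,
    fs: Optional[float] = None,
    *,
    m: int = 2,
    r_factor: float = 0.2,
    target_fs: float = 100.0,
) -> float:
    """Sample entropy SampEn(m, r = r_factor * SD), in nats.

    Matching uses the Chebyshev distance with tolerance inclusive (d <= r)
    and self-matches excluded. When ``fs`` exceeds ``target_fs`` the signal
    is first resampled down to ``target_fs`` — entropy of a heavily
    oversampled signal is dominated by sample-to-sample noise correlation
    and the O(N^2) count is intractable at 1000 Hz window lengths.

    Returns NaN when no template pairs match at length m or m+1 (e.g. a
    constant signal, where SD and hence r is zero).
    """
    x = np.asarray(signal, dtype=np.float64)
    if fs is not None and fs > target_fs:
        frac = Fraction(int(round(target_fs)), int(round(fs))).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    if len(x) < m + 2:
        return math.nan
    sd = float(np.std(x))
    if sd == 0:
        return math.nan
    r = r_factor * sd
    if _HAVE_NUMBA:
        a, b = _sampen_counts(x, m, r)
    else:
        a, b = _sampen_counts_numpy(x, m, r)
    if a == 0 or b == 0:
        return math.nan
    return float(-math.log(a / b))


# --------------------------------------------------------------------------
# impact and lean angles


def impact(signal: np.ndarray, events: np.ndarray, fs: float, *, horizon_s: float = 0.1) -> float:
    """Mean over steps of the peak |acceleration| within 100 ms after contact."""
    events = np.asarray(events)
    if len(events) == 0:
        return math.nan
    x = np.abs(np.asarray(signal, float))
    h = max(1, int(round(horizon_s * fs)))
    peaks = [x[e : e + h].max() for e in events if e < len(x)]
    if not peaks:
        return math.nan
    return float(np.mean(peaks))


def lean_angle_change(first: CorrectedWindow, last: CorrectedWindow) -> tuple[float, float]:
    """Centered (ML, AP) trunk-lean change between the first and last window.

    Each window's angle is the arcsine of the mean uncorrected axis signal
    (the per-window tilt estimate); the first-window angle is subtracted from
    the last-window angle, per axis. Radians.
    """
    return (
        last.tilt.theta_ml - first.tilt.theta_ml,
        last.tilt.theta_ap - first.tilt.theta_ap,
    )


# --------------------------------------------------------------------------
# generic statistical bank

STAT_NAMES = (
    "mean", "sd", "rms", "min", "max", "range", "median", "iqr",
    "skewness", "kurtosis", "mean_abs_change", "zero_cross_rate",
    "n_peaks", "dominant_freq", "power_0_3", "power_3_10", "power_10_30",
    "spectral_entropy", "autocorr_lag1", "line_length",
)


def statistical_bank(signal: np.ndarray, fs: float) -> dict[str, float]:
    """Fixed generic statistical feature bank for one direction signal.

    Spectral quantities exclude the DC component; band powers are fractions
    of total non-DC power in [0,3), [3,10) and [10,30) Hz. Moment-based
    features that are undefined on a constant signal come back NaN.
    """
    x = np.asarray(signal, float)
    n = len(x)
    out: dict[str, float] = {}
    sd = float(np.std(x, ddof=1)) if n > 1 else math.nan
    out["mean"] = float(np.mean(x))
    out["sd"] = sd
    out["rms"] = float(np.sqrt(np.mean(x**2)))
    out["min"] = float(np.min(x))
    out["max"] = float(np.max(x))
    out["range"] = out["max"] - out["min"]
    out["median"] = float(np.median(x))
    q75, q25 = np.percentile(x, [75, 25])
    out["iqr"] = float(q75 - q25)
    if sd and sd > 0:
        out["skewness"] = float(sps.skew(x))
        out["kurtosis"] = float(sps.kurtosis(x))
    else:
        out["skewness"] = math.nan
        out["kurtosis"] = math.nan
    dx = np.diff(x)
    out["mean_abs_change"] = float(np.mean(np.abs(dx))) if n > 1 else math.nan
    xc = x - x.mean()
    crossings = int(np.sum(np.signbit(xc[:-1]) != np.signbit(xc[1:])))
    out["zero_cross_rate"] = crossings / (n / fs)
    if sd and sd > 0:
        peaks, _ = find_peaks(x, prominence=sd, distance=max(1, int(round(0.25 * fs))))
        out["n_peaks"] = float(len(peaks))
    else:
        out["n_peaks"] = 0.0
    # spectrum (DC excluded)
    spec = np.abs(np.fft.rfft(xc)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec, freqs = spec[1:], freqs[1:]
    total = spec.sum()
    if total > 0:
        out["dominant_freq"] = float(freqs[np.argmax(spec)])
        for name, lo, hi in (("power_0_3", 0.0, 3.0), ("power_3_10", 3.0, 10.0), ("power_10_30", 10.0, 30.0)):
            band = (freqs >= lo) & (freqs < hi)
            out[name] = float(spec[band].sum() / total)
        p = spec / total
        p = p[p > 0]
        out["spectral_entropy"] = float(-(p * np.log(p)).sum())
    else:
        out["dominant_freq"] = 0.0
        out["power_0_3"] = out["power_3_10"] = out["power_10_30"] = math.nan
        out["spectral_entropy"] = math.nan
    if sd and sd > 0 and n > 2:
        out["autocorr_lag1"] = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    else:
        out["autocorr_lag1"] = math.nan
    out["line_length"] = float(np.sum(np.abs(dx)))
    return out


# --------------------------------------------------------------------------
# normalization / aggregation


def subject_minmax_normalize(
    windows: pd.DataFrame, *, n_reference: int = 6, exempt: Sequence[str] = ()
) -> pd.DataFrame:
    """Min-max normalize per-subwindow feature values against early windows.

    The per-feature min/max are taken over the first ``n_reference``
    subwindows (rows), so those rows map into [0, 1] exactly while later
    rows may fall outside — expressing drift relative to the fresh state.
    A feature constant over the reference windows maps to 0. Columns listed
    in ``exempt`` pass through untouched.
    """
    if len(windows) < n_reference:
        raise ValueError(f"need >= {n_reference} subwindows for normalization, got {len(windows)}")
    out = windows.copy()
    for col in windows.columns:
        if col in exempt:
            continue
        ref = windows[col].iloc[:n_reference]
        lo, hi = ref.min(), ref.max()
        if pd.isna(lo) or pd.isna(hi) or hi == lo:
            out[col] = 0.0 if not pd.isna(lo) else np.nan
        else:
            out[col] = (windows[col] - lo) / (hi - lo)
    return out


#: per-subwindow features additionally aggregated as an SD across subwindows
SD_AGGREGATED = ("sample_entropy", "impact")


def aggregate_to_subject(norm_windows: pd.DataFrame) -> pd.Series:
    """Aggregate normalized subwindow rows to one subject row.

    Every base feature becomes its mean over subwindows (NaNs ignored);
    sample entropy and impact additionally get an SD-over-subwindows column
    (suffix ``_sd``). A single subwindow leaves the SD features NaN.
    """
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        for col in norm_windows.columns:
            vals = norm_windows[col].to_numpy(dtype=float)
            out[col] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else math.nan
            if any(col.startswith(p) for p in SD_AGGREGATED):
                finite = vals[np.isfinite(vals)]
                out[col + "_sd"] = float(np.std(finite, ddof=1)) if len(finite) > 1 else math.nan
    return pd.Series(out)


def remove_constant_features(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Drop features with the same value for every subject.

    Constant features carry no discriminative information; dropping them also
    disposes of structurally-constant members of the feature bank (e.g. the
    resultant's RMS ratio, which is identically 1).
    """
    if len(table.values) < 2:
        raise ValueError("constant-feature removal needs at least 2 subjects")
    removed = [c for c in table.values.columns if table.values[c].nunique(dropna=False) <= 1]
    kept = [c for c in table.values.columns if c not in removed]
    return (
        FeatureTable(
            values=table.values[kept].copy(),
            defs={c: table.defs[c] for c in kept},
            normalized=table.normalized,
        ),
        removed,
    )


QUESTIONNAIRE_FEATURES = ("distance_m", "gender", "mass_kg", "height_cm", "prev_injury", "insoles")


def attach_questionnaire(table: FeatureTable, records: Sequence[CohortRecord]) -> FeatureTable:
    """Append Cooper distance and questionnaire columns as ND/quest features."""
    recs = {r.subject_id: r for r in records}
    rows = {}
    for sid in table.values.index:
        r = recs.get(sid)
        if r is None:
            raise KeyError(f"no cohort record for subject {sid!r}")
        rows[sid] = {
            "distance_m": np.nan if r.distance_m is None else r.distance_m,
            "gender": r.gender,
            "mass_kg": np.nan if r.mass_kg is None else r.mass_kg,
            "height_cm": np.nan if r.height_cm is None else r.height_cm,
            "prev_injury": np.nan if r.prev_injury is None else float(r.prev_injury),
            "insoles": np.nan if r.insoles is None else float(r.insoles),
        }
    quest = pd.DataFrame.from_dict(rows, orient="index").loc[table.values.index]
    values = pd.concat([table.values, quest], axis=1)
    defs = dict(table.defs)
    for name in QUESTIONNAIRE_FEATURES:
        defs[name] = FeatureDef(name=name, direction="ND", ftype="quest")
    return FeatureTable(values=values, defs=defs, normalized=table.normalized)


# --------------------------------------------------------------------------
# the end-to-end extractor


class GaitFeatureExtractor(BaseEstimator, TransformerMixin):
    """Trace -> subject-level feature row, end to end.

    Runs the full preparation chain (whole-series tilt correction, stage
    detection, cropping, windowed re-correction), computes the sports and
    statistical features on 10-s subwindows, min-max normalizes them per
    subject against the first six subwindows, and aggregates to one row per
    subject. Stateless in the sklearn sense: ``fit`` only validates
    parameters, ``transform`` maps a list of traces to a :class:`FeatureTable`.

    Parameters
    ----------
    subwindow_s, window_s : float
        Subwindow and correction-window lengths, seconds.
    crop_head_s, crop_tail_s : float
        Removed from the start/end of every running stage, seconds.
    n_reference_windows : int
        Number of leading subwindows defining each subject's min/max.
    sampen_m, sampen_r_factor, sampen_fs : SampEn template length, tolerance
        factor (times the signal SD) and working sampling rate.
    step_prominence_g, step_min_dist_s : step-detection thresholds.
    stage_params : StageDetectionParams or None
        Running/walking separation thresholds.

    Attributes
    ----------
    running_time_s_ : dict
        Per-subject total detected (pre-crop) running time after ``transform``.
    n_windows_ : dict
        Per-subject number of two-minute corrected windows.
    """

    def __init__(
        self,
        subwindow_s: float = 10.0,
        window_s: float = 120.0,
        crop_head_s: float = 60.0,
        crop_tail_s: float = 10.0,
        n_reference_windows: int = 6,
        sampen_m: int = 2,
        sampen_r_factor: float = 0.2,
        sampen_fs: float = 100.0,
        step_prominence_g: float = 1.0,
        step_min_dist_s: float = 0.25,
        stage_params: Optional[StageDetectionParams] = None,
    ):
        self.subwindow_s = subwindow_s
        self.window_s = window_s
        self.crop_head_s = crop_head_s
        self.crop_tail_s = crop_tail_s
        self.n_reference_windows = n_reference_windows
        self.sampen_m = sampen_m
        self.sampen_r_factor = sampen_r_factor
        self.sampen_fs = sampen_fs
        self.step_prominence_g = step_prominence_g
        self.step_min_dist_s = step_min_dist_s
        self.stage_params = stage_params

    def fit(self, X=None, y=None) -> "GaitFeatureExtractor":
        if self.subwindow_s <= 0 or self.window_s <= 0:
            raise ValueError("window lengths must be positive")
        if self.window_s < self.subwindow_s:
            raise ValueError("window_s must be >= subwindow_s")
        return self

    # -- per-subject plumbing ------------------------------------------------

    def _subwindow_features(self, win: CorrectedWindow, offset: slice) -> dict[str, float]:
        fs = win.fs
        axes = {
            "VT": win.vt[offset],
            "ML": win.ml[offset],
            "AP": win.ap[offset],
        }
        axes["Res"] = np.sqrt(axes["VT"] ** 2 + axes["ML"] ** 2 + axes["AP"] ** 2)
        events = detect_steps(
            axes["VT"], fs, min_dist_s=self.step_min_dist_s, prominence_g=self.step_prominence_g
        )
        usable = len(events) >= 4
        feats: dict[str, float] = {}
        for d in DIRECTIONS:
            x = axes[d]
            feats[f"rms_ratio_{d}"] = rms_ratio(x, axes["Res"])
            sreg, streg = regularity(x, fs) if usable else (math.nan, math.nan)
            feats[f"step_regularity_{d}"] = sreg
            feats[f"stride_regularity_{d}"] = streg
            feats[f"sample_entropy_{d}"] = sample_entropy(
                x, fs, m=self.sampen_m, r_factor=self.sampen_r_factor, target_fs=self.sampen_fs
            )
            feats[f"impact_{d}"] = impact(x, events, fs) if usable else math.nan
            for name, val in statistical_bank(x, fs).items():
                feats[f"stat_{name}_{d}"] = val
        return feats

    def _extract_subject(self, trace: AccelTrace) -> tuple[pd.Series, float, int]:
        fs = trace.fs
        full = RunningStage(0, len(trace))
        cvt, cml, cap = tilt_correct(trace, full, estimate_tilt(trace, full))
        corrected = AccelTrace(subject_id=trace.subject_id, fs=fs, vt=cvt, ml=cml, ap=cap)
        stages = detect_running_stages(corrected, self.stage_params)
        running_time = sum(len(s) for s in stages) / fs
        cropped = [
            c
            for s in stages
            if (c := crop_stage(s, fs, head_s=self.crop_head_s, tail_s=self.crop_tail_s)) is not None
        ]
        windows = windowed_correction(trace, cropped, window_s=self.window_s)

        sub_len = int(round(self.subwindow_s * fs))
        rows: list[dict[str, float]] = []
        all_intervals: list[np.ndarray] = []
        for win in windows:
            n_sub = len(win.vt) // sub_len
            for k in range(n_sub):
                sl = slice(k * sub_len, (k + 1) * sub_len)
                rows.append(self._subwindow_features(win, sl))
                ev = detect_steps(
                    win.vt[sl], fs, min_dist_s=self.step_min_dist_s, prominence_g=self.step_prominence_g
                )
                if len(ev) >= 2:
                    all_intervals.append(np.diff(ev))

        if len(rows) >= self.n_reference_windows:
            df = pd.DataFrame(rows)
            norm = subject_minmax_normalize(df, n_reference=self.n_reference_windows)
            row = aggregate_to_subject(norm)
        else:
            # too little steady running for this subject; everything missing
            row = pd.Series(dtype=float)

        if all_intervals:
            row["step_time"] = float(np.concatenate(all_intervals).mean() / fs)
        else:
            row["step_time"] = math.nan
        if len(windows) >= 2:
            d_ml, d_ap = lean_angle_change(windows[0], windows[-1])
        else:
            d_ml, d_ap = math.nan, math.nan
        row["angle_change_ML"] = d_ml
        row["angle_change_AP"] = d_ap
        return row, running_time, len(windows)

    def transform(self, traces: Sequence[AccelTrace]) -> FeatureTable:
        rows = {}
        self.running_time_s_: dict[str, float] = {}
        self.n_windows_: dict[str, int] = {}
        for trace in traces:
            row, rt, nw = self._extract_subject(trace)
            rows[trace.subject_id] = row
            self.running_time_s_[trace.subject_id] = rt
            self.n_windows_[trace.subject_id] = nw
        values = pd.DataFrame.from_dict(rows, orient="index")
        defs = {name: self._feature_def(name) for name in values.columns}
        return FeatureTable(values=values, defs=defs, normalized=True)

    @staticmethod
    def _feature_def(name: str) -> FeatureDef:
        if name == "step_time":
            return FeatureDef(name, "ND", "sport")
        if name == "angle_change_ML":
            return FeatureDef(name, "ML", "sport")
        if name == "angle_change_AP":
            return FeatureDef(name, "AP", "sport")
        if name.endswith("_sd"):
            name_base = name[: -len("_sd")]
            base = GaitFeatureExtractor._feature_def(name_base)
            return FeatureDef(name, base.direction, base.ftype)
        direction = name.rsplit("_", 1)[-1]
        if direction not in DIRECTIONS:
            raise ValueError(f"cannot infer direction of feature {name!r}")
        ftype = "stat" if name.startswith("stat_") else "sport"
        return FeatureDef(name, direction, ftype)
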