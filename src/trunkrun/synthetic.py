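"""Synthetic Cooper-test accelerometry and cohorts with known ground truth.

The study's raw recordings are available only on request, so this module
generates stand-in data with the same shape: a 12-minute steady run recorded
by a lower-back tri-axial accelerometer (1000 Hz, clipped at +/-16 g), and a
cohort table of questionnaire answers, Cooper distances and injury labels.

The signal model is deliberately simple — periodic damped-half-sine step
impacts on the vertical axis with small leakage into the horizontal axes,
a tilted (and optionally drifting) gravity field, white noise and optional
walking interruptions. It produces the gross features the downstream pipeline
keys on (cadence, impact peaks, left/right asymmetry, trunk-lean drift)
without attempting biomechanical realism.

Injury labels follow a configurable logistic model on the per-subject latent
gait parameters, so label-recovery experiments have a known answer.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .preprocessing import AccelTrace, CohortRecord, _rotate_inverse

__all__ = [
    "SignalParams",
    "CohortParams",
    "SimulatedCohort",
    "LATENT_NAMES",
    "simulate_run_signal",
    "simulate_cohort",
    "study_composition_records",
]

#: Latent gait parameters a cohort effect size may attach to.
LATENT_NAMES = ("cadence", "impact", "asymmetry", "drift", "noise")

# Gender-conditional questionnaire distributions (means/SDs of the study cohort).
QUESTIONNAIRE_DISTS = {
    "male": {"mass_kg": (71.38, 7.56), "height_cm": (179.86, 6.33), "distance_m": (3000.0, 200.0)},
    "female": {"mass_kg": (62.51, 6.63), "height_cm": (167.19, 5.99), "distance_m": (2600.0, 200.0)},
}
PREV_INJURY_RATE = 0.3
INSOLES_RATE = 0.15


@dataclass
class SignalParams:
    """Parameters of one simulated Cooper-test recording.

    Defaults mirror the study's measurement setup: a 12-minute trial at
    1000 Hz clipped to +/-16 g, a running cadence near 2.8 steps/s and a
    vertical impact peak of ~3 g over the local baseline.
    """

    duration_s: float = 720.0
    fs: float = 1000.0
    cadence_hz: float = 2.8
    step_impact_g: float = 3.0
    tilt_ap_deg: float = 5.0
    tilt_ml_deg: float = 0.0
    noise_sd_g: float = 0.15
    asymmetry: float = 0.1
    drift_deg: float = 0.0
    noise_ramp: Optional[float] = None  # relative noise-SD increase over the trial;
    # fatigue couples lean drift and movement variability, so by default the
    # ramp scales with the drift: 0.15 per degree of AP lean drift.
    walk_breaks: tuple = ()      # ((start_s, end_s), ...) walking intervals
    clip_g: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not 0 < self.cadence_hz < self.fs / 4:
            raise ValueError(f"cadence_hz must lie in (0, fs/4), got {self.cadence_hz}")
        if not 0 <= self.asymmetry < 1:
            raise ValueError(f"asymmetry must lie in [0, 1), got {self.asymmetry}")
        if self.noise_sd_g < 0:
            raise ValueError(f"noise_sd_g must be nonnegative, got {self.noise_sd_g}")
        if self.clip_g <= 0:
            raise ValueError(f"clip_g must be positive, got {self.clip_g}")
        breaks = sorted(tuple(map(tuple, self.walk_breaks)))
        for (s, e) in breaks:
            if not (0 <= s < e <= self.duration_s):
                raise ValueError(f"walk_breaks interval ({s}, {e}) outside [0, {self.duration_s}]")
        for (_, e0), (s1, _) in zip(breaks, breaks[1:]):
            if s1 < e0:
                raise ValueError("walk_breaks must not overlap")
        self.walk_breaks = tuple(breaks)


@dataclass
class CohortParams:
    """Cohort-level parameters: size, composition and the latent->label link.

    ``effect_sizes`` maps latent gait parameters (see :data:`LATENT_NAMES`) to
    per-SD log-odds contributions; ``gender_interaction`` adds extra per-SD
    log-odds for female subjects. The intercept is solved numerically so the
    expected prevalence of the injury label equals ``prevalence_target``.
    """

    n_subjects: int = 200
    female_fraction: float = 0.31      # study cohort: 63 of 204
    prevalence_target: float = 0.25    # study cohort: 41 of 161 included
    effect_sizes: dict = field(default_factory=dict)
    gender_interaction: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if not 0 < self.prevalence_target < 1:
            raise ValueError(f"prevalence_target must lie in (0, 1), got {self.prevalence_target}")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError(f"female_fraction must lie in [0, 1], got {self.female_fraction}")
        for mapping, label in ((self.effect_sizes, "effect_sizes"), (self.gender_interaction, "gender_interaction")):
            unknown = set(mapping) - set(LATENT_NAMES)
            if unknown:
                raise ValueError(f"{label} names unknown latent parameter(s): {sorted(unknown)}; known: {LATENT_NAMES}")


_IMPACT_DURATION_S = 0.05
_AP_LEAK = 0.2
_ML_LEAK = 0.1
_WALK_AMP_FACTOR = 0.35


def _impact_shape(fs: float) -> np.ndarray:
    """Damped half-sine transient (~50 ms), normalized to unit peak."""
    n = max(2, int(round(_IMPACT_DURATION_S * fs)))
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    shape = np.sin(np.pi * u) * np.exp(-2.0 * u)
    return shape / shape.max()


def _in_break(t: float, breaks) -> bool:
    return any(s <= t < e for s, e in breaks)


def simulate_run_signal(p: SignalParams) -> AccelTrace:
    """Simulate one subject's tri-axial Cooper-test recording.

    The world-frame signal (gravity + impacts + noise) is rotated into the
    tilted sensor frame by the exact inverse of the tilt-correction rotation,
    so a correction with the true angles recovers the level signal to machine
    precision. Walking intervals halve the cadence and shrink impact
    amplitudes below the running-detection threshold.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs))
    t = np.arange(n) / p.fs

    # world-frame vertical impacts; alternating left/right amplitudes. Each
    # step transient is balanced by a shallow negative offset over its step
    # interval so the dynamic component integrates to zero per step — over a
    # stride the runner returns to the same vertical velocity, so the mean
    # dynamic acceleration vanishes (which the arcsine tilt estimate relies on).
    vt_dyn = np.zeros(n)
    ml_dyn = np.zeros(n)
    ap_dyn = np.zeros(n)
    shape = _impact_shape(p.fs)
    time_cursor = 0.0
    foot = 0  # 0 = left, 1 = right
    while time_cursor < p.duration_s:
        walking = _in_break(time_cursor, p.walk_breaks)
        step_dt = 1.0 / (p.cadence_hz / 2.0 if walking else p.cadence_hz)
        amp = p.step_impact_g * (1 + p.asymmetry if foot == 0 else 1 - p.asymmetry)
        if walking:
            amp *= _WALK_AMP_FACTOR
        i0 = int(round(time_cursor * p.fs))
        i1 = min(n, int(round((time_cursor + step_dt) * p.fs)))
        if i0 < n:
            seg = shape[: n - i0] * amp
            step = np.zeros(i1 - i0 if i1 > i0 else len(seg))
            step[: len(seg)] += seg[: len(step)]
            step -= seg.sum() / len(step)
            vt_dyn[i0 : i0 + len(step)] += step
            ap_dyn[i0 : i0 + len(step)] += _AP_LEAK * step
            # ML leakage alternates sign with the stance foot
            ml_dyn[i0 : i0 + len(step)] += _ML_LEAK * step * (1 if foot == 0 else -1)
        foot ^= 1
        time_cursor += step_dt

    # gravity field in the world frame
    vt_w = vt_dyn + 1.0
    ml_w = ml_dyn
    ap_w = ap_dyn

    # tilt (with optional linear fatigue drift of the AP lean) -> sensor frame
    theta_ap = np.deg2rad(p.tilt_ap_deg + p.drift_deg * t / p.duration_s)
    theta_ml = np.deg2rad(np.full(n, p.tilt_ml_deg))
    vt_s, ml_s, ap_s = _rotate_inverse(vt_w, ml_w, ap_w, theta_ap, theta_ml)

    if p.noise_sd_g > 0:
        ramp = p.noise_ramp if p.noise_ramp is not None else max(0.0, 0.15 * p.drift_deg)
        sd = p.noise_sd_g * (1.0 + ramp * t / p.duration_s)
        vt_s = vt_s + rng.standard_normal(n) * sd
        ml_s = ml_s + rng.standard_normal(n) * sd
        ap_s = ap_s + rng.standard_normal(n) * sd

    clip = p.clip_g
    return AccelTrace(
        subject_id=f"sim{p.seed}",
        fs=p.fs,
        vt=np.clip(vt_s, -clip, clip),
        ml=np.clip(ml_s, -clip, clip),
        ap=np.clip(ap_s, -clip, clip),
    )


# per-subject latent distributions (mean, sd, lower, upper truncation)
_LATENT_DISTS = {
    "cadence": (2.9, 0.15, 2.4, 3.4),     # steps/s
    "impact": (3.0, 0.5, 1.5, 5.0),       # g
    "asymmetry": (0.12, 0.06, 0.0, 0.4),  # relative L/R amplitude difference
    "drift": (2.0, 1.5, -3.0, 8.0),       # deg of AP lean over the trial
    "noise": (0.15, 0.04, 0.05, 0.35),    # g white-noise SD
}


def _draw_latents(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols = {}
    for name, (mu, sd, lo, hi) in _LATENT_DISTS.items():
        x = rng.normal(mu, sd, size=n)
        cols[name] = np.clip(x, lo, hi)
    return pd.DataFrame(cols)


@dataclass
class SimulatedCohort:
    """Traces + cohort records + the ground-truth sidecar used to create them."""

    traces: list
    records: list
    truth: pd.DataFrame


def simulate_cohort(sp: SignalParams, cp: CohortParams) -> SimulatedCohort:
    """Simulate a cohort of runs and a matching cohort table.

    Per subject, latent gait parameters are drawn from truncated normals
    (see module source for the distributions), a trace is generated with those
    parameters, and the injury label is Bernoulli with log-odds
    ``intercept + sum(effect_sizes[l] * z_l) (+ female interaction terms)``
    where ``z_l`` are the cohort-standardized latents. The intercept is solved
    so the mean predicted probability equals ``prevalence_target``.

    The returned :class:`SimulatedCohort` carries a ground-truth sidecar
    (latents, linear predictor, probability, label) for recovery tests.
    """
    rng = np.random.default_rng(cp.seed)
    n = cp.n_subjects
    latents = _draw_latents(rng, n)
    female = rng.random(n) < cp.female_fraction

    z = (latents - latents.mean()) / latents.std(ddof=0).replace(0.0, 1.0)
    lp = np.zeros(n)
    for name, beta in cp.effect_sizes.items():
        lp += beta * z[name].to_numpy()
    for name, beta in cp.gender_interaction.items():
        lp += beta * z[name].to_numpy() * female

    def mean_prob(b0: float) -> float:
        return float(expit(b0 + lp).mean())

    intercept = brentq(lambda b0: mean_prob(b0) - cp.prevalence_target, -30.0, 30.0, xtol=1e-10)
    prob = expit(intercept + lp)
    label = rng.random(n) < prob

    traces: list[AccelTrace] = []
    records: list[CohortRecord] = []
    trace_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        sid = f"S{i:04d}"
        p_i = replace(
            sp,
            cadence_hz=float(latents.loc[i, "cadence"]),
            step_impact_g=float(latents.loc[i, "impact"]),
            asymmetry=float(latents.loc[i, "asymmetry"]),
            drift_deg=float(latents.loc[i, "drift"]),
            noise_sd_g=float(latents.loc[i, "noise"]),
            tilt_ap_deg=float(np.clip(rng.normal(5.0, 2.0), -15, 15)),
            tilt_ml_deg=float(np.clip(rng.normal(0.0, 2.0), -15, 15)),
            seed=int(trace_seeds[i]),
        )
        trace = simulate_run_signal(p_i)
        trace.subject_id = sid
        traces.append(trace)

        gender = "female" if female[i] else "male"
        q = QUESTIONNAIRE_DISTS[gender]
        records.append(
            CohortRecord(
                subject_id=sid,
                gender=gender,
                mass_kg=float(rng.normal(*q["mass_kg"])),
                height_cm=float(rng.normal(*q["height_cm"])),
                prev_injury=bool(rng.random() < PREV_INJURY_RATE),
                insoles=bool(rng.random() < INSOLES_RATE),
                distance_m=float(rng.normal(*q["distance_m"])),
                status="LLOI" if label[i] else "none",
            )
        )

    truth = latents.copy()
    truth.insert(0, "subject_id", [r.subject_id for r in records])
    truth["female"] = female
    truth["linear_predictor"] = intercept + lp
    truth["probability"] = prob
    truth["label"] = label
    return SimulatedCohort(traces=traces, records=records, truth=truth)


def study_composition_records(
    *,
    n_total: int = 204,
    n_lloi: int = 41,
    n_non_lloi: int = 27,
    n_traumatic_non_lloi: int = 25,
    n_unknown: int = 6,
    n_missing: int = 5,
    n_short_run: int = 5,
    n_female: int = 63,
    seed: int = 0,
) -> list[CohortRecord]:
    """Build a cohort table with the published composition of the study cohort.

    Defaults reproduce the printed counts: 204 participants, of whom 27 had a
    non-LLOI injury (25 traumatic), 6 an unknown status, 5 a missing
    questionnaire value and 5 under ten minutes of running; 41 of the
    remaining subjects developed a lower-limb overuse injury. Exclusion
    categories are disjoint, matching the published arithmetic.
    """
    n_excluded = n_non_lloi + n_unknown + n_missing + n_short_run
    if n_excluded + n_lloi > n_total:
        raise ValueError("composition counts exceed n_total")
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []

    def base(i: int) -> dict:
        gender = "female" if i < n_female else "male"
        q = QUESTIONNAIRE_DISTS[gender]
        return dict(
            subject_id=f"P{i:04d}",
            gender=gender,
            mass_kg=float(rng.normal(*q["mass_kg"])),
            height_cm=float(rng.normal(*q["height_cm"])),
            prev_injury=bool(rng.random() < PREV_INJURY_RATE),
            insoles=bool(rng.random() < INSOLES_RATE),
            distance_m=float(rng.normal(*q["distance_m"])),
            running_time_s=float(rng.uniform(620.0, 720.0)),
        )

    i = 0
    for _ in range(n_non_lloi):
        detail = "traumatic" if (i - 0) < n_traumatic_non_lloi else "other"
        records.append(CohortRecord(status="non-LLOI", injury_detail=detail, **base(i)))
        i += 1
    for _ in range(n_unknown):
        records.append(CohortRecord(status="unknown", **base(i)))
        i += 1
    for _ in range(n_missing):
        kw = base(i)
        kw["mass_kg"] = None
        records.append(CohortRecord(status="none", **kw))
        i += 1
    for _ in range(n_short_run):
        kw = base(i)
        kw["running_time_s"] = float(rng.uniform(300.0, 590.0))
        records.append(CohortRecord(status="none", **kw))
        i += 1
    for _ in range(n_lloi):
        records.append(CohortRecord(status="LLOI", **base(i)))
        i += 1
    while i < n_total:
        records.append(CohortRecord(status="none", **base(i)))
        i += 1
    return records
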