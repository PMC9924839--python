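"""Synthetic 12-lead ECG and feature-table generators with ground truth.

Records are rendered as sums of per-beat Gaussian bumps (one per P, Q,
R, S, T wave) at RR-spaced apex times, which gives analytic control of
every amplitude and exact ground-truth peak locations — chosen over
dynamical-system ECG models precisely for that property; fidelity to
real ECG morphology is a non-goal.  Defaults mirror the acquisition
convention of the target device: 500 Hz sampling for 11 s, i.e. 5500
samples per lead.

Of note, the P wave of the default templates lies below the detector's
minimum-peak-amplitude floor (0.025 mV): the published scan accepts the
*first* qualifying local maximum, so a P wave above the floor would
capture the scan.  A larger P amplitude can be configured to document
that sensitivity.  The aVR template carries the lead's inverted
polarity (small R, deep S) to exercise signed-amplitude handling.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import Beat, PeakAnnotations, seconds_to_samples
from .features import FEATURE_NAMES
from .io import ECGSequence, LEAD_NAMES, lvh_label

WAVE_NAMES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class WaveSpec:
    """One Gaussian wave: signed amplitude (mV), center offset from the
    R apex (s), and width (Gaussian sd, s)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be > 0")


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one heartbeat as five Gaussian waves.

    Invariants: R amplitude > 0, S amplitude <= 0, and wave order
    P < Q <= 0 < S < T along the time axis (R at offset 0).
    """

    P: WaveSpec = WaveSpec(0.01, -0.18, 0.02)
    Q: WaveSpec = WaveSpec(-0.06, -0.035, 0.008)
    R: WaveSpec = WaveSpec(1.0, 0.0, 0.012)
    S: WaveSpec = WaveSpec(-0.3, 0.06, 0.010)
    T: WaveSpec = WaveSpec(0.3, 0.26, 0.04)

    def __post_init__(self) -> None:
        if self.R.amplitude <= 0:
            raise ValueError("R amplitude must be > 0")
        if self.S.amplitude > 0:
            raise ValueError("S amplitude must be <= 0")
        if not (self.P.center < self.Q.center <= 0.0 < self.S.center < self.T.center):
            raise ValueError("wave offsets must satisfy P < Q <= 0 < S < T")

    @property
    def waves(self) -> dict[str, WaveSpec]:
        return {name: getattr(self, name) for name in WAVE_NAMES}

    @property
    def span(self) -> float:
        """Temporal extent covered by the template (3 sd per wave)."""
        left = self.P.center - 3 * self.P.width
        right = self.T.center + 3 * self.T.width
        return right - left

    def render(self, t: np.ndarray, apex_time: float) -> np.ndarray:
        """Evaluate the beat at times ``t`` for an R apex at ``apex_time``."""
        out = np.zeros_like(t)
        for wave in self.waves.values():
            out += wave.amplitude * np.exp(
                -0.5 * ((t - apex_time - wave.center) / wave.width) ** 2
            )
        return out


#: Typical per-lead R amplitude and S magnitude (mV) of a normal adult
#: 12-lead ECG; aVR and V1-V2 are S-dominant.
BASE_AMPLITUDES: dict[str, tuple[float, float]] = {
    "I": (0.6, 0.10),
    "II": (1.0, 0.15),
    "III": (0.5, 0.20),
    "aVR": (0.15, 0.80),
    "aVL": (0.4, 0.15),
    "aVF": (0.7, 0.15),
    "V1": (0.2, 0.90),
    "V2": (0.4, 1.20),
    "V3": (0.7, 0.90),
    "V4": (1.3, 0.50),
    "V5": (1.5, 0.30),
    "V6": (1.2, 0.15),
}


def make_template(
    r_amp: float,
    s_mag: float,
    t_over_r: float = 0.3,
    p_amp: float = 0.01,
) -> BeatTemplate:
    """Template with given R amplitude and S magnitude (both mV >= 0).

    The Q wave is kept shallower than the S valley (at most 60% of its
    depth, capped at 0.06 mV): the backward valley-correction step of
    the detector assumes the S valley is the deepest point of the QRS
    complex, and a Q deeper than S would defeat it.
    """
    if r_amp <= 0:
        raise ValueError(f"R amplitude must be > 0, got {r_amp}")
    if s_mag < 0:
        raise ValueError(f"S magnitude must be >= 0, got {s_mag}")
    base = BeatTemplate()
    return replace(
        base,
        P=replace(base.P, amplitude=p_amp),
        Q=replace(base.Q, amplitude=-min(0.06, 0.6 * s_mag)),
        R=replace(base.R, amplitude=r_amp),
        S=replace(base.S, amplitude=-s_mag),
        T=replace(base.T, amplitude=t_over_r * r_amp),
    )


def default_templates(t_over_r: float = 0.3, p_amp: float = 0.01) -> dict[str, BeatTemplate]:
    """One plausible template per canonical lead."""
    return {
        lead: make_template(r, s, t_over_r=t_over_r, p_amp=p_amp)
        for lead, (r, s) in BASE_AMPLITUDES.items()
    }


def _truth_annotations(
    signal: np.ndarray, apex_times: np.ndarray, fs: float, lead: str
) -> PeakAnnotations:
    """Exact R/S ground truth from the noiseless rendered signal.

    The apex index is the numerical argmax near each nominal apex time
    (render-grid effects can shift it by one sample); the valley is the
    minimum of the standard forward window after it.
    """
    n = signal.size
    half = seconds_to_samples(0.05, fs)
    s_win = seconds_to_samples(0.12, fs)
    ann = PeakAnnotations(lead=lead, fs=fs)
    for a in apex_times:
        j = int(round(a * fs))
        lo, hi = max(j - half, 0), min(j + half, n - 1)
        if lo > hi:
            continue
        r_idx = lo + int(np.argmax(signal[lo : hi + 1]))
        if r_idx + 1 > n - 1:
            continue
        s_lo, s_hi = r_idx + 1, min(r_idx + s_win, n - 1)
        s_idx = s_lo + int(np.argmin(signal[s_lo : s_hi + 1]))
        ann.beats.append(
            Beat(r_idx, float(signal[r_idx]), s_idx, float(signal[s_idx]))
        )
    return ann


def synth_record(
    templates: Mapping[str, BeatTemplate] | None = None,
    heart_rate: float = 72.0,
    duration: float = 11.0,
    fs: float = 500.0,
    noise_sd: float = 0.0,
    rr_jitter: float = 0.0,
    wander_amp: float = 0.0,
    wander_freq: float = 0.25,
    start_offset: float = 0.3,
    seed: int | np.random.Generator = 0,
    subject_id: str = "synthetic",
    sex: str = "unknown",
) -> tuple[ECGSequence, dict[str, PeakAnnotations]]:
    """Render a 12-lead record and its exact peak/valley ground truth.

    Beat apices are spaced by ``60/heart_rate`` seconds (plus seeded
    Gaussian RR jitter of sd ``rr_jitter``) starting at
    ``start_offset``; a negative offset clips the first beat, which is
    how a tall-T misdetection scenario is produced.  Optional white
    noise (sd in mV) and sinusoidal baseline wander are added on top of
    the noiseless signal; the ground truth always refers to the
    noiseless signal and contains only beats whose R and S fall inside
    the record.
    """
    if not (20.0 <= heart_rate <= 250.0):
        raise ValueError(f"implausible heart rate {heart_rate} bpm")
    templates = dict(templates) if templates is not None else default_templates()
    missing = [l for l in LEAD_NAMES if l not in templates]
    if missing:
        raise ValueError(f"templates missing lead(s): {', '.join(missing)}")
    rr = 60.0 / heart_rate
    for lead, tpl in templates.items():
        if tpl.span > rr:
            raise ValueError(
                f"lead {lead}: template span {tpl.span:.3f}s exceeds RR {rr:.3f}s"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    n_beats = int(np.ceil((duration - start_offset) / rr)) + 2
    intervals = rr + rng.normal(0.0, rr_jitter, size=max(n_beats - 1, 0))
    apex_times = start_offset + np.concatenate([[0.0], np.cumsum(intervals)])
    apex_times = apex_times[apex_times < duration + rr]

    leads: dict[str, np.ndarray] = {}
    truth: dict[str, PeakAnnotations] = {}
    for lead in LEAD_NAMES:
        tpl = templates[lead]
        clean = np.zeros(n)
        for a in apex_times:
            clean += tpl.render(t, a)
        in_signal = apex_times[(apex_times >= 0.0) & (apex_times < duration)]
        truth[lead] = _truth_annotations(clean, in_signal, fs, lead)
        noisy = clean
        if wander_amp > 0.0:
            phase = rng.uniform(0.0, 2 * np.pi)
            noisy = noisy + wander_amp * np.sin(2 * np.pi * wander_freq * t + phase)
        if noise_sd > 0.0:
            noisy = noisy + rng.normal(0.0, noise_sd, size=n)
        leads[lead] = noisy
    seq = ECGSequence(leads=leads, fs=fs, subject_id=subject_id, sex=sex)
    return seq, truth


@dataclass(frozen=True)
class CohortSpec:
    """Two-class synthetic cohort layout.

    ``lvh_shifts`` are mean amplitude elevations (mV) applied to the
    LVH class on criteria-relevant features; per-subject variation has
    sd ``amp_sd`` on every feature.  Cohort composition defaults to the
    target study's 173 LVH / 779 control cases with a 90% male cohort.
    """

    n_lvh: int = 173
    n_control: int = 779
    fs: float = 500.0
    duration: float = 11.0
    heart_rate: tuple[float, float] = (60.0, 95.0)
    noise_sd: float = 0.005
    rr_jitter: float = 0.005
    wander_amp: float = 0.0
    wander_freq: float = 0.3
    male_fraction: float = 0.9
    amp_sd: float = 0.12
    lvh_shifts: Mapping[str, float] = field(
        default_factory=lambda: {
            "SV1": 1.2,
            "SV3": 1.0,
            "RaVL": 0.7,
            "RV5": 1.0,
            "RV6": 0.8,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lvh < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        lo, hi = self.heart_rate
        if not (40.0 <= lo <= hi <= 180.0):
            raise ValueError("heart rate range must lie within [40, 180] bpm")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be > 0")
        unknown = set(self.lvh_shifts) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown shifted feature(s): {sorted(unknown)}")


@dataclass(frozen=True)
class CohortCase:
    """One synthetic subject: record, exact truth, and labels."""

    subject_id: str
    sequence: ECGSequence
    truth: dict[str, PeakAnnotations]
    label: bool
    sex: str
    lvmi: float


def _draw_lvmi(rng: np.random.Generator, label: bool, sex: str) -> float:
    base = 115.0 if sex == "male" else 95.0
    if label:
        return float(base + rng.uniform(1.0, 45.0))
    return float(base - rng.uniform(1.0, 45.0))


def synth_cohort(spec: CohortSpec) -> tuple[list[CohortCase], pd.DataFrame]:
    """Generate labelled records plus the ground-truth feature table.

    The LVH class draws per-lead template amplitudes with elevated
    means on the shifted features; controls sit at baseline.  The
    returned table has one row per case with subject_id, sex, lvmi,
    label and the 24 truth amplitudes taken from the templates.
    """
    root = np.random.SeedSequence(spec.seed)
    cases: list[CohortCase] = []
    rows: list[dict] = []
    labels = [True] * spec.n_lvh + [False] * spec.n_control
    for i, (label, child) in enumerate(zip(labels, root.spawn(len(labels)))):
        rng = np.random.default_rng(child)
        sex = "male" if rng.uniform() < spec.male_fraction else "female"
        subject_id = f"synth-{'lvh' if label else 'ctl'}-{i:04d}"
        templates: dict[str, BeatTemplate] = {}
        row: dict = {"subject_id": subject_id, "sex": sex, "label": label}
        for lead in LEAD_NAMES:
            base_r, base_s = BASE_AMPLITUDES[lead]
            r = base_r + rng.normal(0.0, spec.amp_sd)
            s = base_s + rng.normal(0.0, spec.amp_sd)
            if label:
                r += spec.lvh_shifts.get(f"R{lead}", 0.0)
                s += spec.lvh_shifts.get(f"S{lead}", 0.0)
            # floors keep the morphology in the regime the detector
            # assumes: a visible R and an S deeper than the Q wave
            r = max(r, 0.05)
            s = max(s, 0.1)
            templates[lead] = make_template(r, s)
            row[f"R{lead}"] = r
            row[f"S{lead}"] = s
        hr = float(rng.uniform(*spec.heart_rate))
        lvmi = _draw_lvmi(rng, label, sex)
        assert lvh_label(lvmi, sex) == label
        row["lvmi"] = lvmi
        seq, truth = synth_record(
            templates,
            heart_rate=hr,
            duration=spec.duration,
            fs=spec.fs,
            noise_sd=spec.noise_sd,
            rr_jitter=spec.rr_jitter,
            wander_amp=spec.wander_amp,
            wander_freq=spec.wander_freq,
            seed=rng,
            subject_id=subject_id,
            sex=sex,
        )
        cases.append(CohortCase(subject_id, seq, truth, label, sex, lvmi))
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table[["subject_id", "sex", "lvmi", "label"] + list(FEATURE_NAMES)]
    return cases, table


#: Default features carrying the class signal in feature-table draws.
DEFAULT_SHIFTED_FEATURES = ("RI", "RaVL", "RV5", "RV6", "SV1", "SV3")


def synth_feature_table(
    n_per_class: int = 400,
    shifted_features: Sequence[str] = DEFAULT_SHIFTED_FEATURES,
    effect_size: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-class 24-feature table with a known effect size.

    Every feature is standard normal in both classes except the
    ``shifted_features``, whose means differ by ``effect_size``
    standard deviations between classes.  Returns ``(X, y)`` with
    boolean labels (True = positive class).
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    unknown = set(shifted_features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES)
    )
    y = np.array([False] * n_per_class + [True] * n_per_class)
    X.loc[y, list(shifted_features)] += effect_size
    return X, y
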