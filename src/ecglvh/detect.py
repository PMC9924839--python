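"""Automatic R-peak and S-valley detection for 12-lead ECG.

The detector scans each lead left to right and accepts the first strict
local maximum above a minimum peak amplitude (``mpa``); after each
accepted peak a refractory interval of ``miR`` samples suppresses
further candidates, which filters T and P deflections of the same beat
at normal heart rates (60-100 bpm).  The S valley is the minimum within
a short forward window after each R peak.  Because a tall T wave can be
mistaken for the R peak when the scan first meets a beat mid-cycle, a
correction pass searches backward from each preliminary R for a deeper
valley and, when found, relocates the valley there and re-anchors the R
peak as the maximum immediately before it.

No filtering or baseline-wander removal is applied before detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def seconds_to_samples(duration: float, fs: float) -> int:
    """Convert a duration to a sample count with half-up rounding.

    At 500 Hz: 0.12 s -> 60 samples, 0.25 s -> 125, 0.6 s -> 300.
    """
    return int(math.floor(duration * fs + 0.5))


@dataclass(frozen=True)
class DetectorParams:
    """Tunable parameters of the R/S detector.

    Attributes
    ----------
    mpa : float
        Minimum peak amplitude in mV; candidates at or below it are
        ignored.  Default 0.025 mV.
    miR : int
        Refractory interval between adjacent R peaks, in samples.
        Default 300 (0.6 s at 500 Hz, the fastest normal heart rate).
    s_forward_window : float
        Forward search window for the S valley, seconds (default 0.12).
    t_backward_window : float
        Backward search window for the T-misdetection check, seconds
        (default 0.25).
    r_backward_window : float
        Window used to re-anchor the R peak next to a relocated S
        valley, seconds (default 0.12).
    step7_direction : {"backward", "forward"}
        Where to search for the re-anchored R relative to the relocated
        S valley.  "backward" (default) looks before the valley, which
        is where a true R sits in a QRS complex; "forward" is kept for
        fidelity experiments.
    """

    mpa: float = 0.025
    miR: int = 300
    s_forward_window: float = 0.12
    t_backward_window: float = 0.25
    r_backward_window: float = 0.12
    step7_direction: str = "backward"

    def __post_init__(self) -> None:
        if self.mpa < 0:
            raise ValueError("mpa must be >= 0")
        if self.miR < 1:
            raise ValueError("miR must be >= 1 sample")
        for name in ("s_forward_window", "t_backward_window", "r_backward_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.step7_direction not in ("backward", "forward"):
            raise ValueError("step7_direction must be 'backward' or 'forward'")


@dataclass(frozen=True)
class Beat:
    """One detected heartbeat: R peak and the paired S valley.

    ``s_amp_signed`` is the raw sample value at the valley (signed mV);
    magnitude conversion happens in the feature layer.
    """

    r_index: int
    r_amp: float
    s_index: int
    s_amp_signed: float


@dataclass
class PeakAnnotations:
    """Ordered per-lead beat annotations plus detection metadata."""

    lead: str
    fs: float
    beats: list[Beat] = field(default_factory=list)
    warning: str | None = None

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def r_indices(self) -> np.ndarray:
        return np.array([b.r_index for b in self.beats], dtype=int)

    def validate(self) -> None:
        w = seconds_to_samples(0.12, self.fs)
        prev = -1
        for b in self.beats:
            if b.r_index <= prev:
                raise ValueError(f"lead {self.lead}: R indices not strictly increasing")
            if not (b.r_index < b.s_index <= b.r_index + w):
                raise ValueError(
                    f"lead {self.lead}: S index {b.s_index} not within "
                    f"({b.r_index}, {b.r_index + w}]"
                )
            prev = b.r_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lead": self.lead,
                "beat": range(len(self.beats)),
                "r_index": [b.r_index for b in self.beats],
                "r_amp_mV": [b.r_amp for b in self.beats],
                "s_index": [b.s_index for b in self.beats],
                "s_amp_mV": [b.s_amp_signed for b in self.beats],
            }
        )


def detect_preliminary_r(
    signal: np.ndarray, fs: float, params: DetectorParams | None = None
) -> list[int]:
    """Greedy scan for preliminary R peaks.

    Accepts the first sample ``j`` with ``x[j] > mpa`` that is a strict
    local maximum (``x[j-1] < x[j]`` and ``x[j+1] < x[j]``), then skips
    ahead by the refractory interval and repeats.  Returns indices in
    scan order; an empty list is a valid result.
    """
    params = params or DetectorParams()
    x = np.asarray(signal, dtype=float)
    n = x.size
    peaks: list[int] = []
    j = 1
    while j <= n - 2:
        if x[j] > params.mpa and x[j - 1] < x[j] and x[j + 1] < x[j]:
            peaks.append(j)
            j += params.miR
        else:
            j += 1
    return peaks


def locate_s_valley(
    signal: np.ndarray, r_index: int, fs: float, params: DetectorParams | None = None
) -> tuple[int, float]:
    """Minimum of the forward window ``(r, r + 0.12 s]``, earliest on ties.

    The window is truncated at the end of the signal; an R peak at the
    last sample leaves an empty window and raises ``ValueError``.
    """
    params = params or DetectorParams()
    x = np.asarray(signal, dtype=float)
    n = x.size
    if not (0 <= r_index < n):
        raise ValueError(f"r_index {r_index} outside signal of length {n}")
    w = seconds_to_samples(params.s_forward_window, fs)
    lo, hi = r_index + 1, min(r_index + w, n - 1)
    if lo > hi:
        raise ValueError(f"empty S-search window after r_index {r_index}")
    window = x[lo : hi + 1]
    s_index = lo + int(np.argmin(window))
    return s_index, float(x[s_index])


def correct_t_misdetection(
    signal: np.ndarray,
    r_index: int,
    s_index: int,
    fs: float,
    params: DetectorParams | None = None,
) -> tuple[int, int]:
    """Repair beats where the preliminary "R" is actually a T apex.

    Looks for a minimum ``m`` within ``t_backward_window`` before the
    preliminary R.  If ``m`` is deeper than the current S valley, the
    valley moves there and the R peak is re-anchored as the maximum of
    the ``r_backward_window`` immediately before the new valley (or
    after it, in "forward" mode).  Otherwise the inputs are returned
    unchanged, as they are when the backward window lies entirely off
    the signal.
    """
    params = params or DetectorParams()
    x = np.asarray(signal, dtype=float)
    n = x.size
    wb = seconds_to_samples(params.t_backward_window, fs)
    lo = max(r_index - wb, 0)
    if lo >= r_index:
        return r_index, s_index
    window = x[lo:r_index]
    m = float(window.min())
    if m >= x[s_index]:
        return r_index, s_index
    s_new = lo + int(np.argmin(window))
    wr = seconds_to_samples(params.r_backward_window, fs)
    if params.step7_direction == "backward":
        lo2 = max(s_new - wr, 0)
        segment = x[lo2:s_new]
        if segment.size == 0:
            return r_index, s_index
        r_new = lo2 + int(np.argmax(segment))
    else:
        hi2 = min(s_new + wr, n - 1)
        segment = x[s_new + 1 : hi2 + 1]
        if segment.size == 0:
            return r_index, s_index
        r_new = s_new + 1 + int(np.argmax(segment))
    if s_new <= r_new:
        # re-pair: fresh forward S search restores s > r ordering
        try:
            s_new, _ = locate_s_valley(x, r_new, fs, params)
        except ValueError:
            return r_index, s_index
    return r_new, s_new


def detect_lead(
    signal: np.ndarray,
    fs: float,
    params: DetectorParams | None = None,
    lead: str = "",
) -> PeakAnnotations:
    """Full per-lead detection: preliminary R scan, S location, T repair.

    The output is sorted by R index, deduplicated, and satisfies the
    annotation invariants.  Fewer than 3 resulting beats is flagged in
    ``warning`` because downstream medians and beat segmentation need at
    least one interior beat.
    """
    params = params or DetectorParams()
    x = np.asarray(signal, dtype=float)
    n = x.size
    ann = PeakAnnotations(lead=lead, fs=fs)
    if n >= 3:
        for r in detect_preliminary_r(x, fs, params):
            if r >= n - 1:
                continue  # no room for an S valley
            s, _ = locate_s_valley(x, r, fs, params)
            r2, s2 = correct_t_misdetection(x, r, s, fs, params)
            ann.beats.append(
                Beat(
                    r_index=int(r2),
                    r_amp=float(x[r2]),
                    s_index=int(s2),
                    s_amp_signed=float(x[s2]),
                )
            )
    ann.beats.sort(key=lambda b: b.r_index)
    deduped: list[Beat] = []
    for b in ann.beats:
        if deduped and b.r_index <= deduped[-1].r_index:
            continue
        deduped.append(b)
    ann.beats = deduped
    ann.validate()
    if len(ann.beats) < 3:
        ann.warning = (
            f"only {len(ann.beats)} beat(s) detected; medians and beat "
            "segmentation need at least 3"
        )
    return ann


def detect_record(sequence, params: DetectorParams | None = None) -> dict[str, PeakAnnotations]:
    """Run :func:`detect_lead` on every lead of an ECG sequence."""
    return {
        lead: detect_lead(samples, sequence.fs, params, lead=lead)
        for lead, samples in sequence.leads.items()
    }


def annotations_to_frame(annotations: dict[str, PeakAnnotations]) -> pd.DataFrame:
    """Stack per-lead annotations into one long table."""
    frames = [ann.to_frame() for ann in annotations.values() if len(ann)]
    if not frames:
        return pd.DataFrame(
            columns=["lead", "beat", "r_index", "r_amp_mV", "s_index", "s_amp_mV"]
        )
    return pd.concat(frames, ignore_index=True)
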