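"""The 24-feature ECG representation: R and S amplitudes per lead.

A case is summarised by per-lead median R-peak and S-valley amplitudes
after dropping the first and last detected cycles (they are often
incomplete or noisy).  Beat segmentation turns one multi-beat record
into one feature row per interior heartbeat of a reference lead, which
multiplies the training data available per subject.

S features are stored as magnitudes: the depth of the valley below
baseline, floored at 0 when the valley sits above baseline.  Raw signal
zero is taken as baseline (no isoelectric-PR correction).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .detect import PeakAnnotations, seconds_to_samples
from .io import LEAD_NAMES

#: Canonical feature order: 12 R amplitudes then 12 S magnitudes.
FEATURE_NAMES: tuple[str, ...] = tuple(f"R{l}" for l in LEAD_NAMES) + tuple(
    f"S{l}" for l in LEAD_NAMES
)

#: Default reference lead for beat segmentation (conventional rhythm lead).
DEFAULT_REFERENCE_LEAD = "II"

#: Default cross-lead beat-matching tolerance, seconds.
DEFAULT_MATCH_TOL = 0.15


def s_magnitude(s_amp_signed: float) -> float:
    """Depth of an S valley below baseline, >= 0."""
    return max(0.0, -float(s_amp_signed))


def _interior(ann: PeakAnnotations):
    return ann.beats[1:-1]


def median_amplitudes(annotations: Mapping[str, PeakAnnotations]) -> pd.Series:
    """Per-case 24-feature vector from per-lead annotations.

    For each lead independently the first and last beats are dropped
    and the medians of the remaining R amplitudes and S magnitudes
    become the lead's R and S features (even counts average the two
    middle values).  Every lead needs at least 3 detected beats.
    """
    values: dict[str, float] = {}
    for lead in LEAD_NAMES:
        if lead not in annotations:
            raise KeyError(f"annotations missing lead {lead}")
        ann = annotations[lead]
        if len(ann.beats) < 3:
            raise ValueError(
                f"lead {lead}: {len(ann.beats)} beat(s) detected, need >= 3 "
                "for median amplitudes"
            )
        interior = _interior(ann)
        values[f"R{lead}"] = float(np.median([b.r_amp for b in interior]))
        values[f"S{lead}"] = float(
            np.median([s_magnitude(b.s_amp_signed) for b in interior])
        )
    return pd.Series(values, dtype=float).reindex(list(FEATURE_NAMES))


def _fallback_medians(ann: PeakAnnotations) -> tuple[float, float]:
    """Case-median R/S for a lead, tolerating sparse detections."""
    beats = _interior(ann) if len(ann.beats) >= 3 else ann.beats
    if not beats:
        raise ValueError(f"lead {ann.lead}: no beats for fallback medians")
    r = float(np.median([b.r_amp for b in beats]))
    s = float(np.median([s_magnitude(b.s_amp_signed) for b in beats]))
    return r, s


def segment_beats(
    annotations: Mapping[str, PeakAnnotations],
    reference_lead: str = DEFAULT_REFERENCE_LEAD,
    match_tol: float = DEFAULT_MATCH_TOL,
    subject_id: str = "",
    label: bool | None = None,
) -> pd.DataFrame:
    """One 24-feature row per interior beat of the reference lead.

    Rows are anchored on the detected R peaks of ``reference_lead``;
    the first and last cycles are excluded, so a record with ``n``
    reference beats yields ``n - 2`` rows.  Each other lead contributes
    the amplitudes of its own beat whose R index is nearest the anchor
    (one-to-one, within ``match_tol`` seconds); leads with no matching
    beat fall back to their case-median amplitudes.
    """
    if reference_lead not in annotations:
        raise KeyError(f"annotations missing reference lead {reference_lead}")
    ref = annotations[reference_lead]
    if len(ref.beats) < 3:
        raise ValueError(
            f"reference lead {reference_lead}: {len(ref.beats)} beat(s), need >= 3"
        )
    fs = ref.fs
    tol_samples = seconds_to_samples(match_tol, fs)
    anchors = _interior(ref)

    rows: list[dict] = [
        {"subject_id": subject_id, "beat": i} for i in range(len(anchors))
    ]
    for lead in LEAD_NAMES:
        if lead not in annotations:
            raise KeyError(f"annotations missing lead {lead}")
        ann = annotations[lead]
        med_r, med_s = _fallback_medians(ann)
        # one-to-one greedy nearest-neighbour matching within tolerance
        candidates = sorted(
            (abs(b.r_index - a.r_index), i, j)
            for i, a in enumerate(anchors)
            for j, b in enumerate(ann.beats)
            if abs(b.r_index - a.r_index) <= tol_samples
        )
        matched: dict[int, int] = {}
        used_j: set[int] = set()
        for _, i, j in candidates:
            if i not in matched and j not in used_j:
                matched[i] = j
                used_j.add(j)
        for i in range(len(anchors)):
            if i in matched:
                b = ann.beats[matched[i]]
                rows[i][f"R{lead}"] = b.r_amp
                rows[i][f"S{lead}"] = s_magnitude(b.s_amp_signed)
            else:
                rows[i][f"R{lead}"] = med_r
                rows[i][f"S{lead}"] = med_s
    table = pd.DataFrame(rows)
    if label is not None:
        table["label"] = bool(label)  # every beat inherits the case label
    return table[
        ["subject_id", "beat"]
        + list(FEATURE_NAMES)
        + (["label"] if label is not None else [])
    ]


def zscore_fit_apply(train, test=None):
    """Z-score normalisation fitted on the training data only.

    Column means and population (n-denominator) standard deviations are
    estimated from ``train``; both sets are transformed with those
    statistics, so the training columns come out with mean 0 and sd 1
    while the test transform is leakage-free.  Standard deviations
    below 1e-12 are clamped to 1, which maps constant columns to zero.

    Returns ``(train_z, test_z, stats)`` where ``stats`` is a dict with
    ``"mean"`` and ``"sd"`` entries; ``test_z`` is None when no test
    set is given.
    """
    train_df = pd.DataFrame(train)
    if len(train_df) < 2:
        raise ValueError("z-score fitting needs at least 2 training rows")
    mean = train_df.mean(axis=0)
    sd = train_df.std(axis=0, ddof=0)
    sd = sd.where(sd >= 1e-12, 1.0)
    train_z = (train_df - mean) / sd
    test_z = None
    if test is not None:
        test_df = pd.DataFrame(test)
        if list(test_df.columns) != list(train_df.columns):
            test_df = test_df[train_df.columns]
        test_z = (test_df - mean) / sd
    stats = {"mean": mean, "sd": sd}
    if isinstance(train, np.ndarray):
        train_z = train_z.to_numpy()
        if test_z is not None:
            test_z = test_z.to_numpy()
    return train_z, test_z, stats
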