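"""Seven classical ECG voltage criteria for left ventricular hypertrophy.

Each criterion maps a 24-feature amplitude vector (R and S per lead,
mV; S as magnitudes) to a score, the threshold it was compared against,
and a boolean LVH call.  Printed strictness is preserved exactly:
Cornell, Framingham and Lewis use strict ``>``; Sokolow-Lyon, Peguero,
Gubner and the 12-lead sum use ``>=``.

All thresholds live in :data:`DEFAULT_THRESHOLDS` so cohort-specific
recalibration never touches code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io import LEAD_NAMES

#: One config table for every threshold (mV).
DEFAULT_THRESHOLDS: dict = {
    "cornell": {"male": 2.8, "female": 2.0},
    "sokolow": 3.5,
    "peguero": {"male": 2.8, "female": 2.3},
    "framingham": {
        "RaVL": 1.1,
        "RV4-RV6": 2.5,
        "SV1-SV3": 2.5,
        "maxSV1SV2+maxRV5RV6": 3.5,
        "RI+SIII": 2.5,
    },
    "gubner": 2.2,
    "sum12": 17.9,
    "lewis": 1.7,
}

CRITERION_NAMES = ("cornell", "sokolow", "peguero", "framingham", "gubner", "sum12", "lewis")


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of one voltage criterion on one case."""

    name: str
    score: float
    threshold: float
    positive: bool
    detail: dict = field(default_factory=dict)


def _sex_key(sex) -> str:
    sex = str(sex).lower()
    if sex not in ("male", "female"):
        raise ValueError(f"criterion threshold undefined for sex {sex!r}")
    return sex


def _thr(thresholds, name):
    return (thresholds or DEFAULT_THRESHOLDS)[name]


def cornell(f: Mapping[str, float], sex, thresholds=None) -> CriterionResult:
    """Cornell voltage: SV3 + RaVL > 2.8 mV (male) / 2.0 mV (female)."""
    t = _thr(thresholds, "cornell")[_sex_key(sex)]
    score = f["SV3"] + f["RaVL"]
    return CriterionResult("cornell", float(score), float(t), bool(score > t))


def sokolow(f: Mapping[str, float], thresholds=None) -> CriterionResult:
    """Sokolow-Lyon: SV1 + max(RV5, RV6) >= 3.5 mV."""
    t = _thr(thresholds, "sokolow")
    score = f["SV1"] + max(f["RV5"], f["RV6"])
    return CriterionResult("sokolow", float(score), float(t), bool(score >= t))


def peguero(f: Mapping[str, float], sex, thresholds=None) -> CriterionResult:
    """Peguero-Lo Presti: deepest S in any lead + SV4 >= 2.8/2.3 mV.

    The deepest S may itself be SV4, in which case it counts twice.
    """
    t = _thr(thresholds, "peguero")[_sex_key(sex)]
    sd_lead = max(LEAD_NAMES, key=lambda l: f[f"S{l}"])
    sd = f[f"S{sd_lead}"]
    score = sd + f["SV4"]
    return CriterionResult(
        "peguero", float(score), float(t), bool(score >= t), {"deepest_s_lead": sd_lead}
    )


def framingham(f: Mapping[str, float], thresholds=None) -> CriterionResult:
    """Framingham: positive iff any of five strict clauses holds.

    The reported score is the largest clause margin (clause value minus
    its own threshold, mV) against a reference threshold of 0, so the
    printed strictness is preserved; ``detail`` records every clause
    value and which clauses fired.
    """
    t = _thr(thresholds, "framingham")
    clauses = {
        "RaVL": (f["RaVL"], t["RaVL"]),
        "RV4-RV6": (max(f["RV4"], f["RV5"], f["RV6"]), t["RV4-RV6"]),
        "SV1-SV3": (max(f["SV1"], f["SV2"], f["SV3"]), t["SV1-SV3"]),
        "maxSV1SV2+maxRV5RV6": (
            max(f["SV1"], f["SV2"]) + max(f["RV5"], f["RV6"]),
            t["maxSV1SV2+maxRV5RV6"],
        ),
        "RI+SIII": (f["RI"] + f["SIII"], t["RI+SIII"]),
    }
    fired = [name for name, (v, thr) in clauses.items() if v > thr]
    margin = max(v - thr for v, thr in clauses.values())
    return CriterionResult(
        "framingham",
        float(margin),
        0.0,
        bool(fired),
        {"clauses": {k: float(v) for k, (v, _) in clauses.items()}, "fired": fired},
    )


def gubner(f: Mapping[str, float], thresholds=None) -> CriterionResult:
    """Gubner-Ungerleider: RI + SIII >= 2.2 mV."""
    t = _thr(thresholds, "gubner")
    score = f["RI"] + f["SIII"]
    return CriterionResult("gubner", float(score), float(t), bool(score >= t))


def sum12(f: Mapping[str, float], thresholds=None) -> CriterionResult:
    """12-lead sum: sum over leads of max(R, S) >= 17.9 mV."""
    t = _thr(thresholds, "sum12")
    score = math.fsum(max(f[f"R{l}"], f[f"S{l}"]) for l in LEAD_NAMES)
    return CriterionResult("sum12", float(score), float(t), bool(score >= t))


def lewis(f: Mapping[str, float], thresholds=None) -> CriterionResult:
    """Lewis index: (RI + SIII) - (RIII + SI) > 1.7 mV; may be negative."""
    t = _thr(thresholds, "lewis")
    score = (f["RI"] + f["SIII"]) - (f["RIII"] + f["SI"])
    return CriterionResult("lewis", float(score), float(t), bool(score > t))


#: Criteria that need the subject's sex for their threshold.
SEX_SPECIFIC = ("cornell", "peguero")


def evaluate_case(f: Mapping[str, float], sex="unknown", thresholds=None) -> dict[str, CriterionResult]:
    """Apply all seven criteria to one feature vector."""
    out = {
        "sokolow": sokolow(f, thresholds),
        "framingham": framingham(f, thresholds),
        "gubner": gubner(f, thresholds),
        "sum12": sum12(f, thresholds),
        "lewis": lewis(f, thresholds),
    }
    out["cornell"] = cornell(f, sex, thresholds)
    out["peguero"] = peguero(f, sex, thresholds)
    return {name: out[name] for name in CRITERION_NAMES}


def evaluate_criteria_cohort(
    features: pd.DataFrame,
    labels,
    sex=None,
    thresholds=None,
):
    """Confusion-matrix report per criterion over a labelled cohort.

    Parameters
    ----------
    features : DataFrame
        One row per case with the 24 canonical feature columns; a
        ``sex`` column is used when ``sex`` is not given separately.
    labels : boolean sequence
        LVH ground truth (LVH is the positive class).
    sex : sequence, optional

    Returns
    -------
    dict mapping criterion name -> :class:`~ecglvh.models.ModelReport`.
    """
    from .models import ModelReport

    labels = pd.Series(list(labels)).astype(bool).to_numpy()
    if sex is None:
        sex = features["sex"] if "sex" in features.columns else ["unknown"] * len(features)
    sex = list(sex)
    calls = {name: [] for name in CRITERION_NAMES}
    for (_, row), s in zip(features.iterrows(), sex):
        results = evaluate_case(row, sex=s, thresholds=thresholds)
        for name, res in results.items():
            calls[name].append(res.positive)
    return {
        name: ModelReport.from_predictions(labels, calls[name])
        for name in CRITERION_NAMES
    }
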