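"""Reading and writing 12-lead ECG sequences, labels, and reports.

Conventions owned by this module:

* the canonical 12-lead order ``I, II, III, aVR, aVL, aVF, V1..V6``;
* amplitudes are held internally in millivolts (mV);
* sample indices are 0-based half-open.

The wide-CSV dialect is one header row of lead names and one row per
sample.  A header cell may carry a unit suffix in parentheses, e.g.
``"V1 (uV)"``; microvolt columns are converted to mV on read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

#: Canonical 12-lead names in conventional order.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_LEAD_BY_LOWER = {name.lower(): name for name in LEAD_NAMES}

#: LVMI cut-offs (g/m^2) above which a case is labelled LVH, by sex.
LVMI_THRESHOLDS = {"male": 115.0, "female": 95.0}

_HEADER_RE = re.compile(r"^\s*(?P<name>\S+)\s*(?:\((?P<unit>mV|uV|µV)\))?\s*$")


class ECGFormatError(ValueError):
    """Raised when an input file violates the ECG format contract."""


@dataclass
class ECGSequence:
    """A multi-lead ECG record: per-lead sample arrays in mV plus metadata.

    All leads must share one length, contain only finite values, and use
    canonical lead names.  ``fs`` is the sampling frequency in Hz.
    """

    leads: dict[str, np.ndarray]
    fs: float
    subject_id: str = ""
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")
        clean: dict[str, np.ndarray] = {}
        length = None
        for name, samples in self.leads.items():
            if name not in LEAD_NAMES:
                raise ECGFormatError(f"unknown lead name {name!r}")
            arr = np.asarray(samples, dtype=float)
            if arr.ndim != 1:
                raise ECGFormatError(f"lead {name}: samples must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise ECGFormatError(f"lead {name}: non-finite sample values")
            if length is None:
                length = arr.size
            elif arr.size != length:
                raise ECGFormatError(
                    f"lead {name}: length {arr.size} != {length} of other leads"
                )
            clean[name] = arr
        # normalize to canonical order
        self.leads = {n: clean[n] for n in LEAD_NAMES if n in clean}

    @property
    def n_samples(self) -> int:
        if not self.leads:
            return 0
        return next(iter(self.leads.values())).size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def require_complete(self) -> None:
        """Raise unless all 12 canonical leads are present."""
        missing = [n for n in LEAD_NAMES if n not in self.leads]
        if missing:
            raise ECGFormatError(f"missing lead(s): {', '.join(missing)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({n: v for n, v in self.leads.items()})


def _parse_header(columns) -> dict[str, tuple[str, float]]:
    """Map raw CSV column -> (canonical lead, scale-to-mV factor)."""
    out: dict[str, tuple[str, float]] = {}
    for col in columns:
        m = _HEADER_RE.match(str(col))
        if not m:
            raise ECGFormatError(f"cannot parse column header {col!r}")
        name, unit = m.group("name"), m.group("unit")
        canonical = _LEAD_BY_LOWER.get(name.lower())
        if canonical is None:
            raise ECGFormatError(f"unknown lead name {name!r} in header")
        scale = 1e-3 if unit in ("uV", "µV") else 1.0
        if canonical in (v[0] for v in out.values()):
            raise ECGFormatError(f"duplicate lead {canonical} in header")
        out[col] = (canonical, scale)
    return out


def read_ecg(
    path,
    format: str = "csv",
    fs: float = 500.0,
    subject_id: str | None = None,
    sex: str = "unknown",
    require_complete: bool = True,
) -> ECGSequence:
    """Read one ECG record.

    Parameters
    ----------
    path : path-like
        CSV file (wide dialect) or WFDB record name without extension.
    format : {"csv", "wfdb"}
    fs : float
        Sampling frequency for CSV input (WFDB records carry their own).
    require_complete : bool
        If true (default), all 12 canonical leads must be present.
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, float_precision="round_trip")
        mapping = _parse_header(df.columns)
        leads = {}
        for col, (canonical, scale) in mapping.items():
            series = pd.to_numeric(df[col], errors="coerce")
            if series.isna().any():
                bad = int(series.isna().idxmax())
                raise ECGFormatError(
                    f"lead {canonical}: non-numeric or missing value at row {bad}"
                )
            leads[canonical] = series.to_numpy(dtype=float) * scale
        seq = ECGSequence(
            leads=leads,
            fs=fs,
            subject_id=subject_id if subject_id is not None else path.stem,
            sex=sex,
        )
    elif format == "wfdb":
        try:
            import wfdb  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "reading WFDB records requires the optional 'wfdb' package"
            ) from exc
        record = wfdb.rdrecord(str(path))
        leads = {}
        for sig_name, column in zip(record.sig_name, record.p_signal.T):
            canonical = _LEAD_BY_LOWER.get(str(sig_name).strip().lower())
            if canonical is None:
                raise ECGFormatError(f"unmapped WFDB signal name {sig_name!r}")
            leads[canonical] = np.asarray(column, dtype=float)
        seq = ECGSequence(
            leads=leads,
            fs=float(record.fs),
            subject_id=subject_id if subject_id is not None else path.stem,
            sex=sex,
        )
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")
    if require_complete:
        seq.require_complete()
    return seq


def write_ecg(seq: ECGSequence, path) -> None:
    """Write a record as wide CSV (mV).  Round-trips bit-exactly."""
    # 17 significant digits guarantee float64 round-trip
    seq.to_frame().to_csv(path, index=False, float_format="%.17g")


def lvh_label(lvmi: float, sex: str) -> bool:
    """LVH call from the echocardiographic left-ventricular mass index.

    True iff LVMI strictly exceeds 115 g/m^2 (male) or 95 g/m^2 (female).
    """
    if not np.isfinite(lvmi) or lvmi < 0:
        raise ValueError(f"LVMI must be finite and non-negative, got {lvmi}")
    sex = str(sex).lower()
    if sex not in LVMI_THRESHOLDS:
        raise ValueError(f"LVH thresholds are undefined for sex {sex!r}")
    return lvmi > LVMI_THRESHOLDS[sex]


@dataclass(frozen=True)
class CaseLabel:
    """Ground-truth label for one subject."""

    subject_id: str
    lvh: bool
    lvmi: float | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.lvmi is not None and self.sex in LVMI_THRESHOLDS:
            expected = lvh_label(self.lvmi, self.sex)
            if expected != self.lvh:
                raise ValueError(
                    f"{self.subject_id}: lvh={self.lvh} inconsistent with "
                    f"LVMI {self.lvmi} g/m^2 for a {self.sex}"
                )


def write_labels(labels: list[CaseLabel], path) -> None:
    payload = [
        {"subject_id": l.subject_id, "lvh": l.lvh, "lvmi": l.lvmi, "sex": l.sex}
        for l in labels
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_labels(path) -> list[CaseLabel]:
    payload = json.loads(Path(path).read_text())
    return [CaseLabel(**entry) for entry in payload]
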