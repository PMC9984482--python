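"""Pulse-pressure series and short-term variability indices.

Blood pressure in acute ischemic stroke units is typically charted every
four hours for the first 72 h after admission. Pulse pressure (PP) is the
difference between systolic and diastolic pressure (SBP - DBP, mmHg); its
fluctuation over the monitoring window is summarized by six variability
indices in routine use in the blood-pressure-variability literature:

* ``sd``  — sample standard deviation of the PP readings (n-1 denominator);
* ``cv``  — coefficient of variation, 100 * sd / mean;
* ``sv``  — successive variation, the root-mean-square of the n-1
  differences between consecutive readings, with a 1/(n-1) inner factor;
* ``arv`` — average real variability, the plain mean of the absolute
  successive differences;
* ``dmm`` — range, maximum minus minimum reading in the window;
* ``msc`` — maximal successive change, the largest absolute difference
  between consecutive readings.

All operate on the observed reading sequence as recorded: no interpolation
or resampling onto the nominal 4-h grid is performed. Series with too few
readings or with long interruptions are screened out by
:func:`validate_sampling` before index computation, mirroring the exclusion
step of a clinical-registry analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BPReading",
    "BPSeries",
    "SamplingPolicy",
    "PPVIndexSet",
    "SamplingVerdict",
    "derive_pulse_pressure",
    "validate_sampling",
    "summarize_ppv",
    "load_bp_readings",
    "INDEX_NAMES",
]

#: Canonical order of the per-patient PPV summaries (mean first, as in
#: reporting tables).
INDEX_NAMES = ("mean_pp", "sd", "cv", "sv", "arv", "dmm", "msc")


@dataclass(frozen=True)
class BPReading:
    """One blood-pressure reading.

    Parameters
    ----------
    time_offset : float
        Hours since the start of the monitoring window (non-negative).
    sbp, dbp : float
        Systolic and diastolic pressure in mmHg. ``sbp`` must exceed
        ``dbp``; equality or inversion is physiologically invalid and is
        rejected at the point of use.
    """

    time_offset: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if self.time_offset < 0:
            raise ValueError(f"time_offset must be >= 0, got {self.time_offset}")
        if self.sbp <= 0 or self.dbp <= 0:
            raise ValueError("sbp and dbp must be positive")

    @property
    def pp(self) -> float:
        """Pulse pressure, SBP - DBP (mmHg)."""
        return self.sbp - self.dbp


@dataclass
class BPSeries:
    """Ordered blood-pressure readings for one patient.

    ``readings`` must be strictly increasing in ``time_offset``; ties within
    a patient are a data error. The nominal observation window defaults to
    72 h.
    """

    patient_id: str
    readings: list[BPReading]
    window_hours: float = 72.0

    def __post_init__(self) -> None:
        times = [r.time_offset for r in self.readings]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"patient {self.patient_id}: readings must be strictly "
                "increasing in time_offset (duplicate or unsorted times)"
            )
        if times and times[-1] > self.window_hours:
            raise ValueError(
                f"patient {self.patient_id}: reading at {times[-1]} h lies "
                f"outside the {self.window_hours} h window"
            )

    def __len__(self) -> int:
        return len(self.readings)


@dataclass(frozen=True)
class SamplingPolicy:
    """Completeness rules applied before a series enters the analysis.

    A series is accepted when the observed reading count reaches
    ``min_fraction`` of the expected slot count (window / interval + 1,
    inclusive endpoints) and no gap between successive readings exceeds
    ``max_gap_hours``. Defaults: 4-h nominal spacing, 80 % of the 19
    nominal slots, no gap over 8 h (twice the nominal interval).
    """

    interval_hours: float = 4.0
    min_fraction: float = 0.8
    max_gap_hours: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in (0, 1]")
        if self.max_gap_hours < self.interval_hours:
            raise ValueError("max_gap_hours must be >= interval_hours")

    def expected_count(self, window_hours: float) -> int:
        return int(round(window_hours / self.interval_hours)) + 1


@dataclass(frozen=True)
class SamplingVerdict:
    """Outcome of :func:`validate_sampling`; truthy iff accepted."""

    accepted: bool
    reason: str | None = None  # too_few_readings | gap_too_large

    def __bool__(self) -> bool:
        return self.accepted


@dataclass(frozen=True)
class PPVIndexSet:
    """The seven per-patient PP summaries (all mmHg except cv, in %)."""

    mean_pp: float
    sd: float
    cv: float
    sv: float
    arv: float
    dmm: float
    msc: float
    n_readings: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def derive_pulse_pressure(series: BPSeries) -> list[float]:
    """Return the ordered PP sequence (SBP - DBP per reading, mmHg).

    Raises
    ------
    ValueError
        If the series is empty, or any reading has sbp <= dbp (the message
        carries the offending reading index).
    """
    if not series.readings:
        raise ValueError(f"patient {series.patient_id}: empty series")
    pp = []
    for i, r in enumerate(series.readings):
        if r.sbp <= r.dbp:
            raise ValueError(
                f"patient {series.patient_id}: non-positive pulse pressure "
                f"at reading {i} (sbp={r.sbp}, dbp={r.dbp})"
            )
        pp.append(r.sbp - r.dbp)
    return pp


def validate_sampling(series: BPSeries, policy: SamplingPolicy | None = None) -> SamplingVerdict:
    """Check a series against a :class:`SamplingPolicy`.

    Returns a verdict rather than raising: rejection carries a
    machine-readable reason, ``too_few_readings`` or ``gap_too_large``.
    """
    if policy is None:
        policy = SamplingPolicy()
    expected = policy.expected_count(series.window_hours)
    if len(series) < policy.min_fraction * expected:
        return SamplingVerdict(False, "too_few_readings")
    times = [r.time_offset for r in series.readings]
    for t1, t2 in zip(times, times[1:]):
        if t2 - t1 > policy.max_gap_hours:
            return SamplingVerdict(False, "gap_too_large")
    return SamplingVerdict(True)


def summarize_ppv(pp: Sequence[float] | Iterable[float]) -> PPVIndexSet:
    """Compute the seven PP variability summaries of a reading sequence.

    With readings :math:`x_1, \\dots, x_n` and mean :math:`\\bar x`:

    .. math::

        SD &= \\sqrt{\\tfrac{1}{n-1}\\sum_{i=1}^{n}(x_i-\\bar x)^2} \\\\
        CV &= 100\\,SD/\\bar x \\\\
        SV &= \\sqrt{\\tfrac{1}{n-1}\\sum_{i=1}^{n-1}(x_{i+1}-x_i)^2} \\\\
        ARV &= \\tfrac{1}{n-1}\\sum_{i=1}^{n-1}|x_{i+1}-x_i| \\\\
        DMM &= \\max x - \\min x \\qquad
        MSC = \\max_i |x_{i+1}-x_i|

    Requires n >= 2 (successive differences need at least one pair) and a
    positive mean for CV.
    """
    x = np.asarray(list(pp), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 readings for variability indices, got {n}")
    mean = float(x.mean())
    sd = float(math.sqrt(np.sum((x - mean) ** 2) / (n - 1)))
    if mean <= 0:
        raise ValueError("mean pulse pressure must be positive for CV")
    cv = 100.0 * sd / mean
    d = np.diff(x)
    sv = float(math.sqrt(np.sum(d**2) / (n - 1)))
    arv = float(np.mean(np.abs(d)))
    dmm = float(x.max() - x.min())
    msc = float(np.max(np.abs(d)))
    return PPVIndexSet(mean, sd, cv, sv, arv, dmm, msc, n)


def load_bp_readings(path) -> dict[str, BPSeries]:
    """Read a BP readings CSV into per-patient :class:`BPSeries`.

    Expected header: ``patient_id,time_offset_hours,sbp,dbp``. Rows need
    not be pre-sorted; they are sorted per patient on load. Duplicate
    time offsets within a patient raise.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "time_offset_hours", "sbp", "dbp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"readings file missing columns: {sorted(missing)}")
    out: dict[str, BPSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_offset_hours")
        readings = [
            BPReading(float(t), float(s), float(d))
            for t, s, d in zip(grp["time_offset_hours"], grp["sbp"], grp["dbp"])
        ]
        out[str(pid)] = BPSeries(str(pid), readings)
    return out
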