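"""Endpoint calling against negative-control statistics.

A well is positive when its thresholded area exceeds the negative-control
mean by more than three standard deviations (the sigma multiplier is
configurable).  The endpoint of a serial-dilution row is the last positive
well; the first negative well follows it.  Sub-threshold wells *left* of the
last positive well are the high-concentration "edge effect" artifact — the
agglutinated mat rolls into small polygons with deceptively small areas —
and are flagged, never treated as the endpoint.

Negative controls must accompany every run: pellet areas drift with red
blood cell age, so thresholds are never reused across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientControlsError

__all__ = [
    "NegativeControlStats",
    "EndpointCall",
    "QcResult",
    "negative_stats",
    "call_endpoint",
    "qc_positive_control",
]


@dataclass(frozen=True)
class NegativeControlStats:
    """Mean/SD of negative-control well areas and the positivity threshold."""

    mean_area_mm2: float
    sd_area_mm2: float
    threshold_area_mm2: float
    n_wells: int
    sigma_multiplier: float = 3.0


@dataclass(frozen=True)
class EndpointCall:
    """Positivity vector and endpoint of one serial-dilution series.

    ``hau`` is ``dilution_factor ** (last_positive - 1)``; an all-negative
    series is censored: ``last_positive`` is None and ``hau_display`` reads
    "<1" rather than fabricating a zero.
    """

    positivity: tuple[bool, ...]
    artifact_wells: tuple[int, ...]
    last_positive: int | None
    first_negative: int | None
    hau: float | None
    dilution_factor: float
    threshold_area_mm2: float

    @property
    def hau_display(self) -> str:
        if self.hau is None:
            return f"<{self.dilution_factor ** 0:g}"
        return f"{self.hau:g}"


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: str | None = None


def negative_stats(
    neg_areas: Sequence[float], sigma_multiplier: float = 3.0
) -> NegativeControlStats:
    """Summarize the negative-control wells of the current run.

    Uses the sample standard deviation (n-1 denominator).  At least two
    wells are required; running a full PBS row is the norm.
    """
    areas = np.asarray(list(neg_areas), dtype=float)
    if areas.size < 2:
        raise InsufficientControlsError(
            "at least 2 negative-control wells are required per run"
        )
    if np.any(areas < 0) or not np.all(np.isfinite(areas)):
        raise ValueError("negative-control areas must be finite and non-negative")
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1))
    return NegativeControlStats(
        mean_area_mm2=mean,
        sd_area_mm2=sd,
        threshold_area_mm2=mean + sigma_multiplier * sd,
        n_wells=int(areas.size),
        sigma_multiplier=sigma_multiplier,
    )


def call_endpoint(
    areas: Sequence[float],
    stats: NegativeControlStats,
    dilution_factor: float = 2.0,
) -> EndpointCall:
    """Call the endpoint of one ordered dilution series.

    A well is positive iff its area strictly exceeds the threshold ("above"
    the mean+3SD line; ties call negative).  The last positive well is the
    highest positive index; any sub-threshold well strictly left of it is an
    edge-effect artifact flag, excluded from endpoint determination.  Series
    spanning two plates are concatenated by well index before calling; this
    function is agnostic to plate boundaries.
    """
    a = np.asarray(list(areas), dtype=float)
    if a.size < 2:
        raise ValueError("a dilution series needs at least 2 wells")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("areas must be finite and non-negative")
    positive = a > stats.threshold_area_mm2
    pos_idx = np.flatnonzero(positive)
    if pos_idx.size == 0:
        last_pos: int | None = None
        first_neg: int | None = None
        hau: float | None = None
        artifacts: tuple[int, ...] = ()
    else:
        last_pos = int(pos_idx[-1]) + 1  # 1-based
        first_neg = last_pos + 1 if last_pos < a.size else None
        hau = float(dilution_factor) ** (last_pos - 1)
        artifacts = tuple(
            int(i) + 1 for i in range(last_pos - 1) if not positive[i]
        )
    return EndpointCall(
        positivity=tuple(bool(p) for p in positive),
        artifact_wells=artifacts,
        last_positive=last_pos,
        first_negative=first_neg,
        hau=hau,
        dilution_factor=float(dilution_factor),
        threshold_area_mm2=stats.threshold_area_mm2,
    )


def qc_positive_control(
    call: EndpointCall, expected_last_positive: int, tolerance_wells: int = 0
) -> QcResult:
    """Check the positive-control row against its expected endpoint.

    Failure to land the expected last-positive dilution (within tolerance)
    is grounds for repeating the assay.
    """
    if call.last_positive is None:
        return QcResult(False, "positive control produced no positive wells")
    if expected_last_positive < 1 or expected_last_positive > len(call.positivity):
        raise ValueError("expected_last_positive outside the series")
    off = abs(call.last_positive - expected_last_positive)
    if off <= tolerance_wells:
        return QcResult(True)
    return QcResult(
        False,
        f"last positive well {call.last_positive} differs from expected "
        f"{expected_last_positive} by {off} (> {tolerance_wells})",
    )


def _check_invariants(call: EndpointCall) -> None:  # pragma: no cover - debug aid
    if call.last_positive is not None and call.first_negative is not None:
        assert call.first_negative == call.last_positive + 1
    if call.last_positive is not None:
        assert all(w < call.last_positive for w in call.artifact_wells)
        assert not any(call.positivity[call.last_positive:])
    assert math.isfinite(call.threshold_area_mm2)
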