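"""Double-referencing preprocessing of raw sensorgrams.

A raw sample trace is corrected by first subtracting a buffer-blank
injection (removes baseline drift) and then a trace recorded on a
ligand-free reference surface (removes bulk refractive-index jumps), in that
order.  The two subtractions commute mathematically; the stated order is
recorded for auditability.  Finally the curve is re-zeroed at injection
start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ScheduleError
from .kinetics import Sensorgram

__all__ = ["ReferencedSeries", "double_reference"]

#: width of the pre-injection window averaged to re-zero a curve, seconds
ZEROING_WINDOW_S = 5.0


@dataclass
class ReferencedSeries:
    """A set of referenced curves at distinct concentrations, ready to fit."""

    curves: list[Sensorgram]
    blank_applied: bool = True
    surface_applied: bool = True
    processing_order: tuple[str, ...] = ("blank", "empty_surface", "zero")

    def __post_init__(self):
        concs = [c.concentration for c in self.curves]
        if len(set(concs)) != len(concs):
            raise ScheduleError(f"curve concentrations must be distinct, got {concs}")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)


def _interp_onto(target_time: np.ndarray, curve: Sensorgram) -> np.ndarray:
    if target_time[0] < curve.time[0] - 1e-9 or target_time[-1] > curve.time[-1] + 1e-9:
        raise AlignmentError(
            "time ranges do not overlap: target "
            f"[{target_time[0]}, {target_time[-1]}] vs curve "
            f"[{curve.time[0]}, {curve.time[-1]}]"
        )
    return np.interp(target_time, curve.time, curve.response)


def _check_schedule(sample: Sensorgram, other: Sensorgram, what: str) -> None:
    if sample.phase_marks is None or other.phase_marks is None:
        return
    tol = 1e-6
    if abs(sample.t_inject - other.t_inject) > tol or abs(
        (sample.t_dissoc_start or 0) - (other.t_dissoc_start or 0)
    ) > tol:
        raise ScheduleError(
            f"{what} schedule does not match sample: injection at "
            f"{other.t_inject} vs {sample.t_inject}, dissociation at "
            f"{other.t_dissoc_start} vs {sample.t_dissoc_start}"
        )


def zero_at_injection(curve: Sensorgram, window: float = ZEROING_WINDOW_S) -> Sensorgram:
    """Subtract the mean response over the ``window`` s before injection.

    Falls back to the response at injection start when no pre-injection
    samples exist.
    """
    t0 = curve.t_inject
    mask = (curve.time >= t0 - window) & (curve.time < t0)
    if mask.any():
        baseline = float(curve.response[mask].mean())
    else:
        i0 = curve.phase_marks[0] if curve.phase_marks else 0
        baseline = float(curve.response[i0])
    return Sensorgram(
        time=curve.time.copy(),
        response=curve.response - baseline,
        concentration=curve.concentration,
        phase_marks=curve.phase_marks,
        label=curve.label,
    )


def double_reference(
    sample: Sensorgram,
    blank: Sensorgram,
    empty_surface: Sensorgram,
    zeroing_window: float = ZEROING_WINDOW_S,
) -> Sensorgram:
    """Return ``(sample - blank) - empty_surface`` on the sample's time grid.

    The blank and reference-surface traces are linearly interpolated onto the
    sample grid; the result is re-zeroed at injection start.  Negative
    post-reference responses are retained (clipping would bias fits).

    Raises
    ------
    AlignmentError
        If a correction trace does not cover the sample's time range.
    ScheduleError
        If phase marks disagree between the curves.
    """
    _check_schedule(sample, blank, "blank")
    _check_schedule(sample, empty_surface, "empty surface")
    resp = sample.response - _interp_onto(sample.time, blank)
    resp = resp - _interp_onto(sample.time, empty_surface)
    out = Sensorgram(
        time=sample.time.copy(),
        response=resp,
        concentration=sample.concentration,
        phase_marks=sample.phase_marks,
        label=sample.label or "referenced",
    )
    return zero_at_injection(out, window=zeroing_window)


def reference_series(
    samples: list[Sensorgram],
    blank: Sensorgram,
    empty_surface: Sensorgram,
    zeroing_window: float = ZEROING_WINDOW_S,
) -> ReferencedSeries:
    """Double-reference every sample against a shared blank and reference trace."""
    curves = [
        double_reference(s, blank, empty_surface, zeroing_window) for s in samples
    ]
    return ReferencedSeries(curves=curves)
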