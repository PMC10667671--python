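"""Thermocline detection and mixing-period labelling.

A reservoir water column is stratified when a thermocline is present and
completely mixed when it is absent.  Following the common limnological
criterion, a thermocline exists wherever the vertical temperature gradient
exceeds 0.2 degC per metre.  Sampling visits are labelled ``before`` /
``mixing`` / ``after`` from the chronological presence/absence of a
thermocline: one contiguous absent run defines the complete-mixing period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

DEFAULT_GRADIENT_THRESHOLD = 0.2  # degC per metre

PERIODS = ("before", "mixing", "after")


class AmbiguousPeriodsError(ValueError):
    """More than one contiguous run of thermocline-absent visits.

    Carries the run-length encoding so the caller can decide how to
    resolve the ambiguity (e.g. merge runs or drop visits).
    """

    def __init__(self, runs: list[tuple[bool, int]]):
        self.runs = runs
        super().__init__(
            "expected a single contiguous run of thermocline-absent visits, "
            f"got run-length encoding {runs}"
        )


@dataclass(frozen=True)
class TemperatureProfile:
    """A single vertical temperature profile.

    Parameters
    ----------
    depths:
        Depths in metres, strictly increasing, positive.
    temperatures:
        Water temperature in degC, one per depth.
    """

    depths: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        temps = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "temperatures", temps)
        if depths.ndim != 1 or temps.ndim != 1 or depths.shape != temps.shape:
            raise ValueError("depths and temperatures must be 1-D and equal length")
        if depths.size < 2:
            raise ValueError("a profile needs at least two points")
        if np.any(depths <= 0):
            raise ValueError("depths must be positive")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if not (np.all(np.isfinite(depths)) and np.all(np.isfinite(temps))):
            raise ValueError("profile values must be finite")


def thermocline_depth(
    profile: TemperatureProfile,
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD,
) -> Optional[float]:
    """Depth of the thermocline, or ``None`` when the column is mixed.

    Scans successive depth pairs from the surface down and returns the
    deeper endpoint of the first pair whose absolute gradient
    ``|dT| / dz`` strictly exceeds ``gradient_threshold``.  The deeper
    endpoint is used so a single unambiguous boundary depth is reported.
    """
    dz = np.diff(profile.depths)
    grad = np.abs(np.diff(profile.temperatures)) / dz
    exceed = np.nonzero(grad > gradient_threshold)[0]
    if exceed.size == 0:
        return None
    return float(profile.depths[exceed[0] + 1])


def _run_length_encode(presence: Sequence[bool]) -> list[tuple[bool, int]]:
    runs: list[tuple[bool, int]] = []
    for p in presence:
        p = bool(p)
        if runs and runs[-1][0] == p:
            runs[-1] = (p, runs[-1][1] + 1)
        else:
            runs.append((p, 1))
    return runs


def label_periods(thermocline_present: Sequence[bool]) -> list[str]:
    """Label chronologically ordered visits as before / mixing / after.

    The single maximal run of thermocline-absent visits is the complete
    mixing period; thermocline-present visits preceding it are ``before``
    and those following it are ``after``.  All-present input is all
    ``before`` (no disturbance observed); all-absent is all ``mixing``.

    Raises
    ------
    AmbiguousPeriodsError
        If the absent visits form more than one contiguous run.
    """
    presence = [bool(p) for p in thermocline_present]
    if not presence:
        return []
    runs = _run_length_encode(presence)
    absent_runs = [r for r in runs if not r[0]]
    if len(absent_runs) == 0:
        return ["before"] * len(presence)
    if len(absent_runs) > 1:
        raise AmbiguousPeriodsError(runs)
    labels: list[str] = []
    seen_absent = False
    for value, length in runs:
        if not value:
            labels.extend(["mixing"] * length)
            seen_absent = True
        elif not seen_absent:
            labels.extend(["before"] * length)
        else:
            labels.extend(["after"] * length)
    return labels
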