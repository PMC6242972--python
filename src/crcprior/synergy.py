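"""Excess-over-Bliss scoring of drug-combination experiments.

Bliss independence predicts the combined inhibition of two independently
acting drugs as e = i_a + i_b - i_a * i_b, with per-drug inhibition
i = 1 - viability / 100 taken from the single-agent margins of a
checkerboard plate (row/column 0; the [0, 0] well is the vehicle control
at 100%). Excess over Bliss is observed minus expected inhibition: > 0
indicates synergy, < 0 antagonism. Viabilities above 100% are clamped to
100% before scoring. The same arithmetic applies to fixed-dose
time-course (confluency) data, where each condition's effect at a
timepoint is 1 - confluency / control, floored at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError

__all__ = [
    "Checkerboard",
    "BlissSurface",
    "clamp_viability",
    "excess_over_bliss",
    "eob_timecourse",
]


def clamp_viability(matrix) -> np.ndarray:
    """Replace viabilities above 100% by 100%; negative values are an
    upstream normalization bug and raise."""
    arr = np.asarray(matrix, dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative viability: upstream normalization bug")
    return np.minimum(arr, 100.0)


@dataclass
class Checkerboard:
    """Dose-by-dose % viability matrix.

    ``viability[i, j]`` is the combination of ``doses_a[i]`` and
    ``doses_b[j]``; row and column 0 are the single agents and the
    [0, 0] well is the vehicle control. Viability is clamped on
    construction.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = clamp_viability(self.viability)
        if self.viability.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValidationError(
                "viability matrix shape must be (len(doses_a), len(doses_b))"
            )
        if self.viability.shape[0] < 2 or self.viability.shape[1] < 2:
            raise ValidationError("missing single-agent margin row/column")
        for doses in (self.doses_a, self.doses_b):
            if len(doses) > 1 and not (np.diff(doses) > 0).all():
                raise ValidationError("doses must be ascending")


@dataclass
class BlissSurface:
    """Excess-over-Bliss values aligned with the checkerboard layout;
    single-agent margins are identically 0."""

    eob: np.ndarray


def excess_over_bliss(board: Checkerboard) -> BlissSurface:
    """Observed minus Bliss-expected inhibition for every well."""
    inhibition = 1.0 - board.viability / 100.0
    i_a = inhibition[:, 0][:, None]
    i_b = inhibition[0, :][None, :]
    expected = i_a + i_b - i_a * i_b
    return BlissSurface(eob=inhibition - expected)


def eob_timecourse(
    confluency_a,
    confluency_b,
    confluency_comb,
    confluency_ctrl,
    timepoints,
    timepoint,
) -> float:
    """Excess over Bliss at one timepoint of a fixed-dose time course.

    Each condition's effect is 1 - confluency / control at the timepoint,
    floored at 0 (growth above the control is treated as no inhibition).
    """
    timepoints = list(timepoints)
    series = {
        "a": np.asarray(confluency_a, dtype=float),
        "b": np.asarray(confluency_b, dtype=float),
        "comb": np.asarray(confluency_comb, dtype=float),
        "ctrl": np.asarray(confluency_ctrl, dtype=float),
    }
    for name, arr in series.items():
        if arr.shape != (len(timepoints),):
            raise ValidationError(f"condition {name!r} does not share the timepoints")
    if timepoint not in timepoints:
        raise ValidationError(f"timepoint {timepoint!r} absent from the series")
    t = timepoints.index(timepoint)
    ctrl = series["ctrl"][t]
    if ctrl <= 0:
        raise ValidationError("control confluency must be > 0 at the timepoint")
    effect = {
        name: max(0.0, 1.0 - series[name][t] / ctrl) for name in ("a", "b", "comb")
    }
    expected = effect["a"] + effect["b"] - effect["a"] * effect["b"]
    return effect["comb"] - expected
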