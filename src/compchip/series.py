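"""Per-locus ratio time-course containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LocusSeries", "ScaledLocusSeries", "DEFAULT_TIME_GRID"]

#: Default experimental induction time grid in minutes.
DEFAULT_TIME_GRID = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0)


@dataclass
class LocusSeries:
    """Background-normalized competitor/endogenous ratio time course at one locus.

    ``times`` are sorted unique minutes including t = 0; ``values`` are the
    normalized ratios, one per time (averaged over probes and replicates).
    """

    locus_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) and self.times[0] != 0.0:
            raise ValueError("series must include t = 0")


@dataclass
class ScaledLocusSeries:
    """Locus series scaled to the in-vivo occupancy-ratio boundary conditions.

    After background subtraction and scaling the values estimate
    theta_B / theta_A: ~0 at t = 0 and saturating at the induction curve's
    rho_inf.  ``boundary_ok`` records whether the t = 0 value is consistent
    with zero given the fit noise.
    """

    locus_id: str
    times: np.ndarray
    values: np.ndarray
    boundary_ok: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
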