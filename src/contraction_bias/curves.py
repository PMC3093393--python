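"""Containers for binned response curves and slope estimates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ResponseCurve:
    """Fraction of 'first longer' reports against normalized log length.

    bin_centers
        Normalized log lengths in [0, 1] (mean normalized length per bin
        for empirical curves; the evaluation grid for model curves).
    fractions
        Per-bin fraction of 'first longer' reports.  Empirical curves lie
        in [0, 1]; bias-subtracted curves may leave that interval slightly.
    counts
        Per-bin trial counts (None for model-generated curves).
    sem
        Per-bin standard error of the mean across subjects, when the curve
        is a subject average.
    """

    bin_centers: np.ndarray
    fractions: np.ndarray
    counts: np.ndarray | None = None
    sem: np.ndarray | None = None

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.bin_centers.shape != self.fractions.shape:
            raise ValueError("bin_centers and fractions must have equal length")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.bin_centers.shape:
                raise ValueError("counts length mismatch")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)

    def __len__(self) -> int:
        return self.bin_centers.size

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fractions))


@dataclass
class SlopeEstimate:
    """OLS slope of a response curve with a basic bootstrap interval."""

    slope: float
    ci_lo: float
    ci_hi: float
    n_boot: int
    level: float = 0.95

    def __post_init__(self):
        if not self.ci_lo <= self.ci_hi:
            raise ValueError("interval endpoints out of order")

    def contains_zero(self) -> bool:
        return self.ci_lo <= 0.0 <= self.ci_hi
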