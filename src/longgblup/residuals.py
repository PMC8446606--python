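"""Residual-variance classes over the DAP axis.

The residual variance of a longitudinal trait typically changes with plant
age; the model therefore supports a distinct residual variance per DAP class.
The default class map groups each day with the nearest day on which ground
phenotypes were collected, giving 19 intervals on the 27-83 DAP axis.
(This grouping is sometimes counted as 18 classes; the map here carries 19
explicit intervals, and every parameter count uses the intervals actually
present.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ResidualClassMap", "DEFAULT_RESIDUAL_INTERVALS"]

#: default DAP grouping for biomass collection periods: closed [start, end]
DEFAULT_RESIDUAL_INTERVALS = (
    (27, 33), (34, 36), (37, 37), (38, 41), (42, 43), (44, 45), (46, 46),
    (47, 49), (50, 53), (54, 58), (59, 61), (62, 62), (63, 65), (66, 71),
    (72, 74), (75, 76), (77, 80), (81, 82), (83, 83),
)


@dataclass(frozen=True)
class ResidualClassMap:
    """Ordered, disjoint, covering DAP intervals -> residual-variance class."""

    intervals: tuple  # of (start, end) closed integer intervals

    def __post_init__(self):
        iv = tuple((int(a), int(b)) for a, b in self.intervals)
        if not iv:
            raise ValueError("at least one residual interval required")
        for a, b in iv:
            if a > b:
                raise ValueError(f"empty residual interval ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if a2 != b1 + 1:
                raise ValueError(
                    f"residual intervals must be contiguous and ordered; "
                    f"gap/overlap between ({a1},{b1}) and ({a2},{b2})"
                )
        object.__setattr__(self, "intervals", iv)

    @classmethod
    def default(cls) -> "ResidualClassMap":
        return cls(DEFAULT_RESIDUAL_INTERVALS)

    @classmethod
    def homogeneous(cls, dap_min: int, dap_max: int) -> "ResidualClassMap":
        return cls(((dap_min, dap_max),))

    @classmethod
    def from_boundaries(cls, dap_min: int, dap_max: int, boundaries) -> "ResidualClassMap":
        """Build intervals from interior boundary days (class starts)."""
        edges = [dap_min, *sorted(int(b) for b in boundaries), dap_max + 1]
        return cls(tuple((a, b - 1) for a, b in zip(edges, edges[1:])))

    @property
    def n_classes(self) -> int:
        return len(self.intervals)

    @property
    def dap_min(self) -> int:
        return self.intervals[0][0]

    @property
    def dap_max(self) -> int:
        return self.intervals[-1][1]

    def class_of(self, dap) -> np.ndarray:
        """Class index for each DAP value (vectorized)."""
        dap = np.atleast_1d(np.asarray(dap, dtype=int))
        starts = np.array([a for a, _ in self.intervals])
        if dap.min() < self.dap_min or dap.max() > self.dap_max:
            raise ValueError(
                f"DAP outside residual class range [{self.dap_min}, {self.dap_max}]"
            )
        return np.searchsorted(starts, dap, side="right") - 1

    def merged_for_records(self, daps: np.ndarray, min_records: int = 2) -> "ResidualClassMap":
        """Merge classes with fewer than ``min_records`` records rightward.

        Returns a possibly coarser map guaranteeing every class has enough
        records to estimate a variance; merges are logged as warnings.
        """
        cls_idx = self.class_of(daps)
        counts = np.bincount(cls_idx, minlength=self.n_classes)
        iv = [list(p) for p in self.intervals]
        i = 0
        while i < len(iv):
            if counts[i] < min_records and len(iv) > 1:
                j = i + 1 if i + 1 < len(iv) else i - 1
                lo, hi = min(i, j), max(i, j)
                logger.warning(
                    "residual class %s has %d record(s); merging with %s",
                    tuple(iv[lo] if counts[i] < min_records and lo == i else iv[hi]),
                    int(counts[i]), tuple(iv[j]),
                )
                iv[lo] = [iv[lo][0], iv[hi][1]]
                counts[lo] = counts[lo] + counts[hi]
                del iv[hi]
                counts = np.delete(counts, hi)
                i = 0  # re-scan from the left after a merge
            else:
                i += 1
        return ResidualClassMap(tuple(tuple(p) for p in iv))

    def to_config(self) -> list:
        return [list(p) for p in self.intervals]
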