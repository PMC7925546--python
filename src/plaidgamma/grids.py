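"""Contrast grids for plaid stimuli.

A plaid is the superposition of two orthogonal drifting gratings whose
contrasts (c1, c2) vary independently over a fixed set of levels.  The
default grid is the seven contrast levels used throughout the analysis:
0, 7, 10, 14, 21, 31 and 45 percent, represented as fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CONTRASTS = (0.0, 0.07, 0.10, 0.14, 0.21, 0.31, 0.45)


@dataclass(frozen=True)
class ContrastGrid:
    """Ordered contrast levels (fractions) shared by both plaid components.

    The first level must be 0 (blank component) and levels must be strictly
    increasing.  ``pairs()`` enumerates the full (c1, c2) condition grid in
    row-major order, rows indexing c1.
    """

    levels: tuple[float, ...] = field(default=DEFAULT_CONTRASTS)

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.ndim != 1 or lv.size < 2:
            raise ValueError("a contrast grid needs at least two levels")
        if lv[0] != 0.0:
            raise ValueError("the first contrast level must be 0")
        if not np.all(np.diff(lv) > 0):
            raise ValueError("contrast levels must be strictly increasing")
        object.__setattr__(self, "levels", tuple(float(v) for v in lv))

    @property
    def n(self) -> int:
        return len(self.levels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=float)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (C1, C2) meshgrids, rows indexing c1, columns c2."""
        lv = self.as_array()
        c2, c1 = np.meshgrid(lv, lv)
        return c1, c2
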