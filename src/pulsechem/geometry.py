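"""Phantom geometry: a rectangular water box behind an inert air gap.

The beam axis is z.  The water entry face sits at z = 0 (the air gap is
upstream, at negative z, and is chemically inert and lossless); x and y are
centred on the axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Phantom"]


@dataclass(frozen=True)
class Phantom:
    """Water box of size ``extents`` (m) with an upstream air gap (m)."""

    extents: tuple[float, float, float] = (200e-6, 200e-6, 400e-6)
    air_gap: float = 100e-6

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive containment test for (..., 3) points."""
        p = np.asarray(points)
        hx, hy = self.extents[0] / 2.0, self.extents[1] / 2.0
        return (
            (np.abs(p[..., 0]) <= hx)
            & (np.abs(p[..., 1]) <= hy)
            & (p[..., 2] >= 0.0)
            & (p[..., 2] <= self.extents[2])
        )

    def on_entry_face(self, point: np.ndarray, atol: float = 1e-12) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(
            abs(p[2]) <= atol
            and abs(p[0]) <= self.extents[0] / 2.0
            and abs(p[1]) <= self.extents[1] / 2.0
        )
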