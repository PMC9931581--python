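"""2D similarity transforms (scale, rotation, translation) in micron space.

Used both to simulate per-round stage drift and to express the recovered
registration between rounds or magnifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimilarityTransform"]


@dataclass(frozen=True)
class SimilarityTransform:
    """p' = scale * R(rotation) @ p + translation."""

    scale: float = 1.0
    rotation: float = 0.0  # radians, counterclockwise
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_mat = self.matrix
        t = -np.linalg.solve(inv_mat, np.asarray(self.translation))
        return SimilarityTransform(1.0 / self.scale, -self.rotation, (float(t[0]), float(t[1])))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        t = self.apply(np.asarray(other.translation))[0]
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation + other.rotation,
            (float(t[0]), float(t[1])),
        )

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.scale - 1.0) < 1e-12
            and abs(self.rotation) < 1e-12
            and abs(self.translation[0]) < 1e-12
            and abs(self.translation[1]) < 1e-12
        )
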