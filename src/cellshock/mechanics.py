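"""Decoupling of cell deformation into compression and shear.

Under coupled compression-shear loading, the projected-area change is
attributed entirely to the isotropic compression part: shear produces
local, area-preserving shape distortion.  The deformation gradient is
therefore split multiplicatively as

    F = s·I  ×  S,      S = [[1, γx], [γy, 1]] / sqrt(1 − γx·γy)

with det(S) = 1 by construction (admissible for γx·γy < 1), so any
polygon's area scales by exactly s² under F.  The compression factor is
recovered from an observed area ratio as s = sqrt(ζ); the shear part is
deliberately left unquantified — local shape statistics are too noisy
to support it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import as_polygon

__all__ = ["DeformationGradient", "apply_deformation", "decompose_area_change"]


@dataclass(frozen=True)
class DeformationGradient:
    """Isotropic stretch ``s`` plus unit-determinant shear (γx, γy)."""

    s: float = 1.0
    gamma_x: float = 0.0
    gamma_y: float = 0.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("compression factor s must be positive")
        if self.gamma_x * self.gamma_y >= 1.0:
            raise ValueError("degenerate shear: gamma_x * gamma_y must be < 1")

    @property
    def matrix(self) -> np.ndarray:
        gx, gy = self.gamma_x, self.gamma_y
        shear = np.array([[1.0, gx], [gy, 1.0]]) / np.sqrt(1.0 - gx * gy)
        return self.s * shear


def apply_deformation(polygon, grad: DeformationGradient) -> np.ndarray:
    """Map polygon vertices through F = s·I × S; area scales by s²."""
    v = as_polygon(polygon)
    return v @ grad.matrix.T


def decompose_area_change(A_initial: float, A_final: float) -> float:
    """Compression factor s = sqrt(A_final/A_initial) = sqrt(ζ).

    The shear component is unresolved by design: only the isotropic part
    is observable from the projected-area ratio.
    """
    if A_initial <= 0 or A_final <= 0:
        raise ValueError("areas must be positive")
    return float(np.sqrt(A_final / A_initial))
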