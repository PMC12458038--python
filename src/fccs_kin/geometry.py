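"""Confocal detection geometry for dual-color FCCS.

The detection profile of each channel is modelled as a 3D Gaussian,

    W(x, y, z) = exp(-2 (x^2 + y^2) / w_xy^2 - 2 z^2 / w_z^2),

with lateral 1/e^2 waist ``w_xy`` and axial 1/e^2 radius ``w_z``. The
effective (confocal) volume of this profile is the standard

    V_eff = pi^(3/2) * w_xy^2 * w_z,

which converts a molar concentration into the mean number of molecules
sampled by the correlation amplitude, N = c * N_A * V_eff.

Partial spectral overlap of the two detection volumes is summarised by a
single multiplicative efficiency ``f_ov`` in (0, 1]: the cross-correlation
amplitude of a double-labeled species is reduced by exactly this factor.
Geometrically the package realises f_ov as a lateral displacement ``d`` of
the red detection volume with f_ov = exp(-d^2 / w_xy^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AVOGADRO = 6.02214076e23  # mol^-1, exact (SI definition)

__all__ = [
    "AVOGADRO",
    "ConfocalGeometry",
    "effective_volume",
    "mean_particle_number",
]


@dataclass(frozen=True)
class ConfocalGeometry:
    """Two-channel 3D-Gaussian confocal geometry.

    Parameters
    ----------
    w_xy : float
        Lateral 1/e^2 beam-waist radius in meters. Must be positive.
    w_z : float
        Axial 1/e^2 radius in meters. Must satisfy ``w_z >= w_xy``.
    f_ov : float, optional
        Cross-channel volume-overlap efficiency in (0, 1]. Default 0.6,
        the ceiling measured with a double-labeled duplex control.
    """

    w_xy: float
    w_z: float
    f_ov: float = 0.6

    def __post_init__(self) -> None:
        if not (self.w_xy > 0):
            raise ValueError(f"invalid geometry: w_xy must be > 0, got {self.w_xy}")
        if not (self.w_z >= self.w_xy):
            raise ValueError(
                f"invalid geometry: w_z ({self.w_z}) must be >= w_xy ({self.w_xy})"
            )
        if not (0.0 < self.f_ov <= 1.0):
            raise ValueError(f"invalid geometry: f_ov must be in (0, 1], got {self.f_ov}")

    @property
    def s(self) -> float:
        """Structure parameter s = w_z / w_xy (dimensionless)."""
        return self.w_z / self.w_xy

    @property
    def red_channel_offset(self) -> float:
        """Lateral displacement d (m) of the red volume realising f_ov.

        Chosen such that exp(-d^2 / w_xy^2) == f_ov; zero for ideal overlap.
        """
        if self.f_ov >= 1.0:
            return 0.0
        return self.w_xy * math.sqrt(-math.log(self.f_ov))

    @property
    def overlap_dr2(self) -> float:
        """Squared normalised displacement d^2 / w_xy^2 = -ln(f_ov)."""
        return -math.log(self.f_ov)

    def effective_volume(self) -> float:
        """Effective confocal volume in liters."""
        return effective_volume(self)


def effective_volume(geometry: ConfocalGeometry) -> float:
    """Effective 3D-Gaussian confocal volume V_eff in liters.

    V_eff = pi^(3/2) * w_xy^2 * w_z (in m^3), converted to liters.
    """
    v_m3 = math.pi ** 1.5 * geometry.w_xy**2 * geometry.w_z
    return v_m3 * 1e3  # m^3 -> L


def mean_particle_number(c: float, geometry: ConfocalGeometry) -> float:
    """Expected number of molecules in V_eff at molar concentration ``c``.

    N = c * N_A * V_eff; linear in c.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c * AVOGADRO * effective_volume(geometry)
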