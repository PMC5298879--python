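"""Mechanical parameters of an elastic-rod axon.

The classical slender-rod relations link the section moduli to the material
constants:

    B = E * I           bending stiffness  (N m^2), I = pi r^4 / 4
    C = 2 * G * I       twist rigidity     (N m^2)
    G = E / (2 (1 + nu))
    k = E * A / L       axial (stretch) stiffness of the whole rod (N/m)

:class:`MechParams` stores the material constants in SI units and derives
B, C, G on construction unless they are given explicitly (measured values
may legitimately depart from the classical relations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: Default axon radius from TEM, meters.
DEFAULT_RADIUS_M = 100e-9


@dataclass
class MechParams:
    """Unit-checked record of rod mechanical parameters (SI).

    Parameters
    ----------
    E : float
        Young's modulus, Pa.
    nu : float
        Poisson's ratio (dimensionless). Biological materials may fall
        outside [0, 0.5]; set ``allow_exotic_nu=True`` to permit that.
    radius : float
        Rod radius, m.
    G, B, C : float, optional
        Shear modulus (Pa), bending stiffness (N m^2) and twist rigidity
        (N m^2). Derived from E, nu and the section moments when omitted.
    k : float, optional
        Axial stiffness expressed as a modulus in Pa (the energetic cost of
        stretch per unit strain per unit section area). Defaults to E.
    mu : float
        Dynamic viscosity of the surrounding medium, Pa s.
    """

    E: float
    nu: float = 0.5
    radius: float = DEFAULT_RADIUS_M
    G: float | None = None
    B: float | None = None
    C: float | None = None
    k: float | None = None
    mu: float = 1.0
    allow_exotic_nu: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise InvalidParameterError(f"Young's modulus must be > 0, got {self.E}")
        if self.radius <= 0:
            raise InvalidParameterError(f"radius must be > 0, got {self.radius}")
        if not self.allow_exotic_nu and not (0.0 <= self.nu <= 0.5):
            raise InvalidParameterError(
                f"Poisson's ratio {self.nu} outside [0, 0.5]; "
                "pass allow_exotic_nu=True to override"
            )
        if self.G is None:
            self.G = self.E / (2.0 * (1.0 + self.nu))
        if self.B is None:
            self.B = self.E * self.I
        if self.C is None:
            self.C = 2.0 * self.G * self.I
        if self.k is None:
            self.k = self.E
        for name in ("G", "B", "C", "k"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def I(self) -> float:  # noqa: E743 - second moment of area is called I
        """Second moment of area of the circular section, m^4."""
        return math.pi * self.radius**4 / 4.0

    @property
    def A(self) -> float:
        """Cross-sectional area, m^2."""
        return math.pi * self.radius**2

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def axial_stiffness_n_per_m(self, length_m: float) -> float:
        """Whole-rod axial stiffness k_rod = k*A/L in N/m."""
        if length_m <= 0:
            raise InvalidParameterError("length must be > 0")
        return self.k * self.A / length_m
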