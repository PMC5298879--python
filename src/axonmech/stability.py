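"""Analytic buckling criteria for a twisted rod under tension.

A straight rod clamped at both ends, carrying tension ``k`` (N) and twisted
at a uniform rate ``tau`` (rad/m), is linearly stable while the twist rate
stays below

    tau_crit = 2 sqrt(k B) / C

equivalently, at fixed twist rate the rod buckles once the tension drops
below

    k_crit = C^2 tau^2 / (4 B)

which is inversely proportional to the bending stiffness B. The two forms
are exact algebraic inverses of one another.
"""

from __future__ import annotations

import math

from .errors import InvalidParameterError


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise InvalidParameterError(f"{name} must be > 0, got {value}")


def critical_torque(k: float, B: float, C: float) -> float:
    """Critical twist rate tau_crit = 2 sqrt(k B)/C (rad/m).

    Parameters are the tension k (N), bending stiffness B (N m^2) and twist
    rigidity C (N m^2).
    """
    _check_positive(k=k, B=B, C=C)
    return 2.0 * math.sqrt(k * B) / C


def critical_stiffness(C: float, tau: float, B: float) -> float:
    """Critical tension k_crit = C^2 tau^2 / (4 B) (N).

    Below this tension a rod twisted at rate ``tau`` (rad/m) buckles.
    """
    _check_positive(C=C, tau=tau, B=B)
    return C**2 * tau**2 / (4.0 * B)
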