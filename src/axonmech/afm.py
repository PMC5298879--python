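"""Young's modulus from AFM force-indentation curves.

The contact between the AFM tip and the axon is modeled as a Hertzian
impact of an incompressible sphere (the tip, diameter ``d``) on a cylinder
(the axon), which gives a 3/2 power law

    F = a * delta^1.5

with the prefactor ``a`` the only free parameter of the fit. The apparent
Young's modulus follows from ``a`` with a finite-stiffness correction for
the cantilever material (E_b) and the elliptic-integral shape constants
K1, K2 of sphere-cylinder contact:

    E_axon = 9 a E_b K1^1.5 / (8 pi E_b sqrt(d K2) - 9 a K1^1.5)

The formula is implemented in exactly one place
(:func:`modulus_from_prefactor`); its validity is pinned by two checks that
do not depend on the algebraic grouping: the rigid-tip limit E_b -> inf
must reproduce the sphere-on-cylinder Hertz prefactor computed from the
effective contact radius, and E_axon must be monotone increasing in ``a``
on the physical branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NonPhysicalFitError,
    UnitError,
)


@dataclass
class TipModel:
    """Cantilever/tip constants for the sphere-on-cylinder contact model."""

    Eb: float = 3.5e9  # cantilever Young's modulus (Si), Pa
    K1: float = 1.71  # elliptic-integral constant
    K2: float = 0.89  # elliptic-integral constant
    tip_diameter: float = 60e-9  # m
    axon_radius: float = 100e-9  # m, from TEM

    def __post_init__(self) -> None:
        for name in ("Eb", "K1", "K2", "tip_diameter", "axon_radius"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"TipModel.{name} must be > 0")


@dataclass
class ForceCurve:
    """A force-indentation curve (SI), contact point at d = 0."""

    indentation: np.ndarray  # m, non-negative
    force: np.ndarray  # N
    spring_constant: float | None = None  # N/m metadata

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.shape != self.force.shape:
            raise InvalidParameterError("indentation and force must match in length")


def _check_modulus_unit(E_pa: float) -> None:
    # typical axon moduli are kPa-scale; a value of a few units is almost
    # certainly kPa passed where Pa was expected
    if 0 < E_pa < 50:
        raise UnitError(
            f"E = {E_pa} Pa is implausibly small; did you pass kPa instead of Pa?"
        )


def fit_prefactor(curve: ForceCurve, d_range: tuple[float, float] = (0.0, 100e-9)) -> float:
    """Least-squares prefactor of F = a d^1.5 over the indentation range.

    Linear in ``a``, so the estimate is the closed-form projection
    a = sum(F d^1.5) / sum(d^3).
    """
    lo, hi = d_range
    d = curve.indentation
    mask = (d >= lo) & (d <= hi)
    if mask.sum() < 10:
        raise InsufficientDataError(
            f"need >= 10 samples in d range [{lo}, {hi}], got {int(mask.sum())}"
        )
    dd = d[mask]
    ff = curve.force[mask]
    denom = float(np.sum(dd**3))
    if denom <= 0:
        raise InsufficientDataError("degenerate indentation range")
    a = float(np.sum(ff * dd**1.5) / denom)
    if a <= 0:
        raise NonPhysicalFitError(f"fitted prefactor a = {a:.3g} <= 0")
    return a


def _hertz_scale(tip: TipModel) -> float:
    """8 pi sqrt(d K2) / (9 K1^1.5): the geometry factor of the contact."""
    return 8.0 * math.pi * math.sqrt(tip.tip_diameter * tip.K2) / (9.0 * tip.K1**1.5)


def modulus_from_prefactor(a: float, tip: TipModel | None = None) -> float:
    """Apparent axon Young's modulus (Pa) from the fitted prefactor.

    Solves the compliance-series contact relation for the sample modulus;
    diverges as ``a`` approaches the rigid-sample limit.
    """
    tip = tip or TipModel()
    if a <= 0:
        raise InvalidParameterError(f"prefactor a must be > 0, got {a}")
    q = _hertz_scale(tip)  # a_rigid = q * E for a rigid tip
    denom = q * tip.Eb - a
    if denom <= 0:
        raise NonPhysicalFitError(
            f"prefactor a = {a:.3g} exceeds the rigid-sample bound {q * tip.Eb:.3g}; "
            "no physical modulus"
        )
    return a * tip.Eb / denom


def invert_modulus(E_axon: float, tip: TipModel | None = None) -> float:
    """Prefactor ``a`` such that :func:`modulus_from_prefactor` returns E_axon.

    The forward model for synthetic force-curve generation. In the
    compliant-sample limit E_axon << Eb, a ~ q * E_axon (linear).
    """
    tip = tip or TipModel()
    if E_axon <= 0:
        raise InvalidParameterError(f"E_axon must be > 0, got {E_axon}")
    _check_modulus_unit(E_axon)
    q = _hertz_scale(tip)
    return q * tip.Eb * E_axon / (tip.Eb + E_axon)


def rigid_tip_modulus(a: float, tip: TipModel | None = None) -> float:
    """Modulus in the rigid-tip limit E_b -> inf (pure sphere-on-cylinder)."""
    tip = tip or TipModel()
    return a / _hertz_scale(tip)


def fit_modulus(
    curve: ForceCurve,
    tip: TipModel | None = None,
    d_range: tuple[float, float] = (0.0, 100e-9),
) -> tuple[float, float]:
    """Convenience: (a, E_axon_Pa) from a force curve."""
    a = fit_prefactor(curve, d_range)
    return a, modulus_from_prefactor(a, tip)


def find_contact_point(
    indentation_raw: np.ndarray, force_raw: np.ndarray, n_baseline: int = 50, k_sigma: float = 3.0
) -> int:
    """Index where force first exceeds ``k_sigma`` baseline standard deviations.

    The baseline is estimated from the first ``n_baseline`` samples of the
    approach segment.
    """
    f = np.asarray(force_raw, dtype=float)
    base = f[:n_baseline]
    thresh = float(base.mean() + k_sigma * max(base.std(), 1e-30))
    above = np.nonzero(f > thresh)[0]
    if len(above) == 0:
        raise InsufficientDataError("force never exceeds the contact threshold")
    return int(above[0])
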