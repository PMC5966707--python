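"""Incompressible isotropic hyperelastic models under uniaxial tension.

Three two-parameter strain-energy densities widely used for soft tissue
and soft elastomers, written in terms of the first two Cauchy-Green
invariants (``I3 = 1`` under incompressibility):

* Mooney-Rivlin:      ``psi = c1 (I1 - 3) + c2 (I2 - 3)``
* Humphrey:           ``psi = c1 (exp(c2 (I1 - 3)) - 1)``
* Veronda-Westmann:   ``psi = c1 (exp(c2 (I1 - 3)) - 1) - c1 c2 / 2 (I2 - 3)``

For an incompressible uniaxial test with principal stretch ``lam`` the
transverse stretches are ``lam**-0.5``, the lateral Cauchy stresses vanish,
and the axial Cauchy stress has the closed forms

* Mooney-Rivlin:      ``sigma = 2 (lam^2 - 1/lam) (c1 + c2 / lam)``
* Humphrey:           ``sigma = 2 (lam^2 - 1/lam) c1 c2 exp(c2 (I1 - 3))``
* Veronda-Westmann:   ``sigma = 2 (lam^2 - 1/lam) c1 c2
  (exp(c2 (I1 - 3)) - 1 / (2 lam))``

all of which follow from ``sigma_1 = lam_1 d(psi)/d(lam_1) -
lam_3 d(psi)/d(lam_3)``; :func:`stress_from_energy_numeric` evaluates that
derivative route by central finite differences and serves as the module's
independent oracle for the closed forms.

Units: stresses and stress-like coefficients in MPa; stretches and the
exponential models' ``c2`` dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .reference import HUMPHREY, MOONEY_RIVLIN, VERONDA_WESTMANN

__all__ = [
    "MODELS",
    "MODEL_NAMES",
    "HyperelasticParams",
    "UniaxialKinematics",
    "uniaxial_kinematics",
    "strain_energy",
    "uniaxial_stress",
    "stress_from_energy_numeric",
    "initial_tangent_slope",
]

ArrayLike = Union[float, np.ndarray]

# Exponent cap that merely guards against IEEE overflow; the fitter bounds
# c2 well inside this.
_EXP_CAP = 500.0


def _safe_exp(x: ArrayLike) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > _EXP_CAP):
        raise OverflowError(
            f"exponent magnitude exceeds {_EXP_CAP}; c2 or stretch out of the "
            "supported range"
        )
    return np.exp(x)


def _energy_mr(I1, I2, c1, c2):
    return c1 * (I1 - 3.0) + c2 * (I2 - 3.0)


def _energy_humphrey(I1, I2, c1, c2):
    return c1 * (_safe_exp(c2 * (I1 - 3.0)) - 1.0)


def _energy_vw(I1, I2, c1, c2):
    return c1 * (_safe_exp(c2 * (I1 - 3.0)) - 1.0) - 0.5 * c1 * c2 * (I2 - 3.0)


def _prefactor(lam: np.ndarray) -> np.ndarray:
    return 2.0 * (lam**2 - 1.0 / lam)


def _stress_mr(lam, c1, c2):
    return _prefactor(lam) * (c1 + c2 / lam)


def _stress_humphrey(lam, c1, c2):
    i1 = lam**2 + 2.0 / lam
    return _prefactor(lam) * c1 * c2 * _safe_exp(c2 * (i1 - 3.0))


def _stress_vw(lam, c1, c2):
    i1 = lam**2 + 2.0 / lam
    return _prefactor(lam) * c1 * c2 * (_safe_exp(c2 * (i1 - 3.0)) - 0.5 / lam)


@dataclass(frozen=True)
class ModelDef:
    """A registered hyperelastic model.

    ``energy`` maps ``(I1, I2, c1, c2)`` to the strain-energy density;
    ``stress`` maps ``(lam, c1, c2)`` to the uniaxial Cauchy stress;
    ``initial_slope`` gives the analytic tangent stiffness
    ``d(sigma)/d(lam)`` at ``lam = 1``.
    """

    name: str
    energy: Callable[..., np.ndarray]
    stress: Callable[..., np.ndarray]
    initial_slope: Callable[[float, float], float]


MODELS: dict[str, ModelDef] = {
    MOONEY_RIVLIN: ModelDef(
        MOONEY_RIVLIN, _energy_mr, _stress_mr, lambda c1, c2: 6.0 * (c1 + c2)
    ),
    HUMPHREY: ModelDef(
        HUMPHREY, _energy_humphrey, _stress_humphrey, lambda c1, c2: 6.0 * c1 * c2
    ),
    VERONDA_WESTMANN: ModelDef(
        VERONDA_WESTMANN, _energy_vw, _stress_vw, lambda c1, c2: 3.0 * c1 * c2
    ),
}

MODEL_NAMES: tuple[str, ...] = tuple(MODELS)


@dataclass(frozen=True)
class HyperelasticParams:
    """Model identity plus its two material coefficients.

    ``c1`` is stress-like (MPa).  ``c2`` is stress-like for Mooney-Rivlin
    and dimensionless for Humphrey / Veronda-Westmann.  For the exponential
    models a negative product ``c1 * c2`` implies a negative small-strain
    stiffness; that is physically suspect but not forbidden (reported
    Mooney-Rivlin fits for such composites routinely violate the analogous
    ``c1 + c2 > 0`` condition), so it only warns.
    """

    model: str
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of {MODEL_NAMES}"
            )
        if self.model in (HUMPHREY, VERONDA_WESTMANN) and self.c1 * self.c2 < 0:
            warnings.warn(
                f"{self.model}: c1*c2 < 0 implies negative small-strain "
                "stiffness",
                stacklevel=2,
            )

    def stress(self, stretch: ArrayLike) -> np.ndarray:
        return uniaxial_stress(self, stretch)


@dataclass(frozen=True)
class UniaxialKinematics:
    """Principal stretches and invariants of an incompressible uniaxial state."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    I1: np.ndarray
    I2: np.ndarray
    I3: np.ndarray


def _check_stretch(stretch: ArrayLike) -> np.ndarray:
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be strictly positive")
    return lam


def uniaxial_kinematics(stretch: ArrayLike) -> UniaxialKinematics:
    """Incompressible uniaxial kinematics for axial stretch ``lam``.

    Volume preservation forces the transverse stretches to ``lam**-0.5``,
    hence ``I1 = lam^2 + 2/lam``, ``I2 = 2 lam + 1/lam^2`` and ``I3 = 1``
    identically.
    """
    lam = _check_stretch(stretch)
    lat = lam**-0.5
    return UniaxialKinematics(
        lambda1=lam,
        lambda2=lat,
        lambda3=lat,
        I1=lam**2 + 2.0 / lam,
        I2=2.0 * lam + lam**-2,
        I3=np.ones_like(lam),
    )


def strain_energy(
    params: HyperelasticParams, kin: Union[UniaxialKinematics, ArrayLike]
) -> np.ndarray:
    """Strain-energy density (MPa) at the given state.

    Accepts either a :class:`UniaxialKinematics` or a bare stretch, which
    is promoted through :func:`uniaxial_kinematics`.  Zero at the reference
    state for every model.
    """
    if not isinstance(kin, UniaxialKinematics):
        kin = uniaxial_kinematics(kin)
    return MODELS[params.model].energy(kin.I1, kin.I2, params.c1, params.c2)


def uniaxial_stress(params: HyperelasticParams, stretch: ArrayLike) -> np.ndarray:
    """Closed-form uniaxial Cauchy stress (MPa) at stretch ``lam``."""
    lam = _check_stretch(stretch)
    return MODELS[params.model].stress(lam, params.c1, params.c2)


def _psi_of_stretches(
    params: HyperelasticParams, l1: np.ndarray, l2: np.ndarray, l3: np.ndarray
) -> np.ndarray:
    i1 = l1**2 + l2**2 + l3**2
    i2 = l1**2 * l2**2 + l2**2 * l3**2 + l3**2 * l1**2
    return MODELS[params.model].energy(i1, i2, params.c1, params.c2)


def stress_from_energy_numeric(
    params: HyperelasticParams, stretch: ArrayLike, step: float = 1e-5
) -> np.ndarray:
    """Uniaxial Cauchy stress by numeric differentiation of the energy.

    Evaluates ``sigma_1 = lam_1 d(psi)/d(lam_1) - lam_3 d(psi)/d(lam_3)``
    with central differences of ``psi(lam_1, lam_2, lam_3)`` (partials taken
    with the other stretches held fixed), then substitutes the constrained
    state ``lam_2 = lam_3 = lam_1**-0.5``.  Second-order accurate in
    ``step``; independent of the closed forms, so it acts as their oracle.
    """
    if step <= 0.0:
        raise ValueError("step must be positive")
    lam = _check_stretch(stretch)
    if np.any(lam <= step):
        raise ValueError("stretch must exceed the finite-difference step")
    lat = lam**-0.5
    h = step
    dpsi_dl1 = (
        _psi_of_stretches(params, lam + h, lat, lat)
        - _psi_of_stretches(params, lam - h, lat, lat)
    ) / (2.0 * h)
    dpsi_dl3 = (
        _psi_of_stretches(params, lam, lat, lat + h)
        - _psi_of_stretches(params, lam, lat, lat - h)
    ) / (2.0 * h)
    return lam * dpsi_dl1 - lat * dpsi_dl3


def initial_tangent_slope(params: HyperelasticParams) -> float:
    """Analytic ``d(sigma)/d(lam)`` at the reference state ``lam = 1``.

    ``6 (c1 + c2)`` for Mooney-Rivlin, ``6 c1 c2`` for Humphrey and
    ``3 c1 c2`` for Veronda-Westmann.
    """
    return float(MODELS[params.model].initial_slope(params.c1, params.c2))
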