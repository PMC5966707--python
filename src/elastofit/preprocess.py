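"""Seven-step reduction of an engineering curve to true stress vs stretch.

The protocol mirrors standard practice for soft-elastomer coupon tests:

1. trim the leading run of non-positive loads (initial slack);
2. trim everything after the yield point (taken as the global stress
   maximum — for soft coupons the post-peak load drop marks failure/slip);
3. shift the curve to start at the origin;
4. convert to true stress/strain:
   ``sigma_true = sigma_eng (1 + eps_eng)``, ``eps_true = ln(1 + eps_eng)``;
5. fit a cubic polynomial trendline (R² reported, warning below 0.99);
6. resample the trendline on a uniform strain grid (default interval 0.01,
   capped at strain 1 and at the observed data maximum — no extrapolation);
7. map strain to stretch, ``lam = 1 + eps``.

Steps 1-3 are idempotent.  The stretch map applies the linear relation to
the standardized true-strain axis; the kinematically exact alternative
``lam = exp(eps_true)`` is available via configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .specimen_io import EngineeringCurve, RawTensileCurve, SpecimenGeometry
from .specimen_io import engineering_stress_strain

__all__ = [
    "TrueCurve",
    "TrendlineModel",
    "StressStretchCurve",
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "EmptyCurveError",
    "trim_negative_loads",
    "trim_post_yield",
    "shift_to_origin",
    "to_true",
    "fit_cubic_trend",
    "resample_grid",
    "to_stretch",
    "postprocess_pipeline",
]

logger = logging.getLogger(__name__)


class EmptyCurveError(ValueError):
    """The reduction removed every sample."""


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class TrueCurve:
    """True stress (MPa) versus true (logarithmic) strain."""

    true_strain: np.ndarray
    true_stress: np.ndarray

    def __post_init__(self) -> None:
        strain = np.asarray(self.true_strain, dtype=float)
        stress = np.asarray(self.true_stress, dtype=float)
        object.__setattr__(self, "true_strain", strain)
        object.__setattr__(self, "true_stress", stress)
        if strain.ndim != 1 or strain.shape != stress.shape:
            raise ValueError("strain and stress must be equal-length 1-D series")
        if np.any(np.diff(strain) < 0):
            raise ValueError("true_strain must be nondecreasing")

    def __len__(self) -> int:
        return int(self.true_strain.size)


@dataclass(frozen=True)
class TrendlineModel:
    """Least-squares cubic of stress on strain, with its fit domain.

    ``coefficients`` are ascending powers (a0 + a1 e + a2 e² + a3 e³).
    ``r_squared`` is NaN when the stress variance is zero (degenerate fit).
    The domain bounds exist so that resampling never extrapolates.
    """

    coefficients: np.ndarray
    r_squared: float
    strain_min: float
    strain_max: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.size > 4:
            raise ValueError("trendline degree must be <= 3")

    def predict(self, strain: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(strain, dtype=float), self.coefficients
        )


@dataclass(frozen=True)
class StressStretchCurve:
    """Standardized true stress (MPa) on a stretch axis.

    ``interval`` records the uniform strain-grid spacing when the curve
    came from the resampling step; synthetic curves on arbitrary grids
    leave it None.
    """

    stretch: np.ndarray
    stress: np.ndarray
    interval: Optional[float] = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)
        if lam.ndim != 1 or lam.shape != sig.shape:
            raise ValueError("stretch and stress must be equal-length 1-D series")
        if np.any(lam <= 0):
            raise ValueError("stretch must be positive")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretch must be strictly increasing")

    def __len__(self) -> int:
        return int(self.stretch.size)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the reduction.

    ``grid_interval`` is the standardized strain spacing (0.01 by default),
    ``strain_max`` the upper strain bound (1.0, i.e. stretch up to 2),
    ``stretch_map`` either ``"linear"`` (lam = 1 + eps_true) or ``"exp"``
    (lam = exp(eps_true)), and ``r2_warn`` the trendline quality gate.
    """

    grid_interval: float = 0.01
    strain_max: float = 1.0
    stretch_map: str = "linear"
    r2_warn: float = 0.99

    def __post_init__(self) -> None:
        if self.grid_interval <= 0:
            raise ValueError("grid_interval must be > 0")
        if self.strain_max <= self.grid_interval:
            raise ValueError("strain_max must exceed grid_interval")
        if self.stretch_map not in ("linear", "exp"):
            raise ValueError("stretch_map must be 'linear' or 'exp'")


def trim_negative_loads(curve: EngineeringCurve) -> EngineeringCurve:
    """Drop the leading run of samples with non-positive stress.

    Only the initial slack region is removed; an interior dip to zero or
    below is kept but triggers a warning, since it usually indicates grip
    slip rather than slack.
    """
    stress = curve.eng_stress
    positive = stress > 0.0
    if not positive.any():
        raise EmptyCurveError("every sample has non-positive stress")
    first = int(np.argmax(positive))
    out = EngineeringCurve(curve.eng_strain[first:], curve.eng_stress[first:])
    if np.any(out.eng_stress <= 0.0):
        warnings.warn(
            "non-positive stresses remain after the leading trim (interior dip)",
            stacklevel=2,
        )
    return out


def trim_post_yield(curve: EngineeringCurve) -> EngineeringCurve:
    """Keep samples up to and including the global stress maximum.

    A monotonically rising curve is returned unchanged; ties resolve to
    the first occurrence of the maximum.
    """
    if len(curve) == 0:
        raise EmptyCurveError("empty curve")
    k = int(np.argmax(curve.eng_stress))
    return EngineeringCurve(curve.eng_strain[: k + 1], curve.eng_stress[: k + 1])


def shift_to_origin(curve: EngineeringCurve) -> EngineeringCurve:
    """Translate the curve so its first sample sits at (0, 0)."""
    if len(curve) == 0:
        raise EmptyCurveError("empty curve")
    return EngineeringCurve(
        curve.eng_strain - curve.eng_strain[0],
        curve.eng_stress - curve.eng_stress[0],
    )


def to_true(curve: EngineeringCurve) -> TrueCurve:
    """Convert to true stress and logarithmic strain.

    ``sigma_true = sigma_eng (1 + eps_eng)`` and
    ``eps_true = ln(1 + eps_eng)``; requires ``eps_eng > -1``.
    """
    if np.any(curve.eng_strain <= -1.0):
        raise ValueError("engineering strain must exceed -1")
    lam_eng = 1.0 + curve.eng_strain
    return TrueCurve(
        true_strain=np.log(lam_eng),
        true_stress=curve.eng_stress * lam_eng,
    )


def fit_cubic_trend(curve: TrueCurve) -> TrendlineModel:
    """Unconstrained least-squares cubic of true stress on true strain.

    R² is the ordinary coefficient of determination (mean-centered total
    sum of squares); it is NaN for zero-variance stress, and values below
    0.99 warn rather than fail.
    """
    strain = curve.true_strain
    stress = curve.true_stress
    if np.unique(strain).size < 4:
        raise np.linalg.LinAlgError(
            "cubic trendline needs at least 4 distinct strain values"
        )
    coef = np.polynomial.polynomial.polyfit(strain, stress, 3)
    pred = np.polynomial.polynomial.polyval(strain, coef)
    ss_res = float(np.sum((stress - pred) ** 2))
    ss_tot = float(np.sum((stress - stress.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant stress data: R² undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
        if r2 < 0.99:
            warnings.warn(
                f"cubic trendline R² = {r2:.4f} < 0.99; the reduction may be "
                "unreliable for this specimen",
                stacklevel=2,
            )
    return TrendlineModel(
        coefficients=coef,
        r_squared=r2,
        strain_min=float(strain.min()),
        strain_max=float(strain.max()),
    )


def resample_grid(
    trend: TrendlineModel, strain_max: float, interval: float = 0.01
) -> TrueCurve:
    """Evaluate the trendline on the uniform grid interval, 2·interval, ...

    The grid stops at ``min(strain_max, fitted-data maximum)``: the cubic
    is never evaluated beyond the strain range it was fitted on.
    """
    if not 0.0 < interval < strain_max:
        raise ValueError("need 0 < interval < strain_max")
    upper = min(strain_max, trend.strain_max)
    if upper < strain_max:
        logger.info(
            "grid truncated at observed strain maximum %.4g (< requested %.4g)",
            trend.strain_max,
            strain_max,
        )
    n = int(np.floor(upper / interval + 1e-9))
    if n < 1:
        raise EmptyCurveError("no grid nodes below the observed strain maximum")
    grid = interval * np.arange(1, n + 1)
    return TrueCurve(true_strain=grid, true_stress=trend.predict(grid))


def to_stretch(curve: TrueCurve, mode: str = "linear") -> StressStretchCurve:
    """Map the standardized strain axis to stretch.

    ``"linear"`` uses ``lam = 1 + eps`` (the conventional plotting map for
    these curves); ``"exp"`` uses the kinematically exact
    ``lam = exp(eps_true)``.  Stresses are carried over unchanged.
    """
    eps = curve.true_strain
    if mode == "linear":
        lam = 1.0 + eps
    elif mode == "exp":
        lam = np.exp(eps)
    else:
        raise ValueError("mode must be 'linear' or 'exp'")
    interval = None
    if eps.size >= 2:
        d = np.diff(eps)
        if np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            interval = float(d[0])
    return StressStretchCurve(stretch=lam, stress=curve.true_stress, interval=interval)


@dataclass
class PipelineResult:
    """Reduced curve plus the per-stage audit trail."""

    curve: StressStretchCurve
    trend: TrendlineModel
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def trendline_r2(self) -> float:
        return self.trend.r_squared


def postprocess_pipeline(
    raw: RawTensileCurve,
    geometry: SpecimenGeometry,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full seven-step reduction on one machine record.

    Returns the standardized stress-stretch curve together with the cubic
    trendline and the sample count after every stage; stage failures are
    re-raised as :class:`PipelineStageError` naming the stage.
    """
    counts: dict[str, int] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        if hasattr(out, "__len__"):
            counts[name] = len(out)
            logger.debug("stage %s: %d samples", name, len(out))
        return out

    eng = _stage("engineering_stress_strain", engineering_stress_strain, raw, geometry)
    eng = _stage("trim_negative_loads", trim_negative_loads, eng)
    eng = _stage("trim_post_yield", trim_post_yield, eng)
    eng = _stage("shift_to_origin", shift_to_origin, eng)
    true = _stage("to_true", to_true, eng)
    trend = _stage("fit_cubic_trend", fit_cubic_trend, true)
    std = _stage(
        "resample_grid", resample_grid, trend, config.strain_max, config.grid_interval
    )
    curve = _stage("to_stretch", to_stretch, std, config.stretch_map)
    return PipelineResult(curve=curve, trend=trend, stage_counts=counts)
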