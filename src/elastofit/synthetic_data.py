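"""Synthetic tensile specimens with known hyperelastic ground truth.

Every stage of the reduction-and-fitting pipeline is validated against
machine-style records generated here.  A synthetic record emulates what a
universal testing machine produces for a soft elastomer coupon pulled at
constant crosshead speed:

* an initial slack region with small negative loads (the specimen is not
  yet taut; the machine preload is below 0.1 N);
* a monotone loading ramp obtained by inverting the reduction exactly —
  the ground-truth model gives true stress on a stretch axis, which is
  mapped back to engineering stress/strain and then to load/extension via
  the specimen geometry;
* a post-yield tail of linearly decaying load (failure or grip slip);
* optional Gaussian load noise from a single seeded generator.

The composite-family generator interpolates Humphrey-model parameters
between a soft matrix anchor and a stiff fiber anchor.  The mixing rule is
an explicit synthetic stand-in, not a micromechanical claim: it exists so
that fixtures reproduce the qualitative orderings seen in real soft
fiber-reinforced composites (stiffening with fiber volume fraction,
longitudinal >= skewed >= transverse orientation, transverse response
nearly insensitive to fiber count) while staying inside the matrix-fiber
envelope by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .hyperelastic import HUMPHREY, HyperelasticParams, uniaxial_stress
from .preprocess import StressStretchCurve
from .reference import (
    COMPOSITE_FVF_LEVELS,
    ORIENTATIONS_DEG,
    REFERENCE_COEFFICIENTS,
)
from .specimen_io import RawTensileCurve, SpecimenGeometry, save_geometry, save_raw_tensile

__all__ = [
    "SyntheticSpecimenConfig",
    "SyntheticTruth",
    "CompositeFamilySpec",
    "generate_clean_curve",
    "generate_raw_specimen",
    "composite_params",
    "make_fixture_suite",
]

_MATRIX_ANCHOR = HyperelasticParams(HUMPHREY, *REFERENCE_COEFFICIENTS[0.00][HUMPHREY])
_FIBER_ANCHOR = HyperelasticParams(HUMPHREY, *REFERENCE_COEFFICIENTS[1.00][HUMPHREY])


def generate_clean_curve(
    params: HyperelasticParams, grid: np.ndarray
) -> StressStretchCurve:
    """Noise-free forward evaluation of the model on a stretch grid."""
    grid = np.asarray(grid, dtype=float)
    interval = None
    if grid.size >= 2:
        d = np.diff(grid)
        if np.allclose(d, d[0], rtol=1e-9, atol=1e-15):
            interval = float(d[0])
    return StressStretchCurve(
        stretch=grid, stress=uniaxial_stress(params, grid), interval=interval
    )


@dataclass(frozen=True)
class SyntheticSpecimenConfig:
    """Recipe for one machine-style record.

    ``noise_sd`` is the Gaussian load-noise scale as a fraction of the
    peak load; ``slack_points`` the number of pre-contact samples (loads
    strictly negative, bounded by ``preload`` which stays below the 0.1 N
    machine preload); ``yield_stretch`` the stretch at which the injected
    failure begins; ``sampling_rate`` the number of samples per mm of
    crosshead travel (25/mm corresponds to sampling at ten hertz at the
    0.4 mm/s crosshead speed these coupons are pulled at).
    """

    params: HyperelasticParams
    geometry: SpecimenGeometry
    noise_sd: float = 0.0
    slack_points: int = 5
    preload: float = 0.05
    yield_stretch: float = 2.0
    sampling_rate: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slack_points < 0:
            raise ValueError("slack_points must be >= 0")
        if not 0.0 < self.preload < 0.1:
            raise ValueError("preload must lie in (0, 0.1) N")
        if self.yield_stretch <= 1.0:
            raise ValueError("yield_stretch must exceed 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth sidecar written next to each synthetic record."""

    model: str
    c1: float
    c2: float
    slack_points: int
    post_yield_points: int
    yield_stretch: float
    noise_sd: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "c1": self.c1,
            "c2": self.c2,
            "slack_points": self.slack_points,
            "post_yield_points": self.post_yield_points,
            "yield_stretch": self.yield_stretch,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def generate_raw_specimen(
    config: SyntheticSpecimenConfig,
) -> tuple[RawTensileCurve, SyntheticTruth]:
    """Build a file-ready load/extension record plus its truth sidecar.

    The clean ramp inverts the reduction exactly: with true strain
    ``eps_true = lam - 1`` (the same stretch map the pipeline applies),
    engineering strain is ``exp(eps_true) - 1``, engineering stress is
    ``sigma_true / (1 + eps_eng)``, and geometry converts to load and
    extension.  Contact is placed half a sample before the first ramp
    point so that, at zero noise, the leading-trim stage removes exactly
    ``slack_points`` samples and the post-yield trim exactly the decay
    tail.
    """
    geom = config.geometry
    delta = 1.0 / config.sampling_rate
    s = config.slack_points
    contact = (s - 0.5) * delta

    # Loading ramp: extensions on the machine grid strictly past contact,
    # up to the extension where the true-stretch axis reaches yield.
    eps_eng_max = float(np.expm1(config.yield_stretch - 1.0))
    ext_yield = contact + eps_eng_max * geom.gauge_length
    k_max = int(np.floor((ext_yield - s * delta) / delta))
    if k_max < 3:
        raise ValueError(
            "geometry/sampling leave fewer than 4 ramp samples before yield"
        )
    ramp_ext = (s + np.arange(k_max + 1)) * delta
    eps_eng = (ramp_ext - contact) / geom.gauge_length
    lam_true = 1.0 + np.log1p(eps_eng)
    sigma_true = uniaxial_stress(config.params, lam_true)
    ramp_load = sigma_true / (1.0 + eps_eng) * geom.cross_section

    # Slack region: strictly negative loads inside (-preload, 0).
    slack_ext = np.arange(s) * delta
    slack_load = -config.preload * (s - np.arange(s)) / (s + 1.0)

    # Post-yield tail: linear decay over ~10% additional extension,
    # strictly below the peak and strictly decreasing.
    peak = float(ramp_load[-1])
    n_tail = max(3, int(round(0.1 * ramp_ext[-1] / delta)))
    tail_ext = ramp_ext[-1] + np.arange(1, n_tail + 1) * delta
    tail_load = peak * (1.0 - 0.7 * np.arange(1, n_tail + 1) / n_tail)

    ext = np.concatenate([slack_ext, ramp_ext, tail_ext])
    load = np.concatenate([slack_load, ramp_load, tail_load])
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        load = load + rng.normal(0.0, config.noise_sd * peak, size=load.size)

    truth = SyntheticTruth(
        model=config.params.model,
        c1=config.params.c1,
        c2=config.params.c2,
        slack_points=s,
        post_yield_points=n_tail,
        yield_stretch=config.yield_stretch,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return RawTensileCurve(extension=ext, load=load), truth


@dataclass(frozen=True)
class CompositeFamilySpec:
    """One member of the synthetic composite family.

    ``orientation`` is the fiber angle in degrees from the load axis;
    ``n_fibers`` and ``spacing`` (mm) act only as documented monotone
    knobs on the effective fiber volume fraction (more fibers stiffen,
    wider spacing softens); ``transverse_residual`` is the small fraction
    of fiber effect that survives at 90 degrees.
    """

    fvf: float
    orientation: float = 0.0
    n_fibers: int = 1
    spacing: float = 0.0
    matrix_params: HyperelasticParams = _MATRIX_ANCHOR
    fiber_params: HyperelasticParams = _FIBER_ANCHOR
    transverse_residual: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.fvf <= 1.0:
            raise ValueError("fvf must lie in [0, 1]")
        if not 0.0 <= self.orientation <= 90.0:
            raise ValueError("orientation must lie in [0, 90] degrees")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")
        if self.matrix_params.model != HUMPHREY or self.fiber_params.model != HUMPHREY:
            raise ValueError("family anchors must be Humphrey-model parameters")


_N_FIBER_GAIN = 0.08  # effective-FVF gain per extra fiber
_SPACING_LOSS = 0.02  # effective-FVF loss per mm of fiber spacing


def composite_params(spec: CompositeFamilySpec) -> HyperelasticParams:
    """Humphrey parameters for one synthetic composite.

    An effective fiber volume fraction
    ``f_eff = fvf * ((1 - eps_t) cos^4(theta) * S + eps_t)`` captures the
    orientation dependence (quartic in cos(theta), the leading uniaxial
    stiffness scaling of an off-axis fiber) with a small transverse
    residual ``eps_t``; ``S`` applies the fiber-count/spacing knobs and is
    1 at the single-fiber, zero-spacing default.  The initial tangent
    stiffness ``6 c1 c2`` is interpolated log-linearly between the anchors
    and ``c2`` linearly; ``c1`` follows.  Both interpolants are monotone
    in ``f_eff``, so family stresses increase pointwise with ``f_eff`` and
    every family curve lies inside the matrix-fiber envelope.
    """
    m, f = spec.matrix_params, spec.fiber_params
    eps_t = spec.transverse_residual
    cos4 = float(np.cos(np.radians(spec.orientation)) ** 4)
    s_knob = (1.0 + _N_FIBER_GAIN * (spec.n_fibers - 1)) / (
        1.0 + _SPACING_LOSS * spec.spacing
    )
    f_eff = float(np.clip(spec.fvf * ((1.0 - eps_t) * cos4 * s_knob + eps_t), 0.0, 1.0))
    mu_m = 6.0 * m.c1 * m.c2
    mu_f = 6.0 * f.c1 * f.c2
    if mu_m <= 0 or mu_f <= 0:
        raise ValueError("anchor initial stiffnesses must be positive")
    mu = mu_m ** (1.0 - f_eff) * mu_f**f_eff
    c2 = (1.0 - f_eff) * m.c2 + f_eff * f.c2
    c1 = mu / (6.0 * c2)
    return HyperelasticParams(HUMPHREY, c1, c2)


def _battery(seed: int, noise_sd: float) -> list[dict]:
    """The deterministic fixture battery: pure materials, an FVF sweep at
    longitudinal orientation, and an orientation sweep at mid FVF."""
    specs: list[dict] = []

    def add(sid, fvf, orientation, n_fibers, geometry):
        specs.append(
            {
                "id": sid,
                "family": CompositeFamilySpec(
                    fvf=fvf, orientation=orientation, n_fibers=n_fibers
                ),
                "geometry": geometry,
            }
        )

    matrix_geom = SpecimenGeometry(gauge_length=49.5, width=10.0, thickness=2.5)
    add("matrix", 0.0, 0.0, 1, matrix_geom)
    fiber_geom = SpecimenGeometry(
        gauge_length=30.0,
        width=10.0,
        thickness=3.0,
        fiber_volume=900.0,
        n_fibers=1,
    )
    add("fiber", 1.0, 0.0, 1, fiber_geom)
    for fvf in COMPOSITE_FVF_LEVELS:
        total = 30.0 * 10.0 * 3.0
        geom = SpecimenGeometry(
            gauge_length=30.0,
            width=10.0,
            thickness=3.0,
            fiber_volume=fvf * total,
            fiber_angle=0.0,
            n_fibers=1,
        )
        add(f"fvf{int(round(fvf * 100)):02d}", fvf, 0.0, 1, geom)
    for angle in ORIENTATIONS_DEG:
        total = 30.0 * 15.0 * 3.0
        geom = SpecimenGeometry(
            gauge_length=30.0,
            width=15.0,
            thickness=3.0,
            fiber_volume=0.35 * total,
            fiber_angle=angle,
            n_fibers=2,
        )
        add(f"angle{int(angle):02d}", 0.35, angle, 2, geom)
    for i, s in enumerate(specs):
        s["seed"] = seed * 1000 + i
        s["noise_sd"] = noise_sd
    return specs


def make_fixture_suite(
    out_dir: Union[str, Path], seed: int = 0, noise_sd: float = 0.0
) -> dict:
    """Write the deterministic fixture battery and return its manifest.

    For each specimen: a load/extension CSV, a geometry YAML sidecar and a
    ground-truth JSON sidecar; a ``manifest.json`` listing everything.
    Rerunning with the same seed reproduces the files byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for spec in _battery(seed, noise_sd):
        params = composite_params(spec["family"])
        config = SyntheticSpecimenConfig(
            params=params,
            geometry=spec["geometry"],
            noise_sd=spec["noise_sd"],
            seed=spec["seed"],
        )
        raw, truth = generate_raw_specimen(config)
        sid = spec["id"]
        csv_name = f"{sid}.csv"
        geom_name = f"{sid}.geometry.yaml"
        truth_name = f"{sid}.truth.json"
        save_raw_tensile(raw, out / csv_name)
        save_geometry(spec["geometry"], out / geom_name)
        with open(out / truth_name, "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        entries.append(
            {
                "id": sid,
                "csv": csv_name,
                "geometry": geom_name,
                "truth": truth_name,
                "fvf": spec["family"].fvf,
                "orientation": spec["family"].orientation,
            }
        )
    manifest = {"seed": seed, "noise_sd": noise_sd, "specimens": entries}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
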