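"""Reference hyperelastic coefficient sets for a soft-composite family.

These are published curve-fit coefficients for a silicone soft-composite
family (Shore 10 matrix, Shore 30A fibers) characterized in uniaxial
tension at seven fiber volume fractions (FVF), from pure matrix (0.00) to
pure fiber (1.00).  ``c1`` is stress-like and carries the units of the
fitted curves (MPa here); ``c2`` is stress-like for Mooney-Rivlin and
dimensionless for the two exponential models.

They serve two purposes inside this package:

* ground-truth targets for fitter parameter-recovery validation
  (generate a noiseless curve from a row, refit, compare);
* anchors for the synthetic composite family — the ``0.00`` and ``1.00``
  Humphrey rows bound the matrix/fiber behaviour that
  :mod:`elastofit.synthetic_data` interpolates between.
"""

from __future__ import annotations

MOONEY_RIVLIN = "mooney_rivlin"
HUMPHREY = "humphrey"
VERONDA_WESTMANN = "veronda_westmann"

#: FVF -> model -> (c1, c2).  MPa for stress-like coefficients.
REFERENCE_COEFFICIENTS: dict[float, dict[str, tuple[float, float]]] = {
    1.00: {
        MOONEY_RIVLIN: (5e-3, -5.5e-3),
        VERONDA_WESTMANN: (3.8e-3, 3.7e-1),
        HUMPHREY: (1.6e-3, 5.55e-1),
    },
    0.00: {
        MOONEY_RIVLIN: (2e-5, 5e-6),
        VERONDA_WESTMANN: (1e-4, 1.8e-1),
        HUMPHREY: (2e-2, 1e-3),
    },
    0.17: {
        MOONEY_RIVLIN: (5.6e-4, -6.1e-4),
        VERONDA_WESTMANN: (5.9e-4, 2.8e-1),
        HUMPHREY: (3.7e-4, 3.4e-1),
    },
    0.35: {
        MOONEY_RIVLIN: (1.2e-3, -1.3e-3),
        VERONDA_WESTMANN: (9e-4, 3.6e-1),
        HUMPHREY: (5.4e-4, 4.4e-1),
    },
    0.52: {
        MOONEY_RIVLIN: (2.4e-4, -9e-5),
        VERONDA_WESTMANN: (1.5e-3, 3.88e-1),
        HUMPHREY: (9e-4, 4.2e-1),
    },
    0.61: {
        MOONEY_RIVLIN: (3.4e-3, -3.9e-3),
        VERONDA_WESTMANN: (2.5e-3, 3.55e-1),
        HUMPHREY: (1.2e-3, 5e-1),
    },
    0.78: {
        MOONEY_RIVLIN: (3.8e-3, -4e-3),
        VERONDA_WESTMANN: (3e-3, 3.6e-1),
        HUMPHREY: (1.7e-3, 4.6e-1),
    },
}

#: Composite FVF levels that were physically realized (excludes the two
#: pure-material baselines).
COMPOSITE_FVF_LEVELS: tuple[float, ...] = (0.17, 0.35, 0.52, 0.61, 0.78)

#: Fiber orientations studied, degrees relative to the load axis.
ORIENTATIONS_DEG: tuple[float, ...] = (0.0, 45.0, 90.0)
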