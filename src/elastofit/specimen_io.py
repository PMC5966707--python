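"""Specimen geometry, raw tensile records, and engineering stress/strain.

Raw data are load-versus-crosshead-extension tables as exported by a
universal testing machine (MTS-style CSV), paired with per-specimen
geometry metadata (gauge dimensions, fiber content and orientation) in a
YAML or JSON sidecar.  Internal units are fixed: lengths in mm, forces in
N, stresses in MPa (= N/mm²); converters live at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpecimenGeometry",
    "RawTensileCurve",
    "EngineeringCurve",
    "CsvDialect",
    "compute_fvf",
    "engineering_stress_strain",
    "load_raw_tensile",
    "save_raw_tensile",
    "load_geometry",
    "save_geometry",
]

_LENGTH_FACTORS = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "um": 1e-3}
_FORCE_FACTORS = {"N": 1.0, "kN": 1000.0, "mN": 1e-3}


class ParseError(ValueError):
    """Raised when a raw tensile file cannot be interpreted."""


@dataclass(frozen=True)
class SpecimenGeometry:
    """Undeformed gauge-region geometry and fiber layout of one specimen.

    Lengths in mm, volumes in mm³, ``fiber_angle`` in degrees relative to
    the load axis (0 = longitudinal, 90 = transverse).
    """

    gauge_length: float
    width: float
    thickness: float
    fiber_volume: float = 0.0
    total_volume: Optional[float] = None
    fiber_angle: float = 0.0
    n_fibers: int = 0
    fiber_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("gauge_length", "width", "thickness"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.total_volume is None:
            object.__setattr__(
                self, "total_volume", self.gauge_length * self.width * self.thickness
            )
        if self.total_volume <= 0.0:
            raise ValueError("total_volume must be > 0")
        if not 0.0 <= self.fiber_volume <= self.total_volume:
            raise ValueError("fiber_volume must lie in [0, total_volume]")
        if not 0.0 <= self.fiber_angle <= 90.0:
            raise ValueError("fiber_angle must lie in [0, 90] degrees")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")

    @property
    def cross_section(self) -> float:
        """Initial (undeformed) cross-sectional area, mm²."""
        return self.width * self.thickness

    @property
    def fvf(self) -> float:
        return compute_fvf(self)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SpecimenGeometry":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


def compute_fvf(geometry: SpecimenGeometry) -> float:
    """Fiber volume fraction: embedded fiber volume over total specimen volume.

    Dimensionless, in [0, 1]; 0 is pure matrix and 1 pure fiber.  Scale
    invariant: multiplying both volumes by the same factor leaves it
    unchanged.
    """
    return geometry.fiber_volume / geometry.total_volume


@dataclass(frozen=True)
class RawTensileCurve:
    """Machine record: crosshead extension (mm) versus load (N).

    ``strain_rate`` is carried as metadata (mm/s crosshead speed).
    Extension must be nondecreasing and the two series equal length with
    at least 4 samples.
    """

    extension: np.ndarray
    load: np.ndarray
    strain_rate: float = 0.4

    def __post_init__(self) -> None:
        ext = np.asarray(self.extension, dtype=float)
        load = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "extension", ext)
        object.__setattr__(self, "load", load)
        if ext.ndim != 1 or load.ndim != 1 or ext.size != load.size:
            raise ValueError("extension and load must be equal-length 1-D series")
        if ext.size < 4:
            raise ValueError("a tensile record needs at least 4 samples")
        if not (np.isfinite(ext).all() and np.isfinite(load).all()):
            raise ValueError("non-finite values in tensile record")
        diffs = np.diff(ext)
        if np.any(diffs < 0):
            i = int(np.argmax(diffs < 0)) + 1
            raise ValueError(
                f"extension must be nondecreasing; first decrease at index {i}"
            )

    def __len__(self) -> int:
        return int(self.extension.size)


@dataclass(frozen=True)
class EngineeringCurve:
    """Engineering stress (MPa) versus engineering strain (dimensionless)."""

    eng_strain: np.ndarray
    eng_stress: np.ndarray

    def __post_init__(self) -> None:
        strain = np.asarray(self.eng_strain, dtype=float)
        stress = np.asarray(self.eng_stress, dtype=float)
        object.__setattr__(self, "eng_strain", strain)
        object.__setattr__(self, "eng_stress", stress)
        if strain.ndim != 1 or strain.shape != stress.shape:
            raise ValueError("strain and stress must be equal-length 1-D series")
        if np.any(np.diff(strain) < 0):
            raise ValueError("eng_strain must be nondecreasing")

    def __len__(self) -> int:
        return int(self.eng_strain.size)


@dataclass(frozen=True)
class CsvDialect:
    """How to read a raw tensile CSV.

    ``header='auto'`` sniffs a single leading header row; column names are
    matched case-insensitively against extension/displacement and
    load/force patterns, falling back to the first two columns.  Units are
    converted to mm and N on read.
    """

    sep: str = ","
    header: Union[str, int, None] = "auto"
    extension_col: Optional[Union[str, int]] = None
    load_col: Optional[Union[str, int]] = None
    extension_unit: str = "mm"
    load_unit: str = "N"


_EXT_PATTERNS = ("extension", "displacement", "disp", "crosshead", "ext")
_LOAD_PATTERNS = ("load", "force")


def _match_column(columns: list[str], patterns: tuple[str, ...]) -> Optional[str]:
    for pat in patterns:
        for col in columns:
            if pat in str(col).lower():
                return col
    return None


def load_raw_tensile(
    path: Union[str, Path], dialect: CsvDialect = CsvDialect()
) -> RawTensileCurve:
    """Read a load-versus-extension CSV into a validated record.

    Raises :class:`ParseError` for missing or non-numeric columns and
    ``ValueError`` (naming the first offending index) when the extension
    column is not nondecreasing.
    """
    path = Path(path)
    if dialect.header == "auto":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        fields = [f.strip() for f in first.split(dialect.sep)]

        def _numeric(tok: str) -> bool:
            try:
                float(tok)
                return True
            except ValueError:
                return False

        header = 0 if fields and not all(_numeric(f) for f in fields if f) else None
    else:
        header = dialect.header
    try:
        df = pd.read_csv(path, sep=dialect.sep, header=header)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least two columns, found {df.shape[1]}")

    def _pick(spec, patterns, default_pos):
        if spec is not None:
            if isinstance(spec, int):
                return df.columns[spec]
            if spec not in df.columns:
                raise ParseError(f"{path}: column {spec!r} not found")
            return spec
        if header is not None:
            found = _match_column(list(df.columns), patterns)
            if found is not None:
                return found
        return df.columns[default_pos]

    ext_col = _pick(dialect.extension_col, _EXT_PATTERNS, 0)
    load_col = _pick(dialect.load_col, _LOAD_PATTERNS, 1)
    ext = pd.to_numeric(df[ext_col], errors="coerce")
    load = pd.to_numeric(df[load_col], errors="coerce")
    if ext.isna().any() or load.isna().any():
        raise ParseError(f"{path}: non-numeric values in data columns")
    ext_mm = ext.to_numpy(float) * _LENGTH_FACTORS[dialect.extension_unit]
    load_n = load.to_numpy(float) * _FORCE_FACTORS[dialect.load_unit]
    return RawTensileCurve(extension=ext_mm, load=load_n)


def save_raw_tensile(curve: RawTensileCurve, path: Union[str, Path]) -> None:
    """Write a record with canonical column names (extension_mm, load_N)."""
    df = pd.DataFrame({"extension_mm": curve.extension, "load_N": curve.load})
    df.to_csv(path, index=False, float_format="%.9g")


def load_geometry(path: Union[str, Path]) -> SpecimenGeometry:
    """Read a YAML or JSON geometry sidecar (YAML is a JSON superset)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: geometry sidecar must be a mapping")
    return SpecimenGeometry.from_dict(data)


def save_geometry(geometry: SpecimenGeometry, path: Union[str, Path]) -> None:
    path = Path(path)
    data = geometry.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            yaml.safe_dump(data, fh, sort_keys=True)


def engineering_stress_strain(
    raw: RawTensileCurve, geometry: SpecimenGeometry
) -> EngineeringCurve:
    """Normalize a machine record by the undeformed specimen geometry.

    Engineering stress = load / (initial width x thickness), MPa;
    engineering strain = extension / gauge length.
    """
    area = geometry.cross_section
    if area <= 0.0:
        raise ValueError("cross-section area must be > 0")
    return EngineeringCurve(
        eng_strain=raw.extension / geometry.gauge_length,
        eng_stress=raw.load / area,
    )
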