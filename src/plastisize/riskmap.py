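"""Gridded plastic-ingestion risk index for zooplankton.

Classed density rasters (integer exponential classes) are linearised with
``y = 10^((E/C) x)``, the ingestible plastic size class is selected from the
allometric fit, and risk is the elementwise ratio of ingestible plastic
concentration to zooplankton density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .allometry import AllometricFit, predict_max_plastic
from .errors import InvalidGridError, InvalidParameterError, NoClassError

__all__ = [
    "SizeClass",
    "ClassSelection",
    "ClassGrid",
    "ConcentrationGrid",
    "RiskGrid",
    "PLASTIC_SIZE_CLASSES",
    "PLASTIC_N_CLASSES",
    "PLASTIC_MAX_EXPONENT",
    "ZOO_N_CLASSES",
    "ZOO_MAX_EXPONENT",
    "linearise_classes",
    "select_ingestible_class",
    "total_plastic",
    "risk_index",
    "generate_synthetic_grids",
    "write_grid",
    "read_class_grid",
    "read_concentration_grid",
    "read_size_classes",
    "write_size_classes",
    "invert_linearisation",
]

#: Published surface-plastic size classes (mm); upper bound None = unbounded.
PLASTIC_SIZE_CLASSES: tuple[tuple[float, float | None], ...] = (
    (0.33, 1.00),
    (1.00, 4.76),
    (4.76, 20.00),
    (20.00, None),
)

# Exponential-class legends: plastic counts span 1..10^6 over 8 classes,
# zooplankton density 1..10^2 over 5 classes.
PLASTIC_N_CLASSES = 8
PLASTIC_MAX_EXPONENT = 6.0
ZOO_N_CLASSES = 5
ZOO_MAX_EXPONENT = 2.0

PLASTIC_UNITS = "pieces km^-2"
ZOO_UNITS = "mg C m^-3"


@dataclass(frozen=True)
class SizeClass:
    """A plastic length bin; ``upper_mm=None`` means unbounded above."""

    lower_mm: float
    upper_mm: float | None

    def __post_init__(self):
        if self.lower_mm < 0:
            raise InvalidParameterError(f"lower_mm must be >= 0, got {self.lower_mm}")
        if self.upper_mm is not None and not self.upper_mm > self.lower_mm:
            raise InvalidParameterError(
                f"upper_mm must exceed lower_mm, got ({self.lower_mm}, {self.upper_mm})"
            )


@dataclass(frozen=True)
class ClassSelection:
    """Outcome of ingestible-class selection."""

    size_class: SizeClass
    predicted_mm: float
    buffer_mm: float | None  # upper bound minus prediction; None if unbounded


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise InvalidGridError(f"mask shape {mask.shape} != values shape {shape}")
    return mask


@dataclass(frozen=True)
class ClassGrid:
    """2-D raster of integer exponential-class indices with a missing mask."""

    values: np.ndarray
    n_classes: int
    max_exponent: float
    mask: np.ndarray | None = None
    units_note: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidGridError(f"values must be 2-D, got ndim={values.ndim}")
        if self.n_classes < 1:
            raise InvalidGridError(f"n_classes must be >= 1, got {self.n_classes}")
        mask = _as_mask(self.mask, values.shape)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        bad = np.argwhere(
            ~mask
            & ((self.values != np.floor(self.values))
               | (self.values < 0)
               | (self.values > self.n_classes))
        )
        if bad.size:
            r, c = bad[0]
            raise InvalidGridError(
                f"cell ({r}, {c}) holds {self.values[r, c]!r}: class values must "
                f"be integers in [0, {self.n_classes}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ConcentrationGrid:
    """2-D raster of linearised (non-negative real) concentrations."""

    values: np.ndarray
    units: str
    mask: np.ndarray | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidGridError(f"values must be 2-D, got ndim={values.ndim}")
        mask = _as_mask(self.mask, values.shape)
        if np.any(values[~mask] < 0):
            raise InvalidGridError("unmasked concentration values must be >= 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RiskGrid:
    """Elementwise plastic/zooplankton ratio; zero-density cells are masked."""

    values: np.ndarray
    units: str
    mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def linearise_classes(grid: ClassGrid) -> ConcentrationGrid:
    """Map class index x to concentration ``10^((E/C) x)``, preserving the mask."""
    factor = grid.max_exponent / grid.n_classes
    values = np.where(grid.mask, 0.0, 10.0 ** (factor * grid.values))
    return ConcentrationGrid(values=values, units=grid.units_note, mask=grid.mask.copy())


def select_ingestible_class(
    fit: AllometricFit,
    max_body_length_mm: float,
    classes: Sequence[SizeClass | tuple] = PLASTIC_SIZE_CLASSES,
) -> ClassSelection:
    """Pick the smallest size class whose upper bound covers the prediction.

    The point prediction of the maximum ingestible plastic length for the
    community's largest body length is computed, then the first class (bounds
    ascending, upper bounds closed) whose upper bound is >= that prediction is
    returned, together with the slack ("buffer") left to the bound.
    """
    norm = [c if isinstance(c, SizeClass) else SizeClass(*c) for c in classes]
    if not norm:
        raise InvalidParameterError("classes must be non-empty")
    predicted = predict_max_plastic(
        fit, max_body_length_mm, interval_kind=None
    ).point_mm
    for cls in norm:
        if cls.upper_mm is None:
            return ClassSelection(cls, predicted, None)
        if cls.upper_mm >= predicted:
            return ClassSelection(cls, predicted, cls.upper_mm - predicted)
    raise NoClassError(
        f"predicted ingestible length {predicted:.4g} mm exceeds the largest "
        "bounded class and no unbounded class exists"
    )


def total_plastic(grids: Sequence[ConcentrationGrid]) -> ConcentrationGrid:
    """Elementwise sum; a cell is masked only when masked in every input."""
    if not grids:
        raise InvalidGridError("total_plastic requires at least one grid")
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape:
            raise InvalidGridError(
                f"shape mismatch: {g.shape} vs {first.shape}"
            )
        if g.units != first.units:
            raise InvalidGridError(f"unit mismatch: {g.units!r} vs {first.units!r}")
    total = np.zeros(first.shape)
    all_masked = np.ones(first.shape, dtype=bool)
    for g in grids:
        total += np.where(g.mask, 0.0, g.values)
        all_masked &= g.mask
    return ConcentrationGrid(values=total, units=first.units, mask=all_masked)


def risk_index(
    plastic: ConcentrationGrid, zooplankton: ConcentrationGrid
) -> RiskGrid:
    """Plastic concentration over zooplankton density, cellwise.

    Cells masked in either input, or with zero zooplankton density, come out
    masked (no infinities are produced).
    """
    if plastic.shape != zooplankton.shape:
        raise InvalidGridError(
            f"shape mismatch: plastic {plastic.shape} vs "
            f"zooplankton {zooplankton.shape}"
        )
    mask = plastic.mask | zooplankton.mask | (zooplankton.values == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(mask, 0.0, plastic.values / np.where(mask, 1.0, zooplankton.values))
    units = f"({plastic.units}) per ({zooplankton.units})"
    return RiskGrid(values=values, units=units, mask=mask)


def generate_synthetic_grids(
    shape: tuple[int, int], seed: int = 0
) -> tuple[list[ClassGrid], ClassGrid]:
    """Reproducible random class grids: four plastic size-class grids plus one
    zooplankton grid, each with ~10% masked cells."""
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 1 or cols < 1:
        raise InvalidParameterError(f"shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    plastic_grids = []
    for _ in range(len(PLASTIC_SIZE_CLASSES)):
        values = rng.integers(0, PLASTIC_N_CLASSES + 1, size=(rows, cols))
        mask = rng.random((rows, cols)) < 0.1
        plastic_grids.append(
            ClassGrid(
                values=values.astype(float),
                n_classes=PLASTIC_N_CLASSES,
                max_exponent=PLASTIC_MAX_EXPONENT,
                mask=mask,
                units_note=PLASTIC_UNITS,
            )
        )
    zoo_values = rng.integers(0, ZOO_N_CLASSES + 1, size=(rows, cols))
    zoo_mask = rng.random((rows, cols)) < 0.1
    zoo_grid = ClassGrid(
        values=zoo_values.astype(float),
        n_classes=ZOO_N_CLASSES,
        max_exponent=ZOO_MAX_EXPONENT,
        mask=zoo_mask,
        units_note=ZOO_UNITS,
    )
    return plastic_grids, zoo_grid


# ---------------------------------------------------------------------------
# Delimited-text grid I/O: one raster row per line, tab-separated, NA = masked

def write_grid(grid: ClassGrid | ConcentrationGrid | RiskGrid, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in range(grid.values.shape[0]):
            cells = [
                "NA" if grid.mask[r, c] else repr(float(grid.values[r, c]))
                for c in range(grid.values.shape[1])
            ]
            fh.write("\t".join(cells) + "\n")


def _read_values(path) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise InvalidGridError(f"grid file {path} is empty")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InvalidGridError(f"grid file {path} has ragged rows")
    values = np.zeros((len(rows), width))
    mask = np.zeros((len(rows), width), dtype=bool)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell == "NA":
                mask[i, j] = True
            else:
                values[i, j] = float(cell)
    return values, mask


def read_class_grid(
    path, n_classes: int, max_exponent: float, units_note: str = ""
) -> ClassGrid:
    values, mask = _read_values(path)
    return ClassGrid(
        values=values,
        n_classes=n_classes,
        max_exponent=max_exponent,
        mask=mask,
        units_note=units_note,
    )


def read_concentration_grid(path, units: str = "") -> ConcentrationGrid:
    values, mask = _read_values(path)
    return ConcentrationGrid(values=values, units=units, mask=mask)


def write_size_classes(classes: Sequence[SizeClass], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lower_mm,upper_mm\n")
        for cls in classes:
            upper = "" if cls.upper_mm is None else repr(cls.upper_mm)
            fh.write(f"{cls.lower_mm!r},{upper}\n")


def read_size_classes(path) -> list[SizeClass]:
    classes = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header[:2] != ["lower_mm", "upper_mm"]:
            raise InvalidParameterError(
                f"size-class table must have columns lower_mm,upper_mm, got {header}"
            )
        for line in fh:
            line = line.strip()
            if not line:
                continue
            lower, _, upper = line.partition(",")
            classes.append(
                SizeClass(float(lower), float(upper) if upper else None)
            )
    return classes


def invert_linearisation(conc: ConcentrationGrid, n_classes: int, max_exponent: float) -> np.ndarray:
    """Recover class indices from a linearised grid: ``x = (C/E) log10(y)``."""
    factor = n_classes / max_exponent
    with np.errstate(divide="ignore"):
        return np.where(conc.mask, np.nan, factor * np.log10(np.where(conc.mask, 1.0, conc.values)))
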