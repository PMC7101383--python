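"""Synthetic taxon-record datasets for the ingestible-plastic allometry pipeline.

Generates per-taxon gut-content records (body length, largest/smallest
ingested plastic, metadata) with a known log10-log10 linear structure, so
every downstream stage can be exercised and calibrated without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidRecordError

__all__ = [
    "GeneratorConfig",
    "TaxonRecord",
    "RECORD_COLUMNS",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_HABITAT_MIX",
    "calibrate_noise_sd",
    "population_r2",
    "generate_taxa",
    "records_to_frame",
    "frame_to_records",
    "write_records",
    "read_records",
    "write_config",
    "read_config",
]

#: Canonical column order for the delimited-text taxon table.
RECORD_COLUMNS = [
    "taxon_id",
    "taxonomic_class",
    "habitat",
    "n_specimens",
    "body_length_mm",
    "max_plastic_mm",
    "min_plastic_mm",
    "depth_min_m",
    "depth_max_m",
    "latitude",
    "longitude",
    "microscope_used",
]

DEFAULT_CLASS_MIX: Mapping[str, float] = {
    "fish": 0.75,
    "mammal": 0.09,
    "invertebrate": 0.11,
    "reptile": 0.05,
}

# reported habitat percentages sum to 0.97; the remainder is folded into the
# largest category so the mix is a proper distribution
DEFAULT_HABITAT_MIX: Mapping[str, float] = {
    "marine": 0.45,
    "marine+brackish": 0.25,
    "marine+brackish+fresh": 0.05,
    "fresh+brackish": 0.02,
    "fresh": 0.23,
}

#: Observed body-length range of the collated dataset, mm (log10).
DEFAULT_BODY_LOG10_RANGE = (math.log10(9.00), math.log10(10340.0))

#: Published allometric coefficients (log10 mm scale).
DEFAULT_SLOPE = 0.9341
DEFAULT_INTERCEPT = -1.1200


def calibrate_noise_sd(
    target_r2: float,
    slope: float,
    body_log10_range: Sequence[float],
) -> float:
    """Gaussian noise sd (log10 mm) giving population R² = ``target_r2``.

    For a simple linear model with predictor uniform on ``[a, b]`` the signal
    variance is ``slope² (b−a)²/12``; inverting R² = signal/(signal+noise)
    yields ``sd = |slope| (b−a)/√12 · √((1−R²)/R²)``.
    """
    if not (0.0 < target_r2 <= 1.0):
        raise InvalidParameterError(
            f"target_r2 must be in (0, 1], got {target_r2!r}"
        )
    a, b = float(body_log10_range[0]), float(body_log10_range[1])
    if not a < b:
        raise InvalidParameterError(
            f"body_log10_range must satisfy lower < upper, got ({a}, {b})"
        )
    sd_x = (b - a) / math.sqrt(12.0)
    return abs(slope) * sd_x * math.sqrt((1.0 - target_r2) / target_r2)


def population_r2(
    noise_sd: float,
    slope: float,
    body_log10_range: Sequence[float],
) -> float:
    """Population R² implied by a noise sd under the log-uniform design.

    Inverse of :func:`calibrate_noise_sd`: R² = s²/(s² + σ²) with signal
    variance ``s² = slope² (b−a)²/12``.
    """
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    a, b = float(body_log10_range[0]), float(body_log10_range[1])
    if not a < b:
        raise InvalidParameterError(
            f"body_log10_range must satisfy lower < upper, got ({a}, {b})"
        )
    signal_var = slope**2 * (b - a) ** 2 / 12.0
    return signal_var / (signal_var + noise_sd**2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic taxon-record generator.

    ``noise_sd`` may be given directly or derived from ``target_r2`` (noise
    calibrated so the population R² of the max-plastic regression equals the
    target). ``min_plastic_*`` control the deliberately weak smallest-plastic
    relationship; its noise defaults to a calibration at R² = 0.10.
    """

    n_taxa: int = 65
    body_log10_range: tuple[float, float] = DEFAULT_BODY_LOG10_RANGE
    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float | None = None
    target_r2: float | None = 0.42
    min_plastic_slope: float = 0.3
    min_plastic_offset: float = -2.5
    min_plastic_noise_sd: float | None = None
    min_plastic_target_r2: float = 0.10
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    habitat_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_MIX)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise InvalidParameterError(f"n_taxa must be >= 3, got {self.n_taxa}")
        a, b = self.body_log10_range
        if not a < b:
            raise InvalidParameterError(
                f"body_log10_range lower must be < upper, got ({a}, {b})"
            )
        if self.noise_sd is None and self.target_r2 is None:
            raise InvalidParameterError("one of noise_sd / target_r2 is required")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name, mix in (("class_mix", self.class_mix), ("habitat_mix", self.habitat_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"{name} fractions must sum to 1 (got {total!r})"
                )
            if any(f < 0 for f in mix.values()):
                raise InvalidParameterError(f"{name} fractions must be >= 0")

    def resolved_noise_sd(self) -> float:
        """The max-plastic noise sd, calibrating from ``target_r2`` if needed."""
        if self.noise_sd is not None:
            return self.noise_sd
        return calibrate_noise_sd(self.target_r2, self.slope, self.body_log10_range)

    def resolved_min_noise_sd(self) -> float:
        if self.min_plastic_noise_sd is not None:
            return self.min_plastic_noise_sd
        return calibrate_noise_sd(
            self.min_plastic_target_r2, self.min_plastic_slope, self.body_log10_range
        )


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon's gut-content summary: the unit of analysis.

    ``max_plastic_mm`` is the longest plastic piece found in any surveyed
    specimen of the taxon; ``min_plastic_mm`` the shortest, where reported.
    """

    taxon_id: str
    taxonomic_class: str
    habitat: str
    n_specimens: int
    body_length_mm: float
    max_plastic_mm: float
    min_plastic_mm: float | None = None
    depth_min_m: float | None = None
    depth_max_m: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    microscope_used: bool | None = None

    def __post_init__(self):
        if not self.body_length_mm > 0:
            raise InvalidRecordError(
                f"record {self.taxon_id!r}: body_length_mm must be > 0, "
                f"got {self.body_length_mm}"
            )
        if not self.max_plastic_mm > 0:
            raise InvalidRecordError(
                f"record {self.taxon_id!r}: max_plastic_mm must be > 0, "
                f"got {self.max_plastic_mm}"
            )
        if self.min_plastic_mm is not None:
            if not 0 < self.min_plastic_mm <= self.max_plastic_mm:
                raise InvalidRecordError(
                    f"record {self.taxon_id!r}: min_plastic_mm must satisfy "
                    f"0 < min <= max, got min={self.min_plastic_mm}, "
                    f"max={self.max_plastic_mm}"
                )
        if self.n_specimens < 1:
            raise InvalidRecordError(
                f"record {self.taxon_id!r}: n_specimens must be >= 1, "
                f"got {self.n_specimens}"
            )


def _draw_categories(rng: np.random.Generator, mix: Mapping[str, float], n: int) -> np.ndarray:
    names = list(mix.keys())
    probs = np.asarray([mix[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(names, size=n, p=probs)


def generate_taxa(config: GeneratorConfig) -> list[TaxonRecord]:
    """Draw ``config.n_taxa`` synthetic taxon records.

    log10 body lengths are i.i.d. uniform on ``body_log10_range``;
    log10 max-plastic follows the configured line plus Gaussian noise; the
    smallest-plastic response follows its own (weaker) line and is swapped
    with max-plastic in the rare event it lands above it.  Identical configs
    (including seed) produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    a, b = config.body_log10_range

    x = rng.uniform(a, b, size=n)
    noise_sd = config.resolved_noise_sd()
    y_max = config.slope * x + config.intercept + rng.normal(0.0, 1.0, size=n) * noise_sd
    min_sd = config.resolved_min_noise_sd()
    y_min = (
        config.min_plastic_slope * x
        + config.min_plastic_offset
        + rng.normal(0.0, 1.0, size=n) * min_sd
    )
    # min <= max enforced by clamping min down to max; the max-plastic
    # response must keep its exact generating model (calibration and
    # parameter-recovery guarantees depend on it)
    y_min_final = np.minimum(y_min, y_max)
    y_max_final = y_max

    classes = _draw_categories(rng, config.class_mix, n)
    habitats = _draw_categories(rng, config.habitat_mix, n)
    n_specimens = rng.integers(1, 500, size=n)
    depth_min = np.round(rng.uniform(0.0, 50.0, size=n), 1)
    depth_max = depth_min + np.round(10.0 ** rng.uniform(0.5, 3.6, size=n), 1)
    latitude = np.round(rng.uniform(-60.0, 70.0, size=n), 4)
    longitude = np.round(rng.uniform(-180.0, 180.0, size=n), 4)
    microscope = rng.random(size=n) < 0.5
    has_min = rng.random(size=n) < 0.9
    has_depth = rng.random(size=n) < 0.8
    has_coords = rng.random(size=n) < 0.85

    records = []
    for i in range(n):
        records.append(
            TaxonRecord(
                taxon_id=f"taxon_{i + 1:04d}",
                taxonomic_class=str(classes[i]),
                habitat=str(habitats[i]),
                n_specimens=int(n_specimens[i]),
                body_length_mm=float(10.0 ** x[i]),
                max_plastic_mm=float(10.0 ** y_max_final[i]),
                min_plastic_mm=float(10.0 ** y_min_final[i]) if has_min[i] else None,
                depth_min_m=float(depth_min[i]) if has_depth[i] else None,
                depth_max_m=float(depth_max[i]) if has_depth[i] else None,
                latitude=float(latitude[i]) if has_coords[i] else None,
                longitude=float(longitude[i]) if has_coords[i] else None,
                microscope_used=bool(microscope[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Tabular I/O (comma-separated, header row, empty field = missing)

def records_to_frame(records: Sequence[TaxonRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "taxon_id": r.taxon_id,
                "taxonomic_class": r.taxonomic_class,
                "habitat": r.habitat,
                "n_specimens": r.n_specimens,
                "body_length_mm": r.body_length_mm,
                "max_plastic_mm": r.max_plastic_mm,
                "min_plastic_mm": r.min_plastic_mm,
                "depth_min_m": r.depth_min_m,
                "depth_max_m": r.depth_max_m,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "microscope_used": r.microscope_used,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def frame_to_records(
    frame: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> list[TaxonRecord]:
    """Convert a table to records; ``column_map`` renames foreign layouts."""
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in ("body_length_mm", "max_plastic_mm") if c not in frame.columns]
    if missing:
        raise InvalidRecordError(f"table is missing required columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        records.append(
            TaxonRecord(
                taxon_id=str(row.get("taxon_id", f"row_{i}")),
                taxonomic_class=str(row.get("taxonomic_class", "unknown")),
                habitat=str(row.get("habitat", "unknown")),
                n_specimens=int(row.get("n_specimens", 1) if not pd.isna(row.get("n_specimens", 1)) else 1),
                body_length_mm=float(row["body_length_mm"]),
                max_plastic_mm=float(row["max_plastic_mm"]),
                min_plastic_mm=_opt_float(row.get("min_plastic_mm")),
                depth_min_m=_opt_float(row.get("depth_min_m")),
                depth_max_m=_opt_float(row.get("depth_max_m")),
                latitude=_opt_float(row.get("latitude")),
                longitude=_opt_float(row.get("longitude")),
                microscope_used=_opt_bool(row.get("microscope_used")),
            )
        )
    return records


def write_records(records: Sequence[TaxonRecord], path) -> None:
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, lineterminator="\n")


def read_records(path, column_map: Mapping[str, str] | None = None) -> list[TaxonRecord]:
    frame = pd.read_csv(path)
    return frame_to_records(frame, column_map=column_map)


# ---------------------------------------------------------------------------
# Flat key=value config serialisation

def _format_mix(mix: Mapping[str, float]) -> str:
    return ",".join(f"{k}:{v!r}" for k, v in mix.items())


def _parse_mix(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in text.split(","):
        key, _, value = part.partition(":")
        out[key.strip()] = float(value)
    return out


def write_config(config: GeneratorConfig, path) -> None:
    lines = [
        f"n_taxa={config.n_taxa}",
        f"body_log10_lower={config.body_log10_range[0]!r}",
        f"body_log10_upper={config.body_log10_range[1]!r}",
        f"slope={config.slope!r}",
        f"intercept={config.intercept!r}",
        f"noise_sd={'' if config.noise_sd is None else repr(config.noise_sd)}",
        f"target_r2={'' if config.target_r2 is None else repr(config.target_r2)}",
        f"min_plastic_slope={config.min_plastic_slope!r}",
        f"min_plastic_offset={config.min_plastic_offset!r}",
        f"min_plastic_noise_sd={'' if config.min_plastic_noise_sd is None else repr(config.min_plastic_noise_sd)}",
        f"min_plastic_target_r2={config.min_plastic_target_r2!r}",
        f"class_mix={_format_mix(config.class_mix)}",
        f"habitat_mix={_format_mix(config.habitat_mix)}",
        f"seed={config.seed}",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_config(path) -> GeneratorConfig:
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()

    def opt_float(key):
        return float(kv[key]) if kv.get(key) else None

    return GeneratorConfig(
        n_taxa=int(kv["n_taxa"]),
        body_log10_range=(float(kv["body_log10_lower"]), float(kv["body_log10_upper"])),
        slope=float(kv["slope"]),
        intercept=float(kv["intercept"]),
        noise_sd=opt_float("noise_sd"),
        target_r2=opt_float("target_r2"),
        min_plastic_slope=float(kv["min_plastic_slope"]),
        min_plastic_offset=float(kv["min_plastic_offset"]),
        min_plastic_noise_sd=opt_float("min_plastic_noise_sd"),
        min_plastic_target_r2=float(kv["min_plastic_target_r2"]),
        class_mix=_parse_mix(kv["class_mix"]),
        habitat_mix=_parse_mix(kv["habitat_mix"]),
        seed=int(kv["seed"]),
    )
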