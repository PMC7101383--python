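"""Log10-log10 allometric regression of ingestible plastic length on body length.

All model arithmetic happens on the log10 scale; lengths are back-transformed
(base 10) only when results are reported in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    IntervalsUnavailableError,
    InvalidParameterError,
    InvalidRecordError,
)
from .synthetic_data import TaxonRecord

__all__ = [
    "AllometricFit",
    "PredictionResult",
    "ols_simple",
    "fit_loglog",
    "published_fit",
    "predict_max_plastic",
    "body_to_plastic_ratio",
    "write_fit",
    "read_fit",
    "round_half_up",
]

def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (reporting convention for worked values)."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


PUBLISHED_SLOPE = 0.9341
PUBLISHED_INTERCEPT = -1.1200
PUBLISHED_N = 65
PUBLISHED_R2 = 0.42
PUBLISHED_F = 46.06
PUBLISHED_P = 4.7e-09


@dataclass(frozen=True)
class AllometricFit:
    """A fitted (or externally supplied) simple regression on log10 scales.

    ``residual_sd``, ``mean_x`` and ``ss_x`` are the sufficient statistics
    for t-based intervals; they are ``None`` for fits imported from a report
    that prints only coefficients, in which case interval construction is
    refused rather than fabricated.
    """

    slope: float
    intercept: float
    n: int
    residual_sd: float | None
    mean_x: float | None
    ss_x: float | None
    r2: float
    f_stat: float
    p_value: float
    response: str = "max_plastic"

    @property
    def has_intervals(self) -> bool:
        return (
            self.residual_sd is not None
            and self.mean_x is not None
            and self.ss_x is not None
        )


@dataclass(frozen=True)
class PredictionResult:
    """A back-transformed point prediction with optional interval bounds."""

    body_length_mm: float
    point_mm: float
    lower_mm: float | None
    upper_mm: float | None
    level: float | None
    interval_kind: str  # "confidence", "prediction", or "point"


def ols_simple(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Closed-form simple OLS: returns a dict of estimates and diagnostics.

    This is the single regression engine reused by :func:`fit_loglog` and the
    pooled observed-vs-predicted regression in the validation module.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mean_x = float((w * x).sum() / wsum)
    mean_y = float((w * y).sum() / wsum)
    ss_x = float((w * (x - mean_x) ** 2).sum())
    if ss_x <= 0:
        raise InvalidParameterError("predictor has zero variance")
    s_xy = float((w * (x - mean_x) * (y - mean_y)).sum())
    slope = s_xy / ss_x
    intercept = mean_y - slope * mean_x
    resid = y - (slope * x + intercept)
    sse = float((w * resid**2).sum())
    ss_y = float((w * (y - mean_y) ** 2).sum())
    r2 = 1.0 - sse / ss_y if ss_y > 0 else 1.0
    residual_sd = math.sqrt(sse / (n - 2))
    if r2 < 1.0:
        f_stat = (n - 2) * r2 / (1.0 - r2)
        p_value = float(stats.f.sf(f_stat, 1, n - 2))
    else:
        f_stat = math.inf
        p_value = 0.0
    return {
        "slope": slope,
        "intercept": intercept,
        "n": n,
        "residual_sd": residual_sd,
        "mean_x": mean_x,
        "ss_x": ss_x,
        "r2": r2,
        "f_stat": f_stat,
        "p_value": p_value,
    }


def fit_loglog(
    records: Sequence[TaxonRecord],
    response: str = "max_plastic",
    weight_by_specimens: bool = False,
) -> AllometricFit:
    """Unweighted OLS of log10(response length) on log10(body length).

    Records missing the requested response are skipped; non-positive lengths
    are rejected with the offending record named.  ``weight_by_specimens``
    is off by default (point size in scatter displays does not imply a
    weighted fit).
    """
    if response not in ("max_plastic", "min_plastic"):
        raise InvalidParameterError(f"unknown response {response!r}")
    xs, ys, ws = [], [], []
    for r in records:
        value = r.max_plastic_mm if response == "max_plastic" else r.min_plastic_mm
        if value is None:
            continue
        if r.body_length_mm <= 0:
            raise InvalidRecordError(
                f"record {r.taxon_id!r}: non-positive body_length_mm "
                f"({r.body_length_mm})"
            )
        if value <= 0:
            raise InvalidRecordError(
                f"record {r.taxon_id!r}: non-positive {response} length ({value})"
            )
        xs.append(math.log10(r.body_length_mm))
        ys.append(math.log10(value))
        ws.append(float(r.n_specimens))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"need at least 3 usable records for response {response!r}, "
            f"got {len(xs)}"
        )
    est = ols_simple(
        np.asarray(xs), np.asarray(ys), np.asarray(ws) if weight_by_specimens else None
    )
    return AllometricFit(response=response, **est)


def published_fit() -> AllometricFit:
    """The canonical published allometric fit (coefficients as printed).

    Only reported quantities are carried; the interval sufficient statistics
    were never published, so ``has_intervals`` is False and interval requests
    raise rather than guess.
    """
    return AllometricFit(
        slope=PUBLISHED_SLOPE,
        intercept=PUBLISHED_INTERCEPT,
        n=PUBLISHED_N,
        residual_sd=None,
        mean_x=None,
        ss_x=None,
        r2=PUBLISHED_R2,
        f_stat=PUBLISHED_F,
        p_value=PUBLISHED_P,
        response="max_plastic",
    )


def _point_log10(fit: AllometricFit, body_length_mm: float) -> float:
    return fit.slope * math.log10(body_length_mm) + fit.intercept


def predict_max_plastic(
    fit: AllometricFit,
    body_length_mm: float,
    level: float = 0.95,
    interval_kind: str | None = "prediction",
) -> PredictionResult:
    """Predict the maximum ingestible plastic length (mm) for a body length.

    Intervals use the standard t-based simple-regression construction on the
    log10 scale — half-width ``t * s * sqrt(1/n + (x-x̄)²/SSx)`` for the mean
    (confidence), with an extra ``+1`` under the root for a new observation
    (prediction) — and are back-transformed endpoint-wise.  Pass
    ``interval_kind=None`` for a point-only prediction.
    """
    if body_length_mm <= 0:
        raise InvalidParameterError(
            f"body_length_mm must be > 0, got {body_length_mm}"
        )
    point_log10 = _point_log10(fit, body_length_mm)
    point_mm = 10.0**point_log10
    if interval_kind is None:
        return PredictionResult(body_length_mm, point_mm, None, None, None, "point")
    if interval_kind not in ("confidence", "prediction"):
        raise InvalidParameterError(f"unknown interval_kind {interval_kind!r}")
    if not (0.0 < level < 1.0):
        raise InvalidParameterError(f"level must be in (0, 1), got {level}")
    if not fit.has_intervals:
        raise IntervalsUnavailableError(
            "this fit carries no residual_sd/mean_x/ss_x; intervals cannot be "
            "constructed (point prediction available as .point_mm)",
            point_mm=point_mm,
        )
    x = math.log10(body_length_mm)
    t_crit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.n - 2)
    leverage = 1.0 / fit.n + (x - fit.mean_x) ** 2 / fit.ss_x
    if interval_kind == "prediction":
        leverage += 1.0
    half = t_crit * fit.residual_sd * math.sqrt(leverage)
    return PredictionResult(
        body_length_mm=body_length_mm,
        point_mm=point_mm,
        lower_mm=10.0 ** (point_log10 - half),
        upper_mm=10.0 ** (point_log10 + half),
        level=level,
        interval_kind=interval_kind,
    )


def body_to_plastic_ratio(fit: AllometricFit, body_length_mm: float) -> float:
    """Body length divided by the predicted maximum ingestible plastic length."""
    if body_length_mm <= 0:
        raise InvalidParameterError(
            f"body_length_mm must be > 0, got {body_length_mm}"
        )
    return 10.0 ** ((1.0 - fit.slope) * math.log10(body_length_mm) - fit.intercept)


# ---------------------------------------------------------------------------
# Flat text serialisation (keys = field names, one per line, "" = None)

def write_fit(fit: AllometricFit, path) -> None:
    fields = [
        ("slope", fit.slope),
        ("intercept", fit.intercept),
        ("n", fit.n),
        ("residual_sd", fit.residual_sd),
        ("mean_x", fit.mean_x),
        ("ss_x", fit.ss_x),
        ("r2", fit.r2),
        ("f_stat", fit.f_stat),
        ("p_value", fit.p_value),
        ("response", fit.response),
    ]
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in fields:
            fh.write(f"{key}={'' if value is None else value!r}\n".replace("'", ""))


def read_fit(path) -> AllometricFit:
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()

    def opt(key):
        return float(kv[key]) if kv.get(key) else None

    return AllometricFit(
        slope=float(kv["slope"]),
        intercept=float(kv["intercept"]),
        n=int(kv["n"]),
        residual_sd=opt("residual_sd"),
        mean_x=opt("mean_x"),
        ss_x=opt("ss_x"),
        r2=float(kv["r2"]),
        f_stat=float(kv["f_stat"]),
        p_value=float(kv["p_value"]),
        response=kv.get("response", "max_plastic"),
    )
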