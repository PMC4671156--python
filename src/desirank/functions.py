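"""Desirability mapping functions.

A desirability function maps a measured variable onto a 0-1 scale where 1 is
maximally desirable and 0 is unacceptable.  Five shapes cover most situations
in experimental biology -- high-is-good, low-is-good, central-is-good,
extremes-are-good, and categorical -- plus a smooth sigmoidal alternative to
the piecewise-linear monotone shapes.

All numeric functions follow the Derringer-Suich convention: outside the cut
points the desirability sits on a plateau (``des_min`` or ``des_max``), and
between cut points the value is interpolated linearly and raised to a
curvature exponent ``scale``.  ``scale=1`` gives straight lines; ``scale>1``
makes the function harder to satisfy, ``scale<1`` easier.

Conventions shared by every numeric mapping:

* a value exactly on a cut point takes the adjoining plateau value;
* degenerate coincident cut points produce a step function that is
  right-closed (``x >= cut`` takes the value of the large-``x`` side), so a
  ``p < 0.05``-style threshold behaves conventionally;
* missing inputs (NaN) yield missing desirabilities -- missingness is
  resolved later by weight renormalisation, never collapsed to 0, because 0
  means "observed and unacceptable";
* infinite inputs take the corresponding plateau value (log-ratio columns
  can legitimately contain +/-inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, UnknownCategoryError

__all__ = [
    "MonotoneSpec",
    "PlateauSpec",
    "CategoricalSpec",
    "SigmoidSpec",
    "d_high",
    "d_low",
    "d_central",
    "d_ends",
    "d_cat",
    "d_sigmoid",
    "desirability",
    "quantile_cuts",
]

ArrayLike = Union[float, np.ndarray, pd.Series, list, tuple]


def _check_unit_interval(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise InvalidSpecError(f"{name} must lie in [0, 1], got {value!r}")


def _is_deferred(value) -> bool:
    # placeholder cut points (resolved from the data distribution later,
    # e.g. pipeline.QuantileCut) are skipped by spec validation
    import numbers

    return not isinstance(value, numbers.Real)


def _check_finite(name: str, value) -> None:
    if _is_deferred(value):
        return
    if not math.isfinite(value):
        raise InvalidSpecError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MonotoneSpec:
    """Monotone (high-is-good or low-is-good) desirability shape.

    Parameters
    ----------
    cut1, cut2
        Lower and upper cut points in data units, ``cut1 <= cut2``.  Between
        them the desirability is interpolated; outside it is flat.
    des_min, des_max
        Desirability plateaus.  A non-zero ``des_min`` keeps undesirable
        features in the list (deprioritised) instead of removing them.
    scale
        Positive curvature exponent applied to the linear interpolation.
    direction
        ``"high"`` if large values are desirable, ``"low"`` if small ones are.
    """

    cut1: float
    cut2: float
    des_min: float = 0.0
    des_max: float = 1.0
    scale: float = 1.0
    direction: str = "high"

    def __post_init__(self) -> None:
        for name in ("cut1", "cut2"):
            _check_finite(name, getattr(self, name))
        if not (_is_deferred(self.cut1) or _is_deferred(self.cut2)):
            if self.cut1 > self.cut2:
                raise InvalidSpecError(
                    f"cut1 ({self.cut1}) must not exceed cut2 ({self.cut2})"
                )
        _check_unit_interval("des_min", self.des_min)
        _check_unit_interval("des_max", self.des_max)
        if self.des_min > self.des_max:
            raise InvalidSpecError("des_min must not exceed des_max")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise InvalidSpecError(f"scale must be positive, got {self.scale!r}")
        if self.direction not in ("high", "low"):
            raise InvalidSpecError(
                f"direction must be 'high' or 'low', got {self.direction!r}"
            )


@dataclass(frozen=True)
class PlateauSpec:
    """Four-cut shape for central-is-good or extremes-are-good criteria.

    ``cut1 <= cut2 <= cut3 <= cut4``.  For ``direction="central"`` the
    desirability rises from ``des_min`` to a ``des_max`` plateau between
    ``cut2`` and ``cut3`` and falls again; ``direction="ends"`` is the
    reflection (a trough in the middle, maximal desirability in the tails),
    the natural shape for bidirectional fold-changes.
    """

    cut1: float
    cut2: float
    cut3: float
    cut4: float
    des_min: float = 0.0
    des_max: float = 1.0
    scale: float = 1.0
    direction: str = "central"

    def __post_init__(self) -> None:
        cuts = (self.cut1, self.cut2, self.cut3, self.cut4)
        for i, c in enumerate(cuts, start=1):
            _check_finite(f"cut{i}", c)
        if not any(_is_deferred(c) for c in cuts):
            if not (self.cut1 <= self.cut2 <= self.cut3 <= self.cut4):
                raise InvalidSpecError(f"cut points must be ordered, got {cuts}")
        _check_unit_interval("des_min", self.des_min)
        _check_unit_interval("des_max", self.des_max)
        if self.des_min > self.des_max:
            raise InvalidSpecError("des_min must not exceed des_max")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise InvalidSpecError(f"scale must be positive, got {self.scale!r}")
        if self.direction not in ("central", "ends"):
            raise InvalidSpecError(
                f"direction must be 'central' or 'ends', got {self.direction!r}"
            )


@dataclass(frozen=True)
class CategoricalSpec:
    """Per-category desirabilities for a discrete variable.

    ``mapping`` assigns a desirability in [0, 1] to each category label;
    ``default`` is used for unmapped labels, or, if set to the string
    ``"error"``, unmapped labels raise :class:`UnknownCategoryError`.

    Labels are matched exactly first and by their string form second, so a
    0/1 integer column matches a mapping written with "0"/"1" keys (the
    typical round-trip through a YAML config).
    """

    mapping: Mapping[object, float]
    default: Union[float, str] = "error"
    _lookup: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.mapping:
            raise InvalidSpecError("categorical mapping must be non-empty")
        lookup: dict = {}
        for label, d in self.mapping.items():
            d = float(d)
            _check_unit_interval(f"mapping[{label!r}]", d)
            lookup[label] = d
            lookup.setdefault(str(label), d)
        if self.default != "error":
            _check_unit_interval("default", float(self.default))
        object.__setattr__(self, "_lookup", lookup)

    def lookup(self, label: object) -> float:
        if label is None or (isinstance(label, float) and math.isnan(label)):
            return math.nan
        if label in self._lookup:
            return self._lookup[label]
        key = str(label)
        if key in self._lookup:
            return self._lookup[key]
        if self.default == "error":
            raise UnknownCategoryError(
                f"category {label!r} has no desirability mapping"
            )
        return float(self.default)


@dataclass(frozen=True)
class SigmoidSpec:
    """Smooth monotone desirability curve.

    ``d(midpoint) = (des_min + des_max) / 2``; the sign of ``steepness`` sets
    the direction (positive: high values desirable) and its magnitude the
    slope at the midpoint.
    """

    midpoint: float
    steepness: float
    des_min: float = 0.0
    des_max: float = 1.0

    def __post_init__(self) -> None:
        _check_finite("midpoint", self.midpoint)
        if self.steepness == 0 or not math.isfinite(self.steepness):
            raise InvalidSpecError("steepness must be nonzero and finite")
        _check_unit_interval("des_min", self.des_min)
        _check_unit_interval("des_max", self.des_max)
        if self.des_min > self.des_max:
            raise InvalidSpecError("des_min must not exceed des_max")


def _asarray(x: ArrayLike) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return np.atleast_1d(arr), arr.ndim == 0


def _finish(d: np.ndarray, x: np.ndarray, scalar: bool):
    d = np.where(np.isnan(x), np.nan, d)
    return float(d[0]) if scalar else d


def _ramp(x: np.ndarray, lo: float, hi: float, dmin: float, dmax: float,
          scale: float) -> np.ndarray:
    # desirability ramp from dmin at `lo` to dmax at `hi`; only selected
    # where lo < x < hi, but computed densely -- warnings silenced.
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        frac = (x - lo) / (hi - lo)
        return dmin + (dmax - dmin) * np.power(frac, scale)


def d_high(x: ArrayLike, spec: MonotoneSpec) -> ArrayLike:
    """High values are desirable: ``des_min`` below ``cut1``, ``des_max``
    above ``cut2``, interpolated in between."""
    x, scalar = _asarray(x)
    rise = _ramp(x, spec.cut1, spec.cut2, spec.des_min, spec.des_max, spec.scale)
    d = np.select(
        [x < spec.cut1, x < spec.cut2],
        [spec.des_min, rise],
        default=spec.des_max,
    )
    return _finish(d, x, scalar)


def d_low(x: ArrayLike, spec: MonotoneSpec) -> ArrayLike:
    """Low values are desirable (mirror of :func:`d_high`): ``des_max`` below
    ``cut1``, ``des_min`` above ``cut2``."""
    x, scalar = _asarray(x)
    fall = _ramp(x, spec.cut2, spec.cut1, spec.des_min, spec.des_max, spec.scale)
    d = np.select(
        [x >= spec.cut2, x > spec.cut1],
        [spec.des_min, fall],
        default=spec.des_max,
    )
    return _finish(d, x, scalar)


def d_central(x: ArrayLike, spec: PlateauSpec) -> ArrayLike:
    """Central values are desirable: ``des_max`` plateau on [cut2, cut3],
    ``des_min`` outside [cut1, cut4]."""
    x, scalar = _asarray(x)
    rise = _ramp(x, spec.cut1, spec.cut2, spec.des_min, spec.des_max, spec.scale)
    fall = _ramp(x, spec.cut4, spec.cut3, spec.des_min, spec.des_max, spec.scale)
    d = np.select(
        [x < spec.cut1, x < spec.cut2, x < spec.cut3, x < spec.cut4],
        [spec.des_min, rise, spec.des_max, fall],
        default=spec.des_min,
    )
    return _finish(d, x, scalar)


def d_ends(x: ArrayLike, spec: PlateauSpec) -> ArrayLike:
    """Extreme values are desirable (reflection of :func:`d_central`):
    ``des_max`` outside [cut1, cut4], ``des_min`` trough on [cut2, cut3]."""
    x, scalar = _asarray(x)
    fall = _ramp(x, spec.cut2, spec.cut1, spec.des_min, spec.des_max, spec.scale)
    rise = _ramp(x, spec.cut3, spec.cut4, spec.des_min, spec.des_max, spec.scale)
    d = np.select(
        [x >= spec.cut4, x > spec.cut3, x >= spec.cut2, x > spec.cut1],
        [spec.des_max, rise, spec.des_min, fall],
        default=spec.des_max,
    )
    return _finish(d, x, scalar)


def d_cat(labels, spec: CategoricalSpec):
    """Map category labels to desirabilities.

    Accepts a scalar label, a sequence, or a pandas Series (returned as a
    float Series aligned to the input index).
    """
    if isinstance(labels, pd.Series):
        return labels.map(spec.lookup).astype(float)
    if isinstance(labels, (list, tuple, np.ndarray)):
        return np.array([spec.lookup(lab) for lab in labels], dtype=float)
    return spec.lookup(labels)


def d_sigmoid(x: ArrayLike, spec: SigmoidSpec) -> ArrayLike:
    """Smooth logistic desirability between ``des_min`` and ``des_max``."""
    x, scalar = _asarray(x)
    span = spec.des_max - spec.des_min
    with np.errstate(over="ignore"):
        d = spec.des_min + span / (1.0 + np.exp(-spec.steepness * (x - spec.midpoint)))
    return _finish(d, x, scalar)


_DISPATCH = {
    ("monotone", "high"): d_high,
    ("monotone", "low"): d_low,
    ("plateau", "central"): d_central,
    ("plateau", "ends"): d_ends,
}


def desirability(x, spec):
    """Apply any desirability spec, dispatching on its type and direction."""
    if isinstance(spec, MonotoneSpec):
        return _DISPATCH[("monotone", spec.direction)](x, spec)
    if isinstance(spec, PlateauSpec):
        return _DISPATCH[("plateau", spec.direction)](x, spec)
    if isinstance(spec, CategoricalSpec):
        return d_cat(x, spec)
    if isinstance(spec, SigmoidSpec):
        return d_sigmoid(x, spec)
    raise TypeError(f"not a desirability spec: {type(spec).__name__}")


def quantile_cuts(values, fractions) -> list[float]:
    """Convert distribution fractions into data-scale cut points.

    Helper for "the top q% gets maximum desirability"-style criteria: cut
    points are placed at the requested quantiles of ``values`` (NaNs are
    ignored).  No optimisation of cut points is performed.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise InvalidSpecError("cannot place quantile cuts: no finite values")
    return [float(np.quantile(arr, float(q))) for q in np.atleast_1d(fractions)]
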