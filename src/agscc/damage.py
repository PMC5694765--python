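"""Regional agricultural damage functions from welfare-change tables.

A CGE run produces, for each region and each global warming level (1, 2,
3 degC), a welfare change decomposed into a direct productivity effect, a
terms-of-trade effect, and an allocative-efficiency effect, whose sum is the
total equivalent variation.  This module validates that decomposition,
normalizes welfare by the value of production of the four modeled crops,
aggregates countries to the 16 aggregate regions, and fits each region's
damage function of global mean warming: either a piecewise-linear
interpolation through the 1/2/3 degC points with linear extrapolation beyond
3 degC, or a quadratic a*dT + b*dT^2 forced through the origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WELFARE_COLUMNS = (
    "region",
    "warming_C",
    "productivity",
    "terms_of_trade",
    "allocative",
    "total",
    "value_of_production",
)

WARMING_LEVELS = (1.0, 2.0, 3.0)


class DecompositionError(ValueError):
    """Welfare components do not add up to the reported total."""

    def __init__(self, failures: list, max_abs: float):
        self.failures = failures
        self.max_abs = max_abs
        super().__init__(
            f"welfare decomposition violated for {failures} "
            f"(max abs discrepancy {max_abs:.3g})"
        )


class WelfareTable:
    """Per-region welfare changes at 1/2/3 degC with their decomposition."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in WELFARE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"welfare table missing columns: {missing}")
        if len(table) == 0:
            raise ValueError("welfare table is empty")
        if (table["value_of_production"] <= 0).any():
            raise ValueError("value_of_production must be positive")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> list[str]:
        return list(pd.unique(self.table["region"]))

    @classmethod
    def from_csv(cls, path) -> "WelfareTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class DecompositionReport:
    ok: bool
    max_abs_discrepancy: float
    n_rows: int


def validate_decomposition(
    table: WelfareTable, rtol: float = 1e-6
) -> DecompositionReport:
    """Check productivity + terms-of-trade + allocative = total, per row.

    Discrepancies are judged relative to the row's total magnitude (with an
    absolute floor for near-zero totals).  Violations raise
    :class:`DecompositionError` naming the offending (region, level) rows.
    """
    df = table.table
    implied = df["productivity"] + df["terms_of_trade"] + df["allocative"]
    disc = (implied - df["total"]).abs()
    scale = df["total"].abs().clip(lower=1.0)
    bad = disc > rtol * scale
    max_abs = float(disc.max())
    if bad.any():
        failures = [
            (row["region"], float(row["warming_C"]))
            for _, row in df.loc[bad].iterrows()
        ]
        raise DecompositionError(failures, max_abs)
    return DecompositionReport(ok=True, max_abs_discrepancy=max_abs, n_rows=len(df))


def normalize_welfare(ev: float, value_of_production: float) -> float:
    """Welfare change as a fraction of the value of production of the crops."""
    if value_of_production <= 0:
        raise ValueError("value_of_production must be positive")
    return ev / value_of_production


@dataclass
class RegionMapping:
    """Country-to-region assignments with aggregation weights."""

    assignments: Mapping  # country -> region
    weights: Mapping | None = None  # country -> value of agricultural production

    def __post_init__(self):
        if self.weights is not None and any(w < 0 for w in self.weights.values()):
            raise ValueError("aggregation weights must be non-negative")

    def region_of(self, country) -> str:
        try:
            return self.assignments[country]
        except KeyError:
            raise KeyError(f"country {country!r} not in region mapping") from None


def aggregate_regions(country_values: Mapping, mapping: RegionMapping) -> pd.Series:
    """Sum currency-valued country entries into their regions.

    Equivalent variation (and normalizers) aggregate additively, so the
    result is order invariant and conserves the global total.
    """
    series = pd.Series(dict(country_values), dtype=float)
    unmapped = [c for c in series.index if c not in mapping.assignments]
    if unmapped:
        raise KeyError(f"countries not in region mapping: {unmapped}")
    regions = series.index.map(mapping.assignments.__getitem__)
    return series.groupby(regions).sum()


def aggregate_welfare_table(
    country_table: pd.DataFrame, mapping: RegionMapping
) -> WelfareTable:
    """Aggregate a country-level welfare table to regions.

    All components and the value-of-production normalizer sum within
    region before any re-normalization.
    """
    df = country_table.copy()
    unmapped = sorted(set(df["country"]) - set(mapping.assignments))
    if unmapped:
        raise KeyError(f"countries not in region mapping: {unmapped}")
    df["region"] = df["country"].map(mapping.assignments)
    agg = (
        df.groupby(["region", "warming_C"], as_index=False)[
            ["productivity", "terms_of_trade", "allocative", "total", "value_of_production"]
        ].sum()
    )
    return WelfareTable(agg)


@dataclass
class DamageFunction:
    """Welfare change (fraction of agricultural output value) vs global warming.

    ``piecewise_linear``: knots at 0 degC (value 0) and the 1/2/3 degC
    points, extended beyond 3 degC with the 2-to-3 degC segment slope.
    ``quadratic``: a*dT + b*dT^2 over the whole domain (the origin is
    imposed by construction unless an intercept was explicitly allowed).
    """

    region: str
    method: str  # "piecewise_linear" | "quadratic"
    knots: tuple = ()  # ((dT, value), ...) for the linear method
    coeffs: tuple = ()  # (a, b) or (c, a, b) for the quadratic method
    slope: float = 0.0  # extrapolation slope beyond the last knot

    def __call__(self, dT):
        return evaluate_damage(self, dT)

    def to_json(self, path=None) -> str:
        doc = {
            "region": self.region,
            "method": self.method,
            "knots": [list(k) for k in self.knots],
            "coeffs": list(self.coeffs),
            "slope": self.slope,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DamageFunction":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            region=doc["region"],
            method=doc["method"],
            knots=tuple(tuple(k) for k in doc["knots"]),
            coeffs=tuple(doc["coeffs"]),
            slope=doc["slope"],
        )


def build_damage_function(
    points: Mapping,
    method: str = "piecewise_linear",
    region: str = "",
    through_origin: bool = True,
) -> DamageFunction:
    """Fit a regional damage function through the 1/2/3 degC welfare points.

    ``points`` maps warming level (1, 2, 3) to the normalized welfare
    fraction.  The linear method interpolates exactly through the points and
    extrapolates at the final segment's slope; the quadratic method is a
    least-squares fit of a*dT + b*dT^2 through (0,0) and the three points
    (``through_origin=False`` adds an intercept, sacrificing d(0)=0).
    """
    try:
        vals = [float(points[lv]) for lv in (1, 2, 3)]
    except KeyError as e:
        raise ValueError(f"missing welfare point at {e.args[0]} degC") from None
    if method == "piecewise_linear":
        knots = ((0.0, 0.0), (1.0, vals[0]), (2.0, vals[1]), (3.0, vals[2]))
        return DamageFunction(
            region=region, method=method, knots=knots, slope=vals[2] - vals[1]
        )
    if method == "quadratic":
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0] + vals)
        if through_origin:
            X = np.column_stack([t, t**2])
        else:
            X = np.column_stack([np.ones_like(t), t, t**2])
        coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        return DamageFunction(region=region, method=method, coeffs=tuple(coefs))
    raise ValueError(f"unknown method {method!r}")


def evaluate_damage(df: DamageFunction, dT):
    """Evaluate a damage function at non-negative warming (vectorized)."""
    t = np.asarray(dT, dtype=float)
    if np.any(t < 0):
        raise ValueError("cooling (negative dT) is out of the damage-function domain")
    if df.method == "piecewise_linear":
        xs = np.array([k[0] for k in df.knots])
        ys = np.array([k[1] for k in df.knots])
        inside = np.interp(t, xs, ys)
        beyond = ys[-1] + df.slope * (t - xs[-1])
        out = np.where(t > xs[-1], beyond, inside)
    elif df.method == "quadratic":
        if len(df.coeffs) == 2:
            a, b = df.coeffs
            out = a * t + b * t**2
        else:
            c, a, b = df.coeffs
            out = c + a * t + b * t**2
    else:
        raise ValueError(f"unknown method {df.method!r}")
    return float(out) if out.ndim == 0 else out


def damage_functions_from_welfare(
    table: WelfareTable, method: str = "piecewise_linear"
) -> dict[str, DamageFunction]:
    """One damage function per region from a validated welfare table.

    Total equivalent variation is normalized by the region's value of
    production of the modeled crops at each warming level.
    """
    validate_decomposition(table)
    out = {}
    for region, grp in table.table.groupby("region"):
        points = {
            float(row["warming_C"]): normalize_welfare(
                row["total"], row["value_of_production"]
            )
            for _, row in grp.iterrows()
        }
        out[str(region)] = build_damage_function(points, method=method, region=str(region))
    return out
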