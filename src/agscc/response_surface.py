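"""Crop yield-climate response surface.

Estimates how yields of the four major food crops (maize, rice, wheat,
soybean) respond to changes in growing-season temperature, atmospheric CO2,
precipitation, and on-farm agronomic adaptation, from a meta-database of
published point estimates.  The model is a crop-specific quadratic in the
local temperature change, interacted with the baseline growing-season
temperature, plus a saturating CO2-fertilization term that differs between
the C3 crops (rice, wheat, soybean) and the C4 crop (maize), a linear
precipitation term, and an adaptation dummy with a temperature interaction.
There is no global intercept, so the no-adaptation response passes through
the origin: no climate change, no yield change.

Uncertainty is quantified by a block bootstrap that resamples whole studies
(or whole models), respecting correlation between point estimates that share
a source.

Predictions are "adjusted": the adaptation intercept -- the part of reported
adaptation benefit that would accrue even without warming -- is netted out,
and losses are floored at -99%.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

CROPS: tuple[str, ...] = ("maize", "rice", "wheat", "soybean")
C4_CROPS = frozenset({"maize"})

#: Modern CO2 reference concentration (ppm): all study CO2 perturbations are
#: re-expressed as changes relative to this value.
MODERN_CO2_PPM = 360.0

#: Default half-saturation constants (ppm) for the CO2 fertilization curve.
DEFAULT_A_C3 = 100.0
DEFAULT_A_C4 = 50.0

#: Floor applied to adjusted yield-change predictions (percent).
YIELD_FLOOR = -99.0

_TEMP_TERMS = ("dT", "dT2", "dT_tbar", "dT2_tbar")

#: Canonical column labels of the 21-column design matrix.
COEF_LABELS: tuple[str, ...] = tuple(
    f"{term}:{crop}" for crop in CROPS for term in _TEMP_TERMS
) + ("fco2_c3", "fco2_c4", "dP", "dT_adapt", "adapt")

REQUIRED_COLUMNS = (
    "study_id",
    "crop",
    "country",
    "delta_yield_pct",
    "delta_T_C",
    "co2_ppm",
    "co2_baseline_ppm",
    "delta_precip_pct",
    "adapt",
    "baseline_T_C",
)


class RankDeficientDesignError(ValueError):
    """Design matrix does not identify all coefficients."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; unidentifiable columns: "
            + ", ".join(self.columns)
        )


def crop_pathway(crop: str) -> str:
    """Photosynthetic pathway of a crop: maize is C4, the others C3."""
    if crop not in CROPS:
        raise ValueError(f"unknown crop {crop!r}; expected one of {CROPS}")
    return "C4" if crop in C4_CROPS else "C3"


def adjust_co2_delta(co2_scenario, co2_baseline=MODERN_CO2_PPM):
    """Re-express a study's CO2 perturbation against the 360 ppm modern baseline.

    A study reporting scenario concentration ``S`` is treated as
    ``dCO2 = S - 360`` regardless of the baseline the study itself used;
    scenarios below 360 ppm are clamped to zero change (the fertilization
    curve is one-sided and the estimation sample is forward-looking).

    Both arguments accept scalars or arrays; concentrations must be positive.
    """
    s = np.asarray(co2_scenario, dtype=float)
    b = np.asarray(co2_baseline, dtype=float)
    if np.any(s <= 0) or np.any(b <= 0):
        raise ValueError("CO2 concentrations must be positive (ppm)")
    out = np.maximum(s - MODERN_CO2_PPM, 0.0)
    return float(out) if out.ndim == 0 else out


def co2_response(delta_co2, a):
    """Saturating fertilization curve f(dCO2) = dCO2 / (dCO2 + A).

    Strictly increasing and concave in ``dCO2`` with asymptote 1; ``A`` is
    the half-saturation constant in ppm.  Negative deltas are clamped to 0.
    """
    if a <= 0:
        raise ValueError("half-saturation constant A must be positive")
    d = np.maximum(np.asarray(delta_co2, dtype=float), 0.0)
    out = d / (d + a)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PointEstimate:
    """One published yield-change estimate with its climate perturbation."""

    study_id: str
    crop: str
    country: str
    delta_yield: float  # percent
    delta_T: float  # degC, local growing-season change
    co2_scenario: float  # ppm, the study's perturbed concentration
    co2_baseline: float  # ppm, the study's reference concentration
    delta_precip: float  # percent
    adapt: bool
    baseline_T: float  # degC, country-crop growing-season mean
    pub_year: int | None = None
    method: str | None = None  # "process" or "empirical"
    adaptation_type: str | None = None
    model_id: str | None = None

    @property
    def pathway(self) -> str:
        return crop_pathway(self.crop)


class MetaDatabase:
    """An ordered collection of yield-change point estimates.

    Backed by a :class:`pandas.DataFrame` with the canonical column schema
    (see :data:`REQUIRED_COLUMNS`).  Missing precipitation changes are
    imputed as zero with a logged count -- many process studies hold rainfall
    fixed, and dropping those records would silently change the sample.
    """

    def __init__(self, records: pd.DataFrame, provenance: str = ""):
        df = records.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"meta-database missing required columns: {missing}")
        bad_crop = ~df["crop"].isin(CROPS)
        if bad_crop.any():
            idx = df.index[bad_crop][0]
            raise ValueError(
                f"record {idx} has unknown crop {df.loc[idx, 'crop']!r}; "
                f"supported crops are {CROPS}"
            )
        if df["study_id"].isna().any() or (df["study_id"].astype(str) == "").any():
            raise ValueError("every record needs a non-empty study_id (block bootstrap)")
        if (df["delta_yield_pct"] < -100).any():
            raise ValueError("delta_yield_pct below -100% is not a valid yield change")
        if (df["co2_ppm"] <= 0).any() or (df["co2_baseline_ppm"] <= 0).any():
            raise ValueError("CO2 concentrations must be positive")
        n_imputed = int(df["delta_precip_pct"].isna().sum())
        if n_imputed:
            logger.info("imputing delta_precip_pct = 0 for %d records", n_imputed)
            df["delta_precip_pct"] = df["delta_precip_pct"].fillna(0.0)
        df["adapt"] = df["adapt"].astype(bool)
        self.records = df.reset_index(drop=True)
        self.provenance = provenance
        self.n_precip_imputed = n_imputed

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_points(cls, points: Iterable[PointEstimate], provenance: str = "") -> "MetaDatabase":
        rows = [
            {
                "study_id": p.study_id,
                "crop": p.crop,
                "country": p.country,
                "delta_yield_pct": p.delta_yield,
                "delta_T_C": p.delta_T,
                "co2_ppm": p.co2_scenario,
                "co2_baseline_ppm": p.co2_baseline,
                "delta_precip_pct": p.delta_precip,
                "adapt": p.adapt,
                "baseline_T_C": p.baseline_T,
                "pub_year": p.pub_year,
                "method": p.method,
                "adaptation_type": p.adaptation_type,
                "model_id": p.model_id,
            }
            for p in points
        ]
        return cls(pd.DataFrame(rows), provenance)

    @classmethod
    def from_csv(cls, path, baseline_table: pd.DataFrame | None = None,
                 provenance: str | None = None) -> "MetaDatabase":
        """Read the canonical CSV schema.

        ``baseline_table`` (columns country, crop, baseline_T_C) attaches
        baseline growing-season temperatures when the CSV lacks the
        ``baseline_T_C`` column; multi-country studies are expected to have
        been assigned upstream to the country with the highest production of
        the crop.
        """
        df = pd.read_csv(path)
        if "baseline_T_C" not in df.columns:
            if baseline_table is None:
                raise ValueError(
                    "CSV lacks baseline_T_C; supply a (country, crop) baseline table"
                )
            df = df.merge(baseline_table, on=["country", "crop"], how="left")
            if df["baseline_T_C"].isna().any():
                missing = df.loc[df["baseline_T_C"].isna(), ["country", "crop"]]
                raise ValueError(
                    f"baseline table missing entries for: "
                    f"{missing.drop_duplicates().to_dict('records')}"
                )
        return cls(df, provenance if provenance is not None else str(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def subset(self, mask) -> "MetaDatabase":
        return MetaDatabase(self.records.loc[mask], self.provenance)


@dataclass
class CoefficientSet:
    """Fitted response-surface parameters.

    ``values`` holds the 21 regression coefficients in :data:`COEF_LABELS`
    order: per-crop dT, dT^2, dT*Tbar, dT^2*Tbar terms, then the shared C3
    and C4 fertilization amplitudes (percent at full saturation), the
    precipitation slope, the adaptation-temperature interaction, and the
    adaptation intercept.
    """

    values: np.ndarray
    a_c3: float = DEFAULT_A_C3
    a_c4: float = DEFAULT_A_C4
    fit_r2: float | None = None
    n_obs: int = 0
    labels: tuple[str, ...] = COEF_LABELS
    residuals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError(
                f"expected {len(self.labels)} coefficients, got {self.values.shape}"
            )
        if self.a_c3 <= 0 or self.a_c4 <= 0:
            raise ValueError("half-saturation constants must be positive")

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def _per_crop(self, term: str) -> dict[str, float]:
        return {c: self[f"{term}:{c}"] for c in CROPS}

    @property
    def beta1(self) -> dict[str, float]:
        return self._per_crop("dT")

    @property
    def beta2(self) -> dict[str, float]:
        return self._per_crop("dT2")

    @property
    def beta3(self) -> dict[str, float]:
        return self._per_crop("dT_tbar")

    @property
    def beta4(self) -> dict[str, float]:
        return self._per_crop("dT2_tbar")

    @property
    def beta5(self) -> float:
        return self["fco2_c3"]

    @property
    def beta6(self) -> float:
        return self["fco2_c4"]

    @property
    def beta7(self) -> float:
        return self["dP"]

    @property
    def beta8(self) -> float:
        return self["dT_adapt"]

    @property
    def beta9(self) -> float:
        return self["adapt"]

    def predict_raw(self, crop, delta_T, baseline_T, co2_ppm, delta_precip, adapt):
        """Evaluate the regression mean (percent), no adjustment, no clamp.

        Accepts scalars or broadcastable arrays for the climate inputs.
        """
        if crop not in CROPS:
            raise ValueError(f"unknown crop {crop!r}")
        dT = np.asarray(delta_T, dtype=float)
        tbar = np.asarray(baseline_T, dtype=float)
        dP = np.asarray(delta_precip, dtype=float)
        ad = np.asarray(adapt, dtype=float)
        dco2 = adjust_co2_delta(co2_ppm)
        if crop in C4_CROPS:
            fert = self.beta6 * co2_response(dco2, self.a_c4)
        else:
            fert = self.beta5 * co2_response(dco2, self.a_c3)
        y = (
            self[f"dT:{crop}"] * dT
            + self[f"dT2:{crop}"] * dT**2
            + self[f"dT_tbar:{crop}"] * dT * tbar
            + self[f"dT2_tbar:{crop}"] * dT**2 * tbar
            + fert
            + self.beta7 * dP
            + self.beta8 * dT * ad
            + self.beta9 * ad
        )
        return float(y) if np.ndim(y) == 0 else y

    def to_json(self, path=None) -> str:
        doc = {
            "labels": list(self.labels),
            "values": [float(v) for v in self.values],
            "a_c3": self.a_c3,
            "a_c4": self.a_c4,
            "fit_r2": self.fit_r2,
            "n_obs": self.n_obs,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoefficientSet":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            values=np.asarray(doc["values"], dtype=float),
            a_c3=doc["a_c3"],
            a_c4=doc["a_c4"],
            fit_r2=doc.get("fit_r2"),
            n_obs=doc.get("n_obs", 0),
            labels=tuple(doc["labels"]),
        )


@dataclass(frozen=True)
class YieldQuery:
    """Evaluation point for the fitted surface."""

    crop: str
    delta_T_local: float  # degC
    baseline_T: float  # degC
    co2_ppm: float = MODERN_CO2_PPM  # absolute scenario concentration
    delta_precip: float = 0.0  # percent
    adapt: bool = False


def build_design_matrix(
    db: MetaDatabase,
    a_c3: float = DEFAULT_A_C3,
    a_c4: float = DEFAULT_A_C4,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Assemble the 21-column regression design matrix for a meta-database.

    Columns: per-crop {dT, dT^2, dT*Tbar, dT^2*Tbar}, then f1(dCO2)*C3,
    f2(dCO2)*C4, dP, dT*Adapt, Adapt.  No constant column: the
    no-adaptation surface is forced through the origin.
    """
    df = db.records
    dT = df["delta_T_C"].to_numpy(float)
    tbar = df["baseline_T_C"].to_numpy(float)
    dP = df["delta_precip_pct"].to_numpy(float)
    adapt = df["adapt"].to_numpy(float)
    dco2 = adjust_co2_delta(
        df["co2_ppm"].to_numpy(float), df["co2_baseline_ppm"].to_numpy(float)
    )
    is_c4 = df["crop"].isin(C4_CROPS).to_numpy(float)
    cols = []
    for crop in CROPS:
        ind = (df["crop"] == crop).to_numpy(float)
        cols += [dT * ind, dT**2 * ind, dT * tbar * ind, dT**2 * tbar * ind]
    cols += [
        co2_response(dco2, a_c3) * (1.0 - is_c4),
        co2_response(dco2, a_c4) * is_c4,
        dP,
        dT * adapt,
        adapt,
    ]
    return np.column_stack(cols), COEF_LABELS


def _deficient_columns(X: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Name the columns pivoted out by a rank-revealing QR."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [labels[i] for i in sorted(piv[rank:])]


def _ols(X: np.ndarray, y: np.ndarray):
    """Least-squares fast path; returns (coefs, rank, ss_res)."""
    coefs, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    ss_res = float(res[0]) if res.size else float(((y - X @ coefs) ** 2).sum())
    return coefs, rank, ss_res


def fit_response_surface(
    db: MetaDatabase,
    a_c3: float = DEFAULT_A_C3,
    a_c4: float = DEFAULT_A_C4,
) -> CoefficientSet:
    """Fit the 21-parameter response surface by ordinary least squares.

    R-squared is the uncentered version appropriate for a no-intercept
    regression (1 - SS_res / sum y^2); residuals are stored on the result.
    """
    X, labels = build_design_matrix(db, a_c3, a_c4)
    y = db.records["delta_yield_pct"].to_numpy(float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more than {k} records to fit; got {n}")
    coefs, rank, ss_res = _ols(X, y)
    if rank < k:
        raise RankDeficientDesignError(_deficient_columns(X, labels))
    ss_tot = float((y**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CoefficientSet(
        values=coefs,
        a_c3=a_c3,
        a_c4=a_c4,
        fit_r2=r2,
        n_obs=n,
        residuals=y - X @ coefs,
    )


def select_co2_half_saturation(
    db: MetaDatabase,
    candidates_c3: Sequence[float],
    candidates_c4: Sequence[float],
) -> tuple[float, float]:
    """Grid-search the half-saturation constants by fit R-squared.

    Returns the (A_c3, A_c4) pair with the highest R-squared; exact ties go
    to the smaller constants (candidates are scanned in ascending order and
    only strict improvements replace the incumbent).
    """
    if not len(candidates_c3) or not len(candidates_c4):
        raise ValueError("candidate lists must be nonempty")
    if any(a <= 0 for a in candidates_c3) or any(a <= 0 for a in candidates_c4):
        raise ValueError("half-saturation candidates must be positive")
    best = None
    best_r2 = -np.inf
    for a3 in sorted(candidates_c3):
        for a4 in sorted(candidates_c4):
            r2 = fit_response_surface(db, a3, a4).fit_r2
            if r2 > best_r2:
                best, best_r2 = (a3, a4), r2
    return best


@dataclass
class CoefficientEnsemble:
    """Bootstrap distribution of the response-surface coefficients."""

    draws: list[CoefficientSet]
    block_key: str
    seed: int

    def __post_init__(self):
        if self.draws:
            a3 = {d.a_c3 for d in self.draws}
            a4 = {d.a_c4 for d in self.draws}
            if len(a3) > 1 or len(a4) > 1:
                raise ValueError("all draws must share the half-saturation constants")

    @property
    def n_reps(self) -> int:
        return len(self.draws)

    @property
    def coef_matrix(self) -> np.ndarray:
        return np.vstack([d.values for d in self.draws])

    def quantile(self, label: str, q) -> float | np.ndarray:
        """Empirical (type-7, linear interpolation) quantile of a coefficient."""
        if self.n_reps < 2:
            raise ValueError("quantile queries require at least 2 draws")
        col = self.coef_matrix[:, self.draws[0].labels.index(label)]
        return np.quantile(col, q)

    def functional_quantile(self, fn, q):
        """Quantile of any scalar functional of a CoefficientSet."""
        if self.n_reps < 2:
            raise ValueError("quantile queries require at least 2 draws")
        vals = np.asarray([fn(d) for d in self.draws], dtype=float)
        return np.quantile(vals, q)

    def interval(self, label: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        return tuple(self.quantile(label, [lo, 1 - lo]))

    def to_json(self, path=None) -> str:
        d0 = self.draws[0]
        doc = {
            "block_key": self.block_key,
            "seed": self.seed,
            "labels": list(d0.labels),
            "a_c3": d0.a_c3,
            "a_c4": d0.a_c4,
            "draws": [[float(v) for v in d.values] for d in self.draws],
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoefficientEnsemble":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        draws = [
            CoefficientSet(
                values=np.asarray(v, dtype=float),
                a_c3=doc["a_c3"],
                a_c4=doc["a_c4"],
                labels=tuple(doc["labels"]),
            )
            for v in doc["draws"]
        ]
        return cls(draws=draws, block_key=doc["block_key"], seed=doc["seed"])


def block_bootstrap(
    db: MetaDatabase,
    n_reps: int = 1500,
    seed: int = 0,
    block_key: str = "study_id",
    a_c3: float = DEFAULT_A_C3,
    a_c4: float = DEFAULT_A_C4,
    max_redraws: int = 10,
) -> CoefficientEnsemble:
    """Block bootstrap of the response-surface fit.

    Each replicate resamples whole blocks (studies by default, models via
    ``block_key="model_id"``) with replacement -- the same number of blocks
    as the original, each equally likely -- concatenates their records, and
    refits.  This respects correlation between point estimates from the same
    source.  A replicate whose resampled design is rank deficient is redrawn
    from the advancing random stream, up to ``max_redraws`` times, keeping
    ``n_reps`` exact and the whole procedure reproducible under ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if block_key not in db.records.columns:
        raise ValueError(f"block key {block_key!r} not in database columns")
    X, _ = build_design_matrix(db, a_c3, a_c4)
    y = db.records["delta_yield_pct"].to_numpy(float)
    k = X.shape[1]
    # blocks in order of first appearance, so the grouping is deterministic
    codes, _ = pd.factorize(db.records[block_key])
    n_blocks = codes.max() + 1
    blocks = [np.flatnonzero(codes == b) for b in range(n_blocks)]
    rng = np.random.default_rng(seed)
    draws: list[CoefficientSet] = []
    for rep in range(n_reps):
        for attempt in range(max_redraws + 1):
            pick = rng.integers(0, n_blocks, size=n_blocks)
            idx = np.concatenate([blocks[b] for b in pick])
            coefs, rank, ss_res = _ols(X[idx], y[idx])
            if rank == k:
                break
            logger.warning(
                "bootstrap replicate %d: rank-deficient resample (attempt %d), redrawing",
                rep, attempt + 1,
            )
        else:
            raise RankDeficientDesignError(
                [f"replicate {rep}: {max_redraws} redraws exhausted"]
            )
        yb = y[idx]
        ss_tot = float((yb**2).sum())
        draws.append(
            CoefficientSet(
                values=coefs,
                a_c3=a_c3,
                a_c4=a_c4,
                fit_r2=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
                n_obs=len(idx),
            )
        )
    return CoefficientEnsemble(draws=draws, block_key=block_key, seed=seed)


def predict_yield_change(coefs: CoefficientSet, q: YieldQuery) -> float:
    """Adjusted yield-change prediction (percent) for a query point.

    The raw regression value at the query minus the value at zero climate
    change with the same adaptation flag: this nets out the adaptation
    intercept (management changes that would pay off in today's climate)
    while retaining the adaptation-temperature interaction, and forces the
    surface through the origin.  Losses are floored at -99%.
    """
    raw = coefs.predict_raw(
        q.crop, q.delta_T_local, q.baseline_T, q.co2_ppm, q.delta_precip, q.adapt
    )
    base = coefs.predict_raw(q.crop, 0.0, q.baseline_T, MODERN_CO2_PPM, 0.0, q.adapt)
    return float(max(raw - base, YIELD_FLOOR))


def predict_yield_change_field(
    coefs: CoefficientSet,
    crop: str,
    delta_T,
    baseline_T,
    co2_ppm,
    delta_precip=0.0,
    adapt=False,
) -> np.ndarray:
    """Vectorized adjusted prediction over arrays of evaluation points."""
    raw = coefs.predict_raw(crop, delta_T, baseline_T, co2_ppm, delta_precip, adapt)
    base = coefs.predict_raw(
        crop, 0.0, np.asarray(baseline_T, float), MODERN_CO2_PPM, 0.0, adapt
    )
    return np.maximum(raw - base, YIELD_FLOOR)


@dataclass
class VariantFit:
    """Fit of an alternate model specification (flexible column set)."""

    variant: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    fit_r2: float
    n_obs: int


VARIANTS = ("post2005", "cubic", "method_interaction", "adaptation_split")


def run_specification_variant(
    db: MetaDatabase,
    variant: str,
    a_c3: float = DEFAULT_A_C3,
    a_c4: float = DEFAULT_A_C4,
) -> VariantFit:
    """Fit one of the robustness-check specifications.

    ``post2005`` restricts to records published in or after 2005; ``cubic``
    appends crop-specific dT^3 terms; ``method_interaction`` lets the
    temperature terms differ between process-based and empirical studies;
    ``adaptation_split`` replaces the single adaptation dummy with
    cultivar / planting-date / both dummies (and their dT interactions).
    """
    import statsmodels.api as sm

    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    df = db.records
    work = db
    if variant == "post2005":
        if "pub_year" not in df.columns or df["pub_year"].isna().all():
            raise ValueError("variant post2005 requires a pub_year column")
        mask = df["pub_year"].astype(float) >= 2005
        if not mask.any():
            raise ValueError("variant post2005: no records published in 2005 or later")
        work = db.subset(mask)
    X, labels = build_design_matrix(work, a_c3, a_c4)
    labels = list(labels)
    wdf = work.records
    dT = wdf["delta_T_C"].to_numpy(float)
    extra_cols, extra_labels = [], []
    if variant == "cubic":
        for crop in CROPS:
            ind = (wdf["crop"] == crop).to_numpy(float)
            extra_cols.append(dT**3 * ind)
            extra_labels.append(f"dT3:{crop}")
    elif variant == "method_interaction":
        if "method" not in wdf.columns or wdf["method"].isna().all():
            raise ValueError("variant method_interaction requires a method column")
        emp = (wdf["method"] == "empirical").to_numpy(float)
        for crop in CROPS:
            ind = (wdf["crop"] == crop).to_numpy(float)
            extra_cols += [dT * emp * ind, dT**2 * emp * ind]
            extra_labels += [f"dT_empirical:{crop}", f"dT2_empirical:{crop}"]
    elif variant == "adaptation_split":
        if "adaptation_type" not in wdf.columns or wdf["adaptation_type"].isna().all():
            raise ValueError("variant adaptation_split requires an adaptation_type column")
        keep = [i for i, lab in enumerate(labels) if lab not in ("dT_adapt", "adapt")]
        X = X[:, keep]
        labels = [labels[i] for i in keep]
        for atype in ("cultivar", "planting_date", "both"):
            ind = (wdf["adaptation_type"] == atype).to_numpy(float)
            extra_cols += [ind, dT * ind]
            extra_labels += [f"adapt_{atype}", f"dT_adapt_{atype}"]
    if extra_cols:
        X = np.column_stack([X] + extra_cols)
        labels = labels + extra_labels
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(_deficient_columns(X, labels))
    y = wdf["delta_yield_pct"].to_numpy(float)
    res = sm.OLS(y, pd.DataFrame(X, columns=labels)).fit()
    return VariantFit(
        variant=variant,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        fit_r2=float(res.rsquared),
        n_obs=int(res.nobs),
    )
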