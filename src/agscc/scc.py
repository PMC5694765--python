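"""Pulse-based social cost of carbon with a regional, sectoral damage module.

An additive damage module in the style of FUND -- per-region agricultural
damage functions from :mod:`agscc.damage`, plus a configurable "other
sectors" damage function per region -- coupled to the DICE-2013R climate
core: a linear three-reservoir carbon cycle (atmosphere, upper
ocean/biosphere, deep ocean), logarithmic radiative forcing
F = F2x * log2(C/C_pre), and a two-layer (atmosphere / deep ocean)
temperature model.  DICE's published five-year transition matrices are
annualized by linear interpolation, M_annual = I + (M_5yr - I)/5, which
preserves the equilibria (so equilibrium warming at doubled CO2 equals the
configured climate sensitivity).

The SCC is computed by a pulse experiment: add a 1 GtCO2 emissions pulse to
the reference path in the pulse year, difference the damage streams,
discount the increments back to the pulse year at a constant annual rate,
and normalize by the pulse mass.  Because damages are additive over regions
and sectors, the SCC decomposes exactly into (region, sector) contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .damage import DamageFunction, evaluate_damage

#: Atmospheric CO2 mass-to-concentration conversion.
GTC_PER_PPM = 2.13
GTC_PER_GTCO2 = 12.0 / 44.0

SECTORS = ("agriculture", "other")


@dataclass(frozen=True)
class ClimateParams:
    """DICE-2013R central climate parameters (five-year step, annualized).

    ``b12``/``b23`` are the five-year atmosphere-to-upper and upper-to-deep
    carbon transfer fractions; reciprocal transfers follow from the
    equilibrium reservoir masses so that preindustrial is an exact fixed
    point.  ``c1``/``c4`` are the five-year temperature adjustment speeds,
    ``c3`` the atmosphere-to-deep-ocean heat exchange coefficient.
    """

    f2x: float = 3.8  # W m-2 forcing at doubled CO2
    ecs: float = 2.9  # degC equilibrium climate sensitivity
    b12: float = 0.088
    b23: float = 0.0025
    mat_eq: float = 588.0  # GtC preindustrial atmosphere
    mu_eq: float = 1350.0  # GtC upper ocean / biosphere
    ml_eq: float = 10000.0  # GtC deep ocean
    c1: float = 0.098
    c3: float = 0.088
    c4: float = 0.025
    step_years: int = 5  # the published step the annualization divides by

    @property
    def b21(self) -> float:
        return self.b12 * self.mat_eq / self.mu_eq

    @property
    def b32(self) -> float:
        return self.b23 * self.mu_eq / self.ml_eq


@dataclass
class ClimateState:
    """Carbon reservoirs (GtC) and layer temperatures (degC above preindustrial)."""

    mat: float  # atmosphere
    mu: float  # upper ocean / biosphere
    ml: float  # deep ocean
    t_at: float  # atmospheric temperature anomaly
    t_lo: float  # deep-ocean temperature anomaly

    def __post_init__(self):
        if min(self.mat, self.mu, self.ml) < 0:
            raise ValueError("carbon reservoir masses must be non-negative")

    @property
    def ppm(self) -> float:
        return self.mat / GTC_PER_PPM


def preindustrial_state(params: ClimateParams | None = None) -> ClimateState:
    p = params or ClimateParams()
    return ClimateState(mat=p.mat_eq, mu=p.mu_eq, ml=p.ml_eq, t_at=0.0, t_lo=0.0)


def modern_state() -> ClimateState:
    """2010-era initial conditions (DICE-2013R initialization)."""
    return ClimateState(mat=830.4, mu=1527.0, ml=10010.0, t_at=0.80, t_lo=0.0068)


def step_climate(
    state: ClimateState,
    annual_emissions: float,
    params: ClimateParams | None = None,
    forcing_other: float = 0.0,
) -> ClimateState:
    """One annual step: carbon cycle, forcing, two-layer temperature.

    ``annual_emissions`` is in GtCO2; ``forcing_other`` is exogenous
    non-CO2 forcing in W m-2.  The update is deterministic and conserves
    carbon mass exactly (reservoir changes sum to the emitted GtC).
    """
    p = params or ClimateParams()
    if annual_emissions < 0:
        raise ValueError("emissions must be non-negative")
    n = p.step_years
    b12, b21, b23, b32 = p.b12 / n, p.b21 / n, p.b23 / n, p.b32 / n
    e_gtc = annual_emissions * GTC_PER_GTCO2
    mat = state.mat + e_gtc - b12 * state.mat + b21 * state.mu
    mu = state.mu + b12 * state.mat - (b21 + b23) * state.mu + b32 * state.ml
    ml = state.ml + b23 * state.mu - b32 * state.ml
    forcing = p.f2x * np.log2(mat / p.mat_eq) + forcing_other
    t_at = state.t_at + (p.c1 / n) * (
        forcing - (p.f2x / p.ecs) * state.t_at - p.c3 * (state.t_at - state.t_lo)
    )
    t_lo = state.t_lo + (p.c4 / n) * (state.t_at - state.t_lo)
    return ClimateState(mat=mat, mu=mu, ml=ml, t_at=t_at, t_lo=t_lo)


@dataclass
class Scenario:
    """Socio-economic and emissions paths on a common annual index.

    ``emissions`` are global GtCO2 per year; ``gdp``, ``population`` and
    ``ag_share`` are year-by-region frames (index = years).  An optional
    exogenous non-CO2 forcing path rides along (W m-2; zero by default).
    """

    years: np.ndarray
    emissions: np.ndarray
    gdp: pd.DataFrame
    population: pd.DataFrame
    ag_share: pd.DataFrame
    forcing_other: np.ndarray | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.emissions = np.asarray(self.emissions, dtype=float)
        n = len(self.years)
        if self.forcing_other is None:
            self.forcing_other = np.zeros(n)
        self.forcing_other = np.asarray(self.forcing_other, dtype=float)
        for name, arr in (("emissions", self.emissions), ("forcing_other", self.forcing_other)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != years length {n}")
        if (self.emissions < 0).any():
            raise ValueError("emissions must be non-negative")
        for name, frame in (("gdp", self.gdp), ("population", self.population),
                            ("ag_share", self.ag_share)):
            if len(frame) != n:
                raise ValueError(f"{name} frame length != years length")
        if ((self.ag_share < 0) | (self.ag_share > 1)).any().any():
            raise ValueError("agricultural output shares must lie in [0, 1]")
        if list(self.gdp.columns) != list(self.ag_share.columns):
            raise ValueError("gdp and ag_share must share the same region columns")

    @property
    def regions(self) -> list[str]:
        return list(self.gdp.columns)

    def with_pulse(self, pulse_year: int, pulse_gtco2: float) -> "Scenario":
        if pulse_year not in self.years:
            raise ValueError(f"pulse year {pulse_year} not in scenario years")
        emissions = self.emissions.copy()
        emissions[np.searchsorted(self.years, pulse_year)] += pulse_gtco2
        return replace(self, emissions=emissions)

    def to_csv(self, emissions_path, regional_path) -> None:
        pd.DataFrame(
            {"year": self.years, "emissions_gtco2": self.emissions,
             "forcing_other_wm2": self.forcing_other}
        ).to_csv(emissions_path, index=False)
        frames = []
        for name, frame in (("gdp", self.gdp), ("population", self.population),
                            ("ag_share", self.ag_share)):
            f = frame.copy()
            f.insert(0, "variable", name)
            f.insert(0, "year", self.years)
            frames.append(f)
        pd.concat(frames).to_csv(regional_path, index=False)

    @classmethod
    def from_csv(cls, emissions_path, regional_path) -> "Scenario":
        em = pd.read_csv(emissions_path)
        reg = pd.read_csv(regional_path)
        years = em["year"].to_numpy(int)
        frames = {}
        for name in ("gdp", "population", "ag_share"):
            f = reg[reg["variable"] == name].set_index("year").drop(columns="variable")
            frames[name] = f.loc[years]
        return cls(
            years=years,
            emissions=em["emissions_gtco2"].to_numpy(float),
            gdp=frames["gdp"],
            population=frames["population"],
            ag_share=frames["ag_share"],
            forcing_other=em["forcing_other_wm2"].to_numpy(float)
            if "forcing_other_wm2" in em.columns
            else None,
        )


def run_scenario(
    s: Scenario,
    params: ClimateParams | None = None,
    initial_state: ClimateState | None = None,
) -> pd.DataFrame:
    """Iterate the climate module over a scenario's emissions path.

    Returns a year-indexed frame with atmospheric CO2 (ppm) and global mean
    warming above preindustrial (degC), both recorded after each year's
    step.  The initial state defaults to the 2010-era modern state.
    """
    state = initial_state if initial_state is not None else modern_state()
    ppm = np.empty(len(s.years))
    dT = np.empty(len(s.years))
    for i, _ in enumerate(s.years):
        state = step_climate(state, s.emissions[i], params, s.forcing_other[i])
        ppm[i] = state.ppm
        dT[i] = state.t_at
    return pd.DataFrame({"co2_ppm": ppm, "dT": dT}, index=pd.Index(s.years, name="year"))


@dataclass
class DamageConfig:
    """Per-region damage functions for agriculture and lumped other sectors."""

    agriculture: Mapping  # region -> DamageFunction (fraction of ag output value)
    other: Mapping  # region -> DamageFunction (fraction of GDP)

    def __post_init__(self):
        if set(self.agriculture) != set(self.other):
            raise ValueError("agriculture and other-sector region sets differ")

    @property
    def regions(self) -> list[str]:
        return sorted(self.agriculture)

    @classmethod
    def with_zero_other(cls, agriculture: Mapping) -> "DamageConfig":
        zero = {
            r: DamageFunction(region=r, method="quadratic", coeffs=(0.0, 0.0))
            for r in agriculture
        }
        return cls(agriculture=dict(agriculture), other=zero)


def swap_agriculture(cfg: DamageConfig, new_ag: Mapping) -> DamageConfig:
    """Replace the agricultural damage functions, all else untouched."""
    if set(new_ag) != set(cfg.agriculture):
        raise ValueError("replacement agricultural functions cover different regions")
    return DamageConfig(agriculture=dict(new_ag), other=cfg.other)


def damages_path(dT, s: Scenario, cfg: DamageConfig) -> pd.DataFrame:
    """Annual damages in currency by (region, sector); positive = welfare loss.

    Agriculture damages are the damage-function value (a welfare fraction of
    agricultural output value) times the region's agricultural output
    (ag share x GDP), sign-flipped so losses are positive; other-sector
    damages are analogous on full GDP.
    """
    t = np.asarray(dT, dtype=float)
    if len(t) != len(s.years):
        raise ValueError("temperature path and scenario years differ in length")
    if set(cfg.agriculture) != set(s.regions):
        raise ValueError("damage-config regions do not match scenario regions")
    cols = {}
    for r in s.regions:
        ag_output = s.ag_share[r].to_numpy(float) * s.gdp[r].to_numpy(float)
        cols[(r, "agriculture")] = -evaluate_damage(cfg.agriculture[r], t) * ag_output
        cols[(r, "other")] = -evaluate_damage(cfg.other[r], t) * s.gdp[r].to_numpy(float)
    out = pd.DataFrame(cols, index=pd.Index(s.years, name="year"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["region", "sector"])
    return out


def present_value(increments: pd.Series, pulse_year: int, discount: float) -> float:
    """Discount an annual increment stream back to the pulse year.

    Constant annual discounting 1/(1+r)^(t - pulse_year); years before the
    pulse are excluded (their increments are identically zero in a pulse
    experiment).
    """
    if discount <= -1:
        raise ValueError("discount rate must exceed -100%")
    years = np.asarray(increments.index, dtype=int)
    keep = years >= pulse_year
    factors = (1.0 + discount) ** (-(years[keep] - pulse_year))
    return float((increments.to_numpy(float)[keep] * factors).sum())


@dataclass
class SCCResult:
    """Decomposed social cost of carbon from a pulse experiment."""

    scc_total: float  # currency per ton CO2
    contributions: pd.DataFrame  # regions x sectors, currency per ton CO2
    discount: float
    pulse_year: int
    pulse_gtco2: float
    horizon: int

    def by_sector(self) -> pd.Series:
        return self.contributions.sum(axis=0)

    def by_region(self) -> pd.Series:
        return self.contributions.sum(axis=1)


def scc_pulse(
    s: Scenario,
    cfg: DamageConfig,
    pulse_year: int = 2020,
    pulse_gtco2: float = 1.0,
    discount: float = 0.03,
    horizon: int | None = None,
    params: ClimateParams | None = None,
    initial_state: ClimateState | None = None,
) -> SCCResult:
    """Social cost of carbon by a marginal-pulse experiment.

    Runs the climate module along the reference and the pulsed emissions
    paths, differences the (year, region, sector) damage streams, discounts
    the increments to the pulse year, and normalizes by the pulse mass in
    tons.  The decomposition over regions and sectors sums exactly to the
    total.
    """
    horizon = int(horizon) if horizon is not None else int(s.years[-1])
    if horizon < pulse_year:
        raise ValueError("horizon precedes the pulse year")
    keep = s.years <= horizon
    trimmed = replace(
        s,
        years=s.years[keep],
        emissions=s.emissions[keep],
        gdp=s.gdp.iloc[keep],
        population=s.population.iloc[keep],
        ag_share=s.ag_share.iloc[keep],
        forcing_other=s.forcing_other[keep],
    )
    ref_T = run_scenario(trimmed, params, initial_state)["dT"]
    pulsed = trimmed.with_pulse(pulse_year, pulse_gtco2)
    pul_T = run_scenario(pulsed, params, initial_state)["dT"]
    dmg_ref = damages_path(ref_T, trimmed, cfg)
    dmg_pul = damages_path(pul_T, pulsed, cfg)
    incr = dmg_pul - dmg_ref
    tons = pulse_gtco2 * 1e9
    contrib = incr.apply(lambda col: present_value(col, pulse_year, discount)) / tons
    table = contrib.unstack("sector")
    return SCCResult(
        scc_total=float(contrib.sum()),
        contributions=table,
        discount=discount,
        pulse_year=pulse_year,
        pulse_gtco2=pulse_gtco2,
        horizon=horizon,
    )
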