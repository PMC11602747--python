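"""Synthetic trial generator.

Emulates a 10-year randomized complete block fertilization trial on a
single-cotton system: 5 treatments × 6 blocks = 30 plots, one seed-cotton
yield per plot-year, and a final-year panel of 12 soil indicators per plot.

The default configuration is anchored to the published treatment effects of
the study the package models: printed treatment means (e.g. CK bulk density
1.35 g·cm⁻³ falling to 1.22 under M3, nitrate-N rising from 8.18 to
25.32 mg·kg⁻¹ under CF) and printed percent increases versus the
unfertilized control (SOM +99.56 %, TN +90.33 %, NH₄-N +156.35 % under M1;
urease +100.00/71.17/32.43 % and catalase +62.06/45.62/45.63 % under
M1/M2/M3).  Cells with no printed value are package choices that preserve
the published ordering claims; absolute yield levels in particular are not
reported values.  See ``docs/methods.md``.

Yield model per plot-year::

    yield = base[t] + trend[t] * (year - first_year)   (× shock multiplier)
            + block_effect(plot) + residual

with the optional shock emulating the abrupt M1 yield dip in 2019 that
drives the published SYI ordering (M2 > M1).  Values are truncated at 0.

Soil indicators are drawn from a multivariate normal around per-treatment
means with coefficient-of-variation scaled SDs and an exchangeable positive
correlation ρ among the ten nutrient/enzyme indicators, a −ρ coupling of
bulk density to that block, and pH independent.  This matrix is positive
definite for any ρ ∈ [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trial import INDICATOR_NAMES, TREATMENTS, TrialTable

__all__ = ["Anchor", "ANCHORS", "GeneratorConfig", "default_config",
           "generate_yields", "generate_soil_indicators", "generate_trial"]


@dataclass(frozen=True)
class Anchor:
    """A published number used as a generator default, with its provenance."""

    value: float
    source: str


#: Published values the default configuration is anchored to.  Keys are
#: ``<indicator>/<treatment>`` for means and ``<indicator>/<treatment>/pct``
#: for percent increases relative to CK.
ANCHORS: dict[str, Anchor] = {
    "bulk_density/CK": Anchor(1.35, "reported final-year control mean"),
    "bulk_density/M3": Anchor(1.22, "reported final-year M3 mean"),
    "bulk_density/CF/pct": Anchor(9.74, "reported CF increase vs CK, %"),
    "ph/CK": Anchor(7.04, "reported final-year control mean"),
    "ph/M3": Anchor(7.30, "reported final-year M3 mean"),
    "nitrate_n/CK": Anchor(8.18, "reported final-year control mean, mg·kg⁻¹"),
    "nitrate_n/CF": Anchor(25.32, "reported final-year CF mean, mg·kg⁻¹"),
    "organic_matter/M1/pct": Anchor(99.56, "reported M1 increase vs CK, %"),
    "total_n/M1/pct": Anchor(90.33, "reported M1 increase vs CK, %"),
    "ammonium_n/M1/pct": Anchor(156.35, "reported M1 increase vs CK, %"),
    "urease/M1/pct": Anchor(100.00, "reported M1 increase vs CK, %"),
    "urease/M2/pct": Anchor(71.17, "reported M2 increase vs CK, %"),
    "urease/M3/pct": Anchor(32.43, "reported M3 increase vs CK, %"),
    "catalase/M1/pct": Anchor(62.06, "reported M1 increase vs CK, %"),
    "catalase/M2/pct": Anchor(45.62, "reported M2 increase vs CK, %"),
    "catalase/M3/pct": Anchor(45.63, "reported M3 increase vs CK, %"),
    # pre-trial baseline soil survey of the site
    "organic_matter/baseline": Anchor(12.80, "baseline site survey, g·kg⁻¹"),
    "total_n/baseline": Anchor(0.61, "baseline site survey, g·kg⁻¹"),
    "alkali_n/baseline": Anchor(49.00, "baseline site survey, mg·kg⁻¹"),
    "available_p/baseline": Anchor(28.30, "baseline site survey, mg·kg⁻¹"),
    "available_k/baseline": Anchor(191.00, "baseline site survey, mg·kg⁻¹"),
    "ph/baseline": Anchor(7.30, "baseline site survey"),
}

#: nutrient/enzyme block sharing the exchangeable positive correlation
_NUTRIENT_BLOCK = tuple(n for n in INDICATOR_NAMES if n not in ("bulk_density", "ph"))


def _default_indicator_means() -> dict[str, dict[str, float]]:
    """Per-treatment indicator means (treatment -> indicator -> mean).

    Anchored cells reproduce the published values exactly; the remaining
    cells are package choices preserving the published ordering claims
    (M1 highest for SOM/TN/NH4-N/Alkali-N/AP/AK, CF highest for NO3-N and
    bulk density, M3 highest pH, monotone enzyme response in the organic
    share).
    """
    a = {k: v.value for k, v in ANCHORS.items()}
    ck = {
        "bulk_density": a["bulk_density/CK"],
        "ph": a["ph/CK"],
        "organic_matter": a["organic_matter/baseline"],
        "total_n": a["total_n/baseline"],
        "ammonium_n": 3.50,
        "nitrate_n": a["nitrate_n/CK"],
        "alkali_n": a["alkali_n/baseline"],
        "available_p": a["available_p/baseline"],
        "available_k": a["available_k/baseline"],
        "urease": 15.00,
        "catalase": 2.00,
        "alkaline_phosphatase": 0.50,
    }
    means = {
        "CK": dict(ck),
        "CF": {
            "bulk_density": round(ck["bulk_density"] * (1 + a["bulk_density/CF/pct"] / 100), 6),
            "ph": 6.88,
            "organic_matter": 16.50,
            "total_n": 0.85,
            "ammonium_n": 5.50,
            "nitrate_n": a["nitrate_n/CF"],
            "alkali_n": 65.00,
            "available_p": 38.00,
            "available_k": 230.00,
            "urease": 18.00,
            "catalase": 2.30,
            "alkaline_phosphatase": 0.58,
        },
        "M1": {
            "bulk_density": 1.33,
            "ph": 6.90,
            "organic_matter": ck["organic_matter"] * (1 + a["organic_matter/M1/pct"] / 100),
            "total_n": ck["total_n"] * (1 + a["total_n/M1/pct"] / 100),
            "ammonium_n": ck["ammonium_n"] * (1 + a["ammonium_n/M1/pct"] / 100),
            "nitrate_n": 22.00,
            "alkali_n": 88.00,
            "available_p": 52.00,
            "available_k": 290.00,
            "urease": ck["urease"] * (1 + a["urease/M1/pct"] / 100),
            "catalase": ck["catalase"] * (1 + a["catalase/M1/pct"] / 100),
            "alkaline_phosphatase": 0.70,
        },
        "M2": {
            "bulk_density": 1.28,
            "ph": 7.15,
            "organic_matter": 22.00,
            "total_n": 1.05,
            "ammonium_n": 7.80,
            "nitrate_n": 18.00,
            "alkali_n": 80.00,
            "available_p": 46.00,
            "available_k": 265.00,
            "urease": ck["urease"] * (1 + a["urease/M2/pct"] / 100),
            "catalase": ck["catalase"] * (1 + a["catalase/M2/pct"] / 100),
            "alkaline_phosphatase": 0.66,
        },
        "M3": {
            "bulk_density": a["bulk_density/M3"],
            "ph": a["ph/M3"],
            "organic_matter": 19.00,
            "total_n": 0.95,
            "ammonium_n": 6.50,
            "nitrate_n": 14.00,
            "alkali_n": 72.00,
            "available_p": 41.00,
            "available_k": 245.00,
            "urease": ck["urease"] * (1 + a["urease/M3/pct"] / 100),
            "catalase": ck["catalase"] * (1 + a["catalase/M3/pct"] / 100),
            "alkaline_phosphatase": 0.62,
        },
    }
    return means


@dataclass
class GeneratorConfig:
    """Full description of one synthetic trial.

    Yield parameters are in kg·ha⁻¹ (base mean in the first year, linear
    trend per year, additive Gaussian block and residual SDs).  The shock
    maps a treatment to a (year, multiplier) pair applied to that year's
    deterministic mean; it is disabled by default and exists to emulate the
    abrupt single-year yield dip that lowers a treatment's SYI.  Indicator
    noise is parameterized by a coefficient of variation (SD = cv × mean)
    and the exchangeable correlation strength ``rho``.
    """

    seed: int = 0
    n_blocks: int = 6
    years: tuple[int, int] = (2014, 2023)
    yield_base: dict[str, float] = field(
        default_factory=lambda: {"CK": 4200.0, "CF": 5700.0, "M1": 6500.0,
                                 "M2": 6300.0, "M3": 6000.0})
    yield_trend: dict[str, float] = field(
        default_factory=lambda: {"CK": -70.0, "CF": 85.0, "M1": 25.0,
                                 "M2": 15.0, "M3": 50.0})
    block_sd: float = 50.0
    residual_sd: float = 40.0
    yield_shock: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"M1": (2019, 0.75)})
    shock_enabled: bool = False
    indicator_means: dict[str, dict[str, float]] = field(
        default_factory=_default_indicator_means)
    indicator_cv: float | dict[str, float] = 0.03
    rho: float = 0.6

    def cv_of(self, indicator: str) -> float:
        if isinstance(self.indicator_cv, Mapping):
            return float(self.indicator_cv.get(indicator, 0.03))
        return float(self.indicator_cv)

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be ≥ 1")
        if self.years[1] < self.years[0]:
            raise ConfigError("year span is inverted")
        if self.block_sd < 0 or self.residual_sd < 0:
            raise ConfigError("SDs must be ≥ 0")
        if not (0 <= self.rho < 1):
            raise ConfigError("rho must lie in [0, 1)")
        for t in TREATMENTS:
            if t not in self.yield_base or t not in self.yield_trend:
                raise ConfigError(f"yield model missing treatment {t}")
            means = self.indicator_means.get(t)
            if means is None:
                raise ConfigError(f"indicator means missing treatment {t}")
            missing = set(INDICATOR_NAMES) - set(means)
            if missing:
                raise ConfigError(f"treatment {t}: missing indicator means {sorted(missing)}")
            if means["bulk_density"] <= 0:
                raise ConfigError(f"treatment {t}: mean bulk density must be > 0")
            if not (0 < means["ph"] < 14):
                raise ConfigError(f"treatment {t}: mean pH outside (0, 14)")
            for name in _NUTRIENT_BLOCK:
                if means[name] < 0:
                    raise ConfigError(f"treatment {t}: negative mean for {name}")
        for ind in INDICATOR_NAMES:
            if self.cv_of(ind) < 0:
                raise ConfigError("indicator CVs must be ≥ 0")

    # -- (de)serialization for the pipeline's config files -----------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_blocks": self.n_blocks,
            "years": list(self.years),
            "yield_base": dict(self.yield_base),
            "yield_trend": dict(self.yield_trend),
            "block_sd": self.block_sd,
            "residual_sd": self.residual_sd,
            "yield_shock": {t: list(v) for t, v in self.yield_shock.items()},
            "shock_enabled": self.shock_enabled,
            "indicator_means": {t: dict(v) for t, v in self.indicator_means.items()},
            "indicator_cv": (dict(self.indicator_cv)
                             if isinstance(self.indicator_cv, Mapping)
                             else self.indicator_cv),
            "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        cfg = default_config()
        kwargs = {}
        for key in ("seed", "n_blocks", "block_sd", "residual_sd",
                    "shock_enabled", "rho", "indicator_cv"):
            if key in d:
                kwargs[key] = d[key]
        if "years" in d:
            kwargs["years"] = tuple(d["years"])
        for key in ("yield_base", "yield_trend", "indicator_means"):
            if key in d:
                kwargs[key] = d[key]
        if "yield_shock" in d:
            kwargs["yield_shock"] = {t: tuple(v) for t, v in d["yield_shock"].items()}
        return replace(cfg, **kwargs)


def default_config(seed: int = 0) -> GeneratorConfig:
    """The anchored default configuration (see module docstring).

    Implies the published treatment orderings: 10-year mean yield
    M1 > M2 > M3 > CF > CK, a declining control yield, and M1 leading the
    nutrient enrichment.
    """
    cfg = GeneratorConfig(seed=seed)
    cfg.validate()
    return cfg


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams: 0 = yields, 1 = soil
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _plot_id(treatment: str, block: int) -> str:
    return f"{treatment}-B{block}"


def generate_yields(config: GeneratorConfig) -> TrialTable:
    """Simulate the plot-year yield table.

    Each plot carries one block effect shared across all its years (a
    randomized-block field layout) plus iid residual noise per year; the
    deterministic part is the per-treatment linear trend, optionally scaled
    by the shock multiplier in the shock year.  Yields are truncated at 0.
    Byte-identical output for identical (config, seed).
    """
    config.validate()
    rng = _rng(config, 0)
    first, last = config.years
    years = np.arange(first, last + 1)

    rows = []
    for treatment in TREATMENTS:
        base = config.yield_base[treatment]
        trend = config.yield_trend[treatment]
        shock = config.yield_shock.get(treatment) if config.shock_enabled else None
        for block in range(1, config.n_blocks + 1):
            block_effect = rng.normal(0.0, config.block_sd) if config.block_sd else 0.0
            resid = (rng.normal(0.0, config.residual_sd, size=years.size)
                     if config.residual_sd else np.zeros(years.size))
            mean = base + trend * (years - first)
            if shock is not None:
                mean = mean.copy()
                mean[years == shock[0]] *= shock[1]
            values = np.maximum(mean + block_effect + resid, 0.0)
            for year, value in zip(years, values):
                rows.append((_plot_id(treatment, block), block, treatment,
                             int(year), float(value)))
    df = pd.DataFrame(rows, columns=["plot_id", "block", "treatment", "year", "yield"])
    return TrialTable(yields=df)


def _correlation_matrix(rho: float) -> np.ndarray:
    p = len(INDICATOR_NAMES)
    idx = {n: i for i, n in enumerate(INDICATOR_NAMES)}
    c = np.eye(p)
    block = [idx[n] for n in _NUTRIENT_BLOCK]
    for i in block:
        for j in block:
            if i != j:
                c[i, j] = rho
    bd = idx["bulk_density"]
    for j in block:
        c[bd, j] = c[j, bd] = -rho
    return c


def generate_soil_indicators(config: GeneratorConfig) -> TrialTable:
    """Simulate the final-year per-plot soil indicator panel.

    Draws each plot's 12-vector from N(mean_t, D C D) where D holds the
    CV-scaled SDs and C is the exchangeable correlation model; bulk density
    is clipped to stay positive, pH to (0, 14) and concentrations at 0.
    """
    config.validate()
    rng = _rng(config, 1)
    corr = _correlation_matrix(config.rho)
    # rho < 1 guarantees positive definiteness; guard anyway
    w = np.linalg.eigvalsh(corr)
    if w.min() <= 1e-12:
        raise ConfigError(f"correlation model not positive definite (rho={config.rho})")
    chol = np.linalg.cholesky(corr)

    rows = []
    for treatment in TREATMENTS:
        means = np.array([config.indicator_means[treatment][n] for n in INDICATOR_NAMES])
        sds = np.array([config.cv_of(n) * abs(m) for n, m in zip(INDICATOR_NAMES, means)])
        for block in range(1, config.n_blocks + 1):
            z = chol @ rng.standard_normal(len(INDICATOR_NAMES))
            x = means + sds * z
            for i, name in enumerate(INDICATOR_NAMES):
                if name == "bulk_density":
                    x[i] = max(x[i], 1e-6)
                elif name == "ph":
                    x[i] = min(max(x[i], 1e-6), 14 - 1e-6)
                else:
                    x[i] = max(x[i], 0.0)
            rows.append((_plot_id(treatment, block), treatment, *x))
    df = pd.DataFrame(rows, columns=["plot_id", "treatment", *INDICATOR_NAMES])
    return TrialTable(soil=df)


def generate_trial(config: GeneratorConfig) -> TrialTable:
    """Simulate the full trial (yields + soil) from one config."""
    return TrialTable(yields=generate_yields(config).yields,
                      soil=generate_soil_indicators(config).soil)
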