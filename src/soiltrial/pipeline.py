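"""End-to-end orchestration: simulate → score → indices → stats → importance → report.

Every stage reads and writes plain CSV in one artifact directory, so any
intermediate can be inspected, edited or replaced, and any stage can be
rerun on its own.  A manifest (resolved config, package version, SHA-256
per artifact, warnings) makes runs auditable; wall-times go to a separate
``run_log.json`` so that two runs from the same master seed produce
byte-identical analysis artifacts.

Seed policy: the master seed is the entropy of every
:class:`numpy.random.SeedSequence` in the run; modules separate their
streams with disjoint ``spawn_key`` values (yields 0, soil 1, forest 10,
permutation null 11).  Rerunning with the same master seed reproduces
every artifact exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .fieldstats import (check_assumptions, fit_linear, one_way_anova,
                         pairwise_letters, pearson_matrix, stars_for)
from .importance import ImportanceConfig, importance_analysis
from .indices import (ScoreMatrix, compute_sqi, pca_communalities,
                      score_indicators, weights_from_communalities)
from .sustainability import mean_annual_yield, per_treatment_syi
from .synthetic import GeneratorConfig, default_config, generate_trial
from .trial import (INDICATOR_NAMES, TrialTable, default_direction_map,
                    read_soil_table, read_yield_table, validate_design)

__all__ = ["RunConfig", "run_all", "run_stage", "STAGES", "EXPECTED_FILES"]

log = logging.getLogger(__name__)

#: analysis artifacts every complete run must contain (manifest/log excluded)
EXPECTED_FILES = [
    "yields.csv", "soil.csv", "resolved_config.yaml",
    "scores.csv", "score_bounds.csv", "weights.csv",
    "sqi_plots.csv", "sqi_treatments.csv",
    "syi_plots.csv", "syi_treatments.csv",
    "mean_yield_plots.csv", "mean_yield_treatments.csv",
    "anova_summary.csv", "assumptions.csv", "letters.csv",
    "correlation_r.csv", "correlation_p.csv", "correlation_stars.csv",
    "regression_summary.csv",
    "importance_mean_yield.csv", "importance_syi.csv", "importance_summary.csv",
    "report.md",
]

_ANOVA_LABELS = {
    "bulk_density": "BD", "ph": "pH", "organic_matter": "SOM",
    "total_n": "TN", "ammonium_n": "NH4-N", "nitrate_n": "NO3-N",
    "alkali_n": "Alkali-N", "available_p": "AP", "available_k": "AK",
    "urease": "Ur", "catalase": "CAT", "alkaline_phosphatase": "ALP",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either CSV input paths or generator settings feed each table; when a
    path is given it must resolve at startup (fail-fast), otherwise the
    synthetic generator produces the table from the master seed.
    """

    seed: int = 0
    yields_path: str | None = None
    soil_path: str | None = None
    generator: GeneratorConfig = field(default_factory=default_config)
    directions: dict[str, str] = field(default_factory=dict)
    retention: str | int | float = "kaiser"
    pca_on: str = "raw"
    sd_mode: str = "sample"
    comparison: str = "tukey"
    alpha: float = 0.05
    fdr: bool = False
    n_trees: int = 1000
    n_null_permutations: int = 99

    def __post_init__(self) -> None:
        self.generator = dataclasses.replace(self.generator, seed=self.seed)

    def validate(self) -> None:
        for path in (self.yields_path, self.soil_path):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")
        if self.pca_on not in ("raw", "scores"):
            raise ConfigError("pca_on must be 'raw' or 'scores'")
        if self.sd_mode not in ("sample", "population"):
            raise ConfigError("sd_mode must be 'sample' or 'population'")
        if self.comparison not in ("tukey", "lsd"):
            raise ConfigError("comparison must be 'tukey' or 'lsd'")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        self.generator.validate()

    def importance_config(self, response: str) -> ImportanceConfig:
        return ImportanceConfig(n_trees=self.n_trees,
                                n_null_permutations=self.n_null_permutations,
                                seed=self.seed, response=response)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "inputs": {"yields": self.yields_path, "soil": self.soil_path},
            "generator": self.generator.to_dict(),
            "scoring": {"directions": dict(self.directions),
                        "retention": self.retention, "pca_on": self.pca_on},
            "syi": {"sd_mode": self.sd_mode},
            "stats": {"comparison": self.comparison, "alpha": self.alpha,
                      "fdr": self.fdr},
            "importance": {"n_trees": self.n_trees,
                           "n_null_permutations": self.n_null_permutations},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(seed=int(d.get("seed", 0)))
        inputs = d.get("inputs") or {}
        cfg.yields_path = inputs.get("yields")
        cfg.soil_path = inputs.get("soil")
        if "generator" in d:
            cfg.generator = GeneratorConfig.from_dict(d["generator"])
        cfg.generator = dataclasses.replace(cfg.generator, seed=cfg.seed)
        scoring = d.get("scoring") or {}
        cfg.directions = dict(scoring.get("directions") or {})
        cfg.retention = scoring.get("retention", cfg.retention)
        cfg.pca_on = scoring.get("pca_on", cfg.pca_on)
        cfg.sd_mode = (d.get("syi") or {}).get("sd_mode", cfg.sd_mode)
        stats_cfg = d.get("stats") or {}
        cfg.comparison = stats_cfg.get("comparison", cfg.comparison)
        cfg.alpha = float(stats_cfg.get("alpha", cfg.alpha))
        cfg.fdr = bool(stats_cfg.get("fdr", cfg.fdr))
        imp = d.get("importance") or {}
        cfg.n_trees = int(imp.get("n_trees", cfg.n_trees))
        cfg.n_null_permutations = int(imp.get("n_null_permutations",
                                              cfg.n_null_permutations))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# stage plumbing

class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _require(out: Path, filename: str, producer: str) -> Path:
    path = out / filename
    if not path.exists():
        raise StageError(
            f"missing upstream artifact {filename!r}; run the {producer!r} stage first")
    return path


def _write(df: pd.DataFrame, out: Path, name: str, **kwargs) -> None:
    df.to_csv(out / name, index=False, **kwargs)


def _read_trial(out: Path) -> TrialTable:
    yields = read_yield_table(_require(out, "yields.csv", "simulate"))
    soil = read_soil_table(_require(out, "soil.csv", "simulate"))
    return TrialTable(yields=yields.yields, soil=soil.soil)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, out: Path) -> None:
    """Materialize the trial tables (from disk inputs or the generator)."""
    if config.yields_path is not None:
        table_y = read_yield_table(config.yields_path)
    else:
        table_y = TrialTable(yields=generate_trial(config.generator).yields)
    if config.soil_path is not None:
        table_s = read_soil_table(config.soil_path)
    else:
        from .synthetic import generate_soil_indicators
        table_s = generate_soil_indicators(config.generator)

    table = TrialTable(yields=table_y.yields, soil=table_s.soil).canonical()
    report = validate_design(table, (5, config.generator.n_blocks,
                                     config.generator.years[1] - config.generator.years[0] + 1))
    if not report.ok:
        for issue in report.issues:
            log.warning("design check: %s", issue)

    _write(table.yields, out, "yields.csv")
    _write(table.soil, out, "soil.csv")
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def stage_score(config: RunConfig, out: Path) -> None:
    """Min-max score the soil indicators."""
    soil = read_soil_table(_require(out, "soil.csv", "simulate")).soil
    sm = score_indicators(soil, config.directions or None)
    scores = sm.scores.reset_index()
    scores.insert(1, "treatment", sm.treatments.to_numpy())
    _write(scores, out, "scores.csv")
    _write(sm.bounds_used.reset_index(), out, "score_bounds.csv")


def _load_scores(config: RunConfig, out: Path) -> ScoreMatrix:
    scores = pd.read_csv(_require(out, "scores.csv", "score"))
    bounds = pd.read_csv(_require(out, "score_bounds.csv", "score")).set_index("indicator")
    frame = scores.drop(columns=["treatment"]).set_index("plot_id")
    treatments = pd.Series(scores["treatment"].to_numpy(), index=frame.index,
                           name="treatment")
    directions = dict(default_direction_map(), **config.directions)
    return ScoreMatrix(frame, bounds, directions, treatments)


def stage_indices(config: RunConfig, out: Path) -> None:
    """PCA-communality weights, SQI, SYI and mean annual yield."""
    table = _read_trial(out)
    sm = _load_scores(config, out)

    if config.pca_on == "raw":
        basis = table.soil[["plot_id", "treatment", *sm.scores.columns]]
    else:
        basis = sm.scores.reset_index().assign(treatment=sm.treatments.to_numpy())
    comm = pca_communalities(basis, config.retention)
    weights = weights_from_communalities(comm)
    eig = np.full(len(weights.weights), np.nan)
    eig[:min(len(eig), weights.eigenvalues.size)] = \
        weights.eigenvalues[:min(len(eig), weights.eigenvalues.size)]
    _write(pd.DataFrame({
        "indicator": weights.weights.index,
        "communality": weights.communalities.to_numpy(),
        "weight": weights.weights.to_numpy(),
        "eigenvalue": eig,
        "n_retained": weights.n_retained,
        "retention": str(config.retention),
    }), out, "weights.csv")

    sqi = compute_sqi(sm, weights)
    _write(sqi.per_plot, out, "sqi_plots.csv")
    _write(sqi.per_treatment, out, "sqi_treatments.csv")

    syi = per_treatment_syi(table, config.sd_mode)
    _write(syi.per_plot, out, "syi_plots.csv")
    _write(syi.per_treatment, out, "syi_treatments.csv")

    my_plot, my_treat = mean_annual_yield(table)
    _write(my_plot, out, "mean_yield_plots.csv")
    _write(my_treat, out, "mean_yield_treatments.csv")


def _plot_responses(out: Path) -> pd.DataFrame:
    """Per-plot frame: treatment, 12 indicators, mean_yield, sqi, syi."""
    soil = read_soil_table(_require(out, "soil.csv", "simulate")).soil
    my = pd.read_csv(_require(out, "mean_yield_plots.csv", "indices"))
    sqi = pd.read_csv(_require(out, "sqi_plots.csv", "indices"))
    syi = pd.read_csv(_require(out, "syi_plots.csv", "indices"))
    merged = (soil
              .merge(my[["plot_id", "mean_yield"]], on="plot_id")
              .merge(sqi[["plot_id", "sqi"]], on="plot_id")
              .merge(syi[["plot_id", "syi"]], on="plot_id"))
    return merged


def stage_stats(config: RunConfig, out: Path) -> None:
    """ANOVA summary, assumption checks, letters, correlations, regression."""
    merged = _plot_responses(out)
    responses = {_ANOVA_LABELS[n]: n for n in INDICATOR_NAMES}
    responses.update({"Mean yield": "mean_yield", "SQI": "sqi", "SYI": "syi"})

    anova_rows, letter_rows, assumption_rows = [], [], []
    groups = merged["treatment"].to_numpy()
    for label, col in responses.items():
        values = merged[col].to_numpy(dtype=float)
        res = one_way_anova(values, groups, response=label)
        anova_rows.append((label, res.df_between,
                           round(res.F, 3) if np.isfinite(res.F) else np.inf,
                           round(res.p, 3)))
        if res.degenerate:
            log.warning("%s: zero within-group variance; F reported as ∞", label)

        checks = check_assumptions(values, groups, config.alpha)
        for _, row in checks.shapiro.iterrows():
            assumption_rows.append((label, row["group"], row["n"], row["W"],
                                    row["p"], row["assessable"],
                                    checks.levene_stat, checks.levene_p))
        if not checks.shapiro["assessable"].all():
            log.warning("%s: normality not assessable for some group(s)", label)

        letters = pairwise_letters(values, groups, config.comparison, config.alpha)
        se = merged.groupby("treatment")[col].agg(
            lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        for treatment, letter in letters.letters.items():
            letter_rows.append((label, treatment,
                                letters.means[treatment], se[treatment], letter))

    _write(pd.DataFrame(anova_rows, columns=["Index", "df", "F", "P"]),
           out, "anova_summary.csv")
    _write(pd.DataFrame(assumption_rows,
                        columns=["response", "treatment", "n", "shapiro_W",
                                 "shapiro_p", "assessable", "levene_stat",
                                 "levene_p"]),
           out, "assumptions.csv")
    _write(pd.DataFrame(letter_rows,
                        columns=["response", "treatment", "mean", "se", "letter"]),
           out, "letters.csv")

    variables = [*INDICATOR_NAMES, "mean_yield", "sqi", "syi"]
    corr = pearson_matrix(merged, variables)
    if config.fdr:
        from scipy.stats import false_discovery_control
        p = corr.p.to_numpy().copy()
        iu = np.triu_indices_from(p, k=1)
        mask = ~np.isnan(p[iu])
        adj = p[iu]
        adj[mask] = false_discovery_control(adj[mask])
        p[iu] = adj
        p[(iu[1], iu[0])] = adj
        corr.p.loc[:, :] = p
        corr.stars = corr.p.map(stars_for)
        np.fill_diagonal(corr.stars.values, "")
    _write(corr.r.reset_index(names="variable"), out, "correlation_r.csv")
    _write(corr.p.reset_index(names="variable"), out, "correlation_p.csv")
    _write(corr.stars.reset_index(names="variable"), out, "correlation_stars.csv")

    fits = []
    for name, y in (("syi_on_sqi", merged["syi"]),
                    ("mean_yield_on_sqi", merged["mean_yield"])):
        fit = fit_linear(merged["sqi"], y)
        fits.append((name, fit.slope, fit.intercept, fit.r_squared, fit.p, fit.n))
    _write(pd.DataFrame(fits, columns=["model", "slope", "intercept",
                                       "r_squared", "p", "n"]),
           out, "regression_summary.csv")


def stage_importance(config: RunConfig, out: Path) -> None:
    """Forest permutation importance of the indicators for mean yield and SYI."""
    merged = _plot_responses(out)
    predictors = merged[["plot_id", "treatment", *INDICATOR_NAMES]]
    summary = []
    for response, fname in (("mean_yield", "importance_mean_yield.csv"),
                            ("syi", "importance_syi.csv")):
        result = importance_analysis(predictors, merged[response].to_numpy(),
                                     config.importance_config(response))
        table = result.table.copy()
        table["stars"] = table["p"].map(stars_for)
        _write(table, out, fname)
        summary.append((response, result.variance_explained,
                        config.n_trees, config.n_null_permutations))
    _write(pd.DataFrame(summary, columns=["response", "variance_explained_pct",
                                          "n_trees", "n_null_permutations"]),
           out, "importance_summary.csv")


def stage_report(config: RunConfig, out: Path) -> None:
    """Single markdown summary with the headline tables."""
    anova = pd.read_csv(_require(out, "anova_summary.csv", "stats"))
    letters = pd.read_csv(_require(out, "letters.csv", "stats"))
    regression = pd.read_csv(_require(out, "regression_summary.csv", "stats"))
    imp_summary = pd.read_csv(_require(out, "importance_summary.csv", "importance"))
    imp_yield = pd.read_csv(_require(out, "importance_mean_yield.csv", "importance"))

    lines = ["# Trial analysis report", ""]
    lines += ["## Treatment summaries (mean ± SE, shared letters = n.s.)", ""]
    for response in ("Mean yield", "SQI", "SYI"):
        sub = letters[letters["response"] == response]
        lines.append(f"### {response}")
        lines.append("")
        lines.append("| treatment | mean | se | letter |")
        lines.append("|---|---|---|---|")
        for _, row in sub.iterrows():
            lines.append(f"| {row['treatment']} | {row['mean']:.4g} | "
                         f"{row['se']:.3g} | {row['letter']} |")
        lines.append("")

    lines += ["## One-way ANOVA", "", "| Index | df | F | P |", "|---|---|---|---|"]
    for _, row in anova.iterrows():
        lines.append(f"| {row['Index']} | {row['df']} | {row['F']} | {row['P']} |")
    lines.append("")

    lines += ["## SQI–SYI relationship", ""]
    for _, row in regression.iterrows():
        lines.append(f"- {row['model']}: y = {row['slope']:.5f}·x + "
                     f"{row['intercept']:.5f}, R² = {row['r_squared']:.5f}, "
                     f"p = {row['p']:.3g}, n = {row['n']}")
    lines.append("")

    lines += ["## Random-forest importance", ""]
    for _, row in imp_summary.iterrows():
        lines.append(f"- {row['response']}: variance explained "
                     f"{row['variance_explained_pct']:.2f}% "
                     f"({row['n_trees']} trees)")
    top = imp_yield.sort_values("rank").head(5)
    lines.append("")
    lines.append("Top predictors of mean yield: " +
                 ", ".join(f"{r.predictor} ({r.importance:.1f}%{r.stars})"
                           for r in top.itertuples()))
    lines.append("")
    (out / "report.md").write_text("\n".join(lines))


STAGES: dict[str, Callable[[RunConfig, Path], None]] = {
    "simulate": stage_simulate,
    "score": stage_score,
    "indices": stage_indices,
    "stats": stage_stats,
    "importance": stage_importance,
    "report": stage_report,
}


# ---------------------------------------------------------------------------
# manifest and entry points

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(config: RunConfig, out: Path, warnings: list[str],
                    timings: dict[str, float]) -> None:
    files = {p.name: _sha256(p) for p in sorted(out.iterdir())
             if p.is_file() and p.name not in ("manifest.json", "run_log.json")}
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "files": files,
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(json.dumps(
        {"stage_seconds": {k: round(v, 3) for k, v in timings.items()}}, indent=2))


def run_stage(config: RunConfig, out: str | Path, stage: str) -> Path:
    """Run a single stage against the artifacts already in ``out``."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {list(STAGES)}")
    config.validate()
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("soiltrial").addHandler(collector)
    timings: dict[str, float] = {}
    if (out / "run_log.json").exists():
        timings = json.loads((out / "run_log.json").read_text()).get("stage_seconds", {})
    try:
        t0 = time.perf_counter()
        STAGES[stage](config, out)
        timings[stage] = time.perf_counter() - t0
    finally:
        logging.getLogger("soiltrial").removeHandler(collector)
    _write_manifest(config, out, collector.messages, timings)
    return out


def run_all(config: RunConfig, out: str | Path) -> Path:
    """Run every stage in order and write the manifest.

    Fails fast on an invalid config (including unresolvable input paths)
    before any stage runs; a stage failure aborts with the stage name.
    """
    config.validate()
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("soiltrial").addHandler(collector)
    timings: dict[str, float] = {}
    try:
        for name, fn in STAGES.items():
            log.info("stage %s", name)
            t0 = time.perf_counter()
            try:
                fn(config, out)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
    finally:
        logging.getLogger("soiltrial").removeHandler(collector)
    _write_manifest(config, out, collector.messages, timings)
    return out
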