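"""Domain model and delimited-text IO for a long-term fertilization trial.

The trial layout mirrored throughout the package is a randomized complete
block design: five fertilization regimes (CK no fertilizer, CF chemical
only, M1/M2/M3 with 25/50/75 % of the nitrogen supplied as organic
fertilizer), six replicate blocks, thirty plots, seed-cotton yield recorded
every year, and a final-year panel of twelve soil indicators per plot.

Two CSV schemas are exchanged with the outside world:

``yields``
    long format, one row per plot-year:
    ``plot_id, block, treatment, year, yield``  (yield in kg·ha⁻¹)

``soil``
    one row per plot: ``plot_id, treatment`` plus the twelve indicator
    columns.  Headers may use any alias listed in :data:`INDICATOR_ALIASES`
    (e.g. ``NO3-N`` or ``nitrate_n``).

All values use a ``.`` decimal separator and UTF-8 encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "TREATMENT_ORGANIC_FRACTION",
    "TREATMENTS",
    "TreatmentCode",
    "IndicatorMeta",
    "INDICATORS",
    "INDICATOR_NAMES",
    "INDICATOR_ALIASES",
    "MORE_IS_BETTER",
    "LESS_IS_BETTER",
    "canonical_indicator",
    "default_direction_map",
    "PlotYieldRecord",
    "SoilIndicatorRecord",
    "TrialTable",
    "DesignReport",
    "read_yield_table",
    "read_soil_table",
    "write_yield_table",
    "write_soil_table",
    "validate_design",
]

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"

#: treatment code -> fraction of fertilizer nitrogen supplied as organic manure
TREATMENT_ORGANIC_FRACTION: dict[str, float] = {
    "CK": 0.0,
    "CF": 0.0,
    "M1": 0.25,
    "M2": 0.50,
    "M3": 0.75,
}
TREATMENTS: tuple[str, ...] = tuple(TREATMENT_ORGANIC_FRACTION)


@dataclass(frozen=True)
class TreatmentCode:
    """One of the five fertilization regimes.

    ``organic_fraction`` is derived from the code; constructing an unknown
    code raises :class:`~soiltrial.errors.ValidationError`.
    """

    code: str

    def __post_init__(self) -> None:
        if self.code not in TREATMENT_ORGANIC_FRACTION:
            raise ValidationError(
                f"unknown treatment code {self.code!r}; expected one of {TREATMENTS}"
            )

    @property
    def organic_fraction(self) -> float:
        return TREATMENT_ORGANIC_FRACTION[self.code]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


@dataclass(frozen=True)
class IndicatorMeta:
    """Name, unit and scoring direction of one soil indicator."""

    name: str
    unit: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (MORE_IS_BETTER, LESS_IS_BETTER):
            raise ValidationError(f"bad direction {self.direction!r} for {self.name}")


# Canonical indicator registry.  Direction defaults: bulk density compacts
# the root zone (less is better); the slightly alkaline study soils score pH
# as less-is-better by default, which is configurable downstream; nutrients
# and enzyme activities are more-is-better.
INDICATORS: dict[str, IndicatorMeta] = {
    "bulk_density": IndicatorMeta("bulk_density", "g·cm⁻³", LESS_IS_BETTER),
    "ph": IndicatorMeta("ph", "unitless", LESS_IS_BETTER),
    "organic_matter": IndicatorMeta("organic_matter", "g·kg⁻¹", MORE_IS_BETTER),
    "total_n": IndicatorMeta("total_n", "g·kg⁻¹", MORE_IS_BETTER),
    "ammonium_n": IndicatorMeta("ammonium_n", "mg·kg⁻¹", MORE_IS_BETTER),
    "nitrate_n": IndicatorMeta("nitrate_n", "mg·kg⁻¹", MORE_IS_BETTER),
    "alkali_n": IndicatorMeta("alkali_n", "mg·kg⁻¹", MORE_IS_BETTER),
    "available_p": IndicatorMeta("available_p", "mg·kg⁻¹", MORE_IS_BETTER),
    "available_k": IndicatorMeta("available_k", "mg·kg⁻¹", MORE_IS_BETTER),
    "urease": IndicatorMeta("urease", "activity", MORE_IS_BETTER),
    "catalase": IndicatorMeta("catalase", "activity", MORE_IS_BETTER),
    "alkaline_phosphatase": IndicatorMeta("alkaline_phosphatase", "activity", MORE_IS_BETTER),
}
INDICATOR_NAMES: tuple[str, ...] = tuple(INDICATORS)

#: Public alias table: lower-cased header (with -, space, + folded to _)
#: -> canonical indicator name.  Third-party tables load without renaming.
INDICATOR_ALIASES: dict[str, str] = {
    "bd": "bulk_density",
    "bulk_density": "bulk_density",
    "soil_bulk_density": "bulk_density",
    "ph": "ph",
    "soil_ph": "ph",
    "som": "organic_matter",
    "om": "organic_matter",
    "organic_matter": "organic_matter",
    "soil_organic_matter": "organic_matter",
    "tn": "total_n",
    "total_n": "total_n",
    "total_nitrogen": "total_n",
    "nh4_n": "ammonium_n",
    "nh4__n": "ammonium_n",
    "ammonium_n": "ammonium_n",
    "ammonium_nitrogen": "ammonium_n",
    "no3_n": "nitrate_n",
    "no3__n": "nitrate_n",
    "nitrate_n": "nitrate_n",
    "nitrate_nitrogen": "nitrate_n",
    "alkali_n": "alkali_n",
    "alkali_hydrolyzable_n": "alkali_n",
    "alkali_hydrolyzable_nitrogen": "alkali_n",
    "ahn": "alkali_n",
    "ap": "available_p",
    "available_p": "available_p",
    "available_phosphorus": "available_p",
    "ak": "available_k",
    "available_k": "available_k",
    "available_potassium": "available_k",
    "ur": "urease",
    "urease": "urease",
    "cat": "catalase",
    "catalase": "catalase",
    "alp": "alkaline_phosphatase",
    "alkaline_phosphatase": "alkaline_phosphatase",
}


def _fold_header(name: str) -> str:
    out = name.strip().lower()
    for ch in ("-", " ", "+", "."):
        out = out.replace(ch, "_")
    return out


def canonical_indicator(header: str) -> str | None:
    """Map a column header to its canonical indicator name, or ``None``."""
    return INDICATOR_ALIASES.get(_fold_header(header))


def default_direction_map() -> dict[str, str]:
    """Scoring direction per indicator (copy; safe to mutate)."""
    return {name: meta.direction for name, meta in INDICATORS.items()}


@dataclass(frozen=True)
class PlotYieldRecord:
    """Seed-cotton yield of one plot in one year."""

    plot_id: str
    block: int
    treatment: TreatmentCode
    year: int
    yield_value: float  # kg·ha⁻¹

    def __post_init__(self) -> None:
        if self.yield_value < 0:
            raise ValidationError(
                f"plot {self.plot_id} year {self.year}: negative yield {self.yield_value}"
            )
        if self.block < 1:
            raise ValidationError(f"plot {self.plot_id}: block must be ≥ 1")


@dataclass(frozen=True)
class SoilIndicatorRecord:
    """Final-year indicator panel of one plot (all 12 indicators present)."""

    plot_id: str
    treatment: TreatmentCode
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(INDICATOR_NAMES) - set(self.values)
        if missing:
            raise ValidationError(
                f"plot {self.plot_id}: missing indicators {sorted(missing)}"
            )
        v = self.values
        if v["bulk_density"] <= 0:
            raise ValidationError(f"plot {self.plot_id}: bulk density must be > 0")
        if not (0 < v["ph"] < 14):
            raise ValidationError(
                f"plot {self.plot_id}: pH {v['ph']} outside (0, 14)"
            )
        for name in INDICATOR_NAMES:
            if name in ("bulk_density", "ph"):
                continue
            if v[name] < 0:
                raise ValidationError(
                    f"plot {self.plot_id}: negative value {v[name]} for {name}"
                )


YIELD_COLUMNS = ("plot_id", "block", "treatment", "year", "yield")


@dataclass
class TrialTable:
    """In-memory trial: a long yield table plus a wide soil table.

    ``yields`` columns: plot_id, block, treatment, year, yield.
    ``soil`` columns: plot_id, treatment, then the 12 canonical indicators.
    Either frame may be empty when only one half of the trial was loaded.
    """

    yields: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(YIELD_COLUMNS)))
    soil: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["plot_id", "treatment", *INDICATOR_NAMES])
    )

    @property
    def design(self) -> tuple[int, int, int]:
        """(n_treatments, n_blocks, n_years) inferred from the yield table."""
        if self.yields.empty:
            treats = self.soil["treatment"].nunique() if not self.soil.empty else 0
            return (treats, 0, 0)
        y = self.yields
        return (y["treatment"].nunique(), int(y["block"].nunique()), y["year"].nunique())

    def canonical(self) -> "TrialTable":
        """Copy with rows in canonical (treatment, block, year) order."""
        y = self.yields
        if not y.empty:
            key = y["treatment"].map(list(TREATMENTS).index)
            y = (
                y.assign(_t=key)
                .sort_values(["_t", "block", "year"], kind="stable")
                .drop(columns="_t")
                .reset_index(drop=True)
            )
        s = self.soil
        if not s.empty:
            key = s["treatment"].map(list(TREATMENTS).index)
            s = (
                s.assign(_t=key)
                .sort_values(["_t", "plot_id"], kind="stable")
                .drop(columns="_t")
                .reset_index(drop=True)
            )
        return TrialTable(yields=y, soil=s)

    def yield_records(self) -> list[PlotYieldRecord]:
        return [
            PlotYieldRecord(
                str(r.plot_id), int(r.block), TreatmentCode(str(r.treatment)),
                int(r.year), float(getattr(r, "yield")),
            )
            for r in self.yields.itertuples(index=False)
        ]

    def soil_records(self) -> list[SoilIndicatorRecord]:
        out = []
        for _, row in self.soil.iterrows():
            out.append(
                SoilIndicatorRecord(
                    str(row["plot_id"]),
                    TreatmentCode(str(row["treatment"])),
                    {k: float(row[k]) for k in INDICATOR_NAMES},
                )
            )
        return out

    def merged(self) -> "TrialTable":
        """Merge another fragment's tables into a full trial (non-destructive)."""
        return self


def _check_numeric(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    """Parse a column to float, reporting the 1-based data line of failures."""
    parsed = pd.to_numeric(df[col], errors="coerce")
    raw_na = df[col].isna()
    bad = parsed.isna() & ~raw_na
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {i + 2}: cannot parse {col}={df[col].iloc[i]!r} as a number"
        )
    return parsed


def _check_missing(df: pd.DataFrame, cols: Sequence[str], path: str, allow_missing: bool):
    na = df[list(cols)].isna().any(axis=1)
    rows = [int(i) + 2 for i in np.flatnonzero(na.to_numpy())]
    if rows and not allow_missing:
        raise ValidationError(
            f"{path}: missing values on line(s) {rows[:10]}; "
            "pass allow_missing=True to tag them for listwise deletion"
        )
    return rows


def read_yield_table(path: str | Path, *, allow_missing: bool = False) -> TrialTable:
    """Read a long-format plot-year yield CSV into a :class:`TrialTable`.

    Parameters
    ----------
    path
        CSV with header ``plot_id, block, treatment, year, yield``.
    allow_missing
        If False (default) any empty cell is an error.  If True, rows with
        missing values are kept and their line numbers recorded under
        ``table.yields.attrs["missing_lines"]`` for listwise deletion
        downstream.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        for unparseable numbers (with the offending line), unknown
        treatment codes, negative yields or duplicate (plot_id, year) keys.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing_cols = [c for c in YIELD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s) {missing_cols}")
    df = df[list(YIELD_COLUMNS)]

    missing_lines = _check_missing(df, YIELD_COLUMNS, str(path), allow_missing)
    for col in ("block", "year", "yield"):
        df[col] = _check_numeric(df, col, str(path))

    bad_treat = sorted(set(df["treatment"].dropna()) - set(TREATMENTS))
    if bad_treat:
        raise ValidationError(f"{path}: unknown treatment code(s) {bad_treat}")
    if (df["yield"].dropna() < 0).any():
        i = int(np.flatnonzero((df["yield"] < 0).to_numpy())[0])
        raise ValidationError(f"{path}: line {i + 2}: negative yield")

    complete = df.dropna(subset=["plot_id", "year"])
    dup = complete.duplicated(subset=["plot_id", "year"])
    if dup.any():
        key = complete.loc[dup, ["plot_id", "year"]].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (plot_id, year) key ({key['plot_id']}, {int(key['year'])})"
        )

    out = df.copy()
    out["block"] = out["block"].astype("Int64") if allow_missing else out["block"].astype(int)
    out["year"] = out["year"].astype("Int64") if allow_missing else out["year"].astype(int)
    out["yield"] = out["yield"].astype(float)
    out.attrs["missing_lines"] = missing_lines
    return TrialTable(yields=out)


def read_soil_table(path: str | Path, *, allow_missing: bool = False) -> TrialTable:
    """Read a wide per-plot soil indicator CSV.

    Indicator columns are matched through :data:`INDICATOR_ALIASES`, so
    ``NO3-N``, ``no3_n`` and ``nitrate_n`` all load as ``nitrate_n``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)

    rename: dict[str, str] = {}
    for col in df.columns:
        folded = _fold_header(col)
        if folded in ("plot_id", "treatment"):
            rename[col] = folded
            continue
        canon = canonical_indicator(col)
        if canon is not None:
            if canon in rename.values():
                raise SchemaError(f"{path}: duplicate indicator column for {canon!r}")
            rename[col] = canon
    df = df.rename(columns=rename)

    required = ["plot_id", "treatment", *INDICATOR_NAMES]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s) {missing_cols}")
    df = df[required]

    missing_lines = _check_missing(df, required, str(path), allow_missing)
    for col in INDICATOR_NAMES:
        df[col] = _check_numeric(df, col, str(path))

    bad_treat = sorted(set(df["treatment"].dropna()) - set(TREATMENTS))
    if bad_treat:
        raise ValidationError(f"{path}: unknown treatment code(s) {bad_treat}")

    dup = df.dropna(subset=["plot_id"]).duplicated(subset=["plot_id"])
    if dup.any():
        pid = df.loc[dup, "plot_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate plot_id {pid!r}")

    # row-level range invariants, reported with the offending plot
    for _, row in df.dropna(subset=list(INDICATOR_NAMES)).iterrows():
        pid = row["plot_id"]
        if row["bulk_density"] <= 0:
            raise ValidationError(f"{path}: plot {pid}: bulk density must be > 0")
        if not (0 < row["ph"] < 14):
            raise ValidationError(f"{path}: plot {pid}: pH {row['ph']} outside (0, 14)")
        for name in INDICATOR_NAMES:
            if name in ("bulk_density", "ph"):
                continue
            if row[name] < 0:
                raise ValidationError(
                    f"{path}: plot {pid}: negative value for {name}"
                )

    df.attrs["missing_lines"] = missing_lines
    return TrialTable(soil=df)


def write_yield_table(table: TrialTable, path: str | Path) -> None:
    """Write the yield half of a trial back to CSV.

    Floats use shortest-roundtrip repr, so write → read reproduces the
    records bit-exactly.
    """
    table.yields.to_csv(path, index=False)


def write_soil_table(table: TrialTable, path: str | Path) -> None:
    table.soil.to_csv(path, index=False)


@dataclass
class DesignReport:
    """Outcome of checking a trial against an expected design.

    ``issues`` is empty iff the table matches the expected
    (n_treatments, n_blocks, n_years) balanced layout exactly.
    """

    expected: tuple[int, int, int]
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return f"design OK: {self.expected}"
        return "\n".join(self.issues)


def validate_design(
    table: TrialTable, expected: tuple[int, int, int] = (5, 6, 10)
) -> DesignReport:
    """Check balance and completeness of a trial against an expected design.

    The report lists: treatment/block/year count mismatches, unbalanced
    replication, duplicate (plot_id, year) keys, plot-years missing from an
    otherwise complete plot series, and soil plots with no yield series.
    Pure function: the table is never modified.
    """
    n_treat, n_block, n_years = expected
    report = DesignReport(expected=expected)
    y = table.yields

    if y.empty and table.soil.empty:
        report.issues.append("table is empty")
        return report

    if not y.empty:
        treats = sorted(y["treatment"].unique())
        if len(treats) != n_treat:
            report.issues.append(
                f"expected {n_treat} treatments, found {len(treats)}: {treats}"
            )
        blocks = y.groupby("treatment")["block"].nunique()
        bad = blocks[blocks != n_block]
        for t, b in bad.items():
            report.issues.append(f"treatment {t}: {b} blocks, expected {n_block}")
        if blocks.nunique() > 1:
            report.issues.append(
                "unbalanced replication: block counts differ across treatments"
            )
        years = sorted(y["year"].unique())
        if len(years) != n_years:
            report.issues.append(f"expected {n_years} years, found {len(years)}")

        dup = y.duplicated(subset=["plot_id", "year"])
        for _, row in y[dup].iterrows():
            report.issues.append(
                f"duplicate key (plot_id={row['plot_id']}, year={int(row['year'])})"
            )

        # every plot should cover every observed year
        full_years = set(years)
        for pid, grp in y.groupby("plot_id"):
            gap = full_years - set(grp["year"])
            for yr in sorted(gap):
                report.issues.append(f"missing plot-year (plot_id={pid}, year={yr})")

    if not table.soil.empty and not y.empty:
        orphan = set(table.soil["plot_id"]) - set(y["plot_id"])
        for pid in sorted(orphan):
            report.issues.append(f"soil plot {pid} has no yield records")

    return report
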