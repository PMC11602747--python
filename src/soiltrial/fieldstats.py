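"""Treatment-comparison statistics.

One-way ANOVA with explicit sums of squares, Shapiro–Wilk / Levene
assumption checks, pairwise comparisons rendered as a compact letter
display, a starred Pearson correlation matrix, and simple linear
regression — the standard inferential toolkit of an agronomic field trial.

Distributional machinery (F/t distributions, Shapiro–Wilk, Levene,
studentized-range comparisons) comes from :mod:`scipy.stats`; the ANOVA
decomposition and the insert–absorb letter algorithm are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

__all__ = ["AnovaResult", "AssumptionReport", "GroupLetters",
           "CorrelationMatrix", "RegressionFit", "one_way_anova",
           "check_assumptions", "pairwise_letters", "pearson_matrix",
           "fit_linear", "STAR_THRESHOLDS", "stars_for"]

#: two-sided significance stars: p < threshold -> label
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.001, "***"), (0.01, "**"), (0.05, "*"),
)


def stars_for(p: float) -> str:
    """Map a p-value to its significance stars ('' when p ≥ 0.05)."""
    if np.isnan(p):
        return ""
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return ""


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA summary for a single response."""

    response: str
    df_between: int
    df_within: int
    F: float
    p: float
    ss_between: float
    ss_within: float
    degenerate: bool = False  # zero within-group variance

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


@dataclass
class AssumptionReport:
    """Normality (per group) and homogeneity checks at a given α."""

    shapiro: pd.DataFrame  # group, n, W, p, assessable
    levene_stat: float
    levene_p: float
    alpha: float = 0.05

    @property
    def normality_ok(self) -> bool:
        assessed = self.shapiro[self.shapiro["assessable"]]
        return bool((assessed["p"] >= self.alpha).all()) if len(assessed) else False

    @property
    def homogeneity_ok(self) -> bool:
        return bool(self.levene_p >= self.alpha)


@dataclass
class GroupLetters:
    """Compact letter display: sharing a letter ⇔ nonsignificant pair."""

    letters: dict[str, str]
    method: str
    alpha: float
    pairwise_p: pd.DataFrame  # symmetric matrix of pairwise p-values
    means: pd.Series


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r with two-sided p-values and star labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    constant_variables: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RegressionFit:
    """Simple least-squares line y = slope·x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int
    stderr: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise DegenerateDataError("values and groups differ in length")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        out[g] = values[groups == g]
    return out


def one_way_anova(values, groups, response: str = "response") -> AnovaResult:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    ``F = MSB / MSW`` with ``MSB = SSB/(k−1)``, ``MSW = SSW/(N−k)`` and the
    p-value from the F(k−1, N−k) distribution.  Requires ≥ 2 groups with
    ≥ 2 observations each.  Zero within-group variance with nonzero
    between-group variance reports F = ∞, p = 0 and sets ``degenerate``.
    """
    by_group = _split_groups(values, groups)
    if len(by_group) < 2:
        raise DegenerateDataError("ANOVA needs at least 2 groups")
    for g, v in by_group.items():
        if v.size < 2:
            raise DegenerateDataError(f"group {g!r} has fewer than 2 observations")

    all_values = np.concatenate(list(by_group.values()))
    grand = all_values.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in by_group.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    dfb = len(by_group) - 1
    dfw = all_values.size - len(by_group)

    if ssw == 0.0:
        if ssb > 0.0:
            return AnovaResult(response, dfb, dfw, float("inf"), 0.0, ssb, ssw, True)
        return AnovaResult(response, dfb, dfw, 0.0, 1.0, ssb, ssw, True)

    f_stat = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f_stat, dfb, dfw))
    return AnovaResult(response, dfb, dfw, float(f_stat), p, float(ssb), float(ssw))


def check_assumptions(values, groups, alpha: float = 0.05) -> AssumptionReport:
    """Shapiro–Wilk per group and Levene's test across groups.

    Groups with fewer than 3 observations, or constant values, cannot be
    assessed for normality and are flagged (``assessable = False``) rather
    than failed.
    """
    by_group = _split_groups(values, groups)
    rows = []
    for g, v in by_group.items():
        if v.size < 3 or np.ptp(v) == 0:
            rows.append((g, v.size, np.nan, np.nan, False))
            continue
        w, p = stats.shapiro(v)
        rows.append((g, v.size, float(w), float(p), True))
    shapiro = pd.DataFrame(rows, columns=["group", "n", "W", "p", "assessable"])

    usable = [v for v in by_group.values() if v.size >= 2]
    if len(usable) >= 2 and any(np.ptp(v) > 0 for v in usable):
        stat, p = stats.levene(*usable)
        levene_stat, levene_p = float(stat), float(p)
    else:
        levene_stat, levene_p = np.nan, np.nan
    return AssumptionReport(shapiro, levene_stat, levene_p, alpha)


def _pairwise_pvalues(by_group: dict[str, np.ndarray], method: str) -> pd.DataFrame:
    names = list(by_group)
    k = len(names)
    p = pd.DataFrame(np.ones((k, k)), index=names, columns=names)

    if method == "tukey":
        res = stats.tukey_hsd(*by_group.values())
        for i in range(k):
            for j in range(i + 1, k):
                p.iloc[i, j] = p.iloc[j, i] = float(res.pvalue[i, j])
        return p

    if method == "lsd":
        # unadjusted pairwise t-tests on the pooled within-group variance
        dfw = sum(v.size for v in by_group.values()) - k
        msw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values()) / dfw
        for i in range(k):
            for j in range(i + 1, k):
                a, b = by_group[names[i]], by_group[names[j]]
                se = np.sqrt(msw * (1 / a.size + 1 / b.size))
                t = (a.mean() - b.mean()) / se
                pij = 2 * stats.t.sf(abs(t), dfw)
                p.iloc[i, j] = p.iloc[j, i] = float(pij)
        return p

    raise DegenerateDataError(f"unknown comparison method {method!r}")


def _insert_absorb(names: list[str], significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``names`` must be ordered (by descending mean); every unordered pair in
    ``significant`` ends up sharing no letter, every other pair shares at
    least one.
    """
    columns: list[set[str]] = [set(names)]
    for a, b in significant:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb columns that became subsets of others
        columns = [c for c in columns
                   if c and not any(c < other for other in columns)]
        # deduplicate while preserving order
        seen: list[set[str]] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen

    rank = {name: i for i, name in enumerate(names)}
    columns.sort(key=lambda c: min(rank[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {name: [] for name in names}
    for letter, col in zip(alphabet, columns):
        for member in col:
            letters[member].append(letter)
    return {name: "".join(sorted(ls)) for name, ls in letters.items()}


def pairwise_letters(values, groups, method: str = "tukey",
                     alpha: float = 0.05) -> GroupLetters:
    """All-pairs comparisons rendered as lowercase significance letters.

    ``method`` is ``"tukey"`` (studentized-range HSD family, default) or
    ``"lsd"`` (unadjusted pooled-variance t-tests).  Treatments sharing a
    letter do not differ significantly at ``alpha``; 'a' marks the group
    with the highest mean.  The letter set is the deterministic
    insert–absorb reduction of the pairwise significance matrix.
    """
    by_group = _split_groups(values, groups)
    one_way_anova(values, groups)  # enforce preconditions
    means = pd.Series({g: v.mean() for g, v in by_group.items()})
    ordered = list(means.sort_values(ascending=False).index)
    pmat = _pairwise_pvalues(by_group, method)
    significant = {
        (a, b)
        for i, a in enumerate(ordered)
        for b in ordered[i + 1:]
        if pmat.loc[a, b] < alpha
    }
    letters = _insert_absorb(ordered, significant)
    return GroupLetters(letters, method, alpha, pmat, means)


def pearson_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values and stars.

    Constant variables get NaN correlations and are listed in
    ``constant_variables`` instead of raising.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    data = table[variables].astype(float)
    n = len(data)
    if n < 3:
        raise DegenerateDataError("need ≥ 3 observations for correlations")

    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    constant = [v for v in variables if np.ptp(data[v].to_numpy()) == 0]
    for i in range(k):
        for j in range(i + 1, k):
            a, b = variables[i], variables[j]
            if a in constant or b in constant:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(data[a], data[b])
            r.loc[a, b] = r.loc[b, a] = float(rij)
            p.loc[a, b] = p.loc[b, a] = float(pij)
    for v in constant:
        r.loc[v, v] = np.nan
        p.loc[v, v] = np.nan
    star = p.map(stars_for)
    np.fill_diagonal(star.values, "")
    return CorrelationMatrix(r, p, star, constant)


def fit_linear(x, y) -> RegressionFit:
    """Least-squares regression of y on x with R² and the slope's p-value.

    R² equals the squared Pearson correlation of x and y (simple-regression
    identity).  Constant x leaves the slope undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DegenerateDataError("x and y differ in length")
    if x.size < 3:
        raise DegenerateDataError("need ≥ 3 points for regression")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept),
                         float(res.rvalue) ** 2, float(res.pvalue),
                         int(x.size), float(res.stderr))
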