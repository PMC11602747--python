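"""Composite soil quality index (SQI).

Three steps, each exposed separately:

1. **Scoring** — each indicator is mapped linearly onto [0, 1].
   "More is better" indicators use ``Si = (Xi − Xmin) / (Xmax − Xmin)``,
   "less is better" ones use ``Si = (Xmax − Xi) / (Xmax − Xmin)``, with the
   bounds taken over all plots jointly (one shared ruler across
   treatments) unless fixed bounds are supplied.

2. **Weighting** — the indicators are standardized and the eigenstructure
   of their correlation matrix is extracted.  The communality of indicator
   *i* is the variance captured by the retained components,
   ``ci = Σ_k λ_k v_ik²`` over retained components *k*; its weight is the
   communality share ``Wi = ci / Σ_j cj`` so that ``Σ Wi = 1``.

3. **Aggregation** — ``SQI = Σ_i Wi · Si`` per plot, hence SQI ∈ [0, 1],
   with higher values indicating better soil function.

Component retention defaults to the Kaiser rule (eigenvalue ≥ 1) and can be
a fixed count, a cumulative-variance fraction, or ``"all"`` (in which case
every communality is 1 and the weights are uniform).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateDataError
from .trial import (INDICATOR_NAMES, LESS_IS_BETTER, MORE_IS_BETTER,
                    TrialTable, default_direction_map)

__all__ = ["ScoreMatrix", "WeightVector", "SQIResult", "score_indicators",
           "pca_communalities", "weights_from_communalities", "compute_sqi",
           "sqi_pipeline"]

log = logging.getLogger(__name__)

_EIG_FLOOR = 1e-10  # eigenvalues below this are treated as numerical zeros


@dataclass
class ScoreMatrix:
    """Min-max scores (rows = plots, columns = indicators) with provenance."""

    scores: pd.DataFrame
    bounds_used: pd.DataFrame  # index = indicator, columns = xmin, xmax
    directions: dict[str, str]
    treatments: pd.Series  # plot_id -> treatment code
    dropped: list[str] = field(default_factory=list)


@dataclass
class WeightVector:
    """Communalities, normalized weights and the eigenvalue trail."""

    communalities: pd.Series
    weights: pd.Series
    retention: str
    eigenvalues: np.ndarray
    n_retained: int


@dataclass
class SQIResult:
    """Per-plot and per-treatment SQI with full provenance."""

    per_plot: pd.DataFrame        # plot_id, treatment, sqi
    per_treatment: pd.DataFrame   # treatment, mean, se, n
    weights: WeightVector
    scores: ScoreMatrix

    def rescaled(self, factor: float) -> pd.DataFrame:
        """Per-plot SQI multiplied by a display constant.

        Purely cosmetic: the canonical index lives on [0, 1] and every
        statistic in the package uses that scale.
        """
        if factor <= 0:
            raise DegenerateDataError("rescale factor must be > 0")
        out = self.per_plot.copy()
        out["sqi"] = out["sqi"] * factor
        return out


def _soil_frame(table: TrialTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, TrialTable):
        return table.soil
    return table


def score_indicators(
    table: TrialTable | pd.DataFrame,
    directions: dict[str, str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    *,
    drop_degenerate: bool = False,
) -> ScoreMatrix:
    """Score every indicator onto [0, 1] with direction-aware min-max.

    Parameters
    ----------
    table
        A :class:`~soiltrial.trial.TrialTable` or its soil frame.
    directions
        Indicator -> ``more_is_better`` / ``less_is_better``.  Defaults to
        the registry map (bulk density and pH scored less-is-better).
    bounds
        Optional fixed (xmin, xmax) per indicator; indicators not listed
        use data-derived bounds over all plots jointly.
    drop_degenerate
        A constant indicator (xmax == xmin) with data-derived bounds is an
        error by default; with this flag it is dropped with a logged
        warning instead.
    """
    soil = _soil_frame(table)
    directions = dict(default_direction_map(), **(directions or {}))
    indicators = [c for c in soil.columns if c in INDICATOR_NAMES]
    if not indicators:
        raise DegenerateDataError("no indicator columns found")

    scores: dict[str, np.ndarray] = {}
    rows = []
    dropped: list[str] = []
    for name in indicators:
        x = soil[name].to_numpy(dtype=float)
        if bounds is not None and name in bounds:
            xmin, xmax = bounds[name]
        else:
            xmin, xmax = float(np.min(x)), float(np.max(x))
        if xmax == xmin:
            if drop_degenerate:
                log.warning("dropping degenerate indicator %s (constant at %g)", name, xmin)
                dropped.append(name)
                continue
            raise DegenerateDataError(
                f"indicator {name!r} is constant ({xmin}); cannot min-max score"
            )
        if directions.get(name, MORE_IS_BETTER) == LESS_IS_BETTER:
            s = (xmax - x) / (xmax - xmin)
        else:
            s = (x - xmin) / (xmax - xmin)
        scores[name] = np.clip(s, 0.0, 1.0)
        rows.append((name, xmin, xmax))

    frame = pd.DataFrame(scores, index=pd.Index(soil["plot_id"], name="plot_id"))
    bounds_used = pd.DataFrame(rows, columns=["indicator", "xmin", "xmax"]).set_index("indicator")
    treatments = pd.Series(soil["treatment"].to_numpy(),
                           index=frame.index, name="treatment")
    return ScoreMatrix(frame, bounds_used, directions, treatments, dropped)


def pca_communalities(
    values: TrialTable | pd.DataFrame,
    retention: str | int | float = "kaiser",
) -> pd.Series:
    """Communalities of the indicators under a retained-component PCA.

    The columns are z-scored and the eigendecomposition of their
    correlation matrix is taken; the communality of each indicator is the
    summed squared loading over the retained components (``Σ λ_k v_ik²``),
    always in [0, 1].

    ``retention`` is ``"kaiser"`` (eigenvalue ≥ 1, default), ``"all"``, a
    fixed component count (int ≥ 1), or a cumulative-variance fraction
    (float in (0, 1)).  Eigenvalues below 1e-10 are discarded as numerical
    zeros (rank deficiency) with a logged note.
    """
    soil = _soil_frame(values)
    cols = [c for c in soil.columns if c not in ("plot_id", "treatment")]
    x = soil[cols].to_numpy(dtype=float)
    n, p = x.shape
    if n < 3:
        raise DegenerateDataError(f"need ≥ 3 plots for PCA, got {n}")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateDataError(f"constant indicator(s) {bad}; cannot standardize")

    corr = np.corrcoef(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    nonzero = eigval > _EIG_FLOOR
    if not nonzero.all():
        log.info("discarding %d near-zero eigenvalue(s) (rank deficiency)",
                 int((~nonzero).sum()))
    eigval, eigvec = eigval[nonzero], eigvec[:, nonzero]

    if retention == "kaiser":
        keep = int(np.sum(eigval >= 1.0)) or 1
    elif retention == "all":
        keep = eigval.size
    elif isinstance(retention, int) and not isinstance(retention, bool):
        if retention < 1:
            raise DegenerateDataError("retention count must be ≥ 1")
        keep = min(retention, eigval.size)
    elif isinstance(retention, float):
        if not (0 < retention <= 1):
            raise DegenerateDataError("cumulative-variance retention must be in (0, 1]")
        cum = np.cumsum(eigval) / p
        keep = int(np.searchsorted(cum, retention) + 1)
        keep = min(keep, eigval.size)
    else:
        raise DegenerateDataError(f"unknown retention rule {retention!r}")

    load_sq = (eigvec[:, :keep] ** 2) * eigval[:keep]
    comm = np.clip(load_sq.sum(axis=1), 0.0, 1.0)
    out = pd.Series(comm, index=pd.Index(cols, name="indicator"), name="communality")
    out.attrs["eigenvalues"] = eigval
    out.attrs["n_retained"] = keep
    out.attrs["retention"] = str(retention)
    return out


def weights_from_communalities(communalities: pd.Series) -> WeightVector:
    """Normalize communalities into weights: ``Wi = ci / Σ cj``."""
    c = communalities.astype(float)
    if (c < 0).any():
        raise DegenerateDataError("communalities must be ≥ 0")
    total = float(c.sum())
    if total <= 0:
        raise DegenerateDataError("all communalities are zero; weights undefined")
    w = c / total
    return WeightVector(
        communalities=c,
        weights=w.rename("weight"),
        retention=c.attrs.get("retention", "unspecified"),
        eigenvalues=np.asarray(c.attrs.get("eigenvalues", [])),
        n_retained=int(c.attrs.get("n_retained", 0)),
    )


def compute_sqi(scores: ScoreMatrix, weights: WeightVector) -> SQIResult:
    """Aggregate scores into the per-plot SQI and per-treatment summaries.

    The score columns and weight index must name the same indicators;
    any mismatch raises an alignment error listing the symmetric
    difference.  Treatment summaries are arithmetic mean ± standard error.
    """
    score_cols = set(scores.scores.columns)
    weight_idx = set(weights.weights.index)
    if score_cols != weight_idx:
        diff = sorted(score_cols ^ weight_idx)
        raise AlignmentError(f"scores and weights disagree on indicators: {diff}")

    w = weights.weights.reindex(scores.scores.columns)
    sqi = scores.scores.to_numpy() @ w.to_numpy()
    per_plot = pd.DataFrame({
        "plot_id": scores.scores.index,
        "treatment": scores.treatments.to_numpy(),
        "sqi": sqi,
    })
    grp = per_plot.groupby("treatment", sort=False)["sqi"]
    per_treatment = pd.DataFrame({
        "mean": grp.mean(),
        "se": grp.std(ddof=1) / np.sqrt(grp.count()),
        "n": grp.count(),
    }).reset_index()
    return SQIResult(per_plot, per_treatment, weights, scores)


def sqi_pipeline(
    table: TrialTable | pd.DataFrame,
    directions: dict[str, str] | None = None,
    retention: str | int | float = "kaiser",
    *,
    pca_on: str = "raw",
    bounds: dict[str, tuple[float, float]] | None = None,
) -> SQIResult:
    """Run scoring → weighting → aggregation in one call.

    ``pca_on`` selects what feeds the communality PCA: ``"raw"`` (default,
    z-scored measurements) or ``"scores"`` (the min-max scores).
    """
    scores = score_indicators(table, directions, bounds)
    if pca_on == "raw":
        soil = _soil_frame(table)
        basis = soil[["plot_id", "treatment", *scores.scores.columns]]
    elif pca_on == "scores":
        basis = scores.scores.reset_index().assign(treatment=scores.treatments.to_numpy())
    else:
        raise DegenerateDataError(f"pca_on must be 'raw' or 'scores', got {pca_on!r}")
    comm = pca_communalities(basis, retention)
    weights = weights_from_communalities(comm)
    return compute_sqi(scores, weights)
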