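"""Cross-validation and correlation statistics.

Leave-one-out cross-validation of the capacity model: each member of fit set
M is held out in turn, the constants are re-estimated on the remainder, and
the held-out variant's relative capacity (percent of wild type) is predicted.
Agreement between predicted (in silico) and observed (in vitro) capacities is
summarised by Pearson's correlation coefficient with a two-sided t-test
p-value; an ordinary least-squares line (observed on predicted) is reported
for plotting.

ND (not-detected) observations never enter fit sets, but when they are
correlated against predictions they are scored as zero capacity and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError
from .model import (
    FitResult,
    ModelParams,
    Panel,
    fit_parameters,
    predict,
)

__all__ = [
    "CVFold",
    "CorrelationResult",
    "pearson_r",
    "pearson_p",
    "correlate",
    "loo_cross_validate",
]


@dataclass
class CVFold:
    """One leave-one-out fold."""

    held_out_variant: str
    fitted_params: ModelParams
    predicted: float
    observed: float
    fold_sse: float


@dataclass
class CorrelationResult:
    """Pearson correlation with the regression line for plotting."""

    r: float
    n: int
    p: float
    slope: float
    intercept: float
    nd_variants: list[str] = field(default_factory=list)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 points, or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    # guard against |r| creeping past 1 by a few ulp on collinear data
    return float(np.clip(r, -1.0, 1.0))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a correlation coefficient at sample size n.

    Uses ``t = r sqrt(n - 2) / sqrt(1 - r^2)`` against Student's t with
    ``n - 2`` degrees of freedom. A perfect correlation returns the smallest
    positive float with a warning.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: p-value below floating-point resolution")
        return float(np.finfo(float).tiny)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate(predicted, observed, nd_variants: list[str] | None = None) -> CorrelationResult:
    """Pearson r, its p-value, and the OLS line of observed on predicted."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    r = pearson_r(predicted, observed)
    p = pearson_p(r, predicted.size)
    line = stats.linregress(predicted, observed)
    return CorrelationResult(
        r=r,
        n=int(predicted.size),
        p=p,
        slope=float(line.slope),
        intercept=float(line.intercept),
        nd_variants=list(nd_variants or []),
    )


def loo_cross_validate(
    panel: Panel,
    free_epsilon: bool = False,
    n_restarts: int = 20,
    seed: int = 0,
    include_nd: bool = False,
) -> tuple[list[CVFold], CorrelationResult]:
    """Leave-one-out cross-validation over fit set M.

    For each member of M the panel is refitted without it and the member's
    relative capacity is predicted with the fold's constants. Observations
    are expressed as percent of the wild-type member's observed capacity
    when a wild-type record is present, else taken as given (Pearson r is
    scale-invariant, so the correlation is unaffected either way).

    With ``include_nd`` the ND variants (outside M) are appended to the
    correlation as observed-zero points, predicted with the full-panel fit.

    Raises
    ------
    FitError
        If any fold would be under-determined (the message names the fold).
    """
    members = panel.fit_set
    n_free = 4 if free_epsilon else 3
    if len(members) - 1 < n_free:
        raise FitError(
            f"LOO infeasible: folds would have {len(members) - 1} members "
            f"for {n_free} free constants"
        )
    wild_obs = None
    for s, r in members:
        if s.variant == panel.wild_summary.variant:
            wild_obs = r.v_c
    folds: list[CVFold] = []
    for summary, record in members:
        sub = panel.without(summary.variant)
        try:
            fit = fit_parameters(
                sub, free_epsilon=free_epsilon, n_restarts=n_restarts, seed=seed
            )
        except FitError as exc:
            raise FitError(
                f"fold holding out {summary.variant!r} failed: {exc}"
            ) from exc
        predicted = predict(
            summary, record.genotype, fit.params, wild_summary=panel.wild_summary
        ).P_c_relative
        observed = record.v_c
        if wild_obs:
            observed = 100.0 * record.v_c / wild_obs
        folds.append(
            CVFold(
                held_out_variant=summary.variant,
                fitted_params=fit.params,
                predicted=float(predicted),
                observed=float(observed),
                fold_sse=fit.sse,
            )
        )
    preds = [f.predicted for f in folds]
    obs = [f.observed for f in folds]
    nd_names: list[str] = []
    if include_nd:
        full = fit_parameters(
            panel, free_epsilon=free_epsilon, n_restarts=n_restarts, seed=seed
        )
        for summary, record in panel.members:
            if record.is_nd:
                pred = predict(
                    summary,
                    record.genotype,
                    full.params,
                    wild_summary=panel.wild_summary,
                ).P_c_relative
                preds.append(float(pred))
                obs.append(0.0)
                nd_names.append(summary.variant)
    corr = correlate(preds, obs, nd_variants=nd_names)
    return folds, corr
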