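"""Inferential layer: rank correlation, chi-square, two-way ANOVA, selection.

Spearman correlations use mid-ranks for ties, an exact permutation p-value at
small n and the t approximation otherwise.  The model-selection procedure for
the activity metrics follows the usual regression workflow: variance-inflation
screening of collinear predictors, Cook's-distance influence flags, then
backward elimination in which a predictor is dropped when removing it either
improves the AIC or is not significantly worse by a likelihood-ratio test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import (
    InputError,
    InsufficientDataError,
    SingularDesignError,
    UndefinedStatisticError,
)

__all__ = [
    "CorrelationResult",
    "ModelSelectionResult",
    "spearman",
    "chi_square_uniform",
    "two_way_anova",
    "bonferroni_alpha",
    "sidak_alpha",
    "select_rhythm_model",
]

#: Below this n the permutation distribution of rho is enumerated exactly.
EXACT_PERMUTATION_N = 10


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with its p-value and sample size."""

    rho: float
    p_value: float
    n: int
    method: str = "spearman"


@dataclass(frozen=True)
class ModelSelectionResult:
    """Outcome of the VIF / Cook's distance / AIC+LRT selection procedure."""

    retained_predictors: tuple[str, ...]
    vif_dropped: tuple[str, ...]
    influential_points: tuple[int, ...]
    aic_trace: tuple[tuple[str, float], ...] = field(default_factory=tuple)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    return float(np.sum(rx * ry) / denom)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    For n below :data:`EXACT_PERMUTATION_N` the two-sided p-value is exact,
    from full enumeration of the n! orderings of one margin; for larger n the
    usual t approximation on ``rho * sqrt((n-2)/(1-rho^2))`` is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise InsufficientDataError("Spearman needs n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedStatisticError("zero rank variance")
    rho = _rho_from_ranks(rx, ry)
    if n < EXACT_PERMUTATION_N:
        perms = np.array(list(itertools.permutations(range(n))))
        permuted = ry[perms] - ry.mean()
        rxc = rx - rx.mean()
        rhos = (permuted @ rxc) / np.sqrt(
            np.sum(rxc**2) * np.sum((ry - ry.mean()) ** 2)
        )
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "spearman-exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "spearman-t"
    return CorrelationResult(rho=rho, p_value=min(max(p, 0.0), 1.0), n=n, method=method)


def chi_square_uniform(counts: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square of equal strain split within each emergence rank.

    ``counts`` has one row per rank and one column per strain (e.g. AB, TL).
    The expected count in each cell is the rank total divided by the number of
    strains; the statistic sums (O-E)^2/E over all cells with one degree of
    freedom per rank per extra strain.
    """
    observed = counts.to_numpy(dtype=float)
    if observed.ndim != 2 or observed.shape[1] < 2:
        raise InputError("counts must be ranks x strains with >= 2 strains")
    row_totals = observed.sum(axis=1, keepdims=True)
    if np.any(row_totals == 0):
        raise SingularDesignError("a rank with zero total count has no expectation")
    expected = np.broadcast_to(row_totals / observed.shape[1], observed.shape)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    df = observed.shape[0] * (observed.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, df))
    return statistic, df, p


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_time: str = "time",
    factor_style: str = "style",
) -> pd.DataFrame:
    """Two-way ANOVA (type-II sums of squares) with interaction.

    Both factors need at least two levels; the layout may be unbalanced.
    Returns the statsmodels ANOVA table (sum_sq, df, F, PR(>F)) with rows for
    each main effect, the interaction and the residual.
    """
    for factor in (factor_time, factor_style):
        if data[factor].nunique() < 2:
            raise SingularDesignError(f"factor {factor!r} has fewer than 2 levels")
    frame = data.rename(
        columns={value: "_y", factor_time: "_t", factor_style: "_s"}
    )[["_y", "_t", "_s"]]
    model = ols("_y ~ C(_t) * C(_s)", data=frame).fit()
    table = anova_lm(model, typ=2)
    table.index = [
        factor_time,
        factor_style,
        f"{factor_time}:{factor_style}",
        "residual",
    ]
    return table


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison alpha: ``alpha / m``."""
    if m < 1:
        raise InputError("m must be >= 1")
    return alpha / m


def sidak_alpha(alpha: float, m: int) -> float:
    """Sidak-corrected per-comparison alpha: ``1 - (1 - alpha)^(1/m)``."""
    if m < 1:
        raise InputError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def _ols_ssr(design: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(np.sum(resid**2))


def select_rhythm_model(
    predictors: pd.DataFrame,
    response,
    vif_threshold: float = 5.0,
    cooks_threshold: float | None = None,
    alpha: float = 0.05,
) -> ModelSelectionResult:
    """Select the rhythm metrics that predict emergence rank.

    Procedure: (1) iteratively drop the predictor with the highest variance
    inflation factor while any VIF exceeds ``vif_threshold``; (2) flag (but do
    not remove) observations with Cook's distance above ``4/n``; (3) backward
    elimination on the remaining predictors -- at each step the least
    significant predictor is dropped if removing it improves the AIC or its
    likelihood-ratio p-value is at least ``alpha``.  The emergence rank
    response is treated as numeric.
    """
    names = list(predictors.columns)
    if len(names) < 1:
        raise InputError("need at least one candidate predictor")
    y = np.asarray(response, dtype=float)
    x_all = predictors.to_numpy(dtype=float)
    n = y.size
    if x_all.shape[0] != n:
        raise InputError("predictors and response length mismatch")
    if n <= len(names) + 2:
        raise InsufficientDataError("need n > n_predictors + 2 observations")

    # --- 1. multicollinearity screen -------------------------------------
    vif_dropped: list[str] = []
    keep = list(range(len(names)))
    while len(keep) > 1:
        design = sm.add_constant(x_all[:, keep], has_constant="add")
        with np.errstate(divide="ignore"):
            vifs = np.array(
                [variance_inflation_factor(design, j + 1) for j in range(len(keep))]
            )
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        worst = int(np.argmax(vifs))
        if vifs[worst] > vif_threshold:
            vif_dropped.append(names[keep[worst]])
            keep.pop(worst)
        else:
            break
    x = x_all[:, keep]
    kept_names = [names[j] for j in keep]

    # --- 2. influence flags ----------------------------------------------
    full = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    if full.df_resid <= 0 or full.ssr <= 1e-12:
        influential: tuple[int, ...] = ()
    else:
        cooks = full.get_influence().cooks_distance[0]
        threshold = cooks_threshold if cooks_threshold is not None else 4.0 / n
        influential = tuple(int(i) for i in np.flatnonzero(cooks > threshold))

    # --- 3. backward elimination (AIC + LRT) ------------------------------
    def ssr_of(cols: list[int]) -> float:
        design = (
            sm.add_constant(x[:, cols], has_constant="add") if cols else np.ones((n, 1))
        )
        return max(_ols_ssr(design, y), 1e-300)

    def aic_of(cols: list[int]) -> float:
        return n * np.log(ssr_of(cols) / n) + 2.0 * (len(cols) + 1)

    cols = list(range(len(kept_names)))
    trace: list[tuple[str, float]] = [
        ("+".join(kept_names[c] for c in cols) or "intercept", aic_of(cols))
    ]
    while cols:
        current_aic = aic_of(cols)
        current_ssr = ssr_of(cols)
        candidate: int | None = None
        candidate_key: tuple[float, float] | None = None
        for c in cols:
            sub = [k for k in cols if k != c]
            lr = n * (np.log(ssr_of(sub)) - np.log(current_ssr))
            p = float(sps.chi2.sf(max(lr, 0.0), 1))
            sub_aic = aic_of(sub)
            if p >= alpha or sub_aic < current_aic:
                key = (-p, sub_aic)
                if candidate is None or key < candidate_key:
                    candidate, candidate_key = c, key
        if candidate is None:
            break
        cols.remove(candidate)
        trace.append(
            ("+".join(kept_names[c] for c in cols) or "intercept", aic_of(cols))
        )
    retained = tuple(kept_names[c] for c in cols)
    return ModelSelectionResult(
        retained_predictors=retained,
        vif_dropped=tuple(vif_dropped),
        influential_points=influential,
        aic_trace=tuple(trace),
    )
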