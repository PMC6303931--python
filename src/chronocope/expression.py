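"""Relative qPCR quantification (delta-delta-Ct) and expression time series.

Ct tables carry technical triplicates per (fish, gene, timepoint) plus the
housekeeping gene ippA.  Triplicates are averaged on the Ct scale, each target
gene is normalised against ippA measured in the same fish at the same
timepoint (delta-Ct), and relative expression is ``2^(-dCt)``.  The classic
pairwise contrast between early and late emergers is ``2^(dCt_LE - dCt_EE)``,
the fold change of the proactive over the reactive fish.

Because the delta-Ct subtraction removes the housekeeping level, shifting
every Ct value in the table by a constant changes nothing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompleteDesignError, InputError
from .rhythm import TimeSeries

__all__ = [
    "CtRecord",
    "delta_ct",
    "fold_change_ee_vs_le",
    "average_technical_replicates",
    "relative_expression",
    "expression_series_per_fish",
    "expression_series_by_rank",
]

_CT_COLUMNS = ["individual_id", "gene", "time_hct", "ct1", "ct2", "ct3"]


@dataclass(frozen=True)
class CtRecord:
    """Technical triplicate of one gene in one fish at one timepoint."""

    individual_id: str
    gene: str
    time_hct: float
    ct_replicates: tuple[float, float, float]

    @property
    def ct_mean(self) -> float:
        return float(np.mean(self.ct_replicates))


def delta_ct(target_ct: float, housekeeping_ct: float) -> float:
    """Housekeeping-normalised Ct: ``target - housekeeping``."""
    return float(target_ct) - float(housekeeping_ct)


def fold_change_ee_vs_le(delta_ct_ee: float, delta_ct_le: float) -> float:
    """Fold change of EE over LE expression: ``2^(dCt_LE - dCt_EE)``.

    A lower delta-Ct means more transcript, so subtracting the EE value from
    the LE value and exponentiating gives how many fold higher the proactive
    fish expresses the gene.  Swapping the arguments inverts the result.
    """
    return float(2.0 ** (delta_ct_le - delta_ct_ee))


def average_technical_replicates(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse ct1..ct3 to their mean on the Ct (log) scale."""
    missing = [c for c in _CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise InputError(f"Ct table is missing columns {missing}")
    out = ct_table[_CT_COLUMNS[:3]].copy()
    out["ct"] = ct_table[["ct1", "ct2", "ct3"]].mean(axis=1)
    if (out["ct"] <= 0).any():
        raise InputError("Ct values must be positive")
    return out


def relative_expression(
    ct_table: pd.DataFrame,
    housekeeping_gene: str = "ippA",
    normalise: bool = True,
) -> pd.DataFrame:
    """Tidy per-fish relative expression from a triplicate Ct table.

    Returns one row per (fish, target gene, timepoint) with ``delta_ct`` and
    ``rel_expr = 2^(-delta_ct)``; with ``normalise`` each gene is divided by
    its grand mean over all fish and timepoints, which puts genes on a common
    scale while preserving the between-fish level differences that the
    rank-correlation analyses need.
    """
    averaged = average_technical_replicates(ct_table)
    hk = averaged[averaged["gene"] == housekeeping_gene]
    if hk.empty:
        raise InputError(f"no housekeeping gene {housekeeping_gene!r} in table")
    duplicates = hk.duplicated(subset=["individual_id", "time_hct"])
    if duplicates.any():
        raise InputError("more than one housekeeping record per fish/timepoint")
    targets = averaged[averaged["gene"] != housekeeping_gene]
    merged = targets.merge(
        hk[["individual_id", "time_hct", "ct"]],
        on=["individual_id", "time_hct"],
        suffixes=("", "_hk"),
        how="left",
    )
    if merged["ct_hk"].isna().any():
        gaps = merged.loc[
            merged["ct_hk"].isna(), ["individual_id", "time_hct"]
        ].drop_duplicates()
        raise IncompleteDesignError(
            f"missing housekeeping measurements for: {gaps.to_dict('records')}"
        )
    merged["delta_ct"] = merged["ct"] - merged["ct_hk"]
    merged["rel_expr"] = 2.0 ** (-merged["delta_ct"])
    if normalise:
        merged["rel_expr"] = merged["rel_expr"] / merged.groupby("gene")[
            "rel_expr"
        ].transform("mean")
    return merged[["individual_id", "gene", "time_hct", "delta_ct", "rel_expr"]]


def _check_complete(
    table: pd.DataFrame, keys: list[str], expected_times: np.ndarray
) -> None:
    gaps = []
    for key, sub in table.groupby(keys):
        have = np.sort(sub["time_hct"].unique())
        missing = sorted(set(expected_times) - set(have))
        if missing:
            gaps.append((key, missing))
    if gaps:
        raise IncompleteDesignError(f"missing timepoints: {gaps}")


def expression_series_per_fish(
    ct_table: pd.DataFrame, housekeeping_gene: str = "ippA"
) -> dict[tuple[str, str], TimeSeries]:
    """Relative-expression series keyed by (individual_id, gene)."""
    rel = relative_expression(ct_table, housekeeping_gene=housekeeping_gene)
    out: dict[tuple[str, str], TimeSeries] = {}
    for (iid, gene), sub in rel.groupby(["individual_id", "gene"]):
        sub = sub.sort_values("time_hct")
        out[(str(iid), str(gene))] = TimeSeries(
            times=sub["time_hct"].to_numpy(float),
            values=sub["rel_expr"].to_numpy(float),
            channel=str(gene),
            units="relative",
        )
    return out


def expression_series_by_rank(
    ct_table: pd.DataFrame,
    ranks: pd.DataFrame,
    housekeeping_gene: str = "ippA",
) -> dict[tuple[str, int], TimeSeries]:
    """Mean relative-expression series keyed by (gene, emergence rank).

    ``ranks`` maps ``individual_id`` to ``rank``.  Delta-Ct values are
    averaged across fish within each (gene, rank, timepoint) cell before
    exponentiation, and every (gene, rank) series must cover all sampling
    timepoints; gaps raise an error listing them.
    """
    rel = relative_expression(
        ct_table, housekeeping_gene=housekeeping_gene, normalise=False
    )
    merged = rel.merge(ranks[["individual_id", "rank"]], on="individual_id")
    if merged.empty:
        raise InputError("no overlap between Ct table and rank table")
    expected_times = np.sort(rel["time_hct"].unique())
    _check_complete(merged, ["gene", "rank"], expected_times)
    cell = (
        merged.groupby(["gene", "rank", "time_hct"])["delta_ct"]
        .mean()
        .reset_index()
    )
    cell["rel_expr"] = 2.0 ** (-cell["delta_ct"])
    gene_mean = cell.groupby("gene")["rel_expr"].transform("mean")
    cell["rel_expr"] = cell["rel_expr"] / gene_mean
    out: dict[tuple[str, int], TimeSeries] = {}
    for (gene, rank), sub in cell.groupby(["gene", "rank"]):
        sub = sub.sort_values("time_hct")
        out[(str(gene), int(rank))] = TimeSeries(
            times=sub["time_hct"].to_numpy(float),
            values=sub["rel_expr"].to_numpy(float),
            channel=str(gene),
            units="relative",
        )
    return out
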