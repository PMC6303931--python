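"""End-to-end study orchestration: generate, score, quantify, correlate.

``run_full_study`` reproduces the full analysis design on a synthetic cohort:
group emergence ranking (rank 1 = early emerger), random elimination of two
fish per group, qPCR / hormone sampling at the six hCT timepoints, six days of
activity recording (three LD, three LL), rhythm metrics per fish and channel,
Spearman correlations of every metric against emergence rank, and the
VIF / Cook's distance / AIC+LRT model selection on the activity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .behavior import agr_frequency, random_elimination, rank_emergence
from .behavior import MirrorRecord
from .errors import ConfigurationError, UndefinedStatisticError
from .expression import expression_series_by_rank, expression_series_per_fish
from .rhythm import TimeSeries, rhythm_metrics
from .stats import ModelSelectionResult, select_rhythm_model, spearman
from .synthetic import (
    GENE_CHANNELS,
    HORMONE_CHANNELS,
    LL_START_HCT,
    SAMPLING_TIMES_HCT,
    Cohort,
    CohortConfig,
    generate_cohort,
    make_ct_table,
    make_hormone_table,
    make_latency_table,
    make_mirror_table,
    simulate_activity_trace,
)

__all__ = ["RunConfig", "StudyResult", "run_full_study", "make_report"]

#: Versioned output schemas; tests pin these.
METRICS_COLUMNS = [
    "individual_id",
    "channel",
    "regime",
    "auc",
    "amplitude",
    "acrophase",
    "rhythm_strength",
    "vmax",
]
CORRELATION_COLUMNS = ["channel", "metric", "regime", "rho", "p_value", "n"]
SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """What to run and where to put it."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    channels: tuple[str, ...] = GENE_CHANNELS + HORMONE_CHANNELS + ("activity",)
    regimes: tuple[str, ...] = ("LD", "LL")
    n_eliminate: int = 2
    output_dir: str | Path | None = None
    make_figures: bool = False

    def __post_init__(self) -> None:
        for ch in self.channels:
            self.cohort.channel(ch)  # raises ConfigurationError if unknown
        for regime in self.regimes:
            if regime not in ("LD", "LL"):
                raise ConfigurationError(f"unknown regime {regime!r}")
        if not 0 <= self.n_eliminate < self.cohort.group_size:
            raise ConfigurationError("n_eliminate must be in [0, group_size)")


@dataclass
class StudyResult:
    """All tables produced by one study run."""

    config: RunConfig
    roster: pd.DataFrame
    emergence: pd.DataFrame
    mirror: pd.DataFrame
    metrics: pd.DataFrame
    correlations: pd.DataFrame
    selection: ModelSelectionResult | None
    mean_series: dict[tuple[str, int], TimeSeries] = field(default_factory=dict)


def _rank_cohort(cohort: Cohort) -> pd.DataFrame:
    """Group-emergence ranks (no cutoff: the session runs until all emerge)."""
    latency = make_latency_table(cohort, session="group")
    frames = []
    for gid, sub in latency.groupby("group_id", sort=True):
        records = rank_emergence(
            list(zip(sub["individual_id"], sub["latency_s"])), cutoff=None
        )
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": [r.individual_id for r in records],
                    "group_id": gid,
                    "latency_s": [r.latency_s for r in records],
                    "rank": [r.rank for r in records],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _retained_ids(cohort: Cohort, emergence: pd.DataFrame, n_eliminate: int) -> list[str]:
    retained: list[str] = []
    for gid, sub in emergence.groupby("group_id", sort=True):
        rng = substream(cohort.config.seed, gid, "elimination")
        retained.extend(
            random_elimination(list(sub["individual_id"]), n_eliminate, rng)
        )
    return retained


def _activity_metrics(ind_id: str, trace: TimeSeries, regimes) -> list[dict]:
    rows = []
    if "LD" in regimes:
        ld = trace.window(trace.times[0], LL_START_HCT)
        m = rhythm_metrics(ld, with_strength=True, with_vmax=True)
        rows.append(
            dict(
                individual_id=ind_id,
                channel="activity",
                regime="LD",
                auc=m.auc,
                amplitude=m.amplitude,
                acrophase=m.acrophase,
                rhythm_strength=m.rhythm_strength,
                vmax=m.vmax,
            )
        )
    if "LL" in regimes:
        ll = trace.window(LL_START_HCT, np.inf)
        m = rhythm_metrics(ll, with_strength=True, with_vmax=False)
        rows.append(
            dict(
                individual_id=ind_id,
                channel="activity",
                regime="LL",
                auc=m.auc,
                amplitude=m.amplitude,
                acrophase=m.acrophase,
                rhythm_strength=m.rhythm_strength,
                vmax=np.nan,
            )
        )
    return rows


def run_full_study(config: RunConfig) -> StudyResult:
    """Run the whole pipeline; deterministic given the cohort seed."""
    cohort = generate_cohort(config.cohort)
    emergence = _rank_cohort(cohort)
    retained = _retained_ids(cohort, emergence, config.n_eliminate)
    retained_set = set(retained)
    analysed = emergence[emergence["individual_id"].isin(retained_set)]
    rank_of = dict(zip(analysed["individual_id"], analysed["rank"]))
    individuals = [i for i in cohort.individuals if i.id in retained_set]

    # behavioural scoring -------------------------------------------------
    mirror = make_mirror_table(cohort)
    mirror = mirror[mirror["individual_id"].isin(retained_set)].copy()
    freqs = []
    for row in mirror.itertuples(index=False):
        rec = MirrorRecord(
            individual_id=row.individual_id,
            agr_count=int(row.agr_count),
            frz_s=float(row.frz_s),
            lfa_s=float(row.lfa_s),
            duration=float(row.duration_s),
        )
        freqs.append(agr_frequency(rec))
    mirror["agr_freq_per_s"] = [np.nan if f is None else f for f in freqs]
    mirror["excluded"] = [f is None for f in freqs]

    # rhythm metrics per fish and channel ---------------------------------
    metric_rows: list[dict] = []
    gene_channels = [c for c in config.channels if c in GENE_CHANNELS]
    hormone_channels = [c for c in config.channels if c in HORMONE_CHANNELS]
    mean_series: dict[tuple[str, int], TimeSeries] = {}
    if gene_channels:
        ct_table = make_ct_table(cohort, individuals=individuals)
        per_fish = expression_series_per_fish(ct_table)
        for (iid, gene), series in sorted(per_fish.items()):
            if gene not in gene_channels:
                continue
            m = rhythm_metrics(series)
            metric_rows.append(
                dict(
                    individual_id=iid,
                    channel=gene,
                    regime="LD",
                    auc=m.auc,
                    amplitude=m.amplitude,
                    acrophase=m.acrophase,
                    rhythm_strength=np.nan,
                    vmax=np.nan,
                )
            )
        ranks_frame = analysed[["individual_id", "rank"]]
        mean_series = expression_series_by_rank(ct_table, ranks_frame)
    if hormone_channels:
        hormones = make_hormone_table(cohort, individuals=individuals)
        for (iid, channel), sub in hormones.groupby(["individual_id", "channel"]):
            if channel not in hormone_channels:
                continue
            sub = sub.sort_values("time_hct")
            series = TimeSeries(
                times=sub["time_hct"].to_numpy(float),
                values=sub["concentration"].to_numpy(float),
                channel=str(channel),
            )
            m = rhythm_metrics(series)
            metric_rows.append(
                dict(
                    individual_id=iid,
                    channel=channel,
                    regime="LD",
                    auc=m.auc,
                    amplitude=m.amplitude,
                    acrophase=m.acrophase,
                    rhythm_strength=np.nan,
                    vmax=np.nan,
                )
            )
    if "activity" in config.channels:
        for ind in individuals:
            trace = simulate_activity_trace(ind, cohort.config)
            metric_rows.extend(_activity_metrics(ind.id, trace, config.regimes))
    metrics = pd.DataFrame(metric_rows, columns=METRICS_COLUMNS)

    # correlations against emergence rank ---------------------------------
    corr_rows: list[dict] = []

    def _corr(channel: str, metric: str, regime: str, frame: pd.DataFrame, col: str):
        sub = frame.dropna(subset=[col])
        ranks = sub["individual_id"].map(rank_of)
        ok = ranks.notna()
        if ok.sum() < 3:
            return
        try:
            res = spearman(
                ranks[ok].to_numpy(float), sub.loc[ok, col].to_numpy(float)
            )
        except UndefinedStatisticError:
            # a metric that is constant across fish has no rank correlation
            return
        corr_rows.append(
            dict(
                channel=channel,
                metric=metric,
                regime=regime,
                rho=res.rho,
                p_value=res.p_value,
                n=res.n,
            )
        )

    for (channel, regime), sub in metrics.groupby(["channel", "regime"], sort=True):
        for metric in ("auc", "amplitude", "rhythm_strength", "vmax"):
            if sub[metric].notna().sum() >= 3:
                _corr(channel, metric, regime, sub, metric)
    _corr("mirror", "agr_frequency", "", mirror, "agr_freq_per_s")
    weight = cohort.roster()
    weight = weight[weight["individual_id"].isin(retained_set)]
    _corr("body", "weight", "", weight, "body_weight_mg")

    correlations = pd.DataFrame(corr_rows, columns=CORRELATION_COLUMNS)

    # model selection on activity metrics ---------------------------------
    selection: ModelSelectionResult | None = None
    if "activity" in config.channels and "LD" in config.regimes:
        act = metrics[(metrics["channel"] == "activity") & (metrics["regime"] == "LD")]
        act = act.set_index("individual_id")
        predictors = act[["auc", "amplitude", "rhythm_strength", "vmax"]]
        response = act.index.map(rank_of).to_numpy(float)
        selection = select_rhythm_model(predictors, response)

    result = StudyResult(
        config=config,
        roster=cohort.roster(),
        emergence=analysed.reset_index(drop=True),
        mirror=mirror.reset_index(drop=True),
        metrics=metrics,
        correlations=correlations,
        selection=selection,
        mean_series=mean_series,
    )
    if config.output_dir is not None:
        _write_bundle(result, Path(config.output_dir), cohort)
    return result


def _write_bundle(result: StudyResult, outdir: Path, cohort: Cohort) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.roster.to_csv(outdir / "roster.csv", index=False)
    result.emergence.to_csv(outdir / "emergence.csv", index=False)
    result.mirror.to_csv(outdir / "mirror.csv", index=False)
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    result.correlations.to_csv(outdir / "correlations.csv", index=False)
    if result.selection is not None:
        sel = result.selection
        lines = [
            f"retained: {', '.join(sel.retained_predictors) or '(none)'}",
            f"vif_dropped: {', '.join(sel.vif_dropped) or '(none)'}",
            f"influential_points: {len(sel.influential_points)}",
        ] + [f"aic[{model}] = {aic:.4f}" for model, aic in sel.aic_trace]
        (outdir / "selection.txt").write_text("\n".join(lines) + "\n")
    (outdir / "report.md").write_text(make_report(result))
    if result.config.make_figures:
        _write_figures(result, cohort, outdir / "figures")


def _write_figures(result: StudyResult, cohort: Cohort, figdir: Path) -> None:
    """Diagnostic time-course and actogram plots (not publication replicas)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    by_gene: dict[str, list[tuple[int, TimeSeries]]] = {}
    for (gene, rank), series in result.mean_series.items():
        by_gene.setdefault(gene, []).append((rank, series))
    for gene, entries in by_gene.items():
        fig, ax = plt.subplots(figsize=(5, 3))
        for rank, series in sorted(entries):
            if rank in (1, result.config.cohort.group_size):
                label = "EE" if rank == 1 else "LE"
                ax.plot(series.times, series.values, marker="o", label=label)
        ax.set_xlabel("time (hCT)")
        ax.set_ylabel("relative expression")
        ax.set_title(gene)
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / f"expression_{gene}.png", dpi=120)
        plt.close(fig)


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def make_report(result: StudyResult) -> str:
    """Human-readable markdown summary of one study run.

    Lists the cohort layout, the EE-vs-LE contrasts (rank 1 vs rank
    ``group_size``) and the full-rank correlation rows verbatim from the
    correlation table.  Sections for regimes that were not run are omitted.
    """
    cfg = result.config
    lines = [
        "# Study report",
        "",
        f"- schema version: {SCHEMA_VERSION}",
        f"- cohort: {cfg.cohort.n_groups} groups x {cfg.cohort.group_size} fish, "
        f"seed {cfg.cohort.seed}",
        f"- analysed fish: {len(result.emergence)}",
        "",
    ]
    rank_of = dict(zip(result.emergence["individual_id"], result.emergence["rank"]))
    le_rank = cfg.cohort.group_size
    contrasts = []
    for (channel, regime), sub in result.metrics.groupby(
        ["channel", "regime"], sort=True
    ):
        ranks = sub["individual_id"].map(rank_of)
        ee = sub.loc[ranks == 1, "auc"]
        le = sub.loc[ranks == le_rank, "auc"]
        if len(ee) and len(le):
            contrasts.append(
                f"| {channel} | {regime} | {_fmt(ee.mean())} | {_fmt(le.mean())} |"
            )
    if contrasts:
        lines += [
            "## EE vs LE contrast (mean AUC)",
            "",
            "| channel | regime | EE (rank 1) | LE (rank %d) |" % le_rank,
            "|---|---|---|---|",
            *contrasts,
            "",
        ]
    for regime in cfg.regimes:
        sub = result.correlations[result.correlations["regime"] == regime]
        if sub.empty:
            continue
        lines += [
            f"## Rank correlations ({regime})",
            "",
            "| channel | metric | rho | p | n |",
            "|---|---|---|---|---|",
        ]
        for row in sub.itertuples(index=False):
            lines.append(
                f"| {row.channel} | {row.metric} | {_fmt(row.rho)} | "
                f"{_fmt(row.p_value)} | {row.n} |"
            )
        lines.append("")
    behav = result.correlations[result.correlations["regime"] == ""]
    if not behav.empty:
        lines += [
            "## Behavioural and null correlations",
            "",
            "| channel | metric | rho | p | n |",
            "|---|---|---|---|---|",
        ]
        for row in behav.itertuples(index=False):
            lines.append(
                f"| {row.channel} | {row.metric} | {_fmt(row.rho)} | "
                f"{_fmt(row.p_value)} | {row.n} |"
            )
        lines.append("")
    if result.selection is not None:
        lines += [
            "## Activity model selection",
            "",
            f"- retained predictors: "
            f"{', '.join(result.selection.retained_predictors) or '(none)'}",
            f"- dropped for collinearity: "
            f"{', '.join(result.selection.vif_dropped) or '(none)'}",
            f"- influential points flagged: {len(result.selection.influential_points)}",
            "",
        ]
    if not lines[-1] == "":
        lines.append("")
    return "\n".join(lines)
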