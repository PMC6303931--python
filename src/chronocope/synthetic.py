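"""Synthetic zebrafish cohorts with coupled personality and circadian structure.

The generator emulates a laboratory population in which individuals vary along
a proactive--reactive continuum.  A latent boldness score in [0, 1] (1 = most
proactive) drives

* emergence latency (log-linear in shyness, with a stable individual
  component and fresh per-session noise),
* aggression, freezing and approach latency in a mirror-image test,
* the mesor and amplitude of every diurnal channel: five clock genes
  (*bmal1a*, *clock1a*, *per1a*, *cry1a*, *cipca*), whole-body cortisol and
  melatonin, and swimming velocity in 30-min bins.

Each channel value follows a fixed-period cosinor

    x(t) = M(b) + A(b) * cos(2*pi*(t - phi)/24) * D(t) + eps,

with mesor ``M`` and amplitude ``A`` linear in boldness ``b`` between their
``_at_shy`` and ``_at_bold`` extremes, acrophase ``phi`` in hours circadian
time (hCT, 0 = lights on), multiplicative noise ``eps ~ N(0, (cv*M)^2)`` and a
damping factor ``D`` that halves the rhythm every ``ll_damping_halflife``
hours once the light stops cycling (the constant-light challenge).  Values of
concentration and velocity channels are floored at zero after noise.

Swimming velocity additionally carries a per-individual lognormal activity
scale (fish differ in overall activity independently of personality) and one
short burst per day at a shared locomotor ceiling -- a startle/feeding bout
whose height does not depend on boldness.  The daily maximum velocity is
therefore personality-independent by construction, while the sustained rhythm
(mesor, amplitude) is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .behavior import MirrorRecord
from .errors import ConfigurationError
from .rhythm import TimeSeries

__all__ = [
    "SAMPLING_TIMES_HCT",
    "GENE_CHANNELS",
    "HORMONE_CHANNELS",
    "HOUSEKEEPING_GENE",
    "ACTIVITY_START_HCT",
    "LL_START_HCT",
    "ACTIVITY_BIN_H",
    "RhythmGenParams",
    "MirrorParams",
    "CohortConfig",
    "Individual",
    "Cohort",
    "default_channel_params",
    "default_noise_cv",
    "generate_cohort",
    "simulate_emergence_latency",
    "simulate_group_emergence",
    "simulate_mirror_test",
    "simulate_channel_timeseries",
    "simulate_activity_trace",
    "make_latency_table",
    "make_mirror_table",
    "make_ct_table",
    "make_hormone_table",
    "make_activity_table",
]

#: The six sampling timepoints of the gene-expression / hormone time courses,
#: in hours circadian time under the 14:10 light-dark cycle.
SAMPLING_TIMES_HCT: tuple[float, ...] = (1.0, 7.0, 13.0, 15.0, 19.0, 23.0)

GENE_CHANNELS: tuple[str, ...] = ("bmal1a", "clock1a", "per1a", "cry1a", "cipca")
HORMONE_CHANNELS: tuple[str, ...] = ("cortisol", "melatonin")
HOUSEKEEPING_GENE = "ippA"

#: Activity recording starts mid-light-phase of day 1 and runs six days:
#: three under the 14:10 LD cycle, three under constant light (LL).
ACTIVITY_START_HCT = 7.0
LL_START_HCT = ACTIVITY_START_HCT + 72.0
ACTIVITY_BIN_H = 0.5


@dataclass(frozen=True)
class RhythmGenParams:
    """Generative cosinor parameters for one channel.

    Mesor and amplitude are linearly interpolated in boldness between the
    ``_at_shy`` (boldness 0) and ``_at_bold`` (boldness 1) values.  The period
    is fixed at 24 h.  ``daily_max_ceiling`` switches on the shared-ceiling
    burst machinery used by the velocity channel; ``indiv_scale_sd`` is the
    log-scale SD of the per-individual multiplicative level (a stable trait,
    independent of boldness).
    """

    mesor_at_bold: float
    mesor_at_shy: float
    amplitude_at_bold: float
    amplitude_at_shy: float
    acrophase: float
    period: float = 24.0
    floor_at_zero: bool = True
    indiv_scale_sd: float = 0.0
    daily_max_ceiling: float | None = None
    daily_max_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.period != 24.0:
            raise ConfigurationError("rhythm period is fixed at 24 h")
        if self.amplitude_at_bold < 0 or self.amplitude_at_shy < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        if not 0.0 <= self.acrophase < 24.0:
            raise ConfigurationError("acrophase must lie in [0, 24) hCT")

    def mesor(self, boldness: float) -> float:
        return self.mesor_at_shy + (self.mesor_at_bold - self.mesor_at_shy) * boldness

    def amplitude(self, boldness: float) -> float:
        return (
            self.amplitude_at_shy
            + (self.amplitude_at_bold - self.amplitude_at_shy) * boldness
        )


@dataclass(frozen=True)
class MirrorParams:
    """Parameters of the mirror-image stimulation generator.

    ``agr_rate_max`` is the aggressive-act rate (s^-1) of a maximally bold
    fish during mirror-directed time; freezing occupies a fraction
    ``frz_coef * (1 - boldness)`` of the trial (noisy, capped at the full
    duration, so the shyest fish become non-responders), and the latency to
    first approach scales with shyness.
    """

    duration: float = 600.0
    agr_rate_max: float = 0.25
    frz_coef: float = 1.05
    frz_sd: float = 0.15
    lfa_scale: float = 60.0
    lfa_sd: float = 15.0


def default_channel_params() -> dict[str, RhythmGenParams]:
    """Default generative parameters for every registered channel.

    Gene expression is in arbitrary relative units (mesor falls, amplitude
    collapses towards the shy end); cortisol (ng g^-1) has a high flat level
    in shy fish (2.5x the bold mesor) and a light-phase rhythm in bold fish;
    melatonin (pg g^-1) peaks mid-dark in bold fish while shy fish sit at a
    flat intermediate level whose net output exceeds the bold average; swimming
    velocity (mm s^-1) peaks in the first hour of the light phase.
    """
    gene = dict(
        mesor_at_bold=10.0,
        mesor_at_shy=6.0,
        amplitude_at_bold=4.0,
        amplitude_at_shy=0.4,
    )
    return {
        "bmal1a": RhythmGenParams(acrophase=16.0, **gene),
        "clock1a": RhythmGenParams(acrophase=14.0, **gene),
        "per1a": RhythmGenParams(acrophase=1.0, **gene),
        "cry1a": RhythmGenParams(acrophase=3.0, **gene),
        "cipca": RhythmGenParams(acrophase=7.0, **gene),
        "cortisol": RhythmGenParams(
            mesor_at_bold=5.0,
            mesor_at_shy=12.5,
            amplitude_at_bold=4.0,
            amplitude_at_shy=0.0,
            acrophase=1.0,
        ),
        "melatonin": RhythmGenParams(
            mesor_at_bold=100.0,
            mesor_at_shy=150.0,
            amplitude_at_bold=80.0,
            amplitude_at_shy=0.0,
            acrophase=19.0,
        ),
        "activity": RhythmGenParams(
            mesor_at_bold=6.0,
            mesor_at_shy=4.0,
            amplitude_at_bold=5.0,
            amplitude_at_shy=0.5,
            acrophase=1.0,
            indiv_scale_sd=0.3,
            daily_max_ceiling=25.0,
        ),
    }


def default_noise_cv() -> dict[str, float]:
    """Default coefficient of variation of the additive noise per channel."""
    cv = {g: 0.12 for g in GENE_CHANNELS}
    cv.update(cortisol=0.12, melatonin=0.12, activity=0.25)
    return cv


@dataclass(frozen=True)
class CohortConfig:
    """Full calibration of the synthetic study.

    The defaults are the study conditions used throughout the package: nine
    groups of ten fish (72 analysed after the two random eliminations per
    group), a log-linear latency model whose test--retest consistency matches
    the published emergence-test repeatability, and the channel calibration of
    :func:`default_channel_params`.
    """

    n_groups: int = 9
    group_size: int = 10
    seed: int = 0
    latency_scale: float = 55.0
    latency_boldness_slope: float = 3.0
    latency_individual_sd: float = 0.3
    latency_residual_sd: float = 0.15
    channel_params: Mapping[str, RhythmGenParams] = field(
        default_factory=default_channel_params
    )
    noise_cv: Mapping[str, float] = field(default_factory=default_noise_cv)
    ll_damping_halflife: float = 20.0
    mirror: MirrorParams = field(default_factory=MirrorParams)
    body_weight_mean: float = 150.61
    body_weight_sd: float = 17.99
    # qPCR plumbing: reference-gene Ct level, target baseline on the Ct scale
    # (Ct_target = ct_target_base - log2(expression)) and technical-replicate SD.
    ct_reference_level: float = 15.0
    ct_target_base: float = 24.0
    ct_technical_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if self.group_size < 2:
            raise ConfigurationError("group_size must be >= 2")
        for name, sd in (
            ("latency_individual_sd", self.latency_individual_sd),
            ("latency_residual_sd", self.latency_residual_sd),
        ):
            if sd < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.latency_scale <= 0:
            raise ConfigurationError("latency_scale must be > 0")
        if self.ll_damping_halflife <= 0:
            raise ConfigurationError("ll_damping_halflife must be > 0")
        for ch, cv in self.noise_cv.items():
            if cv < 0:
                raise ConfigurationError(f"noise_cv[{ch!r}] must be >= 0")

    def channel(self, name: str) -> RhythmGenParams:
        try:
            return self.channel_params[name]
        except KeyError:
            raise ConfigurationError(f"unknown channel {name!r}") from None

    def noise_free(self) -> "CohortConfig":
        """A copy with every noise source silenced.

        Latency noise, channel noise, the per-individual activity scale and
        the daily burst are all switched off; channel values then trace the
        generative cosinor exactly and emergence rank is a deterministic
        function of boldness.
        """
        params = {
            name: replace(p, indiv_scale_sd=0.0, daily_max_ceiling=None)
            for name, p in self.channel_params.items()
        }
        return replace(
            self,
            latency_individual_sd=0.0,
            latency_residual_sd=0.0,
            channel_params=params,
            noise_cv={name: 0.0 for name in self.noise_cv},
            ct_technical_sd=0.0,
        )


@dataclass(frozen=True)
class Individual:
    """One fish: identity, latent boldness and null covariates."""

    id: str
    group_id: str
    boldness: float
    sex: str
    body_weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.boldness <= 1.0:
            raise ConfigurationError("boldness must lie in [0, 1]")


@dataclass(frozen=True)
class Cohort:
    """A generated cohort plus the configuration that produced it."""

    individuals: tuple[Individual, ...]
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.individuals)

    def groups(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.group_id, []).append(ind)
        return out

    def roster(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [i.id for i in self.individuals],
                "group_id": [i.group_id for i in self.individuals],
                "boldness": [i.boldness for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "body_weight_mg": [i.body_weight for i in self.individuals],
            }
        )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``n_groups x group_size`` fish with uniform boldness.

    Body weight is drawn independently of boldness (it is carried only to
    verify the null of no rank--weight correlation) and sex is an unused
    covariate.  Identical configs produce identical cohorts.
    """
    inds: list[Individual] = []
    ids: set[str] = set()
    for g in range(config.n_groups):
        gid = f"G{g + 1:02d}"
        rng = substream(config.seed, "cohort", gid)
        boldness = rng.uniform(0.0, 1.0, config.group_size)
        weight = rng.normal(
            config.body_weight_mean, config.body_weight_sd, config.group_size
        )
        weight = np.clip(weight, 1.0, None)
        sex = rng.choice(["F", "M"], size=config.group_size)
        for k in range(config.group_size):
            iid = f"{gid}F{k + 1:02d}"
            if iid in ids:
                raise ConfigurationError(f"duplicate individual id {iid}")
            ids.add(iid)
            inds.append(
                Individual(
                    id=iid,
                    group_id=gid,
                    boldness=float(boldness[k]),
                    sex=str(sex[k]),
                    body_weight=float(weight[k]),
                )
            )
    return Cohort(individuals=tuple(inds), config=config)


def simulate_emergence_latency(
    ind: Individual, config: CohortConfig, session: str
) -> float:
    """Latency (s) to leave the shelter in one emergence session.

    ``latency = scale * exp(slope * (1 - b) + u_i + e)`` with the stable
    individual component ``u_i`` keyed by the fish id alone and the residual
    ``e`` keyed by (fish id, session label), so repeated sessions share
    ``u_i`` but draw fresh residuals.
    """
    u = float(
        substream(config.seed, ind.id, "latency-trait").normal(
            0.0, config.latency_individual_sd
        )
    )
    e = float(
        substream(config.seed, ind.id, "latency-session", session).normal(
            0.0, config.latency_residual_sd
        )
    )
    return config.latency_scale * math.exp(
        config.latency_boldness_slope * (1.0 - ind.boldness) + u + e
    )


def simulate_group_emergence(
    cohort: Cohort, session: str = "group"
) -> pd.DataFrame:
    """Latency table for one session of every fish in the cohort."""
    cfg = cohort.config
    return pd.DataFrame(
        {
            "individual_id": [i.id for i in cohort.individuals],
            "group_id": [i.group_id for i in cohort.individuals],
            "session": session,
            "latency_s": [
                simulate_emergence_latency(i, cfg, session)
                for i in cohort.individuals
            ],
        }
    )


def simulate_mirror_test(
    ind: Individual, config: CohortConfig, session: str = "mirror"
) -> MirrorRecord:
    """One mirror-image stimulation trial.

    Freezing occupies a noisy fraction of the trial increasing in shyness and
    capped at the full duration (non-responders); the latency to first
    approach also increases with shyness; aggressive acts are Poisson with a
    rate proportional to boldness over the mirror-directed time.
    """
    p = config.mirror
    rng = substream(config.seed, ind.id, "mirror", session)
    shy = 1.0 - ind.boldness
    frz_frac = p.frz_coef * shy + rng.normal(0.0, p.frz_sd)
    if frz_frac >= 1.0:
        # froze for the whole trial: a non-responder
        return MirrorRecord(
            individual_id=ind.id,
            agr_count=0,
            frz_s=p.duration,
            lfa_s=0.0,
            duration=p.duration,
        )
    frz = float(np.clip(frz_frac, 0.0, 1.0)) * p.duration
    # approach latency can never consume all of the non-frozen time
    lfa_max = 0.8 * (p.duration - frz)
    lfa = float(
        np.clip(p.lfa_scale * shy + rng.normal(0.0, p.lfa_sd), 0.0, lfa_max)
    )
    active = p.duration - frz - lfa
    lam = p.agr_rate_max * ind.boldness * active
    agr = int(rng.poisson(lam)) if lam > 0 else 0
    return MirrorRecord(
        individual_id=ind.id,
        agr_count=agr,
        frz_s=frz,
        lfa_s=lfa,
        duration=p.duration,
    )


def _evaluate_channel(
    params: RhythmGenParams,
    boldness: float,
    times: np.ndarray,
    regime: str,
    halflife: float,
    ll_start: float,
) -> np.ndarray:
    m = params.mesor(boldness)
    a = params.amplitude(boldness)
    phase = np.cos(2.0 * np.pi * (times - params.acrophase) / 24.0)
    if regime == "LL":
        t_ll = np.clip(times - ll_start, 0.0, None)
        damping = np.power(2.0, -t_ll / halflife)
    else:
        damping = np.ones_like(times)
    return m + a * phase * damping


def simulate_channel_timeseries(
    ind: Individual,
    channel: str,
    timepoints: Sequence[float],
    config: CohortConfig,
    regime: str = "LD",
    ll_start: float | None = None,
    session: str = "",
) -> TimeSeries:
    """Simulate one channel of one fish at the given hCT timepoints.

    Under LL the rhythm (not the mesor) is exponentially damped with the
    configured half-life, measured from ``ll_start`` (default: the first
    timepoint).  Noise is multiplicative-mesor Gaussian; concentration and
    velocity channels are floored at zero after noise.  Velocity additionally
    receives the per-individual activity scale and one ceiling burst per 24-h
    day (see the module docstring).
    """
    if len(timepoints) == 0:
        raise ConfigurationError("timepoints must be non-empty")
    if regime not in ("LD", "LL"):
        raise ConfigurationError(f"regime must be 'LD' or 'LL', got {regime!r}")
    params = config.channel(channel)
    times = np.asarray(timepoints, dtype=float)
    if ll_start is None:
        ll_start = float(times[0])
    values = _evaluate_channel(
        params, ind.boldness, times, regime, config.ll_damping_halflife, ll_start
    )
    cv = config.noise_cv.get(channel, 0.0)
    rng = substream(config.seed, ind.id, "channel", channel, regime, session)
    if cv > 0:
        values = values + rng.normal(
            0.0, cv * abs(params.mesor(ind.boldness)), values.shape
        )
    if params.floor_at_zero:
        values = np.clip(values, 0.0, None)
    if params.daily_max_ceiling is not None:
        burst_rng = substream(
            config.seed, ind.id, "burst", channel, regime, session
        )
        t0 = times[0]
        n_days = int(np.floor((times[-1] - t0) / 24.0)) + 1
        for d in range(n_days):
            in_day = np.flatnonzero((times >= t0 + 24.0 * d) & (times < t0 + 24.0 * (d + 1)))
            if in_day.size == 0:
                continue
            pick = in_day[burst_rng.integers(0, in_day.size)]
            values[pick] = params.daily_max_ceiling * (
                1.0 + burst_rng.normal(0.0, params.daily_max_cv)
            )
    if params.indiv_scale_sd > 0:
        scale = math.exp(
            float(
                substream(config.seed, ind.id, "scale", channel).normal(
                    0.0, params.indiv_scale_sd
                )
            )
        )
        values = values * scale
    return TimeSeries(times=times, values=values, channel=channel, units="")


def simulate_activity_trace(ind: Individual, config: CohortConfig) -> TimeSeries:
    """Six-day swimming-velocity trace in 30-min bins.

    Recording starts at 7 hCT of day 1; days 1--3 run under the 14:10 LD
    cycle, days 4--6 under constant light, with the rhythm damping from the
    moment the light stops cycling (79 h on the recording clock).
    """
    n_bins = int(round(144.0 / ACTIVITY_BIN_H))
    times = ACTIVITY_START_HCT + ACTIVITY_BIN_H * np.arange(n_bins)
    ld_mask = times < LL_START_HCT
    ld = simulate_channel_timeseries(
        ind, "activity", times[ld_mask], config, regime="LD", session="trace-ld"
    )
    ll = simulate_channel_timeseries(
        ind,
        "activity",
        times[~ld_mask],
        config,
        regime="LL",
        ll_start=LL_START_HCT,
        session="trace-ll",
    )
    return TimeSeries(
        times=times,
        values=np.concatenate([ld.values, ll.values]),
        channel="activity",
        units="mm/s",
    )


# ---------------------------------------------------------------------------
# table builders (the CSV-facing surface of the generator)
# ---------------------------------------------------------------------------


def make_latency_table(cohort: Cohort, session: str = "group") -> pd.DataFrame:
    return simulate_group_emergence(cohort, session=session)


def make_mirror_table(cohort: Cohort, session: str = "mirror") -> pd.DataFrame:
    rows = [
        simulate_mirror_test(ind, cohort.config, session=session)
        for ind in cohort.individuals
    ]
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in rows],
            "agr_count": [r.agr_count for r in rows],
            "frz_s": [r.frz_s for r in rows],
            "lfa_s": [r.lfa_s for r in rows],
            "duration_s": [r.duration for r in rows],
        }
    )


def make_ct_table(
    cohort: Cohort,
    individuals: Sequence[Individual] | None = None,
    timepoints: Sequence[float] = SAMPLING_TIMES_HCT,
) -> pd.DataFrame:
    """qPCR Ct table: technical triplicates per (fish, gene, timepoint).

    Target Ct values encode the generative expression level E as
    ``Ct = ct_target_base - log2(E)``; the housekeeping gene ippA sits at a
    boldness-independent level.  Columns: individual_id, gene, time_hct,
    ct1..ct3.
    """
    cfg = cohort.config
    if individuals is None:
        individuals = cohort.individuals
    records = []
    for ind in individuals:
        tech = substream(cfg.seed, ind.id, "ct-technical")
        for gene in GENE_CHANNELS:
            ts = simulate_channel_timeseries(ind, gene, timepoints, cfg)
            for t, expr in zip(ts.times, ts.values):
                base = cfg.ct_target_base - math.log2(max(expr, 1e-9))
                reps = base + tech.normal(0.0, cfg.ct_technical_sd, 3)
                records.append((ind.id, gene, float(t), *reps))
        for t in timepoints:
            reps = cfg.ct_reference_level + tech.normal(0.0, cfg.ct_technical_sd, 3)
            records.append((ind.id, HOUSEKEEPING_GENE, float(t), *reps))
    return pd.DataFrame(
        records, columns=["individual_id", "gene", "time_hct", "ct1", "ct2", "ct3"]
    )


def make_hormone_table(
    cohort: Cohort,
    individuals: Sequence[Individual] | None = None,
    timepoints: Sequence[float] = SAMPLING_TIMES_HCT,
) -> pd.DataFrame:
    """Whole-body hormone concentrations per (fish, hormone, timepoint)."""
    cfg = cohort.config
    if individuals is None:
        individuals = cohort.individuals
    records = []
    for ind in individuals:
        for hormone in HORMONE_CHANNELS:
            ts = simulate_channel_timeseries(ind, hormone, timepoints, cfg)
            units = "ng/g" if hormone == "cortisol" else "pg/g"
            for t, v in zip(ts.times, ts.values):
                records.append((ind.id, hormone, float(t), float(v), units))
    return pd.DataFrame(
        records,
        columns=["individual_id", "channel", "time_hct", "concentration", "units"],
    )


def make_activity_table(
    cohort: Cohort, individuals: Sequence[Individual] | None = None
) -> pd.DataFrame:
    """Six-day 30-min binned velocity table with a regime column."""
    if individuals is None:
        individuals = cohort.individuals
    frames = []
    for ind in individuals:
        ts = simulate_activity_trace(ind, cohort.config)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ind.id,
                    "time_h": ts.times,
                    "velocity_mm_s": ts.values,
                    "regime": np.where(ts.times < LL_START_HCT, "LD", "LL"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
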