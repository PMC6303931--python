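"""Scoring of the behavioural assays.

Two assays are scored here: the emergence test (a group of fish leaves a
familiar dark shelter into a novel lit arena; emergence order proxies
risk-taking, rank 1 = early emerger / proactive) and the mirror-image
stimulation test (aggressive acts, freezing and approach latency in front of
a mirror).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateRecordError, InputError, InsufficientDataError

__all__ = [
    "EmergenceRecord",
    "MirrorRecord",
    "rank_emergence",
    "agr_frequency",
    "repeatability_table",
    "random_elimination",
]

#: Freezing for the entire 10-min trial marks a non-responder.
NON_RESPONDER_FRZ_S = 600.0


@dataclass(frozen=True)
class EmergenceRecord:
    """Outcome of one fish in a ranked emergence session."""

    individual_id: str
    latency_s: float
    emerged: bool
    rank: int | None


@dataclass(frozen=True)
class MirrorRecord:
    """Raw counts and durations from one mirror-image stimulation trial."""

    individual_id: str
    agr_count: int
    frz_s: float
    lfa_s: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DegenerateRecordError("trial duration must be > 0")
        if self.frz_s < 0 or self.lfa_s < 0 or self.agr_count < 0:
            raise DegenerateRecordError("counts and durations must be >= 0")
        if self.frz_s + self.lfa_s > self.duration + 1e-9:
            raise DegenerateRecordError("FRZ + LFA exceed the trial duration")


def rank_emergence(
    latencies: Iterable[tuple[str, float]], cutoff: float | None = 600.0
) -> list[EmergenceRecord]:
    """Rank fish by ascending latency; non-emergers get no rank.

    Fish whose latency reaches ``cutoff`` (default 10 min) are flagged as not
    emerged and excluded from ranking; pass ``cutoff=None`` for a session that
    runs until every fish has emerged.  Ties are broken by input order (a
    documented convention -- through a single hatch two fish cannot emerge
    simultaneously).
    """
    items = list(latencies)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate individual ids in latency table")
    if any(lat < 0 for _, lat in items):
        raise InputError("latencies must be >= 0")
    cut = math.inf if cutoff is None else float(cutoff)
    emerged = [(i, lat) for i, lat in items if lat < cut]
    order = np.argsort([lat for _, lat in emerged], kind="stable")
    rank_of = {emerged[j][0]: r + 1 for r, j in enumerate(order)}
    return [
        EmergenceRecord(
            individual_id=i,
            latency_s=float(lat),
            emerged=lat < cut,
            rank=rank_of.get(i),
        )
        for i, lat in items
    ]


def agr_frequency(rec: MirrorRecord) -> float | None:
    """Aggression frequency (s^-1): AGR / (duration - FRZ - LFA).

    Returns ``None`` for non-responders (freezing of 10 min or longer), which
    are excluded from further analysis.  A zero mirror-directed period in a
    responsive fish is an inconsistent record.
    """
    if rec.frz_s >= NON_RESPONDER_FRZ_S:
        return None
    denom = rec.duration - rec.frz_s - rec.lfa_s
    if denom <= 0:
        raise DegenerateRecordError(
            "no mirror-directed time left in a responsive fish"
        )
    return rec.agr_count / denom


def repeatability_table(
    session1: pd.DataFrame, session2: pd.DataFrame
) -> tuple[pd.DataFrame, "CorrelationResult"]:
    """Pair two latency sessions and correlate their log-latencies.

    Both frames need ``individual_id`` and ``latency_s`` columns; fish are
    inner-joined on id (at least 5 shared fish required).  Returns the paired
    log-latency table and the Spearman correlation across sessions.
    """
    from .stats import spearman  # local import: stats imports nothing from here

    merged = session1[["individual_id", "latency_s"]].merge(
        session2[["individual_id", "latency_s"]],
        on="individual_id",
        suffixes=("_1", "_2"),
    )
    if len(merged) < 5:
        raise InsufficientDataError(
            f"repeatability needs >= 5 shared fish, got {len(merged)}"
        )
    paired = pd.DataFrame(
        {
            "individual_id": merged["individual_id"],
            "log_latency_1": np.log(merged["latency_s_1"]),
            "log_latency_2": np.log(merged["latency_s_2"]),
        }
    )
    result = spearman(
        paired["log_latency_1"].to_numpy(), paired["log_latency_2"].to_numpy()
    )
    return paired, result


def random_elimination(
    ids: Sequence[str], n_drop: int, rng: np.random.Generator
) -> list[str]:
    """Randomly drop ``n_drop`` fish; returns retained ids in input order.

    Reproduces the published protocol of randomly eliminating two of the ten
    ranked fish before individual testing (seeded through the cohort seed).
    """
    if n_drop < 0 or n_drop >= len(ids):
        raise InputError("n_drop must be in [0, len(ids))")
    drop = set(rng.choice(len(ids), size=n_drop, replace=False).tolist())
    return [iid for k, iid in enumerate(ids) if k not in drop]
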