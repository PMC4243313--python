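"""Standard (aggregate) vigilance parameters and group comparisons.

Implements the classical descriptive sleep metrics computed from a
fine-vocabulary hypnogram: total time, episode count and mean episode
duration per stage class (WAKE, NREM, REM, SLEEP), sleep fragmentation,
REM latency, SWS-1/SWS-2 latencies and the first REM item, plus an optional
filter that removes short "REM attempts".  Group comparisons use a two-way
fixed-effects ANOVA (treatment x rebound, Type-II sums of squares) followed
by Tukey's HSD across the four cells.

Stage classes: WAKE = AW + PW; NREM = SWS1 + SWS2 + IS; SLEEP = NREM + REM.
An episode is a maximal run of epochs of one class (>= 1 epoch, i.e. >= 4 s).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import asdict, dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .hypnogram_io import Hypnogram

__all__ = [
    "Episode",
    "MetricsRow",
    "GroupComparison",
    "STAGE_CLASSES",
    "episodes",
    "aggregate_metrics",
    "sleep_fragmentation",
    "rem_latency",
    "stage_latency",
    "first_rem_item",
    "filter_rem_attempts",
    "metrics_frame",
    "compare_groups",
]

logger = logging.getLogger(__name__)

#: Fine-stage membership of each coarse stage class.
STAGE_CLASSES: dict[str, frozenset[str]] = {
    "WAKE": frozenset({"AW", "PW", "WAKE"}),
    "NREM": frozenset({"SWS1", "SWS2", "IS", "NREM"}),
    "REM": frozenset({"REM"}),
    "SLEEP": frozenset({"SWS1", "SWS2", "IS", "REM", "NREM", "SLEEP"}),
}

_WAKE_FINE = frozenset({"AW", "PW"})
_SLEEP_FINE = frozenset({"SWS1", "SWS2", "IS", "REM"})


@dataclass(frozen=True)
class Episode:
    """A maximal run of epochs belonging to one stage or stage class."""

    stage: str
    start_epoch: int
    length: int  # epochs

    def duration(self, epoch_length: float) -> float:
        return self.length * epoch_length


@dataclass(frozen=True)
class MetricsRow:
    """Per-subject standard vigilance parameters (times in seconds).

    Latencies and the first REM item are ``None`` when the target stage does
    not occur; mean durations are ``nan`` when a class has no episodes.
    """

    subject_id: str
    group: str
    wake_time: float
    wake_episode_count: int
    wake_mean_duration: float
    nrem_time: float
    nrem_episode_count: int
    nrem_mean_duration: float
    rem_time: float
    rem_episode_count: int
    rem_mean_duration: float
    sleep_time: float
    sleep_episode_count: int
    sleep_mean_duration: float
    sleep_fragmentation: int
    rem_latency: float | None
    sws1_latency: float | None
    sws2_latency: float | None
    first_rem_item: float | None


def _membership(stage_class: str) -> frozenset[str]:
    if stage_class in STAGE_CLASSES:
        return STAGE_CLASSES[stage_class]
    return frozenset({stage_class})  # a single fine label


def _runs(member: Sequence[bool]) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(member):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(member) - start))
    return runs


def episodes(h: Hypnogram, stage_class: str) -> list[Episode]:
    """Maximal episodes of a stage class (or a single fine stage), in order."""
    members = _membership(stage_class)
    return [
        Episode(stage=stage_class, start_epoch=s, length=n)
        for s, n in _runs([st in members for st in h.stages])
    ]


def sleep_fragmentation(h: Hypnogram, *, level: str = "fine") -> int:
    """Number of awakenings (AW or PW episodes) that disconnect sleep.

    A wake bout (maximal AW/PW run) counts only when sleep flanks it on both
    sides within the recording; terminal bouts bound nothing.  With
    ``level="fine"`` (default) every fine AW/PW episode inside such a bout is
    counted separately (AW->PW->AW inside one bout counts 3); with
    ``level="bout"`` each disconnecting bout counts once.
    """
    if level not in ("fine", "bout"):
        raise ValueError("level must be 'fine' or 'bout'")
    n = h.n_epochs
    count = 0
    for start, length in _runs([s in _WAKE_FINE for s in h.stages]):
        if start == 0 or start + length == n:
            continue  # neighbours by maximality are sleep stages
        if level == "bout":
            count += 1
        else:
            segment = h.stages[start : start + length]
            count += 1 + sum(a != b for a, b in zip(segment, segment[1:]))
    return count


def rem_latency(h: Hypnogram) -> float | None:
    """Seconds from the start of sleep to the first REM epoch.

    "Start of sleep" is the first epoch of any non-wake stage.  ``None`` when
    the recording contains no REM (or no sleep at all).
    """
    first_sleep = next((i for i, s in enumerate(h.stages) if s in _SLEEP_FINE), None)
    first_rem = next((i for i, s in enumerate(h.stages) if s == "REM"), None)
    if first_sleep is None or first_rem is None:
        return None
    return (first_rem - first_sleep) * h.epoch_length


def stage_latency(h: Hypnogram, stage: str) -> float | None:
    """Seconds from lights-on to the first epoch of *stage* (e.g. SWS1, SWS2)."""
    idx = next((i for i, s in enumerate(h.stages) if s == stage), None)
    if idx is None:
        return None
    return h.start_time + idx * h.epoch_length


def first_rem_item(h: Hypnogram) -> float | None:
    """Length (s) of the first uninterrupted REM+IS run starting at the first REM.

    After the first REM epoch, IS epochs are permitted until the run is
    broken by any other stage or the recording ends.
    """
    start = next((i for i, s in enumerate(h.stages) if s == "REM"), None)
    if start is None:
        return None
    end = start
    while end < h.n_epochs and h.stages[end] in ("REM", "IS"):
        end += 1
    return (end - start) * h.epoch_length


def filter_rem_attempts(
    h: Hypnogram, min_duration: float = 16.0, max_gap: float = 16.0
) -> Hypnogram:
    """Remove short "REM attempts" under the merged-item episode definition.

    REM runs separated by gaps of other stages shorter than ``max_gap`` are
    merged into one item (spanning from the first to the last REM epoch of
    the merged runs).  Items whose span is shorter than ``min_duration`` have
    their REM epochs relabelled to the dominant stage among the item's
    internal gap epochs; an isolated run borrows the stage of the preceding
    epoch (the following one at the recording start).  Ties prefer the
    preceding epoch's stage.  Total REM time never increases.
    """
    rem_runs = _runs([s == "REM" for s in h.stages])
    if not rem_runs:
        return h
    dt = h.epoch_length
    # group runs into items by gap length
    items: list[list[tuple[int, int]]] = [[rem_runs[0]]]
    for prev, cur in zip(rem_runs, rem_runs[1:]):
        gap_epochs = cur[0] - (prev[0] + prev[1])
        if gap_epochs * dt < max_gap:
            items[-1].append(cur)
        else:
            items.append([cur])
    stages = list(h.stages)
    for item in items:
        first = item[0][0]
        last = item[-1][0] + item[-1][1]  # one past the last REM epoch
        if (last - first) * dt >= min_duration:
            continue
        gap_stages = [stages[i] for i in range(first, last) if stages[i] != "REM"]
        if not gap_stages:
            if first > 0:
                gap_stages = [stages[first - 1]]
            elif last < len(stages):
                gap_stages = [stages[last]]
            else:
                continue  # the whole recording is REM: nothing to borrow
        tally = Counter(gap_stages)
        top = max(tally.values())
        tied = [s for s, c in tally.items() if c == top]
        preceding = stages[first - 1] if first > 0 else None
        if len(tied) > 1 and preceding in tied:
            replacement = preceding
        else:
            replacement = next(s for s in gap_stages if s in tied)
        for i in range(first, last):
            if stages[i] == "REM":
                stages[i] = replacement
    return replace(h, stages=tuple(stages))


def aggregate_metrics(h: Hypnogram) -> MetricsRow:
    """All standard vigilance parameters for one fine-vocabulary hypnogram."""
    if h.vocabulary != "fine":
        raise ValueError("aggregate_metrics requires the fine stage vocabulary")
    dt = h.epoch_length
    values: dict[str, float | int | None] = {}
    for cls, prefix in (
        ("WAKE", "wake"),
        ("NREM", "nrem"),
        ("REM", "rem"),
        ("SLEEP", "sleep"),
    ):
        eps = episodes(h, cls)
        total = sum(e.length for e in eps) * dt
        count = len(eps)
        values[f"{prefix}_time"] = total
        values[f"{prefix}_episode_count"] = count
        values[f"{prefix}_mean_duration"] = total / count if count else float("nan")
    return MetricsRow(
        subject_id=h.subject_id,
        group=h.group,
        sleep_fragmentation=sleep_fragmentation(h),
        rem_latency=rem_latency(h),
        sws1_latency=stage_latency(h, "SWS1"),
        sws2_latency=stage_latency(h, "SWS2"),
        first_rem_item=first_rem_item(h),
        **values,  # type: ignore[arg-type]
    )


def metrics_frame(rows: Iterable[MetricsRow]) -> pd.DataFrame:
    """Per-subject long table of metrics (one row per subject)."""
    return pd.DataFrame([asdict(r) for r in rows])


def _split_group(group: str) -> tuple[str, str]:
    """Default factor coding: 'HC-VEH' -> rebound 'HC', treatment 'VEH'."""
    parts = group.split("-")
    if len(parts) != 2:
        raise ValueError(
            f"cannot derive (rebound, treatment) factors from group {group!r}; "
            f"pass an explicit `factors` mapping"
        )
    return parts[0], parts[1]


@dataclass(frozen=True)
class GroupComparison:
    """Two-way ANOVA + Tukey HSD report for one metric."""

    metric: str
    anova: pd.DataFrame  # rows: treatment, rebound, interaction, residual
    tukey: pd.DataFrame
    n_used: int
    n_dropped: int
    note: str = ""

    def f_statistic(self, effect: str) -> float:
        return float(self.anova.loc[effect, "F"])

    def p_value(self, effect: str) -> float:
        return float(self.anova.loc[effect, "PR(>F)"])


def compare_groups(
    rows: Iterable[MetricsRow] | pd.DataFrame,
    metric: str,
    *,
    factors: Callable[[str], tuple[str, str]] | None = None,
    tukey: bool = True,
) -> GroupComparison:
    """Two-way (treatment x rebound) ANOVA with Tukey HSD for one metric.

    Undefined values (e.g. latencies of subjects lacking the stage) are
    dropped with a logged count.  Unbalanced cells use Type-II sums of
    squares.  A metric with zero variance yields NaN F statistics and a note
    instead of an error.  ``tukey=False`` skips the post-hoc table (useful
    for large simulation sweeps).
    """
    df = rows if isinstance(rows, pd.DataFrame) else metrics_frame(rows)
    if metric not in df.columns:
        raise ValueError(f"unknown metric {metric!r}")
    split = factors or _split_group
    work = df[["subject_id", "group", metric]].copy()
    work["value"] = pd.to_numeric(work[metric])
    n_total = len(work)
    work = work.dropna(subset=["value"])
    n_dropped = n_total - len(work)
    if n_dropped:
        logger.info("metric %s: dropped %d subjects with undefined values", metric, n_dropped)
    work[["rebound", "treatment"]] = [split(g) for g in work["group"]]
    cells = work.groupby(["treatment", "rebound"]).size()
    if len(cells) < 4 or (cells < 2).any():
        raise ValueError(
            f"metric {metric!r}: every treatment x rebound cell needs >= 2 "
            f"subjects (got {cells.to_dict()})"
        )
    note = ""
    if np.ptp(work["value"].to_numpy()) == 0:
        note = "zero between-group variance; F statistics undefined"
        idx = ["C(treatment)", "C(rebound)", "C(treatment):C(rebound)", "Residual"]
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": np.nan, "PR(>F)": np.nan}, index=idx
        )
        tukey_table = pd.DataFrame()
    else:
        model = ols("value ~ C(treatment) * C(rebound)", data=work).fit()
        anova = anova_lm(model, typ=2)
        if tukey:
            hsd = pairwise_tukeyhsd(work["value"], work["group"])
            tukey_table = pd.DataFrame(
                hsd.summary().data[1:], columns=hsd.summary().data[0]
            )
        else:
            tukey_table = pd.DataFrame()
    return GroupComparison(
        metric=metric,
        anova=anova,
        tukey=tukey_table,
        n_used=len(work),
        n_dropped=n_dropped,
        note=note,
    )
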