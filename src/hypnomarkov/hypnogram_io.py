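"""Reading, validating, collapsing and segmenting epoch-scored hypnograms.

A hypnogram is a time-ordered sequence of visually scored vigilance stages,
one label per fixed-length epoch (4 s by default).  Three closed label
vocabularies are supported:

``fine``
    the six rodent polysomnography stages — active/passive wakefulness
    (``AW``/``PW``), light and deep slow-wave sleep (``SWS1``/``SWS2``),
    intermediate stage (``IS``) and ``REM`` sleep;
``three_state``
    ``WAKE``/``NREM``/``REM``, the usual coarse scoring;
``two_state``
    ``WAKE``/``SLEEP``, used where REM is too rare to resolve (e.g. during
    sleep onset).

Files use a minimal self-describing TSV dialect: ``#key<TAB>value`` header
lines followed by one ``epoch<TAB>stage[<TAB>artifact]`` row per epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FINE_STAGES",
    "THREE_STATE_STAGES",
    "TWO_STATE_STAGES",
    "VOCABULARIES",
    "Hypnogram",
    "CollapseMap",
    "FINE_TO_THREE_STATE",
    "FINE_TO_TWO_STATE",
    "THREE_TO_TWO_STATE",
    "HypnogramError",
    "vocabulary_of",
    "read_hypnogram",
    "write_hypnogram",
    "collapse_stages",
    "segment_hypnogram",
]

FINE_STAGES: tuple[str, ...] = ("AW", "PW", "SWS1", "SWS2", "IS", "REM")
THREE_STATE_STAGES: tuple[str, ...] = ("WAKE", "NREM", "REM")
TWO_STATE_STAGES: tuple[str, ...] = ("WAKE", "SLEEP")

#: Name -> ordered label set of each closed vocabulary.
VOCABULARIES: dict[str, tuple[str, ...]] = {
    "fine": FINE_STAGES,
    "three_state": THREE_STATE_STAGES,
    "two_state": TWO_STATE_STAGES,
}

#: Preference order used when inferring a vocabulary from an observed label set.
_VOCABULARY_ORDER = ("fine", "three_state", "two_state")


class HypnogramError(ValueError):
    """Raised for malformed hypnogram files or invalid hypnogram operations."""


def vocabulary_of(labels: Iterable[str]) -> str:
    """Infer the vocabulary name covering *labels*.

    When the label set is compatible with more than one vocabulary (e.g. a
    recording containing only ``REM``) the finest compatible vocabulary wins.
    """
    observed = set(labels)
    for name in _VOCABULARY_ORDER:
        if observed <= set(VOCABULARIES[name]):
            return name
    unknown = observed - set().union(*map(set, VOCABULARIES.values()))
    if unknown:
        raise HypnogramError(f"unknown stage label(s): {sorted(unknown)}")
    raise HypnogramError(
        f"labels {sorted(observed)} mix more than one vocabulary"
    )


@dataclass(frozen=True)
class Hypnogram:
    """An epoch-scored vigilance-stage sequence for one subject.

    Parameters
    ----------
    subject_id, group
        Subject and experimental-group annotations (group labels like
        ``HC-VEH`` encode the rebound and treatment factors).
    stages
        Ordered stage labels, one per epoch, all from one vocabulary.
    epoch_length
        Scoring epoch length in seconds.
    start_time
        Time of the first epoch's start in seconds since lights-on.
    artifact_mask
        Optional per-epoch booleans; ``True`` marks epochs to discard from
        spectral averaging.
    vocabulary
        Explicit vocabulary name; inferred from the labels when omitted.
    """

    subject_id: str
    group: str
    stages: tuple[str, ...]
    epoch_length: float = 4.0
    start_time: float = 0.0
    artifact_mask: tuple[bool, ...] | None = None
    vocabulary: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise HypnogramError("hypnogram must contain at least one epoch")
        if self.epoch_length <= 0:
            raise HypnogramError("epoch_length must be positive")
        object.__setattr__(self, "stages", tuple(self.stages))
        vocab = self.vocabulary or vocabulary_of(self.stages)
        if vocab not in VOCABULARIES:
            raise HypnogramError(f"unknown vocabulary {vocab!r}")
        bad = set(self.stages) - set(VOCABULARIES[vocab])
        if bad:
            raise HypnogramError(
                f"labels {sorted(bad)} are not in vocabulary {vocab!r}"
            )
        object.__setattr__(self, "vocabulary", vocab)
        if self.artifact_mask is not None:
            mask = tuple(bool(b) for b in self.artifact_mask)
            if len(mask) != len(self.stages):
                raise HypnogramError(
                    "artifact_mask length must equal number of epochs"
                )
            object.__setattr__(self, "artifact_mask", mask)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        """Total scored time in seconds."""
        return self.n_epochs * self.epoch_length

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def epoch_start_times(self) -> np.ndarray:
        """Start time of each epoch (seconds since lights-on)."""
        return self.start_time + self.epoch_length * np.arange(self.n_epochs)


@dataclass(frozen=True)
class CollapseMap:
    """A total mapping from one stage vocabulary onto a coarser one."""

    mapping: Mapping[str, str]
    target: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        source = vocabulary_of(self.mapping.keys())
        if set(self.mapping.keys()) != set(VOCABULARIES[source]):
            missing = set(VOCABULARIES[source]) - set(self.mapping.keys())
            raise HypnogramError(
                f"collapse map is not total over {source!r}: missing {sorted(missing)}"
            )
        if self.target not in VOCABULARIES:
            raise HypnogramError(f"unknown target vocabulary {self.target!r}")
        image = set(self.mapping.values())
        if not image <= set(VOCABULARIES[self.target]):
            raise HypnogramError(
                f"map image {sorted(image)} is not within vocabulary {self.target!r}"
            )
        object.__setattr__(self, "source", source)

    source: str = field(init=False)


FINE_TO_THREE_STATE = CollapseMap(
    {"AW": "WAKE", "PW": "WAKE", "SWS1": "NREM", "SWS2": "NREM", "IS": "NREM", "REM": "REM"},
    target="three_state",
)
THREE_TO_TWO_STATE = CollapseMap(
    {"WAKE": "WAKE", "NREM": "SLEEP", "REM": "SLEEP"},
    target="two_state",
)
FINE_TO_TWO_STATE = CollapseMap(
    {f: THREE_TO_TWO_STATE.mapping[c] for f, c in FINE_TO_THREE_STATE.mapping.items()},
    target="two_state",
)


def collapse_stages(h: Hypnogram, cmap: CollapseMap) -> Hypnogram:
    """Relabel every epoch through *cmap*, preserving all other metadata."""
    if h.vocabulary != cmap.source:
        raise HypnogramError(
            f"hypnogram vocabulary {h.vocabulary!r} does not match "
            f"collapse-map source {cmap.source!r}"
        )
    stages = tuple(cmap.mapping[s] for s in h.stages)
    return replace(h, stages=stages, vocabulary=cmap.target)


def segment_hypnogram(h: Hypnogram, boundaries: Sequence[float]) -> list[Hypnogram]:
    """Split *h* at the given boundary times (seconds since lights-on).

    An epoch belongs to the segment containing its start time, so a boundary
    at 2000 s with 4-s epochs puts epochs 0-499 in the first segment.  The
    returned segments partition the epoch sequence and keep absolute
    ``start_time`` values.
    """
    bounds = [float(b) for b in boundaries]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise HypnogramError("boundaries must be strictly increasing")
    for b in bounds:
        if b <= h.start_time or b >= h.end_time:
            raise HypnogramError(
                f"boundary {b} s is outside the recording span "
                f"({h.start_time}-{h.end_time} s)"
            )
    starts = h.epoch_start_times()
    cut_idx = [int(np.searchsorted(starts, b, side="left")) for b in bounds]
    edges = [0, *cut_idx, h.n_epochs]
    segments: list[Hypnogram] = []
    for i0, i1 in zip(edges, edges[1:]):
        if i1 == i0:  # a boundary inside the span always leaves >=1 epoch/side
            raise HypnogramError("segmentation produced an empty segment")
        mask = h.artifact_mask[i0:i1] if h.artifact_mask is not None else None
        segments.append(
            replace(
                h,
                stages=h.stages[i0:i1],
                artifact_mask=mask,
                start_time=h.start_time + i0 * h.epoch_length,
            )
        )
    return segments


_HEADER_KEYS = ("subject", "group", "epoch_length_s", "start_time_s", "vocabulary")


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write *h* in the hypnogram TSV dialect (deterministic ordering)."""
    path = Path(path)
    lines = [
        f"#subject\t{h.subject_id}",
        f"#group\t{h.group}",
        f"#epoch_length_s\t{h.epoch_length:g}",
        f"#start_time_s\t{h.start_time:g}",
        f"#vocabulary\t{h.vocabulary}",
    ]
    for i, stage in enumerate(h.stages):
        if h.artifact_mask is not None:
            lines.append(f"{i}\t{stage}\t{int(h.artifact_mask[i])}")
        else:
            lines.append(f"{i}\t{stage}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read and validate a hypnogram TSV file.

    Raises
    ------
    HypnogramError
        Naming the offending line for unknown stage labels, non-contiguous
        epoch indices or malformed rows.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    stages: list[str] = []
    mask: list[bool] = []
    have_mask = False
    known_labels = set().union(*map(set, VOCABULARIES.values()))
    expected_index = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise HypnogramError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                idx = int(parts[0])
            except ValueError:
                raise HypnogramError(
                    f"{path}:{lineno}: epoch index {parts[0]!r} is not an integer"
                ) from None
            if idx != expected_index:
                raise HypnogramError(
                    f"{path}:{lineno}: non-contiguous epoch index {idx} "
                    f"(expected {expected_index})"
                )
            expected_index += 1
            stage = parts[1]
            if stage not in known_labels:
                raise HypnogramError(
                    f"{path}:{lineno}: unknown stage label {stage!r}"
                )
            stages.append(stage)
            if len(parts) == 3:
                if parts[2] not in ("0", "1"):
                    raise HypnogramError(
                        f"{path}:{lineno}: artifact flag must be 0 or 1, got {parts[2]!r}"
                    )
                have_mask = True
                mask.append(parts[2] == "1")
            else:
                mask.append(False)
    if not stages:
        raise HypnogramError(f"{path}: no epochs found")
    return Hypnogram(
        subject_id=meta.get("subject", path.stem),
        group=meta.get("group", ""),
        stages=tuple(stages),
        epoch_length=float(meta.get("epoch_length_s", 4.0)),
        start_time=float(meta.get("start_time_s", 0.0)),
        artifact_mask=tuple(mask) if have_mask else None,
        vocabulary=meta.get("vocabulary", ""),
    )
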