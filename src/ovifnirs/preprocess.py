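"""Ingestion and conditioning of multi-distance OD recordings.

Segments task blocks out of a continuous recording, references each block to
its pre-onset baseline (the last 5 s before the task phase), and applies the
ethogram-driven exclusion rules: blocks contaminated by interfering behaviors
are dropped, subjects showing an interfering behavior in most blocks are
dropped entirely, and startle blocks are stratified into Move (flight) and
Stand (freezing) groups.

All intervals are half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "ODRecording",
    "BlockSchedule",
    "BehaviorAnnotation",
    "BlockSlice",
    "DeltaODSeries",
    "ExclusionRules",
    "DEFAULT_ETHOGRAM",
    "segment_blocks",
    "compute_delta_od",
    "apply_exclusion",
    "classify_reaction",
    "read_od_csv",
    "write_od_csv",
    "read_annotations_csv",
]

# behaviors recognized by default; config-extensible through ExclusionRules
DEFAULT_ETHOGRAM = frozenset({
    "head_shake", "chewing", "running", "jumping",
    "flight", "freezing", "walking", "standing",
})


@dataclass(frozen=True, order=True)
class Channel:
    """Key of one optical channel: hemisphere x distance x wavelength."""

    hemisphere: str   # "left" | "right"
    distance: str     # "short" | "long"
    wavelength: float # nm

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere}")
        if self.distance not in ("short", "long"):
            raise ValueError(f"distance must be short/long, got {self.distance}")

    @property
    def column(self) -> str:
        wl = int(self.wavelength) if float(self.wavelength).is_integer() else self.wavelength
        return f"{self.hemisphere}_{self.distance}_{wl}"

    @classmethod
    def from_column(cls, name: str) -> "Channel":
        hemi, dist, wl = name.split("_")
        return cls(hemi, dist, float(wl))


@dataclass
class ODRecording:
    """A continuous optical-density recording on a uniform time grid."""

    time: np.ndarray
    od: dict[Channel, np.ndarray]
    subject_id: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-D grid with >= 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(dt > 2.0 * np.median(dt)):
            raise ValueError("recording has gaps larger than one sample")
        n = self.time.size
        for ch, series in self.od.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"channel {ch.column} length {arr.shape} != {n}")
            self.od[ch] = arr

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def channels(self) -> list[Channel]:
        return sorted(self.od)


# analysis windows relative to task onset (phase start), seconds.
# motor: 5 s baseline + 30 s walk + 5 s recovery; the remaining rest is unused.
# startle: 5 s baseline (end of the 30 s pre-stimulus phase) + 3 s stimulus
# + 60 s reaction.
_TASK_WINDOWS = {
    "motor": {"pre": 5.0, "task": 30.0, "post": 5.0},
    "startle": {"pre": 5.0, "task": 3.0, "post": 60.0},
}


@dataclass(frozen=True)
class BlockSchedule:
    """Timing of the repeated task blocks within one recording.

    ``block_starts`` are the onsets of the task phase (walk onset for the
    motor task, umbrella opening for the startle test), seconds from the
    start of the recording.
    """

    task: str
    block_starts: Sequence[float]

    def __post_init__(self) -> None:
        if self.task not in _TASK_WINDOWS:
            raise ValueError(f"task must be one of {sorted(_TASK_WINDOWS)}")
        starts = tuple(float(t) for t in self.block_starts)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("block_starts must be strictly increasing")
        w = self.window
        span = w["task"] + w["post"] + w["pre"]
        if any(b - a < span for a, b in zip(starts, starts[1:])):
            raise ValueError("blocks overlap within the analysis window")
        object.__setattr__(self, "block_starts", starts)

    @property
    def window(self) -> Mapping[str, float]:
        return _TASK_WINDOWS[self.task]

    @property
    def analysis_span(self) -> tuple[float, float]:
        """(offset_start, offset_end) of the analysis window, rel. onset."""
        w = self.window
        return (-w["pre"], w["task"] + w["post"])


@dataclass(frozen=True)
class BehaviorAnnotation:
    """One coded behavior interval from the video ethogram."""

    subject_id: str
    behavior: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"annotation start {self.start} !< end {self.end}")

    def overlaps(self, start: float, end: float) -> bool:
        """Half-open interval overlap with [start, end)."""
        return self.start < end and start < self.end


@dataclass
class BlockSlice:
    """One task block cut to its analysis window."""

    subject_id: str
    task: str
    index: int
    onset: float                 # absolute task-phase onset, s
    time: np.ndarray             # seconds relative to onset
    od: dict[Channel, np.ndarray]
    baseline_window: tuple[float, float]  # relative, [start, end)
    task_window: tuple[float, float]

    @property
    def analysis_window_abs(self) -> tuple[float, float]:
        return (self.onset + self.time[0],
                self.onset + self.time[-1] + (self.time[1] - self.time[0]))


@dataclass
class DeltaODSeries:
    """Baseline-referenced DeltaOD of one block (decadic, dimensionless)."""

    subject_id: str
    task: str
    index: int
    onset: float
    time: np.ndarray
    delta_od: dict[Channel, np.ndarray]
    baseline_window: tuple[float, float]
    task_window: tuple[float, float]
    flags: list[str] = field(default_factory=list)


def segment_blocks(rec: ODRecording, sched: BlockSchedule
                   ) -> tuple[list[BlockSlice], list[tuple[int, str]]]:
    """Cut the recording into per-block analysis windows.

    Returns ``(slices, dropped)`` where ``dropped`` holds ``(block_index,
    reason)`` for blocks whose analysis window leaves the recording.
    Sample selection is half-open ``[onset+off0, onset+off1)``.
    """
    off0, off1 = sched.analysis_span
    w = sched.window
    slices: list[BlockSlice] = []
    dropped: list[tuple[int, str]] = []
    t = rec.time
    for i, onset in enumerate(sched.block_starts):
        lo, hi = onset + off0, onset + off1
        if lo < t[0] - 1e-9 or hi > t[-1] + 1.0 / rec.sampling_rate + 1e-9:
            dropped.append((i, f"analysis window [{lo:g}, {hi:g}) outside recording"))
            continue
        sel = (t >= lo - 1e-9) & (t < hi - 1e-9)
        idx = np.nonzero(sel)[0]
        slices.append(BlockSlice(
            subject_id=rec.subject_id, task=sched.task, index=i, onset=onset,
            time=t[idx] - onset,
            od={ch: series[idx] for ch, series in rec.od.items()},
            baseline_window=(-w["pre"], 0.0),
            task_window=(0.0, w["task"])))
    return slices, dropped


def compute_delta_od(block: BlockSlice) -> DeltaODSeries:
    """DeltaOD(t) = OD(t) - mean(OD over the baseline window), per channel.

    A zero-variance (flat-line) channel is flagged, not rejected.
    """
    b0, b1 = block.baseline_window
    sel = (block.time >= b0 - 1e-9) & (block.time < b1 - 1e-9)
    if not np.any(sel):
        raise ValueError("baseline window contains no samples")
    flags: list[str] = []
    dod = {}
    for ch, series in block.od.items():
        if np.ptp(series) == 0.0:
            flags.append(f"flat_channel:{ch.column}")
        dod[ch] = series - series[sel].mean()
    return DeltaODSeries(
        subject_id=block.subject_id, task=block.task, index=block.index,
        onset=block.onset, time=block.time, delta_od=dod,
        baseline_window=block.baseline_window, task_window=block.task_window,
        flags=flags)


@dataclass(frozen=True)
class ExclusionRules:
    """Ethogram-driven exclusion configuration.

    ``excluding`` behaviors invalidate any block whose analysis window they
    overlap.  A subject is dropped entirely when the fraction of its blocks
    overlapped by one excluding behavior exceeds ``frequent_fraction``
    ("frequent head shaking").  For the startle task, a block with neither
    flight nor freezing in the stimulus+reaction window is excluded.
    """

    excluding: frozenset[str] = frozenset({"head_shake", "chewing", "running", "jumping"})
    frequent_fraction: float = 0.5
    require_reaction: bool = True
    vocabulary: frozenset[str] = DEFAULT_ETHOGRAM

    def validate(self, annotations: Iterable[BehaviorAnnotation]) -> None:
        unknown = {a.behavior for a in annotations} - set(self.vocabulary)
        if unknown:
            raise ValueError(
                f"unknown behavior codes {sorted(unknown)}; "
                f"known vocabulary: {sorted(self.vocabulary)}")


def _block_window_abs(block) -> tuple[float, float]:
    if isinstance(block, (BlockSlice, DeltaODSeries)):
        dt = block.time[1] - block.time[0]
        return block.onset + block.time[0], block.onset + block.time[-1] + dt
    raise TypeError(f"not a block: {type(block)}")


def _reaction_window_abs(block) -> tuple[float, float]:
    """Stimulus + reaction span (task onset through end of window)."""
    dt = block.time[1] - block.time[0]
    return block.onset, block.onset + block.time[-1] + dt


def apply_exclusion(blocks: Sequence, annotations: Sequence[BehaviorAnnotation],
                    rules: ExclusionRules = ExclusionRules(),
                    ) -> tuple[list, list[tuple[object, str]]]:
    """Partition blocks into (retained, excluded-with-reason).

    Deterministic and order-independent: the verdict of each block depends
    only on the annotations overlapping its windows, and subject-level
    exclusion only on per-subject overlap fractions.
    """
    rules.validate(annotations)
    by_subject: dict[str, list] = {}
    for b in blocks:
        by_subject.setdefault(b.subject_id, []).append(b)

    # subject-level: one excluding behavior present in > frequent_fraction of blocks
    frequent_subjects: dict[str, str] = {}
    for subj, subj_blocks in by_subject.items():
        anns = [a for a in annotations if a.subject_id == subj]
        for code in sorted(rules.excluding):
            hits = sum(
                any(a.behavior == code and a.overlaps(*_block_window_abs(b))
                    for a in anns)
                for b in subj_blocks)
            if hits / len(subj_blocks) > rules.frequent_fraction:
                frequent_subjects[subj] = code
                break

    retained: list = []
    excluded: list[tuple[object, str]] = []
    for b in blocks:
        subj_anns = [a for a in annotations if a.subject_id == b.subject_id]
        if b.subject_id in frequent_subjects:
            excluded.append((b, f"subject_frequent_{frequent_subjects[b.subject_id]}"))
            continue
        win = _block_window_abs(b)
        hits = [a for a in subj_anns
                if a.behavior in rules.excluding and a.overlaps(*win)]
        if hits:
            first = min(hits, key=lambda a: (a.start, a.behavior))
            excluded.append((b, f"behavior_{first.behavior}"))
            continue
        if b.task == "startle" and rules.require_reaction:
            rwin = _reaction_window_abs(b)
            has_reaction = any(a.behavior in ("flight", "freezing")
                               and a.overlaps(*rwin) for a in subj_anns)
            if not has_reaction:
                excluded.append((b, "no_reaction"))
                continue
        retained.append(b)
    return retained, excluded


def classify_reaction(block, annotations: Sequence[BehaviorAnnotation]) -> str:
    """Label a retained startle block ``"move"`` (flight) or ``"stand"``
    (freezing without flight).  Flight dominates when both occur.
    """
    if block.task != "startle":
        raise ValueError("reaction classification applies to startle blocks only")
    rwin = _reaction_window_abs(block)
    subj_anns = [a for a in annotations if a.subject_id == block.subject_id
                 and a.overlaps(*rwin)]
    has_flight = any(a.behavior == "flight" for a in subj_anns)
    has_freeze = any(a.behavior == "freezing" for a in subj_anns)
    if has_flight:
        return "move"
    if has_freeze:
        return "stand"
    raise ValueError(
        f"block {block.subject_id}/{block.index} has neither flight nor "
        "freezing; it should have been excluded")


# ---------------------------------------------------------------------------
# file I/O: delimited text, columns `time, <hemi>_<dist>_<wl>`

def read_od_csv(path: str | Path, subject_id: str | None = None) -> ODRecording:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    od = {Channel.from_column(c): df[c].to_numpy(dtype=float)
          for c in df.columns if c != "time"}
    if not od:
        raise ValueError(f"{path}: no channel columns")
    return ODRecording(df["time"].to_numpy(dtype=float), od,
                       subject_id or Path(path).stem)


def write_od_csv(rec: ODRecording, path: str | Path) -> None:
    df = pd.DataFrame({"time": rec.time})
    for ch in rec.channels():
        df[ch.column] = rec.od[ch]
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotations_csv(path: str | Path) -> list[BehaviorAnnotation]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    required = {"subject", "behavior", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    return [BehaviorAnnotation(str(r.subject), str(r.behavior),
                               float(r.start), float(r.end))
            for r in df.itertuples()]
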