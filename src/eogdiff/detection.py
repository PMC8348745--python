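"""Velocity-threshold saccade identification and event matching.

The identifier is the classic two-threshold velocity rule: candidate
events are maximal runs of samples whose absolute velocity exceeds the
onset/offset threshold Pt, and a candidate is kept only if it contains
at least one sample at or above the occurrence threshold Ot (and lasts
at least ``min_duration``). Ground-truth ("exact") events are obtained
by running the same identifier on the noise-free exact velocity profile,
so detector and reference share one event definition.

Detected events are scored against exact events by greedy
maximum-overlap matching; unmatched exact events are *misidentified*
(misses) and unmatched detected events are *over-identified*
(false positives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SyntheticRecord

__all__ = [
    "DetectionConfig",
    "SaccadeEvent",
    "MatchResult",
    "identify_saccades",
    "annotate_exact_events",
    "match_events",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the velocity identifier.

    pt : onset/offset threshold (deg/s); an event spans the contiguous
        samples with |v| >= pt around its peak. Default 20 deg/s.
    ot : occurrence threshold (deg/s); a candidate run must reach ot at
        least once. Must exceed pt. Default 40 deg/s — well above the
        onset threshold and far below any generated peak velocity.
    min_duration : minimum event duration in seconds (default 10 ms,
        rejects single-sample spikes).
    merge_gap : runs separated by less than this many seconds are merged
        before thresholding on ot (default 0: no merging).
    """

    pt: float = 20.0
    ot: float = 40.0
    min_duration: float = 0.010
    merge_gap: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ot > self.pt > 0):
            raise ValueError(
                f"thresholds must satisfy ot > pt > 0, got ot={self.ot}, pt={self.pt}"
            )
        if self.min_duration < 0 or self.merge_gap < 0:
            raise ValueError("min_duration and merge_gap must be >= 0")


@dataclass(frozen=True, order=True)
class SaccadeEvent:
    """One saccade as a closed index interval [onset_index, offset_index]."""

    onset_index: int
    offset_index: int

    def __post_init__(self) -> None:
        if self.onset_index > self.offset_index:
            raise ValueError(
                f"onset {self.onset_index} after offset {self.offset_index}"
            )
        if self.onset_index < 0:
            raise ValueError("negative onset index")

    def onset_time(self, fs: float) -> float:
        return self.onset_index / fs

    def offset_time(self, fs: float) -> float:
        return self.offset_index / fs

    def n_samples(self) -> int:
        return self.offset_index - self.onset_index + 1

    def duration(self, fs: float) -> float:
        return (self.offset_index - self.onset_index) / fs

    def overlap(self, other: "SaccadeEvent") -> int:
        """Number of shared samples with another event."""
        lo = max(self.onset_index, other.onset_index)
        hi = min(self.offset_index, other.offset_index)
        return max(0, hi - lo + 1)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of pairing detected events against exact events."""

    pairs: tuple[tuple[SaccadeEvent, SaccadeEvent], ...]
    misidentified: int
    over_identified: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as closed (start, stop) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.insert(starts, 0, 0)
    if mask[-1]:
        stops = np.append(stops, mask.size - 1)
    return list(zip(starts.tolist(), stops.tolist()))


def identify_saccades(
    velocity: Sequence[float] | np.ndarray,
    fs: float,
    cfg: DetectionConfig | None = None,
) -> list[SaccadeEvent]:
    """Detect saccades in a velocity profile by the two-threshold rule.

    Steps: (1) mark samples with ``|v| >= pt``; (2) take maximal marked
    runs; (3) merge runs separated by less than ``merge_gap``; (4) keep
    runs reaching ``ot``; (5) drop runs shorter than ``min_duration``.
    """
    cfg = cfg or DetectionConfig()
    v = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity contains non-finite samples")
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")

    speed = np.abs(v)
    runs = _runs(speed >= cfg.pt)

    if cfg.merge_gap > 0 and len(runs) > 1:
        gap_samples = cfg.merge_gap * fs
        merged = [runs[0]]
        for start, stop in runs[1:]:
            if start - merged[-1][1] - 1 < gap_samples:
                merged[-1] = (merged[-1][0], stop)
            else:
                merged.append((start, stop))
        runs = merged

    min_samples = cfg.min_duration * fs
    events = [
        SaccadeEvent(start, stop)
        for start, stop in runs
        if speed[start : stop + 1].max() >= cfg.ot
        and (stop - start) >= min_samples
    ]
    return events


def annotate_exact_events(
    record: "SyntheticRecord", cfg: DetectionConfig | None = None
) -> list[SaccadeEvent]:
    """Ground-truth events: the identifier run on the noise-free EVP."""
    return identify_saccades(record.evp, record.fs, cfg)


def _check_disjoint_sorted(events: Sequence[SaccadeEvent], label: str) -> None:
    for a, b in zip(events, events[1:]):
        if b.onset_index <= a.offset_index:
            raise ValueError(f"{label} events overlap or are unsorted: {a} vs {b}")


def match_events(
    exact: Sequence[SaccadeEvent],
    detected: Sequence[SaccadeEvent],
    fs: float | None = None,
) -> MatchResult:
    """Greedy maximum-overlap matching of detected against exact events.

    Each detected event is assigned to the exact event sharing the most
    samples with it (ties: the earlier exact event). An exact event
    keeps at most one detected event — the largest-overlap one (ties:
    the earlier detected event); the rest count as over-identified.
    Detected events overlapping no exact event are over-identified;
    exact events left without a partner are misidentified.
    """
    exact = sorted(exact)
    detected = sorted(detected)
    _check_disjoint_sorted(exact, "exact")
    _check_disjoint_sorted(detected, "detected")

    # detected index -> (overlap, exact index) of its best exact event
    best: dict[int, list[tuple[int, int]]] = {}
    over = 0
    for di, det in enumerate(detected):
        ov = [(det.overlap(ex), ei) for ei, ex in enumerate(exact)]
        ov = [(o, ei) for o, ei in ov if o > 0]
        if not ov:
            over += 1
            continue
        o, ei = max(ov, key=lambda t: (t[0], -t[1]))
        best.setdefault(ei, []).append((o, di))

    pairs = []
    for ei, cands in best.items():
        o, winner = max(cands, key=lambda t: (t[0], -t[1]))
        pairs.append((exact[ei], detected[winner]))
        over += len(cands) - 1

    pairs.sort(key=lambda p: p[0].onset_index)
    mis = len(exact) - len(pairs)
    return MatchResult(pairs=tuple(pairs), misidentified=mis, over_identified=over)
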