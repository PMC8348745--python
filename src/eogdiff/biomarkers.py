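"""Saccadic biomarkers: peak velocity, latency, duration.

Peak velocity is the maximum absolute velocity inside an event — the
key biomarker for SCA2, whose hallmark is saccadic slowing. Latency is
the time from the most recent stimulus transition to saccade onset.
Duration is the onset-to-offset time. Errors introduced by a
differentiator are measured per matched event pair as the absolute
difference between the biomarker computed on the exact velocity
profile (EVP) and on the approximated one (AVP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import SaccadeEvent

__all__ = [
    "BiomarkerSet",
    "BiomarkerErrors",
    "peak_velocity",
    "latency",
    "duration",
    "compute_biomarkers",
    "biomarker_errors",
]

BIOMARKERS = ("peak_velocity", "latency", "duration")


@dataclass(frozen=True)
class BiomarkerSet:
    peak_velocity: float  # deg/s
    latency: float | None  # s; None when no stimulus transition precedes onset
    duration: float  # s


@dataclass(frozen=True)
class BiomarkerErrors:
    """Absolute errors |biomarker(ES) - biomarker(AS)| for one pair."""

    peak_velocity: float
    latency: float | None  # None when latency undefined on either side
    duration: float

    def __post_init__(self) -> None:
        vals = [self.peak_velocity, self.duration]
        if self.latency is not None:
            vals.append(self.latency)
        if any(v < 0 for v in vals):
            raise ValueError("absolute errors cannot be negative")


def peak_velocity(
    event: SaccadeEvent, velocity: Sequence[float] | np.ndarray, fs: float | None = None
) -> float:
    """Max |v| over the closed event interval, in deg/s."""
    v = np.asarray(velocity, dtype=float)
    if event.offset_index >= v.size:
        raise IndexError(
            f"event [{event.onset_index}, {event.offset_index}] exceeds "
            f"signal length {v.size}"
        )
    return float(np.abs(v[event.onset_index : event.offset_index + 1]).max())


def latency(
    event: SaccadeEvent,
    stimulus_transitions: Sequence[float] | np.ndarray,
    fs: float,
) -> float | None:
    """Onset time minus the most recent stimulus transition, in seconds.

    Returns None when no transition precedes the onset; callers exclude
    such events from latency aggregation (they are signalled, not
    silently dropped into another value).
    """
    onset_t = event.onset_time(fs)
    trans = np.asarray(stimulus_transitions, dtype=float)
    before = trans[trans <= onset_t]
    if before.size == 0:
        return None
    return float(onset_t - before.max())


def duration(event: SaccadeEvent, fs: float) -> float:
    """Onset-to-offset time, (offset_index - onset_index) / fs."""
    return event.duration(fs)


def compute_biomarkers(
    event: SaccadeEvent,
    velocity: Sequence[float] | np.ndarray,
    stimulus_transitions: Sequence[float] | np.ndarray,
    fs: float,
) -> BiomarkerSet:
    return BiomarkerSet(
        peak_velocity=peak_velocity(event, velocity),
        latency=latency(event, stimulus_transitions, fs),
        duration=duration(event, fs),
    )


def biomarker_errors(
    pair: tuple[SaccadeEvent, SaccadeEvent],
    evp: Sequence[float] | np.ndarray,
    avp: Sequence[float] | np.ndarray,
    stimulus_transitions: Sequence[float] | np.ndarray,
    fs: float,
) -> BiomarkerErrors:
    """Per-biomarker absolute error for one matched (exact, detected) pair.

    Exact-side biomarkers always come from the EVP, detected-side from
    the AVP; both latencies reference the same stimulus train.
    """
    es, asac = pair
    bm_es = compute_biomarkers(es, evp, stimulus_transitions, fs)
    bm_as = compute_biomarkers(asac, avp, stimulus_transitions, fs)
    if bm_es.latency is None or bm_as.latency is None:
        lat_err = None
    else:
        lat_err = abs(bm_es.latency - bm_as.latency)
    return BiomarkerErrors(
        peak_velocity=abs(bm_es.peak_velocity - bm_as.peak_velocity),
        latency=lat_err,
        duration=abs(bm_es.duration - bm_as.duration),
    )
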