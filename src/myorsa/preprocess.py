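"""Segmentation of recordings into trimmed per-repetition phase segments.

To remove reaction-time transients around each auditory cue, a fixed
fraction (default 15%) of every phase interval is discarded from both the
onset and the recession, keeping the central 70% of each relaxation and
contraction (e.g. 6000 Hz × 3 s × 0.7 = 12,600 contraction samples).
Repetitions are indexed globally across trials: trial 1 contributes
repetitions 1..cycles, trial 2 the next block, and so on.  Features are
computed per repetition; repetitions are grouped, never concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolConfig
from .simulate import RawRecording


class ScheduleError(ValueError):
    """The recording's schedule is inconsistent with the protocol config."""


@dataclass
class PhaseSegment:
    """One trimmed repetition of one phase of one movement."""

    limb: str
    movement: str
    repetition: int
    phase: str
    channel_data: np.ndarray  # channels × samples, mV

    @property
    def n_samples(self) -> int:
        return self.channel_data.shape[1]


def trim_segment(samples: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Return the central ``1 − 2·trim_fraction`` portion of a series.

    The kept length is ``floor(L * (1 − 2*trim_fraction))``; removal is
    symmetric, with any surplus sample dropped from the end.  Works on the
    last axis, so a channels×samples matrix is trimmed column-wise.
    """
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    samples = np.asarray(samples)
    length = samples.shape[-1]
    keep = int(np.floor(length * (1.0 - 2.0 * trim_fraction)))
    start = (length - keep) // 2
    return samples[..., start:start + keep]


def trimmed_length(duration_s: float, sampling_rate: float,
                   trim_fraction: float) -> int:
    """Number of samples a phase of ``duration_s`` keeps after trimming."""
    length = round(duration_s * sampling_rate)
    return int(np.floor(length * (1.0 - 2.0 * trim_fraction)))


def segment_phases(recording: RawRecording,
                   config: ProtocolConfig) -> list[PhaseSegment]:
    """Cut a recording into trimmed per-repetition phase segments.

    Returns ``trials × cycles`` segments per (movement, phase), ordered as
    scheduled.  The repetition index is global across trials (trial 1
    cycles map to 1..cycles_per_trial, trial 2 continues the count).
    """
    segments: list[PhaseSegment] = []
    n_samples = recording.signal.shape[1]
    expected = {phase: config.phase_samples(phase)
                for phase in ("relaxation", "contraction")}
    for row in recording.schedule.itertuples(index=False):
        if row.phase not in expected:
            raise ScheduleError(f"unknown phase {row.phase!r}")
        length = row.end_sample - row.start_sample
        if length != expected[row.phase]:
            raise ScheduleError(
                f"{row.movement} trial {row.trial} cycle {row.cycle} "
                f"{row.phase}: interval of {length} samples does not match "
                f"the configured duration ({expected[row.phase]})")
        if row.start_sample < 0 or row.end_sample > n_samples:
            raise ScheduleError("schedule interval outside the recording")
        repetition = (row.trial - 1) * config.cycles_per_trial + row.cycle
        data = recording.signal[:, row.start_sample:row.end_sample]
        segments.append(PhaseSegment(
            limb=recording.limb,
            movement=row.movement,
            repetition=int(repetition),
            phase=row.phase,
            channel_data=trim_segment(data, config.trim_fraction),
        ))
    return segments
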