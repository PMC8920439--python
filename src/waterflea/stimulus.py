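"""Stimulus schedules for stimulated-swimming recordings.

A recording session alternates natural swimming with timed sensory
stimuli (dim light, bright light, substrate vibration).  The schedule is
a list of labelled, non-overlapping windows inside the recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

STIMULUS_LABELS = ("weak_light", "strong_light", "vibration")
LIGHT_LABELS = ("weak_light", "strong_light")


@dataclass(frozen=True)
class StimulusWindow:
    label: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.label not in STIMULUS_LABELS:
            raise ValueError(f"unknown stimulus label {self.label!r}; expected one of {STIMULUS_LABELS}")
        if not (self.offset_s > self.onset_s >= 0.0):
            raise ValueError(f"stimulus window must satisfy 0 <= onset < offset, got ({self.onset_s}, {self.offset_s})")

    @property
    def is_light(self) -> bool:
        return self.label in LIGHT_LABELS


@dataclass(frozen=True)
class StimulusSchedule:
    """Non-overlapping stimulus windows within a recording of fixed length."""

    windows: tuple[StimulusWindow, ...]
    recording_s: float

    def __post_init__(self) -> None:
        if self.recording_s <= 0:
            raise ValueError("recording length must be positive")
        ordered = sorted(self.windows, key=lambda w: w.onset_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError(f"overlapping stimulus windows: {a} / {b}")
        for w in self.windows:
            if w.offset_s > self.recording_s:
                raise ValueError(f"window {w} extends past recording end {self.recording_s}s")

    def active(self, t_s: float) -> StimulusWindow | None:
        """Window containing time ``t_s`` (onset inclusive, offset exclusive)."""
        for w in self.windows:
            if w.onset_s <= t_s < w.offset_s:
                return w
        return None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "recording_s": self.recording_s,
            "windows": [{"label": w.label, "onset_s": w.onset_s, "offset_s": w.offset_s} for w in self.windows],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusSchedule":
        payload = json.loads(Path(path).read_text())
        windows = tuple(StimulusWindow(w["label"], float(w["onset_s"]), float(w["offset_s"])) for w in payload["windows"])
        return cls(windows=windows, recording_s=float(payload["recording_s"]))


def default_schedule(recording_s: float = 120.0) -> StimulusSchedule:
    """Standard 2-minute stimulated-swimming protocol.

    Weak light at 20-30 s, strong light at 40-50 s and vibration at
    70-80 s; windows falling beyond a shorter recording are dropped.
    """
    canonical = (
        StimulusWindow("weak_light", 20.0, 30.0),
        StimulusWindow("strong_light", 40.0, 50.0),
        StimulusWindow("vibration", 70.0, 80.0),
    )
    kept = tuple(w for w in canonical if w.offset_s <= recording_s)
    return StimulusSchedule(windows=kept, recording_s=recording_s)
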