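"""Stimulus design, stimulus logs, and trial unmixing.

The experiments present a grid of pure tones (frequency x sound level),
each repeated a fixed number of times in randomized order while imaging at a
constant frame rate.  Analysis operates on *trial tensors*: recordings cut
into fixed-length epochs around each tone onset and sorted into a
``unit x time x frequency x level x repeat`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusGrid",
    "StimulusLog",
    "TrialTensor",
    "build_stimulus_grid",
    "default_widefield_grid",
    "default_twophoton_grid",
    "unmix_trials",
]


@dataclass(frozen=True)
class StimulusGrid:
    """The tone frequency x sound level x repeat trial design with frame timing.

    Parameters
    ----------
    frequencies_khz
        Tone frequencies in kHz, strictly increasing.
    levels_db
        Sound levels in dB SPL, strictly increasing.
    n_repeats
        Presentations per (frequency, level) condition.
    frame_rate_hz
        Acquisition frame rate.
    trial_frames
        Frames per trial epoch (T).
    onset_frame
        0-based frame index of tone onset within a trial epoch.  Must leave
        room for a 1 s pre-onset baseline window.
    tone_frames
        Tone duration in frames.  Defaults to 500 ms at the frame rate.
    """

    frequencies_khz: tuple[float, ...]
    levels_db: tuple[float, ...]
    n_repeats: int
    frame_rate_hz: float
    trial_frames: int
    onset_frame: int
    tone_frames: int = 0  # 0 -> derived in __post_init__

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies_khz", tuple(float(f) for f in self.frequencies_khz))
        object.__setattr__(self, "levels_db", tuple(float(a) for a in self.levels_db))
        if self.tone_frames == 0:
            object.__setattr__(self, "tone_frames", int(round(0.5 * self.frame_rate_hz)))
        self._validate()

    def _validate(self) -> None:
        f, a = self.frequencies_khz, self.levels_db
        if len(f) == 0 or len(a) == 0:
            raise ValueError("frequencies and levels must be nonempty")
        if any(x <= 0 for x in f):
            raise ValueError("frequencies must be positive")
        if any(f[i] >= f[i + 1] for i in range(len(f) - 1)):
            raise ValueError(f"frequencies must be strictly increasing, got {f}")
        if any(a[i] >= a[i + 1] for i in range(len(a) - 1)):
            raise ValueError(f"levels must be strictly increasing, got {a}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.trial_frames < 1:
            raise ValueError("trial_frames must be >= 1")
        if self.onset_frame < self.baseline_frames:
            raise ValueError(
                f"onset_frame ({self.onset_frame}) must leave a 1 s baseline "
                f"({self.baseline_frames} frames)"
            )
        if self.onset_frame >= self.trial_frames:
            raise ValueError("onset_frame must lie within the trial")
        if self.tone_frames < 1:
            raise ValueError("tone_frames must be >= 1")

    @property
    def baseline_frames(self) -> int:
        """Length of the 1 s pre-onset baseline window, in frames."""
        return int(round(self.frame_rate_hz))

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies_khz)

    @property
    def n_levels(self) -> int:
        return len(self.levels_db)

    @property
    def n_conditions(self) -> int:
        return self.n_frequencies * self.n_levels

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.n_repeats

    def freq_index(self, freq_khz: float) -> int:
        for i, f in enumerate(self.frequencies_khz):
            if np.isclose(f, freq_khz):
                return i
        raise ValueError(f"unknown frequency {freq_khz} kHz (grid: {self.frequencies_khz})")

    def level_index(self, level_db: float) -> int:
        for i, a in enumerate(self.levels_db):
            if np.isclose(a, level_db):
                return i
        raise ValueError(f"unknown level {level_db} dB (grid: {self.levels_db})")

    def to_dict(self) -> dict:
        return {
            "frequencies_khz": list(self.frequencies_khz),
            "levels_db": list(self.levels_db),
            "n_repeats": self.n_repeats,
            "frame_rate_hz": self.frame_rate_hz,
            "trial_frames": self.trial_frames,
            "onset_frame": self.onset_frame,
            "tone_frames": self.tone_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusGrid":
        return cls(
            frequencies_khz=tuple(d["frequencies_khz"]),
            levels_db=tuple(d["levels_db"]),
            n_repeats=int(d["n_repeats"]),
            frame_rate_hz=float(d["frame_rate_hz"]),
            trial_frames=int(d["trial_frames"]),
            onset_frame=int(d["onset_frame"]),
            tone_frames=int(d["tone_frames"]),
        )


def build_stimulus_grid(
    frequencies_khz: Sequence[float],
    levels_db: Sequence[float],
    n_repeats: int,
    frame_rate_hz: float,
    trial_frames: int,
    onset_frame: int,
    tone_frames: int = 0,
) -> StimulusGrid:
    """Validate and construct a :class:`StimulusGrid`."""
    return StimulusGrid(
        frequencies_khz=tuple(frequencies_khz),
        levels_db=tuple(levels_db),
        n_repeats=n_repeats,
        frame_rate_hz=frame_rate_hz,
        trial_frames=trial_frames,
        onset_frame=onset_frame,
        tone_frames=tone_frames,
    )


DEFAULT_FREQUENCIES_KHZ = (4.0, 8.0, 16.0, 32.0, 64.0)
DEFAULT_LEVELS_DB = (30.0, 50.0, 70.0, 90.0)


def default_widefield_grid(n_repeats: int = 10) -> StimulusGrid:
    """5 frequencies x 4 levels x 10 repeats, 75-frame trials at 30 Hz."""
    return build_stimulus_grid(
        DEFAULT_FREQUENCIES_KHZ, DEFAULT_LEVELS_DB, n_repeats,
        frame_rate_hz=30.0, trial_frames=75, onset_frame=30,
    )


def default_twophoton_grid(n_repeats: int = 10) -> StimulusGrid:
    """5 frequencies x 4 levels x 10 repeats, 75-frame trials at 15 Hz."""
    return build_stimulus_grid(
        DEFAULT_FREQUENCIES_KHZ, DEFAULT_LEVELS_DB, n_repeats,
        frame_rate_hz=15.0, trial_frames=75, onset_frame=15,
    )


@dataclass
class StimulusLog:
    """Acquisition-side record of tone presentations, in temporal order."""

    onset_frames: np.ndarray  # absolute frame of each tone onset
    frequencies_khz: np.ndarray
    levels_db: np.ndarray

    def __post_init__(self) -> None:
        self.onset_frames = np.asarray(self.onset_frames, dtype=int)
        self.frequencies_khz = np.asarray(self.frequencies_khz, dtype=float)
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        n = len(self.onset_frames)
        if len(self.frequencies_khz) != n or len(self.levels_db) != n:
            raise ValueError("log columns must have equal length")
        if n > 1 and np.any(np.diff(self.onset_frames) <= 0):
            raise ValueError("onset frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset_frames)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "onset_frame": self.onset_frames,
                "freq_khz": self.frequencies_khz,
                "level_db": self.levels_db,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusLog":
        df = pd.read_csv(path)
        required = {"trial", "onset_frame", "freq_khz", "level_db"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"stimulus log missing columns: {sorted(missing)}")
        df = df.sort_values("trial")
        return cls(
            onset_frames=df["onset_frame"].to_numpy(),
            frequencies_khz=df["freq_khz"].to_numpy(),
            levels_db=df["level_db"].to_numpy(),
        )


@dataclass
class TrialTensor:
    """Responses unmixed into ``unit x T x F x A x R``.

    ``unit_kind`` distinguishes ROI tensors (two-photon) from pixel tensors
    (widefield).  ``is_dff`` records whether values are raw fluorescence or
    already baseline-normalized dF/F.
    """

    values: np.ndarray  # (units, T, F, A, R)
    grid: StimulusGrid
    unit_kind: str = "roi"  # "roi" | "pixel"
    is_dff: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        expected = (
            v.shape[0],
            self.grid.trial_frames,
            self.grid.n_frequencies,
            self.grid.n_levels,
            self.grid.n_repeats,
        )
        if v.ndim != 5 or v.shape != expected:
            raise ValueError(f"tensor shape {v.shape} does not match grid {expected}")
        if self.unit_kind not in ("roi", "pixel"):
            raise ValueError(f"unknown unit_kind {self.unit_kind!r}")
        self.values = v

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


def unmix_trials(traces: np.ndarray, log: StimulusLog, grid: StimulusGrid) -> TrialTensor:
    """Cut continuous traces into trial epochs and sort them onto the grid.

    Each log entry claims the epoch ``[onset - onset_frame, onset - onset_frame
    + trial_frames)`` of the recording.  The r-th presentation (in temporal
    order) of condition (f, a) fills slot ``(:, :, f, a, r)``; every slot must
    be filled exactly once.
    """
    traces = np.atleast_2d(np.asarray(traces))
    n_units, total = traces.shape
    F, A, R, T = grid.n_frequencies, grid.n_levels, grid.n_repeats, grid.trial_frames
    if len(log) != grid.n_trials:
        raise ValueError(f"log has {len(log)} trials, grid expects {grid.n_trials}")

    out = np.empty((n_units, T, F, A, R), dtype=traces.dtype)
    counts = np.zeros((F, A), dtype=int)
    for onset, fk, lv in zip(log.onset_frames, log.frequencies_khz, log.levels_db):
        fi = grid.freq_index(fk)
        ai = grid.level_index(lv)
        r = counts[fi, ai]
        if r >= R:
            raise ValueError(
                f"condition ({fk} kHz, {lv} dB) presented more than {R} times"
            )
        start = onset - grid.onset_frame
        if start < 0 or start + T > total:
            raise ValueError(
                f"trial epoch [{start}, {start + T}) out of recording bounds (0, {total})"
            )
        out[:, :, fi, ai, r] = traces[:, start : start + T]
        counts[fi, ai] = r + 1
    if np.any(counts != R):
        bad = np.argwhere(counts != R)[0]
        raise ValueError(
            f"incomplete grid: condition ({grid.frequencies_khz[bad[0]]} kHz, "
            f"{grid.levels_db[bad[1]]} dB) has {counts[bad[0], bad[1]]} of {R} repeats"
        )
    return TrialTensor(values=out, grid=grid)
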