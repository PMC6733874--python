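"""Motion-index extraction and stimulus-aligned behavioral profiles.

A well of larvae is filmed; the motion index (MI) at time step ``t`` is the
sum over pixels of absolute intensity differences between consecutive frames,
a cheap proxy for group motor activity.  Profiles are aligned to a timed
stimulus train (acoustic taps, light pulses), and per-stimulus response
magnitudes summarize startle behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, InvalidWindowError

STIMULUS_KINDS = ("acoustic_low", "acoustic_hard", "violet", "blue", "red")

#: Post-stimulus tail (s) included in response-magnitude windows.  A startle
#: bout outlasts a 70 ms tap, so the window extends past stimulus offset.
DEFAULT_TAIL_S = 1.0


@dataclass(frozen=True)
class FrameStack:
    """A time x height x width stack of non-negative grayscale frames."""

    frames: np.ndarray
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise InvalidInputError(f"frames must be 3-D (t, h, w), got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise InvalidInputError("a frame stack needs at least 2 frames")
        if np.any(frames < 0) or not np.all(np.isfinite(frames)):
            raise InvalidInputError("frame intensities must be finite and >= 0")
        if self.frame_rate <= 0:
            raise InvalidInputError("frame_rate must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class StimulusEvent:
    kind: str
    onset_s: float
    duration_s: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise InvalidInputError(f"unknown stimulus kind {self.kind!r}")
        if self.onset_s < 0 or self.duration_s <= 0:
            raise InvalidInputError("stimulus onset must be >= 0 and duration > 0")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class StimulusTrain:
    """Timed stimulus events making up an assay battery.

    A battery concatenates one or more assays; ``assay_starts`` marks assay
    boundaries and every assay segment must last 30-120 s.
    """

    events: tuple[StimulusEvent, ...]
    total_duration_s: float
    assay_starts: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        events = tuple(self.events)
        if not events:
            raise InvalidInputError("a stimulus train needs at least one event")
        onsets = [e.onset_s for e in events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise InvalidInputError("events must be sorted by onset")
        if any(e.offset_s > self.total_duration_s + 1e-9 for e in events):
            raise InvalidInputError("event extends past total_duration_s")
        bounds = list(self.assay_starts) + [self.total_duration_s]
        if list(self.assay_starts) != sorted(self.assay_starts) or bounds[0] != 0.0:
            raise InvalidInputError("assay_starts must be sorted and begin at 0")
        for a, b in zip(bounds, bounds[1:]):
            if not (30.0 <= b - a <= 120.0):
                raise InvalidInputError(f"assay segment [{a}, {b}) outside the 30-120 s bound")
        object.__setattr__(self, "events", events)

    def events_of(self, *kinds: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.kind in kinds)

    @property
    def acoustic_events(self) -> tuple[StimulusEvent, ...]:
        return self.events_of("acoustic_low", "acoustic_hard")

    @property
    def violet_events(self) -> tuple[StimulusEvent, ...]:
        return self.events_of("violet")


@dataclass
class BehavioralProfile:
    """One well's motion-index time series aligned to a stimulus train.

    ``mi[t]`` carries the timestamp of frame ``t+1`` (differences are assigned
    to the later frame), so sample times are ``(t+1)/sample_rate_hz``.
    """

    mi: np.ndarray
    stimulus_train: StimulusTrain
    sample_rate_hz: float = 25.0
    well_id: str = ""
    plate_id: str = ""
    treatment: str = "DMSO"
    concentration_uM: float = 0.0
    n_fish: int = 8
    nmi: np.ndarray = field(init=False, repr=False)
    degenerate: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        mi = np.asarray(self.mi, dtype=float)
        if mi.ndim != 1 or mi.size < 2:
            raise InvalidInputError("mi must be a 1-D series with >= 2 samples")
        if np.any(mi < 0) or not np.all(np.isfinite(mi)):
            raise InvalidInputError("mi must be finite and >= 0")
        self.mi = mi
        if np.max(mi) > 0:
            self.nmi = normalize_motion_index(mi)
            self.degenerate = False
        else:  # fully immobilized well: flag instead of erroring mid-pipeline
            self.nmi = np.zeros_like(mi)
            self.degenerate = True

    @property
    def times_s(self) -> np.ndarray:
        return (np.arange(self.mi.size) + 1.0) / self.sample_rate_hz

    def with_metadata(self, **kwargs) -> "BehavioralProfile":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ResponseMagnitudes:
    """Per-stimulus-type response summaries for one well.

    Magnitudes are means over repeated events of the window-maximum MI; a
    type absent from the battery yields ``None`` (absent, not zero).
    ``zscore``/``normalized_z`` are cohort-level and filled by
    :func:`zscore_normalize` over a well set.
    """

    acoustic_mag: float | None
    violet_mag: float | None
    startle_auc: float
    zscore: float | None = None
    normalized_z: float | None = None


def compute_motion_index(stack: FrameStack) -> np.ndarray:
    """MI series: per-step sum over pixels of |frame_n - frame_{n-1}|."""
    frames = stack.frames
    return np.abs(np.diff(frames, axis=0)).sum(axis=(1, 2))


def normalize_motion_index(mi: np.ndarray, *, on_degenerate: str = "raise") -> np.ndarray:
    """nMI = (MI - min(MI)) / max(MI).

    The divisor is max(MI), not (max - min), so the output maximum is
    (max - min)/max and need not reach 1; a constant positive series maps to
    all zeros.  An all-zero series is degenerate: ``on_degenerate`` selects
    raising (default) or returning zeros (pipeline context).
    """
    mi = np.asarray(mi, dtype=float)
    mx = np.max(mi) if mi.size else 0.0
    if mx <= 0:
        if on_degenerate == "zero":
            return np.zeros_like(mi)
        raise DegenerateInputError("all-zero MI series cannot be normalized")
    return (mi - np.min(mi)) / mx


def _window_indices(
    profile: BehavioralProfile, event: StimulusEvent, tail_s: float = 0.0
) -> np.ndarray:
    times = profile.times_s
    lo, hi = event.onset_s, event.offset_s + tail_s
    idx = np.nonzero((times >= lo) & (times < hi))[0]
    return idx


def startle_magnitude(
    profile: BehavioralProfile, event: StimulusEvent, *, tail_s: float = 0.0
) -> float:
    """Trapezoidal integral of MI over the stimulus window.

    The window is half-open [onset, offset + tail) on the profile's sampling
    grid; the integral uses the profile's sample spacing.
    """
    idx = _window_indices(profile, event, tail_s)
    if idx.size == 0:
        raise InvalidWindowError(
            f"stimulus window [{event.onset_s}, {event.offset_s + tail_s}) contains no samples"
        )
    return float(np.trapezoid(profile.mi[idx], dx=1.0 / profile.sample_rate_hz))


def _window_max(profile: BehavioralProfile, events, tail_s: float) -> float | None:
    maxima = []
    for e in events:
        idx = _window_indices(profile, e, tail_s)
        if idx.size:
            maxima.append(float(np.max(profile.mi[idx])))
    return float(np.mean(maxima)) if maxima else None


def response_magnitudes(
    profile: BehavioralProfile, *, tail_s: float = DEFAULT_TAIL_S
) -> ResponseMagnitudes:
    """Summaries per stimulus type: mean over events of the window-maximum MI.

    Windows extend ``tail_s`` past stimulus offset because startle bouts
    outlast brief taps.  ``startle_auc`` integrates MI over the raw stimulus
    windows (no tail).
    """
    train = profile.stimulus_train
    acoustic = _window_max(profile, train.acoustic_events, tail_s)
    violet = _window_max(profile, train.violet_events, tail_s)
    auc = 0.0
    for e in train.events:
        idx = _window_indices(profile, e, 0.0)
        if idx.size:
            auc += float(np.trapezoid(profile.mi[idx], dx=1.0 / profile.sample_rate_hz))
    return ResponseMagnitudes(acoustic_mag=acoustic, violet_mag=violet, startle_auc=auc)


def zscore_normalize(magnitudes: Sequence[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize a vector of well magnitudes and min-max rescale to [0, 1].

    z = (x - mean) / SD with the sample (n-1) SD; the normalized output is a
    min-max rescale of z across the well set.
    """
    x = np.asarray(magnitudes, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least 2 wells to standardize")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero standard deviation across wells")
    z = (x - float(np.mean(x))) / sd
    z_span = z.max() - z.min()
    normalized = (z - z.min()) / z_span if z_span > 0 else np.zeros_like(z)
    return z, normalized
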