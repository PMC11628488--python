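"""Auditory stimulus-sequence construction for stream-segregation oddball paradigms.

The ASME (Auditory Stream segregation Multiclass ERP) paradigms interleave
``N`` oddball tone streams at a fast overall stimulus onset asynchrony (SOA)
``t`` so that each stream is perceived as a segregated auditory stream with a
within-stream SOA of ``N * t``.  Two four-class variants are provided:

* ``asme4stream`` — four streams, one deviant per stream, overall SOA 0.15 s,
  600 stimuli per trial, per-stream standard:deviant ratio 9:1.
* ``asme2stream`` — two streams, two deviants per stream (one below and one
  above the standard in pitch), overall SOA 0.3 s, 300 stimuli per trial,
  per-stream ratio 8:1:1.

A conventional single-stream auditory ``oddball`` (SOA 1.0 s, ratio 5:1) is
included as a reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "InvalidPlanError",
    "OverlapError",
    "StimulusDef",
    "ParadigmConfig",
    "EventSequence",
    "TrialPlan",
    "LabeledEvents",
    "build_sequence",
    "assign_event_labels",
    "render_audio",
    "write_wav",
    "child_seed",
]

#: Event roles.  ``deviant_low``/``deviant_high`` distinguish the two deviants
#: embedded in each stream of the two-stream paradigm.
ROLES = ("standard", "deviant", "deviant_low", "deviant_high")
DEVIANT_ROLES = ("deviant", "deviant_low", "deviant_high")


class ConfigurationError(ValueError):
    """Raised when a paradigm configuration violates its invariants."""


class InvalidPlanError(ValueError):
    """Raised when a trial plan does not name an attendable deviant."""


class OverlapError(ValueError):
    """Raised when rendered tone bursts would overlap in time."""


@dataclass(frozen=True)
class StimulusDef:
    """One tone stimulus: its stream, identity, oddball role and pitch."""

    stream_index: int
    stimulus_id: str
    role: str
    frequency: float

    def __post_init__(self) -> None:
        if self.stream_index < 1:
            raise ConfigurationError("stream_index must be >= 1")
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}")
        if not self.frequency > 0:
            raise ConfigurationError("frequency must be positive")

    @property
    def is_deviant(self) -> bool:
        return self.role in DEVIANT_ROLES


@dataclass(frozen=True)
class ParadigmConfig:
    """Static description of one stimulation paradigm.

    ``ratio`` orders the per-stream presentation counts as
    ``(standard, deviant_1, deviant_2, ...)`` matching the order of that
    stream's stimuli; e.g. ``(9, 1)`` or ``(8, 1, 1)``.  The within-stream SOA
    is ``n_streams * soa``.
    """

    name: str
    n_streams: int
    soa: float
    n_stimuli_per_trial: int
    ratio: tuple[int, ...]
    stimuli: tuple[StimulusDef, ...]

    def __post_init__(self) -> None:
        if self.n_streams < 1:
            raise ConfigurationError("n_streams must be >= 1")
        if not self.soa > 0:
            raise ConfigurationError("soa must be positive")
        if self.n_stimuli_per_trial < 0:
            raise ConfigurationError("n_stimuli_per_trial must be >= 0")
        if any(r < 0 for r in self.ratio) or sum(self.ratio) <= 0:
            raise ConfigurationError("ratio entries must be non-negative, sum > 0")
        streams = self.stream_indices
        if streams != tuple(range(1, self.n_streams + 1)):
            raise ConfigurationError(
                f"stimuli must cover streams 1..{self.n_streams}, got {streams}"
            )
        for s in streams:
            stims = self.stream_stimuli(s)
            ids = [x.stimulus_id for x in stims]
            if len(set(ids)) != len(ids):
                raise ConfigurationError(f"duplicate stimulus ids in stream {s}")
            if len(stims) != len(self.ratio):
                raise ConfigurationError(
                    f"stream {s} has {len(stims)} stimuli but ratio has "
                    f"{len(self.ratio)} entries"
                )
            if stims[0].role != "standard" or any(not x.is_deviant for x in stims[1:]):
                raise ConfigurationError(
                    "each stream needs one standard first, then deviants"
                )

    @property
    def stream_indices(self) -> tuple[int, ...]:
        return tuple(sorted({s.stream_index for s in self.stimuli}))

    @property
    def soa_stm(self) -> float:
        """Within-stream SOA: ``n_streams * soa``."""
        return self.n_streams * self.soa

    @property
    def events_per_stream(self) -> int:
        if self.n_stimuli_per_trial % self.n_streams:
            raise ConfigurationError(
                f"{self.n_stimuli_per_trial} stimuli do not split evenly over "
                f"{self.n_streams} streams"
            )
        return self.n_stimuli_per_trial // self.n_streams

    def stream_stimuli(self, stream: int) -> tuple[StimulusDef, ...]:
        return tuple(s for s in self.stimuli if s.stream_index == stream)

    def deviants(self) -> tuple[StimulusDef, ...]:
        """All deviant stimuli across streams; defines the selectable classes."""
        return tuple(s for s in self.stimuli if s.is_deviant)

    def role_counts_per_stream(self) -> tuple[int, ...]:
        """Exact per-stream event counts implied by ratio, ordered like ratio."""
        n = self.events_per_stream
        unit, rem = divmod(n, sum(self.ratio))
        if rem:
            raise ConfigurationError(
                f"ratio {self.ratio} does not divide the per-stream count {n}"
            )
        return tuple(r * unit for r in self.ratio)

    def with_n_stimuli(self, n: int) -> "ParadigmConfig":
        return replace(self, n_stimuli_per_trial=n)

    # ---- standard configurations -------------------------------------------------

    @staticmethod
    def asme4stream() -> "ParadigmConfig":
        freqs = {  # tone frequencies per stream, ~2 semitones standard->deviant
            1: (110.00, 123.47),
            2: (415.30, 466.16),
            3: (1567.98, 1760.00),
            4: (5919.91, 6644.86),
        }
        stimuli = []
        for s, (f_std, f_dev) in freqs.items():
            stimuli.append(StimulusDef(s, f"S{s}", "standard", f_std))
            stimuli.append(StimulusDef(s, f"D{s}", "deviant", f_dev))
        return ParadigmConfig(
            name="asme4stream",
            n_streams=4,
            soa=0.15,
            n_stimuli_per_trial=600,
            ratio=(9, 1),
            stimuli=tuple(stimuli),
        )

    @staticmethod
    def asme2stream() -> "ParadigmConfig":
        stimuli = (
            StimulusDef(1, "S1", "standard", 523.3),
            StimulusDef(1, "D1", "deviant_low", 440.0),
            StimulusDef(1, "D2", "deviant_high", 622.3),
            StimulusDef(2, "S2", "standard", 3136.0),
            StimulusDef(2, "D3", "deviant_low", 2637.0),
            StimulusDef(2, "D4", "deviant_high", 3729.3),
        )
        return ParadigmConfig(
            name="asme2stream",
            n_streams=2,
            soa=0.3,
            n_stimuli_per_trial=300,
            ratio=(8, 1, 1),
            stimuli=stimuli,
        )

    @staticmethod
    def oddball(n_stimuli_per_trial: int = 120) -> "ParadigmConfig":
        stimuli = (
            StimulusDef(1, "S", "standard", 500.0),
            StimulusDef(1, "D", "deviant", 1000.0),
        )
        return ParadigmConfig(
            name="oddball",
            n_streams=1,
            soa=1.0,
            n_stimuli_per_trial=n_stimuli_per_trial,
            ratio=(5, 1),
            stimuli=stimuli,
        )

    @staticmethod
    def by_name(name: str, **kwargs) -> "ParadigmConfig":
        try:
            factory = {
                "asme4stream": ParadigmConfig.asme4stream,
                "asme2stream": ParadigmConfig.asme2stream,
                "oddball": ParadigmConfig.oddball,
            }[name]
        except KeyError:
            raise ConfigurationError(f"unknown paradigm {name!r}") from None
        return factory(**kwargs)


@dataclass(frozen=True)
class TrialPlan:
    """Which stream/deviant the listener attends in one trial."""

    target_stream: int
    target_stimulus_id: str
    trial_index: int = 0
    run_index: int = 0


@dataclass
class EventSequence:
    """Ordered stimulus events of one trial.

    Events are ``(onset_seconds, StimulusDef)`` pairs on a strict grid of the
    overall SOA; consecutive events cycle through the streams in fixed order
    1, 2, ..., N so each stream's within-stream SOA is exactly ``N * soa``.
    """

    events: list[tuple[float, StimulusDef]]
    paradigm: ParadigmConfig
    seed: int

    def __len__(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        """Trial duration: one SOA slot per event."""
        return len(self.events) * self.paradigm.soa

    def onsets(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    def to_dataframe(self, labels: "LabeledEvents | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "onset_s": [t for t, _ in self.events],
                "stream": [s.stream_index for _, s in self.events],
                "stimulus_id": [s.stimulus_id for _, s in self.events],
                "role": [s.role for _, s in self.events],
                "frequency_hz": [s.frequency for _, s in self.events],
            }
        )
        if labels is not None:
            df["label"] = labels.labels
        return df

    def to_tsv(self, path: str | Path, labels: "LabeledEvents | None" = None) -> None:
        self.to_dataframe(labels).to_csv(path, sep="\t", index=False)


@dataclass
class LabeledEvents:
    """Binary target/nontarget label plus an auxiliary role tag per event."""

    labels: list[str]
    tags: list[str]
    plan: TrialPlan

    def target_mask(self) -> np.ndarray:
        return np.array([lb == "target" for lb in self.labels])


def _sample_nonadjacent(rng: np.random.Generator, n_slots: int, k: int) -> np.ndarray:
    """Uniformly sample k pairwise non-adjacent slots from 2..n_slots-1.

    Uses the gap bijection: k non-adjacent picks from m slots correspond to k
    unordered picks from m - k + 1.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    m = n_slots - 2  # first two slots of each stream stay deviant-free
    if m - k + 1 < k:
        raise ConfigurationError(
            f"cannot place {k} non-adjacent deviants in {n_slots} slots"
        )
    picks = np.sort(rng.choice(m - k + 1, size=k, replace=False))
    return picks + np.arange(k) + 2


def build_sequence(config: ParadigmConfig, seed: int) -> EventSequence:
    """Generate one trial's event sequence.

    Streams are interleaved cyclically (1..N repeating) on an onset grid of
    the overall SOA.  Within each stream, deviant positions are drawn
    uniformly at random subject to two constraints: no deviant in the
    stream's first two slots, and no two deviants of the same stream in
    adjacent within-stream slots.  Role counts per stream follow the
    configured ratio exactly.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_stimuli_per_trial
    if n == 0:
        return EventSequence(events=[], paradigm=config, seed=seed)

    counts = config.role_counts_per_stream()
    per_stream: dict[int, list[StimulusDef]] = {}
    for stream in config.stream_indices:
        stims = config.stream_stimuli(stream)
        standard, deviants = stims[0], stims[1:]
        n_slots = config.events_per_stream
        dev_counts = counts[1:]
        k = int(sum(dev_counts))
        slots: list[StimulusDef] = [standard] * n_slots
        positions = _sample_nonadjacent(rng, n_slots, k)
        pool = np.repeat(np.arange(len(deviants)), dev_counts)
        rng.shuffle(pool)
        for pos, which in zip(positions, pool):
            slots[pos] = deviants[which]
        per_stream[stream] = slots

    events: list[tuple[float, StimulusDef]] = []
    streams = config.stream_indices
    for i in range(n):
        stream = streams[i % config.n_streams]
        slot = i // config.n_streams
        events.append((i * config.soa, per_stream[stream][slot]))
    return EventSequence(events=events, paradigm=config, seed=seed)


def assign_event_labels(seq: EventSequence, plan: TrialPlan) -> LabeledEvents:
    """Label every event target/nontarget for an attended deviant.

    The attended deviant of the target stream is the target; standards of the
    target stream, any unattended deviant of that stream, and all stimuli of
    the other streams are nontarget.
    """
    cfg = seq.paradigm
    candidates = {
        s.stimulus_id: s for s in cfg.stream_stimuli(plan.target_stream)
    } if plan.target_stream in cfg.stream_indices else {}
    target = candidates.get(plan.target_stimulus_id)
    if target is None:
        raise InvalidPlanError(
            f"stimulus {plan.target_stimulus_id!r} not found in stream "
            f"{plan.target_stream}"
        )
    if not target.is_deviant:
        raise InvalidPlanError(
            f"target stimulus {plan.target_stimulus_id!r} is a standard; "
            "only deviants can be attended"
        )

    labels: list[str] = []
    tags: list[str] = []
    for _, stim in seq.events:
        is_target = (
            stim.stream_index == plan.target_stream
            and stim.stimulus_id == plan.target_stimulus_id
        )
        labels.append("target" if is_target else "nontarget")
        if stim.is_deviant:
            tags.append(f"deviant-class-{stim.stimulus_id}")
        elif stim.stream_index == plan.target_stream:
            tags.append("standard-in-target-stream")
        else:
            tags.append("")
    return LabeledEvents(labels=labels, tags=tags, plan=plan)


def render_audio(
    seq: EventSequence,
    tone_duration: float = 0.1,
    ramp: float = 0.005,
    sample_rate: float = 44100.0,
    amplitude: float = 0.95,
) -> np.ndarray:
    """Render the sequence as a mono waveform of sine bursts.

    Each event contributes a ``tone_duration`` sine burst at its stimulus
    frequency with raised-cosine on/off ramps of length ``ramp``.  Bursts must
    fit inside one SOA slot so that successive tones never overlap.
    """
    if len(seq) == 0:
        return np.zeros(0)
    if tone_duration >= seq.paradigm.soa:
        raise OverlapError(
            f"tone_duration {tone_duration} s >= SOA {seq.paradigm.soa} s: "
            "bursts would overlap"
        )
    fs = float(sample_rate)
    n_total = int(round(seq.duration * fs))
    wave = np.zeros(n_total)
    n_tone = int(round(tone_duration * fs))
    t = np.arange(n_tone) / fs
    env = np.ones(n_tone)
    n_ramp = int(round(ramp * fs))
    if n_ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= r
        env[-n_ramp:] *= r[::-1]
    for onset, stim in seq.events:
        i0 = int(round(onset * fs))
        burst = amplitude * env * np.sin(2 * np.pi * stim.frequency * t)
        wave[i0 : i0 + n_tone] += burst[: max(0, n_total - i0)]
    return wave


def write_wav(path: str | Path, wave: np.ndarray, sample_rate: float = 44100.0) -> None:
    """Write a [-1, 1] waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    pcm = np.clip(wave, -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (pcm * 32767).astype(np.int16))


def child_seed(master_seed: int, *keys: int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and keys."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))


def default_trial_plans(
    config: ParadigmConfig, n_runs: int, seed: int, trials_per_run: int = 4
) -> list[TrialPlan]:
    """Balanced trial plans: each run permutes the selectable deviant classes.

    With four deviants and four trials per run every class is attended once
    per run, mirroring a balanced session layout.
    """
    deviants = config.deviants()
    plans: list[TrialPlan] = []
    for run in range(n_runs):
        rng = np.random.default_rng(child_seed(seed, 7001, run))
        order = rng.permutation(len(deviants))
        for trial in range(trials_per_run):
            dev = deviants[order[trial % len(deviants)]]
            plans.append(
                TrialPlan(
                    target_stream=dev.stream_index,
                    target_stimulus_id=dev.stimulus_id,
                    trial_index=trial,
                    run_index=run,
                )
            )
    return plans
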