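"""Measurement-session protocols for the GPIAS and PPI-threshold paradigms.

A protocol is an ordered, seeded list of trials.  Every session opens with
five startle-only habituation trials (to damp adaptation effects before
data-bearing trials) followed by a pseudo-random permutation of the
balanced condition block: equally many gap and no-gap trials per center
frequency (GPIAS), or equally many tone and no-tone trials overall
(threshold paradigm).  The same seed reproduces the same order, so a
cohort of animals can be run under an identical pseudo-random sequence.

Randomization uses a fixed, named generator (PCG64 with an integer seed)
and a plain Fisher–Yates shuffle, so orders are stable across platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stimulus import TrialSpec

__all__ = [
    "Protocol",
    "ProtocolReport",
    "build_gpias_protocol",
    "build_threshold_protocol",
    "validate_protocol",
    "N_HABITUATION",
]

#: habituation trials opening every session
N_HABITUATION = 5


@dataclass
class Protocol:
    """An ordered, seeded measurement session."""

    trials: list[TrialSpec]
    seed: int
    paradigm: str  # {"gpias", "threshold"}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.paradigm not in ("gpias", "threshold"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def habituation(self) -> list[TrialSpec]:
        return self.trials[:N_HABITUATION]

    @property
    def block(self) -> list[TrialSpec]:
        """Data-bearing trials (habituation excluded from all statistics)."""
        return self.trials[N_HABITUATION:]

    def to_json(self) -> str:
        return json.dumps(
            {
                "paradigm": self.paradigm,
                "seed": self.seed,
                "metadata": self.metadata,
                "trials": [dataclasses.asdict(t) for t in self.trials],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        d = json.loads(text)
        return cls(
            trials=[TrialSpec(**t) for t in d["trials"]],
            seed=d["seed"],
            paradigm=d["paradigm"],
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Protocol":
        return cls.from_json(Path(path).read_text())


def _shuffle(items: list, seed: int) -> list:
    """Fisher–Yates permutation driven by PCG64(seed)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    items = list(items)
    for i in range(len(items) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        items[i], items[j] = items[j], items[i]
    return items


def _assign_noise_seeds(trials: list[TrialSpec], seed: int) -> list[TrialSpec]:
    """Give each trial an independent, reproducible noise seed."""
    children = np.random.SeedSequence(seed).spawn(len(trials))
    return [
        dataclasses.replace(t, noise_seed=int(c.generate_state(1)[0] % (2**31)))
        for t, c in zip(trials, children)
    ]


def build_gpias_protocol(
    center_freqs_hz: list[float],
    half_width_octaves: float = 0.5,
    n_repeats: int = 15,
    seed: int = 0,
    metadata: dict | None = None,
    interleave_frequencies: bool = True,
    **trial_kwargs,
) -> Protocol:
    """GPIAS session: habituation, then a balanced gap/no-gap block.

    Per center frequency, ``n_repeats`` gap and ``n_repeats`` no-gap trials
    are generated and pseudo-randomly permuted.  With
    ``interleave_frequencies`` (default) all frequencies share one
    permutation; otherwise each frequency forms its own shuffled sub-block.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not center_freqs_hz:
        raise ValueError("at least one center frequency required")

    def conditions(freq):
        return [
            TrialSpec(kind=k, center_freq_hz=freq,
                      half_width_octaves=half_width_octaves, **trial_kwargs)
            for k in ("gap", "nogap")
            for _ in range(n_repeats)
        ]

    if interleave_frequencies:
        block = _shuffle([t for f in center_freqs_hz for t in conditions(f)], seed)
    else:
        block = [
            t
            for i, f in enumerate(center_freqs_hz)
            for t in _shuffle(conditions(f), seed + i)
        ]
    trials = [TrialSpec(kind="startle_only", **trial_kwargs)
              for _ in range(N_HABITUATION)] + block
    trials = _assign_noise_seeds(trials, seed)
    return Protocol(trials, seed, "gpias", metadata or {})


def build_threshold_protocol(
    freq_lo_hz: float,
    freq_hi_hz: float,
    octave_step: float = 0.5,
    level_lo_dbspl: float = 2.0,
    level_hi_dbspl: float = 26.0,
    level_step_db: float = 2.0,
    n_repeats: int = 50,
    seed: int = 0,
    metadata: dict | None = None,
    **trial_kwargs,
) -> Protocol:
    """Hearing-threshold session: tone pre-pulses over a frequency x level
    grid, balanced against an equal total of no-tone baseline trials.

    Frequencies step geometrically (``octave_step`` of 1, 1/2 or 1/4
    octaves); levels step arithmetically.  The no-tone trials serve as the
    common baseline pool for every condition of the session.
    """
    if octave_step not in (1.0, 0.5, 0.25):
        raise ValueError("octave_step must be 1, 1/2, or 1/4")
    if level_hi_dbspl < level_lo_dbspl:
        raise ValueError("level_hi_dbspl must be >= level_lo_dbspl")
    if level_step_db <= 0:
        raise ValueError("level_step_db must be > 0")
    if freq_hi_hz < freq_lo_hz:
        raise ValueError("freq_hi_hz must be >= freq_lo_hz")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    n_oct = int(round(np.log2(freq_hi_hz / freq_lo_hz) / octave_step))
    freqs = [freq_lo_hz * 2.0 ** (octave_step * i) for i in range(n_oct + 1)
             if freq_lo_hz * 2.0 ** (octave_step * i) <= freq_hi_hz * (1 + 1e-9)]
    n_lev = int(round((level_hi_dbspl - level_lo_dbspl) / level_step_db))
    levels = [level_lo_dbspl + level_step_db * i for i in range(n_lev + 1)
              if level_lo_dbspl + level_step_db * i <= level_hi_dbspl + 1e-9]

    tone_trials = [
        TrialSpec(kind="tone", tone_freq_hz=f, tone_level_dbspl=lv, **trial_kwargs)
        for f in freqs
        for lv in levels
        for _ in range(n_repeats)
    ]
    notone_trials = [TrialSpec(kind="notone", **trial_kwargs)
                     for _ in range(len(tone_trials))]
    block = _shuffle(tone_trials + notone_trials, seed)
    trials = [TrialSpec(kind="startle_only", **trial_kwargs)
              for _ in range(N_HABITUATION)] + block
    trials = _assign_noise_seeds(trials, seed)
    return Protocol(trials, seed, "threshold", metadata or {})


@dataclass
class ProtocolReport:
    """Counts and invariant checks for a protocol; purely descriptive."""

    n_trials: int
    n_habituation: int
    condition_counts: dict
    habituation_ok: bool
    balanced: bool
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_protocol(p: Protocol) -> ProtocolReport:
    """Check habituation count and condition balance; never mutates."""
    n_hab = 0
    for t in p.trials:
        if t.kind != "startle_only":
            break
        n_hab += 1
    counts: dict = {}
    for t in p.block:
        if t.kind in ("gap", "nogap"):
            key = (t.kind, t.center_freq_hz)
        elif t.kind == "tone":
            key = ("tone", t.tone_freq_hz, t.tone_level_dbspl)
        else:
            key = (t.kind,)
        counts[key] = counts.get(key, 0) + 1

    violations = []
    if n_hab != N_HABITUATION:
        violations.append(
            f"expected {N_HABITUATION} leading startle_only habituation trials, found {n_hab}")
    if p.paradigm == "gpias":
        freqs = {k[1] for k in counts if k[0] in ("gap", "nogap")}
        balanced = all(
            counts.get(("gap", f), 0) == counts.get(("nogap", f), 0) for f in freqs)
        if not balanced:
            violations.append("gap/nogap trial counts differ for some center frequency")
    else:
        n_tone = sum(v for k, v in counts.items() if k[0] == "tone")
        n_notone = counts.get(("notone",), 0)
        balanced = n_tone == n_notone
        if not balanced:
            violations.append(
                f"tone trials ({n_tone}) != notone trials ({n_notone})")
    return ProtocolReport(
        n_trials=len(p.trials),
        n_habituation=n_hab,
        condition_counts=counts,
        habituation_ok=n_hab == N_HABITUATION,
        balanced=balanced,
        violations=violations,
    )
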