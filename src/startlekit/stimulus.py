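"""Acoustic stimulus synthesis for startle-reflex paradigms.

All waveforms are dimensionless digital signals; sound pressure levels are
mapped to digital amplitude through :class:`LevelCalibration`, which states
the dB SPL a unit-RMS signal would produce at the animal's position.  The
standard stimuli of the gap/tone pre-pulse inhibition paradigms are

* band-limited background noise, optionally interrupted by a sin^2-ramped
  gap of silence (the gap pre-stimulus),
* a short pure-tone pre-stimulus, and
* a loud broadband noise burst that elicits the startle reflex.

A trial is rendered as three sample-aligned channels: pre-stimulus,
startle stimulus, and a TTL-style trigger whose rising edge marks startle
onset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "LevelCalibration",
    "TrialSpec",
    "dbspl_to_amplitude",
    "synth_pure_tone",
    "synth_band_noise",
    "insert_gap",
    "synth_startle_burst",
    "assemble_trial",
    "write_wav",
    "read_wav",
]

#: default audio sampling rate, Hz
DEFAULT_RATE = 96_000

_ROLES = ("prestimulus", "startle", "trigger")


class ClippingWarning(UserWarning):
    """Digital waveform exceeds full scale (|sample| > 1)."""


@dataclass
class Waveform:
    """A sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitudes; full scale is +-1.0 for acoustic roles.
        Levels above the calibration reference may legitimately exceed
        full scale digitally (an amplifier absorbs the gain in hardware);
        this is reported via :attr:`clipped`, not rejected.
    rate : float
        Sampling rate in Hz.
    role : str
        One of ``prestimulus``, ``startle``, ``trigger``.
    """

    samples: np.ndarray
    rate: float
    role: str = "prestimulus"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.role == "trigger":
            vals = np.unique(self.samples)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("trigger waveform must be two-valued {0, 1}")
        elif self.clipped:
            warnings.warn(
                "acoustic waveform exceeds full scale (|sample| > 1); "
                "level calibration implies gain beyond digital full scale",
                ClippingWarning,
                stacklevel=3,
            )

    @property
    def clipped(self) -> bool:
        return bool(self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-12)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self.samples) else 0.0

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class LevelCalibration:
    """Maps digital amplitude to sound pressure level.

    ``ref_dbspl`` is the level, in dB SPL, produced by a unit-RMS digital
    signal through the (equalized) playback chain.
    """

    ref_dbspl: float = 100.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ref_dbspl) or self.ref_dbspl <= 0:
            raise ValueError(f"ref_dbspl must be finite and positive, got {self.ref_dbspl}")


def dbspl_to_amplitude(level_dbspl: float, cal: LevelCalibration = LevelCalibration()) -> float:
    """Digital RMS scale factor realizing ``level_dbspl`` under ``cal``.

    A unit-RMS waveform multiplied by the returned factor plays back at the
    requested level: ``10 ** ((level - ref) / 20)``.
    """
    if not np.isfinite(level_dbspl):
        raise ValueError("level must be finite")
    return float(10.0 ** ((level_dbspl - cal.ref_dbspl) / 20.0))


def amplitude_to_dbspl(rms: float, cal: LevelCalibration = LevelCalibration()) -> float:
    """Inverse of :func:`dbspl_to_amplitude` for a measured RMS."""
    if rms <= 0:
        raise ValueError("rms must be positive")
    return float(cal.ref_dbspl + 20.0 * np.log10(rms))


@dataclass
class TrialSpec:
    """Declarative description of one startle trial.

    ``kind`` selects the pre-stimulus paradigm: ``gap``/``nogap`` for
    gap-in-noise trials (background band noise with/without a silent gap),
    ``tone``/``notone`` for pure-tone pre-pulse trials, and
    ``startle_only`` for habituation trials with no pre-stimulus channel.

    Timing convention: ``lead_interval_s`` separates pre-stimulus onset
    (tone onset, or gap end at half amplitude) from startle onset.
    """

    kind: str = "startle_only"
    center_freq_hz: float = 8000.0
    half_width_octaves: float = 0.5
    noise_level_dbspl: float = 60.0
    tone_freq_hz: float = 2000.0
    tone_level_dbspl: float = 60.0
    gap_duration_s: float = 0.050
    gap_ramp_s: float = 0.020
    tone_duration_s: float = 0.040
    tone_ramp_s: float = 0.005
    lead_interval_s: float = 0.100
    startle_duration_s: float = 0.020
    startle_level_dbspl: float = 115.0
    trial_duration_s: float = 1.0
    startle_onset_s: float = 0.7
    noise_seed: int = 0

    _KINDS = ("gap", "nogap", "tone", "notone", "startle_only")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        for name in ("gap_duration_s", "gap_ramp_s", "tone_duration_s",
                     "startle_duration_s", "lead_interval_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gap_ramp_s > self.gap_duration_s and self.kind == "gap":
            raise ValueError("gap_ramp_s must not exceed gap_duration_s")
        if self.kind == "tone" and self.lead_interval_s < self.tone_duration_s:
            raise ValueError("lead_interval_s must be >= tone_duration_s for tone trials")
        if self.startle_onset_s + self.startle_duration_s > self.trial_duration_s:
            raise ValueError("startle stimulus extends past trial end")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrialSpec":
        return cls(**json.loads(text))


def _sin2_ramp(n: int) -> np.ndarray:
    """sin^2 on-ramp from 0 to 1 over n samples (half-amplitude at center)."""
    return np.sin(np.linspace(0.0, np.pi / 2.0, n, endpoint=False)) ** 2


def synth_pure_tone(
    freq_hz: float,
    duration_s: float,
    level_dbspl: float,
    ramp_s: float = 0.005,
    rate: float = DEFAULT_RATE,
    cal: LevelCalibration = LevelCalibration(),
) -> Waveform:
    """Pure-tone pre-stimulus with sin^2 on/off ramps.

    The unramped plateau has RMS equal to ``dbspl_to_amplitude(level)``, so
    the reported level refers to the steady tone, not the ramp-diluted
    average.
    """
    if not 0 < freq_hz < rate / 2:
        raise ValueError(f"tone frequency {freq_hz} Hz outside (0, Nyquist={rate/2} Hz)")
    n = round(duration_s * rate)
    if n == 0:
        return Waveform(np.empty(0), rate, "prestimulus")
    amp = dbspl_to_amplitude(level_dbspl, cal) * np.sqrt(2.0)  # peak from RMS
    t = np.arange(n) / rate
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    n_ramp = min(round(ramp_s * rate), n // 2)
    if n_ramp > 0:
        env = np.ones(n)
        env[:n_ramp] = _sin2_ramp(n_ramp)
        env[n - n_ramp:] = _sin2_ramp(n_ramp)[::-1]
        x *= env
    return Waveform(x, rate, "prestimulus")


def synth_band_noise(
    center_freq_hz: float,
    half_width_octaves: float,
    duration_s: float,
    level_dbspl: float,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    cal: LevelCalibration = LevelCalibration(),
) -> Waveform:
    """Band-limited noise by frequency-domain synthesis.

    Uniform magnitude with independent uniform random phases inside
    ``[f_c * 2**-w, f_c * 2**+w]``, exactly zero outside, scaled to the
    requested RMS level.  Brick-wall band edges make the spectral content
    directly testable.
    """
    f_lo = center_freq_hz * 2.0 ** (-half_width_octaves)
    f_hi = center_freq_hz * 2.0 ** (half_width_octaves)
    if not (0 < f_lo < f_hi < rate / 2):
        raise ValueError(
            f"noise band [{f_lo:.1f}, {f_hi:.1f}] Hz outside (0, Nyquist={rate/2} Hz)")
    n = round(duration_s * rate)
    if n == 0:
        return Waveform(np.empty(0), rate, "prestimulus")
    rng = np.random.Generator(np.random.PCG64(seed))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    spec = np.zeros(len(freqs), dtype=complex)
    phases = rng.uniform(0.0, 2 * np.pi, int(in_band.sum()))
    spec[in_band] = np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    x *= dbspl_to_amplitude(level_dbspl, cal) / rms
    return Waveform(x, rate, "prestimulus")


def insert_gap(
    w: Waveform,
    gap_center_offset_s: float,
    gap_duration_s: float = 0.050,
    ramp_s: float = 0.020,
) -> Waveform:
    """Interrupt a waveform by a sin^2-smoothed gap of silence.

    The gap duration is measured between the half-amplitude points of the
    down and up ramps; the fully silent plateau therefore lasts
    ``gap_duration_s - ramp_s``.
    """
    if gap_duration_s == 0:
        return Waveform(w.samples.copy(), w.rate, w.role)
    if ramp_s > gap_duration_s:
        raise ValueError("ramp_s must not exceed gap_duration_s")
    rate = w.rate
    n_ramp = round(ramp_s * rate)
    n_plateau = round((gap_duration_s - ramp_s) * rate)
    n_notch = 2 * n_ramp + n_plateau
    start = round(gap_center_offset_s * rate) - n_notch // 2
    if start < 0 or start + n_notch > len(w):
        raise ValueError("gap extends past waveform boundary")
    env = np.ones(len(w))
    if n_ramp > 0:
        down = 1.0 - _sin2_ramp(n_ramp)
        env[start:start + n_ramp] = down
        env[start + n_ramp + n_plateau:start + n_notch] = down[::-1]
    env[start + n_ramp:start + n_ramp + n_plateau] = 0.0
    return Waveform(w.samples * env, rate, w.role)


def synth_startle_burst(
    duration_s: float = 0.020,
    level_dbspl: float = 115.0,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    cal: LevelCalibration = LevelCalibration(),
) -> Waveform:
    """Broadband white-noise startle burst at the requested level.

    The canonical startle stimulus is a 20 ms noise burst at 115 dB SPL —
    loud and sudden enough to elicit the whole-body startle reflex.
    """
    n = round(duration_s * rate)
    rng = np.random.Generator(np.random.PCG64(seed))
    x = rng.standard_normal(n)
    if n:
        x *= dbspl_to_amplitude(level_dbspl, cal) / np.sqrt(np.mean(x**2))
    with warnings.catch_warnings():
        # levels above the calibration reference exceed digital full scale
        # by design; the per-trial assembly re-reports clipping
        warnings.simplefilter("ignore", ClippingWarning)
        return Waveform(x, rate, "startle")


#: trigger pulse duration, s (rectangular, amplitude 1)
TRIGGER_DURATION_S = 0.010


def assemble_trial(
    spec: TrialSpec,
    rate: float = DEFAULT_RATE,
    cal: LevelCalibration = LevelCalibration(),
) -> tuple[Waveform, Waveform, Waveform]:
    """Render one trial as (prestimulus, startle, trigger) channels.

    All three channels are sample-aligned and equal length.  The trigger's
    rising edge coincides with startle onset.  Gap trials place the gap so
    its half-amplitude end precedes startle onset by ``lead_interval_s``;
    tone trials place tone onset ``lead_interval_s`` before startle onset.
    """
    n_total = round(spec.trial_duration_s * rate)
    i_startle = round(spec.startle_onset_s * rate)

    pre = np.zeros(n_total)
    if spec.kind in ("gap", "nogap"):
        noise = synth_band_noise(
            spec.center_freq_hz, spec.half_width_octaves, spec.trial_duration_s,
            spec.noise_level_dbspl, rate, spec.noise_seed, cal)
        if spec.kind == "gap":
            # gap center = startle onset - lead - gap_duration/2 (half-amp end
            # of the gap sits lead_interval_s before startle onset)
            center = spec.startle_onset_s - spec.lead_interval_s - spec.gap_duration_s / 2.0
            if center - (spec.gap_duration_s + spec.gap_ramp_s) / 2.0 < 0:
                raise ValueError("gap would start before trial begin")
            noise = insert_gap(noise, center, spec.gap_duration_s, spec.gap_ramp_s)
        pre[:len(noise)] = noise.samples
    elif spec.kind in ("tone", "notone"):
        if spec.kind == "tone":
            tone = synth_pure_tone(
                spec.tone_freq_hz, spec.tone_duration_s, spec.tone_level_dbspl,
                spec.tone_ramp_s, rate, cal)
            i_on = i_startle - round(spec.lead_interval_s * rate)
            if i_on < 0:
                raise ValueError("tone onset before trial begin")
            pre[i_on:i_on + len(tone)] = tone.samples

    burst = synth_startle_burst(
        spec.startle_duration_s, spec.startle_level_dbspl, rate,
        seed=spec.noise_seed + 1, cal=cal)
    startle = np.zeros(n_total)
    startle[i_startle:i_startle + len(burst)] = burst.samples

    trigger = np.zeros(n_total)
    trigger[i_startle:i_startle + round(TRIGGER_DURATION_S * rate)] = 1.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClippingWarning)
        out = (
            Waveform(pre, rate, "prestimulus"),
            Waveform(startle, rate, "startle"),
            Waveform(trigger, rate, "trigger"),
        )
    return out


def write_wav(path: str | Path, channels: Waveform | list[Waveform], *,
              pcm16: bool = False) -> None:
    """Write one or more equal-rate channels to a WAV file.

    Float32 by default; ``pcm16`` rescales to 16-bit integers and rejects
    clipped signals (they cannot be represented).
    """
    if isinstance(channels, Waveform):
        channels = [channels]
    rates = {w.rate for w in channels}
    if len(rates) != 1:
        raise ValueError("all channels must share one sampling rate")
    data = np.stack([w.samples for w in channels], axis=-1)
    if data.shape[-1] == 1:
        data = data[:, 0]
    if pcm16:
        if np.max(np.abs(data)) > 1.0:
            raise ValueError("cannot export clipped signal as 16-bit PCM")
        data = np.round(data * 32767.0).astype(np.int16)
    else:
        data = data.astype(np.float32)
    wavfile.write(str(path), int(rates.pop()), data)


def read_wav(path: str | Path, role: str = "prestimulus") -> list[Waveform]:
    """Read a WAV file as a list of Waveforms (one per channel)."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data / 32767.0
    if data.ndim == 1:
        data = data[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClippingWarning)
        return [Waveform(data[:, i].astype(float), rate, role)
                for i in range(data.shape[1])]
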