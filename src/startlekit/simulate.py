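"""Synthetic animal / platform / room: ground-truth data for every module.

No live animal is in scope, so a statistical stand-in generates the raw
data the rest of the stack consumes:

* **VirtualAnimal** — startle amplitudes are log-normal; a gap
  pre-stimulus multiplies the amplitude by ``1 - gpias_true``, a tone
  pre-stimulus by ``1 - clip(slope * (level - threshold), 0, saturation)``
  (the hard-sigmoid stimulus-response function).  Inhibition is
  multiplicative, matching the ratio-based statistic and the log-normal
  amplitude structure.
* **VirtualPlatform** — the spring-mounted sensor platform is modelled as
  one damped second-order mode per axis: the startle twitch excites a
  decaying sinusoid, superposed with Gaussian sensor noise, plus a TTL
  trigger channel.
* **simulate_lems** — a random smooth, minimum-phase FIR coloration
  standing in for a loudspeaker-enclosure-microphone chain, for
  exercising the equalizer.

Every operation is deterministic given its seed; a session derives
per-trial seeds from the animal's seed, so whole sessions reproduce
bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .equalizer import FIRSystem
from .protocol import Protocol
from .response import DEFAULT_LOWPASS_HZ, DEFAULT_WINDOW_S, AccelRecording, AxisCalibration
from .stimulus import TrialSpec

__all__ = [
    "VirtualAnimal",
    "VirtualPlatform",
    "draw_trial_amplitude",
    "render_accel_trace",
    "simulate_session",
    "simulate_lems",
]

#: startle-response latency after trigger onset, s
RESPONSE_LATENCY_S = 0.020


@dataclass(frozen=True)
class VirtualAnimal:
    """Ground-truth behavioral parameters of a simulated animal.

    ``baseline_mu``/``baseline_sigma`` are the log-normal parameters of
    the uninhibited startle amplitude; ``gpias_true`` the fractional
    inhibition a (perceived) gap produces; ``threshold_dbspl``, ``slope``,
    ``saturation`` the hard-sigmoid PPI parameters for tone pre-stimuli.
    """

    baseline_mu: float = 0.0
    baseline_sigma: float = 0.4
    gpias_true: float = 0.5
    threshold_dbspl: float = 10.0
    slope: float = 0.05
    saturation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sigma <= 0:
            raise ValueError("baseline_sigma must be positive")
        if not 0.0 <= self.gpias_true <= 1.0:
            raise ValueError("gpias_true must be in [0, 1]")
        if self.saturation > 1.0:
            raise ValueError("saturation must be <= 1")


@dataclass(frozen=True)
class VirtualPlatform:
    """Second-order mechanical model of the spring-mounted sensor platform.

    ``resonance_hz`` and ``damping_ratio`` define the platform mode (a
    soft spring suspension resonating well below the 40 Hz analysis
    low-pass); per-axis gains model unequal sensor sensitivity, which the
    axis calibration must undo; ``noise_rms`` is the sensor noise floor in
    the same arbitrary units as the signal.
    """

    resonance_hz: float = 15.0
    damping_ratio: float = 0.25
    gx: float = 1.0
    gy: float = 1.0
    gz: float = 1.0
    noise_rms: float = 0.02
    rate: float = 2000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.damping_ratio < 1.0:
            raise ValueError("damping_ratio must be in (0, 1)")
        if min(self.gx, self.gy, self.gz) <= 0:
            raise ValueError("axis gains must be positive")

    def calibration(self) -> AxisCalibration:
        """Exact inverse-gain calibration, c = 1/g per axis.

        Makes the extracted amplitude equal the drawn ground-truth
        amplitude in absolute units.  The measurement-style calibration
        (:func:`startlekit.response.calibrate_axes`) normalizes cx = 1
        instead; the two differ by a common factor, which the ratio-based
        statistics are invariant to.
        """
        return AxisCalibration(1.0 / self.gx, 1.0 / self.gy, 1.0 / self.gz)


def _true_inhibition(animal: VirtualAnimal, spec: TrialSpec) -> float:
    if spec.kind == "gap":
        return animal.gpias_true
    if spec.kind == "tone":
        return float(np.clip(animal.slope * (spec.tone_level_dbspl - animal.threshold_dbspl),
                             0.0, animal.saturation))
    return 0.0


def draw_trial_amplitude(animal: VirtualAnimal, spec: TrialSpec,
                         trial_index: int = 0) -> float:
    """One startle amplitude: log-normal baseline times (1 - inhibition).

    Deterministic per (animal seed, trial index).
    """
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((animal.seed, trial_index))))
    base = float(np.exp(rng.normal(animal.baseline_mu, animal.baseline_sigma)))
    return base * (1.0 - _true_inhibition(animal, spec))


def _platform_template(platform: VirtualPlatform, n: int, i_resp: int) -> np.ndarray:
    """Unit decaying-sinusoid response starting at i_resp, peak-normalized
    so the extraction pipeline (40 Hz low-pass, 150 ms window, magnitude
    with exact calibration) reads amplitude 1 from a unit draw."""
    t = np.arange(n - i_resp) / platform.rate
    w0 = 2 * np.pi * platform.resonance_hz
    zeta = platform.damping_ratio
    wd = w0 * np.sqrt(1 - zeta**2)
    u = np.zeros(n)
    u[i_resp:] = np.exp(-zeta * w0 * t) * np.sin(wd * t)
    # normalize against the same low-pass the analysis applies
    sos = butter(4, DEFAULT_LOWPASS_HZ, btype="low", fs=platform.rate, output="sos")
    uf = sosfiltfilt(sos, u)
    n_win = int(np.floor(DEFAULT_WINDOW_S * platform.rate)) + 1
    # trigger onset precedes response by the latency; window starts at trigger
    i_trig = i_resp - round(RESPONSE_LATENCY_S * platform.rate)
    peak = np.max(np.sqrt(3.0) * np.abs(uf[i_trig:i_trig + n_win]))
    return u / peak


def render_accel_trace(
    amplitude: float,
    platform: VirtualPlatform,
    trial_length_s: float = 1.0,
    trigger_onset_s: float = 0.7,
    seed: int = 0,
) -> AccelRecording:
    """Render one trial's 3-axis accelerometer + trigger traces.

    The response is a per-axis damped sinusoid starting
    ``RESPONSE_LATENCY_S`` after trigger onset, scaled so that running the
    standard extraction (with the platform's exact axis calibration) on a
    noiseless trace recovers ``amplitude``; Gaussian sensor noise is added
    on top.  The trigger is a 10 ms rectangular pulse.
    """
    if trigger_onset_s + 0.2 > trial_length_s:
        raise ValueError("trial too short: need >= 0.2 s after trigger onset")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    rate = platform.rate
    n = round(trial_length_s * rate)
    i_trig = round(trigger_onset_s * rate)
    i_resp = i_trig + round(RESPONSE_LATENCY_S * rate)
    u = _platform_template(platform, n, i_resp)

    rng = np.random.Generator(np.random.PCG64(seed))
    if platform.noise_rms > 0 and amplitude > 0 and platform.noise_rms >= amplitude:
        warnings.warn("sensor noise floor at or above signal scale", UserWarning)
    axes = []
    for g in (platform.gx, platform.gy, platform.gz):
        noise = rng.normal(0.0, platform.noise_rms, n) if platform.noise_rms > 0 else 0.0
        axes.append(g * amplitude * u + noise)
    trigger = np.zeros(n)
    trigger[i_trig:i_trig + round(0.010 * rate)] = 1.0
    return AccelRecording(axes[0], axes[1], axes[2], trigger, rate)


def simulate_session(
    protocol: Protocol,
    animal: VirtualAnimal,
    platform: VirtualPlatform,
    trial_length_s: float = 1.0,
    trigger_onset_s: float = 0.7,
) -> tuple[list[AccelRecording], pd.DataFrame]:
    """Render every trial of a protocol; return traces + ground truth.

    The ground-truth table carries, per trial, the condition, the drawn
    (true) amplitude and the true inhibition — the quantities downstream
    analysis should recover.
    """
    recs = []
    rows = []
    trial_seeds = np.random.SeedSequence((animal.seed, protocol.seed)).spawn(
        len(protocol.trials))
    for i, spec in enumerate(protocol.trials):
        amp = draw_trial_amplitude(animal, spec, trial_index=i)
        rec = render_accel_trace(
            amp, platform, trial_length_s, trigger_onset_s,
            seed=int(trial_seeds[i].generate_state(1)[0] % (2**31)))
        recs.append(rec)
        rows.append({
            "trial": i,
            "kind": spec.kind,
            "habituation": i < 5,
            "center_freq_hz": spec.center_freq_hz,
            "tone_freq_hz": spec.tone_freq_hz,
            "tone_level_dbspl": spec.tone_level_dbspl,
            "true_amplitude": amp,
            "true_inhibition": _true_inhibition(animal, spec),
        })
    return recs, pd.DataFrame(rows)


def simulate_lems(
    rate: float = 48000.0,
    n_taps: int = 512,
    coloration_db: float = 6.0,
    seed: int = 0,
    band_hz: tuple[float, float] = (2000.0, 20000.0),
) -> FIRSystem:
    """Random smooth minimum-phase FIR coloration over the audio band.

    The log-magnitude is a sum of random Gaussian bumps in log-frequency,
    rescaled so its peak-to-peak deviation across ``band_hz`` equals
    ``+-coloration_db`` (i.e. total swing ``2 * coloration_db``), then
    realized as a minimum-phase impulse response via the cepstrum.
    """
    if coloration_db < 0:
        raise ValueError("coloration_db must be >= 0")
    n_fft = int(2 ** np.ceil(np.log2(8 * n_taps)))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    logmag_db = np.zeros(len(freqs))
    if coloration_db > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        logf = np.log2(np.maximum(freqs, freqs[1] / 2))
        for _ in range(8):
            center = rng.uniform(np.log2(500.0), np.log2(rate / 2))
            width = rng.uniform(0.3, 1.2)  # octaves
            logmag_db += rng.uniform(-1, 1) * np.exp(-0.5 * ((logf - center) / width) ** 2)
        sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
        swing = logmag_db[sel].max() - logmag_db[sel].min()
        logmag_db *= 2.0 * coloration_db / swing
        logmag_db -= logmag_db[sel].mean()
    mag = 10.0 ** (logmag_db / 20.0)
    # minimum-phase realization of the target magnitude
    cep = np.fft.irfft(np.log(mag), n=n_fft)
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1:n_fft // 2] = 2.0 * cep[1:n_fft // 2]
    fold[n_fft // 2] = cep[n_fft // 2]
    h = np.fft.irfft(np.exp(np.fft.rfft(fold)), n=n_fft)[:n_taps]
    return FIRSystem(h, rate)
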