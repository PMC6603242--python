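"""Loudspeaker equalization by adaptive system identification.

The playback chain — loudspeaker, enclosure, microphone (LEMS) — colors
the spectrum of every stimulus.  To flatten it, the chain is identified as
an FIR system with the normalized least-mean-squares (NLMS) adaptive
filter driven by a broadband excitation (white noise or a maximum-length
sequence), the minimum-phase component of the estimate is extracted via
the real cepstrum, and its regularized inverse over the band of interest
(2–20 kHz by default) yields the equalizer filter.  Convolving stimuli
with this filter before playback flattens the cascade's magnitude
response.

A companion utility measures inter-channel latency from simultaneously
played TTL pulses, so trigger, pre-stimulus and startle channels can be
time-aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import max_len_seq, fftconvolve

from .stimulus import Waveform

__all__ = [
    "FIRSystem",
    "EqualizerFilter",
    "NLMSConfig",
    "FlatnessReport",
    "generate_excitation",
    "nlms_identify",
    "minimum_phase",
    "invert_transfer",
    "design_equalizer",
    "apply_equalizer",
    "measure_latency",
]

#: log-magnitude floor used when inverting near-null spectra, dB
SPECTRAL_FLOOR_DB = -100.0


@dataclass
class FIRSystem:
    """A finite impulse response with its sampling rate."""

    coefficients: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size == 0:
            raise ValueError("FIR system must have at least one coefficient")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("FIR coefficients must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.coefficients)

    def freq_response(self, n_fft: int) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies Hz, complex response) on an rfft grid."""
        H = np.fft.rfft(self.coefficients, n=n_fft)
        f = np.fft.rfftfreq(n_fft, d=1.0 / self.rate)
        return f, H


@dataclass
class EqualizerFilter:
    """FIR equalizer flattening a playback chain over a frequency band."""

    coefficients: np.ndarray
    rate: float
    band_hz: tuple[float, float]
    delay_samples: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        f_lo, f_hi = self.band_hz
        if not (0 < f_lo < f_hi < self.rate / 2):
            raise ValueError(f"band {self.band_hz} outside (0, Nyquist)")

    def __len__(self) -> int:
        return len(self.coefficients)

    def save_csv(self, path: str | Path) -> None:
        """One tap per line, plus a JSON sidecar with rate/band metadata."""
        import json

        path = Path(path)
        np.savetxt(path, self.coefficients, fmt="%.18e")
        meta = {"rate": self.rate, "band_hz": list(self.band_hz),
                "delay_samples": self.delay_samples}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load_csv(cls, path: str | Path) -> "EqualizerFilter":
        import json

        path = Path(path)
        taps = np.loadtxt(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(taps, meta["rate"], tuple(meta["band_hz"]),
                   meta.get("delay_samples", 0))


@dataclass(frozen=True)
class NLMSConfig:
    """NLMS hyperparameters.

    ``step_size`` (mu) in (0, 2) controls the per-sample update gain;
    ``regularization`` (delta) guards the normalization against silent
    excitation stretches; ``passes`` repeats the data to refine the
    estimate on short recordings.
    """

    filter_length: int = 2048
    step_size: float = 0.5
    regularization: float = 1e-6
    passes: int = 2

    def __post_init__(self) -> None:
        if self.filter_length < 1:
            raise ValueError("filter_length must be >= 1")
        if not 0.0 <= self.step_size < 2.0:
            raise ValueError("step_size must be in [0, 2)")
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


def generate_excitation(
    kind: str,
    rate: float,
    duration_s: float | None = None,
    mls_order: int | None = None,
    seed: int = 0,
) -> Waveform:
    """Broadband excitation for system identification.

    ``white``: seeded Gaussian noise scaled to RMS 0.5 (headroom below
    full scale).  ``mls``: +-1 maximum-length sequence of length
    ``2**order - 1`` from a primitive linear-feedback shift register; its
    periodic autocorrelation is a near-ideal impulse, which makes the
    excitation spectrally flat.
    """
    from .stimulus import ClippingWarning

    if kind == "white":
        if duration_s is None:
            raise ValueError("white excitation requires duration_s")
        rng = np.random.Generator(np.random.PCG64(seed))
        x = rng.standard_normal(round(duration_s * rate))
        x *= 0.5 / np.sqrt(np.mean(x**2))
        with warnings.catch_warnings():
            # Gaussian tails beyond full scale are expected at RMS 0.5
            warnings.simplefilter("ignore", ClippingWarning)
            return Waveform(x, rate, "prestimulus")
    if kind == "mls":
        if mls_order is None or not 2 <= mls_order <= 20:
            raise ValueError("mls_order must be in [2, 20]")
        bits, _ = max_len_seq(mls_order)
        return Waveform(2.0 * bits - 1.0, rate, "prestimulus")
    raise ValueError(f"unknown excitation kind {kind!r}")


def nlms_identify(
    excitation: Waveform,
    observed: Waveform,
    cfg: NLMSConfig = NLMSConfig(),
) -> tuple[FIRSystem, np.ndarray]:
    """Identify an FIR system from excitation/response with NLMS.

    Per sample: ``e_n = y_n - w^T x_n`` then
    ``w <- w + mu * e_n * x_n / (||x_n||^2 + delta)``, where ``x_n`` is the
    most recent ``filter_length`` excitation samples.  Returns the final
    tap estimate and the squared-error trace of the last pass.
    """
    if excitation.rate != observed.rate:
        raise ValueError("excitation and observation rates differ")
    x = excitation.samples
    y = observed.samples
    L = cfg.filter_length
    n = min(len(x), len(y))
    if n < L:
        raise ValueError(f"signals shorter than filter length ({n} < {L})")
    if not np.any(x):
        raise ValueError("silent excitation cannot identify a system")

    w = np.zeros(L)
    mu, delta = cfg.step_size, cfg.regularization
    err2 = np.empty(n - L + 1)
    # sliding energy of the regressor, updated incrementally
    for p in range(cfg.passes):
        norm2 = float(np.dot(x[:L], x[:L]))
        for i in range(L - 1, n):
            xi = x[i - L + 1:i + 1][::-1]
            e = y[i] - float(np.dot(w, xi))
            w += (mu * e / (norm2 + delta)) * xi
            if p == cfg.passes - 1:
                err2[i - L + 1] = e * e
            if i + 1 < n:
                norm2 += x[i + 1] ** 2 - x[i - L + 1] ** 2
    return FIRSystem(w, excitation.rate), err2


def minimum_phase(h: FIRSystem, n_fft: int | None = None) -> FIRSystem:
    """Minimum-phase counterpart of ``h`` via the real cepstrum.

    The output shares the magnitude spectrum of the input (within
    numerical tolerance of the FFT grid) but has all its zeros inside the
    unit circle, so it admits a stable causal inverse.  Spectral magnitudes
    below the regularization floor are clipped, with a warning.
    """
    if not np.any(h.coefficients):
        raise ValueError("all-zero system has no minimum-phase component")
    if n_fft is None:
        # generous grid: cepstral aliasing falls off with FFT length
        n_fft = int(2 ** np.ceil(np.log2(max(8 * len(h), 4096))))
    if n_fft < 4 * len(h):
        raise ValueError(f"n_fft must be >= 4 * len(h) = {4 * len(h)}")
    H = np.abs(np.fft.rfft(h.coefficients, n=n_fft))
    floor = np.max(H) * 10.0 ** (SPECTRAL_FLOOR_DB / 20.0)
    if np.any(H < floor):
        warnings.warn(
            f"spectral magnitudes below {SPECTRAL_FLOOR_DB} dB floor were "
            "regularized before cepstral inversion", UserWarning)
        H = np.maximum(H, floor)
    # fold the even log-magnitude cepstrum onto the causal side
    cep = np.fft.irfft(np.log(H), n=n_fft)
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1:n_fft // 2] = 2.0 * cep[1:n_fft // 2]
    if n_fft % 2 == 0:
        fold[n_fft // 2] = cep[n_fft // 2]
    h_mp = np.fft.irfft(np.exp(np.fft.rfft(fold)), n=n_fft)[:len(h)]
    return FIRSystem(h_mp, h.rate)


def _raised_cosine_band_mask(freqs: np.ndarray, band_hz: tuple[float, float]) -> np.ndarray:
    """1 inside the band, 0 outside, raised-cosine 1/6-octave transitions."""
    f_lo, f_hi = band_hz
    w = 2.0 ** (1.0 / 6.0)
    mask = np.zeros_like(freqs)
    core = (freqs >= f_lo) & (freqs <= f_hi)
    mask[core] = 1.0
    lo_t = (freqs >= f_lo / w) & (freqs < f_lo)
    with np.errstate(divide="ignore"):
        logf = np.log2(np.maximum(freqs, 1e-12))
    mask[lo_t] = 0.5 * (1 + np.cos(np.pi * (np.log2(f_lo) - logf[lo_t]) * 6.0))
    hi_t = (freqs > f_hi) & (freqs <= f_hi * w)
    mask[hi_t] = 0.5 * (1 + np.cos(np.pi * (logf[hi_t] - np.log2(f_hi)) * 6.0))
    return mask


def invert_transfer(
    h_mp: FIRSystem,
    band_hz: tuple[float, float] = (2000.0, 20000.0),
    n_taps: int = 2048,
    regularization: float = 1e-4,
    n_fft: int | None = None,
) -> EqualizerFilter:
    """Regularized band-limited inverse of a (minimum-phase) system.

    In band, ``G = H* / (|H|^2 + eps)`` with Tikhonov ``eps`` relative to
    the peak of ``|H|^2``; outside the band the equalizer is unity, with
    raised-cosine transitions of 1/6 octave.  Taps are obtained by inverse
    FFT, delayed by ``n_taps // 4`` samples to capture the slight
    non-causal smear regularization introduces, and Tukey-windowed to
    ``n_taps``.
    """
    if n_taps < 8:
        raise ValueError("n_taps must be >= 8")
    f_lo, f_hi = band_hz
    if not (0 < f_lo < f_hi < h_mp.rate / 2):
        raise ValueError(f"band {band_hz} outside (0, Nyquist)")
    if n_fft is None:
        n_fft = int(2 ** np.ceil(np.log2(max(8 * len(h_mp), 8 * n_taps))))
    freqs, H = h_mp.freq_response(n_fft)
    eps = regularization * np.max(np.abs(H)) ** 2
    G_inv = np.conj(H) / (np.abs(H) ** 2 + eps)
    mask = _raised_cosine_band_mask(freqs, band_hz)
    G = mask * G_inv + (1.0 - mask)
    g = np.fft.irfft(G, n=n_fft)
    delay = n_taps // 4
    g = np.roll(g, delay)[:n_taps]
    from scipy.signal.windows import tukey

    g *= tukey(n_taps, alpha=0.1)
    return EqualizerFilter(g, h_mp.rate, band_hz, delay_samples=delay)


@dataclass
class FlatnessReport:
    """In-band flatness of the equalized cascade."""

    max_deviation_db: float
    band_hz: tuple[float, float]
    unequalized_deviation_db: float


def cascade_flatness(
    system: FIRSystem,
    eq: EqualizerFilter,
    n_fft: int = 1 << 15,
) -> FlatnessReport:
    """Max deviation of |G*H| from its in-band median, in dB."""
    casc = fftconvolve(system.coefficients, eq.coefficients)
    C = np.abs(np.fft.rfft(casc, n=n_fft))
    H = np.abs(np.fft.rfft(system.coefficients, n=n_fft))
    f = np.fft.rfftfreq(n_fft, d=1.0 / system.rate)
    sel = (f >= eq.band_hz[0]) & (f <= eq.band_hz[1])

    def dev(mag):
        db = 20 * np.log10(np.maximum(mag[sel], 1e-12))
        return float(np.max(np.abs(db - np.median(db))))

    return FlatnessReport(dev(C), eq.band_hz, dev(H))


def design_equalizer(
    excitation: Waveform,
    recording: Waveform,
    cfg: NLMSConfig = NLMSConfig(),
    band_hz: tuple[float, float] = (2000.0, 20000.0),
    n_taps: int = 2048,
    regularization: float = 1e-4,
) -> tuple[EqualizerFilter, FlatnessReport]:
    """Full calibration chain: identify, minimum-phase, invert.

    Returns the equalizer and a flatness report of the equalized cascade
    against the identified system.
    """
    h_hat, _ = nlms_identify(excitation, recording, cfg)
    h_mp = minimum_phase(h_hat)
    eq = invert_transfer(h_mp, band_hz, n_taps, regularization)
    return eq, cascade_flatness(h_hat, eq)


def apply_equalizer(w: Waveform, eq: EqualizerFilter, *, full: bool = False) -> Waveform:
    """Convolve a waveform with the equalizer before playback.

    By default the output is same-length with the equalizer's design delay
    compensated; ``full`` returns the complete linear convolution of
    length ``len(w) + len(eq) - 1``.
    """
    if w.rate != eq.rate:
        raise ValueError(f"rate mismatch: waveform {w.rate} Hz vs equalizer {eq.rate} Hz")
    y = fftconvolve(w.samples, eq.coefficients)
    if not full:
        y = y[eq.delay_samples:eq.delay_samples + len(w)]
    if y.size and np.max(np.abs(y)) > 1.0:
        warnings.warn("equalized signal exceeds full scale", UserWarning)
    from .stimulus import ClippingWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClippingWarning)
        return Waveform(y, w.rate, w.role)


def measure_latency(
    recorded_pulses: list[Waveform],
    threshold_frac: float = 0.5,
) -> np.ndarray:
    """Per-channel latencies from simultaneously played TTL pulses.

    Each trace must contain exactly one rising edge; the edge is the first
    crossing of ``threshold_frac`` of the trace maximum.  Offsets are in
    samples, relative to the first channel.
    """
    edges = []
    for i, w in enumerate(recorded_pulses):
        x = w.samples
        if not np.any(x > 0):
            raise ValueError(f"channel {i}: no pulse found")
        thr = threshold_frac * np.max(x)
        above = x >= thr
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        if above[0]:
            crossings = np.concatenate(([0], crossings))
        if len(crossings) != 1:
            raise ValueError(
                f"channel {i}: expected exactly one rising edge, found {len(crossings)}")
        edges.append(int(crossings[0]))
    return np.asarray(edges) - edges[0]
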