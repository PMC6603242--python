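"""Startle-amplitude extraction from 3-axis acceleration recordings.

The animal sits on a spring-mounted platform carrying a 3-axis
accelerometer; its whole-body startle twitch shows up as a transient on
all three axes.  The startle (ASR) amplitude is

    A = max_{0 <= t <= 150 ms} a(t),
    a(t) = sqrt((cx*ax)^2 + (cy*ay)^2 + (cz*az)^2),

with t = 0 at startle onset (the trigger's rising edge) and per-axis
calibration factors c so that the same force produces the same reading on
every axis.  Each axis is low-pass filtered (40 Hz, zero phase) before
the vector magnitude is formed: the platform's mechanical response lives
well below 40 Hz and the filter strips sensor noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "AccelRecording",
    "AxisCalibration",
    "ASRAmplitude",
    "align_to_trigger",
    "magnitude_trace",
    "asr_amplitude",
    "calibrate_axes",
    "extract_asr",
]

#: response search window after startle onset, s
DEFAULT_WINDOW_S = 0.150
#: per-axis low-pass cutoff, Hz
DEFAULT_LOWPASS_HZ = 40.0


@dataclass
class AccelRecording:
    """One trial's 3-axis acceleration plus trigger trace.

    ``onset_index`` marks the sample of t = 0 (startle onset); it is 0 for
    raw recordings and set by :func:`align_to_trigger`.  Pre-trigger
    samples are retained with negative times.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    trigger: np.ndarray
    rate: float
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.trigger = np.asarray(self.trigger, dtype=float)
        lengths = {len(self.ax), len(self.ay), len(self.az), len(self.trigger)}
        if len(lengths) != 1:
            raise ValueError("all four traces must have equal length")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def times(self) -> np.ndarray:
        """Times in seconds; 0 at ``onset_index``."""
        return (np.arange(len(self)) - self.onset_index) / self.rate

    def to_csv(self, path: str | Path) -> None:
        """4-column CSV plus JSON sidecar carrying rate and onset."""
        path = Path(path)
        pd.DataFrame(
            {"ax": self.ax, "ay": self.ay, "az": self.az, "trigger": self.trigger}
        ).to_csv(path, index=False, float_format="%.12g")
        path.with_suffix(".json").write_text(
            json.dumps({"rate": self.rate, "onset_index": self.onset_index}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AccelRecording":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(df["ax"].to_numpy(), df["ay"].to_numpy(), df["az"].to_numpy(),
                   df["trigger"].to_numpy(), meta["rate"], meta.get("onset_index", 0))


@dataclass(frozen=True)
class AxisCalibration:
    """Per-axis gain correction: same force -> same calibrated reading."""

    cx: float = 1.0
    cy: float = 1.0
    cz: float = 1.0

    def __post_init__(self) -> None:
        if not (self.cx > 0 and self.cy > 0 and self.cz > 0):
            raise ValueError("calibration factors must be positive")

    def to_json(self) -> str:
        return json.dumps({"cx": self.cx, "cy": self.cy, "cz": self.cz})

    @classmethod
    def from_json(cls, text: str) -> "AxisCalibration":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ASRAmplitude:
    """Peak calibrated acceleration magnitude within the response window."""

    value: float
    peak_time_s: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("amplitude must be nonnegative")


def _rising_edges(trigger: np.ndarray, threshold_frac: float) -> np.ndarray:
    thr = threshold_frac * np.max(trigger)
    above = trigger >= thr
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        edges = np.concatenate(([0], edges))
    return edges


def align_to_trigger(rec: AccelRecording, threshold_frac: float = 0.5) -> AccelRecording:
    """Set t = 0 at the trigger's rising edge.

    Requires exactly one rising edge (first crossing of
    ``threshold_frac * max(trigger)``); anything else indicates a corrupt
    trigger channel and is rejected with a diagnostic.
    """
    if not np.any(rec.trigger > 0):
        raise ValueError("trigger channel contains no pulse")
    edges = _rising_edges(rec.trigger, threshold_frac)
    if len(edges) != 1:
        raise ValueError(
            f"expected exactly one trigger rising edge, found {len(edges)} "
            f"at samples {edges.tolist()[:5]}")
    return replace(rec, onset_index=int(edges[0]))


def magnitude_trace(
    rec: AccelRecording,
    cal: AxisCalibration = AxisCalibration(),
    lowpass_hz: float | None = DEFAULT_LOWPASS_HZ,
) -> np.ndarray:
    """Calibrated acceleration magnitude a(t) over the full recording.

    Each axis is filtered with a 4th-order zero-phase Butterworth low-pass
    (forward-backward) before the Euclidean combination; pass
    ``lowpass_hz=None`` to skip filtering.
    """
    axes = [cal.cx * rec.ax, cal.cy * rec.ay, cal.cz * rec.az]
    if lowpass_hz is not None:
        if lowpass_hz >= rec.rate / 2:
            raise ValueError(
                f"cutoff {lowpass_hz} Hz must be below Nyquist ({rec.rate / 2} Hz)")
        sos = butter(4, lowpass_hz, btype="low", fs=rec.rate, output="sos")
        axes = [sosfiltfilt(sos, a) for a in axes]
    return np.sqrt(np.sum(np.square(axes), axis=0))


def asr_amplitude(
    a_t: np.ndarray,
    rate: float,
    window_s: float = DEFAULT_WINDOW_S,
) -> ASRAmplitude:
    """Peak of a(t) in the closed window [0, window_s] after onset.

    ``a_t`` must start at t = 0.  The window endpoint is inclusive; ties
    resolve to the earliest sample.
    """
    a_t = np.asarray(a_t, dtype=float)
    n_win = int(np.floor(window_s * rate)) + 1
    if len(a_t) < n_win:
        raise ValueError(
            f"trace ({len(a_t)} samples) does not cover the "
            f"{window_s * 1e3:.0f} ms window ({n_win} samples)")
    seg = a_t[:n_win]
    idx = int(np.argmax(seg))  # argmax returns the first maximum
    return ASRAmplitude(value=float(seg[idx]), peak_time_s=idx / rate)


def extract_asr(
    rec: AccelRecording,
    cal: AxisCalibration = AxisCalibration(),
    lowpass_hz: float | None = DEFAULT_LOWPASS_HZ,
    window_s: float = DEFAULT_WINDOW_S,
    threshold_frac: float = 0.5,
) -> ASRAmplitude:
    """Full pipeline: align to trigger, filter, magnitude, windowed peak."""
    aligned = align_to_trigger(rec, threshold_frac)
    a_t = magnitude_trace(aligned, cal, lowpass_hz)
    return asr_amplitude(a_t[aligned.onset_index:], rec.rate, window_s)


def calibrate_axes(
    rec_x: AccelRecording,
    rec_y: AccelRecording,
    rec_z: AccelRecording,
    window_s: float = DEFAULT_WINDOW_S,
    lowpass_hz: float | None = DEFAULT_LOWPASS_HZ,
) -> AxisCalibration:
    """Derive per-axis gains from three equal-force reference recordings.

    Each recording must be dominated by one axis (x, y, z respectively).
    Factors are inversely proportional to the measured peak response and
    normalized so cx = 1.
    """
    peaks = []
    for rec, axis in ((rec_x, "ax"), (rec_y, "ay"), (rec_z, "az")):
        aligned = align_to_trigger(rec)
        a = np.abs(np.asarray(getattr(aligned, axis), dtype=float))
        if lowpass_hz is not None:
            sos = butter(4, lowpass_hz, btype="low", fs=rec.rate, output="sos")
            a = np.abs(sosfiltfilt(sos, np.asarray(getattr(aligned, axis), dtype=float)))
        n_win = int(np.floor(window_s * rec.rate)) + 1
        peak = float(np.max(a[aligned.onset_index:aligned.onset_index + n_win]))
        if peak <= 0:
            raise ValueError(f"zero response on axis {axis[1]}; cannot calibrate")
        peaks.append(peak)
    return AxisCalibration(1.0, peaks[0] / peaks[1], peaks[0] / peaks[2])
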