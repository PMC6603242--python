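"""Organized on-disk storage of sessions, trials and results.

Layout mirrors the session metadata:
``<root>/<experimenter>/<animal>/<treatment>/<session>/trial_<idx>.csv``
with JSON sidecars for rates and a ``session.json`` record.  Everything
is plain CSV/JSON — portable, diff-able and re-readable by any tool.
Raw trial files are write-once: saving over an existing trial requires an
explicit overwrite flag, and no operation mutates a raw file after
creation.
"""

from __future__ import annotations

import datetime
import json
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .protocol import Protocol
from .response import AccelRecording

__all__ = ["SessionRecord", "save_trial", "export_ascii", "load_trial",
           "DEFAULT_CONFIG", "validate_config", "load_config"]

#: columns of the ASCII export, in order
EXPORT_COLUMNS = [
    "trial", "experimenter", "animal", "treatment", "session",
    "kind", "frequency_hz", "level_dbspl", "amplitude", "status",
]


def _slug(text: str) -> str:
    s = re.sub(r"[^A-Za-z0-9._-]+", "_", text.strip())
    return s or "none"


@dataclass
class SessionRecord:
    """One measurement session: metadata, protocol, per-trial files."""

    root: Path
    experimenter: str
    animal: str
    protocol: Protocol
    treatment: str = "none"
    session: str | None = None
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc)
        .isoformat(timespec="seconds"))
    trial_files: dict = field(default_factory=dict)  # index -> relative path
    amplitudes: dict = field(default_factory=dict)   # index -> extracted A
    status_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        if self.session is None:
            self.session = f"session_{self.timestamp.replace(':', '-')}"

    @property
    def directory(self) -> Path:
        return (self.root / _slug(self.experimenter) / _slug(self.animal)
                / _slug(self.treatment) / _slug(self.session))

    def log(self, message: str) -> None:
        now = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
        self.status_log.append(f"{now} {message}")

    def save(self) -> Path:
        """Write the session record (and protocol) to its directory."""
        d = self.directory
        d.mkdir(parents=True, exist_ok=True)
        (d / "protocol.json").write_text(self.protocol.to_json())
        record = {
            "experimenter": self.experimenter,
            "animal": self.animal,
            "treatment": self.treatment,
            "session": self.session,
            "timestamp": self.timestamp,
            "trial_files": {str(k): v for k, v in self.trial_files.items()},
            "amplitudes": {str(k): v for k, v in self.amplitudes.items()},
            "status_log": self.status_log,
        }
        _atomic_write(d / "session.json", json.dumps(record, indent=2))
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "SessionRecord":
        d = Path(directory)
        rec = json.loads((d / "session.json").read_text())
        protocol = Protocol.load(d / "protocol.json")
        obj = cls(
            root=d.parents[3],
            experimenter=rec["experimenter"],
            animal=rec["animal"],
            protocol=protocol,
            treatment=rec["treatment"],
            session=rec["session"],
            timestamp=rec["timestamp"],
            trial_files={int(k): v for k, v in rec["trial_files"].items()},
            amplitudes={int(k): float(v) for k, v in rec["amplitudes"].items()},
            status_log=rec["status_log"],
        )
        return obj


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as f:
            f.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_trial(session: SessionRecord, trial_index: int, rec: AccelRecording,
               overwrite: bool = False) -> Path:
    """Persist one trial's raw traces; refuses silent overwrites."""
    if not 0 <= trial_index < len(session.protocol.trials):
        raise IndexError(
            f"trial index {trial_index} outside protocol "
            f"(0..{len(session.protocol.trials) - 1})")
    d = session.directory
    d.mkdir(parents=True, exist_ok=True)
    path = d / f"trial_{trial_index:04d}.csv"
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    rec.to_csv(path)
    session.trial_files[trial_index] = path.name
    session.log(f"saved trial {trial_index} -> {path.name}")
    session.save()
    return path


def load_trial(session: SessionRecord, trial_index: int) -> AccelRecording:
    if trial_index not in session.trial_files:
        raise KeyError(f"trial {trial_index} has no saved file")
    return AccelRecording.from_csv(session.directory / session.trial_files[trial_index])


def export_ascii(session: SessionRecord, out_path: str | Path,
                 delimiter: str = "\t") -> Path:
    """Tab-separated plain-text export, one row per protocol trial.

    Decimal points are always ``.`` regardless of locale.  Trials without
    an extracted amplitude are flagged ``missing`` rather than dropped.
    """
    if not session.protocol.trials:
        raise ValueError("session has no trials to export")
    rows = []
    for i, spec in enumerate(session.protocol.trials):
        amp = session.amplitudes.get(i)
        if spec.kind in ("gap", "nogap"):
            freq, level = spec.center_freq_hz, spec.noise_level_dbspl
        elif spec.kind in ("tone", "notone"):
            freq, level = spec.tone_freq_hz, spec.tone_level_dbspl
        else:
            freq, level = "", ""
        rows.append({
            "trial": i,
            "experimenter": session.experimenter,
            "animal": session.animal,
            "treatment": session.treatment,
            "session": session.session,
            "kind": spec.kind,
            "frequency_hz": freq,
            "level_dbspl": level,
            "amplitude": "" if amp is None else repr(round(float(amp), 12)),
            "status": "ok" if amp is not None else "missing",
        })
    df = pd.DataFrame(rows, columns=EXPORT_COLUMNS)
    out_path = Path(out_path)
    df.to_csv(out_path, sep=delimiter, index=False)
    return out_path


# ---------------------------------------------------------------------------
# configuration

#: every stimulus/analysis constant with its default; the schema below is
#: the published contract for config files
DEFAULT_CONFIG = {
    "rate_hz": 96000,
    "startle_level_dbspl": 115.0,
    "startle_duration_s": 0.020,
    "gap_duration_s": 0.050,
    "gap_ramp_s": 0.020,
    "tone_duration_s": 0.040,
    "lead_interval_s": 0.100,
    "asr_window_s": 0.150,
    "lowpass_hz": 40.0,
    "equalizer_band_hz": [2000.0, 20000.0],
    "n_bootstrap": 100000,
    "ref_dbspl": 100.0,
}

_CONFIG_SCHEMA = {
    "rate_hz": (int, float),
    "startle_level_dbspl": (int, float),
    "startle_duration_s": (int, float),
    "gap_duration_s": (int, float),
    "gap_ramp_s": (int, float),
    "tone_duration_s": (int, float),
    "lead_interval_s": (int, float),
    "asr_window_s": (int, float),
    "lowpass_hz": (int, float),
    "equalizer_band_hz": list,
    "n_bootstrap": int,
    "ref_dbspl": (int, float),
}


def validate_config(cfg: dict) -> dict:
    """Merge a partial config over the defaults and type-check it."""
    unknown = set(cfg) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **cfg}
    for key, typ in _CONFIG_SCHEMA.items():
        if not isinstance(merged[key], typ):
            raise ValueError(f"config key {key!r} must be {typ}, got {merged[key]!r}")
    band = merged["equalizer_band_hz"]
    if len(band) != 2 or not 0 < band[0] < band[1]:
        raise ValueError("equalizer_band_hz must be [f_lo, f_hi] with 0 < f_lo < f_hi")
    for key in ("gap_duration_s", "gap_ramp_s", "tone_duration_s",
                "lead_interval_s", "asr_window_s"):
        if merged[key] < 0:
            raise ValueError(f"config key {key!r} must be >= 0")
    if merged["gap_ramp_s"] > merged["gap_duration_s"]:
        raise ValueError("gap_ramp_s must not exceed gap_duration_s")
    return merged


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file and validate it."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return validate_config(cfg)
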