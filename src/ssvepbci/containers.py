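"""In-memory containers for multichannel EEG and labeled trial epochs.

The native on-disk format is a plain ``.npy`` array (channels x samples,
microvolts) plus a JSON sidecar holding the sampling rate, channel labels
and trial markers.  Label tables travel separately as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical condition / phase string constants
ATTEND_GABOR = "attend-gabor"
ATTEND_FACE = "attend-face"
FEEDBACK = "feedback"
BASELINE1 = "baseline1"
BASELINE2 = "baseline2"

#: instructed-attention condition implied by each protocol phase
PHASE_CONDITION = {BASELINE1: ATTEND_GABOR, BASELINE2: ATTEND_FACE, FEEDBACK: FEEDBACK}

#: 16 recorded scalp sites plus the occipital triplet used for feature
#: extraction.  The acquisition montage and the feature montage disagree in
#: the source protocol description; the package carries the 19-site union.
MONTAGE_16 = (
    "P1", "PZ", "P2", "CP1", "CPZ", "CP2", "CZ", "C3", "C4",
    "T7", "T8", "FC3", "FC4", "F3", "F4", "FZ",
)
OCCIPITAL = ("O1", "O2", "OZ")
MONTAGE_19 = MONTAGE_16 + OCCIPITAL


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class EEGRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One unique label per row of ``samples``.
    markers : list of (int, int)
        ``(onset_sample, trial_index)`` pairs, strictly increasing in onset.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        onsets = [int(m[0]) for m in self.markers]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("marker onsets must be strictly increasing")
        self.markers = [(int(o), int(t)) for o, t in self.markers]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Total length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    # ---- native container I/O -------------------------------------------

    def save(self, basepath: str | Path) -> None:
        """Write ``<basepath>.npy`` + ``<basepath>.json``."""
        basepath = Path(basepath)
        np.save(basepath.with_suffix(".npy"), self.samples)
        meta = {
            "fs": self.fs,
            "channel_labels": list(self.channel_labels),
            "markers": [[o, t] for o, t in self.markers],
        }
        basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, basepath: str | Path) -> "EEGRecording":
        basepath = Path(basepath)
        samples = np.load(basepath.with_suffix(".npy"))
        meta = json.loads(basepath.with_suffix(".json").read_text())
        return cls(
            samples=samples,
            fs=meta["fs"],
            channel_labels=meta["channel_labels"],
            markers=[tuple(m) for m in meta["markers"]],
        )


def read_edf(path: str | Path) -> EEGRecording:
    """Import an EDF file as an :class:`EEGRecording` (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


@dataclass
class TrialEpoch:
    """One fixed-length labeled trial segment.

    ``condition`` is the instructed attention target; during the feedback
    phase it is recorded as ``"feedback"`` (participants are instructed to
    attend the Gabor throughout that phase).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    condition: str | None = None
    phase: str | None = None
    face_id: str | None = None
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("epoch samples must be 2-D (channels x time)")
        if self.phase in (BASELINE1, BASELINE2) and self.condition is not None:
            if self.condition != PHASE_CONDITION[self.phase]:
                raise ValueError(
                    f"condition {self.condition!r} inconsistent with phase {self.phase!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch") from None


def write_label_table(labels: pd.DataFrame, path: str | Path) -> None:
    """Write the trial label table (trial_index, phase, condition, face_id, onset_sample)."""
    labels.to_csv(path, index=False)


def read_label_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
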