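"""Band-pass filtering and epoching.

The recording chain band-limits all EEG to [1, 40] Hz with a linear-phase
Kaiser-window FIR filter before any feature is computed.  Filtering here is
applied forward-backward (zero phase) so the phase of the frequency tags is
not distorted; the magnitude response is therefore applied twice, which only
deepens the stopband.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import PHASE_CONDITION, EEGRecording, TrialEpoch


@dataclass(frozen=True)
class FilterSpec:
    """A designed FIR band-pass filter and the parameters that produced it."""

    taps: np.ndarray
    fs: float
    low: float
    high: float
    design: dict = field(default_factory=dict)

    @property
    def order(self) -> int:
        return len(self.taps) - 1


# Design margins: the pass/stop edges are placed half a transition width
# inside/outside the nominal band so that attenuation targets hold at the
# stated frequencies (>=40 dB at <=0.5 Hz and >=45 Hz, <=1 dB ripple in
# [2, 38] Hz).
_TRANSITION_HZ = 1.0
_STOP_ATTEN_DB = 50.0


def design_bandpass(fs: float, low: float = 1.0, high: float = 40.0) -> FilterSpec:
    """Design the Kaiser-window FIR band-pass filter.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    low, high : float
        Band edges in Hz; must satisfy ``0 < low < high < fs / 2``.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band [{low}, {high}] Hz outside (0, Nyquist={fs / 2}) for fs={fs}")
    numtaps, beta = signal.kaiserord(_STOP_ATTEN_DB, _TRANSITION_HZ / (fs / 2))
    numtaps |= 1  # type-I (odd length) so the band-pass has no forced nulls
    taps = signal.firwin(
        numtaps, [low, high], window=("kaiser", beta), pass_zero=False, fs=fs
    )
    return FilterSpec(
        taps=taps,
        fs=fs,
        low=low,
        high=high,
        design={
            "window": "kaiser",
            "beta": round(beta, 4),
            "numtaps": numtaps,
            "transition_hz": _TRANSITION_HZ,
            "stopband_atten_db": _STOP_ATTEN_DB,
            "applied": "zero-phase (forward-backward)",
        },
    )


def apply_filter(rec: EEGRecording, spec: FilterSpec) -> EEGRecording:
    """Zero-phase filter every channel of a recording.

    The recording must be longer than three filter orders so the
    forward-backward edge padding is well defined.
    """
    if spec.fs != rec.fs:
        raise ValueError(f"filter designed for fs={spec.fs}, recording has fs={rec.fs}")
    min_len = 3 * spec.order
    if rec.n_samples <= min_len:
        raise ValueError(
            f"recording of {rec.n_samples} samples too short for filter order "
            f"{spec.order} (needs > {min_len})"
        )
    filtered = signal.filtfilt(spec.taps, [1.0], rec.samples, axis=1)
    return EEGRecording(
        samples=filtered,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        markers=list(rec.markers),
    )


def epoch(
    rec: EEGRecording,
    duration: float = 5.0,
    labels: pd.DataFrame | None = None,
) -> list[TrialEpoch]:
    """Cut one fixed-length epoch per marker.

    Each epoch starts exactly at the marker sample and spans
    ``N = round(fs * duration)`` samples (no baseline correction).  An
    optional label table (columns ``trial_index``, ``phase``, ``condition``,
    ``face_id``) annotates the epochs.
    """
    if duration <= 0:
        raise ValueError("epoch duration must be positive")
    n = int(round(rec.fs * duration))
    meta: dict[int, dict] = {}
    if labels is not None:
        meta = {int(r.trial_index): r._asdict() for r in labels.itertuples(index=False)}
    epochs = []
    for onset, trial_index in rec.markers:
        if onset + n > rec.n_samples:
            raise ValueError(
                f"trial {trial_index}: epoch [{onset}, {onset + n}) overruns "
                f"recording of {rec.n_samples} samples"
            )
        row = meta.get(trial_index, {})
        phase = row.get("phase")
        condition = row.get("condition", PHASE_CONDITION.get(phase))
        epochs.append(
            TrialEpoch(
                samples=rec.samples[:, onset : onset + n].copy(),
                fs=rec.fs,
                channel_labels=list(rec.channel_labels),
                condition=condition,
                phase=phase,
                face_id=row.get("face_id"),
                trial_index=int(trial_index),
            )
        )
    return epochs
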