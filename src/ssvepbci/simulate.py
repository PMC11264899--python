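"""Synthetic frequency-tagged EEG.

Emulates the stimulus regime of the attention-training task: every 5-s trial
contains two amplitude-tagged stimuli, an affective face flickering at
8.57 Hz and a Gabor patch at 12 Hz.  Each tag contributes a sinusoid at its
fundamental plus harmonics (amplitude rolloff per order), weighted by where
the simulated participant's attention is allocated, projected onto the scalp
with an occipitally dominant gain profile, and embedded in 1/f^beta pink
noise with a white Gaussian floor.

The tag phase is drawn uniformly per trial so that phase-sensitive features
(the cosine-template correlation) are exercised honestly rather than handed
a fixed phase reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ATTEND_FACE,
    ATTEND_GABOR,
    FEEDBACK,
    MONTAGE_16,
    MONTAGE_19,
    OCCIPITAL,
    EEGRecording,
    InvalidConfigError,
    TrialEpoch,
)
from .protocol import SessionSchedule


def default_channel_gains() -> dict[str, float]:
    """Occipital sites carry the tag at full gain; the rest at 0.2.

    The steady-state response is generated in primary visual cortex, so the
    occipital triplet O1/O2/Oz dominates; the 16 centro-parietal/frontal
    recording sites see only attenuated tag content.
    """
    gains = {ch: 0.2 for ch in MONTAGE_16}
    gains.update({ch: 1.0 for ch in OCCIPITAL})
    return gains


@dataclass
class SimConfig:
    """Parameters of the synthetic session.

    Attributes
    ----------
    f_face, f_gabor : float
        Tag frequencies in Hz (8.57 and 12 by default).
    fs : float
        Sampling rate, Hz.
    trial_duration : float
        Trial length in seconds; ``fs * trial_duration`` must be integral.
    n_harmonics_sim : int
        Harmonics generated per tag (fundamental = order 1).
    harmonic_rolloff : float
        Amplitude ratio between consecutive harmonic orders.
    attention_weights : (float, float)
        ``(attended, unattended)`` tag amplitude multipliers; the condition
        decides which tag receives which weight.
    snr : float or None
        Attended-tag fundamental amplitude (at unit channel gain) divided by
        the noise standard deviation.  ``None`` disables noise entirely.
    noise_exponent : float
        Spectral slope beta of the 1/f^beta pink component.
    white_fraction : float
        Fraction of noise variance contributed by the white floor.
    channel_gains : dict str -> float
        Per-channel tag gain; keys define the montage and channel order.
    """

    f_face: float = 8.57
    f_gabor: float = 12.0
    fs: float = 256.0
    trial_duration: float = 5.0
    n_harmonics_sim: int = 3
    harmonic_rolloff: float = 0.5
    attention_weights: tuple[float, float] = (1.0, 0.3)
    snr: float | None = 1.0
    noise_exponent: float = 1.0
    white_fraction: float = 0.2
    channel_gains: dict[str, float] = field(default_factory=default_channel_gains)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.trial_duration <= 0:
            raise InvalidConfigError("fs and trial_duration must be positive")
        if abs(self.fs * self.trial_duration - round(self.fs * self.trial_duration)) > 1e-9:
            raise InvalidConfigError("trial_duration * fs must be an integer sample count")
        if min(self.attention_weights) < 0:
            raise InvalidConfigError("attention weights must be non-negative")
        if self.fs <= 2 * self.n_harmonics_sim * max(self.f_face, self.f_gabor):
            raise InvalidConfigError(
                "fs must exceed twice the highest generated harmonic frequency"
            )
        if self.snr is not None and self.snr <= 0:
            raise InvalidConfigError("snr must be positive (or None for noiseless)")
        if not self.channel_gains:
            raise InvalidConfigError("channel_gains must name at least one channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))

    @property
    def channel_labels(self) -> list[str]:
        return list(self.channel_gains)

    def tag_weights(self, condition: str) -> dict[float, float]:
        """Map tag frequency -> amplitude weight under a condition.

        Feedback-phase trials are generated with attend-Gabor weights (the
        participant is instructed to attend the Gabor throughout).
        """
        attended, unattended = self.attention_weights
        if condition in (ATTEND_GABOR, FEEDBACK):
            return {self.f_gabor: attended, self.f_face: unattended}
        if condition == ATTEND_FACE:
            return {self.f_gabor: unattended, self.f_face: attended}
        raise ValueError(f"unknown condition {condition!r}")


def _pink_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _tag_signal(config: SimConfig, condition: str, phases: dict[float, float]) -> np.ndarray:
    """Sum of weighted tag harmonics at unit channel gain."""
    t = np.arange(config.n_samples) / config.fs
    sig = np.zeros(config.n_samples)
    for f, w in config.tag_weights(condition).items():
        if w == 0:
            continue
        for order in range(1, config.n_harmonics_sim + 1):
            amp = w * config.harmonic_rolloff ** (order - 1)
            sig += amp * np.sin(2 * np.pi * order * f * t + phases[f])
    return sig


def simulate_epoch(
    config: SimConfig,
    condition: str,
    seed: int | np.random.SeedSequence,
    trial_index: int = 0,
    phase: str | None = None,
    face_id: str | None = None,
) -> TrialEpoch:
    """Generate one labeled trial epoch; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    tag_phases = {
        f: rng.uniform(0, 2 * np.pi) for f in (config.f_face, config.f_gabor)
    }
    base = _tag_signal(config, condition, tag_phases)

    gains = np.array(list(config.channel_gains.values()))
    samples = gains[:, None] * base[None, :]

    if config.snr is not None:
        sigma = 1.0 / config.snr
        wf = config.white_fraction
        for ch in range(samples.shape[0]):
            pink = _pink_noise(rng, config.n_samples, config.noise_exponent)
            white = rng.standard_normal(config.n_samples)
            samples[ch] += sigma * (np.sqrt(1 - wf) * pink + np.sqrt(wf) * white)

    return TrialEpoch(
        samples=samples,
        fs=config.fs,
        channel_labels=config.channel_labels,
        condition=condition,
        phase=phase,
        face_id=face_id,
        trial_index=trial_index,
    )


def simulate_session(
    config: SimConfig,
    schedule: SessionSchedule,
    seed: int,
) -> tuple[EEGRecording, pd.DataFrame]:
    """Generate one continuous recording following a session schedule.

    Trials are laid back to back; each trial's marker is placed at its
    onset sample.  Returns the recording and a label table with columns
    ``trial_index, phase, condition, face_id, onset_sample``.
    """
    n = config.n_samples
    n_trials = len(schedule.trials)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)

    samples = np.empty((len(config.channel_gains), n * n_trials))
    markers = []
    labels = []
    for i, trial in enumerate(schedule.trials):
        ep = simulate_epoch(
            config,
            trial.condition,
            children[i],
            trial_index=trial.trial_index,
            phase=trial.phase,
            face_id=trial.face_id,
        )
        onset = i * n
        samples[:, onset : onset + n] = ep.samples
        markers.append((onset, trial.trial_index))
        labels.append(
            {
                "trial_index": trial.trial_index,
                "phase": trial.phase,
                "condition": trial.condition,
                "face_id": trial.face_id,
                "onset_sample": onset,
            }
        )

    if n_trials == 0:
        samples = np.empty((len(config.channel_gains), 0))

    rec = EEGRecording(
        samples=samples,
        fs=config.fs,
        channel_labels=config.channel_labels,
        markers=markers,
    )
    return rec, pd.DataFrame(
        labels, columns=["trial_index", "phase", "condition", "face_id", "onset_sample"]
    )
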