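"""Spectral features for frequency-tagged attention decoding.

Three families, all computed on the occipital channels of a 5-s epoch:

* **PSD** — the one-sided periodogram ``(1/N)|X(f)|^2`` of the average of
  the configured channels, restricted to bins in [1, 40] Hz.
* **Power bank** — per channel, per tag, per harmonic: band power in
  ``[n*f - f0, n*f + f0]`` normalized by the channel's total one-sided
  power (DC excluded), giving values in [0, 1].
* **Cosine correlation** — per channel, per tag, per harmonic: the Pearson
  correlation between the channel time series and a zero-phase cosine
  template ``cos(2*pi*n*f*t)``.

The FFT length equals the epoch length (1280 samples at the defaults, so a
0.2 Hz bin grid, on which the 8.57 Hz face tag is deliberately off-grid);
band membership is decided purely by bin centers with closed interval
bounds, with no interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OCCIPITAL, TrialEpoch

PSD = "psd"
POWER_BANK = "power_bank"
COSINE_CORR = "cosine_corr"
FAMILIES = (PSD, POWER_BANK, COSINE_CORR)

#: PSD features are reported over this band (Hz), matching the acquisition
#: band-pass.
PSD_BAND = (1.0, 40.0)


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature family to extract and with what parameters."""

    family: str = POWER_BANK
    n_harmonics: int = 3
    f0: float = 2.0
    tag_frequencies: tuple[float, float] = (8.57, 12.0)
    channels: tuple[str, ...] = OCCIPITAL
    use_feature_selection: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not self.channels:
            raise ValueError("channel set must be non-empty")

    def describe(self) -> str:
        name = {PSD: "PSD", POWER_BANK: "Power bank", COSINE_CORR: "Cosine corr"}[self.family]
        parts = []
        if self.family != PSD:
            parts.append(f"n={self.n_harmonics}")
        if self.family == POWER_BANK:
            parts.append(f"f0={self.f0:g}")
        if self.use_feature_selection:
            parts.append("FS")
        return f"{name} ({', '.join(parts)})" if parts else name


@dataclass
class FeatureMatrix:
    """Trials x features matrix with per-trial condition labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: list[str]
    trial_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape inconsistent with feature_names")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per trial required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "condition", self.labels)
        if self.trial_indices:
            df.insert(0, "trial_index", self.trial_indices)
        return df


def _channel_block(ep: TrialEpoch, cfg: FeatureConfig) -> np.ndarray:
    rows = []
    for ch in cfg.channels:
        rows.append(ep.channel(ch))  # raises KeyError if missing
    return np.vstack(rows)


def _check_band(cfg: FeatureConfig, fs: float) -> None:
    top = cfg.n_harmonics * max(cfg.tag_frequencies) + cfg.f0
    if top >= fs / 2:
        raise ValueError(
            f"band edge {top:g} Hz reaches Nyquist ({fs / 2:g} Hz)"
        )


def psd_features(ep: TrialEpoch, cfg: FeatureConfig) -> tuple[np.ndarray, list[str]]:
    """One-sided periodogram of the channel-average signal over [1, 40] Hz."""
    if cfg.family != PSD:
        raise ValueError("config family is not 'psd'")
    block = _channel_block(ep, cfg)
    avg = block.mean(axis=0)
    n = len(avg)
    spec = np.abs(np.fft.rfft(avg)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / ep.fs)
    keep = (freqs >= PSD_BAND[0]) & (freqs <= PSD_BAND[1])
    names = [f"psd|{f:.4g}Hz" for f in freqs[keep]]
    return spec[keep], names


def _harmonic_grid(cfg: FeatureConfig):
    for ch in cfg.channels:
        for f in cfg.tag_frequencies:
            for order in range(1, cfg.n_harmonics + 1):
                yield ch, f, order


def power_bank_features(ep: TrialEpoch, cfg: FeatureConfig) -> tuple[np.ndarray, list[str]]:
    """Normalized band power around each tag harmonic, per channel.

    Denominator is the channel's total one-sided power excluding DC, so
    every ratio lies in [0, 1] and ratios of disjoint bands sum to <= 1.
    """
    if cfg.family != POWER_BANK:
        raise ValueError("config family is not 'power_bank'")
    _check_band(cfg, ep.fs)
    block = _channel_block(ep, cfg)
    n = block.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / ep.fs)
    power = np.abs(np.fft.rfft(block, axis=1)) ** 2
    totals = power[:, 1:].sum(axis=1)  # DC excluded

    values, names = [], []
    ch_index = {ch: i for i, ch in enumerate(cfg.channels)}
    for ch, f, order in _harmonic_grid(cfg):
        lo, hi = order * f - cfg.f0, order * f + cfg.f0
        band = (freqs >= lo) & (freqs <= hi)
        total = totals[ch_index[ch]]
        band_power = power[ch_index[ch], band][freqs[band] > 0].sum()
        values.append(band_power / total if total > 0 else 0.0)
        names.append(f"pb|{ch}|{f:g}Hz|h{order}")
    return np.array(values), names


def cosine_corr_features(ep: TrialEpoch, cfg: FeatureConfig) -> tuple[np.ndarray, list[str]]:
    """Pearson correlation against cosine templates at each tag harmonic.

    Templates use the epoch time base ``t = (0..N-1)/fs`` at phase zero.  A
    zero-variance channel yields r = 0 with a warning.
    """
    if cfg.family != COSINE_CORR:
        raise ValueError("config family is not 'cosine_corr'")
    block = _channel_block(ep, cfg)
    n = block.shape[1]
    t = np.arange(n) / ep.fs

    values, names = [], []
    ch_index = {ch: i for i, ch in enumerate(cfg.channels)}
    for ch, f, order in _harmonic_grid(cfg):
        x = block[ch_index[ch]]
        template = np.cos(2 * np.pi * order * f * t)
        sx = x.std()
        if sx == 0:
            warnings.warn(f"zero-variance channel {ch}; cosine correlation set to 0")
            r = 0.0
        else:
            xc = x - x.mean()
            tc = template - template.mean()
            r = float(np.dot(xc, tc) / (np.linalg.norm(xc) * np.linalg.norm(tc)))
        values.append(r)
        names.append(f"cc|{ch}|{f:g}Hz|h{order}")
    return np.array(values), names


_EXTRACTORS = {
    PSD: psd_features,
    POWER_BANK: power_bank_features,
    COSINE_CORR: cosine_corr_features,
}


def extract_features(ep: TrialEpoch, cfg: FeatureConfig) -> tuple[np.ndarray, list[str]]:
    """Dispatch to the configured family's extractor."""
    return _EXTRACTORS[cfg.family](ep, cfg)


def assemble_feature_matrix(epochs: list[TrialEpoch], cfg: FeatureConfig) -> FeatureMatrix:
    """Featurize a list of epochs; rows ordered by trial index."""
    if not epochs:
        raise ValueError("cannot assemble a feature matrix from zero epochs")
    lengths = {ep.n_samples for ep in epochs}
    if len(lengths) > 1:
        raise ValueError(f"mixed epoch lengths {sorted(lengths)}")
    ordered = sorted(epochs, key=lambda e: e.trial_index)
    rows, names = [], None
    for ep in ordered:
        vec, names = extract_features(ep, cfg)
        rows.append(vec)
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        labels=[ep.condition for ep in ordered],
        trial_indices=[ep.trial_index for ep in ordered],
    )


def write_feature_matrix(fm: FeatureMatrix, path, cfg: FeatureConfig | None = None) -> None:
    """Serialize as CSV; the config travels as a JSON comment header line."""
    import json

    with open(path, "w") as fh:
        if cfg is not None:
            fh.write("# config: " + json.dumps(cfg.__dict__, default=list) + "\n")
        fm.to_frame().to_csv(fh, index=False)
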