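"""EEG epoch preprocessing: band-pass filter, crop, featurize.

Raw trials (trials × channels × time) are turned into feature vectors
in three steps: a zero-phase Butterworth band-pass over the mu/beta
band, a half-open epoch crop [t_start, t_end), and either per-channel
log band-power (the variance of the band-passed epoch, log-transformed)
or plain flattening of the cropped samples.

Defaults follow the common motor-imagery recipe: 250 Hz sampling,
fifth-order Butterworth 8–30 Hz, epoch 1.5–6.5 s — which at 250 Hz is
exactly 1250 samples per channel.  Zero-phase (forward-backward)
application doubles the effective filter order but leaves oscillatory
phase intact, the standard choice for band-power features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["EpochSpec", "bandpass", "epoch_and_featurize", "preprocess"]


@dataclass(frozen=True)
class EpochSpec:
    fs: float = 250.0
    t_start_s: float = 1.5
    t_end_s: float = 6.5
    band_low_hz: float = 8.0
    band_high_hz: float = 30.0
    filter_order: int = 5
    feature_mode: str = "log_bandpower"

    def __post_init__(self) -> None:
        if not self.t_end_s > self.t_start_s:
            raise ValueError("t_end_s must exceed t_start_s")
        if not 0 < self.band_low_hz < self.band_high_hz < self.fs / 2:
            raise ValueError("band must satisfy 0 < low < high < fs/2")
        if self.feature_mode not in ("flatten", "log_bandpower"):
            raise ValueError("feature_mode must be 'flatten' or 'log_bandpower'")

    @property
    def n_epoch_samples(self) -> int:
        return int(round(self.t_end_s * self.fs)) - int(round(self.t_start_s * self.fs))


def bandpass(trials: np.ndarray, spec: EpochSpec) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    Accepts (..., time); each channel of each trial is filtered
    forward-backward, so the magnitude response is squared and the phase
    response is zero.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.shape[-1] <= 3 * spec.filter_order:
        raise ValueError("trial too short for the requested filter order")
    b, a = butter(
        spec.filter_order, [spec.band_low_hz, spec.band_high_hz], btype="bandpass", fs=spec.fs
    )
    return filtfilt(b, a, trials, axis=-1)


def epoch_and_featurize(trials: np.ndarray, spec: EpochSpec) -> np.ndarray:
    """Crop to the epoch window and map each trial to a feature vector.

    Returns an (n_trials × features) matrix: channels·window samples in
    ``flatten`` mode, one log band-power value per channel otherwise.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be (n_trials, n_channels, n_samples)")
    i0 = int(round(spec.t_start_s * spec.fs))
    i1 = int(round(spec.t_end_s * spec.fs))
    if i1 > trials.shape[-1] or i0 < 0:
        raise ValueError("epoch window exceeds trial bounds")
    cropped = trials[:, :, i0:i1]
    if spec.feature_mode == "flatten":
        return cropped.reshape(cropped.shape[0], -1)
    power = cropped.var(axis=-1)
    return np.log(power + np.finfo(float).tiny)


def preprocess(trials: np.ndarray, spec: EpochSpec | None = None) -> np.ndarray:
    """Band-pass then crop+featurize; filtering precedes the crop so the
    filter's edge transients fall outside the analysis window."""
    if spec is None:
        spec = EpochSpec()
    return epoch_and_featurize(bandpass(trials, spec), spec)
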