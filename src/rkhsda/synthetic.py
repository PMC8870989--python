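"""Seeded generators for domain-shifted classification data and toy EEG.

Two scenarios with known ground truth make every pipeline stage testable
without external downloads:

* ``ShiftScenario`` — C Gaussian class blobs; the target domain is the
  same mixture pushed through a rotation in the first two feature
  coordinates and a global translation (covariate shift).  True target
  labels are returned separately and are never consumed by any fitting
  routine.
* ``ToyEEGScenario`` — multichannel trials in which each class drives
  the channels with a class-specific oscillation (8–30 Hz band) through
  a class-specific spatial pattern, plus white noise.  A second session
  (fresh noise, optional channel-gain drift) stands in for the target
  domain of a cross-session transfer problem.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .domain_data import DomainBundle, combine

__all__ = [
    "ShiftScenario",
    "ToyEEGScenario",
    "generate_shifted_gaussians",
    "generate_toy_eeg",
    "generate_toy_eeg_sessions",
]


@dataclass(frozen=True)
class ShiftScenario:
    """Two-domain Gaussian mixture with class-structured covariate shift.

    Class c (c = 0..C−1) has mean ``class_sep·c`` along the first
    feature axis and isotropic noise ``noise_sd``.  Target samples are
    rotated by ``rotation_angle`` in the plane of the first two features
    (about the origin) and then translated by ``shift``.
    """

    C: int = 3
    D: int = 10
    n_per_class_source: int = 30
    n_per_class_target: int = 30
    class_sep: float = 3.0
    shift: tuple = (0.0, 2.0)
    rotation_angle: float = np.pi / 6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.C, self.D, self.n_per_class_source, self.n_per_class_target) < 1:
            raise ValueError("counts and dimensions must be at least 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.D < 2:
            raise ValueError("need D >= 2 for the rotation plane")

    def shift_vector(self) -> np.ndarray:
        v = np.zeros(self.D)
        s = np.asarray(self.shift, dtype=float)
        v[: len(s)] = s
        return v


def _class_means(sc: ShiftScenario) -> np.ndarray:
    means = np.zeros((sc.C, sc.D))
    means[:, 0] = sc.class_sep * np.arange(sc.C)
    return means


def generate_shifted_gaussians(sc: ShiftScenario) -> tuple[DomainBundle, np.ndarray]:
    """Draw a source/target pair; returns (bundle, true target labels).

    The true target labels are for evaluation only — the bundle handed
    to the fitting routines does not carry them.
    """
    rng = np.random.default_rng(sc.seed)
    means = _class_means(sc)

    def draw(n_per_class: int) -> tuple[np.ndarray, np.ndarray]:
        X = np.vstack(
            [means[c] + sc.noise_sd * rng.standard_normal((n_per_class, sc.D)) for c in range(sc.C)]
        )
        y = np.repeat(np.arange(1, sc.C + 1), n_per_class)
        return X, y

    Xs, ys = draw(sc.n_per_class_source)
    Xt, yt = draw(sc.n_per_class_target)

    # covariate shift: rotate target in the (0, 1) plane, then translate
    c, s = np.cos(sc.rotation_angle), np.sin(sc.rotation_angle)
    R2 = np.array([[c, -s], [s, c]])
    Xt = Xt.copy()
    Xt[:, :2] = Xt[:, :2] @ R2.T
    Xt = Xt + sc.shift_vector()

    return combine(Xs, ys, Xt), yt


@dataclass(frozen=True)
class ToyEEGScenario:
    """Band-limited oscillatory trials with class-specific spatial patterns.

    Each trial of class c is ``pattern_c · sin(2π f_c t + φ)`` across
    channels plus white noise; ``snr`` is the amplitude ratio of the
    oscillation peak to the noise standard deviation.  Trials are long
    enough to cover the standard 1.5–6.5 s epoch window.
    """

    n_channels: int = 6
    fs: float = 250.0
    duration_s: float = 7.0
    n_trials_per_class: int = 15
    class_freqs: tuple = (10.0, 22.0)
    snr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.class_freqs)) != len(self.class_freqs):
            raise ValueError("class_freqs must be distinct")
        if not self.fs > 2 * max(self.class_freqs):
            raise ValueError("sampling rate must exceed twice the highest class frequency")

    @property
    def n_classes(self) -> int:
        return len(self.class_freqs)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _spatial_patterns(sc: ToyEEGScenario) -> np.ndarray:
    # deterministic, well-separated per-class channel weightings
    ch = np.arange(sc.n_channels)
    return np.vstack(
        [0.5 + 0.5 * np.cos(np.pi * ch * (c + 1) / sc.n_channels) for c in range(sc.n_classes)]
    )


def generate_toy_eeg(
    sc: ToyEEGScenario, gain: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one session; returns (trials × channels × time, labels 1..C).

    ``gain`` optionally scales each channel (session-to-session drift).
    """
    rng = np.random.default_rng(sc.seed)
    t = np.arange(sc.n_samples) / sc.fs
    patterns = _spatial_patterns(sc)
    n_trials = sc.n_trials_per_class * sc.n_classes
    trials = np.empty((n_trials, sc.n_channels, sc.n_samples))
    labels = np.repeat(np.arange(1, sc.n_classes + 1), sc.n_trials_per_class)
    for i, lab in enumerate(labels):
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * sc.class_freqs[lab - 1] * t + phase)
        signal = sc.snr * np.outer(patterns[lab - 1], osc)
        trials[i] = signal + rng.standard_normal((sc.n_channels, sc.n_samples))
    if gain is not None:
        trials = trials * np.asarray(gain, dtype=float)[None, :, None]
    return trials, labels


def generate_toy_eeg_sessions(
    sc: ToyEEGScenario, gain_drift_sd: float = 0.2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Source and target sessions of the same subject.

    The target session uses an independent noise realization and
    multiplicative per-channel gains drawn around 1 with standard
    deviation ``gain_drift_sd`` — a simple stand-in for electrode and
    state changes between recording days.

    Returns (source trials, source labels, target trials, target labels).
    """
    Xs, ys = generate_toy_eeg(sc)
    rng = np.random.default_rng(sc.seed + 1_000_003)
    gain = np.clip(1.0 + gain_drift_sd * rng.standard_normal(sc.n_channels), 0.2, None)
    Xt, yt = generate_toy_eeg(replace(sc, seed=sc.seed + 1), gain=gain)
    return Xs, ys, Xt, yt
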