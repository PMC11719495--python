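"""Synthetic 35-channel EEG segments with epilepsy/normal class structure.

The generator emulates the composition of a clinical scalp-EEG study used for
binary seizure-disorder screening: many subjects, a variable number of 1-s
segments per subject, and two classes that differ in waveform structure.

* Normal segments are spatially mixed 1/f^beta background processes, each
  channel carrying an additional alpha-band (8-13 Hz) rhythm.
* Epilepsy segments add a generalized spike-and-wave discharge (a sharp
  ~10 ms spike followed by a slow opposite-polarity half-sine wave, the
  complex repeating near 3 Hz) to a focal subset of channels, scaled
  relative to each channel's background RMS.

Randomness is counter-based: one global seed expands into independent
per-subject and per-segment substreams, so generating a subset of subjects
or segments yields bit-identical waveforms to the corresponding slice of the
full dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticConfig",
    "EEGSegment",
    "generate_background",
    "generate_spike_wave",
    "generate_dataset",
]

#: Class label encoding used throughout the package: epilepsy is the
#: positive class (true positives = correctly predicted epileptic).
LABEL_NORMAL = 0
LABEL_EPILEPSY = 1
CLASS_NAMES = ("normal", "epilepsy")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_subjects_per_class:
        Subjects simulated for each of the two classes.
    segments_per_subject_range:
        Inclusive (min, max) bounds of the per-subject segment count, drawn
        uniformly per subject. Variable counts mirror real studies where
        each participant contributes a different number of 1-s samples.
    fs:
        Sampling rate in Hz. 500 Hz gives T=500 samples per 1-s segment and
        a clinically plausible bandwidth.
    n_channels:
        Electrode count; the image pipeline expects 35.
    swd_rate:
        Spike-and-wave fundamental frequency in Hz (classically ~3 Hz).
    swd_amplitude_ratio:
        Spike amplitude over per-channel background RMS (dimensionless).
    focal_channel_fraction:
        Fraction in (0, 1] of channels carrying epileptiform activity.
    alpha_band:
        (low, high) Hz of the background posterior rhythm.
    noise_exponent:
        Spectral slope beta of the 1/f^beta background.
    seed:
        Global seed; all substreams derive from it.
    """

    n_subjects_per_class: int = 40
    segments_per_subject_range: tuple[int, int] = (10, 20)
    fs: float = 500.0
    n_channels: int = 35
    swd_rate: float = 3.0
    swd_amplitude_ratio: float = 4.0
    focal_channel_fraction: float = 0.5
    alpha_band: tuple[float, float] = (8.0, 13.0)
    noise_exponent: float = 1.0
    seed: int = 0
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.segments_per_subject_range
        if not (1 <= lo <= hi):
            raise ValueError("segments_per_subject_range must satisfy 1 <= min <= max")
        if self.fs < 2 * self.alpha_band[1]:
            raise ValueError("fs must be at least 2 x alpha_band.high (Nyquist)")
        if not (0 < self.focal_channel_fraction <= 1):
            raise ValueError("focal_channel_fraction must be in (0, 1]")
        if self.n_subjects_per_class < 1:
            raise ValueError("need at least one subject per class")
        if not (0 < self.swd_rate < self.fs / 10):
            raise ValueError("swd_rate must satisfy 0 < rate < fs/10")


@dataclass
class EEGSegment:
    """One labelled 1-s multichannel sample.

    ``samples`` is an (n_channels, T) float array in arbitrary microvolt-like
    units; classification downstream is scale-robust after per-image
    normalization.
    """

    samples: np.ndarray
    fs: float
    label: int
    subject_id: str
    segment_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def generate_background(
    fs: float,
    duration_s: float = 1.0,
    alpha_band: tuple[float, float] = (8.0, 13.0),
    noise_exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One channel of normal background EEG.

    Spectral synthesis of 1/f^beta noise (unit-amplitude spectrum shaped as
    f^(-beta/2) with uniform random phases) plus a single alpha-band
    sinusoid at a random frequency in ``alpha_band`` with amplitude
    1.5x the noise RMS. Output has zero mean.
    """
    if rng is None:
        rng = np.random.default_rng()
    if fs <= 2 * alpha_band[1]:
        raise ValueError("fs must exceed 2 x alpha_band.high")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(fs * duration_s))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-noise_exponent / 2.0)
    phases = rng.uniform(0.0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    noise = np.fft.irfft(spectrum, n=n)
    noise_rms = float(np.sqrt(np.mean(noise**2)))

    f_alpha = rng.uniform(*alpha_band)
    phi = rng.uniform(0.0, 2 * np.pi)
    t = np.arange(n) / fs
    alpha = 1.5 * noise_rms * np.sin(2 * np.pi * f_alpha * t + phi)

    x = noise + alpha
    return x - x.mean()


#: Spike-and-wave morphology constants: Gaussian spike width and the slow
#: wave's duration / relative amplitude / onset lag after the spike centre.
_SPIKE_SIGMA_S = 0.010
_WAVE_WIDTH_S = 0.180
_WAVE_REL_AMPLITUDE = 0.6
_WAVE_LAG_S = 3 * _SPIKE_SIGMA_S


def generate_spike_wave(
    fs: float,
    duration_s: float = 1.0,
    swd_rate: float = 3.0,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One channel of periodic spike-and-wave discharge.

    Complexes repeat at ``swd_rate`` Hz from a random onset phase. Each
    complex is a sharp Gaussian spike (sigma = 10 ms, height ``amplitude``)
    followed by a slow half-sine wave of opposite polarity (width 180 ms,
    height 0.6 x ``amplitude``).
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0 < swd_rate < fs / 10):
        raise ValueError("swd_rate must satisfy 0 < rate < fs/10")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    x = np.zeros(n)
    if amplitude == 0:
        # still consume the onset draw so signal content is rng-stable
        rng.uniform(0.0, 1.0 / swd_rate)
        return x
    onset = rng.uniform(0.0, 1.0 / swd_rate)
    period = 1.0 / swd_rate
    k = 0
    while True:
        tc = onset + k * period
        if tc >= duration_s:
            break
        x += amplitude * np.exp(-0.5 * ((t - tc) / _SPIKE_SIGMA_S) ** 2)
        w0 = tc + _WAVE_LAG_S
        in_wave = (t >= w0) & (t < w0 + _WAVE_WIDTH_S)
        x[in_wave] -= (
            _WAVE_REL_AMPLITUDE
            * amplitude
            * np.sin(np.pi * (t[in_wave] - w0) / _WAVE_WIDTH_S)
        )
        k += 1
    return x


def _subject_rng(seed: int, class_idx: int, subject_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, class_idx, subject_idx]))


def _segment_rng(
    seed: int, class_idx: int, subject_idx: int, segment_idx: int
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, class_idx, subject_idx, segment_idx])
    )


def _mixing_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random full-rank mixing matrix with unit diagonal dominance.

    Diagonal is 1; each row's off-diagonal entries are scaled to absolute
    sum 0.5, so the matrix is strictly diagonally dominant (hence full
    rank) while still spreading every source across electrodes.
    """
    off = rng.uniform(-1.0, 1.0, size=(n, n))
    np.fill_diagonal(off, 0.0)
    row_sums = np.abs(off).sum(axis=1, keepdims=True)
    off = 0.5 * off / np.where(row_sums == 0, 1.0, row_sums)
    return np.eye(n) + off


def generate_dataset(config: SyntheticConfig) -> tuple[list[EEGSegment], "pd.DataFrame"]:
    """Simulate the full two-class study defined by ``config``.

    Returns the segments plus a manifest table with columns
    (subject_id, segment_id, label, class_name). Subject-level draws
    (segment count, mixing matrix, focal channel subset) are fixed per
    subject; waveforms are drawn per segment.
    """
    import pandas as pd  # deferred: keeps signal-only use light

    segments: list[EEGSegment] = []
    records: list[dict] = []
    n_focal = int(np.ceil(config.focal_channel_fraction * config.n_channels))
    lo, hi = config.segments_per_subject_range

    for class_idx, class_name in enumerate(CLASS_NAMES):
        prefix = "N" if class_idx == LABEL_NORMAL else "E"
        for s in range(config.n_subjects_per_class):
            srng = _subject_rng(config.seed, class_idx, s)
            n_segments = int(srng.integers(lo, hi + 1))
            mixing = _mixing_matrix(config.n_channels, srng)
            focal = srng.choice(config.n_channels, size=n_focal, replace=False)
            subject_id = f"{prefix}{s:03d}"
            for g in range(n_segments):
                grng = _segment_rng(config.seed, class_idx, s, g)
                sources = np.stack(
                    [
                        generate_background(
                            config.fs,
                            config.duration_s,
                            config.alpha_band,
                            config.noise_exponent,
                            grng,
                        )
                        for _ in range(config.n_channels)
                    ]
                )
                samples = mixing @ sources
                if class_idx == LABEL_EPILEPSY:
                    swd = generate_spike_wave(
                        config.fs, config.duration_s, config.swd_rate, 1.0, grng
                    )
                    rms = np.sqrt(np.mean(samples[focal] ** 2, axis=1))
                    samples[focal] += (
                        config.swd_amplitude_ratio * rms[:, None] * swd[None, :]
                    )
                segment_id = f"s{g:03d}"
                segments.append(
                    EEGSegment(
                        samples=samples,
                        fs=config.fs,
                        label=class_idx,
                        subject_id=subject_id,
                        segment_id=segment_id,
                    )
                )
                records.append(
                    {
                        "subject_id": subject_id,
                        "segment_id": segment_id,
                        "label": class_idx,
                        "class_name": class_name,
                    }
                )
    manifest = pd.DataFrame.from_records(records)
    return segments, manifest
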