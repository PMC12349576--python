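"""Preprocessing chain for short-window SSVEP classification.

Raw multichannel EEG is reduced to nine occipital channels, downsampled from
1000 Hz to 250 Hz behind an anti-aliasing low-pass, cropped to a short window
whose start is drawn by a random-initialization sliding window (onset offset
0.14 s for visual latency plus a random r), and pushed through a bank of four
Butterworth bandpass filters whose outputs are stacked, giving a
(4, 9, P) tensor per window.

The four passbands 19-50, 14-38, 9-26 and 3-14 Hz bracket the fundamentals
and harmonics of the four stimulus frequencies below the 50 Hz SNR cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "OCCIPITAL_CHANNELS",
    "FilterBankSpec",
    "WindowSpec",
    "select_channels",
    "downsample",
    "design_filter_bank",
    "apply_filter_bank",
    "random_window",
]

OCCIPITAL_CHANNELS = ("Pz", "P1", "P2", "PO3", "PO4", "POz", "Oz", "O1", "O2")

DEFAULT_BANDS = ((19.0, 50.0), (14.0, 38.0), (9.0, 26.0), (3.0, 14.0))


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered bandpass definitions and the Butterworth design order."""

    bands: tuple = DEFAULT_BANDS
    order: int = 6
    design: str = "butterworth"

    def __post_init__(self):
        for low, high in self.bands:
            if not 0.0 < low < high:
                raise ValueError(f"invalid band ({low}, {high})")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class WindowSpec:
    """Random-initialization sliding window: crop [0.14 + r, 0.14 + r + d] s.

    d_samples is the window length P in samples at fs_out; r is uniform on
    [0, r_max].  By default r_max keeps the window inside the 4 s stimulation
    segment (r_max = 4 - d - 0.14); set it explicitly to allow the window to
    run up to 4 - d, i.e. 0.14 s into the post-stimulation rest.
    """

    d_samples: int = 64
    onset_offset: float = 0.14
    r_max: float | None = None
    fs: float = 250.0
    stim_duration: float = 4.0

    def __post_init__(self):
        if self.d_samples < 1:
            raise ValueError("window length must be >= 1 sample")
        if self.onset_offset < 0:
            raise ValueError("onset offset must be >= 0")
        if self.r_max is not None and self.r_max < 0:
            raise ValueError("r_max must be >= 0")

    @property
    def d_seconds(self) -> float:
        return self.d_samples / self.fs

    @property
    def effective_r_max(self) -> float:
        if self.r_max is not None:
            return self.r_max
        return max(0.0, self.stim_duration - self.d_seconds - self.onset_offset)


def select_channels(recording: np.ndarray, channel_names, wanted_names=OCCIPITAL_CHANNELS):
    """Reorder (channels, samples) rows to exactly the wanted channel order."""
    recording = np.asarray(recording)
    names = list(channel_names)
    idx = []
    for w in wanted_names:
        if w not in names:
            raise KeyError(f"channel '{w}' not present in recording")
        idx.append(names.index(w))
    return recording[idx]


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased integer-factor decimation along the last axis."""
    if fs_in % fs_out != 0:
        raise ValueError(f"fs_in={fs_in} not an integer multiple of fs_out={fs_out}")
    q = int(fs_in // fs_out)
    if q == 1:
        return np.asarray(x, dtype=np.float64).copy()
    return signal.decimate(np.asarray(x, dtype=np.float64), q, ftype="iir",
                           zero_phase=True, axis=-1)


def design_filter_bank(spec: FilterBankSpec = FilterBankSpec(), fs: float = 250.0):
    """Design one stable Butterworth bandpass (SOS form) per band."""
    nyq = fs / 2.0
    bank = []
    for low, high in spec.bands:
        if high >= nyq:
            raise ValueError(f"band edge {high} Hz >= Nyquist {nyq} Hz")
        sos = signal.butter(spec.order, [low, high], btype="bandpass",
                            fs=fs, output="sos")
        poles = np.concatenate([np.roots([1.0, s[4], s[5]]) for s in sos])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(f"unstable design for band ({low}, {high}) at fs={fs}")
        bank.append(sos)
    return bank


def apply_filter_bank(window: np.ndarray, bank, mode: str = "zero-phase") -> np.ndarray:
    """Filter every channel with every band and stack: (..., C, P) -> (..., B, C, P).

    Zero-phase (forward-backward) filtering by default; 'causal' applies a
    single forward pass for real-time fidelity.
    """
    window = np.asarray(window, dtype=np.float64)
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    if mode == "zero-phase":
        slabs = [signal.sosfiltfilt(sos, window, axis=-1) for sos in bank]
    elif mode == "causal":
        slabs = [signal.sosfilt(sos, window, axis=-1) for sos in bank]
    else:
        raise ValueError(f"unknown filtering mode '{mode}'")
    return np.stack(slabs, axis=-3)


def random_window(trial: np.ndarray, ws: WindowSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Crop P contiguous samples starting at round((onset + r) * fs), r ~ U[0, r_max]."""
    trial = np.asarray(trial)
    r = rng.uniform(0.0, ws.effective_r_max)
    start = int(round((ws.onset_offset + r) * ws.fs))
    stop = start + ws.d_samples
    if stop > trial.shape[-1]:
        raise ValueError(
            f"window [{start}, {stop}) overruns trial of {trial.shape[-1]} samples"
        )
    return trial[..., start:stop]
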