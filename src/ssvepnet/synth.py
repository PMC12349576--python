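"""Synthetic multi-subject SSVEP epoch generator.

Emulates the structure of a four-class SSVEP recording session: nine
occipital channels sampled at 1000 Hz, 4 s of stimulation per trial (plus a
short rest tail), four stimulus frequencies, 25 trials per class per subject.
The steady-state response is modelled as a stimulus-locked harmonic series
with geometrically decaying amplitudes, mixed into the channels by a
subject-specific gain pattern, buried in white Gaussian noise calibrated to a
requested per-channel signal-to-noise ratio (SNR).

Phases and channel gains are drawn once per subject (SSVEP responses are
phase-locked to stimulus onset) with small per-trial jitter; a subject-level
signal gain produces subject-to-subject SNR variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "StimulusSet",
    "SynthConfig",
    "SubjectProfile",
    "EpochSet",
    "draw_subject_profile",
    "generate_trial",
    "generate_subject",
    "write_epochs",
    "read_epochs",
]

#: harmonics at or above this frequency carry too little SNR and are omitted
HARMONIC_CUTOFF_HZ = 50.0

DEFAULT_FREQUENCIES = (8.57, 5.45, 12.0, 6.67)
DEFAULT_POSITIONS = ("right", "top", "left", "bottom")


@dataclass(frozen=True)
class StimulusSet:
    """The four flicker stimuli: frequency, class label and screen position."""

    frequencies: tuple = DEFAULT_FREQUENCIES
    labels: tuple = (0, 1, 2, 3)
    positions: tuple = DEFAULT_POSITIONS

    def __post_init__(self):
        if len(self.frequencies) != 4 or len(self.labels) != 4:
            raise ValueError("a StimulusSet holds exactly 4 stimuli")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("stimulus frequencies must be positive")
        if len(set(self.frequencies)) != 4:
            raise ValueError("stimulus frequencies must be pairwise distinct")

    def frequency_of(self, label: int) -> float:
        return self.frequencies[self.labels.index(label)]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    snr_db is the per-channel signal-to-noise power ratio, defined on the
    full band at the raw sampling rate before any filtering; +inf means
    noiseless.  a1 is the fundamental amplitude; harmonic h has amplitude
    a1 * harmonic_decay**(h-1).  noise_sd is only used when the signal power
    is zero (a1 = 0), where the SNR rule cannot set a noise scale.

    noise_color selects the background model: "white" (default) or "pink",
    the latter shaping white noise with a first-order autoregressive filter
    (pole noise_ar) to mimic the low-frequency-dominated spectrum of resting
    EEG; either way the total per-channel noise power honours snr_db.
    """

    n_channels: int = 9
    fs: float = 1000.0
    stim_duration: float = 4.0
    tail_duration: float = 0.2
    n_harmonics: int = 4
    harmonic_decay: float = 0.5
    snr_db: float = 10.0
    a1: float = 1.0
    noise_sd: float = 1.0
    noise_color: str = "white"
    noise_ar: float = 0.95
    subject_gain_sd: float = 0.2
    latency_sd: float = 0.015
    phase_jitter_sd: float = 0.2
    gain_jitter: float = 0.1
    trials_per_class: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if not (np.isfinite(self.snr_db) or self.snr_db == np.inf):
            raise ValueError("snr_db must be finite or +inf")
        if self.n_channels < 1 or self.fs <= 0:
            raise ValueError("invalid channel count or sampling rate")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")
        if not 0.0 <= self.noise_ar < 1.0:
            raise ValueError("noise_ar must lie in [0, 1)")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject latent parameters, drawn once and reused for every trial.

    phases[k, h, c] is the onset-locked phase of harmonic h for class k on
    channel c, composed of a class/harmonic base phase plus a per-channel
    propagation latency tau_c (phase 2*pi*h*f_k*tau_c) — the small
    channel-to-channel delays of real multichannel SSVEP.  channel_gains[c]
    is the stable spatial mixing gain of channel c; signal_gain is the
    subject-level multiplicative signal amplitude (log-normal around 1),
    which shifts the subject's realized SNR.
    """

    phases: np.ndarray
    channel_gains: np.ndarray
    signal_gain: float


@dataclass
class EpochSet:
    """A labelled block of trials: data (trials, channels, samples)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    stimulus: StimulusSet = field(default_factory=StimulusSet)
    subject_id: str = "S00"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.labels.size and not np.isin(self.labels, [0, 1, 2, 3]).all():
            raise ValueError("labels must lie in {0,1,2,3}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _retained_harmonics(f: float, n_harmonics: int) -> np.ndarray:
    """Harmonic multipliers h with h*f below the 50 Hz cutoff."""
    h = np.arange(1, n_harmonics + 1)
    return h[h * f <= HARMONIC_CUTOFF_HZ]


def draw_subject_profile(
    cfg: SynthConfig,
    rng: np.random.Generator,
    stimulus: StimulusSet = StimulusSet(),
) -> SubjectProfile:
    base = rng.uniform(0.0, 2.0 * np.pi, size=(4, cfg.n_harmonics))
    tau = rng.normal(0.0, cfg.latency_sd, size=cfg.n_channels)
    freqs = np.array([stimulus.frequency_of(k) for k in (0, 1, 2, 3)])
    h = np.arange(1, cfg.n_harmonics + 1)
    phases = (base[:, :, None]
              + 2.0 * np.pi * freqs[:, None, None] * h[None, :, None] * tau[None, None, :])
    gains = rng.uniform(0.5, 1.0, size=cfg.n_channels)
    signal_gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd)))
    return SubjectProfile(phases=phases, channel_gains=gains, signal_gain=signal_gain)


def generate_trial(
    stimulus: StimulusSet,
    label: int,
    cfg: SynthConfig,
    rng: np.random.Generator,
    profile: SubjectProfile | None = None,
    return_components: bool = False,
):
    """Simulate one trial: (channels, samples) over stimulation + tail.

    The stored signal and noise components are returned when
    ``return_components`` is set, so the realized SNR can be recomputed
    exactly from the generator's own pieces.
    """
    if label not in stimulus.labels:
        raise ValueError(f"label {label} not in {stimulus.labels}")
    f = stimulus.frequency_of(label)
    harmonics = _retained_harmonics(f, cfg.n_harmonics)
    if harmonics.size and cfg.fs <= 2.0 * f * harmonics[-1]:
        raise ValueError(
            f"fs={cfg.fs} too low for harmonic {harmonics[-1]}*{f} Hz"
        )

    n = int(round((cfg.stim_duration + cfg.tail_duration) * cfg.fs))
    t = np.arange(n) / cfg.fs

    if profile is None:
        profile = draw_subject_profile(cfg, rng, stimulus)
        # standalone use: no jitter on top of the freshly drawn profile
        phase_jit = np.zeros(cfg.n_harmonics)
        gain_jit = np.ones(cfg.n_channels)
    else:
        phase_jit = rng.normal(0.0, cfg.phase_jitter_sd, size=cfg.n_harmonics)
        gain_jit = rng.uniform(1.0 - cfg.gain_jitter, 1.0 + cfg.gain_jitter,
                               size=cfg.n_channels)

    k = stimulus.labels.index(label)
    wave = np.zeros((cfg.n_channels, n))
    for h in harmonics:
        amp = cfg.a1 * cfg.harmonic_decay ** (h - 1)
        # per-channel phase, jittered by a common per-trial latency term
        phi = profile.phases[k, h - 1, :, None] + phase_jit[h - 1]
        wave += amp * np.sin(2.0 * np.pi * h * f * t[None, :] + phi)

    gains = profile.channel_gains * gain_jit          # (channels,)
    nominal = gains[:, None] * wave                   # SNR reference signal
    signal = profile.signal_gain * nominal

    # per-channel noise sd from the nominal (gain=1 subject) signal power, so
    # the subject-level gain shifts the realized SNR as intended
    p_chan = np.mean(nominal**2, axis=1)              # (channels,)
    if cfg.snr_db == np.inf:
        sd_chan = np.zeros(cfg.n_channels)
    elif np.all(p_chan == 0.0):
        sd_chan = np.full(cfg.n_channels, cfg.noise_sd)
    else:
        snr_lin = 10.0 ** (cfg.snr_db / 10.0)
        sd_chan = np.sqrt(p_chan / snr_lin)
    white = rng.standard_normal((cfg.n_channels, n))
    if cfg.noise_color == "pink":
        from scipy.signal import lfilter
        colored = lfilter([1.0], [1.0, -cfg.noise_ar], white, axis=-1)
        # renormalize to unit power via the stationary AR(1) variance
        white = colored * np.sqrt(1.0 - cfg.noise_ar**2)
    noise = sd_chan[:, None] * white

    out = signal + noise
    if return_components:
        return out, signal, noise, sd_chan
    return out


def generate_subject(
    stimulus: StimulusSet,
    cfg: SynthConfig,
    subject_id: str = "S00",
    rng: np.random.Generator | None = None,
    profile: SubjectProfile | None = None,
) -> EpochSet:
    """Simulate one subject's session: 4 * trials_per_class trials in
    randomized order, exactly balanced across classes, sharing one subject
    profile.  Pass the same `profile` to simulate a second session of the
    same subject (e.g. a held-out test session)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if profile is None:
        profile = draw_subject_profile(cfg, rng, stimulus)
    labels = np.repeat(np.arange(4), cfg.trials_per_class)
    rng.shuffle(labels)
    trials = [
        generate_trial(stimulus, int(lab), cfg, rng, profile=profile)
        for lab in labels
    ]
    return EpochSet(
        data=np.stack(trials), labels=labels, fs=cfg.fs,
        stimulus=stimulus, subject_id=subject_id,
    )


def write_epochs(es: EpochSet, path) -> None:
    """Write an EpochSet to an HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data.astype(np.float64))
        f.create_dataset("labels", data=es.labels.astype(np.int8))
        f.attrs["fs"] = es.fs
        f.attrs["subject_id"] = es.subject_id
        f.attrs["frequencies"] = np.asarray(es.stimulus.frequencies)
        f.attrs["class_order"] = np.asarray(es.stimulus.labels)
        f.attrs["positions"] = list(es.stimulus.positions)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "labels"):
            if name not in f:
                raise ValueError(f"malformed epoch container: missing '{name}'")
        for attr in ("fs", "subject_id", "frequencies", "class_order"):
            if attr not in f.attrs:
                raise ValueError(f"malformed epoch container: missing '{attr}'")
        stim = StimulusSet(
            frequencies=tuple(float(x) for x in f.attrs["frequencies"]),
            labels=tuple(int(x) for x in f.attrs["class_order"]),
            positions=tuple(f.attrs.get("positions", DEFAULT_POSITIONS)),
        )
        return EpochSet(
            data=f["data"][...],
            labels=f["labels"][...].astype(np.int64),
            fs=float(f.attrs["fs"]),
            stimulus=stim,
            subject_id=str(f.attrs["subject_id"]),
        )
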