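"""Canonical-correlation SSVEP baselines.

Plain CCA scores a window against sin/cos harmonic templates of each
stimulus frequency and picks the class with the largest first canonical
correlation.  The trained variant (CCA-M3) replaces the synthetic templates
with channel-wise class means of training windows, so the reference carries
the subject's own spatial pattern and harmonic amplitudes.

Harmonics above 50 Hz are dropped from the templates, matching the
preprocessing band limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .synth import HARMONIC_CUTOFF_HZ, StimulusSet

__all__ = [
    "ReferenceSet",
    "build_harmonic_reference",
    "build_harmonic_references",
    "max_canonical_correlation",
    "classify_cca",
    "build_m3_templates",
    "classify_cca_m3",
]

RIDGE = 1e-8


@dataclass(frozen=True)
class ReferenceSet:
    """One template matrix (components x P) per class, in class order."""

    templates: tuple
    kind: str  # "harmonic" | "trained"
    fs: float
    n_harmonics: int = 0

    def __post_init__(self):
        if self.kind not in ("harmonic", "trained"):
            raise ValueError("kind must be 'harmonic' or 'trained'")


def build_harmonic_reference(f: float, fs: float, P: int, H: int = 4) -> np.ndarray:
    """Rows [sin(2*pi*h*f*t); cos(2*pi*h*f*t)] for h = 1..H with h*f <= 50 Hz."""
    h = np.arange(1, H + 1)
    h = h[h * f <= HARMONIC_CUTOFF_HZ]
    if h.size and h[-1] * f > fs / 2:
        raise ValueError(f"harmonic {h[-1]}*{f} Hz exceeds Nyquist {fs / 2} Hz")
    t = np.arange(P) / fs
    rows = []
    for k in h:
        rows.append(np.sin(2 * np.pi * k * f * t))
        rows.append(np.cos(2 * np.pi * k * f * t))
    ref = np.asarray(rows)
    if P < 2 * ref.shape[0]:
        warnings.warn(f"window of {P} samples is short for {ref.shape[0]} "
                      "reference components; CCA may be ill-posed", stacklevel=2)
    return ref


def build_harmonic_references(stimulus: StimulusSet, fs: float, P: int,
                              H: int = 4) -> ReferenceSet:
    templates = tuple(
        build_harmonic_reference(stimulus.frequency_of(k), fs, P, H)
        for k in (0, 1, 2, 3)
    )
    return ReferenceSet(templates=templates, kind="harmonic", fs=fs, n_harmonics=H)


def max_canonical_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest canonical correlation between the row spaces of X and Y.

    Covariance-based solve with a ridge of 1e-8 on the auto-covariances,
    which keeps degenerate (rank-deficient) inputs well defined; a warning is
    issued when the ridge is doing real work.  Symmetric in its arguments and
    invariant to invertible recombination of either matrix's rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the sample axis length")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    n = X.shape[1]
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    scale = max(np.trace(Cxx) / max(len(Cxx), 1), np.trace(Cyy) / max(len(Cyy), 1), 1.0)
    if (np.linalg.matrix_rank(Cxx) < len(Cxx)
            or np.linalg.matrix_rank(Cyy) < len(Cyy)):
        warnings.warn("rank-deficient covariance; using ridge-regularized solve",
                      stacklevel=2)
    Cxx = Cxx + RIDGE * scale * np.eye(len(Cxx))
    Cyy = Cyy + RIDGE * scale * np.eye(len(Cyy))
    Lx = linalg.cholesky(Cxx, lower=True)
    Ly = linalg.cholesky(Cyy, lower=True)
    M = linalg.solve_triangular(Lx, Cxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    s = linalg.svdvals(M)
    return float(np.clip(s[0] if s.size else 0.0, 0.0, 1.0))


def classify_cca(window: np.ndarray, refs: ReferenceSet) -> int:
    """argmax over classes of the first canonical correlation; ties break to
    the lowest class index."""
    scores = [max_canonical_correlation(window, tpl) for tpl in refs.templates]
    return int(np.argmax(scores))


def build_m3_templates(windows: np.ndarray, labels: np.ndarray,
                       fs: float = 250.0) -> ReferenceSet:
    """Class templates = channel-wise means of the training windows (9 x P).

    The windows must be mutually onset-aligned (e.g. all cropped at the
    fixed visual-latency offset): averaging windows cropped at random
    starts cancels the stimulus-locked response — this is the well-known
    window-alignment difficulty of trained-template CCA.  Use
    :func:`build_m3_templates_from_trials` to get aligned templates
    directly from training trials.
    """
    windows = np.asarray(windows, dtype=np.float64)
    labels = np.asarray(labels)
    templates = []
    for k in range(4):
        sel = windows[labels == k]
        if len(sel) == 0:
            raise ValueError(f"no training windows for class {k}")
        templates.append(sel.mean(axis=0))
    return ReferenceSet(templates=tuple(templates), kind="trained", fs=fs)


def build_m3_templates_from_trials(trials: np.ndarray, labels: np.ndarray,
                                   ws, fs: float = 250.0) -> ReferenceSet:
    """Aligned trained templates: every trial is cropped at the fixed
    onset-latency window (r = 0) and the crops are averaged per class."""
    trials = np.asarray(trials, dtype=np.float64)
    start = int(round(ws.onset_offset * ws.fs))
    crops = trials[..., start:start + ws.d_samples]
    return build_m3_templates(crops, labels, fs=fs)


def classify_cca_m3(window: np.ndarray, refs: ReferenceSet) -> int:
    if refs.kind != "trained":
        raise ValueError("CCA-M3 needs trained templates")
    return classify_cca(window, refs)
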