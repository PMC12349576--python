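"""Per-subject study protocol: data -> preprocessing -> classifiers -> metrics.

Bundles the full experimental loop for one virtual subject: simulate a
training session and a held-out test session sharing the subject's latent
profile, downsample to 250 Hz, split the training trials 9:1, harvest
filter-bank windows, train the residual network, build the CCA references
and trained templates, and score every method on identical onset-aligned
test windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import cca, preprocess, synth, training
from .model import ModelConfig, build_model

__all__ = ["SubjectData", "SubjectResult", "make_subject_data",
           "evaluate_subject", "run_study"]


@dataclass
class SubjectData:
    """One subject's preprocessed sessions at 250 Hz."""

    train_trials: np.ndarray
    train_labels: np.ndarray
    test_trials: np.ndarray
    test_labels: np.ndarray
    stimulus: synth.StimulusSet
    fs: float
    subject_id: str


@dataclass
class SubjectResult:
    accuracy_net: float
    accuracy_m3: float
    accuracy_cca: float
    report_net: training.MetricsReport
    history: dict


def make_subject_data(cfg: synth.SynthConfig, subject_id: str,
                      seed: int, stimulus: synth.StimulusSet | None = None,
                      fs_out: float = 250.0) -> SubjectData:
    """Simulate a training and a test session of the same subject and
    downsample both."""
    stimulus = stimulus or synth.StimulusSet()
    rng = np.random.default_rng(seed)
    profile = synth.draw_subject_profile(cfg, rng, stimulus)
    train_es = synth.generate_subject(stimulus, cfg, subject_id, rng, profile=profile)
    test_es = synth.generate_subject(stimulus, cfg, subject_id + "_test", rng,
                                     profile=profile)
    return SubjectData(
        train_trials=preprocess.downsample(train_es.data, cfg.fs, fs_out),
        train_labels=train_es.labels,
        test_trials=preprocess.downsample(test_es.data, cfg.fs, fs_out),
        test_labels=test_es.labels,
        stimulus=stimulus, fs=fs_out, subject_id=subject_id,
    )


def evaluate_subject(data: SubjectData,
                     ws: preprocess.WindowSpec | None = None,
                     train_cfg: training.TrainConfig | None = None,
                     test_windows_per_trial: int = 2,
                     methods: tuple = ("net", "cca-m3", "cca"),
                     seed: int = 0) -> SubjectResult:
    """Run the protocol on one subject; all methods share the same
    onset-aligned test windows."""
    ws = ws or preprocess.WindowSpec(d_samples=64, fs=data.fs)
    train_cfg = train_cfg or training.TrainConfig(seed=seed)
    bank = preprocess.design_filter_bank(preprocess.FilterBankSpec(), data.fs)
    ws_fixed = preprocess.WindowSpec(d_samples=ws.d_samples,
                                     onset_offset=ws.onset_offset,
                                     r_max=0.0, fs=data.fs,
                                     stim_duration=ws.stim_duration)
    rng = np.random.default_rng(seed)

    tr_idx, val_idx = training.split_trials(data.train_labels,
                                            train_cfg.split_ratio, seed=seed)
    test_raw, test_y = training.harvest_windows(
        data.test_trials, data.test_labels, ws_fixed,
        test_windows_per_trial, rng)

    acc = {"net": float("nan"), "cca-m3": float("nan"), "cca": float("nan")}
    report_net, history = None, {}

    if "net" in methods:
        Xtr, ytr = training.harvest_windows(
            data.train_trials[tr_idx], data.train_labels[tr_idx], ws,
            train_cfg.windows_per_trial, rng, bank=bank)
        Xva, yva = training.harvest_windows(
            data.train_trials[val_idx], data.train_labels[val_idx], ws,
            train_cfg.windows_per_trial, rng, bank=bank)
        net = build_model(ModelConfig(P=ws.d_samples), seed=seed)
        net, history = training.train(net, Xtr, ytr, Xva, yva, train_cfg)
        pred = net.predict(preprocess.apply_filter_bank(test_raw, bank))
        report_net = training.evaluate(pred, test_y)
        acc["net"] = report_net.accuracy
    if "cca-m3" in methods:
        refs = cca.build_m3_templates_from_trials(
            data.train_trials[tr_idx], data.train_labels[tr_idx], ws_fixed,
            fs=data.fs)
        pred = [cca.classify_cca_m3(w, refs) for w in test_raw]
        acc["cca-m3"] = training.evaluate(pred, test_y).accuracy
    if "cca" in methods:
        refs = cca.build_harmonic_references(data.stimulus, data.fs, ws.d_samples)
        pred = [cca.classify_cca(w, refs) for w in test_raw]
        acc["cca"] = training.evaluate(pred, test_y).accuracy

    return SubjectResult(accuracy_net=acc["net"], accuracy_m3=acc["cca-m3"],
                         accuracy_cca=acc["cca"], report_net=report_net,
                         history=history)


def run_study(n_subjects: int, cfg: synth.SynthConfig, seed: int = 0,
              ws: preprocess.WindowSpec | None = None,
              train_cfg: training.TrainConfig | None = None,
              methods: tuple = ("net", "cca-m3", "cca"),
              test_windows_per_trial: int = 2) -> dict:
    """Per-subject accuracies (percent) for each method over a cohort of
    virtual subjects."""
    out = {m: [] for m in methods}
    for s in range(n_subjects):
        subj_seed = (seed * 10007 + s) % (2**31 - 1)
        data = make_subject_data(cfg, f"S{s:02d}", subj_seed)
        tc = (dataclasses.replace(train_cfg, seed=subj_seed)
              if train_cfg is not None else None)
        res = evaluate_subject(data, ws=ws, train_cfg=tc,
                               methods=methods, seed=subj_seed,
                               test_windows_per_trial=test_windows_per_trial)
        for m in methods:
            out[m].append({"net": res.accuracy_net, "cca-m3": res.accuracy_m3,
                           "cca": res.accuracy_cca}[m])
    return {m: np.asarray(v) for m, v in out.items()}
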