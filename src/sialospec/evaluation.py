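"""Patient-level stratified cross-validation, metrics, and majority voting.

All spectra of a donor share a fold (no within-donor leakage); folds are
stratified by class via seeded round-robin assignment.  Metrics are pooled
(micro-averaged) over folds at both the spectrum and donor level; donor
calls come from majority voting over that donor's spectrum predictions.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import chemometrics, emsc
from .refinement import SelectionPolicy, two_phase_train
from .spectral_data import DonorRecord, SpectrumSet, crop_region
from .windowed_net import NetConfig, build_net, predict, train

METHODS = ("pca_lda", "nn", "nn_uncertainty")


@dataclass
class FoldAssignment:
    fold_of: dict[str, int]
    K: int


@dataclass
class MetricsReport:
    spectral_accuracy: float
    spectral_sensitivity: float          # disease-class TPR, spectrum level
    spectral_mean_sensitivity: float     # balanced accuracy form
    donor_accuracy: float
    donor_sensitivity: float
    donor_mean_sensitivity: float
    spectral_confusion: np.ndarray       # rows true (control, disease) x cols predicted
    donor_confusion: np.ndarray
    per_fold: list[dict]
    extras: dict[str, Any] = field(default_factory=dict)


def make_folds(donors: list[DonorRecord], K: int = 7, seed: int = 0) -> FoldAssignment:
    """Seeded, class-stratified donor-level fold assignment (round-robin)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    counts = {
        "control": sum(d.label == "control" for d in donors),
        "disease": sum(d.label == "disease" for d in donors),
    }
    min_class = min(counts.values())
    if min_class < K:
        warnings.warn(
            f"smallest class has {min_class} donors < K={K}; reducing K to {min_class}"
        )
        K = min_class
        if K < 2:
            raise ValueError("not enough donors per class for cross-validation")
    fold_of: dict[str, int] = {}
    # round-robin inside each class, carrying the fold counter across classes
    # so total fold sizes stay within one donor of each other
    counter = 0
    for label in ("control", "disease"):
        ids = sorted(d.donor_id for d in donors if d.label == label)
        rng.shuffle(ids)
        for donor_id in ids:
            fold_of[donor_id] = counter % K
            counter += 1
    return FoldAssignment(fold_of=fold_of, K=K)


def majority_vote(
    probabilities: dict[str, float], donor_of: dict[str, str], cut: float = 0.5
) -> dict[str, int]:
    """Donor call = strict majority of per-spectrum calls (prob > cut).

    Exact ties go to disease: a screening label favors sensitivity.  With an
    odd number of spectra per donor ties never occur.
    """
    votes: dict[str, list[int]] = {}
    for sid, prob in probabilities.items():
        votes.setdefault(donor_of[sid], []).append(int(prob > cut))
    out = {}
    for donor, vs in votes.items():
        if not vs:
            raise ValueError(f"donor {donor!r} has no evaluated spectra")
        n_disease = sum(vs)
        out[donor] = int(n_disease * 2 >= len(vs))  # tie -> disease
    return out


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def _metrics_from_confusion(cm: np.ndarray) -> tuple[float, float, float]:
    total = cm.sum()
    acc = float(np.trace(cm) / total) if total else float("nan")
    sens_d = float(cm[1, 1] / cm[1].sum()) if cm[1].sum() else float("nan")
    sens_c = float(cm[0, 0] / cm[0].sum()) if cm[0].sum() else float("nan")
    mean_sens = float(np.nanmean([sens_c, sens_d]))
    return acc, sens_d, mean_sens


def score(
    spectrum_probs: dict[str, float],
    data: SpectrumSet,
    fold_of_spectrum: dict[str, int] | None = None,
    cut: float = 0.5,
) -> MetricsReport:
    """Pooled spectrum- and donor-level metrics from per-spectrum probabilities."""
    label_of = {d.donor_id: 1 if d.label == "disease" else 0 for d in data.donors}
    ids = [s for s in data.spectrum_ids if s in spectrum_probs]
    if len(ids) != len(spectrum_probs):
        raise ValueError("predictions refer to unknown spectrum ids")
    y_true = np.array([label_of[data.donor_of[s]] for s in ids])
    y_pred = np.array([int(spectrum_probs[s] > cut) for s in ids])
    cm_s = _confusion(y_true, y_pred)

    donor_calls = majority_vote(spectrum_probs, data.donor_of, cut)
    donors = sorted(donor_calls)
    cm_d = _confusion(
        np.array([label_of[d] for d in donors]),
        np.array([donor_calls[d] for d in donors]),
    )

    per_fold = []
    if fold_of_spectrum is not None:
        for k in sorted(set(fold_of_spectrum.values())):
            fold_ids = [s for s in ids if fold_of_spectrum[s] == k]
            cm_f = _confusion(
                np.array([label_of[data.donor_of[s]] for s in fold_ids]),
                np.array([int(spectrum_probs[s] > cut) for s in fold_ids]),
            )
            acc, sens, mean_sens = _metrics_from_confusion(cm_f)
            per_fold.append(
                {"fold": k, "n_spectra": len(fold_ids), "accuracy": acc,
                 "sensitivity": sens, "mean_sensitivity": mean_sens}
            )

    acc_s, sens_s, msens_s = _metrics_from_confusion(cm_s)
    acc_d, sens_d, msens_d = _metrics_from_confusion(cm_d)
    return MetricsReport(
        spectral_accuracy=acc_s,
        spectral_sensitivity=sens_s,
        spectral_mean_sensitivity=msens_s,
        donor_accuracy=acc_d,
        donor_sensitivity=sens_d,
        donor_mean_sensitivity=msens_d,
        spectral_confusion=cm_s,
        donor_confusion=cm_d,
        per_fold=per_fold,
    )


def _digest(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()


@dataclass
class ExperimentConfig:
    method: str = "nn_uncertainty"
    K: int = 7
    emsc_degree: int = 6
    crop_low: float = 650.0
    crop_high: float = 3700.0
    variance_target: float = 0.99
    net: NetConfig = field(default_factory=NetConfig)
    T: int = 100
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    female_only: bool = False
    cut: float = 0.5


def run_experiment(
    cohort: SpectrumSet, config: ExperimentConfig, seed: int = 0
) -> MetricsReport:
    """Full cross-validated evaluation of one method on one cohort.

    Per fold: EMSC reference from the training fold only, correction and
    cropping of both partitions, model fit on training donors, prediction of
    every test-fold spectrum (no selection at test time), then pooled
    scoring.  ``extras`` carries per-fold model digests (for leakage audits),
    phase-1 probabilities and metrics for nn_uncertainty, and the pooled
    per-spectrum probabilities.
    """
    if config.method not in METHODS:
        raise ValueError(f"unknown method {config.method!r}; expected one of {METHODS}")
    if config.female_only:
        cohort = cohort.subset_donors(
            [d.donor_id for d in cohort.donors if d.sex == "female"]
        )
    folds = make_folds(cohort.donors, config.K, seed)
    fold_of_spectrum = {
        s: folds.fold_of[cohort.donor_of[s]] for s in cohort.spectrum_ids
    }

    probs: dict[str, float] = {}
    phase1_probs: dict[str, float] = {}
    digests: dict[int, str] = {}
    masks: dict[int, Any] = {}
    reports_by_fold: dict[int, list] = {}

    for k in range(folds.K):
        train_donors = [d.donor_id for d, f in
                        ((d, folds.fold_of[d.donor_id]) for d in cohort.donors) if f != k]
        test_donors = [d.donor_id for d in cohort.donors if folds.fold_of[d.donor_id] == k]
        train_raw = cohort.subset_donors(train_donors)
        test_raw = cohort.subset_donors(test_donors)

        reference = emsc.train_mean_reference(train_raw)
        model = emsc.build_model(reference, config.emsc_degree, cohort.grid)
        train_set, _ = emsc.correct_set(train_raw, model)
        test_set, _ = emsc.correct_set(test_raw, model)
        train_set = crop_region(train_set, config.crop_low, config.crop_high)
        test_set = crop_region(test_set, config.crop_low, config.crop_high)

        fold_seed = seed * 10007 + k
        if config.method == "pca_lda":
            pca = chemometrics.fit_pca(train_set, config.variance_target)
            lda = chemometrics.fit_lda(
                pca.transform(train_set.intensities), train_set.labels()
            )
            pred, _ = chemometrics.predict_lda(lda, pca, test_set)
            for sid, c in zip(test_set.spectrum_ids, pred):
                probs[sid] = float(c)
            digests[k] = _digest([reference, pca.mean, pca.components,
                                  lda.direction, [lda.threshold]])
        else:
            net_cfg = NetConfig(**{**config.net.__dict__, "seed": fold_seed})
            if config.method == "nn":
                net = train(build_net(net_cfg, len(train_set.grid)),
                            train_set.intensities, train_set.labels().astype(float),
                            net_cfg)
                out = predict(net, test_set.intensities)
                digests[k] = _digest([reference] + [net.params[p] for p in sorted(net.params)])
            else:
                result = two_phase_train(
                    train_set, net_cfg, T=config.T, policy=config.policy
                )
                net = result.phase2_net
                out = predict(net, test_set.intensities)
                out1 = predict(result.phase1_net, test_set.intensities)
                for sid, pr in zip(test_set.spectrum_ids, out1):
                    phase1_probs[sid] = float(pr)
                masks[k] = result.mask
                reports_by_fold[k] = result.reports
                digests[k] = _digest(
                    [reference]
                    + [result.phase1_net.params[p] for p in sorted(net.params)]
                    + [net.params[p] for p in sorted(net.params)]
                    + [np.frombuffer(
                        ",".join(sorted(result.mask.keep)).encode(), dtype=np.uint8
                      ).astype(float)]
                )
            for sid, pr in zip(test_set.spectrum_ids, out):
                probs[sid] = float(pr)

    report = score(probs, cohort, fold_of_spectrum, config.cut)
    report.extras["probabilities"] = probs
    report.extras["fold_of_spectrum"] = fold_of_spectrum
    report.extras["fold_model_digests"] = digests
    report.extras["K"] = folds.K
    if config.method == "nn_uncertainty":
        report.extras["phase1"] = score(phase1_probs, cohort, fold_of_spectrum, config.cut)
        report.extras["phase1_probabilities"] = phase1_probs
        report.extras["selection_masks"] = masks
        report.extras["training_reports"] = reports_by_fold
    return report
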