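import itertools

import numpy as np
import pytest
from tests_util import build_labeled_set

from sialospec import (
    CohortConfig,
    DonorRecord,
    ExperimentConfig,
    NetConfig,
    SelectionPolicy,
    generate_cohort,
    majority_vote,
    make_folds,
    run_experiment,
    score,
)


def donors(n_control, n_disease, sex="female"):
    return [DonorRecord(f"c{i}", "control", sex) for i in range(n_control)] + [
        DonorRecord(f"d{i}", "disease", sex) for i in range(n_disease)
    ]


class TestMakeFolds:
    def test_stratified_counts_for_21_donors(self):
        folds = make_folds(donors(11, 10), K=7, seed=0)
        assert folds.K == 7
        per_fold = {k: [] for k in range(7)}
        for d in donors(11, 10):
            per_fold[folds.fold_of[d.donor_id]].append(d.label)
        for labels in per_fold.values():
            assert len(labels) == 3
            assert 1 <= labels.count("control") <= 2
            assert 1 <= labels.count("disease") <= 2

    def test_every_donor_in_exactly_one_fold(self):
        ds = donors(23, 24)
        folds = make_folds(ds, K=7, seed=1)
        assert set(folds.fold_of) == {d.donor_id for d in ds}
        assert set(folds.fold_of.values()) == set(range(7))

    def test_leave_one_donor_out_boundary(self):
        ds = donors(4, 4)
        folds = make_folds(ds, K=4, seed=0)
        counts = np.bincount(list(folds.fold_of.values()))
        assert counts.tolist() == [2, 2, 2, 2]

    def test_k_reduced_with_warning_when_class_too_small(self):
        with pytest.warns(UserWarning, match="reducing K"):
            folds = make_folds(donors(3, 8), K=7, seed=0)
        assert folds.K == 3

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_folds(donors(5, 5), K=1, seed=0)


class TestMajorityVote:
    def test_agrees_with_exhaustive_enumeration_for_five_spectra(self):
        for pattern in itertools.product([0, 1], repeat=5):
            probs = {f"s{i}": 0.9 if v else 0.1 for i, v in enumerate(pattern)}
            vote = majority_vote(probs, {f"s{i}": "d" for i in range(5)})
            assert vote["d"] == int(sum(pattern) >= 3)

    def test_all_control_spectra_give_control_donor(self):
        vote = majority_vote({"a": 0.1, "b": 0.2}, {"a": "d", "b": "d"})
        assert vote["d"] == 0

    def test_even_tie_goes_to_disease(self):
        probs = {"a": 0.9, "b": 0.9, "c": 0.1, "d": 0.1}
        vote = majority_vote(probs, {s: "x" for s in probs})
        assert vote["x"] == 1

    def test_probability_exactly_at_cut_votes_control(self):
        vote = majority_vote({"a": 0.5}, {"a": "d"}, cut=0.5)
        assert vote["d"] == 0


class TestScore:
    @pytest.fixture
    def eight_donor_set(self):
        from sialospec import WavenumberGrid

        labels = [0] * 4 + [1] * 4
        grid = WavenumberGrid(650.0 + 2.0 * np.arange(5))
        return build_labeled_set(np.zeros((8, 5)), labels, grid)

    def test_perfect_predictions_score_one(self, eight_donor_set):
        data = eight_donor_set
        probs = {s: float(data.labels()[i]) for i, s in enumerate(data.spectrum_ids)}
        probs = {s: 0.9 if p == 1.0 else 0.1 for s, p in probs.items()}
        report = score(probs, data)
        assert report.spectral_accuracy == 1.0
        assert report.donor_accuracy == 1.0
        assert report.donor_mean_sensitivity == 1.0

    def test_mean_sensitivity_arithmetic(self, eight_donor_set):
        data = eight_donor_set
        # disease: 3 of 4 donors correct; control: 2 of 4 correct
        probs = {}
        for i, s in enumerate(data.spectrum_ids):
            true = data.labels()[i]
            donor_idx = int(data.donor_of[s][1:])
            if true == 1:
                probs[s] = 0.9 if donor_idx < 7 else 0.1
            else:
                probs[s] = 0.1 if donor_idx < 2 else 0.9
        report = score(probs, data)
        assert report.donor_sensitivity == pytest.approx(0.75)
        assert report.donor_mean_sensitivity == pytest.approx((0.75 + 0.50) / 2)

    def test_pooled_confusion_equals_sum_of_folds(self, eight_donor_set):
        data = eight_donor_set
        rng = np.random.default_rng(0)
        probs = {s: float(p) for s, p in zip(data.spectrum_ids, rng.random(8))}
        fold_of = {s: i % 2 for i, s in enumerate(data.spectrum_ids)}
        report = score(probs, data, fold_of)
        per_fold_total = sum(f["n_spectra"] for f in report.per_fold)
        assert per_fold_total == report.spectral_confusion.sum()


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = CohortConfig(n_control_donors=4, n_disease_donors=4, seed=31)
    data, _ = generate_cohort(cfg)
    return data


FAST_NET = NetConfig(epochs=10, block_units=4, head_units=8)


class TestRunExperiment:
    def test_deterministic_repeat(self, tiny_cohort):
        cfg = ExperimentConfig(method="pca_lda", K=4)
        a = run_experiment(tiny_cohort, cfg, seed=5)
        b = run_experiment(tiny_cohort, cfg, seed=5)
        assert a.extras["probabilities"] == b.extras["probabilities"]
        assert a.spectral_accuracy == b.spectral_accuracy

    def test_keep_all_refinement_has_identical_phase1_to_plain_nn(self, tiny_cohort):
        policy = SelectionPolicy(keep_fraction=1.0)
        cfg_u = ExperimentConfig(method="nn_uncertainty", K=4, net=FAST_NET,
                                 T=5, policy=policy)
        cfg_n = ExperimentConfig(method="nn", K=4, net=FAST_NET)
        ru = run_experiment(tiny_cohort, cfg_u, seed=2)
        rn = run_experiment(tiny_cohort, cfg_n, seed=2)
        # phase-1 of the two-phase run IS the single-phase model at equal seeds
        assert ru.extras["phase1_probabilities"] == rn.extras["probabilities"]
        for mask in ru.extras["selection_masks"].values():
            assert mask.dropped == {}

    def test_every_test_spectrum_predicted_once(self, tiny_cohort):
        cfg = ExperimentConfig(method="pca_lda", K=4)
        r = run_experiment(tiny_cohort, cfg, seed=1)
        assert set(r.extras["probabilities"]) == set(tiny_cohort.spectrum_ids)

    def test_donor_spectra_share_folds(self, tiny_cohort):
        cfg = ExperimentConfig(method="pca_lda", K=4)
        r = run_experiment(tiny_cohort, cfg, seed=1)
        fold_of = r.extras["fold_of_spectrum"]
        for d in tiny_cohort.donors:
            folds = {fold_of[s] for s in tiny_cohort.spectra_of(d.donor_id)}
            assert len(folds) == 1

    def test_female_only_filter_drops_male_donors(self):
        cfg = CohortConfig(n_control_donors=4, n_disease_donors=4, seed=8)
        data, _ = generate_cohort(cfg)
        # relabel one donor male
        data.donors[0] = DonorRecord(data.donors[0].donor_id, "control", "male")
        ec = ExperimentConfig(method="pca_lda", K=3, female_only=True)
        r = run_experiment(data, ec, seed=0)
        male_spectra = set(data.spectra_of(data.donors[0].donor_id))
        assert male_spectra.isdisjoint(r.extras["probabilities"])

    def test_unknown_method_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            run_experiment(tiny_cohort, ExperimentConfig(method="svm"), seed=0)


class TestLeakageFreedom:
    def test_perturbing_test_fold_leaves_fitted_models_bit_identical(self, tiny_cohort):
        """Taint test: fold-k models must not depend on fold-k spectra."""
        cfg = ExperimentConfig(
            method="nn_uncertainty", K=3, net=FAST_NET, T=5,
        )
        base = run_experiment(tiny_cohort, cfg, seed=9)
        fold_of = base.extras["fold_of_spectrum"]
        for k in range(base.extras["K"]):
            perturbed = tiny_cohort.with_intensities(tiny_cohort.intensities.copy())
            idx = [i for i, s in enumerate(perturbed.spectrum_ids) if fold_of[s] == k]
            rng = np.random.default_rng(k)
            perturbed.intensities[idx] += rng.normal(0, 5.0, size=(len(idx),
                                                     perturbed.intensities.shape[1]))
            rerun = run_experiment(perturbed, cfg, seed=9)
            assert rerun.extras["fold_model_digests"][k] == base.extras["fold_model_digests"][k]
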