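"""Speaker-grouped LDA decoding and Matthews φ scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from sonosym.decoding import (
    ConfusionCounts,
    DecodingTask,
    counts_from_confusion,
    cross_modality_decode,
    fit_lda,
    phi_binary,
    phi_from_confusion,
    phi_macro,
    speaker_grouped_folds,
    within_modality_decode,
)
from sonosym.synthetic import SyntheticConfig, generate_corpus


class TestFolds:
    def test_19_speakers_into_10_folds_gives_nine_pairs_and_a_singleton(self):
        speakers = [f"s{i}" for i in range(19)]
        folds = speaker_grouped_folds(speakers, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [1] + [2] * 9

    def test_every_speaker_in_exactly_one_fold(self):
        speakers = [f"s{i}" for i in range(19)]
        folds = speaker_grouped_folds(speakers, 10, seed=3)
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(speakers)

    def test_k_equal_speakers_is_leave_one_speaker_out(self):
        folds = speaker_grouped_folds(["a", "b", "c"], 3, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_same_seed_same_folds(self):
        speakers = [f"s{i}" for i in range(19)]
        assert speaker_grouped_folds(speakers, 10, 7) == speaker_grouped_folds(
            speakers, 10, 7
        )

    def test_more_folds_than_speakers_rejected(self):
        with pytest.raises(ValueError):
            speaker_grouped_folds(["a", "b"], 3, seed=0)


class TestPhi:
    def test_perfect_classification_is_one(self):
        assert phi_binary(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0

    def test_complete_disagreement_is_minus_one(self):
        assert phi_binary(ConfusionCounts(tp=0, fp=5, tn=0, fn=5)) == -1.0

    def test_hand_computed_example(self):
        # (6·3 − 2·1) / sqrt((6+2)(6+1)(3+2)(3+1))
        c = ConfusionCounts(tp=6, fp=2, fn=1, tn=3)
        assert phi_binary(c) == pytest.approx(16 / math.sqrt(8 * 7 * 5 * 4))

    def test_degenerate_margin_returns_zero(self):
        assert phi_binary(ConfusionCounts(tp=0, fp=0, tn=10, fn=0)) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    def test_phi_matches_sklearn_on_reconstructed_predictions(self, tp, fp, tn, fn):
        """Independent oracle: rebuild label vectors and ask sklearn."""
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        if c.n == 0:
            return
        y_true = [1] * (tp + fn) + [0] * (fp + tn)
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        expected = matthews_corrcoef(y_true, y_pred)
        assert phi_binary(c) == pytest.approx(expected, abs=1e-12)

    def test_macro_of_perfect_classes_is_one(self):
        perfect = ConfusionCounts(tp=3, fp=0, tn=6, fn=0)
        assert phi_macro([perfect, perfect, perfect]) == 1.0

    def test_macro_phi_arithmetic_mean(self):
        # classes scoring 1, 0 and -1 average to 0
        cs = [
            ConfusionCounts(tp=5, fp=0, tn=5, fn=0),
            ConfusionCounts(tp=0, fp=0, tn=10, fn=0),
            ConfusionCounts(tp=0, fp=5, tn=0, fn=5),
        ]
        assert phi_macro(cs) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=4, max_size=4))
    def test_two_class_macro_equals_binary_phi(self, cells):
        m = np.array(cells).reshape(2, 2)
        if m.sum() == 0:
            return
        per_class = counts_from_confusion(m)
        binary = phi_binary(per_class[0])
        assert phi_binary(per_class[1]) == pytest.approx(binary, abs=1e-12)
        assert phi_from_confusion(m) == pytest.approx(binary, abs=1e-12)

    def test_random_multiclass_predictions_score_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 10_000)
        pred = rng.integers(0, 3, 10_000)
        m = np.zeros((3, 3), int)
        for t, p in zip(y, pred):
            m[t, p] += 1
        assert abs(phi_from_confusion(m)) < 0.05


class TestFitLda:
    def test_separated_clouds_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        model = fit_lda(X, y)
        assert (model.predict(X) == y).all()

    def test_shuffled_labels_give_chance_test_accuracy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 5))
        y = rng.integers(0, 2, 400)
        accs = []
        for _ in range(100):
            perm = rng.permutation(400)
            model = fit_lda(X[perm[:300]], y[perm[:300]])
            accs.append((model.predict(X[perm[300:]]) == y[perm[300:]]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_duplicated_feature_column_survives_via_shrinkage(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(40, 2))
        X = np.hstack([base, base[:, :1]])  # singular covariance
        y = (base[:, 0] > 0).astype(int)
        model = fit_lda(X, y)
        assert (model.predict(X) == y).mean() > 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((4, 2)), [1, 1, 1, 1])


@pytest.fixture(scope="module")
def small_separable():
    cfg = SyntheticConfig(beta_manner=1.0, beta_vowel=1.0, sigma_speaker=0.0, seed=23)
    return generate_corpus(cfg)[0]


class TestWithinModality:
    def test_separable_corpus_decodes_movement_near_perfectly(self, small_separable):
        task = DecodingTask(target="movement", modality_train="AV", modality_test="AV",
                            subset="consonant", reps=10, seed=1)
        res = within_modality_decode(small_separable, task)
        assert res.phi_median >= 0.95

    def test_null_corpus_phi_within_permutation_band(self, table, null_corpus):
        """φ at the null falls inside the label-permutation 95% band."""
        records, _ = null_corpus
        task = DecodingTask(target="movement", modality_train="A", modality_test="A",
                            subset="consonant", reps=10, seed=1)
        res = within_modality_decode(records, task)
        # permutation oracle: shuffle movement labels within the A block
        rng = np.random.default_rng(5)
        import dataclasses

        a_records = [r for r in records if r.modality == "A"]
        phis = []
        for _ in range(60):
            moves = [r.movement for r in a_records]
            rng.shuffle(moves)
            shuffled = [
                dataclasses.replace(r, movement=m) for r, m in zip(a_records, moves)
            ]
            r_null = within_modality_decode(
                shuffled, dataclasses.replace(task, reps=1)
            )
            phis.append(r_null.phi_median)
        lo, hi = np.percentile(phis, [2.5, 97.5])
        assert lo <= res.phi_median <= hi

    def test_single_repetition_equals_plain_grouped_cv(self, small_separable):
        task = DecodingTask(target="movement", modality_train="AV", modality_test="AV",
                            subset="all", reps=1, seed=9)
        res = within_modality_decode(small_separable, task)
        assert res.phi_iqr == 0.0
        assert np.allclose(res.confusion_iqr.values, 0.0)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_single_repetition_confusion_rows_sum_to_one(self, default_corpus, seed):
        """Each repetition's matrix holds proportions over true-class items."""
        records, _ = default_corpus
        task = DecodingTask(target="movement", modality_train="V", modality_test="V",
                            subset="all", reps=1, seed=seed)
        res = within_modality_decode(records, task)
        assert np.allclose(res.confusion_median.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic_given_seed(self, default_corpus):
        records, _ = default_corpus
        task = DecodingTask(target="movement", modality_train="A", modality_test="A",
                            subset="all", reps=3, seed=4)
        r1 = within_modality_decode(records, task)
        r2 = within_modality_decode(records, task)
        assert r1.phi_per_rep.tolist() == r2.phi_per_rep.tolist()
        assert r1.confusion_median.equals(r2.confusion_median)

    def test_mismatched_modalities_rejected(self, default_corpus):
        records, _ = default_corpus
        task = DecodingTask(modality_train="A", modality_test="V")
        with pytest.raises(ValueError):
            within_modality_decode(records, task)

    def test_aggregate_per_speaker_mode_runs(self, small_separable):
        task = DecodingTask(target="movement", modality_train="AV", modality_test="AV",
                            subset="all", reps=3, seed=1, aggregate_per_speaker=True,
                            k=5)
        res = within_modality_decode(small_separable, task)
        assert res.phi_median > 0.9


class TestCrossModality:
    def test_shared_code_transfers_but_permuted_video_code_does_not(self):
        """Movement code shared by A and AV transfers; an unrelated V code fails."""
        cfg = SyntheticConfig(v_code_permuted=True, seed=7)
        records, _ = generate_corpus(cfg)
        common = dict(target="movement", subset="all", reps=5, seed=2)
        hi = cross_modality_decode(
            records, DecodingTask(modality_train="A", modality_test="AV", **common)
        )
        lo = cross_modality_decode(
            records, DecodingTask(modality_train="A", modality_test="V", **common)
        )
        assert hi.phi_median > 0.5
        assert lo.phi_median < 0.1

    def test_deterministic_given_seed(self, default_corpus):
        records, _ = default_corpus
        task = DecodingTask(target="movement", modality_train="A", modality_test="AV",
                            subset="all", reps=3, seed=8)
        r1 = cross_modality_decode(records, task)
        r2 = cross_modality_decode(records, task)
        assert r1.phi_per_rep.tolist() == r2.phi_per_rep.tolist()

    def test_self_transfer_consistent_with_within_modality(self, small_separable):
        within = within_modality_decode(
            small_separable,
            DecodingTask(modality_train="AV", modality_test="AV",
                         subset="consonant", reps=5, seed=3),
        )
        selfx = cross_modality_decode(
            small_separable,
            DecodingTask(modality_train="AV", modality_test="AV",
                         subset="consonant", reps=5, seed=3),
        )
        assert abs(within.phi_median - selfx.phi_median) < 0.1

    def test_missing_class_in_test_modality_rejected(self, default_corpus):
        records, _ = default_corpus
        trimmed = [
            r for r in records if not (r.modality == "V" and r.movement == "ring")
        ]
        task = DecodingTask(target="movement", modality_train="A", modality_test="V",
                            subset="all", reps=2, seed=1)
        with pytest.raises(ValueError, match="ring"):
            cross_modality_decode(trimmed, task)
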