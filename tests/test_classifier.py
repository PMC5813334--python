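"""AUC, feature selection, SVM training and scoring contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from episig.io_formats import BetaMatrix
from episig import classifier as clf
from episig import synthetic_data as synth


class TestProbeAuc:
    def test_worked_example(self):
        values = [2.5, 3.5, 1.0, 2.0, 3.0]
        labels = [True, True, False, False, False]
        assert clf.probe_auc(values, labels) == pytest.approx(5.0 / 6.0)

    def test_perfect_separation(self):
        assert clf.probe_auc([5, 6, 7, 1, 2], [1, 1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert clf.probe_auc([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            clf.probe_auc([1, 2, 3], [True, True, True])

    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=2, max_size=15),
        st.data(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_pairwise_count_oracle(self, values, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(values), max_size=len(values))
        )
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = True, False
        cases = [v for v, l in zip(values, labels) if l]
        ctrls = [v for v, l in zip(values, labels) if not l]
        wins = sum(c > d for c, d in itertools.product(cases, ctrls))
        ties = sum(c == d for c, d in itertools.product(cases, ctrls))
        expected = (wins + 0.5 * ties) / (len(cases) * len(ctrls))
        assert clf.probe_auc(values, labels) == pytest.approx(expected)


def _sheet(groups):
    return pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(len(groups))],
            "labeled_sex": "M",
            "group": groups,
            "age": 1,
            "role": "training",
        }
    )


class TestSelectFeatures:
    def _beta(self, rows):
        values = pd.DataFrame(
            rows, index=[f"cg{i}" for i in range(len(rows))],
            columns=[f"s{j}" for j in range(len(rows[0]))],
        )
        return BetaMatrix(values)

    def test_perfectly_correlated_pair_keeps_one(self):
        pat, ctl = [0.2, 0.25], [0.7, 0.75, 0.8]
        beta = self._beta([pat + ctl, pat + ctl])
        sheet = _sheet(["patient"] * 2 + ["control"] * 3)
        sel = clf.select_features(beta, sheet, ["cg0", "cg1"])
        assert sel.retained_after_auc == ["cg0", "cg1"]
        assert len(sel.retained_after_pruning) == 1

    def test_moderate_correlation_keeps_both(self):
        # two separating probes engineered to |r| well below sqrt(0.8)
        beta = self._beta(
            [
                [0.20, 0.25, 0.22, 0.70, 0.75, 0.80, 0.72, 0.78],
                [0.30, 0.28, 0.33, 0.80, 0.72, 0.71, 0.79, 0.74],
            ]
        )
        sheet = _sheet(["patient"] * 3 + ["control"] * 5)
        corr = beta.values.T.corr().iloc[0, 1]
        sel = clf.select_features(beta, sheet, ["cg0", "cg1"], r2_cut=corr**2 + 0.05)
        assert sel.retained_after_pruning == ["cg0", "cg1"]

    def test_no_separating_probe_is_an_error(self):
        beta = self._beta([[0.5, 0.5, 0.5, 0.5, 0.5]])
        sheet = _sheet(["patient"] * 2 + ["control"] * 3)
        with pytest.raises(ValueError, match="separates"):
            clf.select_features(beta, sheet, ["cg0"])

    @staticmethod
    def _greedy_oracle(corr, threshold):
        """Literal restatement of the pruning rule, pair by pair."""
        keep = list(corr.index)
        while True:
            best = None
            for a, b in itertools.combinations(keep, 2):
                r = abs(corr.loc[a, b])
                if r > threshold and (best is None or r > best[0]):
                    best = (r, a, b)
            if best is None:
                return keep
            _, a, b = best
            mean = {
                p: np.mean([abs(corr.loc[p, q]) for q in keep if q != p])
                for p in (a, b)
            }
            if mean[a] > mean[b]:
                keep.remove(a)
            elif mean[b] > mean[a]:
                keep.remove(b)
            else:
                keep.remove(max(a, b))

    def test_blocked_fixture_matches_greedy_oracle(self, signature_cohort):
        _, _, beta, sheet, truth = signature_cohort
        probes = truth.signature_probes[:10]
        sel = clf.select_features(beta, sheet, probes)
        by = sheet.set_index("sample_id")["group"]
        samples = [s for s in beta.sample_ids if by[s] in ("patient", "control")]
        corr = beta.values.loc[sel.retained_after_auc, samples].T.corr()
        expected = self._greedy_oracle(corr, sel.pruning_threshold)
        assert sorted(sel.retained_after_pruning) == sorted(expected)

    def test_sample_order_invariance(self, signature_cohort):
        _, _, beta, sheet, truth = signature_cohort
        probes = truth.signature_probes[:20]
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(beta.sample_ids))
        beta2 = BetaMatrix(beta.values.iloc[:, perm])
        a = clf.select_features(beta, sheet, probes)
        b = clf.select_features(beta2, sheet, probes)
        assert a.retained_after_pruning == b.retained_after_pruning


@pytest.fixture(scope="module")
def trained(signature_cohort):
    _, _, beta, sheet, truth = signature_cohort
    sel = clf.select_features(beta, sheet, truth.signature_probes)
    model = clf.train_svm(beta, sheet, sel.retained_after_pruning, seed=3)
    return beta, sheet, sel, model


class TestTrainSvm:
    def test_separating_cohort_reaches_full_cv_accuracy(self, trained):
        _, _, _, model = trained
        assert model.cv_accuracy == 100.0

    def test_training_samples_all_predicted_correctly(self, trained):
        beta, sheet, _, model = trained
        scores = clf.predict_scores(model, beta)
        by = sheet.set_index("sample_id")["group"]
        assert all(scores.loc[s, "predicted_class"] == by[s] for s in scores.index)

    def test_deterministic_under_fixed_seed(self, signature_cohort, trained):
        _, _, beta, sheet, truth = signature_cohort
        _, _, sel, model = trained
        again = clf.train_svm(beta, sheet, sel.retained_after_pruning, seed=3)
        assert (again.C, again.gamma, again.cv_accuracy) == (
            model.C, model.gamma, model.cv_accuracy,
        )
        pd.testing.assert_frame_equal(
            clf.predict_scores(again, beta), clf.predict_scores(model, beta)
        )

    def test_permuted_labels_fall_to_majority_accuracy(self, signature_cohort, trained):
        _, _, beta, sheet, _ = signature_cohort
        _, _, sel, _ = trained
        rng = np.random.default_rng(0)
        shuffled = sheet.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        model = clf.train_svm(beta, shuffled, sel.retained_after_pruning, seed=3)
        majority = 100.0 * (sheet["group"] == "control").mean()
        assert model.cv_accuracy == pytest.approx(majority, abs=12.0)

    def test_noise_degrades_accuracy_on_average(self):
        def mean_cv(noise_sd, seeds=(30, 31, 32)):
            accs = []
            for seed in seeds:
                effects = synth.signature_probe_effects(15, 5, 300, (0.20, 0.35), seed)
                cfg = synth.SimulationConfig(
                    n_background_probes=300, planted_probe_effects=effects,
                    noise_sd=noise_sd, seed=seed,
                )
                manifest = synth.generate_manifest(cfg)
                beta, sheet, truth = synth.simulate_cohort(cfg, manifest)
                model = clf.train_svm(beta, sheet, truth.signature_probes, seed=seed)
                accs.append(model.cv_accuracy)
            return np.mean(accs)

        assert mean_cv(0.15) >= mean_cv(1.2)

    def test_missing_class_rejected(self, signature_cohort, trained):
        _, _, beta, sheet, _ = signature_cohort
        _, _, sel, _ = trained
        two_class = sheet[sheet["group"] != "carrier"]
        with pytest.raises(ValueError, match="three classes"):
            clf.train_svm(beta, two_class, sel.retained_after_pruning, seed=3)


class TestPredictScores:
    def test_scores_are_probabilities(self, trained):
        beta, _, _, model = trained
        scores = clf.predict_scores(model, beta)
        mat = scores[["score_patient", "score_carrier", "score_control"]].to_numpy()
        assert (mat >= 0).all() and (mat <= 1).all()
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-6)

    def test_flat_sample_flagged_when_uncertain(self, trained):
        beta, _, _, model = trained
        flat = BetaMatrix(
            pd.DataFrame({"flat": 0.5}, index=beta.probe_ids, dtype=float)
        )
        scores = clf.predict_scores(model, flat)
        row = scores.loc["flat"]
        total = row[["score_patient", "score_carrier", "score_control"]].sum()
        assert total == pytest.approx(1.0, abs=1e-6)
        top = row[["score_patient", "score_carrier", "score_control"]].max()
        assert bool(row["ambiguous"]) == (top < clf.SCORE_CUTOFF)

    def test_missing_probes_listed(self, trained):
        beta, _, _, model = trained
        reduced = beta.subset_probes([p for p in beta.probe_ids if p != model.probe_ids[0]])
        with pytest.raises(ValueError, match=model.probe_ids[0]):
            clf.predict_scores(model, reduced)


class TestSpecificity:
    def test_external_cohort_predicted_control(self, signature_cohort, trained):
        cfg, manifest, _, _, _ = signature_cohort
        _, _, _, model = trained
        ext = synth.simulate_external_cohorts(
            cfg, manifest, model.probe_ids, n_controls=60, n_other=40, n_other_probes=120
        )
        result = clf.evaluate_specificity(model, ext.beta, ext.sheet)
        assert result.specificity == 100.0
        assert result.per_group["control"].sum() == 100

    def test_empty_cohort_rejected(self, trained):
        beta, sheet, _, model = trained
        empty = beta.subset_samples([])
        with pytest.raises(ValueError, match="empty"):
            clf.evaluate_specificity(model, empty, sheet)
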