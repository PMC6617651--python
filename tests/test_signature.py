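import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

import methsig as ms
from methsig.signature import ScoringError, _pearson


def _antipodal_model():
    pid = pd.Index(["cg1", "cg2", "cg3"], name="probe_id")
    case = pd.Series([0.8, 0.2, 0.6], index=pid)
    ctrl = pd.Series([0.2, 0.8, 0.4], index=pid)
    rng = lambda s: pd.DataFrame({"min": s - 0.05, "max": s + 0.05})
    return ms.SignatureModel(pid, case, ctrl, rng(case), rng(ctrl))


class TestScoring:
    def test_case_profile_scores_two(self):
        model = _antipodal_model()
        res = ms.score_sample(model.case_profile.rename("q"), model)
        assert res.r_case == pytest.approx(1.0)
        assert res.r_control == pytest.approx(-1.0)
        assert res.score == pytest.approx(2.0)
        assert res.label == "pathogenic"

    def test_control_profile_scores_minus_two(self):
        model = _antipodal_model()
        res = ms.score_sample(model.control_profile.rename("q"), model)
        assert res.score == pytest.approx(-2.0)
        assert res.label == "benign"

    def test_swapping_profiles_negates_every_score(self, small_run, small_dataset):
        model = small_run.model
        swapped = ms.SignatureModel(
            model.probe_ids, model.control_profile, model.case_profile,
            model.control_range, model.case_range,
        )
        Y = small_dataset.beta.beta.loc[model.probe_ids]
        a = model.score_many(Y)["score"]
        b = swapped.score_many(Y)["score"]
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=5.0),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    def test_affine_invariance_of_score(self, seed, scale, shift):
        """Pearson r is scale/shift invariant, so affine transforms of the
        query vector leave the score unchanged."""
        model = _antipodal_model()
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.uniform(0, 1, 3), index=model.probe_ids, name="q")
        base = ms.score_sample(x, model).score
        trans = ms.score_sample(scale * x + shift, model).score
        assert trans == pytest.approx(base, abs=1e-9)

    def test_single_probe_signature_refuses(self):
        pid = pd.Index(["cg1"], name="probe_id")
        s = pd.Series([0.5], index=pid)
        r = pd.DataFrame({"min": [0.4], "max": [0.6]}, index=pid)
        model = ms.SignatureModel(pid, s, s, r, r)
        with pytest.raises(ScoringError, match=">= 3"):
            ms.score_sample(pd.Series([0.5], index=pid, name="q"), model)

    def test_zero_variance_sample_refuses(self):
        model = _antipodal_model()
        flat = pd.Series(0.5, index=model.probe_ids, name="q")
        with pytest.raises(ScoringError, match="zero-variance"):
            ms.score_sample(flat, model)

    def test_missing_probes_pairwise_complete_up_to_ten_percent(self, small_run, small_dataset):
        model = small_run.model
        x = small_dataset.beta.beta.loc[model.probe_ids].iloc[:, 0].copy()
        full = ms.score_sample(x, model).score
        x_missing = x.copy()
        x_missing.iloc[: int(0.05 * len(x))] = np.nan
        partial = ms.score_sample(x_missing, model).score
        assert abs(partial - full) < 0.05
        x_bad = x.copy()
        x_bad.iloc[: int(0.2 * len(x))] = np.nan
        with pytest.raises(ScoringError, match="<90%"):
            ms.score_sample(x_bad, model)

    def test_replicate_stability_under_small_noise(self, small_run, small_dataset):
        """Logit-scale noise of sd 0.01 moves scores by well under 0.01,
        the replicate-concordance the scoring is expected to show."""
        model = small_run.model
        rng = np.random.default_rng(0)
        for col in small_dataset.beta.sample_ids[:5]:
            x = small_dataset.beta.beta.loc[model.probe_ids, col]
            noisy = pd.Series(
                expit(logit(np.clip(x, 1e-6, 1 - 1e-6)) + rng.normal(0, 0.01, len(x))),
                index=x.index, name=col,
            )
            assert abs(model.score(noisy).score - model.score(x).score) < 0.01


class TestReferenceProfiles:
    def test_median_and_range_match_sort_oracle(self, small_run, small_dataset):
        model = small_run.model
        beta, _, sheet, _ = small_dataset
        case = beta.beta.loc[model.probe_ids, sheet.ids_in_group("case")].to_numpy()
        srt = np.sort(case, axis=1)
        n = case.shape[1]
        median = (srt[:, (n - 1) // 2] + srt[:, n // 2]) / 2
        np.testing.assert_allclose(model.case_profile.to_numpy(), median, atol=1e-12)
        np.testing.assert_allclose(model.case_range["min"].to_numpy(), srt[:, 0], atol=1e-15)
        np.testing.assert_allclose(model.case_range["max"].to_numpy(), srt[:, -1], atol=1e-15)

    def test_small_group_example(self):
        pid = pd.Index(["cgA", "cgB", "cgC"], name="probe_id")
        beta = pd.DataFrame(
            {"c1": [0.2, 0.3, 0.1], "c2": [0.4, 0.5, 0.2], "c3": [0.6, 0.4, 0.3],
             "k1": [0.1, 0.1, 0.1], "k2": [0.2, 0.2, 0.2]},
            index=pid,
        )
        model = ms.build_reference_profiles(beta, pid, ["c1", "c2", "c3"], ["k1", "k2"])
        assert model.case_profile["cgA"] == pytest.approx(0.4)
        assert model.case_range.loc["cgA"].tolist() == [0.2, 0.6]

    def test_json_round_trip(self, small_run, tmp_path):
        model = small_run.model
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ms.SignatureModel.from_json(path)
        np.testing.assert_allclose(back.case_profile, model.case_profile)
        np.testing.assert_allclose(back.control_range["max"], model.control_range["max"])
        assert list(back.probe_ids) == list(model.probe_ids)


class TestEvaluate:
    def _scores(self, labels):
        return pd.DataFrame(
            {"label": labels}, index=[f"s{i}" for i in range(len(labels))]
        )

    def test_all_correct(self):
        pred = self._scores(["pathogenic"] * 8 + ["benign"] * 94)
        truth = pd.Series(["pathogenic"] * 8 + ["benign"] * 94, index=pred.index)
        out = ms.evaluate(pred, truth)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_one_control_misclassified(self):
        pred = self._scores(["pathogenic"] * 9 + ["benign"] * 93)
        truth = pd.Series(["pathogenic"] * 8 + ["benign"] * 94, index=pred.index)
        out = ms.evaluate(pred, truth)
        assert out["specificity"] == pytest.approx(93 / 94)

    def test_empty_class_flagged(self):
        pred = self._scores(["benign", "benign"])
        truth = pd.Series(["benign", "benign"], index=pred.index)
        out = ms.evaluate(pred, truth)
        assert np.isnan(out["sensitivity"]) and out["undefined_metric"]


class TestClustering:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.3, 0.01, (10, 6))
        b = rng.normal(0.6, 0.01, (10, 6))
        Y = pd.DataFrame(np.column_stack([a, b]),
                         index=[f"p{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(12)])
        _, labels = ms.cluster_samples(Y)
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicate_samples_merge_at_zero(self):
        Y = pd.DataFrame({"s1": [0.1, 0.5], "s2": [0.1, 0.5], "s3": [0.9, 0.9]})
        Z, _ = ms.cluster_samples(Y)
        assert Z[0, 2] == 0.0

    def test_signature_probes_separate_cases_from_controls(self, small_run, small_dataset):
        beta, _, sheet, _ = small_dataset
        _, labels = ms.cluster_samples(beta, small_run.signature_probes)
        groups = sheet.table["group"]
        case_labels = set(labels[groups == "case"])
        ctrl_labels = set(labels[groups == "control"])
        assert len(case_labels) == 1 and len(ctrl_labels) == 1
        assert case_labels != ctrl_labels
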