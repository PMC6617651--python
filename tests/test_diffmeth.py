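import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methsig as ms
from methsig.diffmeth import DesignError, ModerationError


def _design(n_case=4, n_ctrl=8, seed=0):
    rng = np.random.default_rng(seed)
    n = n_case + n_ctrl
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "group": np.r_[np.ones(n_case), np.zeros(n_ctrl)],
            "age": rng.uniform(3, 40, n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestProbeOLS:
    def test_exact_linear_probe_recovered(self):
        X = _design()
        y = 0.5 + 0.2 * X["group"]
        Y = pd.DataFrame([y.to_numpy()] * 12, index=[f"p{i}" for i in range(12)], columns=X.index)
        out = ms.fit_probe_models(Y, X)
        np.testing.assert_allclose(out["b"], 0.2, atol=1e-12)
        np.testing.assert_allclose(out["s2"], 0.0, atol=1e-20)
        assert (out["d"] == len(X) - 3).all()

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = _design(seed=3)
        Y = pd.DataFrame(rng.uniform(0.2, 0.8, (15, len(X))),
                         index=[f"p{i}" for i in range(15)], columns=X.index)
        base = ms.fit_probe_models(Y, X)
        perm = rng.permutation(len(X))
        out = ms.fit_probe_models(Y.iloc[:, perm], X.iloc[perm])
        pd.testing.assert_frame_equal(base, out)

    def test_group_coefficient_is_unbiased(self):
        """Monte-Carlo over 1000 probes: mean(b_hat) within 0.01 of the
        simulated coefficient 0.1 (OLS unbiasedness)."""
        rng = np.random.default_rng(4)
        X = _design(8, 23, seed=4)
        signal = 0.4 + 0.1 * X["group"].to_numpy()
        Y = pd.DataFrame(signal + rng.normal(0, 0.03, (1000, len(X))),
                         index=[f"p{i}" for i in range(1000)], columns=X.index)
        out = ms.fit_probe_models(Y, X)
        assert abs(out["b"].mean() - 0.1) < 0.01

    def test_collinear_design_names_column(self):
        X = _design()
        X["age2"] = X["age"]
        Y = pd.DataFrame(np.full((12, len(X)), 0.5),
                         index=[f"p{i}" for i in range(12)], columns=X.index)
        with pytest.raises(DesignError, match="age"):
            ms.fit_probe_models(Y, X)


class TestModeration:
    def test_homogeneous_variances_pass_through(self):
        s2 = np.full(50, 0.004)
        mod = ms.moderate_variances(s2, d=26)
        np.testing.assert_allclose(mod["s2_tilde"], s2)
        assert np.isinf(mod["d0"])

    def test_infinite_prior_injected_pins_to_prior(self):
        rng = np.random.default_rng(5)
        s2 = rng.uniform(0.001, 0.01, 40)
        mod = ms.moderate_variances(s2, d=26, d0_override=np.inf)
        assert np.unique(mod["s2_tilde"]).size == 1
        np.testing.assert_allclose(mod["s2_tilde"], mod["s0_2"])

    def test_zero_prior_injected_recovers_ordinary_t(self):
        rng = np.random.default_rng(6)
        X = _design(8, 23, seed=6)
        Y = pd.DataFrame(0.5 + rng.normal(0, 0.05, (60, len(X))),
                         index=[f"p{i}" for i in range(60)], columns=X.index)
        ols = ms.fit_probe_models(Y, X)
        mod = ms.moderate_variances(
            ols["s2"].to_numpy(), float(ols["d"].iloc[0]),
            b=ols["b"].to_numpy(), se_unscaled=ols["se_unscaled"].to_numpy(),
            d0_override=0.0,
        )
        np.testing.assert_allclose(mod["s2_tilde"], ols["s2"])
        ordinary_t = ols["b"] / (ols["se_unscaled"] * np.sqrt(ols["s2"]))
        np.testing.assert_allclose(mod["t_mod"], ordinary_t)

    def test_degenerate_variances_error(self):
        with pytest.raises(ModerationError):
            ms.moderate_variances(np.zeros(20), d=26)

    def test_scaled_f_hyperparameters_recovered(self):
        """Oracle: simulate from the generating model (d0=4, s0^2=0.01,
        d=26) and recover the hyperparameters by the moment estimator."""
        rng = np.random.default_rng(7)
        m = 20000
        s2 = 0.01 * (rng.chisquare(26, m) / 26) * (4.0 / rng.chisquare(4.0, m))
        mod = ms.moderate_variances(s2, d=26)
        assert abs(mod["d0"] - 4.0) / 4.0 < 0.15
        assert abs(mod["s0_2"] - 0.01) / 0.01 < 0.10

    def test_matches_limma_on_heterogeneous_variances(self, tmp_path):
        """Independent oracle: limma's lmFit/eBayes on the same matrix."""
        rng = np.random.default_rng(7)
        n, m = 12, 300
        X = _design(6, 6, seed=7)
        sig = 0.05 * np.sqrt(4 / rng.chisquare(4, m))
        Y = pd.DataFrame(0.5 + rng.normal(0, 1, (m, n)) * sig[:, None],
                         index=[f"p{i}" for i in range(m)], columns=X.index)
        ols = ms.fit_probe_models(Y, X)
        mod = ms.moderate_variances(
            ols["s2"].to_numpy(), float(ols["d"].iloc[0]),
            b=ols["b"].to_numpy(), se_unscaled=ols["se_unscaled"].to_numpy(),
        )
        Y.to_csv(tmp_path / "y.csv")
        X.to_csv(tmp_path / "x.csv")
        script = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1))
        x <- as.matrix(read.csv("{tmp_path}/x.csv", row.names=1))
        fit <- eBayes(lmFit(y, x))
        write.csv(data.frame(t=fit$t[,"group"], p=fit$p.value[,"group"]),
                  "{tmp_path}/out.csv")
        cat(fit$df.prior, fit$s2.prior, "\\n")
        """
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        d0_r, s02_r = map(float, proc.stdout.split())
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert mod["d0"] == pytest.approx(d0_r, rel=1e-6)
        assert mod["s0_2"] == pytest.approx(s02_r, rel=1e-6)
        np.testing.assert_allclose(mod["t_mod"], ref["t"].to_numpy(), rtol=1e-8)
        np.testing.assert_allclose(mod["p"], ref["p"].to_numpy(), rtol=1e-8, atol=1e-12)


def bh_stepup_oracle(p):
    """Textbook O(m^2) step-up: p_adj_(k) = min_{l >= k} m * p_(l) / l."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            candidates.append(m * p[order[later_pos - 1]] / later_pos)
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(ms.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert ms.adjust_bh([0.37]) == pytest.approx([0.37])
        np.testing.assert_allclose(ms.adjust_bh([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            ms.adjust_bh([0.5, 1.5])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_brute_force_stepup(self, p):
        np.testing.assert_allclose(ms.adjust_bh(p), bh_stepup_oracle(p), atol=1e-12)


class TestSignatureSelection:
    def _stats(self, rows):
        df = pd.DataFrame(rows, columns=["p_adj", "delta_beta"])
        df.index = [f"cg{i}" for i in range(len(df))]
        return df

    def test_both_thresholds_are_strict(self):
        stats = self._stats([
            (0.04, 0.09),    # delta too small
            (0.05, 0.20),    # p_adj at the boundary
            (0.04, 0.10),    # delta at the boundary
            (0.049, 0.101),  # passes both
        ])
        assert ms.select_signature(stats, alpha=0.05, min_abs_delta=0.10) == ["cg3"]

    def test_ordering_by_padj_then_delta_then_id(self):
        stats = self._stats([
            (0.01, 0.15), (0.01, 0.25), (0.001, -0.12), (0.01, 0.25),
        ])
        assert ms.select_signature(stats) == ["cg2", "cg1", "cg3", "cg0"]

    def test_recovers_planted_signature(self, small_run, small_dataset):
        selected = set(small_run.signature_probes)
        truth = set(small_dataset.truth.signature_probe_ids)
        recall = len(selected & truth) / len(truth)
        precision = len(selected & truth) / len(selected)
        assert recall >= 0.90
        assert precision >= 0.90


def test_derivation_excludes_young_samples(small_dataset):
    """Only samples older than min_age enter the derivation model."""
    beta, _, sheet, _ = small_dataset
    table = sheet.table.copy()
    table.loc[table.index[:3], "age"] = 1.0
    young_sheet = ms.SampleSheet(table)
    dm = ms.DifferentialMethylation.from_sample_sheet(beta, young_sheet, min_age=2.0)
    assert set(table.index[:3]).isdisjoint(dm.design.index)
    assert (table.loc[dm.design.index, "age"] > 2.0).all()
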