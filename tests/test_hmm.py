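import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from pmdkit import intervals
from pmdkit.hmm import (
    DegenerateStateError,
    SegmentationModel,
    decode,
    fit_hmm,
    select_model,
    subtract_blacklist,
    windows_to_domains,
)


def random_model(rng, dim=2):
    means = rng.uniform(-2, 2, size=(2, dim))
    covs = []
    for _ in range(2):
        a = rng.normal(size=(dim, dim))
        covs.append(a @ a.T + 0.3 * np.eye(dim))
    transmat = rng.dirichlet([3, 1], size=2)
    start = rng.dirichlet([1, 1])
    return SegmentationModel(
        features=("alpha", "pcc")[:dim] if dim == 2 else ("alpha", "pcc", "m_value"),
        means=means, covars=np.array(covs), transmat=transmat, startprob=start,
        feat_mean=np.zeros(dim), feat_std=np.ones(dim),
    )


def windows_frame(X, features=("alpha", "pcc"), chrom="chr1"):
    df = pd.DataFrame(X, columns=list(features))
    for col in ("alpha", "pcc", "m_value"):
        if col not in df.columns:
            df[col] = 0.5
    df["pcc_defined"] = True
    df["chrom"] = chrom
    n = len(df)
    df["start"] = np.arange(n) * 1000
    df["end"] = df["start"] + 1000
    df["n_cpgs"] = 201
    df["mean_beta"] = 0.5
    return df


def viterbi_enumeration(model, X):
    """Brute-force most-probable state path over all 2^L binary paths."""
    L = len(X)
    logem = np.stack(
        [multivariate_normal(model.means[k], model.covars[k]).logpdf(X) for k in (0, 1)],
        axis=1,
    )
    paths = (np.arange(2**L)[:, None] >> np.arange(L)) & 1
    lp = np.log(model.startprob)[paths[:, 0]] + logem[0, paths[:, 0]]
    for t in range(1, L):
        lp += np.log(model.transmat)[paths[:, t - 1], paths[:, t]] + logem[t, paths[:, t]]
    return paths[np.argmax(lp)]


class TestSelectModel:
    def test_low_percentile_selects_3d(self, rng):
        betas = np.concatenate([np.full(2000, 0.005), rng.uniform(0.3, 0.9, 8000)])
        assert select_model(betas) == 3

    def test_high_percentile_selects_2d(self, rng):
        assert select_model(rng.uniform(0.3, 0.9, 10_000)) == 2

    def test_boundary_is_strict_less_than(self):
        betas = np.concatenate([np.full(3000, 0.025), np.full(7000, 0.8)])
        assert np.quantile(betas, 0.1) == 0.025
        assert select_model(betas) == 2

    def test_too_few_sites_warns_and_defaults_2d(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_model(np.full(500, 0.001)) == 2
        assert any("defaulting" in r.message for r in caplog.records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_model(np.array([]))


class TestFitHmm:
    def cluster_windows(self, rng, n=120):
        """Two well-separated feature clusters in alternating runs."""
        states = np.repeat([1, 0, 1, 0, 1, 0], n // 6)[:n]
        alpha = np.where(states == 0, 2.0, 0.5) + rng.normal(0, 0.1, n)
        pcc = np.where(states == 0, -0.6, 0.0) + rng.normal(0, 0.05, n)
        m = np.where(states == 0, -1.0, 2.5) + rng.normal(0, 0.1, n)
        X = np.column_stack([alpha, pcc])
        df = windows_frame(X)
        df["m_value"] = m
        df["mean_beta"] = np.where(states == 0, 0.45, 0.85)
        return df, states

    def test_recovers_cluster_means(self, rng):
        df, states = self.cluster_windows(rng)
        model = fit_hmm(df, dim=2, seed=0)
        # state 0 is PMD (larger alpha)
        assert abs(model.means[0, 0] - 2.0) < 0.1
        assert abs(model.means[1, 0] - 0.5) < 0.1
        assert abs(model.means[0, 1] + 0.6) < 0.1

    def test_loglik_trace_non_decreasing(self, rng):
        df, _ = self.cluster_windows(rng)
        model = fit_hmm(df, dim=2, seed=0)
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.maximum(1, np.abs(trace[:-1]))).all()

    def test_same_seed_refits_identically(self, rng):
        df, _ = self.cluster_windows(rng)
        a = fit_hmm(df, dim=2, seed=7, n_restarts=3)
        b = fit_hmm(df, dim=2, seed=7, n_restarts=3)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.covars, b.covars)
        np.testing.assert_array_equal(a.transmat, b.transmat)

    def test_identical_features_degenerate(self):
        df = windows_frame(np.full((80, 2), 1.0))
        with pytest.raises(DegenerateStateError):
            fit_hmm(df, dim=2, seed=0)

    def test_too_few_windows_rejected(self, rng):
        df = windows_frame(rng.normal(size=(30, 2)))
        with pytest.raises(ValueError, match=">= 50"):
            fit_hmm(df, dim=2, seed=0)

    def test_restart_label_permutations_agree(self, rng):
        """EM started from perturbed inits must yield the same PMD calls."""
        df, states = self.cluster_windows(rng)
        baseline = decode(fit_hmm(df, dim=2, seed=0), df)
        for seed in range(1, 4):
            model = fit_hmm(df, dim=2, seed=seed, n_restarts=2)
            assert (decode(model, df) == baseline).all()

    def test_serialization_round_trip(self, rng):
        df, _ = self.cluster_windows(rng)
        model = fit_hmm(df, dim=2, seed=0)
        back = SegmentationModel.from_json(model.to_json())
        np.testing.assert_allclose(back.means, model.means)
        np.testing.assert_allclose(back.transmat, model.transmat)
        assert back.features == model.features


class TestDecode:
    def test_single_window_maximum_likelihood(self, rng):
        model = random_model(rng)
        x = model.means[0] + 0.01
        labels = decode(model, windows_frame(x[None, :]))
        assert labels.tolist() == ["PMD"]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            model = random_model(rng)
            L = int(rng.integers(2, 13))
            X = rng.normal(0, 1.5, size=(L, 2))
            got = decode(model, windows_frame(X))
            expect = viterbi_enumeration(model, X)
            assert (np.where(got == "PMD", 0, 1) == expect).all(), f"trial {trial}"

    def test_sticky_transitions_smooth_alternating_evidence(self, rng):
        model = random_model(rng)
        model.means = np.array([[-1.0, 0.0], [1.0, 0.0]])
        model.covars = np.array([np.eye(2)] * 2)
        model.transmat = np.array([[0.99, 0.01], [0.01, 0.99]])
        model.startprob = np.array([0.5, 0.5])
        x = np.zeros((12, 2))
        x[:, 0] = np.where(np.arange(12) % 2 == 0, -0.3, 0.3)  # weak alternation
        labels = decode(model, windows_frame(x))
        ml = np.where(x[:, 0] < 0, "PMD", "HMD")
        assert (labels[1:] != labels[:-1]).sum() < (ml[1:] != ml[:-1]).sum()

    def test_all_windows_strongly_hmd(self, rng):
        model = random_model(rng)
        X = np.tile(model.means[1], (6, 1))
        assert (decode(model, windows_frame(X)) == "HMD").all()

    def test_undefined_windows_inherit_nearest_defined_state(self, rng):
        model = random_model(rng)
        model.means = np.array([[-2.0, 0.0], [2.0, 0.0]])
        model.covars = np.array([np.eye(2)] * 2)
        X = np.array([[-2.0, 0], [0, 0], [2.0, 0], [2.0, 0]])
        df = windows_frame(X)
        df.loc[1, "pcc_defined"] = False  # undefined; equidistant -> preceding
        labels = decode(model, df)
        assert labels.tolist() == ["PMD", "PMD", "HMD", "HMD"]

    def test_feature_mismatch_rejected(self, rng):
        model = random_model(rng, dim=3)
        df = windows_frame(np.zeros((4, 2))).drop(columns=["m_value"])
        with pytest.raises(ValueError, match="mismatch"):
            decode(model, df)


class TestWindowsToDomains:
    def frame(self, labels):
        n = len(labels)
        return (
            windows_frame(np.zeros((n, 2))),
            np.array(["PMD" if c == "P" else "HMD" for c in labels]),
        )

    def test_run_length_merge(self):
        df, labels = self.frame("PPHHH")
        doms = windows_to_domains(labels, df)
        assert doms["state"].tolist() == ["PMD", "HMD"]
        assert doms[["start", "end"]].values.tolist() == [[0, 2000], [2000, 5000]]

    def test_short_run_absorbed(self):
        df, labels = self.frame("PHP")
        doms = windows_to_domains(labels, df, min_windows=2)
        assert doms["state"].tolist() == ["PMD"]
        assert doms["n_windows"].tolist() == [3]

    def test_empty_input(self):
        df, labels = self.frame("")
        assert len(windows_to_domains(labels, df)) == 0

    def test_domains_alternate_and_tile(self, moderate_fit):
        _, _, res = moderate_fit
        for _, sub in res.domains.groupby("chrom"):
            states = sub["state"].tolist()
            assert all(a != b for a, b in zip(states, states[1:]))
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()


class TestSubtractBlacklist:
    def domains(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "state": ["PMD"],
             "n_windows": [5], "mean_beta": [0.5]}
        )

    def test_interior_subtraction_preserves_state(self):
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [40], "end": [60]})
        out = subtract_blacklist(self.domains(), bl)
        assert out[["start", "end"]].values.tolist() == [[0, 40], [60, 100]]
        assert (out["state"] == "PMD").all()

    def test_full_cover_removes_domain(self):
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200]})
        assert len(subtract_blacklist(self.domains(), bl)) == 0

    def test_disjoint_blacklist_no_change(self):
        bl = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [200]})
        out = subtract_blacklist(self.domains(), bl)
        assert out[["start", "end"]].values.tolist() == [[0, 100]]


class TestPMDResults:
    def test_summary_mentions_model_and_fraction(self, moderate_fit):
        _, _, res = moderate_fit
        text = res.summary()
        assert "2D" in text and "PMD genome fraction" in text

    def test_genome_fraction_windowed_denominator(self, moderate_fit):
        _, _, res = moderate_fit
        f = res.genome_fraction()
        pmd_bp = intervals.total_bp(res.pmds)
        assert f == pytest.approx(pmd_bp / intervals.total_bp(res.domains))
        assert 0 < f < 1
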