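"""Signal summarization, prior-regularized EM, posterior calling."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rarearray.calling import (
    CallingParams,
    call_genotypes,
    fit_clusters,
    posterior_matrix,
    summarize_signals,
)
from rarearray.types import AA, AB, BB, NOCALL, SignalSummary

from conftest import make_config, run_calling, toy_probeset_annotation


def make_intensity_table(values) -> pd.DataFrame:
    """values: list of (probeset, replicate, sample, A, B)."""
    return pd.DataFrame(
        values,
        columns=["probeset_id", "probe_replicate_index", "sample_id", "channel_A", "channel_B"],
    )


def summary_from_contrasts(contrasts: dict[str, dict[str, list[float]]]) -> SignalSummary:
    """Hand-built summary: probeset -> sample -> replicate contrasts."""
    rows = {}
    for probeset, by_sample in contrasts.items():
        n_rep = len(next(iter(by_sample.values())))
        for rep in range(1, n_rep + 1):
            rows[(probeset, rep)] = {s: v[rep - 1] for s, v in by_sample.items()}
    rep = pd.DataFrame(rows).T
    rep.index.names = ["probeset_id", "probe_replicate_index"]
    rep.columns.name = "sample_id"
    contrast = rep.groupby(level="probeset_id").mean()
    return SignalSummary(contrast=contrast, size=contrast * 0.0, replicate_contrast=rep)


class TestSummarizeSignals:
    def test_equal_channels_give_zero_contrast(self):
        table = make_intensity_table(
            [("PS1", r, "S1", 500.0, 500.0) for r in (1, 2, 3)]
        )
        summary = summarize_signals(table, toy_probeset_annotation(["PS1"]))
        assert summary.contrast.loc["PS1", "S1"] == 0.0

    def test_powers_of_two_with_pseudocount(self):
        table = make_intensity_table([("PS1", r, "S1", 4095.0, 255.0) for r in (1, 2, 3)])
        summary = summarize_signals(table, toy_probeset_annotation(["PS1"]))
        assert summary.contrast.loc["PS1", "S1"] == pytest.approx(4.0)

    def test_replicates_averaged(self):
        # per-replicate contrasts 2.0, 2.2, 2.4 (B channel = 1 so log2(B+1)=1)
        table = make_intensity_table(
            [("PS1", r, "S1", 2 ** (c + 1) - 1, 1.0) for r, c in zip((1, 2, 3), (2.0, 2.2, 2.4))]
        )
        summary = summarize_signals(table, toy_probeset_annotation(["PS1"]))
        assert summary.contrast.loc["PS1", "S1"] == pytest.approx(2.2)
        assert list(summary.replicate_contrast.loc["PS1"]["S1"]) == pytest.approx(
            [2.0, 2.2, 2.4]
        )

    def test_negative_intensity_rejected(self):
        table = make_intensity_table([("PS1", 1, "S1", -5.0, 10.0)])
        with pytest.raises(ValueError, match="negative"):
            summarize_signals(table, toy_probeset_annotation(["PS1"], 1))

    def test_unannotated_probeset_rejected(self):
        table = make_intensity_table([("PSX", 1, "S1", 5.0, 10.0)])
        with pytest.raises(ValueError, match="annotation"):
            summarize_signals(table, toy_probeset_annotation(["PS1"], 1))

    def test_replicate_count_mismatch_rejected(self):
        table = make_intensity_table([("PS1", 1, "S1", 5.0, 10.0)])
        with pytest.raises(ValueError, match="replicate count"):
            summarize_signals(table, toy_probeset_annotation(["PS1"], 3))


def two_group_summary(aa_values, ab_values) -> tuple[SignalSummary, pd.DataFrame]:
    samples = [f"S{i}" for i in range(len(aa_values) + len(ab_values))]
    values = list(aa_values) + list(ab_values)
    contrasts = {"PS1": {s: [v] * 3 for s, v in zip(samples, values)}}
    manifest = pd.DataFrame(
        {"sample_id": samples, "plate_id": "P001", "batch_id": "B001"}
    )
    return summary_from_contrasts(contrasts), manifest


class TestFitClusters:
    def test_two_groups_recover_sample_means(self):
        aa = [2.9, 3.05, 3.1, 2.95, 3.0, 3.0]
        ab = [0.05, -0.05, 0.1, -0.1]
        summary, manifest = two_group_summary(aa, ab)
        model = fit_clusters(summary, manifest)
        means = model.means("PS1", "B001")
        assert means[AA] == pytest.approx(np.mean(aa), abs=0.1)
        assert means[AB] == pytest.approx(np.mean(ab), abs=0.1)

    def test_empty_clusters_retain_prior(self):
        summary, manifest = two_group_summary([3.0] * 12, [])
        params = CallingParams()
        model = fit_clusters(summary, manifest, params)
        means = model.means("PS1", "B001")
        variances = model.variances("PS1", "B001")
        assert means[AA] == pytest.approx(3.0, abs=0.05)
        assert means[AB] == pytest.approx(0.0, abs=1e-6)
        assert means[BB] == pytest.approx(-3.0, abs=1e-6)
        assert variances[AB] == pytest.approx(params.prior_var, abs=1e-6)
        assert variances[BB] == pytest.approx(params.prior_var, abs=1e-6)

    def test_em_matches_grid_search_oracle(self):
        """10-sample instance whose group means coincide with the prior
        centers (so the prior pull on the means is zero): EM must agree
        with brute-force likelihood maximization over a parameter grid."""
        aa = [2.8, 2.9, 3.0, 3.0, 3.1, 3.2, 3.0]  # mean exactly 3.0
        ab = [-0.2, 0.0, 0.2]  # mean exactly 0.0
        summary, manifest = two_group_summary(aa, ab)
        model = fit_clusters(summary, manifest)
        em_means = model.means("PS1", "B001")

        x = np.array(aa + ab)
        grid = np.round(np.arange(-0.5, 0.51, 0.05), 10)
        best, best_ll = None, -np.inf
        for d_aa, d_ab in itertools.product(grid, grid):
            mu = np.array([3.0 + d_aa, 0.0 + d_ab, -3.0])
            w = np.array([0.7, 0.3, 1e-9])
            w = w / w.sum()
            ll = np.log(
                (w * stats.norm.pdf(x[:, None], mu[None, :], 0.25)).sum(axis=1)
            ).sum()
            if ll > best_ll:
                best, best_ll = mu, ll
        assert em_means[AA] == pytest.approx(best[AA], abs=0.06)
        assert em_means[AB] == pytest.approx(best[AB], abs=0.06)

    def test_cluster_mean_ordering_invariant(self):
        exp = run_calling(make_config(n_samples=150, n_probesets=6, seed=4))
        p = exp.model.params
        assert (p["mean_AA"] > p["mean_AB"]).all()
        assert (p["mean_AB"] > p["mean_BB"]).all()

    def test_weights_sum_to_one(self):
        exp = run_calling(make_config(n_samples=150, n_probesets=6, seed=4))
        w = exp.model.params[["w_AA", "w_AB", "w_BB"]].to_numpy().sum(axis=1)
        assert np.allclose(w, 1.0)

    def test_single_sample_batch_rejected(self):
        contrasts = {"PS1": {"S0": [3.0] * 3}}
        summary = summary_from_contrasts(contrasts)
        manifest = pd.DataFrame(
            {"sample_id": ["S0"], "plate_id": "P001", "batch_id": "B001"}
        )
        with pytest.raises(ValueError, match="batch"):
            fit_clusters(summary, manifest)


class TestCallGenotypes:
    def test_sample_at_cluster_mean_high_confidence(self):
        summary, manifest = two_group_summary([3.0] * 10, [0.0] * 3)
        model = fit_clusters(summary, manifest)
        calls = call_genotypes(summary, model, manifest)
        assert calls.calls.loc["PS1", "S0"] == AA
        assert calls.confidence.loc["PS1", "S0"] > 0.99

    def test_equidistant_sample_is_nocall(self):
        from conftest import toy_cluster_model

        contrasts = {"PS1": {"S0": [1.5] * 3, "S1": [3.0] * 3}}
        summary = summary_from_contrasts(contrasts)
        manifest = pd.DataFrame(
            {"sample_id": ["S0", "S1"], "plate_id": "P001", "batch_id": "B001"}
        )
        model = toy_cluster_model(["PS1"], ["B001"])
        calls = call_genotypes(summary, model, manifest, confidence_threshold=0.95)
        # equidistant between AA (3.0) and AB (0.0) clusters of equal
        # variance and weight: posterior ~0.5 each -> NoCall
        assert calls.calls.loc["PS1", "S0"] == NOCALL
        assert calls.confidence.loc["PS1", "S0"] == pytest.approx(0.5, abs=1e-6)

    def test_posterior_matches_bayes_rule_oracle(self):
        """Two-cluster toy model checked against direct Bayes arithmetic."""
        means = np.array([2.0, -1.0, -50.0])
        variances = np.array([0.5, 0.25, 1.0])
        weights = np.array([0.6, 0.4, 1e-300])
        x = np.array([0.3, 1.9, -1.2])
        post = posterior_matrix(x, means, variances, weights)
        for i, xi in enumerate(x):
            f = weights[:2] * stats.norm.pdf(xi, means[:2], np.sqrt(variances[:2]))
            expected = f / f.sum()
            assert post[i, :2] == pytest.approx(expected, abs=1e-9)

    def test_no_noise_concordance_100pct(self, clean_experiment):
        assert clean_experiment.concordance() == 1.0

    def test_calls_invariant_to_sample_order(self):
        cfg = make_config(n_samples=100, n_probesets=5, seed=8)
        exp = run_calling(cfg)
        manifest_rev = exp.manifest.iloc[::-1].reset_index(drop=True)
        model = fit_clusters(exp.summary, manifest_rev)
        calls = call_genotypes(exp.summary, model, manifest_rev)
        assert calls.calls.loc[exp.base.probesets, exp.base.samples].equals(exp.base.calls)

    def test_calls_invariant_to_global_rescale(self):
        cfg = make_config(n_samples=100, n_probesets=5, seed=8)
        intens, ann, _ = __import__("rarearray.synthdata", fromlist=["simulate_experiment"]).simulate_experiment(cfg)
        mani = cfg.manifest()
        scaled = intens.copy()
        scaled[["channel_A", "channel_B"]] *= 4.0
        a = summarize_signals(intens, ann)
        b = summarize_signals(scaled, ann)
        ma, mb = fit_clusters(a, mani), fit_clusters(b, mani)
        ca = call_genotypes(a, ma, mani)
        cb = call_genotypes(b, mb, mani)
        assert ca.calls.equals(cb.calls)

    def test_nocall_set_monotone_in_threshold(self):
        exp = run_calling(make_config(n_samples=150, n_probesets=8, seed=9))
        strict = call_genotypes(exp.summary, exp.model, exp.manifest, 0.99)
        loose = call_genotypes(exp.summary, exp.model, exp.manifest, 0.80)
        nocall_strict = strict.calls.to_numpy() == NOCALL
        nocall_loose = loose.calls.to_numpy() == NOCALL
        assert not (nocall_loose & ~nocall_strict).any()
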