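"""Shared fixtures: small simulated experiments and fitted calling stacks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from rarearray.calling import CallingParams, call_genotypes, fit_clusters, summarize_signals
from rarearray.synthdata import (
    ProbesetSpec,
    SimulationConfig,
    random_probeset_specs,
    simulate_experiment,
)
from rarearray.types import ClusterModel, GenotypeMatrix


def make_config(
    n_samples=300,
    n_plates=2,
    plates_per_batch=2,
    n_probesets=12,
    seed=11,
    spec_seed=5,
    **overrides,
):
    spec_kwargs = {
        k: overrides.pop(k)
        for k in ("maf_range", "n_cross_hyb", "contamination_factor", "n_replicate_probes")
        if k in overrides
    }
    specs = tuple(random_probeset_specs(n_probesets, seed=spec_seed, **spec_kwargs))
    return SimulationConfig(
        n_samples=n_samples,
        n_plates=n_plates,
        plates_per_batch=plates_per_batch,
        probeset_specs=specs,
        seed=seed,
        **overrides,
    )


@dataclass
class CalledExperiment:
    config: SimulationConfig
    intensities: pd.DataFrame
    annotation: pd.DataFrame
    truth: object
    manifest: pd.DataFrame
    summary: object
    model: ClusterModel
    base: GenotypeMatrix

    def truth_codes(self) -> np.ndarray:
        return self.truth.genotypes.loc[self.base.probesets, self.base.samples].to_numpy()

    def concordance(self, matrix: GenotypeMatrix | None = None) -> float:
        m = matrix if matrix is not None else self.base
        return float((m.calls.to_numpy() == self.truth_codes()).mean())


def run_calling(config: SimulationConfig, params: CallingParams = CallingParams()) -> CalledExperiment:
    intensities, annotation, truth = simulate_experiment(config)
    manifest = config.manifest()
    summary = summarize_signals(intensities, annotation, epsilon=params.epsilon)
    model = fit_clusters(summary, manifest, params)
    base = call_genotypes(summary, model, manifest, params.confidence_threshold)
    return CalledExperiment(
        config, intensities, annotation, truth, manifest, summary, model, base
    )


@pytest.fixture(scope="session")
def clean_experiment() -> CalledExperiment:
    """Pathology-free experiment: the no-noise limit for downstream stages."""
    return run_calling(make_config(n_samples=300, n_probesets=15, seed=11))


@pytest.fixture(scope="session")
def shifted_experiment() -> CalledExperiment:
    """One plate in a 3-plate batch with a -2.0 contrast shift (false hets)."""
    cfg = make_config(
        n_samples=360,
        n_plates=3,
        plates_per_batch=3,
        n_probesets=12,
        seed=23,
        batch_shift={"P002": -2.0},
        shift_channel="A",
    )
    return run_calling(cfg)


@pytest.fixture(scope="session")
def artifact_experiment() -> CalledExperiment:
    """Strong one-replicate artifacts creating false heterozygous calls."""
    cfg = make_config(
        n_samples=400,
        n_probesets=12,
        seed=31,
        artifact_rate=0.02,
        artifact_factor_range=(64.0, 256.0),
    )
    return run_calling(cfg)


def toy_probeset_annotation(probeset_ids, n_replicates=3) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probeset_id": list(probeset_ids),
            "rsid": [f"rs{i}" for i, _ in enumerate(probeset_ids)],
            "chrom": "1",
            "pos": [1000 * (i + 1) for i, _ in enumerate(probeset_ids)],
            "ref": "A",
            "alt": "G",
            "n_replicate_probes": n_replicates,
            "panel": "",
        }
    )


def toy_cluster_model(
    probeset_ids,
    batch_ids,
    means=(3.0, 0.0, -3.0),
    variances=(0.25, 0.25, 0.25),
    weights=(1 / 3, 1 / 3, 1 / 3),
) -> ClusterModel:
    index = pd.MultiIndex.from_product(
        [list(probeset_ids), list(batch_ids)], names=["probeset_id", "batch_id"]
    )
    data = np.tile(np.concatenate([means, variances, weights, [1.0]]), (len(index), 1))
    frame = pd.DataFrame(
        data,
        index=index,
        columns=ClusterModel._MEAN_COLS
        + ClusterModel._VAR_COLS
        + ClusterModel._W_COLS
        + ["converged"],
    )
    frame["converged"] = frame["converged"].astype(bool)
    return ClusterModel(frame)
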