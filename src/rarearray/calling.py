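"""Cluster-based genotype calling of two-channel probeset signals.

Signals are summarized per probeset x sample into *contrast*
(log2(A) - log2(B), allele-discriminating) and *size*
((log2(A) + log2(B)) / 2, overall intensity), averaged across replicate
probes, with a pseudocount guard on the raw intensities.

Calling fits, per probeset and per batch, a 3-component 1-D Gaussian
mixture in contrast by EM regularized with pseudo-observation priors whose
centers sit at (+c, 0, -c). A cluster that attracts no samples keeps its
prior parameters — this is what makes genotypes callable when a batch
contains no (or almost no) minor-allele carriers. Calls are posterior
argmax with a NoCall confidence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from rarearray.types import (
    NOCALL,
    PROV_ORIGINAL,
    ClusterModel,
    GenotypeMatrix,
    SignalSummary,
)

__all__ = [
    "CallingParams",
    "summarize_signals",
    "fit_clusters",
    "call_genotypes",
    "posterior_matrix",
]


@dataclass(frozen=True)
class CallingParams:
    """Tunables of the calling stage (defaults documented in FORMATS.md)."""

    epsilon: float = 1.0
    prior_center: float = 3.0
    prior_var: float = 0.25
    prior_weight: float = 2.0
    confidence_threshold: float = 0.95
    max_iter: int = 300
    tol: float = 1e-9

    @property
    def prior_centers(self) -> np.ndarray:
        return np.array([self.prior_center, 0.0, -self.prior_center])


def summarize_signals(
    intensities: pd.DataFrame,
    annotation: pd.DataFrame,
    epsilon: float = 1.0,
) -> SignalSummary:
    """Contrast/size summaries from a long intensity table.

    A pseudocount ``epsilon`` is added to the raw intensities before log2,
    keeping the transform finite at zero signal.
    """
    required = {"probeset_id", "probe_replicate_index", "sample_id", "channel_A", "channel_B"}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    if (intensities[["channel_A", "channel_B"]].to_numpy() < 0).any():
        raise ValueError("negative intensities in input")

    known = set(annotation["probeset_id"])
    present = pd.unique(intensities["probeset_id"])
    unknown = [p for p in present if p not in known]
    if unknown:
        raise ValueError(f"probesets missing from annotation: {unknown[:5]}")

    la = np.log2(intensities["channel_A"].to_numpy(float) + epsilon)
    lb = np.log2(intensities["channel_B"].to_numpy(float) + epsilon)
    work = intensities[["probeset_id", "probe_replicate_index", "sample_id"]].copy()
    work["contrast"] = la - lb
    work["size"] = (la + lb) / 2.0

    replicate_contrast = work.pivot(
        index=["probeset_id", "probe_replicate_index"],
        columns="sample_id",
        values="contrast",
    )
    n_rep = annotation.set_index("probeset_id")["n_replicate_probes"]
    counts = replicate_contrast.groupby(level="probeset_id").size()
    bad = counts[counts != n_rep.reindex(counts.index)]
    if len(bad):
        raise ValueError(
            f"replicate count mismatch with annotation for probesets: {list(bad.index[:5])}"
        )

    contrast = replicate_contrast.groupby(level="probeset_id").mean()
    size = (
        work.pivot(
            index=["probeset_id", "probe_replicate_index"],
            columns="sample_id",
            values="size",
        )
        .groupby(level="probeset_id")
        .mean()
    )
    return SignalSummary(
        contrast=contrast, size=size, replicate_contrast=replicate_contrast
    )


# ---------------------------------------------------------------------------


def _log_norm_pdf(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def posterior_matrix(
    x: np.ndarray, means: np.ndarray, variances: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Posterior cluster membership, Bayes rule over the mixture components.

    ``x`` broadcasts against trailing component axes: for ``x`` of shape
    ``(...,)`` and parameters of shape ``(3,)`` (or ``(..., 3)``), returns
    posteriors of shape ``(..., 3)``.
    """
    lp = np.log(weights) + _log_norm_pdf(np.asarray(x, float)[..., None], means, variances)
    return np.exp(lp - logsumexp(lp, axis=-1, keepdims=True))


def _em_batch(X: np.ndarray, params: CallingParams) -> tuple[np.ndarray, ...]:
    """Vectorized prior-regularized EM over P probesets with N samples each.

    Returns (means, variances, weights, converged) with shapes
    (P,3), (P,3), (P,3), (P,).
    """
    P, N = X.shape
    k0 = params.prior_weight  # pseudo-observations on each cluster mean/variance
    a0 = params.prior_weight  # pseudo-counts on mixing weights
    m0 = np.broadcast_to(params.prior_centers, (P, 3)).copy()
    v0 = params.prior_var

    mu = m0.copy()
    var = np.full((P, 3), v0)
    w = np.full((P, 3), 1.0 / 3.0)
    converged = np.zeros(P, dtype=bool)

    for _ in range(params.max_iter):
        lp = np.log(w)[:, None, :] + _log_norm_pdf(X[:, :, None], mu[:, None, :], var[:, None, :])
        r = np.exp(lp - logsumexp(lp, axis=2, keepdims=True))  # (P, N, 3)

        nk = r.sum(axis=1)  # (P, 3)
        sum_x = np.einsum("pnk,pn->pk", r, X)
        mu_new = (k0 * m0 + sum_x) / (k0 + nk)
        dev = (X[:, :, None] - mu_new[:, None, :]) ** 2
        s = np.einsum("pnk,pnk->pk", r, dev)
        var_new = np.maximum((k0 * v0 + s) / (k0 + nk), 1e-6)
        w_new = (a0 + nk) / (3.0 * a0 + N)

        delta = np.max(
            np.stack(
                [np.abs(mu_new - mu), np.abs(var_new - var), np.abs(w_new - w)]
            ).reshape(3, P, 3),
            axis=(0, 2),
        )
        mu, var, w = mu_new, var_new, w_new
        converged |= delta < params.tol
        if converged.all():
            break

    # enforce the allele convention: contrast mean AA > AB > BB
    order = np.argsort(-mu, axis=1, kind="stable")
    rows = np.arange(P)[:, None]
    return mu[rows, order], var[rows, order], w[rows, order], converged


def fit_clusters(
    summary: SignalSummary,
    manifest: pd.DataFrame,
    params: CallingParams = CallingParams(),
) -> ClusterModel:
    """Fit the per-probeset, per-batch contrast mixture model."""
    rows = []
    index = []
    for batch_id, grp in manifest.groupby("batch_id", sort=True):
        samples = [s for s in summary.samples if s in set(grp["sample_id"])]
        if len(samples) < 2:
            raise ValueError(f"batch {batch_id}: need >= 2 samples to fit clusters")
        X = summary.contrast[samples].to_numpy(float)
        mu, var, w, conv = _em_batch(X, params)
        for i, probeset_id in enumerate(summary.probesets):
            index.append((probeset_id, batch_id))
            rows.append(np.concatenate([mu[i], var[i], w[i], [conv[i]]]))
    frame = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["probeset_id", "batch_id"]),
        columns=ClusterModel._MEAN_COLS
        + ClusterModel._VAR_COLS
        + ClusterModel._W_COLS
        + ["converged"],
    )
    frame["converged"] = frame["converged"].astype(bool)
    return ClusterModel(frame)


def call_genotypes(
    summary: SignalSummary,
    model: ClusterModel,
    manifest: pd.DataFrame,
    confidence_threshold: float = 0.95,
) -> GenotypeMatrix:
    """Posterior-argmax genotype calls with a NoCall confidence threshold.

    Probesets whose EM did not converge in a batch are set to NoCall with
    NaN confidence for every sample of that batch.
    """
    out = GenotypeMatrix.empty_like(summary.probesets, summary.samples)
    for batch_id, grp in manifest.groupby("batch_id", sort=True):
        samples = [s for s in summary.samples if s in set(grp["sample_id"])]
        if not samples:
            continue
        mu, var, w, conv = model.batch_arrays(summary.probesets, batch_id)
        X = summary.contrast[samples].to_numpy(float)  # (P, N)
        post = posterior_matrix(X, mu[:, None, :], var[:, None, :], w[:, None, :])
        calls = np.argmax(post, axis=2).astype(np.int8)
        conf = np.max(post, axis=2)
        calls[conf < confidence_threshold] = NOCALL
        calls[~conv, :] = NOCALL
        conf[~conv, :] = np.nan
        out.calls.loc[:, samples] = calls
        out.confidence.loc[:, samples] = conf
    out.provenance.loc[:, :] = PROV_ORIGINAL
    return out
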