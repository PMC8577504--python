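"""Rare het adjustment: demote internally inconsistent heterozygous calls.

A heterozygous (AB) call is trustworthy only if its replicate probes agree.
Two consistency checks run per AB call:

1. **replicate dispersion** — ``D = max_i |contrast_i - median(contrasts)|``
   must not exceed ``d_max``;
2. **per-replicate cluster membership** — every replicate contrast must sit
   nearest the AB cluster of the sample's batch model.

Failing either check demotes the call to NoCall with provenance "rarehet".
Calls other than AB are never touched, which also makes the operation
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rarearray.types import (
    AB,
    NOCALL,
    PROV_RAREHET,
    ClusterModel,
    GenotypeMatrix,
    SignalSummary,
)

__all__ = ["RareHetParams", "rare_het_adjust"]


@dataclass(frozen=True)
class RareHetParams:
    d_max: float = 1.0  # max replicate deviation from the median, contrast units


def rare_het_adjust(
    calls: GenotypeMatrix,
    summary: SignalSummary,
    model: ClusterModel,
    manifest: pd.DataFrame,
    params: RareHetParams = RareHetParams(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the rare het adjustment.

    Returns the adjusted matrix and an audit table with one row per
    inspected AB call (probeset_id, sample_id, dispersion,
    replicates_in_ab_cluster, verdict).
    """
    out = calls.copy()
    batch_of = manifest.set_index("sample_id")["batch_id"]
    decisions: list[dict] = []

    ab_mask = calls.calls.to_numpy() == AB
    for i in np.flatnonzero(ab_mask.any(axis=1)):
        probeset_id = calls.probesets[i]
        try:
            reps = summary.replicate_contrast.loc[probeset_id]
        except KeyError:
            raise ValueError(
                f"missing replicate signal data for probeset {probeset_id}"
            ) from None
        ab_samples = calls.samples[ab_mask[i]]
        arr = reps[ab_samples].to_numpy(float)  # (n_replicates, n_ab)
        med = np.median(arr, axis=0)
        dispersion = np.max(np.abs(arr - med), axis=0)

        in_ab = np.ones(len(ab_samples), dtype=bool)
        for j, sample_id in enumerate(ab_samples):
            means = model.means(probeset_id, batch_of[sample_id])
            nearest = np.argmin(np.abs(arr[:, j][:, None] - means[None, :]), axis=1)
            in_ab[j] = bool((nearest == AB).all())

        demote = (dispersion > params.d_max) | ~in_ab
        for j, sample_id in enumerate(ab_samples):
            decisions.append(
                {
                    "probeset_id": probeset_id,
                    "sample_id": sample_id,
                    "dispersion": float(dispersion[j]),
                    "replicates_in_ab_cluster": bool(in_ab[j]),
                    "verdict": "demote_to_nocall" if demote[j] else "keep",
                }
            )
        if demote.any():
            demoted = ab_samples[demote]
            out.calls.loc[probeset_id, demoted] = NOCALL
            out.confidence.loc[probeset_id, demoted] = np.nan
            out.provenance.loc[probeset_id, demoted] = PROV_RAREHET

    audit = pd.DataFrame(
        decisions,
        columns=[
            "probeset_id",
            "sample_id",
            "dispersion",
            "replicates_in_ab_cluster",
            "verdict",
        ],
    )
    return out, audit
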