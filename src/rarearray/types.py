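"""Shared domain containers: genotype matrices, signal summaries, cluster models.

Conventions
-----------
* Allele A is the reference (major) allele; allele B the alternate (minor).
* Contrast = log2(A) - log2(B), so AA sits at positive contrast and BB at
  negative contrast.
* Genotype calls are stored as int8 codes: 0=AA, 1=AB, 2=BB, -1=NoCall.
* Matrices are indexed by probeset_id (rows) and sample_id (columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA: int = 0
AB: int = 1
BB: int = 2
NOCALL: int = -1

CALL_LABELS: dict[int, str] = {AA: "AA", AB: "AB", BB: "BB", NOCALL: "NoCall"}
CALL_CODES: dict[str, int] = {v: k for k, v in CALL_LABELS.items()}

GENOTYPE_ORDER: tuple[str, str, str] = ("AA", "AB", "BB")

PROV_ORIGINAL: int = 0
PROV_RAREHET: int = 1
PROV_ADVNORM: int = 2
PROV_CONFLICT: int = 3

PROV_LABELS: dict[int, str] = {
    PROV_ORIGINAL: "original",
    PROV_RAREHET: "rarehet",
    PROV_ADVNORM: "advnorm",
    PROV_CONFLICT: "conflict",
}
PROV_CODES: dict[str, int] = {v: k for k, v in PROV_LABELS.items()}


@dataclass
class GenotypeMatrix:
    """Per-probeset, per-sample genotype calls with confidence and provenance.

    Attributes
    ----------
    calls
        int8 frame of call codes (see module docstring).
    confidence
        float frame; posterior probability of the chosen cluster. NaN for
        cells whose NoCall did not come from confidence thresholding.
    provenance
        int8 frame of adjustment provenance codes.
    """

    calls: pd.DataFrame
    confidence: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame in (("confidence", self.confidence), ("provenance", self.provenance)):
            if not frame.index.equals(self.calls.index) or not frame.columns.equals(
                self.calls.columns
            ):
                raise ValueError(f"{name} frame is not aligned with calls")

    @property
    def probesets(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> pd.Index:
        return self.calls.columns

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), self.confidence.copy(), self.provenance.copy()
        )

    def aligned_with(self, other: "GenotypeMatrix") -> bool:
        return self.calls.index.equals(other.calls.index) and self.calls.columns.equals(
            other.calls.columns
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.calls.equals(other.calls)
            and self.confidence.equals(other.confidence)
            and self.provenance.equals(other.provenance)
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with human-readable labels (TSV serialization)."""
        idx, cols = self.calls.index, self.calls.columns
        return pd.DataFrame(
            {
                "probeset_id": np.repeat(idx.to_numpy(), len(cols)),
                "sample_id": np.tile(cols.to_numpy(), len(idx)),
                "call": pd.Series(self.calls.to_numpy().ravel()).map(CALL_LABELS),
                "confidence": self.confidence.to_numpy().ravel(),
                "provenance": pd.Series(self.provenance.to_numpy().ravel()).map(
                    PROV_LABELS
                ),
            }
        )

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "GenotypeMatrix":
        required = {"probeset_id", "sample_id", "call", "confidence", "provenance"}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"genotype table missing columns: {sorted(missing)}")
        codes = long["call"].map(CALL_CODES)
        if codes.isna().any():
            bad = long.loc[codes.isna(), "call"].unique()
            raise ValueError(f"unknown call labels: {list(bad)}")
        prov = long["provenance"].map(PROV_CODES)
        if prov.isna().any():
            bad = long.loc[prov.isna(), "provenance"].unique()
            raise ValueError(f"unknown provenance labels: {list(bad)}")
        idx = ["probeset_id", "sample_id"]
        calls = (
            long.assign(code=codes.astype(np.int8))
            .pivot(index=idx[0], columns=idx[1], values="code")
            .astype(np.int8)
        )
        conf = long.pivot(index=idx[0], columns=idx[1], values="confidence").astype(float)
        provenance = (
            long.assign(pcode=prov.astype(np.int8))
            .pivot(index=idx[0], columns=idx[1], values="pcode")
            .astype(np.int8)
        )
        return cls(calls, conf.loc[calls.index, calls.columns], provenance.loc[calls.index, calls.columns])

    @classmethod
    def empty_like(cls, probesets, samples) -> "GenotypeMatrix":
        idx = pd.Index(probesets, name="probeset_id")
        cols = pd.Index(samples, name="sample_id")
        calls = pd.DataFrame(np.full((len(idx), len(cols)), NOCALL, dtype=np.int8), idx, cols)
        conf = pd.DataFrame(np.full((len(idx), len(cols)), np.nan), idx, cols)
        prov = pd.DataFrame(
            np.full((len(idx), len(cols)), PROV_ORIGINAL, dtype=np.int8), idx, cols
        )
        return cls(calls, conf, prov)


@dataclass
class SignalSummary:
    """Contrast/size summaries of two-channel intensities.

    ``contrast`` and ``size`` are probeset x sample frames averaged across
    replicate probes; ``replicate_contrast`` keeps the per-replicate contrast
    (MultiIndex rows: probeset_id, probe_replicate_index) for the rare-het
    replicate-consistency test.
    """

    contrast: pd.DataFrame
    size: pd.DataFrame
    replicate_contrast: pd.DataFrame

    @property
    def probesets(self) -> pd.Index:
        return self.contrast.index

    @property
    def samples(self) -> pd.Index:
        return self.contrast.columns


@dataclass
class ClusterModel:
    """Per-probeset, per-batch 3-component Gaussian mixture in contrast.

    ``params`` is indexed by (probeset_id, batch_id) with columns
    ``mean_AA mean_AB mean_BB var_AA var_AB var_BB w_AA w_AB w_BB converged``.
    Cluster means satisfy mean_AA > mean_AB > mean_BB.
    """

    params: pd.DataFrame

    _MEAN_COLS = [f"mean_{g}" for g in GENOTYPE_ORDER]
    _VAR_COLS = [f"var_{g}" for g in GENOTYPE_ORDER]
    _W_COLS = [f"w_{g}" for g in GENOTYPE_ORDER]

    def row(self, probeset_id: str, batch_id: str) -> pd.Series:
        return self.params.loc[(probeset_id, batch_id)]

    def means(self, probeset_id: str, batch_id: str) -> np.ndarray:
        return self.row(probeset_id, batch_id)[self._MEAN_COLS].to_numpy(float)

    def variances(self, probeset_id: str, batch_id: str) -> np.ndarray:
        return self.row(probeset_id, batch_id)[self._VAR_COLS].to_numpy(float)

    def weights(self, probeset_id: str, batch_id: str) -> np.ndarray:
        return self.row(probeset_id, batch_id)[self._W_COLS].to_numpy(float)

    def batch_arrays(self, probesets: pd.Index, batch_id: str):
        """(means, variances, weights, converged) stacked over ``probesets``."""
        sub = self.params.xs(batch_id, level="batch_id").loc[probesets]
        return (
            sub[self._MEAN_COLS].to_numpy(float),
            sub[self._VAR_COLS].to_numpy(float),
            sub[self._W_COLS].to_numpy(float),
            sub["converged"].to_numpy(bool),
        )


@dataclass
class GroundTruth:
    """Truth bookkeeping for a simulated experiment.

    ``genotypes`` holds the true genotype codes; ``signal_genotypes`` the
    genotypes the signal model actually drew from (they differ only for
    cross-hybridizing probesets). Every injected pathology is recorded.
    """

    genotypes: pd.DataFrame
    signal_genotypes: pd.DataFrame
    artifact_cells: pd.DataFrame
    shifted_plates: dict[str, float]
    shift_channel: str
    cross_hyb_probesets: list[str]
    true_maf: pd.Series
    contamination_maf: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
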