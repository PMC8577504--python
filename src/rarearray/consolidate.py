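"""Merge the two adjustment tracks and account for what changed.

The rare het adjustment and the advanced normalization both start from the
same base calls and run independently. Consolidation is cell-wise:

* neither track changed the cell -> keep the base call;
* exactly one track changed it -> keep that change;
* both changed it to the same call -> keep it;
* both changed it and they disagree -> NoCall with provenance "conflict".

Adjustment accounting classifies every variant that carried at least one
heterozygous call before adjustment into three exclusive categories:
adjusted to wild-type (no minor-allele call remains), het count modified
(changed, but minor-allele calls remain), or unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rarearray.types import (
    AB,
    BB,
    NOCALL,
    PROV_CONFLICT,
    PROV_RAREHET,
    GenotypeMatrix,
)
from rarearray._round import percent

__all__ = ["AdjustmentSummary", "consolidate", "summarize_adjustments"]


def consolidate(
    calls_rarehet: GenotypeMatrix,
    calls_advnorm: GenotypeMatrix,
    base: GenotypeMatrix,
) -> GenotypeMatrix:
    """Cell-wise merge of the two adjusted matrices against the base calls."""
    if not (base.aligned_with(calls_rarehet) and base.aligned_with(calls_advnorm)):
        raise ValueError("genotype matrices do not cover identical cells")

    b = base.calls.to_numpy()
    r = calls_rarehet.calls.to_numpy()
    a = calls_advnorm.calls.to_numpy()
    changed_r = r != b
    changed_a = a != b
    conflict = changed_r & changed_a & (r != a)
    take_r = changed_r & ~conflict
    take_a = changed_a & ~changed_r  # advnorm-only changes

    calls = b.copy()
    calls[take_r] = r[take_r]
    calls[take_a] = a[take_a]
    calls[conflict] = NOCALL

    conf = base.confidence.to_numpy().copy()
    conf[take_r] = calls_rarehet.confidence.to_numpy()[take_r]
    conf[take_a] = calls_advnorm.confidence.to_numpy()[take_a]
    conf[conflict] = np.nan

    prov = base.provenance.to_numpy().copy()
    prov[take_r] = calls_rarehet.provenance.to_numpy()[take_r]
    prov[take_a] = calls_advnorm.provenance.to_numpy()[take_a]
    # both changed to the same call: rarehet only ever demotes, so a shared
    # change to NoCall is credited to rarehet, anything else to advnorm
    both_same = changed_r & changed_a & ~conflict
    prov[both_same & (r == NOCALL)] = PROV_RAREHET
    prov[conflict] = PROV_CONFLICT

    idx, cols = base.calls.index, base.calls.columns
    return GenotypeMatrix(
        pd.DataFrame(calls, idx, cols),
        pd.DataFrame(conf, idx, cols),
        pd.DataFrame(prov, idx, cols),
    )


@dataclass(frozen=True)
class AdjustmentSummary:
    """Counts and percentages of per-variant adjustment outcomes.

    Percentages are relative to ``n_variants_with_het`` (variants with at
    least one AB call before adjustment), rounded half-up to 2 decimals.
    """

    n_variants_with_het: int
    n_adjusted_to_wildtype: int
    n_het_count_modified: int
    n_unchanged: int

    def __post_init__(self) -> None:
        total = (
            self.n_adjusted_to_wildtype + self.n_het_count_modified + self.n_unchanged
        )
        if total != self.n_variants_with_het:
            raise ValueError(
                "adjustment categories do not partition the het-bearing variants: "
                f"{self.n_adjusted_to_wildtype} + {self.n_het_count_modified} + "
                f"{self.n_unchanged} != {self.n_variants_with_het}"
            )

    @property
    def n_adjusted(self) -> int:
        """Variants changed in any way by the algorithms."""
        return self.n_adjusted_to_wildtype + self.n_het_count_modified

    @property
    def pct_adjusted(self) -> float | None:
        return percent(self.n_adjusted, self.n_variants_with_het)

    @property
    def pct_adjusted_to_wildtype(self) -> float | None:
        return percent(self.n_adjusted_to_wildtype, self.n_variants_with_het)

    @property
    def pct_het_count_modified(self) -> float | None:
        return percent(self.n_het_count_modified, self.n_variants_with_het)

    @property
    def pct_unchanged(self) -> float | None:
        return percent(self.n_unchanged, self.n_variants_with_het)

    def as_dict(self) -> dict:
        return {
            "n_variants_with_het": self.n_variants_with_het,
            "n_adjusted": self.n_adjusted,
            "n_adjusted_to_wildtype": self.n_adjusted_to_wildtype,
            "n_het_count_modified": self.n_het_count_modified,
            "n_unchanged": self.n_unchanged,
            "pct_adjusted": self.pct_adjusted,
            "pct_adjusted_to_wildtype": self.pct_adjusted_to_wildtype,
            "pct_het_count_modified": self.pct_het_count_modified,
            "pct_unchanged": self.pct_unchanged,
        }

    def report_block(self) -> str:
        d = self.as_dict()
        lines = [f"variants with >=1 het call: {d['n_variants_with_het']}"]
        for key in ("adjusted", "adjusted_to_wildtype", "het_count_modified", "unchanged"):
            lines.append(
                f"  {key.replace('_', ' ')}: {d['n_' + key]}"
                f" ({d['pct_' + key]}%)"
            )
        return "\n".join(lines)


def summarize_adjustments(
    base: GenotypeMatrix, final: GenotypeMatrix
) -> AdjustmentSummary:
    """Classify het-bearing variants by what the adjustments did to them."""
    if not base.aligned_with(final):
        raise ValueError("genotype matrices do not cover identical cells")
    b = base.calls.to_numpy()
    f = final.calls.to_numpy()
    het_before = (b == AB).sum(axis=1)
    het_after = (f == AB).sum(axis=1)
    minor_after = ((f == AB) | (f == BB)).sum(axis=1)

    with_het = het_before > 0
    wildtype = with_het & (minor_after == 0)
    modified = with_het & ~wildtype & (het_after != het_before)
    unchanged = with_het & ~wildtype & ~modified
    return AdjustmentSummary(
        n_variants_with_het=int(with_het.sum()),
        n_adjusted_to_wildtype=int(wildtype.sum()),
        n_het_count_modified=int(modified.sum()),
        n_unchanged=int(unchanged.sum()),
    )
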