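"""Disease-panel screening evaluation: MAF-binned PPV/NPV bookkeeping.

Positive calls (heterozygous or homozygous-alternate on panel variants) form
the validation worklist; each row is confirmed or refuted by the gold
standard (wet-lab confirmation in real data, simulation truth in synthetic
runs). Reference-MAF bins follow the two screening bins: MAF <= 0.01% and
0.01% < MAF <= 1%. NPV is evaluated over a seeded random sample of negative
(wild-type) calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rarearray._round import percent
from rarearray.types import AA, AB, BB, CALL_LABELS, GenotypeMatrix

__all__ = [
    "BIN_LOW",
    "BIN_HIGH",
    "BIN_NOT_RARE",
    "ScreeningReport",
    "bin_by_maf",
    "export_validation_list",
    "sample_negative_calls",
    "ppv",
    "npv",
    "evaluate_screening",
]

BIN_LOW = "MAF<=0.01%"
BIN_HIGH = "0.01%<MAF<=1%"
BIN_NOT_RARE = "not_rare"
BIN_UNBINNED = "unbinned"

SCREENING_BINS = (BIN_HIGH, BIN_LOW)

_MINOR_CALLS = (AB, BB)


def bin_by_maf(variants, ref_mafs: pd.Series) -> pd.Series:
    """Assign each variant to a screening MAF bin on its reference MAF.

    The 0.01% boundary belongs to the lower bin; MAFs above 1% are outside
    the rare-variant regime and map to ``not_rare``; variants without a
    reference MAF map to ``unbinned``.
    """
    idx = pd.Index(variants, name="variant_id")
    maf = ref_mafs.reindex(idx).astype(float)
    out = pd.Series(BIN_UNBINNED, index=idx, name="maf_bin", dtype=object)
    known = maf.notna()
    out[known & (maf <= 1e-4)] = BIN_LOW
    out[known & (maf > 1e-4) & (maf <= 1e-2)] = BIN_HIGH
    out[known & (maf > 1e-2)] = BIN_NOT_RARE
    return out


def export_validation_list(
    final: GenotypeMatrix, panels: pd.DataFrame
) -> pd.DataFrame:
    """Worklist of minor-allele calls on panel variants needing confirmation.

    ``panels`` has columns ``panel`` and ``variant_id``; panels may overlap,
    in which case a call appears once per panel.
    """
    c = final.calls
    rows = []
    for panel_name, grp in panels.groupby("panel", sort=True):
        members = [v for v in grp["variant_id"] if v in c.index]
        if not members:
            continue
        sub = c.loc[members]
        mask = sub.isin(_MINOR_CALLS)
        stacked = sub.where(mask).stack().astype(int)
        for (variant_id, sample_id), code in stacked.items():
            rows.append(
                {
                    "panel": panel_name,
                    "variant_id": variant_id,
                    "sample_id": sample_id,
                    "call": CALL_LABELS[code],
                }
            )
    return pd.DataFrame(rows, columns=["panel", "variant_id", "sample_id", "call"])


def sample_negative_calls(
    final: GenotypeMatrix,
    panels: pd.DataFrame,
    fraction: float = 0.0135,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded random sample of wild-type (AA) calls on panel variants.

    The sampled fraction defaults to the 1.35% of negative calls checked for
    NPV estimation.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction={fraction}: must be in [0, 1]")
    rng = np.random.default_rng(seed)
    c = final.calls
    rows = []
    for panel_name, grp in panels.groupby("panel", sort=True):
        members = [v for v in grp["variant_id"] if v in c.index]
        if not members:
            continue
        sub = c.loc[members]
        neg = sub.where(sub == AA).stack()
        n_pick = int(round(fraction * len(neg)))
        if n_pick == 0:
            continue
        picked = rng.choice(len(neg), size=n_pick, replace=False)
        for pos in sorted(picked):
            variant_id, sample_id = neg.index[pos]
            rows.append(
                {
                    "panel": panel_name,
                    "variant_id": variant_id,
                    "sample_id": sample_id,
                    "call": "AA",
                }
            )
    return pd.DataFrame(rows, columns=["panel", "variant_id", "sample_id", "call"])


def ppv(tp: int, fp: int) -> float | None:
    """Positive predictive value as a percentage (2 decimals, half-up)."""
    return percent(tp, tp + fp)


def npv(tn: int, fn: int) -> float | None:
    """Negative predictive value as a percentage (2 decimals, half-up)."""
    return percent(tn, tn + fn)


@dataclass
class ScreeningReport:
    """Per-panel, per-MAF-bin confusion counts and predictive values."""

    table: pd.DataFrame

    def as_records(self) -> list[dict]:
        return self.table.reset_index().to_dict(orient="records")

    def cell(self, panel: str, maf_bin: str) -> pd.Series:
        return self.table.loc[(panel, maf_bin)]


def _is_minor(genotypes: pd.Series) -> pd.Series:
    return genotypes.isin(["AB", "BB"])


def evaluate_screening(
    worklist: pd.DataFrame,
    gold_standard: pd.DataFrame,
    bins: pd.Series,
    negatives: pd.DataFrame | None = None,
) -> ScreeningReport:
    """Confront the worklist (and sampled negatives) with the gold standard.

    * TP: minor-allele call with a confirmed minor-allele genotype;
    * FP: minor-allele call refuted (gold standard wild-type);
    * TN / FN: analogous over the sampled negative calls.

    Every worklist and negative row must be covered by the gold standard.
    PPV/NPV are percentages rounded half-up to 2 decimals; a zero
    denominator yields None with the matching ``*_defined`` flag False.
    """
    gold = gold_standard.set_index(["sample_id", "variant_id"])["confirmed_genotype"]
    if gold.index.has_duplicates:
        raise ValueError("gold standard has duplicate (sample, variant) rows")

    def lookup(frame: pd.DataFrame, label: str) -> pd.Series:
        key = pd.MultiIndex.from_frame(frame[["sample_id", "variant_id"]])
        confirmed = gold.reindex(key)
        if confirmed.isna().any():
            missing = [tuple(t) for t in key[confirmed.isna()][:10]]
            raise ValueError(f"{label} rows missing from gold standard: {missing}")
        return pd.Series(confirmed.to_numpy(), index=frame.index)

    counts: dict[tuple[str, str], dict[str, int]] = {}
    panels = sorted(set(worklist.get("panel", pd.Series(dtype=object))).union(
        set(negatives.get("panel", pd.Series(dtype=object))) if negatives is not None else set()
    ))
    for panel in panels:
        for maf_bin in SCREENING_BINS:
            counts[(panel, maf_bin)] = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}

    if len(worklist):
        confirmed = lookup(worklist, "worklist")
        minor = _is_minor(confirmed)
        wbins = bins.reindex(worklist["variant_id"]).to_numpy()
        for panel, maf_bin, is_tp in zip(worklist["panel"], wbins, minor):
            if maf_bin not in SCREENING_BINS:
                continue
            counts[(panel, maf_bin)]["TP" if is_tp else "FP"] += 1

    if negatives is not None and len(negatives):
        confirmed = lookup(negatives, "negative sample")
        minor = _is_minor(confirmed)
        nbins = bins.reindex(negatives["variant_id"]).to_numpy()
        for panel, maf_bin, is_fn in zip(negatives["panel"], nbins, minor):
            if maf_bin not in SCREENING_BINS:
                continue
            counts[(panel, maf_bin)]["FN" if is_fn else "TN"] += 1

    records = []
    for (panel, maf_bin), c in counts.items():
        p = ppv(c["TP"], c["FP"])
        n = npv(c["TN"], c["FN"])
        records.append(
            {
                "panel": panel,
                "maf_bin": maf_bin,
                **c,
                "PPV": p,
                "ppv_defined": p is not None,
                "NPV": n,
                "npv_defined": n is not None,
            }
        )
    table = pd.DataFrame(
        records,
        columns=[
            "panel",
            "maf_bin",
            "TP",
            "FP",
            "TN",
            "FN",
            "PPV",
            "ppv_defined",
            "NPV",
            "npv_defined",
        ],
    )
    return ScreeningReport(table.set_index(["panel", "maf_bin"]))
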