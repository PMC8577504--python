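"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated with a header row; columns are documented in
FORMATS.md. Writers are deterministic (fixed column order, fixed float
formatting) so that identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rarearray.types import (
    CALL_LABELS,
    GenotypeMatrix,
    GroundTruth,
)

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_intensities",
    "read_manifest",
    "read_annotation",
    "read_ref_maf",
    "read_genotypes",
    "write_genotypes",
    "write_truth",
    "read_truth",
    "read_gold_standard",
    "panels_from_annotation",
    "write_vcf",
    "sha256_file",
]

FLOAT_FORMAT = "%.10g"

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def _require_columns(frame: pd.DataFrame, columns: set[str], what: str) -> None:
    missing = columns - set(frame.columns)
    if missing:
        raise ValueError(f"{what} missing columns: {sorted(missing)}")


def read_intensities(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype={"probeset_id": str, "sample_id": str})
    _require_columns(
        frame,
        {"probeset_id", "probe_replicate_index", "sample_id", "channel_A", "channel_B"},
        "intensity table",
    )
    return frame


def read_manifest(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype=str)
    _require_columns(frame, {"sample_id", "plate_id", "batch_id"}, "sample manifest")
    return frame


def read_annotation(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype={"probeset_id": str, "chrom": str, "panel": str})
    _require_columns(
        frame,
        {"probeset_id", "rsid", "chrom", "pos", "ref", "alt", "n_replicate_probes"},
        "probeset annotation",
    )
    if "panel" in frame.columns:
        frame["panel"] = frame["panel"].fillna("")
    return frame


def read_ref_maf(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype={"variant_id": str})
    _require_columns(frame, {"variant_id", "ref_maf"}, "reference MAF table")
    return frame


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    write_tsv(matrix.to_long(), path)


def read_genotypes(path) -> GenotypeMatrix:
    frame = read_tsv(path, dtype={"probeset_id": str, "sample_id": str})
    return GenotypeMatrix.from_long(frame)


def read_gold_standard(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype=str)
    _require_columns(
        frame, {"sample_id", "variant_id", "confirmed_genotype"}, "gold standard"
    )
    return frame


def panels_from_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """panel/variant membership table from the annotation's panel column.

    A probeset may belong to several panels, separated by ``;``.
    """
    rows = []
    for probeset_id, panel in zip(annotation["probeset_id"], annotation.get("panel", "")):
        if not isinstance(panel, str) or not panel:
            continue
        for name in panel.split(";"):
            name = name.strip()
            if name:
                rows.append({"panel": name, "variant_id": probeset_id})
    return pd.DataFrame(rows, columns=["panel", "variant_id"])


# --- ground truth -----------------------------------------------------------


def write_truth(truth: GroundTruth, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geno = truth.genotypes.stack().map(CALL_LABELS).rename("genotype").reset_index()
    geno.columns = ["probeset_id", "sample_id", "genotype"]
    write_tsv(geno, directory / "truth_genotypes.tsv")
    write_tsv(truth.artifact_cells, directory / "truth_artifacts.tsv")
    meta = {
        "shifted_plates": truth.shifted_plates,
        "shift_channel": truth.shift_channel,
        "cross_hyb_probesets": truth.cross_hyb_probesets,
        "true_maf": {k: float(v) for k, v in truth.true_maf.items()},
        "contamination_maf": {k: float(v) for k, v in truth.contamination_maf.items()},
    }
    (directory / "truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_truth(directory) -> GroundTruth:
    directory = Path(directory)
    geno = read_tsv(directory / "truth_genotypes.tsv", dtype=str)
    codes = {v: k for k, v in CALL_LABELS.items()}
    genotypes = (
        geno.assign(code=geno["genotype"].map(codes).astype(np.int8))
        .pivot(index="probeset_id", columns="sample_id", values="code")
        .astype(np.int8)
    )
    artifacts = read_tsv(directory / "truth_artifacts.tsv")
    meta = json.loads((directory / "truth.json").read_text())
    return GroundTruth(
        genotypes=genotypes,
        signal_genotypes=genotypes,
        artifact_cells=artifacts,
        shifted_plates=meta["shifted_plates"],
        shift_channel=meta["shift_channel"],
        cross_hyb_probesets=meta["cross_hyb_probesets"],
        true_maf=pd.Series(meta["true_maf"], name="true_maf").rename_axis("probeset_id"),
        contamination_maf=pd.Series(
            meta["contamination_maf"], name="contamination_maf", dtype=float
        ).rename_axis("probeset_id"),
    )


def truth_gold_standard(truth: GroundTruth) -> pd.DataFrame:
    """Gold-standard confirmation table backed by simulation truth."""
    geno = truth.genotypes.stack().map(CALL_LABELS).rename("confirmed_genotype")
    out = geno.reset_index()
    out.columns = ["variant_id", "sample_id", "confirmed_genotype"]
    return out[["sample_id", "variant_id", "confirmed_genotype"]]


# --- VCF --------------------------------------------------------------------


def write_vcf(final: GenotypeMatrix, annotation: pd.DataFrame, path, source: str = "rarearray") -> int:
    """Write consolidated calls as VCF 4.2 (GT plus a provenance FORMAT tag).

    Positions are 1-based from the annotation. Variants lacking coordinates
    are skipped with a warning. Returns the number of records written.
    """
    from rarearray.types import PROV_LABELS

    ann = annotation.set_index("probeset_id")
    samples = list(final.samples)
    records = []
    for probeset_id in final.probesets:
        if probeset_id not in ann.index:
            warnings.warn(f"no annotation for {probeset_id}; skipped in VCF")
            continue
        row = ann.loc[probeset_id]
        if pd.isna(row["chrom"]) or pd.isna(row["pos"]):
            warnings.warn(f"missing coordinates for {probeset_id}; skipped in VCF")
            continue
        calls = final.calls.loc[probeset_id]
        provs = final.provenance.loc[probeset_id]
        sample_fields = [
            f"{_VCF_GT[int(calls[s])]}:{PROV_LABELS[int(provs[s])]}" for s in samples
        ]
        records.append(
            (
                str(row["chrom"]),
                int(row["pos"]),
                "\t".join(
                    [
                        str(row["chrom"]),
                        str(int(row["pos"])),
                        str(row["rsid"]) if pd.notna(row["rsid"]) else probeset_id,
                        str(row["ref"]),
                        str(row["alt"]),
                        ".",
                        ".",
                        f"PROBESET={probeset_id}",
                        "GT:PV",
                    ]
                    + sample_fields
                ),
            )
        )
    records.sort(key=lambda t: (t[0], t[1]))
    contigs = sorted({r[0] for r in records})

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=PROBESET,Number=1,Type=String,Description="Array probeset id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=PV,Number=1,Type=String,Description='
            '"Adjustment provenance (original/rarehet/advnorm/conflict)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        if samples:
            fh.write("\t" + "\t".join(samples))
        fh.write("\n")
        for _, _, line in records:
            fh.write(line + "\n")
    return len(records)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def dump_yaml(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
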