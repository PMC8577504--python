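"""Simulation of two-channel array experiments with known ground truth.

The signal model is log2-normal per genotype cluster: for a probeset with
contrast separation ``c`` and mean size ``s`` the channel log2-means are

* AA: (s + c/2, s - c/2)   -> contrast +c
* AB: (s, s)               -> contrast 0
* BB: (s - c/2, s + c/2)   -> contrast -c

Raw linear intensities are ``2**x`` of those draws. Pathologies:

* **artifacts** ("bubble/scratch"): a randomly chosen replicate probe of a
  randomly chosen cell gets one channel multiplied by a heavy factor,
  producing an extremely high signal on that channel;
* **plate shifts** (batch effect): all probes of samples on designated
  plates get a constant additive log2 shift on the configured channel(s);
* **cross-hybridization**: the signal model of flagged probesets draws from
  genotypes at a contamination MAF decoupled from the true MAF, so the
  array-derived allele frequency disagrees with the reference.

Random streams for genotypes, channel noise, artifacts and contamination are
spawned independently from the one config seed, so toggling a pathology off
leaves every other draw bit-identical — this is what makes the pathology
bookkeeping verifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from rarearray.types import AA, AB, BB, GroundTruth

__all__ = [
    "ProbesetSpec",
    "SimulationConfig",
    "simulate_experiment",
    "simulate_reference_maf",
    "random_probeset_specs",
]

RARE_MAF_LIMIT = 0.01  # rare-variant regime: MAF < 1%


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class ProbesetSpec:
    """Signal-model description of one probeset (one interrogated variant)."""

    probeset_id: str
    true_maf: float
    n_replicate_probes: int = 3
    contrast_separation: float = 3.0
    mean_size: float = 10.0
    channel_sd: float = 0.18
    cross_hyb: bool = False
    contamination_maf: float = 0.0
    panel: str = ""
    rsid: str = ""
    chrom: str = "1"
    pos: int = 0
    ref: str = "A"
    alt: str = "G"

    def validate(self) -> None:
        if not (0.0 <= self.true_maf < RARE_MAF_LIMIT):
            raise ConfigurationError(
                f"true_maf={self.true_maf} for {self.probeset_id}: must be in [0, 0.01)"
            )
        if self.n_replicate_probes < 1:
            raise ConfigurationError(
                f"n_replicate_probes={self.n_replicate_probes} for {self.probeset_id}: must be >= 1"
            )
        if self.contrast_separation <= 0:
            raise ConfigurationError(
                f"contrast_separation={self.contrast_separation} for {self.probeset_id}:"
                " AA and BB cluster means must be distinct"
            )
        if self.channel_sd <= 0:
            raise ConfigurationError(
                f"channel_sd={self.channel_sd} for {self.probeset_id}: must be > 0"
            )
        if self.cross_hyb and not (0.0 <= self.contamination_maf < 1.0):
            raise ConfigurationError(
                f"contamination_maf={self.contamination_maf} for {self.probeset_id}:"
                " must be a frequency"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment."""

    n_samples: int
    n_plates: int
    probeset_specs: tuple[ProbesetSpec, ...]
    seed: int
    plates_per_batch: int = 24
    artifact_rate: float = 0.0
    artifact_factor_range: tuple[float, float] = (4.0, 16.0)
    batch_shift: dict[str, float] = field(default_factory=dict)
    shift_channel: str = "A"

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError(f"n_samples={self.n_samples}: must be > 0")
        if self.n_plates <= 0:
            raise ConfigurationError(f"n_plates={self.n_plates}: must be > 0")
        if self.plates_per_batch < 1:
            raise ConfigurationError(
                f"plates_per_batch={self.plates_per_batch}: must be >= 1"
            )
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ConfigurationError(
                f"artifact_rate={self.artifact_rate}: must be in [0, 1)"
            )
        lo, hi = self.artifact_factor_range
        if not (1.0 < lo <= hi):
            raise ConfigurationError(
                f"artifact_factor_range={self.artifact_factor_range}: need 1 < lo <= hi"
            )
        if self.shift_channel not in ("A", "B", "both"):
            raise ConfigurationError(
                f"shift_channel={self.shift_channel!r}: must be 'A', 'B' or 'both'"
            )
        if not self.probeset_specs:
            raise ConfigurationError("probeset_specs: at least one probeset required")
        seen: set[str] = set()
        for spec in self.probeset_specs:
            spec.validate()
            if spec.probeset_id in seen:
                raise ConfigurationError(
                    f"probeset_specs: duplicate probeset_id {spec.probeset_id}"
                )
            seen.add(spec.probeset_id)
        plate_ids = set(self.plate_ids())
        for plate in self.batch_shift:
            if plate not in plate_ids:
                raise ConfigurationError(f"batch_shift: unknown plate {plate}")

    # -- layout ------------------------------------------------------------
    def sample_ids(self) -> list[str]:
        width = max(4, len(str(self.n_samples)))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]

    def plate_ids(self) -> list[str]:
        return [f"P{i:03d}" for i in range(1, self.n_plates + 1)]

    def manifest(self) -> pd.DataFrame:
        """sample -> plate -> batch layout (samples split evenly over plates)."""
        samples = self.sample_ids()
        plates = self.plate_ids()
        plate_of = [plates[i * self.n_plates // self.n_samples] for i in range(self.n_samples)]
        batch_of = [
            f"B{(int(p[1:]) - 1) // self.plates_per_batch + 1:03d}" for p in plate_of
        ]
        return pd.DataFrame(
            {"sample_id": samples, "plate_id": plate_of, "batch_id": batch_of}
        )

    def annotation(self) -> pd.DataFrame:
        rows = []
        for i, spec in enumerate(self.probeset_specs):
            rows.append(
                {
                    "probeset_id": spec.probeset_id,
                    "rsid": spec.rsid or f"rs{900000 + i}",
                    "chrom": spec.chrom,
                    "pos": spec.pos or (10_000 + 1_000 * i),
                    "ref": spec.ref,
                    "alt": spec.alt,
                    "n_replicate_probes": spec.n_replicate_probes,
                    "panel": spec.panel,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        specs: list[ProbesetSpec] = []
        for entry in raw.pop("probesets", []) or []:
            specs.append(ProbesetSpec(**entry))
        gen = raw.pop("probeset_grid", None)
        if gen is not None:
            seed = raw.get("seed")
            if seed is None:
                raise ConfigurationError("seed: required in simulation config")
            specs.extend(random_probeset_specs(seed=int(seed) + 1, **gen))
        if "seed" not in raw:
            raise ConfigurationError("seed: required in simulation config")
        if "batch_shift" in raw and raw["batch_shift"] is not None:
            shift = dict(raw["batch_shift"])
            raw["shift_channel"] = shift.pop("channel", raw.get("shift_channel", "A"))
            raw["batch_shift"] = {str(k): float(v) for k, v in shift.pop("plates", {}).items()}
            if shift:
                raise ConfigurationError(f"batch_shift: unknown keys {sorted(shift)}")
        if "artifact_factor_range" in raw and raw["artifact_factor_range"] is not None:
            raw["artifact_factor_range"] = tuple(raw["artifact_factor_range"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(probeset_specs=tuple(specs), **{k: v for k, v in raw.items()})
        cfg.validate()
        return cfg


def random_probeset_specs(
    n: int,
    seed: int,
    maf_range: tuple[float, float] = (0.001, 0.009),
    n_cross_hyb: int = 0,
    contamination_factor: float = 8.0,
    n_replicate_probes: int = 3,
    contrast_separation: float = 3.0,
    channel_sd: float = 0.18,
    panel: str = "",
    prefix: str = "AX",
) -> list[ProbesetSpec]:
    """Convenience generator of ``n`` probeset specs with MAFs in a range.

    The first ``n_cross_hyb`` probesets are marked cross-hybridizing with a
    contamination MAF of ``contamination_factor`` times the true MAF (capped
    just under 1).
    """
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    mafs = rng.uniform(lo, hi, size=n)
    specs = []
    for i, maf in enumerate(mafs):
        cross = i < n_cross_hyb
        specs.append(
            ProbesetSpec(
                probeset_id=f"{prefix}{i + 1:05d}",
                true_maf=float(maf),
                n_replicate_probes=n_replicate_probes,
                contrast_separation=contrast_separation,
                channel_sd=channel_sd,
                cross_hyb=cross,
                contamination_maf=min(float(maf) * contamination_factor, 0.999) if cross else 0.0,
                panel=panel,
            )
        )
    return specs


# ---------------------------------------------------------------------------


def _draw_genotypes(rng: np.random.Generator, maf: float, n: int) -> np.ndarray:
    """Hardy-Weinberg genotype draw at minor allele frequency ``maf``."""
    p_bb = maf * maf
    p_ab = 2.0 * maf * (1.0 - maf)
    u = rng.random(n)
    geno = np.full(n, AA, dtype=np.int8)
    geno[u < p_ab + p_bb] = AB
    geno[u < p_bb] = BB
    return geno


def _cluster_log2_means(spec: ProbesetSpec) -> np.ndarray:
    """(3, 2) array of (log2 A, log2 B) cluster means for AA, AB, BB."""
    c, s = spec.contrast_separation, spec.mean_size
    return np.array(
        [[s + c / 2.0, s - c / 2.0], [s, s], [s - c / 2.0, s + c / 2.0]]
    )


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an array experiment.

    Returns
    -------
    intensities
        Long frame: probeset_id, probe_replicate_index, sample_id,
        channel_A, channel_B (raw linear intensities).
    annotation
        Probeset annotation frame.
    truth
        :class:`~rarearray.types.GroundTruth` recording genotypes and every
        injected pathology.
    """
    config.validate()
    manifest = config.manifest()
    samples = manifest["sample_id"].to_numpy()
    n = len(samples)

    geno_rng, noise_rng, artifact_rng, contam_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    )

    probeset_ids = [spec.probeset_id for spec in config.probeset_specs]
    true_geno = {}
    signal_geno = {}
    blocks: list[pd.DataFrame] = []

    for spec in config.probeset_specs:
        g_true = _draw_genotypes(geno_rng, spec.true_maf, n)
        if spec.cross_hyb:
            g_signal = _draw_genotypes(contam_rng, spec.contamination_maf, n)
        else:
            g_signal = g_true
        true_geno[spec.probeset_id] = g_true
        signal_geno[spec.probeset_id] = g_signal

        m = spec.n_replicate_probes
        means = _cluster_log2_means(spec)[g_signal]  # (n, 2)
        noise = noise_rng.normal(0.0, spec.channel_sd, size=(m, n, 2))
        log2_sig = means[None, :, :] + noise  # (m, n, 2)

        rep_idx = np.repeat(np.arange(1, m + 1), n)
        blocks.append(
            pd.DataFrame(
                {
                    "probeset_id": spec.probeset_id,
                    "probe_replicate_index": rep_idx,
                    "sample_id": np.tile(samples, m),
                    "channel_A": np.exp2(log2_sig[:, :, 0]).ravel(),
                    "channel_B": np.exp2(log2_sig[:, :, 1]).ravel(),
                }
            )
        )

    intensities = pd.concat(blocks, ignore_index=True)

    # --- bubble/scratch artifacts: one replicate, one channel, heavy factor
    artifact_rows = []
    if config.artifact_rate > 0:
        lo, hi = config.artifact_factor_range
        for spec in config.probeset_specs:
            hit = artifact_rng.random(n) < config.artifact_rate
            for j in np.flatnonzero(hit):
                rep = int(artifact_rng.integers(1, spec.n_replicate_probes + 1))
                channel = "A" if artifact_rng.random() < 0.5 else "B"
                factor = float(artifact_rng.uniform(lo, hi))
                artifact_rows.append(
                    {
                        "probeset_id": spec.probeset_id,
                        "sample_id": samples[j],
                        "probe_replicate_index": rep,
                        "channel": channel,
                        "factor": factor,
                    }
                )
    artifact_cells = pd.DataFrame(
        artifact_rows,
        columns=["probeset_id", "sample_id", "probe_replicate_index", "channel", "factor"],
    )
    if len(artifact_cells):
        key = ["probeset_id", "probe_replicate_index", "sample_id"]
        idx = intensities.set_index(key).index
        for channel in ("A", "B"):
            sub = artifact_cells[artifact_cells["channel"] == channel]
            if not len(sub):
                continue
            locs = idx.get_indexer(
                pd.MultiIndex.from_frame(
                    sub[["probeset_id", "probe_replicate_index", "sample_id"]]
                )
            )
            col = f"channel_{channel}"
            intensities.loc[locs, col] = (
                intensities.loc[locs, col].to_numpy() * sub["factor"].to_numpy()
            )

    # --- plate-level additive log2 shift (batch effect)
    if config.batch_shift:
        plate_of = manifest.set_index("sample_id")["plate_id"]
        shift_per_sample = plate_of.map(config.batch_shift).fillna(0.0)
        mult = np.exp2(shift_per_sample.reindex(intensities["sample_id"]).to_numpy())
        if config.shift_channel in ("A", "both"):
            intensities["channel_A"] = intensities["channel_A"] * mult
        if config.shift_channel in ("B", "both"):
            intensities["channel_B"] = intensities["channel_B"] * mult

    sample_idx = pd.Index(samples, name="sample_id")
    truth = GroundTruth(
        genotypes=pd.DataFrame(true_geno, index=sample_idx).T.rename_axis("probeset_id"),
        signal_genotypes=pd.DataFrame(signal_geno, index=sample_idx).T.rename_axis(
            "probeset_id"
        ),
        artifact_cells=artifact_cells,
        shifted_plates={k: float(v) for k, v in config.batch_shift.items() if v != 0.0},
        shift_channel=config.shift_channel,
        cross_hyb_probesets=[s.probeset_id for s in config.probeset_specs if s.cross_hyb],
        true_maf=pd.Series(
            {s.probeset_id: s.true_maf for s in config.probeset_specs}, name="true_maf"
        ).rename_axis("probeset_id"),
        contamination_maf=pd.Series(
            {s.probeset_id: s.contamination_maf for s in config.probeset_specs if s.cross_hyb},
            name="contamination_maf",
            dtype=float,
        ).rename_axis("probeset_id"),
    )
    truth.genotypes = truth.genotypes.astype(np.int8).loc[probeset_ids]
    truth.signal_genotypes = truth.signal_genotypes.astype(np.int8).loc[probeset_ids]
    return intensities, config.annotation(), truth


def simulate_reference_maf(
    truth: GroundTruth, ref_cohort_size: int, seed: int
) -> pd.DataFrame:
    """Reference (sequencing-cohort) MAF table, resampled from the true MAFs.

    The reference cohort is an independent binomial draw of
    ``2 * ref_cohort_size`` alleles per variant at the true MAF — array and
    reference frequencies therefore differ by sampling noise, as they would
    between two real cohorts. Cross-hybridizing probesets keep their *true*
    MAF here, decoupled from the contaminated array signal.
    """
    if ref_cohort_size <= 0:
        raise ConfigurationError(f"ref_cohort_size={ref_cohort_size}: must be > 0")
    rng = np.random.default_rng(seed)
    alleles = 2 * ref_cohort_size
    mafs = truth.true_maf.to_numpy(float)
    counts = rng.binomial(alleles, mafs)
    return pd.DataFrame(
        {"variant_id": truth.true_maf.index, "ref_maf": counts / alleles}
    )


def clean_config(config: SimulationConfig) -> SimulationConfig:
    """The same experiment with every pathology switched off."""
    specs = tuple(
        replace(s, cross_hyb=False, contamination_maf=0.0) for s in config.probeset_specs
    )
    return replace(config, artifact_rate=0.0, batch_shift={}, probeset_specs=specs)
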