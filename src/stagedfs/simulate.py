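"""Synthetic paired expression + somatic-mutation fixtures with planted drivers.

Emulates the data regime of a bulk tumor/normal RNA-seq cohort with a matched
somatic-mutation call set: overdispersed (negative-binomial) counts, a heavy
tumor/normal class imbalance, a minority of driver genes that are both
recurrently mutated and differentially expressed, and a background of
passenger genes mutated at a low rate.  Every downstream stage of the
pipeline is testable on these fixtures without any external download.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mutation import VARIANT_TYPES, MutationRecord

# sigma of the log-normal spread of per-gene baseline means; fixed so that the
# generator's conditions are part of the package, not a tuning knob
_LOGNORMAL_SIGMA = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic tumor/normal cohort.

    Defaults mirror a down-scaled bulk cohort: strong class imbalance,
    ~2 000 genes, a small set of planted drivers that are recurrently
    mutated (15% of tumors) and 4-fold overexpressed, and passengers
    mutated at a background rate of 0.5%.
    """

    n_tumor: int = 120
    n_normal: int = 30
    n_genes: int = 2000
    n_drivers: int = 40
    baseline_mean: float = 100.0
    dispersion: float = 2.0
    driver_log2fc: float = 2.0
    driver_mut_rate: float = 0.15
    passenger_mut_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("n_tumor and n_normal must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.n_drivers <= self.n_genes:
            raise ValueError("n_drivers must satisfy 0 <= n_drivers <= n_genes")
        for name in ("driver_mut_rate", "passenger_mut_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Which genes were planted as drivers and with what effect."""

    driver_genes: frozenset[str]
    planted_log2fc: dict[str, float] = field(repr=False)
    planted_mut_rate: dict[str, float] = field(repr=False)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Named substream so each stage can be regenerated independently."""
    key = zlib.crc32(label.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _gene_symbols(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _sample_barcodes(n_tumor: int, n_normal: int) -> tuple[list[str], list[str]]:
    tum = [f"TCGA-SYN-{i:04d}-01" for i in range(1, n_tumor + 1)]
    nrm = [f"TCGA-SYN-{i:04d}-11" for i in range(n_tumor + 1, n_tumor + n_normal + 1)]
    return tum, nrm


def simulate_expression(config: SimulationConfig):
    """Simulate a genes x samples count matrix with planted driver effects.

    Counts are negative binomial with per-gene baseline means drawn
    log-normally around ``baseline_mean``; driver genes have tumor-group mean
    equal to the normal-group mean times ``2**driver_log2fc``.

    Returns
    -------
    (ExpressionMatrix, GroundTruth)
    """
    from .expression import ExpressionMatrix

    genes = _gene_symbols(config.n_genes)
    tumor_ids, normal_ids = _sample_barcodes(config.n_tumor, config.n_normal)
    samples = tumor_ids + normal_ids
    labels = pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
        index=samples,
        name="label",
    )

    rng = _substream(config.seed, "expression")
    driver_idx = rng.choice(config.n_genes, size=config.n_drivers, replace=False)
    driver_mask = np.zeros(config.n_genes, dtype=bool)
    driver_mask[driver_idx] = True

    base_mean = config.baseline_mean * np.exp(
        _LOGNORMAL_SIGMA * rng.standard_normal(config.n_genes)
    )
    tumor_mean = np.where(
        driver_mask, base_mean * 2.0**config.driver_log2fc, base_mean
    )

    shape = config.dispersion

    def _nb(mean: np.ndarray, n_cols: int) -> np.ndarray:
        p = shape / (shape + mean)
        return rng.negative_binomial(
            shape, p[:, None], size=(config.n_genes, n_cols)
        )

    counts = np.hstack([_nb(tumor_mean, config.n_tumor), _nb(base_mean, config.n_normal)])
    values = pd.DataFrame(counts, index=genes, columns=samples)

    driver_genes = frozenset(genes[i] for i in driver_idx)
    truth = GroundTruth(
        driver_genes=driver_genes,
        planted_log2fc={
            g: (config.driver_log2fc if g in driver_genes else 0.0) for g in genes
        },
        planted_mut_rate={
            g: (
                config.driver_mut_rate
                if g in driver_genes
                else config.passenger_mut_rate
            )
            for g in genes
        },
    )
    return ExpressionMatrix(values=values, labels=labels, scale="counts"), truth


def simulate_mutations(
    config: SimulationConfig, truth: GroundTruth, sample_ids
) -> list[MutationRecord]:
    """Emit MAF-like mutation records over the tumor samples.

    Each (gene, tumor sample) pair mutates independently with the gene's
    planted rate; the variant type is sampled uniformly (downstream coding is
    presence/absence, so composition is cosmetic).
    """
    sample_ids = list(sample_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids passed to simulate_mutations")
    if any(not s for s in sample_ids):
        raise ValueError("empty sample id passed to simulate_mutations")
    rng = _substream(config.seed, "mutation")
    genes = sorted(truth.planted_mut_rate)
    rates = np.array([truth.planted_mut_rate[g] for g in genes])
    hits = rng.random((len(genes), len(sample_ids))) < rates[:, None]
    variant_draw = rng.integers(0, len(VARIANT_TYPES), size=hits.shape)
    records: list[MutationRecord] = []
    gi, si = np.nonzero(hits)
    for g, s in zip(gi, si):
        records.append(
            MutationRecord(
                gene=genes[g],
                variant_type=VARIANT_TYPES[variant_draw[g, s]],
                sample=sample_ids[s],
            )
        )
    return records


def write_fixture(directory, expr, records, truth) -> dict[str, Path]:
    """Write expression/MAF/label/truth files; read-back is the identity.

    Returns the mapping of logical name -> path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "maf": directory / "mutations.maf",
        "labels": directory / "labels.tsv",
        "truth": directory / "truth.tsv",
    }

    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(paths["expression"], sep="\t")

    maf = pd.DataFrame(
        [(r.gene, r.variant_type, r.sample) for r in records],
        columns=["Hugo_Symbol", "Variant_Type", "Tumor_Sample_Barcode"],
    )
    maf.to_csv(paths["maf"], sep="\t", index=False)

    labels = expr.labels.rename_axis("sample").reset_index()
    labels.to_csv(paths["labels"], sep="\t", index=False)

    rows = [
        (g, truth.planted_log2fc[g], truth.planted_mut_rate[g])
        for g in sorted(truth.driver_genes)
    ]
    pd.DataFrame(rows, columns=["gene", "log2fc", "mut_rate"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        driver_genes=frozenset(df["gene"]),
        planted_log2fc=dict(zip(df["gene"], df["log2fc"])),
        planted_mut_rate=dict(zip(df["gene"], df["mut_rate"])),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
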