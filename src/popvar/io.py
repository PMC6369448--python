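"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as VCF (written as plain text with GT fields, read back
through cyvcf2) or as a wide TSV; intensities as a long TSV with one row
per (variant, sample); phenotype, onset, QC and quality tables as plain
TSVs; simulation configs as YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, IntensityTable
from .exceptions import DataError
from .simulate import CovariateModel, EffectSpec, OnsetModel, SimConfig, TraitSpec

__all__ = [
    "write_vcf",
    "read_vcf_genotypes",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_intensity_tsv",
    "read_intensity_tsv",
    "write_table",
    "read_table",
    "config_to_yaml",
    "config_from_yaml",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(genotypes: GenotypeMatrix, panel: pd.DataFrame, path) -> None:
    """Write observed genotypes as an uncompressed VCF with GT fields."""
    meta = panel.set_index("variant_id")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(genotypes.variant_ids):
            row = meta.loc[vid]
            gts = "\t".join(_GT_STRINGS[int(g)] for g in genotypes.genotypes[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf_genotypes(path, batch_ids=None) -> GenotypeMatrix:
    """Read GT fields from a VCF into a genotype matrix.

    ``batch_ids`` (one label per sample) may be supplied since VCF does
    not carry batch structure; defaults to a single batch.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns, ids = [], []
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    remap = np.array([0, 1, -1, 2], dtype=np.int8)
    for variant in vcf:
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(remap[variant.gt_types])
    vcf.close()
    if not columns:
        raise DataError(f"no variants in {path}")
    geno = np.column_stack(columns)
    if batch_ids is None:
        batch_ids = np.zeros(len(samples), dtype=int)
    return GenotypeMatrix(geno, samples, ids, np.asarray(batch_ids))


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Wide TSV: sample_id, batch_id, then one column per variant."""
    df = pd.DataFrame(genotypes.genotypes, columns=genotypes.variant_ids)
    df.insert(0, "batch_id", genotypes.batch_ids)
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "batch_id"}
    if not required.issubset(df.columns):
        raise DataError(f"genotype TSV must carry columns {required}")
    variant_ids = [c for c in df.columns if c not in required]
    return GenotypeMatrix(
        df[variant_ids].to_numpy(dtype=np.int8),
        df["sample_id"].astype(str).tolist(),
        variant_ids,
        df["batch_id"].to_numpy(),
    )


def write_intensity_tsv(intensities: IntensityTable, path, variant_ids=None) -> None:
    intensities.long_frame(variant_ids).to_csv(path, sep="\t", index=False)


def read_intensity_tsv(path) -> IntensityTable:
    df = pd.read_csv(path, sep="\t")
    wide_a = df.pivot(index="sample_id", columns="variant_id", values="intensity_a")
    wide_b = df.pivot(index="sample_id", columns="variant_id", values="intensity_b")
    batches = df.drop_duplicates("sample_id").set_index("sample_id")["batch_id"]
    samples = wide_a.index.tolist()
    return IntensityTable(
        a=wide_a.to_numpy(dtype=np.float32),
        b=wide_b.to_numpy(dtype=np.float32),
        sample_ids=[str(s) for s in samples],
        variant_ids=[str(v) for v in wide_a.columns],
        batch_ids=batches.loc[samples].to_numpy(),
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_to_yaml(config: SimConfig, path) -> None:
    payload = asdict(config)
    with Path(path).open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with Path(path).open() as fh:
        payload = yaml.safe_load(fh)
    if "covariate_model" in payload:
        payload["covariate_model"] = CovariateModel(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in payload["covariate_model"].items()}
        )
    if "onset_model" in payload:
        om = payload["onset_model"]
        payload["onset_model"] = OnsetModel(
            disease_id=om["disease_id"],
            baseline_knots=tuple(tuple(k) for k in om["baseline_knots"]),
            carrier_knots=tuple(tuple(k) for k in om["carrier_knots"]),
        )
    if "traits" in payload:
        payload["traits"] = tuple(TraitSpec(**t) for t in payload["traits"])
    if "effect_specs" in payload:
        payload["effect_specs"] = tuple(EffectSpec(**e) for e in payload["effect_specs"])
    for key in ("maf_range", "batch_sizes"):
        if payload.get(key) is not None:
            payload[key] = tuple(payload[key])
    if "quality_class_probs" in payload:
        payload["quality_class_probs"] = tuple(payload["quality_class_probs"])
    config = SimConfig(**payload)
    config.validate()
    return config
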