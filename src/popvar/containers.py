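"""In-memory containers shared across the pipeline.

A cohort is represented by a dense genotype matrix (samples x variants,
int8, -1 for a missing call) and, when intensity-level data are available,
a pair of equally shaped two-channel intensity matrices.  Batch labels are
carried per sample, mirroring how array genotyping is organised in plates
and batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Dense diploid genotype matrix with sample/variant/batch labels."""

    genotypes: np.ndarray  # (n_samples, n_variants) int8; -1 = missing
    sample_ids: list[str]
    variant_ids: list[str]
    batch_ids: np.ndarray  # (n_samples,) integer batch label per sample

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.batch_ids = np.asarray(self.batch_ids)
        n_s, n_v = self.genotypes.shape
        if len(self.sample_ids) != n_s or len(self.variant_ids) != n_v:
            raise DataError("genotype matrix dimensions do not match labels")
        if self.batch_ids.shape != (n_s,):
            raise DataError("one batch label per sample required")
        self._index = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.genotypes[:, self._index[variant_id]]
        except KeyError:
            raise DataError(f"unknown variant {variant_id!r}") from None

    def dosage(self, variant_id: str) -> np.ndarray:
        """Genotype column as float dosage with NaN for missing calls."""
        col = self.column(variant_id).astype(float)
        col[col == MISSING] = np.nan
        return col


@dataclass
class IntensityTable:
    """Two-channel (A/B allele) probe intensities per sample and variant."""

    a: np.ndarray  # (n_samples, n_variants) float32
    b: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    batch_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float32)
        self.b = np.asarray(self.b, dtype=np.float32)
        if self.a.shape != self.b.shape:
            raise DataError("channel matrices must share a shape")
        if self.batch_ids is None:
            raise DataError("batch assignment required for intensity data")
        self.batch_ids = np.asarray(self.batch_ids)
        self._index = {v: j for j, v in enumerate(self.variant_ids)}

    def column(self, variant_id: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            j = self._index[variant_id]
        except KeyError:
            raise DataError(f"variant {variant_id!r} absent from intensity table") from None
        return self.a[:, j].astype(float), self.b[:, j].astype(float)

    def long_frame(self, variant_ids=None) -> pd.DataFrame:
        """Tidy (variant, sample) rows, the on-disk TSV layout."""
        ids = list(self.variant_ids if variant_ids is None else variant_ids)
        frames = []
        for vid in ids:
            a, b = self.column(vid)
            frames.append(
                pd.DataFrame(
                    {
                        "variant_id": vid,
                        "sample_id": self.sample_ids,
                        "batch_id": self.batch_ids,
                        "intensity_a": a,
                        "intensity_b": b,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)
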