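"""Per-variant quality control for array-genotyped cohorts.

Computes minor-allele frequency, the exact Hardy-Weinberg test, call
missingness, and applies the rare-variant filter cascade (MAF < 1%,
polymorphic, HWE p > 0.05, missingness < 0.01).  Also provides the
batch-distribution diagnostic used to detect rare genotype calls that are
concentrated in a single genotyping batch, a signature of batch-level
assay failure.

Genotype columns are integer-coded: 0/1/2 copies of the alternate allele,
-1 (or ``numpy.nan``) for a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .exceptions import DataError

__all__ = [
    "QCMetrics",
    "BatchSkewResult",
    "QCThresholds",
    "compute_maf",
    "hwe_exact_test",
    "compute_missingness",
    "compute_qc_metrics",
    "apply_qc_filters",
    "batch_skew_check",
    "allele_count_scatter",
]

MISSING = -1


@dataclass(frozen=True)
class QCMetrics:
    """Per-variant QC summary."""

    variant_id: str
    maf: float
    hwe_p: float
    missingness: float
    n_called: int
    minor_allele_count: int


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; all comparisons are strict, matching the
    convention that a variant with MAF exactly 1%, HWE p exactly 0.05 or
    missingness exactly 0.01 is excluded."""

    max_maf: float = 0.01
    min_hwe_p: float = 0.05
    max_missingness: float = 0.01


@dataclass(frozen=True)
class BatchSkewResult:
    """Outcome of the single-batch concentration diagnostic."""

    variant_id: str
    total_rare_calls: int
    max_batch_calls: int
    max_batch_fraction: float
    binomial_p: float
    flagged: bool


def _clean_column(genotypes) -> np.ndarray:
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise DataError("genotype column must be a nonempty 1-D array")
    g = np.where(np.isnan(g), MISSING, g)
    return g.astype(np.int64)


def compute_maf(genotypes, variant_id: str = "?") -> float:
    """Minor-allele frequency of a diploid genotype column.

    The frequency is folded: the count of the rarer allele divided by
    twice the number of non-missing calls, always in [0, 0.5].
    """
    g = _clean_column(genotypes)
    called = g[g != MISSING]
    if called.size == 0:
        raise DataError(f"variant {variant_id}: all genotypes missing, MAF undefined")
    alt = int(called.sum())
    total = 2 * int(called.size)
    return min(alt, total - alt) / total


def compute_missingness(genotypes) -> float:
    """Fraction of samples with a missing call."""
    g = _clean_column(genotypes)
    return float(np.mean(g == MISSING))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test for a biallelic diploid site.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts, the probabilities that are no larger than the
    probability of the observed heterozygote count.  A monomorphic site
    returns 1.  Computed in log space so that biobank-scale counts are
    handled exactly enough (relative error << the 1e-12 acceptance slack
    used when accumulating the tail).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise DataError(f"genotype counts must be nonnegative integers, got {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise DataError("at least one genotyped sample required")
    # fold so that `rare` is the minor allele count
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0
    # possible het counts share the parity of the minor allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    rare_homs = (rare - hets) // 2
    common_homs = n - hets - rare_homs
    valid = common_homs >= 0
    hets, rare_homs, common_homs = hets[valid], rare_homs[valid], common_homs[valid]
    # log P(het = h | n, rare) up to a shared constant
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(rare_homs + 1)
        - gammaln(hets + 1)
        - gammaln(common_homs + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het]
    if p_obs.size != 1:  # pragma: no cover - inconsistent counts
        raise DataError("observed heterozygote count incompatible with allele totals")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def compute_qc_metrics(
    genotypes,
    variant_id: str = "?",
    x_linked: bool = False,
    is_female=None,
) -> QCMetrics:
    """MAF, exact HWE p, missingness and call counts for one column.

    For X-linked variants (``x_linked=True`` with a per-sample
    ``is_female`` mask), the HWE test is computed on female samples only:
    hemizygous males violate the diploid exact test and never enter the
    heterozygote count.  MAF and missingness still use all samples.
    """
    g = _clean_column(genotypes)
    called = g[g != MISSING]
    if called.size == 0:
        raise DataError(f"variant {variant_id}: all genotypes missing")
    n_het = int(np.sum(called == 1))
    n_alt = int(np.sum(called == 2))
    n_ref = int(called.size) - n_het - n_alt
    alt_count = n_het + 2 * n_alt
    mac = min(alt_count, 2 * called.size - alt_count)
    if x_linked:
        if is_female is None:
            raise DataError(f"variant {variant_id}: X-linked HWE needs is_female")
        f = g[np.asarray(is_female, dtype=bool)]
        f = f[f != MISSING]
        if f.size == 0:
            hwe_p = 1.0
        else:
            f_het = int(np.sum(f == 1))
            f_alt = int(np.sum(f == 2))
            hwe_p = hwe_exact_test(int(f.size) - f_het - f_alt, f_het, f_alt)
    else:
        hwe_p = hwe_exact_test(n_ref, n_het, n_alt)
    return QCMetrics(
        variant_id=variant_id,
        maf=mac / (2 * called.size),
        hwe_p=hwe_p,
        missingness=float(np.mean(g == MISSING)),
        n_called=int(called.size),
        minor_allele_count=int(mac),
    )


def qc_metrics_frame(genotype_matrix) -> pd.DataFrame:
    """QC metrics for every variant of a genotype matrix.

    ``genotype_matrix`` is anything with ``genotypes`` (samples x variants)
    and ``variant_ids`` attributes, or a plain 2-D array.
    """
    geno = getattr(genotype_matrix, "genotypes", genotype_matrix)
    ids = getattr(genotype_matrix, "variant_ids", None)
    geno = np.asarray(geno)
    if ids is None:
        ids = [f"var{j}" for j in range(geno.shape[1])]
    rows = [compute_qc_metrics(geno[:, j], str(ids[j])) for j in range(geno.shape[1])]
    return pd.DataFrame([r.__dict__ for r in rows])


# ordered filter cascade; a variant is annotated with its first failure
_RULES = ("common", "monomorphic", "hwe", "missingness")


def apply_qc_filters(
    metrics: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Apply the rare-variant filter cascade to a QC metrics table.

    Retains variants with ``0 < maf < max_maf``, ``hwe_p > min_hwe_p`` and
    ``missingness < max_missingness`` (strict inequalities).  Returns the
    input with two extra columns: ``excluded`` and ``reason`` (the first
    failing rule in the fixed order common -> monomorphic -> HWE ->
    missingness, empty string when retained).
    """
    t = thresholds or QCThresholds()
    out = metrics.copy()
    reasons = np.full(len(out), "", dtype=object)
    maf = out["maf"].to_numpy(dtype=float)
    hwe = out["hwe_p"].to_numpy(dtype=float)
    miss = out["missingness"].to_numpy(dtype=float)
    for rule, failing in (
        ("common", maf >= t.max_maf),
        ("monomorphic", maf <= 0),
        ("hwe", hwe <= t.min_hwe_p),
        ("missingness", miss >= t.max_missingness),
    ):
        reasons[(reasons == "") & failing] = rule
    out["excluded"] = reasons != ""
    out["reason"] = reasons
    return out


def batch_skew_check(
    rare_calls_per_batch, batch_sizes, variant_id: str = "?", alpha: float = 0.05
) -> BatchSkewResult:
    """Test whether a variant's rare genotype calls pile up in one batch.

    Under the null, each rare call lands in batch b with probability
    proportional to the batch size.  The reported p-value is the upper
    binomial tail for the batch with the most calls, Bonferroni-multiplied
    by the number of batches and capped at 1.  A variant is flagged when
    the adjusted p-value is below ``alpha`` or when every rare call comes
    from a single batch (with more than one batch present).
    """
    calls = np.asarray(rare_calls_per_batch, dtype=np.int64)
    sizes = np.asarray(batch_sizes, dtype=np.float64)
    if calls.shape != sizes.shape:
        raise DataError("rare_calls_per_batch and batch_sizes must align")
    if (calls < 0).any() or (sizes <= 0).any():
        raise DataError("negative call counts or non-positive batch sizes")
    total = int(calls.sum())
    n_batches = calls.size
    if total == 0:
        return BatchSkewResult(variant_id, 0, 0, float("nan"), 1.0, False)
    b = int(calls.argmax())
    max_calls = int(calls[b])
    prob = sizes[b] / sizes.sum()
    tail = float(binom.sf(max_calls - 1, total, prob))  # P(X >= max_calls)
    adj = min(1.0, tail * n_batches)
    single = max_calls == total and n_batches > 1
    return BatchSkewResult(
        variant_id=variant_id,
        total_rare_calls=total,
        max_batch_calls=max_calls,
        max_batch_fraction=max_calls / total,
        binomial_p=adj,
        flagged=bool(adj < alpha or single),
    )


def rare_calls_by_batch(genotypes, batch_ids) -> np.ndarray:
    """Count rare-genotype calls (dosage >= 1) per batch for one variant."""
    g = _clean_column(genotypes)
    batches = np.asarray(batch_ids)
    if batches.shape != g.shape:
        raise DataError("batch assignment missing or misaligned")
    rare = g >= 1
    labels = np.unique(batches)
    return np.array([int(np.sum(rare & (batches == b))) for b in labels])


def allele_count_scatter(genotype_matrix, batch_ids=None) -> pd.DataFrame:
    """Total minor-allele count vs maximum single-batch count, per variant.

    Produces the table behind the total-vs-max-batch allele count scatter
    used for visual outlier review; no filtering is applied.
    """
    geno = np.asarray(getattr(genotype_matrix, "genotypes", genotype_matrix))
    ids = getattr(genotype_matrix, "variant_ids", None)
    if batch_ids is None:
        batch_ids = getattr(genotype_matrix, "batch_ids", None)
    if batch_ids is None:
        raise DataError("batch assignment required")
    batches = np.asarray(batch_ids)
    if ids is None:
        ids = [f"var{j}" for j in range(geno.shape[1])]
    labels = np.unique(batches)
    onehot = batches[:, None] == labels[None, :]  # samples x batches
    alleles = np.where(geno == MISSING, 0, geno)
    # fold per variant: minor allele is the rarer one over called genotypes
    called = geno != MISSING
    alt = alleles.sum(axis=0)
    tot = 2 * called.sum(axis=0)
    use_alt = alt <= tot - alt
    rows = []
    for j, vid in enumerate(ids):
        col = alleles[:, j] if use_alt[j] else np.where(called[:, j], 2 - alleles[:, j], 0)
        per_batch = col @ onehot
        rows.append((str(vid), int(per_batch.sum()), int(per_batch.max())))
    return pd.DataFrame(rows, columns=["variant_id", "total_allele_count", "max_batch_allele_count"])
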