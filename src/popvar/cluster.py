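"""Intensity cluster-plot quality assessment for rare array variants.

Rare variants on genotyping arrays cannot be judged batch-by-batch (too
few carriers per batch), so all batches are pooled into a single cluster
plot per variant.  This module summarises such a plot statistically and
maps the summary onto the 1-5 visual-review rubric:

    1  poor quality, no discernible separate clusters
    2  poor quality, no discernible clusters and noisy data
    3  unclear / uncertain
    4  good quality, clearly separable clusters but noisy data
    5  good quality, clear separation between clusters

Scores 1-2 are grouped as low quality (likely array false positives),
3 as unclear, 4-5 as high quality.  Manual scores from human reviewers
can be ingested alongside and take precedence over the automated rubric.

Two details of the separation statistic matter for rare variants.
First, a pair of genotype clusters counts as resolved only relative to
the more dispersed member of the pair (the largest-eigenvalue SD of the
wider class), so a diffuse smear of spurious heterozygote calls drags
separation down even when the tight major cluster sits far away.
Second, a variant with fewer than a handful of rare calls carries no
visual evidence of a real second cluster, so such variants are capped at
a low score regardless of geometry - the same convention a human reviewer
applies to ultra-rare variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import MISSING, GenotypeMatrix, IntensityTable
from .exceptions import DataError

__all__ = [
    "MAF_BIN_EDGES_PCT",
    "ClusterData",
    "ClusterModel",
    "QualityAssessment",
    "RocResult",
    "ScoreThresholds",
    "assemble_cluster_data",
    "fit_cluster_model",
    "separation_statistics",
    "assign_quality_score",
    "score_variant",
    "score_panel",
    "ingest_manual_scores",
    "scorer_agreement",
    "bin_by_maf",
    "expand_bin_table",
    "fpr_at_maf_threshold",
    "roc_maf_vs_quality",
]

#: MAF bin edges in percent used for quality-by-frequency tables; bins are
#: half-open [lo, hi) except the final bin which is closed at 1%.
MAF_BIN_EDGES_PCT = (0.0, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class ClusterData:
    """Combined-batch intensity points with their genotype calls."""

    variant_id: str
    points: pd.DataFrame  # intensity_a, intensity_b, called_genotype, batch_id
    n_batches_present: int


@dataclass
class ClusterModel:
    """Gaussian summary of a cluster plot: per-called-class moments
    (mean, covariance, weight, point count)."""

    variant_id: str
    components: dict  # class -> dict(center, cov, weight, n)

    @property
    def classes_present(self) -> tuple:
        return tuple(sorted(self.components))


@dataclass(frozen=True)
class ScoreThresholds:
    """Rubric thresholds: separation below ``s_lo`` means no discernible
    clusters, above ``s_hi`` clear separation; ``noise_hi`` splits the
    clean from the noisy variant of each rubric level; ``min_rare_calls``
    is the smallest carrier count at which cluster geometry is judged at
    all (below it a variant is scored low on evidence grounds)."""

    s_lo: float = 1.5
    s_hi: float = 3.0
    noise_hi: float = 0.5
    min_rare_calls: int = 5


@dataclass(frozen=True)
class QualityAssessment:
    variant_id: str
    separation: float
    noise: float
    score: int
    group: str  # low / unclear / high
    n_rare_calls: int
    silhouette: float = float("nan")


@dataclass
class RocResult:
    auc: float
    ci: tuple
    curve_points: pd.DataFrame  # fpr, tpr, threshold_maf_pct
    fpr_at_thresholds: dict  # threshold (percent) -> FP/(FP+TP) above it


def group_from_score(score: int) -> str:
    """Integer rubric score -> low / unclear / high group."""
    if score <= 2:
        return "low"
    if score == 3:
        return "unclear"
    return "high"


def group_from_average(avg: float) -> str:
    """Averaged multi-reviewer score -> group (low < 2.5, high > 4)."""
    if avg < 2.5:
        return "low"
    if avg > 4.0:
        return "high"
    return "unclear"


# ---------------------------------------------------------------------------
# cluster assembly and model fitting


def assemble_cluster_data(
    intensities: IntensityTable, genotypes: GenotypeMatrix, variant_id: str
) -> ClusterData:
    """Merge all batches into one labeled point set for a variant."""
    a, b = intensities.column(variant_id)
    calls = genotypes.column(variant_id)
    if a.shape[0] != calls.shape[0]:
        raise DataError(f"variant {variant_id}: intensity and genotype samples differ")
    pts = pd.DataFrame(
        {
            "intensity_a": a,
            "intensity_b": b,
            "called_genotype": calls.astype(int),
            "batch_id": intensities.batch_ids,
        }
    )
    return ClusterData(variant_id, pts, int(pd.unique(pts["batch_id"]).size))


def _class_moments(xy: np.ndarray, labels: np.ndarray):
    comps = {}
    present = [g for g in (0, 1, 2) if np.any(labels == g)]
    n_total = sum(int(np.sum(labels == g)) for g in present)
    # pooled within-class spherical variance, the fallback for singletons
    within = [
        float(np.trace(np.cov(xy[labels == g], rowvar=False)) / 2)
        for g in present
        if np.sum(labels == g) >= 2
    ]
    pooled_var = float(np.mean(within)) if within else max(
        float(np.mean(np.var(xy, axis=0))), 1e-8
    )
    for g in present:
        pts = xy[labels == g]
        center = pts.mean(axis=0)
        if len(pts) < 2:
            cov = np.eye(2) * pooled_var
        else:
            cov = np.atleast_2d(np.cov(pts, rowvar=False))
            if len(pts) < 5:
                # shrink small classes toward spherical (trace-preserving)
                lam = (5 - len(pts)) / 4
                cov = (1 - lam) * cov + lam * np.eye(2) * np.trace(cov) / 2
        comps[g] = {
            "center": center,
            "cov": np.atleast_2d(cov),
            "weight": len(pts) / n_total,
            "n": int(len(pts)),
        }
    return comps


def fit_cluster_model(cluster_data: ClusterData) -> ClusterModel:
    """Fit a Gaussian summary per called genotype class.

    Per class the model records the sample mean, sample covariance
    (shrunk toward spherical for classes with fewer than 5 points, and
    falling back to a pooled spherical estimate for singleton classes)
    and the class weight among called points.
    """
    pts = cluster_data.points
    if len(pts) < 2:
        raise DataError(f"variant {cluster_data.variant_id}: need at least 2 points")
    xy = pts[["intensity_a", "intensity_b"]].to_numpy(dtype=float)
    labels = pts["called_genotype"].to_numpy()
    comps = _class_moments(xy, labels)
    if not comps:
        raise DataError(f"variant {cluster_data.variant_id}: no called genotypes")
    return ClusterModel(cluster_data.variant_id, comps)


# ---------------------------------------------------------------------------
# separation / noise / silhouette


def _class_sd(cov: np.ndarray) -> float:
    """Largest-axis SD of a class: sqrt of the top covariance eigenvalue."""
    eig = np.linalg.eigvalsh(np.atleast_2d(cov))
    return float(np.sqrt(max(float(eig[-1]), 1e-18)))


def _pairwise_separation(comps: dict) -> float:
    """Minimum separation over adjacent genotype-class pairs.

    Each pair's separation is the center distance divided by the pooled
    SD of the pair, where pooling is governed by the wider class (its
    largest-axis SD): an elongated smear of spurious calls is not a
    resolved cluster however far its centroid sits from the main cloud.
    Only adjacent genotype classes are compared (0-1, 1-2): the 0-2 pair
    always has the heterozygote cluster between it.
    """
    keys = sorted(comps)
    if len(keys) < 2:
        return 0.0
    best = np.inf
    for i, j in zip(keys[:-1], keys[1:]):
        ci, cj = comps[i], comps[j]
        delta = np.asarray(cj["center"], float) - np.asarray(ci["center"], float)
        d = float(np.linalg.norm(delta))
        if d <= 0:
            return 0.0
        sd = max(_class_sd(ci["cov"]), _class_sd(cj["cov"]))
        best = min(best, d / sd)
    return float(best)


def _brute_silhouette(xy: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette by the O(n^2) pairwise-distance definition."""
    uniq = np.unique(labels)
    if uniq.size < 2:
        return float("nan")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    s = np.zeros(len(xy))
    for i in range(len(xy)):
        own = labels == labels[i]
        n_own = own.sum()
        a = d[i, own].sum() / (n_own - 1) if n_own > 1 else 0.0
        b = min(d[i, labels == g].mean() for g in uniq if g != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


def separation_statistics(
    model: ClusterModel,
    cluster_data: ClusterData | None = None,
    compute_silhouette: bool = False,
    max_silhouette_points: int = 800,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(separation, noise, silhouette) for a fitted cluster model.

    separation: minimum center distance over adjacent genotype-class
    pairs in units of the wider class's largest-axis SD; 0 for
    single-class (monomorphic) data.
    noise: mean within-class RMS dispersion relative to the mean class
    center magnitude, a scale-free "how fuzzy are the blobs".
    silhouette: mean silhouette of called points under their call labels
    (pairwise-distance definition, majority class subsampled); NaN unless
    requested or fewer than two called classes.
    """
    comps = model.components
    separation = _pairwise_separation(comps)
    sds = [np.sqrt(max(np.trace(c["cov"]) / 2, 0.0)) for c in comps.values()]
    scale = float(np.mean([np.linalg.norm(c["center"]) for c in comps.values()]))
    noise = float(np.mean(sds) / scale) if scale > 0 else float("inf")
    sil = float("nan")
    if compute_silhouette and cluster_data is not None:
        pts = cluster_data.points
        called = pts[pts["called_genotype"] != MISSING]
        labels = called["called_genotype"].to_numpy()
        xy = called[["intensity_a", "intensity_b"]].to_numpy(dtype=float)
        if np.unique(labels).size >= 2:
            if len(xy) > max_silhouette_points:
                counts = pd.Series(labels).value_counts()
                major = counts.idxmax()
                minor_idx = np.flatnonzero(labels != major)
                budget = max(max_silhouette_points - minor_idx.size, 50)
                rng = np.random.default_rng(seed)
                major_idx = rng.choice(
                    np.flatnonzero(labels == major),
                    size=min(budget, int(counts.max())),
                    replace=False,
                )
                idx = np.concatenate([minor_idx, major_idx])
                xy, labels = xy[idx], labels[idx]
            sil = _brute_silhouette(xy, labels)
    return separation, noise, sil


def assign_quality_score(
    separation: float,
    noise: float,
    n_rare_calls: int,
    thresholds: ScoreThresholds | None = None,
    variant_id: str = "?",
    silhouette: float = float("nan"),
) -> QualityAssessment:
    """Map separation/noise statistics onto the 1-5 rubric.

    Monotone in separation: clear separation (>= s_hi) scores 5 (clean)
    or 4 (noisy); intermediate separation scores 3 (unclear); below s_lo
    the variant scores 2 (noisy) or 1.  A variant with no rare calls
    carries no evidence of a real variant and scores 1; below
    ``min_rare_calls`` carriers the geometry of the rare class is
    uninformative and the score is capped at 2, mirroring how reviewers
    treat ultra-rare variants.
    """
    t = thresholds or ScoreThresholds()
    if n_rare_calls == 0:
        score = 1
    elif separation >= t.s_hi:
        score = 5 if noise <= t.noise_hi else 4
    elif separation >= t.s_lo:
        score = 3
    else:
        score = 2 if noise > t.noise_hi else 1
    if 0 < n_rare_calls < t.min_rare_calls:
        score = min(score, 2)
    return QualityAssessment(
        variant_id=variant_id,
        separation=float(separation),
        noise=float(noise),
        score=score,
        group=group_from_score(score),
        n_rare_calls=int(n_rare_calls),
        silhouette=silhouette,
    )


def _n_rare_calls(calls: np.ndarray) -> int:
    called = calls[calls != MISSING]
    if called.size == 0:
        return 0
    alt = int(np.sum(called == 1) + 2 * np.sum(called == 2))
    if alt * 2 <= 2 * called.size:  # alt is the minor allele
        return int(np.sum(called >= 1))
    return int(np.sum(called <= 1))


def score_variant(
    intensities: IntensityTable,
    genotypes: GenotypeMatrix,
    variant_id: str,
    thresholds: ScoreThresholds | None = None,
    compute_silhouette: bool = False,
) -> QualityAssessment:
    """Assemble, fit and score a single variant's cluster plot."""
    data = assemble_cluster_data(intensities, genotypes, variant_id)
    model = fit_cluster_model(data)
    sep, noise, sil = separation_statistics(
        model, data, compute_silhouette=compute_silhouette
    )
    n_rare = _n_rare_calls(data.points["called_genotype"].to_numpy())
    return assign_quality_score(
        sep, noise, n_rare, thresholds, variant_id=variant_id, silhouette=sil
    )


def score_panel(
    intensities: IntensityTable,
    genotypes: GenotypeMatrix,
    variant_ids=None,
    thresholds: ScoreThresholds | None = None,
    compute_silhouette: bool = False,
) -> pd.DataFrame:
    """Automated quality assessment for every variant of a panel."""
    ids = list(variant_ids if variant_ids is not None else genotypes.variant_ids)
    rows = []
    for vid in ids:
        qa = score_variant(
            intensities,
            genotypes,
            vid,
            thresholds=thresholds,
            compute_silhouette=compute_silhouette,
        )
        rows.append(qa.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manual scores


def ingest_manual_scores(
    score_table_1: pd.DataFrame, score_table_2: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Average manual reviewer scores and derive groups.

    Input tables carry ``variant_id`` and ``score`` (integers 1-5).  The
    averaged score uses whichever reviewers scored a variant; a variant is
    retained for downstream association analysis only when its average
    score is strictly greater than 4.
    """
    tables = [score_table_1] + ([score_table_2] if score_table_2 is not None else [])
    frames = []
    for i, t in enumerate(tables, start=1):
        t = t[["variant_id", "score"]].copy()
        if not t["score"].between(1, 5).all():
            bad = t.loc[~t["score"].between(1, 5), "score"].tolist()
            raise DataError(f"scores outside 1-5 from reviewer {i}: {bad}")
        frames.append(t)
    merged = pd.concat(frames).groupby("variant_id", as_index=False)["score"].mean()
    merged = merged.rename(columns={"score": "avg_score"})
    merged["group"] = merged["avg_score"].map(group_from_average)
    merged["retained"] = merged["avg_score"] > 4.0
    return merged


def scorer_agreement(scores_1, scores_2) -> tuple[float, float]:
    """Inter-reviewer concordance: (Pearson r^2, % low-vs-high agreement).

    The percent agreement is computed only over variants where both
    reviewers assigned a decisive score (1-2 = low, 4-5 = high); unclear
    scores are excluded from the denominator.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape or s1.size < 2:
        raise DataError("score vectors must be equal-length with >= 2 entries")
    if np.unique(s1).size < 2 or np.unique(s2).size < 2:
        raise DataError("constant scores: correlation undefined")
    r = np.corrcoef(s1, s2)[0, 1]
    decisive = (s1 != 3) & (s2 != 3)
    if not decisive.any():
        return float(r**2), float("nan")
    agree = (s1[decisive] <= 2) == (s2[decisive] <= 2)
    return float(r**2), float(100.0 * agree.mean())


# ---------------------------------------------------------------------------
# MAF binning and FPR/ROC calibration


def _bin_index(maf_pct: np.ndarray) -> np.ndarray:
    edges = np.asarray(MAF_BIN_EDGES_PCT)
    idx = np.searchsorted(edges, maf_pct, side="right") - 1
    idx[np.asarray(maf_pct) == edges[-1]] = len(edges) - 2  # closed last bin
    return idx


def bin_by_maf(panel: pd.DataFrame, include_total: bool = True) -> pd.DataFrame:
    """Count low (FP), high (TP) and unclear variants per MAF bin.

    ``panel`` needs ``maf_pct`` (minor-allele frequency in percent) and
    ``group`` columns.  Bins are half-open [lo, hi) in percent with the
    final bin closed at 1%.  Any variant above 1% should have been removed
    by QC and raises an error.
    """
    if len(panel) == 0:
        maf = np.array([])
        groups = np.array([])
    else:
        maf = panel["maf_pct"].to_numpy(dtype=float)
        groups = panel["group"].to_numpy()
    if np.any(maf > MAF_BIN_EDGES_PCT[-1]):
        raise DataError("variants with MAF > 1% present; QC should have removed them")
    if np.any(maf < 0):
        raise DataError("negative MAF")
    idx = _bin_index(maf) if maf.size else np.array([], dtype=int)
    rows = []
    for b in range(len(MAF_BIN_EDGES_PCT) - 1):
        sel = idx == b
        rows.append(
            {
                "bin_lo": MAF_BIN_EDGES_PCT[b],
                "bin_hi": MAF_BIN_EDGES_PCT[b + 1],
                "fp": int(np.sum(sel & (groups == "low"))),
                "tp": int(np.sum(sel & (groups == "high"))),
                "unclear": int(np.sum(sel & (groups == "unclear"))),
            }
        )
    table = pd.DataFrame(rows)
    table["total"] = table[["fp", "tp", "unclear"]].sum(axis=1)
    if include_total:
        total = table[["fp", "tp", "unclear", "total"]].sum()
        total_row = pd.DataFrame(
            [{"bin_lo": np.nan, "bin_hi": np.nan, **total.to_dict()}]
        )
        table = pd.concat([table, total_row], ignore_index=True)
    return table


def expand_bin_table(bin_table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant (maf_pct, group) rows from a binned count table.

    Each variant is placed at its bin midpoint, which is the resolution a
    binned table supports; useful for feeding binned published counts into
    the per-variant FPR and ROC machinery.
    """
    t = bin_table.dropna(subset=["bin_lo"])
    rows = []
    for _, r in t.iterrows():
        mid = (r["bin_lo"] + r["bin_hi"]) / 2
        for group, col in (("low", "fp"), ("high", "tp"), ("unclear", "unclear")):
            rows.extend({"maf_pct": mid, "group": group} for _ in range(int(r[col])))
    return pd.DataFrame(rows, columns=["maf_pct", "group"])


def fpr_at_maf_threshold(table: pd.DataFrame, maf_threshold_pct: float) -> float:
    """False-positive rate FP/(FP+TP) among variants with MAF above a cutoff.

    Accepts either a binned count table (the cutoff must coincide with a
    bin boundary; bins at or above it are included) or a per-variant table
    with ``maf_pct``/``group`` columns (strictly greater than the cutoff).
    Unclear variants are excluded throughout.
    """
    if {"bin_lo", "fp", "tp"}.issubset(table.columns):
        t = table.dropna(subset=["bin_lo"])
        if not np.isclose(t["bin_lo"], maf_threshold_pct).any():
            raise DataError(
                f"threshold {maf_threshold_pct} does not align with a bin boundary"
            )
        sel = t[t["bin_lo"] >= maf_threshold_pct - 1e-12]
        fp, tp = int(sel["fp"].sum()), int(sel["tp"].sum())
    else:
        above = table[table["maf_pct"] > maf_threshold_pct]
        fp = int((above["group"] == "low").sum())
        tp = int((above["group"] == "high").sum())
    if fp + tp == 0:
        raise DataError("no decisively scored variants above the MAF threshold")
    return fp / (fp + tp)


def _auc_rank(maf: np.ndarray, is_high: np.ndarray) -> float:
    """Concordance AUC (ties count 1/2) of MAF as a predictor of quality."""
    ranks = rankdata(maf)
    n1 = int(is_high.sum())
    n0 = is_high.size - n1
    if n1 == 0 or n0 == 0:
        raise DataError("need at least one low and one high quality variant")
    return float((ranks[is_high].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_maf_vs_quality(
    maf_pct,
    group,
    n_boot: int = 2000,
    seed: int = 0,
    fpr_thresholds_pct: tuple = (0.001, 0.005),
) -> RocResult:
    """Empirical ROC of MAF as a predictor of high analytical quality.

    AUC is the pairwise concordance probability (Mann-Whitney statistic
    with ties counted 1/2); its CI comes from a seeded class-stratified
    bootstrap.  ``fpr_at_thresholds`` reports FP/(FP+TP) among variants
    with MAF strictly above each requested cutoff.  Unclear variants are
    dropped before any computation.
    """
    df = pd.DataFrame({"maf_pct": np.asarray(maf_pct, float), "group": np.asarray(group)})
    df = df[df["group"] != "unclear"].reset_index(drop=True)
    is_high = (df["group"] == "high").to_numpy()
    maf = df["maf_pct"].to_numpy()
    auc = _auc_rank(maf, is_high)
    rng = np.random.default_rng(seed)
    hi_idx = np.flatnonzero(is_high)
    lo_idx = np.flatnonzero(~is_high)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        hi = rng.choice(hi_idx, size=hi_idx.size, replace=True)
        lo = rng.choice(lo_idx, size=lo_idx.size, replace=True)
        idx = np.concatenate([hi, lo])
        lab = np.zeros(idx.size, dtype=bool)
        lab[: hi.size] = True
        boots[i] = _auc_rank(maf[idx], lab)
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    # empirical curve: classify high when maf > threshold
    thresholds = np.concatenate([[-np.inf], np.unique(maf)])
    pts = []
    n1, n0 = is_high.sum(), (~is_high).sum()
    for t in thresholds:
        pred = maf > t
        tpr = float(np.sum(pred & is_high) / n1)
        fpr = float(np.sum(pred & ~is_high) / n0)
        pts.append((fpr, tpr, t))
    curve = pd.DataFrame(pts, columns=["fpr", "tpr", "threshold_maf_pct"])
    curve = curve.sort_values(["fpr", "tpr"]).reset_index(drop=True)
    fprs = {}
    for t in fpr_thresholds_pct:
        try:
            fprs[t] = fpr_at_maf_threshold(df, t)
        except DataError:
            fprs[t] = float("nan")
    return RocResult(auc=auc, ci=ci, curve_points=curve, fpr_at_thresholds=fprs)
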