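"""Phenome-wide association scan for prioritized rare variants.

One variant is tested against many traits: Fisher's exact test on a
carrier-by-outcome 2x2 table for binary traits (a rare heterozygous
variant is essentially a carrier/non-carrier contrast, and the exact test
is robust at a handful of carriers), and covariate-adjusted ordinary
least squares for continuous traits (age, sex unless the trait is
sex-specific, assessment center, genotyping chip and ten ancestry
principal components).  Significance is gated by a single Bonferroni
threshold alpha / (n_variants x n_traits).  A conditional-analysis step
refits each significant pair against the most-associated regional variant
within a window, removing associations explained by linkage
disequilibrium with a nearby causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .exceptions import DataError

__all__ = [
    "TraitDefinition",
    "FisherResult",
    "fisher_exact_2x2",
    "linear_association",
    "bonferroni_threshold",
    "run_phewas",
    "conditional_analysis",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "center", "chip") + tuple(
    f"pc{i}" for i in range(1, 11)
)

#: phenotype columns treated as categorical factors in regression designs
CATEGORICAL_COVARIATES = ("center", "chip")


@dataclass(frozen=True)
class TraitDefinition:
    """A phenotype column and how to analyse it."""

    trait_id: str
    kind: str  # "continuous" or "binary"
    sex_specific: bool = False
    covariates: tuple = DEFAULT_COVARIATES

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise DataError(f"unknown trait kind {self.kind!r}")

    def design_covariates(self) -> tuple:
        if self.sex_specific:
            return tuple(c for c in self.covariates if c != "sex")
        return tuple(self.covariates)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def fisher_exact_2x2(
    carrier_cases: int,
    carrier_controls: int,
    noncarrier_cases: int,
    noncarrier_controls: int,
) -> FisherResult:
    """Two-sided Fisher's exact test on a carrier-by-outcome table.

    The p-value is the exact conditional tail (sum of hypergeometric
    probabilities no larger than the observed table's).  The odds ratio
    is the sample cross-product, with the Haldane-Anscombe 0.5 correction
    applied to every cell when any cell is zero, and a 95% CI from
    Woolf's logit method on the (corrected) table.
    """
    cells = (carrier_cases, carrier_controls, noncarrier_cases, noncarrier_controls)
    if any(int(c) != c or c < 0 for c in cells):
        raise DataError(f"cell counts must be nonnegative integers: {cells}")
    a, b, c, d = (float(x) for x in cells)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DataError("empty margin in 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return FisherResult(
        odds_ratio=float(odds),
        ci_low=float(odds * np.exp(-z * se)),
        ci_high=float(odds * np.exp(z * se)),
        p=float(p),
    )


def fisher_achieved_size(
    n_total: int, n_cases: int, n_carriers: int, alpha: float = 0.05
) -> float:
    """Exact attainable size of the two-sided Fisher test at ``alpha``.

    Being discrete, the exact test rejects with probability somewhat
    below alpha; this returns the actual rejection probability under the
    null for the given margins (total sample size, case count, carrier
    count), by enumerating the hypergeometric support.  Useful as the
    correct reference when calibrating simulated type-I error.
    """
    k = np.arange(max(0, n_carriers + n_cases - n_total), min(n_carriers, n_cases) + 1)
    pmf = stats.hypergeom.pmf(k, n_total, n_cases, n_carriers)
    order = np.argsort(pmf, kind="stable")
    cum = np.cumsum(pmf[order])
    # p-value of each outcome: total probability of outcomes no more likely
    idx = np.searchsorted(pmf[order], pmf[order] * (1 + 1e-12), side="right") - 1
    pvals = np.empty_like(pmf)
    pvals[order] = cum[idx]
    return float(pmf[pvals <= alpha * (1 + 1e-12)].sum())


def _design_matrix(covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """Expand a covariate frame into a numeric design block (no constant)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((0, 0)), []
    blocks, names = [], []
    for col in covariates.columns:
        s = covariates[col]
        if col in CATEGORICAL_COVARIATES or s.dtype == object or str(s.dtype) == "category":
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns.tolist())
        else:
            blocks.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
    return np.hstack(blocks) if blocks else np.empty((len(covariates), 0)), names


def linear_association(
    trait_values, dosage, covariate_matrix: pd.DataFrame | None = None
) -> tuple[float, tuple[float, float], float]:
    """OLS of a continuous trait on allele dosage plus covariates.

    Returns (beta, 95% Wald CI, two-sided p) for the dosage coefficient,
    from the t distribution with the residual degrees of freedom.
    Samples with any missing element are dropped (complete-case).
    """
    y = np.asarray(trait_values, dtype=float)
    g = np.asarray(dosage, dtype=float)
    cov_block, names = _design_matrix(covariate_matrix)
    if cov_block.size:
        complete = np.isfinite(y) & np.isfinite(g) & np.all(np.isfinite(cov_block), axis=1)
        cov_block = cov_block[complete]
    else:
        complete = np.isfinite(y) & np.isfinite(g)
        cov_block = np.empty((int(complete.sum()), 0))
    y, g = y[complete], g[complete]
    n = y.size
    k = 2 + cov_block.shape[1]
    if n < k + 1:
        raise DataError(f"only {n} complete cases for {k} design columns")
    if np.ptp(g) == 0:
        raise DataError("monomorphic in analysis set")
    X = np.column_stack([np.ones(n), g, cov_block])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DataError(
            "rank-deficient design; collinear columns among: "
            + ", ".join(["const", "dosage"] + names)
        )
    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(beta_hat[1])
    if se == 0:
        return beta, (beta, beta), 0.0 if beta != 0 else 1.0
    tval = beta / se
    p = float(2 * stats.t.sf(abs(tval), dof))
    tcrit = float(stats.t.ppf(0.975, dof))
    return beta, (beta - tcrit * se, beta + tcrit * se), p


def bonferroni_threshold(n_variants: int, n_traits: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / (n_variants * n_traits)."""
    if n_variants <= 0 or n_traits <= 0:
        raise DataError("variant and trait counts must be positive")
    if not 0 < alpha < 1:
        raise DataError("alpha must be in (0, 1)")
    return alpha / (n_variants * n_traits)


def _binary_test(trait: np.ndarray, dosage: np.ndarray):
    """Fisher test on the dominant carrier coding; returns row fields."""
    ok = np.isfinite(trait) & np.isfinite(dosage)
    trait, dosage = trait[ok], dosage[ok]
    carrier = dosage >= 1
    a = int(np.sum(carrier & (trait == 1)))
    b = int(np.sum(carrier & (trait == 0)))
    c = int(np.sum(~carrier & (trait == 1)))
    d = int(np.sum(~carrier & (trait == 0)))
    if a + b == 0:
        return None, "untestable_no_carriers", int(ok.sum())
    if c + d == 0 or a + c == 0 or b + d == 0:
        return None, "untestable_empty_margin", int(ok.sum())
    return fisher_exact_2x2(a, b, c, d), "ok", int(ok.sum())


def run_phewas(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    traits: list[TraitDefinition],
    variant_ids=None,
    alpha: float = 0.05,
    standardize_continuous: bool = False,
) -> pd.DataFrame:
    """Scan every (variant, trait) pair and flag Bonferroni-significant hits.

    Untestable pairs (no carriers among phenotyped samples, monomorphic in
    the analysis set, empty table margins) are recorded with an explicit
    status instead of being dropped.  The significance threshold is
    ``alpha`` divided by the number of *attempted* tests (variants x
    traits), matching the convention of correcting for the full scan.
    """
    ids = list(variant_ids if variant_ids is not None else genotypes.variant_ids)
    threshold = bonferroni_threshold(len(ids), len(traits), alpha)
    rows = []
    for trait in traits:
        y = phenotypes[trait.trait_id].to_numpy(dtype=float)
        if trait.kind == "continuous" and standardize_continuous:
            mu, sd = np.nanmean(y), np.nanstd(y)
            y = (y - mu) / sd if sd > 0 else y
        cov_cols = [c for c in trait.design_covariates() if c in phenotypes.columns]
        covs = phenotypes[cov_cols] if cov_cols else None
        for vid in ids:
            dosage = genotypes.dosage(vid)
            row = {
                "variant_id": vid,
                "trait_id": trait.trait_id,
                "method": "fisher" if trait.kind == "binary" else "linear",
                "effect": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "n_effective": 0,
                "status": "ok",
                "significant": False,
                "conditional_status": "not_tested",
            }
            if trait.kind == "binary":
                res, status, n_eff = _binary_test(y, dosage)
                row["status"], row["n_effective"] = status, n_eff
                if res is not None:
                    row.update(
                        effect=res.odds_ratio,
                        ci_low=res.ci_low,
                        ci_high=res.ci_high,
                        p=res.p,
                    )
            else:
                try:
                    beta, ci, p = linear_association(y, dosage, covs)
                    ok = np.isfinite(y) & np.isfinite(dosage)
                    row.update(
                        effect=beta, ci_low=ci[0], ci_high=ci[1], p=p,
                        n_effective=int(ok.sum()),
                    )
                except DataError as err:
                    row["status"] = (
                        "untestable_monomorphic"
                        if "monomorphic" in str(err)
                        else "untestable_insufficient_data"
                    )
            if row["status"] == "ok" and np.isfinite(row["p"]):
                row["significant"] = bool(row["p"] < threshold)
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out


def _logistic_conditional_p(y, X) -> float:
    """p-value of column 1 of X in a logistic fit; 1.0 when the fit is
    degenerate (perfect collinearity or separation), i.e. the variant
    carries no information beyond the conditioning variant."""
    import statsmodels.api as sm

    if np.linalg.matrix_rank(X) < X.shape[1]:
        return 1.0
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        p = float(fit.pvalues[1])
        return p if np.isfinite(p) else 1.0
    except Exception:
        return 1.0


def conditional_analysis(
    results: pd.DataFrame,
    genotypes: GenotypeMatrix,
    variant_positions: pd.DataFrame,
    phenotypes: pd.DataFrame,
    traits: list[TraitDefinition],
    window_bp: int = 1_000_000,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Condition each significant hit on its strongest regional neighbour.

    For every significant (variant, trait) pair, the most-associated other
    variant for the same trait within ``window_bp`` (centered: +/- half a
    window) is added to the model as an extra covariate and the pair is
    refit (OLS for continuous traits, logistic for binary).  If the
    conditional p-value rises above the Bonferroni threshold the
    association is marked ``explained_by_regional_variant``, otherwise
    ``independent``.  Pairs with no regional neighbour stay ``not_tested``.
    Ties for the strongest neighbour break by smallest p, then largest
    absolute effect, then smallest position.
    """
    if threshold is None:
        threshold = results.attrs.get("bonferroni_threshold")
    if threshold is None:
        raise DataError("no Bonferroni threshold available")
    pos = variant_positions.set_index("variant_id")
    trait_by_id = {t.trait_id: t for t in traits}
    out = results.copy()
    half = window_bp / 2
    for i, row in out[out["significant"] == True].iterrows():  # noqa: E712
        vid, tid = row["variant_id"], row["trait_id"]
        if vid not in pos.index:
            raise DataError(f"no position for variant {vid}")
        chrom, p0 = pos.loc[vid, "chrom"], pos.loc[vid, "pos"]
        region = pos[(pos["chrom"] == chrom) & (abs(pos["pos"] - p0) <= half)].index
        candidates = out[
            (out["trait_id"] == tid)
            & out["variant_id"].isin(region)
            & (out["variant_id"] != vid)
            & np.isfinite(out["p"])
        ].copy()
        if candidates.empty:
            out.loc[i, "conditional_status"] = "not_tested"
            continue
        candidates["_pos"] = candidates["variant_id"].map(pos["pos"])
        candidates["_abseff"] = candidates["effect"].abs()
        candidates = candidates.sort_values(
            ["p", "_abseff", "_pos"], ascending=[True, False, True]
        )
        proxy = candidates.iloc[0]["variant_id"]
        trait = trait_by_id[tid]
        y = phenotypes[tid].to_numpy(dtype=float)
        g = genotypes.dosage(vid)
        gr = genotypes.dosage(proxy)
        cov_cols = [c for c in trait.design_covariates() if c in phenotypes.columns]
        cov_block, _ = _design_matrix(phenotypes[cov_cols] if cov_cols else None)
        if cov_block.size == 0:
            cov_block = np.empty((len(y), 0))
        ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(gr)
        if cov_block.shape[1]:
            ok &= np.all(np.isfinite(cov_block), axis=1)
        X = np.column_stack(
            [np.ones(int(ok.sum())), g[ok], gr[ok], cov_block[ok]]
        )
        if trait.kind == "binary":
            cond_p = _logistic_conditional_p(y[ok], X)
        else:
            if np.linalg.matrix_rank(X) < X.shape[1]:
                cond_p = 1.0
            else:
                try:
                    _, _, cond_p = linear_association(
                        y[ok],
                        g[ok],
                        pd.DataFrame(
                            np.column_stack([gr[ok], cov_block[ok]])
                        ),
                    )
                except DataError:
                    cond_p = 1.0
        out.loc[i, "conditional_p"] = cond_p
        out.loc[i, "conditional_proxy"] = proxy
        out.loc[i, "conditional_status"] = (
            "explained_by_regional_variant" if cond_p >= threshold else "independent"
        )
    return out
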