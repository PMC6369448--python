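"""Fully synthetic biobank cohorts with known truth.

Emulates what a large genotyping-array biobank looks like from the
analyst's side: a variant panel with ClinVar-style annotation, diploid
genotypes drawn under Hardy-Weinberg equilibrium, two-channel probe
intensities organised in genotyping batches, an array-style genotype
caller (so observed calls contain miscalls and missingness), phenotypes
with covariate structure, and age-of-onset data with configurable
cumulative incidence among carriers.

Each variant belongs to one of three analytical-validity classes:

``true_poly_good``
    a real polymorphism with tight, well-separated intensity clusters;
``true_poly_noisy``
    a real polymorphism whose clusters are inflated along the
    total-intensity (radial) direction, the classic fuzzy assay;
``monomorphic_smear``
    no real variation at all: a single tight cluster plus a sparse heavy
    tail of points along the A=B diagonal that the caller converts into
    spurious rare heterozygote calls - the synthetic embodiment of an
    array false positive.

The class mixture is MAF-dependent (rarer variants are much more likely
to be smears), mirroring how analytical validity degrades with MAF on
real arrays.

Determinism: all randomness flows from one master seed; each pipeline
stage (and each variant within the intensity/calling stages) draws from
its own child stream with a fixed labeled offset, so stages are
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cluster import MAF_BIN_EDGES_PCT
from .containers import GenotypeMatrix, IntensityTable
from .exceptions import ConfigurationError, DataError

__all__ = [
    "SimConfig",
    "CovariateModel",
    "TraitSpec",
    "EffectSpec",
    "OnsetModel",
    "SimulatedCohort",
    "QUALITY_CLASSES",
    "DEFAULT_CLASS_PROBS",
    "build_variant_panel",
    "sample_truth_genotypes",
    "render_intensities",
    "call_observed_genotypes",
    "simulate_traits_and_onset",
    "simulate_cohort",
    "duplicate_as_proxy",
    "draw_onset_ages",
    "default_traits",
]

QUALITY_CLASSES = ("true_poly_good", "true_poly_noisy", "monomorphic_smear")

# labeled child-stream offsets, one per pipeline stage
_STAGE_PANEL = 1
_STAGE_GENO = 2
_STAGE_INTENS = 3
_STAGE_CALL = 4
_STAGE_COVAR = 5
_STAGE_TRAIT = 6
_STAGE_ONSET = 7
_STAGE_BATCH = 8

# ---------------------------------------------------------------------------
# intensity-plane geometry: three genotype cluster centers on an arc of
# radius R (hom-ref near the A axis, het on the diagonal, hom-alt near the
# B axis); d is the distance between adjacent centers and sets the unit in
# which per-class separation scalars are expressed.

_R = 2.0
_ANGLES_DEG = (10.0, 45.0, 80.0)
_CENTERS = np.array(
    [
        [_R * math.cos(math.radians(a)), _R * math.sin(math.radians(a))]
        for a in _ANGLES_DEG
    ]
)
_D = float(np.linalg.norm(_CENTERS[1] - _CENTERS[0]))
_DIAG = np.array([math.sqrt(0.5), math.sqrt(0.5)])
_CROSS = np.array([math.sqrt(0.5), -math.sqrt(0.5)])
#: smallest within-cluster SD, as a fraction of d (the "clean assay" width)
_TIGHT = 1.0 / 8.0

#: default MAF-bin -> quality-class probabilities.  Indexed by the bins of
#: :data:`popvar.cluster.MAF_BIN_EDGES_PCT`; the mixture follows the
#: empirical pattern that array false positives dominate below 0.005% MAF
#: and vanish above 0.1%, smoothed so that the true false-positive rate is
#: monotone in MAF.
DEFAULT_CLASS_PROBS = (
    {"true_poly_good": 0.01, "true_poly_noisy": 0.01, "monomorphic_smear": 0.98},
    {"true_poly_good": 0.02, "true_poly_noisy": 0.08, "monomorphic_smear": 0.90},
    {"true_poly_good": 0.11, "true_poly_noisy": 0.10, "monomorphic_smear": 0.79},
    {"true_poly_good": 0.50, "true_poly_noisy": 0.17, "monomorphic_smear": 0.33},
    {"true_poly_good": 0.80, "true_poly_noisy": 0.08, "monomorphic_smear": 0.12},
    {"true_poly_good": 0.95, "true_poly_noisy": 0.035, "monomorphic_smear": 0.015},
    {"true_poly_good": 1.00, "true_poly_noisy": 0.0, "monomorphic_smear": 0.0},
    {"true_poly_good": 1.00, "true_poly_noisy": 0.0, "monomorphic_smear": 0.0},
)

_MODY_GENES = ("HNF1A", "HNF4A", "GCK", "HNF1B")
_DD_GENES = ("COL4A3", "GNAS", "HIST1H1E", "RNF135", "TGIF1", "ARID1B", "TCF4")
_OTHER_GENES = (
    "HBB", "PALB2", "HOXB13", "LRRK2", "MYH7", "FLG", "TSHR", "ERCC4",
    "OCA2", "PER3", "TACR3", "TMPRSS6", "NPC1", "SEC23B", "ACSF3", "SLC6A19",
)
_GENE_MOI = {g: "AD" for g in _MODY_GENES + _DD_GENES}
_GENE_MOI.update(
    {g: "AR" for g in ("HBB", "ERCC4", "OCA2", "TACR3", "TMPRSS6", "NPC1",
                       "SEC23B", "ACSF3", "SLC6A19")}
)
_GENE_MECHANISM = {g: "haploinsufficiency" for g in _DD_GENES}

_CONSEQUENCE_PROBS = {
    "nonsynonymous": 0.50,
    "stopgain": 0.12,
    "frameshift": 0.12,
    "inframe_indel": 0.06,
    "synonymous": 0.15,
    "other": 0.05,
}
_CLINVAR_PROBS = {
    "pathogenic": 0.35,
    "likely_pathogenic": 0.25,
    "conflicting": 0.10,
    "none": 0.20,
    "benign": 0.07,
    "reclassified_benign": 0.03,
}
#: probability a variant is present in external reference databases
#: (gnomAD/1000G-style), by quality class - real variants usually are,
#: array artifacts usually are not
_IN_REFERENCE_PROB = {
    "true_poly_good": 0.92,
    "true_poly_noisy": 0.75,
    "monomorphic_smear": 0.08,
}


@dataclass(frozen=True)
class CovariateModel:
    """Population covariates: age at assessment, sex, assessment center,
    genotyping chip and ten ancestry principal components."""

    age_range: tuple = (37.0, 73.0)
    female_fraction: float = 0.54
    n_centers: int = 10
    secondary_chip_fraction: float = 0.06
    n_pcs: int = 10
    pc_sd: float = 1.0


@dataclass(frozen=True)
class TraitSpec:
    trait_id: str
    kind: str  # continuous | binary
    prevalence: float = 0.05  # binary traits only
    noise_sd: float = 1.0  # continuous traits only
    sex_specific: bool = False


@dataclass(frozen=True)
class EffectSpec:
    """A planted variant -> trait effect with known magnitude.

    ``effect_type``: ``beta`` (additive effect on a continuous trait, in
    trait units per allele), ``log_odds_ratio`` (per-allele log odds on a
    binary trait) or ``hazard_scale`` (the variant's carriers follow the
    onset model's carrier incidence curve).
    """

    variant_id: str
    trait_id: str
    effect_type: str  # beta | log_odds_ratio | hazard_scale
    magnitude: float


@dataclass(frozen=True)
class OnsetModel:
    """Age-of-onset model via cumulative incidence curves.

    Each curve is a tuple of (age, cumulative incidence) knots,
    interpolated linearly from (0, 0) and flat beyond the last knot.
    Defaults emulate a late-onset common disease (diabetes-like): 0.5% of
    non-carriers affected by 40 rising to 6% by 73, versus 10% of
    carriers affected by 40 rising to 28% by 73.
    """

    disease_id: str = "diabetes"
    baseline_knots: tuple = ((40.0, 0.005), (73.0, 0.06))
    carrier_knots: tuple = ((40.0, 0.10), (73.0, 0.28))


def default_traits(n_continuous: int = 10, n_binary: int = 10) -> tuple:
    """Default trait panel: continuous traits with unit noise and binary
    traits at 5% prevalence; the last continuous trait is sex-specific."""
    cont = [
        TraitSpec(f"trait_c{i}", "continuous", sex_specific=(i == n_continuous))
        for i in range(1, n_continuous + 1)
    ]
    binary = [TraitSpec(f"trait_b{i}", "binary") for i in range(1, n_binary + 1)]
    return tuple(cont + binary)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic biobank realisation."""

    master_seed: int = 0
    n_samples: int = 20_000
    n_variants: int = 2_000
    n_batches: int = 106
    batch_sizes: tuple | None = None  # defaults to near-equal batches
    maf_range: tuple = (1e-5, 1e-2)  # fractions, log-uniform
    quality_class_probs: tuple = DEFAULT_CLASS_PROBS
    #: adjacent-cluster distance in units of the class's widest SD
    separations: dict = field(
        default_factory=lambda: {
            "true_poly_good": 8.0,
            "true_poly_noisy": 2.5,
            "monomorphic_smear": 0.0,
        }
    )
    batch_log_sd: float = 0.05
    call_boundary: float = 0.58  # rare-prior-shifted, in adjacent-center units
    nocall_halfwidth: float = 0.05
    class_missingness: dict = field(
        default_factory=lambda: {
            "true_poly_good": 0.0005,
            "true_poly_noisy": 0.005,
            "monomorphic_smear": 0.005,
        }
    )
    covariate_model: CovariateModel = CovariateModel()
    traits: tuple = field(default_factory=default_traits)
    effect_specs: tuple = ()
    onset_model: OnsetModel = OnsetModel()

    def resolved_batch_sizes(self) -> np.ndarray:
        if self.batch_sizes is not None:
            return np.asarray(self.batch_sizes, dtype=int)
        base = self.n_samples // self.n_batches
        sizes = np.full(self.n_batches, base, dtype=int)
        sizes[: self.n_samples - base * self.n_batches] += 1
        return sizes

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1 or self.n_batches < 1:
            raise ConfigurationError("counts must be positive")
        sizes = self.resolved_batch_sizes()
        if sizes.sum() != self.n_samples or (sizes <= 0).any():
            raise ConfigurationError(
                f"batch sizes must be positive and sum to n_samples "
                f"({sizes.sum()} != {self.n_samples})"
            )
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.01):
            raise ConfigurationError("maf_range must lie within (0, 0.01]")
        if len(self.quality_class_probs) != len(MAF_BIN_EDGES_PCT) - 1:
            raise ConfigurationError(
                "quality_class_probs needs one mapping per MAF bin"
            )
        for i, probs in enumerate(self.quality_class_probs):
            if set(probs) != set(QUALITY_CLASSES):
                raise ConfigurationError(f"bin {i}: classes must be {QUALITY_CLASSES}")
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
                raise ConfigurationError(f"bin {i}: probabilities must sum to 1")
        trait_ids = {t.trait_id for t in self.traits}
        if len(trait_ids) != len(self.traits):
            raise ConfigurationError("duplicate trait ids")
        for spec in self.effect_specs:
            if spec.effect_type not in ("beta", "log_odds_ratio", "hazard_scale"):
                raise ConfigurationError(f"unknown effect type {spec.effect_type!r}")
            if spec.effect_type != "hazard_scale" and spec.trait_id not in trait_ids:
                raise ConfigurationError(f"effect references unknown trait {spec.trait_id!r}")


@dataclass
class SimulatedCohort:
    """Everything one synthetic realisation produces, truth included."""

    config: SimConfig
    panel: pd.DataFrame
    truth_genotypes: GenotypeMatrix
    intensities: IntensityTable
    observed_genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    onset: pd.DataFrame


def _rng(config: SimConfig, stage: int, sub: int | None = None) -> np.random.Generator:
    seeds = [config.master_seed, stage] + ([sub] if sub is not None else [])
    return np.random.default_rng(seeds)


def _weighted_choice(rng, options, probs, size):
    p = np.asarray(probs, dtype=float)
    return np.asarray(options, dtype=object)[rng.choice(len(options), size=size, p=p / p.sum())]


# ---------------------------------------------------------------------------
# panel


def build_variant_panel(config: SimConfig) -> pd.DataFrame:
    """Draw the variant panel: identity, annotation and ground truth.

    Frequencies are log-uniform over ``maf_range``; each variant's
    quality class is drawn from the MAF-bin-specific mixture.  Smear
    variants have ``true_maf`` 0 (there is no real variant) but keep the
    drawn frequency as their spurious-call tail mass, so the artifact's
    apparent frequency matches the bin it was planted in.
    """
    config.validate()
    rng = _rng(config, _STAGE_PANEL)
    n = config.n_variants
    lo, hi = config.maf_range
    drawn_maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    edges = np.asarray(MAF_BIN_EDGES_PCT)
    bin_idx = np.clip(np.searchsorted(edges, drawn_maf * 100, side="right") - 1,
                      0, len(edges) - 2)
    classes = np.empty(n, dtype=object)
    for b in range(len(edges) - 1):
        sel = bin_idx == b
        if sel.any():
            probs = config.quality_class_probs[b]
            classes[sel] = _weighted_choice(
                rng, QUALITY_CLASSES, [probs[c] for c in QUALITY_CLASSES], int(sel.sum())
            )
    genes = _weighted_choice(
        rng,
        _MODY_GENES + _DD_GENES + _OTHER_GENES,
        [1.5] * len(_MODY_GENES) + [1.5] * len(_DD_GENES) + [1.0] * len(_OTHER_GENES),
        n,
    )
    consequences = _weighted_choice(
        rng, list(_CONSEQUENCE_PROBS), list(_CONSEQUENCE_PROBS.values()), n
    )
    clinvar = _weighted_choice(
        rng, list(_CLINVAR_PROBS), list(_CLINVAR_PROBS.values()), n
    )
    in_ref_p = np.array([_IN_REFERENCE_PROB[c] for c in classes])
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
    is_smear = classes == "monomorphic_smear"
    band = {
        "true_poly_good": (4, 5),
        "true_poly_noisy": (2, 4),
        "monomorphic_smear": (1, 2),
    }
    panel = pd.DataFrame(
        {
            "variant_id": [f"var{j:05d}" for j in range(n)],
            "chrom": [str(c) for c in rng.integers(1, 23, size=n)],
            "pos": rng.integers(1, 120_000_000, size=n),
            "ref": ref,
            "alt": alt,
            "gene": genes,
            "consequence": consequences,
            "clinvar_class": clinvar,
            "disease": [f"{g} related disorder" for g in genes],
            "moi": [_GENE_MOI.get(g, "NA") for g in genes],
            "mechanism": [_GENE_MECHANISM.get(g, "other") for g in genes],
            "in_reference_db": rng.random(n) < in_ref_p,
            "quality_class": classes,
            "maf_bin": bin_idx,
            "drawn_maf": drawn_maf,
            "true_maf": np.where(is_smear, 0.0, drawn_maf),
            "tail_mass": np.where(is_smear, 2 * drawn_maf, 0.0),
            "expected_score_lo": [band[c][0] for c in classes],
            "expected_score_hi": [band[c][1] for c in classes],
        }
    )
    return panel


# ---------------------------------------------------------------------------
# genotypes


def _batch_assignment(config: SimConfig) -> np.ndarray:
    return np.repeat(np.arange(config.n_batches), config.resolved_batch_sizes())


def sample_truth_genotypes(panel: pd.DataFrame, config: SimConfig) -> GenotypeMatrix:
    """Diploid genotypes under Hardy-Weinberg equilibrium at ``true_maf``.

    Each genotype is Binomial(2, true_maf), which is exactly the HWE
    distribution; smear variants are all homozygous reference.
    """
    config.validate()
    rng = _rng(config, _STAGE_GENO)
    p = panel["true_maf"].to_numpy(dtype=float)
    geno = rng.binomial(2, np.broadcast_to(p, (config.n_samples, len(p)))).astype(np.int8)
    return GenotypeMatrix(
        genotypes=geno,
        sample_ids=[f"S{i:06d}" for i in range(config.n_samples)],
        variant_ids=panel["variant_id"].tolist(),
        batch_ids=_batch_assignment(config),
    )


# ---------------------------------------------------------------------------
# intensities


def _class_axes(quality_class: str, center_idx: int, separation: float):
    """Per-cluster big-axis (radial) and small-axis (tangential) SDs."""
    small = _TIGHT * _D
    if quality_class == "true_poly_noisy" and separation > 0:
        big = _D / separation
    else:
        big = small
    e = _CENTERS[center_idx] / np.linalg.norm(_CENTERS[center_idx])
    t = np.array([-e[1], e[0]])
    return e, t, max(big, small), small


def render_intensities(
    truth_genotypes: GenotypeMatrix, panel: pd.DataFrame, config: SimConfig
) -> IntensityTable:
    """Two-channel intensities per (sample, variant).

    Cluster geometry is quality-class specific: good variants get tight
    isotropic clusters, noisy variants get radially inflated ones, and
    smear variants get a single tight cluster plus a sparse heavy tail of
    points strung along the A=B diagonal (landing in the heterozygote
    calling region).  Per-batch multiplicative channel scalings (log
    normal with SD ``batch_log_sd``) model plate/chemistry variation.
    """
    config.validate()
    if truth_genotypes.batch_ids is None:
        raise DataError("batch assignment missing")
    n_s, n_v = truth_genotypes.genotypes.shape
    batch_rng = _rng(config, _STAGE_BATCH)
    factors = np.exp(
        batch_rng.normal(0.0, config.batch_log_sd, size=(config.n_batches, 2))
    )
    fa = factors[truth_genotypes.batch_ids, 0]
    fb = factors[truth_genotypes.batch_ids, 1]
    A = np.empty((n_s, n_v), dtype=np.float32)
    B = np.empty((n_s, n_v), dtype=np.float32)
    classes = panel["quality_class"].to_numpy()
    tails = panel["tail_mass"].to_numpy(dtype=float)
    seps = panel["quality_class"].map(config.separations).to_numpy(dtype=float)
    for j in range(n_v):
        rng = _rng(config, _STAGE_INTENS, j)
        g = truth_genotypes.genotypes[:, j].astype(int)
        xy = np.empty((n_s, 2))
        for cls_idx in (0, 1, 2):
            sel = g == cls_idx
            if not sel.any():
                continue
            e, t, big, small = _class_axes(classes[j], cls_idx, seps[j])
            m = int(sel.sum())
            z1 = rng.normal(size=m)[:, None]
            z2 = rng.normal(size=m)[:, None]
            xy[sel] = _CENTERS[cls_idx] + z1 * big * e + z2 * small * t
        if classes[j] == "monomorphic_smear" and tails[j] > 0:
            spray = rng.random(n_s) < tails[j]
            m = int(spray.sum())
            if m:
                rho = rng.uniform(0.8, 5.0, size=m)[:, None]
                cross = rng.normal(0.0, 0.08, size=m)[:, None]
                xy[spray] = rho * _DIAG + cross * _CROSS
        np.maximum(xy, 0.0, out=xy)
        A[:, j] = xy[:, 0] * fa
        B[:, j] = xy[:, 1] * fb
    return IntensityTable(
        a=A,
        b=B,
        sample_ids=truth_genotypes.sample_ids,
        variant_ids=truth_genotypes.variant_ids,
        batch_ids=truth_genotypes.batch_ids,
    )


# ---------------------------------------------------------------------------
# calling


def _normalize_by_batch(x: np.ndarray, batch_ids: np.ndarray) -> np.ndarray:
    """Scale each batch so its median intensity matches the global median,
    the usual plate-normalisation step before calling."""
    out = x.astype(float).copy()
    global_med = np.median(x)
    for b in np.unique(batch_ids):
        sel = batch_ids == b
        med = np.median(x[sel])
        if med > 0:
            out[sel] *= global_med / med
    return out


def call_observed_genotypes(
    intensities: IntensityTable, panel: pd.DataFrame, config: SimConfig
) -> GenotypeMatrix:
    """Array-style genotype calling from intensities.

    Points are classified by their affine coordinates along the
    hom-ref -> het and het -> hom-alt center axes, with decision
    boundaries shifted toward the rare classes (``call_boundary`` > 0.5,
    a rare-variant prior) and a no-call band of ``nocall_halfwidth``
    around each boundary.  Per-class random missingness is added on top.
    Observed calls therefore differ from truth exactly where the
    geometry says they should: hardly at all for good variants, and with
    spurious rare heterozygote calls for monomorphic smears.
    """
    config.validate()
    n_s = len(intensities.sample_ids)
    n_v = len(intensities.variant_ids)
    v01 = _CENTERS[1] - _CENTERS[0]
    v12 = _CENTERS[2] - _CENTERS[1]
    d2 = _D**2
    b = config.call_boundary
    w = config.nocall_halfwidth
    miss_p = panel["quality_class"].map(config.class_missingness).to_numpy(dtype=float)
    geno = np.empty((n_s, n_v), dtype=np.int8)
    for j in range(n_v):
        a_raw, b_raw = intensities.a[:, j], intensities.b[:, j]
        x = _normalize_by_batch(a_raw, intensities.batch_ids)
        y = _normalize_by_batch(b_raw, intensities.batch_ids)
        u01 = ((x - _CENTERS[0, 0]) * v01[0] + (y - _CENTERS[0, 1]) * v01[1]) / d2
        u12 = ((x - _CENTERS[1, 0]) * v12[0] + (y - _CENTERS[1, 1]) * v12[1]) / d2
        calls = np.zeros(n_s, dtype=np.int8)
        beyond_ref = u01 >= b + w
        calls[beyond_ref & (u12 <= b - w)] = 1
        calls[beyond_ref & (u12 >= b + w)] = 2
        nocall = ((u01 > b - w) & (u01 < b + w)) | (
            beyond_ref & (u12 > b - w) & (u12 < b + w)
        )
        calls[nocall] = -1
        if miss_p[j] > 0:
            rng = _rng(config, _STAGE_CALL, j)
            calls[rng.random(n_s) < miss_p[j]] = -1
        geno[:, j] = calls
    return GenotypeMatrix(
        genotypes=geno,
        sample_ids=intensities.sample_ids,
        variant_ids=intensities.variant_ids,
        batch_ids=intensities.batch_ids,
    )


# ---------------------------------------------------------------------------
# traits and onset


def _piecewise_cuminc(knots: tuple) -> tuple[np.ndarray, np.ndarray]:
    ages = np.concatenate([[0.0], [k[0] for k in knots]])
    probs = np.concatenate([[0.0], [k[1] for k in knots]])
    if np.any(np.diff(ages) <= 0) or np.any(np.diff(probs) < 0) or probs[-1] > 1:
        raise ConfigurationError("cumulative incidence knots must be increasing")
    return ages, probs


def draw_onset_ages(rng: np.random.Generator, n: int, knots: tuple) -> np.ndarray:
    """Sample onset ages from a piecewise-linear cumulative incidence
    curve; NaN for subjects who never develop the disease."""
    ages, probs = _piecewise_cuminc(knots)
    u = rng.random(n)
    onset = np.full(n, np.nan)
    will = u < probs[-1]
    onset[will] = np.interp(u[will], probs, ages)
    return onset


def simulate_traits_and_onset(
    genotypes: GenotypeMatrix, panel: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes with covariate structure, plus age-of-onset data.

    Continuous traits are a linear predictor over covariates plus the
    planted per-variant betas and Gaussian noise; binary traits follow a
    logistic model anchored at the trait's target prevalence.  Onset ages
    follow the onset model's cumulative incidence curves - carriers of
    any ``hazard_scale``-flagged variant use the carrier curve - and are
    censored at the simulated age at assessment.
    """
    config.validate()
    known = set(genotypes.variant_ids)
    for spec in config.effect_specs:
        if spec.variant_id not in known:
            raise ConfigurationError(f"effect references unknown variant {spec.variant_id!r}")
    cov = config.covariate_model
    n = genotypes.n_samples
    crng = _rng(config, _STAGE_COVAR)
    pheno = pd.DataFrame({"sample_id": genotypes.sample_ids})
    pheno["age"] = crng.uniform(*cov.age_range, size=n)
    pheno["sex"] = (crng.random(n) < cov.female_fraction).astype(int)  # 1 = female
    pheno["center"] = crng.integers(0, cov.n_centers, size=n)
    pheno["chip"] = (crng.random(n) < cov.secondary_chip_fraction).astype(int)
    for i in range(1, cov.n_pcs + 1):
        pheno[f"pc{i}"] = crng.normal(0.0, cov.pc_sd, size=n)

    effects_by_trait: dict[str, list[EffectSpec]] = {}
    for spec in config.effect_specs:
        if spec.effect_type in ("beta", "log_odds_ratio"):
            effects_by_trait.setdefault(spec.trait_id, []).append(spec)

    for t_idx, trait in enumerate(config.traits):
        trng = _rng(config, _STAGE_TRAIT, t_idx)
        lp = (
            trng.normal(0, 0.02) * (pheno["age"].to_numpy() - 55.0)
            + trng.normal(0, 0.2) * pheno["sex"].to_numpy()
            + trng.normal(0, 0.1, size=cov.n_centers)[pheno["center"].to_numpy()]
            + trng.normal(0, 0.1) * pheno["chip"].to_numpy()
        )
        for i in range(1, cov.n_pcs + 1):
            lp = lp + trng.normal(0, 0.05) * pheno[f"pc{i}"].to_numpy()
        genetic = np.zeros(n)
        for spec in effects_by_trait.get(trait.trait_id, []):
            dose = np.maximum(genotypes.column(spec.variant_id).astype(float), 0.0)
            genetic += spec.magnitude * dose
        if trait.kind == "continuous":
            values = lp + genetic + trng.normal(0, trait.noise_sd, size=n)
        else:
            prob = expit(logit(trait.prevalence) + lp + genetic)
            values = (trng.random(n) < prob).astype(float)
        if trait.sex_specific:
            values = np.where(pheno["sex"].to_numpy() == 1, values, np.nan)
        pheno[trait.trait_id] = values

    orng = _rng(config, _STAGE_ONSET)
    carrier_variants = [
        s.variant_id for s in config.effect_specs if s.effect_type == "hazard_scale"
    ]
    carrier = np.zeros(n, dtype=bool)
    for vid in carrier_variants:
        carrier |= np.maximum(genotypes.column(vid).astype(float), 0.0) >= 1
    onset_age = np.full(n, np.nan)
    m = config.onset_model
    if (~carrier).any():
        onset_age[~carrier] = draw_onset_ages(orng, int((~carrier).sum()), m.baseline_knots)
    if carrier.any():
        onset_age[carrier] = draw_onset_ages(orng, int(carrier.sum()), m.carrier_knots)
    assessed = pheno["age"].to_numpy()
    event = np.isfinite(onset_age) & (onset_age <= assessed)
    onset = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "disease": m.disease_id,
            "carrier": carrier,
            "age_assessment": assessed,
            "age_onset": np.where(event, onset_age, np.nan),
            "event": event,
        }
    )
    return pheno, onset


# ---------------------------------------------------------------------------
# convenience


def simulate_cohort(config: SimConfig, use_observed_for_traits: bool = False) -> SimulatedCohort:
    """Run every simulation stage and bundle the results."""
    panel = build_variant_panel(config)
    truth = sample_truth_genotypes(panel, config)
    intens = render_intensities(truth, panel, config)
    observed = call_observed_genotypes(intens, panel, config)
    basis = observed if use_observed_for_traits else truth
    pheno, onset = simulate_traits_and_onset(basis, panel, config)
    return SimulatedCohort(
        config=config,
        panel=panel,
        truth_genotypes=truth,
        intensities=intens,
        observed_genotypes=observed,
        phenotypes=pheno,
        onset=onset,
    )


def duplicate_as_proxy(
    genotypes: GenotypeMatrix,
    panel: pd.DataFrame,
    source_id: str,
    new_id: str,
    pos_offset: int = 1_000,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Append a perfect-LD copy of a variant under a new identifier.

    The duplicate shares the source's genotype column and annotation but
    sits ``pos_offset`` bases away - a minimal linkage-disequilibrium
    proxy for exercising conditional analysis.
    """
    if new_id in genotypes.variant_ids:
        raise DataError(f"variant id {new_id!r} already present")
    col = genotypes.column(source_id)
    geno = np.column_stack([genotypes.genotypes, col]).astype(np.int8)
    new_matrix = GenotypeMatrix(
        genotypes=geno,
        sample_ids=genotypes.sample_ids,
        variant_ids=list(genotypes.variant_ids) + [new_id],
        batch_ids=genotypes.batch_ids,
    )
    src = panel[panel["variant_id"] == source_id]
    if len(src) != 1:
        raise DataError(f"variant {source_id!r} not in panel")
    row = src.iloc[0].copy()
    row["variant_id"] = new_id
    row["pos"] = int(row["pos"]) + pos_offset
    new_panel = pd.concat([panel, row.to_frame().T], ignore_index=True)
    return new_matrix, new_panel
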