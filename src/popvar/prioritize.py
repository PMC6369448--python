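"""Selection of putatively clinically relevant variants.

Two complementary routes feed the analysis set: variants with at least
one pathogenic or likely-pathogenic assertion in a ClinVar-style
annotation (conflicting records count as long as one assertion was
pathogenic; records since reclassified benign are dropped), and -
irrespective of any database record - protein-truncating variants
(stop-gain, frameshift) plus known pathogenic functional variants
(nonsynonymous, in-frame indels with a pathogenic classification) in
curated disease gene panels.  The final analysis set intersects
prioritization with QC and cluster-quality gates, with full per-variant
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import DataError

__all__ = [
    "GenePanel",
    "CONSEQUENCES",
    "CLINVAR_CLASSES",
    "select_clinvar_pathogenic",
    "select_panel_variants",
    "build_analysis_set",
]

CONSEQUENCES = (
    "stopgain",
    "frameshift",
    "nonsynonymous",
    "inframe_indel",
    "synonymous",
    "other",
)
CLINVAR_CLASSES = (
    "pathogenic",
    "likely_pathogenic",
    "conflicting",
    "benign",
    "reclassified_benign",
    "none",
)

#: ClinVar-style classes that carry at least one pathogenic assertion.
#: ``conflicting`` means conflicting submissions of which at least one was
#: pathogenic/likely pathogenic; purely benign conflicts are expected to be
#: annotated ``benign`` upstream.
PATHOGENIC_CLASSES = ("pathogenic", "likely_pathogenic", "conflicting")

PTV_CONSEQUENCES = ("stopgain", "frameshift")
FUNCTIONAL_CONSEQUENCES = ("nonsynonymous", "inframe_indel")


@dataclass
class GenePanel:
    """A curated disease gene panel with per-gene mode of inheritance."""

    panel_id: str
    genes: pd.DataFrame  # gene, moi, mechanism

    def __post_init__(self):
        if len(self.genes) == 0:
            raise DataError(f"panel {self.panel_id}: empty gene set")
        self.gene_set = set(self.genes["gene"])

    @classmethod
    def from_records(cls, panel_id: str, records) -> "GenePanel":
        return cls(panel_id, pd.DataFrame(records, columns=["gene", "moi", "mechanism"]))


def _check_vocab(panel: pd.DataFrame) -> None:
    bad_cons = set(panel["consequence"]) - set(CONSEQUENCES)
    bad_clin = set(panel["clinvar_class"]) - set(CLINVAR_CLASSES)
    if bad_cons or bad_clin:
        raise DataError(
            f"unknown annotation values: consequence={bad_cons}, clinvar={bad_clin}"
        )


def select_clinvar_pathogenic(panel: pd.DataFrame) -> pd.DataFrame:
    """Variants with at least one pathogenic/likely-pathogenic assertion.

    Conflicting classifications are not excluded; variants reclassified as
    benign since annotation are.
    """
    _check_vocab(panel)
    keep = panel["clinvar_class"].isin(PATHOGENIC_CLASSES)
    return panel[keep].copy()


def select_panel_variants(panel: pd.DataFrame, gene_panel: GenePanel) -> pd.DataFrame:
    """Panel-gene variants selected by consequence, ClinVar-independent.

    Protein-truncating variants (stop-gain, frameshift) in a panel gene are
    always selected; nonsynonymous and in-frame indel variants only when
    they additionally carry a pathogenic/likely-pathogenic classification.
    Unknown gene symbols in the panel produce a warning attribute, not an
    error, since curated lists routinely outpace annotation builds.
    """
    _check_vocab(panel)
    in_panel = panel["gene"].isin(gene_panel.gene_set)
    ptv = panel["consequence"].isin(PTV_CONSEQUENCES)
    functional = panel["consequence"].isin(FUNCTIONAL_CONSEQUENCES) & panel[
        "clinvar_class"
    ].isin(("pathogenic", "likely_pathogenic"))
    out = panel[in_panel & (ptv | functional)].copy()
    out.attrs["unknown_panel_genes"] = sorted(
        gene_panel.gene_set - set(panel["gene"])
    )
    return out


def build_analysis_set(
    prioritized: pd.DataFrame,
    qc_table: pd.DataFrame,
    quality_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect prioritization, QC and cluster-quality gates.

    ``qc_table`` must carry ``variant_id``/``excluded`` (from the QC filter
    cascade) and ``quality_table`` ``variant_id``/``group``.  Returns
    (analysis_set, provenance): the analysis set is the subset passing all
    three gates (prioritized, QC-passed, quality group high); provenance
    records every prioritized variant with a boolean per gate.
    """
    for name, table, cols in (
        ("qc", qc_table, {"variant_id", "excluded"}),
        ("quality", quality_table, {"variant_id", "group"}),
    ):
        missing = cols - set(table.columns)
        if missing:
            raise DataError(f"{name} table missing columns {missing}")
    ids = prioritized["variant_id"]
    orphans = set(ids) - set(qc_table["variant_id"]) | set(ids) - set(
        quality_table["variant_id"]
    )
    if orphans:
        raise DataError(f"variants without QC or quality records: {sorted(orphans)}")
    qc = qc_table.set_index("variant_id")["excluded"]
    grp = quality_table.set_index("variant_id")["group"]
    provenance = prioritized[["variant_id"]].copy()
    provenance["prioritized"] = True
    provenance["qc_passed"] = (~qc.loc[ids]).to_numpy()
    provenance["high_quality"] = (grp.loc[ids] == "high").to_numpy()
    provenance["in_analysis_set"] = (
        provenance["qc_passed"] & provenance["high_quality"]
    )
    analysis = prioritized[provenance["in_analysis_set"].to_numpy()].copy()
    return analysis, provenance
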