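"""Small reference datasets bundled with the package.

The headline reference is the published manual cluster-plot evaluation of
4,585 putatively clinically relevant rare variants genotyped on the UK
Biobank arrays, binned by minor-allele frequency: per bin, the number of
variants judged false positive (score 1-2), true positive (score 4-5) and
unclear (score 3).  Those counts anchor the package's MAF-binning, FPR
and ROC calibration machinery.  Example MODY and developmental-disorder
gene panels are provided for the prioritization rules.
"""

from __future__ import annotations

import pandas as pd

from .prioritize import GenePanel

__all__ = [
    "ukb_quality_by_maf_bin",
    "mody_gene_panel",
    "dd_gene_panel",
]

# (bin_lo_pct, bin_hi_pct, fp, tp, unclear) from the published manual
# evaluation of rare-variant cluster plots on the UK Biobank arrays
_UKB_QUALITY_COUNTS = (
    (0.0, 0.0005, 511, 0, 11),
    (0.0005, 0.001, 607, 8, 59),
    (0.001, 0.005, 1598, 218, 210),
    (0.005, 0.01, 138, 204, 73),
    (0.01, 0.05, 66, 456, 48),
    (0.05, 0.1, 2, 129, 5),
    (0.1, 0.5, 6, 189, 7),
    (0.5, 1.0, 0, 40, 0),
)


def ukb_quality_by_maf_bin() -> pd.DataFrame:
    """Reference MAF-binned quality counts (FP / TP / unclear per bin).

    Returns a table in the same layout that
    :func:`popvar.cluster.bin_by_maf` produces (without a totals row):
    columns ``bin_lo``/``bin_hi`` in percent plus per-group counts.
    """
    table = pd.DataFrame(
        _UKB_QUALITY_COUNTS, columns=["bin_lo", "bin_hi", "fp", "tp", "unclear"]
    )
    table["total"] = table[["fp", "tp", "unclear"]].sum(axis=1)
    return table


def mody_gene_panel() -> GenePanel:
    """Example maturity-onset diabetes of the young (MODY) gene panel."""
    return GenePanel.from_records(
        "MODY",
        [
            ("HNF1A", "AD", "other"),
            ("HNF4A", "AD", "other"),
            ("GCK", "AD", "other"),
            ("HNF1B", "AD", "haploinsufficiency"),
        ],
    )


def dd_gene_panel() -> GenePanel:
    """Example dominant developmental-disorder gene panel."""
    return GenePanel.from_records(
        "DD",
        [
            ("COL4A3", "AD", "haploinsufficiency"),
            ("GNAS", "AD", "haploinsufficiency"),
            ("HIST1H1E", "AD", "haploinsufficiency"),
            ("RNF135", "AD", "haploinsufficiency"),
            ("TGIF1", "AD", "haploinsufficiency"),
            ("ARID1B", "AD", "haploinsufficiency"),
            ("TCF4", "AD", "haploinsufficiency"),
        ],
    )
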