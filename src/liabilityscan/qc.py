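"""Editing rules applied to markers, genotyped individuals and sires.

Markers and genotyped individuals with call rate below 99% are discarded,
then monomorphic markers and markers with minor allele frequency below
0.05, then non-autosomal markers; genotyped sires keep their genotype only
if at least 5 daughters have a phenotype.  "Below" is strict throughout:
a marker at exactly MAF 0.05 or an individual at exactly 99% survives.

Rule order (documented, reported in QcReport): individual call rate ->
marker call rate -> monomorphic/MAF -> autosome.  Allele frequencies are
computed after the call-rate removals so they describe the analyzed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import MISSING, MarkerPanel

__all__ = ["QcThresholds", "QcReport", "filter_markers", "filter_individuals",
           "mean_impute"]


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.99
    min_maf: float = 0.05
    autosomes: frozenset = frozenset(str(c) for c in range(1, 30))
    min_phenotyped_daughters: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.min_call_rate <= 1.0):
            raise ValueError("min_call_rate must be in (0, 1]")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class QcReport:
    """Per-rule removal counts plus surviving ID lists."""

    rule_order: list = field(default_factory=list)
    removed: dict = field(default_factory=dict)       # rule -> count
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0
    surviving_markers: list = field(default_factory=list)
    surviving_individuals: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rule_order": self.rule_order,
            "removed": self.removed,
            "n_markers_in": self.n_markers_in,
            "n_markers_out": self.n_markers_out,
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
        }


def _marker_call_rate(g: np.ndarray) -> np.ndarray:
    return (g != MISSING).mean(axis=0)


def _individual_call_rate(g: np.ndarray) -> np.ndarray:
    return (g != MISSING).mean(axis=1)


def filter_markers(panel: MarkerPanel, thresholds: QcThresholds = QcThresholds()
                   ) -> tuple[MarkerPanel, QcReport]:
    """Drop markers failing call-rate, monomorphism/MAF or autosome rules."""
    report = QcReport(
        rule_order=["marker_call_rate", "monomorphic_or_maf", "non_autosomal"],
        n_markers_in=panel.n_markers,
        n_individuals_in=panel.n_individuals,
    )
    g = panel.genotypes
    keep = _marker_call_rate(g) >= thresholds.min_call_rate
    report.removed["marker_call_rate"] = int((~keep).sum())

    # frequencies on the post-call-rate marker set
    p = panel.compute_allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    poly = (p > 0.0) & (p < 1.0)
    ok = poly & (maf >= thresholds.min_maf)
    report.removed["monomorphic_or_maf"] = int((keep & ~ok).sum())
    keep &= ok

    chrom = panel.marker_map["chrom"].astype(str).to_numpy()
    auto = np.isin(chrom, list(thresholds.autosomes))
    report.removed["non_autosomal"] = int((keep & ~auto).sum())
    keep &= auto

    if not keep.any():
        raise ValueError("no markers survive QC")
    out = panel.subset_markers(keep)
    report.n_markers_out = out.n_markers
    report.n_individuals_out = out.n_individuals
    report.surviving_markers = out.marker_map["marker"].tolist()
    report.surviving_individuals = list(out.ids)
    return out, report


def filter_individuals(panel: MarkerPanel, phenotypes: pd.DataFrame,
                       thresholds: QcThresholds = QcThresholds()
                       ) -> tuple[MarkerPanel, QcReport]:
    """Drop genotyped individuals with low call rate, and genotyped sires
    with fewer than ``min_phenotyped_daughters`` phenotyped daughters.

    Removal is from the genotyped set only; dropped animals remain in the
    pedigree.  An empty surviving set is legal (pedigree-only evaluation).
    """
    report = QcReport(
        rule_order=["individual_call_rate", "min_phenotyped_daughters"],
        n_markers_in=panel.n_markers,
        n_individuals_in=panel.n_individuals,
    )
    keep = _individual_call_rate(panel.genotypes) >= thresholds.min_call_rate
    report.removed["individual_call_rate"] = int((~keep).sum())

    counts = phenotypes.loc[phenotypes["y"].notna(), "sire"].value_counts()
    enough = np.array([
        counts.get(i, 0) >= thresholds.min_phenotyped_daughters
        for i in panel.ids
    ])
    report.removed["min_phenotyped_daughters"] = int((keep & ~enough).sum())
    keep &= enough

    out = panel.subset_individuals(panel.ids[keep])
    report.n_markers_out = out.n_markers
    report.n_individuals_out = out.n_individuals
    report.surviving_markers = out.marker_map["marker"].tolist()
    report.surviving_individuals = list(out.ids)
    return out, report


def mean_impute(panel: MarkerPanel) -> np.ndarray:
    """Float genotype matrix with missing calls replaced by 2p.

    Used only when building relationship matrices; genotype files are
    never rewritten with imputed values.
    """
    g = panel.genotypes.astype(float)
    p = panel.allele_freqs
    miss = panel.genotypes == MISSING
    if miss.any():
        g[miss] = np.broadcast_to(2.0 * p, g.shape)[miss]
    return g
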