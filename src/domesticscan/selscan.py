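"""The three-criterion purifying-selection scan.

A SNP is called under purifying selection when, in the wild-vs-landrace
contrast:

1. its per-site reduction of diversity exceeds the mean gene-level RoD
   of the neutral loci (the neutral baseline),
2. its per-site Hudson F_ST is strictly positive, and
3. Tajima's D of the landrace group at that site is defined and strictly
   negative.

Criterion 1 is evaluated in cross-multiplied form,
``pi_wild > baseline * pi_landrace``, so a site with an infinite RoD
(landrace invariant) passes without dividing by zero -- but such a site
necessarily fails criterion 3 (no segregating landrace allele means an
undefined D), so it is never called.  Gene-level calls aggregate SNP
calls: a gene is under selection when at least one of its SNPs passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    """Raised when the neutral baseline cannot be computed."""


@dataclass
class NeutralBaseline:
    """Mean gene-level RoD over the neutral loci with finite RoD."""

    mean_rod: float
    n_loci_used: int
    n_loci_excluded_nonfinite: int


@dataclass
class SelectionCall:
    """Gene-level aggregation of per-SNP selection calls."""

    gene_id: str
    n_snps_total: int
    n_snps_selected: int
    selected_snps: list[tuple[int, str | None]]  # (cds_position, functional_class)
    under_selection: bool
    has_nonsyn_selected: bool


def neutral_baseline(gene_stats: pd.DataFrame) -> NeutralBaseline:
    """Calibrate the RoD baseline on neutral loci.

    ``gene_stats`` must carry ``is_neutral`` and ``rod`` columns; only
    neutral rows enter.  Loci with non-finite RoD (landrace-invariant or
    both groups invariant) are excluded from the mean and counted.
    """
    neutral = gene_stats.loc[gene_stats["is_neutral"], "rod"].to_numpy(dtype=float)
    finite = neutral[np.isfinite(neutral)]
    if finite.size == 0:
        raise CalibrationError("no neutral locus with finite RoD")
    return NeutralBaseline(
        mean_rod=float(finite.mean()),
        n_loci_used=int(finite.size),
        n_loci_excluded_nonfinite=int(neutral.size - finite.size),
    )


def snp_selection_test(pi_wild: float, pi_landrace: float, fst_site: float,
                       tajima_d_site_landrace: float,
                       baseline: NeutralBaseline) -> bool:
    """Apply the three criteria to one SNP's per-site statistics."""
    if math.isnan(pi_wild) or math.isnan(pi_landrace):
        return False
    crit1 = pi_wild > baseline.mean_rod * pi_landrace
    crit2 = (not math.isnan(fst_site)) and fst_site > 0
    crit3 = (not math.isnan(tajima_d_site_landrace)) and tajima_d_site_landrace < 0
    return crit1 and crit2 and crit3


def flag_selected_snps(site_stats: pd.DataFrame,
                       baseline: NeutralBaseline) -> pd.DataFrame:
    """Add a boolean ``selected`` column applying the three criteria per row."""
    out = site_stats.copy()
    out["selected"] = [
        snp_selection_test(row.pi_wild, row.pi_landrace, row.fst_site,
                           row.tajima_d_site_landrace, baseline)
        for row in site_stats.itertuples()
    ]
    return out


def gene_selection_calls(site_stats: pd.DataFrame,
                         baseline: NeutralBaseline) -> list[SelectionCall]:
    """Aggregate per-SNP calls to gene level.

    Returns one call per gene present in ``site_stats`` (genes with zero
    SNPs in the table are absent -- they trivially carry no selected SNP).
    """
    flagged = (site_stats if "selected" in site_stats.columns
               else flag_selected_snps(site_stats, baseline))
    has_func = "functional_class" in flagged.columns
    calls = []
    for gene_id, grp in flagged.groupby("gene_id", sort=True):
        sel = grp[grp["selected"]]
        snps = [(int(r.cds_position),
                 getattr(r, "functional_class", None) if has_func else None)
                for r in sel.itertuples()]
        calls.append(SelectionCall(
            gene_id=str(gene_id),
            n_snps_total=len(grp),
            n_snps_selected=len(sel),
            selected_snps=snps,
            under_selection=len(sel) >= 1,
            has_nonsyn_selected=any(fc == "nonsynonymous" for _, fc in snps),
        ))
    return calls


def selection_calls_table(calls: list[SelectionCall]) -> pd.DataFrame:
    """One row per gene, for the selection_calls TSV."""
    return pd.DataFrame([{
        "gene_id": c.gene_id,
        "n_snps_total": c.n_snps_total,
        "n_snps_selected": c.n_snps_selected,
        "under_selection": c.under_selection,
        "has_nonsyn_selected": c.has_nonsyn_selected,
    } for c in calls])
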