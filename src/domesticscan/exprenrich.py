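"""Seed-preferential expression classification and selection enrichment.

A gene is classified as seed-preferential when its maximum FPKM over
seed-tissue samples exceeds twice its maximum over non-seed samples
(strict inequality), with the non-seed maximum floored at 1 FPKM so a
gene silent outside the seed does not produce an infinite fold change.
Enrichment of selection among seed-preferential genes is tested with an
uncorrected Pearson chi-square on the 2x2 gene table, implemented from
the textbook formula (the statistic is the point of the module, so it is
not delegated to a library; only the chi-square(1) survival function for
the p-value comes from scipy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

FOLD_THRESHOLD = 2.0
FPKM_FLOOR = 1.0


@dataclass
class ExpressionProfile:
    """Per-gene FPKM values over labeled tissue samples."""

    gene_id: str
    fpkm_by_sample: dict[str, float]
    tissue_class: dict[str, str]          # sample -> {"seed", "non_seed"}

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fpkm_by_sample.values()):
            raise ValueError(f"{self.gene_id}: negative FPKM")
        classes = set(self.tissue_class.values())
        if not {"seed", "non_seed"} <= classes:
            raise ValueError(f"{self.gene_id}: need both seed and non_seed samples")

    @property
    def max_seed(self) -> float:
        return max(v for s, v in self.fpkm_by_sample.items()
                   if self.tissue_class[s] == "seed")

    @property
    def max_nonseed(self) -> float:
        return max(v for s, v in self.fpkm_by_sample.items()
                   if self.tissue_class[s] == "non_seed")


@dataclass
class ContingencyTable2x2:
    """Counts: rows seed-preferential yes/no, columns under-selection yes/no."""

    a: int  # seed-preferential & selected
    b: int  # seed-preferential & not selected
    c: int  # not seed-preferential & selected
    d: int  # not seed-preferential & not selected

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")


def classify_seed_preferential(profile: ExpressionProfile,
                               fold_threshold: float = FOLD_THRESHOLD,
                               floor: float = FPKM_FLOOR) -> bool:
    """True iff max seed FPKM > fold_threshold * max(max non-seed FPKM, floor)."""
    return profile.max_seed > fold_threshold * max(profile.max_nonseed, floor)


def pearson_chi2_2x2(table: ContingencyTable2x2) -> dict[str, float]:
    """Uncorrected Pearson chi-square for a 2x2 table, df = 1.

    chi2 = sum (O - E)^2 / E with expected counts from the margins.
    Returns ``nan`` statistic when any margin is zero.
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if n == 0 or (row == 0).any() or (col == 0).any():
        return {"statistic": math.nan, "df": 1, "p_value": math.nan}
    expected = np.outer(row, col) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return {"statistic": chi2, "df": 1,
            "p_value": float(_scipy_stats.chi2.sf(chi2, df=1))}


def read_expression(expression_path, tissues_path) -> list[ExpressionProfile]:
    """Read the FPKM matrix and the sample-label/tissue-class TSVs."""
    expr = pd.read_csv(expression_path, sep="\t", index_col="gene_id")
    tissues = pd.read_csv(tissues_path, sep="\t", header=None,
                          names=["sample_label", "tissue_class"])
    klass = dict(zip(tissues["sample_label"], tissues["tissue_class"]))
    missing = [c for c in expr.columns if c not in klass]
    if missing:
        raise ValueError(f"expression samples without tissue class: {missing}")
    return [
        ExpressionProfile(gene_id=str(g),
                          fpkm_by_sample=expr.loc[g].to_dict(),
                          tissue_class={c: klass[c] for c in expr.columns})
        for g in expr.index
    ]


def enrichment_report(under_selection: dict[str, bool],
                      profiles: list[ExpressionProfile],
                      fold_threshold: float = FOLD_THRESHOLD) -> dict:
    """Build the seed-preferential x under-selection 2x2 table and test it.

    Only genes present in both inputs enter.  Percentages of genes under
    selection within each expression class are rounded to the nearest
    integer, matching how such enrichments are reported.
    """
    shared = [p for p in profiles if p.gene_id in under_selection]
    if not shared:
        raise ValueError("no genes shared between selection calls and expression")
    a = b = c = d = 0
    seed_pref_flags = {}
    for p in shared:
        sp = classify_seed_preferential(p, fold_threshold)
        seed_pref_flags[p.gene_id] = sp
        sel = under_selection[p.gene_id]
        if sp and sel:
            a += 1
        elif sp:
            b += 1
        elif sel:
            c += 1
        else:
            d += 1
    table = ContingencyTable2x2(a, b, c, d)
    chi2 = pearson_chi2_2x2(table)
    pct_seed = round(100.0 * a / (a + b)) if a + b else math.nan
    pct_other = round(100.0 * c / (c + d)) if c + d else math.nan
    return {
        "table": {"a": a, "b": b, "c": c, "d": d},
        "n_genes": len(shared),
        "pct_selected_in_seed_preferential": pct_seed,
        "pct_selected_in_others": pct_other,
        "chi2": chi2["statistic"],
        "p_value": chi2["p_value"],
        "seed_preferential": seed_pref_flags,
    }
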