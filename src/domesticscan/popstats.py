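"""Core population-genetic estimators.

Gene-level and per-site nucleotide diversity (theta-pi, Nei & Li), Watterson's
theta, Tajima's D, Hudson's F_ST, and the reduction of diversity (RoD) --
the fold decrease of theta-pi in the landrace group relative to the
wild/weedy group, the central quantity of the domestication scan.

Missing data are handled complete-case per site: a site contributes
within-group information only where the group has >= 2 non-missing calls.
Undefined statistics (e.g. Tajima's D with no segregating sites, F_ST with
zero between-group diversity) are returned as ``nan`` and serialized as
``NA``; an infinite RoD (landrace invariant, wild variable) is ``inf``,
serialized as ``Inf``.

Gene-level theta-pi divides by the full CDS length, so values are on the
per-site scale of published diversity estimates (order 1e-3 for sorghum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from domesticscan.seqio import AlignmentMatrix, Dataset

WILD = "wild_weedy"
LANDRACE = "landrace"


@dataclass
class GeneStats:
    """Per-gene summary statistics for the wild-vs-landrace contrast."""

    gene_id: str
    n_sites_polymorphic: int
    theta_pi_by_group: dict[str, float]
    theta_w_by_group: dict[str, float]
    tajima_d_by_group: dict[str, float]
    fst: float
    rod: float


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 normalizing constants of Tajima's D.

    Exact published small-sample constants for a sample of ``n`` sequences.
    """
    if n < 2:
        raise ValueError("Tajima constants need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _subset_rows(matrix: AlignmentMatrix, samples: list[str] | None) -> np.ndarray:
    if samples is None:
        return matrix.alleles
    return matrix.alleles[matrix.sample_indices(samples), :]


def _site_counts(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case reference/alternate allele counts per site."""
    n_alt = (rows == 1).sum(axis=0)
    n_ref = (rows == 0).sum(axis=0)
    return n_ref, n_alt


def _site_pi(n_ref: np.ndarray, n_alt: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 2*nr*na / (n*(n-1)); 0 where n < 2."""
    n = n_ref + n_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * n_ref * n_alt / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def theta_pi(matrix: AlignmentMatrix, samples: list[str] | None = None) -> float:
    """Average pairwise diversity per site (Nei & Li theta-pi).

    Sums per-site pairwise mismatch rates over the polymorphic sites and
    divides by the full CDS length; monomorphic sites contribute zero.
    Returns ``nan`` when no site has two usable samples.
    """
    rows = _subset_rows(matrix, samples)
    if rows.shape[0] < 2:
        return math.nan
    if matrix.n_sites == 0:
        return 0.0
    n_ref, n_alt = _site_counts(rows)
    if np.all(n_ref + n_alt < 2):
        return math.nan
    return float(_site_pi(n_ref, n_alt).sum() / matrix.cds_length)


def segregating_sites(matrix: AlignmentMatrix, samples: list[str] | None = None) -> int:
    """Number of sites segregating (both alleles seen) within the subset."""
    rows = _subset_rows(matrix, samples)
    n_ref, n_alt = _site_counts(rows)
    return int(np.sum((n_ref >= 1) & (n_alt >= 1)))


def watterson_theta(matrix: AlignmentMatrix, samples: list[str] | None = None) -> float:
    """Watterson's per-site theta, S / (a1 * L), with per-site complete-case n."""
    rows = _subset_rows(matrix, samples)
    if rows.shape[0] < 2:
        return math.nan
    n_ref, n_alt = _site_counts(rows)
    seg = (n_ref >= 1) & (n_alt >= 1)
    total = 0.0
    for n in (n_ref + n_alt)[seg]:
        total += 1.0 / tajima_constants(int(n))["a1"]
    return total / matrix.cds_length


def mean_pairwise_differences(matrix: AlignmentMatrix,
                              samples: list[str] | None = None) -> float:
    """Mean pairwise difference count k-bar (summed over sites, not per site)."""
    rows = _subset_rows(matrix, samples)
    if rows.shape[0] < 2:
        return math.nan
    n_ref, n_alt = _site_counts(rows)
    return float(_site_pi(n_ref, n_alt).sum())


def tajima_d(matrix: AlignmentMatrix, samples: list[str] | None = None) -> float:
    """Tajima's D for the subset; ``nan`` when S = 0 or n < 4.

    D = (k-bar - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard
    small-sample constants of :func:`tajima_constants` and n taken as the
    subset size (the panel emulated here has no missing calls; with
    missing data the statistic is approximate).
    """
    rows = _subset_rows(matrix, samples)
    n = rows.shape[0]
    if n < 4:
        return math.nan
    s = segregating_sites(matrix, samples)
    if s == 0:
        return math.nan
    k = mean_pairwise_differences(matrix, samples)
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return float((k - s / c["a1"]) / math.sqrt(var))


def _site_between(n_ref_a, n_alt_a, n_ref_b, n_alt_b) -> np.ndarray:
    """Per-site mean pairwise difference rate across between-group pairs."""
    na, nb = n_ref_a + n_alt_a, n_ref_b + n_alt_b
    with np.errstate(divide="ignore", invalid="ignore"):
        hb = (n_ref_a * n_alt_b + n_alt_a * n_ref_b) / (na * nb)
    return np.where((na >= 1) & (nb >= 1), hb, 0.0)


def hudson_fst(matrix: AlignmentMatrix, group_a: list[str],
               group_b: list[str]) -> float:
    """Gene-level Hudson F_ST = 1 - Hw/Hb between two sample groups.

    Hw is the unweighted mean of the two within-group per-site
    heterozygosities and Hb the between-group pairwise difference rate;
    both are summed over the sites where each group has >= 2 usable
    samples before taking the ratio (ratio-of-sums aggregation).  May be
    negative; ``nan`` when the summed Hb is zero or a group never has two
    usable samples.
    """
    rows_a = _subset_rows(matrix, group_a)
    rows_b = _subset_rows(matrix, group_b)
    if rows_a.shape[0] < 2 or rows_b.shape[0] < 2:
        return math.nan
    if matrix.n_sites == 0:
        return math.nan
    nra, naa = _site_counts(rows_a)
    nrb, nab = _site_counts(rows_b)
    usable = (nra + naa >= 2) & (nrb + nab >= 2)
    if not usable.any():
        return math.nan
    hw = 0.5 * (_site_pi(nra, naa) + _site_pi(nrb, nab))
    hb = _site_between(nra, naa, nrb, nab)
    hb_sum = float(hb[usable].sum())
    if hb_sum == 0.0:
        return math.nan
    return 1.0 - float(hw[usable].sum()) / hb_sum


def rod(pi_wild: float, pi_landrace: float) -> float:
    """Reduction of diversity: fold decrease of theta-pi in the landrace group.

    ``inf`` when the landrace group is invariant but the wild group is
    not; ``nan`` when both diversities are zero.
    """
    if pi_wild < 0 or pi_landrace < 0:
        raise ValueError("diversity values must be non-negative")
    if pi_landrace == 0.0:
        return math.inf if pi_wild > 0 else math.nan
    return pi_wild / pi_landrace


def per_site_stats(matrix: AlignmentMatrix, wild: list[str],
                   landrace: list[str]) -> pd.DataFrame:
    """Per-SNP statistics over a 1-bp sliding window (window = step = 1).

    For every site in the matrix: within-group per-site diversities,
    Hudson F_ST restricted to the site, Tajima's D of the landrace group
    evaluated at the site alone (S = 1; ``nan`` where the landrace group
    is monomorphic or has fewer than 4 usable calls), and the per-site
    RoD.  Returns one row per site.
    """
    rows_w = _subset_rows(matrix, wild)
    rows_l = _subset_rows(matrix, landrace)
    nrw, naw = _site_counts(rows_w)
    nrl, nal = _site_counts(rows_l)
    nw, nl = nrw + naw, nrl + nal
    pi_w = np.where(nw >= 2, _site_pi(nrw, naw), np.nan)
    pi_l = np.where(nl >= 2, _site_pi(nrl, nal), np.nan)

    hb = _site_between(nrw, naw, nrl, nal)
    hw = 0.5 * (_site_pi(nrw, naw) + _site_pi(nrl, nal))
    with np.errstate(divide="ignore", invalid="ignore"):
        fst_site = 1.0 - hw / hb
    fst_site = np.where((nw >= 2) & (nl >= 2) & (hb > 0), fst_site, np.nan)

    d_site = np.full(matrix.n_sites, np.nan)
    for j in range(matrix.n_sites):
        n = int(nl[j])
        if n >= 4 and nrl[j] >= 1 and nal[j] >= 1:
            c = tajima_constants(n)
            d_site[j] = (pi_l[j] - 1.0 / c["a1"]) / math.sqrt(c["e1"])

    rod_site = np.full(matrix.n_sites, np.nan)
    for j in range(matrix.n_sites):
        if not (math.isnan(pi_w[j]) or math.isnan(pi_l[j])):
            rod_site[j] = rod(float(pi_w[j]), float(pi_l[j]))

    return pd.DataFrame({
        "gene_id": matrix.gene_id,
        "cds_position": matrix.positions,
        "ref_allele": matrix.ref_alleles,
        "alt_allele": matrix.alt_alleles,
        "pi_wild": pi_w,
        "pi_landrace": pi_l,
        "fst_site": fst_site,
        "tajima_d_site_landrace": d_site,
        "rod_site": rod_site,
    })


def gene_stats(matrix: AlignmentMatrix, wild: list[str],
               landrace: list[str]) -> GeneStats:
    """All gene-level statistics for one gene."""
    pooled = wild + landrace
    pi_w = theta_pi(matrix, wild)
    pi_l = theta_pi(matrix, landrace)
    return GeneStats(
        gene_id=matrix.gene_id,
        n_sites_polymorphic=segregating_sites(matrix, pooled),
        theta_pi_by_group={WILD: pi_w, LANDRACE: pi_l},
        theta_w_by_group={WILD: watterson_theta(matrix, wild),
                          LANDRACE: watterson_theta(matrix, landrace)},
        tajima_d_by_group={WILD: tajima_d(matrix, wild),
                           LANDRACE: tajima_d(matrix, landrace)},
        fst=hudson_fst(matrix, wild, landrace),
        rod=rod(pi_w if not math.isnan(pi_w) else 0.0,
                pi_l if not math.isnan(pi_l) else 0.0),
    )


def gene_stats_table(dataset: Dataset, wild_label: str = WILD,
                     landrace_label: str = LANDRACE) -> pd.DataFrame:
    """Gene-level statistics for every gene in a dataset, one row per gene."""
    wild = dataset.samples_in_group(wild_label)
    landrace = dataset.samples_in_group(landrace_label)
    rows = []
    for gene_id in sorted(dataset.matrices):
        gs = gene_stats(dataset.matrices[gene_id], wild, landrace)
        rows.append({
            "gene_id": gs.gene_id,
            "is_neutral": dataset.gene_models[gene_id].is_neutral,
            "n_sites_polymorphic": gs.n_sites_polymorphic,
            "theta_pi_wild": gs.theta_pi_by_group[WILD],
            "theta_pi_landrace": gs.theta_pi_by_group[LANDRACE],
            "theta_w_wild": gs.theta_w_by_group[WILD],
            "theta_w_landrace": gs.theta_w_by_group[LANDRACE],
            "tajima_d_wild": gs.tajima_d_by_group[WILD],
            "tajima_d_landrace": gs.tajima_d_by_group[LANDRACE],
            "fst": gs.fst,
            "rod": gs.rod,
        })
    return pd.DataFrame(rows)


def site_stats_table(dataset: Dataset, wild_label: str = WILD,
                     landrace_label: str = LANDRACE) -> pd.DataFrame:
    """Per-site statistics for every gene, concatenated."""
    wild = dataset.samples_in_group(wild_label)
    landrace = dataset.samples_in_group(landrace_label)
    frames = [per_site_stats(dataset.matrices[g], wild, landrace)
              for g in sorted(dataset.matrices)
              if dataset.matrices[g].n_sites > 0]
    if not frames:
        return pd.DataFrame(columns=["gene_id", "cds_position", "ref_allele",
                                     "alt_allele", "pi_wild", "pi_landrace",
                                     "fst_site", "tajima_d_site_landrace",
                                     "rod_site"])
    return pd.concat(frames, ignore_index=True)


def write_stats_tsv(df: pd.DataFrame, path) -> None:
    """Write a statistics table with Inf/NA conventions for non-finite values."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda v: "NA" if math.isnan(v) else ("Inf" if math.isinf(v) else repr(v))
            )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
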