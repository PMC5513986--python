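"""Haplotype enumeration and haplotype-network construction.

For each gene the distinct CDS haplotypes over its polymorphic sites are
enumerated (samples with any missing call at those sites are excluded,
complete-case), tabulated by population group, and linked into a
minimum-spanning-tree network over pairwise Hamming distances.  An MST
is used instead of a statistical-parsimony network: it is deterministic
and testable while preserving the qualitative content of a haplotype
map -- distance-weighted links between haplotypes with node sizes
proportional to carrier counts and colors by group.  Ties are broken by
(distance, smaller haplotype index pair), so the edge set is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from domesticscan.seqio import AlignmentMatrix


@dataclass
class HaplotypeSet:
    """Distinct haplotypes of one gene with per-group carrier counts."""

    gene_id: str
    haplotypes: list[str]                      # allele strings over polymorphic sites
    counts_by_group: pd.DataFrame              # haplotype index x group
    n_samples_excluded_missing: int
    edges: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def total_count(self) -> int:
        return int(self.counts_by_group.to_numpy().sum())


def enumerate_haplotypes(matrix: AlignmentMatrix,
                         groups: dict[str, str]) -> HaplotypeSet:
    """Enumerate distinct haplotypes with per-group carrier counts.

    Haplotypes are strings of actual alleles (ref/alt bases) over the
    gene's polymorphic sites, ordered by first appearance in sample
    order so numbering is stable.  With zero polymorphic sites the
    result is a single (empty-string) haplotype carried by everyone.
    """
    group_order = sorted(set(groups.values()))
    hap_index: dict[str, int] = {}
    counts: list[dict[str, int]] = []
    excluded = 0
    for i, sample in enumerate(matrix.sample_ids):
        row = matrix.alleles[i, :]
        if (row < 0).any():
            excluded += 1
            continue
        hap = "".join(matrix.alt_alleles[j] if row[j] else matrix.ref_alleles[j]
                      for j in range(matrix.n_sites))
        if hap not in hap_index:
            hap_index[hap] = len(hap_index)
            counts.append({g: 0 for g in group_order})
        counts[hap_index[hap]][groups[sample]] += 1
    haplotypes = sorted(hap_index, key=hap_index.get)
    counts_df = pd.DataFrame(counts, columns=group_order, dtype=int)
    counts_df.index.name = "haplotype"
    return HaplotypeSet(
        gene_id=matrix.gene_id,
        haplotypes=haplotypes,
        counts_by_group=counts_df,
        n_samples_excluded_missing=excluded,
    )


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_network(haps: HaplotypeSet) -> HaplotypeSet:
    """Attach minimum-spanning-tree edges over pairwise Hamming distances.

    Kruskal's algorithm over edges sorted by (distance, i, j); with the
    deterministic tie-break the MST edge list is unique for given
    haplotype numbering.  Returns the same set with ``edges`` filled:
    (i, j, distance) with i < j, exactly n_haplotypes - 1 edges.
    """
    k = haps.n_haplotypes
    edges_all = sorted(
        (hamming(haps.haplotypes[i], haps.haplotypes[j]), i, j)
        for i in range(k) for j in range(i + 1, k)
    )
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst: list[tuple[int, int, int]] = []
    for d, i, j in edges_all:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst.append((i, j, d))
            if len(mst) == k - 1:
                break
    haps.edges = mst
    return haps


def haplotypes_table(haps: HaplotypeSet) -> pd.DataFrame:
    """One row per haplotype: allele string and per-group counts."""
    df = haps.counts_by_group.copy()
    df.insert(0, "haplotype_id", [f"H{i + 1}" for i in range(haps.n_haplotypes)])
    df.insert(1, "alleles", haps.haplotypes)
    df.insert(0, "gene_id", haps.gene_id)
    return df.reset_index(drop=True)


def edges_table(haps: HaplotypeSet) -> pd.DataFrame:
    """One row per MST edge with the Hamming distance as length."""
    return pd.DataFrame(
        [{"gene_id": haps.gene_id, "hap_i": f"H{i + 1}", "hap_j": f"H{j + 1}",
          "distance": d} for i, j, d in haps.edges],
        columns=["gene_id", "hap_i", "hap_j", "distance"])


def plot_network(haps: HaplotypeSet, ax=None):
    """Draw the network: circles scaled by carrier count, colored by group.

    Requires matplotlib; layout is a deterministic spring embedding over
    the MST edges.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    k = haps.n_haplotypes
    rng = np.random.default_rng(0)
    pos = rng.standard_normal((k, 2))
    for _ in range(200):  # simple force-directed relaxation on the tree
        disp = np.zeros_like(pos)
        for i in range(k):
            delta = pos[i] - pos
            dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-6)
            disp[i] += (delta / dist[:, None] / dist[:, None]).sum(axis=0)
        for i, j, d in haps.edges:
            delta = pos[i] - pos[j]
            dist = max(np.linalg.norm(delta), 1e-6)
            pull = delta / dist * (dist - max(d, 1)) * 0.1
            disp[i] -= pull
            disp[j] += pull
        pos += 0.05 * disp
    totals = haps.counts_by_group.sum(axis=1).to_numpy()
    for i, j, d in haps.edges:
        ax.plot(*zip(pos[i], pos[j]), color="0.6", zorder=1)
        mid = (pos[i] + pos[j]) / 2
        ax.annotate(str(d), mid, fontsize=7, color="0.4")
    groups = list(haps.counts_by_group.columns)
    cmap = plt.get_cmap("tab10")
    for i in range(k):
        frac = haps.counts_by_group.iloc[i].to_numpy()
        start = 0.0
        for gi, g in enumerate(groups):
            if frac[gi] == 0:
                continue
            ax.pie([frac[gi], totals[i] - frac[gi]],
                   colors=[cmap(gi), (0, 0, 0, 0)],
                   center=pos[i], radius=0.12 * np.sqrt(totals[i]),
                   startangle=90 + 360 * start / max(totals[i], 1),
                   counterclock=False, frame=True)
            start += frac[gi]
    ax.set_title(haps.gene_id)
    ax.set_aspect("equal")
    ax.autoscale()
    ax.axis("off")
    return ax
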