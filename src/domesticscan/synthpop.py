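"""Synthetic two-population domestication data generator.

Simulates per-gene haploid allele matrices under a structured coalescent
that emulates the wild/weedy-vs-landrace resequencing design: a single
panmictic ancestral population splits at ``t_split`` (time in units of
2N generations, measured from the present) into a wild population of
relative size 1 and a landrace population whose size is multiplied by
``bottleneck_factor`` (the domestication bottleneck).  Mutations follow
the infinite-sites model, placed as Poisson events on branches at rate
theta/2 per site per unit time (theta = 4N*mu), with collided positions
resampled so every polymorphic site stays biallelic.

Purifying selection at candidate genes is emulated at mutation-selection
balance: on top of the neutral genealogy, each landrace copy of a derived
allele is purged (reverted to the ancestral state) with probability
``1 - 1/selection_rod``, independently per site and carrier.  Derived
alleles thus stay segregating in the landrace but at low frequency,
which is the joint signature the scan detects -- reduced landrace
diversity (high RoD), an excess of rare landrace variants (negative
Tajima's D), and allele frequencies shifted away from the wild group
(positive F_ST).  The truth table records the realized, not the nominal,
reduction of diversity.

Besides allele matrices, :func:`generate_dataset` writes every input the
downstream pipeline consumes -- reference FASTA, VCF, groups TSV, gene
annotation, an FPKM expression table over seed and non-seed tissue
samples with selected genes enriched among the seed-preferential set --
plus a ground-truth table for parameter-recovery tests.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from domesticscan.seqio import AlignmentMatrix

BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised for non-viable simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-population domestication scenario.

    Defaults emulate the 25-genotype panel: 12 wild/weedy + 13 landrace
    samples (the published split of the 25 is not available; the sum is),
    114 candidate and 159 neutral genes, 1500-bp CDS, and theta = 0.005
    per site, putting wild-group diversity at the scale of resequenced
    sorghum candidate genes (theta*L = 7.5).  The split 0.3 coalescent
    time units ago with a 2-fold landrace size reduction yields the
    differentiation and neutral diversity loss expected of a strongly
    selfing crop and its wild progenitor (neutral F_ST around 0.25,
    neutral RoD around 2); selected candidate genes get a nominal
    10-fold extra landrace diversity reduction.
    """

    n_wild: int = 12
    n_landrace: int = 13
    n_candidate_genes: int = 114
    n_neutral_genes: int = 159
    cds_length: int = 1500
    theta: float = 0.005
    t_split: float = 0.3
    bottleneck_factor: float = 0.5
    selection_rod: float = 10.0
    frac_selected: float = 0.5
    frac_seed_preferential_selected: float = 0.7
    frac_seed_preferential_other: float = 0.2
    n_seed_samples: int = 4
    n_nonseed_samples: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wild < 2 or self.n_landrace < 2:
            raise ConfigurationError("need >= 2 samples per group")
        if self.cds_length % 3 != 0:
            raise ConfigurationError("cds_length must be a multiple of 3")
        if self.theta < 0:
            raise ConfigurationError("theta must be >= 0")
        if not 0 < self.bottleneck_factor <= 1:
            raise ConfigurationError("bottleneck_factor must be in (0, 1]")
        if self.selection_rod < 1:
            raise ConfigurationError("selection_rod must be >= 1")
        if not 0 <= self.frac_selected <= 1:
            raise ConfigurationError("frac_selected must be in [0, 1]")
        if self.n_seed_samples < 2 or self.n_nonseed_samples < 5:
            raise ConfigurationError("need >= 2 seed and >= 5 non-seed samples")

    @property
    def sample_ids(self) -> list[str]:
        return ([f"wild{i:02d}" for i in range(self.n_wild)]
                + [f"land{i:02d}" for i in range(self.n_landrace)])

    @property
    def group_labels(self) -> list[str]:
        return ["wild_weedy"] * self.n_wild + ["landrace"] * self.n_landrace


@dataclass
class _Lineage:
    desc: frozenset          # leaf indices below this lineage
    mlen: float = 0.0        # mutation-effective length of the open branch


def _coalesce(rng: np.random.Generator, lineages: list[_Lineage]) -> _Lineage:
    i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
    b = lineages.pop(j)
    a = lineages.pop(i)
    parent = _Lineage(desc=a.desc | b.desc)
    return parent, a, b


def _advance_two_demes(wild: list[_Lineage], land: list[_Lineage],
                       b: float, t: float, t_end: float,
                       rng: np.random.Generator,
                       branches: list[_Lineage]) -> float:
    """Run the two-deme coalescent from t to t_end; returns the end time."""
    while t < t_end and (len(wild) + len(land)) > 1:
        rate_w = len(wild) * (len(wild) - 1) / 2.0
        rate_l = (len(land) * (len(land) - 1) / 2.0) / b
        total = rate_w + rate_l
        dt = t_end - t if total == 0 else min(rng.exponential(1.0 / total), t_end - t)
        for lin in wild + land:
            lin.mlen += dt
        t += dt
        if t >= t_end:
            break
        pool = wild if rng.random() < rate_w / total else land
        parent, a, c = _coalesce(rng, pool)
        branches.extend([a, c])
        pool.append(parent)
    if (len(wild) + len(land)) == 1 and t < t_end:
        (wild + land)[0].mlen += t_end - t
        t = t_end
    return t


def _simulate_tree(config: SimulationConfig,
                   rng: np.random.Generator) -> list[_Lineage]:
    """Neutral structured-coalescent gene tree; returns closed branches.

    Each returned lineage carries the leaf set below it and the length
    of the branch above it.
    """
    wild = [_Lineage(frozenset([i])) for i in range(config.n_wild)]
    land = [_Lineage(frozenset([config.n_wild + i]))
            for i in range(config.n_landrace)]
    branches: list[_Lineage] = []
    t = _advance_two_demes(wild, land, config.bottleneck_factor, 0.0,
                           config.t_split, rng, branches)
    # merged ancestral population of size 1
    lineages = wild + land
    while len(lineages) > 1:
        k = len(lineages)
        dt = rng.exponential(2.0 / (k * (k - 1)))
        for lin in lineages:
            lin.mlen += dt
        parent, a, c = _coalesce(rng, lineages)
        branches.extend([a, c])
        lineages.append(parent)
    return branches  # root branch (the last open lineage) carries no mutations


def _apply_purifying_selection(alleles: np.ndarray, n_wild: int,
                               selection_rod: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Purge derived alleles from landrace samples, site by site.

    Emulates mutation-selection balance under purifying selection in the
    domesticated lineage: each landrace copy of a derived allele is
    reverted to the ancestral state with probability 1 - 1/selection_rod,
    independently per site and carrier.  Derived alleles therefore stay
    segregating in the landrace but at low frequency, which jointly
    lowers landrace diversity (high RoD), skews the landrace frequency
    spectrum toward rare variants (negative Tajima's D), and shifts
    landrace allele frequencies away from the wild group (positive
    F_ST) -- the signature the scan's three criteria are built around.
    Sites where the derived allele is fixed in the landrace are left
    untouched (selection removes variants; it does not resurrect
    ancestral alleles that no landrace sample carries).
    """
    out = alleles.copy()
    q = 1.0 - 1.0 / selection_rod
    land = out[n_wild:, :]
    for j in range(out.shape[1]):
        carriers = np.nonzero(land[:, j] == 1)[0]
        if len(carriers) == 0 or len(carriers) == land.shape[0]:
            continue
        purge = carriers[rng.random(len(carriers)) < q]
        land[purge, j] = 0
    return out


def random_cds(length: int, rng: np.random.Generator) -> str:
    """Random CDS starting with ATG, length a multiple of 3."""
    seq = rng.choice(BASES, size=length)
    seq[:3] = list("ATG")
    return "".join(seq)


def simulate_gene(config: SimulationConfig, selected: bool,
                  rng: np.random.Generator,
                  gene_id: str = "gene",
                  reference_cds: str | None = None) -> AlignmentMatrix:
    """Simulate one gene's haploid allele matrix.

    With ``theta = 0`` the matrix has no polymorphic sites.  Each
    polymorphic site is biallelic (infinite sites with position
    resampling on collision); the derived allele is the alternate.
    """
    if reference_cds is None:
        reference_cds = random_cds(config.cds_length, rng)
    branches = _simulate_tree(config, rng)
    total_len = sum(b.mlen for b in branches)
    n_mut = rng.poisson(config.theta / 2.0 * config.cds_length * total_len)

    n = config.n_wild + config.n_landrace
    taken: dict[int, frozenset] = {}
    if n_mut > 0 and total_len > 0:
        weights = np.array([b.mlen for b in branches])
        weights = weights / weights.sum()
        for _ in range(n_mut):
            b = branches[rng.choice(len(branches), p=weights)]
            if len(b.desc) == n:  # spans all samples: not polymorphic, skip
                continue
            pos = int(rng.integers(config.cds_length))
            while pos in taken:
                pos = int(rng.integers(config.cds_length))
            taken[pos] = b.desc

    positions = sorted(taken)
    alleles = np.zeros((n, len(positions)), dtype=np.int8)
    for j, pos in enumerate(positions):
        alleles[sorted(taken[pos]), j] = 1

    if selected and config.selection_rod > 1.0:
        alleles = _apply_purifying_selection(alleles, config.n_wild,
                                             config.selection_rod, rng)
        keep = alleles.any(axis=0)  # sites fully purged are monomorphic again
        alleles = alleles[:, keep]
        positions = [p for p, k in zip(positions, keep) if k]

    ref_alleles, alt_alleles = [], []
    for pos in positions:
        ref = reference_cds[pos]
        alt = str(rng.choice(BASES[BASES != ref]))
        ref_alleles.append(ref)
        alt_alleles.append(alt)

    return AlignmentMatrix(
        gene_id=gene_id,
        sample_ids=config.sample_ids,
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
        alleles=alleles,
        cds_length=config.cds_length,
    )


def _realized_rod(matrix: AlignmentMatrix, config: SimulationConfig) -> float:
    from domesticscan import popstats
    wild = matrix.sample_ids[:config.n_wild]
    land = matrix.sample_ids[config.n_wild:]
    pi_w = popstats.theta_pi(matrix, wild)
    pi_l = popstats.theta_pi(matrix, land)
    if math.isnan(pi_w) or math.isnan(pi_l):
        return math.nan
    return popstats.rod(pi_w, pi_l)


def _write_vcf(path: Path, matrices: list[AlignmentMatrix],
               sample_ids: list[str], cds_lengths: dict[str, int]) -> None:
    lines = ["##fileformat=VCFv4.2",
             "##source=domesticscan-synthpop"]
    for m in matrices:
        lines.append(f"##contig=<ID={m.gene_id},length={cds_lengths[m.gene_id]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    for m in matrices:
        for j, (pos, ref, alt) in enumerate(m.sites()):
            gts = "\t".join(str(int(a)) if a >= 0 else "." for a in m.alleles[:, j])
            lines.append(f"{m.gene_id}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


def _simulate_expression(gene_ids: list[str], seed_pref: dict[str, bool],
                         config: SimulationConfig,
                         rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM table over seed and non-seed tissue samples.

    Non-seed FPKM values are log-normal around a per-gene baseline; seed
    values get an extra fold factor, drawn above 2 for seed-preferential
    genes and near 1 otherwise.  Values are floored at 0 (exactly 0 with
    small probability, emulating non-expressed tissue).
    """
    seed_cols = [f"seed_{i}" for i in range(config.n_seed_samples)]
    nonseed_cols = [f"tissue_{i}" for i in range(config.n_nonseed_samples)]
    rows = {}
    for g in gene_ids:
        base = float(rng.lognormal(mean=2.0, sigma=1.0))
        nonseed = base * rng.lognormal(0.0, 0.4, size=config.n_nonseed_samples)
        if seed_pref[g]:
            fold = 2.0 + float(rng.lognormal(mean=0.8, sigma=0.5))
        else:
            fold = float(rng.lognormal(mean=0.0, sigma=0.3))
        seed = base * fold * rng.lognormal(0.0, 0.4, size=config.n_seed_samples)
        vals = np.concatenate([seed, nonseed])
        vals[rng.random(vals.size) < 0.02] = 0.0
        rows[g] = np.round(vals, 4)
    expr = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=seed_cols + nonseed_cols)
    expr.index.name = "gene_id"
    tissues = pd.DataFrame({
        "sample_label": seed_cols + nonseed_cols,
        "tissue_class": ["seed"] * len(seed_cols) + ["non_seed"] * len(nonseed_cols),
    })
    return expr, tissues


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write all pipeline inputs for a synthetic panel; returns the truth table.

    Outputs under ``outdir``: ``reference.fasta``, ``variants.vcf``,
    ``groups.tsv``, ``annotation.tsv``, ``expression.tsv``,
    ``tissues.tsv`` and ``truth.tsv`` (per-gene is_neutral / is_selected
    flags with realized RoD).  Identical ``rng_seed`` values reproduce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)

    candidate_ids = [f"cand{i:04d}" for i in range(config.n_candidate_genes)]
    neutral_ids = [f"neut{i:04d}" for i in range(config.n_neutral_genes)]
    n_selected = int(round(config.frac_selected * config.n_candidate_genes))
    selected_flags = {g: i < n_selected for i, g in enumerate(candidate_ids)}

    fasta_records, matrices, truth_rows, ann_rows = [], [], [], []
    for gene_id in candidate_ids + neutral_ids:
        is_neutral = gene_id.startswith("neut")
        selected = (not is_neutral) and selected_flags[gene_id]
        ref = random_cds(config.cds_length, rng)
        m = simulate_gene(config, selected, rng, gene_id=gene_id, reference_cds=ref)
        fasta_records.append((gene_id, ref))
        matrices.append(m)
        ann_rows.append({"gene_id": gene_id, "cds_length": config.cds_length,
                         "strand": "+", "is_neutral": is_neutral})
        truth_rows.append({"gene_id": gene_id, "is_neutral": is_neutral,
                           "is_selected": selected,
                           "realized_rod": _realized_rod(m, config)})

    with open(outdir / "reference.fasta", "w") as fh:
        for gene_id, seq in fasta_records:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    _write_vcf(outdir / "variants.vcf", matrices, config.sample_ids,
               {m.gene_id: m.cds_length for m in matrices})

    pd.DataFrame({"sample_id": config.sample_ids,
                  "group_label": config.group_labels}
                 ).to_csv(outdir / "groups.tsv", sep="\t", index=False, header=False)

    pd.DataFrame(ann_rows).to_csv(outdir / "annotation.tsv", sep="\t", index=False)

    seed_pref = {}
    for g in candidate_ids:
        p = (config.frac_seed_preferential_selected if selected_flags[g]
             else config.frac_seed_preferential_other)
        seed_pref[g] = bool(rng.random() < p)
    expr, tissues = _simulate_expression(candidate_ids, seed_pref, config, rng)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    tissues.to_csv(outdir / "tissues.tsv", sep="\t", index=False, header=False)

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)

    return {row["gene_id"]: row for row in truth_rows}


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for byte-identity checks."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
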