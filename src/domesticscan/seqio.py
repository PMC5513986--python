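"""Readers and writers for the pipeline's on-disk formats.

Inputs are per-gene CDS reference sequences (multi-FASTA, one record per
gene), per-sample SNP genotypes over those CDS (VCF v4.2, haploid GT,
1-based POS in CDS coordinates), a two-column sample-to-group TSV, and a
gene annotation TSV.  The reader assembles one :class:`AlignmentMatrix`
per gene, the substrate of all downstream statistics.

Conventions
-----------
* Internal coordinates are 0-based half-open; conversion to and from the
  1-based VCF convention happens only at this boundary.
* Only biallelic SNP records are kept.  Multi-allelic records and indels
  are dropped with a logged warning.
* Heterozygous or partially missing genotype calls become missing: the
  panel emulated here consists of near-homozygous inbred lines coded as
  one haplotype per sample, so a heterozygous call carries no usable
  phase information.
* Minus-strand genes are reverse-complemented into coding orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

GROUP_LABELS = {
    "wild_weedy",
    "landrace",
    "improved",
    "guinea_margaritiferum",
    "propinquum",
}


class ConsistencyError(ValueError):
    """Raised when input files contradict each other."""


@dataclass(frozen=True)
class SampleGroup:
    """A sample and the population group it belongs to."""

    sample_id: str
    group_label: str

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ConsistencyError(
                f"unknown group label {self.group_label!r} for sample "
                f"{self.sample_id!r}; expected one of {sorted(GROUP_LABELS)}"
            )


@dataclass
class GeneModel:
    """A gene's CDS reference sequence and annotation."""

    gene_id: str
    cds_length: int
    strand: str
    is_neutral: bool
    reference_cds: str

    def __post_init__(self) -> None:
        if len(self.reference_cds) != self.cds_length:
            raise ConsistencyError(
                f"{self.gene_id}: reference length {len(self.reference_cds)} "
                f"!= annotated cds_length {self.cds_length}"
            )
        if self.strand not in {"+", "-"}:
            raise ConsistencyError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class AlignmentMatrix:
    """Per-gene samples x polymorphic-sites allele matrix.

    ``alleles[i, j]`` is 0 (reference), 1 (alternate) or -1 (missing) for
    sample ``sample_ids[i]`` at ``positions[j]`` (0-based CDS coordinate).
    ``cds_length`` is the full CDS length; monomorphic sites are implicit.
    """

    gene_id: str
    sample_ids: list[str]
    positions: np.ndarray          # (n_sites,) int64, strictly increasing
    ref_alleles: list[str]
    alt_alleles: list[str]
    alleles: np.ndarray            # (n_samples, n_sites) int8
    cds_length: int
    sites_dropped: int = 0         # multi-allelic / indel records excluded

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n, s = self.alleles.shape if self.alleles.size else (len(self.sample_ids), 0)
        if self.alleles.size == 0:
            self.alleles = self.alleles.reshape(len(self.sample_ids), 0)
        if self.alleles.shape[0] != len(self.sample_ids):
            raise ConsistencyError(f"{self.gene_id}: allele matrix rows != samples")
        if self.alleles.shape[1] != len(self.positions):
            raise ConsistencyError(f"{self.gene_id}: allele matrix cols != sites")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ConsistencyError(f"{self.gene_id}: positions not strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        """Row indices of the given samples, in the given order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise ConsistencyError(f"{self.gene_id}: unknown sample {exc}") from exc

    def sites(self) -> list[tuple[int, str, str]]:
        """(position, ref, alt) triples in position order."""
        return list(zip(self.positions.tolist(), self.ref_alleles, self.alt_alleles))


def read_groups(groups_path: str | Path) -> dict[str, str]:
    """Read the 2-column sample_id / group_label TSV into a dict."""
    df = pd.read_csv(groups_path, sep="\t", header=None,
                     names=["sample_id", "group_label"], dtype=str, comment="#")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ConsistencyError(f"duplicate sample id {dup!r} in {groups_path}")
    for row in df.itertuples():
        SampleGroup(row.sample_id, row.group_label)  # validates the label
    return dict(zip(df["sample_id"], df["group_label"]))


def read_annotation(annotation_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(annotation_path, sep="\t",
                     dtype={"gene_id": str, "cds_length": int, "strand": str})
    required = {"gene_id", "cds_length", "strand", "is_neutral"}
    if not required.issubset(df.columns):
        raise ConsistencyError(
            f"annotation file missing columns {sorted(required - set(df.columns))}"
        )
    df["is_neutral"] = df["is_neutral"].astype(bool)
    return df


def read_gene_models(fasta_path: str | Path, annotation_path: str | Path) -> dict[str, GeneModel]:
    """Join the reference FASTA and annotation table into GeneModel records.

    Minus-strand sequences are reverse-complemented so every model's
    ``reference_cds`` is in coding orientation.
    """
    ann = read_annotation(annotation_path).set_index("gene_id")
    models: dict[str, GeneModel] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in ann.index:
            raise ConsistencyError(f"FASTA record {rec.id!r} absent from annotation")
        row = ann.loc[rec.id]
        seq = str(rec.seq).upper()
        if row["strand"] == "-":
            seq = str(Seq(seq).reverse_complement())
        models[rec.id] = GeneModel(
            gene_id=rec.id,
            cds_length=int(row["cds_length"]),
            strand=str(row["strand"]),
            is_neutral=bool(row["is_neutral"]),
            reference_cds=seq,
        )
    missing = set(ann.index) - set(models)
    if missing:
        raise ConsistencyError(f"annotation genes missing from FASTA: {sorted(missing)[:5]}")
    return models


def _genotype_code(gt: list) -> int:
    """Collapse a cyvcf2 genotype entry to 0/1/MISSING.

    Haploid entries are ``[allele, phased]``; diploid ``[a, b, phased]``.
    Any heterozygous or partially missing diploid call is treated as
    missing (inbred-line assumption).
    """
    alleles = gt[:-1]
    if any(a < 0 for a in alleles):
        return MISSING
    if len(set(alleles)) > 1:
        return MISSING
    return int(alleles[0])


def read_alignment_matrices(
    vcf_path: str | Path,
    gene_models: dict[str, GeneModel],
    groups: dict[str, str],
) -> dict[str, AlignmentMatrix]:
    """Assemble one AlignmentMatrix per gene from a CDS-coordinate VCF.

    Every gene in ``gene_models`` gets a matrix, with zero sites if the
    VCF has no records for it.  Records are sorted by position internally,
    so the VCF record order does not matter.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in groups:
            raise ConsistencyError(f"VCF sample {s!r} absent from groups file")

    per_gene: dict[str, list[tuple[int, str, str, list[int]]]] = {g: [] for g in gene_models}
    dropped: dict[str, int] = {g: 0 for g in gene_models}
    for rec in vcf:
        gene_id = rec.CHROM
        if gene_id not in gene_models:
            raise ConsistencyError(f"VCF contig {gene_id!r} absent from annotation")
        if len(rec.ALT) != 1 or not rec.is_snp:
            logger.warning("dropping non-biallelic-SNP record %s:%s", gene_id, rec.POS)
            dropped[gene_id] += 1
            continue
        pos0 = rec.POS - 1
        model = gene_models[gene_id]
        if not 0 <= pos0 < model.cds_length:
            raise ConsistencyError(
                f"{gene_id}: VCF POS {rec.POS} outside CDS of length {model.cds_length}"
            )
        codes = [_genotype_code(gt) for gt in rec.genotypes]
        per_gene[gene_id].append((pos0, rec.REF, rec.ALT[0], codes))

    matrices: dict[str, AlignmentMatrix] = {}
    for gene_id, records in per_gene.items():
        records.sort(key=lambda r: r[0])
        model = gene_models[gene_id]
        positions = np.array([r[0] for r in records], dtype=np.int64)
        alleles = (
            np.array([r[3] for r in records], dtype=np.int8).T
            if records else np.zeros((len(samples), 0), dtype=np.int8)
        )
        matrices[gene_id] = AlignmentMatrix(
            gene_id=gene_id,
            sample_ids=samples,
            positions=positions,
            ref_alleles=[r[1] for r in records],
            alt_alleles=[r[2] for r in records],
            alleles=alleles,
            cds_length=model.cds_length,
            sites_dropped=dropped[gene_id],
        )
    return matrices


@dataclass
class Dataset:
    """All parsed inputs for one pipeline run."""

    gene_models: dict[str, GeneModel]
    groups: dict[str, str]
    matrices: dict[str, AlignmentMatrix]

    def samples_in_group(self, group_label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group_label]


def read_inputs(
    fasta_path: str | Path,
    vcf_path: str | Path,
    groups_path: str | Path,
    annotation_path: str | Path,
) -> Dataset:
    """Read and cross-validate all pipeline inputs."""
    groups = read_groups(groups_path)
    gene_models = read_gene_models(fasta_path, annotation_path)
    matrices = read_alignment_matrices(vcf_path, gene_models, groups)
    return Dataset(gene_models=gene_models, groups=groups, matrices=matrices)
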