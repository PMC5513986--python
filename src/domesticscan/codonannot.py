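"""Synonymous / non-synonymous classification of CDS SNPs.

Each biallelic SNP is evaluated against the reference codon context only
(no haplotype-aware multi-SNP codons), translated with the standard
nuclear genetic code; a substitution that preserves the amino acid is
synonymous, anything else -- including stop gain or loss -- is
non-synonymous.
"""

from __future__ import annotations

import logging

import pandas as pd
from Bio.Seq import Seq

from domesticscan.seqio import GeneModel

logger = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"

_VALID = set("ACGT")


def classify_snp(reference_cds: str, cds_position: int,
                 ref_allele: str, alt_allele: str) -> str:
    """Classify one SNP as ``synonymous`` or ``nonsynonymous``.

    ``cds_position`` is 0-based within a CDS whose length is a multiple
    of 3 and whose first base is the first codon position.
    """
    if len(reference_cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if not 0 <= cds_position < len(reference_cds):
        raise ValueError(f"position {cds_position} outside CDS")
    if ref_allele not in _VALID or alt_allele not in _VALID:
        raise ValueError(f"ambiguous base in {ref_allele!r}/{alt_allele!r}")
    if reference_cds[cds_position] != ref_allele:
        raise ValueError(
            f"reference mismatch at {cds_position}: CDS has "
            f"{reference_cds[cds_position]!r}, VCF says {ref_allele!r}"
        )
    codon_start = (cds_position // 3) * 3
    offset = cds_position - codon_start
    codon = reference_cds[codon_start:codon_start + 3]
    mutated = codon[:offset] + alt_allele + codon[offset + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS


def annotate_site_stats(site_stats: pd.DataFrame,
                        gene_models: dict[str, GeneModel]) -> pd.DataFrame:
    """Add a ``functional_class`` column to a per-site statistics table.

    Genes whose CDS length is not a multiple of 3 are excluded from
    annotation (class left missing) with a warning.
    """
    classes = []
    warned: set[str] = set()
    for row in site_stats.itertuples():
        model = gene_models[row.gene_id]
        if model.cds_length % 3 != 0:
            if row.gene_id not in warned:
                logger.warning("%s: CDS length %d not a multiple of 3; "
                               "skipping codon annotation",
                               row.gene_id, model.cds_length)
                warned.add(row.gene_id)
            classes.append(None)
            continue
        classes.append(classify_snp(model.reference_cds, int(row.cds_position),
                                    row.ref_allele, row.alt_allele))
    out = site_stats.copy()
    out["functional_class"] = classes
    return out
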