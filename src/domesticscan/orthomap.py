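"""Ortholog identification by merging BBH and synteny evidence.

Bidirectional best hits (BBH) are derived from two tabular protein
homology hit files (standard 12-column tab-separated alignment format):
a pair (a, b) is kept when b is a's highest-scoring subject in the
forward table and a is b's highest-scoring subject in the reverse table.
Ties are broken deterministically by higher bit-score, then lower
e-value, then lexicographic subject id.  BBH pairs are merged with
synteny-derived pairs into ortholog records labeled by method (BBH,
synteny, or both), with inclusion-exclusion accounting per source
species and an overall unique-target tally in which a target found for
two or more source species counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HIT_COLUMNS = ["query", "subject", "pct_identity", "length", "mismatches",
               "gap_opens", "q_start", "q_end", "s_start", "s_end",
               "evalue", "bitscore"]


@dataclass(frozen=True)
class OrthologRecord:
    source_species: str
    source_gene: str
    target_gene: str
    method: str  # "BBH" | "synteny" | "both"


def read_hit_table(path) -> pd.DataFrame:
    """Read a 12-column tabular homology hit file."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                         comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed hit table {path}: {exc}") from exc
    required = df[["query", "subject", "evalue", "bitscore"]]
    bad_rows = required.isna().any(axis=1)
    if bad_rows.any():
        line = int(np.flatnonzero(bad_rows)[0]) + 1
        raise ValueError(f"malformed hit table {path}: missing field at line {line}")
    for col in ("evalue", "bitscore"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"malformed hit table {path}: non-numeric {col}")
    return df


def best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: highest bit-score, then lowest e-value,
    then lexicographically smallest subject id."""
    ranked = hits.sort_values(["query", "bitscore", "evalue", "subject"],
                              ascending=[True, False, True, True],
                              kind="mergesort")
    top = ranked.drop_duplicates("query", keep="first")
    return dict(zip(top["query"], top["subject"]))


def bbh_pairs(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> set[tuple[str, str]]:
    """Bidirectional best hit pairs (a, b) between two hit tables."""
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    return {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}


def merge_evidence(bbh: set[tuple[str, str]], synteny: set[tuple[str, str]],
                   source_species: str) -> list[OrthologRecord]:
    """Union of the two evidence sets with method labels.

    A pair in both sets is labeled ``both``; the inclusion-exclusion
    identity |union| = |BBH| + |synteny| - |both| is asserted on every
    call.
    """
    union = bbh | synteny
    records = [OrthologRecord(
        source_species=source_species,
        source_gene=a,
        target_gene=b,
        method="both" if (a, b) in bbh and (a, b) in synteny
        else ("BBH" if (a, b) in bbh else "synteny"),
    ) for a, b in sorted(union)]
    n_both = sum(r.method == "both" for r in records)
    assert len(records) == len(bbh) + len(synteny) - n_both
    return records


def unique_targets(records: list[OrthologRecord]) -> set[str]:
    """Distinct target genes in a record set."""
    return {r.target_gene for r in records}


def venn_counts(records_by_species: dict[str, list[OrthologRecord]]) -> dict:
    """Per-species and overall unique-target accounting.

    ``overall_unique`` counts each target gene once even when it was
    found from several source species; ``shared_by_2plus`` is the number
    of targets found for at least two species.
    """
    per_species = {sp: unique_targets(recs)
                   for sp, recs in records_by_species.items()}
    all_targets: dict[str, int] = {}
    for targets in per_species.values():
        for t in targets:
            all_targets[t] = all_targets.get(t, 0) + 1
    return {
        "per_species_unique": {sp: len(t) for sp, t in per_species.items()},
        "overall_unique": len(all_targets),
        "shared_by_2plus": sum(1 for v in all_targets.values() if v >= 2),
        "targets": set(all_targets),
    }


def add_external_candidates(targets: set[str], extra_genes: list[str]) -> set[str]:
    """Union of ortholog targets with an externally curated gene list."""
    return set(targets) | set(extra_genes)


def records_table(records_by_species: dict[str, list[OrthologRecord]]) -> pd.DataFrame:
    """Flat orthologs table (target gene, approach, source gene, species)."""
    rows = [{"target_gene": r.target_gene, "approach": r.method,
             "source_gene": r.source_gene, "source_species": r.source_species}
            for recs in records_by_species.values() for r in recs]
    return pd.DataFrame(rows, columns=["target_gene", "approach",
                                       "source_gene", "source_species"])
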