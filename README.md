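# domesticscan

A candidate-gene domestication scan for resequenced crop panels, built
around the wild-vs-landrace contrast used in cereal domestication
genetics (the package's synthetic panel emulates a 25-genotype sorghum
resequencing design: 12 wild/weedy plus 13 landrace inbred lines).

Given per-gene CDS reference sequences, a haploid SNP VCF over those CDS,
and sample-to-group assignments, the pipeline computes population-genetic
summary statistics at gene and single-SNP resolution and applies a
three-criterion purifying-selection classifier calibrated on neutral
loci. Supporting stages classify SNPs as synonymous or non-synonymous,
test whether seed-preferentially expressed genes are enriched for
selection, merge bidirectional-best-hit (BBH) and synteny ortholog
evidence, and build haplotype networks for genes under selection.

## The statistics

For a group of *n* haploid sequences over a CDS of length *L*:

- **Nucleotide diversity** θ&pi; (Nei & Li): the mean pairwise difference
  rate, Σ<sub>sites</sub> 2 n<sub>ref</sub> n<sub>alt</sub> / (n (n−1)) / L.
- **Watterson's θ<sub>W</sub>**: S / (a₁ L) with
  a₁ = Σ<sub>i=1</sub><sup>n−1</sup> 1/i and S the number of segregating
  sites.
- **Tajima's D**: (k̄ − S/a₁) / √(e₁S + e₂S(S−1)) with the standard
  small-sample constants; negative D marks an excess of rare variants.
- **Hudson's F<sub>ST</sub>**: 1 − H<sub>w</sub>/H<sub>b</sub>, the
  within-group versus between-group mean pairwise difference rates,
  aggregated over sites as a ratio of sums.
- **RoD (reduction of diversity)**:
  θ&pi;<sup>wild</sup> / θ&pi;<sup>landrace</sup>, the fold decrease of
  diversity in the domesticated group.

A SNP is called **under purifying selection** when (1) its per-site RoD
exceeds the mean gene-level RoD of the neutral loci, (2) its per-site
F<sub>ST</sub> is strictly positive, and (3) Tajima's D of the landrace
group at that site is defined and strictly negative. A gene is under
selection when at least one of its SNPs passes. Criterion 1 is evaluated
in cross-multiplied form (&pi;<sub>wild</sub> > RoD̄<sub>neutral</sub> ·
&pi;<sub>landrace</sub>), so a landrace-invariant site never divides by
zero — and is never called, because its site-level D is undefined.

## Worked example

Simulate a small panel (20 candidate genes, half under selection, plus
30 neutral loci) and run the full scan:

```sh
domesticscan simulate --data-dir demo_data --seed 7 --n-candidate 20 --n-neutral 30
domesticscan run --data-dir demo_data --out-dir demo_out --seed 7
```

The run prints the summary it also writes to `demo_out/summary.json`:

```json
{
  "enrichment": {
    "chi2": 4.313725490196077,
    "n_genes": 20,
    "p_value": 0.03780608119761285,
    "pct_selected_in_others": 0,
    "pct_selected_in_seed_preferential": 33,
    "table": {"a": 3, "b": 6, "c": 0, "d": 11}
  },
  "n_candidate_genes": 20,
  "n_candidate_genes_under_selection": 3,
  "n_genes": 50,
  "n_genes_under_selection": 10,
  "n_genes_with_nonsyn_selected": 9,
  "n_neutral_genes": 30,
  "n_neutral_genes_under_selection": 7,
  "n_snps_nonsynonymous": 1151,
  "n_snps_selected": 37,
  "n_snps_synonymous": 354,
  "n_snps_total": 1505,
  "neutral_baseline_rod": 2.2112882956036306,
  "neutral_loci_excluded_nonfinite": 0,
  "neutral_loci_used": 30,
  "rng_seed": 7
}
```

Reading the output: 1,505 CDS SNPs were found across the 50 genes; the
neutral RoD baseline calibrated on the 30 neutral loci is 2.21; 37 SNPs
in 10 genes pass all three criteria (3 of the 20 candidates, plus 7
neutral loci called by chance — the scan's false-call rate); 9 of the
called genes carry a non-synonymous selected SNP. The enrichment block
is the 2×2 seed-preferential × under-selection table over the 20
candidate genes with its uncorrected Pearson chi-square. At this toy
size the percentages are noisy; the full-size benchmark lives in the
acceptance script.

Per-gene statistics, per-SNP statistics with functional class, selection
calls, selected SNPs, expression classes, and haplotype tables/edges are
written as TSV files next to the summary.

The same pipeline runs on real data: point `--data-dir` at a directory
containing `reference.fasta`, `variants.vcf` (haploid GT, 1-based POS in
CDS coordinates), `groups.tsv`, `annotation.tsv`, and optionally
`expression.tsv`/`tissues.tsv`.

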