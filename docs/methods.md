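# Methods

## Scope and model

The package implements a candidate-gene domestication scan for a
two-group resequencing panel of near-homozygous inbred lines: a
wild/weedy group (the ancestral gene pool) and a landrace group (the
domesticated descendants). Samples are coded as one haplotype each;
heterozygous calls in input VCFs are treated as missing rather than
phased, because inbred panels carry almost no true heterozygosity and
any phasing rule would be invented. All statistics operate on per-gene
allele matrices over biallelic CDS SNPs; multi-allelic records and
indels are excluded on input.

## Estimators

Gene-level nucleotide diversity θπ divides the summed per-site pairwise
difference rates by the full CDS length, so monomorphic sites dilute the
estimate and values land on the familiar per-site scale (order 10⁻³ for
a diverse grass). Whether published per-gene diversities divide by CDS
or total gene length is often ambiguous; this package standardizes on
CDS length, which is the region the SNPs are ascertained in.

Missing data are handled complete-case per site: allele counts at a site
use only the non-missing calls, and a site with fewer than two usable
calls in a group contributes no within-group information there. Tajima's
D uses the subset size as n; with missing data it is therefore an
approximation, exact on the generator's complete matrices.

Hudson's F_ST is 1 − Hw/Hb with Hw the unweighted mean of the two
within-group per-site heterozygosities (the two groups are of similar
size) and Hb the between-group pairwise difference rate. The gene-level
value aggregates sites as a ratio of sums, the standard way to combine
Hudson's estimator across sites; per-site values use the same formula on
one site. F_ST may be negative; it is undefined (NA) when Hb sums to
zero.

RoD is θπ(wild)/θπ(landrace): +Inf when the landrace group is invariant
but the wild group is not, NA when both are invariant. The neutral
baseline is the arithmetic mean of finite gene-level RoD over the
neutral loci; non-finite loci are excluded and counted, since a single
landrace-invariant neutral locus would otherwise make the mean infinite
and the scan vacuous.

## The per-SNP selection test

Per-SNP statistics use a 1-bp window with 1-bp step, i.e. every SNP is
its own window. The site-level Tajima's D is computed on the landrace
group with S = 1: D = (π̂ − 1/a₁)/√e₁, with π̂ the site heterozygosity
expressed as a count. The landrace group is used because the scan's
question is whether the domesticated lineage shows the skewed, rare-
variant-dominated spectrum expected under purifying selection; the
choice of group is an interpretation this package fixes explicitly.
Sites where the landrace group is monomorphic have undefined site D and
fail criterion 3 rather than being dropped: a site that cannot
demonstrate a frequency skew is conservatively not called, even though
its (infinite) RoD would pass criterion 1 in cross-multiplied form.

"F_ST positive" and "Tajima's D negative" are read as strict
inequalities. The optional gene-level percentile screen that would
replace genome-wide ranking thresholds is configurable and off by
default, since no genome-wide distribution ships with the package.

## The synthetic panel

The generator's defaults define the study conditions: 12 wild + 13
landrace haploid samples (a 25-genotype panel whose published group
split is unavailable; the total is), 114 candidate and 159 neutral
genes, 1500-bp CDS, θ = 4Nμ = 0.005 per site. Genealogies follow a
structured coalescent with time in units of 2N generations: a single
ancestral population of relative size 1 splits t_split = 0.3 units
before the present into a wild population of size 1 and a landrace
population of size bottleneck_factor = 0.5. Mutations are infinite-sites
Poisson events at rate θ/2 per site per unit branch length; a mutation
landing on an occupied position is re-placed, keeping every site
biallelic. Under these conditions the wild group shows θπ ≈ 0.005 and
the neutral loci show RoD ≈ 1.9 and F_ST ≈ 0.26 — the scale of
diversity loss and differentiation expected between a strongly selfing
crop's landraces and its wild progenitor, where selfing deflates
effective size and inflates differentiation relative to outcrossers.
The wild group is panmictic at constant size for its entire history, so
its neutral expectations are exact (E[S] = a₁θL, E[θπ] = θ) and anchor
the calibration tests; the pooled 25-sample statistics are cross-checked
against a matched msprime model instead, because population structure
inflates them above the panmictic closed form.

Purifying selection at candidate genes is emulated at mutation-selection
balance: on top of the neutral genealogy, each landrace copy of a
derived allele is purged (reverted to ancestral) with probability
1 − 1/selection_rod, independently per site and carrier. Sites where the
derived allele is fixed in the landrace are left untouched — selection
removes variants, it does not resurrect alleles no landrace carries.
This produces exactly the joint pattern the scan tests for: landrace
diversity reduced about selection_rod-fold, derived alleles still
segregating in the landrace but rare (negative site-level Tajima's D),
and landrace frequencies displaced from the wild group (positive F_ST).
A genealogy-only emulation (compressing landrace branch lengths, i.e. a
sweep) was evaluated first and rejected: a swept gene's landrace group
is monomorphic at almost every wild-polymorphic site, its site-level D
is undefined, and the three-criterion test — by its own conservative
composition — can essentially never call it, inverting the intended
signal. The purging model sacrifices within-gene haplotype linkage at
selected landrace genes (purging is independent across sites), which
slightly inflates their apparent haplotype diversity in network plots;
all single-site statistics are unaffected. The truth table records the
realized, not nominal, RoD of every gene.

Expression data emulate an FPKM atlas with 4 seed and 5 non-seed tissue
samples: non-seed values are log-normal around a per-gene baseline
(baseline ~ LogNormal(2, 1), sample noise ~ LogNormal(0, 0.4)); seed
values get an extra fold factor drawn above 2 for seed-preferential
genes and near 1 otherwise; 2% of entries are zeroed to emulate
non-expressed tissues. Selected genes are made seed-preferential with
probability 0.7 versus 0.2 for other candidates, so the enrichment
stage has signal to detect.

What passing tests on this panel do not show: the generator has no
recombination within genes, no selfing-rate dynamics, no multi-allelic
sites, no missing genotypes, uniform gene length and mutation rate, and
site-independent selection. Real resequencing panels violate all of
these; the tests demonstrate correctness of the estimators and the
internal consistency of the scan, not its field performance.

## Seed-expression enrichment

A gene is seed-preferential when max(seed FPKM) > 2 × max(non-seed
FPKM), strict, with the non-seed maximum floored at 1 FPKM. The floor
handles genes silent outside the seed without inventing infinite fold
changes, while keeping genuinely seed-specific genes positive; 1 FPKM is
the conventional detection threshold. Enrichment of selection among
seed-preferential genes uses the uncorrected Pearson chi-square on the
2×2 gene table with a χ²(1) p-value. Applied to the published gene
counts (17/5 seed-preferential, 46/46 others) the statistic is 5.34
(Yates-corrected: 4.29); the value printed alongside those counts in the
source literature (6.546) is not recovered by the Pearson formula, a
continuity-corrected Pearson, or a G-test, and the package reports the
faithfully computed statistic rather than tuning toward the printed one.

## Orthologs, haplotypes, numerics

BBH derivation consumes standard 12-column tabular protein-homology hit
files; running the aligner is out of scope, so real or synthetic hit
tables plug in equally. Best hits rank by bit-score, then lower e-value,
then lexicographic subject id — published descriptions usually say only
"highest score", so ties are broken deterministically and documented.
Evidence merging is a labeled union (BBH / synteny / both); the
inclusion-exclusion identity |union| = |BBH| + |synteny| − |both| is
asserted on every call, and the cross-species tally counts a target gene
once however many source species found it.

Haplotype networks use complete-case haplotypes over each gene's
polymorphic sites and a minimum spanning tree over pairwise Hamming
distances, with ties broken by (distance, haplotype index pair). An MST
was chosen over statistical-parsimony networks because it is
deterministic and testable against exhaustive enumeration while
preserving the figure semantics: distance-weighted links, node sizes
proportional to carrier counts, colors by group.

Numerical conventions: undefined statistics are NaN in memory and "NA"
in TSVs; infinite RoD serializes as "Inf". Tajima's D requires n ≥ 4 and
S ≥ 1. The chi-square is NaN when any margin is zero. All randomness in
the generator and pipeline flows from one integer seed, and equal seeds
give byte-identical outputs.

## Problem sizes

The test suite runs the scan benchmark at the full study size (159
neutral + 100 candidate genes) and the neutral calibration at 200
replicate genes against 200 msprime replicates; oracle-equivalence
checks use 100-150 random matrices of up to 8 samples x 20 sites. The
acceptance script repeats the benchmark and calibration at the same
sizes.
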