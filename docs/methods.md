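# Methods

## Scope and data model

`famsnp` operates on raw consumer SNP-chip genotype downloads: UTF-8 text
with `#`-prefixed header comments, then one marker per line with four
tab-separated fields — marker identifier (`rs…` from dbSNP or vendor
internal `i…`), chromosome (1–22, X, Y, MT), 1-based position, and a
genotype of one or two characters from `{A,C,G,T,I,D}` or `--` for a
no-call. Coordinates are stored 1-based inclusive as in the vendor files;
the assembly label is metadata only (no liftover). Genotypes are kept in
the orientation given — all files compared are assumed to come from one
vendor on the plus strand, so no strand flipping is attempted. Unsorted
input is accepted and sorted into canonical order on read; duplicate marker
identifiers are an error (failing fast beats silently keeping the first).
Chromosome tokens are normalized case-insensitively, with `M` accepted for
`MT`. Haploid single-character genotypes are parsed and preserved, but all
downstream analyses operate on autosomes where calls are diploid. Every
analysis module first restricts to chromosomes 1–22, because X/Y/MT
genotype semantics (hemizygosity in males, haploid mitochondria) would
contaminate diploid-model statistics.

## Undercall error model

Eligible markers for error estimation are `rs`-identified autosomal SNPs
with genotypes over `{A,C,G,T}` or `--`; vendor-internal and indel markers
are excluded (both exclusions can be relaxed via flags for sensitivity
analysis). The model assumes each truly present allele is missed
independently with uniform probability x (the undercall rate) and that no
wrong allele is ever observed. The conditional call probabilities are:

| truth        | NULL | HOM          | HET          |
|--------------|------|--------------|--------------|
| heterozygous | x²   | 2x           | 1 − 2x − x²  |
| homozygous   | x    | 1 − x        | —            |

The `2x` term is the first-order form of 2x(1−x); the partition is used
literally so that the probabilities sum to one exactly, which requires
x < √2 − 1. The simulator implements exactly this partition (not
independent per-allele dropout), so the estimator's model is the
generator's model and parameter recovery is exact in expectation — the grid
round-trip property `solve(expected(f, x)) = x` holds to 10⁻⁶.

Estimation solves the cubic `x³ + (1+HOM)x² + (3·HET + 2·HOM − 3)x + NULL = 0`
with a polynomial root finder (`numpy.roots`), filters real roots to
`[0, √2 − 1)`, and validates candidates by forward-model residual with ties
broken toward the smallest root; in the regime of interest (x ≪ 1) the
admissible root is unique, which the grid test confirms. The degenerate
input HET = 0 with NULL > 0 returns the homozygous-only solution x = NULL
with a warning that f is unidentifiable. Derived quantities follow as
f = HET/(1 − 2x − x²), missing = (f − HET)·N, and
het2hom = missing − N·NULL·HET/(HET + HOM). Reported counts are rounded
half-up for display; exact values are retained on the estimate object.

**Known limitation.** The het2hom correction term apportions no-calls using
the *called* heterozygous fraction, which is appropriate when no-calls are
dominated by general assay dropout. Under the pure undercall model above,
heterozygous sites reach NULL only at rate x² while the correction removes
≈ N·f·x(1−f), so against data generated by the pure model the formula
understates the realized het→hom count by a factor of about (1+f)/2. The
formula is reproduced as printed; the discrepancy matters only when judging
it against the simulator's realized counts, and the suite covering that
comparison documents the gap rather than hiding it.

## Similarity scoring

At a shared marker, two genotypes are compared as allele multisets: equal
multisets are a match, exactly one shared allele occurrence a half-match,
none a conflict. Identity = matches + half_matches/2 and difference =
conflicts + half_matches/2, so identity + difference equals the shared
total exactly. No-calls are treated as empty multisets — `--` against a
called genotype is a conflict, `--` against `--` a match. This convention
makes the three categories partition the entire shared marker set and is
what reconciles parent–child conflict counts (thousands, dominated by
cross no-call sites at per-individual no-call rates of ~0.2%) with the far
smaller MIE counts, which exclude no-calls entirely. Heterozygote order is
ignored (`AG` ≡ `GA`).

Two pairwise similarities are tested for difference with Pearson's
chi-squared on the 2×2 identity/difference table with Yates continuity
correction (each |O − E| reduced by min(0.5, |O − E|), 1 df) — the same
procedure as R's `chisq.test`. Scores are rounded half-up to integers
before the test; at the magnitudes involved (10⁵–10⁶) the half-count
rounding is irrelevant to four significant figures, which is how p-values
are reported.

## Mendelian checks and deletion inference

A duo MIE is a site where parent and child have disjoint allele sets; a
trio MIE is a site where no choice of one allele from each parent
reproduces the child. Both predicates are checked against exhaustive
transmission-enumeration oracles over the full small genotype space in the
test suite. Sites with any no-call among the involved individuals are
skipped. Between relatives other than parent and offspring the same
disjoint-allele rule counts *pseudo-MIEs*: full incompatibilities expected
from incomplete genome sharing. Indel alleles (I/D) participate as ordinary
alleles.

Hemizygous deletions shared by a parent–offspring pair are inferred from
the signature they leave: within the deleted segment each carrier has one
chromosome copy, the chip reports the remaining allele as homozygous, and
wherever the two remaining alleles differ the reported genotypes are
disjoint. The scanner merges consecutive duo-incompatible sites separated
by at most `max_gap_bp` (default 50 kb) with no intervening heterozygous
call in either individual (a het call implies two copies and terminates a
candidate), and reports segments with at least `min_sites` (default 3)
supporting sites. These thresholds are validated against simulation truth
only — they are exposed as flags and should be re-tuned for chips with very
different marker densities. Segment bounds are the first and last
supporting sites (1-based inclusive internally; BED output converts to
0-based half-open).

## Inheritance-state analysis

States are defined by transmitted-**copy** equality, not allele values:
identical (same parental copy from both parents), haploidentical maternal /
paternal (same copy from that parent only), nonidentical. Enumerating the
16 labeled transmission choices per site and keeping those that reproduce
both children's genotypes makes homozygous parents correctly
non-informative for their own transmission. A site consistent with one
state contributes weight 1; with exactly two states, 0.5 each; three or
more states carry no information and contribute nothing; an empty set is a
state-consistency error (impossible genotypes, i.e. genotyping error) and
is counted on the track. Sites with any no-call in the quartet are skipped.

Weights accumulate into non-overlapping bins (default 1 Mb,
`bin = position // bin_bp`, partial end bins kept). A bin's state is the
unique top-weight state; bins with no informative weight — or with a tie,
which arises in near-empty partial bins and carries no majority evidence —
are left unassigned. Genome state fractions are assigned-bin shares, with
no smoothing or sub-bin breakpoint refinement: block boundaries are
reported at bin resolution only. The sibling-only mode additionally
enumerates both unobserved parents' genotypes over the site's allele
universe (biallelic assumption) and merges the two haploidentical states,
which cannot be distinguished without parental genotypes.

## Pedigree simulator

The simulated pedigree is two grandparent founders whose children are
Mother and Aunt, an unrelated founder Father, and two children of Father ×
Mother — the minimal structure realizing every relationship the analyses
use (parent–offspring, two full-sib pairs, avuncular, unrelated). Founder
haplotypes are drawn from per-marker alternate-allele frequencies
(Hardy–Weinberg; linkage equilibrium between markers — no LD model, which
suffices because no analysis here uses LD). Marker panels place SNPs
uniformly over the genome with frequencies Uniform(0.05, 0.95) by default;
chromosomes default to 22 equal lengths of 130 Mb, with GRCh37 autosome
lengths available as `HUMAN_AUTOSOME_LENGTHS` for realistic runs. Meioses
lay down Poisson(rate × length) crossovers per chromosome at a default rate
of 10⁻⁸ per bp (≈1 cM/Mb) and record the source copy of every transmitted
marker, from which true inheritance states and their block boundaries
follow exactly.

Observed genotypes apply the undercall partition above with default
x = 0.003 — the middle of the 0.25–0.60% range estimated for real chips,
and small enough that the implied no-call rate (≈ (1−f)x) lands near the
~0.2% reported for real data. An optional independent `nocall_extra`
probability models assay dropout separately. Deletions are specified
explicitly (carrier, chromosome, interval), planted on a fair-coin-chosen
haplotype before the carrier's gametes are drawn, and therefore transmit
mendelianly with the carrying haplotype. All randomness flows from one
master seed through named substreams (founders, meioses, errors,
structural events), so stages are individually reproducible.

What the simulator does **not** emulate: population structure and
admixture, linkage disequilibrium, chip-specific marker ascertainment,
batch effects, allele-frequency-dependent error, and X-chromosome
genetics. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
artifact of real chip data.

## Problem sizes and numerical conventions

The test suite exercises simulated families of 20k–100k markers; the
undercall-recovery checks use 500k markers (where the binomial sampling
error on x at x = 0.005 is a few percent), and quartet state-track checks
use ~100k markers on the 22 human autosomes (~35 informative markers per
1 Mb bin, enough that bin ties are rare). The reproduction script averages
the identical-state genome fraction over four replicate quartets: with
crossovers at 1 per 100 Mb a single quartet has only ~140 recombination
blocks and a per-state fraction standard deviation near 3.7 percentage
points, so replication is used to estimate the 25% expectation with SD
under 2 points. Counts displayed as integers are rounded half-up.
Half-match weights of 0.5 cancel exactly in identity + difference, so no
floating-point tolerance is needed there; proportion identities elsewhere
are asserted to within 10⁻⁶ or stated sampling tolerances.
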