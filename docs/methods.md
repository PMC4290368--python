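# Methods

This note documents the statistical models implemented in `ibisgen`, the
choices made where a procedure is underdetermined by common practice, and
what the synthetic-data generators do and do not emulate.

## Diversity statistics

**Per-individual heterozygosity** is the count of heterozygous genotypes
divided by an externally supplied callable length (bp). Missing genotypes
contribute to neither numerator nor denominator, so low-coverage samples
are not biased downward. The callable length is the caller's
responsibility: with read-alignment-derived calls it is the number of
positions with sufficient depth, not the assembly size.

**Watterson's estimator** `θ_S = K/(a·L)` with `a` the (n−1)-th harmonic
number is computed exactly; it is undefined for n < 2 chromosomes and the
function refuses rather than returning a degenerate value.

**The pooled-heterozygosity scan.** Per SNP the most- and least-abundant
allele counts (`n_MAJ`, `n_MIN`) are pooled across individuals; per window
the counts are summed first and the formula
`H_p = 2 Σn_MAJ Σn_MIN/(Σn_MAJ+Σn_MIN)²` applied once to the sums —
never averaged over per-SNP values, which would weight balanced rare SNPs
equally with well-covered ones. When read depths (AD-style fields) are
unavailable, genotype counts (2·hom + het per allele) substitute for read
counts; this fallback is what `pooled_allele_counts` provides and is noted
in its docstring. Major/minor assignment happens per SNP before
summation; ties contribute symmetrically and need no tie-break.

Windows are non-overlapping tiles by default (a `step` below the width
gives true sliding windows). A trailing partial tile is kept but flagged;
flagged windows — including those with fewer than `min_snps` SNPs
(default 10 in the scan configuration, lower in the desk-scale drivers) —
are excluded from the genome-wide mean and standard deviation so
near-empty windows cannot inflate the tails. The Z-transform uses the
sample (n−1) standard deviation. The sweep threshold is the q = 0.01
standard-normal quantile, −2.326; the threshold is a parameter, not a
constant, so other stringencies are one argument away.

**`H_t/H_0` decay.** The founder cohort is every individual carrying the
earliest time label; `H_0` is that cohort's mean heterozygosity, and the
regression of `H_t/H_0` on time is ordinary least squares with the
two-sided p from the t distribution on n−2 df. Under pure drift the
expectation is `H_t = H_0 (1 − 1/2N)^t`, the closed form the simulator is
validated against.

**Neutral mutation rate.** `μ = d·g/(2T)` from pairwise divergence `d`,
generation time `g` (years) and divergence time `T` (years): divergence
accumulates along both branches, hence the factor 2.

## Coding-variant effects

Effects come from reconstructing the codon containing the SNP on the
coding strand (reverse-complementing minus-strand genes) and translating
the reference and alternate codons under the standard genetic code —
Biopython supplies the genetic code and complementation. Codons split
across exon junctions are handled by concatenating exon sequence in
coding order before locating the codon; sites in incomplete terminal
codons raise and are skipped (with a count) by the batch classifier.
A substitution in the initiator ATG is `start_loss`. For SNPs,
loss-of-function means `stop_gain` or `start_loss`; frameshift LoF from
indels is accepted as a precomputed input, never called internally.

**NS/S** is a count ratio of non-synonymous to synonymous heterozygous
sites within one diploid genome — a per-genome load measure — not a
site-normalised dN/dS; with zero synonymous sites the ratio is reported
as missing rather than infinite.

**DAF spectra** use the outgroup-derived ancestral allele stored with the
genotype matrix; sites where the ancestral base matches neither allele
are excluded with a reported count, frequencies are over non-missing
genotypes only, and bins are right-closed on (0, 1].

**Fisher's exact test** is computed by hypergeometric enumeration over
the fixed-margin support (one-sided in both directions plus the
minimum-likelihood two-sided sum). The per-gene LoF enrichment runs the
one-sided test in each direction at unadjusted α = 0.05 by default,
with an optional Benjamini–Hochberg mode; both one- and two-sided
p-values are exposed because the convention in comparative screens
varies.

## Linkage and structure

**EM haplotype frequencies.** For two biallelic loci in unphased
diploids, only the double-heterozygote class has ambiguous phase. The EM
starts from linkage equilibrium (product of allele frequencies),
reassigns double heterozygotes between coupling and repulsion by their
current relative likelihood, and stops when no frequency moves more than
1e-8 (cap 1,000 iterations). The log-likelihood is available for the
monotonicity check the tests assert. `r² = D²/(p_A q_A p_B q_B)`.

A caveat documented here because it shapes the validation: the EM
optimum is the genotype-likelihood MLE, which differs from the *realised*
gamete counts of the sample by roughly `√n_dh/2n` (phase noise among
`n_dh` double heterozygotes). The phased-truth check therefore uses a
strong-LD configuration — gamete frequencies (0.48, 0.02, 0.02, 0.48) —
where double-het phase is nearly deterministic and 1e-3 agreement at
n = 500 is attainable; under balanced frequencies no estimator could
match the realised counts that tightly from genotypes alone.

**Site filters** mirror the Haploview-style parameter set: minor-allele
frequency ≥ 0.1, genotyped fraction ≥ 0.6, Hardy–Weinberg exact-test
p ≥ 0.001 (conditional enumeration over heterozygote counts), pairs
within 300 kb. Distance bins default to 1 kb up to 10 kb and 5 kb beyond,
resolving both a ~1-kb and a ~60-kb half-max regime; pairs per bin are
capped at 100,000 by seeded subsampling. The half-max distance is found
by linear interpolation between bin midpoints from the curve's peak; a
curve that never reaches half its maximum reports `"> max_distance"`.

**F_ST** is Weir & Cockerham's (1984) θ: per-locus among-population (a),
among-individual (b) and within-individual (c) variance components from
allele frequencies and observed heterozygosity, combined genome-wide as
`Σa / Σ(a+b+c)` (ratio of averages). Loci monomorphic overall are
skipped; slightly negative estimates near zero are legitimate for the
unbiased estimator and are not clipped. Against a finite island model
with d demes the expectation is approximately
`1/(1 + 4Nm (d/(d−1))²)`; validation uses 16 demes so the finite-deme
correction (~7%) stays small.

## STR forensics

The perfect-repeat scanner reports maximal exact tandem runs of 2–6-bp
primitive units (an `ATATAT` run is a 2-bp repeat, never 4-bp or 6-bp),
broken at N, left-most maximal, with a minimum total run length.
Degenerate (mismatch-tolerant) repeat discovery is out of scope.

Panel statistics follow standard forensic practice where a published
formula is not fixed:

- **Match probability** uses observed (counted) genotype frequencies,
  not Hardy–Weinberg expectations; `PD = 1 − PM` per locus and the
  combined power of discrimination is `1 − Π PM_i`.
- **Exclusion probability** is computed by exact enumeration over every
  (mother genotype, paternal allele, maternal allele, random-man
  genotype) combination under HWE and Mendelian transmission — several
  closed forms circulate and disagree, so enumeration is the
  implementation and Monte-Carlo simulation the cross-check. Combined
  `PE = 1 − Π(1 − PE_i)`.
- **Paternity index** is the likelihood ratio
  `P(child | mother, alleged father) / P(child | mother, random man)`
  with both terms from Mendelian enumeration; the probability of
  paternity uses the conventional prior of 0.5 (configurable). A
  mother–child incompatibility raises with the locus named.
- **Sex calling**: the W-linked marker's female allele is the Z-fragment
  length plus a 31-bp insertion; its presence calls ZW, its absence with
  a valid Z allele calls ZZ, and missing data is inconclusive.

Major-allele ties break toward the smaller repeat count so outputs are
deterministic.

## Synthetic data

The generators emulate the study system — a refounding from two breeding
pairs — at desk scale (N ≤ a few hundred, a few Mb, ≤ ~200 generations):

- **Wright–Fisher**: forward in time, diploid, piecewise-constant N.
  Each offspring draws two parents uniformly and independently — the
  classic monoecious model with selfing at probability 1/N — because
  under it mean heterozygosity decays exactly as `H_0 (1 − 1/2N)^t`, the
  closed form every drift check compares against. A no-selfing option
  exists; it introduces a one-generation transient and an effective size
  near N + 1/2, so the closed form then holds only asymptotically.
  Standing variation starts at frequency 0.5; infinite-sites mutations
  arrive at Poisson(μL) per gamete at fresh positions; recombination is
  at most one crossover per gamete. The founding state defines the
  ancestral allele, standing in for an outgroup alignment.
- **Island model**: unlinked loci, gamete migration at rate m to a
  uniformly chosen other deme, no mutation, initial frequency 0.5.
- **Pedigrees**: a monogamous managed-breeding mode (deterministic
  offspring counts and alternating sexes, so two founder pairs with two
  offspring per pair double each season: 4, 4, 8, 16) and a random-mating
  mode; a season with no possible pairs yields an explicit extinction
  result.
- **STR transmission**: symmetric single-step stepwise mutation per
  meiosis (variance grows as rate × generations); an allele that would
  reach zero repeats reflects to +1. Multi-step mutations are omitted —
  the single-step model is the simplest with a known variance law.
- **Coding landscapes** place 1–5-exon ORFs on both strands and implant
  variants whose labels are derived by codon arithmetic on the coding
  sequence itself, independently of the genome-coordinate classifier that
  will be tested against them. The default NS/S implant ratio is 0.69,
  the per-genome value observed in the most severely bottlenecked genome
  of the study system this package models.

What the simulators do **not** reproduce: sequencing error and depth
variation (genotypes are truth after masking), selection (sweep-like
signals would need externally imposed diversity masks), sex chromosomes
(the W marker is transmitted as a pedigree-linked locus), overlapping
real-world pedigree complications (half-sibs, re-pairing after death).
Passing tests therefore demonstrate correctness of the statistics on
idealised inputs, not robustness to calling artefacts.

## Numerical conventions

Internal coordinates are 0-based half-open; VCF positions stay 1-based in
the genotype matrix, and the single conversion point is the window
arithmetic (`start = ((p−1) div width)·width`). Missing data is explicit
everywhere (never encoded as 0); degenerate inputs (constant Hp vector,
monomorphic locus in the EM, empty founder cohort, single subpopulation)
raise rather than return NaN silently. All simulation entry points take
a seed and are bit-reproducible under it.

## Problem sizes

The bundled drivers and validation runs use desk-scale sizes chosen to
make Monte-Carlo standard errors small enough for 3-SE checks while
keeping each run in seconds to a couple of minutes on one CPU: 200
replicates for drift-decay trajectories, 500 diploids for the EM check,
100 pedigree replicates × 100 candidate non-fathers for paternity
ranking, 16 demes × 50 diploids × 200 generations × 100 loci for the
island model.
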