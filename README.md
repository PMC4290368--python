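# ibisgen

Conservation-genomics statistics for severely bottlenecked bird
populations, built around the recovery of a species refounded from two
breeding pairs. The package implements, as tested and reusable code, the
analyses that sit downstream of variant calling in such a study:

- **Genome diversity** — per-individual heterozygosity rates, Watterson's
  `θ_S = K / (a·L)` with `a = Σ_{i=1}^{n-1} 1/i`, and the `H_t/H_0`
  heterozygosity-decay regression against recovery time (under pure drift
  `H_t = H_0 (1 − 1/2N)^t`).
- **Fixation scan** — pooled heterozygosity per genomic window,
  `H_p = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)²`, Z-standardised genome-wide
  (`ZH_p`), with windows at `ZH_p ≤ −2.326` (the q = 0.01 normal quantile)
  flagged as candidate fixation/sweep regions.
- **Functional load** — codon-level classification of coding SNPs
  (synonymous / missense / stop-gain / stop-loss / start-loss, both
  strands, codons split across exons), per-genome NS/S heterozygosity
  ratios, derived-allele-frequency spectra from an outgroup-ancestral
  state, and per-gene loss-of-function enrichment by exact Fisher tests.
- **Linkage and structure** — two-locus `r² = D²/(p_A q_A p_B q_B)` from
  EM haplotype-frequency estimation on unphased diploids with
  Haploview-style site filters, LD-decay curves with the half-max
  distance, and Weir–Cockerham F_ST with ratio-of-averages combination.
- **STR forensics** — a perfect tandem-repeat scanner, locus summaries
  (major–minor allele size differences, expected heterozygosity), and the
  DNA-identification-platform statistics: match probability / power of
  discrimination, exclusion probability by exact triplet enumeration,
  paternity index and Essen-Möller probability of paternity, and sex
  calling from a female-specific W-chromosome insertion allele.
- **Synthetic data with ground truth** — forward Wright–Fisher simulation
  under piecewise-constant demography (bottlenecks included), a finite
  island model, managed-breeding pedigrees, stepwise-mutation STR
  transmission, and coding landscapes with effect-labelled variant
  implants. Every generator is deterministic under its seed.

The intended users are population/conservation geneticists who want these
statistics as plain Python functions over VCF/TSV/BED inputs, with the
simulators providing fully known ground truth for validation.

## Worked example

```python
import numpy as np
from ibisgen import diversity as dv, simulate as sim

# a population crashes to two breeding pairs, then recovers
cfg = sim.DemographyConfig(epochs=[(100, 10), (4, 10), (50, 20)],
                           genome_length=2_000_000, n_initial_sites=400,
                           recombination_rate=1e-6, seed=1)
gm, truth = sim.simulate_wright_fisher(cfg, sample_size=8)
print(f"het before/after: {truth.het_trajectory[0]:.3f} -> "
      f"{truth.het_trajectory[-1]:.3f}")
theta = dv.watterson_theta(K=gm.n_sites, n=2 * gm.n_samples, L=2_000_000)
print(f"theta_S = {theta.theta_s:.2e}")
print(f"mu = {dv.neutral_mutation_rate(0.1031, 3, 38.98e6):.4g}")
```

prints

```
het before/after: 0.502 -> 0.118
theta_S = 6.03e-05
mu = 3.967e-09
```

The 40-generation bottleneck erases three quarters of the founding
heterozygosity; `θ_S` is the sample estimate of the population mutation
parameter over the surveyed 2 Mb; the last line is the two-species
mutation-rate calculation `μ = d·g / (2T)` from 10.31% sequence
divergence, a 3-year generation time and a 38.98-My split.

## Analysis scripts

`analysis/01_simulate_recovery.py` … `06_str_platform.py` are thin,
numbered drivers that run the full story — simulate the recovery scenario,
measure diversity and decay, scan for fixation windows, classify coding
load, estimate LD/F_ST, and build the STR identification panel — printing
a short narrative and writing their tables under `results/`. Run them in
order from the repository root.

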