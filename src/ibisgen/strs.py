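"""STR diversity summaries and the forensic identification-panel statistics.

Covers: a perfect (non-degenerate) tandem-repeat scanner for synthetic
sequence, per-locus allele summaries (major/minor size differences, expected
heterozygosity), and the DNA-identification-platform statistics — match
probability / power of discrimination from observed genotype frequencies,
probability of excluding a random non-father by exact enumeration over
(mother, child, unrelated man) triplets, the paternity index likelihood
ratio, and W-linked sex calling from a female-specific insertion allele.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import prod

import numpy as np
import pandas as pd

from .io_formats import StrGenotypeTable


# ---------------------------------------------------------------------------
# perfect-repeat scanner

def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a repeat of a shorter word."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def scan_perfect_strs(sequence: str, unit_sizes=(2, 3, 4, 5, 6),
                      min_total_length: int = 12) -> pd.DataFrame:
    """Maximal exact tandem runs of 2-6 bp units; no mismatches or indels.

    Runs containing N are broken; the reported unit is primitive (an ATATAT
    run is a 2-bp, never a 4-bp, repeat) and runs shorter than
    ``min_total_length`` bases are dropped.  Left-most maximal reporting:
    each run is reported once, at its left-most start, with the full run
    length (which may include a trailing partial unit).

    Returns columns start/end (0-based half-open)/unit/unit_size/n_repeats.
    """
    seq = sequence.upper()
    n = len(seq)
    rows = []
    covered: dict[int, set[tuple[int, int]]] = {}
    for k in sorted(unit_sizes):
        reported: list[tuple[int, int]] = []
        i = 0
        while i + k <= n:
            unit = seq[i:i + k]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            j = i + k
            while j < n and seq[j] == seq[j - k]:
                j += 1
            run_len = j - i
            if run_len >= 2 * k and run_len >= min_total_length:
                # skip runs that are sub-runs of an already-reported run of
                # the same unit size (left-most maximal)
                if not any(a <= i and j <= b for a, b in reported):
                    # skip runs whose primitive period is shorter (covered by
                    # a smaller unit size already scanned)
                    shorter = any(
                        a <= i and j <= b
                        for kk in unit_sizes if kk < k
                        for a, b in covered.get(kk, set())
                    )
                    if not shorter:
                        rows.append((i, j, unit, k, run_len // k))
                        reported.append((i, j))
            i += 1
        covered[k] = set((a, b) for a, b in reported)
    df = pd.DataFrame(rows, columns=["start", "end", "unit",
                                     "unit_size", "n_repeats"])
    return df.sort_values(["start", "unit_size"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# locus summaries

@dataclass
class StrLocusSummary:
    locus_id: str
    unit_size: int
    allele_counts: dict[int, int]
    n_alleles: int
    major_allele: int
    minor_alleles: list[int]
    size_differences_bp: list[int]
    expected_heterozygosity: float

    @property
    def allele_freqs(self) -> dict[int, float]:
        total = sum(self.allele_counts.values())
        return {a: c / total for a, c in self.allele_counts.items()}


def str_locus_summary(table: StrGenotypeTable, locus: str) -> StrLocusSummary:
    """Allele frequencies, major/minor size differences and expected het.

    Frequencies come from the 2n observed (non-missing) alleles.  The major
    allele is the most frequent; ties break toward the smaller repeat count.
    Expected heterozygosity is 1 - sum(p_i^2).
    """
    pairs = [p for p in table.locus_column(locus) if p is not None]
    if not pairs:
        raise ValueError(f"locus {locus}: all genotypes missing")
    alleles = [a for p in pairs for a in p]
    counts: dict[int, int] = {}
    for a in alleles:
        counts[a] = counts.get(a, 0) + 1
    major = min(counts, key=lambda a: (-counts[a], a))
    minors = sorted(a for a in counts if a != major)
    unit = table.unit_size[locus]
    total = len(alleles)
    he = 1.0 - sum((c / total) ** 2 for c in counts.values())
    return StrLocusSummary(
        locus_id=locus, unit_size=unit, allele_counts=dict(sorted(counts.items())),
        n_alleles=len(counts), major_allele=major, minor_alleles=minors,
        size_differences_bp=[abs(major - a) * unit for a in minors],
        expected_heterozygosity=he)


def polymorphic_fraction(summaries: list[StrLocusSummary],
                         min_alleles: int = 4) -> pd.Series:
    """Fraction of loci with >= min_alleles alleles, per unit-size class."""
    if not summaries:
        raise ValueError("no locus summaries")
    df = pd.DataFrame({"unit": [s.unit_size for s in summaries],
                       "poly": [s.n_alleles >= min_alleles for s in summaries]})
    return df.groupby("unit")["poly"].mean()


# ---------------------------------------------------------------------------
# identification-panel statistics

def match_probability(table: StrGenotypeTable, locus: str) -> float:
    """PM = sum of squared observed (unordered) genotype frequencies.

    The probability two random individuals share a genotype at the locus,
    from counting, not from Hardy-Weinberg expectation.
    """
    gts = [tuple(sorted(p)) for p in table.locus_column(locus) if p is not None]
    if not gts:
        raise ValueError(f"locus {locus}: no genotypes")
    n = len(gts)
    counts: dict[tuple, int] = {}
    for g in gts:
        counts[g] = counts.get(g, 0) + 1
    return sum((c / n) ** 2 for c in counts.values())


def discrimination_power(table: StrGenotypeTable, locus: str) -> float:
    """PD = 1 - PM for one locus."""
    return 1.0 - match_probability(table, locus)


def combined_discrimination_power(pms: list[float]) -> float:
    """Combined PD over a panel: 1 - product of per-locus match probabilities."""
    return 1.0 - prod(pms)


def exclusion_probability(allele_freqs: dict[int, float]) -> float:
    """Per-locus probability of excluding a random non-father.

    Exact enumeration under Hardy-Weinberg and Mendelian transmission over
    every (mother genotype, true-father genotype, maternal allele, paternal
    allele, random-man genotype) combination: the man is excluded when he
    carries no allele that could be the child's paternal allele given the
    mother.  No closed form is relied upon.
    """
    alleles = sorted(allele_freqs)
    p = allele_freqs
    if len(alleles) < 2:
        return 0.0
    total = 0.0
    for m1, m2 in itertools.product(alleles, repeat=2):     # ordered mother
        pm = p[m1] * p[m2]
        for pa in alleles:                                   # paternal allele
            ppa = p[pa]
            for ma in (m1, m2):                              # maternal allele
                prob_case = pm * ppa * 0.5
                child = tuple(sorted((ma, pa)))
                paternal_set = _possible_paternal(child, (m1, m2))
                p_excl = 0.0
                for g1, g2 in itertools.product(alleles, repeat=2):
                    if g1 not in paternal_set and g2 not in paternal_set:
                        p_excl += p[g1] * p[g2]
                total += prob_case * p_excl
    return total


def _possible_paternal(child: tuple[int, int], mother: tuple[int, int]) -> set[int]:
    """Alleles the true father could have transmitted, given mother and child."""
    c1, c2 = child
    out = set()
    if c1 in mother:
        out.add(c2)
    if c2 in mother:
        out.add(c1)
    return out


def combined_exclusion_probability(pes: list[float]) -> float:
    """Combined PE over a panel: 1 - product of per-locus non-exclusion."""
    return 1.0 - prod(1.0 - pe for pe in pes)


def paternity_index(mother: tuple[int, int], child: tuple[int, int],
                    alleged_father: tuple[int, int],
                    allele_freqs: dict[int, float]) -> float:
    """Single-locus PI = P(child | mother, alleged father) / P(child | mother, random man).

    Both terms come from Mendelian enumeration: the mother transmits each of
    her alleles with probability 1/2, the alleged father likewise; the random
    man transmits an allele drawn from the population frequencies.  A
    mother-child incompatibility (no maternal allele can explain the child)
    raises an error.
    """
    child_s = tuple(sorted(child))

    def p_child_given(paternal_dist: dict[int, float]) -> float:
        tot = 0.0
        for ma in mother:
            for pa, ppa in paternal_dist.items():
                if tuple(sorted((ma, pa))) == child_s:
                    tot += 0.5 * ppa
        return tot

    random_man = {a: f for a, f in allele_freqs.items()}
    denom = p_child_given(random_man)
    if denom == 0:
        raise ValueError(
            f"mother {mother} cannot produce child {child} with any father")
    father_dist: dict[int, float] = {}
    for a in alleged_father:
        father_dist[a] = father_dist.get(a, 0.0) + 0.5
    return p_child_given(father_dist) / denom


def probability_of_paternity(pis: list[float], prior: float = 0.5) -> float:
    """Essen-Moller W from per-locus PIs: PI*prior / (PI*prior + 1 - prior)."""
    if not 0 < prior < 1:
        raise ValueError("prior must lie in (0, 1)")
    pi = prod(pis)
    return pi * prior / (pi * prior + (1.0 - prior))


# ---------------------------------------------------------------------------
# W-linked sex calling

@dataclass(frozen=True)
class SexCall:
    individual: str
    alleles: tuple[int, int] | None
    call: str  # ZZ / ZW / inconclusive


def sex_call(individual: str, marker_alleles: tuple[int, int] | None,
             z_length: int, w_insertion: int = 31) -> SexCall:
    """Call sex from the W-linked marker: the W allele is Z length + insertion.

    Females (ZW) show the +``w_insertion``-bp fragment; males (ZZ) show only
    the Z-length fragment; a missing genotype is inconclusive.
    """
    if marker_alleles is None:
        return SexCall(individual, None, "inconclusive")
    w_len = z_length + w_insertion
    has_w = w_len in marker_alleles
    has_z = z_length in marker_alleles
    if has_w:
        return SexCall(individual, marker_alleles, "ZW")
    if has_z:
        return SexCall(individual, marker_alleles, "ZZ")
    return SexCall(individual, marker_alleles, "inconclusive")
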