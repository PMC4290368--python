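"""Coding-variant effects, NS/S load, derived-allele spectra and LoF enrichment.

A SNP inside a coding exon is classified by rebuilding the codon it sits in on
the coding strand (reverse-complementing minus-strand genes) and translating
the reference and alternate codons under the standard genetic code.  The NS/S
statistic is a plain count ratio of non-synonymous to synonymous heterozygous
sites within one diploid genome — a per-genome load measure, not a
site-normalised dN/dS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io_formats import HET, CdsModel, GenotypeMatrix

_STOPS = set(standard_dna_table.stop_codons)

EFFECTS = ("synonymous", "missense", "stop_gain", "stop_loss", "start_loss")
NONSYNONYMOUS = {"missense", "stop_gain", "stop_loss", "start_loss"}
LOF_EFFECTS = {"stop_gain", "start_loss"}


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str
    chrom: str
    pos0: int          # 0-based genome position of the SNP
    codon_index: int   # 0-based codon index along the CDS
    ref_codon: str
    alt_codon: str
    effect: str
    lof: bool


def _translate_codon(codon: str) -> str:
    return "*" if codon in _STOPS else standard_dna_table.forward_table[codon]


def classify_coding_snp(cds: CdsModel, chrom_seq: str, pos0: int,
                        ref: str, alt: str) -> CodingEffect:
    """Effect of substituting ``ref``->``alt`` at 0-based genome position ``pos0``.

    The site must fall in one of the CDS exons and ``chrom_seq`` must carry
    ``ref`` at the site.  Codons split across exon junctions are handled by
    concatenating exon sequence in coding order before locating the codon.
    """
    # genome offsets of every CDS base, in coding (5'->3') order
    offsets: list[int] = []
    for a, b in cds.exons:
        offsets.extend(range(a, b))
    if cds.strand == "-":
        offsets = offsets[::-1]
    try:
        cds_index = offsets.index(pos0)
    except ValueError:
        raise ValueError(
            f"position {pos0} not in CDS exons of {cds.gene_id}") from None
    if chrom_seq[pos0].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at {cds.chrom}:{pos0}: sequence has "
            f"{chrom_seq[pos0]!r}, expected {ref!r}")

    coding = "".join(chrom_seq[i] for i in offsets).upper()
    if cds.strand == "-":
        coding = str(Seq(coding).complement())  # offsets already reversed
    ref_base = ref.upper() if cds.strand == "+" else str(Seq(ref).complement()).upper()
    alt_base = alt.upper() if cds.strand == "+" else str(Seq(alt).complement()).upper()
    assert coding[cds_index] == ref_base

    # phase = bases of a truncated first codon at the 5' end
    k = cds_index - cds.phase
    if k < 0:
        raise ValueError(
            f"{cds.gene_id}: site at {pos0} lies in an incomplete first codon")
    codon_index, within = divmod(k, 3)
    start = cds.phase + codon_index * 3
    ref_codon = coding[start:start + 3]
    if len(ref_codon) < 3:
        raise ValueError(
            f"{cds.gene_id}: site at {pos0} lies in an incomplete codon")
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]

    aa_ref = _translate_codon(ref_codon)
    aa_alt = _translate_codon(alt_codon)
    if codon_index == 0 and cds.phase == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        effect = "start_loss"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop_gain"
    elif aa_ref == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    return CodingEffect(cds.gene_id, cds.chrom, pos0, codon_index,
                        ref_codon, alt_codon, effect, effect in LOF_EFFECTS)


def classify_sites(gm: GenotypeMatrix, models: list[CdsModel],
                   sequences: dict[str, str]) -> pd.DataFrame:
    """Classify every matrix site that falls inside a CDS exon.

    Sites inside incomplete terminal codons are skipped (count logged in the
    returned frame's ``attrs['n_skipped']``).  Returns columns
    chrom/pos/gene_id/effect/lof indexed like the matching matrix rows.
    """
    exon_map: list[tuple[str, int, int, CdsModel]] = []
    for m in models:
        for a, b in m.exons:
            exon_map.append((m.chrom, a, b, m))
    rows, n_skipped = [], 0
    for i in range(gm.n_sites):
        p0 = int(gm.pos[i]) - 1
        for chrom, a, b, m in exon_map:
            if chrom == gm.chrom[i] and a <= p0 < b:
                try:
                    eff = classify_coding_snp(m, sequences[chrom], p0,
                                              gm.ref[i], gm.alt[i])
                except ValueError:
                    n_skipped += 1
                    break
                rows.append((i, gm.chrom[i], int(gm.pos[i]), m.gene_id,
                             eff.effect, eff.lof))
                break
    df = pd.DataFrame(rows, columns=["site", "chrom", "pos", "gene_id",
                                     "effect", "lof"])
    df.attrs["n_skipped"] = n_skipped
    return df


def ns_s_ratio(effects: pd.Series | list[str]) -> float:
    """Non-synonymous / synonymous count ratio over one genome's het sites.

    Returns NaN when the synonymous count is zero (ratio undefined).
    """
    eff = pd.Series(effects)
    ns = int(eff.isin(NONSYNONYMOUS).sum())
    s = int((eff == "synonymous").sum())
    if s == 0:
        return float("nan")
    return ns / s


def ns_s_per_sample(gm: GenotypeMatrix, site_effects: pd.DataFrame) -> pd.Series:
    """NS/S of heterozygous coding sites, per sample."""
    out = {}
    for j, sid in enumerate(gm.sample_ids):
        het_sites = set(np.nonzero(gm.gt[:, j] == HET)[0])
        eff = site_effects.loc[site_effects["site"].isin(het_sites), "effect"]
        out[sid] = ns_s_ratio(eff)
    return pd.Series(out, name="ns_s")


def daf_spectrum(gm: GenotypeMatrix, site_effects: pd.DataFrame,
                 n_bins: int = 10) -> pd.DataFrame:
    """Derived-allele-frequency spectrum, per effect class (NS vs S).

    The ancestral allele comes from the matrix ``anc`` column (outgroup
    reference); the derived allele is the other one.  Frequencies are over
    non-missing genotypes; sites without ancestral information are excluded
    (count in ``attrs['n_excluded']``).  Fractions within each class sum
    to 1; bins partition (0, 1] with right-closed edges.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    classes = {"S": ["synonymous"], "NS": sorted(NONSYNONYMOUS)}
    freqs: dict[str, list[float]] = {"S": [], "NS": []}
    n_excluded = 0
    by_site = site_effects.set_index("site")["effect"]
    for site, effect in by_site.items():
        anc = gm.anc[site]
        if anc == ".":
            n_excluded += 1
            continue
        valid = gm.gt[site] >= 0
        n_chrom = 2 * int(valid.sum())
        if n_chrom == 0:
            n_excluded += 1
            continue
        alt_count = int(np.where(valid, gm.gt[site], 0).sum())
        derived = alt_count if anc == gm.ref[site] else n_chrom - alt_count
        if derived == 0:
            continue  # no derived allele observed: not a segregating derived site
        key = "S" if effect in classes["S"] else "NS"
        freqs[key].append(derived / n_chrom)
    if not freqs["S"] and not freqs["NS"]:
        raise ValueError("no sites with ancestral information")
    rows = {}
    for key in ("NS", "S"):
        f = np.asarray(freqs[key])
        if f.size:
            # right-closed bins on (0, 1]: freq == edge goes to the lower bin
            idx = np.clip(np.searchsorted(edges, f, side="left") - 1, 0, n_bins - 1)
            hist = np.bincount(idx, minlength=n_bins)
            rows[key] = hist / hist.sum()
        else:
            rows[key] = np.full(n_bins, np.nan)
    df = pd.DataFrame(rows, index=pd.IntervalIndex.from_breaks(edges, closed="right"))
    df.attrs["n_excluded"] = n_excluded
    return df


# ---------------------------------------------------------------------------
# Fisher's exact test and LoF enrichment

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> dict[str, float]:
    """One- and two-sided Fisher exact p for the table [[a, b], [c, d]].

    Exact hypergeometric enumeration over all tables with the observed
    margins; ``one_sided_greater`` tests enrichment of the top-left cell,
    ``two_sided`` sums all tables with probability <= the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    from scipy.stats import hypergeom
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    greater = float(pmf[support >= a].sum())
    less = float(pmf[support <= a].sum())
    two = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return {"one_sided_greater": min(greater, 1.0),
            "one_sided_less": min(less, 1.0),
            "two_sided": min(two, 1.0)}


def lof_enrichment(lof_matrix: pd.DataFrame, groups: pd.Series,
                   alpha: float = 0.05, bh_correct: bool = False):
    """Genes with group-biased loss of function, per direction.

    ``lof_matrix`` is a gene x species boolean frame; ``groups`` labels each
    species column with one of two group names.  Each gene gets a 2x2 table
    (LoF vs intact x group) tested one-sided in each direction; genes with
    p < alpha are returned per direction.  With ``bh_correct`` the per-
    direction p-values are Benjamini-Hochberg adjusted first.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    g1 = [s for s in lof_matrix.columns if groups[s] == labels[0]]
    g2 = [s for s in lof_matrix.columns if groups[s] == labels[1]]
    if not g1 or not g2:
        raise ValueError("each group must be non-empty")
    recs = []
    for gene, row in lof_matrix.iterrows():
        a = int(row[g1].sum()); b = len(g1) - a
        c = int(row[g2].sum()); d = len(g2) - c
        p = fisher_exact_2x2(a, b, c, d)
        recs.append((gene, a, c, p["one_sided_greater"], p["one_sided_less"]))
    df = pd.DataFrame(recs, columns=["gene", f"lof_{labels[0]}",
                                     f"lof_{labels[1]}", "p_greater", "p_less"])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        for col in ("p_greater", "p_less"):
            df[col] = multipletests(df[col], method="fdr_bh")[1]
    enriched_1 = df.loc[df["p_greater"] < alpha]
    enriched_2 = df.loc[df["p_less"] < alpha]
    return {labels[0]: enriched_1, labels[1]: enriched_2, "all": df}
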