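"""Coding-effect classification, NS/S, DAF spectra and Fisher/LoF tests."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from ibisgen import coding
from ibisgen import io_formats as io
from ibisgen import simulate as sim


def single_exon_gene(cds: str, strand: str = "+", pad: int = 10):
    """A one-gene chromosome; returns (model, sequence)."""
    if strand == "+":
        insert = cds
    else:
        insert = str(Seq(cds).reverse_complement())
    seq = "T" * pad + insert + "T" * pad
    model = io.CdsModel("g", "chr1", strand, [(pad, pad + len(cds))])
    return model, seq


class TestClassifyCodingSnp:
    def test_missense(self):
        model, seq = single_exon_gene("ATGATGTAA")  # M M *
        # third base of the second codon: ATG -> ATA is M -> I
        eff = coding.classify_coding_snp(model, seq, 10 + 5, "G", "A")
        assert eff.effect == "missense" and not eff.lof

    def test_synonymous(self):
        model, seq = single_exon_gene("ATGCTGTAA")  # M L *
        eff = coding.classify_coding_snp(model, seq, 10 + 5, "G", "A")  # CTG->CTA
        assert eff.effect == "synonymous"

    def test_stop_gain_is_lof(self):
        model, seq = single_exon_gene("ATGTGGTAA")  # M W *
        eff = coding.classify_coding_snp(model, seq, 10 + 5, "G", "A")  # TGG->TGA
        assert eff.effect == "stop_gain" and eff.lof

    def test_start_loss_is_lof(self):
        model, seq = single_exon_gene("ATGAAATAA")
        eff = coding.classify_coding_snp(model, seq, 10, "A", "G")  # ATG->GTG
        assert eff.effect == "start_loss" and eff.lof

    def test_minus_strand_codon(self):
        model, seq = single_exon_gene("ATGTGGTAA", strand="-")
        # genome position of the coding TGG third base: coding index 5 maps to
        # genome pad + (len - 1 - 5)
        pos0 = 10 + (9 - 1 - 5)
        ref = seq[pos0]
        eff = coding.classify_coding_snp(model, seq, pos0, ref, "T")  # comp A
        assert eff.effect == "stop_gain"

    def test_outside_cds_and_ref_mismatch(self):
        model, seq = single_exon_gene("ATGTGGTAA")
        with pytest.raises(ValueError, match="not in CDS"):
            coding.classify_coding_snp(model, seq, 2, "T", "A")
        with pytest.raises(ValueError, match="mismatch"):
            coding.classify_coding_snp(model, seq, 12, "C", "A")

    def test_brute_force_translation_oracle(self, cds_landscape, rng):
        """Full-CDS translate-before/after agrees with the codon classifier.

        Randomised multi-exon genes on both strands, including codons split
        across exon junctions; random substitutions, not only the implants.
        """
        seqs, models, _ = cds_landscape
        seq = seqs["chr1"]
        for model in models:
            offsets = []
            for a, b in model.exons:
                offsets.extend(range(a, b))
            if model.strand == "-":
                offsets = offsets[::-1]
            cds_seq = "".join(seq[i] for i in offsets)
            if model.strand == "-":
                cds_seq = str(Seq(cds_seq).complement())
            for _ in range(30):
                ci = int(rng.integers(len(offsets)))
                pos0 = offsets[ci]
                ref_g = seq[pos0]
                alt_g = str(rng.choice([b for b in "ACGT" if b != ref_g]))
                eff = coding.classify_coding_snp(model, seq, pos0, ref_g, alt_g)
                # oracle: translate the whole CDS before and after
                alt_c = alt_g if model.strand == "+" else str(Seq(alt_g).complement())
                mutated = cds_seq[:ci] + alt_c + cds_seq[ci + 1:]
                aa0 = str(Seq(cds_seq).translate())
                aa1 = str(Seq(mutated).translate())
                if ci < 3 and not mutated.startswith("ATG"):
                    expect = "start_loss"
                elif aa0 == aa1:
                    expect = "synonymous"
                elif "*" in aa1[:-1] or (aa1[-1] == "*" and aa0[-1] != "*"):
                    expect = "stop_gain"
                elif aa0[-1] == "*" and aa1[-1] != "*":
                    expect = "stop_loss"
                else:
                    expect = "missense"
                assert eff.effect == expect, (model.gene_id, ci, ref_g, alt_g)

    def test_implanted_labels_recovered_exactly(self, cds_landscape):
        seqs, models, implants = cds_landscape
        by_id = {m.gene_id: m for m in models}
        for _, r in implants.iterrows():
            eff = coding.classify_coding_snp(by_id[r.gene_id], seqs[r.chrom],
                                             r.pos0, r.ref, r.alt)
            assert eff.effect == r.true_effect


class TestNsS:
    def test_printed_count_pair(self):
        effects = ["missense"] * 69 + ["synonymous"] * 100
        assert coding.ns_s_ratio(effects) == pytest.approx(0.69)

    @pytest.mark.parametrize("effects,expected", [
        (["synonymous"] * 5, 0.0),
        (["missense", "synonymous"], 1.0),
    ])
    def test_edges(self, effects, expected):
        assert coding.ns_s_ratio(effects) == expected

    def test_zero_synonymous_is_missing(self):
        assert math.isnan(coding.ns_s_ratio(["missense"] * 3))

    def test_implant_ratio_recovered_exactly(self, cds_landscape):
        seqs, models, implants = cds_landscape
        gm = sim.implants_to_genotype_matrix(implants)
        effects = coding.classify_sites(gm, models, seqs)
        nss = coding.ns_s_per_sample(gm, effects)
        n_s = (implants["true_effect"] == "synonymous").sum()
        n_ns = len(implants) - n_s
        assert nss["ind0"] == pytest.approx(n_ns / n_s)


def daf_matrix(derived_counts, n_samples=9, effects=None):
    """Matrix with given alt (=derived) allele counts; anc = ref."""
    m = len(derived_counts)
    gt = np.zeros((m, n_samples), np.int8)
    for i, c in enumerate(derived_counts):
        full, rem = divmod(c, 2)
        gt[i, :full] = 2
        if rem:
            gt[i, full] = 1
    gm = io.GenotypeMatrix(
        [f"s{j}" for j in range(n_samples)], np.array(["chr1"] * m, object),
        np.arange(1, m + 1) * 10, np.array(["A"] * m, object),
        np.array(["G"] * m, object), np.array(["A"] * m, object), gt)
    eff = effects or ["synonymous"] * m
    table = pd.DataFrame({"site": range(m), "chrom": "chr1",
                          "pos": gm.pos, "gene_id": "g", "effect": eff,
                          "lof": False})
    return gm, table


class TestDafSpectrum:
    def test_binning_rule(self):
        gm, eff = daf_matrix([2])  # 2 of 18 chromosomes -> (0.1, 0.2]
        spec = coding.daf_spectrum(gm, eff)
        assert spec["S"].iloc[1] == 1.0

    def test_fixed_derived_in_last_bin(self):
        gm, eff = daf_matrix([18, 18])
        spec = coding.daf_spectrum(gm, eff)
        assert spec["S"].iloc[-1] == 1.0

    def test_fractions_sum_to_one(self, rng):
        gm, eff = daf_matrix(list(rng.integers(1, 19, 40)),
                             effects=list(rng.choice(
                                 ["synonymous", "missense"], 40)))
        spec = coding.daf_spectrum(gm, eff)
        assert spec["S"].sum() == pytest.approx(1.0, abs=1e-12)
        assert spec["NS"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_ancestral_information_errors(self):
        gm, eff = daf_matrix([2])
        gm.anc[:] = "."
        with pytest.raises(ValueError):
            coding.daf_spectrum(gm, eff)

    def test_neutral_labels_indistinguishable(self, rng):
        """Effects assigned independently of frequency: NS and S spectra agree.

        Permutation oracle: the observed NS-vs-S spectrum distance is typical
        of label permutations.
        """
        counts = list(rng.integers(1, 19, 300))
        labels = list(rng.choice(["synonymous", "missense"], 300))
        gm, eff = daf_matrix(counts, effects=labels)
        spec = coding.daf_spectrum(gm, eff)
        obs = np.nansum(np.abs(spec["NS"] - spec["S"]))
        null = []
        for _ in range(200):
            eff2 = eff.copy()
            eff2["effect"] = rng.permutation(eff["effect"].to_numpy())
            s2 = coding.daf_spectrum(gm, eff2)
            null.append(np.nansum(np.abs(s2["NS"] - s2["S"])))
        assert obs <= np.quantile(null, 0.99)


def fisher_enumeration_oracle(a, b, c, d):
    """Exhaustive fixed-margin enumeration with exact rational arithmetic."""
    from fractions import Fraction
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {}
    for x in range(lo, hi + 1):
        probs[x] = Fraction(math.comb(row1, x)
                            * math.comb(n - row1, col1 - x),
                            math.comb(n, col1))
    p_obs = probs[a]
    return (float(sum(p for x, p in probs.items() if x >= a)),
            float(sum(p for x, p in probs.items() if x <= a)),
            float(sum(p for p in probs.values() if p <= p_obs)))


class TestFisherExact:
    def test_lof_pattern_table(self):
        """LoF in 3 of 8 vs 0 of 15: one-sided p = 56/1771, significant."""
        p = coding.fisher_exact_2x2(3, 5, 0, 15)
        assert p["one_sided_greater"] == pytest.approx(56 / 1771)
        assert p["one_sided_greater"] < 0.05

    def test_no_signal_and_symmetry(self):
        assert coding.fisher_exact_2x2(0, 8, 0, 15)["one_sided_greater"] == 1.0
        assert coding.fisher_exact_2x2(4, 4, 4, 4)["two_sided"] == pytest.approx(1.0)

    def test_enumeration_oracle_random_tables(self, rng):
        for _ in range(60):
            a, b, c, d = rng.integers(0, 16, 4)
            got = coding.fisher_exact_2x2(int(a), int(b), int(c), int(d))
            g, l, t = fisher_enumeration_oracle(int(a), int(b), int(c), int(d))
            assert got["one_sided_greater"] == pytest.approx(g, abs=1e-12)
            assert got["one_sided_less"] == pytest.approx(l, abs=1e-12)
            assert got["two_sided"] == pytest.approx(t, abs=1e-9)

    def test_agrees_with_scipy_cross_check(self, rng):
        from scipy.stats import fisher_exact
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            got = coding.fisher_exact_2x2(a, b, c, d)
            assert got["one_sided_greater"] == pytest.approx(
                fisher_exact([[a, b], [c, d]], "greater")[1], abs=1e-10)
            assert got["two_sided"] == pytest.approx(
                fisher_exact([[a, b], [c, d]], "two-sided")[1], abs=1e-9)


class TestLofEnrichment:
    def matrix(self, rows, n_ev=8, n_lc=15):
        cols = [f"ev{i}" for i in range(n_ev)] + [f"lc{i}" for i in range(n_lc)]
        groups = pd.Series({c: ("EV" if c.startswith("ev") else "LC")
                            for c in cols})
        return pd.DataFrame(rows, columns=cols), groups

    def test_extreme_gene_enriched(self):
        m, g = self.matrix([[True] * 8 + [False] * 15])
        m.index = ["gene1"]
        res = coding.lof_enrichment(m, g)
        assert list(res["EV"]["gene"]) == ["gene1"]
        assert res["LC"].empty

    def test_no_lof_in_neither_list(self):
        m, g = self.matrix([[False] * 23])
        res = coding.lof_enrichment(m, g)
        assert res["EV"].empty and res["LC"].empty

    def test_null_false_positive_rate(self, rng):
        """Equal LoF probability in both groups: per-direction FPR <= alpha."""
        n_genes = 1000
        rows = rng.random((n_genes, 23)) < 0.2
        m, g = self.matrix(rows)
        res = coding.lof_enrichment(m, g, alpha=0.05)
        for side in ("EV", "LC"):
            fpr = len(res[side]) / n_genes
            assert fpr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_genes)

    def test_empty_group_errors(self):
        m, g = self.matrix([[True] * 23])
        with pytest.raises(ValueError):
            coding.lof_enrichment(m, g.replace({"LC": "EV"}))
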