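"""EM haplotype frequencies, r2, LD decay, HWE filter and FST."""

import math

import numpy as np
import pandas as pd
import pytest

from ibisgen import io_formats as io
from ibisgen import linkage as ld
from ibisgen import simulate as sim


def phased_population(f_true, n, rng):
    """Draw n diploids from gamete frequencies; return (gt_a, gt_b, sample_f).

    Genotypes are alt-allele dosages; index 0 of f is the ref-ref gamete.
    """
    gam = rng.choice(4, size=(n, 2), p=f_true)
    hap_ref_a = (gam // 2 == 0).astype(int)
    hap_ref_b = (gam % 2 == 0).astype(int)
    gt_a = 2 - hap_ref_a.sum(axis=1)
    gt_b = 2 - hap_ref_b.sum(axis=1)
    sample_f = np.bincount(gam.ravel(), minlength=4) / (2 * n)
    return gt_a, gt_b, sample_f


class TestEm:
    def test_no_double_het_equals_direct_counting(self, rng):
        # construct genotypes with no double heterozygotes
        gt_a = np.array([0, 0, 2, 2, 1, 1, 0, 2])
        gt_b = np.array([0, 2, 0, 2, 0, 2, 1, 1])
        f = ld.em_haplotype_freqs(gt_a, gt_b)
        # direct gamete counting (phase is determined)
        counts = np.zeros(4)
        for a, b in zip(gt_a, gt_b):
            ra, rb = 2 - a, 2 - b
            for _ in range(2):
                ha = 1 if ra >= 1 else 0
                hb = 1 if rb >= 1 else 0
                counts[(1 - ha) * 2 + (1 - hb)] += 1
                ra -= ha
                rb -= hb
        np.testing.assert_allclose(f, counts / counts.sum(), atol=1e-7)

    def test_complete_ld(self):
        gt_a = np.array([0] * 5 + [2] * 5 + [1] * 4)
        gt_b = gt_a.copy()  # only ref-ref and alt-alt gametes
        f = ld.em_haplotype_freqs(gt_a, gt_b)
        assert f[0] + f[3] == pytest.approx(1.0, abs=1e-6)
        assert ld.r_squared(f) == pytest.approx(1.0, abs=1e-6)

    def test_phased_truth_oracle(self, rng):
        """EM on unphased data recovers the sampled gamete frequencies.

        Strong-LD configuration at n = 500 where double-heterozygote phase
        is nearly deterministic, so the genotype-likelihood optimum sits
        within 1e-3 of the realised gamete frequencies.
        """
        f_true = np.array([0.48, 0.02, 0.02, 0.48])
        gt_a, gt_b, sample_f = phased_population(f_true, 500, rng)
        f = ld.em_haplotype_freqs(gt_a, gt_b)
        assert np.max(np.abs(f - sample_f)) < 1e-3

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError):
            ld.em_haplotype_freqs(np.zeros(10, int), np.array([0, 1] * 5))

    def test_log_likelihood_non_decreasing(self, rng):
        f_true = np.array([0.3, 0.2, 0.3, 0.2])
        gt_a, gt_b, _ = phased_population(f_true, 120, rng)
        _, trace = ld.em_haplotype_freqs(gt_a, gt_b, return_trace=True)
        lls = [ld.em_log_likelihood(f, gt_a, gt_b) for f in trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_em_equals_phase_known_counting(self, rng):
        """With true phase supplied, direct counting and EM give the same r2."""
        f_true = np.array([0.5, 0.1, 0.1, 0.3])
        gt_a, gt_b, sample_f = phased_population(f_true, 400, rng)
        r2_em = ld.r_squared(ld.em_haplotype_freqs(gt_a, gt_b))
        r2_direct = ld.r_squared(sample_f)
        assert r2_em == pytest.approx(r2_direct, abs=0.02)


class TestRSquared:
    def test_independent_loci(self):
        f = np.array([0.35, 0.35, 0.15, 0.15])  # f(AB) = pA * pB
        assert ld.r_squared(f) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        assert ld.r_squared(np.array([0.4, 0.1, 0.1, 0.4])) == pytest.approx(0.36)

    def test_complete_association(self):
        assert ld.r_squared(np.array([0.7, 0.0, 0.0, 0.3])) == pytest.approx(1.0)


def hwe_oracle(n_rr, n_het, n_aa):
    """Closed-form conditional probabilities with exact factorials."""
    from fractions import Fraction
    n = n_rr + n_het + n_aa
    n_rare = 2 * min(n_rr, n_aa) + n_het
    if n == 0 or n_rare == 0:
        return 1.0
    def prob(h):
        r_hom = (n_rare - h) // 2
        c_hom = n - h - r_hom
        return Fraction(
            math.factorial(n) * 2**h * math.factorial(n_rare)
            * math.factorial(2 * n - n_rare),
            math.factorial(h) * math.factorial(r_hom) * math.factorial(c_hom)
            * math.factorial(2 * n))
    hets = range(n_rare % 2, n_rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    @pytest.mark.parametrize("counts", [(5, 5, 5), (0, 20, 0), (10, 0, 10),
                                        (7, 3, 1), (0, 1, 12)])
    def test_against_closed_form_oracle(self, counts):
        assert ld.hwe_exact_test(*counts) == pytest.approx(
            hwe_oracle(*counts), abs=1e-9)

    def test_random_tables(self, rng):
        for _ in range(40):
            c = tuple(int(x) for x in rng.integers(0, 15, 3))
            assert ld.hwe_exact_test(*c) == pytest.approx(
                hwe_oracle(*c), abs=1e-9)

    def test_symmetric_in_homozygote_swap(self, rng):
        for _ in range(20):
            a, h, b = (int(x) for x in rng.integers(0, 12, 3))
            assert ld.hwe_exact_test(a, h, b) == pytest.approx(
                ld.hwe_exact_test(b, h, a))


def matrix_from_gt(gt, positions=None, chrom="chr1"):
    gt = np.asarray(gt, np.int8)
    m = gt.shape[0]
    pos = positions if positions is not None else np.arange(1, m + 1) * 100
    return io.GenotypeMatrix(
        [f"s{j}" for j in range(gt.shape[1])], np.array([chrom] * m, object),
        np.asarray(pos), np.array(["A"] * m, object),
        np.array(["G"] * m, object), np.array(["."] * m, object), gt)


class TestSiteFilter:
    def test_each_filter_is_respected(self):
        cfg = ld.LdConfig(min_maf=0.1, min_genotyped_fraction=0.6,
                          hwe_p_cutoff=0.001)
        n = 20
        good = [1] * 8 + [0] * 6 + [2] * 6
        low_maf = [1] + [0] * 19
        low_call = [1, 0, 2, 1] + [-1] * 16
        hwe_fail = [1] * 20  # all het: extreme HWE violation
        gm = matrix_from_gt([good, low_maf, low_call, hwe_fail])
        keep = ld.site_filter(gm, cfg)
        assert list(keep) == [True, False, False, False]


class TestLdDecay:
    def test_single_pair_curve(self, rng):
        f_true = np.array([0.45, 0.05, 0.05, 0.45])
        gam = rng.choice(4, size=(60, 2), p=f_true)
        gt_a = 2 - (gam // 2 == 0).sum(axis=1)
        gt_b = 2 - (gam % 2 == 0).sum(axis=1)
        gm = matrix_from_gt(np.vstack([gt_a, gt_b]), positions=[100, 1600])
        curve = ld.ld_decay_curve(gm, ld.LdConfig(), seed=0)
        row = curve.dropna(subset=["mean_r2"])
        assert len(row) == 1
        expected = ld.r_squared(ld.em_haplotype_freqs(gt_a, gt_b))
        assert row["mean_r2"].iloc[0] == pytest.approx(expected)
        assert row["bin_lo"].iloc[0] == 1000  # distance 1500

    def test_everything_filtered_errors(self):
        gm = matrix_from_gt([[1] + [0] * 19, [0] * 19 + [1]])
        with pytest.raises(ValueError):
            ld.ld_decay_curve(gm, ld.LdConfig(min_maf=0.2))

    def test_decay_with_recombination_coalescent_check(self):
        """Mean r2 declines with distance on coalescent-simulated data."""
        import msprime
        ts = msprime.sim_ancestry(samples=25, population_size=1_000,
                                  sequence_length=100_000,
                                  recombination_rate=5e-8, random_seed=11)
        ts = msprime.sim_mutations(ts, rate=5e-7, random_seed=12)
        gt, pos = [], []
        for var in ts.variants():
            if len(var.alleles) != 2:
                continue
            g = var.genotypes.reshape(-1, 2).sum(axis=1)
            if 0 < g.sum() < 2 * 25 * 2:
                gt.append(g)
                pos.append(int(var.site.position) + 1)
        uniq, last = [], -1
        for i in range(len(pos)):
            if pos[i] > last:
                uniq.append(i)
                last = pos[i]
        # thin evenly across the region so every distance bin holds pairs
        keep = [uniq[j] for j in
                np.linspace(0, len(uniq) - 1, 120).astype(int)]
        gm = matrix_from_gt(np.array([gt[i] for i in keep]),
                            positions=[pos[i] for i in keep])
        cfg = ld.LdConfig(max_distance=100_000, min_maf=0.1)
        bins = np.arange(0, 100_001, 10_000)
        curve = ld.ld_decay_curve(gm, cfg, distance_bins=bins, seed=0)
        cur = curve.dropna(subset=["mean_r2"])
        from scipy.stats import spearmanr
        rho, _ = spearmanr(cur["mid"], cur["mean_r2"])
        assert rho < 0


class TestHalfMax:
    def curve(self, mids, r2):
        return pd.DataFrame({"bin_lo": np.asarray(mids) - 5_000,
                             "bin_hi": np.asarray(mids) + 5_000,
                             "mid": mids, "mean_r2": r2,
                             "n_pairs": 10})

    def test_exact_hit(self):
        c = self.curve([0, 10_000, 20_000], [1.0, 0.5, 0.25])
        assert ld.half_max_distance(c) == 10_000

    def test_interpolation(self):
        c = self.curve([0, 10_000, 20_000], [0.8, 0.6, 0.2])
        assert ld.half_max_distance(c) == pytest.approx(15_000)

    def test_flat_curve_reports_beyond_range(self):
        c = self.curve([0, 10_000, 20_000], [0.4, 0.4, 0.4])
        out = ld.half_max_distance(c, max_distance=300_000)
        assert out == "> 300000"

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            ld.half_max_distance(self.curve([], []))


class TestFst:
    def test_fixed_alternate_alleles(self):
        gt = np.array([[0] * 6 + [2] * 6] * 20)
        gm = matrix_from_gt(gt)
        sub = pd.Series({f"s{j}": ("p1" if j < 6 else "p2") for j in range(12)})
        res = ld.weir_cockerham_fst(gm, sub)
        assert res.theta == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        n = 100
        gt = rng.choice([0, 1, 2], size=(150, 2 * n), p=[0.25, 0.5, 0.25])
        gm = matrix_from_gt(gt)
        sub = pd.Series({f"s{j}": ("p1" if j < n else "p2")
                         for j in range(2 * n)})
        res = ld.weir_cockerham_fst(gm, sub)
        assert abs(res.theta) < 0.02

    def test_duplication_near_invariance(self):
        """Duplicating every individual moves theta only through the O(1/n)
        finite-sample corrections, not through the allele-frequency signal."""
        gm, labels = sim.simulate_island_model(
            4, 40, 0.005, n_loci=60, n_generations=120, seed=8,
            sample_per_deme=20)
        base = ld.weir_cockerham_fst(gm, labels).theta
        gt2 = np.concatenate([gm.gt, gm.gt], axis=1)
        ids2 = gm.sample_ids + [s + "_dup" for s in gm.sample_ids]
        gm2 = io.GenotypeMatrix(ids2, gm.chrom, gm.pos, gm.ref, gm.alt,
                                gm.anc, gt2)
        sub2 = pd.Series({s: labels[s.replace("_dup", "")] for s in ids2})
        dup = ld.weir_cockerham_fst(gm2, sub2).theta
        assert dup == pytest.approx(base, rel=0.05)

    def test_single_population_errors(self, small_wf):
        gm, _ = small_wf
        sub = pd.Series({s: "only" for s in gm.sample_ids})
        with pytest.raises(ValueError):
            ld.weir_cockerham_fst(gm, sub)

    def test_island_model_equilibrium(self):
        """Estimate within 20% of 1/(1 + 4Nm) in a 16-deme island model."""
        d, N, m = 16, 50, 0.005
        gm, labels = sim.simulate_island_model(
            d, N, m, n_loci=100, n_generations=200, seed=5, sample_per_deme=15)
        res = ld.weir_cockerham_fst(gm, labels)
        expected = 1.0 / (1.0 + 4 * N * m)
        assert abs(res.theta - expected) / expected < 0.20
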