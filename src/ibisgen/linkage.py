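"""Two-locus linkage disequilibrium and population structure.

r-squared between SNP pairs is computed from maximum-likelihood two-locus
haplotype frequencies estimated by EM on unphased diploid genotypes; only the
double-heterozygote class has ambiguous phase.  LD decay is summarised as the
mean r2 per distance bin and the distance at which it falls to half its
maximum.  Differentiation among subpopulations uses the Weir-Cockerham
variance-components estimator of FST with ratio-of-averages combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass
class LdConfig:
    """Pair-filtering parameters for the LD scan (Haploview-style)."""

    max_distance: int = 300_000
    min_maf: float = 0.1
    min_genotyped_fraction: float = 0.6
    hwe_p_cutoff: float = 0.001
    max_pairs_per_bin: int = 100_000

    def __post_init__(self) -> None:
        if not (0 <= self.min_maf < 0.5 and 0 < self.min_genotyped_fraction <= 1
                and 0 <= self.hwe_p_cutoff < 1 and self.max_distance > 0):
            raise ValueError("LdConfig parameter out of range")


def default_distance_bins(max_distance: int = 300_000) -> np.ndarray:
    """1-kb bins to 10 kb, then 5-kb bins to max_distance.

    Resolves both a ~1 kb and a ~60 kb half-max regime.
    """
    fine = np.arange(0, 10_000 + 1, 1_000)
    coarse = np.arange(15_000, max_distance + 1, 5_000)
    return np.concatenate([fine, coarse])


# ---------------------------------------------------------------------------
# EM haplotype frequencies

def em_haplotype_freqs(gt_a: np.ndarray, gt_b: np.ndarray,
                       tol: float = 1e-8, max_iter: int = 1000,
                       return_trace: bool = False):
    """ML two-locus gamete frequencies (AB, Ab, aB, ab) from unphased genotypes.

    ``gt_a``/``gt_b`` are alt-allele dosages (0/1/2, -1 missing) at the two
    loci; 'A'/'B' denote the reference alleles.  Starts from linkage
    equilibrium (product of allele frequencies) and iterates the standard EM
    in which only double heterozygotes are re-phased; stops when no frequency
    moves more than ``tol`` or after ``max_iter`` iterations.
    """
    ok = (gt_a >= 0) & (gt_b >= 0)
    a, b = gt_a[ok], gt_b[ok]
    if a.size == 0:
        raise ValueError("no individual genotyped at both loci")
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        raise ValueError("monomorphic locus: r2 undefined")
    n = a.size
    # known gamete counts from the 8 unambiguous genotype classes
    counts = np.zeros(4)  # AB, Ab, aB, ab ; A = ref at locus 1, B = ref at 2
    ref_a, ref_b = 2 - a, 2 - b          # ref-allele dosages
    n_dh = int(np.sum((a == 1) & (b == 1)))
    for i in range(n):
        if a[i] == 1 and b[i] == 1:
            continue
        # each individual contributes two gametes; for non-double-hets the
        # pairing is determined
        if a[i] == 1:
            hapA = [1, 0]                # one gamete carries A, the other a
        else:
            hapA = [ref_a[i] // 2] * 2
        if b[i] == 1:
            hapB = [1, 0]
        else:
            hapB = [ref_b[i] // 2] * 2
        if a[i] == 1 and b[i] != 1:      # phase irrelevant: B alleles equal
            pairs = [(1, hapB[0]), (0, hapB[1])]
        elif b[i] == 1 and a[i] != 1:
            pairs = [(hapA[0], 1), (hapA[1], 0)]
        else:
            pairs = list(zip(hapA, hapB))
        for hA, hB in pairs:
            counts[(1 - hA) * 2 + (1 - hB)] += 1
    pA = ref_a.mean() / 2
    pB = ref_b.mean() / 2
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    total = 2.0 * n
    trace = [f.copy()]
    for _ in range(max_iter):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        denom = coupling + repulsion
        w = 0.5 if denom == 0 else coupling / denom
        new = counts.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= total
        trace.append(new.copy())
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return (f, trace) if return_trace else f


def em_log_likelihood(f: np.ndarray, gt_a: np.ndarray, gt_b: np.ndarray) -> float:
    """Multinomial log-likelihood of unphased two-locus genotypes under ``f``."""
    ok = (gt_a >= 0) & (gt_b >= 0)
    fAB, fAb, faB, fab = np.clip(f, 1e-300, None)
    fr = {(1, 1): fAB, (1, 0): fAb, (0, 1): faB, (0, 0): fab}
    ll = 0.0
    for gA, gB in zip(2 - gt_a[ok], 2 - gt_b[ok]):  # ref dosages
        if gA == 1 and gB == 1:
            p = 2.0 * (fAB * fab + fAb * faB)
        elif gA == 1:
            hB = 1 if gB == 2 else 0
            p = 2.0 * fr[(1, hB)] * fr[(0, hB)]
        elif gB == 1:
            hA = 1 if gA == 2 else 0
            p = 2.0 * fr[(hA, 1)] * fr[(hA, 0)]
        else:
            p = fr[(1 if gA == 2 else 0, 1 if gB == 2 else 0)] ** 2
        ll += np.log(max(p, 1e-300))
    return float(ll)


def r_squared(hap_freqs: np.ndarray) -> float:
    """r2 = D^2 / (pA qA pB qB) from gamete frequencies (AB, Ab, aB, ab)."""
    fAB, fAb, faB, fab = hap_freqs
    pA = fAB + fAb
    pB = fAB + faB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return float("nan")
    D = fAB - pA * pB
    return float(D * D / denom)


# ---------------------------------------------------------------------------
# site filters

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg p (Wigginton-style mid-less enumeration).

    Sums the probabilities of all heterozygote counts, conditional on the
    allele counts, whose probability does not exceed the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n == 0 or rare == 0:
        return 1.0
    # possible het counts share parity with `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(hets.size)
    from scipy.special import gammaln
    common = 2 * n - rare
    for i, h in enumerate(hets):
        r_hom = (rare - h) // 2
        c_hom = n - h - r_hom
        logp[i] = (h * np.log(2) - gammaln(h + 1) - gammaln(r_hom + 1)
                   - gammaln(c_hom + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.where(hets == n_het)[0][0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-9)].sum()))


def site_filter(gm: GenotypeMatrix, config: LdConfig) -> np.ndarray:
    """Boolean mask of sites passing MAF, call-rate and HWE filters."""
    keep = np.zeros(gm.n_sites, dtype=bool)
    for i in range(gm.n_sites):
        g = gm.gt[i]
        ok = g >= 0
        n = int(ok.sum())
        if n == 0 or n / gm.n_samples < config.min_genotyped_fraction:
            continue
        alt = int(g[ok].sum())
        maf = min(alt, 2 * n - alt) / (2 * n)
        if maf < config.min_maf:
            continue
        n_het = int(np.sum(g[ok] == 1))
        n_hom_alt = int(np.sum(g[ok] == 2))
        n_hom_ref = n - n_het - n_hom_alt
        if hwe_exact_test(n_hom_ref, n_het, n_hom_alt) < config.hwe_p_cutoff:
            continue
        keep[i] = True
    return keep


def ld_decay_curve(gm: GenotypeMatrix, config: LdConfig | None = None,
                   distance_bins: np.ndarray | None = None,
                   seed: int | None = None) -> pd.DataFrame:
    """Mean r2 per distance bin over all passing SNP pairs within max_distance.

    Pairs per bin are capped at ``config.max_pairs_per_bin`` by seeded random
    subsampling.  Returns columns bin_lo/bin_hi/mid/mean_r2/n_pairs; bins
    without pairs carry NaN.
    """
    config = config or LdConfig()
    bins = distance_bins if distance_bins is not None \
        else default_distance_bins(config.max_distance)
    rng = np.random.default_rng(seed)
    keep = site_filter(gm, config)
    idx = np.nonzero(keep)[0]
    pair_bins: list[list[float]] = [[] for _ in range(len(bins) - 1)]
    pairs_by_bin: list[list[tuple[int, int]]] = [[] for _ in range(len(bins) - 1)]
    for ii, i in enumerate(idx):
        for j in idx[ii + 1:]:
            if gm.chrom[i] != gm.chrom[j]:
                break
            d = int(gm.pos[j] - gm.pos[i])
            if d > config.max_distance:
                break
            k = int(np.searchsorted(bins, d, side="right") - 1)
            if 0 <= k < len(pair_bins):
                pairs_by_bin[k].append((i, j))
    total_pairs = 0
    for k, plist in enumerate(pairs_by_bin):
        if len(plist) > config.max_pairs_per_bin:
            sel = rng.choice(len(plist), config.max_pairs_per_bin, replace=False)
            plist = [plist[s] for s in sel]
        for i, j in plist:
            try:
                f = em_haplotype_freqs(gm.gt[i].astype(int), gm.gt[j].astype(int))
            except ValueError:
                continue
            r2 = r_squared(f)
            if np.isfinite(r2):
                pair_bins[k].append(r2)
                total_pairs += 1
    if total_pairs == 0:
        raise ValueError("no SNP pairs pass the LD filters")
    rows = []
    for k in range(len(bins) - 1):
        vals = pair_bins[k]
        rows.append((bins[k], bins[k + 1], 0.5 * (bins[k] + bins[k + 1]),
                     float(np.mean(vals)) if vals else np.nan, len(vals)))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mid",
                                       "mean_r2", "n_pairs"])


def half_max_distance(curve: pd.DataFrame, max_distance: int | None = None):
    """Distance at which mean r2 first falls to half its maximum.

    Linear interpolation between adjacent bin midpoints; if the curve never
    reaches half-max, returns the string ``"> <max_distance>"``.
    """
    cur = curve.dropna(subset=["mean_r2"])
    if cur.empty:
        raise ValueError("empty LD curve")
    r2 = cur["mean_r2"].to_numpy()
    mid = cur["mid"].to_numpy()
    peak = r2.max()
    if peak <= 0:
        raise ValueError("curve maximum must be positive")
    half = peak / 2.0
    start = int(np.argmax(r2))
    for k in range(start, len(r2)):
        if r2[k] <= half:
            if k == start or r2[k] == half:
                return float(mid[k])
            x0, x1 = mid[k - 1], mid[k]
            y0, y1 = r2[k - 1], r2[k]
            return float(x0 + (y0 - half) * (x1 - x0) / (y0 - y1))
    limit = max_distance if max_distance is not None else int(cur["bin_hi"].max())
    return f"> {limit}"


# ---------------------------------------------------------------------------
# Weir-Cockerham FST

@dataclass
class FstResult:
    """Per-locus variance components and the ratio-of-averages estimate."""

    per_locus: pd.DataFrame  # columns: site, a, b, c, theta
    theta: float             # sum(a) / sum(a + b + c)


def weir_cockerham_fst(gm: GenotypeMatrix, subpop: pd.Series) -> FstResult:
    """Weir-Cockerham (1984) theta over subpopulations.

    ``subpop`` maps sample id -> subpopulation label.  Per locus the among-
    population (a), among-individual (b) and within-individual (c) variance
    components are computed from allele frequencies and observed
    heterozygosity; the genome-wide estimate is sum(a)/sum(a+b+c).  Loci
    monomorphic overall, or without a genotyped individual in >= 2
    subpopulations, are skipped.
    """
    pops = sorted(subpop.unique())
    if len(pops) < 2:
        raise ValueError("need at least two subpopulations")
    cols = {p: [gm.sample_ids.index(s) for s in subpop.index[subpop == p]]
            for p in pops}
    rows = []
    for i in range(gm.n_sites):
        n_i, p_i, h_i = [], [], []
        for p in pops:
            g = gm.gt[i, cols[p]]
            ok = g >= 0
            n = int(ok.sum())
            if n == 0:
                continue
            n_i.append(n)
            p_i.append(float(g[ok].sum()) / (2 * n))       # alt freq
            h_i.append(float(np.sum(g[ok] == 1)) / n)      # obs het
        r = len(n_i)
        if r < 2:
            continue
        n_i = np.asarray(n_i, float)
        p_i = np.asarray(p_i, float)
        h_i = np.asarray(h_i, float)
        nbar = n_i.mean()
        pbar = np.sum(n_i * p_i) / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        theta_l = a / (a + b + c) if (a + b + c) != 0 else np.nan
        rows.append((i, a, b, c, theta_l))
    if not rows:
        raise ValueError("no informative loci for FST")
    df = pd.DataFrame(rows, columns=["site", "a", "b", "c", "theta"])
    tot = (df["a"] + df["b"] + df["c"]).sum()
    return FstResult(per_locus=df, theta=float(df["a"].sum() / tot))
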