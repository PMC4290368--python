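"""Heterozygosity-based diversity statistics and the windowed fixation scan.

The central scan statistic is pooled heterozygosity over a genomic window,

    Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))**2,

where n_MAJ and n_MIN are, per SNP, the read counts of the most- and
least-abundant allele pooled across individuals; Hp is Z-standardised
genome-wide (ZHp) and strongly negative windows mark runs of allele
fixation.  Also here: per-individual heterozygosity rates, the Watterson
estimator of the population mutation parameter, the Ht/H0 heterozygosity
decay regression, and the two-species neutral mutation-rate calculator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HET, GenotypeMatrix, window_index

DEFAULT_ZHP_THRESHOLD = -2.326  # normal_quantile(0.01), see call_sweep_windows


@dataclass
class ThetaEstimate:
    """Watterson's estimator: theta_s = K / (a * L), a the harmonic number."""

    K: int
    n: int
    L: float
    a: float
    theta_s: float


def individual_heterozygosity(gm: GenotypeMatrix, sample: str,
                              callable_length: float) -> float:
    """Heterozygous-site count for ``sample`` divided by callable length (bp).

    Missing genotypes contribute to neither numerator nor denominator; the
    denominator is the externally supplied callable length, as for
    read-alignment-derived calls.
    """
    if callable_length <= 0:
        raise ValueError("callable_length must be positive")
    j = gm.sample_index(sample)
    return int(np.sum(gm.gt[:, j] == HET)) / callable_length


def watterson_theta(K: int, n: int, L: float) -> ThetaEstimate:
    """Watterson theta_s from K segregating sites in n chromosomes over L bp."""
    if n < 2:
        raise ValueError("Watterson estimator undefined for n < 2")
    if L <= 0 or K < 0:
        raise ValueError("require L > 0 and K >= 0")
    a = float(np.sum(1.0 / np.arange(1, n)))
    return ThetaEstimate(K=K, n=n, L=L, a=a, theta_s=K / (a * L))


def pooled_allele_counts(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP (n_maj, n_min) from genotype counts: 2*hom + het per allele.

    Fallback for inputs without read depths: allele counts across individuals
    stand in for pooled read counts.
    """
    valid = gm.gt >= 0
    alt_count = np.where(valid, gm.gt, 0).sum(axis=1)
    total = 2 * valid.sum(axis=1)
    ref_count = total - alt_count
    n_maj = np.maximum(ref_count, alt_count)
    n_min = np.minimum(ref_count, alt_count)
    return pd.DataFrame({"chrom": gm.chrom, "pos": gm.pos,
                         "n_maj": n_maj, "n_min": n_min})


def hp_from_sums(sum_maj: float, sum_min: float) -> float:
    tot = sum_maj + sum_min
    if tot == 0:
        return float("nan")
    return 2.0 * sum_maj * sum_min / tot**2


def window_hp(counts: pd.DataFrame, windows: pd.DataFrame,
              min_snps: int = 10) -> pd.DataFrame:
    """Pooled heterozygosity per window from per-SNP major/minor counts.

    ``counts`` needs columns chrom/pos (1-based)/n_maj/n_min with
    n_maj >= n_min >= 0; ``windows`` is a tiling from ``make_windows``.
    Counts are summed over the SNPs inside each window and the Hp formula is
    applied once to the sums (not averaged per SNP).  Windows that are
    partial tiles or hold fewer than ``min_snps`` SNPs are flagged and
    excluded from the genome-wide standardisation.
    """
    if (counts["n_min"] > counts["n_maj"]).any() or (counts["n_min"] < 0).any():
        raise ValueError("require n_maj >= n_min >= 0 per SNP")
    out = windows.reset_index(drop=True).copy()
    sum_maj = np.zeros(len(out))
    sum_min = np.zeros(len(out))
    n_snps = np.zeros(len(out), dtype=int)
    by_chrom = {c: sub.sort_values("pos") for c, sub in counts.groupby("chrom")}
    for i, w in out.iterrows():
        sub = by_chrom.get(w["chrom"])
        if sub is None:
            continue
        # SNP at 1-based pos p lies in [start, end) iff start < p <= end
        lo = np.searchsorted(sub["pos"].to_numpy(), w["start"], side="right")
        hi = np.searchsorted(sub["pos"].to_numpy(), w["end"], side="right")
        sum_maj[i] = sub["n_maj"].to_numpy()[lo:hi].sum()
        sum_min[i] = sub["n_min"].to_numpy()[lo:hi].sum()
        n_snps[i] = hi - lo
    out["sum_n_maj"] = sum_maj
    out["sum_n_min"] = sum_min
    out["n_snps"] = n_snps
    out["hp"] = [hp_from_sums(a, b) for a, b in zip(sum_maj, sum_min)]
    out["flagged"] = out["partial"] | (out["n_snps"] < min_snps)
    return out


def zhp_transform(hp_values: np.ndarray) -> np.ndarray:
    """Z-standardise Hp: (Hp - mean) / sd, with the sample (n-1) sd."""
    hp = np.asarray(hp_values, dtype=float)
    if hp.size < 2:
        raise ValueError("need at least 2 windows to standardise")
    sd = hp.std(ddof=1)
    if sd == 0:
        raise ValueError("constant Hp: standard deviation is zero")
    return (hp - hp.mean()) / sd


def add_zhp(hp_windows: pd.DataFrame) -> pd.DataFrame:
    """Attach ZHp computed over unflagged windows; flagged windows get NaN."""
    out = hp_windows.copy()
    ok = ~out["flagged"].to_numpy()
    hp = out.loc[ok, "hp"].to_numpy()
    zhp = np.full(len(out), np.nan)
    zhp[ok] = zhp_transform(hp)
    out["zhp"] = zhp
    return out


def normal_quantile(q: float) -> float:
    """Inverse standard-normal CDF; the scan threshold is normal_quantile(0.01)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    return float(stats.norm.ppf(q))


def call_sweep_windows(hp_windows: pd.DataFrame,
                       threshold: float = DEFAULT_ZHP_THRESHOLD):
    """Windows with ZHp <= threshold, plus a (count, percent) summary.

    Returns ``(swept, summary)`` where summary has keys ``n_swept``,
    ``n_windows`` (unflagged windows entering the scan) and ``percent``
    (1-decimal percentage).
    """
    scanned = hp_windows.loc[~hp_windows["flagged"]]
    swept = scanned.loc[scanned["zhp"] <= threshold]
    n, total = len(swept), len(scanned)
    summary = {"n_swept": n, "n_windows": total,
               "percent": round(100.0 * n / total, 1) if total else float("nan")}
    return swept, summary


def annotate_windows_with_genes(windows: pd.DataFrame,
                                genes: pd.DataFrame) -> dict[tuple, list[str]]:
    """Map each window to the genes overlapping it by >= 1 bp.

    ``genes`` has columns gene_id/chrom/start/end (0-based half-open).  Gene
    lists are ordered by start position.
    """
    out: dict[tuple, list[str]] = {}
    genes = genes.sort_values(["chrom", "start"])
    for _, w in windows.iterrows():
        sel = genes[(genes["chrom"] == w["chrom"])
                    & (genes["start"] < w["end"])
                    & (genes["end"] > w["start"])]
        out[(w["chrom"], int(w["start"]), int(w["end"]))] = list(sel["gene_id"])
    return out


@dataclass
class DecaySeries:
    """Per-individual Ht/H0 ratios against recovery time."""

    time_points: np.ndarray
    het_values: np.ndarray
    h0: float
    ratios: np.ndarray


def ht_h0_series(het_values, time_points,
                 founder_time=None) -> DecaySeries:
    """Normalise per-individual heterozygosity by the founder-cohort mean.

    The founder cohort is every individual carrying the earliest time label
    (or ``founder_time`` if given); its mean heterozygosity is H0.
    """
    t = np.asarray(time_points, dtype=float)
    h = np.asarray(het_values, dtype=float)
    if founder_time is None:
        founder_time = t.min()
    founders = h[t == founder_time]
    if founders.size == 0:
        raise ValueError("founder cohort is empty")
    h0 = float(founders.mean())
    if h0 <= 0:
        raise ValueError("founder-cohort mean heterozygosity must be positive")
    return DecaySeries(t, h, h0, h / h0)


def decay_regression(series: DecaySeries):
    """OLS of Ht/H0 on time: slope, intercept, Pearson r, two-sided p.

    p is from the t distribution with n-2 df; at least 3 points and 2
    distinct times are required.
    """
    t, y = series.time_points, series.ratios
    if t.size < 3:
        raise ValueError("need at least 3 points for the regression")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points")
    res = stats.linregress(t, y)
    return {"slope": res.slope, "intercept": res.intercept,
            "pearson_r": res.rvalue, "p_value": res.pvalue,
            "slope_stderr": res.stderr}


def neutral_mutation_rate(divergence: float, generation_time_years: float,
                          divergence_time_years: float) -> float:
    """Per-site per-generation mutation rate from pairwise divergence.

    mu = divergence * generation_time / (2 * divergence_time): the observed
    divergence accumulates along both lineages since the species split.
    """
    if divergence < 0 or generation_time_years <= 0 or divergence_time_years <= 0:
        raise ValueError("inputs must be positive (divergence >= 0)")
    return divergence * generation_time_years / (2.0 * divergence_time_years)
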