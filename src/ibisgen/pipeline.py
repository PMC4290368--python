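"""End-to-end orchestration over fully synthetic inputs, plus group comparison.

``run_pipeline`` drives one seeded scenario through every analysis stage —
simulate, diversity + theta, Hp/ZHp scan, coding effects, LD + FST, STR
panel — and returns a machine-readable report whose every number comes from
one stage's output.  ``compare_groups`` is the two-group species comparison
(Welch t plus a seeded permutation companion) used for EV-versus-LC style
contrasts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import coding, diversity, io_formats, linkage, simulate, strs

logger = logging.getLogger("ibisgen")


@dataclass
class RunConfig:
    """One pipeline run: a simulation scenario plus per-stage parameters."""

    out_dir: str
    seed: int = 0
    # scenario: founder bottleneck then recovery, at desk scale
    founder_pairs: int = 2
    pedigree_generations: int = 4
    bottleneck_epochs: list[tuple[int, int]] = field(
        default_factory=lambda: [(100, 10), (4, 10), (50, 20)])
    n_initial_sites: int = 300
    genome_length: int = 2_000_000
    recombination_rate: float = 1e-6
    sample_size: int = 8
    window_width: int = 200_000
    zhp_q: float = 0.01
    min_snps_per_window: int = 5
    str_loci: int = 22
    str_mutation_rate: float = 0.005


def compare_groups(values: pd.Series, groups: pd.Series, seed: int = 0,
                   n_permutations: int = 10_000) -> dict:
    """Two-group comparison: means, medians, Welch t, permutation p.

    ``values`` holds one statistic per species; ``groups`` the two group
    labels.  The permutation test permutes labels and compares absolute mean
    differences (two-sided, distribution-free).
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    x = values[groups == labels[0]].dropna().to_numpy()
    y = values[groups == labels[1]].dropna().to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        if abs(pooled[:len(x)].mean() - pooled[len(x):].mean()) >= obs - 1e-15:
            hits += 1
    return {
        "groups": labels,
        "mean": {labels[0]: float(x.mean()), labels[1]: float(y.mean())},
        "median": {labels[0]: float(np.median(x)), labels[1]: float(np.median(y))},
        "mean_difference": float(x.mean() - y.mean()),
        "welch_t": float(t), "welch_p": float(p),
        "permutation_p": (hits + 1) / (n_permutations + 1),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; write tables; return the report.

    Re-running with an identical config and seed reproduces identical
    outputs.  A stage failure raises with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {"seed": config.seed,
                                   "config": {k: v for k, v in vars(config).items()}}}
    stage = "simulate"
    try:
        demo = simulate.DemographyConfig(
            epochs=config.bottleneck_epochs, mu=0.0,
            genome_length=config.genome_length,
            recombination_rate=config.recombination_rate,
            n_initial_sites=config.n_initial_sites, seed=config.seed)
        gm, truth = simulate.simulate_wright_fisher(
            demo, sample_size=config.sample_size)
        io_formats.write_vcf(gm, out / "snps.vcf",
                             {"chr1": config.genome_length})
        ped = simulate.simulate_pedigree(
            config.founder_pairs, config.pedigree_generations, seed=config.seed)
        io_formats.write_pedigree(ped, out / "pedigree.tsv")
        loci = [simulate.StrLocusConfig(f"STR{i}", unit_size=4,
                                        mutation_rate=config.str_mutation_rate)
                for i in range(config.str_loci)]
        str_table, _ = simulate.simulate_str_smm(ped, loci, seed=config.seed + 1)
        io_formats.write_str_table(str_table, out / "str_genotypes.tsv")

        stage = "diversity"
        het = pd.Series({s: diversity.individual_heterozygosity(
            gm, s, config.genome_length) for s in gm.sample_ids}, name="het")
        het.to_csv(out / "heterozygosity.tsv", sep="\t")
        theta = diversity.watterson_theta(
            K=gm.n_sites, n=2 * gm.n_samples, L=config.genome_length)
        report["diversity"] = {
            "stage": "diversity",
            "mean_heterozygosity": float(het.mean()),
            "theta_s": theta.theta_s, "K": theta.K,
        }

        stage = "scan"
        windows = io_formats.make_windows({"chr1": config.genome_length},
                                          width=config.window_width)
        counts = diversity.pooled_allele_counts(gm)
        hw = diversity.window_hp(counts, windows,
                                 min_snps=config.min_snps_per_window)
        hw = diversity.add_zhp(hw)
        io_formats.write_windows_bed(hw, out / "hp_windows.bed")
        thr = diversity.normal_quantile(config.zhp_q)
        swept, summary = diversity.call_sweep_windows(hw, threshold=thr)
        report["scan"] = {"stage": "scan", "threshold": thr, **summary}

        stage = "effects"
        seqs, models, implants = simulate.generate_cds_landscape(
            genome_length=300_000, gene_count=12, seed=config.seed,
            n_synonymous=100)
        eff_gm = simulate.implants_to_genotype_matrix(implants)
        effects = coding.classify_sites(eff_gm, models, seqs)
        effects.to_csv(out / "coding_effects.tsv", sep="\t", index=False)
        nss = coding.ns_s_per_sample(eff_gm, effects)
        report["effects"] = {"stage": "effects",
                             "ns_s": {k: float(v) for k, v in nss.items()},
                             "n_sites": int(len(effects))}

        stage = "linkage"
        sub = pd.Series({s: f"pop{i % 2}" for i, s in enumerate(gm.sample_ids)})
        fst = linkage.weir_cockerham_fst(gm, sub)
        report["linkage"] = {"stage": "linkage", "fst": fst.theta,
                             "n_loci": int(len(fst.per_locus))}

        stage = "str_panel"
        summaries = [strs.str_locus_summary(str_table, l)
                     for l in str_table.locus_ids]
        pms = [strs.match_probability(str_table, l) for l in str_table.locus_ids]
        pes = [strs.exclusion_probability(s.allele_freqs) for s in summaries]
        report["str_panel"] = {
            "stage": "str_panel",
            "mean_expected_het": float(np.mean(
                [s.expected_heterozygosity for s in summaries])),
            "combined_pd": strs.combined_discrimination_power(pms),
            "combined_pe": strs.combined_exclusion_probability(pes),
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
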