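"""Coding-variant load: effects, NS/S, DAF spectra and LoF enrichment.

Classifies the implanted variants from 01 against the coding landscape,
verifies the NS/S implant ratio comes back exactly, builds the derived-
allele-frequency spectrum, and runs the per-gene loss-of-function Fisher
contrast on the published-style 8-vs-15 carnivore grouping, including the
3-of-8 vs 0-of-15 single-gene pattern.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ibisgen import coding, pipeline
from ibisgen import io_formats as io
from ibisgen import simulate as sim

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

# Published per-species NS/S for the paired comparison (endangered/vulnerable
# birds against their least-concern relatives).
NS_S_EV = [0.69, 0.84, 0.63, 0.84, 0.80]
NS_S_LC = [0.41, 0.57, 0.32, 0.58]


def main() -> None:
    models = io.read_cds_table(ROOT / "data" / "cds_models.tsv")
    implants = pd.read_csv(ROOT / "data" / "implanted_variants.tsv", sep="\t")
    with open(ROOT / "data" / "coding_genome.fa") as fh:
        fh.readline()
        seq = "".join(line.strip() for line in fh)
    gm = sim.implants_to_genotype_matrix(implants)
    effects = coding.classify_sites(gm, models, {"chr1": seq})
    effects.to_csv(ROOT / "coding_effects.tsv", sep="\t", index=False)

    truth = implants.set_index(implants["pos0"] + 1)["true_effect"]
    pred = effects.set_index("pos")["effect"]
    match = (pred.reindex(truth.index) == truth).mean()
    nss = coding.ns_s_per_sample(gm, effects)
    print(f"effect classification: {100 * match:.1f}% of implanted labels "
          f"recovered; NS/S = {nss['ind0']:.2f} (implanted 0.69)")

    spec = coding.daf_spectrum(gm, effects)
    spec.to_csv(ROOT / "daf_spectrum.tsv", sep="\t")
    print(f"DAF spectrum over {len(effects)} sites "
          f"({spec.attrs['n_excluded']} without ancestral state excluded)")

    p = coding.fisher_exact_2x2(3, 5, 0, 15)
    print(f"single-gene LoF contrast (3/8 vs 0/15): one-sided "
          f"p = {p['one_sided_greater']:.4f}")

    rng = np.random.default_rng(SEED)
    lof = pd.DataFrame(rng.random((500, 23)) < 0.15,
                       columns=[f"ev{i}" for i in range(8)]
                       + [f"lc{i}" for i in range(15)])
    lof.iloc[:12, :8] = True  # twelve genes inactivated across the EV group
    groups = pd.Series({c: ("EV" if c.startswith("ev") else "LC")
                        for c in lof.columns})
    res = coding.lof_enrichment(lof, groups, alpha=0.05)
    res["all"].to_csv(ROOT / "lof_enrichment.tsv", sep="\t", index=False)
    print(f"LoF enrichment: {len(res['EV'])} genes biased toward EV, "
          f"{len(res['LC'])} toward LC (one-sided Fisher, alpha 0.05)")

    vals = pd.Series(NS_S_EV + NS_S_LC,
                     index=[f"sp{i}" for i in range(9)])
    grp = pd.Series(["EV"] * 5 + ["LC"] * 4, index=vals.index)
    cmp = pipeline.compare_groups(vals, grp, seed=SEED)
    print(f"published NS/S contrast: EV median {cmp['median']['EV']:.2f} vs "
          f"LC median {cmp['median']['LC']:.2f}; Welch p = "
          f"{cmp['welch_p']:.3f}, permutation p = {cmp['permutation_p']:.3f}")


if __name__ == "__main__":
    main()
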