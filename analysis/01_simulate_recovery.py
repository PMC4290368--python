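"""Simulate the recovery scenario every downstream analysis consumes.

A diploid population crashes from N = 100 to two breeding pairs (N = 4) and
recovers to N = 50; eight survivors are sampled.  Alongside the SNP matrix,
a four-generation managed-breeding pedigree is grown from two founder pairs
and 22 tetranucleotide STR loci plus a W-linked sex marker are transmitted
through it.  Outputs land in results/data/ as VCF and TSV.
"""

from pathlib import Path

from ibisgen import io_formats as io
from ibisgen import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    demo = sim.DemographyConfig(
        epochs=[(100, 10), (4, 10), (50, 20)], mu=0.0,
        genome_length=2_000_000, recombination_rate=1e-6,
        n_initial_sites=400, seed=SEED)
    gm, truth = sim.simulate_wright_fisher(demo, sample_size=8)
    io.write_vcf(gm, OUT / "snps.vcf", {"chr1": demo.genome_length})
    print(f"wrote {gm.n_sites} SNP sites x {gm.n_samples} samples "
          f"(final-generation het {truth.het_trajectory[-1]:.3f}, "
          f"founders {truth.het_trajectory[0]:.3f})")

    ped = sim.simulate_pedigree(founder_pairs=2, generations=4, seed=SEED)
    io.write_pedigree(ped, OUT / "pedigree.tsv")
    print(f"pedigree: {len(ped.table)} individuals over "
          f"{ped.table['time'].max() + 1} generations")

    loci = [sim.StrLocusConfig(f"STR{i:02d}", unit_size=4,
                               mutation_rate=0.005,
                               founder_alleles=tuple(range(8, 16)))
            for i in range(22)]
    table, _ = sim.simulate_str_smm(ped, loci, seed=SEED + 1)
    io.write_str_table(table, OUT / "str_genotypes.tsv")
    print(f"STR table: {len(table.sample_ids)} x {len(table.locus_ids)} loci")

    seqs, models, implants = sim.generate_cds_landscape(
        genome_length=300_000, gene_count=12, seed=SEED,
        n_synonymous=100, ns_s_ratio=0.69)
    io.write_cds_table(models, OUT / "cds_models.tsv")
    implants.to_csv(OUT / "implanted_variants.tsv", sep="\t", index=False)
    with open(OUT / "coding_genome.fa", "w") as fh:
        fh.write(">chr1\n")
        seq = seqs["chr1"]
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")
    print(f"coding landscape: {len(models)} genes, {len(implants)} implants")


if __name__ == "__main__":
    main()
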