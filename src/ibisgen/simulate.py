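"""Forward-in-time generators for every input the pipeline consumes.

Everything here is built around the recovery narrative of a species rescued
from a handful of founders: a diploid Wright-Fisher population under a
piecewise-constant size trajectory (severe bottleneck included), an island
model for subdivided populations, stepwise-mutating STR loci transmitted
through explicit pedigrees, managed-breeding pedigrees grown from founder
pairs, and a coding landscape with variants implanted at known
synonymous/missense/stop-gain labels.  All generators are deterministic
under their seed and return the ground truth alongside the observable data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CdsModel, GenotypeMatrix, Pedigree, StrGenotypeTable

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class DemographyConfig:
    """Piecewise-constant diploid population sizes driving the simulator.

    ``epochs`` is an ordered list of (N, duration-in-generations) pairs,
    earliest first.  ``n_initial_sites`` standing biallelic sites start at
    frequency ``initial_freq`` in the founders (their ancestral state is the
    reference allele).  ``mu`` is the per-site per-generation mutation rate
    on a genome of ``genome_length`` bp under infinite sites;
    ``recombination_rate`` is per bp per generation (single crossover per
    gamete at most).
    """

    epochs: list[tuple[int, int]]
    mu: float = 0.0
    genome_length: int = 1_000_000
    recombination_rate: float = 0.0
    n_initial_sites: int = 200
    initial_freq: float = 0.5
    allow_selfing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        for N, dur in self.epochs:
            if N < 2:
                raise ValueError("all N must be >= 2")
            if dur < 0:
                raise ValueError("durations must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted next to the observable tables."""

    positions: np.ndarray | None = None
    haplotypes: np.ndarray | None = None     # (2N, S) final-generation phase
    ancestral: np.ndarray | None = None
    het_trajectory: np.ndarray | None = None  # mean observed het per generation
    pedigree: Pedigree | None = None
    str_mutation_events: list | None = None
    effect_labels: pd.DataFrame | None = None


def _emit_genotype_matrix(hap: np.ndarray, positions: np.ndarray,
                          sample_idx: np.ndarray, chrom: str = "chr1",
                          rng: np.random.Generator | None = None,
                          sample_prefix: str = "ind") -> GenotypeMatrix:
    """Genotypes of selected diploid individuals from a (2N, S) haplotype array."""
    order = np.argsort(positions)
    positions = positions[order]
    hap = hap[:, order]
    gt = (hap[2 * sample_idx] + hap[2 * sample_idx + 1]).T.astype(np.int8)
    m = len(positions)
    rng = rng or np.random.default_rng(0)
    ref = _BASES[rng.integers(0, 4, m)]
    alt = np.array([_BASES[(list(_BASES).index(r) + 1) % 4] for r in ref])
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(len(sample_idx))],
        chrom=np.array([chrom] * m, object), pos=positions.astype(np.int64),
        ref=ref.astype(object), alt=alt.astype(object),
        anc=ref.astype(object).copy(),  # ancestral = founding (reference) state
        gt=gt)


def simulate_wright_fisher(config: DemographyConfig, sample_size: int | None = None):
    """Forward diploid Wright-Fisher under the configured size trajectory.

    Each offspring draws two parents uniformly and independently — the
    classic monoecious model, under which mean heterozygosity decays exactly
    as H0 * (1 - 1/(2N))**t; with ``allow_selfing=False`` the two parents
    are distinct, which adds a one-generation transient and shifts the
    effective size to about N + 1/2.  Each gamete is one parental haplotype,
    or a single-crossover recombinant with probability
    ``recombination_rate * genome_length``; new mutations arise at
    Poisson(mu * L) fresh positions per gamete (infinite sites).  Returns
    ``(GenotypeMatrix, SimTruth)`` with the final generation sampled; the
    truth carries the full phase, ancestral states, and the per-generation
    mean observed heterozygosity.
    """
    rng = np.random.default_rng(config.seed)
    N0 = config.epochs[0][0]
    S = config.n_initial_sites
    L = config.genome_length
    positions = np.sort(rng.choice(np.arange(1, L + 1), size=S, replace=False)
                        ).astype(np.int64)
    hap = (rng.random((2 * N0, S)) < config.initial_freq).astype(np.int8)
    het_traj = [float(np.mean(hap[0::2] != hap[1::2]))] if S else [0.0]
    p_rec = min(1.0, config.recombination_rate * L)

    def make_gamete(parent: int, hap: np.ndarray) -> np.ndarray:
        h1, h2 = hap[2 * parent], hap[2 * parent + 1]
        if rng.random() < 0.5:
            h1, h2 = h2, h1
        if p_rec > 0 and rng.random() < p_rec:
            bp = rng.integers(1, L + 1)
            left = positions < bp
            g = np.where(left, h1, h2)
        else:
            g = h1.copy()
        return g

    for N, duration in config.epochs:
        for _ in range(duration):
            N_prev = hap.shape[0] // 2
            new = np.empty((2 * N, hap.shape[1]), dtype=np.int8)
            new_muts: list[tuple[int, int]] = []  # (gamete row, position)
            for child in range(N):
                mother = rng.integers(N_prev)
                if config.allow_selfing:
                    father = rng.integers(N_prev)
                else:
                    father = rng.integers(N_prev - 1)
                    if father >= mother:
                        father += 1
                new[2 * child] = make_gamete(mother, hap)
                new[2 * child + 1] = make_gamete(father, hap)
                if config.mu > 0:
                    for row in (2 * child, 2 * child + 1):
                        k = rng.poisson(config.mu * L)
                        for _ in range(k):
                            new_muts.append((row, int(rng.integers(1, L + 1))))
            hap = new
            if new_muts:
                existing = set(positions.tolist())
                add_pos, add_cols = [], []
                for row, pos in new_muts:
                    while pos in existing:
                        pos = int(rng.integers(1, L + 1))
                    existing.add(pos)
                    col = np.zeros(hap.shape[0], dtype=np.int8)
                    col[row] = 1
                    add_pos.append(pos)
                    add_cols.append(col)
                positions = np.concatenate([positions, np.array(add_pos, np.int64)])
                hap = np.concatenate([hap, np.stack(add_cols, axis=1)], axis=1)
            het_traj.append(float(np.mean(hap[0::2] != hap[1::2]))
                            if hap.shape[1] else 0.0)

    N_final = hap.shape[0] // 2
    k = sample_size if sample_size is not None else N_final
    if k > N_final:
        raise ValueError(f"sample size {k} exceeds population size {N_final}")
    sample_idx = rng.choice(N_final, size=k, replace=False)
    sample_idx.sort()
    gm = _emit_genotype_matrix(hap, positions, sample_idx,
                               rng=np.random.default_rng(config.seed + 1))
    truth = SimTruth(positions=positions, haplotypes=hap,
                     ancestral=np.zeros(len(positions), np.int8),
                     het_trajectory=np.array(het_traj))
    return gm, truth


def simulate_island_model(n_demes: int, deme_size: int, migration_rate: float,
                          n_loci: int, n_generations: int, seed: int = 0,
                          sample_per_deme: int | None = None):
    """Finite island model with unlinked biallelic loci, no mutation.

    Each gamete's parent is drawn from the home deme with probability
    1 - m, otherwise from a uniformly chosen other deme; loci assort freely.
    Loci start at frequency 0.5 everywhere.  Returns ``(GenotypeMatrix,
    labels)`` where labels maps sample id -> deme name.  At equilibrium the
    expected differentiation is about 1 / (1 + 4*N*m*(d/(d-1))**2).
    """
    rng = np.random.default_rng(seed)
    d, N, S = n_demes, deme_size, n_loci
    hap = (rng.random((d, 2 * N, S)) < 0.5).astype(np.int8)
    for _ in range(n_generations):
        new = np.empty_like(hap)
        for dem in range(d):
            for g in range(2 * N):
                if d > 1 and rng.random() < migration_rate:
                    src = rng.integers(d - 1)
                    if src >= dem:
                        src += 1
                else:
                    src = dem
                parent = rng.integers(N)
                # free recombination: per-locus random pick of the two
                # parental alleles
                pick = rng.integers(0, 2, S)
                new[dem, g] = hap[src, 2 * parent + pick, np.arange(S)]
        hap = new
    k = sample_per_deme if sample_per_deme is not None else N
    sample_ids, rows, labels = [], [], {}
    for dem in range(d):
        idx = rng.choice(N, size=k, replace=False)
        for i in idx:
            sid = f"d{dem}_i{i}"
            sample_ids.append(sid)
            labels[sid] = f"deme{dem}"
            rows.append(hap[dem, 2 * i] + hap[dem, 2 * i + 1])
    gt = np.array(rows, dtype=np.int8).T
    positions = np.arange(1, S + 1, dtype=np.int64) * 1000
    ref = np.array(["A"] * S, object)
    alt = np.array(["C"] * S, object)
    gm = GenotypeMatrix(sample_ids, np.array(["chr1"] * S, object), positions,
                        ref, alt, np.array(["."] * S, object), gt)
    return gm, pd.Series(labels)


# ---------------------------------------------------------------------------
# pedigrees

def simulate_pedigree(founder_pairs: int, generations: int,
                      offspring_per_pair: int = 2, mode: str = "monogamous",
                      seed: int = 0,
                      founder_sexes: list[str] | None = None) -> Pedigree:
    """Grow a pedigree from founder breeding pairs.

    ``monogamous`` mode emulates managed breeding: every living individual
    joins at most one pair per generation (all accumulated individuals stay
    in the breeding pool, so with 2 offspring per pair the census doubles
    each season); offspring sexes alternate ZZ/ZW deterministically so pairs
    always form.  ``random`` mode draws sexes and pair counts at random.  A
    generation producing no offspring yields an extinction result
    (``Pedigree.extinct``), not an exception.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = itertools.count()
    males, females = [], []
    if founder_sexes is not None:
        for sex in founder_sexes:
            iid = f"F{next(counter)}"
            rows.append((iid, None, None, sex, 0))
            (males if sex == "ZZ" else females).append(iid)
    else:
        if founder_pairs < 1:
            raise ValueError("need at least one founder pair")
        for _ in range(founder_pairs):
            for sex, pool in (("ZZ", males), ("ZW", females)):
                iid = f"F{next(counter)}"
                rows.append((iid, None, None, sex, 0))
                pool.append(iid)
    extinct = False
    flip = 0
    for gen in range(1, generations + 1):
        pairs = list(zip(males, females))
        if mode == "random":
            rng.shuffle(males)
            rng.shuffle(females)
            pairs = list(zip(males, females))
        if not pairs:
            extinct = True
            break
        produced = 0
        for sire, dam in pairs:
            n_off = (offspring_per_pair if mode == "monogamous"
                     else rng.poisson(offspring_per_pair))
            for _ in range(n_off):
                iid = f"G{gen}_{next(counter)}"
                if mode == "monogamous":
                    sex = "ZZ" if flip % 2 == 0 else "ZW"
                    flip += 1
                else:
                    sex = "ZZ" if rng.random() < 0.5 else "ZW"
                rows.append((iid, sire, dam, sex, gen))
                (males if sex == "ZZ" else females).append(iid)
                produced += 1
        if produced == 0:
            extinct = True
            break
    df = pd.DataFrame(rows, columns=["individual", "sire", "dam", "sex", "time"])
    return Pedigree(df, extinct=extinct)


# ---------------------------------------------------------------------------
# STR transmission under the stepwise mutation model

@dataclass
class StrLocusConfig:
    locus_id: str
    unit_size: int
    mutation_rate: float = 0.0
    founder_alleles: tuple[int, ...] = (8, 9, 10, 11, 12)

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 0.1:
            raise ValueError("STR mutation rate must lie in [0, 0.1]")


def simulate_str_smm(pedigree: Pedigree, loci: list[StrLocusConfig],
                     seed: int = 0):
    """Transmit STR alleles down a pedigree under the symmetric SMM.

    Founders draw each allele uniformly from the locus's founder set; every
    meiosis passes one random parental allele, mutated +-1 repeat (equal
    probability each way) with the locus's mutation rate.  An allele that
    would reach 0 repeats is reflected back to +1.  Returns
    ``(StrGenotypeTable, SimTruth)``; the truth lists every mutation event as
    (individual, locus, parent, from_allele, to_allele).
    """
    rng = np.random.default_rng(seed)
    order = pedigree.table.sort_values("time")
    genotypes: dict[str, dict[str, tuple[int, int]]] = {}
    events: list[tuple] = []

    def transmit(parent_id: str | None, locus: StrLocusConfig, child: str):
        if parent_id is None or parent_id not in genotypes:
            return int(rng.choice(locus.founder_alleles))
        a = genotypes[parent_id][locus.locus_id][rng.integers(2)]
        if locus.mutation_rate > 0 and rng.random() < locus.mutation_rate:
            step = 1 if rng.random() < 0.5 else -1
            b = a + step
            if b <= 0:
                b = a + 1  # reflect away from zero repeats
            events.append((child, locus.locus_id, parent_id, a, b))
            return b
        return a

    for _, row in order.iterrows():
        iid, sire, dam = row["individual"], row["sire"], row["dam"]
        sire = None if pd.isna(sire) else sire
        dam = None if pd.isna(dam) else dam
        genotypes[iid] = {
            loc.locus_id: (transmit(sire, loc, iid), transmit(dam, loc, iid))
            for loc in loci
        }
    sample_ids = list(order["individual"])
    table = StrGenotypeTable(
        sample_ids=sample_ids,
        locus_ids=[l.locus_id for l in loci],
        unit_size={l.locus_id: l.unit_size for l in loci},
        alleles=[[genotypes[s][l.locus_id] for l in loci] for s in sample_ids])
    return table, SimTruth(pedigree=pedigree, str_mutation_events=events)


def w_marker_table(pedigree: Pedigree, z_length: int = 200,
                   w_insertion: int = 31) -> dict[str, tuple[int, int]]:
    """Fragment lengths at the W-linked sex marker, from recorded sexes.

    Females (ZW) carry the Z fragment and the W fragment (+31 bp insertion);
    males (ZZ) carry two Z fragments.
    """
    out = {}
    for _, row in pedigree.table.iterrows():
        if row["sex"] == "ZW":
            out[row["individual"]] = (z_length, z_length + w_insertion)
        elif row["sex"] == "ZZ":
            out[row["individual"]] = (z_length, z_length)
        else:
            out[row["individual"]] = None
    return out


# ---------------------------------------------------------------------------
# coding landscape with implanted, effect-labelled variants

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE = [c for c in _CODONS if c not in _STOPS]
_AA = {}
for _c in _CODONS:
    from Bio.Seq import Seq as _Seq
    _AA[_c] = "*" if _c in _STOPS else str(_Seq(_c).translate())


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def generate_cds_landscape(genome_length: int, gene_count: int, seed: int = 0,
                           n_synonymous: int = 50, ns_s_ratio: float = 0.69,
                           codons_per_gene: tuple[int, int] = (60, 200)):
    """Random genome with valid multi-exon ORFs and effect-labelled implants.

    Genes are placed without overlap on both strands with 1-5 exons each; a
    gene's CDS starts with ATG, has no internal stop and ends with a stop
    codon.  Variants are implanted at known labels: ``n_synonymous``
    synonymous changes plus ``round(ns_s_ratio * n_synonymous)`` missense or
    stop-gain changes.  The implanted label is derived by codon arithmetic
    on the coding sequence itself, independently of the genome-coordinate
    classifier that consumes the output.  Returns ``(sequences, models,
    implants)`` where implants has columns chrom/pos0/ref/alt/true_effect/
    gene_id.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    seq = list(rng.choice(list("ACGT"), genome_length))
    models: list[CdsModel] = []
    cds_seqs: dict[str, str] = {}
    cursor = 100
    for g in range(gene_count):
        n_codons = int(rng.integers(*codons_per_gene))
        body = ["ATG"] + [str(rng.choice(_SENSE)) for _ in range(n_codons - 2)]
        body.append(str(rng.choice(sorted(_STOPS))))
        cds = "".join(body)
        n_exons = int(rng.integers(1, 6))
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
        introns = [int(rng.integers(20, 80)) for _ in range(n_exons - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        genome_pieces = pieces if strand == "+" else \
            [_revcomp(p) for p in reversed(pieces)]
        block = sum(map(len, pieces)) + sum(introns)
        if cursor + block + 100 > genome_length:
            raise ValueError("genes do not fit in the genome; increase length")
        exons = []
        pos = cursor
        for i, piece in enumerate(genome_pieces):
            exons.append((pos, pos + len(piece)))
            seq[pos:pos + len(piece)] = list(piece)
            pos += len(piece)
            if i < len(introns):
                pos += introns[i]
        cursor = pos + int(rng.integers(50, 150))
        gid = f"gene{g}"
        models.append(CdsModel(gid, chrom, strand, exons, phase=0))
        cds_seqs[gid] = cds
    sequence = "".join(seq)

    n_ns = int(round(ns_s_ratio * n_synonymous))
    targets = ["synonymous"] * n_synonymous + ["nonsynonymous"] * n_ns
    implants, used = [], set()
    for want in targets:
        for _ in range(10_000):
            m = models[rng.integers(len(models))]
            cds = cds_seqs[m.gene_id]
            ci = int(rng.integers(1, len(cds) // 3 - 1))  # skip start & stop codons
            within = int(rng.integers(3))
            codon = cds[3 * ci:3 * ci + 3]
            ref_b = codon[within]
            alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
            alt_codon = codon[:within] + alt_b + codon[within + 1:]
            if _AA[alt_codon] == _AA[codon]:
                label = "synonymous"
            elif _AA[alt_codon] == "*":
                label = "stop_gain"
            else:
                label = "missense"
            ok = (label == "synonymous") if want == "synonymous" \
                else (label in ("missense", "stop_gain"))
            if not ok:
                continue
            # coding index -> genome position
            offsets: list[int] = []
            for a, b in m.exons:
                offsets.extend(range(a, b))
            if m.strand == "-":
                offsets = offsets[::-1]
            pos0 = offsets[3 * ci + within]
            if (m.chrom, pos0) in used:
                continue
            used.add((m.chrom, pos0))
            ref_g = ref_b if m.strand == "+" else _COMP[ref_b]
            alt_g = alt_b if m.strand == "+" else _COMP[alt_b]
            implants.append((m.chrom, pos0, ref_g, alt_g, label, m.gene_id))
            break
        else:
            raise RuntimeError("could not place an implant of the requested class")
    implants_df = pd.DataFrame(
        implants, columns=["chrom", "pos0", "ref", "alt", "true_effect", "gene_id"])
    return {chrom: sequence}, models, implants_df


def implants_to_genotype_matrix(implants: pd.DataFrame,
                                sample_id: str = "ind0") -> GenotypeMatrix:
    """One-sample matrix heterozygous at every implanted site."""
    df = implants.sort_values("pos0")
    m = len(df)
    return GenotypeMatrix(
        sample_ids=[sample_id],
        chrom=df["chrom"].to_numpy(object),
        pos=(df["pos0"].to_numpy() + 1).astype(np.int64),
        ref=df["ref"].to_numpy(object), alt=df["alt"].to_numpy(object),
        anc=df["ref"].to_numpy(object).copy(),
        gt=np.ones((m, 1), dtype=np.int8))
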