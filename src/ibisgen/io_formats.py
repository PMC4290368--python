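"""Readers, writers and container types for every external table the pipeline touches.

Internal coordinates are 0-based half-open throughout; VCF input/output keeps
its native 1-based positions in ``GenotypeMatrix.pos``.  The single conversion
point is :func:`window_index` / :func:`make_windows`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("ibisgen")

# genotype codes used in GenotypeMatrix.gt
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for n samples at m sites.

    ``pos`` is 1-based (as printed in a VCF).  ``gt`` is an (m, n) int8 array
    with codes 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.  ``anc`` holds
    the ancestral base where known, '.' otherwise.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    anc: np.ndarray
    gt: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.pos)
        for name in ("chrom", "ref", "alt", "anc"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if len(arr) != m:
                raise ValueError(f"{name} has length {len(arr)}, expected {m}")
            setattr(self, name, arr)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (m, len(self.sample_ids)):
            raise ValueError(
                f"gt shape {self.gt.shape} != ({m}, {len(self.sample_ids)})"
            )
        if np.any(self.ref == self.alt):
            raise ValueError("alt must differ from ref at every site")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        bad = (self.anc != ".") & (self.anc != self.ref) & (self.anc != self.alt)
        if np.any(bad):
            raise ValueError("ancestral allele must be ref, alt or '.'")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None


@dataclass(frozen=True)
class WindowSpec:
    """One genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} <= start {self.start}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CdsModel:
    """Coding-sequence model: ordered exon intervals on the coding strand.

    ``exons`` are 0-based half-open genome intervals, stored in genome order;
    for a minus-strand gene the 5'->3' coding order is the reverse.  ``phase``
    is the number of bases of the first codon missing at the 5' end (0 for a
    complete CDS).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (a, b), (c, d) in zip(ex, ex[1:]):
            if c < b:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for a, b in ex:
            if b <= a:
                raise ValueError(f"{self.gene_id}: empty exon [{a},{b})")
        self.exons = ex

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class StrGenotypeTable:
    """Diploid repeat-count alleles per individual per STR locus.

    ``alleles[i][j]`` is an unordered ``(a1, a2)`` pair of positive ints or
    ``None`` for missing.  Missingness is explicit — never encoded as 0.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    unit_size: dict[str, int]
    alleles: list[list[tuple[int, int] | None]]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample id")
        for loc in self.locus_ids:
            u = self.unit_size.get(loc)
            if u not in (2, 3, 4, 5, 6):
                raise ValueError(f"locus {loc}: unit size {u} not in 2..6")
        for i, row in enumerate(self.alleles):
            if len(row) != len(self.locus_ids):
                raise ValueError(f"row {i} has {len(row)} entries")
            for pair in row:
                if pair is not None and (pair[0] <= 0 or pair[1] <= 0):
                    raise ValueError("allele values must be positive")

    def locus_column(self, locus: str) -> list[tuple[int, int] | None]:
        j = self.locus_ids.index(locus)
        return [row[j] for row in self.alleles]


@dataclass
class Pedigree:
    """Pedigree table: individual, sire, dam, sex (ZZ/ZW/unknown), time label."""

    table: pd.DataFrame  # columns: individual, sire, dam, sex, time
    extinct: bool = False

    def __post_init__(self) -> None:
        req = {"individual", "sire", "dam", "sex", "time"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"pedigree table needs columns {sorted(req)}")
        if self.table["individual"].duplicated().any():
            raise ValueError("duplicated individual id")
        self._check_acyclic()
        known = self.table.set_index("individual")["sex"]
        for _, row in self.table.iterrows():
            s, d = row["sire"], row["dam"]
            if pd.notna(s) and s in known.index and known[s] == "ZW":
                raise ValueError(f"sire {s} recorded as ZW")
            if pd.notna(d) and d in known.index and known[d] == "ZZ":
                raise ValueError(f"dam {d} recorded as ZZ")

    def _check_acyclic(self) -> None:
        parents = {
            r["individual"]: [p for p in (r["sire"], r["dam"]) if pd.notna(p)]
            for _, r in self.table.iterrows()
        }
        state: dict[str, int] = {}

        def visit(v: str) -> None:
            state[v] = 1
            for p in parents.get(v, []):
                if state.get(p) == 1:
                    raise ValueError(f"pedigree cycle through {v}")
                if p not in state:
                    visit(p)
            state[v] = 2

        for v in parents:
            if v not in state:
                visit(v)

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["individual"] == individual]
        if row.empty:
            raise KeyError(f"unknown individual {individual!r}")
        s, d = row.iloc[0]["sire"], row.iloc[0]["dam"]
        return (None if pd.isna(s) else s, None if pd.isna(d) else d)


# ---------------------------------------------------------------------------
# window arithmetic (the single 1-based -> 0-based conversion point)

def window_index(pos_1based: int, width: int) -> int:
    """Tile index of a 1-based VCF position under ``width``-bp tiling."""
    return (pos_1based - 1) // width


def make_windows(chrom_lengths: dict[str, int], width: int = 500_000,
                 step: int | None = None) -> pd.DataFrame:
    """Tile each chromosome into windows; columns chrom/start/end/partial.

    By default the windows are non-overlapping ``width``-bp tiles (the mode in
    which a ~1.26-Gb genome yields ~2,514 windows of 500 kb).  Passing
    ``step < width`` gives true sliding windows.  A trailing window shorter
    than ``width`` is kept but flagged ``partial``; windowed statistics skip
    flagged windows by default.
    """
    step = width if step is None else step
    if step <= 0 or width <= 0:
        raise ValueError("width and step must be positive")
    rows = []
    for chrom, L in chrom_lengths.items():
        start = 0
        while start < L:
            end = min(start + width, L)
            rows.append((chrom, start, end, end - start < width))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


# ---------------------------------------------------------------------------
# VCF

def read_vcf_subset(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs with a GT field from a minimal VCF.

    Multiallelic and indel records are skipped (count logged).  The ancestral
    allele is taken from an ``AA`` INFO tag when present.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        chrom, pos, ref, alt, anc, rows = [], [], [], [], [], []
        skipped = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            r, a = rec.ref, rec.alts[0]
            if len(r) != 1 or len(a) != 1 or a == "*":
                skipped += 1
                continue
            if "GT" not in rec.format:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} has no GT format field"
                )
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for j, s in enumerate(samples):
                g = rec.samples[s]["GT"]
                if g is None or any(x is None for x in g):
                    continue
                row[j] = int(sum(g))
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(r)
            alt.append(a)
            try:
                aa = rec.info.get("AA", ".")
            except ValueError:  # AA tag absent from the header definition
                aa = "."
            if isinstance(aa, tuple):
                aa = aa[0]
            anc.append(aa if aa in (r, a) else ".")
            rows.append(row)
    if skipped:
        logger.info("read_vcf_subset: skipped %d non-biallelic-SNP records", skipped)
    gt = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    gm = GenotypeMatrix(samples, np.array(chrom, object), np.array(pos),
                        np.array(ref, object), np.array(alt, object),
                        np.array(anc, object), gt)
    gm.n_skipped = skipped  # type: ignore[attr-defined]
    return gm


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed minimal VCF."""
    if chrom_lengths is None:
        chrom_lengths = {}
        for c in pd.unique(gm.chrom):
            chrom_lengths[str(c)] = int(gm.pos[gm.chrom == c].max()) + 1000
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, L in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_sites):
            info = f"AA={gm.anc[i]}" if gm.anc[i] != "." else "."
            gts = "\t".join(_GT_STR[int(g)] for g in gm.gt[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# windows BED

def write_windows_bed(windows: pd.DataFrame, path: str | Path) -> None:
    """Write a window table (chrom/start/end + statistics columns) as BED.

    Coordinates are written as stored: 0-based half-open.
    """
    if (windows["end"] <= windows["start"]).any():
        raise ValueError("window with end <= start")
    windows.to_csv(path, sep="\t", index=False, header=True, na_rep="NA")


def read_windows_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if (df["end"] <= df["start"]).any():
        raise ValueError("window with end <= start")
    return df


# ---------------------------------------------------------------------------
# STR tables

def write_str_table(table: StrGenotypeTable, path: str | Path) -> None:
    """TSV with a ``#unit_size`` metadata row; alleles as ``a/b``, missing '.'."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(table.locus_ids) + "\n")
        fh.write("#unit_size\t"
                 + "\t".join(str(table.unit_size[l]) for l in table.locus_ids)
                 + "\n")
        for sid, row in zip(table.sample_ids, table.alleles):
            cells = ["." if p is None else f"{p[0]}/{p[1]}" for p in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_str_table(path: str | Path) -> StrGenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        locus_ids = header[1:]
        meta = fh.readline().rstrip("\n").split("\t")
        if meta[0] != "#unit_size":
            raise ValueError("second line must be the #unit_size metadata row")
        unit_size = {l: int(u) for l, u in zip(locus_ids, meta[1:])}
        sample_ids: list[str] = []
        alleles: list[list[tuple[int, int] | None]] = []
        for ln, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            sample_ids.append(parts[0])
            row: list[tuple[int, int] | None] = []
            for j, cell in enumerate(parts[1:]):
                if cell in (".", "./.", ""):
                    row.append(None)
                    continue
                try:
                    a, b = cell.split("/")
                    row.append((int(a), int(b)))
                except ValueError:
                    raise ValueError(
                        f"non-integer allele at line {ln}, locus {locus_ids[j]}"
                    ) from None
            alleles.append(row)
    return StrGenotypeTable(sample_ids, locus_ids, unit_size, alleles)


# ---------------------------------------------------------------------------
# pedigree tables

def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False, na_rep=".")


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", na_values=["."],
                     dtype={"individual": str, "sire": str, "dam": str})
    return Pedigree(df)


# ---------------------------------------------------------------------------
# CDS interval tables (BED-like: gene, chrom, strand, exon list, phase)

def write_cds_table(models: Sequence[CdsModel], path: str | Path) -> None:
    rows = [
        (m.gene_id, m.chrom, m.strand,
         ",".join(f"{a}-{b}" for a, b in m.exons), m.phase)
        for m in models
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "exons", "phase"]
                 ).to_csv(path, sep="\t", index=False)


def read_cds_table(path: str | Path) -> list[CdsModel]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        exons = [tuple(map(int, x.split("-"))) for x in r["exons"].split(",")]
        out.append(CdsModel(r["gene_id"], r["chrom"], r["strand"], exons,
                            int(r["phase"])))
    return out
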