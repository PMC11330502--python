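"""Annotated-genome container and flat-file IO (FASTA, GFF3, BED, TSV, JSON).

Coordinates are 0-based half-open internally; GFF3 is emitted 1-based closed
and BED 0-based half-open, following the usual conventions of each format.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int           # 0-based inclusive
    end: int             # 0-based exclusive
    strand: str          # '+' or '-'
    cds: str             # coding-strand sequence, phase 0, length % 3 == 0
    family: str
    subgenome: str       # 'A', 'D', 'B' or 'ancestor'

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if len(self.cds) % 3:
            raise ValueError(f"CDS of {self.gene_id} not a whole number of codons")
        if self.end - self.start != len(self.cds):
            raise ValueError(f"gene {self.gene_id}: span != CDS length")


@dataclass
class MaskInterval:
    chrom: str
    start: int
    end: int
    mask_class: str      # 'repeat' or 'artifact'


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus gene models and mask intervals."""

    chromosomes: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    masks: list[MaskInterval] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= len(self.chromosomes[g.chrom])):
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
            span = self.chromosomes[g.chrom][g.start:g.end]
            expect = g.cds if g.strand == "+" else revcomp(g.cds)
            if span != expect:
                raise ValueError(f"gene {g.gene_id}: CDS does not match genome span")

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted((g for g in self.genes if g.chrom == chrom),
                      key=lambda g: g.start)

    def gene_index(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    # ------------------------------------------------------------------ IO
    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in sorted(self.chromosomes.items())]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in sorted(self.chromosomes.items()):
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                attrs = (f"ID={g.gene_id};family={g.family};"
                         f"subgenome={g.subgenome}")
                row = [g.chrom, "allokit", "gene", str(g.start + 1), str(g.end),
                       ".", g.strand, ".", attrs]
                fh.write("\t".join(row) + "\n")
                cds = [g.chrom, "allokit", "CDS", str(g.start + 1), str(g.end),
                       ".", g.strand, "0", f"ID={g.gene_id}.cds;Parent={g.gene_id}"]
                fh.write("\t".join(cds) + "\n")

    def write_masks_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.masks, key=lambda m: (m.chrom, m.start)):
                fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.mask_class}\n")


def read_genome(fasta: str | Path, gff3: str | Path | None = None,
                masks_bed: str | Path | None = None) -> AnnotatedGenome:
    chromosomes = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(fasta), "fasta")}
    genome = AnnotatedGenome(chromosomes=chromosomes)
    if gff3 is not None:
        for line in Path(gff3).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            start, end = int(cols[3]) - 1, int(cols[4])
            span = chromosomes[cols[0]][start:end]
            cds = span if cols[6] == "+" else revcomp(span)
            genome.genes.append(Gene(
                gene_id=attrs["ID"], chrom=cols[0], start=start, end=end,
                strand=cols[6], cds=cds,
                family=attrs.get("family", attrs["ID"]),
                subgenome=attrs.get("subgenome", ".")))
    if masks_bed is not None:
        for line in Path(masks_bed).read_text().splitlines():
            if not line:
                continue
            cols = line.split("\t")
            genome.masks.append(MaskInterval(cols[0], int(cols[1]), int(cols[2]),
                                             cols[3] if len(cols) > 3 else "repeat"))
    return genome


@dataclass
class GroundTruth:
    """Generative truth records that let tests score parameter recovery."""

    syntelog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    deleted_genes: dict[str, list[str]] = field(default_factory=dict)
    tandem_arrays: list[list[str]] = field(default_factory=list)
    homoeolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    subgenome_of: dict[str, str] = field(default_factory=dict)   # chromosome -> label
    repeat_consensus: dict[str, str] = field(default_factory=dict)
    n_ancestor_genes: int = 0
    # B chromosome
    b_chromosome: str | None = None
    b_source_segments: list[tuple[int, int, str, int, int]] = field(default_factory=list)
    b_copies: int | None = None
    # observations
    ploidy: int | None = None
    het_sites: pd.DataFrame | None = None        # chrom,pos0,ref,alt,consequence
    artifact_regions: list[tuple[str, int, int]] = field(default_factory=list)
    true_pi_syn: float | None = None
    true_pi_nonsyn: float | None = None

    def validate_against(self, genome: AnnotatedGenome) -> None:
        known = {g.gene_id for g in genome.genes}
        deleted = {gid for ids in self.deleted_genes.values() for gid in ids}
        for a, b, _ in self.syntelog_pairs:
            for gid in (a, b):
                if gid not in known and gid not in deleted:
                    raise ValueError(f"truth references unknown gene {gid}")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        if self.het_sites is not None:
            payload["het_sites"] = self.het_sites.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------- TSV IO
ALLELE_DEPTH_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]
COVERAGE_COLUMNS = ["chrom", "win_start", "win_end", "depth"]


def write_allele_depths(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ALLELE_DEPTH_COLUMNS)


def read_allele_depths(path: str | Path) -> pd.DataFrame:
    """Read a biallelic allele-depth table from TSV or (uncompressed) VCF.

    VCF rows must carry an AD format field; multiallelic rows are dropped and
    counted in ``df.attrs['n_multiallelic_dropped']``.
    """
    path = Path(path)
    first = path.open().readline()
    if first.startswith("##fileformat=VCF"):
        return _read_allele_depths_vcf(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(ALLELE_DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-depth table missing columns {sorted(missing)}")
    return df


def _read_allele_depths_vcf(path: Path) -> pd.DataFrame:
    rows, dropped = [], 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt = cols[0], int(cols[1]), cols[2], cols[3], cols[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                dropped += 1
                continue
            fmt = cols[8].split(":")
            sample = cols[9].split(":")
            try:
                ad = sample[fmt.index("AD")].split(",")
            except ValueError:
                dropped += 1
                continue
            rows.append((chrom, pos, ref, alt, int(ad[0]), int(ad[1])))
    df = pd.DataFrame(rows, columns=ALLELE_DEPTH_COLUMNS)
    df.attrs["n_multiallelic_dropped"] = dropped
    return df


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COVERAGE_COLUMNS)


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coverage table missing columns {sorted(missing)}")
    return df
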