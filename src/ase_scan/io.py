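"""File-format boundary: FASTA, phased VCF, FASTQ, GFF3, BED, TSV.

Reading goes through the established parsers (Biopython, cyvcf2, pysam,
gffutils); writing emits plain text so synthetic runs are byte-identical
under a fixed seed (gzip members are written with mtime=0 for the same
reason).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import Panel


# ---------------------------------------------------------------- FASTA

def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ VCF

def write_vcf(panel: Panel, path: str | Path) -> None:
    """Phased VCF 4.2 with GT ("0|1") and an INFO AF field."""
    lines = ["##fileformat=VCFv4.2", "##source=ase-scan"]
    for chrom in pd.unique(panel.sites["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.individuals)
    )
    for j in range(panel.n_sites):
        s = panel.sites.iloc[j]
        gts = []
        for i in range(panel.n_individuals):
            a, b = panel.gt_a[i, j], panel.gt_b[i, j]
            gts.append(".|." if a == -1 else f"{a}|{b}")
        lines.append(
            f"{s['chrom']}\t{s['pos']}\t{s['site_id']}\t{s['ref']}\t{s['alt']}\t.\tPASS\t"
            f"AF={s['af_alt']:.6f}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> Panel:
    """Load a phased biallelic-SNP VCF into a Panel (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, cols_a, cols_b = [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise ValueError(f"non-biallelic-SNP record at {v.CHROM}:{v.POS}")
        af = v.INFO.get("AF")
        rows.append((v.ID, v.CHROM, v.POS, v.REF, v.ALT[0], np.nan if af is None else float(af)))
        g = np.array([gt[:2] for gt in v.genotypes], dtype=np.int8)
        cols_a.append(g[:, 0])
        cols_b.append(g[:, 1])
    sites = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "ref", "alt", "af_alt"])
    gt_a = np.column_stack(cols_a) if cols_a else np.empty((len(individuals), 0), np.int8)
    gt_b = np.column_stack(cols_b) if cols_b else np.empty((len(individuals), 0), np.int8)
    # cyvcf2 encodes missing as -1 on either haplotype; enforce both-missing
    miss = (gt_a == -1) | (gt_b == -1)
    gt_a[miss] = -1
    gt_b[miss] = -1
    return Panel(sites=sites, individuals=individuals, gt_a=gt_a, gt_b=gt_b)


# ---------------------------------------------------------------- FASTQ

def write_fastq_gz(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Gzipped FASTQ with constant Q40 qualities and mtime=0 (so identical
    simulations give identical bytes)."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as fh:
            for name, seq in reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n".encode("ascii"))


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return [(entry.name, entry.sequence.upper()) for entry in fh]


# ------------------------------------------------------------------ GFF

def write_gff3(models, path: str | Path) -> None:
    """Gene models as GFF3 (gene/mRNA/exon/CDS/UTR features, 1-based
    inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for g in models:
        gs, ge = g.span
        lines.append(
            f"{g.chrom}\t.\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        for tx in g.transcripts:
            ts, te = tx.span
            ttype = "mRNA" if tx.is_coding else "ncRNA"
            lines.append(
                f"{g.chrom}\t.\t{ttype}\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={g.gene_id}"
            )
            for kind, ivs in (
                ("exon", tx.exons),
                ("CDS", tx.cds),
                ("five_prime_UTR", tx.utr5),
                ("three_prime_UTR", tx.utr3),
            ):
                for a, b in ivs:
                    lines.append(
                        f"{g.chrom}\t.\t{kind}\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                        f"Parent={tx.transcript_id}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path):
    """Load gene models from GFF3 via gffutils (in-memory database)."""
    import gffutils

    from .annotate import GeneModel, Transcript

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for tx in db.children(gene, level=1):
            ivs = {"exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []}
            for child in db.children(tx, level=1):
                if child.featuretype in ivs:
                    ivs[child.featuretype].append((child.start - 1, child.end))
            transcripts.append(
                Transcript(
                    transcript_id=tx.id,
                    exons=ivs["exon"],
                    cds=ivs["CDS"],
                    utr5=ivs["five_prime_UTR"],
                    utr3=ivs["three_prime_UTR"],
                )
            )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                transcripts=transcripts,
            )
        )
    return models


# ------------------------------------------------------------------ BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """Feature intervals from BED (chrom, start, end[, label]); BED is
    already 0-based half-open."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(label=[f"feat{i}" for i in range(len(df))])
    df.columns = ["chrom", "start", "end", "label"]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(features: pd.DataFrame, path: str | Path) -> None:
    features[["chrom", "start", "end", "label"]].to_csv(
        str(path), sep="\t", header=False, index=False
    )


# ------------------------------------------------------------------ TSV

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
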