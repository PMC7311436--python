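"""Variant consequence classification and external-feature intersection.

A deliberately compact, fully testable consequence classifier over
explicit gene models: each SNP is resolved against every overlapping
transcript to 5'/3' UTR, synonymous or missense (codon translated
strand-aware with the standard genetic code), splice region (within 8
intronic or 3 exonic bases of an intron boundary), intron or non-coding
transcript; sites outside every transcript span are intergenic.  When
several classes apply, the most severe is reported, in the conventional
severity order MISSENSE > SYNONYMOUS > SPLICE_REGION > 5'UTR > 3'UTR >
INTRON > NONCODING_TRANSCRIPT.  There are no upstream/downstream classes:
only transcribed positions are considered.

Also provides interval intersection of sites against external feature
BEDs (CNV regions, eQTL targets) and rs-ID list comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree


class Consequence(Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_REGION = "splice_region"
    FIVE_PRIME_UTR = "5_prime_utr"
    THREE_PRIME_UTR = "3_prime_utr"
    INTRON = "intron"
    NONCODING_TRANSCRIPT = "noncoding_transcript"
    INTERGENIC = "intergenic"


SEVERITY = [
    Consequence.MISSENSE,
    Consequence.SYNONYMOUS,
    Consequence.SPLICE_REGION,
    Consequence.FIVE_PRIME_UTR,
    Consequence.THREE_PRIME_UTR,
    Consequence.INTRON,
    Consequence.NONCODING_TRANSCRIPT,
]
_RANK = {c: i for i, c in enumerate(SEVERITY)}

SPLICE_INTRON_BASES = 8
SPLICE_EXON_BASES = 3


@dataclass
class Transcript:
    """Exon/CDS/UTR structure; all intervals 0-based half-open, stored in
    genomic (left-to-right) order regardless of strand."""

    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in self.exons + self.cds + self.utr5 + self.utr3:
            if a >= b:
                raise ValueError("intervals must satisfy start < end")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons overlap within a transcript")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    @property
    def span(self) -> tuple[int, int]:
        s = min(t.span[0] for t in self.transcripts)
        e = max(t.span[1] for t in self.transcripts)
        return s, e


def _contains(intervals: list[tuple[int, int]], pos0: int) -> bool:
    return any(a <= pos0 < b for a, b in intervals)


def _splice_region(tx: Transcript, pos0: int) -> bool:
    """Within 1-8 bases of an intron boundary inside the intron, or 1-3
    inside the exon.  Only internal boundaries (between adjacent exons)
    qualify."""
    for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:]):
        # intron is [e1, s2); boundaries at e1 (donor side) and s2 (acceptor)
        if e1 <= pos0 < min(e1 + SPLICE_INTRON_BASES, s2):
            return True
        if max(s2 - SPLICE_INTRON_BASES, e1) <= pos0 < s2:
            return True
        if e1 - SPLICE_EXON_BASES <= pos0 < e1:
            return True
        if s2 <= pos0 < s2 + SPLICE_EXON_BASES:
            return True
    return False


def _codon_change(
    tx: Transcript, strand: str, pos0: int, ref: str, alt: str, chrom_seq: str
) -> Consequence:
    """Translate the codon containing pos0 with ref vs alt base."""
    cds_pos = []  # genomic positions of CDS bases, left to right
    for a, b in tx.cds:
        cds_pos.extend(range(a, b))
    i = cds_pos.index(pos0)
    cds_seq = [chrom_seq[p] for p in cds_pos]
    if chrom_seq[pos0] != ref:
        raise ValueError(f"reference base mismatch at position {pos0 + 1}")
    if strand == "-":
        cds_seq = [str(Seq(b).reverse_complement()) for b in reversed(cds_seq)]
        i = len(cds_pos) - 1 - i
        ref_b = str(Seq(ref).reverse_complement())
        alt_b = str(Seq(alt).reverse_complement())
    else:
        ref_b, alt_b = ref, alt
    start = 3 * (i // 3)
    codon_ref = cds_seq[start : start + 3]
    codon_alt = list(codon_ref)
    codon_alt[i - start] = alt_b
    assert codon_ref[i - start] == ref_b
    aa_ref = str(Seq("".join(codon_ref)).translate())
    aa_alt = str(Seq("".join(codon_alt)).translate())
    return Consequence.SYNONYMOUS if aa_ref == aa_alt else Consequence.MISSENSE


def _classify_in_transcript(
    tx: Transcript, strand: str, pos0: int, ref: str, alt: str, chrom_seq: str
) -> Consequence | None:
    s, e = tx.span
    if not s <= pos0 < e:
        return None
    applicable: list[Consequence] = []
    exonic = _contains(tx.exons, pos0)
    if _splice_region(tx, pos0):
        applicable.append(Consequence.SPLICE_REGION)
    if exonic:
        if not tx.is_coding:
            applicable.append(Consequence.NONCODING_TRANSCRIPT)
        elif _contains(tx.cds, pos0):
            applicable.append(_codon_change(tx, strand, pos0, ref, alt, chrom_seq))
        elif _contains(tx.utr5, pos0):
            applicable.append(Consequence.FIVE_PRIME_UTR)
        elif _contains(tx.utr3, pos0):
            applicable.append(Consequence.THREE_PRIME_UTR)
        else:
            applicable.append(
                Consequence.NONCODING_TRANSCRIPT
            )  # exonic but neither CDS nor UTR
    else:
        applicable.append(Consequence.INTRON)
    return min(applicable, key=lambda c: _RANK[c])


def map_site_to_genes(site: pd.Series, models: list[GeneModel]) -> list[str]:
    """Genes whose transcript span contains the site, any strand."""
    pos0 = int(site["pos"]) - 1
    out = []
    for g in models:
        if g.chrom != site["chrom"]:
            continue
        s, e = g.span
        if s <= pos0 < e:
            out.append(g.gene_id)
    return out


def classify_variant(
    site: pd.Series, models: list[GeneModel], reference: dict[str, str]
) -> dict:
    """One consequence per site: most severe across overlapping transcripts.

    ``site`` carries chrom, 1-based pos, ref, alt.  Returns
    ``{"site_id", "gene_ids", "consequence"}``; sites in no gene are
    intergenic with an empty gene list.
    """
    pos0 = int(site["pos"]) - 1
    chrom_seq = reference[site["chrom"]]
    best: Consequence | None = None
    gene_ids: list[str] = []
    for g in models:
        if g.chrom != site["chrom"]:
            continue
        gs, ge = g.span
        if not gs <= pos0 < ge:
            continue
        gene_ids.append(g.gene_id)
        for tx in g.transcripts:
            c = _classify_in_transcript(tx, g.strand, pos0, site["ref"], site["alt"], chrom_seq)
            if c is not None and (best is None or _RANK[c] < _RANK[best]):
                best = c
    if not gene_ids:
        return {"site_id": site["site_id"], "gene_ids": [], "consequence": Consequence.INTERGENIC}
    return {"site_id": site["site_id"], "gene_ids": gene_ids, "consequence": best}


def classify_sites(
    sites: pd.DataFrame, models: list[GeneModel], reference: dict[str, str]
) -> pd.DataFrame:
    """Consequence table for many sites, with class percentages computable
    downstream (each site gets exactly one class)."""
    rows = []
    for _, site in sites.iterrows():
        r = classify_variant(site, models, reference)
        rows.append(
            (r["site_id"], ",".join(r["gene_ids"]), r["consequence"].value)
        )
    return pd.DataFrame(rows, columns=["site_id", "gene_ids", "consequence"])


def interval_overlap(sites: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """(site, feature) pairs where the feature's half-open interval
    contains the site position.

    ``features`` columns: chrom, start, end (half-open), label.  Each pair
    is reported once; output order follows the site table.
    """
    if (features["start"] >= features["end"]).any():
        raise ValueError("feature intervals must satisfy start < end")
    trees: dict[str, IntervalTree] = {}
    for _, f in features.iterrows():
        trees.setdefault(str(f["chrom"]), IntervalTree()).addi(
            int(f["start"]), int(f["end"]), f["label"]
        )
    rows = []
    for _, s in sites.iterrows():
        tree = trees.get(str(s["chrom"]))
        if tree is None:
            continue
        pos0 = int(s["pos"]) - 1
        labels = sorted({iv.data for iv in tree.at(pos0)})
        rows.extend((s["site_id"], lab) for lab in labels)
    return pd.DataFrame(rows, columns=["site_id", "feature"])


def compare_snp_lists(ours: list[str], external: list[str]) -> dict:
    """Intersection of two SNP id lists, normalised for case/whitespace."""
    a = {s.strip().lower(): s.strip() for s in ours if s.strip()}
    b = {s.strip().lower() for s in external if s.strip()}
    common = sorted(a[k] for k in a.keys() & b)
    n_ours = len(a)
    union = len(a.keys() | b)
    return {
        "intersection": common,
        "n_common": len(common),
        "n_ours": n_ours,
        "n_external": len(b),
        "share_of_ours_pct": (
            round(100.0 * len(common) / n_ours, 2) if n_ours else 0.0
        ),
        "jaccard": len(common) / union if union else 0.0,
    }
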