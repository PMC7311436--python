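"""Personalized diploid genomes and perfect-match allele-specific counting.

Each individual's two haplotype sequences are the reference with the
phased alleles substituted at SNP positions.  A read is assigned to an
allele only if it (or its reverse complement) occurs as an exact,
full-length substring of exactly one haplotype at exactly one genomic
locus covering the SNP; reads matching both haplotypes (they span no
heterozygous site) or multiple loci are ambiguous and discarded, and reads
matching neither (sequencing errors) are unassigned.  This is the strict
"every base identical" contract of allele-aware perfect-match mapping.

Internally coordinates are 0-based half-open; the 1-based VCF convention
is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .panel import Panel
from .synth import reverse_complement


class AssignmentOutcome(Enum):
    ALLELE1 = "allele1"  # the site's reference allele
    ALLELE2 = "allele2"  # the site's alternate allele
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


@dataclass
class HaplotypePair:
    """Two personalized sequences per chromosome for one individual."""

    individual: str
    seq_a: dict[str, str]
    seq_b: dict[str, str]


def build_haplotypes(reference: dict[str, str], panel: Panel, individual: str) -> HaplotypePair:
    """Substitute the individual's phased alleles into the reference.

    Haplotype A carries the first allele of each phased genotype, haplotype
    B the second; missing genotypes leave the reference base on both.
    """
    i = panel.individuals.index(individual)
    seq_a = {c: bytearray(s, "ascii") for c, s in reference.items()}
    seq_b = {c: bytearray(s, "ascii") for c, s in reference.items()}
    for j in range(panel.n_sites):
        chrom = panel.sites.at[j, "chrom"]
        pos0 = int(panel.sites.at[j, "pos"]) - 1
        ref, alt = panel.sites.at[j, "ref"], panel.sites.at[j, "alt"]
        if reference[chrom][pos0] != ref:
            raise ValueError(
                f"panel ref allele {ref} at {chrom}:{pos0 + 1} does not match reference"
            )
        for code, seq in ((panel.gt_a[i, j], seq_a), (panel.gt_b[i, j], seq_b)):
            if code == -1:
                continue
            base = ref if code == 0 else alt
            seq[chrom][pos0] = ord(base)
    return HaplotypePair(
        individual=individual,
        seq_a={c: s.decode("ascii") for c, s in seq_a.items()},
        seq_b={c: s.decode("ascii") for c, s in seq_b.items()},
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start offsets of needle in haystack."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _occurrences(read: str, pair: HaplotypePair) -> list[tuple[str, str, int]]:
    """Distinct (haplotype, chrom, start) perfect occurrences of the read,
    searching both orientations; an occurrence found on both strands at one
    locus counts once."""
    hits: set[tuple[str, str, int]] = set()
    for query in (read, reverse_complement(read)):
        for hap, seqs in (("A", pair.seq_a), ("B", pair.seq_b)):
            for chrom, seq in seqs.items():
                for start in _find_all(seq, query):
                    hits.add((hap, chrom, start))
    return sorted(hits)


def _resolve(hits: list[tuple[str, str, int]]) -> tuple[str, str, int] | str:
    """Collapse occurrence list to a unique (hap, chrom, start), or a
    terminal outcome string ('ambiguous' / 'unassigned')."""
    if not hits:
        return "unassigned"
    loci = {(c, s) for _, c, s in hits}
    if len(loci) > 1:
        return "ambiguous"  # multi-locus
    haps = {h for h, _, _ in hits}
    if len(haps) > 1:
        return "ambiguous"  # perfect in both haplotypes
    return hits[0]


def assign_read(read: str, pair: HaplotypePair, site: pd.Series, hap_a_code: int, hap_b_code: int) -> AssignmentOutcome:
    """Classify one read against one heterozygous site.

    ``site`` is a panel row (chrom, pos, ref, alt); ``hap_a_code`` /
    ``hap_b_code`` are the individual's phased allele codes (0 ref, 1 alt)
    at that site.
    """
    if not read:
        raise ValueError("empty read")
    if hap_a_code == hap_b_code:
        raise ValueError("assign_read is defined for heterozygous sites only")
    res = _resolve(_occurrences(read, pair))
    if res == "unassigned":
        return AssignmentOutcome.UNASSIGNED
    if res == "ambiguous":
        return AssignmentOutcome.AMBIGUOUS
    hap, chrom, start = res
    pos0 = int(site["pos"]) - 1
    if site["chrom"] != chrom or not start <= pos0 < start + len(read):
        return AssignmentOutcome.AMBIGUOUS  # unique hit, but does not cover the site
    code = hap_a_code if hap == "A" else hap_b_code
    return AssignmentOutcome.ALLELE1 if code == 0 else AssignmentOutcome.ALLELE2


def _kmer_index(pair: HaplotypePair, k: int) -> dict[str, list[tuple[str, str, int]]]:
    index: dict[str, list[tuple[str, str, int]]] = {}
    for hap, seqs in (("A", pair.seq_a), ("B", pair.seq_b)):
        for chrom, seq in seqs.items():
            for start in range(len(seq) - k + 1):
                index.setdefault(seq[start : start + k], []).append((hap, chrom, start))
    return index


def count_alleles(
    reads: list[tuple[str, str]] | list[str],
    pair: HaplotypePair,
    panel: Panel,
) -> pd.DataFrame:
    """Perfect-match allele counts at the individual's heterozygous sites.

    Returns one row per heterozygous site with columns ``individual,
    site_id, chrom, pos, ref_count, alt_count`` (zero rows are kept so a
    site with no informative reads appears as (0, 0)).  When all reads
    share one length, occurrences are resolved through a k-mer hash of the
    two haplotype genomes; mixed-length inputs fall back to substring
    scanning.  Both routes implement the identical unique-perfect-match
    rule.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    i = panel.individuals.index(pair.individual)
    het = np.flatnonzero(panel.het_mask()[i])
    by_chrom: dict[str, list[int]] = {}
    for j in het:
        by_chrom.setdefault(panel.sites.at[j, "chrom"], []).append(int(j))
    pos_by_chrom = {
        c: np.array([int(panel.sites.at[j, "pos"]) - 1 for j in js]) for c, js in by_chrom.items()
    }

    ref_counts = np.zeros(panel.n_sites, dtype=np.int64)
    alt_counts = np.zeros(panel.n_sites, dtype=np.int64)

    lengths = {len(s) for s in seqs}
    index = _kmer_index(pair, next(iter(lengths))) if len(lengths) == 1 else None

    for read in seqs:
        if index is not None:
            hits = set(index.get(read, ()))
            rc = reverse_complement(read)
            if rc != read:
                hits.update(index.get(rc, ()))
            res = _resolve(sorted(hits))
        else:
            res = _resolve(_occurrences(read, pair))
        if isinstance(res, str):
            continue
        hap, chrom, start = res
        if chrom not in pos_by_chrom:
            continue
        pos = pos_by_chrom[chrom]
        lo = np.searchsorted(pos, start)
        hi = np.searchsorted(pos, start + len(read))
        for idx in range(lo, hi):
            j = by_chrom[chrom][idx]
            code = panel.gt_a[i, j] if hap == "A" else panel.gt_b[i, j]
            if code == 0:
                ref_counts[j] += 1
            else:
                alt_counts[j] += 1

    rows = [
        (
            pair.individual,
            panel.sites.at[j, "site_id"],
            panel.sites.at[j, "chrom"],
            int(panel.sites.at[j, "pos"]),
            int(ref_counts[j]),
            int(alt_counts[j]),
        )
        for j in het
    ]
    return pd.DataFrame(
        rows, columns=["individual", "site_id", "chrom", "pos", "ref_count", "alt_count"]
    )


def coverage_filter(records: pd.DataFrame, min_total: int = 20) -> tuple[pd.DataFrame, pd.Series]:
    """Keep records with >= ``min_total`` allele-informative reads.

    Returns the kept records and a per-site testability flag (a site is
    testable iff at least one individual record survives the filter).
    Only allele-assigned reads count toward the threshold; ambiguous and
    unassigned reads never enter the records.
    """
    total = records["ref_count"] + records["alt_count"]
    kept = records.loc[total >= min_total].reset_index(drop=True)
    testable = pd.Series(
        records["site_id"].unique(), name="site_id"
    ).to_frame()
    testable["testable"] = testable["site_id"].isin(kept["site_id"])
    return kept, testable.set_index("site_id")["testable"]
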