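"""Containers for a biallelic SNP panel with phased genotypes.

The panel holds per-site metadata (chromosome, 1-based position, ref/alt
alleles, population alt-allele frequency) together with two haplotype
matrices of allele codes: ``gt_a`` carries the first allele of every phased
genotype, ``gt_b`` the second.  Codes are 0 (reference), 1 (alternate) and
-1 (missing; always missing on both haplotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["site_id", "chrom", "pos", "ref", "alt", "af_alt"]


@dataclass
class Panel:
    """Phased genotypes for ``n_individuals`` x ``n_sites`` biallelic SNPs.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per SNP with columns ``site_id, chrom, pos, ref, alt,
        af_alt``; ``pos`` is 1-based as in VCF.
    individuals : list of str
        Sample identifiers, ordered as the rows of the genotype matrices.
    gt_a, gt_b : numpy.ndarray of int8, shape (n_individuals, n_sites)
        Allele code carried by the first / second haplotype of each phased
        genotype (0 = ref, 1 = alt, -1 = missing).
    """

    sites: pd.DataFrame
    individuals: list[str] = field(default_factory=list)
    gt_a: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int8))
    gt_b: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int8))

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n_ind, n_sites = self.gt_a.shape
        if self.gt_b.shape != (n_ind, n_sites):
            raise ValueError("gt_a and gt_b shapes differ")
        if n_ind != len(self.individuals):
            raise ValueError("genotype rows do not match individuals")
        if n_sites != len(self.sites):
            raise ValueError("genotype columns do not match sites")
        if ((self.gt_a == -1) != (self.gt_b == -1)).any():
            raise ValueError("missing genotypes must be missing on both haplotypes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def missing_mask(self) -> np.ndarray:
        """Boolean (individual x site) mask of missing genotypes."""
        return self.gt_a == -1

    def het_mask(self) -> np.ndarray:
        """Boolean (individual x site) mask of heterozygous calls."""
        return (self.gt_a != self.gt_b) & (self.gt_a != -1)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-site genotype tallies (n_rr, n_ra, n_aa, n_missing).

        ``n_rr`` counts ref-homozygotes, ``n_ra`` heterozygotes, ``n_aa``
        alt-homozygotes; phase is ignored.
        """
        miss = self.missing_mask()
        dosage = np.where(miss, -1, self.gt_a + self.gt_b)
        return pd.DataFrame(
            {
                "site_id": self.sites["site_id"],
                "n_rr": (dosage == 0).sum(axis=0),
                "n_ra": (dosage == 1).sum(axis=0),
                "n_aa": (dosage == 2).sum(axis=0),
                "n_missing": miss.sum(axis=0),
            }
        )

    def alt_frequency(self) -> np.ndarray:
        """Observed alt-allele frequency per site, from non-missing calls.

        Sites with no called genotypes yield NaN.
        """
        miss = self.missing_mask()
        called = (~miss).sum(axis=0)
        alt = np.where(miss, 0, self.gt_a).sum(axis=0) + np.where(
            miss, 0, self.gt_b
        ).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / (2.0 * called), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        af = self.alt_frequency()
        return np.minimum(af, 1.0 - af)

    def site_call_rate(self) -> np.ndarray:
        if self.n_individuals == 0:
            return np.full(self.n_sites, np.nan)
        return 1.0 - self.missing_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.full(self.n_individuals, np.nan)
        return 1.0 - self.missing_mask().mean(axis=1)

    def subset_sites(self, keep: np.ndarray) -> "Panel":
        """Return a new panel restricted to sites selected by ``keep``
        (boolean mask or integer index array, in site order)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Panel(
            sites=self.sites.iloc[keep].reset_index(drop=True),
            individuals=list(self.individuals),
            gt_a=self.gt_a[:, keep].copy(),
            gt_b=self.gt_b[:, keep].copy(),
        )

    def subset_individuals(self, keep_ids: list[str]) -> "Panel":
        idx = [self.individuals.index(i) for i in keep_ids]
        return Panel(
            sites=self.sites.copy(),
            individuals=list(keep_ids),
            gt_a=self.gt_a[idx, :].copy(),
            gt_b=self.gt_b[idx, :].copy(),
        )
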