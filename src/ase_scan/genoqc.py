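"""Genotype quality control: MAF, call-rate, Hardy-Weinberg and autosome
filters applied to a phased SNP panel.

Sample-level filtering runs first; per-site statistics (MAF, call rate,
HWE) are then recomputed on the kept samples, mirroring standard GWAS-QC
tooling.  MAF is computed from non-missing calls only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .panel import Panel

DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 30))  # cattle: 29 autosomes


@dataclass
class QCConfig:
    maf_min: float = 0.05
    site_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    autosomes_only: bool = True
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES
    hwe_method: str = "exact"  # "exact" or "chisq"

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.site_call_rate_min, self.sample_call_rate_min, self.hwe_p_min):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError("hwe_method must be 'exact' or 'chisq'")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count:

        P(n_Aa = h | n, n_A)  ∝  2^h · n! / ( ((n_A-h)/2)! · h! · ((n_a-h)/2)! )

    with h ranging over values matching the parity of n_A.  Monomorphic
    sites have a single attainable outcome and return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("all genotypes missing: HWE test undefined")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    hs = np.arange(rare % 2, rare + 1, 2)
    logp = (
        hs * np.log(2.0)
        - gammaln((n_A - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((n_a - hs) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hs == n_Aa)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square HWE goodness-of-fit test (no continuity correction)."""
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("all genotypes missing: HWE test undefined")
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def sample_filters(panel: Panel, config: QCConfig) -> list[str]:
    """Individuals whose genotype call rate meets ``sample_call_rate_min``."""
    rates = panel.sample_call_rate()
    return [ind for ind, r in zip(panel.individuals, rates) if r >= config.sample_call_rate_min]


def site_filters(panel: Panel, config: QCConfig) -> tuple[list[str], pd.DataFrame]:
    """Apply per-site filters; return kept site ids and a full report.

    A site is kept iff it is autosomal, MAF >= maf_min, call rate >=
    site_call_rate_min and HWE p >= hwe_p_min.  The report lists every
    failed criterion per site (comma-joined in the ``reasons`` column).
    """
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    hwe = hwe_exact_test if config.hwe_method == "exact" else hwe_chisq_test
    counts = panel.genotype_counts()
    maf = panel.minor_allele_frequency()
    call = panel.site_call_rate()

    rows = []
    for j in range(panel.n_sites):
        reasons = []
        chrom = str(panel.sites.at[j, "chrom"])
        if config.autosomes_only and chrom not in config.autosomes:
            reasons.append("autosome")
        n_called = int(counts.at[j, "n_rr"] + counts.at[j, "n_ra"] + counts.at[j, "n_aa"])
        if n_called == 0:
            hwe_p = np.nan
            reasons.append("call_rate")
            reasons.append("maf")
        else:
            hwe_p = hwe(int(counts.at[j, "n_rr"]), int(counts.at[j, "n_ra"]), int(counts.at[j, "n_aa"]))
            if maf[j] < config.maf_min:
                reasons.append("maf")
            if call[j] < config.site_call_rate_min:
                reasons.append("call_rate")
            if hwe_p < config.hwe_p_min:
                reasons.append("hwe")
        rows.append(
            (
                panel.sites.at[j, "site_id"],
                chrom,
                float(maf[j]) if n_called else np.nan,
                float(call[j]),
                hwe_p,
                not reasons,
                ",".join(reasons),
            )
        )
    report = pd.DataFrame(
        rows, columns=["site_id", "chrom", "maf", "call_rate", "hwe_p", "kept", "reasons"]
    )
    kept = report.loc[report["kept"], "site_id"].tolist()
    return kept, report


@dataclass
class QCResult:
    panel: Panel
    site_report: pd.DataFrame
    kept_individuals: list[str]
    removed_individuals: list[str] = field(default_factory=list)


def apply_qc(panel: Panel, config: QCConfig | None = None) -> QCResult:
    """Full QC pass: sample filters first, then site filters on kept samples."""
    config = config or QCConfig()
    kept_ind = sample_filters(panel, config)
    removed_ind = [i for i in panel.individuals if i not in kept_ind]
    sub = panel.subset_individuals(kept_ind) if removed_ind else panel
    kept_sites, report = site_filters(sub, config)
    keep_mask = sub.sites["site_id"].isin(kept_sites).to_numpy()
    return QCResult(
        panel=sub.subset_sites(keep_mask),
        site_report=report,
        kept_individuals=kept_ind,
        removed_individuals=removed_ind,
    )
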