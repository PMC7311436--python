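"""Allelic-imbalance calling: exact binomial tests with BH-FDR control.

Each coverage-passing heterozygous (individual, site) observation is an
independent test of H0: the two alleles contribute reads equally
(Binomial(n, 1/2)).  P-values are exact two-sided (minimum-likelihood
definition, which for the symmetric null coincides with the doubled
smaller tail), adjusted jointly across all tests of a run by the
Benjamini-Hochberg step-up procedure.  An observation is significant when
its q-value is strictly below the FDR level, and monoallelic when it is
significant with a zero minor-allele count.

The calling stage is exposed as a model/results pair:

>>> res = AllelicImbalance(counts).fit()
>>> res.calls          # per-observation p, q, flags
>>> res.summary()      # run-level overview
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import profiles


@dataclass
class CallConfig:
    """FDR level and BH scope ("global" across all tests, or
    "per_individual")."""

    alpha: float = 0.05
    scope: str = "global"
    min_coverage: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.scope not in ("global", "per_individual"):
            raise ValueError("scope must be 'global' or 'per_individual'")


def binomial_two_sided(k, n):
    """Exact two-sided binomial p-value under H0: p = 1/2.

    Sums P(X = j) over all j with P(X = j) <= P(X = k); for the symmetric
    null this equals min(1, 2 * P(X <= min(k, n - k))).  Vectorised;
    scalar inputs return a float.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n_arr = np.atleast_1d(np.asarray(n, dtype=np.int64))
    k_arr, n_arr = np.broadcast_arrays(k_arr, n_arr)
    if (n_arr < 1).any():
        raise ValueError("n must be >= 1")
    if ((k_arr < 0) | (k_arr > n_arr)).any():
        raise ValueError("k must lie in [0, n]")
    tail = np.minimum(k_arr, n_arr - k_arr)
    p = np.minimum(1.0, 2.0 * stats.binom.cdf(tail, n_arr, 0.5))
    # guard against cdf rounding to exactly 0 at huge n
    p = np.maximum(p, np.finfo(float).tiny)
    return float(p[0]) if np.isscalar(k) or np.ndim(k) == 0 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ) on the sorted p-values, mapped
    back to input order; output is capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_monoallelic(k, n, significant):
    """Monoallelic = significant allelic imbalance with a silent allele."""
    k = np.asarray(k)
    n = np.asarray(n)
    return np.asarray(significant) & (np.minimum(k, n - k) == 0)


def call_ase(records: pd.DataFrame, config: CallConfig | None = None) -> pd.DataFrame:
    """Test every allele-count record; returns the calls table.

    ``records`` needs columns ``individual, site_id, ref_count, alt_count``
    (``chrom``/``pos`` are carried through when present).  BH adjustment is
    applied across all records jointly (default) or within each individual.
    Empty input yields an empty, correctly-typed frame.
    """
    config = config or CallConfig()
    out = records.copy().reset_index(drop=True)
    out["n"] = out["ref_count"] + out["alt_count"]
    if len(out) == 0:
        for col in ("n", "p_value", "q_value"):
            out[col] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        out["monoallelic"] = pd.Series(dtype=bool)
        return out
    out["p_value"] = binomial_two_sided(out["ref_count"].to_numpy(), out["n"].to_numpy())
    if config.scope == "global":
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = (
            out.groupby("individual", group_keys=False)["p_value"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    out["significant"] = out["q_value"] < config.alpha
    out["monoallelic"] = flag_monoallelic(
        out["ref_count"].to_numpy(), out["n"].to_numpy(), out["significant"].to_numpy()
    )
    return out


class AllelicImbalance:
    """Allelic-imbalance model over per-individual allele-count records.

    Parameters
    ----------
    counts : pandas.DataFrame
        Allele-informative read counts with columns ``individual, site_id,
        ref_count, alt_count`` (plus optional ``chrom, pos``), one row per
        heterozygous (individual, site).
    config : CallConfig, optional
        FDR level (default 0.05), BH scope and minimum coverage (default
        20 informative reads; records below it are excluded before
        testing).
    """

    def __init__(self, counts: pd.DataFrame, config: CallConfig | None = None):
        self.config = config or CallConfig()
        total = counts["ref_count"] + counts["alt_count"]
        self.counts = counts.loc[total >= self.config.min_coverage].reset_index(drop=True)
        self.n_excluded = int((total < self.config.min_coverage).sum())

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, **kwargs) -> "AllelicImbalance":
        return cls(counts, CallConfig(**kwargs) if kwargs else None)

    def fit(self) -> "ASEResults":
        return ASEResults(self, call_ase(self.counts, self.config))


class ASEResults:
    """Fitted calls plus profile summaries for an allelic-imbalance run."""

    def __init__(self, model: AllelicImbalance, calls: pd.DataFrame):
        self.model = model
        self.calls = calls

    @property
    def n_tests(self) -> int:
        return len(self.calls)

    @property
    def n_significant(self) -> int:
        return int(self.calls["significant"].sum())

    @property
    def n_monoallelic(self) -> int:
        return int(self.calls["monoallelic"].sum())

    def site_summaries(self) -> pd.DataFrame:
        return profiles.summarize_sites(self.calls)

    def individual_summaries(self):
        return profiles.individual_profile(self.calls)

    def summary(self) -> str:
        """Run-level overview as a plain-text table."""
        buf = io.StringIO()
        frac = 100.0 * self.n_significant / self.n_tests if self.n_tests else 0.0
        summ = self.site_summaries()
        n_sites = len(summ)
        n_ase = int(summ["is_ase_site"].sum()) if n_sites else 0
        print("Allelic imbalance (binomial test, BH-FDR)", file=buf)
        print("=" * 46, file=buf)
        print(f"{'FDR level (alpha)':<34}{self.model.config.alpha:>12g}", file=buf)
        print(f"{'Min coverage (informative reads)':<34}{self.model.config.min_coverage:>12d}", file=buf)
        print(f"{'Tests (individual x site)':<34}{self.n_tests:>12d}", file=buf)
        print(f"{'Significant tests':<34}{self.n_significant:>12d}", file=buf)
        print(f"{'Significant fraction (%)':<34}{frac:>12.2f}", file=buf)
        print(f"{'Monoallelic tests':<34}{self.n_monoallelic:>12d}", file=buf)
        print(f"{'Testable SNPs':<34}{n_sites:>12d}", file=buf)
        print(f"{'ASE SNPs (>=1 significant ind.)':<34}{n_ase:>12d}", file=buf)
        return buf.getvalue()

    def plot_individual_profile(self, ax=None):
        """Scatter of ASE-SNP count vs tested-SNP count per individual,
        with the OLS fit line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ind, r2 = profiles.individual_profile(self.calls)
        x = ind["n_tested_sites"].to_numpy(dtype=float)
        y = ind["n_ase_sites"].to_numpy(dtype=float)
        ax.scatter(x, y, color="tab:blue")
        if r2 is not None and len(ind) >= 2 and np.ptp(x) > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, color="tab:red", label=f"OLS, $R^2$={r2:.2f}")
            ax.legend()
        ax.set_xlabel("SNPs tested per individual")
        ax.set_ylabel("ASE SNPs per individual")
        return ax
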