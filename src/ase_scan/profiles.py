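"""Site- and individual-level ASE profile statistics.

Aggregates per-(individual, site) calls into the summaries an ASE scan
reports: per-SNP consistency (share of tested heterozygotes that are
significant), ASE/biallelic site classification, monoallelic proportions,
allele-direction consistency against population major/minor alleles,
occurrence histograms, per-chromosome distributions and the per-individual
tested-vs-ASE regression.

Percentages are rounded half-up to two decimals, matching how consistency
tables are conventionally printed (43/46 -> 93.48).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


class Direction(Enum):
    MAJOR_CONSISTENT = "major_consistent"
    MINOR_CONSISTENT = "minor_consistent"
    MIXED = "mixed"
    NOT_EVALUATED = "not_evaluated"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (numpy/python bankers' rounding would turn
    0.125 into 0.12; reported proportions use the conventional 0.13)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_site(records: pd.DataFrame) -> pd.Series:
    """Summary for the call records of a single site.

    Returns n_tested, n_ase, ase_proportion (percent of tested
    heterozygous individuals that are significant), n_monoallelic,
    monoallelic_proportion_of_ase and the is_ase_site flag.
    """
    if len(records) == 0:
        raise ValueError("summarize_site needs at least one record")
    n_tested = len(records)
    n_ase = int(records["significant"].sum())
    n_mono = int(records["monoallelic"].sum())
    return pd.Series(
        {
            "n_tested": n_tested,
            "n_ase": n_ase,
            "ase_proportion": round_half_up(100.0 * n_ase / n_tested),
            "n_monoallelic": n_mono,
            "monoallelic_proportion_of_ase": (
                round_half_up(100.0 * n_mono / n_ase) if n_ase else np.nan
            ),
            "is_ase_site": n_ase >= 1,
        }
    )


def summarize_sites(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-site summaries over a full calls table (one row per site)."""
    if len(calls) == 0:
        return pd.DataFrame(
            columns=[
                "site_id",
                "n_tested",
                "n_ase",
                "ase_proportion",
                "n_monoallelic",
                "monoallelic_proportion_of_ase",
                "is_ase_site",
            ]
        )
    out = (
        calls.groupby("site_id", sort=True)
        .apply(summarize_site, include_groups=False)
        .reset_index()
    )
    for c in ("n_tested", "n_ase", "n_monoallelic"):
        out[c] = out[c].astype(int)
    out["is_ase_site"] = out["is_ase_site"].astype(bool)
    return out


def classify_sites(summaries: pd.DataFrame) -> dict[str, list[str]]:
    """Partition sites into ASE (>=1 significant individual) vs biallelic."""
    ase = summaries.loc[summaries["n_ase"] >= 1, "site_id"].tolist()
    biallelic = summaries.loc[summaries["n_ase"] == 0, "site_id"].tolist()
    return {"ase": ase, "biallelic": biallelic}


def direction_analysis(
    calls: pd.DataFrame,
    sites: pd.DataFrame,
    min_ase: int = 5,
) -> pd.DataFrame:
    """Allele-direction consistency per site among significant individuals.

    ``sites`` must provide ``site_id`` and ``af_alt`` (population
    alternate-allele frequency on the QC-passed cohort); the major allele
    is alt when af_alt > 0.5, otherwise ref (ties resolved to ref).  Sites
    with fewer than ``min_ase`` significant individuals are NOT_EVALUATED.
    Equal ref/alt counts cannot be significant under the binomial test, so
    every significant record has a strict majority allele.
    """
    af = sites.set_index("site_id")["af_alt"]
    rows = []
    for site_id, grp in calls.groupby("site_id", sort=True):
        sig = grp.loc[grp["significant"]]
        if len(sig) < min_ase:
            rows.append((site_id, Direction.NOT_EVALUATED.value))
            continue
        major_is_alt = af[site_id] > 0.5
        higher_is_alt = sig["alt_count"] > sig["ref_count"]
        higher_is_major = higher_is_alt == major_is_alt
        if higher_is_major.all():
            d = Direction.MAJOR_CONSISTENT
        elif (~higher_is_major).all():
            d = Direction.MINOR_CONSISTENT
        else:
            d = Direction.MIXED
        rows.append((site_id, d.value))
    return pd.DataFrame(rows, columns=["site_id", "direction"])


def occurrence_histogram(summaries: pd.DataFrame) -> dict:
    """Distribution of ASE occurrence (n_ase) across ASE sites.

    Returns exact per-count tallies plus the headline bins: sites with
    exactly one significant individual, with five or more, and with more
    than fifty — each with its percentage of all ASE sites (half-up, two
    decimals).
    """
    ase = summaries.loc[summaries["n_ase"] >= 1]
    total = len(ase)
    counts = ase["n_ase"].value_counts().sort_index()
    bins = {
        "=1": int((ase["n_ase"] == 1).sum()),
        ">=5": int((ase["n_ase"] >= 5).sum()),
        ">50": int((ase["n_ase"] > 50).sum()),
    }
    pct = {
        k: (round_half_up(100.0 * v / total) if total else 0.0) for k, v in bins.items()
    }
    return {"counts": counts, "n_ase_sites": total, "bins": bins, "percent": pct}


def chromosome_distribution(
    summaries: pd.DataFrame,
    sites: pd.DataFrame,
    min_ase: int = 5,
) -> pd.DataFrame:
    """Per-chromosome tested/ASE tallies in two scenarios.

    For each chromosome with at least one tested site: number of tested
    sites, ASE sites (>=1 significant individual) with percentage, and the
    restriction to sites with >= ``min_ase`` significant individuals with
    its percentage; ``n_ase_lt_min`` and ``n_biallelic`` complete the
    partition.  Chromosomes without tested sites are omitted.
    """
    coord = sites.set_index("site_id")["chrom"]
    missing = set(summaries["site_id"]) - set(coord.index)
    if missing:
        raise ValueError(f"unknown chromosome for sites: {sorted(missing)[:3]}")
    df = summaries.copy()
    df["chrom"] = df["site_id"].map(coord)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        n_tested = len(grp)
        n_ase = int((grp["n_ase"] >= 1).sum())
        n_ge = int((grp["n_ase"] >= min_ase).sum())
        rows.append(
            {
                "chrom": chrom,
                "n_tested": n_tested,
                "n_ase": n_ase,
                "pct_ase": round_half_up(100.0 * n_ase / n_tested),
                "n_ase_ge_min": n_ge,
                "pct_ase_ge_min": round_half_up(100.0 * n_ge / n_tested),
                "n_ase_lt_min": n_ase - n_ge,
                "n_biallelic": n_tested - n_ase,
            }
        )
    return pd.DataFrame(rows)


def individual_profile(calls: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Per-individual tallies and the OLS R^2 of ASE count on tested count.

    The fit (ordinary least squares on raw counts) needs at least three
    individuals and non-constant x; otherwise R^2 is None.
    """
    tallies = (
        calls.groupby("individual", sort=True)
        .agg(
            n_tested_sites=("site_id", "size"),
            n_ase_sites=("significant", "sum"),
        )
        .reset_index()
    )
    tallies["n_ase_sites"] = tallies["n_ase_sites"].astype(int)
    r2 = None
    if len(tallies) >= 3:
        x = tallies["n_tested_sites"].to_numpy(dtype=float)
        y = tallies["n_ase_sites"].to_numpy(dtype=float)
        if np.ptp(x) > 0:
            if np.ptp(y) == 0:
                r2 = 0.0
            else:
                r2 = float(stats.linregress(x, y).rvalue ** 2)
    return tallies, r2


def top_sites(
    summaries: pd.DataFrame, n: int = 10, site_meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Most consistently imbalanced sites: ranked by number of significant
    individuals, then consistency percentage, then site id."""
    out = summaries.sort_values(
        ["n_ase", "ase_proportion", "site_id"], ascending=[False, False, True]
    ).head(n)
    if site_meta is not None:
        out = out.merge(site_meta, on="site_id", how="left")
    return out.reset_index(drop=True)
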