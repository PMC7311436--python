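"""Shared synthetic fixtures; everything is generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ase_scan import synth
from ase_scan.synth import SimulationConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale cohort: 2 x 20 kb chromosomes, 50 SNPs, 10 individuals."""
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length=20_000,
        n_sites=50,
        n_individuals=10,
        mean_coverage=30.0,
        base_error_rate=0.005,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    """(reference, panel, truth, reads) generated once per session."""
    r1, r2, r3, r4 = small_cfg.spawn_rngs()
    ref = synth.generate_reference(small_cfg, r1)
    panel = synth.generate_panel(ref, small_cfg, r2)
    truth = synth.assign_truth(panel, small_cfg, r3)
    reads = synth.generate_reads(ref, panel, truth, small_cfg, r4)
    return ref, panel, truth, reads


def make_calls(rows: list[tuple]) -> pd.DataFrame:
    """Hand-built calls table: (individual, site_id, ref_count, alt_count,
    significant[, monoallelic])."""
    recs = []
    for r in rows:
        ind, site, ref_c, alt_c, sig = r[:5]
        mono = r[5] if len(r) > 5 else (sig and min(ref_c, alt_c) == 0)
        recs.append(
            {
                "individual": ind,
                "site_id": site,
                "ref_count": ref_c,
                "alt_count": alt_c,
                "n": ref_c + alt_c,
                "significant": sig,
                "monoallelic": mono,
            }
        )
    return pd.DataFrame(recs)
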