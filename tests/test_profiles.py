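"""Profile aggregation: consistency proportions, partitions, direction,
histograms, chromosome tables, individual regression."""

import numpy as np
import pandas as pd
import pytest

from ase_scan import profiles
from ase_scan.profiles import Direction, round_half_up

from conftest import make_calls


class TestSummarizeSite:
    @pytest.mark.parametrize(
        "n_ase,n_tested,expected",
        [(43, 46, 93.48), (79, 87, 90.80), (68, 84, 80.95), (41, 46, 89.13)],
    )
    def test_consistency_proportion_rounding(self, n_ase, n_tested, expected):
        rows = [("i%d" % i, "s0", 30, 0, i < n_ase) for i in range(n_tested)]
        summ = profiles.summarize_site(make_calls(rows))
        assert summ["ase_proportion"] == expected
        assert summ["n_ase"] == n_ase and summ["n_tested"] == n_tested

    def test_single_tested_individual(self):
        summ = profiles.summarize_site(make_calls([("i0", "s0", 25, 0, True)]))
        assert summ["ase_proportion"] == 100.00
        assert bool(summ["is_ase_site"])

    def test_monoallelic_proportion_of_ase(self):
        rows = [
            ("i0", "s0", 30, 0, True),   # monoallelic
            ("i1", "s0", 28, 2, True),   # significant, not monoallelic
            ("i2", "s0", 15, 15, False),
        ]
        summ = profiles.summarize_site(make_calls(rows))
        assert summ["n_monoallelic"] == 1
        assert summ["monoallelic_proportion_of_ase"] == 50.00

    def test_round_half_up_vs_bankers(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(93.478260, 2) == 93.48


class TestClassifySites:
    def test_partition_by_any_significant(self):
        calls = make_calls(
            [("i%d" % i, "s0", 20, 10, False) for i in range(14)]
            + [("i0", "s1", 25, 0, True), ("i1", "s1", 12, 13, False)]
        )
        summ = profiles.summarize_sites(calls)
        parts = profiles.classify_sites(summ)
        assert parts["biallelic"] == ["s0"]
        assert parts["ase"] == ["s1"]

    def test_all_monoallelic_truth_sites_in_ase_partition(self, small_cfg, small_data):
        from ase_scan import synth
        from ase_scan.asecall import AllelicImbalance

        _, panel, truth, _ = small_data
        counts = synth.simulate_counts(panel, truth, small_cfg)
        res = AllelicImbalance(counts).fit()
        parts = profiles.classify_sites(res.site_summaries())
        tested = set(res.calls["site_id"])
        mono_sites = set(truth.loc[truth["class_label"] == "monoallelic", "site_id"])
        assert (mono_sites & tested) <= set(parts["ase"])


class TestDirection:
    def _sites(self, af_alt):
        return pd.DataFrame({"site_id": ["s0"], "af_alt": [af_alt]})

    def test_major_consistent(self):
        # alt is major (af 0.7); all five significant carriers favor alt
        calls = make_calls([("i%d" % i, "s0", 2, 28, True) for i in range(5)])
        calls["alt_count"] = [28] * 5
        out = profiles.direction_analysis(calls, self._sites(0.7))
        assert out.at[0, "direction"] == Direction.MAJOR_CONSISTENT.value

    def test_minor_consistent(self):
        calls = make_calls([("i%d" % i, "s0", 2, 28, True) for i in range(5)])
        out = profiles.direction_analysis(calls, self._sites(0.3))  # alt minor
        assert out.at[0, "direction"] == Direction.MINOR_CONSISTENT.value

    def test_mixed_with_one_dissenter(self):
        rows = [("i%d" % i, "s0", 2, 28, True) for i in range(4)]
        rows.append(("i4", "s0", 28, 2, True))
        out = profiles.direction_analysis(make_calls(rows), self._sites(0.7))
        assert out.at[0, "direction"] == Direction.MIXED.value

    def test_below_min_ase_not_evaluated(self):
        calls = make_calls([("i%d" % i, "s0", 2, 28, True) for i in range(4)])
        out = profiles.direction_analysis(calls, self._sites(0.7))
        assert out.at[0, "direction"] == Direction.NOT_EVALUATED.value

    def test_truth_planted_on_major_allele_recovered(self):
        from ase_scan import synth
        from ase_scan.asecall import AllelicImbalance
        from ase_scan.synth import SimulationConfig

        cfg = SimulationConfig(
            seed=23, n_sites=20, n_individuals=40, chrom_length=20_000,
            theta_classes=((0.9, 1.0),), favored_allele="major",
            base_error_rate=0.0, mean_coverage=40.0,
        )
        panel = synth.generate_panel(synth.generate_reference(cfg), cfg)
        truth = synth.assign_truth(panel, cfg)
        counts = synth.simulate_counts(panel, truth, cfg)
        res = AllelicImbalance(counts).fit()
        out = profiles.direction_analysis(res.calls, panel.sites)
        evaluated = out[out["direction"] != Direction.NOT_EVALUATED.value]
        assert len(evaluated) > 0
        assert (evaluated["direction"] == Direction.MAJOR_CONSISTENT.value).all()


class TestHistogram:
    def test_hand_counted_bins(self):
        summ = pd.DataFrame(
            {"site_id": ["a", "b", "c", "d"], "n_ase": [1, 1, 5, 60]}
        )
        hist = profiles.occurrence_histogram(summ)
        assert hist["bins"] == {"=1": 2, ">=5": 2, ">50": 1}
        assert hist["percent"] == {"=1": 50.00, ">=5": 50.00, ">50": 25.00}

    def test_empty_ase_set(self):
        summ = pd.DataFrame({"site_id": ["a"], "n_ase": [0]})
        hist = profiles.occurrence_histogram(summ)
        assert hist["n_ase_sites"] == 0
        assert hist["bins"] == {"=1": 0, ">=5": 0, ">50": 0}

    def test_random_summaries_match_tally_oracle(self):
        rng = np.random.default_rng(31)
        n_ase = rng.integers(0, 60, size=200)
        summ = pd.DataFrame({"site_id": [f"s{i}" for i in range(200)], "n_ase": n_ase})
        hist = profiles.occurrence_histogram(summ)
        ase = n_ase[n_ase >= 1]
        assert hist["bins"]["=1"] == int((ase == 1).sum())
        assert hist["bins"][">=5"] == int((ase >= 5).sum())
        assert hist["bins"][">50"] == int((ase > 50).sum())
        assert dict(hist["counts"]) == {
            int(v): int((ase == v).sum()) for v in sorted(set(ase))
        }


class TestChromosomeDistribution:
    def _sites(self, ids, chroms):
        return pd.DataFrame({"site_id": ids, "chrom": chroms, "af_alt": 0.3})

    def test_single_chromosome_half_ase(self):
        summ = pd.DataFrame(
            {"site_id": ["a", "b", "c", "d"], "n_ase": [1, 0, 2, 0]}
        )
        out = profiles.chromosome_distribution(summ, self._sites(list("abcd"), ["1"] * 4))
        assert len(out) == 1
        assert out.at[0, "pct_ase"] == 50.00
        assert out.at[0, "n_biallelic"] == 2

    def test_untested_chromosome_omitted_and_unknown_rejected(self):
        summ = pd.DataFrame({"site_id": ["a"], "n_ase": [1]})
        out = profiles.chromosome_distribution(summ, self._sites(["a"], ["2"]))
        assert out["chrom"].tolist() == ["2"]
        with pytest.raises(ValueError):
            profiles.chromosome_distribution(
                pd.DataFrame({"site_id": ["zz"], "n_ase": [1]}), self._sites(["a"], ["2"])
            )

    def test_restricted_scenario_never_exceeds_unrestricted(self):
        rng = np.random.default_rng(41)
        ids = [f"s{i}" for i in range(120)]
        summ = pd.DataFrame({"site_id": ids, "n_ase": rng.integers(0, 12, 120)})
        sites = self._sites(ids, rng.choice(["1", "2", "3"], 120))
        out = profiles.chromosome_distribution(summ, sites)
        assert (out["n_ase_ge_min"] <= out["n_ase"]).all()
        assert (out["pct_ase_ge_min"] <= out["pct_ase"]).all()
        # recount oracle per chromosome
        df = summ.assign(chrom=summ["site_id"].map(sites.set_index("site_id")["chrom"]))
        for _, row in out.iterrows():
            grp = df[df["chrom"] == row["chrom"]]
            assert row["n_tested"] == len(grp)
            assert row["n_ase"] == int((grp["n_ase"] >= 1).sum())


class TestIndividualProfile:
    def test_proportional_counts_r2_one(self):
        rows = []
        for i, n in enumerate([10, 20, 30, 40]):
            for j in range(n):
                rows.append((f"i{i}", f"s{i}_{j}", 25, 0, j < n // 2))
        _, r2 = profiles.individual_profile(make_calls(rows))
        assert r2 == pytest.approx(1.0)

    def test_constant_ase_r2_zero(self):
        rows = []
        for i, n in enumerate([10, 20, 30]):
            for j in range(n):
                rows.append((f"i{i}", f"s{i}_{j}", 25, 0, j < 5))
        _, r2 = profiles.individual_profile(make_calls(rows))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_closed_form(self):
        rng = np.random.default_rng(51)
        rows = []
        tallies = {}
        for i in range(6):
            n = int(rng.integers(5, 30))
            k = int(rng.integers(0, n + 1))
            tallies[f"i{i}"] = (n, k)
            for j in range(n):
                rows.append((f"i{i}", f"s{i}_{j}", 25, 0, j < k))
        tab, r2 = profiles.individual_profile(make_calls(rows))
        x = np.array([tallies[i][0] for i in tab["individual"]], float)
        y = np.array([tallies[i][1] for i in tab["individual"]], float)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        want = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r2 == pytest.approx(want, rel=1e-9)

    def test_fewer_than_three_individuals_no_fit(self):
        rows = [("i0", "s0", 25, 0, True), ("i1", "s1", 25, 0, False)]
        tab, r2 = profiles.individual_profile(make_calls(rows))
        assert len(tab) == 2 and r2 is None


class TestConservation:
    def test_site_and_individual_tallies_agree(self, small_cfg, small_data):
        from ase_scan import synth
        from ase_scan.asecall import AllelicImbalance

        _, panel, truth, _ = small_data
        counts = synth.simulate_counts(panel, truth, small_cfg)
        res = AllelicImbalance(counts).fit()
        summ = res.site_summaries()
        tab, _ = profiles.individual_profile(res.calls)
        assert summ["n_ase"].sum() == tab["n_ase_sites"].sum()
        assert summ["n_tested"].sum() == tab["n_tested_sites"].sum()

    def test_proportion_invariant_to_record_order(self):
        rows = [("i%d" % i, "s0", 30, 0, i % 3 == 0) for i in range(9)]
        a = profiles.summarize_site(make_calls(rows))
        b = profiles.summarize_site(make_calls(rows[::-1]))
        assert a["ase_proportion"] == b["ase_proportion"]


class TestTopSites:
    def test_ranking_order(self):
        summ = pd.DataFrame(
            {
                "site_id": ["a", "b", "c"],
                "n_tested": [46, 87, 46],
                "n_ase": [43, 79, 43],
                "ase_proportion": [93.48, 90.80, 93.48],
                "n_monoallelic": [0, 0, 0],
                "monoallelic_proportion_of_ase": [0.0, 0.0, 0.0],
                "is_ase_site": [True, True, True],
            }
        )
        top = profiles.top_sites(summ, 3)
        assert top["site_id"].tolist() == ["b", "a", "c"]
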