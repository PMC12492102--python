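"""Clade contrast scans and presence/absence classification rules."""

import numpy as np
import pandas as pd
import pytest

from hymevol import (
    CladeResolution,
    GeneFamilyTurnover,
    SimConfig,
    differential_loss,
    parse_newick,
    presence_classes,
    rapid_enrichment,
    simulate_counts,
    size_contrast,
)


def fake_clade(name, n_branches):
    ids = frozenset(f"{name}_b{i}" for i in range(n_branches))
    return CladeResolution(name, frozenset(), ids, float(n_branches))


def events_from_rapid(clades_rapid: dict):
    """Build a long event table from {clade: {og: n_rapid_branches}}."""
    rows = []
    for clade, per_og in clades_rapid.items():
        for i, b in enumerate(sorted(clade.branch_ids)):
            for og, k in per_og.items():
                rapid = i < k
                rows.append((og, b, 1 if rapid else 0, 0.01 if rapid else 1.0, rapid))
    return pd.DataFrame(rows, columns=["og_id", "branch_id", "delta", "p_event", "rapid"])


class TestRapidEnrichment:
    def test_haldane_table_example(self):
        a, b = fake_clade("A", 40), fake_clade("B", 30)
        ev = events_from_rapid({a: {"og1": 5}, b: {"og1": 0}})
        rep = rapid_enrichment(ev, a, b)
        row = rep.table.loc["og1"]
        assert row["odds_ratio"] == pytest.approx(9.4507, abs=1e-3)
        assert row["direction"] == "A"

    def test_equal_fractions_not_enriched(self):
        a, b = fake_clade("A", 40), fake_clade("B", 30)
        ev = events_from_rapid({a: {"og1": 4}, b: {"og1": 3}})
        rep = rapid_enrichment(ev, a, b)
        assert rep.table.loc["og1", "odds_ratio"] == pytest.approx(1.0)
        assert not rep.table.loc["og1", "decision"]

    def test_untested_families_excluded_before_bh(self):
        a, b = fake_clade("A", 10), fake_clade("B", 10)
        ev = events_from_rapid({a: {"og1": 3, "og2": 0}, b: {"og1": 0, "og2": 0}})
        rep = rapid_enrichment(ev, a, b)
        assert list(rep.table.index) == ["og1"]
        assert "og2" in rep.skipped

    def test_overlapping_clades_rejected(self):
        a = fake_clade("A", 5)
        with pytest.raises(ValueError, match="share"):
            rapid_enrichment(pd.DataFrame(columns=["og_id", "branch_id", "rapid"]), a, a)

    def test_swap_maps_or_to_reciprocal(self):
        a, b = fake_clade("A", 40), fake_clade("B", 30)
        ev = events_from_rapid({a: {"og1": 5}, b: {"og1": 2}})
        fwd = rapid_enrichment(ev, a, b).table.loc["og1"]
        rev = rapid_enrichment(ev, b, a).table.loc["og1"]
        assert rev["odds_ratio"] == pytest.approx(1 / fwd["odds_ratio"])
        assert rev["p"] == pytest.approx(fwd["p"])


class TestRateContrast:
    @pytest.fixture
    def six_leaf_model(self):
        # two 3-leaf clades, all terminal branches 10 My
        tree = parse_newick(
            "((a1:10,(a2:10,a3:10):5):5,(b1:10,(b2:10,b3:10):5):5);"
        )
        a = CladeResolution(
            "A", frozenset({"a1", "a2", "a3"}),
            frozenset(tree.branch_id[tree._name_to_node[n]] for n in ("a1", "a2", "a3")),
            30.0)
        b = CladeResolution(
            "B", frozenset({"b1", "b2", "b3"}),
            frozenset(tree.branch_id[tree._name_to_node[n]] for n in ("b1", "b2", "b3")),
            30.0)
        return tree, a, b

    def test_exact_one_sided_example(self, six_leaf_model):
        tree, a, b = six_leaf_model
        deltas = pd.DataFrame(0, index=["og"], columns=tree.branch_ids)
        for name, d in [("a1", 10), ("a2", 8), ("a3", 9), ("b1", 1), ("b2", 0), ("b3", 2)]:
            deltas.loc["og", tree.branch_id[tree._name_to_node[name]]] = d
        from hymevol import TurnoverResults

        long = deltas.stack().reset_index()
        long.columns = ["og_id", "branch_id", "delta"]
        res = TurnoverResults.from_events(tree, long)
        rep = res.rate_contrast(a, b)
        # rates A = (1.0, 0.8, 0.9), B = (0.1, 0, 0.2): U = 9, exact p = 1/20
        assert rep.table.loc["og", "p"] == pytest.approx(0.05)
        assert rep.table.loc["og", "direction"] == "A"

    def test_identical_rates_never_significant(self, six_leaf_model):
        tree, a, b = six_leaf_model
        deltas = pd.DataFrame(2, index=["og"], columns=tree.branch_ids)
        from hymevol import TurnoverResults

        long = deltas.stack().reset_index()
        long.columns = ["og_id", "branch_id", "delta"]
        rep = TurnoverResults.from_events(tree, long).rate_contrast(a, b)
        assert rep.table.loc["og", "p"] >= 0.5
        assert not rep.table.loc["og", "decision"]


class TestSizeContrast:
    def test_exact_example(self):
        counts = pd.DataFrame(
            {"s1": [10], "s2": [12], "s3": [9], "t1": [1], "t2": [0], "t3": [2]},
            index=["og"],
        )
        rep = size_contrast(counts, ["s1", "s2", "s3"], ["t1", "t2", "t3"])
        assert rep.table.loc["og", "p"] == pytest.approx(0.05)

    def test_equal_counts_not_significant(self):
        counts = pd.DataFrame({f"x{i}": [3] for i in range(6)}, index=["og"])
        rep = size_contrast(counts, [f"x{i}" for i in range(3)],
                            [f"x{i}" for i in range(3, 6)])
        # exact enumeration: every labeling ties, so P(U >= U_obs) = 1
        assert rep.table.loc["og", "p"] == pytest.approx(1.0)
        assert not rep.table.loc["og", "decision"]

    def test_strong_separation_survives_fdr(self):
        rng = np.random.default_rng(0)
        zeros = {f"a{i}": [0] * 5 for i in range(10)}
        highs = {f"b{i}": list(rng.integers(5, 9, size=5)) for i in range(10)}
        counts = pd.DataFrame({**highs, **zeros},
                              index=[f"og{k}" for k in range(5)])
        rep = size_contrast(counts, [f"b{i}" for i in range(10)],
                            [f"a{i}" for i in range(10)])
        assert (rep.table["p_adj"] < 0.001).all()

    def test_species_in_both_groups_rejected(self):
        counts = pd.DataFrame({"x": [1], "y": [1], "z": [1], "w": [1]}, index=["og"])
        with pytest.raises(ValueError, match="both groups"):
            size_contrast(counts, ["x", "y"], ["y", "z"])


class TestPresenceClasses:
    @pytest.fixture
    def counts(self):
        out_sp = [f"o{i}" for i in range(10)]
        test_sp = [f"t{i}" for i in range(20)]
        data = {}
        for s in out_sp:
            data[s] = {"missing_fam": 0, "boundary_fam": 0, "novel_fam": 0}
        for i, s in enumerate(out_sp):
            data[s]["missing_fam"] = 1 if i < 8 else 0  # 8/10 = 0.8 > 0.7
            data[s]["boundary_fam"] = 1 if i < 7 else 0  # 7/10 = 0.7, not > 0.7
        for s in test_sp:
            data[s] = {"missing_fam": 0, "boundary_fam": 0, "novel_fam": 0}
        for i, s in enumerate(test_sp):
            data[s]["novel_fam"] = 1 if i < 15 else 0  # 15/20 = 0.75 > 0.7
        return pd.DataFrame(data), test_sp, out_sp

    def test_missing_and_novel_with_strict_boundaries(self, counts):
        df, test_sp, out_sp = counts
        missing, novel = presence_classes(df, test_sp, out_sp)
        assert missing == ["missing_fam"]
        assert novel == ["novel_fam"]

    def test_column_order_invariance(self, counts):
        df, test_sp, out_sp = counts
        shuffled = df[list(reversed(df.columns))]
        assert presence_classes(shuffled, test_sp, out_sp) == presence_classes(
            df, test_sp, out_sp)

    def test_empty_group_rejected(self, counts):
        df, test_sp, _ = counts
        with pytest.raises(ValueError):
            presence_classes(df, test_sp, [])


class TestDifferentialLoss:
    def make_counts(self, lost_a, n_a, lost_o, n_o):
        data = {}
        for i in range(n_a):
            data[f"p{i}"] = {"fam": 0 if i < lost_a else 2}
        for i in range(n_o):
            data[f"q{i}"] = {"fam": 0 if i < lost_o else 2}
        return pd.DataFrame(data), [f"p{i}" for i in range(n_a)], [f"q{i}" for i in range(n_o)]

    def test_paper_thresholds(self):
        df, a, o = self.make_counts(12, 50, 1, 81)  # 0.24 > 0.2; 0.0123 <= 0.02
        assert differential_loss(df, a, o) == ["fam"]

    def test_clade_boundary_strict(self):
        df, a, o = self.make_counts(10, 50, 1, 81)  # exactly 0.20: excluded
        assert differential_loss(df, a, o) == []

    def test_other_boundary_inclusive_then_exceeded(self):
        df, a, o = self.make_counts(12, 50, 2, 81)  # 0.0247 > 0.02: excluded
        assert differential_loss(df, a, o) == []
        df, a, o = self.make_counts(12, 50, 1, 50)  # 0.02 exactly: allowed
        assert differential_loss(df, a, o) == ["fam"]


class TestNullCalibration:
    def test_enrichment_null_rate_bounded(self, demo_tree):
        # no clade effects: enrichment scan flags (almost) nothing
        tree, clades = demo_tree
        cfg = SimConfig(seed=12, n_families=800)
        counts, _ = simulate_counts(tree, cfg)
        res = GeneFamilyTurnover(tree, counts).fit()
        rep = res.rapid_enrichment(clades["Parasitoida"], clades["Aculeata"])
        assert rep.n_significant / max(len(rep.table), 1) <= 0.07
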