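"""Lineage ordering, epoch clustering, and per-strain effect classification."""

import math

import numpy as np
import pytest

import citfit as cf
from citfit.io import read_tree

from conftest import constant_effect, make_effect


def _records_from(names_mus, sd=0.003, seed=0, gen_step=1000):
    return [
        cf.StrainRecord(name, i * gen_step, make_effect(name, mu, sd=sd, seed=seed))
        for i, (name, mu) in enumerate(names_mus)
    ]


class TestLineageOrdering:
    def test_ladder_tree_all_on_path(self, mimic_bundle):
        tree = read_tree(mimic_bundle["newick"])
        terminal = mimic_bundle["metadata"].strain.iloc[-1]
        ordering = cf.main_lineage_order(
            mimic_bundle["records"], tree=tree, terminal=terminal
        )
        assert len(ordering.ordered) == len(mimic_bundle["records"])
        assert not ordering.excluded
        gens = [r.generation for r in ordering.ordered]
        assert gens == sorted(gens)

    def test_deep_private_branch_excluded(self):
        # OFF hangs 6000 generations off the backbone between A and B
        newick = "((A:1,(OFF:6000,(B:1,C:1):500):1000):1000);"
        tree = read_tree(newick)
        records = [
            cf.StrainRecord(s, g, constant_effect(s, 1.0))
            for s, g in [("A", 0), ("OFF", 5000), ("B", 10_000), ("C", 10_000)]
        ]
        ordering = cf.main_lineage_order(records, tree=tree, terminal="C")
        assert [r.strain for r in ordering.ordered] == ["A", "B", "C"]
        (rec, reason), = ordering.excluded
        assert rec.strain == "OFF"
        assert "divergence" in reason

    def test_divergence_from_metadata_without_tree(self):
        records = [
            cf.StrainRecord("A", 0, constant_effect("A", 1.0), divergence=100),
            cf.StrainRecord("B", 5000, constant_effect("B", 1.0), divergence=7000),
        ]
        ordering = cf.main_lineage_order(records)
        assert [r.strain for r in ordering.ordered] == ["A"]
        assert ordering.excluded[0][0].strain == "B"

    def test_manual_exclusion_list(self):
        records = [
            cf.StrainRecord("A", 0, constant_effect("A", 1.0)),
            cf.StrainRecord("B", 1000, constant_effect("B", 1.0)),
        ]
        ordering = cf.main_lineage_order(records, exclude_strains={"B"})
        assert [r.strain for r in ordering.ordered] == ["A"]
        assert ordering.excluded[0][1] == "excluded by configuration"

    def test_missing_terminal_rejected(self):
        tree = read_tree("((A:1,B:1):1);")
        with pytest.raises(ValueError, match="terminal"):
            cf.main_lineage_order(
                [cf.StrainRecord("A", 0, constant_effect("A", 1.0))],
                tree=tree, terminal="ZZZ",
            )

    def test_strain_absent_from_tree_excluded(self):
        tree = read_tree("((A:1,B:1):1);")
        records = [
            cf.StrainRecord("A", 0, constant_effect("A", 1.0)),
            cf.StrainRecord("GHOST", 100, constant_effect("GHOST", 1.0)),
        ]
        ordering = cf.main_lineage_order(records, tree=tree, terminal="B")
        assert [r.strain for r in ordering.ordered] == ["A"]
        assert ordering.excluded[0][1] == "absent from tree"


class TestClustering:
    def test_identical_draws_single_group(self):
        records = [
            cf.StrainRecord(f"S{i}", 1000 * i, constant_effect(f"S{i}", 1.02))
            for i in range(5)
        ]
        res = cf.cluster_adjacent(cf.LineageOrdering(ordered=records))
        assert len(res.groups) == 1
        assert res.groups[0].strains == [f"S{i}" for i in range(5)]
        assert not res.intermediates

    def test_mimic_lineage_epoch_recovery(self, mimic_clusters, mimic_bundle):
        """The four-epoch synthetic lineage is recovered with its boundaries."""
        res = mimic_clusters
        assert [len(g.members) for g in res.groups] == [3, 3, 3, 3]
        truth = mimic_bundle["metadata"].set_index("strain")["epoch"]
        for i, g in enumerate(res.groups):
            assert all(truth[s] == i for s in g.strains)

    def test_recovery_rate_over_seeds(self):
        """Boundary recovery >= 95% over 100 seeded study-mimic realizations."""
        ok = 0
        for seed in range(100):
            meta, _, comp = cf.simulate_lineage_study(cf.LineageSimSpec(seed=seed))
            effects = cf.combined_effects_from_table(comp, b_reps=10_000, seed=seed)
            records = [
                cf.StrainRecord(r.strain, r.generation, effects[r.strain])
                for r in meta.itertuples()
            ]
            res = cf.cluster_adjacent(cf.LineageOrdering(ordered=records))
            if [len(g.members) for g in res.groups] == [3, 3, 3, 3] and (
                not res.intermediates
            ):
                ok += 1
        assert ok >= 95

    def test_partition_and_separation_invariants(self, mimic_clusters, mimic_bundle):
        res = mimic_clusters
        clustered = [s for g in res.groups for s in g.strains]
        clustered += [r.strain for r in res.intermediates]
        assert sorted(clustered) == sorted(mimic_bundle["metadata"].strain)
        # groups are contiguous and ordered in time
        spans = [(g.gen_start, g.gen_end) for g in res.groups]
        assert spans == sorted(spans)
        assert all(e1 < s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))
        # consecutive groups differ significantly on pooled effects
        from citfit.lineage import _group_boot
        for g1, g2 in zip(res.groups, res.groups[1:]):
            p = cf.pairwise_difference_test(_group_boot(g1), _group_boot(g2)).p
            assert p <= 0.05

    def test_determinism(self, mimic_bundle):
        records = mimic_bundle["records"]
        a = cf.cluster_adjacent(cf.LineageOrdering(ordered=list(records)))
        b = cf.cluster_adjacent(cf.LineageOrdering(ordered=list(records)))
        assert [g.strains for g in a.groups] == [g.strains for g in b.groups]
        assert [g.pooled_point for g in a.groups] == [g.pooled_point for g in b.groups]

    def test_wide_ci_boundary_strain_is_intermediate(self):
        """A strain between two distinct groups, compatible with both, is
        assigned to neither (the published ZDB310 situation)."""
        records = _records_from(
            [("A0", 1.00), ("A1", 1.00), ("A2", 1.00)]
        )
        records.append(
            cf.StrainRecord("MID", 3500, make_effect("MID", 1.02, sd=0.025))
        )
        records += [
            cf.StrainRecord(f"B{i}", 4000 + 1000 * i, make_effect(f"B{i}", 1.04))
            for i in range(3)
        ]
        res = cf.cluster_adjacent(cf.LineageOrdering(ordered=records))
        assert [g.strains for g in res.groups] == [["A0", "A1", "A2"],
                                                   ["B0", "B1", "B2"]]
        assert [r.strain for r in res.intermediates] == ["MID"]

    def test_empty_ordering_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cf.cluster_adjacent(cf.LineageOrdering(ordered=[]))


class TestGroupwiseEffect:
    def test_single_member_equals_member(self):
        rec = cf.StrainRecord("A", 0, make_effect("A", 1.02))
        point, ci, _ = cf.groupwise_effect([rec])
        assert point == rec.effect.w_combined
        assert ci == (rec.effect.boot.ci_lo, rec.effect.boot.ci_hi)

    def test_constant_draw_members_average_exactly(self):
        recs = [
            cf.StrainRecord("A", 0, constant_effect("A", 1.02)),
            cf.StrainRecord("B", 100, constant_effect("B", 1.04)),
        ]
        point, ci, _ = cf.groupwise_effect(recs)
        assert point == pytest.approx(1.03)
        assert ci == (pytest.approx(1.03), pytest.approx(1.03))

    def test_ci_shrinks_like_root_k_members(self):
        """Three members with draws N(1.024, 0.005^2): half-width ~ 1.96*0.005/sqrt(3)."""
        rng = np.random.default_rng(3)
        recs = []
        for name in ("A", "B", "C"):
            draws = rng.normal(1.024, 0.005, 20_000)
            boot = cf.BootstrapResult(
                point=1.024, b_reps=draws.size, ci_level=0.95,
                ci_lo=float(np.quantile(draws, 0.025)),
                ci_hi=float(np.quantile(draws, 0.975)), draws=draws,
            )
            recs.append(cf.StrainRecord(
                name, 0, cf.CombinedEffect(name, 1.024, boot, 10, 10)))
        _, (lo, hi), _ = cf.groupwise_effect(recs)
        expected = 1.96 * 0.005 / math.sqrt(3)
        assert (hi - lo) / 2 == pytest.approx(expected, rel=0.05)


class TestClassification:
    def test_degenerate_categories(self):
        recs = [
            cf.StrainRecord("UP", 0, constant_effect("UP", 1.05)),
            cf.StrainRecord("DOWN", 0, constant_effect("DOWN", 0.95)),
            cf.StrainRecord("CRASH", 0, constant_effect("CRASH", 0.75)),
        ]
        cats = {c.strain: c for c in cf.classify_effects(recs)}
        assert cats["UP"].category == "significant_benefit"
        assert cats["DOWN"].category == "significant_deficit"
        assert not cats["DOWN"].severe
        assert cats["CRASH"].category == "significant_deficit"
        assert cats["CRASH"].severe

    def test_neutral_with_benefit_not_excluded(self):
        """A noisy neutral strain cannot rule out a >= 1% benefit; a precise
        one can."""
        def centered(name, sd, seed):
            rng = np.random.default_rng(seed)
            draws = 1.0 + rng.normal(0, sd, 10_000)
            boot = cf.BootstrapResult(
                point=1.0, b_reps=draws.size, ci_level=0.95,
                ci_lo=float(np.quantile(draws, 0.025)),
                ci_hi=float(np.quantile(draws, 0.975)), draws=draws,
            )
            return cf.StrainRecord(name, 0, cf.CombinedEffect(name, 1.0, boot, 10, 10))

        noisy = centered("N", 0.01, 5)
        precise = centered("P", 0.002, 6)
        cats = {c.strain: c for c in cf.classify_effects([noisy, precise])}
        assert cats["N"].category == "neutral"
        assert cats["N"].benefit_ge_1pct_not_excluded
        assert cats["P"].category == "neutral"
        assert not cats["P"].benefit_ge_1pct_not_excluded

    def test_mimic_lineage_classification(self, mimic_bundle):
        """Anti-potentiated epoch strains classify as deficits, the final
        epoch as benefits, under the study-mimic noise level."""
        cats = {c.strain: c for c in cf.classify_effects(mimic_bundle["records"])}
        truth = mimic_bundle["metadata"].set_index("strain")["true_effect"]
        for strain, eff in truth.items():
            if eff <= -0.05:
                assert cats[strain].category == "significant_deficit"
            elif eff >= 0.017:
                assert cats[strain].category == "significant_benefit"
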