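"""Diet index math: condensing, exclusions, the two estimators, IRI variants."""

import importlib.resources

import numpy as np
import pandas as pd
import pytest

from trophicoverlap import diet, io, published, synthetic
from trophicoverlap.schemas import CategoryMap, ValidationError

from conftest import item, make_stomach


@pytest.fixture
def demo_map():
    path = importlib.resources.files("trophicoverlap") / "configs" / "demo_category_map.csv"
    return io.read_category_map(str(path))


class TestCondense:
    def test_identity_map_aggregates_within_fish(self):
        s = make_stomach(items=[item("Crab", 1, 0.3), item("Crab", 2, 0.2)])
        cmap = CategoryMap({"Crab": "Crab"})
        (out,) = diet.condense_categories([s], cmap)
        assert len(out.items) == 1
        assert out.items[0].count == 3
        assert out.items[0].weight == pytest.approx(0.5)

    def test_two_taxa_merge_additively(self):
        s = make_stomach(items=[item("portunus spp.", 1, 0.30), item("xanthidae", 1, 0.20)])
        cmap = CategoryMap({"portunus spp.": "Crab", "xanthidae": "Crab"})
        (out,) = diet.condense_categories([s], cmap)
        assert out.items[0].taxon == "Crab"
        assert out.items[0].weight == pytest.approx(0.50)

    def test_unmapped_taxon_named_in_error(self):
        s = make_stomach(items=[item("mystery worm")])
        with pytest.raises(ValidationError, match="mystery worm"):
            diet.condense_categories([s], CategoryMap({"crab": "Crab"}))

    def test_demo_map_condenses_46_taxa_to_28_categories(self, demo_map):
        assert len(demo_map) == 46
        samples = [make_stomach(fish_id=f"F{i}", items=[item(t)])
                   for i, t in enumerate(demo_map.mapping)]
        out = diet.condense_categories(samples, demo_map)
        cats = {i.taxon for s in out for i in s.items}
        assert len(cats) == 28

    def test_flags_partition_aggregation(self):
        s = make_stomach(items=[item("portunus spp.", 1, 0.3),
                                item("xanthidae", 1, 0.2, bait=True)])
        cmap = CategoryMap({"portunus spp.": "Crab", "xanthidae": "Crab"})
        (out,) = diet.condense_categories([s], cmap)
        assert len(out.items) == 2  # bait kept separate from identifiable Crab


class TestFilter:
    def test_bait_only_fish_retained_without_items(self):
        s = make_stomach(items=[item("bait", bait=True)])
        (out,) = diet.filter_contents([s])
        assert out.items == () and not out.has_identifiable_prey

    def test_both_flags_false_is_identity(self):
        s = make_stomach(items=[item("crab"), item("chyme", unid=True)])
        (out,) = diet.filter_contents([s], exclude_bait=False, exclude_unidentifiable=False)
        assert out == s

    def test_unidentifiable_mass_fraction_removed(self):
        # identifiable 23.9 g + chyme 76.1 g: post-filter weight is 23.9% of total
        s = make_stomach(items=[item("crab", 1, 23.9), item("chyme", 0, 76.1, unid=True)])
        (out,) = diet.filter_contents([s])
        pre = sum(i.weight for i in s.items)
        post = sum(i.weight for i in out.items)
        assert post / pre == pytest.approx(0.239)


class TestDietSummary:
    def test_occurrence_is_fraction_of_stomachs_with_prey(self):
        samples = [make_stomach(f"F{i}", items=[item("Crab" if i < 2 else "Fish")])
                   for i in range(4)]
        summ = diet.diet_summary(samples)
        assert summ.pctO["Crab"] == pytest.approx(50.0)

    def test_single_stomach_single_category_degenerate(self):
        summ = diet.diet_summary([make_stomach(items=[item("Fish", 2, 1.0)])])
        for v in (summ.pctN, summ.pctW, summ.pctO, summ.pctIRI):
            assert v["Fish"] == pytest.approx(100.0)

    def test_pooled_vs_mean_of_stomachs_hand_example(self):
        # A: 3 of X (0.3 g); B: 1 of X (0.1 g) + 1 of Y (0.3 g)
        samples = [
            make_stomach("A", items=[item("X", 3, 0.3)]),
            make_stomach("B", items=[item("X", 1, 0.1), item("Y", 1, 0.3)]),
        ]
        pooled = diet.diet_summary(samples, estimator="pooled")
        assert pooled.pctN["X"] == pytest.approx(80.0)
        assert pooled.pctW["X"] == pytest.approx(100 * 0.4 / 0.7)
        assert pooled.pctO["X"] == pytest.approx(100.0)
        mos = diet.diet_summary(samples, estimator="mean_of_stomachs")
        assert mos.pctN["X"] == pytest.approx(75.0)  # (100 + 50) / 2
        assert mos.pctN_se["X"] == pytest.approx(np.std([100, 50], ddof=1) / np.sqrt(2))

    def test_no_identifiable_prey_is_error(self):
        with pytest.raises(ValidationError, match="identifiable"):
            diet.diet_summary([make_stomach(items=[])])

    def test_pooled_percentages_sum_to_100(self):
        rng = np.random.default_rng(11)
        samples = [
            make_stomach(f"F{i}", items=[
                item(c, int(rng.integers(1, 5)), float(rng.uniform(0.01, 2)))
                for c in rng.choice(list("ABCDE"), size=rng.integers(1, 4), replace=False)
            ])
            for i in range(30)
        ]
        summ = diet.diet_summary(samples)
        for v in (summ.pctN, summ.pctW, summ.pctIRI):
            assert v.sum() == pytest.approx(100.0, abs=1e-9)

    def test_order_and_row_splitting_invariance(self):
        base = [
            make_stomach("A", items=[item("X", 3, 0.3)]),
            make_stomach("B", items=[item("X", 1, 0.1), item("Y", 1, 0.3)]),
        ]
        split = [
            make_stomach("B", items=[item("Y", 1, 0.3), item("X", 1, 0.1)]),
            make_stomach("A", items=[item("X", 1, 0.1), item("X", 2, 0.2)]),
        ]
        a, b = diet.diet_summary(base), diet.diet_summary(split)
        pd.testing.assert_series_equal(a.pctN, b.pctN)
        pd.testing.assert_series_equal(a.pctW, b.pctW, atol=1e-12)
        pd.testing.assert_series_equal(a.pctO, b.pctO)

    def test_merging_categories_never_decreases_shares(self):
        rng = np.random.default_rng(5)
        samples = [
            make_stomach(f"F{i}", items=[
                item(c, int(rng.integers(1, 4)), float(rng.uniform(0.05, 1)))
                for c in rng.choice(list("ABCD"), size=rng.integers(1, 4), replace=False)
            ])
            for i in range(20)
        ]
        before = diet.diet_summary(samples)
        merged = diet.condense_categories(
            samples, CategoryMap({"A": "AB", "B": "AB", "C": "C", "D": "D"}))
        after = diet.diet_summary(merged)
        for metric in ("pctN", "pctW", "pctO"):
            merged_val = getattr(after, metric)["AB"]
            assert merged_val >= max(getattr(before, metric)[["A", "B"]]) - 1e-12

    def test_zero_weight_item_contributes_to_n_and_o_only(self):
        samples = [make_stomach(items=[item("Mite", 2, 0.0), item("Fish", 1, 1.0)])]
        summ = diet.diet_summary(samples)
        assert summ.pctN["Mite"] == pytest.approx(200 / 3)
        assert summ.pctW["Mite"] == 0.0
        assert summ.pctO["Mite"] == 100.0


class TestIRI:
    def test_zero_occurrence_zero_iri_both_variants(self):
        n = pd.Series({"a": 50.0, "b": 50.0})
        o = pd.Series({"a": 100.0, "b": 0.0})
        for variant in diet.IRI_VARIANTS:
            iri, _ = diet.compute_iri(n, n, o, variant)
            assert iri["b"] == 0.0

    def test_additive_variant_reproduces_printed_pctiri_ratios(self):
        """The printed %IRI column is only consistent with the classical
        additive (%N+%W)x%O form, not the multiplicative one."""
        t = published.ALL_SITES
        n, w, o = (t[(m, "RS")] for m in ("pctN", "pctW", "pctO"))
        iri_add, _ = diet.compute_iri(n, w, o, "additive")
        printed = t[("pctIRI", "RS")]
        for cat in ("Gastropod", "Crab"):
            recon = iri_add[cat] / iri_add["Fish"]
            assert recon == pytest.approx(printed[cat] / printed["Fish"], rel=0.01)
        iri_mul, _ = diet.compute_iri(n, w, o, "multiplicative")
        mul_ratio = iri_mul["Gastropod"] / iri_mul["Fish"]
        assert abs(mul_ratio / (printed["Gastropod"] / printed["Fish"]) - 1) > 0.10

    def test_additive_hand_values(self):
        # Fish (27.61+36.19)*42.11 and Gastropod (16.72+16.01)*26.32
        t = published.ALL_SITES
        iri, _ = diet.compute_iri(t[("pctN", "RS")], t[("pctW", "RS")],
                                  t[("pctO", "RS")], "additive")
        assert iri["Fish"] == pytest.approx(2686.6, abs=0.5)
        assert iri["Gastropod"] == pytest.approx(861.5, abs=0.5)

    def test_all_zero_iri_is_error(self):
        z = pd.Series({"a": 0.0, "b": 0.0})
        with pytest.raises(ValidationError, match="zero"):
            diet.compute_iri(z, z, z)


def test_pooled_pctw_converges_to_generator_truth():
    """With no overdispersion, chyme, or covariate structure, pooled %W
    approaches the generator's base composition (within 1 point at n=2000)."""
    params = synthetic.DietGeneratorParams(
        concentration=np.inf,
        unid_fraction={"RS": 0.0, "VS": 0.0},
        empty_prob={"RS": 0.0, "VS": 0.0},
        effects={},
    )
    df = synthetic.simulate_stomachs(params, {"RS": 2000}, seed=42)
    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        p = os.path.join(d, "s.csv")
        df.to_csv(p, index=False)
        samples = io.read_stomach_table(p)
    summ = diet.diet_summary(diet.filter_contents(samples))
    truth = pd.Series(100 * np.asarray(params.base["RS"]), index=params.categories)
    dev = (summ.pctW.reindex(truth.index, fill_value=0.0) - truth).abs().max()
    assert dev < 1.0 * np.sqrt(5000 / 2000)  # 1-point bound at n=5000, 1/sqrt(n) scaled
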