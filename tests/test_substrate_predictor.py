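"""Substrate-class rules, TBDT record derivation, and the category table."""

import numpy as np
import pytest

from pulquant.feature_classifier import FeatureKind, TbdtCall
from pulquant.pul_caller import call_clusters
from pulquant.substrate_predictor import (
    NO_CAZYME,
    NO_SUBSTRATE_PREDICTED,
    SubstrateRule,
    SubstrateRuleTable,
    TbdtCategory,
    TbdtRecord,
    annotate_tbdts,
    derive_category,
    predict_substrate,
    round1,
    tabulate_categories,
)

from conftest import make_contig

TBDT = (FeatureKind.TBDT,)
SUSC = (FeatureKind.TBDT, FeatureKind.SUSC_LIKE)
CAZ = (FeatureKind.CAZYME,)
RULES = SubstrateRuleTable.default()


def pul_with(families, susc=False):
    markers = {1: (SUSC if susc else TBDT, frozenset())}
    for i, fam in enumerate(families):
        markers[2 + i] = (CAZ, frozenset({fam}))
    genes = make_contig(markers, 12)
    (cluster,) = call_clusters(genes, 7)
    return cluster


class TestPredictSubstrate:
    @pytest.mark.parametrize(
        "families,expected",
        [
            (["GH16", "GH17"], "laminarin"),
            (["PL6", "PL7"], "alginate"),
            (["GH13", "GH31"], "alpha_glucan"),
            (["GH92", "GH38"], "mannose_rich"),
            (["GH10", "GH43"], "xylose_rich"),
            (["GH29", "GH92"], "fmx"),        # fucose + mannose indicator groups
            (["GH95", "GH43"], "fmx"),        # fucose + xylose indicator groups
            (["GH13", "GH16"], NO_SUBSTRATE_PREDICTED),  # two eligible classes
            (["GH13", "GH29", "GH92"], NO_SUBSTRATE_PREDICTED),
            (["GH29"], NO_SUBSTRATE_PREDICTED),  # single-group fucose evidence
            (["GH5"], NO_SUBSTRATE_PREDICTED),   # no indicator at all
        ],
    )
    def test_default_rules(self, families, expected):
        assert predict_substrate(pul_with(families), RULES) == expected

    def test_scores_match_brute_force_over_classes(self):
        pul = pul_with(["GH16", "GH17", "GH13"])
        families = pul.family_set
        eligible = [
            name for name, rule in RULES.rules.items() if rule.eligible(families)
        ]
        expected = eligible[0] if len(eligible) == 1 else NO_SUBSTRATE_PREDICTED
        assert predict_substrate(pul, RULES) == expected

    def test_empty_family_set_rejected(self):
        cluster = pul_with(["GH16"])
        cluster.cazyme_families.clear()
        with pytest.raises(ValueError, match="no CAZyme"):
            predict_substrate(cluster, RULES)

    def test_gene_order_irrelevant(self):
        pul = pul_with(["GH16", "GH17"])
        shuffled = pul
        shuffled.gene_span = list(reversed(pul.gene_span))
        assert predict_substrate(shuffled, RULES) == "laminarin"

    def test_adding_veto_family_is_monotone(self):
        """Growing a veto set never gains that class new PULs."""
        puls = [pul_with(f) for f in (["GH16", "GH17"], ["GH16", "GH30"], ["GH17"])]
        base = SubstrateRuleTable.default()
        vetoed = SubstrateRuleTable.default()
        vetoed.rules["laminarin"] = SubstrateRule(
            indicator_families={"GH16", "GH17", "GH30"}, veto_families={"GH30"}
        )
        n_base = sum(predict_substrate(p, base) == "laminarin" for p in puls)
        n_veto = sum(predict_substrate(p, vetoed) == "laminarin" for p in puls)
        assert n_veto <= n_base


class TestAnnotateTbdts:
    def test_categories_follow_cluster_context(self):
        genes = make_contig(
            {
                1: (SUSC, frozenset()),
                3: (CAZ, frozenset({"GH16"})),
                4: (CAZ, frozenset({"GH17"})),
                # isolated susC-like TBDT, no CAZyme context
                20: (SUSC, frozenset()),
            },
            30,
        )
        clusters = call_clusters(genes, 7)
        calls = {
            genes[1].gene_id: TbdtCall(True, True),
            genes[20].gene_id: TbdtCall(True, True),
        }
        substrates = {clusters[0].cluster_id: "laminarin"}
        records = {r.gene_id: r for r in annotate_tbdts(calls, clusters, substrates)}
        assert records[genes[1].gene_id].category is TbdtCategory.SUSC_SUBSTRATE
        assert records[genes[20].gene_id].substrate == NO_CAZYME
        assert records[genes[20].gene_id].category is TbdtCategory.SUSC_NO_CAZYME

    def test_ambiguous_pul_gives_cazyme_no_substrate(self):
        genes = make_contig(
            {1: (TBDT, frozenset()), 2: (CAZ, frozenset({"GH13"})), 3: (CAZ, frozenset({"GH16"}))},
            10,
        )
        clusters = call_clusters(genes, 7)
        calls = {genes[1].gene_id: TbdtCall(True, False)}
        substrates = {clusters[0].cluster_id: NO_SUBSTRATE_PREDICTED}
        (rec,) = annotate_tbdts(calls, clusters, substrates)
        assert rec.category is TbdtCategory.NONSUSC_CAZYME_NO_SUBSTRATE

    @pytest.mark.parametrize(
        "susc,substrate,expected",
        [
            (True, "laminarin", TbdtCategory.SUSC_SUBSTRATE),
            (True, NO_SUBSTRATE_PREDICTED, TbdtCategory.SUSC_CAZYME_NO_SUBSTRATE),
            (True, NO_CAZYME, TbdtCategory.SUSC_NO_CAZYME),
            (False, "fmx", TbdtCategory.NONSUSC_SUBSTRATE),
            (False, NO_SUBSTRATE_PREDICTED, TbdtCategory.NONSUSC_CAZYME_NO_SUBSTRATE),
            (False, NO_CAZYME, TbdtCategory.NONSUSC_NO_CAZYME),
        ],
    )
    def test_category_is_pure_function(self, susc, substrate, expected):
        assert derive_category(susc, substrate) is expected


def records_with_counts(counts):
    """TBDT records with the given per-category counts, in category order."""
    records = []
    for cat, n in zip(TbdtCategory, counts):
        susc = cat.value.startswith("SusC")
        if "no CAZymes" in cat.value:
            substrate = NO_CAZYME
        elif "no substrate" in cat.value:
            substrate = NO_SUBSTRATE_PREDICTED
        else:
            substrate = "laminarin"
        for i in range(n):
            records.append(
                TbdtRecord(
                    protein_id=f"{cat.name}_{i}",
                    gene_id=f"{cat.name}_{i}",
                    is_susc_like=susc,
                    substrate=substrate,
                )
            )
    return records


class TestTabulateCategories:
    def test_percentages_from_observed_category_counts(self):
        records = records_with_counts([67, 18, 221, 28, 54, 873])
        table = tabulate_categories(records).set_index("category")
        expected = {
            TbdtCategory.SUSC_SUBSTRATE: (67, 5.3),
            TbdtCategory.SUSC_CAZYME_NO_SUBSTRATE: (18, 1.4),
            TbdtCategory.SUSC_NO_CAZYME: (221, 17.5),
            TbdtCategory.NONSUSC_SUBSTRATE: (28, 2.2),
            TbdtCategory.NONSUSC_CAZYME_NO_SUBSTRATE: (54, 4.3),
            TbdtCategory.NONSUSC_NO_CAZYME: (873, 69.2),
        }
        for cat, (count, pct) in expected.items():
            assert table.loc[cat.value, "count"] == count
            assert table.loc[cat.value, "pct_of_tbdts"] == pct
        assert table["count"].sum() == 1261

    def test_single_record_is_one_hundred_percent(self):
        records = records_with_counts([1, 0, 0, 0, 0, 0])
        table = tabulate_categories(records).set_index("category")
        assert table.loc[TbdtCategory.SUSC_SUBSTRATE.value, "pct_of_tbdts"] == 100.0
        assert table["pct_of_tbdts"].drop(TbdtCategory.SUSC_SUBSTRATE.value).eq(0.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_percentages_sum_to_100_within_rounding(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 400, size=6)
        if counts.sum() == 0:
            counts[0] = 1
        table = tabulate_categories(records_with_counts(counts))
        assert table["count"].sum() == counts.sum()
        assert abs(table["pct_of_tbdts"].sum() - 100.0) <= 0.3

    def test_nsaf_shares(self):
        records = records_with_counts([2, 0, 0, 0, 0, 2])
        nsaf = {r.protein_id: 1.0 for r in records}
        table = tabulate_categories(records, nsaf).set_index("category")
        assert table.loc[TbdtCategory.SUSC_SUBSTRATE.value, "mean_nsaf_pct"] == 2.0
        assert table.loc[TbdtCategory.SUSC_SUBSTRATE.value, "pct_of_tbdt_nsaf"] == 50.0

    def test_missing_nsaf_warns_and_counts_zero(self):
        records = records_with_counts([1, 0, 0, 0, 0, 1])
        nsaf = {records[0].protein_id: 1.5}
        with pytest.warns(UserWarning, match="lack %NSAF"):
            table = tabulate_categories(records, nsaf).set_index("category")
        assert table.loc[TbdtCategory.NONSUSC_NO_CAZYME.value, "mean_nsaf_pct"] == 0.0


def test_round1_is_half_away_from_zero():
    assert round1(5.25) == 5.3
    assert round1(5.24) == 5.2
    assert round1(-5.25) == -5.3
    assert round1(69.2307) == 69.2
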