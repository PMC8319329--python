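"""Gene feature classification: dbCAN filtering, confirmation, TBDT calls, categories."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulquant.annotation_io import AlignmentHit, DomainHit
from pulquant.feature_classifier import (
    CategoryRule,
    FeatureKind,
    FilterConfig,
    TbdtCall,
    assign_categories,
    classify_tbdt,
    confirm_cazymes,
    filter_cazyme_hits,
    gene_families,
    is_marker,
    label_genes,
)

from conftest import make_contig, make_gene

CFG = FilterConfig()


def dhit(gene="g1", prof="GH16", e=1e-30, cov=0.8, ali=(1, 200), score=100.0):
    return DomainHit(
        query_id=gene,
        profile_id=prof,
        e_value=e,
        bitscore=score,
        ali_from=ali[0],
        ali_to=ali[1],
        hmm_cov=cov,
    )


def ahit(gene="g1", subject="r1|GH16", ident=50.0, e=1e-40, cover=80.0, score=300.0):
    return AlignmentHit(
        query_id=gene,
        subject_id=subject,
        pct_identity=ident,
        e_value=e,
        bitscore=score,
        query_cover=cover,
    )


class TestFilterCazymeHits:
    @pytest.mark.parametrize(
        "e,cov,ali,accepted",
        [
            (1e-6, 0.5, (1, 100), True),   # long alignment, passes 1e-5 gate
            (1e-4, 0.4, (1, 60), True),    # short alignment, passes 1e-3 gate
            (1e-50, 0.2, (1, 200), False), # coverage gate
            (1e-4, 0.5, (1, 100), False),  # long alignment fails 1e-5 gate
            (1e-2, 0.5, (1, 60), False),   # short alignment fails 1e-3 gate
        ],
    )
    def test_dbcan_gates(self, e, cov, ali, accepted):
        out = filter_cazyme_hits([dhit(e=e, cov=cov, ali=ali)], CFG)
        assert (out.get("g1") == {"GH16"}) is accepted

    def test_evalue_boundaries_are_strict(self):
        assert not filter_cazyme_hits([dhit(e=1e-5, ali=(1, 100))], CFG)
        assert not filter_cazyme_hits([dhit(e=1e-3, ali=(1, 60))], CFG)

    def test_overlapping_hits_keep_lower_evalue(self):
        hits = [
            dhit(prof="GH16", e=1e-30, ali=(10, 250)),
            dhit(prof="GH17", e=1e-20, ali=(20, 240)),
        ]
        assert filter_cazyme_hits(hits, CFG) == {"g1": {"GH16"}}

    def test_non_overlapping_hits_both_kept(self):
        hits = [
            dhit(prof="GH16", e=1e-30, ali=(1, 100)),
            dhit(prof="CBM6", e=1e-20, ali=(150, 250)),
        ]
        assert filter_cazyme_hits(hits, CFG) == {"g1": {"GH16", "CBM6"}}

    @settings(max_examples=100, derandomize=True)
    @given(
        hits=st.lists(
            st.builds(
                dhit,
                gene=st.sampled_from(["g1", "g2"]),
                prof=st.sampled_from(["GH16", "GH17", "PL6"]),
                e=st.floats(1e-60, 1e-1),
                cov=st.floats(0.0, 1.0),
                ali=st.tuples(st.integers(1, 100), st.integers(101, 300)),
            ),
            max_size=12,
        )
    )
    def test_acceptance_predicate_matches_brute_force(self, hits):
        """Each accepted family has >=1 hit passing the stated predicate; no
        rejected hit family survives unless another hit carried it."""
        out = filter_cazyme_hits(hits, CFG)
        c = CFG.cazyme_hmm

        def passes(h):
            gate = c.evalue_long if h.ali_len > c.short_len_aa else c.evalue_short
            return h.hmm_cov > c.min_cov and h.e_value < gate

        passing = {(h.query_id, h.profile_id) for h in hits if passes(h)}
        got = {(g, f) for g, fams in out.items() for f in fams}
        assert got <= passing  # dedup only removes
        # every gene with a passing hit keeps its single best family
        for gene in {g for g, _ in passing}:
            assert gene in out and out[gene]


class TestConfirmCazymes:
    def test_all_thresholds_met_confirms(self):
        out = confirm_cazymes({"g1": {"GH16"}}, [ahit(ident=35.0, e=1e-25, cover=50.0)], CFG)
        assert out == {"g1": {"GH16"}}

    def test_evalue_gate_drops_family(self):
        out = confirm_cazymes({"g1": {"GH16"}}, [ahit(e=1e-15)], CFG)
        assert out == {}

    def test_hits_to_other_family_do_not_confirm(self):
        out = confirm_cazymes({"g1": {"GH16"}}, [ahit(subject="r1|GH99")], CFG)
        assert out == {}

    def test_inclusive_cover_and_identity_minima(self):
        out = confirm_cazymes({"g1": {"GH16"}}, [ahit(ident=30.0, cover=40.0)], CFG)
        assert out == {"g1": {"GH16"}}

    def test_missing_coverage_raises(self):
        hit = AlignmentHit("g1", "r1|GH16", 50.0, 1e-40, 300.0, query_cover=None)
        with pytest.raises(ValueError, match="coverage"):
            confirm_cazymes({"g1": {"GH16"}}, [hit], CFG)

    @settings(max_examples=60, derandomize=True)
    @given(
        aln=st.lists(
            st.builds(
                ahit,
                subject=st.sampled_from(["r|GH16", "r|GH17"]),
                ident=st.floats(10, 100),
                e=st.floats(1e-60, 1e-10),
                cover=st.floats(0, 100),
            ),
            max_size=8,
        )
    )
    def test_confirmation_only_removes(self, aln):
        before = {"g1": {"GH16", "GH17"}}
        after = confirm_cazymes(before, aln, CFG)
        for gene, fams in after.items():
            assert fams <= before[gene]


class TestClassifyTbdt:
    def test_susc_model_hit_sets_both_flags(self):
        out = classify_tbdt([dhit(prof="TIGR04056")], CFG)
        assert out["g1"] == TbdtCall(is_tbdt=True, is_susc_like=True)

    def test_panel_hits_without_susc_model(self):
        out = classify_tbdt([dhit(prof="PF00593"), dhit(prof="PF07715")], CFG)
        assert out["g1"] == TbdtCall(is_tbdt=True, is_susc_like=False)

    def test_no_panel_hits(self):
        assert classify_tbdt([dhit(prof="PF99999")], CFG) == {}

    def test_adding_hits_is_monotone(self):
        base = [dhit(prof="PF00593")]
        more = base + [dhit(prof="TIGR04056"), dhit(prof="PF07715")]
        assert classify_tbdt(base, CFG)["g1"].is_tbdt
        assert classify_tbdt(more, CFG)["g1"].is_tbdt
        assert classify_tbdt(more, CFG)["g1"].is_susc_like

    def test_susc_model_must_be_in_panel(self):
        with pytest.raises(ValueError):
            FilterConfig(tbdt_models=("PF00593",), susc_model="TIGR04056")


class TestLabelGenes:
    def test_gt_only_gene_is_not_a_marker(self):
        genes = make_contig({}, 1)
        out = label_genes(genes, {genes[0].gene_id: {"GT2"}}, {})
        (gene,) = out
        kinds = {lab.kind for lab in gene.labels}
        assert kinds == {FeatureKind.GLYCOSYL_TRANSFERASE}
        assert not is_marker(gene)

    def test_mixed_gt_gene_keeps_only_non_gt_families(self):
        genes = make_contig({}, 1)
        out = label_genes(genes, {genes[0].gene_id: {"GH16", "GT2"}}, {})
        (gene,) = out
        assert is_marker(gene)
        assert gene_families(gene) == {"GH16"}

    def test_susc_gene_gets_both_tbdt_labels(self):
        genes = make_contig({}, 1)
        out = label_genes(genes, {}, {genes[0].gene_id: TbdtCall(True, True)})
        kinds = {lab.kind for lab in out[0].labels}
        assert kinds == {FeatureKind.TBDT, FeatureKind.SUSC_LIKE}
        assert is_marker(out[0])

    def test_unknown_gene_in_annotation_raises(self):
        genes = make_contig({}, 1)
        with pytest.raises(ValueError, match="unknown genes"):
            label_genes(genes, {"ghost": {"GH16"}}, {})


class TestAssignCategories:
    CATS = {
        "ABC transporter": CategoryRule(pfam={"PF00005"}, tcdb_prefixes={"3.A.1"}),
        "porin": CategoryRule(pfam={"PF00267"}, tcdb_prefixes={"1.B.1"}),
    }

    def test_pfam_hit_alone_suffices(self):
        out = assign_categories(
            ["p1"], [dhit(gene="p1", prof="PF00005")], [], self.CATS, CFG
        )
        assert out["p1"] == {"ABC transporter"}

    def test_tcdb_hit_above_gate_is_ignored(self):
        hit = ahit(gene="p1", subject="3.A.1.5.1", e=1e-9)
        out = assign_categories(["p1"], [], [hit], self.CATS, CFG)
        assert out["p1"] == set()

    def test_tcdb_hit_below_gate_matches_prefix(self):
        hit = ahit(gene="p1", subject="3.A.1.5.1", e=1e-12)
        out = assign_categories(["p1"], [], [hit], self.CATS, CFG)
        assert out["p1"] == {"ABC transporter"}

    def test_prefix_match_respects_dot_boundaries(self):
        hit = ahit(gene="p1", subject="1.B.14.1.1", e=1e-12)
        out = assign_categories(["p1"], [], [hit], self.CATS, CFG)
        assert out["p1"] == set()

    def test_hits_in_two_categories_give_both(self):
        out = assign_categories(
            ["p1"],
            [dhit(gene="p1", prof="PF00005"), dhit(gene="p1", prof="PF00267")],
            [],
            self.CATS,
            CFG,
        )
        assert out["p1"] == {"ABC transporter", "porin"}
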