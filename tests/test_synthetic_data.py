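"""The synthetic community generator: determinism, planted truth, calibration."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pulquant.quantify import nsaf_percent, rpkm
from pulquant.substrate_predictor import NO_CAZYME
from pulquant.synthetic_data import (
    GeneratorConfig,
    expected_shares,
    generate_community,
    simulate_expression,
    simulate_metagenome_counts,
)


def dir_digest(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(d).iterdir()):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    generate_community(GeneratorConfig(seed=3), tmp_path / "a")
    generate_community(GeneratorConfig(seed=3), tmp_path / "b")
    assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")


def test_different_seeds_differ(tmp_path):
    generate_community(GeneratorConfig(seed=3), tmp_path / "a")
    generate_community(GeneratorConfig(seed=4), tmp_path / "b")
    assert dir_digest(tmp_path / "a") != dir_digest(tmp_path / "b")


@pytest.fixture(scope="module")
def truth(tmp_path_factory):
    return generate_community(GeneratorConfig(seed=2), tmp_path_factory.mktemp("gen"))


@pytest.fixture(scope="module")
def clean(tmp_path_factory):
    cfg = GeneratorConfig(seed=5, clean=True)
    community = generate_community(cfg, tmp_path_factory.mktemp("clean_gen"))
    return community, simulate_expression(community, cfg)


class TestPlantedTruth:
    def test_planted_clusters_satisfy_window_rule(self, truth):
        w = truth.cfg.window
        for cluster in truth.clusters:
            idx = sorted(cluster.marker_indices)
            assert len(idx) >= 2
            assert all(b - a <= w for a, b in zip(idx, idx[1:]))

    def test_near_miss_decoys_sit_just_beyond_window(self, truth):
        w = truth.cfg.window
        for tbdt_gid, caz_gid in truth.near_miss_pairs:
            gap = truth.planted[caz_gid].index - truth.planted[tbdt_gid].index
            assert gap == w + 1
            assert truth.tbdt_truth[tbdt_gid].substrate == NO_CAZYME

    def test_every_substrate_class_is_planted(self, truth):
        planted_classes = {c.substrate for c in truth.clusters if c.is_pul}
        assert set(truth.cfg.class_shares) <= planted_classes

    def test_truth_tables_cover_every_planted_element(self, truth):
        gene_ids = {g.gene_id for g in truth.genes}
        assert set(truth.tbdt_truth) <= gene_ids
        assert set(truth.expr_group) <= gene_ids
        for cluster in truth.clusters:
            assert set(cluster.gene_ids) <= gene_ids
        assert set(truth.mag_assign_truth) == set(truth.expr_group)

    def test_block_spacing_prevents_accidental_linkage(self, truth):
        """Markers of different planted blocks never fall within the window."""
        w = truth.cfg.window
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for bi, cluster in enumerate(truth.clusters):
            for idx in cluster.marker_indices:
                by_contig.setdefault(cluster.contig_id, []).append((idx, bi))
        for pairs in by_contig.values():
            pairs.sort()
            for (ia, ba), (ib, bb) in zip(pairs, pairs[1:]):
                if ba != bb:
                    assert ib - ia > w


class TestConfigValidation:
    def test_contig_too_small_rejected(self):
        with pytest.raises(ValueError, match="genes_per_contig"):
            GeneratorConfig(genes_per_contig=10)

    def test_class_shares_must_fit_under_tbdt_total(self):
        with pytest.raises(ValueError, match="class shares"):
            GeneratorConfig(class_shares={"laminarin": (10.0, 25.0)})


class TestExpression:
    def test_clean_mode_reproduces_expected_class_shares(self, clean):
        truth, matrix = clean
        nsaf = nsaf_percent(matrix)
        shares = expected_shares(truth)
        for d in truth.design:
            rep = d.replicate_ids[0]
            for cls in truth.cfg.class_shares:
                members = [p for p, g in truth.expr_group.items() if g == cls]
                got = nsaf.loc[members, rep].sum()
                assert got == pytest.approx(shares.loc[cls, d.sample_id], rel=1e-9)

    def test_clean_tbdt_total_share_trajectory(self, clean):
        truth, matrix = clean
        nsaf = nsaf_percent(matrix)
        tbdts = [p for p, g in truth.expr_group.items() if g != "background"]
        for t, d in enumerate(truth.design):
            got = nsaf.loc[tbdts, d.replicate_ids[0]].sum()
            assert got == pytest.approx(truth.cfg.tbdt_total_share[t], rel=1e-9)

    def test_noisy_mode_has_missing_cells(self, tmp_path):
        cfg = GeneratorConfig(seed=5)
        truth = generate_community(cfg, tmp_path)
        matrix = simulate_expression(truth, cfg)
        frac = matrix.values.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15

    def test_low_dispersion_replicate_means_near_expectation(self, tmp_path):
        cfg = GeneratorConfig(seed=6, nb_dispersion=1e-4, missing_rate=0.0)
        truth = generate_community(cfg, tmp_path)
        matrix = simulate_expression(truth, cfg)
        clean_cfg = cfg.model_copy(update={"clean": True})
        expect = simulate_expression(truth, clean_cfg).values
        # largest proteins: relative error of the replicate mean stays small
        big = expect.mean(axis=1).nlargest(10).index
        got = matrix.values.loc[big].mean(axis=1)
        assert np.allclose(got, expect.loc[big].mean(axis=1), rtol=0.05)


class TestMetagenome:
    def test_expected_rpkm_recovered_within_monte_carlo_error(self, tmp_path):
        cfg = GeneratorConfig(seed=7)
        truth = generate_community(cfg, tmp_path)
        reads = simulate_metagenome_counts(truth, cfg)
        values = rpkm(reads)
        for cls, expected in (("alginate", 11.2), ("mannose_rich", 11.7)):
            genes = [g for g, t in truth.tbdt_truth.items() if t.expr_group == cls]
            class_series = values.loc[genes].sum(axis=0)
            mean = class_series.mean()
            se = class_series.std(ddof=1) / np.sqrt(len(class_series))
            assert abs(mean - expected) < max(3 * se, 0.05 * expected)

    def test_zero_rate_gene_would_yield_zero_counts(self, tmp_path):
        cfg = GeneratorConfig(seed=7, class_rpkm={**GeneratorConfig().class_rpkm, "alginate": 0.0})
        truth = generate_community(cfg, tmp_path)
        reads = simulate_metagenome_counts(truth, cfg)
        genes = [g for g, t in truth.tbdt_truth.items() if t.expr_group == "alginate"]
        assert (reads.counts.loc[genes] == 0).all().all()

    def test_library_sizes_vary_but_expected_rpkm_does_not(self, tmp_path):
        cfg = GeneratorConfig(seed=8)
        truth = generate_community(cfg, tmp_path)
        reads = simulate_metagenome_counts(truth, cfg)
        assert reads.library_size.max() / reads.library_size.min() <= 2.0 + 1e-9
        values = rpkm(reads)
        # flat truth: per-class means across samples stay within a few percent
        for cls in truth.cfg.class_shares:
            genes = [g for g, t in truth.tbdt_truth.items() if t.expr_group == cls]
            series = values.loc[genes].sum(axis=0)
            assert series.std(ddof=1) / series.mean() < 0.2
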