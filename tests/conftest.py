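"""Shared fixtures: synthetic communities and helpers for building labelled genes."""

from __future__ import annotations

import numpy as np
import pytest

from pulquant.annotation_io import GeneRecord
from pulquant.feature_classifier import FeatureKind, FeatureLabel
from pulquant.pipeline import RunConfig, run_pipeline
from pulquant.synthetic_data import GeneratorConfig, generate_community


def make_gene(
    contig: str,
    index: int,
    kinds: tuple[FeatureKind, ...] = (),
    families: frozenset[str] = frozenset(),
) -> GeneRecord:
    """One gene with the given labels; coordinates derived from the index."""
    labels = set()
    for kind in kinds:
        if kind in (FeatureKind.CAZYME, FeatureKind.GLYCOSYL_TRANSFERASE):
            labels.add(FeatureLabel(kind, families))
        else:
            labels.add(FeatureLabel(kind))
    start = 1 + index * 1000
    gene = GeneRecord(
        gene_id=f"{contig}_g{index:03d}",
        contig_id=contig,
        index=index,
        start=start,
        end=start + 899,
    )
    gene.labels = labels
    return gene


def make_contig(
    markers: dict[int, tuple[tuple[FeatureKind, ...], frozenset[str]]],
    n_genes: int,
    contig: str = "ctg1",
) -> list[GeneRecord]:
    """A contig of ``n_genes`` genes with markers planted at given indices."""
    genes = []
    for idx in range(n_genes):
        kinds, fams = markers.get(idx, ((), frozenset()))
        genes.append(make_gene(contig, idx, kinds, fams))
    return genes


def random_labeled_genes(
    rng: np.random.Generator,
    n_genes: int,
    n_contigs: int = 2,
    marker_prob: float = 0.25,
) -> list[GeneRecord]:
    """Random gene table mixing marker kinds, GT-only genes, and fillers."""
    marker_kinds = [
        (FeatureKind.TBDT,),
        (FeatureKind.TBDT, FeatureKind.SUSC_LIKE),
        (FeatureKind.SUSD_LIKE,),
        (FeatureKind.SULFATASE,),
        (FeatureKind.CAZYME,),
    ]
    families = ["GH16", "GH13", "PL6", "GH92", "GH10"]
    genes: list[GeneRecord] = []
    per_contig = n_genes // n_contigs or 1
    for c in range(n_contigs):
        contig = f"rc{c}"
        for idx in range(per_contig):
            r = rng.random()
            if r < marker_prob:
                kinds = marker_kinds[rng.integers(len(marker_kinds))]
                fams = (
                    frozenset({families[rng.integers(len(families))]})
                    if FeatureKind.CAZYME in kinds
                    else frozenset()
                )
                genes.append(make_gene(contig, idx, kinds, fams))
            elif r < marker_prob + 0.05:
                genes.append(
                    make_gene(contig, idx, (FeatureKind.GLYCOSYL_TRANSFERASE,), frozenset({"GT2"}))
                )
            else:
                genes.append(make_gene(contig, idx))
    return genes


@pytest.fixture(scope="session")
def clean_community(tmp_path_factory):
    """Noise-free synthetic community plus a full pipeline run over it."""
    in_dir = tmp_path_factory.mktemp("clean_in")
    out_dir = tmp_path_factory.mktemp("clean_out")
    cfg = GeneratorConfig(seed=11, clean=True)
    truth = generate_community(cfg, in_dir)
    result = run_pipeline(RunConfig.from_dir(in_dir, out_dir))
    return truth, result


@pytest.fixture(scope="session")
def noisy_community(tmp_path_factory):
    """Default (noisy) synthetic bloom plus a full pipeline run over it."""
    in_dir = tmp_path_factory.mktemp("noisy_in")
    out_dir = tmp_path_factory.mktemp("noisy_out")
    cfg = GeneratorConfig(seed=11)
    truth = generate_community(cfg, in_dir)
    result = run_pipeline(RunConfig.from_dir(in_dir, out_dir))
    return truth, result
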