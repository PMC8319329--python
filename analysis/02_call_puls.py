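#!/usr/bin/env python
"""Classify gene features, call clusters with the seven-gene window, and
predict PUL substrates on the clean community; verify recovery against truth.

Requires 01_simulate_community.py.  Writes results/puls.tsv and
results/clusters.bed.
"""

from pathlib import Path

from pulquant.annotation_io import clusters_to_bed
from pulquant.pipeline import (
    RunConfig,
    classify_stage,
    cluster_stage,
    load_genes,
    substrate_stage,
    _clusters_frame,
)
from pulquant.synthetic_data import GeneratorConfig, generate_community

SEED = 11
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    in_dir = ROOT / "scratch/synthetic/clean"
    if not in_dir.exists():
        generate_community(GeneratorConfig(seed=SEED, clean=True), in_dir)
    truth = generate_community(GeneratorConfig(seed=SEED, clean=True), in_dir)

    cfg = RunConfig.from_dir(in_dir, ROOT / "scratch/puls_out")
    genes = load_genes(cfg)
    genes, _, _ = classify_stage(cfg, genes)
    clusters, puls = cluster_stage(genes, cfg.window)
    substrates = substrate_stage(puls, cfg.rules)

    out = ROOT / "results"
    _clusters_frame(puls, substrates).to_csv(out / "puls.tsv", sep="\t", index=False)
    clusters_to_bed(clusters).to_csv(
        out / "clusters.bed", sep="\t", index=False, header=False
    )

    planted = {(c.contig_id, tuple(sorted(c.marker_indices))) for c in truth.clusters}
    called = {
        (c.contig_id, tuple(sorted(g.index for g in c.gene_span if g.gene_id in c.marker_ids)))
        for c in clusters
    }
    print(f"{len(clusters)} clusters called, {len(puls)} PULs")
    print(f"planted clusters recovered: {len(called & planted)}/{len(planted)}")
    print(f"false-positive clusters: {len(called - planted)}")
    by_class: dict[str, int] = {}
    for cls in substrates.values():
        by_class[cls] = by_class.get(cls, 0) + 1
    for cls in sorted(by_class):
        print(f"  {cls}: {by_class[cls]} PULs")


if __name__ == "__main__":
    main()
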