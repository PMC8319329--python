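"""Sliding-window calling of CAZyme-rich gene clusters and PULs.

Marker genes (degradative CAZymes, sulfatases, TBDTs, SusD-like genes; never
GT-only genes) are linked whenever two markers on the same contig lie within
``window`` gene positions of each other (ordinal index difference, default 7).
Linkage is transitive, so clusters are connected components and may exceed
the window length — this reproduces tandem-PUL structures where two susCD
pairs share a CAZyme complement.  A cluster needs at least two markers;
clusters containing both a TBDT and at least one degradative CAZyme are
polysaccharide utilisation loci (PULs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .annotation_io import GeneRecord
from .feature_classifier import FeatureKind, gene_families, is_marker


@dataclass
class GeneCluster:
    """A contiguous span of genes grouped by the sliding-window rule.

    ``gene_span`` covers every gene (marker or not) between the component's
    lowest and highest marker index, inclusive.
    """

    cluster_id: str
    contig_id: str
    gene_span: list[GeneRecord]
    marker_ids: set[str]
    has_tbdt: bool
    cazyme_families: Counter = field(default_factory=Counter)

    @property
    def start(self) -> int:
        return min(g.start for g in self.gene_span)

    @property
    def end(self) -> int:
        return max(g.end for g in self.gene_span)

    @property
    def marker_indices(self) -> list[int]:
        return sorted(g.index for g in self.gene_span if g.gene_id in self.marker_ids)

    @property
    def family_set(self) -> frozenset[str]:
        return frozenset(self.cazyme_families)


def call_clusters(genes: Sequence[GeneRecord], window: int = 7) -> list[GeneCluster]:
    """Group marker genes into clusters with a ``window``-gene sliding window.

    Two markers on the same contig are linked iff their ordinal index
    difference is <= ``window``; clusters are the connected components with
    at least two markers (singletons are discarded).  On a line, components
    equal chains of consecutive markers with gaps <= ``window``, which is how
    they are built here; tests check equivalence against the full pairwise
    graph oracle.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")

    by_contig: dict[str, list[GeneRecord]] = {}
    for gene in genes:
        by_contig.setdefault(gene.contig_id, []).append(gene)

    clusters: list[GeneCluster] = []
    for contig in sorted(by_contig):
        contig_genes = sorted(by_contig[contig], key=lambda g: g.index)
        by_index = {g.index: g for g in contig_genes}
        markers = [g for g in contig_genes if is_marker(g)]
        if not markers:
            continue

        components: list[list[GeneRecord]] = []
        current = [markers[0]]
        for prev, cur in zip(markers, markers[1:]):
            if cur.index - prev.index <= window:
                current.append(cur)
            else:
                components.append(current)
                current = [cur]
        components.append(current)

        n = 0
        for comp in components:
            if len(comp) < 2:
                continue
            lo, hi = comp[0].index, comp[-1].index
            span = [by_index[i] for i in range(lo, hi + 1) if i in by_index]
            fams: Counter = Counter()
            for g in span:
                fams.update(gene_families(g))
            clusters.append(
                GeneCluster(
                    cluster_id=f"{contig}:cl{n}",
                    contig_id=contig,
                    gene_span=span,
                    marker_ids={g.gene_id for g in comp},
                    has_tbdt=any(
                        lab.kind is FeatureKind.TBDT for g in span for lab in g.labels
                    ),
                    cazyme_families=fams,
                )
            )
            n += 1
    return clusters


def select_puls(clusters: Sequence[GeneCluster]) -> list[GeneCluster]:
    """PULs: clusters with a TBDT and at least one degradative CAZyme family.

    Substrate prediction works from CAZyme content, so a TBDT-containing
    cluster without any non-GT CAZyme cannot be a functional PUL call; it
    stays a plain cluster.  Input ordering is preserved.
    """
    return [c for c in clusters if c.has_tbdt and len(c.cazyme_families) > 0]
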