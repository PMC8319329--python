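"""End-to-end orchestration: classify -> cluster -> substrate -> taxonomy ->
quantify -> aggregate, from files on disk to result tables on disk.

Each stage is a plain function over the shared data model so the command-line
subcommands, the analysis scripts, and :func:`run_pipeline` compose the same
way; composing stages manually yields the same outputs as the one-shot run.
All inputs are validated up front (fail fast, before any stage runs) and the
effective configuration is serialised into the output directory as a run
manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import annotation_io as aio
from .annotation_io import GeneRecord, SampleDesign
from .feature_classifier import (
    FilterConfig,
    TbdtCall,
    classify_tbdt,
    confirm_cazymes,
    filter_cazyme_hits,
    label_genes,
)
from .pul_caller import GeneCluster, call_clusters, select_puls
from .quantify import (
    AbundanceMatrix,
    ReadCountTable,
    TimeSeriesTable,
    aggregate,
    average_replicates,
    nsaf_percent,
    rpkm,
)
from .substrate_predictor import (
    SubstrateRuleTable,
    TbdtRecord,
    annotate_tbdts,
    predict_substrate,
    tabulate_categories,
    tbdt_records_frame,
)
from .taxonomy import (
    SpeciesCluster,
    assign_protein_to_mag,
    build_species_clusters,
    read_mag_table,
)

_INPUT_FILES = {
    "genes_gff": "genes.gff3",
    "cazyme_domtbl": "cazyme_domtbl.txt",
    "tbdt_domtbl": "tbdt_domtbl.txt",
    "cazy_confirm": "cazy_confirm.tsv",
    "susd_ids": "susd_ids.txt",
    "sulfatase_ids": "sulfatase_ids.txt",
    "mag_hits": "mag_hits.tsv",
    "subject_map": "subject_map.tsv",
    "contig_map": "contig_map.tsv",
    "mag_quality": "mag_quality.tsv",
    "mag_distances": "mag_distances.tsv",
    "design": "design.tsv",
    "spectra": "spectra.tsv",
    "protein_lengths": "protein_lengths.tsv",
    "readcounts": "readcounts.tsv",
    "gene_lengths": "gene_lengths.tsv",
    "library_sizes": "library_sizes.tsv",
}


class RunConfig(BaseModel):
    """Paths and thresholds for one pipeline run."""

    inputs: dict[str, Path]
    out_dir: Path
    window: int = 7
    filters: FilterConfig = Field(default_factory=FilterConfig)
    rules: SubstrateRuleTable = Field(default_factory=SubstrateRuleTable.default)
    species_threshold: float = 0.05
    abundance_mode: str = "quantitative"

    @classmethod
    def from_dir(cls, in_dir: Path | str, out_dir: Path | str, **kwargs) -> "RunConfig":
        in_dir = Path(in_dir)
        return cls(
            inputs={key: in_dir / name for key, name in _INPUT_FILES.items()},
            out_dir=Path(out_dir),
            **kwargs,
        )

    def validate_inputs(self) -> None:
        missing_keys = set(_INPUT_FILES) - set(self.inputs)
        if missing_keys:
            raise FileNotFoundError(f"run config lacks input paths: {sorted(missing_keys)}")
        missing = [str(p) for p in self.inputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class RunResult:
    """Everything a pipeline run produces, in memory plus written paths."""

    genes: list[GeneRecord]
    tbdt_calls: dict[str, TbdtCall]
    clusters: list[GeneCluster]
    puls: list[GeneCluster]
    substrates: dict[str, str]
    tbdt_records: list[TbdtRecord]
    category_summary: pd.DataFrame
    assignments: dict[str, str]
    species_clusters: list[SpeciesCluster]
    nsaf_sample: pd.DataFrame
    nsaf_series: TimeSeriesTable
    rpkm_values: pd.DataFrame
    rpkm_series: TimeSeriesTable
    design: list[SampleDesign]
    written: dict[str, Path]


def _read_id_set(path: Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def load_genes(cfg: RunConfig) -> list[GeneRecord]:
    contig_map = pd.read_csv(cfg.inputs["contig_map"], sep="\t", dtype=str)
    genome_of = dict(zip(contig_map["contig_id"], contig_map["genome_id"]))
    with open(cfg.inputs["genes_gff"]) as fh:
        return aio.read_gene_table(fh, genome_map=genome_of)


def classify_stage(
    cfg: RunConfig, genes: Sequence[GeneRecord]
) -> tuple[list[GeneRecord], dict[str, TbdtCall], dict[str, set[str]]]:
    """Label every gene from the raw scanner tables."""
    with open(cfg.inputs["cazyme_domtbl"]) as fh:
        caz_hits = aio.read_domain_hits(fh)
    with open(cfg.inputs["cazy_confirm"]) as fh:
        confirm_hits = aio.read_alignment_hits(fh)
    with open(cfg.inputs["tbdt_domtbl"]) as fh:
        tbdt_hits = aio.read_domain_hits(fh)

    hmm_families = filter_cazyme_hits(caz_hits, cfg.filters)
    cazymes = confirm_cazymes(hmm_families, confirm_hits, cfg.filters)
    tbdt_calls = classify_tbdt(tbdt_hits, cfg.filters)
    labelled = label_genes(
        list(genes),
        cazymes,
        tbdt_calls,
        susd_ids=_read_id_set(cfg.inputs["susd_ids"]),
        sulfatase_ids=_read_id_set(cfg.inputs["sulfatase_ids"]),
    )
    return labelled, tbdt_calls, cazymes


def cluster_stage(
    genes: Sequence[GeneRecord], window: int
) -> tuple[list[GeneCluster], list[GeneCluster]]:
    clusters = call_clusters(genes, window=window)
    return clusters, select_puls(clusters)


def substrate_stage(
    puls: Sequence[GeneCluster], rules: SubstrateRuleTable
) -> dict[str, str]:
    return {pul.cluster_id: predict_substrate(pul, rules) for pul in puls}


def taxonomy_stage(
    cfg: RunConfig,
) -> tuple[list[SpeciesCluster], dict[str, str], dict[str, str]]:
    """Species clusters, protein-to-MAG assignments, and per-protein taxa."""
    mags = read_mag_table(cfg.inputs["mag_quality"])
    distances = pd.read_csv(cfg.inputs["mag_distances"], sep="\t", index_col=0)
    species = build_species_clusters(mags, distances, cfg.species_threshold)

    subj_map = pd.read_csv(cfg.inputs["subject_map"], sep="\t", dtype=str)
    subject_to_mag = dict(zip(subj_map["subject_id"], subj_map["mag_id"]))
    with open(cfg.inputs["mag_hits"]) as fh:
        hits = aio.read_alignment_hits(fh)
    assignments = assign_protein_to_mag(hits, subject_to_mag, cfg.filters)

    taxonomy_of_mag = {m.mag_id: m.taxonomy for m in mags}
    taxon_of = {
        protein: taxonomy_of_mag.get(mag, "unassigned")
        for protein, mag in assignments.items()
    }
    return species, assignments, taxon_of


def quantify_stage(
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, list[SampleDesign]]:
    """Sample-level mean %NSAF, per-protein bloom-mean %NSAF, and RPKM."""
    with open(cfg.inputs["design"]) as fh:
        design = aio.read_design(fh)
    spectra = pd.read_csv(cfg.inputs["spectra"], sep="\t", index_col=0)
    lengths = pd.read_csv(cfg.inputs["protein_lengths"], sep="\t", index_col=0)[
        "length_aa"
    ]
    matrix = AbundanceMatrix(
        values=spectra, lengths=lengths, design=list(design), mode=cfg.abundance_mode
    )
    nsaf_sample = average_replicates(nsaf_percent(matrix), design)
    protein_mean_nsaf = nsaf_sample.mean(axis=1)

    counts = pd.read_csv(cfg.inputs["readcounts"], sep="\t", index_col=0)
    len_kbp = pd.read_csv(cfg.inputs["gene_lengths"], sep="\t", index_col=0)[
        "length_kbp"
    ]
    libs = pd.read_csv(cfg.inputs["library_sizes"], sep="\t", index_col=0)
    reads = ReadCountTable(
        counts=counts, feature_len_kbp=len_kbp, library_size=libs["total_reads"]
    )
    return nsaf_sample, protein_mean_nsaf, rpkm(reads), design


def _clusters_frame(clusters: Sequence[GeneCluster], substrates: Mapping[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "contig_id": c.contig_id,
                "first_index": c.gene_span[0].index,
                "last_index": c.gene_span[-1].index,
                "start": c.start,
                "end": c.end,
                "n_markers": len(c.marker_ids),
                "has_tbdt": c.has_tbdt,
                "cazyme_families": ",".join(sorted(c.cazyme_families.elements())),
                "substrate": substrates.get(c.cluster_id, ""),
            }
            for c in clusters
        ],
        columns=[
            "cluster_id", "contig_id", "first_index", "last_index", "start", "end",
            "n_markers", "has_tbdt", "cazyme_families", "substrate",
        ],
    ).sort_values(["contig_id", "first_index"], kind="mergesort").reset_index(drop=True)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute every stage and write the result bundle to ``cfg.out_dir``."""
    cfg.validate_inputs()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = load_genes(cfg)
    genes, tbdt_calls, _cazymes = classify_stage(cfg, genes)
    clusters, puls = cluster_stage(genes, cfg.window)
    substrates = substrate_stage(puls, cfg.rules)
    species, assignments, taxon_of = taxonomy_stage(cfg)
    nsaf_sample, protein_mean_nsaf, rpkm_values, design = quantify_stage(cfg)

    records = annotate_tbdts(tbdt_calls, clusters, substrates, taxon_of=taxon_of)
    category_summary = tabulate_categories(
        records, protein_mean_nsaf.to_dict()
    )

    substrate_of_protein = {
        r.protein_id: r.substrate for r in records if r.substrate in cfg.rules.rules
    }
    tbdt_nsaf = nsaf_sample.loc[
        [p for p in substrate_of_protein if p in nsaf_sample.index]
    ]
    nsaf_series = aggregate(tbdt_nsaf, substrate_of_protein, group_key="substrate")
    substrate_of_gene = {
        r.gene_id: r.substrate for r in records if r.substrate in cfg.rules.rules
    }
    rpkm_tbdt = rpkm_values.loc[
        [g for g in substrate_of_gene if g in rpkm_values.index]
    ]
    rpkm_series = aggregate(rpkm_tbdt, substrate_of_gene, group_key="substrate")

    day_of = {d.sample_id: d.julian_day for d in design}
    tables = {
        "clusters": _clusters_frame(clusters, substrates),
        "puls": _clusters_frame(puls, substrates),
        "tbdt_records": tbdt_records_frame(records),
        "category_summary": category_summary,
        "nsaf_substrate_series": nsaf_series.to_long(day_of),
        "rpkm_substrate_series": rpkm_series.to_long(),
        "protein_mag_assignments": pd.DataFrame(
            sorted(assignments.items()), columns=["protein_id", "mag_id"]
        ),
        "species_clusters": pd.DataFrame(
            [
                {
                    "representative": s.representative,
                    "members": ",".join(sorted(s.members)),
                }
                for s in species
            ],
            columns=["representative", "members"],
        ).sort_values("representative", kind="mergesort"),
    }
    written = aio.write_results(tables, out_dir, bed_clusters=clusters)

    manifest = {
        "window": cfg.window,
        "species_threshold": cfg.species_threshold,
        "abundance_mode": cfg.abundance_mode,
        "filters": cfg.filters.model_dump(),
        "rules": cfg.rules.model_dump(),
        "inputs": {k: str(v) for k, v in cfg.inputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    written["manifest"] = manifest_path

    return RunResult(
        genes=genes,
        tbdt_calls=tbdt_calls,
        clusters=clusters,
        puls=puls,
        substrates=substrates,
        tbdt_records=records,
        category_summary=category_summary,
        assignments=assignments,
        species_clusters=species,
        nsaf_sample=nsaf_sample,
        nsaf_series=nsaf_series,
        rpkm_values=rpkm_values,
        rpkm_series=rpkm_series,
        design=design,
        written=written,
    )
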