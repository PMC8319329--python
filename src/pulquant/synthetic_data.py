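"""Synthetic bloom-community generator with full ground truth.

Emulates the study design this pipeline targets: a multi-species
bacterioplankton community sampled over a spring phytoplankton bloom, with
six metaproteome dates (three biological replicates each) and nine
metagenome dates.  The generator plants, per species and contig:

* valid PULs for each substrate class (SusC-like or plain TBDT plus SusD,
  plus indicator CAZymes, all within the seven-gene window);
* ambiguous PULs whose CAZyme content matches two classes (truth:
  ``no_substrate_predicted``);
* near-miss decoys — marker pairs at gap ``window + 1`` that must NOT
  cluster;
* GT-only decoy runs (glycosyl transferases are not clustering markers);
* lone TBDTs with no CAZyme context (truth: ``no_cazyme``);
* classifier-exercise genes whose HMM/alignment hits are engineered to pass
  or fail specific filter branches.

Expression follows a late-bloom substrate shift: the total TBDT share of the
proteome rises from 13.9% to 21.0% (mean 16.7%), glucan-targeting classes
(laminarin, alpha-glucan) decline in share while fucose/mannose/xylose-
containing polymer, alginate, mannose- and xylose-rich classes rise
(log-linear trajectories; alginate 0.01% -> 0.1%, fmx 0.2% -> 1.0%).
Replicate spectral counts are negative-binomial (gamma-Poisson) around the
expected shares with ~10% of protein/replicate cells dropped to missing.
Metagenome read counts are Poisson around time-constant per-gene RPKM (the
gene-frequency side of the expression/frequency decoupling), with the
alginate and mannose class RPKM sums calibrated to 11.2 and 11.7.

All randomness flows from the single config seed; layout, expression and
metagenome draws use separate substreams, so the three outputs are
individually reproducible.  Output files use the same formats as real
inputs, so the pipeline cannot distinguish synthetic from real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .annotation_io import GeneRecord, SampleDesign
from .quantify import AbundanceMatrix, ReadCountTable
from .substrate_predictor import NO_CAZYME, NO_SUBSTRATE_PREDICTED
from .taxonomy import MagRecord, UNASSIGNED

PROTEOME_DAYS = (77, 91, 110, 124, 132, 138)
METAGENOME_DAYS = (76, 81, 91, 103, 110, 117, 123, 133, 138)

OTHER_TBDT = "tbdt_other"
BACKGROUND = "background"


class GeneratorConfig(BaseModel):
    """Study-condition parameters of the synthetic community."""

    n_species: int = 8
    contigs_per_species: int = 3
    genes_per_contig: int = 60
    window: int = 7

    # per-class expected share of total protein (%), start -> end, log-linear
    class_shares: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "laminarin": (1.0, 0.6),
            "alpha_glucan": (0.8, 0.4),
            "alginate": (0.01, 0.1),
            "fmx": (0.2, 1.0),
            "mannose_rich": (0.15, 0.5),
            "xylose_rich": (0.1, 0.3),
        }
    )
    # total TBDT share of the proteome per sample (%), mean 16.7
    tbdt_total_share: tuple[float, ...] = (13.9, 14.5, 15.2, 16.5, 19.1, 21.0)

    n_samples: int = 6
    n_replicates: int = 3
    proteome_days: tuple[int, ...] = PROTEOME_DAYS
    metagenome_days: tuple[int, ...] = METAGENOME_DAYS

    total_spectra: float = 50_000.0
    nb_dispersion: float = 0.05
    missing_rate: float = 0.10
    n_background_proteins: int = 300

    # time-constant expected RPKM summed over each class's genes
    class_rpkm: dict[str, float] = Field(
        default_factory=lambda: {
            "laminarin": 30.0,
            "alpha_glucan": 25.0,
            "alginate": 11.2,
            "fmx": 25.0,
            "mannose_rich": 11.7,
            "xylose_rich": 15.0,
            OTHER_TBDT: 40.0,
        }
    )
    library_size_range: tuple[float, float] = (2.0e7, 4.0e7)

    n_lone_tbdts: int = 6
    n_near_miss_pairs: int = 4
    n_gt_runs: int = 3
    mag_unassigned_rate: float = 0.15

    clean: bool = False  # expectation-valued abundances, no missing cells
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "GeneratorConfig":
        if self.n_samples != len(self.proteome_days):
            raise ValueError("n_samples must match proteome_days")
        if len(self.tbdt_total_share) != self.n_samples:
            raise ValueError("tbdt_total_share must have one value per sample")
        if self.genes_per_contig < 2 * self.window + 8:
            raise ValueError(
                "genes_per_contig too small to lay out blocks with window spacing"
            )
        for t in range(self.n_samples):
            if self._class_share_sum(t) >= self.tbdt_total_share[t]:
                raise ValueError("class shares exceed the total TBDT share")
        return self

    def _class_share_sum(self, t: int) -> float:
        return sum(
            _loglinear(s0, s1, t, self.n_samples) for s0, s1 in self.class_shares.values()
        )


def _loglinear(start: float, end: float, t: int, n: int) -> float:
    if n == 1:
        return start
    return start * (end / start) ** (t / (n - 1))


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    contig_id: str
    index: int
    role: str  # tbdt_susc | tbdt | susd | caz | sulf | gt | filler | exercise tags
    families: frozenset[str] = frozenset()
    length_nt: int = 900


@dataclass(frozen=True)
class PlantedCluster:
    """Truth for one planted marker block that must (or must not) cluster."""

    contig_id: str
    marker_indices: tuple[int, ...]
    gene_ids: tuple[str, ...]
    has_tbdt: bool
    is_pul: bool
    substrate: str | None  # class name, no_substrate_predicted, or None (non-PUL)


@dataclass(frozen=True)
class TbdtTruth:
    is_susc_like: bool
    substrate: str  # class | no_substrate_predicted | no_cazyme
    expr_group: str


@dataclass
class CommunityTruth:
    """Complete ground truth plus in-memory copies of everything written."""

    cfg: GeneratorConfig
    genes: list[GeneRecord]
    planted: dict[str, PlantedGene]
    clusters: list[PlantedCluster]
    near_miss_pairs: list[tuple[str, str]]
    gt_runs: list[tuple[str, ...]]
    tbdt_truth: dict[str, TbdtTruth]
    mags: list[MagRecord]
    distances: pd.DataFrame
    retained_mags: set[str]
    species_groups: list[frozenset[str]]
    representatives: dict[frozenset[str], str]
    mag_assign_truth: dict[str, str]
    subject_to_mag: dict[str, str]
    contig_genome: dict[str, str]
    expr_group: dict[str, str]
    susd_ids: set[str]
    sulfatase_ids: set[str]
    design: list[SampleDesign]
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def expected_class_share(self) -> pd.DataFrame:
        """Expected %-of-proteome per substrate class per sample."""
        cfg = self.cfg
        data = {
            cls: [
                _loglinear(s0, s1, t, cfg.n_samples) for t in range(cfg.n_samples)
            ]
            for cls, (s0, s1) in cfg.class_shares.items()
        }
        return pd.DataFrame(
            data, index=[d.sample_id for d in self.design]
        ).T

    def trend_sign(self, cls: str) -> int:
        s0, s1 = self.cfg.class_shares[cls]
        return int(np.sign(s1 - s0))


# ---------------------------------------------------------------------------
# community layout


@dataclass(frozen=True)
class _BlockGene:
    rel: int
    role: str
    families: frozenset[str] = frozenset()
    length_nt: int = 1200


@dataclass(frozen=True)
class _Block:
    kind: str  # pul | ambiguous | nontbdt_cluster | lone | near_miss | gt_run | exercise
    genes: tuple[_BlockGene, ...]
    substrate: str | None = None
    susc: bool = False

    @property
    def span(self) -> int:
        return max(g.rel for g in self.genes) + 1


def _pul_block(substrate: str, susc: bool, fam_a: str, fam_b: str, extra_gt: bool = False) -> _Block:
    genes = [
        _BlockGene(0, "tbdt_susc" if susc else "tbdt", length_nt=2940),
        _BlockGene(1, "susd" if susc else "filler", length_nt=1500),
        _BlockGene(2, "caz", frozenset({fam_a})),
        _BlockGene(3, "filler", length_nt=900),
        _BlockGene(4, "caz", frozenset({fam_b})),
    ]
    if extra_gt:
        genes.append(_BlockGene(5, "caz", frozenset({fam_a, "GT2"})))
    return _Block("pul", tuple(genes), substrate=substrate, susc=susc)


def _ambiguous_block(susc: bool, fams: Sequence[str]) -> _Block:
    genes = [
        _BlockGene(0, "tbdt_susc" if susc else "tbdt", length_nt=2940),
        _BlockGene(1, "susd" if susc else "filler", length_nt=1500),
    ]
    genes += [
        _BlockGene(2 + i, "caz", frozenset({f})) for i, f in enumerate(fams)
    ]
    return _Block("ambiguous", tuple(genes), substrate=NO_SUBSTRATE_PREDICTED, susc=susc)


def _default_blocks(cfg: GeneratorConfig) -> list[_Block]:
    """The planted block roster: every class twice, plus decoys and exercises."""
    pul_plan = [
        ("laminarin", True, "GH16", "GH17", True),
        ("laminarin", False, "GH17", "GH30", False),
        ("alpha_glucan", True, "GH13", "GH31", False),
        ("alpha_glucan", False, "GH13", "GH65", False),
        ("alginate", True, "PL6", "PL7", False),
        ("alginate", False, "PL12", "PL17", False),
        ("fmx", True, "GH29", "GH92", False),
        ("fmx", True, "GH95", "GH43", False),
        ("mannose_rich", True, "GH92", "GH38", False),
        ("mannose_rich", True, "GH76", "GH92", False),
        ("xylose_rich", True, "GH10", "GH43", False),
        ("xylose_rich", False, "GH67", "GH115", False),
    ]
    blocks = [_pul_block(*args) for args in pul_plan]
    blocks.append(_ambiguous_block(True, ["GH13", "GH29", "GH92"]))
    blocks.append(_ambiguous_block(False, ["GH16", "GH13"]))
    # CAZyme-containing clusters without a TBDT: clusters but never PULs
    blocks.append(
        _Block(
            "nontbdt_cluster",
            (
                _BlockGene(0, "sulf", length_nt=1500),
                _BlockGene(2, "caz", frozenset({"GH16"})),
            ),
        )
    )
    blocks.append(
        _Block(
            "nontbdt_cluster",
            (
                _BlockGene(0, "sulf", length_nt=1500),
                _BlockGene(3, "caz", frozenset({"PL7"})),
            ),
        )
    )
    for i in range(cfg.n_lone_tbdts):
        blocks.append(
            _Block(
                "lone",
                (_BlockGene(0, "tbdt_susc" if i % 2 == 0 else "tbdt", length_nt=2940),),
                susc=i % 2 == 0,
            )
        )
    for i in range(cfg.n_near_miss_pairs):
        blocks.append(
            _Block(
                "near_miss",
                (
                    _BlockGene(0, "tbdt_susc" if i % 2 == 0 else "tbdt", length_nt=2940),
                    _BlockGene(cfg.window + 1, "caz", frozenset({"GH16"})),
                ),
                susc=i % 2 == 0,
            )
        )
    for _ in range(cfg.n_gt_runs):
        blocks.append(
            _Block(
                "gt_run",
                (
                    _BlockGene(0, "gt", frozenset({"GT2"})),
                    _BlockGene(1, "gt", frozenset({"GT4"})),
                    _BlockGene(2, "gt", frozenset({"GT2"})),
                ),
            )
        )
    # classifier-exercise singletons (no cluster impact)
    blocks.append(_Block("exercise", (_BlockGene(0, "caz_lowcov", frozenset({"GH13"})),)))
    blocks.append(_Block("exercise", (_BlockGene(0, "caz_short", frozenset({"GH31"})),)))
    blocks.append(_Block("exercise", (_BlockGene(0, "caz_overlap", frozenset({"GH16", "GH17"})),)))
    blocks.append(_Block("exercise", (_BlockGene(0, "caz_noconfirm", frozenset({"GH65"})),)))
    return blocks


_ROLE_LENGTH = {"filler": 900}

_BACTEROIDETES = "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Flavobacteriales"
_GAMMA = "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales"


def generate_community(cfg: GeneratorConfig, out_dir: Path | str) -> CommunityTruth:
    """Lay out the community, write every input file, and return the truth.

    Deterministic given ``cfg`` (byte-identical files for the same seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 11])

    species = [f"S{i + 1:02d}" for i in range(cfg.n_species)]
    contigs = [
        f"{sp}_c{j + 1}" for sp in species for j in range(cfg.contigs_per_species)
    ]
    primary_mag = {sp: f"MAG_{sp}" for sp in species}
    contig_genome = {c: primary_mag[c.split("_")[0]] for c in contigs}

    # --- place blocks round-robin with > window spacing between blocks
    blocks = _default_blocks(cfg)
    cursors = {c: 1 for c in contigs}
    placements: list[tuple[_Block, str, int]] = []
    ci = 0
    for block in blocks:
        placed = False
        for _ in range(len(contigs)):
            contig = contigs[ci % len(contigs)]
            ci += 1
            base = cursors[contig]
            if base + block.span <= cfg.genes_per_contig:
                placements.append((block, contig, base))
                cursors[contig] = base + block.span + cfg.window + 2
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible layout: genes_per_contig too small for the block roster"
            )

    planted: dict[str, PlantedGene] = {}
    occupied: dict[tuple[str, int], PlantedGene] = {}

    def gene_id_at(contig: str, idx: int) -> str:
        return f"{contig}_g{idx:03d}"

    for block, contig, base in placements:
        for bg in block.genes:
            idx = base + bg.rel
            gid = gene_id_at(contig, idx)
            pg = PlantedGene(gid, contig, idx, bg.role, bg.families, bg.length_nt)
            planted[gid] = pg
            occupied[(contig, idx)] = pg

    genes: list[GeneRecord] = []
    for contig in contigs:
        for idx in range(cfg.genes_per_contig):
            pg = occupied.get((contig, idx))
            length = pg.length_nt if pg else _ROLE_LENGTH["filler"]
            start = 1 + idx * 3200
            genes.append(
                GeneRecord(
                    gene_id=gene_id_at(contig, idx),
                    contig_id=contig,
                    genome_id=contig_genome[contig],
                    index=idx,
                    start=start,
                    end=start + length - 1,
                    strand="+" if idx % 2 == 0 else "-",
                )
            )

    # --- cluster/PUL truth
    clusters: list[PlantedCluster] = []
    near_miss_pairs: list[tuple[str, str]] = []
    gt_runs: list[tuple[str, ...]] = []
    tbdt_truth: dict[str, TbdtTruth] = {}
    susd_ids: set[str] = set()
    sulfatase_ids: set[str] = set()

    for block, contig, base in placements:
        gids = tuple(gene_id_at(contig, base + bg.rel) for bg in block.genes)
        marker_rels = [
            bg.rel
            for bg in block.genes
            if bg.role in ("tbdt", "tbdt_susc", "susd", "caz", "sulf")
        ]
        if block.kind in ("pul", "ambiguous"):
            tbdt_gid = gids[0]
            tbdt_truth[tbdt_gid] = TbdtTruth(
                is_susc_like=block.susc,
                substrate=block.substrate,
                expr_group=block.substrate
                if block.substrate in cfg.class_shares
                else OTHER_TBDT,
            )
            if block.susc:
                susd_ids.add(gene_id_at(contig, base + 1))
            clusters.append(
                PlantedCluster(
                    contig_id=contig,
                    marker_indices=tuple(base + r for r in marker_rels),
                    gene_ids=gids,
                    has_tbdt=True,
                    is_pul=True,
                    substrate=block.substrate,
                )
            )
        elif block.kind == "nontbdt_cluster":
            sulfatase_ids.add(gids[0])
            clusters.append(
                PlantedCluster(
                    contig_id=contig,
                    marker_indices=tuple(base + r for r in marker_rels),
                    gene_ids=gids,
                    has_tbdt=False,
                    is_pul=False,
                    substrate=None,
                )
            )
        elif block.kind == "lone":
            tbdt_truth[gids[0]] = TbdtTruth(
                is_susc_like=block.susc, substrate=NO_CAZYME, expr_group=OTHER_TBDT
            )
        elif block.kind == "near_miss":
            tbdt_truth[gids[0]] = TbdtTruth(
                is_susc_like=block.susc, substrate=NO_CAZYME, expr_group=OTHER_TBDT
            )
            near_miss_pairs.append((gids[0], gids[1]))
        elif block.kind == "gt_run":
            gt_runs.append(gids)

    # --- MAG roster: one primary per species, two variants, one QC failure
    mags: list[MagRecord] = []
    sizes = rng.integers(2_000_000, 4_000_000, size=len(species))
    for i, sp in enumerate(species):
        taxonomy = _BACTEROIDETES if i % 2 == 0 else _GAMMA
        mags.append(
            MagRecord(
                mag_id=primary_mag[sp],
                size_bp=int(sizes[i]),
                completeness_a=90.0 + (i % 5),
                completeness_b=88.0 + (i % 6),
                contamination_a=1.0 + 0.3 * (i % 4),
                contamination_b=1.5 + 0.2 * (i % 3),
                taxonomy=f"{taxonomy};g__Genus{sp}",
            )
        )
    # small, less complete sibling: representative stays with the primary
    mags.append(
        MagRecord(
            mag_id="MAG_S01_sib",
            size_bp=int(sizes[0]) - 400_000,
            completeness_a=70.0,
            completeness_b=68.0,
            contamination_a=2.0,
            contamination_b=2.5,
            taxonomy=mags[0].taxonomy,
        )
    )
    # larger sibling with near-equivalent completeness and no worse
    # contamination: overrides the default representative of species 2
    s02 = mags[1]
    mags.append(
        MagRecord(
            mag_id="MAG_S02_big",
            size_bp=s02.size_bp + 300_000,
            completeness_a=s02.completeness_a - 3.0,
            completeness_b=s02.completeness_b - 3.0,
            contamination_a=s02.contamination_a,
            contamination_b=s02.contamination_b,
            taxonomy=s02.taxonomy,
        )
    )
    mags.append(
        MagRecord(
            mag_id="MAG_junk",
            size_bp=900_000,
            completeness_a=42.0,
            completeness_b=45.0,
            contamination_a=8.0,
            contamination_b=6.5,
            taxonomy="d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria",
        )
    )

    mag_ids = [m.mag_id for m in mags]
    dist = pd.DataFrame(0.0, index=mag_ids, columns=mag_ids)
    for i, a in enumerate(mag_ids):
        for j, b in enumerate(mag_ids):
            if i < j:
                same = a.split("_")[1] == b.split("_")[1]  # MAG_<sp>[_suffix]
                d = 0.03 if same else round(0.3 + 0.01 * ((i * 7 + j * 3) % 40), 3)
                dist.loc[a, b] = dist.loc[b, a] = d

    retained = {m.mag_id for m in mags if m.mag_id != "MAG_junk"}
    species_groups = sorted(
        (
            frozenset(
                mid for mid in retained if mid.split("_")[1] == sp
            )
            for sp in species
        ),
        key=min,
    )
    representatives = {
        grp: ("MAG_S02_big" if "MAG_S02_big" in grp else primary_mag[min(grp).split("_")[1]])
        for grp in species_groups
    }

    # --- expressed protein roster and MAG-assignment truth
    filler_ids = [
        g.gene_id
        for g in genes
        if g.gene_id not in planted
    ]
    background = sorted(
        rng.choice(filler_ids, size=cfg.n_background_proteins, replace=False)
    )
    expr_group: dict[str, str] = {gid: t.expr_group for gid, t in tbdt_truth.items()}
    for gid in background:
        expr_group[gid] = BACKGROUND

    proteins = sorted(expr_group)
    gene_contig = {g.gene_id: g.contig_id for g in genes}
    mag_assign_truth: dict[str, str] = {}
    subject_to_mag: dict[str, str] = {}
    aln_rows: list[str] = []
    subj_n = 0
    tie_break_budget = 3
    for protein in proteins:
        mag = contig_genome[gene_contig[protein]]
        # a sub-threshold decoy hit exercises the identity gate
        wrong_mag = primary_mag[species[(species.index(mag.split("_")[1]) + 1) % len(species)]]
        subj_n += 1
        decoy_subject = f"{wrong_mag}|p{subj_n}"
        subject_to_mag[decoy_subject] = wrong_mag
        if rng.random() < cfg.mag_unassigned_rate:
            mag_assign_truth[protein] = UNASSIGNED
            aln_rows.append(_aln_row(protein, decoy_subject, 98.5, 1e-60, 380.0, 95.0))
            continue
        mag_assign_truth[protein] = mag
        subj_n += 1
        subject = f"{mag}|p{subj_n}"
        subject_to_mag[subject] = mag
        aln_rows.append(_aln_row(protein, subject, 99.6, 1e-60, 410.0, 98.0))
        aln_rows.append(_aln_row(protein, decoy_subject, 98.5, 1e-60, 380.0, 95.0))
        if tie_break_budget > 0:
            # second passing hit with a lower bitscore: best-hit rule decides
            tie_break_budget -= 1
            sib = "MAG_S01_sib" if mag == "MAG_S01" else mag
            subj_n += 1
            weaker = f"{sib}|p{subj_n}"
            subject_to_mag[weaker] = sib
            aln_rows.append(_aln_row(protein, weaker, 99.3, 1e-50, 395.0, 97.0))

    # --- write input files
    files: dict[str, Path] = {}

    gff_lines = ["##gff-version 3"]
    for g in genes:
        gff_lines.append(
            "\t".join(
                [
                    g.contig_id,
                    "pulquant_sim",
                    "CDS",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    "0",
                    f"ID={g.gene_id}",
                ]
            )
        )
    files["genes_gff"] = _write(out_dir / "genes.gff3", "\n".join(gff_lines) + "\n")

    files["cazyme_domtbl"] = _write(
        out_dir / "cazyme_domtbl.txt", _cazyme_domtbl(planted.values())
    )
    files["tbdt_domtbl"] = _write(
        out_dir / "tbdt_domtbl.txt", _tbdt_domtbl(planted.values())
    )
    files["cazy_confirm"] = _write(
        out_dir / "cazy_confirm.tsv", _confirm_table(planted.values())
    )
    files["susd_ids"] = _write(out_dir / "susd_ids.txt", "\n".join(sorted(susd_ids)) + "\n")
    files["sulfatase_ids"] = _write(
        out_dir / "sulfatase_ids.txt", "\n".join(sorted(sulfatase_ids)) + "\n"
    )
    files["mag_hits"] = _write(out_dir / "mag_hits.tsv", "\n".join(aln_rows) + "\n")
    files["subject_map"] = _write(
        out_dir / "subject_map.tsv",
        "subject_id\tmag_id\n"
        + "\n".join(f"{s}\t{m}" for s, m in sorted(subject_to_mag.items()))
        + "\n",
    )
    files["contig_map"] = _write(
        out_dir / "contig_map.tsv",
        "contig_id\tgenome_id\n"
        + "\n".join(f"{c}\t{m}" for c, m in sorted(contig_genome.items()))
        + "\n",
    )

    mag_df = pd.DataFrame(
        [
            {
                "mag_id": m.mag_id,
                "size_bp": m.size_bp,
                "completeness_a": m.completeness_a,
                "completeness_b": m.completeness_b,
                "contamination_a": m.contamination_a,
                "contamination_b": m.contamination_b,
                "taxonomy": m.taxonomy,
            }
            for m in mags
        ]
    )
    mag_df.to_csv(out_dir / "mag_quality.tsv", sep="\t", index=False)
    files["mag_quality"] = out_dir / "mag_quality.tsv"
    dist.rename_axis("mag_id").to_csv(out_dir / "mag_distances.tsv", sep="\t")
    files["mag_distances"] = out_dir / "mag_distances.tsv"

    design = [
        SampleDesign(
            sample_id=f"P{t + 1}",
            julian_day=cfg.proteome_days[t],
            replicate_ids=tuple(
                f"P{t + 1}_r{r + 1}" for r in range(cfg.n_replicates)
            ),
        )
        for t in range(cfg.n_samples)
    ]
    design_df = pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "julian_day": d.julian_day,
                "replicate_ids": ",".join(d.replicate_ids),
            }
            for d in design
        ]
    )
    design_df.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    files["design"] = out_dir / "design.tsv"

    truth = CommunityTruth(
        cfg=cfg,
        genes=genes,
        planted=planted,
        clusters=clusters,
        near_miss_pairs=near_miss_pairs,
        gt_runs=gt_runs,
        tbdt_truth=tbdt_truth,
        mags=mags,
        distances=dist,
        retained_mags=retained,
        species_groups=species_groups,
        representatives=representatives,
        mag_assign_truth=mag_assign_truth,
        subject_to_mag=subject_to_mag,
        contig_genome=contig_genome,
        expr_group=expr_group,
        susd_ids=susd_ids,
        sulfatase_ids=sulfatase_ids,
        design=design,
        files=files,
    )

    abundance = simulate_expression(truth, cfg)
    spectra = abundance.values.copy()
    spectra.index.name = "protein_id"
    spectra.to_csv(out_dir / "spectra.tsv", sep="\t")
    files["spectra"] = out_dir / "spectra.tsv"
    lengths = abundance.lengths.rename("length_aa")
    lengths.index.name = "protein_id"
    lengths.to_csv(out_dir / "protein_lengths.tsv", sep="\t")
    files["protein_lengths"] = out_dir / "protein_lengths.tsv"

    reads = simulate_metagenome_counts(truth, cfg)
    counts = reads.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(out_dir / "readcounts.tsv", sep="\t")
    files["readcounts"] = out_dir / "readcounts.tsv"
    glen = reads.feature_len_kbp.rename("length_kbp")
    glen.index.name = "gene_id"
    glen.to_csv(out_dir / "gene_lengths.tsv", sep="\t")
    files["gene_lengths"] = out_dir / "gene_lengths.tsv"
    libs = reads.library_size.rename("total_reads").to_frame()
    libs.insert(0, "julian_day", list(cfg.metagenome_days))
    libs.index.name = "sample_id"
    libs.to_csv(out_dir / "library_sizes.tsv", sep="\t")
    files["library_sizes"] = out_dir / "library_sizes.tsv"

    # truth tables, for inspection and for truth-recovery reports
    tbdt_df = pd.DataFrame(
        [
            {
                "protein_id": gid,
                "is_susc_like": t.is_susc_like,
                "substrate": t.substrate,
                "expr_group": t.expr_group,
            }
            for gid, t in sorted(tbdt_truth.items())
        ]
    )
    tbdt_df.to_csv(out_dir / "truth_tbdts.tsv", sep="\t", index=False)
    files["truth_tbdts"] = out_dir / "truth_tbdts.tsv"
    cluster_df = pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "marker_indices": ",".join(map(str, c.marker_indices)),
                "has_tbdt": c.has_tbdt,
                "is_pul": c.is_pul,
                "substrate": c.substrate if c.substrate else "",
            }
            for c in clusters
        ]
    )
    cluster_df.to_csv(out_dir / "truth_clusters.tsv", sep="\t", index=False)
    files["truth_clusters"] = out_dir / "truth_clusters.tsv"
    assign_df = pd.DataFrame(
        sorted(mag_assign_truth.items()), columns=["protein_id", "mag_id"]
    )
    assign_df.to_csv(out_dir / "truth_mag_assign.tsv", sep="\t", index=False)
    files["truth_mag_assign"] = out_dir / "truth_mag_assign.tsv"

    return truth


def _write(path: Path, text: str) -> Path:
    path.write_text(text)
    return path


def _aln_row(
    query: str,
    subject: str,
    identity: float,
    evalue: float,
    bitscore: float,
    qcov: float,
) -> str:
    return "\t".join(
        [
            query,
            subject,
            f"{identity:.1f}",
            "500", "5", "0", "1", "500", "1", "500",
            f"{evalue:.1e}",
            f"{bitscore:.1f}",
            f"{qcov:.1f}",
        ]
    )


def _domtbl_row(
    profile: str,
    tlen: int,
    query: str,
    qlen: int,
    i_evalue: float,
    score: float,
    hmm_from: int,
    hmm_to: int,
    ali_from: int,
    ali_to: int,
) -> str:
    return (
        f"{profile} - {tlen} {query} - {qlen} {i_evalue:.1e} {score:.1f} 0.1 "
        f"1 1 {i_evalue:.1e} {i_evalue:.1e} {score:.1f} 0.1 "
        f"{hmm_from} {hmm_to} {ali_from} {ali_to} {ali_from} {ali_to} 0.95 -"
    )


def _cazyme_domtbl(planted) -> str:
    lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------",
        "# target name accession tlen query name accession qlen E-value score bias # of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to env_from env_to acc description",
    ]
    for pg in sorted(planted, key=lambda p: p.gene_id):
        qlen = pg.length_nt // 3
        if pg.role in ("caz", "gt"):
            for fam in sorted(pg.families):
                lines.append(
                    _domtbl_row(fam, 300, pg.gene_id, qlen, 1e-30, 250.0, 11, 290, 15, 295)
                )
        elif pg.role == "caz_lowcov":
            # fails the dbCAN coverage gate despite a strong e-value
            for fam in sorted(pg.families):
                lines.append(
                    _domtbl_row(fam, 300, pg.gene_id, qlen, 1e-50, 300.0, 1, 55, 1, 55)
                )
        elif pg.role == "caz_short":
            # short-alignment branch: 60 aa, e-value between the two gates
            for fam in sorted(pg.families):
                lines.append(
                    _domtbl_row(fam, 100, pg.gene_id, qlen, 1e-4, 40.0, 21, 80, 1, 60)
                )
        elif pg.role == "caz_overlap":
            # two overlapping accepted hits; dedup keeps the lower e-value
            fams = sorted(pg.families)
            lines.append(
                _domtbl_row(fams[0], 300, pg.gene_id, qlen, 1e-30, 250.0, 11, 290, 10, 250)
            )
            lines.append(
                _domtbl_row(fams[1], 300, pg.gene_id, qlen, 1e-20, 180.0, 11, 290, 20, 240)
            )
        elif pg.role == "caz_noconfirm":
            # passes the HMM stage but gets no confirming alignment
            for fam in sorted(pg.families):
                lines.append(
                    _domtbl_row(fam, 300, pg.gene_id, qlen, 1e-30, 250.0, 11, 290, 15, 295)
                )
    return "\n".join(lines) + "\n"


def _tbdt_domtbl(planted) -> str:
    lines = ["# hmmscan per-domain output"]
    for pg in sorted(planted, key=lambda p: p.gene_id):
        if pg.role not in ("tbdt", "tbdt_susc"):
            continue
        qlen = pg.length_nt // 3
        lines.append(
            _domtbl_row("PF00593", 650, pg.gene_id, qlen, 1e-60, 400.0, 5, 640, 300, 960)
        )
        if pg.role == "tbdt_susc":
            lines.append(
                _domtbl_row("TIGR04056", 900, pg.gene_id, qlen, 1e-80, 600.0, 3, 890, 20, 950)
            )
        else:
            lines.append(
                _domtbl_row("PF07715", 120, pg.gene_id, qlen, 1e-25, 90.0, 2, 118, 30, 150)
            )
    return "\n".join(lines) + "\n"


def _confirm_table(planted) -> str:
    rows = []
    n = 0
    for pg in sorted(planted, key=lambda p: p.gene_id):
        if pg.role in ("caz", "gt", "caz_short", "caz_overlap"):
            for fam in sorted(pg.families):
                n += 1
                rows.append(
                    _aln_row(pg.gene_id, f"czy{n:04d}|{fam}", 55.0, 1e-40, 320.0, 80.0)
                )
        elif pg.role == "caz_noconfirm":
            for fam in sorted(pg.families):
                n += 1
                # e-value above the confirmation cutoff: family must drop
                rows.append(
                    _aln_row(pg.gene_id, f"czy{n:04d}|{fam}", 55.0, 1e-15, 120.0, 80.0)
                )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# expression and metagenome simulation


def _group_weights(
    proteins: Sequence[str], expr_group: Mapping[str, str], rng: np.random.Generator
) -> pd.Series:
    """Fixed per-protein weights, normalised within each expression group."""
    w = pd.Series(rng.lognormal(mean=0.0, sigma=0.5, size=len(proteins)), index=proteins)
    groups = pd.Series([expr_group[p] for p in proteins], index=proteins)
    return w / groups.map(w.groupby(groups).sum())


def expected_shares(truth: CommunityTruth) -> pd.DataFrame:
    """Expected %-of-proteome per expression group per sample."""
    cfg = truth.cfg
    rows: dict[str, list[float]] = {}
    for cls, (s0, s1) in cfg.class_shares.items():
        rows[cls] = [_loglinear(s0, s1, t, cfg.n_samples) for t in range(cfg.n_samples)]
    class_sum = np.sum(list(rows.values()), axis=0)
    tbdt_total = np.asarray(cfg.tbdt_total_share)
    rows[OTHER_TBDT] = list(tbdt_total - class_sum)
    rows[BACKGROUND] = list(100.0 - tbdt_total)
    return pd.DataFrame(rows, index=[d.sample_id for d in truth.design]).T


def simulate_expression(
    truth: CommunityTruth, cfg: GeneratorConfig | None = None
) -> AbundanceMatrix:
    """Draw the protein x replicate quantitative-value matrix.

    Expected values follow the group share trajectories; replicates are
    gamma-Poisson (negative-binomial) with the configured dispersion, and a
    fraction of protein/replicate cells is set missing.  With ``cfg.clean``
    the expectations are returned exactly with no missing cells.
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng([cfg.seed, 23])
    proteins = sorted(truth.expr_group)
    weights = _group_weights(proteins, truth.expr_group, rng)
    shares = expected_shares(truth)

    lengths = {}
    gene_by_id = {g.gene_id: g for g in truth.genes}
    for p in proteins:
        lengths[p] = gene_by_id[p].length_aa

    columns: list[str] = []
    data: dict[str, np.ndarray] = {}
    for d in truth.design:
        group_share = shares[d.sample_id]
        mu = np.array(
            [
                cfg.total_spectra
                * group_share[truth.expr_group[p]]
                / 100.0
                * weights[p]
                for p in proteins
            ]
        )
        for rep in d.replicate_ids:
            if cfg.clean:
                vals = mu.copy()
            else:
                lam = rng.gamma(
                    shape=1.0 / cfg.nb_dispersion,
                    scale=mu * cfg.nb_dispersion,
                )
                vals = rng.poisson(lam).astype(float)
                drop = rng.random(len(proteins)) < cfg.missing_rate
                vals[drop] = np.nan
            data[rep] = vals
            columns.append(rep)

    values = pd.DataFrame(data, index=proteins, columns=columns)
    return AbundanceMatrix(
        values=values,
        lengths=pd.Series(lengths),
        design=list(truth.design),
        mode="quantitative",
    )


def simulate_metagenome_counts(
    truth: CommunityTruth, cfg: GeneratorConfig | None = None
) -> ReadCountTable:
    """Draw time-flat Poisson read counts for every TBDT gene.

    Expected per-gene RPKM is constant across the nine metagenome samples;
    class RPKM totals follow ``cfg.class_rpkm``.  Library sizes vary up to
    two-fold across samples, which RPKM must cancel out.
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng([cfg.seed, 37])
    gene_by_id = {g.gene_id: g for g in truth.genes}

    tbdt_genes = sorted(truth.tbdt_truth)
    group_of = {g: truth.tbdt_truth[g].expr_group for g in tbdt_genes}
    weights = _group_weights(tbdt_genes, group_of, rng)
    rpkm_expect = pd.Series(
        [cfg.class_rpkm[group_of[g]] * weights[g] for g in tbdt_genes], index=tbdt_genes
    )

    lo, hi = cfg.library_size_range
    libs = pd.Series(
        np.round(rng.uniform(lo, hi, size=len(cfg.metagenome_days))),
        index=[f"M{t + 1}" for t in range(len(cfg.metagenome_days))],
    )
    len_kbp = pd.Series(
        {g: gene_by_id[g].end - gene_by_id[g].start + 1 for g in tbdt_genes},
        dtype=float,
    ) / 1000.0

    counts = {}
    for sample in libs.index:
        mu = rpkm_expect * len_kbp * libs[sample] / 1e6
        counts[sample] = rng.poisson(mu.to_numpy())
    counts_df = pd.DataFrame(counts, index=tbdt_genes)
    return ReadCountTable(
        counts=counts_df, feature_len_kbp=len_kbp, library_size=libs
    )
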