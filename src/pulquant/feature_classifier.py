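"""Turn raw domain/alignment hits into gene feature labels and protein categories.

The feature vocabulary follows the Sus nomenclature of Bacteroidetes glycan
uptake: TonB-dependent transporters (TBDTs), their SusC-like subfamily,
SusD-like substrate-binding partners, sulfatases, and CAZymes (with
biosynthetic glycosyl transferases set aside, since only degradative CAZymes
mark polysaccharide utilisation loci).

CAZyme calls follow the two-stage dbCAN convention: an HMM-hit filter
(coverage and length-dependent e-value gates plus overlap deduplication),
then confirmation by alignment against a tagged CAZyme reference set.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, Field, model_validator

from .annotation_io import AlignmentHit, DomainHit, GeneRecord


class FeatureKind(str, enum.Enum):
    CAZYME = "cazyme"
    GLYCOSYL_TRANSFERASE = "glycosyl_transferase"
    TBDT = "tbdt"
    SUSC_LIKE = "susc_like"
    SUSD_LIKE = "susd_like"
    SULFATASE = "sulfatase"
    OTHER = "other"


#: label kinds that make a gene a clustering marker (GT-only genes excluded)
MARKER_KINDS = frozenset(
    {FeatureKind.CAZYME, FeatureKind.SULFATASE, FeatureKind.TBDT, FeatureKind.SUSD_LIKE}
)


@dataclass(frozen=True)
class FeatureLabel:
    """A feature kind plus its CAZyme families (nonempty only for CAZyme/GT)."""

    kind: FeatureKind
    families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind in (FeatureKind.CAZYME, FeatureKind.GLYCOSYL_TRANSFERASE):
            if not self.families:
                raise ValueError(f"{self.kind.value} label requires families")
        elif self.families:
            raise ValueError(f"{self.kind.value} label must not carry families")
        if self.kind is FeatureKind.GLYCOSYL_TRANSFERASE and not all(
            f.startswith("GT") for f in self.families
        ):
            raise ValueError("glycosyl transferase families must begin 'GT'")


# Reconstructed default panel: TIGR04056 (the SusC-like-specific model) plus
# plug/beta-barrel TonB-dependent receptor profiles.  The exact historical
# ten-model list is configuration, not a claim.
DEFAULT_TBDT_MODELS = (
    "TIGR04056",
    "PF00593",
    "PF07715",
    "TIGR01776",
    "TIGR01778",
    "TIGR01782",
    "TIGR01783",
    "TIGR01785",
    "TIGR01786",
    "TIGR02804",
)
SUSC_MODEL = "TIGR04056"


class CazymeHmmFilter(BaseModel):
    """dbCAN-style HMM hit gates: e-value branches on alignment length."""

    evalue_long: float = 1e-5
    evalue_short: float = 1e-3
    short_len_aa: int = 80
    min_cov: float = 0.3


class CazymeConfirmFilter(BaseModel):
    """Alignment confirmation gates against the CAZyme reference set."""

    max_evalue: float = 1e-20
    min_query_cover_pct: float = 40.0
    min_identity_pct: float = 30.0


class TcdbFilter(BaseModel):
    max_evalue: float = 1e-10


class MagAssignFilter(BaseModel):
    min_identity_pct: float = 99.0
    max_evalue: float = 1e-4


class FilterConfig(BaseModel):
    """All classification thresholds in one validated bundle.

    Comparison conventions (applied consistently): e-value gates are strict
    (<); identity and coverage minima are inclusive (>=); the HMM coverage
    gate is strict (>), matching the dbCAN parser.
    """

    cazyme_hmm: CazymeHmmFilter = Field(default_factory=CazymeHmmFilter)
    cazyme_confirm: CazymeConfirmFilter = Field(default_factory=CazymeConfirmFilter)
    tbdt_models: tuple[str, ...] = DEFAULT_TBDT_MODELS
    susc_model: str = SUSC_MODEL
    tcdb: TcdbFilter = Field(default_factory=TcdbFilter)
    mag_assign: MagAssignFilter = Field(default_factory=MagAssignFilter)

    @model_validator(mode="after")
    def _susc_in_panel(self) -> "FilterConfig":
        if self.susc_model not in self.tbdt_models:
            raise ValueError("susc_model must be one of tbdt_models")
        return self


def _hit_passes_dbcan(hit: DomainHit, cfg: CazymeHmmFilter) -> bool:
    if hit.hmm_cov <= cfg.min_cov:
        return False
    if hit.ali_len > cfg.short_len_aa:
        return hit.e_value < cfg.evalue_long
    return hit.e_value < cfg.evalue_short


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    """Overlap of two query alignments as a fraction of the shorter one."""
    overlap = min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1
    if overlap <= 0:
        return 0.0
    return overlap / min(a.ali_len, b.ali_len)


def filter_cazyme_hits(
    hits: Iterable[DomainHit], cfg: FilterConfig | None = None
) -> dict[str, set[str]]:
    """Apply the dbCAN hit filter; return accepted families per gene.

    A hit is accepted iff its profile coverage exceeds ``min_cov`` and its
    e-value clears the long- or short-alignment gate.  Accepted hits on the
    same gene that overlap by more than half of the shorter alignment are
    deduplicated keeping the lower e-value.
    """
    cfg = cfg or FilterConfig()
    by_gene: dict[str, list[DomainHit]] = defaultdict(list)
    for hit in hits:
        if _hit_passes_dbcan(hit, cfg.cazyme_hmm):
            by_gene[hit.query_id].append(hit)

    families: dict[str, set[str]] = {}
    for gene, gene_hits in by_gene.items():
        kept: list[DomainHit] = []
        # greedy by ascending e-value; deterministic tie-break on coordinates
        for hit in sorted(
            gene_hits, key=lambda h: (h.e_value, -h.bitscore, h.ali_from, h.profile_id)
        ):
            if all(_overlap_fraction(hit, k) <= 0.5 for k in kept):
                kept.append(hit)
        if kept:
            families[gene] = {h.profile_id for h in kept}
    return families


def family_of_subject(subject_id: str) -> str:
    """Family tag of a CAZyme reference subject: the token after the last '|'."""
    return subject_id.rsplit("|", 1)[-1]


def confirm_cazymes(
    hmm_families: Mapping[str, set[str]],
    aln_hits: Iterable[AlignmentHit],
    cfg: FilterConfig | None = None,
    subject_family: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Keep only HMM families confirmed by a passing alignment to that family.

    A family survives for a gene iff at least one alignment hit to a subject
    tagged with that family has e-value < ``max_evalue``, query cover >=
    ``min_query_cover_pct`` and identity >= ``min_identity_pct``.  Genes left
    with no family are dropped.  Hits lacking coverage raise: confirmation
    must never pass silently without its coverage gate.
    """
    cfg = cfg or FilterConfig()
    gate = cfg.cazyme_confirm

    confirmed_pairs: set[tuple[str, str]] = set()
    for hit in aln_hits:
        if hit.query_id not in hmm_families:
            continue
        if hit.query_cover is None:
            raise ValueError(
                f"alignment hit {hit.query_id}->{hit.subject_id} lacks query coverage; "
                "supply a coverage column or query lengths"
            )
        fam = (
            subject_family[hit.subject_id]
            if subject_family is not None
            else family_of_subject(hit.subject_id)
        )
        if (
            hit.e_value < gate.max_evalue
            and hit.query_cover >= gate.min_query_cover_pct
            and hit.pct_identity >= gate.min_identity_pct
        ):
            confirmed_pairs.add((hit.query_id, fam))

    out: dict[str, set[str]] = {}
    for gene, fams in hmm_families.items():
        kept = {f for f in fams if (gene, f) in confirmed_pairs}
        if kept:
            out[gene] = kept
    return out


@dataclass(frozen=True)
class TbdtCall:
    is_tbdt: bool
    is_susc_like: bool


def classify_tbdt(
    hits: Iterable[DomainHit], cfg: FilterConfig | None = None
) -> dict[str, TbdtCall]:
    """Classify genes as TBDT / SusC-like from panel model hits.

    A gene is a TBDT iff it has at least one hit to any panel model at the
    scanner's own reporting threshold (no extra e-value gate); it is
    SusC-like iff at least one of those hits is to the SusC-specific model.
    SusC-like implies TBDT by construction.
    """
    cfg = cfg or FilterConfig()
    panel = set(cfg.tbdt_models)
    calls: dict[str, TbdtCall] = {}
    susc: dict[str, bool] = defaultdict(bool)
    seen: set[str] = set()
    for hit in hits:
        if hit.profile_id not in panel:
            continue
        seen.add(hit.query_id)
        if hit.profile_id == cfg.susc_model:
            susc[hit.query_id] = True
    for gene in seen:
        calls[gene] = TbdtCall(is_tbdt=True, is_susc_like=susc[gene])
    return calls


def label_genes(
    genes: Sequence[GeneRecord],
    cazymes: Mapping[str, set[str]],
    tbdts: Mapping[str, TbdtCall],
    susd_ids: set[str] = frozenset(),
    sulfatase_ids: set[str] = frozenset(),
) -> list[GeneRecord]:
    """Attach feature labels to gene records (returns the same records, labelled).

    Genes whose only CAZyme families are GT* are labelled glycosyl
    transferase (not a clustering marker); mixed GT/non-GT genes are CAZyme
    markers carrying only their non-GT families for substrate logic.
    """
    known = {g.gene_id for g in genes}
    for name, ids in (
        ("cazyme", cazymes.keys()),
        ("tbdt", tbdts.keys()),
        ("susd", susd_ids),
        ("sulfatase", sulfatase_ids),
    ):
        stray = set(ids) - known
        if stray:
            raise ValueError(f"{name} annotation references unknown genes: {sorted(stray)[:5]}")

    for gene in genes:
        labels: set[FeatureLabel] = set()
        fams = cazymes.get(gene.gene_id)
        if fams:
            gt = frozenset(f for f in fams if f.startswith("GT"))
            non_gt = frozenset(fams) - gt
            if non_gt:
                labels.add(FeatureLabel(FeatureKind.CAZYME, non_gt))
            elif gt:
                labels.add(FeatureLabel(FeatureKind.GLYCOSYL_TRANSFERASE, gt))
        call = tbdts.get(gene.gene_id)
        if call and call.is_tbdt:
            labels.add(FeatureLabel(FeatureKind.TBDT))
            if call.is_susc_like:
                labels.add(FeatureLabel(FeatureKind.SUSC_LIKE))
        if gene.gene_id in susd_ids:
            labels.add(FeatureLabel(FeatureKind.SUSD_LIKE))
        if gene.gene_id in sulfatase_ids:
            labels.add(FeatureLabel(FeatureKind.SULFATASE))
        gene.labels = labels
    return list(genes)


def is_marker(gene: GeneRecord) -> bool:
    """True iff the gene carries a clustering-marker label (GT-only excluded)."""
    return any(lab.kind in MARKER_KINDS for lab in gene.labels)


def gene_families(gene: GeneRecord, include_gt: bool = False) -> frozenset[str]:
    """Substrate-relevant (non-GT) CAZyme families on a gene."""
    fams: set[str] = set()
    for lab in gene.labels:
        if lab.kind is FeatureKind.CAZYME:
            fams |= lab.families
        elif include_gt and lab.kind is FeatureKind.GLYCOSYL_TRANSFERASE:
            fams |= lab.families
    return frozenset(fams)


class CategoryRule(BaseModel):
    """Membership rule for one protein category (Pfam set OR TCDB prefixes)."""

    pfam: set[str] = Field(default_factory=set)
    tcdb_prefixes: set[str] = Field(default_factory=set)


def _tcdb_prefix_match(subject_id: str, prefix: str) -> bool:
    return subject_id == prefix or subject_id.startswith(prefix + ".")


def assign_categories(
    protein_ids: Iterable[str],
    pfam_hits: Iterable[DomainHit],
    tcdb_hits: Iterable[AlignmentHit],
    category_cfg: Mapping[str, CategoryRule],
    cfg: FilterConfig | None = None,
) -> dict[str, set[str]]:
    """Assign proteins to functional categories via Pfam OR TCDB membership.

    A protein belongs to a category iff it has a Pfam hit whose accession is
    in the category's Pfam set, or a TCDB alignment hit below the e-value
    gate whose subject family matches one of the category's TCDB prefixes
    (dot-boundary matching on the TC number).
    """
    cfg = cfg or FilterConfig()
    proteins = set(protein_ids)
    out: dict[str, set[str]] = {p: set() for p in proteins}

    pfam_by_protein: dict[str, set[str]] = defaultdict(set)
    for hit in pfam_hits:
        if hit.query_id in proteins:
            pfam_by_protein[hit.query_id].add(hit.profile_id)
    tcdb_by_protein: dict[str, set[str]] = defaultdict(set)
    for hit in tcdb_hits:
        if hit.query_id in proteins and hit.e_value < cfg.tcdb.max_evalue:
            tcdb_by_protein[hit.query_id].add(hit.subject_id)

    for protein in proteins:
        for name, rule in category_cfg.items():
            if pfam_by_protein[protein] & rule.pfam or any(
                _tcdb_prefix_match(s, pre)
                for s in tcdb_by_protein[protein]
                for pre in rule.tcdb_prefixes
            ):
                out[protein].add(name)
    return out
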