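"""Substrate-class prediction for PULs and the TBDT category tabulation.

Each PUL is scored against a configurable rule table mapping polysaccharide
substrate classes to indicator CAZyme families.  A class is eligible when
enough distinct indicator families are present (and, for composite classes
such as the fucose/mannose/xylose-containing polymers, enough distinct
indicator groups) and no veto family occurs.  Exactly one eligible class
yields a call; zero or several yield ``no_substrate_predicted`` — a
deliberately conservative ambiguity rule.

TBDTs are then filed into the six standard expression categories (SusC-like
or not, crossed with substrate predicted / CAZyme-associated without
substrate / no CAZyme association) and summarised with their %NSAF shares.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .feature_classifier import TbdtCall
from .pul_caller import GeneCluster

NO_SUBSTRATE_PREDICTED = "no_substrate_predicted"
NO_CAZYME = "no_cazyme"

# Indicator groups for the composite fucose/mannose/xylose class.
FUCOSE_FAMILIES = frozenset({"GH29", "GH95"})
MANNOSE_FAMILIES = frozenset({"GH92", "GH38", "GH76"})
XYLOSE_FAMILIES = frozenset({"GH10", "GH43", "GH67", "GH115"})


class SubstrateRule(BaseModel):
    """Eligibility rule for one substrate class."""

    indicator_families: set[str]
    min_indicators: int = 1
    veto_families: set[str] = Field(default_factory=set)
    indicator_groups: tuple[frozenset[str], ...] | None = None
    min_groups: int = 1

    @model_validator(mode="after")
    def _nonempty(self) -> "SubstrateRule":
        if not self.indicator_families:
            raise ValueError("indicator_families must be nonempty")
        if self.min_indicators < 1 or self.min_groups < 1:
            raise ValueError("min_indicators and min_groups must be >= 1")
        return self

    def eligible(self, families: frozenset[str]) -> bool:
        if len(self.indicator_families & families) < self.min_indicators:
            return False
        if self.veto_families & families:
            return False
        if self.indicator_groups is not None:
            touched = sum(1 for grp in self.indicator_groups if grp & families)
            if touched < self.min_groups:
                return False
        return True


class SubstrateRuleTable(BaseModel):
    """Substrate classes and their indicator-family rules."""

    rules: dict[str, SubstrateRule]

    @classmethod
    def default(cls) -> "SubstrateRuleTable":
        """Shipped default rule table.

        This is a reconstruction from the characterised functions of common
        marine CAZyme families, not a published collection: laminarin
        (beta-1,3-glucan) hydrolases, alpha-glucan (glycogen/starch)
        hydrolases, alginate lyases, and the fucose/mannose/xylose-containing
        cell-wall polymer indicators.  The composite fmx class requires
        indicator hits in at least two of the three sugar groups; the
        single-sugar mannose/xylose classes veto the other groups' indicators
        so that composite evidence resolves to fmx rather than an ambiguity.
        """
        fmx_groups = (FUCOSE_FAMILIES, MANNOSE_FAMILIES, XYLOSE_FAMILIES)
        return cls(
            rules={
                "laminarin": SubstrateRule(indicator_families={"GH16", "GH17", "GH30"}),
                "alpha_glucan": SubstrateRule(indicator_families={"GH13", "GH31", "GH65"}),
                "alginate": SubstrateRule(indicator_families={"PL6", "PL7", "PL12", "PL17"}),
                "mannose_rich": SubstrateRule(
                    indicator_families=set(MANNOSE_FAMILIES),
                    veto_families=set(FUCOSE_FAMILIES | XYLOSE_FAMILIES),
                ),
                "xylose_rich": SubstrateRule(
                    indicator_families=set(XYLOSE_FAMILIES),
                    veto_families=set(FUCOSE_FAMILIES | MANNOSE_FAMILIES),
                ),
                "fmx": SubstrateRule(
                    indicator_families=set(
                        FUCOSE_FAMILIES | MANNOSE_FAMILIES | XYLOSE_FAMILIES
                    ),
                    min_indicators=2,
                    indicator_groups=fmx_groups,
                    min_groups=2,
                ),
            }
        )

    @property
    def classes(self) -> list[str]:
        return list(self.rules)


def predict_substrate(
    pul: GeneCluster, rules: SubstrateRuleTable | None = None
) -> str:
    """Predict the substrate class of a PUL from its CAZyme family content.

    Scoring counts distinct indicator families present in the PUL span.
    Exactly one eligible class wins; zero or >= 2 eligible classes resolve to
    ``no_substrate_predicted``.  Order of genes within the PUL is irrelevant.
    """
    rules = rules or SubstrateRuleTable.default()
    families = pul.family_set
    if not families:
        raise ValueError(f"PUL {pul.cluster_id} has no CAZyme families")
    eligible = [name for name, rule in rules.rules.items() if rule.eligible(families)]
    if len(eligible) == 1:
        return eligible[0]
    return NO_SUBSTRATE_PREDICTED


class TbdtCategory(str, enum.Enum):
    """The six TBDT expression categories (SusC-like x substrate evidence)."""

    SUSC_SUBSTRATE = "SusC-like with polysaccharide substrate predicted"
    SUSC_CAZYME_NO_SUBSTRATE = "SusC-like with CAZyme but no substrate predicted"
    SUSC_NO_CAZYME = "SusC-like with no CAZymes"
    NONSUSC_SUBSTRATE = "Not SusC-like with polysaccharide substrate predicted"
    NONSUSC_CAZYME_NO_SUBSTRATE = "Not SusC-like with CAZyme but no substrate predicted"
    NONSUSC_NO_CAZYME = "Not SusC-like with no CAZymes"


def derive_category(is_susc_like: bool, substrate: str) -> TbdtCategory:
    """Category is a pure function of the SusC flag and the substrate value."""
    if substrate == NO_CAZYME:
        return TbdtCategory.SUSC_NO_CAZYME if is_susc_like else TbdtCategory.NONSUSC_NO_CAZYME
    if substrate == NO_SUBSTRATE_PREDICTED:
        return (
            TbdtCategory.SUSC_CAZYME_NO_SUBSTRATE
            if is_susc_like
            else TbdtCategory.NONSUSC_CAZYME_NO_SUBSTRATE
        )
    return TbdtCategory.SUSC_SUBSTRATE if is_susc_like else TbdtCategory.NONSUSC_SUBSTRATE


@dataclass(frozen=True)
class TbdtRecord:
    """One expressed TBDT with its SusC flag, taxon, and substrate decision."""

    protein_id: str
    gene_id: str
    is_susc_like: bool
    substrate: str
    taxon: str = "unassigned"

    @property
    def category(self) -> TbdtCategory:
        return derive_category(self.is_susc_like, self.substrate)


def annotate_tbdts(
    tbdt_calls: Mapping[str, TbdtCall],
    clusters: Sequence[GeneCluster],
    substrates: Mapping[str, str],
    taxon_of: Mapping[str, str] | None = None,
    protein_of: Mapping[str, str] | None = None,
) -> list[TbdtRecord]:
    """Build one :class:`TbdtRecord` per TBDT gene.

    A TBDT inside a PUL with a substrate call gets that class; inside a
    CAZyme-containing cluster without a call it gets
    ``no_substrate_predicted``; otherwise ``no_cazyme``.  ``substrates`` maps
    cluster_id to class for the PULs.  ``taxon_of``/``protein_of`` optionally
    map gene_id to taxon and protein id (protein defaults to the gene id).
    """
    cluster_of_gene: dict[str, GeneCluster] = {}
    for cluster in clusters:
        for gene in cluster.gene_span:
            assert gene.gene_id not in cluster_of_gene, (
                f"gene {gene.gene_id} in two clusters"
            )
            cluster_of_gene[gene.gene_id] = cluster

    records: list[TbdtRecord] = []
    for gene_id in sorted(tbdt_calls):
        call = tbdt_calls[gene_id]
        if not call.is_tbdt:
            continue
        cluster = cluster_of_gene.get(gene_id)
        if cluster is None or not cluster.cazyme_families:
            substrate = NO_CAZYME
        else:
            substrate = substrates.get(cluster.cluster_id, NO_SUBSTRATE_PREDICTED)
        records.append(
            TbdtRecord(
                protein_id=(protein_of or {}).get(gene_id, gene_id),
                gene_id=gene_id,
                is_susc_like=call.is_susc_like,
                substrate=substrate,
                taxon=(taxon_of or {}).get(gene_id, "unassigned"),
            )
        )
    return records


def round1(x: float) -> float:
    """Round to 1 decimal, ties away from zero (matches printed table style)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


CATEGORY_ORDER = tuple(TbdtCategory)


def tabulate_categories(
    records: Sequence[TbdtRecord],
    nsaf: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Summarise TBDT records by category (the standard six-row table).

    Columns: count, pct_of_tbdts (1 decimal), mean_nsaf_pct (sum over the
    category of each protein's across-sample mean %NSAF) and pct_of_tbdt_nsaf
    (1 decimal).  Records without an %NSAF value contribute 0 with a warning.
    """
    if not records:
        raise ValueError("no TBDT records to tabulate")
    nsaf = nsaf or {}
    missing = [r.protein_id for r in records if r.protein_id not in nsaf]
    if missing and nsaf:
        warnings.warn(
            f"{len(missing)} TBDT records lack %NSAF values; treated as 0",
            stacklevel=2,
        )

    total = len(records)
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    nsaf_sums = {cat: 0.0 for cat in CATEGORY_ORDER}
    for rec in records:
        counts[rec.category] += 1
        nsaf_sums[rec.category] += nsaf.get(rec.protein_id, 0.0)
    total_nsaf = sum(nsaf_sums.values())

    rows = []
    for cat in CATEGORY_ORDER:
        rows.append(
            {
                "category": cat.value,
                "count": counts[cat],
                "pct_of_tbdts": round1(100.0 * counts[cat] / total),
                "mean_nsaf_pct": nsaf_sums[cat],
                "pct_of_tbdt_nsaf": round1(100.0 * nsaf_sums[cat] / total_nsaf)
                if total_nsaf > 0
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def tbdt_records_frame(records: Iterable[TbdtRecord]) -> pd.DataFrame:
    """Flat table of TBDT records (deterministic row order by protein id)."""
    df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "gene_id": r.gene_id,
                "is_susc_like": r.is_susc_like,
                "substrate": r.substrate,
                "category": r.category.value,
                "taxon": r.taxon,
            }
            for r in records
        ],
        columns=["protein_id", "gene_id", "is_susc_like", "substrate", "category", "taxon"],
    )
    return df.sort_values("protein_id", kind="mergesort").reset_index(drop=True)
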