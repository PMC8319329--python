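"""MAG quality filtering, species clustering, and protein-to-MAG assignment.

MAGs pass quality control when at least one estimator pair reports
completeness above 50% with contamination (or redundancy) below 5%; each
completeness estimate is paired with its own tool's contamination estimate.
Retained MAGs are clustered into approximate species by single-linkage on a
MASH-style genome distance matrix at distance < 0.05 (roughly ANI > 95%),
and each species cluster gets a representative: the most complete member,
unless a substantially larger MAG (> 100 kbp) with no worse contamination
and near-equivalent completeness is present.

Expressed proteins are assigned to MAGs by best high-identity alignment
(identity > 99%, e-value < 1e-4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .annotation_io import AlignmentHit
from .feature_classifier import FilterConfig

UNASSIGNED = "unassigned"


@dataclass
class MagRecord:
    """One MAG with two completeness/contamination estimates and a lineage."""

    mag_id: str
    size_bp: int
    completeness_a: float
    completeness_b: float
    contamination_a: float
    contamination_b: float
    taxonomy: str = ""

    def __post_init__(self) -> None:
        for attr in ("completeness_a", "completeness_b"):
            val = getattr(self, attr)
            if val > 100.0:
                warnings.warn(
                    f"{self.mag_id}: {attr} {val} > 100, clamping", stacklevel=2
                )
                setattr(self, attr, 100.0)
            if val < 0:
                raise ValueError(f"{self.mag_id}: negative {attr}")
        for attr in ("contamination_a", "contamination_b"):
            if not 0.0 <= getattr(self, attr) <= 100.0:
                raise ValueError(f"{self.mag_id}: {attr} outside [0,100]")

    @property
    def best_completeness(self) -> float:
        return max(self.completeness_a, self.completeness_b)


@dataclass(frozen=True)
class SpeciesCluster:
    """An approximate species: member MAGs and the chosen representative."""

    members: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


def qc_retain(mags: Iterable[MagRecord]) -> list[MagRecord]:
    """Retain MAGs passing either estimator's completeness/contamination gate.

    Retention: (completeness_a > 50 and contamination_a < 5) or
    (completeness_b > 50 and contamination_b < 5).  Each estimator's
    completeness is paired with the same tool's contamination estimate.
    """
    return [
        m
        for m in mags
        if (m.completeness_a > 50.0 and m.contamination_a < 5.0)
        or (m.completeness_b > 50.0 and m.contamination_b < 5.0)
    ]


def cluster_species(
    distances: pd.DataFrame, threshold: float = 0.05
) -> list[frozenset[str]]:
    """Single-linkage species groups: components of the graph {distance < t}.

    ``distances`` is a square symmetric matrix (MAG x MAG, zero diagonal,
    values in [0,1]).  Returns member sets sorted by their smallest MAG id.
    """
    ids = list(distances.index)
    if list(distances.columns) != ids:
        raise ValueError("distance matrix must have identical row/column ids")
    mat = distances.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(mat - mat.T).max(initial=0.0) > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond tolerance 1e-9")
    if mat.min(initial=0.0) < 0 or mat.max(initial=0.0) > 1:
        raise ValueError("distances must lie in [0,1]")

    adjacency = csr_matrix(mat < threshold)
    n_comp, labels = connected_components(adjacency, directed=False)
    groups: dict[int, set[str]] = {}
    for mag_id, lab in zip(ids, labels):
        groups.setdefault(int(lab), set()).add(mag_id)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: min(g))


def choose_representative(
    members: Iterable[str],
    mags: Mapping[str, MagRecord],
    size_margin_bp: int = 100_000,
    completeness_margin: float = 5.0,
) -> str:
    """Pick the species-representative MAG.

    Default: the member with the highest completeness (either estimator),
    ties broken lexicographically.  Override: a member more than
    ``size_margin_bp`` larger than the default, with contamination no worse
    under both estimators and completeness within ``completeness_margin``
    percentage points, replaces it (largest such member; ties lexicographic).
    """
    member_list = sorted(members)
    if not member_list:
        raise ValueError("empty species cluster")
    default = max(member_list, key=lambda m: (mags[m].best_completeness, m))
    # max with key prefers later ties; enforce lexicographic-smallest instead
    best_c = mags[default].best_completeness
    default = min(m for m in member_list if mags[m].best_completeness == best_c)

    d = mags[default]
    challengers = [
        m
        for m in member_list
        if m != default
        and mags[m].size_bp > d.size_bp + size_margin_bp
        and mags[m].contamination_a <= d.contamination_a
        and mags[m].contamination_b <= d.contamination_b
        and mags[m].best_completeness >= d.best_completeness - completeness_margin
    ]
    if not challengers:
        return default
    top_size = max(mags[m].size_bp for m in challengers)
    return min(m for m in challengers if mags[m].size_bp == top_size)


def build_species_clusters(
    mags: Sequence[MagRecord], distances: pd.DataFrame, threshold: float = 0.05
) -> list[SpeciesCluster]:
    """QC-retain, cluster, and choose representatives in one pass."""
    retained = qc_retain(mags)
    ids = [m.mag_id for m in retained]
    by_id = {m.mag_id: m for m in retained}
    sub = distances.loc[ids, ids]
    return [
        SpeciesCluster(members=grp, representative=choose_representative(grp, by_id))
        for grp in cluster_species(sub, threshold)
    ]


def assign_protein_to_mag(
    hits: Iterable[AlignmentHit],
    subject_to_mag: Mapping[str, str],
    cfg: FilterConfig | None = None,
) -> dict[str, str]:
    """Assign each query protein to a MAG by its best passing alignment.

    Passing hits require identity > ``min_identity_pct`` and e-value <
    ``max_evalue``; among them the highest bitscore wins (ties: lowest
    e-value, then lexicographic subject id).  Proteins without a passing hit
    map to ``"unassigned"``; hits to subjects without a MAG mapping are
    dropped with a warning.
    """
    cfg = cfg or FilterConfig()
    gate = cfg.mag_assign
    best: dict[str, AlignmentHit] = {}
    unmapped_subjects: set[str] = set()
    queries: set[str] = set()
    for hit in hits:
        queries.add(hit.query_id)
        if hit.pct_identity <= gate.min_identity_pct or hit.e_value >= gate.max_evalue:
            continue
        if hit.subject_id not in subject_to_mag:
            unmapped_subjects.add(hit.subject_id)
            continue
        cur = best.get(hit.query_id)
        if cur is None or (
            (-hit.bitscore, hit.e_value, hit.subject_id)
            < (-cur.bitscore, cur.e_value, cur.subject_id)
        ):
            best[hit.query_id] = hit
    if unmapped_subjects:
        warnings.warn(
            f"{len(unmapped_subjects)} alignment subjects lack a MAG mapping; "
            "their queries count as unassigned",
            stacklevel=2,
        )
    return {
        q: (subject_to_mag[best[q].subject_id] if q in best else UNASSIGNED)
        for q in queries
    }


def read_mag_table(stream) -> list[MagRecord]:
    """Read a MAG quality TSV (mag_id, size_bp, completeness/contamination a+b, taxonomy)."""
    df = pd.read_csv(stream, sep="\t")
    return [
        MagRecord(
            mag_id=str(row.mag_id),
            size_bp=int(row.size_bp),
            completeness_a=float(row.completeness_a),
            completeness_b=float(row.completeness_b),
            contamination_a=float(row.contamination_a),
            contamination_b=float(row.contamination_b),
            taxonomy=str(row.taxonomy),
        )
        for row in df.itertuples()
    ]
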