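"""Readers and writers for the tabular formats the pipeline consumes and emits.

Inputs are the standard text dialects produced by gene callers and scanners:
GFF3 gene coordinate tables, HMMER per-domain hit tables (``--domtblout``),
and 12/13-column tab-separated pairwise alignment hit tables (BLAST/DIAMOND
``outfmt 6``).  Outputs are deterministic TSV tables plus BED exports of gene
cluster spans.

Coordinate conventions: internal coordinates are 1-based inclusive (GFF3
native); BED export converts to 0-based half-open.  Gene "distance" used by
the cluster caller is the ordinal index difference on a contig, never base
pairs, and indices never cross contig boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, TextIO

import pandas as pd

UNBINNED = "unbinned"


class ParseError(ValueError):
    """Raised when an input table cannot be parsed; names the offending line."""


@dataclass
class GeneRecord:
    """One predicted gene on a contig.

    ``index`` is the 0-based ordinal of the gene on its contig, assigned by
    ascending start coordinate (ties broken by end, then gene_id).  ``labels``
    holds :class:`~pulquant.feature_classifier.FeatureLabel` objects and is
    empty until the classifier runs.
    """

    gene_id: str
    contig_id: str
    genome_id: str = UNBINNED
    index: int = 0
    start: int = 1
    end: int = 1
    strand: str = "+"
    labels: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_aa(self) -> int:
        """Protein length implied by the CDS span (3 nt per residue)."""
        return (self.end - self.start + 1) // 3


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit (one row of a per-domain table).

    ``hmm_cov`` is the fraction of the profile covered by the alignment,
    computed as (hmm_to - hmm_from + 1) / profile_length.
    """

    query_id: str
    profile_id: str
    e_value: float
    bitscore: float
    ali_from: int
    ali_to: int
    hmm_cov: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"{self.query_id}: negative e-value")
        if not 0.0 <= self.hmm_cov <= 1.0:
            raise ValueError(f"{self.query_id}: hmm_cov {self.hmm_cov} outside [0,1]")
        if self.ali_from > self.ali_to:
            raise ValueError(f"{self.query_id}: ali_from > ali_to")

    @property
    def ali_len(self) -> int:
        """Alignment length on the query, inclusive of both ends."""
        return self.ali_to - self.ali_from + 1


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise alignment hit (one row of a tabular BLAST/DIAMOND table).

    ``query_cover`` is percent of the query covered, or ``None`` when the
    table had no coverage column and no query lengths were supplied.
    Downstream operations that need coverage raise on ``None`` rather than
    passing silently.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    e_value: float
    bitscore: float
    query_cover: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"{self.query_id}: identity outside [0,100]")
        if self.query_cover is not None and not 0.0 <= self.query_cover <= 100.0:
            raise ValueError(f"{self.query_id}: query cover outside [0,100]")


@dataclass(frozen=True)
class SampleDesign:
    """One sample of the study design: collection day and replicate columns."""

    sample_id: str
    julian_day: int
    replicate_ids: tuple[str, ...]


def _as_lines(stream: str | TextIO) -> Iterable[tuple[int, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, line in enumerate(stream, start=1):
        yield lineno, line.rstrip("\n")


def _gff_attributes(attr_col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr_col.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_table(
    gff_stream: str | TextIO,
    genome_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[GeneRecord]:
    """Parse a GFF3 stream into :class:`GeneRecord` lists with contig-local indices.

    CDS features are used; if a file carries no CDS rows, ``gene`` rows are
    used instead.  Per-contig ordinal indices are assigned by ascending start
    coordinate (ties: end, then gene_id) and restart at 0 on every contig.

    ``genome_map`` optionally maps contig_id to a genome/MAG id; contigs
    without a mapping are recorded as ``"unbinned"``.
    """
    rows: list[tuple[str, str, int, int, str, str]] = []  # (type, contig, start, end, strand, id)
    in_fasta = False
    for lineno, line in _as_lines(gff_stream):
        if in_fasta or not line.strip():
            continue
        if line.startswith("##FASTA"):
            in_fasta = True
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
        if ftype not in ("CDS", "gene"):
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        gene_id = _gff_attributes(attrs).get("ID")
        if not gene_id:
            raise ParseError(f"GFF3 line {lineno}: feature lacks an ID attribute")
        if strand not in ("+", "-"):
            raise ParseError(f"GFF3 line {lineno}: bad strand {strand!r}")
        rows.append((ftype, contig, start, end, strand, gene_id))

    use_type = "CDS" if any(r[0] == "CDS" for r in rows) else "gene"
    rows = [r for r in rows if r[0] == use_type]

    seen: set[str] = set()
    for _, _, _, _, _, gid in rows:
        if gid in seen:
            raise ValueError(f"duplicate gene ID {gid!r} in GFF3 input")
        seen.add(gid)

    def genome_of(contig: str) -> str:
        if genome_map is None:
            return UNBINNED
        if callable(genome_map):
            return genome_map(contig)
        return genome_map.get(contig, UNBINNED)

    records: list[GeneRecord] = []
    by_contig: dict[str, list[tuple[str, str, int, int, str, str]]] = {}
    for r in rows:
        by_contig.setdefault(r[1], []).append(r)
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda r: (r[2], r[3], r[5]))
        for idx, (_, _, start, end, strand, gid) in enumerate(ordered):
            records.append(
                GeneRecord(
                    gene_id=gid,
                    contig_id=contig,
                    genome_id=genome_of(contig),
                    index=idx,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return records


# Column offsets of HMMER3's --domtblout per-domain table (whitespace-delimited;
# the trailing free-text description is not split).  Target = profile for
# hmmscan-style searches.
_DOMTBL_MIN_COLS = 22


def read_domain_hits(domtbl_stream: str | TextIO) -> list[DomainHit]:
    """Parse a HMMER per-domain table (``--domtblout`` dialect).

    One :class:`DomainHit` per data row.  The per-domain independent e-value
    (``i-Evalue``) and domain bit score are used; profile coverage is computed
    from the hmm coordinate span and the profile length column.
    """
    hits: list[DomainHit] = []
    for lineno, line in _as_lines(domtbl_stream):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split(None, _DOMTBL_MIN_COLS)
        if len(cols) < _DOMTBL_MIN_COLS:
            raise ParseError(
                f"domtblout line {lineno}: expected >= {_DOMTBL_MIN_COLS} columns"
            )
        try:
            tlen = int(cols[2])
            e_value = float(cols[12])
            bitscore = float(cols[13])
            hmm_from, hmm_to = int(cols[15]), int(cols[16])
            ali_from, ali_to = int(cols[17]), int(cols[18])
        except ValueError as exc:
            raise ParseError(f"domtblout line {lineno}: non-numeric field") from exc
        profile = cols[0]
        if profile.endswith(".hmm"):
            profile = profile[: -len(".hmm")]
        hits.append(
            DomainHit(
                query_id=cols[3],
                profile_id=profile,
                e_value=e_value,
                bitscore=bitscore,
                ali_from=ali_from,
                ali_to=ali_to,
                hmm_cov=(hmm_to - hmm_from + 1) / tlen,
            )
        )
    return hits


def read_alignment_hits(
    tab_stream: str | TextIO,
    query_lengths: Mapping[str, int] | None = None,
) -> list[AlignmentHit]:
    """Parse a 12/13-column tab-separated alignment table (``outfmt 6`` dialect).

    With 13 columns the last is taken as percent query coverage.  With 12,
    coverage is computed as 100*(qend-qstart+1)/query_length when
    ``query_lengths`` is given, else left unavailable (``None``).
    """
    hits: list[AlignmentHit] = []
    for lineno, line in _as_lines(tab_stream):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) not in (12, 13):
            raise ParseError(
                f"alignment line {lineno}: expected 12 or 13 columns, got {len(cols)}"
            )
        try:
            pct_identity = float(cols[2])
            qstart, qend = int(cols[6]), int(cols[7])
            e_value = float(cols[10])
            bitscore = float(cols[11])
            cover = float(cols[12]) if len(cols) == 13 else None
        except ValueError as exc:
            raise ParseError(f"alignment line {lineno}: non-numeric field") from exc
        query_id = cols[0]
        if cover is None and query_lengths is not None:
            qlen = query_lengths.get(query_id)
            if qlen:
                cover = 100.0 * (abs(qend - qstart) + 1) / qlen
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=cols[1],
                pct_identity=pct_identity,
                e_value=e_value,
                bitscore=bitscore,
                query_cover=cover,
            )
        )
    return hits


def read_design(stream: str | TextIO) -> list[SampleDesign]:
    """Read a study design TSV: sample_id, julian_day, comma-joined replicate ids."""
    df = pd.read_csv(_ensure_io(stream), sep="\t", dtype=str)
    designs = [
        SampleDesign(
            sample_id=row["sample_id"],
            julian_day=int(row["julian_day"]),
            replicate_ids=tuple(row["replicate_ids"].split(",")),
        )
        for _, row in df.iterrows()
    ]
    days = [d.julian_day for d in designs]
    if days != sorted(days) or len(set(days)) != len(days):
        raise ValueError("design julian days must be strictly increasing")
    if len({d.sample_id for d in designs}) != len(designs):
        raise ValueError("duplicate sample ids in design")
    return designs


def _ensure_io(stream: str | TextIO) -> TextIO:
    return io.StringIO(stream) if isinstance(stream, str) else stream


def clusters_to_bed(clusters: Sequence) -> pd.DataFrame:
    """Convert gene clusters to a BED frame (0-based half-open coordinates)."""
    rows = [
        {
            "chrom": c.contig_id,
            "start": min(g.start for g in c.gene_span) - 1,
            "end": max(g.end for g in c.gene_span),
            "name": c.cluster_id,
        }
        for c in clusters
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start", "name"], kind="mergesort").reset_index(drop=True)


def write_table(df: pd.DataFrame, path: Path | str, sort_by: Sequence[str] | None = None) -> None:
    """Write a result table as TSV with a deterministic row order."""
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: Path | str,
    bed_clusters: Sequence | None = None,
) -> dict[str, Path]:
    """Write every result table (TSV) plus an optional cluster BED export.

    Tables are written in sorted-name order with their existing column order;
    rerunning on identical inputs produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        write_table(tables[name], path)
        written[name] = path
    if bed_clusters is not None:
        path = out_dir / "clusters.bed"
        clusters_to_bed(bed_clusters).to_csv(path, sep="\t", index=False, header=False)
        written["clusters.bed"] = path
    return written
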