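"""Gene coordinates, domain hits, and the genomes x families presence/absence matrix.

This module holds the ingestion layer of the pipeline: GFF3 gene/CDS
coordinates, protein-family domain hits (HMMER ``tblout``/``domtblout`` or a
simplified five-column TSV), genome metadata, and the presence-calling policy
that turns per-gene hits into a binary phylogenetic profile per family.

Coordinates follow the GFF3 convention (1-based, inclusive) on the public
:class:`GeneFeature` type; arithmetic that wants half-open 0-based intervals
goes through :meth:`GeneFeature.interval`, the single conversion point.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "Strand",
    "GeneFeature",
    "DomainHit",
    "GenomeMetadata",
    "PresencePolicy",
    "PresenceAbsenceMatrix",
    "normalize_family_id",
    "parse_gff",
    "parse_domain_hits",
    "build_presence_matrix",
    "read_metadata_tsv",
    "write_metadata_tsv",
]


class Strand(str, Enum):
    """Transcription strand of a gene."""

    FORWARD = "+"
    REVERSE = "-"

    @classmethod
    def from_gff(cls, symbol: str) -> "Strand":
        if symbol == "+":
            return cls.FORWARD
        if symbol == "-":
            return cls.REVERSE
        raise ValueError(f"unstranded or unknown strand symbol: {symbol!r}")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: contig, 1-based inclusive coordinates, strand."""

    genome_id: str
    contig_id: str
    gene_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, end >= start
    strand: Strand

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )

    def interval(self) -> tuple[int, int]:
        """Half-open 0-based interval; the one place the convention changes."""
        return self.start - 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One family-to-gene assignment from a domain scan."""

    genome_id: str
    gene_id: str
    family_id: str
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")


@dataclass(frozen=True)
class GenomeMetadata:
    """Taxonomic and environmental context for one genome."""

    genome_id: str
    domain_of_life: str  # "archaea" or "bacteria"
    taxon_path: tuple[str, ...] = ()  # (phylum, order, genus)
    isolation_source: str | None = None

    def __post_init__(self) -> None:
        if self.domain_of_life not in ("archaea", "bacteria"):
            raise ValueError(
                f"domain_of_life must be 'archaea' or 'bacteria', got {self.domain_of_life!r}"
            )


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_family_id(accession: str) -> str:
    """Strip a trailing release-version suffix (``PF18330.5`` -> ``PF18330``).

    Comparisons elsewhere are done on the normalized, upper-cased form so
    that accessions from different Pfam/TIGRFAM releases collate together.
    """
    return _VERSION_SUFFIX.sub("", accession.strip()).upper()


def _as_lines(source: str | Path | IO[str]) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source  # type: ignore[misc]
    else:
        with open(source, "rt") as handle:
            yield from handle


def parse_gff(
    source: str | Path | IO[str],
    genome_id: str,
    feature_types: Sequence[str] = ("CDS",),
) -> list[GeneFeature]:
    """Parse GFF3 text into :class:`GeneFeature` records.

    Only features whose type is in ``feature_types`` are retained (default:
    CDS, since domain hits address protein-coding genes). Malformed feature
    lines are skipped with a warning; an input with no feature lines yields
    an empty list.
    """
    wanted = set(feature_types)
    features: list[GeneFeature] = []
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted errors per line
            logger.warning("%s line %d: unparseable GFF3 record (%s); skipped",
                           genome_id, lineno, exc)
            continue
        if feat.featuretype not in wanted:
            continue
        attrs = feat.attributes
        gene_id = None
        for key in ("ID", "locus_tag", "Name"):
            if key in attrs and attrs[key]:
                gene_id = attrs[key][0]
                break
        if gene_id is None:
            gene_id = f"{feat.seqid}:{feat.start}-{feat.end}"
        try:
            features.append(
                GeneFeature(
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    gene_id=gene_id,
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=Strand.from_gff(feat.strand),
                )
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d: invalid coordinates/strand (%s); skipped",
                           genome_id, lineno, exc)
    return features


# Column layout of HMMER3 space-delimited tabular outputs. The description
# field at the end may itself contain spaces, so rows are split with a max
# field count and indexed from the front.
_TBLOUT_COLS = {"gene": 0, "family_acc": 3, "family_name": 2, "e_value": 4, "score": 5}
_DOMTBLOUT_COLS = {"gene": 0, "family_acc": 4, "family_name": 3, "e_value": 6, "score": 7}


def _parse_hmmer_row(fields: list[str], cols: Mapping[str, int]) -> tuple[str, str, float, float]:
    gene = fields[cols["gene"]]
    family = fields[cols["family_acc"]]
    if family == "-":
        family = fields[cols["family_name"]]
    e_value = float(fields[cols["e_value"]])
    score = float(fields[cols["score"]])
    return gene, family, e_value, score


def parse_domain_hits(
    source: str | Path | IO[str],
    dialect: str = "tsv",
    genome_id: str | None = None,
) -> list[DomainHit]:
    """Parse a domain-hit table into :class:`DomainHit` records.

    Parameters
    ----------
    source:
        Path or text stream.
    dialect:
        ``"tblout"`` or ``"domtblout"`` (HMMER3 whitespace-delimited, ``#``
        comments), or ``"tsv"`` — a simplified table with columns
        ``genome_id, gene_id, family_id, score, e_value`` (header optional).
    genome_id:
        Required for the HMMER dialects, which carry no genome column
        (one scan output per genome is the expected layout).

    Family accessions are normalized (version suffix stripped, upper-cased).
    Rows with a non-numeric e-value are skipped with a warning.
    """
    if dialect not in ("tblout", "domtblout", "tsv"):
        raise ValueError(f"unknown domain-hit dialect: {dialect!r}")
    if dialect in ("tblout", "domtblout") and genome_id is None:
        raise ValueError(f"dialect {dialect!r} requires genome_id (no genome column)")

    hits: list[DomainHit] = []
    cols = _TBLOUT_COLS if dialect == "tblout" else _DOMTBLOUT_COLS
    first_data_line = True
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            if dialect == "tsv":
                fields = line.split("\t")
                if len(fields) < 5:
                    fields = line.split()
                if len(fields) < 5:
                    raise ValueError("expected 5 columns")
                if first_data_line and fields[0] == "genome_id":
                    first_data_line = False
                    continue  # header row
                first_data_line = False
                g, gene, family, score, evalue = fields[:5]
                hit = DomainHit(g, gene, normalize_family_id(family),
                                float(score), float(evalue))
            else:
                fields = line.split()
                gene, family, evalue, score = _parse_hmmer_row(fields, cols)
                hit = DomainHit(genome_id, gene, normalize_family_id(family),  # type: ignore[arg-type]
                                score, evalue)
        except (ValueError, IndexError) as exc:
            logger.warning("domain hits line %d: %s; row skipped", lineno, exc)
            continue
        hits.append(hit)
    return hits


@dataclass(frozen=True)
class PresencePolicy:
    """Thresholds that decide whether a hit supports a presence call.

    Defaults follow common Pfam-screen practice: e-value <= 1e-5 and no
    bit-score floor. Both are explicit so every run can log them.
    """

    max_e_value: float | None = 1e-5
    min_bit_score: float | None = None

    def admits(self, hit: DomainHit) -> bool:
        if self.max_e_value is not None and hit.e_value > self.max_e_value:
            return False
        if self.min_bit_score is not None and hit.bit_score < self.min_bit_score:
            return False
        return True


@dataclass
class PresenceAbsenceMatrix:
    """Genomes x families binary matrix with per-genome metadata.

    ``data`` is a pandas DataFrame indexed by genome_id with one 0/1 int8
    column per family. Rows cover every genome in the metadata, including
    all-zero rows for genomes with no qualifying hit (the negative
    background of every screen).
    """

    data: pd.DataFrame
    metadata: dict[str, GenomeMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate genome_ids in matrix rows")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate family_ids in matrix columns")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("matrix entries must be exactly 0 or 1")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.data.columns)

    def column(self, family_id: str) -> np.ndarray:
        key = normalize_family_id(family_id)
        if key not in self.data.columns:
            raise KeyError(f"family {family_id!r} is not a matrix column")
        return self.data[key].to_numpy()

    def presence_count(self, family_id: str) -> int:
        return int(self.column(family_id).sum())

    def domain_labels(self) -> np.ndarray:
        """Per-row domain-of-life labels aligned with the matrix index."""
        return np.array(
            [self.metadata[g].domain_of_life if g in self.metadata else "unknown"
             for g in self.data.index]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, metadata: Iterable[GenomeMetadata] = ()
    ) -> "PresenceAbsenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="genome_id").astype(np.int8)
        return cls(frame, {m.genome_id: m for m in metadata})


def build_presence_matrix(
    hits: Iterable[DomainHit],
    metadata: Iterable[GenomeMetadata],
    policy: PresencePolicy = PresencePolicy(),
    alias_groups: Mapping[str, Iterable[str]] | None = None,
) -> PresenceAbsenceMatrix:
    """Collapse qualifying hits into a genomes x families 0/1 matrix.

    A genome scores 1 for a family iff it has at least one hit to that
    family passing ``policy``; multiple hits per genome collapse to a single
    presence call. Genomes listed in ``metadata`` but absent from the hits
    appear as all-zero rows. A hit whose genome is missing from the metadata
    is an error (the negative background would otherwise be ill-defined).

    ``alias_groups`` maps a group label to member family accessions (e.g.
    ``{"RNL3": ["PF18330", "TIGR01209"]}``); each group becomes a single
    column that is the union of its members, and the member columns are
    dropped.
    """
    meta = {m.genome_id: m for m in metadata}
    if len(meta) == 0:
        raise ValueError("metadata is empty: no genomes to profile")

    rows: dict[str, set[str]] = {g: set() for g in meta}
    seen_families: set[str] = set()
    unknown: set[str] = set()
    for hit in hits:
        if hit.genome_id not in rows:
            unknown.add(hit.genome_id)
            continue
        seen_families.add(normalize_family_id(hit.family_id))
        if policy.admits(hit):
            rows[hit.genome_id].add(normalize_family_id(hit.family_id))
    if unknown:
        raise ValueError(
            "hits reference genomes absent from metadata: "
            + ", ".join(sorted(unknown))
        )

    # Families are columns as soon as any hit mentions them, so a family
    # whose every hit fails the policy still shows up as an all-zero column.
    families = sorted(seen_families)
    frame = pd.DataFrame(
        0, index=sorted(rows), columns=families, dtype=np.int8
    )
    for genome, present in rows.items():
        if present:
            frame.loc[genome, sorted(present)] = 1

    if alias_groups:
        for label, members in alias_groups.items():
            norm_label = normalize_family_id(label)
            norm_members = [normalize_family_id(m) for m in members]
            hit_cols = [m for m in norm_members if m in frame.columns]
            union = (
                frame[hit_cols].max(axis=1).astype(np.int8)
                if hit_cols
                else pd.Series(0, index=frame.index, dtype=np.int8)
            )
            frame = frame.drop(columns=hit_cols)
            frame[norm_label] = union
        frame = frame[sorted(frame.columns)]

    return PresenceAbsenceMatrix(frame, meta)


_META_COLUMNS = ["genome_id", "domain_of_life", "phylum", "order", "genus",
                 "isolation_source"]


def read_metadata_tsv(path: str | Path | IO[str]) -> list[GenomeMetadata]:
    """Read a genome-metadata TSV (genome_id, domain_of_life, phylum, order,
    genus, isolation_source)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"genome_id", "domain_of_life"} - set(frame.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        taxon = tuple(
            getattr(row, level) for level in ("phylum", "order", "genus")
            if hasattr(row, level)
        )
        records.append(
            GenomeMetadata(
                genome_id=row.genome_id,
                domain_of_life=row.domain_of_life,
                taxon_path=taxon,
                isolation_source=getattr(row, "isolation_source", "") or None,
            )
        )
    seen: set[str] = set()
    for rec in records:
        if rec.genome_id in seen:
            raise ValueError(f"duplicate genome_id in metadata: {rec.genome_id}")
        seen.add(rec.genome_id)
    return records


def write_metadata_tsv(records: Iterable[GenomeMetadata], path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("\t".join(_META_COLUMNS) + "\n")
        for rec in records:
            taxon = list(rec.taxon_path) + [""] * (3 - len(rec.taxon_path))
            out.write(
                "\t".join(
                    [rec.genome_id, rec.domain_of_life, *taxon[:3],
                     rec.isolation_source or ""]
                )
                + "\n"
            )
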