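"""Gene-neighborhood analysis: distance and orientation of anchor-partner pairs.

For every genome carrying at least one anchor-family gene and one
partner-family gene, the pair with the smallest intergenic gap on a shared
contig is selected (one pair per genome — the analysis counts genomes, not
gene copies). The gap is the boundary-to-boundary distance with overlapping
or abutting genes scoring 0, so "abutting" always counts as co-localized.
Orientation is classified as divergent (head-to-head, the "bidirectional"
arrangement), convergent (tail-to-tail), or tandem (same strand, co-linear).

Circular replicons are supported by an optional wraparound distance; the
default is linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .profiles import (
    DomainHit,
    GeneFeature,
    GenomeMetadata,
    PresencePolicy,
    Strand,
    normalize_family_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "NeighborPair",
    "CoLocStratum",
    "CoLocalizationSummary",
    "DifferentContigsError",
    "intergenic_distance",
    "classify_orientation",
    "nearest_pairs",
    "colocalization_summary",
    "pairs_to_tsv",
    "pairs_to_bed",
]

DEFAULT_COLOC_THRESHOLD = 5_000  # bp; "< 5 kb" is strict


class Orientation(str, Enum):
    DIVERGENT = "divergent"  # <- ->  head-to-head / bidirectional
    CONVERGENT = "convergent"  # -> <-  tail-to-tail
    TANDEM = "tandem"  # -> ->  co-linear, same strand


class DifferentContigsError(ValueError):
    """Signals that an intergenic distance is undefined across contigs."""


def _ordered(g1: GeneFeature, g2: GeneFeature) -> tuple[GeneFeature, GeneFeature]:
    """Left/right order by position; deterministic on exact coordinate ties."""
    if (g1.start, g1.end, g1.gene_id) <= (g2.start, g2.end, g2.gene_id):
        return g1, g2
    return g2, g1


def intergenic_distance(
    g1: GeneFeature,
    g2: GeneFeature,
    contig_length: int | None = None,
    circular: bool = False,
) -> int:
    """Boundary-to-boundary gap in bp between two genes on one contig.

    gap = max(0, right.start - left.end - 1) with genes ordered by start;
    overlapping or abutting genes score 0. Symmetric in its arguments.
    With ``circular`` and a ``contig_length``, the wraparound gap is also
    considered and the smaller of the two is returned.
    """
    if g1.contig_id != g2.contig_id:
        raise DifferentContigsError(
            f"{g1.gene_id} ({g1.contig_id}) and {g2.gene_id} ({g2.contig_id}) "
            "are on different contigs"
        )
    left, right = _ordered(g1, g2)
    linear = max(0, right.start - left.end - 1)
    if circular:
        if contig_length is None:
            raise ValueError("circular distance requires contig_length")
        wrap = max(0, contig_length - right.end + left.start - 1)
        return min(linear, wrap)
    return linear


def classify_orientation(g1: GeneFeature, g2: GeneFeature) -> Orientation:
    """Orientation class of two stranded genes on one contig.

    Same strand -> tandem. Otherwise genes are ordered by position: a
    reverse-strand left gene facing a forward-strand right gene is
    divergent (promoters back-to-back); forward-then-reverse is convergent.
    Invariant under argument order.
    """
    if g1.contig_id != g2.contig_id:
        raise DifferentContigsError("orientation is undefined across contigs")
    if g1.strand == g2.strand:
        return Orientation.TANDEM
    left, right = _ordered(g1, g2)
    if left.strand is Strand.REVERSE and right.strand is Strand.FORWARD:
        return Orientation.DIVERGENT
    return Orientation.CONVERGENT


@dataclass(frozen=True)
class NeighborPair:
    """Minimal-distance anchor-partner gene pair for one genome.

    ``distance`` and ``orientation`` are None when the genes share no
    contig; ``co_localized`` requires a shared contig and a gap strictly
    below the threshold it was evaluated at.
    """

    genome_id: str
    anchor_gene: GeneFeature
    partner_gene: GeneFeature
    same_contig: bool
    distance: int | None
    orientation: Orientation | None
    co_localized: bool

    def __post_init__(self) -> None:
        if self.co_localized and not self.same_contig:
            raise ValueError("co_localized pair must share a contig")
        if self.same_contig and self.distance is None:
            raise ValueError("same-contig pair must carry a distance")


def _genes_for_families(
    features: Iterable[GeneFeature],
    hits: Iterable[DomainHit],
    families: frozenset[str],
    policy: PresencePolicy | None,
) -> dict[str, list[GeneFeature]]:
    """Per-genome gene lists for genes hit by any of ``families``."""
    by_key: dict[tuple[str, str], GeneFeature] = {
        (f.genome_id, f.gene_id): f for f in features
    }
    out: dict[str, list[GeneFeature]] = {}
    seen: set[tuple[str, str]] = set()
    for hit in hits:
        if normalize_family_id(hit.family_id) not in families:
            continue
        if policy is not None and not policy.admits(hit):
            continue
        key = (hit.genome_id, hit.gene_id)
        if key in seen:
            continue
        seen.add(key)
        gene = by_key.get(key)
        if gene is None:
            logger.warning(
                "genome %s: hit gene %s has no coordinates; excluded",
                hit.genome_id, hit.gene_id,
            )
            continue
        out.setdefault(hit.genome_id, []).append(gene)
    for genes in out.values():
        genes.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
    return out


def nearest_pairs(
    features: Iterable[GeneFeature],
    hits: Iterable[DomainHit],
    anchor: str | Iterable[str],
    partner: str | Iterable[str],
    policy: PresencePolicy | None = None,
    threshold: int = DEFAULT_COLOC_THRESHOLD,
    circular_contigs: bool = False,
    contig_lengths: Mapping[tuple[str, str], int] | None = None,
) -> list[NeighborPair]:
    """Minimal-distance anchor-partner pair for every dual-positive genome.

    ``anchor``/``partner`` may be single accessions or alias groups
    (iterables of accessions treated as one family). Among same-contig
    combinations the smallest gap wins, ties broken by lower anchor start
    then lower partner start. When the families only occur on different
    contigs the pair is still reported, with ``same_contig=False``.
    ``contig_lengths`` maps (genome_id, contig_id) to length for the
    circular-distance option.
    """
    anchor_set = frozenset(
        normalize_family_id(f)
        for f in ([anchor] if isinstance(anchor, str) else anchor)
    )
    partner_set = frozenset(
        normalize_family_id(f)
        for f in ([partner] if isinstance(partner, str) else partner)
    )
    features = list(features)
    hits = list(hits)
    anchor_genes = _genes_for_families(features, hits, anchor_set, policy)
    partner_genes = _genes_for_families(features, hits, partner_set, policy)

    pairs: list[NeighborPair] = []
    for genome_id in sorted(set(anchor_genes) & set(partner_genes)):
        best: tuple[int, int, int] | None = None  # (distance, a.start, p.start)
        best_pair: tuple[GeneFeature, GeneFeature] | None = None
        for a_gene in anchor_genes[genome_id]:
            for p_gene in partner_genes[genome_id]:
                if a_gene.contig_id != p_gene.contig_id:
                    continue
                length = (
                    contig_lengths.get((genome_id, a_gene.contig_id))
                    if contig_lengths
                    else None
                )
                dist = intergenic_distance(
                    a_gene, p_gene,
                    contig_length=length,
                    circular=circular_contigs and length is not None,
                )
                key = (dist, a_gene.start, p_gene.start)
                if best is None or key < best:
                    best = key
                    best_pair = (a_gene, p_gene)
        if best_pair is not None:
            a_gene, p_gene = best_pair
            dist = best[0]  # type: ignore[index]
            pairs.append(
                NeighborPair(
                    genome_id=genome_id,
                    anchor_gene=a_gene,
                    partner_gene=p_gene,
                    same_contig=True,
                    distance=dist,
                    orientation=classify_orientation(a_gene, p_gene),
                    co_localized=dist < threshold,
                )
            )
        else:
            a_gene = anchor_genes[genome_id][0]
            p_gene = partner_genes[genome_id][0]
            pairs.append(
                NeighborPair(
                    genome_id=genome_id,
                    anchor_gene=a_gene,
                    partner_gene=p_gene,
                    same_contig=False,
                    distance=None,
                    orientation=None,
                    co_localized=False,
                )
            )
    return pairs


@dataclass(frozen=True)
class CoLocStratum:
    """Co-localization tallies within one stratum of dual-positive genomes."""

    n_dual_positive: int
    n_co_localized: int
    orientation_counts: dict[str, int]

    @property
    def fraction_co_localized(self) -> float | None:
        if self.n_dual_positive == 0:
            return None
        return self.n_co_localized / self.n_dual_positive


@dataclass(frozen=True)
class CoLocalizationSummary:
    threshold: int
    overall: CoLocStratum
    by_domain: dict[str, CoLocStratum] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"stratum": "all", **_stratum_row(self.overall)}]
        for label, stratum in sorted(self.by_domain.items()):
            rows.append({"stratum": f"domain:{label}", **_stratum_row(stratum)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _stratum_row(s: CoLocStratum) -> dict[str, object]:
    frac = s.fraction_co_localized
    return {
        "n_dual_positive": s.n_dual_positive,
        "n_co_localized": s.n_co_localized,
        "fraction_co_localized": None if frac is None else round(frac, 4),
        "pct_co_localized": None if frac is None else round(100 * frac, 1),
        "n_divergent": s.orientation_counts.get("divergent", 0),
        "n_convergent": s.orientation_counts.get("convergent", 0),
        "n_tandem": s.orientation_counts.get("tandem", 0),
    }


def _tally(pairs: list[NeighborPair], threshold: int) -> CoLocStratum:
    coloc = [
        p for p in pairs
        if p.same_contig and p.distance is not None and p.distance < threshold
    ]
    counts = {o.value: 0 for o in Orientation}
    for p in coloc:
        assert p.orientation is not None
        counts[p.orientation.value] += 1
    return CoLocStratum(
        n_dual_positive=len(pairs),
        n_co_localized=len(coloc),
        orientation_counts=counts,
    )


def colocalization_summary(
    pairs: Iterable[NeighborPair],
    metadata: Iterable[GenomeMetadata] | Mapping[str, GenomeMetadata] = (),
    threshold: int = DEFAULT_COLOC_THRESHOLD,
) -> CoLocalizationSummary:
    """Tally co-localization and orientation of anchor-partner pairs.

    A pair is co-localized iff it shares a contig and its gap is strictly
    below ``threshold``. Orientation tallies cover co-localized pairs only,
    so they always sum to ``n_co_localized``. Strata follow the
    domain-of-life labels in ``metadata``; genomes without metadata land in
    an "unknown" stratum.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    pair_list = list(pairs)
    if isinstance(metadata, Mapping):
        meta = dict(metadata)
    else:
        meta = {m.genome_id: m for m in metadata}

    by_domain: dict[str, list[NeighborPair]] = {}
    for p in pair_list:
        label = meta[p.genome_id].domain_of_life if p.genome_id in meta else "unknown"
        by_domain.setdefault(label, []).append(p)

    return CoLocalizationSummary(
        threshold=threshold,
        overall=_tally(pair_list, threshold),
        by_domain={k: _tally(v, threshold) for k, v in by_domain.items()},
    )


def pairs_to_tsv(pairs: Iterable[NeighborPair], path: str | Path) -> None:
    rows = [
        {
            "genome_id": p.genome_id,
            "anchor_gene": p.anchor_gene.gene_id,
            "partner_gene": p.partner_gene.gene_id,
            "anchor_contig": p.anchor_gene.contig_id,
            "partner_contig": p.partner_gene.contig_id,
            "same_contig": int(p.same_contig),
            "distance": "" if p.distance is None else p.distance,
            "orientation": "" if p.orientation is None else p.orientation.value,
            "co_localized": int(p.co_localized),
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pairs_to_bed(pairs: Iterable[NeighborPair], path: str | Path) -> None:
    """BED6 (0-based half-open) export of the paired loci for browser review."""
    with open(path, "wt") as out:
        for p in pairs:
            for role, gene in (("anchor", p.anchor_gene), ("partner", p.partner_gene)):
                lo, hi = gene.interval()
                out.write(
                    "\t".join(
                        [
                            gene.contig_id,
                            str(lo),
                            str(hi),
                            f"{p.genome_id}|{role}|{gene.gene_id}",
                            "0",
                            gene.strand.value,
                        ]
                    )
                    + "\n"
                )
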