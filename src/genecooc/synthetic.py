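"""Synthetic genome collections with planted co-occurrence and co-localization.

The generator emulates the statistical skeleton of a prokaryotic genome
collection screened for two linked gene families: an anchor family present
in a minority of genomes, a partner family whose prevalence is conditional
on anchor status, a bed of mutually independent background families, and —
in dual-positive genomes — an anchor-partner gene pair planted either
co-localized (gap drawn below the co-localization threshold, orientation
drawn from a divergent-heavy mixture) or distant. Every planted quantity is
recorded in a :class:`TruthManifest`, which downstream tests treat as exact
ground truth: re-ingesting the emitted GFF3/TSV files must reproduce it.

Each genome is a single contig of non-overlapping genes laid left to right;
genes carry no sequence (the pipeline never needs one). One seeded generator
drives the collection; per-genome substreams are spawned deterministically,
so the same seed yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

from pathlib import Path
import numpy as np

from .colocalization import (
    DEFAULT_COLOC_THRESHOLD,
    NeighborPair,
    Orientation,
    classify_orientation,
    intergenic_distance,
)
from .profiles import (
    DomainHit,
    GeneFeature,
    GenomeMetadata,
    PresenceAbsenceMatrix,
    Strand,
    write_metadata_tsv,
)

__all__ = [
    "Uniform",
    "SimulationParams",
    "GenomeTruth",
    "TruthManifest",
    "SyntheticCollection",
    "simulate_collection",
    "fixture_from_counts",
    "Fixture",
]

_GENE_LEN_RANGE = (300, 1500)  # bp, uniform
_GAP_MEAN = 500  # bp, exponential inter-gene gap
_GAP_CAP = 5_000  # bp, truncation of the inter-gene gap


@dataclass(frozen=True)
class Uniform:
    """Uniform integer distance law on the closed interval [low, high]."""

    low: int
    high: int

    def __post_init__(self) -> None:
        if not 0 <= self.low <= self.high:
            raise ValueError(f"invalid distance law bounds [{self.low}, {self.high}]")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))


_ORIENTATIONS = (Orientation.DIVERGENT, Orientation.CONVERGENT, Orientation.TANDEM)

_ARCH_TAXA = [
    ("Halobacteriota", "Halobacteriales", "Haloarcula"),
    ("Halobacteriota", "Methanosarcinales", "Methanosarcina"),
    ("Methanobacteriota", "Methanococcales", "Methanococcus"),
    ("Methanobacteriota", "Thermococcales", "Thermococcus"),
]
_BACT_TAXA = [
    ("Aquificota", "Aquificales", "Aquifex"),
    ("Pseudomonadota", "Ectothiorhodospirales", "Thioalkalivibrio"),
    ("Pseudomonadota", "Nitrococcales", "Halorhodospira"),
    ("Nitrospirota", "Thermodesulfovibrionales", "Thermodesulfovibrio"),
]
_SOURCES = ["saltern", "hydrothermal vent", "thermal spring", "soda lake", "marine"]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic collection.

    Defaults mirror the structure of a real two-family screen at desk
    scale: a rare anchor (prevalence 0.05), a partner that is common given
    the anchor (0.89) and absent otherwise, 200 independent background
    families at prevalence 0.3, and co-localization in 44% of dual-positive
    genomes with a divergent-heavy orientation mixture.
    """

    n_genomes: int = 1_000
    p_anchor: float = 0.05
    p_partner_given_anchor: float = 0.89
    p_partner_given_no_anchor: float = 0.0
    n_background_families: int = 200
    background_prevalence: float = 0.3
    p_coloc_given_both: float = 0.44
    coloc_distance_law: Uniform = Uniform(0, DEFAULT_COLOC_THRESHOLD - 1)
    far_distance_law: Uniform = Uniform(DEFAULT_COLOC_THRESHOLD, 50_000)
    p_far_second_contig: float = 0.0
    orientation_mix: tuple[float, float, float] = (0.90, 0.05, 0.05)
    contig_length: int = 300_000
    genes_per_genome: int = 20
    archaeal_fraction: float = 0.5
    anchor_family: str = "PF09745"
    partner_family: str = "PF18330"
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_anchor": self.p_anchor,
            "p_partner_given_anchor": self.p_partner_given_anchor,
            "p_partner_given_no_anchor": self.p_partner_given_no_anchor,
            "background_prevalence": self.background_prevalence,
            "p_coloc_given_both": self.p_coloc_given_both,
            "p_far_second_contig": self.p_far_second_contig,
            "archaeal_fraction": self.archaeal_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if abs(sum(self.orientation_mix) - 1.0) > 1e-9:
            raise ValueError("orientation_mix must sum to 1")
        if any(w < 0 for w in self.orientation_mix):
            raise ValueError("orientation_mix weights must be >= 0")
        if self.n_genomes < 1 or self.genes_per_genome < 2:
            raise ValueError("need >= 1 genome and >= 2 genes per genome")
        # Worst-case span with capped inter-gene gaps; checked up front so an
        # infeasible contig fails before any file is written.
        worst = (
            self.genes_per_genome * _GENE_LEN_RANGE[1]
            + self.genes_per_genome * (_GAP_CAP + 1)
            + max(self.far_distance_law.high, self.coloc_distance_law.high)
        )
        if worst > self.contig_length:
            raise ValueError(
                f"contig_length {self.contig_length} cannot hold "
                f"{self.genes_per_genome} genes (worst-case span {worst} bp)"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationParams":
        data = dict(raw)
        for law in ("coloc_distance_law", "far_distance_law"):
            if law in data and isinstance(data[law], (list, tuple, dict)):
                spec = data[law]
                if isinstance(spec, dict):
                    data[law] = Uniform(int(spec["low"]), int(spec["high"]))
                else:
                    data[law] = Uniform(int(spec[0]), int(spec[1]))
        if "orientation_mix" in data:
            data["orientation_mix"] = tuple(float(w) for w in data["orientation_mix"])
        return cls(**data)


@dataclass(frozen=True)
class GenomeTruth:
    """Planted state of one genome."""

    genome_id: str
    domain_of_life: str
    taxon_path: tuple[str, ...]
    anchor_present: bool
    partner_present: bool
    co_localized: bool | None  # None unless dual-positive
    distance: int | None  # planted anchor-partner gap (dual-positive only)
    same_contig: bool | None
    orientation: str | None


@dataclass
class TruthManifest:
    """Ground truth for a whole collection, plus realized global counts."""

    params: SimulationParams
    genomes: list[GenomeTruth]

    @property
    def n_anchor_pos(self) -> int:
        return sum(g.anchor_present for g in self.genomes)

    @property
    def n_partner_pos(self) -> int:
        return sum(g.partner_present for g in self.genomes)

    @property
    def n_both(self) -> int:
        return sum(g.anchor_present and g.partner_present for g in self.genomes)

    @property
    def n_co_localized(self) -> int:
        return sum(bool(g.co_localized) for g in self.genomes)

    def orientation_counts(self) -> dict[str, int]:
        counts = {o.value: 0 for o in _ORIENTATIONS}
        for g in self.genomes:
            if g.co_localized and g.orientation is not None:
                counts[g.orientation] += 1
        return counts

    def domain_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for g in self.genomes:
            d = out.setdefault(
                g.domain_of_life,
                {"n_genomes": 0, "n_anchor_pos": 0, "n_both": 0, "n_co_localized": 0},
            )
            d["n_genomes"] += 1
            d["n_anchor_pos"] += g.anchor_present
            d["n_both"] += g.anchor_present and g.partner_present
            d["n_co_localized"] += bool(g.co_localized)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": _params_to_jsonable(self.params),
            "global": {
                "n_genomes": len(self.genomes),
                "n_anchor_pos": self.n_anchor_pos,
                "n_partner_pos": self.n_partner_pos,
                "n_both": self.n_both,
                "n_co_localized": self.n_co_localized,
                "orientation_counts": self.orientation_counts(),
                "by_domain": self.domain_counts(),
            },
            "genomes": [asdict(g) for g in self.genomes],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _params_to_jsonable(params: SimulationParams) -> dict:
    raw = asdict(params)
    raw["coloc_distance_law"] = [params.coloc_distance_law.low, params.coloc_distance_law.high]
    raw["far_distance_law"] = [params.far_distance_law.low, params.far_distance_law.high]
    raw["orientation_mix"] = list(params.orientation_mix)
    return raw


@dataclass
class SyntheticCollection:
    """In-memory result of a simulation, writable to standard flat files."""

    params: SimulationParams
    features: list[GeneFeature]
    hits: list[DomainHit]
    metadata: list[GenomeMetadata]
    manifest: TruthManifest

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write GFF3 (one file per genome under gff/), hits.tsv,
        metadata.tsv, and manifest.json. Same params+seed give
        byte-identical files."""
        out = Path(out_dir)
        gff_dir = out / "gff"
        gff_dir.mkdir(parents=True, exist_ok=True)

        by_genome: dict[str, list[GeneFeature]] = {}
        for feat in self.features:
            by_genome.setdefault(feat.genome_id, []).append(feat)
        for meta in self.metadata:
            path = gff_dir / f"{meta.genome_id}.gff"
            with open(path, "wt") as fh:
                fh.write("##gff-version 3\n")
                for g in sorted(
                    by_genome.get(meta.genome_id, []),
                    key=lambda x: (x.contig_id, x.start),
                ):
                    fh.write(
                        "\t".join(
                            [
                                g.contig_id,
                                "genecooc_sim",
                                "CDS",
                                str(g.start),
                                str(g.end),
                                ".",
                                g.strand.value,
                                "0",
                                f"ID={g.gene_id}",
                            ]
                        )
                        + "\n"
                    )

        hits_path = out / "hits.tsv"
        with open(hits_path, "wt") as fh:
            fh.write("genome_id\tgene_id\tfamily_id\tscore\te_value\n")
            for h in self.hits:
                fh.write(
                    f"{h.genome_id}\t{h.gene_id}\t{h.family_id}\t"
                    f"{h.bit_score:.1f}\t{h.e_value:.3e}\n"
                )

        meta_path = out / "metadata.tsv"
        write_metadata_tsv(self.metadata, meta_path)

        manifest_path = out / "manifest.json"
        self.manifest.to_json(manifest_path)
        return {
            "gff_dir": gff_dir,
            "hits": hits_path,
            "metadata": meta_path,
            "manifest": manifest_path,
        }

    def checksum(self) -> str:
        """SHA-256 over a canonical rendering of everything a write() emits."""
        digest = hashlib.sha256()
        for feat in self.features:
            digest.update(
                f"{feat.genome_id}|{feat.contig_id}|{feat.gene_id}|"
                f"{feat.start}|{feat.end}|{feat.strand.value}\n".encode()
            )
        for h in self.hits:
            digest.update(
                f"{h.genome_id}|{h.gene_id}|{h.family_id}|{h.bit_score:.1f}|"
                f"{h.e_value:.3e}\n".encode()
            )
        for m in self.metadata:
            digest.update(f"{m.genome_id}|{m.domain_of_life}|{m.taxon_path}\n".encode())
        return digest.hexdigest()


def _sample_orientation(rng: np.random.Generator, mix: tuple[float, float, float]) -> Orientation:
    idx = int(rng.choice(3, p=np.asarray(mix) / sum(mix)))
    return _ORIENTATIONS[idx]


def _pair_strands(
    rng: np.random.Generator, orientation: Orientation
) -> tuple[Strand, Strand]:
    """(left, right) strands realizing an orientation class."""
    if orientation is Orientation.TANDEM:
        s = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
        return s, s
    if orientation is Orientation.DIVERGENT:
        return Strand.REVERSE, Strand.FORWARD
    return Strand.FORWARD, Strand.REVERSE


def simulate_collection(params: SimulationParams) -> SyntheticCollection:
    """Generate a genome collection with planted co-occurrence structure.

    Per genome: anchor presence ~ Bernoulli(p_anchor); partner presence
    conditional on anchor status; background families independent of both.
    In dual-positive genomes the anchor and partner genes are adjacent with
    a planted intergenic gap — below the co-localization threshold with
    probability ``p_coloc_given_both`` (gap from ``coloc_distance_law``,
    orientation from ``orientation_mix``), otherwise a distant gap from
    ``far_distance_law`` or, with probability ``p_far_second_contig``, the
    partner on a second contig. All genes are non-overlapping.
    """
    params.validate()
    n = params.n_genomes
    n_arch = round(params.archaeal_fraction * n)
    streams = np.random.SeedSequence(params.seed).spawn(n)

    width = max(4, len(str(n)))
    features: list[GeneFeature] = []
    hits: list[DomainHit] = []
    metadata: list[GenomeMetadata] = []
    truths: list[GenomeTruth] = []
    bg_families = [f"BG{j:04d}" for j in range(params.n_background_families)]

    for i in range(n):
        rng = np.random.default_rng(streams[i])
        domain = "archaea" if i < n_arch else "bacteria"
        genome_id = f"{'ARC' if domain == 'archaea' else 'BAC'}{i:0{width}d}"
        taxa = _ARCH_TAXA if domain == "archaea" else _BACT_TAXA
        taxon = taxa[int(rng.integers(len(taxa)))]
        source = _SOURCES[int(rng.integers(len(_SOURCES)))]
        metadata.append(GenomeMetadata(genome_id, domain, taxon, source))

        anchor = rng.random() < params.p_anchor
        p_partner = (
            params.p_partner_given_anchor if anchor else params.p_partner_given_no_anchor
        )
        partner = rng.random() < p_partner

        coloc: bool | None = None
        planted_dist: int | None = None
        orientation: Orientation | None = None
        second_contig = False
        if anchor and partner:
            coloc = rng.random() < params.p_coloc_given_both
            if coloc:
                planted_dist = params.coloc_distance_law.sample(rng)
                orientation = _sample_orientation(rng, params.orientation_mix)
            else:
                second_contig = rng.random() < params.p_far_second_contig
                if not second_contig:
                    planted_dist = params.far_distance_law.sample(rng)
                    orientation = _sample_orientation(rng, params.orientation_mix)

        n_genes = params.genes_per_genome
        # Gene slots for anchor/partner. When both are planted on the main
        # contig they occupy adjacent slots; which one sits left is random.
        anchor_slot = partner_slot = -1
        anchor_left = bool(rng.random() < 0.5)
        if anchor and partner and not second_contig:
            left_slot = int(rng.integers(0, n_genes - 1))
            anchor_slot = left_slot if anchor_left else left_slot + 1
            partner_slot = left_slot + 1 if anchor_left else left_slot
        else:
            if anchor:
                anchor_slot = int(rng.integers(0, n_genes))
            if partner and not second_contig:
                partner_slot = int(rng.integers(0, n_genes))
                while partner_slot == anchor_slot:
                    partner_slot = int(rng.integers(0, n_genes))

        pair_left_slot = min(anchor_slot, partner_slot) if (
            anchor_slot >= 0 and partner_slot >= 0
        ) else None
        pair_strands = (
            _pair_strands(rng, orientation)
            if pair_left_slot is not None and orientation is not None
            else None
        )

        cursor = 0  # 1-based inclusive end of the previous gene (0 = contig start)
        genome_feats: list[GeneFeature] = []
        for slot in range(n_genes):
            if (
                pair_left_slot is not None
                and slot == pair_left_slot + 1
                and planted_dist is not None
            ):
                gap = planted_dist
            else:
                gap = min(_GAP_CAP, int(rng.exponential(_GAP_MEAN)))
            length = int(rng.integers(_GENE_LEN_RANGE[0], _GENE_LEN_RANGE[1] + 1))
            start = cursor + gap + 1  # 1-based inclusive
            end = start + length - 1
            cursor = end
            if pair_strands is not None and slot == pair_left_slot:
                strand = pair_strands[0]
            elif pair_strands is not None and slot == pair_left_slot + 1:
                strand = pair_strands[1]
            else:
                strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
            genome_feats.append(
                GeneFeature(genome_id, f"{genome_id}_c1", f"{genome_id}_g{slot:03d}",
                            start, end, strand)
            )
        features.extend(genome_feats)

        if cursor > params.contig_length:
            raise AssertionError(
                "placement overflow despite feasibility pre-check"
            )

        def add_hit(slot_idx: int, family: str, contig_suffix: str = "c1") -> None:
            gene_id = (
                f"{genome_id}_g{slot_idx:03d}"
                if contig_suffix == "c1"
                else f"{genome_id}_x000"
            )
            e_val = 10.0 ** -float(rng.uniform(10, 50))
            score = float(rng.uniform(80, 300))
            hits.append(DomainHit(genome_id, gene_id, family, round(score, 1), e_val))

        if anchor:
            add_hit(anchor_slot, params.anchor_family)
        if partner:
            if second_contig:
                length = int(rng.integers(_GENE_LEN_RANGE[0], _GENE_LEN_RANGE[1] + 1))
                start = 1 + min(_GAP_CAP, int(rng.exponential(_GAP_MEAN)))
                feat = GeneFeature(
                    genome_id, f"{genome_id}_c2", f"{genome_id}_x000",
                    start, start + length - 1,
                    Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE,
                )
                features.append(feat)
                add_hit(-1, params.partner_family, contig_suffix="c2")
            else:
                add_hit(partner_slot, params.partner_family)
        for fam in bg_families:
            if rng.random() < params.background_prevalence:
                slot_idx = int(rng.integers(0, n_genes))
                add_hit(slot_idx, fam)

        truths.append(
            GenomeTruth(
                genome_id=genome_id,
                domain_of_life=domain,
                taxon_path=taxon,
                anchor_present=anchor,
                partner_present=partner,
                co_localized=coloc,
                distance=planted_dist,
                same_contig=None if not (anchor and partner) else not second_contig,
                orientation=None if orientation is None else orientation.value,
            )
        )

    manifest = TruthManifest(params=params, genomes=truths)
    return SyntheticCollection(params, features, hits, metadata, manifest)


@dataclass
class Fixture:
    """Deterministic matrix + pair list whose summaries hit requested counts."""

    matrix: PresenceAbsenceMatrix
    pairs: list[NeighborPair]
    metadata: list[GenomeMetadata]


def fixture_from_counts(
    dual_arch: int,
    anchor_only_arch: int,
    dual_bact: int,
    anchor_only_bact: int,
    n_negative_arch: int = 50,
    n_negative_bact: int = 50,
    *,
    partner_only_arch: int = 0,
    partner_only_bact: int = 0,
    coloc_arch: int = 0,
    coloc_bact: int = 0,
    tandem_arch: int = 0,
    tandem_bact: int = 0,
    anchor_family: str = "PF09745",
    partner_family: str = "PF18330",
    coloc_distance: int = 1_000,
    far_distance: int = 20_000,
) -> Fixture:
    """Build, with no randomness, a collection realizing exact printed counts.

    ``dual_*`` genomes carry anchor and partner, ``anchor_only_*`` just the
    anchor, ``partner_only_*`` just the partner, and ``n_negative_*`` are
    the all-negative background. Of the dual-positive genomes per domain,
    the first ``coloc_*`` get an anchor-partner pair at ``coloc_distance``
    bp (< 5 kb by default) and the rest at ``far_distance`` bp; the first
    ``tandem_*`` of the co-localized pairs are same-strand, the remainder
    divergent. Summaries computed on the result equal the requested counts
    exactly, which makes worked examples from published tables testable.
    """
    for name, count in {
        "dual_arch": dual_arch, "anchor_only_arch": anchor_only_arch,
        "dual_bact": dual_bact, "anchor_only_bact": anchor_only_bact,
        "n_negative_arch": n_negative_arch, "n_negative_bact": n_negative_bact,
        "partner_only_arch": partner_only_arch, "partner_only_bact": partner_only_bact,
        "coloc_arch": coloc_arch, "coloc_bact": coloc_bact,
        "tandem_arch": tandem_arch, "tandem_bact": tandem_bact,
    }.items():
        if count < 0:
            raise ValueError(f"{name} must be >= 0")
    if coloc_arch > dual_arch or coloc_bact > dual_bact:
        raise ValueError("co-localized count cannot exceed dual-positive count")
    if tandem_arch > coloc_arch or tandem_bact > coloc_bact:
        raise ValueError("tandem count cannot exceed co-localized count")
    if coloc_distance >= DEFAULT_COLOC_THRESHOLD:
        raise ValueError("coloc_distance must lie below the 5 kb threshold")
    if far_distance < DEFAULT_COLOC_THRESHOLD:
        raise ValueError("far_distance must lie at or above the 5 kb threshold")

    import pandas as pd  # local import keeps module load light

    rows: list[tuple[str, str, int, int]] = []  # (genome_id, domain, anchor, partner)
    pairs: list[NeighborPair] = []

    def emit_domain(
        tag: str, domain: str, dual: int, anchor_only: int, partner_only: int,
        negative: int, coloc: int, tandem: int,
    ) -> None:
        idx = 0
        for k in range(dual):
            genome_id = f"{tag}{idx:05d}"
            idx += 1
            rows.append((genome_id, domain, 1, 1))
            gap = coloc_distance if k < coloc else far_distance
            is_tandem = k < tandem
            anchor_gene = GeneFeature(
                genome_id, f"{genome_id}_c1", f"{genome_id}_anchor",
                1_000, 1_900,
                Strand.FORWARD if is_tandem else Strand.REVERSE,
            )
            p_start = anchor_gene.end + gap + 1
            partner_gene = GeneFeature(
                genome_id, f"{genome_id}_c1", f"{genome_id}_partner",
                p_start, p_start + 900, Strand.FORWARD,
            )
            dist = intergenic_distance(anchor_gene, partner_gene)
            pairs.append(
                NeighborPair(
                    genome_id=genome_id,
                    anchor_gene=anchor_gene,
                    partner_gene=partner_gene,
                    same_contig=True,
                    distance=dist,
                    orientation=classify_orientation(anchor_gene, partner_gene),
                    co_localized=dist < DEFAULT_COLOC_THRESHOLD,
                )
            )
        for _ in range(anchor_only):
            rows.append((f"{tag}{idx:05d}", domain, 1, 0))
            idx += 1
        for _ in range(partner_only):
            rows.append((f"{tag}{idx:05d}", domain, 0, 1))
            idx += 1
        for _ in range(negative):
            rows.append((f"{tag}{idx:05d}", domain, 0, 0))
            idx += 1

    emit_domain("ARC", "archaea", dual_arch, anchor_only_arch, partner_only_arch,
                n_negative_arch, coloc_arch, tandem_arch)
    emit_domain("BAC", "bacteria", dual_bact, anchor_only_bact, partner_only_bact,
                n_negative_bact, coloc_bact, tandem_bact)

    anchor_key = anchor_family.upper()
    partner_key = partner_family.upper()
    frame = pd.DataFrame(
        {
            anchor_key: [r[2] for r in rows],
            partner_key: [r[3] for r in rows],
        },
        index=[r[0] for r in rows],
        dtype="int8",
    )
    frame = frame[sorted(frame.columns)]
    metadata = [GenomeMetadata(r[0], r[1]) for r in rows]
    matrix = PresenceAbsenceMatrix(frame, {m.genome_id: m for m in metadata})
    return Fixture(matrix=matrix, pairs=pairs, metadata=metadata)
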