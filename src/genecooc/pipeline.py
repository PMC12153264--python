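"""End-to-end orchestration: config in, report bundle out.

A :class:`PipelineConfig` points either at real inputs (a GFF3 directory,
a hits table, a metadata TSV) or at a simulation scenario — never both.
:func:`run_pipeline` then builds the presence/absence matrix, screens all
families against the anchor, summarizes anchor/partner co-occurrence, finds
and classifies neighbor pairs, and writes TSV tables, three iToL rings
(anchor-positive, partner-positive, co-localized), an optional pruned tree,
a provenance JSON, and a run log that records every defaulted threshold.
Outputs are byte-stable: the same config and seed reproduce the same files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata as importlib_metadata
from pathlib import Path

import yaml
from Bio import Phylo

from .colocalization import (
    DEFAULT_COLOC_THRESHOLD,
    colocalization_summary,
    nearest_pairs,
    pairs_to_bed,
    pairs_to_tsv,
)
from .cooccurrence import (
    cooccurrence_summary,
    enrichment_to_tsv,
    screen_all_families,
)
from .itol import attach_tree, write_itol_binary_dataset
from .profiles import (
    PresencePolicy,
    build_presence_matrix,
    normalize_family_id,
    parse_domain_hits,
    parse_gff,
    read_metadata_tsv,
)
from .synthetic import SimulationParams, simulate_collection

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source must be set."""

    out_dir: str | Path = "genecooc_out"
    # Real inputs
    gff_dir: str | Path | None = None
    hits_path: str | Path | None = None
    hits_dialect: str = "tsv"
    metadata_path: str | Path | None = None
    # Or a simulation scenario
    scenario: SimulationParams | None = None
    # Families
    anchor: str = "PF09745"
    anchor_aliases: tuple[str, ...] = ()
    partner: str = "PF18330"
    partner_aliases: tuple[str, ...] = ("TIGR01209",)
    # Thresholds
    max_e_value: float | None = 1e-5
    min_bit_score: float | None = None
    alpha: float = 0.05
    coloc_threshold: int = DEFAULT_COLOC_THRESHOLD
    circular_contigs: bool = False
    # Misc
    tree_path: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = any(
            v is not None for v in (self.gff_dir, self.hits_path, self.metadata_path)
        )
        if has_paths and self.scenario is not None:
            raise ValueError(
                "config sets both input paths and a simulation scenario; "
                "exactly one input source is allowed"
            )
        if not has_paths and self.scenario is None:
            raise ValueError("config sets neither input paths nor a scenario")
        if has_paths and not all(
            v is not None for v in (self.gff_dir, self.hits_path, self.metadata_path)
        ):
            raise ValueError("real inputs need gff_dir, hits_path and metadata_path")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.coloc_threshold <= 0:
            raise ValueError("coloc_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        data = dict(raw)
        if "scenario" in data and isinstance(data["scenario"], dict):
            data["scenario"] = SimulationParams.from_dict(data["scenario"])
        for key in ("anchor_aliases", "partner_aliases"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_jsonable(self) -> dict:
        raw = dataclasses.asdict(self)
        for key in ("out_dir", "gff_dir", "hits_path", "metadata_path", "tree_path"):
            if raw[key] is not None:
                raw[key] = str(raw[key])
        if self.scenario is not None:
            from .synthetic import _params_to_jsonable

            raw["scenario"] = _params_to_jsonable(self.scenario)
        raw["anchor_aliases"] = list(self.anchor_aliases)
        raw["partner_aliases"] = list(self.partner_aliases)
        return raw


@dataclass
class PipelineResult:
    """Handles on everything a run produced, in memory and on disk."""

    matrix: object
    enrichment: list
    cooccurrence: object
    pairs: list
    colocalization: object
    outputs: dict[str, Path] = field(default_factory=dict)


def _anchor_group(config: PipelineConfig) -> tuple[str, list[str]]:
    members = [config.anchor, *config.anchor_aliases]
    label = normalize_family_id(config.anchor)
    return label, [normalize_family_id(m) for m in members]


def _partner_group(config: PipelineConfig) -> tuple[str, list[str]]:
    members = [config.partner, *config.partner_aliases]
    label = normalize_family_id(config.partner)
    return label, [normalize_family_id(m) for m in members]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run profiling, enrichment, co-occurrence, and co-localization; write
    the report bundle under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("genecooc")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    policy = PresencePolicy(
        max_e_value=config.max_e_value, min_bit_score=config.min_bit_score
    )
    logger.info(
        "presence policy: max_e_value=%s min_bit_score=%s (defaults, not from "
        "any published methods)", policy.max_e_value, policy.min_bit_score,
    )
    logger.info(
        "enrichment: two-sided exact hypergeometric test, BH FDR alpha=%s; "
        "co-localization threshold: gap < %d bp (strict)",
        config.alpha, config.coloc_threshold,
    )

    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, seed=config.seed)
        collection = simulate_collection(scenario)
        features = collection.features
        hits = collection.hits
        metadata = collection.metadata
        collection.write(out / "inputs")
        logger.info("simulated %d genomes (seed %d)", scenario.n_genomes, config.seed)
    else:
        metadata = read_metadata_tsv(config.metadata_path)
        hits = parse_domain_hits(config.hits_path, dialect=config.hits_dialect)
        features = []
        gff_dir = Path(config.gff_dir)
        if not gff_dir.is_dir():
            raise FileNotFoundError(f"GFF directory not found: {gff_dir}")
        for gff in sorted(gff_dir.glob("*.gff*")):
            features.extend(parse_gff(gff, genome_id=gff.name.split(".")[0]))
        logger.info(
            "parsed %d genomes, %d gene features, %d domain hits",
            len(metadata), len(features), len(hits),
        )

    anchor_label, anchor_members = _anchor_group(config)
    partner_label, partner_members = _partner_group(config)
    alias_groups = {anchor_label: anchor_members, partner_label: partner_members}

    matrix = build_presence_matrix(hits, metadata, policy, alias_groups=alias_groups)
    matrix.to_tsv(out / "presence_matrix.tsv")
    logger.info(
        "presence matrix: %d genomes x %d families; anchor-positive %d",
        len(matrix.genome_ids), len(matrix.family_ids),
        matrix.presence_count(anchor_label),
    )

    enrichment = screen_all_families(matrix, anchor_label, alpha=config.alpha)
    enrichment_to_tsv(enrichment, out / "enrichment.tsv")

    summary = cooccurrence_summary(matrix, anchor_label, partner_label)
    summary.to_tsv(out / "cooccurrence_summary.tsv")

    pairs = nearest_pairs(
        features, hits, anchor_members, partner_members,
        policy=policy, threshold=config.coloc_threshold,
        circular_contigs=config.circular_contigs,
    )
    pairs_to_tsv(pairs, out / "pairs.tsv")
    pairs_to_bed(pairs, out / "pairs.bed")

    coloc = colocalization_summary(
        pairs, matrix.metadata, threshold=config.coloc_threshold
    )
    coloc.to_tsv(out / "colocalization_summary.tsv")

    # Fig-1-style rings, innermost to outermost: anchor+, partner+, co-localized.
    genome_ids = matrix.genome_ids
    anchor_col = matrix.column(anchor_label)
    partner_col = matrix.column(partner_label)
    coloc_ids = {p.genome_id for p in pairs if p.co_localized}
    rings = {
        "itol_anchor.txt": ("anchor_positive", "#1f77b4",
                            [int(v) for v in anchor_col]),
        "itol_partner.txt": ("partner_positive", "#2ca02c",
                             [int(v) for v in partner_col]),
        "itol_colocalized.txt": ("co_localized", "#d62728",
                                 [int(g in coloc_ids) for g in genome_ids]),
    }
    outputs: dict[str, Path] = {
        "presence_matrix": out / "presence_matrix.tsv",
        "enrichment": out / "enrichment.tsv",
        "cooccurrence_summary": out / "cooccurrence_summary.tsv",
        "pairs": out / "pairs.tsv",
        "pairs_bed": out / "pairs.bed",
        "colocalization_summary": out / "colocalization_summary.tsv",
        "log": out / "run.log",
    }
    for filename, (label, color, values) in rings.items():
        write_itol_binary_dataset(genome_ids, values, label, color=color,
                                  path=out / filename)
        outputs[filename.removesuffix(".txt")] = out / filename

    if config.tree_path is not None:
        tree, report = attach_tree(
            Path(config.tree_path).read_text(), genome_ids
        )
        tree_out = out / "tree_pruned.nwk"
        Phylo.write(tree, str(tree_out), "newick")
        (out / "tree_match_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
        outputs["tree"] = tree_out
        logger.info(
            "tree: %d matched leaves, %d pruned, %d genomes without a leaf",
            len(report["matched"]), len(report["pruned"]),
            len(report["genomes_without_leaf"]),
        )

    config_json = json.dumps(config.to_jsonable(), sort_keys=True)
    try:
        version = importlib_metadata.version("genecooc")
    except importlib_metadata.PackageNotFoundError:
        version = "unknown"
    provenance = {
        "package": "genecooc",
        "version": version,
        "seed": config.seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "record_counts": {
            "genomes": len(matrix.genome_ids),
            "families": len(matrix.family_ids),
            "gene_features": len(features),
            "domain_hits": len(hits),
            "neighbor_pairs": len(pairs),
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    outputs["provenance"] = out / "provenance.json"

    return PipelineResult(
        matrix=matrix,
        enrichment=enrichment,
        cooccurrence=summary,
        pairs=pairs,
        colocalization=coloc,
        outputs=outputs,
    )
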