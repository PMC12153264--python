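"""Ingestion layer: GFF3/hit parsing and the presence/absence matrix."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genecooc.profiles import (
    DomainHit,
    GenomeMetadata,
    PresencePolicy,
    Strand,
    build_presence_matrix,
    normalize_family_id,
    parse_domain_hits,
    parse_gff,
)
from genecooc.synthetic import SimulationParams, simulate_collection

GFF_ONE_CDS = """##gff-version 3
##sequence-region ctg1 1 5000
ctg1\ttest\tCDS\t100\t200\t.\t+\t0\tID=geneA
"""

GFF_HEADERS_ONLY = """##gff-version 3
##sequence-region ctg1 1 5000
"""


class TestParseGff:
    def test_single_cds_maps_fields(self):
        feats = parse_gff(io.StringIO(GFF_ONE_CDS), genome_id="G1")
        assert len(feats) == 1
        f = feats[0]
        assert (f.genome_id, f.contig_id, f.gene_id) == ("G1", "ctg1", "geneA")
        assert (f.start, f.end, f.strand) == (100, 200, Strand.FORWARD)

    def test_headers_only_gives_empty_collection(self):
        assert parse_gff(io.StringIO(GFF_HEADERS_ONLY), genome_id="G1") == []

    def test_type_filter_is_configurable(self):
        text = GFF_ONE_CDS + "ctg1\ttest\tgene\t300\t400\t.\t-\t.\tID=geneB\n"
        cds_only = parse_gff(io.StringIO(text), "G1")
        both = parse_gff(io.StringIO(text), "G1", feature_types=("CDS", "gene"))
        assert [f.gene_id for f in cds_only] == ["geneA"]
        assert [f.gene_id for f in both] == ["geneA", "geneB"]

    def test_malformed_line_skipped_with_warning(self, caplog):
        text = GFF_ONE_CDS + "ctg1\ttest\tCDS\tnot_a_number\t500\t.\t+\t0\tID=bad\n"
        with caplog.at_level("WARNING"):
            feats = parse_gff(io.StringIO(text), "G1")
        assert [f.gene_id for f in feats] == ["geneA"]
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_generator_roundtrip_preserves_coordinates(self, tmp_path):
        collection = simulate_collection(
            SimulationParams(n_genomes=1, p_anchor=1.0, genes_per_genome=10, seed=3)
        )
        paths = collection.write(tmp_path)
        gff = next(iter(paths["gff_dir"].glob("*.gff")))
        feats = parse_gff(gff, genome_id=collection.metadata[0].genome_id)
        assert len(feats) == 10
        expected = {
            (f.gene_id, f.start, f.end, f.strand) for f in collection.features
        }
        assert {(f.gene_id, f.start, f.end, f.strand) for f in feats} == expected


TBLOUT = """#                                                               --- full sequence ---
# target name        accession  query name           accession    E-value  score  bias
geneA                -          HARP                 PF09745.12   1e-30    120.0  0.1  some description here
geneB                -          Rnl                  PF18330.5    2e-08     55.2  0.0  another description
"""

DOMTBLOUT_COMMENTS = "# comment\n# another comment\n"


class TestParseDomainHits:
    def test_simple_tsv_row(self):
        hits = parse_domain_hits(
            io.StringIO("G1\tgeneA\tPF09745\t120.0\t1e-30\n"), dialect="tsv"
        )
        assert len(hits) == 1
        h = hits[0]
        assert (h.genome_id, h.gene_id, h.family_id) == ("G1", "geneA", "PF09745")
        assert h.e_value == pytest.approx(1e-30)

    def test_tsv_header_is_skipped(self):
        text = "genome_id\tgene_id\tfamily_id\tscore\te_value\nG1\tg\tPF1\t10\t1e-9\n"
        assert len(parse_domain_hits(io.StringIO(text), dialect="tsv")) == 1

    def test_tblout_fields_and_version_stripping(self):
        hits = parse_domain_hits(io.StringIO(TBLOUT), dialect="tblout", genome_id="G1")
        assert [(h.gene_id, h.family_id) for h in hits] == [
            ("geneA", "PF09745"),
            ("geneB", "PF18330"),
        ]
        assert hits[0].bit_score == pytest.approx(120.0)

    def test_comment_only_domtblout_is_empty(self):
        hits = parse_domain_hits(
            io.StringIO(DOMTBLOUT_COMMENTS), dialect="domtblout", genome_id="G1"
        )
        assert hits == []

    def test_unknown_dialect_is_configuration_error(self):
        with pytest.raises(ValueError, match="dialect"):
            parse_domain_hits(io.StringIO(""), dialect="csv")

    def test_non_numeric_evalue_row_skipped(self, caplog):
        text = "G1\tg1\tPF1\t10\tnot_a_number\nG1\tg2\tPF1\t10\t1e-9\n"
        with caplog.at_level("WARNING"):
            hits = parse_domain_hits(io.StringIO(text), dialect="tsv")
        assert [h.gene_id for h in hits] == ["g2"]

    @pytest.mark.parametrize(
        "raw,expected",
        [("PF18330.5", "PF18330"), ("pf09745", "PF09745"), ("TIGR01209", "TIGR01209")],
    )
    def test_family_normalization(self, raw, expected):
        assert normalize_family_id(raw) == expected


def _meta(*genome_ids):
    return [GenomeMetadata(g, "archaea") for g in genome_ids]


class TestBuildPresenceMatrix:
    def test_single_qualifying_hit(self):
        m = build_presence_matrix(
            [DomainHit("G1", "g", "PF1", 100.0, 1e-30)], _meta("G1"),
            PresencePolicy(max_e_value=1e-5),
        )
        assert m.data.to_numpy().tolist() == [[1]]

    def test_hit_failing_policy_scores_zero(self):
        m = build_presence_matrix(
            [DomainHit("G1", "g", "PF1", 100.0, 1e-3)], _meta("G1"),
            PresencePolicy(max_e_value=1e-5),
        )
        assert m.data.to_numpy().tolist() == [[0]]

    def test_hitless_genomes_appear_as_zero_rows(self):
        m = build_presence_matrix(
            [DomainHit("G1", "g", "PF1", 100.0, 1e-30)], _meta("G1", "G2", "G3")
        )
        assert len(m.genome_ids) == 3
        assert m.column("PF1").sum() == 1

    def test_unknown_genome_in_hits_is_error(self):
        with pytest.raises(ValueError, match="GX"):
            build_presence_matrix(
                [DomainHit("GX", "g", "PF1", 100.0, 1e-30)], _meta("G1")
            )

    def test_alias_group_unions_members(self):
        hits = [
            DomainHit("G1", "g1", "PF18330", 100.0, 1e-30),
            DomainHit("G2", "g2", "TIGR01209", 100.0, 1e-30),
        ]
        m = build_presence_matrix(
            hits, _meta("G1", "G2", "G3"),
            alias_groups={"RNL3": ["PF18330", "TIGR01209"]},
        )
        assert m.family_ids == ["RNL3"]
        assert m.column("RNL3").tolist() == [1, 1, 0]

    def test_generator_presence_calls_match_manifest(self):
        params = SimulationParams(
            n_genomes=40, p_anchor=0.5, n_background_families=5, seed=11
        )
        c = simulate_collection(params)
        m = build_presence_matrix(c.hits, c.metadata)
        assert m.presence_count(params.anchor_family) == c.manifest.n_anchor_pos

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_roundtrip_manifest_over_random_seeds(self, seed):
        """Generator -> emitted text -> parsers reproduces presence calls."""
        params = SimulationParams(
            n_genomes=15, p_anchor=0.4, n_background_families=3,
            genes_per_genome=6, seed=seed,
        )
        c = simulate_collection(params)
        hits = parse_domain_hits(
            io.StringIO(_hits_text(c)), dialect="tsv"
        )
        m = build_presence_matrix(hits, c.metadata)
        anchor_calls = {
            g: bool(v) for g, v in zip(m.genome_ids, m.column(params.anchor_family))
        } if params.anchor_family in m.family_ids else {g: False for g in m.genome_ids}
        truth = {t.genome_id: t.anchor_present for t in c.manifest.genomes}
        assert anchor_calls == truth

    @settings(max_examples=25, deadline=None)
    @given(
        max_e_small=st.floats(1e-40, 1e-10), factor=st.floats(1.0, 1e20), seed=st.integers(0, 10_000)
    )
    def test_relaxing_evalue_policy_is_monotone(self, max_e_small, factor, seed):
        """A larger e-value ceiling never turns a presence call off."""
        rng = np.random.default_rng(seed)
        hits = [
            DomainHit(f"G{i%5}", f"g{i}", f"PF{i%3}", 50.0, float(10 ** rng.uniform(-40, 0)))
            for i in range(30)
        ]
        meta = _meta(*{h.genome_id for h in hits})
        strict = build_presence_matrix(hits, meta, PresencePolicy(max_e_value=max_e_small))
        loose = build_presence_matrix(
            hits, meta, PresencePolicy(max_e_value=max_e_small * factor)
        )
        common = [f for f in strict.family_ids if f in loose.family_ids]
        for fam in common:
            assert (loose.column(fam) >= strict.column(fam)).all()


def _hits_text(collection):
    lines = ["genome_id\tgene_id\tfamily_id\tscore\te_value"]
    for h in collection.hits:
        lines.append(f"{h.genome_id}\t{h.gene_id}\t{h.family_id}\t{h.bit_score}\t{h.e_value}")
    return "\n".join(lines) + "\n"
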