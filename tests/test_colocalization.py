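"""Neighborhood analysis: gaps, orientation classes, and nearest pairs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genecooc.colocalization import (
    DifferentContigsError,
    NeighborPair,
    Orientation,
    classify_orientation,
    colocalization_summary,
    intergenic_distance,
    nearest_pairs,
)
from genecooc.profiles import DomainHit, GeneFeature, GenomeMetadata, Strand
from genecooc.synthetic import SimulationParams, simulate_collection
from conftest import nearest_pair_bruteforce


def gene(start, end, strand="+", contig="c1", gid=None, genome="G1"):
    return GeneFeature(
        genome, contig, gid or f"g{start}", start, end,
        Strand.FORWARD if strand == "+" else Strand.REVERSE,
    )


class TestIntergenicDistance:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            ((100, 200), (301, 400), 100),
            ((100, 200), (201, 300), 0),  # abutting
            ((100, 250), (200, 400), 0),  # overlapping clamps to zero
            ((100, 200), (202, 300), 1),
        ],
    )
    def test_gap_convention(self, g1, g2, expected):
        assert intergenic_distance(gene(*g1), gene(*g2)) == expected
        assert intergenic_distance(gene(*g2), gene(*g1)) == expected  # symmetric

    def test_cross_contig_is_undefined(self):
        with pytest.raises(DifferentContigsError):
            intergenic_distance(gene(1, 10, contig="A"), gene(1, 10, contig="B"))

    def test_circular_wraparound(self):
        g1, g2 = gene(10, 100), gene(9_800, 9_900)
        assert intergenic_distance(g1, g2) == 9_699
        assert intergenic_distance(g1, g2, contig_length=10_000, circular=True) == 109

    @settings(max_examples=100, deadline=None)
    @given(
        s1=st.integers(1, 10_000), l1=st.integers(1, 2_000),
        s2=st.integers(1, 10_000), l2=st.integers(1, 2_000),
    )
    def test_symmetry_property(self, s1, l1, s2, l2):
        g1, g2 = gene(s1, s1 + l1), gene(s2, s2 + l2, gid="other")
        assert intergenic_distance(g1, g2) == intergenic_distance(g2, g1)


class TestClassifyOrientation:
    def test_head_to_head_is_divergent(self):
        left, right = gene(100, 600, "-"), gene(1_000, 1_500, "+")
        assert classify_orientation(left, right) is Orientation.DIVERGENT

    def test_tail_to_tail_is_convergent(self):
        left, right = gene(100, 600, "+"), gene(1_000, 1_500, "-")
        assert classify_orientation(left, right) is Orientation.CONVERGENT

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_equal_strands_are_tandem(self, strand):
        assert (
            classify_orientation(gene(1, 10, strand), gene(20, 30, strand))
            is Orientation.TANDEM
        )

    def test_exhaustive_strand_combinations_are_partitioned(self):
        """All 4 strand pairs x 2 argument orders land in exactly one class
        and the classification is order-invariant."""
        for s_left in "+-":
            for s_right in "+-":
                left, right = gene(100, 200, s_left), gene(300, 400, s_right)
                forward = classify_orientation(left, right)
                backward = classify_orientation(right, left)
                assert forward is backward
                if s_left == s_right:
                    assert forward is Orientation.TANDEM
                elif s_left == "-":
                    assert forward is Orientation.DIVERGENT
                else:
                    assert forward is Orientation.CONVERGENT


def _hit(genome, gene_id, family):
    return DomainHit(genome, gene_id, family, 100.0, 1e-30)


class TestNearestPairs:
    def test_minimum_gap_pair_is_chosen(self):
        feats = [
            gene(1_000, 2_000, gid="anchor"),
            gene(6_001, 7_000, gid="near"),  # gap 4000
            gene(42_001, 43_000, gid="far"),  # gap 40000
        ]
        hits = [_hit("G1", "anchor", "A"), _hit("G1", "near", "P"), _hit("G1", "far", "P")]
        (pair,) = nearest_pairs(feats, hits, "A", "P")
        assert pair.partner_gene.gene_id == "near"
        assert pair.distance == 4_000
        assert pair.co_localized

    def test_cross_contig_only_pair(self):
        feats = [gene(1, 900, gid="anchor", contig="A"), gene(1, 900, gid="partner", contig="B")]
        hits = [_hit("G1", "anchor", "A"), _hit("G1", "partner", "P")]
        (pair,) = nearest_pairs(feats, hits, "A", "P")
        assert not pair.same_contig
        assert not pair.co_localized
        assert pair.distance is None and pair.orientation is None

    def test_hit_without_coordinates_excluded_with_warning(self, caplog):
        feats = [gene(1, 900, gid="anchor"), gene(2_000, 2_900, gid="partner")]
        hits = [
            _hit("G1", "anchor", "A"),
            _hit("G1", "partner", "P"),
            _hit("G1", "ghost", "P"),
        ]
        with caplog.at_level("WARNING"):
            (pair,) = nearest_pairs(feats, hits, "A", "P")
        assert pair.partner_gene.gene_id == "partner"
        assert any("ghost" in rec.message for rec in caplog.records)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_matches_bruteforce_scan(self, data):
        """Independent all-pairs oracle on up to 20 genes per genome."""
        n_anchor = data.draw(st.integers(1, 4))
        n_partner = data.draw(st.integers(1, 16))
        feats, hits = [], []
        for i in range(n_anchor + n_partner):
            start = data.draw(st.integers(1, 50_000))
            length = data.draw(st.integers(100, 2_000))
            contig = data.draw(st.sampled_from(["c1", "c2"]))
            gid = f"g{i:02d}"
            feats.append(gene(start, start + length, contig=contig, gid=gid))
            hits.append(_hit("G1", gid, "A" if i < n_anchor else "P"))
        pairs = nearest_pairs(feats, hits, "A", "P")
        oracle = nearest_pair_bruteforce(feats[:n_anchor], feats[n_anchor:])
        assert len(pairs) == 1
        pair = pairs[0]
        if oracle is None:
            assert not pair.same_contig
        else:
            (dist, a_start, p_start), a, p = oracle
            assert pair.same_contig
            assert pair.distance == dist
            assert (pair.anchor_gene.start, pair.partner_gene.start) == (a_start, p_start)

    def test_planted_coloc_fraction_recovered(self):
        """80% planted co-localization over 1,000 genomes lands inside the
        99% binomial interval around 0.8."""
        params = SimulationParams(
            n_genomes=1_000, p_anchor=1.0, p_partner_given_anchor=1.0,
            p_coloc_given_both=0.8, n_background_families=0, seed=29,
        )
        c = simulate_collection(params)
        pairs = nearest_pairs(c.features, c.hits, params.anchor_family, params.partner_family)
        assert len(pairs) == 1_000
        frac = sum(p.co_localized for p in pairs) / len(pairs)
        half = 2.576 * np.sqrt(0.8 * 0.2 / 1_000)
        assert 0.8 - half <= frac <= 0.8 + half
        # and the realized co-localized set matches the manifest exactly
        truth = {g.genome_id for g in c.manifest.genomes if g.co_localized}
        assert {p.genome_id for p in pairs if p.co_localized} == truth


def _pair(genome, distance, orientation=Orientation.DIVERGENT, same_contig=True):
    a = gene(1_000, 1_900, "-", genome=genome, gid=f"{genome}_a")
    if same_contig:
        p = gene(1_900 + distance + 1, 1_900 + distance + 900, "+",
                 genome=genome, gid=f"{genome}_p")
        ori = classify_orientation(a, p)
        if orientation is Orientation.TANDEM:
            a = gene(1_000, 1_900, "+", genome=genome, gid=f"{genome}_a")
            ori = Orientation.TANDEM
        return NeighborPair(genome, a, p, True, distance, ori, distance < 5_000)
    p = gene(1, 900, "+", contig="c2", genome=genome, gid=f"{genome}_p")
    return NeighborPair(genome, a, p, False, None, None, False)


class TestColocalizationSummary:
    def test_archaeal_fraction_from_printed_counts(self, printed_counts_fixture):
        meta = printed_counts_fixture.metadata
        s = colocalization_summary(printed_counts_fixture.pairs, meta)
        arch = s.by_domain["archaea"]
        assert (arch.n_dual_positive, arch.n_co_localized) == (501, 163)
        assert arch.fraction_co_localized == pytest.approx(163 / 501)
        bact = s.by_domain["bacteria"]
        assert (bact.n_dual_positive, bact.n_co_localized) == (164, 127)

    def test_distance_exactly_at_threshold_is_not_colocalized(self):
        s = colocalization_summary([_pair("G1", 5_000)], [GenomeMetadata("G1", "archaea")])
        assert s.overall.n_co_localized == 0

    def test_empty_pair_collection(self):
        s = colocalization_summary([], [])
        assert s.overall.n_dual_positive == 0
        assert s.overall.fraction_co_localized is None

    def test_orientation_tallies_sum_to_n_colocalized(self):
        pairs = [
            _pair("G1", 100),
            _pair("G2", 4_999),
            _pair("G3", 200, orientation=Orientation.TANDEM),
            _pair("G4", 9_000),
            _pair("G5", 0, same_contig=False),
        ]
        meta = [GenomeMetadata(f"G{i}", "archaea") for i in range(1, 6)]
        s = colocalization_summary(pairs, meta)
        assert s.overall.n_co_localized == 3
        assert sum(s.overall.orientation_counts.values()) == 3
        assert s.overall.orientation_counts["tandem"] == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(17)
        pairs = [_pair(f"G{i}", int(rng.integers(0, 20_000))) for i in range(60)]
        meta = [GenomeMetadata(f"G{i}", "bacteria") for i in range(60)]
        counts = [
            colocalization_summary(pairs, meta, threshold=t).overall.n_co_localized
            for t in (500, 2_000, 5_000, 10_000, 25_000)
        ]
        assert counts == sorted(counts)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            colocalization_summary([], [], threshold=0)
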