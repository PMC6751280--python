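import numpy as np
import pytest

from splicedyn.models import GenomeSequence
from splicedyn.polya import (
    PolyACluster,
    PolyARecord,
    cluster_polya_sites,
    hexamer_enrichment,
    nucleotide_composition,
    sites_per_gene,
    stage_site_sharing,
)

from conftest import make_gene, make_tx


def recs(positions, chrom="chr1", strand="+", count=1):
    return [PolyARecord(chrom, p, strand, count) for p in positions]


class TestClustering:
    def test_window_chaining(self):
        out = cluster_polya_sites(recs([100, 105, 130]), window=20)
        assert [c.member_positions for c in out] == [(100, 105), (130,)]

    def test_single_record(self):
        (c,) = cluster_polya_sites(recs([42]))
        assert c.support == 1 and c.representative_position == 42

    def test_input_order_invariance_and_member_union(self):
        pos = [500, 100, 130, 105, 470]
        a = cluster_polya_sites(recs(pos))
        b = cluster_polya_sites(recs(sorted(pos)))
        assert [c.member_positions for c in a] == [c.member_positions for c in b]
        assert sorted(p for c in a for p in c.member_positions) == sorted(pos)

    def test_representative_max_support_then_three_prime(self):
        records = recs([100] * 3 + [110] * 5 + [115] * 5)
        (c,) = cluster_polya_sites(records)
        assert c.representative_position == 115  # tie on support, 3'-most on '+'
        (cm,) = cluster_polya_sites(
            recs([100] * 5 + [110] * 5, strand="-")
        )
        assert cm.representative_position == 100  # 3'-most on '-' is smallest

    def test_strands_not_mixed(self):
        out = cluster_polya_sites(
            recs([100]) + recs([105], strand="-")
        )
        assert len(out) == 2


class TestSitesPerGene:
    def _gene(self, gid="g1", span=(1000, 2000), strand="+"):
        return make_gene(
            [make_tx(f"{gid}.t", [span], gene=gid, strand=strand)],
            gene=gid, strand=strand,
        )

    def test_counts_and_fractions(self):
        g1, g2 = self._gene("g1"), self._gene("g2", span=(10_000, 11_000))
        clusters = [
            PolyACluster("chr1", "+", 2100, 3, (2100,)),
            PolyACluster("chr1", "+", 2400, 2, (2400,)),
            PolyACluster("chr1", "+", 11_200, 2, (11_200,)),
        ]
        counts, mean, frac_multi, unassigned = sites_per_gene(clusters, [g1, g2])
        assert counts["g1"] == 2 and counts["g2"] == 1
        assert mean == pytest.approx(1.5)
        assert frac_multi == pytest.approx(0.5)
        assert unassigned == []

    def test_min_support_filters(self):
        g1 = self._gene("g1")
        clusters = [PolyACluster("chr1", "+", 2100, 1, (2100,))]
        counts, _, _, _ = sites_per_gene(clusters, [g1], min_support=2)
        assert counts.empty

    def test_unassigned_reported(self):
        g1 = self._gene("g1")
        far = PolyACluster("chr1", "+", 50_000, 5, (50_000,))
        _, _, _, unassigned = sites_per_gene([far], [g1])
        assert unassigned == [far]


class TestStageSharing:
    def _gene(self):
        return make_gene([make_tx("t", [(1000, 2000)], gene="g")], gene="g")

    def test_same_site_everywhere_unchanged(self):
        g = self._gene()
        cl = lambda p: [PolyACluster("chr1", "+", p, 3, (p,))]
        shared = stage_site_sharing({"E1": cl(2100), "E3": cl(2110)}, [g])
        assert shared["g"]  # 2100 vs 2110 within the 20-nt window

    def test_extra_site_changes(self):
        g = self._gene()
        one = [PolyACluster("chr1", "+", 2100, 3, (2100,))]
        two = one + [PolyACluster("chr1", "+", 2400, 3, (2400,))]
        shared = stage_site_sharing({"E1": one, "E3": two}, [g])
        assert not shared["g"]


class TestComposition:
    def test_all_a_genome(self):
        g = GenomeSequence({"chr1": "A" * 500})
        comp = nucleotide_composition(
            [PolyACluster("chr1", "+", 250, 1, (250,))], g
        )
        assert np.allclose(comp["A"], 1.0)

    def test_one_hot_known_flank(self):
        seq = "A" * 200 + "C" + "A" * 200
        g = GenomeSequence({"chr1": seq})
        comp = nucleotide_composition(
            [PolyACluster("chr1", "+", 211, 1, (211,))], g
        )
        assert comp.loc[-10, "C"] == 1.0  # the single C sits 10 nt upstream

    def test_minus_strand_is_complemented(self):
        seq = "A" * 200 + "G" + "A" * 200
        g = GenomeSequence({"chr1": seq})
        comp = nucleotide_composition(
            [PolyACluster("chr1", "-", 191, 1, (191,))], g
        )
        # genomic G at 201 is 10 nt upstream in '-' orientation, read as C
        assert comp.loc[-10, "C"] == 1.0

    def test_rows_sum_to_one(self, synthetic_bundle):
        genome, _, _, records, _ = synthetic_bundle
        clusters = cluster_polya_sites(records)
        comp = nucleotide_composition(clusters, genome)
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)


class TestHexamers:
    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(0)
        chunks, positions = [], []
        cursor = 0
        for i in range(200):
            w = rng.choice(list("CGT"), size=80)  # A-free background
            if i < 160:  # 80% of windows carry the signal (window = bases 20..69)
                j = rng.integers(25, 60)
                w[j : j + 6] = list("AATAAA")
            chunks.append("".join(w))
            cursor += 80
            positions.append(cursor - 10)
        g = GenomeSequence({"chr1": "".join(chunks)})
        clusters = [PolyACluster("chr1", "+", p, 2, (p,)) for p in positions]
        out = hexamer_enrichment(clusters, g, upstream=50)
        assert out[0].motif == "AATAAA"
        assert out[0].observed >= 100

    def test_single_window_contains_motif(self):
        g = GenomeSequence({"chr1": "C" * 30 + "AAATAAA" + "C" * 63})
        (m,) = [
            x for x in hexamer_enrichment(
                [PolyACluster("chr1", "+", 60, 1, (60,))], g
            )
            if x.motif == "AATAAA"
        ]
        assert m.observed == 1

    def test_null_windows_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            seq = "".join(rng.choice(list("ACGT"), size=15000,
                                     p=[0.29, 0.21, 0.21, 0.29]))
            g = GenomeSequence({"chr1": seq})
            positions = 100 + np.arange(50) * 280 + rng.integers(0, 200, size=50)
            clusters = [PolyACluster("chr1", "+", int(p), 2, (int(p),))
                        for p in positions]
            out = hexamer_enrichment(clusters, g)
            if out[0].p * 4096 < 0.05:
                hits += 1
        assert hits <= 2

    def test_generator_signal_recovered(self, synthetic_bundle):
        genome, _, _, records, _ = synthetic_bundle
        clusters = cluster_polya_sites(records)
        out = hexamer_enrichment(clusters, genome)
        assert out[0].motif == "AATAAA"


class TestGeneratorTruth:
    def test_cluster_count_equals_planted(self, synthetic_bundle):
        _, _, _, records, truth = synthetic_bundle
        clusters = cluster_polya_sites(records)
        planted = sum(len(v) for v in truth.polya_truth.values())
        assert len(clusters) == planted
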