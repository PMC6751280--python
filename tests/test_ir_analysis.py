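import math

import numpy as np
import pytest
from scipy import stats

from splicedyn.events import detect_events
from splicedyn.introns import (
    RepresentativeCDS,
    SpliceSitePWM,
    classify_ptc,
    filter_ir_transcripts_for_ptc,
    longest_orf,
    rank_sum_test,
    retained_intron_features,
    score_splice_sites,
    train_splice_pwm,
)
from splicedyn.io import extract_introns, transcript_sequence
from splicedyn.models import GenomeSequence, ValidationError

from conftest import make_gene, make_tx
from _oracles import brute_force_longest_orf


def _ir_setup(strand="+", intron_seq=None, span=1000):
    """A two-isoform IR gene whose retained intron content is controlled."""
    seq = list("A" * span)
    # gene span 1..1000; intron 901..950 would be at ratio 0.9 -- built per test
    return seq


class TestRetainedIntronFeatures:
    def test_position_ratio_plus(self):
        g = GenomeSequence({"chr1": "A" * 1000})
        gene = make_gene([
            make_tx("a", [(1, 900), (961, 1000)]),
            make_tx("b", [(1, 1000)]),
        ])
        (ev,) = detect_events(gene)
        (feat,) = retained_intron_features([ev], [gene], g)
        assert feat.position_ratio == pytest.approx(0.9)

    def test_position_ratio_minus_is_mirrored(self):
        g = GenomeSequence({"chr1": "A" * 1000})
        gene = make_gene([
            make_tx("a", [(1, 40), (101, 1000)], strand="-"),
            make_tx("b", [(1, 1000)], strand="-"),
        ], strand="-")
        (ev,) = detect_events(gene)
        (feat,) = retained_intron_features([ev], [gene], g)
        # intron 41..100; on '-' distance from 3' end (genomic end) dominates
        assert feat.position_ratio == pytest.approx((1000 - 100) / 1000)

    def test_gc_and_canonical(self):
        seq = list("A" * 400)
        seq[100:200] = list("GT" + "GC" * 48 + "AG")
        g = GenomeSequence({"chr1": "".join(seq)})
        gene = make_gene([
            make_tx("a", [(1, 100), (201, 400)]),
            make_tx("b", [(1, 400)]),
        ])
        (ev,) = detect_events(gene)
        (feat,) = retained_intron_features([ev], [gene], g)
        assert feat.canonical
        assert feat.length == 100
        assert feat.gc == pytest.approx((2 + 96) / 100)


class TestSyntheticContrasts:
    def test_degenerate_retained_sites_score_below_canonical(self):
        from splicedyn import synthetic as syn

        genome = syn.generate_genome(1, 300_000, seed=80)
        genes, truth = syn.generate_gene_models(
            genome, 30, {"IR": 30}, seed=81, degenerate_ir_fraction=1.0
        )
        retained = {(gid, sig) for _, gid, sig in truth.as_events}
        non_retained, retained_recs = [], []
        for g in genes:
            spliced = max(g.transcripts, key=lambda t: t.n_exons)
            for rec in extract_introns(spliced, genome):
                if (g.gene_id, (rec.start, rec.end)) in retained:
                    retained_recs.append(rec)
                else:
                    non_retained.append(rec)
        pwm = train_splice_pwm(non_retained, genome)
        def mean_score(recs):
            scores = [score_splice_sites(r, pwm, genome) for r in recs]
            return np.mean([d + a for d, a in scores])
        assert mean_score(retained_recs) < mean_score(non_retained)

    def test_retained_introns_sit_three_prime_of_spliced_ones(self):
        from splicedyn import synthetic as syn
        from splicedyn.events import detect_events
        from splicedyn.introns import retained_intron_features

        genome = syn.generate_genome(1, 300_000, seed=82)
        genes, truth = syn.generate_gene_models(genome, 30, {"IR": 30}, seed=83)
        ir_events = [e for g in genes for e in detect_events(g)]
        feats = retained_intron_features(ir_events, genes, genome)
        retained_pos = np.mean([f.position_ratio for f in feats])
        # non-retained introns of the same genes (the 5' intron of each)
        by_id = {g.gene_id: g for g in genes}
        others = []
        for g in genes:
            spliced = max(g.transcripts, key=lambda t: t.n_exons)
            sig = next(s for _, gid, s in truth.as_events if gid == g.gene_id)
            gstart, gend = g.span
            for s, e in spliced.introns():
                if (s, e) != sig:
                    ratio = ((s - gstart) / g.length if g.strand == "+"
                             else (gend - e) / g.length)
                    others.append(ratio)
        assert retained_pos > np.mean(others)


class TestSplicePWM:
    def _introns(self, genome, windows):
        txs = []
        for i, _ in enumerate(windows):
            base = 1 + i * 300
            txs.append(make_tx(f"t{i}", [(base, base + 49), (base + 100, base + 149)],
                               gene=f"g{i}"))
        return [rec for t in txs for rec in extract_introns(t, genome)]

    def test_hand_tallied_counts(self):
        # three introns with identical windows: probabilities collapse to
        # indicator + pseudocount
        seq = list("A" * 1200)
        for i in range(3):
            s = 50 + i * 300  # intron start (1-based) = base+50
            seq[s : s + 6] = list("GTAAGT")
            e = 50 + i * 300 + 99  # intron end
            seq[e - 21 : e + 1] = list("T" * 20 + "AG"[0] + "G")
            seq[e - 2 : e] = list("AG")
        g = GenomeSequence({"chr1": "".join(seq)})
        introns = self._introns(g, range(3))
        pwm = train_splice_pwm(introns, g, pseudocount=0.5)
        assert np.allclose(pwm.donor.sum(axis=1), 1.0)
        assert np.allclose(pwm.acceptor.sum(axis=1), 1.0)
        # donor position 3 (first intronic) saw G three times:
        assert pwm.donor[3, 2] == pytest.approx((3 + 0.5) / (3 + 2.0))

    def test_pseudocount_limit(self):
        seq = list("A" * 1200)
        for i in range(3):
            s = 50 + i * 300
            seq[s : s + 2] = list("GT")
            e = s + 99
            seq[e - 1 : e + 1] = list("AG")
        g = GenomeSequence({"chr1": "".join(seq)})
        introns = self._introns(g, range(3))
        pwm = train_splice_pwm(introns, g, pseudocount=1e-9)
        assert pwm.donor[3, 2] == pytest.approx(1.0)  # P(G) at first intronic base

    def test_empty_training_set(self, toy_genome):
        with pytest.raises(ValidationError):
            train_splice_pwm([], toy_genome)

    def test_uniform_pwm_scores_zero(self):
        g = GenomeSequence({"chr1": "ACGT" * 300})
        t = make_tx("t", [(1, 50), (151, 200)])
        (intron,) = extract_introns(t, g)
        pwm = SpliceSitePWM(
            donor=np.full((9, 4), 0.25),
            acceptor=np.full((23, 4), 0.25),
            background=np.full(4, 0.25),
        )
        d, a = score_splice_sites(intron, pwm, g)
        assert d == pytest.approx(0.0) and a == pytest.approx(0.0)

    def test_consensus_site_is_argmax(self):
        rng = np.random.default_rng(0)
        donor = rng.dirichlet(np.ones(4), size=9)
        acceptor = rng.dirichlet(np.ones(4), size=23)
        pwm = SpliceSitePWM(donor=donor, acceptor=acceptor,
                            background=np.full(4, 0.25))
        bases = "ACGT"
        consensus = "".join(bases[i] for i in donor.argmax(axis=1))
        best = sum(math.log2(donor[i, donor[i].argmax()] / 0.25) for i in range(9))
        for _ in range(50):
            w = "".join(rng.choice(list(bases), size=9))
            score = sum(
                math.log2(donor[i, bases.index(b)] / 0.25) for i, b in enumerate(w)
            )
            assert score <= best + 1e-12


class TestRankSum:
    def test_exact_small_sample(self):
        u, p = rank_sum_test([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples(self):
        _, p = rank_sum_test([1, 2], [1, 2])
        assert p == 1.0

    def test_constant_pooled(self):
        _, p = rank_sum_test([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_symmetry(self):
        u1, p1 = rank_sum_test([1, 2, 7], [3, 4])
        u2, p2 = rank_sum_test([3, 4], [1, 2, 7])
        assert u1 + u2 == 3 * 2
        assert p1 == pytest.approx(p2)

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 40), rng.normal(0.7, 1, 35)
        u, p = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestLongestORF:
    def test_simple(self):
        r = longest_orf("ATGAAATAA")
        assert r.has_orf and r.start == 0 and r.stop == 8

    def test_no_orf(self):
        assert not longest_orf("CCCCCC").has_orf

    def test_orf_length_divisible_by_three(self):
        r = longest_orf("GATGAAACCCTGAG")
        assert r.has_orf and (r.stop - r.start + 1) % 3 == 0

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            r = longest_orf(seq)
            oracle = brute_force_longest_orf(seq)
            got = (r.start, r.stop) if r.has_orf else None
            assert got == oracle


class TestPTC:
    def _transcript_with_distance(self, distance):
        """Build genome + 2-exon transcript whose ORF stop sits `distance` nt
        upstream of the last junction."""
        orf = "ATG" + "AAA" * 15 + "TAA"  # stop last base at coord 50
        junction = 50 + distance  # 0-based junction coordinate
        exon1_len = junction + 1
        total = exon1_len + 48
        seq = orf + "C" * (total - len(orf))
        chrom = seq[:exon1_len] + "G" * 100 + seq[exon1_len:]
        g = GenomeSequence({"chr1": chrom})
        t = make_tx("t", [(1, exon1_len), (exon1_len + 101, exon1_len + 100 + 48)])
        return t, g

    @pytest.mark.parametrize("distance,expected", [(51, True), (50, False), (60, True)])
    def test_50nt_rule_boundary(self, distance, expected):
        t, g = self._transcript_with_distance(distance)
        orf = longest_orf(transcript_sequence(t, g))
        assert orf.stop == 50
        assert classify_ptc(t, orf) is expected
        assert orf.stop_to_last_junction == distance

    def test_stop_in_last_exon_is_not_ptc(self):
        seq = "C" * 100 + "G" * 50 + "ATGAAATAA" + "C" * 40
        g = GenomeSequence({"chr1": seq})
        t = make_tx("t", [(1, 100), (151, 199)])
        orf = longest_orf(transcript_sequence(t, g))
        assert orf.has_orf
        assert classify_ptc(t, orf) is False

    def test_single_exon_not_evaluable(self):
        t = make_tx("t", [(1, 99)])
        orf = longest_orf("ATG" + "AAA" * 10 + "TAA")
        with pytest.raises(ValidationError):
            classify_ptc(t, orf)


class TestPTCFilter:
    def test_inside_outside_overlap(self):
        reps = {"g": RepresentativeCDS(gene_id="g", cds_start=100, cds_end=500)}
        t = make_tx("t", [(1, 150), (451, 600)], gene="g")
        kept, excl = filter_ir_transcripts_for_ptc(
            [(t, (200, 300)), (t, (550, 580)), (t, (450, 520))], reps
        )
        assert [iv for _, iv in kept] == [(200, 300)]
        reasons = dict(excl)
        assert reasons["t"] in ("outside_cds", "overlapping_cds_boundary")
        assert len(excl) == 2

    def test_missing_representative(self):
        t = make_tx("t", [(1, 150), (451, 600)], gene="g")
        kept, excl = filter_ir_transcripts_for_ptc([(t, (200, 300))], {})
        assert kept == [] and excl == [("t", "no_representative")]
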