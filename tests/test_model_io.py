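import numpy as np
import pytest

from splicedyn.io import (
    GTFParseError,
    extract_introns,
    read_expression_table,
    read_transcript_gtf,
    transcript_sequence,
    write_transcript_gtf,
)
from splicedyn.models import (
    GenomeSequence,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)

from conftest import make_gene, make_tx


class TestGTF:
    def test_minimal_parse(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        genes = read_transcript_gtf(p)
        assert len(genes) == 1
        assert len(genes[0].transcripts) == 1
        assert genes[0].transcripts[0].exons == ((1, 100), (201, 300))

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.gtf"
        p.write_text("")
        assert read_transcript_gtf(p) == []

    def test_missing_attribute_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g2";\n'
        )
        with pytest.raises(GTFParseError, match="line 2"):
            read_transcript_gtf(p)

    def test_unstranded_rejected(self, tmp_path):
        p = tmp_path / "dot.gtf"
        p.write_text('chr1\tx\texon\t1\t100\t.\t.\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(GTFParseError, match="strand"):
            read_transcript_gtf(p)

    def test_overlapping_exons_rejected(self, tmp_path):
        p = tmp_path / "ov.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t50\t150\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValidationError, match="overlap"):
            read_transcript_gtf(p)

    def test_round_trip_random_models(self, tmp_path):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(20):
            strand = "+" if i % 2 else "-"
            txs = []
            for j in range(int(rng.integers(1, 4))):
                cuts = np.sort(
                    rng.choice(np.arange(1, 200), size=2 * int(rng.integers(1, 5)),
                               replace=False)
                ) * 5
                exons = [
                    (int(cuts[2 * k]), int(cuts[2 * k + 1]))
                    for k in range(len(cuts) // 2)
                ]
                txs.append(
                    make_tx(f"g{i}.t{j}", exons, gene=f"g{i}", strand=strand,
                            chrom=f"chr{i % 3 + 1}")
                )
            genes.append(
                make_gene(txs, gene=f"g{i}", strand=strand, chrom=f"chr{i % 3 + 1}")
            )
        p = tmp_path / "rt.gtf"
        write_transcript_gtf(genes, p)
        back = read_transcript_gtf(p)
        orig = {
            t.transcript_id: (t.gene_id, t.chrom, t.strand, t.exons)
            for g in genes for t in g.transcripts
        }
        rt = {
            t.transcript_id: (t.gene_id, t.chrom, t.strand, t.exons)
            for g in back for t in g.transcripts
        }
        assert rt == orig

    def test_write_empty(self, tmp_path):
        p = tmp_path / "empty.gtf"
        write_transcript_gtf([], p)
        assert p.read_text() == ""


class TestIntrons:
    def test_plus_strand_dinucleotides(self):
        seq = ["A"] * 300
        seq[100:102] = "GT"
        seq[198:200] = "AG"
        g = GenomeSequence({"chr1": "".join(seq)})
        t = make_tx("t", [(1, 100), (201, 300)])
        (rec,) = extract_introns(t, g)
        assert (rec.start, rec.end) == (101, 200)
        assert rec.donor_dinuc == "GT" and rec.acceptor_dinuc == "AG"
        assert rec.canonical

    def test_minus_strand_dinucleotides(self):
        # canonical on '-': genomic end holds revcomp of GT = AC, start holds CT
        seq = ["A"] * 300
        seq[100:102] = "CT"
        seq[198:200] = "AC"
        g = GenomeSequence({"chr1": "".join(seq)})
        t = make_tx("t", [(1, 100), (201, 300)], strand="-")
        (rec,) = extract_introns(t, g)
        assert rec.donor_dinuc == "GT" and rec.acceptor_dinuc == "AG"

    def test_single_exon_no_introns(self, toy_genome):
        assert extract_introns(make_tx("t", [(1, 50)]), toy_genome) == []

    def test_exons_and_introns_tile_span(self, toy_genome):
        rng = np.random.default_rng(3)
        for _ in range(30):
            cuts = np.sort(rng.choice(np.arange(1, 99), size=8, replace=False)) * 10
            t = make_tx("t", [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, 8, 2)],
                        chrom="chr1")
            g = GenomeSequence({"chr1": "A" * 1000})
            intervals = sorted(list(t.exons) + [(r.start, r.end)
                                                for r in extract_introns(t, g)])
            flat = [x for iv in intervals for x in iv]
            assert flat[0] == t.start and flat[-1] == t.end
            for a, b in zip(flat[1:-1:2], flat[2::2]):
                assert b == a + 1

    def test_out_of_bounds(self, toy_genome):
        t = make_tx("t", [(900, 950), (990, 1100)])
        with pytest.raises(ValidationError):
            extract_introns(t, toy_genome)


class TestTranscriptSequence:
    def test_plus_strand(self):
        g = GenomeSequence({"chr1": "ATGCCCTAA"})
        t = make_tx("t", [(1, 3), (7, 9)])
        assert transcript_sequence(t, g) == "ATGTAA"

    def test_minus_strand_is_revcomp(self):
        g = GenomeSequence({"chr1": "ATGCCCTAA"})
        plus = make_tx("t", [(1, 3), (7, 9)])
        minus = make_tx("t", [(1, 3), (7, 9)], strand="-")
        assert transcript_sequence(minus, g) == reverse_complement(
            transcript_sequence(plus, g)
        )

    def test_length_equals_exon_sum(self, toy_genome):
        rng = np.random.default_rng(5)
        for _ in range(25):
            cuts = np.sort(rng.choice(np.arange(1, 99), size=6, replace=False)) * 10
            exons = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, 6, 2)]
            t = make_tx("t", exons, strand=rng.choice(["+", "-"]))
            assert len(transcript_sequence(t, toy_genome)) == sum(
                e - s + 1 for s, e in exons
            )


class TestExpressionTable:
    def _write(self, tmp_path, body):
        p = tmp_path / "expr.tsv"
        p.write_text(body)
        return p

    def test_parse_toy(self, tmp_path):
        p = self._write(
            tmp_path,
            "transcript_id\tgene_id\tE1_1\tE2_1\n" "t1\tg1\t1.0\t2.0\n" "t2\tg1\t0.0\t3.0\n",
        )
        m = read_expression_table(p)
        assert m.values.shape == (2, 2)
        assert m.sample_meta.loc["E1_1"].tolist() == ["E1", 1]
        assert m.tx2gene["t2"] == "g1"

    def test_negative_value_rejected(self, tmp_path):
        p = self._write(
            tmp_path, "transcript_id\tgene_id\tE1_1\n" "t1\tg1\t-1\n"
        )
        with pytest.raises(ValidationError):
            read_expression_table(p)

    def test_duplicate_transcript_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "transcript_id\tgene_id\tE1_1\n" "t1\tg1\t1\n" "t1\tg1\t2\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_expression_table(p)

    def test_bad_sample_name_rejected(self, tmp_path):
        p = self._write(
            tmp_path, "transcript_id\tgene_id\tE9_1\n" "t1\tg1\t1\n"
        )
        with pytest.raises(ValidationError):
            read_expression_table(p)
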