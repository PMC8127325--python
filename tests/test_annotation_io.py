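"""Genome/GFF3/label-table reading and the longest-CDS intron extraction."""

import pytest

from introness import annotation_io as aio


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenome:
    def test_single_record(self, tmp_path):
        p = write(tmp_path, "g.fa", ">c1\nACGT\n")
        assert aio.read_genome(p) == {"c1": "ACGT"}

    def test_case_normalized(self, tmp_path):
        p = write(tmp_path, "g.fa", ">c1\nacgt\n")
        assert aio.read_genome(p)["c1"] == "ACGT"

    def test_two_contigs_lengths(self, tmp_path, rng):
        s1 = "".join(rng.choice(list("ACGT"), 100))
        s2 = "".join(rng.choice(list("ACGT"), 50))
        p = write(tmp_path, "g.fa", f">a\n{s1[:60]}\n{s1[60:]}\n>b\n{s2}\n")
        # independent line-by-line reader
        seqs, cur = {}, None
        for line in p.read_text().splitlines():
            if line.startswith(">"):
                cur = line[1:].split()[0]
                seqs[cur] = ""
            else:
                seqs[cur] += line.strip().upper()
        assert aio.read_genome(p) == seqs
        assert len(seqs["a"]) == 100 and len(seqs["b"]) == 50

    def test_malformed_names_line(self, tmp_path):
        p = write(tmp_path, "g.fa", "ACGT\n>c1\nACGT\n")
        with pytest.raises(ValueError, match="line 1"):
            aio.read_genome(p)

    def test_duplicate_contig(self, tmp_path):
        p = write(tmp_path, "g.fa", ">c1\nAC\n>c1\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            aio.read_genome(p)


GFF_HEADER = "##gff-version 3\n"


def gff_gene(contig, gid, strand, exons, tid=None, cds=None):
    tid = tid or f"{gid}.t1"
    cds = cds or exons
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    rows = [
        f"{contig}\tt\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gid}",
        f"{contig}\tt\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\tID={tid};Parent={gid}",
    ]
    for k, (s, e) in enumerate(exons):
        rows.append(f"{contig}\tt\texon\t{s}\t{e}\t.\t{strand}\t.\tID={tid}.e{k};Parent={tid}")
    for k, (s, e) in enumerate(cds):
        rows.append(f"{contig}\tt\tCDS\t{s}\t{e}\t.\t{strand}\t0\tID={tid}.c{k};Parent={tid}")
    return "\n".join(rows) + "\n"


class TestExtractIntrons:
    def test_plus_strand_gap(self, tmp_path):
        contig = "A" * 100 + "C" * 100 + "G" * 100
        fa = write(tmp_path, "g.fa", f">c1\n{contig}\n")
        gff = write(
            tmp_path, "a.gff3",
            GFF_HEADER + gff_gene("c1", "g1", "+", [(1, 100), (201, 300)]),
        )
        genes = aio.extract_introns(gff, aio.read_genome(fa))
        (g,) = genes
        (i,) = g.introns
        assert i.ordinal == 1 and i.length == 100 and i.sequence == "C" * 100

    def test_minus_strand_reverse_complement(self, tmp_path):
        # 10-bp intron, genomic plus-strand text GTACCTGAAG at 11..20
        plus_intron = "GTACCTGAAG"
        contig = "A" * 10 + plus_intron + "T" * 10
        fa = write(tmp_path, "g.fa", f">c1\n{contig}\n")
        gff = write(
            tmp_path, "a.gff3",
            GFF_HEADER + gff_gene("c1", "g1", "-", [(1, 10), (21, 30)]),
        )
        (g,) = aio.extract_introns(gff, aio.read_genome(fa))
        # hand reverse complement of GTACCTGAAG
        assert g.introns[0].sequence == "CTTCAGGTAC"

    def test_longest_cds_transcript_wins(self, tmp_path):
        contig = "A" * 50 + "C" * 50 + "G" * 100 + "T" * 100 + "A" * 200
        fa = write(tmp_path, "g.fa", f">c1\n{contig}\n")
        # t1: CDS total 150; t2: CDS total 300 -> introns from t2 only
        body = gff_gene("c1", "g1", "+", [(1, 50), (101, 200)], tid="g1.t1",
                        cds=[(1, 50), (101, 200)])
        body += "\n".join(
            gff_gene("c1", "g1", "+", [(1, 100), (201, 400)], tid="g1.t2",
                     cds=[(1, 100), (201, 400)]).splitlines()[1:]
        ) + "\n"
        gff = write(tmp_path, "a.gff3", GFF_HEADER + body)
        (g,) = aio.extract_introns(gff, aio.read_genome(fa))
        (i,) = g.introns
        assert i.transcript_id == "g1.t2"
        assert i.sequence == "G" * 100  # bases 101..200 of the contig

    def test_cds_tie_breaks_to_smallest_transcript_id(self, tmp_path):
        contig = "ACGT" * 100
        fa = write(tmp_path, "g.fa", f">c1\n{contig}\n")
        body = gff_gene("c1", "g1", "+", [(1, 50), (101, 150)], tid="g1.tb")
        body += "\n".join(
            gff_gene("c1", "g1", "+", [(1, 50), (101, 150)], tid="g1.ta")
            .splitlines()[1:]
        ) + "\n"
        gff = write(tmp_path, "a.gff3", GFF_HEADER + body)
        (g,) = aio.extract_introns(gff, aio.read_genome(fa))
        assert g.introns[0].transcript_id == "g1.ta"

    def test_overlapping_exons_error(self, tmp_path):
        fa = write(tmp_path, "g.fa", ">c1\n" + "ACGT" * 50 + "\n")
        gff = write(
            tmp_path, "a.gff3",
            GFF_HEADER + gff_gene("c1", "g1", "+", [(1, 100), (50, 150)]),
        )
        with pytest.raises(ValueError, match="g1.t1"):
            aio.extract_introns(gff, aio.read_genome(fa))

    def test_intronless_gene_empty_list(self, tmp_path):
        fa = write(tmp_path, "g.fa", ">c1\n" + "ACGT" * 50 + "\n")
        gff = write(tmp_path, "a.gff3",
                    GFF_HEADER + gff_gene("c1", "g1", "+", [(1, 100)]))
        (g,) = aio.extract_introns(gff, aio.read_genome(fa))
        assert g.introns == []

    def test_span_identity(self, tmp_path):
        """Intron lengths + exon lengths tile the transcript genomic span."""
        exons = [(1, 80), (161, 240), (301, 400)]
        fa = write(tmp_path, "g.fa", ">c1\n" + "ACGT" * 100 + "\n")
        gff = write(tmp_path, "a.gff3", GFF_HEADER + gff_gene("c1", "g1", "+", exons))
        (g,) = aio.extract_introns(gff, aio.read_genome(fa))
        exon_bp = sum(e - s + 1 for s, e in exons)
        span = exons[-1][1] - exons[0][0] + 1
        assert exon_bp + g.total_intronic_bp == span


class TestLabels:
    def test_read_table(self, tmp_path):
        p = write(
            tmp_path, "l.tsv",
            "gene_id\tn_essential\tn_total\tcategory\n"
            "g1\t10\t10\tessential\ng2\t0\t12\tnonessential\n",
        )
        t = aio.read_essentiality(p)
        assert (t["g1"].n_essential, t["g1"].n_total) == (10, 10)
        assert (t["g2"].n_essential, t["g2"].n_total) == (0, 12)

    def test_malformed_count(self, tmp_path):
        p = write(
            tmp_path, "l.tsv",
            "gene_id\tn_essential\tn_total\tcategory\ng1\tx\t10\tessential\n",
        )
        with pytest.raises(ValueError, match="g1"):
            aio.read_essentiality(p)

    def test_count_exceeds_total(self, tmp_path):
        p = write(
            tmp_path, "l.tsv",
            "gene_id\tn_essential\tn_total\tcategory\ng1\t11\t10\tessential\n",
        )
        with pytest.raises(ValueError):
            aio.read_essentiality(p)

    def test_duplicate_gene(self, tmp_path):
        p = write(
            tmp_path, "l.tsv",
            "gene_id\tn_essential\tn_total\tcategory\n"
            "g1\t1\t10\tconditional\ng1\t2\t10\tconditional\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            aio.read_essentiality(p)

    @pytest.mark.parametrize(
        "n_ess,n_tot,category,binary",
        [
            (10, 10, "essential", "essential"),
            (3, 10, "conditional", "discarded"),
            (6, 10, "conditional", "essential"),
            (5, 10, "conditional", "essential"),  # exactly half kept
            (0, 12, "nonessential", "nonessential"),
        ],
    )
    def test_assign_label(self, n_ess, n_tot, category, binary):
        assert aio.assign_label(n_ess, n_tot, category).binary == binary

    def test_half_rule_configurable(self):
        lab = aio.assign_label(5, 10, "conditional", half_is_essential=False)
        assert lab.binary == "discarded"

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            aio.assign_label(0, 0, "essential")


class TestRoundTrip:
    def test_fasta_round_trip(self, tmp_path, rng):
        from conftest import make_gene

        genes = [
            make_gene("gA", ["GT" + "".join(rng.choice(list("ACGT"), 96)) + "AG"
                             for _ in range(3)]),
            make_gene("gB", ["GTAACCGGTTAG"], category="nonessential"),
        ]
        path = tmp_path / "introns.fa"
        aio.write_intron_fasta(genes, path)
        back = {g.gene_id: g for g in aio.read_intron_fasta(path)}
        for g in genes:
            got = back[g.gene_id]
            assert [i.sequence for i in got.introns] == [
                i.sequence for i in g.introns
            ]
            assert [i.ordinal for i in got.introns] == [
                i.ordinal for i in g.introns
            ]

    def test_one_transcript_per_gene(self, tmp_path):
        """All extracted introns of a gene come from a single transcript."""
        contig = "ACGT" * 200
        fa = write(tmp_path, "g.fa", f">c1\n{contig}\n")
        body = gff_gene("c1", "g1", "+", [(1, 50), (101, 160), (201, 260)])
        body += "\n".join(
            gff_gene("c1", "g1", "+", [(1, 50), (201, 260)], tid="g1.t9")
            .splitlines()[1:]
        ) + "\n"
        gff = write(tmp_path, "a.gff3", GFF_HEADER + body)
        (g,) = aio.extract_introns(gff, aio.read_genome(fa))
        assert len({i.transcript_id for i in g.introns}) == 1
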