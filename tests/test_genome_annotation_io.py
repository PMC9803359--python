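"""FASTA/annotation parsing, intron derivation and window extraction."""
import pytest

from splicegrammar.genome_annotation_io import (
    AnnotationError,
    FastaError,
    Genome,
    GenomeSequence,
    Intron,
    ShortIntronError,
    SpliceSiteWindow,
    TranscriptModel,
    WindowError,
    acceptor_window,
    donor_window,
    extract_introns,
    extract_window,
    read_annotation,
    read_fasta,
    read_windows_tsv,
    reverse_complement,
    write_windows_tsv,
)


def test_read_fasta_uppercases_and_preserves_order(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1\nacgt\n>chr2\nTTTT\nAAAA\n")
    genome = read_fasta(fa)
    assert [rec.name for rec in genome] == ["chr1", "chr2"]
    assert genome["chr1"].seq == "ACGT"
    assert genome["chr2"].seq == "TTTTAAAA"


def test_read_fasta_converts_u_and_keeps_ambiguity_codes(tmp_path, caplog):
    fa = tmp_path / "g.fa"
    fa.write_text(">a\nACGU\n>b\nRYKM\n>c\nacgtn\n")
    with caplog.at_level("WARNING"):
        genome = read_fasta(fa)
    assert genome["a"].seq == "ACGT"
    assert genome["b"].seq == "RYKM"
    assert genome["c"].seq == "ACGTN"
    assert "ambiguity" in caplog.text


@pytest.mark.parametrize(
    "content", ["", "ACGT\n>late header\nACGT\n"], ids=["empty", "headerless"]
)
def test_read_fasta_rejects_malformed(tmp_path, content):
    fa = tmp_path / "bad.fa"
    fa.write_text(content)
    with pytest.raises(FastaError):
        read_fasta(fa)


def test_read_fasta_rejects_duplicate_headers(tmp_path):
    fa = tmp_path / "dup.fa"
    fa.write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(FastaError, match="duplicate"):
        read_fasta(fa)


def test_fetch_strand_and_bounds():
    genome = Genome([GenomeSequence("c", "AACCGGTT")])
    assert genome.fetch("c", 0, 4, "+") == "AACC"
    assert genome.fetch("c", 0, 4, "-") == "GGTT"
    with pytest.raises(WindowError):
        genome.fetch("c", 4, 9)
    with pytest.raises(WindowError):
        genome.fetch("c", -1, 4)


GTF = (
    'chr1\tx\texon\t1\t100\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\tx\texon\t201\t300\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1";\n'
)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_read_gtf_coordinate_conversion(tmp_path, strand):
    gtf = tmp_path / "a.gtf"
    gtf.write_text(GTF.format(strand=strand))
    (tx,) = read_annotation(gtf)
    assert tx.exons == ((0, 100), (200, 300))
    assert tx.strand == strand
    assert tx.gene_id == "g1"


def test_read_gff3_hierarchy_gene_grouping(tmp_path):
    lines = ["##gff-version 3"]
    for g, t, offset in (("gA", "tA1", 0), ("gA", "tA2", 0), ("gB", "tB1", 1000)):
        lines.append(f"chr1\tx\tmRNA\t{1+offset}\t{300+offset}\t.\t+\t.\tID={t};Parent={g}")
        lines.append(f"chr1\tx\texon\t{1+offset}\t{100+offset}\t.\t+\t.\tParent={t}")
        lines.append(f"chr1\tx\texon\t{201+offset}\t{300+offset}\t.\t+\t.\tParent={t}")
    gff = tmp_path / "a.gff3"
    gff.write_text("\n".join(lines) + "\n")
    models = {t.transcript_id: t for t in read_annotation(gff)}
    assert len(models) == 3
    assert models["tA1"].gene_id == "gA"
    assert models["tA2"].gene_id == "gA"
    assert models["tB1"].gene_id == "gB"
    assert models["tB1"].exons == ((1000, 1100), (1200, 1300))


def test_read_annotation_errors(tmp_path):
    bad = tmp_path / "bad.gtf"
    bad.write_text('chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g";\n')
    with pytest.raises(AnnotationError, match="attribution"):
        read_annotation(bad, dialect="gtf")
    mixed = tmp_path / "mixed.gtf"
    mixed.write_text(
        'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tx\texon\t201\t300\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
    )
    with pytest.raises(AnnotationError, match="mixed-strand"):
        read_annotation(mixed, dialect="gtf")


def test_extract_introns_strand_and_dedup():
    plus = TranscriptModel("t+", "g", "c", "+", ((0, 100), (200, 300)))
    (intron,) = extract_introns([plus])
    assert (intron.start, intron.end) == (100, 200)
    assert intron.donor_pos == 100 and intron.acceptor_pos == 199

    minus = TranscriptModel("t-", "g", "c", "-", ((0, 100), (200, 300)))
    (intron_m,) = extract_introns([minus])
    assert intron_m.donor_pos == 199 and intron_m.acceptor_pos == 100

    twin = TranscriptModel("t2", "g", "c", "+", ((0, 100), (200, 300), (400, 500)))
    assert len(extract_introns([plus, twin], dedup=True)) == 2  # (100,200) shared
    assert len(extract_introns([plus, twin], dedup=False)) == 3
    dup = extract_introns([plus, plus], dedup=False)
    assert len(dup) == 2
    assert len(extract_introns([plus, plus], dedup=True)) == 1


def test_extract_window_donor_examples(toy_genome):
    # exon ...GATTC | GTGAG... : -2..-1 "UC", +1..+5 "GUGAG" (UC//GUGAG donor)
    intron = Intron("chr1", "+", 10, 30)
    w = extract_window(intron, toy_genome, "five_prime")
    assert w.seq == "UUCGUGAG"
    assert w.subseq((-2, -1)) == "UC"
    assert w.subseq((1, 2, 3, 4, 5)) == "GUGAG"
    assert w.origin == ("chr1", "+", 10)
    assert w.notation == "UUC//GUGAG"


def test_extract_window_acceptor_example(toy_genome):
    # intron ...TGCAG | CA... : -5..-1 "UGCAG" ending UAG-like, +1..+2 "CA"
    intron = Intron("chr1", "+", 10, 30)
    w = extract_window(intron, toy_genome, "three_prime")
    assert w.seq == "UGCAGCA"
    assert w.subseq((-3, -2, -1)) == "CAG"
    assert w.subseq((1, 2)) == "CA"


def test_minus_strand_window_is_reverse_complement():
    # construct a genome whose minus-strand reading gives the plus-strand window
    plus_seq = "ATCGAGATTC" + "GTGAGTTTTTTTTTTTGCAG" + "CATTTGGGGG"
    flipped = Genome([GenomeSequence("chr1", reverse_complement(plus_seq))])
    n = len(plus_seq)
    intron = Intron("chr1", "-", n - 30, n - 10)
    w = extract_window(intron, flipped, "five_prime")
    assert w.seq == "UUCGUGAG"


def test_window_boundary_and_short_intron_errors(toy_genome):
    with pytest.raises(WindowError):
        extract_window(Intron("chr1", "+", 2, 30), toy_genome, "five_prime")
    with pytest.raises(ShortIntronError):
        extract_window(Intron("chr1", "+", 10, 14), toy_genome, "five_prime")


def test_donor_acceptor_notation_parsing():
    w = donor_window("UC//GUGAG")
    assert w.subseq((-2, -1)) == "UC" and w.subseq((1, 2, 3, 4, 5)) == "GUGAG"
    assert donor_window("AAG//GUAAG").seq == "AAGGUAAG"
    a = acceptor_window("UUGCAG\\\\CA")
    assert a.subseq((-3, -2, -1)) == "CAG" and a.subseq((1, 2)) == "CA"


def test_windows_tsv_round_trip(tmp_path, toy_genome):
    intron = Intron("chr1", "+", 10, 30)
    windows = [
        extract_window(intron, toy_genome, "five_prime"),
        extract_window(intron, toy_genome, "three_prime"),
    ]
    path = tmp_path / "w.tsv"
    write_windows_tsv(windows, path)
    back = read_windows_tsv(path)
    assert back == windows
    assert [w.positions for w in back] == [w.positions for w in windows]
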