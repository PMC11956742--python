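import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from sixframe import sfdb_builder as sb
from sixframe.reference_io import GeneModel, GenomeSequence, TranscriptModel
from sixframe.sample_genome import apply_variants
from sixframe.sfdb_builder import FRAME_LABELS, NonExonRegion


def gene(gene_id, chrom, strand, *transcript_exons):
    txs = tuple(
        TranscriptModel(f"{gene_id}t{i}", chrom, strand, tuple(exons))
        for i, exons in enumerate(transcript_exons, start=1)
    )
    return GeneModel(gene_id, chrom, strand, txs)


def sample_of(seq_map):
    return apply_variants(GenomeSequence(seq_map), [])


# ---------------------------------------------------------------------------
# non-exon extraction


def test_extract_single_gap():
    g = gene("g1", "c1", "+", [(1, 20), (51, 100)])
    regions = sb.extract_nonexon_regions([g])
    assert [(r.start, r.end) for r in regions] == [(21, 50)]
    assert regions[0].gene_id == "g1" and regions[0].index == 0


def test_extract_union_across_transcripts():
    # exon union of (1,30)+(61,100) and (1,40)+(81,100) is (1,40),(61,100):
    # the only gap is (41,60)
    g = gene("g1", "c1", "+", [(1, 30), (61, 100)], [(1, 40), (81, 100)])
    regions = sb.extract_nonexon_regions([g])
    assert [(r.start, r.end) for r in regions] == [(41, 60)]
    # brute-force per-base membership oracle over positions 1..100
    exonic = set()
    for t in g.transcripts:
        for s, e in t.exons:
            exonic.update(range(s, e + 1))
    expected = sorted(set(range(g.span[0], g.span[1] + 1)) - exonic)
    got = sorted(
        pos for r in regions for pos in range(r.start, r.end + 1)
    )
    assert got == expected


def test_extract_single_exon_gene_empty():
    g = gene("g1", "c1", "+", [(10, 90)])
    assert sb.extract_nonexon_regions([g]) == []


def test_extract_regions_disjoint_sorted_inside_span():
    g = gene("g1", "c1", "-", [(10, 20), (41, 50), (71, 90)])
    regions = sb.extract_nonexon_regions([g])
    spans = [(r.start, r.end) for r in regions]
    assert spans == [(21, 40), (51, 70)]
    assert all(g.span[0] <= s <= e <= g.span[1] for s, e in spans)


# ---------------------------------------------------------------------------
# six-frame translation


def test_translate_f0_example():
    # ATG AAA TAG GCC -> "MK" stop "A"
    segs = sb.translate_six_frames("ATGAAATAGGCC")["f0"]
    assert [s.peptide for s in segs] == ["MK", "A"]


def test_translate_r0_example():
    # reverse complement of ATGAAATAGGCC is GGCCTATTTCAT -> GLFH
    segs = sb.translate_six_frames("ATGAAATAGGCC")["r0"]
    assert [s.peptide for s in segs] == ["GLFH"]


def test_translate_below_codon_length():
    result = sb.translate_six_frames("AT")
    assert all(result[f] == [] for f in FRAME_LABELS)


def test_translate_n_codon_is_x():
    segs = sb.translate_six_frames("ATGANA")["f0"]
    assert [s.peptide for s in segs] == ["MX"]


def test_translate_exactly_six_frames():
    assert set(sb.translate_six_frames("ATGAAATAGGCC")) == set(FRAME_LABELS)
    assert len(FRAME_LABELS) == 6


def test_segment_spans_retranslate():
    seq = "ATGAAATAGGCCTTTGACCATTAA"
    region = NonExonRegion("g", "c1", 101, 100 + len(seq), 0)
    genome = GenomeSequence({"c1": "A" * 100 + seq + "A" * 10})
    for frame, segs in sb.translate_six_frames(seq, region).items():
        for s in segs:
            sub = genome.fetch("c1", s.span[0], s.span[1])
            if frame[0] == "r":
                sub = str(Seq(sub).reverse_complement())
            assert str(Seq(sub).translate()) == s.peptide


def test_truncation_flags():
    segs = sb.translate_six_frames("ATGAAATAGGCC")["f0"]
    first, last = segs
    assert first.start_truncated and not first.end_truncated
    assert not last.start_truncated and last.end_truncated


# frame cover: no stops, length 3k -> f0 translation has length len/3
def test_frame_cover_closed_form():
    seq = "GCT" * 50  # alanines, no stop
    segs = sb.translate_six_frames(seq)["f0"]
    assert len(segs) == 1 and len(segs[0].peptide) == 50


DNA = st.text(alphabet="ACGT", min_size=0, max_size=300)


@given(DNA)
@settings(max_examples=60, deadline=None)
def test_strand_symmetry(s):
    from sixframe.reference_io import reverse_complement

    fwd = sb.translate_six_frames(s)
    rev = sb.translate_six_frames(reverse_complement(s))
    for o in range(3):
        assert [x.peptide for x in fwd[f"f{o}"]] == [x.peptide for x in rev[f"r{o}"]]
        assert [x.peptide for x in fwd[f"r{o}"]] == [x.peptide for x in rev[f"f{o}"]]


def brute_force_segments(seq, frame):
    """Independent oracle: Bio.Seq codon-by-codon translation."""
    o = int(frame[1])
    s = seq if frame[0] == "f" else str(Seq(seq).reverse_complement())
    aas = []
    for i in range(o, len(s) - 2, 3):
        codon = s[i : i + 3]
        aas.append("X" if "N" in codon else str(Seq(codon).translate()))
    return [seg for seg in "".join(aas).split("*") if seg]


@given(st.text(alphabet="ACGTN", min_size=0, max_size=300))
@settings(max_examples=80, deadline=None)
def test_oracle_equivalence_random_regions(s):
    result = sb.translate_six_frames(s)
    for frame in FRAME_LABELS:
        assert [x.peptide for x in result[frame]] == brute_force_segments(s, frame)


# ---------------------------------------------------------------------------
# build_sfdb


def test_dedup_accumulates_provenance():
    # two regions with identical sequence give the same peptides
    seq = "ATGAAAGGGTTTCCCTAA"  # MKGFP then stop
    genome = GenomeSequence({"c1": seq + "T" * 6 + seq})
    sample = sample_of(genome.records)
    r1 = NonExonRegion("g1", "c1", 1, 18, 0)
    r2 = NonExonRegion("g2", "c1", 25, 42, 0)
    records = sb.build_sfdb([r1, r2], sample, min_len=5)
    mk = [r for r in records if r.peptide == "MKGFP"]
    assert len(mk) == 1
    assert len(mk[0].provenance) == 2
    assert {p.gene_id for p in mk[0].provenance} == {"g1", "g2"}


def test_min_len_drops_short_segments():
    sample = sample_of({"c1": "ATGAAATAGGCC"})
    region = NonExonRegion("g1", "c1", 1, 12, 0)
    assert sb.build_sfdb([region], sample, min_len=7) == []


def test_frame_partition_keys():
    sample = sample_of({"c1": "ATGAAAGGGTTTCCCTAA" * 3})
    region = NonExonRegion("g1", "c1", 1, 54, 0)
    per_frame = sb.build_sfdb([region], sample, min_len=1, frame_partition=True)
    assert set(per_frame) == set(FRAME_LABELS)


def test_il_not_merged_in_database():
    # CTT=L and ATT=I stay distinct records
    sample = sample_of({"c1": "CTTCTTCTTCTTTAAATTATTATTATT"})
    region = NonExonRegion("g1", "c1", 1, 27, 0)
    records = sb.build_sfdb([region], sample, min_len=4)
    peps = {r.peptide for r in records}
    assert "LLLL" in peps and "IIII" in peps


# ---------------------------------------------------------------------------
# FASTA output


def test_write_sfdb_header_and_roundtrip(tmp_path):
    sample = sample_of({"c1": "ATGAAAGGGTTTCCCTAA"})
    region = NonExonRegion("g1", "c1", 1, 18, 0)
    records = sb.build_sfdb([region], sample, min_len=2)
    path = tmp_path / "sfdb.fa"
    sb.write_sfdb_fasta(records, path)
    text = path.read_text()
    assert text.startswith(">NAPTP|g1|c1:")
    # single-locus records end with |0
    assert all(line.endswith("|0") for line in text.splitlines() if line.startswith(">"))
    back = sb.read_sfdb_fasta(path)
    assert [r.peptide for r in back] == [r.peptide for r in records]
    assert [r.provenance[0].span for r in back] == [r.provenance[0].span for r in records]
    assert (tmp_path / "sfdb.fa.provenance.tsv").exists()


def test_write_empty_sfdb(tmp_path):
    path = tmp_path / "sfdb.fa"
    sb.write_sfdb_fasta([], path)
    assert path.read_text() == ""
    assert (tmp_path / "sfdb.fa.provenance.tsv").read_text().count("\n") == 1
    assert sb.read_sfdb_fasta(path) == []


def test_planted_antisense_peptide_single_record(basic_fixture):
    # a 9-aa intronic peptide planted antisense appears in exactly one
    # record of the per-frame SFDB built from its own scene
    fx = basic_fixture
    sample = apply_variants(
        fx.reference, [v for v in fx.variants if v.p_value < fx.p_threshold]
    )
    regions = sb.extract_nonexon_regions(fx.genes)
    per_frame = sb.build_sfdb(regions, sample, min_len=7, frame_partition=True)
    plant = next(
        p for p in fx.plants if p.verdict == "unique_nonexon" and p.orientation == "antisense"
    )
    hits = [
        (frame, rec)
        for frame, recs in per_frame.items()
        for rec in recs
        if plant.sequence in rec.peptide
    ]
    assert len(hits) == 1
    frame, rec = hits[0]
    # antisense to a '-' strand gene means translation on '+', and vice versa
    gene_strand = next(g.strand for g in fx.genes if g.gene_id == plant.gene)
    expected_prefix = "f" if gene_strand == "-" else "r"
    assert frame.startswith(expected_prefix)
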