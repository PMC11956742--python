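import pytest

from sixframe import peptide_verify as pv
from sixframe.reference_io import GeneModel, GenomeSequence, InputError, TranscriptModel
from sixframe.sample_genome import apply_variants
from sixframe.synthfix import count_genomic_occurrences


def cand(seq):
    return pv.CandidatePeptide(seq)


def sample_of(seq_map):
    return apply_variants(GenomeSequence(seq_map), [])


def gene(gene_id, chrom, strand, exons):
    tx = TranscriptModel(f"{gene_id}t1", chrom, strand, tuple(exons))
    return GeneModel(gene_id, chrom, strand, (tx,))


# ---------------------------------------------------------------------------
# candidate input


def test_read_peptides_plain_and_tsv(tmp_path):
    plain = tmp_path / "p.txt"
    plain.write_text("MKWVTF\nPEPTIDER\n")
    cands, rejected = pv.read_peptides(plain)
    assert [c.sequence for c in cands] == ["MKWVTF", "PEPTIDER"]
    tsv = tmp_path / "p.tsv"
    tsv.write_text("sequence\tsample_id\nMKWVTF\ts1\n")
    cands, _ = pv.read_peptides(tsv)
    assert cands == [pv.CandidatePeptide("MKWVTF", "s1")]


def test_read_peptides_ambiguous_residues(tmp_path):
    p = tmp_path / "p.txt"
    p.write_text("MKXVTF\n")
    with pytest.raises(InputError, match="invalid residues"):
        pv.read_peptides(p)
    cands, rejected = pv.read_peptides(p, lenient=True)
    assert cands == []
    assert rejected[0][1] == "ambiguous_aa"


# ---------------------------------------------------------------------------
# proteome exclusion


def test_exclude_known_substring():
    retained, excluded = pv.exclude_known([cand("MKWVTF")], {"p1": "AMKWVTFI"})
    assert retained == []
    assert excluded[0][0].sequence == "MKWVTF"


def test_exclude_known_il_no_false_positive():
    # F != L even under I/L equivalence
    retained, excluded = pv.exclude_known([cand("MKWVTF")], {"p1": "AMKWVTLI"})
    assert [c.sequence for c in retained] == ["MKWVTF"]


def test_exclude_known_il_equivalence():
    # brute-force check with the equivalence alphabet: fold both sides I=L
    needle, hay = "PEPTIDE", "XXPEPTLDEXX".replace("X", "A")
    folded_match = any(
        needle.replace("L", "I") == hay[i : i + len(needle)].replace("L", "I")
        for i in range(len(hay) - len(needle) + 1)
    )
    assert folded_match  # oracle agrees the match exists
    retained, excluded = pv.exclude_known([cand("PEPTIDE")], {"p1": hay})
    assert retained == []
    # and exact matching keeps it
    retained, _ = pv.exclude_known([cand("PEPTIDE")], {"p1": hay}, il_equivalent=False)
    assert len(retained) == 1


def test_exclude_known_empty_proteome_warns():
    with pytest.warns(UserWarning, match="empty proteome"):
        retained, excluded = pv.exclude_known([cand("MKWVTF")], {})
    assert len(retained) == 1 and excluded == []


# ---------------------------------------------------------------------------
# occurrence scan + classification


def test_locate_two_loci():
    genome = {"c1": "ATGAAATTTTTTATGAAA"}
    occs = pv.locate_occurrences("MK", sample_of(genome), [])
    mk_hits = [o for o in occs if o.strand == "+"]
    assert len(mk_hits) == 2
    assert [o.span for o in mk_hits] == [(1, 6), (13, 18)]


def test_locate_absent():
    assert pv.locate_occurrences("WWWW", sample_of({"c1": "A" * 60}), []) == []


def test_locate_reverse_strand_span():
    # plant "MK" on the - strand: revcomp(ATGAAA)=TTTCAT at the start
    genome = {"c1": "TTTCAT" + "C" * 12}
    occs = pv.locate_occurrences("MK", sample_of(genome), [])
    (occ,) = occs
    assert occ.strand == "-" and occ.frame == "r0"
    assert occ.span == (1, 6)


def test_locate_in_exon_flag():
    genome = {"c1": "ATGAAATTTTTTATGAAA"}
    g = gene("g1", "c1", "+", [(1, 8)])
    occs = pv.locate_occurrences("MK", sample_of(genome), [g])
    first, second = [o for o in occs if o.strand == "+"]
    assert first.in_exon  # span (1,6) overlaps exon (1,8)
    assert not second.in_exon
    assert first.host_genes == ("g1",)
    assert second.host_genes == ()


def test_classify_rule_table():
    occ_nonexon = pv.GenomicOccurrence("c1", "+", "f0", (1, 6), (1, 6), False, (), 0)
    occ_exon = pv.GenomicOccurrence("c1", "+", "f0", (1, 6), (1, 6), True, (), 0)
    c = cand("MK")
    assert pv.classify(c, []) == "absent"
    assert pv.classify(c, [occ_nonexon, occ_exon]) == "multiple_occurrence"
    assert pv.classify(c, [occ_exon]) == "exonic"
    assert pv.classify(c, [occ_nonexon]) == "unique_nonexon"


# ---------------------------------------------------------------------------
# annotation


def _annotated_single(genome_map, genes, peptide, **kw):
    sample = sample_of(genome_map)
    occs = pv.locate_occurrences(peptide, sample, genes)
    assert len(occs) == 1
    return pv.annotate(occs[0], genes, sample, **kw)


def test_annotate_tryptic_termini():
    # CGT=R . ATGAAA=MK(ends K) . GCT=A  -> N-term tryptic, C-term tryptic
    genome = {"c1": "CGTATGAAAGCT" + "CCCCCACCCCCACCCCCA"}
    g = gene("g1", "c1", "+", [(25, 30)])
    ann = _annotated_single(genome, [g], "MK")
    assert ann.flank_up == "R" and ann.nterm_tryptic
    assert ann.cterm_tryptic  # peptide ends in K
    assert ann.flanked == "R.MK.A"


def test_annotate_nontryptic_nterm():
    # TTT=F . ATGGAC=MD . TGG=W -> neither terminus tryptic
    genome = {"c1": "TTTATGGACTGG" + "CCACCACCACCACCACCA"}
    g = gene("g1", "c1", "+", [(25, 30)])
    ann = _annotated_single(genome, [g], "MD")
    assert ann.flank_up == "F" and not ann.nterm_tryptic
    assert not ann.cterm_tryptic
    assert ann.flanked == "F.MD.W"


def test_annotate_no_cut_before_p():
    # peptide ends K but is followed by P
    genome = {"c1": "CGTATGAAACCT" + "CCACCACCACCACCACCA"}
    g = gene("g1", "c1", "+", [(25, 30)])
    ann = _annotated_single(genome, [g], "MK")
    assert ann.cterm_tryptic  # default: semi-tryptic, P does not veto
    ann2 = _annotated_single(genome, [g], "MK", no_cut_before_p=True)
    assert not ann2.cterm_tryptic


def test_annotate_edge_flank_is_dash():
    genome = {"c1": "ATGAAA" + "CCACCACCACCACCACCA"}
    g = gene("g1", "c1", "+", [(19, 24)])
    ann = _annotated_single(genome, [g], "MK")
    assert ann.flank_up == "-"


def test_annotate_sense_antisense():
    # gene span (1,30) contains the occurrence (4,9); exon union does not
    genome = {"c1": "CGTATGAAAGCT" + "CCACCACCACCACCACCA"}
    plus_gene = gene("g1", "c1", "+", [(1, 2), (25, 30)])
    minus_gene = gene("g1", "c1", "-", [(1, 2), (25, 30)])
    assert _annotated_single(genome, [plus_gene], "MK").orientation == "sense"
    assert _annotated_single(genome, [minus_gene], "MK").orientation == "antisense"


def test_annotate_intergenic():
    genome = {"c1": "CGTATGAAAGCT" + "CCACCACCACCACCACCA"}
    far_gene = gene("g1", "c1", "+", [(19, 24)])
    ann = _annotated_single(genome, [far_gene], "MK")
    assert ann.gene == "none" and ann.orientation == "intergenic"


def test_annotate_host_gene_smallest_span():
    genome = {"c1": "CGTATGAAAGCT" + "CCACCACCACCACCACCA"}
    big = gene("gbig", "c1", "+", [(1, 30)])
    small = gene("gsmall", "c1", "+", [(1, 2), (14, 16)])
    # the occurrence (4,9) is a gap of both genes' exon unions
    ann = _annotated_single(genome, [big, small], "MK")
    assert ann.gene == "gsmall"
    assert set(ann.host_genes) == {"gbig", "gsmall"}


# ---------------------------------------------------------------------------
# minimal length


def test_minimal_length_walk():
    # segment MKAAAA then stop: peptide MK at its start -> 6
    genome = {"c1": "ATGAAAGCTGCAGCCGCGTAA" + "CCACCACCACCACCACCA"}
    sample = sample_of(genome)
    (occ,) = pv.locate_occurrences("MK", sample, [])
    length, lower = pv.estimate_minimal_length(occ, sample)
    assert (length, lower) == (6, False)


def test_minimal_length_peptide_ends_at_stop():
    genome = {"c1": "ATGAAATAA" + "CCACCACCACCACCACCA"}
    sample = sample_of(genome)
    (occ,) = pv.locate_occurrences("MK", sample, [])
    length, lower = pv.estimate_minimal_length(occ, sample)
    assert (length, lower) == (2, False)


def test_minimal_length_boundary_lower_bound():
    # no downstream stop before the chrom end
    genome = {"c1": "CCC" + "ATGAAA" + "GCTGCA"}
    sample = sample_of(genome)
    (occ,) = pv.locate_occurrences("MK", sample, [])
    length, lower = pv.estimate_minimal_length(occ, sample)
    assert lower is True
    assert length == 4  # MK + AA to the sequence end


def test_minimal_length_from_upstream_stop():
    # stop, R, MK, A, stop: default 3 (MKA), upstream-stop convention 4 (RMKA)
    genome = {"c1": "TAACGTATGAAAGCTTAA" + "CCACCACCACCACCACCA"}
    sample = sample_of(genome)
    (occ,) = pv.locate_occurrences("MK", sample, [])
    assert pv.estimate_minimal_length(occ, sample) == (3, False)
    assert pv.estimate_minimal_length(occ, sample, from_upstream_stop=True) == (4, False)


def test_minimal_length_fixture_arithmetic(funnel_fixture):
    # every unique plant: minimal_length = |peptide| + pad_to_stop by construction
    for p in funnel_fixture.plants:
        if p.verdict == "unique_nonexon":
            assert p.minimal_length > len(p.sequence)


# ---------------------------------------------------------------------------
# funnel + report


def test_verify_candidates_partition(funnel_fixture, funnel_sample):
    fx = funnel_fixture
    cands = [cand(s) for s in fx.candidates]
    res = pv.verify_candidates(cands, funnel_sample, fx.genes, proteome=fx.proteome)
    assert len(res.annotations) == len(cands)
    assert sum(
        res.counts[k]
        for k in ("known_protein", "absent", "multiple_occurrence", "exonic", "unique_nonexon")
    ) == len(cands)


def test_locate_matches_naive_scan(funnel_fixture, funnel_sample):
    fx = funnel_fixture
    scanner = pv.OccurrenceScanner(funnel_sample, fx.genes)
    for pep in fx.candidates:
        assert len(scanner.locate(pep)) == count_genomic_occurrences(
            funnel_sample.genome, pep
        )


def test_report_rows_and_columns(funnel_fixture, funnel_sample, tmp_path):
    fx = funnel_fixture
    cands = [cand(s) for s in fx.candidates]
    res = pv.verify_candidates(cands, funnel_sample, fx.genes, proteome=fx.proteome)
    out = tmp_path / "report.tsv"
    df = pv.report(res.annotations, out)
    assert len(df) == len(cands)
    assert out.read_text().splitlines()[0].startswith("peptide\tverdict")


def test_report_empty(tmp_path):
    out = tmp_path / "report.tsv"
    df = pv.report([], out)
    assert len(df) == 0
    assert out.read_text().splitlines()[0].startswith("peptide")
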