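"""Verification funnel for MS-derived candidate peptides.

Steps: exclude candidates found in the annotated proteome, locate each
survivor in six-frame genome space, demand a single unique non-exonic
occurrence, annotate orientation against the host gene, recover flanking
residues and tryptic status, and estimate the minimal product length.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .reference_io import (
    GeneModel,
    InputError,
    merge_intervals,
    intervals_overlap,
)
from .sample_genome import GAP, SampleGenome
from .sfdb_builder import (
    FORWARD_FRAMES,
    REVERSE_FRAMES,
    translate_codon,
    translate_frame,
)

__all__ = [
    "CandidatePeptide",
    "GenomicOccurrence",
    "NaPtpAnnotation",
    "OccurrenceScanner",
    "read_peptides",
    "exclude_known",
    "locate_occurrences",
    "classify",
    "annotate",
    "estimate_minimal_length",
    "verify_candidates",
    "report",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("BZXUO")


def fold_il(seq: str) -> str:
    """Collapse I/L (indistinguishable by mass) onto one symbol."""
    return seq.replace("L", "I")


@dataclass(frozen=True)
class CandidatePeptide:
    sequence: str
    sample_id: str | None = None
    psm_count: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("candidate peptide must be non-empty")


@dataclass(frozen=True)
class GenomicOccurrence:
    chrom: str
    strand: str  # + | -
    frame: str  # chrom-relative frame label
    span: tuple[int, int]  # sample coordinates, 1-based inclusive
    ref_span: tuple[int | None, int | None]  # GAP components for insertions
    in_exon: bool
    host_genes: tuple[str, ...]
    aa_index: int  # offset within the chrom-frame translation


@dataclass
class NaPtpAnnotation:
    peptide: str
    verdict: str  # unique_nonexon | multiple_occurrence | exonic | absent | known_protein
    occurrence: GenomicOccurrence | None = None
    gene: str | None = None
    host_genes: tuple[str, ...] = ()
    orientation: str | None = None  # sense | antisense | intergenic
    flank_up: str = "-"
    flank_down: str = "-"
    nterm_tryptic: bool | None = None
    cterm_tryptic: bool | None = None
    minimal_length: int | None = None
    minimal_length_lower_bound: bool = False
    sample_id: str | None = None

    @property
    def flanked(self) -> str:
        return f"{self.flank_up}.{self.peptide}.{self.flank_down}"


# ---------------------------------------------------------------------------
# candidate input


def read_peptides(path: str | os.PathLike, lenient: bool = False):
    """Read a candidate list: plain text (one peptide per line) or TSV with
    a ``sequence`` column and optional ``sample_id``.

    Returns (candidates, rejected) where rejected holds (CandidatePeptide,
    reason) pairs; candidates with B/Z/X/U/O are an error unless ``lenient``,
    in which case they are auto-rejected with reason ``ambiguous_aa``.
    """
    rows: list[tuple[str, str | None]] = []
    with open(path) as fh:
        first = fh.readline()
        if "\t" in first and "sequence" in first.lower().split("\t")[0:3] or \
                first.lower().startswith("sequence"):
            cols = [c.strip().lower() for c in first.rstrip("\n").split("\t")]
            i_seq = cols.index("sequence")
            i_sid = cols.index("sample_id") if "sample_id" in cols else None
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                rows.append(
                    (fields[i_seq].strip().upper(),
                     fields[i_sid].strip() if i_sid is not None else None)
                )
        else:
            for line in [first, *fh]:
                token = line.strip().upper()
                if token:
                    rows.append((token.split("\t")[0], None))

    candidates: list[CandidatePeptide] = []
    rejected: list[tuple[CandidatePeptide, str]] = []
    for seq, sid in rows:
        bad = set(seq) - AA_ALPHABET
        if bad:
            if bad <= AMBIGUOUS_AA and lenient:
                rejected.append((CandidatePeptide(seq, sid), "ambiguous_aa"))
                continue
            raise InputError(f"{path}: peptide {seq!r} has invalid residues {sorted(bad)}")
        candidates.append(CandidatePeptide(seq, sid))
    return candidates, rejected


# ---------------------------------------------------------------------------
# proteome exclusion


def exclude_known(
    candidates: list[CandidatePeptide],
    proteome: str | os.PathLike | dict[str, str],
    il_equivalent: bool = True,
):
    """Split candidates into (retained, excluded) by substring search
    against an annotated proteome FASTA.

    With ``il_equivalent`` (default, matching MS indistinguishability) I and
    L are treated as the same residue.
    """
    if isinstance(proteome, (str, os.PathLike)):
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(proteome), "fasta")}
    else:
        seqs = {k: v.upper() for k, v in proteome.items()}
    if not seqs:
        warnings.warn("empty proteome: no candidates excluded", stacklevel=2)
        return list(candidates), []

    key = fold_il if il_equivalent else (lambda s: s)
    haystack = "\n".join(key(s) for s in seqs.values())
    retained: list[CandidatePeptide] = []
    excluded: list[tuple[CandidatePeptide, str]] = []
    for cand in candidates:
        if key(cand.sequence) in haystack:
            excluded.append((cand, "known_protein"))
        else:
            retained.append(cand)
    return retained, excluded


# ---------------------------------------------------------------------------
# genomic occurrence scan


class OccurrenceScanner:
    """Precomputed six-frame translations and exon index of a sample genome.

    Frame labels here are chrom-relative: f{o} reads the forward strand at
    offset o from position 1, r{o} reads the reverse complement at offset o
    from its start (the chrom end).
    """

    def __init__(
        self,
        sample: SampleGenome,
        genes: list[GeneModel],
        il_equivalent: bool = False,
    ):
        from .reference_io import reverse_complement

        self.sample = sample
        self.genes = genes
        self.il_equivalent = il_equivalent
        self._translations: dict[tuple[str, str], str] = {}
        for chrom, seq in sample.genome.records.items():
            rc = reverse_complement(seq)
            for o in range(3):
                self._translations[(chrom, f"f{o}")] = translate_frame(seq, o)
                self._translations[(chrom, f"r{o}")] = translate_frame(rc, o)
        self._exons: dict[str, list[tuple[int, int]]] = {}
        self._gene_spans: dict[str, list[tuple[int, int, str]]] = {}
        for g in genes:
            self._exons.setdefault(g.chrom, []).extend(g.exon_union())
            self._gene_spans.setdefault(g.chrom, []).append((*g.span, g.gene_id))
        self._exons = {c: merge_intervals(v) for c, v in self._exons.items()}

    def locate(self, peptide: str) -> list[GenomicOccurrence]:
        key = fold_il if self.il_equivalent else (lambda s: s)
        needle = key(peptide)
        plen = len(peptide)
        out: list[GenomicOccurrence] = []
        for (chrom, frame), translation in self._translations.items():
            hay = key(translation)
            L = self.sample.genome.length(chrom)
            offset = int(frame[1])
            start = hay.find(needle)
            while start != -1:
                if frame[0] == "f":
                    span = (
                        offset + 3 * start + 1,
                        offset + 3 * (start + plen - 1) + 3,
                    )
                    strand = "+"
                else:
                    span = (
                        L - offset - 3 * (start + plen - 1) - 2,
                        L - offset - 3 * start,
                    )
                    strand = "-"
                out.append(self._make_occurrence(chrom, strand, frame, span, start))
                start = hay.find(needle, start + 1)
        out.sort(key=lambda o: (o.chrom, o.span, o.frame))
        return out

    def _make_occurrence(self, chrom, strand, frame, span, aa_index):
        exons = self._exons.get(chrom, [])
        in_exon = intervals_overlap(exons, span[0], span[1]) if exons else False
        hosts = tuple(
            sorted(
                gid
                for s, e, gid in self._gene_spans.get(chrom, [])
                if s <= span[0] and span[1] <= e
            )
        )
        ref_lo, _ = self.sample.map.to_reference(chrom, span[0])
        ref_hi, _ = self.sample.map.to_reference(chrom, span[1])
        return GenomicOccurrence(
            chrom, strand, frame, span, (ref_lo, ref_hi), in_exon, hosts, aa_index
        )

    def frame_translation(self, chrom: str, frame: str) -> str:
        return self._translations[(chrom, frame)]


def locate_occurrences(
    peptide: str,
    sample: SampleGenome,
    genes: list[GeneModel],
    il_equivalent: bool = False,
) -> list[GenomicOccurrence]:
    """Exhaustive six-frame scan of every chrom for one peptide.

    For many peptides build an OccurrenceScanner once and reuse it.
    """
    return OccurrenceScanner(sample, genes, il_equivalent).locate(peptide)


def classify(candidate: CandidatePeptide, occurrences: list[GenomicOccurrence]) -> str:
    """Verdict rule table: 0 hits -> absent; >=2 -> multiple_occurrence;
    one exon-overlapping hit -> exonic; one non-exonic hit -> unique_nonexon."""
    if not occurrences:
        return "absent"
    if len(occurrences) >= 2:
        return "multiple_occurrence"
    return "exonic" if occurrences[0].in_exon else "unique_nonexon"


# ---------------------------------------------------------------------------
# annotation of unique non-exonic occurrences


def _gene_by_id(genes: list[GeneModel], gene_id: str) -> GeneModel:
    return next(g for g in genes if g.gene_id == gene_id)


def _flank_residue(scanner: OccurrenceScanner, occ: GenomicOccurrence, after: bool) -> str:
    translation = scanner.frame_translation(occ.chrom, occ.frame)
    if after:
        plen = (occ.span[1] - occ.span[0] + 1) // 3
        idx = occ.aa_index + plen
    else:
        idx = occ.aa_index - 1
    if idx < 0 or idx >= len(translation):
        return "-"
    aa = translation[idx]
    return "-" if aa == "*" else aa  # stop codons are not residues


def annotate(
    occurrence: GenomicOccurrence,
    genes: list[GeneModel],
    sample: SampleGenome,
    scanner: OccurrenceScanner | None = None,
    no_cut_before_p: bool = False,
    minlen_from_upstream_stop: bool = False,
    candidate: CandidatePeptide | None = None,
) -> NaPtpAnnotation:
    """Full annotation of a verified unique non-exonic occurrence."""
    if scanner is None:
        scanner = OccurrenceScanner(sample, genes)
    translation = scanner.frame_translation(occurrence.chrom, occurrence.frame)
    plen = (occurrence.span[1] - occurrence.span[0] + 1) // 3
    peptide = translation[occurrence.aa_index : occurrence.aa_index + plen]

    if occurrence.host_genes:
        host = min(
            (_gene_by_id(genes, gid) for gid in occurrence.host_genes),
            key=lambda g: (g.span[1] - g.span[0], g.gene_id),
        )
        gene_id = host.gene_id
        orientation = "sense" if occurrence.strand == host.strand else "antisense"
    else:
        gene_id = "none"
        orientation = "intergenic"

    up = _flank_residue(scanner, occurrence, after=False)
    down = _flank_residue(scanner, occurrence, after=True)

    nterm = up in ("K", "R")
    cterm = peptide[-1] in ("K", "R")
    if no_cut_before_p:
        if nterm and peptide[0] == "P":
            nterm = False
        if cterm and down == "P":
            cterm = False

    minlen, lower_bound = estimate_minimal_length(
        occurrence, sample, scanner=scanner, from_upstream_stop=minlen_from_upstream_stop
    )
    return NaPtpAnnotation(
        peptide=peptide,
        verdict="unique_nonexon",
        occurrence=occurrence,
        gene=gene_id,
        host_genes=occurrence.host_genes,
        orientation=orientation,
        flank_up=up,
        flank_down=down,
        nterm_tryptic=nterm,
        cterm_tryptic=cterm,
        minimal_length=minlen,
        minimal_length_lower_bound=lower_bound,
        sample_id=candidate.sample_id if candidate else None,
    )


def estimate_minimal_length(
    occurrence: GenomicOccurrence,
    sample: SampleGenome,
    scanner: OccurrenceScanner | None = None,
    genes: list[GeneModel] | None = None,
    from_upstream_stop: bool = False,
) -> tuple[int, bool]:
    """Shortest product containing the detected peptide and terminating at
    the first downstream in-frame stop.

    Returns (length_aa, lower_bound) where lower_bound marks a walk that hit
    the sequence end before any stop. With ``from_upstream_stop`` the count
    starts at the residue after the nearest upstream stop instead of at the
    peptide itself.
    """
    if scanner is None:
        scanner = OccurrenceScanner(sample, genes or [])
    translation = scanner.frame_translation(occurrence.chrom, occurrence.frame)
    plen = (occurrence.span[1] - occurrence.span[0] + 1) // 3
    end = occurrence.aa_index + plen  # first index past the peptide

    stop_idx = translation.find("*", end)
    lower_bound = stop_idx == -1
    downstream = (len(translation) if lower_bound else stop_idx) - end

    start = occurrence.aa_index
    if from_upstream_stop:
        up_stop = translation.rfind("*", 0, occurrence.aa_index)
        start = up_stop + 1  # -1 -> 0: sequence edge
        lower_bound = lower_bound or up_stop == -1
    return plen + (occurrence.aa_index - start) + downstream, lower_bound


# ---------------------------------------------------------------------------
# funnel driver + report


@dataclass
class FunnelResult:
    annotations: list[NaPtpAnnotation]
    counts: dict[str, int] = field(default_factory=dict)


def verify_candidates(
    candidates: list[CandidatePeptide],
    sample: SampleGenome,
    genes: list[GeneModel],
    proteome: str | os.PathLike | dict[str, str] | None = None,
    il_equivalent_proteome: bool = True,
    il_equivalent_genome: bool = False,
    no_cut_before_p: bool = False,
    minlen_from_upstream_stop: bool = False,
) -> FunnelResult:
    """Run the full exclusion funnel over a candidate list.

    Every input candidate ends up in exactly one terminal category:
    known_protein, absent, multiple_occurrence, exonic or unique_nonexon.
    """
    annotations: list[NaPtpAnnotation] = []
    if proteome is not None:
        retained, excluded = exclude_known(candidates, proteome, il_equivalent_proteome)
        for cand, reason in excluded:
            annotations.append(
                NaPtpAnnotation(cand.sequence, reason, sample_id=cand.sample_id)
            )
    else:
        retained = list(candidates)

    scanner = OccurrenceScanner(sample, genes, il_equivalent=il_equivalent_genome)
    for cand in retained:
        occs = scanner.locate(cand.sequence)
        verdict = classify(cand, occs)
        if verdict == "unique_nonexon":
            ann = annotate(
                occs[0],
                genes,
                sample,
                scanner=scanner,
                no_cut_before_p=no_cut_before_p,
                minlen_from_upstream_stop=minlen_from_upstream_stop,
                candidate=cand,
            )
            # re-translation consistency check on every run
            assert (
                fold_il(ann.peptide) == fold_il(cand.sequence)
                if scanner.il_equivalent
                else ann.peptide == cand.sequence
            ), f"span re-translation mismatch for {cand.sequence}"
            ann.sample_id = cand.sample_id
            annotations.append(ann)
        else:
            occ = occs[0] if len(occs) == 1 else None
            annotations.append(
                NaPtpAnnotation(
                    cand.sequence, verdict, occurrence=occ, sample_id=cand.sample_id
                )
            )

    counts: dict[str, int] = {
        "candidates": len(candidates),
        "known_protein": 0,
        "absent": 0,
        "multiple_occurrence": 0,
        "exonic": 0,
        "unique_nonexon": 0,
    }
    for ann in annotations:
        counts[ann.verdict] += 1
    return FunnelResult(annotations, counts)


def report(annotations: list[NaPtpAnnotation], path: str | os.PathLike) -> pd.DataFrame:
    """One TSV row per candidate: verdict, reference locus, orientation,
    flanked notation, minimal length and tryptic status."""
    rows = []
    for a in annotations:
        occ = a.occurrence
        rows.append(
            {
                "peptide": a.peptide,
                "verdict": a.verdict,
                "chrom": occ.chrom if occ else "",
                "ref_start": "" if not occ or occ.ref_span[0] is GAP else occ.ref_span[0],
                "ref_end": "" if not occ or occ.ref_span[1] is GAP else occ.ref_span[1],
                "strand": occ.strand if occ else "",
                "frame": occ.frame if occ else "",
                "gene": a.gene or "",
                "orientation": a.orientation or "",
                "flanked": a.flanked if a.verdict == "unique_nonexon" else "",
                "nterm_tryptic": "" if a.nterm_tryptic is None else int(a.nterm_tryptic),
                "cterm_tryptic": "" if a.cterm_tryptic is None else int(a.cterm_tryptic),
                "minimal_length": a.minimal_length if a.minimal_length is not None else "",
                "minlen_lower_bound": int(a.minimal_length_lower_bound),
                "sample_id": a.sample_id or "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "peptide", "verdict", "chrom", "ref_start", "ref_end", "strand",
            "frame", "gene", "orientation", "flanked", "nterm_tryptic",
            "cterm_tryptic", "minimal_length", "minlen_lower_bound", "sample_id",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
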