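"""Non-exon region extraction, six-frame translation into stop-delimited
peptide segments, redundancy reduction and FASTA output of the resulting
six-frame proteomics database (SFDB).

Frame labels: f0/f1/f2 read the forward strand at offsets 0/1/2 from the
region start; r0/r1/r2 read the reverse complement at offsets 0/1/2 from
its start (i.e. from the region end on the genome).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from Bio.Data import CodonTable

from .reference_io import (
    GeneModel,
    GenomeSequence,
    merge_intervals,
    reverse_complement,
    subtract_intervals,
)
from .sample_genome import SampleGenome

__all__ = [
    "FRAME_LABELS",
    "FORWARD_FRAMES",
    "REVERSE_FRAMES",
    "STOP_CODONS",
    "NonExonRegion",
    "TranslatedSegment",
    "Provenance",
    "SfdbRecord",
    "translate_codon",
    "translate_frame",
    "extract_nonexon_regions",
    "translate_six_frames",
    "build_sfdb",
    "write_sfdb_fasta",
    "read_sfdb_fasta",
]

FORWARD_FRAMES = ("f0", "f1", "f2")
REVERSE_FRAMES = ("r0", "r1", "r2")
FRAME_LABELS = FORWARD_FRAMES + REVERSE_FRAMES

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
STOP_CODONS = frozenset(_TABLE.stop_codons)  # {TAA, TAG, TGA}
_CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in STOP_CODONS:
    _CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str:
    """Standard-table translation; any codon containing N yields X."""
    aa = _CODON_TO_AA.get(codon)
    if aa is None:
        return "X"  # contains N (or other masked base)
    return aa


def translate_frame(seq: str, offset: int) -> str:
    """Translate one frame of ``seq`` ('*' for stops, 'X' for N codons).

    Trailing bases short of a full codon are dropped.
    """
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(offset, len(seq) - 2, 3)
    )


@dataclass(frozen=True)
class NonExonRegion:
    """Intronic gap of one gene, in sample-genome coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    index: int  # ordinal within the gene


@dataclass(frozen=True)
class TranslatedSegment:
    """Maximal stop-free peptide run in one frame of one region."""

    peptide: str
    frame: str
    region: NonExonRegion | None
    aa_offset: int
    span: tuple[int, int]  # genomic span of first..last codon, 1-based incl.
    start_truncated: bool  # no upstream stop (segment starts at region edge)
    end_truncated: bool  # no downstream stop


@dataclass(frozen=True)
class Provenance:
    gene_id: str
    chrom: str
    span: tuple[int, int]
    frame: str
    boundary_truncated: bool


@dataclass
class SfdbRecord:
    peptide: str
    provenance: list[Provenance]


def extract_nonexon_regions(genes: list[GeneModel]) -> list[NonExonRegion]:
    """Per gene: gene span minus the union of all exons of all transcripts.

    Zero-length gaps are dropped (guaranteed by interval arithmetic); genes
    fully covered by exons yield nothing.
    """
    out: list[NonExonRegion] = []
    for gene in genes:
        gaps = subtract_intervals(gene.span, gene.exon_union())
        for i, (start, end) in enumerate(gaps):
            out.append(NonExonRegion(gene.gene_id, gene.chrom, start, end, i))
    return out


def _segments_of_frame(
    translation: str,
    frame: str,
    region: NonExonRegion | None,
    region_start: int,
    region_end: int,
) -> list[TranslatedSegment]:
    offset = int(frame[1])
    forward = frame[0] == "f"
    n_codons = len(translation)
    segments: list[TranslatedSegment] = []
    i = 0
    while i < n_codons:
        if translation[i] == "*":
            i += 1
            continue
        j = i
        while j < n_codons and translation[j] != "*":
            j += 1
        # codons i..j-1 form a maximal stop-free run
        if forward:
            span = (
                region_start + offset + 3 * i,
                region_start + offset + 3 * (j - 1) + 2,
            )
        else:
            span = (
                region_end - offset - 3 * (j - 1) - 2,
                region_end - offset - 3 * i,
            )
        segments.append(
            TranslatedSegment(
                peptide=translation[i:j],
                frame=frame,
                region=region,
                aa_offset=i,
                span=span,
                start_truncated=(i == 0),
                end_truncated=(j == n_codons),
            )
        )
        i = j
    return segments


def translate_six_frames(
    region_seq: str, region: NonExonRegion | None = None
) -> dict[str, list[TranslatedSegment]]:
    """Stop-delimited segments of all six reading frames of a region.

    Stop codons terminate segments and are never emitted; codons containing
    N translate to X. When ``region`` is given, segment spans are genomic
    (sample coordinates); otherwise they are relative to the sequence
    (start = 1).
    """
    start = region.start if region else 1
    end = region.end if region else len(region_seq)
    rc = reverse_complement(region_seq)
    out: dict[str, list[TranslatedSegment]] = {}
    for frame in FRAME_LABELS:
        seq = region_seq if frame[0] == "f" else rc
        translation = translate_frame(seq, int(frame[1]))
        out[frame] = _segments_of_frame(translation, frame, region, start, end)
    return out


def build_sfdb(
    regions: list[NonExonRegion],
    sample: SampleGenome,
    min_len: int = 7,
    frame_partition: bool = False,
) -> dict[str, list[SfdbRecord]] | list[SfdbRecord]:
    """Translate every region, drop segments shorter than ``min_len`` and
    collapse exact-duplicate peptides, accumulating provenance.

    With ``frame_partition`` the deduplication and output are per frame
    label (each frame searched separately downstream); otherwise one merged
    list is returned. I and L are kept distinct here; any I/L folding
    happens only at match time.
    """
    buckets: dict[str, dict[str, SfdbRecord]] = {f: {} for f in FRAME_LABELS}
    for region in regions:
        seq = sample.genome.fetch(region.chrom, region.start, region.end)
        for frame, segments in translate_six_frames(seq, region).items():
            for seg in segments:
                if len(seg.peptide) < min_len:
                    continue
                prov = Provenance(
                    region.gene_id,
                    region.chrom,
                    seg.span,
                    frame,
                    seg.start_truncated or seg.end_truncated,
                )
                rec = buckets[frame].get(seg.peptide)
                if rec is None:
                    buckets[frame][seg.peptide] = SfdbRecord(seg.peptide, [prov])
                else:
                    rec.provenance.append(prov)
    if frame_partition:
        return {f: list(buckets[f].values()) for f in FRAME_LABELS}
    merged: dict[str, SfdbRecord] = {}
    for frame in FRAME_LABELS:
        for pep, rec in buckets[frame].items():
            if pep in merged:
                merged[pep].provenance.extend(rec.provenance)
            else:
                merged[pep] = SfdbRecord(pep, list(rec.provenance))
    return list(merged.values())


def write_sfdb_fasta(
    sfdb: list[SfdbRecord],
    path: str | os.PathLike,
    sidecar_path: str | os.PathLike | None = None,
    width: int = 60,
) -> None:
    """One FASTA record per unique peptide.

    Header grammar: ``>NAPTP|<gene>|<chrom>:<start>-<end>|<frame>|<n_extra_loci>``
    using the first provenance entry; the full provenance goes to a sidecar
    TSV (default: <path>.provenance.tsv).
    """
    if sidecar_path is None:
        sidecar_path = str(path) + ".provenance.tsv"
    with open(path, "w") as fa, open(sidecar_path, "w") as tsv:
        tsv.write("peptide\tgene\tchrom\tstart\tend\tframe\tboundary_truncated\n")
        for rec in sfdb:
            p = rec.provenance[0]
            fa.write(
                f">NAPTP|{p.gene_id}|{p.chrom}:{p.span[0]}-{p.span[1]}|{p.frame}"
                f"|{len(rec.provenance) - 1}\n"
            )
            for i in range(0, len(rec.peptide), width):
                fa.write(rec.peptide[i : i + width] + "\n")
            for p in rec.provenance:
                tsv.write(
                    f"{rec.peptide}\t{p.gene_id}\t{p.chrom}\t{p.span[0]}\t{p.span[1]}"
                    f"\t{p.frame}\t{int(p.boundary_truncated)}\n"
                )


def read_sfdb_fasta(path: str | os.PathLike) -> list[SfdbRecord]:
    """Round-trip reader: peptides plus first-locus provenance from headers."""
    records: list[SfdbRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        _, gene, locus, frame, n_extra = header.split("|")
        chrom, span = locus.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        records.append(
            SfdbRecord(
                "".join(chunks),
                [Provenance(gene, chrom, (start, end), frame, False)],
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return records
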