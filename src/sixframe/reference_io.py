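"""Readers for the three standard inputs (genome FASTA, GTF gene models,
variant tables) plus interval and strand utilities.

Coordinate convention: 1-based inclusive everywhere, matching GTF.
"""

from __future__ import annotations

import io
import os
import re
from bisect import bisect_right
from dataclasses import dataclass, field

from Bio import SeqIO
from gffutils.feature import feature_from_line

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "GeneModel",
    "VariantRecord",
    "read_genome",
    "write_genome",
    "read_annotation",
    "read_variants",
    "reverse_complement",
    "merge_intervals",
    "intervals_overlap",
    "subtract_intervals",
]

DNA_ALPHABET = frozenset("ACGTN")
# IUPAC ambiguity codes other than N; replaced by N only under lenient reading
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeSequence:
    """Chromosome id -> uppercase nucleotide string over {A,C,G,T,N}."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, seq in self.records.items():
            if not seq:
                raise InputError(f"empty sequence for chrom {chrom!r}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise InputError(
                    f"chrom {chrom!r} contains characters outside ACGTN: {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def length(self, chrom: str) -> int:
        return len(self.records[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive [start, end]."""
        return self.records[chrom][start - 1 : end]


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(
                f"transcript {self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise InputError(
                    f"transcript {self.transcript_id}: exon start {start} > end {end}"
                )
            if start <= prev_end:
                raise InputError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping at {start}"
                )
            prev_end = end


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for t in self.transcripts for e in t.exons]
        ends = [e[1] for t in self.transcripts for e in t.exons]
        return (min(starts), max(ends))

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of every exon of every transcript."""
        return merge_intervals(
            [e for t in self.transcripts for e in t.exons]
        )


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str  # SNP | INS | DEL
    p_value: float

    def __post_init__(self) -> None:
        if self.kind == "SNP" and not (len(self.ref) == 1 == len(self.alt)):
            raise InputError(f"SNP at {self.chrom}:{self.pos} must be 1bp ref and alt")
        if self.kind == "INS" and not len(self.alt) > len(self.ref):
            raise InputError(f"INS at {self.chrom}:{self.pos} must have |alt|>|ref|")
        if self.kind == "DEL" and not len(self.ref) > len(self.alt):
            raise InputError(f"DEL at {self.chrom}:{self.pos} must have |ref|>|alt|")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval covered by the ref allele (1-based inclusive)."""
        return (self.pos, self.pos + len(self.ref) - 1)


def _classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    raise InputError(f"cannot classify equal-length multi-base alleles {ref}>{alt}")


# ---------------------------------------------------------------------------
# strand / interval utilities


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}. Involution; N maps to N."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InputError(f"reverse_complement: invalid characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent 1-based inclusive intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def intervals_overlap(merged: list[tuple[int, int]], start: int, end: int) -> bool:
    """Does [start, end] intersect any interval of a merged, sorted list?"""
    i = bisect_right(merged, (start, float("inf"))) - 1
    if i >= 0 and merged[i][1] >= start:
        return True
    return i + 1 < len(merged) and merged[i + 1][0] <= end


def subtract_intervals(
    span: tuple[int, int], merged: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Gaps of `span` not covered by the merged interval list."""
    gaps: list[tuple[int, int]] = []
    cursor = span[0]
    for start, end in merged:
        if end < span[0] or start > span[1]:
            continue
        if start > cursor:
            gaps.append((cursor, start - 1))
        cursor = max(cursor, end + 1)
    if cursor <= span[1]:
        gaps.append((cursor, span[1]))
    return gaps


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | os.PathLike, lenient: bool = False) -> GenomeSequence:
    """Load a FASTA into a GenomeSequence, uppercasing all bases.

    Ambiguity codes other than N raise unless ``lenient`` is set, in which
    case they become N. Duplicate record ids are a hard error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputError(f"duplicate chrom id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            amb = bad & _IUPAC_AMBIGUOUS
            if amb and lenient and not (bad - _IUPAC_AMBIGUOUS):
                seq = re.sub(f"[{''.join(sorted(amb))}]", "N", seq)
            else:
                offender = min(bad)
                pos = seq.index(offender) + 1
                raise InputError(
                    f"chrom {rec.id!r}: invalid character {offender!r} at position {pos}"
                )
        records[rec.id] = seq
    return GenomeSequence(records)


def write_genome(genome: GenomeSequence, path: str | os.PathLike, width: int = 60) -> None:
    """Write FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for chrom, seq in genome.records.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Parse exon features of an ENSEMBL-style GTF into GeneModels.

    Features other than ``exon`` are ignored. Native 1-based inclusive
    coordinates are kept unchanged.
    """
    # gene_id -> transcript_id -> (chrom, strand, [spans])
    genes: dict[str, dict[str, tuple[str, str, list[tuple[int, int]]]]] = {}
    gene_strand: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line.rstrip("\n"))
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise InputError(f"{path}:{lineno}: unparsable GTF line ({exc})") from exc
            if feat.featuretype != "exon":
                continue
            if feat.strand not in ("+", "-"):
                raise InputError(f"{path}:{lineno}: exon with strand {feat.strand!r}")
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise InputError(
                    f"{path}:{lineno}: exon missing {exc.args[0]} attribute"
                ) from exc
            if gene_id in gene_strand and gene_strand[gene_id] != feat.strand:
                raise InputError(
                    f"{path}:{lineno}: strand conflict within gene {gene_id!r}"
                )
            gene_strand[gene_id] = feat.strand
            tx = genes.setdefault(gene_id, {}).setdefault(
                transcript_id, (feat.seqid, feat.strand, [])
            )
            if tx[0] != feat.seqid:
                raise InputError(
                    f"{path}:{lineno}: transcript {transcript_id!r} spans chroms"
                )
            tx[2].append((feat.start, feat.end))

    models: list[GeneModel] = []
    for gene_id, txs in genes.items():
        transcripts = tuple(
            TranscriptModel(tid, chrom, strand, tuple(sorted(spans)))
            for tid, (chrom, strand, spans) in txs.items()
        )
        chroms = {t.chrom for t in transcripts}
        if len(chroms) != 1:
            raise InputError(f"gene {gene_id!r} has transcripts on several chroms")
        models.append(
            GeneModel(gene_id, transcripts[0].chrom, gene_strand[gene_id], transcripts)
        )
    return models


# ---------------------------------------------------------------------------
# variants (VCF 4.x or VarScan2 tabular, auto-detected)


def read_variants(
    path: str | os.PathLike,
    p_threshold: float = 0.01,
    pval_info_key: str = "PVAL",
    qual_as_pvalue: bool = False,
    permissive_missing_p: bool = False,
) -> list[VariantRecord]:
    """Read variants, keeping only records with p_value < ``p_threshold``.

    The format is auto-detected from the header: ``##fileformat=VCF`` /
    ``#CHROM`` mark a VCF, anything else is treated as VarScan2-style TSV.
    Multi-allelic VCF records are split per alt. Output is sorted by
    (chrom, pos).
    """
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##fileformat=VCF") or head.startswith("#CHROM"):
        out = _read_vcf(path, pval_info_key, qual_as_pvalue, permissive_missing_p)
    else:
        out = _read_varscan(path, permissive_missing_p)
    out = [v for v in out if v.p_value < p_threshold]
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def _read_vcf(path, pval_info_key, qual_as_pvalue, permissive_missing_p):
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if pval_info_key in rec.info:
                raw = rec.info[pval_info_key]
                pval = float(raw[0] if isinstance(raw, tuple) else raw)
            elif qual_as_pvalue and rec.qual is not None:
                pval = 10 ** (-rec.qual / 10)
            elif permissive_missing_p:
                pval = 0.0  # always passes the threshold
            else:
                raise InputError(
                    f"{path}: record {rec.chrom}:{rec.pos} has no {pval_info_key!r} "
                    "INFO field (use permissive mode or qual_as_pvalue)"
                )
            for alt in rec.alts or ():
                ref, alt = rec.ref.upper(), alt.upper()
                if ref == alt:
                    continue
                out.append(
                    VariantRecord(
                        rec.chrom, rec.pos, ref, alt, _classify_alleles(ref, alt), pval
                    )
                )
    return out


_PVAL_COLUMN_PREFERENCE = ("variant_p_value", "somatic_p_value", "pvalue", "p_value")


def _read_varscan(path, permissive_missing_p):
    out: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        try:
            i_chrom = cols.get("chrom", cols.get("chromosome"))
            i_pos = cols["position"]
            i_ref = cols["ref"]
            i_var = cols.get("var", cols.get("varallele", cols.get("alt")))
        except KeyError as exc:
            raise InputError(f"{path}: not a VarScan2 table, missing column {exc}") from exc
        if i_chrom is None or i_var is None:
            raise InputError(f"{path}: not a VarScan2 table (no chrom/var column)")
        i_pval = next(
            (cols[c] for c in _PVAL_COLUMN_PREFERENCE if c in cols), None
        )
        if i_pval is None and not permissive_missing_p:
            raise InputError(f"{path}: no p-value column in VarScan2 header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                chrom = fields[i_chrom]
                pos = int(fields[i_pos])
                ref = fields[i_ref].upper()
                var = fields[i_var].upper()
                pval = float(fields[i_pval]) if i_pval is not None else 0.0
            except (IndexError, ValueError) as exc:
                raise InputError(f"{path}:{lineno}: unparsable record ({exc})") from exc
            # VarScan indel notation: +SEQ insertion, -SEQ deletion
            if var.startswith("+"):
                ref_a, alt_a = ref, ref + var[1:]
            elif var.startswith("-"):
                ref_a, alt_a = ref + var[1:], ref
            else:
                ref_a, alt_a = ref, var
            if ref_a == alt_a:
                continue
            out.append(
                VariantRecord(
                    chrom, pos, ref_a, alt_a, _classify_alleles(ref_a, alt_a), pval
                )
            )
    return out
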