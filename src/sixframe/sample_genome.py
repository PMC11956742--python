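"""Incorporate filtered variants into the reference genome and keep a
bidirectional coordinate map between sample and reference positions."""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field

from .reference_io import GenomeSequence, InputError, VariantRecord

__all__ = ["AlignmentBlock", "CoordinateMap", "SampleGenome", "apply_variants",
           "lift_to_reference", "write_liftover_table", "GAP"]

#: sentinel returned for sample positions that fall inside inserted sequence
GAP = None


@dataclass(frozen=True)
class AlignmentBlock:
    """One piece of the sample<->reference alignment.

    kind 'M': length bases map 1:1 starting at (sample_start, ref_start).
    kind 'I': sample-only (inserted) bases; ref_start is the nearest
              reference position at or before the insertion (0 if none).
    kind 'D': reference-only (deleted) bases; sample_start is the nearest
              sample position at or before the deletion (0 if none).
    """

    kind: str
    sample_start: int
    ref_start: int
    length: int


@dataclass
class CoordinateMap:
    """Per-chrom piecewise monotone mapping sample-position <-> reference."""

    blocks: dict[str, list[AlignmentBlock]] = field(default_factory=dict)

    def to_reference(self, chrom: str, pos: int) -> tuple[int | None, int]:
        """Map a sample position to reference.

        Returns (ref_pos, ref_pos) for mapped positions and
        (GAP, flanking_ref_pos) inside insertions.
        """
        blocks = self._chrom_blocks(chrom)
        candidates = [b for b in blocks if b.kind in ("M", "I")]
        i = bisect_right([b.sample_start for b in candidates], pos) - 1
        if i < 0:
            raise InputError(f"position {pos} before start of {chrom}")
        b = candidates[i]
        offset = pos - b.sample_start
        if offset >= b.length:
            raise InputError(f"position {pos} beyond end of sample chrom {chrom}")
        if b.kind == "I":
            return GAP, b.ref_start
        return b.ref_start + offset, b.ref_start + offset

    def to_sample(self, chrom: str, pos: int) -> tuple[int | None, int]:
        """Map a reference position to sample; (GAP, flank) inside deletions."""
        blocks = self._chrom_blocks(chrom)
        candidates = [b for b in blocks if b.kind in ("M", "D")]
        i = bisect_right([b.ref_start for b in candidates], pos) - 1
        if i < 0:
            raise InputError(f"position {pos} before start of {chrom}")
        b = candidates[i]
        offset = pos - b.ref_start
        if offset >= b.length:
            raise InputError(f"position {pos} beyond end of reference chrom {chrom}")
        if b.kind == "D":
            return GAP, b.sample_start
        return b.sample_start + offset, b.sample_start + offset

    def _chrom_blocks(self, chrom: str) -> list[AlignmentBlock]:
        try:
            return self.blocks[chrom]
        except KeyError:
            raise InputError(f"unknown chrom {chrom!r} in coordinate map") from None


@dataclass
class SampleGenome:
    genome: GenomeSequence
    map: CoordinateMap
    applied: list[VariantRecord]
    skipped: list[tuple[VariantRecord, str]]


def lift_to_reference(cmap: CoordinateMap, chrom: str, pos: int) -> tuple[int | None, int]:
    """Map a sample position to reference coordinates (see CoordinateMap)."""
    return cmap.to_reference(chrom, pos)


def _select_non_overlapping(variants: list[VariantRecord]) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Greedy significance-first selection of pairwise non-overlapping variants.

    Candidates are considered by ascending (p_value, input order); a variant
    overlapping an already-accepted one on its reference span is skipped.
    """
    order = sorted(range(len(variants)), key=lambda i: (variants[i].p_value, i))
    accepted_idx: list[int] = []
    accepted_spans: dict[str, list[tuple[int, int]]] = {}
    skipped: list[tuple[VariantRecord, str]] = []
    for i in order:
        v = variants[i]
        span = v.ref_span
        spans = accepted_spans.setdefault(v.chrom, [])
        if any(span[0] <= e and s <= span[1] for s, e in spans):
            skipped.append((v, "overlap"))
            continue
        spans.append(span)
        accepted_idx.append(i)
    accepted_idx.sort()
    return [variants[i] for i in accepted_idx], skipped


def apply_variants(genome: GenomeSequence, variants: list[VariantRecord]) -> SampleGenome:
    """Edit the reference with the variant set, producing the sample genome.

    Input must be sorted by (chrom, pos). Ref-allele mismatches are skipped
    with reason ``ref_mismatch``; of overlapping variants the one with the
    smallest p_value wins, the rest are skipped with reason ``overlap``.
    Edits are applied right-to-left per chrom so indels never shift the
    positions of edits still to come.
    """
    key = [(v.chrom, v.pos) for v in variants]
    if key != sorted(key):
        raise InputError("variant list is not sorted by (chrom, pos)")

    skipped: list[tuple[VariantRecord, str]] = []
    checked: list[VariantRecord] = []
    for v in variants:
        if v.chrom not in genome:
            skipped.append((v, "unknown_chrom"))
            continue
        start, end = v.ref_span
        if end > genome.length(v.chrom) or genome.fetch(v.chrom, start, end) != v.ref:
            skipped.append((v, "ref_mismatch"))
            continue
        checked.append(v)

    accepted, overlap_skipped = _select_non_overlapping(checked)
    skipped.extend(overlap_skipped)

    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in accepted:
        by_chrom.setdefault(v.chrom, []).append(v)

    edited: dict[str, str] = {}
    cmap = CoordinateMap()
    for chrom, refseq in genome.records.items():
        todo = by_chrom.get(chrom, [])
        seq = refseq
        for v in reversed(todo):  # right-to-left
            start, end = v.ref_span
            seq = seq[: start - 1] + v.alt + seq[end:]
        edited[chrom] = seq
        cmap.blocks[chrom] = _build_blocks(len(refseq), todo)

    return SampleGenome(GenomeSequence(edited), cmap, accepted, skipped)


def _build_blocks(ref_len: int, variants: list[VariantRecord]) -> list[AlignmentBlock]:
    """Walk accepted variants left-to-right, emitting alignment blocks.

    Per variant the common length min(|ref|,|alt|) is aligned 1:1; surplus
    alt becomes an I block, surplus ref a D block.
    """
    blocks: list[AlignmentBlock] = []
    ref_cursor = 1  # next unconsumed reference position
    sample_cursor = 1
    for v in variants:
        if v.pos > ref_cursor:
            n = v.pos - ref_cursor
            blocks.append(AlignmentBlock("M", sample_cursor, ref_cursor, n))
            sample_cursor += n
            ref_cursor += n
        common = min(len(v.ref), len(v.alt))
        if common:
            blocks.append(AlignmentBlock("M", sample_cursor, ref_cursor, common))
            sample_cursor += common
            ref_cursor += common
        if len(v.alt) > len(v.ref):
            blocks.append(
                AlignmentBlock("I", sample_cursor, ref_cursor - 1, len(v.alt) - common)
            )
            sample_cursor += len(v.alt) - common
        elif len(v.ref) > len(v.alt):
            blocks.append(
                AlignmentBlock("D", sample_cursor - 1, ref_cursor, len(v.ref) - common)
            )
            ref_cursor += len(v.ref) - common
    if ref_cursor <= ref_len:
        blocks.append(AlignmentBlock("M", sample_cursor, ref_cursor, ref_len - ref_cursor + 1))
    return blocks


def write_liftover_table(cmap: CoordinateMap, path: str | os.PathLike) -> None:
    """Sidecar TSV: chrom, sample_start, ref_start, length, kind."""
    with open(path, "w") as fh:
        fh.write("chrom\tsample_start\tref_start\tlength\tkind\n")
        for chrom, blocks in cmap.blocks.items():
            for b in blocks:
                fh.write(f"{chrom}\t{b.sample_start}\t{b.ref_start}\t{b.length}\t{b.kind}\n")
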