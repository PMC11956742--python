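"""Deterministic generator of synthetic genomes, annotations, variants,
proteomes and candidate peptide lists with a ground-truth manifest.

Every pipeline stage is testable against these fixtures without any
download. All generators are bit-reproducible for a fixed seed; peptide
back-translation uses a deterministic codon choice (lexicographic, with
collision re-roll) so fixtures are stable across platforms.

Frame labels recorded in the manifest are chrom-relative, matching the
convention of peptide_verify.OccurrenceScanner.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .reference_io import (
    GeneModel,
    GenomeSequence,
    InputError,
    TranscriptModel,
    VariantRecord,
    reverse_complement,
)
from .sfdb_builder import STOP_CODONS, _TABLE

__all__ = [
    "PlantedPeptide",
    "Fixture",
    "make_genome",
    "plant_gene",
    "plant_peptide",
    "make_decoys",
    "make_variants",
    "naive_apply",
    "count_genomic_occurrences",
    "build_scenario",
    "write_scenario",
    "SCENARIOS",
]

_BASES = "ACGT"

# aa -> lexicographically sorted codon list (standard table, stops excluded)
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)


def back_translate(peptide: str, attempt: int = 0) -> str:
    """Deterministic codon choice: attempt 0 takes the lexicographically
    first codon of each residue; higher attempts rotate the choice."""
    codons = []
    for aa in peptide:
        options = _CODONS_FOR[aa]
        codons.append(options[attempt % len(options)])
    return "".join(codons)


# ---------------------------------------------------------------------------
# generators


def make_genome(
    n_chrom: int, chrom_length: int, gc_fraction: float = 0.5, seed: int = 0
) -> GenomeSequence:
    """Random genome with the requested GC content; chroms named chr1..chrN."""
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    records = {}
    for i in range(n_chrom):
        bases = rng.choice(list(_BASES), size=chrom_length, p=[p_at, p_gc, p_gc, p_at])
        records[f"chr{i + 1}"] = "".join(bases)
    return GenomeSequence(records)


def plant_gene(
    genome: GenomeSequence,
    chrom: str,
    gene_id: str,
    exon_layout: dict[str, list[tuple[int, int]]],
    strand: str,
    source: str = "synthfix",
) -> tuple[GeneModel, str]:
    """Build a GeneModel from an explicit per-transcript exon layout and the
    matching GTF text (gene/transcript/exon features). The genome sequence
    itself is untouched."""
    transcripts = tuple(
        TranscriptModel(tid, chrom, strand, tuple(sorted(exons)))
        for tid, exons in exon_layout.items()
    )
    gene = GeneModel(gene_id, chrom, strand, transcripts)
    span = gene.span
    if span[1] > genome.length(chrom):
        raise InputError(f"gene {gene_id} extends past end of {chrom}")
    lines = [
        f'{chrom}\t{source}\tgene\t{span[0]}\t{span[1]}\t.\t{strand}\t.\tgene_id "{gene_id}";'
    ]
    for t in transcripts:
        t_span = (t.exons[0][0], t.exons[-1][1])
        lines.append(
            f'{chrom}\t{source}\ttranscript\t{t_span[0]}\t{t_span[1]}\t.\t{strand}\t.\t'
            f'gene_id "{gene_id}"; transcript_id "{t.transcript_id}";'
        )
        for start, end in t.exons:
            lines.append(
                f'{chrom}\t{source}\texon\t{start}\t{end}\t.\t{strand}\t.\t'
                f'gene_id "{gene_id}"; transcript_id "{t.transcript_id}";'
            )
    return gene, "\n".join(lines) + "\n"


@dataclass
class PlantedPeptide:
    sequence: str
    verdict: str
    gene: str | None
    orientation: str | None
    frame: str | None
    chrom: str | None
    span: tuple[int, int] | None  # reference coordinates of the peptide codons
    flank_up: str | None
    flank_down: str | None
    minimal_length: int | None

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["span"] = list(self.span) if self.span else None
        return d


def _write_into(chars: list[str], start: int, segment: str) -> None:
    chars[start - 1 : start - 1 + len(segment)] = list(segment)


def plant_peptide(
    chars_by_chrom: dict[str, list[str]],
    chrom: str,
    region: tuple[int, int],
    translation_strand: str,
    frame_offset: int,
    peptide: str,
    pad_to_stop: int,
    flank_up: str = "R",
    flank_down: str = "A",
    attempt: int = 0,
    margin: int = 6,
) -> dict:
    """Write a stop-delimited construct encoding ``peptide`` into ``region``.

    Construct layout in translation direction:
    stop | flank_up codon | peptide codons | flank_down + filler codons
    (pad_to_stop residues after the peptide) | stop.
    The ground-truth minimal product length is |peptide| + pad_to_stop.
    Antisense constructs are written as their reverse complement.

    Returns placement info: peptide genomic span, chrom-relative frame
    label and strand.
    """
    if pad_to_stop < 1:
        raise InputError("pad_to_stop must be >= 1")
    fillers = "G" * (pad_to_stop - 1)
    body = back_translate(flank_up + peptide + flank_down + fillers, attempt)
    construct = "TAA" + body + "TAA"
    if any(
        construct[i : i + 3] in STOP_CODONS for i in range(3, len(construct) - 3, 3)
    ):  # codons of residues can never be stops; guard anyway
        raise InputError("internal stop in back-translated construct")

    chars = chars_by_chrom[chrom]
    L = len(chars)
    rstart, rend = region
    n = len(construct)
    p = len(peptide)
    if translation_strand == "+":
        g = rstart + margin
        g += (frame_offset + 1 - g) % 3  # peptide codon starts at g+6
        if g + n - 1 > rend - margin:
            raise InputError(f"construct does not fit in region {region}")
        _write_into(chars, g, construct)
        pep_span = (g + 6, g + 6 + 3 * p - 1)
        frame = f"f{(g + 5) % 3}"
    elif translation_strand == "-":
        b = rend - margin
        b -= (b - (L + 6 - frame_offset)) % 3  # (L - b + 6) % 3 == frame_offset
        a = b - n + 1
        if a < rstart + margin:
            raise InputError(f"construct does not fit in region {region}")
        _write_into(chars, a, reverse_complement(construct))
        pep_span = (b - 6 - 3 * p + 1, b - 6)
        frame = f"r{(L - b + 6) % 3}"
    else:
        raise InputError(f"bad strand {translation_strand!r}")
    return {"span": pep_span, "frame": frame, "strand": translation_strand}


def make_decoys(
    proteome_size: int,
    include: dict[str, str] | None = None,
    seed: int = 0,
    length: int = 240,
) -> dict[str, str]:
    """Random decoy proteome; peptides in ``include`` (name -> sequence) are
    embedded mid-sequence so their verdict is known_protein."""
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    proteome: dict[str, str] = {}
    for i in range(proteome_size):
        proteome[f"decoy{i + 1}"] = "".join(rng.choice(aas, size=length))
    for j, (name, pep) in enumerate(sorted((include or {}).items())):
        host = "".join(rng.choice(aas, size=length))
        mid = length // 2
        proteome[f"known_{name}"] = host[:mid] + pep + host[mid:]
    return proteome


def naive_apply(genome: GenomeSequence, variants: list[VariantRecord]) -> GenomeSequence:
    """Independent reference editor (oracle for sample_genome): walk each
    chrom left to right, splicing alt alleles in place of ref alleles."""
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out = {}
    for chrom, seq in genome.records.items():
        parts = []
        cursor = 0  # 0-based index of next unconsumed base
        for v in sorted(by_chrom.get(chrom, []), key=lambda v: v.pos):
            parts.append(seq[cursor : v.pos - 1])
            parts.append(v.alt)
            cursor = v.pos - 1 + len(v.ref)
        parts.append(seq[cursor:])
        out[chrom] = "".join(parts)
    return GenomeSequence(out)


def make_variants(
    genome: GenomeSequence,
    n_snp: int,
    n_indel: int,
    seed: int = 0,
    allowed_spans: dict[str, tuple[int, int]] | None = None,
    n_above_threshold: int = 0,
    p_threshold: float = 0.01,
) -> tuple[list[VariantRecord], GenomeSequence]:
    """Random non-overlapping variants plus the expected edited genome.

    Variants are restricted to ``allowed_spans`` (per-chrom interval) so
    planted constructs are never disturbed. ``n_above_threshold`` extra SNPs
    get p-values >= p_threshold and must be filtered out by the reader; the
    expected genome is computed (by the independent naive editor) from the
    passing variants only.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(allowed_spans) if allowed_spans else sorted(genome.records)
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    variants: list[VariantRecord] = []

    def place(span_len: int) -> tuple[str, int] | None:
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            lo, hi = (
                allowed_spans[chrom]
                if allowed_spans
                else (1, genome.length(chrom) - span_len)
            )
            pos = int(rng.integers(lo, hi - span_len + 1))
            if all(pos + span_len < s or e < pos - 1 for s, e in taken[chrom]):
                taken[chrom].append((pos, pos + span_len))
                return chrom, pos
        return None

    def rand_p() -> float:
        return float(rng.uniform(1e-6, p_threshold * 0.9))

    for _ in range(n_snp):
        loc = place(1)
        if loc is None:
            break
        chrom, pos = loc
        ref = genome.fetch(chrom, pos, pos)
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
        variants.append(VariantRecord(chrom, pos, ref, alt, "SNP", rand_p()))
    for _ in range(n_indel):
        loc = place(4)
        if loc is None:
            break
        chrom, pos = loc
        if rng.random() < 0.5:
            ref = genome.fetch(chrom, pos, pos)
            ins = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 4))))
            variants.append(VariantRecord(chrom, pos, ref, ref + ins, "INS", rand_p()))
        else:
            k = int(rng.integers(1, 4))
            ref = genome.fetch(chrom, pos, pos + k)
            variants.append(VariantRecord(chrom, pos, ref, ref[0], "DEL", rand_p()))
    for _ in range(n_above_threshold):
        loc = place(1)
        if loc is None:
            break
        chrom, pos = loc
        ref = genome.fetch(chrom, pos, pos)
        alt = _BASES[(_BASES.index(ref) + 2) % 4]
        variants.append(
            VariantRecord(
                chrom, pos, ref, alt, "SNP", float(rng.uniform(p_threshold, 0.5))
            )
        )

    variants.sort(key=lambda v: (v.chrom, v.pos))
    passing = [v for v in variants if v.p_value < p_threshold]
    return variants, naive_apply(genome, passing)


def count_genomic_occurrences(genome: GenomeSequence, peptide: str) -> int:
    """Independent six-frame occurrence count using Bio.Seq translation
    (the post-plant collision check and the scan oracle for tests)."""
    total = 0
    for seq in genome.records.values():
        for strand_seq in (Seq(seq), Seq(seq).reverse_complement()):
            for o in range(3):
                usable = len(strand_seq) - o
                prot = str(strand_seq[o : o + usable - usable % 3].translate())
                start = prot.find(peptide)
                while start != -1:
                    total += 1
                    start = prot.find(peptide, start + 1)
    return total


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class Fixture:
    scenario: str
    seed: int
    reference: GenomeSequence  # genome as emitted (variants NOT applied)
    genes: list[GeneModel]
    gtf_text: str
    variants: list[VariantRecord]  # including above-threshold records
    proteome: dict[str, str]
    candidates: list[str]
    plants: list[PlantedPeptide] = field(default_factory=list)
    expected_sample: GenomeSequence | None = None
    p_threshold: float = 0.01

    @property
    def manifest(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "p_threshold": self.p_threshold,
            "n_variants": len(self.variants),
            "plants": [p.as_dict() for p in self.plants],
            "candidates": self.candidates,
        }


_GENE_LAYOUT = {
    # gene_id: (chrom, strand, {transcript: exons})
    "g1": ("chr1", "+", {
        "g1t1": [(1000, 1500), (3500, 4200), (8000, 9000)],
        "g1t2": [(1000, 1500), (5000, 5600), (8000, 9000)],
    }),
    "g2": ("chr1", "-", {
        "g2t1": [(12000, 12800), (16500, 17200), (19000, 20000)],
    }),
    "g3": ("chr1", "+", {
        "g3t1": [(25000, 25600), (29500, 31000)],
    }),
    "g4": ("chr2", "-", {
        "g4t1": [(2000, 2600), (6000, 6700), (9000, 9500)],
        "g4t2": [(2000, 2600), (9000, 9500)],
    }),
    "g5": ("chr2", "+", {
        "g5t1": [(15000, 15800), (19500, 20200), (21500, 22000)],
    }),
}

# intron regions of the layout above (gap of the per-gene exon union)
_INTRONS = {
    "g1": [(1501, 3499), (4201, 4999), (5601, 7999)],
    "g2": [(12801, 16499), (17201, 18999)],
    "g3": [(25601, 29499)],
    "g4": [(2601, 5999), (6701, 8999)],
    "g5": [(15801, 19499), (20201, 21499)],
}

SCENARIOS = ("basic", "funnel", "antisense")


def _frame_from_span(strand: str, span: tuple[int, int], chrom_len: int) -> str:
    """Chrom-relative frame label of a codon-aligned span."""
    if strand == "+":
        return f"f{(span[0] - 1) % 3}"
    return f"r{(chrom_len - span[1]) % 3}"


def _strand_for(gene_strand: str, orientation: str) -> str:
    if orientation == "sense":
        return gene_strand
    return "-" if gene_strand == "+" else "+"


def build_scenario(
    scenario: str,
    seed: int = 0,
    chrom_length: int = 100_000,
    n_decoys: int = 20,
) -> Fixture:
    """Assemble one of the named fixture scenes (basic | funnel | antisense).

    Planting is verified by an independent post-plant six-frame scan; codon
    choices are re-rolled on collision.
    """
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}")
    base = make_genome(2, chrom_length, gc_fraction=0.5, seed=seed)
    genes: list[GeneModel] = []
    gtf_parts: list[str] = []
    for gene_id, (chrom, strand, layout) in _GENE_LAYOUT.items():
        gene, gtf = plant_gene(base, chrom, gene_id, layout, strand)
        genes.append(gene)
        gtf_parts.append(gtf)
    gtf_text = "".join(gtf_parts)

    # plant requests: (name, peptide, gene, region, orientation, frame_offset,
    #                  pad_to_stop, flank_up, flank_down, verdict)
    requests = _scenario_requests(scenario)

    plants: list[PlantedPeptide] = []
    for attempt in range(12):
        chars = {c: list(s) for c, s in base.records.items()}
        placements: dict[str, list[dict]] = {}
        ok = True
        for name, pep, gene_id, region, orientation, fo, pad, fu, fd, verdict in requests:
            gene_strand = _GENE_LAYOUT[gene_id][1]
            chrom = _GENE_LAYOUT[gene_id][0]
            strand = _strand_for(gene_strand, orientation)
            info = plant_peptide(
                chars, chrom, region, strand, fo, pep, pad, fu, fd, attempt=attempt
            )
            placements.setdefault(pep, []).append(
                {**info, "chrom": chrom, "gene": gene_id, "orientation": orientation,
                 "flank_up": fu, "flank_down": fd, "pad": pad, "verdict": verdict,
                 "name": name}
            )
        planted_genome = GenomeSequence({c: "".join(v) for c, v in chars.items()})
        for pep, infos in placements.items():
            if count_genomic_occurrences(planted_genome, pep) != len(infos):
                ok = False
                break
        if ok:
            break
    else:
        raise InputError("could not plant peptides without collisions")

    # non-genomic candidates
    plants = []
    candidates: list[str] = list(placements)
    known_pep = "AYWDQHNTK"
    absent_pep = "WWHHDDYYKK"
    include: dict[str, str] = {}
    if scenario in ("basic", "funnel"):
        candidates.append(known_pep)
        include[known_pep] = known_pep
        plants.append(
            PlantedPeptide(known_pep, "known_protein", None, None, None, None,
                           None, None, None, None)
        )
    if scenario == "funnel":
        candidates.append(absent_pep)
        plants.append(
            PlantedPeptide(absent_pep, "absent", None, None, None, None, None,
                           None, None, None)
        )
    for pep in (known_pep, absent_pep):
        if count_genomic_occurrences(planted_genome, pep) != 0:
            raise InputError(f"control peptide {pep} unexpectedly present in genome")

    proteome = make_decoys(n_decoys, include, seed=seed + 1)
    for pep in candidates:
        if pep not in include and any(pep in s for s in proteome.values()):
            raise InputError("decoy proteome accidentally contains a plant")

    # variants: confined to plant-free tails of each chrom so that sample
    # coordinates inside genes equal reference coordinates
    allowed = {"chr1": (40_000, chrom_length - 10), "chr2": (30_000, chrom_length - 10)}
    variants, expected = make_variants(
        planted_genome, n_snp=10, n_indel=4, seed=seed + 2,
        allowed_spans=allowed, n_above_threshold=2,
    )

    reference = planted_genome
    if scenario == "funnel":
        # one variant-dependent plant: break a peptide base in the emitted
        # reference and ship the repairing SNP, so the peptide exists only
        # in the sample-specific genome
        reference, fix = _break_and_fix(planted_genome, placements)
        variants = sorted(variants + [fix], key=lambda v: (v.chrom, v.pos))
        expected = naive_apply(
            reference, [v for v in variants if v.p_value < 0.01]
        )

    # manifest frame labels are chrom-relative on the SAMPLE genome; tail
    # indels change the chrom length and with it the reverse-frame lattice,
    # so recompute from the final expected sample chrom lengths
    for pep, infos in placements.items():
        if len(infos) > 1:
            plants.append(
                PlantedPeptide(pep, "multiple_occurrence", None, None, None,
                               None, None, None, None, None)
            )
            continue
        info = infos[0]
        chrom_len = len(expected[info["chrom"]])
        frame = _frame_from_span(info["strand"], info["span"], chrom_len)
        if info["verdict"] == "unique_nonexon":
            plants.append(
                PlantedPeptide(
                    pep, "unique_nonexon", info["gene"], info["orientation"], frame,
                    info["chrom"], info["span"], info["flank_up"], info["flank_down"],
                    len(pep) + info["pad"],
                )
            )
        else:  # exonic
            plants.append(
                PlantedPeptide(pep, "exonic", info["gene"], None, frame,
                               info["chrom"], info["span"], None, None, None)
            )

    return Fixture(
        scenario=scenario,
        seed=seed,
        reference=reference,
        genes=genes,
        gtf_text=gtf_text,
        variants=variants,
        proteome=proteome,
        candidates=sorted(candidates),
        plants=plants,
        expected_sample=expected,
    )


def _break_and_fix(genome: GenomeSequence, placements):
    """Flip the middle base of the first codon of the variant-tagged plant
    to a residue-changing base; return (broken genome, repairing SNP)."""
    info = next(
        i for infos in placements.values() for i in infos if i["name"] == "variant_plant"
    )
    chrom = info["chrom"]
    span = info["span"]
    # middle base of the first peptide codon in genome orientation
    pos = span[0] + 1 if info["strand"] == "+" else span[1] - 1
    good = genome.fetch(chrom, pos, pos)
    codon_start = span[0] if info["strand"] == "+" else span[1] - 2
    codon = genome.fetch(chrom, codon_start, codon_start + 2)
    for bad in _BASES:
        if bad == good:
            continue
        mutated = codon[: pos - codon_start] + bad + codon[pos - codon_start + 1 :]
        rc = reverse_complement(mutated)
        reading = mutated if info["strand"] == "+" else rc
        if reading not in STOP_CODONS:
            records = dict(genome.records)
            s = records[chrom]
            records[chrom] = s[: pos - 1] + bad + s[pos:]
            fix = VariantRecord(chrom, pos, bad, good, "SNP", 1e-5)
            return GenomeSequence(records), fix
    raise InputError("could not construct variant-dependent plant")


def _scenario_requests(scenario: str):
    g1i = _INTRONS["g1"]
    g2i = _INTRONS["g2"]
    g3i = _INTRONS["g3"]
    g4i = _INTRONS["g4"]
    g5i = _INTRONS["g5"]
    if scenario == "basic":
        return [
            ("sense_plant", "MKAAYLTER", "g1", g1i[0], "sense", 0, 11, "R", "A", "unique_nonexon"),
            ("anti_plant", "WTDHRCVMK", "g2", g2i[0], "antisense", 1, 13, "K", "S", "unique_nonexon"),
        ]
    if scenario == "funnel":
        exon_g1 = (1000, 1500)  # first exon of g1
        return [
            ("sense_plant", "MKAAYLTER", "g1", g1i[0], "sense", 0, 11, "R", "A", "unique_nonexon"),
            ("anti_plant", "WTDHRCVMK", "g2", g2i[0], "antisense", 1, 13, "K", "S", "unique_nonexon"),
            ("anti_plant2", "NDYWHQCTR", "g1", g1i[2], "antisense", 2, 16, "F", "G", "unique_nonexon"),
            ("dup_a", "GHWNDYRAK", "g3", g3i[0], "sense", 0, 9, "R", "A", "multiple_occurrence"),
            ("dup_b", "GHWNDYRAK", "g4", g4i[0], "sense", 1, 9, "R", "A", "multiple_occurrence"),
            ("exon_plant", "QYHWDNTRK", "g1", exon_g1, "sense", 0, 5, "R", "A", "exonic"),
            ("variant_plant", "DQWYHNTMK", "g5", g5i[0], "sense", 2, 11, "R", "A", "unique_nonexon"),
        ]
    # antisense: one sense, four antisense (orientation-mix scene)
    return [
        ("sense_plant", "MKAAYLTER", "g1", g1i[0], "sense", 0, 11, "R", "A", "unique_nonexon"),
        ("a1", "WTDHRCVMK", "g2", g2i[0], "antisense", 0, 11, "K", "S", "unique_nonexon"),
        ("a2", "NDYWHQCTR", "g2", g2i[1], "antisense", 1, 12, "R", "G", "unique_nonexon"),
        ("a3", "HDWYNCTKR", "g4", g4i[0], "antisense", 2, 13, "F", "A", "unique_nonexon"),
        ("a4", "YQWHDNARK", "g5", g5i[1], "antisense", 0, 14, "R", "T", "unique_nonexon"),
    ]


# ---------------------------------------------------------------------------
# emission


def write_scenario(fixture: Fixture, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write genome.fa, genes.gtf, variants.vcf, proteome.fa, peptides.tsv
    and manifest.json; returns the path map."""
    from .reference_io import write_genome

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        name: os.path.join(out_dir, name)
        for name in (
            "genome.fa", "genes.gtf", "variants.vcf", "proteome.fa",
            "peptides.tsv", "manifest.json",
        )
    }
    write_genome(fixture.reference, paths["genome.fa"])
    with open(paths["genes.gtf"], "w") as fh:
        fh.write(fixture.gtf_text)
    _write_vcf(fixture, paths["variants.vcf"])
    with open(paths["proteome.fa"], "w") as fh:
        for name, seq in fixture.proteome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["peptides.tsv"], "w") as fh:
        fh.write("sequence\tsample_id\n")
        for pep in fixture.candidates:
            fh.write(f"{pep}\t{fixture.scenario}\n")
    with open(paths["manifest.json"], "w") as fh:
        json.dump(fixture.manifest, fh, indent=1)
    return paths


def _write_vcf(fixture: Fixture, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in fixture.reference.records.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write(
            '##INFO=<ID=PVAL,Number=1,Type=Float,Description="Caller p-value">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in fixture.variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tPVAL={v.p_value:.3g}\n"
            )
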