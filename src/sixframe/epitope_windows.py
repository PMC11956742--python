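"""Enumerate 8-14-mer MHC-I candidate windows across flanked peptides and
export them for an external binding predictor."""

from __future__ import annotations

import os
from dataclasses import dataclass

from .peptide_verify import NaPtpAnnotation

__all__ = [
    "FlankedNaPtp",
    "EpitopeWindow",
    "flank_and_measure",
    "parse_flanked",
    "enumerate_windows",
    "export_predictor_input",
    "summarize_orientation",
]

#: flank placeholders that do not count as real residues
_NON_RESIDUE = ("-", "*", "")


@dataclass(frozen=True)
class FlankedNaPtp:
    """MS-identified core plus its genomic flanking residues.

    ``flanked`` concatenates up-flank, core and down-flank, skipping
    placeholder flanks; ``reported_length`` counts core plus real flanks,
    reproducing the published length convention.
    """

    core: str
    up: str
    down: str
    source: str | None = None  # e.g. host gene id

    @property
    def flanked(self) -> str:
        up = "" if self.up in _NON_RESIDUE else self.up
        down = "" if self.down in _NON_RESIDUE else self.down
        return up + self.core + down

    @property
    def reported_length(self) -> int:
        return len(self.flanked)


def parse_flanked(notation: str, source: str | None = None) -> FlankedNaPtp:
    """Parse dot notation 'X.PEPTIDE.Y' ('-' marks a missing flank)."""
    up, core, down = notation.split(".")
    return FlankedNaPtp(core=core, up=up, down=down, source=source)


def flank_and_measure(annotation: NaPtpAnnotation | str) -> FlankedNaPtp:
    """Build the flanked peptide from a verified annotation (or directly
    from a dot-notation string) and measure its reported length."""
    if isinstance(annotation, str):
        return parse_flanked(annotation)
    return FlankedNaPtp(
        core=annotation.peptide,
        up=annotation.flank_up,
        down=annotation.flank_down,
        source=annotation.gene,
    )


@dataclass(frozen=True)
class EpitopeWindow:
    peptide: str
    k: int
    offset: int
    source: str | None = None


def enumerate_windows(
    flanked: FlankedNaPtp, kmin: int = 8, kmax: int = 14
) -> list[EpitopeWindow]:
    """All contiguous k-mers of the flanked string for k in [kmin, kmax],
    ordered by (k, offset). Count = sum over k of (L - k + 1)."""
    if kmin > kmax:
        raise ValueError(f"kmin {kmin} > kmax {kmax}")
    s = flanked.flanked
    out: list[EpitopeWindow] = []
    for k in range(kmin, kmax + 1):
        for offset in range(len(s) - k + 1):
            out.append(EpitopeWindow(s[offset : offset + k], k, offset, flanked.source))
    return out


def export_predictor_input(
    windows: list[EpitopeWindow],
    path: str | os.PathLike,
    format: str = "PEPLIST",
    unique: bool = False,
) -> int:
    """Write predictor input: PEPLIST (one peptide per line, the peptide-mode
    input of MHC-I binding predictors) or FASTA with source|offset|k headers.

    Returns the number of records written.
    """
    fmt = format.upper()
    if fmt not in ("PEPLIST", "FASTA"):
        raise ValueError(f"unknown predictor input format {format!r}")
    items = windows
    if unique:
        seen: set[str] = set()
        items = []
        for w in windows:
            if w.peptide not in seen:
                seen.add(w.peptide)
                items.append(w)
    with open(path, "w") as fh:
        for w in items:
            if fmt == "PEPLIST":
                fh.write(w.peptide + "\n")
            else:
                fh.write(f">{w.source or 'NA'}|{w.offset}|{w.k}\n{w.peptide}\n")
    return len(items)


def summarize_orientation(items) -> dict[str, int]:
    """Exhaustive {sense, antisense} count over annotations or raw labels."""
    counts = {"sense": 0, "antisense": 0}
    for item in items:
        orientation = item if isinstance(item, str) else item.orientation
        if orientation in counts:
            counts[orientation] += 1
    return counts
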