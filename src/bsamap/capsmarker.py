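"""CAPS (cleaved amplified polymorphic sequence) marker tools.

Restriction-site scanning with IUPAC recognition strings, in-silico digestion
of linear amplicons, assay design distinguishing two SNP alleles by band
pattern, and genotype calling from observed band lengths.

Coordinate conventions: cut positions are 0-based between-base indices on the
top strand; fragment lengths are reported sorted ascending.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str  # IUPAC, top strand
    cut_offset: int   # bases after recognition start, top strand

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ValueError(f"{self.name}: recognition must be >= 4 bases")
        if any(b not in _IUPAC for b in rec):
            raise ValueError(f"{self.name}: non-IUPAC character in recognition {rec!r}")
        if not (0 <= self.cut_offset <= len(rec)):
            raise ValueError(f"{self.name}: cut_offset outside recognition")
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        return str(Seq(self.recognition).reverse_complement()) == self.recognition


@dataclass(frozen=True)
class DigestResult:
    cut_positions: tuple[int, ...]    # sorted, 0-based between bases
    fragment_lengths: tuple[int, ...]  # sorted ascending


@dataclass(frozen=True)
class CapsAssay:
    amplicon_allele_D: str
    amplicon_allele_R: str
    enzyme: Enzyme
    bands_D: tuple[int, ...]
    bands_R: tuple[int, ...]
    bands_H: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if sorted(self.bands_D) == sorted(self.bands_R):
            raise ValueError("assay does not distinguish alleles")
        # heterozygote shows every band of both alleles, deduplicated by length
        object.__setattr__(self, "bands_H",
                           tuple(sorted(set(self.bands_D) | set(self.bands_R))))

    def to_dict(self) -> dict:
        return {
            "enzyme": self.enzyme.name,
            "recognition": self.enzyme.recognition,
            "cut_offset": self.enzyme.cut_offset,
            "amplicon_allele_D": self.amplicon_allele_D,
            "amplicon_allele_R": self.amplicon_allele_R,
            "bands_D": list(self.bands_D),
            "bands_R": list(self.bands_R),
            "bands_H": list(self.bands_H),
        }


def load_enzymes(path: str | Path | None = None) -> list[Enzyme]:
    """Load an enzyme table TSV (name, site, cut_offset); default: bundled table."""
    if path is None:
        text = resources.files("bsamap").joinpath("data/enzymes.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    enzymes = []
    for ln in lines[1:]:
        name, site, cut = ln.split("\t")
        enzymes.append(Enzyme(name, site, int(cut)))
    return enzymes


def get_enzyme(name: str, path: str | Path | None = None) -> Enzyme:
    for e in load_enzymes(path):
        if e.name.lower() == name.lower():
            return e
    raise KeyError(f"enzyme {name!r} not in table")


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, b in enumerate(seq):
        if b not in "ACGT":
            raise ValueError(f"non-nucleotide character {b!r} at position {i + 1}")
    return seq


def scan_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut positions of every recognition match.

    Matches the recognition on the top strand and, for non-palindromic
    recognitions, its reverse complement as well (the enzyme binds
    double-stranded DNA in either orientation). Overlapping matches are all
    reported; duplicate cut coordinates are collapsed.
    """
    seq = _check_sequence(seq)
    cuts: set[int] = set()
    pattern = re.compile("(?=" + "".join(_IUPAC[b] for b in enzyme.recognition) + ")")
    for m in pattern.finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset)
    if not enzyme.is_palindromic:
        rc = str(Seq(enzyme.recognition).reverse_complement())
        pattern_rc = re.compile("(?=" + "".join(_IUPAC[b] for b in rc) + ")")
        # bottom-strand site: top-strand cut mirrors the offset from the far end
        for m in pattern_rc.finditer(seq):
            cuts.add(m.start() + len(rc) - enzyme.cut_offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: str, enzyme: Enzyme) -> DigestResult:
    """Fragment a linear sequence at every cut site; lengths sum exactly."""
    seq = _check_sequence(seq)
    cuts = scan_sites(seq, enzyme)
    edges = [0, *cuts, len(seq)]
    fragments = sorted(b - a for a, b in zip(edges[:-1], edges[1:]))
    return DigestResult(tuple(cuts), tuple(fragments))


def undigested_length(fragments: Sequence[int]) -> int:
    """Length of the uncut product: the sum of its digestion fragments."""
    fragments = list(fragments)
    if not fragments:
        raise ValueError("empty fragment list")
    if any(f <= 0 for f in fragments):
        raise ValueError("fragment lengths must be positive")
    return sum(fragments)


def design_caps(amplicon_A: str, amplicon_B: str,
                enzymes: Iterable[Enzyme]) -> list[CapsAssay]:
    """Assays for every enzyme whose digest band pattern separates the alleles.

    Assays are ranked by gel resolvability: the minimum length difference
    between any distinguishing band of one allele and the nearest band of
    the other, descending.
    """
    a = _check_sequence(amplicon_A)
    b = _check_sequence(amplicon_B)
    if len(a) != len(b):
        raise ValueError("amplicons must be equal length")
    if a == b:
        raise ValueError("no polymorphism: amplicons are identical")
    assays = []
    for enz in enzymes:
        bands_a = digest(a, enz).fragment_lengths
        bands_b = digest(b, enz).fragment_lengths
        if sorted(bands_a) != sorted(bands_b):
            assays.append(CapsAssay(a, b, enz, bands_a, bands_b))
    assays.sort(key=lambda x: -_resolvability(x.bands_D, x.bands_R))
    return assays


def _resolvability(bands_a: Sequence[int], bands_b: Sequence[int]) -> int:
    only_a = set(bands_a) - set(bands_b)
    only_b = set(bands_b) - set(bands_a)
    diffs = [abs(x - y) for x in only_a for y in set(bands_b)] \
        + [abs(x - y) for x in only_b for y in set(bands_a)]
    return min(diffs) if diffs else 0


def call_genotype(observed_bands: Sequence[int], assay: CapsAssay,
                  tolerance_bp: int = 0) -> str:
    """Match an observed band multiset to D, R or H; no match -> "unknown"."""
    if any(b <= 0 for b in observed_bands):
        raise ValueError("band lengths must be positive")
    for label, expected in (("D", assay.bands_D), ("R", assay.bands_R),
                            ("H", assay.bands_H)):
        if _bands_match(observed_bands, expected, tolerance_bp):
            return label
    return "unknown"


def _bands_match(observed: Sequence[int], expected: Sequence[int],
                 tolerance: int) -> bool:
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tolerance
               for o, e in zip(sorted(observed), sorted(expected)))


def cds_protein_length(cds_length_bp: int) -> int:
    """Amino acids encoded by a CDS that includes its stop codon."""
    if cds_length_bp % 3 != 0:
        raise ValueError(f"CDS length {cds_length_bp} not divisible by 3")
    if cds_length_bp < 6:
        raise ValueError("CDS too short for a start and a stop codon")
    return cds_length_bp // 3 - 1


def write_assay_report(assays: Sequence[CapsAssay], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([a.to_dict() for a in assays], fh, indent=2)
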