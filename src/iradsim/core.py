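"""Core data model: restriction enzymes, panels, genomes and IUPAC motif matching.

Restriction enzymes used for inverse RAD-seq recognize short (typically 4-8 bp)
palindromic DNA motifs. Motifs are stored as IUPAC strings so that enzymes with
degenerate recognition sequences (e.g. ApoI, R^AATTY) can be supplied by the
user, even though all six built-in enzymes have concrete recognition sites.

Coordinate convention: every interval in this package is 0-based, half-open.
Sequences are upper-cased on ingest; soft-masking is ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "Enzyme",
    "Panel",
    "Genome",
    "builtin_enzyme",
    "builtin_enzyme_names",
    "load_enzyme_table",
    "iupac_match",
    "iupac_regex",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]

# IUPAC nucleotide codes -> set of concrete bases each code stands for.
# Note: a genome base N never satisfies any pattern symbol (including pattern
# N); digestion requires real sequence, so the expansions below deliberately
# exclude N.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, honouring IUPAC ambiguity codes."""
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


def _validate_iupac(pattern: str) -> None:
    bad = set(pattern) - set(IUPAC_CODES)
    if not pattern:
        raise ValueError("empty IUPAC pattern")
    if bad:
        raise ValueError(
            f"invalid IUPAC symbol(s) {sorted(bad)} in pattern {pattern!r}"
        )


def iupac_regex(pattern: str) -> str:
    """Regex source matching one occurrence of an IUPAC motif on ACGTN text."""
    _validate_iupac(pattern)
    parts = []
    for sym in pattern:
        bases = sorted(IUPAC_CODES[sym])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(parts)


def iupac_match(pattern: str, sequence: str) -> list[int]:
    """All 0-based start positions where *pattern* matches *sequence*.

    Overlapping occurrences are all reported. Sequence N matches nothing.
    """
    rx = re.compile("(?=" + iupac_regex(pattern) + ")")
    return [m.start() for m in rx.finditer(sequence)]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: a name and its IUPAC recognition motif."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        _validate_iupac(self.recognition)

    @property
    def palindromic(self) -> bool:
        """True when the motif equals its own IUPAC reverse complement."""
        return self.recognition == reverse_complement(self.recognition)

    def __len__(self) -> int:
        return len(self.recognition)


# Type II enzymes used in the iRAD-seq panels; all recognize palindromes.
_BUILTIN = {
    "msei": Enzyme("MseI", "TTAA"),
    "mspi": Enzyme("MspI", "CCGG"),
    "alui": Enzyme("AluI", "AGCT"),
    "dpnii": Enzyme("DpnII", "GATC"),
    "hindiii": Enzyme("HindIII", "AAGCTT"),
    "hinp1i": Enzyme("HinP1I", "GCGC"),
}


def builtin_enzyme_names() -> list[str]:
    return [e.name for e in _BUILTIN.values()]


def builtin_enzyme(name: str) -> Enzyme:
    """Look up a built-in enzyme by (case-insensitive) name."""
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise LookupError(
            f"unknown enzyme {name!r}; available: {', '.join(builtin_enzyme_names())}"
        ) from None


def load_enzyme_table(path: str | Path) -> dict[str, Enzyme]:
    """Load extra enzymes from a 2-column TSV (name, recognition)."""
    table: dict[str, Enzyme] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
        name, recog = fields
        if name in table:
            raise ValueError(f"{path}:{ln}: duplicate enzyme name {name!r}")
        table[name] = Enzyme(name, recog)
    return table


@dataclass(frozen=True)
class Panel:
    """An ordered set of enzymes applied together in one digestion."""

    enzymes: tuple[Enzyme, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValueError("a panel needs at least one enzyme")
        names = [e.name for e in self.enzymes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate enzyme names in panel: {names}")
        if not self.name:
            object.__setattr__(self, "name", "+".join(names))

    @classmethod
    def from_names(
        cls,
        names: Iterable[str] | str,
        name: str = "",
        extra: Mapping[str, Enzyme] | None = None,
    ) -> "Panel":
        """Build a panel from enzyme names, e.g. ``"MseI,MspI,AluI"``.

        *extra* maps names to user-defined enzymes (see load_enzyme_table),
        consulted before the built-in registry.
        """
        if isinstance(names, str):
            names = [n.strip() for n in names.split(",") if n.strip()]
        enzymes = []
        for n in names:
            if extra and n in extra:
                enzymes.append(extra[n])
            else:
                enzymes.append(builtin_enzyme(n))
        return cls(tuple(enzymes), name=name)

    def __iter__(self) -> Iterator[Enzyme]:
        return iter(self.enzymes)

    def __len__(self) -> int:
        return len(self.enzymes)


@dataclass
class Genome:
    """An ordered collection of chromosome sequences (uppercase, may contain N)."""

    sequences: dict[str, str]
    name: str = "genome"

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def non_n_length(self) -> int:
        return sum(len(s) - s.count("N") for s in self.sequences.values())

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def read_fasta(path: str | Path, name: str | None = None) -> Genome:
    """Read a (multi-)FASTA file into a Genome, upper-casing sequences."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(seqs, name=name or Path(path).stem)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
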