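"""In silico digestion: recognition-site scanning and site-free fragment derivation.

Inverse RAD-seq sequences the fragments that do NOT contain a recognition
site of the enzyme panel (negative selection): library molecules carrying a
site are cleaved and lose an adapter. The sequenceable space of a panel on a
genome is therefore the set of site-free intervals, computed here under two
boundary conventions:

``between_sites``
    Fragments run from the end of one (merged) recognition-site interval to
    the start of the next; the site bases themselves belong to no fragment.
    With terminal fragments included this partitions the genome exactly into
    fragments plus merged site intervals.

``maximal_site_free``
    Maximal intervals that contain no *complete* occurrence of any panel
    motif. These may extend into the flanking recognition sites (all but one
    base), so consecutive fragments can share a few bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .core import Genome, Panel, iupac_regex, reverse_complement

__all__ = [
    "Site",
    "SiteIndex",
    "Fragment",
    "FragmentSet",
    "scan_sites",
    "derive_fragments",
    "panel_regex",
    "write_sites_bed",
    "write_fragments_bed",
    "read_fragments_bed",
]

CONVENTIONS = ("between_sites", "maximal_site_free")


@dataclass(frozen=True)
class Site:
    start: int
    end: int
    enzyme: str


@dataclass
class SiteIndex:
    """Per-chromosome sorted, deduplicated recognition-site intervals."""

    panel_name: str
    genome_name: str
    sites: dict[str, list[Site]]

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def merged_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Union of site intervals on one chromosome (overlaps merged)."""
        merged: list[tuple[int, int]] = []
        for s in self.sites.get(chrom, []):
            if merged and s.start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], s.end))
            else:
                merged.append((s.start, s.end))
        return merged

    def merged_site_length(self) -> int:
        return sum(
            e - s for chrom in self.sites for s, e in self.merged_intervals(chrom)
        )


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentSet:
    """Site-free fragments of one panel on one genome."""

    panel_name: str
    genome_name: str
    fragments: list[Fragment]
    convention: str = "between_sites"
    include_terminal: bool = True

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def by_chrom(self) -> dict[str, list[Fragment]]:
        out: dict[str, list[Fragment]] = {}
        for f in self.fragments:
            out.setdefault(f.chrom, []).append(f)
        return out

    def total_length(self) -> int:
        return sum(f.length for f in self.fragments)

    def union_length(self, min_length: int = 0) -> int:
        """Total bases covered by fragments of at least *min_length* bp.

        Under ``maximal_site_free`` consecutive fragments can share their
        partial-site flanks, so the union can be smaller than the sum of
        lengths; under ``between_sites`` the two are equal.
        """
        total = 0
        for frags in self.by_chrom().values():
            last_end = -1
            for f in sorted(frags, key=lambda f: f.start):
                if f.length < min_length:
                    continue
                total += f.end - max(f.start, last_end) if f.end > last_end else 0
                last_end = max(last_end, f.end)
        return total


def scan_sites(genome: Genome, panel: Panel) -> SiteIndex:
    """Find every recognition site of *panel* in *genome*.

    Forward-strand motif matches are unioned with reverse-strand matches
    (scanned as the reverse-complement motif on the forward strand and
    reported in forward coordinates). Palindromic motifs — all the built-in
    enzymes — yield each site exactly once. Results are sorted by
    (start, end) and deduplicated on the interval.
    """
    index: dict[str, list[Site]] = {}
    for chrom, seq in genome.sequences.items():
        found: dict[tuple[int, int], str] = {}
        for enz in panel:
            motifs = {enz.recognition}
            if not enz.palindromic:
                motifs.add(reverse_complement(enz.recognition))
            for motif in motifs:
                rx = re.compile("(?=" + iupac_regex(motif) + ")")
                for m in rx.finditer(seq):
                    key = (m.start(), m.start() + len(motif))
                    found.setdefault(key, enz.name)
        index[chrom] = [
            Site(s, e, name) for (s, e), name in sorted(found.items())
        ]
    return SiteIndex(panel.name, genome.name, index)


def panel_regex(panel: Panel) -> re.Pattern[str]:
    """Compiled regex matching any panel motif on either strand."""
    motifs: list[str] = []
    for enz in panel:
        motifs.append(iupac_regex(enz.recognition))
        if not enz.palindromic:
            motifs.append(iupac_regex(reverse_complement(enz.recognition)))
    return re.compile("|".join(dict.fromkeys(motifs)))


def _minimal_sites(sites: list[Site]) -> list[tuple[int, int]]:
    """Intervals minimal under containment (these alone constrain site-free
    intervals: avoiding every minimal site avoids every site)."""
    ivals = sorted({(s.start, s.end) for s in sites})
    # equal starts: keep only the shortest
    by_start: list[tuple[int, int]] = []
    for s, e in ivals:
        if by_start and by_start[-1][0] == s:
            continue
        by_start.append((s, e))
    # drop intervals whose end is >= some later interval's end
    keep: list[tuple[int, int]] = []
    suffix_min = float("inf")
    for s, e in reversed(by_start):
        if e < suffix_min:
            keep.append((s, e))
            suffix_min = e
    keep.reverse()
    return keep


def derive_fragments(
    sites: SiteIndex,
    genome: Genome,
    convention: str = "between_sites",
    include_terminal: bool = True,
) -> FragmentSet:
    """Derive the site-free fragments implied by a site index.

    Zero-length fragments are dropped. A chromosome with no site yields the
    single fragment [0, L). ``include_terminal`` controls the chromosome-end
    fragments under ``between_sites`` (they are always emitted under
    ``maximal_site_free``, where the convention has no site to trim them by).
    """
    if convention not in CONVENTIONS:
        raise ValueError(
            f"unknown boundary convention {convention!r}; choose from {CONVENTIONS}"
        )
    frags: list[Fragment] = []
    for chrom, length in genome.lengths.items():
        chrom_sites = sites.sites.get(chrom, [])
        if not chrom_sites:
            if length > 0:
                frags.append(Fragment(chrom, 0, length))
            continue
        if convention == "between_sites":
            merged = sites.merged_intervals(chrom)
            prev_end = None
            for s, e in merged:
                if prev_end is None:
                    if include_terminal and s > 0:
                        frags.append(Fragment(chrom, 0, s))
                elif s > prev_end:
                    frags.append(Fragment(chrom, prev_end, s))
                prev_end = e
            if include_terminal and prev_end is not None and prev_end < length:
                frags.append(Fragment(chrom, prev_end, length))
        else:  # maximal_site_free
            minimal = _minimal_sites(chrom_sites)
            starts = [0] + [s + 1 for s, _ in minimal]
            ends = [e - 1 for _, e in minimal] + [length]
            for a, b in zip(starts, ends):
                if b > a:
                    frags.append(Fragment(chrom, a, b))
    return FragmentSet(
        sites.panel_name, genome.name, frags, convention, include_terminal
    )


def write_sites_bed(index: SiteIndex, path: str | Path) -> None:
    """BED6 export: name = enzyme, score = interval length, strand '.'"""
    with open(path, "w") as fh:
        for chrom, chrom_sites in index.sites.items():
            for s in chrom_sites:
                fh.write(
                    f"{chrom}\t{s.start}\t{s.end}\t{s.enzyme}\t{s.end - s.start}\t.\n"
                )


def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    """BED6 export: name = frag_<i> (1-based), score = fragment length."""
    with open(path, "w") as fh:
        for i, f in enumerate(frags, 1):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tfrag_{i}\t{f.length}\t.\n")


def read_fragments_bed(
    path: str | Path,
    panel_name: str = "",
    genome_name: str = "",
    convention: str = "between_sites",
) -> FragmentSet:
    frags = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end = line.split("\t")[:3]
        frags.append(Fragment(chrom, int(start), int(end)))
    return FragmentSet(panel_name, genome_name, frags, convention)
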