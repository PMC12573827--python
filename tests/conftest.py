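"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's regex/minimal-interval code
paths: motif matching is per-offset set comparison, site scanning checks
both strands at every position, and fragment derivation works from first
principles on the site list.
"""

from __future__ import annotations

import numpy as np
import pytest

from iradsim.core import IUPAC_CODES, Genome, Panel, reverse_complement

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_match(pattern: str, sequence: str) -> list[int]:
    """Per-offset IUPAC comparison; genome N matches nothing."""
    hits = []
    m = len(pattern)
    for i in range(len(sequence) - m + 1):
        ok = True
        for p, s in zip(pattern, sequence[i : i + m]):
            if s == "N" or s not in IUPAC_CODES[p]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


def naive_scan(genome: Genome, panel: Panel) -> dict[str, list[tuple[int, int, str]]]:
    """Both-strand per-offset scan, reverse hits mapped to forward coords."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, seq in genome.sequences.items():
        found = {}
        for enz in panel:
            motif = enz.recognition
            rc = reverse_complement(motif)
            for i in naive_match(motif, seq):
                found.setdefault((i, i + len(motif)), enz.name)
            for i in naive_match(rc, seq):
                found.setdefault((i, i + len(rc)), enz.name)
        out[chrom] = [(s, e, n) for (s, e), n in sorted(found.items())]
    return out


def naive_between_fragments(
    sites: list[tuple[int, int]], length: int, include_terminal: bool = True
) -> list[tuple[int, int]]:
    """Complement of the merged site intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(sites):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return [(0, length)] if length else []
    frags = []
    if include_terminal and merged[0][0] > 0:
        frags.append((0, merged[0][0]))
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if s2 > e1:
            frags.append((e1, s2))
    if include_terminal and merged[-1][1] < length:
        frags.append((merged[-1][1], length))
    return frags


def naive_maximal_site_free(
    sites: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Maximal intervals containing no complete site, from first principles.

    For each start a, the largest admissible end is min over sites fully to
    the right of a of (site_end - 1); an interval is maximal when no
    interval with an earlier start reaches as far.
    """
    if not sites:
        return [(0, length)] if length else []
    uniq = sorted(set(sites))
    b_max = np.empty(length + 1, dtype=int)
    for a in range(length + 1):
        ends = [e for s, e in uniq if s >= a]
        b_max[a] = min(e - 1 for s, e in uniq if s >= a) if ends else length
    frags = []
    prev = -1
    for a in range(length + 1):
        if b_max[a] > prev and b_max[a] > a:
            frags.append((a, int(b_max[a])))
        prev = max(prev, b_max[a])
    # keep only maximal (drop intervals nested in an earlier one)
    out = []
    for a, b in frags:
        if not out or b > out[-1][1]:
            out.append((a, b))
    return out


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.5) -> Genome:
    bases = np.array(list("ACGT"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(bases, size=length, p=p))
    return Genome({"c1": seq}, name="rand")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def panel_a() -> Panel:
    return Panel.from_names("AluI,MseI,MspI", name="Panel_A")


@pytest.fixture
def panel_b() -> Panel:
    return Panel.from_names("HindIII,MseI,MspI", name="Panel_B")


@pytest.fixture
def tiny_genome() -> Genome:
    # one MseI site (TTAA) at 6, one MspI site (CCGG) at 14
    return Genome({"c1": "ACGACG" + "TTAA" + "ACGA" + "CCGG" + "ACGACGAC"}, name="tiny")
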