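"""Backcross-progeny genotyping: informative markers, sliding-window
smoothing, recombination breakpoints, and population bin markers.

Pipeline (per population):

1. ``select_informative`` keeps SNPs where both parents are homozygous for
   different alleles — the only sites that assign parental origin.
2. ``code_progeny`` codes each line at each marker as A (parent-A
   homozygote), B (parent-B homozygote), H (heterozygote) or U (missing or
   carrying a non-parental allele).
3. ``window_calls`` smooths each line/chromosome track with a sliding
   window of ``w`` informative markers and a purity threshold, absorbing
   runs shorter than a minimum run length.
4. ``call_breakpoints`` places one breakpoint per state transition, as the
   interval between the flanking markers.
5. ``build_bin_map`` projects all lines' breakpoint midpoints as bin
   boundaries; within a bin no line changes state, so bins act as the
   population's markers for linkage mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "select_informative",
    "code_progeny",
    "window_calls",
    "call_breakpoints",
    "Breakpoint",
    "BinMap",
    "build_bin_map",
    "genotype_population",
    "read_genotype_tsv",
    "read_genotype_vcf",
]

META_COLS = ("chrom", "pos", "parent_A", "parent_B")
MISSING = {"./.", ".|.", ".", "", "NA", None}


def _alleles(gt: str) -> tuple[str, str] | None:
    """Parse a genotype string like 'G/T' or 'G|T' ('GT' also accepted)."""
    if gt is None or (isinstance(gt, float) and np.isnan(gt)):
        return None
    gt = str(gt).strip().upper()
    if gt in ("./.", ".|.", ".", "", "NA"):
        return None
    for sep in "/|":
        if sep in gt:
            a, b = gt.split(sep, 1)
            break
    else:
        if len(gt) == 2:
            a, b = gt[0], gt[1]
        else:
            return None
    if a == "." or b == ".":
        return None
    return a, b


def select_informative(table: pd.DataFrame) -> pd.DataFrame:
    """Keep SNPs where both parents are homozygous with different alleles.

    The input table has columns chrom, pos, parent_A, parent_B (parent
    columns hold either a bare allele, e.g. 'G', or a genotype, e.g.
    'G/G'), plus one column per progeny line. Returned rows carry
    single-base parent_A/parent_B alleles. Emits a warning-friendly empty
    frame when nothing is informative.
    """
    keep = []
    a_allele = []
    b_allele = []
    for row in table.itertuples(index=False):
        pa = _alleles(row.parent_A) or (
            (row.parent_A, row.parent_A) if _valid_base(row.parent_A) else None
        )
        pb = _alleles(row.parent_B) or (
            (row.parent_B, row.parent_B) if _valid_base(row.parent_B) else None
        )
        ok = (
            pa is not None
            and pb is not None
            and pa[0] == pa[1]
            and pb[0] == pb[1]
            and pa[0] != pb[0]
        )
        keep.append(ok)
        a_allele.append(pa[0] if ok else None)
        b_allele.append(pb[0] if ok else None)
    out = table.loc[keep].copy()
    out["parent_A"] = [a for a, k in zip(a_allele, keep) if k]
    out["parent_B"] = [b for b, k in zip(b_allele, keep) if k]
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return out


def _valid_base(x) -> bool:
    return isinstance(x, str) and len(x) == 1 and x.upper() in "ACGT"


def code_progeny(markers: pd.DataFrame, lines: list[str] | None = None) -> pd.DataFrame:
    """Code each line at each informative marker as A/B/H/U.

    A: homozygous parent-A allele; B: homozygous parent-B; H: one of each;
    U: missing or carrying any non-parental allele.
    """
    if lines is None:
        lines = [c for c in markers.columns if c not in META_COLS]
    out = markers[list(META_COLS)].copy()
    for ln in lines:
        codes = []
        for gt, a, b in zip(markers[ln], markers["parent_A"], markers["parent_B"]):
            pair = _alleles(gt)
            if pair is None:
                codes.append("U")
            elif set(pair) == {a}:
                codes.append("A")
            elif set(pair) == {b}:
                codes.append("B")
            elif set(pair) == {a, b}:
                codes.append("H")
            else:
                codes.append("U")
        out[ln] = codes
    return out


def _window_states(
    codes: np.ndarray, w: int, purity: float
) -> np.ndarray:
    """Sliding-window state for each window start over a U-free code array."""
    n = len(codes)
    isA = (codes == "A").astype(float)
    isB = (codes == "B").astype(float)
    isH = (codes == "H").astype(float)
    kern = np.ones(w)
    cA = np.convolve(isA, kern, mode="valid")
    cB = np.convolve(isB, kern, mode="valid")
    cH = np.convolve(isH, kern, mode="valid")
    states = np.full(n - w + 1, "?", dtype="U1")
    hom = cA + cB
    with np.errstate(divide="ignore", invalid="ignore"):
        fA = np.where(hom > 0, cA / hom, np.nan)
    states[cH / w >= purity] = "H"
    states[(hom > 0) & (fA >= purity) & (states == "?")] = "A"
    states[(hom > 0) & (fA <= 1 - purity) & (states == "?")] = "B"
    return states


def _fill_ambiguous(states: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Carry the previous decided state into ambiguous windows; leading
    ambiguity is backfilled from the first decided window. All-ambiguous
    tracks fall back to the majority code."""
    out = states.copy()
    decided = np.flatnonzero(out != "?")
    if decided.size == 0:
        return np.full(len(out), _majority(codes), dtype="U1")
    first = decided[0]
    out[:first] = out[first]
    for i in range(first + 1, len(out)):
        if out[i] == "?":
            out[i] = out[i - 1]
    return out


def _majority(codes: np.ndarray) -> str:
    vals, counts = np.unique(codes[codes != "U"], return_counts=True)
    if vals.size == 0:
        return "U"
    return str(vals[np.argmax(counts)])


def _absorb_short_runs(states: np.ndarray, min_run: int) -> np.ndarray:
    """Iteratively relabel runs shorter than min_run to their larger
    neighbour, shortest runs first (deterministic tie-break: leftmost,
    preferring the left neighbour)."""
    runs = _runs(states)
    while len(runs) > 1:
        lengths = [e - s for s, e, _ in runs]
        order = sorted(range(len(runs)), key=lambda i: (lengths[i], i))
        idx = order[0]
        if lengths[idx] >= min_run:
            break
        s, e, _ = runs[idx]
        left = runs[idx - 1] if idx > 0 else None
        right = runs[idx + 1] if idx < len(runs) - 1 else None
        if left is not None and (
            right is None or (left[1] - left[0]) >= (right[1] - right[0])
        ):
            new_state = left[2]
        else:
            new_state = right[2]
        states = states.copy()
        states[s:e] = new_state
        runs = _runs(states)
    return states


def _runs(states: np.ndarray) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[i - 1]:
            runs.append((start, i, str(states[start])))
            start = i
    return runs


def window_calls(
    positions: np.ndarray,
    codes: np.ndarray,
    w: int = 15,
    purity: float = 0.8,
    min_run: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth one line/chromosome code track.

    Windows span ``w`` consecutive informative (non-U) markers and slide by
    one marker. A window is called A or B when the majority fraction among
    homozygous codes reaches ``purity``, H when the heterozygous fraction
    does; otherwise the previous window's state is carried. Each marker
    takes the state of the window centred on it (clamped at the ends), and
    runs shorter than ``min_run`` (default ``w``) markers are absorbed into
    their neighbours.

    Returns (positions of informative markers, smoothed state per marker).
    Chromosomes with fewer than ``w`` informative markers get a single
    majority call.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    if min_run is None:
        min_run = w
    positions = np.asarray(positions)
    codes = np.asarray(codes, dtype="U1")
    mask = codes != "U"
    pos_i = positions[mask]
    codes_i = codes[mask]
    n = len(codes_i)
    if n == 0:
        return pos_i, np.empty(0, dtype="U1")
    if n < w:
        return pos_i, np.full(n, _majority(codes_i), dtype="U1")
    win = _fill_ambiguous(_window_states(codes_i, w, purity), codes_i)
    # assign each marker the state of the window centred on it
    centers = np.arange(len(win)) + w // 2
    per_marker = np.empty(n, dtype="U1")
    per_marker[centers] = win
    per_marker[: centers[0]] = win[0]
    per_marker[centers[-1] :] = win[-1]
    per_marker = _absorb_short_runs(per_marker, min_run)
    return pos_i, per_marker


@dataclass(frozen=True)
class Breakpoint:
    line: str
    chrom: str
    left_pos: int  # position of last marker of the left segment (1-based)
    right_pos: int  # position of first marker of the right segment
    left_state: str
    right_state: str

    @property
    def midpoint(self) -> int:
        return (self.left_pos + self.right_pos) // 2


def call_breakpoints(
    positions: np.ndarray,
    states: np.ndarray,
    chrom: str,
    line: str,
) -> list[Breakpoint]:
    """One breakpoint per state transition in a smoothed track."""
    bps = []
    for i in range(1, len(states)):
        if states[i] != states[i - 1]:
            bps.append(
                Breakpoint(
                    line,
                    chrom,
                    int(positions[i - 1]),
                    int(positions[i]),
                    str(states[i - 1]),
                    str(states[i]),
                )
            )
    return bps


@dataclass
class BinMap:
    """Population-level recombination bins and per-line bin states."""

    bins: pd.DataFrame  # columns: chrom, start, end + one state column per line
    n_breakpoints: int
    breakpoints_per_line: dict[str, int]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def line_columns(self) -> list[str]:
        return [c for c in self.bins.columns if c not in ("chrom", "start", "end")]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, row in enumerate(self.bins.itertuples(index=False), 1):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\tbin_{i}\t{row.end - row.start}\t.\n"
                )

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def build_bin_map(
    breakpoints: list[Breakpoint],
    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
    chrom_lengths: dict[str, int],
) -> BinMap:
    """Build population bins from all lines' breakpoints.

    Each breakpoint contributes its interval midpoint as a boundary;
    boundaries are deduplicated and sorted per chromosome, and bins are the
    intervals between consecutive boundaries (plus the chromosome ends,
    0-based half-open). A line's state in a bin is its smoothed state over
    the markers inside the bin (the state at the nearest marker when the
    bin contains none). Adjacent bins with identical state vectors across
    all lines are merged.
    """
    lines = sorted(tracks)
    boundaries: dict[str, set[int]] = {c: set() for c in chrom_lengths}
    for bp in breakpoints:
        boundaries[bp.chrom].add(bp.midpoint)
    per_line_counts = {ln: 0 for ln in lines}
    for bp in breakpoints:
        per_line_counts[bp.line] = per_line_counts.get(bp.line, 0) + 1

    rows = []
    for chrom, length in chrom_lengths.items():
        bounds = sorted(b for b in boundaries.get(chrom, set()) if 0 < b < length)
        edges = [0] + bounds + [length]
        chrom_bins = []
        for s, e in zip(edges, edges[1:]):
            states = {}
            for ln in lines:
                pos, st = tracks[ln].get(chrom, (np.empty(0), np.empty(0, dtype="U1")))
                if len(pos) == 0:
                    states[ln] = "U"
                    continue
                inside = (pos > s) & (pos <= e)  # 1-based marker positions
                if inside.any():
                    states[ln] = _majority_state(st[inside])
                else:
                    nearest = int(np.argmin(np.minimum(np.abs(pos - s), np.abs(pos - e))))
                    states[ln] = str(st[nearest])
            chrom_bins.append({"chrom": chrom, "start": s, "end": e, **states})
        # merge adjacent bins with identical state vectors
        merged = []
        for b in chrom_bins:
            if merged and all(merged[-1][ln] == b[ln] for ln in lines):
                merged[-1]["end"] = b["end"]
            else:
                merged.append(b)
        rows.extend(merged)
    bins = pd.DataFrame(rows)
    return BinMap(bins, len(breakpoints), per_line_counts)


def _majority_state(states: np.ndarray) -> str:
    vals, counts = np.unique(states, return_counts=True)
    return str(vals[np.argmax(counts)])


def genotype_population(
    table: pd.DataFrame,
    chrom_lengths: dict[str, int],
    w: int = 15,
    purity: float = 0.8,
    min_run: int | None = None,
) -> tuple[pd.DataFrame, dict, list[Breakpoint], BinMap]:
    """Full pipeline: informative selection → coding → smoothing → bins.

    Returns (coded marker table, per-line smoothed tracks, breakpoints,
    bin map). ``chrom_lengths`` supplies chromosome ends for the bin
    partition.
    """
    markers = select_informative(table)
    if markers.empty:
        raise ValueError("no informative SNPs: parents share all genotyped alleles")
    coded = code_progeny(markers)
    lines = [c for c in coded.columns if c not in META_COLS]
    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    breakpoints: list[Breakpoint] = []
    for ln in lines:
        tracks[ln] = {}
        for chrom in chrom_lengths:
            sub = coded[coded["chrom"] == chrom]
            if sub.empty:
                continue
            pos, states = window_calls(
                sub["pos"].to_numpy(),
                sub[ln].to_numpy(dtype="U1"),
                w=w,
                purity=purity,
                min_run=min_run,
            )
            tracks[ln][chrom] = (pos, states)
            breakpoints.extend(call_breakpoints(pos, states, chrom, ln))
    binmap = build_bin_map(breakpoints, tracks, chrom_lengths)
    return coded, tracks, breakpoints, binmap


def read_genotype_tsv(path) -> pd.DataFrame:
    """Read the plain genotype table: chrom, pos, parent_A, parent_B, lines..."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV lacks required column(s): {missing}")
    return df


def read_genotype_vcf(path, parent_a: str, parent_b: str) -> pd.DataFrame:
    """Read per-sample genotypes from a VCF into the package's table layout.

    ``parent_a``/``parent_b`` name the parental samples; all other samples
    become progeny columns. Only biallelic SNP records are used.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in (parent_a, parent_b):
        if p not in samples:
            raise ValueError(f"sample {p!r} not in VCF (has: {samples})")
    progeny = [s for s in samples if s not in (parent_a, parent_b)]
    ia, ib = samples.index(parent_a), samples.index(parent_b)
    rows = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        alleles = [var.REF] + var.ALT

        def gt_str(idx: int) -> str:
            g = var.genotypes[idx]
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                return "./."
            return f"{alleles[a]}/{alleles[b]}"

        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "parent_A": gt_str(ia),
            "parent_B": gt_str(ib),
        }
        for s in progeny:
            row[s] = gt_str(samples.index(s))
        rows.append(row)
    return pd.DataFrame(rows)
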