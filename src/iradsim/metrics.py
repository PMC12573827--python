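"""Panel evaluation statistics: threshold counts, coverage, gaps, window density.

These are the numbers a designer looks at when choosing an enzyme panel:
how many site-free fragments exceed a usable length, what share of the
genome they cover, how long the marker deserts (gaps) between them are, and
how evenly fragments spread along chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Genome, Panel
from .digest import FragmentSet, SiteIndex, derive_fragments, scan_sites

__all__ = [
    "PanelReport",
    "GapProfile",
    "threshold_summary",
    "gap_profile",
    "window_density",
    "write_bedgraph",
    "compare_panels",
]


def _retained(frags: FragmentSet, threshold: int, strict: bool = True):
    if strict:
        return [f for f in frags if f.length > threshold]
    return [f for f in frags if f.length >= threshold]


def _denominator(genome: Genome, mode: str) -> int:
    if mode == "total_bases":
        return genome.total_length
    if mode == "non_N_bases":
        return genome.non_n_length
    raise ValueError(f"unknown denominator mode {mode!r}")


@dataclass
class PanelReport:
    """Fragment count and genome coverage at each length threshold."""

    panel_name: str
    genome_name: str
    denominator_mode: str
    denominator: int
    table: pd.DataFrame  # columns: threshold, fragment_count, covered_bases, coverage_fraction

    def at(self, threshold: int) -> pd.Series:
        row = self.table[self.table["threshold"] == threshold]
        if row.empty:
            raise KeyError(f"threshold {threshold} not in report")
        return row.iloc[0]


def threshold_summary(
    frags: FragmentSet,
    thresholds: list[int],
    genome: Genome,
    denominator_mode: str = "total_bases",
    strict: bool = True,
) -> PanelReport:
    """Count fragments longer than each threshold and their genome coverage.

    ``strict`` selects "length > T" (the default reading of *longer than*);
    set False for "length >= T".
    """
    denom = _denominator(genome, denominator_mode)
    rows = []
    for t in thresholds:
        if t < 0:
            raise ValueError("thresholds must be non-negative")
        kept = _retained(frags, t, strict)
        covered = sum(f.length for f in kept)
        rows.append(
            {
                "threshold": t,
                "fragment_count": len(kept),
                "covered_bases": covered,
                "coverage_fraction": covered / denom if denom else 0.0,
            }
        )
    return PanelReport(
        frags.panel_name, frags.genome_name, denominator_mode, denom, pd.DataFrame(rows)
    )


@dataclass
class GapProfile:
    """Gaps between length-retained fragments.

    A gap is the interval between the end of one retained fragment and the
    start of the next (plus, by default, the chromosome ends outside the
    first/last retained fragment). This matches the printed definition of
    gap length — the *distance* between fragments — so recognition-site
    bases falling inside a gap count toward its length. The site-excluded
    total (``gap_length_excl_sites``) is also provided; with it, retained
    coverage + gap fraction + merged-site fraction sums to exactly 1 under
    the between-sites convention with terminal gaps on.
    """

    retain_threshold: int
    gaps: pd.DataFrame  # columns: chrom, start, end, length
    genome_length: int
    total_gap_length: int
    gap_genome_fraction: float
    gap_length_excl_sites: int | None = None

    def n_gaps_gt(self, min_length: int) -> int:
        return int((self.gaps["length"] > min_length).sum())


def gap_profile(
    frags: FragmentSet,
    retain_threshold: int,
    genome: Genome,
    include_terminal_gaps: bool = True,
    sites: SiteIndex | None = None,
    strict: bool = True,
) -> GapProfile:
    """Profile the gaps left between fragments longer than *retain_threshold*.

    A chromosome with no retained fragment contributes one whole-chromosome
    gap. Pass the matching ``sites`` index to also get the site-excluded gap
    total used by the coverage+gap+site conservation identity.
    """
    if retain_threshold < 0:
        raise ValueError("retain_threshold must be >= 0")
    kept = _retained(frags, retain_threshold, strict)
    by_chrom: dict[str, list] = {}
    for f in kept:
        by_chrom.setdefault(f.chrom, []).append(f)
    records = []
    for chrom, length in genome.lengths.items():
        fl = sorted(by_chrom.get(chrom, []), key=lambda f: f.start)
        if not fl:
            if length > 0:
                records.append((chrom, 0, length))
            continue
        if include_terminal_gaps and fl[0].start > 0:
            records.append((chrom, 0, fl[0].start))
        for left, right in zip(fl, fl[1:]):
            if right.start > left.end:
                records.append((chrom, left.end, right.start))
        if include_terminal_gaps and fl[-1].end < length:
            records.append((chrom, fl[-1].end, length))
    gaps = pd.DataFrame(records, columns=["chrom", "start", "end"])
    gaps["length"] = gaps["end"] - gaps["start"]
    total = int(gaps["length"].sum())
    excl = None
    if sites is not None:
        site_in_gaps = 0
        for chrom in genome:
            merged = sites.merged_intervals(chrom)
            gsub = gaps[gaps["chrom"] == chrom]
            starts = gsub["start"].to_numpy()
            ends = gsub["end"].to_numpy()
            for s, e in merged:
                # overlap of site interval [s,e) with each gap
                ov = np.minimum(ends, e) - np.maximum(starts, s)
                site_in_gaps += int(ov[ov > 0].sum())
        excl = total - site_in_gaps
    gl = genome.total_length
    return GapProfile(
        retain_threshold, gaps, gl, total, total / gl if gl else 0.0, excl
    )


def window_density(
    frags: FragmentSet,
    retain_threshold: int,
    genome: Genome,
    window: int = 10_000,
    step: int | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-window fragment count and covered-base fraction.

    Windows of *window* bp tile (or, with ``step`` < window, slide along)
    each chromosome; the last window may be short. A fragment overlapping a
    window boundary is counted in every window it touches.

    Returns a DataFrame with columns chrom, start, end, n_fragments,
    covered_bases, covered_fraction.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or window
    kept = _retained(frags, retain_threshold, strict)
    by_chrom: dict[str, list] = {}
    for f in kept:
        by_chrom.setdefault(f.chrom, []).append(f)
    rows = []
    for chrom, length in genome.lengths.items():
        fl = sorted(by_chrom.get(chrom, []), key=lambda f: f.start)
        starts = np.array([f.start for f in fl])
        ends = np.array([f.end for f in fl])
        for ws in range(0, max(length, 1), step):
            we = min(ws + window, length)
            if starts.size:
                ov = np.minimum(ends, we) - np.maximum(starts, ws)
                hit = ov > 0
                n = int(hit.sum())
                covered = int(ov[hit].sum())
            else:
                n, covered = 0, 0
            rows.append((chrom, ws, we, n, covered, covered / (we - ws)))
            if we == length:
                break
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_fragments", "covered_bases", "covered_fraction"],
    )


def write_bedgraph(
    track: pd.DataFrame, path: str | Path, value: str = "covered_fraction"
) -> None:
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{getattr(row, value):g}\n")


def compare_panels(
    genome: Genome,
    panels: list[Panel],
    thresholds: list[int],
    baseline: int = 0,
    convention: str = "between_sites",
    denominator_mode: str = "total_bases",
    strict: bool = True,
) -> pd.DataFrame:
    """Tabulate fragment counts/coverage for several panels on one genome.

    One row per (panel, threshold). Delta columns give the relative decrease
    versus the baseline panel, (baseline - panel) / baseline, so a positive
    delta means the panel retains fewer/smaller fragments than the baseline.
    """
    if not panels:
        raise ValueError("need at least one panel")
    reports = []
    for panel in panels:
        sites = scan_sites(genome, panel)
        frags = derive_fragments(sites, genome, convention=convention)
        rep = threshold_summary(frags, thresholds, genome, denominator_mode, strict)
        df = rep.table.copy()
        df.insert(0, "panel", panel.name)
        reports.append(df)
    out = pd.concat(reports, ignore_index=True)
    base_name = panels[baseline].name
    base = out[out["panel"] == base_name].set_index("threshold")
    for col in ("fragment_count", "coverage_fraction"):
        b = out["threshold"].map(base[col])
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"delta_{col}"] = np.where(b > 0, (b - out[col]) / b, 0.0)
    return out
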