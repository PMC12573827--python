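"""Deterministic synthetic data: genomes with planted recognition sites and
backcross populations with known crossovers.

Real reference assemblies are hundreds of Mb; every test and demonstration
in this package instead runs on genomes built here, whose ground truth
(site positions, crossover positions) is known exactly.

The genome generator plants motif occurrences with exponentially distributed
spacing (mean ``target_site_spacing``), mimicking the roughly geometric
spacing of short motifs in real sequence. In ``clean`` mode the background
between planted sites is repaired so it contains no accidental occurrence of
any planted motif: site truth tables are then exhaustive.

The population generator emulates advanced backcross lines (e.g. BC1F4):
each chromosome of each line is a mosaic of parental segments separated by
Poisson-planted crossovers, observed through an evenly spaced SNP marker
grid with genotyping error and missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Genome, iupac_match, IUPAC_CODES

__all__ = [
    "SynthGenomeConfig",
    "synth_genome",
    "BCPopulationConfig",
    "simulate_bc_population",
    "PopulationTruth",
]


@dataclass
class SynthGenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 100_000
    target_site_spacing: float = 500.0
    planted_motifs: tuple[str, ...] = ("TTAA", "CCGG", "AGCT")
    gc_content: float = 0.46
    n_run_rate: float = 0.0
    seed: int = 0
    clean: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.n_run_rate < 1.0:
            raise ValueError("n_run_rate must be in [0, 1)")
        maxlen = max(len(m) for m in self.planted_motifs)
        if self.chrom_length <= maxlen:
            raise ValueError("chrom_length must exceed the longest motif")
        if self.target_site_spacing < maxlen:
            raise ValueError(
                f"target_site_spacing {self.target_site_spacing} shorter than "
                f"longest motif ({maxlen} bp): sites would overlap"
            )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _concretize(motif: str, rng: np.random.Generator) -> str:
    """Replace IUPAC ambiguity codes with a random concrete base."""
    return "".join(
        sym if len(IUPAC_CODES[sym]) == 1 else rng.choice(sorted(IUPAC_CODES[sym]))
        for sym in motif
    )


def _repair_accidental(
    arr: np.ndarray,
    motifs: tuple[str, ...],
    planted: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> np.ndarray:
    """Mutate background bases until no accidental motif occurrence remains.

    Bases inside planted intervals are never touched. Each round rescans,
    because a repair can itself create a new occurrence.
    """
    protected = np.zeros(len(arr), dtype=bool)
    for s, e in planted:
        protected[s:e] = True
    for _ in range(max_rounds):
        seq = arr.tobytes().decode()
        planted_set = set(planted)
        bad: list[tuple[int, int]] = []
        for motif in motifs:
            for pos in iupac_match(motif, seq):
                iv = (pos, pos + len(motif))
                if iv not in planted_set:
                    bad.append(iv)
        if not bad:
            return arr
        for s, e in bad:
            cand = [i for i in range(s, e) if not protected[i]]
            if not cand:
                continue  # fully inside planted sites; cannot repair
            i = cand[len(cand) // 2]
            cur = arr[i]
            choices = [b for b in _BASES if b != cur]
            arr[i] = choices[rng.integers(len(choices))]
    return arr


def synth_genome(config: SynthGenomeConfig) -> tuple[Genome, pd.DataFrame]:
    """Generate a genome with planted motif occurrences.

    Returns the genome and a truth table (columns chrom, start, end, motif)
    listing every planted site. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    truth_rows = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _random_bases(rng, config.chrom_length, config.gc_content)
        planted: list[tuple[int, int]] = []
        pos = 0
        while True:
            gap = rng.exponential(config.target_site_spacing)
            pos += max(int(round(gap)), 1)
            motif = config.planted_motifs[rng.integers(len(config.planted_motifs))]
            if pos + len(motif) > config.chrom_length:
                break
            concrete = _concretize(motif, rng)
            arr[pos : pos + len(motif)] = np.frombuffer(
                concrete.encode(), dtype="S1"
            )
            planted.append((pos, pos + len(motif)))
            truth_rows.append((chrom, pos, pos + len(motif), motif))
            pos += len(motif)
        if config.clean:
            arr = _repair_accidental(arr, config.planted_motifs, planted, rng)
        if config.n_run_rate > 0:
            arr = _insert_n_runs(arr, planted, config.n_run_rate, rng)
        seqs[chrom] = arr.tobytes().decode()
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "motif"])
    return Genome(seqs, name=f"synth_seed{config.seed}"), truth


def _insert_n_runs(
    arr: np.ndarray,
    planted: list[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
    mean_run: int = 100,
) -> np.ndarray:
    protected = np.zeros(len(arr), dtype=bool)
    for s, e in planted:
        # protect one extra base on each side so runs never abut a site
        protected[max(s - 1, 0) : e + 1] = True
    target = int(rate * len(arr))
    placed = 0
    attempts = 0
    while placed < target and attempts < 10_000:
        attempts += 1
        run = max(int(rng.geometric(1.0 / mean_run)), 1)
        run = min(run, target - placed)
        start = int(rng.integers(0, max(len(arr) - run, 1)))
        if protected[start : start + run].any():
            continue
        arr[start : start + run] = b"N"
        protected[start : start + run] = True
        placed += run
    return arr


# ---------------------------------------------------------------------------
# Backcross population with known crossovers
# ---------------------------------------------------------------------------

#: Expected genotype-class proportions (A homozygous, heterozygous, B
#: homozygous) for a BC1F4 design: one backcross to parent A, then three
#: further selfed generations halve the residual heterozygosity each time.
BC1F4_PROPORTIONS = (0.72, 0.06, 0.22)


@dataclass
class BCPopulationConfig:
    n_lines: int = 50
    n_chroms: int = 10
    chrom_length: int = 40_000_000
    marker_spacing: int = 20_000
    crossovers_per_chrom: float = 1.0  # Poisson mean, per line per chromosome
    state_proportions: tuple[float, float, float] = BC1F4_PROPORTIONS
    genotype_error: float = 0.01
    missing_rate: float = 0.02
    seed: int = 0


@dataclass
class PopulationTruth:
    """Ground truth accompanying a simulated SNP table."""

    config: BCPopulationConfig
    crossovers: pd.DataFrame  # columns: line, chrom, pos
    true_states: dict[str, dict[str, np.ndarray]]  # line -> chrom -> codes
    marker_positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]


_STATES = np.array(["A", "H", "B"])


def _segment_states(
    n_segments: int, props: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a state per segment from the class proportions, consecutive
    segments forced to differ (a crossover changes the genotype class)."""
    states = np.empty(n_segments, dtype="U1")
    prev = -1
    for i in range(n_segments):
        while True:
            s = rng.choice(3, p=props)
            if s != prev:
                break
        states[i] = _STATES[s]
        prev = s
    return states


def simulate_bc_population(
    config: BCPopulationConfig,
) -> tuple[pd.DataFrame, PopulationTruth]:
    """Simulate a genotyped backcross-derived population.

    Returns a SNP table in the package's TSV layout — columns chrom, pos
    (1-based), parent_A, parent_B, then one genotype column per line
    ("X/Y" strings, "./." for missing) — and the ground truth (crossover
    positions and per-marker true states).

    Markers sit every ``marker_spacing`` bp. Parental alleles are drawn so
    every marker is informative (both parents homozygous for different
    bases). Genotyping error replaces the observed genotype by one of the
    other two classes.
    """
    rng = np.random.default_rng(config.seed)
    props = np.asarray(config.state_proportions, dtype=float)
    props = props / props.sum()
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    lines = [f"line{i + 1:03d}" for i in range(config.n_lines)]
    chrom_lengths = {c: config.chrom_length for c in chroms}

    marker_positions = {
        c: np.arange(
            config.marker_spacing, config.chrom_length + 1, config.marker_spacing
        )
        for c in chroms
    }

    # parental alleles per marker: two distinct bases
    allele_rows = []
    for c in chroms:
        for pos in marker_positions[c]:
            a = "ACGT"[rng.integers(4)]
            b = rng.choice([x for x in "ACGT" if x != a])
            allele_rows.append((c, int(pos), a, b))
    table = pd.DataFrame(allele_rows, columns=["chrom", "pos", "parent_A", "parent_B"])

    co_rows = []
    true_states: dict[str, dict[str, np.ndarray]] = {}
    geno_cols: dict[str, list[str]] = {ln: [] for ln in lines}
    for ln in lines:
        true_states[ln] = {}
        for c in chroms:
            pos = marker_positions[c]
            k = rng.poisson(config.crossovers_per_chrom)
            breaks = np.sort(rng.uniform(0, config.chrom_length, size=k))
            for b in breaks:
                co_rows.append((ln, c, float(b)))
            states = _segment_states(k + 1, props, rng)
            seg_idx = np.searchsorted(breaks, pos)
            truth_codes = states[seg_idx]
            true_states[ln][c] = truth_codes

            observed = truth_codes.copy()
            err = rng.random(len(pos)) < config.genotype_error
            for i in np.flatnonzero(err):
                others = [s for s in "AHB" if s != observed[i]]
                observed[i] = others[rng.integers(2)]
            miss = rng.random(len(pos)) < config.missing_rate

            a = table.loc[table["chrom"] == c, "parent_A"].to_numpy()
            b = table.loc[table["chrom"] == c, "parent_B"].to_numpy()
            geno = np.where(
                observed == "A",
                np.char.add(np.char.add(a, "/"), a),
                np.where(
                    observed == "B",
                    np.char.add(np.char.add(b, "/"), b),
                    np.char.add(np.char.add(a, "/"), b),
                ),
            )
            geno[miss] = "./."
            geno_cols[ln].extend(geno.tolist())
    for ln in lines:
        table[ln] = geno_cols[ln]

    crossovers = pd.DataFrame(co_rows, columns=["line", "chrom", "pos"])
    truth = PopulationTruth(
        config, crossovers, true_states, marker_positions, chrom_lengths
    )
    return table, truth
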