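"""Tagmentation library simulation with pooled digestion and size selection.

The library model follows the inverse-RAD workflow: Tn5 tagmentation is
modelled as independent inserts dropped uniformly over the genome (weighted
by chromosome length), each flanked by adapters of fixed total length.
Pooled digestion then removes every insert that contains a complete
recognition site of the panel — except with probability ``p_escape``, the
single knob for incomplete digestion. Finally, size selection keeps inserts
whose total molecule length (insert + adapters) falls in the selection
window, and the survivors are emitted as a paired-end FASTQ with a truth
table recording every insert's fate.

Defaults reflect the published protocol: 136 bp of adapters, a 430-780 bp
total-length selection window (i.e. 294-644 bp inserts) and 150 bp
paired-end reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .core import Genome, Panel, reverse_complement
from .digest import panel_regex

__all__ = [
    "SimConfig",
    "SimTruth",
    "draw_inserts",
    "apply_digestion",
    "size_select",
    "emit_reads",
    "simulate_library",
]

FATES = ("digested", "size_excluded", "sequenced")


@dataclass
class SimConfig:
    n_inserts: int = 100_000
    insert_distribution: str = "lognormal"  # lognormal | normal | constant
    insert_mean: float = 450.0  # median for lognormal; mean for normal; value for constant
    insert_sigma: float = 0.35  # log-sd (lognormal) or sd in bp (normal)
    insert_min: int = 50
    insert_max: int = 2_000
    adapter_len: int = 136
    size_min_total: int = 430
    size_max_total: int = 780
    read_len: int = 150
    p_escape: float = 0.0
    seed: int = 0
    sample_barcodes: tuple[str, ...] = ("S01",)

    def __post_init__(self) -> None:
        if self.size_min_total <= self.adapter_len:
            raise ValueError("size_min_total must exceed adapter_len")
        if not 0.0 <= self.p_escape <= 1.0:
            raise ValueError("p_escape must be in [0, 1]")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")

    @property
    def insert_window(self) -> tuple[int, int]:
        """Selected insert-length range implied by the total-length window."""
        return (
            self.size_min_total - self.adapter_len,
            self.size_max_total - self.adapter_len,
        )


def _draw_lengths(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.insert_distribution == "lognormal":
        x = rng.lognormal(np.log(config.insert_mean), config.insert_sigma, n)
    elif config.insert_distribution == "normal":
        x = rng.normal(config.insert_mean, config.insert_sigma, n)
    elif config.insert_distribution == "constant":
        x = np.full(n, config.insert_mean)
    else:
        raise ValueError(f"unknown insert distribution {config.insert_distribution!r}")
    return np.clip(np.round(x), config.insert_min, config.insert_max).astype(int)


def draw_inserts(
    genome: Genome, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw tagmentation inserts uniformly over the genome.

    Start positions are uniform over the concatenated genome (chromosomes
    weighted by length); lengths come from the configured model and the
    insert is constrained to lie within its chromosome. Inserts longer than
    the chosen chromosome are redrawn (bounded retries).

    Returns a DataFrame with columns chrom, start, end, length, barcode and
    an ``insert_id`` index.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = list(genome.sequences)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    if lengths.sum() == 0:
        raise ValueError("empty genome")
    weights = lengths / lengths.sum()

    n = config.n_inserts
    chrom_idx = np.empty(n, dtype=int)
    ins_len = np.empty(n, dtype=int)
    todo = np.arange(n)
    for _ in range(100):
        chrom_idx[todo] = rng.choice(len(chroms), size=len(todo), p=weights)
        ins_len[todo] = _draw_lengths(config, len(todo), rng)
        todo = todo[ins_len[todo] > lengths[chrom_idx[todo]]]
        if todo.size == 0:
            break
    else:
        raise RuntimeError(
            "could not place all inserts: insert lengths exceed chromosome sizes"
        )
    max_start = lengths[chrom_idx] - ins_len
    start = np.floor(rng.random(n) * (max_start + 1)).astype(int)
    barcodes = rng.choice(len(config.sample_barcodes), size=n)
    df = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(chrom_idx, categories=chroms),
            "start": start,
            "end": start + ins_len,
            "length": ins_len,
            "barcode": [config.sample_barcodes[i] for i in barcodes],
        }
    )
    df.index.name = "insert_id"
    return df


def apply_digestion(
    inserts: pd.DataFrame,
    panel: Panel,
    genome: Genome,
    p_escape: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mark site-containing inserts and apply digestion with escapes.

    Adds columns ``contains_site`` (a complete panel motif occurs in the
    insert on either strand), ``escaped`` (site-containing insert that
    survived, probability ``p_escape``) and ``fate`` (``digested`` or
    ``pending``).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rx = panel_regex(panel)
    contains = np.empty(len(inserts), dtype=bool)
    seqs = genome.sequences
    for i, (chrom, s, e) in enumerate(
        zip(inserts["chrom"], inserts["start"], inserts["end"])
    ):
        contains[i] = rx.search(seqs[chrom], s, e) is not None
    out = inserts.copy()
    out["contains_site"] = contains
    escaped = contains & (rng.random(len(out)) < p_escape)
    out["escaped"] = escaped
    out["fate"] = np.where(contains & ~escaped, "digested", "pending")
    return out


def size_select(inserts: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Resolve pending inserts into sequenced / size_excluded.

    A molecule is kept when insert length + adapter length lies within
    [size_min_total, size_max_total], both ends inclusive.
    """
    out = inserts.copy()
    total = out["length"] + config.adapter_len
    in_window = (total >= config.size_min_total) & (total <= config.size_max_total)
    pending = out["fate"] == "pending"
    out.loc[pending & in_window, "fate"] = "sequenced"
    out.loc[pending & ~in_window, "fate"] = "size_excluded"
    return out


@dataclass
class SimTruth:
    """Per-insert fates plus the residual-site summary of the emitted reads."""

    table: pd.DataFrame
    n_sequenced: int
    n_reads: int
    n_reads_with_site: int

    @property
    def fraction_reads_with_site(self) -> float:
        return self.n_reads_with_site / self.n_reads if self.n_reads else 0.0


def _open_out(path: str | Path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def emit_reads(
    inserts: pd.DataFrame,
    genome: Genome,
    config: SimConfig,
    panel: Panel,
    out_prefix: str | Path,
) -> SimTruth:
    """Write paired FASTQ for sequenced inserts plus a per-insert truth TSV.

    R1 is the first ``read_len`` bases of the insert; R2 the reverse
    complement of the last ``read_len`` bases (for inserts shorter than the
    read length both reads span the whole insert). Adapter bases are never
    emitted. Read names encode the barcode and insert id. Base qualities are
    uniform ('I'). Output FASTQ is gzipped when the prefix implies ``.gz``
    is wanted via ``out_prefix`` ending in ``.gz``-less path + default: the
    files are ``<prefix>_R1.fastq.gz`` and ``<prefix>_R2.fastq.gz``.
    """
    out_prefix = str(out_prefix)
    r1_path = out_prefix + "_R1.fastq.gz"
    r2_path = out_prefix + "_R2.fastq.gz"
    truth_path = out_prefix + ".truth.tsv"
    rx = panel_regex(panel)
    seqs = genome.sequences

    n_reads = 0
    n_with_site = 0
    read_site_flags = np.zeros(len(inserts), dtype=bool)
    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        qual = "I" * config.read_len
        for row in inserts[inserts["fate"] == "sequenced"].itertuples():
            ins = seqs[row.chrom][row.start : row.end]
            r1 = ins[: config.read_len]
            r2 = reverse_complement(ins[-config.read_len :])
            name = f"{row.barcode}:{row.Index}:{row.chrom}:{row.start}-{row.end}"
            f1.write(f"@{name}/1\n{r1}\n+\n{qual[: len(r1)]}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{qual[: len(r2)]}\n")
            n_reads += 2
            flags = [
                bool(rx.search(r)) or bool(rx.search(reverse_complement(r)))
                for r in (r1, r2)
            ]
            n_with_site += sum(flags)
            if any(flags):
                read_site_flags[row.Index] = True

    truth = inserts.copy()
    truth["read_contains_site"] = read_site_flags
    truth.to_csv(truth_path, sep="\t")
    return SimTruth(
        truth,
        int((truth["fate"] == "sequenced").sum()),
        n_reads,
        n_with_site,
    )


def simulate_library(
    genome: Genome,
    panel: Panel,
    config: SimConfig,
    out_prefix: str | Path | None = None,
) -> tuple[pd.DataFrame, SimTruth | None]:
    """Run the full pipeline: draw, digest, size-select and (optionally) emit.

    With ``out_prefix=None`` no FASTQ is written and only the fate table is
    returned.
    """
    rng = np.random.default_rng(config.seed)
    inserts = draw_inserts(genome, config, rng)
    inserts = apply_digestion(inserts, panel, genome, config.p_escape, rng)
    inserts = size_select(inserts, config)
    truth = None
    if out_prefix is not None:
        truth = emit_reads(inserts, genome, config, panel, out_prefix)
        inserts = truth.table
    return inserts, truth
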