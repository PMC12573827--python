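"""Screen sequencing reads for residual restriction-recognition sites.

After inverse-RAD digestion, reads that still contain a panel recognition
site are the footprint of incomplete digestion (or of sites destroyed by
variants in the sequenced accession). This module classifies reads per
enzyme, reports the per-enzyme and any-enzyme containment fractions, and
can emit a FASTQ with the site-containing reads (or pairs) removed.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass
from pathlib import Path

import pysam

from .core import Enzyme, Panel, iupac_regex, reverse_complement

__all__ = ["ScreenReport", "classify_read", "screen_fastq"]


def _enzyme_regex(enz: Enzyme) -> re.Pattern[str]:
    pats = [iupac_regex(enz.recognition)]
    if not enz.palindromic:
        pats.append(iupac_regex(reverse_complement(enz.recognition)))
    return re.compile("|".join(pats))


def classify_read(sequence: str, panel: Panel) -> dict[str, bool]:
    """Per-enzyme flags: does the read contain a complete recognition site?

    A flag is true when the enzyme's motif occurs in the read or in its
    reverse complement (identical for the palindromic built-ins). Read N
    bases match nothing; an empty read yields all-false.
    """
    seq = sequence.upper()
    rc = reverse_complement(seq)
    return {
        enz.name: bool(rx.search(seq)) or bool(rx.search(rc))
        for enz, rx in ((e, _enzyme_regex(e)) for e in panel)
    }


@dataclass
class ScreenReport:
    """Counts of site-containing reads (or pairs) for one panel."""

    panel_name: str
    unit: str  # "read" or "pair"
    n_units: int
    per_enzyme: dict[str, int]
    n_containing_any: int

    @property
    def fraction_without_any(self) -> float:
        if self.n_units == 0:
            return 0.0
        return 1.0 - self.n_containing_any / self.n_units

    def enzyme_fraction(self, name: str) -> float:
        return self.per_enzyme[name] / self.n_units if self.n_units else 0.0

    def to_dict(self) -> dict:
        return {
            "panel": self.panel_name,
            "unit": self.unit,
            "n_units": self.n_units,
            "n_containing_any": self.n_containing_any,
            "fraction_without_any": self.fraction_without_any,
            "per_enzyme": {
                name: {"n_containing": n, "fraction": self.enzyme_fraction(name)}
                for name, n in self.per_enzyme.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("enzyme\tn_containing\tfraction\n")
            for name, n in self.per_enzyme.items():
                fh.write(f"{name}\t{n}\t{self.enzyme_fraction(name):.6f}\n")
            fh.write(f"ANY\t{self.n_containing_any}\t{1 - self.fraction_without_any:.6f}\n")


def _open_out(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _write_record(fh, rec) -> None:
    qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
    comment = f" {rec.comment}" if rec.comment else ""
    fh.write(f"@{rec.name}{comment}\n{rec.sequence}\n+\n{qual}\n")


def screen_fastq(
    r1_path: str | Path,
    panel: Panel,
    r2_path: str | Path | None = None,
    filter_mode: str = "report",
    out_prefix: str | Path | None = None,
    per_read: bool = False,
) -> ScreenReport:
    """Stream one FASTQ (or a pair) and tally residual recognition sites.

    By default paired input is scored per *pair*: a pair counts as
    containing a site when either mate does, because the insert — not the
    read — is the unit digestion acts on. ``per_read=True`` scores each
    mate independently (single-end input is always per read).

    ``filter_mode="drop-containing"`` additionally writes
    ``<out_prefix>_R1.fastq.gz`` (and ``_R2``) with the containing
    reads/pairs removed, preserving record order.
    """
    if filter_mode not in ("report", "drop-containing"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    if filter_mode == "drop-containing" and out_prefix is None:
        raise ValueError("drop-containing mode needs out_prefix")
    regexes = {e.name: _enzyme_regex(e) for e in panel}

    paired = r2_path is not None
    unit = "read" if (per_read or not paired) else "pair"
    per_enzyme = {e.name: 0 for e in panel}
    n_units = 0
    n_any = 0

    out1 = out2 = None
    if filter_mode == "drop-containing":
        out1 = _open_out(f"{out_prefix}_R1.fastq.gz")
        if paired:
            out2 = _open_out(f"{out_prefix}_R2.fastq.gz")

    def flags_for(seq: str) -> dict[str, bool]:
        seq = seq.upper()
        rc = reverse_complement(seq)
        return {
            name: bool(rx.search(seq)) or bool(rx.search(rc))
            for name, rx in regexes.items()
        }

    try:
        with pysam.FastxFile(str(r1_path)) as fq1:
            if paired:
                fq2 = pysam.FastxFile(str(r2_path))
                it2 = iter(fq2)
            for rec1 in fq1:
                f1 = flags_for(rec1.sequence)
                if paired:
                    try:
                        rec2 = next(it2)
                    except StopIteration:
                        raise ValueError("R1 has more records than R2") from None
                    f2 = flags_for(rec2.sequence)
                    if unit == "pair":
                        combined = {k: f1[k] or f2[k] for k in f1}
                        n_units += 1
                        for k, v in combined.items():
                            per_enzyme[k] += v
                        any_hit = any(combined.values())
                        n_any += any_hit
                    else:
                        n_units += 2
                        for f in (f1, f2):
                            for k, v in f.items():
                                per_enzyme[k] += v
                        n_any += any(f1.values()) + any(f2.values())
                        any_hit = any(f1.values()) or any(f2.values())
                    if out1 is not None and not any_hit:
                        _write_record(out1, rec1)
                        _write_record(out2, rec2)
                else:
                    n_units += 1
                    for k, v in f1.items():
                        per_enzyme[k] += v
                    any_hit = any(f1.values())
                    n_any += any_hit
                    if out1 is not None and not any_hit:
                        _write_record(out1, rec1)
            if paired:
                try:
                    next(it2)
                except StopIteration:
                    pass
                else:
                    raise ValueError("R2 has more records than R1")
                fq2.close()
    finally:
        for fh in (out1, out2):
            if fh is not None:
                fh.close()

    return ScreenReport(panel.name, unit, n_units, per_enzyme, n_any)
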