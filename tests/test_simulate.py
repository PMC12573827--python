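"""Tagmentation library simulation: inserts, digestion, size selection, reads."""

import gzip

import numpy as np
import pandas as pd
import pytest

from iradsim.core import Genome, Panel, reverse_complement
from iradsim.digest import derive_fragments, scan_sites
from iradsim.simulate import (
    SimConfig,
    apply_digestion,
    draw_inserts,
    emit_reads,
    simulate_library,
    size_select,
)
from iradsim.synthetic import SynthGenomeConfig, synth_genome

from conftest import random_genome


@pytest.fixture(scope="module")
def sim_genome():
    g, _ = synth_genome(
        SynthGenomeConfig(n_chroms=2, chrom_length=100_000, target_site_spacing=800, seed=11)
    )
    return g


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(size_min_total=100, adapter_len=136)
    with pytest.raises(ValueError):
        SimConfig(p_escape=1.5)
    assert SimConfig().insert_window == (294, 644)


def test_draw_inserts_deterministic(sim_genome):
    cfg = SimConfig(n_inserts=500, seed=42)
    a = draw_inserts(sim_genome, cfg)
    b = draw_inserts(sim_genome, cfg)
    pd.testing.assert_frame_equal(a, b)


def test_chromosome_share_follows_length(rng):
    g = Genome({"small": "A" * 250_000, "big": "A" * 750_000})
    cfg = SimConfig(n_inserts=100_000, seed=1)
    ins = draw_inserts(g, cfg)
    share = (ins["chrom"] == "big").mean()
    sigma = np.sqrt(0.75 * 0.25 / 100_000)
    assert abs(share - 0.75) < 3 * sigma


def test_constant_length_model(sim_genome):
    cfg = SimConfig(n_inserts=200, insert_distribution="constant", insert_mean=400, seed=3)
    ins = draw_inserts(sim_genome, cfg)
    assert (ins["length"] == 400).all()
    assert (ins["end"] <= ins["chrom"].map(sim_genome.lengths).astype(int)).all()


def test_insert_longer_than_chromosome_errors():
    g = Genome({"c1": "ACGT" * 25})  # 100 bp
    cfg = SimConfig(
        n_inserts=10, insert_distribution="constant", insert_mean=500,
        insert_min=500, insert_max=500, seed=1,
    )
    with pytest.raises(RuntimeError, match="chromosome"):
        draw_inserts(g, cfg)


def test_digestion_no_escape_means_pending_site_free(sim_genome, panel_a, rng):
    cfg = SimConfig(n_inserts=2_000, seed=7)
    ins = apply_digestion(draw_inserts(sim_genome, cfg), panel_a, sim_genome, 0.0, rng)
    pending = ins[ins["fate"] == "pending"]
    assert not pending["contains_site"].any()
    digested = ins[ins["fate"] == "digested"]
    assert digested["contains_site"].all()


def test_full_escape_equals_no_digestion(sim_genome, panel_a):
    cfg = SimConfig(n_inserts=2_000, seed=7)
    base = draw_inserts(sim_genome, cfg)
    rng = np.random.default_rng(0)
    ins = apply_digestion(base, panel_a, sim_genome, 1.0, rng)
    assert (ins["fate"] == "pending").all()


def test_pending_inserts_lie_in_site_free_fragments(sim_genome, panel_a, rng):
    """Cross-module check: a site-free insert sits inside some maximal
    site-free fragment of the digestion model."""
    cfg = SimConfig(n_inserts=1_000, seed=9)
    ins = apply_digestion(draw_inserts(sim_genome, cfg), panel_a, sim_genome, 0.0, rng)
    frags = derive_fragments(
        scan_sites(sim_genome, panel_a), sim_genome, "maximal_site_free"
    )
    by_chrom = {c: [(f.start, f.end) for f in fl] for c, fl in frags.by_chrom().items()}
    for row in ins[ins["fate"] == "pending"].itertuples():
        assert any(
            s <= row.start and row.end <= e for s, e in by_chrom[row.chrom]
        ), (row.chrom, row.start, row.end)


def test_size_selection_window_arithmetic(sim_genome):
    # 294 + 136 = 430 (kept, lower edge); 645 + 136 = 781 (excluded)
    cfg = SimConfig()
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [0, 0, 0],
            "end": [294, 644, 645],
            "length": [294, 644, 645],
            "barcode": ["S01"] * 3,
            "contains_site": [False] * 3,
            "escaped": [False] * 3,
            "fate": ["pending"] * 3,
        }
    )
    out = size_select(df, cfg)
    assert out["fate"].tolist() == ["sequenced", "sequenced", "size_excluded"]


def test_fate_conservation(sim_genome, panel_a):
    cfg = SimConfig(n_inserts=5_000, p_escape=0.1, seed=13)
    ins, _ = simulate_library(sim_genome, panel_a, cfg)
    counts = ins["fate"].value_counts()
    assert set(ins["fate"]) <= {"digested", "size_excluded", "sequenced"}
    assert counts.sum() == cfg.n_inserts


def test_emit_reads_slicing(tmp_path):
    rng = np.random.default_rng(5)
    g = random_genome(rng, 1_000)
    ref = g["c1"]
    panel = Panel.from_names("MseI")
    cfg = SimConfig(read_len=150)
    df = pd.DataFrame(
        {
            "chrom": ["c1"],
            "start": [100],
            "end": [400],
            "length": [300],
            "barcode": ["S01"],
            "contains_site": [False],
            "escaped": [False],
            "fate": ["sequenced"],
        }
    )
    truth = emit_reads(df, g, cfg, panel, tmp_path / "sim")
    r1 = gzip.open(tmp_path / "sim_R1.fastq.gz", "rt").read().splitlines()
    r2 = gzip.open(tmp_path / "sim_R2.fastq.gz", "rt").read().splitlines()
    assert r1[1] == ref[100:250]
    assert r2[1] == reverse_complement(ref[250:400])
    assert truth.n_reads == 2
    assert (tmp_path / "sim.truth.tsv").exists()


def test_short_insert_reads_span_whole_insert(tmp_path):
    rng = np.random.default_rng(6)
    g = random_genome(rng, 500)
    cfg = SimConfig(read_len=150)
    df = pd.DataFrame(
        {
            "chrom": ["c1"], "start": [10], "end": [110], "length": [100],
            "barcode": ["S01"], "contains_site": [False], "escaped": [False],
            "fate": ["sequenced"],
        }
    )
    emit_reads(df, g, cfg, Panel.from_names("MseI"), tmp_path / "s")
    r1 = gzip.open(tmp_path / "s_R1.fastq.gz", "rt").read().splitlines()
    r2 = gzip.open(tmp_path / "s_R2.fastq.gz", "rt").read().splitlines()
    assert r1[1] == g["c1"][10:110]
    assert r2[1] == reverse_complement(g["c1"][10:110])


def test_empty_sequenced_set_valid_fastq(tmp_path, sim_genome, panel_a):
    df = pd.DataFrame(
        columns=["chrom", "start", "end", "length", "barcode",
                 "contains_site", "escaped", "fate"]
    )
    truth = emit_reads(df, sim_genome, SimConfig(), panel_a, tmp_path / "e")
    assert truth.n_reads == 0
    assert gzip.open(tmp_path / "e_R1.fastq.gz", "rt").read() == ""


def test_sequenced_fraction_shrinks_with_panel(sim_genome):
    """More enzymes digest more inserts (same insert stream)."""
    small = Panel.from_names("MseI")
    big = Panel.from_names("MseI,MspI,AluI")
    cfg = SimConfig(n_inserts=5_000, seed=21)
    base = draw_inserts(sim_genome, cfg)
    rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
    n_small = (
        size_select(apply_digestion(base, small, sim_genome, 0.0, rng1), cfg)["fate"]
        == "sequenced"
    ).sum()
    n_big = (
        size_select(apply_digestion(base, big, sim_genome, 0.0, rng2), cfg)["fate"]
        == "sequenced"
    ).sum()
    assert n_big <= n_small
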