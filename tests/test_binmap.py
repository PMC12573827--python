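"""Informative-marker selection, genotype coding, smoothing, breakpoints, bins."""

import numpy as np
import pandas as pd
import pytest

from iradsim.binmap import (
    Breakpoint,
    build_bin_map,
    call_breakpoints,
    code_progeny,
    genotype_population,
    select_informative,
    window_calls,
)
from iradsim.synthetic import BCPopulationConfig, simulate_bc_population


def _table(rows, lines=()):
    cols = ["chrom", "pos", "parent_A", "parent_B", *lines]
    return pd.DataFrame(rows, columns=cols)


def test_select_informative_keeps_homozygous_polymorphic():
    t = _table(
        [
            ("c1", 100, "G/G", "T/T"),   # informative
            ("c1", 200, "G/T", "T/T"),   # parent A heterozygous
            ("c1", 300, "A/A", "A/A"),   # monomorphic
            ("c1", 400, "./.", "T/T"),   # parent A missing
            ("c1", 500, "C", "A"),       # bare-allele form, informative
        ]
    )
    kept = select_informative(t)
    assert kept["pos"].tolist() == [100, 500]
    assert kept["parent_A"].tolist() == ["G", "C"]
    assert kept["parent_B"].tolist() == ["T", "A"]


def test_select_informative_matches_brute_force(rng):
    genos = ["A/A", "C/C", "G/G", "T/T", "A/C", "G/T", "./."]
    rows = [
        ("c1", i * 10, genos[rng.integers(len(genos))], genos[rng.integers(len(genos))])
        for i in range(1, 300)
    ]
    t = _table(rows)
    kept = select_informative(t)

    def informative(pa, pb):
        if "." in pa or "." in pb:
            return False
        a1, a2 = pa.split("/")
        b1, b2 = pb.split("/")
        return a1 == a2 and b1 == b2 and a1 != b1

    want = [pos for _, pos, pa, pb in rows if informative(pa, pb)]
    assert kept["pos"].tolist() == want


def test_zero_informative_is_empty():
    t = _table([("c1", 100, "A/A", "A/A")])
    assert select_informative(t).empty


@pytest.mark.parametrize(
    "gt,code",
    [("G/G", "A"), ("T/T", "B"), ("G/T", "H"), ("T/G", "H"), ("./.", "U"), ("C/C", "U")],
)
def test_code_progeny_rules(gt, code):
    t = _table([("c1", 100, "G/G", "T/T", gt)], lines=["L1"])
    markers = select_informative(t)
    coded = code_progeny(markers)
    assert coded["L1"].tolist() == [code]


def test_window_calls_uniform_track():
    pos = np.arange(1, 21) * 1_000
    codes = np.array(["A"] * 20)
    p, states = window_calls(pos, codes, w=15)
    assert (states == "A").all()
    assert (p == pos).all()


def test_window_calls_alternating_carries_state():
    """A 50/50 mixture never reaches purity: the call carries over."""
    pos = np.arange(1, 41) * 1_000
    codes = np.array(["A", "B"] * 20)
    _, states = window_calls(pos, codes, w=15, purity=0.8)
    assert len(set(states)) == 1  # one carried state, no spurious breakpoints


def test_window_calls_short_chromosome_majority():
    pos = np.array([100, 200, 300])
    codes = np.array(["B", "B", "A"])
    _, states = window_calls(pos, codes, w=15)
    assert (states == "B").all()


def test_window_calls_skips_uninformative():
    pos = np.arange(1, 26) * 100
    codes = np.array(["A"] * 10 + ["U"] * 5 + ["A"] * 10)
    p, states = window_calls(pos, codes, w=15)
    assert len(p) == 20
    assert (states == "A").all()


def test_window_calls_detects_planted_crossover():
    """One crossover, 1% noise: the transition lands within one window."""
    rng = np.random.default_rng(42)
    n = 200
    pos = np.arange(1, n + 1) * 20_000
    truth = np.array(["A"] * 100 + ["B"] * 100)
    codes = truth.copy()
    for i in np.flatnonzero(rng.random(n) < 0.01):
        codes[i] = rng.choice([s for s in "AHB" if s != truth[i]])
    p, states = window_calls(pos, codes, w=15)
    flips = np.flatnonzero(states[1:] != states[:-1])
    assert len(flips) == 1
    assert abs(int(flips[0]) + 1 - 100) <= 15


def test_call_breakpoints_single_transition():
    pos = np.arange(1, 9) * 100
    states = np.array(list("AAAABBBB"))
    bps = call_breakpoints(pos, states, "c1", "L1")
    assert len(bps) == 1
    bp = bps[0]
    assert (bp.left_pos, bp.right_pos) == (400, 500)
    assert (bp.left_state, bp.right_state) == ("A", "B")
    assert bp.midpoint == 450


def test_call_breakpoints_none_on_uniform():
    pos = np.arange(1, 9) * 100
    assert call_breakpoints(pos, np.array(["A"] * 8), "c1", "L1") == []


def test_purity_monotonicity():
    """Raising purity never increases the number of called breakpoints."""
    rng = np.random.default_rng(9)
    n = 600
    pos = np.arange(1, n + 1) * 10_000
    truth = np.array(["A"] * 200 + ["H"] * 200 + ["B"] * 200)
    codes = truth.copy()
    for i in np.flatnonzero(rng.random(n) < 0.05):
        codes[i] = rng.choice([s for s in "AHB" if s != truth[i]])
    counts = []
    for purity in (0.6, 0.7, 0.8, 0.9):
        _, states = window_calls(pos, codes, w=15, purity=purity)
        counts.append(len(call_breakpoints(pos, states, "c", "l")))
    assert counts == sorted(counts, reverse=True)


def test_build_bin_map_two_lines_three_bins():
    L = 3_000_000
    pos = np.arange(1, 31) * 100_000
    t1 = np.array(["A"] * 10 + ["B"] * 20)
    t2 = np.array(["A"] * 20 + ["H"] * 10)
    tracks = {"L1": {"c1": (pos, t1)}, "L2": {"c1": (pos, t2)}}
    bps = call_breakpoints(pos, t1, "c1", "L1") + call_breakpoints(pos, t2, "c1", "L2")
    bm = build_bin_map(bps, tracks, {"c1": L})
    assert bm.n_bins == 3
    assert bm.bins["start"].tolist() == [0, 1_050_000, 2_050_000]
    assert bm.bins["end"].tolist() == [1_050_000, 2_050_000, L]
    assert bm.bins["L1"].tolist() == ["A", "B", "B"]
    assert bm.bins["L2"].tolist() == ["A", "A", "H"]
    # tiling conservation
    assert (bm.bins["end"] - bm.bins["start"]).sum() == L


def test_no_breakpoints_one_bin_per_chromosome():
    pos = np.arange(1, 11) * 1_000
    tracks = {"L1": {"c1": (pos, np.array(["A"] * 10)), "c2": (pos, np.array(["B"] * 10))}}
    bm = build_bin_map([], tracks, {"c1": 10_000, "c2": 10_000})
    assert bm.n_bins == 2


def test_adjacent_identical_bins_merged():
    """Bins whose state vectors agree across all lines collapse."""
    cfg = BCPopulationConfig(n_lines=8, n_chroms=2, chrom_length=5_000_000, seed=13)
    table, truth = simulate_bc_population(cfg)
    _, _, bps, bm = genotype_population(table, truth.chrom_lengths)
    lines = bm.line_columns()
    for chrom in ("chr1", "chr2"):
        sub = bm.bins[bm.bins["chrom"] == chrom].reset_index(drop=True)
        for i in range(1, len(sub)):
            assert any(sub.loc[i, ln] != sub.loc[i - 1, ln] for ln in lines)
        # tiling
        assert (sub["end"] - sub["start"]).sum() == 5_000_000
        assert (sub["start"].iloc[1:].to_numpy() == sub["end"].iloc[:-1].to_numpy()).all()


def test_breakpoint_count_recovery_poisson2():
    """~2 crossovers per line on one long chromosome: called count within 10%."""
    cfg = BCPopulationConfig(
        n_lines=50, n_chroms=1, chrom_length=60_000_000,
        crossovers_per_chrom=2.0, seed=31,
    )
    table, truth = simulate_bc_population(cfg)
    _, _, bps, _ = genotype_population(table, truth.chrom_lengths)
    planted = len(truth.crossovers)
    assert planted > 0
    assert abs(len(bps) - planted) / planted <= 0.10


def test_genotype_population_requires_informative():
    t = _table([("c1", 100, "A/A", "A/A", "A/A")], lines=["L1"])
    with pytest.raises(ValueError, match="informative"):
        genotype_population(t, {"c1": 1_000})
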