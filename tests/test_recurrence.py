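"""Extreme thresholds, sweep-line recurrent regions, gene frequencies."""

import numpy as np
import pandas as pd
import pytest

import cnaburden as cb
from oracles import brute_force_regions, percentile_type7


def _events(rows):
    """Rows of (sample, chrom, start, end, cn, direction) -> event frame."""
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                     "cn", "direction"])
    df["size"] = df["end"] - df["start"]
    return df


def _random_toy_events(rng, n_samples=6, genome_len=10_000):
    rows = []
    for s in range(rng.integers(2, n_samples + 1)):
        for _ in range(rng.integers(0, 6)):
            start = int(rng.integers(0, genome_len - 100))
            end = int(start + rng.integers(50, 3000))
            gain = rng.uniform() < 0.55
            cn = float(rng.uniform(2.4, 6.0)) if gain else float(rng.uniform(0.4, 1.6))
            rows.append((f"S{s}", "chr1", start, min(end, genome_len),
                         cn, "gain" if gain else "loss"))
    return _events(rows)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_percentile_thresholds_match_rank_arithmetic():
    abnormal = [0.5, 0.8, 1.0, 1.2, 1.4, 3.0, 3.5, 4.0, 5.0, 6.0]
    seg = pd.DataFrame({"cn": abnormal + [2.0, 2.1]})
    thr = cb.extreme_thresholds(seg)
    assert thr.low == pytest.approx(percentile_type7(abnormal, 0.10))
    assert thr.high == pytest.approx(percentile_type7(abnormal, 0.90))
    assert thr.low == pytest.approx(0.77)
    assert thr.high == pytest.approx(5.1)
    assert thr.mode == "percentile"


def test_degenerate_percentiles_collapse_to_shared_value():
    seg = pd.DataFrame({"cn": [3.5] * 12})
    thr = cb.extreme_thresholds(seg)
    assert thr.low == thr.high == 3.5


def test_no_abnormal_segments_is_error():
    seg = pd.DataFrame({"cn": [2.0, 2.1, 1.9]})
    with pytest.raises(ValueError, match="no abnormal"):
        cb.extreme_thresholds(seg)


# ---------------------------------------------------------------------------
# recurrent regions
# ---------------------------------------------------------------------------

def test_no_extreme_events_no_regions():
    ev = _events([("S1", "chr1", 0, 100, 2.5, "gain")])   # not extreme
    assert cb.recurrent_regions(ev, "gain").empty


def test_staggered_gain_ladder_support_profile():
    """Staggered gains with support 1,2,3,3,2,1 across six atoms: one region
    over the >=2 atoms whose core is the >=3 stretch."""
    ev = _events([
        ("S1", "chr1", 0, 30, 5.0, "gain"),
        ("S2", "chr1", 10, 40, 5.0, "gain"),
        ("S3", "chr1", 20, 50, 5.0, "gain"),
        ("S4", "chr1", 30, 60, 5.0, "gain"),
    ])
    regions = cb.recurrent_regions(ev, "gain", min_core=3, min_flank=2)
    assert len(regions) == 1
    r = regions.iloc[0]
    assert (r["start"], r["end"]) == (10, 50)
    assert (r["core_start"], r["core_end"]) == (20, 40)
    assert r["core_support"] == 3
    assert bool(r["flank_extended"]) is True


@pytest.mark.parametrize("seed", range(40))
def test_sweep_line_equals_per_base_counting(seed):
    rng = np.random.default_rng(seed)
    ev = _random_toy_events(rng)
    thr = cb.ExtremeThresholds()
    for direction in ("gain", "loss"):
        got = cb.recurrent_regions(ev, direction, thr, min_core=3, min_flank=2)
        exp = brute_force_regions(ev, direction, thr.low, thr.high,
                                  min_core=3, min_flank=2, genome_len=10_000)
        assert len(got) == len(exp)
        for g, e in zip(got.to_dict("records"), exp):
            assert (g["start"], g["end"]) == (e["start"], e["end"])
            assert (g["core_start"], g["core_end"]) == (e["core_start"], e["core_end"])
            assert g["core_support"] == e["core_support"]


def test_support_counts_distinct_samples_not_events():
    ev = _events([
        ("S1", "chr1", 0, 100, 5.0, "gain"),
        ("S1", "chr1", 50, 150, 4.0, "gain"),   # same sample, overlapping
        ("S2", "chr1", 0, 150, 5.0, "gain"),
        ("S3", "chr1", 0, 150, 5.0, "gain"),
    ])
    regions = cb.recurrent_regions(ev, "gain", min_core=3, min_flank=2)
    assert len(regions) == 1
    assert regions.iloc[0]["core_support"] == 3     # S1 counted once


def test_raising_min_core_never_adds_regions(rng):
    for seed in range(10):
        ev = _random_toy_events(np.random.default_rng(seed))
        n3 = len(cb.recurrent_regions(ev, "gain", min_core=3))
        n4 = len(cb.recurrent_regions(ev, "gain", min_core=4))
        assert n4 <= n3


def test_invalid_direction_rejected():
    ev = _events([("S1", "chr1", 0, 100, 5.0, "gain")])
    with pytest.raises(ValueError, match="direction"):
        cb.recurrent_regions(ev, "amplification")


# ---------------------------------------------------------------------------
# gene frequencies
# ---------------------------------------------------------------------------

def test_gene_overlapping_nothing_counts_zero():
    ev = _events([("S1", "chr1", 0, 100, 5.0, "gain")])
    genes = pd.DataFrame([{"gene": "G", "chrom": "chr2", "start": 0, "end": 50}])
    with pytest.warns(UserWarning, match="absent"):
        freq = cb.gene_cna_frequency(ev, genes, "gain")
    assert freq.iloc[0]["n_cases"] == 0


@pytest.mark.parametrize("seed", range(15))
def test_gene_counts_match_quadratic_overlap_oracle(seed):
    rng = np.random.default_rng(seed)
    ev = _random_toy_events(rng)
    genes = pd.DataFrame([{"gene": f"G{i}", "chrom": "chr1",
                           "start": int(rng.integers(0, 9000)),
                           "end": int(rng.integers(0, 9000)) + 200}
                          for i in range(5)])
    genes["end"] = genes[["start", "end"]].max(axis=1) + 1
    thr = cb.ExtremeThresholds()
    for direction in ("gain", "loss"):
        freq = cb.gene_cna_frequency(ev, genes, direction, thr)
        for _, row in freq.iterrows():
            expected = set()
            for r in ev.itertuples(index=False):
                extreme = r.cn > thr.high if direction == "gain" else r.cn < thr.low
                if (r.direction == direction and extreme and r.chrom == row["chrom"]
                        and r.start < row["end"] and r.end > row["start"]):
                    expected.add(r.sample_id)
            assert row["n_cases"] == len(expected)


def test_gene_counts_invariant_to_event_splitting(rng):
    ev = _events([("S1", "chr1", 100, 500, 5.0, "gain"),
                  ("S2", "chr1", 200, 400, 5.0, "gain")])
    split = _events([("S1", "chr1", 100, 300, 5.0, "gain"),
                     ("S1", "chr1", 300, 500, 5.0, "gain"),
                     ("S2", "chr1", 200, 400, 5.0, "gain")])
    genes = pd.DataFrame([{"gene": "G", "chrom": "chr1", "start": 250, "end": 350}])
    a = cb.gene_cna_frequency(ev, genes, "gain").iloc[0]["n_cases"]
    b = cb.gene_cna_frequency(split, genes, "gain").iloc[0]["n_cases"]
    assert a == b == 2


def test_kinase_union_semantics():
    genes = pd.DataFrame([
        {"gene": "ERBB2", "chrom": "chr17", "start": 100, "end": 200},
        {"gene": "EGFR", "chrom": "chr7", "start": 100, "end": 200},
        {"gene": "MET", "chrom": "chr7", "start": 500, "end": 600},
        {"gene": "KRAS", "chrom": "chr12", "start": 100, "end": 200},
    ])
    no_gain = _events([("S1", "chr17", 100, 200, 1.0, "loss")])
    assert cb.kinase_gain_cases(no_gain, genes) == 0
    double = _events([("S1", "chr17", 50, 250, 6.0, "gain"),
                      ("S1", "chr7", 50, 250, 6.0, "gain"),
                      ("S2", "chr12", 150, 180, 6.0, "gain")])
    assert cb.kinase_gain_cases(double, genes) == 2    # S1 counts once
    with pytest.raises(ValueError, match="provide all"):
        cb.kinase_gain_cases(double, genes.iloc[:2])
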