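"""Independent brute-force oracles used by the test suite.

Each oracle deliberately re-derives a quantity by the most transparent means
available (row-by-row iteration, per-base counting, rank arithmetic,
expected-event accounting) and never calls the implementation path it
checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CN_PALETTE = (0.5, 1.0, 1.5, 1.69, 1.7, 2.0, 2.3, 2.31, 2.5, 3.0, 3.0 + 3e-3, 4.1)


def random_segment_table(rng: np.random.Generator, max_rows: int = 12,
                         n_samples: int = 2,
                         chroms: tuple[str, ...] = ("chr1", "chr2")) -> pd.DataFrame:
    """Small random segment table exercising gaps, adjacency and near-ties."""
    rows = []
    for s in range(rng.integers(1, n_samples + 1)):
        sid = f"S{s}"
        for chrom in chroms[: rng.integers(1, len(chroms) + 1)]:
            pos = int(rng.integers(0, 1000))
            for _ in range(rng.integers(0, max_rows + 1)):
                if rng.uniform() < 0.35:
                    pos += int(rng.integers(1, 5000))
                length = int(rng.integers(100, 20000))
                rows.append((sid, chrom, pos, pos + length,
                             int(rng.integers(1, 50)),
                             float(rng.choice(CN_PALETTE))))
                pos += length
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                       "n_markers", "cn"])


def brute_force_cnas(segments: pd.DataFrame,
                     normal_range: tuple[float, float] = (1.7, 2.3),
                     tol: float = 5e-3) -> pd.DataFrame:
    """Row-by-row enumeration of maximal contiguous equal-cn abnormal runs."""
    lo, hi = normal_range
    out: list[dict] = []

    def flush(run, sid, chrom):
        if not run:
            return
        w = sum(r.n_markers for r in run)
        cn = sum(r.cn * r.n_markers for r in run) / w
        out.append({"sample_id": sid, "chrom": chrom,
                    "start": run[0].start, "end": run[-1].end,
                    "cn": cn, "direction": "gain" if cn > hi else "loss",
                    "size": run[-1].end - run[0].start,
                    "member_segments": len(run), "n_markers": w})

    for (sid, chrom), sub in segments.groupby(["sample_id", "chrom"], sort=True):
        run: list = []
        for r in sub.sort_values("start").itertuples(index=False):
            abnormal = (r.cn < lo) or (r.cn > hi)
            if not abnormal:
                flush(run, sid, chrom)
                run = []
                continue
            if run and run[-1].end == r.start and abs(run[-1].cn - r.cn) <= tol:
                run.append(r)
            else:
                flush(run, sid, chrom)
                run = [r]
        flush(run, sid, chrom)
    cols = ["sample_id", "chrom", "start", "end", "cn", "direction", "size",
            "member_segments", "n_markers"]
    return pd.DataFrame(out, columns=cols)


def refine_segments(segments: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Split random rows into two adjacent rows with identical cn."""
    rows = []
    for r in segments.itertuples(index=False):
        if r.end - r.start >= 2 and rng.uniform() < 0.5:
            mid = int(rng.integers(r.start + 1, r.end))
            m1 = max(int(r.n_markers) // 2, 1)
            m2 = max(int(r.n_markers) - m1, 1)
            rows.append((r.sample_id, r.chrom, r.start, mid, m1, r.cn))
            rows.append((r.sample_id, r.chrom, mid, r.end, m2, r.cn))
        else:
            rows.append(tuple(r))
    return pd.DataFrame(rows, columns=segments.columns)


def brute_force_regions(events: pd.DataFrame, direction: str,
                        low: float, high: float, min_core: int, min_flank: int,
                        genome_len: int) -> list[dict]:
    """Per-base distinct-sample support counting on a small genome."""
    regions = []
    for chrom in sorted(events["chrom"].unique()):
        cov = np.zeros(genome_len, dtype=int)
        sub = events[events["chrom"] == chrom]
        for _sid, se in sub.groupby("sample_id"):
            mask = np.zeros(genome_len, dtype=bool)
            for r in se.itertuples(index=False):
                extreme = r.cn > high if direction == "gain" else r.cn < low
                if r.direction == direction and extreme:
                    mask[r.start:r.end] = True
            cov += mask
        in_run = cov >= min_flank
        b = 0
        while b < genome_len:
            if not in_run[b]:
                b += 1
                continue
            e = b
            while e < genome_len and in_run[e]:
                e += 1
            core = np.nonzero(cov[b:e] >= min_core)[0]
            if len(core):
                regions.append({
                    "chrom": chrom, "start": b, "end": e,
                    "core_start": b + int(core[0]),
                    "core_end": b + int(core[-1]) + 1,
                    "core_support": int(cov[b:e].max()),
                })
            b = e
    return regions


def percentile_type7(values, q: float) -> float:
    """Linear interpolation between order statistics (Hyndman–Fan type 7)."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    if lo + 1 >= len(v):
        return float(v[-1])
    return float(v[lo] + (h - lo) * (v[lo + 1] - v[lo]))


def quantile_type6(values, q: float) -> float:
    """SPSS weighted-average quantile (Hyndman–Fan type 6)."""
    v = sorted(values)
    h = (len(v) + 1) * q
    lo = int(np.floor(h))
    if lo < 1:
        return float(v[0])
    if lo >= len(v):
        return float(v[-1])
    return float(v[lo - 1] + (h - lo) * (v[lo] - v[lo - 1]))


def logrank_chi2(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by expected-event accounting."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a = np.asarray(events_a, bool)
    events_b = np.asarray(events_b, bool)
    all_event_times = np.unique(np.concatenate([times_a[events_a], times_b[events_b]]))
    O_a = E_a = V = 0.0
    for t in all_event_times:
        n_a = np.sum(times_a >= t)
        n_b = np.sum(times_b >= t)
        n = n_a + n_b
        d = np.sum((times_a == t) & events_a) + np.sum((times_b == t) & events_b)
        d_a = np.sum((times_a == t) & events_a)
        O_a += d_a
        E_a += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return float((O_a - E_a) ** 2 / V)


def fisher_2x2_two_sided(tab: np.ndarray) -> float:
    """Exhaustive hypergeometric enumeration; two-sided by probability mass."""
    from math import comb
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return float(total)
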