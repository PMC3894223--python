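"""Independent-CNA calling and the total CNA count.

The unit of the burden statistic is the *independent CNA*: a maximal run of
contiguous segments whose copy number lies strictly outside the diploid
normal range (closed interval, default [1.7, 2.3]) and is identical along the
run. Two surviving segments are contiguous iff they are adjacent rows of the
segment table with zero genomic gap (``end == start``) and no intervening
normal segment; contiguous segments with *unequal* copy number remain
separate events, so every copy-number step contributes one event — making the
total count essentially a breakpoint count. "Identical" copy number is
equality within a small tolerance (default 5e-3), since estimated copy
numbers are floats; the tolerance sits below any plausible estimation
granularity and is configurable.

Per-tumor segmental aneuploidy is quantified as the total number of
independent CNAs; gains are events with copy number above the normal range,
losses below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import validate_segments

SIZE_BIN_EDGES = (1_000, 10_000, 100_000, 1_000_000, 10_000_000)
SIZE_BIN_LABELS = ("<1kb", "1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")

EVENT_COLUMNS = ["sample_id", "chrom", "start", "end", "cn", "direction",
                 "size", "member_segments", "n_markers"]


def call_cnas(segments: pd.DataFrame,
              normal_range: tuple[float, float] = (1.7, 2.3),
              cn_tolerance: float = 5e-3,
              merge_across_gaps: bool = False,
              chromosomes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Call independent CNAs from a segment table.

    Steps: (1) drop segments whose copy number lies inside the closed normal
    interval; (2) mark surviving segments contiguous iff they were adjacent
    rows with ``end == start`` (``merge_across_gaps=True`` relaxes the
    zero-gap requirement but an intervening normal segment still separates);
    (3) merge contiguous runs whose copy numbers agree within
    ``cn_tolerance`` into one event with marker-weighted mean copy number;
    contiguous segments with unequal copy number stay separate events.

    Returns one row per event with columns
    ``sample_id, chrom, start, end, cn, direction, size, member_segments,
    n_markers``.
    """
    lo, hi = normal_range
    if lo >= hi:
        raise ValueError("normal_range must satisfy lo < hi")
    if chromosomes is None:
        chromosomes = tuple(dict.fromkeys(segments["chrom"]))
    seg = validate_segments(segments, chromosomes)
    seg["_row"] = np.arange(len(seg))

    cn = seg["cn"].to_numpy()
    abnormal = (cn < lo) | (cn > hi)           # boundary values are NORMAL
    ab = seg[abnormal]
    if ab.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)

    same_block = (ab["sample_id"].eq(ab["sample_id"].shift())
                  & ab["chrom"].eq(ab["chrom"].shift())
                  & ab["_row"].eq(ab["_row"].shift() + 1)   # no intervening row
                  & (ab["cn"] - ab["cn"].shift()).abs().le(cn_tolerance))
    if not merge_across_gaps:
        same_block &= ab["start"].eq(ab["end"].shift())     # zero genomic gap
    event_id = (~same_block).cumsum()

    weighted = ab["cn"] * ab["n_markers"]
    grouped = ab.assign(_w=weighted).groupby(event_id, sort=True)
    events = grouped.agg(
        sample_id=("sample_id", "first"), chrom=("chrom", "first"),
        start=("start", "min"), end=("end", "max"),
        _w=("_w", "sum"), n_markers=("n_markers", "sum"),
        member_segments=("cn", "size"))
    events["cn"] = events.pop("_w") / events["n_markers"]
    events["direction"] = np.where(events["cn"] > hi, "gain", "loss")
    events["size"] = events["end"] - events["start"]
    return events[EVENT_COLUMNS].reset_index(drop=True)


def total_cna_count(events: pd.DataFrame) -> int:
    """Total independent-CNA count for a single sample's events (pure count)."""
    if len(events) and events["sample_id"].nunique() > 1:
        raise ValueError("events from multiple samples; use count_per_sample")
    return int(len(events))


def count_per_sample(events: pd.DataFrame,
                     samples: list[str] | None = None) -> pd.Series:
    """Per-sample total CNA counts; ``samples`` adds zero-count tumors."""
    counts = events.groupby("sample_id").size() if len(events) else pd.Series(dtype=int)
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    return counts.astype(int).rename("total_cna_count")


def size_bin_fractions(sizes: np.ndarray) -> dict[str, float]:
    """Fractions in the six size bins (left-closed edges 1 kb .. 10 Mb)."""
    if len(sizes) == 0:
        return {lab: float("nan") for lab in SIZE_BIN_LABELS}
    which = np.searchsorted(np.asarray(SIZE_BIN_EDGES), np.asarray(sizes), side="right")
    return {lab: float(np.mean(which == i)) for i, lab in enumerate(SIZE_BIN_LABELS)}


@dataclass
class BurdenSummary:
    """Per-tumor (or pooled) CNA burden: counts, direction split, sizes."""
    sample_id: str
    total_cna_count: int
    gain_count: int
    loss_count: int
    median_size: float                    # bp; NaN when there are no events
    size_bin_fractions: dict[str, float]


def burden_summary(events: pd.DataFrame, sample_id: str | None = None) -> BurdenSummary:
    """Summarize one sample's events (or a pooled table with sample_id='ALL')."""
    if sample_id is None:
        ids = events["sample_id"].unique() if len(events) else []
        sample_id = ids[0] if len(ids) == 1 else "ALL"
    sizes = events["size"].to_numpy() if len(events) else np.array([])
    gains = int((events["direction"] == "gain").sum()) if len(events) else 0
    return BurdenSummary(
        sample_id=sample_id,
        total_cna_count=int(len(events)),
        gain_count=gains,
        loss_count=int(len(events)) - gains,
        median_size=float(np.median(sizes)) if len(sizes) else float("nan"),
        size_bin_fractions=size_bin_fractions(sizes),
    )


def burden_table(events: pd.DataFrame,
                 samples: list[str] | None = None) -> pd.DataFrame:
    """Per-sample burden summaries as a DataFrame (zero rows for CNA-free tumors)."""
    ids = samples if samples is not None else sorted(events["sample_id"].unique())
    rows = []
    for sid in ids:
        s = burden_summary(events[events["sample_id"] == sid], sample_id=sid)
        row = {"sample_id": s.sample_id, "total_cna_count": s.total_cna_count,
               "gain_count": s.gain_count, "loss_count": s.loss_count,
               "median_size": s.median_size}
        row.update({f"frac_{lab}": v for lab, v in s.size_bin_fractions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def counts_by_chromosome(events: pd.DataFrame,
                         samples: list[str] | None = None,
                         chromosomes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Samples x chromosomes table of CNA counts."""
    if chromosomes is None:
        chromosomes = tuple(dict.fromkeys(events["chrom"]))
    pivot = (events.groupby(["sample_id", "chrom"]).size().unstack(fill_value=0)
             if len(events) else pd.DataFrame())
    pivot = pivot.reindex(columns=list(chromosomes), fill_value=0)
    if samples is not None:
        pivot = pivot.reindex(samples, fill_value=0)
    return pivot.astype(int)
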