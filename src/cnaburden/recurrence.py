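"""Recurrent extreme-CNA regions and gene-level CNA frequencies.

Candidate target regions are identified by a count-based heuristic: an
*extreme* CNA is one whose copy number falls outside a pair of thresholds —
either fixed (default 1.474 / 3.025, the values derived from the original
cohort) or recomputed as the 10th/90th percentile copy number of all
segments outside the normal range, pooled across samples and unweighted by
size or marker count. A *core* region carries extreme CNA of one direction
in at least ``min_core`` distinct tumors (default 3); its lateral boundaries
are extended conservatively through flanking positions supported by at least
``min_flank`` tumors (default 2). Support counts distinct samples, never
events, so a tumor with two overlapping extreme gains contributes once.

Gene-level frequency is the number of distinct samples with at least one
extreme event of the given direction overlapping any portion of the gene
span (>= 1 bp under half-open arithmetic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExtremeThresholds:
    """Copy-number cuts defining extreme CNA (strictly outside [low, high])."""
    low: float = 1.474
    high: float = 3.025
    mode: str = "fixed"           # "fixed" | "percentile"

    def __post_init__(self):
        # low == high can legitimately arise from degenerate percentiles
        if self.low > self.high:
            raise ValueError("extreme thresholds must satisfy low <= high")


def extreme_thresholds(segments: pd.DataFrame,
                       normal_range: tuple[float, float] = (1.7, 2.3),
                       ) -> ExtremeThresholds:
    """10th/90th percentile copy number of all abnormal segments, pooled.

    Percentiles use linear interpolation between order statistics (the
    common type-7 convention). Segments are unweighted; all samples pool.
    """
    lo, hi = normal_range
    cn = segments["cn"].to_numpy()
    ab = cn[(cn < lo) | (cn > hi)]
    if len(ab) == 0:
        raise ValueError("no abnormal segments; percentile thresholds undefined")
    if len(ab) < 10:
        warnings.warn(f"only {len(ab)} abnormal segments; percentile thresholds "
                      "will be unstable")
    low, high = np.percentile(ab, [10, 90])
    return ExtremeThresholds(low=float(low), high=float(high), mode="percentile")


def extreme_events(events: pd.DataFrame, thresholds: ExtremeThresholds,
                   direction: str) -> pd.DataFrame:
    """Events of one direction with copy number beyond the extreme cut."""
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    if direction == "gain":
        mask = events["cn"] > thresholds.high
    else:
        mask = events["cn"] < thresholds.low
    return events[mask & (events["direction"] == direction)]


def _merge_sample_intervals(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Union of one sample's intervals on one chromosome (sorted, merged)."""
    order = np.argsort(sub["start"].to_numpy(), kind="stable")
    starts = sub["start"].to_numpy()[order]
    ends = sub["end"].to_numpy()[order]
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def recurrent_regions(events: pd.DataFrame, direction: str,
                      thresholds: ExtremeThresholds | None = None,
                      min_core: int = 3, min_flank: int = 2) -> pd.DataFrame:
    """Sweep-line discovery of recurrent extreme-CNA regions of one direction.

    The breakpoints of all extreme events partition each chromosome into
    atoms; per-atom support is the number of distinct samples whose extreme
    events cover the atom. Each maximal run of atoms with support >=
    ``min_flank`` that contains at least one atom with support >= ``min_core``
    is emitted as one region; flank-only runs are discarded.

    Returns columns ``chrom, start, end, direction, core_start, core_end,
    core_support, flank_extended``.
    """
    thresholds = thresholds or ExtremeThresholds()
    ev = extreme_events(events, thresholds, direction)
    out_rows = []
    for chrom, chrom_ev in ev.groupby("chrom", sort=False):
        starts_all, ends_all = [], []
        for _sid, sub in chrom_ev.groupby("sample_id"):
            s, e = _merge_sample_intervals(sub)
            starts_all.append(s)
            ends_all.append(e)
        starts = np.sort(np.concatenate(starts_all))
        ends = np.sort(np.concatenate(ends_all))
        bps = np.unique(np.concatenate([starts, ends]))
        atom_lo = bps[:-1]
        atom_hi = bps[1:]
        # distinct-sample support: per-sample intervals are disjoint, so
        # coverage depth == number of covering samples
        support = (np.searchsorted(starts, atom_lo, side="right")
                   - np.searchsorted(ends, atom_lo, side="right"))
        run_start = None
        core_atoms: list[int] = []
        peak = 0
        for i in range(len(atom_lo) + 1):
            in_run = i < len(atom_lo) and support[i] >= min_flank
            if in_run and run_start is None:
                run_start, core_atoms, peak = i, [], 0
            if in_run:
                peak = max(peak, int(support[i]))
                if support[i] >= min_core:
                    core_atoms.append(i)
            if not in_run and run_start is not None:
                if core_atoms:
                    r_lo, r_hi = int(atom_lo[run_start]), int(atom_hi[i - 1])
                    c_lo = int(atom_lo[core_atoms[0]])
                    c_hi = int(atom_hi[core_atoms[-1]])
                    out_rows.append({
                        "chrom": chrom, "start": r_lo, "end": r_hi,
                        "direction": direction,
                        "core_start": c_lo, "core_end": c_hi,
                        "core_support": peak,
                        "flank_extended": (r_lo < c_lo) or (r_hi > c_hi),
                    })
                run_start = None
    cols = ["chrom", "start", "end", "direction", "core_start", "core_end",
            "core_support", "flank_extended"]
    return pd.DataFrame(out_rows, columns=cols)


def gene_cna_frequency(events: pd.DataFrame, genes: pd.DataFrame,
                       direction: str,
                       thresholds: ExtremeThresholds | None = None) -> pd.DataFrame:
    """Distinct-sample counts of extreme CNA overlapping each gene span.

    A sample counts for a gene if it has >= 1 extreme event of the given
    direction whose interval overlaps the gene span by >= 1 bp (half-open).
    Genes on chromosomes absent from the event data get count 0 with a
    warning.
    """
    thresholds = thresholds or ExtremeThresholds()
    ev = extreme_events(events, thresholds, direction)
    seen_chroms = set(events["chrom"].unique()) if len(events) else set()
    missing = sorted(set(genes["chrom"]) - seen_chroms)
    if missing:
        warnings.warn(f"gene chromosomes absent from event data: {missing}")
    rows = []
    for _, g in genes.iterrows():
        mask = (ev["chrom"] == g["chrom"]) & (ev["start"] < g["end"]) \
            & (ev["end"] > g["start"])
        rows.append({"gene": g["gene"], "chrom": g["chrom"],
                     "start": g["start"], "end": g["end"],
                     "direction": direction,
                     "n_cases": int(ev.loc[mask, "sample_id"].nunique())})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "direction", "n_cases"])


def kinase_gain_cases(events: pd.DataFrame, genes: pd.DataFrame,
                      thresholds: ExtremeThresholds | None = None,
                      kinases: tuple[str, ...] = ("ERBB2", "EGFR", "MET", "KRAS"),
                      ) -> int:
    """Distinct samples with an extreme gain over any of the kinase genes.

    Union semantics: a sample gaining two kinases counts once. ``ERBB2`` is
    the HGNC symbol for HER2; both names are accepted in the gene table.
    """
    thresholds = thresholds or ExtremeThresholds()
    aliases = {"HER2": "ERBB2"}
    gnames = genes["gene"].map(lambda g: aliases.get(g, g))
    wanted = genes[gnames.isin(kinases)]
    if gnames[gnames.isin(kinases)].nunique() < len(kinases):
        have = sorted(gnames[gnames.isin(kinases)].unique())
        raise ValueError(f"gene table must provide all of {kinases}; found {have}")
    ev = extreme_events(events, thresholds, "gain")
    samples: set[str] = set()
    for _, g in wanted.iterrows():
        mask = (ev["chrom"] == g["chrom"]) & (ev["start"] < g["end"]) \
            & (ev["end"] > g["start"])
        samples.update(ev.loc[mask, "sample_id"])
    return len(samples)
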