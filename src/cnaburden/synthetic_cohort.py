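"""Synthetic tumor-cohort generator with ground truth.

Emulates a 41-tumor SNP-array cohort of superficial gastroesophageal
adenocarcinoma: per-tumor probe-level copy-number profiles, the ground-truth
segment tables behind them, planted recurrent gain/loss loci at controlled
prevalences, and clinical outcome tables in which the intermediate-burden
group carries an elevated hazard. Every downstream stage of the pipeline is
therefore testable with no external data.

Statistical structure of a simulated tumor
------------------------------------------
* the per-tumor number of independent CNAs is log-uniform on [11, 433]
  (reproducing the observed order-of-magnitude spread and, approximately,
  the observed median of ~82);
* CNA sizes follow a categorical mixture over six bins
  (<1 kb, 1–10 kb, 10–100 kb, 100 kb–1 Mb, 1–10 Mb, >10 Mb) with weights
  (0.016, 0.202, 0.351, 0.179, 0.179, 0.072), log-uniform within bin;
* gains outnumber losses 1.7 : 1 (gain fraction 1.7/2.7);
* gain copy numbers are uniform on [2.4, 8], losses uniform on [0.5, 1.6];
* planted recurrent loci are carried by exactly ``round(prevalence × n)``
  tumors with direction-appropriate extreme copy number;
* events never overlap within a tumor (each is separated by at least
  ``min_event_gap`` bp of diploid genome), so the ground-truth event count
  equals the requested count exactly;
* probe copy number = truth + GC bias (``amplitude × (gc − mean gc)``) +
  Gaussian noise.

The default genome carries full-length hg19 chromosome sizes (22 autosomes
plus X, ~3.04 Gb): with the absolute size mixture above, high-count tumors
occupy up to ~1 Gb of genome and need that much room to place events without
overlap. ``toy_genome(scale)`` provides proportionally scaled-down genomes
for fast tests; callers using them should scale counts/sizes accordingly.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right, insort
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CANONICAL_CHROMS, CLINICAL_COLUMNS, validate_clinical, validate_genes,
    validate_probes, validate_segments,
)

#: hg19 chromosome lengths (bp), autosomes + X.
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560,
}

# Approximate hg19 consensus-coding spans of genes recurrently gained/lost in
# gastroesophageal adenocarcinoma, with the planting scenario used by the
# default cohort: direction and number of carrier tumors out of 41.
GENE_CNA_SCENARIO: tuple[tuple[str, str, int, int, str, int], ...] = (
    ("FHIT",    "chr3",   59735036,  61237133, "loss", 23),
    ("WWOX",    "chr16",  78133310,  79246564, "loss", 10),
    ("CDKN2A",  "chr9",   21967751,  22009312, "loss",  6),
    ("MACROD2", "chr20",  13976015,  16033841, "loss",  6),
    ("SMAD4",   "chr18",  48556583,  48611411, "loss",  6),
    ("RUNX1",   "chr21",  36160098,  36421595, "loss",  6),
    ("PTPRD",   "chr9",    8314246,  10612723, "loss",  4),
    ("GMDS",    "chr6",    1624041,   2245868, "loss",  3),
    ("ERBB2",   "chr17",  37844393,  37884915, "gain",  8),
    ("CCND1",   "chr11",  69455873,  69469242, "gain",  8),
    ("EGFR",    "chr7",   55086725,  55324313, "gain",  6),
    ("MET",     "chr7",  116312459, 116438440, "gain",  4),
    ("KRAS",    "chr12",  25358180,  25403854, "gain",  4),
    ("MYC",     "chr8",  128748315, 128753680, "gain",  4),
    ("CDK6",    "chr7",   92234235,  92465908, "gain",  4),
    ("GATA4",   "chr8",   11534468,  11617511, "gain",  4),
    ("GATA6",   "chr18",  19749404,  19782224, "gain",  4),
    ("VEGFA",   "chr6",   43737946,  43754224, "gain",  4),
    ("KLF5",    "chr13",  73629113,  73651680, "gain",  3),
)

SIZE_BIN_EDGES = (1_000, 10_000, 100_000, 1_000_000, 10_000_000)


def _default_gc(chrom_index: int, pos: np.ndarray, mean: float, amplitude: float,
                period: float) -> np.ndarray:
    """Smooth per-chromosome GC profile: two incommensurate sinusoids."""
    phase = 2.0 * np.pi * chrom_index / 23.0
    gc = (mean
          + amplitude * np.sin(2.0 * np.pi * pos / period + phase)
          + 0.3 * amplitude * np.sin(2.0 * np.pi * pos / (period * 9.7) + 2.0 * phase))
    return np.clip(gc, 0.25, 0.65)


@dataclass(frozen=True)
class GenomeSpec:
    """Array design: chromosome lengths, probe density and GC landscape."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(HG19_LENGTHS))
    probe_spacing: float = 3_000.0     # mean bp between probes
    gc_mean: float = 0.45
    gc_amplitude: float = 0.10
    gc_period: float = 4_000_000.0

    def __post_init__(self):
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.probe_spacing <= 0:
            raise ValueError("probe spacing must be positive")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def gc_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        idx = list(self.chrom_lengths).index(chrom)
        return _default_gc(idx, np.asarray(pos, dtype=float), self.gc_mean,
                           self.gc_amplitude, self.gc_period)


def default_genome() -> GenomeSpec:
    """Full-size hg19-like genome at SNP-6-like probe density (~1M probes)."""
    return GenomeSpec()


def toy_genome(scale: float = 0.05, probe_spacing: float = 3_000.0) -> GenomeSpec:
    """Proportionally scaled-down genome for fast tests."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    lengths = {c: max(int(round(length * scale)), 10_000)
               for c, length in HG19_LENGTHS.items()}
    return GenomeSpec(chrom_lengths=lengths, probe_spacing=probe_spacing)


def scale_factor(genome: GenomeSpec, chrom: str) -> float:
    return genome.chrom_lengths[chrom] / HG19_LENGTHS[chrom]


@dataclass(frozen=True)
class RecurrentLocus:
    """A genomic locus planted as a recurrent gain or loss."""
    name: str
    chrom: str
    start: int
    end: int
    direction: str          # "gain" | "loss"
    prevalence: float       # fraction of tumors carrying the event

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")


def default_gene_annotation(genome: Optional[GenomeSpec] = None) -> pd.DataFrame:
    """Gene spans of the default scenario, scaled to ``genome`` if given."""
    genome = genome or default_genome()
    rows = []
    for gene, chrom, start, end, _direction, _cases in GENE_CNA_SCENARIO:
        if chrom not in genome.chrom_lengths:
            continue
        f = scale_factor(genome, chrom)
        s, e = int(round(start * f)), int(round(end * f))
        rows.append({"gene": gene, "chrom": chrom, "start": s, "end": max(e, s + 1)})
    return validate_genes(pd.DataFrame(rows))


def default_recurrent_loci(genome: Optional[GenomeSpec] = None,
                           n_tumors: int = 41) -> list[RecurrentLocus]:
    """Planted loci of the default scenario (prevalences out of 41)."""
    genome = genome or default_genome()
    loci = []
    for gene, chrom, start, end, direction, cases in GENE_CNA_SCENARIO:
        if chrom not in genome.chrom_lengths:
            continue
        f = scale_factor(genome, chrom)
        s, e = int(round(start * f)), int(round(end * f))
        loci.append(RecurrentLocus(gene, chrom, s, max(e, s + 1), direction, cases / 41.0))
    return loci


@dataclass
class CohortSpec:
    """Cohort-level generative law. Defaults reproduce the study conditions."""

    n_tumors: int = 41
    count_range: tuple[int, int] = (11, 433)          # log-uniform per-tumor CNA count
    size_bin_weights: tuple[float, ...] = (0.016, 0.202, 0.351, 0.179, 0.179, 0.072)
    size_min: float = 200.0           # lower edge of the sub-kilobase bin
    size_max: float = 5.0e7           # truncation of the >10 Mb tail (see methods)
    gain_fraction: float = 1.7 / 2.7
    gain_cn: tuple[float, float] = (2.4, 8.0)
    loss_cn: tuple[float, float] = (0.5, 1.6)
    planted_gain_cn: tuple[float, float] = (3.2, 8.0)   # above the extreme-gain cut
    planted_loss_cn: tuple[float, float] = (0.5, 1.3)   # below the extreme-loss cut
    recurrent_loci: Optional[Sequence[RecurrentLocus]] = None  # None -> default scenario
    probe_noise_sd: float = 0.2
    gc_bias_amplitude: float = 0.3
    min_event_gap: int = 1_000        # diploid bp guaranteed between events

    def __post_init__(self):
        # the published bin percentages sum to 99.9%; tolerate rounding and
        # renormalize at draw time
        if abs(sum(self.size_bin_weights) - 1.0) > 0.01:
            raise ValueError("size-bin weights must sum to 1")
        if len(self.size_bin_weights) != len(SIZE_BIN_EDGES) + 1:
            raise ValueError("need one weight per size bin")
        if not 0 <= self.gain_fraction <= 1:
            raise ValueError("gain fraction must lie in [0, 1]")


@dataclass
class SurvivalSpec:
    """Exponential outcome model with a burden-group hazard multiplier."""

    os_rate: float = 0.008            # baseline death hazard per month
    hr_intermediate: float = 3.7      # hazard multiplier, intermediate-burden group
    rec_rate: float = 0.004           # baseline recurrence hazard per month
    hr_recurrence: float = 7.3        # recurrence multiplier, intermediate group
    censor_window: tuple[float, float] = (24.0, 104.0)  # uniform admin censoring, months
    n_perioperative: int = 2          # deaths within 3 months of surgery

    def __post_init__(self):
        if self.os_rate <= 0 or self.rec_rate <= 0:
            raise ValueError("rates must be positive")
        if self.hr_intermediate <= 0 or self.hr_recurrence <= 0:
            raise ValueError("hazard ratios must be positive")


# ---------------------------------------------------------------------------
# Probe grid
# ---------------------------------------------------------------------------

def probe_positions(genome: GenomeSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Per-chromosome 1-based probe positions with exponential spacing."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9e3779b9]))
    grid = {}
    for chrom, length in genome.chrom_lengths.items():
        n_est = int(length / genome.probe_spacing * 1.4) + 16
        gaps = rng.exponential(genome.probe_spacing, size=n_est)
        pos = 1 + np.floor(np.cumsum(gaps)).astype(np.int64)
        pos = np.unique(pos[pos <= length])
        grid[chrom] = pos
    return grid


def _markers_in(pos: np.ndarray, start: int, end: int) -> int:
    """Probes with 1-based position in (start, end] — i.e. inside [start, end)."""
    return int(np.searchsorted(pos, end, side="right")
               - np.searchsorted(pos, start, side="right"))


# ---------------------------------------------------------------------------
# Event drawing and placement
# ---------------------------------------------------------------------------

def _draw_sizes(rng: np.random.Generator, n: int, spec: CohortSpec,
                genome: GenomeSpec) -> np.ndarray:
    edges = [spec.size_min, *SIZE_BIN_EDGES,
             min(spec.size_max, 0.9 * max(genome.chrom_lengths.values()))]
    w = np.asarray(spec.size_bin_weights, dtype=float)
    bins = rng.choice(len(w), size=n, p=w / w.sum())
    lo = np.array([edges[b] for b in bins])
    hi = np.array([max(edges[b + 1], edges[b] * 1.001) for b in bins])
    u = rng.uniform(size=n)
    sizes = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    return np.maximum(sizes.astype(np.int64), 1)


def _draw_counts(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    lo, hi = spec.count_range
    u = rng.uniform(np.log(lo), np.log(hi), size=n)
    return np.clip(np.rint(np.exp(u)).astype(int), lo, hi)


class _Occupancy:
    """Per-chromosome sorted interval sets for non-overlap rejection sampling."""

    def __init__(self, chroms: Sequence[str]):
        self._iv: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def fits(self, chrom: str, start: int, end: int, gap: int) -> bool:
        iv = self._iv[chrom]
        i = bisect_right(iv, (start, end))
        if i > 0 and iv[i - 1][1] + gap > start:
            return False
        if i < len(iv) and end + gap > iv[i][0]:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._iv[chrom], (start, end))


def _place_events(rng: np.random.Generator, genome: GenomeSpec,
                  sizes: Sequence[int], occupancy: _Occupancy,
                  gap: int, max_tries: int = 1000) -> list[tuple[str, int, int]]:
    """Place events of the given sizes uniformly without overlap (big first)."""
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    order = np.argsort(sizes)[::-1]
    placed: list[Optional[tuple[str, int, int]]] = [None] * len(sizes)
    for idx in order:
        size = int(sizes[idx])
        ok = lengths >= size + 2 * gap
        if not ok.any():
            raise ValueError(
                f"no chromosome can host an event of {size} bp; "
                "use a larger genome or smaller events")
        p = np.where(ok, lengths, 0.0)
        p /= p.sum()
        for _try in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=p)]
            start = int(rng.integers(0, genome.chrom_lengths[chrom] - size + 1))
            if occupancy.fits(chrom, start, start + size, gap):
                occupancy.add(chrom, start, start + size)
                placed[idx] = (chrom, start, start + size)
                break
        else:
            raise ValueError(
                f"could not place a {size} bp event after {max_tries} tries; "
                "the genome is too crowded — use a larger genome or fewer/smaller events")
    return placed  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Single-tumor profile
# ---------------------------------------------------------------------------

def _truth_segments(genome: GenomeSpec, sample_id: str,
                    events: pd.DataFrame, grid: dict[str, np.ndarray]) -> pd.DataFrame:
    """Alternating diploid / aberrant runs covering every chromosome."""
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in events.groupby("chrom")} if len(events) else {}
    for chrom, length in genome.chrom_lengths.items():
        pos = grid[chrom]
        cursor = 0
        for _, ev in by_chrom.get(chrom, pd.DataFrame()).iterrows():
            if ev["start"] > cursor:
                rows.append((sample_id, chrom, cursor, int(ev["start"]),
                             max(_markers_in(pos, cursor, int(ev["start"])), 1), 2.0))
            rows.append((sample_id, chrom, int(ev["start"]), int(ev["end"]),
                         max(_markers_in(pos, int(ev["start"]), int(ev["end"])), 1),
                         float(ev["cn"])))
            cursor = int(ev["end"])
        if cursor < length:
            rows.append((sample_id, chrom, cursor, length,
                         max(_markers_in(pos, cursor, length), 1), 2.0))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                     "n_markers", "cn"])
    return validate_segments(df, tuple(genome.chrom_lengths))


def _probe_table(genome: GenomeSpec, sample_id: str, truth: pd.DataFrame,
                 grid: dict[str, np.ndarray], spec: CohortSpec,
                 rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for chrom in genome.chrom_lengths:
        pos = grid[chrom]
        seg = truth[truth["chrom"] == chrom]
        # truth cn at each probe: probes at 1-based pos p live in [p-1, p)
        idx = np.searchsorted(seg["end"].to_numpy(), pos - 1, side="right")
        idx = np.clip(idx, 0, len(seg) - 1)
        cn_truth = seg["cn"].to_numpy()[idx]
        gc = genome.gc_at(chrom, pos)
        cn = (cn_truth
              + spec.gc_bias_amplitude * (gc - genome.gc_mean)
              + rng.normal(0.0, spec.probe_noise_sd, size=len(pos)))
        frames.append(pd.DataFrame({
            "sample_id": sample_id,
            "probe_id": [f"{chrom}_p{i}" for i in range(len(pos))],
            "chrom": chrom, "pos": pos,
            "cn": np.maximum(cn, 0.0),
            "gc": np.round(gc, 6),
        }))
    return validate_probes(pd.concat(frames, ignore_index=True),
                           tuple(genome.chrom_lengths))


def simulate_profile(genome: GenomeSpec, n_cnas: int, spec: CohortSpec,
                     seed: int, *, sample_id: str = "T1",
                     with_probes: bool = True, segmentable: bool = False,
                     min_markers: int = 20,
                     planted: Optional[pd.DataFrame] = None,
                     grid: Optional[dict[str, np.ndarray]] = None,
                     ) -> tuple[Optional[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate one tumor profile.

    Parameters
    ----------
    n_cnas : total number of independent CNAs to plant, including any in
        ``planted`` (a frame with columns chrom/start/end/cn/direction of
        pre-placed events, e.g. recurrent loci).
    segmentable : floor background event sizes so every aberrant run covers at
        least ``min_markers`` probes (for segmentation-recovery studies).

    Returns
    -------
    (probe table or None, ground-truth segment table, ground-truth event table)
    """
    if n_cnas < 0:
        raise ValueError("n_cnas must be non-negative")
    ss = np.random.SeedSequence(seed)
    rng_place, rng_cn, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))
    if grid is None:
        grid = probe_positions(genome, seed=int(ss.generate_state(1)[0] % (2**31)))

    occupancy = _Occupancy(list(genome.chrom_lengths))
    ev_rows = []
    if planted is not None and len(planted):
        for _, ev in planted.iterrows():
            occupancy.add(ev["chrom"], int(ev["start"]), int(ev["end"]))
            ev_rows.append({"chrom": ev["chrom"], "start": int(ev["start"]),
                            "end": int(ev["end"]), "cn": float(ev["cn"]),
                            "direction": ev["direction"], "planted": True})
    n_background = max(n_cnas - len(ev_rows), 0)
    if n_background:
        sizes = _draw_sizes(rng_place, n_background, spec, genome)
        if segmentable:
            floor = int((min_markers + 5) * genome.probe_spacing)
            sizes = np.maximum(sizes, floor)
        where = _place_events(rng_place, genome, sizes, occupancy,
                              gap=spec.min_event_gap)
        gains = rng_cn.uniform(size=n_background) < spec.gain_fraction
        cn_gain = rng_cn.uniform(*spec.gain_cn, size=n_background)
        cn_loss = rng_cn.uniform(*spec.loss_cn, size=n_background)
        for (chrom, start, end), g, cg, cl in zip(where, gains, cn_gain, cn_loss):
            ev_rows.append({"chrom": chrom, "start": start, "end": end,
                            "cn": float(cg if g else cl),
                            "direction": "gain" if g else "loss", "planted": False})
    events = pd.DataFrame(ev_rows, columns=["chrom", "start", "end", "cn",
                                            "direction", "planted"])
    events.insert(0, "sample_id", sample_id)
    events["size"] = events["end"] - events["start"]
    truth = _truth_segments(genome, sample_id, events, grid)
    probes = (_probe_table(genome, sample_id, truth, grid, spec, rng_noise)
              if with_probes else None)
    return probes, truth, events


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Everything simulate_cohort produced, with ground truth."""
    segments: pd.DataFrame                 # truth segments, all tumors
    events: pd.DataFrame                   # truth events, all tumors
    probes: Optional[dict[str, pd.DataFrame]]
    loci: pd.DataFrame                     # planted loci with carrier lists
    counts: pd.Series                      # requested (= realized) CNA count per tumor
    genome: GenomeSpec
    spec: CohortSpec
    seed: int


def simulate_cohort(spec: Optional[CohortSpec] = None,
                    genome: Optional[GenomeSpec] = None,
                    seed: int = 0, *, with_probes: bool = False,
                    segmentable: bool = False, min_markers: int = 20,
                    ) -> CohortResult:
    """Simulate a cohort of tumors with planted recurrent loci.

    Each recurrent locus is planted in exactly ``round(prevalence × n_tumors)``
    tumors; the carrier event covers the locus plus random flanks, with a
    direction-appropriate extreme copy number. Remaining events per tumor are
    background, drawn from the cohort size/direction/copy-number laws.
    """
    spec = spec or CohortSpec()
    genome = genome or default_genome()
    loci = (list(spec.recurrent_loci) if spec.recurrent_loci is not None
            else default_recurrent_loci(genome, spec.n_tumors))
    for locus in loci:
        if locus.chrom not in genome.chrom_lengths or \
           locus.end > genome.chrom_lengths[locus.chrom]:
            raise ValueError(f"recurrent locus {locus.name} lies outside the genome")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sample_ids = [f"T{i + 1:03d}" for i in range(spec.n_tumors)]
    counts = _draw_counts(rng, spec.n_tumors, spec)

    planted_per_tumor: dict[str, list[dict]] = {s: [] for s in sample_ids}
    loci_rows = []
    for locus in loci:
        n_carriers = int(round(locus.prevalence * spec.n_tumors))
        if n_carriers < 1:
            warnings.warn(f"locus {locus.name}: prevalence × n_tumors < 1, skipped")
            loci_rows.append({"name": locus.name, "chrom": locus.chrom,
                              "start": locus.start, "end": locus.end,
                              "direction": locus.direction,
                              "prevalence": locus.prevalence,
                              "n_carriers": 0, "carriers": ()})
            continue
        carriers = sorted(rng.choice(spec.n_tumors, size=n_carriers, replace=False))
        width = locus.end - locus.start
        flank_max = max(width // 2, int(5 * genome.probe_spacing))
        cn_lo, cn_hi = (spec.planted_gain_cn if locus.direction == "gain"
                        else spec.planted_loss_cn)
        for ci in carriers:
            f_left = int(rng.integers(0, flank_max + 1))
            f_right = int(rng.integers(0, flank_max + 1))
            start = max(locus.start - f_left, 0)
            end = min(locus.end + f_right, genome.chrom_lengths[locus.chrom])
            planted_per_tumor[sample_ids[ci]].append({
                "chrom": locus.chrom, "start": start, "end": end,
                "cn": float(rng.uniform(cn_lo, cn_hi)),
                "direction": locus.direction,
            })
        loci_rows.append({"name": locus.name, "chrom": locus.chrom,
                          "start": locus.start, "end": locus.end,
                          "direction": locus.direction,
                          "prevalence": locus.prevalence,
                          "n_carriers": n_carriers,
                          "carriers": tuple(sample_ids[ci] for ci in carriers)})

    grid = probe_positions(genome, seed=int(ss.generate_state(1)[0] % (2**31)))
    tumor_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(spec.n_tumors)]

    seg_frames, ev_frames = [], []
    probes: Optional[dict[str, pd.DataFrame]] = {} if with_probes else None
    realized = {}
    for sid, count, tseed in zip(sample_ids, counts, tumor_seeds):
        planted = pd.DataFrame(planted_per_tumor[sid])
        n_total = max(int(count), len(planted))
        p, truth, events = simulate_profile(
            genome, n_total, spec, tseed, sample_id=sid,
            with_probes=with_probes, segmentable=segmentable,
            min_markers=min_markers, planted=planted if len(planted) else None,
            grid=grid)
        seg_frames.append(truth)
        ev_frames.append(events)
        realized[sid] = len(events)
        if probes is not None:
            probes[sid] = p
    segments = pd.concat(seg_frames, ignore_index=True)
    events = pd.concat(ev_frames, ignore_index=True)
    return CohortResult(
        segments=segments, events=events, probes=probes,
        loci=pd.DataFrame(loci_rows),
        counts=pd.Series(realized, name="total_cna_count"),
        genome=genome, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# Clinical outcomes
# ---------------------------------------------------------------------------

def simulate_clinical(groups: pd.Series, spec: Optional[SurvivalSpec] = None,
                      seed: int = 0) -> pd.DataFrame:
    """Simulate a clinical outcome table for samples with assigned burden groups.

    Survival and recurrence times are exponential; the intermediate-burden
    group carries multiplicative hazards ``hr_intermediate`` (death) and
    ``hr_recurrence`` (recurrence). All clinical covariates are drawn
    independently of the burden group — the simulated cohort has, by
    construction, no group–covariate association. Covariate frequencies follow
    the study population (mostly male, median age 66, predominantly T1b, ~37%
    node-positive, ~39% poorly differentiated).
    """
    spec = spec or SurvivalSpec()
    if len(groups) == 0:
        raise ValueError("empty group list")
    bad = set(groups) - {"low", "intermediate", "high"}
    if bad:
        raise ValueError(f"unknown burden groups {sorted(bad)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5ca1ab1e]))
    n = len(groups)
    inter = (groups == "intermediate").to_numpy()

    os_rate = np.where(inter, spec.os_rate * spec.hr_intermediate, spec.os_rate)
    rec_rate = np.where(inter, spec.rec_rate * spec.hr_recurrence, spec.rec_rate)
    death = rng.exponential(1.0 / os_rate)
    recur = rng.exponential(1.0 / rec_rate)
    censor = rng.uniform(*spec.censor_window, size=n)

    os_time = np.minimum(death, censor)
    os_event = death <= censor
    rec_time = np.minimum.reduce([recur, death, censor])
    rec_event = (recur < death) & (recur <= censor)

    perioperative = np.zeros(n, dtype=bool)
    if spec.n_perioperative > 0:
        chosen = rng.choice(n, size=min(spec.n_perioperative, n), replace=False)
        perioperative[chosen] = True
        early = rng.uniform(0.3, 3.0, size=len(chosen))
        os_time[chosen] = early
        os_event[chosen] = True
        rec_time[chosen] = early
        rec_event[chosen] = False

    clinical = pd.DataFrame({
        "sample_id": groups.index.astype(str),
        "age": np.clip(np.rint(rng.normal(66, 9, size=n)), 40, 92).astype(int),
        "sex": rng.choice(["M", "F"], size=n, p=[35 / 41, 6 / 41]),
        "t_stage": rng.choice(T_STAGE_P[0], size=n, p=T_STAGE_P[1]),
        "n_stage": rng.choice(N_STAGE_P[0], size=n, p=N_STAGE_P[1]),
        "m_stage": rng.choice(M_STAGE_P[0], size=n, p=M_STAGE_P[1]),
        "grade": rng.choice(GRADE_P[0], size=n, p=GRADE_P[1]),
        "angioinvasion": rng.uniform(size=n) < 14 / 41,
        "tumor_size": np.round(np.clip(rng.lognormal(np.log(2.5), 0.45, size=n),
                                       0.5, 9.0), 1),
        "ln_resected": rng.poisson(22, size=n),
        "os_time": os_time,
        "os_event": os_event,
        "rec_time": rec_time,
        "rec_event": rec_event,
        "perioperative_death": perioperative,
    }, columns=CLINICAL_COLUMNS)
    return validate_clinical(clinical)


T_STAGE_P = (["T1a", "T1b", "T2"], [6 / 41, 34 / 41, 1 / 41])
N_STAGE_P = (["N0", "N1", "N2", "N3"], [26 / 41, 10 / 41, 4 / 41, 1 / 41])
M_STAGE_P = (["M0", "M1"], [40 / 41, 1 / 41])
GRADE_P = (["WD-MD", "PD"], [25 / 41, 16 / 41])
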