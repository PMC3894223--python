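"""Readers and writers for the on-disk formats of the copy-number burden pipeline.

Four tables flow through the pipeline:

* **probe table** — per-probe copy-number estimates with local GC context
  (tab-separated; columns ``sample_id, probe_id, chrom, pos, cn, gc``).
  ``pos`` is a 1-based point coordinate; ``cn`` is absolute copy number with
  diploid = 2.0; ``gc`` is the GC fraction of the surrounding window.
* **segment table** — contiguous constant-copy-number intervals per tumor in a
  SEG-like dialect (``ID, chrom, loc.start, loc.end, num.mark, seg.cn`` plus a
  derived ``seg.log2`` column for conventional SEG consumers). On disk the
  intervals are 1-based inclusive, following the SEG convention.
* **gene annotation** — BED4 (``chrom, start, end, gene``), 0-based half-open.
* **clinical table** — CSV of per-patient covariates, survival/recurrence
  times (months) and event indicators.

Internally every interval is **0-based half-open**; the converters at this
boundary are the only place coordinate conventions change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Default chromosome universe: autosomes plus X (SNP-array content).
CANONICAL_CHROMS: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_markers", "cn"]
PROBE_COLUMNS = ["sample_id", "probe_id", "chrom", "pos", "cn", "gc"]
GENE_COLUMNS = ["gene", "chrom", "start", "end"]

CLINICAL_COLUMNS = [
    "sample_id", "age", "sex", "t_stage", "n_stage", "m_stage", "grade",
    "angioinvasion", "tumor_size", "ln_resected",
    "os_time", "os_event", "rec_time", "rec_event", "perioperative_death",
]

T_STAGE_LEVELS = ("T1a", "T1b", "T2")
N_STAGE_LEVELS = ("N0", "N1", "N2", "N3")
M_STAGE_LEVELS = ("M0", "M1")
GRADE_LEVELS = ("WD-MD", "PD")

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


class FormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


def _chrom_rank(chroms: pd.Series, universe: tuple[str, ...]) -> pd.Series:
    rank = {c: i for i, c in enumerate(universe)}
    unknown = sorted(set(chroms.unique()) - set(universe))
    if unknown:
        raise FormatError(
            f"unknown chromosome names {unknown}; accepted names are {list(universe)}"
        )
    return chroms.map(rank)


def sort_genomic(df: pd.DataFrame, chromosomes: tuple[str, ...] = CANONICAL_CHROMS,
                 by: str = "start") -> pd.DataFrame:
    """Sort a table by (sample, chromosome-in-genome-order, position)."""
    out = df.assign(_rank=_chrom_rank(df["chrom"], chromosomes))
    keys = [c for c in ("sample_id", "_rank", by) if c in out.columns or c == "_rank" or c == by]
    out = out.sort_values(keys, kind="mergesort").drop(columns="_rank")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Segment tables (SEG-like dialect)
# ---------------------------------------------------------------------------

def validate_segments(df: pd.DataFrame,
                      chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> pd.DataFrame:
    """Validate and canonicalize a segment table.

    Enforces the SegmentTable invariants: half-open intervals with
    ``end > start``, ``n_markers >= 1``, finite non-negative ``cn``, known
    chromosome names, and — within each (sample, chromosome) — sorted,
    non-overlapping intervals. Returns a sorted copy.
    """
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment table is missing columns {missing}")
    out = df[SEGMENT_COLUMNS].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    for col in ("start", "end", "n_markers"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(np.int64)
    out["cn"] = pd.to_numeric(out["cn"], errors="raise").astype(float)

    bad = out.index[out["end"] <= out["start"]]
    if len(bad):
        raise FormatError(f"segments with end <= start at rows {list(bad[:5])}")
    bad = out.index[out["n_markers"] < 1]
    if len(bad):
        raise FormatError(f"segments with n_markers < 1 at rows {list(bad[:5])}")
    cn = out["cn"].to_numpy()
    if not np.all(np.isfinite(cn)) or (cn < 0).any():
        raise FormatError("segment cn must be finite and non-negative")

    out = sort_genomic(out, chromosomes)
    # overlap check within (sample, chrom) after sorting
    same = (out["sample_id"].eq(out["sample_id"].shift())
            & out["chrom"].eq(out["chrom"].shift()))
    overlap = same & (out["start"] < out["end"].shift())
    if overlap.any():
        rows = out[overlap | overlap.shift(-1, fill_value=False)]
        detail = rows[["sample_id", "chrom", "start", "end"]].head(6).to_string(index=False)
        raise FormatError(f"overlapping segments within a sample-chromosome:\n{detail}")
    return out


def read_seg(path, chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> pd.DataFrame:
    """Read a SEG-like TSV into an internal segment table.

    The on-disk dialect is tab-separated with header
    ``ID, chrom, loc.start, loc.end, num.mark, seg.cn`` (extra columns such as
    ``seg.log2`` are ignored) and 1-based inclusive coordinates; they are
    converted to 0-based half-open. Rows may appear in any order — the reader
    sorts.
    """
    raw = pd.read_csv(path, sep="\t")
    required = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.cn"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"SEG file {path} is missing columns {missing}")
    df = pd.DataFrame({
        "sample_id": raw["ID"].astype(str),
        "chrom": raw["chrom"].astype(str),
        "start": pd.to_numeric(raw["loc.start"]).astype(np.int64) - 1,
        "end": pd.to_numeric(raw["loc.end"]).astype(np.int64),
        "n_markers": pd.to_numeric(raw["num.mark"]).astype(np.int64),
        "cn": pd.to_numeric(raw["seg.cn"]).astype(float),
    })
    return validate_segments(df, chromosomes)


def write_seg(segments: pd.DataFrame, path,
              chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> None:
    """Write a segment table as SEG-like TSV (1-based inclusive on disk).

    A derived ``seg.log2`` column (log2 of cn relative to diploid, with cn
    floored at 1e-3 to keep homozygous deletions finite) is emitted for
    interoperability; it is ignored on read.
    """
    df = validate_segments(segments, chromosomes)
    out = pd.DataFrame({
        "ID": df["sample_id"],
        "chrom": df["chrom"],
        "loc.start": df["start"] + 1,
        "loc.end": df["end"],
        "num.mark": df["n_markers"],
        "seg.cn": df["cn"],
        "seg.log2": np.log2(np.maximum(df["cn"].to_numpy(), 1e-3) / 2.0),
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation (BED4)
# ---------------------------------------------------------------------------

def validate_genes(df: pd.DataFrame,
                   chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table is missing columns {missing}")
    out = df[GENE_COLUMNS].copy()
    out["gene"] = out["gene"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = pd.to_numeric(out["start"]).astype(np.int64)
    out["end"] = pd.to_numeric(out["end"]).astype(np.int64)
    if (out["end"] <= out["start"]).any():
        raise FormatError("gene intervals must satisfy end > start")
    _chrom_rank(out["chrom"], chromosomes)
    # multi-interval genes are pre-merged to their spanning interval
    out = (out.groupby(["gene", "chrom"], as_index=False)
              .agg(start=("start", "min"), end=("end", "max")))
    if out["gene"].duplicated().any():
        dup = out.loc[out["gene"].duplicated(), "gene"].tolist()
        raise FormatError(f"gene symbols on multiple chromosomes: {dup}")
    return sort_genomic(out[GENE_COLUMNS], chromosomes)


def read_bed(path, chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> pd.DataFrame:
    """Read BED4 gene spans (0-based half-open, as internal)."""
    raw = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene"], comment="#")
    return validate_genes(raw, chromosomes)


def write_bed(genes: pd.DataFrame, path,
              chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> None:
    df = validate_genes(genes, chromosomes)
    df[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Probe tables
# ---------------------------------------------------------------------------

def validate_probes(df: pd.DataFrame,
                    chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"probe table is missing columns {missing}")
    out = df[PROBE_COLUMNS].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["probe_id"] = out["probe_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = pd.to_numeric(out["pos"]).astype(np.int64)
    out["cn"] = pd.to_numeric(out["cn"]).astype(float)
    out["gc"] = pd.to_numeric(out["gc"]).astype(float)
    cn = out["cn"].to_numpy()
    if not np.all(np.isfinite(cn)) or (cn < 0).any():
        raise FormatError("probe cn must be finite and non-negative")
    gc = out["gc"].to_numpy()
    if not np.all(np.isfinite(gc)) or (gc < 0).any() or (gc > 1).any():
        raise FormatError("probe gc must lie in [0, 1]")
    out = sort_genomic(out, chromosomes, by="pos")
    dup = out.duplicated(subset=["sample_id", "chrom", "pos"])
    if dup.any():
        raise FormatError(
            f"duplicate probe positions within a sample-chromosome at rows {list(out.index[dup][:5])}"
        )
    return out


def read_probes(path, chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> pd.DataFrame:
    return validate_probes(pd.read_csv(path, sep="\t"), chromosomes)


def write_probes(probes: pd.DataFrame, path,
                 chromosomes: tuple[str, ...] = CANONICAL_CHROMS) -> None:
    validate_probes(probes, chromosomes).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def _parse_bool(series: pd.Series, col: str) -> pd.Series:
    if series.dtype == bool:
        return series
    def one(v, i):
        s = str(v).strip().lower()
        if s not in _BOOL_MAP:
            raise FormatError(f"column {col!r}, row {i}: cannot parse {v!r} as boolean")
        return _BOOL_MAP[s]
    return pd.Series([one(v, i) for i, v in series.items()], index=series.index, dtype=bool)


def _normalize_level(value: str, levels: tuple[str, ...], col: str, row) -> str:
    s = str(value).strip()
    aliases = {"WD": "WD-MD", "MD": "WD-MD", "WD or MD": "WD-MD", "WD/MD": "WD-MD"}
    s = aliases.get(s, s)
    for lv in levels:
        if s.lower() == lv.lower():
            return lv
    raise FormatError(f"column {col!r}, row {row}: {value!r} not in {levels}")


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table is missing columns {missing}")
    out = df[CLINICAL_COLUMNS].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    for col in ("age", "tumor_size", "os_time", "rec_time"):
        try:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = list(out.index[bad.isna()][:5])
            raise FormatError(f"column {col!r}: non-parsable values at rows {rows}") from exc
    out["ln_resected"] = pd.to_numeric(out["ln_resected"]).astype(np.int64)
    out["sex"] = out["sex"].astype(str).str.strip().str.upper().str[0]
    if not set(out["sex"]).issubset({"M", "F"}):
        raise FormatError("sex must be M or F")
    for col, levels in (("t_stage", T_STAGE_LEVELS), ("n_stage", N_STAGE_LEVELS),
                        ("m_stage", M_STAGE_LEVELS), ("grade", GRADE_LEVELS)):
        out[col] = [_normalize_level(v, levels, col, i) for i, v in out[col].items()]
    for col in ("angioinvasion", "os_event", "rec_event", "perioperative_death"):
        out[col] = _parse_bool(out[col], col)
    for col in ("os_time", "rec_time"):
        if (out[col] < 0).any():
            raise FormatError(f"negative times in column {col!r}")
    bad = out.index[out["rec_time"] > out["os_time"] + 1e-9]
    if len(bad):
        raise FormatError(f"rec_time > os_time at rows {list(bad[:5])}")
    if out["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in clinical table")
    return out.reset_index(drop=True)


def read_clinical(path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path))


def write_clinical(clinical: pd.DataFrame, path) -> None:
    validate_clinical(clinical).to_csv(path, index=False)
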