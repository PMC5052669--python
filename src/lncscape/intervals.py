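"""Promoter windows, ChIP-peak overlap and estrogen-induction categories.

All coordinates are 0-based half-open (BED convention). Two intervals on
the same chromosome overlap iff ``max(starts) < min(ends)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "promoter_windows",
    "peak_promoter_overlap",
    "promoter_binding_flags",
    "induction_category",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    id: str
    chrom: str
    tss: int
    strand: str
    length_bp: int = 1000

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"{self.id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be + or -")


def promoter_windows(models: Sequence[TranscriptModel], mode: str = "symmetric",
                     upstream_bp: int = 5000, downstream_bp: int = 5000) -> list[GenomicInterval]:
    """Promoter intervals anchored at unique transcription start sites.

    ``symmetric`` spans ``[tss - u, tss + d)`` with upstream/downstream
    swapped on the minus strand; ``upstream_only`` spans the ``u`` bases
    upstream of the TSS. Transcripts sharing (chrom, tss, strand) collapse
    to one window whose name joins their ids with commas. Windows are
    clamped at position 0.
    """
    if mode not in ("symmetric", "upstream_only"):
        raise ValueError(f"unknown promoter mode {mode!r}")
    if upstream_bp <= 0 or downstream_bp <= 0:
        raise ValueError("window sizes must be > 0")
    by_tss: dict[tuple, list[str]] = {}
    for m in models:
        by_tss.setdefault((m.chrom, m.tss, m.strand), []).append(m.id)
    out = []
    for (chrom, tss, strand), ids in sorted(by_tss.items()):
        if mode == "symmetric":
            u, d = (upstream_bp, downstream_bp) if strand == "+" else (downstream_bp, upstream_bp)
            start, end = tss - u, tss + d
        else:
            start, end = (tss - upstream_bp, tss) if strand == "+" else (tss, tss + upstream_bp)
        start = max(0, start)
        if start >= end:  # TSS at/near 0 on the + strand with upstream_only
            continue
        out.append(GenomicInterval(chrom, start, end, strand, ",".join(sorted(ids))))
    return out


def _merged_coverage(starts: np.ndarray, ends: np.ndarray) -> int:
    # total covered bases of a set of clipped intervals (merged)
    order = np.argsort(starts, kind="stable")
    total = 0
    cur_s = cur_e = None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return int(total)


def peak_promoter_overlap(peaks: Sequence[GenomicInterval],
                          promoters: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Per-promoter overlap with a peak set.

    Returns a DataFrame indexed by promoter name with columns ``bound``
    (>= 1 overlapping peak), ``overlap_bp`` (merged covered bases) and
    ``n_peaks``. Sweep over sorted starts per chromosome.
    """
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in peaks_by_chrom:
        peaks_by_chrom[chrom].sort(key=lambda iv: iv.start)
    rows = {}
    for prom in promoters:
        if prom.name in rows:
            raise ValueError(f"duplicate promoter name {prom.name!r}")
        chrom_peaks = peaks_by_chrom.get(prom.chrom, [])
        starts = np.array([p.start for p in chrom_peaks], dtype=np.int64)
        ends = np.array([p.end for p in chrom_peaks], dtype=np.int64)
        if len(chrom_peaks):
            # candidate peaks: start < prom.end and end > prom.start
            hi = np.searchsorted(starts, prom.end, side="left")
            sel = ends[:hi] > prom.start
            s = np.maximum(starts[:hi][sel], prom.start)
            e = np.minimum(ends[:hi][sel], prom.end)
            n = int(sel.sum())
            ov = _merged_coverage(s, e) if n else 0
        else:
            n, ov = 0, 0
        rows[prom.name] = {"bound": n >= 1, "overlap_bp": ov, "n_peaks": n}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("promoter")


def promoter_binding_flags(models: Sequence[TranscriptModel],
                           peaks: Sequence[GenomicInterval],
                           mode: str = "symmetric",
                           upstream_bp: int = 5000,
                           downstream_bp: int = 5000) -> pd.Series:
    """Boolean peak-in-promoter flag per transcript id.

    Collapsed promoter windows are expanded back so every transcript
    sharing a bound TSS is flagged.
    """
    proms = promoter_windows(models, mode=mode, upstream_bp=upstream_bp,
                             downstream_bp=downstream_bp)
    table = peak_promoter_overlap(peaks, proms)
    flags = {m.id: False for m in models}
    for name, row in table.iterrows():
        for tid in name.split(","):
            flags[tid] = flags[tid] or bool(row["bound"])
    return pd.Series(flags, name="er_bound")


def induction_category(fold_change: float) -> str:
    """Arrow category for estrogen induction: ``high`` above 2.5-fold,
    ``low`` above 1.5-fold, else ``none`` (strict inequalities)."""
    if fold_change <= 0:
        raise ValueError(f"fold_change must be > 0, got {fold_change}")
    if fold_change > 2.5:
        return "high"
    if fold_change > 1.5:
        return "low"
    return "none"


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
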