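"""Windowed genome scan for SNV/indel hotspots (kataegis-like clusters).

The genome is tiled in fixed non-overlapping windows (default 1 Mb; the last
window of each chromosome may be shorter).  Each window's combined SNV+indel
count is tested against a Poisson null at the genome-wide mean per-bp rate,
length-adjusted for short windows, with Benjamini-Hochberg control across
windows.  Flagged windows are then annotated with two common non-biological
explanations: elevated local copy number, and proximity to centromeres or
telomeres (where mapping artefacts concentrate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cna import CopyNumberSegment
from .genome import GenomeModel
from .variants import SomaticVariant

__all__ = ["WindowRecord", "window_counts", "call_hotspots", "annotate_explanations"]


@dataclass
class WindowRecord:
    """One tiling window with counts, test results and explanation flags."""

    chrom: str
    index: int
    start: int  # 1-based inclusive
    end: int
    snv_count: int = 0
    indel_count: int = 0
    expected: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    flagged: bool = False
    cn_explained: bool = False
    near_centromere_or_telomere: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_count(self) -> int:
        return self.snv_count + self.indel_count


def window_counts(
    variants: Sequence[SomaticVariant],
    genome: GenomeModel,
    window_size: int = 1_000_000,
) -> list[WindowRecord]:
    """Tile the genome and count SNVs and indels per window.

    A 1-based position ``p`` falls in window ``(p - 1) // window_size``, so a
    variant at exactly ``window_size + 1`` opens the second window.  A variant
    beyond its chromosome end raises, naming the record.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    records: list[WindowRecord] = []
    lookup: dict[tuple[str, int], WindowRecord] = {}
    for chrom, length in genome.chromosomes:
        n_windows = (length + window_size - 1) // window_size
        for i in range(n_windows):
            start = i * window_size + 1
            end = min((i + 1) * window_size, length)
            rec = WindowRecord(chrom=chrom, index=i, start=start, end=end)
            records.append(rec)
            lookup[(chrom, i)] = rec
    for v in variants:
        if v.pos < 1 or v.pos > genome.chrom_length(v.chrom):
            raise ValueError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} beyond chromosome end"
            )
        rec = lookup[(v.chrom, (v.pos - 1) // window_size)]
        if v.is_snv:
            rec.snv_count += 1
        else:
            rec.indel_count += 1
    return records


def call_hotspots(
    records: Sequence[WindowRecord], alpha: float = 0.05
) -> list[WindowRecord]:
    """Flag windows whose counts exceed the genome-wide Poisson expectation.

    Per window, a one-sided upper-tail Poisson p-value is computed against
    the genome-wide mean per-bp rate times the window length; BH-adjusted
    q-values are compared to ``alpha``.  With zero variants, nothing is
    flagged.  Records are modified in place and returned.
    """
    if not records:
        raise ValueError("no windows")
    total = sum(r.total_count for r in records)
    total_len = sum(r.length for r in records)
    if total == 0:
        for r in records:
            r.expected = 0.0
            r.p_value = 1.0
            r.q_value = 1.0
            r.flagged = False
        return list(records)
    rate = total / total_len
    counts = np.array([r.total_count for r in records])
    expected = rate * np.array([r.length for r in records], dtype=float)
    # P(X >= observed) under Poisson(expected)
    pvals = stats.poisson.sf(counts - 1, expected)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, e, p, q in zip(records, expected, pvals, qvals):
        r.expected = float(e)
        r.p_value = float(p)
        r.q_value = float(max(p, q))  # BH never drops below the raw p
        r.flagged = r.q_value <= alpha
    return list(records)


def annotate_explanations(
    records: Sequence[WindowRecord],
    segments: Sequence[CopyNumberSegment],
    genome: GenomeModel,
    cn_threshold: float = 2.5,
    margin: int = 2_000_000,
) -> list[WindowRecord]:
    """Annotate windows with copy-number and centromere/telomere explanations.

    ``cn_explained`` is set when the length-weighted mean total copy number
    over the window exceeds ``cn_threshold``; the centromere/telomere flag is
    set when the window overlaps a ``margin``-bp band around either landmark
    (overlap by a single bp suffices).
    """
    segs_by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        segs_by_chrom.setdefault(s.chrom, []).append(s)
    for r in records:
        mean_cn = 2.0
        segs = segs_by_chrom.get(r.chrom)
        if segs:
            weighted = 0.0
            covered = 0
            for s in segs:
                ov = min(s.end, r.end) - max(s.start, r.start) + 1
                if ov > 0:
                    weighted += ov * s.total_cn
                    covered += ov
            if covered > 0:
                mean_cn = weighted / covered
        r.cn_explained = mean_cn > cn_threshold

        cen = genome.centromeres[r.chrom]
        length = genome.chrom_length(r.chrom)
        bands = [
            (cen - margin, cen + margin),        # centromere
            (1, margin),                          # p telomere
            (length - margin + 1, length),        # q telomere
        ]
        r.near_centromere_or_telomere = any(
            r.start <= hi and r.end >= lo for lo, hi in bands
        )
    return list(records)
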