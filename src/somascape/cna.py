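"""Copy-number analyses on segment tables.

Covers per-sample burden (fraction of genome altered), cohort-recurrent
regions, homozygous deletions over a gene catalog, chromothripsis calling by
joint copy-number/LOH state transitions per chromosome arm, and amplicon
allele-fraction profiling around an anchor gene.

Chromothripsis here is an operational definition: an arm is flagged when the
number of transitions between adjacent segments whose joint state
``(total_cn, loh)`` differs reaches a threshold (default 10).  Segments
straddling the centromere are split there, so a shattered p arm is never
diluted by a quiet q arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeModel

__all__ = [
    "CopyNumberSegment",
    "AmpliconProfile",
    "fraction_genome_altered",
    "chromothripsis_scan",
    "count_arm_transitions",
    "recurrent_regions",
    "event_coverage",
    "homozygous_deletions",
    "amplicon_profile",
    "amplicon_mutation_excess",
    "expected_het_baf",
    "count_cnvs",
]


@dataclass(frozen=True)
class CopyNumberSegment:
    """A genomic interval with total and minor-allele copy number.

    1-based inclusive coordinates.  LOH is derived: minor copy number zero
    while at least one copy remains.  By convention ``minor_cn <= total_cn/2``.
    """

    sample: str
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: start > end")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds major allele for total_cn {self.total_cn}"
            )

    @property
    def loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1

    @property
    def major_cn(self) -> int:
        return self.total_cn - self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, bool]:
        """Joint copy-number/LOH state used for transition counting."""
        return (self.total_cn, self.loh)

    @property
    def altered(self) -> bool:
        return self.total_cn != 2 or self.loh


def _by_chrom(segments: Iterable[CopyNumberSegment]) -> dict[str, list[CopyNumberSegment]]:
    out: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        out.setdefault(s.chrom, []).append(s)
    for segs in out.values():
        segs.sort(key=lambda s: s.start)
    return out


def _check_tiling(segments: Sequence[CopyNumberSegment], genome: GenomeModel) -> None:
    """Require segments to tile every chromosome exactly; report gaps/overlaps."""
    per_chrom = _by_chrom(segments)
    problems = []
    for chrom in genome.chrom_names:
        length = genome.chrom_length(chrom)
        segs = per_chrom.get(chrom, [])
        cursor = 1
        for s in segs:
            if s.start > cursor:
                problems.append(f"{chrom}:{cursor}-{s.start - 1} gap")
            elif s.start < cursor:
                problems.append(f"{chrom}:{s.start}-{cursor - 1} overlap")
            cursor = s.end + 1
        if cursor <= length:
            problems.append(f"{chrom}:{cursor}-{length} gap")
    if problems:
        raise ValueError("segments do not tile the genome: " + "; ".join(problems[:10]))


def fraction_genome_altered(
    segments: Sequence[CopyNumberSegment], genome: GenomeModel
) -> float:
    """Percent of the genome with total copy number != 2 or LOH, in [0, 100].

    Copy-neutral LOH counts as altered.  Segments must tile the genome; gaps
    or overlaps raise with the offending intervals listed.
    """
    _check_tiling(segments, genome)
    altered = sum(s.length for s in segments if s.altered)
    return 100.0 * altered / genome.total_length


def count_cnvs(segments: Sequence[CopyNumberSegment]) -> int:
    """Number of discrete non-diploid-heterozygous segments."""
    return sum(1 for s in segments if s.altered)


# ---------------------------------------------------------------------------
# Chromothripsis
# ---------------------------------------------------------------------------

def _split_at_centromere(
    segments: Sequence[CopyNumberSegment], genome: GenomeModel
) -> dict[tuple[str, str], list[CopyNumberSegment]]:
    """Per-arm segment lists, splitting any centromere-straddling segment."""
    arms: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for s in segments:
        cen = genome.centromeres[s.chrom]
        pieces = []
        if s.end <= cen:
            pieces.append((s, "p"))
        elif s.start > cen:
            pieces.append((s, "q"))
        else:
            pieces.append((CopyNumberSegment(s.sample, s.chrom, s.start, cen,
                                             s.total_cn, s.minor_cn), "p"))
            pieces.append((CopyNumberSegment(s.sample, s.chrom, cen + 1, s.end,
                                             s.total_cn, s.minor_cn), "q"))
        for piece, arm in pieces:
            arms.setdefault((s.chrom, arm), []).append(piece)
    for segs in arms.values():
        segs.sort(key=lambda s: s.start)
    return arms


def count_arm_transitions(arm_segments: Sequence[CopyNumberSegment]) -> int:
    """Adjacent-segment boundaries where the joint (total_cn, LOH) state changes.

    Equals the number of distinct joint-state runs minus one.
    """
    segs = sorted(arm_segments, key=lambda s: s.start)
    return sum(1 for a, b in zip(segs, segs[1:]) if a.state != b.state)


def chromothripsis_scan(
    segments: Sequence[CopyNumberSegment],
    genome: GenomeModel,
    min_transitions: int = 10,
) -> list[dict]:
    """Scan every chromosome arm of one sample for chromothripsis.

    Returns one record per arm with at least one segment:
    ``{"sample", "chrom", "arm", "n_transitions", "flagged"}``, flagged iff
    ``n_transitions >= min_transitions``.
    """
    sample = segments[0].sample if segments else ""
    arms = _split_at_centromere(segments, genome)
    out = []
    for chrom in genome.chrom_names:
        for arm in ("p", "q"):
            segs = arms.get((chrom, arm))
            if not segs:
                continue
            n = count_arm_transitions(segs)
            out.append({
                "sample": sample, "chrom": chrom, "arm": arm,
                "n_transitions": n, "flagged": n >= min_transitions,
            })
    return out


# ---------------------------------------------------------------------------
# Cohort recurrence and homozygous deletions
# ---------------------------------------------------------------------------

_EVENT_PREDICATES = {
    "gain": lambda s: s.total_cn > 2,
    "loss": lambda s: s.total_cn < 2,
    "loh": lambda s: s.loh,
}


def event_coverage(
    cohort_segments: dict[str, Sequence[CopyNumberSegment]],
    event_type: str = "gain",
) -> list[tuple[str, int, int, int]]:
    """Per-interval sample counts for an event type, by boundary sweep.

    Returns elementary intervals ``(chrom, start, end, n_samples)`` (1-based
    inclusive) of constant count, covering exactly the union of event-bearing
    segments; within each interval every base is covered by the same
    ``n_samples`` distinct samples.
    """
    try:
        pred = _EVENT_PREDICATES[event_type]
    except KeyError:
        raise ValueError(f"unknown event type {event_type!r}") from None

    events: dict[str, list[tuple[int, int, str]]] = {}
    for sample, segs in cohort_segments.items():
        for s in segs:
            if pred(s):
                # 0-based half-open for the sweep
                events.setdefault(s.chrom, []).append((s.start - 1, s.end, sample))

    out: list[tuple[str, int, int, int]] = []
    for chrom in sorted(events):
        evs = events[chrom]
        bounds = sorted({b for s0, e0, _ in evs for b in (s0, e0)})
        for lo, hi in zip(bounds, bounds[1:]):
            n = len({smp for s0, e0, smp in evs if s0 <= lo and e0 >= hi})
            if n > 0:
                out.append((chrom, lo + 1, hi, n))
    return out


def recurrent_regions(
    cohort_segments: dict[str, Sequence[CopyNumberSegment]],
    min_samples: int = 6,
    event_type: str = "gain",
) -> list[tuple[str, int, int, int]]:
    """Maximal regions where >= ``min_samples`` samples carry the event type.

    Adjacent constant-count intervals (from :func:`event_coverage`) meeting
    the threshold are merged; the reported ``n_samples`` is the peak count
    within the merged region.  Coordinates are 1-based inclusive.
    """
    regions: list[tuple[str, int, int, int]] = []
    for chrom, start, end, n in event_coverage(cohort_segments, event_type):
        if n < min_samples:
            continue
        if regions and regions[-1][0] == chrom and regions[-1][2] + 1 == start:
            c, s0, _, n0 = regions[-1]
            regions[-1] = (c, s0, end, max(n0, n))
        else:
            regions.append((chrom, start, end, n))
    return regions


def homozygous_deletions(
    segments: Sequence[CopyNumberSegment], genome: GenomeModel
) -> list[tuple[str, str]]:
    """(sample, gene) pairs where a total_cn=0 segment overlaps the gene >= 1 bp."""
    out = []
    for s in segments:
        if s.total_cn != 0:
            continue
        for g in genome.genes_overlapping(s.chrom, s.start, s.end):
            out.append((s.sample, g.name))
    return sorted(set(out))


# ---------------------------------------------------------------------------
# Amplicon profiling
# ---------------------------------------------------------------------------

def expected_het_baf(total_cn: int, major_cn: int, purity: float = 1.0) -> float:
    """Expected tumour B-allele fraction of a germline het on the major allele.

    With purity ``p`` and a het site at major:minor = ``major_cn`` :
    ``total_cn - major_cn`` in tumour cells, the expected major-allele BAF is
    ``(p*major + (1-p)*1) / (p*total + (1-p)*2)``; at purity 1 this is
    ``major_cn / total_cn``.
    """
    if total_cn < 1:
        raise ValueError("total_cn must be >= 1")
    return (purity * major_cn + (1 - purity) * 1) / (purity * total_cn + (1 - purity) * 2)


@dataclass
class AmpliconProfile:
    """Allele-fraction profile of an amplified region around an anchor gene."""

    sample: str
    anchor_gene: str
    chrom: str
    start: int
    end: int
    rows: list[dict] = field(default_factory=list)  # position, class, tumour_baf, constit_baf
    cn_track: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, total_cn)
    asymmetry: float | None = None
    empty_reason: str | None = None

    @property
    def is_empty(self) -> bool:
        return self.empty_reason is not None


def amplicon_profile(
    variants: Sequence,
    germline_hets: Sequence[dict],
    segments: Sequence[CopyNumberSegment],
    anchor_gene: str,
    genome: GenomeModel,
    cn_threshold: int = 3,
) -> AmpliconProfile:
    """Profile the amplified region containing ``anchor_gene``.

    The region is the maximal contiguous run of segments with
    ``total_cn >= cn_threshold`` containing the anchor.  Rows hold the tumour
    BAF/VAF of every germline het and somatic variant in the region; the
    asymmetry statistic is the mean of ``|tumour BAF - 0.5|`` over germline
    hets (0 for a balanced region, ``major/CN - 0.5`` under pure asymmetric
    amplification).

    ``germline_hets`` are dicts with keys chrom, pos, tumour_baf and
    optionally constitutional_baf.
    """
    gene = genome.gene(anchor_gene)
    sample = segments[0].sample if segments else ""
    segs = sorted((s for s in segments if s.chrom == gene.chrom), key=lambda s: s.start)
    anchor_idx = [
        i for i, s in enumerate(segs)
        if s.total_cn >= cn_threshold and s.start <= gene.end and s.end >= gene.start
    ]
    if not anchor_idx:
        return AmpliconProfile(
            sample=sample, anchor_gene=anchor_gene, chrom=gene.chrom, start=0, end=0,
            empty_reason=f"no segment with total_cn >= {cn_threshold} overlaps {anchor_gene}",
        )
    lo = hi = anchor_idx[0]
    while lo > 0 and segs[lo - 1].total_cn >= cn_threshold and segs[lo - 1].end + 1 == segs[lo].start:
        lo -= 1
    while hi + 1 < len(segs) and segs[hi + 1].total_cn >= cn_threshold and segs[hi].end + 1 == segs[hi + 1].start:
        hi += 1
    region = segs[lo:hi + 1]
    start, end = region[0].start, region[-1].end

    prof = AmpliconProfile(
        sample=sample, anchor_gene=anchor_gene, chrom=gene.chrom, start=start, end=end,
        cn_track=[(s.start, s.end, s.total_cn) for s in region],
    )
    het_bafs = []
    for h in germline_hets:
        if h["chrom"] == gene.chrom and start <= h["pos"] <= end:
            prof.rows.append({
                "position": h["pos"], "class": "germline-het",
                "tumour_baf": h["tumour_baf"],
                "constitutional_baf": h.get("constitutional_baf", 0.5),
            })
            het_bafs.append(h["tumour_baf"])
    for v in variants:
        if v.chrom == gene.chrom and start <= v.pos <= end and v.vaf is not None:
            prof.rows.append({
                "position": v.pos, "class": "somatic",
                "tumour_baf": v.vaf, "constitutional_baf": 0.0,
            })
    prof.rows.sort(key=lambda r: r["position"])
    if het_bafs:
        prof.asymmetry = float(np.mean(np.abs(np.asarray(het_bafs) - 0.5)))
    else:
        prof.empty_reason = None  # region valid, asymmetry undefined
        prof.asymmetry = None
    return prof


def amplicon_mutation_excess(
    variants: Sequence,
    region: tuple[str, int, int],
    genome: GenomeModel,
    segments: Sequence[CopyNumberSegment] | None = None,
) -> dict:
    """Observed/expected mutation-density ratios inside an amplified region.

    The background density is computed from the whole genome excluding the
    region, separately for SNVs and indels.  Alongside the raw ratios, a
    copy-number-adjusted expectation (background density scaled by mean
    total_cn / 2 over the region) is reported: an observed density above even
    that expectation cannot be accounted for by the extra copies alone.
    """
    chrom, start, end = region
    if end < start:
        raise ValueError("zero-length region")
    region_len = end - start + 1
    bg_len = genome.total_length - region_len
    in_region = lambda v: v.chrom == chrom and start <= v.pos <= end

    obs = {"SNV": 0, "indel": 0}
    bg = {"SNV": 0, "indel": 0}
    for v in variants:
        (obs if in_region(v) else bg)[v.variant_class] += 1

    mean_cn = 2.0
    if segments:
        w = [(min(s.end, end) - max(s.start, start) + 1, s.total_cn)
             for s in segments if s.chrom == chrom and s.start <= end and s.end >= start]
        tot = sum(x for x, _ in w)
        if tot > 0:
            mean_cn = sum(x * cn for x, cn in w) / tot

    out = {"region": region, "mean_total_cn": mean_cn}
    for cls, key in (("SNV", "snv"), ("indel", "indel")):
        bg_density = bg[cls] / bg_len
        expected = bg_density * region_len
        cn_expected = expected * mean_cn / 2.0
        ratio = obs[cls] / expected if expected > 0 else float("inf") if obs[cls] else float("nan")
        out[f"{key}_observed"] = obs[cls]
        out[f"{key}_expected"] = expected
        out[f"{key}_ratio"] = ratio
        out[f"{key}_cn_adjusted_expected"] = cn_expected
        out[f"{key}_exceeds_cn_expectation"] = obs[cls] > cn_expected
    return out
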