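"""Somatic variant records, record-level filters, and file IO.

The record-level filters implement the call-set hygiene applied before any
downstream analysis: a minimum read depth of 10 at the site, removal of
known polymorphisms at population frequency > 0.05, removal of exact-match
blacklisted sites seen in unrelated constitutional genomes (systematic
pipeline artefacts), and — for inter-chromosomal breakpoint predictions — a
confidence-score / supporting-read-pair / in-gene filter.

All filters are pure, order-preserving and idempotent; records are never
mutated.  Missing annotations never cause removal here: a variant with no
population frequency is kept, because there is no evidence against it.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .genome import GenomeModel

__all__ = [
    "SomaticVariant",
    "BreakpointRecord",
    "depth_filter",
    "population_filter",
    "blacklist_filter",
    "filter_breakpoints",
    "read_somatic_vcf",
    "write_somatic_vcf",
    "read_annotation_table",
    "read_segments",
    "write_segments",
    "read_breakpoints",
]

CONSEQUENCES = frozenset(
    {"missense", "stop-gain", "stop-loss", "splice-site", "frameshift",
     "synonymous", "UTR", "intergenic"}
)
TRUNCATING = frozenset({"stop-gain", "stop-loss", "frameshift"})
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call with read counts and functional annotations.

    ``pos`` is 1-based.  ``variant_class`` is ``"SNV"`` iff ref and alt are
    both single bases, else ``"indel"``; it is derived automatically when not
    given.  Optional scores, when present, must lie in [0, 1].
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None
    alt_reads: int | None = None
    variant_class: str = field(default="")
    gene: str | None = None
    consequence: str | None = None
    sift_score: float | None = None
    polyphen2_score: float | None = None
    population_af: float | None = None
    loh_flag: bool | None = None
    quality_flag: bool = True  # False marks calls failing manual/visual review

    def __post_init__(self) -> None:
        inferred = "SNV" if (len(self.ref) == 1 and len(self.alt) == 1) else "indel"
        if not self.variant_class:
            object.__setattr__(self, "variant_class", inferred)
        elif self.variant_class != inferred:
            raise ValueError(
                f"{self.key}: class {self.variant_class!r} inconsistent with alleles"
            )
        if self.depth is not None and self.alt_reads is not None:
            if not 0 <= self.alt_reads <= self.depth:
                raise ValueError(f"{self.key}: alt_reads {self.alt_reads} > depth {self.depth}")
        for name in ("sift_score", "polyphen2_score", "population_af"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.key}: {name}={v} outside [0,1]")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"{self.key}: unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    @property
    def vaf(self) -> float | None:
        if self.depth in (None, 0) or self.alt_reads is None:
            return None
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class BreakpointRecord:
    """A predicted inter-chromosomal breakpoint (BreakDancer-style)."""

    sample: str
    chromA: str
    posA: int
    chromB: str
    posB: int
    score: float
    supporting_read_pairs: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.supporting_read_pairs < 0:
            raise ValueError("supporting_read_pairs must be >= 0")


# ---------------------------------------------------------------------------
# Record-level filters
# ---------------------------------------------------------------------------

def depth_filter(
    variants: Sequence[SomaticVariant], min_depth: int = 10
) -> list[SomaticVariant]:
    """Keep variants at sites covered by at least ``min_depth`` reads (inclusive)."""
    return [v for v in variants if v.depth is not None and v.depth >= min_depth]


def population_filter(
    variants: Sequence[SomaticVariant], max_af: float = 0.05
) -> list[SomaticVariant]:
    """Drop variants at population frequency strictly above ``max_af``.

    Records with no population frequency annotation are retained.
    """
    return [v for v in variants if v.population_af is None or v.population_af <= max_af]


def blacklist_filter(
    variants: Sequence[SomaticVariant],
    blacklist: set[tuple[str, int, str, str]],
) -> list[SomaticVariant]:
    """Drop variants whose (chrom, pos, ref, alt) key is blacklisted exactly."""
    return [v for v in variants if v.key not in blacklist]


def filter_breakpoints(
    records: Sequence[BreakpointRecord],
    genome: GenomeModel,
    min_score: float = 99,
    min_pairs: int = 10,
    require_in_gene: bool = True,
) -> list[BreakpointRecord]:
    """Confidence filter for breakpoint predictions.

    Keeps records with score >= ``min_score`` and at least ``min_pairs``
    supporting read pairs; with ``require_in_gene`` at least one anchor must
    fall inside a catalogued gene.
    """
    out = []
    for r in records:
        if r.score < min_score or r.supporting_read_pairs < min_pairs:
            continue
        if require_in_gene:
            if not (genome.genes_at(r.chromA, r.posA) or genome.genes_at(r.chromB, r.posB)):
                continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# VCF IO (VCF 4.2, FORMAT DP and AD)
# ---------------------------------------------------------------------------

def write_somatic_vcf(
    variants: Sequence[SomaticVariant], path: str | os.PathLike, genome: GenomeModel | None = None
) -> None:
    """Write one sample's variants to a VCF 4.2 file with DP and AD."""
    variants = list(variants)
    samples = {v.sample for v in variants}
    if len(samples) > 1:
        raise ValueError(f"one sample per VCF; got {sorted(samples)}")
    sample = samples.pop() if samples else "SAMPLE"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if genome is not None:
            for name, length in genome.chromosomes:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            if v.depth is None or v.alt_reads is None:
                fmt, val = "GT", "0/1"
            else:
                fmt = "GT:DP:AD"
                val = f"0/1:{v.depth}:{v.depth - v.alt_reads},{v.alt_reads}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t{fmt}\t{val}\n"
            )


def read_somatic_vcf(
    path: str | os.PathLike,
    annotation_table: pd.DataFrame | None = None,
    sample: str | None = None,
) -> list[SomaticVariant]:
    """Read a single-sample VCF into :class:`SomaticVariant` records.

    ``annotation_table`` (see :func:`read_annotation_table`) is joined on
    (chrom, pos, ref, alt); unannotated records keep empty annotation fields.
    Missing DP/AD leaves the read-count fields unset.  Multi-allelic sites are
    split into one record per alt allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    vcf_samples = vcf.samples
    if sample is None:
        sample = vcf_samples[0] if vcf_samples else "SAMPLE"

    ann: dict[tuple[str, int, str, str], dict] = {}
    if annotation_table is not None:
        for row in annotation_table.itertuples(index=False):
            ann[(str(row.chrom), int(row.pos), row.ref, row.alt)] = {
                "gene": None if pd.isna(row.gene) else str(row.gene),
                "consequence": None if pd.isna(row.consequence) else str(row.consequence),
                "sift_score": None if pd.isna(row.sift) else float(row.sift),
                "polyphen2_score": None if pd.isna(row.polyphen2) else float(row.polyphen2),
                "population_af": None if pd.isna(row.pop_af) else float(row.pop_af),
            }

    out: list[SomaticVariant] = []
    for rec in vcf:
        try:
            depth = int(rec.format("DP")[0][0]) if rec.format("DP") is not None else None
        except (TypeError, ValueError):
            depth = None
        ad = rec.format("AD")
        for i, alt in enumerate(rec.ALT):
            alt_reads = None
            if ad is not None:
                try:
                    alt_reads = int(ad[0][i + 1])
                except (IndexError, TypeError, ValueError):
                    alt_reads = None
            if alt_reads is not None and depth is None:
                depth = int(sum(x for x in ad[0] if x >= 0))
            extra = ann.get((str(rec.CHROM), int(rec.POS), rec.REF, alt), {})
            out.append(
                SomaticVariant(
                    sample=sample,
                    chrom=str(rec.CHROM),
                    pos=int(rec.POS),
                    ref=rec.REF,
                    alt=alt,
                    depth=depth,
                    alt_reads=alt_reads,
                    **extra,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Tabular IO: annotation, segments, breakpoints (gzip-tolerant TSVs)
# ---------------------------------------------------------------------------

def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


_ANN_COLS = ["chrom", "pos", "ref", "alt", "gene", "consequence", "sift", "polyphen2", "pop_af"]


def read_annotation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Annotation TSV: chrom pos ref alt gene consequence sift polyphen2 pop_af."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    missing = set(_ANN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


_SEG_COLS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn", "loh_flag"]


def write_segments(segments: Iterable, path: str | os.PathLike) -> None:
    """Write copy-number segments (1-based inclusive) as TSV."""
    rows = [
        {
            "sample": s.sample, "chrom": s.chrom, "start": s.start, "end": s.end,
            "total_cn": s.total_cn, "minor_cn": s.minor_cn, "loh_flag": int(s.loh),
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_segments(path: str | os.PathLike) -> list:
    from .cna import CopyNumberSegment

    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(_SEG_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return [
        CopyNumberSegment(
            sample=r.sample, chrom=r.chrom, start=int(r.start), end=int(r.end),
            total_cn=int(r.total_cn), minor_cn=int(r.minor_cn),
        )
        for r in df.itertuples(index=False)
    ]


def read_breakpoints(path: str | os.PathLike) -> list[BreakpointRecord]:
    """Breakpoint TSV: sample chromA posA chromB posB score num_read_pairs."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chromA": str, "chromB": str, "sample": str})
    return [
        BreakpointRecord(
            sample=r.sample, chromA=r.chromA, posA=int(r.posA),
            chromB=r.chromB, posB=int(r.posB), score=float(r.score),
            supporting_read_pairs=int(r.num_read_pairs),
        )
        for r in df.itertuples(index=False)
    ]
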